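"""2-fold cross-validation and the value of the asymmetry channel.

Cross-validates the default 4-channel model on a small easy suite, then
repeats without the ASYM channel to show the ablation ordering.
"""

from srcstroke import PatchConfig, PipelineConfig, cross_validate, generate_suite, prepare_study

suite = generate_suite("easy", 8, seed=23)
studies = [ph.study for ph in suite]
prepared = [prepare_study(s) for s in studies]

full = cross_validate(studies, PipelineConfig(), seed=3, prepared=prepared)
no_asym = cross_validate(
    studies,
    PipelineConfig(patch=PatchConfig(channels=("b0", "dwi", "adc"))),
    seed=3,
    prepared=prepared,
)

print("per-study DC (4 channels):", [round(x, 3) for x in full["DC"]])
print(f"mean DC, 4 channels (B0,DWI,ADC,ASYM): {full['DC'].mean():.4f}")
print(f"mean DC, 3 channels (ASYM off)       : {no_asym['DC'].mean():.4f}")

# Every study is segmented once as a held-out case.  Dropping the
# asymmetry channel costs Dice even on easy phantoms - the mirrored
# contrast is complementary evidence the raw channels do not carry.
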