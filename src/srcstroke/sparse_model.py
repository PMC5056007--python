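"""Elastic-net sparse coding, dictionary learning and residue classification.

The sparse code of a sample s against a dictionary D solves

    min_a  1/2 ||s - D a||_2^2 + lambda1 ||a||_1 + lambda2/2 ||a||_2^2,

the elastic net: the L1 term enforces sparsity, the L2 term stabilises the
code when atoms are strongly correlated (as patches from homogeneous tissue
are).  Setting lambda2 = 0 recovers the plain lasso.  The solver is cyclic
coordinate descent, vectorised across samples sharing the dictionary.

Per-class dictionaries (infarct / normal) are learned by alternating sparse
coding with a block coordinate-descent atom update under a unit-L2-norm
constraint, either over the full sample set ("batch", with warm-started
codes so the objective is non-increasing across epochs) or with mini-batch
stochastic approximation ("online") for large sample sets.

Classification is sparse-representation classification (SRC): encode the
sample against the concatenated global dictionary and assign the class whose
sub-dictionary reconstructs it with the smaller residue.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volumes_io import ValidationError

__all__ = [
    "ElasticNetParams",
    "unit_normalize",
    "ClassDictionary",
    "SparseCode",
    "sparse_encode",
    "sparse_encode_batch",
    "enet_objective",
    "dictionary_objective",
    "learn_dictionary",
    "classify_sample",
    "classify_batch",
]


@dataclass(frozen=True)
class ElasticNetParams:
    """Elastic-net solver parameters.

    lambda1
        L1 (sparsity) weight, >= 0.
    lambda2
        L2 (stability) weight, >= 0.
    max_iter
        Maximum full coordinate-descent cycles.
    tol
        Convergence tolerance on the maximum coefficient change per cycle.
    """

    lambda1: float = 0.3
    lambda2: float = 0.1
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValidationError("lambda1 and lambda2 must be >= 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class ClassDictionary:
    """Per-class atom matrix with unit-L2-norm columns.

    ``objective_trace`` holds the epoch-level learning objective when the
    dictionary was learned in batch mode (None for online learning).
    """

    atoms: np.ndarray  # (m, K)
    class_label: str
    objective_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=np.float64)
        if self.atoms.ndim != 2 or self.atoms.size == 0:
            raise ValidationError("atoms must be a nonempty m x K matrix")
        norms = np.linalg.norm(self.atoms, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValidationError("dictionary columns must have unit L2 norm")

    @property
    def m(self) -> int:
        return self.atoms.shape[0]

    @property
    def K(self) -> int:
        return self.atoms.shape[1]


@dataclass
class SparseCode:
    """Result of one elastic-net solve."""

    coefficients: np.ndarray
    objective: float
    nnz: int
    converged: bool = True


def unit_normalize(X: np.ndarray, axis: int = 1) -> np.ndarray:
    """Scale vectors to unit L2 norm (zero vectors pass through unchanged).

    Elastic-net weights are calibrated for unit-scale samples; on raw
    [0, 255]-scale patch features the penalties would be negligible relative
    to the fit term and the class residues become ill-conditioned.
    """
    X = np.asarray(X, dtype=np.float64)
    n = np.linalg.norm(X, axis=axis, keepdims=True)
    n = np.where(n == 0, 1.0, n)
    return X / n


def enet_objective(s: np.ndarray, D: np.ndarray, a: np.ndarray, p: ElasticNetParams) -> float:
    r = s - D @ a
    return float(
        0.5 * (r @ r) + p.lambda1 * np.abs(a).sum() + 0.5 * p.lambda2 * (a @ a)
    )


def _cd_solve(S: np.ndarray, D: np.ndarray, p: ElasticNetParams, A0=None):
    """Cyclic coordinate descent on columns of S (m, n) sharing D (m, K).

    Returns (A, converged) with A of shape (K, n).  Warm start from ``A0``
    when given.  Each coordinate update is the exact elastic-net minimiser
    for that coordinate, so the objective never increases.
    """
    m, n = S.shape
    K = D.shape[1]
    g = np.einsum("ij,ij->j", D, D)  # per-atom squared norms
    denom = g + p.lambda2
    if A0 is None:
        A = np.zeros((K, n))
        R = S.copy()
    else:
        A = np.array(A0, dtype=np.float64)
        R = S - D @ A
    lam1 = p.lambda1
    order = np.arange(K)
    converged = False
    for _ in range(p.max_iter):
        max_delta = 0.0
        for j in order:
            if denom[j] <= 0.0:
                continue
            rho = D[:, j] @ R + g[j] * A[j]
            new = np.sign(rho) * np.maximum(np.abs(rho) - lam1, 0.0) / denom[j]
            delta = new - A[j]
            md = np.abs(delta).max() if n else 0.0
            if md > 0.0:
                R -= np.outer(D[:, j], delta)
                A[j] = new
                if md > max_delta:
                    max_delta = md
        if max_delta <= p.tol:
            converged = True
            break
    return A, converged


def sparse_encode(s: np.ndarray, D: np.ndarray, p: ElasticNetParams) -> SparseCode:
    """Solve the elastic net for a single sample.

    Returns the coefficient vector, the achieved objective value and the
    number of nonzeros.  Deterministic for fixed inputs; if the coordinate
    cycle does not reach ``p.tol`` within ``p.max_iter`` iterations the best
    iterate is returned with ``converged=False``.
    """
    s = np.asarray(s, dtype=np.float64).ravel()
    D = np.asarray(D, dtype=np.float64)
    if D.ndim != 2 or D.size == 0:
        raise ValidationError("dictionary must be a nonempty m x K matrix")
    if s.size != D.shape[0]:
        raise ValidationError(f"sample dim {s.size} != atom dim {D.shape[0]}")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(D))):
        raise ValidationError("non-finite inputs")
    A, conv = _cd_solve(s[:, None], D, p)
    a = A[:, 0]
    if not conv:
        warnings.warn("elastic-net solve did not converge; returning best iterate", stacklevel=2)
    return SparseCode(
        coefficients=a,
        objective=enet_objective(s, D, a, p),
        nnz=int(np.count_nonzero(a)),
        converged=conv,
    )


def sparse_encode_batch(S: np.ndarray, D: np.ndarray, p: ElasticNetParams, A0=None) -> np.ndarray:
    """Sparse-code many samples at once; S is (m, n), returns A (K, n)."""
    S = np.asarray(S, dtype=np.float64)
    A, _ = _cd_solve(S, D, p, A0=A0)
    return A


def dictionary_objective(S: np.ndarray, D: np.ndarray, A: np.ndarray, p: ElasticNetParams) -> float:
    """Mean per-sample elastic-net objective over the sample set (columns of S)."""
    R = S - D @ A
    n = S.shape[1]
    return float(
        (0.5 * np.sum(R * R) + p.lambda1 * np.abs(A).sum() + 0.5 * p.lambda2 * np.sum(A * A)) / n
    )


def _update_atoms(D: np.ndarray, B: np.ndarray, G: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Block coordinate descent on atoms under the unit-norm constraint.

    B = S A^T (m, K) and G = A A^T (K, K) are the sufficient statistics of
    the quadratic fit term.  Each column update is the exact minimiser of
    the column subproblem on the unit sphere, so the fit term never
    increases.  Atoms with no support (G_jj ~ 0) are left unchanged.
    """
    D = D.copy()
    K = D.shape[1]
    for j in range(K):
        if G[j, j] <= eps:
            continue
        u = B[:, j] - D @ G[:, j] + G[j, j] * D[:, j]
        nu = np.linalg.norm(u)
        if nu > eps:
            D[:, j] = u / nu
    return D


def _init_atoms(S: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded draw of K distinct samples, unit-normalised; random-pad if short."""
    m, n = S.shape
    norms = np.linalg.norm(S, axis=0)
    usable = np.nonzero(norms > 1e-12)[0]
    # deduplicate identical columns so initial atoms are distinct
    if usable.size:
        uniq = np.unique(np.round(S[:, usable], 9).T, axis=0, return_index=True)[1]
        usable = usable[np.sort(uniq)]
    k_take = min(K, usable.size)
    D = np.empty((m, K))
    if k_take:
        pick = rng.choice(usable, size=k_take, replace=False)
        D[:, :k_take] = S[:, pick] / norms[pick]
    if k_take < K:
        warnings.warn(
            f"only {k_take} distinct samples for {K} atoms; padding with random atoms",
            stacklevel=3,
        )
        pad = rng.standard_normal((m, K - k_take))
        D[:, k_take:] = pad / np.linalg.norm(pad, axis=0)
    return D


def learn_dictionary(
    samples: np.ndarray,
    K: int,
    p: ElasticNetParams,
    epochs: int = 10,
    seed: int = 0,
    mode: str = "online",
    batch_size: int = 256,
    class_label: str = "unlabelled",
) -> ClassDictionary:
    """Learn a K-atom dictionary minimising the mean elastic-net objective.

    Parameters
    ----------
    samples
        (n, m) array, one feature vector per row.
    mode
        "batch": full alternation with warm-started codes; the epoch-level
        objective is non-increasing (up to float round-off).  "online":
        mini-batch stochastic approximation with accumulated sufficient
        statistics — much faster on large n, monotone only in expectation.
    seed
        Drives initial atom selection and mini-batch shuffling; identical
        seeds reproduce the dictionary bit-for-bit.
    """
    S = np.asarray(samples, dtype=np.float64).T  # (m, n)
    if not np.all(np.isfinite(S)):
        raise ValidationError("non-finite samples")
    m, n = S.shape
    if K <= 0:
        raise ValidationError("K must be >= 1")
    if n < K:
        warnings.warn(f"fewer samples ({n}) than atoms ({K})", stacklevel=2)
    rng = np.random.default_rng(seed)
    D = _init_atoms(S, K, rng)

    trace = None
    if mode == "batch":
        # warm-started codes + exact column updates => the epoch objective
        # can never increase
        A = None
        trace = []
        for _ in range(epochs):
            A = sparse_encode_batch(S, D, p, A0=A)
            B = S @ A.T
            G = A @ A.T
            D = _update_atoms(D, B, G)
            trace.append(dictionary_objective(S, D, A, p))
        trace = np.asarray(trace)
    elif mode == "online":
        Gacc = np.zeros((K, K))
        Bacc = np.zeros((m, K))
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                Sb = S[:, idx]
                A = sparse_encode_batch(Sb, D, p)
                Gacc += A @ A.T
                Bacc += Sb @ A.T
                D = _update_atoms(D, Bacc, Gacc)
    else:
        raise ValidationError(f"unknown learning mode {mode!r}")

    return ClassDictionary(atoms=D, class_label=class_label, objective_trace=trace)


def _class_residues(S: np.ndarray, D_list, A: np.ndarray) -> np.ndarray:
    """Residues ||s - D_i delta_i(a)||^2 per class, shape (n_classes, n)."""
    res = np.empty((len(D_list), S.shape[1]))
    lo = 0
    for i, Di in enumerate(D_list):
        hi = lo + Di.shape[1]
        R = S - Di @ A[lo:hi]
        res[i] = np.einsum("ij,ij->j", R, R)
        lo = hi
    return res


def classify_sample(
    s: np.ndarray,
    D_infarct: ClassDictionary,
    D_normal: ClassDictionary,
    p: ElasticNetParams,
) -> tuple[str, dict[str, float]]:
    """SRC decision for one sample: class with the lower reconstruction residue.

    The sample is encoded once against the concatenated global dictionary;
    each class residue uses only that class's coefficients.  Ties go to
    "normal" (conservative toward false positives).
    """
    labels, res = classify_batch(np.asarray(s, dtype=np.float64).reshape(-1, 1), D_infarct, D_normal, p)
    return (
        "infarct" if labels[0] else "normal",
        {"infarct": float(res[0, 0]), "normal": float(res[1, 0])},
    )


def classify_batch(
    S: np.ndarray,
    D_infarct: ClassDictionary,
    D_normal: ClassDictionary,
    p: ElasticNetParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised SRC over samples in the columns of S (m, n).

    Returns (labels, residues): labels is a boolean array (True = infarct),
    residues is (2, n) ordered (infarct, normal).
    """
    if D_infarct.m != D_normal.m:
        raise ValidationError("class dictionaries disagree on feature dimension")
    if S.shape[0] != D_infarct.m:
        raise ValidationError(
            f"feature dim {S.shape[0]} != dictionary atom dim {D_infarct.m}"
        )
    D = np.concatenate([D_infarct.atoms, D_normal.atoms], axis=1)
    A = sparse_encode_batch(S, D, p)
    res = _class_residues(S, [D_infarct.atoms, D_normal.atoms], A)
    labels = res[0] < res[1]  # tie -> normal
    return labels, res
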