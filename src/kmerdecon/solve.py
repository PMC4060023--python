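"""Non-negative least squares with Tikhonov regularization.

The abundance model is min ½‖Ax − b‖² subject to x ≥ 0, where A is the
column-normalized reference k-mer matrix and b the metagenome composition
vector.  The solver is a Lawson–Hanson active-set method: it maintains a
passive set P of strictly positive coordinates, solves the unconstrained
least-squares problem on P, and exchanges variables until the
Karush–Kuhn–Tucker conditions hold — zero gradient on P, non-positive
gradient on the active (zero) set.

Reference genomes with near-identical composition make A ill-conditioned;
a ridge penalty ½λ²‖x‖² (equivalently, augmenting A with λ·I rows and b
with zeros) stabilizes the split among such columns.  λ = 0 reduces exactly
to plain NNLS.  The simplex constraint Σx = 1 is imposed afterwards by
normalization, so reported abundances are relative DNA proportions.

Determinism: entering-variable ties are broken by lowest column index, the
boundary-hitting variable is the first index attaining the minimal step,
and the anti-cycling tolerance is 10·ε·‖A‖₂.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_LAMBDA",
    "AbundanceProfile",
    "nnls",
    "solve_nnls",
    "solve_regularized",
    "normalize_to_simplex",
    "threshold_profile",
    "fit_profile",
]

#: Default ridge strength, relative to a column-normalized A.  Small enough
#: not to perturb well-conditioned problems, nonzero to split mass evenly
#: among (near-)collinear reference columns.
DEFAULT_LAMBDA = 1e-4

_SUM_TOL = 1e-9


@dataclass
class AbundanceProfile:
    """Genome-level relative abundances on the probability simplex.

    ``abundances`` is non-negative and sums to 1, unless ``degenerate`` is
    set (empty input or all-zero raw solution), in which case it is all
    zeros.  ``residual_norm`` is ‖Ax − b‖ at the raw (pre-normalization)
    solution on the original, unaugmented system.
    """

    genome_ids: list[str]
    abundances: np.ndarray
    residual_norm: float
    lambda_used: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        a = np.asarray(self.abundances, dtype=np.float64)
        if (a < 0).any():
            raise ValueError("abundances must be non-negative")
        s = a.sum()
        if self.degenerate:
            if s != 0:
                raise ValueError("degenerate profile must be all-zero")
        elif abs(s - 1.0) > _SUM_TOL:
            raise ValueError(f"abundances sum to {s!r}, expected 1")
        self.abundances = a


def nnls(
    A: np.ndarray,
    b: np.ndarray,
    tol: float | None = None,
    max_iter: int | None = None,
) -> tuple[np.ndarray, float]:
    """Lawson–Hanson active-set NNLS: min ½‖Ax−b‖², x ≥ 0.

    Returns ``(x, residual_norm)``.  Deterministic for fixed inputs; raises
    ``ValueError`` on non-finite entries.
    """
    A = np.ascontiguousarray(A, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64).ravel()
    if A.ndim != 2 or A.shape[0] != b.size:
        raise ValueError(f"incompatible shapes A{A.shape}, b({b.size},)")
    if not np.isfinite(A).all() or not np.isfinite(b).all():
        raise ValueError("non-finite entries in A or b")
    m, n = A.shape
    if tol is None:
        tol = 10.0 * np.finfo(np.float64).eps * np.linalg.norm(A, 2)
    if max_iter is None:
        max_iter = max(30, 10 * n)

    x = np.zeros(n, dtype=np.float64)
    passive = np.zeros(n, dtype=bool)

    outer = 0
    while outer < max_iter:
        outer += 1
        w = A.T @ (b - A @ x)
        w_cand = np.where(passive, -np.inf, w)
        j = int(np.argmax(w_cand))  # ties -> lowest index
        if not np.isfinite(w_cand[j]) or w_cand[j] <= tol:
            break
        passive[j] = True
        inner = 0
        while True:
            inner += 1
            cols = np.flatnonzero(passive)
            zsol, *_ = np.linalg.lstsq(A[:, cols], b, rcond=None)
            if zsol.size and zsol.min() > 0 or not zsol.size:
                x = np.zeros(n, dtype=np.float64)
                x[cols] = zsol
                break
            z = np.zeros(n, dtype=np.float64)
            z[cols] = zsol
            drop = passive & (z <= 0)
            idx = np.flatnonzero(drop)
            denom = x[idx] - z[idx]
            safe = denom > 0
            if not safe.any() or inner > max_iter:
                # numerical dead end: discard the offending variables
                passive[idx] = False
                x[idx] = 0.0
                x = np.maximum(x, 0.0)
                break
            steps = x[idx][safe] / denom[safe]
            pos = int(np.argmin(steps))  # first index on ties
            alpha = float(steps[pos])
            x = x + alpha * (z - x)
            i_star = int(idx[safe][pos])
            x[i_star] = 0.0
            passive[i_star] = False
            x[~passive] = 0.0
            np.maximum(x, 0.0, out=x)
    return x, float(np.linalg.norm(A @ x - b))


#: Alias matching the operation vocabulary used elsewhere in the package.
solve_nnls = nnls


def solve_regularized(
    A: np.ndarray, b: np.ndarray, lam: float
) -> tuple[np.ndarray, float]:
    """Ridge-stabilized NNLS: min ½‖Ax−b‖² + ½λ²‖x‖², x ≥ 0.

    Implemented by augmenting A with λ·I rows and b with zeros, then solving
    plain NNLS.  ``λ = 0`` is exactly :func:`nnls`.  The returned residual
    norm is measured on the original system, ‖Ax − b‖.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    if lam == 0:
        return nnls(A, b)
    A = np.ascontiguousarray(A, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64).ravel()
    n = A.shape[1]
    A_aug = np.vstack([A, lam * np.eye(n)])
    b_aug = np.concatenate([b, np.zeros(n)])
    x, _ = nnls(A_aug, b_aug)
    return x, float(np.linalg.norm(A @ x - b))


def normalize_to_simplex(raw: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale a non-negative vector to sum 1.

    Returns ``(abundances, degenerate)``; an all-zero input stays all-zero
    with the degenerate flag set.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if (raw < 0).any():
        raise ValueError("raw abundances must be non-negative")
    s = raw.sum()
    if s > 0:
        return raw / s, False
    return np.zeros_like(raw), True


def threshold_profile(
    profile: AbundanceProfile, min_abundance: float
) -> AbundanceProfile:
    """Zero out entries below ``min_abundance`` and renormalize to sum 1.

    A reporting convenience: cutoff 0 is the identity; a cutoff exceeding
    every entry yields a degenerate all-zero profile.
    """
    if not 0 <= min_abundance < 1:
        raise ValueError(
            f"min_abundance must be in [0, 1), got {min_abundance}"
        )
    if min_abundance == 0 or profile.degenerate:
        return replace(profile)
    kept = np.where(profile.abundances >= min_abundance,
                    profile.abundances, 0.0)
    abundances, degenerate = normalize_to_simplex(kept)
    return replace(profile, abundances=abundances, degenerate=degenerate)


def fit_profile(
    db,
    metagenome,
    lam: float = DEFAULT_LAMBDA,
    min_abundance: float = 0.0,
) -> AbundanceProfile:
    """Full genome-level fit: regularized NNLS, simplex normalization, cutoff.

    ``db`` is a ReferenceMatrix, ``metagenome`` a MetagenomeVector over the
    same k-mer space (or a bare frequency vector of length m).
    """
    b = getattr(metagenome, "frequencies", metagenome)
    space = getattr(metagenome, "space", None)
    if space is not None and space != db.space:
        raise ValueError(
            f"metagenome k={space.k} does not match reference k={db.k}"
        )
    raw, rnorm = solve_regularized(db.matrix, b, lam)
    abundances, degenerate = normalize_to_simplex(raw)
    profile = AbundanceProfile(
        genome_ids=list(db.genome_ids),
        abundances=abundances,
        residual_norm=rnorm,
        lambda_used=lam,
        degenerate=degenerate,
    )
    return threshold_profile(profile, min_abundance)
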