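"""Entropy-based selection of the incompatibility model (Step 1).

For a binary phenotype D with case proportion p, the Shannon entropy in bits
is ``H(D) = -p log2 p - (1-p) log2 (1-p)``.  Each incompatibility model splits
families into "high risk" (classification in the model's risk classes) and
"low risk" groups; the conditional entropy

    H(D | MFGI) = H(D | high) P(high) + H(D | low) P(low)

measures how much phenotype uncertainty remains after the split, and the
information-gain ratio

    R = (H(D) - H(D | MFGI)) / H(D)

is the fraction of phenotype entropy the model explains.  The model with the
largest R over the 11 candidates is selected only if a permutation test shows
the maximum is unlikely under no association: phenotype labels are permuted B
times, the maximum ratio ``R_b^max`` over all 11 models is recorded per
permutation, and the empirical p-value is the fraction of permuted maxima
strictly exceeding the observed one.  If that p-value is not below the cutoff
tau, the full model (Model 11) is used instead.

Permutations are evaluated through an exact sufficient-statistic identity:
every ratio depends on a permuted label vector only through the per-class
case counts, whose joint permutation distribution is multivariate
hypergeometric over the five classification classes.  Resampling those counts
is therefore identical in distribution to shuffling labels, and one count
draw serves all 11 models jointly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .genotype_models import (
    MISMATCH_CLASSES,
    PairClass,
    class_counts,
    code_incompatibility,
    standard_models,
)

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "binary_entropy",
    "conditional_entropy",
    "information_gain_ratio",
    "compute_all_ratios",
    "permutation_select",
    "pooled_permutation_select",
]

# (11, 5) membership matrix over class indices (COMPATIBLE, M1, M2, M3, M4)
_MODEL_MASK = np.zeros((11, 5), dtype=np.int64)
for _i, _m in enumerate(standard_models()):
    for _c in _m.risk_classes:
        _MODEL_MASK[_i, int(_c)] = 1


def binary_entropy(p_case: float) -> float:
    """Entropy in bits of a Bernoulli(p) outcome, with 0·log2(0) := 0."""
    p = float(p_case)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p_case must lie in [0, 1], got {p}")
    if p in (0.0, 1.0):
        return 0.0
    return float(-p * np.log2(p) - (1.0 - p) * np.log2(1.0 - p))


def _entropy_vec(p: np.ndarray) -> np.ndarray:
    """Elementwise binary entropy, safe at 0 and 1."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    inside = (p > 0.0) & (p < 1.0)
    q = p[inside]
    out[inside] = -q * np.log2(q) - (1.0 - q) * np.log2(1.0 - q)
    return out


def conditional_entropy(y, risk) -> float:
    """Weighted within-group entropy H(D | risk) in bits.

    Groups are risk=1 and risk=0; an empty group contributes zero with
    weight zero.
    """
    y = np.asarray(y, dtype=np.float64)
    risk = np.asarray(risk)
    if y.shape != risk.shape:
        raise ValueError("y and risk must have equal length")
    n = y.size
    n1 = int(np.count_nonzero(risk))
    n0 = n - n1
    h = 0.0
    if n1:
        h += (n1 / n) * binary_entropy(float(y[risk == 1].mean()))
    if n0:
        h += (n0 / n) * binary_entropy(float(y[risk == 0].mean()))
    return h


def information_gain_ratio(y, risk) -> float:
    """R = 1 - H(D|MFGI)/H(D); zero by convention when H(D) = 0."""
    y = np.asarray(y, dtype=np.float64)
    h_d = binary_entropy(float(y.mean()))
    if h_d == 0.0:
        return 0.0
    r = 1.0 - conditional_entropy(y, risk) / h_d
    # clip tiny negative rounding residue
    return float(min(max(r, 0.0), 1.0))


def _ratios_from_counts(n_k: np.ndarray, c_k: np.ndarray) -> np.ndarray:
    """Information-gain ratios of the 11 models from per-class counts.

    ``n_k``: (5,) family counts per class; ``c_k``: (..., 5) case counts per
    class (a trailing batch axis is allowed).  Returns ratios of shape
    (..., 11).
    """
    n = int(n_k.sum())
    c_k = np.asarray(c_k, dtype=np.float64)
    c = c_k.sum(axis=-1, keepdims=True)
    h_d = _entropy_vec(c / n)  # (...,1)

    n_high = _MODEL_MASK @ n_k.astype(np.float64)          # (11,)
    n_low = n - n_high
    c_high = c_k @ _MODEL_MASK.T                           # (...,11)
    c_low = c - c_high

    with np.errstate(invalid="ignore", divide="ignore"):
        p_high = np.where(n_high > 0, c_high / np.where(n_high > 0, n_high, 1), 0.0)
        p_low = np.where(n_low > 0, c_low / np.where(n_low > 0, n_low, 1), 0.0)
    h_cond = (n_high / n) * _entropy_vec(p_high) + (n_low / n) * _entropy_vec(p_low)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = np.where(h_d > 0, 1.0 - h_cond / np.where(h_d > 0, h_d, 1.0), 0.0)
    return np.clip(ratios, 0.0, 1.0)


def compute_all_ratios(y, classifications) -> np.ndarray:
    """Information-gain ratios for the 11 standard models, in model order."""
    y = np.asarray(y, dtype=np.int64)
    n_k, c_k = class_counts(classifications, y)
    return _ratios_from_counts(n_k, c_k.astype(np.float64))


@dataclass(frozen=True)
class SelectionConfig:
    """Settings for the permutation-guarded selection step.

    ``tau`` must be at least 1/``n_permutations`` or the empirical p-value
    could never fall below it.  ``add_one_correction`` switches to the
    (1 + #exceedances)/(1 + B) estimator; the plain strict-exceedance
    fraction is the default.
    """

    n_permutations: int = 10_000
    tau: float = 1e-4
    seed: Optional[int | np.random.Generator] = None
    add_one_correction: bool = False

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if not 0.0 < self.tau < 1.0:
            raise ValueError("tau must lie in (0, 1)")
        if self.tau < 1.0 / self.n_permutations:
            raise ValueError(
                f"tau={self.tau} < 1/B={1.0 / self.n_permutations}: "
                "the permutation p-value could never fall below tau"
            )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of Step 1 for one locus."""

    ratios: np.ndarray
    candidate_id: int
    r_max: float
    p_empirical: Optional[float]
    final_model_id: int
    defaulted: bool


def _candidate(ratios: np.ndarray) -> tuple[int, float]:
    """Maximal-ratio model; ties go to the fewest risk classes then lowest id.

    The standard models are already ordered singletons < pairs < full set,
    so first-argmax in id order implements the tie-break.
    """
    idx = int(np.argmax(ratios))
    return idx + 1, float(ratios[idx])


def _permuted_max_ratios(n_k: np.ndarray, n_cases: int, b: int,
                         rng: np.random.Generator) -> np.ndarray:
    """B draws of max-over-models ratio under phenotype-label permutation."""
    perm_counts = rng.multivariate_hypergeometric(n_k, n_cases, size=b)
    return _ratios_from_counts(n_k, perm_counts).max(axis=1)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def permutation_select(y, classifications, config: SelectionConfig) -> SelectionResult:
    """Select the analysis model for one locus via the permutation guard.

    Degenerate inputs (single-class phenotype, or no mismatched pairs so
    every ratio is zero) skip the permutation and default to Model 11.
    """
    y = np.asarray(y, dtype=np.int64)
    n_k, c_k = class_counts(classifications, y)
    ratios = _ratios_from_counts(n_k, c_k.astype(np.float64))
    candidate_id, r_max = _candidate(ratios)

    n_cases = int(c_k.sum())
    if n_cases in (0, int(n_k.sum())) or r_max == 0.0:
        return SelectionResult(ratios, candidate_id, r_max, None, 11, True)

    rng = _as_rng(config.seed)
    null_max = _permuted_max_ratios(n_k, n_cases, config.n_permutations, rng)
    exceed = int(np.count_nonzero(null_max > r_max))
    if config.add_one_correction:
        p_emp = (1 + exceed) / (1 + config.n_permutations)
    else:
        p_emp = exceed / config.n_permutations
    if p_emp < config.tau:
        return SelectionResult(ratios, candidate_id, r_max, p_emp, candidate_id, False)
    return SelectionResult(ratios, candidate_id, r_max, p_emp, 11, False)


def pooled_permutation_select(
    y,
    classifications_per_locus: Sequence,
    n_permutations_per_locus: int = 20,
    tau: float = 0.05,
    seed=None,
) -> tuple[list[SelectionResult], np.ndarray]:
    """Genome-wide selection with a pooled permutation null.

    Returns the per-locus selection results together with the pooled null
    sample itself (up to L x B maximum ratios; degenerate loci contribute
    none).

    For each permutation and each locus the maximum ratio over the 11 models
    is computed; all L x B values are pooled into a single null sample, and
    each locus's empirical p-value is the fraction of pooled values strictly
    exceeding its own observed maximum.  Pooling trades per-locus resolution
    for far fewer permutations per locus and folds the multiplicity of the
    scan into the null.  Degenerate loci contribute nothing to the pool and
    default to Model 11.

    Families classified MENDEL_ERROR or MISSING at a locus are excluded from
    that locus only (per-marker deletion): each locus's entropies, observed
    maximum, and null draws use its remaining families.
    """
    y = np.asarray(y, dtype=np.int64)
    if len(classifications_per_locus) < 1:
        raise ValueError("need at least one locus")
    rng = _as_rng(seed)

    observed: list[tuple[np.ndarray, int, float, bool]] = []
    pooled: list[np.ndarray] = []
    for cls in classifications_per_locus:
        # families flagged MENDEL_ERROR/MISSING at this locus fall outside the
        # five analysis classes and are excluded from this locus only
        n_k, c_k = class_counts(cls, y)
        ratios = _ratios_from_counts(n_k, c_k.astype(np.float64))
        cand, r_max = _candidate(ratios)
        n_cases = int(c_k.sum())
        degenerate = n_cases in (0, int(n_k.sum())) or r_max == 0.0
        observed.append((ratios, cand, r_max, degenerate))
        if not degenerate:
            pooled.append(_permuted_max_ratios(n_k, n_cases, n_permutations_per_locus, rng))

    null_pool = np.concatenate(pooled) if pooled else np.empty(0)
    results = []
    for ratios, cand, r_max, degenerate in observed:
        if degenerate or null_pool.size == 0:
            results.append(SelectionResult(ratios, cand, r_max, None, 11, True))
            continue
        p_emp = float(np.count_nonzero(null_pool > r_max) / null_pool.size)
        final = cand if p_emp < tau else 11
        results.append(SelectionResult(ratios, cand, r_max, p_emp, final, False))
    return results, null_pool
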