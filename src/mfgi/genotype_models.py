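"""Mother-offspring genotype pairs, mismatch classes, and incompatibility models.

Genotypes at a bi-allelic locus are coded as counts of the minor allele A:
``aa = 0``, ``Aa = 1``, ``AA = 2``.  A Mendelian-consistent mother-offspring
pair either shares a genotype or differs by one allele copy; the four possible
mismatched combinations are the classes M1-M4:

====  =========  ===========
class  mother     offspring
====  =========  ===========
M1     AA (2)     Aa (1)
M2     Aa (1)     AA (2)
M3     Aa (1)     aa (0)
M4     aa (0)     Aa (1)
====  =========  ===========

The pairs (AA, aa) and (aa, AA) are impossible under Mendelian inheritance
and are flagged as genotyping errors.  An *incompatibility model* declares a
non-empty subset of {M1..M4} "high risk"; eleven biologically plausible
subsets are enumerated by :func:`standard_models`, Model 11 being the union
of all four classes (the "full model").
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "PairClass",
    "MFGIModel",
    "classify_pair",
    "classify_pairs",
    "standard_models",
    "get_model",
    "code_incompatibility",
    "recode_to_minor_allele",
    "RecodeResult",
    "MendelianErrorInData",
]

#: Sentinel integer for a missing genotype in integer-coded arrays.
MISSING: int = -1


class PairClass(IntEnum):
    """Classification of one mother-offspring genotype pair."""

    COMPATIBLE = 0
    M1 = 1
    M2 = 2
    M3 = 3
    M4 = 4
    MENDEL_ERROR = 5
    MISSING = 6


# 3x3 lookup, rows = maternal genotype, cols = offspring genotype
_CLASS_TABLE = np.array(
    [
        # offspring:   0 (aa)                1 (Aa)          2 (AA)
        [PairClass.COMPATIBLE, PairClass.M4, PairClass.MENDEL_ERROR],  # mother aa
        [PairClass.M3, PairClass.COMPATIBLE, PairClass.M2],            # mother Aa
        [PairClass.MENDEL_ERROR, PairClass.M1, PairClass.COMPATIBLE],  # mother AA
    ],
    dtype=np.int8,
)

#: The four mismatch classes, in index order.
MISMATCH_CLASSES = (PairClass.M1, PairClass.M2, PairClass.M3, PairClass.M4)


class MendelianErrorInData(ValueError):
    """Raised when a Mendelian-impossible pair reaches incompatibility coding."""


@dataclass(frozen=True)
class MFGIModel:
    """One incompatibility model: a set of mismatch classes declared high risk.

    Parameters
    ----------
    model_id
        Identifier 1-11 for the standard models; any positive integer for
        user-defined ones.
    risk_classes
        Non-empty subset of {M1, M2, M3, M4}.
    description
        Free-text account of the biological scenario the model encodes.
    """

    model_id: int
    risk_classes: frozenset
    description: str = ""

    def __post_init__(self) -> None:
        if not self.risk_classes:
            raise ValueError("risk_classes must be non-empty")
        bad = set(self.risk_classes) - set(MISMATCH_CLASSES)
        if bad:
            raise ValueError(f"risk_classes must be mismatch classes, got {bad}")


_STANDARD: tuple[MFGIModel, ...] = (
    MFGIModel(1, frozenset({PairClass.M1}),
              "Mother has 1 more copy of allele A than the heterozygous offspring"),
    MFGIModel(2, frozenset({PairClass.M2}),
              "Offspring has 1 more copy of allele A than the heterozygous mother"),
    MFGIModel(3, frozenset({PairClass.M3}),
              "Mother has risk allele A that the offspring does not"),
    MFGIModel(4, frozenset({PairClass.M4}),
              "Offspring has risk allele A that the mother does not"),
    MFGIModel(5, frozenset({PairClass.M1, PairClass.M2}),
              "Mother-offspring pair has 3 copies of A allele"),
    MFGIModel(6, frozenset({PairClass.M1, PairClass.M3}),
              "Mother has 1 more copy of A allele"),
    MFGIModel(7, frozenset({PairClass.M1, PairClass.M4}),
              "Offspring has an allele that the mother does not"),
    MFGIModel(8, frozenset({PairClass.M2, PairClass.M3}),
              "Mother has an allele that the offspring does not"),
    MFGIModel(9, frozenset({PairClass.M2, PairClass.M4}),
              "Offspring has 1 more copy of the A allele"),
    MFGIModel(10, frozenset({PairClass.M3, PairClass.M4}),
              "Mother-offspring pair possesses 3 copies of allele a"),
    MFGIModel(11, frozenset(MISMATCH_CLASSES),
              "All possible mismatched maternal-fetal genotype combinations"),
)


def standard_models() -> list[MFGIModel]:
    """Return the 11 standard incompatibility models, in id order.

    Models 1-4 are the singleton classes, 5-10 the six pairs, and 11 the
    full set {M1, M2, M3, M4}.
    """
    return list(_STANDARD)


def get_model(model_id: int) -> MFGIModel:
    """Return the standard model with the given id (1-11)."""
    if not 1 <= model_id <= 11:
        raise ValueError(f"standard model ids are 1..11, got {model_id}")
    return _STANDARD[model_id - 1]


def classify_pair(g_m: int, g_o: int) -> PairClass:
    """Classify a single mother-offspring genotype pair.

    Either genotype missing yields :attr:`PairClass.MISSING`; the
    Mendelian-impossible combinations (2,0) and (0,2) yield
    :attr:`PairClass.MENDEL_ERROR`.
    """
    if g_m == MISSING or g_o == MISSING:
        return PairClass.MISSING
    if g_m not in (0, 1, 2) or g_o not in (0, 1, 2):
        raise ValueError(f"genotypes must be 0, 1, 2 or missing; got ({g_m}, {g_o})")
    return PairClass(_CLASS_TABLE[g_m, g_o])


def classify_pairs(g_m: np.ndarray, g_o: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_pair` over integer genotype arrays.

    Missing genotypes are coded as :data:`MISSING` (-1).  Returns an int8
    array of :class:`PairClass` values.
    """
    g_m = np.asarray(g_m)
    g_o = np.asarray(g_o)
    if g_m.shape != g_o.shape:
        raise ValueError("maternal and offspring arrays must have equal shape")
    valid_vals = {-1, 0, 1, 2}
    if not set(np.unique(g_m)).issubset(valid_vals) or not set(np.unique(g_o)).issubset(valid_vals):
        raise ValueError("genotype arrays may only contain -1 (missing), 0, 1, 2")
    out = np.full(g_m.shape, PairClass.MISSING, dtype=np.int8)
    ok = (g_m >= 0) & (g_o >= 0)
    out[ok] = _CLASS_TABLE[g_m[ok], g_o[ok]]
    return out


def code_incompatibility(model: MFGIModel, classifications: Sequence | np.ndarray) -> np.ndarray:
    """Binary incompatibility indicator G_ic under ``model``.

    ``values[i] = 1`` iff family *i*'s classification lies in the model's
    risk classes.  Mendelian-error or missing classifications must be
    filtered out upstream; their presence raises :class:`MendelianErrorInData`
    / :class:`ValueError` naming the offending families.
    """
    cls = np.asarray(classifications, dtype=np.int8)
    bad = np.flatnonzero(cls == PairClass.MENDEL_ERROR)
    if bad.size:
        raise MendelianErrorInData(
            f"Mendelian-inconsistent pairs at indices {bad[:10].tolist()}"
            f"{'...' if bad.size > 10 else ''}; exclude them before coding"
        )
    if np.any(cls == PairClass.MISSING):
        idx = np.flatnonzero(cls == PairClass.MISSING)
        raise ValueError(f"missing classifications at indices {idx[:10].tolist()}")
    mask = np.zeros(7, dtype=np.int8)
    for c in model.risk_classes:
        mask[c] = 1
    return mask[cls]


@dataclass(frozen=True)
class RecodeResult:
    """Outcome of orienting a genotype column pair to minor-allele counts."""

    maternal: np.ndarray
    offspring: np.ndarray
    maf: float
    flipped: bool
    monomorphic: bool


def recode_to_minor_allele(maternal, offspring) -> RecodeResult:
    """Orient genotype codes so they count the minor allele.

    The allele frequency is estimated from the non-missing *maternal*
    genotypes (mothers are population draws; offspring are not independent
    of them).  If the counted allele has frequency > 0.5 both columns are
    flipped ``g -> 2 - g``; a frequency of exactly 0.5 is left unchanged.
    Monomorphic columns (maf 0 after orientation) are returned unchanged
    with the ``monomorphic`` flag set.
    """
    g_m = np.asarray(maternal, dtype=np.int64).copy()
    g_o = np.asarray(offspring, dtype=np.int64).copy()
    obs = g_m[g_m != MISSING]
    if obs.size == 0:
        return RecodeResult(g_m, g_o, 0.0, False, True)
    freq = float(obs.mean() / 2.0)
    flipped = freq > 0.5
    if flipped:
        m_miss, o_miss = g_m == MISSING, g_o == MISSING
        g_m = 2 - g_m
        g_o = 2 - g_o
        g_m[m_miss] = MISSING
        g_o[o_miss] = MISSING
        freq = 1.0 - freq
    return RecodeResult(g_m, g_o, freq, flipped, monomorphic=(freq == 0.0))


def class_counts(classifications: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-class family and case counts over the five analysis classes.

    Returns ``(n_k, c_k)`` of length 5, indexed (COMPATIBLE, M1, M2, M3, M4),
    where ``n_k`` counts families in class *k* and ``c_k`` those with y = 1.
    These counts are a sufficient statistic for every entropy quantity the
    selection step computes.
    """
    cls = np.asarray(classifications, dtype=np.int8)
    y = np.asarray(y)
    n_k = np.bincount(cls, minlength=5)[:5].astype(np.int64)
    c_k = np.bincount(cls, weights=y, minlength=5)[:5].astype(np.int64)
    return n_k, c_k
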