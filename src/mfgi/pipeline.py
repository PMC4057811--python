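"""Per-SNP scanning of mother-offspring pair tables.

The canonical input is a wide tab-separated table with one row per family:

    family_id  phenotype  [cov_*...]  <snp>_m  <snp>_o  ...

``phenotype`` is 0/1, genotype cells are allele counts {0, 1, 2} or a
missing token (default ``NA``), and any column starting with ``cov_`` is a
numeric covariate entering every regression.  SNP columns come in
``<snp>_m`` (maternal) / ``<snp>_o`` (offspring) pairs.

``scan`` runs the full per-SNP analysis: minor-allele orientation, per-SNP
exclusion of families with a missing genotype or a Mendelian-inconsistent
pair, entropy-based model selection (per-locus or pooled permutation null),
the likelihood-ratio test under the selected model, and the full-model
(Model 11) baseline test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association_test import LogisticSpec, lrt_incompatibility
from .entropy_selection import (
    SelectionConfig,
    SelectionResult,
    permutation_select,
    pooled_permutation_select,
)
from .genotype_models import (
    MISSING,
    PairClass,
    classify_pairs,
    code_incompatibility,
    get_model,
    recode_to_minor_allele,
)

__all__ = [
    "PairTable",
    "read_pair_table",
    "filter_samples_by_missingness",
    "scan",
    "write_results",
]

SCAN_COLUMNS = [
    "snp_id", "n_used", "n_excluded_mendel", "n_excluded_missing", "maf",
    "selected_model", "permutation_p", "p_two_step", "p_full_model",
    "p_bonferroni", "odds_ratio", "ci_lower", "ci_upper", "flags",
]


@dataclass(frozen=True)
class PairTable:
    """Validated mother-offspring pair data.

    ``genotypes`` holds the integer-coded SNP columns (missing = -1) named
    ``<snp>_m`` / ``<snp>_o``; ``covariates`` is the numeric covariate frame
    (possibly empty).
    """

    family_id: pd.Series
    phenotype: np.ndarray
    genotypes: pd.DataFrame
    covariates: pd.DataFrame
    snp_ids: list

    @property
    def n_families(self) -> int:
        return len(self.phenotype)

    def snp_arrays(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """Integer maternal/offspring genotype columns for one SNP."""
        return (self.genotypes[f"{snp_id}_m"].to_numpy(),
                self.genotypes[f"{snp_id}_o"].to_numpy())


def read_pair_table(path, missing_token: str = "NA") -> PairTable:
    """Read and validate a wide pair table from TSV.

    Malformed genotype cells and non-binary phenotypes are rejected with the
    offending row and column named.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"family_id", "phenotype"}
    if not required.issubset(df.columns):
        raise ValueError(f"missing required columns: {sorted(required - set(df.columns))}")

    pheno_raw = df["phenotype"]
    bad_pheno = ~pheno_raw.isin({"0", "1"})
    if bad_pheno.any():
        row = int(df.index[bad_pheno][0])
        raise ValueError(f"non-binary phenotype {pheno_raw.iloc[row]!r} at row {row}")
    phenotype = pheno_raw.astype(np.int64).to_numpy()

    cov_cols = [c for c in df.columns if c.startswith("cov_")]
    covariates = df[cov_cols].astype(np.float64) if cov_cols else pd.DataFrame(index=df.index)

    geno_cols = [c for c in df.columns
                 if c not in required and c not in cov_cols
                 and (c.endswith("_m") or c.endswith("_o"))]
    snp_ids: list[str] = []
    for c in geno_cols:  # first-appearance order
        sid = c[:-2]
        if sid not in snp_ids:
            snp_ids.append(sid)
    for sid in snp_ids:
        for suffix in ("_m", "_o"):
            if f"{sid}{suffix}" not in df.columns:
                raise ValueError(f"SNP {sid!r} lacks its {suffix} column")

    geno = {}
    for col in geno_cols:
        raw = df[col]
        vals = raw.where(raw != missing_token, "-1")
        ok = vals.isin({"-1", "0", "1", "2"})
        if not ok.all():
            row = int(df.index[~ok][0])
            raise ValueError(f"malformed genotype {raw.iloc[row]!r} at row {row}, column {col!r}")
        geno[col] = vals.astype(np.int64)
    genotypes = pd.DataFrame(geno, index=df.index)

    return PairTable(df["family_id"], phenotype, genotypes, covariates, snp_ids)


def filter_samples_by_missingness(table: PairTable,
                                  threshold: float = 0.5) -> tuple[PairTable, list]:
    """Drop families with too many missing genotypes.

    A family is removed when the fraction of missing genotypes among its
    maternal columns *or* among its offspring columns strictly exceeds
    ``threshold``.  Returns the filtered table and the removed family ids.
    """
    m_cols = [c for c in table.genotypes.columns if c.endswith("_m")]
    o_cols = [c for c in table.genotypes.columns if c.endswith("_o")]
    if not m_cols:
        return table, []
    miss_m = (table.genotypes[m_cols] == MISSING).mean(axis=1).to_numpy()
    miss_o = (table.genotypes[o_cols] == MISSING).mean(axis=1).to_numpy()
    drop = (miss_m > threshold) | (miss_o > threshold)
    removed = table.family_id[drop].tolist()
    keep = ~drop
    filtered = PairTable(
        table.family_id[keep].reset_index(drop=True),
        table.phenotype[keep],
        table.genotypes.loc[keep].reset_index(drop=True),
        table.covariates.loc[keep].reset_index(drop=True),
        list(table.snp_ids),
    )
    return filtered, removed


@dataclass
class _Locus:
    """One SNP's oriented genotypes and classifications, pre-exclusion."""

    snp_id: str
    cls_full: np.ndarray  # all families; MENDEL_ERROR/MISSING marked
    keep: np.ndarray      # analysis families (bool mask)
    g_m: np.ndarray       # kept families only
    g_o: np.ndarray
    maf: float
    flags: list


def _prepare_locus(table: PairTable, snp_id: str) -> _Locus:
    raw_m, raw_o = table.snp_arrays(snp_id)
    rec = recode_to_minor_allele(raw_m, raw_o)
    cls_full = classify_pairs(rec.maternal, rec.offspring)
    keep = (cls_full != PairClass.MISSING) & (cls_full != PairClass.MENDEL_ERROR)
    flags = []
    if rec.monomorphic:
        flags.append("monomorphic")
    if rec.flipped:
        flags.append("flipped")
    return _Locus(snp_id, cls_full, keep, rec.maternal[keep], rec.offspring[keep],
                  rec.maf, flags)


def scan(
    table: PairTable,
    config: Optional[SelectionConfig] = None,
    covariate_names: Optional[Sequence[str]] = None,
    pooled: bool = False,
    select: bool = True,
) -> pd.DataFrame:
    """Per-SNP two-step analysis of a pair table.

    Returns one row per SNP with the selected model, the permutation p-value
    of the selection step, the two-step LRT p-value, the full-model baseline
    p-value, a convenience Bonferroni column, and the odds ratio with 95% CI
    under the analysis model.  With ``pooled=True`` the selection null pools
    the per-permutation maximum ratios across all loci (the genome-wide
    scheme, ``n_permutations`` per locus); otherwise each locus gets its own
    permutation null.  With ``select=False`` Model 11 is used everywhere and
    the two p-value columns coincide.
    """
    cfg = config if config is not None else SelectionConfig(n_permutations=20, tau=0.05)
    if covariate_names is None:
        covariate_names = list(table.covariates.columns)
    cov_all = table.covariates[list(covariate_names)].to_numpy() if covariate_names else None

    loci = [_prepare_locus(table, sid) for sid in table.snp_ids]
    rng = np.random.default_rng(cfg.seed) if not isinstance(cfg.seed, np.random.Generator) \
        else cfg.seed

    pooled_sel: dict[str, SelectionResult] = {}
    if select and pooled:
        results, _ = pooled_permutation_select(
            table.phenotype, [ld.cls_full for ld in loci],
            n_permutations_per_locus=cfg.n_permutations,
            tau=cfg.tau, seed=rng,
        )
        pooled_sel = {ld.snp_id: res for ld, res in zip(loci, results)}

    rows = [_scan_one(table, ld, cfg, cov_all, select, pooled_sel if pooled else None, rng)
            for ld in loci]
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def _scan_one(table, ld: _Locus, cfg, cov_all, select, pooled_sel, rng):
    flags = list(ld.flags)
    y = table.phenotype[ld.keep]
    cls = ld.cls_full[ld.keep]
    n_used = int(ld.keep.sum())
    base = {
        "snp_id": ld.snp_id, "n_used": n_used,
        "n_excluded_mendel": int((ld.cls_full == PairClass.MENDEL_ERROR).sum()),
        "n_excluded_missing": int((ld.cls_full == PairClass.MISSING).sum()),
        "maf": ld.maf,
    }
    if n_used < 2 or y.min() == y.max():
        flags.append("skipped")
        return {**base, "selected_model": np.nan, "permutation_p": np.nan,
                "p_two_step": np.nan, "p_full_model": np.nan,
                "p_bonferroni": np.nan, "odds_ratio": np.nan,
                "ci_lower": np.nan, "ci_upper": np.nan, "flags": ";".join(flags)}

    cov = cov_all[ld.keep] if cov_all is not None else None

    if select:
        sel = pooled_sel[ld.snp_id] if pooled_sel is not None \
            else permutation_select(y, cls, replace(cfg, seed=rng))
        final_id = sel.final_model_id
        perm_p = sel.p_empirical
        if sel.defaulted:
            flags.append("defaulted")
    else:
        final_id, perm_p = 11, None

    res_sel = _locus_lrt(y, cls, ld, final_id, cov)
    res_full = res_sel if final_id == 11 else _locus_lrt(y, cls, ld, 11, cov)
    if not res_sel.converged:
        flags.append("separation")

    return {
        **base,
        "selected_model": final_id,
        "permutation_p": np.nan if perm_p is None else perm_p,
        "p_two_step": res_sel.p_value,
        "p_full_model": res_full.p_value,
        "p_bonferroni": min(1.0, res_sel.p_value * len(table.snp_ids))
        if np.isfinite(res_sel.p_value) else np.nan,
        "odds_ratio": res_sel.odds_ratio,
        "ci_lower": res_sel.ci_lower,
        "ci_upper": res_sel.ci_upper,
        "flags": ";".join(flags),
    }


def _locus_lrt(y, cls, ld: _Locus, model_id: int, cov):
    g_ic = code_incompatibility(get_model(model_id), cls)
    spec = LogisticSpec(y.astype(np.int64), ld.g_m.astype(np.int64),
                        ld.g_o.astype(np.int64), g_ic, cov)
    return lrt_incompatibility(spec, selected_model_id=model_id)


def write_results(results: pd.DataFrame, path) -> None:
    """Write scan results as TSV with 4-decimal p-values and odds ratios."""
    out = results.copy()
    for col in ("maf", "permutation_p", "p_two_step", "p_full_model",
                "p_bonferroni", "odds_ratio", "ci_lower", "ci_upper"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.4f}")
    out.to_csv(path, sep="\t", index=False)
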