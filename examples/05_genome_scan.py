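"""Multi-SNP scan with a pooled permutation null.

Builds a wide pair table (one row per family, one maternal/offspring column
pair per SNP) with one signal SNP among nulls, applies the case-study-style
filters, and scans every SNP with the two-step procedure.  The permutation
maxima are pooled across loci (B per locus), the scheme used for scans of
hundreds of candidate SNPs.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from mfgi import SelectionConfig, filter_samples_by_missingness, read_pair_table, scan, write_results
from mfgi.simulation import PopulationConfig, SCENARIOS, ScenarioConfig, draw_sample, simulate_population

rng = np.random.default_rng(27)
n_families, n_snps = 700, 12

frames = {"family_id": [f"fam{i:03d}" for i in range(n_families)]}
signal = ScenarioConfig("signal", alpha_m=0.0, alpha_o=0.0, alpha_ic=1.3,
                        generating_model_id=1)
pheno = None
for j in range(n_snps):
    scen = signal if j == 3 else SCENARIOS["I"]
    pop = simulate_population(PopulationConfig(30_000, maf=0.25), scen, rng=rng)
    s = draw_sample(pop, n_families, rng)
    if pheno is None or j == 3:
        pheno = s.y  # phenotype driven by the signal locus
    frames[f"snp{j:02d}_m"] = s.g_m
    frames[f"snp{j:02d}_o"] = s.g_o
frames["phenotype"] = pheno
frames["cov_age"] = np.round(rng.normal(29, 6, n_families), 1)

workdir = Path(tempfile.mkdtemp(prefix="mfgi_scan_"))
path = workdir / "scan_input.tsv"
pd.DataFrame(frames).to_csv(path, sep="\t", index=False)

table = read_pair_table(path)
table, removed = filter_samples_by_missingness(table, threshold=0.5)
print(f"{table.n_families} families retained ({len(removed)} removed for missingness)")

results = scan(table, SelectionConfig(n_permutations=20, tau=0.05, seed=28),
               covariate_names=["cov_age"], pooled=True)
write_results(results, workdir / "scan_results.tsv")
print(f"(full results written to {workdir / 'scan_results.tsv'})")
cols = ["snp_id", "selected_model", "permutation_p", "p_two_step",
        "p_full_model", "odds_ratio", "flags"]
print(results[cols].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
# snp03 carries a Model-1 effect: it attains the smallest two-step p-value,
# with Model 1 as its analysis model, while the full-model baseline dilutes
# it towards insignificance.  Most null SNPs default to Model 11; with the
# deliberately loose tau = 0.05 an occasional null locus is selected too
# (the cost of hunting for as many true positives as possible), and a
# "separation" flag marks fits whose Wald quantities are untrustworthy.
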