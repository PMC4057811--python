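"""Liability-threshold simulation of mother-offspring populations.

A population of N families is generated in three stages:

1. *Parents.*  Maternal and paternal genotypes are independent multinomial
   draws from the same genotype law (symmetric mating): Hardy-Weinberg
   proportions ((1-q)^2, 2q(1-q), q^2) for (aa, Aa, AA) given a minor-allele
   frequency q, or an explicit (AA, Aa, aa) frequency triple for
   Hardy-Weinberg disequilibrium.
2. *Offspring.*  Each parent transmits one allele under Mendelian
   inheritance (a heterozygote transmits either allele with probability
   1/2).  Paternal genotypes are then dropped to mimic the mother-offspring
   study design.
3. *Phenotype.*  A latent liability

       z = alpha0 + alpha_m*Gm + alpha_o*Go + alpha_ic*Gic + eps,
       eps ~ N(0, sigma^2)

   is dichotomised at its empirical (1 - prevalence) quantile, so the
   population disease prevalence equals the target (5% by default).  Gic is
   the binary indicator coded by the scenario's *generating* model.

For heritability-parameterised scenarios the incompatibility effect is
calibrated from the target h2 through sigma_T^2 = alpha_ic^2 q(1-q) + sigma^2
and h2 = 1 - sigma^2/sigma_T^2, where q is the population fraction of
incompatible pairs under the generating model; the unique positive solution
is alpha_ic = sqrt(h2 * sigma^2 / ((1 - h2) q (1 - q))).

Experiments treat the simulated data as a population from which independent
samples of size n are drawn; rejection fractions over replicates estimate
type I error (null scenarios) or power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .association_test import two_step_test
from .entropy_selection import SelectionConfig
from .genotype_models import PairClass, classify_pairs, code_incompatibility, get_model

__all__ = [
    "PopulationConfig",
    "ScenarioConfig",
    "Population",
    "SampleData",
    "ExperimentResult",
    "SCENARIOS",
    "HWD_GENOTYPE_FREQS",
    "sample_parents",
    "mendelian_offspring",
    "calibrate_alpha_ic",
    "simulate_population",
    "draw_sample",
    "run_experiment",
]

#: Study genotype frequencies under Hardy-Weinberg disequilibrium, as
#: (AA, Aa, aa) = (homozygous carriers, heterozygotes, noncarriers).
HWD_GENOTYPE_FREQS: tuple[float, float, float] = (0.18, 0.47, 0.35)


@dataclass(frozen=True)
class PopulationConfig:
    """Genotype law, population size, and disease prevalence.

    Exactly one of ``maf`` (Hardy-Weinberg proportions) or
    ``genotype_freqs`` (explicit (AA, Aa, aa) triple) selects the law.
    """

    n_families: int = 1_000_000
    maf: Optional[float] = 0.2
    genotype_freqs: Optional[tuple[float, float, float]] = None
    prevalence: float = 0.05
    seed: Optional[int | np.random.Generator] = None

    def __post_init__(self) -> None:
        if (self.maf is None) == (self.genotype_freqs is None):
            raise ValueError("specify exactly one of maf or genotype_freqs")
        if self.maf is not None and not 0.0 < self.maf <= 0.5:
            raise ValueError("HWE maf must lie in (0, 0.5]")
        if self.genotype_freqs is not None:
            f = np.asarray(self.genotype_freqs, dtype=np.float64)
            if f.size != 3 or np.any(f < 0) or not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
                raise ValueError("genotype_freqs must be 3 non-negative values summing to 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")

    def genotype_probs(self) -> np.ndarray:
        """Probabilities of genotypes (0, 1, 2) = (aa, Aa, AA)."""
        if self.maf is not None:
            q = self.maf
            return np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2])
        f_aa2, f_het, f_aa0 = self.genotype_freqs
        return np.array([f_aa0, f_het, f_aa2])


@dataclass(frozen=True)
class ScenarioConfig:
    """Effect sizes of one simulation scenario.

    Either ``alpha_ic`` is given directly or ``h2`` requests calibration of
    the incompatibility effect to a target heritability.  The
    ``generating_model_id`` names which incompatibility model codes Gic in
    the liability; it is bookkeeping only when alpha_ic = 0.
    """

    scenario_id: str
    alpha_m: float = 0.0
    alpha_o: float = 0.0
    alpha_ic: Optional[float] = None
    h2: Optional[float] = None
    generating_model_id: int = 11
    alpha0: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if (self.alpha_ic is None) == (self.h2 is None):
            raise ValueError("specify exactly one of alpha_ic or h2")
        if self.h2 is not None and not 0.0 <= self.h2 < 1.0:
            raise ValueError("h2 must lie in [0, 1)")


def _std_scenario(sid: str, am: float, ao: float, aic: float) -> ScenarioConfig:
    return ScenarioConfig(sid, alpha_m=am, alpha_o=ao, alpha_ic=aic)


#: The nine study scenarios: I no effects; II/III a single main effect;
#: IV-VI incompatibility plus main effects; VII-IX incompatibility only at
#: heritability 0.05/0.10/0.15.
SCENARIOS: dict[str, ScenarioConfig] = {
    "I": _std_scenario("I", 0.0, 0.0, 0.0),
    "II": _std_scenario("II", 0.4, 0.0, 0.0),
    "III": _std_scenario("III", 0.0, 0.4, 0.0),
    "IV": _std_scenario("IV", 0.4, 0.0, 0.4),
    "V": _std_scenario("V", 0.0, 0.4, 0.4),
    "VI": _std_scenario("VI", 0.2, 0.2, 0.4),
    "VII": ScenarioConfig("VII", h2=0.05),
    "VIII": ScenarioConfig("VIII", h2=0.10),
    "IX": ScenarioConfig("IX", h2=0.15),
}


@dataclass(frozen=True)
class Population:
    """A simulated mother-offspring population with liabilities and labels."""

    maternal: np.ndarray
    offspring: np.ndarray
    classifications: np.ndarray
    liability: np.ndarray
    disease: np.ndarray
    q_incompatible: float
    alpha_ic: float
    scenario: ScenarioConfig
    config: PopulationConfig


@dataclass(frozen=True)
class SampleData:
    """One analysis sample drawn from a population."""

    y: np.ndarray
    g_m: np.ndarray
    g_o: np.ndarray
    classifications: np.ndarray


@dataclass(frozen=True)
class ExperimentResult:
    """Rejection fraction and model-selection frequencies over replicates."""

    estimate: float
    n_replicates: int
    n_failed: int
    sample_size: int
    approach: str
    alpha_level: float
    selection_proportions: Optional[np.ndarray]  # index m-1 = frequency of model m

    @property
    def mc_se(self) -> float:
        """Binomial Monte-Carlo standard error of the rejection fraction."""
        m = self.n_replicates - self.n_failed
        return math.sqrt(self.estimate * (1 - self.estimate) / m) if m else math.nan


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_parents(config: PopulationConfig,
                   rng: Optional[np.random.Generator] = None) -> tuple[np.ndarray, np.ndarray]:
    """Draw maternal and paternal genotypes independently from the same law."""
    rng = _as_rng(config.seed if rng is None else rng)
    probs = config.genotype_probs()
    n = config.n_families
    g_m = rng.choice(3, size=n, p=probs).astype(np.int8)
    g_f = rng.choice(3, size=n, p=probs).astype(np.int8)
    return g_m, g_f


def mendelian_offspring(g_m: np.ndarray, g_f: np.ndarray,
                        rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Transmit one allele per parent: homozygotes deterministically, a
    heterozygote either allele with probability 1/2."""
    rng = _as_rng(rng)
    g_m = np.asarray(g_m)
    g_f = np.asarray(g_f)
    n = g_m.size
    a_m = (g_m == 2) | ((g_m == 1) & (rng.random(n) < 0.5))
    a_f = (g_f == 2) | ((g_f == 1) & (rng.random(n) < 0.5))
    return (a_m.astype(np.int8) + a_f.astype(np.int8))


def calibrate_alpha_ic(h2: float, q: float, sigma2: float = 1.0) -> float:
    """Incompatibility effect size giving heritability h2.

    Solves sigma_T^2 = alpha_ic^2 q(1-q) + sigma^2 together with
    h2 = 1 - sigma^2/sigma_T^2 for the positive root:
    alpha_ic = sqrt(h2 sigma^2 / ((1-h2) q (1-q))).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError("h2 must lie in [0, 1)")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly between 0 and 1")
    return math.sqrt(h2 * sigma2 / ((1.0 - h2) * q * (1.0 - q)))


def simulate_population(config: PopulationConfig, scenario: ScenarioConfig,
                        rng: Optional[np.random.Generator] = None) -> Population:
    """Generate a full population under one scenario.

    The disease threshold is the empirical (1 - prevalence) quantile of the
    realised liabilities, so the population prevalence matches the target up
    to rank rounding.  ``q_incompatible`` records the population fraction
    with Gic = 1 under the generating model.
    """
    rng = _as_rng(config.seed if rng is None else rng)
    g_m, g_f = sample_parents(config, rng)
    g_o = mendelian_offspring(g_m, g_f, rng)
    cls = classify_pairs(g_m, g_o)

    model = get_model(scenario.generating_model_id)
    g_ic = code_incompatibility(model, cls)
    q = float(g_ic.mean())

    if scenario.h2 is not None:
        alpha_ic = calibrate_alpha_ic(scenario.h2, q, scenario.sigma2)
    else:
        alpha_ic = float(scenario.alpha_ic)

    sd = math.sqrt(scenario.sigma2)
    z = (scenario.alpha0
         + scenario.alpha_m * g_m
         + scenario.alpha_o * g_o
         + alpha_ic * g_ic
         + rng.normal(0.0, sd, size=config.n_families))
    threshold = np.quantile(z, 1.0 - config.prevalence)
    disease = (z > threshold).astype(np.int8)
    return Population(g_m, g_o.astype(np.int8), cls, z, disease, q, alpha_ic,
                      scenario, config)


def draw_sample(population: Population, n: int,
                rng: np.random.Generator | int | None = None) -> SampleData:
    """Simple random sample of n families, without replacement."""
    if n > population.maternal.size:
        raise ValueError("sample size exceeds population size")
    rng = _as_rng(rng)
    idx = rng.choice(population.maternal.size, size=n, replace=False)
    return SampleData(
        y=population.disease[idx].astype(np.int64),
        g_m=population.maternal[idx].astype(np.int64),
        g_o=population.offspring[idx].astype(np.int64),
        classifications=population.classifications[idx],
    )


def _run_replicates(population, n, rep_seed, n_replicates, select, selection,
                    alpha_level):
    """Rejection/failure/selection tallies over replicates on one population."""
    sel_counts = np.zeros(11, dtype=np.int64)
    rejections = 0
    failed = 0
    for ss in rep_seed.spawn(n_replicates):
        rng = np.random.default_rng(ss)
        sample = draw_sample(population, n, rng)
        if sample.y.min() == sample.y.max():
            failed += 1
            continue
        cfg_sel = None
        if select:
            base = selection if selection is not None else SelectionConfig()
            cfg_sel = replace(base, seed=rng)
        sel, res = two_step_test(sample.y, sample.classifications,
                                 sample.g_m, sample.g_o,
                                 config=cfg_sel, select=select)
        if select:
            sel_counts[sel.final_model_id - 1] += 1
        if not np.isfinite(res.p_value):
            # separated or non-converged fit: no usable p-value
            failed += 1
            continue
        if res.p_value < alpha_level:
            rejections += 1
    return rejections, failed, sel_counts


def run_experiment(
    scenario: ScenarioConfig,
    n: int,
    n_replicates: int,
    approach: str = "full_model",
    pop_config: Optional[PopulationConfig] = None,
    selection: Optional[SelectionConfig] = None,
    alpha_level: float = 0.05,
    seed: int | None = None,
    population: Optional[Population] = None,
    n_populations: int = 1,
) -> ExperimentResult:
    """Estimate the rejection fraction of one approach under one scenario.

    A population is simulated (or supplied) and ``n_replicates`` independent
    samples of size ``n`` are drawn from it; each is analysed by the chosen
    approach and the fraction of replicates with LRT p-value below
    ``alpha_level`` is returned.  For the model-selection approach the
    frequency with which each of the 11 models ends up as the analysis model
    is tallied as well.  Replicates with a degenerate sample (single-class
    phenotype) or a separated/non-converged fit carry no usable p-value;
    they are excluded from the denominator and counted in ``n_failed``.

    ``n_populations > 1`` splits the replicates evenly over that many
    independently simulated populations, averaging out population-realisation
    noise (one large population behaves like the average of several smaller
    ones).  Per-population and per-replicate random streams are spawned from
    the master seed, so results are reproducible and order-independent.
    """
    if approach not in ("full_model", "model_selection"):
        raise ValueError("approach must be 'full_model' or 'model_selection'")
    if not 0.0 <= alpha_level <= 1.0:
        raise ValueError("alpha_level must lie in [0, 1]")
    if n_populations < 1 or n_replicates < n_populations:
        raise ValueError("need 1 <= n_populations <= n_replicates")

    master = np.random.SeedSequence(seed)
    select = approach == "model_selection"
    cfg = pop_config if pop_config is not None else PopulationConfig()

    if population is not None:
        blocks = [(population, master.spawn(1)[0], n_replicates)]
    else:
        per = [n_replicates // n_populations] * n_populations
        for i in range(n_replicates % n_populations):
            per[i] += 1
        blocks = []
        for block_seed, reps in zip(master.spawn(n_populations), per):
            pop_seed, rep_seed = block_seed.spawn(2)
            pop = simulate_population(cfg, scenario,
                                      rng=np.random.default_rng(pop_seed))
            blocks.append((pop, rep_seed, reps))

    sel_counts = np.zeros(11, dtype=np.int64)
    rejections = 0
    failed = 0
    for pop, rep_seed, reps in blocks:
        r, f, s = _run_replicates(pop, n, rep_seed, reps, select, selection,
                                  alpha_level)
        rejections += r
        failed += f
        sel_counts += s

    used = n_replicates - failed
    estimate = rejections / used if used else math.nan
    proportions = sel_counts / sel_counts.sum() if select and sel_counts.sum() else None
    return ExperimentResult(estimate, n_replicates, failed, n, approach,
                            alpha_level, proportions)
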