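"""Linked genotype–phenotype cohort simulators.

Two generative models, mirroring an EHR-biobank GWAS setting:

* **Cox model** — genotypes drive the hazard of a multivariable proportional
  hazards model with an Exponential baseline event-time scale, Gamma(1,1)
  censoring capped at an administrative bound, and Unif left truncation.
  Individuals whose event or censoring time precedes their truncation time
  are never observed and are removed, exactly as a biobank never enrolls
  patients who had the event (or left) before their first visit.
* **Logistic model** — a binary outcome generated from allele counts plus a
  Normal "age" covariate, with an independent Unif censoring age that can
  hide events occurring after censoring.

All randomness flows from one integer seed through named substreams, so each
component (MAFs, genotypes, coefficients, times, ...) is independently
reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import CalibrationError, ConfigurationError, SimulationError
from .genotypes import GenotypeMatrix
from .phenotype import SurvivalPhenotype

__all__ = [
    "MafSpectrum",
    "SimCoxConfig",
    "SimLogisticConfig",
    "SimulatedCohort",
    "sample_mafs",
    "simulate_genotypes",
    "simulate_cox_cohort",
    "simulate_logistic_cohort",
    "calibrate_maf_upper",
]

_SUBSTREAMS = ("mafs", "genotypes", "coefficients", "times", "censoring",
               "truncation", "age", "outcome")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child stream of the config seed."""
    idx = _SUBSTREAMS.index(name)
    ss = np.random.SeedSequence(seed, spawn_key=(idx,))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class MafSpectrum:
    """Distribution that per-SNP minor-allele frequencies are drawn from.

    Either ``uniform`` on (low, high] within (0, 0.5], or resampling with
    replacement from an explicit list of frequencies (e.g. a platform's
    empirical spectrum).
    """

    kind: str = "uniform"
    low: float = 0.01
    high: float = 0.5
    values: Optional[tuple] = None

    def __post_init__(self):
        if self.kind == "uniform":
            if not (0.0 < self.low <= self.high <= 0.5):
                raise ConfigurationError(
                    "uniform MAF bounds must satisfy 0 < low <= high <= 0.5"
                )
        elif self.kind == "explicit":
            vals = np.asarray(self.values, dtype=float)
            if vals.size == 0 or np.any(vals <= 0) or np.any(vals > 0.5):
                raise ConfigurationError("explicit MAFs must lie in (0, 0.5]")
        else:
            raise ConfigurationError(f"unknown MAF spectrum kind {self.kind!r}")

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "uniform":
            return rng.uniform(self.low, self.high, n)
        vals = np.asarray(self.values, dtype=float)
        return rng.choice(vals, size=n, replace=True)


@dataclass(frozen=True)
class SimCoxConfig:
    """Cox generative model.

    Defaults are the reference study conditions: 50,000 haploid individuals,
    100 true risk alleles with log hazard ratios Unif(0.3, 0.5), baseline
    event-time scale 10,000 (i.e. baseline hazard 1e-4 per time unit),
    censoring min(Gamma(1,1), 2), truncation Unif(0, 0.1).
    """

    n_individuals: int = 50_000
    n_snps: int = 100
    n_true: int = 100
    coef_low: float = 0.3
    coef_high: float = 0.5
    baseline_scale: float = 10_000.0
    censor_shape: float = 1.0
    censor_rate: float = 1.0
    censor_cap: float = 2.0
    trunc_low: float = 0.0
    trunc_high: float = 0.1
    ploidy: int = 1
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    seed: int = 0

    def __post_init__(self):
        if self.n_true > self.n_snps:
            raise ConfigurationError("n_true cannot exceed n_snps")
        if self.coef_low > self.coef_high:
            raise ConfigurationError("coef_low must be <= coef_high")
        if not (self.censor_cap > self.trunc_high > self.trunc_low >= 0
                or (self.trunc_low == self.trunc_high >= 0)):
            raise ConfigurationError(
                "require censor_cap > trunc_high > trunc_low >= 0"
            )
        if self.baseline_scale <= 0:
            raise ConfigurationError("baseline_scale must be positive")
        if self.ploidy not in (1, 2):
            raise ConfigurationError("ploidy must be 1 or 2")


@dataclass(frozen=True)
class SimLogisticConfig:
    """Logistic generative model.

    Defaults: age Normal(60, 5) with log-odds 0.001/year, 100 true alleles
    with log odds Unif(0.3, 0.7), censoring age Unif(50, 85).  The intercept
    is unidentified by the study description, so ``intercept="auto"``
    calibrates it to a target marginal event rate (default 0.30).
    """

    n_individuals: int = 50_000
    n_snps: int = 100
    n_true: int = 100
    coef_low: float = 0.3
    coef_high: float = 0.7
    age_mean: float = 60.0
    age_sd: float = 5.0
    age_coef: float = 0.001
    intercept: Union[str, float] = "auto"
    target_event_rate: float = 0.30
    censor_low: float = 50.0
    censor_high: float = 85.0
    ploidy: int = 1
    maf_spectrum: MafSpectrum = field(default_factory=MafSpectrum)
    seed: int = 0

    def __post_init__(self):
        if self.n_true > self.n_snps:
            raise ConfigurationError("n_true cannot exceed n_snps")
        if self.censor_low >= self.censor_high:
            raise ConfigurationError("censor_low must be < censor_high")
        if self.age_sd <= 0:
            raise ConfigurationError("age_sd must be positive")
        if isinstance(self.intercept, str) and self.intercept != "auto":
            raise ConfigurationError("intercept must be a number or 'auto'")


@dataclass
class SimulatedCohort:
    """Output of either simulator, aligned to the *retained* individuals."""

    genotypes: GenotypeMatrix
    truth_mask: np.ndarray  # per-SNP bool: true risk allele?
    true_coefs: np.ndarray  # per-SNP generative coefficient (0 for nulls)
    pheno: SurvivalPhenotype  # counting-process outcome for Cox fitting
    status: np.ndarray  # binary outcome for logistic fitting
    n_removed: int  # individuals dropped (truncation; 0 for logistic model)
    model: str  # "cox" | "logistic"
    extras: dict = field(default_factory=dict)

    @property
    def event_rate(self) -> float:
        return float(np.mean(self.status))


def sample_mafs(spectrum: MafSpectrum, n_snps: int, seed: int) -> np.ndarray:
    """Draw ``n_snps`` minor-allele frequencies from the spectrum."""
    if n_snps < 1:
        raise ConfigurationError("n_snps must be >= 1")
    return spectrum.sample(n_snps, _substream(seed, "mafs"))


def simulate_genotypes(mafs, n_individuals: int, ploidy: int = 1,
                       seed: int = 0) -> GenotypeMatrix:
    """Independent Binomial(ploidy, f) allele counts, one column per SNP."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ConfigurationError("minor allele frequencies must lie in (0, 0.5]")
    if ploidy not in (1, 2):
        raise ConfigurationError("ploidy must be 1 or 2")
    rng = _substream(seed, "genotypes")
    vals = rng.binomial(ploidy, mafs, size=(n_individuals, len(mafs)))
    return GenotypeMatrix(vals.astype(float), ploidy=ploidy)


def _draw_coefs(n_snps, n_true, low, high, seed):
    """The first ``n_true`` SNPs are the true risk alleles."""
    rng = _substream(seed, "coefficients")
    coefs = np.zeros(n_snps)
    coefs[:n_true] = rng.uniform(low, high, n_true)
    mask = np.zeros(n_snps, dtype=bool)
    mask[:n_true] = True
    return coefs, mask


def simulate_cox_cohort(config: SimCoxConfig) -> SimulatedCohort:
    """Simulate event/censoring/truncation times from the Cox model.

    Event times use the inverse-CDF construction
    ``T = -log(U) * baseline_scale / exp(x' beta)``; censoring is
    ``C = min(Gamma(shape, 1/rate), censor_cap)``; truncation
    ``L ~ Unif(trunc_low, trunc_high)``.  Individuals with
    ``min(T, C) < L`` are removed; the retained get
    ``(entry=L, exit=min(T, C), status=1{T <= C})``.
    """
    cfg = config
    mafs = sample_mafs(cfg.maf_spectrum, cfg.n_snps, cfg.seed)
    G = simulate_genotypes(mafs, cfg.n_individuals, cfg.ploidy, cfg.seed)
    coefs, mask = _draw_coefs(cfg.n_snps, cfg.n_true, cfg.coef_low,
                              cfg.coef_high, cfg.seed)
    eta = G.values[:, mask] @ coefs[mask]

    rng_t = _substream(cfg.seed, "times")
    T = rng_t.exponential(1.0, cfg.n_individuals) * cfg.baseline_scale * np.exp(-eta)
    rng_c = _substream(cfg.seed, "censoring")
    C = np.minimum(
        rng_c.gamma(cfg.censor_shape, 1.0 / cfg.censor_rate, cfg.n_individuals),
        cfg.censor_cap,
    )
    rng_l = _substream(cfg.seed, "truncation")
    L = rng_l.uniform(cfg.trunc_low, cfg.trunc_high, cfg.n_individuals)

    exit_time = np.minimum(T, C)
    status = (T <= C).astype(np.int8)
    keep = exit_time > L
    n_removed = int(cfg.n_individuals - keep.sum())
    if keep.sum() == 0:
        raise SimulationError("truncation removed every individual")
    geno = GenotypeMatrix(G.values[keep], G.snp_ids, np.flatnonzero(keep),
                          cfg.ploidy)
    pheno = SurvivalPhenotype(L[keep], exit_time[keep], status[keep],
                              ids=np.flatnonzero(keep))
    return SimulatedCohort(
        genotypes=geno, truth_mask=mask, true_coefs=coefs, pheno=pheno,
        status=status[keep], n_removed=n_removed, model="cox",
        extras={"mafs": mafs, "event_time": T[keep], "censor_time": C[keep]},
    )


def _calibrate_intercept(base_eta: np.ndarray, target: float) -> float:
    def rate(c):
        return float(np.mean(expit(c + base_eta))) - target

    lo, hi = -30.0, 30.0
    if rate(lo) > 0 or rate(hi) < 0:
        raise CalibrationError(
            f"cannot bracket target event rate {target} with any intercept"
        )
    return brentq(rate, lo, hi, xtol=1e-10)


def simulate_logistic_cohort(config: SimLogisticConfig) -> SimulatedCohort:
    """Simulate a binary outcome from the logistic model plus censoring.

    ``status ~ Bernoulli(sigmoid(intercept + age_coef*age + x' beta))`` with
    ``age ~ Normal(age_mean, age_sd)``.  For the Cox comparator the observed
    time is ``min(age, censor)`` with the event zeroed when ``age > censor``
    (the event would occur after follow-up ended), and no left truncation.
    """
    cfg = config
    mafs = sample_mafs(cfg.maf_spectrum, cfg.n_snps, cfg.seed)
    G = simulate_genotypes(mafs, cfg.n_individuals, cfg.ploidy, cfg.seed)
    coefs, mask = _draw_coefs(cfg.n_snps, cfg.n_true, cfg.coef_low,
                              cfg.coef_high, cfg.seed)
    age = _substream(cfg.seed, "age").normal(cfg.age_mean, cfg.age_sd,
                                             cfg.n_individuals)
    base_eta = G.values[:, mask] @ coefs[mask] + cfg.age_coef * age
    if cfg.intercept == "auto":
        intercept = _calibrate_intercept(base_eta, cfg.target_event_rate)
    else:
        intercept = float(cfg.intercept)
    p = expit(intercept + base_eta)
    rng_y = _substream(cfg.seed, "outcome")
    status = (rng_y.uniform(size=cfg.n_individuals) < p).astype(np.int8)
    censor = _substream(cfg.seed, "censoring").uniform(
        cfg.censor_low, cfg.censor_high, cfg.n_individuals
    )
    observed_time = np.minimum(age, censor)
    observed_status = (status == 1) & (age <= censor)
    pheno = SurvivalPhenotype(
        np.zeros(cfg.n_individuals), observed_time,
        observed_status.astype(np.int8),
    )
    return SimulatedCohort(
        genotypes=G, truth_mask=mask, true_coefs=coefs, pheno=pheno,
        status=observed_status.astype(np.int8), n_removed=0, model="logistic",
        extras={"mafs": mafs, "age": age, "censor_time": censor,
                "latent_status": status, "intercept": intercept},
    )


def calibrate_maf_upper(config: SimCoxConfig, target_event_rate: float = 0.302,
                        n_probe: int = 2_000, n_reps: int = 20,
                        tol: float = 0.005, seed: int = 12345) -> tuple:
    """Choose the Unif MAF upper bound so the mean event rate hits a target.

    The empirical platform MAF spectrum behind the reference study is not
    public; a Unif(low, upper) surrogate is calibrated instead: bisection on
    ``upper`` where each evaluation runs ``n_reps`` scaled-down cohorts
    (``n_probe`` individuals) through the *actual* generator and averages
    their event rates.  Returns ``(upper, achieved_event_rate)``.
    """
    if config.maf_spectrum.kind != "uniform":
        raise ConfigurationError("calibration requires a uniform MAF spectrum")
    low = config.maf_spectrum.low
    child_seeds = np.random.SeedSequence(seed).generate_state(n_reps) % (2**31)

    def mean_rate(upper: float) -> float:
        rates = []
        for s in child_seeds:
            cfg = replace(
                config, n_individuals=n_probe,
                maf_spectrum=MafSpectrum("uniform", low, upper), seed=int(s),
            )
            rates.append(simulate_cox_cohort(cfg).event_rate)
        return float(np.mean(rates))

    lo, hi = low + 1e-4, 0.5
    r_lo, r_hi = mean_rate(lo), mean_rate(hi)
    if not (r_lo < target_event_rate < r_hi):
        raise CalibrationError(
            f"target event rate {target_event_rate} not bracketed: "
            f"rate({lo:.4f})={r_lo:.4f}, rate({hi})={r_hi:.4f}"
        )
    while hi - lo > 1e-3:
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_event_rate:
            lo = mid
        else:
            hi = mid
    upper = 0.5 * (lo + hi)
    achieved = mean_rate(upper)
    if abs(achieved - target_event_rate) > max(tol, 0.05):
        raise CalibrationError(
            f"calibration landed at event rate {achieved:.4f}, "
            f"target {target_event_rate}"
        )
    return upper, achieved
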