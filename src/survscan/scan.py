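"""Per-SNP association scans and their evaluation.

A scan fits one model per SNP — left-truncated Cox, logistic, or the
sequential combination (logistic everywhere, Cox refit where the logistic
p-value clears a loose filter) — against a shared phenotype, and returns a
tidy per-SNP results table.  Evaluation helpers compute Bonferroni-based
true/false positive rates across simulation replicates, the genomic
inflation factor, genotype QC filters, and sensitivity against a map of
known associations grouped into LD blocks.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .cox import CoxPH, RiskSetStructure, cox_scan_univariate
from .exceptions import AlignmentError, ConfigurationError
from .genotypes import GenotypeMatrix
from .logistic import Logistic
from .phenotype import SurvivalPhenotype
from .simulate import (SimCoxConfig, SimLogisticConfig, SimulatedCohort,
                       simulate_cox_cohort, simulate_logistic_cohort)
from .splines import rcs_basis

__all__ = [
    "run_scan",
    "sequential_scan",
    "qc_filter_snps",
    "hwe_exact_test",
    "evaluate_power",
    "genomic_inflation",
    "catalog_sensitivity",
    "scan_cohort",
    "power_study",
    "PowerReport",
]

RESULT_COLUMNS = ["snp_id", "chrom", "pos", "af", "n_used", "method", "beta",
                  "se", "stat", "p", "p_bonf", "stage", "converged"]


# ---------------------------------------------------------------------------
# alignment helpers
# ---------------------------------------------------------------------------

def _align(G: GenotypeMatrix, pheno: SurvivalPhenotype, covariates):
    """Reorder phenotype (and covariates) rows to the genotype id order."""
    gids = np.asarray(G.individual_ids)
    pids = np.asarray(pheno.ids)
    if len(gids) != len(pids) or set(gids.tolist()) != set(pids.tolist()):
        raise AlignmentError("genotype and phenotype individual ids differ")
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        if covariates.shape[0] != len(pids):
            raise AlignmentError("covariate rows do not match phenotype")
    if np.array_equal(gids, pids):
        return pheno, covariates
    pos = pd.Series(np.arange(len(pids)), index=pids)
    order = pos.loc[gids].to_numpy()
    return pheno.subset(order), (None if covariates is None else covariates[order])


# ---------------------------------------------------------------------------
# scans
# ---------------------------------------------------------------------------

def _finish(df: pd.DataFrame, m) -> pd.DataFrame:
    m = len(df["snp_id"].unique()) if m is None else int(m)
    df = df.copy()
    df["p_bonf"] = np.minimum(1.0, m * df["p"])
    return df


def run_scan(G: GenotypeMatrix, pheno: SurvivalPhenotype, covariates=None,
             method: str = "cox", status=None, m=None, ties: str = "efron",
             bonferroni: bool = True) -> pd.DataFrame:
    """Fit one model per SNP: genotype (additive allele count) + covariates.

    Parameters
    ----------
    G, pheno
        Aligned by individual id (reordered automatically; a set mismatch is
        an error).
    covariates : (n, c) array, optional
        Extra columns for every fit (PCs, spline-encoded ages, ...).
    method : {"cox", "logistic"}
    status : 0/1 vector, optional
        Outcome for the logistic model; defaults to ``pheno.status``.
    m : int, optional
        Bonferroni denominator; defaults to the number of SNPs scanned.
        Simulation studies override it with the full-genome test count.

    Missing genotypes are handled per-SNP complete-case; a SNP whose fit
    fails to converge (or separates) gets ``p = NaN`` and ``converged=False``.
    """
    if method not in ("cox", "logistic"):
        raise ValueError(f"unknown scan method {method!r}")
    pheno, covariates = _align(G, pheno, covariates)
    y = pheno.status if status is None else np.asarray(status)
    vals = G.values
    any_missing = np.isnan(vals).any(axis=0)
    structure = RiskSetStructure(pheno) if method == "cox" else None
    logistic_start = None
    if method == "logistic":
        # warm start: covariate-only fit, genotype coefficient at zero
        base = np.ones((len(y), 1)) if covariates is None else \
            np.column_stack([np.ones(len(y)), covariates])
        res0 = Logistic(y, base, add_intercept=False).fit()
        logistic_start = np.insert(res0.params, 1, 0.0)

    af = G.allele_freq()
    # GWAS fast path: untied univariate Cox, vectorized over SNP blocks
    if (method == "cox" and covariates is None and not any_missing.any()
            and not structure.has_ties):
        fast = cox_scan_univariate(structure, vals)
        ok = fast["converged"] & ~fast["diverged"]
        with np.errstate(invalid="ignore"):
            z = fast["beta"] / fast["se"]
        df = pd.DataFrame({
            "snp_id": G.snp_ids, "chrom": G.chrom, "pos": G.pos, "af": af,
            "n_used": len(pheno),
            "method": method, "beta": fast["beta"], "se": fast["se"],
            "stat": z, "p": np.where(ok, 2.0 * stats.norm.sf(np.abs(z)), np.nan),
            "stage": method, "converged": ok,
        })
        return _finish(df, m) if bonferroni else df

    rows = []
    for j in range(G.n_snps):
        g = vals[:, j]
        row = {"snp_id": G.snp_ids[j], "chrom": G.chrom[j], "pos": G.pos[j],
               "af": af[j], "method": method, "stage": method}
        if any_missing[j]:
            keep = ~np.isnan(g)
            sub_pheno = pheno.subset(keep)
            sub_cov = None if covariates is None else covariates[keep]
            sub_y = y[keep]
            sub_g = g[keep]
            sub_structure = None
        else:
            keep = None
            sub_pheno, sub_cov, sub_y, sub_g = pheno, covariates, y, g
            sub_structure = structure
        row["n_used"] = len(sub_g)
        try:
            if method == "cox":
                X = sub_g[:, None] if sub_cov is None else \
                    np.column_stack([sub_g, sub_cov])
                res = CoxPH(X, sub_pheno, ties=ties,
                            structure=sub_structure).fit()
                ok = res.converged and not res.diverged
                idx = 0
            else:
                X = np.column_stack([np.ones(len(sub_g)), sub_g]) if sub_cov is None \
                    else np.column_stack([np.ones(len(sub_g)), sub_g, sub_cov])
                res = Logistic(sub_y, X, add_intercept=False).fit(
                    start_params=None if keep is not None else logistic_start)
                ok = res.converged and not res.separated
                idx = 1
            row.update(
                beta=res.params[idx], se=res.bse[idx],
                stat=res.zvalues[idx],
                p=res.pvalues[idx] if ok else np.nan,
                converged=ok,
            )
        except (ValueError, FloatingPointError):
            row.update(beta=np.nan, se=np.nan, stat=np.nan, p=np.nan,
                       converged=False)
        rows.append(row)
    df = pd.DataFrame(rows)
    return _finish(df, m) if bonferroni else df


def sequential_scan(G: GenotypeMatrix, pheno: SurvivalPhenotype,
                    covariates_logistic=None, covariates_cox=None,
                    status=None, filter_p: float = 1e-4, m=None,
                    ties: str = "efron") -> pd.DataFrame:
    """Logistic scan everywhere; Cox refit where logistic p <= ``filter_p``.

    The reported p-value is the Cox p for SNPs passing the filter and the
    logistic p otherwise (a SNP failing a 1e-4 screen cannot reach
    genome-wide significance either way); ``stage`` records which model
    produced each row.  The Bonferroni denominator is unchanged by the
    filtering.
    """
    logi = run_scan(G, pheno, covariates_logistic, method="logistic",
                    status=status, m=m, bonferroni=False)
    pass_mask = (logi["p"] <= filter_p).fillna(False).to_numpy()
    out = logi.copy()
    out["method"] = "sequential"
    if pass_mask.any():
        sub = G.subset_snps(pass_mask)
        cox = run_scan(sub, pheno, covariates_cox, method="cox", ties=ties,
                       m=m, bonferroni=False)
        cox = cox.set_index("snp_id")
        idx = np.flatnonzero(pass_mask)
        for col in ("beta", "se", "stat", "p", "converged", "n_used"):
            out.loc[idx, col] = cox[col].to_numpy()
        out.loc[idx, "stage"] = "cox"
    m_eff = G.n_snps if m is None else m
    return _finish(out, m_eff)


# ---------------------------------------------------------------------------
# genotype QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact two-sided Hardy–Weinberg test (sum of probabilities <= observed).

    Conditions on the minor-allele count and enumerates all heterozygote
    counts of the same parity, as standard in GWAS QC.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    n_rare = 2 * n_hom_rare + n_het
    if n_rare > n:  # ensure "rare" really is the minor allele
        n_rare = 2 * n - n_rare
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) % 2 == 0]
    hom_r = (n_rare - hets) // 2
    hom_c = n - hets - hom_r
    hets = hets[hom_c >= 0]
    hom_r = hom_r[hom_c >= 0]
    hom_c = hom_c[hom_c >= 0]
    from scipy.special import gammaln
    logw = (hets * np.log(2.0) - gammaln(hets + 1) - gammaln(hom_r + 1)
            - gammaln(hom_c + 1))
    logp = logw - logsumexp(logw)
    obs_idx = np.flatnonzero(hets == n_het)
    if len(obs_idx) == 0:
        raise ValueError("heterozygote count inconsistent with allele count")
    p_obs = logp[obs_idx[0]]
    probs = np.exp(logp)
    return float(np.minimum(1.0, probs[logp <= p_obs + 1e-12].sum()))


def qc_filter_snps(G: GenotypeMatrix, maf_min: float = 0.01,
                   call_rate_min: float = 0.95,
                   hwe_p_min: float = 0.001):
    """Standard GWAS QC: MAF, call-rate and Hardy–Weinberg thresholds.

    Returns ``(filtered GenotypeMatrix, exclusion log)`` where the log has
    one row per removed SNP with comma-joined failure reasons.  HWE uses the
    exact test and only applies to diploid genotypes (a haploid matrix has
    no heterozygote class).
    """
    maf = G.maf()
    call = G.call_rate()
    reasons = [[] for _ in range(G.n_snps)]
    with np.errstate(invalid="ignore"):
        maf_fail = ~(maf >= maf_min)  # NaN (all-missing) also fails
    for j in np.flatnonzero(maf_fail):
        reasons[j].append("maf")
    for j in np.flatnonzero(call < call_rate_min):
        reasons[j].append("call_rate")
    if G.ploidy == 2:
        for j in range(G.n_snps):
            g = G.values[:, j]
            g = g[~np.isnan(g)]
            counts = [(g == 1).sum(), (g == 2).sum(), (g == 0).sum()]
            if sum(counts) == 0:
                continue
            if hwe_exact_test(*map(int, counts)) < hwe_p_min:
                reasons[j].append("hwe")
    drop = np.array([len(r) > 0 for r in reasons])
    log = pd.DataFrame(
        {
            "snp_id": G.snp_ids[drop],
            "reason": [",".join(r) for r, d in zip(reasons, drop) if d],
        }
    )
    if drop.all():
        raise ValueError("QC removed every SNP")
    return G.subset_snps(~drop), log


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def genomic_inflation(p_values) -> float:
    """Genomic inflation factor: median association chi2 over the null median."""
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values to estimate lambda_GC")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


@dataclass
class PowerReport:
    """TPR/FPR per Bonferroni cutoff and method, averaged over replicates."""

    table: pd.DataFrame  # cutoff, method, tpr, fpr, tpr_se, fpr_se, n_replicates
    tpr_diff: pd.DataFrame  # cutoff, diff (cox - logistic), se, ci_low, ci_high
    cutoffs: tuple
    m: int

    def __repr__(self) -> str:
        return ("<PowerReport>\n" + self.table.to_string(index=False)
                + "\n\nTPR difference (cox - logistic):\n"
                + self.tpr_diff.to_string(index=False))


def _truth_series(result: pd.DataFrame, truth) -> pd.Series:
    if isinstance(truth, pd.Series):
        return truth.astype(bool)
    truth = np.asarray(truth, dtype=bool)
    ids = result["snp_id"].unique()
    if len(ids) != len(truth):
        raise ValueError("truth mask length does not match scanned SNPs")
    return pd.Series(truth, index=ids)


def evaluate_power(results, truth_masks, cutoffs=(0.01, 0.05, 0.1),
                   m=None) -> PowerReport:
    """Bonferroni TPR/FPR across replicates.

    ``results`` is one per-SNP table per replicate (rows may mix methods);
    ``truth_masks`` the matching per-replicate truth indicators (bool array
    in scanned-SNP order, or Series indexed by snp_id).  TPR is the fraction
    of true risk alleles with adjusted p below the cutoff, FPR the same over
    null alleles; non-converged SNPs are excluded from both numerator and
    denominator.  ``m`` recomputes adjusted p-values when given.
    """
    cutoffs = tuple(cutoffs)
    if any(not (0 < c < 1) for c in cutoffs):
        raise ValueError("cutoffs must lie in (0, 1)")
    if len(results) != len(truth_masks):
        raise ValueError("one truth mask per replicate required")
    per_rep = []
    for rep_i, (res, truth) in enumerate(zip(results, truth_masks)):
        truth_s = _truth_series(res, truth)
        df = res.copy()
        df["is_true"] = df["snp_id"].map(truth_s).astype(bool)
        if m is not None:
            df["p_bonf"] = np.minimum(1.0, int(m) * df["p"])
        ok = df["converged"].fillna(False).astype(bool) & df["p"].notna()
        df = df[ok]
        for method, sub in df.groupby("method", sort=True):
            for c in cutoffs:
                sig = sub["p_bonf"] < c
                t = sub["is_true"]
                per_rep.append({
                    "replicate": rep_i, "method": method, "cutoff": c,
                    "tpr": sig[t].mean() if t.any() else np.nan,
                    "fpr": sig[~t].mean() if (~t).any() else np.nan,
                })
    per = pd.DataFrame(per_rep)
    agg = (
        per.groupby(["cutoff", "method"], sort=True)
        .agg(tpr=("tpr", "mean"), fpr=("fpr", "mean"),
             tpr_se=("tpr", "sem"), fpr_se=("fpr", "sem"),
             n_replicates=("replicate", "count"))
        .reset_index()
    )
    diff_rows = []
    methods = set(per["method"])
    if {"cox", "logistic"} <= methods:
        wide = per.pivot_table(index=["replicate", "cutoff"], columns="method",
                               values="tpr").reset_index()
        for c in cutoffs:
            d = wide.loc[wide["cutoff"] == c, "cox"] - \
                wide.loc[wide["cutoff"] == c, "logistic"]
            se = d.sem()
            diff_rows.append({
                "cutoff": c, "diff": d.mean(), "se": se,
                "ci_low": d.mean() - 1.96 * se, "ci_high": d.mean() + 1.96 * se,
            })
    m_eff = int(m) if m is not None else len(_truth_series(results[0], truth_masks[0]))
    return PowerReport(table=agg, tpr_diff=pd.DataFrame(diff_rows),
                       cutoffs=cutoffs, m=m_eff)


def catalog_sensitivity(result: pd.DataFrame, blocks: pd.DataFrame, cutoffs,
                        other: pd.DataFrame = None) -> pd.DataFrame:
    """Fraction of known phenotype-LD-block pairs detected at each cutoff.

    A block counts as detected when at least one of its SNPs has p <= cutoff.
    When a second scan is supplied, the relative change
    ``(sens - sens_other) / sens_other`` is added (Cox vs logistic).
    """
    if len(blocks) == 0:
        raise ValueError("empty LD block map")
    required = {"phenotype", "block_id", "snp_id"}
    if not required <= set(blocks.columns):
        raise ValueError(f"block map needs columns {sorted(required)}")
    missing = set(blocks["snp_id"]) - set(result["snp_id"])
    if missing:
        raise ValueError(f"block map references SNPs absent from scan: "
                         f"{sorted(missing)[:5]}")

    def best_p(res):
        merged = blocks.merge(res[["snp_id", "p"]], on="snp_id", how="left")
        return merged.groupby(["phenotype", "block_id"])["p"].min()

    bp = best_p(result)
    rows = []
    bp_other = best_p(other) if other is not None else None
    for c in np.atleast_1d(cutoffs):
        sens = float((bp <= c).mean())
        row = {"cutoff": c, "sensitivity": sens}
        if bp_other is not None:
            sens_o = float((bp_other <= c).mean())
            row["sensitivity_other"] = sens_o
            row["relative_change"] = (sens - sens_o) / sens_o if sens_o > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simulation study driver
# ---------------------------------------------------------------------------

def cohort_covariates(cohort: SimulatedCohort):
    """Nuisance covariates the logistic comparator uses for each cohort type.

    Cox-model cohorts: restricted cubic splines (5 knots) of exit age and of
    follow-up length (exit minus entry).  Logistic-model cohorts: a 5-knot
    spline of the observed age.
    """
    if cohort.model == "cox":
        b1, _ = rcs_basis(cohort.pheno.exit, n_knots=5)
        b2, _ = rcs_basis(cohort.pheno.exit - cohort.pheno.entry, n_knots=5)
        return np.column_stack([b1, b2])
    b1, _ = rcs_basis(cohort.pheno.exit, n_knots=5)
    return b1


def scan_cohort(cohort: SimulatedCohort, methods=("cox", "logistic"),
                m=None, filter_p: float = 1e-4) -> pd.DataFrame:
    """Run the requested scans on one simulated cohort and stack the rows.

    The Cox scan is univariate genotype-only (left-truncated for Cox-model
    cohorts, entry 0 otherwise); the logistic scan adds the spline
    covariates from :func:`cohort_covariates`.
    """
    cov_logistic = cohort_covariates(cohort)
    parts = []
    for method in methods:
        if method == "cox":
            parts.append(run_scan(cohort.genotypes, cohort.pheno, None,
                                  method="cox", m=m))
        elif method == "logistic":
            parts.append(run_scan(cohort.genotypes, cohort.pheno,
                                  cov_logistic, method="logistic",
                                  status=cohort.status, m=m))
        elif method == "sequential":
            parts.append(sequential_scan(cohort.genotypes, cohort.pheno,
                                         covariates_logistic=cov_logistic,
                                         status=cohort.status,
                                         filter_p=filter_p, m=m))
        else:
            raise ValueError(f"unknown method {method!r}")
    return pd.concat(parts, ignore_index=True)


def power_study(config, n_replicates: int, cutoffs=(0.01, 0.05, 0.1),
                m: int = 800_000, methods=("cox", "logistic"),
                filter_p: float = 1e-4, progress: bool = False) -> PowerReport:
    """Replicate the generative model and measure TPR/FPR for each method.

    ``config`` is a :class:`SimCoxConfig` or :class:`SimLogisticConfig`; its
    seed spawns one child seed per replicate.  ``m`` is the full-genome
    Bonferroni denominator, so desk-scale runs (few thousand simulated SNPs)
    still face full-scale significance thresholds.
    """
    if n_replicates < 1:
        raise ConfigurationError("need at least one replicate")
    child = np.random.SeedSequence(config.seed).generate_state(n_replicates) % (2**31)
    results, masks = [], []
    for i in range(n_replicates):
        if progress and i % 10 == 0:
            print(f"replicate {i + 1}/{n_replicates}", flush=True)
        cfg = replace(config, seed=int(child[i]))
        if isinstance(cfg, SimCoxConfig):
            cohort = simulate_cox_cohort(cfg)
        else:
            cohort = simulate_logistic_cohort(cfg)
        results.append(scan_cohort(cohort, methods=methods, m=m,
                                   filter_p=filter_p))
        masks.append(cohort.truth_mask)
    return evaluate_power(results, masks, cutoffs=cutoffs, m=m)
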