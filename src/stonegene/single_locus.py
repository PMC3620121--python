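"""Per-SNP association statistics for case-control genotype data.

Implements the single-locus toolkit of a candidate-gene study: Hardy-
Weinberg equilibrium tests (asymptotic and exact), crude odds ratios with
Woolf confidence intervals, covariate-adjusted odds ratios by unconditional
logistic regression, the Cochran-Armitage trend test, and its Monte-Carlo
(label permutation) p-value.  :class:`SingleLocusScan` bundles these into a
statsmodels-style model whose :meth:`~SingleLocusScan.fit` returns a results
object with one report block per SNP, shaped like the genotype/allele
tables of a typical candidate-gene association report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, MISSING, Cohort, genotype_counts

Z975 = stats.norm.ppf(0.975)


# -- Hardy-Weinberg -----------------------------------------------------------

@dataclass(frozen=True)
class HweResult:
    statistic: float
    p_value: float
    monomorphic: bool = False


def hwe_test(counts: Sequence[int], method: str = "chi_square") -> HweResult:
    """Hardy-Weinberg equilibrium test from a (hom-wild, het, hom-variant)
    genotype count triple.

    ``chi_square``: 1-df Pearson statistic against expected counts from the
    sample allele frequency.  ``exact``: two-sided exact test summing, over
    the conditional distribution of the heterozygote count given the minor
    allele count, all outcomes at most as probable as the observed one.
    A monomorphic sample returns statistic 0, p = 1, flagged.
    """
    n0, n1, n2 = (int(c) for c in counts)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n0 + n1 + n2
    n_var = n1 + 2 * n2
    if n_var == 0 or n_var == 2 * n:
        return HweResult(0.0, 1.0, monomorphic=True)

    if method == "chi_square":
        q = n_var / (2 * n)
        exp = np.array([(1 - q) ** 2, 2 * q * (1 - q), q ** 2]) * n
        stat = float((((np.array([n0, n1, n2]) - exp) ** 2) / exp).sum())
        return HweResult(stat, float(stats.chi2.sf(stat, df=1)))
    if method == "exact":
        return hwe_exact(counts)
    raise ValueError(f"unknown HWE method {method!r}")


def hwe_exact(counts: Sequence[int]) -> HweResult:
    """Exact HWE test (see :func:`hwe_test` with ``method='exact'``)."""
    n0, n1, n2 = (int(c) for c in counts)
    n = n0 + n1 + n2
    n_var = n1 + 2 * n2
    if n_var == 0 or n_var == 2 * n:
        return HweResult(0.0, 1.0, monomorphic=True)
    rare = min(n_var, 2 * n - n_var)
    hets = np.arange(rare % 2, rare + 1, 2)
    from scipy.special import gammaln

    naa = (rare - hets) // 2
    nbb = n - naa - hets
    logp = (hets * np.log(2.0)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
            + gammaln(n + 1) - gammaln(naa + 1.0) - gammaln(hets + 1.0)
            - gammaln(nbb + 1.0))
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n1]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count incompatible with allele count")
    p = float(probs[probs <= p_obs[0] * (1 + 1e-12)].sum())
    return HweResult(float("nan"), min(1.0, p))


# -- odds ratios --------------------------------------------------------------

@dataclass(frozen=True)
class OrResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float = float("nan")
    corrected: bool = False      # Haldane-Anscombe +0.5 applied
    unstable: bool = False       # separation / unreliable CI


def crude_or(table: np.ndarray | Sequence[Sequence[float]]) -> OrResult:
    """Crude odds ratio with Woolf 95% CI from a 2x2 table.

    Rows are (control, case); columns (unexposed, exposed).  A zero cell
    triggers the Haldane-Anscombe +0.5 correction (flagged); a zero row or
    column makes the OR undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("crude_or requires a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: a row or column of the table is zero")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    orr = (t[1, 1] * t[0, 0]) / (t[1, 0] * t[0, 1])
    se = float(np.sqrt((1.0 / t).sum()))
    log_or = float(np.log(orr))
    return OrResult(
        odds_ratio=float(orr),
        ci_low=float(np.exp(max(log_or - Z975 * se, -700.0))),
        ci_high=float(np.exp(min(log_or + Z975 * se, 700.0))),
        corrected=corrected,
    )


_GENO_CODING = {
    "het_vs_wild": None,
    "hom_vs_wild": None,
    "dominant": lambda g: (g >= 1).astype(float),
    "recessive": lambda g: (g == 2).astype(float),
    "additive": lambda g: g.astype(float),
    "trend": lambda g: g.astype(float),
}


@dataclass(frozen=True)
class AssocResult:
    """One fitted association contrast for one SNP."""
    snp_id: str
    model: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    adjusted: bool
    n_used: int
    n_dropped_covariates: int = 0
    separation: bool = False


def adjusted_or(cohort: Cohort, snp_id: str, model: str = "dominant",
                covariates: Sequence[str] = ()) -> AssocResult:
    """Odds ratio for a genotype contrast from unconditional logistic
    regression of status on the coded genotype plus covariates.

    ``model`` is one of het_vs_wild, hom_vs_wild (single-genotype contrasts
    fitted on the corresponding subset), dominant, recessive or
    additive/trend.  ``covariates`` may name ``age`` and/or ``sex`` from the
    cohort's covariate table; individuals missing a requested covariate are
    dropped and counted.  Wald CIs and p-values.
    """
    import statsmodels.api as sm

    if model not in _GENO_CODING:
        raise ValueError(f"unknown genotype model {model!r}")
    g = cohort.column(snp_id).astype(float)
    keep = g != MISSING
    if model == "het_vs_wild":
        keep &= np.isin(g, (0, 1))
        x = g.copy()
    elif model == "hom_vs_wild":
        keep &= np.isin(g, (0, 2))
        x = (g == 2).astype(float)
    else:
        x = _GENO_CODING[model](g)

    cols = {"genotype": x}
    dropped = 0
    for cov in covariates:
        if cohort.covariates is None or cov not in cohort.covariates:
            raise ValueError(f"covariate {cov!r} not present in cohort")
        v = cohort.covariates[cov]
        if cov == "sex":
            vals = v.map({"female": 1.0, "male": 0.0})
        else:
            vals = pd.to_numeric(v, errors="coerce")
        miss = vals.isna().to_numpy()
        dropped += int((keep & miss).sum())
        keep &= ~miss
        cols[cov] = vals.to_numpy(dtype=float)
    y = (cohort.status == CASE).astype(float)[keep]
    X = sm.add_constant(
        pd.DataFrame({k: v[keep] for k, v in cols.items()}), has_constant="add")
    if y.min() == y.max():
        raise ValueError("both outcome classes required for logistic regression")

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            if not fit.mle_retvals.get("converged", True):
                separation = True
        except Exception:
            separation = True
            try:
                fit = sm.Logit(y, X).fit_regularized(alpha=1e-8, disp=0,
                                                     maxiter=200)
            except Exception:
                # complete separation: no finite MLE at all
                return AssocResult(
                    snp_id=snp_id, model=model, odds_ratio=float("inf"),
                    ci_low=0.0, ci_high=float("inf"), p_value=float("nan"),
                    adjusted=bool(covariates), n_used=int(keep.sum()),
                    n_dropped_covariates=dropped, separation=True)
    beta = float(fit.params["genotype"])
    se = float(fit.bse["genotype"]) if np.isfinite(fit.bse["genotype"]) else float("inf")
    if not np.isfinite(se) or se > 50 or abs(beta) > 15:
        separation = True
    return AssocResult(
        snp_id=snp_id,
        model=model,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z975 * se)),
        ci_high=float(np.exp(beta + Z975 * se)),
        p_value=float(fit.pvalues["genotype"]),
        adjusted=bool(covariates),
        n_used=int(keep.sum()),
        n_dropped_covariates=dropped,
        separation=separation,
    )


# -- trend tests --------------------------------------------------------------

@dataclass(frozen=True)
class TrendResult:
    statistic: float
    p_value: float
    degenerate: bool = False


def armitage_trend(table: np.ndarray | Sequence[Sequence[float]],
                   scores: Sequence[float] | None = None) -> TrendResult:
    """Cochran-Armitage trend test (1 df) on a 2 x k table.

    Rows are (control, case); columns are ordered genotype categories with
    default scores 0..k-1.  For a 2x2 table the statistic equals the Pearson
    chi-square.  If all individuals fall in a single column the result is
    statistic 0, p = 1, flagged degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError("trend test requires a 2 x k table with k >= 2")
    s = np.arange(t.shape[1], dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.shape != (t.shape[1],):
        raise ValueError("one score per genotype column required")
    n_col = t.sum(axis=0)
    n = t.sum()
    r = t[1].sum()  # cases
    if n == 0 or r == 0 or r == n or (n_col > 0).sum() < 2:
        return TrendResult(0.0, 1.0, degenerate=True)
    num = n * (s * t[1]).sum() - r * (s * n_col).sum()
    var = r * (n - r) * (n * (s ** 2 * n_col).sum() - ((s * n_col).sum()) ** 2)
    if var <= 0:
        return TrendResult(0.0, 1.0, degenerate=True)
    stat = float(n * num ** 2 / var)
    return TrendResult(stat, float(stats.chi2.sf(stat, df=1)))


def mcs_trend_p(table: np.ndarray | Sequence[Sequence[float]],
                reps: int = 10_000, seed: int = 0,
                scores: Sequence[float] | None = None) -> float:
    """Monte-Carlo (permutation) p-value for the Cochran-Armitage trend test.

    Status labels are permuted over the pooled genotype vector implied by
    the table; p = (1 + #{permuted statistic >= observed}) / (reps + 1).
    """
    if reps < 100:
        raise ValueError("at least 100 permutation replicates required")
    t = np.asarray(table, dtype=np.int64)
    obs = armitage_trend(t, scores).statistic
    k = t.shape[1]
    genotypes = np.repeat(np.arange(k), t.sum(axis=0))
    n, r = len(genotypes), int(t[1].sum())
    rng = np.random.default_rng(seed)
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    n_col = t.sum(axis=0).astype(float)
    # the permutation only changes the per-column case counts
    sum_s_ncol = float((s * n_col).sum())
    sum_s2_ncol = float((s ** 2 * n_col).sum())
    var = r * (n - r) * (n * sum_s2_ncol - sum_s_ncol ** 2)
    if var <= 0:
        return 1.0
    count = 0
    for _ in range(reps):
        perm = rng.permutation(n)[:r]
        case_counts = np.bincount(genotypes[perm], minlength=k)
        num = n * float((s * case_counts).sum()) - r * sum_s_ncol
        stat = n * num ** 2 / var
        if stat >= obs - 1e-12:
            count += 1
    return (1 + count) / (reps + 1)


# -- model/results facade -------------------------------------------------------

class SingleLocusScan:
    """Per-SNP association scan over a cohort (model object).

    Parameters
    ----------
    cohort : Cohort
    covariates : sequence of str
        Covariate names (``age``, ``sex``) used for adjusted odds ratios;
        empty for crude logistic fits.
    """

    def __init__(self, cohort: Cohort, covariates: Sequence[str] = ()):
        cohort.require_both_groups()
        self.cohort = cohort
        self.covariates = tuple(covariates)

    def fit(self, mcs_reps: int = 10_000, seed: int = 0,
            adjusted: bool | None = None) -> "SingleLocusResults":
        """Compute the full per-SNP report (genotype contrasts, dominant and
        allele-level odds ratios, trend and Monte-Carlo trend p, HWE)."""
        use_logistic = adjusted if adjusted is not None else bool(self.covariates)
        rows = []
        for snp in self.cohort.snps:
            sid = snp.snp_id
            tab3 = genotype_counts(self.cohort, sid, "genotypic")
            dom = genotype_counts(self.cohort, sid, "dominant")
            allelic = genotype_counts(self.cohort, sid, "allelic")
            trend = armitage_trend(tab3)
            mcs = mcs_trend_p(tab3, reps=mcs_reps, seed=seed)
            hwe_ctrl = hwe_test(tab3[0])
            contrasts: dict[str, OrResult | AssocResult] = {}
            for name, tab in (
                ("het_vs_wild", tab3[:, (0, 1)]),
                ("hom_vs_wild", tab3[:, (0, 2)]),
                ("dominant", dom),
                ("allelic", allelic),
            ):
                try:
                    if use_logistic and name != "allelic":
                        contrasts[name] = adjusted_or(
                            self.cohort, sid, model=name, covariates=self.covariates)
                    else:
                        contrasts[name] = crude_or(tab)
                except ValueError:
                    contrasts[name] = None
            rows.append({
                "snp": snp, "counts": tab3, "dominant": dom, "allelic": allelic,
                "contrasts": contrasts, "trend": trend, "mcs_p": mcs,
                "hwe_control": hwe_ctrl,
            })
        return SingleLocusResults(self, rows, mcs_reps=mcs_reps, seed=seed)


class SingleLocusResults:
    """Results of a :class:`SingleLocusScan` fit."""

    def __init__(self, model: SingleLocusScan, rows: list[dict],
                 mcs_reps: int, seed: int):
        self.model = model
        self.rows = rows
        self.mcs_reps = mcs_reps
        self.seed = seed

    def _or_fields(self, res) -> tuple[float, float, float, float]:
        if res is None:
            return (float("nan"),) * 4
        p = res.p_value if hasattr(res, "p_value") else float("nan")
        return res.odds_ratio, res.ci_low, res.ci_high, p

    def summary(self) -> pd.DataFrame:
        """One row per SNP with the headline statistics."""
        recs = []
        for row in self.rows:
            snp = row["snp"]
            or_dom = self._or_fields(row["contrasts"]["dominant"])
            or_all = self._or_fields(row["contrasts"]["allelic"])
            recs.append({
                "snp_id": snp.snp_id, "gene": snp.gene, "pathway": snp.pathway,
                "label": snp.label,
                "n_control": int(row["counts"][0].sum()),
                "n_case": int(row["counts"][1].sum()),
                "hwe_control_p": row["hwe_control"].p_value,
                "p_trend": row["trend"].p_value,
                "p_mcs": row["mcs_p"],
                "or_dominant": or_dom[0], "or_dominant_low": or_dom[1],
                "or_dominant_high": or_dom[2],
                "or_allelic": or_all[0], "or_allelic_low": or_all[1],
                "or_allelic_high": or_all[2],
            })
        return pd.DataFrame.from_records(recs)

    def report(self) -> pd.DataFrame:
        """Long-format report shaped like a published genotype/allele table:
        per SNP, genotype rows, Ptrend, MCS, pooled carrier row and allele
        rows, each with counts, percentages and OR (95% CI)."""
        lines = []
        for row in self.rows:
            snp, t = row["snp"], row["counts"]
            n_ctrl, n_case = t[0].sum(), t[1].sum()
            geno_labels = [snp.wild_allele * 2,
                           snp.wild_allele + snp.variant_allele,
                           snp.variant_allele * 2]
            contrast_for_col = {1: "het_vs_wild", 2: "hom_vs_wild"}

            def fmt_or(res):
                if res is None or not np.isfinite(res.odds_ratio):
                    return "", ""
                p = res.p_value if hasattr(res, "p_value") and np.isfinite(res.p_value) else None
                return ("" if p is None else f"{p:.3f}",
                        f"{res.odds_ratio:.2f} ({res.ci_low:.2f}-{res.ci_high:.2f})")

            for col in range(3):
                p_str, or_str = ("-", "1 (reference)") if col == 0 else \
                    fmt_or(row["contrasts"].get(contrast_for_col.get(col)))
                lines.append({
                    "snp_id": snp.snp_id, "label": snp.label,
                    "row": geno_labels[col],
                    "control": f"{t[0, col]} ({100 * t[0, col] / n_ctrl:.1f})",
                    "case": f"{t[1, col]} ({100 * t[1, col] / n_case:.1f})",
                    "p": p_str, "or_ci": or_str,
                })
            lines.append({"snp_id": snp.snp_id, "label": snp.label, "row": "Ptrend",
                          "control": "", "case": "",
                          "p": f"{row['trend'].p_value:.3f}", "or_ci": ""})
            lines.append({"snp_id": snp.snp_id, "label": snp.label, "row": "MCS",
                          "control": "", "case": "",
                          "p": f"{row['mcs_p']:.3f}", "or_ci": ""})
            dom = row["dominant"]
            p_str, or_str = fmt_or(row["contrasts"]["dominant"])
            lines.append({
                "snp_id": snp.snp_id, "label": snp.label,
                "row": f"{geno_labels[1]}+{geno_labels[2]}",
                "control": f"{dom[0, 1]} ({100 * dom[0, 1] / n_ctrl:.1f})",
                "case": f"{dom[1, 1]} ({100 * dom[1, 1] / n_case:.1f})",
                "p": p_str, "or_ci": or_str,
            })
            alle = row["allelic"]
            lines.append({
                "snp_id": snp.snp_id, "label": snp.label, "row": snp.wild_allele,
                "control": f"{alle[0, 0]} ({100 * alle[0, 0] / (2 * n_ctrl):.1f})",
                "case": f"{alle[1, 0]} ({100 * alle[1, 0] / (2 * n_case):.1f})",
                "p": "-", "or_ci": "1 (reference)",
            })
            p_str, or_str = fmt_or(row["contrasts"]["allelic"])
            lines.append({
                "snp_id": snp.snp_id, "label": snp.label, "row": snp.variant_allele,
                "control": f"{alle[0, 1]} ({100 * alle[0, 1] / (2 * n_ctrl):.1f})",
                "case": f"{alle[1, 1]} ({100 * alle[1, 1] / (2 * n_case):.1f})",
                "p": p_str, "or_ci": or_str,
            })
        return pd.DataFrame(lines,
                            columns=["snp_id", "label", "row", "control", "case",
                                     "p", "or_ci"])

    def to_tsv(self, path) -> None:
        self.report().to_csv(path, sep="\t", index=False)
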