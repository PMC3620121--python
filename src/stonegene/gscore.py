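"""Cumulative genotype risk score (G-score).

The score counts, per individual, the number of risk alleles carried across
a SNP panel: each marker contributes 2 for the homozygous risk genotype, 1
for a heterozygote and 0 otherwise, so a 13-SNP panel spans 0..26.  In the
default ("variant") preset the risk allele is the variant allele at every
marker, regardless of the direction of its marginal association; a
direction-aware preset that flips protective markers is available but is
not the default.

Provided statistics: group means +- SD with a Welch test (overall and per
pathway), per-level odds ratios relative to the control-median score level,
a per-allele (ordinal) odds ratio from logistic regression, and an exact
score distribution oracle by convolution of per-SNP genotype frequency
triples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, MISSING, Cohort
from .single_locus import Z975


def compute_scores(cohort: Cohort, snp_subset: Sequence[str] | None = None,
                   direction: str = "variant") -> tuple[pd.Series, int]:
    """Per-individual risk-allele count.

    Individuals with a missing genotype at any scored SNP are excluded;
    the excluded count is returned alongside the scores (indexed by
    individual id).  ``direction="variant"`` counts variant alleles at all
    SNPs; ``"manifest"`` counts each SNP's designated risk allele (wild
    homozygote scores 2 when the wild allele is the risk allele).
    """
    if direction not in ("variant", "manifest"):
        raise ValueError("direction must be 'variant' or 'manifest'")
    snp_ids = list(snp_subset) if snp_subset is not None else cohort.snp_ids
    if not snp_ids:
        raise ValueError("G-score requires a non-empty SNP subset")
    cols = [cohort.snp_index(s) for s in snp_ids]
    geno = cohort.genotypes[:, cols].astype(np.int64)
    complete = (geno != MISSING).all(axis=1)
    coded = geno.copy()
    if direction == "manifest":
        for j, sid in enumerate(snp_ids):
            if cohort.snp(sid).risk_allele == "wild":
                coded[:, j] = 2 - coded[:, j]
    scores = coded.sum(axis=1)[complete]
    ids = [i for i, ok in zip(cohort.ids, complete) if ok]
    return pd.Series(scores, index=ids, name="gscore"), int((~complete).sum())


def max_score(n_snps: int) -> int:
    """Theoretical maximum of the score over ``n_snps`` biallelic markers."""
    return 2 * n_snps


@dataclass(frozen=True)
class GroupSummary:
    mean_case: float
    sd_case: float
    mean_control: float
    sd_control: float
    p_value: float
    n_case: int
    n_control: int


def score_summary(scores: pd.Series, status: pd.Series | np.ndarray) -> GroupSummary:
    """Group means +- SD and Welch two-sample p for case vs control scores."""
    status = np.asarray(status)
    case = scores.values[status == CASE]
    ctrl = scores.values[status == CONTROL]
    if len(case) == 0 or len(ctrl) == 0:
        raise ValueError("score summary requires both groups")
    if np.var(case) == 0 and np.var(ctrl) == 0 and case.mean() == ctrl.mean():
        p = 1.0
    else:
        p = float(stats.ttest_ind(case, ctrl, equal_var=False).pvalue)
    return GroupSummary(
        mean_case=float(case.mean()), sd_case=float(case.std(ddof=1)),
        mean_control=float(ctrl.mean()), sd_control=float(ctrl.std(ddof=1)),
        p_value=p, n_case=len(case), n_control=len(ctrl))


def level_ors(scores: pd.Series, status: np.ndarray,
              covariates: pd.DataFrame | None = None,
              reference: int | None = None) -> pd.DataFrame:
    """Odds ratio per score level relative to a reference level.

    The reference defaults to the control-group median score.  Fitted by
    logistic regression of status on score-level indicator variables (plus
    covariates when supplied); levels that are empty in either group after
    cross-tabulation are pooled toward the reference and flagged.
    """
    import statsmodels.api as sm

    status = np.asarray(status, dtype=float)
    vals = scores.values.astype(int)
    if reference is None:
        reference = int(np.median(vals[status == CONTROL]))
    levels = np.unique(vals)
    if reference not in levels:
        reference = int(levels[np.argmin(np.abs(levels - reference))])

    pooled: list[int] = []
    ok_levels = []
    for lv in levels:
        if lv == reference:
            ok_levels.append(lv)
            continue
        n_case = ((vals == lv) & (status == 1)).sum()
        n_ctrl = ((vals == lv) & (status == 0)).sum()
        if n_case == 0 or n_ctrl == 0:
            pooled.append(lv)
        else:
            ok_levels.append(lv)
    work = vals.copy()
    for lv in pooled:
        work[work == lv] = reference

    X = pd.DataFrame({f"level_{lv}": (work == lv).astype(float)
                      for lv in ok_levels if lv != reference})
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c]
            X[c] = v.map({"female": 1.0, "male": 0.0}).values if c == "sex" \
                else pd.to_numeric(v, errors="coerce").values
    X = sm.add_constant(X, has_constant="add")
    keep = ~X.isna().any(axis=1).values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(status[keep], X.loc[keep]).fit(disp=0, maxiter=200)

    rows = []
    for lv in ok_levels:
        if lv == reference:
            rows.append({"level": lv, "odds_ratio": 1.0, "ci_low": np.nan,
                         "ci_high": np.nan, "p_value": np.nan,
                         "is_reference": True, "pooled": False})
            continue
        b = fit.params[f"level_{lv}"]
        se = fit.bse[f"level_{lv}"]
        rows.append({"level": lv, "odds_ratio": float(np.exp(b)),
                     "ci_low": float(np.exp(b - Z975 * se)),
                     "ci_high": float(np.exp(b + Z975 * se)),
                     "p_value": float(fit.pvalues[f"level_{lv}"]),
                     "is_reference": False, "pooled": False})
    for lv in pooled:
        rows.append({"level": lv, "odds_ratio": np.nan, "ci_low": np.nan,
                     "ci_high": np.nan, "p_value": np.nan,
                     "is_reference": False, "pooled": True})
    return pd.DataFrame(rows).sort_values("level").reset_index(drop=True)


def per_allele_or(scores: pd.Series, status: np.ndarray,
                  covariates: pd.DataFrame | None = None) -> dict:
    """Per-risk-allele odds ratio: the score entered as an ordinal term in a
    logistic regression of status (plus covariates)."""
    import statsmodels.api as sm

    status = np.asarray(status, dtype=float)
    X = pd.DataFrame({"gscore": scores.values.astype(float)})
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c]
            X[c] = v.map({"female": 1.0, "male": 0.0}).values if c == "sex" \
                else pd.to_numeric(v, errors="coerce").values
    X = sm.add_constant(X, has_constant="add")
    keep = ~X.isna().any(axis=1).values
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(status[keep], X.loc[keep]).fit(disp=0, maxiter=200)
    b, se = float(fit.params["gscore"]), float(fit.bse["gscore"])
    return {"odds_ratio": float(np.exp(b)),
            "ci_low": float(np.exp(b - Z975 * se)),
            "ci_high": float(np.exp(b + Z975 * se)),
            "p_value": float(fit.pvalues["gscore"])}


def score_pmf_convolution(triples: Sequence[Sequence[float]]) -> np.ndarray:
    """Exact score distribution under inter-SNP independence.

    Sequentially convolves the M three-point genotype distributions;
    returns the pmf over support 0..2M (sums to 1 within 1e-12).
    """
    pmf = np.array([1.0])
    for t in triples:
        t = np.asarray(t, dtype=float)
        if t.shape != (3,) or (t < 0).any():
            raise ValueError("each triple must be 3 non-negative probabilities")
        pmf = np.convolve(pmf, t / t.sum())
    return pmf


class GenotypeScore:
    """Model facade for the cumulative genotype score on a cohort."""

    def __init__(self, cohort: Cohort, snp_subset: Sequence[str] | None = None,
                 direction: str = "variant",
                 covariates: Sequence[str] = ()):
        cohort.require_both_groups()
        self.cohort = cohort
        self.snp_subset = list(snp_subset) if snp_subset is not None else None
        self.direction = direction
        self.covariates = tuple(covariates)

    def fit(self, reference_level: int | None = None) -> "GScoreResults":
        scores, n_excl = compute_scores(self.cohort, self.snp_subset, self.direction)
        id_pos = {iid: i for i, iid in enumerate(self.cohort.ids)}
        rows = np.array([id_pos[i] for i in scores.index])
        status = self.cohort.status[rows]
        cov = None
        if self.covariates:
            cov = self.cohort.covariates.iloc[rows][list(self.covariates)]
        overall = score_summary(scores, status)

        pathways = {}
        snp_ids = self.snp_subset or self.cohort.snp_ids
        for pw in sorted({self.cohort.snp(s).pathway for s in snp_ids}):
            sub = [s for s in snp_ids if self.cohort.snp(s).pathway == pw]
            pw_scores, _ = compute_scores(self.cohort, sub, self.direction)
            pw_rows = np.array([id_pos[i] for i in pw_scores.index])
            pathways[pw] = score_summary(pw_scores, self.cohort.status[pw_rows])

        lors = level_ors(scores, status, covariates=cov, reference=reference_level)
        pa = per_allele_or(scores, status, covariates=cov)
        return GScoreResults(self, scores, status, overall, pathways, lors, pa,
                             n_excluded=n_excl)


class GScoreResults:
    def __init__(self, model, scores, status, overall, pathways, level_table,
                 per_allele, n_excluded):
        self.model = model
        self.scores = scores
        self.status = status
        self.overall = overall
        self.pathway_summaries = pathways
        self.level_table = level_table
        self.per_allele = per_allele
        self.n_excluded = n_excluded

    def summary(self) -> pd.DataFrame:
        """Group score means per pathway and overall, with Welch p-values."""
        rows = []
        for pw, s in self.pathway_summaries.items():
            rows.append({"pathway": pw,
                         "case": f"{s.mean_case:.2f}±{s.sd_case:.2f}",
                         "control": f"{s.mean_control:.2f}±{s.sd_control:.2f}",
                         "p_value": s.p_value})
        s = self.overall
        rows.append({"pathway": "overall",
                     "case": f"{s.mean_case:.2f}±{s.sd_case:.2f}",
                     "control": f"{s.mean_control:.2f}±{s.sd_control:.2f}",
                     "p_value": s.p_value})
        return pd.DataFrame(rows, columns=["pathway", "case", "control", "p_value"])
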