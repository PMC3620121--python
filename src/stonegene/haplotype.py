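"""Haplotype frequency estimation (EM), pairwise LD, and haplotype association.

For 2-3 SNP systems the haplotype phase of an unphased multilocus genotype
is latent; frequencies are estimated with the standard
expectation-maximisation algorithm over diplotypes (pairs of haplotypes):
the E-step assigns each compatible diplotype a probability proportional to
the product of the current haplotype frequencies (doubled for heterozygous
diplotypes) and the M-step re-estimates frequencies from expected gamete
counts.  The observed-data log-likelihood is non-decreasing across
iterations and is checked at every step.

Pairwise linkage disequilibrium is summarised as D, D' and r^2 from a
4-vector of haplotype frequencies ordered (wild,wild), (wild,variant),
(variant,wild), (variant,variant); D is computed on the variant alleles.

Haplotype case-control association follows the expected-count convention:
haplotype counts are 2N x frequency per group, compared against a reference
haplotype with Woolf confidence intervals, plus a global chi-square test
over the full haplotype count table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CASE, CONTROL, MISSING, Cohort
from .single_locus import OrResult, crude_or


@dataclass
class HaplotypeSet:
    """EM-estimated haplotype frequencies for one group of individuals."""

    snp_ids: tuple[str, ...]
    haplotypes: list[str]          # allele strings, e.g. "TGC"
    frequencies: np.ndarray        # per haplotype, sums to 1
    loglik: float
    n_iter: int
    converged: bool
    n_individuals: int
    loglik_path: list[float] = field(default_factory=list, repr=False)

    def as_series(self) -> pd.Series:
        return pd.Series(self.frequencies, index=self.haplotypes)


@dataclass(frozen=True)
class LdStats:
    D: float
    D_prime: float
    r2: float


def _diplotype_table(k: int) -> dict[tuple[int, ...], list[tuple[int, int]]]:
    """Map each multilocus genotype to the compatible (h1, h2) index pairs,
    h1 <= h2, haplotypes indexed by their binary allele string."""
    haps = list(itertools.product((0, 1), repeat=k))
    index = {h: i for i, h in enumerate(haps)}
    table: dict[tuple[int, ...], list[tuple[int, int]]] = {}
    for h1 in haps:
        for h2 in haps:
            if index[h1] > index[h2]:
                continue
            geno = tuple(a + b for a, b in zip(h1, h2))
            table.setdefault(geno, []).append((index[h1], index[h2]))
    return table


def em_haplotypes(cohort: Cohort, snp_ids: Sequence[str], group: str = "pooled",
                  tol: float = 1e-8, max_iter: int = 500,
                  seed: int | None = None) -> HaplotypeSet:
    """EM haplotype frequency estimation for 2-3 SNPs in one status group.

    Individuals with a missing genotype at any of the SNPs are excluded.
    Initialisation is the product of observed allele frequencies
    (deterministic); if that run fails to converge, seeded random restarts
    are attempted.  Convergence: max absolute frequency change < ``tol``.
    """
    k = len(snp_ids)
    if not 2 <= k <= 3:
        raise ValueError("haplotype systems of 2 or 3 SNPs are supported")
    cols = [cohort.snp_index(s) for s in snp_ids]
    geno = cohort.genotypes[:, cols]
    mask = (geno != MISSING).all(axis=1)
    if group == "case":
        mask &= cohort.status == CASE
    elif group == "control":
        mask &= cohort.status == CONTROL
    elif group != "pooled":
        raise ValueError("group must be 'case', 'control' or 'pooled'")
    geno = geno[mask]
    if len(geno) == 0:
        raise ValueError("no complete multilocus genotypes in the requested group")

    haps = list(itertools.product((0, 1), repeat=k))
    n_hap = len(haps)
    dip = _diplotype_table(k)
    cells, counts = np.unique(geno, axis=0, return_counts=True)
    cell_pairs = [dip[tuple(c)] for c in cells]

    p_allele = geno.mean(axis=0) / 2.0
    init = np.array([
        np.prod([p if a else 1 - p for a, p in zip(h, p_allele)]) for h in haps])
    init = np.clip(init, 1e-12, None)
    init /= init.sum()

    def run(freq: np.ndarray) -> tuple[np.ndarray, list[float], int, bool]:
        path: list[float] = []
        for it in range(1, max_iter + 1):
            ll = 0.0
            expected = np.zeros(n_hap)
            for pairs, cnt in zip(cell_pairs, counts):
                probs = np.array([
                    (2.0 if i != j else 1.0) * freq[i] * freq[j] for i, j in pairs])
                tot = probs.sum()
                if tot <= 0:
                    tot = 1e-300
                ll += cnt * np.log(tot)
                w = probs / tot
                for (i, j), wij in zip(pairs, w):
                    expected[i] += cnt * wij
                    expected[j] += cnt * wij
            if path and ll < path[-1] - 1e-9:
                raise RuntimeError("EM log-likelihood decreased")
            path.append(ll)
            new = expected / (2.0 * counts.sum())
            delta = np.abs(new - freq).max()
            freq = new
            if delta < tol:
                return freq, path, it, True
        return freq, path, max_iter, False

    freq, path, n_iter, converged = run(init.copy())
    if not converged:
        rng = np.random.default_rng(0 if seed is None else seed)
        for _ in range(5):
            start = rng.dirichlet(np.ones(n_hap))
            freq2, path2, n2, conv2 = run(start)
            if conv2 and (not path or path2[-1] >= path[-1] - 1e-9):
                freq, path, n_iter, converged = freq2, path2, n2, True
                break

    def hap_str(h: tuple[int, ...]) -> str:
        return "".join(
            cohort.snp(sid).variant_allele if a else cohort.snp(sid).wild_allele
            for sid, a in zip(snp_ids, h))

    return HaplotypeSet(
        snp_ids=tuple(snp_ids),
        haplotypes=[hap_str(h) for h in haps],
        frequencies=freq,
        loglik=path[-1],
        n_iter=n_iter,
        converged=converged,
        n_individuals=int(counts.sum()),
        loglik_path=path,
    )


def gamete_counting(cohort: Cohort, snp_ids: Sequence[str],
                    group: str = "pooled") -> np.ndarray:
    """Direct gamete counting for datasets with at most one heterozygous
    locus per individual (phase unambiguous).  Oracle for the EM."""
    k = len(snp_ids)
    cols = [cohort.snp_index(s) for s in snp_ids]
    geno = cohort.genotypes[:, cols]
    mask = (geno != MISSING).all(axis=1)
    if group == "case":
        mask &= cohort.status == CASE
    elif group == "control":
        mask &= cohort.status == CONTROL
    geno = geno[mask]
    if ((geno == 1).sum(axis=1) > 1).any():
        raise ValueError("phase ambiguous: individual heterozygous at >1 locus")
    haps = list(itertools.product((0, 1), repeat=k))
    index = {h: i for i, h in enumerate(haps)}
    counts = np.zeros(len(haps))
    for g in geno:
        h1 = tuple(1 if x == 2 else (1 if x == 1 else 0) for x in g)
        h2 = tuple(1 if x == 2 else 0 for x in g)
        counts[index[h1]] += 1
        counts[index[h2]] += 1
    return counts / counts.sum()


def ld_stats(freqs: Sequence[float]) -> LdStats:
    """Pairwise LD from haplotype frequencies (ww, wv, vw, vv).

    D = f(vv) - p1 p2 on the variant alleles; D' = |D| / D_max with the
    sign-dependent maximum; r^2 = D^2 / (p1 q1 p2 q2).  Raises for a
    monomorphic locus.
    """
    f = np.asarray(freqs, dtype=float)
    if f.shape != (4,) or (f < -1e-12).any() or abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("haplotype frequencies must be a 4-vector summing to 1")
    p1 = f[2] + f[3]  # variant at first locus
    p2 = f[1] + f[3]
    if min(p1, 1 - p1, p2, 1 - p2) <= 0:
        raise ValueError("LD undefined for a monomorphic locus")
    d = f[3] - p1 * p2
    if d >= 0:
        d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    else:
        d_max = min(p1 * p2, (1 - p1) * (1 - p2))
    d_prime = 0.0 if d == 0 else abs(d) / d_max
    r2 = d ** 2 / (p1 * (1 - p1) * p2 * (1 - p2))
    return LdStats(D=float(d), D_prime=float(min(d_prime, 1.0)), r2=float(r2))


def pairwise_ld(cohort: Cohort, snp_pair: Sequence[str],
                group: str = "pooled") -> LdStats:
    """EM-estimated haplotype frequencies for a SNP pair, summarised as LD."""
    hs = em_haplotypes(cohort, tuple(snp_pair), group=group)
    return ld_stats(hs.frequencies)


@dataclass
class HaplotypeAssoc:
    """Per-haplotype case-control association versus a reference haplotype."""

    table: pd.DataFrame           # haplotype, freq_case, freq_control, OR, CI, p
    global_chi2: float
    global_p: float
    reference: str


def haplotype_assoc(hs_case: HaplotypeSet, hs_control: HaplotypeSet,
                    reference: str | None = None,
                    min_freq: float = 0.01) -> HaplotypeAssoc:
    """Compare haplotype frequency distributions between cases and controls.

    Expected haplotype counts are 2N x frequency per group (EM convention,
    not best-guess phase).  Haplotypes below ``min_freq`` in both groups are
    pooled into a "rare" class.  ``reference`` defaults to the all-wild
    haplotype; per-haplotype ORs use Woolf CIs, the global test is a
    chi-square over the pooled haplotype count table.
    """
    if hs_case.snp_ids != hs_control.snp_ids:
        raise ValueError("case and control haplotype sets cover different SNPs")
    haps = hs_case.haplotypes
    if hs_control.haplotypes != haps:
        raise ValueError("haplotype orderings differ")
    if reference is None:
        reference = haps[0]  # lexicographically first = all wild alleles
    if reference not in haps:
        raise ValueError(f"reference haplotype {reference!r} not in the system")

    f_case = np.asarray(hs_case.frequencies, dtype=float)
    f_ctrl = np.asarray(hs_control.frequencies, dtype=float)
    keep = (f_case >= min_freq) | (f_ctrl >= min_freq)
    keep[haps.index(reference)] = True
    labels = [h for h, k in zip(haps, keep) if k]
    fc = f_case[keep]
    fk = f_ctrl[keep]
    if (~keep).any():
        labels.append("rare")
        fc = np.append(fc, f_case[~keep].sum())
        fk = np.append(fk, f_ctrl[~keep].sum())

    n_case = 2 * hs_case.n_individuals
    n_ctrl = 2 * hs_control.n_individuals
    c_case = fc * n_case
    c_ctrl = fk * n_ctrl
    ref_i = labels.index(reference)

    rows = []
    for i, h in enumerate(labels):
        if i == ref_i:
            rows.append({"haplotype": h, "freq_case": fc[i], "freq_control": fk[i],
                         "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan,
                         "p_value": np.nan, "is_reference": True})
            continue
        table = np.array([[c_ctrl[ref_i], c_ctrl[i]],
                          [c_case[ref_i], c_case[i]]])
        try:
            orr = crude_or(table)
            chi2, p, *_ = stats.chi2_contingency(np.maximum(table, 1e-9),
                                                 correction=False)[:2]
        except ValueError:
            orr = OrResult(np.nan, np.nan, np.nan)
            p = np.nan
        rows.append({"haplotype": h, "freq_case": fc[i], "freq_control": fk[i],
                     "odds_ratio": orr.odds_ratio, "ci_low": orr.ci_low,
                     "ci_high": orr.ci_high, "p_value": p, "is_reference": False})

    full = np.vstack([c_ctrl, c_case])
    pos = full.sum(axis=0) > 0
    chi2, p_global, *_ = stats.chi2_contingency(full[:, pos], correction=False)[:2]
    if np.allclose(fc, fk):
        chi2, p_global = 0.0, 1.0
    return HaplotypeAssoc(
        table=pd.DataFrame(rows), global_chi2=float(chi2),
        global_p=float(p_global), reference=reference)


class HaplotypeEM:
    """Model facade: EM haplotype analysis of one SNP system in a cohort."""

    def __init__(self, cohort: Cohort, snp_ids: Sequence[str]):
        self.cohort = cohort
        self.snp_ids = tuple(snp_ids)

    def fit(self, tol: float = 1e-8, max_iter: int = 500,
            min_freq: float = 0.01, reference: str | None = None
            ) -> "HaplotypeResults":
        case = em_haplotypes(self.cohort, self.snp_ids, "case", tol, max_iter)
        control = em_haplotypes(self.cohort, self.snp_ids, "control", tol, max_iter)
        pooled = em_haplotypes(self.cohort, self.snp_ids, "pooled", tol, max_iter)
        assoc = haplotype_assoc(case, control, reference=reference,
                                min_freq=min_freq)
        ld = ld_stats(pooled.frequencies) if len(self.snp_ids) == 2 else None
        return HaplotypeResults(self, case, control, pooled, assoc, ld)


class HaplotypeResults:
    def __init__(self, model, case, control, pooled, assoc, ld):
        self.model = model
        self.case = case
        self.control = control
        self.pooled = pooled
        self.assoc = assoc
        self.ld = ld

    def summary(self) -> pd.DataFrame:
        df = self.assoc.table.copy()
        df.attrs["global_p"] = self.assoc.global_p
        return df
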