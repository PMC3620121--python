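"""Synthetic case-control cohort generators.

Two sampling schemes are provided:

* **Retrospective** (:func:`simulate_cohort`): genotypes are drawn
  conditionally on case/control status from per-group genotype frequency
  triples, matching how a case-control study samples.  SNPs are independent
  except within declared LD blocks, where the two haplotypes of each
  individual are drawn from the block's four haplotype frequencies.
  Covariates (sex, age) are drawn independently of genotype.

* **Prospective / penetrance-based** (:func:`simulate_epistasis`):
  population individuals are drawn under Hardy-Weinberg and linkage
  equilibrium, disease status is drawn from a multilocus penetrance table,
  and sampling continues until the case and control quotas are filled.
  This is the harness used to check that interaction detectors (MDR, CART)
  recover embedded effects.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; a fixed seed yields a bit-identical cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CASE, CONTROL, Cohort
from .manifest import SnpDef

_TOL = 1e-9


@dataclass(frozen=True)
class LdBlock:
    """A pair of SNPs simulated jointly from haplotype frequencies.

    Haplotype frequencies are ordered (wild,wild), (wild,variant),
    (variant,wild), (variant,variant) with respect to the two SNPs' variant
    alleles.
    """

    snp_ids: tuple[str, str]
    hap_freq_control: tuple[float, float, float, float]
    hap_freq_case: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        for name, f in (("control", self.hap_freq_control), ("case", self.hap_freq_case)):
            f = np.asarray(f, dtype=float)
            if f.shape != (4,) or (f < -_TOL).any() or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"{self.snp_ids}: invalid {name} haplotype frequencies")

    def freqs(self, group: str) -> np.ndarray:
        return np.asarray(self.hap_freq_case if group == "case" else self.hap_freq_control)


@dataclass
class CohortSpec:
    """Specification of a retrospective synthetic cohort.

    ``genotype_freqs`` maps snp_id -> {"control": (f0,f1,f2), "case": ...}.
    SNPs covered by an ``ld_blocks`` entry are drawn from the block's
    haplotype frequencies instead of their marginal triples.
    """

    n_case: int
    n_control: int
    snps: list[SnpDef]
    genotype_freqs: Mapping[str, Mapping[str, Sequence[float]]]
    ld_blocks: list[LdBlock] = field(default_factory=list)
    female_fraction: Mapping[str, float] | float | None = None
    age: Mapping[str, tuple[float, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("group sizes must be positive")
        ids = {s.snp_id for s in self.snps}
        for snp_id, groups in self.genotype_freqs.items():
            if snp_id not in ids:
                raise ValueError(f"frequencies given for unknown SNP {snp_id!r}")
            for grp in ("control", "case"):
                f = np.asarray(groups[grp], dtype=float)
                if f.shape != (3,) or (f < -_TOL).any() or abs(f.sum() - 1.0) > 1e-9:
                    raise ValueError(f"{snp_id}: invalid {grp} genotype triple")
        block_snps = [s for b in self.ld_blocks for s in b.snp_ids]
        if len(block_snps) != len(set(block_snps)):
            raise ValueError("a SNP appears in more than one LD block")
        for s in block_snps:
            if s not in ids:
                raise ValueError(f"LD block references unknown SNP {s!r}")

    def female_frac(self, group: str) -> float | None:
        if self.female_fraction is None:
            return None
        if isinstance(self.female_fraction, Mapping):
            return float(self.female_fraction[group])
        return float(self.female_fraction)


def simulate_cohort(spec: CohortSpec, seed: int | None = None) -> Cohort:
    """Draw a retrospective case-control cohort from a :class:`CohortSpec`."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    snp_ids = [s.snp_id for s in spec.snps]
    col = {sid: j for j, sid in enumerate(snp_ids)}
    block_members = {sid for b in spec.ld_blocks for sid in b.snp_ids}

    n = spec.n_control + spec.n_case
    geno = np.zeros((n, len(spec.snps)), dtype=np.int8)
    status = np.concatenate([
        np.full(spec.n_control, CONTROL, dtype=np.int8),
        np.full(spec.n_case, CASE, dtype=np.int8),
    ])
    slices = {"control": slice(0, spec.n_control), "case": slice(spec.n_control, n)}
    sizes = {"control": spec.n_control, "case": spec.n_case}

    for grp in ("control", "case"):
        m, sl = sizes[grp], slices[grp]
        for sid in snp_ids:
            if sid in block_members:
                continue
            f = np.asarray(spec.genotype_freqs[sid][grp], dtype=float)
            geno[sl, col[sid]] = rng.choice(3, size=m, p=f / f.sum())
        for block in spec.ld_blocks:
            f = block.freqs(grp)
            # two haplotypes per individual; haplotype index bit0 = second SNP
            haps = rng.choice(4, size=(m, 2), p=f / f.sum())
            a_first = (haps >> 1).sum(axis=1)
            a_second = (haps & 1).sum(axis=1)
            geno[sl, col[block.snp_ids[0]]] = a_first
            geno[sl, col[block.snp_ids[1]]] = a_second

    cov = None
    if spec.female_fraction is not None or spec.age is not None:
        sex = np.empty(n, dtype=object)
        age = np.full(n, np.nan)
        for grp in ("control", "case"):
            m, sl = sizes[grp], slices[grp]
            ff = spec.female_frac(grp)
            if ff is not None:
                sex[sl] = np.where(rng.random(m) < ff, "female", "male")
            else:
                sex[sl] = "female"
            if spec.age is not None:
                mu, sd = spec.age[grp]
                age[sl] = rng.normal(mu, sd, size=m)
        cov = pd.DataFrame({"age": age, "sex": sex})

    ids = [f"K{i + 1:05d}" for i in range(spec.n_control)] + \
          [f"G{i + 1:05d}" for i in range(spec.n_case)]
    return Cohort(ids=ids, snps=list(spec.snps), genotypes=geno,
                  status=status, covariates=cov)


# -- penetrance-based (prospective) simulation ---------------------------------


@dataclass
class PenetranceModel:
    """Multilocus penetrance table: P(case | genotype cell) for k loci.

    ``penetrance`` maps every genotype tuple in {0,1,2}^k to a probability.
    """

    loci: tuple[str, ...]
    penetrance: Mapping[tuple[int, ...], float]
    prevalence: float = 0.1

    def __post_init__(self) -> None:
        k = len(self.loci)
        cells = set(itertools.product((0, 1, 2), repeat=k))
        if set(self.penetrance) != cells:
            raise ValueError(f"penetrance must cover all {3 ** k} genotype cells")
        for cell, p in self.penetrance.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"penetrance {p} for cell {cell} outside [0, 1]")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence outside [0, 1]")

    # -- convenience constructors used by recovery tests --------------------

    @classmethod
    def xor_two_locus(cls, loci: tuple[str, str], high: float = 0.5,
                      low: float = 0.05) -> "PenetranceModel":
        """Pure two-locus interaction: risk is elevated exactly when one of
        the two loci (and only one) carries at least one variant allele."""
        pen = {}
        for g1, g2 in itertools.product((0, 1, 2), repeat=2):
            carrier1, carrier2 = g1 > 0, g2 > 0
            pen[(g1, g2)] = high if carrier1 != carrier2 else low
        return cls(loci=loci, penetrance=pen, prevalence=low)

    @classmethod
    def single_locus_dominant(cls, locus: str, other: str,
                              carrier: float = 0.8,
                              noncarrier: float = 0.2) -> "PenetranceModel":
        """Dominant single-locus effect at ``locus``; ``other`` is a null
        companion locus so the cell space stays two-dimensional."""
        pen = {}
        for g1, g2 in itertools.product((0, 1, 2), repeat=2):
            pen[(g1, g2)] = carrier if g1 > 0 else noncarrier
        return cls(loci=(locus, other), penetrance=pen, prevalence=noncarrier)

    @classmethod
    def null(cls, loci: tuple[str, ...], prevalence: float = 0.3) -> "PenetranceModel":
        pen = {cell: prevalence
               for cell in itertools.product((0, 1, 2), repeat=len(loci))}
        return cls(loci=loci, penetrance=pen, prevalence=prevalence)


class SimulationError(RuntimeError):
    """Raised when case/control quotas cannot be filled."""


def simulate_epistasis(
    model: PenetranceModel,
    maf: Sequence[float],
    n_case: int,
    n_control: int,
    seed: int = 0,
    noise_snps: int = 0,
    noise_maf: float = 0.3,
    max_draws: int | None = None,
) -> Cohort:
    """Prospective sampling under a multilocus penetrance model.

    Genotypes at the model loci (variant-allele frequencies ``maf``) and at
    ``noise_snps`` additional null markers are drawn under HWE and linkage
    equilibrium; case status is Bernoulli with the cell's penetrance.
    Sampling proceeds in batches until both quotas are met, or fails after
    ``max_draws`` population draws (default ``2000 * (n_case + n_control)``).
    """
    k = len(model.loci)
    if len(maf) != k:
        raise ValueError("one variant-allele frequency required per model locus")
    rng = np.random.default_rng(seed)
    if max_draws is None:
        max_draws = 2000 * (n_case + n_control)

    pen_table = np.empty([3] * k)
    for cell, p in model.penetrance.items():
        pen_table[cell] = p

    snps = [SnpDef(sid, "SIM", "other", "A", "B") for sid in model.loci]
    snps += [SnpDef(f"NULL{i + 1}", "SIM", "other", "A", "B")
             for i in range(noise_snps)]

    got_case: list[np.ndarray] = []
    got_control: list[np.ndarray] = []
    need_case, need_control = n_case, n_control
    drawn = 0
    batch = max(1024, n_case + n_control)
    freqs = list(maf) + [noise_maf] * noise_snps
    while (need_case > 0 or need_control > 0) and drawn < max_draws:
        b = min(batch, max_draws - drawn)
        drawn += b
        g = np.column_stack([rng.binomial(2, f, size=b) for f in freqs]).astype(np.int8)
        p_case = pen_table[tuple(g[:, :k].T)]
        is_case = rng.random(b) < p_case
        if need_case > 0:
            take = g[is_case][:need_case]
            got_case.append(take)
            need_case -= len(take)
        if need_control > 0:
            take = g[~is_case][:need_control]
            got_control.append(take)
            need_control -= len(take)
    if need_case > 0 or need_control > 0:
        raise SimulationError(
            f"could not fill quotas after {drawn} draws "
            f"(missing {need_case} cases, {need_control} controls)")

    geno = np.vstack([np.vstack(got_control), np.vstack(got_case)])
    status = np.concatenate([
        np.full(n_control, CONTROL, dtype=np.int8),
        np.full(n_case, CASE, dtype=np.int8),
    ])
    ids = [f"K{i + 1:05d}" for i in range(n_control)] + \
          [f"G{i + 1:05d}" for i in range(n_case)]
    return Cohort(ids=ids, snps=snps, genotypes=geno, status=status)


# -- LD helpers ---------------------------------------------------------------

def haplotype_freqs_from_dprime(p1: float, p2: float, dprime: float
                                ) -> tuple[float, float, float, float]:
    """Haplotype frequencies for two loci with given variant-allele
    frequencies and a positive (variant-with-variant) D' coupling.

    Returns frequencies ordered (w,w), (w,v), (v,w), (v,v).
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("allele frequencies must be in (0, 1)")
    if not 0.0 <= dprime <= 1.0:
        raise ValueError("D' must be in [0, 1]")
    d_max = min(p1 * (1 - p2), (1 - p1) * p2)
    d = dprime * d_max
    f_vv = p1 * p2 + d
    f_vw = p1 * (1 - p2) - d
    f_wv = (1 - p1) * p2 - d
    f_ww = (1 - p1) * (1 - p2) + d
    return (f_ww, f_wv, f_vw, f_vv)
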