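"""Case-control cohort container and text-format readers/writers.

Genotypes are stored as an ``N x M`` ``int8`` matrix counting copies of the
manifest-designated *variant* allele (0/1/2), with ``-1`` for a missing
call.  Status is 1 for cases, 0 for controls.  Two plain-text dialects are
supported:

* PED/MAP — white-space separated, six leading PED columns
  (FID IID PAT MAT SEX PHENO, sex 1=male/2=female, phenotype 2=case,
  1=control), then two allele tokens per SNP, ``0 0`` meaning missing.
* delimited matrix — one row per individual with columns
  ``id  status  age  sex  <snp_id> ...`` where genotype entries are
  0/1/2/NA; status is ``case``/``control``.

Both are loss-lessly round-trippable.  Pseudo-cohorts can also be rebuilt
from published per-SNP genotype count tables (``expand_counts``), which
reproduces every per-SNP marginal exactly but carries no joint structure.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .manifest import SnpDef, load_manifest, validate_manifest, write_manifest

logger = logging.getLogger(__name__)

MISSING = -1  #: sentinel for a missing genotype call

CASE, CONTROL = 1, 0


@dataclass
class Cohort:
    """Individuals x SNPs genotype matrix with case/control labels.

    Attributes
    ----------
    ids : list of str
        Individual identifiers, in matrix row order.
    snps : list of SnpDef
        Marker definitions, in matrix column order.
    genotypes : ndarray of int8, shape (N, M)
        Variant-allele counts 0/1/2, or ``MISSING``.
    status : ndarray of int8, shape (N,)
        1 = case, 0 = control.
    covariates : DataFrame or None
        Optional per-individual covariates (columns ``age`` in years and
        ``sex`` coded ``"male"``/``"female"``), indexed like ``ids``.
    """

    ids: list[str]
    snps: list[SnpDef]
    genotypes: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.status = np.asarray(self.status, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.ids) != n:
            raise ValueError(f"{len(self.ids)} ids but {n} genotype rows")
        if len(self.snps) != m:
            raise ValueError(f"{len(self.snps)} SNPs but {m} genotype columns")
        validate_manifest(self.snps)
        if self.status.shape != (n,):
            raise ValueError("status length does not match individuals")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype entries must be 0/1/2 or missing")
        if not np.isin(self.status, (0, 1)).all():
            raise ValueError("status entries must be 0 (control) or 1 (case)")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise ValueError("covariate rows do not match individuals")
            self.covariates = self.covariates.reset_index(drop=True)

    # -- basic introspection -------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_case(self) -> int:
        return int((self.status == CASE).sum())

    @property
    def n_control(self) -> int:
        return int((self.status == CONTROL).sum())

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP {snp_id!r}") from None

    def snp(self, snp_id: str) -> SnpDef:
        return self.snps[self.snp_index(snp_id)]

    def column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self.snp_index(snp_id)]

    def require_both_groups(self) -> None:
        if self.n_case == 0 or self.n_control == 0:
            raise ValueError("operation requires at least one case and one control")

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row-subset the cohort with a boolean mask."""
        mask = np.asarray(mask, dtype=bool)
        cov = self.covariates.loc[mask].reset_index(drop=True) if self.covariates is not None else None
        return Cohort(
            ids=[i for i, keep in zip(self.ids, mask) if keep],
            snps=list(self.snps),
            genotypes=self.genotypes[mask].copy(),
            status=self.status[mask].copy(),
            covariates=cov,
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Genotypes (NaN for missing) plus status/covariates as a DataFrame."""
        geno = self.genotypes.astype(float)
        geno[geno == MISSING] = np.nan
        df = pd.DataFrame(geno, columns=self.snp_ids)
        df.insert(0, "status", np.where(self.status == CASE, "case", "control"))
        df.insert(0, "id", self.ids)
        if self.covariates is not None:
            for col in self.covariates.columns:
                df[col] = self.covariates[col].values
        return df


@dataclass
class CountTable:
    """Per-SNP 2x3 genotype counts (rows control, case; columns 0/1/2).

    ``collapsed`` marks tables whose source pooled heterozygotes with
    variant homozygotes into a single carrier row; for such tables column 1
    holds the pooled carrier count and column 2 is zero.
    """

    snp_id: str
    counts: np.ndarray  # shape (2, 3): rows control, case
    collapsed: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 3):
            raise ValueError(f"{self.snp_id}: counts must be 2x3")
        if (self.counts < 0).any():
            raise ValueError(f"{self.snp_id}: negative counts")
        if self.collapsed and self.counts[:, 2].any():
            raise ValueError(f"{self.snp_id}: collapsed table must have empty column 2")

    @property
    def control(self) -> np.ndarray:
        return self.counts[0]

    @property
    def case(self) -> np.ndarray:
        return self.counts[1]


# -- contingency tables ------------------------------------------------------

GENOTYPE_MODELS = ("genotypic", "dominant", "recessive", "allelic")


def genotype_counts(cohort: Cohort, snp_id: str, model: str = "genotypic") -> np.ndarray:
    """Group x genotype contingency table for one SNP.

    Missing genotypes are excluded pairwise.  Rows are (control, case);
    columns depend on ``model``:

    * ``genotypic`` — genotypes 0/1/2 (2x3);
    * ``dominant``  — wild homozygote vs variant carrier (2x2);
    * ``recessive`` — non-variant-homozygote vs variant homozygote (2x2);
    * ``allelic``   — wild vs variant allele counts (2x2), variant count =
      het + 2 x hom-variant per group.
    """
    g = cohort.column(snp_id)
    table = np.zeros((2, 3), dtype=np.int64)
    for row, grp in enumerate((CONTROL, CASE)):
        sel = g[(cohort.status == grp) & (g != MISSING)]
        table[row] = np.bincount(sel, minlength=3)[:3]
    if model == "genotypic":
        return table
    if model == "dominant":
        return np.column_stack([table[:, 0], table[:, 1] + table[:, 2]])
    if model == "recessive":
        return np.column_stack([table[:, 0] + table[:, 1], table[:, 2]])
    if model == "allelic":
        wild = 2 * table[:, 0] + table[:, 1]
        variant = table[:, 1] + 2 * table[:, 2]
        return np.column_stack([wild, variant])
    raise ValueError(f"unknown model {model!r}; expected one of {GENOTYPE_MODELS}")


def count_tables(cohort: Cohort) -> list[CountTable]:
    """Genotypic CountTable for every SNP of the cohort."""
    return [CountTable(s.snp_id, genotype_counts(cohort, s.snp_id)) for s in cohort.snps]


# -- pseudo-cohort reconstruction from printed tables -------------------------

def expand_counts(
    tables: Sequence[CountTable],
    snps: Sequence[SnpDef],
    n_control: int,
    n_case: int,
    collapsed_mode: str = "het",
) -> Cohort:
    """Rebuild an individual-level pseudo-cohort from per-SNP count tables.

    Each SNP column is filled independently and deterministically: within
    each status group the genotypes are laid out in ascending order and then
    shuffled by a fixed per-column permutation, so every per-SNP marginal
    equals the input table exactly while the columns carry no systematic
    joint structure.  Collapsed carrier rows are expanded as all
    heterozygotes by
    default (``collapsed_mode="het"``, which preserves printed allele
    counts) or as all variant homozygotes (``"hom"``).
    """
    if collapsed_mode not in ("het", "hom"):
        raise ValueError("collapsed_mode must be 'het' or 'hom'")
    by_id = {t.snp_id: t for t in tables}
    missing = [s.snp_id for s in snps if s.snp_id not in by_id]
    if missing:
        raise ValueError(f"no count table for SNPs {missing}")
    for t in tables:
        sums = t.counts.sum(axis=1)
        if sums[0] != n_control or sums[1] != n_case:
            raise ValueError(
                f"{t.snp_id}: row sums {tuple(sums)} do not match group sizes "
                f"({n_control}, {n_case})")

    n = n_control + n_case
    geno = np.empty((n, len(snps)), dtype=np.int8)
    for j, snp in enumerate(snps):
        t = by_id[snp.snp_id]
        counts = t.counts.copy()
        if t.collapsed and collapsed_mode == "hom":
            counts[:, 2] = counts[:, 1]
            counts[:, 1] = 0
        rng = np.random.default_rng(j)  # fixed per-column permutation
        geno[:, j] = np.concatenate([
            rng.permutation(np.repeat([0, 1, 2], counts[0])),
            rng.permutation(np.repeat([0, 1, 2], counts[1])),
        ])
    ids = [f"K{i + 1:04d}" for i in range(n_control)] + \
          [f"G{i + 1:04d}" for i in range(n_case)]
    status = np.concatenate([
        np.full(n_control, CONTROL, dtype=np.int8),
        np.full(n_case, CASE, dtype=np.int8),
    ])
    return Cohort(ids=ids, snps=list(snps), genotypes=geno, status=status)


# -- PED/MAP dialect ----------------------------------------------------------

def _code_call(a1: str, a2: str, snp: SnpDef) -> int:
    if a1 == "0" and a2 == "0":
        return MISSING
    alleles = {snp.wild_allele: 0, snp.variant_allele: 1}
    if a1 not in alleles or a2 not in alleles:
        return -2  # unresolvable against manifest
    return alleles[a1] + alleles[a2]


def read_ped(ped_path: str | Path, map_path: str | Path,
             manifest: Sequence[SnpDef]) -> Cohort:
    """Read a PED/MAP pair against a manifest.

    The MAP file fixes SNP order; every MAP snp_id must exist in the
    manifest.  Allele calls not matching the manifest become missing and are
    counted in a logged warning.
    """
    map_path, ped_path = Path(map_path), Path(ped_path)
    by_id = {s.snp_id: s for s in manifest}
    snps: list[SnpDef] = []
    with map_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{map_path}:{lineno}: malformed MAP line")
            snp_id = parts[1]
            if snp_id not in by_id:
                raise ValueError(f"{map_path}:{lineno}: SNP {snp_id!r} not in manifest")
            snps.append(by_id[snp_id])

    ids: list[str] = []
    status_l: list[int] = []
    sex_l: list[str] = []
    rows: list[list[int]] = []
    unresolved = 0
    with ped_path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * len(snps):
                raise ValueError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * len(snps)} fields, "
                    f"got {len(parts)}")
            ids.append(parts[1])
            sex_l.append({"1": "male", "2": "female"}.get(parts[4], "unknown"))
            if parts[5] not in ("1", "2"):
                raise ValueError(f"{ped_path}:{lineno}: phenotype must be 1 or 2")
            status_l.append(CASE if parts[5] == "2" else CONTROL)
            row = []
            for j, snp in enumerate(snps):
                code = _code_call(parts[6 + 2 * j], parts[7 + 2 * j], snp)
                if code == -2:
                    unresolved += 1
                    code = MISSING
                row.append(code)
            rows.append(row)
    if unresolved:
        logger.warning("%s: %d genotype call(s) did not match the manifest "
                       "alleles and were set to missing", ped_path, unresolved)
    cov = pd.DataFrame({"age": np.nan, "sex": sex_l}, index=range(len(ids)))
    cohort = Cohort(ids=ids, snps=snps, genotypes=np.array(rows, dtype=np.int8),
                    status=np.array(status_l, dtype=np.int8), covariates=cov)
    return cohort


def write_ped(cohort: Cohort, ped_path: str | Path, map_path: str | Path) -> None:
    ped_path, map_path = Path(ped_path), Path(map_path)
    with map_path.open("w") as fh:
        for s in cohort.snps:
            fh.write(f"0\t{s.snp_id}\t0\t0\n")
    sex_code = {"male": "1", "female": "2"}
    with ped_path.open("w") as fh:
        for i, iid in enumerate(cohort.ids):
            sex = "0"
            if cohort.covariates is not None and "sex" in cohort.covariates:
                sex = sex_code.get(str(cohort.covariates["sex"].iloc[i]), "0")
            pheno = "2" if cohort.status[i] == CASE else "1"
            fields = [iid, iid, "0", "0", sex, pheno]
            for j, snp in enumerate(cohort.snps):
                g = cohort.genotypes[i, j]
                if g == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [snp.wild_allele] * (2 - g) + [snp.variant_allele] * g
            fh.write(" ".join(fields) + "\n")


# -- delimited matrix dialect --------------------------------------------------

def read_delimited(path: str | Path, manifest: Sequence[SnpDef]) -> Cohort:
    """Read a tab-delimited genotype matrix (id, status, age, sex, SNP...)."""
    path = Path(path)
    by_id = {s.snp_id: s for s in manifest}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None or header[:2] != ["id", "status"]:
            raise ValueError(f"{path}: header must start with 'id\\tstatus'")
        has_cov = header[2:4] == ["age", "sex"]
        snp_cols = header[4:] if has_cov else header[2:]
        unknown = [c for c in snp_cols if c not in by_id]
        if unknown:
            raise ValueError(f"{path}: SNPs not in manifest: {unknown}")
        snps = [by_id[c] for c in snp_cols]
        ids, status_l, ages, sexes, rows = [], [], [], [], []
        unresolved = 0
        for lineno, parts in enumerate(reader, start=2):
            if not parts:
                continue
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields, "
                                 f"got {len(parts)}")
            ids.append(parts[0])
            if parts[1] not in ("case", "control"):
                raise ValueError(f"{path}:{lineno}: status must be case/control")
            status_l.append(CASE if parts[1] == "case" else CONTROL)
            off = 2
            if has_cov:
                ages.append(float(parts[2]) if parts[2] not in ("", "NA") else np.nan)
                sexes.append(parts[3])
                off = 4
            row = []
            for tok in parts[off:]:
                if tok in ("NA", ""):
                    row.append(MISSING)
                elif tok in ("0", "1", "2"):
                    row.append(int(tok))
                else:
                    unresolved += 1
                    row.append(MISSING)
            rows.append(row)
    if unresolved:
        logger.warning("%s: %d unparseable genotype entr(ies) set to missing",
                       path, unresolved)
    cov = None
    if has_cov:
        cov = pd.DataFrame({"age": ages, "sex": sexes})
    return Cohort(ids=ids, snps=snps, genotypes=np.array(rows, dtype=np.int8),
                  status=np.array(status_l, dtype=np.int8), covariates=cov)


def write_delimited(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    has_cov = cohort.covariates is not None
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = ["id", "status"] + (["age", "sex"] if has_cov else []) + cohort.snp_ids
        writer.writerow(header)
        for i, iid in enumerate(cohort.ids):
            row = [iid, "case" if cohort.status[i] == CASE else "control"]
            if has_cov:
                age = cohort.covariates["age"].iloc[i]
                row.append("NA" if pd.isna(age) else f"{float(age):g}")
                row.append(str(cohort.covariates["sex"].iloc[i]))
            row += ["NA" if g == MISSING else str(int(g)) for g in cohort.genotypes[i]]
            writer.writerow(row)


# -- format-dispatching loaders -------------------------------------------------

def load_cohort(path: str | Path, format: str,
                manifest: str | Path | Sequence[SnpDef]) -> Cohort:
    """Load a cohort from ``ped_map`` (path = PED file; MAP alongside with
    ``.map`` suffix) or ``delimited`` format."""
    if not isinstance(manifest, (str, Path)):
        snps = list(manifest)
    else:
        snps = load_manifest(manifest)
    path = Path(path)
    if format == "ped_map":
        return read_ped(path, path.with_suffix(".map"), snps)
    if format == "delimited":
        return read_delimited(path, snps)
    raise ValueError(f"unknown format {format!r}")


def write_cohort(cohort: Cohort, path: str | Path, format: str) -> None:
    path = Path(path)
    if format == "ped_map":
        write_ped(cohort, path, path.with_suffix(".map"))
    elif format == "delimited":
        write_delimited(cohort, path)
    else:
        raise ValueError(f"unknown format {format!r}")
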