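"""SNP manifest: identity, alleles and pathway membership of each marker.

A manifest row fixes, once and for all, which allele of a biallelic SNP is
the *wild* (ancestral/reference) allele and which is the *variant*.  All
genotype coding downstream (0 = homozygous wild, 1 = heterozygous,
2 = homozygous variant) is defined relative to this designation — never
relative to the observed minor allele, which can flip between samples.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: Pathways of the gallstone candidate-gene panel; "other" is allowed for
#: markers outside the three study pathways.
PATHWAYS = ("hormonal", "hepatocanalicular", "adipogenesis", "other")

_MANIFEST_COLUMNS = ("snp_id", "gene", "pathway", "wild_allele",
                     "variant_allele", "risk_allele")


@dataclass(frozen=True)
class SnpDef:
    """Definition of one biallelic SNP.

    Parameters
    ----------
    snp_id : str
        Unique identifier (rsID or study label).
    gene : str
        Gene symbol the marker belongs to.
    pathway : str
        One of :data:`PATHWAYS`.
    wild_allele, variant_allele : str
        Single-character nucleotide / indel codes (e.g. ``"C"``, ``"T"``,
        ``"D"``/``"I"`` for an insertion-deletion).
    risk_allele : str
        ``"variant"`` or ``"wild"``: which allele the risk score counts.
    label : str
        Optional human-readable label for reports (defaults to ``snp_id``).
    """

    snp_id: str
    gene: str
    pathway: str
    wild_allele: str
    variant_allele: str
    risk_allele: str = "variant"
    label: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.pathway not in PATHWAYS:
            raise ValueError(
                f"{self.snp_id}: pathway {self.pathway!r} not in {PATHWAYS}")
        if len(self.wild_allele) != 1 or len(self.variant_allele) != 1:
            raise ValueError(f"{self.snp_id}: alleles must be single characters")
        if self.wild_allele == self.variant_allele:
            raise ValueError(f"{self.snp_id}: wild and variant alleles are equal")
        if self.risk_allele not in ("wild", "variant"):
            raise ValueError(f"{self.snp_id}: risk_allele must be 'wild' or 'variant'")
        if not self.label:
            object.__setattr__(self, "label", self.snp_id)

    @property
    def risk_allele_char(self) -> str:
        return self.variant_allele if self.risk_allele == "variant" else self.wild_allele


def validate_manifest(snps: Sequence[SnpDef]) -> None:
    """Raise if SNP ids are not unique."""
    seen: set[str] = set()
    for s in snps:
        if s.snp_id in seen:
            raise ValueError(f"duplicate snp_id in manifest: {s.snp_id}")
        seen.add(s.snp_id)


def load_manifest(path: str | Path) -> list[SnpDef]:
    """Read a tab-delimited manifest (header: snp_id gene pathway wild_allele
    variant_allele risk_allele [label])."""
    path = Path(path)
    snps: list[SnpDef] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_MANIFEST_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                snps.append(SnpDef(
                    snp_id=row["snp_id"].strip(),
                    gene=row["gene"].strip(),
                    pathway=row["pathway"].strip(),
                    wild_allele=row["wild_allele"].strip(),
                    variant_allele=row["variant_allele"].strip(),
                    risk_allele=row["risk_allele"].strip() or "variant",
                    label=(row.get("label") or "").strip(),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{i}: bad manifest row: {exc}") from exc
    validate_manifest(snps)
    return snps


def write_manifest(snps: Iterable[SnpDef], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_MANIFEST_COLUMNS + ("label",))
        for s in snps:
            writer.writerow([s.snp_id, s.gene, s.pathway, s.wild_allele,
                             s.variant_allele, s.risk_allele, s.label])
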