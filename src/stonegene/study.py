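"""Built-in gallstone candidate-gene panel: 13 SNPs in 9 genes.

The published study genotyped 13 biallelic polymorphisms across three
candidate pathways (hormonal receptors, hepatocanalicular transporters,
adipogenesis differentiation) in 230 gallstone cases and 220 controls.  The
per-group genotype count tables printed in the report are reproduced here
as machine-readable inputs, together with the demographic summary and the
two linkage-disequilibrium pairs, so that:

* ``pseudo_cohort()`` rebuilds an individual-level cohort whose per-SNP
  marginals equal the printed tables exactly (no joint structure), and
* ``cohort_spec()`` builds a synthetic-cohort specification that emulates
  the study's frequencies, LD, sex ratio and age distribution.

For several markers the source pooled variant carriers into a single row;
for every one of these the printed allele counts equal the pooled carrier
counts, which is only consistent with zero variant homozygotes, so the
pooled count is stored in the heterozygote column with ``collapsed=True``.
"""

from __future__ import annotations

import numpy as np

from .cohort import Cohort, CountTable, expand_counts
from .manifest import SnpDef

N_CASE = 230
N_CONTROL = 220

#: age mean and SD (years) per group
AGE = {"control": (49.0, 9.8), "case": (48.6, 11.9)}
#: observed female fraction per group (143/220 controls, 147/230 cases)
FEMALE_FRACTION = {"control": 143 / 220, "case": 147 / 230}

PANEL: list[SnpDef] = [
    SnpDef("rs2234693", "ESR1", "hormonal", "C", "T", label="ESR1 IVS1-397C>T"),
    SnpDef("rs9340799", "ESR1", "hormonal", "A", "G", label="ESR1 IVS1-351A>G"),
    SnpDef("rs1801132", "ESR1", "hormonal", "C", "G", label="ESR1 Ex4-122C>G"),
    SnpDef("rs1271572", "ESR2", "hormonal", "A", "C", label="ESR2 -789A>C"),
    SnpDef("rs1256049", "ESR2", "hormonal", "G", "A", label="ESR2 1082G>A"),
    SnpDef("rs1042838", "PGR", "hormonal", "D", "I", label="PGR ins/del"),
    SnpDef("rs4994", "ADRB3", "hormonal", "T", "C", label="ADRB3 -190T>C"),
    SnpDef("rs1800544", "ADRA2A", "hormonal", "C", "G", label="ADRA2A -1291C>G"),
    SnpDef("rs11887534", "ABCG8", "hepatocanalicular", "G", "C", label="ABCG8 145G>C (D19H)"),
    SnpDef("rs11045819", "SLCO1B1", "hepatocanalicular", "C", "A", label="SLCO1B1 Exon4 C>A"),
    SnpDef("rs4149056", "SLCO1B1", "hepatocanalicular", "T", "C", label="SLCO1B1 Ex6+40T>C"),
    SnpDef("rs2228314", "SREBP2", "adipogenesis", "G", "C", label="SREBP2 1784G>C"),
    SnpDef("rs1801282", "PPARG2", "adipogenesis", "C", "G", label="PPARG2 C>G (Pro12Ala)"),
]

#: printed genotype counts: snp_id -> ((control 0,1,2), (case 0,1,2), collapsed)
#: collapsed=True: carriers pooled in the source; pooled count in column 1.
GENOTYPE_COUNTS: dict[str, tuple[tuple[int, int, int], tuple[int, int, int], bool]] = {
    "rs2234693": ((91, 110, 19), (64, 128, 38), False),
    "rs9340799": ((90, 109, 21), (69, 117, 44), False),
    "rs1801132": ((106, 104, 10), (120, 97, 13), False),
    "rs1271572": ((94, 109, 17), (105, 107, 18), False),
    "rs1256049": ((206, 14, 0), (212, 18, 0), True),
    "rs1042838": ((181, 39, 0), (208, 22, 0), True),
    "rs4994": ((178, 42, 0), (158, 72, 0), True),
    "rs1800544": ((61, 117, 42), (53, 117, 60), False),
    "rs11887534": ((209, 11, 0), (206, 24, 0), True),
    "rs11045819": ((205, 15, 0), (200, 30, 0), True),
    "rs4149056": ((212, 8, 0), (218, 12, 0), True),
    "rs2228314": ((145, 73, 2), (138, 82, 10), False),
    "rs1801282": ((178, 42, 0), (176, 54, 0), True),
}

#: SNP pairs reported in strong LD, with the published D' values
LD_PAIRS: dict[tuple[str, str], float] = {
    ("rs2234693", "rs9340799"): 0.575,
    ("rs11045819", "rs4149056"): 0.8916,
}


def manifest() -> list[SnpDef]:
    """The 13-SNP study manifest (fresh copy)."""
    return list(PANEL)


def count_tables() -> list[CountTable]:
    """The printed genotype count tables, in panel order."""
    return [
        CountTable(snp_id=s.snp_id,
                   counts=np.array(GENOTYPE_COUNTS[s.snp_id][:2]),
                   collapsed=GENOTYPE_COUNTS[s.snp_id][2])
        for s in PANEL
    ]


def pseudo_cohort(collapsed_mode: str = "het") -> Cohort:
    """Individual-level pseudo-cohort reconstructed from the printed tables.

    Per-SNP genotype marginals match the publication exactly; columns are
    filled independently, so multi-locus statistics computed from this
    cohort exercise the machinery but do not reproduce the study's joint
    (individual-level) results.
    """
    return expand_counts(count_tables(), PANEL, N_CONTROL, N_CASE,
                         collapsed_mode=collapsed_mode)


def genotype_frequencies() -> dict[str, dict[str, tuple[float, float, float]]]:
    """Per-group genotype frequency triples implied by the printed tables."""
    out: dict[str, dict[str, tuple[float, float, float]]] = {}
    for s in PANEL:
        ctrl, case, _ = GENOTYPE_COUNTS[s.snp_id]
        out[s.snp_id] = {
            "control": tuple(np.asarray(ctrl) / N_CONTROL),
            "case": tuple(np.asarray(case) / N_CASE),
        }
    return out


def cohort_spec(seed: int = 0):
    """CohortSpec emulating the study cohort (sizes, frequencies, LD, covariates)."""
    from .simulate import CohortSpec, LdBlock, haplotype_freqs_from_dprime

    freqs = genotype_frequencies()
    blocks = []
    for (a, b), dprime in LD_PAIRS.items():
        per_group = {}
        for grp in ("control", "case"):
            pa = freqs[a][grp][1] / 2 + freqs[a][grp][2]
            pb = freqs[b][grp][1] / 2 + freqs[b][grp][2]
            per_group[grp] = haplotype_freqs_from_dprime(pa, pb, dprime)
        blocks.append(LdBlock(snp_ids=(a, b),
                              hap_freq_control=per_group["control"],
                              hap_freq_case=per_group["case"]))
    return CohortSpec(
        n_case=N_CASE,
        n_control=N_CONTROL,
        snps=manifest(),
        genotype_freqs=freqs,
        ld_blocks=blocks,
        female_fraction=dict(FEMALE_FRACTION),
        age=dict(AGE),
        seed=seed,
    )
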