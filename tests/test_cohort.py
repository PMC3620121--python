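"""Data model: loaders/writers, count expansion, contingency tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stonegene as sg
from stonegene.cohort import CASE, CONTROL, MISSING, read_delimited, read_ped

from conftest import make_cohort


# -- PED/MAP and delimited round trips ----------------------------------------

def _write_fixture_ped(tmp_path, manifest):
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    map_.write_text("".join(f"0\t{s.snp_id}\t0\t0\n" for s in manifest))
    ped.write_text(
        "f1 i1 0 0 1 1 C C A A\n"
        "f2 i2 0 0 2 2 C T G G\n"
    )
    return ped, map_


def test_ped_direct_genotype_coding(tmp_path, two_snp_manifest):
    ped, map_ = _write_fixture_ped(tmp_path, two_snp_manifest)
    cohort = read_ped(ped, map_, two_snp_manifest)
    assert cohort.ids == ["i1", "i2"]
    assert cohort.genotypes.tolist() == [[0, 0], [1, 2]]
    assert cohort.status.tolist() == [CONTROL, CASE]
    assert list(cohort.covariates["sex"]) == ["male", "female"]


def test_ped_unresolvable_allele_becomes_missing(tmp_path, two_snp_manifest, caplog):
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    map_.write_text("".join(f"0\t{s.snp_id}\t0\t0\n" for s in two_snp_manifest))
    ped.write_text("f1 i1 0 0 1 1 C X 0 0\n")
    with caplog.at_level("WARNING"):
        cohort = read_ped(ped, map_, two_snp_manifest)
    assert cohort.genotypes.tolist() == [[MISSING, MISSING]]
    assert "1 genotype call" in caplog.text


def test_ped_malformed_line_names_line_number(tmp_path, two_snp_manifest):
    ped = tmp_path / "toy.ped"
    map_ = tmp_path / "toy.map"
    map_.write_text("".join(f"0\t{s.snp_id}\t0\t0\n" for s in two_snp_manifest))
    ped.write_text("f1 i1 0 0 1 1 C C A A\nf2 i2 0 0 1 2 C C\n")
    with pytest.raises(ValueError, match=":2"):
        read_ped(ped, map_, two_snp_manifest)


def test_delimited_nn_entry_missing_with_warning(tmp_path, two_snp_manifest, caplog):
    path = tmp_path / "toy.tsv"
    path.write_text("id\tstatus\tsnpA\tsnpB\n"
                    "i1\tcase\tNN\t1\n")
    with caplog.at_level("WARNING"):
        cohort = read_delimited(path, two_snp_manifest)
    assert cohort.genotypes.tolist() == [[MISSING, 1]]
    assert "1 unparseable" in caplog.text


@pytest.mark.parametrize("fmt", ["ped_map", "delimited"])
def test_write_load_round_trip(tmp_path, fmt, synthetic_study_cohort):
    path = tmp_path / ("c.ped" if fmt == "ped_map" else "c.tsv")
    sg.write_cohort(synthetic_study_cohort, path, fmt)
    back = sg.load_cohort(path, fmt, synthetic_study_cohort.snps)
    np.testing.assert_array_equal(back.genotypes,
                                  synthetic_study_cohort.genotypes)
    np.testing.assert_array_equal(back.status, synthetic_study_cohort.status)
    assert back.ids == synthetic_study_cohort.ids


def test_manifest_round_trip(tmp_path):
    sg.write_manifest(sg.study.manifest(), tmp_path / "m.tsv")
    back = sg.load_manifest(tmp_path / "m.tsv")
    assert back == sg.study.manifest()


# -- expand_counts -------------------------------------------------------------

def test_expand_counts_reproduces_printed_marginals(study_cohort):
    for table in sg.study.count_tables():
        got = sg.genotype_counts(study_cohort, table.snp_id)
        if table.collapsed:
            pooled = np.column_stack([got[:, 0], got[:, 1] + got[:, 2]])
            expect = np.column_stack([table.counts[:, 0], table.counts[:, 1]])
            np.testing.assert_array_equal(pooled, expect)
        else:
            np.testing.assert_array_equal(got, table.counts)


def test_expand_counts_all_wild_controls():
    snps = [sg.SnpDef("x", "G", "other", "A", "B")]
    t = sg.CountTable("x", [[220, 0, 0], [100, 80, 50]])
    cohort = sg.expand_counts([t], snps, 220, 230)
    ctrl = cohort.genotypes[cohort.status == CONTROL, 0]
    assert (ctrl == 0).all()


def test_expand_counts_row_sum_mismatch_raises():
    snps = [sg.SnpDef("x", "G", "other", "A", "B")]
    t = sg.CountTable("x", [[1, 0, 0], [2, 0, 0]])
    with pytest.raises(ValueError, match="row sums"):
        sg.expand_counts([t], snps, 5, 2)


@settings(deadline=None, max_examples=25)
@given(st.lists(
    st.tuples(st.lists(st.integers(0, 40), min_size=3, max_size=3),
              st.lists(st.integers(0, 40), min_size=3, max_size=3)),
    min_size=1, max_size=5))
def test_expand_then_recount_is_identity(tables_raw):
    """expand_counts followed by genotype_counts returns the inputs exactly."""
    snps, tables = [], []
    for j, (ctrl, case) in enumerate(tables_raw):
        ctrl = [ctrl[0] + 1, ctrl[1], ctrl[2]]
        case = [case[0] + 1, case[1], case[2]]
        # pad all tables to common group sizes
        snps.append(sg.SnpDef(f"s{j}", "G", "other", "A", "B"))
        tables.append((ctrl, case))
    n_ctrl = max(sum(c) for c, _ in tables)
    n_case = max(sum(c) for _, c in tables)
    cts = []
    for sid, (ctrl, case) in zip(snps, tables):
        ctrl[0] += n_ctrl - sum(ctrl)
        case[0] += n_case - sum(case)
        cts.append(sg.CountTable(sid.snp_id, [ctrl, case]))
    cohort = sg.expand_counts(cts, snps, n_ctrl, n_case)
    for ct in cts:
        np.testing.assert_array_equal(
            sg.genotype_counts(cohort, ct.snp_id), ct.counts)


# -- genotype_counts models ------------------------------------------------------

def test_allelic_counts_match_printed_allele_row(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs2234693", "allelic")
    assert t[1, 1] == 204  # variant T alleles among cases
    assert t[1, 0] == 256
    assert t[0, 1] == 148


def test_dominant_pooling_arithmetic(study_cohort):
    t = sg.genotype_counts(study_cohort, "rs2234693", "dominant")
    assert t[0].tolist() == [91, 129]


def test_allelic_all_wild_group():
    cohort = make_cohort([[0], [0], [1]], [0, 0, 1])
    t = sg.genotype_counts(cohort, "s1", "allelic")
    assert t[0].tolist() == [4, 0]  # controls carry no variant alleles


def test_allelic_counts_sum_to_two_per_individual(synthetic_study_cohort):
    c = synthetic_study_cohort
    for sid in c.snp_ids[:4]:
        t = sg.genotype_counts(c, sid, "allelic")
        geno = sg.genotype_counts(c, sid, "genotypic")
        np.testing.assert_array_equal(t.sum(axis=1), 2 * geno.sum(axis=1))


def test_unknown_snp_id_raises(study_cohort):
    with pytest.raises(KeyError):
        sg.genotype_counts(study_cohort, "rs0")


def test_missing_genotypes_excluded_pairwise():
    cohort = make_cohort([[0, MISSING], [1, 1], [2, 0], [MISSING, 2]],
                         [0, 0, 1, 1])
    t = sg.genotype_counts(cohort, "s1")
    assert t.sum() == 3
    t2 = sg.genotype_counts(cohort, "s2")
    assert t2.sum() == 3
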