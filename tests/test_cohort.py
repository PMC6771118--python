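import textwrap

import pytest

import bestqspr as bq
from bestqspr.cohort import CohortParseError, load_cohort_table, write_cohort_table


def test_reference_cohort_counts(reference_cohort):
    """36 probands, of whom 27 carry BCVA for both eyes."""
    assert len(reference_cohort) == 36
    report = bq.validate_cohort(reference_cohort)
    assert report.n_rows == 36
    assert report.n_bcva_complete == 27
    assert "P20" in report.missing_bcva_ids


def test_grouping_is_a_partition(reference_cohort):
    groups = bq.group_by_variant(reference_cohort)
    sizes = sum(len(g) for g in groups.values())
    assert sizes == len(reference_cohort)
    ids = [r.proband_id for g in groups.values() for r in g]
    assert sorted(ids) == sorted(r.proband_id for r in reference_cohort)


def test_grouping_by_protein_change_not_nucleotide(reference_cohort):
    """c.888C>G and c.888C>A both encode p.(Asn296Lys) and share a group."""
    groups = {v.canonical: g for v, g in bq.group_by_variant(reference_cohort).items()}
    assert [r.proband_id for r in groups["p.(Asn296Lys)"]] == ["P32", "P33"]
    assert [r.proband_id for r in groups["p.(Gly15Asp)"]] == ["P5", "P6", "P7"]
    changes = {r.nucleotide_change for r in groups["p.(Asn296Lys)"]}
    assert changes == {"c.888C>G", "c.888C>A"}


def test_single_record_singleton_group(reference_cohort):
    one = [reference_cohort[0]]
    groups = bq.group_by_variant(one)
    assert len(groups) == 1 and sum(len(g) for g in groups.values()) == 1


def test_decimal_comma_dialect(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(
        textwrap.dedent(
            """\
            proband_id;age_years;amino_acid_change;bcva_le;bcva_re
            X1;12,85;p.(Asn296Lys);0,3;0,1
            """
        )
    )
    (rec,) = load_cohort_table(p, decimal=",")
    assert rec.age_years == pytest.approx(12.85)
    assert rec.bcva_le == pytest.approx(0.3)


def test_missing_cells_accept_na_dash_empty(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(
        "proband_id,age_years,amino_acid_change,bcva_le,bcva_re\n"
        "X1,40,p.(Thr2Ile),NA,-\n"
        "X2,41,p.(Thr2Ile),,0.3\n"
    )
    recs = load_cohort_table(p)
    assert not recs[0].has_bcva
    assert recs[1].partially_missing


def test_header_only_file_gives_empty_list(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("proband_id,age_years,amino_acid_change,bcva_le,bcva_re\n")
    assert load_cohort_table(p) == []


def test_missing_mandatory_column_raises(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("proband_id,amino_acid_change\nX1,p.(Thr2Ile)\n")
    with pytest.raises(CohortParseError, match="age_years"):
        load_cohort_table(p)


def test_row_level_error_names_row(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(
        "proband_id,age_years,amino_acid_change,bcva_le,bcva_re\n"
        "X1,40,p.(Thr2Ile),0,0\n"
        "X2,-3,p.(Thr2Ile),0,0\n"
    )
    with pytest.raises(CohortParseError, match="row 1"):
        load_cohort_table(p)


def test_round_trip_preserves_fields(reference_cohort, tmp_path):
    out = tmp_path / "again.csv"
    write_cohort_table(reference_cohort, out)
    again = load_cohort_table(out)
    assert len(again) == len(reference_cohort)
    for a, b in zip(reference_cohort, again):
        assert a.proband_id == b.proband_id
        assert a.age_years == b.age_years
        assert a.variant.canonical == b.variant.canonical
        assert a.bcva_le == b.bcva_le and a.bcva_re == b.bcva_re
        assert a.stage_le == b.stage_le and a.stage_re == b.stage_re
        assert a.allele_state == b.allele_state


def test_reference_energy_table(reference_energies):
    assert len(reference_energies) == 25
    by_id = {r.point_id: r for r in reference_energies}
    stop = by_id["P20"]
    assert stop.variant.truncating and stop.dde_dim is None
    # the decimal-comma cells of the source table are carried as numbers
    assert by_id["P17"].mean_bdsi == pytest.approx(32.60)
    assert by_id["P32-P33"].mean_bdsi == pytest.approx(12.85)
    assert by_id["P32-P33"].dde_cabin == pytest.approx(80.0)
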