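"""Strain-table parsing, extremophily classification and survey statistics."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ferrohab.strains import (
    AdaptationThresholds,
    StrainRecord,
    StrainTableError,
    classify_adaptations,
    donor_use_crosstab,
    envelope_extrema,
    is_polyextremophile,
    optimum_midpoint,
    parse_strain_table,
    summarize_counts,
    sweet_spot_stats,
    write_strain_table,
)


class TestParsing:
    def test_range_midpoint_and_nd(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "name\tsection\tT_opt\tT_min\tT_max\tpH_opt\n"
            "A\tthermophile\t30 - 35\t20\t40\tND\n"
        )
        (rec,) = parse_strain_table(p)
        assert rec.T_opt == (30.0, 35.0)
        assert rec.optimum("T") == 32.5
        assert rec.pH_opt is None

    def test_negative_range_endpoints(self, table1_db):
        rec = next(r for r in table1_db if "svalbardensis" in r.name)
        assert rec.T_min == -2.0

    def test_malformed_numeric_reports_line(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("name\tT_opt\nA\tthirty\n")
        with pytest.raises(StrainTableError, match="t.tsv:2"):
            parse_strain_table(p)

    def test_multi_section_strain_merged_with_both_labels(self, table1_db):
        rec = next(r for r in table1_db if "Saccharolobus shibatae" in r.name)
        assert rec.labels == {"hyperthermophile", "acidophile"}
        assert rec.optimum("T") == 81.0 and rec.optimum("pH") == 3.0

    def test_conflicting_duplicate_rows_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "name\tsection\tT_opt\nA\tthermophile\t55\nA\thyperthermophile\t80\n"
        )
        with pytest.raises(StrainTableError, match="conflicting"):
            parse_strain_table(p)

    def test_write_read_round_trip(self, tmp_path, table1_db):
        p = tmp_path / "out.tsv"
        write_strain_table(table1_db, p)
        back = parse_strain_table(p)
        assert {r.name for r in back} == {r.name for r in table1_db}
        orig = {r.name: r for r in table1_db}
        for rec in back:
            assert rec.labels == orig[rec.name].labels
            assert rec.optimum("T") == orig[rec.name].optimum("T")
            assert rec.optimum("pH") == orig[rec.name].optimum("pH")


class TestMidpoint:
    @pytest.mark.parametrize(
        "value,expected", [((30, 35), 32.5), ((7, 7.5), 7.25), (50, 50.0)]
    )
    def test_examples(self, value, expected):
        assert optimum_midpoint(value) == expected

    def test_inverted_pair_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            optimum_midpoint((35, 30))


class TestClassification:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            ({"T_opt": 105.0}, {"hyperthermophile"}),
            ({"pH_opt": (1.2, 1.5)}, {"acidophile"}),
            ({"T_opt": 81.0, "pH_opt": 3.0}, {"hyperthermophile", "acidophile"}),
            ({"P_opt": 10.0}, {"piezophile"}),
            ({"T_opt": 47.5}, set()),  # just below the thermophile band
            ({"pH_opt": 5.0}, set()),  # acidophile cutoff is strict
            ({"T_opt": 30.0, "pH_opt": 7.0, "NaCl_opt": 2.0}, set()),
        ],
    )
    def test_cutoffs(self, kwargs, expected):
        rec = StrainRecord(name="x", **kwargs)
        assert classify_adaptations(rec) == expected

    def test_polyextremophile_flag(self):
        labels = classify_adaptations(StrainRecord(name="x", T_opt=81.0, pH_opt=3.0))
        assert is_polyextremophile(labels)
        assert not is_polyextremophile(frozenset({"acidophile"}))

    def test_fixture_labels_reproduced(self, table1_db):
        for rec in table1_db:
            assert classify_adaptations(rec) == rec.labels, rec.name

    def test_no_strain_gets_two_temperature_or_pH_labels(self, table1_db):
        for rec in table1_db:
            labels = classify_adaptations(rec)
            assert len(labels & {"psychrophile", "thermophile", "hyperthermophile"}) <= 1
            assert len(labels & {"acidophile", "alkaliphile"}) <= 1

    @given(
        t=st.one_of(st.none(), st.floats(min_value=-10, max_value=130)),
        ph=st.one_of(st.none(), st.floats(min_value=0, max_value=14)),
    )
    def test_missing_parameters_yield_no_label(self, t, ph):
        rec = StrainRecord(name="x", T_opt=t, pH_opt=ph)
        labels = classify_adaptations(rec)
        if t is None:
            assert not labels & {"psychrophile", "thermophile", "hyperthermophile"}
        if ph is None:
            assert not labels & {"acidophile", "alkaliphile"}


class TestSummaries:
    def test_fixture_counts(self, table1_db):
        counts = summarize_counts(table1_db)
        assert counts["psychrophile"] == 4
        assert counts["thermophile"] == 20
        assert counts["hyperthermophile"] == 17
        assert counts["acidophile"] == 14
        assert counts["alkaliphile"] == 7
        assert counts["halophile"] == 4
        assert counts["piezophile"] == 2
        assert counts["polyextremophile"] == 7

    def test_empty_database_counts(self):
        counts = summarize_counts([])
        assert counts["total"] == 0
        assert all(v == 0 for k, v in counts.items() if k != "total")

    def test_counts_permutation_invariant_and_additive(self, table1_db):
        shuffled = list(table1_db)
        random.Random(1).shuffle(shuffled)
        assert summarize_counts(shuffled) == summarize_counts(table1_db)
        half = len(table1_db) // 2
        a, b = summarize_counts(table1_db[:half]), summarize_counts(table1_db[half:])
        whole = summarize_counts(table1_db)
        assert {k: a[k] + b[k] for k in whole} == whole

    def test_fixture_envelope_extrema(self, table1_db):
        t_lo, t_hi, ph_lo, ph_hi = envelope_extrema(table1_db)
        assert t_lo == -2.0
        assert t_hi == 121.0
        assert ph_lo == 1.0
        assert ph_hi == 10.7

    def test_single_record_envelope(self):
        rec = StrainRecord(name="x", T_opt=30.0, T_min=20.0, T_max=40.0)
        assert envelope_extrema([rec]) == (20.0, 40.0, None, None)

    def test_extrema_monotone_under_union(self, table1_db):
        sub = envelope_extrema(table1_db[:10])
        full = envelope_extrema(table1_db)
        assert full[0] <= sub[0] and full[1] >= sub[1]

    def test_sweet_spot_all_inside(self):
        db = [StrainRecord(name=f"s{i}", T_opt=30.0, pH_opt=7.0) for i in range(5)]
        assert sweet_spot_stats(db) == (5, 5, 0)

    def test_sweet_spot_outside_both(self):
        db = [
            StrainRecord(name="in", T_opt=25.0, pH_opt=7.0),
            StrainRecord(name="hot-but-neutral", T_opt=80.0, pH_opt=7.0),
            StrainRecord(name="corner", T_opt=80.0, pH_opt=2.0),
        ]
        assert sweet_spot_stats(db) == (1, 2, 1)


class TestDonorCrosstab:
    @staticmethod
    def _db():
        return [
            StrainRecord(
                name="hyper1", T_opt=90.0,
                donors={"hydrogen": "used", "carboxylates": "used"},
            ),
            StrainRecord(
                name="hyper2", T_opt=85.0,
                donors={"hydrogen": "used", "sugars": "tested-not-used"},
            ),
            StrainRecord(
                name="meso", T_opt=30.0,
                donors={"hydrogen": "tested-not-used", "carboxylates": "used"},
            ),
            StrainRecord(name="untested", T_opt=30.0, donors={}),
        ]

    def test_hyperthermophiles_all_use_hydrogen(self):
        tabs = donor_use_crosstab(self._db(), by_adaptation=True)
        used, tested = tabs["hyperthermophile"]["hydrogen"]
        assert (used, tested) == (2, 2)

    def test_untested_excluded_from_denominator(self):
        tab = donor_use_crosstab(self._db())
        assert tab["hydrogen"] == (2, 3)  # the fourth strain never tested
        assert tab["carboxylates"] == (2, 2)

    def test_matches_naive_row_iteration(self, table1_db):
        tab = donor_use_crosstab(table1_db)
        for cls, (used, tested) in tab.items():
            n_used = sum(1 for r in table1_db if r.donor_status(cls) == "used")
            n_tested = sum(
                1 for r in table1_db if r.donor_status(cls) != "untested"
            )
            assert (used, tested) == (n_used, n_tested)


class TestThresholdConfig:
    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            AdaptationThresholds(thermophile_T_from=80.0, hyperthermophile_T_from=72.0)
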