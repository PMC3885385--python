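"""CTI/CTV computation, species exclusions and cross-taxon correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermocomm as tc
from thermocomm.indices import MissingStiError, UndefinedIndexError


def tiny_dataset(occ_rows, squares=None):
    occ = pd.DataFrame(occ_rows, columns=["square_id", "survey_index", "year", "species_id"])
    if squares is None:
        ids = occ["square_id"].unique()
        squares = pd.DataFrame({"square_id": ids,
                                "altitude_m": np.linspace(400, 1200, len(ids)),
                                "altitudinal_range_m": 100.0})
    return tc.SurveyDataset(occ, squares)


class TestExclusions:
    def test_wandering_species_removed(self):
        rows = [(f"q{i}", 1, 2003, "Vanessa atalanta") for i in range(3)]
        rows += [(f"q{i}", 1, 2003, "Pieris napi") for i in range(3)]
        ds = tiny_dataset(rows)
        out = tc.apply_exclusions(ds, list(tc.DEFAULT_BUTTERFLY_EXCLUSIONS))
        assert len(out.occurrences) == 3
        assert set(out.occurrences["species_id"]) == {"Pieris napi"}

    def test_empty_list_is_identity(self):
        ds = tiny_dataset([("q0", 1, 2003, "A"), ("q0", 2, 2008, "B")])
        out = tc.apply_exclusions(ds, [])
        pd.testing.assert_frame_equal(out.occurrences, ds.occurrences)

    def test_unknown_ids_warn_but_pass(self, caplog):
        ds = tiny_dataset([("q0", 1, 2003, "A")])
        with caplog.at_level("WARNING"):
            out = tc.apply_exclusions(ds, ["NotHere"])
        assert "NotHere" in caplog.text
        assert len(out.occurrences) == 1

    def test_excluding_all_species_empties_square(self):
        ds = tiny_dataset([("q0", 1, 2003, "A"), ("q0", 2, 2008, "A")])
        out = tc.apply_exclusions(ds, ["A"])
        sti = tc.StiTable(pd.DataFrame({"species_id": ["A"], "group": ["g"], "sti": [3.0]}))
        table = tc.index_table(out, sti, "g")
        assert (table.richness == 0).all()


class TestIndexArithmetic:
    def test_cti_singleton_and_symmetry(self):
        assert tc.compute_cti([3.0]) == 3.0
        assert tc.compute_cti([2.0, 4.0]) == 3.0

    def test_cti_against_brute_force_sum(self):
        rng = np.random.default_rng(50)
        stis = rng.uniform(1, 5, 50)
        total = 0.0
        for v in stis:
            total += v
        assert tc.compute_cti(stis) == pytest.approx(total / 50, abs=1e-12)

    def test_cti_empty_undefined(self):
        with pytest.raises(UndefinedIndexError):
            tc.compute_cti([])

    def test_ctv_trivials(self):
        assert tc.compute_ctv([3.0, 3.0, 3.0]) == 0.0
        assert tc.compute_ctv([2.0, 4.0]) == pytest.approx(np.sqrt(2), abs=1e-5)

    def test_ctv_against_two_pass_oracle(self):
        rng = np.random.default_rng(51)
        stis = rng.uniform(8, 13, 50)
        mean = sum(stis) / len(stis)
        ss = sum((v - mean) ** 2 for v in stis)
        assert tc.compute_ctv(stis) == pytest.approx(np.sqrt(ss / 49), abs=1e-12)

    def test_ctv_singleton_undefined(self):
        with pytest.raises(UndefinedIndexError):
            tc.compute_ctv([3.0])

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=1, max_value=5), min_size=2, max_size=30))
    def test_cti_bounded_by_member_stis_and_ctv_zero_iff_constant(self, stis):
        cti = tc.compute_cti(stis)
        assert min(stis) - 1e-12 <= cti <= max(stis) + 1e-12
        ctv = tc.compute_ctv(stis)
        assert ctv >= 0
        if ctv == 0:
            assert len(set(stis)) == 1

    def test_removing_warm_species_decreases_cti(self):
        stis = [2.0, 3.0, 4.5, 5.0]
        cti = tc.compute_cti(stis)
        assert tc.compute_cti([v for v in stis if v != 5.0]) < cti


class TestIndexTable:
    STI = tc.StiTable(pd.DataFrame(
        {"species_id": ["A", "B", "C"], "group": "g", "sti": [2.0, 4.0, 5.0]}))

    def test_forced_arithmetic(self):
        ds = tiny_dataset([("q0", 1, 2003, "A"), ("q0", 1, 2003, "B"),
                           ("q0", 2, 2008, "B"), ("q0", 2, 2008, "C")])
        table = tc.index_table(ds, self.STI, "g").set_index("survey_index")
        assert table.loc[1, "cti"] == pytest.approx(3.0)
        assert table.loc[2, "cti"] == pytest.approx(4.5)

    def test_missing_sti_is_hard_error_naming_species(self):
        ds = tiny_dataset([("q0", 1, 2003, "A"), ("q0", 1, 2003, "Zzz")])
        with pytest.raises(MissingStiError, match="Zzz"):
            tc.index_table(ds, self.STI, "g")

    def test_duplicate_occurrences_do_not_change_cti(self):
        base = [("q0", 1, 2003, "A"), ("q0", 1, 2003, "B")]
        ds = tiny_dataset(base)
        ds_dup = tiny_dataset(base + [("q0", 1, 2003, "B")])
        t1 = tc.index_table(ds, self.STI, "g")
        t2 = tc.index_table(ds_dup, self.STI, "g")
        pd.testing.assert_frame_equal(t1, t2)

    def test_record_count_is_two_per_square(self, shift_dataset, butterfly_indices):
        assert len(butterfly_indices) == 2 * shift_dataset.n_squares
        assert butterfly_indices["richness"].notna().all()

    def test_richness_below_two_flags_ctv_only(self):
        ds = tiny_dataset([("q0", 1, 2003, "A"), ("q0", 2, 2008, "A"),
                           ("q0", 2, 2008, "B")])
        table = tc.index_table(ds, self.STI, "g").set_index("survey_index")
        assert table.loc[1, "cti"] == pytest.approx(2.0)   # richness 1: CTI kept
        assert np.isnan(table.loc[1, "ctv"])               # ... CTV missing
        assert table.loc[2, "ctv"] == pytest.approx(np.sqrt(2.0))


class TestCrossTaxonCorrelation:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, t, df, p = tc.cross_taxon_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert df == 8
        assert p < 1e-10

    def test_degrees_of_freedom_at_study_size(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 214))
        _, _, df, _ = tc.cross_taxon_correlation(x, y)
        assert df == 212

    def test_permutation_null_uniform_p(self):
        rng = np.random.default_rng(99)
        x = rng.normal(size=214)
        ps, rs = [], []
        for _ in range(200):
            r, _, _, p = tc.cross_taxon_correlation(x, rng.permutation(x))
            ps.append(p)
            rs.append(abs(r))
        assert np.mean(rs) < 0.15
        assert 0.35 < np.mean(ps) < 0.65  # uniform p-values average 0.5

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedIndexError):
            tc.cross_taxon_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_coupled_groups_correlate(self, shift_dataset):
        # two taxon groups driven by the same altitude field: survey-1 CTIs agree
        pools = [tc.generate_species_pool(60, (8, 13), seed=s) for s in (21, 22)]
        ctis = []
        for i, pool in enumerate(pools):
            scenario = tc.ShiftScenario(n_squares=100, seed=77 + i)
            ds = tc.generate_surveys(pool, scenario)
            table = tc.index_table(ds, tc.StiTable(pool.sti_table("g")), "g")
            first = table[table.survey_index == 1].set_index("square_id")["cti"]
            ctis.append(first)
        joined = pd.concat(ctis, axis=1, keys=["a", "b"]).dropna()
        r, _, _, _ = tc.cross_taxon_correlation(joined["a"], joined["b"])
        assert r > 0.5
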