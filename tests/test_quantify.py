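"""Spike-in normalization, translation-efficiency tables and selectors."""

from statistics import median

import numpy as np
import pandas as pd
import pytest

from naptrap.library import ReporterLibrary, ReporterRecord
from naptrap.quantify import (
    ExperimentDesign,
    SampleInfo,
    Selector,
    SpikeinLadder,
    apply_selector,
    build_tables,
    normalize,
    spikein_factors,
    total_count_factors,
    translation,
)

LADDER = SpikeinLadder({f"sp{i}#spikein": a for i, a in enumerate((1, 5, 25, 50, 125), 1)})


def ladder_counts(scale):
    return {f"sp{i}#spikein": scale * a for i, a in enumerate((10, 50, 250, 500, 1250), 1)}


def two_condition_design(n_reps=3, condition="c"):
    samples = []
    for fraction in ("input", "pulldown"):
        for rep in range(1, n_reps + 1):
            samples.append(SampleInfo(f"{fraction}_{rep}", condition, fraction, rep))
    return ExperimentDesign(samples)


class TestSpikeinFactors:
    def test_proportional_ladders_give_proportional_factors(self):
        counts = {"s1": ladder_counts(1), "s2": ladder_counts(2)}
        f = spikein_factors(counts, LADDER)
        assert f["s2"] == pytest.approx(2 * f["s1"])
        assert f["s1"] == pytest.approx(10.0)

    def test_single_dropout_survives_via_median(self):
        counts = ladder_counts(1)
        counts["sp3#spikein"] = 0
        f = spikein_factors({"s": counts}, LADDER)
        assert np.isfinite(f["s"]) and f["s"] > 0

    def test_all_zero_ladder_is_hard_error(self):
        with pytest.raises(ValueError, match="total-count|CPM"):
            spikein_factors({"s": {n: 0 for n in LADDER.amounts}}, LADDER)

    def test_random_poisson_counts_match_median_oracle(self, rng):
        counts = {n: int(rng.poisson(50 * a)) for n, a in LADDER.amounts.items()}
        f = spikein_factors({"s": counts}, LADDER)
        oracle = median(counts[n] / a for n, a in LADDER.amounts.items() if counts[n] > 0)
        assert f["s"] == pytest.approx(oracle)


class TestNormalize:
    def test_division_by_factor(self):
        out = normalize({"s": {"a#reporter": 100}}, {"s": 2.0})
        assert out.loc["a#reporter", "s"] == 50

    def test_cpm_fallback(self):
        factors = total_count_factors({"s": {"a#reporter": 3, "b#reporter": 1}})
        out = normalize({"s": {"a#reporter": 3, "b#reporter": 1}}, factors)
        assert out.loc["a#reporter", "s"] == pytest.approx(750_000)
        assert out.loc["b#reporter", "s"] == pytest.approx(250_000)

    def test_cpm_excludes_spikeins_from_total(self):
        counts = {"s": {"a#reporter": 3, "b#reporter": 1, "sp1#spikein": 996}}
        factors = total_count_factors(counts)
        out = normalize(counts, factors)
        assert out.loc["a#reporter", "s"] == pytest.approx(750_000)

    def test_scaling_sample_invariance_under_spikein_normalization(self, rng):
        base = {**ladder_counts(1), **{f"r{i}#reporter": int(rng.integers(1, 500)) for i in range(30)}}
        scaled = {k: 7 * v for k, v in base.items()}
        f = spikein_factors({"a": base, "b": scaled}, LADDER)
        out = normalize({"a": base, "b": scaled}, f)
        assert np.allclose(out["a"], out["b"], rtol=1e-12)


class TestTranslation:
    def make_counts(self, input_counts, pulldown_counts, n_reps=3):
        counts = {}
        for rep in range(1, n_reps + 1):
            counts[f"input_{rep}"] = dict(input_counts)
            counts[f"pulldown_{rep}"] = dict(pulldown_counts)
        return counts

    def unit_factors(self, counts):
        return {s: 1.0 for s in counts}

    def test_identity_ratio(self):
        counts = self.make_counts({"a#reporter": 100}, {"a#reporter": 100})
        tab = translation(counts, two_condition_design(), self.unit_factors(counts))
        assert np.allclose(tab.te.loc["a#reporter"], 1.0)
        assert tab.mean_te.loc["a#reporter", "c"] == pytest.approx(1.0)

    def test_doubling(self):
        counts = self.make_counts({"a#reporter": 100}, {"a#reporter": 200})
        tab = translation(counts, two_condition_design(), self.unit_factors(counts))
        assert tab.mean_te.loc["a#reporter", "c"] == pytest.approx(2.0)

    def test_ratio_vs_log2_mean_of_1_2_4(self):
        counts = {}
        for rep, ratio in zip((1, 2, 3), (1, 2, 4)):
            counts[f"input_{rep}"] = {"a#reporter": 100}
            counts[f"pulldown_{rep}"] = {"a#reporter": 100 * ratio}
        design = two_condition_design()
        f = {s: 1.0 for s in counts}
        ratio_tab = translation(counts, design, f, te_function="ratio")
        assert ratio_tab.mean_te.loc["a#reporter", "c"] == pytest.approx(7 / 3)
        log_tab = translation(counts, design, f, te_function="log2_ratio")
        assert log_tab.mean_te.loc["a#reporter", "c"] == pytest.approx(1.0)

    def test_zero_input_is_missing_not_zero_or_inf(self):
        counts = self.make_counts({"a#reporter": 0}, {"a#reporter": 50}, n_reps=1)
        tab = translation(counts, two_condition_design(n_reps=1), self.unit_factors(counts))
        assert np.isnan(tab.te.loc["a#reporter", "c:1"])

    def test_spikeins_excluded_from_te(self):
        counts = self.make_counts(
            {"a#reporter": 10, "sp1#spikein": 10}, {"a#reporter": 10, "sp1#spikein": 10}, n_reps=1
        )
        tab = translation(counts, two_condition_design(n_reps=1), self.unit_factors(counts))
        assert "sp1#spikein" not in tab.te.index
        assert "sp1#spikein" in tab.raw.index

    def test_te_invariant_to_sample_scaling_with_spikein_factors(self, rng):
        reporters = {f"r{i}#reporter": int(rng.integers(50, 500)) for i in range(20)}
        counts = {
            "input_1": {**reporters, **ladder_counts(1)},
            "pulldown_1": {**{k: 2 * v for k, v in reporters.items()}, **ladder_counts(1)},
        }
        design = two_condition_design(n_reps=1)
        base = translation(counts, design, spikein_factors(counts, LADDER)).mean_te
        counts_scaled = dict(counts)
        counts_scaled["pulldown_1"] = {k: 5 * v for k, v in counts["pulldown_1"].items()}
        scaled = translation(
            counts_scaled, design, spikein_factors(counts_scaled, LADDER)
        ).mean_te
        assert np.allclose(base["c"], scaled["c"], rtol=1e-12)


class TestSelector:
    def make_table(self, rows, n_reps=3):
        counts = {}
        for rep in range(1, n_reps + 1):
            counts[f"input_{rep}"] = {name: vals[rep - 1] for name, vals in rows.items()}
            counts[f"pulldown_{rep}"] = {name: 100 for name in rows}
        design = two_condition_design(n_reps)
        tab = translation(counts, design, {s: 1.0 for s in counts})
        return tab, design

    def test_boundary_pass(self):
        tab, design = self.make_table({"a#reporter": (120, 101, 100)})
        apply_selector(tab, design, Selector("sel", ("c",), 100))
        assert bool(tab.pass_flags["sel"]["a#reporter"])

    def test_one_low_replicate_fails(self):
        tab, design = self.make_table({"a#reporter": (120, 99, 300)})
        apply_selector(tab, design, Selector("sel", ("c",), 100))
        assert not bool(tab.pass_flags["sel"]["a#reporter"])

    def test_random_table_matches_brute_force(self, rng):
        rows = {f"r{i}#reporter": tuple(int(x) for x in rng.integers(0, 200, 3)) for i in range(100)}
        tab, design = self.make_table(rows)
        apply_selector(tab, design, Selector("sel", ("c",), 100))
        for name, vals in rows.items():
            assert bool(tab.pass_flags["sel"][name]) == all(v >= 100 for v in vals)

    def test_unknown_condition_rejected(self):
        tab, design = self.make_table({"a#reporter": (1, 1, 1)})
        with pytest.raises(ValueError, match="unknown condition"):
            apply_selector(tab, design, Selector("sel", ("nope",), 100))


class TestBuildTables:
    @pytest.fixture
    def tiny_setup(self):
        lib = ReporterLibrary(
            [
                ReporterRecord("a#reporter", "ACGTACGTAC", "reporter"),
                ReporterRecord("b#reporter", "TTGGCCAATT", "reporter"),
                ReporterRecord("sp1#spikein", "GGGGGCCCCC", "spikein"),
            ]
        )
        counts = {
            "input_1": {"a#reporter": 200, "b#reporter": 50, "sp1#spikein": 100},
            "input_2": {"a#reporter": 200, "b#reporter": 50, "sp1#spikein": 100},
            "pulldown_1": {"a#reporter": 400, "b#reporter": 25, "sp1#spikein": 100},
            "pulldown_2": {"a#reporter": 400, "b#reporter": 25, "sp1#spikein": 100},
        }
        design = two_condition_design(n_reps=2)
        ladder = SpikeinLadder({"sp1#spikein": 1})
        return lib, counts, design, ladder

    def test_hand_checked_outputs(self, tiny_setup, tmp_path):
        lib, counts, design, ladder = tiny_setup
        tab = build_tables(
            counts, design, lib, [Selector("main", ("c",), 100)], tmp_path, ladder=ladder
        )
        # factor = 100 for every sample, so TE = raw pulldown/input ratio
        assert tab.mean_te.loc["a#reporter", "c"] == pytest.approx(2.0)
        assert tab.mean_te.loc["b#reporter", "c"] == pytest.approx(0.5)
        assert bool(tab.pass_flags["main"]["a#reporter"])
        assert not bool(tab.pass_flags["main"]["b#reporter"])  # 50 < 100 in inputs
        avg = pd.read_csv(tmp_path / "average_translation.csv", index_col="reporter")
        assert avg.loc["a#reporter", "c"] == pytest.approx(2.0)
        assert avg.loc["a#reporter", "insert_seq"] == "ACGTACGTAC"
        filt = pd.read_csv(tmp_path / "main_filtered_average_translation.csv", index_col="reporter")
        assert list(filt.index) == ["a#reporter"]

    def test_filtered_rows_subset_with_equal_values(self, tiny_setup, tmp_path):
        lib, counts, design, ladder = tiny_setup
        tab = build_tables(
            counts, design, lib, [Selector("main", ("c",), 10)], tmp_path, ladder=ladder
        )
        filt = tab.filtered("main")
        assert set(filt.mean_te.index) <= set(tab.mean_te.index)
        pd.testing.assert_frame_equal(filt.mean_te, tab.mean_te.loc[filt.mean_te.index])

    def test_reruns_byte_identical(self, tiny_setup, tmp_path):
        lib, counts, design, ladder = tiny_setup
        sels = [Selector("main", ("c",), 100)]
        build_tables(counts, design, lib, sels, tmp_path / "run1", ladder=ladder)
        build_tables(counts, design, lib, sels, tmp_path / "run2", ladder=ladder)
        for name in ("raw_counts", "normalized_counts", "translation", "average_translation"):
            a = (tmp_path / "run1" / f"{name}.csv").read_bytes()
            b = (tmp_path / "run2" / f"{name}.csv").read_bytes()
            assert a == b

    def test_relative_db_path_rejected(self, tiny_setup, tmp_path):
        lib, counts, design, ladder = tiny_setup
        with pytest.raises(ValueError, match="absolute"):
            build_tables(
                counts, design, lib, [Selector("main", ("c",), 100)], tmp_path,
                db_path="relative/utr5.db", ladder=ladder,
            )

    def test_sqlite_store_round_trips(self, tiny_setup, tmp_path):
        import sqlite3

        lib, counts, design, ladder = tiny_setup
        db = tmp_path / "store.db"
        tab = build_tables(
            counts, design, lib, [Selector("main", ("c",), 100)], tmp_path,
            db_path=str(db), ladder=ladder,
        )
        con = sqlite3.connect(db)
        try:
            avg = pd.read_sql("select * from average_translation", con, index_col="reporter")
        finally:
            con.close()
        pd.testing.assert_frame_equal(avg.sort_index(), tab.mean_te.sort_index(), check_names=False)
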