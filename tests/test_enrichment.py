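"""Replicate correlation, TE-rank groups and k-mer enrichment statistics."""

import math

import numpy as np
import pandas as pd
import pytest

from naptrap.enrichment import (
    EnrichmentConfig,
    ReporterGroups,
    define_groups,
    kmer_enrichment,
    kmer_presence,
    replicate_correlation,
)


class TestReplicateCorrelation:
    def test_duplicate_replicate_r_is_one(self, rng):
        x = rng.lognormal(size=100)
        te = pd.DataFrame({"r1": x, "r2": x})
        corr = replicate_correlation(te)
        assert corr.loc["r1", "r2"] == pytest.approx(1.0)

    def test_negated_around_mean_r_is_minus_one(self, rng):
        x = rng.normal(size=100)
        te = pd.DataFrame({"r1": x, "r2": 2 * x.mean() - x})
        assert replicate_correlation(te).loc["r1", "r2"] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_formula(self, rng):
        te = pd.DataFrame(rng.lognormal(size=(500, 3)), columns=["a", "b", "c"])
        corr = replicate_correlation(te)
        for c1 in te.columns:
            for c2 in te.columns:
                x, y = te[c1].to_numpy(), te[c2].to_numpy()
                r = ((x - x.mean()) * (y - y.mean())).sum() / math.sqrt(
                    ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
                )
                assert corr.loc[c1, c2] == pytest.approx(r, abs=1e-12)

    def test_symmetric_unit_diagonal(self, rng):
        te = pd.DataFrame(rng.lognormal(size=(50, 4)))
        corr = replicate_correlation(te)
        assert np.allclose(corr, corr.T) and np.allclose(np.diag(corr), 1.0)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            replicate_correlation(pd.DataFrame({"r1": [1.0, 2.0]}))

    def test_plots_written(self, rng, tmp_path):
        te = pd.DataFrame(rng.lognormal(size=(50, 2)), columns=["r1", "r2"])
        replicate_correlation(te, out_dir=tmp_path, fig_format="png")
        assert (tmp_path / "replicates_heatmap.png").stat().st_size > 0
        assert (tmp_path / "replicates_scatter.png").stat().st_size > 0


class TestDefineGroups:
    def test_hundred_reporters_rnum_point1_gives_groups_of_ten(self, rng):
        te = pd.Series(rng.lognormal(size=100), index=[f"r{i:03d}" for i in range(100)])
        groups = define_groups(te, cfg=EnrichmentConfig(rnum=0.1))
        assert len(groups["repressed"]) == 10 and len(groups["activated"]) == 10
        assert not set(groups["repressed"]) & set(groups["activated"])

    def test_ordered_input_bottom_indices_repressed(self):
        te = pd.Series(np.arange(1.0, 101.0), index=[f"r{i:03d}" for i in range(100)])
        groups = define_groups(te, cfg=EnrichmentConfig(rnum=0.1))
        assert groups["repressed"] == [f"r{i:03d}" for i in range(10)]
        assert groups["activated"] == [f"r{i:03d}" for i in range(90, 100)]

    def test_rank_invariance_under_monotone_transform(self, rng):
        te = pd.Series(rng.lognormal(size=60), index=[f"r{i:02d}" for i in range(60)])
        g1 = define_groups(te, cfg=EnrichmentConfig(rnum=0.2))
        g2 = define_groups(np.exp(te * 3), cfg=EnrichmentConfig(rnum=0.2))
        assert g1.groups == g2.groups

    def test_ties_broken_lexicographically(self):
        te = pd.Series(1.0, index=["b", "a", "d", "c"])
        groups = define_groups(te, cfg=EnrichmentConfig(rnum=0.5))
        assert groups["repressed"] == ["a", "b"] and groups["activated"] == ["c", "d"]

    def test_empty_group_rejected(self):
        te = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="empty group"):
            define_groups(te, cfg=EnrichmentConfig(rnum=0.3))

    def test_two_sample_planted_quadrants_recovered(self, rng):
        # 4 planted blocks of 10 in the corners + 60 mid-range reporters;
        # each per-sample extreme tier holds 20 reporters, so rnum = 0.2
        names = [f"r{i:03d}" for i in range(100)]
        te1 = pd.Series(0.0, index=names)
        te2 = pd.Series(0.0, index=names)
        blocks = {
            "both_low": names[0:10],
            "both_high": names[10:20],
            "sample1_high": names[20:30],
            "sample2_high": names[30:40],
        }
        mid = names[40:]
        te1[blocks["both_low"]], te2[blocks["both_low"]] = 0.01, 0.01
        te1[blocks["both_high"]], te2[blocks["both_high"]] = 100.0, 100.0
        te1[blocks["sample1_high"]], te2[blocks["sample1_high"]] = 100.0, 0.01
        te1[blocks["sample2_high"]], te2[blocks["sample2_high"]] = 0.01, 100.0
        te1[mid] = rng.uniform(0.5, 2.0, len(mid))
        te2[mid] = rng.uniform(0.5, 2.0, len(mid))
        groups = define_groups(te1, te2, EnrichmentConfig(rnum=0.2))
        assert groups.groups == {k: sorted(v) for k, v in blocks.items()}


def hypergeom_tail_oracle(g, N, K, n):
    """P(X >= g), X ~ Hypergeom(N, K, n), by direct combinatorial enumeration."""
    total = math.comb(N, n)
    acc = 0
    for k in range(g, min(K, n) + 1):
        acc += math.comb(K, k) * math.comb(N - K, n - k)
    return acc / total


class TestKmerEnrichment:
    def seqs(self, rng, n, length=30):
        return {
            f"r{i:03d}": "".join("ACGT"[b] for b in rng.integers(0, 4, length))
            for i in range(n)
        }

    def test_closed_form_log2_at_zero_pseudocount(self):
        # Planted k-mer in all 10 group members and in half of the 40-reporter
        # background: enrichment = log2((10/10)/(20/40)) = 1 at pc = 0.
        motif = "AAAAA"
        seqs = {}
        for i in range(40):
            body = "CGTCGTCGTCGTCGTCGTCGTCGTCG"
            seqs[f"r{i:03d}"] = (motif if i < 20 else "CCCCC") + body
        group = [f"r{i:03d}" for i in range(10)]
        cfg = EnrichmentConfig(rnum=0.25, klen=5, pseudocount=0.0)
        [rec] = kmer_enrichment({"g": group}, seqs, cfg)["g"].query("kmer == 'AAAAA'").to_dict("records")
        assert rec["log2_enrichment"] == pytest.approx(1.0)
        assert rec["frequency_group"] == 1.0 and rec["frequency_background"] == 0.5

    def test_klen5_yields_1024_records(self, rng):
        seqs = self.seqs(rng, 30)
        groups = {"g": list(seqs)[:5]}
        df = kmer_enrichment(groups, seqs, EnrichmentConfig(klen=5))["g"]
        assert len(df) == 4**5
        assert df["adjusted_p"].ge(df["p_value"] - 1e-15).all()

    def test_group_equal_background_has_zero_enrichment(self, rng):
        seqs = self.seqs(rng, 12)
        df = kmer_enrichment({"g": list(seqs)}, seqs, EnrichmentConfig(klen=3))["g"]
        assert np.allclose(df["log2_enrichment"], 0.0)

    def test_counts_conserve(self, rng):
        seqs = self.seqs(rng, 25)
        groups = {"g": list(seqs)[:6]}
        df = kmer_enrichment(groups, seqs, EnrichmentConfig(klen=3))["g"]
        assert (df["group_present"] <= 6).all()
        assert (df["bg_present"] <= 25).all()
        assert (df["group_present"] <= df["bg_present"]).all()

    def test_presence_counts_once_per_reporter(self):
        presence = kmer_presence({"a": "AAAAAA"}, 3)
        assert presence["a"] == frozenset({"AAA"})

    def test_pvalues_match_enumeration_oracle_on_small_background(self, rng):
        seqs = self.seqs(rng, 25, length=12)
        members = sorted(seqs)[:7]
        df = kmer_enrichment({"g": members}, seqs, EnrichmentConfig(klen=2, pseudocount=0.5))["g"]
        for rec in df.itertuples():
            oracle = hypergeom_tail_oracle(rec.group_present, 25, rec.bg_present, 7)
            assert rec.p_value == pytest.approx(oracle, rel=1e-9)

    def test_disjoint_swap_antisymmetry_from_counts(self, rng):
        # With frequencies computed on the disjoint split (group vs rest),
        # swapping the two sets negates the log2 enrichment at pc = 0.
        seqs = self.seqs(rng, 20)
        members = sorted(seqs)[:10]
        rest = sorted(set(seqs) - set(members))
        df = kmer_enrichment(
            {"g": members, "rest": rest}, seqs, EnrichmentConfig(klen=3, pseudocount=0.0)
        )
        g, r = df["g"].set_index("kmer"), df["rest"].set_index("kmer")
        both = (g["group_present"] > 0) & (r["group_present"] > 0)
        enr_fwd = np.log2(g.loc[both, "frequency_group"] / r.loc[both, "frequency_group"])
        enr_rev = np.log2(r.loc[both, "frequency_group"] / g.loc[both, "frequency_group"])
        assert np.allclose(enr_fwd, -enr_rev)

    def test_rna_alphabet_transliterates(self, rng):
        seqs = self.seqs(rng, 10)
        df = kmer_enrichment(
            {"g": list(seqs)[:2]}, seqs, EnrichmentConfig(klen=3, rna_alphabet=True)
        )["g"]
        assert df["kmer"].str.contains("U").any() and not df["kmer"].str.contains("T").any()

    def test_klen_longer_than_shortest_insert_rejected(self):
        with pytest.raises(ValueError, match="shortest insert"):
            kmer_enrichment({"g": ["a"]}, {"a": "ACGT"}, EnrichmentConfig(klen=10))

    def test_tables_and_plot_written(self, rng, tmp_path):
        seqs = self.seqs(rng, 15)
        kmer_enrichment(
            {"g": list(seqs)[:4]}, seqs, EnrichmentConfig(klen=3),
            out_dir=tmp_path, fig_format="png",
        )
        assert (tmp_path / "kmer_enrichment_g.csv").exists()
        assert (tmp_path / "kmer_enrichment_g.png").stat().st_size > 0
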