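"""q-values, significance calls, method union, cis/trans, hotspots."""

import numpy as np
import pandas as pd
import pytest

import sqtlmap as sq
from sqtlmap import fdr


def bh_oracle(p):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for i in range(m - 1, -1, -1):
        running = min(running, p[order[i]] * m / (i + 1))
        adj[order[i]] = running
    return adj


def call_table(rows):
    return pd.DataFrame(
        rows,
        columns=["gene_id", "pheno_chrom", "pheno_pos", "locus_chrom", "locus_pos", "p", "q"],
    )


class TestQvalues:
    def test_degenerate_all_ones(self):
        q, pi0 = sq.qvalues(np.ones(10))
        np.testing.assert_allclose(q, 1.0)
        assert pi0 == 1.0

    def test_bh_equivalence_when_pi0_forced_to_one(self, rng):
        p = rng.uniform(size=20)
        q, _ = sq.qvalues(p, pi0=1.0)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_pi0_estimate_with_half_signal(self, rng):
        p = np.concatenate([rng.uniform(0, 1e-6, 1000), rng.uniform(size=1000)])
        _, pi0 = sq.qvalues(p)
        assert pi0 <= 0.7

    def test_monotone_in_p_and_bounded(self, rng):
        p = rng.uniform(size=500) ** 2
        q, pi0 = sq.qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert (q <= 1).all() and (q >= p * pi0 - 1e-12).all()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            sq.qvalues(np.array([0.5, 1.5]))

    def test_nan_propagates(self):
        q, _ = sq.qvalues(np.array([0.1, np.nan, 0.9]))
        assert np.isnan(q[1]) and np.isfinite(q[[0, 2]]).all()


class TestCallSignificant:
    def test_empty_input(self):
        out = sq.call_significant(pd.DataFrame(columns=["p"]))
        assert out.empty

    def test_hand_set_threshold_straddle(self):
        tab = pd.DataFrame(
            {
                "p": [5e-5, 5e-5, 2e-4, 1e-6, 0.5, 1e-5],
                "q": [0.1, 0.5, 0.1, 0.38, 0.9, 0.39],
            }
        )
        out = sq.call_significant(tab, p_thresh=1e-4, q_thresh=0.39)
        # by-hand: rows must satisfy both p<=1e-4 and q<=0.39
        assert len(out) == 3
        assert set(out["p"]) == {5e-5, 1e-6, 1e-5}

    def test_unit_thresholds_keep_everything(self, rng):
        tab = pd.DataFrame({"p": rng.uniform(size=30)})
        out = sq.call_significant(tab, p_thresh=1.0, q_thresh=1.0)
        assert len(out) == 30


class TestCombineMethods:
    @staticmethod
    def synth_calls(n, prefix, shared=0, shared_prefix="S"):
        genes = [f"{shared_prefix}{i}" for i in range(shared)] + [
            f"{prefix}{i}" for i in range(n - shared)
        ]
        return call_table(
            [(g, "2L", 1000, "2L", 5000, 1e-5, 0.1) for g in genes]
        )

    def test_reported_study_overlap_arithmetic(self):
        a = self.synth_calls(974, "E", shared=112)
        b = self.synth_calls(374, "I", shared=112)
        _, counts = sq.combine_methods(a, b)
        assert counts == {"nA": 974, "nB": 374, "nShared": 112, "nUnion": 1236}

    def test_disjoint_tables(self):
        a = self.synth_calls(3, "E")
        b = self.synth_calls(4, "I")
        union, counts = sq.combine_methods(a, b)
        assert counts["nUnion"] == 7 and counts["nShared"] == 0
        assert set(union["overlap"]) == {"exon_only", "isoform_only"}

    def test_identical_tables(self):
        a = self.synth_calls(5, "E")
        union, counts = sq.combine_methods(a, a.copy())
        assert counts == {"nA": 5, "nB": 5, "nShared": 5, "nUnion": 5}
        assert (union["overlap"] == "shared").all()

    def test_duplicate_keys_deduplicated_to_best_p(self):
        a = call_table(
            [
                ("g1", "2L", 1, "2L", 5, 1e-3, 0.1),
                ("g1", "2L", 1, "2L", 5, 1e-8, 0.1),
            ]
        )
        b = self.synth_calls(1, "I")
        with pytest.warns(UserWarning, match="duplicate"):
            union, counts = sq.combine_methods(a, b)
        assert counts["nA"] == 1
        assert union[union["gene_id"] == "g1"]["p"].iloc[0] == 1e-8


class TestCisTrans:
    def test_zero_distance_is_cis(self):
        tab = call_table([("g", "2L", 100, "2L", 100, 1e-5, 0.1)])
        assert sq.classify_cis_trans(tab)["cis_trans"].iloc[0] == "cis"

    def test_window_boundary_is_closed(self):
        tab = call_table([("g", "2L", 0, "2L", 1_000_000, 1e-5, 0.1)])
        assert sq.classify_cis_trans(tab, cis_window=1_000_000)["cis_trans"].iloc[0] == "cis"

    def test_hand_computed_labels(self):
        rows = [
            ("g1", "2L", 100_000, "2L", 150_000, 1e-5, 0.1),   # 50 kb -> cis
            ("g2", "2L", 100_000, "3L", 150_000, 1e-5, 0.1),   # other chrom -> trans
            ("g3", "2L", 0, "2L", 2_000_000, 1e-5, 0.1),       # 2 Mb -> trans
            ("g4", "3L", 5_000_000, "3L", 4_100_000, 1e-5, 0.1),  # 900 kb -> cis
            ("g5", "3L", 5_000_000, "3L", 6_100_000, 1e-5, 0.1),  # 1.1 Mb -> trans
            ("g6", "2L", 42, "2L", 42, 1e-5, 0.1),
            ("g7", "X", 1, "2L", 1, 1e-5, 0.1),
            ("g8", "2L", 500, "2L", 1_000_499, 1e-5, 0.1),     # 999,999 -> cis
        ]
        out = sq.classify_cis_trans(call_table(rows))
        assert list(out["cis_trans"]) == [
            "cis", "trans", "trans", "cis", "trans", "cis", "trans", "cis",
        ]

    def test_unknown_chromosome_unclassified(self):
        tab = call_table([("g", None, 1, "2L", 5, 1e-5, 0.1)])
        assert sq.classify_cis_trans(tab)["cis_trans"].iloc[0] == "unclassified"


class TestHotspots:
    @staticmethod
    def scattered(rng, loci, n=200, n_genes=150):
        idx = rng.integers(0, len(loci), n)
        return pd.DataFrame(
            {
                "gene_id": [f"g{i:03d}" for i in rng.integers(0, n_genes, n)],
                "locus_chrom": loci["chrom"].to_numpy()[idx],
                "locus_pos": loci["pos"].to_numpy()[idx],
                "p": rng.uniform(0, 1e-4, n),
                "cis_trans": "trans",
            }
        )

    def test_empty_calls(self):
        hot, prof = sq.find_hotspots(pd.DataFrame(), seed=0)
        assert hot.empty and prof.empty

    def test_uniform_scatter_yields_no_hotspot(self):
        loci = sq.default_locus_grid({"2L": 1_500_000, "3L": 1_500_000}, 25_000)
        zeros = 0
        for s in range(6):
            calls = self.scattered(np.random.default_rng(70 + s), loci)
            hot, _ = sq.find_hotspots(
                calls, bin_size=200_000, n_perm=500, seed=s, loci=loci
            )
            zeros += hot.empty
        assert zeros >= 5

    def test_concentrated_calls_give_unique_hotspot(self):
        loci = sq.default_locus_grid({"2L": 1_500_000, "3L": 1_500_000}, 25_000)
        rng = np.random.default_rng(4)
        calls = self.scattered(rng, loci, n=60)
        hub = pd.DataFrame(
            {
                "gene_id": [f"hub{i}" for i in range(50)],
                "locus_chrom": "3L",
                "locus_pos": 1_125_000,
                "p": 1e-9,
                "cis_trans": "trans",
            }
        )
        hot, prof = sq.find_hotspots(
            pd.concat([calls, hub]), bin_size=200_000, n_perm=500, seed=5, loci=loci
        )
        assert len(hot) == 1
        row = hot.iloc[0]
        assert row["chrom"] == "3L" and row["start"] <= 1_125_000 < row["end"]
        assert row["n_genes"] >= 50

    def test_profile_counts_distinct_genes(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a", "a", "b", "c"],
                "locus_chrom": ["2L"] * 4,
                "locus_pos": [10, 110_000, 20, 30],
                "p": [1e-9, 1e-8, 1e-7, 1e-6],
                "cis_trans": "trans",
            }
        )
        _, prof = sq.find_hotspots(calls, bin_size=100_000, n_perm=100, seed=0, collapse=False)
        assert prof.set_index("start")["n_genes"].to_dict() == {0: 3, 100_000: 1}

    def test_gene_relabelling_leaves_profile_invariant(self, rng):
        loci = sq.default_locus_grid({"2L": 1_000_000}, 25_000)
        calls = self.scattered(rng, loci, n=120)
        relabel = {g: f"x{g}" for g in calls["gene_id"].unique()}
        renamed = calls.assign(gene_id=calls["gene_id"].map(relabel))
        _, p1 = sq.find_hotspots(calls, bin_size=200_000, n_perm=100, seed=1, loci=loci)
        _, p2 = sq.find_hotspots(renamed, bin_size=200_000, n_perm=100, seed=1, loci=loci)
        pd.testing.assert_frame_equal(p1, p2)

    def test_low_permutation_count_warns(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["a"], "locus_chrom": ["2L"], "locus_pos": [10],
                "p": [1e-9], "cis_trans": ["trans"],
            }
        )
        with pytest.warns(UserWarning, match="unstable"):
            sq.find_hotspots(calls, n_perm=50, seed=0)


class TestEndToEndFdrBehaviour:
    def test_pi0_near_one_on_null_scan(self, small_panel):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        qn = sq.quantile_normalize(frac.values)
        resid, _ = sq.remove_pcs(qn, 3, protect=sp["env"])
        frac.values = resid
        assoc = sq.scan(frac, sp["genotypes"], sp["samples"])
        _, pi0 = fdr.qvalues(assoc["p"].to_numpy())
        assert pi0 > 0.8
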