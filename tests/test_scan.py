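"""Nested G×E model fits, the genome scan, and differential expression."""

import numpy as np
import pandas as pd
import pytest

import sqtlmap as sq
from sqtlmap.scan import ScanConfig, n_tests
from tests_support_oracles import exon_designs, isoform_designs, oracle_partial_f


def random_instance(rng, n_rils=12, n_founders=3, blur=0.2):
    """A small random founder-probability design with both environments."""
    labels = rng.integers(0, n_founders, size=n_rils)
    G1 = np.eye(n_founders)[labels]
    noise = rng.dirichlet(np.ones(n_founders), size=n_rils)
    G1 = (1 - blur) * G1 + blur * noise
    G = np.vstack([G1, G1])  # each RIL in both conditions
    E = np.repeat([0.0, 1.0], n_rils)
    return G, E


class TestExonModel:
    def test_constant_response_gives_null_statistic(self, rng):
        G, E = random_instance(rng)
        _, _, rec = sq.fit_exon_model(np.full(len(E), 3.7), G, E)
        assert rec["F"] == 0.0 and rec["p"] == 1.0

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(6):
            G, E = random_instance(rng)
            y = rng.normal(size=len(E))
            _, _, rec = sq.fit_exon_model(y, G, E)
            X0, XA = exon_designs(G, E)
            F, df1, df2, p = oracle_partial_f(X0, XA, y)
            assert rec["F"] == pytest.approx(F, abs=1e-8)
            assert (rec["df1"], rec["df2"]) == (df1, df2)
            assert rec["p"] == pytest.approx(p, abs=1e-10)

    def test_invariant_to_reference_founder(self, rng):
        G, E = random_instance(rng, n_founders=5)
        y = rng.normal(size=len(E))
        founders = [f"A{i+1}" for i in range(5)]
        stats_ = [
            sq.fit_exon_model(y, G, E, founders=founders, ref_founder=f)[2]["F"]
            for f in founders
        ]
        assert max(stats_) - min(stats_) < 1e-8

    def test_zero_probability_founder_columns_do_not_change_f(self, rng):
        G, E = random_instance(rng)
        y = rng.normal(size=len(E))
        _, _, a = sq.fit_exon_model(y, G, E)
        G_pad = np.column_stack([G, np.zeros((len(E), 2))])
        _, _, b = sq.fit_exon_model(y, G_pad, E)
        assert a["F"] == pytest.approx(b["F"], abs=1e-8)

    def test_missing_values_dropped_pairwise(self, rng):
        G, E = random_instance(rng, n_rils=20)
        y = rng.normal(size=len(E))
        y_miss = y.copy()
        y_miss[[1, 5]] = np.nan
        keep = ~np.isnan(y_miss)
        _, _, a = sq.fit_exon_model(y_miss, G, E)
        _, _, b = sq.fit_exon_model(y[keep], G[keep], E[keep])
        assert a["F"] == pytest.approx(b["F"], abs=1e-10)

    def test_too_few_samples_per_environment_flagged(self, rng):
        G, E = random_instance(rng, n_rils=6)
        y = rng.normal(size=len(E))
        y[E == 1] = np.nan
        y[np.flatnonzero(E == 1)[0]] = 0.0
        _, _, rec = sq.fit_exon_model(y, G, E)
        assert rec["flagged"] and np.isnan(rec["p"])


class TestIsoformModel:
    @pytest.mark.parametrize("tested_block", ["as_printed", "gxe_only"])
    @pytest.mark.parametrize("sample_intercepts", [True, False])
    def test_agrees_with_normal_equations_oracle(self, rng, tested_block, sample_intercepts):
        for _ in range(5):
            G, E = random_instance(rng, n_rils=8, n_founders=2)
            K = 2
            Y = rng.normal(size=(K, len(E)))
            _, _, rec = sq.fit_isoform_model(
                Y, G, E, tested_block=tested_block, sample_intercepts=sample_intercepts
            )
            y, X0, XA = isoform_designs(Y, G, E, tested_block, sample_intercepts)
            F, df1, df2, p = oracle_partial_f(X0, XA, y)
            assert rec["F"] == pytest.approx(F, abs=1e-8)
            assert (rec["df1"], rec["df2"]) == (df1, df2)
            assert rec["p"] == pytest.approx(p, abs=1e-10)

    def test_constant_response_gives_null_statistic(self, rng):
        G, E = random_instance(rng)
        Y = np.full((3, len(E)), 1.23)
        _, _, rec = sq.fit_isoform_model(Y, G, E)
        assert rec["F"] == 0.0 and rec["p"] == 1.0

    def test_invariant_to_reference_founder(self, rng):
        G, E = random_instance(rng, n_founders=4)
        Y = rng.normal(size=(3, len(E)))
        founders = [f"A{i+1}" for i in range(4)]
        Fs = [
            sq.fit_isoform_model(Y, G, E, founders=founders, ref_founder=f)[2]["F"]
            for f in founders
        ]
        assert max(Fs) - min(Fs) < 1e-8

    def test_planted_usage_flip_detected(self):
        # founder-specific, exposure-conditional isoform flip at delta=2:
        # carrier samples swap isoform usage only under exposure
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(900 + seed)
            n_rils, K = 100, 2
            labels = rng.integers(0, 8, size=n_rils)
            G1 = np.eye(8)[labels]
            G = np.vstack([G1, G1])
            E = np.repeat([0.0, 1.0], n_rils)
            carrier = np.tile(labels == 2, 2).astype(float)
            Y = rng.normal(scale=1.0, size=(K, 2 * n_rils))
            Y[0] += 2.0 * carrier * E
            Y[1] -= 2.0 * carrier * E
            _, _, rec = sq.fit_isoform_model(Y, G, E)
            hits += rec["p"] < 1e-4
        assert hits >= 16

    def test_incomplete_block_rejected(self, rng):
        G, E = random_instance(rng)
        Y = rng.normal(size=(2, len(E)))
        Y[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            sq.fit_isoform_model(Y, G, E)


class TestScan:
    def test_cross_product_arithmetic(self):
        assert n_tests(3, 7) == 21
        with pytest.raises(ValueError):
            n_tests(-1, 5)

    def test_single_pair_scan(self, small_panel):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        one = sq.PhenotypeMatrix(
            values=frac.values.iloc[[0]],
            anchors=frac.anchors.iloc[[0]],
            kind="exon_fraction",
        )
        geno = sp["genotypes"]
        sub = sq.GenotypeTensor(
            rils=geno.rils, loci=geno.loci.iloc[[0]], founders=geno.founders,
            probs=geno.probs[:, [0], :],
        )
        assoc = sq.scan(one, sub, sp["samples"])
        assert len(assoc) == 1

    def test_scan_deterministic_and_complete(self, small_panel):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        sub = sq.PhenotypeMatrix(
            values=frac.values.iloc[:10], anchors=frac.anchors.iloc[:10],
            kind="exon_fraction",
        )
        a = sq.scan(sub, sp["genotypes"], sp["samples"])
        b = sq.scan(sub, sp["genotypes"], sp["samples"])
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 10 * sp["genotypes"].n_loci

    def test_batched_path_matches_per_fit_path(self, small_panel, rng):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        vals = frac.values.iloc[:8].copy()
        vals.iloc[rng.integers(0, 8, 5), 2] = np.nan  # mixed missingness patterns
        sub = sq.PhenotypeMatrix(
            values=vals, anchors=frac.anchors.iloc[:8], kind="exon_fraction"
        )
        assoc = sq.scan(sub, sp["genotypes"], sp["samples"])
        env = sp["env"]
        ril_idx = sp["genotypes"].ril_index(sp["samples"]["ril"].tolist())
        for _ in range(12):
            row = assoc.iloc[rng.integers(len(assoc))]
            loci = sp["genotypes"].loci
            j = loci.index[
                (loci["chrom"] == row["locus_chrom"]) & (loci["pos"] == row["locus_pos"])
            ][0]
            y = vals.loc[row["phenotype_id"]].to_numpy()
            _, _, rec = sq.fit_exon_model(y, sp["genotypes"].probs[ril_idx, j, :], env)
            assert rec["F"] == pytest.approx(row["F"], abs=1e-8, nan_ok=True)
            assert rec["top_founder"] == row["top_founder"]

    def test_cis_window_restricts_loci(self, small_panel):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        sub = sq.PhenotypeMatrix(
            values=frac.values.iloc[:3], anchors=frac.anchors.iloc[:3],
            kind="exon_fraction",
        )
        assoc = sq.scan(sub, sp["genotypes"], sp["samples"],
                        ScanConfig(cis_window=50_000))
        assert (assoc["locus_chrom"] == assoc["pheno_chrom"]).all()
        assert ((assoc["locus_pos"] - assoc["pheno_pos"]).abs() <= 50_000).all()

    def test_sample_mismatch_is_hard_error(self, small_panel):
        sp = small_panel
        frac = sq.exon_fraction(sp["exon_counts"], sp["tx_counts"], sp["annotation"])
        bad = sp["samples"].iloc[:-4]
        with pytest.raises(ValueError, match="absent"):
            sq.scan(frac, sp["genotypes"], bad)


class TestDifferentialExpression:
    def _sheet(self, n):
        rils = [f"R{i}" for i in range(n)]
        return sq.make_sample_sheet(rils)

    def test_identical_conditions_are_null(self, rng):
        ss = self._sheet(10)
        base = rng.integers(50, 500, size=20)
        counts = pd.DataFrame(
            np.tile(base[:, None], (1, 20)),
            index=[f"t{i}" for i in range(20)], columns=ss["sample"],
        )
        de = sq.differential_expression(counts, ss)
        np.testing.assert_allclose(de["M"], 0.0, atol=1e-12)
        assert (de["p"] > 0.9).all()

    def test_exact_twofold_change(self):
        ss = self._sheet(6)
        pb = ss["treatment"] == "pb"
        # libraries balanced (300 reads everywhere) so CPM scaling cancels
        counts = pd.DataFrame(
            {"t1": np.where(pb, 200, 100), "t2": np.where(pb, 100, 200)},
            index=ss["sample"],
        ).T
        de = sq.differential_expression(counts, ss, pseudocount=0.0)
        assert de.loc["t1", "M"] == pytest.approx(1.0, abs=1e-9)
        assert de.loc["t2", "M"] == pytest.approx(-1.0, abs=1e-9)

    def test_planted_log2fc_recovered(self, rng):
        ss = self._sheet(40)
        n_tx = 200
        mu = rng.uniform(100, 1000, size=n_tx)
        lam = np.tile(mu[:, None], (1, 80)) * np.exp(rng.normal(0, 0.15, (n_tx, 80)))
        pb_cols = (ss["treatment"] == "pb").to_numpy()
        planted = np.arange(30)
        lam[np.ix_(planted, np.flatnonzero(pb_cols))] *= 2.0
        counts = pd.DataFrame(
            rng.poisson(lam), index=[f"t{i}" for i in range(n_tx)],
            columns=ss["sample"],
        )
        de = sq.differential_expression(counts, ss)
        m = de.iloc[planted]["M"].to_numpy()
        se = m.std(ddof=1) / np.sqrt(len(m))
        # library-size normalization shifts all M by a common offset; compare
        # against the unplanted background
        background = de.iloc[30:]["M"].mean()
        assert abs((m.mean() - background) - 1.0) < 3 * se

    def test_unpaired_ril_excluded_with_warning(self, rng):
        ss = self._sheet(5)
        ss = ss.iloc[:-1]  # drop the pb sample of the last RIL
        counts = pd.DataFrame(
            rng.integers(10, 100, size=(5, len(ss))),
            index=[f"t{i}" for i in range(5)], columns=ss["sample"],
        )
        with pytest.warns(UserWarning, match="unpaired"):
            sq.differential_expression(counts, ss)
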