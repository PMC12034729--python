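"""Generator contracts: geometry, determinism, copula fidelity, verdict noise."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import ndtr

from cislink.annotation_io import FeatureSet
from cislink.cis_pairing import find_cis_pairs, gap_bp
from cislink.lncrna_filter import consensus_noncoding
from cislink.synthetic import (
    SimConfig,
    simulate_coding_calls,
    simulate_dataset,
    simulate_expression,
    simulate_layout,
)

SMALL = SimConfig(n_lncrna=40, n_mrna=80, n_planted_pairs=15, n_null_pairs=10,
                  n_far_pairs=8, chrom_length_bp=30_000_000, seed=5)


class TestLayout:
    def test_planted_and_null_gaps_within_window(self):
        features, truth = simulate_layout(SMALL)
        for l, m, _, _ in truth.planted_pairs:
            assert gap_bp(truth.layout[l], truth.layout[m]) <= SMALL.window_bp
        for l, m in truth.null_pairs:
            assert gap_bp(truth.layout[l], truth.layout[m]) <= SMALL.window_bp

    def test_pairing_recovers_exactly_the_designated_in_window_pairs(self):
        features, truth = simulate_layout(SMALL)
        lnc = features.with_biotype("lncRNA")
        mrna = features.with_biotype("mRNA")
        found = {(p.lncrna_id, p.mrna_id) for p in find_cis_pairs(lnc, mrna, SMALL.window_bp)}
        designated = {(l, m) for l, m, _, _ in truth.planted_pairs} | set(truth.null_pairs)
        assert found == designated

    def test_far_pairs_exceed_twice_the_window(self):
        _, truth = simulate_layout(SMALL)
        assert truth.far_pairs
        for l, m, _ in truth.far_pairs:
            assert gap_bp(truth.layout[l], truth.layout[m]) > 2 * SMALL.window_bp

    def test_same_seed_identical_layout(self):
        f1, t1 = simulate_layout(SMALL)
        f2, t2 = simulate_layout(SMALL)
        assert f1.to_frame().equals(f2.to_frame())
        assert t1.planted_pairs == t2.planted_pairs

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="chromosome"):
            simulate_layout(SimConfig(n_lncrna=500, n_mrna=1500, n_planted_pairs=400,
                                      n_null_pairs=100, chrom_length_bp=1_000_000))

    def test_de_directions_follow_both_up_flags(self):
        _, truth = simulate_layout(SMALL)
        for l, m, _, both_up in truth.planted_pairs:
            expect = SMALL.de_log2fc if both_up else -SMALL.de_log2fc
            assert truth.planted_de[l] == expect
            assert truth.planted_de[m] == expect


class TestExpression:
    def test_same_seed_identical_counts(self):
        features, truth = simulate_layout(SMALL)
        m1 = simulate_expression(features, truth, SMALL)
        m2 = simulate_expression(features, truth, SMALL)
        assert m1.values.equals(m2.values)

    def test_uncoupled_pair_uncorrelated_at_large_n(self):
        cfg = SimConfig(n_case=500, n_control=500, n_lncrna=6, n_mrna=6,
                        n_planted_pairs=0, n_null_pairs=4, frac_extra_de=0.0,
                        chrom_length_bp=5_000_000, seed=8)
        features, truth = simulate_layout(cfg)
        mat = simulate_expression(features, truth, cfg)
        for l, m in truth.null_pairs:
            r = np.corrcoef(mat.values.loc[l], mat.values.loc[m])[0, 1]
            assert abs(r) < 0.1

    def test_planted_de_shifts_group_means(self):
        cfg = SimConfig(n_case=200, n_control=200, n_lncrna=10, n_mrna=20,
                        n_planted_pairs=8, n_null_pairs=0, frac_extra_de=0.0,
                        frac_pairs_up=1.0, chrom_length_bp=20_000_000, seed=9)
        features, truth = simulate_layout(cfg)
        mat = simulate_expression(features, truth, cfg)
        case = mat.samples_of("case")
        control = mat.samples_of("control")
        for fid in truth.planted_de:
            est = np.log2(mat.values.loc[fid, case].mean() / mat.values.loc[fid, control].mean())
            assert est == pytest.approx(cfg.de_log2fc, abs=0.4)

    @pytest.mark.parametrize("rho", [0.5, 0.8, 0.95])
    def test_copula_attenuation_matches_independent_oracle(self, rho):
        """Empirical count-scale r tracks an independently coded copula draw.

        The oracle builds the bivariate normal by explicit Cholesky
        factorisation and inverts the NB CDF at fixed marginal parameters;
        NB discreteness attenuates the latent rho, and both routes must
        agree on the attenuated value.
        """
        cfg = SimConfig(n_case=2500, n_control=2500, n_lncrna=2, n_mrna=2,
                        n_planted_pairs=2, n_null_pairs=0, frac_extra_de=0.0,
                        frac_pairs_up=1.0, de_log2fc=0.0, rho=rho,
                        chrom_length_bp=5_000_000, seed=21)
        features, truth = simulate_layout(cfg)
        mat = simulate_expression(features, truth, cfg)
        l, m, _, _ = truth.planted_pairs[0]
        r_sim = np.corrcoef(mat.values.loc[l], mat.values.loc[m])[0, 1]

        rng = np.random.default_rng(999)
        n = 50_000
        chol = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        z = chol @ rng.standard_normal((2, n))
        size = 1.0 / cfg.nb_dispersion
        # oracle marginal means estimated from the simulated features
        mus = [float(mat.values.loc[l].mean()), float(mat.values.loc[m].mean())]
        x = stats.nbinom.ppf(ndtr(z[0]), size, size / (size + mus[0]))
        y = stats.nbinom.ppf(ndtr(z[1]), size, size / (size + mus[1]))
        r_oracle = np.corrcoef(x, y)[0, 1]
        assert r_sim == pytest.approx(r_oracle, abs=0.05)


class TestCodingCalls:
    def test_noiseless_calls_recover_true_lncrnas_exactly(self):
        features, truth = simulate_layout(SMALL)
        calls = simulate_coding_calls(features, truth, flip_prob=0.0, seed=1)
        true_lnc = {f.feature_id for f in features if f.biotype == "lncRNA"}
        assert consensus_noncoding(calls, min_votes=3) == true_lnc

    def test_same_seed_identical_verdicts(self):
        features, truth = simulate_layout(SMALL)
        c1 = simulate_coding_calls(features, truth, 0.3, seed=4)
        c2 = simulate_coding_calls(features, truth, 0.3, seed=4)
        assert c1 == c2

    def test_noisy_retention_matches_binomial_expectation(self):
        """flip_prob=0.4 retains true lncRNAs at P(Bin(4, 0.6) >= 3) = 0.4752."""
        cfg = SimConfig(n_lncrna=2000, n_mrna=10, n_planted_pairs=0, n_null_pairs=0,
                        chrom_length_bp=500_000_000, seed=13)
        features, truth = simulate_layout(cfg)
        calls = simulate_coding_calls(features, truth, flip_prob=0.4, seed=13)
        true_lnc = [f.feature_id for f in features if f.biotype == "lncRNA"]
        kept = consensus_noncoding([c for c in calls if c.feature_id in set(true_lnc)], 3)
        expected = stats.binom.sf(2, 4, 0.6)  # 0.4752
        rate = len(kept) / len(true_lnc)
        se = np.sqrt(expected * (1 - expected) / len(true_lnc))
        assert abs(rate - expected) <= 3 * se


def test_dataset_files_round_trip(tmp_path):
    cfg = SimConfig(n_lncrna=20, n_mrna=40, n_planted_pairs=8, n_null_pairs=4,
                    chrom_length_bp=20_000_000, seed=2)
    ds = simulate_dataset(cfg, out_dir=tmp_path)
    for name in ("annotation.gtf", "counts.tsv", "coding_calls.tsv", "truth.json",
                 "conditions.yaml"):
        assert (tmp_path / name).exists()
    from cislink.annotation_io import read_annotation
    from cislink.synthetic import SyntheticTruth

    back = read_annotation(tmp_path / "annotation.gtf")
    assert sorted(back.ids()) == sorted(ds.features.ids())
    truth = SyntheticTruth.from_json(tmp_path / "truth.json")
    assert truth.planted_pairs == ds.truth.planted_pairs
    assert truth.layout["LNC0001"] == ds.truth.layout["LNC0001"]
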