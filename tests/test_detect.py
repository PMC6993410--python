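import numpy as np
import pandas as pd
import pytest

from methtdm.detect import (candidate_motifs, delta_correlation,
                            derive_motif_seed, detect_methtdms,
                            permutation_test, stratify_samples)
from methtdm.errors import ConfigError, DegenerateInputError
from methtdm.simulate import simulate_profiles
from methtdm.designs import recovery_combos, recovery_config

from conftest import make_omics


class TestStratify:
    def test_thirty_cases_give_twelve_twelve(self):
        row = pd.Series(np.linspace(0, 1, 30),
                        index=[f"PE{i:02d}" for i in range(30)])
        s = stratify_samples(row)
        assert len(s.low_ids) == len(s.high_ids) == 12
        assert not set(s.low_ids) & set(s.high_ids)

    def test_values_one_to_ten(self):
        row = pd.Series(range(1, 11), index=[f"S{i}" for i in range(1, 11)])
        s = stratify_samples(row, fraction=0.4)
        assert list(s.low_ids) == ["S1", "S2", "S3", "S4"]
        assert list(s.high_ids) == ["S7", "S8", "S9", "S10"]

    def test_ties_broken_by_sample_id(self):
        row = pd.Series([5.0] * 10, index=[f"S{i:02d}" for i in range(10)])
        s = stratify_samples(row, fraction=0.4)
        assert list(s.low_ids) == ["S00", "S01", "S02", "S03"]
        assert list(s.high_ids) == ["S06", "S07", "S08", "S09"]

    def test_monotone_transform_leaves_strata_unchanged(self):
        rng = np.random.default_rng(0)
        row = pd.Series(rng.uniform(0.01, 0.99, 20),
                        index=[f"S{i:02d}" for i in range(20)])
        a = stratify_samples(row)
        b = stratify_samples(np.log2(row))  # log2 is strictly monotone
        assert a.low_ids == b.low_ids and a.high_ids == b.high_ids

    def test_fraction_out_of_range(self):
        row = pd.Series(range(10), index=[f"S{i}" for i in range(10)])
        with pytest.raises(ConfigError):
            stratify_samples(row, fraction=0.7)


def exact_delta_fixture():
    """Motif whose |delta| is exactly 1.6 (r_low = +0.8, r_high = -0.8)."""
    ids = [f"P{i}" for i in range(1, 9)]
    meth = pd.Series([0.1, 0.1, 0.2, 0.2, 0.8, 0.8, 0.9, 0.9], index=ids)
    tf = pd.Series([1, 2, 3, 4, 1, 2, 3, 4], index=ids, dtype=float)
    gene = pd.Series([1, 3, 2, 4, 4, 2, 3, 1], index=ids, dtype=float)
    return tf, gene, meth, ids


class TestDeltaCorrelation:
    def test_exact_reversal(self):
        tf, gene, meth, _ = exact_delta_fixture()
        strat = stratify_samples(meth, fraction=0.5)
        r_low, r_high, delta = delta_correlation(tf, gene, strat)
        assert r_low == pytest.approx(0.8)
        assert r_high == pytest.approx(-0.8)
        assert delta == pytest.approx(-1.6)

    def test_swapping_strata_negates_delta(self):
        tf, gene, meth, _ = exact_delta_fixture()
        s = stratify_samples(meth, fraction=0.5)
        swapped = type(s)(site=s.site, low_ids=s.high_ids, high_ids=s.low_ids)
        assert delta_correlation(tf, gene, s)[2] == pytest.approx(
            -delta_correlation(tf, gene, swapped)[2])

    def test_same_structure_both_strata_gives_small_delta(self):
        rng = np.random.default_rng(1)
        ids = [f"P{i:02d}" for i in range(30)]
        x = pd.Series(rng.standard_normal(30), index=ids)
        y = pd.Series(0.9 * x + 0.3 * rng.standard_normal(30), index=ids)
        meth = pd.Series(rng.uniform(size=30), index=ids)
        _, _, delta = delta_correlation(x, y, stratify_samples(meth))
        assert abs(delta) < 0.5

    def test_degenerate_stratum_raises(self):
        ids = [f"P{i}" for i in range(1, 9)]
        tf = pd.Series([1.0] * 4 + [1, 2, 3, 4], index=ids)
        gene = pd.Series(range(8), index=ids, dtype=float)
        meth = pd.Series(np.linspace(0, 1, 8), index=ids)
        with pytest.raises(DegenerateInputError):
            delta_correlation(tf, gene, stratify_samples(meth, fraction=0.5))


def motif_matrices():
    tf, gene, meth, ids = exact_delta_fixture()
    tf_m = make_omics(tf.to_numpy()[None, :].tolist(), feature_ids=["T"],
                      case=ids, control=[])
    gene_m = make_omics(gene.to_numpy()[None, :].tolist(), feature_ids=["G"],
                        case=ids, control=[])
    meth_m = make_omics(meth.to_numpy()[None, :].tolist(), feature_ids=["s"],
                        case=ids, control=[])
    return tf_m, gene_m, meth_m


class TestCandidateMotifs:
    def test_delta_threshold_is_strict(self):
        tf_m, gene_m, meth_m = motif_matrices()
        inter = pd.DataFrame({"tf": ["T"], "gene": ["G"]})
        # stratification at fraction 0.5 gives |delta| = 1.6 exactly
        at, _, _ = candidate_motifs(inter, ["s"], tf_m, gene_m, meth_m,
                                    fraction=0.5, delta_threshold=1.6)
        below, _, _ = candidate_motifs(inter, ["s"], tf_m, gene_m, meth_m,
                                       fraction=0.5, delta_threshold=1.59)
        assert len(at) == 0
        assert len(below) == 1

    def test_empty_inputs_give_empty_output(self):
        tf_m, gene_m, meth_m = motif_matrices()
        cands, tested, _ = candidate_motifs(
            pd.DataFrame({"tf": [], "gene": []}), [], tf_m, gene_m, meth_m)
        assert len(cands) == 0 and len(tested) == 0


class TestPermutationTest:
    def test_zero_delta_gives_p_one(self):
        ids = [f"P{i:02d}" for i in range(10)]
        # identical values in a pattern that makes r_low == r_high exactly
        tf = make_omics([[1, 2, 3, 4, 5, 1, 2, 3, 4, 5]], feature_ids=["T"],
                        case=ids, control=[])
        gene = make_omics([[2, 4, 6, 8, 10, 2, 4, 6, 8, 10]],
                          feature_ids=["G"], case=ids, control=[])
        meth = make_omics([np.linspace(0, 1, 10).tolist()], feature_ids=["s"],
                          case=ids, control=[])
        p = permutation_test("s", "T", "G", tf, gene, meth, fraction=0.5,
                             n_perm=200, seed=1)
        assert p == pytest.approx(1.0)

    def test_minimal_p_is_add_one_bound(self):
        cfg = recovery_config(seed=3, n_planted=1, n_null=0)
        tf_m, gene_m, meth_m, truth = simulate_profiles(cfg)
        site, tf, gene = next(iter(truth.motifs))
        p = permutation_test(site, tf, gene, tf_m, gene_m, meth_m,
                             n_perm=1000, seed=0)
        assert p >= 1 / 1001 - 1e-15
        assert p < 0.05  # an overwhelming planted reversal

    def test_deterministic_and_order_independent_seeding(self):
        cfg = recovery_config(seed=4, n_planted=2, n_null=0)
        tf_m, gene_m, meth_m, truth = simulate_profiles(cfg)
        keys = sorted(truth.motifs)
        p_fwd = [permutation_test(*k, tf_m, gene_m, meth_m, n_perm=100, seed=7)
                 for k in keys]
        p_rev = [permutation_test(*k, tf_m, gene_m, meth_m, n_perm=100, seed=7)
                 for k in reversed(keys)]
        assert p_fwd == list(reversed(p_rev))
        assert derive_motif_seed(7, *keys[0]) != derive_motif_seed(8, *keys[0])


class TestDetect:
    def test_no_candidates_empty_result(self):
        tf_m, gene_m, meth_m = motif_matrices()
        res = detect_methtdms(pd.DataFrame({"tf": ["T"], "gene": ["G"]}),
                              ["s"], tf_m, gene_m, meth_m, fraction=0.5,
                              delta_threshold=1.99, n_perm=50)
        assert len(res.significant) == 0
        assert list(res.significant.columns) == ["site", "tf", "gene", "r_low",
                                                 "r_high", "delta", "p_perm", "q"]

    def test_recovery_of_planted_reversals_single_seed(self):
        cfg = recovery_config(seed=0, n_planted=10, n_null=50)
        tf_m, gene_m, meth_m, truth = simulate_profiles(cfg)
        res = detect_methtdms(
            pd.DataFrame(truth.correlated_pairs, columns=["tf", "gene"]),
            [], tf_m, gene_m, meth_m, n_perm=500, seed=0,
            combos=recovery_combos(truth))
        found = set(zip(res.significant["site"], res.significant["tf"],
                        res.significant["gene"]))
        assert len(found & set(truth.motifs)) >= 9

    def test_significant_sorted_by_q_then_contrast(self):
        cfg = recovery_config(seed=0, n_planted=5, n_null=20)
        tf_m, gene_m, meth_m, truth = simulate_profiles(cfg)
        res = detect_methtdms(
            pd.DataFrame(truth.correlated_pairs, columns=["tf", "gene"]),
            [], tf_m, gene_m, meth_m, n_perm=200, seed=0,
            combos=recovery_combos(truth))
        q = res.significant["q"].to_numpy()
        assert (np.diff(q) >= 0).all()
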