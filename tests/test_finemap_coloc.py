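"""Wakefield ABFs, PIPs, and the five-hypothesis colocalization masses."""

import numpy as np
import pytest
from scipy.special import logsumexp

from coloxwas.finemap_coloc import (ColocConfig, OverlapError, SignalFineMap,
                                    coloc_pair, conditional_coloc,
                                    pip_from_labf, wakefield_labf)
from coloxwas.synthetic import ScenarioSpec, feature_qtl_sumstats, \
    make_scenario


class TestWakefieldLabf:
    def test_null_z_shrinks_below_zero(self):
        labf = wakefield_labf(0.0, 0.05, 0.0225)
        assert labf == pytest.approx(0.5 * np.log(0.0025 / 0.025))
        assert labf < 0

    def test_closed_form_value(self):
        """beta=0.1, se=0.05, W=0.0225: labf = 0.5 (ln 0.1 + 3.6)."""
        labf = wakefield_labf(0.1, 0.05, 0.0225)
        V, W, z2 = 0.0025, 0.0225, 4.0
        assert labf == pytest.approx(
            0.5 * (np.log(V / (V + W)) + z2 * W / (V + W)), rel=1e-12)
        assert labf == pytest.approx(0.5 * (np.log(0.1) + 3.6), rel=1e-10)
        assert labf == pytest.approx(0.64871, abs=1e-5)

    def test_vanishing_prior_kills_evidence(self):
        for z in (0.0, 3.0, 10.0):
            assert wakefield_labf(z * 0.05, 0.05, 1e-12) == \
                pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_labf(0.1, 0.0, 0.0225)


class TestPip:
    def test_equal_labfs_give_uniform_pips(self):
        fm = pip_from_labf([f"s{i}" for i in range(8)], np.full(8, 2.5))
        np.testing.assert_allclose(fm.pip, 1 / 8)

    def test_two_snp_softmax(self):
        fm = pip_from_labf(["a", "b"], np.array([10.0, 0.0]))
        assert fm.pip[0] == pytest.approx(1 / (1 + np.exp(-10)), rel=1e-9)
        assert fm.pip[1] == pytest.approx(4.54e-5, rel=1e-2)

    def test_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(0)
        labfs = rng.normal(size=20) * 100
        a = pip_from_labf(list("abcdefghijklmnopqrst"), labfs)
        b = pip_from_labf(list("abcdefghijklmnopqrst"), labfs + 500)
        np.testing.assert_allclose(a.pip, b.pip, rtol=1e-10)
        assert a.pip.sum() == pytest.approx(1.0, abs=1e-9)

    def test_large_spread_is_stable(self):
        fm = pip_from_labf(["a", "b"], np.array([800.0, 0.0]))
        assert fm.pip[0] == pytest.approx(1.0)
        assert np.isfinite(fm.pip).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pip_from_labf([], np.array([]))


def _enumerate_masses(l1, l2, cfg):
    """Explicit enumeration over all causal configurations (the oracle)."""
    bf1, bf2 = np.exp(l1), np.exp(l2)
    m = len(bf1)
    L0 = 1.0
    L1 = cfg.p1 * bf1.sum()
    L2 = cfg.p2 * bf2.sum()
    L3 = cfg.p1 * cfg.p2 * sum(
        bf1[i] * bf2[j] for i in range(m) for j in range(m) if i != j)
    L4 = cfg.p12 * sum(bf1[i] * bf2[i] for i in range(m))
    L = np.array([L0, L1, L2, L3, L4])
    return L / L.sum()


class TestColocPair:
    def test_matches_enumeration_oracle(self):
        """For m <= 12 SNPs the five masses match explicit enumeration."""
        cfg = ColocConfig()
        rng = np.random.default_rng(1)
        for m in (1, 2, 5, 12):
            for _ in range(5):
                ids = [f"s{i}" for i in range(m)]
                l1 = rng.normal(2, 3, m)
                l2 = rng.normal(2, 3, m)
                res = coloc_pair(SignalFineMap(ids, l1, np.empty(0)),
                                 SignalFineMap(ids, l2, np.empty(0)), cfg)
                expected = _enumerate_masses(l1, l2, cfg)
                got = np.array([res.pp[h] for h in
                                ("H0", "H1", "H2", "H3", "H4")])
                np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_single_snp_has_no_h3(self):
        ids = ["only"]
        res = coloc_pair(SignalFineMap(ids, np.array([20.0]), np.empty(0)),
                         SignalFineMap(ids, np.array([18.0]), np.empty(0)))
        assert res.pp["H3"] == 0.0
        assert res.pp["H4"] > max(res.pp["H1"], res.pp["H2"])

    def test_all_null_labfs_favor_h0(self):
        ids = [f"s{i}" for i in range(100)]
        zero = np.zeros(100)
        res = coloc_pair(SignalFineMap(ids, zero, np.empty(0)),
                         SignalFineMap(ids, zero, np.empty(0)))
        # direct evaluation of the masses: L=(1, .01, .01, 9.9e-5, 1e-3)
        assert res.pp["H0"] == pytest.approx(
            _enumerate_masses(zero, zero, ColocConfig())[0], abs=1e-10)
        assert res.pp["H0"] > 0.97
        assert res.pp["H0"] == max(res.pp.values())

    def test_swapping_traits_swaps_h1_h2(self):
        rng = np.random.default_rng(2)
        ids = [f"s{i}" for i in range(30)]
        l1, l2 = rng.normal(0, 4, 30), rng.normal(0, 4, 30)
        a = coloc_pair(SignalFineMap(ids, l1, np.empty(0)),
                       SignalFineMap(ids, l2, np.empty(0)))
        b = coloc_pair(SignalFineMap(ids, l2, np.empty(0)),
                       SignalFineMap(ids, l1, np.empty(0)))
        assert a.pp["H1"] == pytest.approx(b.pp["H2"], rel=1e-10)
        assert a.pp["H2"] == pytest.approx(b.pp["H1"], rel=1e-10)
        for h in ("H0", "H3", "H4"):
            assert a.pp[h] == pytest.approx(b.pp[h], rel=1e-10)

    def test_pp_sums_to_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(1, 40)
            ids = [f"s{i}" for i in range(m)]
            res = coloc_pair(
                SignalFineMap(ids, rng.normal(0, 10, m), np.empty(0)),
                SignalFineMap(ids, rng.normal(0, 10, m), np.empty(0)))
            assert sum(res.pp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_h4_monotone_in_p12(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(20)]
        l1 = rng.normal(1, 3, 20)
        l2 = l1 + rng.normal(0, 0.5, 20)
        last = -1.0
        for p12 in (1e-7, 1e-6, 1e-5, 5e-5, 9.9e-5):
            cfg = ColocConfig(p12=p12)
            pp4 = coloc_pair(SignalFineMap(ids, l1, np.empty(0)),
                             SignalFineMap(ids, l2, np.empty(0)),
                             cfg).pp["H4"]
            assert pp4 >= last
            last = pp4

    def test_identical_sharp_signals_drive_h4_to_one(self):
        ids = [f"s{i}" for i in range(50)]
        labf = np.zeros(50)
        labf[25] = 40.0
        res = coloc_pair(SignalFineMap(ids, labf, np.empty(0)),
                         SignalFineMap(ids, labf, np.empty(0)))
        assert res.pp["H4"] > 0.99

    def test_mismatched_snp_sets_rejected(self):
        a = SignalFineMap(["x"], np.array([1.0]), np.empty(0))
        b = SignalFineMap(["y"], np.array([1.0]), np.empty(0))
        with pytest.raises(OverlapError):
            coloc_pair(a, b)


class TestConditionalColoc:
    def test_single_shared_scenario_colocalizes(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="single_shared", seed=seed + 400))
            qtl = feature_qtl_sumstats(bundle, "feature_1")
            res = conditional_coloc(qtl, bundle.sumstats["trait_1"],
                                    bundle.panel,
                                    bundle.models[0].gene_span)
            hits += any(r.pp["H4"] >= 0.8 for r in res)
        assert hits >= 0.8 * reps

    def test_distinct_in_ld_scenario_prefers_h3(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="distinct_in_ld", seed=seed + 500))
            qtl = feature_qtl_sumstats(bundle, "feature_1")
            res = conditional_coloc(qtl, bundle.sumstats["trait_1"],
                                    bundle.panel,
                                    bundle.models[0].gene_span)
            best = max(res, key=lambda r: r.pp["H4"])
            hits += best.pp["H3"] > best.pp["H4"]
        assert hits >= 0.7 * reps

    def test_two_signals_only_shared_signal_colocalizes(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="two_signals", seed=seed + 600))
            shared = bundle.truth.causal_snps_by_feature["feature_1"][0]
            qtl = feature_qtl_sumstats(bundle, "feature_1")
            res = conditional_coloc(qtl, bundle.sumstats["trait_1"],
                                    bundle.panel,
                                    bundle.models[0].gene_span)
            coloced = [r for r in res if r.pp["H4"] >= 0.8]
            # exactly the trait signal matching the shared causal SNP
            ok = (len(coloced) >= 1 and all(
                shared in r.trait_signal or _near(bundle, shared,
                                                  r.trait_signal)
                for r in coloced))
            hits += ok
        assert hits >= 0.7 * reps

    def test_every_result_sums_to_one(self):
        bundle = make_scenario(ScenarioSpec(name="two_signals", seed=700))
        qtl = feature_qtl_sumstats(bundle, "feature_1")
        res = conditional_coloc(qtl, bundle.sumstats["trait_1"],
                                bundle.panel, bundle.models[0].gene_span)
        for r in res:
            assert sum(r.pp.values()) == pytest.approx(1.0, abs=1e-9)


def _near(bundle, causal, signal_name, r2=0.8):
    """Does the lead named in signal_name tag the causal SNP at r2 > 0.8?"""
    lead = signal_name.split(":")[-1]
    if lead == "marginal":
        return False
    return bundle.panel.correlation([lead, causal])[0, 1] ** 2 > r2
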