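"""Approximate conditional & joint analysis against exact-regression oracles."""

import numpy as np
import pytest
from scipy import stats

from coloxwas import cojo
from coloxwas.synthetic import (ScenarioSpec, make_scenario,
                                marginal_sumstats_from_individuals,
                                simulate_ld_panel)

from conftest import make_sumstats


def _individual_gwas(seed, n=5000, p=30, causal=None, effects=None,
                     ld_decay=0.6):
    """Panel + phenotype + in-sample sumstats for the exact oracle."""
    spec = ScenarioSpec(p_snps=p, n_panel=n, ld_decay=ld_decay, seed=seed)
    panel = simulate_ld_panel(spec)
    rng = np.random.default_rng(seed + 10_000)
    y = rng.standard_normal(n)
    if causal:
        for idx, eff in zip(causal, effects):
            d = panel.dosages[:, idx]
            y = y + eff * (d - d.mean()) / d.std()
    ss = marginal_sumstats_from_individuals(panel, y, "t")
    return panel, y, ss


def _exact_joint(panel, y, snp_ids):
    """Exact multiple regression of y on the dosage columns (with intercept)."""
    idx = panel.index_of(snp_ids)
    X = np.column_stack([np.ones(len(y)), panel.dosages[:, idx]])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return coef[1:], np.sqrt(np.diag(cov)[1:])


class TestApproxJointFit:
    def test_single_snp_returns_marginal(self, small_panel):
        ss = make_sumstats(small_panel, np.arange(10, dtype=float))
        ms = cojo.MarginalStats.from_sumstats(ss)
        out = cojo.approx_joint_fit(ms, ["rs3"], small_panel)
        assert out["b_joint"].iloc[0] == ms.b[2]
        assert out["se_joint"].iloc[0] == ms.se[2]

    def test_matches_exact_two_snp_least_squares(self):
        """Panel = GWAS sample: joint effects within 5% of exact OLS."""
        worst = 0.0
        for seed in range(15):
            panel, y, ss = _individual_gwas(
                seed, causal=[8, 20], effects=[0.08, 0.06])
            ms = cojo.MarginalStats.from_sumstats(ss)
            out = cojo.approx_joint_fit(ms, ["rs9", "rs21"], panel,
                                        ridge=0.0)
            b_exact, se_exact = _exact_joint(panel, y, ["rs9", "rs21"])
            # marginals are on the dosage scale, as is the oracle
            rel = np.abs(out["b_joint"].to_numpy() - b_exact) / \
                np.abs(b_exact)
            worst = max(worst, rel.max())
        assert worst < 0.05

    def test_joint_se_close_to_exact(self):
        panel, y, ss = _individual_gwas(3, causal=[8, 20],
                                        effects=[0.08, 0.06])
        ms = cojo.MarginalStats.from_sumstats(ss)
        out = cojo.approx_joint_fit(ms, ["rs9", "rs21"], panel, ridge=0.0)
        _, se_exact = _exact_joint(panel, y, ["rs9", "rs21"])
        np.testing.assert_allclose(out["se_joint"], se_exact, rtol=0.1)

    def test_uncorrelated_snps_keep_marginal_effects(self, small_panel):
        panel = small_panel
        panel.dosages[:, 0] = np.tile([0, 0, 2, 2], 50)
        panel.dosages[:, 5] = np.tile([0, 2, 0, 2], 50)
        ss = make_sumstats(panel, np.arange(10, dtype=float))
        ms = cojo.MarginalStats.from_sumstats(ss)
        out = cojo.approx_joint_fit(ms, ["rs1", "rs6"], panel, ridge=0.0)
        # equal per-SNP N: orthogonal system returns marginal b
        np.testing.assert_allclose(out["b_joint"], ms.b[[0, 5]], atol=1e-6)

    def test_empty_set_rejected(self, small_panel):
        ss = make_sumstats(small_panel, np.zeros(10))
        ms = cojo.MarginalStats.from_sumstats(ss)
        with pytest.raises(ValueError):
            cojo.approx_joint_fit(ms, [], small_panel)


class TestConditionalStats:
    def test_orthogonal_target_keeps_marginal(self, small_panel):
        panel = small_panel
        panel.dosages[:, 0] = np.tile([0, 0, 2, 2], 50)
        panel.dosages[:, 9] = np.tile([0, 2, 0, 2], 50)
        ss = make_sumstats(panel, np.arange(10, dtype=float) + 1)
        ms = cojo.MarginalStats.from_sumstats(ss)
        cond = cojo.conditional_stats(ms, ["rs1"], panel,
                                      ridge=0.0).set_index("snp_id")
        assert cond.loc["rs10", "b_cond"] == pytest.approx(
            ms.b[9], abs=1e-6 * abs(ms.b[9]))

    def test_perfect_proxy_is_masked(self, small_panel):
        panel = small_panel.subset(small_panel.snp_ids)
        panel.dosages[:, 1] = panel.dosages[:, 0]  # synthetic duplicate
        z = np.arange(10, dtype=float) + 1
        z[1] = z[0]
        ss = make_sumstats(panel, z)
        ms = cojo.MarginalStats.from_sumstats(ss)
        cond = cojo.conditional_stats(ms, ["rs1"], panel).set_index("snp_id")
        assert bool(cond.loc["rs2", "masked"])
        assert np.isnan(cond.loc["rs2", "b_cond"])

    def test_empty_conditioning_set_rejected(self, small_panel):
        ss = make_sumstats(small_panel, np.zeros(10))
        ms = cojo.MarginalStats.from_sumstats(ss)
        with pytest.raises(ValueError):
            cojo.conditional_stats(ms, [], small_panel)

    def test_conditioning_on_causal_kills_region(self):
        """single_shared: conditioning on the causal SNP leaves no residual
        association in the window."""
        wins = 0
        reps = 20
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="single_shared", seed=seed))
            causal = bundle.truth.causal_snps_by_trait["trait_1"][0]
            ms = cojo.MarginalStats.from_sumstats(bundle.sumstats["trait_1"])
            cond = cojo.conditional_stats(ms, [causal], bundle.panel)
            zc = np.abs(cond["b_cond"] / cond["se_cond"]).dropna()
            wins += zc.max() < 3.5
        assert wins >= 0.9 * reps


class TestCojoSlct:
    def test_null_region_selects_nothing(self):
        spec = ScenarioSpec(p_snps=40, n_panel=1000, seed=40)
        panel = simulate_ld_panel(spec)
        rng = np.random.default_rng(40)
        from coloxwas.synthetic import simulate_gwas_sumstats
        ss = simulate_gwas_sumstats(panel, np.zeros(40), 1e5, rng)
        ms = cojo.MarginalStats.from_sumstats(ss)
        sig = cojo.cojo_slct(ms, panel)
        assert sig.lead_snps == []
        assert sig.used_marginal

    def test_single_causal_recovers_causal_or_proxy(self):
        wins = 0
        reps = 20
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="single_shared", seed=seed + 100))
            causal = bundle.truth.causal_snps_by_trait["trait_1"][0]
            ms = cojo.MarginalStats.from_sumstats(bundle.sumstats["trait_1"])
            sig = cojo.cojo_slct(ms, bundle.panel)
            if len(sig.lead_snps) != 1:
                continue
            lead = sig.lead_snps[0]
            if lead == causal:
                wins += 1
            else:
                r2 = bundle.panel.correlation([lead, causal])[0, 1] ** 2
                wins += r2 > 0.8
        assert wins >= 0.9 * reps

    def test_two_signals_recovered(self):
        wins = 0
        reps = 20
        for seed in range(reps):
            bundle = make_scenario(
                ScenarioSpec(name="two_signals", seed=seed + 200))
            ms = cojo.MarginalStats.from_sumstats(bundle.sumstats["trait_1"])
            sig = cojo.cojo_slct(ms, bundle.panel)
            wins += len(sig.lead_snps) == 2
        assert wins >= 0.85 * reps

    def test_leads_satisfy_pairwise_r2_constraint(self):
        bundle = make_scenario(ScenarioSpec(name="two_signals", seed=301))
        ms = cojo.MarginalStats.from_sumstats(bundle.sumstats["trait_1"])
        sig = cojo.cojo_slct(ms, bundle.panel, collinearity=0.1)
        if len(sig.lead_snps) >= 2:
            R = bundle.panel.correlation(sig.lead_snps)
            off = R[np.triu_indices_from(R, k=1)]
            assert (off**2 <= 0.1).all()

    def test_matches_exact_stepwise_regression(self):
        """Panel = GWAS sample, no ridge: selected set equals the set from
        exact stepwise regression on individual data."""
        agree = 0
        reps = 12
        for seed in range(reps):
            panel, y, ss = _individual_gwas(
                seed + 50, n=5000, causal=[5, 22], effects=[0.09, 0.07])
            ms = cojo.MarginalStats.from_sumstats(ss)
            sig = cojo.cojo_slct(ms, panel, ridge=0.0)
            exact = _exact_stepwise(panel, y, p_entry=5e-8,
                                    collinearity=0.1)
            agree += set(sig.lead_snps) == set(exact)
        assert agree >= 0.95 * reps


def _exact_stepwise(panel, y, p_entry, collinearity):
    """Forward stepwise OLS on individual-level data (the oracle)."""
    n, p = panel.dosages.shape
    X = panel.dosages
    selected: list[int] = []
    while True:
        best_p, best_j = 1.0, None
        for j in range(p):
            if j in selected:
                continue
            if selected:
                R = np.corrcoef(X[:, selected + [j]], rowvar=False)
                if (np.atleast_2d(R)[-1, :-1] ** 2 > collinearity).any():
                    continue
            cols = np.column_stack([np.ones(n), X[:, selected + [j]]])
            coef, *_ = np.linalg.lstsq(cols, y, rcond=None)
            resid = y - cols @ coef
            sigma2 = resid @ resid / (n - cols.shape[1])
            cov = sigma2 * np.linalg.inv(cols.T @ cols)
            t = coef[-1] / np.sqrt(cov[-1, -1])
            pval = 2 * stats.norm.sf(abs(t))
            if pval < best_p:
                best_p, best_j = pval, j
        if best_j is None or best_p >= p_entry:
            break
        selected.append(best_j)
        if len(selected) >= 10:
            break
    return [panel.snp_ids[j] for j in selected]
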