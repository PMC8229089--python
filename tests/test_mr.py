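import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmr.mr import (Instrument, MrParams, MRResult, NoInstrument,
                       bidirectional_filter, forward_mr, gls_mr,
                       remove_pleiotropic, reverse_mr, select_instrument)
from methmr.simulate import ScenarioConfig, simulate_locus
from methmr.sumstats import harmonize

from conftest import make_panel, make_sumstats


def make_instrument(b_zx, se_zx, b_zy, se_zy, ld=None):
    import pandas as pd
    n = len(b_zx)
    return Instrument(
        exposure_id="exp", outcome_id="out",
        snps=pd.DataFrame({
            "snp_id": [f"s{i}" for i in range(n)],
            "b_zx": b_zx, "se_zx": se_zx, "b_zy": b_zy, "se_zy": se_zy}),
        ld=np.eye(n) if ld is None else np.asarray(ld))


def ivw_oracle(b_zx, se_zx, b_zy, se_zy):
    """Independent inverse-variance-weighted meta-analysis of Wald ratios."""
    b = np.asarray(b_zy) / np.asarray(b_zx)
    v = (np.asarray(se_zy) ** 2 + b ** 2 * np.asarray(se_zx) ** 2) \
        / np.asarray(b_zx) ** 2
    w = 1.0 / v
    return float((w * b).sum() / w.sum()), float(1.0 / math.sqrt(w.sum()))


class TestSelectInstrument:
    def _panel_with_r2(self, r2_ab, r2_ac, r2_bc, seed=0):
        r = np.sqrt([r2_ab, r2_ac, r2_bc])
        R = np.array([[1, r[0], r[1]], [r[0], 1, r[2]], [r[1], r[2], 1.0]])
        return make_panel(R, 20_000, np.random.default_rng(seed),
                          ["A", "B", "C"])

    def test_greedy_example(self):
        # A(p=1e-20), B(p=1e-15, r2(A,B)=0.8), C(p=1e-9, r2 with A,C tiny)
        panel = self._panel_with_r2(0.8, 0.01, 0.02)
        z = {"A": 9.26, "B": 7.94, "C": 6.0}  # z for p 1e-20, 1e-15, 1e-9
        exp = make_sumstats("m", ["A", "B", "C"],
                            [z["A"] * .01, z["B"] * .01, z["C"] * .01],
                            [.01] * 3)
        out = make_sumstats("y", ["A", "B", "C"], [.01] * 3, [.01] * 3)
        instr = select_instrument(exp, out, panel)
        assert instr.snps["snp_id"].tolist() == ["A", "C"]
        assert instr.provenance["removed_ld"] == 1

    def test_all_in_ld_keeps_single_best(self):
        panel = self._panel_with_r2(0.8, 0.7, 0.75)
        exp = make_sumstats("m", ["A", "B", "C"], [.09, .08, .07], [.01] * 3)
        out = make_sumstats("y", ["A", "B", "C"], [.01] * 3, [.01] * 3)
        instr = select_instrument(exp, out, panel)
        assert instr.snps["snp_id"].tolist() == ["A"]

    def test_no_significant_snps(self):
        panel = self._panel_with_r2(0.01, 0.01, 0.01)
        exp = make_sumstats("m", ["A", "B", "C"], [.01] * 3, [.01] * 3)
        out = make_sumstats("y", ["A", "B", "C"], [.01] * 3, [.01] * 3)
        res = select_instrument(exp, out, panel)
        assert isinstance(res, NoInstrument)
        assert "significant" in res.reason

    def test_retained_pairwise_r2_below_threshold(self, causal_locus):
        hq, hg = harmonize(causal_locus.mqtl.sset, causal_locus.gwas,
                           causal_locus.panel)
        instr = select_instrument(hq, hg, causal_locus.panel)
        off = instr.ld[np.triu_indices(instr.n_snps, 1)]
        assert np.all(off ** 2 < 0.05)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 1000))
    def test_greedy_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        m = 8
        A = rng.standard_normal((m, m))
        R = A @ A.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        panel = make_panel(R, 5000, rng)
        ids = [s[0] for s in panel.snp_index]
        z = rng.uniform(5.6, 40, m)
        exp = make_sumstats("m", ids, z * 0.01, [0.01] * m)
        out = make_sumstats("y", ids, rng.normal(0, .01, m), [0.01] * m)
        instr = select_instrument(exp, out, panel)
        # independent re-implementation of the greedy rule
        from methmr.sumstats import ld_matrix
        order = sorted(range(m), key=lambda i: (-z[i] ** 2, ids[i]))
        Rhat = ld_matrix(panel, [ids[i] for i in order])
        kept = []
        for i in range(m):
            if all(Rhat[i, j] ** 2 < 0.05 for j in kept):
                kept.append(i)
        expected = [ids[order[i]] for i in kept]
        got = instr.snps["snp_id"].tolist() if isinstance(instr, Instrument) else []
        assert got == expected


class TestGlsMr:
    def test_single_snp_hand_computation(self):
        instr = make_instrument([0.5], [0.05], [0.1], [0.02])
        res = gls_mr(instr)
        assert res.b_xy == pytest.approx(0.2, rel=1e-12)
        assert res.se_xy == pytest.approx(
            math.sqrt((0.02 ** 2 + 0.2 ** 2 * 0.05 ** 2) / 0.5 ** 2), rel=1e-12)
        assert res.se_xy == pytest.approx(0.0447, abs=2e-4)

    def test_duplicated_snps_shrink_se_by_sqrt_k(self):
        one = gls_mr(make_instrument([0.5], [0.05], [0.1], [0.02]))
        k = 4
        four = gls_mr(make_instrument([0.5] * k, [0.05] * k, [0.1] * k,
                                      [0.02] * k))
        assert four.b_xy == pytest.approx(one.b_xy, rel=1e-12)
        assert four.se_xy == pytest.approx(one.se_xy / math.sqrt(k), rel=1e-10)

    def test_identity_ld_equals_ivw_oracle(self):
        rng = np.random.default_rng(5)
        n = 12
        b_zx = rng.uniform(0.2, 0.8, n) * rng.choice([-1, 1], n)
        se_zx = rng.uniform(0.01, 0.05, n)
        b_zy = rng.normal(0.05, 0.03, n)
        se_zy = rng.uniform(0.005, 0.02, n)
        res = gls_mr(make_instrument(b_zx, se_zx, b_zy, se_zy))
        b_ivw, se_ivw = ivw_oracle(b_zx, se_zx, b_zy, se_zy)
        assert res.b_xy == pytest.approx(b_ivw, abs=1e-10)
        assert res.se_xy == pytest.approx(se_ivw, abs=1e-10)

    def test_full_ld_matches_statsmodels_gls(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        n = 8
        A = rng.standard_normal((n, n)) * 0.25
        R = A @ A.T + np.eye(n)
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        b_zx = rng.uniform(0.3, 0.9, n)
        se_zx = rng.uniform(0.01, 0.04, n)
        b_zy = rng.normal(0.04, 0.02, n)
        se_zy = rng.uniform(0.01, 0.03, n)
        instr = make_instrument(b_zx, se_zx, b_zy, se_zy, ld=R)
        res = gls_mr(instr)
        from methmr.mr import _ratio_cov
        b, V = _ratio_cov(instr)
        fit = sm.GLS(b, np.ones((n, 1)), sigma=V).fit()
        assert res.b_xy == pytest.approx(float(fit.params[0]), abs=1e-8)
        assert res.se_xy == pytest.approx(
            math.sqrt(float(fit.normalized_cov_params[0, 0])), abs=1e-8)

    @settings(max_examples=30, deadline=None)
    @given(st.floats(0.2, 5.0), st.booleans())
    def test_scale_equivariance(self, c, negate):
        if negate:
            c = -c
        b_zx = np.array([0.5, 0.4, -0.6])
        se_zx = np.array([0.02, 0.03, 0.02])
        b_zy = np.array([0.05, 0.03, -0.07])
        se_zy = np.array([0.01, 0.01, 0.02])
        r1 = gls_mr(make_instrument(b_zx, se_zx, b_zy, se_zy))
        r2 = gls_mr(make_instrument(c * b_zx, abs(c) * se_zx, b_zy, se_zy))
        assert r2.b_xy == pytest.approx(r1.b_xy / c, rel=1e-9)
        assert r2.p_xy == pytest.approx(r1.p_xy, rel=1e-6)


class TestRemovePleiotropic:
    def test_exact_shared_ratio_none_removed(self):
        instr = make_instrument([0.5, 0.4, 0.6], [0.02] * 3,
                                [0.1, 0.08, 0.12], [0.01] * 3)
        out, removed = remove_pleiotropic(instr)
        assert removed == []
        assert out.n_snps == 3

    def test_two_snps_skipped_with_flag(self):
        instr = make_instrument([0.5, 0.4], [0.02] * 2, [0.1, 0.2], [0.01] * 2)
        out, removed = remove_pleiotropic(instr)
        assert removed == []
        assert any("skipped" in f for f in out.flags)

    def test_planted_outlier_removed_over_reps(self):
        hits, total = 0, 25
        for seed in range(total):
            cfg = ScenarioConfig.preset("pleiotropy", seed=seed,
                                        n_exposure_cohort=4000,
                                        n_outcome_cohort=4000, n_panel=400,
                                        n_snps_per_locus=100,
                                        h2_y_direct=0.03)
            loc = simulate_locus(cfg, with_expression=False)
            hq, hg = harmonize(loc.mqtl.sset, loc.gwas, loc.panel)
            res = forward_mr(hq, hg, loc.panel)
            if isinstance(res, MRResult):
                hits += loc.truth.causal_snps[0] in \
                    [s for s, _ in res.removed_snps]
        assert hits / total > 0.7


class TestReverse:
    def test_role_swap_involution(self, causal_locus):
        hq, hg = harmonize(causal_locus.mqtl.sset, causal_locus.gwas,
                           causal_locus.panel)
        f = forward_mr(hq, hg, causal_locus.panel)
        r = reverse_mr(hg, hq, causal_locus.panel)  # swapped call
        assert isinstance(f, MRResult) and isinstance(r, MRResult)
        assert r.b_xy == pytest.approx(f.b_xy, rel=1e-12)
        assert r.se_xy == pytest.approx(f.se_xy, rel=1e-12)
        assert r.direction == "reverse" and f.direction == "forward"

    def test_reverse_scenario_detected(self):
        hits, total = 0, 15
        for seed in range(total):
            cfg = ScenarioConfig.preset("reverse", seed=seed,
                                        n_exposure_cohort=4000,
                                        n_outcome_cohort=4000, n_panel=400,
                                        n_snps_per_locus=100)
            loc = simulate_locus(cfg, with_expression=False)
            hq, hg = harmonize(loc.mqtl.sset, loc.gwas, loc.panel)
            rev = reverse_mr(hq, hg, loc.panel)
            hits += isinstance(rev, MRResult) and rev.p_xy < 0.05
        assert hits / total > 0.9


class TestBidirectionalFilter:
    def _res(self, direction, p, b=0.1):
        return MRResult("m", "y", direction, b, 0.01, p, 5)

    def test_retained(self):
        d = bidirectional_filter(self._res("forward", 1e-9),
                                 self._res("reverse", 0.4))
        assert d.retained and d.reason == "ok"

    def test_reverse_causation_excluded(self):
        d = bidirectional_filter(self._res("forward", 1e-9),
                                 self._res("reverse", 0.01))
        assert not d.retained and d.reason == "reverse causation"

    def test_below_forward_threshold(self):
        d = bidirectional_filter(self._res("forward", 1e-6),
                                 self._res("reverse", 0.4))
        assert not d.retained and d.reason == "below forward threshold"

    def test_no_reverse_instrument_passes_through(self):
        d = bidirectional_filter(self._res("forward", 1e-9),
                                 NoInstrument("y", "m", "nothing significant"))
        assert d.retained and "no reverse instrument" in d.reason
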