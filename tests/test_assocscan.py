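"""Scan oracle equivalence, FDR adjustment, PVE decomposition, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import growthgwas as gg
from growthgwas import assocscan as asc


@pytest.fixture(scope="module")
def scan_setup(filtered_panel):
    filt, imputed, zero_var, pcs = filtered_panel
    rng = np.random.default_rng(0)
    y = pd.Series(rng.normal(0, 1, filt.n_genotypes), index=filt.genotypes)
    return filt, imputed, zero_var, pcs, y


def _oracle_ols(y, cov, x):
    """Independent per-marker OLS t-test via normal equations."""
    X = np.column_stack([cov, x])
    n, p = X.shape
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma2 = resid @ resid / (n - p)
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * xtx_inv[-1, -1])
    from scipy import stats
    t = coef[-1] / se
    return coef[-1], 2 * stats.t.sf(abs(t), n - p)


class TestScan:
    def test_first_iteration_matches_ols_oracle(self, scan_setup):
        filt, imputed, zero_var, pcs, y = scan_setup
        rec = asc.scan_trait(y, filt, pcs, asc.ScanParams(max_loop=1))
        cov = np.column_stack([np.ones(filt.n_genotypes), pcs.scores[:, :4]])
        rng = np.random.default_rng(1)
        for j in rng.choice(np.flatnonzero(~zero_var), 40, replace=False):
            _, p_oracle = _oracle_ols(y.to_numpy(), cov, imputed[j])
            assert abs(np.log10(p_oracle) - np.log10(rec["p_value"].iloc[j])) < 1e-8

    def test_disabling_pseudo_qtn_machinery_reduces_to_single_marker_test(
            self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        rng = np.random.default_rng(2)
        j = int(rng.choice(np.flatnonzero(~zero_var)))
        x = imputed[j] - imputed[j].mean()
        y = pd.Series(0.5 * x + rng.normal(0, 1, filt.n_genotypes),
                      index=filt.genotypes)
        one_loop = asc.scan_trait(y, filt, pcs, asc.ScanParams(max_loop=1))
        full = asc.scan_trait(y, filt, pcs, asc.ScanParams(max_loop=1,
                                                           qtn_threshold=1e-300))
        pd.testing.assert_frame_equal(one_loop, full)

    def test_scan_is_deterministic(self, scan_setup):
        filt, _, _, pcs, y = scan_setup
        r1 = asc.scan_trait(y, filt, pcs, asc.ScanParams())
        r2 = asc.scan_trait(y, filt, pcs, asc.ScanParams())
        pd.testing.assert_frame_equal(r1, r2)

    def test_allele_coding_flip_flips_effect_and_keeps_p(self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        rng = np.random.default_rng(3)
        j = int(rng.choice(np.flatnonzero(~zero_var)))
        y = pd.Series(imputed[j] * 0.4 + rng.normal(0, 1, filt.n_genotypes),
                      index=filt.genotypes)
        rec = asc.scan_trait(y, filt, pcs, asc.ScanParams(max_loop=1))

        import dataclasses
        flipped = dataclasses.replace(filt, dosages=filt.dosages.copy())
        flipped.dosages[j] = 2.0 - flipped.dosages[j]
        rec_f = asc.scan_trait(y, flipped, pcs, asc.ScanParams(max_loop=1))
        assert rec_f["effect"].iloc[j] == pytest.approx(-rec["effect"].iloc[j])
        assert rec_f["p_value"].iloc[j] == pytest.approx(rec["p_value"].iloc[j])

    def test_zero_variance_marker_p_missing(self, scan_setup):
        filt, _, zero_var, pcs, y = scan_setup
        if not zero_var.any():
            import dataclasses
            filt = dataclasses.replace(filt, dosages=filt.dosages.copy())
            filt.dosages[0] = 1.0
            zero_var = gg.impute_for_scan(filt)[1]
        rec = asc.scan_trait(y, filt, pcs, asc.ScanParams(max_loop=1))
        assert rec["p_value"][zero_var].isna().all()

    def test_too_few_genotypes_aborts(self):
        markers = pd.DataFrame({"marker_id": ["m0"], "chromosome": "A01",
                                "position": [1], "marker_class": "SNP"})
        panel = gg.MarkerPanel(markers, np.array([[0.0, 1.0, 2.0]]),
                               ["a", "b", "c"])
        y = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        pcs = gg.PcScores(np.zeros((3, 4)), np.zeros(4))
        with pytest.raises(ValueError, match="covariates"):
            asc.scan_trait(y, panel, pcs, asc.ScanParams())

    def test_planted_qtl_found_with_pseudo_qtn_iterations(self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        rng = np.random.default_rng(4)
        eligible = np.flatnonzero((filt.markers["maf"] > 0.25).to_numpy() & ~zero_var)
        j = int(rng.choice(eligible))
        xc = imputed[j] - imputed[j].mean()
        b = np.sqrt(0.15 / 0.85 / xc.var())
        y = pd.Series(b * xc + rng.normal(0, 1, filt.n_genotypes),
                      index=filt.genotypes)
        rec = asc.adjust_fdr(asc.scan_trait(y, filt, pcs, asc.ScanParams()))
        top = int(rec["p_value"].idxmin())
        from growthgwas.ldcandidates import pairwise_r2
        assert top == j or pairwise_r2(imputed[top], imputed[j]) >= 0.6


class TestFdr:
    def test_hand_computed_example(self):
        rec = pd.DataFrame({"p_value": [0.001, 0.01, 0.02, 0.8]})
        adj = asc.adjust_fdr(rec)["p_value_fdr"].to_numpy()
        assert np.allclose(adj, [0.004, 0.02, 0.02666667, 0.8], atol=1e-8)

    def test_all_equal_p_stay_equal(self):
        rec = pd.DataFrame({"p_value": [0.3] * 7})
        adj = asc.adjust_fdr(rec)["p_value_fdr"]
        assert np.allclose(adj, 0.3)

    def test_matches_brute_force_step_up_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            p = rng.uniform(0, 1, 1000)
            adj = asc.adjust_fdr(pd.DataFrame({"p_value": p}))["p_value_fdr"].to_numpy()
            # independent step-up implementation
            m = len(p)
            order = np.argsort(p)
            stepped = p[order] * m / np.arange(1, m + 1)
            stepped = np.minimum.accumulate(stepped[::-1])[::-1]
            expected = np.empty(m)
            expected[order] = np.minimum(stepped, 1.0)
            assert np.allclose(adj, expected, atol=1e-12)

    def test_missing_p_excluded_from_m(self):
        rec = pd.DataFrame({"p_value": [0.01, np.nan, 0.04]})
        adj = asc.adjust_fdr(rec)["p_value_fdr"]
        assert np.isnan(adj.iloc[1])
        assert adj.iloc[0] == pytest.approx(0.02)  # m = 2, not 3

    def test_significance_boundary_uses_less_or_equal(self):
        rec = pd.DataFrame({"p_value": [0.05, 0.5]})
        out = asc.adjust_fdr(rec, level=0.1)
        # adjusted P exactly at the level counts as significant
        assert out["p_value_fdr"].iloc[0] == pytest.approx(0.1)
        assert bool(out["significant"].iloc[0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=2,
                    max_size=60))
    def test_adjustment_is_monotone_and_rank_preserving(self, pvals):
        rec = pd.DataFrame({"p_value": pvals})
        out = asc.adjust_fdr(rec)
        assert (out["p_value_fdr"] >= out["p_value"] - 1e-15).all()
        order = np.argsort(out["p_value"].to_numpy(), kind="mergesort")
        adj_sorted = out["p_value_fdr"].to_numpy()[order]
        assert (np.diff(adj_sorted) >= -1e-15).all()


class TestPve:
    def test_single_marker_pve_equals_regression_r2(self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        rng = np.random.default_rng(6)
        j = int(np.flatnonzero(~zero_var)[10])
        y = pd.Series(imputed[j] * 0.8 + rng.normal(0, 1, filt.n_genotypes),
                      index=filt.genotypes)
        sig = pd.DataFrame({"marker_id": [filt.markers["marker_id"].iloc[j]],
                            "p_value": [1e-9]})
        pve = asc.estimate_pve(y, sig, filt)
        r2 = np.corrcoef(imputed[j], y.to_numpy())[0, 1] ** 2
        assert pve["pve_pct"].iloc[0] == pytest.approx(100 * r2, abs=1e-6)

    def test_ld_pair_order_dependence_and_bounded_total(self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        # find a marker pair in strong LD
        ok = np.flatnonzero(~zero_var)
        pair = None
        for a in ok[:200]:
            for b in ok[ok > a][:50]:
                r = np.corrcoef(imputed[a], imputed[b])[0, 1] ** 2
                if 0.6 < r < 0.999:
                    pair = (int(a), int(b))
                    break
            if pair:
                break
        assert pair is not None
        a, b = pair
        rng = np.random.default_rng(7)
        y = pd.Series(imputed[a] * 0.8 + rng.normal(0, 0.5, filt.n_genotypes),
                      index=filt.genotypes)
        ids = filt.markers["marker_id"]
        fwd = asc.estimate_pve(y, pd.DataFrame(
            {"marker_id": [ids.iloc[a], ids.iloc[b]], "p_value": [1e-9, 1e-4]}), filt)
        rev = asc.estimate_pve(y, pd.DataFrame(
            {"marker_id": [ids.iloc[a], ids.iloc[b]], "p_value": [1e-4, 1e-9]}), filt)
        assert fwd["pve_pct"].sum() <= 100.0 + 1e-9
        assert rev["pve_pct"].sum() <= 100.0 + 1e-9
        # entry order changes the split between the two correlated markers
        fwd_a = fwd.set_index("marker_id")["pve_pct"][ids.iloc[a]]
        rev_a = rev.set_index("marker_id")["pve_pct"][ids.iloc[a]]
        assert abs(fwd_a - rev_a) > 1e-6

    def test_uncorrelated_marker_gets_near_zero_pve(self, scan_setup):
        filt, imputed, zero_var, pcs, _ = scan_setup
        rng = np.random.default_rng(8)
        j, k = np.flatnonzero(~zero_var)[[5, 100]]
        y = pd.Series(rng.normal(0, 1, filt.n_genotypes), index=filt.genotypes)
        ids = filt.markers["marker_id"]
        pve = asc.estimate_pve(y, pd.DataFrame(
            {"marker_id": [ids.iloc[j], ids.iloc[k]], "p_value": [1e-6, 1e-5]}),
            filt)
        assert (pve["pve_pct"] < 5.0).all()
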