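"""Marker encoding, filtering rules, imputation, PCA and group frequencies."""

import numpy as np
import pandas as pd
import pytest

import growthgwas as gg
from growthgwas import markerqc


def _snp_table(states_by_marker, positions=None, chrom="A01"):
    rows = []
    for i, (mid, states) in enumerate(states_by_marker.items()):
        rows.append({"marker_id": mid, "chromosome": chrom,
                     "position": (positions or {}).get(mid, 100 * (i + 1)),
                     **{f"g{j}": s for j, s in enumerate(states)}})
    return pd.DataFrame(rows)


class TestEncode:
    def test_snp_coding_and_heterozygous(self):
        snp = _snp_table({"m1": ["AA", "AB", "BB", np.nan]})
        panel = gg.encode_markers(snp)
        assert list(panel.dosages[0][:3]) == [0.0, 1.0, 2.0]
        assert np.isnan(panel.dosages[0][3])

    def test_reciprocal_cnv_event_becomes_missing(self):
        snp = _snp_table({"m1": ["AA", "AB", "BB", "AA"]})
        cnv = _snp_table({"d1": ["normal", "deletion", "duplication", np.nan]})
        cnv["marker_class"] = "DEL"
        panel = gg.encode_markers(snp, cnv)
        row = panel.dosages[panel.markers["marker_id"] == "d1"][0]
        assert row[0] == 0.0 and row[1] == 2.0
        assert np.isnan(row[2])  # duplication at a deletion marker
        assert np.isnan(row[3])

    def test_cnv_position_shifted_off_snp_position(self):
        snp = _snp_table({"m1": ["AA", "BB", "AA", "BB"]}, positions={"m1": 500})
        cnv = _snp_table({"d1": ["normal", "deletion", "normal", "deletion"]},
                         positions={"d1": 500})
        cnv["marker_class"] = "DEL"
        panel = gg.encode_markers(snp, cnv)
        pos = panel.markers.set_index("marker_id")["position"]
        assert pos["m1"] == 500 and pos["d1"] == 501

    def test_cnv_shift_falls_back_to_minus_one_on_collision(self):
        snp = _snp_table({"m1": ["AA", "BB"], "m2": ["AA", "BB"]},
                         positions={"m1": 500, "m2": 501})
        cnv = _snp_table({"d1": ["normal", "deletion"]}, positions={"d1": 500})
        cnv["marker_class"] = "DEL"
        panel = gg.encode_markers(snp, cnv)
        assert panel.markers.set_index("marker_id")["position"]["d1"] == 499

    def test_unknown_states_rejected(self):
        with pytest.raises(ValueError, match="unknown SNP call"):
            gg.encode_markers(_snp_table({"m1": ["AA", "XY"]}))
        cnv = _snp_table({"d1": ["normal", "weird"]})
        cnv["marker_class"] = "DEL"
        with pytest.raises(ValueError, match="unknown CNV call"):
            gg.encode_markers(_snp_table({"m1": ["AA", "BB"]}), cnv)


class TestFilter:
    def _panel_from_dosages(self, dosages):
        m = len(dosages)
        markers = pd.DataFrame({
            "marker_id": [f"m{i}" for i in range(m)], "chromosome": "A01",
            "position": np.arange(1, m + 1) * 100, "marker_class": "SNP"})
        return markerqc.MarkerPanel(markers, np.asarray(dosages, dtype=float),
                                    [f"g{j}" for j in range(len(dosages[0]))]
                                    ).with_stats()

    def test_maf_boundary_smaller_than_is_strict(self):
        # 500 genotypes: 9 alt alleles -> MAF 0.009 (removed); 10 -> 0.010 (kept)
        base = np.zeros(500)
        removed, kept = base.copy(), base.copy()
        removed[:9] = 1.0
        kept[:10] = 1.0
        panel = self._panel_from_dosages([removed, kept])
        filt, log = gg.filter_markers(panel)
        assert list(filt.markers["marker_id"]) == ["m1"]
        assert log.iloc[0]["rules"] == "maf"

    def test_missing_boundary_exactly_10pct_kept(self):
        a = np.tile([0.0, 2.0], 50)
        at_boundary, above = a.copy(), a.copy()
        at_boundary[:10] = np.nan  # 10% missing: kept
        above[:11] = np.nan  # 11%: removed
        panel = self._panel_from_dosages([at_boundary, above])
        filt, _ = gg.filter_markers(panel)
        assert list(filt.markers["marker_id"]) == ["m0"]

    def test_het_boundary_exactly_25pct_kept(self):
        a = np.tile([0.0, 2.0], 50)
        at_boundary, above = a.copy(), a.copy()
        at_boundary[:25] = 1.0
        above[:26] = 1.0
        panel = self._panel_from_dosages([at_boundary, above])
        filt, _ = gg.filter_markers(panel)
        assert list(filt.markers["marker_id"]) == ["m0"]

    def test_filter_matches_brute_force_oracle_and_is_idempotent(self):
        rng = np.random.default_rng(42)
        n = 80
        dosages = []
        for _ in range(100):
            p = rng.uniform(0.0, 0.5)
            d = rng.choice([0.0, 1.0, 2.0], size=n,
                           p=[(1 - p) ** 2, 2 * p * (1 - p), p**2])
            d[rng.random(n) < rng.uniform(0, 0.2)] = np.nan
            dosages.append(d)
        panel = self._panel_from_dosages(dosages)
        filt, log = gg.filter_markers(panel)

        survivors = []
        for i, d in enumerate(dosages):  # independent re-check of the rules
            obs = d[~np.isnan(d)]
            freq = obs.sum() / (2 * len(obs)) if len(obs) else np.nan
            maf = min(freq, 1 - freq) if len(obs) else np.nan
            miss = np.isnan(d).mean()
            het = (obs == 1).mean() if len(obs) else 0.0
            if not (np.isnan(maf) or maf < 0.01 or miss > 0.10 or het > 0.25):
                survivors.append(f"m{i}")
        assert list(filt.markers["marker_id"]) == survivors
        assert len(filt.markers) + len(log) == 100

        again, log2 = gg.filter_markers(filt)
        assert len(log2) == 0 and again.n_markers == filt.n_markers

    def test_everything_removed_raises(self):
        panel = self._panel_from_dosages([np.zeros(50)])
        with pytest.raises(ValueError, match="degenerate"):
            gg.filter_markers(panel)


class TestImpute:
    def test_missing_replaced_by_heterozygous_and_counts_match(self):
        rng = np.random.default_rng(0)
        d = rng.choice([0.0, 2.0], size=(30, 40))
        mask = rng.random(d.shape) < 0.15
        d[mask] = np.nan
        markers = pd.DataFrame({"marker_id": [f"m{i}" for i in range(30)],
                                "chromosome": "A01",
                                "position": np.arange(30) * 10 + 1,
                                "marker_class": "SNP"})
        panel = markerqc.MarkerPanel(markers, d, [f"g{j}" for j in range(40)])
        imputed, zero_var = gg.impute_for_scan(panel)
        assert (imputed[mask] == 1.0).all()
        assert np.array_equal(imputed[~mask], d[~mask])

    def test_all_missing_marker_becomes_constant_and_flagged(self):
        d = np.array([[np.nan] * 6, [0, 2, 0, 2, 0, 2]], dtype=float)
        markers = pd.DataFrame({"marker_id": ["m0", "m1"], "chromosome": "A01",
                                "position": [1, 2], "marker_class": "SNP"})
        panel = markerqc.MarkerPanel(markers, d, [f"g{j}" for j in range(6)])
        imputed, zero_var = gg.impute_for_scan(panel)
        assert (imputed[0] == 1.0).all()
        assert list(zero_var) == [True, False]

    def test_no_missing_is_identity(self):
        d = np.array([[0.0, 1.0, 2.0]])
        markers = pd.DataFrame({"marker_id": ["m0"], "chromosome": "A01",
                                "position": [1], "marker_class": "SNP"})
        panel = markerqc.MarkerPanel(markers, d, ["a", "b", "c"])
        imputed, _ = gg.impute_for_scan(panel)
        assert np.array_equal(imputed, d)


class TestPca:
    def test_scores_match_eigendecomposition_oracle_up_to_sign(self):
        X = np.array([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0]])  # 2 markers x 3 genotypes
        pcs = gg.compute_pcs(X, k=2)
        Xc = X.T - X.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc @ Xc.T)
        order = np.argsort(evals)[::-1]
        for j in range(pcs.k):
            oracle = evecs[:, order[j]] * np.sqrt(max(evals[order[j]], 0))
            assert (np.allclose(pcs.scores[:, j], oracle, atol=1e-8)
                    or np.allclose(pcs.scores[:, j], -oracle, atol=1e-8))

    def test_identical_genotypes_degenerate(self):
        X = np.ones((5, 4))
        with pytest.warns(UserWarning, match="zero total variance"):
            pcs = gg.compute_pcs(X, k=2)
        assert pcs.degenerate

    def test_scores_invariant_to_marker_order(self, filtered_panel):
        filt, imputed, _, pcs = filtered_panel
        rng = np.random.default_rng(5)
        perm = rng.permutation(imputed.shape[0])
        pcs2 = gg.compute_pcs(imputed[perm], k=4)
        for j in range(4):
            assert (np.allclose(pcs.scores[:, j], pcs2.scores[:, j], atol=1e-6)
                    or np.allclose(pcs.scores[:, j], -pcs2.scores[:, j], atol=1e-6))

    def test_pools_separate_better_than_shuffled_labels(self, small_panel,
                                                        filtered_panel):
        from sklearn.metrics import silhouette_score

        panel, truth, _ = small_panel
        _, _, _, pcs = filtered_panel
        real = silhouette_score(pcs.scores[:, :3], truth.pools)
        rng = np.random.default_rng(0)
        shuffled = [silhouette_score(pcs.scores[:, :3], rng.permutation(truth.pools))
                    for _ in range(20)]
        assert real > 0
        assert real > np.max(shuffled)


class TestGroupFrequencies:
    def _panel(self, dosages):
        m = len(dosages)
        markers = pd.DataFrame({"marker_id": [f"m{i}" for i in range(m)],
                                "chromosome": "A01",
                                "position": np.arange(m) * 10 + 1,
                                "marker_class": "SNP"})
        return markerqc.MarkerPanel(markers, np.asarray(dosages, float),
                                    [f"g{j}" for j in range(len(dosages[0]))])

    def test_fixed_balanced_private_and_missing_groups(self):
        dosages = [
            [2, 2, 2, 2, 0, 0, 0, 0],   # fixed for B in group x
            [0, 2, 0, 2, 0, 0, 2, 2],   # balanced 0/2 in both groups
            [2, 2, 0, 0, 0, 0, 0, 0],   # allele private to group x
            [np.nan, np.nan, np.nan, np.nan, 0, 0, 0, 2],  # no calls in x
        ]
        groups = ["x", "x", "x", "x", "y", "y", "y", "y"]
        freqs = gg.allele_freq_by_group(self._panel(dosages), groups)
        assert freqs.loc[0, "x"] == 1.0 and freqs.loc[0, "y"] == 0.0
        assert freqs.loc[1, "x"] == 0.5 and freqs.loc[1, "y"] == 0.5
        assert freqs.loc[2, "y"] == 0.0 and freqs.loc[2, "x"] > 0
        assert np.isnan(freqs.loc[3, "x"]) and freqs.loc[3, "y"] == 0.25


def test_panel_tsv_round_trip(tmp_path, small_panel):
    panel, _, _ = small_panel
    g, m = tmp_path / "g.tsv", tmp_path / "m.tsv"
    markerqc.write_panel_tsv(panel, g, m)
    back = markerqc.read_panel_tsv(g, m)
    assert back.genotypes == panel.genotypes
    assert np.array_equal(back.dosages, panel.dosages, equal_nan=True)
    assert back.markers["marker_id"].equals(panel.markers["marker_id"])
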