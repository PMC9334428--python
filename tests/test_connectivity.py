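"""Fisher-Z connectivity, group tests, hemispheric scopes, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from iccsync import connectivity


def _tcs_from(pairs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    return {k: np.asarray(v, dtype=float) for k, v in pairs.items()}


class TestPairwiseConnectivity:
    def test_known_correlation_recovered(self):
        rng = np.random.default_rng(0)
        n, rho = 240, 0.6
        base = rng.normal(size=(1, n))
        other = rho * base + np.sqrt(1 - rho**2) * rng.normal(size=(1, n))
        table = connectivity.pairwise_connectivity(_tcs_from({"a": base, "b": other}))
        r = table["r"].iloc[0]
        assert r == pytest.approx(rho, abs=0.12)
        assert table["z"].iloc[0] == pytest.approx(np.arctanh(r))
        assert table["z_std"].iloc[0] == pytest.approx(np.arctanh(r) * np.sqrt(240))

    def test_orthogonal_sinusoids_near_zero(self):
        t = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        table = connectivity.pairwise_connectivity(
            _tcs_from({"a": [np.sin(4 * t)], "b": [np.cos(4 * t)]})
        )
        assert abs(table["z_std"].iloc[0]) < 1e-8

    def test_identical_series_skipped(self):
        x = np.random.default_rng(1).normal(size=(1, 50))
        table = connectivity.pairwise_connectivity(_tcs_from({"a": x, "b": x}))
        assert table.empty

    def test_window_scaling_of_z_std(self):
        # halving the window at fixed r halves z_std by sqrt(2)
        t = np.arange(240.0)
        x = np.sin(2 * np.pi * t / 60)
        y = np.sin(2 * np.pi * t / 60 + 0.4)
        tcs = _tcs_from({"a": [x], "b": [y]})
        full = connectivity.pairwise_connectivity(tcs)
        half = connectivity.pairwise_connectivity(tcs, window=(0, 120))
        r_f, r_h = full["r"].iloc[0], half["r"].iloc[0]
        assert r_f == pytest.approx(r_h, abs=1e-6)  # same phase offset
        assert full["z_std"].iloc[0] == pytest.approx(
            half["z_std"].iloc[0] * np.sqrt(2), rel=1e-6
        )


class TestGroupConnectivityTest:
    def test_zero_values_give_t_zero_p_one(self):
        table = pd.DataFrame(
            {"subject": range(5), "roi_a": "a", "roi_b": "b",
             "r": 0.0, "z": 0.0, "z_std": 0.0, "n_window": 240}
        )
        res = connectivity.group_connectivity_test(table)
        assert res["t"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0
        assert not res["fdr_reject"].iloc[0]

    def test_hand_computed_t(self):
        z = np.array([0.1, 0.2, 0.3, 0.2, 0.2])
        table = pd.DataFrame(
            {"subject": range(5), "roi_a": "a", "roi_b": "b",
             "r": np.tanh(z), "z": z, "z_std": z * np.sqrt(240), "n_window": 240}
        )
        res = connectivity.group_connectivity_test(table)
        expected_t = z.mean() / (z.std(ddof=1) / np.sqrt(5))
        assert res["t"].iloc[0] == pytest.approx(expected_t)
        assert res["p"].iloc[0] == pytest.approx(
            2 * stats.t.sf(expected_t, 4)
        )

    def test_power_at_planted_effect(self):
        # mean z 0.3, sd 0.1, N = 25: essentially always rejected
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            z = rng.normal(0.3, 0.1, 25)
            table = pd.DataFrame(
                {"subject": range(25), "roi_a": "a", "roi_b": "b",
                 "r": np.tanh(z), "z": z, "z_std": z * np.sqrt(240),
                 "n_window": 240}
            )
            res = connectivity.group_connectivity_test(table, alpha=0.05)
            hits += bool(res["fdr_reject"].iloc[0])
        assert hits / 40 >= 0.95


class TestHemisphericSummaries:
    def _table(self, M=2):
        rng = np.random.default_rng(3)
        rows = []
        names = ["L1", "L2", "R1", "R2"]
        from itertools import combinations

        for a, b in combinations(names, 2):
            for s in range(M):
                z = rng.normal()
                rows.append({"subject": s, "roi_a": a, "roi_b": b,
                             "r": np.tanh(z), "z": z, "z_std": z, "n_window": 240})
        return pd.DataFrame(rows), {n: n[0] for n in names}

    def test_scope_pair_counts(self):
        table, hemi = self._table()
        t = table.copy()
        # 2L+2R entries: 1 left pair, 1 right pair, 4 inter pairs
        out = connectivity.hemispheric_summaries(table, hemi)
        sub0 = t[t.subject == 0]
        left = sub0[(sub0.roi_a == "L1") & (sub0.roi_b == "L2")]["z_std"].mean()
        assert out.loc[0, "left"] == pytest.approx(left)
        inter_pairs = sub0[
            sub0.apply(lambda r: {r.roi_a[0], r.roi_b[0]} == {"L", "R"}, axis=1)
        ]
        assert len(inter_pairs) == 4
        assert out.loc[0, "inter"] == pytest.approx(inter_pairs["z_std"].mean())

    def test_constant_z_gives_equal_scopes(self):
        table, hemi = self._table()
        table["z_std"] = 0.7
        out = connectivity.hemispheric_summaries(table, hemi)
        assert np.allclose(out.to_numpy(), 0.7)

    def test_planted_left_asymmetry_detected(self):
        table, hemi = self._table(M=20)
        boost = (table.roi_a.str[0] == "L") & (table.roi_b.str[0] == "L")
        table.loc[boost, "z_std"] += 2.0
        out = connectivity.hemispheric_summaries(table, hemi)
        assert out["left"].mean() > out["right"].mean()


class TestPartialCorrelation:
    def test_no_covariates_is_plain_pearson(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        r, p = connectivity.partial_correlation(y, x)
        rr, pp = stats.pearsonr(y, x)
        assert r == pytest.approx(rr)
        assert p == pytest.approx(pp, rel=1e-6)

    def test_residualization_oracle(self):
        # y = x + c exactly: controlling c leaves the pure x-residual link
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        c = rng.normal(size=60)
        y = x + c
        r, _ = connectivity.partial_correlation(y, x, c)
        # brute-force two-stage regression
        Z = np.column_stack([np.ones(60), c])
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        assert r == pytest.approx(np.corrcoef(ry, rx)[0, 1], rel=1e-12)
        assert r > 0.9

    def test_agrees_with_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        N = 30
        C = rng.normal(size=(N, 3))
        x = rng.normal(size=N) + C @ [0.3, -0.2, 0.1]
        y = 0.5 * x + rng.normal(size=N) + C @ [0.2, 0.1, -0.4]
        r, p = connectivity.partial_correlation(y, x, C)
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": C[:, 0], "c2": C[:, 1], "c3": C[:, 2]}
        )
        out = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        assert r == pytest.approx(out["r"].iloc[0], abs=1e-10)
        assert p == pytest.approx(out["p_val"].iloc[0], rel=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        N = 30
        C = rng.normal(size=(N, 2))
        x, y = rng.normal(size=N), rng.normal(size=N)
        r1, p1 = connectivity.partial_correlation(y, x, C)
        r2, p2 = connectivity.partial_correlation(
            3.0 * y - 2.0, -0.5 * x + 1.0, C * 4.0 + 7.0
        )
        assert abs(r2) == pytest.approx(abs(r1), rel=1e-10)
        assert p2 == pytest.approx(p1, rel=1e-8)

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(8)
        c = rng.normal(size=20)
        C = np.column_stack([c, 2 * c])
        with pytest.raises(ValueError):
            connectivity.partial_correlation(
                rng.normal(size=20), rng.normal(size=20), C
            )
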