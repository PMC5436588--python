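import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestscape.change_analysis import (
    INDICATORS,
    change_rate,
    indicator_power,
    nfc_vs_rate_slope,
    simple_regression,
    variation_partition,
)


def _table_from_values(values: dict[str, dict[str, np.ndarray]]) -> pd.DataFrame:
    """Build a (cell_id, period) table from {column: {period: vector}}."""
    periods = list(next(iter(values.values())))
    n = len(next(iter(next(iter(values.values())).values())))
    idx = pd.MultiIndex.from_product(
        [range(n), periods], names=["cell_id", "period"]
    )
    df = pd.DataFrame(index=idx)
    for col, per_period in values.items():
        stacked = np.column_stack([per_period[p] for p in periods]).ravel()
        df[col] = stacked
    return df


class TestChangeRate:
    def test_per_decade_arithmetic(self):
        nfc = {"p1": np.array([0.5]), "p2": np.array([0.3])}
        table = _table_from_values({"NFC": nfc})
        ch = change_rate(table, "p1", "p2", years=60)
        assert ch["d_nfc"].iloc[0] == pytest.approx(-0.2)
        assert ch["rate"].iloc[0] == pytest.approx(-0.2 / 6.0)

    def test_no_change_is_zero(self):
        nfc = {"p1": np.array([0.4, 0.7]), "p2": np.array([0.4, 0.7])}
        ch = change_rate(_table_from_values({"NFC": nfc}), "p1", "p2")
        assert (ch["rate"] == 0).all()

    def test_modes_and_relative_drops_zero_cells(self):
        nfc = {"p1": np.array([0.5, 0.0]), "p2": np.array([0.25, 0.1])}
        table = _table_from_values({"NFC": nfc})
        raw = change_rate(table, "p1", "p2", mode="raw")
        assert raw["rate"].iloc[0] == pytest.approx(-0.25)
        rel = change_rate(table, "p1", "p2", mode="relative")
        assert list(rel.index) == [0]
        assert rel["rate"].iloc[0] == pytest.approx(-0.5)

    def test_missing_period_named_in_error(self):
        table = _table_from_values({"NFC": {"p1": np.array([0.5])}})
        with pytest.raises(ValueError, match="p9"):
            change_rate(table, "p1", "p9")

    def test_matches_spreadsheet_recomputation(self, small_dataset):
        table = small_dataset.cell_table
        ch = change_rate(table, "p1", "p4", years=60)
        a = table.xs("p1", level="period")
        b = table.xs("p4", level="period")
        np.testing.assert_allclose(ch["d_nfc"], (b["NFC"] - a["NFC"]).loc[ch.index])
        np.testing.assert_allclose(
            ch["d_SRL_main"], (b["SRL_main"] - a["SRL_main"]).loc[ch.index]
        )
        np.testing.assert_allclose(ch["rate"], ch["d_nfc"] / 6.0)


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        s = simple_regression(x, 2 * x)
        assert s.slope == pytest.approx(2.0)
        assert s.adj_r2_pct == pytest.approx(100.0)
        assert s.p_value == 0.0

    def test_zero_sample_covariance(self):
        x = np.array([-1.0, 0.0, 1.0, 0.0])
        y = np.array([0.0, 1.0, 0.0, -1.0])  # orthogonal to x
        s = simple_regression(x, y)
        assert s.slope == pytest.approx(0.0, abs=1e-12)
        assert s.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_regression(np.ones(5), np.arange(5.0))

    def test_matches_statsmodels_oracle(self):
        """Slope/intercept/adjusted R²/F/p agree with statsmodels to 1e-10."""
        import statsmodels.api as sm

        rng = np.random.default_rng(17)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            s = simple_regression(x, y)
            ols = sm.OLS(y, sm.add_constant(x)).fit()
            assert s.intercept == pytest.approx(ols.params[0], abs=1e-10)
            assert s.slope == pytest.approx(ols.params[1], abs=1e-10)
            assert s.adj_r2_pct / 100 == pytest.approx(ols.rsquared_adj, abs=1e-10)
            assert s.f_stat == pytest.approx(ols.fvalue, rel=1e-10)
            assert s.p_value == pytest.approx(ols.f_pvalue, abs=1e-12)


def _changes_frame(rng, n=400, driver="SRL_main", noise=0.05):
    """Synthetic change table: the rate responds to one indicator only."""
    df = pd.DataFrame({f"d_{c}": rng.normal(size=n) for c in INDICATORS})
    df["rate"] = -0.5 * df[f"d_{driver}"] + noise * rng.normal(size=n)
    df["nfc_t1"] = rng.uniform(0, 1, n)
    df["nfc_t2"] = df["nfc_t1"] + df["rate"]
    df["d_nfc"] = df["rate"]
    return df


class TestIndicatorPower:
    def test_driving_indicator_ranks_first(self):
        rng = np.random.default_rng(23)
        power = indicator_power(_changes_frame(rng))
        assert power["adj_r2_pct"].idxmax() == "SRL_main"

    def test_pure_noise_indicator_near_zero(self):
        rng = np.random.default_rng(29)
        df = _changes_frame(rng, n=1_000)
        power = indicator_power(df)
        for ind in INDICATORS:
            if ind != "SRL_main":
                assert abs(power.loc[ind, "adj_r2_pct"]) < 2.0

    def test_duplicated_indicator_identical_rows(self):
        rng = np.random.default_rng(31)
        df = _changes_frame(rng)
        df["d_SRL_secondary"] = df["d_SRL_main"]
        power = indicator_power(df)
        a = power.loc["SRL_main", ["slope", "adj_r2_pct", "p_value"]]
        b = power.loc["SRL_secondary", ["slope", "adj_r2_pct", "p_value"]]
        np.testing.assert_allclose(a.to_numpy(float), b.to_numpy(float))

    def test_constant_indicator_skipped_with_warning(self):
        rng = np.random.default_rng(37)
        df = _changes_frame(rng)
        df["d_MND_secondary"] = 0.0
        with pytest.warns(UserWarning, match="MND_secondary"):
            power = indicator_power(df)
        assert "MND_secondary" not in power.index


class TestVariationPartition:
    def test_identity_holds_exactly(self):
        rng = np.random.default_rng(41)
        part = variation_partition(_changes_frame(rng))
        assert part.unique_main + part.unique_secondary + part.shared == pytest.approx(
            part.adj_r2_combined, abs=1e-12
        )

    def test_noise_secondary_has_no_unique_share(self):
        rng = np.random.default_rng(43)
        part = variation_partition(_changes_frame(rng, n=1_000, noise=0.02))
        assert part.adj_r2_main > 90.0
        assert abs(part.unique_secondary) < 2.0

    def test_identical_groups_share_everything(self):
        rng = np.random.default_rng(47)
        df = _changes_frame(rng)
        for m in ("SRL", "DNR", "NON", "MND"):
            df[f"d_{m}_secondary"] = df[f"d_{m}_main"]
        with pytest.warns(UserWarning, match="collinear"):
            part = variation_partition(df)
        assert part.shared == pytest.approx(part.adj_r2_combined, abs=1e-6)
        assert abs(part.unique_main) < 1e-6 and abs(part.unique_secondary) < 1e-6

    def test_frozen_group_explains_nothing(self):
        rng = np.random.default_rng(53)
        df = _changes_frame(rng)
        for m in ("SRL", "DNR", "NON", "MND"):
            df[f"d_{m}_secondary"] = 0.0
        with pytest.warns(UserWarning, match="constant"):
            part = variation_partition(df)
        assert part.adj_r2_secondary == 0.0
        assert part.p_secondary == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        part = variation_partition(_changes_frame(rng, n=60, noise=1.0))
        total = part.unique_main + part.unique_secondary + part.shared
        assert total == pytest.approx(part.adj_r2_combined, abs=1e-9)


class TestNfcVsRate:
    def test_independent_rate_gives_null_slope(self):
        rng = np.random.default_rng(59)
        n = 2_000
        nfc = {"p1": rng.uniform(0.2, 0.8, n)}
        nfc["p2"] = nfc["p1"] + rng.normal(0, 0.05, n)
        table = _table_from_values({"NFC": nfc})
        s = nfc_vs_rate_slope(table, "p1", "p2")
        # regression-attenuation from shared noise is the only signal
        assert s.p_value > 1e-4 or abs(s.slope) < 0.05

    def test_designed_coupling_gives_positive_slope(self):
        """Stronger loss in low-cover cells yields slope > 0, p < 0.01."""
        rng = np.random.default_rng(61)
        n = 1_000
        start = rng.uniform(0.1, 0.9, n)
        loss = 0.3 * (1.0 - start) + 0.02 * rng.normal(size=n)
        nfc = {"p1": start, "p2": np.clip(start - loss, 0, 1)}
        s = nfc_vs_rate_slope(_table_from_values({"NFC": nfc}), "p1", "p2")
        assert s.slope > 0
        assert s.p_value < 0.01

    def test_exact_linear_coupling_full_r2(self):
        start = np.linspace(0.1, 0.9, 50)
        nfc = {"p1": start, "p2": start - 0.2 * (1 - start)}
        s = nfc_vs_rate_slope(_table_from_values({"NFC": nfc}), "p1", "p2")
        assert s.adj_r2_pct == pytest.approx(100.0)
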