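"""GAMM engine: cyclic bases, model selection, prediction, inference."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from finsong.trend_models import (cyclic_spline_basis, fit_ini_model,
                                  fit_spectral_model, predict_monthly,
                                  select_model)


def seasonal_frame(seed=0, years=(2, 3, 4), amp=2.5, constant_years=(),
                   songs_per_cell=2, inis_per_song=25, shape=60.0,
                   singer_sd=0.04):
    """Gamma INIs with a cosine seasonal mean (or flat for constant years).

    Each song gets its own singer with a log-normal singer-level offset,
    matching the one-singer-per-day design the random intercept models.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sy in years:
        for m in range(1, 13):
            for s in range(songs_per_cell):
                if sy in constant_years:
                    mean = 15.0
                else:
                    mean = 12.5 + amp * np.cos(2 * np.pi * (m - 3.5) / 12)
                mean = mean * np.exp(rng.normal(0.0, singer_sd))
                vals = rng.gamma(shape, mean / shape, size=inis_per_song)
                rows += [dict(ini=v, month=m, song_year=sy,
                              singer=f"{sy}-{m:02d}-{s}") for v in vals]
    return pd.DataFrame(rows)


class TestCyclicBasis:
    def test_periodicity_of_basis_values(self):
        x = np.linspace(0.0, 12.0, 97)
        B1, _ = cyclic_spline_basis(x, k=12, period=12)
        B2, _ = cyclic_spline_basis(x + 12.0, k=12, period=12)
        assert np.allclose(B1, B2, atol=1e-12)

    def test_partition_of_unity(self):
        x = np.linspace(0.0, 12.0, 50)
        B, _ = cyclic_spline_basis(x, k=12, period=12)
        assert np.allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_penalty_annihilates_constants(self):
        _, S = cyclic_spline_basis(np.arange(12.0), k=12, period=12)
        assert np.allclose(S @ np.ones(12), 0.0, atol=1e-12)


class TestFitIniModel:
    def test_intercept_only_data_predicts_grand_mean(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame([
            dict(ini=v, month=m, song_year=sy, singer=f"{sy}-{m}")
            for sy in (2, 3, 4) for m in range(1, 13)
            for v in rng.gamma(80, 12.0 / 80, size=20)])
        fit = fit_ini_model(df, "m1")
        pred = predict_monthly(fit, 3)["predicted"]
        gm = df["ini"].mean()
        assert np.allclose(pred, gm, rtol=0.02)
        # the month smooth should be shrunk toward nothing
        assert fit.edf_by_term["s(Month)"] < 3.0

    def test_non_positive_ini_rejected(self):
        df = seasonal_frame(seed=1)
        df.loc[0, "ini"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_ini_model(df, "m1")

    def test_single_month_design_rejected(self):
        df = seasonal_frame(seed=1)
        with pytest.raises(ValueError, match="one month"):
            fit_ini_model(df[df["month"] == 3], "m1")

    def test_row_order_invariance(self):
        df = seasonal_frame(seed=3, years=(2, 3), songs_per_cell=1,
                            inis_per_song=15)
        f1 = fit_ini_model(df, "m2")
        f2 = fit_ini_model(df.sample(frac=1, random_state=9), "m2")
        assert np.allclose(f1.beta, f2.beta, atol=1e-6)
        assert f1.aic == pytest.approx(f2.aic, abs=1e-4)


class TestSelectModel:
    def test_minimum_aic_wins(self):
        df = seasonal_frame(seed=4, years=(2, 3), songs_per_cell=1,
                            inis_per_song=12)
        f1 = fit_ini_model(df, "m1")
        f2 = fit_ini_model(df, "m2")
        best = select_model([f1, f2])
        assert best.aic == min(f1.aic, f2.aic)

    def test_single_fit_returned_unchanged(self):
        df = seasonal_frame(seed=4, years=(2, 3), songs_per_cell=1,
                            inis_per_song=12)
        f1 = fit_ini_model(df, "m1")
        assert select_model([f1]) is f1

    def test_anomalous_year_coefficient_significant_under_m2(self):
        # one flat-INI year among seasonal years: M2 wins and that year's
        # categorical coefficient is clearly nonzero
        df = seasonal_frame(seed=42, years=(2, 3, 4), constant_years=(4,),
                            songs_per_cell=3, inis_per_song=12,
                            singer_sd=0.02)
        f2 = fit_ini_model(df, "m2")
        f1 = fit_ini_model(df, "m1")
        assert select_model([f1, f2]).form == "m2"
        # SongYear levels (2, 3, 4) with 2 as reference: row [1] is year 4
        row = f2.param_table.set_index("term").loc["SongYear[1]"]
        assert row["p"] < 0.01
        assert row["estimate"] > 0  # the anomalous year sings longer INIs

    def test_fits_on_different_data_rejected(self):
        a = seasonal_frame(seed=5, years=(2, 3), songs_per_cell=1,
                           inis_per_song=10)
        b = seasonal_frame(seed=6, years=(2, 3), songs_per_cell=1,
                           inis_per_song=10)
        with pytest.raises(ValueError, match="different data"):
            select_model([fit_ini_model(a, "m1"), fit_ini_model(b, "m1")])


@pytest.fixture(scope="module")
def seasonal_fit():
    return fit_ini_model(seasonal_frame(seed=7), "m1")


class TestPrediction:

    def test_cyclic_wrap_month_13_equals_month_1(self, seasonal_fit):
        p = predict_monthly(seasonal_fit, 3, months=np.array([1.0, 13.0]))
        assert p["predicted"].iloc[0] == pytest.approx(
            p["predicted"].iloc[1], rel=1e-9)

    def test_seasonal_sign_short_period_below_long_period(self, seasonal_fit):
        p = predict_monthly(seasonal_fit, 3).set_index("month")["predicted"]
        assert p.loc[[9, 10, 11, 12]].mean() < p.loc[[3, 4, 5]].mean()

    def test_intervals_positive_under_log_link(self, seasonal_fit):
        p = predict_monthly(seasonal_fit, 3)
        assert (p["ci_low"] > 0).all()
        assert (p["ci_low"] < p["predicted"]).all()
        assert (p["predicted"] < p["ci_high"]).all()

    def test_unknown_song_year_rejected(self, seasonal_fit):
        with pytest.raises(ValueError, match="not in the fitted data"):
            predict_monthly(seasonal_fit, 99)


class TestSpectralModels:
    @staticmethod
    def _notes(seed, sinusoid_amp=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for sy, year in ((2, 2017), (3, 2018), (4, 2019)):
            for m in (1, 2, 3, 4, 7, 8, 9, 10, 11, 12):
                for d in (5, 15):
                    date = f"{year if m >= 7 else year + 1}-{m:02d}-{d:02d}"
                    mean = 19.5 + sinusoid_amp * np.sin(2 * np.pi * m / 12)
                    vals = rng.gamma(400.0, mean / 400.0, size=12)
                    rows += [dict(cf=v, month=m, song_year=sy, date=date)
                             for v in vals]
        return pd.DataFrame(rows)

    def test_constant_spectra_yield_no_significant_smooths(self):
        hits = 0
        for seed in range(5):
            fit = fit_spectral_model(self._notes(seed), "cf")
            sig = (fit.smooth_table["p"] < 0.05).any()
            hits += not sig
        assert hits >= 4  # >= 90%-style behavior at 5 seeds

    def test_injected_annual_sinusoid_detected(self):
        fit = fit_spectral_model(self._notes(11, sinusoid_amp=2.0), "cf")
        month_row = fit.smooth_table.set_index("term").loc["s(Month)"]
        assert month_row["p"] < 0.01

    def test_identity_link_fit_recovers_level(self):
        fit = fit_spectral_model(self._notes(3), "cf")
        assert np.median(fit.fitted) == pytest.approx(19.5, rel=0.02)


class TestAgainstMgcv:
    def test_monthly_pattern_matches_mgcv_gam(self, tmp_path):
        """Independent oracle: mgcv's cyclic-spline Gamma GAM on the same
        data should produce the same seasonal shape (r > 0.95) and a
        matching overall level."""
        df = seasonal_frame(seed=12, years=(2, 3), songs_per_cell=1,
                            inis_per_song=20)
        fit = fit_ini_model(df, "m1")
        ours = predict_monthly(fit, 2)["predicted"].to_numpy()

        data_csv = tmp_path / "d.csv"
        out_csv = tmp_path / "pred.csv"
        df.to_csv(data_csv, index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(f"""
library(mgcv)
d <- read.csv("{data_csv}")
d$singer <- factor(d$singer)
m <- gam(ini ~ s(month, bs="cc", k=12) + song_year + s(singer, bs="re"),
         knots=list(month=c(0.5, 12.5)),
         family=Gamma(link="log"), data=d, method="REML")
nd <- data.frame(month=1:12, song_year=2, singer=d$singer[1])
p <- predict(m, nd, type="response",
             exclude="s(singer)", newdata.guaranteed=TRUE)
write.csv(data.frame(month=1:12, pred=p), "{out_csv}", row.names=FALSE)
""")
        subprocess.run(["Rscript", "--vanilla", str(rscript)], check=True,
                       capture_output=True)
        theirs = pd.read_csv(out_csv)["pred"].to_numpy()
        r = np.corrcoef(ours, theirs)[0, 1]
        assert r > 0.95
        assert np.mean(ours) == pytest.approx(np.mean(theirs), rel=0.02)
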