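"""Exceedance verdicts, intensity bins, risk factors and total scores."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from climenv import (
    FIVE_COLOUR_BINS,
    METHODS_BINS,
    Envelope,
    IntensityBins,
    bin_intensity,
    cee_pipeline,
    evaluate_exceedance,
    risk_factor,
    total_score,
)


def _env(lower, upper, species="sp", variable="bio01", **kw) -> Envelope:
    return Envelope(species=species, variable=variable, lower=lower,
                    upper=upper, **kw)


class TestEvaluateExceedance:
    def test_interior_point(self):
        assert evaluate_exceedance(7.0, _env(0.0, 10.0)) == ("none", None)

    def test_positive_exceedance_percentage(self):
        sign, pct = evaluate_exceedance(12.0, _env(0.0, 10.0))
        assert sign == "positive"
        assert pct == pytest.approx(20.0)

    def test_negative_exceedance_percentage(self):
        sign, pct = evaluate_exceedance(-0.3, _env(0.0, 10.0))
        assert sign == "negative"
        assert pct == pytest.approx(3.0)

    def test_open_side_never_exceeds(self):
        env = _env(None, 10.0, data_range=(-5.0, 12.0),
                   lower_open_reason="no-crossing-in-range")
        assert evaluate_exceedance(-100.0, env) == ("none", None)
        sign, pct = evaluate_exceedance(13.0, env)
        # size proxy: upper bound minus the data-range minimum = 15
        assert sign == "positive"
        assert pct == pytest.approx(100 * 3.0 / 15.0)

    def test_both_open_is_an_error(self):
        env = _env(None, None, lower_open_reason="non-unimodal",
                   upper_open_reason="non-unimodal")
        with pytest.raises(ValueError, match="both bounds OPEN"):
            evaluate_exceedance(1.0, env)

    def test_scale_invariance(self, rng):
        lower, upper = 2.0, 12.0
        for _ in range(20):
            v = rng.uniform(-5, 20)
            a, s_ = 9.0, 40.0  # affine rescale x -> a*x + s_
            sign1, pct1 = evaluate_exceedance(v, _env(lower, upper))
            sign2, pct2 = evaluate_exceedance(
                a * v + s_, _env(a * lower + s_, a * upper + s_))
            assert sign1 == sign2
            if pct1 is None:
                assert pct2 is None
            else:
                assert pct2 == pytest.approx(pct1, rel=1e-9)


class TestBinIntensity:
    @pytest.mark.parametrize("intensity,label", [
        (3.0, ">0-5"), (5.0, ">0-5"), (5.01, "5-10"), (12.0, "10-15"),
        (20.0, "15-25"), (27.5, "25-30"), (30.0, "25-30"), (47.0, ">30"),
    ])
    def test_methods_bins(self, intensity, label):
        assert bin_intensity(intensity, METHODS_BINS) == label

    def test_five_colour_preset_merges_mid_bins(self):
        assert bin_intensity(20.0, FIVE_COLOUR_BINS) == "15-30"
        assert bin_intensity(47.0, FIVE_COLOUR_BINS) == ">30"

    def test_non_exceedance_cannot_be_binned(self):
        with pytest.raises(ValueError):
            bin_intensity(0.0)
        with pytest.raises(ValueError):
            bin_intensity(-3.0)

    def test_invalid_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            IntensityBins(edges=(5.0, 10.0), labels=("a", "b"))
        with pytest.raises(ValueError):
            IntensityBins(edges=(0.0, 5.0), labels=("a",))


def _records(signs_intensities) -> pd.DataFrame:
    return pd.DataFrame(signs_intensities, columns=["sign", "intensity"])


class TestRiskFactor:
    def test_simple_counting(self):
        rec = _records([("positive", 2.0)] * 25 + [("none", None)] * 75)
        out = risk_factor(rec, 100)
        assert out["frequency"] == pytest.approx(25.0)

    def test_zero_exceedances(self):
        out = risk_factor(_records([("none", None)] * 10), 10)
        assert out["frequency"] == 0.0
        assert all(v == 0.0 for v in out["by_bin"].values())

    def test_injected_fraction_recovered_exactly(self, rng):
        rows = ([("positive", float(rng.uniform(1, 50)))] * 30
                + [("negative", float(rng.uniform(1, 50)))] * 10
                + [("none", None)] * 60)
        out = risk_factor(_records(rows), 100)
        assert out["frequency"] == pytest.approx(40.0)
        assert out["by_sign"]["positive"] == pytest.approx(30.0)
        assert out["by_sign"]["negative"] == pytest.approx(10.0)

    def test_bins_partition_total(self, rng):
        rows = [("positive", float(rng.uniform(0.01, 60))) for _ in range(37)]
        rows += [("negative", float(rng.uniform(0.01, 60))) for _ in range(13)]
        rows += [("none", None)] * 50
        out = risk_factor(_records(rows), 100)
        assert sum(out["by_bin"].values()) == pytest.approx(out["frequency"],
                                                            abs=1e-9)
        assert sum(out["by_sign"].values()) == pytest.approx(out["frequency"],
                                                             abs=1e-9)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            risk_factor(_records([]), 0)


def _loadings(d: dict[str, tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"load1": {k: v[0] for k, v in d.items()},
         "load2": {k: v[1] for k, v in d.items()}}
    )


class TestTotalScore:
    def test_single_variable_equals_its_frequency(self):
        score, _, w = total_score(pd.Series({"bio01": 42.0}),
                                  _loadings({"bio01": (0.3, -0.2)}))
        assert score == pytest.approx(42.0)
        assert w["bio01"] == pytest.approx(1.0)

    def test_zero_frequencies_zero_score(self):
        score, _, _ = total_score(
            pd.Series({"bio01": 0.0, "bio12": 0.0}),
            _loadings({"bio01": (1, 0), "bio12": (0, 1)}))
        assert score == 0.0

    def test_hand_computed_weighted_mean(self):
        freqs = pd.Series({"a": 10.0, "b": 20.0, "c": 30.0})
        lo = _loadings({"a": (1, 0), "b": (0, 1), "c": (1, 1)})
        score, contrib, _ = total_score(freqs, lo)
        assert score == pytest.approx((10 + 20 + 60) / 4)
        assert contrib["c"] == pytest.approx(15.0)

    def test_missing_loadings_named(self):
        with pytest.raises(KeyError, match="bio19"):
            total_score(pd.Series({"bio19": 5.0}), _loadings({"bio01": (1, 0)}))


def _pool(level, bio01_values) -> pd.DataFrame:
    n = len(bio01_values)
    return pd.DataFrame({
        "level": level, "model": "m", "run": "r",
        "year": np.arange(2000, 2000 + n), "bio01": bio01_values,
    })


class TestCEEPipeline:
    ENVS = {
        ("narrow", "bio01"): _env(6.0, 10.0, species="narrow"),
        ("wide", "bio01"): _env(4.0, 12.0, species="wide"),
    }
    LOADINGS = _loadings({"bio01": (1.0, 0.0)})

    def test_interior_pool_has_zero_frequencies(self, rng):
        pool = _pool(1.2, rng.uniform(6.5, 9.5, 50))
        risk, scores = cee_pipeline(self.ENVS, pool, self.LOADINGS)
        assert (risk["frequency_pct"] == 0).all()
        assert (scores["score"] == 0).all()

    def test_injected_exceedances_recover_exact_frequency(self, rng):
        values = np.r_[rng.uniform(6.5, 9.5, 60), rng.uniform(10.5, 11.5, 40)]
        risk, _ = cee_pipeline(self.ENVS, _pool(3.0, values), self.LOADINGS)
        narrow_pos = risk[(risk["species"] == "narrow") & (risk["sign"] == "positive")
                          & (risk["bin"] == "all")]
        assert narrow_pos["frequency_pct"].iloc[0] == pytest.approx(40.0)
        wide_pos = risk[(risk["species"] == "wide") & (risk["sign"] == "positive")
                        & (risk["bin"] == "all")]
        assert wide_pos["frequency_pct"].iloc[0] == pytest.approx(0.0)

    def test_nested_envelopes_order_frequencies(self, rng):
        values = rng.uniform(8.0, 13.0, 200)
        risk, _ = cee_pipeline(self.ENVS, _pool(3.0, values), self.LOADINGS)
        pos = risk[(risk["sign"] == "positive") & (risk["bin"] == "all")]
        f = pos.set_index("species")["frequency_pct"]
        assert f["narrow"] >= f["wide"]

    def test_warming_monotonicity(self, rng):
        base = rng.uniform(5.0, 10.5, 100)
        freqs = []
        for level, offset in ((1.5, 0.0), (2.0, 1.0), (3.0, 2.5)):
            risk, _ = cee_pipeline(self.ENVS, _pool(level, base + offset),
                                   self.LOADINGS)
            pos = risk[(risk["species"] == "narrow") & (risk["sign"] == "positive")
                       & (risk["bin"] == "all")]
            freqs.append(float(pos["frequency_pct"].iloc[0]))
        assert freqs == sorted(freqs)

    def test_sign_exclusivity_and_bin_partition(self, rng):
        values = rng.uniform(-2.0, 16.0, 300)
        risk, _ = cee_pipeline(self.ENVS, _pool(2.0, values), self.LOADINGS)
        for (sp, var, lvl), grp in risk.groupby(["species", "variable", "level"]):
            total = grp[grp["bin"] == "all"]["frequency_pct"].sum()
            binned = grp[grp["bin"] != "all"]["frequency_pct"].sum()
            assert binned == pytest.approx(total, abs=1e-9)
        # sign exclusivity: each pooled year counted at most once
        pos = risk[(risk["bin"] == "all") & (risk["sign"] == "positive")]
        neg = risk[(risk["bin"] == "all") & (risk["sign"] == "negative")]
        merged = pos.merge(neg, on=["species", "variable", "level"])
        assert (merged["frequency_pct_x"] + merged["frequency_pct_y"] <= 100 + 1e-9).all()

    def test_both_open_pairs_skipped_not_fatal(self, rng, caplog):
        envs = dict(self.ENVS)
        envs[("narrow", "bio12")] = Envelope(
            species="narrow", variable="bio12", lower=None, upper=None,
            lower_open_reason="non-unimodal", upper_open_reason="non-unimodal")
        pool = _pool(1.5, rng.uniform(6.5, 9.5, 20))
        pool["bio12"] = rng.uniform(500, 700, 20)
        with caplog.at_level("INFO"):
            risk, _ = cee_pipeline(envs, pool, self.LOADINGS)
        assert not ((risk["species"] == "narrow")
                    & (risk["variable"] == "bio12")).any()
        assert any("both bounds OPEN" in r.message for r in caplog.records)
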