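"""Plant aggregation, fresh/dry calibration, heritability, correlations."""

import numpy as np
import pandas as pd
import pytest

from inflorascan import (
    apply_calibration,
    broad_sense_heritability,
    correlation_matrix,
    fit_fresh_dry_calibration,
    simulate_clonal_trait,
    summarize_plant,
    summarize_plants,
)
from inflorascan.plant_metrics import TRAITS


def _records(sizes, ish=None):
    n = len(sizes)
    ish = np.full(n, 0.5) if ish is None else np.asarray(ish)
    df = pd.DataFrame(
        {
            "object_id": np.arange(1, n + 1),
            "pixel_count": (np.asarray(sizes) / 0.05**2).astype(int),
            "IS_cm2": sizes,
            "IL_cm": np.sqrt(sizes) * 2,
            "IW_cm": np.sqrt(sizes),
            "CH_cm2": np.asarray(sizes) * 1.1,
            "HP_cm": np.sqrt(sizes) * 5,
            "ISH": ish,
        }
    )
    return df


META = {"plant_id": "P1", "genotype_id": "G1", "state": "dry", "IDB_g": 100.0}


class TestSummarizePlant:
    def test_counts_and_totals(self):
        s = summarize_plant(_records([2.0, 3.0, 5.0]), META)
        assert s.IN == 3
        assert s.TIC_cm2 == pytest.approx(10.0, abs=0)
        assert s.means["IS_cm2"] == pytest.approx(10 / 3)

    def test_single_object_sd_flagged(self):
        s = summarize_plant(_records([4.0]), META)
        assert np.isnan(s.sds["IS_cm2"])

    def test_degenerate_objects_excluded_from_ish_only(self):
        df = _records([1.0, 2.0, 3.0], ish=[0.5, np.nan, 0.7])
        s = summarize_plant(df, META)
        assert s.IN == 3
        assert s.means["ISH"] == pytest.approx(0.6)

    def test_matches_twopass_oracle(self):
        rng = np.random.default_rng(0)
        sizes = rng.lognormal(1.2, 0.7, 300)
        df = _records(sizes)
        s = summarize_plant(df, META)
        for t in TRAITS:
            vals = df[t].to_numpy()
            mean = sum(vals) / len(vals)
            var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            assert s.means[t] == pytest.approx(mean, rel=1e-12)
            assert s.sds[t] == pytest.approx(np.sqrt(var), rel=1e-12)

    def test_tic_additivity_exact(self):
        rng = np.random.default_rng(1)
        sizes = rng.lognormal(1.2, 0.7, 101)
        whole = summarize_plant(_records(sizes), META).TIC_cm2
        part1 = summarize_plant(_records(sizes[:40]), META).TIC_cm2
        part2 = summarize_plant(_records(sizes[40:]), META).TIC_cm2
        assert whole == part1 + part2  # same left-to-right float summation

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_plant(_records([]), META)


class TestCalibration:
    @staticmethod
    def _paired_tables(slope=0.8, intercept=-0.1, noise=0.0, n=14, seed=0):
        rng = np.random.default_rng(seed)
        fresh = pd.DataFrame({"plant_id": [f"P{i}" for i in range(n)]})
        dry = fresh.copy()
        for t in ("IW_cm_mean", "IL_cm_mean"):
            x = rng.uniform(2, 6, n)
            fresh[t] = x
            dry[t] = slope * x + intercept + rng.normal(0, noise, n)
        return fresh, dry

    def test_identity_line(self):
        fresh, dry = self._paired_tables(slope=1.0, intercept=0.0)
        cal = fit_fresh_dry_calibration(fresh, dry)
        c = cal["IW_cm_mean"]
        assert c.slope == pytest.approx(1.0)
        assert c.intercept == pytest.approx(0.0, abs=1e-12)
        assert c.r2 == pytest.approx(1.0)

    def test_recovers_slope_with_noise(self):
        fresh, dry = self._paired_tables(noise=0.01, seed=3)
        cal = fit_fresh_dry_calibration(fresh, dry)
        c = cal["IW_cm_mean"]
        assert abs(c.slope - 0.8) < 0.05
        assert c.calibratable

    def test_independent_trait_flagged(self):
        rng = np.random.default_rng(5)
        fresh = pd.DataFrame(
            {"plant_id": [f"P{i}" for i in range(14)], "IW_cm_mean": rng.uniform(2, 6, 14)}
        )
        dry = pd.DataFrame(
            {"plant_id": fresh["plant_id"], "IW_cm_mean": rng.uniform(2, 6, 14)}
        )
        cal = fit_fresh_dry_calibration(fresh, dry)
        assert not cal["IW_cm_mean"].calibratable
        assert cal["IW_cm_mean"].r2 < 0.5

    def test_too_few_pairs_rejected(self):
        fresh, dry = self._paired_tables(n=2)
        with pytest.raises(ValueError, match="3"):
            fit_fresh_dry_calibration(fresh, dry)

    def test_apply_and_roundtrip(self):
        fresh, dry = self._paired_tables()
        cal = fit_fresh_dry_calibration(fresh, dry)
        s = summarize_plant(_records([2.0, 3.0, 4.0]), {**META, "state": "fresh"})
        # restrict to the fitted traits by building a table row instead
        table = pd.DataFrame([s.to_row()])
        mapped = apply_calibration(table, cal, "fresh_to_dry")
        assert mapped.loc[0, "state"] == "dry"
        assert mapped.loc[0, "IW_cm_mean"] == pytest.approx(
            0.8 * table.loc[0, "IW_cm_mean"] - 0.1
        )
        back = apply_calibration(mapped, cal, "dry_to_fresh")
        assert back.loc[0, "IW_cm_mean"] == pytest.approx(
            table.loc[0, "IW_cm_mean"], rel=1e-9
        )
        assert back.loc[0, "state"] == "fresh"

    def test_known_affine_example(self):
        fresh, dry = self._paired_tables(slope=0.8, intercept=-0.1)
        cal = fit_fresh_dry_calibration(fresh, dry)
        table = pd.DataFrame([{"plant_id": "P", "state": "fresh", "IW_cm_mean": 4.0,
                               "IL_cm_mean": 4.0}])
        out = apply_calibration(table, cal, "fresh_to_dry")
        assert out.loc[0, "IW_cm_mean"] == pytest.approx(3.1)


class TestHeritability:
    def test_pure_genetic_signal_gives_one(self):
        df = pd.DataFrame(
            {
                "genotype_id": ["A", "A", "B", "B", "C", "C"],
                "trait": [1.0, 1.0, 2.0, 2.0, 3.0, 3.0],
            }
        )
        assert broad_sense_heritability(df, "trait").h2 == 1.0

    def test_pure_noise_truncated_to_zero(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "genotype_id": np.repeat(list("ABCD"), 3),
                "trait": np.tile([0.0, 1.0, -1.0], 4),  # identical group means
            }
        )
        res = broad_sense_heritability(df, "trait")
        assert res.h2 == 0.0
        assert res.v_g == 0.0

    def test_recovery_of_known_components(self):
        """Mean estimate across replicates lands near the simulated truth."""
        h2s = [
            broad_sense_heritability(
                simulate_clonal_trait(100, 4, 0.4, 0.6, seed=1000 + r), "value"
            ).h2
            for r in range(60)
        ]
        assert abs(np.mean(h2s) - 0.4) < 0.05

    def test_affine_invariance(self):
        df = simulate_clonal_trait(30, 4, 0.3, 0.7, seed=2)
        base = broad_sense_heritability(df, "value").h2
        df["value"] = 5.0 * df["value"] - 11.0
        assert broad_sense_heritability(df, "value").h2 == pytest.approx(base, rel=1e-9)

    def test_unbalanced_groups_supported(self):
        df = simulate_clonal_trait(40, 5, 0.5, 0.5, seed=3)
        df = df.drop(df.index[::7])  # make it unbalanced
        res = broad_sense_heritability(df, "value")
        assert 0 <= res.h2 <= 1
        assert res.k1 < 5

    def test_no_replication_rejected(self):
        df = pd.DataFrame({"genotype_id": list("ABC"), "trait": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="replication"):
            broad_sense_heritability(df, "trait")


class TestCorrelationMatrix:
    def test_perfect_line(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1})
        r, p = correlation_matrix(df, ["x", "y"])
        assert r.loc["x", "y"] == pytest.approx(1.0)
        assert r.loc["x", "x"] == 1.0

    def test_insignificant_entries_blanked(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"x": rng.normal(size=10), "y": rng.normal(size=10)})
        r, p = correlation_matrix(df, ["x", "y"])
        if p.loc["x", "y"] > 0.05:
            assert np.isnan(r.loc["x", "y"])

    def test_tic_idb_coupling(self):
        rng = np.random.default_rng(13)
        tic = rng.uniform(250, 2500, 120)
        idb = 0.12 * tic * (1 + rng.normal(0, 0.04, 120))
        df = pd.DataFrame({"TIC_cm2": tic, "IDB_g": idb})
        r, _ = correlation_matrix(df, ["TIC_cm2", "IDB_g"])
        assert r.loc["TIC_cm2", "IDB_g"] > 0.95

    def test_constant_trait_flagged(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        r, p = correlation_matrix(df, ["x", "y"])
        assert np.isnan(p.loc["x", "y"])


def test_summarize_plants_population_table():
    objects = pd.concat(
        [
            _records([2.0, 3.0]).assign(plant_id="P1"),
            _records([5.0, 7.0, 9.0]).assign(plant_id="P2"),
        ],
        ignore_index=True,
    )
    meta = pd.DataFrame(
        {
            "plant_id": ["P1", "P2"],
            "genotype_id": ["G1", "G1"],
            "state": ["dry", "dry"],
            "IDB_g": [10.0, 20.0],
        }
    )
    plants = summarize_plants(objects, meta)
    assert list(plants["IN"]) == [2, 3]
    assert plants.loc[plants["plant_id"] == "P2", "TIC_cm2"].item() == 21.0
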