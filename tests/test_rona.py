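"""RONA: regression projection, clamping, weighting and aggregation."""

import numpy as np
import pandas as pd
import pytest

from popadapt.core import EnvFrame
from popadapt.rona import RONAModel, pop_allele_freqs
from popadapt.simulate import SimConfig, FutureShift, simulate_dataset


def _env(pops, current, future_cols):
    cur = pd.DataFrame(current, index=pd.Index(pops, name="population_id"))
    fut = pd.DataFrame(future_cols, index=cur.index)
    fut.columns = pd.MultiIndex.from_tuples(fut.columns,
                                            names=["ev", "scenario", "model"])
    return EnvFrame(current=cur, future=fut)


class TestPopFreqs:
    def test_min_inds_boundary(self, toy_matrix):
        G = toy_matrix(np.zeros((13, 4)), samples=[f"S{i}" for i in range(13)])
        samples = pd.DataFrame({
            "sample_id": G.samples,
            "population_id": ["small"] * 6 + ["big"] * 7,
            "group_id": "G", "latitude": 0.0, "longitude": 0.0,
            "altitude": 0.0})
        freqs = pop_allele_freqs(G, samples, min_inds=7)
        assert list(freqs.index) == ["big"]  # 6 dropped, 7 retained

    def test_all_dropped_raises(self, toy_matrix):
        G = toy_matrix(np.zeros((3, 2)))
        samples = pd.DataFrame({
            "sample_id": G.samples, "population_id": "p",
            "group_id": "G", "latitude": 0.0, "longitude": 0.0,
            "altitude": 0.0})
        with pytest.raises(ValueError):
            pop_allele_freqs(G, samples, min_inds=7)

    def test_fixture_retained_count_matches_truth(self, small_bundle):
        b = small_bundle
        freqs = pop_allele_freqs(b.genotypes, b.samples, min_inds=7)
        expected = (b.samples.groupby("population_id").size() >= 7).sum()
        assert len(freqs) == expected


class TestRona:
    def test_noiseless_cline_closed_form(self):
        """f = 0.1 + 0.02*EV with R^2 = 1; population at EV 10 moving to
        EV 15 requires frequency 0.40 vs 0.30 -> RONA = 0.10."""
        pops = [f"P{i}" for i in range(5)]
        ev = np.array([0.0, 5.0, 10.0, 20.0, 30.0])
        f = 0.1 + 0.02 * ev
        fut = ev.copy()
        fut[2] = 15.0
        env = _env(pops, {"EV": ev}, {("EV", "S", "m1"): fut})
        freqs = pd.DataFrame({0: f}, index=pops)
        res = RONAModel(freqs, env, {"EV": [0]}).fit()
        t = res.table.set_index("population")
        assert t.loc["P2", "rona"] == pytest.approx(0.10, abs=1e-12)
        assert t.drop("P2")["rona"].abs().max() < 1e-12

    def test_future_equals_current_gives_zero(self):
        pops = [f"P{i}" for i in range(4)]
        ev = np.array([1.0, 2.0, 3.0, 4.0])
        f = 0.2 + 0.1 * ev
        env = _env(pops, {"EV": ev}, {("EV", "S", "m1"): ev})
        res = RONAModel(pd.DataFrame({0: f}, index=pops), env,
                        {"EV": [0]}).fit()
        assert res.table["rona"].abs().max() < 1e-12

    def test_prediction_clamped_to_unit_interval(self):
        pops = [f"P{i}" for i in range(4)]
        ev = np.array([1.0, 2.0, 3.0, 4.0])
        f = 0.2 + 0.2 * ev  # slope 0.2: future 8 predicts 1.8 -> clamp to 1
        env = _env(pops, {"EV": ev}, {("EV", "S", "m1"): ev + 4.0})
        res = RONAModel(pd.DataFrame({0: np.clip(f, 0, 1)}, index=pops),
                        env, {"EV": [0]}).fit()
        t = res.table.set_index("population")
        # P3: current f = 1.0, prediction 1.8 clamped to 1.0 -> distance 0
        assert t.loc["P3", "rona"] == pytest.approx(0.0, abs=1e-9)
        assert t.loc["P3", "rona_unclamped"] > 0.5

    def test_zero_weight_locus_contributes_nothing(self):
        rng = np.random.default_rng(0)
        pops = [f"P{i}" for i in range(6)]
        ev = np.linspace(0, 10, 6)
        clean = 0.1 + 0.05 * ev
        noise = np.full(6, 0.4)  # constant -> R^2 = 0
        env = _env(pops, {"EV": ev}, {("EV", "S", "m1"): ev + 2.0})
        r1 = RONAModel(pd.DataFrame({0: clean}, index=pops), env,
                       {"EV": [0]}).fit()
        r2 = RONAModel(pd.DataFrame({0: clean, 1: noise}, index=pops), env,
                       {"EV": [0, 1]}).fit()
        np.testing.assert_allclose(r1.table["rona"], r2.table["rona"],
                                   atol=1e-12)

    def test_affine_ev_rescaling_invariance(self):
        pops = [f"P{i}" for i in range(6)]
        ev = np.linspace(2, 12, 6)
        rng = np.random.default_rng(1)
        f = np.clip(0.3 + 0.04 * ev + rng.normal(0, 0.02, 6), 0, 1)
        fut = ev + 3.0
        env1 = _env(pops, {"EV": ev}, {("EV", "S", "m1"): fut})
        env2 = _env(pops, {"EV": 10 * ev + 5}, {("EV", "S", "m1"): 10 * fut + 5})
        r1 = RONAModel(pd.DataFrame({0: f}, index=pops), env1, {"EV": [0]}).fit()
        r2 = RONAModel(pd.DataFrame({0: f}, index=pops), env2, {"EV": [0]}).fit()
        np.testing.assert_allclose(r1.table["rona"], r2.table["rona"],
                                   atol=1e-12)


class TestAggregation:
    @staticmethod
    def _multi_model_results():
        pops = [f"P{i}" for i in range(4)]
        ev = np.array([1.0, 3.0, 5.0, 7.0])
        f = 0.1 + 0.05 * ev
        fut = {("EV", "S", m): ev + d for m, d in
               [("m1", 1.0), ("m2", 2.0), ("m3", 3.0)]}
        env = _env(pops, {"EV": ev}, fut)
        return RONAModel(pd.DataFrame({0: f}, index=pops), env,
                         {"EV": [0]}).fit()

    def test_mean_and_se_closed_form(self):
        res = self._multi_model_results()
        agg = res.aggregate()
        # per-model RONA = 0.05 * delta -> values {0.05, 0.10, 0.15}
        row = agg.iloc[0]
        assert row["mean_rona"] == pytest.approx(0.10, abs=1e-12)
        assert row["se"] == pytest.approx(np.std([0.05, 0.10, 0.15], ddof=1)
                                          / np.sqrt(3), abs=1e-12)

    def test_identical_models_zero_se(self):
        pops = [f"P{i}" for i in range(4)]
        ev = np.array([1.0, 3.0, 5.0, 7.0])
        f = 0.1 + 0.05 * ev
        fut = {("EV", "S", m): ev + 2.0 for m in ["m1", "m2"]}
        env = _env(pops, {"EV": ev}, fut)
        res = RONAModel(pd.DataFrame({0: f}, index=pops), env,
                        {"EV": [0]}).fit()
        assert res.aggregate()["se"].abs().max() < 1e-12

    def test_scenario_monotonicity_on_fixture(self, small_bundle):
        """Bigger planted shift (SSP585 > SSP126) implies larger mean RONA,
        strongly rank-correlated across populations."""
        from scipy.stats import spearmanr
        b = small_bundle
        freqs = pop_allele_freqs(b.genotypes, b.samples, min_inds=7)
        idx = np.flatnonzero(b.truth.locus_class == "adaptive")
        by_ev = {}
        pos_to_idx = {i: i for i in idx}
        adaptive = b.truth.adaptive
        loci_index = {(c, int(p)): i for i, (c, p) in enumerate(
            zip(b.genotypes.loci["chrom"], b.genotypes.loci["pos"]))}
        for _, row in adaptive.iterrows():
            if row["ev"] in b.env.future.columns.get_level_values("ev"):
                by_ev.setdefault(row["ev"], []).append(
                    loci_index[(row["chrom"], int(row["pos"]))])
        res = RONAModel(freqs, b.env, by_ev).fit()
        agg = res.aggregate()
        piv = agg.pivot_table(index=["population", "ev"], columns="scenario",
                              values="mean_rona")
        assert (piv["SSP585"] >= piv["SSP126"]).mean() > 0.9
        rho = spearmanr(piv["SSP126"], piv["SSP585"]).statistic
        assert rho > 0.9

    def test_zero_future_shift_gives_zero_rona(self):
        cfg = SimConfig(seed=3, n_neutral_loci=300, n_adaptive_loci=6,
                        future_shift=FutureShift(
                            base={"SSP126": 0.0, "SSP585": 0.0},
                            spatial_gradient=0.0, model_jitter_sd=0.0))
        b = simulate_dataset(cfg)
        freqs = pop_allele_freqs(b.genotypes, b.samples, min_inds=7)
        idx = list(np.flatnonzero(b.truth.locus_class == "adaptive"))
        res = RONAModel(freqs, b.env, {"Bio1": idx}).fit(current="fitted")
        assert res.table["rona"].abs().max() < 1e-12
        # with the observed baseline, zero shift leaves only residual noise
        res_obs = RONAModel(freqs, b.env, {"Bio1": idx}).fit()
        assert res_obs.table["rona"].mean() < 0.5
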