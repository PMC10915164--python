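"""Generator: panel invariants, renewal-process kinetics, noise-law moments."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from porescreen.sas import sas_raw_moments, sas_sample, sas_stats
from porescreen.synth import (
    BACKGROUND,
    AnalyteModel,
    MixtureSpec,
    SubState,
    TraceSpec,
    expected_event_count,
    make_default_panel,
    panel_by_name,
    simulate_features,
    simulate_trace,
)


class TestPanel:
    def test_target_roster(self, panel):
        assert len(panel) == 11
        names = {m.name for m in panel}
        assert {"CAT", "3-CQA", "D-SOR", "XYL", "L-MA", "D-MA",
                "L-TA", "CA", "ICIT", "D-GLC", "D-FRU"} == names

    def test_alpha_hydroxy_acids_positive_going(self, panel):
        for m in panel:
            if m.category == "alpha_hydroxy_acid":
                assert all(s.ratio_mean > 0 for s in m.sub_states)
            elif m.category in {"diphenol", "alditol", "saccharide"}:
                assert all(s.ratio_mean < 0 for s in m.sub_states)

    def test_saccharides_multi_substate(self, panel):
        by = panel_by_name(panel)
        assert len(by["D-GLC"].sub_states) >= 2
        assert len(by["D-FRU"].sub_states) >= 2
        for m in panel:
            if m.category in {"diphenol", "alditol", "alpha_hydroxy_acid"}:
                assert len(m.sub_states) == 1

    def test_unknown_roster(self, panel_with_unknowns):
        extra = {m.name for m in panel_with_unknowns} - {m.name for m in make_default_panel()}
        assert extra == {"sucrose", "U1", "U2", "U3", BACKGROUND}

    def test_weights_sum_and_positive_tau_k(self, panel_with_unknowns):
        for m in panel_with_unknowns:
            assert m.mean_dwell > 0 and m.calibration_k >= 0
            if m.category != BACKGROUND:
                assert abs(sum(s.weight for s in m.sub_states) - 1.0) < 1e-9
                assert all(-1 < s.ratio_mean < 1 for s in m.sub_states)

    def test_pairwise_separation_at_least_4_pooled_sd(self, panel):
        fm = simulate_features(panel, {m.name: 300 for m in panel}, seed=5)
        df = fm.to_frame()
        stats = df.groupby("label").agg(["mean", "std"])
        names = sorted(df["label"].unique())
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                seps = []
                for col in ["ratio", "std", "kurt", "skew", "dwell"]:
                    da = abs(stats.loc[a, (col, "mean")] - stats.loc[b, (col, "mean")])
                    pooled = math.sqrt(
                        0.5 * (stats.loc[a, (col, "std")] ** 2 + stats.loc[b, (col, "std")] ** 2)
                    )
                    seps.append(da / pooled)
                assert max(seps) >= 4.0, f"{a} vs {b} under-separated"

    @pytest.mark.parametrize(
        "kwargs",
        [
            # alpha-hydroxy acid must be positive-going
            dict(name="x", category="alpha_hydroxy_acid",
                 sub_states=(SubState(1.0, -0.2, 2.0, 0.0, 1.0),), mean_dwell=30, calibration_k=1e-3),
            # saccharide needs >= 2 sub-states
            dict(name="x", category="saccharide",
                 sub_states=(SubState(1.0, -0.2, 2.0, 0.0, 1.0),), mean_dwell=30, calibration_k=1e-3),
            # weights must sum to 1
            dict(name="x", category="diphenol",
                 sub_states=(SubState(0.5, -0.2, 2.0, 0.0, 1.0),), mean_dwell=30, calibration_k=1e-3),
            # diphenol is negative-going
            dict(name="x", category="diphenol",
                 sub_states=(SubState(1.0, 0.2, 2.0, 0.0, 1.0),), mean_dwell=30, calibration_k=1e-3),
        ],
    )
    def test_invalid_models_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalyteModel(**kwargs)


class TestSinhArcsinh:
    @pytest.mark.parametrize("eps,delta", [(0.0, 1.0), (0.5, 0.9), (-0.6, 1.4), (0.3, 0.7)])
    def test_moments_match_numerical_integration(self, eps, delta):
        raw = []
        for p in (1, 2, 3, 4):
            f = lambda z: math.sinh((math.asinh(z) + eps) / delta) ** p * math.exp(
                -z * z / 2
            ) / math.sqrt(2 * math.pi)
            raw.append(quad(f, -12, 12, limit=300)[0])
        got = sas_raw_moments(eps, delta)
        for g, r in zip(got, raw):
            assert g == pytest.approx(r, rel=1e-8, abs=1e-10)

    def test_gaussian_special_case(self):
        mean, sd, skew, kurt = sas_stats(0.0, 1.0)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert sd == pytest.approx(1.0, rel=1e-12)
        assert skew == pytest.approx(0.0, abs=1e-12)
        assert kurt == pytest.approx(3.0, rel=1e-12)

    def test_sample_moments_match_analytic_within_2pct(self):
        rng = np.random.default_rng(7)
        eps, delta = 0.5, 0.9
        s = sas_sample(rng, eps, delta, 1_000_000)
        _, sd, skew, kurt = sas_stats(eps, delta)
        assert np.std(s) == pytest.approx(sd, rel=0.02)
        d = s - s.mean()
        m2 = np.mean(d**2)
        assert np.mean(d**3) / m2**1.5 == pytest.approx(skew, rel=0.02)
        assert np.mean(d**4) / m2**2 == pytest.approx(kurt, rel=0.02)
        assert abs(s.mean()) < 5e-3  # centred draw

    def test_shape_parameters_steer_moments(self):
        assert sas_stats(0.8, 1.0)[2] > 0 > sas_stats(-0.8, 1.0)[2]
        assert sas_stats(0.0, 0.7)[3] > 3.0 > sas_stats(0.0, 1.4)[3]


class TestExpectedEventCount:
    def _one_class_panel(self, k, tau):
        return [AnalyteModel("A", "diphenol",
                             (SubState(1.0, -0.3, 2.0, 0.0, 1.0),), tau, k)]

    def test_closed_form(self):
        # lambda = 0.01/ms, tau = 50 ms, 150 s -> 150000/(100+50) = 1000
        panel = self._one_class_panel(k=0.001, tau=50.0)
        out = expected_event_count(panel, MixtureSpec(entries=(("A", 10.0),)), 150_000.0)
        assert out["total"] == pytest.approx(1000.0)
        assert out["A"] == pytest.approx(out["total"])  # single class takes all

    def test_poisson_limit_small_tau(self):
        panel = self._one_class_panel(k=0.001, tau=1e-9)
        out = expected_event_count(panel, MixtureSpec(entries=(("A", 10.0),)), 150_000.0)
        assert out["total"] == pytest.approx(0.01 * 150_000.0, rel=1e-6)

    def test_zero_rate_gives_zero_counts(self):
        panel = self._one_class_panel(k=0.001, tau=50.0)
        out = expected_event_count(panel, MixtureSpec(entries=(("A", 0.0),)), 1000.0)
        assert out["total"] == 0.0 and out["A"] == 0.0

    def test_class_shares_proportional_to_rate(self, panel):
        mix = MixtureSpec(entries=(("CAT", 2.0), ("L-MA", 1.0)))
        out = expected_event_count(panel, mix, 60_000.0)
        by = panel_by_name(panel)
        lam_cat = by["CAT"].calibration_k * 2.0
        lam_lma = by["L-MA"].calibration_k * 1.0
        assert out["CAT"] / out["L-MA"] == pytest.approx(lam_cat / lam_lma)


class TestSimulateTrace:
    def test_empty_mixture_is_flat_open_pore(self, panel):
        spec = TraceSpec(duration_s=5.0, sampling_rate=5000.0)
        mix = MixtureSpec(entries=(("CAT", 0.0),), background_noise_rate=0.0)
        trace, truth = simulate_trace(panel, mix, spec, seed=1)
        assert len(truth) == 0
        se = spec.baseline_noise_sd / math.sqrt(trace.n_samples)
        # filtering reduces the sample-mean variance even further; 3 SE of
        # the unfiltered noise is a conservative envelope
        assert abs(trace.samples.mean() - spec.open_pore_current) < 3 * se + 0.05

    def test_same_seed_bit_identical(self, panel):
        spec = TraceSpec(duration_s=3.0, sampling_rate=5000.0)
        mix = MixtureSpec(entries=(("CAT", 2.0), ("D-GLC", 20.0)))
        t1, g1 = simulate_trace(panel, mix, spec, seed=99)
        t2, g2 = simulate_trace(panel, mix, spec, seed=99)
        assert np.array_equal(t1.samples, t2.samples)
        assert g1.to_frame().equals(g2.to_frame())

    def test_event_count_matches_renewal_oracle(self):
        # single analyte, k = 0.001 /mM/ms at 1 mM, tau 50 ms, t = 150 s
        panel = [AnalyteModel("A", "diphenol",
                              (SubState(1.0, -0.3, 2.0, 0.0, 1.0),), 50.0, 0.001)]
        mix = MixtureSpec(entries=(("A", 1.0),))
        spec = TraceSpec(duration_s=150.0, sampling_rate=2500.0)
        expected = expected_event_count(panel, mix, 150_000.0)["total"]
        counts = [len(simulate_trace(panel, mix, spec, seed=s)[1]) for s in (11, 12, 13)]
        for c in counts:
            assert abs(c - expected) <= 4 * math.sqrt(expected)

    def test_exclusive_occupancy_over_many_traces(self, panel):
        spec = TraceSpec(duration_s=2.0, sampling_rate=2500.0)
        mix = MixtureSpec(entries=(("CAT", 20.0), ("L-MA", 10.0)), background_noise_rate=0.002)
        for s in range(50):
            _, truth = simulate_trace(panel, mix, spec, seed=s)
            recs = truth.records
            for a, b in zip(recs, recs[1:]):
                assert b.start_ms >= a.end_ms  # never overlapping
                assert a.end_ms > a.start_ms

    def test_unknown_analyte_rejected(self, panel):
        spec = TraceSpec(duration_s=1.0)
        with pytest.raises(KeyError):
            simulate_trace(panel, MixtureSpec(entries=(("nope", 1.0),)), spec, seed=0)

    def test_rate_linear_in_concentration_with_occupancy_correction(self):
        # fitted through-origin slope of event rate vs C matches the
        # occupancy-corrected oracle lambda/(1 + lambda*tau) within 5%
        panel = [AnalyteModel("A", "alditol",
                              (SubState(1.0, -0.4, 2.0, 0.0, 1.0),), 25.0, 0.0005)]
        duration_ms = 400_000.0
        spec = TraceSpec(duration_s=duration_ms / 1e3, sampling_rate=2500.0)
        concs = (1.0, 4.0)
        rates, oracle = [], []
        for conc in concs:
            lam = 0.0005 * conc
            mix = MixtureSpec(entries=(("A", conc),))
            count = sum(
                len(simulate_trace(panel, mix, spec, seed=s)[1]) for s in (21, 22)
            )
            rates.append(count / (2 * duration_ms))
            oracle.append(lam / (1.0 + lam * 25.0))
        c = np.array(concs)
        slope = float((c * np.array(rates)).sum() / (c**2).sum())
        slope_oracle = float((c * np.array(oracle)).sum() / (c**2).sum())
        assert slope == pytest.approx(slope_oracle, rel=0.05)


class TestSimulateFeatures:
    def test_counts_and_labels_and_sign(self, panel):
        fm = simulate_features(panel, {"CAT": 500}, seed=3)
        assert len(fm) == 500
        assert set(fm.labels) == {"CAT"}
        assert (fm.data["ratio"] < 0).all()  # diphenols are negative-going

    def test_enantiomers_separable(self, panel):
        fm = simulate_features(panel, {"L-MA": 500, "D-MA": 500}, seed=3)
        df = fm.to_frame()
        g = df.groupby("label")["ratio"]
        gap = abs(g.mean()["L-MA"] - g.mean()["D-MA"])
        pooled = math.sqrt(0.5 * (g.std()["L-MA"] ** 2 + g.std()["D-MA"] ** 2))
        assert gap / pooled >= 2.0

    def test_all_dwells_exceed_filter(self, panel_with_unknowns):
        counts = {"CAT": 200, "D-GLC": 200, BACKGROUND: 200}
        fm = simulate_features(panel_with_unknowns, counts, seed=4)
        assert (fm.data["dwell"] > 10.0).all()

    def test_deterministic_under_seed(self, panel):
        a = simulate_features(panel, {"XYL": 100}, seed=8)
        b = simulate_features(panel, {"XYL": 100}, seed=8)
        assert a.data.equals(b.data)

    def test_unknown_class_rejected(self, panel):
        with pytest.raises(KeyError):
            simulate_features(panel, {"nope": 10}, seed=0)

    def test_saccharide_features_multimodal(self, panel):
        fm = simulate_features(panel, {"D-FRU": 600}, seed=9)
        r = fm.data["ratio"].to_numpy()
        # two sub-states at -0.68 and -0.76 with sd 0.004: no events in between
        assert ((r < -0.72).sum() > 200) and ((r > -0.72).sum() > 200)
        assert ((-0.74 < r) & (r < -0.70)).sum() == 0
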