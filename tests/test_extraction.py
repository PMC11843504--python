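"""Pass assignment, arrival-time line fitting and reconstruction."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cimpass import (
    CompoundRef,
    MobilityExtractor,
    PassObservation,
    assign_pass_numbers,
    extract_series,
    fit_mobility,
    measure_t0,
    reconstruct_tn,
    sample_compounds,
    simulate_series,
    three_point_tp,
)
from cimpass.peaktable import Peak, PeakTable


def _obs(pairs, name="X", adduct="[M+H]+"):
    return [
        PassObservation(name=name, adduct=adduct, n=n, t_n=t, separation_time=0.0)
        for n, t in pairs
    ]


class TestMeasureT0:
    REF = CompoundRef("X", "[M+H]+", 500.0)

    def _zero_table(self, peaks):
        return PeakTable(separation_time=0.01, peaks=peaks)

    def test_reads_matched_arrival_time(self):
        table = self._zero_table([Peak(mz=500.0, intensity=10, arrival_time=6.40)])
        assert measure_t0(table, self.REF) == 6.40

    def test_error_when_no_match(self):
        table = self._zero_table([Peak(mz=501.0, intensity=10, arrival_time=6.4)])
        with pytest.raises(ValueError, match="t0 unavailable"):
            measure_t0(table, self.REF)

    def test_two_peaks_highest_intensity_wins(self):
        # delegates the tie-break to the m/z matcher
        table = self._zero_table(
            [
                Peak(mz=500.000, intensity=10, arrival_time=6.4),
                Peak(mz=500.002, intensity=99, arrival_time=7.7),
            ]
        )
        assert measure_t0(table, self.REF) == 7.7

    def test_wrong_separation_time_rejected(self):
        table = PeakTable(separation_time=5.0, peaks=[Peak(mz=500, intensity=1, arrival_time=6)])
        with pytest.raises(ValueError, match="zero-pass"):
            measure_t0(table, self.REF)


class TestAssignPassNumbers:
    def test_exact_line_assigns_consecutive_passes(self):
        arrivals = [(7, 17.0), (18, 28.0), (29, 39.0), (40, 50.0), (50, 61.0)]
        result = assign_pass_numbers(arrivals, t0=6.0)
        assert [o.n for o in result.observations] == [1, 2, 3, 4, 5]
        assert result.tp_estimate == pytest.approx(11.0)

    def test_single_observation_is_an_error(self):
        with pytest.raises(ValueError, match="cannot assign"):
            assign_pass_numbers([(5, 17.0)], t0=6.0)

    def test_outlier_is_flagged_unassigned(self):
        arrivals = [(7, 17.0), (18, 28.0), (29, 39.0), (33, 43.5), (40, 50.0), (50, 61.0)]
        result = assign_pass_numbers(arrivals, t0=6.0)
        assert result.unassigned == [3]
        assert [o.n for o in result.observations] == [1, 2, 3, 4, 5]

    def test_tp_seed_bypasses_first_pass_heuristic(self):
        arrivals = [(30, 39.0), (40, 50.0), (50, 61.0)]
        result = assign_pass_numbers(arrivals, t0=6.0, tp_seed=11.0)
        assert [o.n for o in result.observations] == [3, 4, 5]

    def test_wrap_around_matches_simulator_ground_truth(self):
        """Two interleaving compounds (tp 10 vs 13): assignments equal the truth."""
        import dataclasses

        compounds = sample_compounds(2, seed=5)
        compounds = [
            dataclasses.replace(compounds[0], true_tp=10.0),
            dataclasses.replace(compounds[1], true_tp=13.0),
        ]
        series, truth = simulate_series(compounds)
        refs = [CompoundRef(c.name, c.adduct, c.mz) for c in compounds]
        for ref, c in zip(refs, compounds):
            t0 = measure_t0(series.zero_pass_table(), ref)
            arrivals, expected_n = [], []
            for T in series.schedule:
                grp = truth[(truth["name"] == c.name) & (truth["separation_time"] == T)]
                if grp.empty:
                    continue
                top = grp.loc[grp["intensity"].idxmax()]
                arrivals.append((T, top["t_observed"]))
                expected_n.append(int(top["n"]))
            result = assign_pass_numbers(arrivals, t0)
            assert result.unassigned == []
            assert [o.n for o in result.observations] == expected_n


class TestFitMobility:
    def test_exact_line(self):
        fit = fit_mobility(_obs([(1, 17.0), (2, 28.0), (3, 39.0), (4, 50.0), (5, 61.0)]))
        assert fit.tp == pytest.approx(11.0)
        assert fit.t0_fitted == pytest.approx(6.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.quality_flag == "ok"

    def test_measured_t0_is_canonical(self):
        fit = fit_mobility(
            _obs([(1, 17.0), (2, 28.0), (3, 39.0), (4, 50.0), (5, 61.0)]), t0_measured=6.05
        )
        assert fit.t0 == 6.05
        assert fit.t0_fitted == pytest.approx(6.0)

    def test_four_passes_flagged_low_pass_count(self):
        fit = fit_mobility(_obs([(1, 17.0), (2, 28.0), (3, 39.0), (4, 50.0)]))
        assert fit.quality_flag == "low_pass_count"
        assert fit.n_passes_used == 4

    def test_fewer_than_two_passes_is_an_error(self):
        with pytest.raises(ValueError, match="2 distinct pass"):
            fit_mobility(_obs([(3, 39.0), (3, 39.1)]))

    def test_per_pass_mean_enters_the_fit(self):
        # pass 2 observed twice; the mean (28.0) must sit on the fitted line
        fit = fit_mobility(_obs([(1, 17.0), (2, 27.0), (2, 29.0), (3, 39.0)]))
        assert fit.tp == pytest.approx(11.0)
        assert fit.t0_fitted == pytest.approx(6.0)

    def test_large_within_pass_dispersion_flags_poor_fit(self):
        # bimodal arrival distribution: same pass, very different arrival times
        fit = fit_mobility(_obs([(1, 17.0), (2, 26.0), (2, 31.0), (3, 39.0), (4, 50.0), (5, 61.0)]))
        assert fit.quality_flag == "poor_fit"

    def test_slope_recovered_within_three_se_over_replicates(self):
        """Monte-Carlo at 0.1% multiplicative noise: mean tp estimate within 3 SE of truth."""
        rng = np.random.default_rng(77)
        t0, tp, n_rep = 6.0, 11.0, 200
        estimates = []
        for _ in range(n_rep):
            ns = np.arange(1, 9)
            ts = (t0 + ns * tp) * (1 + rng.normal(0, 1e-3, ns.size))
            fit = fit_mobility(_obs(zip(ns, ts)))
            estimates.append(fit.tp)
        est = np.asarray(estimates)
        se = est.std(ddof=1) / np.sqrt(n_rep)
        assert abs(est.mean() - tp) < 3 * se


class TestReconstruct:
    def test_arithmetic(self):
        fit = fit_mobility(_obs([(1, 17.0), (2, 28.0)]), t0_measured=6.0)
        assert reconstruct_tn(fit, 9) == pytest.approx(105.0)
        assert reconstruct_tn(fit, 0) == pytest.approx(6.0)

    def test_negative_pass_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_tn((6.0, 11.0), -1)

    @given(
        st.floats(0.1, 30), st.floats(5, 30), st.integers(0, 50)
    )
    def test_telescoping_identity(self, t0, tp, n):
        assert reconstruct_tn((t0, tp), n + 1) - reconstruct_tn((t0, tp), n) == pytest.approx(
            tp, rel=1e-12
        )


class TestThreePoint:
    def test_exact_triple(self):
        res = three_point_tp(2.0, 12.0, 52.0)
        assert (res.n, res.tp) == (5, 10.0)

    def test_near_exact_triple(self):
        res = three_point_tp(2.0, 12.0, 51.8)
        assert res.n == 5
        assert res.tp == pytest.approx(9.96)
        assert res.consistency == pytest.approx(0.02)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            three_point_tp(12.0, 12.0, 52.0)
        with pytest.raises(ValueError, match="at least t1"):
            three_point_tp(2.0, 12.0, 11.0)

    def test_agrees_with_slope_fit_on_noiseless_triples(self, rng):
        """The three-measurement shortcut and the full slope fit coincide without noise."""
        for _ in range(50):
            t0 = rng.uniform(5, 8)
            tp = rng.uniform(10, 14)
            n = rng.integers(2, 11)
            res = three_point_tp(t0, t0 + tp, t0 + n * tp)
            assert res.n == n
            fit = fit_mobility(_obs([(k, t0 + k * tp) for k in range(1, n + 1)]))
            assert res.tp == pytest.approx(fit.tp, rel=1e-9)


class TestEndToEnd:
    def test_noiseless_extraction_recovers_truth_to_machine_precision(self, noiseless_sim):
        compounds, series, _, refs = noiseless_sim
        fits, failures = extract_series(series, refs)
        assert not failures
        by_name = {f.name: f for f in fits}
        for c in compounds:
            fit = by_name[c.name]
            assert fit.tp == pytest.approx(c.true_tp, rel=1e-12)
            assert fit.t0 == pytest.approx(c.true_t0, rel=1e-12)
            assert fit.quality_flag == "ok"

    def test_estimator_api(self, noiseless_sim):
        _, series, _, refs = noiseless_sim
        est = MobilityExtractor(tol_ppm=10.0)
        assert est.get_params()["tol_ppm"] == 10.0
        est.set_params(tol_ppm=12.0).fit(series, refs)
        frame = est.to_frame()
        assert set(frame["name"]) == {r.name for r in refs}
        assert (frame["flag"] == "ok").all()
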