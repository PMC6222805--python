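"""Persistence tracing, residence times and correlation lifetimes."""

import numpy as np
import pytest

import solvgraph as sg
from solvgraph.errors import AnalysisError


def _presence_graphs(present, n_frames=None):
    """Graphs where one site-partner edge exists in the given frames."""
    sv, pv = sg.SiteVertex(0, "O9", 1), sg.SiteVertex(1, "H1", 10)
    n = n_frames if n_frames is not None else (max(present) + 1 if present else 1)
    return [sg.FrameGraph(t, [sv, pv],
                          [sg.GraphEdge(sv, pv, 0.2)] if t in present else [])
            for t in range(n)]


class TestTracePersistence:
    def test_full_length_event_is_both_censored(self):
        events = sg.trace_persistence(_presence_graphs(set(range(10))), "O9")
        assert len(events) == 1
        e = events[0]
        assert e.length == 10 and e.left_censored and e.right_censored

    def test_single_absence_splits_runs(self):
        events = sg.trace_persistence(_presence_graphs({0, 1, 2, 4, 5}), "O9")
        assert [e.length for e in events] == [3, 2]
        assert events[0].left_censored and not events[0].right_censored
        assert events[1].right_censored

    def test_gap_tolerance_merges_runs(self):
        graphs = _presence_graphs({0, 1, 2, 4, 5})
        events = sg.trace_persistence(graphs, "O9", gap_tolerance=1)
        assert [e.length for e in events] == [6]  # tolerated gap counts

    def test_unknown_site_raises(self):
        with pytest.raises(AnalysisError):
            sg.trace_persistence(_presence_graphs({0}), "nope")

    def test_geometric_run_lengths_recovered(self):
        """With per-frame break probability p the mean run length is 1/p."""
        p = 0.2
        params = sg.SyntheticParams(n_waters=40, n_frames=15000,
                                    unbind_prob=p, bind_prob=0.4, seed=12)
        graphs = sg.graphs_from_states(sg.simulate_occupancy(params))
        events = []
        for site in sg.SITE_LABELS:
            events += sg.trace_persistence(graphs, site,
                                           partner_mode="molecule")
        events = [e for e in events
                  if not (e.left_censored or e.right_censored)]
        assert len(events) >= 10_000
        assert np.mean([e.length for e in events]) == pytest.approx(1 / p,
                                                                    rel=0.05)

    def test_molecule_mode_survives_hydrogen_swap(self):
        """A hydrogen swap ends the hydrogen-label run but not the
        molecule-ID run."""
        sv = sg.SiteVertex(0, "O9", 1)
        h1 = sg.SiteVertex(1, "H1", 11)
        h2 = sg.SiteVertex(1, "H2", 12)
        graphs = [sg.FrameGraph(t, [sv, h1, h2],
                                [sg.GraphEdge(sv, h1 if t < 3 else h2, 0.2)])
                  for t in range(6)]
        hyd = sg.trace_persistence(graphs, "O9", partner_mode="hydrogen")
        mol = sg.trace_persistence(graphs, "O9", partner_mode="molecule")
        assert sorted(e.length for e in hyd) == [3, 3]
        assert [e.length for e in mol] == [6]


class TestResidenceTime:
    def _events(self, lengths):
        return [sg.PersistenceEvent("O9", k, 0, n) for k, n in enumerate(lengths)]

    def test_mean_of_durations(self):
        summ = sg.residence_time(self._events([2, 2, 4]), 0.5, correction=1)
        assert summ.mean_lifetime == pytest.approx(8 / 3 * 0.5)

    def test_doubling_convention(self):
        summ = sg.residence_time(self._events([2, 2, 4]), 0.5, correction=2)
        assert summ.mean_lifetime == pytest.approx(8 / 3)
        auto = sg.residence_time(self._events([2, 2, 4]), 0.5,
                                 correction="auto", partner_mode="hydrogen")
        assert auto.correction == 2.0
        assert auto.mean_lifetime == summ.mean_lifetime

    def test_empty_events_undefined(self):
        with pytest.raises(AnalysisError):
            sg.residence_time([], 0.5)

    def test_equals_histogram_weighted_formulation(self):
        """The per-event mean equals sum_t t * P(t) over the duration
        histogram: the two printed formulations are one estimator."""
        rng = np.random.default_rng(8)
        for _ in range(50):
            lengths = rng.integers(1, 30, size=rng.integers(1, 200)).tolist()
            summ = sg.residence_time(self._events(lengths), 0.5, correction=1)
            durations = np.array(lengths) * 0.5
            vals, cnt = np.unique(durations, return_counts=True)
            weighted = float((vals * cnt / cnt.sum()).sum())
            assert summ.mean_lifetime == pytest.approx(weighted)
            assert sum(summ.histogram.values()) == pytest.approx(1.0)

    def test_markov_parameter_recovery(self):
        """Molecule-mode residence time converges to the generator's mean
        bound time 1/p frames."""
        params = sg.SyntheticParams(n_waters=40, n_frames=10000,
                                    unbind_prob=0.25, bind_prob=0.4, seed=2)
        graphs = sg.graphs_from_states(sg.simulate_occupancy(params))
        events = []
        for site in sg.SITE_LABELS:
            events += sg.trace_persistence(graphs, site, partner_mode="molecule")
        summ = sg.residence_time(events, params.frame_interval,
                                 correction="auto", partner_mode="molecule",
                                 include_censored=False)
        expect = params.frame_interval / params.unbind_prob
        assert summ.mean_lifetime == pytest.approx(expect, rel=0.05)

    def test_hydrogen_mode_doubled_matches_molecule_mode(self):
        """With balanced hydrogen swapping, doubling the hydrogen-traced
        lifetime reproduces the molecule-traced lifetime."""
        params = sg.SyntheticParams(n_waters=40, n_frames=15000,
                                    unbind_prob=0.2, bind_prob=0.4, seed=4)
        graphs = sg.graphs_from_states(sg.simulate_occupancy(params))
        hyd, mol = [], []
        for site in sg.SITE_LABELS:
            hyd += sg.trace_persistence(graphs, site, partner_mode="hydrogen")
            mol += sg.trace_persistence(graphs, site, partner_mode="molecule")
        t_h = sg.residence_time(hyd, 0.5, correction=2,
                                include_censored=False).mean_lifetime
        t_m = sg.residence_time(mol, 0.5, correction=1,
                                include_censored=False).mean_lifetime
        assert t_h == pytest.approx(t_m, rel=0.07)


class TestCorrelation:
    def test_permanent_bond_is_unity(self):
        s = np.ones((1, 100), dtype=bool)
        series = sg.hb_correlation(s, 0.5)
        assert series.values[0] == 1.0
        assert (series.values == 1.0).all()

    def test_bond_only_at_origin_decays_to_zero(self):
        s = np.zeros((1, 200), dtype=bool)
        s[0, 0] = True
        series = sg.hb_correlation(s, 0.5)
        assert series.values[0] == 1.0
        assert (series.values[1:] == 0.0).all()

    def test_never_bonded_is_undefined(self):
        with pytest.raises(AnalysisError):
            sg.hb_correlation(np.zeros((3, 50), dtype=bool), 0.5)

    def test_matches_direct_double_loop(self):
        """FFT evaluation equals the literal double loop over origins."""
        rng = np.random.default_rng(5)
        s = rng.random((4, 120)) < 0.4
        series = sg.hb_correlation(s, 0.5, max_lag=20.0)
        for lag_idx in [0, 1, 7, 23, 40]:
            num = sum(int(s[p, t] and s[p, t + lag_idx])
                      for p in range(4) for t in range(120 - lag_idx))
            den = sum(int(s[p, t]) for p in range(4)
                      for t in range(120 - lag_idx))
            assert series.values[lag_idx] == pytest.approx(num / den)

    def test_markov_chain_analytic_decay(self):
        """C_HB of a two-state Markov pair matches pi + (1-pi) lambda^t."""
        rng = np.random.default_rng(10)
        p_off, p_on = 0.08, 0.04
        T, n_pairs = 6000, 40
        s = np.zeros((n_pairs, T), dtype=bool)
        state = rng.random(n_pairs) < p_on / (p_on + p_off)
        for t in range(T):
            r = rng.random(n_pairs)
            state = np.where(state, r >= p_off, r < p_on)
            s[:, t] = state
        series = sg.hb_correlation(s, 0.5, max_lag=25.0)
        lam = 1 - p_on - p_off
        pi = p_on / (p_on + p_off)
        analytic = pi + (1 - pi) * lam ** (series.lags / 0.5)
        assert np.abs(series.values - analytic).max() < 0.03


class TestIntegrateLifetime:
    def test_constant_series_integrates_to_span(self):
        lags = np.arange(0, 10.5, 0.5)
        series = sg.CorrelationSeries(lags, np.ones_like(lags),
                                      np.ones_like(lags), 0.5)
        est = sg.integrate_lifetime(series)
        assert est.lifetime == pytest.approx(10.0)
        assert est.truncation_lag == pytest.approx(10.0)

    def test_exponential_recovers_tau(self):
        tau = 2.0
        lags = np.arange(0, 40 * tau, 0.01)
        series = sg.CorrelationSeries(lags, np.exp(-lags / tau),
                                      np.ones_like(lags), 0.01)
        assert sg.integrate_lifetime(series).lifetime == pytest.approx(tau,
                                                                       rel=0.02)

    def test_single_lag_has_no_area(self):
        series = sg.CorrelationSeries(np.array([0.0]), np.array([1.0]),
                                      np.array([5]), 0.5)
        assert sg.integrate_lifetime(series).lifetime == 0.0


def test_continuous_lifetime_below_intermittent_with_rebinding():
    """On a series with rebinding, the continuous-persistence lifetime is at
    most the intermittent correlation lifetime."""
    params = sg.SyntheticParams(n_waters=30, n_frames=6000, unbind_prob=0.3,
                                bind_prob=0.5, seed=14)
    graphs = sg.graphs_from_states(sg.simulate_occupancy(params))
    cont, inter = [], []
    for site in sg.SITE_LABELS:
        events = sg.trace_persistence(graphs, site, partner_mode="molecule")
        cont.append(sg.residence_time(events, 0.5, correction=1).mean_lifetime)
        states = sg.pair_state_series(graphs, site, partner_mode="molecule")
        series = sg.hb_correlation(states, 0.5, max_lag=100.0)
        inter.append(sg.integrate_lifetime(series).lifetime)
    assert np.mean(cont) <= np.mean(inter)
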