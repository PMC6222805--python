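"""Hydrogen-bond persistence, residence times and correlation lifetimes.

Two counting conventions are supported when tracing a site's contacts:

* hydrogen mode — the partner is the individual water hydrogen, so a bound
  water that swaps which hydrogen points at the site terminates one run and
  starts another.  Mean lifetimes in this mode are conventionally doubled,
  because a bound water spends on average half its residence on each
  hydrogen.
* molecule mode — the partner is the water molecule ID, so hydrogen swaps do
  not interrupt a run and the run length is the true residence time of the
  water at the site.

A "continuous persistence" run is a maximal uninterrupted stretch of frames;
by default a single absent frame terminates a run (zero gap tolerance, with a
configurable tolerance).  The intermittent correlation function C_HB(t)
instead asks whether a pair bonded at t0 is bonded again at t0+t regardless
of what happened in between; its time integral is the correlation-function
lifetime, which on any series with rebinding is at least as long as the
continuous-persistence lifetime.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Mapping, NamedTuple, Sequence

import numpy as np

from .errors import AnalysisError
from .graphs import FrameGraph, SiteVertex

__all__ = [
    "PersistenceEvent", "ResidenceTimeSummary", "CorrelationSeries",
    "trace_persistence", "residence_time", "pair_state_series",
    "hb_correlation", "integrate_lifetime", "LifetimeEstimate",
]


@dataclass(frozen=True)
class PersistenceEvent:
    """One maximal uninterrupted run of a site-partner contact."""

    site: str
    partner: Hashable
    start_frame: int
    length: int  # frames, >= 1
    left_censored: bool = False
    right_censored: bool = False


def trace_persistence(graphs: Sequence[FrameGraph], site: str,
                      partner_mode: str = "hydrogen",
                      gap_tolerance: int = 0) -> list[PersistenceEvent]:
    """Trace maximal contact runs of one site along a graph sequence.

    partner_mode "hydrogen" keys runs by the partner vertex (an individual
    water hydrogen); "molecule" keys them by the partner molecule index, so
    the run survives a hydrogen swap.  A gap of more than ``gap_tolerance``
    absent frames terminates a run (default 0: any absence terminates);
    tolerated gap frames count toward the run length.  Events touching the
    first or last frame are flagged censored.
    """
    if partner_mode not in ("hydrogen", "molecule"):
        raise ValueError("partner_mode must be 'hydrogen' or 'molecule'")
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if not graphs:
        raise AnalysisError("trace_persistence needs at least one frame")
    v = graphs[0].find_site(site)
    present: dict[Hashable, list[int]] = {}
    for t, g in enumerate(graphs):
        for w in g.neighbors(v):
            key: Hashable = w if partner_mode == "hydrogen" else w.mol
            present.setdefault(key, []).append(t)
    n_frames = len(graphs)
    events: list[PersistenceEvent] = []
    for key in sorted(present, key=repr):
        frames = present[key]
        start = frames[0]
        prev = frames[0]
        for t in frames[1:] + [None]:
            if t is None or t - prev > gap_tolerance + 1:
                events.append(PersistenceEvent(
                    site, key, start, prev - start + 1,
                    left_censored=(start == 0),
                    right_censored=(prev == n_frames - 1)))
                if t is not None:
                    start = t
            if t is not None:
                prev = t
    events.sort(key=lambda e: (e.start_frame, repr(e.partner)))
    return events


@dataclass
class ResidenceTimeSummary:
    """Mean lifetime of one site's contacts plus the duration histogram."""

    site: str
    mean_lifetime: float           # ps, correction applied
    event_count: int
    histogram: dict[float, float]  # duration (ps) -> occurrence probability P(t_i)
    correction: float
    frame_interval: float

    def validate(self) -> None:
        total = sum(self.histogram.values())
        if abs(total - 1.0) > 1e-9:
            raise AnalysisError("P(t_i) does not sum to 1")


def residence_time(events: Sequence[PersistenceEvent],
                   frame_interval: float = 0.5,
                   correction: float | str = "auto",
                   partner_mode: str | None = None,
                   include_censored: bool = True) -> ResidenceTimeSummary:
    """Mean contact lifetime, i.e. the average persistence weighted by the
    occurrence probability P(t_i) of each duration.

    ``correction="auto"`` applies the doubling convention (factor 2) when
    ``partner_mode`` is "hydrogen" and 1 otherwise.  Censored events (runs
    touching a trajectory end) are included by default.
    """
    if correction == "auto":
        correction = 2.0 if partner_mode == "hydrogen" else 1.0
    correction = float(correction)
    kept = [e for e in events
            if include_censored or not (e.left_censored or e.right_censored)]
    if not kept:
        raise AnalysisError("residence time undefined: no events")
    durations = np.array([e.length for e in kept], dtype=float) * frame_interval
    values, counts = np.unique(durations, return_counts=True)
    probs = counts / counts.sum()
    # the two formulations coincide: mean over events == sum_t t * P(t)
    mean = float((values * probs).sum()) * correction
    site = kept[0].site
    return ResidenceTimeSummary(site, mean, len(kept),
                                dict(zip(values.tolist(), probs.tolist())),
                                correction, frame_interval)


# ---------------------------------------------------------------------------
# Correlation-function lifetimes

def pair_state_series(graphs: Sequence[FrameGraph], site: str,
                      partner_mode: str = "hydrogen") -> np.ndarray:
    """Boolean presence matrix (n_partners, n_frames) of one site's contacts."""
    if not graphs:
        raise AnalysisError("need at least one frame")
    v = graphs[0].find_site(site)
    keys: dict[Hashable, int] = {}
    rows: list[tuple[int, int]] = []
    for t, g in enumerate(graphs):
        for w in g.neighbors(v):
            key: Hashable = w if partner_mode == "hydrogen" else w.mol
            if key not in keys:
                keys[key] = len(keys)
            rows.append((keys[key], t))
    states = np.zeros((max(len(keys), 1), len(graphs)), dtype=bool)
    for i, t in rows:
        states[i, t] = True
    return states


@dataclass
class CorrelationSeries:
    """Intermittent hydrogen-bond correlation function C_HB(t)."""

    lags: np.ndarray       # ps, ascending, lags[0] == 0
    values: np.ndarray     # C_HB at each lag, in [0, 1], values[0] == 1
    n_samples: np.ndarray  # bonded origins contributing at each lag
    frame_interval: float


def hb_correlation(pair_states: Mapping[Hashable, Sequence[bool]] | np.ndarray,
                   frame_interval: float = 0.5,
                   max_lag: float | None = None) -> CorrelationSeries:
    """Intermittent correlation C_HB(t) = <s(t0) s(t0+t)> / <s(t0)^2>.

    ``pair_states`` holds one boolean bonded/unbonded series per donor-
    acceptor pair on a common frame grid (mapping or 2-D array).  Every frame
    serves as a time origin; the normalization restricts origins to those
    valid for each lag, so a permanently bonded pair gives C_HB == 1.
    ``max_lag`` is in ps and defaults to half the trajectory.
    """
    if isinstance(pair_states, Mapping):
        series = np.asarray([np.asarray(s, dtype=bool)
                             for s in pair_states.values()])
    else:
        series = np.atleast_2d(np.asarray(pair_states, dtype=bool))
    if series.size == 0 or not series.any():
        raise AnalysisError("C_HB undefined: no pair is ever bonded")
    n_pairs, n_frames = series.shape
    if max_lag is None:
        n_lags = max(n_frames // 2, 1)
    else:
        n_lags = min(int(round(max_lag / frame_interval)) + 1, n_frames)
    s = series.astype(float)
    # numerator via FFT autocorrelation, summed over pairs
    nfft = 1 << (2 * n_frames - 1).bit_length()
    f = np.fft.rfft(s, n=nfft, axis=1)
    ac = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :n_lags].sum(axis=0)
    # denominator: bonded origins t0 <= n_frames-1-lag, summed over pairs
    prefix = np.cumsum(s.sum(axis=0))  # prefix[t] = bonded origins in frames 0..t
    denom = prefix[n_frames - 1 - np.arange(n_lags)]
    valid = denom > 0
    values = np.zeros(n_lags)
    values[valid] = np.round(ac[valid]) / denom[valid]
    values = np.clip(values, 0.0, 1.0)
    lags = np.arange(n_lags) * frame_interval
    return CorrelationSeries(lags, values, denom.astype(np.int64),
                             frame_interval)


class LifetimeEstimate(NamedTuple):
    """Integrated correlation lifetime and the lag at which it was truncated."""

    lifetime: float        # ps
    truncation_lag: float  # ps


def integrate_lifetime(series: CorrelationSeries) -> LifetimeEstimate:
    """Trapezoidal integral of C_HB over the available lags (ps)."""
    if series.lags.size == 0:
        raise AnalysisError("empty correlation series")
    if series.lags.size == 1:
        return LifetimeEstimate(0.0, float(series.lags[0]))
    life = float(np.trapezoid(series.values, series.lags))
    return LifetimeEstimate(life, float(series.lags[-1]))
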