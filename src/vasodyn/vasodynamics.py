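"""ΔF/F conversion, vasospasm detection, and vessel-dynamics metrics.

A vasospasm appears in a lumen-dye recording as a transient drop in a
vessel's fluorescence.  The detector is scale-free and objective: the
noise scale is estimated robustly (median absolute deviation), candidate
events are samples below −k·σ, and each event's extent is grown to the
half-threshold crossings (hysteresis).  Event magnitude and phase
durations come from a per-event least-squares trapezoid fit, which is
near-unbiased in the presence of noise (a raw-minimum magnitude is biased
deep by the expected extremum of the noise over the trough and is exposed
separately as ``trough_dff``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from . import stats as vstats
from .synthio import VesselTrace

__all__ = [
    "VasospasmEvent",
    "VesselMetrics",
    "CohortMetrics",
    "compute_dff",
    "detect_vasospasms",
    "analyze_trace",
    "vessel_metrics",
    "cohort_summary",
    "metrics_frame",
]

MAD_TO_SIGMA = 1.4826  # consistency constant for Gaussian noise


@dataclass(frozen=True)
class VasospasmEvent:
    """One detected constriction episode.

    All times in seconds on the trace's clock.  ``magnitude`` is the peak
    fractional ΔF/F drop in percent (trapezoid-fit plateau depth);
    ``onset_time`` and ``termination_time`` are the fitted onset and
    recovery phase durations.  ``trough_dff`` is the raw (smoothed) minimum
    ΔF/F within the event, in percent, kept for diagnostics.
    """

    onset_t: float
    trough_t: float
    end_t: float
    magnitude: float
    onset_time: float
    termination_time: float
    trough_dff: float = 0.0

    def __post_init__(self):
        if not (self.onset_t <= self.trough_t <= self.end_t):
            raise ValueError("event requires onset_t <= trough_t <= end_t")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")

    @property
    def duration(self) -> float:
        return self.end_t - self.onset_t


@dataclass
class VesselMetrics:
    """Per-vessel summary of detected vasospasm activity."""

    vessel_id: str
    animal_id: str
    cohort: str
    recording_hours: float
    n_events: int
    rate: float                 # events / hour
    likelihood: float           # percent of recording time in spasm
    spasm_seconds: float
    mean_magnitude: float = np.nan
    mean_duration: float = np.nan
    mean_onset_time: float = np.nan
    mean_termination_time: float = np.nan


@dataclass
class CohortMetrics:
    """Cohort-level means ± s.e.m. and two-sample comparisons.

    ``summaries`` maps cohort → metric → (mean, sem, n); ``comparisons``
    maps metric → :class:`~vasodyn.stats.TestResult`; ``units`` records the
    unit of analysis (vessel / animal / event) used for each comparison.
    """

    summaries: dict
    comparisons: dict
    units: dict
    fraction_of_vessels: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ΔF/F
# ---------------------------------------------------------------------------

def compute_dff(trace: VesselTrace, baseline_window: float = 600.0,
                exclude: np.ndarray | None = None) -> np.ndarray:
    """Fractional fluorescence change against a running-median baseline.

    ``ΔF/F_t = (F_t − F0_t)/F0_t`` with ``F0`` the centered running median
    over ``baseline_window`` seconds, truncated at the trace edges.  The
    result is invariant to rescaling the fluorescence.  ``exclude`` is an
    optional boolean mask of samples (detected events) to leave out of the
    baseline, which removes the downward pull events exert on a plain
    running median.  Raises if the baseline is non-positive anywhere
    (degenerate recording).
    """
    dt = trace.sample_interval
    if baseline_window < 10 * dt:
        raise ValueError("baseline_window must span at least 10 samples")
    f = np.asarray(trace.fluorescence, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("fluorescence contains non-finite values")
    w = int(round(baseline_window / dt))
    fs = pd.Series(f)
    if exclude is not None:
        fs = fs.mask(np.asarray(exclude, dtype=bool))
    f0 = fs.rolling(w, center=True, min_periods=1).median()
    f0 = f0.ffill().bfill().to_numpy()
    if np.any(~np.isfinite(f0)) or np.any(f0 <= 0):
        raise ValueError("running-median baseline is non-positive; invalid trace")
    return (f - f0) / f0


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs; stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return list(zip(idx[::2], idx[1::2]))


def _trapezoid(t, t0, w_on, w_pl, w_term, depth):
    t1, t2 = t0 + w_on, t0 + w_on + w_pl
    t3 = t2 + w_term
    out = np.zeros_like(t)
    if w_on > 0:
        m = (t >= t0) & (t < t1)
        out[m] = (t[m] - t0) / w_on
    m = (t >= t1) & (t <= t2)
    out[m] = 1.0
    if w_term > 0:
        m = (t > t2) & (t <= t3)
        out[m] = (t3 - t[m]) / w_term
    return -depth * out


def _fit_trapezoid(t, y, t_on, t_end, dt):
    """Least-squares trapezoid fit on a padded window around one event."""
    pad = max(5.0, 0.2 * (t_end - t_on))
    sel = (t >= t_on - pad) & (t <= t_end + pad)
    tw, yw = t[sel], y[sel]
    depth0 = max(-yw.min(), 1e-6)
    # initial plateau: samples deeper than 90% of the minimum
    deep = yw <= -0.9 * depth0
    if deep.any():
        t1_0 = float(tw[deep][0])
        t2_0 = float(tw[deep][-1])
    else:  # pragma: no cover - defensive
        t1_0 = t2_0 = float(tw[np.argmin(yw)])
    x0 = np.array([t_on, max(t1_0 - t_on, dt), max(t2_0 - t1_0, dt),
                   max(t_end - t2_0, dt), depth0])
    lb = [tw[0], 0.0, 0.0, 0.0, 0.0]
    ub = [tw[-1], tw[-1] - tw[0], tw[-1] - tw[0], tw[-1] - tw[0], np.inf]
    x0 = np.clip(x0, lb, ub)

    def resid(x):
        return _trapezoid(tw, *x) - yw

    try:
        res = optimize.least_squares(resid, x0, bounds=(lb, ub), xtol=1e-10)
        return res.x
    except Exception:  # pragma: no cover - defensive
        return x0


def detect_vasospasms(
    dff: np.ndarray,
    time: np.ndarray | None = None,
    *,
    sample_interval: float = 1.0,
    k_sigma: float = 3.0,
    min_duration: float = 10.0,
    smooth_window: float = 9.0,
) -> list[VasospasmEvent]:
    """Detect vasospasms in a ΔF/F series.

    Noise scale σ is the MAD of the series × 1.4826; candidate events are
    samples below −k·σ, grown by hysteresis to the −k·σ/2 crossings, merged
    when separated by less than ``min_duration`` (so one noise sample cannot
    split an episode), and discarded when shorter than ``min_duration``.  The
    trough is the minimum of a lightly smoothed series within the event.
    """
    dff = np.asarray(dff, dtype=float)
    if dff.size == 0 or not np.all(np.isfinite(dff)):
        raise ValueError("dff must be non-empty and finite")
    if k_sigma <= 0:
        raise ValueError("k_sigma must be positive")
    if time is None:
        time = np.arange(dff.size) * sample_interval
    else:
        time = np.asarray(time, dtype=float)
        sample_interval = float(time[1] - time[0]) if time.size > 1 else sample_interval

    sigma = MAD_TO_SIGMA * np.median(np.abs(dff - np.median(dff)))
    if sigma == 0.0:
        sigma = np.finfo(float).tiny  # noiseless trace: any dip triggers
    thr, half = -k_sigma * sigma, -k_sigma * sigma / 2.0

    below_half = dff < half
    candidates = _runs(dff < thr)
    half_runs = _runs(below_half)
    # map each candidate to its enclosing half-threshold run (hysteresis growth)
    events_idx = []
    for (cs, ce) in candidates:
        for (hs, he) in half_runs:
            if hs <= cs and ce <= he:
                if not events_idx or events_idx[-1] != (hs, he):
                    events_idx.append((hs, he))
                break
    # bridge sub-min_duration gaps between grown runs: one noise sample
    # popping above the hysteresis level must not split a single episode
    gap = max(int(round(min_duration / sample_interval)), 1)
    merged: list[tuple[int, int]] = []
    for (s, e) in events_idx:
        if merged and s - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    events_idx = merged

    w = max(int(round(smooth_window / sample_interval)), 1)
    kernel = np.ones(w) / w
    smoothed = np.convolve(dff, kernel, mode="same")

    out: list[VasospasmEvent] = []
    for (s, e) in events_idx:
        dur = (e - s) * sample_interval
        if dur < min_duration:
            continue
        seg = smoothed[s:e]
        trough_i = s + int(np.argmin(seg))
        t_on, t_end = float(time[s]), float(time[e - 1] + sample_interval)
        t0, w_on, w_pl, w_term, depth = _fit_trapezoid(time, dff, t_on, t_end,
                                                       sample_interval)
        # magnitude: mean ΔF/F over the fitted plateau interior when the
        # plateau is long enough (unbiased; the LS depth itself carries a
        # small shallow bias from the nonlinear breakpoints at low SNR)
        t1, t2 = t0 + w_on, t0 + w_on + w_pl
        interior = (time >= t1 + sample_interval) & (time <= t2 - sample_interval)
        if interior.sum() >= 3 and np.mean(dff[interior]) < 0:
            depth = -float(np.mean(dff[interior]))
        if depth <= 0:  # degenerate fit; fall back to the smoothed trough
            depth = -float(seg.min())
        if depth <= 0:
            continue  # not a genuine dip
        # event extent = fitted trapezoid support (near-unbiased against the
        # hysteresis crossings, which sit inside the true ramps), clipped to
        # the trace and forced to contain the trough sample
        t3 = t0 + w_on + w_pl + w_term
        onset = min(max(float(t0), float(time[0])), float(time[trough_i]))
        end = max(min(float(t3), float(time[-1] + sample_interval)),
                  float(time[trough_i]))
        out.append(VasospasmEvent(
            onset_t=onset,
            trough_t=float(time[trough_i]),
            end_t=end,
            magnitude=float(depth * 100.0),
            onset_time=float(w_on),
            termination_time=float(w_term),
            trough_dff=float(-seg.min() * 100.0),
        ))
    # fitted supports of neighbouring events may touch; trim at midpoints so
    # the non-overlap contract holds
    for a, b in zip(out, out[1:]):
        if b.onset_t < a.end_t:
            mid = 0.5 * (a.trough_t + b.trough_t)
            object.__setattr__(a, "end_t", min(a.end_t, mid))
            object.__setattr__(b, "onset_t", max(b.onset_t, mid))
    return out


def analyze_trace(trace: VesselTrace, *, baseline_window: float = 600.0,
                  k_sigma: float = 3.0, min_duration: float = 10.0,
                  smooth_window: float = 9.0, max_passes: int = 5) -> list[VasospasmEvent]:
    """ΔF/F conversion plus iterative masked-baseline vasospasm detection.

    The first pass detects events on a plain running-median ΔF/F.  Each
    further pass recomputes the baseline with every sample so far flagged
    as an event masked out (events no longer drag the median down, which
    also rescues events in dense clusters that a single pass hides) and
    re-runs detection on the corrected series.  Iteration stops when the
    flagged-sample set stops growing.  This is the entry point the
    pipeline uses.
    """
    pad = 2.0 * smooth_window  # cover ramp tails the fits may miss
    mask = np.zeros(trace.time.size, dtype=bool)
    events: list[VasospasmEvent] = []
    for _ in range(max_passes):
        dff = compute_dff(trace, baseline_window,
                          exclude=mask if mask.any() else None)
        events = detect_vasospasms(dff, trace.time, k_sigma=k_sigma,
                                   min_duration=min_duration,
                                   smooth_window=smooth_window)
        new_mask = mask.copy()
        for ev in events:
            new_mask |= ((trace.time >= ev.onset_t - pad)
                         & (trace.time < ev.end_t + pad))
        if new_mask.sum() == mask.sum():
            break
        mask = new_mask
    return events


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def vessel_metrics(events: list[VasospasmEvent], trace: VesselTrace) -> VesselMetrics:
    """Rate (events/hour) and likelihood (% of recording time in spasm)."""
    dur_total = trace.recording_duration
    ev = sorted(events, key=lambda e: e.onset_t)
    for a, b in zip(ev, ev[1:]):
        if b.onset_t < a.end_t:
            raise ValueError("overlapping events violate the detector contract")
    for e in ev:
        if e.onset_t < trace.time[0] or e.end_t > trace.time[-1] + trace.sample_interval:
            raise ValueError("event outside trace extent")
    hours = dur_total / 3600.0
    spasm_s = float(sum(e.duration for e in ev))
    mm = VesselMetrics(
        vessel_id=trace.vessel_id,
        animal_id=trace.animal_id,
        cohort=trace.cohort,
        recording_hours=hours,
        n_events=len(ev),
        rate=len(ev) / hours,
        likelihood=100.0 * spasm_s / dur_total,
        spasm_seconds=spasm_s,
    )
    if ev:
        mm.mean_magnitude = float(np.mean([e.magnitude for e in ev]))
        mm.mean_duration = float(np.mean([e.duration for e in ev]))
        mm.mean_onset_time = float(np.mean([e.onset_time for e in ev]))
        mm.mean_termination_time = float(np.mean([e.termination_time for e in ev]))
    return mm


def metrics_frame(metrics: list[VesselMetrics]) -> pd.DataFrame:
    """Per-vessel metrics as a tidy DataFrame."""
    return pd.DataFrame([vars(m) for m in metrics])


_DEFAULT_UNITS = {
    "rate": "vessel",
    "likelihood": "vessel",
    "mean_magnitude": "vessel",
    "mean_duration": "vessel",
    "mean_onset_time": "vessel",
    "mean_termination_time": "vessel",
    "fraction_of_vessels": "animal",
}


def cohort_summary(metrics: list[VesselMetrics],
                   units: dict | None = None) -> CohortMetrics:
    """Cohort means ± s.e.m. with two-sample comparisons.

    The unit of analysis per comparison (vessel or animal) is explicit and
    recorded in the result; by default rate/likelihood and the per-event
    summaries compare at the vessel level and the fraction-of-vessels
    statistic at the animal level (averaged within each animal first).
    With more than two cohorts only summaries are produced; single-unit
    cohorts skip comparison with a warning.
    """
    units = {**_DEFAULT_UNITS, **(units or {})}
    df = metrics_frame(metrics)
    cohorts = sorted(df["cohort"].unique())
    measures = ["rate", "likelihood", "mean_magnitude", "mean_duration",
                "mean_onset_time", "mean_termination_time"]

    summaries: dict = {}
    fractions: dict = {}
    for c in cohorts:
        sub = df[df["cohort"] == c]
        summaries[c] = {}
        for m in measures:
            vals = sub[m].dropna().to_numpy()
            n = vals.size
            summaries[c][m] = {
                "mean": float(vals.mean()) if n else np.nan,
                "sem": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                "n": int(n),
            }
        # pooled likelihood across vessels (time-weighted), kept alongside
        summaries[c]["pooled_likelihood"] = {
            "mean": float(100.0 * sub["spasm_seconds"].sum()
                          / (sub["recording_hours"].sum() * 3600.0)),
            "sem": np.nan,
            "n": int(len(sub)),
        }
        per_animal = sub.groupby("animal_id")["n_events"].apply(
            lambda s: 100.0 * (s > 0).mean())
        fractions[c] = {
            "per_animal": per_animal.to_dict(),
            "mean": float(per_animal.mean()),
            "sem": float(per_animal.std(ddof=1) / np.sqrt(len(per_animal)))
            if len(per_animal) > 1 else np.nan,
        }

    comparisons: dict = {}
    if len(cohorts) == 2:
        ca, cb = cohorts
        for m in measures:
            unit = units.get(m, "vessel")
            xa, xb = _unit_values(df, ca, m, unit), _unit_values(df, cb, m, unit)
            if len(xa) < 2 or len(xb) < 2:
                warnings.warn(f"cohort comparison for {m!r} skipped: "
                              "fewer than two units in a cohort")
                continue
            comparisons[m] = vstats.two_sample_t(xa, xb)
        fa = np.array(list(fractions[ca]["per_animal"].values()))
        fb = np.array(list(fractions[cb]["per_animal"].values()))
        if fa.size >= 2 and fb.size >= 2:
            comparisons["fraction_of_vessels"] = vstats.two_sample_t(fa, fb)
        else:
            warnings.warn("fraction-of-vessels comparison skipped: "
                          "fewer than two animals in a cohort")
    return CohortMetrics(summaries, comparisons,
                         {m: units.get(m, "vessel")
                          for m in measures + ["fraction_of_vessels"]},
                         fractions)


def _unit_values(df: pd.DataFrame, cohort: str, measure: str, unit: str) -> np.ndarray:
    sub = df[df["cohort"] == cohort]
    if unit == "animal":
        return sub.groupby("animal_id")[measure].mean().dropna().to_numpy()
    return sub[measure].dropna().to_numpy()
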