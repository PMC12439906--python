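"""Halide-sensor quench kinetics and short-circuit-current extraction.

The hYFP:mKate ratio of a cell expressing active CFTR decays after iodide
addition as

    y(t) = y0 + A1 * exp(-k1 * t)

where y0 is the baseline ratio at t -> infinity, fixed during fitting to the
pre-quench plateau measured before iodide addition; A1 is the amplitude and
k1 the observed rate constant. Replicate traces of one condition are fit
globally: one shared k1, one amplitude per replicate. The quenching
half-life is t_1/2 = ln(2) / k1.

Ussing-chamber traces are reduced to delta-I_SC: the signed difference
between a pre-event baseline and the level of a stable post-event plateau
sustained for at least five minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


@dataclass
class DecayFit:
    """Parameters of the global exponential quench fit."""

    y0: float
    k1: float
    amplitudes: dict[str, float]
    t_half: float
    rss: float
    n_obs: int
    converged: bool
    at_bound: bool = False  # k1 pinned at zero (no measurable decay)

    @property
    def A1(self) -> float:
        """Amplitude (mean over replicates when fit globally)."""
        return float(np.mean(list(self.amplitudes.values())))


def half_life(k1: float) -> float:
    """t_1/2 = ln(2)/k1; undefined (NaN) for k1 = 0."""
    if k1 < 0:
        raise ValueError("k1 must be >= 0")
    if k1 == 0:
        return math.nan
    return math.log(2.0) / k1


def _bin_medians(t: np.ndarray, y: np.ndarray, width: float) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(t)
    t, y = t[order], y[order]
    bins = np.floor(t / width).astype(int)
    tb, yb = [], []
    for b in np.unique(bins):
        m = bins == b
        tb.append(t[m].mean())
        yb.append(float(np.median(y[m])))
    return np.asarray(tb), np.asarray(yb)


def fit_quench_global(
    traces: pd.DataFrame,
    y0_fixed: float,
    bin_width: float | None = 5.0,
    shared_k1: bool = True,
) -> DecayFit:
    """Global least-squares fit of the quench decay with y0 held fixed.

    ``traces`` has columns ``time``, ``value`` and optionally ``replicate``;
    observations at t < 0 (pre-quench) are excluded from the fit. k1 is
    shared across the condition's replicates with one amplitude each; with
    ``shared_k1=False`` each replicate is fit independently and the mean k1
    is returned (for comparison with the global structure). Single-cell
    scatter is pre-aggregated into time-bin medians of ``bin_width`` seconds
    (pass None to fit raw points).
    """
    if y0_fixed <= 0:
        raise ValueError("y0_fixed must be > 0")
    df = traces[traces["time"] >= 0]
    if "replicate" not in df.columns:
        df = df.assign(replicate="rep1")
    if len(df) < 10 or df["time"].nunique() < 2:
        raise ValueError(
            f"need >= 10 observations over >= 2 distinct times "
            f"(got {len(df)} over {df['time'].nunique()})"
        )
    reps = sorted(df["replicate"].unique())

    if not shared_k1:
        fits = [
            fit_quench_global(df[df["replicate"] == r], y0_fixed, bin_width=bin_width)
            for r in reps
        ]
        k1 = float(np.mean([f.k1 for f in fits]))
        amps = {r: f.amplitudes[r] for r, f in zip(reps, fits)}
        return DecayFit(
            y0=y0_fixed, k1=k1, amplitudes=amps, t_half=half_life(k1),
            rss=float(sum(f.rss for f in fits)), n_obs=int(sum(f.n_obs for f in fits)),
            converged=all(f.converged for f in fits),
            at_bound=any(f.at_bound for f in fits),
        )

    data: list[tuple[np.ndarray, np.ndarray]] = []
    for r in reps:
        sub = df[df["replicate"] == r]
        t = sub["time"].to_numpy(float)
        y = sub["value"].to_numpy(float)
        if bin_width is not None:
            t, y = _bin_medians(t, y, bin_width)
        data.append((t, y))

    # initial guesses: amplitude from earliest observations, rate from a
    # log-linear regression of (y - y0) where positive
    a0 = []
    for t, y in data:
        i = np.argsort(t)[: max(3, len(t) // 10)]
        a0.append(max(float(np.mean(y[i])) - y0_fixed, 1e-6))
    t_all = np.concatenate([t for t, _ in data])
    y_all = np.concatenate([y for _, y in data])
    pos = y_all - y0_fixed > 1e-12
    if pos.sum() >= 2 and np.ptp(t_all[pos]) > 0:
        slope = np.polyfit(t_all[pos], np.log(y_all[pos] - y0_fixed), 1)[0]
        k0 = max(-float(slope), 1e-6)
    else:
        k0 = 1e-3

    def resid(params: np.ndarray) -> np.ndarray:
        k1 = params[0]
        out = []
        for (t, y), a in zip(data, params[1:]):
            out.append(a * np.exp(-k1 * t) + y0_fixed - y)
        return np.concatenate(out)

    x0 = np.array([k0] + a0)
    lo = np.zeros_like(x0)
    res = least_squares(resid, x0, bounds=(lo, np.inf), xtol=1e-15, ftol=1e-15, gtol=1e-15)
    if not res.success:
        raise RuntimeError(
            f"global quench fit did not converge: {res.message} "
            f"(n_obs={len(y_all)}, t range {t_all.min():.3g}-{t_all.max():.3g})"
        )
    k1 = float(res.x[0])
    if k1 < 1e-10:  # numerically at the k1 >= 0 bound: no measurable decay
        k1 = 0.0
    amps = {r: float(a) for r, a in zip(reps, res.x[1:])}
    return DecayFit(
        y0=y0_fixed,
        k1=k1,
        amplitudes=amps,
        t_half=half_life(k1),
        rss=float(np.sum(res.fun**2)),
        n_obs=int(len(y_all)),
        converged=True,
        at_bound=bool(k1 == 0.0),
    )


@dataclass
class PlateauResult:
    delta_i: float
    baseline: float
    plateau: float
    window: tuple[float, float]


@dataclass
class StabilityCriteria:
    """Rolling-window plateau stability rule.

    A sample is stable when, over the centred ``window`` seconds around it,
    the fitted slope magnitude is below ``slope_frac`` of the trace's value
    range per minute and the SD is below ``sd_frac`` of the range.
    """

    window: float = 60.0
    slope_frac: float = 0.01
    sd_frac: float = 0.02


def delta_isc(
    trace: pd.DataFrame,
    events: dict[str, float],
    event: str,
    plateau_min_duration: float = 300.0,
    criteria: StabilityCriteria | None = None,
) -> PlateauResult:
    """Signed current change from baseline to the post-event stable plateau.

    The baseline is the mean over the stability window immediately preceding
    the event. After the event, contiguous stretches of stable samples (see
    :class:`StabilityCriteria`) lasting at least ``plateau_min_duration``
    seconds are candidate plateaus; the longest is used (ties broken by the
    larger excursion from baseline). Transient overshoots shorter than the
    duration rule are thereby rejected.
    """
    if criteria is None:
        criteria = StabilityCriteria()
    if event not in events:
        raise ValueError(f"event {event!r} not in marker table")
    t_event = float(events[event])
    t = trace["time"].to_numpy(float)
    y = trace["current"].to_numpy(float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    rng_y = float(np.ptp(y))
    slope_tol = criteria.slope_frac * rng_y / 60.0 if rng_y > 0 else np.inf
    sd_tol = criteria.sd_frac * rng_y if rng_y > 0 else np.inf

    pre = (t >= t_event - criteria.window) & (t < t_event)
    if not pre.any():
        pre = t < t_event
    if not pre.any():
        raise ValueError("no samples before the event for a baseline")
    baseline = float(np.mean(y[pre]))

    post_idx = np.flatnonzero(t >= t_event)
    if len(post_idx) == 0 or t[post_idx[-1]] - t_event < plateau_min_duration:
        raise ValueError("insufficient post-event samples for the plateau duration")

    half = criteria.window / 2.0
    stable = np.zeros(len(t), dtype=bool)
    for i in post_idx:
        m = (t >= t[i] - half) & (t <= t[i] + half)
        if m.sum() < 3:
            continue
        tw, yw = t[m], y[m]
        slope = np.polyfit(tw, yw, 1)[0]
        if abs(slope) <= slope_tol and float(np.std(yw)) <= sd_tol:
            stable[i] = True

    # longest contiguous stable run among post-event samples; ties broken by
    # the larger excursion from baseline
    best_key: tuple[float, float] | None = None
    best_level = best_window = None
    run_start = None
    for j in range(len(post_idx) + 1):
        ok = j < len(post_idx) and stable[post_idx[j]]
        if ok and run_start is None:
            run_start = j
        if not ok and run_start is not None:
            seg = post_idx[run_start:j]
            dur = float(t[seg[-1]] - t[seg[0]])
            if dur >= plateau_min_duration:
                level = float(np.mean(y[seg]))
                key = (dur, abs(level - baseline))
                if best_key is None or key > best_key:
                    best_key = key
                    best_level = level
                    best_window = (float(t[seg[0]]), float(t[seg[-1]]))
            run_start = None
    if best_key is None:
        raise ValueError(
            "no stable plateau of the required duration found; consider relaxing "
            "the stability tolerances"
        )
    return PlateauResult(
        delta_i=best_level - baseline,
        baseline=baseline,
        plateau=best_level,
        window=best_window,
    )


def percent_wt_activity(delta_variant: float, delta_wt_fsk: float) -> float:
    """Functional activation as a percentage of the WT forskolin response."""
    if delta_wt_fsk == 0:
        raise ValueError("WT reference current change is zero")
    return 100.0 * delta_variant / delta_wt_fsk
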