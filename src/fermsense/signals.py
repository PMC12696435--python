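"""Streaming signal conditioning for inline optical-density probes.

An inline turbidity probe reports a transmission channel (light passing
through the culture, which decays towards zero as biomass accumulates) and a
reflection channel (backscatter, which grows roughly linearly with biomass).
Gas bubbles in a stirred, sparged fermenter make both channels spiky, so the
raw signals are smoothed with a trailing (causal) unweighted moving average
before any transform — real-time prediction cannot look ahead.

The soft-sensor predictors built here are:

* ``inv_trans_ma``   — 1 / smoothed transmission (linearizes the saturating
  transmission response with respect to OD600),
* ``refl_ma``        — smoothed reflection, passed through,
* ``antifoam_pct``   — cumulative diluted antifoam as % of fermenter volume
  (antifoam emulsions are optically active, so dosing shifts both channels),
* ``interaction``    — the product ``inv_trans_ma * refl_ma``.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pandas as pd

from .exceptions import DegenerateSignalError, InvalidInputError

#: Columns of a probe log, in canonical order. Times are hours since run
#: start; transmission/reflection are detector units; volumes in mL.
PROBE_LOG_COLUMNS = (
    "time_h",
    "transmission",
    "reflection",
    "do_pct",
    "volume_ml",
    "antifoam_cum_ml",
)

#: Predictor names, in the canonical model order.
FEATURE_NAMES = ("inv_trans_ma", "refl_ma", "antifoam_pct", "interaction")

#: Guard for the inverse transform, in detector units. Below this the
#: transmission signal carries no usable information (opaque culture or
#: sensor dropout) and 1/T would explode.
TRANSMISSION_EPS = 1e-9

#: Default smoothing window, hours.
DEFAULT_MA_WINDOW = 0.2


def moving_average(times, values, window: float = DEFAULT_MA_WINDOW):
    """Trailing unweighted moving average over a time window.

    The smoothed value at time ``t`` is the arithmetic mean of all samples
    with timestamps in the half-open interval ``(t - window, t]`` — causal,
    so it can run in real time. Output timestamps equal input timestamps;
    partial windows at the start of a run simply average the samples that
    exist (no padding).

    Parameters
    ----------
    times, values : array-like
        Sample timestamps (hours, strictly increasing) and values.
    window : float
        Window length in hours, > 0.

    Returns
    -------
    numpy.ndarray
        Smoothed values, same length as the input.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size == 0 or t.shape != v.shape:
        raise InvalidInputError("times/values must be equal-length non-empty 1-d arrays")
    if window <= 0:
        raise InvalidInputError("window must be > 0")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidInputError("timestamps must be strictly increasing")
    csum = np.concatenate(([0.0], np.cumsum(v)))
    right = np.arange(1, t.size + 1)
    # first index with timestamp > t - window  ->  half-open (t-w, t]
    left = np.searchsorted(t, t - window, side="right")
    return (csum[right] - csum[left]) / (right - left)


class StreamingMovingAverage:
    """Incremental trailing moving average, one sample at a time.

    Produces values identical to :func:`moving_average` applied to the full
    series (the closed-loop controller consumes this form).
    """

    def __init__(self, window: float = DEFAULT_MA_WINDOW):
        if window <= 0:
            raise InvalidInputError("window must be > 0")
        self.window = window
        self._buf: deque[tuple[float, float]] = deque()
        self._last_t = -np.inf

    def update(self, time: float, value: float) -> float:
        if time <= self._last_t:
            raise InvalidInputError("timestamps must be strictly increasing")
        self._last_t = time
        self._buf.append((time, value))
        cutoff = time - self.window
        while self._buf[0][0] <= cutoff:
            self._buf.popleft()
        # direct O(w) sum: immune to float drift over long runs
        return float(sum(x for _, x in self._buf) / len(self._buf))


def antifoam_pct(antifoam_cum_ml, volume_ml):
    """Cumulative diluted antifoam as a percentage of fermenter volume.

    Antifoam stocks are nearly opaque oil-in-water emulsions whose apparent
    OD is strongly dilution dependent, so the dosed *volume fraction* is the
    tractable predictor: ``100 * antifoam_cum_ml / volume_ml``.
    """
    af = np.asarray(antifoam_cum_ml, dtype=float)
    v = np.asarray(volume_ml, dtype=float)
    if np.any(af < 0) or np.any(v <= 0):
        raise InvalidInputError("antifoam_cum_ml must be >= 0 and volume_ml > 0")
    out = 100.0 * af / v
    return float(out) if out.ndim == 0 else out


def build_features(trans_ma, refl_ma, antifoam_cum_ml, volume_ml):
    """Turn smoothed probe channels into the model's predictor terms.

    Parameters are scalars or equal-length arrays of the MA-smoothed
    transmission and reflection plus the raw antifoam/volume channels.

    Returns a dict mapping :data:`FEATURE_NAMES` to values (scalars in,
    scalars out).

    Raises
    ------
    DegenerateSignalError
        If any smoothed transmission is at or below
        :data:`TRANSMISSION_EPS`.
    """
    t_ma = np.asarray(trans_ma, dtype=float)
    r_ma = np.asarray(refl_ma, dtype=float)
    if np.any(t_ma <= TRANSMISSION_EPS):
        raise DegenerateSignalError(
            f"smoothed transmission <= {TRANSMISSION_EPS} detector units: "
            "culture opaque beyond probe range or sensor dropout"
        )
    inv = 1.0 / t_ma
    af = antifoam_pct(antifoam_cum_ml, volume_ml)
    inter = inv * r_ma
    if t_ma.ndim == 0:
        return {
            "inv_trans_ma": float(inv),
            "refl_ma": float(r_ma),
            "antifoam_pct": float(af),
            "interaction": float(inter),
        }
    return {
        "inv_trans_ma": inv,
        "refl_ma": r_ma,
        "antifoam_pct": np.asarray(af, dtype=float),
        "interaction": inter,
    }


def featurize_log(log: pd.DataFrame, window: float = DEFAULT_MA_WINDOW) -> pd.DataFrame:
    """Smooth a probe log and append the model's predictor columns.

    Parameters
    ----------
    log : pandas.DataFrame
        Probe log with (at least) the :data:`PROBE_LOG_COLUMNS`.
    window : float
        Moving-average window, hours.

    Returns
    -------
    pandas.DataFrame
        Copy of the input with ``trans_ma``, ``refl_ma``, ``inv_trans_ma``,
        ``antifoam_pct`` and ``interaction`` appended.
    """
    missing = [c for c in PROBE_LOG_COLUMNS if c not in log.columns]
    if missing:
        raise InvalidInputError(f"probe log missing columns: {missing}")
    out = log.copy()
    t = out["time_h"].to_numpy(dtype=float)
    out["trans_ma"] = moving_average(t, out["transmission"].to_numpy(dtype=float), window)
    out["refl_ma"] = moving_average(t, out["reflection"].to_numpy(dtype=float), window)
    feats = build_features(
        out["trans_ma"].to_numpy(),
        out["refl_ma"].to_numpy(),
        out["antifoam_cum_ml"].to_numpy(dtype=float),
        out["volume_ml"].to_numpy(dtype=float),
    )
    for name in ("inv_trans_ma", "antifoam_pct", "interaction"):
        out[name] = feats[name]
    return out
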