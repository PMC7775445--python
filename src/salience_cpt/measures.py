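"""ERP component quantification.

Amplitude is the *signed area*: the integral (trapezoid rule, uV*ms) of the
polarity-consistent part of the waveform inside the component window — the
positive part for P3 components, the magnitude of the negative part for the
N2 (so N2 statistics are reported as positive magnitudes).  Latency is the
*50% fractional-area latency*: the time at which the cumulative rectified
area reaches half the total window area.  Both measures model the waveform
as piecewise-linear between samples and rectify *after* interpolation
(zero-crossing nodes are inserted exactly), so they are exact for the
interpolated waveform rather than approximations on the sample grid.

Mean effects are measured on the average difference wave (critical minus
reference condition); trial-to-trial variability is the SD of per-trial
measures of the critical condition at the component electrode (a per-trial
difference wave does not exist).  Window edges snap to the nearest sample of
the native grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import EpochsSet, _interval_slice

logger = logging.getLogger(__name__)


class EmptyAverageError(ValueError):
    """No usable trials to average."""


@dataclass(frozen=True)
class ComponentWindow:
    """Electrode + time window + polarity defining one ERP measure."""

    name: str
    electrode: str
    t_start: float
    t_end: float
    polarity: str  # 'positive' or 'negative'
    critical: str
    reference: str

    def __post_init__(self) -> None:
        if self.t_start >= self.t_end:
            raise ValueError("t_start must be < t_end")
        if self.polarity not in ("positive", "negative"):
            raise ValueError("polarity must be 'positive' or 'negative'")


#: The study's component definitions, including the Pz replication sites for
#: both P3 effects.
DEFAULT_WINDOWS = (
    ComponentWindow("inhibition_P3", "POz", 300.0, 600.0, "positive", "NoGo", "StandardGo"),
    ComponentWindow("salience_P3", "POz", 350.0, 600.0, "positive", "SalientGo", "StandardGo"),
    ComponentWindow("salience_N2", "Fz", 250.0, 350.0, "negative", "SalientGo", "StandardGo"),
    ComponentWindow("inhibition_P3", "Pz", 300.0, 600.0, "positive", "NoGo", "StandardGo"),
    ComponentWindow("salience_P3", "Pz", 350.0, 600.0, "positive", "SalientGo", "StandardGo"),
)


@dataclass
class ComponentMeasures:
    """Per-subject summary for one component at one electrode."""

    component: str
    electrode: str
    mean_amplitude: float  # uV*ms, signed area of the average difference wave
    mean_latency: float  # ms, 50% fractional-area latency of the difference wave
    amp_sd: float  # uV*ms, SD of per-trial amplitudes (critical condition)
    lat_sd: float  # ms, SD of per-trial latencies
    n_trials_used: int


def usable_mask(metadata: pd.DataFrame, condition: str, exclude_errors: bool = True) -> np.ndarray:
    """Trials entering the ERP: correct trials of one condition.

    Correct = HIT for Go conditions, CorrectInhibition for NoGo.  Without an
    ``outcome`` column all trials of the condition are used.
    """
    mask = (metadata["condition"] == condition).to_numpy()
    if exclude_errors and "outcome" in metadata.columns:
        correct = "CorrectInhibition" if condition == "NoGo" else "HIT"
        mask &= (metadata["outcome"] == correct).to_numpy()
    return mask


def condition_average(epochs: EpochsSet, condition: str, exclude_errors: bool = True) -> np.ndarray:
    """Average waveform (channels x samples) over usable trials."""
    mask = usable_mask(epochs.metadata, condition, exclude_errors)
    if not mask.any():
        raise EmptyAverageError(f"no usable {condition} trials")
    return epochs.data[mask].mean(axis=0)


def difference_wave(critical_avg: np.ndarray, reference_avg: np.ndarray) -> np.ndarray:
    """Pointwise critical minus reference."""
    if critical_avg.shape != reference_avg.shape:
        raise ValueError("waveform shapes do not match")
    return critical_avg - reference_avg


def _rectified_window(
    wave: np.ndarray, times: np.ndarray, window: ComponentWindow
) -> tuple:
    """(t, r): rectified waveform inside the window, crossings resolved.

    The waveform is modelled as piecewise-linear between samples and
    rectified *after* interpolation: zero-crossing nodes are inserted exactly,
    so the rectified signal is again piecewise-linear on the returned grid.
    Window edges snap to the nearest sample.
    """
    if window.t_start < times[0] - 1e-9 or window.t_end > times[-1] + 1e-9:
        raise ValueError("component window lies outside the epoch")
    sl = _interval_slice(times, window.t_start, window.t_end)
    t = np.asarray(times, dtype=float)[sl]
    v = np.asarray(wave, dtype=float)[sl]
    if window.polarity == "negative":
        v = -v
    v1, v2 = v[:-1], v[1:]
    crossing = ((v1 > 0) & (v2 < 0)) | ((v1 < 0) & (v2 > 0))
    if crossing.any():
        idx = np.nonzero(crossing)[0]
        tc = t[idx] + (t[idx + 1] - t[idx]) * v[idx] / (v[idx] - v[idx + 1])
        t = np.insert(t, idx + 1, tc)
        v = np.insert(v, idx + 1, 0.0)
    return t, np.clip(v, 0.0, None)


def signed_area_amplitude(
    wave: np.ndarray, times: np.ndarray, window: ComponentWindow
) -> float:
    """Polarity-rectified area (uV*ms) of a 1-D waveform inside the window."""
    t, r = _rectified_window(wave, times, window)
    return float(np.trapezoid(r, t))


def fractional_area_latency(
    wave: np.ndarray,
    times: np.ndarray,
    window: ComponentWindow,
    fraction: float = 0.5,
) -> float:
    """Time (ms) at which the cumulative rectified area reaches ``fraction``
    of the total window area.  Returns NaN when the window holds no
    polarity-consistent area (undefined latency, excluded from statistics).

    The waveform is treated as piecewise-linear between samples, so the
    cumulative area is piecewise-quadratic; the crossing is solved exactly
    within the bracketing sample interval.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    t, r = _rectified_window(wave, times, window)

    h = np.diff(t)
    seg = 0.5 * (r[:-1] + r[1:]) * h
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        logger.info("zero rectified area in %s window: latency undefined", window.name)
        return float("nan")

    target = fraction * total
    j = int(np.searchsorted(cum, target, side="left"))
    j = min(max(j, 1), len(cum) - 1)
    rem = target - cum[j - 1]
    r1, r2 = r[j - 1], r[j]
    hh = h[j - 1]
    if hh <= 0.0:  # degenerate segment from a float-snapped crossing node
        return float(t[j - 1])
    a = (r2 - r1) / (2.0 * hh)
    # solve a*x^2 + r1*x = rem for x in [0, hh] (stable Muller form)
    disc = r1 * r1 + 4.0 * a * rem
    denom = r1 + np.sqrt(max(disc, 0.0))
    if denom <= 0.0:
        x = 0.0
    else:
        x = 2.0 * rem / denom
    return float(t[j - 1] + min(max(x, 0.0), hh))


def single_trial_measures(
    epochs: EpochsSet,
    window: ComponentWindow,
    exclude_errors: bool = True,
    smooth_hz: float | None = None,
) -> pd.DataFrame:
    """Per-trial signed area and fractional-area latency for the critical
    condition at the component electrode.

    ``smooth_hz`` optionally low-pass filters single trials before latency
    extraction (off by default).  Trials with undefined latency are kept
    with NaN latency and excluded from latency statistics only.
    """
    mask = usable_mask(epochs.metadata, window.critical, exclude_errors)
    n = int(mask.sum())
    if n < 2:
        raise EmptyAverageError(
            f"need >= 2 usable {window.critical} trials, got {n}"
        )
    traces = epochs.pick(window.electrode)[mask]
    times = epochs.times
    if smooth_hz is not None:
        from mne.filter import filter_data

        traces = filter_data(
            np.ascontiguousarray(traces, dtype=np.float64),
            sfreq=epochs.sfreq, l_freq=None, h_freq=smooth_hz, verbose="error",
        )
    amps = np.array([signed_area_amplitude(tr, times, window) for tr in traces])
    lats = np.array([fractional_area_latency(tr, times, window) for tr in traces])
    return pd.DataFrame(
        {
            "trial": epochs.metadata.loc[mask, "trial"].to_numpy()
            if "trial" in epochs.metadata.columns
            else np.nonzero(mask)[0],
            "amplitude": amps,
            "latency": lats,
        }
    )


def component_measures(
    epochs_critical: EpochsSet,
    epochs_reference: EpochsSet,
    window: ComponentWindow,
    exclude_errors: bool = True,
    smooth_hz: float | None = None,
) -> ComponentMeasures:
    """Mean amplitude/latency from the average difference wave plus
    trial-wise SDs from single trials of the critical condition."""
    crit_avg = condition_average(epochs_critical, window.critical, exclude_errors)
    ref_avg = condition_average(epochs_reference, window.reference, exclude_errors)
    diff = difference_wave(crit_avg, ref_avg)
    ch = epochs_critical.ch_names.index(window.electrode)
    times = epochs_critical.times

    mean_amp = signed_area_amplitude(diff[ch], times, window)
    mean_lat = fractional_area_latency(diff[ch], times, window)

    st = single_trial_measures(epochs_critical, window, exclude_errors, smooth_hz)
    lat_ok = st["latency"].notna()
    n_undef = int((~lat_ok).sum())
    if n_undef:
        logger.info("%s: %d trial(s) with undefined latency excluded from lat_sd",
                    window.name, n_undef)
    return ComponentMeasures(
        component=window.name,
        electrode=window.electrode,
        mean_amplitude=mean_amp,
        mean_latency=mean_lat,
        amp_sd=float(st["amplitude"].std(ddof=1)),
        lat_sd=float(st.loc[lat_ok, "latency"].std(ddof=1)) if lat_ok.sum() >= 2 else float("nan"),
        n_trials_used=len(st),
    )


def measures_table(
    epochs: EpochsSet,
    windows=DEFAULT_WINDOWS,
    exclude_errors: bool = True,
    smooth_hz: float | None = None,
) -> pd.DataFrame:
    """One row per component window for a single subject's EpochsSet."""
    rows = []
    for w in windows:
        m = component_measures(epochs, epochs, w, exclude_errors, smooth_hz)
        rows.append(
            {
                "component": m.component,
                "site": m.electrode,
                "mean_amp": m.mean_amplitude,
                "mean_lat": m.mean_latency,
                "amp_sd": m.amp_sd,
                "lat_sd": m.lat_sd,
                "n_trials": m.n_trials_used,
            }
        )
    return pd.DataFrame(rows)
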