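"""Band filtering, epoching, baseline correction, and sensor normalization.

Two analysis bands are used: slow cortical potentials (SCP, 0.05-5 Hz,
analyzed at 10 Hz) and the classic event-related-field range (ERF, low-pass
35 Hz with no high-pass, analyzed at 100 Hz).  Filters are 3rd-order
Butterworth applied forward-backward (zero phase); downsampling applies an
extra zero-phase anti-alias low-pass before decimation, with the epoch grid
anchored so that stimulus onset (t = 0) falls on a sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EVENT_COLUMNS, SensorEpochs

EPOCH_WINDOW = (-0.5, 3.0)  # seconds relative to stimulus onset


@dataclass(frozen=True)
class BandSpec:
    """An analysis frequency band.

    ``l_freq`` is the high-pass edge in Hz (``None`` keeps DC), ``h_freq``
    the low-pass edge, ``target_rate`` the analysis sampling rate after
    decimation, and ``order`` the Butterworth order (applied twice by the
    forward-backward pass).
    """

    name: str
    l_freq: float | None
    h_freq: float
    target_rate: float
    order: int = 3

    def __post_init__(self) -> None:
        if self.h_freq > self.target_rate / 2:
            raise ValueError(
                f"band {self.name!r}: low-pass edge {self.h_freq} Hz exceeds the "
                f"Nyquist frequency of the {self.target_rate} Hz target rate"
            )


SCP_BAND = BandSpec("scp", 0.05, 5.0, 10.0)
ERF_BAND = BandSpec("erf", None, 35.0, 100.0)
BANDS = {"scp": SCP_BAND, "erf": ERF_BAND}


def filter_band(
    continuous: np.ndarray,
    sfreq: float,
    band: BandSpec,
    detrend: bool = True,
) -> tuple[np.ndarray, float]:
    """Zero-phase band filter and decimate a continuous recording.

    ``continuous`` is ``... x samples``.  The recording is (optionally)
    demeaned and linearly detrended per channel, filtered with the band's
    Butterworth filter via ``sosfiltfilt``, low-pass filtered again at 45%
    of the target rate for anti-aliasing, and decimated by the (integer)
    ratio of sampling rates.  Returns the decimated data and the new rate.
    """
    continuous = np.asarray(continuous, dtype=float)
    nyq = sfreq / 2
    if band.h_freq >= nyq:
        raise ValueError(
            f"low-pass edge {band.h_freq} Hz is not below the input Nyquist {nyq} Hz"
        )
    ratio = sfreq / band.target_rate
    q = int(round(ratio))
    if abs(ratio - q) > 1e-9:
        raise ValueError(
            f"sampling rate {sfreq} Hz is not an integer multiple of the "
            f"target rate {band.target_rate} Hz"
        )
    x = continuous
    if detrend:
        x = signal.detrend(x, axis=-1, type="linear")
        if band.l_freq is None:
            # detrending removed the mean; nothing more to do for a DC band
            pass
    if band.l_freq is None:
        sos = signal.butter(band.order, band.h_freq, btype="low", fs=sfreq, output="sos")
    else:
        sos = signal.butter(
            band.order, [band.l_freq, band.h_freq], btype="band", fs=sfreq, output="sos"
        )
    x = signal.sosfiltfilt(sos, x, axis=-1)
    if q > 1:
        aa = signal.butter(4, 0.45 * band.target_rate, btype="low", fs=sfreq, output="sos")
        x = signal.sosfiltfilt(aa, x, axis=-1)
        x = x[..., ::q]
    return x, band.target_rate


def epoch_and_baseline(
    continuous: np.ndarray,
    sfreq: float,
    events: pd.DataFrame,
    window: tuple[float, float] = EPOCH_WINDOW,
    band: str = "raw",
) -> SensorEpochs:
    """Cut 3.5 s epochs around stimulus onsets and baseline-correct them.

    ``continuous`` is ``sensors x samples`` (one subject's recording);
    ``events`` needs an ``onset_sample`` column (sample index of stimulus
    onset) plus the usual trial metadata.  Per sensor and trial, the mean
    over the pre-stimulus window (t < 0) is subtracted, so the baseline
    mean is zero by construction.  Events whose epoch would run past either
    edge of the recording are dropped with a warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2:
        raise ValueError("continuous must be sensors x samples")
    if "onset_sample" not in events.columns:
        raise ValueError("events table needs an 'onset_sample' column")
    t0, t1 = window
    i0, i1 = int(round(t0 * sfreq)), int(round(t1 * sfreq))
    n_time = i1 - i0 + 1
    time = (i0 + np.arange(n_time)) / sfreq

    kept_rows = []
    epochs = []
    n_samples = continuous.shape[1]
    for _, row in events.iterrows():
        onset = int(row["onset_sample"])
        lo, hi = onset + i0, onset + i1
        if lo < 0 or hi >= n_samples:
            warnings.warn(
                f"dropping trial at sample {onset}: epoch exceeds recording edge",
                stacklevel=2,
            )
            continue
        epochs.append(continuous[:, lo : hi + 1])
        kept_rows.append(row)
    if not epochs:
        raise ValueError("no trial fits inside the recording")
    values = np.stack(epochs)  # trials x sensors x time
    baseline = values[:, :, time < 0].mean(axis=2, keepdims=True)
    values = values - baseline

    ev = pd.DataFrame(kept_rows).reset_index(drop=True)
    if "subject" not in ev.columns:
        ev.insert(0, "subject", 0)
    ev["trial"] = np.arange(len(ev))
    for col in EVENT_COLUMNS:
        if col not in ev.columns:
            ev[col] = -1
    return SensorEpochs(
        values=values[np.newaxis], time=time, sfreq=sfreq, events=ev, band=band
    )


def baseline_correct(epochs: SensorEpochs) -> SensorEpochs:
    """Subtract each sensor's pre-stimulus (t < 0) mean per trial."""
    if not np.any(epochs.time < 0):
        raise ValueError("epochs contain no pre-stimulus samples")
    out = epochs.copy()
    base = out.values[:, :, :, epochs.time < 0].mean(axis=3, keepdims=True)
    out.values = out.values - base
    return out


def normalize_across_sensors(epochs: SensorEpochs) -> SensorEpochs:
    """Z-score the sensor vector at every (subject, trial, time) sample.

    Uses the sample standard deviation (ddof = 1), so the Pearson
    correlation between two normalized sensor vectors equals their dot
    product divided by ``n_sensors - 1``.
    """
    if epochs.n_sensors < 2:
        raise ValueError("normalization across sensors needs at least 2 sensors")
    v = epochs.values
    mean = v.mean(axis=2, keepdims=True)
    sd = v.std(axis=2, ddof=1, keepdims=True)
    bad = np.nonzero(sd.squeeze(axis=2) == 0)
    if bad[0].size:
        s, t, ti = bad[0][0], bad[1][0], bad[2][0]
        raise ValueError(
            f"zero-variance sensor vector at subject {s}, trial {t}, time index {ti}"
        )
    out = epochs.copy()
    out.values = (v - mean) / sd
    return out
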