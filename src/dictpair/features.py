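"""Log-spectral-power feature extraction for multichannel EEG trials.

Each trial (channels x samples) is band-pass filtered per frequency band
with a zero-phase Butterworth filter, then reduced to the natural log of
the RMS amplitude over nonoverlapping 1 s windows.  The resulting feature
matrix has one row per (band, channel) pair, band-major, and one column
per complete window.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: RMS floor applied before taking the log, so silent windows never yield -inf.
RMS_FLOOR = 1e-12

#: Upper band edges are clipped to this fraction of the Nyquist frequency.
NYQUIST_MARGIN = 0.99


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got ({self.lo}, {self.hi})"
            )


#: The five analysis bands: merged delta+theta, alpha, beta and two gamma bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta_theta", 1.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 35.0),
    BandSpec("gamma1", 35.0, 70.0),
    BandSpec("gamma2", 70.0, 100.0),
)


@dataclass
class RawTrial:
    """A single multichannel recording with its class label."""

    data: np.ndarray  # channels x samples
    fs: float
    subject_id: str
    label: int
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trial data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.shape[1] < self.fs:
            raise ValueError(
                f"trial has {self.data.shape[1]} samples, "
                f"need at least one full 1 s window ({self.fs} samples)"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("trial data contains NaN or infinite values")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


@dataclass
class FeatureMatrix:
    """(bands x channels) x windows feature block for one trial or subject."""

    values: np.ndarray
    feature_index: list[tuple[str, str]]  # (band name, channel name), row order
    subject_id: str
    labels: np.ndarray  # one label per window (column)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape[0] != len(self.feature_index):
            raise ValueError("feature_index length must equal row count")
        if self.values.shape[1] != len(self.labels):
            raise ValueError("one label required per window column")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")


@dataclass(frozen=True)
class FilterSpec:
    """A designed band-pass filter in second-order-section form."""

    sos: np.ndarray = field(repr=False)
    band: BandSpec = None
    fs: float = 0.0
    order: int = 8


def design_bandpass(band: BandSpec, fs: float, order: int = 8) -> FilterSpec:
    """Design a stable Butterworth band-pass filter for ``band`` at rate ``fs``.

    The upper edge is clipped to ``0.99 * fs / 2``; a band whose lower edge
    reaches or exceeds the clipped upper edge is rejected.  ``order`` is the
    prototype order handed to the Butterworth design.
    """
    nyq = fs / 2.0
    hi = min(band.hi, NYQUIST_MARGIN * nyq)
    if band.lo >= hi:
        raise ValueError(
            f"band {band.name!r} ({band.lo}-{band.hi} Hz) does not fit below "
            f"the Nyquist limit at fs={fs} Hz (usable ceiling {hi:.2f} Hz)"
        )
    sos = sps.butter(order, [band.lo, hi], btype="bandpass", fs=fs, output="sos")
    return FilterSpec(sos=sos, band=BandSpec(band.name, band.lo, hi), fs=fs, order=order)


def zero_phase_filter(x: np.ndarray, filt: FilterSpec) -> np.ndarray:
    """Apply ``filt`` forward and backward (zero group delay)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("zero_phase_filter expects a 1-D signal")
    if x.size <= 3 * filt.order:
        raise ValueError(
            f"signal of length {x.size} too short for order-{filt.order} "
            "zero-phase filtering"
        )
    return sps.sosfiltfilt(filt.sos, x)


def window_log_rms(x: np.ndarray, fs: float, log_base: float = math.e) -> np.ndarray:
    """Log RMS over nonoverlapping 1 s windows; trailing partial window dropped."""
    x = np.asarray(x, dtype=float)
    win = int(round(fs))
    if win <= 0:
        raise ValueError(f"sampling rate must be positive, got {fs}")
    n_win = x.size // win
    if n_win < 1:
        raise ValueError(f"signal of length {x.size} shorter than one window ({win})")
    chunks = x[: n_win * win].reshape(n_win, win)
    rms = np.sqrt(np.mean(chunks**2, axis=1))
    out = np.log(np.maximum(rms, RMS_FLOOR))
    if log_base != math.e:
        out = out / math.log(log_base)
    return out


def extract_log_spectral_power(
    trial: RawTrial,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    log_base: float = math.e,
) -> FeatureMatrix:
    """Extract the (bands x channels) x windows log-spectral-power matrix.

    Rows are ordered band-major (all channels of band 1, then band 2, ...);
    every window column inherits the trial label.  A band that cannot fit
    below the Nyquist limit is dropped with a warning; if no band survives,
    an error is raised.
    """
    ch_names = trial.channel_names or [f"ch{i}" for i in range(trial.n_channels)]
    rows: list[np.ndarray] = []
    index: list[tuple[str, str]] = []
    for band in bands:
        try:
            filt = design_bandpass(band, trial.fs)
        except ValueError as exc:
            warnings.warn(f"dropping band: {exc}", stacklevel=2)
            continue
        for ci in range(trial.n_channels):
            try:
                filtered = zero_phase_filter(trial.data[ci], filt)
                rows.append(window_log_rms(filtered, trial.fs, log_base=log_base))
            except ValueError as exc:
                raise ValueError(
                    f"band {band.name!r}, channel {ch_names[ci]!r}: {exc}"
                ) from exc
            index.append((band.name, ch_names[ci]))
    if not rows:
        raise ValueError(
            f"no band fits below the Nyquist limit at fs={trial.fs} Hz"
        )
    values = np.vstack(rows)
    labels = np.full(values.shape[1], trial.label, dtype=int)
    return FeatureMatrix(values, index, trial.subject_id, labels)
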