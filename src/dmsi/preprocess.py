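"""Sensor-space conditioning of MEG recordings.

Filtering (DC removal, line-frequency notch, bandpass), resampling, epoching
of interictal spikes into 2 s windows around the marked peak, per-type
averaging into "studies", and baseline noise-covariance estimation.

Conventions
-----------
* Epoch window is half-open, [-1 s, +1 s) at the working rate: at 600 Hz an
  epoch has exactly 1,200 samples with the spike peak at index 600.
* The baseline for noise covariance is [-1.0 s, -0.1 s) of the averaged
  epoch: the nominal 1 s baseline trimmed by a 100 ms guard before the peak
  so that no spike energy leaks into the noise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal

__all__ = [
    "SensorRecording",
    "AveragedStudy",
    "NoiseCovariance",
    "StudyRejectedError",
    "condition_recording",
    "epoch_and_average",
    "estimate_noise_covariance",
    "MIN_EPOCHS",
]

MIN_EPOCHS = 5  # studies with fewer usable spikes are rejected


class StudyRejectedError(RuntimeError):
    """A study failed an inclusion rule; ``reason`` is a short machine code."""

    def __init__(self, reason: str, message: str):
        super().__init__(message)
        self.reason = reason


@dataclass
class SensorRecording:
    """Continuous multichannel recording with spike event markers.

    ``event_markers`` is a list of ``(time_s, spike_type)`` pairs; times are
    in seconds from the start of the recording and survive filtering and
    resampling unchanged.
    """

    samples: np.ndarray  # channels x time
    sampling_rate_hz: float
    channel_names: list[str]
    event_markers: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValueError("one channel name per row required")
        dur = self.samples.shape[1] / self.sampling_rate_hz
        for t, _ in self.event_markers:
            if not 0 <= t <= dur:
                raise ValueError(f"marker at {t} s outside recording of {dur:.2f} s")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.sampling_rate_hz


@dataclass
class AveragedStudy:
    """One averaged spike group — the unit of source imaging analysis."""

    average: np.ndarray  # channels x time, 2 s window
    sampling_rate_hz: float
    peak_index: int
    n_epochs: int
    spike_type: str
    patient_id: str = ""
    study_id: str = ""
    baseline_window_s: tuple[float, float] = (-1.0, -0.1)  # relative to peak

    def __post_init__(self) -> None:
        self.average = np.asarray(self.average, dtype=float)
        n_t = self.average.shape[1]
        expect = int(round(2.0 * self.sampling_rate_hz))
        if n_t != expect:
            raise ValueError(f"epoch must span exactly 2 s ({expect} samples), got {n_t}")
        if self.peak_index != expect // 2:
            raise ValueError("peak_index must sit at the epoch midpoint")
        if self.n_epochs < MIN_EPOCHS:
            raise ValueError(f"studies require >= {MIN_EPOCHS} epochs")
        b0, b1 = self.baseline_window_s
        if not (-1.0 <= b0 < b1 <= 1.0):
            raise ValueError("baseline window must lie within the epoch")
        if b1 > -0.05 and b0 < 0.05:
            raise ValueError("baseline window must avoid the 100 ms around the peak")

    @property
    def peak_data(self) -> np.ndarray:
        """Sensor vector at the spike peak (the data the solvers invert)."""
        return self.average[:, self.peak_index]

    def baseline_slice(self) -> slice:
        b0, b1 = self.baseline_window_s
        fs = self.sampling_rate_hz
        i0 = self.peak_index + int(round(b0 * fs))
        i1 = self.peak_index + int(round(b1 * fs))
        return slice(i0, i1)


@dataclass
class NoiseCovariance:
    """Sensor noise covariance C estimated from a spike-free baseline."""

    values: np.ndarray
    regularization_applied: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("covariance must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("covariance must be symmetric (tol 1e-10)")
        if np.linalg.eigvalsh(v).min() <= 0:
            raise ValueError("covariance must be positive definite")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def whitener(self) -> np.ndarray:
        """Symmetric inverse square root C^{-1/2}."""
        w, v = np.linalg.eigh(self.values)
        return (v / np.sqrt(w)) @ v.T


def condition_recording(
    rec: SensorRecording,
    notch_hz: float = 60.0,
    band_hz: tuple[float, float] = (0.3, 70.0),
    target_rate_hz: float = 600.0,
) -> SensorRecording:
    """DC removal, notch + bandpass filtering, and resampling.

    Zero-phase (forward-backward) second-order-section filters; the notch is
    a Q=30 IIR notch whose forward-backward application attenuates a pure
    line-frequency tone well beyond 26 dB.  The band high edge must stay
    below the Nyquist frequency of the target rate.
    """
    lo, hi = band_hz
    if hi >= target_rate_hz / 2:
        raise ValueError(
            f"band high edge {hi} Hz must be below Nyquist {target_rate_hz / 2} Hz"
        )
    fs = rec.sampling_rate_hz
    x = rec.samples - rec.samples.mean(axis=1, keepdims=True)

    b, a = signal.iirnotch(notch_hz, Q=30.0, fs=fs)
    sos_notch = signal.tf2sos(b, a)
    x = signal.sosfiltfilt(sos_notch, x, axis=1)

    sos_band = signal.butter(4, (lo, hi), btype="bandpass", output="sos", fs=fs)
    x = signal.sosfiltfilt(sos_band, x, axis=1)

    if not np.isclose(fs, target_rate_hz):
        frac = Fraction(target_rate_hz / fs).limit_denominator(1000)
        x = signal.resample_poly(x, frac.numerator, frac.denominator, axis=1)
    return SensorRecording(x, target_rate_hz, list(rec.channel_names), list(rec.event_markers))


def epoch_and_average(
    rec: SensorRecording,
    spike_type: str,
    artifact_intervals_s: list[tuple[float, float]] = (),
    patient_id: str = "",
    study_id: str = "",
) -> AveragedStudy:
    """Segment 2 s epochs around marked spike peaks and average them.

    Epochs overlapping a declared artifact interval, or extending beyond the
    recording, are excluded.  Fewer than five usable epochs rejects the
    study (``StudyRejectedError`` with a reason code).
    """
    fs = rec.sampling_rate_hz
    half = int(round(fs))  # 1 s of samples
    epochs = []
    for t, typ in rec.event_markers:
        if typ != spike_type:
            continue
        p = int(round(t * fs))
        i0, i1 = p - half, p + half  # [-1, +1) -> 2*half samples
        if i0 < 0 or i1 > rec.samples.shape[1]:
            continue
        t0, t1 = t - 1.0, t + 1.0
        if any(a0 < t1 and a1 > t0 for a0, a1 in artifact_intervals_s):
            continue
        epochs.append(rec.samples[:, i0:i1])
    if len(epochs) < MIN_EPOCHS:
        raise StudyRejectedError(
            "too_few_epochs",
            f"only {len(epochs)} usable epochs of type {spike_type!r} "
            f"(minimum {MIN_EPOCHS})",
        )
    avg = np.mean(epochs, axis=0)
    return AveragedStudy(
        avg,
        sampling_rate_hz=fs,
        peak_index=half,
        n_epochs=len(epochs),
        spike_type=spike_type,
        patient_id=patient_id,
        study_id=study_id,
    )


def estimate_noise_covariance(
    study: AveragedStudy,
    diagonal_loading: float = 0.1,
) -> NoiseCovariance:
    """Sample covariance of the averaged baseline, with diagonal loading.

    ``diagonal_loading`` is the fraction of the mean diagonal added to the
    diagonal to guarantee positive definiteness of the (typically
    rank-deficient) MEG covariance.  With loading disabled, a zero-variance
    channel or a baseline shorter than the channel count is rejected.
    """
    X = study.average[:, study.baseline_slice()]
    n_ch, n_t = X.shape
    if diagonal_loading <= 0 and n_t < n_ch:
        raise ValueError("baseline shorter than channel count requires regularization")
    Xc = X - X.mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / max(n_t - 1, 1)
    if diagonal_loading <= 0 and np.any(np.diag(C) == 0):
        raise ValueError("zero-variance channel; enable diagonal loading")
    if diagonal_loading > 0:
        C = C + diagonal_loading * np.mean(np.diag(C)) * np.eye(n_ch)
    return NoiseCovariance(C, regularization_applied=float(max(diagonal_loading, 0.0)))
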