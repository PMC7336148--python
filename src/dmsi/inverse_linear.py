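"""Linear distributed inverse operators: depth-weighted MNE, dSPM, sLORETA.

All three share the depth-weighted minimum-norm kernel

    W = R G' (G R G' + lambda C)^{-1}

where ``R`` is the diagonal source prior (depth weighting, R_ii proportional
to the gain-column norm to the power -2*depth_exponent, normalized to unit
mean), ``C`` the sensor noise covariance and ``lambda`` the Tikhonov
regularization, set from an assumed SNR as
``lambda = trace(G R G') / (trace(C) snr^2)``.

* MNE reports the rectified current amplitudes ``|W m|`` at the spike peak.
* dSPM divides each source estimate by its noise sensitivity
  ``sqrt(w_i C w_i')`` (a z-score against projected sensor noise).
* sLORETA divides by the square root of the model-variance diagonal
  ``S = W G R``, which makes the point-source localization error exactly
  zero for noiseless data (argmax of ``(g_j' M^{-1} g_i)^2 / (g_j' M^{-1}
  g_j)`` over j is attained at i by the Cauchy-Schwarz inequality).

The estimator classes follow the scikit-learn protocol: hyperparameters in
``__init__``, fitted state (trailing underscore) created by ``fit``, map
computation in ``transform``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .forward import GainMatrix
from .preprocess import AveragedStudy, NoiseCovariance

__all__ = [
    "InverseKernel",
    "SourceMap",
    "compute_depth_weights",
    "regularization_lambda",
    "build_wmne_kernel",
    "solve_mne",
    "solve_dspm",
    "solve_sloreta",
    "MNESolver",
    "DSPMSolver",
    "SLORETASolver",
]

METHOD_LABELS = ("MNE", "sLORETA", "dSPM", "cMEM", "Ave")


@dataclass
class InverseKernel:
    """Sources x channels linear inverse operator with its ingredients."""

    kernel: np.ndarray  # W, sources x channels
    depth_weights: np.ndarray  # diagonal of R
    regularization_lambda: float
    whitening_applied: bool = False

    def __post_init__(self) -> None:
        self.kernel = np.asarray(self.kernel, dtype=float)
        self.depth_weights = np.asarray(self.depth_weights, dtype=float)
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel contains non-finite entries")
        if self.regularization_lambda <= 0:
            raise ValueError("regularization lambda must be positive")
        if np.any(self.depth_weights <= 0):
            raise ValueError("depth weights must be positive")


@dataclass
class SourceMap:
    """Per-vertex nonnegative amplitude at the spike peak for one method."""

    amplitudes: np.ndarray
    method_label: str
    study_id: str = ""
    units_note: str = "arbitrary"

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 1:
            raise ValueError("amplitudes must be a vector over mesh vertices")
        if not np.all(np.isfinite(self.amplitudes)):
            raise ValueError("amplitudes must be finite")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be nonnegative (rectified)")
        if self.method_label not in METHOD_LABELS:
            raise ValueError(f"method_label must be one of {METHOD_LABELS}")

    @property
    def n_vertices(self) -> int:
        return len(self.amplitudes)

    def argmax(self) -> int:
        # ties broken at the lowest vertex index (np.argmax convention)
        return int(np.argmax(self.amplitudes))


def compute_depth_weights(
    G: GainMatrix, depth_exponent: float = 0.5, clip_percentile: float = 99.9
) -> np.ndarray:
    """Diagonal depth prior R_ii = ||g_i||^(-2*depth_exponent), unit mean.

    Weights are clipped at the given upper percentile before normalization so
    that numerically silent (near-radial) sources do not receive explosive
    prior variance.
    """
    norms = np.linalg.norm(G.values, axis=0)
    if np.any(norms == 0):
        raise ValueError("gain contains an exactly zero column; remove silent sources")
    w = norms ** (-2.0 * depth_exponent)
    w = np.minimum(w, np.percentile(w, clip_percentile))
    return w / w.mean()


def regularization_lambda(G: GainMatrix, R: np.ndarray, C: NoiseCovariance, snr: float) -> float:
    """Tikhonov lambda from an assumed amplitude SNR (default snr=3 upstream)."""
    grg_trace = float(np.einsum("ij,j,ij->", G.values, R, G.values))
    return grg_trace / (float(np.trace(C.values)) * snr**2)


def build_wmne_kernel(
    G: GainMatrix,
    C: NoiseCovariance,
    depth_exponent: float = 0.5,
    snr: float = 3.0,
    max_condition: float = 1e12,
) -> InverseKernel:
    """Depth-weighted minimum-norm kernel W = R G' (G R G' + lambda C)^{-1}.

    Raises
    ------
    np.linalg.LinAlgError
        If the regularized system is numerically singular; the message
        reports the condition number.
    """
    if G.n_channels != C.n_channels:
        raise ValueError("gain and covariance channel counts differ")
    R = compute_depth_weights(G, depth_exponent)
    lam = regularization_lambda(G, R, C, snr)
    M = (G.values * R) @ G.values.T + lam * C.values
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > max_condition:
        raise np.linalg.LinAlgError(
            f"regularized system is numerically singular (condition number {cond:.3e})"
        )
    W = (R[:, None] * G.values.T) @ np.linalg.inv(M)
    return InverseKernel(W, R, lam)


def _check_channels(kernel: InverseKernel, study: AveragedStudy) -> np.ndarray:
    m = study.peak_data
    if kernel.kernel.shape[1] != m.shape[0]:
        raise ValueError(
            f"kernel expects {kernel.kernel.shape[1]} channels, study has {m.shape[0]}"
        )
    return m


def solve_mne(kernel: InverseKernel, study: AveragedStudy) -> SourceMap:
    """Rectified minimum-norm amplitudes |W m| at the spike peak."""
    m = _check_channels(kernel, study)
    return SourceMap(np.abs(kernel.kernel @ m), "MNE", study_id=study.study_id)


def solve_dspm(kernel: InverseKernel, C: NoiseCovariance, study: AveragedStudy) -> SourceMap:
    """Noise-normalized map z_i = |w_i m| / sqrt(w_i C w_i')."""
    m = _check_channels(kernel, study)
    W = kernel.kernel
    denom = np.sqrt(np.einsum("ij,jk,ik->i", W, C.values, W))
    if np.any(denom == 0):
        raise ValueError("zero kernel row: dSPM normalization undefined")
    return SourceMap(np.abs(W @ m) / denom, "dSPM", study_id=study.study_id)


def solve_sloreta(kernel: InverseKernel, G: GainMatrix, study: AveragedStudy) -> SourceMap:
    """Standardized map s_i = |w_i m| / sqrt(S_ii), S = W G R.

    Only the diagonal of the model-variance matrix S is formed:
    ``S_ii = (w_i . g_i) R_ii``.
    """
    m = _check_channels(kernel, study)
    W = kernel.kernel
    s_diag = np.einsum("ij,ji->i", W, G.values) * kernel.depth_weights
    if np.any(s_diag <= 0):
        raise ValueError("nonpositive model variance encountered in sLORETA")
    return SourceMap(np.abs(W @ m) / np.sqrt(s_diag), "sLORETA", study_id=study.study_id)


class _LinearInverseBase(BaseEstimator):
    """Shared fit logic for the minimum-norm family."""

    method_label: str = "MNE"

    def __init__(self, depth_exponent: float = 0.5, snr: float = 3.0):
        self.depth_exponent = depth_exponent
        self.snr = snr

    def fit(self, gain: GainMatrix, noise_cov: NoiseCovariance):
        """Precompute the inverse kernel for a gain / noise-covariance pair."""
        self.gain_ = gain
        self.noise_cov_ = noise_cov
        self.kernel_ = build_wmne_kernel(
            gain, noise_cov, depth_exponent=self.depth_exponent, snr=self.snr
        )
        return self

    def _solve(self, study: AveragedStudy) -> SourceMap:
        raise NotImplementedError

    def transform(self, studies) -> SourceMap | list[SourceMap]:
        """Map one study (or a list of studies) to source map(s)."""
        if not hasattr(self, "kernel_"):
            raise RuntimeError("estimator is not fitted; call fit(gain, noise_cov) first")
        if isinstance(studies, AveragedStudy):
            return self._solve(studies)
        return [self._solve(s) for s in studies]

    def fit_transform(self, gain, noise_cov, studies):
        return self.fit(gain, noise_cov).transform(studies)


class MNESolver(_LinearInverseBase):
    """Depth-weighted minimum-norm estimate (wMNE)."""

    method_label = "MNE"

    def _solve(self, study: AveragedStudy) -> SourceMap:
        return solve_mne(self.kernel_, study)


class DSPMSolver(_LinearInverseBase):
    """Dynamic statistical parametric mapping (noise-normalized MNE)."""

    method_label = "dSPM"

    def _solve(self, study: AveragedStudy) -> SourceMap:
        return solve_dspm(self.kernel_, self.noise_cov_, study)


class SLORETASolver(_LinearInverseBase):
    """Standardized low-resolution electromagnetic tomography."""

    method_label = "sLORETA"

    def _solve(self, study: AveragedStudy) -> SourceMap:
        return solve_sloreta(self.kernel_, self.gain_, study)
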