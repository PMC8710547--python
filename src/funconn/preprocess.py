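"""Temporal preprocessing of regional time series and motion-based
subject exclusion.

Stage order is fixed: discard initial volumes -> nuisance regression
(with linear detrend) -> band-pass filtering, mirroring the standard
resting-state pipeline this package targets. Motion screening uses the
Power-style framewise displacement (sum of absolute backward differences
of the six rigid-body parameters, rotations converted to arc length on a
50 mm sphere) and excludes a subject when max |translation| > 2.5 mm,
max |rotation| > 2.5 deg, or mean FD > 0.5 mm — all strict inequalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PreprocessConfig",
    "ExclusionDecision",
    "discard_initial_volumes",
    "framewise_displacement",
    "apply_exclusion",
    "friston24",
    "regress_nuisance",
    "bandpass_filter",
    "preprocess_series",
]


@dataclass
class PreprocessConfig:
    n_discard: int = 10
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    tr_seconds: float = 2.0
    nuisance_spec: tuple[str, ...] = ("wm_signal", "csf_signal", "friston24", "linear_trend")
    fd_threshold: float = 0.5
    translation_threshold_mm: float = 2.5
    rotation_threshold_deg: float = 2.5
    head_radius_mm: float = 50.0

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if not (0.0 <= self.band_low_hz < self.band_high_hz < nyquist):
            raise ValueError(
                f"require 0 <= band_low < band_high < Nyquist ({nyquist:.3f} Hz)"
            )
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")


@dataclass
class ExclusionDecision:
    keep: bool
    reasons: list[str] = field(default_factory=list)
    max_translation_mm: float = 0.0
    max_rotation_deg: float = 0.0
    mean_fd: float = 0.0


def discard_initial_volumes(ts: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first `n_discard` rows (volumes) of a (T, N) matrix."""
    ts = np.asarray(ts)
    if n_discard >= ts.shape[0]:
        raise ValueError(
            f"cannot discard {n_discard} volumes from a series of length {ts.shape[0]}"
        )
    return ts[n_discard:]


def framewise_displacement(trace: np.ndarray, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD from a (T, 6) motion trace.

    Columns 0-2 are translations in mm, columns 3-5 rotations in degrees;
    rotations contribute as arc length on a sphere of `head_radius_mm`.
    FD[0] = 0 by convention.
    """
    m = np.asarray(trace, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 volumes to compute FD")
    d = np.abs(np.diff(m, axis=0))
    d[:, 3:] *= head_radius_mm * np.pi / 180.0
    fd = np.concatenate([[0.0], d.sum(axis=1)])
    return fd


def apply_exclusion(trace: np.ndarray, cfg: PreprocessConfig | None = None) -> ExclusionDecision:
    """Motion-based keep/exclude decision with every violated rule listed."""
    cfg = cfg or PreprocessConfig()
    m = np.asarray(trace, dtype=float)
    max_trans = float(np.abs(m[:, :3]).max())
    max_rot = float(np.abs(m[:, 3:]).max())
    mean_fd = float(framewise_displacement(m, cfg.head_radius_mm).mean())
    reasons = []
    if max_trans > cfg.translation_threshold_mm:
        reasons.append("translation")
    if max_rot > cfg.rotation_threshold_deg:
        reasons.append("rotation")
    if mean_fd > cfg.fd_threshold:
        reasons.append("mean_fd")
    return ExclusionDecision(
        keep=not reasons,
        reasons=reasons,
        max_translation_mm=max_trans,
        max_rotation_deg=max_rot,
        mean_fd=mean_fd,
    )


def friston24(trace: np.ndarray) -> np.ndarray:
    """Friston-24 motion regressors: the 6 parameters, their one-volume
    lags, and the squares of both (T, 24)."""
    m = np.asarray(trace, dtype=float)
    if m.ndim != 2 or m.shape[1] != 6:
        raise ValueError("motion trace must be (T, 6)")
    lag = np.vstack([np.zeros((1, 6)), m[:-1]])
    return np.hstack([m, lag, m**2, lag**2])


def regress_nuisance(ts: np.ndarray, regressors: np.ndarray | None) -> np.ndarray:
    """Residualize every region on [intercept | regressors] by least squares.

    Rank-deficient designs are repaired by dropping collinear columns
    (with a warning); the output always has the input's shape and its
    columns are orthogonal to every retained regressor.
    """
    y = np.asarray(ts, dtype=float)
    t_len = y.shape[0]
    if regressors is None or np.size(regressors) == 0:
        return y - y.mean(axis=0)
    r = np.asarray(regressors, dtype=float)
    if r.ndim == 1:
        r = r[:, None]
    if r.shape[0] != t_len:
        raise ValueError("regressors must have the same number of rows as the series")
    x = np.column_stack([np.ones(t_len), r])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        keep = [0]
        for c in range(1, x.shape[1]):
            cand = x[:, keep + [c]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(c)
        warnings.warn(
            f"rank-deficient nuisance design: dropped {x.shape[1] - len(keep)} "
            "collinear column(s)"
        )
        x = x[:, keep]
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def bandpass_filter(ts: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase frequency-domain ideal band-pass.

    Keeps Fourier bins with band_low <= f <= band_high and zeroes the
    rest (DC included); output length equals input length. A pure
    spectral mask is exactly idempotent; linear detrending is the
    nuisance-regression stage's job (where it sits in the pipeline
    order), so low-frequency trend leakage should be removed before
    filtering.
    """
    cfg = cfg or PreprocessConfig(n_discard=0)
    y = np.asarray(ts, dtype=float)
    t_len = y.shape[0]
    spec = np.fft.rfft(y, axis=0)
    freqs = np.fft.rfftfreq(t_len, d=cfg.tr_seconds)
    mask = (freqs >= cfg.band_low_hz) & (freqs <= cfg.band_high_hz)
    spec[~mask] = 0.0
    return np.fft.irfft(spec, n=t_len, axis=0)


def preprocess_series(
    ts: np.ndarray,
    motion: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    cfg: PreprocessConfig | None = None,
) -> np.ndarray:
    """Full temporal pipeline: discard -> nuisance regression -> band-pass.

    `motion` (T, 6) is expanded to Friston-24 regressors when the config
    requests them; `nuisance` holds any extra T x K regressors (e.g. the
    white-matter / CSF surrogate signals). Both are trimmed by
    `n_discard` alongside the series.
    """
    cfg = cfg or PreprocessConfig()
    y = discard_initial_volumes(ts, cfg.n_discard)
    cols = []
    if "linear_trend" in cfg.nuisance_spec:
        cols.append(np.linspace(-1.0, 1.0, y.shape[0])[:, None])
    if nuisance is not None and np.size(nuisance):
        nz = np.asarray(nuisance, dtype=float)
        if nz.ndim == 1:
            nz = nz[:, None]
        cols.append(discard_initial_volumes(nz, cfg.n_discard))
    if motion is not None and "friston24" in cfg.nuisance_spec:
        cols.append(friston24(discard_initial_volumes(motion, cfg.n_discard)))
    reg = np.hstack(cols) if cols else None
    y = regress_nuisance(y, reg)
    return bandpass_filter(y, cfg)
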