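"""Resting-state preprocessing chain for 4D BOLD grids.

Stage order is fixed: discard initial volumes → (slice timing, a no-op for
synthetic data) → nuisance regression (24 motion terms, linear trend, WM and
CSF mean signals, intercept) → ideal band-pass filter 0.01–0.1 Hz →
3D Gaussian smoothing at 6 mm FWHM. Every stage is a pure function; the
driver returns a provenance record of stages and parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .synthdata import SubjectDataset

__all__ = [
    "PreprocConfig",
    "FDSeries",
    "discard_initial_volumes",
    "compute_fd",
    "motion_qc",
    "friston24",
    "build_nuisance_design",
    "regress_nuisance",
    "bandpass",
    "gaussian_smooth",
    "preprocess_subject",
]


@dataclass(frozen=True)
class PreprocConfig:
    n_discard: int = 10
    band: tuple = (0.01, 0.1)          # Hz
    fwhm_mm: float = 6.0
    motion_thresh_mm: float = 3.0
    motion_thresh_deg: float = 3.0
    fd_radius_mm: float = 50.0
    voxel_size_mm: float = 3.0
    # "data": smooth the time series before FC; "maps": leave the series
    # unsmoothed and smooth derived FC maps downstream instead.
    smooth_domain: str = "data"

    def validate(self, n_volumes: int, tr: float) -> None:
        low, high = self.band
        nyquist = 1.0 / (2.0 * tr)
        if not (0 < low < high < nyquist):
            raise ValueError(f"band {self.band} outside (0, Nyquist={nyquist:g})")
        if not (0 <= self.n_discard < n_volumes):
            raise ValueError("n_discard must be < n_volumes")
        if self.fwhm_mm < 0:
            raise ValueError("fwhm must be >= 0")
        if self.smooth_domain not in ("data", "maps"):
            raise ValueError("smooth_domain must be 'data' or 'maps'")


@dataclass(frozen=True)
class FDSeries:
    """Power-style framewise displacement, one value per volume (leading 0)."""

    fd: np.ndarray
    mean_fd: float


def discard_initial_volumes(bold: np.ndarray, n: int) -> np.ndarray:
    """Drop the first ``n`` volumes (signal-equilibration discard)."""
    if not 0 <= n < bold.shape[-1]:
        raise ValueError(
            f"cannot discard {n} of {bold.shape[-1]} volumes (empty result)")
    return bold[..., n:]


def compute_fd(motion: np.ndarray, radius_mm: float = 50.0) -> FDSeries:
    """Framewise displacement: sum of |Δtranslation| plus radius·|Δrotation|.

    ``motion`` is (t, 6) with translations in mm and rotations in radians;
    rotations are converted to arc length on a sphere of ``radius_mm``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have 6 parameter columns")
    if motion.shape[0] < 2:
        raise ValueError("motion needs at least 2 time points")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius_mm * d[:, 3:].sum(axis=1)
    return FDSeries(fd=np.concatenate([[0.0], fd]), mean_fd=float(fd.mean()))


def motion_qc(motion: np.ndarray, thresh_mm: float = 3.0,
              thresh_deg: float = 3.0):
    """Head-motion exclusion check against translation/rotation thresholds.

    Excursion is measured from the first (reference) volume. Returns
    ``(passed, offending_volumes)``.
    """
    motion = np.asarray(motion, dtype=float)
    exc = motion - motion[0]
    bad_t = np.abs(exc[:, :3]).max(axis=1) > thresh_mm
    bad_r = np.degrees(np.abs(exc[:, 3:]).max(axis=1)) > thresh_deg
    offending = np.flatnonzero(bad_t | bad_r)
    return offending.size == 0, offending


def friston24(motion: np.ndarray) -> np.ndarray:
    """24-parameter motion expansion: [p, p_{t-1}, p², p_{t-1}²] per parameter.

    The one-step-back series is padded with 0 at the first time point.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must have 6 parameter columns")
    shifted = np.vstack([np.zeros(6), motion[:-1]])
    return np.hstack([motion, shifted, motion ** 2, shifted ** 2])


def build_nuisance_design(motion: np.ndarray, wm_signal: np.ndarray,
                          csf_signal: np.ndarray) -> np.ndarray:
    """Nuisance design: Friston-24 + linear trend + WM + CSF + intercept (k=28)."""
    t = motion.shape[0]
    trend = np.linspace(-1, 1, t)
    return np.column_stack([
        friston24(motion), trend, wm_signal, csf_signal, np.ones(t)])


def regress_nuisance(bold: np.ndarray, design: np.ndarray) -> np.ndarray:
    """OLS residuals of every voxel time series on the nuisance design.

    Columns are scaled to unit RMS for conditioning (scaling preserves the
    column space, so residuals equal those of the raw design); dependent or
    all-zero columns of a rank-deficient design are dropped with a warning.
    """
    t = bold.shape[-1]
    X = np.asarray(design, dtype=float)
    if X.shape[0] != t:
        raise ValueError(f"design has {X.shape[0]} rows, bold has {t} volumes")
    norms = np.sqrt((X * X).mean(axis=0))
    zero = norms == 0
    if zero.any():
        warnings.warn(f"dropping {int(zero.sum())} all-zero design column(s)",
                      RuntimeWarning)
        X, norms = X[:, ~zero], norms[~zero]
    Xs = X / norms
    if np.linalg.matrix_rank(Xs) < Xs.shape[1]:
        keep = _independent_columns(Xs)
        warnings.warn(
            f"nuisance design rank deficient; dropped {Xs.shape[1] - keep.sum()} "
            "dependent column(s)", RuntimeWarning)
        Xs = Xs[:, keep]
    Q, _ = np.linalg.qr(Xs, mode="reduced")
    Y = bold.reshape(-1, t).T.astype(float)      # (t, V)
    resid = Y - Q @ (Q.T @ Y)
    return np.ascontiguousarray(resid.T).reshape(bold.shape)


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Greedy left-to-right selection of a full-rank column subset."""
    keep = np.zeros(X.shape[1], dtype=bool)
    basis = []
    for j in range(X.shape[1]):
        trial = basis + [X[:, j]]
        if np.linalg.matrix_rank(np.column_stack(trial)) == len(trial):
            basis = trial
            keep[j] = True
    return keep


def bandpass(bold: np.ndarray, tr: float, low: float = 0.01,
             high: float = 0.1) -> np.ndarray:
    """Ideal frequency-mask band-pass filter per voxel time series.

    DFT components with ``low <= f <= high`` are retained, everything else
    (including DC) is zeroed — the frequency-domain filter used by the
    common resting-state toolboxes, exactly testable on on-bin sinusoids.
    """
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high <= nyquist):
        raise ValueError(f"band ({low}, {high}) outside (0, Nyquist={nyquist:g}]")
    n = bold.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= low) & (freqs <= high)
    spec = np.fft.rfft(bold, axis=-1)
    spec[..., ~keep] = 0
    return np.fft.irfft(spec, n=n, axis=-1)


def gaussian_smooth(bold: np.ndarray, fwhm_mm: float,
                    voxel_size_mm: float = 3.0) -> np.ndarray:
    """Volume-wise 3D Gaussian smoothing, σ = FWHM/(2√(2 ln 2)) in voxels.

    Boundary handling is reflect padding; ``fwhm_mm=0`` is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return bold.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm
    sigma = (sigma_vox,) * 3 + ((0.0,) if bold.ndim == 4 else ())
    return ndimage.gaussian_filter(bold.astype(float), sigma=sigma, mode="reflect")


def preprocess_subject(dataset: SubjectDataset, config: PreprocConfig = PreprocConfig()):
    """Run the full chain on one subject; returns (dataset, provenance list).

    The returned dataset holds the preprocessed series and the trimmed
    motion trace; the input is left untouched (the chain is pure).
    """
    config.validate(dataset.n_volumes, dataset.tr)
    stages = []
    bold = discard_initial_volumes(np.asarray(dataset.bold, dtype=float),
                                   config.n_discard)
    motion = dataset.motion[config.n_discard:]
    stages.append({"stage": "discard_initial_volumes", "n": config.n_discard})
    stages.append({"stage": "slice_timing", "note": "no-op for synthetic data"})

    wm = bold[dataset.wm_mask].mean(axis=0)
    csf = bold[dataset.csf_mask].mean(axis=0)
    design = build_nuisance_design(motion, wm, csf)
    bold = regress_nuisance(bold, design)
    stages.append({"stage": "regress_nuisance", "n_columns": design.shape[1]})

    bold = bandpass(bold, dataset.tr, *config.band)
    stages.append({"stage": "bandpass", "band_hz": list(config.band)})

    if config.smooth_domain == "data":
        bold = gaussian_smooth(bold, config.fwhm_mm, config.voxel_size_mm)
    stages.append({"stage": "gaussian_smooth", "fwhm_mm": config.fwhm_mm,
                   "domain": config.smooth_domain})

    out = replace_dataset(dataset, bold=bold.astype(np.float32), motion=motion)
    return out, stages


def replace_dataset(dataset: SubjectDataset, **kw) -> SubjectDataset:
    return replace(dataset, **kw)
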