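"""Seed-to-voxel static FC maps and sliding-window dynamic FC variability.

Static FC is the Pearson correlation of every voxel's time series with a
seed ROI's mean series, Fisher r-to-z transformed. Dynamic FC variability is
the standard deviation, across sliding windows (default 30 TR length, 1 TR
step, Hamming taper), of the per-window seed-to-voxel correlations — a
larger SD marks greater temporal fluctuation of coupling strength.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthdata import AtlasVolume, SubjectDataset

__all__ = [
    "WindowSpec",
    "FCMap",
    "WindowStack",
    "DynFCMap",
    "n_windows",
    "roi_mean_timeseries",
    "fisher_z",
    "static_fc_map",
    "windowed_fc",
    "dynamic_fc_map",
    "subject_fc_battery",
]

_R_CLIP = 1.0 - 1e-7  # |r| is clipped here before atanh to keep maps finite


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window parameters: length and step in TR units, taper choice."""

    length_tr: int = 30
    step_tr: int = 1
    taper: str = "hamming"

    def __post_init__(self):
        if self.length_tr <= 2:
            raise ValueError("window length must exceed 2 TR")
        if self.step_tr < 1:
            raise ValueError("step must be >= 1 TR")
        if self.taper not in ("hamming", "rectangular"):
            raise ValueError(f"unknown taper {self.taper!r}")

    def weights(self) -> np.ndarray:
        if self.taper == "hamming":
            return np.hamming(self.length_tr)
        return np.ones(self.length_tr)


@dataclass
class FCMap:
    """Per-subject 3D map of Fisher-z static FC for one seed."""

    values: np.ndarray
    seed: int
    subject_id: str = ""
    zero_variance: np.ndarray | None = None  # voxels flagged z=0 for flat series


@dataclass
class WindowStack:
    """Per-window 3D correlation grids, stacked along the first axis."""

    r: np.ndarray            # (n_windows, x, y, z)
    spec: WindowSpec

    @property
    def n_windows(self) -> int:
        return self.r.shape[0]


@dataclass
class DynFCMap:
    """SD (the variability measure) and mean of r across windows, per voxel."""

    sd: np.ndarray
    mean: np.ndarray
    seed: int
    subject_id: str = ""


def n_windows(n_timepoints: int, spec: WindowSpec) -> int:
    """Number of sliding windows: floor((T - length)/step) + 1."""
    if spec.length_tr > n_timepoints:
        raise ValueError(
            f"window of {spec.length_tr} TR exceeds series length {n_timepoints}")
    return (n_timepoints - spec.length_tr) // spec.step_tr + 1


def roi_mean_timeseries(bold: np.ndarray, atlas: AtlasVolume, label: int,
                        brain_mask: np.ndarray | None = None) -> np.ndarray:
    """Unweighted mean time series over one ROI's voxels."""
    mask = atlas.voxels(label)
    if brain_mask is not None:
        mask = mask & brain_mask
    if not mask.any():
        raise ValueError(f"ROI label {label} has no voxels inside the mask")
    return np.asarray(bold, dtype=float)[mask].mean(axis=0)


def fisher_z(r):
    """Fisher r-to-z transform, with |r| clipped to 1 - 1e-7 to stay finite."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    return np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))


def _pearson_vs_seed(X: np.ndarray, seed: np.ndarray,
                     weights: np.ndarray | None = None):
    """Pearson r of every row of X (V, T) with the seed series.

    With ``weights`` the correlation is the weighted-moment version:
    weighted means, variances and covariance with the taper as weights.
    Zero-variance rows get r = 0 and are flagged.
    """
    T = seed.shape[0]
    if weights is None:
        w = np.full(T, 1.0 / T)
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    sc = seed - w @ seed
    Xc = X - (X @ w)[:, None]
    cov = Xc @ (w * sc)
    var_s = w @ (sc * sc)
    var_x = (Xc * Xc) @ w
    # constant rows leave only rounding residue after centering
    ms = np.maximum((X * X) @ w, np.finfo(float).tiny)
    flat = var_x <= 1e-14 * ms
    if var_s <= 1e-14 * max(float(w @ (seed * seed)), np.finfo(float).tiny):
        raise ValueError("seed series is constant")
    denom = np.sqrt(np.where(flat, 1.0, var_x) * var_s)
    r = np.where(flat, 0.0, cov / denom)
    return np.clip(r, -1.0, 1.0), flat


def static_fc_map(bold: np.ndarray, seed_series: np.ndarray, seed: int = 0,
                  subject_id: str = "",
                  brain_mask: np.ndarray | None = None) -> FCMap:
    """Voxel-wise Pearson correlation with the seed, Fisher z-transformed."""
    bold = np.asarray(bold, dtype=float)
    if bold.shape[-1] != seed_series.shape[0]:
        raise ValueError("seed series length must match bold time length")
    shape = bold.shape[:-1]
    X = bold.reshape(-1, bold.shape[-1])
    r, flat = _pearson_vs_seed(X, np.asarray(seed_series, dtype=float))
    z = fisher_z(r)
    z[flat] = 0.0
    zv = flat.reshape(shape)
    if brain_mask is not None:
        z[~brain_mask.reshape(-1)] = 0.0
    return FCMap(values=z.reshape(shape), seed=seed, subject_id=subject_id,
                 zero_variance=zv)


def windowed_fc(bold: np.ndarray, seed_series: np.ndarray,
                spec: WindowSpec = WindowSpec()) -> WindowStack:
    """Per-window (taper-weighted) seed-to-voxel correlation maps."""
    bold = np.asarray(bold, dtype=float)
    seed_series = np.asarray(seed_series, dtype=float)
    T = bold.shape[-1]
    if seed_series.shape[0] != T:
        raise ValueError("seed series length must match bold time length")
    W = n_windows(T, spec)
    shape = bold.shape[:-1]
    X = bold.reshape(-1, T)
    w = spec.weights()
    out = np.empty((W,) + shape)
    for k in range(W):
        start = k * spec.step_tr
        sl = slice(start, start + spec.length_tr)
        r, _ = _pearson_vs_seed(X[:, sl], seed_series[sl], weights=w)
        out[k] = r.reshape(shape)
    return WindowStack(r=out, spec=spec)


def dynamic_fc_map(stack: WindowStack, seed: int = 0, subject_id: str = "",
                   z_domain: bool = False) -> DynFCMap:
    """Per-voxel SD (ddof=1) and mean of correlation across windows.

    ``z_domain=True`` computes the SD/mean on Fisher-z values instead of r.
    """
    if stack.n_windows < 2:
        raise ValueError("need at least 2 windows to compute variability")
    vals = fisher_z(stack.r) if z_domain else stack.r
    return DynFCMap(sd=vals.std(axis=0, ddof=1), mean=vals.mean(axis=0),
                    seed=seed, subject_id=subject_id)


def subject_fc_battery(dataset: SubjectDataset, atlas: AtlasVolume,
                       spec: WindowSpec = WindowSpec(),
                       seeds=None, z_domain_sd: bool = False) -> dict:
    """Static + dynamic maps for every seed label of a preprocessed subject.

    Returns ``{label: (FCMap, DynFCMap)}`` for the requested seeds (default
    every atlas label, 28 for the full nucleus atlas).
    """
    seeds = atlas.seed_labels if seeds is None else list(seeds)
    bold = np.asarray(dataset.bold, dtype=float)
    out = {}
    for label in seeds:
        ts = roi_mean_timeseries(bold, atlas, label, dataset.brain_mask)
        fcm = static_fc_map(bold, ts, seed=label, subject_id=dataset.subject_id,
                            brain_mask=dataset.brain_mask)
        stack = windowed_fc(bold, ts, spec)
        dyn = dynamic_fc_map(stack, seed=label, subject_id=dataset.subject_id,
                             z_domain=z_domain_sd)
        out[label] = (fcm, dyn)
    return out
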