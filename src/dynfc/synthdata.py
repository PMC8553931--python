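"""Synthetic resting-state BOLD cohorts with planted seed-target coupling.

Generates multi-subject 4D datasets whose statistical structure matches what
a seed-to-voxel functional-connectivity analysis assumes: band-limited
BOLD-like voxel signals, a labeled nucleus atlas, per-subject rigid-body
motion traces, tissue masks, and a clinical score table. Coupling between a
seed region and a target region is either stationary (a static-FC effect) or
slowly amplitude-modulated (a dynamic-FC-variability effect) with
group-dependent modulation amplitude, so every downstream stage of the
pipeline can be validated against known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "THALAMIC_NUCLEI",
    "PlantedEffect",
    "CohortSpec",
    "SubjectDataset",
    "AtlasVolume",
    "build_atlas",
    "coupling_series",
    "band_limited_noise",
    "generate_subject",
    "generate_clinical_table",
    "generate_cohort",
    "write_cohort",
]

GROUPS = ("FOG", "NFOG", "HC")

# Dorsal thalamus subdivisions used as seeds: 14 nuclei per hemisphere
# (the reuniens is conventionally excluded as too small to analyse).
THALAMIC_NUCLEI = (
    "AV", "LP", "VA", "VL", "VPL", "IL", "MDm", "MDl",
    "LGN", "MGN", "PuA", "PuM", "PuL", "PuI",
)

# Clinical score distributions used for the synthetic cohort table
# (mean, sd) per group; NA entries are omitted for groups that lack them.
_CLINICAL_DISTS = {
    "age": {"FOG": (65.32, 8.385), "NFOG": (65.24, 6.796), "HC": (63.88, 8.212)},
    "mmse": {"FOG": (26.0, 2.517), "NFOG": (26.12, 1.878), "HC": (27.2, 1.5)},
    "illness_duration": {"FOG": (7.44, 4.435), "NFOG": (6.70, 2.309)},
    "updrs3": {"FOG": (33.32, 15.247), "NFOG": (32.96, 10.964)},
    "ledd": {"FOG": (466.0, 179.971), "NFOG": (377.5, 132.925)},
    "hoehn_yahr": {"FOG": (2.6, 0.791), "NFOG": (2.46, 0.721)},
    "nfogq": {"FOG": (20.52, 5.539)},
}
_MALE_FRACTION = {"FOG": 13 / 25, "NFOG": 13 / 25, "HC": 11 / 25}


@dataclass(frozen=True)
class PlantedEffect:
    """A seed→target coupling effect planted into the cohort.

    ``base_coupling`` is the stationary correlation-scale coupling between
    the seed's latent signal and the target region. For
    ``kind="dynamic_variability"`` the coupling is modulated sinusoidally
    with group-dependent amplitude ``modulation_amplitude[group]`` and
    period ``modulation_period`` seconds; for ``kind="static_fc"`` all
    amplitudes must be zero and the group difference (if any) lies in
    ``base_coupling_by_group``.
    """

    seed_roi: int
    target_roi: int
    kind: str = "dynamic_variability"
    base_coupling: float = 0.3
    modulation_amplitude: dict = field(default_factory=dict)
    modulation_period: float = 180.0
    base_coupling_by_group: dict = field(default_factory=dict)
    # Per-subject modulation amplitudes are drawn around the group value
    # with this coefficient of variation (0 = identical within group).
    amplitude_cv: float = 0.25
    # Optional slow-random-walk modulation instead of the sinusoid.
    modulation_mode: str = "sinusoid"

    def __post_init__(self):
        if self.kind not in ("static_fc", "dynamic_variability"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.modulation_mode not in ("sinusoid", "random_walk"):
            raise ValueError(f"unknown modulation mode {self.modulation_mode!r}")
        amps = dict(self.modulation_amplitude)
        if any(a < 0 for a in amps.values()):
            raise ValueError("modulation amplitudes must be >= 0")
        if self.kind == "static_fc" and any(a != 0 for a in amps.values()):
            raise ValueError("static_fc effect must have zero modulation amplitude")
        max_amp = max(amps.values(), default=0.0)
        bases = [self.base_coupling] + list(self.base_coupling_by_group.values())
        if any(abs(b) + max_amp >= 1 for b in bases):
            raise ValueError(
                "invalid effect: |base_coupling| + max modulation amplitude "
                f"reaches {max(abs(b) for b in bases) + max_amp:.3f} >= 1"
            )

    def group_amplitude(self, group: str) -> float:
        return float(self.modulation_amplitude.get(group, 0.0))

    def group_base(self, group: str) -> float:
        return float(self.base_coupling_by_group.get(group, self.base_coupling))


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults emulate a three-group resting-state study: 25 subjects per
    group, 185 volumes at TR = 2 s, with signals band-limited to the
    0.01–0.1 Hz range conventionally analysed at rest.
    """

    n_per_group: int = 25
    n_volumes: int = 185
    tr: float = 2.0
    grid_shape: tuple = (16, 16, 16)
    groups: tuple = GROUPS
    effects: tuple = ()
    rng_seed: int = 0
    noise_sigma: float = 0.5           # voxel noise SD relative to unit-variance latent
    band: tuple = (0.01, 0.1)          # Hz, generation band of the BOLD-like signals
    motion_step_mm: float = 0.02       # SD of the per-volume translation random-walk step
    motion_step_rad: float = 2e-4      # SD of the per-volume rotation random-walk step
    nfogq_rho: float = 0.6             # target corr. of NFOGQ with true modulation amplitude

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.groups) != 3:
            raise ValueError("exactly three groups are expected")
        if self.n_volumes < 4:
            raise ValueError("n_volumes too small")
        if min(self.grid_shape) < 6 or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 dims of at least 6 voxels")
        object.__setattr__(self, "effects", tuple(self.effects))
        # the grid must be able to host all atlas labels plus tissue masks
        build_atlas(self.grid_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = [asdict(e) for e in self.effects]
        return d


@dataclass
class SubjectDataset:
    """One subject's 4D BOLD grid plus motion trace, tissue masks and label."""

    bold: np.ndarray              # (x, y, z, t)
    motion: np.ndarray            # (t, 6): 3 translations mm, 3 rotations rad
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    brain_mask: np.ndarray
    group: str
    subject_id: str
    tr: float = 2.0
    # ground truth for validation analyses, never consumed by the pipeline
    true_amplitude: float = 0.0

    def __post_init__(self):
        if self.bold.ndim != 4:
            raise ValueError("bold must be 4D (x, y, z, t)")
        if self.motion.shape != (self.bold.shape[3], 6):
            raise ValueError("motion must be (t, 6)")
        for m in (self.wm_mask, self.csf_mask):
            if np.any(m & ~self.brain_mask):
                raise ValueError("tissue masks must be subsets of brain_mask")
        if np.any(self.wm_mask & self.csf_mask):
            raise ValueError("WM and CSF masks must be disjoint")

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[3]


@dataclass(frozen=True)
class AtlasVolume:
    """Integer label volume with a label → region-name lookup (0 = background).

    ``lookup`` holds the nucleus seed labels (1..28); ``targets`` holds the
    larger cortical target regions (101..) that planted effects project to.
    """

    labels: np.ndarray
    lookup: dict
    targets: dict = field(default_factory=dict)

    def voxels(self, label: int) -> np.ndarray:
        """Boolean mask of one label's voxels."""
        if label not in self.lookup and label not in self.targets:
            raise KeyError(f"label {label} not in atlas")
        return self.labels == label

    @property
    def seed_labels(self) -> list:
        return sorted(self.lookup)


def build_atlas(grid_shape, nuclei=THALAMIC_NUCLEI) -> AtlasVolume:
    """Lay out compact 2x2x2 ROI boxes for every nucleus x hemisphere.

    Boxes sit on a lattice with one-voxel gaps, left-hemisphere labels are
    odd, right even (label = 2*i+1 / 2*i+2 for nucleus i). The two lattice
    slots after the last ROI are reserved by ``generate_subject`` for the
    WM and CSF masks. Raises if the grid cannot host every label.
    """
    step, box = 3, 2
    slots = [
        (i, j, k)
        for i in range(grid_shape[0] // step)
        for j in range(grid_shape[1] // step)
        for k in range(grid_shape[2] // step)
    ]
    n_labels = 2 * len(nuclei)
    if len(slots) < n_labels + 2:  # +2 tissue-mask slots
        raise ValueError(
            f"grid {grid_shape} too small for {n_labels} ROI labels plus tissue masks"
        )
    labels = np.zeros(grid_shape, dtype=np.int32)
    lookup = {}
    for idx, name in enumerate(nuclei):
        for hemi_offset, hemi in ((1, "L"), (2, "R")):
            label = 2 * idx + hemi_offset
            i, j, k = slots[label - 1]
            labels[i * step:i * step + box,
                   j * step:j * step + box,
                   k * step:k * step + box] = label
            lookup[label] = f"Thal_{name}_{hemi}"
    # Larger "cortical" target regions (4x4x4) in the free upper-x half of
    # the grid: planted effects project a nucleus seed onto one of these,
    # mirroring seed-to-voxel analyses where the coupled region is a patch
    # of cortex much larger than a nucleus. Requires a grid of >= 12 voxels.
    targets = {}
    nx, ny, nz = grid_shape
    if min(grid_shape) >= 12:
        tbox = 4
        x0 = nx - tbox - 1
        corners = [(1, 1), (1, nz - tbox - 1), (ny - tbox - 1, 1),
                   (ny - tbox - 1, nz - tbox - 1)]
        for t, (y0, z0) in enumerate(corners):
            label = 101 + t
            block = labels[x0:x0 + tbox, y0:y0 + tbox, z0:z0 + tbox]
            if np.any(block != 0):
                continue
            labels[x0:x0 + tbox, y0:y0 + tbox, z0:z0 + tbox] = label
            targets[label] = f"Ctx_{'ABCD'[t]}"
    return AtlasVolume(labels=labels, lookup=lookup, targets=targets)


def _mask_slot(grid_shape, slot_index) -> np.ndarray:
    """2x2x2 box at a lattice slot (used for the WM/CSF mask slots)."""
    step, box = 3, 2
    slots = [
        (i, j, k)
        for i in range(grid_shape[0] // step)
        for j in range(grid_shape[1] // step)
        for k in range(grid_shape[2] // step)
    ]
    i, j, k = slots[slot_index]
    m = np.zeros(grid_shape, dtype=bool)
    m[i * step:i * step + box, j * step:j * step + box, k * step:k * step + box] = True
    return m


def coupling_series(effect: PlantedEffect, group: str, n_volumes: int, tr: float,
                    rng: np.random.Generator, amplitude: float | None = None) -> np.ndarray:
    """Time-varying coupling coefficient c(t) for one subject.

    Sinusoid mode: ``c(t) = base + a*sin(2*pi*t*tr/period + phi)`` with the
    phase drawn once from ``rng``. Random-walk mode: a reflected Gaussian
    random walk scaled to the same RMS excursion, for robustness checks.
    Raises if the series could reach |c| >= 1.
    """
    a = effect.group_amplitude(group) if amplitude is None else float(amplitude)
    base = effect.group_base(group)
    if abs(base) + a >= 1:
        raise ValueError(
            f"coupling series invalid: |{base}| + {a} = {abs(base) + a:.3f} >= 1"
        )
    t = np.arange(n_volumes) * tr
    if effect.modulation_mode == "sinusoid" or a == 0:
        phi = rng.uniform(0, 2 * np.pi)
        return base + a * np.sin(2 * np.pi * t / effect.modulation_period + phi)
    # slow random walk with the sinusoid's RMS (a/sqrt(2)), reflected at +-a
    steps = rng.normal(0.0, 1.0, n_volumes)
    walk = np.cumsum(steps)
    walk -= walk.mean()
    rms = np.sqrt(np.mean(walk ** 2))
    walk = walk / rms * (a / np.sqrt(2)) if rms > 0 else walk
    walk = np.clip(walk, -a, a)
    return base + walk


def band_limited_noise(shape, tr: float, band, rng: np.random.Generator) -> np.ndarray:
    """White Gaussian noise restricted to a frequency band, unit variance.

    ``shape`` is (..., t); an ideal frequency mask keeps DFT bins with
    ``band[0] <= f <= band[1]`` and the result is standardized per series.
    """
    x = rng.standard_normal(shape)
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr)
    keep = (freqs >= band[0]) & (freqs <= band[1])
    if not keep.any():
        raise ValueError(f"band {band} contains no DFT bin at T={n}, TR={tr}")
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0
    y = np.fft.irfft(spec, n=n, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return y / sd


def _subject_amplitude(effect: PlantedEffect, group: str, rng) -> float:
    """Per-subject modulation amplitude around the group value."""
    a = effect.group_amplitude(group)
    if a == 0 or effect.amplitude_cv == 0:
        return a
    draw = a * (1.0 + effect.amplitude_cv * rng.standard_normal())
    hi = 1.0 - abs(effect.group_base(group)) - 1e-3
    return float(np.clip(draw, 0.0, hi))


def generate_subject(spec: CohortSpec, group: str, rng: np.random.Generator,
                     subject_id: str = "sub-000",
                     atlas: AtlasVolume | None = None) -> SubjectDataset:
    """Simulate one subject's 4D BOLD grid, motion trace and tissue masks.

    Background voxels carry independent band-limited noise. Seed-ROI voxels
    share a unit-variance latent signal plus voxel noise. Each target-ROI
    voxel is ``c(t)*latent + sqrt(1-c(t)^2)*independent + voxel noise`` with
    its own independent component, so the expected windowed correlation with
    the seed tracks c(t) while sampling noise stays voxel-wise independent.
    """
    if group not in spec.groups:
        raise ValueError(f"unknown group {group!r}")
    atlas = atlas or build_atlas(spec.grid_shape)
    T = spec.n_volumes
    bold = band_limited_noise(spec.grid_shape + (T,), spec.tr, spec.band, rng)

    true_amp = 0.0
    for effect in spec.effects:
        latent = band_limited_noise((T,), spec.tr, spec.band, rng)
        amp = _subject_amplitude(effect, group, rng)
        true_amp = max(true_amp, amp)
        c = coupling_series(effect, group, T, spec.tr, rng, amplitude=amp)

        seed_mask = atlas.voxels(effect.seed_roi)
        targ_mask = atlas.voxels(effect.target_roi)
        n_targ = int(targ_mask.sum())
        nz = spec.noise_sigma
        seed_noise = band_limited_noise((int(seed_mask.sum()), T), spec.tr, spec.band, rng)
        indep = band_limited_noise((n_targ, T), spec.tr, spec.band, rng)
        targ_noise = band_limited_noise((n_targ, T), spec.tr, spec.band, rng)
        bold[seed_mask] = latent + nz * seed_noise
        bold[targ_mask] = (c * latent + np.sqrt(1.0 - c ** 2) * indep
                           + nz * targ_noise)

    # cumulative small-step random walk: gentle drifting head motion
    steps = np.empty((T, 6))
    steps[:, :3] = rng.normal(0, spec.motion_step_mm, (T, 3))
    steps[:, 3:] = rng.normal(0, spec.motion_step_rad, (T, 3))
    steps[0] = 0.0
    motion = np.cumsum(steps, axis=0)

    brain_mask = np.ones(spec.grid_shape, dtype=bool)
    n_rois = 2 * len(THALAMIC_NUCLEI)
    wm_mask = _mask_slot(spec.grid_shape, n_rois)
    csf_mask = _mask_slot(spec.grid_shape, n_rois + 1)
    return SubjectDataset(
        bold=bold.astype(np.float32), motion=motion, wm_mask=wm_mask,
        csf_mask=csf_mask, brain_mask=brain_mask, group=group,
        subject_id=subject_id, tr=spec.tr, true_amplitude=true_amp,
    )


def _correlated_scores(anchor: np.ndarray, rho: float, rng) -> np.ndarray:
    """Standard-normal scores with target correlation ``rho`` to ``anchor``."""
    n = len(anchor)
    noise = rng.standard_normal(n)
    sd = anchor.std()
    z = (anchor - anchor.mean()) / sd if sd > 0 else np.zeros(n)
    return rho * z + np.sqrt(max(0.0, 1 - rho ** 2)) * noise


def generate_clinical_table(spec: CohortSpec, subjects: list, rng) -> pd.DataFrame:
    """Clinical score table for a cohort (NFOGQ present only for FOG).

    NFOGQ is generated with correlation ``spec.nfogq_rho`` to each FOG
    subject's true planted modulation amplitude, so the clinical-association
    stage of the pipeline has a recoverable ground truth.
    """
    rows = []
    by_group: dict = {}
    for s in subjects:
        by_group.setdefault(s.group, []).append(s)
    nfogq_by_id = {}
    fog = by_group.get("FOG", [])
    if fog:
        amps = np.array([s.true_amplitude for s in fog])
        z = _correlated_scores(amps, spec.nfogq_rho, rng)
        m, sd = _CLINICAL_DISTS["nfogq"]["FOG"]
        vals = np.clip(m + sd * z, 1.0, 28.0)
        nfogq_by_id = {s.subject_id: v for s, v in zip(fog, vals)}

    for group, members in by_group.items():
        n = len(members)
        n_male = int(round(_MALE_FRACTION.get(group, 0.5) * n))
        sexes = ["M"] * n_male + ["F"] * (n - n_male)
        for i, s in enumerate(members):
            row = {"subject_id": s.subject_id, "group": group, "sex": sexes[i]}
            for col in ("age", "mmse", "illness_duration", "updrs3", "ledd",
                        "hoehn_yahr", "nfogq"):
                dist = _CLINICAL_DISTS[col].get(group)
                if dist is None:
                    row[col] = np.nan
                elif col == "nfogq":
                    row[col] = nfogq_by_id[s.subject_id]
                elif col == "hoehn_yahr":
                    m, sd = dist
                    row[col] = float(np.clip(round(2 * (m + sd * rng.standard_normal())) / 2, 1.0, 5.0))
                else:
                    m, sd = dist
                    row[col] = m + sd * rng.standard_normal()
            rows.append(row)
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec):
    """Generate the full cohort: subjects, atlas and clinical table.

    Returns ``(subjects, atlas, clinical)`` with ``3 * n_per_group``
    subjects. Identical ``spec.rng_seed`` gives a bit-identical cohort.
    """
    root = np.random.SeedSequence(spec.rng_seed)
    subject_seed, clinical_seed = root.spawn(2)
    atlas = build_atlas(spec.grid_shape)
    subjects = []
    seeds = subject_seed.spawn(3 * spec.n_per_group)
    k = 0
    for group in spec.groups:
        for i in range(spec.n_per_group):
            rng = np.random.default_rng(seeds[k])
            subjects.append(generate_subject(
                spec, group, rng, subject_id=f"sub-{group}-{i:03d}", atlas=atlas))
            k += 1
    clinical = generate_clinical_table(
        spec, subjects, np.random.default_rng(clinical_seed))
    return subjects, atlas, clinical


def dynamic_effect_spec(rng_seed: int = 0, n_per_group: int = 25,
                        grid_shape=(12, 12, 12), n_volumes: int = 185,
                        fog_amplitude: float = 0.35,
                        nfogq_rho: float = 0.6) -> CohortSpec:
    """Canonical test-bed cohort: one dynamic-variability effect in FOG only.

    A strongly coupled nucleus→cortex pair (left intralaminar seed, label
    11, onto cortical target region 101; base coupling 0.6) whose coupling
    is sinusoidally modulated with amplitude ``fog_amplitude`` in the FOG
    group and unmodulated elsewhere. NFOGQ-like scores correlate with the
    per-subject amplitude at ``nfogq_rho``.
    """
    effect = PlantedEffect(
        seed_roi=11, target_roi=101, kind="dynamic_variability",
        base_coupling=0.6, modulation_amplitude={"FOG": fog_amplitude})
    return CohortSpec(n_per_group=n_per_group, n_volumes=n_volumes,
                      grid_shape=tuple(grid_shape), effects=(effect,),
                      rng_seed=rng_seed, nfogq_rho=nfogq_rho)


def null_cohort_spec(rng_seed: int = 0, n_per_group: int = 8,
                     grid_shape=(12, 12, 12), n_volumes: int = 120) -> CohortSpec:
    """A no-effect cohort for calibration of false-positive rates."""
    return CohortSpec(n_per_group=n_per_group, n_volumes=n_volumes,
                      grid_shape=tuple(grid_shape), effects=(),
                      rng_seed=rng_seed)


def write_cohort(spec: CohortSpec, out_dir, subjects=None, atlas=None, clinical=None):
    """Write a cohort to disk: NIfTI volumes, TSV clinical table, JSON spec."""
    from . import io as dio  # local import: io depends on this module's types

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if subjects is None:
        subjects, atlas, clinical = generate_cohort(spec)
    dio.write_volume(atlas.labels, out / "atlas.nii", voxel_size_mm=3.0)
    with open(out / "atlas_lookup.json", "w") as fh:
        json.dump({"seeds": {str(k): v for k, v in atlas.lookup.items()},
                   "targets": {str(k): v for k, v in atlas.targets.items()}},
                  fh, indent=1)
    for s in subjects:
        dio.write_volume(s.bold, out / f"{s.subject_id}_bold.nii",
                         voxel_size_mm=3.0, tr=s.tr)
        dio.write_motion(s.motion, out / f"rp_{s.subject_id}.txt")
        dio.write_volume(s.wm_mask.astype(np.int16), out / f"{s.subject_id}_wm.nii", 3.0)
        dio.write_volume(s.csf_mask.astype(np.int16), out / f"{s.subject_id}_csf.nii", 3.0)
    clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(spec.to_dict(), fh, indent=1)
    return out
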