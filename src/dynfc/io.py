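"""NIfTI/TSV/JSON formats, run configuration, provenance, and the pipeline driver.

Volumes travel as NIfTI-1 with the voxel size (and TR for 4D series) in the
header; motion as 6-column text (mm, mm, mm, rad, rad, rad); tables as TSV;
configuration and provenance as JSON/YAML. ``run_pipeline`` binds the whole
analysis — simulate, preprocess, FC, group inference, window-length
validation, demographics table — into one reproducible run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from . import fc as fc_mod
from . import inference, preprocess, summary_stats, synthdata

__all__ = [
    "ConfigError",
    "DataError",
    "read_volume",
    "write_volume",
    "read_motion",
    "write_motion",
    "ProvenanceLog",
    "RunConfig",
    "load_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or missing data (CLI exit code 3)."""


# ---------------------------------------------------------------- volumes

def write_volume(data: np.ndarray, path, voxel_size_mm: float = 3.0,
                 tr: float | None = None) -> Path:
    """Write a 3D/4D grid as NIfTI-1; TR goes into the 4th pixdim."""
    path = Path(path)
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    zooms = (voxel_size_mm,) * 3
    if data.ndim == 4:
        zooms += (tr if tr is not None else 1.0,)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def read_volume(path):
    """Read a NIfTI volume; returns ``(data, voxel_size_mm, tr_or_None)``."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()
    except Exception as exc:  # malformed file
        raise DataError(f"cannot read NIfTI {path}: {exc}") from exc
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, float(zooms[0]), tr


def write_motion(motion: np.ndarray, path) -> Path:
    """6-column motion trace, realignment-parameter text convention."""
    path = Path(path)
    np.savetxt(path, np.asarray(motion), fmt="%.10e")
    return path


def read_motion(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise DataError(f"motion file not found: {path}")
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[1] != 6:
        raise DataError(f"motion file {path} must have 6 columns")
    return m


# ------------------------------------------------------------- provenance

class ProvenanceLog:
    """Append-only record of pipeline stages, parameters and output files."""

    def __init__(self):
        self.records = []

    def add(self, stage: str, params=None, outputs=None):
        self.records.append({
            "stage": stage,
            "params": params or {},
            "outputs": [str(o) for o in (outputs or [])],
            "time": time.strftime("%Y-%m-%dT%H:%M:%S"),
        })

    def write(self, path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1)
        return path


def _file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ------------------------------------------------------------ run config

@dataclass(frozen=True)
class RunConfig:
    """Declarative configuration of one end-to-end analysis run."""

    cohort: synthdata.CohortSpec = field(default_factory=synthdata.CohortSpec)
    preproc: preprocess.PreprocConfig = field(default_factory=preprocess.PreprocConfig)
    window: fc_mod.WindowSpec = field(default_factory=fc_mod.WindowSpec)
    validation_window: fc_mod.WindowSpec = field(
        default_factory=lambda: fc_mod.WindowSpec(length_tr=50))
    seeds: tuple = ()                 # empty = every seed carrying an effect
    cdt_p: float = 0.001
    fwe_p: float = 0.05
    n_perm: int = 1000
    connectivity: int = 26
    posthoc_alpha: float = 0.001
    correlate_mode: str = "fog_nfog_diff"   # or "all_significant"
    inference_seed: int = 12345
    out_dir: str = "dynfc_run"

    def validate(self) -> None:
        t_after = self.cohort.n_volumes - self.preproc.n_discard
        for w in (self.window, self.validation_window):
            if w.length_tr > t_after:
                raise ConfigError(
                    f"window of {w.length_tr} TR exceeds the {t_after} volumes "
                    "remaining after discard")
        if self.correlate_mode not in ("fog_nfog_diff", "all_significant"):
            raise ConfigError(f"unknown correlate_mode {self.correlate_mode!r}")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")
        self.preproc.validate(self.cohort.n_volumes, self.cohort.tr)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d


def load_config(path) -> RunConfig:
    """Build a RunConfig from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    try:
        cohort_raw = dict(raw.pop("cohort", {}))
        effects = [synthdata.PlantedEffect(**e)
                   for e in cohort_raw.pop("effects", [])]
        for key in ("grid_shape", "groups", "band"):
            if key in cohort_raw:
                cohort_raw[key] = tuple(cohort_raw[key])
        cohort = synthdata.CohortSpec(effects=tuple(effects), **cohort_raw)
        pre_raw = dict(raw.pop("preproc", {}))
        if "band" in pre_raw:
            pre_raw["band"] = tuple(pre_raw["band"])
        pre = preprocess.PreprocConfig(**pre_raw)
        win = fc_mod.WindowSpec(**raw.pop("window", {}))
        vwin_raw = raw.pop("validation_window", {"length_tr": 50})
        vwin = fc_mod.WindowSpec(**vwin_raw)
        if "seeds" in raw:
            raw["seeds"] = tuple(raw["seeds"])
        cfg = RunConfig(cohort=cohort, preproc=pre, window=win,
                        validation_window=vwin, **raw)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
    cfg.validate()
    return cfg


# --------------------------------------------------------------- pipeline

def run_pipeline(config: RunConfig, write_outputs: bool = True) -> dict:
    """Execute simulate → preprocess → FC → inference → validation → report.

    Returns a result bundle with the per-seed cluster tables, post-hoc and
    correlation results, the validation table, the demographics table and
    the provenance log. With ``write_outputs`` the TSV reports, provenance
    and report hashes are written under ``config.out_dir``.
    """
    config.validate()
    prov = ProvenanceLog()
    out = Path(config.out_dir)
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)

    subjects, atlas, clinical = synthdata.generate_cohort(config.cohort)
    prov.add("simulate", {"rng_seed": config.cohort.rng_seed,
                          "n_subjects": len(subjects)})

    pre_subjects, fd_means = [], {}
    for s in subjects:
        ps, stages = preprocess.preprocess_subject(s, config.preproc)
        fd_means[s.subject_id] = preprocess.compute_fd(
            s.motion, config.preproc.fd_radius_mm).mean_fd
        pre_subjects.append(ps)
    prov.add("preprocess", {"stages": stages, "n_subjects": len(pre_subjects)})

    design = inference.GroupDesign(tuple(s.group for s in pre_subjects))
    seeds = tuple(config.seeds) or tuple(sorted(
        {e.seed_roi for e in config.cohort.effects})) or tuple(atlas.seed_labels)

    rng = np.random.default_rng(config.inference_seed)
    cluster_rows, posthoc_rows, corr_rows = [], [], []
    dyn_sig_clusters = []
    for seed in seeds:
        static_maps, dyn_maps = [], []
        for ds in pre_subjects:
            battery = fc_mod.subject_fc_battery(ds, atlas, config.window,
                                                seeds=[seed])
            fcm, dyn = battery[seed]
            static_maps.append(fcm.values)
            dyn_maps.append(dyn.sd)
        for measure, maps in (("static", np.asarray(static_maps)),
                              ("dynamic", np.asarray(dyn_maps))):
            clusters, posthoc = inference.seed_group_analysis(
                maps, design, cdt_p=config.cdt_p, fwe_p=config.fwe_p,
                n_perm=config.n_perm, connectivity=config.connectivity,
                posthoc_alpha=config.posthoc_alpha, rng=rng)
            for ci, c in enumerate(clusters):
                cluster_rows.append({
                    "seed": seed, "measure": measure, "cluster": ci,
                    "size": c.size, "peak_x": c.peak_coord[0],
                    "peak_y": c.peak_coord[1], "peak_z": c.peak_coord[2],
                    "peak_f": c.peak_f, "p_fwe": c.p_fwe,
                    "significant": c.significant})
            for ci, tests in posthoc.items():
                for t in tests:
                    posthoc_rows.append({
                        "seed": seed, "measure": measure, "cluster": ci,
                        "pair": f"{t.pair[0]}-{t.pair[1]}", "t": t.t,
                        "df": t.df, "p": t.p, "significant": t.significant})
            if measure == "dynamic":
                for ci, c in enumerate(clusters):
                    if not c.significant:
                        continue
                    if config.correlate_mode == "fog_nfog_diff":
                        tests = posthoc.get(ci, [])
                        fog_nfog = [t for t in tests
                                    if set(t.pair) == {"FOG", "NFOG"}]
                        if not (fog_nfog and fog_nfog[0].significant):
                            continue
                    dyn_sig_clusters.append((seed, c))
                    means = inference.extract_cluster_means(maps, c)
                    fog_idx = design.indices("FOG")
                    scores = clinical.set_index("subject_id").loc[
                        [pre_subjects[i].subject_id for i in fog_idx], "nfogq"
                    ].to_numpy()
                    r, p = inference.correlate_clinical(means[fog_idx], scores)
                    corr_rows.append({"seed": seed, "cluster": ci,
                                      "r": r, "p": p, "n": len(scores)})
    prov.add("group_inference", {"seeds": list(seeds), "n_perm": config.n_perm,
                                 "cdt_p": config.cdt_p, "fwe_p": config.fwe_p})

    validation = inference.validate_window_length(
        pre_subjects, atlas, dyn_sig_clusters, design,
        spec_50tr=config.validation_window)
    prov.add("validation", {"window_length_tr": config.validation_window.length_tr,
                            "n_clusters": len(dyn_sig_clusters)})

    fd_series = pd.Series(fd_means)
    table1 = summary_stats.table1_report(clinical, groups=design.group_names,
                                         fd_by_subject=fd_series)
    prov.add("table1", {"n_rows": len(table1)})

    bundle = {
        "clusters": pd.DataFrame(
            cluster_rows, columns=["seed", "measure", "cluster", "size",
                                   "peak_x", "peak_y", "peak_z", "peak_f",
                                   "p_fwe", "significant"]),
        "posthoc": pd.DataFrame(
            posthoc_rows, columns=["seed", "measure", "cluster", "pair", "t",
                                   "df", "p", "significant"]),
        "correlations": pd.DataFrame(
            corr_rows, columns=["seed", "cluster", "r", "p", "n"]),
        "validation": validation,
        "table1": table1,
        "clinical": clinical,
        "design": design,
        "provenance": prov,
    }
    if write_outputs:
        manifest = {}
        for name in ("clusters", "posthoc", "correlations", "validation",
                     "table1", "clinical"):
            p = out / f"{name}.tsv"
            bundle[name].to_csv(p, sep="\t", index=False)
            manifest[name] = _file_hash(p)
        with open(out / "config.json", "w") as fh:
            json.dump(config.to_dict(), fh, indent=1)
        with open(out / "report_hashes.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
        prov.add("report", outputs=sorted(manifest))
        prov.write(out / "provenance.json")
        bundle["report_hashes"] = manifest
    return bundle
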