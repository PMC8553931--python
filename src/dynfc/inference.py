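"""Three-group voxel-wise inference with cluster-level permutation FWE.

Maps are compared with a one-way fixed-effects ANOVA per voxel; a
cluster-defining threshold (voxel p < 0.001 on the F scale) selects
supra-threshold connected components, whose family-wise error is controlled
by the max-cluster-size permutation distribution under group-label
relabeling. Significant clusters feed post-hoc pooled-variance pairwise
t-tests, a clinical correlation stage, and a window-length robustness check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fc import WindowSpec, dynamic_fc_map, roi_mean_timeseries, windowed_fc

__all__ = [
    "GroupDesign",
    "ClusterResult",
    "PosthocResult",
    "voxelwise_oneway_anova",
    "f_threshold_from_p",
    "cluster_label",
    "permutation_cluster_fwe",
    "extract_cluster_means",
    "posthoc_pairwise",
    "correlate_clinical",
    "seed_group_analysis",
    "validate_window_length",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class GroupDesign:
    """Subject → group assignment over exactly three groups."""

    labels: tuple                     # one group label per subject, in map order

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        groups = self.group_names
        if len(groups) != 3:
            raise ValueError(f"need exactly 3 groups, got {groups}")
        for g in groups:
            if self.labels.count(g) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")

    @property
    def group_names(self) -> tuple:
        seen = []
        for g in self.labels:
            if g not in seen:
                seen.append(g)
        return tuple(seen)

    def indices(self, group) -> np.ndarray:
        return np.array([i for i, g in enumerate(self.labels) if g == group])

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class ClusterResult:
    """A supra-threshold cluster with its permutation-corrected p-value."""

    size: int
    peak_coord: tuple
    peak_f: float
    p_fwe: float = np.nan
    member_voxels: np.ndarray = field(default=None, repr=False)
    significant: bool = False


@dataclass(frozen=True)
class PosthocResult:
    pair: tuple
    t: float
    df: int
    p: float
    direction: int                    # sign of mean(pair[0]) - mean(pair[1])
    significant: bool


def _group_index_matrix(design: GroupDesign):
    groups = design.group_names
    idx = [design.indices(g) for g in groups]
    ns = np.array([len(i) for i in idx])
    return idx, ns


def voxelwise_oneway_anova(maps: np.ndarray, design: GroupDesign):
    """Per-voxel one-way fixed-effects F over three groups.

    ``maps`` is (n_subjects, ...voxels...). Returns ``(F, (df1, df2))`` with
    df = (k-1, N-k). Voxels with zero between- and within-group variance get
    F = 0; zero within-variance with non-zero between gives F = inf.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] != design.n:
        raise ValueError("number of maps does not match the design")
    idx, ns = _group_index_matrix(design)
    k, N = len(idx), design.n
    grand = maps.mean(axis=0)
    ssb = np.zeros(maps.shape[1:])
    ssw = np.zeros(maps.shape[1:])
    for ii, n_i in zip(idx, ns):
        gm = maps[ii].mean(axis=0)
        ssb += n_i * (gm - grand) ** 2
        ssw += ((maps[ii] - gm) ** 2).sum(axis=0)
    df1, df2 = k - 1, N - k
    msb, msw = ssb / df1, ssw / df2
    # voxels that are constant across all subjects leave only rounding
    # residue in both sums of squares: define F = 0 there, not 0/0
    scale = np.maximum((maps * maps).mean(axis=0), np.finfo(float).tiny)
    tiny_b, tiny_w = ssb <= 1e-12 * N * scale, ssw <= 1e-12 * N * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    F = np.where(tiny_w, np.where(tiny_b, 0.0, np.inf), F)
    return F, (df1, df2)


def f_threshold_from_p(p: float, df1: int, df2: int) -> float:
    """F-scale cluster-defining threshold from a voxel-level p cutoff."""
    return float(stats.f.isf(p, df1, df2))


def cluster_label(stat_map: np.ndarray, threshold: float,
                  connectivity: int = 26):
    """Connected components of supra-threshold voxels.

    ``connectivity`` is 6, 18 or 26 (faces / +edges / +corners). Returns a
    list of ClusterResult (without corrected p), largest first.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 6, 18 or 26")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    supra = stat_map > threshold
    labeled, n = ndimage.label(supra, structure=structure)
    clusters = []
    for lab in range(1, n + 1):
        mask = labeled == lab
        vals = np.where(mask, stat_map, -np.inf)
        peak = np.unravel_index(np.argmax(vals), stat_map.shape)
        clusters.append(ClusterResult(
            size=int(mask.sum()), peak_coord=tuple(int(c) for c in peak),
            peak_f=float(stat_map[peak]), member_voxels=mask))
    clusters.sort(key=lambda c: c.size, reverse=True)
    return clusters


def _max_cluster_size(stat_map, threshold, structure) -> int:
    labeled, n = ndimage.label(stat_map > threshold, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labeled.ravel())[1:].max())


def permutation_cluster_fwe(maps: np.ndarray, design: GroupDesign,
                            cdt_p: float = 0.001, fwe_p: float = 0.05,
                            n_perm: int = 1000, connectivity: int = 26,
                            rng=None):
    """Cluster-level FWE by the max-cluster-size permutation distribution.

    Group labels are permuted across subjects (valid for a one-way design);
    each cluster's corrected p is ``(1 + #{perm max size >= observed size})
    / (n_perm + 1)``; clusters with ``p_fwe < fwe_p`` are flagged.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng)
    maps = np.asarray(maps, dtype=float)
    F, (df1, df2) = voxelwise_oneway_anova(maps, design)
    thr = f_threshold_from_p(cdt_p, df1, df2)
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    clusters = cluster_label(F, thr, connectivity)

    labels = np.asarray(design.labels, dtype=object)
    null_max = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        perm = rng.permutation(design.n)
        d = GroupDesign(tuple(labels[perm]))
        Fp, _ = voxelwise_oneway_anova(maps, d)
        null_max[b] = _max_cluster_size(Fp, thr, structure)
    for c in clusters:
        exceed = int((null_max >= c.size).sum())
        c.p_fwe = (exceed + 1) / (n_perm + 1)
        c.significant = c.p_fwe < fwe_p
    return clusters


def extract_cluster_means(maps: np.ndarray, cluster: ClusterResult) -> np.ndarray:
    """Per-subject unweighted mean of map values over the cluster's voxels."""
    maps = np.asarray(maps, dtype=float)
    mask = cluster.member_voxels
    if mask.shape != maps.shape[1:]:
        raise ValueError("cluster mask does not match map grid")
    return maps[:, mask].mean(axis=1)


def posthoc_pairwise(values: np.ndarray, design: GroupDesign,
                     alpha: float = 0.001):
    """Pooled-variance two-sample t-test for every group pair."""
    values = np.asarray(values, dtype=float)
    groups = design.group_names
    out = []
    for i in range(3):
        for j in range(i + 1, 3):
            a = values[design.indices(groups[i])]
            b = values[design.indices(groups[j])]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            out.append(PosthocResult(
                pair=(groups[i], groups[j]), t=float(t),
                df=len(a) + len(b) - 2, p=float(p),
                direction=int(np.sign(a.mean() - b.mean())),
                significant=bool(p < alpha)))
    return out


def correlate_clinical(cluster_means: np.ndarray, scores: np.ndarray):
    """Pearson r and two-tailed p between cluster means and clinical scores."""
    x = np.asarray(cluster_means, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)):
        raise ValueError("missing values in correlation input")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input to correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def seed_group_analysis(maps_by_subject: np.ndarray, design: GroupDesign,
                        cdt_p: float = 0.001, fwe_p: float = 0.05,
                        n_perm: int = 1000, connectivity: int = 26,
                        posthoc_alpha: float = 0.001, rng=None):
    """Cluster inference + post-hoc tests for one seed's stacked maps.

    Returns ``(clusters, posthoc)`` where ``posthoc`` maps each significant
    cluster index to its three pairwise test results.
    """
    clusters = permutation_cluster_fwe(
        maps_by_subject, design, cdt_p=cdt_p, fwe_p=fwe_p,
        n_perm=n_perm, connectivity=connectivity, rng=rng)
    posthoc = {}
    for i, c in enumerate(clusters):
        if c.significant:
            means = extract_cluster_means(maps_by_subject, c)
            posthoc[i] = posthoc_pairwise(means, design, alpha=posthoc_alpha)
    return clusters, posthoc


def validate_window_length(datasets, atlas, significant_clusters,
                           design: GroupDesign,
                           spec_50tr: WindowSpec = WindowSpec(length_tr=50),
                           z_domain_sd: bool = False) -> pd.DataFrame:
    """ROI-wise robustness check of dynamic-FC effects at a longer window.

    For every ``(seed_label, cluster)`` found significant in the main
    (30 TR) analysis, dynamic FC is recomputed on the same preprocessed
    datasets at the longer window, cluster-mean values are compared across
    groups by one-way ANOVA plus pairwise t-tests, and the direction of the
    group ordering is reported so concordance with the main analysis can be
    assessed.
    """
    rows = []
    groups = design.group_names
    for seed_label, cluster in significant_clusters:
        sd_maps = []
        for ds in datasets:
            ts = roi_mean_timeseries(ds.bold, atlas, seed_label, ds.brain_mask)
            stack = windowed_fc(np.asarray(ds.bold, dtype=float), ts, spec_50tr)
            dyn = dynamic_fc_map(stack, seed=seed_label,
                                 subject_id=ds.subject_id, z_domain=z_domain_sd)
            sd_maps.append(dyn.sd)
        sd_maps = np.asarray(sd_maps)
        means = extract_cluster_means(sd_maps, cluster)
        F, (df1, df2) = voxelwise_oneway_anova(means[:, None], design)
        p = float(stats.f.sf(F[0], df1, df2))
        group_means = {g: float(means[design.indices(g)].mean()) for g in groups}
        top = max(group_means, key=group_means.get)
        rows.append({
            "seed": seed_label, "cluster_size": cluster.size,
            "window_length_tr": spec_50tr.length_tr,
            "F": float(F[0]), "df1": df1, "df2": df2, "p": p,
            **{f"mean_{g}": group_means[g] for g in groups},
            "highest_group": top,
        })
    return pd.DataFrame(rows)
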