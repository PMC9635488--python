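"""Voxelwise searchlight representational similarity mapping.

Each in-mask voxel serves once as the center of a sphere of fixed radius (in
voxels); the correlation-distance RDM of the beta patterns inside the sphere
is compared to a model RDM by Spearman (optionally partial Spearman)
correlation and the coefficient is written to the center voxel.  Subject
maps are Gaussian-smoothed, Fisher transformed and entered into a one-sample
t test; supra-threshold voxels are reduced to clusters that survive a
volume-extent criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata, t as t_dist

from .errors import DegenerateDataError
from .rdm import RDM, compute_rdm, rdm_partial_spearman, rdm_spearman

log = logging.getLogger(__name__)

_RHO_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic-by-default voxel grid geometry."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.shape) or any(v <= 0 for v in self.voxel_size):
            raise ValueError("dimensions and voxel sizes must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_mm(self, ijk: np.ndarray) -> np.ndarray:
        return np.asarray(ijk) * np.asarray(self.voxel_size) + np.asarray(self.origin)


def check_mask(mask: np.ndarray, grid: VolumeGrid) -> np.ndarray:
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid.shape:
        raise ValueError(f"mask shape {mask.shape} != grid {grid.shape}")
    if not mask.any():
        raise ValueError("mask must contain at least one voxel")
    return mask


@dataclass
class BetaSeries:
    """Per-subject beta coefficients: one value per (stimulus, in-mask voxel).

    ``data`` has shape (n_stimuli, n_in_mask_voxels) with columns ordered by
    ``np.flatnonzero(mask)`` (C order).
    """

    subject_id: str
    grid: VolumeGrid
    labels: tuple[str, ...]
    mask: np.ndarray
    data: np.ndarray

    def __post_init__(self):
        self.mask = check_mask(self.mask, self.grid)
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=float)
        n_vox = int(self.mask.sum())
        if self.data.shape != (len(self.labels), n_vox):
            raise ValueError(
                f"data shape {self.data.shape} != "
                f"({len(self.labels)}, {n_vox})"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("beta values must be finite")

    @property
    def n_stimuli(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class SearchlightConfig:
    radius: int = 3
    min_occupancy: float = 0.5  # fraction of the full sphere required
    method: str = "spearman"    # or "partial_spearman"

    def __post_init__(self):
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if not 0.0 <= self.min_occupancy <= 1.0:
            raise ValueError("min_occupancy must be in [0, 1]")
        if self.method not in ("spearman", "partial_spearman"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class GroupInferenceConfig:
    fwhm_mm: float = 6.0
    voxel_p: float = 0.001
    cluster_extent_mm3: float = 234.9
    connectivity: int = 2           # ndimage structure rank: 1=faces, 2=+edges, 3=+corners
    two_sided: bool = True
    fisher_after_smoothing: bool = True
    report_sign: str = "positive"   # cluster table reports this sign

    def __post_init__(self):
        if self.fwhm_mm < 0 or self.cluster_extent_mm3 < 0:
            raise ValueError("fwhm and extent must be >= 0")
        if not 0.0 < self.voxel_p < 1.0:
            raise ValueError("voxel_p must be in (0, 1)")
        if self.connectivity not in (1, 2, 3):
            raise ValueError("connectivity must be 1, 2 or 3")


@dataclass
class SearchlightMap:
    """Per-voxel model-brain correlation; NaN outside mask or at skipped centers."""

    subject_id: str
    grid: VolumeGrid
    values: np.ndarray
    method: str
    n_skipped: int = 0


@dataclass
class GroupMap:
    grid: VolumeGrid
    t: np.ndarray
    df: int
    mean_z: np.ndarray


@dataclass
class ClusterTable:
    clusters: pd.DataFrame = field(default_factory=pd.DataFrame)

    @staticmethod
    def columns() -> list[str]:
        return ["cluster_id", "n_voxels", "volume_mm3",
                "peak_t", "peak_x_mm", "peak_y_mm", "peak_z_mm"]


def sphere_offsets(radius: int) -> np.ndarray:
    """All integer offsets (i, j, k) with i^2+j^2+k^2 <= radius^2.

    Includes (0, 0, 0); at radius 3 this is 123 offsets.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    grid = np.mgrid[-r:r + 1, -r:r + 1, -r:r + 1].reshape(3, -1).T
    keep = (grid ** 2).sum(axis=1) <= radius ** 2
    return grid[keep]


def _column_map(mask: np.ndarray) -> np.ndarray:
    """Full-grid flat index -> beta column (or -1 outside the mask)."""
    colmap = np.full(mask.size, -1, dtype=np.int64)
    colmap[np.flatnonzero(mask.ravel())] = np.arange(int(mask.sum()))
    return colmap


def _sphere_columns(center: np.ndarray, offsets: np.ndarray,
                    mask: np.ndarray, colmap: np.ndarray) -> np.ndarray:
    coords = center + offsets
    inside = ((coords >= 0) & (coords < np.asarray(mask.shape))).all(axis=1)
    coords = coords[inside]
    flat = np.ravel_multi_index(tuple(coords.T), mask.shape)
    cols = colmap[flat]
    return cols[cols >= 0]


def neural_rdm(betas: BetaSeries, center: Sequence[int],
               offsets: np.ndarray,
               min_occupancy: float = 0.5) -> RDM:
    """Correlation-distance RDM of the beta patterns in one sphere.

    Spheres truncated by the mask or the volume edge are accepted while
    occupancy stays at or above ``min_occupancy`` of the full sphere.
    """
    colmap = _column_map(betas.mask)
    cols = _sphere_columns(np.asarray(center, int), offsets, betas.mask, colmap)
    if len(cols) < max(2, int(np.ceil(min_occupancy * len(offsets)))):
        raise DegenerateDataError(
            f"sphere at {tuple(center)} has occupancy {len(cols)}/{len(offsets)}"
        )
    return compute_rdm(betas.data[:, cols], betas.labels)


@dataclass(frozen=True)
class _Comparison:
    """Preprocessed model (and optional control) RDM for fast per-center use."""

    name: str
    model_ranks: np.ndarray
    control_ranks: np.ndarray | None = None
    r_mc: float = 0.0


def _center_ranks(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    return r - r.mean()


def _prepare_comparisons(model_rdms: Sequence[tuple[str, RDM, RDM | None]],
                         labels: tuple[str, ...]) -> list[_Comparison]:
    comps = []
    for name, model, control in model_rdms:
        if model.labels != labels:
            raise ValueError(f"model RDM {name!r} labels do not match betas")
        mr = _center_ranks(model.upper())
        mr /= np.linalg.norm(mr)
        if control is None:
            comps.append(_Comparison(name, mr))
        else:
            if control.labels != labels:
                raise ValueError(f"control RDM for {name!r} labels mismatch")
            cr = _center_ranks(control.upper())
            cr /= np.linalg.norm(cr)
            r_mc = float(np.dot(mr, cr))
            if abs(r_mc) >= 1.0 - 1e-12:
                raise DegenerateDataError(
                    "model and control RDMs rank-identical"
                )
            comps.append(_Comparison(name, mr, cr, r_mc))
    return comps


def _batch_ranks(D: np.ndarray) -> np.ndarray:
    """Row-wise ranks via argsort; rows with ties fall back to average ranks.

    Ordinal ranks equal average ranks whenever a row has no duplicate
    values, which is the generic case for correlation distances of noisy
    patterns; rows containing exact ties are re-ranked with
    :func:`scipy.stats.rankdata` so the result always uses average ranks.
    """
    k, p = D.shape
    order = np.argsort(D, axis=1)
    R = np.empty_like(D)
    np.put_along_axis(R, order,
                      np.broadcast_to(np.arange(1, p + 1, dtype=D.dtype), (k, p)),
                      axis=1)
    sorted_vals = np.take_along_axis(D, order, axis=1)
    tied = (np.diff(sorted_vals, axis=1) == 0).any(axis=1)
    for i in np.flatnonzero(tied):
        R[i] = rankdata(D[i])
    return R


def searchlight_maps(betas: BetaSeries,
                     comparisons: Sequence[tuple[str, RDM, RDM | None]],
                     config: SearchlightConfig = SearchlightConfig(),
                     batch_size: int = 64,
                     ) -> dict[str, SearchlightMap]:
    """Searchlight maps for several model RDMs in a single pass.

    The neural RDM of each sphere is computed and rank-transformed once,
    then correlated with every requested (model, optional control) pair;
    sharing the pass keeps multi-analysis runs close to single-analysis
    cost.  Centers are processed in batches so the rank transform and the
    correlations run vectorized.
    """
    mask = betas.mask
    offsets = sphere_offsets(config.radius)
    full = len(offsets)
    min_vox = max(2, int(np.ceil(config.min_occupancy * full)))
    colmap = _column_map(mask)
    comps = _prepare_comparisons(comparisons, betas.labels)
    maps = {c.name: np.full(betas.grid.shape, np.nan) for c in comps}
    n = betas.n_stimuli
    iu = np.triu_indices(n, k=1)
    n_pairs = len(iu[0])
    centers = np.argwhere(mask)
    n_skipped = 0
    X = betas.data

    buf = np.empty((batch_size, n_pairs))
    buf_centers: list[tuple[int, int, int]] = []

    def flush() -> None:
        nonlocal n_skipped
        k = len(buf_centers)
        if k == 0:
            return
        R = _batch_ranks(buf[:k])
        R -= R.mean(axis=1, keepdims=True)
        nrm = np.linalg.norm(R, axis=1)
        ok = nrm > 0
        n_skipped += int((~ok).sum())
        R[ok] /= nrm[ok, None]
        idx = tuple(np.asarray(buf_centers).T)
        for comp in comps:
            r_tm = R @ comp.model_ranks
            if comp.control_ranks is None:
                vals = r_tm
            else:
                r_tc = R @ comp.control_ranks
                with np.errstate(invalid="ignore", divide="ignore"):
                    denom = np.sqrt((1 - r_tc ** 2) * (1 - comp.r_mc ** 2))
                    vals = (r_tm - r_tc * comp.r_mc) / denom
            vals = np.where(ok, vals, np.nan)
            maps[comp.name][idx] = vals
        buf_centers.clear()

    for center in centers:
        cols = _sphere_columns(center, offsets, mask, colmap)
        if len(cols) < min_vox:
            n_skipped += 1
            continue
        A = X[:, cols]
        A = A - A.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(A, axis=1)
        if (norms == 0).any():
            n_skipped += 1
            continue
        G = (A @ A.T) / np.outer(norms, norms)
        buf[len(buf_centers)] = -G[iu]  # 1 - r shifted; ranks are shift-invariant
        buf_centers.append(tuple(center))
        if len(buf_centers) == batch_size:
            flush()
    flush()
    if n_skipped:
        log.info("searchlight: skipped %d low-occupancy/degenerate centers",
                 n_skipped)
    out = {}
    for comp in comps:
        method = "spearman" if comp.control_ranks is None else "partial_spearman"
        out[comp.name] = SearchlightMap(betas.subject_id, betas.grid,
                                        maps[comp.name], method, n_skipped)
    return out


def searchlight_map(betas: BetaSeries, model_rdm: RDM,
                    config: SearchlightConfig = SearchlightConfig(),
                    control_rdm: RDM | None = None) -> SearchlightMap:
    """Single-model searchlight map (see :func:`searchlight_maps`)."""
    if config.method == "partial_spearman" and control_rdm is None:
        raise ValueError("partial_spearman requires a control RDM")
    control = control_rdm if config.method == "partial_spearman" else None
    return searchlight_maps(betas, [("map", model_rdm, control)], config)["map"]


def searchlight_map_slow(betas: BetaSeries, model_rdm: RDM,
                         config: SearchlightConfig = SearchlightConfig(),
                         control_rdm: RDM | None = None) -> SearchlightMap:
    """Reference implementation: explicit per-voxel loop through the public
    RDM API.  Slow; used for verification."""
    offsets = sphere_offsets(config.radius)
    values = np.full(betas.grid.shape, np.nan)
    n_skipped = 0
    for center in np.argwhere(betas.mask):
        try:
            nrdm = neural_rdm(betas, center, offsets, config.min_occupancy)
        except DegenerateDataError:
            n_skipped += 1
            continue
        if config.method == "partial_spearman":
            cmp_ = rdm_partial_spearman(nrdm, model_rdm, control_rdm)
        else:
            cmp_ = rdm_spearman(nrdm, model_rdm)
        values[tuple(center)] = cmp_.rho
    return SearchlightMap(betas.subject_id, betas.grid, values,
                          config.method, n_skipped)


def smooth_map(values: np.ndarray, fwhm_mm: float, grid: VolumeGrid,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Gaussian smoothing with mask-aware renormalization.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, converted to voxel units.
    Values outside the valid region contribute nothing; the kernel is
    renormalized by the smoothed validity indicator so constant maps stay
    constant up to the mask edge.
    """
    values = np.asarray(values, dtype=float)
    if fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    valid = np.isfinite(values)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    if fwhm_mm == 0:
        out = np.where(valid, values, np.nan)
        return out
    sigma_vox = [fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / v
                 for v in grid.voxel_size]
    filled = np.where(valid, values, 0.0)
    num = ndimage.gaussian_filter(filled, sigma_vox)
    den = ndimage.gaussian_filter(valid.astype(float), sigma_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~valid] = np.nan
    return out


def fisher_z(rho: np.ndarray) -> np.ndarray:
    """atanh with |rho| clipped just below 1 to keep z finite."""
    return np.arctanh(np.clip(rho, -_RHO_CLIP, _RHO_CLIP))


def group_inference(maps: Sequence[SearchlightMap],
                    mask: np.ndarray,
                    config: GroupInferenceConfig = GroupInferenceConfig(),
                    ) -> tuple[GroupMap, ClusterTable]:
    """Smooth, Fisher-transform, one-sample t test, cluster-extent threshold.

    By default each subject map is smoothed first and Fisher z is applied to
    the smoothed correlations (set ``fisher_after_smoothing=False`` to z
    first).  Voxels where any subject is missing, or with zero
    between-subject variance, are excluded from inference.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 subjects")
    grid = maps[0].grid
    mask = check_mask(mask, grid)
    stack = []
    for m in maps:
        if m.grid != grid:
            raise ValueError("subject maps must share a grid")
        vals = m.values
        finite = vals[np.isfinite(vals)]
        if finite.size and np.abs(finite).max() >= 1.0:
            log.warning("subject %s: |rho| >= 1 clipped before Fisher z",
                        m.subject_id)
        if config.fisher_after_smoothing:
            vals = fisher_z(smooth_map(vals, config.fwhm_mm, grid, mask))
        else:
            vals = smooth_map(fisher_z(vals), config.fwhm_mm, grid, mask)
        stack.append(vals)
    Z = np.stack(stack)  # (n_subjects, *shape)
    n = Z.shape[0]
    df = n - 1
    valid = np.isfinite(Z).all(axis=0) & mask
    mean = np.full(grid.shape, np.nan)
    mean[valid] = Z[:, valid].mean(axis=0)
    sd = np.full(grid.shape, np.nan)
    sd[valid] = Z[:, valid].std(axis=0, ddof=1)
    degenerate = valid & (sd == 0)
    if degenerate.any():
        log.warning("%d voxel(s) with zero between-subject variance excluded",
                    int(degenerate.sum()))
        valid &= ~degenerate
    t = np.full(grid.shape, np.nan)
    t[valid] = mean[valid] / (sd[valid] / np.sqrt(n))
    group = GroupMap(grid=grid, t=t, df=df, mean_z=mean)
    table = cluster_table(group, config)
    return group, table


def _threshold_t(config: GroupInferenceConfig, df: int) -> float:
    if config.two_sided:
        return float(t_dist.ppf(1.0 - config.voxel_p / 2.0, df))
    return float(t_dist.ppf(1.0 - config.voxel_p, df))


def label_clusters(binary: np.ndarray, connectivity: int = 2
                   ) -> tuple[np.ndarray, int]:
    """Connected components of a binary volume (1=faces, 2=+edges, 3=+corners)."""
    structure = ndimage.generate_binary_structure(3, connectivity)
    return ndimage.label(binary, structure=structure)


def cluster_table(group: GroupMap,
                  config: GroupInferenceConfig = GroupInferenceConfig(),
                  ) -> ClusterTable:
    """Supra-threshold clusters surviving the volume-extent criterion."""
    t_crit = _threshold_t(config, group.df)
    t = group.t
    if config.report_sign == "negative":
        supra = t < -t_crit
    else:
        supra = t > t_crit
    labels, n_comp = label_clusters(np.nan_to_num(supra, nan=0).astype(bool),
                                    config.connectivity)
    vol = group.grid.voxel_volume
    rows = []
    for comp in range(1, n_comp + 1):
        idx = np.argwhere(labels == comp)
        n_vox = len(idx)
        if n_vox * vol < config.cluster_extent_mm3:
            continue
        tvals = t[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(tvals))]
        peak_mm = group.grid.to_mm(peak)
        rows.append({
            "cluster_id": len(rows) + 1,
            "n_voxels": n_vox,
            "volume_mm3": n_vox * vol,
            "peak_t": float(t[tuple(peak)]),
            "peak_x_mm": peak_mm[0], "peak_y_mm": peak_mm[1],
            "peak_z_mm": peak_mm[2],
        })
    frame = pd.DataFrame(rows, columns=ClusterTable.columns())
    return ClusterTable(frame)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def write_beta_series(betas: BetaSeries, nii_path, labels_path) -> None:
    """4-D NIfTI (stimulus along the 4th axis) plus a stimulus-label sidecar TSV."""
    vol = np.zeros(betas.grid.shape + (betas.n_stimuli,), dtype=np.float32)
    vol[betas.mask, :] = betas.data.T
    nib.save(nib.Nifti1Image(vol, betas.grid.affine), str(nii_path))
    pd.DataFrame({"stimulus": list(betas.labels)}).to_csv(
        labels_path, sep="\t", index=False)


def read_beta_series(nii_path, labels_path, mask: np.ndarray,
                     subject_id: str = "sub") -> BetaSeries:
    img = nib.load(str(nii_path))
    vol = np.asarray(img.dataobj, dtype=float)
    grid = grid_from_affine(vol.shape[:3], img.affine)
    mask = check_mask(mask, grid)
    labels = pd.read_csv(labels_path, sep="\t")["stimulus"].astype(str).tolist()
    if vol.ndim != 4 or vol.shape[3] != len(labels):
        raise ValueError(
            f"{nii_path}: 4th axis ({vol.shape[3:]}) does not match "
            f"{len(labels)} sidecar labels"
        )
    return BetaSeries(subject_id, grid, labels, mask, vol[mask, :].T)


def write_volume(values: np.ndarray, grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32),
                             grid.affine), str(path))


def read_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    return data, grid_from_affine(data.shape[:3], img.affine)


def grid_from_affine(shape, affine: np.ndarray) -> VolumeGrid:
    voxel_size = tuple(float(v) for v in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VolumeGrid(tuple(shape), voxel_size, origin)
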