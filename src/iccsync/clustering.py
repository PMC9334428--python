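"""ROI time-course extraction and network identification.

Supra-threshold voxels (those surviving the surrogate-null + FDR step)
are averaged within each atlas ROI per subject; ROIs whose voxels carry
two distinct response shapes are split into two sub-ROIs; and the
group-level mean series are grouped into networks by multi-restart
K-means with the number of clusters chosen by the mean Silhouette width.

Series are z-scored before clustering so that Euclidean distance acts as
a correlation-like shape distance: the grouping is driven by the shape
of the transient response to the condition change, not its amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

__all__ = [
    "ROISeries",
    "ROISeriesSet",
    "NetworkPartition",
    "roi_mean_timecourses",
    "homogeneity_split",
    "network_partition",
]

logger = logging.getLogger(__name__)

#: Kaufman & Rousseeuw's "reasonable structure" band starts at 0.5; a
#: candidate 2-way split of an ROI is accepted only above it.
SPLIT_SILHOUETTE = 0.5


@dataclass
class ROISeries:
    """Mean time courses over one ROI's (or sub-ROI's) supra-threshold voxels."""

    roi_id: int
    roi_name: str
    hemisphere: str
    subject_tcs: np.ndarray  # (M, n)
    group_tc: np.ndarray  # (n,)
    n_supra_voxels: int
    supra_fraction: float
    sub_roi: int = 0
    voxel_indices: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ROISeriesSet:
    entries: list[ROISeries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def group_matrix(self) -> np.ndarray:
        """(n_entries, n) stack of group-level mean series."""
        return np.vstack([e.group_tc for e in self.entries])


@dataclass(frozen=True)
class NetworkPartition:
    K: int
    labels: np.ndarray
    silhouette_mean: float
    silhouette_per_K: dict[int, float]


def _zscore_rows(A: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    sd = A.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot z-score a constant series")
    return A / sd


def roi_mean_timecourses(
    subject_data: np.ndarray,
    suprathreshold_mask: np.ndarray,
    atlas: np.ndarray,
    labels: dict[int, tuple[str, str]] | None = None,
    min_voxels: int = 4,
) -> ROISeriesSet:
    """Per-ROI mean series over supra-threshold voxels, per subject.

    Parameters
    ----------
    subject_data : (M, x, y, z, n) ndarray
        Per-subject 4-D volumes stacked on the first axis.
    suprathreshold_mask : (x, y, z) boolean ndarray
        Voxels surviving the surrogate + FDR threshold.
    atlas : (x, y, z) integer ndarray
        ROI labels; 0 = background.
    labels : mapping label_id -> (roi_name, hemisphere), optional.
    min_voxels : int
        ROIs whose intersection with the mask holds fewer voxels than
        this are dropped (logged): a remnant of one or two voxels is
        more likely false-positive noise than a synchronized region,
        and is too small for the homogeneity split anyway.
    """
    subject_data = np.asarray(subject_data, dtype=float)
    atlas = np.asarray(atlas)
    mask = np.asarray(suprathreshold_mask, dtype=bool)
    if atlas.shape != mask.shape or subject_data.shape[1:4] != atlas.shape:
        raise ValueError(
            f"grid mismatch: data {subject_data.shape[1:4]}, atlas {atlas.shape}, "
            f"mask {mask.shape}"
        )
    entries: list[ROISeries] = []
    flat_idx = np.arange(atlas.size).reshape(atlas.shape)
    for roi_id in np.unique(atlas):
        if roi_id == 0:
            continue
        in_roi = atlas == roi_id
        sel = in_roi & mask
        n_supra = int(sel.sum())
        if n_supra < max(min_voxels, 1):
            logger.warning(
                "ROI %s: %d supra-threshold voxel(s) < %d; dropped",
                roi_id, n_supra, min_voxels,
            )
            continue
        name, hemi = (labels or {}).get(int(roi_id), (f"roi{int(roi_id)}", ""))
        subject_tcs = subject_data[:, sel, :].mean(axis=1)  # (M, n)
        entries.append(
            ROISeries(
                roi_id=int(roi_id),
                roi_name=name,
                hemisphere=hemi,
                subject_tcs=subject_tcs,
                group_tc=subject_tcs.mean(axis=0),
                n_supra_voxels=n_supra,
                supra_fraction=n_supra / int(in_roi.sum()),
                voxel_indices=flat_idx[sel],
            )
        )
    return ROISeriesSet(entries)


def homogeneity_split(
    entry: ROISeries,
    voxel_series: np.ndarray,
    subject_data: np.ndarray | None = None,
    random_state: int = 0,
) -> list[ROISeries]:
    """Split one ROI into two sub-ROIs if its voxels carry two shapes.

    ``voxel_series`` is (n_voxels, n): each supra-threshold voxel's
    mean-across-subjects series.  A K-means (K=2) split of the z-scored
    series is accepted only when the mean Silhouette width is at least
    0.5; otherwise the entry is returned unchanged.  ROIs with fewer
    than 4 supra-threshold voxels are never split.

    When ``subject_data`` is given as (M, n_voxels, n) the sub-ROI
    subject-level means are recomputed from it; otherwise they are
    approximated by the parent entry's subject series offset by the
    sub-ROI group shape.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    if voxel_series.ndim != 2 or voxel_series.shape[0] != entry.n_supra_voxels:
        raise ValueError("voxel_series must be (n_supra_voxels, n)")
    if entry.n_supra_voxels < 4:
        return [entry]
    Z = _zscore_rows(voxel_series)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(Z)
    lab = km.labels_
    if len(np.unique(lab)) < 2:
        return [entry]
    sil = silhouette_score(Z, lab)
    if sil < SPLIT_SILHOUETTE:
        return [entry]
    out = []
    for k in (0, 1):
        sel = lab == k
        if subject_data is not None:
            sub_tcs = np.asarray(subject_data, dtype=float)[:, sel, :].mean(axis=1)
        else:
            shape_k = voxel_series[sel].mean(axis=0)
            sub_tcs = entry.subject_tcs - entry.group_tc + shape_k
        out.append(
            ROISeries(
                roi_id=entry.roi_id,
                roi_name=f"{entry.roi_name}.{k}",
                hemisphere=entry.hemisphere,
                subject_tcs=sub_tcs,
                group_tc=sub_tcs.mean(axis=0),
                n_supra_voxels=int(sel.sum()),
                supra_fraction=entry.supra_fraction * sel.mean(),
                sub_roi=k,
                voxel_indices=(
                    entry.voxel_indices[sel] if entry.voxel_indices is not None else None
                ),
            )
        )
    return out


def network_partition(
    group_tcs: np.ndarray,
    K_range: tuple[int, int] = (2, 6),
    n_restarts: int = 100,
    random_state: int = 0,
) -> NetworkPartition:
    """Cluster group-level series into networks; choose K by Silhouette.

    ``group_tcs`` is (n_entries, n).  Each series is z-scored, K-means is
    run with ``n_restarts`` restarts for every candidate K, and the K
    with the largest mean Silhouette width wins.
    """
    G = np.asarray(group_tcs, dtype=float)
    if G.ndim != 2:
        raise ValueError("group_tcs must be (n_entries, n)")
    Z = _zscore_rows(G)
    if np.allclose(Z, Z[0], atol=1e-10):
        raise ValueError("all series identical: no cluster structure to find")
    k_lo, k_hi = K_range
    if k_lo < 2:
        raise ValueError("minimum candidate K is 2")
    if G.shape[0] < k_hi + 1:
        k_hi = G.shape[0] - 1
        logger.warning("too few series; shrinking K range to (%d, %d)", k_lo, k_hi)
    if k_hi < k_lo:
        raise ValueError("not enough series for any candidate K")
    sil_per_K: dict[int, float] = {}
    labels_per_K: dict[int, np.ndarray] = {}
    for K in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=K, n_init=n_restarts, random_state=random_state).fit(Z)
        if len(np.unique(km.labels_)) < K:
            sil_per_K[K] = -1.0
            labels_per_K[K] = km.labels_
            continue
        sil_per_K[K] = float(silhouette_score(Z, km.labels_))
        labels_per_K[K] = km.labels_
    best = max(sil_per_K, key=sil_per_K.get)
    return NetworkPartition(
        K=best,
        labels=labels_per_K[best],
        silhouette_mean=sil_per_K[best],
        silhouette_per_K=sil_per_K,
    )
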