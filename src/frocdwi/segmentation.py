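"""Whole-lesion 3D segmentation from a 2D seed by fuzzy C-means clustering.

A reader draws a 2D region of interest on the largest cross-section of the
lesion in the b = 800 s/mm^2 volume; this module grows it into a 3D
whole-lesion mask by intensity clustering.  Plain fuzzy C-means (objective
``sum_{i,k} u_ik**m * (x_k - c_i)**2``, alternating membership / centroid
updates) is run on the intensities inside a dilated bounding box around the
seed; the cluster that best covers the seed is binarized at membership 0.5
and reduced to the 26-connected component touching the seed.

The clustering domain is local (seed bounding box + margin), not the whole
breast volume: a global two-class split would be dominated by air and fat
rather than the lesion/parenchyma contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["RoiMask", "FcmConfig", "fcm_cluster", "segment_lesion_3d", "copy_roi_to_maps",
           "SegmentationError"]


class SegmentationError(RuntimeError):
    """Lesion segmentation failed (empty component, seed outside volume...)."""


@dataclass
class RoiMask:
    """Boolean region of interest on the image grid.

    ``kind`` is "2d" (a single-slice seed, ``slice_index`` set) or "3d"
    (whole-lesion).  The mask array always spans the full 3D grid.
    """

    mask: np.ndarray
    kind: str = "3d"
    slice_index: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("RoiMask stores a 3D boolean grid")
        if not self.mask.any():
            raise ValueError("empty ROI")
        if self.kind == "2d":
            zs = np.unique(np.argwhere(self.mask)[:, 2])
            if zs.size != 1:
                raise ValueError("a 2D ROI must lie on exactly one slice")
            if self.slice_index is None:
                self.slice_index = int(zs[0])
            elif self.slice_index != int(zs[0]):
                raise ValueError("slice_index disagrees with the mask")
        elif self.kind != "3d":
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FcmConfig:
    n_clusters: int = 2
    m: float = 2.0                 # fuzzifier
    tolerance: float = 1e-5        # max centroid shift to stop
    max_iter: int = 100
    seed: int = 0
    margin: int = 10               # in-plane bounding-box dilation, voxels

    def __post_init__(self) -> None:
        if self.m <= 1:
            raise ValueError("fuzzifier m must exceed 1")
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")


def fcm_cluster(values, config: FcmConfig | None = None, init_centroids=None):
    """Fuzzy C-means on a 1D intensity list.

    Returns ``(memberships, centroids, objective_history)`` where
    ``memberships`` is (n_clusters, n_samples) with columns summing to 1.
    Initialization is deterministic: centroids at evenly spaced percentiles
    of the data (10th/90th for two clusters), so the same input always gives
    the same clustering; ``init_centroids`` overrides it.
    """
    config = config or FcmConfig()
    x = np.asarray(values, dtype=float).ravel()
    if np.unique(x).size < config.n_clusters:
        raise ValueError(
            f"need >= {config.n_clusters} distinct values, got {np.unique(x).size}"
        )
    c = config.n_clusters
    if init_centroids is None:
        pct = np.linspace(10, 90, c)
        centroids = np.percentile(x, pct).astype(float)
        if np.unique(centroids).size < c:
            # skewed class balance: percentiles coincide; spread over the range
            centroids = np.linspace(x.min(), x.max(), c)
    else:
        centroids = np.asarray(init_centroids, dtype=float).copy()
        if centroids.shape != (c,):
            raise ValueError("init_centroids must have one entry per cluster")

    power = 2.0 / (config.m - 1.0)
    # convergence threshold scales with the data spread so that clustering is
    # equivariant under affine intensity rescaling
    stop_shift = config.tolerance * float(np.ptp(x))
    objective: list[float] = []
    u = None
    for _ in range(config.max_iter):
        d2 = (x[None, :] - centroids[:, None]) ** 2
        u = _memberships(d2, power)
        um = u**config.m
        objective.append(float(np.sum(um * d2)))
        new_centroids = (um @ x) / um.sum(axis=1)
        shift = float(np.max(np.abs(new_centroids - centroids)))
        centroids = new_centroids
        if shift < stop_shift:
            break
    # final memberships for the converged centroids
    d2 = (x[None, :] - centroids[:, None]) ** 2
    u = _memberships(d2, power)
    objective.append(float(np.sum(u**config.m * d2)))
    return u, centroids, np.asarray(objective)


def _memberships(d2: np.ndarray, power: float) -> np.ndarray:
    """Standard FCM membership update from squared distances (c, n)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-power / 2.0)
        ratio = inv / inv.sum(axis=0)[None, :]
    # samples coinciding with a centroid: full membership there (split on ties)
    hit = d2 == 0
    return np.where(
        hit.any(axis=0)[None, :],
        hit / np.maximum(hit.sum(axis=0), 1)[None, :],
        ratio,
    )


def segment_lesion_3d(volume, roi2d: RoiMask, config: FcmConfig | None = None) -> RoiMask:
    """Grow a 2D seed into a whole-lesion 3D mask on a 3D volume.

    Clusters intensities in a search box around the seed (in-plane margin
    from config, full z extent), picks the cluster with the highest mean
    membership over the seed voxels, thresholds memberships at 0.5, and
    keeps the 26-connected component overlapping the seed.
    """
    config = config or FcmConfig()
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    if roi2d.mask.shape != vol.shape:
        raise SegmentationError("seed ROI is not on the volume grid")
    if roi2d.kind != "2d":
        raise ValueError("seed must be a 2D ROI")

    seed = roi2d.mask
    coords = np.argwhere(seed)
    x0, y0 = coords[:, 0].min(), coords[:, 1].min()
    x1, y1 = coords[:, 0].max(), coords[:, 1].max()
    mgn = config.margin
    box = np.zeros_like(seed)
    box[
        max(0, x0 - mgn): x1 + mgn + 1,
        max(0, y0 - mgn): y1 + mgn + 1,
        :,
    ] = True

    values = vol[box]
    u, centroids, _ = fcm_cluster(values, config)

    membership_vol = np.zeros((config.n_clusters,) + vol.shape)
    for i in range(config.n_clusters):
        membership_vol[i][box] = u[i]
    seed_means = [membership_vol[i][seed].mean() for i in range(config.n_clusters)]
    lesion_cluster = int(np.argmax(seed_means))

    binary = membership_vol[lesion_cluster] >= 0.5
    labels, _ = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=int))
    seed_labels = np.unique(labels[seed])
    seed_labels = seed_labels[seed_labels > 0]
    if seed_labels.size == 0:
        raise SegmentationError(
            "selected cluster produced no component overlapping the seed "
            f"(centroids {centroids}, seed mean memberships {seed_means})"
        )
    # the component with the largest seed overlap
    overlaps = [(labels[seed] == lab).sum() for lab in seed_labels]
    component = labels == seed_labels[int(np.argmax(overlaps))]
    if component[seed].sum() < 0.5 * seed.sum():
        raise SegmentationError(
            "segmented component covers less than half the seed; "
            "check seed placement or contrast"
        )
    return RoiMask(mask=component, kind="3d")


def copy_roi_to_maps(roi3d: RoiMask, maps) -> tuple[dict[str, np.ndarray], dict[str, int]]:
    """Extract per-parameter value lists at the ROI voxels of fitted maps.

    Fit-failed voxels (and, for mu, unidentifiable ones) are excluded;
    returns ``(values_by_param, excluded_counts_by_param)``.
    """
    if roi3d.mask.shape != maps.shape:
        raise ValueError("ROI grid does not match the parameter-map grid")
    values: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for name, arr in maps.maps.items():
        ok = roi3d.mask & maps.usable(name)
        values[name] = arr[ok]
        excluded[name] = int(roi3d.mask.sum() - ok.sum())
    return values, excluded
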