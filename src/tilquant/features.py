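"""The fixed 43-feature representation of a segmented nucleus.

The registry pins an ordered, versioned list of exactly 43 features in five
groups — shape (12), intensity (12), texture (13), neighbourhood (3) and
gradient/edge (3) — the vector the cell classifier consumes.  Shape comes
from the region mask, intensity from the nucleus-signal grayscale within
the region, texture from grey-level co-occurrence statistics of the
region's bounding patch (quantised to 32 levels, background masked to the
region median), neighbourhood from the centroid cloud, and gradient from
the boundary gradient magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew
from skimage.feature import graycomatrix
from skimage.measure import regionprops

FEATURE_REGISTRY_VERSION = "1.0"

SHAPE_FEATURES = (
    "area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
    "eccentricity",
    "solidity",
    "extent",
    "circularity",
    "convex_area",
    "orientation",
    "equivalent_diameter",
    "boundary_roughness",
)
INTENSITY_FEATURES = (
    "intensity_mean",
    "intensity_sd",
    "intensity_min",
    "intensity_max",
    "intensity_median",
    "intensity_mad",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_q10",
    "intensity_q90",
    "integrated_intensity",
    "ring_contrast",
)
TEXTURE_FEATURES = (
    "glcm_contrast",
    "glcm_dissimilarity",
    "glcm_homogeneity",
    "glcm_energy",
    "glcm_correlation",
    "glcm_asm",
    "glcm_entropy",
    "glcm_max_prob",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_diff_variance",
)
NEIGHBOURHOOD_FEATURES = ("neighbor_count", "nn_distance", "local_density")
GRADIENT_FEATURES = ("gradient_mean", "gradient_sd", "gradient_max")

FEATURE_NAMES: tuple[str, ...] = (
    SHAPE_FEATURES
    + INTENSITY_FEATURES
    + TEXTURE_FEATURES
    + NEIGHBOURHOOD_FEATURES
    + GRADIENT_FEATURES
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 43

GLCM_LEVELS = 32
DEFAULT_NEIGHBOR_RADIUS = 50.0


@dataclass
class CellRecord:
    """One segmented nucleus: identity, location, 43-vector, optional label."""

    cell_id: int
    slide_id: str
    tile_index: int
    centroid: tuple[float, float]
    features: np.ndarray
    label: Optional[str] = None
    registry_version: str = FEATURE_REGISTRY_VERSION

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.features.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("feature vector must be finite")


def neighbor_count(
    centroids: Sequence[tuple[float, float]], radius_px: float
) -> np.ndarray:
    """Number of *other* centroids within Euclidean distance <= radius."""
    if radius_px <= 0:
        raise ValueError("radius must be > 0")
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return np.zeros(0, dtype=int)
    tree = cKDTree(pts)
    counts = tree.query_ball_point(pts, r=radius_px, return_length=True)
    return np.asarray(counts, dtype=int) - 1  # drop self


def _neighbourhood_features(
    centroids: np.ndarray, radius_px: float
) -> np.ndarray:
    """(n, 3) array: count within radius, nearest-neighbour distance, density."""
    n = len(centroids)
    out = np.zeros((n, 3))
    if n == 0:
        return out
    counts = neighbor_count(centroids, radius_px)
    out[:, 0] = counts
    if n > 1:
        tree = cKDTree(centroids)
        k = min(4, n)
        dists, _ = tree.query(centroids, k=k)
        out[:, 1] = dists[:, 1]
        # inverse mean distance to the (up to) 3 nearest neighbours
        mean_knn = dists[:, 1:].mean(axis=1)
        out[:, 2] = 1.0 / np.maximum(mean_knn, 1e-9)
    else:
        out[:, 1] = np.inf  # replaced below by caller-safe large value
        out[:, 1] = 1e6
    return out


def _glcm_features(patch: np.ndarray) -> np.ndarray:
    """13 co-occurrence statistics on a [0,1] patch quantised to 32 levels."""
    lo, hi = patch.min(), patch.max()
    if hi > lo:
        q = np.floor((patch - lo) / (hi - lo) * (GLCM_LEVELS - 1e-9)).astype(np.uint8)
    else:
        q = np.zeros(patch.shape, dtype=np.uint8)
    glcm = graycomatrix(
        q,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=GLCM_LEVELS,
        symmetric=True,
        normed=True,
    )
    p = glcm[:, :, 0, :].mean(axis=2)  # average over the 4 directions
    i, j = np.indices(p.shape)
    mu_i = (i * p).sum()
    mu_j = (j * p).sum()
    sd_i = math.sqrt(max(((i - mu_i) ** 2 * p).sum(), 0.0))
    sd_j = math.sqrt(max(((j - mu_j) ** 2 * p).sum(), 0.0))

    contrast = ((i - j) ** 2 * p).sum()
    dissimilarity = (np.abs(i - j) * p).sum()
    homogeneity = (p / (1.0 + (i - j) ** 2)).sum()
    asm = (p**2).sum()
    energy = math.sqrt(asm)
    if sd_i > 0 and sd_j > 0:
        correlation = (((i - mu_i) * (j - mu_j) * p).sum()) / (sd_i * sd_j)
    else:
        correlation = 1.0
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    max_prob = float(p.max())
    cs = (((i + j) - mu_i - mu_j) ** 3 * p).sum()  # cluster shade
    cp = (((i + j) - mu_i - mu_j) ** 4 * p).sum()  # cluster prominence
    sum_avg = ((i + j) * p).sum()
    sum_var = (((i + j) - sum_avg) ** 2 * p).sum()
    diff_mean = dissimilarity
    diff_var = ((np.abs(i - j) - diff_mean) ** 2 * p).sum()
    return np.array(
        [
            contrast,
            dissimilarity,
            homogeneity,
            energy,
            correlation,
            asm,
            entropy,
            max_prob,
            cs,
            cp,
            sum_avg,
            sum_var,
            diff_var,
        ]
    )


def extract_features(
    labels: np.ndarray,
    gray: np.ndarray,
    slide_id: str = "",
    tile_index: int = 0,
    neighbor_radius_px: float = DEFAULT_NEIGHBOR_RADIUS,
) -> list[CellRecord]:
    """Compute the 43-vector for every labelled nucleus.

    ``labels`` and ``gray`` must share shape; one record per label, ordered
    by label id.  Neighbourhood features use all centroids in this label
    map.
    """
    labels = np.asarray(labels)
    gray = np.asarray(gray, dtype=np.float64)
    if labels.shape != gray.shape:
        raise ValueError("labels and gray must share shape")
    props = regionprops(labels, intensity_image=gray)
    if not props:
        return []

    centroids = np.array([rp.centroid for rp in props])
    nbh = _neighbourhood_features(centroids, neighbor_radius_px)

    grad_r = ndi.sobel(gray, axis=0)
    grad_c = ndi.sobel(gray, axis=1)
    grad_mag = np.hypot(grad_r, grad_c)

    records: list[CellRecord] = []
    for idx, rp in enumerate(props):
        area = float(rp.area)
        perim = float(rp.perimeter_crofton) if rp.perimeter_crofton > 0 else 1.0
        convex_area = float(rp.area_convex)
        eq_diam = float(rp.equivalent_diameter_area)
        circularity = 4.0 * math.pi * area / perim**2
        # boundary roughness: actual perimeter over equivalent-circle perimeter
        roughness = perim / (math.pi * eq_diam) if eq_diam > 0 else 1.0
        shape = np.array(
            [
                area,
                perim,
                float(rp.axis_major_length),
                float(rp.axis_minor_length),
                float(rp.eccentricity),
                float(rp.solidity),
                float(rp.extent),
                circularity,
                convex_area,
                float(rp.orientation),
                eq_diam,
                roughness,
            ]
        )

        vals = gray[rp.slice][rp.image]
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        skw = float(_skew(vals)) if vals.size > 2 and vals.std() > 0 else 0.0
        krt = float(_kurtosis(vals)) if vals.size > 3 and vals.std() > 0 else 0.0
        ring = _ring_contrast(labels, gray, rp)
        intensity = np.array(
            [
                float(vals.mean()),
                float(vals.std()),
                float(vals.min()),
                float(vals.max()),
                med,
                mad,
                skw,
                krt,
                float(np.quantile(vals, 0.10)),
                float(np.quantile(vals, 0.90)),
                float(vals.sum()),
                ring,
            ]
        )

        patch = gray[rp.slice].copy()
        patch[~rp.image] = med  # mask background to the region median
        texture = _glcm_features(patch)

        boundary = rp.image & ~ndi.binary_erosion(rp.image)
        bgrad = grad_mag[rp.slice][boundary]
        if bgrad.size == 0:
            bgrad = np.zeros(1)
        gradient = np.array(
            [float(bgrad.mean()), float(bgrad.std()), float(bgrad.max())]
        )

        vec = np.concatenate([shape, intensity, texture, nbh[idx], gradient])
        records.append(
            CellRecord(
                cell_id=int(rp.label),
                slide_id=slide_id,
                tile_index=tile_index,
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                features=vec,
            )
        )
    return records


def _ring_contrast(labels: np.ndarray, gray: np.ndarray, rp) -> float:
    """Mean interior intensity minus mean intensity of a 2-px outer ring."""
    r0, c0, r1, c1 = rp.bbox
    pad = 3
    rr0, cc0 = max(r0 - pad, 0), max(c0 - pad, 0)
    rr1, cc1 = min(r1 + pad, labels.shape[0]), min(c1 + pad, labels.shape[1])
    sub_lab = labels[rr0:rr1, cc0:cc1]
    region = sub_lab == rp.label
    ring = ndi.binary_dilation(region, iterations=2) & ~region & (sub_lab == 0)
    sub_gray = gray[rr0:rr1, cc0:cc1]
    inner = float(sub_gray[region].mean())
    outer = float(sub_gray[ring].mean()) if ring.any() else inner
    return inner - outer


def records_to_matrix(records: Sequence[CellRecord]) -> np.ndarray:
    """Stack feature vectors into an (n, 43) matrix."""
    if not records:
        return np.zeros((0, N_FEATURES))
    return np.vstack([r.features for r in records])
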