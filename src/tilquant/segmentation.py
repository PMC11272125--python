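"""Nucleus segmentation: colour transform, Otsu threshold, opening, watershed.

The stage turns an RGB H&E tile into an integer label map of individual
haematoxylin-positive nuclei.  Whole sections are processed as a 10x10 grid
of tiles (processed independently, then merged at their offsets), which
bounds per-tile memory and mirrors how large sections are handled in
practice.

Everything here is deterministic: there is no randomness in this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab
from skimage.morphology import disk, h_maxima
from skimage.segmentation import watershed


class DegenerateImageError(ValueError):
    """The image carries no usable contrast (e.g. constant pixels)."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the segmentation stage.

    opening_radius_px : disk radius of the morphological opening that
        removes speckle after thresholding.
    min_nucleus_area_px : regions smaller than this are discarded
        (sub-lymphocyte debris at the synthetic pixel scale).
    hmax_suppression : prominence (in px of the distance transform) a
        local maximum needs to seed a watershed basin.
    dist_smooth_sigma : Gaussian smoothing of the distance transform
        before seed detection; regularises the spurious maxima that
        irregular (cancer-like) boundaries induce.
    connectivity : pixel connectivity, 4 or 8.
    grid : tiling of whole sections, default 10x10 = 100 parts.
    """

    opening_radius_px: int = 1
    min_nucleus_area_px: int = 9
    hmax_suppression: float = 2.0
    dist_smooth_sigma: float = 1.0
    connectivity: int = 8
    grid: tuple[int, int] = (10, 10)
    min_tile_px: int = 100  # tiles never shrink below this: seams would
    # otherwise cut most nuclei on small images (tiling exists for
    # efficiency on large sections, not as a fixed geometry)

    def __post_init__(self) -> None:
        if self.opening_radius_px < 0:
            raise ValueError("opening_radius_px must be >= 0")
        if self.min_nucleus_area_px < 1:
            raise ValueError("min_nucleus_area_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    @property
    def _conn(self) -> int:
        return 1 if self.connectivity == 4 else 2


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIELAB (D65); L in [0, 100]."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    return rgb2lab(img)


def to_nucleus_grayscale(img: np.ndarray) -> np.ndarray:
    """Project an RGB tile onto a [0, 1] nucleus-signal channel.

    LAB channels are standardised with their per-channel mean/SD, the
    standardised lightness is negated (haematoxylin-dark nuclei score HIGH),
    and the result is affinely rescaled to [0, 1].

    Raises
    ------
    DegenerateImageError
        If every channel is constant (zero SD), e.g. a blank tile.
    """
    lab = rgb_to_lab(img)
    sds = lab.std(axis=(0, 1))
    if np.all(sds == 0):
        raise DegenerateImageError("constant image: no nucleus signal")
    means = lab.mean(axis=(0, 1))
    l_std = (lab[:, :, 0] - means[0]) / (sds[0] if sds[0] > 0 else 1.0)
    score = -l_std
    lo, hi = score.min(), score.max()
    if hi == lo:
        raise DegenerateImageError("constant lightness: no nucleus signal")
    return (score - lo) / (hi - lo)


def lightness_complement(img: np.ndarray) -> np.ndarray:
    """Absolute nucleus-signal channel: (100 - L*)/100, in [0, 1].

    Unlike :func:`to_nucleus_grayscale` this scale is anchored to the CIELAB
    lightness axis rather than to the slide's own intensity range, so
    per-cell intensity features are comparable across sections regardless
    of their cellular composition (a section with no truly basophilic
    nuclei must not have its darkest nuclei stretched to full signal).
    """
    lab = rgb_to_lab(img)
    return np.clip((100.0 - lab[:, :, 0]) / 100.0, 0.0, 1.0)


def otsu_threshold(gray: np.ndarray, n_bins: int = 256) -> float:
    """Otsu's threshold: maximise between-class variance over bin boundaries.

    The histogram uses ``n_bins`` equal right-open bins over [min, max].
    Ties are broken towards the lowest maximising boundary. Returns the
    threshold value (a bin edge) on the grayscale's own scale.
    """
    gray = np.asarray(gray, dtype=np.float64).ravel()
    lo, hi = gray.min(), gray.max()
    if lo == hi:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    hist, edges = np.histogram(gray, bins=n_bins, range=(lo, hi))
    p = hist / hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0

    w0 = np.cumsum(p)                      # weight of class <= t, per boundary
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * (1.0 - w0))
    sigma_b = np.nan_to_num(sigma_b[:-1], nan=-1.0, posinf=-1.0)
    k = int(np.argmax(sigma_b))            # argmax takes the first (lowest) tie
    return float(edges[k + 1])


def binarize_and_open(
    gray: np.ndarray, threshold: float, params: SegmentationParams
) -> np.ndarray:
    """Foreground mask (gray > t*), cleaned with a disk opening."""
    mask = np.asarray(gray) > threshold
    if params.opening_radius_px > 0:
        mask = ndi.binary_opening(mask, structure=disk(params.opening_radius_px))
    return mask


def watershed_split(
    mask: np.ndarray, gray: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Split touching nuclei along distance-transform ridges.

    Seeds are the h-maxima of the Euclidean distance transform
    (h = ``hmax_suppression``); watershed floods the negated distance
    transform within the mask. Regions below the minimum area are dropped
    and labels are renumbered contiguously from 1.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    dist = ndi.distance_transform_edt(mask)
    if params.dist_smooth_sigma > 0:
        dist = ndi.gaussian_filter(dist, params.dist_smooth_sigma)
    seeds_mask = h_maxima(dist, params.hmax_suppression)
    markers, n_seed = ndi.label(
        seeds_mask, structure=np.ones((3, 3)) if params.connectivity == 8 else None
    )
    if n_seed == 0:
        labels, _ = ndi.label(
            mask, structure=np.ones((3, 3)) if params.connectivity == 8 else None
        )
    else:
        labels = watershed(-dist, markers, mask=mask, connectivity=params._conn)
        # components no seed reached (none here, mask-restricted) stay 0
        unlabeled = mask & (labels == 0)
        if unlabeled.any():
            extra, n_extra = ndi.label(unlabeled, structure=np.ones((3, 3)))
            labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return _filter_and_relabel(labels, params.min_nucleus_area_px)


def _filter_and_relabel(labels: np.ndarray, min_area: int) -> np.ndarray:
    """Drop regions below min_area and renumber labels contiguously."""
    labels = np.asarray(labels)
    if labels.max() == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_area
    keep[0] = False
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels]


def tile_image(
    img: np.ndarray, grid: tuple[int, int] = (10, 10)
) -> list[tuple[np.ndarray, tuple[int, int]]]:
    """Split an image into a row-major grid of tiles with offsets.

    Width/height are divided by floor; remainder pixels are appended to the
    last column / last row of tiles, so reassembling tiles at their offsets
    reproduces the input exactly.  An image smaller than the grid falls back
    to a single tile.
    """
    img = np.asarray(img)
    rows, cols = grid
    h, w = img.shape[:2]
    if h < rows or w < cols:
        return [(img, (0, 0))]
    th, tw = h // rows, w // cols
    tiles = []
    for i in range(rows):
        r0 = i * th
        r1 = (i + 1) * th if i < rows - 1 else h
        for j in range(cols):
            c0 = j * tw
            c1 = (j + 1) * tw if j < cols - 1 else w
            tiles.append((img[r0:r1, c0:c1], (r0, c0)))
    return tiles


def segment_tile(img: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Full single-tile pipeline: grayscale -> Otsu -> opening -> watershed."""
    gray = to_nucleus_grayscale(img)
    t = otsu_threshold(gray)
    mask = binarize_and_open(gray, t, params)
    return watershed_split(mask, gray, params)


def segment_slide(
    img: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Segment a whole section tile-by-tile and merge into a global label map.

    The nucleus grayscale and the Otsu threshold are computed once on the
    whole section (a background-only tile has no bimodal histogram, so a
    per-tile threshold would slice noise), after which each tile of the
    cleaned foreground mask is watershed-split independently and pasted
    back at its offset.  A nucleus straddling a tile boundary appears as
    one fragment per tile; when two fragments touch across the seam the
    smaller one is suppressed so each physical nucleus keeps a single
    label.  An all-background section yields an empty label map.
    """
    params = params or SegmentationParams()
    img = np.asarray(img)
    h, w = img.shape[:2]
    try:
        gray = to_nucleus_grayscale(img)
        t = otsu_threshold(gray)
    except DegenerateImageError:
        # an all-background section has no contrast and no nuclei
        return np.zeros((h, w), dtype=np.int32)
    mask = binarize_and_open(gray, t, params)
    if not mask.any():
        return np.zeros((h, w), dtype=np.int32)

    grid = _effective_grid(h, w, params)
    global_labels = np.zeros((h, w), dtype=np.int32)
    next_label = 0
    for tile_mask, (r0, c0) in tile_image(mask, grid):
        gtile = gray[r0 : r0 + tile_mask.shape[0], c0 : c0 + tile_mask.shape[1]]
        tl = watershed_split(tile_mask, gtile, params)
        n = int(tl.max())
        if n == 0:
            continue
        view = global_labels[r0 : r0 + tile_mask.shape[0], c0 : c0 + tile_mask.shape[1]]
        view[tl > 0] = tl[tl > 0] + next_label
        next_label += n
    if next_label == 0:
        return global_labels
    global_labels = _suppress_boundary_fragments(global_labels, grid)
    return _filter_and_relabel(global_labels, params.min_nucleus_area_px)


def _effective_grid(h: int, w: int, params: SegmentationParams) -> tuple[int, int]:
    """Clamp the grid so no tile falls below ``min_tile_px`` per side."""
    rows, cols = params.grid
    rows = max(1, min(rows, h // params.min_tile_px)) if h >= params.min_tile_px else 1
    cols = max(1, min(cols, w // params.min_tile_px)) if w >= params.min_tile_px else 1
    return rows, cols


_SEAM_BAND = 3  # px: per-tile opening erodes tile edges, so fragments of one
# nucleus may sit a pixel or two apart across a seam; "touching" is judged
# within this band


def _nearest_nonzero(band: np.ndarray, from_end: bool) -> np.ndarray:
    """Per column, the nonzero label nearest the seam within a band (else 0)."""
    out = np.zeros(band.shape[1], dtype=band.dtype)
    rows = range(band.shape[0] - 1, -1, -1) if from_end else range(band.shape[0])
    for r in rows:
        fill = (out == 0) & (band[r] > 0)
        out[fill] = band[r][fill]
    return out


def _suppress_boundary_fragments(
    labels: np.ndarray, grid: tuple[int, int]
) -> np.ndarray:
    """Remove the smaller of any two labels that touch across a tile seam."""
    h, w = labels.shape
    rows, cols = grid
    if h < rows or w < cols:
        return labels
    th, tw = h // rows, w // cols
    areas = np.bincount(labels.ravel())
    suppressed: set[int] = set()

    def _handle(a_line: np.ndarray, b_line: np.ndarray) -> None:
        touch = (a_line > 0) & (b_line > 0) & (a_line != b_line)
        for la, lb in set(zip(a_line[touch].tolist(), b_line[touch].tolist())):
            if la in suppressed or lb in suppressed:
                continue
            smaller = la if areas[la] <= areas[lb] else lb
            suppressed.add(smaller)

    for i in range(1, rows):
        r = i * th
        above = _nearest_nonzero(labels[max(r - _SEAM_BAND, 0) : r, :], from_end=True)
        below = _nearest_nonzero(labels[r : r + _SEAM_BAND, :], from_end=False)
        _handle(above, below)
    for j in range(1, cols):
        c = j * tw
        left = _nearest_nonzero(
            labels[:, max(c - _SEAM_BAND, 0) : c].T, from_end=True
        )
        right = _nearest_nonzero(labels[:, c : c + _SEAM_BAND].T, from_end=False)
        _handle(left, right)

    if suppressed:
        kill = np.isin(labels, list(suppressed))
        labels = np.where(kill, 0, labels)
    return labels
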