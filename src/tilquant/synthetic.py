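"""Synthetic H&E-like slides and survival cohorts with known ground truth.

Every downstream stage of the pipeline (segmentation, feature extraction,
classification, TIL quantification, survival analysis) is exercised against
data produced here, so the generators are first-class, tested code.

The slide generator draws three nucleus morphologies on an eosin-pink
background:

* **cancer** — large nuclei (radius 8–16 px) with irregular, radially
  perturbed boundaries and speckled chromatin texture;
* **lymphocyte** — small (radius 3–5 px), nearly circular, uniformly dark
  (basophilic) nuclei;
* **stroma** — strongly elongated nuclei (ellipse axis ratio >= 3), the
  fibroblast / endothelial morphology.

The cohort generator draws survival times from an exponential
proportional-hazards model whose log-hazard is linear in the TIL percentage
plus categorical covariate effects, with independent exponential censoring.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("cancer", "lymphocyte", "stroma")

# morphology priors (pixels); chosen so size / eccentricity / texture separate
# the three classes for the downstream classifier
LYMPHOCYTE_RADIUS = (3.0, 5.0)
CANCER_RADIUS = (8.0, 16.0)
STROMA_MAJOR = (8.0, 14.0)
STROMA_AXIS_RATIO = (3.0, 5.0)

PLACEMENT_RETRY_CAP = 1000

# haematoxylin / eosin palette (RGB, uint8 scale)
_BACKGROUND = np.array([235.0, 200.0, 215.0])
_CLASS_COLOR = {
    "cancer": np.array([110.0, 70.0, 150.0]),
    "lymphocyte": np.array([45.0, 30.0, 95.0]),
    "stroma": np.array([95.0, 60.0, 135.0]),
}
_CLASS_TEXTURE_SD = {"cancer": 28.0, "lymphocyte": 4.0, "stroma": 6.0}


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without exceeding the retry cap."""


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic H&E-like slide.

    ``class_fractions`` is (cancer, lymphocyte, stroma) and must sum to 1.
    ``overlap_fraction`` of nuclei are intentionally placed touching an
    existing neighbour to exercise watershed splitting.
    """

    width_px: int = 1000
    height_px: int = 1000
    n_nuclei: int = 200
    class_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    overlap_fraction: float = 0.0
    noise_sd: float = 3.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("slide must be at least 1x1 px")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        fr = self.class_fractions
        if len(fr) != 3 or any(f < 0 or f > 1 for f in fr):
            raise ValueError("class_fractions must be three proportions in [0,1]")
        if abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must be in [0,1]")


@dataclass
class GroundTruth:
    """Reference standard for one synthetic slide.

    ``true_mask`` is an integer label map (0 = background, labels 1..K);
    ``true_labels[i]`` is the class of label ``i + 1``.
    ``true_til_proportion`` is in percent, or ``None`` when no nuclei exist.
    """

    true_mask: np.ndarray
    true_labels: list[str]
    true_til_proportion: Optional[float]
    centroids: list[tuple[float, float]] = field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        return {c: sum(1 for lab in self.true_labels if lab == c) for c in CLASS_NAMES}


def _nucleus_footprint(rng: np.random.Generator, cls: str):
    """Sample one nucleus shape; returns (offsets_rc, effective_radius).

    ``offsets_rc`` is an (m, 2) int array of pixel offsets relative to the
    nucleus centre.
    """
    if cls == "lymphocyte":
        r = rng.uniform(*LYMPHOCYTE_RADIUS)
        extent = int(math.ceil(r)) + 1
        yy, xx = np.mgrid[-extent : extent + 1, -extent : extent + 1]
        inside = yy**2 + xx**2 <= r**2
        eff = r
    elif cls == "cancer":
        r0 = rng.uniform(*CANCER_RADIUS)
        # radial boundary noise from a few random Fourier harmonics
        n_harm = 4
        amps = rng.uniform(0.0, 0.08, size=n_harm)
        phases = rng.uniform(0, 2 * math.pi, size=n_harm)
        extent = int(math.ceil(r0 * 1.25)) + 1
        yy, xx = np.mgrid[-extent : extent + 1, -extent : extent + 1]
        theta = np.arctan2(yy, xx)
        rad = np.sqrt(yy**2 + xx**2)
        rb = r0 * (
            1.0
            + sum(
                a * np.cos((k + 2) * theta + p)
                for k, (a, p) in enumerate(zip(amps, phases))
            )
        )
        inside = rad <= rb
        eff = r0 * 1.1
    elif cls == "stroma":
        a = rng.uniform(*STROMA_MAJOR)
        ratio = rng.uniform(*STROMA_AXIS_RATIO)
        b = max(a / ratio, 1.2)
        phi = rng.uniform(0, math.pi)
        extent = int(math.ceil(a)) + 1
        yy, xx = np.mgrid[-extent : extent + 1, -extent : extent + 1]
        # rotate coordinates into the ellipse frame
        xr = xx * math.cos(phi) + yy * math.sin(phi)
        yr = -xx * math.sin(phi) + yy * math.cos(phi)
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        eff = a
    else:  # pragma: no cover
        raise ValueError(f"unknown class {cls!r}")
    offs = np.argwhere(inside) - extent
    return offs, eff


def generate_slide(spec: SlideSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a synthetic H&E-like RGB slide with ground truth.

    Returns ``(image, truth)`` where ``image`` is uint8 HxWx3. Identical
    spec (including seed) gives bit-identical output.

    Raises
    ------
    PlacementError
        If a nucleus cannot be placed within the per-nucleus retry cap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    classes = rng.choice(3, size=spec.n_nuclei, p=np.asarray(spec.class_fractions))
    class_list = [CLASS_NAMES[c] for c in classes]
    n_overlap = int(round(spec.overlap_fraction * spec.n_nuclei))

    mask = np.zeros((h, w), dtype=np.int32)
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    # gentle eosin mottle so the background is not flat
    img += rng.normal(0.0, 2.0, size=(h, w, 1))

    placed: list[tuple[float, float, float]] = []  # (row, col, eff_radius)
    labels: list[str] = []
    centroids: list[tuple[float, float]] = []

    for i, cls in enumerate(class_list):
        offs, eff = _nucleus_footprint(rng, cls)
        want_overlap = placed and i >= spec.n_nuclei - n_overlap
        for attempt in range(PLACEMENT_RETRY_CAP + 1):
            if attempt == PLACEMENT_RETRY_CAP:
                raise PlacementError(
                    f"could not place nucleus {i} ({cls}) in {PLACEMENT_RETRY_CAP} tries"
                )
            if want_overlap:
                ar, ac, arad = placed[rng.integers(len(placed))]
                d = (arad + eff) * rng.uniform(0.7, 0.95)
                ang = rng.uniform(0, 2 * math.pi)
                r_c = ar + d * math.sin(ang)
                c_c = ac + d * math.cos(ang)
                if not (eff <= r_c < h - eff and eff <= c_c < w - eff):
                    continue
                # stay clear of everything except the chosen anchor
                ok = all(
                    (r_c - pr) ** 2 + (c_c - pc) ** 2 >= (eff + prad + 2.0) ** 2
                    or (pr == ar and pc == ac)
                    for pr, pc, prad in placed
                )
            else:
                r_c = rng.uniform(eff, h - eff) if h > 2 * eff else h / 2
                c_c = rng.uniform(eff, w - eff) if w > 2 * eff else w / 2
                ok = all(
                    (r_c - pr) ** 2 + (c_c - pc) ** 2 >= (eff + prad + 2.0) ** 2
                    for pr, pc, prad in placed
                )
            if ok:
                break

        rows = offs[:, 0] + int(round(r_c))
        cols = offs[:, 1] + int(round(c_c))
        keep = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        rows, cols = rows[keep], cols[keep]
        free = mask[rows, cols] == 0  # first-placed nucleus keeps shared pixels
        rows, cols = rows[free], cols[free]
        mask[rows, cols] = i + 1

        color = _CLASS_COLOR[cls]
        tex = rng.normal(0.0, _CLASS_TEXTURE_SD[cls], size=(rows.size, 3))
        img[rows, cols] = color + tex

        placed.append((r_c, c_c, eff))
        labels.append(cls)
        centroids.append((r_c, c_c))

    if spec.blur_sigma > 0:
        for ch in range(3):
            img[:, :, ch] = gaussian_filter(img[:, :, ch], spec.blur_sigma)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    n = len(labels)
    if n == 0:
        til = None
    else:
        til = 100.0 * sum(1 for c in labels if c == "lymphocyte") / n
    return img, GroundTruth(mask, labels, til, centroids)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated patient cohort.

    Hazard for patient *j*:  ``baseline_hazard * exp(beta_til * TIL_j% +
    sum_c covariate_effects[c] * x_jc)`` with x_jc ~ Bernoulli(1/2).
    Censoring is an independent Exponential(``censoring_rate``) draw, with an
    optional administrative cutoff.
    """

    n_patients: int = 1000
    beta_til: float = math.log(0.965)
    covariate_effects: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"sex_male": 0.3, "advanced_stage": 0.7}
    )
    baseline_hazard: float = 0.15
    censoring_rate: float = 0.10
    til_distribution: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"mu": math.log(3.0), "sigma": 1.0}
    )
    admin_cutoff: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.baseline_hazard <= 0 or self.censoring_rate <= 0:
            raise ValueError("rates must be > 0")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table under the exponential proportional-hazards model.

    Columns: ``til_pct``, one 0/1 column per covariate effect, ``time``
    (years), ``event`` (1 = death observed). TIL % is log-normal (right-
    skewed, matching real TIL distributions) and capped at 100.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    mu = spec.til_distribution.get("mu", math.log(3.0))
    sigma = spec.til_distribution.get("sigma", 1.0)
    til = np.minimum(rng.lognormal(mu, sigma, size=n), 100.0)

    lp = spec.beta_til * til
    cols: dict[str, np.ndarray] = {"til_pct": til}
    for name, beta in spec.covariate_effects.items():
        x = rng.integers(0, 2, size=n)
        cols[name] = x
        lp = lp + beta * x

    event_time = rng.exponential(1.0, size=n) / (spec.baseline_hazard * np.exp(lp))
    censor_time = rng.exponential(1.0 / spec.censoring_rate, size=n)
    if spec.admin_cutoff is not None:
        censor_time = np.minimum(censor_time, spec.admin_cutoff)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)

    cols["time"] = time
    cols["event"] = event
    return pd.DataFrame(cols)


def generate_training_slide_set(
    cancer_type: str, n_per_class: int = 200, seed: int = 0
) -> tuple[np.ndarray, GroundTruth]:
    """A dense slide with balanced classes, for building labelled training sets.

    The three cancer-type presets perturb the morphology slightly (AEGJ, GAC
    and ESCC sections differ cytomorphologically), but all remain within the
    class priors so one feature registry serves all.
    """
    presets = {"AEGJ": 11, "GAC": 23, "ESCC": 37}
    if cancer_type not in presets:
        raise ValueError(f"unknown cancer type {cancer_type!r}")
    n = 3 * n_per_class
    side = int(math.ceil(math.sqrt(n / 150.0) * 1000))
    spec = SlideSpec(
        width_px=side,
        height_px=side,
        n_nuclei=n,
        class_fractions=(1 / 3, 1 / 3, 1 / 3),
        seed=seed * 1000 + presets[cancer_type],
    )
    return generate_slide(spec)
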