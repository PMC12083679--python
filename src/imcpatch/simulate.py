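"""Synthetic IMC cohorts with grade-dependent Shh/TGF-β co-localization.

The generator produces the statistical structure the patch analysis assumes:
each image carries a latent fibrosis field (smoothed white noise thresholded
at a grade-specific quantile, so the fibrotic area fraction is exact), and the
TGF-β and Shh channels are Poisson count rasters whose means are elevated
inside the fibrotic mask. The Shh elevation grows with fibrosis grade, which
is precisely the co-localization signal the downstream split-and-compare
pipeline is built to detect. DNA marks tissue via randomly placed nucleus
disks; rare hot pixels emulate the count artifacts that motivate the
outlier-discard step.

A separate helper draws scaled-TGF-β-like values straight from a bimodal
mixture whose analytic density has its interior minimum at a chosen point;
it is the ground truth for density-split threshold recovery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage, stats
from skimage.draw import disk

from ._errors import ConfigurationError
from .io import GRADES, Cohort, MarkerImage, MarkerPanel, REQUIRED_MARKERS

log = logging.getLogger(__name__)


@dataclass
class SyntheticConfig:
    """All generator knobs; ``seed`` fully determines the cohort.

    Rates are IMC dual counts per pixel. Defaults emulate a 32-sample cohort
    (8 images per grade G0-G3) with TGF-β elevated 8-fold-plus inside
    fibrotic regions and an Shh enrichment that increases with grade.
    """

    image_size_px: tuple[int, int] = (500, 500)
    pixel_size_um: float = 1.0
    field_smoothness_px: float = 40.0
    fibrotic_fraction_by_grade: dict = field(
        default_factory=lambda: {"G0": 0.02, "G1": 0.10, "G2": 0.25, "G3": 0.40}
    )
    tgfb_background: float = 1.0
    tgfb_fibrotic: float = 8.0
    shh_background: float = 2.0
    shh_effect_by_grade: dict = field(
        default_factory=lambda: {"G0": 0.0, "G1": 1.0, "G2": 2.0, "G3": 3.0}
    )
    nuclei_density_per_mm2: float = 2000.0
    nucleus_radius_px: int = 3
    dna_mean_count: float = 10.0
    hot_pixel_prob: float = 1e-4
    hot_pixel_value: float = 500.0
    n_per_grade: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.image_size_px
        if rows <= 0 or cols <= 0:
            raise ConfigurationError(f"image_size_px must be positive, got {self.image_size_px}")
        if self.n_per_grade < 1:
            raise ConfigurationError(f"n_per_grade must be >= 1, got {self.n_per_grade}")
        for name in (
            "tgfb_background",
            "tgfb_fibrotic",
            "shh_background",
            "nuclei_density_per_mm2",
            "dna_mean_count",
            "hot_pixel_prob",
            "hot_pixel_value",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for g, frac in self.fibrotic_fraction_by_grade.items():
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"fibrotic fraction for {g} outside [0,1]: {frac}")
        for g, eff in self.shh_effect_by_grade.items():
            if eff < 0:
                raise ConfigurationError(f"shh effect for {g} must be >= 0: {eff}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_size_px"] = list(self.image_size_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "image_size_px" in d:
            d["image_size_px"] = tuple(d["image_size_px"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-image oracle: the latent fibrotic mask and the effects baked in."""

    sample_id: str
    grade: str
    fibrotic_mask: np.ndarray
    fibrotic_fraction: float
    shh_effect: float


def _panel() -> MarkerPanel:
    return MarkerPanel.from_markers(REQUIRED_MARKERS)


def _fibrotic_mask(rng: np.random.Generator, shape, smoothness: float, fraction: float):
    if fraction <= 0.0:
        return np.zeros(shape, dtype=bool)
    latent = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=smoothness)
    if fraction >= 1.0:
        return np.ones(shape, dtype=bool)
    cutoff = np.quantile(latent, 1.0 - fraction)
    return latent >= cutoff


def generate_image(grade: str, config: SyntheticConfig, seed: int):
    """One synthetic image; returns ``(MarkerImage, GroundTruth)``.

    Channel construction, in fixed RNG order: latent field and fibrotic mask;
    TGF-β ~ Poisson(bg + fibrotic·mask); Shh ~ Poisson(bg + effect(grade)·mask);
    DNA ~ Poisson(mean) inside nucleus disks and Poisson(0.1·mean) outside;
    finally each pixel of each channel is independently replaced by
    ``hot_pixel_value`` with probability ``hot_pixel_prob``.
    """
    if grade not in config.fibrotic_fraction_by_grade or grade not in config.shh_effect_by_grade:
        raise ConfigurationError(f"unknown grade {grade!r}; configured: {sorted(config.fibrotic_fraction_by_grade)}")
    shape = tuple(config.image_size_px)
    rng = np.random.default_rng(seed)

    mask = _fibrotic_mask(rng, shape, config.field_smoothness_px,
                          config.fibrotic_fraction_by_grade[grade])
    effect = float(config.shh_effect_by_grade[grade])

    tgfb = rng.poisson(config.tgfb_background + config.tgfb_fibrotic * mask).astype(np.float64)
    shh = rng.poisson(config.shh_background + effect * mask).astype(np.float64)

    area_mm2 = shape[0] * shape[1] * (config.pixel_size_um * 1e-3) ** 2
    n_nuclei = int(round(config.nuclei_density_per_mm2 * area_mm2))
    nuc = np.zeros(shape, dtype=bool)
    centers = rng.uniform(0, 1, size=(n_nuclei, 2)) * np.array(shape)
    for r, c in centers:
        rr, cc = disk((r, c), config.nucleus_radius_px, shape=shape)
        nuc[rr, cc] = True
    dna_rate = np.where(nuc, config.dna_mean_count, 0.1 * config.dna_mean_count)
    dna = rng.poisson(dna_rate).astype(np.float64)

    channels = np.stack([dna, shh, tgfb])  # panel order: DNA, Shh, TGFb
    if config.hot_pixel_prob > 0:
        hot = rng.random(channels.shape) < config.hot_pixel_prob
        channels[hot] = config.hot_pixel_value

    image = MarkerImage(
        pixels=channels,
        panel=_panel(),
        pixel_size_um=config.pixel_size_um,
        grade=grade,
        is_case=grade != "G0",
    )
    truth = GroundTruth(
        sample_id=image.sample_id,
        grade=grade,
        fibrotic_mask=mask,
        fibrotic_fraction=float(mask.mean()),
        shh_effect=effect,
    )
    return image, truth


def image_seed(cohort_seed: int, index: int) -> int:
    """Deterministic per-image seed derived from the cohort seed."""
    return int(np.random.SeedSequence([int(cohort_seed), int(index)]).generate_state(1)[0])


def generate_cohort(config: SyntheticConfig):
    """Full cohort: ``n_per_grade`` images per grade G0-G3.

    G0 images are labeled ``is_case=False`` and double as the control stratum.
    Per-image seeds are hashed from ``(config.seed, image index)`` so cohorts
    are reproducible and images mutually independent.
    """
    images, truths = [], []
    index = 0
    for grade in GRADES:
        for k in range(config.n_per_grade):
            image, truth = generate_image(grade, config, image_seed(config.seed, index))
            image.sample_id = f"S{index:02d}_{grade}"
            truth.sample_id = image.sample_id
            images.append(image)
            truths.append(truth)
            index += 1
    return Cohort(images=images, metadata_source=f"synthetic(seed={config.seed})"), truths


# ---------------------------------------------------------------------------
# bimodal mixture with a prescribed density minimum


def _trunc(loc: float, scale: float):
    """Normal truncated to [0, inf) — scaled intensities are non-negative."""
    return stats.truncnorm(a=-loc / scale, b=np.inf, loc=loc, scale=scale)


def mixture_low_weight(
    minimum_at: float,
    loc_low: float,
    scale_low: float,
    loc_high: float,
    scale_high: float,
) -> float:
    """Weight of the low component so the mixture density is stationary at ``minimum_at``.

    Setting w·f1'(t) + (1-w)·f2'(t) = 0 with f1 decaying and f2 rising at t
    places the interior valley of the two-component density exactly at t.
    """
    f1, f2 = _trunc(loc_low, scale_low), _trunc(loc_high, scale_high)
    t = minimum_at
    d1 = -(t - loc_low) / scale_low**2 * f1.pdf(t)
    d2 = -(t - loc_high) / scale_high**2 * f2.pdf(t)
    if not (d1 < 0 < d2):
        raise ConfigurationError(
            f"minimum_at={t} does not lie between the component modes ({loc_low}, {loc_high})"
        )
    return float(d2 / (d2 - d1))


def _mixture_params(minimum_at, loc_low, scale_low, loc_high, scale_high):
    if loc_low is None:
        loc_low = 0.4 * minimum_at
    if loc_high is None:
        loc_high = minimum_at + 0.4
    return loc_low, scale_low, loc_high, scale_high


def mixture_pdf(
    x,
    minimum_at: float,
    loc_low: float | None = None,
    scale_low: float = 0.04,
    loc_high: float | None = None,
    scale_high: float = 0.18,
):
    """Analytic density of the bimodal mixture (for brute-force verification)."""
    loc_low, scale_low, loc_high, scale_high = _mixture_params(
        minimum_at, loc_low, scale_low, loc_high, scale_high
    )
    w = mixture_low_weight(minimum_at, loc_low, scale_low, loc_high, scale_high)
    return w * _trunc(loc_low, scale_low).pdf(x) + (1 - w) * _trunc(loc_high, scale_high).pdf(x)


def bimodal_patch_values(
    n: int,
    minimum_at: float,
    rng: np.random.Generator,
    loc_low: float | None = None,
    scale_low: float = 0.04,
    loc_high: float | None = None,
    scale_high: float = 0.18,
) -> np.ndarray:
    """Draw n scaled-intensity-like values whose density minimum sits at ``minimum_at``.

    Components are truncated normals on [0, inf); the low-component weight is
    solved analytically so the mixture's interior valley is exactly at the
    requested point.
    """
    loc_low, scale_low, loc_high, scale_high = _mixture_params(
        minimum_at, loc_low, scale_low, loc_high, scale_high
    )
    w = mixture_low_weight(minimum_at, loc_low, scale_low, loc_high, scale_high)
    low = rng.random(n) < w
    f1, f2 = _trunc(loc_low, scale_low), _trunc(loc_high, scale_high)
    out = np.empty(n)
    out[low] = f1.rvs(size=int(low.sum()), random_state=rng)
    out[~low] = f2.rvs(size=int((~low).sum()), random_state=rng)
    return out
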