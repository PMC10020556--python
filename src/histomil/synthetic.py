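"""Synthetic slide cohort with planted morphology/genotype structure.

Real H&E whole-slide cohorts with paired genotype calls are rarely shareable,
so this module renders procedural stand-ins that preserve the statistical
structure the pipeline assumes:

* five visually distinct tissue morphologies (tumor, immune foci, stroma,
  necrosis, normal) laid out as contiguous regions on a near-white background;
* low tumor content (target median tumor area fraction 0.364);
* a slide-level binary genotype whose signal lives in tumor-region texture
  (blob length-scale differs by genotype, scaled by ``signal_strength``) with
  a secondary immune-density signal (wild-type slides receive
  ``immune_boost_wildtype`` proportionally more immune area);
* a specimen registry with configurable per-driver counts; and
* pathologist-style patch review tables with configurable planted
  associations for validating the statistics and rules-mining layer.

Everything is deterministic given the seed.  Textures are procedural
(class-specific blob size / colour / orientation statistics from filtered
noise): CPU-cheap, controllable, and seed-stable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

# ---------------------------------------------------------------------------
# morphology classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MorphologyClass:
    name: str
    index: int


MORPHOLOGY_CLASSES: tuple[MorphologyClass, ...] = (
    MorphologyClass("tumor", 0),
    MorphologyClass("immune", 1),
    MorphologyClass("stroma", 2),
    MorphologyClass("necrosis", 3),
    MorphologyClass("normal", 4),
)
CLASS_NAMES = tuple(c.name for c in MORPHOLOGY_CLASSES)
CLASS_BY_NAME = {c.name: c for c in MORPHOLOGY_CLASSES}
#: sentinel value for non-tissue pixels in morphology masks
BACKGROUND_LABEL = 255

# driver-mutation categories; EGFR is the positive (mutant) class
DRIVER_CATEGORIES = ("EGFR", "ALK", "BRAF", "ERBB2", "KRAS",
                     "MET", "RET", "ROS1", "wildtype")

#: per-driver specimen counts of the lung adenocarcinoma study cohort
STUDY_DRIVER_COUNTS: dict[str, int] = {
    "EGFR": 716, "ALK": 85, "BRAF": 93, "ERBB2": 81, "KRAS": 606,
    "MET": 76, "RET": 35, "ROS1": 18, "wildtype": 389,
}

# pathologist review vocabularies
ARCHITECTURES = ("acinar", "lepidic", "papillary", "micropapillary",
                 "mucinous", "solid")
CYTOLOGIES = ("hobnail", "columnar", "mucinous", "sarcomatoid", "anaplastic",
              "large cell", "small cell", "other")
NON_NEOPLASTIC = ("fibrosis", "pneumonia", "inflammation", "other")
NUMERIC_REVIEW_FIELDS = ("tumor_nuclei_fraction", "necrosis_fraction",
                         "peritumoral_immune_fraction",
                         "intratumoral_immune_fraction")
CATEGORICAL_REVIEW_FIELDS = {
    "predominant_architecture": ARCHITECTURES,
    "minor_architecture": ARCHITECTURES,
    "cytology": CYTOLOGIES,
    "non_neoplastic": NON_NEOPLASTIC,
}

#: default area-fraction targets; tumor matches the cohort's median tumor
#: content, the rest approximate a diverse resection with enough support in
#: every class for patch-level work at reduced slide sizes
DEFAULT_FRACTIONS: dict[str, float] = {
    "tumor": 0.364, "normal": 0.25, "stroma": 0.15,
    "immune": 0.05, "necrosis": 0.06,
}

_REGION_BLOCK = 8  # region assignment granularity in pixels


# ---------------------------------------------------------------------------
# slide spec and rendering
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSlideSpec:
    """Recipe for one synthetic slide.

    ``signal_strength`` >= 0 scales how strongly the tumor texture's blob
    length-scale encodes the genotype (0 = no signal);
    ``immune_boost_wildtype`` >= 0 controls the extra immune density signal
    of wild-type slides: their immune foci render with a ``1 + 0.35 x
    boost`` coarser texture scale at identical area, so the signal lives in
    immune-region appearance rather than slide composition or brightness.
    ``mutation_patch_size`` is only used to validate that at least a 2 x 2
    grid of mutation patches fits.
    """

    width: int = 4096
    height: int = 4096
    magnification: str = "20x"
    morphology_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FRACTIONS))
    genotype: str = "mutant"
    signal_strength: float = 1.0
    immune_boost_wildtype: float = 1.0
    seed: int = 0
    mutation_patch_size: int = 1024
    #: probability that a slide expresses the tumor-texture genotype effect
    #: at full strength; non-penetrant slides express it at one quarter.
    #: Morphological correlates of genotype are not universal across tumors,
    #: and partial penetrance is what gives bag-level models that can also
    #: read the immune-density signal an edge over tumor-only models.
    signal_penetrance: float = 0.75
    #: sd (in 8-bit intensity units) of the per-slide stain jitter: a random
    #: RGB offset and contrast scale applied to all tissue, emulating
    #: slide-to-slide staining variation; independent of genotype
    stain_jitter: float = 6.0
    #: relative sd of per-slide nuisance variation in each class's texture
    #: parameters (blob scale and contrast); emulates slide-to-slide
    #: morphology/processing variability, independent of genotype.  The
    #: tumor class receives 0.3x this sd so the planted genotype effect on
    #: tumor texture stays readable against its own nuisance.
    texture_jitter: float = 0.45

    def validate(self) -> None:
        if self.genotype not in ("mutant", "wildtype"):
            raise ValueError(f"genotype must be mutant/wildtype, got {self.genotype!r}")
        unknown = set(self.morphology_fractions) - set(CLASS_NAMES)
        if unknown:
            raise ValueError(f"unknown morphology classes: {sorted(unknown)}")
        fracs = self.morphology_fractions
        if any(f < 0 for f in fracs.values()):
            raise ValueError("morphology fractions must be non-negative")
        total = sum(fracs.values())
        if total > 1.0 + 1e-9:
            raise ValueError(
                f"morphology fractions sum to {total:.3f} > 1; the remainder "
                "of the slide is background, so fractions must sum to <= 1")
        if self.signal_strength < 0 or self.immune_boost_wildtype < 0:
            raise ValueError("signal_strength and immune_boost_wildtype must be >= 0")
        if min(self.width, self.height) < 2 * self.mutation_patch_size:
            raise ValueError(
                f"slide extent {self.width}x{self.height} must be at least "
                f"2x the mutation patch size ({self.mutation_patch_size})")
        if self.width % _REGION_BLOCK or self.height % _REGION_BLOCK:
            raise ValueError(f"slide extent must be divisible by {_REGION_BLOCK}")


@dataclass
class SyntheticSlide:
    image: np.ndarray            # (H, W, 3) uint8
    morphology_mask: np.ndarray  # (H, W) uint8; class index, 255 = background
    genotype: str
    spec: SyntheticSlideSpec
    slide_id: str = "slide"

    def realized_fractions(self) -> dict[str, float]:
        n = self.morphology_mask.size
        return {c.name: float(np.count_nonzero(self.morphology_mask == c.index)) / n
                for c in MORPHOLOGY_CLASSES}

    @property
    def is_mutant(self) -> bool:
        return self.genotype == "mutant"


def _effective_fractions(spec: SyntheticSlideSpec) -> dict[str, float]:
    return dict(spec.morphology_fractions)


def _assign_regions(spec: SyntheticSlideSpec,
                    rng: np.random.Generator) -> np.ndarray:
    """Block-level class label map; contiguous blobs hitting the target
    fractions exactly up to block rounding."""
    hb, wb = spec.height // _REGION_BLOCK, spec.width // _REGION_BLOCK
    n_blocks = hb * wb
    sigma = max(2.0, min(hb, wb) / 16.0)
    labels = np.full(n_blocks, BACKGROUND_LABEL, dtype=np.uint8)
    unassigned = np.ones(n_blocks, dtype=bool)
    fracs = _effective_fractions(spec)
    for cls in MORPHOLOGY_CLASSES:
        target = fracs.get(cls.name, 0.0)
        n_take = int(round(target * n_blocks))
        if n_take == 0:
            continue
        fld = gaussian_filter(rng.standard_normal((hb, wb)), sigma).ravel()
        fld[~unassigned] = -np.inf
        take = np.argsort(fld, kind="stable")[::-1][:min(n_take, int(unassigned.sum()))]
        labels[take] = cls.index
        unassigned[take] = False
    return labels.reshape(hb, wb)


# per-class texture parameters: (blob sigma, anisotropy, fg colour, bg colour,
# fg threshold quantile).  Colours are H&E-like; every tissue colour has HSV
# saturation comfortably above typical masking thresholds.
_TEXTURES = {
    "tumor":    (2.5, 1.0, (96, 60, 150), (205, 160, 205), 0.5),
    # immune: sparse dark lymphocyte-like dots on light ground; the overall
    # mean intensity matches the tissue mix it displaces, so immune density
    # is a texture signal, not a slide-brightness signal
    "immune":   (1.5, 1.0, (60, 60, 150), (215, 200, 225), 0.8),
    "stroma":   (1.0, 6.0, (225, 130, 165), (245, 195, 210), 0.5),
    "necrosis": (1.6, 1.0, (185, 158, 165), (215, 190, 198), 0.5),
    "normal":   (5.0, 1.0, (235, 175, 200), (248, 218, 230), 0.5),
}


def _texture(name: str, shape: tuple[int, int], rng: np.random.Generator,
             genotype: str, signal_strength: float,
             texture_jitter: float = 0.0,
             immune_boost: float = 0.0) -> np.ndarray:
    sigma, aniso, fg, bg, q = _TEXTURES[name]
    fg = np.asarray(fg, dtype=np.float32)
    bg = np.asarray(bg, dtype=np.float32)
    if name == "tumor" and signal_strength > 0:
        # genotype is encoded in the blob length-scale of the tumor texture
        direction = 1.0 if genotype == "mutant" else -1.0
        sigma = sigma * (1.0 + 0.20 * signal_strength * direction)
    if name == "immune" and genotype == "wildtype" and immune_boost > 0:
        # the immune response of wild-type slides shows as coarser, more
        # aggregated foci at identical area and dot coverage — a pure
        # texture-density signal, neutral in slide-level brightness
        sigma = sigma * (1.0 + 0.35 * immune_boost)
    if texture_jitter > 0:
        # slide-level nuisance, drawn per class per slide; damped for tumor
        # so the genotype effect dominates the tumor class's own nuisance
        tj = texture_jitter * (0.3 if name == "tumor" else 1.0)
        sigma = sigma * float(np.exp(rng.normal(0.0, tj)))
        amp = float(np.exp(rng.normal(0.0, tj)))
        mid = (fg + bg) / 2.0
        fg = mid + (fg - mid) * amp
        bg = mid + (bg - mid) * amp
    noise = rng.standard_normal(shape, dtype=np.float32)
    fld = gaussian_filter(noise, (sigma, sigma * aniso))
    sample = fld.ravel()[::7]
    lo, hi = np.quantile(sample, [0.02, 0.98])
    t = np.clip((fld - np.quantile(sample, q)) / max(hi - lo, 1e-9) * 4.0 + 0.5,
                0.0, 1.0)
    if texture_jitter > 0:
        # within-slide regional contrast variation: patches of one class on
        # one slide do not all look alike
        coarse = gaussian_filter(
            rng.standard_normal((max(shape[0] // 64, 1),
                                 max(shape[1] // 64, 1)),
                                dtype=np.float32), 1.0)
        amp_field = np.exp(0.6 * texture_jitter
                           * np.kron(coarse, np.ones((64, 64),
                                                     dtype=np.float32))
                           [:shape[0], :shape[1]])
        t = np.clip((t - 0.5) * amp_field + 0.5, 0.0, 1.0)
    img = t[..., None] * fg + (1.0 - t[..., None]) * bg
    img += (3.0 * rng.standard_normal(shape, dtype=np.float32))[..., None]
    return img


def generate_slide(spec: SyntheticSlideSpec, slide_id: str = "slide") -> SyntheticSlide:
    """Render one synthetic slide; byte-identical for identical specs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    block_labels = _assign_regions(spec, rng)
    mask = np.kron(block_labels, np.ones((_REGION_BLOCK, _REGION_BLOCK),
                                         dtype=np.uint8))
    penetrant = rng.random() < spec.signal_penetrance
    signal = spec.signal_strength * (1.0 if penetrant else 0.25)
    # near-white background so HSV saturation masking behaves as on real slides
    img = np.full((h, w, 3), (250.0, 248.0, 249.0), dtype=np.float32)
    img += (1.5 * rng.standard_normal((h, w), dtype=np.float32))[..., None]
    for cls in MORPHOLOGY_CLASSES:
        sel = mask == cls.index
        if not sel.any():
            continue
        tex = _texture(cls.name, (h, w), rng, spec.genotype,
                       signal, spec.texture_jitter,
                       spec.immune_boost_wildtype)
        img[sel] = tex[sel]
    if spec.stain_jitter > 0:
        tissue = mask != BACKGROUND_LABEL
        offset = rng.normal(0.0, spec.stain_jitter, size=3)
        contrast = float(np.exp(rng.normal(0.0, spec.stain_jitter / 120.0)))
        img[tissue] = (img[tissue] - 160.0) * contrast + 160.0 + offset
    image = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSlide(image=image, morphology_mask=mask,
                          genotype=spec.genotype, spec=spec, slide_id=slide_id)


def generate_cohort(n_mutant: int, n_wildtype: int, seed: int = 0,
                    slide_size: int = 1024, mutation_patch_size: int = 128,
                    signal_strength: float = 1.0,
                    immune_boost_wildtype: float = 1.0,
                    tumor_fraction: float = 0.364,
                    tumor_fraction_jitter: float = 0.12,
                    stain_jitter: float = 6.0,
                    signal_penetrance: float = 0.75) -> list[SyntheticSlide]:
    """Generate a cohort of slides with per-slide tumor-content variation.

    Tumor fractions are drawn symmetrically around ``tumor_fraction`` so the
    cohort median matches the target; remaining fractions keep their default
    proportions scaled to fit.
    """
    rng = np.random.default_rng(seed)
    slides = []
    genotypes = ["mutant"] * n_mutant + ["wildtype"] * n_wildtype
    for i, genotype in enumerate(genotypes):
        tf = float(np.clip(rng.normal(tumor_fraction, tumor_fraction_jitter),
                           0.12, 0.62))
        # per-slide compositional variability in the non-tumor classes
        others = {k: v * float(np.exp(rng.normal(0.0, 0.3)))
                  for k, v in DEFAULT_FRACTIONS.items() if k != "tumor"}
        budget = min(sum(others.values()), 0.95 - tf)
        scale = budget / sum(others.values())
        fracs = {"tumor": tf, **{k: v * scale for k, v in others.items()}}
        spec = SyntheticSlideSpec(
            width=slide_size, height=slide_size,
            morphology_fractions=fracs, genotype=genotype,
            signal_strength=signal_strength,
            immune_boost_wildtype=immune_boost_wildtype,
            seed=int(rng.integers(0, 2**31)),
            mutation_patch_size=mutation_patch_size,
            stain_jitter=stain_jitter,
            signal_penetrance=signal_penetrance)
        slides.append(generate_slide(spec, slide_id=f"SL{i:04d}"))
    return slides


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------


def generate_registry(counts: dict[str, int] | None = None,
                      seed: int = 0) -> pd.DataFrame:
    """Specimen registry: one row per specimen, EGFR category flagged mutant.

    Columns: ``specimen_id``, ``driver_category``, ``is_mutant``,
    ``slide_ref``.  Row order is shuffled deterministically by ``seed``.
    """
    counts = STUDY_DRIVER_COUNTS if counts is None else counts
    unknown = set(counts) - set(DRIVER_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown driver categories: {sorted(unknown)}")
    if any(v < 0 for v in counts.values()):
        raise ValueError("driver counts must be >= 0")
    cats = [cat for cat in DRIVER_CATEGORIES
            for _ in range(int(counts.get(cat, 0)))]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cats))
    rows = [{"specimen_id": f"S{i:06d}",
             "driver_category": cats[j],
             "is_mutant": cats[j] == "EGFR",
             "slide_ref": f"S{i:06d}.tiff"}
            for i, j in enumerate(order)]
    return pd.DataFrame(rows, columns=["specimen_id", "driver_category",
                                       "is_mutant", "slide_ref"])


# ---------------------------------------------------------------------------
# review tables
# ---------------------------------------------------------------------------


@dataclass
class ReviewEffects:
    """Planted associations for synthetic review tables.

    ``categorical`` maps ``(field, value)`` to a pair of probability-weight
    multipliers ``(mutant, wildtype)`` applied when sampling the bag-level
    dominant category.  ``numeric`` maps a numeric field to its group means
    ``(mutant_mean, wildtype_mean)``.  ``ReviewEffects.null()`` plants
    nothing, so every mined rule's lift converges to 1.
    """

    categorical: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=dict)
    numeric: dict[str, tuple[float, float]] = field(default_factory=dict)
    dominance: float = 0.6  # probability a patch repeats the bag's dominant category

    @classmethod
    def null(cls) -> "ReviewEffects":
        return cls()

    @classmethod
    def default(cls) -> "ReviewEffects":
        return cls(
            categorical={
                ("predominant_architecture", "solid"): (1.0, 4.0),
                ("predominant_architecture", "lepidic"): (3.0, 1.0),
                ("cytology", "hobnail"): (2.5, 1.0),
                ("non_neoplastic", "inflammation"): (1.0, 3.0),
            },
            numeric={
                "tumor_nuclei_fraction": (0.70, 0.58),
                "peritumoral_immune_fraction": (0.18, 0.35),
                "intratumoral_immune_fraction": (0.12, 0.25),
                "necrosis_fraction": (0.08, 0.10),
            },
        )


def generate_review_table(n_bags: int, patches_per_bag: int, seed: int = 0,
                          effects: ReviewEffects | None = None) -> pd.DataFrame:
    """Per-patch pathologist-style review rows with a planted predicted-status
    column; ``n_bags * patches_per_bag`` rows."""
    if patches_per_bag <= 0:
        raise ValueError("patches_per_bag must be positive")
    if n_bags <= 0:
        raise ValueError("n_bags must be positive")
    effects = ReviewEffects.default() if effects is None else effects
    rng = np.random.default_rng(seed)
    rows = []
    for b in range(n_bags):
        status = "mutant" if rng.random() < 0.5 else "wildtype"
        si = 0 if status == "mutant" else 1
        dominant = {}
        for fld, vocab in CATEGORICAL_REVIEW_FIELDS.items():
            w = np.ones(len(vocab))
            for (efld, value), mult in effects.categorical.items():
                if efld == fld and value in vocab:
                    w[vocab.index(value)] *= mult[si]
            dominant[fld] = vocab[rng.choice(len(vocab), p=w / w.sum())]
        for rank in range(patches_per_bag):
            row = {"bag_id": f"B{b:03d}", "patch_rank": rank,
                   "predicted_status": status}
            for fld, vocab in CATEGORICAL_REVIEW_FIELDS.items():
                if rng.random() < effects.dominance:
                    row[fld] = dominant[fld]
                else:
                    row[fld] = vocab[rng.integers(len(vocab))]
            for fld in NUMERIC_REVIEW_FIELDS:
                mean = effects.numeric.get(fld, (0.4, 0.4))[si]
                row[fld] = float(np.clip(rng.normal(mean, 0.15), 0.0, 1.0))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_slide(slide: SyntheticSlide, image_path, mask_path=None) -> None:
    """Write the RGB image (TIFF or PNG by extension) and, optionally, the
    morphology mask as single-channel PNG (pixel value = class index,
    255 = background)."""
    from PIL import Image

    path = str(image_path)
    if path.endswith((".tif", ".tiff")):
        import tifffile
        tifffile.imwrite(path, slide.image)
    else:
        Image.fromarray(slide.image).save(path)
    if mask_path is not None:
        Image.fromarray(slide.morphology_mask, mode="L").save(str(mask_path))


def spec_to_dict(spec: SyntheticSlideSpec) -> dict:
    return dataclasses.asdict(spec)
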