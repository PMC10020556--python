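"""Tissue masking and grid patch extraction.

Slides are masked on a down-sampled copy (HSV saturation thresholding
followed by small-object removal and small-hole filling), then square
patches are taken exhaustively from a non-overlapping grid anchored at
(0, 0), 0-based and row-major with half-open extents.  A patch is kept when
the fraction of tissue-mask pixels under its footprint reaches
``min_tissue_fraction`` (default 0.2, the mutation-model criterion); no
further selection is applied.  Patches for morphology training instead
require ``min_region_fraction`` (default 0.75) of their area inside a single
annotated region.

Two geometric adapters reconcile patch sizes with model input sizes:
``center_crop_resize`` (1024 -> central 512 -> 448, whose classification is
propagated to the whole 1024 px patch) and ``resize_for_mil``
(1024 -> 224, full frame).  Both default to the full-scale geometry but take
explicit sizes so reduced desk-scale grids use the same code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv
from skimage.morphology import remove_small_holes, remove_small_objects
from skimage.transform import resize as _sk_resize

from .synthetic import CLASS_BY_NAME, MORPHOLOGY_CLASSES

MANIFEST_COLUMNS = ["slide_id", "row", "col", "size", "tissue_fraction",
                    "annotation_fraction", "morphology_call"]


@dataclass
class TissueMask:
    mask: np.ndarray  # 2-D bool at 1/downsample scale
    downsample: int

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("tissue mask must be 2-D")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")

    def full_res(self, shape: tuple[int, int]) -> np.ndarray:
        """Nearest upsampling back to slide resolution, cropped to ``shape``."""
        ds = self.downsample
        big = np.kron(self.mask, np.ones((ds, ds), dtype=bool))
        return big[:shape[0], :shape[1]]


@dataclass
class PatchManifest:
    """Ordered patch records plus the extraction parameters that made them."""

    df: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in MANIFEST_COLUMNS:
            if col not in self.df.columns:
                self.df[col] = np.nan
        self.df = self.df[MANIFEST_COLUMNS].reset_index(drop=True)
        dup = self.df.duplicated(subset=["slide_id", "row", "col"])
        if dup.any():
            raise ValueError("duplicate patch origins in manifest")

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, params: dict | None = None) -> "PatchManifest":
        return cls(pd.read_csv(path), params or {})


def _validate_rgb(slide: np.ndarray) -> np.ndarray:
    slide = np.asarray(slide)
    if slide.ndim != 3 or slide.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) array, got shape {slide.shape}")
    return slide


def tissue_mask(slide: np.ndarray, downsample: int = 16,
                saturation_threshold: float = 0.07,
                min_object_px: int = 64, min_hole_px: int = 64) -> TissueMask:
    """HSV-saturation tissue mask computed on a block-mean downsampled slide.

    White background has saturation ~0 and is rejected; stained tissue
    saturates well above the default 0.07 threshold.  Objects smaller than
    ``min_object_px`` (at mask scale) are removed and holes smaller than
    ``min_hole_px`` filled.
    """
    slide = _validate_rgb(slide)
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    h, w = slide.shape[:2]
    ds = downsample
    ph, pw = -h % ds, -w % ds
    small = slide.astype(float)
    if ph or pw:  # pad with white so padding reads as background
        small = np.pad(small, ((0, ph), (0, pw), (0, 0)),
                       constant_values=255.0)
    hb, wb = small.shape[0] // ds, small.shape[1] // ds
    small = small.reshape(hb, ds, wb, ds, 3).mean(axis=(1, 3))
    sat = rgb2hsv(small / 255.0)[..., 1]
    mask = sat > saturation_threshold
    if min_object_px > 1:
        mask = remove_small_objects(mask, max_size=min_object_px - 1)
    if min_hole_px > 1:
        mask = remove_small_holes(mask, max_size=min_hole_px - 1)
    return TissueMask(mask=mask, downsample=ds)


def _grid_fractions(binary: np.ndarray, size: int) -> np.ndarray:
    """Per-cell mean of ``binary`` over the non-overlapping ``size`` grid."""
    nr, nc = binary.shape[0] // size, binary.shape[1] // size
    view = binary[:nr * size, :nc * size].astype(float)
    return view.reshape(nr, size, nc, size).mean(axis=(1, 3))


def extract_patches(slide, mask: TissueMask, size: int = 1024,
                    min_tissue_fraction: float = 0.2,
                    slide_id: str = "slide") -> PatchManifest:
    """Exhaustive non-overlapping grid extraction filtered by tissue fraction."""
    if not 0.0 <= min_tissue_fraction <= 1.0:
        raise ValueError("min_tissue_fraction must be in [0, 1]")
    if isinstance(slide, np.ndarray):
        shape = slide.shape[:2]
    else:
        shape = tuple(slide)
    params = {"size": size, "min_tissue_fraction": min_tissue_fraction,
              "downsample": mask.downsample}
    if size > min(shape):
        warnings.warn(f"patch size {size} exceeds slide extent {shape}; "
                      "empty manifest")
        return PatchManifest(pd.DataFrame(columns=MANIFEST_COLUMNS), params)
    tissue = mask.full_res(shape)
    fractions = _grid_fractions(tissue, size)
    rows = []
    for i in range(fractions.shape[0]):
        for j in range(fractions.shape[1]):
            tf = float(fractions[i, j])
            if tf >= min_tissue_fraction:
                rows.append({"slide_id": slide_id, "row": i * size,
                             "col": j * size, "size": size,
                             "tissue_fraction": tf})
    return PatchManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS[:5]), params)


def extract_annotation_patches(region_masks, size: int = 512,
                               min_region_fraction: float = 0.75,
                               slide_id: str = "slide",
                               precedence: list[str] | None = None) -> PatchManifest:
    """Labelled grid patches for morphology training.

    ``region_masks`` is either a labelled morphology mask (class index per
    pixel, background sentinel) or a mapping class name -> boolean mask.
    A patch is labelled with a class when at least ``min_region_fraction`` of
    its pixels fall inside that class's annotated region.  Overlapping
    annotations are rejected unless a ``precedence`` order is declared.
    """
    if isinstance(region_masks, np.ndarray):
        labelled = np.asarray(region_masks)
        masks = {c.name: labelled == c.index for c in MORPHOLOGY_CLASSES}
    else:
        masks = {name: np.asarray(m, dtype=bool)
                 for name, m in region_masks.items()}
        unknown = set(masks) - set(CLASS_BY_NAME)
        if unknown:
            raise ValueError(f"unknown morphology classes: {sorted(unknown)}")
        overlap = sum(m.astype(int) for m in masks.values()) > 1
        if overlap.any():
            if precedence is None:
                raise ValueError("overlapping annotations require a declared "
                                 "precedence order")
            claimed = np.zeros(overlap.shape, dtype=bool)
            for name in precedence:
                masks[name] = masks[name] & ~claimed
                claimed |= masks[name]
    shape = next(iter(masks.values())).shape
    params = {"size": size, "min_region_fraction": min_region_fraction}
    if size > min(shape):
        warnings.warn("patch size exceeds annotation extent; empty manifest")
        return PatchManifest(pd.DataFrame(columns=MANIFEST_COLUMNS), params)
    per_class = {name: _grid_fractions(m, size) for name, m in masks.items()}
    rows = []
    nr, nc = next(iter(per_class.values())).shape
    for i in range(nr):
        for j in range(nc):
            for name in sorted(per_class):
                frac = float(per_class[name][i, j])
                if frac >= min_region_fraction:
                    rows.append({"slide_id": slide_id, "row": i * size,
                                 "col": j * size, "size": size,
                                 "annotation_fraction": frac,
                                 "morphology_call": name})
                    break  # fractions are exclusive above 0.5
    df = pd.DataFrame(rows, columns=["slide_id", "row", "col", "size",
                                     "annotation_fraction", "morphology_call"])
    return PatchManifest(df, params)


def get_patch(slide: np.ndarray, record) -> np.ndarray:
    """Crop the pixels of one manifest record from the slide."""
    r, c, s = int(record["row"]), int(record["col"]), int(record["size"])
    return slide[r:r + s, c:c + s]


def _resize(img: np.ndarray, out_size: int) -> np.ndarray:
    out = _sk_resize(img.astype(float), (out_size, out_size),
                     order=1, preserve_range=True, anti_aliasing=None)
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def center_crop_resize(patch: np.ndarray, in_size: int = 1024,
                       crop_size: int = 512, out_size: int = 448) -> np.ndarray:
    """Central ``crop_size`` window of an ``in_size`` patch, bilinearly
    resized to ``out_size`` (default 1024 -> 512 -> 448).

    The morphology call made on this crop is propagated to the whole patch
    by the profiling step.
    """
    patch = _validate_rgb(patch)
    if patch.shape[:2] != (in_size, in_size):
        raise ValueError(f"expected a {in_size}x{in_size} patch, got "
                         f"{patch.shape[:2]}")
    off = (in_size - crop_size) // 2
    crop = patch[off:off + crop_size, off:off + crop_size]
    return _resize(crop, out_size)


def resize_for_mil(patch: np.ndarray, in_size: int = 1024,
                   out_size: int = 224) -> np.ndarray:
    """Full-frame bilinear resize (default 1024 -> 224), no crop."""
    patch = _validate_rgb(patch)
    if patch.shape[:2] != (in_size, in_size):
        raise ValueError(f"expected a {in_size}x{in_size} patch, got "
                         f"{patch.shape[:2]}")
    return _resize(patch, out_size)
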