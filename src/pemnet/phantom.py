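"""Synthetic mammography phantoms with exact ground-truth masks.

An MLO-view phantom is a dark background, a bright breast half-ellipse
anchored to one lateral (chest-wall) edge, and a brighter triangular
pectoral wedge in the top corner on that side.  The wedge boundary is a
quadratic Bezier between its top-edge and chest-wall anchor points, so a
curvature of 0 gives a straight muscle boundary and positive values bow it
outward into the breast.  CC-view phantoms lack the wedge.  Optional bright
artefact disks sit in the non-breast margin (mimicking acquisition
artefacts and labels) and Gaussian mass-like blobs sit inside the breast.

Noise is added after the geometry, so the stored masks are exact; with a
fixed seed, regeneration is byte-identical.  A ``side='right'`` phantom is
the exact horizontal mirror of the ``side='left'`` phantom with the same
seed (all randomness is drawn in the left-oriented frame).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import binary_dilation
from skimage.draw import disk as draw_disk
from skimage.morphology import disk as disk_footprint

__all__ = ["PhantomSpec", "LabeledImage", "generate_phantom", "generate_dataset",
           "save_dataset", "load_dataset"]

SIDES = ("left", "right")
VIEWS = ("MLO", "CC")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and noise parameters of one phantom.

    Default intensities keep the contrast ordering observed in MLO
    mammograms: background < breast tissue < pectoral muscle.
    """

    width: int = 256
    height: int = 256
    side: str = "left"
    view: str = "MLO"
    breast_axes: tuple[float, float] | None = None  # (semi-width, semi-height) px
    pectoral_base: float = 0.45    # fraction of height along the chest wall
    pectoral_reach: float = 0.30   # fraction of width along the top edge
    boundary_curvature: float = 0.0
    intensity_bg: float = 6.0
    intensity_breast: float = 120.0
    intensity_pectoral: float = 190.0
    noise_sigma: float = 5.0
    n_artefacts: int = 0
    n_masses: int = 0
    margin: int = 8
    seed: int = 0

    def resolved_axes(self) -> tuple[float, float]:
        if self.breast_axes is not None:
            return tuple(self.breast_axes)
        return (0.55 * self.width, 0.42 * self.height)

    def validate(self):
        if self.width < 32 or self.height < 32:
            raise ValueError(f"width/height must be >= 32, got {self.width}x{self.height}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        for name in ("pectoral_base", "pectoral_reach"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("intensity_bg", "intensity_breast", "intensity_pectoral"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_artefacts < 0 or self.n_masses < 0:
            raise ValueError("n_artefacts and n_masses must be >= 0")
        if self.margin < 0:
            raise ValueError(f"margin must be >= 0, got {self.margin}")
        a, b = self.resolved_axes()
        if a <= 0 or b <= 0:
            raise ValueError(f"breast_axes must be positive, got {(a, b)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["breast_axes"] is not None:
            d["breast_axes"] = list(d["breast_axes"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if d.get("breast_axes") is not None:
            d["breast_axes"] = tuple(d["breast_axes"])
        return cls(**d)


@dataclass
class LabeledImage:
    """An 8-bit phantom with its exact pectoral and breast masks."""

    image: np.ndarray          # (H, W) uint8
    pectoral_mask: np.ndarray  # (H, W) uint8 in {0, 1}
    breast_mask: np.ndarray    # (H, W) uint8 in {0, 1}; breast includes pectoral
    meta: PhantomSpec

    def validate(self):
        if not (self.image.shape == self.pectoral_mask.shape == self.breast_mask.shape):
            raise ValueError("image and mask dimensions disagree")
        for name in ("pectoral_mask", "breast_mask"):
            m = getattr(self, name)
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} is not {{0,1}}-valued")
        if np.any(self.pectoral_mask & ~self.breast_mask.astype(bool)):
            raise ValueError("pectoral_mask is not a subset of breast_mask")


def pectoral_boundary(spec: PhantomSpec, n_bezier: int = 2048):
    """Wedge boundary (the bowed hypotenuse) in the left frame.

    Returns (rows, cols) sampled along the quadratic Bezier running from
    the top-edge anchor (0, reach*W) to the chest-wall anchor (base*H, 0).
    The control point sits on the chord midpoint, displaced along the
    outward normal by ``boundary_curvature`` times the chord length, so
    curvature 0 is a straight muscle boundary and positive values bow it
    into the breast.
    """
    base = spec.pectoral_base * spec.height
    reach = spec.pectoral_reach * spec.width
    p0 = np.array([0.0, reach])   # on the top edge
    p1 = np.array([base, 0.0])    # on the chest-wall edge
    chord = p1 - p0
    length = float(np.hypot(*chord))
    # normal pointing away from the image corner -> positive curvature bows outward
    normal = np.array([chord[1], -chord[0]])
    normal = -normal / np.linalg.norm(normal)
    ctrl = (p0 + p1) / 2 + spec.boundary_curvature * length * normal
    t = np.linspace(0.0, 1.0, n_bezier)[:, None]
    bez = (1 - t) ** 2 * p0 + 2 * t * (1 - t) * ctrl + t ** 2 * p1
    return bez[:, 0], bez[:, 1]


def _rasterize_wedge(spec: PhantomSpec) -> np.ndarray:
    """Area-faithful wedge fill: per image row, fill the columns up to the
    rounded horizontal extent of the Bezier boundary at that row."""
    h, w = spec.height, spec.width
    mask = np.zeros((h, w), dtype=bool)
    base = spec.pectoral_base * h
    if base <= 0 or spec.pectoral_reach <= 0:
        return mask
    brow, bcol = pectoral_boundary(spec)
    order = np.argsort(brow)
    rows = np.arange(min(h, int(np.ceil(base))))
    cmax = np.interp(rows, brow[order], bcol[order])
    ncols = np.clip(np.rint(cmax).astype(int), 0, w)
    mask[rows, :] = np.arange(w)[None, :] < ncols[:, None]
    return mask


def generate_phantom(spec: PhantomSpec) -> LabeledImage:
    """Render one phantom; see the module docstring for the geometry."""
    spec.validate()
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)

    # --- geometry, built in the left-oriented frame
    a, b = spec.resolved_axes()
    cy = 0.5 * h
    rows, cols = np.mgrid[0:h, 0:w]
    breast = (cols / a) ** 2 + ((rows - cy) / b) ** 2 <= 1.0

    pectoral = np.zeros((h, w), dtype=bool)
    if spec.view == "MLO":
        pectoral = _rasterize_wedge(spec)

    # empty border on the non-chest side and bottom; the chest wall and the
    # top corner stay anchored to the image edge as in real MLO crops
    if spec.margin:
        breast[:, w - spec.margin:] = False
        breast[h - spec.margin:, :] = False
        pectoral[:, w - spec.margin:] = False
        pectoral[h - spec.margin:, :] = False

    breast_total = breast | pectoral

    image = np.full((h, w), spec.intensity_bg, dtype=np.float64)
    image[breast] = spec.intensity_breast
    image[pectoral] = spec.intensity_pectoral

    # --- mass-like blobs inside the breast (image only; masks stay geometric)
    breast_only = breast_total & ~pectoral
    if spec.n_masses and breast_only.any():
        flat = np.flatnonzero(breast_only)
        for _ in range(spec.n_masses):
            centre = np.unravel_index(rng.choice(flat), (h, w))
            sigma = rng.uniform(3.0, 8.0)
            amp = rng.uniform(30.0, 60.0)
            blob = amp * np.exp(-((rows - centre[0]) ** 2 + (cols - centre[1]) ** 2)
                                / (2 * sigma ** 2))
            image += blob * breast_only

    # --- bright artefact disks in the non-breast margin
    if spec.n_artefacts:
        keep_out = binary_dilation(breast_total, disk_footprint(6))
        for _ in range(spec.n_artefacts):
            radius = int(rng.integers(1, 5))
            for _try in range(100):
                r0 = int(rng.integers(radius, h - radius))
                c0 = int(rng.integers(radius, w - radius))
                if not keep_out[r0, c0]:
                    rr, cc = draw_disk((r0, c0), radius, shape=(h, w))
                    image[rr, cc] = 230.0
                    break

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    pectoral_u8 = pectoral.astype(np.uint8)
    breast_u8 = breast_total.astype(np.uint8)
    if spec.side == "right":
        image = image[:, ::-1].copy()
        pectoral_u8 = pectoral_u8[:, ::-1].copy()
        breast_u8 = breast_u8[:, ::-1].copy()

    out = LabeledImage(image=image, pectoral_mask=pectoral_u8,
                       breast_mask=breast_u8, meta=spec)
    out.validate()
    return out


# --------------------------------------------------------------------- dataset
_INT_FIELDS = {"width", "height", "n_artefacts", "n_masses", "margin"}
_CHOICE_FIELDS = {"side", "view"}

#: Default per-field variability for MLO segmentation datasets: both
#: lateralities, wedge size/shape spanning small to large muscles, straight
#: to clearly curved boundaries, moderate contrast variation and mild noise.
DEFAULT_MLO_RANGES = {
    "side": ["left", "right"],
    "pectoral_base": (0.30, 0.55),
    "pectoral_reach": (0.20, 0.45),
    "boundary_curvature": (-0.10, 0.20),
    "intensity_breast": (100.0, 140.0),
    "intensity_pectoral": (170.0, 210.0),
    "noise_sigma": (3.0, 8.0),
    "n_masses": (0, 2),
    "n_artefacts": (0, 3),
}

#: View-classification datasets draw MLO and CC views with equal probability.
DEFAULT_VIEW_RANGES = {**DEFAULT_MLO_RANGES, "view": ["MLO", "CC"]}


def _draw_field(name: str, spec_range, rng: np.random.Generator):
    if name in _CHOICE_FIELDS:
        options = list(spec_range)
        if not options:
            raise ValueError(f"empty choice list for field {name!r}")
        return options[int(rng.integers(len(options)))]
    lo, hi = spec_range
    if lo > hi:
        raise ValueError(f"empty range for field {name!r}: ({lo}, {hi})")
    if name in _INT_FIELDS:
        return int(rng.integers(int(lo), int(hi) + 1))
    return float(rng.uniform(lo, hi))


def generate_dataset(n: int, spec_ranges: dict | None = None, seed: int = 0,
                     base_spec: PhantomSpec | None = None):
    """Draw ``n`` phantoms with per-field values sampled from ``spec_ranges``.

    ``spec_ranges`` maps PhantomSpec field names to (min, max) ranges, or to
    an option list for the categorical fields ``side`` and ``view``.  Fields
    not listed keep the value from ``base_spec``.  Returns
    ``(samples, manifest)`` where the manifest records every realised spec;
    the draw is fully determined by ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    spec_ranges = spec_ranges or {}
    base_spec = base_spec or PhantomSpec()
    valid = {f.name for f in dataclasses.fields(PhantomSpec)}
    unknown = set(spec_ranges) - valid
    if unknown:
        raise ValueError(f"unknown PhantomSpec fields in ranges: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    samples, manifest = [], []
    for _ in range(n):
        overrides = {name: _draw_field(name, rg, rng)
                     for name, rg in sorted(spec_ranges.items())}
        overrides["seed"] = int(rng.integers(2 ** 31))
        spec = dataclasses.replace(base_spec, **overrides)
        samples.append(generate_phantom(spec))
        manifest.append(spec.to_dict())
    return samples, manifest


def _write_mask(path: Path, mask: np.ndarray, scale255: bool):
    arr = (mask * 255).astype(np.uint8) if scale255 else mask.astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def save_dataset(samples, manifest, out_dir, scale255: bool = False):
    """Write images/masks as 8-bit grayscale PNG plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        stem = f"phantom_{i:04d}"
        Image.fromarray(s.image, mode="L").save(out / f"{stem}.png")
        _write_mask(out / f"{stem}_pectoral.png", s.pectoral_mask, scale255)
        _write_mask(out / f"{stem}_breast.png", s.breast_mask, scale255)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def load_dataset(in_dir):
    """Re-read a saved dataset (masks are re-binarised on load)."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    samples = []
    for i, meta in enumerate(manifest):
        stem = f"phantom_{i:04d}"
        image = np.asarray(Image.open(src / f"{stem}.png"))
        pect = (np.asarray(Image.open(src / f"{stem}_pectoral.png")) > 0).astype(np.uint8)
        breast = (np.asarray(Image.open(src / f"{stem}_breast.png")) > 0).astype(np.uint8)
        samples.append(LabeledImage(image=image, pectoral_mask=pect,
                                    breast_mask=breast,
                                    meta=PhantomSpec.from_dict(meta)))
    return samples, manifest
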