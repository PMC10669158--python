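"""Procedural single-leaf images with ground-truth masks and disease overlays.

Emulates the controlled-capture setting of curated leaf datasets: one leaf
per image on a uniform bright background, healthy vs. diseased classes
distinguished by stylized symptom overlays (rings, spots, edge necrosis,
mottle, yellowing), with exact instance masks and class-imbalanced dataset
assembly.  The renderers are stylized, not photorealistic — their job is to
give every other module a seeded, measurable target distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .masks import INSTANCE_MARKS_1, BinaryMask
from .schedule import ConfigurationError

__all__ = [
    "LeafSpec",
    "DiseaseStyle",
    "DISEASE_STYLES",
    "DatasetManifest",
    "generate_leaf",
    "apply_disease",
    "generate_dataset",
    "demo_class_table",
]

DISEASE_STYLES = (
    "concentric-ring-blight",
    "dark-spot",
    "edge-blight",
    "mosaic-mottle",
    "curl-yellowing-tint",
)


@dataclass(frozen=True)
class LeafSpec:
    """Shape and palette parameters of a procedural leaf.

    Axes are fractions of the raster; occupancy must land in [0.2, 0.8].
    """

    size: int = 64
    axis_major: float = 0.38
    axis_minor: float = 0.27
    tip_taper: float = 0.25
    margin_noise: float = 0.06
    venation: float = 0.5
    leaf_color: tuple[float, float, float] = (0.18, 0.46, 0.14)
    background_color: tuple[float, float, float] = (0.84, 0.82, 0.78)
    color_jitter: float = 0.04


@dataclass(frozen=True)
class DiseaseStyle:
    """A stylized symptom class.

    ``intensity`` in [0, 1] scales symptom count and blend strength;
    ``edge_bias`` in [0, 1] weights placement toward the leaf boundary
    band (1 confines all changed pixels to the band).
    """

    style: str = "dark-spot"
    intensity: float = 0.6
    max_spots: int = 8
    spot_radius_frac: tuple[float, float] = (0.04, 0.10)
    edge_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.style not in DISEASE_STYLES:
            raise ConfigurationError(
                f"unknown disease style {self.style!r}; choose from {DISEASE_STYLES}"
            )
        if not 0.0 <= self.intensity <= 1.0:
            raise ConfigurationError("intensity must be in [0, 1]")
        if not 0.0 <= self.edge_bias <= 1.0:
            raise ConfigurationError("edge_bias must be in [0, 1]")


def generate_leaf(
    spec: LeafSpec, rng: np.random.Generator
) -> tuple[np.ndarray, BinaryMask]:
    """Render a healthy leaf and its exact instance mask.

    The contour is a star-shaped polar curve (ellipse radius modulated by
    a short Fourier series plus a tip taper), so it cannot self-intersect.
    """
    n = spec.size
    yy, xx = np.mgrid[0:n, 0:n]
    cy = cx = (n - 1) / 2.0
    dy, dx = (yy - cy) / n, (xx - cx) / n
    theta = np.arctan2(dy, dx)
    r = np.hypot(dy, dx)
    a, b = spec.axis_major, spec.axis_minor
    base = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        ck, sk = rng.normal(0, 1, 2)
        wobble += ck * np.cos(k * theta) + sk * np.sin(k * theta)
    radius = base * (1.0 + spec.margin_noise * wobble / 4.0)
    radius *= 1.0 - spec.tip_taper * 0.3 * (1.0 + np.cos(theta)) / 2.0
    grid = (r <= radius).astype(np.uint8)
    occupancy = grid.mean()
    if not 0.2 <= occupancy <= 0.8:
        raise ConfigurationError(
            f"leaf occupies {occupancy:.2f} of the raster, outside [0.2, 0.8]"
        )
    mask = BinaryMask(grid, INSTANCE_MARKS_1)

    img = np.empty((n, n, 3))
    img[:] = spec.background_color
    leaf_rgb = np.array(spec.leaf_color) + rng.normal(0, spec.color_jitter, 3)
    leaf = np.broadcast_to(leaf_rgb, (n, n, 3)).copy()
    # venation: a darker midrib plus oblique secondary veins
    vein = np.exp(-((dy * n / 1.5) ** 2)) + 0.6 * (
        np.abs(np.sin(dx * n * 0.9 + dy * n * 1.7)) < 0.12
    )
    leaf -= spec.venation * 0.08 * np.clip(vein, 0, 1)[..., None]
    leaf += rng.normal(0, 0.015, leaf.shape)  # mild texture
    sel = grid.astype(bool)
    img[sel] = leaf[sel]
    return np.clip(img, 0.0, 1.0), mask


def _boundary_band(mask: BinaryMask, band_frac: float = 0.2) -> np.ndarray:
    """Leaf pixels within a band of the contour (distance-transform based)."""
    inside = mask.grid.astype(bool)
    dist = ndimage.distance_transform_edt(inside)
    width = max(1.0, band_frac * np.sqrt(mask.area() / np.pi))
    return inside & (dist <= width)


def apply_disease(
    image: np.ndarray,
    mask: BinaryMask,
    style: DiseaseStyle,
    rng: np.random.Generator,
) -> np.ndarray:
    """Overlay stylized symptoms; only leaf pixels may change.

    Candidate symptom sites are pre-drawn once, so raising intensity with
    the same seed renders a superset of the same symptoms (the changed
    pixel count is monotone in intensity).
    """
    mask.require(INSTANCE_MARKS_1)
    image = np.asarray(image, dtype=np.float64)
    n = image.shape[0]
    inside = mask.grid.astype(bool)
    band = _boundary_band(mask)
    allowed = (band if style.edge_bias >= 1.0 else inside)
    out = image.copy()
    alpha = 0.85 * style.intensity

    # pre-draw all candidate spot sites (used for spot-like styles)
    ys, xs = np.nonzero(inside)
    band_flags = band[ys, xs].astype(np.float64)
    w = (1.0 - style.edge_bias) + style.edge_bias * band_flags
    if w.sum() == 0:
        return out
    w = w / w.sum()
    order = rng.choice(len(ys), size=min(style.max_spots, len(ys)), replace=False, p=w)
    radii = rng.uniform(*style.spot_radius_frac, size=len(order)) * n
    n_active = int(np.ceil(style.intensity * len(order)))
    if style.intensity == 0.0 or n_active == 0:
        return out

    yy, xx = np.mgrid[0:n, 0:n]
    overlay = np.zeros(image.shape[:2])
    if style.style in ("dark-spot", "concentric-ring-blight", "mosaic-mottle"):
        for i in range(n_active):
            cy, cx, rad = ys[order[i]], xs[order[i]], radii[i]
            d = np.hypot(yy - cy, xx - cx)
            blob = np.clip(1.0 - d / rad, 0.0, 1.0)
            if style.style == "concentric-ring-blight":
                blob *= 0.55 + 0.45 * np.cos(d / rad * 3 * np.pi) ** 2
            overlay = np.maximum(overlay, blob)
        tint = {
            "dark-spot": (0.22, 0.13, 0.06),
            "concentric-ring-blight": (0.35, 0.22, 0.08),
            "mosaic-mottle": (0.75, 0.72, 0.25),
        }[style.style]
    elif style.style == "edge-blight":
        noise = ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.5)
        overlay = band.astype(float) * np.clip(0.6 + noise, 0.0, 1.0)
        tint = (0.42, 0.27, 0.10)
        allowed = band
    else:  # curl-yellowing-tint: whole-leaf discoloration
        overlay = inside.astype(float)
        tint = (0.72, 0.70, 0.22)
        alpha = 0.5 * style.intensity
    overlay = overlay * allowed
    blend = (alpha * overlay)[..., None]
    out = out * (1.0 - blend) + np.asarray(tint) * blend
    changed = allowed
    out = np.where(changed[..., None], out, image)
    return np.clip(out, 0.0, 1.0)


@dataclass
class DatasetManifest:
    """What a generated dataset contains; round-trips through JSON."""

    seed: int
    size: int
    classes: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"seed": self.seed, "size": self.size, "classes": self.classes},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        obj = json.loads(text)
        return cls(seed=obj["seed"], size=obj["size"], classes=obj["classes"])


def demo_class_table(scale: int = 10) -> dict[str, dict]:
    """Imbalanced class counts echoing a curated tomato subset (10:8:...:1).

    ``scale=10`` gives counts 10, 8, 7, 6, 5, 4, 3, 2, 1 across the nine
    disease styles/variants plus 12 healthy.
    """
    diseases = [
        ("late-blight", "dark-spot", 10),
        ("early-blight", "concentric-ring-blight", 8),
        ("septoria-spot", "dark-spot", 7),
        ("target-spot", "concentric-ring-blight", 6),
        ("mosaic-virus", "mosaic-mottle", 5),
        ("yellow-curl", "curl-yellowing-tint", 4),
        ("spider-mites", "mosaic-mottle", 3),
        ("leaf-mold", "edge-blight", 2),
        ("bacterial-spot", "dark-spot", 1),
    ]
    table = {"healthy": {"count": round(1.2 * scale), "style": None}}
    for name, style, units in diseases:
        table[name] = {"count": round(units * scale / 10), "style": style}
    return table


def generate_dataset(
    classes: dict[str, dict],
    out_dir: str | Path,
    rng: np.random.Generator,
    spec: LeafSpec = LeafSpec(),
    paired_domains: tuple[str, str] | None = None,
) -> DatasetManifest:
    """Emit image/mask PNG pairs per class plus a JSON manifest.

    ``classes`` maps class name -> {"count": int, "style": style-name or
    None for healthy, optional "intensity"/"edge_bias"}.  Zero-count
    classes are skipped with a notice.  ``paired_domains=(healthy_cls,
    disease_cls)`` additionally emits the domainX/domainX_masks/domainY/
    domainY_masks layout used for translation training.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(rng.integers(2**31))
    manifest = DatasetManifest(seed=seed, size=spec.size)
    master = np.random.default_rng(seed)
    for name, cfg in classes.items():
        count = int(cfg.get("count", 0))
        if count < 0:
            raise ConfigurationError(f"negative count for class {name!r}")
        if count == 0:
            print(f"[leafdiffuse] class {name!r} has count 0; omitted from manifest")
            continue
        style = None
        if cfg.get("style"):
            style = DiseaseStyle(
                style=cfg["style"],
                intensity=float(cfg.get("intensity", 0.6)),
                edge_bias=float(cfg.get("edge_bias", 0.0)),
            )
        img_dir = out / "images" / name
        msk_dir = out / "masks" / name
        img_dir.mkdir(parents=True, exist_ok=True)
        msk_dir.mkdir(parents=True, exist_ok=True)
        files = []
        for i in range(count):
            sub = np.random.default_rng(master.integers(2**31))
            image, mask = generate_leaf(spec, sub)
            if style is not None:
                image = apply_disease(image, mask, style, sub)
            img_path = img_dir / f"{name}_{i:04d}.png"
            msk_path = msk_dir / f"{name}_{i:04d}.png"
            iio.imwrite(img_path, (image * 255).round().astype(np.uint8))
            iio.imwrite(msk_path, (mask.grid * 255).astype(np.uint8))
            files.append(
                {"image": str(img_path.relative_to(out)), "mask": str(msk_path.relative_to(out))}
            )
        manifest.classes[name] = {
            "count": count,
            "style": cfg.get("style"),
            "files": files,
        }
    if paired_domains is not None:
        x_cls, y_cls = paired_domains
        for domain, cls in (("domainX", x_cls), ("domainY", y_cls)):
            if cls not in manifest.classes:
                raise ConfigurationError(f"paired domain class {cls!r} was not generated")
            d_img = out / domain
            d_msk = out / f"{domain}_masks"
            d_img.mkdir(exist_ok=True)
            d_msk.mkdir(exist_ok=True)
            for i, f in enumerate(manifest.classes[cls]["files"]):
                for src, dst in ((f["image"], d_img), (f["mask"], d_msk)):
                    data = (out / src).read_bytes()
                    (dst / f"pair_{i:04d}.png").write_bytes(data)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
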