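"""Synthetic fundus-like images with exact ground-truth disc/cup geometry.

Each image is a dark retina background carrying a bright elliptical optic
disc that contains a still-brighter elliptical cup, crossed by dark
vessel-like curvilinear strokes, with additive Gaussian noise. The disc and
cup masks are exact rasterizations of the generating ellipses (a pixel is
foreground iff its centre satisfies the ellipse inequality), so every
downstream quantity — vertical diameters, areas, radius profiles — has a
known geometric truth. Vessels and noise perturb only the RGB image, never
the masks, mirroring how human annotations ignore vessels crossing the disc.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SyntheticSpec", "LabeledFundus", "SpecSampler",
    "generate_fundus", "generate_dataset", "save_fundus", "load_fundus",
]


@dataclass
class SyntheticSpec:
    """Generating parameters for one synthetic fundus image.

    ``cup_to_disc_factor`` scales the disc semi-axes to give the cup
    semi-axes, so for a centred cup it is (up to pixelization) the vertical
    cup-to-disc diameter ratio. ``cup_center_offset`` displaces the cup
    centre from the disc centre; it is clamped so the cup stays inside the
    disc.
    """

    image_size: int = 256
    disc_center: tuple[float, float] = (128.0, 128.0)  # (row, col)
    disc_semi_axes: tuple[float, float] = (60.0, 55.0)  # (vertical, horizontal)
    cup_to_disc_factor: float = 0.5
    cup_center_offset: tuple[float, float] = (0.0, 0.0)
    disc_rotation: float = 0.0  # degrees, counter-clockwise
    vessel_count: int = 4
    noise_sigma: float = 8.0
    background_level: tuple[int, int, int] = (120, 45, 25)
    disc_level: tuple[int, int, int] = (225, 160, 90)
    cup_level: tuple[int, int, int] = (250, 215, 150)
    margin: int = 4
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.cup_to_disc_factor <= 1.0:
            raise ValueError("cup_to_disc_factor must lie in (0, 1]")
        a, b = self.disc_semi_axes
        if a <= 0 or b <= 0:
            raise ValueError("disc semi-axes must be positive")
        r, c = self.disc_center
        reach = max(a, b)
        s = self.image_size
        if (r - reach < self.margin or c - reach < self.margin
                or r + reach > s - self.margin or c + reach > s - self.margin):
            raise ValueError("disc does not fit inside the image with the margin")


@dataclass
class LabeledFundus:
    """An RGB image with optional binary disc/cup ground-truth masks."""

    image: np.ndarray               # (H, W, 3) uint8
    disc_mask: np.ndarray | None    # (H, W) bool
    cup_mask: np.ndarray | None     # (H, W) bool
    meta: dict = field(default_factory=dict)


def _ellipse_mask(size: int, center, semi_axes, rotation_deg: float) -> np.ndarray:
    """Pixel-centre rasterization of a rotated ellipse."""
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    dr, dc = rr - center[0], cc - center[1]
    th = np.deg2rad(rotation_deg)
    # rotate coordinates into the ellipse frame (vertical axis = semi_axes[0])
    u = dr * np.cos(th) - dc * np.sin(th)
    v = dr * np.sin(th) + dc * np.cos(th)
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _cup_geometry(spec: SyntheticSpec):
    """Cup centre and semi-axes, with the offset clamped for containment.

    For same-rotation ellipses whose axes are the disc's scaled by factor f,
    the cup is contained when the offset, expressed in the disc frame, keeps
    every cup boundary point inside the disc; we binary-search the largest
    admissible fraction of the requested offset (1.0 when already fine).
    """
    f = spec.cup_to_disc_factor
    cup_axes = (f * spec.disc_semi_axes[0], f * spec.disc_semi_axes[1])
    off = np.asarray(spec.cup_center_offset, dtype=np.float64)

    th = np.deg2rad(spec.disc_rotation)
    ang = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    a, b = spec.disc_semi_axes

    def contained(t: float) -> bool:
        # cup boundary in the disc frame: centre offset (rotated) + scaled axes
        dr = t * off[0]
        dc = t * off[1]
        u0 = dr * np.cos(th) - dc * np.sin(th)
        v0 = dr * np.sin(th) + dc * np.cos(th)
        u = u0 + cup_axes[0] * np.cos(ang)
        v = v0 + cup_axes[1] * np.sin(ang)
        return bool(np.all((u / a) ** 2 + (v / b) ** 2 <= 1.0 + 1e-12))

    if not contained(0.0):
        raise ValueError("cup cannot be contained in the disc (factor too large)")
    t = 1.0
    if not contained(1.0):
        lo, hi = 0.0, 1.0
        for _ in range(40):
            mid = (lo + hi) / 2
            if contained(mid):
                lo = mid
            else:
                hi = mid
        t = lo
    center = (spec.disc_center[0] + t * off[0], spec.disc_center[1] + t * off[1])
    return center, cup_axes


def _draw_vessels(image: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> None:
    """Dark quadratic-Bezier strokes radiating from near the disc centre."""
    size = spec.image_size
    for _ in range(spec.vessel_count):
        p0 = np.asarray(spec.disc_center) + rng.normal(0, 6, 2)
        angle = rng.uniform(0, 2 * np.pi)
        reach = rng.uniform(0.5, 1.2) * size
        p2 = p0 + reach * np.array([np.sin(angle), np.cos(angle)])
        p1 = (p0 + p2) / 2 + rng.normal(0, size * 0.08, 2)
        t = np.linspace(0, 1, 3 * size)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2
        half = rng.uniform(0.8, 1.8)
        lo = np.clip(np.floor(pts - half).astype(int), 0, size - 1)
        hi = np.clip(np.ceil(pts + half).astype(int), 0, size - 1)
        strength = rng.uniform(0.45, 0.7)
        painted = np.zeros((size, size), bool)
        for (r0, c0), (r1, c1) in zip(lo, hi):
            painted[r0:r1 + 1, c0:c1 + 1] = True
        image[painted] = image[painted] * (1 - strength)


def generate_fundus(spec: SyntheticSpec) -> LabeledFundus:
    """Render one synthetic fundus image with exact disc/cup masks.

    Identical spec (including seed) gives identical output; the masks depend
    only on the geometry, so two seeds differing only in noise/vessels share
    byte-identical masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size

    disc = _ellipse_mask(size, spec.disc_center, spec.disc_semi_axes, spec.disc_rotation)
    cup_center, cup_axes = _cup_geometry(spec)
    cup = _ellipse_mask(size, cup_center, cup_axes, spec.disc_rotation)
    cup &= disc  # guard against boundary-pixel protrusion from rasterization

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = spec.background_level
    img[disc] = spec.disc_level
    img[cup] = spec.cup_level

    # soft rim: slight brightening of the disc edge towards the background
    _draw_vessels(img, spec, rng)
    img += rng.normal(0.0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    return LabeledFundus(image=img, disc_mask=disc, cup_mask=cup,
                         meta={"spec": asdict(spec)})


@dataclass
class SpecSampler:
    """Uniform parameter ranges for sampling per-image specs."""

    image_size: int = 256
    disc_semi_axis_range: tuple[float, float] = (40.0, 70.0)
    axis_ratio_range: tuple[float, float] = (0.85, 1.0)  # horizontal/vertical
    cup_factor_range: tuple[float, float] = (0.3, 0.8)
    center_jitter: float = 20.0
    cup_offset_sigma: float = 3.0
    rotation_range: tuple[float, float] = (-20.0, 20.0)
    vessel_count: int = 4
    noise_sigma: float = 8.0
    margin: int = 4

    def sample(self, rng: np.random.Generator, seed: int) -> SyntheticSpec:
        size = self.image_size
        a = rng.uniform(*self.disc_semi_axis_range)
        # cap so the disc always fits the frame with its margin
        max_reach = size / 2 - self.margin - 2
        a = min(a, max_reach)
        b = a * rng.uniform(*self.axis_ratio_range)
        reach = max(a, b)
        lo = reach + self.margin + 1
        hi = size - reach - self.margin - 1
        mid = size / 2
        jit = min(self.center_jitter, max(0.0, (hi - lo) / 2))
        center = (float(np.clip(mid + rng.uniform(-jit, jit), lo, hi)),
                  float(np.clip(mid + rng.uniform(-jit, jit), lo, hi)))
        return SyntheticSpec(
            image_size=size,
            disc_center=center,
            disc_semi_axes=(float(a), float(b)),
            cup_to_disc_factor=float(rng.uniform(*self.cup_factor_range)),
            cup_center_offset=tuple(rng.normal(0, self.cup_offset_sigma, 2)),
            disc_rotation=float(rng.uniform(*self.rotation_range)),
            vessel_count=self.vessel_count,
            noise_sigma=self.noise_sigma,
            margin=self.margin,
            seed=int(seed),
        )


def generate_dataset(n: int, sampler: SpecSampler | None = None,
                     seed: int = 0) -> list[LabeledFundus]:
    """Generate ``n`` independent labelled images; reproducible under ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = sampler or SpecSampler()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = sampler.sample(rng, seed=int(rng.integers(0, 2 ** 31 - 1)))
        out.append(generate_fundus(spec))
    return out


# ---------------------------------------------------------------------------
# disk I/O (PNG images, 0/255 PNG masks, JSON spec sidecars)


def save_fundus(sample: LabeledFundus, directory, stem: str) -> None:
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", sample.image)
    if sample.disc_mask is not None:
        iio.imwrite(directory / f"{stem}_disc.png",
                    (sample.disc_mask.astype(np.uint8) * 255))
    if sample.cup_mask is not None:
        iio.imwrite(directory / f"{stem}_cup.png",
                    (sample.cup_mask.astype(np.uint8) * 255))
    (directory / f"{stem}.json").write_text(json.dumps(sample.meta, indent=2))


def load_fundus(directory, stem: str) -> LabeledFundus:
    import imageio.v3 as iio

    directory = Path(directory)
    image = iio.imread(directory / f"{stem}.png")
    def _mask(path):
        return (iio.imread(path) > 127) if path.exists() else None

    meta_path = directory / f"{stem}.json"
    return LabeledFundus(
        image=image,
        disc_mask=_mask(directory / f"{stem}_disc.png"),
        cup_mask=_mask(directory / f"{stem}_cup.png"),
        meta=json.loads(meta_path.read_text()) if meta_path.exists() else {},
    )
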