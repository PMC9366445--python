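"""Synthetic puparium-like image sets with controllable group structure.

Real whitefly puparia are elongate-oval larval cases with a posterior
vasiform orifice and a crenulated dorsal margin; the taxonomic signal
separating cryptic species is a subtle joint shift of outline shape and
interior structure, smaller than the between-species differences but larger
than the specimen-to-specimen jitter introduced by mounting and imaging.

This module emulates that statistical situation with a closed-form shape
family: a superellipse body outline, a sinusoidal margin crenulation, and a
Gaussian interior blob standing in for the vasiform orifice.  Each group
shifts the shape-parameter vector along a seeded unit-norm direction scaled
by a single effect size ``delta``; each specimen adds rotation / scale /
brightness / pixel-noise jitter; the rearing substrate (hairy vs glabrous
host leaves) applies one deterministic aspect-ratio and margin-amplitude
shift to every group, mirroring the ecophenotypic plasticity of the insect.

At ``delta = 0`` the group label carries no information (images are
exchangeable across groups); at large ``delta`` the groups are cleanly
separable after the standard 28x28 preparation.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "JitterConfig",
    "SyntheticConfig",
    "SpecimenImage",
    "generate_image_set",
    "write_image_set",
    "TABLE1_HAIRY",
    "TABLE1_GLABROUS",
]

SUBSTRATES = ("hairy", "glabrous")

#: Per-group sample sizes of the two published B. tabaci image sets
#: (15 genetic species; hairy- and glabrous-leaf rearing substrates).
TABLE1_HAIRY = (34, 37, 32, 30, 32, 24, 22, 25, 21, 19, 21, 22, 20, 24, 23)
TABLE1_GLABROUS = (30, 32, 30, 31, 31, 17, 11, 25, 26, 22, 24, 19, 19, 22, 27)


class ConfigurationError(ValueError):
    """Invalid generator configuration; the message names the field."""


@dataclass(frozen=True)
class JitterConfig:
    """Per-specimen nuisance variation (imaging / mounting jitter).

    Units: degrees for rotation, relative fraction for scale and brightness,
    8-bit gray levels for additive pixel noise.
    """

    rotation_deg: float = 4.0
    scale: float = 0.04
    brightness: float = 0.04
    pixel_noise: float = 3.0

    def validate(self) -> None:
        for name in ("rotation_deg", "scale", "brightness", "pixel_noise"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"jitter.{name} must be non-negative")


@dataclass(frozen=True)
class SyntheticConfig:
    n_groups: int = 15
    per_group: int | Sequence[int] = 25
    substrate: str = "hairy"
    effect_size: float = 1.0
    jitter: JitterConfig = field(default_factory=JitterConfig)
    image_size: int = 128
    seed: int = 0

    def group_sizes(self) -> list[int]:
        if isinstance(self.per_group, (int, np.integer)):
            return [int(self.per_group)] * self.n_groups
        sizes = [int(k) for k in self.per_group]
        if len(sizes) != self.n_groups:
            raise ConfigurationError(
                f"per_group list has {len(sizes)} entries but n_groups={self.n_groups}"
            )
        return sizes

    def validate(self) -> None:
        if self.n_groups < 2:
            raise ConfigurationError("n_groups must be >= 2")
        if any(k < 1 for k in self.group_sizes()):
            raise ConfigurationError("per_group entries must all be >= 1")
        if self.substrate not in SUBSTRATES:
            raise ConfigurationError(
                f"substrate must be one of {SUBSTRATES}, got {self.substrate!r}"
            )
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be non-negative")
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32 pixels")
        self.jitter.validate()


@dataclass
class SpecimenImage:
    """One specimen image plus its manifest metadata.

    ``pixels`` holds 8-bit gray levels in [0, 255] for raw images and floats
    in [0, 1] after preparation (see :mod:`pupanet.prep`).
    """

    specimen_id: str
    group: str
    substrate: str
    pixels: np.ndarray

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


# Base shape-parameter vector and the per-parameter sensitivity of the
# group offsets.  The 8 parameters are: log semi-axis (long), log semi-axis
# (short), superellipse exponent, margin crenulation amplitude, crenulation
# frequency, blob position (fraction of the long axis), log blob size,
# body gray level.
_BASE = np.array([np.log(0.40), np.log(0.26), 2.2, 0.020, 12.0, 0.45, np.log(0.16), 0.45])
_SENS = np.array([0.07, 0.07, 0.45, 0.012, 2.5, 0.10, 0.22, 0.07])

_BLOB_GRAY = 0.05


def _substrate_shift(params: np.ndarray, substrate: str) -> np.ndarray:
    """Deterministic ecophenotypic shift: hairy leaves yield narrower bodies
    with a more strongly crenulated margin than glabrous leaves."""
    p = params.copy()
    if substrate == "glabrous":
        p[1] += np.log(1.10)   # broader body
        p[3] *= 0.6            # smoother margin
    return p


def _render(size: int, params: np.ndarray, angle_deg: float, scale: float) -> np.ndarray:
    """Render one specimen as a float image in [0, 1] on a white field."""
    log_a, log_b, expo, amp, freq, blob_pos, log_blob, body_gray = params
    a, b = np.exp(log_a) * scale, np.exp(log_b) * scale
    expo = max(expo, 1.2)
    body_gray = float(np.clip(body_gray, 0.15, 0.85))

    half = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    x = (xx - half + 0.5) / half
    y = (yy - half + 0.5) / half
    th = np.deg2rad(angle_deg)
    xr = np.cos(th) * x + np.sin(th) * y
    yr = -np.sin(th) * x + np.cos(th) * y

    eps = 1e-9
    rho = (np.abs(xr / b) ** expo + np.abs(yr / a) ** expo) ** (1.0 / expo)
    phi = np.arctan2(yr, xr)
    boundary = 1.0 + amp * np.sin(freq * phi)
    signed = rho - boundary

    # ~1.2-pixel anti-aliased edge, expressed in rho units
    w = 1.2 / (half * min(a, b) + eps)
    mask = np.clip(0.5 - signed / (2.0 * w), 0.0, 1.0)

    # interior: radial shading, faint transverse striations, and the
    # posterior blob (vasiform-orifice analogue)
    interior = body_gray * (1.0 + 0.18 * rho**2)
    interior += 0.04 * np.sin(10.0 * np.pi * yr / (2 * a))
    blob_sigma = np.exp(log_blob) * a
    d2 = xr**2 + (yr - blob_pos * a) ** 2
    g = np.exp(-d2 / (2.0 * blob_sigma**2 + eps))
    interior = interior * (1.0 - g) + _BLOB_GRAY * g
    interior = np.clip(interior, 0.01, 1.0)

    # sclerotized margin rim (~3 px) and the orifice core are fully black,
    # like the darkest structures of stained-free slide mounts
    r = np.sqrt(xr**2 + yr**2)
    rim = 4.5 * rho / (half * r + eps)
    interior[(rho <= boundary) & (rho >= boundary - rim)] = 0.0
    interior[g > 0.25] = 0.0

    return 1.0 * (1.0 - mask) + interior * mask


def generate_image_set(config: SyntheticConfig) -> tuple[list[SpecimenImage], pd.DataFrame]:
    """Generate a labelled synthetic image set.

    Returns the images (8-bit grayscale rasters on a white background) and a
    manifest with columns ``path, specimen_id, group, substrate``; ``path``
    is filled in by :func:`write_image_set`.  Identical config + seed yields
    a bit-identical set.
    """
    config.validate()
    sizes = config.group_sizes()
    n_total = sum(sizes)

    root = np.random.SeedSequence(config.seed)
    offsets_ss, jitter_ss = root.spawn(2)

    # one unit-norm direction per group in shape-parameter space
    rng_off = np.random.default_rng(offsets_ss)
    dirs = rng_off.standard_normal((config.n_groups, _BASE.size))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    spec_streams = jitter_ss.spawn(n_total)

    images: list[SpecimenImage] = []
    rows = []
    idx = 0
    for gi, gsize in enumerate(sizes):
        group = f"sp{gi + 1:02d}"
        params = _BASE + config.effect_size * _SENS * dirs[gi]
        params = _substrate_shift(params, config.substrate)
        for si in range(gsize):
            rng = np.random.default_rng(spec_streams[idx])
            jit = config.jitter
            angle = rng.normal(0.0, jit.rotation_deg)
            scale = float(np.exp(rng.normal(0.0, jit.scale)))
            bright = float(np.exp(rng.normal(0.0, jit.brightness)))
            p = params.copy()
            p[7] = np.clip(p[7] * bright, 0.15, 0.85)

            img = _render(config.image_size, p, angle, scale)
            if jit.pixel_noise > 0:
                noise = rng.normal(0.0, jit.pixel_noise / 255.0, img.shape)
                # noise only on textured interior; the white frame and the
                # black rim/orifice are noise-free structural anchors
                inside = (img < 1.0) & (img > 0.005)
                img = np.where(inside, np.clip(img + noise, 0.0, 1.0), img)
            raster = np.round(img * 255.0).astype(np.uint8)

            sid = f"{group}_s{si + 1:03d}"
            images.append(SpecimenImage(sid, group, config.substrate, raster))
            rows.append({"path": "", "specimen_id": sid, "group": group,
                         "substrate": config.substrate})
            idx += 1

    manifest = pd.DataFrame(rows, columns=["path", "specimen_id", "group", "substrate"])
    return images, manifest


def image_png_bytes(image: SpecimenImage) -> bytes:
    buf = io.BytesIO()
    Image.fromarray(image.pixels, mode="L").save(buf, format="PNG")
    return buf.getvalue()


def write_image_set(images: list[SpecimenImage], manifest: pd.DataFrame,
                    out_dir: str | Path) -> pd.DataFrame:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest; returns the
    manifest with ``path`` filled in."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    for i, img in enumerate(images):
        rel = f"{img.specimen_id}.png"
        (out / rel).write_bytes(image_png_bytes(img))
        manifest.loc[manifest.index[i], "path"] = rel
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_image_set(manifest_path: str | Path) -> tuple[list[SpecimenImage], pd.DataFrame]:
    """Load a PNG/TIFF image set from a CSV manifest written by
    :func:`write_image_set` (or hand-assembled for real specimen images)."""
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    base = manifest_path.parent
    images = []
    for _, row in manifest.iterrows():
        arr = np.asarray(Image.open(base / row["path"]))
        images.append(SpecimenImage(str(row["specimen_id"]), str(row["group"]),
                                    str(row["substrate"]), arr))
    return images, manifest
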