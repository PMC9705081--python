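"""Seeded synthetic anterior-segment phantom with paired lesion masks.

The private clinical dataset behind this work cannot be redistributed, so the
package generates eye-like stand-ins that exercise every pipeline contract:
an elliptical sclera on a dark lid/skin background, concentric iris and pupil
disks, curvilinear episcleral vessels, additive Gaussian sensor noise, and —
for the pterygium class — a wing-shaped (wedge) fibrovascular lesion growing
from the nasal margin across the limbus onto the cornea.  The mask is, by
construction, exactly the rendered wedge's pixel support.

Realism is deliberately minimal (geometric primitives plus noise); the
phantom is meant to be *learnable* and *contract-exact*, not photorealistic.
All randomness flows from a single seed, so every sample is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .preprocess_io import (
    NORMAL, PTERYGIUM, AnteriorSegmentImage, InvalidInputError, Manifest,
    ManifestRecord, SegMask, save_image, save_manifest, save_mask,
    split_train_val,
)

EXTENT_RANGE = (0.15, 0.8)  # positive-class lesion extents: neither sub-pixel nor full-cornea


@dataclasses.dataclass
class EyePhantomParams:
    """Knobs of one rendered phantom; defaults give a plausible desk-scale eye."""

    image_size: int = 224
    sclera_color: tuple[int, int, int] = (238, 232, 226)
    iris_color: tuple[int, int, int] = (96, 72, 48)
    pupil_color: tuple[int, int, int] = (18, 14, 14)
    lesion_extent: float = 0.0        # fraction of corneal radius covered, 0 = normal
    lesion_side: str = "nasal-left"   # or "nasal-right"
    vessel_density: float = 2.0       # vessels per 100x100 px of sclera
    noise_sd: float = 6.0             # additive Gaussian, intensity units
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lesion_extent <= 1.0:
            raise InvalidInputError(f"lesion_extent {self.lesion_extent} outside [0, 1]")
        if self.lesion_side not in ("nasal-left", "nasal-right"):
            raise InvalidInputError(f"unknown lesion_side {self.lesion_side!r}")
        for c in (self.sclera_color, self.iris_color, self.pupil_color):
            if len(c) != 3 or any(not 0 <= v <= 255 for v in c):
                raise InvalidInputError(f"invalid RGB triple {c}")
        if self.image_size < 16:
            raise InvalidInputError("image_size must be >= 16")

    @property
    def label(self) -> str:
        return PTERYGIUM if self.lesion_extent > 0 else NORMAL


def _geometry(size: int):
    cy = cx = (size - 1) / 2.0
    iris_r = 0.30 * size
    pupil_r = 0.115 * size
    sclera_ab = (0.46 * size, 0.60 * size)  # semi-axes (vertical, horizontal)
    return cy, cx, iris_r, pupil_r, sclera_ab


def lesion_wedge_support(params: EyePhantomParams) -> np.ndarray:
    """Boolean H x W support of the lesion wedge (empty when extent is 0).

    The wedge is a horizontal triangle: its base sits on the sclera a quarter
    corneal-radius outside the limbus on the chosen nasal side, its apex lies
    ``lesion_extent`` corneal radii inside the limbus, and its half-width
    tapers linearly from 0.45 corneal radii at the base to zero at the apex.
    The support grows strictly with ``lesion_extent`` at fixed geometry.
    """
    s = params.image_size
    if params.lesion_extent <= 0:
        return np.zeros((s, s), dtype=bool)
    cy, cx, iris_r, _, _ = _geometry(s)
    sign = -1.0 if params.lesion_side == "nasal-left" else 1.0
    base_x = cx + sign * (iris_r * 1.25)             # on the sclera, past the limbus
    apex_x = cx + sign * (iris_r * (1.0 - params.lesion_extent))
    length = abs(base_x - apex_x)
    half_w = 0.45 * iris_r
    rr, cc = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
    t = (cc - apex_x) / (base_x - apex_x)            # 0 at apex, 1 at base
    inside_axis = (t >= 0.0) & (t <= 1.0) & (length > 0)
    return inside_axis & (np.abs(rr - cy) <= half_w * t)


def generate_sample(params: EyePhantomParams) -> tuple[AnteriorSegmentImage, SegMask, str]:
    """Render one phantom; returns (image, mask, label), deterministic per seed."""
    s = params.image_size
    rng = np.random.default_rng(params.seed)
    cy, cx, iris_r, pupil_r, (sa, sb) = _geometry(s)
    rr, cc = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")

    img = np.empty((s, s, 3), dtype=np.float64)
    img[:] = (64, 44, 38)                               # lid/skin background
    sclera = ((rr - cy) / sa) ** 2 + ((cc - cx) / sb) ** 2 <= 1.0
    img[sclera] = params.sclera_color
    dist = np.hypot(rr - cy, cc - cx)
    img[dist <= iris_r] = params.iris_color
    img[dist <= pupil_r] = params.pupil_color

    # episcleral vessels: jittered polylines walking inward from the sclera edge
    n_vessels = int(round(params.vessel_density * s * s / 10000.0))
    pil = Image.fromarray(np.clip(img, 0, 255).astype(np.uint8))
    draw = ImageDraw.Draw(pil)
    for _ in range(n_vessels):
        ang = rng.uniform(0, 2 * np.pi)
        r0 = rng.uniform(0.9, 1.0)
        y = cy + sa * r0 * np.sin(ang)
        x = cx + sb * r0 * np.cos(ang)
        pts = [(x, y)]
        for _ in range(rng.integers(3, 7)):
            step = rng.uniform(0.04, 0.09) * s
            toward = np.arctan2(cy - y, cx - x) + rng.normal(0, 0.5)
            x, y = x + step * np.cos(toward), y + step * np.sin(toward)
            pts.append((x, y))
        draw.line(pts, fill=(180, 60, 55), width=max(1, s // 160))
    img = np.asarray(pil).astype(np.float64)
    img[~sclera & (dist > iris_r)] = (64, 44, 38)       # keep vessels on the eye only
    img[dist <= pupil_r] = params.pupil_color

    wedge = lesion_wedge_support(params)
    if wedge.any():
        # fleshy, vascularized overgrowth: blend toward sclera tones, add vessels
        flesh = np.array([228, 158, 148], dtype=np.float64)
        img[wedge] = 0.2 * img[wedge] + 0.8 * flesh
        lesion_layer = Image.fromarray(np.zeros((s, s), np.uint8))
        ldraw = ImageDraw.Draw(lesion_layer)
        ys, xs = np.nonzero(wedge)
        for _ in range(max(2, n_vessels)):
            i = rng.integers(0, len(xs))
            x, y = float(xs[i]), float(ys[i])
            pts = [(x, y)]
            for _ in range(3):
                x += rng.normal(0, 0.03 * s)
                y += rng.normal(0, 0.03 * s)
                pts.append((x, y))
            ldraw.line(pts, fill=255, width=max(1, s // 200))
        strokes = (np.asarray(lesion_layer) > 0) & wedge   # clip to the wedge
        img[strokes] = (172, 62, 60)

    img += rng.normal(0.0, params.noise_sd, img.shape)
    image = AnteriorSegmentImage(np.clip(np.rint(img), 0, 255).astype(np.uint8),
                                 source_id=f"phantom-{params.seed}")
    mask = SegMask(wedge.astype(np.uint8))
    return image, mask, params.label


def generate_dataset(n_normal: int, n_pterygium: int, size: int, seed: int,
                     out_dir: str | Path, split: bool = True,
                     preview: bool = False) -> Manifest:
    """Render a labeled dataset to ``out_dir`` and write its manifest CSV.

    Per-sample seeds are spawned from the master seed; positive-class lesion
    extents are drawn uniformly from [0.15, 0.8] with a random nasal side.
    The training pool gets a 9:1 train/validation split when ``split`` is on.
    """
    if n_normal < 0 or n_pterygium < 0:
        raise InvalidInputError("sample counts must be >= 0")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    records: list[ManifestRecord] = []
    previews: list[np.ndarray] = []
    for idx in range(n_normal + n_pterygium):
        positive = idx >= n_normal
        sample_seed = int(master.integers(0, 2**31 - 1))
        extent = float(master.uniform(*EXTENT_RANGE)) if positive else 0.0
        side = "nasal-left" if master.random() < 0.5 else "nasal-right"
        params = EyePhantomParams(image_size=size, lesion_extent=extent,
                                  lesion_side=side, seed=sample_seed)
        image, mask, label = generate_sample(params)
        name = f"{label}_{idx:04d}"
        save_image(image, out_dir / "images" / f"{name}.png")
        mask_rel = None
        if positive:
            save_mask(mask, out_dir / "masks" / f"{name}.png")
            mask_rel = f"masks/{name}.png"
        records.append(ManifestRecord(f"images/{name}.png", label, mask_rel))
        if preview and len(previews) < 16:
            previews.append(image.pixels)
    if split and records:
        records = split_train_val(records, seed=seed)
    manifest = Manifest(records, root=out_dir)
    save_manifest(manifest, out_dir / "manifest.csv")
    if preview and previews:
        _write_contact_sheet(previews, out_dir / "preview.png")
    return manifest


def _write_contact_sheet(tiles: list[np.ndarray], path: Path, cols: int = 4) -> None:
    s = tiles[0].shape[0]
    rows = (len(tiles) + cols - 1) // cols
    sheet = np.zeros((rows * s, cols * s, 3), dtype=np.uint8)
    for i, tile in enumerate(tiles):
        r, c = divmod(i, cols)
        sheet[r * s:(r + 1) * s, c * s:(c + 1) * s] = tile
    Image.fromarray(sheet).save(path)
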