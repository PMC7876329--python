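"""Synthetic field imagery with known flowering-plant point annotations.

Fields are rendered as green plant beds separated by bare road stripes.
Plants sit on a jittered lattice inside the beds; a seeded Bernoulli draw
decides which plants flower, and each flowering plant gets a small reddish
radial-gradient blob with one point annotation at its center. Everything
downstream (targets, training, counting, active learning) can therefore be
exercised against exact ground truth with no external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .annotation_io import write_annotations, write_manifest
from .density_targets import PointAnnotationSet

__all__ = ["SyntheticFieldSpec", "generate_field", "generate_dataset"]


@dataclass
class SyntheticFieldSpec:
    image_height: int = 256
    image_width: int = 256
    bed_width: int = 48
    road_width: int = 12
    plant_spacing: int = 10
    flowering_fraction: float = 0.5
    blob_radius_range: tuple = (3.0, 5.0)
    blob_color: tuple = (205, 70, 55)       # reddish inflorescence
    background_color: tuple = (52, 96, 40)  # field green
    road_color: tuple = (120, 105, 80)      # bare soil
    texture_noise_sd: float = 5.0
    jitter_sd: float = 1.0
    seed: int = 0
    illumination_gradient: bool = False
    # optional map bed_index -> flowering fraction, e.g. to simulate a
    # failed-forcing bed among healthy ones
    bed_fraction_overrides: dict | None = None

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.flowering_fraction <= 1.0:
            raise ValueError("flowering_fraction must be in [0, 1]")
        rmin, rmax = self.blob_radius_range
        if rmin > rmax or rmin < 1:
            raise ValueError("blob_radius_range must satisfy 1 <= min <= max")
        if self.bed_width <= 0 or self.road_width <= 0:
            raise ValueError("bed and road widths must be positive")
        if self.plant_spacing < 1:
            raise ValueError("plant_spacing must be >= 1")


def road_mask(spec: SyntheticFieldSpec) -> np.ndarray:
    """Boolean (H, W) mask, True on road stripes."""
    period = spec.bed_width + spec.road_width
    cols = np.arange(spec.image_width)
    return np.broadcast_to((cols % period) >= spec.bed_width,
                           (spec.image_height, spec.image_width)).copy()


def _bed_index(col: float, spec: SyntheticFieldSpec) -> int:
    return int(col // (spec.bed_width + spec.road_width))


def _lattice_sites(spec: SyntheticFieldSpec):
    """Plant lattice positions restricted to bed columns, row-major."""
    period = spec.bed_width + spec.road_width
    sp = spec.plant_spacing
    half = sp / 2.0
    sites = []
    r = half
    while r < spec.image_height:
        c = half
        while c < spec.image_width:
            if (c % period) < spec.bed_width:
                sites.append((r, c))
            c += sp
        r += sp
    return sites


def _stamp_blob(img: np.ndarray, r: float, c: float, radius: float,
                color: np.ndarray) -> None:
    """Radial linear falloff from color at the center to the underlying
    image at the blob edge."""
    h, w = img.shape[:2]
    iR = int(math.ceil(radius))
    r0, r1 = max(0, int(r) - iR), min(h, int(r) + iR + 2)
    c0, c1 = max(0, int(c) - iR), min(w, int(c) + iR + 2)
    rr = np.arange(r0, r1, dtype=float)[:, None]
    cc = np.arange(c0, c1, dtype=float)[None, :]
    dist = np.sqrt((rr - r) ** 2 + (cc - c) ** 2)
    t = np.clip(1.0 - dist / radius, 0.0, 1.0)[..., None]
    img[r0:r1, c0:c1] = (1 - t) * img[r0:r1, c0:c1] + t * color


def generate_field(spec: SyntheticFieldSpec):
    """Render one field image and its ground-truth annotations.

    Returns ``(rgb, annotations)`` where ``rgb`` is (H, W, 3) uint8 and
    ``annotations`` holds one (row, col) point per rendered blob. Output
    is bit-identical for identical spec (including seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = spec.background_color
    roads = road_mask(spec)
    img[roads] = spec.road_color

    bg = np.asarray(spec.background_color, dtype=float)
    blob = np.asarray(spec.blob_color, dtype=float)
    rmin, rmax = spec.blob_radius_range
    overrides = spec.bed_fraction_overrides or {}

    points = []
    for r_site, c_site in _lattice_sites(spec):
        # fixed draw order per site keeps the stream aligned across specs
        jr, jc = rng.normal(0.0, 1.0, 2) * spec.jitter_sd
        u_flower = rng.random()
        radius = rng.uniform(rmin, rmax)
        rosette_shade = rng.uniform(0.75, 0.95)
        r, c = r_site + jr, c_site + jc
        if not (0 <= r < h and 0 <= c < w):
            continue
        # every plant gets a darker rosette disc so non-flowering plants
        # are visible texture, not blank background
        _stamp_blob(img, r, c, spec.plant_spacing * 0.45, bg * rosette_shade)
        frac = overrides.get(_bed_index(c_site, spec),
                             spec.flowering_fraction)
        if u_flower < frac:
            _stamp_blob(img, r, c, radius, blob)
            points.append((r, c))

    if spec.illumination_gradient:
        theta = rng.uniform(0, 2 * math.pi)
        rr = np.arange(h)[:, None]
        cc = np.arange(w)[None, :]
        ramp = (math.cos(theta) * rr / max(h - 1, 1)
                + math.sin(theta) * cc / max(w - 1, 1))
        ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-12)
        img *= (0.85 + 0.3 * ramp)[..., None]

    if spec.texture_noise_sd > 0:
        img += rng.normal(0.0, spec.texture_noise_sd, img.shape)

    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)
    ann = PointAnnotationSet("field", np.array(points).reshape(-1, 2))
    return rgb, ann


def split_counts(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n items over split fractions."""
    fracs = [float(f) for f in fractions]
    if abs(sum(fracs) - 1.0) > 1e-9:
        raise ValueError(f"split fractions {fracs} must sum to 1")
    raw = [f * n for f in fracs]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fracs)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_dataset(spec: SyntheticFieldSpec, n_patches: int,
                     patch_size: int, split_fractions=(0.8, 0.1, 0.1), *,
                     out_dir=None, flowering_fraction_range=None
                     ) -> pd.DataFrame:
    """Generate a train/val/test dataset of synthetic patches.

    Each patch is rendered from its own child seed of ``spec.seed``; test
    patches come from a separate seed stream so they never share a
    generator configuration with train/val. When ``out_dir`` is given,
    patches are written as 8-bit PNG with per-patch annotation CSVs and a
    manifest CSV; otherwise the manifest carries the in-memory arrays in
    extra columns (``image``, ``points``).
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    counts = split_counts(n_patches, split_fractions)
    splits = (["train"] * counts[0] + ["val"] * counts[1]
              + ["test"] * counts[2])

    ss = np.random.SeedSequence(spec.seed)
    trainval_stream, test_stream = ss.spawn(2)
    n_trainval = counts[0] + counts[1]
    seeds = list(trainval_stream.generate_state(n_trainval)) + \
        list(test_stream.generate_state(counts[2]))

    frac_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    for i, (split, seed) in enumerate(zip(splits, seeds)):
        frac = spec.flowering_fraction
        if flowering_fraction_range is not None:
            lo, hi = flowering_fraction_range
            frac = float(frac_rng.uniform(lo, hi))
        pspec = replace(spec, image_height=patch_size,
                        image_width=patch_size, seed=int(seed),
                        flowering_fraction=frac)
        rgb, ann = generate_field(pspec)
        image_id = f"patch_{i:05d}"
        ann = PointAnnotationSet(image_id, ann.points)
        row = {"image_id": image_id, "split": split}
        if out_dir is not None:
            img_path = out_dir / "images" / f"{image_id}.png"
            ann_path = out_dir / "annotations" / f"{image_id}.csv"
            Image.fromarray(rgb).save(img_path)
            write_annotations({image_id: ann}, ann_path)
            row["path"] = str(img_path)
            row["annotation_path"] = str(ann_path)
        else:
            row["path"] = ""
            row["annotation_path"] = ""
            row["image"] = rgb
            row["points"] = ann
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
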