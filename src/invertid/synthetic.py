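"""Synthetic multi-view specimen image sequences.

Emulates the structure of a backlit-cuvette imaging archive: each specimen
sinks through an ethanol-filled cuvette and is photographed by two orthogonal
cameras, producing a per-specimen sequence of dark silhouettes on a bright
background. The generator reproduces the statistical structure that matters
downstream — taxon-specific frame counts inversely related to sinking speed
(from ~16 to ~360 frames per specimen across the default 16-taxon community),
body-size distributions spanning more than an order of magnitude, two
alternating camera views with foreshortening, in-plane tumbling, and vertical
drift — without attempting photorealism.

Silhouettes are superellipse bodies with optional line-segment appendages;
taxa differ in mean area, elongation, appendage count/length, darkness and
texture noise. All randomness derives from a master seed; each specimen's
stream is keyed by a stable hash of (master seed, specimen id) so output is
reproducible regardless of generation order.

Disk layout: ``<out>/<taxon>/<specimen_id>/frame_<k>_<view>.png`` (8-bit
grayscale PNG) plus a manifest CSV with header
``specimen_id,taxon,n_frames,views``; the ``views`` column packs per-frame
view tags into a string of 'A'/'B' characters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.special import gamma as _gamma

__all__ = [
    "SyntheticTaxonSpec",
    "Frame",
    "SpecimenRecord",
    "make_taxon_specs",
    "generate_specimen",
    "generate_dataset",
    "load_dataset",
    "DEFAULT_FRAMES_BASE",
    "SENSOR_HEIGHT",
    "SENSOR_WIDTH",
    "BACKGROUND",
]

#: default frames recorded for a specimen of unit sinking speed
DEFAULT_FRAMES_BASE = 360.0
#: pre-crop sensor frame, width fixed by the 10 mm cuvette (496 px)
SENSOR_HEIGHT = 700
SENSOR_WIDTH = 496
#: backlit background intensity
BACKGROUND = 0.95
#: hard cap on frames per specimen
FRAME_CAP = 400

VIEW_A = "view_A"
VIEW_B = "view_B"


@dataclass(frozen=True)
class SyntheticTaxonSpec:
    """Parameters controlling one taxon's silhouette rendering.

    ``base_area_mm2`` is the taxon mean silhouette area; individual specimens
    draw their area from a log-normal with that mean and coefficient of
    variation ``area_cv``. ``sinking_speed`` is relative: a specimen records
    ``frames_base / sinking_speed`` frames (constant frame rate, faster
    sinkers are seen fewer times).
    """

    taxon_id: int
    name: str
    base_area_mm2: float
    area_cv: float
    elongation: float
    n_appendages: int
    appendage_length_frac: float
    gray_level: float
    sinking_speed: float
    texture_noise: float

    def __post_init__(self) -> None:
        if self.base_area_mm2 <= 0:
            raise ValueError("base_area_mm2 must be positive")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")
        if not (0 <= self.gray_level < BACKGROUND):
            raise ValueError("gray_level must lie in [0, background)")
        if self.sinking_speed <= 0:
            raise ValueError("sinking_speed must be positive")


@dataclass
class Frame:
    """A single grayscale frame: intensities in [0, 1], row-major."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValueError("frame must be a non-empty 2-D grid")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SpecimenRecord:
    """A labeled specimen: ordered frames plus per-frame view tags."""

    specimen_id: str
    taxon_id: int
    frames: list = field(default_factory=list)
    view_tags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("a specimen needs at least one frame")
        if len(self.view_tags) != len(self.frames):
            raise ValueError("one view tag per frame required")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames of a specimen share pixel dimensions")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _specimen_seed(master_seed: int, specimen_id: str) -> int:
    """Stable sub-seed from (master seed, specimen id), independent of order."""
    digest = hashlib.sha256(f"{master_seed}:{specimen_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


# Shape-parameter ladders cycled across taxa; combined with strictly distinct
# areas they guarantee pairwise-distinct (area, elongation, appendages).
_ELONGATIONS = (1.2, 2.2, 3.2, 1.6, 2.7, 4.0, 1.9, 3.6)
_APPENDAGES = (0, 2, 4, 6, 1, 3, 5, 2)


def make_taxon_specs(
    n_taxa: int, seed: int, speed_range: tuple[float, float] = (1.0, 22.5)
) -> list[SyntheticTaxonSpec]:
    """Build a deterministic community of ``n_taxa`` distinct taxa.

    Mean areas are log-spaced over 0.5–15 mm2 (>= 10x smallest-to-largest,
    matching the order-of-magnitude spread of real communities) and sinking
    speeds are geometric over ``speed_range`` — the default [1, 22.5] makes
    mean frame counts run from ~360 down to ~16 at ``DEFAULT_FRAMES_BASE``;
    pass a narrow range for communities with comparable frame counts.
    """
    if n_taxa < 2:
        raise ValueError("classification needs at least 2 taxa")
    rng = np.random.default_rng(seed)
    areas = np.geomspace(0.5, 15.0, n_taxa)
    speeds = np.geomspace(speed_range[0], speed_range[1], n_taxa)
    # slow sinkers are not systematically the small taxa: decouple the ladders
    speed_order = rng.permutation(n_taxa)
    specs = []
    for i in range(n_taxa):
        specs.append(
            SyntheticTaxonSpec(
                taxon_id=i,
                name=f"taxon_{i:02d}",
                base_area_mm2=float(areas[i]),
                area_cv=0.25,
                elongation=_ELONGATIONS[i % len(_ELONGATIONS)],
                n_appendages=_APPENDAGES[i % len(_APPENDAGES)],
                appendage_length_frac=float(rng.uniform(0.25, 0.6)),
                gray_level=float(rng.uniform(0.05, 0.35)),
                sinking_speed=float(speeds[speed_order[i]]),
                texture_noise=float(rng.uniform(0.02, 0.05)),
            )
        )
    return specs


# mm per px from the 10 mm cuvette imaged across 496 px
_MM_PER_PX = 10.0 / 496.0


def _superellipse_axes(area_px: float, elongation: float, p: float) -> tuple[float, float]:
    """Semi-axes (a, b) of a superellipse |u/a|^p + |v/b|^p <= 1 of given area.

    Area = 4ab * Gamma(1+1/p)^2 / Gamma(1+2/p); a/b = elongation.
    """
    g = _gamma(1 + 1 / p) ** 2 / _gamma(1 + 2 / p)
    b = float(np.sqrt(area_px / (4.0 * elongation * g)))
    return elongation * b, b


def _render_frame(
    height: int,
    width: int,
    center: tuple[float, float],
    a: float,
    b: float,
    p_exp: float,  # superellipse exponent; rendering is hard-wired to 4
    theta: float,
    foreshorten: float,
    appendage_angles: np.ndarray,
    appendage_len: float,
    appendage_width: float,
    gray_level: float,
    texture_noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Rasterize one silhouette frame; returns intensities in [0, 1].

    The silhouette inequality is only evaluated inside a bounding window
    around the specimen (its reach is a + appendage length), which keeps
    rendering cost proportional to specimen size rather than frame size.
    """
    ct, st = np.cos(theta), np.sin(theta)

    def body_coords(r0: int, r1: int, c0: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
        dy = np.arange(r0, r1, dtype=float)[:, None] - center[0]
        dx = np.arange(c0, c1, dtype=float)[None, :] - center[1]
        u = ct * dx + st * dy
        v = (-st * dx + ct * dy) / foreshorten  # orthogonal view compresses width
        return u, v

    def clip_window(lo_r: float, hi_r: float, lo_c: float, hi_c: float):
        return (
            max(0, int(np.floor(lo_r))),
            min(height, int(np.ceil(hi_r)) + 1),
            max(0, int(np.floor(lo_c))),
            min(width, int(np.ceil(hi_c)) + 1),
        )

    mask = np.zeros((height, width), dtype=bool)
    reach = a + 2.0
    r0, r1, c0, c1 = clip_window(
        center[0] - reach, center[0] + reach, center[1] - reach, center[1] + reach
    )
    u, v = body_coords(r0, r1, c0, c1)
    # even superellipse exponent: integer powers via squaring, no fractional pow
    u2 = np.square(u / a)
    v2 = np.square(v / b)
    mask[r0:r1, c0:c1] = np.square(u2) + np.square(v2) <= 1.0
    pad = appendage_width + 2.0
    for phi in appendage_angles:
        # segment from body boundary outward, in body coordinates
        u0, v0 = a * np.cos(phi), b * np.sin(phi)
        u1 = (a + appendage_len) * np.cos(phi)
        v1 = (b + appendage_len) * np.sin(phi)
        # endpoints back in image coordinates bound the appendage's sub-window
        pts = []
        for uu, vv in ((u0, v0), (u1, v1)):
            vv_img = vv * foreshorten
            pts.append(
                (center[0] + st * uu + ct * vv_img, center[1] + ct * uu - st * vv_img)
            )
        pr = [p_[0] for p_ in pts]
        pc = [p_[1] for p_ in pts]
        ar0, ar1, ac0, ac1 = clip_window(
            min(pr) - pad, max(pr) + pad, min(pc) - pad, max(pc) + pad
        )
        if ar0 >= ar1 or ac0 >= ac1:
            continue
        ua, va = body_coords(ar0, ar1, ac0, ac1)
        su, sv = u1 - u0, v1 - v0
        seg_len2 = su * su + sv * sv
        t = np.clip(((ua - u0) * su + (va - v0) * sv) / seg_len2, 0.0, 1.0)
        dist2 = (ua - (u0 + t * su)) ** 2 + (va - (v0 + t * sv)) ** 2
        mask[ar0:ar1, ac0:ac1] |= dist2 <= appendage_width**2
    img = np.full((height, width), BACKGROUND)
    img += rng.normal(0.0, texture_noise, size=img.shape)
    img[mask] = gray_level + rng.normal(0.0, texture_noise, size=int(mask.sum()))
    return np.clip(img, 0.0, 1.0)


def generate_specimen(
    spec: SyntheticTaxonSpec,
    specimen_id: str,
    frames_base: float = DEFAULT_FRAMES_BASE,
    seed: int = 0,
    height: int = SENSOR_HEIGHT,
    width: int = SENSOR_WIDTH,
    frame_cap: int = FRAME_CAP,
) -> SpecimenRecord:
    """Render one specimen's frame sequence.

    The frame count is ``clamp(round(frames_base / sinking_speed), 1, cap)``.
    The specimen's silhouette area is drawn once from a log-normal (mean
    ``base_area_mm2``, CV ``area_cv``) and rendered in every frame with a
    random-walk in-plane rotation (tumbling, step sigma = 10 degrees) and a
    monotone vertical drift (sinking). Frames alternate between the two
    orthogonal camera views; the second view shows the same body rotated 90
    degrees about the vertical axis, i.e. with foreshortened width.
    """
    if frames_base <= 0:
        raise ValueError("frames_base must be positive")
    rng = np.random.default_rng(_specimen_seed(seed, specimen_id))
    n_frames = int(np.clip(round(frames_base / spec.sinking_speed), 1, frame_cap))

    # per-specimen draws
    if spec.area_cv > 0:
        sigma2 = np.log(1 + spec.area_cv**2)
        mu = np.log(spec.base_area_mm2) - sigma2 / 2
        area_mm2 = float(rng.lognormal(mu, np.sqrt(sigma2)))
    else:
        area_mm2 = spec.base_area_mm2
    area_px = area_mm2 / (_MM_PER_PX**2)
    p_exp = 4.0  # must match the exponent hard-wired in _render_frame
    a, b = _superellipse_axes(area_px, spec.elongation, p_exp)
    app_len = spec.appendage_length_frac * a
    # keep the silhouette inside the cuvette field of view
    reach = a + app_len + 4.0
    max_reach = min(width, height) / 2.0 - 4.0
    if reach > max_reach:
        shrink = max_reach / reach
        a, b, app_len = a * shrink, b * shrink, app_len * shrink
    thickness = float(rng.uniform(0.45, 0.85))  # body depth / body width
    phis = rng.uniform(0, 2 * np.pi, size=spec.n_appendages)

    theta = float(rng.uniform(0, 2 * np.pi))
    psi = float(rng.uniform(0, 2 * np.pi))  # azimuth about the vertical axis
    margin = a + app_len + 4.0
    row_lo, row_hi = margin, height - margin
    col_center = width / 2.0
    frames, tags = [], []
    for k in range(n_frames):
        frac = k / max(n_frames - 1, 1)
        row = row_lo + frac * (row_hi - row_lo) + rng.normal(0, 2.0)
        row = float(np.clip(row, row_lo, row_hi))
        col = float(np.clip(col_center + rng.normal(0, 6.0), margin, width - margin))
        view = VIEW_A if k % 2 == 0 else VIEW_B
        # The two cameras see the same 3-D pose from orthogonal azimuths: the
        # projected width of an elliptical cross-section (depth = thickness x
        # width) at azimuth psi is sqrt(cos^2 psi + thickness^2 sin^2 psi);
        # the orthogonal camera sees psi + 90 deg. The azimuth random-walks
        # frame to frame, so some frames show ambiguous, strongly
        # foreshortened silhouettes — the pose noise that specimen-level
        # voting averages out.
        if view == VIEW_A:
            fs = float(np.sqrt(np.cos(psi) ** 2 + thickness**2 * np.sin(psi) ** 2))
        else:
            fs = float(np.sqrt(np.sin(psi) ** 2 + thickness**2 * np.cos(psi) ** 2))
        pixels = _render_frame(
            height, width, (row, col), a, b, p_exp, theta, fs,
            phis, app_len, 1.8, spec.gray_level, spec.texture_noise, rng,
        )
        frames.append(Frame(pixels))
        tags.append(view)
        theta += float(rng.normal(0, np.deg2rad(10.0)))  # in-plane tumble
        # the azimuth decorrelates faster than the in-plane angle: a sinking
        # specimen spins about its long axis more freely than it pitches
        psi += float(rng.normal(0, np.deg2rad(30.0)))  # azimuthal tumble
    return SpecimenRecord(specimen_id, spec.taxon_id, frames, tags)


def _view_char(tag: str) -> str:
    return "A" if tag == VIEW_A else "B"


def frame_to_png_bytes(frame: Frame) -> Image.Image:
    """8-bit grayscale PIL image for a frame."""
    return Image.fromarray(np.round(frame.pixels * 255).astype(np.uint8), mode="L")


def generate_dataset(
    specs: list[SyntheticTaxonSpec],
    n_specimens_per_taxon: int,
    frames_base: float = DEFAULT_FRAMES_BASE,
    seed: int = 0,
    out_dir: str | Path | None = None,
    height: int = SENSOR_HEIGHT,
    width: int = SENSOR_WIDTH,
) -> pd.DataFrame:
    """Generate a full labeled dataset; optionally write PNG frames to disk.

    Returns the manifest (``specimen_id, taxon, n_frames, views``). When
    ``out_dir`` is given, one folder per specimen is written under its taxon
    name and a ``manifest.csv`` is placed at the root.
    """
    if n_specimens_per_taxon < 1:
        raise ValueError("n_specimens_per_taxon must be positive")
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    for spec in specs:
        for j in range(n_specimens_per_taxon):
            sid = f"{spec.name}_s{j:03d}"
            rec = generate_specimen(spec, sid, frames_base, seed, height, width)
            rows.append(
                {
                    "specimen_id": sid,
                    "taxon": spec.name,
                    "n_frames": rec.n_frames,
                    "views": "".join(_view_char(t) for t in rec.view_tags),
                }
            )
            if out is not None:
                folder = out / spec.name / sid
                folder.mkdir(parents=True, exist_ok=True)
                for k, (frame, tag) in enumerate(zip(rec.frames, rec.view_tags)):
                    frame_to_png_bytes(frame).save(
                        folder / f"frame_{k:04d}_{_view_char(tag)}.png"
                    )
    manifest = pd.DataFrame(rows, columns=["specimen_id", "taxon", "n_frames", "views"])
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_dataset(root: str | Path) -> tuple[pd.DataFrame, dict[str, SpecimenRecord]]:
    """Read a written dataset back into SpecimenRecords keyed by specimen id."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    taxon_ids = {t: i for i, t in enumerate(sorted(manifest["taxon"].unique()))}
    records: dict[str, SpecimenRecord] = {}
    for _, row in manifest.iterrows():
        folder = root / row["taxon"] / row["specimen_id"]
        frames, tags = [], []
        for path in sorted(folder.glob("frame_*.png")):
            arr = np.asarray(Image.open(path), dtype=float) / 255.0
            frames.append(Frame(arr))
            tags.append(VIEW_A if path.stem.endswith("_A") else VIEW_B)
        records[row["specimen_id"]] = SpecimenRecord(
            row["specimen_id"], taxon_ids[row["taxon"]], frames, tags
        )
    return manifest, records
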