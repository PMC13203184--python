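"""Synthetic apical-view echo phantoms.

Real apical transthoracic echo frames are sector-shaped (fan with the probe
apex at the top): bright speckled myocardium around dark blood-filled
chambers, with the four standard apical views distinguished by which
chambers and septa cross the imaging plane (A2C: 2 cells, A3C: 3, A4C: 4,
A5C: 4 + aortic root).  The phantom reproduces exactly those features and
nothing more: a fan-shaped tissue field textured by multiplicative speckle,
one dark cardiac silhouette (size/aspect/tilt/gain sampled per clip from a
class-independent distribution) partitioned into ``chamber_count`` cells by
thin bright septal walls, sinusoidal area pulsation over the cardiac cycle,
small rigid inter-frame jitter, and the class imbalance of the study
dataset (2170 frames in 217 clips).

The geometry is deliberately minimal: the classes are separable by the
wall topology when clean, yet degradable — the coarse silhouette that
survives heavy corruption carries no class information.  It is not a
physical B-mode simulation (no point-spread function, no scanline
geometry).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from PIL import Image


class View(enum.Enum):
    """The four apical view classes; the value is the visible chamber count."""

    A2C = 2
    A3C = 3
    A4C = 4
    A5C = 5

    @property
    def label(self) -> str:
        return self.name

    @property
    def chamber_count(self) -> int:
        return self.value


VIEWS = [View.A2C, View.A3C, View.A4C, View.A5C]

# Emulated study composition: 52+39+107+19 = 217 clips, frame totals per class
# 518/390/1075/187 = 2170 frames at ~10 frames per clip (the final clip of a
# class is shortened or lengthened to hit the exact total).
DEFAULT_SEQUENCES_PER_CLASS = {"A2C": 52, "A3C": 39, "A4C": 107, "A5C": 19}
DEFAULT_FRAMES_PER_CLASS = {"A2C": 518, "A3C": 390, "A4C": 1075, "A5C": 187}


@dataclass
class PhantomConfig:
    """Parameters of the phantom generator.

    All geometric quantities are fractions of the image size unless the name
    says pixels.  Defaults reproduce the study dataset's shape.
    """

    image_height: int = 256
    image_width: int = 256
    frames_per_sequence: int = 10
    sequences_per_class: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SEQUENCES_PER_CLASS)
    )
    frames_per_class: dict[str, int] | None = field(
        default_factory=lambda: dict(DEFAULT_FRAMES_PER_CLASS)
    )
    # real clip lengths vary around the ten-frame mean; per-clip jitter is
    # configurable but defaults to exactly frames_per_sequence (and is
    # ignored when exact class totals are requested via frames_per_class)
    frame_count_jitter: int = 0
    baseline_speckle_sigma: float = 0.15
    motion_amplitude: float = 2.0  # pixels of rigid inter-frame jitter
    tissue_intensity: float = 0.55
    chamber_intensity: float = 0.065  # center of the blood-pool floor intensity
    chamber_floor_jitter: float = 0.025  # per-sequence floor spread (uniform +/-)
    gain_range: tuple[float, float] = (0.8, 1.25)  # per-sequence gain (TGC knob)
    pulse_amplitude: float = 0.06  # sinusoidal whole-heart axis modulation
    av_motion_amplitude: float = 0.04  # AV-plane excursion (silhouette units)
    wall_thickness_frac: float = 0.02  # septal wall thickness / min(H, W)
    silhouette_center: tuple[float, float] = (0.53, 0.50)  # (cy, cx) fractions
    silhouette_axes: tuple[float, float] = (0.30, 0.17)  # (ry, rx) fractions
    center_jitter: float = 0.02  # per-sequence center jitter (uniform, frac)
    axis_jitter: float = 0.13  # relative axis jitter, uniform +/-
    rotation_max_deg: float = 9.0  # per-sequence silhouette tilt
    sector_half_angle_deg: float = 45.0
    sector_radius_frac: float = 0.95
    edge_softness_px: float = 1.5
    resample_speckle_per_frame: bool = True
    max_retries: int = 50

    def validate(self) -> None:
        if self.image_height < 64 or self.image_width < 64:
            raise ValueError("image dimensions must be >= 64")
        if self.frames_per_sequence < 1:
            raise ValueError("frames_per_sequence must be >= 1")
        for label, n in self.sequences_per_class.items():
            if n < 1:
                raise ValueError(f"sequences_per_class[{label}] must be >= 1")
        if self.baseline_speckle_sigma < 0:
            raise ValueError("baseline_speckle_sigma must be >= 0")
        if self.frames_per_class is not None:
            for label, n_seq in self.sequences_per_class.items():
                total = self.frames_per_class.get(label)
                if total is not None and total < n_seq:
                    raise ValueError(f"frames_per_class[{label}] < sequence count")


@dataclass
class Frame:
    """A single grayscale frame; values in [0, 1], zero outside the sector."""

    pixels: np.ndarray
    frame_id: str
    sequence_id: str
    frame_index: int


@dataclass
class Sequence:
    sequence_id: str
    view: View
    frames: list[Frame]


@dataclass
class PhantomGeometry:
    """One clip's sampled anatomy.

    Every view shares the same *cardiac silhouette* — a dark (blood-filled)
    rotated ellipse whose size, aspect, tilt and brightness vary per clip but
    whose distribution is identical across classes.  The view class is
    encoded purely in the *internal partition*: thin bright septal walls
    divide the silhouette into ``chamber_count`` cells (AV plane for all
    views; a full interventricular/interatrial septum for A4C/A5C; a partial
    septum below the AV plane for A3C; a small bright aortic-root ring with a
    dark lumen for A5C).  Class identity therefore lives in fine structure
    that the artifact simulators can destroy, while the coarse silhouette —
    which survives heavy degradation — carries no class information.

    ``u`` runs along the long (apex-to-base) axis, ``v`` along the short
    axis, both normalized so the silhouette boundary is the unit circle.
    """

    cy: float  # silhouette center, pixels
    cx: float
    ry: float  # semi-axes, pixels
    rx: float
    rotation: float  # radians, per-clip tilt
    tissue_gain: float  # per-clip overall gain (operator TGC surrogate)
    chamber_floor: float  # blood-pool intensity
    u_av: float  # AV-plane position (local units, >0 toward the atria)
    v_sep: float | None  # septum lateral position; None for A2C
    septum_full: bool  # full-span septum (A4C/A5C) vs below-AV only (A3C)
    root: tuple[float, float, float] | None  # (u0, v0, lumen radius px) A5C
    wall_px: float  # septal wall thickness, pixels


def _view_topology(view: View) -> tuple[bool, bool, bool]:
    """(has septum, septum is full-span, has aortic root) per view."""
    return {
        View.A2C: (False, False, False),
        View.A3C: (True, False, False),
        View.A4C: (True, True, False),
        View.A5C: (True, True, True),
    }[view]


def sector_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean fan mask: apex at top-center, opening downward."""
    H, W = config.image_height, config.image_width
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    apex_y, apex_x = 2.0, (W - 1) / 2.0
    dy = yy - apex_y
    dx = xx - apex_x
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(np.abs(dx), np.maximum(dy, 1e-9)))
    return (dy >= 0) & (radius <= config.sector_radius_frac * H) & (
        angle <= config.sector_half_angle_deg
    )


def _inside_sector(y: np.ndarray, x: np.ndarray, config: PhantomConfig, margin: float) -> np.ndarray:
    H, W = config.image_height, config.image_width
    apex_y, apex_x = 2.0, (W - 1) / 2.0
    dy = y - apex_y
    dx = x - apex_x
    radius = np.hypot(dx, dy)
    angle = np.degrees(np.arctan2(np.abs(dx), np.maximum(dy, 1e-9)))
    # shrink the admissible fan by `margin` pixels (approximate for the angle)
    ang_margin = np.degrees(margin / np.maximum(radius, 1.0))
    return (
        (dy >= margin)
        & (radius <= config.sector_radius_frac * H - margin)
        & (angle <= config.sector_half_angle_deg - ang_margin)
    )


def _silhouette_boundary(g: PhantomGeometry, scale: float, n: int = 96):
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    ey, ex = g.ry * scale * np.sin(t), g.rx * scale * np.cos(t)
    c, s = math.cos(g.rotation), math.sin(g.rotation)
    return g.cy + c * ey - s * ex, g.cx + s * ey + c * ex


def _geometry_valid(g: PhantomGeometry, config: PhantomConfig) -> bool:
    margin = config.motion_amplitude + 2.0
    grow = 1.0 + config.pulse_amplitude
    y, x = _silhouette_boundary(g, grow)
    if not np.all(_inside_sector(y, x, config, margin)):
        return False
    if g.root is not None:
        u0, v0, r_px = g.root
        ru = (r_px + g.wall_px) / g.ry
        rv = (r_px + g.wall_px) / g.rx
        # root ring (at its largest AV excursion) must stay inside the heart
        if math.hypot(abs(u0) + ru, abs(v0) + rv) > 0.9:
            return False
    return True


def sample_geometry(view: View, rng: np.random.Generator, config: PhantomConfig) -> PhantomGeometry:
    """Sample one clip's anatomy; rejected layouts (silhouette poking out of
    the sector, root ring too close to the wall) are resampled, bounded by
    ``config.max_retries``."""
    H, W = config.image_height, config.image_width
    size = min(H, W)
    wall_px = max(3.0, config.wall_thickness_frac * size) * rng.uniform(0.9, 1.25)
    has_sep, sep_full, has_root = _view_topology(view)
    for _ in range(config.max_retries):
        cy0, cx0 = config.silhouette_center
        ry0, rx0 = config.silhouette_axes
        j = config.center_jitter
        g = PhantomGeometry(
            cy=(cy0 + rng.uniform(-j, j)) * H,
            cx=(cx0 + rng.uniform(-j, j)) * W,
            ry=ry0 * H * (1.0 + rng.uniform(-config.axis_jitter, config.axis_jitter)),
            rx=rx0 * W * (1.0 + rng.uniform(-config.axis_jitter, config.axis_jitter)),
            rotation=math.radians(
                rng.uniform(-config.rotation_max_deg, config.rotation_max_deg)
            ),
            tissue_gain=rng.uniform(*config.gain_range),
            chamber_floor=config.chamber_intensity
            + rng.uniform(-config.chamber_floor_jitter, config.chamber_floor_jitter),
            u_av=rng.uniform(0.12, 0.32),
            v_sep=(
                rng.uniform(0.0, 0.2) if has_sep and not sep_full
                else rng.uniform(-0.12, 0.12) if has_sep else None
            ),
            septum_full=sep_full,
            root=None,
            wall_px=wall_px,
        )
        if has_root:
            g.root = (
                g.u_av - rng.uniform(0.28, 0.38),  # above the AV plane
                (g.v_sep or 0.0) + rng.uniform(-0.05, 0.05),
                rng.uniform(0.040, 0.058) * size,  # lumen radius, px
            )
        if _geometry_valid(g, config):
            return g
    raise RuntimeError(f"could not sample a valid {view.label} geometry "
                       f"in {config.max_retries} attempts")


def render_frame(
    view: View,
    phase: float,
    geometry: PhantomGeometry,
    rng: np.random.Generator,
    config: PhantomConfig,
    frame_id: str = "f00",
    sequence_id: str = "s000",
    frame_index: int = 0,
    jitter: tuple[float, float] = (0.0, 0.0),
    texture: np.ndarray | None = None,
) -> Frame:
    """Render one phantom frame at cardiac phase ``phase`` in [0, 1).

    The silhouette pulses sinusoidally with the cycle (whole-heart area
    modulation) and the AV plane shifts along the long axis, so every
    chamber cell's area is phase-modulated.  Tissue is multiplied by a
    per-frame lognormal speckle texture (mean 1, log-std
    ``baseline_speckle_sigma``).  Deterministic given the rng state.
    """
    has_sep, sep_full, has_root = _view_topology(view)
    if has_sep != (geometry.v_sep is not None) or has_root != (geometry.root is not None):
        raise ValueError(f"geometry does not match the {view.label} topology")
    H, W = config.image_height, config.image_width
    mask = sector_mask(config)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    dy_jit, dx_jit = jitter
    pulse = 1.0 + config.pulse_amplitude * math.sin(2 * math.pi * phase)
    ry_s, rx_s = geometry.ry * pulse, geometry.rx * pulse
    dy = yy - (geometry.cy + dy_jit)
    dx = xx - (geometry.cx + dx_jit)
    c, s = math.cos(geometry.rotation), math.sin(geometry.rotation)
    u = (c * dy + s * dx) / ry_s
    v = (-s * dy + c * dx) / rx_s
    interior = u * u + v * v <= 1.0

    u_av = geometry.u_av + config.av_motion_amplitude * math.sin(2 * math.pi * phase)
    walls = np.abs(u - u_av) <= 0.5 * geometry.wall_px / ry_s
    if geometry.v_sep is not None:
        septum = np.abs(v - geometry.v_sep) <= 0.5 * geometry.wall_px / rx_s
        if not geometry.septum_full:
            septum &= u > u_av
        walls |= septum
    dark = interior & ~walls
    if geometry.root is not None:
        u0, v0, r_px = geometry.root
        d2 = ((u - u0) * ry_s / r_px) ** 2 + ((v - v0) * rx_s / r_px) ** 2
        ring_outer = (r_px + geometry.wall_px) / r_px
        dark[(d2 > 1.0) & (d2 <= ring_outer**2)] = False  # bright root wall
        dark[d2 <= 1.0] = True  # dark root lumen

    # depth-dependent gain: mild attenuation with distance from the probe
    tissue = config.tissue_intensity * geometry.tissue_gain * (1.0 - 0.18 * yy / H)
    clean = np.where(dark, geometry.chamber_floor, tissue)
    if config.edge_softness_px > 0:
        from scipy.ndimage import gaussian_filter

        clean = gaussian_filter(clean, sigma=0.5 * config.edge_softness_px)

    sigma = config.baseline_speckle_sigma
    if texture is None:
        if sigma > 0:
            texture = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=(H, W)))
        else:
            texture = np.ones((H, W))
    pixels = np.clip(clean * texture, 0.0, 1.0)
    pixels[~mask] = 0.0
    return Frame(
        pixels=pixels.astype(np.float32),
        frame_id=frame_id,
        sequence_id=sequence_id,
        frame_index=frame_index,
    )


def count_chambers(pixels: np.ndarray, threshold_frac: float = 0.4, min_area: int = 25) -> int:
    """Count dark connected components inside the sector.

    Thresholds at ``threshold_frac`` of the mean in-sector intensity and
    discards specks below ``min_area`` pixels.
    """
    from skimage import measure

    sector = pixels > 0
    if not sector.any():
        return 0
    dark = sector & (pixels < threshold_frac * pixels[sector].mean())
    labeled = measure.label(dark, connectivity=1)
    sizes = np.bincount(labeled.ravel())
    return int(np.sum(sizes[1:] >= min_area))


def generate_sequence(
    view: View,
    seed: int | np.random.SeedSequence,
    config: PhantomConfig,
    sequence_id: str | None = None,
    n_frames: int | None = None,
) -> Sequence:
    """Generate one clip: frames share a geometry, rendered at phases k/n.

    The sampled geometry is verified once by rendering a probe frame and
    counting dark components; geometries that do not resolve into exactly
    ``chamber_count`` components are resampled (bounded retries).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    n = int(n_frames if n_frames is not None else config.frames_per_sequence)
    if n < 1:
        raise ValueError("a sequence needs at least one frame")
    sid = sequence_id or f"{view.label}_s000"

    geometry = None
    for _ in range(config.max_retries):
        candidate = sample_geometry(view, rng, config)
        probe = render_frame(view, 0.0, candidate, np.random.default_rng(0), config)
        if count_chambers(probe.pixels) == view.chamber_count:
            geometry = candidate
            break
    if geometry is None:
        raise RuntimeError(f"no geometry with {view.chamber_count} resolvable "
                           f"chambers after {config.max_retries} attempts")

    shared_texture = None
    if not config.resample_speckle_per_frame and config.baseline_speckle_sigma > 0:
        s = config.baseline_speckle_sigma
        shared_texture = np.exp(
            rng.normal(-0.5 * s**2, s, size=(config.image_height, config.image_width))
        )

    frames = []
    for k in range(n):
        a = config.motion_amplitude
        jitter = (rng.uniform(-a, a), rng.uniform(-a, a)) if a > 0 else (0.0, 0.0)
        frames.append(
            render_frame(
                view,
                phase=k / n,
                geometry=geometry,
                rng=rng,
                config=config,
                frame_id=f"{sid}_f{k:02d}",
                sequence_id=sid,
                frame_index=k,
                jitter=jitter,
                texture=shared_texture,
            )
        )
    return Sequence(sequence_id=sid, view=view, frames=frames)


def plan_dataset(config: PhantomConfig, seed: int = 0) -> list[tuple[str, View, int]]:
    """Per-sequence (sequence_id, view, n_frames) allocation.

    Each clip gets ``frames_per_sequence`` frames; when ``frames_per_class``
    pins an exact per-class total, the final clip of the class absorbs the
    remainder (it may be shorter or longer than the others).  Without exact
    totals, ``frame_count_jitter`` spreads clip lengths uniformly within
    +/- that many frames of the mean.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9A7]))
    plan = []
    for view in VIEWS:
        n_seq = config.sequences_per_class.get(view.label, 0)
        if n_seq == 0:
            continue
        per = config.frames_per_sequence
        if config.frames_per_class is None and config.frame_count_jitter > 0:
            j = min(config.frame_count_jitter, per - 1)
            counts = list(rng.integers(per - j, per + j + 1, size=n_seq))
        else:
            counts = [per] * n_seq
        if config.frames_per_class is not None:
            total = config.frames_per_class.get(view.label, per * n_seq)
            counts[-1] = total - per * (n_seq - 1)
            if counts[-1] < 1:
                raise ValueError(f"frame total for {view.label} too small for "
                                 f"{n_seq} sequences")
        for i, c in enumerate(counts):
            plan.append((f"{view.label}_s{i:03d}", view, int(c)))
    return plan


def iter_sequences(config: PhantomConfig, seed: int) -> Iterator[Sequence]:
    """Generate the full dataset lazily, one sequence at a time.

    Each sequence gets an independent child seed spawned from ``seed`` in a
    fixed order, so generation is reproducible and order-independent.
    """
    plan = plan_dataset(config, seed)
    children = np.random.SeedSequence(seed).spawn(len(plan))
    for (sid, view, n_frames), child in zip(plan, children):
        yield generate_sequence(view, child, config, sequence_id=sid, n_frames=n_frames)


def frame_to_png(frame: Frame, path: Path) -> None:
    arr = np.clip(np.round(frame.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def png_to_pixels(path: Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32)
    return arr / 255.0


def generate_dataset(config: PhantomConfig, seed: int, out_dir: Path | str):
    """Write the dataset to disk: one 8-bit grayscale PNG per frame plus a
    manifest (CSV and JSON).  Returns the manifest DataFrame."""
    import pandas as pd

    out = Path(out_dir)
    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for seq in iter_sequences(config, seed):
        seq_dir = frames_dir / seq.sequence_id
        seq_dir.mkdir(exist_ok=True)
        for fr in seq.frames:
            rel = Path("frames") / seq.sequence_id / f"{fr.frame_id}.png"
            frame_to_png(fr, out / rel)
            rows.append(
                {
                    "frame_id": fr.frame_id,
                    "sequence_id": fr.sequence_id,
                    "label": seq.view.label,
                    "frame_index": fr.frame_index,
                    "path": str(rel),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    manifest.to_json(out / "manifest.json", orient="records", indent=1)
    return manifest
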