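"""Parametric axial head phantoms with ground truth.

Each phantom is a 512x512 (configurable) axial slice pair — a T1-like and a
FLAIR-like channel — built from concentric ellipses: a bright skull
annulus, a dark subdural/CSF gap (optionally thin and broken), a
mid-intensity textured brain, and an optional hyperintense tumor blob.  The
confound that motivates skull stripping is reproduced on purpose: skull and
tumor share nearly the same T1 intensity.  The FLAIR channel is the same
anatomy with tumor contrast boosted and CSF suppressed, warped by a known
rigid offset, so registration can be scored against truth.

Gap discontinuities are modelled as short arc-shaped breaks (4-8 px each)
totalling ``gap_break_fraction`` of the gap pixels: long enough that a 3x3
window cannot bridge them — which is what forces the stripping loop to grow
its window — but short enough to close within a realistic iteration count.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import BinaryMask, GrayImage
from .registration import RigidTransform, warp

__all__ = ["PhantomSpec", "Phantom", "generate", "default_suite"]


class PhantomSpecError(ValueError):
    """Raised for geometrically impossible phantom specifications."""


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and corruption parameters of one phantom.

    Lengths are pixels, intensities are on [0, 1].  Defaults describe a
    512x512 slice at 0.5 mm pixels.  ``tumor_radius_px = 0`` means no
    tumor; ``tumor_center = None`` places the tumor off-centre inside the
    brain automatically.  The rigid offset (rotation about the image
    centre, translations in pixels) is applied to the FLAIR channel.
    """

    size: int = 512
    spacing_mm: float = 0.5
    skull_semi_axes: Tuple[float, float] = (190.0, 155.0)  # (row, col) semi-axes
    skull_thickness_px: float = 14.0
    gap_width_px: float = 3.0
    gap_break_fraction: float = 0.0
    brain_mean: float = 0.52
    brain_texture_sd: float = 0.05
    tumor_center: Optional[Tuple[float, float]] = None
    tumor_radius_px: float = 30.0
    tumor_intensity: float = 0.88
    necrotic_core_radius_px: float = 0.0
    skull_intensity: float = 0.90
    csf_intensity: float = 0.06
    background_intensity: float = 0.03
    noise_sd: float = 0.015
    bias_amplitude: float = 0.04
    rotation_deg: float = 0.0
    tx_px: float = 0.0
    ty_px: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 64:
            raise PhantomSpecError("size must be >= 64")
        if self.gap_width_px < 0:
            raise PhantomSpecError("gap_width_px must be >= 0")
        if not 0 <= self.gap_break_fraction < 1:
            raise PhantomSpecError("gap_break_fraction must be in [0, 1)")
        if self.tumor_radius_px < 0:
            raise PhantomSpecError("tumor_radius_px must be >= 0")
        a_r, a_c = self.skull_semi_axes
        inner_r = a_r - self.skull_thickness_px - self.gap_width_px
        inner_c = a_c - self.skull_thickness_px - self.gap_width_px
        if inner_r <= 8 or inner_c <= 8:
            raise PhantomSpecError("skull/gap geometry leaves no room for the brain")


@dataclasses.dataclass(frozen=True)
class Phantom:
    """A generated pair plus ground-truth masks (synthetic stand-ins for
    expert segmentations)."""

    t1: GrayImage
    flair: GrayImage
    true_transform: RigidTransform
    masks: Dict[str, BinaryMask]
    spec: PhantomSpec


def _ellipse(size: int, center: Tuple[float, float], semi: Tuple[float, float]) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(np.float64)
    if semi[0] <= 0 or semi[1] <= 0:
        return np.zeros((size, size), dtype=bool)
    return ((rr - center[0]) / semi[0]) ** 2 + ((cc - center[1]) / semi[1]) ** 2 <= 1.0


def _bias_field(size: int, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth second-order polynomial surface scaled to [-amplitude, amplitude]."""
    if amplitude == 0:
        return np.zeros((size, size))
    u = (np.arange(size) - size / 2) / (size / 2)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    coef = rng.uniform(-1.0, 1.0, size=6)
    surf = (
        coef[0] * uu
        + coef[1] * vv
        + coef[2] * uu * vv
        + coef[3] * uu * uu
        + coef[4] * vv * vv
        + coef[5]
    )
    peak = np.abs(surf).max()
    if peak == 0:
        return np.zeros((size, size))
    return amplitude * surf / peak


def _break_gap(
    gap: np.ndarray,
    center: Tuple[float, float],
    fraction: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Delete arc-shaped runs of gap pixels; return (remaining gap, bridges)."""
    if fraction <= 0 or not gap.any():
        return gap, np.zeros_like(gap)
    rows, cols = np.nonzero(gap)
    angles = np.arctan2(rows - center[0], cols - center[1])
    radius = np.hypot(rows - center[0], cols - center[1]).mean()
    n_gap = rows.size
    target = fraction * n_gap
    removed = np.zeros(n_gap, dtype=bool)
    guard = 0
    while removed.sum() < target and guard < 100:
        guard += 1
        arc_len_px = rng.uniform(4.0, 8.0)
        arc_half_angle = arc_len_px / (2.0 * radius)
        center_angle = rng.uniform(-np.pi, np.pi)
        delta = np.angle(np.exp(1j * (angles - center_angle)))
        removed |= np.abs(delta) <= arc_half_angle
    bridges = np.zeros_like(gap)
    bridges[rows[removed], cols[removed]] = True
    return gap & ~bridges, bridges


def generate(spec: PhantomSpec) -> Phantom:
    """Build one phantom from a spec (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    center = ((size - 1) / 2.0, (size - 1) / 2.0)
    a_r, a_c = spec.skull_semi_axes
    th = spec.skull_thickness_px
    gw = spec.gap_width_px

    head = _ellipse(size, center, (a_r, a_c))
    skull_inner = _ellipse(size, center, (a_r - th, a_c - th))
    brain_outer = _ellipse(size, center, (a_r - th - gw, a_c - th - gw))
    skull = head & ~skull_inner
    gap = skull_inner & ~brain_outer
    brain = brain_outer
    gap, bridges = _break_gap(gap, center, spec.gap_break_fraction, rng)

    if spec.tumor_radius_px > 0:
        if spec.tumor_center is None:
            ang = rng.uniform(0, 2 * np.pi)
            dist = 0.35 * min(a_r - th - gw, a_c - th - gw)
            t_center = (center[0] + dist * np.sin(ang), center[1] + dist * np.cos(ang))
        else:
            t_center = spec.tumor_center
        r = spec.tumor_radius_px
        margin_r = (a_r - th - gw) - r
        margin_c = (a_c - th - gw) - r
        if margin_r <= 0 or margin_c <= 0 or (
            ((t_center[0] - center[0]) / margin_r) ** 2
            + ((t_center[1] - center[1]) / margin_c) ** 2
            > 1.0
        ):
            raise PhantomSpecError("tumor does not fit inside the brain")
        tumor = _ellipse(size, t_center, (r, r))
        core = (
            _ellipse(size, t_center, (spec.necrotic_core_radius_px,) * 2)
            if spec.necrotic_core_radius_px > 0
            else np.zeros_like(tumor)
        )
    else:
        tumor = np.zeros_like(brain)
        core = np.zeros_like(brain)

    texture = rng.normal(0.0, spec.brain_texture_sd, size=(size, size))

    def compose(
        background: float,
        skull_i: float,
        csf_i: float,
        brain_i: float,
        tumor_i: float,
        core_i: float,
        texture_scale: float,
        bias_rng: np.random.Generator,
        noise_rng: np.random.Generator,
        offset: Optional[RigidTransform],
    ) -> GrayImage:
        img = np.full((size, size), background)
        img[skull] = skull_i
        img[gap] = csf_i
        img[brain] = brain_i
        img[bridges] = brain_i
        img[brain] += texture_scale * texture[brain]
        img[tumor] = tumor_i
        img[core] = core_i
        img += _bias_field(size, spec.bias_amplitude * brain_i, bias_rng) * head
        img = np.clip(img, 0.0, 1.0)
        gray = GrayImage(img, (spec.spacing_mm, spec.spacing_mm))
        if offset is not None and (
            offset.rotation_deg or offset.tx_mm or offset.ty_mm
        ):
            gray = warp(gray, offset)
        noisy = gray.pixels + noise_rng.normal(0.0, spec.noise_sd, size=(size, size))
        return GrayImage(np.clip(noisy, 0.0, 1.0), gray.spacing)

    true_transform = RigidTransform(
        spec.rotation_deg,
        spec.tx_px * spec.spacing_mm,
        spec.ty_px * spec.spacing_mm,
    )
    # independent, seed-derived streams so channel noise is uncorrelated
    t1 = compose(
        spec.background_intensity,
        spec.skull_intensity,
        spec.csf_intensity,
        spec.brain_mean,
        spec.tumor_intensity,
        0.40,
        1.0,
        np.random.default_rng(spec.seed + 1_000_003),
        np.random.default_rng(spec.seed + 2_000_003),
        None,
    )
    flair = compose(
        0.02,
        0.30,
        0.03,
        0.45,
        0.95,
        0.55,
        0.8,
        np.random.default_rng(spec.seed + 1_000_003),  # same scanner bias
        np.random.default_rng(spec.seed + 3_000_003),
        true_transform,
    )

    spacing = (spec.spacing_mm, spec.spacing_mm)
    masks = {
        "head": BinaryMask(head, spacing),
        "skull": BinaryMask(skull, spacing),
        "gap": BinaryMask(gap, spacing),
        "brain": BinaryMask(brain, spacing),
        "tumor": BinaryMask(tumor, spacing),
    }
    return Phantom(t1=t1, flair=flair, true_transform=true_transform, masks=masks, spec=spec)


def default_suite(n: int, base_seed: int = 1, size: int = 512) -> List[Phantom]:
    """The standard randomized phantom suite used for evaluation.

    Gap widths cycle through 3, 2, 1, 4 px with the 1-px cases broken
    (break fraction 0.1) — at least a quarter of the suite exercises the
    thin/discontinuous subdural space.  Every sixth phantom is tumor-free.
    Rigid offsets are drawn uniformly with rotation <= 10 degrees and
    translation <= 15 px per axis.  Phantom ``i`` uses seed
    ``base_seed + i``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scale = size / 512.0
    gap_cycle = [3.0, 2.0, 1.0, 4.0]
    phantoms = []
    for i in range(n):
        seed = base_seed + i
        rng = np.random.default_rng(seed)
        gap_w = max(gap_cycle[i % 4] * scale, 1.0)
        break_frac = 0.1 if i % 4 == 2 else 0.0  # the thin cases are broken too
        tumor_r = 0.0 if i % 6 == 5 else float(rng.uniform(18.0, 40.0)) * scale
        spec = PhantomSpec(
            size=size,
            skull_semi_axes=(
                (190.0 + float(rng.uniform(-10, 10))) * scale,
                (155.0 + float(rng.uniform(-10, 10))) * scale,
            ),
            skull_thickness_px=(14.0 + float(rng.uniform(-2, 2))) * scale,
            gap_width_px=gap_w,
            gap_break_fraction=break_frac,
            tumor_radius_px=tumor_r,
            rotation_deg=float(rng.uniform(-10, 10)),
            tx_px=float(rng.uniform(-15, 15)) * scale,
            ty_px=float(rng.uniform(-15, 15)) * scale,
            seed=seed,
        )
        phantoms.append(generate(spec))
    return phantoms
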