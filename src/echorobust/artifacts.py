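"""Parametric simulators of three ultrasound artifacts.

Each simulator maps a clean frame to a degraded frame and is an exact
identity at severity 0:

* **Motion blur** — horizontal 1-D convolution with a normalized line kernel
  of length ``L`` pixels (probe/patient displacement along one axis).  ``L``
  may be fractional: the kernel is a continuous box of width ``L`` sampled on
  the integer grid, so every grid value (step 2.5) is well defined and the
  taps always sum to one.
* **Acoustic shadowing** — a conical occlusion with vertex at the probe
  position (top-center) widening toward the bottom of the image; pixels
  inside the cone are *replaced* by low-level noise ``|eps|`` with
  ``eps ~ N(0, (f * mean(I))^2)``, mimicking the signal-free region behind a
  rib or prosthesis.  Severity is the base width of the cone as a fraction of
  the image width.
* **Speckle noise** — multiplicative Gaussian noise,
  ``I_noisy = I + I * N(0, sigma^2)``, the standard signal-dependent speckle
  model; severity is the dimensionless standard deviation ``sigma``.

All outputs are clipped to [0, 1].  ``apply_artifact`` derives a per-frame
rng deterministically from (base seed, frame id, family, severity), so runs
are reproducible and frames are mutually independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from echorobust.phantom import Frame

FAMILIES = ("motion_blur", "acoustic_shadow", "speckle")

# severity ranges of the degradation protocol
SEVERITY_RANGES = {
    "motion_blur": (0.0, 20.0),
    "acoustic_shadow": (0.0, 0.7),
    "speckle": (0.0, 3.0),
}


@dataclass(frozen=True)
class BlurKernel:
    """Normalized horizontal line kernel; taps are symmetric and sum to 1."""

    L: float
    taps: np.ndarray


@dataclass(frozen=True)
class ShadowSpec:
    width_fraction: float
    epsilon_sigma_fraction: float = 0.03  # noise std as fraction of mean brightness

    def __post_init__(self):
        if not 0.0 <= self.width_fraction <= 1.0:
            raise ValueError("width_fraction must be in [0, 1]")
        if self.epsilon_sigma_fraction < 0:
            raise ValueError("epsilon_sigma_fraction must be >= 0")

    def opening_angle(self, H: int, W: int) -> float:
        """Cone opening angle (radians), derived from the base width: the
        severity parameter is the width, never the angle."""
        return 2.0 * np.arctan(self.width_fraction * W / (2.0 * H))


@dataclass(frozen=True)
class SpeckleSpec:
    noise_amount: float  # dimensionless sigma of the multiplicative Gaussian

    def __post_init__(self):
        if self.noise_amount < 0:
            raise ValueError("noise_amount must be >= 0")


@dataclass(frozen=True)
class ArtifactSpec:
    """One point of the degradation protocol: an artifact family + severity."""

    family: str
    severity: float

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown artifact family {self.family!r}")
        lo, hi = SEVERITY_RANGES[self.family]
        if not lo <= self.severity <= hi:
            raise ValueError(
                f"{self.family} severity {self.severity} outside [{lo}, {hi}]"
            )


def build_blur_kernel(L: float) -> BlurKernel:
    """Sample a continuous box of width ``L`` on the integer pixel grid.

    Tap ``i`` receives the overlap of the unit cell ``[i-1/2, i+1/2]`` with
    the box ``[-L/2, L/2]``, divided by ``L``.  ``L <= 1`` collapses to the
    identity kernel.
    """
    if L < 0:
        raise ValueError("blur length must be >= 0")
    if L <= 1.0:
        return BlurKernel(L=L, taps=np.array([1.0]))
    half = L / 2.0
    m = int(np.ceil(half - 0.5))
    offsets = np.arange(-m, m + 1)
    lo = np.maximum(offsets - 0.5, -half)
    hi = np.minimum(offsets + 0.5, half)
    taps = np.maximum(hi - lo, 0.0) / L
    return BlurKernel(L=L, taps=taps)


def motion_blur(frame: Frame, L: float) -> Frame:
    """Horizontal blur with reflect border handling; identity at ``L <= 1``."""
    kernel = build_blur_kernel(L)
    if kernel.taps.size == 1:
        return replace(frame, pixels=frame.pixels.copy())
    out = ndimage.convolve1d(
        frame.pixels.astype(np.float64), kernel.taps, axis=1, mode="reflect"
    )
    return replace(frame, pixels=np.clip(out, 0.0, 1.0).astype(np.float32))


def shadow_mask(H: int, W: int, wf: float) -> np.ndarray:
    """Filled triangle: vertex at top-center, base of width ``wf * W`` on the
    bottom row.  Row ``y`` masks columns within ``(wf*W/2) * y/(H-1)`` of the
    center; ``wf = 0`` is the empty mask."""
    if H < 1 or W < 1:
        raise ValueError("mask dimensions must be >= 1")
    if not 0.0 <= wf <= 1.0:
        raise ValueError("width fraction must be in [0, 1]")
    if wf == 0.0:
        return np.zeros((H, W), dtype=bool)
    center = (W - 1) / 2.0
    cols = np.abs(np.arange(W) - center)
    depth = np.arange(H) / max(H - 1, 1)
    halfwidth = (wf * W / 2.0) * depth
    return cols[None, :] <= halfwidth[:, None]


def acoustic_shadow(frame: Frame, spec: ShadowSpec, rng: np.random.Generator) -> Frame:
    """Replace pixels inside the cone by ``|eps|``, eps ~ N(0, (f*mean I)^2)."""
    pixels = frame.pixels.astype(np.float64)
    H, W = pixels.shape
    mask = shadow_mask(H, W, spec.width_fraction)
    if not mask.any():
        return replace(frame, pixels=frame.pixels.copy())
    sigma = spec.epsilon_sigma_fraction * float(pixels.mean())
    out = pixels.copy()
    if sigma > 0:
        out[mask] = np.abs(rng.normal(0.0, sigma, size=int(mask.sum())))
    else:
        out[mask] = 0.0
    return replace(frame, pixels=np.clip(out, 0.0, 1.0).astype(np.float32))


def speckle(frame: Frame, spec: SpeckleSpec, rng: np.random.Generator) -> Frame:
    """Multiplicative Gaussian speckle: ``I * (1 + z)``, z ~ N(0, sigma^2)."""
    if spec.noise_amount == 0.0:
        return replace(frame, pixels=frame.pixels.copy())
    pixels = frame.pixels.astype(np.float64)
    z = rng.normal(0.0, spec.noise_amount, size=pixels.shape)
    out = pixels * (1.0 + z)
    return replace(frame, pixels=np.clip(out, 0.0, 1.0).astype(np.float32))


def _frame_rng(base_seed: int, frame_id: str, family: str, severity: float) -> np.random.Generator:
    """Deterministic, frame-independent rng for the stochastic simulators."""
    key = f"{frame_id}|{family}|{severity:.6g}".encode()
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.default_rng([int(base_seed), int.from_bytes(digest, "big")])


def apply_artifact(frame: Frame, spec: ArtifactSpec, base_seed: int = 0) -> Frame:
    """Dispatch to the family simulator; severity 0 is a pixel-identical copy."""
    if spec.family == "motion_blur":
        return motion_blur(frame, spec.severity)
    rng = _frame_rng(base_seed, frame.frame_id, spec.family, spec.severity)
    if spec.family == "acoustic_shadow":
        return acoustic_shadow(frame, ShadowSpec(width_fraction=spec.severity), rng)
    if spec.family == "speckle":
        return speckle(frame, SpeckleSpec(noise_amount=spec.severity), rng)
    raise ValueError(f"unknown artifact family {spec.family!r}")
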