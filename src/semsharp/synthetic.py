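"""Synthetic micrograph-like fixtures with controlled structure and blur.

Real SEM micrographs of polished samples combine piecewise-constant regions
with strong boundaries (the cartoon structure), dense oscillatory texture,
and sensor noise.  The generator emulates exactly those ingredients: random
discs and rectangles with distinct gray levels, sinusoidal texture confined
to a random subset of regions, and additive Gaussian noise.  A blur series
convolves one scene with Gaussian PSFs of increasing scale, with noise
added after blurring so the series varies only focus - mirroring a
defocus series acquired at fixed detector settings.  Pseudo-MOS ground
truth is ordinal: blur rank reversed.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import ndimage

from .io import Micrograph

DEFAULT_BLUR_SIGMAS = (0.0, 1.0, 2.0, 3.0)


@dataclasses.dataclass
class SceneSpec:
    """Parameters of one synthetic micrograph scene.

    Defaults describe a realistic mid-magnification micrograph: a handful
    of grain-like regions with strong boundaries, visible but subordinate
    texture, and mild sensor noise (sigma 2 on the 0-255 scale).  The
    texture defaults (peak-to-peak 24 at 0.125 cycles/pixel) keep local
    texture gradients (~9 gray/px) below the smoothed gradient response of
    strong region boundaries, the edge-dominated regime this kind of
    micrograph occupies; texture whose gradients rival the edges would make
    the decomposition classify the boundaries themselves as texture.
    """

    size: tuple[int, int] = (256, 256)
    n_shapes: int = 6
    texture_amplitude: float = 24.0
    texture_frequency: float = 0.125
    noise_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.size) < 128:
            raise ValueError("scenes must be at least 128x128")
        if not 0.0 < self.texture_frequency <= 0.5:
            raise ValueError("texture_frequency must lie in (0, 0.5]")
        if self.n_shapes < 0 or self.texture_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("counts and amplitudes must be non-negative")


@dataclasses.dataclass
class BlurSeries:
    """One scene rendered at graded Gaussian blur levels."""

    scene: SceneSpec
    blur_sigmas: tuple[float, ...]
    images: list[Micrograph]
    pseudo_mos: np.ndarray

    def __post_init__(self) -> None:
        sigmas = np.asarray(self.blur_sigmas, dtype=np.float64)
        if sigmas[0] != 0.0 or np.any(np.diff(sigmas) <= 0):
            raise ValueError("blur_sigmas must be strictly increasing from 0")
        if np.any(np.diff(self.pseudo_mos) >= 0):
            raise ValueError("pseudo_mos must be strictly decreasing")


def _render_parts(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (clean scene, noise field) pair for one spec."""
    rng = np.random.default_rng(spec.seed)
    m, n = spec.size
    rows, cols = np.mgrid[0:m, 0:n]

    background = rng.uniform(60.0, 100.0)
    img = np.full((m, n), background)
    labels = np.zeros((m, n), dtype=np.intp)

    # distinct, well-separated gray levels for the shapes
    levels = rng.permutation(np.linspace(20.0, 235.0, max(spec.n_shapes, 1)))
    for k in range(spec.n_shapes):
        kind = rng.integers(0, 2)
        if kind == 0:  # disc
            cy, cx = rng.uniform(0.15, 0.85, 2) * (m, n)
            r = rng.uniform(0.08, 0.22) * min(m, n)
            region = (rows - cy) ** 2 + (cols - cx) ** 2 <= r * r
        else:  # axis-aligned rectangle
            h = rng.uniform(0.12, 0.35) * m
            w = rng.uniform(0.12, 0.35) * n
            top = rng.uniform(0.05, 0.9) * (m - h)
            left = rng.uniform(0.05, 0.9) * (n - w)
            region = ((rows >= top) & (rows < top + h)
                      & (cols >= left) & (cols < left + w))
        img[region] = levels[k]
        labels[region] = k + 1

    if spec.texture_amplitude > 0:
        # sinusoidal texture on a random subset of regions (incl. background)
        textured = rng.random(spec.n_shapes + 1) < 0.5
        textured[rng.integers(0, spec.n_shapes + 1)] = True  # at least one
        phi = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        carrier = np.sin(
            2 * np.pi * spec.texture_frequency
            * (rows * np.sin(phi) + cols * np.cos(phi)) + phase)
        tex_mask = textured[labels]
        img = img + np.where(tex_mask,
                             0.5 * spec.texture_amplitude * carrier, 0.0)

    noise = rng.normal(0.0, spec.noise_sigma, (m, n)) if spec.noise_sigma > 0 \
        else np.zeros((m, n))
    return np.clip(img, 0.0, 255.0), noise


def render_scene(spec: SceneSpec) -> Micrograph:
    """Render one scene (cartoon structure + texture + noise), clipped to [0, 255]."""
    clean, noise = _render_parts(spec)
    pixels = np.clip(clean + noise, 0.0, 255.0)
    return Micrograph(pixels=pixels, intensity_scale=255.0,
                      identifier=f"scene-seed{spec.seed}-blur0")


def make_blur_series(spec: SceneSpec,
                     blur_sigmas: Sequence[float] = DEFAULT_BLUR_SIGMAS
                     ) -> BlurSeries:
    """Render one scene under graded Gaussian defocus blur.

    The clean scene is blurred at each PSF scale and the same noise field
    is added afterwards, so only focus varies across the series.  The
    sigma-0 image is identical to :func:`render_scene` output.
    """
    sigmas = tuple(float(s) for s in blur_sigmas)
    if not sigmas or sigmas[0] != 0.0 or any(
            b <= a for a, b in zip(sigmas, sigmas[1:])):
        raise ValueError("blur_sigmas must be strictly increasing from 0")
    clean, noise = _render_parts(spec)
    images = []
    for s in sigmas:
        blurred = clean if s == 0.0 else ndimage.gaussian_filter(
            clean, s, mode="nearest", radius=int(np.ceil(4 * s)))
        pixels = np.clip(blurred + noise, 0.0, 255.0)
        images.append(Micrograph(
            pixels=pixels, intensity_scale=255.0,
            identifier=f"scene-seed{spec.seed}-blur{s:g}"))
    pseudo_mos = np.arange(len(sigmas), 0, -1, dtype=np.float64)
    return BlurSeries(scene=spec, blur_sigmas=sigmas, images=images,
                      pseudo_mos=pseudo_mos)


def make_power_law_field(size: tuple[int, int], alpha: float,
                         seed: int) -> Micrograph:
    """Random-phase field whose amplitude spectrum decays as f^-alpha.

    Used as the parameter-recovery fixture for the spectral-slope
    estimator: the log-log radial amplitude profile of the field is a
    straight line with slope -alpha.
    """
    if not 0.5 <= alpha <= 4.0:
        raise ValueError("alpha must lie in [0.5, 4]")
    rng = np.random.default_rng(seed)
    m, n = size
    fy = np.fft.fftfreq(m)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    radius = np.hypot(fy, fx)
    amp = np.zeros((m, n))
    np.divide(1.0, radius ** alpha, out=amp, where=radius > 0)
    spectrum = amp * (rng.standard_normal((m, n))
                      + 1j * rng.standard_normal((m, n)))
    field = np.real(np.fft.ifft2(spectrum))
    lo, hi = field.min(), field.max()
    pixels = (field - lo) / (hi - lo) * 255.0 if hi > lo else np.zeros((m, n))
    return Micrograph(pixels=pixels, intensity_scale=255.0,
                      identifier=f"powerlaw-a{alpha:g}-seed{seed}")


#: The five standard scene parameterizations of the calibration suite:
#: variations of shape count and texture strength/frequency, all inside the
#: edge-dominated regime (texture gradients below boundary responses).
SCENE_VARIANTS: tuple[dict, ...] = (
    dict(n_shapes=6, texture_amplitude=24.0, texture_frequency=0.125),
    dict(n_shapes=4, texture_amplitude=16.0, texture_frequency=0.125),
    dict(n_shapes=8, texture_amplitude=24.0, texture_frequency=0.1),
    dict(n_shapes=6, texture_amplitude=12.0, texture_frequency=0.15),
    dict(n_shapes=5, texture_amplitude=20.0, texture_frequency=0.125),
)


def fixture_suite(n_scenes: int = 5, n_seeds: int = 3,
                  blur_sigmas: Sequence[float] = DEFAULT_BLUR_SIGMAS,
                  size: tuple[int, int] = (256, 256)) -> list[BlurSeries]:
    """The standard graded-blur calibration suite: scenes x seeds x blur levels.

    Each scene is a distinct parameterization (shape count, texture
    strength and frequency); each seed is an independent random
    realization of its geometry, texture placement and noise.
    """
    suite = []
    for scene_idx in range(n_scenes):
        variant = SCENE_VARIANTS[scene_idx % len(SCENE_VARIANTS)]
        for seed_idx in range(n_seeds):
            spec = SceneSpec(size=size, seed=1000 * scene_idx + seed_idx,
                             **variant)
            suite.append(make_blur_series(spec, blur_sigmas))
    return suite
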