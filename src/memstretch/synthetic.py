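"""Synthetic test data with known ground truth.

Two generators emulate the raw inputs of a stretch-device experiment:

* fibrous-texture images whose fiber axes follow an axial von Mises
  distribution with controllable concentration ``kappa`` — stand-ins for
  phalloidin-stained F-actin micrographs;
* bead image pairs related by a known affine deformation with sub-pixel
  localisation jitter — stand-ins for microsphere calibration recordings.

Every generator takes an explicit seed and returns the ground truth next to
the rendered image, so recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberImageSpec",
    "BeadImageSpec",
    "sample_axial_von_mises",
    "render_fiber_image",
    "render_bead_pair",
]


@dataclass(frozen=True)
class FiberImageSpec:
    """Fibrous texture: straight anti-aliased segments on a noisy background."""

    shape: tuple[int, int] = (256, 256)
    n_fibers: int = 120
    mean_axis: float = 0.0  # degrees in [0, 180)
    kappa: float = 2.0  # axial von Mises concentration, >= 0
    fiber_length: float = 60.0  # px
    fiber_width: float = 2.0  # px (drawn by repeated offset strokes)
    fiber_intensity: float = 0.8
    background: float = 0.05
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")
        if self.n_fibers < 0:
            raise ValueError("n_fibers must be non-negative")


@dataclass(frozen=True)
class BeadImageSpec:
    """Paired bead images under a known affine map ``x' = F x + c``."""

    shape: tuple[int, int] = (256, 256)
    n_beads: int = 100
    psf_sigma: float = 1.5  # px
    deformation_gradient: tuple[tuple[float, float], tuple[float, float]] = (
        (1.0, 0.0),
        (0.0, 1.0),
    )
    translation: tuple[float, float] = (0.0, 0.0)
    jitter_sd: float = 0.0  # localisation jitter on deformed positions, px
    noise_sd: float = 0.01  # additive image noise
    min_separation: float = 8.0  # px between bead centres
    margin: float = 20.0  # keep-out border so deformed beads stay in frame
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.deformation_gradient, float)
        if f.shape != (2, 2) or abs(np.linalg.det(f)) < 1e-12:
            raise ValueError("deformation gradient must be an invertible 2x2 matrix")


def sample_axial_von_mises(
    n: int, mean_axis: float, kappa: float, seed: int | np.random.Generator
) -> np.ndarray:
    """Axial von Mises sample: angles in degrees on [0, 180).

    Draws ``phi ~ vonMises(2 * mean_axis, kappa)`` on the circle and returns
    ``phi / 2`` — the standard angle-doubling construction for axial data.
    ``kappa = 0`` reduces to the uniform axial distribution, and the expected
    resultant length on doubled angles is the Bessel ratio ``I1(k)/I0(k)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phi = rng.vonmises(np.radians(2.0 * mean_axis), kappa, size=n)
    return np.mod(np.degrees(phi) / 2.0, 180.0)


def render_fiber_image(spec: FiberImageSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render a fiber image; returns ``(image, true_fiber_angles_deg)``.

    Fibers are drawn as anti-aliased segments with additive intensity and
    clipping at 1; centres are uniform over the frame, axes are sampled from
    the axial von Mises law of the spec.  ``n_fibers = 0`` yields pure noise.
    """
    from skimage.draw import line_aa

    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    img = np.full((h, w), spec.background, dtype=float)
    angles = (
        sample_axial_von_mises(spec.n_fibers, spec.mean_axis, spec.kappa, rng)
        if spec.n_fibers
        else np.empty(0)
    )
    centers = rng.uniform(0, [h, w], size=(spec.n_fibers, 2))
    n_strokes = max(1, int(round(spec.fiber_width)))
    for (cy, cx), ang in zip(centers, angles):
        # x = column axis, angle measured from x toward y (rows)
        dx = np.cos(np.radians(ang)) * spec.fiber_length / 2
        dy = np.sin(np.radians(ang)) * spec.fiber_length / 2
        # offset strokes perpendicular to the axis emulate fiber width
        px, py = -np.sin(np.radians(ang)), np.cos(np.radians(ang))
        for k in range(n_strokes):
            off = k - (n_strokes - 1) / 2
            r0 = int(round(cy - dy + off * py))
            c0 = int(round(cx - dx + off * px))
            r1 = int(round(cy + dy + off * py))
            c1 = int(round(cx + dx + off * px))
            rr, cc, val = line_aa(r0, c0, r1, c1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[keep], cc[keep]] += spec.fiber_intensity * val[keep]
    img = np.clip(img, 0.0, 1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img, angles


def _place_beads(rng: np.random.Generator, spec: BeadImageSpec) -> np.ndarray:
    """Uniform bead positions (x, y) with a minimum pairwise separation."""
    h, w = spec.shape
    lo = spec.margin
    hix, hiy = w - spec.margin, h - spec.margin
    area = max(hix - lo, 0) * max(hiy - lo, 0)
    if area <= 0 or spec.n_beads * spec.min_separation**2 > area:
        raise ValueError("bead density incompatible with the minimum separation")
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < spec.n_beads:
        attempts += 1
        if attempts > 200 * spec.n_beads:
            raise ValueError("bead density incompatible with the minimum separation")
        cand = rng.uniform([lo, lo], [hix, hiy])
        if all(np.hypot(*(cand - p)) >= spec.min_separation for p in pts):
            pts.append(cand)
    return np.array(pts)


def _render_spots(positions: np.ndarray, spec: BeadImageSpec, rng) -> np.ndarray:
    h, w = spec.shape
    img = np.zeros((h, w), dtype=float)
    half = int(np.ceil(4 * spec.psf_sigma))
    for x, y in positions:
        r0 = max(0, int(y) - half)
        r1 = min(h, int(y) + half + 1)
        c0 = max(0, int(x) - half)
        c1 = min(w, int(x) + half + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        img[r0:r1, c0:c1] += np.exp(
            -((cols - x) ** 2 + (rows - y) ** 2) / (2 * spec.psf_sigma**2)
        )
    img = np.clip(img, 0.0, 1.0)
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    return img


def render_bead_pair(
    spec: BeadImageSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Render a reference/deformed bead image pair.

    Deformation is applied about the image centre: ``x' = F (x - m) + m + c``
    with jitter added to the deformed positions.  Returns
    ``(ref_image, def_image, F, ref_positions, def_positions)`` where
    positions are exact sub-pixel ground truth in (x, y) pixel coordinates.
    """
    rng = np.random.default_rng(spec.seed)
    f = np.asarray(spec.deformation_gradient, float)
    ref = _place_beads(rng, spec)
    mid = np.array([spec.shape[1] / 2.0, spec.shape[0] / 2.0])
    deformed = (ref - mid) @ f.T + mid + np.asarray(spec.translation, float)
    if spec.jitter_sd > 0:
        deformed = deformed + rng.normal(0.0, spec.jitter_sd, deformed.shape)
    img_ref = _render_spots(ref, spec, rng)
    img_def = _render_spots(deformed, spec, rng)
    return img_ref, img_def, f, ref, deformed
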