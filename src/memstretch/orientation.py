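"""Structure-tensor quantification of fiber alignment in micrographs.

F-actin stress fibers in phalloidin-stained images are axial data: a fiber
at angle ``theta`` is indistinguishable from ``theta + 180``.  Local fiber
direction is taken from the structure tensor (the Gaussian-smoothed outer
product of the intensity gradient): the eigenvector of the *smaller*
eigenvalue points along the fiber (least intensity variation), and the
eigenvalue contrast gives a 0-1 coherence.  Summary statistics use circular
statistics on doubled angles: the resultant length ``R`` (0 = random,
1 = perfectly aligned), the mean axis, and the circular standard deviation
``sqrt(-2 ln R)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OrientationField",
    "AlignmentStats",
    "structure_tensor",
    "orientation_and_coherence",
    "axial_stats",
    "alignment_stats",
    "rose_histogram",
    "relative_change",
    "circular_sd",
    "analyze_image",
]


@dataclass(frozen=True)
class OrientationField:
    """Per-pixel fiber axis (degrees in [0, 180)) and coherence in [0, 1]."""

    theta: np.ndarray
    coherence: np.ndarray
    mask: np.ndarray


@dataclass(frozen=True)
class AlignmentStats:
    """Axial summary statistics of an orientation field or angle sample."""

    R: float
    mean_axis: float
    circ_sd: float
    n_effective: float
    rose_edges: np.ndarray
    rose_weights: np.ndarray


def structure_tensor(
    image: np.ndarray, sigma_gradient: float = 1.5, sigma_window: float = 6.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed structure-tensor components ``(Jxx, Jxy, Jyy)``.

    Gradients are derivative-of-Gaussian filters at ``sigma_gradient``; the
    outer-product components are then averaged with a Gaussian window at
    ``sigma_window``.  ``x`` is the column axis, ``y`` the row axis.
    """
    from scipy.ndimage import gaussian_filter

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("structure_tensor expects a single-channel image")
    if sigma_gradient <= 0 or sigma_window <= 0:
        raise ValueError("sigmas must be positive")
    if min(img.shape) < int(4 * sigma_window) + 1:
        raise ValueError("image smaller than the smoothing-kernel support")
    gx = gaussian_filter(img, sigma_gradient, order=(0, 1))
    gy = gaussian_filter(img, sigma_gradient, order=(1, 0))
    jxx = gaussian_filter(gx * gx, sigma_window)
    jxy = gaussian_filter(gx * gy, sigma_window)
    jyy = gaussian_filter(gy * gy, sigma_window)
    return jxx, jxy, jyy


def orientation_and_coherence(
    jxx: np.ndarray, jxy: np.ndarray, jyy: np.ndarray, trace_eps: float = 0.0
) -> OrientationField:
    """Eigen-decomposition of the structure tensor, per pixel.

    The dominant eigenvector of ``J`` is the direction of fastest intensity
    variation (across fibers); the fiber axis is perpendicular to it:
    ``theta = atan2(2 Jxy, Jxx - Jyy)/2 + 90`` reduced modulo 180.  Coherence
    is ``(l1 - l2)/(l1 + l2)``, set to 0 where the trace vanishes.
    """
    theta = np.degrees(0.5 * np.arctan2(2.0 * jxy, jxx - jyy)) + 90.0
    theta = np.mod(theta, 180.0)
    trace = jxx + jyy
    spread = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(trace > trace_eps, spread / np.where(trace > 0, trace, 1.0), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    return OrientationField(theta=theta, coherence=coherence, mask=np.ones_like(theta, bool))


def axial_stats(
    angles_deg: np.ndarray,
    weights: np.ndarray | None = None,
    n_bins: int = 18,
    sd_convention: str = "doubled",
) -> AlignmentStats:
    """Circular statistics of axial angles (degrees, modulo 180).

    Angles are doubled onto the full circle; ``R`` is the weighted resultant
    length, the mean axis is half the resultant angle, and the circular SD is
    ``sqrt(-2 ln R)`` in the doubled-angle convention (``"axial"`` halves it).
    """
    ang = np.asarray(angles_deg, dtype=float).ravel()
    if ang.size == 0:
        raise ValueError("no angles supplied")
    w = np.ones_like(ang) if weights is None else np.asarray(weights, float).ravel()
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all weights are zero")
    phi = np.radians(2.0 * ang)
    c = float((w * np.cos(phi)).sum() / wsum)
    s = float((w * np.sin(phi)).sum() / wsum)
    r = float(np.hypot(c, s))
    mean_axis = float(np.mod(np.degrees(0.5 * np.arctan2(s, c)), 180.0))
    sd = circular_sd(r, convention=sd_convention) if r > 0 else float("inf")
    edges, rose = rose_histogram(ang, n_bins=n_bins, weights=w)
    return AlignmentStats(
        R=r,
        mean_axis=mean_axis,
        circ_sd=sd,
        n_effective=float(wsum),
        rose_edges=edges,
        rose_weights=rose,
    )


def circular_sd(r: float, convention: str = "doubled") -> float:
    """Circular standard deviation in degrees implied by a resultant length R.

    ``"doubled"`` applies ``sqrt(-2 ln R)`` directly to the doubled-angle
    resultant (the convention that reproduces the published index/SD pairs);
    ``"axial"`` halves it to map the dispersion back to axis space.
    """
    if not (0 < r <= 1):
        raise ValueError("R must lie in (0, 1]")
    sd = np.degrees(np.sqrt(max(-2.0 * np.log(r), 0.0)))
    if convention == "doubled":
        return float(sd)
    if convention == "axial":
        return float(sd / 2.0)
    raise ValueError(f"unknown convention {convention!r}")


def alignment_stats(
    of: OrientationField,
    weighting: str = "coherence",
    n_bins: int = 18,
    sd_convention: str = "doubled",
) -> AlignmentStats:
    """Axial statistics of an orientation field over its analysis mask."""
    m = of.mask.astype(bool)
    if not m.any():
        raise ValueError("orientation mask selects no pixels")
    if weighting == "coherence":
        w = of.coherence[m]
    elif weighting == "uniform":
        w = np.ones(int(m.sum()))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return axial_stats(of.theta[m], w, n_bins=n_bins, sd_convention=sd_convention)


def rose_histogram(
    angles_deg: np.ndarray, n_bins: int = 18, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Axial histogram over [0, 180) with weights normalised to sum 1.

    Returns ``(bin_edges, weights)``; a rose plot mirrors each bin at +180
    for display only, so the histogram itself lives on the half-circle.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    ang = np.mod(np.asarray(angles_deg, float).ravel(), 180.0)
    hist, edges = np.histogram(ang, bins=n_bins, range=(0.0, 180.0), weights=weights)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return edges, hist


def relative_change(r_baseline: float, r_condition: float) -> float:
    """Percent change of the alignment index relative to a baseline."""
    if r_baseline == 0:
        raise ValueError("baseline alignment index must be non-zero")
    return 100.0 * (r_condition - r_baseline) / r_baseline


def orientation_mask(
    image: np.ndarray,
    of: OrientationField,
    coherence_floor: float = 0.2,
    intensity_rule: str = "otsu",
) -> np.ndarray:
    """Analysis mask: coherent pixels on foreground (fiber) intensity.

    Background is excluded by Otsu thresholding of the image (or kept
    entirely with ``intensity_rule="none"``); pixels with coherence at or
    below ``coherence_floor`` are dropped as directionally uninformative.
    """
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    mask = of.coherence > coherence_floor
    if intensity_rule == "otsu":
        if np.ptp(img) > 0:
            mask &= img > threshold_otsu(img)
    elif intensity_rule != "none":
        raise ValueError(f"unknown intensity_rule {intensity_rule!r}")
    return mask


def analyze_image(
    image: np.ndarray,
    sigma_gradient: float = 1.5,
    sigma_window: float = 6.0,
    weighting: str = "coherence",
    coherence_floor: float = 0.2,
    intensity_rule: str = "otsu",
    n_bins: int = 18,
    sd_convention: str = "doubled",
) -> tuple[OrientationField, AlignmentStats]:
    """Full per-image pipeline: structure tensor -> orientations -> statistics."""
    jxx, jxy, jyy = structure_tensor(image, sigma_gradient, sigma_window)
    of = orientation_and_coherence(jxx, jxy, jyy)
    mask = orientation_mask(image, of, coherence_floor, intensity_rule)
    if not mask.any():  # fall back to coherence-only mask on dim images
        mask = of.coherence > coherence_floor
    of = OrientationField(theta=of.theta, coherence=of.coherence, mask=mask)
    return of, alignment_stats(of, weighting=weighting, n_bins=n_bins, sd_convention=sd_convention)
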