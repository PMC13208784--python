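"""Membrane strain from fluorescent bead tracking.

Micron-scale fluorescent beads seeded on the membrane surface are imaged
before and at peak vacuum; their displacements encode the in-plane
deformation of the culture surface.  The pipeline is: sub-pixel bead
detection in each frame, mutual-nearest-neighbour matching between frames,
and a least-squares affine fit ``x' = F x + c`` whose deformation gradient
``F`` yields Green-Lagrange strain and the scalar "average strain"
(mean principal engineering strain) used to calibrate the device.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BeadSet",
    "BeadMatches",
    "StrainEstimate",
    "detect_beads",
    "match_beads",
    "fit_deformation",
    "local_strain_map",
    "iterative_affine_match",
    "matches_apply",
    "BeadTrackingModel",
]


@dataclass(frozen=True)
class BeadSet:
    """Sub-pixel bead centroids, pixel coordinates (x = column, y = row)."""

    centroids: np.ndarray  # (n, 2)
    intensities: np.ndarray  # (n,)

    def __len__(self) -> int:
        return len(self.centroids)


@dataclass(frozen=True)
class BeadMatches:
    """One-to-one correspondences between a reference and a deformed set."""

    ref_index: np.ndarray
    def_index: np.ndarray
    ref_xy: np.ndarray
    def_xy: np.ndarray

    def __len__(self) -> int:
        return len(self.ref_index)

    @property
    def displacements(self) -> np.ndarray:
        return self.def_xy - self.ref_xy


@dataclass(frozen=True)
class StrainEstimate:
    """Affine deformation recovered from matched beads.

    ``deformation_gradient`` is the 2x2 ``F`` of ``x' = F x + c``;
    ``green_strain = (F^T F - I)/2``; ``engineering_avg_strain`` is the mean
    of the two principal stretches (singular values of ``F``) minus one,
    i.e. the single-number strain the device calibration quotes.
    """

    deformation_gradient: np.ndarray
    translation: np.ndarray
    green_strain: np.ndarray
    engineering_avg_strain: float
    residual_rms: float
    n_matches: int

    @property
    def principal_stretches(self) -> np.ndarray:
        return np.linalg.svd(self.deformation_gradient, compute_uv=False)


def detect_beads(
    image: np.ndarray,
    intensity_threshold: float | None = None,
    min_separation: float = 5.0,
    refine_window: int = 7,
) -> BeadSet:
    """Detect bright spots and refine them to sub-pixel centroids.

    Local maxima above ``intensity_threshold`` (default: Otsu if the image is
    non-constant) and at least ``min_separation`` px apart are refined by an
    intensity-weighted centre of mass in a ``refine_window`` square.  An
    image with no candidates yields an empty set, not an error.
    """
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("detect_beads expects a single-channel image")
    if img.size == 0 or np.ptp(img) == 0:
        return BeadSet(np.empty((0, 2)), np.empty(0))
    if intensity_threshold is None:
        intensity_threshold = float(threshold_otsu(img))
    peaks = peak_local_max(
        img,
        min_distance=max(1, int(round(min_separation))),
        threshold_abs=intensity_threshold,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return BeadSet(np.empty((0, 2)), np.empty(0))

    half = refine_window // 2
    cents, inten = [], []
    for r, c in peaks:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        patch = img[r0:r1, c0:c1]
        base = patch.min()
        wts = patch - base
        tot = wts.sum()
        if tot <= 0:
            cy, cx = float(r), float(c)
        else:
            rows, cols = np.mgrid[r0:r1, c0:c1]
            cy = float((wts * rows).sum() / tot)
            cx = float((wts * cols).sum() / tot)
        cents.append((cx, cy))
        inten.append(float(img[r, c]))
    order = np.lexsort(np.array(cents).T[::-1])  # deterministic ordering
    return BeadSet(np.array(cents)[order], np.array(inten)[order])


def match_beads(ref: BeadSet, deformed: BeadSet, search_radius: float) -> BeadMatches:
    """Mutual-nearest-neighbour matching within ``search_radius`` pixels.

    A pair is kept only if each bead is the other's nearest neighbour, which
    makes the matching one-to-one by construction; unmatched beads are
    dropped.  Raises if no pair matches (the radius is then too small).
    """
    from scipy.spatial import cKDTree

    if len(ref) == 0 or len(deformed) == 0:
        raise ValueError("both bead sets must be non-empty")
    t_ref, t_def = cKDTree(ref.centroids), cKDTree(deformed.centroids)
    d_rd, j_rd = t_def.query(ref.centroids, distance_upper_bound=search_radius)
    _, j_dr = t_ref.query(deformed.centroids, distance_upper_bound=search_radius)

    ri, di = [], []
    for i, (dist, j) in enumerate(zip(d_rd, j_rd)):
        if np.isfinite(dist) and j < len(deformed) and j_dr[j] == i:
            ri.append(i)
            di.append(j)
    if not ri:
        raise ValueError(
            "no bead pairs matched within the search radius; increase the radius"
        )
    ri = np.asarray(ri)
    di = np.asarray(di)
    return BeadMatches(ri, di, ref.centroids[ri], deformed.centroids[di])


def fit_deformation(matches: BeadMatches) -> StrainEstimate:
    """Least-squares affine fit to the matched displacements.

    Solves ``x' = F x + c`` for the 2x2 deformation gradient and translation;
    needs at least three non-collinear matches.  Positions are centred before
    solving for numerical conditioning (this changes only ``c``).
    """
    n = len(matches)
    if n < 3:
        raise ValueError("need at least 3 matches to fit an affine deformation")
    x = matches.ref_xy - matches.ref_xy.mean(axis=0)
    if np.linalg.matrix_rank(x - x.mean(axis=0), tol=1e-9) < 2:
        raise ValueError("matched beads are collinear; affine fit is rank-deficient")
    a = np.hstack([matches.ref_xy, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(a, matches.def_xy, rcond=None)
    f = coef[:2].T
    c = coef[2]
    resid = matches.def_xy - (matches.ref_xy @ f.T + c)
    green = 0.5 * (f.T @ f - np.eye(2))
    stretches = np.linalg.svd(f, compute_uv=False)
    return StrainEstimate(
        deformation_gradient=f,
        translation=c,
        green_strain=green,
        engineering_avg_strain=float(stretches.mean() - 1.0),
        residual_rms=float(np.sqrt((resid**2).sum(axis=1).mean())),
        n_matches=n,
    )


def local_strain_map(
    matches: BeadMatches,
    window_size: float,
    stride: float,
    min_beads: int = 3,
):
    """Moving-window affine fits over the match positions.

    Returns a pandas DataFrame with one row per window (centre coordinates,
    window match count, and the fitted strain quantities); windows with fewer
    than ``min_beads`` usable matches, or with a degenerate configuration,
    are emitted with NaN estimates rather than dropped or zero-filled.
    """
    import pandas as pd

    xy = matches.ref_xy
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    xs = np.arange(lo[0] + window_size / 2, hi[0] - window_size / 2 + stride, stride)
    ys = np.arange(lo[1] + window_size / 2, hi[1] - window_size / 2 + stride, stride)
    if len(xs) == 0:
        xs = np.array([(lo[0] + hi[0]) / 2])
    if len(ys) == 0:
        ys = np.array([(lo[1] + hi[1]) / 2])

    rows = []
    for cx in xs:
        for cy in ys:
            sel = (np.abs(xy[:, 0] - cx) <= window_size / 2) & (
                np.abs(xy[:, 1] - cy) <= window_size / 2
            )
            row = {"x": cx, "y": cy, "n_beads": int(sel.sum())}
            if sel.sum() >= min_beads:
                sub = BeadMatches(
                    matches.ref_index[sel],
                    matches.def_index[sel],
                    matches.ref_xy[sel],
                    matches.def_xy[sel],
                )
                try:
                    est = fit_deformation(sub)
                    row.update(
                        f_xx=est.deformation_gradient[0, 0],
                        f_xy=est.deformation_gradient[0, 1],
                        f_yx=est.deformation_gradient[1, 0],
                        f_yy=est.deformation_gradient[1, 1],
                        green_xx=est.green_strain[0, 0],
                        green_yy=est.green_strain[1, 1],
                        green_xy=est.green_strain[0, 1],
                        avg_strain=est.engineering_avg_strain,
                        residual_rms=est.residual_rms,
                    )
                except ValueError:
                    pass
            rows.append(row)
    cols = [
        "x", "y", "n_beads", "f_xx", "f_xy", "f_yx", "f_yy",
        "green_xx", "green_yy", "green_xy", "avg_strain", "residual_rms",
    ]
    return pd.DataFrame(rows).reindex(columns=cols)


def iterative_affine_match(
    ref: BeadSet,
    deformed: BeadSet,
    search_radius: float,
    n_iter: int = 4,
) -> tuple[BeadMatches, StrainEstimate]:
    """Affine-compensated matching for displacements comparable to spacing.

    Plain nearest-neighbour matching fails once bead displacements approach
    the inter-bead spacing (a 10 % stretch moves peripheral beads by many
    pixels).  Here matching and fitting alternate: reference positions are
    warped by the current affine estimate, mutual nearest neighbours are
    found between warped and deformed positions, and the affine fit is
    redone on the original coordinates of the matched pairs.  With a correct
    match set the estimate is stationary, so a few iterations suffice.
    """
    est: StrainEstimate | None = None
    matches = match_beads(ref, deformed, search_radius)
    for _ in range(n_iter):
        est = fit_deformation(matches)
        warped = BeadSet(
            matches_apply(est, ref.centroids), ref.intensities
        )
        # residual displacements after compensation are small, so a tighter
        # radius suppresses spurious pairs
        resid_radius = max(3.0 * est.residual_rms, 2.0)
        new = match_beads(warped, deformed, min(search_radius, resid_radius))
        new = BeadMatches(
            new.ref_index, new.def_index, ref.centroids[new.ref_index], new.def_xy
        )
        if len(new) == len(matches) and np.array_equal(new.ref_index, matches.ref_index):
            matches = new
            break
        matches = new
    return matches, fit_deformation(matches)


def matches_apply(est: StrainEstimate, xy: np.ndarray) -> np.ndarray:
    """Apply a fitted affine map to positions."""
    return xy @ est.deformation_gradient.T + est.translation


class BeadTrackingModel:
    """Reference/deformed image pair -> affine strain estimate.

    Thin model wrapper over :func:`detect_beads` / :func:`match_beads` /
    :func:`fit_deformation`; ``fit()`` returns the :class:`StrainEstimate`.
    """

    def __init__(
        self,
        ref_image: np.ndarray,
        def_image: np.ndarray,
        *,
        intensity_threshold: float | None = None,
        min_separation: float = 5.0,
        search_radius: float = 20.0,
    ) -> None:
        self.ref_image = ref_image
        self.def_image = def_image
        self.intensity_threshold = intensity_threshold
        self.min_separation = min_separation
        self.search_radius = search_radius
        self.ref_beads: BeadSet | None = None
        self.def_beads: BeadSet | None = None
        self.matches: BeadMatches | None = None

    def fit(self) -> StrainEstimate:
        self.ref_beads = detect_beads(
            self.ref_image, self.intensity_threshold, self.min_separation
        )
        self.def_beads = detect_beads(
            self.def_image, self.intensity_threshold, self.min_separation
        )
        self.matches, est = iterative_affine_match(
            self.ref_beads, self.def_beads, self.search_radius
        )
        return est
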