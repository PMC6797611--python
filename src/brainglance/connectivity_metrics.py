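"""Subject-level map computations from 4D time series.

Two voxel-wise resting-state measures are provided:

* **Eigenvector centrality mapping (ECM)** — the dominant eigenvector of
  the voxel-by-voxel similarity matrix ``A`` with
  ``A[u, v] = (r_uv + 1) / 2``, where ``r_uv`` is the Pearson correlation
  of the two voxels' series.  The additive shift makes ``A`` non-negative,
  so by Perron–Frobenius the dominant eigenvector is unique and can be
  chosen non-negative.  ``A`` is never formed explicitly: with the
  row-standardized data matrix ``Z`` (each voxel's series mean-centered
  and scaled to unit norm), ``A x = (Z (Zᵀ x) + sum(x) · 1) / 2``, which
  power iteration evaluates in O(n·T) per step.

* **Regional homogeneity (ReHo)** — per voxel, Kendall's coefficient of
  concordance ``W`` over the series in the voxel's spatial neighborhood
  (7, 19 or 27 voxels), with mid-ranks and the standard tie correction.

Also here: the discrete-cosine temporal high-pass and separable Gaussian
smoothing used in the native-versus-template comparison experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .volumes import ScalarVolume, TimeSeriesVolume, ValidationError

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))


@dataclass
class SmoothingSpec:
    """Gaussian kernel: FWHM in millimetres; 0 means identity."""

    fwhm_mm: float
    truncation_radius: float = 4.0

    def __post_init__(self):
        if self.fwhm_mm < 0:
            raise ValidationError(f"fwhm_mm must be >= 0, got {self.fwhm_mm}")
        if self.truncation_radius <= 0:
            raise ValidationError("truncation_radius must be positive")


# ---------------------------------------------------------------------------
# temporal high-pass


def dct_basis(T: int, n_components: int) -> np.ndarray:
    """Orthonormal DCT-II low-frequency basis, column 0 the constant."""
    t = np.arange(T)
    B = np.cos(np.pi * np.arange(n_components)[None, :] * (t[:, None] + 0.5) / T)
    return B / np.linalg.norm(B, axis=0, keepdims=True)


def highpass_filter(ts: TimeSeriesVolume, cutoff_seconds: float) -> TimeSeriesVolume:
    """Remove frequency content below 1/cutoff via DCT projection.

    The low-frequency span has ``floor(2·T·tr/cutoff) + 1`` components
    including the constant, so the voxel mean is removed as well; the
    residual of the least-squares projection is returned.  Voxels outside
    the mask are set to zero.
    """
    T = ts.n_timepoints
    if cutoff_seconds <= 2.0 * ts.tr_seconds:
        raise ValidationError(
            f"cutoff_seconds ({cutoff_seconds}) must exceed twice the TR "
            f"({ts.tr_seconds})"
        )
    K = int(np.floor(2.0 * T * ts.tr_seconds / cutoff_seconds)) + 1
    if K >= T:
        raise ValidationError(
            f"cutoff {cutoff_seconds}s is too short for a {T}-volume series: "
            f"the low-frequency basis ({K} components) would span everything"
        )
    B = dct_basis(T, K)
    X = ts.masked_data()
    resid = X - (X @ B) @ B.T
    out = np.zeros_like(ts.grid)
    out[ts.mask] = resid
    return TimeSeriesVolume(
        out, ts.tr_seconds, ts.mask.copy(), ts.voxel_size, ts.space_tag, ts.affine
    )


# ---------------------------------------------------------------------------
# eigenvector centrality


def _standardized_rows(ts: TimeSeriesVolume) -> np.ndarray:
    X = ts.masked_data()
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        coords = np.argwhere(ts.mask)[bad]
        raise ValidationError(
            f"{bad.size} masked voxel(s) have zero temporal variance, e.g. at "
            f"indices {coords[:5].tolist()}"
        )
    return Xc / norms[:, None]


def compute_ecm(
    ts: TimeSeriesVolume,
    tol: float = 1e-10,
    max_iterations: int = 10000,
    seed: int | None = None,
) -> ScalarVolume:
    """Eigenvector centrality of A = (corr + 1)/2, matrix-free.

    Power iteration starts from the uniform positive vector (or a seeded
    random positive vector) and stops when the Rayleigh estimate of the
    dominant eigenvalue changes by less than ``tol`` relatively.  The
    result has unit Euclidean norm over the mask and is zero outside it.
    """
    n = int(ts.mask.sum())
    if n < 2:
        raise ValidationError("ECM needs at least 2 masked voxels")
    Z = _standardized_rows(ts)
    if seed is None:
        x = np.full(n, 1.0 / np.sqrt(n))
    else:
        rng = np.random.default_rng(seed)
        x = np.abs(rng.standard_normal(n)) + 1e-12
        x /= np.linalg.norm(x)
    lam_prev = np.inf
    for _ in range(max_iterations):
        y = 0.5 * (Z @ (Z.T @ x) + x.sum())
        lam = float(np.linalg.norm(y))
        if lam == 0.0:
            break
        x_new = y / lam
        # require both the eigenvalue estimate and the vector itself to be
        # stable, so the result is independent of the starting vector
        dx = float(np.max(np.abs(x_new - x)))
        x = x_new
        if abs(lam - lam_prev) <= tol * lam and dx <= 1e-2 * tol:
            break
        lam_prev = lam
    x = np.maximum(x, 0.0)  # clip numerical dust; A >= 0 keeps x >= 0
    x /= np.linalg.norm(x)
    out = np.zeros(ts.mask.shape)
    out[ts.mask] = x
    return ScalarVolume(out, ts.voxel_size, ts.space_tag, ts.affine)


# ---------------------------------------------------------------------------
# regional homogeneity


def _neighborhood_offsets(neighborhood: int) -> np.ndarray:
    if neighborhood not in (7, 19, 27):
        raise ValidationError(f"neighborhood must be 7, 19 or 27, got {neighborhood}")
    offs = []
    for d in product((-1, 0, 1), repeat=3):
        manhattan = sum(abs(v) for v in d)
        if neighborhood == 7 and manhattan > 1:
            continue
        if neighborhood == 19 and manhattan > 2:
            continue
        offs.append(d)
    return np.array(offs, dtype=int)


def _tie_corrections(ranks: np.ndarray) -> np.ndarray:
    """Per series, sum of (c³ - c) over groups of tied time points."""
    T = ranks.shape[1]
    out = np.empty(ranks.shape[0])
    for i, row in enumerate(ranks):
        _, counts = np.unique(row, return_counts=True)
        out[i] = float(np.sum(counts.astype(float) ** 3 - counts))
    return out


def compute_reho(ts: TimeSeriesVolume, neighborhood: int = 27) -> ScalarVolume:
    """Kendall's W of each voxel's series with its spatial neighbors.

    For the K in-mask series of a voxel's neighborhood (the voxel plus
    its face/edge/corner neighbors, clipped at mask and volume borders),
    each series is ranked over time with mid-ranks and

        W = 12 · Σ_t (R_t − R̄)² / (K²(T³ − T) − K·ΣT_j),

    where R_t is the rank sum at time t and T_j the tie correction of
    series j.  W is 1 iff all series are rank-identical.
    """
    T = ts.n_timepoints
    if T < 3:
        raise ValidationError(f"ReHo needs at least 3 time points, got {T}")
    offsets = _neighborhood_offsets(neighborhood)
    _standardized_rows(ts)  # enforce the zero-variance contract
    X = ts.masked_data()
    ranks = rankdata(X, axis=1)
    ties = _tie_corrections(ranks)

    shape = ts.mask.shape
    row_of = np.full(shape, -1, dtype=np.int64)
    row_of[ts.mask] = np.arange(X.shape[0])

    out = np.zeros(shape)
    coords = np.argwhere(ts.mask)
    for (x, y, z), row in zip(coords, row_of[ts.mask]):
        pts = offsets + (x, y, z)
        inside = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[inside]
        rows = row_of[pts[:, 0], pts[:, 1], pts[:, 2]]
        rows = rows[rows >= 0]
        K = rows.size
        R_t = ranks[rows].sum(axis=0)
        S = float(np.sum((R_t - R_t.mean()) ** 2))
        denom = K * K * (T**3 - T) - K * float(ties[rows].sum())
        out[x, y, z] = min(1.0, 12.0 * S / denom)
    return ScalarVolume(out, ts.voxel_size, ts.space_tag, ts.affine)


# ---------------------------------------------------------------------------
# spatial smoothing


def _sigmas_vox(fwhm_mm: float, voxel_size) -> tuple[float, ...]:
    return tuple(fwhm_mm * FWHM_TO_SIGMA / v for v in voxel_size)


def smooth_volume(vol: ScalarVolume, spec: SmoothingSpec) -> ScalarVolume:
    """Separable Gaussian smoothing; zero-padded outside the volume.

    σ per axis is ``fwhm / sqrt(8·ln 2)`` millimetres converted to voxel
    units; FWHM 0 returns the input unchanged.  No mask renormalization
    is applied at the boundary.
    """
    if spec.fwhm_mm == 0:
        return ScalarVolume(vol.grid.copy(), vol.voxel_size, vol.space_tag, vol.affine)
    smoothed = ndimage.gaussian_filter(
        vol.grid,
        sigma=_sigmas_vox(spec.fwhm_mm, vol.voxel_size),
        mode="constant",
        cval=0.0,
        truncate=spec.truncation_radius,
    )
    return ScalarVolume(smoothed, vol.voxel_size, vol.space_tag, vol.affine)


def smooth_timeseries(ts: TimeSeriesVolume, spec: SmoothingSpec) -> TimeSeriesVolume:
    """Apply :func:`smooth_volume`'s kernel to every time frame."""
    if spec.fwhm_mm == 0:
        grid = ts.grid.copy()
    else:
        grid = ndimage.gaussian_filter(
            ts.grid,
            sigma=_sigmas_vox(spec.fwhm_mm, ts.voxel_size) + (0.0,),
            mode="constant",
            cval=0.0,
            truncate=spec.truncation_radius,
        )
    return TimeSeriesVolume(
        grid, ts.tr_seconds, ts.mask.copy(), ts.voxel_size, ts.space_tag, ts.affine
    )
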