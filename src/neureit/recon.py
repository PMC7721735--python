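"""Linearized EIT inversion and image post-processing.

Peak δV measurement vectors are inverted through the voxelized sensitivity
matrix with 0th-order Tikhonov regularization,

    δσ = argmin ‖J δσ − δV‖² + λ‖δσ‖²,   λ = α·s_max(J)²,

computed via the SVD of J.  Background inter-stimulus noise epochs are
projected through the same regularized inverse; dividing each voxel of the
signal reconstruction by the SD of the noise reconstructions yields a
z-score image, which also flattens the spatially varying sensitivity of the
ring geometry.  Post-processing follows the standard recipe: median filter
(radius 1), mean filter (radius 3), min–max normalization to [0, 1] inside
the circular mask; the fascicle center of mass is the intensity-weighted
centroid of the voxels above half maximum (FWHM rule).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .conventions import polar_from_xy
from .forward import JacobianMatrix


class ReconError(RuntimeError):
    pass


@dataclass
class ReconConfig:
    alpha: float = 1e-2  # λ = alpha · s_max², fixed-α rule
    lambda_rule: str = "fixed"  # "fixed" | "gcv"
    n_noise_epochs: int = 30
    median_radius: int = 1
    mean_radius: int = 3
    fwhm_fraction: float = 0.5

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not (0.0 < self.fwhm_fraction < 1.0):
            raise ValueError("FWHM fraction must be in (0, 1)")


@dataclass
class PixelImage:
    """Square voxel image on the nerve cross-section.

    values : (n, n) float; entries outside `mask` are NaN-free zeros but
        carry no meaning.
    kind : "dsigma" (S/m), "zscore" (dimensionless) or "normalized".
    """

    values: np.ndarray
    mask: np.ndarray
    voxel_size_um: float
    kind: str = "dsigma"
    voxel_centers_um: np.ndarray | None = None
    grid_index: np.ndarray | None = None

    def __post_init__(self):
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite voxel values inside mask")

    def masked(self) -> np.ndarray:
        return self.values[self.mask]

    def xy_um(self):
        """Pixel-center coordinates (µm): x increases with column, y with row
        *decreasing* is not used — grid row index maps to y directly via the
        voxel center table built by the Jacobian projection."""
        n = self.values.shape[0]
        c = (np.arange(n) - (n - 1) / 2.0) * self.voxel_size_um
        return np.meshgrid(c, c, indexing="xy")


@dataclass
class FascicleCoM:
    x_um: float
    y_um: float
    r_um: float
    theta_deg: float
    label: str = ""
    technique: str = "EIT"
    nerve_id: str = ""
    side: str = "right"


class TikhonovSolver:
    """Regularized inverse of a voxel Jacobian, shared between the signal
    reconstruction and the noise projections (same λ)."""

    def __init__(self, J: JacobianMatrix, config: ReconConfig, dv_for_gcv=None):
        if J.kind != "voxel":
            raise ValueError("reconstruction expects a voxel-space Jacobian")
        A = J.matrix
        if A.size == 0 or not np.any(A):
            raise ReconError("rank-0 Jacobian")
        self.J = J
        self.U, self.s, self.Vt = np.linalg.svd(A, full_matrices=False)
        if self.s[0] == 0:
            raise ReconError("rank-0 Jacobian")
        if config.lambda_rule == "gcv":
            if dv_for_gcv is None:
                raise ValueError("GCV rule needs the measurement vector")
            self.lam = self._gcv_lambda(np.asarray(dv_for_gcv, float))
        else:
            self.lam = config.alpha * self.s[0] ** 2
        self.filt = self.s / (self.s**2 + self.lam)

    def _gcv_lambda(self, dv: np.ndarray) -> float:
        beta = self.U.T @ dv
        m = dv.size
        lams = self.s[0] ** 2 * np.logspace(-8, 0, 60)
        best, best_g = lams[0], np.inf
        for lam in lams:
            f = self.s**2 / (self.s**2 + lam)
            resid = np.sum(((1 - f) * beta) ** 2) + (dv @ dv - beta @ beta)
            denom = (m - np.sum(f)) ** 2
            g = resid / denom
            if g < best_g:
                best, best_g = lam, g
        return float(best)

    def solve(self, dv: np.ndarray) -> np.ndarray:
        """Voxel solution(s); dv may be (m,) or (k, m)."""
        dv = np.atleast_2d(np.asarray(dv, dtype=float))
        x = (self.filt[None, :] * (dv @ self.U)) @ self.Vt
        return x[0] if x.shape[0] == 1 else x

    def to_image(self, x: np.ndarray, kind: str = "dsigma") -> PixelImage:
        J = self.J
        n = J.grid_shape[0]
        vals = np.zeros((n, n))
        mask = np.zeros((n, n), dtype=bool)
        vals[J.grid_index[:, 0], J.grid_index[:, 1]] = x
        mask[J.grid_index[:, 0], J.grid_index[:, 1]] = True
        return PixelImage(
            values=vals,
            mask=mask,
            voxel_size_um=J.voxel_size * 1e6,
            kind=kind,
            voxel_centers_um=J.voxel_centers * 1e6,
            grid_index=J.grid_index,
        )


def tikhonov_reconstruct(
    J: JacobianMatrix, dv: np.ndarray, config: ReconConfig | None = None
) -> PixelImage:
    """0th-order Tikhonov reconstruction of a measurement vector."""
    config = config or ReconConfig()
    dv = np.asarray(dv, dtype=float)
    if dv.size == 0:
        raise ReconError("empty measurement vector")
    if dv.shape[-1] != J.matrix.shape[0]:
        raise ValueError("measurement vector length does not match Jacobian rows")
    solver = TikhonovSolver(J, config, dv_for_gcv=dv)
    return solver.to_image(solver.solve(dv), kind="dsigma")


def noise_zscore(
    J: JacobianMatrix,
    recon_of_signal: PixelImage,
    noise_epochs: np.ndarray,
    config: ReconConfig | None = None,
    solver: TikhonovSolver | None = None,
) -> PixelImage:
    """Divide each voxel by the SD of reconstructions of background noise
    epochs (same regularization), yielding a z-score image."""
    config = config or ReconConfig()
    noise_epochs = np.atleast_2d(np.asarray(noise_epochs, dtype=float))
    if noise_epochs.shape[0] < 20:
        raise ValueError("need at least 20 noise epochs for the z-score")
    if solver is None:
        solver = TikhonovSolver(J, config, dv_for_gcv=noise_epochs.mean(axis=0))
    xn = solver.solve(noise_epochs)
    sd = np.std(xn, axis=0, ddof=1)
    if np.any(sd == 0):
        raise ReconError("zero noise SD in at least one voxel")
    n = J.grid_shape[0]
    sd_img = np.zeros((n, n))
    sd_img[J.grid_index[:, 0], J.grid_index[:, 1]] = sd
    z = np.zeros_like(recon_of_signal.values)
    z[recon_of_signal.mask] = (
        recon_of_signal.values[recon_of_signal.mask] / sd_img[recon_of_signal.mask]
    )
    return replace(recon_of_signal, values=z, kind="zscore")


def postprocess(image: PixelImage, config: ReconConfig | None = None) -> PixelImage:
    """Median filter (radius 1) → mean filter (radius 3) → min–max normalize
    to [0, 1] within the mask.  Square (Chebyshev) neighborhoods, reflection
    padding at the array edges; outside-mask voxels are treated as zero."""
    config = config or ReconConfig()
    arr = np.where(image.mask, image.values, 0.0)
    med = ndimage.median_filter(arr, size=2 * config.median_radius + 1, mode="reflect")
    mean = ndimage.uniform_filter(med, size=2 * config.mean_radius + 1, mode="reflect")
    vals = mean[image.mask]
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        raise ReconError("constant image; normalization degenerate")
    out = np.zeros_like(mean)
    out[image.mask] = (vals - lo) / (hi - lo)
    return replace(image, values=out, kind="normalized")


def fwhm_com(
    image: PixelImage,
    fraction: float = 0.5,
    label: str = "",
    technique: str = "EIT",
    nerve_id: str = "",
    side: str = "right",
) -> FascicleCoM:
    """Intensity-weighted center of mass over voxels at or above
    ``fraction`` × max (full width at half maximum for the default 0.5)."""
    vals = image.values
    thr = fraction * vals[image.mask].max()
    sel = image.mask & (vals >= thr)
    if not np.any(sel):
        raise ReconError("no voxels above the FWHM threshold")
    n = vals.shape[0]
    c = (np.arange(n) - (n - 1) / 2.0) * image.voxel_size_um
    # grid_index rows are (iy, ix) with y increasing along the row index
    X, Y = np.meshgrid(c, c, indexing="xy")
    w = vals[sel]
    x0 = float(np.sum(w * X[sel]) / np.sum(w))
    y0 = float(np.sum(w * Y[sel]) / np.sum(w))
    r, th = polar_from_xy(x0, y0)
    return FascicleCoM(
        x_um=x0,
        y_um=y0,
        r_um=float(r),
        theta_deg=float(th),
        label=label,
        technique=technique,
        nerve_id=nerve_id,
        side=side,
    )
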