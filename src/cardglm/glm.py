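"""First-level GLM with AR(1) prewhitening and nonparametric group inference.

First level: ordinary least squares, a single AR(1) coefficient pooled over
in-mask voxels from the lag-1 autocorrelation of the OLS residuals,
prewhitening of data and design by the AR(1) inverse square root, and a
refit; contrasts give per-voxel effect and t maps.

Second level: one-sample sign-flip permutation test on subject contrast
maps. The statistic is a pseudo-t whose denominator uses a spatially
smoothed variance image (Gaussian, FWHM in voxels), which stabilizes the
low-degrees-of-freedom variance estimate of small cohorts. Family-wise
error is controlled with the permutation distribution of the maximum
pseudo-t over the mask; sign patterns are fully enumerated when 2^n does
not exceed the requested permutation count, otherwise Monte-Carlo sampled
with the identity pattern always included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage

from .design import DesignMatrix
from .synth import BoldDataset

__all__ = [
    "GlmResult",
    "GroupResult",
    "fit_first_level",
    "contrast_t",
    "group_permutation",
    "smooth_volume",
    "estimate_ar1",
]


@dataclass
class GlmResult:
    """First-level fit: coefficients, noise variance, and whitened geometry."""

    betas: np.ndarray            # (n_columns, n_voxels)
    sigma2: np.ndarray           # (n_voxels,)
    phi: float                   # pooled AR(1) coefficient
    dof: int                     # frames minus design rank
    column_names: list[str]
    xtx_inv: np.ndarray          # (XᵀX)⁻¹ of the whitened design
    mask: np.ndarray
    contrast_maps: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def effect_volume(self, weights: np.ndarray) -> np.ndarray:
        """Contrast effect as a 3D volume (NaN outside the mask)."""
        effect, _ = contrast_t(self, weights)
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = effect
        return vol


@dataclass
class GroupResult:
    """Sign-flip permutation inference on a cohort of contrast maps."""

    pseudo_t: np.ndarray         # (n_voxels,)
    max_null: np.ndarray         # (n_permutations,)
    fwe_p: np.ndarray            # (n_voxels,)
    threshold: float             # pseudo-t at the (1 − alpha) max-null quantile
    alpha: float
    n_permutations: int
    mask: np.ndarray
    full_enumeration: bool

    @property
    def significant(self) -> np.ndarray:
        """Boolean per-voxel map of FWE-significant voxels (fwe_p ≤ alpha)."""
        return self.fwe_p <= self.alpha

    def volume(self, values: np.ndarray) -> np.ndarray:
        vol = np.full(self.mask.shape, np.nan)
        vol[self.mask] = values
        return vol


def estimate_ar1(residuals: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of (t, voxels) residuals."""
    num = float(np.sum(residuals[1:] * residuals[:-1]))
    den = float(np.sum(residuals**2))
    return num / den if den > 0 else 0.0


def _ar1_residual_bias(x: np.ndarray) -> float:
    """First-order bias of the residual lag-1 autocorrelation under white noise.

    OLS residuals are slightly anticorrelated even for white noise because
    the hat matrix removes p degrees of freedom: E[φ̂] ≈ tr(A M)/tr(M) with
    A the symmetrized lag operator and M the residual-forming matrix. Only
    the first off-diagonal of M is needed: tr(A M) = Σ_t M[t, t+1].
    """
    t, p = x.shape
    xtx_inv = np.linalg.inv(x.T @ x)
    # Σ_t H[t, t+1] with H = X (XᵀX)⁻¹ Xᵀ
    h_adj = float(np.sum((x[:-1] @ xtx_inv) * x[1:]))
    return -h_adj / (t - p)


def _whiten(x: np.ndarray, phi: float) -> np.ndarray:
    """Apply the AR(1) inverse square-root transform along axis 0."""
    w = np.empty_like(x, dtype=float)
    w[0] = np.sqrt(1.0 - phi**2) * x[0]
    w[1:] = x[1:] - phi * x[:-1]
    return w


def fit_first_level(
    data: BoldDataset, design: DesignMatrix, ar1: bool = True
) -> GlmResult:
    """OLS fit, pooled AR(1) estimate, prewhitening, and refit.

    With ``ar1=False`` the autocorrelation model is skipped (φ = 0) and the
    result is a plain OLS fit.
    """
    y = data.timeseries()
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"data has {y.shape[0]} frames but design has {x.shape[0]} rows"
        )
    if data.mask.sum() == 0:
        raise ValueError("empty mask")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        _raise_rank_deficiency(x, design.column_names)

    if ar1:
        beta_ols, *_ = np.linalg.lstsq(x, y, rcond=None)
        resid = y - x @ beta_ols
        # bias-correct the pooled residual autocorrelation for the degrees
        # of freedom the fit removes, then keep φ in the stationary range
        phi = estimate_ar1(resid) - _ar1_residual_bias(x)
        phi = float(np.clip(phi, -0.95, 0.95))
    else:
        phi = 0.0

    xw = _whiten(x, phi)
    yw = _whiten(y, phi)
    if np.linalg.matrix_rank(xw) < xw.shape[1]:
        _raise_rank_deficiency(xw, design.column_names)
    betas, *_ = np.linalg.lstsq(xw, yw, rcond=None)
    residw = yw - xw @ betas
    dof = x.shape[0] - x.shape[1]
    sigma2 = np.sum(residw**2, axis=0) / dof
    xtx_inv = np.linalg.inv(xw.T @ xw)
    return GlmResult(
        betas=betas,
        sigma2=sigma2,
        phi=phi,
        dof=dof,
        column_names=list(design.column_names),
        xtx_inv=xtx_inv,
        mask=data.mask,
    )


def _raise_rank_deficiency(x: np.ndarray, names: list[str]) -> None:
    # name the columns involved in the (near-)linear dependency
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    bad = [names[j] for j in np.nonzero(diag < 1e-10 * diag.max())[0]]
    raise np.linalg.LinAlgError(
        f"design is rank deficient; dependent columns: {bad or 'unidentified'}"
    )


def contrast_t(
    result: GlmResult, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel contrast effect wᵀβ and its t statistic on the whitened fit."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(result.column_names),):
        raise ValueError(
            f"contrast length {w.shape} does not match the "
            f"{len(result.column_names)} design columns"
        )
    if not np.any(w):
        raise ValueError("contrast weights are all zero")
    effect = w @ result.betas
    var_scale = float(w @ result.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(result.sigma2 * var_scale)
    return effect, t


def contrast_vector(column_names: list[str], name: str) -> np.ndarray:
    """Indicator contrast selecting one named design column."""
    w = np.zeros(len(column_names))
    w[column_names.index(name)] = 1.0
    return w


def smooth_volume(
    values: np.ndarray, mask: np.ndarray, fwhm_vox: float
) -> np.ndarray:
    """Gaussian-smooth in-mask voxel values; returns an in-mask vector.

    Uses normalized (mask-weighted) convolution so voxels outside the mask
    never leak into the smoothed image.
    """
    if fwhm_vox <= 0:
        return values
    sigma = fwhm_vox / np.sqrt(8.0 * np.log(2.0))
    vol = np.zeros(mask.shape)
    vol[mask] = values
    sm = ndimage.gaussian_filter(vol, sigma)
    norm = ndimage.gaussian_filter(mask.astype(float), sigma)
    return sm[mask] / norm[mask]


def _sign_patterns(
    n_subjects: int, n_permutations: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    if 2**n_subjects <= n_permutations:
        signs = np.array(list(product((1.0, -1.0), repeat=n_subjects)))
        return signs, True
    signs = rng.choice([1.0, -1.0], size=(n_permutations, n_subjects))
    signs[0] = 1.0  # the observed labeling is always part of the null
    return signs, False


def group_permutation(
    contrast_maps: np.ndarray,
    mask: np.ndarray,
    n_permutations: int = 10_000,
    variance_smoothing_fwhm: float = 2.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> GroupResult:
    """One-sample sign-flip permutation test with variance smoothing.

    ``contrast_maps`` is (n_subjects, x, y, z) on a common grid. For each
    sign pattern s the statistic at voxel v is the pseudo-t
    ``mean(s·c_v) / sqrt(smoothed_var(s·c) / n)``; the FWE-corrected p-value
    of voxel v is the fraction of patterns whose maximum pseudo-t over the
    mask is ≥ the observed pseudo-t at v (ties counted against rejection).
    ``variance_smoothing_fwhm`` is in voxel units.
    """
    maps = np.asarray(contrast_maps, dtype=float)
    if maps.ndim != 4:
        raise ValueError("contrast_maps must be (n_subjects, x, y, z)")
    n = maps.shape[0]
    if n < 2:
        raise ValueError("group inference needs at least 2 subjects")
    if maps.shape[1:] != mask.shape:
        raise ValueError("contrast maps and mask are on different grids")

    m = maps[:, mask]                       # (n, voxels)
    rng = np.random.default_rng(seed)
    signs, full = _sign_patterns(n, n_permutations, rng)
    n_perm = signs.shape[0]

    ss = np.sum(m**2, axis=0)               # invariant under sign flips
    means = signs @ m / n                   # (n_perm, voxels)
    var = (ss[None, :] - n * means**2) / (n - 1)
    var = np.maximum(var, 0.0)
    if variance_smoothing_fwhm > 0:
        var = np.stack(
            [smooth_volume(v, mask, variance_smoothing_fwhm) for v in var]
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        pseudo = means / np.sqrt(var / n)
    pseudo = np.nan_to_num(pseudo, nan=0.0, posinf=np.inf)

    observed = m.mean(axis=0)
    obs_var = (ss - n * observed**2) / (n - 1)
    obs_var = np.maximum(obs_var, 0.0)
    if variance_smoothing_fwhm > 0:
        obs_var = smooth_volume(obs_var, mask, variance_smoothing_fwhm)
    with np.errstate(divide="ignore", invalid="ignore"):
        observed_t = observed / np.sqrt(obs_var / n)
    observed_t = np.nan_to_num(observed_t, nan=0.0, posinf=np.inf)

    max_null = pseudo.max(axis=1)
    fwe_p = (max_null[:, None] >= observed_t[None, :]).mean(axis=0)
    fwe_p = np.maximum(fwe_p, 1.0 / n_perm)
    threshold = float(np.quantile(max_null, 1.0 - alpha, method="higher"))
    return GroupResult(
        pseudo_t=observed_t,
        max_null=max_null,
        fwe_p=fwe_p,
        threshold=threshold,
        alpha=alpha,
        n_permutations=n_perm,
        mask=mask,
        full_enumeration=full,
    )
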