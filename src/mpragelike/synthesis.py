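"""MPRAGE-like synthesis: regularized contrast ratios, Δs/s, SSIM, λ sweep.

The MPRAGE-like image is a voxelwise ratio of the first-echo T1w magnitude
over an approximately inverted-contrast denominator built from the PDw
and/or MTw magnitudes:

    S = (T1w - λ) / (D + λ),   D = 0.5·(PDw + MTw) | MTw | PDw

Because numerator and denominator carry the same receive-coil sensitivity,
the ratio cancels multiplicative receive bias (exactly at λ = 0).  The
additive regularization λ suppresses noise amplification where the
denominator is small (background), at the cost of reintroducing some
spatial inhomogeneity.  After the ratio, intensities outside a clip window
(default (0, 500) a.u.) are set to 0, which zeroes the background.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    ContrastVolume,
    DegenerateInput,
    GridMismatch,
    InvalidParams,
    MissingContrast,
    NonFiniteInput,
    grid_compatible,
    validate_grid_compatible,
)

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "MPRAGELikeRecipe",
    "SSIMParams",
    "LambdaSweepResult",
    "compute_mprage_like",
    "relative_difference_map",
    "ssim",
    "sweep_lambda",
]

#: λ values swept when selecting the regularization term.
DEFAULT_LAMBDA_GRID: tuple[float, ...] = (0.0, 50.0, 100.0, 200.0, 300.0, 400.0, 500.0)

VARIANTS = ("all", "MT", "PD")


@dataclass(frozen=True)
class MPRAGELikeRecipe:
    """Which denominator to use, the regularization λ, and the clip window.

    ``clip_low``/``clip_high`` bound the retained intensity range; voxels
    outside it are set to 0.  Pass ``clip=False`` at call sites (or set both
    bounds to +/-inf) to disable clipping for analysis.  The default window
    (0, 500) assumes inputs on the raw-scanner intensity scale; rescale it
    together with any intensity normalization.
    """

    variant: str = "all"
    lambda_reg: float = 100.0
    clip_low: float = 0.0
    clip_high: float = 500.0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidParams(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.lambda_reg < 0:
            raise InvalidParams(f"lambda_reg must be >= 0, got {self.lambda_reg}")
        if not self.clip_low < self.clip_high:
            raise InvalidParams("clip_low must be < clip_high")


@dataclass(frozen=True)
class SSIMParams:
    """Stabilization constants and evaluation mode for SSIM.

    When ``c1``/``c2``/``c3`` are None they are derived from the dynamic
    range L of the reference image as c1 = (k1 L)^2, c2 = (k2 L)^2,
    c3 = c2 / 2 (the conventional parameterization).  ``mode`` is ``global``
    (whole-volume statistics, the default) or ``windowed`` (mean of
    per-window values over a cubic sliding window).
    """

    c1: float | None = None
    c2: float | None = None
    c3: float | None = None
    k1: float = 0.01
    k2: float = 0.03
    mode: str = "global"
    window_size: int = 7
    dynamic_range: float | None = None

    def __post_init__(self) -> None:
        for name in ("c1", "c2", "c3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidParams(f"{name} must be >= 0")
        if self.mode not in ("global", "windowed"):
            raise InvalidParams("mode must be 'global' or 'windowed'")
        if self.mode == "windowed" and self.window_size % 2 != 1:
            raise InvalidParams("window_size must be odd")

    def constants(self, reference: np.ndarray) -> tuple[float, float, float]:
        """Resolve (c1, c2, c3), deriving missing ones from the data range."""
        L = self.dynamic_range
        if L is None:
            L = float(np.ptp(reference))
        c1 = (self.k1 * L) ** 2 if self.c1 is None else self.c1
        c2 = (self.k2 * L) ** 2 if self.c2 is None else self.c2
        c3 = c2 / 2.0 if self.c3 is None else self.c3
        return float(c1), float(c2), float(c3)


@dataclass
class LambdaSweepResult:
    """Per-subject SSIM over the λ grid, with the selected λ.

    ``ssim_values[i, j]`` is subject ``i`` at ``lambda_values[j]``.
    ``selected_lambda`` maximizes the subject-mean SSIM; ties break toward
    the smaller λ.
    """

    lambda_values: tuple[float, ...]
    ssim_values: np.ndarray
    mean_ssim: np.ndarray = field(init=False)
    sd_ssim: np.ndarray = field(init=False)
    selected_lambda: float = field(init=False)

    def __post_init__(self) -> None:
        self.ssim_values = np.atleast_2d(np.asarray(self.ssim_values, dtype=float))
        if self.ssim_values.shape[1] != len(self.lambda_values):
            raise InvalidParams("ssim_values columns must match lambda_values")
        self.mean_ssim = self.ssim_values.mean(axis=0)
        self.sd_ssim = (
            self.ssim_values.std(axis=0, ddof=1)
            if self.ssim_values.shape[0] > 1
            else np.zeros(len(self.lambda_values))
        )
        # argmax returns the first maximizer; sorting λ ascending makes the
        # tie-break fall on the smaller λ.
        order = np.argsort(self.lambda_values)
        best = order[int(np.argmax(self.mean_ssim[order]))]
        self.selected_lambda = float(self.lambda_values[best])


def _denominator(
    variant: str,
    pdw: ContrastVolume | None,
    mtw: ContrastVolume | None,
) -> np.ndarray:
    if variant == "all":
        if pdw is None or mtw is None:
            raise MissingContrast("variant 'all' requires both PDw and MTw")
        return 0.5 * (pdw.data + mtw.data)
    if variant == "MT":
        if mtw is None:
            raise MissingContrast("variant 'MT' requires MTw")
        return mtw.data
    if pdw is None:
        raise MissingContrast("variant 'PD' requires PDw")
    return pdw.data


def compute_mprage_like(
    t1w: ContrastVolume,
    pdw: ContrastVolume | None = None,
    mtw: ContrastVolume | None = None,
    recipe: MPRAGELikeRecipe = MPRAGELikeRecipe(),
    clip: bool = True,
) -> ContrastVolume:
    """Synthesize the MPRAGE-like image for one subject.

    Parameters
    ----------
    t1w, pdw, mtw
        First-echo magnitude volumes on a common grid.  Only the contrasts
        required by ``recipe.variant`` need be supplied.
    recipe
        Variant, λ and clip window.
    clip
        When False the clip step is skipped (used by bias-cancellation and
        closed-form analyses).

    Returns
    -------
    ContrastVolume with ``weighting='synthetic'`` on the input grid.
    """
    present = [v for v in (t1w, pdw, mtw) if v is not None]
    for v in present:
        if not np.all(np.isfinite(v.data)):
            raise NonFiniteInput(f"{v.weighting} input contains non-finite values")
    if len(present) >= 2:
        validate_grid_compatible(present)
    denom = _denominator(recipe.variant, pdw, mtw)

    lam = recipe.lambda_reg
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (t1w.data - lam) / (denom + lam)
    out = np.where(np.isfinite(out), out, 0.0)
    if clip:
        out = np.where((out < recipe.clip_low) | (out > recipe.clip_high), 0.0, out)
    return ContrastVolume(
        out, spacing=t1w.spacing, affine=t1w.affine, weighting="synthetic"
    )


def relative_difference_map(
    image_lambda: ContrastVolume, image_lambda0: ContrastVolume
) -> tuple[np.ndarray, int]:
    """Voxelwise percent signal change of a regularized image vs its λ=0 image.

    Δs/s = 100 · (s(λ) − s(0)) / s(0).  Voxels with s(0) = 0 are NaN; the
    count of such voxels is returned alongside the map.
    """
    if not grid_compatible(image_lambda, image_lambda0):
        raise GridMismatch("Δs/s inputs are not on the same grid")
    s0 = image_lambda0.data
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * (image_lambda.data - s0) / s0
    zero = s0 == 0
    rel = np.where(zero, np.nan, rel)
    return rel, int(zero.sum())


def ssim(
    x: ContrastVolume | np.ndarray,
    y: ContrastVolume | np.ndarray,
    params: SSIMParams = SSIMParams(),
) -> float:
    """Structural similarity between two volumes.

    Global mode evaluates the three-factor luminance/contrast/structure
    product once from whole-volume means, SDs (ddof=1) and covariance:

        SSIM = (2 μx μy + C1)(2 σx σy + C2) / ((μx²+μy²+C1)(σx²+σy²+C2))
               × (cov + C3) / (σx σy + C3)

    Windowed mode averages the same expression over a cubic sliding window.
    """
    xa = x.data if isinstance(x, ContrastVolume) else np.asarray(x, dtype=float)
    ya = y.data if isinstance(y, ContrastVolume) else np.asarray(y, dtype=float)
    if isinstance(x, ContrastVolume) and isinstance(y, ContrastVolume):
        if not grid_compatible(x, y):
            raise GridMismatch("SSIM inputs are not on the same grid")
    if xa.shape != ya.shape:
        raise GridMismatch(f"SSIM inputs differ in shape: {xa.shape} vs {ya.shape}")
    if xa.size < 2:
        raise DegenerateInput("SSIM needs at least 2 voxels")
    c1, c2, c3 = params.constants(ya)
    if np.array_equal(xa, ya):
        # exact identity: every factor is 1 (constant pair with all-zero
        # constants is the 0/0 degenerate case)
        if np.ptp(xa) == 0 and c1 == c2 == c3 == 0:
            raise DegenerateInput("constant identical images with zero constants")
        return 1.0

    if params.mode == "global":
        return float(_ssim_formula(xa, ya, c1, c2, c3, ddof=1))

    w = params.window_size
    size = (w,) * 3
    n = float(w**3)
    mx = ndimage.uniform_filter(xa, size, mode="reflect")
    my = ndimage.uniform_filter(ya, size, mode="reflect")
    mxx = ndimage.uniform_filter(xa * xa, size, mode="reflect")
    myy = ndimage.uniform_filter(ya * ya, size, mode="reflect")
    mxy = ndimage.uniform_filter(xa * ya, size, mode="reflect")
    bessel = n / (n - 1.0)
    vx = np.maximum((mxx - mx * mx) * bessel, 0.0)
    vy = np.maximum((myy - my * my) * bessel, 0.0)
    cov = (mxy - mx * my) * bessel
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    num = (2 * mx * my + c1) * (2 * sx * sy + c2) * (cov + c3)
    den = (mx**2 + my**2 + c1) * (vx + vy + c2) * (sx * sy + c3)
    if np.any(den == 0):
        raise DegenerateInput("zero SSIM denominator; use nonzero constants")
    return float(np.mean(num / den))


def _ssim_formula(
    x: np.ndarray, y: np.ndarray, c1: float, c2: float, c3: float, ddof: int
) -> float:
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(ddof=ddof), y.std(ddof=ddof)
    cov = ((x - mx) * (y - my)).sum() / (x.size - ddof)
    den1 = mx**2 + my**2 + c1
    den2 = sx**2 + sy**2 + c2
    den3 = sx * sy + c3
    if den1 == 0 or den2 == 0 or den3 == 0:
        # identical-image limit: each factor tends to 1 as variances vanish
        if np.array_equal(x, y):
            return 1.0
        raise DegenerateInput(
            "SSIM denominator is zero (constant inputs with zero constants)"
        )
    return (
        (2 * mx * my + c1)
        / den1
        * (2 * sx * sy + c2)
        / den2
        * (cov + c3)
        / den3
    )


def sweep_lambda(
    subject_contrast_sets: Sequence[dict],
    reference_volumes: Sequence[ContrastVolume],
    variant: str = "all",
    lambda_values: Sequence[float] = DEFAULT_LAMBDA_GRID,
    ssim_params: SSIMParams = SSIMParams(),
    clip: bool = True,
    clip_bounds: tuple[float, float] = (0.0, 500.0),
) -> LambdaSweepResult:
    """Select λ by maximizing the mean SSIM against per-subject references.

    ``subject_contrast_sets`` is one dict per subject with keys among
    ``t1w``/``pdw``/``mtw``; ``reference_volumes`` supplies the matching
    reference anatomical image for each subject.
    """
    lams = [float(l) for l in lambda_values]
    if not lams or any(l < 0 for l in lams):
        raise InvalidParams("lambda_values must be nonempty and nonnegative")
    if len(subject_contrast_sets) != len(reference_volumes):
        raise InvalidParams("need exactly one reference per subject")
    values = np.empty((len(subject_contrast_sets), len(lams)))
    for i, (contrasts, ref) in enumerate(zip(subject_contrast_sets, reference_volumes)):
        for j, lam in enumerate(lams):
            recipe = MPRAGELikeRecipe(
                variant=variant,
                lambda_reg=lam,
                clip_low=clip_bounds[0],
                clip_high=clip_bounds[1],
            )
            img = compute_mprage_like(
                contrasts["t1w"],
                contrasts.get("pdw"),
                contrasts.get("mtw"),
                recipe,
                clip=clip,
            )
            values[i, j] = ssim(img, ref, ssim_params)
    return LambdaSweepResult(tuple(lams), values)
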