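"""Image-quality and segmentation-agreement metrics.

SNR and CNR over label-defined ROIs, Dice overlap and average symmetric
surface distance (ASSD) between segmentations, region-wise aggregation with
the missing-region rule (Dice 0 / ASSD NaN for regions absent from the test
segmentation), relative volume differences, and the two-sided Wilcoxon
signed-rank test with Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .core import (
    BothEmpty,
    AllZeroDifferences,
    ContrastVolume,
    EmptyROI,
    EmptySegment,
    GridMismatch,
    InvalidParams,
    LabelVolume,
    OverlappingROIs,
    ROIMask,
    TooFewPairs,
    grid_compatible,
    validate_grid_compatible,
)

__all__ = [
    "SurfaceSpec",
    "RegionMetricRow",
    "snr",
    "cnr",
    "dice",
    "assd",
    "boundary_voxels",
    "aggregate_segmentations",
    "relative_volume_difference",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
]


@dataclass(frozen=True)
class SurfaceSpec:
    """Boundary-extraction convention for surface distances.

    A surface voxel is a foreground voxel with at least one background
    neighbor under the given connectivity; distances are Euclidean between
    boundary-voxel centers, in mm, using the per-axis spacing.
    """

    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.connectivity not in (6, 18, 26):
            raise InvalidParams("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        rank = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, rank)


@dataclass
class RegionMetricRow:
    region_id: int
    region_name: str
    dsc: float
    assd_mm: float
    volume_ref_mm3: float
    volume_test_mm3: float
    rel_volume_diff_percent: float


def _roi_values(image: ContrastVolume, roi: ROIMask) -> np.ndarray:
    if not grid_compatible(image, roi):
        raise GridMismatch("image and ROI are not on the same grid")
    if roi.n_voxels == 0:
        raise EmptyROI(f"ROI {roi.name!r} is empty")
    return image.data[roi.mask]


def snr(image: ContrastVolume, roi: ROIMask) -> float:
    """Mean over SD (ddof=1) of the image within the ROI."""
    v = _roi_values(image, roi)
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    if sd == 0.0:
        warnings.warn(f"zero variance in ROI {roi.name!r}; SNR is +inf")
        return float("inf")
    return float(v.mean() / sd)


def cnr(image: ContrastVolume, roi_a: ROIMask, roi_b: ROIMask) -> float:
    """|mean_A − mean_B| / sqrt(SD_A² + SD_B²) with ddof=1 SDs."""
    if np.any(roi_a.mask & roi_b.mask):
        raise OverlappingROIs(f"ROIs {roi_a.name!r} and {roi_b.name!r} overlap")
    va = _roi_values(image, roi_a)
    vb = _roi_values(image, roi_b)
    var = (va.std(ddof=1) ** 2 if va.size > 1 else 0.0) + (
        vb.std(ddof=1) ** 2 if vb.size > 1 else 0.0
    )
    diff = abs(float(va.mean()) - float(vb.mean()))
    if var == 0.0:
        if diff == 0.0:
            return 0.0
        warnings.warn("zero variance in both ROIs; CNR is +inf")
        return float("inf")
    return diff / float(np.sqrt(var))


def dice(g: ROIMask, p: ROIMask) -> float:
    """Dice similarity coefficient 2|G∩P| / (|G| + |P|)."""
    if not grid_compatible(g, p):
        raise GridMismatch("masks are not on the same grid")
    ng, np_ = g.n_voxels, p.n_voxels
    if ng == 0 and np_ == 0:
        raise BothEmpty("both masks are empty")
    inter = int((g.mask & p.mask).sum())
    return 2.0 * inter / (ng + np_)


def boundary_voxels(mask: np.ndarray, surface: SurfaceSpec = SurfaceSpec()) -> np.ndarray:
    """Indices (N, 3) of foreground voxels with a background neighbor.

    Voxels on the array edge count as boundary (the outside is background).
    """
    mask = np.asarray(mask, bool)
    interior = ndimage.binary_erosion(mask, structure=surface.structure, border_value=0)
    return np.argwhere(mask & ~interior)


def assd(g: ROIMask, p: ROIMask, surface: SurfaceSpec = SurfaceSpec()) -> float:
    """Average symmetric surface distance in mm.

    ASSD = (Σ_i d(G_i → P) + Σ_j d(P_j → G)) / (N_G + N_P)

    over boundary-voxel centers, with anisotropy-aware Euclidean distances.
    """
    if not grid_compatible(g, p):
        raise GridMismatch("masks are not on the same grid")
    if g.n_voxels == 0 or p.n_voxels == 0:
        raise EmptySegment("ASSD requires both masks nonempty")
    sp = np.asarray(g.spacing)
    bg = boundary_voxels(g.mask, surface) * sp
    bp = boundary_voxels(p.mask, surface) * sp
    d_gp = cKDTree(bp).query(bg, k=1)[0]
    d_pg = cKDTree(bg).query(bp, k=1)[0]
    return float((d_gp.sum() + d_pg.sum()) / (len(bg) + len(bp)))


def relative_volume_difference(v_ref_mm3: float, v_test_mm3: float) -> float:
    """100 × (V_test − V_ref) / V_ref."""
    if v_ref_mm3 == 0:
        return float("nan")
    return 100.0 * (v_test_mm3 - v_ref_mm3) / v_ref_mm3


def aggregate_segmentations(
    reference: LabelVolume,
    test: LabelVolume,
    exclude_ids: Sequence[int] = (),
    surface: SurfaceSpec = SurfaceSpec(),
) -> tuple[pd.DataFrame, dict]:
    """Region-wise Dice/ASSD/volume table plus summary statistics.

    Every nonzero region present in the reference and not excluded yields a
    row.  Regions with no voxels in the test segmentation get Dice 0 and
    ASSD NaN.  The summary holds median, IQR bounds (25th/75th) and
    5th/95th percentiles over finite values, plus NaN counts.
    """
    validate_grid_compatible([reference, test])
    voxvol = reference.voxel_volume_mm3
    rows: list[RegionMetricRow] = []
    ids = sorted(set(np.unique(reference.labels).tolist()) - {0} - set(exclude_ids))
    for rid in ids:
        gm = reference.labels == rid
        pm = test.labels == rid
        name = reference.region_table.get(rid, str(rid))
        v_ref = float(gm.sum()) * voxvol
        v_test = float(pm.sum()) * voxvol
        g = ROIMask(gm, reference.spacing, reference.affine, name=name)
        p = ROIMask(pm, reference.spacing, reference.affine, name=name)
        if pm.sum() == 0:
            d, a = 0.0, float("nan")  # missing-region rule
        else:
            d = dice(g, p)
            a = assd(g, p, surface)
        rows.append(
            RegionMetricRow(
                region_id=int(rid),
                region_name=name,
                dsc=d,
                assd_mm=a,
                volume_ref_mm3=v_ref,
                volume_test_mm3=v_test,
                rel_volume_diff_percent=relative_volume_difference(v_ref, v_test),
            )
        )
    table = pd.DataFrame([r.__dict__ for r in rows])
    summary: dict[str, dict] = {}
    for col in ("dsc", "assd_mm", "rel_volume_diff_percent"):
        vals = table[col].to_numpy(dtype=float) if len(table) else np.array([])
        finite = vals[np.isfinite(vals)]
        summary[col] = {
            "median": float(np.median(finite)) if finite.size else float("nan"),
            "q25": float(np.percentile(finite, 25)) if finite.size else float("nan"),
            "q75": float(np.percentile(finite, 75)) if finite.size else float("nan"),
            "p5": float(np.percentile(finite, 5)) if finite.size else float("nan"),
            "p95": float(np.percentile(finite, 95)) if finite.size else float("nan"),
            "n_nan": int(np.size(vals) - finite.size),
        }
    return table, summary


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped first.  The exact null distribution (full
    sign enumeration) is used when n ≤ 20 and the |differences| are
    tie-free; otherwise the normal approximation with tie and continuity
    correction.  Returns (W, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidParams("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise AllZeroDifferences("all paired differences are zero")
    if d.size < 5:
        raise TooFewPairs(f"need >= 5 nonzero differences, got {d.size}")
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 20 and not has_ties) else "approx"
    res = stats.wilcoxon(
        d, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise significance threshold alpha / n_tests."""
    if not (0 < alpha < 1):
        raise InvalidParams("alpha must be in (0, 1)")
    if n_tests < 1:
        raise InvalidParams("n_tests must be >= 1")
    return alpha / n_tests
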