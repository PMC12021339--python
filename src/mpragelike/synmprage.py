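"""Comparator path: quantitative-map fitting and synthetic MPRAGE.

The apparent longitudinal relaxation rate R1app and proton-density
amplitude A are estimated from the dual-flip-angle (PDw, T1w) spoiled-GRE
pair with the standard small-flip-angle rational approximations; the
apparent MT saturation δapp follows from the MTw signal.  A pure-T1w
synthetic MPRAGE is then produced by evaluating an inversion-prepared
signal model voxelwise on the R1 map with unit equilibrium magnetization,
receive profile and transmit field (M0 = RP = B1 = 1), and the background
is masked via an Otsu threshold on the PD map followed by binary dilation
and closing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import (
    AcquisitionParams,
    ContrastVolume,
    DegenerateAngles,
    DegenerateInput,
    GridMismatch,
    InvalidParams,
    MPRAGETiming,
    QuantMap,
    ROIMask,
    grid_compatible,
    validate_grid_compatible,
)

__all__ = [
    "SynMPRAGEParams",
    "MaskingParams",
    "ReadoutParams",
    "estimate_r1app",
    "estimate_pd_amplitude",
    "estimate_mtsat",
    "mprage_signal",
    "compute_synmprage",
    "background_mask_from_pd",
]

# physical plausibility window for apparent R1 (s^-1); values outside are
# flagged NaN before synthesis to keep estimation outliers from inflating
# the synthetic image's noise
R1_PLAUSIBLE = (0.0, 10.0)


@dataclass(frozen=True)
class ReadoutParams:
    """Gradient-echo readout train for the steady-state MPRAGE model.

    The echo spacing and number of lines are placeholder defaults (not part
    of the printed protocol); the k-space-center line is taken at the
    midpoint of the train.
    """

    echo_spacing: float = 0.006  # s
    n_lines: int = 192

    def __post_init__(self) -> None:
        if self.echo_spacing <= 0 or self.n_lines < 1:
            raise InvalidParams("readout needs positive echo spacing and >= 1 line")


@dataclass(frozen=True)
class SynMPRAGEParams:
    """Sequence timing plus the scalar M0/RP/B1 terms (all fixed to 1 in the
    replication configuration) and the signal model choice."""

    sequence: MPRAGETiming = MPRAGETiming(ti=1.1, tr_cycle=2.7, alpha=math.radians(5.0), te=0.00214)
    m0: float = 1.0
    rp: float = 1.0
    b1: float = 1.0
    model: str = "ir_closed_form"  # ir_closed_form | readout_steady_state
    readout: ReadoutParams = field(default_factory=ReadoutParams)

    def __post_init__(self) -> None:
        if self.model not in ("ir_closed_form", "readout_steady_state"):
            raise InvalidParams(f"unknown model {self.model!r}")
        if self.m0 <= 0 or self.rp <= 0 or self.b1 <= 0:
            raise InvalidParams("m0, rp, b1 must be positive")
        if self.model == "readout_steady_state":
            n_center = self.readout.n_lines // 2
            if n_center * self.readout.echo_spacing >= self.sequence.ti:
                raise InvalidParams("readout train before k-space center exceeds TI")


@dataclass(frozen=True)
class MaskingParams:
    """Background-mask construction from the PD map.

    Negative PD values (non-physical fit outliers) are removed before the
    Otsu threshold; the binary mask is then dilated and closed with ball
    structuring elements of the given radii (radius 0 = no-op).
    """

    dilation_radius: int = 2
    closing_radius: int = 2
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.dilation_radius < 0 or self.closing_radius < 0:
            raise InvalidParams("morphology radii must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise InvalidParams("connectivity must be 6, 18 or 26")


def _local_angles(
    acq: AcquisitionParams, contrast: str, b1_map: np.ndarray | None
) -> np.ndarray | float:
    a = acq.alpha_nom[contrast]
    return a if b1_map is None else np.asarray(b1_map, dtype=float) * a


def estimate_r1app(
    t1w: ContrastVolume,
    pdw: ContrastVolume,
    acq: AcquisitionParams,
    b1_map: np.ndarray | None = None,
) -> QuantMap:
    """Apparent R1 (s^-1) from the dual-flip-angle pair.

    R1app = (S_T1·α_T1/TR_T1 − S_PD·α_PD/TR_PD)
            / (2·(S_PD/α_PD − S_T1/α_T1))

    which exactly inverts the small-flip-angle spoiled-GRE signal.  When a
    relative-B1 map is given, local flip angles B1 × nominal replace the
    nominal ones.  Negative or non-finite results are set to NaN.
    """
    validate_grid_compatible([t1w, pdw])
    a_t1 = _local_angles(acq, "T1w", b1_map)
    a_pd = _local_angles(acq, "PDw", b1_map)
    if np.all(np.isclose(a_t1, a_pd)):
        raise DegenerateAngles("T1w and PDw flip angles must differ")
    tr_t1, tr_pd = acq.tr["T1w"], acq.tr["PDw"]
    s_t1, s_pd = t1w.data, pdw.data
    num = s_t1 * a_t1 / tr_t1 - s_pd * a_pd / tr_pd
    den = 2.0 * (s_pd / a_pd - s_t1 / a_t1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = num / den
    bad = ~np.isfinite(r1) | (r1 < R1_PLAUSIBLE[0]) | (r1 > R1_PLAUSIBLE[1])
    r1 = np.where(bad, np.nan, r1)
    return QuantMap(r1, spacing=t1w.spacing, affine=t1w.affine, quantity="R1")


def estimate_pd_amplitude(
    t1w: ContrastVolume,
    pdw: ContrastVolume,
    acq: AcquisitionParams,
    b1_map: np.ndarray | None = None,
) -> QuantMap:
    """Proton-density amplitude A (a.u.) from the same dual-angle pair.

    A = S_PD·S_T1·(TR_PD·α_T1/α_PD − TR_T1·α_PD/α_T1)
        / (S_T1·TR_PD·α_T1 − S_PD·TR_T1·α_PD)

    A is receive-weighted (no calibration to water content is attempted).
    """
    validate_grid_compatible([t1w, pdw])
    a_t1 = _local_angles(acq, "T1w", b1_map)
    a_pd = _local_angles(acq, "PDw", b1_map)
    tr_t1, tr_pd = acq.tr["T1w"], acq.tr["PDw"]
    s_t1, s_pd = t1w.data, pdw.data
    num = s_pd * s_t1 * (tr_pd * a_t1 / a_pd - tr_t1 * a_pd / a_t1)
    den = s_t1 * tr_pd * a_t1 - s_pd * tr_t1 * a_pd
    with np.errstate(divide="ignore", invalid="ignore"):
        amp = num / den
    amp = np.where(np.isfinite(amp), amp, np.nan)
    return QuantMap(amp, spacing=t1w.spacing, affine=t1w.affine, quantity="PD")


def estimate_mtsat(
    mtw: ContrastVolume,
    r1: QuantMap,
    pd_amplitude: QuantMap | np.ndarray,
    acq: AcquisitionParams,
    b1_map: np.ndarray | None = None,
) -> QuantMap:
    """Apparent MT saturation δapp (dimensionless, per TR).

    δapp = (A·α_MT/S_MT − 1)·TR_MT·R1app − α_MT²/2

    exactly inverting the small-angle MT-weighted signal.  Voxels with
    S_MT ≤ 0 are NaN.
    """
    validate_grid_compatible([mtw, r1])
    amp = pd_amplitude.data if isinstance(pd_amplitude, QuantMap) else np.asarray(pd_amplitude, float)
    a_mt = _local_angles(acq, "MTw", b1_map)
    tr_mt = acq.tr["MTw"]
    s_mt = mtw.data
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = (amp * a_mt / s_mt - 1.0) * tr_mt * r1.data - a_mt**2 / 2.0
    delta = np.where((s_mt <= 0) | ~np.isfinite(delta), np.nan, delta)
    return QuantMap(delta, spacing=mtw.spacing, affine=mtw.affine, quantity="MTsat")


def mprage_signal(
    r1_value: float | np.ndarray, params: SynMPRAGEParams = SynMPRAGEParams()
) -> float | np.ndarray:
    """Synthetic MPRAGE signal (a.u.) for a given R1.

    ir_closed_form (default):
        S = m0 · sin(α) · (1 − 2·e^(−TI·R1) + e^(−TR·R1))
    readout_steady_state:
        S = m0 · sin(α) · Mz at the k-space-center excitation of the
        periodic steady state of {perfect inversion → relax (TI − n_c·τ) →
        n_c readout pulses (α, spacing τ) → relax to TR}.

    Both are scaled by rp (= 1 in the replication configuration) and use
    the effective flip angle b1 × α.
    """
    r1 = np.asarray(r1_value, dtype=float)
    if np.any(r1 < 0):
        raise InvalidParams("R1 must be >= 0")
    seq = params.sequence
    alpha = params.b1 * seq.alpha
    if params.model == "ir_closed_form":
        s = params.m0 * math.sin(alpha) * (
            1.0 - 2.0 * np.exp(-seq.ti * r1) + np.exp(-seq.tr_cycle * r1)
        )
    else:
        s = params.m0 * math.sin(alpha) * _steady_state_mz(r1, seq, alpha, params.readout)
    s = s * params.rp
    return s if isinstance(r1_value, np.ndarray) else float(s)

def _steady_state_mz(
    r1: np.ndarray, seq: MPRAGETiming, alpha: float, rd: ReadoutParams
) -> np.ndarray:
    """Longitudinal magnetization (units of m0) at the k-space-center pulse.

    One cycle maps Mz linearly, Mz -> a·Mz + b; compositions of relaxation
    (Mz -> Mz·e^(-tR1) + 1 − e^(-tR1)), perfect inversion (Mz -> −Mz) and
    excitation (Mz -> Mz·cos α) stay linear, so the periodic steady state is
    b_total / (1 − a_total) and the center value follows by replay.
    """
    n_center = max(rd.n_lines // 2, 1)
    tau = rd.echo_spacing
    t_pre = seq.ti - n_center * tau
    t_post = seq.tr_cycle - seq.ti - (rd.n_lines - n_center) * tau
    t_post = max(t_post, 0.0)
    cos_a = math.cos(alpha)

    def relax(a, b, t):
        e = np.exp(-t * r1)
        return a * e, b * e + (1.0 - e)

    def cycle(a, b, n_stop=None):
        a, b = -a, -b  # inversion
        a, b = relax(a, b, t_pre)
        for k in range(rd.n_lines):
            if n_stop is not None and k == n_stop:
                return a, b
            a, b = a * cos_a, b * cos_a  # excitation tips away sin component
            a, b = relax(a, b, tau)
        return relax(a, b, t_post)

    a_tot, b_tot = cycle(np.ones_like(r1), np.zeros_like(r1))
    mz_start = b_tot / (1.0 - a_tot)
    a_c, b_c = cycle(np.ones_like(r1), np.zeros_like(r1), n_stop=n_center)
    return a_c * mz_start + b_c


def compute_synmprage(
    r1_map: QuantMap,
    params: SynMPRAGEParams = SynMPRAGEParams(),
    mask: ROIMask | None = None,
) -> ContrastVolume:
    """Voxelwise synthetic MPRAGE from an R1 map.

    NaN / flagged R1 voxels map to 0; voxels outside the optional mask are
    set to 0.
    """
    if mask is not None and not grid_compatible(r1_map, mask):
        raise GridMismatch("mask is not on the R1 grid")
    r1 = r1_map.data
    valid = np.isfinite(r1) & (r1 >= R1_PLAUSIBLE[0]) & (r1 <= R1_PLAUSIBLE[1])
    out = np.zeros(r1.shape)
    out[valid] = mprage_signal(r1[valid], params)
    if mask is not None:
        out[~mask.mask] = 0.0
    return ContrastVolume(
        out, spacing=r1_map.spacing, affine=r1_map.affine, weighting="synthetic"
    )


def _ball(radius: int, connectivity: int) -> np.ndarray:
    if radius == 0:
        return np.ones((1, 1, 1), bool)
    order = {6: 1, 18: 2, 26: np.inf}[connectivity]
    span = np.arange(-radius, radius + 1)
    zz, yy, xx = np.meshgrid(span, span, span, indexing="ij")
    if order == 1:
        return np.abs(zz) + np.abs(yy) + np.abs(xx) <= radius
    if order == 2:
        return zz**2 + yy**2 + xx**2 <= radius**2
    return np.maximum.reduce([np.abs(zz), np.abs(yy), np.abs(xx)]) <= radius


def background_mask_from_pd(
    pd_map: QuantMap, params: MaskingParams = MaskingParams()
) -> ROIMask:
    """Brain mask from the PD map: drop negative outliers, Otsu-threshold,
    then binary dilation and closing.

    The threshold used is recorded on the returned mask as
    ``otsu_threshold``.
    """
    data = np.asarray(pd_map.data, dtype=float)
    finite = data[np.isfinite(data)]
    finite = finite[finite >= 0]  # negative fit outliers are not brain
    if finite.size == 0 or np.unique(finite).size < 2:
        raise DegenerateInput("PD map needs >= 2 distinct nonnegative finite values")
    thr = float(threshold_otsu(finite))
    mask = np.isfinite(data) & (data > thr)
    if params.dilation_radius > 0:
        mask = ndimage.binary_dilation(
            mask, structure=_ball(params.dilation_radius, params.connectivity)
        )
    if params.closing_radius > 0:
        mask = ndimage.binary_closing(
            mask, structure=_ball(params.closing_radius, params.connectivity)
        )
    roi = ROIMask(mask, spacing=pd_map.spacing, affine=pd_map.affine, name="pd_otsu")
    roi.otsu_threshold = thr  # type: ignore[attr-defined]
    return roi
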