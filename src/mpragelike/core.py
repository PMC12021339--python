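"""Shared domain types, grid conventions, and validation.

All volumes live on a common voxel grid (inputs are assumed coregistered);
operations act in voxel space and physical distances use the per-axis voxel
spacing in mm.  Flip angles are accepted in degrees at user-facing
interfaces and stored in radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "MpragelikeError",
    "GridMismatch",
    "MissingContrast",
    "NonFiniteInput",
    "DegenerateInput",
    "DegenerateAngles",
    "NonPositiveSignal",
    "EmptyROI",
    "OverlappingROIs",
    "BothEmpty",
    "EmptySegment",
    "TooFewPairs",
    "AllZeroDifferences",
    "InvalidParams",
    "InvalidSpec",
    "FormatError",
    "MPRAGETiming",
    "AcquisitionParams",
    "ContrastVolume",
    "QuantMap",
    "LabelVolume",
    "ROIMask",
    "grid_compatible",
    "validate_grid_compatible",
    "default_acquisition",
]

GRID_RTOL = 1e-4

CONTRASTS = ("T1w", "PDw", "MTw")
WEIGHTINGS = ("T1w", "PDw", "MTw", "synthetic", "reference")
QUANTITIES = ("R1", "MTsat", "PD")


class MpragelikeError(Exception):
    """Base class for all package errors."""


class GridMismatch(MpragelikeError):
    pass


class MissingContrast(MpragelikeError):
    pass


class NonFiniteInput(MpragelikeError):
    pass


class DegenerateInput(MpragelikeError):
    pass


class DegenerateAngles(MpragelikeError):
    pass


class NonPositiveSignal(MpragelikeError):
    pass


class EmptyROI(MpragelikeError):
    pass


class OverlappingROIs(MpragelikeError):
    pass


class BothEmpty(MpragelikeError):
    pass


class EmptySegment(MpragelikeError):
    pass


class TooFewPairs(MpragelikeError):
    pass


class AllZeroDifferences(MpragelikeError):
    pass


class InvalidParams(MpragelikeError):
    pass


class InvalidSpec(MpragelikeError):
    pass


class FormatError(MpragelikeError):
    pass


def _as_spacing(spacing: Sequence[float]) -> tuple[float, float, float]:
    sp = tuple(float(s) for s in spacing)
    if len(sp) != 3 or any(s <= 0 for s in sp):
        raise InvalidParams(f"spacing must be three positive values, got {spacing}")
    return sp  # type: ignore[return-value]


def _as_affine(affine: np.ndarray | None, spacing: tuple[float, float, float]) -> np.ndarray:
    if affine is None:
        aff = np.diag((*spacing, 1.0))
    else:
        aff = np.asarray(affine, dtype=float)
        if aff.shape != (4, 4):
            raise InvalidParams(f"affine must be 4x4, got shape {aff.shape}")
    return aff


@dataclass
class _GridVolume:
    """3D scalar field plus voxel grid geometry (spacing in mm, 4x4 affine)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidParams(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)
        self.affine = _as_affine(self.affine, self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ContrastVolume(_GridVolume):
    """A 3D magnitude image (a.u.) of one contrast weighting.

    ``weighting`` identifies which acquisition the image comes from
    (T1w/PDw/MTw first-echo magnitude, a synthesized image, or a reference
    anatomical).  Values must be finite.
    """

    weighting: str = "T1w"
    echo_index: int = 1

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float, copy=False)
        if self.weighting not in WEIGHTINGS:
            raise InvalidParams(
                f"weighting must be one of {WEIGHTINGS}, got {self.weighting!r}"
            )
        if int(self.echo_index) < 1:
            raise InvalidParams("echo_index must be >= 1")
        if not np.all(np.isfinite(self.data)):
            raise NonFiniteInput(
                f"{self.weighting} volume contains NaN/Inf values"
            )


@dataclass
class QuantMap(_GridVolume):
    """A 3D quantitative parameter map.

    ``quantity`` is one of R1 (s^-1), MTsat (dimensionless saturation per
    TR), or PD (a.u.).  NaN marks voxels flagged during estimation.
    """

    quantity: str = "R1"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(float, copy=False)
        if self.quantity not in QUANTITIES:
            raise InvalidParams(
                f"quantity must be one of {QUANTITIES}, got {self.quantity!r}"
            )


@dataclass
class LabelVolume(_GridVolume):
    """Integer segmentation with a region-id -> name table; background is 0."""

    region_table: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int32)
            if not np.allclose(self.data, as_int, atol=0):
                raise InvalidParams("label data must be integer-valued")
            self.data = as_int
        self.region_table = dict(self.region_table)
        present = set(np.unique(self.data).tolist()) - {0}
        missing = present - set(self.region_table)
        if missing:
            raise InvalidParams(
                f"region_table missing names for label ids {sorted(missing)}"
            )

    @property
    def labels(self) -> np.ndarray:
        return self.data

    def mask(self, ids: int | Sequence[int], name: str | None = None) -> "ROIMask":
        """Boolean ROI for one label id or a set of ids."""
        if np.isscalar(ids):
            ids = [int(ids)]  # type: ignore[list-item]
        ids = [int(i) for i in ids]  # type: ignore[union-attr]
        if name is None:
            name = "+".join(self.region_table.get(i, str(i)) for i in ids)
        m = np.isin(self.data, ids)
        return ROIMask(m, self.spacing, self.affine, name=name)


@dataclass
class ROIMask(_GridVolume):
    """Boolean region-of-interest on the same grid as its source volume."""

    name: str = "roi"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.data = self.data.astype(bool, copy=False)

    @property
    def mask(self) -> np.ndarray:
        return self.data

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class MPRAGETiming:
    """Inversion-prepared sequence timing: TI, cycle TR, excitation flip, TE.

    Times in seconds, flip angle in radians.  ``ti`` must precede the end of
    the cycle (``ti < tr_cycle``).
    """

    ti: float
    tr_cycle: float
    alpha: float
    te: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < math.pi / 2):
            raise InvalidParams(f"flip angle must be in (0, pi/2) rad, got {self.alpha}")
        if self.ti <= 0 or self.tr_cycle <= 0:
            raise InvalidParams("TI and TR must be positive")
        if self.ti >= self.tr_cycle:
            raise InvalidParams(f"TI ({self.ti}) must be < cycle TR ({self.tr_cycle})")


@dataclass(frozen=True)
class AcquisitionParams:
    """Nominal flip angles (rad) and TRs (s) per contrast, plus the
    inversion-prepared reference sequence timing.

    Construct from protocol units with :meth:`from_protocol` (degrees / ms).
    """

    alpha_nom: Mapping[str, float]
    tr: Mapping[str, float]
    te_list: tuple[float, ...] = ()
    mprage: MPRAGETiming | None = None

    def __post_init__(self) -> None:
        for c, a in self.alpha_nom.items():
            if not (0 < a < math.pi / 2):
                raise InvalidParams(
                    f"flip angle for {c} must be in (0, pi/2) rad, got {a}"
                )
        for c, t in self.tr.items():
            if t <= 0:
                raise InvalidParams(f"TR for {c} must be positive, got {t}")

    @classmethod
    def from_protocol(
        cls,
        flip_deg: Mapping[str, float],
        tr_ms: Mapping[str, float],
        te_ms: Sequence[float] = (),
        mprage_flip_deg: float | None = None,
        mprage_ti_ms: float | None = None,
        mprage_tr_ms: float | None = None,
        mprage_te_ms: float = 0.0,
    ) -> "AcquisitionParams":
        mpr = None
        if mprage_flip_deg is not None:
            mpr = MPRAGETiming(
                ti=mprage_ti_ms / 1000.0,
                tr_cycle=mprage_tr_ms / 1000.0,
                alpha=math.radians(mprage_flip_deg),
                te=mprage_te_ms / 1000.0,
            )
        return cls(
            alpha_nom={c: math.radians(a) for c, a in flip_deg.items()},
            tr={c: t / 1000.0 for c, t in tr_ms.items()},
            te_list=tuple(t / 1000.0 for t in te_ms),
            mprage=mpr,
        )


def default_acquisition() -> AcquisitionParams:
    """Protocol defaults: MTw/PDw/T1w flip 6/5/25 deg, TR 50.5/34.0/34.0 ms;
    reference MPRAGE flip 5 deg, TI 1100 ms, TR 2700 ms, TE 2.14 ms."""
    return AcquisitionParams.from_protocol(
        flip_deg={"MTw": 6.0, "PDw": 5.0, "T1w": 25.0},
        tr_ms={"MTw": 50.5, "PDw": 34.0, "T1w": 34.0},
        te_ms=(4.7, 11.8, 18.9, 26.0),
        mprage_flip_deg=5.0,
        mprage_ti_ms=1100.0,
        mprage_tr_ms=2700.0,
        mprage_te_ms=2.14,
    )


def grid_compatible(a: _GridVolume, b: _GridVolume, rtol: float = GRID_RTOL) -> bool:
    """True iff shapes, spacings and affines agree within ``rtol`` relative."""
    if a.shape != b.shape:
        return False
    if not np.allclose(a.spacing, b.spacing, rtol=rtol, atol=0):
        return False
    scale = max(1.0, float(np.abs(a.affine).max()))
    return bool(np.allclose(a.affine, b.affine, rtol=rtol, atol=rtol * scale))


def validate_grid_compatible(volumes: Sequence[_GridVolume], rtol: float = GRID_RTOL) -> None:
    """Raise :class:`GridMismatch` naming the first offending pair and axis."""
    if len(volumes) < 2:
        raise InvalidParams("need at least two volumes to compare grids")
    ref = volumes[0]
    for i, v in enumerate(volumes[1:], start=1):
        if ref.shape != v.shape:
            axis = next(
                (k for k, (x, y) in enumerate(zip(ref.shape, v.shape)) if x != y),
                0,
            )
            raise GridMismatch(
                f"volumes 0 and {i} differ in shape on axis {axis}: "
                f"{ref.shape} vs {v.shape}"
            )
        sp_ok = np.isclose(ref.spacing, v.spacing, rtol=rtol, atol=0)
        if not sp_ok.all():
            axis = int(np.flatnonzero(~sp_ok)[0])
            raise GridMismatch(
                f"volumes 0 and {i} differ in spacing on axis {axis}: "
                f"{ref.spacing[axis]} vs {v.spacing[axis]} mm"
            )
        if not grid_compatible(ref, v, rtol=rtol):
            raise GridMismatch(f"volumes 0 and {i} differ in affine")
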