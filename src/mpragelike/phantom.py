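"""Seeded digital brain phantom emitting MTw/PDw/T1w spoiled-GRE contrasts.

The phantom is a set of nested, seeded-jittered ellipsoids (CSF envelope,
cortical GM shell, WM core, two embedded subcortical nuclei) with per-tissue
R1 / PD / MT-saturation values, smooth multiplicative transmit and receive
fields, and optional Gaussian or Rician noise.  Signals follow the spoiled
gradient-echo equations the ratio-image approximations rest on, in either a
small-flip-angle or an exact-SPGR (Ernst) form, so every downstream module
can be tested end-to-end against known ground truth without any download.

Default tissue parameters are 7T-plausible configuration values shipped in
``data/tissue_defaults.json``; they are implementation choices, not measured
constants, and tests read them from the config so alternates can be swapped
in.  PD is scaled so raw contrast intensities land in the hundreds-to-
thousands range matching the default clip window of the synthesis module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np

from .core import (
    AcquisitionParams,
    ContrastVolume,
    InvalidParams,
    InvalidSpec,
    LabelVolume,
    QuantMap,
    default_acquisition,
)

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "load_default_tissues",
    "make_label_phantom",
    "spgr_signal",
    "mprage_like_closed_form",
    "simulate_contrast_set",
    "simulate_phantom",
]


@dataclass(frozen=True)
class TissueClass:
    id: int
    r1: float  # s^-1
    pd: float  # a.u.
    mtsat: float  # dimensionless saturation per TR
    r2star: float = 0.0  # s^-1, metadata only (no multi-echo decay simulated)


@dataclass(frozen=True)
class TissueParams:
    """Per-tissue-class parameters keyed by class name."""

    classes: Mapping[str, TissueClass]

    def __post_init__(self) -> None:
        if "background" not in self.classes or self.classes["background"].id != 0:
            raise InvalidSpec("tissue set must contain 'background' with id 0")
        if self.classes["background"].pd != 0:
            raise InvalidSpec("background PD must be 0")
        ids = [t.id for t in self.classes.values()]
        if len(set(ids)) != len(ids):
            raise InvalidSpec("tissue class ids must be unique")

    @property
    def region_table(self) -> dict[int, str]:
        return {t.id: name for name, t in self.classes.items() if t.id != 0}

    def map_of(self, attr: str, labels: np.ndarray) -> np.ndarray:
        """Paint a parameter map from a label array."""
        out = np.zeros(labels.shape, dtype=float)
        for t in self.classes.values():
            out[labels == t.id] = getattr(t, attr)
        return out


def load_default_tissues() -> TissueParams:
    text = resources.files("mpragelike.data").joinpath("tissue_defaults.json").read_text()
    raw = json.loads(text)
    return TissueParams(
        {name: TissueClass(**params) for name, params in raw.items()}
    )


@dataclass(frozen=True)
class FieldSpec:
    """Smooth multiplicative field: seeded low-frequency cosine mixture
    rescaled linearly into [low, high]."""

    low: float = 1.0
    high: float = 1.0
    n_components: int = 3

    def __post_init__(self) -> None:
        if not (0 < self.low <= self.high):
            raise InvalidSpec("field bounds must satisfy 0 < low <= high")


@dataclass(frozen=True)
class NoiseSpec:
    kind: str = "none"  # none | gaussian | rician
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "rician"):
            raise InvalidSpec(f"unknown noise kind {self.kind!r}")
        if self.sd < 0:
            raise InvalidSpec("noise sd must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Everything that determines one simulated dataset, including the seed.

    Transmit range defaults to [0.75, 1.25] of nominal (realized flip angles
    between 75% and 125% of nominal are typical at 7T); the receive field is
    shared by all three contrasts.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    transmit_field: FieldSpec = FieldSpec(0.75, 1.25)
    receive_field: FieldSpec = FieldSpec(0.8, 1.2)
    noise: NoiseSpec = NoiseSpec("rician", 20.0)
    signal_model: str = "small_angle"  # small_angle | exact_spgr
    jitter: float = 0.05  # relative semi-axis jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or min(self.shape) < 16:
            raise InvalidSpec("phantom shape must be 3D with >= 16 voxels per axis")
        if self.signal_model not in ("small_angle", "exact_spgr"):
            raise InvalidSpec(f"unknown signal model {self.signal_model!r}")


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return q <= 1.0


def make_label_phantom(
    spec: PhantomSpec, tissues: TissueParams | None = None
) -> LabelVolume:
    """Deterministic (seeded) nested-ellipsoid label map.

    Layout: CSF envelope > cortical GM shell > WM core, with two ellipsoidal
    nuclei (thalamus, putamen) embedded in the WM.  Semi-axes and centers are
    jittered by the seed so repeated seeds exercise surface metrics on
    different geometry; equal specs give bit-identical maps.
    """
    if tissues is None:
        tissues = load_default_tissues()
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    base_center = np.array(shape, dtype=float) / 2.0 - 0.5
    center = base_center + rng.uniform(-1.5, 1.5, size=3)
    ax = np.array(shape, dtype=float)

    def jit(scale: float) -> np.ndarray:
        return scale * ax * (1.0 + rng.uniform(-spec.jitter, spec.jitter, size=3))

    labels = np.zeros(shape, dtype=np.int32)
    ids = {name: t.id for name, t in tissues.classes.items()}
    labels[_ellipsoid(shape, center, jit(0.44))] = ids["CSF"]
    labels[_ellipsoid(shape, center, jit(0.38))] = ids["cortical_GM"]
    labels[_ellipsoid(shape, center, jit(0.30))] = ids["WM"]
    # two nuclei left/right of midline, inside the WM core
    nuc_ax = np.maximum(jit(0.06), 1.6)
    off = 0.12 * ax[0]
    thal_c = center + np.array([-off, 0.0, 0.0]) + rng.uniform(-1.0, 1.0, 3)
    put_c = center + np.array([off, 0.0, 0.0]) + rng.uniform(-1.0, 1.0, 3)
    labels[_ellipsoid(shape, thal_c, nuc_ax)] = ids["thalamus"]
    labels[_ellipsoid(shape, put_c, np.maximum(jit(0.055), 1.6))] = ids["putamen"]

    vol = LabelVolume(labels, spacing=spec.spacing, region_table=tissues.region_table)
    counts = {i: int((labels == i).sum()) for i in ids.values()}
    empty = [i for i, n in counts.items() if n == 0]
    if empty:
        raise InvalidSpec(f"phantom geometry produced empty classes {empty}")
    return vol


def _smooth_field(shape, fspec: FieldSpec, rng: np.random.Generator) -> np.ndarray:
    """Strictly positive smooth field in [low, high]."""
    if fspec.low == fspec.high:
        return np.full(shape, fspec.low)
    grids = np.meshgrid(
        *[np.linspace(0.0, 1.0, s) for s in shape], indexing="ij", sparse=True
    )
    f = np.zeros(shape)
    for _ in range(fspec.n_components):
        freq = rng.uniform(0.5, 1.5, size=3)
        phase = rng.uniform(0, 2 * math.pi, size=3)
        amp = rng.uniform(0.5, 1.0)
        term = amp
        for g, fr, ph in zip(grids, freq, phase):
            term = term * np.cos(2 * math.pi * fr * g + ph)
        f = f + term
    lo, hi = float(f.min()), float(f.max())
    if hi == lo:
        return np.full(shape, 0.5 * (fspec.low + fspec.high))
    return fspec.low + (f - lo) * (fspec.high - fspec.low) / (hi - lo)


def spgr_signal(
    r1: float | np.ndarray,
    pd: float | np.ndarray,
    delta: float | np.ndarray,
    alpha: float | np.ndarray,
    tr: float,
    model: str = "small_angle",
) -> np.ndarray:
    """Spoiled-GRE steady-state signal with optional MT saturation.

    small_angle:
        S = pd · α · TR·R1 / (α²/2 + δ + TR·R1)
    exact_spgr (Ernst with per-TR fractional saturation δ of the
    longitudinal magnetization):
        S = pd · sin(α) · (1 − E) / (1 − (1 − δ)·cos(α)·E),  E = exp(−TR·R1)

    δ = 0 reduces the MT-weighted formula to the plain SPGR signal; pd
    carries any receive-profile scaling.
    """
    if tr <= 0:
        raise InvalidParams("TR must be positive")
    r1 = np.asarray(r1, dtype=float)
    delta = np.asarray(delta, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0) or np.any(alpha >= math.pi / 2):
        raise InvalidParams("flip angle must be in (0, pi/2) rad")
    if np.any(delta < 0):
        raise InvalidParams("MT saturation delta must be >= 0")
    if model == "small_angle":
        denom = alpha**2 / 2.0 + delta + tr * r1
        with np.errstate(invalid="ignore", divide="ignore"):
            s = np.where(denom > 0, pd * alpha * tr * r1 / np.where(denom > 0, denom, 1.0), 0.0)
        return s
    if model == "exact_spgr":
        e = np.exp(-tr * r1)
        denom = 1.0 - (1.0 - delta) * np.cos(alpha) * e
        return pd * np.sin(alpha) * (1.0 - e) / denom
    raise InvalidParams(f"unknown signal model {model!r}")


def mprage_like_closed_form(
    r1: np.ndarray,
    delta: np.ndarray,
    acq: AcquisitionParams,
    variant: str = "all",
    transmit: np.ndarray | float = 1.0,
) -> np.ndarray:
    """Receive-bias-free prediction of the λ=0 ratio image from R1 and δ.

    Built from the per-contrast weight w_X = α_X·TR_X / (α_X² + 2δ_X +
    2·TR_X·R1), which equals S_X / (2·PD·R1) in the small-angle model, so
    every ratio of signals equals the same ratio of weights.  The printed
    two-contrast form without the TR ratio is the special case of equal TRs
    (as in the default protocol).  ``transmit`` scales the nominal flip
    angles for B1+-aware predictions.
    """
    r1 = np.asarray(r1, dtype=float)
    delta = np.asarray(delta, dtype=float)

    def w(contrast: str, d) -> np.ndarray:
        a = acq.alpha_nom[contrast] * np.asarray(transmit, dtype=float)
        tr = acq.tr[contrast]
        return a * tr / (a**2 + 2.0 * np.asarray(d) + 2.0 * tr * r1)

    num = w("T1w", 0.0)
    if variant == "all":
        den = 0.5 * (w("MTw", delta) + w("PDw", 0.0))
    elif variant == "MT":
        den = w("MTw", delta)
    elif variant == "PD":
        den = w("PDw", 0.0)
    else:
        raise InvalidParams(f"unknown variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    return np.where(np.isfinite(out), out, 0.0)


def simulate_contrast_set(
    labels: LabelVolume,
    tissues: TissueParams,
    acq: AcquisitionParams,
    spec: PhantomSpec,
) -> dict:
    """Simulate the three first-echo MPM contrasts plus ground truth.

    Per voxel the local flip angle is transmit_field × nominal α, the signal
    comes from :func:`spgr_signal` (δ applies only to the MTw contrast), all
    three contrasts share one multiplicative receive field, and seeded noise
    is added last.  Returns ``{'mtw','pdw','t1w'}`` ContrastVolumes plus
    ground-truth maps and both fields under ``'truth'``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = labels.shape
    lab = labels.labels
    r1 = tissues.map_of("r1", lab)
    pd = tissues.map_of("pd", lab)
    delta = tissues.map_of("mtsat", lab)

    transmit = _smooth_field(shape, spec.transmit_field, rng)
    receive = _smooth_field(shape, spec.receive_field, rng)

    contrasts: dict[str, ContrastVolume] = {}
    for key, weighting in (("mtw", "MTw"), ("pdw", "PDw"), ("t1w", "T1w")):
        alpha_local = transmit * acq.alpha_nom[weighting]
        d = delta if weighting == "MTw" else 0.0
        sig = spgr_signal(r1, pd, d, alpha_local, acq.tr[weighting], spec.signal_model)
        sig = sig * receive
        sig = _add_noise(sig, spec.noise, rng)
        contrasts[key] = ContrastVolume(
            sig, spacing=spec.spacing, weighting=weighting
        )

    truth = {
        "r1": QuantMap(r1, spacing=spec.spacing, quantity="R1"),
        "pd": QuantMap(pd, spacing=spec.spacing, quantity="PD"),
        "delta": QuantMap(delta, spacing=spec.spacing, quantity="MTsat"),
        "transmit": transmit,
        "receive": receive,
        "labels": labels,
    }
    return {**contrasts, "truth": truth}


def _add_noise(signal: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    if noise.kind == "none" or noise.sd == 0:
        return signal
    if noise.kind == "gaussian":
        return signal + rng.normal(0.0, noise.sd, signal.shape)
    # rician: magnitude of a complex Gaussian perturbation of the signal
    re = signal + rng.normal(0.0, noise.sd, signal.shape)
    im = rng.normal(0.0, noise.sd, signal.shape)
    return np.hypot(re, im)


def simulate_phantom(
    spec: PhantomSpec,
    tissues: TissueParams | None = None,
    acq: AcquisitionParams | None = None,
) -> dict:
    """Convenience one-call phantom: label map + contrasts + ground truth."""
    if tissues is None:
        tissues = load_default_tissues()
    if acq is None:
        acq = default_acquisition()
    labels = make_label_phantom(spec, tissues)
    return simulate_contrast_set(labels, tissues, acq, spec)


def noiseless(spec: PhantomSpec) -> PhantomSpec:
    """Copy of a spec with noise switched off."""
    return replace(spec, noise=NoiseSpec("none", 0.0))
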