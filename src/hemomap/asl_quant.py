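"""Multi-delay pcASL kinetic-model fitting for calibrated CBF and ATT maps.

The tissue compartment follows the standard pcASL general kinetic model with
a plug-flow bolus of labelled blood; an optional macrovascular (arterial)
component is available behind a flag but disabled by default, since the
tissue term carries the CBF estimate.  CBF is handled internally in
mL g^-1 s^-1 and reported in mL/100 g/min (factor 6000), calibrated
voxelwise by the measured M0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .qbold_fit import smooth_volume

__all__ = [
    "AslProtocol",
    "PerfusionState",
    "asl_signal",
    "fit_cbf_att",
    "fit_asl_volume",
    "preprocess_asl",
    "CBF_UNIT_FACTOR",
]

logger = logging.getLogger(__name__)

#: mL g^-1 s^-1  ->  mL / 100 g / min.
CBF_UNIT_FACTOR = 6000.0


@dataclass(frozen=True)
class AslProtocol:
    """pcASL acquisition and kinetic constants.

    plds : post-labeling delays, seconds (ascending).
    label_duration : labeling bolus duration, seconds.
    t1b / t1t : longitudinal relaxation times of blood / tissue, seconds.
    lam : brain/blood partition coefficient, mL/g.
    alpha : labeling efficiency (fraction).
    """

    plds: tuple = (0.9, 1.2, 1.4, 1.8, 2.1)
    label_duration: float = 2.0
    t1b: float = 1.65
    t1t: float = 1.3
    lam: float = 0.9
    alpha: float = 0.85

    def __post_init__(self):
        object.__setattr__(self, "plds", tuple(float(p) for p in self.plds))
        for name in ("label_duration", "t1b", "t1t", "lam", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        p = np.asarray(self.plds)
        if p.size == 0 or np.any(p < 0):
            raise ValueError("plds must be non-negative")
        if p.size > 1 and np.any(np.diff(p) <= 0):
            raise ValueError("plds must be strictly increasing")

    @property
    def pld_array(self) -> np.ndarray:
        return np.asarray(self.plds, dtype=float)


@dataclass(frozen=True)
class PerfusionState:
    """Per-voxel perfusion parameters.

    cbf : perfusion in mL/100 g/min (reporting units).
    att : arterial transit time, seconds.
    m0 : equilibrium magnetization, arbitrary units.
    """

    cbf: float
    att: float
    m0: float = 1.0

    def __post_init__(self):
        if self.cbf < 0:
            raise ValueError(f"cbf must be >= 0, got {self.cbf}")
        if self.att < 0:
            raise ValueError(f"att must be >= 0, got {self.att}")


def _dm_core(f, att, m0, proto: AslProtocol, t):
    """Labelled-blood difference signal at time-since-labeling-onset ``t``.

    ``f`` is perfusion in mL g^-1 s^-1.  Plug-flow bolus: zero before
    arrival, inflow saturation during the bolus, T1t decay afterwards; the
    three branches are continuous at t = ATT and t = ATT + LD.
    """
    f, att, m0, t = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (f, att, m0, t))
    )
    ld = proto.label_duration
    amp = 2.0 * proto.alpha * (m0 / proto.lam) * f * proto.t1t * np.exp(-att / proto.t1b)
    during = 1.0 - np.exp(-np.clip(t - att, 0, None) / proto.t1t)
    after = (1.0 - np.exp(-ld / proto.t1t)) * np.exp(-np.clip(t - att - ld, 0, None) / proto.t1t)
    out = np.where(t < att, 0.0, amp * np.where(t < att + ld, during, after))
    return out


def _dm_arterial(abv, att_a, m0, proto: AslProtocol, t):
    """Optional macrovascular component: labelled blood transiting large vessels."""
    t = np.asarray(t, dtype=float)
    inside = (t >= att_a) & (t < att_a + proto.label_duration)
    return np.where(inside, 2.0 * proto.alpha * m0 * abv * np.exp(-t / proto.t1b), 0.0)


def asl_signal(state: PerfusionState, proto: AslProtocol, pld, *,
               arterial_blood_volume: float = 0.0, arterial_att: float | None = None):
    """Difference signal dM at post-labeling delay(s) ``pld`` (seconds).

    The macrovascular term is added only when ``arterial_blood_volume`` > 0
    (default off).
    """
    pld_arr = np.asarray(pld, dtype=float)
    if np.any(pld_arr < 0):
        raise ValueError("pld must be >= 0")
    t = proto.label_duration + pld_arr
    f = state.cbf / CBF_UNIT_FACTOR
    out = _dm_core(f, state.att, state.m0, proto, t)
    if arterial_blood_volume > 0:
        att_a = state.att if arterial_att is None else arterial_att
        out = out + _dm_arterial(arterial_blood_volume, att_a, state.m0, proto, t)
    return float(out) if pld_arr.ndim == 0 else out


def fit_cbf_att(series, m0: float, proto: AslProtocol, *,
                att_init: float = 1.3) -> PerfusionState | None:
    """Nonlinear least-squares fit of (CBF, ATT) to a per-voxel dM series.

    Returns None for invalid input (non-positive M0 or non-finite samples)
    so a volume fit can flag the voxel instead of aborting.  All-zero series
    yield CBF = 0 with the initial ATT.  Deterministic.
    """
    y = np.asarray(series, dtype=float)
    plds = proto.pld_array
    if y.shape != plds.shape:
        raise ValueError(f"series has {y.size} samples but protocol lists {plds.size} PLDs")
    if plds.size < 2:
        raise ValueError("need at least 2 PLDs to fit CBF and ATT")
    if not np.isfinite(m0) or m0 <= 0 or not np.all(np.isfinite(y)):
        return None
    if np.all(y == 0):
        return PerfusionState(cbf=0.0, att=att_init, m0=float(m0))

    t = proto.label_duration + plds
    # Scale init from the peak sample assuming the bolus has fully arrived.
    denom = (2.0 * proto.alpha * (m0 / proto.lam) * proto.t1t
             * np.exp(-att_init / proto.t1b) * (1.0 - np.exp(-proto.label_duration / proto.t1t)))
    f_init = max(float(np.max(y)) / denom, 1e-6) if denom > 0 else 1e-2

    def residuals(x):
        f, att = x
        return _dm_core(f, att, m0, proto, t) - y

    res = least_squares(
        residuals,
        x0=np.array([f_init, att_init]),
        bounds=(np.array([0.0, 0.0]), np.array([1.0, float(t.max())])),
        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
    )
    f_hat, att_hat = res.x
    return PerfusionState(cbf=float(f_hat) * CBF_UNIT_FACTOR, att=float(att_hat), m0=float(m0))


def preprocess_asl(volumes: np.ndarray, *, sigma_mm: float = 1.5,
                   voxel_size_mm=(3.0, 3.0, 3.0), mask: np.ndarray | None = None) -> np.ndarray:
    """Smooth a PLD-stacked 4-D dM series (last axis = PLD) with a 1.5 mm kernel."""
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError("expected a 4-D PLD-stacked array")
    out = np.empty_like(volumes)
    for k in range(volumes.shape[-1]):
        out[..., k] = smooth_volume(volumes[..., k], sigma_mm, voxel_size_mm)
    if mask is not None:
        out[~np.asarray(mask, dtype=bool)] = 0.0
    return out


def fit_asl_volume(dm_4d: np.ndarray, m0_vol: np.ndarray, mask: np.ndarray,
                   proto: AslProtocol, *, deduplicate: bool = True):
    """Fit CBF/ATT for every masked voxel of a PLD-stacked volume.

    Returns ``(cbf_map, att_map, valid_mask)`` with NaN outside valid voxels.
    Identical (series, M0) pairs are fitted once and shared.
    """
    dm_4d = np.asarray(dm_4d, dtype=float)
    if dm_4d.ndim != 4 or dm_4d.shape[-1] != len(proto.plds):
        raise ValueError("dm_4d must be 4-D with one volume per protocol PLD")
    mask = np.asarray(mask, dtype=bool)
    m0_vol = np.asarray(m0_vol, dtype=float)
    if mask.shape != dm_4d.shape[:-1] or m0_vol.shape != mask.shape:
        raise ValueError("grid mismatch between dm series, m0 and mask")

    rows = np.column_stack([dm_4d[mask], m0_vol[mask]])
    if deduplicate and rows.shape[0]:
        uniq, inverse = np.unique(rows, axis=0, return_inverse=True)
    else:
        uniq, inverse = rows, np.arange(rows.shape[0])
    logger.info("fitting %d voxels (%d unique ASL series)", rows.shape[0], uniq.shape[0])

    fits = [fit_cbf_att(row[:-1], row[-1], proto) for row in uniq]
    cbf = np.full(mask.shape, np.nan)
    att = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    if rows.shape[0]:
        cbf[mask] = [np.nan if f is None else f.cbf for f in (fits[j] for j in inverse)]
        att[mask] = [np.nan if f is None else f.att for f in (fits[j] for j in inverse)]
        valid[mask] = [fits[j] is not None for j in inverse]
    return cbf, att, valid
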