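"""Closed-form two-compartment signal model for asymmetric spin-echo (ASE) MRI.

The voxel signal is the volume-weighted sum of an extravascular tissue
compartment, whose reversible dephasing around randomly oriented vessels is
described by a short-/long-offset asymptotic pair, and an intravascular blood
compartment given by the Fresnel-integral closed form of the static-dephasing
powder average.  The physiological link between the oxygen extraction fraction
(OEF), the deoxygenated blood volume fraction (DBV), the characteristic
frequency ``delta_omega`` and the reversible relaxation rate ``R2' = DBV *
delta_omega`` lives here as well, so that simulation and fitting share one
set of physical relations.

All quantities are SI internally: seconds, s^-1, tesla, and dimensionless
fractions.  Percent and milliseconds appear only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import fresnel

__all__ = [
    "GAMMA_PROTON",
    "REGIME_BOUNDARY_FACTOR",
    "AseProtocol",
    "TissueConstants",
    "VoxelState",
    "DephasingDerived",
    "delta_omega",
    "oef_from_r2p_dbv",
    "dephasing",
    "r2b",
    "tissue_signal",
    "blood_signal",
    "total_signal",
    "ase_signal_stack",
    "powder_average_oracle",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.675e8

#: The long-offset regime starts at Tc = 1.76 * tc with tc = 1 / delta_omega.
REGIME_BOUNDARY_FACTOR = 1.76

#: Default spin-echo displacement times: tau = 0 plus 16..40 ms in 4 ms steps.
DEFAULT_TAUS = (0.0, 0.016, 0.020, 0.024, 0.028, 0.032, 0.036, 0.040)


@dataclass(frozen=True)
class AseProtocol:
    """ASE acquisition timing shared by simulation and fitting.

    Parameters
    ----------
    te : float
        Echo time in seconds.
    tr : float
        Repetition time in seconds.
    taus : tuple of float
        Ordered spin-echo displacement times in seconds; strictly increasing,
        all non-negative.
    b0 : float
        Main field strength in tesla.
    """

    te: float = 0.056
    tr: float = 3.0
    taus: tuple = DEFAULT_TAUS
    b0: float = 3.0

    def __post_init__(self):
        object.__setattr__(self, "taus", tuple(float(t) for t in self.taus))
        if self.te <= 0:
            raise ValueError(f"te must be positive, got {self.te}")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.b0 <= 0:
            raise ValueError(f"b0 must be positive, got {self.b0}")
        t = np.asarray(self.taus, dtype=float)
        if t.size == 0:
            raise ValueError("taus must be non-empty")
        if np.any(t < 0):
            raise ValueError("all taus must be >= 0")
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("taus must be strictly increasing")

    @property
    def tau_array(self) -> np.ndarray:
        return np.asarray(self.taus, dtype=float)


@dataclass(frozen=True)
class TissueConstants:
    """Fixed physical/physiological constants of the signal model.

    gamma : proton gyromagnetic ratio, rad s^-1 T^-1.
    dchi0 : susceptibility difference between fully oxygenated and fully
        deoxygenated red cells (dimensionless, SI).
    r2t : irreversible transverse relaxation rate of bulk tissue, s^-1.
    hct : fractional hematocrit.
    """

    gamma: float = GAMMA_PROTON
    dchi0: float = 0.264e-6
    r2t: float = 11.5
    hct: float = 0.40

    def __post_init__(self):
        for name in ("gamma", "dchi0", "r2t", "hct"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.hct < 1.0:
            raise ValueError(f"hct must be in (0, 1), got {self.hct}")


@dataclass(frozen=True)
class VoxelState:
    """Per-voxel physiology: the unit of simulation and fitting.

    s0 : equilibrium signal amplitude (arbitrary units, > 0).
    oef : oxygen extraction fraction, stored as a fraction in [0, 1].
    dbv : deoxygenated blood volume, stored as a fraction in [0, 1).
    """

    s0: float
    oef: float
    dbv: float

    def __post_init__(self):
        if self.s0 <= 0:
            raise ValueError(f"s0 must be positive, got {self.s0}")
        if not 0.0 <= self.oef <= 1.0:
            raise ValueError(f"oef must be a fraction in [0, 1], got {self.oef}")
        if not 0.0 <= self.dbv < 1.0:
            raise ValueError(f"dbv must be a fraction in [0, 1), got {self.dbv}")


@dataclass(frozen=True)
class DephasingDerived:
    """Dephasing quantities derived from a voxel state.

    delta_omega : characteristic frequency, s^-1.
    r2p : reversible relaxation rate R2' = DBV * delta_omega, s^-1.
    tc_small : characteristic time tc = 1 / delta_omega, seconds.
    tc_boundary : regime boundary Tc = 1.76 * tc, seconds.
    """

    delta_omega: float
    r2p: float
    tc_small: float
    tc_boundary: float


def delta_omega(oef, const: TissueConstants, b0: float):
    """Characteristic dephasing frequency (s^-1) for a given OEF.

    ``delta_omega = (4*pi/3) * gamma * B0 * dchi0 * Hct * OEF``, zero iff
    ``oef`` is zero.  Accepts scalars or arrays; negative or >1 OEF raises.
    """
    oef_arr = np.asarray(oef, dtype=float)
    if np.any(oef_arr < 0) or np.any(oef_arr > 1):
        raise ValueError("oef must lie in [0, 1]")
    out = (4.0 * np.pi / 3.0) * const.gamma * b0 * const.dchi0 * const.hct * oef_arr
    return float(out) if out.ndim == 0 else out


def oef_from_r2p_dbv(r2p, dbv, const: TissueConstants, b0: float):
    """Invert ``R2' = DBV * delta_omega(OEF)`` for OEF.

    ``OEF = 3 * R2' / (4*pi * gamma * B0 * dchi0 * Hct * DBV)``.  Vectorized;
    where ``dbv`` is zero the result is NaN (the caller decides validity).
    """
    r2p_arr = np.asarray(r2p, dtype=float)
    dbv_arr = np.asarray(dbv, dtype=float)
    unit = (4.0 * np.pi / 3.0) * const.gamma * b0 * const.dchi0 * const.hct
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dbv_arr != 0, r2p_arr / (dbv_arr * unit), np.nan)
    return float(out) if out.ndim == 0 else out


def dephasing(state: VoxelState, const: TissueConstants, b0: float) -> DephasingDerived:
    """Derive (delta_omega, R2', tc, Tc) from a voxel state."""
    dw = delta_omega(state.oef, const, b0)
    tc = 1.0 / dw if dw > 0 else np.inf
    return DephasingDerived(
        delta_omega=dw,
        r2p=state.dbv * dw,
        tc_small=tc,
        tc_boundary=REGIME_BOUNDARY_FACTOR * tc,
    )


def r2b(hct, oef):
    """Transverse relaxation rate of blood (s^-1) from hematocrit and OEF.

    ``R2b = 16.4*Hct + 4.5 + (165.2*Hct + 55.7) * OEF**2``; monotone
    increasing in both arguments on their valid domains.
    """
    hct_arr = np.asarray(hct, dtype=float)
    oef_arr = np.asarray(oef, dtype=float)
    if np.any(hct_arr <= 0) or np.any(hct_arr >= 1):
        raise ValueError("hct must lie in (0, 1)")
    if np.any(oef_arr < 0) or np.any(oef_arr > 1):
        raise ValueError("oef must lie in [0, 1]")
    out = _r2b_raw(hct_arr, oef_arr)
    return float(out) if np.ndim(out) == 0 else out


def _r2b_raw(hct, oef):
    # Unvalidated form; the fitter may probe transiently unphysical OEF.
    return 16.4 * hct + 4.5 + (165.2 * hct + 55.7) * oef**2


def _tissue_core(s0, dbv, dw, r2t, te, tau):
    """Asymptotic tissue signal, broadcast over voxel arrays and tau.

    Short-offset branch exp(-(3/10)*DBV*(dw*tau)^2) for tau < Tc, long-offset
    branch exp(DBV - DBV*dw*tau) for tau >= Tc, with Tc = 1.76/dw selected
    per voxel.  dw == 0 voxels stay on the (flat) short branch.
    """
    s0, dbv, dw, tau = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (s0, dbv, dw, tau))
    )
    base = s0 * np.exp(-r2t * te)
    short = np.exp(-0.3 * dbv * (dw * tau) ** 2)
    with np.errstate(over="ignore"):
        longb = np.exp(dbv - dbv * dw * tau)
    with np.errstate(divide="ignore", over="ignore"):
        tc_boundary = np.where(dw > 0, REGIME_BOUNDARY_FACTOR / np.where(dw > 0, dw, 1.0), np.inf)
    return base * np.where(tau < tc_boundary, short, longb)


def _blood_core(dw, r2b_val, te, tau):
    """Complex blood-compartment signal, broadcast over arrays.

    ``exp(-R2b*TE + i*dw*tau/2) * (C(eta) - i*S(eta)) / eta`` with
    ``eta = sqrt(3*dw*tau/pi)`` and C, S the normalized Fresnel integrals.
    The tau -> 0 limit of the Fresnel factor is 1 (no division by zero).
    """
    dw, r2b_val, tau = np.broadcast_arrays(
        *(np.asarray(a, dtype=float) for a in (dw, r2b_val, tau))
    )
    x = dw * tau
    eta = np.sqrt(3.0 * x / np.pi)
    s_f, c_f = fresnel(eta)  # scipy returns (S, C)
    safe_eta = np.where(eta > 0, eta, 1.0)
    factor = np.where(eta > 0, (c_f - 1j * s_f) / safe_eta, 1.0 + 0.0j)
    return np.exp(-r2b_val * te + 0.5j * x) * factor


def tissue_signal(state: VoxelState, const: TissueConstants, proto: AseProtocol, tau):
    """Extravascular tissue signal at displacement time(s) ``tau`` (seconds)."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    dw = delta_omega(state.oef, const, proto.b0)
    out = _tissue_core(state.s0, state.dbv, dw, const.r2t, proto.te, tau_arr)
    return float(out) if tau_arr.ndim == 0 else out


def blood_signal(state: VoxelState, const: TissueConstants, proto: AseProtocol, tau):
    """Complex intravascular blood signal; downstream code uses its magnitude."""
    tau_arr = np.asarray(tau, dtype=float)
    if np.any(tau_arr < 0):
        raise ValueError("tau must be >= 0")
    dw = delta_omega(state.oef, const, proto.b0)
    r2b_val = r2b(const.hct, state.oef)
    out = _blood_core(dw, r2b_val, proto.te, tau_arr)
    return complex(out) if tau_arr.ndim == 0 else out


def total_signal(state: VoxelState, const: TissueConstants, proto: AseProtocol, tau):
    """Magnitude-valued two-compartment voxel signal.

    ``S0 * DBV * |Sb(tau)| + (1 - DBV) * St(tau)`` with ``St`` carrying S0
    internally; reduces to :func:`tissue_signal` at DBV = 0 and to
    ``S0 * |Sb|`` at DBV = 1.
    """
    st = tissue_signal(state, const, proto, tau)
    sb = blood_signal(state, const, proto, tau)
    out = state.s0 * state.dbv * np.abs(sb) + (1.0 - state.dbv) * st
    return float(out) if np.ndim(out) == 0 else out


def ase_signal_stack(s0, oef, dbv, const: TissueConstants, proto: AseProtocol) -> np.ndarray:
    """Vectorized total ASE signal over voxel arrays, stacked along a new last axis.

    Parameters are broadcastable arrays of per-voxel S0 / OEF / DBV fractions;
    the returned array has shape ``(*voxels, len(proto.taus))``.
    """
    s0 = np.asarray(s0, dtype=float)
    oef = np.asarray(oef, dtype=float)
    dbv = np.asarray(dbv, dtype=float)
    dw = delta_omega(oef, const, proto.b0)
    r2b_val = r2b(const.hct, oef)
    out = np.empty(np.broadcast_shapes(s0.shape, oef.shape, dbv.shape) + (len(proto.taus),))
    for k, tau in enumerate(proto.taus):
        st = _tissue_core(s0, dbv, dw, const.r2t, proto.te, tau)
        sb = np.abs(_blood_core(dw, r2b_val, proto.te, tau))
        out[..., k] = s0 * dbv * sb + (1.0 - dbv) * st
    return out


@lru_cache(maxsize=8)
def _unit_interval_leggauss(n: int):
    # node generation is O(n^2); cache it so repeated oracle calls are cheap
    x, w = np.polynomial.legendre.leggauss(n)
    return 0.5 * (x + 1.0), 0.5 * w


def powder_average_oracle(delta_omega_val: float, tau: float, n_points: int = 2000) -> complex:
    """Numerical orientation average used as an independent reference for Eq-form checks.

    Evaluates ``int_0^1 exp(-i * dw * tau * (3x^2 - 1)/2) dx`` by Gauss-Legendre
    quadrature with ``n_points`` nodes, verifying convergence by doubling the
    node count (relative change must be <= 1e-8).
    """
    if n_points < 1000:
        raise ValueError("n_points must be >= 1000")
    a = float(delta_omega_val) * float(tau)

    def quad(n: int) -> complex:
        u, w = _unit_interval_leggauss(n)
        return complex(np.sum(w * np.exp(-1j * a * (3.0 * u**2 - 1.0) / 2.0)))

    v1 = quad(n_points)
    v2 = quad(2 * n_points)
    if abs(v2 - v1) > 1e-8 * max(abs(v2), 1e-300):
        raise ArithmeticError("powder-average quadrature did not converge")
    return v2
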