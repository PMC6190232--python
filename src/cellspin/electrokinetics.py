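"""Electrokinetic driving of cell self-rotation: DEP force, CM factor, torque.

A dielectric particle in a non-uniform AC field experiences a time-averaged
dielectrophoretic (DEP) force

    <F_DEP> = 2 pi R^3 eps_m Re[K(w)] grad|E_rms|^2

whose sign follows the real part of the Clausius-Mossotti (CM) factor
``K(w)``.  For a single-shell cell (cytoplasm + membrane of capacitance
``C_mem`` suspended in a medium) Re[K] is the rational function of the
relaxation times

    tau_c = eps_c / sigma_c     tau_1  = eps_m / sigma_m
    tau_2 = C_mem R / sigma_c   tau_2' = C_mem R / sigma_m

evaluated here with genuine complex arithmetic.

Cells whose effective permittivity/conductivity contrast with the medium is
non-zero can also self-rotate in a *linearly polarized* (non-rotating) AC
field; the driving torque about an axis perpendicular to the field lines is

    T = (9/4) V eps_1 E0^2 (eps_r - sigma_r) / ((eps_r + 2)(sigma_r + 2))
        * [ (X + X0)/((X + X0)^2 + 1) + (X - X0)/((X - X0)^2 + 1) ]

with X = w*tau, X0 = w0*tau (w0 the angular frequency of the cellular
motion), tau = (eps_p + 2 eps_m)/(sigma_p + 2 sigma_m) and V the cell
volume.  This module exposes the physics as standalone utilities; it is
deliberately not coupled to the image pipeline (predicting a steady-state
rotation rate would additionally require a rotational drag model).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VACUUM_PERMITTIVITY",
    "CellMediumParams",
    "cm_real",
    "dep_force_magnitude",
    "rotation_torque",
]

#: Vacuum permittivity epsilon_0 in F/m.
VACUUM_PERMITTIVITY = 8.8541878128e-12


@dataclass(frozen=True)
class CellMediumParams:
    """Dielectric description of a shelled cell in a suspending medium.

    Parameters
    ----------
    cell_radius : float
        Cell radius R in meters.
    eps_c, sigma_c : float
        Cytoplasm permittivity (F/m) and conductivity (S/m).
    eps_m, sigma_m : float
        Medium permittivity (F/m) and conductivity (S/m).
    c_mem : float
        Membrane capacitance per unit area (F/m^2).
    eps_p, sigma_p : float, optional
        Effective whole-particle permittivity/conductivity used by the
        self-rotation torque model (``eps_r = eps_p/eps_m`` etc.).
    e0 : float, optional
        Applied field amplitude E0 in V/m (torque model).
    """

    cell_radius: float
    eps_c: float
    sigma_c: float
    eps_m: float
    sigma_m: float
    c_mem: float
    eps_p: float | None = None
    sigma_p: float | None = None
    e0: float | None = None

    def __post_init__(self) -> None:
        for name in ("cell_radius", "eps_c", "sigma_c", "eps_m", "sigma_m", "c_mem"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        for name in ("eps_p", "sigma_p", "e0"):
            val = getattr(self, name)
            if val is not None and not val > 0:
                raise ValueError(f"{name} must be positive when given")

    # single-shell relaxation times
    @property
    def tau_c(self) -> float:
        return self.eps_c / self.sigma_c

    @property
    def tau_1(self) -> float:
        return self.eps_m / self.sigma_m

    @property
    def tau_2(self) -> float:
        return self.c_mem * self.cell_radius / self.sigma_c

    @property
    def tau_2p(self) -> float:
        return self.c_mem * self.cell_radius / self.sigma_m

    # torque-model ratios
    def _require_particle(self) -> tuple[float, float]:
        if self.eps_p is None or self.sigma_p is None:
            raise ValueError("eps_p and sigma_p are required for the torque model")
        return self.eps_p, self.sigma_p

    @property
    def eps_r(self) -> float:
        eps_p, _ = self._require_particle()
        return eps_p / self.eps_m

    @property
    def sigma_r(self) -> float:
        _, sigma_p = self._require_particle()
        return sigma_p / self.sigma_m

    @property
    def tau(self) -> float:
        """Maxwell-Wagner relaxation time (eps_p + 2 eps_m)/(sigma_p + 2 sigma_m)."""
        eps_p, sigma_p = self._require_particle()
        return (eps_p + 2.0 * self.eps_m) / (sigma_p + 2.0 * self.sigma_m)

    @property
    def volume(self) -> float:
        """Cell volume 4/3 pi R^3 in m^3."""
        return 4.0 / 3.0 * math.pi * self.cell_radius**3


def cm_real(params: CellMediumParams, omega) -> float | np.ndarray:
    """Real part of the single-shell Clausius-Mossotti factor at ``omega``.

    Accepts a scalar or array of angular frequencies (rad/s, >= 0).  The DC
    limit is exactly 0.5 for any physical parameters.
    """
    w = np.asarray(omega, dtype=float)
    if np.any(w < 0):
        raise ValueError("omega must be >= 0")
    tc, t1, t2, t2p = params.tau_c, params.tau_1, params.tau_2, params.tau_2p
    num = -(w**2) * (t1 * t2 - tc * t2p) + 1j * w * (t2p - t1 - t2) - 1.0
    den = w**2 * (tc * t2p + 2.0 * t1 * t2) - 1j * w * (t2p + 2.0 * t1 + t2) - 2.0
    out = (num / den).real
    return float(out) if np.isscalar(omega) else out


def dep_force_magnitude(
    cell_radius: float, eps_m: float, re_k: float, grad_e2: float
) -> float:
    """Time-averaged DEP force 2 pi R^3 eps_m Re[K] grad|E_rms|^2 (N).

    Signed: a negative value means repulsion from the high-field region.
    """
    if not cell_radius > 0:
        raise ValueError("cell_radius must be positive")
    return 2.0 * math.pi * cell_radius**3 * eps_m * re_k * grad_e2


def rotation_torque(params: CellMediumParams, x, x0) -> float | np.ndarray:
    """Self-rotation torque T(X, X0) in a linearly polarized field (N m).

    ``x = omega * tau`` is the dimensionless field frequency and
    ``x0 = omega_0 * tau`` the dimensionless frequency of the cellular
    motion.  Odd in ``x`` when ``x0 = 0``, and identically zero when the
    permittivity and conductivity ratios coincide (``eps_r == sigma_r``).
    Uses ``eps_1 = eps_m`` as the field-energy permittivity.
    """
    if params.e0 is None:
        raise ValueError("field amplitude e0 is required for the torque model")
    xa = np.asarray(x, dtype=float)
    x0a = np.asarray(x0, dtype=float)
    eps_r, sigma_r = params.eps_r, params.sigma_r
    prefactor = (
        2.25
        * params.volume
        * params.eps_m
        * params.e0**2
        * (eps_r - sigma_r)
        / ((eps_r + 2.0) * (sigma_r + 2.0))
    )
    bracket = (xa + x0a) / ((xa + x0a) ** 2 + 1.0) + (xa - x0a) / ((xa - x0a) ** 2 + 1.0)
    out = prefactor * bracket
    return float(out) if np.isscalar(x) and np.isscalar(x0) else out
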