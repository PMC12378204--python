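"""Thermodynamic core of the chromatin phase-field model.

The nucleus is described by three volume fractions -- heterochromatin
``phi_h``, euchromatin ``phi_e`` and nucleoplasm ``phi_n`` -- that sum to
one.  The independent state variables are ``phi_n`` and the order parameter
``phi_d = phi_h - phi_e`` (positive in heterochromatic regions, negative in
euchromatic ones).  The free energy density has three contributions:

* a double-well bulk term ``(c/2) [phi_e**2 + phi_h**2 (phi_h0 - phi_h)**2]``
  whose minima sit at the euchromatic state ``(phi_h, phi_e) = (0, 0)`` and
  the heterochromatic state ``(phi_h0, 0)``,
* an interfacial penalty ``(kappa/2) (|grad phi_n|**2 + |grad phi_d|**2)``,
* a chromatin-lamina attraction ``-(V(phi_h)/d0) exp(-d/d0)`` that decays
  away from the nuclear envelope over a molecular length ``d0``.

Units are nm, s and pN throughout: energy densities are pN/nm^2 (energy per
unit area of the 2D section), affinities V are pN*nm per nm^2 of lamina.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "ModelParams",
    "CompositionField",
    "PotentialField",
    "composition_from_state",
    "state_from_composition",
    "bulk_free_energy_density",
    "lamina_energy_density",
    "total_free_energy",
    "chemical_potentials",
    "reaction_rate",
    "composite_rate",
]

#: tolerance for composition range checks
EPS_PHI = 1e-6


class CompositionDomainError(ValueError):
    """Raised when (phi_n, phi_d) leaves the physical simplex."""


class GeometryError(ValueError):
    """Raised for invalid geometric inputs (e.g. negative lamina distance)."""


def composite_rate(gamma_a: float, gamma_b: float) -> float:
    """Harmonic composition of two sequential first-order reaction steps.

    The overall methylation rate composes deacetylation (HDAC) and
    methyltransferase (HMT) steps as ``1/G = 1/G_a + 1/G_b``; the analogous
    composition holds for acetylation (HDM then HAT).  The composite rate is
    bounded by the slower step.  ``inf`` is accepted for an instantaneous
    step.
    """
    if gamma_a < 0 or gamma_b < 0:
        raise ValueError("rates must be nonnegative")
    if gamma_a == 0 and gamma_b == 0:
        raise ValueError("undefined composite rate: both step rates are zero")
    if np.isinf(gamma_a):
        return float(gamma_b)
    if np.isinf(gamma_b):
        return float(gamma_a)
    return float(gamma_a * gamma_b / (gamma_a + gamma_b))


def _linear_affinity(phi_h, v_ec: float, v_hc: float, phi_h0: float):
    """Default chromatin-lamina affinity interpolation V(phi_h).

    Linear between V(0)=V_EC and V(phi_h0)=V_HC, clipped outside [0, phi_h0].
    The physical results depend only weakly on the interpolation shape, so a
    pluggable linear ramp is used.
    """
    s = np.clip(np.asarray(phi_h, dtype=float) / phi_h0, 0.0, 1.0)
    return v_ec + (v_hc - v_ec) * s


def _linear_affinity_prime(phi_h, v_ec: float, v_hc: float, phi_h0: float):
    """d V / d phi_h for the linear ramp (zero outside [0, phi_h0])."""
    p = np.asarray(phi_h, dtype=float)
    inside = (p >= 0.0) & (p <= phi_h0)
    return np.where(inside, (v_hc - v_ec) / phi_h0, 0.0)


@dataclass(frozen=True)
class ModelParams:
    """Physical parameters of the chromatin phase-field model.

    Attributes
    ----------
    c : float
        Chromatin-chromatin interaction strength per unit volume (pN/nm^2).
    kappa : float
        Interfacial energy penalty (pN).
    phi_h0 : float
        Heterochromatin-well composition, in (0, 1].
    d0 : float
        Decay length of the chromatin-lamina attraction (nm).
    V_EC, V_HC : float
        Lamina affinity of pure euchromatin / heterochromatin
        (pN*nm per nm^2 of lamina).  ``V_LAD = V_HC - V_EC``.
    M_n, M_d : float
        Mobilities of nucleoplasm and of epigenetic marks
        (nm^2 per (pN/nm^2) per s).
    Gamma_ac : float
        Effective acetylation rate (1/s).
    D_h : float
        Effective heterochromatin diffusivity used by the interior-domain
        size relation (nm^2/s).
    Gamma_HDAC, Gamma_HMT, Gamma_HDM, Gamma_HAT : float, optional
        Component rates; when given, the composite methylation /
        acetylation rates follow the harmonic composition.
    """

    c: float = 8e-3
    kappa: float = 0.8
    phi_h0: float = 0.8
    d0: float = 2.5
    V_EC: float = 0.0
    V_HC: float = 0.0
    M_n: float = 1.0
    M_d: float = 1.0
    Gamma_ac: float = 1e-3
    D_h: float = 8.33
    Gamma_HDAC: float | None = None
    Gamma_HMT: float | None = None
    Gamma_HDM: float | None = None
    Gamma_HAT: float | None = None
    affinity: Callable = field(default=_linear_affinity, repr=False)
    affinity_prime: Callable = field(default=_linear_affinity_prime, repr=False)

    def __post_init__(self):
        for name in ("c", "kappa", "d0", "M_n", "M_d", "Gamma_ac", "D_h"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (0 < self.phi_h0 <= 1):
            raise ValueError("phi_h0 must lie in (0, 1]")

    @property
    def V_LAD(self) -> float:
        """Preferential lamina affinity of heterochromatin over euchromatin."""
        return self.V_HC - self.V_EC

    @property
    def l_int(self) -> float:
        """Interface width scale sqrt(kappa/c), in nm."""
        return float(np.sqrt(self.kappa / self.c))

    @property
    def Gamma_me(self) -> float | None:
        """Composite methylation rate from HDAC + HMT steps, if given."""
        if self.Gamma_HDAC is None or self.Gamma_HMT is None:
            return None
        return composite_rate(self.Gamma_HDAC, self.Gamma_HMT)

    @property
    def Gamma_ac_composite(self) -> float | None:
        """Composite acetylation rate from HDM + HAT steps, if given."""
        if self.Gamma_HDM is None or self.Gamma_HAT is None:
            return None
        return composite_rate(self.Gamma_HDM, self.Gamma_HAT)

    def V(self, phi_h):
        """Chromatin-lamina affinity at composition ``phi_h``."""
        return self.affinity(phi_h, self.V_EC, self.V_HC, self.phi_h0)

    def V_prime(self, phi_h):
        return self.affinity_prime(phi_h, self.V_EC, self.V_HC, self.phi_h0)

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "c", "kappa", "phi_h0", "d0", "V_EC", "V_HC",
                "M_n", "M_d", "Gamma_ac", "D_h",
            )
        }
        for k in ("Gamma_HDAC", "Gamma_HMT", "Gamma_HDM", "Gamma_HAT"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def composition_from_state(phi_n, phi_d, eps: float = EPS_PHI):
    """Map the state variables (phi_n, phi_d) to (phi_h, phi_e).

    ``phi_h = (1 - phi_n + phi_d)/2`` and ``phi_e = (1 - phi_n - phi_d)/2``;
    together with ``phi_n`` they sum to one identically.  Inputs outside the
    physical simplex beyond tolerance raise :class:`CompositionDomainError`.
    """
    phi_n = np.asarray(phi_n, dtype=float)
    phi_d = np.asarray(phi_d, dtype=float)
    if np.any(np.abs(phi_d) > 1.0 - phi_n + eps):
        raise CompositionDomainError(
            "|phi_d| exceeds 1 - phi_n beyond tolerance: state off the simplex"
        )
    phi_h = 0.5 * (1.0 - phi_n + phi_d)
    phi_e = 0.5 * (1.0 - phi_n - phi_d)
    return phi_h, phi_e


def state_from_composition(phi_h, phi_e):
    """Inverse of :func:`composition_from_state`."""
    phi_h = np.asarray(phi_h, dtype=float)
    phi_e = np.asarray(phi_e, dtype=float)
    return 1.0 - phi_h - phi_e, phi_h - phi_e


@dataclass
class CompositionField:
    """Gridded (phi_n, phi_d) state of one simulated nucleus.

    Arrays are 2D over the bounding lattice of the nucleus; values are
    meaningful only where ``mask`` is True.  ``h`` is the lattice spacing
    in nm.
    """

    h: float
    phi_n: np.ndarray
    phi_d: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.phi_n.shape != self.phi_d.shape or self.phi_n.shape != self.mask.shape:
            raise ValueError("phi_n, phi_d and mask must share one lattice shape")

    @property
    def phi_h(self) -> np.ndarray:
        return 0.5 * (1.0 - self.phi_n + self.phi_d)

    @property
    def phi_e(self) -> np.ndarray:
        return 0.5 * (1.0 - self.phi_n - self.phi_d)

    def validate(self, eps: float = 1e-6) -> None:
        m = self.mask
        for name, arr in (("phi_h", self.phi_h), ("phi_e", self.phi_e),
                          ("phi_n", self.phi_n)):
            v = arr[m]
            if np.any(v < -eps) or np.any(v > 1 + eps):
                raise CompositionDomainError(f"{name} outside [0,1] beyond tolerance")

    def copy(self) -> "CompositionField":
        return CompositionField(self.h, self.phi_n.copy(), self.phi_d.copy(),
                                self.mask)


@dataclass
class PotentialField:
    """Chemical potentials mu_n, mu_d (pN/nm^2) on the model lattice."""

    h: float
    mu_n: np.ndarray
    mu_d: np.ndarray
    mask: np.ndarray


def bulk_free_energy_density(phi_h, phi_e, params: ModelParams):
    """Double-well bulk free energy density (pN/nm^2).

    ``(c/2) [phi_e**2 + phi_h**2 (phi_h0 - phi_h)**2]``.  Nonnegative, and
    zero exactly at the euchromatic well (0, 0) and the heterochromatic well
    (phi_h0, 0).  Note the euchromatic well is the water-rich state: the
    printed bulk term penalises phi_e**2, so its minimum sits at phi_e = 0.
    """
    phi_h = np.asarray(phi_h, dtype=float)
    phi_e = np.asarray(phi_e, dtype=float)
    return 0.5 * params.c * (
        phi_e ** 2 + phi_h ** 2 * (params.phi_h0 - phi_h) ** 2
    )


def bulk_derivatives(phi_h, phi_e, params: ModelParams):
    """(d f_bulk / d phi_h, d f_bulk / d phi_e)."""
    phi_h = np.asarray(phi_h, dtype=float)
    phi_e = np.asarray(phi_e, dtype=float)
    dfh = params.c * phi_h * (params.phi_h0 - phi_h) * (params.phi_h0 - 2.0 * phi_h)
    dfe = params.c * phi_e
    return dfh, dfe


def lamina_energy_density(phi_h, d, params: ModelParams):
    """Chromatin-lamina interaction energy density, ``-(V(phi_h)/d0) e^{-d/d0}``.

    ``d`` is the distance to the nuclear envelope in nm (must be >= 0); the
    attraction decays over the molecular scale ``d0`` of the anchoring
    proteins.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise GeometryError("distance to lamina must be nonnegative")
    return -(params.V(phi_h) / params.d0) * np.exp(-d / params.d0)


def _shifted(arr_p, mask_p, di: int, dj: int):
    """Neighbor values on the padded lattice, mirrored where absent."""
    ny, nx = arr_p.shape
    nb = arr_p[1 + di: ny - 1 + di, 1 + dj: nx - 1 + dj]
    ok = mask_p[1 + di: ny - 1 + di, 1 + dj: nx - 1 + dj]
    ctr = arr_p[1:-1, 1:-1]
    return np.where(ok, nb, ctr)


def _masked_gradient_sq(arr: np.ndarray, mask: np.ndarray, h: float) -> np.ndarray:
    """|grad arr|^2 as a sum over forward links, no-flux at the mask boundary.

    Each lattice link contributes ``((f_b - f_a)/h)**2`` once, attributed to
    its lower cell; links leaving the mask are absent (mirror condition).
    This link-based discretization is exactly the one whose variational
    derivative is the masked 5-point Laplacian, so the discrete energy and
    the discrete chemical potentials form a consistent pair.
    """
    arr_p = np.pad(arr, 1)
    mask_p = np.pad(mask, 1, constant_values=False)
    out = np.zeros_like(arr)
    for di, dj in ((1, 0), (0, 1)):
        fwd = _shifted(arr_p, mask_p, di, dj)
        out += ((fwd - arr) / h) ** 2
    out[~mask] = 0.0
    return out


def masked_laplacian(arr: np.ndarray, mask: np.ndarray, h: float) -> np.ndarray:
    """5-point Laplacian with mirror conditions at the mask boundary."""
    arr_p = np.pad(arr, 1)
    mask_p = np.pad(mask, 1, constant_values=False)
    ctr = arr_p[1:-1, 1:-1]
    out = np.zeros_like(arr)
    for di, dj in ((1, 0), (0, 1)):
        out += _shifted(arr_p, mask_p, di, dj) + \
            _shifted(arr_p, mask_p, -di, -dj) - 2.0 * ctr
    out[~mask] = 0.0
    return out / h ** 2


def total_free_energy(fieldc: CompositionField, geom, params: ModelParams) -> float:
    """Discrete free energy integral over the nucleus mask (pN*nm per unit depth).

    Sum of bulk, interfacial ``(kappa/2)(|grad phi_n|^2 + |grad phi_d|^2)``
    and lamina contributions, times the cell area ``h**2``.
    """
    if fieldc.mask.shape != geom.mask.shape or fieldc.h != geom.h:
        raise ValueError("field and geometry lattices do not match")
    m = fieldc.mask
    h = fieldc.h
    phi_h, phi_e = fieldc.phi_h, fieldc.phi_e
    f = bulk_free_energy_density(phi_h, phi_e, params)
    f = f + 0.5 * params.kappa * (
        _masked_gradient_sq(fieldc.phi_n, m, h)
        + _masked_gradient_sq(fieldc.phi_d, m, h)
    )
    f = f + lamina_energy_density(phi_h, geom.distance, params)
    return float(np.sum(f[m]) * h * h)


def chemical_potentials(fieldc: CompositionField, geom,
                        params: ModelParams) -> PotentialField:
    """Variational derivatives mu_n = df/dphi_n, mu_d = df/dphi_d.

    The bulk and lamina terms enter through the chain rule
    (d phi_h/d phi_n = -1/2, d phi_h/d phi_d = +1/2, d phi_e/d phi_n = -1/2,
    d phi_e/d phi_d = -1/2); the interfacial term contributes
    ``-kappa * laplacian(phi)`` for each state variable.
    """
    m = fieldc.mask
    h = fieldc.h
    phi_h, phi_e = fieldc.phi_h, fieldc.phi_e
    dfh, dfe = bulk_derivatives(phi_h, phi_e, params)
    lam = -(params.V_prime(phi_h) / params.d0) * np.exp(-geom.distance / params.d0)
    mu_n = -0.5 * (dfh + dfe) - 0.5 * lam - params.kappa * masked_laplacian(
        fieldc.phi_n, m, h)
    mu_d = 0.5 * (dfh - dfe) + 0.5 * lam - params.kappa * masked_laplacian(
        fieldc.phi_d, m, h)
    mu_n[~m] = 0.0
    mu_d[~m] = 0.0
    return PotentialField(h=h, mu_n=mu_n, mu_d=mu_d, mask=m)


def reaction_rate(phi_h, phi_e, Gamma_me, Gamma_ac):
    """Epigenetic interconversion contribution to d(phi_d)/dt (1/s).

    ``2 (Gamma_me * phi_e - Gamma_ac * phi_h)``: methylation converts
    euchromatin to heterochromatin, acetylation the reverse; the factor 2
    arises because converting a unit of one phase into the other changes
    phi_d = phi_h - phi_e by two units.  Zero iff
    ``phi_h / phi_e = Gamma_me / Gamma_ac``.
    """
    Gamma_me = np.asarray(Gamma_me, dtype=float)
    Gamma_ac = np.asarray(Gamma_ac, dtype=float)
    if np.any(Gamma_me < 0) or np.any(Gamma_ac < 0):
        raise ValueError("reaction rates must be nonnegative")
    return 2.0 * (Gamma_me * np.asarray(phi_e, float)
                  - Gamma_ac * np.asarray(phi_h, float))
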