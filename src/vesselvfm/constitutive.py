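"""Four-fiber-family + thrombus hyperelastic model.

The aortic wall is modelled as an elastin-dominated neoHookean matrix plus
three Fung-type exponential fiber contributions (circumferential, axial and
two symmetric diagonal families at +/-beta); intramural thrombus is a
separate neoHookean solid.  Constituents are deposited under prestretch
(constrained-mixture deposition stretch tensors G_i), so the traction-free
reference state generally carries residual stress.

The material is treated as incompressible: all energies are evaluated on the
isochoric part ``F_bar = F / J^(1/3)`` and the stress is split into a
deviatoric, constitutively determined part plus an undetermined reaction
pressure.  The reaction pressure never enters the virtual-fields
identification because all virtual strain fields used are trace-free.

Sign convention for the tension/compression split: ``<x>+ = max(x, 0)`` and
``<x>- = max(-x, 0)``; the compressive branch is weighted by ``alpha`` and
enters the stress with the sign required by the energy derivative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import THROMBUS, WALL, LocalBasisField, SectorPartition

__all__ = [
    "SectorParameters",
    "MaterialField",
    "StressState",
    "DEFAULT_BOUNDS",
    "NONLINEAR_NAMES",
    "LINEAR_NAMES",
    "fiber_directions",
    "deposition_tensors",
    "fung_fiber_energy",
    "strain_energy",
    "cauchy_stress",
    "linearized_circumferential_stiffness",
    "metric_maps",
]

LINEAR_NAMES = ("c1", "c2", "c3", "c4", "c5")
NONLINEAR_NAMES = ("k1", "k2", "k3", "G1", "G2", "G3", "G4", "beta", "alpha")

#: Default identification bounds for the nonlinear parameter set.  Spans
#: cover published murine aorta four-fiber fits; override via RunConfig.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "c1": (0.0, 500.0),
    "c2": (0.0, 500.0),
    "c3": (0.0, 500.0),
    "c4": (0.0, 500.0),
    "c5": (0.0, 500.0),
    "k1": (0.01, 10.0),
    "k2": (0.01, 10.0),
    "k3": (0.01, 10.0),
    "G1": (1.0, 1.3),
    "G2": (1.0, 1.3),
    "G3": (1.0, 1.3),
    "G4": (1.0, 2.5),
    "beta": (np.deg2rad(15.0), np.deg2rad(75.0)),
    "alpha": (0.0, 1.0),
}


@dataclass
class SectorParameters:
    """Material parameters of one sector.

    Moduli c1..c5 in kPa (c5 only meaningful where thrombus is present),
    exponential shape factors k1..k3, deposition stretches G1..G4, diagonal
    fiber angle beta (rad) and compression weighting alpha in [0, 1].
    """

    c1: float = 0.0
    c2: float = 0.0
    c3: float = 0.0
    c4: float = 0.0
    c5: float = 0.0
    k1: float = 0.1
    k2: float = 0.1
    k3: float = 0.1
    G1: float = 1.0
    G2: float = 1.0
    G3: float = 1.0
    G4: float = 1.0
    beta: float = np.pi / 4
    alpha: float = 0.0

    def validate(self) -> None:
        if min(self.c1, self.c2, self.c3, self.c4, self.c5) < 0:
            raise ValueError("moduli c1..c5 must be nonnegative")
        if min(self.k1, self.k2, self.k3) <= 0:
            raise ValueError("shape factors k1..k3 must be positive")
        if min(self.G1, self.G2, self.G3, self.G4) <= 0:
            raise ValueError("deposition stretches must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if not 0.0 < self.beta < np.pi / 2:
            raise ValueError("beta must lie in (0, pi/2)")

    def linear(self) -> np.ndarray:
        return np.array([self.c1, self.c2, self.c3, self.c4, self.c5])

    def nonlinear(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in NONLINEAR_NAMES])


@dataclass
class MaterialField:
    """Sector-wise parameter sets plus the global axial deposition stretch."""

    partition: SectorPartition
    sectors: list[SectorParameters]
    G_a: float = 1.0
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )

    def __post_init__(self) -> None:
        if len(self.sectors) != self.partition.n_sectors:
            raise ValueError("one SectorParameters per sector required")

    @classmethod
    def homogeneous(
        cls, partition: SectorPartition, params: SectorParameters, G_a: float = 1.0
    ) -> "MaterialField":
        return cls(partition, [replace(params) for _ in range(partition.n_sectors)], G_a)

    def params_of_tets(self, name: str) -> np.ndarray:
        """Per-tet values of one named parameter."""
        per_sector = np.array([getattr(s, name) for s in self.sectors])
        return per_sector[self.partition.flat_index()]


@dataclass
class StressState:
    """Deviatoric Cauchy stress (kPa), energy density and local extracts."""

    sigma_dev: np.ndarray  # (..., 3, 3)
    W: np.ndarray          # (...,)
    e_c: np.ndarray
    e_a: np.ndarray
    e_o: np.ndarray

    @property
    def sigma_cc(self) -> np.ndarray:
        """Circumferential deviatoric Cauchy stress component."""
        return np.einsum("...i,...ij,...j->...", self.e_c, self.sigma_dev, self.e_c)

    @property
    def sigma_aa(self) -> np.ndarray:
        return np.einsum("...i,...ij,...j->...", self.e_a, self.sigma_dev, self.e_a)

    @property
    def sigma_oo(self) -> np.ndarray:
        return np.einsum("...i,...ij,...j->...", self.e_o, self.sigma_dev, self.e_o)


# -- building blocks -----------------------------------------------------

def fiber_directions(beta, e_c: np.ndarray, e_a: np.ndarray) -> dict[str, np.ndarray]:
    """Unit directions of the four fiber families in the local triad."""
    beta = np.asarray(beta)[..., None]
    return {
        "a1": e_c,
        "a2": e_a,
        "a3p": np.cos(beta) * e_c + np.sin(beta) * e_a,
        "a3m": np.cos(beta) * e_c - np.sin(beta) * e_a,
    }


def _outer(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., :, None] * b[..., None, :]


def deposition_tensors(
    params: SectorParameters,
    G_a: float,
    e_c: np.ndarray,
    e_a: np.ndarray,
    e_o: np.ndarray,
    unimodular: bool = False,
) -> dict[str, np.ndarray]:
    """Deposition stretch tensors G_1, G_2, G_3+/-, G_4.

    As printed, fiber tensors use a 1/G transverse factor (determinant 1/G);
    ``unimodular=True`` switches to 1/sqrt(G) so det = 1.  G_4 is always
    unimodular by construction.
    """
    eye = np.broadcast_to(np.eye(3), e_c.shape + (3,))
    dirs = fiber_directions(params.beta, e_c, e_a)
    out = {}
    for key, G, a in (
        ("G1", params.G1, dirs["a1"]),
        ("G2", params.G2, dirs["a2"]),
        ("G3p", params.G3, dirs["a3p"]),
        ("G3m", params.G3, dirs["a3m"]),
    ):
        trans = 1.0 / np.sqrt(G) if unimodular else 1.0 / G
        A = _outer(a, a)
        out[key] = G * A + trans * (eye - A)
    out["G4"] = (
        params.G4 * _outer(e_c, e_c)
        + G_a * _outer(e_a, e_a)
        + (1.0 / (params.G4 * G_a)) * _outer(e_o, e_o)
    )
    return out


def _split(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Tension/compression split <x>+, <x>-."""
    return np.maximum(x, 0.0), np.maximum(-x, 0.0)


_EXP_CAP = 50.0


def _checked_exp(x: np.ndarray) -> np.ndarray:
    if np.any(x > _EXP_CAP):
        bad = np.flatnonzero(np.atleast_1d(x) > _EXP_CAP)
        raise FloatingPointError(
            f"fiber invariant excursion overflows the exponential (entries {bad[:5].tolist()})"
        )
    return np.exp(x)


def fung_fiber_energy(invariant: np.ndarray, c, k, alpha) -> np.ndarray:
    """Fung-type exponential fiber energy for one family/direction.

    ``invariant`` is the squared prestretched fiber stretch
    ``(F_bar G a).(F_bar G a)``; energy is zero at invariant 1.
    """
    ip, im = _split(np.asarray(invariant) - 1.0)
    wt = _checked_exp(k * ip**2) - 1.0
    wc = _checked_exp(k * im**2) - 1.0
    return c / (4.0 * k) * (wt + alpha * wc)


def _psi(invariant: np.ndarray, k, alpha) -> np.ndarray:
    """Stress coefficient: derivative of the Fung energy wrt the invariant
    (times 2/c), tension minus weighted compression branch."""
    ip, im = _split(np.asarray(invariant) - 1.0)
    return ip * _checked_exp(k * ip**2) - alpha * im * _checked_exp(k * im**2)


def _isochoric(F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("non-positive Jacobian in deformation gradient")
    return F / np.cbrt(J)[..., None, None], J


def _fiber_invariant(Fbar: np.ndarray, G: float, a: np.ndarray) -> np.ndarray:
    """I = |F_bar G_i a|^2 = G^2 |F_bar a|^2 for a fiber tensor G_i."""
    m = np.einsum("...ij,...j->...i", Fbar, a)
    return G**2 * np.einsum("...i,...i->...", m, m)


def strain_energy(
    F: np.ndarray,
    params: SectorParameters,
    region,
    e_c: np.ndarray,
    e_a: np.ndarray,
    e_o: np.ndarray,
    G_a: float = 1.0,
    unimodular: bool = False,
) -> np.ndarray:
    """Strain energy density W (kPa), region-gated.

    Wall points sum the four fiber-family/matrix terms; thrombus points use
    the neoHookean thrombus term.  The volumetric part U(J) is omitted under
    the incompressible-evaluation convention (J is expected near 1).
    """
    Fbar, _ = _isochoric(np.asarray(F, dtype=float))
    region = np.asarray(region)
    dirs = fiber_directions(params.beta, e_c, e_a)
    if unimodular:
        # transverse deposition factor alters |F_bar G a| only through the
        # fiber-direction component, which is unchanged -> same invariant
        pass
    W = np.zeros(Fbar.shape[:-2])
    wall = region == WALL
    if np.any(wall):
        w = np.zeros_like(W)
        for G, a, c, k in (
            (params.G1, dirs["a1"], params.c1, params.k1),
            (params.G2, dirs["a2"], params.c2, params.k2),
            (params.G3, dirs["a3p"], params.c3, params.k3),
            (params.G3, dirs["a3m"], params.c3, params.k3),
        ):
            inv = _fiber_invariant(Fbar, G, a)
            w = w + fung_fiber_energy(inv, c, k, params.alpha)
        G4 = deposition_tensors(params, G_a, e_c, e_a, e_o, unimodular)["G4"]
        FG4 = Fbar @ G4
        w = w + params.c4 / 2.0 * (np.einsum("...ij,...ij->...", FG4, FG4) - 3.0)
        W = np.where(wall, w, W)
    imt = region == THROMBUS
    if np.any(imt):
        w5 = params.c5 / 2.0 * (np.einsum("...ij,...ij->...", Fbar, Fbar) - 3.0)
        W = np.where(imt, w5, W)
    return W


def cauchy_stress(
    F: np.ndarray,
    params: SectorParameters,
    region,
    e_c: np.ndarray,
    e_a: np.ndarray,
    e_o: np.ndarray,
    G_a: float = 1.0,
    unimodular: bool = False,
) -> StressState:
    """Deviatoric Cauchy stress (kPa) and energy density.

    The spherical reaction (-dU/dJ I) is indeterminate for an incompressible
    material and is resolved only where a boundary condition supplies it; it
    is dropped here because every virtual strain used in identification is
    trace-free.
    """
    F = np.asarray(F, dtype=float)
    Fbar, J = _isochoric(F)
    region = np.asarray(region)
    dirs = fiber_directions(params.beta, e_c, e_a)
    sig = np.zeros(Fbar.shape[:-2] + (3, 3))
    wall = region == WALL
    if np.any(wall):
        s = np.zeros_like(sig)
        for G, a, c, k in (
            (params.G1, dirs["a1"], params.c1, params.k1),
            (params.G2, dirs["a2"], params.c2, params.k2),
            (params.G3, dirs["a3p"], params.c3, params.k3),
            (params.G3, dirs["a3m"], params.c3, params.k3),
        ):
            m = G * np.einsum("...ij,...j->...i", Fbar, a)
            inv = np.einsum("...i,...i->...", m, m)
            psi = _psi(inv, k, params.alpha)
            s = s + (c * psi)[..., None, None] * _dev(_outer(m, m))
        G4 = deposition_tensors(params, G_a, e_c, e_a, e_o, unimodular)["G4"]
        FG4 = Fbar @ G4
        s = s + params.c4 * _dev(FG4 @ np.swapaxes(FG4, -1, -2))
        sig = np.where(wall[..., None, None], s, sig)
    imt = region == THROMBUS
    if np.any(imt):
        s5 = params.c5 * _dev(Fbar @ np.swapaxes(Fbar, -1, -2))
        sig = np.where(imt[..., None, None], s5, sig)
    sig = sig / J[..., None, None]
    W = strain_energy(F, params, region, e_c, e_a, e_o, G_a, unimodular)
    return StressState(sigma_dev=sig, W=W, e_c=e_c, e_a=e_a, e_o=e_o)


def _dev(T: np.ndarray) -> np.ndarray:
    tr = np.einsum("...ii->...", T) / 3.0
    return T - tr[..., None, None] * np.broadcast_to(np.eye(3), T.shape)


def linearized_circumferential_stiffness(
    F: np.ndarray,
    params: SectorParameters,
    region,
    e_c: np.ndarray,
    e_a: np.ndarray,
    e_o: np.ndarray,
    G_a: float = 1.0,
    delta: float = 1e-4,
) -> np.ndarray:
    """Incremental circumferential modulus (MPa) about a deformed state.

    Central finite difference of the circumferential Cauchy stress under a
    superposed circumferential stretch ``1 + delta`` with isochoric radial
    compensation ``1/(1 + delta)``:

        C = d(sigma_cc) / d(ln lambda_c)   (converted from kPa to MPa)
    """
    F = np.asarray(F, dtype=float)
    eye = np.broadcast_to(np.eye(3), F.shape)

    def perturbed(sign: float) -> np.ndarray:
        d = sign * delta
        P = eye + d * _outer(e_c, e_c) + (1.0 / (1.0 + d) - 1.0) * _outer(e_o, e_o)
        return P @ F

    sp = cauchy_stress(perturbed(+1), params, region, e_c, e_a, e_o, G_a).sigma_cc
    sm = cauchy_stress(perturbed(-1), params, region, e_c, e_a, e_o, G_a).sigma_cc
    return (sp - sm) / (2.0 * delta) / 1000.0


def metric_maps(
    F_by_state: dict,
    field_: MaterialField,
    region: np.ndarray,
    basis: LocalBasisField,
    stress_state_key,
    energy_state_key,
    pressure_kpa: float = 0.0,
    xi_tet: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-tet maps of the four headline metrics.

    Circumferential stretch, circumferential Cauchy stress (kPa) and
    linearized stiffness (MPa) are evaluated at ``stress_state_key``
    (typically the 140 mmHg state); stored energy (kPa) at
    ``energy_state_key`` (typically the 80 mmHg reference).

    The reaction pressure of the incompressible material is indeterminate
    from the constitutive law alone; the reported circumferential stress
    resolves it from the radial traction boundary conditions,

        sigma_cc ~ dev_cc - dev_oo + sigma_rr,
        sigma_rr ~ -p (1 - xi),

    with ``xi`` the transmural coordinate (0 at the lumen, 1 outside), so
    the luminal face carries -p and the adventitia is traction-free.  Pass
    ``pressure_kpa = 0`` to report the deviatoric difference alone.
    """
    for key in (stress_state_key, energy_state_key):
        if key not in F_by_state:
            raise KeyError(f"deformation state {key!r} missing")
    Fs = np.asarray(F_by_state[stress_state_key], dtype=float)
    Fe = np.asarray(F_by_state[energy_state_key], dtype=float)
    flat = field_.partition.flat_index()
    n = len(flat)
    lam = np.linalg.norm(np.einsum("tij,tj->ti", Fs, basis.e_c), axis=1)
    sig = np.zeros(n)
    stiff = np.zeros(n)
    energy = np.zeros(n)
    for s in range(field_.partition.n_sectors):
        m = flat == s
        if not m.any():
            continue
        p = field_.sectors[s]
        st = cauchy_stress(Fs[m], p, region[m], basis.e_c[m], basis.e_a[m],
                           basis.e_o[m], field_.G_a)
        sig[m] = st.sigma_cc - st.sigma_oo
        stiff[m] = linearized_circumferential_stiffness(
            Fs[m], p, region[m], basis.e_c[m], basis.e_a[m], basis.e_o[m], field_.G_a
        )
        energy[m] = strain_energy(Fe[m], p, region[m], basis.e_c[m], basis.e_a[m],
                                  basis.e_o[m], field_.G_a)
    if pressure_kpa:
        if xi_tet is None:
            raise ValueError("xi_tet required to resolve the radial stress")
        sig = sig - pressure_kpa * (1.0 - np.asarray(xi_tet))
    return {
        "circ_stretch": lam,
        "circ_stress_kpa": sig,
        "circ_stiffness_mpa": stiff,
        "stored_energy_kpa": energy,
    }
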