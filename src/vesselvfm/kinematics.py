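"""Fusion of surface and volumetric displacement grids; deformation gradients.

Outer-surface displacements (pDIC-style: a regular angular x axial grid on
the adventitia, 3 components) constrain the wall motion at the outer radius;
volumetric displacements (DVC-style: a 3D lattice with in-plane components
only) constrain the transmural variation.  The fused transverse displacement
is assumed to vary linearly in R between fitted inner-surface nodal values
and the measured outer values, blended over the surface grid by periodic
bilinear shape functions.  The axial displacement, unavailable from the
volumetric data, follows a Love-Kirchhoff cross-section field
``w = w_av(Z) + R_x(Z) X + R_y(Z) Y`` fitted to the surface data.

Displacement data are stored in micrometres (matching the measurement
scale); the fused model and all gradients work in millimetres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SurfaceRadiusMap, VesselMesh

__all__ = [
    "MMHG_TO_KPA",
    "LoadState",
    "LoadSchedule",
    "SurfaceDisplacementField",
    "VolumeDisplacementField",
    "FusedDisplacementModel",
    "DeformationState",
    "interp_weights_zeta",
    "fit_inner_displacement",
    "fit_axial_beam",
    "build_fused_model",
    "deformation_gradient_field",
    "accumulate_increments",
]

MMHG_TO_KPA = 0.133322
UM_TO_MM = 1e-3


@dataclass
class LoadState:
    """One quasi-static load configuration.

    ``axial_stretch`` is relative to the in vivo axial stretch lambda_iv
    (so the reference state has axial_stretch == 1).
    """

    index: int
    pressure_mmhg: float
    axial_stretch: float
    axial_force_mn: float = 0.0

    @property
    def pressure_kpa(self) -> float:
        return self.pressure_mmhg * MMHG_TO_KPA


@dataclass
class LoadSchedule:
    """Ordered load states with the in vivo reference convention.

    The reference configuration is (80 mmHg, lambda_iv); ``lam_iv`` records
    the in vivo axial stretch itself.  ``p_ref_kpa`` and ``f_ref_mn`` are the
    reference pressure and axial force used to normalize the virtual fields.
    """

    states: list[LoadState]
    lam_iv: float = 1.4
    reference_pressure_mmhg: float = 80.0
    f_ref_mn: float | None = None

    def __post_init__(self) -> None:
        idx = [s.index for s in self.states]
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise ValueError("state indices must be unique and contiguous from 1")
        if any(s.pressure_mmhg <= 0 for s in self.states):
            raise ValueError("pressures must be positive")
        if self.reference_index is None:
            raise ValueError(
                f"reference state ({self.reference_pressure_mmhg} mmHg, "
                "axial_stretch 1) missing from schedule"
            )
        for s in self.states:
            if not 0.9 <= s.axial_stretch <= 1.2:
                warnings.warn(
                    f"state {s.index}: axial stretch {s.axial_stretch} outside "
                    "the [0.9, 1.2] sanity band",
                    stacklevel=2,
                )

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def reference_index(self) -> int | None:
        """Position (0-based) of the reference state in ``states``."""
        for i, s in enumerate(self.states):
            if (
                abs(s.pressure_mmhg - self.reference_pressure_mmhg) < 1e-9
                and abs(s.axial_stretch - 1.0) < 1e-9
            ):
                return i
        return None

    @property
    def p_ref_kpa(self) -> float:
        return self.reference_pressure_mmhg * MMHG_TO_KPA

    @property
    def f_ref(self) -> float:
        if self.f_ref_mn is not None:
            return self.f_ref_mn
        return float(self.states[self.reference_index].axial_force_mn)


@dataclass
class SurfaceDisplacementField:
    """pDIC-style surface grid: (theta, z) lattice on S_out, 3 components (um)."""

    thetas: np.ndarray      # (n_t,) in [-pi, pi), uniform
    zs: np.ndarray          # (n_z,)
    disp_um: np.ndarray     # (n_states, n_t, n_z, 3)

    @property
    def n_nodes(self) -> int:
        return len(self.thetas) * len(self.zs)


@dataclass
class VolumeDisplacementField:
    """DVC-style 3D lattice with in-plane components only and a validity mask."""

    points_mm: np.ndarray   # (Q, 3)
    uv_um: np.ndarray       # (n_states, Q, 2)
    mask: np.ndarray        # (Q,) bool, True = valid

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())


def interp_weights_zeta(theta, z, thetas: np.ndarray, zs: np.ndarray,
                        derivatives: bool = False):
    """Periodic bilinear shape-function weights on the surface grid.

    Returns ``(idx, w)`` (flat indices into an ``(n_t, n_z)`` array and
    weights summing to 1), or ``(idx, w, dw_dtheta, dw_dz)`` when
    ``derivatives`` is requested.  Periodic across the +/-pi seam in theta;
    raises for z outside the grid.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n_t, n_z = len(thetas), len(zs)
    if np.any(z < zs[0] - 1e-9) or np.any(z > zs[-1] + 1e-9):
        raise ValueError("query z outside [Z_down, Z_up]")
    z = np.clip(z, zs[0], zs[-1])
    dt = 2 * np.pi / n_t
    t = np.mod(theta - thetas[0], 2 * np.pi)
    it = np.floor(t / dt).astype(int) % n_t
    ft = t / dt - np.floor(t / dt)
    it1 = (it + 1) % n_t
    iz = np.clip(np.searchsorted(zs, z, side="right") - 1, 0, n_z - 2)
    dz = zs[iz + 1] - zs[iz]
    fz = (z - zs[iz]) / dz
    idx = np.stack(
        [it * n_z + iz, it1 * n_z + iz, it * n_z + iz + 1, it1 * n_z + iz + 1],
        axis=-1,
    )
    w = np.stack([(1 - ft) * (1 - fz), ft * (1 - fz), (1 - ft) * fz, ft * fz], axis=-1)
    if not derivatives:
        return idx, w
    dwt = np.stack(
        [-(1 - fz) / dt, (1 - fz) / dt, -fz / dt, fz / dt], axis=-1
    )
    dwz = np.stack(
        [-(1 - ft) / dz, -ft / dz, (1 - ft) / dz, ft / dz], axis=-1
    )
    return idx, w, dwt, dwz


@dataclass
class FusedDisplacementModel:
    """Continuous transmural displacement model for every load state.

    Internal units are mm.  ``u_out``/``u_in`` hold the transverse nodal
    coefficients at the outer/inner surface per state; ``beam`` holds the
    per-station Love-Kirchhoff coefficients (w_av, R_x, R_y).
    """

    thetas: np.ndarray       # surface grid
    zs: np.ndarray
    r_in_nodes: np.ndarray   # (n_t, n_z) nodal inner radii, mm
    r_out_nodes: np.ndarray  # (n_t, n_z) nodal outer radii, mm
    u_out: np.ndarray        # (S, n_t, n_z, 2) mm
    u_in: np.ndarray         # (S, n_t, n_z, 2) mm
    beam: np.ndarray         # (S, n_z, 3) mm / dimensionless: (w_av, R_x, R_y)
    fit_rms_um: np.ndarray = field(default=None)  # (S,) inner-fit residual RMS

    @property
    def n_states(self) -> int:
        return len(self.u_out)

    # -- evaluation ------------------------------------------------------
    def _cyl(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        R = np.hypot(X[:, 0], X[:, 1])
        Th = np.arctan2(X[:, 1], X[:, 0])
        return X, R, Th, X[:, 2]

    def _radial_blend(self, idx: np.ndarray, R: np.ndarray, clamp: bool = True):
        rin = self.r_in_nodes.reshape(-1)[idx]
        rout = self.r_out_nodes.reshape(-1)[idx]
        h = rout - rin
        if clamp:
            out_by = np.maximum(R[:, None] - rout, rin - R[:, None]).max(axis=1)
            if np.any(out_by > 1e-3):  # 1 um
                warnings.warn(
                    f"{int((out_by > 1e-3).sum())} query points lie outside the "
                    "wall by > 1 um; radially clamped",
                    stacklevel=3,
                )
            Rc = np.clip(R[:, None], rin, rout)
        else:
            Rc = np.broadcast_to(R[:, None], rin.shape)
        a = (Rc - rin) / h
        return a

    def evaluate(self, X: np.ndarray, state: int) -> np.ndarray:
        """Fused displacement (mm) at material points X (mm) for one state."""
        X, R, Th, Z = self._cyl(X)
        idx, w = interp_weights_zeta(Th, Z, self.thetas, self.zs)
        a = self._radial_blend(idx, R)
        uo = self.u_out[state].reshape(-1, 2)[idx]   # (N, 4, 2)
        ui = self.u_in[state].reshape(-1, 2)[idx]
        ut = np.einsum("nk,nkc->nc", w, a[..., None] * uo + (1 - a[..., None]) * ui)
        wav, rx, ry = self._beam_at(Z, state)
        wz = wav + rx * X[:, 0] + ry * X[:, 1]
        return np.column_stack([ut, wz])

    def _beam_at(self, Z: np.ndarray, state: int, derivative: bool = False):
        """Linear interpolation (or its slope) of beam coefficients in Z."""
        zs = self.zs
        iz = np.clip(np.searchsorted(zs, Z, side="right") - 1, 0, len(zs) - 2)
        dz = zs[iz + 1] - zs[iz]
        fz = np.clip((Z - zs[iz]) / dz, 0.0, 1.0)
        c = self.beam[state]
        if derivative:
            sl = (c[iz + 1] - c[iz]) / dz[:, None]
            return sl[:, 0], sl[:, 1], sl[:, 2]
        v = c[iz] * (1 - fz[:, None]) + c[iz + 1] * fz[:, None]
        return v[:, 0], v[:, 1], v[:, 2]

    def gradient(self, X: np.ndarray, state: int) -> np.ndarray:
        """Cartesian displacement gradient (dimensionless) at points X.

        Analytic chain-rule differentiation of the radial-blend / beam
        representation through cylindrical coordinates.
        """
        X, R, Th, Z = self._cyl(X)
        idx, w, dwt, dwz = interp_weights_zeta(Th, Z, self.thetas, self.zs,
                                               derivatives=True)
        rin = self.r_in_nodes.reshape(-1)[idx]
        rout = self.r_out_nodes.reshape(-1)[idx]
        h = rout - rin
        a = (R[:, None] - rin) / h
        uo = self.u_out[state].reshape(-1, 2)[idx]
        ui = self.u_in[state].reshape(-1, 2)[idx]
        blend = a[..., None] * uo + (1 - a[..., None]) * ui   # (N, 4, 2)
        dR = np.einsum("nk,nkc->nc", w, (uo - ui) / h[..., None])
        dT = np.einsum("nk,nkc->nc", dwt, blend)
        dZ = np.einsum("nk,nkc->nc", dwz, blend)
        ct, st = np.cos(Th)[:, None], np.sin(Th)[:, None]
        Rn = R[:, None]
        dX = ct * dR - st / Rn * dT
        dY = st * dR + ct / Rn * dT
        grad = np.zeros((len(X), 3, 3))
        grad[:, 0:2, 0] = dX
        grad[:, 0:2, 1] = dY
        grad[:, 0:2, 2] = dZ
        rx, ry = self._beam_at(Z, state)[1:3]
        dwav, drx, dry = self._beam_at(Z, state, derivative=True)
        grad[:, 2, 0] = rx
        grad[:, 2, 1] = ry
        grad[:, 2, 2] = dwav + drx * X[:, 0] + dry * X[:, 1]
        return grad


@dataclass
class DeformationState:
    """Deformation gradients per tet for one load state.

    ``J_raw`` records the determinant of the reconstructed gradient before
    any incompressibility correction (a reconstruction-quality diagnostic).
    """

    F: np.ndarray       # (T, 3, 3)
    J: np.ndarray       # (T,)
    Fbar: np.ndarray    # (T, 3, 3), det = 1
    lam_theta: np.ndarray  # (T,) circumferential stretch |F e_c|
    J_raw: np.ndarray | None = None


def fit_inner_displacement(
    surface: SurfaceDisplacementField,
    volume: VolumeDisplacementField,
    radii: SurfaceRadiusMap,
    state: int,
    ridge: float = 1e-6,
) -> tuple[np.ndarray, float]:
    """Least-squares inner-surface nodal transverse displacements (mm).

    Solves for the inner coefficients of the radial-blend representation so
    the fused field best matches the valid volumetric (u, v) samples.  The
    solve is expressed in the offset ``u_in - u_out`` with a small ridge, so
    nodes unconstrained by volumetric data (e.g. under imaging shadows)
    default to the outer (pDIC) value, i.e. uniform through-wall motion.
    Returns ``(u_in, rms_um)``.
    """
    n_t, n_z = len(surface.thetas), len(surface.zs)
    valid = volume.mask
    n_nodes = n_t * n_z
    if valid.sum() < 3 * n_nodes:
        raise ValueError(
            f"too few valid volume points ({int(valid.sum())}) to constrain "
            f"{n_nodes} surface nodes (need >= 3 per node on average)"
        )
    P = volume.points_mm[valid]
    Rq = np.hypot(P[:, 0], P[:, 1])
    Tq = np.arctan2(P[:, 1], P[:, 0])
    idx, w = interp_weights_zeta(Tq, P[:, 2], surface.thetas, surface.zs)
    rin = radii.eval_r_in(surface.thetas[:, None] * np.ones(n_z),
                          np.ones((n_t, 1)) * surface.zs).reshape(-1)
    rout = radii.eval_r_out(surface.thetas[:, None] * np.ones(n_z),
                            np.ones((n_t, 1)) * surface.zs).reshape(-1)
    h = rout[idx] - rin[idx]
    a = (Rq[:, None] - rin[idx]) / h
    rows = np.repeat(np.arange(len(P)), 4)
    B = sp.coo_matrix(
        ((w * (1 - a)).ravel(), (rows, idx.ravel())), shape=(len(P), n_nodes)
    ).tocsr()
    BtB = (B.T @ B).tocsc()
    diag = BtB.diagonal()
    weak = diag < 1e-10
    if weak.any():
        warnings.warn(
            f"{int(weak.sum())} surface nodes have no volumetric support; "
            "their inner displacement defaults to the surface value",
            stacklevel=2,
        )
    lam = ridge * max(diag.max(), 1.0)
    A = BtB + lam * sp.identity(n_nodes, format="csc")
    solve = spla.factorized(A)
    u_out = surface.disp_um[state, :, :, :2].reshape(-1, 2) * UM_TO_MM
    d = volume.uv_um[state][valid] * UM_TO_MM
    x = np.empty((n_nodes, 2))
    resid = np.empty_like(d)
    for c in range(2):
        known = np.asarray((sp.coo_matrix((w.ravel(), (rows, idx.ravel())),
                                          shape=(len(P), n_nodes)).tocsr()
                            @ u_out[:, c]))
        r = d[:, c] - known
        x[:, c] = solve(B.T @ r)
        resid[:, c] = B @ x[:, c] - r
    u_in = (u_out + x).reshape(n_t, n_z, 2)
    rms_um = float(np.sqrt(np.mean(resid**2)) / UM_TO_MM)
    return u_in, rms_um


def fit_axial_beam(
    surface: SurfaceDisplacementField, radii: SurfaceRadiusMap, state: int
) -> np.ndarray:
    """Per-station Love-Kirchhoff fit of the axial surface displacement.

    Returns (n_z, 3) coefficients (w_av, R_x, R_y) in mm / dimensionless.
    Stations with fewer than 3 usable, non-collinear nodes inherit the
    nearest fitted neighbour with a warning.
    """
    n_t, n_z = len(surface.thetas), len(surface.zs)
    rout = radii.eval_r_out(
        np.repeat(surface.thetas, n_z), np.tile(surface.zs, n_t)
    ).reshape(n_t, n_z)
    coeffs = np.full((n_z, 3), np.nan)
    for j in range(n_z):
        Xn = rout[:, j] * np.cos(surface.thetas)
        Yn = rout[:, j] * np.sin(surface.thetas)
        wz = surface.disp_um[state, :, j, 2] * UM_TO_MM
        A = np.column_stack([np.ones(n_t), Xn, Yn])
        if n_t < 3 or np.linalg.matrix_rank(A) < 3:
            continue
        coeffs[j], *_ = np.linalg.lstsq(A, wz, rcond=None)
    bad = np.isnan(coeffs[:, 0])
    if bad.all():
        raise ValueError("no axial station has enough usable surface nodes")
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} axial stations lack usable nodes; inheriting "
            "neighbour fits",
            stacklevel=2,
        )
        good = np.flatnonzero(~bad)
        for j in np.flatnonzero(bad):
            coeffs[j] = coeffs[good[np.argmin(np.abs(good - j))]]
    return coeffs


def build_fused_model(
    surface: SurfaceDisplacementField,
    volume: VolumeDisplacementField,
    radii: SurfaceRadiusMap,
    ridge: float = 1e-6,
) -> FusedDisplacementModel:
    """Fit the fused displacement model for every load state."""
    n_t, n_z = len(surface.thetas), len(surface.zs)
    S = len(surface.disp_um)
    tg = np.repeat(surface.thetas, n_z)
    zg = np.tile(surface.zs, n_t)
    r_in_n = radii.eval_r_in(tg, zg).reshape(n_t, n_z)
    r_out_n = radii.eval_r_out(tg, zg).reshape(n_t, n_z)
    u_out = surface.disp_um[:, :, :, :2] * UM_TO_MM
    u_in = np.empty_like(u_out)
    beam = np.empty((S, n_z, 3))
    rms = np.empty(S)
    for s in range(S):
        u_in[s], rms[s] = fit_inner_displacement(surface, volume, radii, s, ridge)
        beam[s] = fit_axial_beam(surface, radii, s)
    return FusedDisplacementModel(
        thetas=surface.thetas, zs=surface.zs,
        r_in_nodes=r_in_n, r_out_nodes=r_out_n,
        u_out=u_out, u_in=u_in, beam=beam, fit_rms_um=rms,
    )


def deformation_gradient_field(
    model: FusedDisplacementModel,
    mesh: VesselMesh,
    state: int,
    e_c: np.ndarray | None = None,
    e_o: np.ndarray | None = None,
    incompressibility: str = "radial",
) -> DeformationState:
    """Deformation gradient per tet (at centroids) for one load state.

    The transmural (radial) displacement gradient is the least constrained
    part of the reconstruction: the volumetric data fix only a linear-in-R
    trend of the transverse motion.  Incompressibility supplies the missing
    constraint; ``incompressibility`` selects how det F is driven to 1:

    - ``"radial"`` (default): rescale the radial stretch only, leaving the
      well-measured in-plane and axial components untouched;
    - ``"isochoric"``: rely on the uniform F / J^(1/3) rescaling downstream;
    - ``"none"``: alias of "isochoric" (kept for symmetry).
    """
    Xc = mesh.tet_centroids()
    grad = model.gradient(Xc, state)
    F = np.broadcast_to(np.eye(3), grad.shape).copy() + grad
    J = np.linalg.det(F)
    if np.any(J <= 0):
        bad = np.flatnonzero(J <= 0)
        raise ValueError(f"non-positive Jacobian in tets {bad[:10].tolist()}")
    n_off = int((np.abs(J - 1) > 0.05).sum())
    if n_off:
        warnings.warn(
            f"|J - 1| exceeds 0.05 in {n_off} tets; check the displacement "
            "reconstruction", stacklevel=2)
    Th = np.arctan2(Xc[:, 1], Xc[:, 0])
    if e_c is None:
        e_c = np.column_stack([-np.sin(Th), np.cos(Th), np.zeros(len(Th))])
    J_raw = J
    if incompressibility == "radial":
        if e_o is None:
            e_o = np.column_stack([np.cos(Th), np.sin(Th), np.zeros(len(Th))])
        corr = 1.0 / J - 1.0
        F = (np.broadcast_to(np.eye(3), F.shape)
             + corr[:, None, None] * e_o[:, :, None] * e_o[:, None, :]) @ F
        J = np.linalg.det(F)
    elif incompressibility not in ("isochoric", "none"):
        raise ValueError(f"unknown incompressibility mode {incompressibility!r}")
    Fbar = F / np.cbrt(J)[:, None, None]
    lam = np.linalg.norm(np.einsum("tij,tj->ti", F, e_c), axis=1)
    return DeformationState(F=F, J=J, Fbar=Fbar, lam_theta=lam, J_raw=J_raw)


class ComposedDisplacement:
    """Total displacement obtained by composing incremental fields."""

    def __init__(self, increments, inverse: bool = False, additive: bool = False,
                 max_iter: int = 50, tol: float = 1e-12):
        self._inc = list(increments)
        self._inverse = inverse
        self._additive = additive
        self._max_iter = max_iter
        self._tol = tol

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self._additive:
            u = np.zeros_like(X)
            for inc in self._inc:
                u = u + inc(X)
            return -u if self._inverse else u
        x = X.copy()
        if not self._inverse:
            for inc in self._inc:
                x = x + inc(x)
            return x - X
        # invert the chain: walk increments last-to-first, solving
        # y + u(y) = x by fixed-point iteration
        for inc in reversed(self._inc):
            y = x.copy()
            for _ in range(self._max_iter):
                y_new = x - inc(y)
                if np.max(np.abs(y_new - y)) < self._tol:
                    y = y_new
                    break
                y = y_new
            x = y
        return x - X


def accumulate_increments(
    increments, reference_index: int, additive: bool = False
) -> list[ComposedDisplacement]:
    """Total displacement fields from a chain of incremental fields.

    ``increments[k]`` must be a callable mapping positions in state k to the
    incremental displacement toward state k+1 (both mm).  Returns one total
    field per state (len(increments)+1 entries), each giving displacement
    relative to the state at ``reference_index``; states before the
    reference accumulate inverse increments.
    """
    n_states = len(increments) + 1
    if not 0 <= reference_index < n_states:
        raise ValueError("reference index outside the state chain")
    totals = []
    for k in range(n_states):
        if k >= reference_index:
            chain = increments[reference_index:k]
            totals.append(ComposedDisplacement(chain, additive=additive))
        else:
            chain = increments[k:reference_index]
            totals.append(ComposedDisplacement(chain, inverse=True, additive=additive))
    return totals
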