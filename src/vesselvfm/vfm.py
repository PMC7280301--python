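"""Virtual fields method: virtual fields, power assembly, identification.

The principle of virtual power turns the measured full-field deformation into
linear equations for the sector-wise moduli: for any admissible virtual
velocity field u* with trace-free virtual strain eps*, the internal virtual
power (stress contracted with eps*, integrated over the deformed domain)
balances the external virtual power of the applied pressure and axial force.
Because the strain energy is linear in the moduli c1..c5 at fixed nonlinear
parameters Xi, each (virtual field, load state) pair yields one linear
equation; stacking them gives a rectangular system A(Xi) c = P*_ext solved in
the least-squares sense.  The nonlinear set Xi is found by a genetic
algorithm minimizing the least-squares residual.

Two virtual-field families are used, centred on each material sector (at its
deformed position): a pressure-normalized radial 1/r field and a
force-normalized axial extension field, both modulated by a Gaussian kernel
in (theta, z).  The axial family's axial component uses the z-antiderivative
of the kernel so that its virtual strain is exactly trace-free, which makes
the identification provably insensitive to the indeterminate reaction
pressure of the incompressible material.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import nnls
from scipy.special import erf

from .constitutive import (
    DEFAULT_BOUNDS,
    NONLINEAR_NAMES,
    MaterialField,
    SectorParameters,
    _psi,
)
from .geometry import THROMBUS, WALL, LocalBasisField, SectorPartition, VesselMesh
from .kinematics import DeformationState, LoadSchedule

__all__ = [
    "VirtualField",
    "VirtualPowerSystem",
    "IdentificationConfig",
    "IdentificationResult",
    "weight_kernel",
    "sector_deformed_centers",
    "VFMContext",
    "solve_linear",
    "projector_cost",
    "genetic_minimize",
    "identify",
]

_SYM_W = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])  # xx yy zz xy xz yz


def _wrap(dtheta: np.ndarray) -> np.ndarray:
    return np.arctan2(np.sin(dtheta), np.cos(dtheta))


def kernel_denominators(n_theta: int, n_z: int, z_extent: float,
                        mode: str = "printed") -> tuple[float, float]:
    """Gaussian kernel denominators.

    ``printed`` uses the widths exactly as published (10*pi/N_theta and
    5*(Z_up-Z_down)/N_z, dimensionally odd but well defined); ``squared``
    squares them for sensitivity studies.
    """
    a_t = 10.0 * np.pi / n_theta
    a_z = 5.0 * z_extent / n_z
    if mode == "squared":
        return a_t**2, a_z**2
    if mode != "printed":
        raise ValueError(f"unknown kernel mode {mode!r}")
    return a_t, a_z


def weight_kernel(dtheta, dz, n_theta: int, n_z: int, z_extent: float,
                  mode: str = "printed"):
    """Spatial localization kernel W in (0, 1], centred at (0, 0)."""
    a_t, a_z = kernel_denominators(n_theta, n_z, z_extent, mode)
    dtheta = _wrap(np.asarray(dtheta, dtype=float))
    return np.exp(-(dtheta**2) / a_t - np.asarray(dz, dtype=float) ** 2 / a_z)


@dataclass
class VirtualField:
    """One virtual velocity field and its (analytic) virtual strain.

    family 1: radial 1/r field normalized by the reference pressure;
    family 2: axial extension field normalized by the reference axial force.
    ``a_theta``/``a_z`` are the kernel denominators (may be inf to flatten
    the kernel).  The field is singular on the axis; evaluation inside
    ``r_min`` raises.
    """

    family: int
    theta_c: float
    z_c: float
    a_theta: float
    a_z: float
    p_ref: float
    f_ref: float
    r_min: float = 0.05

    def _kernel(self, theta, z):
        dth = _wrap(theta - self.theta_c)
        dz = z - self.z_c
        if np.isinf(self.a_theta):
            kt, kt_t = np.ones_like(dth), np.zeros_like(dth)
        else:
            kt = np.exp(-(dth**2) / self.a_theta)
            kt_t = -2.0 * dth / self.a_theta * kt
        if np.isinf(self.a_z):
            kz, kz_z = np.ones_like(dz), np.zeros_like(dz)
            phi_z = dz  # antiderivative of 1
        else:
            kz = np.exp(-(dz**2) / self.a_z)
            kz_z = -2.0 * dz / self.a_z * kz
            phi_z = 0.5 * np.sqrt(np.pi * self.a_z) * erf(dz / np.sqrt(self.a_z))
        W = kt * kz
        W_t = kt_t * kz
        W_z = kt * kz_z
        phi = kt * phi_z           # d(phi)/dz = W
        phi_t = kt_t * phi_z
        return W, W_t, W_z, phi, phi_t

    def evaluate(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Virtual displacement (N, 3) and strain (N, 3, 3) at deformed points."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        xx, yy, zz = x[:, 0], x[:, 1], x[:, 2]
        r2 = xx**2 + yy**2
        if np.any(r2 < self.r_min**2):
            raise ValueError("evaluation point inside the axis exclusion radius")
        theta = np.arctan2(yy, xx)
        W, W_t, W_z, phi, phi_t = self._kernel(theta, zz)
        n = len(x)
        u = np.zeros((n, 3))
        e = np.zeros((n, 3, 3))
        if self.family == 1:
            f = 1.0 / self.p_ref
            u[:, 0] = f * xx / r2 * W
            u[:, 1] = f * yy / r2 * W
            e[:, 0, 0] = f * ((yy**2 - xx**2) * W - xx * yy * W_t) / r2**2
            e[:, 1, 1] = f * ((xx**2 - yy**2) * W + xx * yy * W_t) / r2**2
            e[:, 0, 1] = f * (-2 * xx * yy * W + 0.5 * (xx**2 - yy**2) * W_t) / r2**2
            e[:, 0, 2] = f * 0.5 * xx / r2 * W_z
            e[:, 1, 2] = f * 0.5 * yy / r2 * W_z
        elif self.family == 2:
            f = 1.0 / self.f_ref
            u[:, 0] = -f * 0.5 * xx * W
            u[:, 1] = -f * 0.5 * yy * W
            u[:, 2] = f * phi
            e[:, 0, 0] = f * (-0.5 * W + 0.5 * xx * yy * W_t / r2)
            e[:, 1, 1] = f * (-0.5 * W - 0.5 * xx * yy * W_t / r2)
            e[:, 2, 2] = f * W
            e[:, 0, 1] = f * 0.25 * (yy**2 - xx**2) * W_t / r2
            e[:, 0, 2] = f * (-0.25 * xx * W_z - 0.5 * yy * phi_t / r2)
            e[:, 1, 2] = f * (-0.25 * yy * W_z + 0.5 * xx * phi_t / r2)
        else:
            raise ValueError("family must be 1 or 2")
        e[:, 1, 0] = e[:, 0, 1]
        e[:, 2, 0] = e[:, 0, 2]
        e[:, 2, 1] = e[:, 1, 2]
        return u, e


def sector_deformed_centers(
    partition: SectorPartition, x_def: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Weighted deformed (theta, z) centroid of each sector.

    theta uses a weighted circular mean.  Empty sectors fall back to the
    reference bin centre.
    """
    flat = partition.flat_index()
    n = partition.n_sectors
    th = np.arctan2(x_def[:, 1], x_def[:, 0])
    cs = np.bincount(flat, weights=weights * np.cos(th), minlength=n)
    sn = np.bincount(flat, weights=weights * np.sin(th), minlength=n)
    wz = np.bincount(flat, weights=weights * x_def[:, 2], minlength=n)
    wt = np.bincount(flat, weights=weights, minlength=n)
    centers = np.zeros((n, 2))
    t_mid = 0.5 * (partition.theta_edges[:-1] + partition.theta_edges[1:])
    z_mid = 0.5 * (partition.z_edges[:-1] + partition.z_edges[1:])
    for s in range(n):
        it, iz = divmod(s, partition.n_z)
        if wt[s] > 0:
            centers[s] = [np.arctan2(sn[s], cs[s]), wz[s] / wt[s]]
        else:
            centers[s] = [t_mid[it], z_mid[iz]]
    return centers


@dataclass
class VirtualPowerSystem:
    """Assembled rectangular system A(Xi) c = P*_ext."""

    A: np.ndarray            # (n_rows, n_cols) after column pruning
    p_ext: np.ndarray        # (n_rows,)
    col_labels: list[tuple[int, int]]   # (sector flat index, i in 1..5)
    row_labels: list[tuple[int, int, int]]  # (state, sector flat, family)


@dataclass
class IdentificationConfig:
    """Settings for the inverse identification."""

    n_theta: int = 1
    n_z: int = 1
    bounds: dict = dc_field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    fixed: dict = dc_field(default_factory=dict)  # e.g. {"alpha": 0.0}
    G_a: float = 1.25
    kernel_mode: str = "printed"
    r_min: float = 0.05
    pressure_surface: str = "inner"   # "outer" reproduces an S_out-based variant
    optimizer: str = "de"             # "de" (differential evolution) or "ga"
    de_popsize: int = 15              # scipy popsize multiplier
    de_maxiter: int = 60
    polish: bool = True               # simplex descent from the best candidate
    polish_maxfev: int = 3000
    population: int = 60
    generations: int = 120
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    mutation_sd_frac: float = 0.05
    mutation_sd_decay: float = 0.985
    elitism: int = 2
    state_subset: list[int] | None = None


@dataclass
class IdentificationResult:
    """Best-fit material field with solver diagnostics and the GA trace."""

    material_field: MaterialField
    cost: float
    c_vector: np.ndarray
    col_labels: list[tuple[int, int]]
    ga_trace: np.ndarray
    residual_rel: float
    rank: int
    converged: bool = True

    def summary_frame(self):
        import pandas as pd

        rows = []
        part = self.material_field.partition
        for s, p in enumerate(self.material_field.sectors):
            it, iz = divmod(s, part.n_z)
            rows.append({
                "i_theta": it, "i_z": iz,
                "c1": p.c1, "c2": p.c2, "c3": p.c3, "c4": p.c4, "c5": p.c5,
                "k1": p.k1, "k2": p.k2, "k3": p.k3,
                "G1": p.G1, "G2": p.G2, "G3": p.G3, "G4": p.G4,
                "beta_deg": np.rad2deg(p.beta), "alpha": p.alpha,
            })
        return pd.DataFrame(rows)


class VFMContext:
    """Precomputed quantities for repeated A(Xi) assembly.

    Holds, per load state: isochoric kinematic vectors in the local triad,
    virtual strains at deformed tet centroids (contracted against the
    state-independent outer-product basis), quadrature weights, and the
    external virtual power vector.  Everything except the Fung stress
    coefficients is independent of Xi, so a cost evaluation reduces to
    elementwise exponentials and small matrix products.
    """

    def __init__(
        self,
        mesh: VesselMesh,
        partition: SectorPartition,
        basis: LocalBasisField,
        def_states: list[DeformationState],
        schedule: LoadSchedule,
        node_disp_mm: np.ndarray,          # (S, N, 3)
        config: IdentificationConfig | None = None,
    ):
        self.mesh = mesh
        self.partition = partition
        self.basis = basis
        self.schedule = schedule
        self.config = config or IdentificationConfig(
            n_theta=partition.n_theta, n_z=partition.n_z)
        states = range(len(def_states))
        if self.config.state_subset is not None:
            states = self.config.state_subset
        self.state_ids = list(states)
        self.def_states = def_states
        self.node_disp = node_disp_mm
        self.n_sectors = partition.n_sectors
        self.n_vf = 2 * self.n_sectors
        self._precompute()

    # -- precomputation --------------------------------------------------
    def _precompute(self) -> None:
        mesh, part, basis = self.mesh, self.partition, self.basis
        V0 = mesh.tet_volumes()
        flat = part.flat_index()
        self.wall_idx = [np.flatnonzero((flat == s) & (mesh.region == WALL))
                         for s in range(self.n_sectors)]
        self.imt_idx = [np.flatnonzero((flat == s) & (mesh.region == THROMBUS))
                        for s in range(self.n_sectors)]
        z_lo, z_hi = mesh.z_bounds
        a_t, a_z = kernel_denominators(part.n_theta, part.n_z, z_hi - z_lo,
                                       self.config.kernel_mode)
        Xc = mesh.tet_centroids()
        node_of_tet = mesh.tets
        p_ref = self.schedule.p_ref_kpa
        f_ref = self.schedule.f_ref
        if abs(f_ref) < 1e-9:
            f_ref = 1.0  # degenerate normalizer; keep fields finite
        self.p_ref, self.f_ref = p_ref, f_ref

        self.per_state = []
        for s in self.state_ids:
            ds = self.def_states[s]
            u_nodes = self.node_disp[s]
            x_def = Xc + u_nodes[node_of_tet].mean(axis=1)
            w_q = V0 * ds.J  # deformed volumes
            centers = sector_deformed_centers(part, x_def, w_q)
            fields = []
            for sec in range(self.n_sectors):
                for fam in (1, 2):
                    fields.append(VirtualField(
                        family=fam, theta_c=centers[sec, 0], z_c=centers[sec, 1],
                        a_theta=a_t, a_z=a_z, p_ref=p_ref, f_ref=f_ref,
                        r_min=self.config.r_min))
            Fb = ds.Fbar
            fc = np.einsum("tij,tj->ti", Fb, basis.e_c)
            fa = np.einsum("tij,tj->ti", Fb, basis.e_a)
            fo = np.einsum("tij,tj->ti", Fb, basis.e_o)
            eps6 = np.empty((self.n_vf, mesh.n_tets, 6))
            for v, fld in enumerate(fields):
                _, e = fld.evaluate(x_def)
                eps6[v] = np.stack([e[:, 0, 0], e[:, 1, 1], e[:, 2, 2],
                                    e[:, 0, 1], e[:, 0, 2], e[:, 1, 2]], axis=-1)
            eps6 *= _SYM_W  # fold symmetric-contraction weights in
            def sym6(a, b):
                return np.stack([
                    a[:, 0] * b[:, 0], a[:, 1] * b[:, 1], a[:, 2] * b[:, 2],
                    0.5 * (a[:, 0] * b[:, 1] + a[:, 1] * b[:, 0]),
                    0.5 * (a[:, 0] * b[:, 2] + a[:, 2] * b[:, 0]),
                    0.5 * (a[:, 1] * b[:, 2] + a[:, 2] * b[:, 1]),
                ], axis=-1)
            # V0-weighted contractions (V, T): quadrature J^-1 * (.) * J V0
            EVcc = np.einsum("vtk,tk,t->vt", eps6, sym6(fc, fc), V0)
            EVaa = np.einsum("vtk,tk,t->vt", eps6, sym6(fa, fa), V0)
            EVoo = np.einsum("vtk,tk,t->vt", eps6, sym6(fo, fo), V0)
            EVca = np.einsum("vtk,tk,t->vt", eps6, sym6(fc, fa), V0)
            BB = np.einsum("tij,tkj->tik", Fb, Fb)  # F_bar F_bar^T
            bb6 = np.stack([BB[:, 0, 0], BB[:, 1, 1], BB[:, 2, 2],
                            BB[:, 0, 1], BB[:, 0, 2], BB[:, 1, 2]], axis=-1)
            EVth = np.einsum("vtk,tk,t->vt", eps6, bb6, V0)
            self.per_state.append({
                "state": s,
                "x_def": x_def,
                "fields": fields,
                "EVcc": EVcc, "EVaa": EVaa, "EVoo": EVoo, "EVca": EVca,
                "EVth": EVth,
                "ncc": np.einsum("ti,ti->t", fc, fc),
                "naa": np.einsum("ti,ti->t", fa, fa),
                "dca": np.einsum("ti,ti->t", fc, fa),
                # per-sector Xi-independent sums for the neoHookean columns
                "Scc": np.stack([EVcc[:, ix].sum(axis=1) for ix in self.wall_idx], axis=1),
                "Saa": np.stack([EVaa[:, ix].sum(axis=1) for ix in self.wall_idx], axis=1),
                "Soo": np.stack([EVoo[:, ix].sum(axis=1) for ix in self.wall_idx], axis=1),
                "Sth": np.stack([EVth[:, ix].sum(axis=1) for ix in self.imt_idx], axis=1),
            })

        # column bookkeeping: 5 per sector, prune structurally empty columns
        V0w = V0
        wall_vol = np.array([V0w[ix].sum() for ix in self.wall_idx])
        imt_vol = np.array([V0w[ix].sum() for ix in self.imt_idx])
        keep = []
        labels = []
        for sec in range(self.n_sectors):
            for i in range(1, 6):
                has = imt_vol[sec] > 0 if i == 5 else wall_vol[sec] > 0
                if has:
                    keep.append(sec * 5 + i - 1)
                    labels.append((sec, i))
        self.col_keep = np.array(keep, dtype=int)
        self.col_labels = labels
        self.row_labels = [
            (st["state"], sec, fam)
            for st in self.per_state
            for sec in range(self.n_sectors)
            for fam in (1, 2)
        ]
        self._p_ext = None

    # -- external power ---------------------------------------------------
    def _deformed_surface(self, state_pos: int, which: str):
        mesh = self.mesh
        facets = mesh.inner_facets if which == "inner" else mesh.outer_facets
        nodes = mesh.nodes + self.node_disp[self.per_state[state_pos]["state"]]
        v0, v1, v2 = nodes[facets[:, 0]], nodes[facets[:, 1]], nodes[facets[:, 2]]
        cent = (v0 + v1 + v2) / 3.0
        avec = 0.5 * np.cross(v1 - v0, v2 - v0)
        # outward normal of the tissue domain: toward the axis on S_in,
        # away from it on S_out
        radial = np.einsum("ij,ij->i", avec, np.column_stack(
            [cent[:, 0], cent[:, 1], np.zeros(len(cent))]))
        want_negative = which == "inner"
        s = radial.mean()
        if (s > 0) == want_negative:
            warnings.warn(f"flipping {which} facet normals (orientation test)",
                          stacklevel=2)
            avec = -avec
        return cent, avec, nodes

    def _end_sections(self, state_pos: int):
        """Deformed end-annulus geometry: (z_end, r_i, r_o) for both ends."""
        mesh = self.mesh
        nodes_def = mesh.nodes + self.node_disp[self.per_state[state_pos]["state"]]
        inner, outer = mesh.boundary_node_sets()
        z_ref = mesh.nodes[:, 2]
        z_lo, z_hi = mesh.z_bounds
        tol = 1e-6 * max(z_hi - z_lo, 1.0)
        out = []
        for z_end, sign in ((z_hi, +1), (z_lo, -1)):
            sel_i = inner[np.abs(z_ref[inner] - z_end) < tol]
            sel_o = outer[np.abs(z_ref[outer] - z_end) < tol]
            if len(sel_i) == 0 or len(sel_o) == 0:
                raise RuntimeError("could not locate end-section boundary nodes")
            ri = np.hypot(nodes_def[sel_i, 0], nodes_def[sel_i, 1]).mean()
            ro = np.hypot(nodes_def[sel_o, 0], nodes_def[sel_o, 1]).mean()
            zd = nodes_def[np.concatenate([sel_i, sel_o]), 2].mean()
            out.append((zd, ri, ro, sign))
        return out

    def external_power(self) -> np.ndarray:
        """P*_ext per row, from measured pressure and axial force."""
        if self._p_ext is not None:
            return self._p_ext
        p_ext = np.zeros(len(self.per_state) * self.n_vf)
        n_q_t, n_q_r = 64, 4
        tq = np.linspace(-np.pi, np.pi, n_q_t, endpoint=False)
        for sp, st in enumerate(self.per_state):
            state = self.schedule.states[st["state"]]
            p = state.pressure_kpa
            f_ax = state.axial_force_mn
            cent, avec, _ = self._deformed_surface(sp, self.config.pressure_surface)
            ends = self._end_sections(sp)
            for v, fld in enumerate(st["fields"]):
                u_s, _ = fld.evaluate(cent)
                val = -p * np.einsum("ij,ij->", avec, u_s)
                if fld.family == 2:
                    for zd, ri, ro, sign in ends:
                        rq = np.linspace(ri, ro, n_q_r)
                        RR, TT = np.meshgrid(rq, tq, indexing="ij")
                        pts = np.column_stack([
                            (RR * np.cos(TT)).ravel(), (RR * np.sin(TT)).ravel(),
                            np.full(RR.size, zd)])
                        uz = fld.evaluate(pts)[0][:, 2].reshape(RR.shape)
                        # area-average of the axial virtual displacement
                        w_mean = np.average(uz, weights=np.broadcast_to(RR, uz.shape))
                        N_tot = f_ax + p * np.pi * ri**2
                        val += sign * N_tot * w_mean
                p_ext[sp * self.n_vf + v] = val
        self._p_ext = p_ext
        return p_ext

    # -- assembly ---------------------------------------------------------
    def xi_to_sector_array(self, xi_flat: np.ndarray) -> np.ndarray:
        """Reshape the GA vector into per-sector rows of the 9 nonlinear params,
        substituting fixed values."""
        free_names = [n for n in NONLINEAR_NAMES if n not in self.config.fixed]
        n_free = len(free_names)
        arr = np.empty((self.n_sectors, 9))
        xi_flat = np.asarray(xi_flat, dtype=float).reshape(self.n_sectors, n_free)
        for j, name in enumerate(NONLINEAR_NAMES):
            if name in self.config.fixed:
                arr[:, j] = self.config.fixed[name]
            else:
                arr[:, j] = xi_flat[:, free_names.index(name)]
        return arr

    def ga_bounds(self) -> np.ndarray:
        free_names = [n for n in NONLINEAR_NAMES if n not in self.config.fixed]
        b = np.array([self.config.bounds[n] for n in free_names],
                     dtype=float).reshape(-1, 2)
        return np.tile(b, (self.n_sectors, 1))

    def assemble(self, xi_sectors: np.ndarray) -> np.ndarray:
        """A(Xi): rows (state x sector-center x family), pruned columns."""
        n_rows = len(self.per_state) * self.n_vf
        A = np.zeros((n_rows, 5 * self.n_sectors))
        G_a = self.config.G_a
        for sp, st in enumerate(self.per_state):
            rows = slice(sp * self.n_vf, (sp + 1) * self.n_vf)
            for sec in range(self.n_sectors):
                k1, k2, k3, G1, G2, G3, G4, beta, alpha = xi_sectors[sec]
                ix = self.wall_idx[sec]
                base = sec * 5
                if len(ix):
                    ncc, naa, dca = st["ncc"][ix], st["naa"][ix], st["dca"][ix]
                    A[rows, base + 0] = st["EVcc"][:, ix] @ (
                        G1**2 * _psi(G1**2 * ncc, k1, alpha))
                    A[rows, base + 1] = st["EVaa"][:, ix] @ (
                        G2**2 * _psi(G2**2 * naa, k2, alpha))
                    cb, sb = np.cos(beta), np.sin(beta)
                    e3 = (cb**2 * st["EVcc"][:, ix] + sb**2 * st["EVaa"][:, ix])
                    x3 = 2.0 * sb * cb * st["EVca"][:, ix]
                    for sgn in (+1.0, -1.0):
                        inv = G3**2 * (cb**2 * ncc + sb**2 * naa + sgn * 2 * sb * cb * dca)
                        w3 = G3**2 * _psi(inv, k3, alpha)
                        A[rows, base + 2] += (e3 + sgn * x3) @ w3
                    A[rows, base + 3] = (
                        G4**2 * st["Scc"][:, sec]
                        + G_a**2 * st["Saa"][:, sec]
                        + (G4 * G_a) ** -2 * st["Soo"][:, sec]
                    )
                if len(self.imt_idx[sec]):
                    A[rows, base + 4] = st["Sth"][:, sec]
        return A[:, self.col_keep]

    def row_weights(self) -> np.ndarray:
        """Family-wise row equilibration weights.

        The p_ref / F_ref prefactors are meant to bring both virtual-field
        families to comparable virtual-power magnitudes, but the raw
        reference force can still leave the axial family one to two orders
        of magnitude below the pressure family, effectively discarding the
        axial information in the least-squares solve.  Rows are therefore
        scaled by the inverse RMS external power of their family
        (consistently on A and P*_ext), which is a weighted least squares
        with equal aggregate weight per family.
        """
        if getattr(self, "_row_w", None) is None:
            p = self.external_power()
            fam = np.array([f for _, _, f in self.row_labels])
            w = np.ones_like(p)
            for f in (1, 2):
                rms = np.sqrt(np.mean(p[fam == f] ** 2))
                if rms > 0:
                    w[fam == f] = 1.0 / rms
            self._row_w = w
        return self._row_w

    def solve_weighted(self, A: np.ndarray) -> tuple[np.ndarray, float, int]:
        w = self.row_weights()
        return solve_linear(A * w[:, None], self.external_power() * w)

    def cost(self, xi_flat: np.ndarray) -> float:
        try:
            A = self.assemble(self.xi_to_sector_array(xi_flat))
        except FloatingPointError:
            # Fung exponential overflow: infeasible candidate
            return 1e30
        _, resid, _ = self.solve_weighted(A)
        return float(resid**2)

    def internal_power(self, field_: MaterialField) -> np.ndarray:
        """P*_int per row for a given material field (power-balance oracle)."""
        xi = np.stack([s.nonlinear() for s in field_.sectors])
        A = self.assemble(xi)
        c_full = np.concatenate([s.linear() for s in field_.sectors])
        return A @ c_full[self.col_keep]

    def build_system(self, xi_sectors: np.ndarray) -> VirtualPowerSystem:
        return VirtualPowerSystem(
            A=self.assemble(xi_sectors),
            p_ext=self.external_power(),
            col_labels=self.col_labels,
            row_labels=self.row_labels,
        )


def solve_linear(A: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, float, int]:
    """Least-squares moduli with nonnegativity fallback.

    Returns (c, residual norm, rank).  Negative components (unphysical
    moduli) trigger a nonnegative re-solve.
    """
    if A.shape[0] < A.shape[1]:
        raise ValueError("fewer rows than unknowns; add virtual fields or states")
    c, _, rank, _ = np.linalg.lstsq(A, p, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"rank-deficient virtual power system (rank {rank} < {A.shape[1]}); "
            "minimum-norm solution returned", stacklevel=2)
    if np.any(c < -1e-9 * max(1.0, np.abs(c).max())):
        c, _ = nnls(A, p)
    resid = float(np.linalg.norm(A @ c - p))
    return c, resid, int(rank)


def projector_cost(A: np.ndarray, p: np.ndarray) -> float:
    """Cost in the explicit projector form (algebraic mirror of the
    residual-norm form; used as a cross-check)."""
    M = A @ np.linalg.pinv(A.T @ A) @ A.T
    r = (M - np.eye(len(p))) @ p
    return float(r @ r)


def genetic_minimize(
    fun,
    bounds: np.ndarray,
    seed: int,
    population: int = 60,
    generations: int = 120,
    tournament: int = 3,
    crossover_rate: float = 0.9,
    mutation_rate: float = 0.25,
    mutation_sd_frac: float = 0.05,
    mutation_sd_decay: float = 0.985,
    elitism: int = 2,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Real-coded genetic algorithm over box bounds.

    Tournament selection, blend (BLX-0.5) crossover, Gaussian mutation with
    a geometrically annealed step size, and elitism.  Deterministic for a
    fixed seed.  Returns (best_x, best_f, per-generation best trace).
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    span = hi - lo
    d = len(bounds)
    pop = lo + span * rng.random((population, d))
    fit = np.array([fun(x) for x in pop])
    trace = np.empty(generations)
    sd = mutation_sd_frac * span
    for g in range(generations):
        order = np.argsort(fit)
        new = [pop[i].copy() for i in order[:elitism]]
        while len(new) < population:
            idx = rng.integers(population, size=(2, tournament))
            pa = pop[idx[0][np.argmin(fit[idx[0]])]]
            pb = pop[idx[1][np.argmin(fit[idx[1]])]]
            if rng.random() < crossover_rate:
                gamma = rng.uniform(-0.5, 1.5, size=d)
                child = pa + gamma * (pb - pa)
            else:
                child = pa.copy()
            mut = rng.random(d) < mutation_rate
            child = child + mut * rng.normal(0.0, sd, size=d)
            new.append(np.clip(child, lo, hi))
        pop = np.array(new[:population])
        keep = min(elitism, population)
        fit = np.concatenate([fit[order[:keep]],
                              [fun(x) for x in pop[keep:]]])
        sd = sd * mutation_sd_decay
        trace[g] = fit.min()
    best = int(np.argmin(fit))
    return pop[best].copy(), float(fit[best]), trace


def identify(
    mesh: VesselMesh,
    partition: SectorPartition,
    basis: LocalBasisField,
    def_states: list[DeformationState],
    schedule: LoadSchedule,
    node_disp_mm: np.ndarray,
    config: IdentificationConfig,
    seed: int = 0,
) -> IdentificationResult:
    """Full hybrid identification: GA over Xi with inner linear solves."""
    ctx = VFMContext(mesh, partition, basis, def_states, schedule,
                     node_disp_mm, config)
    bounds = ctx.ga_bounds()
    if len(bounds) == 0:
        best_xi, best_f, trace = np.empty(0), ctx.cost(np.empty(0)), np.empty(0)
    elif config.optimizer == "de":
        from scipy.optimize import differential_evolution

        hist: list[float] = []
        res = differential_evolution(
            ctx.cost, [tuple(b) for b in bounds], seed=seed,
            popsize=config.de_popsize, maxiter=config.de_maxiter,
            tol=0.0, polish=True, init="sobol",
            callback=lambda xk, convergence=0.0: hist.append(ctx.cost(xk)) and False,
        )
        best_xi, best_f, trace = res.x, float(res.fun), np.asarray(hist)
    elif config.optimizer == "ga":
        best_xi, best_f, trace = genetic_minimize(
            ctx.cost, bounds, seed,
            population=config.population, generations=config.generations,
            tournament=config.tournament, crossover_rate=config.crossover_rate,
            mutation_rate=config.mutation_rate,
            mutation_sd_frac=config.mutation_sd_frac,
            mutation_sd_decay=config.mutation_sd_decay, elitism=config.elitism,
        )
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    if config.polish and len(bounds):
        from scipy.optimize import minimize

        lo, hi = bounds[:, 0], bounds[:, 1]
        res = minimize(lambda x: ctx.cost(np.clip(x, lo, hi)), best_xi,
                       method="Nelder-Mead",
                       options={"maxfev": config.polish_maxfev,
                                "xatol": 1e-9, "fatol": 1e-15})
        if res.fun < best_f:
            best_xi, best_f = np.clip(res.x, lo, hi), float(res.fun)
    xi_sec = ctx.xi_to_sector_array(best_xi)
    A = ctx.assemble(xi_sec)
    p = ctx.external_power() * ctx.row_weights()
    c, resid, rank = ctx.solve_weighted(A)
    c_full = np.zeros(5 * ctx.n_sectors)
    c_full[ctx.col_keep] = c
    sectors = []
    for sec in range(ctx.n_sectors):
        k1, k2, k3, G1, G2, G3, G4, beta, alpha = xi_sec[sec]
        sectors.append(SectorParameters(
            c1=c_full[sec * 5], c2=c_full[sec * 5 + 1], c3=c_full[sec * 5 + 2],
            c4=c_full[sec * 5 + 3], c5=c_full[sec * 5 + 4],
            k1=k1, k2=k2, k3=k3, G1=G1, G2=G2, G3=G3, G4=G4,
            beta=beta, alpha=alpha))
    mf = MaterialField(partition, sectors, G_a=config.G_a,
                       bounds=dict(config.bounds))
    rel = resid / max(np.linalg.norm(p), 1e-30)
    return IdentificationResult(
        material_field=mf, cost=float(resid**2), c_vector=c,
        col_labels=ctx.col_labels, ga_trace=trace, residual_rel=float(rel),
        rank=rank)
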