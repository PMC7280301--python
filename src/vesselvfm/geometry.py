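"""Vessel mesh model, sector partitioning, local material basis and alignment.

The computational domain is a tetrahedral mesh of the vessel segment between
the luminal surface ``S_in`` and the adventitial surface ``S_out``.  Each
tetrahedron carries a region label (aortic wall or intramural thrombus).  The
vessel centreline is assumed to coincide with the global z-axis; the angular
coordinate is ``Theta = atan2(y, x)`` in ``(-pi, pi]``.

A transmural scalar ``xi`` (0 on the lumen, 1 on the adventitia) is obtained
by solving Laplace's equation with linear tetrahedral finite elements; its
gradient defines the local radial direction, from which an orthonormal
material triad (circumferential, axial, radial) is built per element.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = [
    "VesselMesh",
    "SectorPartition",
    "LocalBasisField",
    "SurfaceRadiusMap",
    "build_sector_partition",
    "solve_radial_scalar",
    "build_local_basis",
    "rigid_align_axis",
    "surface_radius_maps",
]

WALL = 0
THROMBUS = 1


@dataclass
class VesselMesh:
    """Tetrahedral vessel domain with region labels and boundary surfaces.

    Parameters
    ----------
    nodes : (N, 3) float array
        Node coordinates in mm, vessel axis along z.
    tets : (T, 4) int array
        Tetrahedra (positive signed volume under the stored node order).
    region : (T,) int array
        Region label per tet: 0 = wall, 1 = intramural thrombus.
    inner_facets, outer_facets : (F, 3) int arrays
        Triangulations of the luminal (S_in) and adventitial (S_out)
        boundary surfaces, referencing mesh nodes.
    """

    nodes: np.ndarray
    tets: np.ndarray
    region: np.ndarray
    inner_facets: np.ndarray
    outer_facets: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=int)
        self.region = np.asarray(self.region, dtype=int)
        self.inner_facets = np.asarray(self.inner_facets, dtype=int)
        self.outer_facets = np.asarray(self.outer_facets, dtype=int)

    # -- basic queries ---------------------------------------------------
    @property
    def n_tets(self) -> int:
        return len(self.tets)

    @property
    def z_bounds(self) -> tuple[float, float]:
        z = self.nodes[:, 2]
        return float(z.min()), float(z.max())

    def tet_volumes(self) -> np.ndarray:
        """Signed volumes (mm^3); positive for a valid mesh."""
        p = self.nodes[self.tets]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def tet_centroids(self) -> np.ndarray:
        return self.nodes[self.tets].mean(axis=1)

    def boundary_node_sets(self) -> tuple[np.ndarray, np.ndarray]:
        inner = np.unique(self.inner_facets)
        outer = np.unique(self.outer_facets)
        return inner, outer

    def validate(self) -> None:
        """Check the structural invariants; raise ValueError on violation."""
        if self.n_tets == 0:
            raise ValueError("mesh has no tetrahedra")
        vols = self.tet_volumes()
        if np.any(vols <= 0):
            bad = np.flatnonzero(vols <= 0)[:10]
            raise ValueError(f"non-positive tet volumes, e.g. tets {bad.tolist()}")
        if self.region.shape != (self.n_tets,):
            raise ValueError("region labels must be one per tet")
        if not np.isin(self.region, [WALL, THROMBUS]).all():
            raise ValueError("region labels must be 0 (wall) or 1 (thrombus)")
        nmax = len(self.nodes)
        for name, fac in (("S_in", self.inner_facets), ("S_out", self.outer_facets)):
            if len(fac) and (fac.min() < 0 or fac.max() >= nmax):
                raise ValueError(f"{name} facets reference nonexistent nodes")
        inner, outer = self.boundary_node_sets()
        if len(inner) == 0 or len(outer) == 0:
            raise ValueError("empty boundary surface")


@dataclass
class SectorPartition:
    """Angular x axial partition of the domain, tets binned by centroid."""

    n_theta: int
    n_z: int
    theta_edges: np.ndarray   # (n_theta + 1,) over [-pi, pi]
    z_edges: np.ndarray       # (n_z + 1,) over [Z_down, Z_up]
    sector_of_tet: np.ndarray  # (T, 2) int: (i_theta, i_z)

    @property
    def n_sectors(self) -> int:
        return self.n_theta * self.n_z

    def flat_index(self) -> np.ndarray:
        """Flattened sector index per tet: i_theta * n_z + i_z."""
        return self.sector_of_tet[:, 0] * self.n_z + self.sector_of_tet[:, 1]


@dataclass
class LocalBasisField:
    """Transmural scalar (per node) and orthonormal material triad (per tet)."""

    xi: np.ndarray    # (N,) in [0, 1]
    e_a: np.ndarray   # (T, 3) axial unit vectors
    e_o: np.ndarray   # (T, 3) radial (grad xi) unit vectors
    e_c: np.ndarray   # (T, 3) circumferential, e_c = e_a x e_o


def build_sector_partition(mesh: VesselMesh, n_theta: int, n_z: int) -> SectorPartition:
    """Bin tets into ``n_theta x n_z`` material sectors by centroid.

    Angular bins are half-open ``[edge_k, edge_{k+1})`` with a periodic wrap
    at +/-pi; axial bins tile ``[Z_down, Z_up]`` (the last bin closed).
    """
    if mesh.n_tets == 0:
        raise ValueError("cannot partition an empty mesh")
    if n_theta < 1 or n_z < 1:
        raise ValueError("n_theta and n_z must be >= 1")
    z_lo, z_hi = mesh.z_bounds
    cent = mesh.tet_centroids()
    theta = np.arctan2(cent[:, 1], cent[:, 0])
    i_t = np.floor((theta + np.pi) / (2 * np.pi / n_theta)).astype(int) % n_theta
    i_z = np.floor((cent[:, 2] - z_lo) / ((z_hi - z_lo) / n_z)).astype(int)
    i_z = np.clip(i_z, 0, n_z - 1)
    part = SectorPartition(
        n_theta=n_theta,
        n_z=n_z,
        theta_edges=np.linspace(-np.pi, np.pi, n_theta + 1),
        z_edges=np.linspace(z_lo, z_hi, n_z + 1),
        sector_of_tet=np.column_stack([i_t, i_z]),
    )
    counts = np.bincount(part.flat_index(), minlength=part.n_sectors)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        warnings.warn(
            f"{len(empty)} sector(s) contain no tets (flat indices {empty.tolist()}); "
            "identification will be rank-deficient there",
            stacklevel=2,
        )
    return part


def _shape_gradients(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Constant gradients of the 4 linear shape functions per tet.

    Returns (grads, volumes) with grads of shape (T, 4, 3).
    """
    p = nodes[tets]  # (T, 4, 3)
    a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
    vol6 = np.einsum("ij,ij->i", np.cross(a, b), c)
    # gradients of barycentric coordinates: rows of inverse Jacobian
    J = np.stack([a, b, c], axis=1)  # (T, 3, 3) rows = edge vectors
    Jinv = np.linalg.inv(J)          # columns give grad lambda_1..3
    g123 = np.transpose(Jinv, (0, 2, 1))  # (T, 3(node), 3(xyz))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)
    return grads, vol6 / 6.0


def solve_radial_scalar(mesh: VesselMesh, rtol: float = 1e-10) -> np.ndarray:
    """Solve Laplace's equation for the transmural coordinate ``xi``.

    Linear tetrahedral FE solution with Dirichlet data xi=0 on S_in and
    xi=1 on S_out; Dirichlet rows are eliminated before the sparse solve.
    """
    inner, outer = mesh.boundary_node_sets()
    if len(inner) == 0 or len(outer) == 0:
        raise ValueError("both boundary surfaces must be nonempty")
    if np.intersect1d(inner, outer).size:
        raise ValueError("S_in and S_out node sets must be disjoint")

    n = len(mesh.nodes)
    grads, vols = _shape_gradients(mesh.nodes, mesh.tets)
    # element stiffness: K_ab = vol * grad_a . grad_b
    ke = np.einsum("t,tax,tbx->tab", vols, grads, grads)
    rows = np.repeat(mesh.tets, 4, axis=1).ravel()
    cols = np.tile(mesh.tets, (1, 4)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    xi = np.zeros(n)
    xi[outer] = 1.0
    fixed = np.zeros(n, dtype=bool)
    fixed[inner] = True
    fixed[outer] = True
    free = ~fixed
    rhs = -K[free][:, fixed] @ xi[fixed]
    Kff = K[free][:, free]
    try:
        sol = spla.spsolve(Kff.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "Laplace solve failed (disconnected boundary sets or degenerate mesh)"
        ) from exc
    if not np.all(np.isfinite(sol)):
        raise RuntimeError("Laplace solve produced non-finite values; check that "
                           "S_in and S_out are connected through the mesh")
    res = np.linalg.norm(Kff @ sol - rhs)
    if res > rtol * max(1.0, np.linalg.norm(rhs)):
        warnings.warn(f"Laplace solve residual {res:.2e} above tolerance", stacklevel=2)
    xi[free] = sol
    return xi


def build_local_basis(mesh: VesselMesh, xi: np.ndarray, tol: float = 1e-12) -> LocalBasisField:
    """Per-tet orthonormal triad (e_c, e_a, e_o) from the transmural scalar.

    e_a is the global axis; e_o is grad(xi) orthogonalized against e_a and
    normalized; e_c = e_a x e_o.  Raises if grad(xi) is degenerate in a tet.
    """
    grads, _ = _shape_gradients(mesh.nodes, mesh.tets)
    gxi = np.einsum("tax,ta->tx", grads, xi[mesh.tets])  # (T, 3)
    e_a = np.zeros_like(gxi)
    e_a[:, 2] = 1.0
    g_perp = gxi - gxi[:, 2:3] * e_a
    nrm = np.linalg.norm(g_perp, axis=1)
    bad = np.flatnonzero(nrm < tol)
    if bad.size:
        raise ValueError(
            f"near-zero transmural gradient in tets {bad[:10].tolist()} "
            "(degenerate geometry)"
        )
    e_o = g_perp / nrm[:, None]
    e_c = np.cross(e_a, e_o)
    return LocalBasisField(xi=xi, e_a=e_a, e_o=e_o, e_c=e_c)


# -- axis-constrained rigid alignment -----------------------------------

def _nn_cost(a: np.ndarray, b: np.ndarray, tree_b: cKDTree) -> float:
    d_ab, _ = tree_b.query(a, k=1)
    tree_a = cKDTree(a)
    d_ba, _ = tree_a.query(b, k=1)
    return float(np.sum(d_ab**2) + np.sum(d_ba**2))


def _apply(points: np.ndarray, phi: float, dz: float) -> np.ndarray:
    c, s = np.cos(phi), np.sin(phi)
    out = points.copy()
    out[:, 0] = c * points[:, 0] - s * points[:, 1]
    out[:, 1] = s * points[:, 0] + c * points[:, 1]
    out[:, 2] = points[:, 2] + dz
    return out


def rigid_align_axis(
    points_a: np.ndarray,
    points_b: np.ndarray,
    coarse_step_deg: float = 1.0,
    n_dz: int = 11,
) -> tuple[float, float]:
    """Axis-constrained rigid registration of two point clouds.

    Finds the rotation ``phi`` about the z-axis and translation ``dz``
    along it such that ``R(phi) a + dz k`` best matches ``b`` under a
    symmetric nearest-neighbour sum of squared distances.  A coarse grid
    scan over phi (1 degree steps by default) avoids the local minima of
    the nearest-neighbour cost before simplex refinement.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 points in each set")
    tree_b = cKDTree(b)
    dz0 = float(b[:, 2].mean() - a[:, 2].mean())
    span = max(np.ptp(a[:, 2]), np.ptp(b[:, 2]), 1e-6)
    dz_grid = dz0 + np.linspace(-0.25 * span, 0.25 * span, n_dz)
    phis = np.deg2rad(np.arange(-180.0, 180.0, coarse_step_deg))
    best = (np.inf, 0.0, dz0)
    for phi in phis:
        for dz in dz_grid:
            c = _nn_cost(_apply(a, phi, dz), b, tree_b)
            if c < best[0]:
                best = (c, phi, dz)
    res = minimize(
        lambda p: _nn_cost(_apply(a, p[0], p[1]), b, tree_b),
        x0=[best[1], best[2]],
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-12},
    )
    phi, dz = float(res.x[0]), float(res.x[1])
    phi = float(np.arctan2(np.sin(phi), np.cos(phi)))  # wrap to (-pi, pi]
    return phi, dz


# -- surface radius maps -------------------------------------------------

@dataclass
class SurfaceRadiusMap:
    """Interpolable inner/outer radius and thickness maps on a (Theta, Z) grid."""

    thetas: np.ndarray   # (n_t,) sorted in [-pi, pi)
    zs: np.ndarray       # (n_z,)
    r_in: np.ndarray     # (n_t, n_z) mm
    r_out: np.ndarray    # (n_t, n_z) mm
    thickness: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.thickness = self.r_out - self.r_in

    def _interp(self, values: np.ndarray, theta, z) -> np.ndarray:
        idx, w = periodic_bilinear_weights(theta, z, self.thetas, self.zs)
        flat = values.reshape(-1)
        return (flat[idx] * w).sum(axis=-1)

    def eval_r_in(self, theta, z) -> np.ndarray:
        return self._interp(self.r_in, theta, z)

    def eval_r_out(self, theta, z) -> np.ndarray:
        return self._interp(self.r_out, theta, z)

    def eval_thickness(self, theta, z) -> np.ndarray:
        return self._interp(self.thickness, theta, z)


def periodic_bilinear_weights(theta, z, thetas: np.ndarray, zs: np.ndarray):
    """Bilinear interpolation weights on a grid periodic in theta.

    Returns ``(idx, w)`` where ``idx`` has shape (..., 4) of flat indices
    into an array of shape ``(len(thetas), len(zs))`` and ``w`` the
    matching nonnegative weights summing to 1.  Queries with z outside
    the grid raise.
    """
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    z = np.atleast_1d(np.asarray(z, dtype=float))
    n_t, n_z = len(thetas), len(zs)
    if np.any(z < zs[0] - 1e-9) or np.any(z > zs[-1] + 1e-9):
        raise ValueError("query z outside the axial extent of the grid")
    z = np.clip(z, zs[0], zs[-1])
    # angular cell (uniform spacing assumed, periodic wrap across the seam)
    dt = 2 * np.pi / n_t
    t = np.mod(theta - thetas[0], 2 * np.pi)
    it = np.floor(t / dt).astype(int) % n_t
    ft = t / dt - np.floor(t / dt)
    it1 = (it + 1) % n_t
    # axial cell
    iz = np.clip(np.searchsorted(zs, z, side="right") - 1, 0, n_z - 2)
    fz = (z - zs[iz]) / (zs[iz + 1] - zs[iz])
    idx = np.stack(
        [it * n_z + iz, it1 * n_z + iz, it * n_z + iz + 1, it1 * n_z + iz + 1],
        axis=-1,
    )
    w = np.stack(
        [(1 - ft) * (1 - fz), ft * (1 - fz), (1 - ft) * fz, ft * fz], axis=-1
    )
    return idx, w


def _ray_surface_radius(
    origin_z: np.ndarray, theta: np.ndarray, nodes: np.ndarray, facets: np.ndarray
) -> np.ndarray:
    """Radius where rays from the axis hit a triangulated surface.

    Rays start at (0, 0, z) with direction (cos t, sin t, 0).  Returns NaN
    where a ray misses the surface (Moller-Trumbore, vectorized over facets).
    """
    v0 = nodes[facets[:, 0]]
    e1 = nodes[facets[:, 1]] - v0
    e2 = nodes[facets[:, 2]] - v0
    out = np.full(len(theta), np.nan)
    for i, (t, zq) in enumerate(zip(theta, origin_z)):
        d = np.array([np.cos(t), np.sin(t), 0.0])
        o = np.array([0.0, 0.0, zq])
        p = np.cross(d, e2)
        det = np.einsum("ij,ij->i", e1, p)
        ok = np.abs(det) > 1e-14
        inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        s = o - v0
        u = np.einsum("ij,ij->i", s, p) * inv
        q = np.cross(s, e1)
        v = (q @ d) * inv
        r = np.einsum("ij,ij->i", e2, q) * inv
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (r > 1e-9)
        if np.any(hit):
            out[i] = r[hit].min()
    return out


def surface_radius_maps(
    mesh: VesselMesh, thetas: np.ndarray, zs: np.ndarray
) -> SurfaceRadiusMap:
    """Build R_in / R_out / thickness maps by ray casting from the axis.

    Rays that miss a surface (e.g. at a jagged mesh border) are filled by
    interpolation from angular neighbours with a warning.
    """
    tg, zg = np.meshgrid(thetas, zs, indexing="ij")
    t_flat, z_flat = tg.ravel(), zg.ravel()
    r_in = _ray_surface_radius(z_flat, t_flat, mesh.nodes, mesh.inner_facets)
    r_out = _ray_surface_radius(z_flat, t_flat, mesh.nodes, mesh.outer_facets)
    shape = (len(thetas), len(zs))
    r_in, r_out = r_in.reshape(shape), r_out.reshape(shape)
    for name, arr in (("R_in", r_in), ("R_out", r_out)):
        nan = np.isnan(arr)
        if nan.any():
            warnings.warn(
                f"{int(nan.sum())} {name} samples missed the surface; "
                "interpolated from angular neighbours",
                stacklevel=2,
            )
            for j in range(shape[1]):
                col = arr[:, j]
                miss = np.isnan(col)
                if miss.all():
                    raise ValueError(f"no {name} ray hits at z index {j}")
                if miss.any():
                    good = np.flatnonzero(~miss)
                    col[miss] = np.interp(
                        np.flatnonzero(miss), good, col[good], period=shape[0]
                    )
    return SurfaceRadiusMap(thetas=np.asarray(thetas, float), zs=np.asarray(zs, float),
                            r_in=r_in, r_out=r_out)
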