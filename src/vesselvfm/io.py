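"""File formats and run configuration.

All artifacts are plain text: meshes as legacy ASCII VTK unstructured grids
(tet cells plus an integer cell-data array ``region``: 0 = wall,
1 = thrombus; boundary triangulations as separate triangle VTK files),
displacement grids and tables as tab-separated values with headers, the load
schedule as CSV, and run configuration as YAML validated against a strict
schema (unknown keys rejected).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from .constitutive import LINEAR_NAMES, NONLINEAR_NAMES, MaterialField, SectorParameters
from .geometry import SectorPartition, VesselMesh
from .kinematics import (
    LoadSchedule,
    LoadState,
    SurfaceDisplacementField,
    VolumeDisplacementField,
)

__all__ = [
    "RunConfig",
    "write_mesh_vtk",
    "read_mesh_vtk",
    "write_surface_grid",
    "read_surface_grid",
    "write_volume_grid",
    "read_volume_grid",
    "write_schedule",
    "read_schedule",
    "write_parameter_table",
    "read_parameter_table",
]


class GASettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    population: int = 60
    generations: int = 120
    tournament: int = 3
    crossover_rate: float = 0.9
    mutation_rate: float = 0.25
    mutation_sd_frac: float = 0.05
    mutation_sd_decay: float = 0.985
    elitism: int = 2


class RunConfig(BaseModel):
    """Schema-validated run configuration (YAML round-trippable)."""

    model_config = ConfigDict(extra="forbid")

    n_theta: int = 2
    n_z: int = 2
    seed: int = 0
    G_a: float = 1.25
    kernel_mode: str = "printed"
    pressure_surface: str = "inner"
    r_min: float = 0.05
    bounds: dict[str, tuple[float, float]] | None = None
    fixed: dict[str, float] = {}
    ga: GASettings = GASettings()
    units: dict[str, str] = {
        "length": "mm", "displacement": "um", "pressure": "mmHg",
        "force": "mN", "modulus": "kPa",
    }

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=False)

    def identification_config(self):
        from .vfm import IdentificationConfig
        from .constitutive import DEFAULT_BOUNDS

        bounds = dict(DEFAULT_BOUNDS)
        if self.bounds:
            bounds.update({k: tuple(v) for k, v in self.bounds.items()})
        return IdentificationConfig(
            n_theta=self.n_theta, n_z=self.n_z, bounds=bounds,
            fixed=dict(self.fixed), G_a=self.G_a,
            kernel_mode=self.kernel_mode, r_min=self.r_min,
            pressure_surface=self.pressure_surface,
            population=self.ga.population, generations=self.ga.generations,
            tournament=self.ga.tournament, crossover_rate=self.ga.crossover_rate,
            mutation_rate=self.ga.mutation_rate,
            mutation_sd_frac=self.ga.mutation_sd_frac,
            mutation_sd_decay=self.ga.mutation_sd_decay, elitism=self.ga.elitism,
        )


# -- legacy ASCII VTK ----------------------------------------------------

def _write_vtk(path, points, cells, cell_type, cell_data=None):
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 2.0\nvesselvfm mesh\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(points)} double\n")
        for p in points:
            fh.write(f"{p[0]:.12g} {p[1]:.12g} {p[2]:.12g}\n")
        k = cells.shape[1]
        fh.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        for c in cells:
            fh.write(f"{k} " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join([str(cell_type)] * len(cells)) + "\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                arr = np.asarray(arr)
                if np.issubdtype(arr.dtype, np.integer):
                    fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(map(str, arr)) + "\n")
                else:
                    fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    fh.write("\n".join(f"{v:.10g}" for v in arr) + "\n")


def _read_vtk(path):
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    points = cells = None
    cell_data = {}
    n_cells = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("POINTS"):
            n = int(ln.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals += lines[i].split()
                i += 1
            points = np.array(vals, dtype=float).reshape(n, 3)
            continue
        if ln.startswith("CELLS"):
            n_cells = int(ln.split()[1])
            rows = []
            i += 1
            for _ in range(n_cells):
                parts = lines[i].split()
                rows.append([int(x) for x in parts[1:]])
                i += 1
            cells = np.array(rows, dtype=int)
            continue
        if ln.startswith("SCALARS"):
            parts = ln.split()
            name, dtype = parts[1], parts[2]
            i += 2  # skip LOOKUP_TABLE
            vals = []
            while len(vals) < n_cells:
                vals += lines[i].split()
                i += 1
            cell_data[name] = np.array(
                vals, dtype=int if dtype == "int" else float)
            continue
        i += 1
    return points, cells, cell_data


def write_mesh_vtk(mesh: VesselMesh, path) -> None:
    """Write the tet mesh (+ region cell data) and boundary triangle files.

    ``path`` is the main .vtk file; ``<stem>_inner.vtk`` and
    ``<stem>_outer.vtk`` hold the boundary triangulations.
    """
    path = Path(path)
    _write_vtk(path, mesh.nodes, mesh.tets, 10, {"region": mesh.region})
    _write_vtk(path.with_name(path.stem + "_inner.vtk"), mesh.nodes,
               mesh.inner_facets, 5)
    _write_vtk(path.with_name(path.stem + "_outer.vtk"), mesh.nodes,
               mesh.outer_facets, 5)


def write_metric_maps_vtk(mesh: VesselMesh, maps: dict, path) -> None:
    """Write per-tet metric maps as cell-data arrays on the tet mesh."""
    data = {"region": mesh.region}
    data.update(maps)
    _write_vtk(Path(path), mesh.nodes, mesh.tets, 10, data)


def read_mesh_vtk(path) -> VesselMesh:
    path = Path(path)
    points, tets, cdata = _read_vtk(path)
    if "region" not in cdata:
        raise ValueError(f"{path}: missing 'region' cell-data array")
    _, inner, _ = _read_vtk(path.with_name(path.stem + "_inner.vtk"))
    _, outer, _ = _read_vtk(path.with_name(path.stem + "_outer.vtk"))
    mesh = VesselMesh(nodes=points, tets=tets, region=cdata["region"],
                      inner_facets=inner, outer_facets=outer)
    mesh.validate()
    return mesh


# -- displacement grids --------------------------------------------------

def write_surface_grid(field: SurfaceDisplacementField, path) -> None:
    n_t, n_z = len(field.thetas), len(field.zs)
    S = len(field.disp_um)
    it, iz = np.unravel_index(np.arange(n_t * n_z), (n_t, n_z))
    df = pd.DataFrame({
        "node": np.arange(n_t * n_z),
        "theta": field.thetas[it],
        "z": field.zs[iz],
    })
    for s in range(S):
        for c, name in enumerate("uvw"):
            df[f"{name}{s + 1}"] = field.disp_um[s].reshape(-1, 3)[:, c]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_surface_grid(path) -> SurfaceDisplacementField:
    df = pd.read_csv(path, sep="\t")
    thetas = np.unique(df["theta"])
    zs = np.unique(df["z"])
    n_t, n_z = len(thetas), len(zs)
    S = sum(1 for c in df.columns if c.startswith("u") and c[1:].isdigit())
    disp = np.empty((S, n_t, n_z, 3))
    for s in range(S):
        for c, name in enumerate("uvw"):
            disp[s, :, :, c] = df[f"{name}{s + 1}"].to_numpy().reshape(n_t, n_z)
    return SurfaceDisplacementField(thetas=thetas, zs=zs, disp_um=disp)


def write_volume_grid(field: VolumeDisplacementField, path) -> None:
    df = pd.DataFrame({
        "point": np.arange(len(field.points_mm)),
        "x": field.points_mm[:, 0], "y": field.points_mm[:, 1],
        "z": field.points_mm[:, 2],
        "mask": field.mask.astype(int),
    })
    for s in range(len(field.uv_um)):
        df[f"u{s + 1}"] = field.uv_um[s, :, 0]
        df[f"v{s + 1}"] = field.uv_um[s, :, 1]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_volume_grid(path) -> VolumeDisplacementField:
    df = pd.read_csv(path, sep="\t")
    pts = df[["x", "y", "z"]].to_numpy()
    mask = df["mask"].to_numpy().astype(bool)
    S = sum(1 for c in df.columns if c.startswith("u") and c[1:].isdigit())
    uv = np.empty((S, len(pts), 2))
    for s in range(S):
        uv[s, :, 0] = df[f"u{s + 1}"]
        uv[s, :, 1] = df[f"v{s + 1}"]
    return VolumeDisplacementField(points_mm=pts, uv_um=uv, mask=mask)


# -- schedule and parameter tables --------------------------------------

def write_schedule(schedule: LoadSchedule, path) -> None:
    df = pd.DataFrame([{
        "index": s.index, "pressure_mmhg": s.pressure_mmhg,
        "axial_stretch": s.axial_stretch, "axial_force_mn": s.axial_force_mn,
    } for s in schedule.states])
    with open(path, "w") as fh:
        fh.write(f"# lam_iv={schedule.lam_iv} "
                 f"reference_pressure_mmhg={schedule.reference_pressure_mmhg}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def read_schedule(path) -> LoadSchedule:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh)
    states = [LoadState(index=int(r["index"]),
                        pressure_mmhg=float(r["pressure_mmhg"]),
                        axial_stretch=float(r["axial_stretch"]),
                        axial_force_mn=float(r["axial_force_mn"]))
              for _, r in df.iterrows()]
    return LoadSchedule(states=states, lam_iv=float(meta["lam_iv"]),
                        reference_pressure_mmhg=float(
                            meta["reference_pressure_mmhg"]))


def write_parameter_table(field: MaterialField, path) -> None:
    part = field.partition
    rows = []
    for s, p in enumerate(field.sectors):
        it, iz = divmod(s, part.n_z)
        row = {"i_theta": it, "i_z": iz}
        row.update({n: getattr(p, n) for n in LINEAR_NAMES + NONLINEAR_NAMES})
        rows.append(row)
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# n_theta={part.n_theta} n_z={part.n_z} G_a={field.G_a} "
                 f"theta0={part.theta_edges[0]} z0={part.z_edges[0]} "
                 f"z1={part.z_edges[-1]}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_parameter_table(path) -> MaterialField:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        df = pd.read_csv(fh)
    n_theta, n_z = int(meta["n_theta"]), int(meta["n_z"])
    part = SectorPartition(
        n_theta=n_theta, n_z=n_z,
        theta_edges=np.linspace(-np.pi, np.pi, n_theta + 1),
        z_edges=np.linspace(float(meta["z0"]), float(meta["z1"]), n_z + 1),
        sector_of_tet=np.empty((0, 2), dtype=int))
    sectors = [SectorParameters(**{
        n: float(r[n]) for n in LINEAR_NAMES + NONLINEAR_NAMES})
        for _, r in df.sort_values(["i_theta", "i_z"]).iterrows()]
    return MaterialField(part, sectors, G_a=float(meta["G_a"]))
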