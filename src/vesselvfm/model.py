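"""Model/Results front-end for the inverse characterization.

``VesselVFMModel`` bundles the measured inputs (mesh, surface and volume
displacement grids, load schedule) the way a statsmodels model bundles
endog/exog; ``fit`` runs displacement fusion, deformation-gradient
reconstruction and the hybrid genetic/linear virtual-fields identification,
returning a ``VFMResults`` object that carries the sector-wise parameter
estimates, fit diagnostics, a ``summary()`` table and the derived metric
maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import io as vio
from .constitutive import MaterialField, metric_maps
from .geometry import (
    LocalBasisField,
    SectorPartition,
    SurfaceRadiusMap,
    VesselMesh,
    build_local_basis,
    build_sector_partition,
    solve_radial_scalar,
    surface_radius_maps,
)
from .kinematics import (
    LoadSchedule,
    SurfaceDisplacementField,
    VolumeDisplacementField,
    build_fused_model,
    deformation_gradient_field,
)
from .vfm import IdentificationConfig, IdentificationResult, VFMContext, identify

__all__ = ["VesselVFMModel", "VFMResults"]


class VesselVFMModel:
    """Inverse material-characterization model for one vessel specimen.

    Parameters
    ----------
    mesh : VesselMesh
        Reference-configuration tetrahedral domain with region labels.
    surface : SurfaceDisplacementField
        Outer-surface displacement grid (all load states).
    volume : VolumeDisplacementField
        Volumetric in-plane displacement lattice (all load states).
    schedule : LoadSchedule
        Pressures, axial stretches and axial forces per state.
    config : IdentificationConfig, optional
        Partition size, parameter bounds and optimizer settings.
    """

    def __init__(
        self,
        mesh: VesselMesh,
        surface: SurfaceDisplacementField,
        volume: VolumeDisplacementField,
        schedule: LoadSchedule,
        config: IdentificationConfig | None = None,
    ):
        mesh.validate()
        self.mesh = mesh
        self.surface = surface
        self.volume = volume
        self.schedule = schedule
        self.config = config or IdentificationConfig()
        # geometric preprocessing (cheap, deterministic)
        self.partition: SectorPartition = build_sector_partition(
            mesh, self.config.n_theta, self.config.n_z)
        self.xi = solve_radial_scalar(mesh)
        self.basis: LocalBasisField = build_local_basis(mesh, self.xi)
        self.radii: SurfaceRadiusMap = surface_radius_maps(
            mesh, surface.thetas, surface.zs)
        self._fused = None

    @classmethod
    def from_directory(cls, path, config: IdentificationConfig | None = None):
        """Load mesh/grids/schedule written by the package's own writers."""
        from pathlib import Path

        p = Path(path)
        return cls(
            mesh=vio.read_mesh_vtk(p / "mesh.vtk"),
            surface=vio.read_surface_grid(p / "surface.tsv"),
            volume=vio.read_volume_grid(p / "volume.tsv"),
            schedule=vio.read_schedule(p / "schedule.csv"),
            config=config,
        )

    @property
    def fused(self):
        if self._fused is None:
            self._fused = build_fused_model(self.surface, self.volume, self.radii)
        return self._fused

    def deformation_states(self):
        return [
            deformation_gradient_field(self.fused, self.mesh, s,
                                       self.basis.e_c, self.basis.e_o)
            for s in range(self.fused.n_states)
        ]

    def fit(self, seed: int = 0) -> "VFMResults":
        """Run the full identification and wrap the outcome."""
        def_states = self.deformation_states()
        node_disp = np.stack([
            self.fused.evaluate(self.mesh.nodes, s)
            for s in range(self.fused.n_states)
        ])
        result = identify(self.mesh, self.partition, self.basis, def_states,
                          self.schedule, node_disp, self.config, seed=seed)
        return VFMResults(model=self, result=result, def_states=def_states)


@dataclass
class VFMResults:
    """Estimates, diagnostics and derived maps of a fitted model."""

    model: VesselVFMModel
    result: IdentificationResult
    def_states: list

    @property
    def material_field(self) -> MaterialField:
        return self.result.material_field

    @property
    def params(self):
        """Sector-wise parameter table (DataFrame)."""
        return self.result.summary_frame()

    def _state_index(self, pressure_mmhg: float) -> int:
        for i, s in enumerate(self.model.schedule.states):
            if (abs(s.pressure_mmhg - pressure_mmhg) < 1e-9
                    and abs(s.axial_stretch - 1.0) < 1e-9):
                return i
        raise KeyError(f"no state at {pressure_mmhg} mmHg, lambda_iv")

    def metric_maps(self, stress_pressure: float = 140.0,
                    energy_pressure: float = 80.0) -> dict[str, np.ndarray]:
        """Per-tet stretch/stress/stiffness maps at ``stress_pressure`` and
        stored energy at ``energy_pressure`` (both at the in vivo stretch)."""
        i_s = self._state_index(stress_pressure)
        i_e = self._state_index(energy_pressure)
        F_by_state = {i_s: self.def_states[i_s].F, i_e: self.def_states[i_e].F}
        xi_tet = self.model.xi[self.model.mesh.tets].mean(axis=1)
        return metric_maps(
            F_by_state, self.material_field, self.model.mesh.region,
            self.model.basis, i_s, i_e,
            pressure_kpa=self.model.schedule.states[i_s].pressure_kpa,
            xi_tet=xi_tet)

    def surface_raster(self, values: np.ndarray, n_theta: int = 36,
                       n_z: int = 20) -> np.ndarray:
        """Through-wall mean of a per-tet scalar on a (theta, z) raster."""
        cent = self.model.mesh.tet_centroids()
        th = np.arctan2(cent[:, 1], cent[:, 0])
        z_lo, z_hi = self.model.mesh.z_bounds
        it = np.floor((th + np.pi) / (2 * np.pi / n_theta)).astype(int) % n_theta
        iz = np.clip(np.floor((cent[:, 2] - z_lo) / ((z_hi - z_lo) / n_z))
                     .astype(int), 0, n_z - 1)
        num = np.zeros((n_theta, n_z))
        den = np.zeros((n_theta, n_z))
        np.add.at(num, (it, iz), values)
        np.add.at(den, (it, iz), 1.0)
        with np.errstate(invalid="ignore"):
            return num / den

    def plot_metric(self, name: str = "circ_stiffness_mpa", ax=None, **kwargs):
        """Raster plot of one derived metric over (theta, z)."""
        import matplotlib.pyplot as plt

        maps = self.metric_maps()
        raster = self.surface_raster(maps[name])
        if ax is None:
            _, ax = plt.subplots()
        z_lo, z_hi = self.model.mesh.z_bounds
        im = ax.imshow(raster.T, origin="lower", aspect="auto",
                       extent=[-180, 180, z_lo, z_hi], **kwargs)
        ax.set_xlabel("circumferential position (deg)")
        ax.set_ylabel("axial position (mm)")
        ax.set_title(name)
        plt.colorbar(im, ax=ax)
        return ax

    def summary(self) -> str:
        """Human-readable fit report."""
        r = self.result
        part = self.material_field.partition
        lines = [
            "Virtual Fields Identification Results",
            "=" * 54,
            f"sectors:              {part.n_theta} x {part.n_z}",
            f"load states:          {self.model.schedule.n_states}",
            f"linear unknowns:      {len(r.c_vector)}",
            f"cost H:               {r.cost:.6g}",
            f"relative residual:    {r.residual_rel:.3e}",
            f"system rank:          {r.rank}",
            "",
            r.summary_frame().to_string(index=False,
                                        float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def save(self, path) -> None:
        vio.write_parameter_table(self.material_field, path)
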