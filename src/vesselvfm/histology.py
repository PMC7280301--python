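"""Histology partitioning, thickness registration and correlation statistics.

Stained cross-sections (pentachrome-type: fibrin red, collagen yellow-grey,
elastin black) are classified pixel-wise into constituent classes, divided
into a polar partition (25 circumferential x 5 radial by default) of area
fractions, and registered to the mechanical reconstruction by matching the
normalized angular thickness profile of the section against the mesh-derived
thickness map.  Structure-property relations are then quantified with
Pearson and Spearman correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import pearsonr, spearmanr
from skimage.color import rgb2lab

from .geometry import SurfaceRadiusMap

__all__ = [
    "CLASS_NAMES",
    "DEFAULT_PALETTE",
    "HistologyClassMap",
    "PartitionedFractions",
    "ThicknessProfile",
    "classify_colors",
    "partition_fractions",
    "thickness_profile",
    "register_section",
    "correlate",
]

#: Fixed class vocabulary; index order also encodes the tie-break priority
#: (fibrin > collagen > elastin > other) after the two non-tissue classes.
CLASS_NAMES = ("background", "lumen", "fibrin", "collagen", "elastin", "other")

#: Reference RGB colors (0-255) emulating a pentachrome-type stain.  These
#: are stand-ins for instrument-specific calibration values.
DEFAULT_PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (255, 255, 255),
    "lumen": (235, 235, 235),
    "fibrin": (200, 60, 80),
    "collagen": (200, 170, 90),
    "elastin": (30, 30, 30),
    "other": (160, 120, 160),
}

TISSUE_CLASSES = ("fibrin", "collagen", "elastin", "other")


@dataclass
class HistologyClassMap:
    """Per-pixel constituent labels of one stained cross-section."""

    labels: np.ndarray          # (H, W) int, indices into CLASS_NAMES
    pixel_size_um: float = 2.0
    section_id: str = "S1"

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == CLASS_NAMES.index(name)

    @property
    def tissue_mask(self) -> np.ndarray:
        return ~(self.class_mask("background") | self.class_mask("lumen"))

    def centroid(self) -> np.ndarray:
        """Tissue centroid in pixel coordinates (row, col)."""
        rows, cols = np.nonzero(self.tissue_mask)
        if len(rows) == 0:
            raise ValueError("empty tissue mask")
        return np.array([rows.mean(), cols.mean()])


@dataclass
class PartitionedFractions:
    """Constituent area fractions on the polar partition of a section."""

    fractions: np.ndarray       # (n_circ, n_rad, len(TISSUE_CLASSES))
    pixel_counts: np.ndarray    # (n_circ, n_rad)
    class_names: tuple = TISSUE_CLASSES

    @property
    def n_partitions(self) -> int:
        return self.fractions.shape[0] * self.fractions.shape[1]

    def fraction_of(self, name: str) -> np.ndarray:
        return self.fractions[..., self.class_names.index(name)]


@dataclass
class ThicknessProfile:
    """Angular wall-thickness profile of a histology section (um)."""

    thetas: np.ndarray          # (n,) in [-pi, pi)
    thickness_um: np.ndarray    # (n,)
    registered_offset: tuple[float, float] | None = None

    @property
    def relative(self) -> np.ndarray:
        m = self.thickness_um.max()
        return self.thickness_um / m if m > 0 else self.thickness_um


def classify_colors(
    rgb: np.ndarray,
    palette: dict[str, tuple] | None = None,
    pixel_size_um: float = 2.0,
    section_id: str = "S1",
) -> HistologyClassMap:
    """Nearest-reference-color classification in CIELAB space.

    Ties are broken deterministically by the class priority order
    fibrin > collagen > elastin > other (background/lumen first only when
    strictly closest).
    """
    palette = palette or DEFAULT_PALETTE
    rgb = np.asarray(rgb)
    if rgb.dtype != np.uint8:
        rgb = np.clip(rgb, 0, 255).astype(np.uint8)
    lab = rgb2lab(rgb / 255.0)
    priority = ("fibrin", "collagen", "elastin", "other", "background", "lumen")
    refs = np.array([palette[n] for n in priority], dtype=float) / 255.0
    ref_lab = rgb2lab(refs.reshape(1, -1, 3)).reshape(-1, 3)
    d2 = ((lab[..., None, :] - ref_lab) ** 2).sum(axis=-1)
    # argmin returns the first (= highest priority) class on exact ties
    best = np.argmin(d2, axis=-1)
    labels = np.empty(best.shape, dtype=int)
    for i, name in enumerate(priority):
        labels[best == i] = CLASS_NAMES.index(name)
    return HistologyClassMap(labels=labels, pixel_size_um=pixel_size_um,
                             section_id=section_id)


def _polar_coords(map_: HistologyClassMap):
    c = map_.centroid()
    rows, cols = np.indices(map_.labels.shape)
    dy, dx = rows - c[0], cols - c[1]
    return np.hypot(dx, dy), np.arctan2(dy, dx)


def partition_fractions(
    map_: HistologyClassMap, n_circ: int = 25, n_rad: int = 5
) -> PartitionedFractions:
    """Polar partition of constituent area fractions around the centroid.

    Radial bins are taken between the per-ray inner and outer tissue
    boundaries so the partition tiles the annular tissue mask; the "other"
    class absorbs the remainder, making fractions sum to 1 per partition.
    """
    r, th = _polar_coords(map_)
    tissue = map_.tissue_mask
    it = np.floor((th + np.pi) / (2 * np.pi / n_circ)).astype(int) % n_circ
    # per-sector radial boundaries of the tissue annulus
    fractions = np.zeros((n_circ, n_rad, len(TISSUE_CLASSES)))
    counts = np.zeros((n_circ, n_rad), dtype=int)
    class_idx = {n: CLASS_NAMES.index(n) for n in TISSUE_CLASSES}
    for s in range(n_circ):
        sel = tissue & (it == s)
        if not sel.any():
            continue
        r_lo, r_hi = r[sel].min(), r[sel].max()
        edges = np.linspace(r_lo, r_hi + 1e-9, n_rad + 1)
        ir = np.clip(np.searchsorted(edges, r[sel], side="right") - 1, 0, n_rad - 1)
        lab = map_.labels[sel]
        for j in range(n_rad):
            m = ir == j
            n = int(m.sum())
            counts[s, j] = n
            if n:
                for k, name in enumerate(TISSUE_CLASSES):
                    fractions[s, j, k] = np.mean(lab[m] == class_idx[name])
    if (counts == 0).any():
        warnings.warn(
            f"{int((counts == 0).sum())} empty partitions (rays with no tissue)",
            stacklevel=2)
    return PartitionedFractions(fractions=fractions, pixel_counts=counts)


def thickness_profile(
    map_: HistologyClassMap, n_theta: int = 360, smooth_window: int = 5
) -> ThicknessProfile:
    """Per-angle tissue thickness from rays cast from the section centroid.

    Thickness is the outer minus inner tissue boundary radius along each
    ray, smoothed by a periodic moving average.
    """
    r, th = _polar_coords(map_)
    tissue = map_.tissue_mask
    it = np.floor((th + np.pi) / (2 * np.pi / n_theta)).astype(int) % n_theta
    thick = np.zeros(n_theta)
    for s in range(n_theta):
        sel = tissue & (it == s)
        if sel.any():
            thick[s] = r[sel].max() - r[sel].min()
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        thick = np.convolve(np.r_[thick[-(smooth_window - 1):], thick],
                            k, mode="valid")
    thetas = -np.pi + (np.arange(n_theta) + 0.5) * 2 * np.pi / n_theta
    return ThicknessProfile(thetas=thetas,
                            thickness_um=thick * map_.pixel_size_um)


def _registration_cost(
    profile: ThicknessProfile, mesh_thickness: SurfaceRadiusMap,
    theta: float, z: float,
) -> float:
    """Squared difference of normalized thickness profiles, integrated in angle."""
    t_mesh_max = mesh_thickness.thickness.max()
    sample_th = profile.thetas
    t_mesh = mesh_thickness.eval_thickness(
        np.arctan2(np.sin(sample_th + theta), np.cos(sample_th + theta)),
        np.full_like(sample_th, z))
    diff = profile.relative - t_mesh / t_mesh_max
    return float(np.trapezoid(diff**2, sample_th))


def register_section(
    profile: ThicknessProfile,
    mesh_thickness: SurfaceRadiusMap,
    z_step_mm: float = 0.07,
    theta_step_deg: float = 1.0,
) -> tuple[float, float, float]:
    """Register a histology thickness profile to the mesh thickness map.

    Minimizes the normalized-thickness mismatch over a rotation theta and an
    axial position z: coarse grid scan (1 degree x slice spacing) followed by
    Nelder-Mead refinement.  Returns (theta*, z*, C*).  A nearly flat cost
    landscape (axisymmetric thickness) returns the grid best with a warning.
    """
    zs = np.arange(mesh_thickness.zs[0], mesh_thickness.zs[-1] + 1e-9, z_step_mm)
    thetas = np.deg2rad(np.arange(-180.0, 180.0, theta_step_deg))
    best = (np.inf, 0.0, float(zs[0]))
    costs = []
    for z in zs:
        for t in thetas:
            c = _registration_cost(profile, mesh_thickness, t, z)
            costs.append(c)
            if c < best[0]:
                best = (c, t, z)
    costs = np.asarray(costs)
    if np.ptp(costs) < 1e-12 * max(costs.max(), 1.0):
        warnings.warn("flat registration cost landscape (axisymmetric "
                      "thickness); returning grid best", stacklevel=2)
        return best[1], best[2], best[0]
    res = minimize(
        lambda p: _registration_cost(
            profile, mesh_thickness, p[0],
            float(np.clip(p[1], mesh_thickness.zs[0], mesh_thickness.zs[-1]))),
        x0=[best[1], best[2]], method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-12})
    theta = float(np.arctan2(np.sin(res.x[0]), np.cos(res.x[0])))
    z = float(np.clip(res.x[1], mesh_thickness.zs[0], mesh_thickness.zs[-1]))
    return theta, z, float(res.fun)


@dataclass
class CorrelationReport:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    significant: bool = field(init=False)

    def __post_init__(self) -> None:
        self.significant = bool(self.pearson_p < 0.05)


def correlate(properties: np.ndarray, fractions: np.ndarray) -> CorrelationReport:
    """Pearson and Spearman correlation between paired vectors.

    Two-sided p-values; significance threshold P < 0.05.  Raises for fewer
    than 3 pairs or zero variance (undefined correlation).
    """
    x = np.asarray(properties, dtype=float).ravel()
    y = np.asarray(fractions, dtype=float).ravel()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    pr = pearsonr(x, y)
    sr = spearmanr(x, y)
    return CorrelationReport(
        pearson_r=float(pr.statistic), pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic), spearman_p=float(sr.pvalue),
        n=len(x))


def synthetic_section(
    r_in_px: float = 80.0,
    r_out_px: float = 130.0,
    size: int = 300,
    offset_px: tuple[float, float] = (0.0, 0.0),
    angular_classes: list[tuple[float, float, str]] | None = None,
    pixel_size_um: float = 4.0,
    rgb_noise_sd: float = 0.0,
    seed: int = 0,
    palette: dict | None = None,
) -> np.ndarray:
    """Paint a synthetic stained annulus (RGB image) for tests and demos.

    The annulus is centred in the image, optionally offset (eccentric), and
    painted per angular span with the palette color of the named class;
    unspecified angles default to collagen.  Gaussian RGB noise emulates
    staining variability.
    """
    palette = palette or DEFAULT_PALETTE
    rng = np.random.default_rng(seed)
    yy, xx = np.indices((size, size))
    cy, cx = size / 2 + offset_px[0], size / 2 + offset_px[1]
    rr = np.hypot(xx - size / 2, yy - size / 2)
    rr_in = np.hypot(xx - cx, yy - cy)
    th = np.arctan2(yy - size / 2, xx - size / 2)
    img = np.full((size, size, 3), palette["background"], dtype=float)
    img[rr_in < r_in_px] = palette["lumen"]
    ring = (rr_in >= r_in_px) & (rr <= r_out_px)
    img[ring] = palette["collagen"]
    for lo, hi, name in angular_classes or []:
        sel = ring & (th >= lo) & (th < hi)
        img[sel] = palette[name]
    if rgb_noise_sd > 0:
        img = img + rng.normal(0, rgb_noise_sd, img.shape)
    return np.clip(img, 0, 255).astype(np.uint8)
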