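"""Displacement fusion, fused-model evaluation and deformation gradients."""

import numpy as np
import pytest

from vesselvfm.kinematics import (
    LoadSchedule,
    LoadState,
    SurfaceDisplacementField,
    VolumeDisplacementField,
    accumulate_increments,
    build_fused_model,
    deformation_gradient_field,
    fit_axial_beam,
    fit_inner_displacement,
    interp_weights_zeta,
)

from conftest import small_scenario


# -- interpolation weights ----------------------------------------------

def test_zeta_weights_grid_node_and_partition_of_unity(rng):
    thetas = np.linspace(-np.pi, np.pi, 10, endpoint=False)
    zs = np.linspace(0.0, 4.0, 7)
    # exactly on a grid node -> weight 1 there
    idx, w = interp_weights_zeta(thetas[3], zs[2], thetas, zs)
    k = np.argmax(w[0])
    assert w[0, k] == pytest.approx(1.0, abs=1e-12)
    assert idx[0, k] == 3 * 7 + 2
    # interior queries: nonnegative, sum to 1
    q_t = rng.uniform(-np.pi, np.pi, 100)
    q_z = rng.uniform(0, 4, 100)
    idx, w = interp_weights_zeta(q_t, q_z, thetas, zs)
    assert np.all(w >= -1e-12)
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


def test_zeta_weights_periodic_seam():
    thetas = np.linspace(-np.pi, np.pi, 10, endpoint=False)
    zs = np.linspace(0.0, 4.0, 5)
    idx, w = interp_weights_zeta(np.pi - 1e-3, 1.9, thetas, zs)
    cols_t = idx[0] // 5
    assert 9 in cols_t and 0 in cols_t  # both seam columns engaged
    assert np.all(w[0] > 0)


def test_zeta_weights_reject_out_of_range_z():
    thetas = np.linspace(-np.pi, np.pi, 6, endpoint=False)
    zs = np.linspace(0.0, 4.0, 5)
    with pytest.raises(ValueError, match="z"):
        interp_weights_zeta(0.0, 5.0, thetas, zs)


def test_zeta_weight_derivatives_match_finite_differences(rng):
    thetas = np.linspace(-np.pi, np.pi, 8, endpoint=False)
    zs = np.linspace(0.0, 3.0, 6)
    vals = rng.normal(size=(8, 6)).ravel()

    def f(t, z):
        idx, w = interp_weights_zeta(t, z, thetas, zs)
        return (vals[idx] * w).sum()

    h = 1e-7
    for t, z in [(0.13, 1.21), (-2.4, 0.77), (3.0, 2.5)]:
        idx, w, dwt, dwz = interp_weights_zeta(t, z, thetas, zs, derivatives=True)
        an_t = (vals[idx] * dwt).sum()
        an_z = (vals[idx] * dwz).sum()
        assert an_t == pytest.approx((f(t + h, z) - f(t - h, z)) / (2 * h), rel=1e-5)
        assert an_z == pytest.approx((f(t, z + h) - f(t, z - h)) / (2 * h), rel=1e-5)


# -- inner-displacement fit ----------------------------------------------

def test_fit_inner_recovers_forward_generated_coefficients(bundle, rng):
    """Volume samples generated exactly from the radial-blend model must
    return the generating inner coefficients to solver tolerance."""
    surf = bundle.surface
    radii = bundle.radii
    n_t, n_z = len(surf.thetas), len(surf.zs)
    model = build_fused_model(surf, bundle.volume, radii)
    u_in_true = rng.normal(0, 0.02, (n_t, n_z, 2))  # mm
    model.u_in[0] = u_in_true
    pts = bundle.volume.points_mm[bundle.volume.mask]
    rr = np.hypot(pts[:, 0], pts[:, 1])
    sc = bundle.scenario
    pts = pts[(rr > sc.r_in + 0.01) & (rr < sc.r_out - 0.01)]  # avoid clamping
    sub = pts[rng.choice(len(pts), 6000, replace=False)]
    uv = model.evaluate(sub, 0)[:, :2]
    vol = VolumeDisplacementField(
        points_mm=sub, uv_um=(uv / 1e-3)[None], mask=np.ones(len(sub), bool))
    surf1 = SurfaceDisplacementField(
        thetas=surf.thetas, zs=surf.zs, disp_um=surf.disp_um[:1])
    u_fit, rms = fit_inner_displacement(surf1, vol, radii, 0, ridge=1e-10)
    assert np.abs(u_fit - u_in_true).max() / np.abs(u_in_true).max() < 1e-6
    assert rms < 1e-3  # um


def test_fit_inner_null_data_gives_zero(bundle):
    surf = bundle.surface
    vol = bundle.volume
    surf0 = SurfaceDisplacementField(surf.thetas, surf.zs,
                                     np.zeros_like(surf.disp_um[:1]))
    vol0 = VolumeDisplacementField(vol.points_mm,
                                   np.zeros_like(vol.uv_um[:1]), vol.mask)
    u_in, rms = fit_inner_displacement(surf0, vol0, bundle.radii, 0)
    np.testing.assert_allclose(u_in, 0.0, atol=1e-12)
    assert rms == pytest.approx(0.0, abs=1e-9)


def test_fit_inner_noise_residual_matches_noise_level(bundle, rng):
    """Gaussian 12 um volume noise must surface as ~12 um fit residual RMS."""
    surf = bundle.surface
    vol = bundle.volume
    noisy = VolumeDisplacementField(
        vol.points_mm,
        vol.uv_um[:1] + rng.normal(0, 12.0, vol.uv_um[:1].shape),
        vol.mask)
    _, rms = fit_inner_displacement(surf, noisy, bundle.radii, 0)
    assert abs(rms - 12.0) / 12.0 < 0.15


def test_fit_inner_requires_volume_support(bundle):
    vol = bundle.volume
    starved = VolumeDisplacementField(vol.points_mm, vol.uv_um,
                                      np.zeros_like(vol.mask))
    with pytest.raises(ValueError, match="valid volume points"):
        fit_inner_displacement(bundle.surface, starved, bundle.radii, 0)


# -- axial beam fit ------------------------------------------------------

def _surface_with_axial(bundle, coeffs):
    """Surface field whose axial component follows given (w_av, Rx, Ry)."""
    surf = bundle.surface
    n_t, n_z = len(surf.thetas), len(surf.zs)
    tg = np.repeat(surf.thetas, n_z)
    zg = np.tile(surf.zs, n_t)
    r = bundle.radii.eval_r_out(tg, zg)
    X, Y = r * np.cos(tg), r * np.sin(tg)
    w = (coeffs[0] + coeffs[1] * X + coeffs[2] * Y) / 1e-3  # mm -> um
    disp = np.zeros((1, n_t, n_z, 3))
    disp[0, :, :, 2] = w.reshape(n_t, n_z)
    return SurfaceDisplacementField(surf.thetas, surf.zs, disp)


def test_axial_beam_exact_linear_model(bundle):
    surf = _surface_with_axial(bundle, (0.1, 0.02, -0.01))
    c = fit_axial_beam(surf, bundle.radii, 0)
    np.testing.assert_allclose(c, np.broadcast_to([0.1, 0.02, -0.01], c.shape),
                               atol=1e-12)


def test_axial_beam_constant_field(bundle):
    surf = _surface_with_axial(bundle, (0.25, 0.0, 0.0))
    c = fit_axial_beam(surf, bundle.radii, 0)
    np.testing.assert_allclose(c[:, 0], 0.25, atol=1e-12)
    np.testing.assert_allclose(c[:, 1:], 0.0, atol=1e-12)


def test_axial_beam_noise_standard_errors(bundle, rng):
    """Coefficient scatter over seeds matches the OLS closed form within 20%."""
    surf0 = _surface_with_axial(bundle, (0.1, 0.02, -0.01))
    n_t, n_z = len(surf0.thetas), len(surf0.zs)
    sd_um = 50.0
    station = n_z // 2
    tg = np.repeat(surf0.thetas, n_z)
    zg = np.tile(surf0.zs, n_t)
    r = bundle.radii.eval_r_out(tg, zg).reshape(n_t, n_z)
    X = np.column_stack([np.ones(n_t),
                         r[:, station] * np.cos(surf0.thetas),
                         r[:, station] * np.sin(surf0.thetas)])
    cov = (sd_um * 1e-3) ** 2 * np.linalg.inv(X.T @ X)
    se_expect = np.sqrt(np.diag(cov))
    draws = []
    for _ in range(200):
        noisy = SurfaceDisplacementField(
            surf0.thetas, surf0.zs,
            surf0.disp_um + rng.normal(0, sd_um, surf0.disp_um.shape))
        draws.append(fit_axial_beam(noisy, bundle.radii, 0)[station])
    se_emp = np.std(np.array(draws), axis=0)
    assert np.all(np.abs(se_emp - se_expect) / se_expect < 0.2)


# -- fused-model evaluation ----------------------------------------------

def test_evaluate_reproduces_surface_values_at_outer_nodes(bundle, fused):
    surf = bundle.surface
    n_z = len(surf.zs)
    s = 2
    for it, iz in [(0, 0), (5, 3), (17, n_z - 1)]:
        t, z = surf.thetas[it], surf.zs[iz]
        r = fused.r_out_nodes[it, iz]
        X = np.array([[r * np.cos(t), r * np.sin(t), z]])
        u = fused.evaluate(X, s)[0]
        np.testing.assert_allclose(u[:2] / 1e-3, surf.disp_um[s, it, iz, :2],
                                   atol=1e-6)


def test_evaluate_midwall_blend_hand_value(bundle, fused):
    """At a node's (theta, z) and the radial midpoint, the transverse value
    is the mean of the inner and outer coefficients."""
    it, iz = 4, 5
    t, z = bundle.surface.thetas[it], bundle.surface.zs[iz]
    r = 0.5 * (fused.r_in_nodes[it, iz] + fused.r_out_nodes[it, iz])
    X = np.array([[r * np.cos(t), r * np.sin(t), z]])
    u = fused.evaluate(X, 1)[0]
    expect = 0.5 * (fused.u_out[1, it, iz] + fused.u_in[1, it, iz])
    np.testing.assert_allclose(u[:2], expect, atol=1e-12)


def test_rigid_translation_reproduced_everywhere(bundle, rng):
    surf = bundle.surface
    vol = bundle.volume
    t_mm = np.array([0.05, -0.03, 0.08])
    disp = np.zeros((1,) + surf.disp_um.shape[1:])
    disp[0, :, :, :] = t_mm / 1e-3
    uv = np.zeros((1,) + vol.uv_um.shape[1:])
    uv[0, :, :] = t_mm[:2] / 1e-3
    model = build_fused_model(
        SurfaceDisplacementField(surf.thetas, surf.zs, disp),
        VolumeDisplacementField(vol.points_mm, uv, vol.mask), bundle.radii)
    pts = bundle.volume.points_mm[bundle.volume.mask][
        rng.choice(bundle.volume.n_valid, 100, replace=False)]
    u = model.evaluate(pts, 0)
    np.testing.assert_allclose(u, np.broadcast_to(t_mm, u.shape), atol=1e-9)
    # rigid motion -> F = I
    ds = deformation_gradient_field(model, bundle.mesh, 0)
    np.testing.assert_allclose(ds.F, np.broadcast_to(np.eye(3), ds.F.shape),
                               atol=1e-8)


def test_gradient_matches_finite_differences(bundle, fused, rng):
    """Analytic chain-rule gradient vs central differences of evaluate."""
    sc = bundle.scenario
    # probe at generic points, away from interpolation-cell boundaries where
    # the piecewise representation legitimately kinks
    n_t, n_z = len(fused.thetas), len(fused.zs)
    it = rng.integers(0, n_t, 20)
    iz = rng.integers(0, n_z - 1, 20)
    th = fused.thetas[it] + (2 * np.pi / n_t) * rng.uniform(0.3, 0.7, 20)
    z = fused.zs[iz] + np.diff(fused.zs)[iz] * rng.uniform(0.3, 0.7, 20)
    R = rng.uniform(sc.r_in + 0.02, sc.r_out - 0.02, 20)
    X = np.column_stack([R * np.cos(th), R * np.sin(th), z])
    s = 3
    grad = fused.gradient(X, s)
    h = 1e-3  # 1 um step
    for ax in range(3):
        dX = np.zeros(3)
        dX[ax] = h
        fd = (fused.evaluate(X + dX, s) - fused.evaluate(X - dX, s)) / (2 * h)
        scale = max(np.abs(grad[:, :, ax]).max(), 1e-6)
        assert np.abs(fd - grad[:, :, ax]).max() / scale < 1e-4


def test_affine_field_reproduced(bundle):
    """An affine displacement encoded in both grids returns F = I + A."""
    A = np.array([[0.004, -0.002, 0.001],
                  [0.003, 0.005, -0.002],
                  [-0.001, 0.002, 0.006]])
    surf = bundle.surface
    vol = bundle.volume
    n_t, n_z = len(surf.thetas), len(surf.zs)
    tg = np.repeat(surf.thetas, n_z)
    zg = np.tile(surf.zs, n_t)
    r = bundle.radii.eval_r_out(tg, zg)
    Xs = np.column_stack([r * np.cos(tg), r * np.sin(tg), zg])
    disp = ((Xs @ A.T) / 1e-3).reshape(n_t, n_z, 3)[None]
    uv = ((vol.points_mm @ A.T)[:, :2] / 1e-3)[None]
    model = build_fused_model(
        SurfaceDisplacementField(surf.thetas, surf.zs, disp),
        VolumeDisplacementField(vol.points_mm, uv, vol.mask), bundle.radii)
    ds = deformation_gradient_field(model, bundle.mesh, 0,
                                    incompressibility="none")
    # the bilinear-in-(theta, z) surface interpolation reproduces an affine
    # field up to its angular discretization error, O(dtheta * |A|)
    np.testing.assert_allclose(ds.F, np.broadcast_to(np.eye(3) + A, ds.F.shape),
                               atol=1e-3)


def test_tube_kinematics_oracle(bundle, fused, basis):
    """Circumferential stretch from the fused model matches r(R)/R within 1%."""
    s = [i for i, st in enumerate(bundle.schedule.states)
         if st.pressure_mmhg == 140 and st.axial_stretch == 1.0][0]
    ds = deformation_gradient_field(fused, bundle.mesh, s, basis.e_c, basis.e_o)
    cent = bundle.mesh.tet_centroids()
    R = np.hypot(cent[:, 0], cent[:, 1])
    lam_true = bundle.forward_states[s].deformed_radius(R) / R
    assert np.abs(ds.lam_theta - lam_true).max() / lam_true.max() < 0.01
    assert np.all(ds.J > 0)
    np.testing.assert_allclose(np.linalg.det(ds.Fbar), 1.0, atol=1e-10)


# -- incremental accumulation --------------------------------------------

def test_accumulate_inverse_composition_cancels():
    inc = lambda x: np.full_like(x, 0.1) * np.array([1.0, -0.5, 0.2])
    inv = lambda x: -inc(x)
    totals = accumulate_increments([inc, inv], reference_index=0)
    X = np.array([[0.5, 0.2, 1.0], [1.0, 0.0, 2.0]])
    np.testing.assert_allclose(totals[2].evaluate(X), 0.0, atol=1e-12)


def test_accumulate_translations_add():
    t1 = np.array([0.1, 0.0, 0.05])
    t2 = np.array([-0.02, 0.03, 0.0])
    totals = accumulate_increments(
        [lambda x: np.broadcast_to(t1, x.shape),
         lambda x: np.broadcast_to(t2, x.shape)], reference_index=0)
    X = np.array([[0.3, 0.4, 1.2]])
    np.testing.assert_allclose(totals[2].evaluate(X), (t1 + t2)[None], atol=1e-12)
    # states before the reference accumulate inverse increments
    totals_r = accumulate_increments(
        [lambda x: np.broadcast_to(t1, x.shape)], reference_index=1)
    np.testing.assert_allclose(totals_r[0].evaluate(X), -t1[None], atol=1e-10)


def test_accumulate_forward_chain_matches_direct_totals(bundle):
    """Composing synthetic tube increments reproduces the direct total field."""
    sc = bundle.scenario
    fstates = bundle.forward_states
    ref = bundle.schedule.reference_index
    chain = fstates[ref:ref + 4]  # reference + three increments upward

    def make_inc(a, b):
        def inc(x):
            X = a.material_coords(x)
            return b.displacement(X) - a.displacement(X)
        return inc

    incs = [make_inc(chain[k], chain[k + 1]) for k in range(3)]
    totals = accumulate_increments(incs, reference_index=0)
    rng = np.random.default_rng(3)
    R = rng.uniform(sc.r_in + 0.02, sc.r_out - 0.02, 50)
    th = rng.uniform(-np.pi, np.pi, 50)
    z = rng.uniform(0.2, sc.length - 0.2, 50)
    X = np.column_stack([R * np.cos(th), R * np.sin(th), z])
    direct = chain[3].displacement(X) - chain[0].displacement(X)
    # increments act on positions of the reference (80 mmHg) configuration
    X0 = X + chain[0].displacement(X)
    got = totals[3].evaluate(X0)
    assert np.abs(got - direct).max() < 2e-3  # 2 um


# -- schedule conventions ------------------------------------------------

def test_schedule_reference_and_validation():
    states = [LoadState(index=j + 1, pressure_mmhg=p, axial_stretch=m)
              for j, (p, m) in enumerate(
                  (p, m) for m in (0.95, 1.0, 1.05)
                  for p in (20, 40, 60, 80, 100, 120, 140))]
    sched = LoadSchedule(states=states, lam_iv=1.4)
    assert sched.n_states == 21
    ref = sched.states[sched.reference_index]
    assert ref.pressure_mmhg == 80 and ref.axial_stretch == 1.0
    assert sched.p_ref_kpa == pytest.approx(80 * 0.133322)
    with pytest.raises(ValueError, match="contiguous"):
        LoadSchedule(states=states[:-1] + [LoadState(99, 140, 1.05)])
    with pytest.raises(ValueError, match="reference"):
        LoadSchedule(states=[LoadState(1, 40, 1.0), LoadState(2, 60, 1.0)])
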