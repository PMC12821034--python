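"""Amplitudes, buffer subtraction, Debye equivalence, density correction."""

import dataclasses

import numpy as np
import pytest

from hydrashell import synthetic_data as synth
from hydrashell.envelope import build_envelope
from hydrashell.formfactors import default_table
from hydrashell.model_io import Frame, FrameSet
from hydrashell.saxs_core import (
    QGrid,
    amplitude,
    debye_curve,
    fibonacci_directions,
    intensity_curve,
)


def test_fibonacci_directions_unit_norm():
    d = fibonacci_directions(200)
    np.testing.assert_allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
    # quasi-uniform: mean direction close to zero
    assert np.linalg.norm(d.mean(axis=0)) < 0.02


def test_qgrid_always_contains_zero():
    g = QGrid(q_values=np.array([0.5, 1.0]), n_directions=10)
    assert 0.0 in g.q_values


def test_amplitude_at_zero_is_total_electrons():
    fr = Frame([[0, 0, 0], [3, 0, 0]], ["O", "C"], ["UNK"] * 2, [1, 2], ["solute"] * 2)
    a = amplitude(fr, np.zeros(3))
    tab = default_table()
    assert a.imag == pytest.approx(0.0, abs=1e-12)
    assert a.real == pytest.approx(tab.f0("O") + tab.f0("C"))


def test_amplitude_single_atom_at_origin_is_formfactor():
    fr = Frame([[0, 0, 0]], ["O"], ["UNK"], [1], ["solute"])
    q = np.array([1.3, 0.0, 0.0])
    a = amplitude(fr, q)
    assert a == pytest.approx(default_table().formfactor("O", 1.3) + 0j)


def test_amplitude_two_site_cosine():
    # sites at +-a/2 along x: A = 2 cos(q a / 2) f(q), a in nm for the phase
    a_len = 4.0  # Angstrom
    fr = Frame([[a_len / 2, 0, 0], [-a_len / 2, 0, 0]], ["C", "C"],
               ["UNK"] * 2, [1, 2], ["solute"] * 2)
    q = 2.5  # 1/nm
    amp = amplitude(fr, np.array([q, 0.0, 0.0]))
    expected = 2 * np.cos(q * (a_len / 10.0) / 2.0) * default_table().formfactor("C", q)
    assert amp.real == pytest.approx(expected, rel=1e-12)
    assert amp.imag == pytest.approx(0.0, abs=1e-12)


def test_vacuum_matches_debye_sum(point_table):
    spec = synth.SyntheticSpec(n_solute_atoms=100, seed=31)
    sol = synth.make_solute(spec)
    fs = FrameSet([sol], kind="system")
    grid = QGrid(q_values=np.linspace(0, 3.0, 10), n_directions=200)
    curve = intensity_curve(fs, None, None, grid, table=point_table, vacuum_mode=True)
    deb = debye_curve(sol, curve.q, table=point_table)
    np.testing.assert_allclose(curve.I, deb, rtol=0.01)


def test_direction_count_convergence(point_table):
    spec = synth.SyntheticSpec(n_solute_atoms=100, seed=31)
    sol = synth.make_solute(spec)
    fs = FrameSet([sol], kind="system")
    q = np.linspace(0, 3.0, 8)
    I1 = intensity_curve(fs, None, None, QGrid(q, n_directions=100),
                         table=point_table, vacuum_mode=True).I
    I2 = intensity_curve(fs, None, None, QGrid(q, n_directions=200),
                         table=point_table, vacuum_mode=True).I
    np.testing.assert_allclose(I1, I2, rtol=0.01)


def test_identical_statistics_cancel(point_table):
    """System == buffer distribution: I(q) = 0 within 3 sigma at all q."""
    from hydrashell.envelope import Envelope

    box = (36.0, 36.0, 36.0)
    sys_fs = synth.make_water_box(box, seed=41, n_frames=30)
    sys_fs = FrameSet(sys_fs.frames, kind="system")
    buf = synth.make_water_box(box, seed=42, n_frames=30)
    env = Envelope(np.array([[18.0, 18.0, 18.0]]), d=9.0)  # anchored at box center
    grid = QGrid(q_values=np.linspace(0, 2.0, 6), n_directions=30)
    curve = intensity_curve(sys_fs, buf, env, grid, table=point_table)
    assert np.all(np.abs(curve.I) <= 3.0 * np.maximum(curve.sigma, 1e-9))


def test_forward_scattering_contract_small(small_sphere_system, small_buffer, point_table):
    """I(0) equals the square of the signed mean amplitude difference within
    3 sigma (Poisson frame-to-frame fluctuations cancel in expectation)."""
    _, system, truth = small_sphere_system
    env = build_envelope(system, d=9.0)
    grid = QGrid(q_values=np.array([0.0]), n_directions=1)
    curve = intensity_curve(system, small_buffer, env, grid, table=point_table)
    i0 = curve.metadata["I0"]
    signed = curve.signed_contrast
    assert i0 == pytest.approx(signed**2, abs=3 * max(curve.sigma[0], 1e-9))


def test_density_correction_restores_light_buffer(small_sphere_system, point_table):
    """A deliberately 2% light buffer biases the contrast; correcting the
    buffer density to the target restores the proper-buffer result."""
    _, system, _ = small_sphere_system
    spec_box = (46.0, 46.0, 46.0)
    buf_ok = synth.make_water_box(spec_box, bulk_density=33.4, seed=61, n_frames=20)
    buf_light = synth.make_water_box(spec_box, bulk_density=33.4 * 0.98, seed=61, n_frames=20)
    env = build_envelope(system, d=9.0)
    grid = QGrid(q_values=np.array([0.0]), n_directions=1)
    ref = intensity_curve(system, buf_ok, env, grid, table=point_table)
    raw = intensity_curve(system, buf_light, env, grid, table=point_table)
    fixed = intensity_curve(system, buf_light, env, grid, table=point_table,
                            rho_target=334.0, mc_seed=3)
    gamma = fixed.metadata["gamma"]
    assert 1.005 < gamma < 1.04
    err_raw = abs(raw.signed_contrast - ref.signed_contrast)
    err_fixed = abs(fixed.signed_contrast - ref.signed_contrast)
    se = np.hypot(ref.signed_contrast_se, fixed.signed_contrast_se)
    assert err_fixed < err_raw
    assert err_fixed <= 3 * se


def test_density_correction_identity_and_linearity(small_sphere_system, point_table):
    _, system, _ = small_sphere_system
    buf = synth.make_water_box((46.0, 46.0, 46.0), seed=71, n_frames=10)
    env = build_envelope(system, d=9.0)
    grid = QGrid(q_values=np.array([0.0]), n_directions=1)
    a = intensity_curve(system, buf, env, grid, table=point_table)
    # measured density back as target: gamma == 1, identity transform
    from hydrashell.envelope import envelope_volume, select_solvent

    vol, _ = envelope_volume(env, seed=0)
    electrons = []
    for fr in buf:
        sel = select_solvent(fr, env, recenter=True)
        electrons.append(sum(point_table.f0(str(el)) for el in sel.elements))
    rho_meas = float(np.mean(electrons)) / (vol / 1000.0)
    b = intensity_curve(system, buf, env, grid, table=point_table,
                        rho_target=rho_meas, mc_seed=0)
    assert b.metadata["gamma"] == pytest.approx(1.0, abs=1e-12)
    assert b.signed_contrast == pytest.approx(a.signed_contrast, rel=1e-12)


def test_errors_on_bad_inputs(small_sphere_system, point_table):
    _, system, _ = small_sphere_system
    grid = QGrid(q_values=np.array([0.0]), n_directions=1)
    with pytest.raises(ValueError, match="buffer"):
        intensity_curve(system, None, None, grid, table=point_table)
    with pytest.raises(ValueError):
        QGrid(q_values=np.array([0.0]), n_directions=0)
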