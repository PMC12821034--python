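"""Cavity-volume grid method against analytic and Monte-Carlo oracles."""

import numpy as np
import pytest

from hydrashell.excluded_volume import VolumeSpec, probe_sensitivity, ses_volume
from hydrashell.model_io import Frame


def _atoms(positions, element="C"):
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    n = len(positions)
    return Frame(positions, [element] * n, ["UNK"] * n, list(range(1, n + 1)),
                 ["solute"] * n)


def _two_sphere_excluded_mc(c1, c2, r, probe, n_mc=2_000_000, seed=0):
    """MC oracle on the exact probe-accessibility definition for two spheres.

    A point is accessible iff some probe center at distance >= r from both
    sphere surfaces lies within `probe` of it, i.e. iff the distance from
    the point to the complement of the union of the two (r+probe)-spheres
    is <= probe.  For two spheres that distance is the minimum over: the
    radial exit through either sphere (if the exit lands outside the other)
    and the distance to the intersection circle of the enlarged spheres.
    """
    c1, c2 = np.asarray(c1, float), np.asarray(c2, float)
    R = r + probe
    rng = np.random.default_rng(seed)
    lo = np.minimum(c1, c2) - (R + 1)
    hi = np.maximum(c1, c2) + (R + 1)
    pts = rng.random((n_mc, 3)) * (hi - lo) + lo
    d1 = np.linalg.norm(pts - c1, axis=1)
    d2 = np.linalg.norm(pts - c2, axis=1)
    inside = (d1 < R) | (d2 < R)
    # nearest point on either enlarged sphere surface, if it lies outside the
    # other enlarged sphere (hence is an allowed probe center)
    with np.errstate(invalid="ignore", divide="ignore"):
        exit1 = c1 + (pts - c1) / d1[:, None] * R
        ok1 = np.linalg.norm(exit1 - c2, axis=1) >= R
        cand1 = np.where(ok1, np.abs(R - d1), np.inf)
        exit2 = c2 + (pts - c2) / d2[:, None] * R
        ok2 = np.linalg.norm(exit2 - c1, axis=1) >= R
        cand2 = np.where(ok2, np.abs(R - d2), np.inf)
    escape = np.minimum(cand1, cand2)
    # distance to the intersection circle of the two enlarged spheres
    axis = c2 - c1
    L = np.linalg.norm(axis)
    if L < 2 * R:  # equal spheres intersect: circle in the midplane
        u = axis / L
        a = L / 2.0
        rc = np.sqrt(R**2 - a**2)
        center = c1 + a * u
        rel = pts - center
        h = rel @ u
        rho = np.linalg.norm(rel - np.outer(h, u), axis=1)
        d_circle = np.sqrt(h**2 + (rho - rc) ** 2)
        escape = np.minimum(escape, d_circle)
    accessible = ~inside | (escape <= probe)
    frac_excluded = np.mean(~accessible)
    return frac_excluded * np.prod(hi - lo)


def test_single_atom_matches_sphere_volume():
    res = ses_volume(_atoms([[0, 0, 0]]), VolumeSpec(n_rotations=3, seed=1))
    exact = 4.0 / 3.0 * np.pi * 1.7**3 / 1000.0
    assert res.volume == pytest.approx(exact, rel=0.02)


def test_disjoint_atoms_are_additive():
    res = ses_volume(_atoms([[0, 0, 0], [10, 0, 0]]), VolumeSpec(n_rotations=3, seed=1))
    exact = 2 * 4.0 / 3.0 * np.pi * 1.7**3 / 1000.0
    assert res.volume == pytest.approx(exact, rel=0.02)


def test_reentrant_pair_exceeds_union_and_matches_mc_oracle():
    r, probe, sep = 1.7, 1.4, 4.0
    res = ses_volume(_atoms([[0, 0, 0], [sep, 0, 0]]),
                     VolumeSpec(probe_radius=probe, n_rotations=4, seed=2))
    # analytic union of two vdW spheres (they do not overlap at 4.0 A)
    union = 2 * 4.0 / 3.0 * np.pi * r**3
    assert res.volume * 1000 > union * 1.01  # re-entrant bridge adds volume
    oracle = _two_sphere_excluded_mc([0, 0, 0], [sep, 0, 0], r, probe)
    assert res.volume * 1000 == pytest.approx(oracle, rel=0.02)


def test_probe_zero_reduces_to_vdw_union():
    r, d = 1.7, 2.0  # overlapping spheres
    res = ses_volume(_atoms([[0, 0, 0], [d, 0, 0]]),
                     VolumeSpec(probe_radius=0.0, n_rotations=3, seed=3))
    union = 2 * 4 / 3 * np.pi * r**3 - np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0
    assert res.volume * 1000 == pytest.approx(union, rel=0.01)


def test_probe_sensitivity_monotone():
    frame = _atoms([[0, 0, 0], [3.6, 0, 0], [1.8, 3.0, 0]])
    table = probe_sensitivity(frame, VolumeSpec(n_rotations=3, seed=4),
                              probes=(1.3, 1.4, 1.5))
    v13, v14, v15 = (table[p].volume for p in (1.3, 1.4, 1.5))
    assert v13 <= v14 <= v15
    # a single convex atom is probe-independent (within grid-jitter noise)
    single = probe_sensitivity(_atoms([[0, 0, 0]]),
                               VolumeSpec(n_rotations=10, seed=4), probes=(1.3, 1.5))
    tol = 3 * np.hypot(single[1.3].se, single[1.5].se) + 1e-5
    assert single[1.3].volume == pytest.approx(single[1.5].volume, abs=tol)


def test_grid_convergence_single_atom():
    coarse = ses_volume(_atoms([[0, 0, 0]]), VolumeSpec(grid_spacing=0.16,
                                                        n_rotations=2, seed=5))
    fine = ses_volume(_atoms([[0, 0, 0]]), VolumeSpec(grid_spacing=0.08,
                                                      n_rotations=2, seed=5))
    assert abs(fine.volume - coarse.volume) / fine.volume < 0.005


def test_missing_radius_raises():
    fr = Frame([[0, 0, 0]], ["Zz"], ["UNK"], [1], ["solute"])
    with pytest.raises(KeyError, match="Zz"):
        ses_volume(fr, VolumeSpec(n_rotations=1))


def test_vdw_radii_on_frame_take_precedence():
    fr = Frame([[0, 0, 0]], ["C"], ["UNK"], [1], ["solute"],
               vdw_radii=np.array([2.8]))
    res = ses_volume(fr, VolumeSpec(n_rotations=2, seed=6))
    exact = 4 / 3 * np.pi * 2.8**3 / 1000.0
    assert res.volume == pytest.approx(exact, rel=0.02)
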