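"""Synthetic hydrated-solute and pure-water ensembles with known ground truth.

The generator emulates the inputs of an explicit-solvent SAXS
calculation without running MD:

* a rigid coarse-grained solute of point-scatterer beads (pseudo-element
  ``X``) with a chosen electron count per bead;
* water at the experimental bulk electron density of 334 e/nm^3
  (33.4 molecules/nm^3 at 10 e per molecule), placed as an ideal gas
  (Poisson counts, uniform positions) or with a hard-core O-O exclusion;
* a hydration-shell region at a stated distance range from the solute
  surface carrying an exactly known excess or deficit of ``shell_excess``
  water molecules per frame;
* a matched pure-water buffer box.

Water oxygens are excluded from a hard core of radius
:data:`EXCLUSION_DISTANCE` around every solute bead.  Beads are assigned
a van der Waals radius equal to that exclusion distance, so the
probe-excluded (cavity) volume of the solute closely matches the volume
that is actually unavailable to water oxygens -- the property that makes
the contrast decomposition recover the injected shell excess.

Everything is a pure function of (spec, seed).  The injected excess is
recoverable by direct counting in the shell region, independent of the
scattering path; that counting oracle is the primary ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Frame, FrameSet, write_gro

__all__ = [
    "EXCLUSION_DISTANCE",
    "SOLUTE_ELEMENT",
    "SyntheticSpec",
    "GroundTruth",
    "make_solute",
    "make_water_box",
    "hydrate",
    "make_variant_series",
    "formfactor_table_for",
    "shell_volume_mc",
    "count_shell_waters",
    "save_frameset",
]

#: Hard-core distance between a solute bead center and any water oxygen (A).
EXCLUSION_DISTANCE = 2.8
#: Pseudo-element symbol of synthetic solute beads (flat form factor).
SOLUTE_ELEMENT = "X"

_OH_BOND = 0.96          # A
_HOH_ANGLE = np.deg2rad(104.52)
_HARD_CORE_OO = 2.6      # A, hard_core water mode
_CHAIN_BOND = 3.8        # A, chain shape


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic hydrated system.

    ``bulk_density`` is in molecules/nm^3; all lengths in Angstrom.
    ``shell_excess`` is the signed number of water molecules added to
    (or removed from) the shell_inner..shell_outer distance band around
    the solute surface, exactly, in every frame.
    """

    solute_shape: str = "sphere"            # sphere | rod | chain
    solute_radius_or_length: float = 10.0
    n_solute_atoms: int = 300
    electrons_per_solute_atom: float = 6.0
    site_labels: dict[int, str] = field(default_factory=dict)
    box: tuple[float, float, float] = (50.0, 50.0, 50.0)
    bulk_density: float = 33.4              # molecules / nm^3
    shell_inner: float = 2.8
    shell_outer: float = 6.0
    shell_excess: int = 0
    n_frames: int = 50
    seed: int = 0
    water_mode: str = "ideal_gas"           # ideal_gas | hard_core

    def __post_init__(self):
        if self.shell_inner >= self.shell_outer:
            raise ValueError("shell_inner must be < shell_outer")
        if self.bulk_density <= 0:
            raise ValueError("bulk_density must be positive")
        if self.water_mode not in ("ideal_gas", "hard_core"):
            raise ValueError(f"unknown water_mode {self.water_mode!r}")

    @property
    def number_density_A3(self) -> float:
        """Bulk number density in molecules per A^3."""
        return self.bulk_density / 1000.0


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually injected (the acceptance oracle)."""

    delta_n_hs_true: float                  # shell excess, molecules per frame
    n_waters_bulk_expected: float           # E[molecules] per frame before shell edits
    spec: SyntheticSpec


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


# ---------------------------------------------------------------------------
# Solute
# ---------------------------------------------------------------------------

def make_solute(spec: SyntheticSpec) -> Frame:
    """Rigid solute frame centered at the origin; deterministic in spec.seed."""
    n = spec.n_solute_atoms
    if n < 1:
        raise ValueError("need at least one solute atom")
    rng = _rng(spec.seed, 0)
    L = spec.solute_radius_or_length
    if spec.solute_shape == "sphere":
        # uniform in a ball of radius L
        pts = rng.standard_normal((n, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= L * rng.random(n)[:, None] ** (1.0 / 3.0)
        if n == 1:
            pts = np.zeros((1, 3))
    elif spec.solute_shape == "rod":
        z = np.linspace(-L / 2.0, L / 2.0, n) if n > 1 else np.zeros(1)
        pts = np.column_stack([np.zeros(n), np.zeros(n), z])
    elif spec.solute_shape == "chain":
        z = _CHAIN_BOND * np.arange(n, dtype=float)
        z -= z.mean()
        pts = np.column_stack([np.zeros(n), np.zeros(n), z])
    else:
        raise ValueError(f"unknown solute shape {spec.solute_shape!r}")
    labels = [spec.site_labels.get(i, "") for i in range(n)]
    return Frame(
        coords=pts,
        elements=[SOLUTE_ELEMENT] * n,
        residue_names=["BEA"] * n,
        residue_ids=np.ones(n, dtype=int),
        roles=["solute"] * n,
        site_labels=labels,
        names=[SOLUTE_ELEMENT] * n,
        vdw_radii=np.full(n, EXCLUSION_DISTANCE),
        box=None,
    )


def formfactor_table_for(spec: SyntheticSpec):
    """Default form-factor table extended with the solute point scatterer."""
    from .formfactors import default_table

    return default_table().with_point_atom(SOLUTE_ELEMENT, spec.electrons_per_solute_atom)


# ---------------------------------------------------------------------------
# Water placement
# ---------------------------------------------------------------------------

def _water_sites(o_coords: np.ndarray, rng: np.random.Generator) -> tuple[np.ndarray, ...]:
    """Rigid O + 2H geometry with random orientation per molecule."""
    n = len(o_coords)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    # arbitrary perpendicular for the second OH direction
    helper = rng.standard_normal((n, 3))
    perp = np.cross(u, helper)
    norms = np.linalg.norm(perp, axis=1, keepdims=True)
    bad = norms[:, 0] < 1e-10
    if np.any(bad):
        perp[bad] = np.cross(u[bad], u[bad] + [0.1, 0.2, 0.3])
        norms = np.linalg.norm(perp, axis=1, keepdims=True)
    perp /= norms
    h1 = o_coords + _OH_BOND * u
    v2 = np.cos(_HOH_ANGLE) * u + np.sin(_HOH_ANGLE) * perp
    h2 = o_coords + _OH_BOND * v2
    return h1, h2


def _assemble_frame(solute: Frame | None, o_coords: np.ndarray,
                    rng: np.random.Generator, box: Sequence[float]) -> Frame:
    """Stack solute beads (if any) and water molecules into one Frame."""
    n_w = len(o_coords)
    h1, h2 = _water_sites(o_coords, rng) if n_w else (np.zeros((0, 3)),) * 2
    w_coords = np.empty((3 * n_w, 3))
    w_coords[0::3] = o_coords
    w_coords[1::3] = h1
    w_coords[2::3] = h2
    w_elements = np.tile(np.array(["O", "H", "H"], dtype=object), n_w)
    w_names = np.tile(np.array(["OW", "HW1", "HW2"], dtype=object), n_w)
    base_rid = 2 if solute is not None else 1
    w_resids = np.repeat(np.arange(base_rid, base_rid + n_w), 3)
    if solute is None:
        return Frame(w_coords, w_elements, ["SOL"] * (3 * n_w), w_resids,
                     ["solvent"] * (3 * n_w), names=w_names, box=box)
    ns = len(solute)
    coords = np.vstack([solute.coords, w_coords])
    elements = np.concatenate([solute.elements, w_elements])
    resnames = np.concatenate([solute.residue_names, np.full(3 * n_w, "SOL", dtype=object)])
    resids = np.concatenate([solute.residue_ids, w_resids])
    roles = np.concatenate([solute.roles, np.full(3 * n_w, "solvent", dtype=object)])
    labels = np.concatenate([solute.site_labels, np.full(3 * n_w, "", dtype=object)])
    names = np.concatenate([solute.names, w_names])
    vdw = None
    if solute.vdw_radii is not None:
        vdw = np.concatenate([solute.vdw_radii, np.full(3 * n_w, 1.52)])
    return Frame(coords, elements, resnames, resids, roles, labels, names, vdw, box)


def _sample_bulk_oxygens(box: np.ndarray, density_A3: float, mode: str,
                         rng: np.random.Generator) -> np.ndarray:
    vol = float(np.prod(box))
    n = rng.poisson(density_A3 * vol)
    pts = rng.random((n, 3)) * box
    if mode == "hard_core":
        kept: list[np.ndarray] = []
        tree_pts: list[np.ndarray] = []
        attempts = 0
        max_attempts = 60 * max(n, 1)
        i = 0
        while len(kept) < n:
            if i >= len(pts):
                extra = rng.random((max(n, 64), 3)) * box
                pts = np.vstack([pts, extra])
            cand = pts[i]
            i += 1
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError(
                    "hard_core water placement failed: density too high for "
                    f"O-O exclusion {_HARD_CORE_OO} A"
                )
            if tree_pts:
                d = np.linalg.norm(np.asarray(tree_pts) - cand, axis=1)
                if np.min(d) < _HARD_CORE_OO:
                    continue
            kept.append(cand)
            tree_pts.append(cand)
        return np.asarray(kept) if kept else np.zeros((0, 3))
    return pts


def make_water_box(box: Sequence[float], bulk_density: float = 33.4,
                   mode: str = "ideal_gas", seed: int = 0, n_frames: int = 1) -> FrameSet:
    """Pure-water buffer frames: N ~ Poisson(rho * V) molecules per frame.

    ``bulk_density`` in molecules/nm^3, box lengths in Angstrom.  In
    ``hard_core`` mode O-O distances below 2.6 A are rejected.
    """
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    if mode not in ("ideal_gas", "hard_core"):
        raise ValueError(f"unknown water mode {mode!r}")
    density_A3 = bulk_density / 1000.0
    frames = []
    for k in range(n_frames):
        rng = _rng(seed, 10, k)
        o = _sample_bulk_oxygens(box, density_A3, mode, rng)
        frames.append(_assemble_frame(None, o, rng, box))
    return FrameSet(frames, kind="buffer",
                    metadata={"bulk_density": bulk_density, "mode": mode, "seed": seed})


# ---------------------------------------------------------------------------
# Hydration with known shell excess
# ---------------------------------------------------------------------------

def _check_margins(solute_centered: np.ndarray, spec: SyntheticSpec) -> None:
    box = np.asarray(spec.box, dtype=float)
    lo = solute_centered.min(axis=0)
    hi = solute_centered.max(axis=0)
    margin = spec.shell_outer + 9.0
    if np.any(lo < margin - 1e-9) or np.any(box - hi < margin - 1e-9):
        raise ValueError(
            f"box {tuple(box)} too small: need >= {margin:.1f} A between every "
            "solute atom and each box face (shell_outer + 9 A)"
        )


def _sample_shell_points(tree: cKDTree, centers: np.ndarray, n: int,
                         inner: float, outer: float, box: np.ndarray,
                         rng: np.random.Generator,
                         around: np.ndarray | None = None) -> np.ndarray:
    """Rejection-sample n points whose distance to the solute surface band
    [inner, outer] holds; optionally anchored around specific site centers."""
    out = np.empty((n, 3))
    got = 0
    tries = 0
    while got < n:
        tries += 1
        if tries > 2000:
            raise RuntimeError("shell placement did not converge")
        m = max(4 * (n - got), 64)
        if around is None:
            cand = rng.random((m, 3)) * box
        else:
            # uniform in the spherical band [inner, outer] around a site
            sites = around[rng.integers(0, len(around), m)]
            u = rng.standard_normal((m, 3))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            r = (rng.random(m) * (outer**3 - inner**3) + inner**3) ** (1.0 / 3.0)
            cand = sites + u * r[:, None]
            inside = np.all((cand >= 0) & (cand < box), axis=1)
            cand = cand[inside]
            if not len(cand):
                continue
        d, _ = tree.query(cand)
        if around is None:
            keep = (d >= max(inner, EXCLUSION_DISTANCE)) & (d <= outer)
        else:
            # the radial draw already guarantees the band around the chosen
            # site; only the surface hard core can still reject a sample
            keep = d >= EXCLUSION_DISTANCE
        cand = cand[keep]
        take = min(n - got, len(cand))
        out[got:got + take] = cand[:take]
        got += take
    return out


def hydrate(solute: Frame, spec: SyntheticSpec) -> tuple[FrameSet, GroundTruth]:
    """Hydrated system frames with exactly ``spec.shell_excess`` extra (or
    removed) shell waters per frame; returns the ensemble and its truth."""
    box = np.asarray(spec.box, dtype=float)
    centered = solute.coords - solute.coords.mean(axis=0) + box / 2.0
    _check_margins(centered, spec)
    solute_c = solute.subset(np.ones(len(solute), dtype=bool))
    solute_c.coords = centered
    tree = cKDTree(centered)
    label_mask = solute_c.site_labels != ""
    frames = []
    dN = int(spec.shell_excess)
    for k in range(spec.n_frames):
        rng = _rng(spec.seed, 1, k)
        o = _sample_bulk_oxygens(box, spec.number_density_A3, spec.water_mode, rng)
        if len(o):
            d, _ = tree.query(o)
            o = o[d >= EXCLUSION_DISTANCE]
        if dN > 0:
            extra = _sample_shell_points(tree, centered, dN, spec.shell_inner,
                                         spec.shell_outer, box, rng)
            o = np.vstack([o, extra]) if len(o) else extra
        elif dN < 0:
            d, _ = tree.query(o) if len(o) else (np.empty(0), None)
            in_shell = np.flatnonzero((d >= spec.shell_inner) & (d <= spec.shell_outer))
            if len(in_shell) < -dN:
                raise ValueError(
                    f"frame {k}: cannot delete {-dN} shell waters, only "
                    f"{len(in_shell)} present"
                )
            drop = rng.choice(in_shell, size=-dN, replace=False)
            o = np.delete(o, drop, axis=0)
        frames.append(_assemble_frame(solute_c, o, rng, box))
    truth = GroundTruth(
        delta_n_hs_true=float(dN),
        n_waters_bulk_expected=float(spec.number_density_A3 * np.prod(box)),
        spec=spec,
    )
    fs = FrameSet(frames, kind="system", metadata={"seed": spec.seed, "shell_excess": dN})
    return fs, truth


def make_variant_series(
    solute: Frame,
    base_spec: SyntheticSpec,
    per_site_excess: dict[str, float],
) -> dict[str, tuple[FrameSet, GroundTruth]]:
    """One hydrated system per variant label.

    Variant ``v`` adds ``per_site_excess[v]`` waters per labeled solute
    site, placed in the shell band around those sites (negative values
    delete shell waters near the sites).  All variants share the same
    base-water realization per frame (common random numbers), so variant
    differences isolate the injected shell signal.  The ground truth per
    variant is ``n_sites * per_site_excess[v]``.
    """
    if not per_site_excess:
        return {}
    site_idx = np.flatnonzero(solute.site_labels != "")
    if site_idx.size == 0:
        raise ValueError("solute has no labeled sites")
    n_sites = int(site_idx.size)
    box = np.asarray(base_spec.box, dtype=float)
    centered = solute.coords - solute.coords.mean(axis=0) + box / 2.0
    _check_margins(centered, base_spec)
    solute_c = solute.subset(np.ones(len(solute), dtype=bool))
    solute_c.coords = centered
    tree = cKDTree(centered)
    sites = centered[site_idx]

    out: dict[str, tuple[FrameSet, GroundTruth]] = {}
    # pre-draw the shared base waters per frame
    base_oxygens = []
    for k in range(base_spec.n_frames):
        rng = _rng(base_spec.seed, 1, k)
        o = _sample_bulk_oxygens(box, base_spec.number_density_A3, base_spec.water_mode, rng)
        if len(o):
            d, _ = tree.query(o)
            o = o[d >= EXCLUSION_DISTANCE]
        base_oxygens.append(o)

    for vi, (label, excess) in enumerate(per_site_excess.items()):
        total = n_sites * float(excess)
        dN = int(round(total))
        if abs(total - dN) > 1e-6:
            raise ValueError(
                f"variant {label!r}: n_sites * per_site_excess = {total} is not integral"
            )
        frames = []
        for k in range(base_spec.n_frames):
            rng = _rng(base_spec.seed, 2, vi, k)
            o = base_oxygens[k].copy()
            if dN > 0:
                extra = _sample_shell_points(tree, centered, dN, base_spec.shell_inner,
                                             base_spec.shell_outer, box, rng, around=sites)
                o = np.vstack([o, extra]) if len(o) else extra
            elif dN < 0:
                dsite = cKDTree(sites).query(o)[0] if len(o) else np.empty(0)
                in_band = np.flatnonzero(
                    (dsite >= base_spec.shell_inner) & (dsite <= base_spec.shell_outer)
                )
                if len(in_band) < -dN:
                    raise ValueError(
                        f"variant {label!r} frame {k}: cannot delete {-dN} waters, "
                        f"only {len(in_band)} in the site shell band"
                    )
                drop = rng.choice(in_band, size=-dN, replace=False)
                o = np.delete(o, drop, axis=0)
            frames.append(_assemble_frame(solute_c, o, rng, box))
        fs = FrameSet(frames, kind="system",
                      metadata={"variant": label, "n_sites": n_sites,
                                "seed": base_spec.seed})
        truth = GroundTruth(delta_n_hs_true=float(dN),
                            n_waters_bulk_expected=float(
                                base_spec.number_density_A3 * np.prod(box)),
                            spec=replace(base_spec, shell_excess=dN))
        out[label] = (fs, truth)
    return out


# ---------------------------------------------------------------------------
# Counting oracles and persistence
# ---------------------------------------------------------------------------

def shell_volume_mc(solute_coords: np.ndarray, inner: float, outer: float,
                    n_mc: int = 200_000, seed: int = 0) -> float:
    """Monte-Carlo volume (A^3) of the band inner <= d(nearest bead) <= outer."""
    tree = cKDTree(solute_coords)
    rng = _rng(seed, 99)
    lo = solute_coords.min(axis=0) - outer
    hi = solute_coords.max(axis=0) + outer
    pts = rng.random((n_mc, 3)) * (hi - lo) + lo
    d, _ = tree.query(pts)
    frac = np.mean((d >= inner) & (d <= outer))
    return float(frac * np.prod(hi - lo))


def count_shell_waters(system: FrameSet, inner: float, outer: float) -> np.ndarray:
    """Per-frame count of water oxygens in the shell band around the solute."""
    counts = []
    for fr in system:
        tree = cKDTree(fr.coords[fr.solute_mask])
        o_idx = fr.solvent_oxygen_indices()
        if o_idx.size == 0:
            counts.append(0)
            continue
        d, _ = tree.query(fr.coords[o_idx])
        counts.append(int(np.sum((d >= inner) & (d <= outer))))
    return np.asarray(counts)


def save_frameset(fs: FrameSet, outdir: str | Path, prefix: str = "frame") -> list[Path]:
    """Write one GRO file per frame (sorted order matches frame order)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    width = max(4, len(str(len(fs))))
    for k, fr in enumerate(fs):
        p = outdir / f"{prefix}{k:0{width}d}.gro"
        write_gro(fr, p)
        paths.append(p)
    return paths
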