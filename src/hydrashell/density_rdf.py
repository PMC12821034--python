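"""3D solvent electron-density maps and water-oxygen RDFs.

Density maps average the solvent electron content per voxel over frames
(nearest-voxel binning, so electron conservation is exact: the voxel
sum times the voxel volume equals the mean binned electron count).
Densities are reported in e/nm^3; dividing by the bulk value 334 e/nm^3
gives the normalized map, whose deviation from 1 is the shell contrast
density entering the Rg analysis.

RDFs are pair-distance histograms of water oxygens around a reference
selection, normalized by the configured *bulk* number density:

    g(r) = h(r) / (n_ref * n_frames * 4 pi r^2 dr * rho_bulk).

Near a solute g(r) therefore need not tend to 1 at large r; peak heights
directly measure hydration-shell structure relative to bulk water.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .envelope import Envelope
from .formfactors import FormFactorTable, default_table
from .model_io import Frame, FrameSet

__all__ = ["DensityMap", "Rdf", "density_map", "rdf", "select_reference"]


@dataclass
class DensityMap:
    origin: np.ndarray        # A
    spacing: float            # A
    rho: np.ndarray           # e/nm^3, shape (nx, ny, nz)
    n_frames: int
    metadata: dict = field(default_factory=dict)

    @property
    def normalized(self) -> np.ndarray:
        """rho / rho_bulk with rho_bulk = 334 e/nm^3 unless overridden."""
        return self.rho / self.metadata.get("rho_bulk", 334.0)

    def total_electrons(self) -> float:
        """Voxel sum x voxel volume: mean electrons binned per frame."""
        voxel_nm3 = (self.spacing / 10.0) ** 3
        return float(self.rho.sum() * voxel_nm3)

    def write_dx(self, path: str | Path) -> None:
        """Plain-text OpenDX scalar field (e/nm^3)."""
        nx, ny, nz = self.rho.shape
        o = self.origin
        h = self.spacing
        lines = [
            f"object 1 class gridpositions counts {nx} {ny} {nz}",
            f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
            f"delta {h:.6f} 0 0",
            f"delta 0 {h:.6f} 0",
            f"delta 0 0 {h:.6f}",
            f"object 2 class gridconnections counts {nx} {ny} {nz}",
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
        ]
        flat = self.rho.ravel(order="C")
        for i in range(0, len(flat), 3):
            lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
        lines.append('attribute "dep" string "positions"')
        lines.append('object "density" class field')
        Path(path).write_text("\n".join(lines) + "\n")

    def write_ccp4(self, path: str | Path) -> None:
        """Binary CCP4/MRC map via gemmi (for viewers such as PyMOL)."""
        import gemmi

        grid = gemmi.FloatGrid(*self.rho.shape)
        grid.set_unit_cell(gemmi.UnitCell(
            self.rho.shape[0] * self.spacing,
            self.rho.shape[1] * self.spacing,
            self.rho.shape[2] * self.spacing, 90, 90, 90))
        arr = np.asarray(grid, dtype=np.float32)
        arr[...] = self.rho.astype(np.float32)
        m = gemmi.Ccp4Map()
        m.grid = grid
        m.update_ccp4_header()
        m.write_ccp4_map(str(path))


@dataclass
class Rdf:
    r: np.ndarray             # bin centers, A
    g: np.ndarray             # dimensionless
    counts: np.ndarray        # raw pair counts per bin
    selection: str
    metadata: dict = field(default_factory=dict)


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares superposition: returns rotation, mobile centroid, ref centroid."""
    mc = mobile.mean(axis=0)
    rc = ref.mean(axis=0)
    H = (mobile - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    Rm = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return Rm, mc, rc


def density_map(system: FrameSet, env: Envelope, spacing: float = 0.5,
                align: str = "none", table: FormFactorTable | None = None,
                rho_bulk: float = 334.0) -> DensityMap:
    """Frame-averaged solvent electron density on the envelope bounding box.

    Solvent atoms deposit their zero-angle electron count into the
    nearest voxel.  ``align='kabsch'`` superposes each frame's solute
    onto the first frame before binning (for unrestrained ensembles).
    """
    if align not in ("none", "kabsch"):
        raise ValueError(f"unknown align mode {align!r}")
    tab = table or default_table()
    lo, hi = env.bounding_box
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    acc = np.zeros(shape)
    ref_solute = system.frames[0].coords[system.frames[0].solute_mask]
    if align == "kabsch" and len(ref_solute) < 4:
        raise ValueError("kabsch alignment needs at least 4 solute atoms")
    for fr in system:
        coords = fr.coords
        if align == "kabsch":
            Rm, mc, rc = _kabsch(coords[fr.solute_mask], ref_solute)
            coords = (coords - mc) @ Rm.T + rc
        mask = fr.solvent_mask
        pts = coords[mask]
        w = np.array([0.0 if el == "M" else tab.f0(str(el)) for el in fr.elements[mask]])
        idx = np.rint((pts - lo) / spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        np.add.at(acc, tuple(idx[ok].T), w[ok])
    voxel_nm3 = (spacing / 10.0) ** 3
    rho = acc / (len(system) * voxel_nm3)
    return DensityMap(origin=lo.copy(), spacing=float(spacing), rho=rho,
                      n_frames=len(system),
                      metadata={"align": align, "rho_bulk": rho_bulk})


def select_reference(frame: Frame, descriptor: str) -> np.ndarray:
    """Atom indices for a reference descriptor.

    Supported forms: ``label:<site_label>``, ``resname:<name>``,
    ``element:<symbol>``, ``index:<i,j,...>``.
    """
    kind, _, value = descriptor.partition(":")
    if kind == "label":
        idx = np.flatnonzero(frame.site_labels == value)
    elif kind == "resname":
        idx = np.flatnonzero(frame.residue_names == value)
    elif kind == "element":
        idx = np.flatnonzero(frame.elements == value)
    elif kind == "index":
        idx = np.array([int(x) for x in value.split(",")], dtype=int)
    else:
        raise ValueError(f"unknown selection descriptor {descriptor!r}")
    if idx.size == 0:
        raise ValueError(f"selection {descriptor!r} matched no atoms")
    return idx


def rdf(system: FrameSet, ref_selection: str | np.ndarray, dr: float = 0.05,
        r_max: float = 12.0, rho_bulk: float = 33.4) -> Rdf:
    """Radial distribution function of water oxygens around a selection.

    ``rho_bulk`` is the bulk *number* density in molecules/nm^3 used for
    normalization.  Averaged over frames with equal weight.
    """
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    n_ref_total = 0
    for fr in system:
        if isinstance(ref_selection, str):
            ref_idx = select_reference(fr, ref_selection)
        else:
            ref_idx = np.asarray(ref_selection, dtype=int)
        if ref_idx.size == 0:
            raise ValueError("empty reference selection")
        o_idx = fr.solvent_oxygen_indices()
        n_ref_total += ref_idx.size
        if o_idx.size == 0:
            continue
        tree = cKDTree(fr.coords[o_idx])
        pairs = tree.query_ball_point(fr.coords[ref_idx], r_max)
        dists = []
        for i, neigh in enumerate(pairs):
            if not neigh:
                continue
            d = np.linalg.norm(fr.coords[o_idx][neigh] - fr.coords[ref_idx[i]], axis=1)
            dists.append(d)
        if dists:
            alld = np.concatenate(dists)
            alld = alld[alld > 1e-9]  # a reference that is itself a water O
            counts += np.histogram(alld, bins=edges)[0]
    r_centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * r_centers**2 * dr          # A^3
    density_A3 = rho_bulk / 1000.0
    norm = n_ref_total * shell_vol * density_A3
    g = np.divide(counts, norm, out=np.zeros_like(counts), where=norm > 0)
    sel_name = ref_selection if isinstance(ref_selection, str) else "indices"
    return Rdf(r=r_centers, g=g, counts=counts, selection=str(sel_name),
               metadata={"dr": dr, "r_max": r_max, "rho_bulk": rho_bulk,
                         "n_frames": len(system)})
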