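"""Domain types for atomistic frames and coordinate/curve I/O.

A :class:`Frame` is one configuration of a hydrated solute (or of a pure
water box): coordinates in Angstrom, element symbols, residue labels, a
solute/solvent role per atom and, when periodic, three orthorhombic box
lengths.  A :class:`FrameSet` is an ordered collection of frames standing
in for a trajectory, tagged as ``system`` (solute + water) or ``buffer``
(water only).

Internally frames are arrays (structure-of-arrays) for speed;
:class:`AtomSite` is a per-atom view used at the API boundary.

Coordinate files are parsed with MDAnalysis (PDB and GRO dialects);
GRO nm coordinates are converted to Angstrom at this boundary and the
internal unit is Angstrom everywhere.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "WATER_RESNAMES",
    "AtomSite",
    "Frame",
    "FrameSet",
    "read_structure",
    "read_frameset",
    "write_gro",
    "write_saxs_curve",
    "read_saxs_curve",
]

#: Residue names recognized as water (GROMACS and PDB conventions).
WATER_RESNAMES = frozenset({"SOL", "HOH", "WAT", "TIP3", "TIP4", "TIP4P", "TIP5"})

# Elements resolvable from leading characters of an atom name.  Two-letter
# symbols are checked first; GROMACS water hydrogens (HW1, MW, ...) are
# special-cased below.
_TWO_LETTER = {"NA": "Na", "CL": "Cl", "MG": "Mg", "FE": "Fe", "ZN": "Zn", "CA2": "Ca"}


def element_from_name(name: str, resname: str = "") -> str:
    """Infer the chemical element from an atom name (PDB/GROMACS style)."""
    name = name.strip()
    if not name:
        raise ValueError("empty atom name")
    upper = name.upper()
    if upper.startswith(("MW", "EPW", "EP", "M")) and resname.upper() in WATER_RESNAMES:
        return "M"  # TIP4P-family virtual site: 0 electrons, kept in frames
    if resname.upper() in {"NA", "NA+", "SOD"} or upper in {"NA", "NA+", "SOD"}:
        return "Na"
    if resname.upper() in {"CL", "CL-", "CLA"} or upper in {"CL", "CL-", "CLA"}:
        return "Cl"
    stripped = upper.lstrip("0123456789")
    for two, sym in _TWO_LETTER.items():
        if stripped.startswith(two):
            return sym
    first = stripped[:1]
    if first in {"H", "C", "N", "O", "S", "P", "X"}:
        return first
    raise ValueError(f"cannot infer element for atom name {name!r} (residue {resname!r})")


@dataclass(frozen=True)
class AtomSite:
    """One atom site: a view row of a :class:`Frame`."""

    id: int
    element: str
    coords: np.ndarray  # (3,) Angstrom
    residue_name: str
    residue_id: int
    site_label: str = ""
    role: str = "solute"  # "solute" | "solvent"
    vdw_radius: float | None = None

    def __post_init__(self):
        if self.role not in ("solute", "solvent"):
            raise ValueError(f"role must be 'solute' or 'solvent', got {self.role!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.id}")


class Frame:
    """One configuration of atom sites, optionally with an orthorhombic box.

    Parameters are parallel arrays over atoms; ``coords`` in Angstrom,
    ``box`` three edge lengths in Angstrom or ``None`` for vacuum.
    """

    def __init__(
        self,
        coords: np.ndarray,
        elements: Sequence[str],
        residue_names: Sequence[str],
        residue_ids: Sequence[int],
        roles: Sequence[str] | np.ndarray,
        site_labels: Sequence[str] | None = None,
        names: Sequence[str] | None = None,
        vdw_radii: np.ndarray | None = None,
        box: Sequence[float] | None = None,
    ):
        self.coords = np.ascontiguousarray(coords, dtype=float).reshape(-1, 3)
        n = len(self.coords)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        self.elements = np.asarray(elements, dtype=object)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.residue_ids = np.asarray(residue_ids, dtype=int)
        roles = np.asarray(roles, dtype=object)
        if not set(np.unique(roles)) <= {"solute", "solvent"}:
            raise ValueError("roles must be 'solute' or 'solvent'")
        self.roles = roles
        self.site_labels = (
            np.asarray(site_labels, dtype=object)
            if site_labels is not None
            else np.full(n, "", dtype=object)
        )
        self.names = (
            np.asarray(names, dtype=object) if names is not None else self.elements.copy()
        )
        self.vdw_radii = None if vdw_radii is None else np.asarray(vdw_radii, dtype=float)
        self.box = None if box is None else np.asarray(box, dtype=float).reshape(3)
        for arr in (self.elements, self.residue_names, self.residue_ids, self.roles,
                    self.site_labels, self.names):
            if len(arr) != n:
                raise ValueError("inconsistent per-atom array lengths")

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.coords)

    @property
    def atoms(self) -> Iterator[AtomSite]:
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> AtomSite:
        return AtomSite(
            id=i,
            element=str(self.elements[i]),
            coords=self.coords[i],
            residue_name=str(self.residue_names[i]),
            residue_id=int(self.residue_ids[i]),
            site_label=str(self.site_labels[i]),
            role=str(self.roles[i]),
            vdw_radius=None if self.vdw_radii is None else float(self.vdw_radii[i]),
        )

    # -- role helpers ----------------------------------------------------
    @property
    def solute_mask(self) -> np.ndarray:
        return self.roles == "solute"

    @property
    def solvent_mask(self) -> np.ndarray:
        return self.roles == "solvent"

    def subset(self, mask: np.ndarray) -> "Frame":
        idx = np.asarray(mask)
        return Frame(
            self.coords[idx],
            self.elements[idx],
            self.residue_names[idx],
            self.residue_ids[idx],
            self.roles[idx],
            self.site_labels[idx],
            self.names[idx],
            None if self.vdw_radii is None else self.vdw_radii[idx],
            self.box,
        )

    def solvent_molecules(self) -> list[np.ndarray]:
        """Index groups of intact solvent molecules (contiguous residue runs)."""
        idx = np.flatnonzero(self.solvent_mask)
        if idx.size == 0:
            return []
        rid = self.residue_ids[idx]
        breaks = np.flatnonzero(np.diff(rid) != 0) + 1
        return [g for g in np.split(idx, breaks)]

    def solvent_oxygen_indices(self) -> np.ndarray:
        """Index of the O atom of every intact solvent molecule."""
        out = []
        for grp in self.solvent_molecules():
            els = self.elements[grp]
            o = grp[els == "O"]
            if o.size != 1:
                raise ValueError(
                    f"solvent molecule (residue {self.residue_ids[grp[0]]}) has "
                    f"{o.size} oxygen atoms; expected exactly 1"
                )
            out.append(o[0])
        return np.asarray(out, dtype=int)


@dataclass
class FrameSet:
    """Ordered frames plus an ensemble kind and optional per-frame weights."""

    frames: list[Frame]
    kind: str = "system"  # "system" | "buffer"
    weights: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("system", "buffer"):
            raise ValueError(f"kind must be 'system' or 'buffer', got {self.kind!r}")
        if not self.frames:
            raise ValueError("FrameSet needs at least one frame")
        counts = {int(f.solute_mask.sum()) for f in self.frames}
        if self.kind == "system" and len(counts) > 1:
            raise ValueError(f"inconsistent solute atom counts across frames: {sorted(counts)}")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != len(self.frames):
                raise ValueError("weights length must match frame count")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _is_water(resname: str, water_resnames: frozenset[str] = WATER_RESNAMES) -> bool:
    return resname.strip().upper() in water_resnames


def read_structure(path: str | os.PathLike, format: str = "auto",
                   water_resnames: frozenset[str] = WATER_RESNAMES) -> Frame:
    """Read a PDB or GRO coordinate file into a :class:`Frame`.

    Elements come from the PDB element column when present, otherwise from
    the atom name.  Residues named SOL/HOH/WAT/TIP* are flagged as solvent.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower() or "pdb"
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported format {fmt!r}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # mass/element guessing chatter
        u = mda.Universe(str(path), format=fmt.upper())
    atoms = u.atoms
    coords = atoms.positions.astype(float)  # MDAnalysis: always Angstrom
    names = [str(n) for n in atoms.names]
    resnames = [str(r) for r in atoms.resnames]
    resids = np.asarray(atoms.resids, dtype=int)
    elements = []
    file_elements = getattr(atoms, "elements", None)
    for i, name in enumerate(names):
        el = ""
        if file_elements is not None:
            el = str(file_elements[i]).strip()
            el = el.capitalize() if len(el) > 1 else el.upper()
        if not el:
            try:
                el = element_from_name(name, resnames[i])
            except ValueError as exc:
                raise ValueError(f"{path}: atom {i + 1}: {exc}") from exc
        elements.append(el)
    roles = ["solvent" if _is_water(r, water_resnames) else "solute" for r in resnames]
    box = None
    if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
        if not np.allclose(u.dimensions[3:], 90.0):
            raise ValueError(f"{path}: only orthorhombic boxes are supported")
        box = u.dimensions[:3].astype(float)
    return Frame(coords, elements, resnames, resids, roles, names=names, box=box)


def read_frameset(dir_or_list: str | os.PathLike | Iterable[str | os.PathLike],
                  kind: str = "system", format: str = "auto") -> FrameSet:
    """Read a directory (sorted by filename) or explicit list of coordinate files."""
    if isinstance(dir_or_list, (str, os.PathLike)):
        d = Path(dir_or_list)
        paths = sorted(
            p for p in d.iterdir() if p.suffix.lower() in (".pdb", ".gro")
        ) if d.is_dir() else []
    else:
        paths = [Path(p) for p in dir_or_list]
    if not paths:
        raise ValueError("no coordinate files to read")
    frames = []
    n_solute = None
    for k, p in enumerate(paths):
        fr = read_structure(p, format=format)
        ns = int(fr.solute_mask.sum())
        if kind == "system":
            if n_solute is None:
                n_solute = ns
            elif ns != n_solute:
                raise ValueError(
                    f"frame {k + 1} ({p.name}): {ns} solute atoms, expected {n_solute}"
                )
        frames.append(fr)
    return FrameSet(frames, kind=kind)


def write_gro(frame: Frame, path: str | os.PathLike, title: str = "hydrashell frame") -> None:
    """Write a frame as a GROMACS GRO file (coordinates converted to nm)."""
    path = Path(path)
    n = len(frame)
    lines = [title, f"{n:5d}"]
    for i in range(n):
        resid = int(frame.residue_ids[i]) % 100000
        x, y, z = frame.coords[i] / 10.0
        lines.append(
            f"{resid:5d}{str(frame.residue_names[i])[:5]:<5s}"
            f"{str(frame.names[i])[:5]:>5s}{(i + 1) % 100000:5d}"
            f"{x:8.3f}{y:8.3f}{z:8.3f}"
        )
    box = frame.box if frame.box is not None else np.zeros(3)
    lines.append(f"{box[0] / 10.0:10.5f}{box[1] / 10.0:10.5f}{box[2] / 10.0:10.5f}")
    path.write_text("\n".join(lines) + "\n")


def write_saxs_curve(curve, path: str | os.PathLike) -> None:
    """Write a SAXS curve as 3-column text: q (1/nm), I (e^2), sigma (e^2)."""
    q = np.asarray(curve.q, dtype=float)
    I = np.asarray(curve.I, dtype=float)
    if q.size == 0:
        raise ValueError("cannot write an empty curve")
    sigma = getattr(curve, "sigma", None)
    sigma = np.zeros_like(I) if sigma is None else np.asarray(sigma, dtype=float)
    header = ["# SAXS curve (buffer-subtracted, orientationally averaged)",
              "# q[1/nm]  I[e^2]  sigma[e^2]"]
    meta = getattr(curve, "metadata", None)
    if meta:
        for k in sorted(meta):
            header.append(f"# {k} = {meta[k]}")
    rows = [f"{qi:.12e} {Ii:.12e} {si:.12e}" for qi, Ii, si in zip(q, I, sigma)]
    Path(path).write_text("\n".join(header + rows) + "\n")


def read_saxs_curve(path: str | os.PathLike):
    """Read back a 3-column SAXS curve written by :func:`write_saxs_curve`."""
    from .saxs_core import SaxsCurve

    data = np.loadtxt(path, comments="#", ndmin=2)
    return SaxsCurve(q=data[:, 0], I=data[:, 1], sigma=data[:, 2], metadata={})
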