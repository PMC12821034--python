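"""Solute-anchored envelope selecting the solvent that scatters.

The envelope is the distance-``d`` dilation of the union of solute
coordinates over all system frames: a point is inside iff its distance
to that reference cloud is at most ``d`` (default 9 A, large enough to
contain the whole hydration shell).  The *same* envelope instance
filters both the system and the buffer ensembles, mirroring the
experimental sample-minus-buffer protocol.

Water molecules are kept whole: a molecule is selected iff its oxygen
lies inside the envelope, so selected solvent always carries an integer
number of 10-electron units.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .model_io import Frame, FrameSet

__all__ = ["Envelope", "build_envelope", "select_solvent", "envelope_volume"]


class Envelope:
    """Distance-d dilation of a reference solute point cloud (Angstrom)."""

    def __init__(self, reference_cloud: np.ndarray, d: float = 9.0):
        cloud = np.asarray(reference_cloud, dtype=float).reshape(-1, 3)
        if len(cloud) == 0:
            raise ValueError("envelope needs at least one solute atom")
        if d < 0:
            raise ValueError("margin d must be non-negative")
        self.cloud = cloud
        self.d = float(d)
        self._tree = cKDTree(cloud)
        self._mc_volume: tuple[float, float] | None = None

    def inside(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: distance to the reference cloud <= d."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        dist, _ = self._tree.query(pts.reshape(-1, 3))
        mask = dist <= self.d
        return bool(mask[0]) if single else mask

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        lo = self.cloud.min(axis=0) - self.d
        hi = self.cloud.max(axis=0) + self.d
        return lo, hi

    @property
    def center(self) -> np.ndarray:
        lo, hi = self.bounding_box
        return (lo + hi) / 2.0


def build_envelope(system: FrameSet, d: float = 9.0) -> Envelope:
    """Envelope around the union of solute coordinates of all system frames."""
    clouds = [fr.coords[fr.solute_mask] for fr in system]
    cloud = np.vstack([c for c in clouds if len(c)]) if clouds else np.zeros((0, 3))
    return Envelope(cloud, d=d)


def select_solvent(frame: Frame, env: Envelope, recenter: bool = False) -> Frame:
    """Subset of ``frame`` that contributes to scattering.

    Whole water molecules are included iff their oxygen is inside the
    envelope; solute atoms are always included.  With ``recenter`` the
    frame (typically a buffer frame) is first translated so its box
    center coincides with the envelope's bounding-box center.
    """
    coords = frame.coords
    if recenter:
        if frame.box is None:
            raise ValueError("recenter requires a periodic box")
        shift = env.center - frame.box / 2.0
        coords = coords + shift
    keep = frame.solute_mask.copy()
    o_idx = frame.solvent_oxygen_indices()
    if o_idx.size:
        inside_o = env.inside(coords[o_idx])
        for grp, ok in zip(frame.solvent_molecules(), inside_o):
            if ok:
                keep[grp] = True
    sub = frame.subset(keep)
    if recenter:
        sub.coords = coords[keep]
    return sub


def envelope_volume(env: Envelope, n_mc: int = 100_000, seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo envelope volume in A^3 with its binomial standard error."""
    if n_mc < 10_000:
        raise ValueError("need at least 1e4 Monte-Carlo samples")
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 7]))
    lo, hi = env.bounding_box
    vol_box = float(np.prod(hi - lo))
    pts = rng.random((n_mc, 3)) * (hi - lo) + lo
    hits = env.inside(pts)
    p = float(np.mean(hits))
    se = float(np.sqrt(max(p * (1 - p), 0.0) / n_mc))
    result = (p * vol_box, se * vol_box)
    env._mc_volume = result
    return result
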