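"""Guinier analysis, hydration-induced Rg shift, and contrast decomposition.

At low momentum transfer a SAXS curve obeys the Guinier law
``ln I(q) = ln I0 - q^2 Rg^2 / 3``; a weighted linear fit of ln I
against q^2 over the window q * Rg <= 1.3 yields the forward scattering
I0 and the scattering radius of gyration Rg_SAXS (which includes the
hydration shell).  The bare-solute Rg_prot is the electron-weighted
radius of gyration of the solute coordinates, and

    dRg = Rg_SAXS - Rg_prot

is the hydration-shell footprint on Rg: positive when excess shell
density sits far from the contrast-weighted center.

The total contrast splits into solute and shell parts,

    dNe_total = (Ne_prot - rho_solv * V_prot) + dNe_hs,

with rho_solv = 334 e/nm^3 and V_prot the probe-excluded solute volume.
The sign ambiguity of taking sqrt(I0) is avoided by using the signed
zero-angle amplitude difference that the explicit-solvent calculation
already provides.  dNe_hs / 10 is the shell excess in water molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formfactors import FormFactorTable, default_table
from .model_io import FrameSet
from .saxs_core import SaxsCurve

__all__ = [
    "GuinierResult",
    "ContrastResult",
    "DeltaRg",
    "guinier_fit",
    "rg_protein",
    "delta_rg",
    "decompose_contrast",
]

RHO_SOLV_DEFAULT = 334.0  # e/nm^3, experimental bulk water electron density


@dataclass
class GuinierResult:
    I0: float               # e^2
    rg_saxs: float          # Angstrom
    I0_se: float
    rg_se: float
    q_window: tuple[float, float]   # 1/nm
    n_points: int


@dataclass
class ContrastResult:
    ne_prot: float          # e
    v_prot: float           # nm^3
    v_prot_se: float
    rho_solv: float         # e/nm^3
    dne_prot: float         # e
    dne_total: float        # signed e
    dne_hs: float           # e
    dne_hs_se: float
    metadata: dict = field(default_factory=dict)

    @property
    def waters_hs(self) -> float:
        """Shell contrast in water-molecule equivalents (dNe_hs / 10)."""
        return self.dne_hs / 10.0

    @property
    def waters_hs_se(self) -> float:
        return self.dne_hs_se / 10.0


@dataclass
class DeltaRg:
    rg_saxs: float
    rg_prot: float
    delta: float
    se: float


def guinier_fit(curve: SaxsCurve, qrg_limit: float = 1.3, min_points: int = 5) -> GuinierResult:
    """Iterative weighted Guinier fit of ln I vs q^2.

    The window starts from all positive-intensity points above q = 0 and
    shrinks until q_hi * Rg <= ``qrg_limit`` is self-consistent.  Points
    with non-positive intensity are skipped; weights are sigma-based
    when the curve carries finite errors, else uniform.
    """
    q = curve.q          # 1/nm
    I = curve.I
    sig = curve.sigma
    usable = (q > 0) & (I > 0) & np.isfinite(I)
    if usable.sum() < min_points:
        raise ValueError(f"need at least {min_points} positive low-q points for Guinier fit")

    def fit(mask):
        x = (q[mask] / 10.0) ** 2          # 1/A^2, so Rg comes out in A
        y = np.log(I[mask])
        s = sig[mask]
        if np.all(s > 0):
            w = (I[mask] / s) ** 2          # var(ln I) = (sigma/I)^2
        else:
            w = np.ones_like(x)
        W = np.sum(w)
        xm = np.sum(w * x) / W
        ym = np.sum(w * y) / W
        sxx = np.sum(w * (x - xm) ** 2)
        if sxx <= 0:
            raise ValueError("degenerate Guinier window (all q equal)")
        slope = np.sum(w * (x - xm) * (y - ym)) / sxx
        intercept = ym - slope * xm
        # covariance of weighted LS (assuming the quoted sigmas)
        if np.all(s > 0):
            var_slope = 1.0 / sxx
            var_intercept = 1.0 / W + xm**2 / sxx
        else:  # scale by residual variance
            n = len(x)
            resid = y - (intercept + slope * x)
            dof = max(n - 2, 1)
            s2 = np.sum(w * resid**2) / dof
            var_slope = s2 / sxx
            var_intercept = s2 * (1.0 / W + xm**2 / sxx)
        return slope, intercept, var_slope, var_intercept

    mask = usable.copy()
    prev_key = None
    for _ in range(20):
        slope, intercept, vs, vi = fit(mask)
        rg2 = -3.0 * slope                 # A^2
        rg = float(np.sqrt(rg2)) if rg2 > 0 else 0.0
        if rg > 0:
            q_hi = qrg_limit / (rg / 10.0)  # 1/nm
        else:
            q_hi = q[usable].max()
        new_mask = usable & (q <= q_hi)
        if new_mask.sum() < min_points:
            # keep the lowest min_points usable q values
            idx = np.flatnonzero(usable)[:min_points]
            new_mask = np.zeros_like(usable)
            new_mask[idx] = True
        key = new_mask.tobytes()
        if key == prev_key or np.array_equal(new_mask, mask):
            mask = new_mask
            break
        prev_key = mask.tobytes()
        mask = new_mask
    else:
        raise ValueError("Guinier window did not converge in 20 iterations")

    slope, intercept, vs, vi = fit(mask)
    rg2 = -3.0 * slope
    if rg2 <= 0:
        raise ValueError("negative Guinier slope: no positive Rg^2 in the fit window")
    rg = float(np.sqrt(rg2))
    I0 = float(np.exp(intercept))
    rg_se = float(3.0 * np.sqrt(vs) / (2.0 * rg))
    qs = q[mask]
    return GuinierResult(
        I0=I0,
        rg_saxs=rg,
        I0_se=float(I0 * np.sqrt(vi)),
        rg_se=rg_se,
        q_window=(float(qs.min()), float(qs.max())),
        n_points=int(mask.sum()),
    )


def rg_protein(system: FrameSet, table: FormFactorTable | None = None,
               weighting: str = "electron") -> tuple[float, float]:
    """Bare-solute radius of gyration (A), mean +/- SE over frames.

    Weights are zero-angle electron counts per atom (``electron``,
    default) or unity (``uniform``).
    """
    tab = table or default_table()
    values = []
    for fr in system:
        sol = fr.subset(fr.solute_mask)
        if len(sol) == 0:
            raise ValueError("frame has no solute atoms")
        if weighting == "electron":
            w = np.array([0.0 if el == "M" else tab.f0(str(el)) for el in sol.elements])
        elif weighting == "uniform":
            w = np.ones(len(sol))
        else:
            raise ValueError(f"unknown weighting {weighting!r}")
        W = w.sum()
        center = (w[:, None] * sol.coords).sum(axis=0) / W
        rg2 = float(np.sum(w * np.sum((sol.coords - center) ** 2, axis=1)) / W)
        values.append(np.sqrt(rg2))
    values = np.asarray(values)
    se = float(values.std(ddof=1) / np.sqrt(len(values))) if len(values) > 1 else 0.0
    return float(values.mean()), se


def delta_rg(guinier: GuinierResult, rg_prot: tuple[float, float]) -> DeltaRg:
    """Hydration-shell Rg shift Rg_SAXS - Rg_prot with errors in quadrature."""
    rp, rp_se = rg_prot
    return DeltaRg(
        rg_saxs=guinier.rg_saxs,
        rg_prot=rp,
        delta=guinier.rg_saxs - rp,
        se=float(np.hypot(guinier.rg_se, rp_se)),
    )


def decompose_contrast(
    signed_dne_total: float,
    ne_prot: float,
    v_prot: float,
    rho_solv: float = RHO_SOLV_DEFAULT,
    signed_dne_se: float = 0.0,
    v_prot_se: float = 0.0,
) -> ContrastResult:
    """Split the signed total contrast into solute and hydration-shell parts.

    ``signed_dne_total`` is Re[<A(0)> - <B(0)>] from the scattering
    calculation (resolving the sign that a bare sqrt(I0) would leave
    ambiguous); ``v_prot`` in nm^3.
    """
    if v_prot <= 0:
        raise ValueError("protein volume must be positive")
    dne_prot = ne_prot - rho_solv * v_prot
    dne_hs = signed_dne_total - dne_prot
    se = float(np.hypot(signed_dne_se, rho_solv * v_prot_se))
    return ContrastResult(
        ne_prot=float(ne_prot),
        v_prot=float(v_prot),
        v_prot_se=float(v_prot_se),
        rho_solv=float(rho_solv),
        dne_prot=float(dne_prot),
        dne_total=float(signed_dne_total),
        dne_hs=float(dne_hs),
        dne_hs_se=se,
    )
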