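"""Per-site contrast/Rg scores, pairwise modification deltas, error models.

Two error models mirror how trajectory and ensemble statistics are
summarized: contiguous time-block averaging (10 blocks by default) for
a single trajectory, and the plain standard error over independent
conformations for ensembles.

Scores compare variants of the same solute against a reference variant
(alanine in the amino-acid application): the per-site contrast score is
the excess shell water count relative to the reference divided by the
number of mutated sites, and analogously for the Rg shift.  Variants
come from separate simulations, so their errors combine in quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariantResult",
    "ScoreTable",
    "block_error",
    "conformation_error",
    "per_site_score",
    "pairwise_delta",
]


@dataclass
class VariantResult:
    label: str
    waters_hs: float
    waters_hs_se: float
    dne_hs: float
    dne_hs_se: float
    delta_rg: float = np.nan
    delta_rg_se: float = np.nan
    n_sites: int = 1

    def __post_init__(self):
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")


@dataclass
class ScoreTable:
    reference: str
    table: pd.DataFrame  # index: variant; columns: score_contrast, score_contrast_se, score_rg, score_rg_se
    metadata: dict = field(default_factory=dict)


def block_error(series: np.ndarray, n_blocks: int = 10) -> float:
    """SE of the mean from contiguous equal time blocks (remainder to last).

    Robust to autocorrelation on scales shorter than the block length;
    a correlated series yields a larger SE than the naive iid estimate.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < n_blocks:
        raise ValueError(f"series of length {len(x)} cannot form {n_blocks} blocks")
    size = len(x) // n_blocks
    means = [
        x[b * size: (b + 1) * size if b < n_blocks - 1 else len(x)].mean()
        for b in range(n_blocks)
    ]
    return float(np.std(means, ddof=1) / np.sqrt(n_blocks))


def conformation_error(values: np.ndarray) -> tuple[float, float]:
    """Mean and SE over independent conformations (SD / sqrt(n))."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 conformations")
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))


def per_site_score(results: list[VariantResult], reference: str = "ALA") -> ScoreTable:
    """Per-site scores of every variant relative to the reference variant.

    score_contrast is in waters per site, score_rg in Angstrom per site;
    the reference row is exactly 0 +/- 0 by construction.
    """
    by_label = {r.label: r for r in results}
    if reference not in by_label:
        raise ValueError(f"reference variant {reference!r} not present")
    ref = by_label[reference]
    n_sites = {r.n_sites for r in results}
    if len(n_sites) != 1:
        raise ValueError(f"variants disagree on n_sites: {sorted(n_sites)}")
    ns = ref.n_sites
    rows = {}
    for r in results:
        if r.label == reference:
            rows[r.label] = (0.0, 0.0, 0.0, 0.0)
            continue
        sc = (r.waters_hs - ref.waters_hs) / ns
        sc_se = float(np.hypot(r.waters_hs_se, ref.waters_hs_se)) / ns
        sr = (r.delta_rg - ref.delta_rg) / ns
        sr_se = float(np.hypot(r.delta_rg_se, ref.delta_rg_se)) / ns
        rows[r.label] = (sc, sc_se, sr, sr_se)
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["score_contrast", "score_contrast_se", "score_rg", "score_rg_se"],
    )
    df.index.name = "variant"
    return ScoreTable(reference=reference, table=df, metadata={"n_sites": ns})


def pairwise_delta(results: list[VariantResult], from_label: str, to_label: str,
                   per_site: bool = True) -> tuple[float, float]:
    """Change of shell contrast (electrons) for a chemical modification.

    Returns (dne_hs(to) - dne_hs(from), SE in quadrature), divided by
    the site count when ``per_site`` (the scale on which single-residue
    modifications are tabulated).
    """
    by_label = {r.label: r for r in results}
    for lab in (from_label, to_label):
        if lab not in by_label:
            raise ValueError(f"variant {lab!r} not present")
    a, b = by_label[from_label], by_label[to_label]
    div = a.n_sites if per_site else 1
    delta = (b.dne_hs - a.dne_hs) / div
    se = float(np.hypot(a.dne_hs_se, b.dne_hs_se)) / div
    return float(delta), se
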