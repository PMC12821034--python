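"""Atomic X-ray form factors.

Atomic scattering amplitudes are parameterized with the standard
four-Gaussian Cromer-Mann fit,

    f(s) = sum_i a_i exp(-b_i s^2) + c,      s = q_A / (4 pi),

with ``q_A`` the momentum transfer in 1/A.  Throughout the package the
momentum transfer ``q`` is expressed in 1/nm; the conversion to the
``s``-convention of the Cromer-Mann tables happens in this module only.

At zero angle ``f(0) = sum_i a_i + c`` equals the electron count of the
neutral atom, which is what enters the protein electron number and the
10-electron bookkeeping of water in the contrast decomposition.

Point scatterers (flat ``f(q) = Z``) can be registered for synthetic
coarse-grained sites; they are used by the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "CromerMannCoeffs",
    "FormFactorTable",
    "default_table",
    "formfactor",
    "molecule_electrons",
]

_FOURPI = 4.0 * np.pi


@dataclass(frozen=True)
class CromerMannCoeffs:
    """Four-Gaussian coefficients: a (e), b (A^2), constant c (e)."""

    a: tuple[float, float, float, float]
    b: tuple[float, float, float, float]
    c: float

    def f0(self) -> float:
        return float(sum(self.a) + self.c)

    def __call__(self, q_nm: np.ndarray | float) -> np.ndarray | float:
        """Evaluate f(q) for q in 1/nm."""
        q = np.asarray(q_nm, dtype=float)
        s2 = (q / (10.0 * _FOURPI)) ** 2  # q[1/nm] -> q[1/A] -> s, squared
        a = np.asarray(self.a)
        b = np.asarray(self.b)
        out = np.exp(-np.multiply.outer(s2, b)) @ a + self.c
        return out if out.shape else float(out)


class FormFactorTable:
    """Element -> Cromer-Mann coefficient lookup.

    The default table covers H, C, N, O, P, S, Na, Cl.  Additional
    entries (e.g. flat point-scatterer pseudo-elements for synthetic
    solutes) can be registered on a copy via :meth:`with_point_atom`.
    """

    def __init__(self, coeffs: dict[str, CromerMannCoeffs]):
        self._coeffs = dict(coeffs)

    def __contains__(self, element: str) -> bool:
        return element in self._coeffs

    def elements(self) -> list[str]:
        return sorted(self._coeffs)

    def get(self, element: str) -> CromerMannCoeffs:
        try:
            return self._coeffs[element]
        except KeyError:
            raise KeyError(
                f"no form-factor entry for element {element!r}; "
                f"known: {', '.join(self.elements())}"
            ) from None

    def with_point_atom(self, element: str, electrons: float) -> "FormFactorTable":
        """Return a copy with a q-independent scatterer of given electron count."""
        coeffs = dict(self._coeffs)
        coeffs[element] = CromerMannCoeffs((0.0, 0.0, 0.0, 0.0), (0.0, 0.0, 0.0, 0.0), float(electrons))
        return FormFactorTable(coeffs)

    def f0(self, element: str) -> float:
        return self.get(element).f0()

    def formfactor(self, element: str, q_nm: np.ndarray | float):
        """f(q) in electrons for q (scalar or array) in 1/nm."""
        q = np.asarray(q_nm, dtype=float)
        if np.any(q < 0):
            raise ValueError("q must be non-negative")
        return self.get(element)(q_nm)


def _load_default() -> FormFactorTable:
    coeffs: dict[str, CromerMannCoeffs] = {}
    text = resources.files("hydrashell.data").joinpath("cromer_mann.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        el = parts[0]
        vals = [float(x) for x in parts[1:]]
        coeffs[el] = CromerMannCoeffs(tuple(vals[0:4]), tuple(vals[4:8]), vals[8])
    return FormFactorTable(coeffs)


_DEFAULT: FormFactorTable | None = None


def default_table() -> FormFactorTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = _load_default()
    return _DEFAULT


def formfactor(element: str, q_nm: np.ndarray | float, table: FormFactorTable | None = None):
    """Atomic form factor f(q) in electrons, q in 1/nm."""
    return (table or default_table()).formfactor(element, q_nm)


def molecule_electrons(composition: dict[str, int], table: FormFactorTable | None = None) -> float:
    """Zero-angle electron count of a molecule given as {element: count}.

    ``{"O": 1, "H": 2}`` evaluates to 10.0 e within coefficient rounding,
    the per-molecule electron count used for water throughout.
    """
    tab = table or default_table()
    return float(sum(n * tab.f0(el) for el, n in composition.items()))
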