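"""Monoisotopic mass and adduct m/z arithmetic.

Used to verify metabolite ion assignments: given a molecular formula, the
theoretical m/z of singly charged adducts ([M+H]+, [M+Na]+, dehydration
fragments [M+H-kH2O]+, ...) is the neutral monoisotopic mass plus the
cation mass (electron-corrected), and agreement with a measured ion is
reported as a signed ppm error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

#: Electron-corrected masses of the charge carriers (Da).
PROTON_MASS = 1.007276
SODIUM_CATION_MASS = 22.989218
POTASSIUM_CATION_MASS = 38.963158
AMMONIUM_CATION_MASS = 18.033823

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _load_element_masses() -> dict[str, float]:
    text = resources.files("bgcnet.data").joinpath("element_masses.tsv").read_text()
    masses = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        element, mass = line.split("\t")
        masses[element] = float(mass)
    return masses


ELEMENT_MASSES = _load_element_masses()
WATER_MASS = 2 * ELEMENT_MASSES["H"] + ELEMENT_MASSES["O"]


@dataclass(frozen=True)
class Formula:
    """Element -> count map with a canonical Hill-order string form."""

    counts: tuple[tuple[str, int], ...]

    @property
    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __str__(self) -> str:
        d = self.as_dict
        parts = []
        for el in ("C", "H"):
            if el in d:
                parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        for el in sorted(set(d) - {"C", "H"}):
            parts.append(el + (str(d[el]) if d[el] > 1 else ""))
        return "".join(parts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = self.as_dict
        for el, n in other.as_dict.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(tuple(sorted(merged.items())))


def parse_formula(s: str) -> Formula:
    """Parse a Hill-notation-like formula string, e.g. ``C29H38N2O6``."""
    s = s.strip()
    if not s:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(s):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {s!r} at position {pos}")
        element, digits = match.groups()
        if element not in ELEMENT_MASSES:
            raise ValueError(
                f"unknown element {element!r}; supported: {sorted(ELEMENT_MASSES)}"
            )
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(s):
        raise ValueError(f"cannot parse formula {s!r} at position {pos}")
    return Formula(tuple(sorted(counts.items())))


def monoisotopic_mass(f: Formula) -> float:
    """Sum of most-abundant-isotope atomic masses, in Da."""
    return sum(ELEMENT_MASSES[el] * n for el, n in f.counts)


def _normalize_adduct(label: str) -> str:
    return label.replace("−", "-").replace(" ", "")


_DEHYDRATION = re.compile(r"^\[M\+H-(\d*)H2O\]\+$")

_SIMPLE_ADDUCTS = {
    "[M+H]+": PROTON_MASS,
    "[M+Na]+": SODIUM_CATION_MASS,
    "[M+K]+": POTASSIUM_CATION_MASS,
    "[M+NH4]+": AMMONIUM_CATION_MASS,
}


def adduct_offset(adduct: str) -> float:
    """Mass offset (Da) added to the neutral monoisotopic mass M."""
    label = _normalize_adduct(adduct)
    if label in _SIMPLE_ADDUCTS:
        return _SIMPLE_ADDUCTS[label]
    match = _DEHYDRATION.match(label)
    if match:
        k = int(match.group(1) or 1)
        return PROTON_MASS - k * WATER_MASS
    supported = sorted(_SIMPLE_ADDUCTS) + ["[M+H-H2O]+", "[M+H-2H2O]+", "..."]
    raise ValueError(f"unsupported adduct {adduct!r}; supported: {supported}")


def adduct_mz(f: Formula, adduct: str) -> float:
    """Theoretical m/z of a singly charged adduct or dehydration fragment."""
    return monoisotopic_mass(f) + adduct_offset(adduct)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative deviation in parts per million."""
    if observed <= 0 or theoretical <= 0:
        raise ValueError("m/z values must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def load_reference_compounds() -> dict[str, Formula]:
    """Named reference compounds shipped with the package (name -> formula)."""
    text = resources.files("bgcnet.data").joinpath("reference_compounds.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, formula, _note = line.split("\t")
        out[name] = parse_formula(formula)
    return out


def mass_check(
    formula: Formula, assignments: list[tuple[str, float]]
) -> list[dict]:
    """Verify (adduct label, observed m/z) assignments against theory."""
    rows = []
    for adduct, observed in assignments:
        theo = adduct_mz(formula, adduct)
        rows.append(
            {
                "formula": str(formula),
                "adduct": _normalize_adduct(adduct),
                "theoretical_mz": theo,
                "observed_mz": observed,
                "ppm_error": ppm_error(observed, theo),
            }
        )
    return rows
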