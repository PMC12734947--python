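"""Molecular formulas over the CHNOPS element set.

Everything downstream of the mass spectrometer speaks in terms of
:class:`ElementCounts`: integer atom counts over carbon, hydrogen, nitrogen,
oxygen, phosphorus and sulfur, the six biologically dominant elements that the
formula-assignment stage permits.  This module provides the monoisotopic-mass
arithmetic, the [M-H]- adduct conversion used in negative-ionisation mode,
ring-and-double-bond equivalents (RDBE), and the element-ratio plausibility
rules of the Seven-Golden-Rules family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields, replace

ELEMENTS = ("c", "h", "n", "o", "p", "s")

#: Mass of the lightest stable isotope of each element (Da).
MONOISOTOPIC_MASS = {
    "c": 12.0,
    "h": 1.0078250319,
    "n": 14.0030740052,
    "o": 15.9949146221,
    "p": 30.97376151,
    "s": 31.97207069,
}

#: Proton mass (Da); the electron mass is implicitly carried in this value,
#: the standard convention for deprotonated negative-mode ions.
PROTON_MASS = 1.007276466


@dataclass(frozen=True, order=True)
class ElementCounts:
    """Atom counts of a CHNOPS molecular formula.

    Counts are non-negative integers for real formulas; composite (averaged)
    formulas use :class:`soilstoich.stoichiometry.CompositeFormula` instead,
    which carries rational counts.
    """

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    p: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            v = getattr(self, el)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"element count {el}={v!r} must be a non-negative integer")
        if self.total_atoms() < 1:
            raise ValueError("a formula must contain at least one atom")

    def total_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.p + self.s

    def as_tuple(self) -> tuple[int, int, int, int, int, int]:
        return (self.c, self.h, self.n, self.o, self.p, self.s)

    def hill_formula(self) -> str:
        """Formula string in Hill order (C, H, then other elements alphabetically)."""
        return hill_formula(dict(zip(ELEMENTS, self.as_tuple())))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


def hill_formula(counts: dict[str, int | float]) -> str:
    """Hill-order formula string from a lowercase element->count mapping.

    Carbon first, hydrogen second, remaining elements alphabetically; counts of
    one are written without a digit, zero counts are omitted.  Float counts
    (composites) are rendered with up to four decimals, trailing zeros trimmed.
    """

    def fmt(el: str, v: int | float) -> str:
        if v == 0:
            return ""
        sym = el.upper()
        if v == 1:
            return sym
        if isinstance(v, float) and not float(v).is_integer():
            return f"{sym}{v:.4f}".rstrip("0").rstrip(".")
        return f"{sym}{int(v)}"

    ordered = ["c", "h"] + sorted(el for el in counts if el not in ("c", "h"))
    return "".join(fmt(el, counts.get(el, 0)) for el in ordered)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a plain formula string like ``C6H12O6`` into :class:`ElementCounts`.

    Only C, H, N, O, P, S are accepted; anything else raises ``ValueError``.
    """
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text.strip()):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        pos = m.end()
        el = m.group(1).lower()
        if el not in counts:
            raise ValueError(f"element {m.group(1)!r} is outside the CHNOPS set")
        counts[el] += int(m.group(2)) if m.group(2) else 1
    if pos != len(text.strip()):
        raise ValueError(f"cannot parse formula {text!r}")
    return ElementCounts(**counts)


def monoisotopic_mass(f: ElementCounts) -> float:
    """Neutral monoisotopic mass in Da (sum of lightest-isotope atomic masses)."""
    return sum(getattr(f, el) * MONOISOTOPIC_MASS[el] for el in ELEMENTS)


def neutral_mass_from_mz(mz: float, adduct: str = "[M-H]-") -> float:
    """Neutral monoisotopic mass from an observed m/z for a supported adduct.

    Only the deprotonated negative-mode ion [M-H]- is supported: M = m/z + m_p.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    _check_adduct(adduct)
    return mz + PROTON_MASS


def mz_from_neutral_mass(mass: float, adduct: str = "[M-H]-") -> float:
    """Inverse of :func:`neutral_mass_from_mz`."""
    if mass <= PROTON_MASS:
        raise ValueError("neutral mass must exceed the proton mass")
    _check_adduct(adduct)
    return mass - PROTON_MASS


def _check_adduct(adduct: str) -> None:
    # accept common unicode spellings of the minus sign
    canonical = adduct.replace("−", "-").replace("⁻", "-")
    if canonical not in ("[M-H]-", "[M-H]"):
        raise ValueError(f"unsupported adduct {adduct!r}; only [M-H]- is implemented")


def rdbe(f: ElementCounts | dict) -> float:
    """Ring-and-double-bond equivalents: C - H/2 + (N + P)/2 + 1.

    O and S are taken divalent (no contribution); P is treated trivalent by
    default, the usual choice for most organics.  May be half-integral, which
    the nitrogen-rule parity check reports on.
    """
    if isinstance(f, dict):
        c, h, n, p = f.get("c", 0), f.get("h", 0), f.get("n", 0), f.get("p", 0)
    else:
        c, h, n, p = f.c, f.h, f.n, f.p
    return c - h / 2.0 + (n + p) / 2.0 + 1.0


@dataclass(frozen=True)
class FormulaRules:
    """Element-ratio and RDBE plausibility rules (Seven-Golden-Rules common ranges).

    All bounds are overridable.  ``min_carbon`` = 0 disables the carbon-ratio
    checks entirely (degenerate inorganic hydrides such as water then pass on
    RDBE alone).  The nitrogen-rule parity of RDBE is *reported*, never used to
    reject: for deprotonated even/odd-electron ions the bookkeeping is
    ambiguous.
    """

    min_carbon: int = 1
    hc_min: float = 0.2
    hc_max: float = 3.1
    nc_max: float = 1.3
    oc_max: float = 1.2
    pc_max: float = 0.3
    sc_max: float = 0.8
    rdbe_min: float = 0.0


@dataclass(frozen=True)
class RuleReport:
    """Outcome of :func:`element_ratio_rules` with per-rule detail."""

    passed: bool
    failed_rules: tuple[str, ...]
    rdbe: float
    rdbe_integer: bool  # nitrogen-rule parity, informational only


DEFAULT_RULES = FormulaRules()


def element_ratio_rules(f: ElementCounts, rules: FormulaRules = DEFAULT_RULES) -> RuleReport:
    """Check a formula against element-ratio ranges and the RDBE floor.

    Returns a :class:`RuleReport`; ``passed`` is True iff every enforced rule
    holds.  RDBE integrality (nitrogen-rule parity) is recorded but does not
    affect ``passed``.
    """
    failed: list[str] = []
    r = rdbe(f)
    if f.c < rules.min_carbon:
        failed.append("min_carbon")
    elif f.c > 0:
        if not (rules.hc_min <= f.h / f.c <= rules.hc_max):
            failed.append("h_c_range")
        if f.n / f.c > rules.nc_max:
            failed.append("n_c_max")
        if f.o / f.c > rules.oc_max:
            failed.append("o_c_max")
        if f.p / f.c > rules.pc_max:
            failed.append("p_c_max")
        if f.s / f.c > rules.sc_max:
            failed.append("s_c_max")
    if r < rules.rdbe_min:
        failed.append("rdbe_min")
    return RuleReport(
        passed=not failed,
        failed_rules=tuple(failed),
        rdbe=r,
        rdbe_integer=float(r).is_integer(),
    )
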