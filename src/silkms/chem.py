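"""Elemental formulas, isotope masses, label schemes and extraction windows.

Targeted isotopologue quantification monitors one narrow m/z window per
isotopic channel of a compound's diagnostic ion.  This module computes the
exact m/z of each channel (monoisotopic ion mass, shifted by the heavy-isotope
substitutions of a label scheme, corrected for the electron removed on
ionisation) and the natural-abundance isotopologue envelope used to reason
about spectral interference between channels.

Isotope masses and abundances are an embedded NIST/IUPAC table; nothing here
calls out to external services.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Formula",
    "IsotopeTable",
    "ISOTOPES",
    "LabelScheme",
    "MzWindow",
    "IonTarget",
    "LabelingDesign",
    "monoisotopic_mass",
    "ion_mz",
    "labeled_mz",
    "window_for",
    "isotopologue_envelope",
    "build_target_table",
]

#: Mass of the electron in Da (CODATA).
ELECTRON_MASS = 0.000548579909
#: Mass of the proton in Da (CODATA); equals m(1H) - m(e-).
PROTON_MASS = 1.007276466

SUPPORTED_ELEMENTS = frozenset({"C", "H", "N", "O", "P", "S", "F", "Cl"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnknownElementError(ValueError):
    """An element symbol outside the supported set was encountered."""

    def __init__(self, symbol: str):
        self.symbol = symbol
        super().__init__(
            f"unknown element symbol {symbol!r}; supported: "
            + ", ".join(sorted(SUPPORTED_ELEMENTS))
        )


@dataclass(frozen=True)
class Formula:
    """Elemental composition, e.g. ``Formula.parse("C10H9NO2")`` for IAA.

    Counts are strictly positive integers; the empty formula is permitted
    only as the additive identity (mass 0).
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise UnknownElementError(el)
            n = int(n)
            if n < 1:
                raise ValueError(f"atom count for {el} must be >= 1, got {n}")
            clean[el] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "Formula":
        """Parse a Hill-style formula string such as ``"C9H8N"``."""
        text = text.strip()
        if not text:
            return cls({})
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            if not m.group(0):
                break
            sym, num = m.group(1), m.group(2)
            counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
            pos = m.end()
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        return cls(counts)

    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __str__(self) -> str:
        order = ["C", "H"] + sorted(set(self.counts) - {"C", "H"})
        return "".join(
            f"{el}{self.counts[el] if self.counts[el] != 1 else ''}"
            for el in order
            if el in self.counts
        )


# Per element: list of (mass number, exact mass / Da, natural abundance).
# NIST atomic weights and isotopic compositions; lightest isotope first.
_NIST_ISOTOPES: dict[str, list[tuple[int, float, float]]] = {
    "H": [(1, 1.0078250319, 0.999885), (2, 2.0141017779, 0.000115)],
    "C": [(12, 12.0, 0.9893), (13, 13.0033548378, 0.0107)],
    "N": [(14, 14.0030740052, 0.99636), (15, 15.0001088984, 0.00364)],
    "O": [
        (16, 15.9949146221, 0.99757),
        (17, 16.9991315, 0.00038),
        (18, 17.9991604, 0.00205),
    ],
    "P": [(31, 30.97376151, 1.0)],
    "S": [
        (32, 31.97207069, 0.9499),
        (33, 32.97145850, 0.0075),
        (34, 33.96786683, 0.0425),
        (36, 35.96708088, 0.0001),
    ],
    "F": [(19, 18.99840320, 1.0)],
    "Cl": [(35, 34.96885271, 0.7576), (37, 36.96590260, 0.2424)],
}


class IsotopeTable:
    """Exact masses and natural abundances per element.

    Invariants (checked at construction): per element, abundances sum to 1
    within 1e-6 and exact masses increase strictly with mass number.
    """

    def __init__(self, data: Mapping[str, Sequence[tuple[int, float, float]]] | None = None):
        self._data = {el: sorted(rows) for el, rows in (data or _NIST_ISOTOPES).items()}
        for el, rows in self._data.items():
            total = sum(a for _, _, a in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"abundances for {el} sum to {total}, not 1")
            masses = [m for _, m, _ in rows]
            if any(b <= a for a, b in zip(masses, masses[1:])):
                raise ValueError(f"exact masses for {el} not increasing")

    def isotopes(self, element: str) -> list[tuple[int, float, float]]:
        try:
            return self._data[element]
        except KeyError:
            raise UnknownElementError(element) from None

    def lightest_mass(self, element: str) -> float:
        return self.isotopes(element)[0][1]

    def mass_of(self, element: str, mass_number: int) -> float:
        for mn, mass, _ in self.isotopes(element):
            if mn == mass_number:
                return mass
        raise ValueError(f"no isotope {mass_number}{element} in table")

    def heavy_shift(self, element: str, mass_number: int) -> float:
        """Exact-mass increment of one heavy substitution, e.g. 13C -> +1.00335."""
        return self.mass_of(element, mass_number) - self.lightest_mass(element)


#: Default isotope table used throughout.
ISOTOPES = IsotopeTable()

_SCHEME_TOKEN = re.compile(r"(\d+)([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class LabelScheme:
    """Heavy-isotope substitutions, e.g. ``LabelScheme.parse("13C6,15N1")``.

    Each substitution is (element, heavy mass number, number of atoms
    substituted).  An empty scheme is the unlabeled channel.
    """

    substitutions: tuple[tuple[str, int, int], ...] = ()

    @classmethod
    def parse(cls, text: str) -> "LabelScheme":
        text = text.strip().strip("[]")
        if not text:
            return cls()
        subs = []
        for part in re.split(r"[,\s]+", text):
            m = _SCHEME_TOKEN.fullmatch(part)
            if not m:
                raise ValueError(f"cannot parse label token {part!r}")
            mass_number, el, count = int(m.group(1)), m.group(2), m.group(3)
            subs.append((el, mass_number, int(count) if count else 1))
        return cls(tuple(subs))

    def validate(self, formula: Formula, table: IsotopeTable = ISOTOPES) -> None:
        """Raise if substitutions exceed available atoms or name unknown isotopes."""
        per_element: dict[str, int] = {}
        for el, mn, n in self.substitutions:
            table.mass_of(el, mn)  # raises if absent
            per_element[el] = per_element.get(el, 0) + n
        for el, n in per_element.items():
            if n > formula[el]:
                raise ValueError(
                    f"label scheme substitutes {n} {el} atoms but formula "
                    f"{formula} has only {formula[el]}"
                )

    def mass_shift(self, table: IsotopeTable = ISOTOPES) -> float:
        return sum(n * table.heavy_shift(el, mn) for el, mn, n in self.substitutions)

    def __bool__(self) -> bool:
        return bool(self.substitutions)

    def __str__(self) -> str:
        if not self.substitutions:
            return "unlabeled"
        return ",".join(f"{mn}{el}{n}" for el, mn, n in self.substitutions)


def monoisotopic_mass(formula: Formula, table: IsotopeTable = ISOTOPES) -> float:
    """Sum of lightest-isotope exact masses over all atoms, in Da."""
    return sum(n * table.lightest_mass(el) for el, n in formula.counts.items())


def ion_mz(
    formula: Formula,
    charge: int = 1,
    protonated: bool = False,
    table: IsotopeTable = ISOTOPES,
) -> float:
    """m/z of a cation given as its formula, optionally protonated.

    The formula of a non-protonated target (e.g. the quinolinium fragment
    C9H8N+) is the cation's own composition; one electron mass per positive
    charge is subtracted.  Only singly charged positive ions are in scope.
    """
    if charge != 1:
        raise ValueError(f"only charge +1 supported, got {charge}")
    mass = monoisotopic_mass(formula, table)
    if protonated:
        mass += table.lightest_mass("H")
    return (mass - charge * ELECTRON_MASS) / charge


def labeled_mz(base_ion_mz: float, scheme: LabelScheme, table: IsotopeTable = ISOTOPES) -> float:
    """Shift an ion m/z by a label scheme's exact-mass increment (charge +1)."""
    return base_ion_mz + scheme.mass_shift(table)


@dataclass(frozen=True)
class MzWindow:
    """Closed m/z interval used for chromatogram extraction."""

    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"window low {self.low} must be < high {self.high}")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, mz: float) -> bool:
        return self.low <= mz <= self.high

    def overlaps(self, other: "MzWindow") -> bool:
        return self.low <= other.high and other.low <= self.high

    def rounded(self, ndigits: int = 4) -> "MzWindow":
        return MzWindow(round(self.low, ndigits), round(self.high, ndigits))


DEFAULT_HALF_WIDTH = 0.0010  # m/z; matches the narrow extraction ranges used


def window_for(mz: float, half_width: float = DEFAULT_HALF_WIDTH, ppm: bool = False) -> MzWindow:
    """Symmetric extraction window around an exact m/z.

    Bounds are reported rounded to 4 decimal places (round-half-even), the
    convention under which the published quinolinium windows are reproduced
    exactly.  ``ppm=True`` interprets ``half_width`` in parts per million.
    """
    if half_width <= 0:
        raise ValueError(f"half-width must be positive, got {half_width}")
    hw = mz * half_width * 1e-6 if ppm else half_width
    return MzWindow(round(mz - hw, 4), round(mz + hw, 4))


def isotopologue_envelope(
    formula: Formula,
    max_shift: int,
    table: IsotopeTable = ISOTOPES,
) -> np.ndarray:
    """Relative abundances of M+0 .. M+max_shift, with M+0 := 100.

    Computed by per-element multinomial expansion: each element contributes
    the polynomial (sum_i a_i x^s_i)^n over its isotopes, where s_i is the
    nominal mass shift relative to the lightest isotope; the product over
    elements is truncated at ``max_shift`` and normalised to the
    monoisotopic coefficient.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    poly = np.zeros(max_shift + 1)
    poly[0] = 1.0
    for el, n in formula.counts.items():
        rows = table.isotopes(el)
        base_mn = rows[0][0]
        elem = np.zeros(max_shift + 1)
        for mn, _, abundance in rows:
            shift = mn - base_mn
            if shift <= max_shift:
                elem[shift] += abundance
        # (elem)^n via repeated truncated convolution; n is small in practice
        power = np.zeros(max_shift + 1)
        power[0] = 1.0
        for _ in range(n):
            power = np.convolve(power, elem)[: max_shift + 1]
        poly = np.convolve(poly, power)[: max_shift + 1]
    return 100.0 * poly / poly[0]


@dataclass(frozen=True)
class IonTarget:
    """One monitored isotopologue channel of one compound."""

    compound: str
    ion_formula: Formula
    channel: str  # endogenous | tracer | internal-standard | monoisotopomer
    scheme: LabelScheme
    mz: float
    window: MzWindow
    rt_window: tuple[float, float]  # min
    charge: int = 1
    protonated: bool = False
    acquisition: str | None = None  # SIM segment "lo-hi" or PRM precursor
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.window.contains(self.mz):
            raise ValueError(
                f"{self.compound}/{self.channel}: window {self.window} does not "
                f"contain computed m/z {self.mz:.4f}"
            )
        if self.rt_window[0] >= self.rt_window[1]:
            raise ValueError("retention-time window must have rt_lo < rt_hi")


@dataclass(frozen=True)
class LabelingDesign:
    """Which label scheme populates each monitored channel.

    The baseline scheme is the pre-existing (endogenous) isotopic channel —
    e.g. 15N1 for plants raised on 15N salts — the tracer scheme the channel
    fed by the supplied labeled precursor, and the internal-standard scheme
    the spiked quantification standard.
    """

    tracer: LabelScheme
    baseline: LabelScheme = LabelScheme()
    internal_standard: LabelScheme | None = None

    def channels(self) -> list[tuple[str, LabelScheme]]:
        out = [("endogenous", self.baseline), ("tracer", self.tracer)]
        if self.internal_standard is not None:
            out.append(("internal-standard", self.internal_standard))
        return out


def build_target_table(
    compounds: Iterable[tuple[str, Formula | str, tuple[float, float], str | None]],
    design: LabelingDesign,
    half_width: float = DEFAULT_HALF_WIDTH,
    protonated: bool = False,
    table: IsotopeTable = ISOTOPES,
) -> list[IonTarget]:
    """One IonTarget per (compound x channel role).

    ``compounds`` yields (name, ion formula, RT window (min), acquisition
    filter or None).  Channels whose windows overlap are flagged with a
    cross-talk warning on both targets; they remain quantifiable.
    """
    targets: list[IonTarget] = []
    for name, formula, rt_window, acquisition in compounds:
        if isinstance(formula, str):
            formula = Formula.parse(formula)
        base = ion_mz(formula, 1, protonated, table)
        per_compound: list[IonTarget] = []
        for role, scheme in design.channels():
            scheme.validate(formula, table)
            mz = labeled_mz(base, scheme, table)
            per_compound.append(
                IonTarget(
                    compound=name,
                    ion_formula=formula,
                    channel=role,
                    scheme=scheme,
                    mz=mz,
                    window=window_for(mz, half_width),
                    rt_window=tuple(rt_window),
                    protonated=protonated,
                    acquisition=acquisition,
                )
            )
        # cross-talk: any pair of channel windows that overlap
        for i, a in enumerate(per_compound):
            notes = []
            for j, b in enumerate(per_compound):
                if i != j and a.window.overlaps(b.window):
                    notes.append(
                        f"cross-talk: {a.channel} window overlaps {b.channel} "
                        f"({b.window.low:.4f}-{b.window.high:.4f})"
                    )
            if notes:
                a = replace(a, warnings=tuple(notes))
            targets.append(a)
    return targets
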