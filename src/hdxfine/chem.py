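"""Elemental formulas, exact isotope masses, and peptide chemistry.

This module is the chemistry substrate for everything else: elemental
formulas (with the fixed label ``D`` for deuterium, distinct from natural
hydrogen), an embedded isotope mass/abundance table, peptide-sequence to
formula conversion (including C-terminal amidation and user-specified
elemental add/remove modifications), charge/adduct arithmetic, and
exchangeable-hydrogen counting under selectable policies.

Masses are monoisotopic throughout, in daltons (Da).
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable, Optional

__all__ = [
    "ISOTOPES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
    "ElementalFormula",
    "parse_formula",
    "monoisotopic_mass",
    "peptide_formula",
    "ion_mz",
    "exchangeable_sites",
    "Ion",
    "AA_COMPOSITIONS",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings, unknown symbols, or
    modifications that would drive an atom count negative."""


# ---------------------------------------------------------------------------
# Isotope table
# ---------------------------------------------------------------------------
# Exact masses from the AME atomic-mass evaluation, representative natural
# abundances from the IUPAC-CIAAW compilation.  ``D`` is the fixed deuterium
# label: pure 2H, abundance 1 — distinct from natural hydrogen ``H`` which
# keeps its trace 2H component.  Per element: (mass Da, abundance), masses
# strictly increasing, abundances summing to 1.
ISOTOPES: dict[str, tuple[tuple[float, float], ...]] = {
    "H": ((1.00782503207, 0.999885), (2.01410177812, 0.000115)),
    "D": ((2.01410177812, 1.0),),
    "C": ((12.0, 0.9893), (13.00335483507, 0.0107)),
    "N": ((14.00307400443, 0.99636), (15.00010889888, 0.00364)),
    "O": (
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ),
    "S": (
        (31.97207117441, 0.9499),
        (32.97145890980, 0.0075),
        (33.96786700400, 0.0425),
        (35.96708070620, 0.0001),
    ),
    "P": ((30.97376199842, 1.0),),
}

ELECTRON_MASS = 0.000548579909  # Da
#: Mass of the proton (H atom minus one electron); the default ionization
#: adduct for positive-mode electrospray.
PROTON_MASS = ISOTOPES["H"][0][0] - ELECTRON_MASS  # 1.00727645216 Da

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Display order: C first, then D, then H, then everything else alphabetically
# (the convention used for deuterium-labeled peptide formulas, e.g.
# C63D2H98N18O13S).
_DISPLAY_ORDER = {"C": 0, "D": 1, "H": 2}


class ElementalFormula(Mapping):
    """An immutable element/label -> count map.

    Counts are non-negative integers over the supported symbol table
    (C, H, N, O, S, P and the deuterium label D).  Supports ``+``, ``-``
    (raising :class:`FormulaError` on a negative result) and ``*`` by a
    non-negative integer.

    >>> ElementalFormula({"H": 2, "O": 1}) + ElementalFormula({"H": 1})
    ElementalFormula('H3O')
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Optional[Mapping[str, int]] = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for sym, n in src.items():
                if sym not in ISOTOPES:
                    raise FormulaError(f"unknown element or label symbol {sym!r}")
                if not isinstance(n, (int,)) or isinstance(n, bool):
                    raise FormulaError(f"count for {sym!r} must be an integer, got {n!r}")
                if n < 0:
                    raise FormulaError(f"negative count for {sym!r}: {n}")
                merged[sym] = merged.get(sym, 0) + n
        self._counts = {s: n for s, n in merged.items() if n > 0}

    # Mapping protocol ------------------------------------------------------
    def __getitem__(self, sym: str) -> int:
        return self._counts[sym]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, sym: str, default: int = 0) -> int:
        return self._counts.get(sym, default)

    # Arithmetic ------------------------------------------------------------
    def __add__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) + n
        return ElementalFormula(out)

    def __sub__(self, other: Mapping[str, int]) -> "ElementalFormula":
        out = dict(self._counts)
        for sym, n in other.items():
            out[sym] = out.get(sym, 0) - n
            if out[sym] < 0:
                raise FormulaError(
                    f"removing {n} {sym} leaves a negative count ({out[sym]})"
                )
        return ElementalFormula(out)

    def __mul__(self, k: int) -> "ElementalFormula":
        if not isinstance(k, int) or k < 0:
            raise FormulaError(f"formula multiplier must be a non-negative integer, got {k!r}")
        return ElementalFormula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {s: n for s, n in other.items() if n}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    # Rendering -------------------------------------------------------------
    def __str__(self) -> str:
        parts = []
        for sym in sorted(self._counts, key=lambda s: (_DISPLAY_ORDER.get(s, 3), s)):
            n = self._counts[sym]
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({str(self)!r})"

    # Convenience -----------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        return parse_formula(text)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self)

    def total_atoms(self) -> int:
        return sum(self._counts.values())


def parse_formula(text: str) -> ElementalFormula:
    """Parse a formula string like ``"C63H98N18O13S"`` or ``"C63DH99N18O13S"``.

    Each token is an element/label symbol followed by an optional positive
    integer multiplicity (absent = 1).  Unknown symbols and malformed counts
    raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None or m.start() != pos:
            raise FormulaError(f"malformed formula at {text[pos:pos+4]!r} (position {pos})")
        sym, digits = m.groups()
        if sym not in ISOTOPES:
            raise FormulaError(f"unknown element or label symbol {sym!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            n = int(digits)
            if n <= 0:
                raise FormulaError(f"multiplicity for {sym!r} must be positive, got {digits!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementalFormula(counts)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass in Da: each element contributes its lightest-isotope
    exact mass (for CHNOPS the lightest is also the most abundant); the label
    ``D`` contributes the 2H mass."""
    total = 0.0
    for sym, n in formula.items():
        try:
            table = ISOTOPES[sym]
        except KeyError:
            raise FormulaError(f"unknown element or label symbol {sym!r}") from None
        total += n * table[0][0]
    return total


# ---------------------------------------------------------------------------
# Peptides
# ---------------------------------------------------------------------------
# Residue (amino-acid minus water) compositions of the standard 20 residues.
AA_COMPOSITIONS: dict[str, ElementalFormula] = {
    aa: ElementalFormula(c)
    for aa, c in {
        "G": {"C": 2, "H": 3, "N": 1, "O": 1},
        "A": {"C": 3, "H": 5, "N": 1, "O": 1},
        "S": {"C": 3, "H": 5, "N": 1, "O": 2},
        "P": {"C": 5, "H": 7, "N": 1, "O": 1},
        "V": {"C": 5, "H": 9, "N": 1, "O": 1},
        "T": {"C": 4, "H": 7, "N": 1, "O": 2},
        "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
        "L": {"C": 6, "H": 11, "N": 1, "O": 1},
        "I": {"C": 6, "H": 11, "N": 1, "O": 1},
        "N": {"C": 4, "H": 6, "N": 2, "O": 2},
        "D": {"C": 4, "H": 5, "N": 1, "O": 3},
        "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
        "K": {"C": 6, "H": 12, "N": 2, "O": 1},
        "E": {"C": 5, "H": 7, "N": 1, "O": 3},
        "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
        "H": {"C": 6, "H": 7, "N": 3, "O": 1},
        "F": {"C": 9, "H": 9, "N": 1, "O": 1},
        "R": {"C": 6, "H": 12, "N": 4, "O": 1},
        "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
        "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    }.items()
}

_WATER = ElementalFormula({"H": 2, "O": 1})
# C-terminal amidation: -OH -> -NH2, i.e. add H and N, remove one O.
_AMIDATION_ADD = ElementalFormula({"H": 1, "N": 1})
_AMIDATION_REMOVE = ElementalFormula({"O": 1})


def peptide_formula(
    sequence: str,
    modifications: Iterable[tuple[Mapping[str, int], Mapping[str, int]]] = (),
    termini: str = "free",
) -> ElementalFormula:
    """Elemental formula of a peptide.

    Sums residue compositions, adds one water for the free termini, applies
    C-terminal amidation when ``termini == "amidated"`` and then each
    modification as an ``(add, remove)`` pair of elemental deltas.

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence (standard 20 residues).
    modifications : iterable of (add, remove)
        Elemental additions/subtractions applied after assembly; a removal
        that would drive any count negative raises :class:`FormulaError`.
    termini : {"free", "amidated"}
        ``"amidated"`` converts the C-terminal acid to a primary amide.
    """
    if not sequence:
        raise FormulaError("empty peptide sequence")
    if termini not in ("free", "amidated"):
        raise FormulaError(f"unknown termini mode {termini!r}")
    counts: dict[str, int] = {}
    for i, aa in enumerate(sequence.upper()):
        comp = AA_COMPOSITIONS.get(aa)
        if comp is None:
            raise FormulaError(f"unknown residue {aa!r} at position {i + 1}")
        for sym, n in comp.items():
            counts[sym] = counts.get(sym, 0) + n
    formula = ElementalFormula(counts) + _WATER
    if termini == "amidated":
        formula = (formula + _AMIDATION_ADD) - _AMIDATION_REMOVE
    for add, remove in modifications:
        formula = (formula + ElementalFormula(add)) - ElementalFormula(remove)
    return formula


def ion_mz(
    neutral_mass: float,
    z: int,
    m_adduct: float = PROTON_MASS,
    auto_protonate: bool = True,
) -> float:
    """m/z of a charged species.

    With ``auto_protonate`` on, z adduct masses (protons by default) are
    added: ``(M + z * m_adduct) / z``.  With it off, the neutral mass is
    assumed to already embed any charge carriers (minus the charge's worth of
    electrons) and is simply divided by z.
    """
    if not isinstance(z, int) or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z!r}")
    if auto_protonate:
        return (neutral_mass + z * m_adduct) / z
    return neutral_mass / z


# ---------------------------------------------------------------------------
# Exchangeable hydrogens
# ---------------------------------------------------------------------------
# Side-chain hydrogens bound to N, O, or S (neutral species): these exchange
# with solvent deuterium, unlike carbon-bound hydrogens.
_SIDECHAIN_LABILE = {
    "R": 5, "N": 2, "Q": 2, "K": 2, "S": 1, "T": 1, "Y": 1,
    "C": 1, "D": 1, "E": 1, "H": 1, "W": 1,
}


def exchangeable_sites(
    sequence: Optional[str] = None,
    formula: Optional[Mapping[str, int]] = None,
    policy: str = "all_labile",
    termini: str = "free",
) -> int:
    """Count deuterium-exchangeable hydrogens.

    Policies
    --------
    ``backbone_amide``
        Peptide bonds whose amide nitrogen is not proline — the slowly
        exchanging sites usually interpreted in protein HDX.
    ``all_labile``
        All N/O/S-bound hydrogens: backbone amides plus side chains plus the
        termini (N-terminal amine 2, C-terminal acid 1 or amide 2).  This is
        the upper bound on how far a deuterium ladder can extend.
    ``all_H``
        Total hydrogen count of the formula (formula mode only).
    """
    if policy == "all_H":
        if formula is None:
            if sequence is None:
                raise ValueError("all_H policy requires a formula or sequence")
            formula = peptide_formula(sequence, termini=termini)
        return formula.get("H", 0) + formula.get("D", 0)
    if sequence is None:
        raise ValueError(f"policy {policy!r} requires a sequence")
    seq = sequence.upper()
    for i, aa in enumerate(seq):
        if aa not in AA_COMPOSITIONS:
            raise FormulaError(f"unknown residue {aa!r} at position {i + 1}")
    if policy == "backbone_amide":
        return sum(1 for aa in seq[1:] if aa != "P")
    if policy == "all_labile":
        n = sum(1 for aa in seq[1:] if aa != "P")  # backbone amide NH
        n += 1 if seq[0] == "P" else 2             # N-terminal amine
        n += 2 if termini == "amidated" else 1     # C-terminal amide / acid
        n += sum(_SIDECHAIN_LABILE.get(aa, 0) for aa in seq)
        return n
    raise ValueError(f"unknown exchangeable-site policy {policy!r}")


# ---------------------------------------------------------------------------
# Ions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Ion:
    """A charged species: an elemental formula (or a bare monoisotopic mass),
    a positive charge, an adduct mass, and its exchangeable-site count.

    ``neutral_monoisotopic_mass`` is the neutral species' mass; the observed
    monoisotopic m/z is ``(M + z * m_adduct) / z``.
    """

    neutral_monoisotopic_mass: float
    z: int
    formula: Optional[ElementalFormula] = None
    m_adduct: float = PROTON_MASS
    n_exchangeable: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.z, int) or self.z < 1:
            raise ValueError(f"charge must be a positive integer, got {self.z!r}")
        if self.n_exchangeable < 0:
            raise ValueError("n_exchangeable must be non-negative")
        if self.formula is not None:
            fmass = monoisotopic_mass(self.formula)
            if abs(fmass - self.neutral_monoisotopic_mass) > 1e-9:
                raise ValueError(
                    f"neutral mass {self.neutral_monoisotopic_mass!r} inconsistent "
                    f"with formula mass {fmass!r}"
                )
            n_h = self.formula.get("H", 0) + self.formula.get("D", 0)
            if self.n_exchangeable > n_h:
                raise ValueError(
                    f"n_exchangeable ({self.n_exchangeable}) exceeds hydrogen count ({n_h})"
                )

    @property
    def mono_mz(self) -> float:
        return ion_mz(self.neutral_monoisotopic_mass, self.z, self.m_adduct)

    @classmethod
    def from_formula(
        cls,
        formula: ElementalFormula | str,
        z: int,
        m_adduct: float = PROTON_MASS,
        n_exchangeable: Optional[int] = None,
        label: str = "",
    ) -> "Ion":
        if isinstance(formula, str):
            formula = parse_formula(formula)
        if n_exchangeable is None:
            n_exchangeable = exchangeable_sites(formula=formula, policy="all_H")
        return cls(
            neutral_monoisotopic_mass=monoisotopic_mass(formula),
            z=z,
            formula=formula,
            m_adduct=m_adduct,
            n_exchangeable=n_exchangeable,
            label=label or str(formula),
        )

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        z: int,
        modifications: Iterable[tuple[Mapping[str, int], Mapping[str, int]]] = (),
        termini: str = "free",
        site_policy: str = "all_labile",
        m_adduct: float = PROTON_MASS,
        label: str = "",
    ) -> "Ion":
        formula = peptide_formula(sequence, modifications, termini)
        n_ex = exchangeable_sites(sequence=sequence, policy=site_policy, termini=termini)
        return cls(
            neutral_monoisotopic_mass=monoisotopic_mass(formula),
            z=z,
            formula=formula,
            m_adduct=m_adduct,
            n_exchangeable=n_ex,
            label=label or sequence,
        )

    @classmethod
    def from_mono_mz(
        cls,
        mono_mz: float,
        z: int,
        n_exchangeable: int = 0,
        m_adduct: float = PROTON_MASS,
        label: str = "",
    ) -> "Ion":
        """Ion defined only by an observed monoisotopic m/z and charge (the
        formula-free workflow)."""
        return cls(
            neutral_monoisotopic_mass=mono_mz * z - z * m_adduct,
            z=z,
            formula=None,
            m_adduct=m_adduct,
            n_exchangeable=n_exchangeable,
            label=label or f"mz{mono_mz:.4f}/z{z}",
        )
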