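"""In-silico proteolysis and matching of digest peptides to deuterated spectra.

Bottom-up HDX digests the labeled protein under quench conditions (classically
with pepsin, which cleaves promiscuously), so this module provides named
enzyme rules, custom rules, and an all-fragments fallback, plus matching of
the resulting peptides against spectra — including distributions whose
monoisotopic peak is below the noise, in which case the mono is assigned from
the peptide's theoretical mass and the ladder alignment is bounded by the
peptide's exchangeable-site count.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem import (
    AA_COMPOSITIONS,
    PROTON_MASS,
    ElementalFormula,
    FormulaError,
    exchangeable_sites,
    ion_mz,
    monoisotopic_mass,
    peptide_formula,
)
from .detect import detect_distributions
from .hdx_theory import DELTA_2H
from .spectrum_io import PeakList

__all__ = [
    "EnzymeRule",
    "ENZYMES",
    "DigestPeptide",
    "PeptideMatch",
    "load_fasta",
    "digest",
    "all_fragments",
    "match_peptides",
    "match_report",
]


@dataclass(frozen=True)
class EnzymeRule:
    """Cleavage specificity: cut after ``cleave_after`` residues unless the
    next residue is in ``blocked_by``, and/or before ``cleave_before``
    residues.  ``pattern`` allows a custom regex whose match positions are
    cut points (cut after the match start)."""

    name: str
    cleave_after: frozenset[str] = frozenset()
    blocked_by: frozenset[str] = frozenset()
    cleave_before: frozenset[str] = frozenset()
    pattern: Optional[str] = None

    def cut_sites(self, sequence: str) -> list[int]:
        """0-based boundaries i meaning a cut between sequence[i-1] and
        sequence[i]; excludes the ends."""
        n = len(sequence)
        sites = set()
        if self.pattern:
            for m in re.finditer(self.pattern, sequence):
                pos = m.start() + 1
                if 0 < pos < n:
                    sites.add(pos)
        for i in range(1, n):
            prev, cur = sequence[i - 1], sequence[i]
            if prev in self.cleave_after and cur not in self.blocked_by:
                sites.add(i)
            if cur in self.cleave_before:
                sites.add(i)
        return sorted(sites)


ENZYMES: dict[str, EnzymeRule] = {
    "trypsin": EnzymeRule("trypsin", frozenset("KR"), frozenset("P")),
    "chymotrypsin": EnzymeRule("chymotrypsin", frozenset("FWY"), frozenset("P")),
    "glu-c": EnzymeRule("glu-c", frozenset("E")),
    "lys-c": EnzymeRule("lys-c", frozenset("K")),
    "asp-n": EnzymeRule("asp-n", cleave_before=frozenset("D")),
    # pepsin above pH 2 cleaves broadly; this is a coarse consensus rule —
    # the all-fragments mode is the safety net for real pepsin digests
    "pepsin": EnzymeRule("pepsin", frozenset("FLWYAEQ")),
}


@dataclass(frozen=True)
class DigestPeptide:
    """A digest fragment with 1-based inclusive coordinates in its parent."""

    sequence: str
    start: int
    end: int
    formula: ElementalFormula = field(repr=False, default=None)  # type: ignore[assignment]
    neutral_monoisotopic_mass: float = 0.0
    n_exchangeable: int = 0

    @classmethod
    def from_slice(
        cls, parent: str, start0: int, end0: int, site_policy: str = "all_labile"
    ) -> "DigestPeptide":
        seq = parent[start0:end0]
        f = peptide_formula(seq)
        return cls(
            sequence=seq,
            start=start0 + 1,
            end=end0,
            formula=f,
            neutral_monoisotopic_mass=monoisotopic_mass(f),
            n_exchangeable=exchangeable_sites(sequence=seq, policy=site_policy),
        )


def load_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein records from a FASTA file.

    Lowercase residues are uppercased (with a warning), a trailing ``*`` stop
    is trimmed (with a warning), and ambiguous residues (X/B/Z or anything
    without a defined composition) are rejected with their position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq)
        if seq.endswith("*"):
            warnings.warn(f"{rec.id}: trimmed trailing stop '*'")
            seq = seq[:-1]
        if seq != seq.upper():
            warnings.warn(f"{rec.id}: lowercase residues uppercased")
            seq = seq.upper()
        for i, aa in enumerate(seq):
            if aa not in AA_COMPOSITIONS:
                raise FormulaError(
                    f"{rec.id}: residue {aa!r} at position {i + 1} has no "
                    "defined elemental composition"
                )
        out.append((rec.id, seq))
    return out


def digest(
    sequence: str,
    rule: EnzymeRule | str,
    missed_cleavages: int = 0,
    site_policy: str = "all_labile",
) -> list[DigestPeptide]:
    """Cleave ``sequence`` with an enzyme rule, allowing up to
    ``missed_cleavages`` internal uncut sites.  With 0 missed cleavages the
    fragments tile the parent exactly."""
    if isinstance(rule, str):
        try:
            rule = ENZYMES[rule.lower()]
        except KeyError:
            raise ValueError(
                f"unknown enzyme {rule!r}; known: {sorted(ENZYMES)}"
            ) from None
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be non-negative")
    sequence = sequence.upper()
    bounds = [0] + rule.cut_sites(sequence) + [len(sequence)]
    peptides = []
    seen = set()
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            key = (bounds[i], bounds[j])
            if key not in seen:
                seen.add(key)
                peptides.append(
                    DigestPeptide.from_slice(sequence, bounds[i], bounds[j], site_policy)
                )
    return peptides


def all_fragments(
    sequence: str, min_len: int, max_len: int, site_policy: str = "all_labile"
) -> list[DigestPeptide]:
    """Every contiguous fragment with length in [min_len, max_len]."""
    n = len(sequence)
    if not 1 <= min_len <= max_len <= n:
        raise ValueError(f"need 1 <= min_len <= max_len <= {n}")
    sequence = sequence.upper()
    return [
        DigestPeptide.from_slice(sequence, s, s + L, site_policy)
        for L in range(min_len, max_len + 1)
        for s in range(n - L + 1)
    ]


@dataclass
class PeptideMatch:
    peptide: DigestPeptide
    spectrum_id: str
    z: int
    mono_mz_theoretical: float
    mass_error_ppm: float
    n_matched: int
    mono_detected: bool
    rmse_da: float
    ambiguous: bool = False


def _longest_consecutive(matched: np.ndarray) -> int:
    best = run = 0
    for m in matched:
        run = run + 1 if m else 0
        best = max(best, run)
    return best


def match_peptides(
    peptides: Sequence[DigestPeptide],
    spectra: Mapping[str, PeakList],
    z_range: Sequence[int] = (1, 2, 3),
    tol_ppm: float = 2.0,
    allow_missing_mono: bool = False,
    min_ladder_peaks: int = 3,
    m_adduct: float = PROTON_MASS,
) -> list[PeptideMatch]:
    """Match digest peptides to deuterated spectra.

    Standard mode: a peptide matches when a detected distribution's candidate
    monoisotopic m/z lies within ``tol_ppm`` of the peptide's theoretical
    mono m/z at the detected charge.

    Missing-mono mode (``allow_missing_mono``): the theoretical mono m/z
    anchors a deuterium ladder ``mono + d * (m2H - m1H)/z`` for
    d = 0..n_exchangeable only — the exchangeable-site count bounds how far
    from the mono a distribution may plausibly sit — and the peptide matches
    when at least ``min_ladder_peaks`` consecutive rungs align with observed
    peaks.  The mono is then assigned from the theoretical mass even if no
    peak was detected there.

    Peptides indistinguishable within tolerance (e.g. identical elemental
    composition) are all reported, flagged ambiguous.  Results are sorted by
    (spectrum, mono m/z, rmse, -n_matched).
    """
    if not peptides:
        raise ValueError("no peptides to match")
    matches: list[PeptideMatch] = []
    for spec_id, peaks in spectra.items():
        detected = detect_distributions(
            peaks, z_candidates=z_range, min_peaks=min_ladder_peaks
        ) if not allow_missing_mono else None
        for pep in peptides:
            for z in z_range:
                theo = ion_mz(pep.neutral_monoisotopic_mass, z, m_adduct)
                tol_da = tol_ppm * 1e-6 * theo
                if not allow_missing_mono:
                    for ion in detected:
                        if ion.z != z:
                            continue
                        err = ion.candidate_mono_mz - theo
                        if abs(err) <= tol_da:
                            matches.append(
                                PeptideMatch(
                                    peptide=pep,
                                    spectrum_id=spec_id,
                                    z=z,
                                    mono_mz_theoretical=theo,
                                    mass_error_ppm=err / theo * 1e6,
                                    n_matched=ion.n_peaks,
                                    mono_detected=True,
                                    rmse_da=abs(err),
                                )
                            )
                else:
                    spacing = DELTA_2H / z
                    targets = theo + spacing * np.arange(pep.n_exchangeable + 1)
                    errs = []
                    matched = np.zeros(len(targets), dtype=bool)
                    for d, t in enumerate(targets):
                        lo = np.searchsorted(peaks.mz, t - tol_da, side="left")
                        hi = np.searchsorted(peaks.mz, t + tol_da, side="right")
                        if hi > lo:
                            matched[d] = True
                            sub = peaks.mz[lo:hi]
                            errs.append(float(sub[np.argmin(np.abs(sub - t))] - t))
                    if _longest_consecutive(matched) >= min_ladder_peaks:
                        err_arr = np.array(errs)
                        matches.append(
                            PeptideMatch(
                                peptide=pep,
                                spectrum_id=spec_id,
                                z=z,
                                mono_mz_theoretical=theo,
                                mass_error_ppm=float(np.mean(err_arr) / theo * 1e6),
                                n_matched=int(matched.sum()),
                                mono_detected=bool(matched[0]),
                                rmse_da=float(np.sqrt(np.mean(err_arr**2))),
                            )
                        )
    # flag ambiguity: same spectrum & charge, theoretical monos within the
    # combined tolerance window
    for i, a in enumerate(matches):
        for b in matches[i + 1:]:
            if (
                a.spectrum_id == b.spectrum_id
                and a.z == b.z
                and a.peptide is not b.peptide
                and abs(a.mono_mz_theoretical - b.mono_mz_theoretical)
                <= 2 * tol_ppm * 1e-6 * a.mono_mz_theoretical
            ):
                a.ambiguous = b.ambiguous = True
    matches.sort(
        key=lambda m: (m.spectrum_id, m.mono_mz_theoretical, m.rmse_da, -m.n_matched)
    )
    return matches


def match_report(matches: Sequence[PeptideMatch]) -> pd.DataFrame:
    """Exportable CSV table of peptide-spectrum matches."""
    rows = [
        {
            "peptide": m.peptide.sequence,
            "start": m.peptide.start,
            "end": m.peptide.end,
            "spectrum": m.spectrum_id,
            "z": m.z,
            "mono_mz_theoretical": m.mono_mz_theoretical,
            "mass_error_ppm": m.mass_error_ppm,
            "n_peaks_matched": m.n_matched,
            "mono_detected": m.mono_detected,
            "ambiguous": m.ambiguous,
        }
        for m in matches
    ]
    return pd.DataFrame(rows)
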