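"""HDX mass-defect constants, deuterium peak ladders, and FTICR physics.

The quantity that makes direct HDX readout possible at ultrahigh resolving
power is the HDX mass defect

    m_HDX = (m(2H) - m(1H)) - (m(13C) - m(12C))  ~  2.922 mDa:

an ion that gained a deuterium is m_HDX/z heavier than its isotopomer that
instead carries one extra 13C, so once peaks separated by m_HDX/z are
resolved, deuterium-associated ("pseudomonoisotopic") peaks stand free of
the natural-abundance heavy-isotope peaks.

For an FTICR operating at low pressure in magnitude mode, resolving power is

    RP = m/dm50 = 1.274e7 * z * B0 * Tacq / m,

where the mass variable m is the absolute ion mass z * (m/z) — the cyclotron
frequency goes as z*B0/m, so RP reduces to 1.274e7 * B0 * Tacq / (m/z) and
the explicit z cancels.  The peak width needed to separate two equal
Lorentzian peaks a distance m_HDX/z apart with a 50% valley is

    dm50 = (m_HDX / z) * sqrt(sqrt(33) - 5) / sqrt(2).

Equating the two expressions for RP at m/z = (M + z*m_adduct)/z gives the
minimum acquisition period for a neutral mass M:

    Tacq = (M + z*m_adduct)^2 / (1.274e7 * dm50 * z^2 * Beff),

where Beff is the effective field (the physical field times the absorption-
mode gain, 1-2x).  The absolute-mass reading of m is the only one under
which this Tacq expression carries z^2; reading m as the m/z value would
give z^3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem import ISOTOPES, PROTON_MASS

__all__ = [
    "DELTA_13C",
    "DELTA_2H",
    "M_HDX",
    "FTICR_CONSTANT",
    "hdx_mass_defect",
    "fine_structure_spacing",
    "InstrumentModel",
    "PeakLadder",
    "peak_ladder",
    "required_peak_width",
    "required_resolving_power",
    "magnitude_mode_rp",
    "acquisition_time",
    "calibration_table",
]

#: 13C - 12C mass difference, Da.
DELTA_13C = ISOTOPES["C"][1][0] - ISOTOPES["C"][0][0]
#: 2H - 1H mass difference, Da.
DELTA_2H = ISOTOPES["H"][1][0] - ISOTOPES["H"][0][0]
#: The HDX mass defect (~2.922 mDa).
M_HDX = DELTA_2H - DELTA_13C

#: Low-pressure magnitude-mode FTICR resolving-power constant (SI-derived,
#: with m/z in Th, B0 in T, Tacq in s).
FTICR_CONSTANT = 1.274e7

#: 50%-valley width factor for two equal-height Lorentzians: dm50 relative
#: to their separation.
_VALLEY_FACTOR = math.sqrt(math.sqrt(33.0) - 5.0) / math.sqrt(2.0)


def hdx_mass_defect() -> float:
    """m_HDX = (2H - 1H) - (13C - 12C) in Da (~2.922 mDa)."""
    return M_HDX


def fine_structure_spacing(z: int) -> float:
    """m_HDX / z: the spacing, in m/z, between a d-deuterium peak and its
    (d-1 deuterium, +1 13C) neighbour within one nominal-mass cluster."""
    _check_charge(z)
    return M_HDX / z


def _check_charge(z: int) -> None:
    if not isinstance(z, (int, np.integer)) or z < 1:
        raise ValueError(f"charge must be a positive integer, got {z!r}")


@dataclass(frozen=True)
class InstrumentModel:
    """An FTICR instrument: field strength and detection mode.

    ``absorption_gain`` is the resolving-power improvement of absorption-mode
    phasing over magnitude mode (1 to 2).  If left unset in absorption mode
    it defaults to the conservative 1.45 at 9.4 T and the maximal 2.0 at
    higher fields.
    """

    B0: float
    mode: str = "magnitude"
    absorption_gain: float | None = None

    def __post_init__(self) -> None:
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")
        if self.mode not in ("magnitude", "absorption"):
            raise ValueError(f"unknown mode {self.mode!r}")
        gain = self.absorption_gain
        if self.mode == "magnitude":
            if gain is None:
                gain = 1.0
            if gain != 1.0:
                raise ValueError("absorption_gain must be 1 in magnitude mode")
        else:
            if gain is None:
                gain = 1.45 if abs(self.B0 - 9.4) < 0.05 else 2.0
            if not 1.0 <= gain <= 2.0:
                raise ValueError("absorption_gain must lie in [1, 2]")
        object.__setattr__(self, "absorption_gain", gain)

    @property
    def effective_field(self) -> float:
        """B0 times the absorption-mode gain (Tesla)."""
        return self.B0 * self.absorption_gain


@dataclass(frozen=True)
class PeakLadder:
    """The m/z positions of an isotopomer's deuterium ladder.

    ``mz_values[d]`` is the m/z of the species with ``k_13C`` carbon-13 and
    ``d`` deuterium (d = 0..n_max); consecutive rungs are exactly
    ``DELTA_2H / z`` apart.
    """

    mono_mz: float
    z: int
    k_13C: int
    mz_values: np.ndarray = field(repr=False)

    @property
    def n_max(self) -> int:
        return len(self.mz_values) - 1


def peak_ladder(mono_mz: float, z: int, k_13C: int = 0, n_max: int = 0) -> PeakLadder:
    """Pseudomonoisotopic peak positions for an isotopomer series.

    ``mz[d] = mono_mz + (k_13C * DELTA_13C + d * DELTA_2H) / z`` — the
    monoisotopic m/z shifted by k 13C substitutions plus d deuterium.
    k = 0 gives the pseudomonoisotopic ladder proper.
    """
    _check_charge(z)
    if n_max < 0:
        raise ValueError("n_max must be non-negative")
    if k_13C < 0:
        raise ValueError("k_13C must be non-negative")
    d = np.arange(n_max + 1)
    mz = mono_mz + (k_13C * DELTA_13C + d * DELTA_2H) / z
    return PeakLadder(mono_mz=mono_mz, z=z, k_13C=k_13C, mz_values=mz)


def required_peak_width(z: int) -> float:
    """dm50: full width at half maximum (Da on the m/z axis) at which two
    equal Lorentzians separated by m_HDX/z show a 50%-maximum valley."""
    _check_charge(z)
    return (M_HDX / z) * _VALLEY_FACTOR


def required_resolving_power(mz: float, z: int) -> float:
    """Resolving power m/dm50 needed to resolve deuterium fine structure at
    this m/z and charge."""
    if mz <= 0:
        raise ValueError("mz must be positive")
    return mz / required_peak_width(z)


def magnitude_mode_rp(mz: float, z: int, B0: float, Tacq: float) -> float:
    """Low-pressure magnitude-mode FTICR resolving power,
    ``1.274e7 * z * B0 * Tacq / m`` with m the absolute ion mass ``z * mz``
    (equivalently ``1.274e7 * B0 * Tacq / mz``)."""
    _check_charge(z)
    if mz <= 0 or B0 <= 0 or Tacq <= 0:
        raise ValueError("mz, B0 and Tacq must be positive")
    return FTICR_CONSTANT * z * B0 * Tacq / (z * mz)


def acquisition_time(
    M: float,
    z: int,
    instrument: InstrumentModel,
    m_adduct: float = PROTON_MASS,
) -> float:
    """Minimum ICR acquisition period (s) to resolve deuterium-associated
    peaks of a neutral mass M at charge z:

        Tacq = (M + z*m_adduct)^2 / (1.274e7 * dm50(z) * z^2 * Beff).
    """
    _check_charge(z)
    if M <= 0 or m_adduct < 0:
        raise ValueError("M must be positive and m_adduct non-negative")
    dm50 = required_peak_width(z)
    return (M + z * m_adduct) ** 2 / (
        FTICR_CONSTANT * dm50 * z**2 * instrument.effective_field
    )


def calibration_table(mono_mz: float, z: int, n_max: int, k_13C: int = 0) -> pd.DataFrame:
    """Deuterium-associated m/z table (for calibrating spectra in external
    software): one row per deuterium count with its exact m/z."""
    ladder = peak_ladder(mono_mz, z, k_13C, n_max)
    return pd.DataFrame(
        {
            "n_deuterium": np.arange(n_max + 1),
            "k_13C": k_13C,
            "z": z,
            "mz": ladder.mz_values,
        }
    )
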