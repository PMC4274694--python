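"""Deuterium-incorporation estimation from fine-structure-resolved spectra.

The estimator maps the pseudomonoisotopic ladder of an ion onto a centroided
spectrum: starting from the monoisotopic m/z, the positions of the d = 0, 1,
2, ... deuterium species (spaced (m(2H)-m(1H))/z apart) are computed, peak
intensities are collected in narrow bins around each position, and the
fraction each bin contributes to the bin total gives the deuteration
distribution; its first moment is the mean deuterium uptake.  The same
ladder is evaluated for the isotopomer series carrying exactly one, two, ...
13C (and no other heavy isotopes), and the headline estimate is taken from
the most intense series — usually the 13C = 0 series for small peptides.
Mass accuracy is summarized as the RMSE between matched centroids and their
theoretical positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

from .chem import ISOTOPES, Ion
from .hdx_theory import M_HDX, peak_ladder
from .spectrum_io import PeakList, Spectrum, fit_line_intensities

__all__ = [
    "IonNotDetectedError",
    "CrossTalkError",
    "SeriesResult",
    "IncorporationResult",
    "bin_intensity",
    "default_bin_tolerance",
    "default_k_max",
    "estimate_incorporation",
    "incorporation_report",
]


class IonNotDetectedError(RuntimeError):
    """No ladder position of any isotopomer series matched a peak."""


class CrossTalkError(ValueError):
    """Bin tolerance so wide that neighbouring fine-structure species
    (m_HDX/z apart) would bleed into each other's bins."""


@dataclass(frozen=True)
class SeriesResult:
    """Deuterium distribution read off one k-13C isotopomer series."""

    k_13C: int
    intensities: np.ndarray
    observed_mz: np.ndarray  # NaN where no peak matched
    theoretical_mz: np.ndarray

    @property
    def total_intensity(self) -> float:
        return float(self.intensities.sum())

    @property
    def detected(self) -> bool:
        return self.total_intensity > 0

    @property
    def fractions(self) -> np.ndarray:
        tot = self.intensities.sum()
        if tot <= 0:
            return np.full_like(self.intensities, np.nan)
        return self.intensities / tot

    @property
    def mean_d(self) -> float:
        f = self.fractions
        return float(np.dot(np.arange(len(f)), f))

    @property
    def sd_d(self) -> float:
        f = self.fractions
        d = np.arange(len(f))
        var = float(np.dot(d**2, f) - self.mean_d**2)
        return float(np.sqrt(max(var, 0.0)))

    @property
    def n_matched(self) -> int:
        return int(np.sum(~np.isnan(self.observed_mz)))


@dataclass(frozen=True)
class IncorporationResult:
    """Full estimation output for one ion: all isotopomer series, the
    selected (most intense) series, its mean/SD, and mass-error RMSE over
    every matched peak."""

    ion: Ion
    series: tuple[SeriesResult, ...]
    selected_k: int
    tol: np.ndarray

    @property
    def selected(self) -> SeriesResult:
        return self.series[self.selected_k]

    @property
    def mean_d(self) -> float:
        return self.selected.mean_d

    @property
    def sd_d(self) -> float:
        return self.selected.sd_d

    @property
    def fractions(self) -> np.ndarray:
        return self.selected.fractions

    def _mass_errors(self) -> tuple[np.ndarray, np.ndarray]:
        da, theo = [], []
        for s in self.series:
            ok = ~np.isnan(s.observed_mz)
            da.append(s.observed_mz[ok] - s.theoretical_mz[ok])
            theo.append(s.theoretical_mz[ok])
        return np.concatenate(da), np.concatenate(theo)

    @property
    def n_matched(self) -> int:
        return sum(s.n_matched for s in self.series)

    @property
    def rmse_da(self) -> float:
        err, _ = self._mass_errors()
        return float(np.sqrt(np.mean(err**2))) if len(err) else np.nan

    @property
    def rmse_ppm(self) -> float:
        err, theo = self._mass_errors()
        if not len(err):
            return np.nan
        return float(np.sqrt(np.mean((err / theo * 1e6) ** 2)))


def bin_intensity(
    peaks: PeakList, target: float, tol: float
) -> tuple[float, Optional[float]]:
    """Total intensity of peaks within ``[target - tol, target + tol]`` and
    their intensity-weighted mean m/z (None when nothing matches)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    lo = np.searchsorted(peaks.mz, target - tol, side="left")
    hi = np.searchsorted(peaks.mz, target + tol, side="right")
    if hi <= lo:
        return 0.0, None
    inten = peaks.intensity[lo:hi]
    mz = peaks.mz[lo:hi]
    total = float(inten.sum())
    return total, float(np.dot(mz, inten) / total)


def default_bin_tolerance(target: float, z: int) -> float:
    """min(2 ppm of the target, 0.3 * m_HDX / z): tight enough that a
    d-deuterium bin cannot capture its (d+1 deuterium, -1 13C) neighbour one
    fine-structure spacing away."""
    return min(2e-6 * target, 0.3 * M_HDX / z)


def default_k_max(ion: Ion, cap: int = 10) -> int:
    """Smallest k whose natural k-13C isotopomer abundance falls below 5% of
    the all-12C species (binomial in the carbon count); 3 when the formula
    is unknown."""
    if ion.formula is None:
        return 3
    n_c = ion.formula.get("C", 0)
    if n_c == 0:
        return 0
    r = ISOTOPES["C"][1][1] / ISOTOPES["C"][0][1]
    for k in range(1, min(n_c, cap) + 1):
        if comb(n_c, k) * r**k < 0.05:
            return k
    return min(n_c, cap)


def estimate_incorporation(
    peaks: PeakList | Spectrum,
    ion: Ion,
    n_max: Optional[int] = None,
    k_max: Optional[int] = None,
    tol: Optional[float] = None,
) -> IncorporationResult:
    """Estimate the deuterium-incorporation distribution of ``ion`` from a
    spectrum.

    For each isotopomer series k = 0..k_max the ladder positions
    ``mono + (k*d13C + d*d2H)/z`` (d = 0..n_max) are binned against the peak
    list; within a series the binned intensities normalise to fractions f_d,
    giving mean = sum(d f_d) and population SD.  The reported estimate comes
    from the series with the largest total intensity.

    ``peaks`` may be a centroided :class:`PeakList` or a profile
    :class:`Spectrum`; a profile is converted by targeted extraction
    (:func:`~hdxfine.spectrum_io.fit_line_intensities` at the ladder
    positions), which keeps ladder lines sitting below the peak-detection
    threshold instead of truncating them to zero intensity.

    Parameters
    ----------
    n_max :
        Ladder length; defaults to the ion's exchangeable-site count.
    k_max :
        Highest 13C series; defaults to :func:`default_k_max`.
    tol :
        Bin half-width in Da; defaults per target to
        :func:`default_bin_tolerance`.  Must stay below 0.4 * m_HDX / z.

    Raises
    ------
    IonNotDetectedError
        If every ladder position of every series is empty.
    CrossTalkError
        If ``tol`` is too wide for the fine-structure spacing.
    """
    if n_max is None:
        n_max = ion.n_exchangeable
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    if k_max is None:
        k_max = default_k_max(ion)
    guard = 0.4 * M_HDX / ion.z
    if tol is not None and tol >= guard:
        raise CrossTalkError(
            f"tol {tol:g} Da >= 0.4*m_HDX/z = {guard:g} Da: bins would overlap "
            "neighbouring fine-structure species"
        )
    mono = ion.mono_mz
    ladders = [
        peak_ladder(mono, ion.z, k_13C=k, n_max=n_max) for k in range(k_max + 1)
    ]
    if isinstance(peaks, Spectrum):
        targets = np.concatenate([lad.mz_values for lad in ladders])
        peaks = fit_line_intensities(peaks, np.sort(targets))
    series = []
    tols = []
    for ladder in ladders:
        inten = np.zeros(n_max + 1)
        observed = np.full(n_max + 1, np.nan)
        for d, target in enumerate(ladder.mz_values):
            t = tol if tol is not None else default_bin_tolerance(target, ion.z)
            tols.append(t)
            inten[d], obs = bin_intensity(peaks, target, t)
            if obs is not None:
                observed[d] = obs
        series.append(
            SeriesResult(
                k_13C=ladder.k_13C,
                intensities=inten,
                observed_mz=observed,
                theoretical_mz=ladder.mz_values,
            )
        )
    totals = [s.total_intensity for s in series]
    if max(totals) <= 0:
        name = ion.label or f"{ion.mono_mz:.4f}"
        raise IonNotDetectedError(
            f"ion {name} not detected: no peaks within tolerance of any "
            "ladder position"
        )
    selected_k = int(np.argmax(totals))
    return IncorporationResult(
        ion=ion, series=tuple(series), selected_k=selected_k, tol=np.array(tols)
    )


def incorporation_report(
    results: Sequence[IncorporationResult],
) -> pd.DataFrame:
    """One row per analysed ion: identity, selected series, mean/SD deuterium
    uptake, per-d fractions, mass-error RMSE (Da and ppm), peaks matched."""
    if not results:
        raise ValueError("no results to report")
    rows = []
    for r in results:
        frac = r.fractions
        rows.append(
            {
                "ion": r.ion.label,
                "mono_mz": r.ion.mono_mz,
                "z": r.ion.z,
                "selected_k_13C": r.selected_k,
                "mean_D": r.mean_d,
                "sd_D": r.sd_d,
                "fractions": ";".join(f"{x:.6f}" for x in frac),
                "rmse_da": r.rmse_da,
                "rmse_ppm": r.rmse_ppm,
                "n_peaks_matched": r.n_matched,
            }
        )
    return pd.DataFrame(rows)
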