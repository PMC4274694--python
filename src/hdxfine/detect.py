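"""Formula-free detection of deuterium-resolved isotope distributions.

When no composition is known, deuterated ions can still be found by their
ladder signature: runs of peaks spaced (m(2H)-m(1H))/z apart.  Peaks are
chained greedily per candidate charge, the best charge per chain is the one
matching the most peaks (ties to the larger z, whose harmonics subsume the
lower), and overlapping chains are resolved by descending total intensity.
The leftmost chain member is proposed as the monoisotopic m/z; because the
monoisotopic species of a deuterated ion is typically depleted, a chain
whose left edge carries a large share of the envelope is flagged as possibly
truncated (true mono below noise, up to n_exchangeable rungs further left).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem import Ion, PROTON_MASS
from .hdx_theory import DELTA_2H
from .incorporation import IncorporationResult, estimate_incorporation
from .spectrum_io import PeakList

__all__ = ["DetectedIon", "detect_distributions", "estimate_from_mono"]

#: Chains whose leftmost peak exceeds this fraction of the chain maximum are
#: flagged mono_observed=False (depleted-mono heuristic).
EDGE_FRACTION = 0.3


@dataclass(frozen=True)
class DetectedIon:
    """A candidate isotopically resolved distribution."""

    candidate_mono_mz: float
    z: int
    n_peaks: int
    support: np.ndarray          # matched centroids, ascending
    support_intensity: np.ndarray
    mono_observed: bool

    @property
    def total_intensity(self) -> float:
        return float(self.support_intensity.sum())


def _chains_for_z(
    mz: np.ndarray, intensity: np.ndarray, spacing: float, tol: float
) -> list[np.ndarray]:
    """Maximal runs of peak indices with consecutive spacing within tol."""
    chains = []
    n = len(mz)
    is_head = np.ones(n, dtype=bool)
    # next[i]: peak closest to mz[i] + spacing within tol, else -1
    nxt = np.full(n, -1, dtype=int)
    for i in range(n):
        target = mz[i] + spacing
        j = int(np.searchsorted(mz, target))
        best, best_err = -1, tol
        for cand in (j - 1, j):
            if 0 <= cand < n:
                err = abs(mz[cand] - target)
                if err <= best_err:
                    best, best_err = cand, err
        nxt[i] = best
        if best >= 0:
            is_head[best] = False
    for i in np.nonzero(is_head)[0]:
        chain = [i]
        while nxt[chain[-1]] >= 0:
            chain.append(nxt[chain[-1]])
        if len(chain) > 1:
            chains.append(np.array(chain))
    return chains


def detect_distributions(
    peaks: PeakList,
    z_candidates: Sequence[int] = (1, 2, 3),
    min_peaks: int = 3,
    tol: float = 0.005,
    edge_fraction: float = EDGE_FRACTION,
) -> list[DetectedIon]:
    """Find deuterium-ladder candidates in a centroided spectrum.

    Returns candidates sorted by descending total intensity; each peak is
    assigned to at most one chain (greedy by intensity, then more matched
    peaks, then larger z).
    """
    if min_peaks < 3:
        raise ValueError("min_peaks must be >= 3")
    if len(peaks) == 0:
        return []
    candidates: list[tuple[float, int, int, np.ndarray]] = []
    for z in sorted(set(z_candidates)):
        if z < 1:
            raise ValueError("charges must be positive")
        spacing = DELTA_2H / z
        for chain in _chains_for_z(peaks.mz, peaks.intensity, spacing, tol):
            if len(chain) >= min_peaks:
                total = float(peaks.intensity[chain].sum())
                candidates.append((total, len(chain), z, chain))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]), reverse=True)
    used = np.zeros(len(peaks), dtype=bool)
    out = []
    for total, n, z, chain in candidates:
        if used[chain].any():
            continue
        used[chain] = True
        sup_mz = peaks.mz[chain]
        sup_in = peaks.intensity[chain]
        mono_observed = bool(sup_in[0] <= edge_fraction * sup_in.max())
        out.append(
            DetectedIon(
                candidate_mono_mz=float(sup_mz[0]),
                z=z,
                n_peaks=n,
                support=sup_mz,
                support_intensity=sup_in,
                mono_observed=mono_observed,
            )
        )
    return out


def estimate_from_mono(
    peaks: PeakList,
    mono_mz: float,
    z: int,
    n_max: int,
    tol: Optional[float] = None,
    m_adduct: float = PROTON_MASS,
) -> IncorporationResult:
    """Estimate incorporation from a user-supplied monoisotopic m/z and
    charge (no formula: only the 13C = 0 series is evaluated).

    The result is only as good as the supplied mono m/z — if the true
    monoisotopic species is not detectable it must still be specified
    correctly, or every deuterium count is off by the same integer.
    """
    ion = Ion.from_mono_mz(mono_mz, z, n_exchangeable=n_max, m_adduct=m_adduct)
    return estimate_incorporation(peaks, ion, n_max=n_max, k_max=0, tol=tol)
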