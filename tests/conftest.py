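import numpy as np
import pytest

from hdxfine import ElementalFormula, Ion, PeakList, peptide_formula
from hdxfine.hdx_theory import DELTA_2H

#: Human substance P, the worked example used throughout: C-terminally
#: amidated RPKPQQFFGLM, observed as [M+2H]2+.
SUBSTANCE_P = "RPKPQQFFGLM"


@pytest.fixture(scope="session")
def substance_p_formula() -> ElementalFormula:
    return peptide_formula(SUBSTANCE_P, termini="amidated")


@pytest.fixture(scope="session")
def substance_p_ion() -> Ion:
    return Ion.from_sequence(SUBSTANCE_P, z=2, termini="amidated")


def ladder_peaklist(mono_mz: float, z: int, intensities) -> PeakList:
    """A noise-free centroid ladder: peaks exactly at the pseudomonoisotopic
    positions mono + d*(m2H - m1H)/z with the given intensities."""
    intensities = np.asarray(intensities, dtype=float)
    mz = mono_mz + (DELTA_2H / z) * np.arange(len(intensities))
    keep = intensities > 0
    return PeakList(mz[keep], intensities[keep], provenance="synthetic-line")
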