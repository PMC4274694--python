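"""Isotopic fine-structure patterns against an exhaustive enumeration oracle,
and composite deuterated-spectrum modeling."""

import itertools
import math

import numpy as np
import pytest

from hdxfine.chem import (
    ELECTRON_MASS,
    ISOTOPES,
    ElementalFormula,
    FormulaError,
    monoisotopic_mass,
    parse_formula,
)
from hdxfine.fine_structure import (
    DeuterationDistribution,
    deuterated_formula,
    fine_structure,
    model_deuterated_spectrum,
)
from hdxfine.hdx_theory import DELTA_2H


def brute_force_pattern(formula):
    """Independent oracle: enumerate an isotope choice for every single atom,
    multiply abundances, sum masses, and aggregate identical species.

    Exponential in the atom count — usable only for tiny formulas.
    """
    lines = [(0.0, 1.0)]
    for sym, n in formula.items():
        iso = ISOTOPES[sym]
        expanded = []
        for mass, ab in lines:
            for combo in itertools.product(range(len(iso)), repeat=n):
                m = mass + sum(iso[i][0] for i in combo)
                a = ab * math.prod(iso[i][1] for i in combo)
                expanded.append((m, a))
        lines = expanded
    lines.sort()
    masses = np.array([m for m, _ in lines])
    abunds = np.array([a for _, a in lines])
    # identical isotope multisets summed in different atom orders scatter by
    # ~1e-12; distinct species are >= 1e-5 apart for formulas this small
    groups = np.concatenate(([0], np.cumsum(np.diff(masses) > 1e-10)))
    n = groups[-1] + 1
    m_sum = np.zeros(n)
    a_sum = np.zeros(n)
    w_sum = np.zeros(n)
    np.add.at(a_sum, groups, abunds)
    np.add.at(m_sum, groups, masses * abunds)
    np.add.at(w_sum, groups, abunds)
    return m_sum / w_sum, a_sum


def random_small_formulas(n, seed):
    """Random formulas with <= 12 atoms, capped so the per-atom enumeration
    stays below ~3e5 species."""
    rng = np.random.default_rng(seed)
    symbols = ["C", "H", "N", "O", "S"]
    out = []
    while len(out) < n:
        counts = {}
        budget = int(rng.integers(2, 13))
        for sym in rng.permutation(symbols):
            if budget <= 0:
                break
            k = int(rng.integers(0, budget + 1))
            if k:
                counts[sym] = k
                budget -= k
        if not counts:
            continue
        size = math.prod(len(ISOTOPES[s]) ** c for s, c in counts.items())
        if size <= 3e5:
            out.append(ElementalFormula(counts))
    return out


class TestDeuteratedFormula:
    def test_zero_labels_identity(self):
        f = parse_formula("C63H100N18O13S")
        assert deuterated_formula(f, 0) == f

    def test_two_labels(self):
        f = parse_formula("C63H100N18O13S")
        assert str(deuterated_formula(f, 2)) == "C63D2H98N18O13S"

    def test_exceeding_available_h_rejected(self):
        with pytest.raises(FormulaError):
            deuterated_formula(parse_formula("H2O"), 3)


class TestFineStructure:
    def test_methane_closed_form(self):
        aC = ISOTOPES["C"][0][1]
        aH = ISOTOPES["H"][0][1]
        pat = fine_structure(parse_formula("CH4"), prune_threshold=0, merge_tolerance=0)
        assert pat.masses[0] == pytest.approx(16.0313, abs=1e-4)
        assert pat.abundances[0] == pytest.approx(aC * aH**4, rel=1e-12)
        # second-lightest cluster contains the 13C line at +1.00336
        d = pat.masses - pat.masses[0]
        assert np.any(np.abs(d - 1.00336) < 1e-4)

    def test_c2_binomial(self):
        a, b = ISOTOPES["C"][0][1], ISOTOPES["C"][1][1]
        pat = fine_structure(ElementalFormula({"C": 2}), prune_threshold=0, merge_tolerance=0)
        assert np.allclose(pat.abundances, [a * a, 2 * a * b, b * b], rtol=1e-12)
        assert pat.abundances.sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exhaustive_oracle_equivalence(self, seed):
        """Pruned-convolution patterns equal the per-atom enumeration for
        random small formulas (mass 1e-9 Da, abundance 1e-12)."""
        for f in random_small_formulas(10, seed):
            pat = fine_structure(f, prune_threshold=0, merge_tolerance=0)
            om, oa = brute_force_pattern(f)
            # aggregate the implementation's lines on the oracle's grid
            assert len(pat) == len(om), str(f)
            assert np.allclose(pat.masses, om, atol=1e-9), str(f)
            assert np.allclose(pat.abundances, oa, atol=1e-12), str(f)

    def test_conservation_with_pruning(self, substance_p_formula):
        pat = fine_structure(substance_p_formula, prune_threshold=1e-8)
        assert pat.abundances.sum() + pat.pruning_loss == pytest.approx(1.0, abs=1e-9)

    def test_lightest_line_is_monoisotopic(self, substance_p_formula):
        pat = fine_structure(substance_p_formula)
        assert pat.masses[0] == monoisotopic_mass(substance_p_formula)

    def test_fixed_label_contributes_pure_2h(self):
        pat = fine_structure(ElementalFormula({"D": 3}), prune_threshold=0)
        assert len(pat) == 1
        assert pat.masses[0] == pytest.approx(3 * ISOTOPES["D"][0][0], abs=1e-12)
        assert pat.abundances[0] == 1.0

    def test_monotone_pruning(self, substance_p_formula):
        loose = fine_structure(substance_p_formula, prune_threshold=1e-6)
        tight = fine_structure(substance_p_formula, prune_threshold=1e-9)
        # every line reported at the loose threshold survives the tight one
        for m, a in zip(loose.masses, loose.abundances):
            j = np.argmin(np.abs(tight.masses - m))
            assert abs(tight.masses[j] - m) < 1e-6
            assert abs(tight.abundances[j] - a) <= 1e-6

    def test_invalid_prune_threshold(self, substance_p_formula):
        with pytest.raises(ValueError):
            fine_structure(substance_p_formula, prune_threshold=0.01)


class TestModelDeuteratedSpectrum:
    def test_degenerate_distribution_matches_plain_pattern(self, substance_p_formula):
        lines = model_deuterated_spectrum(substance_p_formula, 2, [1.0])
        f_ion = substance_p_formula + ElementalFormula({"H": 2})
        pat = fine_structure(f_ion)
        mz = (pat.masses - 2 * ELECTRON_MASS) / 2
        assert len(lines) == len(pat)
        assert np.allclose(lines.mz, mz, atol=1e-9)
        assert np.allclose(lines.intensity, pat.abundances, atol=1e-12)

    def test_single_label_shifts_lines(self, substance_p_formula):
        base = model_deuterated_spectrum(substance_p_formula, 2, [1.0])
        one = model_deuterated_spectrum(substance_p_formula, 2, [0.0, 1.0])
        # the strongest lines shift by exactly Delta(2H)/z
        top_base = base.mz[np.argsort(base.intensity)[-5:]]
        top_one = one.mz[np.argsort(one.intensity)[-5:]]
        assert np.allclose(np.sort(top_one) - np.sort(top_base), DELTA_2H / 2, atol=1e-6)

    def test_substance_p_fine_structure_lines(self, substance_p_formula):
        """The printed isotopologue positions appear in the composite: the
        2x13C line at 675.3747 and the 1x13C+1D line at 675.3762."""
        lines = model_deuterated_spectrum(substance_p_formula, 2, [0.5, 0.5])
        for target in (675.3747, 675.3762):
            assert np.min(np.abs(lines.mz - target)) < 5e-5

    def test_cluster_top_three_ordering(self, substance_p_formula):
        """Right-to-left within a nominal-mass cluster, the three tallest
        lines are the 0-, 1-, 2-13C species of decreasing deuterium."""
        dist = DeuterationDistribution(np.full(9, 1 / 9))
        lines = model_deuterated_spectrum(substance_p_formula, 2, dist)
        mono = 674.37135
        # cluster at nominal M+6 (0.5 m/z per unit at z=2)
        lo, hi = mono + 2.95, mono + 3.05
        sel = (lines.mz >= lo) & (lines.mz <= hi)
        mzs, ints = lines.mz[sel], lines.intensity[sel]
        top3 = np.sort(mzs[np.argsort(ints)[-3:]])[::-1]  # descending m/z
        spacing = np.diff(top3)
        assert np.allclose(-spacing, 0.0015, atol=1e-4)

    def test_distribution_validation(self):
        with pytest.raises(ValueError):
            DeuterationDistribution(np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            DeuterationDistribution(np.array([1.5, -0.5]))

    def test_total_abundance_weighted(self, substance_p_formula):
        dist = [0.25, 0.75]
        lines = model_deuterated_spectrum(substance_p_formula, 2, dist)
        f_ion = substance_p_formula + ElementalFormula({"H": 2})
        expected = sum(
            fd * fine_structure(deuterated_formula(f_ion, d)).abundances.sum()
            for d, fd in enumerate(dist)
        )
        assert lines.intensity.sum() == pytest.approx(expected, abs=1e-9)
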