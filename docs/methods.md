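# Methods

This note records the models, algorithms, numerical choices and known
limitations behind `hdxfine`, in the order the pipeline runs.

## Chemistry substrate

Isotope masses come from the AME atomic-mass evaluation and natural
abundances from the IUPAC-CIAAW representative values, embedded as a static
table in `chem.py` (H, C, N, O, S, P, and the fixed label `D` = pure ²H).
The printed reference m/z values (e.g. 674.3713 for the substance P
[M+2H]²⁺) are reproducible only with ≥7-decimal masses, which is why the
table is pinned rather than delegated to a dependency; the test suite
cross-checks it against `pyteomics.mass.nist_mass` as an independent oracle.

Protonation uses the proton mass m(¹H) − mₑ = 1.00727645 Da at full
precision internally; values are rounded only for display. When charge
carriers are instead embedded in a formula (auto-protonation disabled), m/z
is computed as (mass − z·mₑ)/z so the electron deficit is still accounted.

Exchangeable-hydrogen counting is policy-based because no single rule suits
every use: `backbone_amide` (peptide-bond NH, excluding proline) matches how
protein HDX data are usually interpreted; `all_labile` (all N/O/S-bound H
including termini and side chains) bounds how far a deuterium ladder can
physically extend and is the default for matching; `all_H` is the formula
hydrogen count. Side-chain labile counts use the neutral species (Arg 5,
Lys/Asn/Gln 2, Ser/Thr/Tyr/Cys/Asp/Glu/His/Trp 1).

## FTICR planning relations

Three relations connect instrument settings to the resolution needed for
direct deuterium readout:

1. magnitude-mode resolving power `RP = 1.274e7·z·B₀·T_acq/m`, with `m` the
   **absolute ion mass** `z·(m/z)` — the cyclotron-frequency reading, under
   which the explicit z cancels (`RP = 1.274e7·B₀·T_acq/(m/z)`);
2. the 50%-valley width for equal Lorentzians separated by `m_HDX/z`:
   `Δm₅₀ = (m_HDX/z)·√(√33−5)/√2 ≈ 0.6101·m_HDX/z`;
3. the acquisition period obtained by equating the two at
   `m/z = (M+z·m_adduct)/z`:
   `T_acq = (M+z·m_adduct)²/(1.274e7·Δm₅₀·z²·B̄₀)`.

The absolute-mass reading in (1) is the only one under which (3) carries z²
(a pure-m/z reading would give z³); the package keeps them algebraically
consistent to 1e-9 relative, which the property tests enforce. Absorption-
mode gains default to 1.45 at 9.4 T (a conservative published figure) and
2.0 (the theoretical maximum) elsewhere, overridable per instrument.

## Fine-structure computation

Patterns are computed per element by multinomial expansion over the
element's isotopes, then combined by pairwise convolution in ascending
pattern-size order. Numerical choices:

- **Mass excesses, not absolute masses**, are convolved: each element
  pattern is shifted by its all-lightest-isotope mass before convolution and
  the formula's monoisotopic mass is added back at the end. The lightest
  line therefore equals `monoisotopic_mass(f)` bit-exactly, and intermediate
  sums lose no precision to large offsets.
- **Pruning** at threshold 1e-8 (abundance) is applied to element patterns,
  intermediate products, and the final pattern. Dropping an intermediate
  term below the threshold is safe because every later convolution factor
  has abundance ≤ 1, so a surviving final line can never have had a
  sub-threshold prefix. The un-reported abundance is exposed as
  `pruning_loss`, and abundance + loss = 1 to 1e-9.
- **Merging** collapses lines within 1e-6 Da (abundance-weighted mean mass)
  — three orders of magnitude below the 0.0015 m/z fine-structure spacing at
  z = 2, so distinct observable species never merge.
- Deuterium labels are a separate pure-²H species; **natural hydrogen keeps
  its trace ²H abundance** (1.15e-4) in the remaining pool. Whether the
  original approach included that trace on unlabeled sites is not
  documented; ours is toggleable (`natural_deuterium=False`). The z
  charge-carrying protons are added as natural H before labeling: they are
  exchange-irrelevant but isotopically natural.
- The exhaustive per-atom enumeration (exponential, test-only) is the
  oracle: for random ≤12-atom formulas the convolution must agree to 1e-9 Da
  and 1e-12 abundance.

A composite deuterated spectrum weights the fine structure of each
d-labeled formula by the fraction f_d and merges the union of lines; with
dist = [1, 0, ...] it reduces exactly to the unlabeled pattern.

## Spectrum handling and peak extraction

Input is headerless two-column ASCII (m/z, intensity; whitespace or commas),
the least common denominator across instrument vendors; rows are sorted and
duplicate m/z summed, and malformed lines are reported with their line
number. Preprocessing (optional): discrete wavelet denoising (sym8, level
⌊log₂ n⌋ − 4, soft universal threshold with the noise scale from the MAD of
the finest detail coefficients) and a moving-minimum/moving-average
baseline, clipped at zero. These are stated defaults of this package, not
reproductions of the original tool's unpublished choices. The m/z axis can
be slid by a constant (default) or in ppm; proper external calibration is
still assumed for assignment work.

Peak picking detects local maxima whose height **and prominence** exceed
`min_snr` (default 3) times a robust noise scale (1.4826×MAD over the lower
80% intensity quantiles; synthetic raw spectra keep their negative noise
excursions, so the median-based scale is unbiased). Prominence matters:
noise ripples riding on the tail pedestal of a strong Lorentzian pass a
height test but not a prominence test. Centroids are refined by 3-point
parabolic interpolation.

Apex intensities are then re-estimated by a **joint non-negative
least-squares fit of Lorentzian line shapes** at the picked centroids,
clustered wherever gaps exceed 6 FWHM (tails < 1% beyond that), with a
single spectrum-wide FWHM taken from the strong peaks (weak-peak
half-prominence widths are biased narrow). This matters at fine-structure
spacings: neighbouring lines sit ~3 FWHM apart, so a raw apex reading is
inflated by neighbour tails, while the joint fit both deconvolves the
overlap and averages grid noise down by roughly √(points per peak width).
A common line-shape mismatch rescales all amplitudes equally and cancels
when the estimator normalises.

`fit_line_intensities` extends the same fit with *supplied* positions
(targeted extraction): a line below the detection threshold still receives
its small fitted amplitude instead of being truncated to zero — the
difference between a biased and an (approximately) unbiased deuteration
distribution when part of the envelope is near the noise floor.

The synthetic generator renders line spectra as Lorentzians (the natural
FTICR peak shape; Gaussian optional) on a grid of ≤ FWHM/5, adds a constant
baseline and seeded white Gaussian noise, and is deterministic per seed.

## The incorporation estimator

For an ion of known mono m/z and charge, the pseudomonoisotopic ladder
`mz[d] = mono + (k·Δ¹³C + d·Δ²H)/z` is evaluated for the isotopomer series
k = 0..k_max; spectrum intensity is collected in bins of half-width
`min(2 ppm, 0.3·m_HDX/z)` around each position (the cap keeps a bin from
touching its fine-structure neighbour one `m_HDX/z` away; requesting a
tolerance ≥ 0.4·m_HDX/z is a hard error). Within a series the binned
intensities normalise to fractions, mean = Σ d·f_d, SD = population formula.
The headline estimate comes from the series with the largest total
intensity — usually k = 0 for small peptides; all series are reported so a
weighted combination can be formed downstream if preferred. k_max defaults
to the first k whose natural k-¹³C abundance falls below 5% of the base
(k = 4 for substance P's 63 carbons), or 3 without a formula. Missing rungs
legitimately score zero (the monoisotopic peak of a deuterated species is
depleted). Mass accuracy is summarised as the RMSE of (observed −
theoretical) over all matched peaks, in Da and ppm.

Profile input is routed through targeted extraction at the ladder positions
(see above); centroided input is binned as-is.

## Formula-free detection

Deuterium ladders are found by chaining peaks whose consecutive spacing
matches `Δ²H/z` within a tolerance (default 0.005 Da), per candidate charge;
the deuterium spacing, not the ¹³C spacing, is targeted because deuterated
distributions are the objects of interest. The best charge for a chain is
the one matching the most peaks, ties to the larger z (higher-z harmonics
subsume lower); overlapping chains are resolved greedily by descending total
intensity with each peak assigned once. The leftmost member is proposed as
the mono m/z. Because a deuterated ion's monoisotopic peak is strongly
depleted, a chain whose left edge carries more than `edge_fraction`
(default 0.3) of the chain maximum is flagged `mono_observed=False`: its
true mono plausibly sits below the noise, up to n_exchangeable rungs further
left. This is a heuristic — a genuinely flat envelope can be flagged
spuriously — and the flag is advisory, not a gate.

## Digestion and matching

Built-in cleavage rules: trypsin and chymotrypsin (blocked by P1′ proline),
Glu-C, Lys-C, Asp-N (N-terminal side of D), and a coarse pepsin-above-pH-2
consensus (after F/L/W/Y/A/E/Q). Because acid proteases cleave too broadly
for any site rule to be trusted, the all-fragments mode (every substring in
a length range) is the safety net. Coordinates are 1-based inclusive.
Zero-missed-cleavage digests tile the parent exactly — a property test, not
an assumption.

Standard matching accepts a peptide when a detected distribution's candidate
mono lies within the ppm tolerance of the theoretical mono m/z at some
charge. Missing-mono matching anchors the ladder at the theoretical mono and
requires ≥ 3 *consecutive* rungs to align, never extending past the
peptide's exchangeable-site count — that bound is what keeps a heavily
deuterated, mono-less envelope from matching arbitrary peptides. The mono is
then reported as assigned-from-theory with `mono_detected=False`. Peptides
indistinguishable within tolerance (same elemental composition, or chance
coincidence) are all reported and flagged ambiguous; ties order by ladder
RMSE, then matched-peak count.

## Synthetic data: what it does and does not emulate

The generator produces exactly the physics the estimator relies on:
fine-structure line positions and abundances, Lorentzian peak shape at a
uniform sampling of ≤ FWHM/5, white Gaussian noise at a chosen base-peak
SNR, optional constant baseline and calibration offset. The round-trip
tests use substance P at z = 2, FWHM 5×10⁻⁴ m/z (resolving power ≈ 1.35M
at m/z 674 — the regime in which fine structure is actually resolved),
base-peak SNR 50, and Dirichlet(1)-random deuteration distributions over
d = 0..8 — deliberately spread distributions that exercise weak-line
extraction. Problem sizes (50 spectra of ~60k points) keep the full suite
in single-digit minutes on one core.

Not emulated: correlated (pink) detector noise, space-charge frequency
shifts and coalescence of closely spaced peaks, intensity-dependent peak
widths, chromatographic scan averaging, and back-exchange. Passing
round-trip tests therefore demonstrates correctness of the calculation
chain under ideal line shapes, not robustness to every instrumental
artefact; on real data the mass-calibration and alignment tools exist
precisely because those artefacts occur.

## Known limitations

- The estimator assumes fine structure is resolved; below the required
  resolving power the pseudomonoisotopic bins capture blended intensity and
  the distribution is no longer meaningful (no automatic fallback to
  envelope-centroid methods).
- Chimeric, overlapping envelopes are not deconvolved; detection assigns
  each peak to one chain greedily.
- The pepsin rule is a coarse consensus; use all-fragments for real pepsin
  digests.
- `mono_observed` is heuristic (see above).
- Back-exchange correction and kinetic (time-course) fitting are out of
  scope; the package reports per-spectrum uptake only.
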