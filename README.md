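# hdxfine

Deuterium-uptake estimation for hydrogen/deuterium-exchange mass spectrometry
(HDX-MS) in the regime where **isotopic fine structure is resolved**.

## The problem

HDX-MS probes protein structure by incubating a molecule in D₂O and measuring
how many labile hydrogens exchange for deuterium. At ordinary resolving
powers the deuterated peaks overlap the natural heavy-isotope peaks (¹³C,
¹⁵N, ¹⁸O, ³⁴S), so deuterium content must be inferred from centroid shifts of
whole isotope envelopes. At ultrahigh resolving power the nuclear mass
defects separate these species: an ion that gained one deuterium is heavier
than its one-¹³C isotopomer by

    m_HDX = (m(²H) − m(¹H)) − (m(¹³C) − m(¹²C)) ≈ 2.922 mDa,

and once peaks m_HDX/z apart are resolved, the deuterium-only
("pseudomonoisotopic") peaks can be read directly. `hdxfine` implements the
whole workflow around that observation:

- **chem** — elemental formulas (with a fixed `D` label), an embedded
  AME/IUPAC isotope table, peptide→formula conversion with modifications and
  C-terminal amidation, adduct/charge arithmetic, exchangeable-site counting
  (`backbone_amide`, `all_labile`, `all_H` policies).
- **hdx_theory** — m_HDX, pseudomonoisotopic peak ladders
  `mz[d] = mono + (k·Δ¹³C + d·Δ²H)/z`, and FTICR planning: the 50%-valley
  Lorentzian peak width `Δm₅₀ = (m_HDX/z)·√(√33−5)/√2`, the magnitude-mode
  resolving power `RP = 1.274×10⁷·B₀·T_acq/(m/z)`, and the acquisition
  period `T_acq = (M+z·m_adduct)²/(1.274×10⁷·Δm₅₀·z²·B̄₀)` with absorption-
  mode effective field B̄₀.
- **spectrum_io** — headerless two-column ASCII spectra, wavelet denoising,
  baseline subtraction, m/z alignment shifts, peak picking with joint
  Lorentzian amplitude fitting, and a seeded synthetic-spectrum generator.
- **fine_structure** — exact isotopic fine-structure patterns by pruned
  multinomial convolution, deuterium-labeled formulas, and composite
  theoretical spectra for a measured deuteration distribution.
- **incorporation** — the estimator: bin spectrum intensity at the ladder
  positions of each k-¹³C isotopomer series, normalise to a deuteration
  distribution, report mean, SD, and mass-error RMSE from the most abundant
  series.
- **detect** / **digest** — formula-free ladder detection with charge
  inference, in-silico proteolysis (trypsin, chymotrypsin, Glu-C, Lys-C,
  Asp-N, pepsin, custom rules, all-fragments mode), and peptide–spectrum
  matching including distributions whose monoisotopic peak is undetectable.
- **cli** — `hdxfine calc | model | detect | digest | match | plan |
  simulate | batch`.

## Worked example

Simulate a deuterated spectrum of substance P (C-terminally amidated
RPKPQQFFGLM, the classic demonstration peptide) with a known symmetric
uptake distribution of mean 3.5, then estimate the uptake back from the
spectrum alone:

```sh
hdxfine simulate --sequence RPKPQQFFGLM --amidated --z 2 \
    --fractions 0.05,0.1,0.15,0.2,0.2,0.15,0.1,0.05 --seed 7 --out subp_d2o.txt
hdxfine calc --spectrum subp_d2o.txt --sequence RPKPQQFFGLM --amidated --z 2 --n-max 7
```

```
        ion   mono_mz  z  selected_k_13C   mean_D     sd_D                                                               fractions  rmse_da  rmse_ppm  n_peaks_matched
RPKPQQFFGLM 674.37135  2               0 3.507928 1.801859 0.050565;0.098240;0.149573;0.198676;0.199133;0.153952;0.100808;0.049054 0.000109  0.160654               35
```

The sequence is converted to C₆₃H₉₈N₁₈O₁₃S (monoisotopic [M+2H]²⁺ at m/z
674.3713); intensities at the pseudomonoisotopic ladder recover the input
fractions, the mean uptake 3.51 vs the true 3.5, and sub-ppm mass residuals.
`selected_k_13C 0` says the estimate came from the all-¹²C isotopomer
series, the most intense one for a peptide this small.

Planning an experiment instead: how long an ICR transient does a 1 kDa
peptide need on a 21 T instrument in absorption mode?

```sh
hdxfine plan --mass 1000 --z 1,2,3 --field 21 --mode absorption
```

```
 z          mz  dm50_mDa  resolving_power   Tacq_s
 1 1001.007276  1.782800    561480.437372 1.050396
 2  501.007276  0.891400    562045.434286 0.526256
 3  334.340610  0.594267    562610.431201 0.351543
```

At z = 2 the deuterium fine structure resolves in ~0.53 s — compatible with
the fast chromatography HDX demands.

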