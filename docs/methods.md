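# Methods

## Scope and model

`hydropep` characterizes enzymatic protein hydrolysates from MS-based
peptide identification tables. The underlying view is that a hydrolysate's
bulk behaviour (emulsifying, foaming, antioxidative) is the cumulative
property of all its peptides, and that MS1 precursor intensity is a usable
relative-abundance proxy: high responders are assumed to be highly
abundant, so intensity-weighted population statistics describe the mixture
better than per-identification counts. Both weighted and unweighted
statistics are always computed side by side so the assumption stays
visible rather than baked in.

## Per-peptide properties

For a peptide of sequence length `L` (PCL):

* **PMW** is the sum of residue masses plus one water. Monoisotopic
  masses are the default because high-resolution MS pipelines report
  monoisotopic values; an average-mass mode exists for bench comparisons.
* **Pz**, net charge at pH 7, is the fixed side-chain contribution sum:
  Lys +1, Arg +1, His +0.1, Asp −1, Glu −1, Cys −0.07; all other residues
  and both termini contribute 0. The terminal amine (+≈1) and carboxylate
  (−≈1) approximately cancel at neutral pH, which is why a side-chain-only
  model is coherent. This is deliberately not a Henderson–Hasselbalch
  titration; there is no pH parameter.

## Weighted population statistics

Weighted means are `x_avg = Σ x_p I_p / Σ I_p` with MS1 intensity `I_p`
as weight; the weighted SD uses the finite-population correction

    SD = sqrt( Σ I_p (x_p − x_avg)² / ((M−1)/M · Σ I_p) ),

with `M` the number of non-zero weights. Unweighted columns use the same
formulas with unit weights, where the expression reduces to the ordinary
sample statistics; one formula serves both, which is also how the code is
written. Zero-intensity records ("not detected") are dropped at ingestion
by default since they carry no weight; a flag retains them.

Relative intensity (RI) is a peptide's percentage of the sample's summed
MS1 intensity; duplicate sequences are aggregated before normalization.
Ranking is by descending intensity with lexicographic tie-breaking (the
tie rule is a package choice; ties are measure-zero in real data).
Cross-sample fold changes are RI ratios, displayed at one decimal with
half-up rounding, as are all report-facing numbers.

### Binning

Histogram bins follow fixed rules: PCL in 5-residue bins labelled by
centre (3–7 → 5, 8–12 → 10, …); PMW regrouped into 500 Da bins
([150, 750) → 500, [750, 1250) → 1000, …) with everything above 4250 Da
pooled at 4500 Da; Pz rounded half-up to the nearest integer and capped
at −7 (below −6.51) and +3 (above +2.5). The integer-rounding rule for Pz
closes the small gaps the interval notation of the source convention
leaves open (e.g. values near 0.495); the caps are implemented exactly as
stated, including their asymmetry.

## Degree of hydrolysis

`DH% = 100 · αAN_hyd / αAN_tot` from free α-amino-nitrogen readings, and
the DH-based mean chain length is the reciprocal of the cleaved-bond
fraction, `PCL_DH = 100 / DH%`. The reciprocal reading is the only one
consistent with worked values (27.0 % → 3.7 residues). For synthetic
digests the package also books the *true* DH exactly (cleaved bonds over
total bonds), which lets one quantify how far an assay-style DH and a
ground-truth DH can drift apart.

## Amphiphilicity scores

Raw scores on the Kyte–Doolittle scale `h`:

* α: length-normalized hydrophobic moment at 100°/residue,
  `|Σ_j h_j e^{i·j·100°}| / L` — facial amphiphilicity of a helix.
* β: the same moment at 180°/residue, `|Σ_j h_j (−1)^j| / L` — strand
  face alternation.
* γ: `max_k |mean(h[1..k]) − mean(h[k+1..L])|` over contiguous splits
  with both segments ≥ 3 residues — axial (two-region) amphiphilicity.
  Three residues is the smallest stretch we accept as a "region"; the
  choice is a package convention.

These operationalizations realize the qualitative definitions (largest
amphiphilic vector in a given conformation; distinct hydrophobic and
hydrophilic regions). They are not claimed to reproduce any specific
published scorer bit-for-bit: reference implementations leave details
(face partitioning vs. vector moments, null composition) unspecified, so
exact agreement with published per-peptide score tables is out of scope.
Qualitative agreement is good — e.g. the decapeptide IIAPPERKYS comes out
strongly γ-dominant here (z_γ ≈ 3.1 at the default null) as it does in
published rankings.

### Null normalization

Raw scores grow with length differently per conformation, so each is
z-normalized against a null of 40,000 random peptides of the same length:
`z = (s − μ(L)) / σ(L)`, with σ the population SD (at n = 40,000 the
sample/population distinction is negligible). The default null
composition is uniform over the 20 standard residues; a frequency table
can be supplied. Nulls are cached in-process per (length, n, seed,
composition), and the RNG stream is derived from (seed, length, n) so one
root seed reproducibly covers a whole scoring pass. Scoring is fully
vectorized; a 40,000-peptide null for one length builds in well under a
second.

A peptide with `z > 2` (strict) in some conformation is flagged as a
predicted emulsifier in that conformation. Under a normal null this would
be the top 2.5 %; the empirical nulls are right-skewed (especially γ), so
the tests assert the weaker, checkable statement that ≥ 95 % of null
peptides fall below z = 2, and the normal-theory interpretation is
reported as an interpretation, not asserted.

### Pipeline filters

Scoring is applied to the top-100 peptides by MS1 intensity with PCL > 6
(shorter peptides cannot form a well-defined interfacial secondary
structure). Antioxidant candidates are the top-100 with PCL ≤ 30; their
activity scores come from external neural-network predictors and are only
passed through, never computed here.

## Assay calculators

EAI `= 2·2.303·A0·D/(φ·c·10⁴)` (m²/g), ESI `= A0/(A0−A10)·10` (min, ∞
when no decay is measured — reported as a distinct infinite-stability
signal, not an overflow), FC/FS as volume percentages (FS undefined when
no foam forms), DPPH inhibition `= (1 − (A_s − A_0)/A_b)·100`, ferrous
chelation `= (A_blank − (A_sample − A_blind))/A_blank·100`. Inhibition is
not clamped to [0, 100]; negative values expose assay problems.
IC50/EC50 is read off an OLS line of inhibition on concentration over all
supplied points (no origin constraint, no point selection); a non-positive
slope is an error, and an IC50 outside the measured inhibition range is
returned but flagged as extrapolated. The DPPH negative control is taken
per measurement point; pooling it is a data-preparation choice upstream
of the calculator.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Proteome**: by default 100 entries (scaled down from reference-scale
  proteomes for test-speed; reference-scale counts are exercised in the
  counting helpers analytically), lengths uniform ±20 % around the target
  mean, residues i.i.d. from a fish-muscle-like composition (Glu/Asp/Lys/
  Leu-rich); an exact composition of any specific substrate is not
  reproduced.
* **Digest**: each peptide bond C-terminal to residue `r` is cut with
  probability `specificity[r]` per generation — Bernoulli per bond, not
  kinetics, because ranked, specificity-flavoured peptide sets are all
  the downstream analyses need. Two built-in profiles: a Leu/Phe-
  preferring neutral-protease profile ({L: 0.8, F: 0.8}) and a broad
  subtilisin-like profile (0.6 over A/V/L/I/M/F/W/Y). Fragments outside
  the 3–65 residue identification window stay in the log (they count for
  true DH) but are excluded from the observable table, mimicking how free
  amino acids, dipeptides and grey-zone peptides escape identification.
* **Intensities**: log-normal (ln-scale mean 14 ≈ 1.2·10⁶ arbitrary
  units, ln-SD 1.5 — typical MS1 dynamic range of ~3–4 orders of
  magnitude) times `exp(−b·PCL)` with default b = 0.03, a mild version of
  the shorter-peptides-fly-better bias; b = 0 switches it off.
* **Dose–response**: inhibition `= 50 + slope·(conc − IC50_true) + ε`,
  so the noiseless line crosses 50 % exactly at the true IC50.

What the generator does *not* emulate: sequence-dependent flyability,
retention-time effects, identification FDR, missing-value structure, or
real substrate composition. Passing tests therefore demonstrate that the
arithmetic and the estimators are correct and self-consistent under
controlled conditions — not that any specific published table of measured
values is recovered, which would require the unpublished raw data.

## Numerical and design choices

* Report-facing rounding is half-up (`0.05 → 0.1`), one decimal for fold
  changes and chain lengths, matching bench-table conventions; internal
  values are full precision.
* Weighted statistics require ≥ 2 non-zero weights (the SD denominator is
  undefined otherwise); all-zero weights are an error, not a NaN.
* Determinism: every generator and the whole pipeline are pure functions
  of (configuration, seed); re-running a configuration produces
  byte-identical reports.
* Problem sizes in the validation suite (e.g. 100-protein proteomes,
  2,000-peptide nulls in pipeline smoke tests, 40,000 where the null
  itself is under test) are chosen to exercise every code path at
  comfortable interactive speed; the statistical assertions set their
  tolerances from the Monte-Carlo error at those sizes.

## Known limitations

* PMW/Pz of modified residues are computed on the plain sequence after
  stripping modification marks; modification mass shifts are ignored.
* The charge model is valid only at pH 7 by construction.
* Published per-peptide amphiphilicity scores are approximated in rank
  and sign, not reproduced numerically (see above).
* IC50 by straight-line regression is only sensible in the quasi-linear
  mid-range of a dose–response curve; no sigmoidal model is offered
  because the estimator is defined as linear.
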