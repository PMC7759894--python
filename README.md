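# hydropep

Intensity-weighted peptide profiling for enzymatic protein hydrolysates.

Protein hydrolysates — e.g. from fish-processing side-streams — are
complex peptide mixtures whose bulk behaviour (emulsifying, foaming,
antioxidative activity) is the cumulative property of thousands of
peptides. `hydropep` characterizes such mixtures from MS-based peptide
identification tables (MaxQuant `peptides.txt`-style TSV) for food-protein
and peptidomics researchers:

* **Per-peptide properties**: chain length (PCL), molecular weight (PMW,
  residue masses + water), and net charge at pH 7 (Pz) from a fixed
  side-chain contribution table (K/R +1, H +0.1, D/E −1, C −0.07).
* **Weighted population statistics**: MS1-intensity-weighted and
  unweighted means, `x_avg = Σ x_p I_p / Σ I_p`, with weighted SD
  `√(Σ I_p (x_p − x_avg)² / ((M−1)/M · Σ I_p))` (M = non-zero weights),
  binned histograms, relative-intensity (RI %) abundance, and
  cross-sample fold changes.
* **Amphiphilicity scoring**: raw α / β / γ scores on the Kyte–Doolittle
  scale (hydrophobic moment at 100°/residue and 180°/residue; best
  two-segment mean contrast), z-normalized against 40,000 random
  same-length peptides, `z = (s − μ(L)) / σ(L)`; `z > 2` flags a
  predicted emulsifier conformation.
* **Hydrolysis metrics**: DH% from α-amino-N, DH-based mean chain length
  `PCL_DH = 100 / DH%`, and exact true-DH bookkeeping for in-silico
  digests.
* **Assay calculators**: EAI, ESI, foaming capacity/stability, DPPH and
  ferrous-chelation inhibition, and IC50/EC50 by linear regression.
* **Synthetic data**: proteome generator, enzyme-specificity-flavoured
  stochastic digests with ground-truth DH, MS1-like intensities with an
  optional length bias, and dose–response series with known IC50 — so the
  whole pipeline is testable end-to-end with no external data.

See `docs/methods.md` for the full model description and the design
choices.

## Worked example

Simulate a hydrolysate (100 synthetic proteins, broad subtilisin-like
digest), then profile it:

```sh
hydropep simulate --n-proteins 100 --mean-length 326 \
    --enzyme alcalase --seed 1 --out demo/sim
# wrote 4271 peptide records; true DH = 21.48%

hydropep profile --input demo/sim/peptides.tsv --out demo/profile \
    --top-n 20 --null-n 40000 --seed 1
# wrote 6 report files to demo/profile
```

`demo/profile/report.json` then contains the per-sample summary:

```json
"alcalase": {
 "n_peptides": 4009, "m_nonzero": 4009,
 "pcl_avg": 6.1441,  "pcl_avg_u": 6.9481,
 "pmw_avg": 732.3482, "pmw_avg_u": 825.8362,
 "pz_avg": -0.4073,  "pz_avg_u": -0.4839,
 "sd_pcl": 3.6995, "sd_pmw": 428.7516, "sd_pz": 1.5288
}
```

The weighted mean chain length (6.14) sits below the unweighted one
(6.95) because the simulated MS1 intensities carry a mild bias towards
shorter peptides — exactly the kind of weighting effect the summary is
designed to expose. The scored table (top-20 most abundant peptides with
PCL > 6) reports z-scores per conformation and flags predicted
emulsifiers:

```text
sequence  rank  ri_pct  z_alpha  z_beta  z_gamma best  flags
EKRRQNCY     3  1.0952  -0.4564 -0.4923   0.5754 gamma
DDTNDKI      4  1.0214   1.0944  0.3181  -0.3972 alpha
LEYKLKMM    23  0.3800   0.8712  2.2590  -0.3076 beta   beta
```

Here `LEYKLKMM` exceeds z = 2 in the β-strand projection: its
hydrophobic/hydrophilic alternation beats ~97–98 % of random peptides of
its length, marking it a predicted β-emulsifier.

Library use mirrors the CLI:

```python
from hydropep import read_peptide_table, summarize_sample
from hydropep.amphiphilicity import score_peptide
from hydropep.hydrolysis import pcl_from_dh

parsed = read_peptide_table("demo/sim/peptides.tsv")
summary = summarize_sample(parsed.records)
score = score_peptide("IIAPPERKYS", n=40000, seed=1)   # z_gamma ≈ 3.15
pcl_dh = pcl_from_dh(27.0, decimals=1)                 # 3.7 residues
```

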