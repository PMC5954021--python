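# glycoemt

Quantitative pipelines around PD-L1 N-glycosylation and the
epithelial–mesenchymal transition (EMT): mass-spectrometry-based
N-glycan **site-occupancy** quantification with a spontaneous-deamidation
control, two-arm **EMT signature scoring** of expression matrices with
gene–score correlation, and the small companion study metrics
(quantitative IHC score, caliper tumor volume, MFI fold change). A
synthetic-data module generates inputs with known ground truth for every
stage, so the whole pipeline is testable without any external download.

Intended for proteomics / cancer-biology analysts who need a
reproducible, scriptable implementation of these calculations rather
than spreadsheet arithmetic.

## The core calculations

**N-glycan site occupancy.** PNGase F removes N-linked glycans and
converts the occupied Asn (N) to Asp (D), shifting the tryptic peptide
mass by the exact deamidation delta (0.984016 Da). Peptide species are
quantified from extracted ion chromatograms (XICs) in a ±10 ppm window
around the calculated accurate m/z, normalized across samples with two
non-glycosylated reference peptides (DQLSLGNAALQITDVK, m/z 843.4570 at
2+; AEVIWTSSDHQVLSGK, m/z 586.3003 at 3+). With

- *I*<sub>N</sub> — normalized intensity of the native (N×T) peptide after PNGase F,
- *I*<sub>NF</sub> — normalized intensity of the de-glycosylated (D×T) peptide after PNGase F,
- *I*<sub>ND</sub> — normalized D×T intensity from a control run without PNGase F
  (spontaneous deamidation),

the percent site occupancy is

    occupancy % = (I_NF − I_ND) / (I_N + I_NF) × 100

clamped to [0, 100] with QC flags. Full occupancy implies
*I*<sub>N</sub> = 0 and *I*<sub>ND</sub> = 0, giving exactly 100%.

**EMT score.** Raw expression is transformed to gene-wise log2 ratios
(log2(x + pseudocount), median-centered per gene so 0 means
"unchanged"), and each sample is scored as

    EMT score = mean(log ratio, mesenchymal arm) − mean(log ratio, epithelial arm)

over a 37-gene two-arm signature (20 mesenchymal + 17 epithelial);
higher is more mesenchymal-like. Gene–score and gene–gene association
use Pearson correlation with two-sided p-values.

**Study metrics.** IHC score = percent positive (0–100) × intensity
grade (0–3), range 0–300; tumor volume = *l* × *w*² / 2 (longest ×
shortest caliper diameter, mm³); MFI fold change = treated / control.

## Worked example

Simulate three replicate MS runs at a true occupancy of 65% with a 10%
spontaneous-deamidation rate and 5% multiplicative noise, then quantify:

```bash
glycoemt simulate ms --seed 7 --theta 0.65 --d 0.1 --noise-cv 0.05 \
    --n-replicates 3 -o peaks.csv
glycoemt occupancy peaks.csv -o occupancy.tsv
```

`occupancy.tsv`:

```
site_id  sample_id  IN        INF       IND        raw_percent  occupancy_percent  flags
site1    rep1       0.314626  0.694435  0.0332664  65.5         65.5
site1    rep2       0.302331  0.653249  0.0328647  64.9         64.9
site1    rep3       0.310886  0.706677  0.0365113  65.9         65.9
```

The formula recovers the simulated 65% occupancy to within the noise of
each replicate. Scoring a simulated two-group expression matrix whose
PD-L1 gene (CD274) is linked to group membership:

```bash
glycoemt simulate expr --seed 7 --effect 1.0 --linked CD274:0.5 -o expr.tsv
glycoemt emt expr.tsv -o scores.tsv --correlate-genes CD274 \
    --correlations-out corr.tsv
```

Epithelial-group samples score around −1.2, mesenchymal-group samples
around +1.2 (the construction separates the group means by twice the
per-arm effect), and `corr.tsv` reports the CD274–EMT-score correlation
`r = 0.538, p = 7.7e-09, n = 100` — positive, as built into the
simulation. Every command writes a JSON run log (inputs, parameters,
version, constants hash) next to its output; identical inputs produce
byte-identical outputs.

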