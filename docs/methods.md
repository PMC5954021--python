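# Methods

## Site-occupancy model

The occupancy stage treats each glycosite × sample as three observable
normalized intensities. Let θ be the fraction of protein molecules
carrying a glycan at the site, d the fraction of *unoccupied* sequons
that deamidate spontaneously during sample handling, and A the sample's
protein abundance in arbitrary MS units. Assuming equal recovery and MS
response for the N×T and D×T forms of the same peptide, the expected
intensities are

    I_N  = A (1 − θ)(1 − d)      native peptide, PNGase F run
    I_NF = A (θ + (1 − θ) d)     Asp peptide, PNGase F run
    I_ND = A (1 − θ) d           Asp peptide, control (no PNGase F) run

and the estimator (I_NF − I_ND) / (I_N + I_NF) × 100 equals 100·θ
identically — for any A and any d. θ and d are the generator's own
latent parameters; only the intensities are observables. The estimator
is clamped to [0, 100]: sampling noise can push I_ND above I_NF at low
occupancy, producing a negative raw value that is clamped to 0 and
flagged `negative_raw` rather than dropped. A zero denominator
(no native and no de-glycosylated signal) leaves the occupancy unset
with flag `zero_denominator`.

Key assumptions: a single defined tryptic peptide per site (no
miscleavage variants, no charge-state summation), equal ionization of
the N and D forms, and negligible in-source deamidation differences
between the two runs.

## Mass and m/z arithmetic

Peptide masses are monoisotopic residue sums plus one water
(18.010565 Da), using the standard 5-decimal residue table; the proton
mass is 1.00727646 Da, so [M + zH]^z+ has m/z (M + z·1.00727646)/z.
This table reproduces the two reference peptides' published m/z
(843.4570 at 2+, 586.3003 at 3+) exactly at 4-decimal precision. The
Asn→Asp shift uses the exact monoisotopic delta 0.984016 Da rather than
the nominal one mass unit: at m/z ~850 a 10 ppm window is ±0.0085,
so the ~0.49 m/z separation of the 2+ species is resolved with three
orders of magnitude to spare, but the exact delta keeps the window
centered on the true species.

## XIC extraction and peak quantity

An extracted ion chromatogram sums, per scan, all centroid intensities
inside the closed window target·(1 ± ppm·1e-6); boundary ties are
included, and both bound inclusion and tolerance-widening monotonicity
are tested properties. The per-ion quantity is the **trapezoidal area**
of the trace over retention time (a single-point trace degenerates to
its intensity; an empty trace to 0). Apex height is the obvious
alternative; area was chosen because it is robust to retention-time
sampling density, which the simulator varies freely. The default
tolerance is 10 ppm, configurable via `--ppm`.

## Reference normalization

Protein amount is equalized across samples using the two
non-glycosylated reference peptides. Per sample, the scale factor is
mean(baseline reference intensities) / mean(sample reference
intensities), pooling reference rows across both run conditions of that
sample — i.e. both runs of a sample share that sample's own reference
anchor. The arithmetic mean of the two reference peptides is used; the
baseline sample defaults to the first sample in input order and is
configurable (`--baseline-sample`). Because occupancy is a ratio of
same-sample intensities, it is invariant to any per-sample rescaling —
a tested property — so normalization matters only for cross-sample
intensity comparisons and the low-signal floor. `low_signal` is flagged
when I_N + I_NF falls below 1e-6 of the baseline reference mean
(there is no principled instrument threshold for synthetic data; the
floor is configurable in code).

## EMT scoring

Raw matrices are transformed as log2(x + pseudocount) and centered
gene-wise so 0 means "unchanged for this gene". The centering statistic
is the **median** across samples (mean exposed via `--center`): the
score's defining convention ties 0 to "unchanged", and the median is
robust to the skewed, zero-inflated marginals of RNA-seq counts. The
default pseudocount is 1 on an RSEM-like scale. The score is the mean
log ratio over found mesenchymal-arm genes minus the mean over found
epithelial-arm genes; genes missing from the matrix are dropped with a
warning and per-arm coverage is reported, while an arm with no matches
is fatal. Gene matching is exact and case-sensitive after whitespace
strip — alias resolution is out of scope.

The packaged signature file (`emt_signature_synthetic.tsv`) is a
synthetic stand-in: 20 canonical mesenchymal and 17 canonical
epithelial gene symbols arranged in the expected two-arm, 37-gene
structure. Analyses of real data should supply their preferred
signature via `--signature`.

Heatmap color ramps are linear per RGB channel from the neutral color
(black for expression, gray for scores) to the full hue (red/green for
expression, yellow/blue for scores) at |value| ≥ vmax (defaults 3.0 and
1.0 log2 units — purely presentational). Clustering and tree viewers
are out of scope; the color-matrix output orders samples by descending
EMT score as its deterministic stand-in for sample ordering.

## Study metrics

IHC score = percent positive × intensity grade; the grade is a single
ordinal 0–3 per specimen (digital composite intensities are not
modeled), and fractional grades are rejected. Tumor volume
l × w² / 2 swaps its arguments with a warning when w > l rather than
failing, since caliper tables frequently transpose the two. Marker
correlation is Pearson on raw scores by default with Spearman as a
config alternative (no method is canonical for tissue-microarray score
correlations).

## Synthetic-data generators

*MS runs*: expected intensities from the model above; noise is
multiplicative log-normal with mean 1 and a chosen CV, applied
independently per intensity — MS peak intensities are positive and
approximately CV-stable, and the choice makes "noise 0" an exact
identity. Reference peptides scale with A under the same noise.
Defaults: d = 0.1, CV = 0 (noise is opt-in), 3 replicates.

*Spectra*: each table intensity becomes a Gaussian elution profile
(default center 10 min, σ = 0.5 min) sampled on a uniform grid of 50
scans spanning ±4σ, so the trapezoidal XIC area reproduces the table
intensity to well under 2% at m/z jitter ≤ 2 ppm; jitter is Gaussian in
ppm around the theoretical m/z, and jitter beyond the extraction window
produces the expected signal loss.

*Expression*: per-gene baselines ~ N(8, 1.5) log2 units; in the
mesenchymal group, mesenchymal-arm genes shift +effect and
epithelial-arm genes −effect (so the group mean score difference is
2·effect, ≈ 2 at the default effect of 1); linked genes achieve a
requested point-biserial correlation with group membership through
β = σ·ρ/√(1−ρ²); residual noise σ = 0.5 log2 units; values return to
raw space as powers of two. Default 50 + 50 samples, 20 background
genes.

*IHC*: a latent equicorrelated multivariate normal per specimen, mapped
monotonically to percent positive (100·Φ(z)) and to grades 0–3 by the
fixed latent-quantile cuts {0.25, 0.5, 0.75} (arbitrary but frozen for
reproducibility). Discretization attenuates the latent correlation, so
recovered score correlations are biased toward zero — tests assert
recovery bands, not equality. The default table size is 129 specimens,
matching a tissue-microarray-sized cohort.

These generators emulate structure, not realism: no isotope envelopes,
no chromatographic tailing or retention drift, no real transcriptome
marginals or batch effects. Passing tests demonstrate the
*calculations* are correct and the pipeline recovers known ground
truth under its stated noise model — not that the noise model matches
any particular instrument or cohort.

## Numerical and interface choices

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); identical configs give byte-identical
outputs, and run logs deliberately contain no timestamps. Reported
precision follows the field's prints: m/z at 4 decimals, occupancy at
1 decimal. Problem sizes in tests (3 replicates, 50-scan spectra,
30–120-sample matrices, 200-repetition null calibration) are chosen as
the smallest sizes at which the asserted tolerances are statistically
meaningful. Exit codes: 0 on success, 2 on validation failure;
`--strict` escalates row-level range violations from per-row error
records to a validation failure.

mzML I/O is intentionally minimal: MS1 centroid arrays (32/64-bit,
plain or zlib) and scan start times, which is exactly what XIC
extraction consumes. MS/MS identification, isotope-envelope
deconvolution, retention-time alignment and glycan composition
assignment are out of scope.

## Known limitations

- One ion per peptide form: miscleavages and charge-state summation are
  not modeled.
- Occupancy variance across replicates is reported only implicitly (one
  row per replicate); no pooled uncertainty estimate is made.
- The EMT score treats arms as exchangeable gene sets; no gene
  weighting or signature re-derivation.
- The IHC grade mapping shares one latent variable with percent
  positive per marker, which overstates the percent–grade coupling
  relative to real stains.
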