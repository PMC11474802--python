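# Methods

This note records the model behind `isohyl`, the defaults it ships with,
and the reasoning for choices that are not forced by the chemistry.

## Chemical model

Protein lysine 5-hydroxylation (5-Hyl) places a hydroxyl on carbon 5 of
the lysine side chain, adjacent to the ε-amine. Among the hydroxylysine
constitutional isomers only 5-Hyl forms a 1,2-aminoalcohol, which sodium
periodate cleaves to an aldehyde with loss of methanimine (net −CH5N).
The aldehyde then condenses with methoxyamine to an oxime ether
(+CH5NO −H2O), or with biotin hydrazide or D3-methoxyamine. The package
models every reaction as composition arithmetic over a fixed monoisotopic
element table (H 1.0078250319, C 12, N 14.0030740052, O 15.9949146221,
S 31.97207069, D 2.0141017780; proton 1.00727646688). All derived masses
trace to that single table.

Summing the steps relative to unmodified lysine —
hydroxylation (+O), periodate (−CH5N), methoxyamine conjugation
(+CH5NO −H2O) — yields the composite search delta O(+1) H(−2),
i.e. +13.9793 Da, which is what the search applies as one variable
modification (`hyl5_ox_moa`). Its diagnostic neutral loss is CH5NO
(47.0371 Da); the D3 reagent shifts reagent-derived masses by +3.0188 Da.
The biotin-hydrazide form's cumulative delta is C9H11N3O2S: the same
two-step algebra with biotin hydrazide (C10H18N4O2S) condensing as a
hydrazone (−H2O).

Isomer selectivity is modeled structurally: the periodate transform is the
identity on species without a 1,2-aminoalcohol motif (e.g. the
1-aminopentan-3-ol and 5-amino-2-pentanol analogs of the aminopentanol
test molecule, and 4-/3-hydroxylysine by extension), and it raises an
error if applied twice.

## Peptide model and search

Digestion is tryptic (cleave after K/R, not before P); a modified lysine
blocks cleavage, so peptides carrying 5-Hyl retain internal K. Up to 6
missed cleavages are enumerated (modified-K blocking makes high missed
counts routine). Fragmentation produces b/y ions at all charge states up
to the precursor charge; ions covering a modified span additionally get
neutral-loss variants (one loss per ion), and the precursor and its loss
are included.

Scoring is a binomial survival function: with n observed peaks, fragment
tolerance t (0.5 Da) and a fixed m/z span of 1900, the chance that a
random peak matches a theoretical ion is p = n·2t/1900; the score is
−10·log10 P(X ≥ k) for k matched of m theoretical ions. This is the
standard Andromeda-style tail bound, but it is not numerically identical
to any published engine's score, so published score cutoffs (e.g. "score
40") do not transfer. Error control therefore does not use a score
cutoff: reversed-sequence decoys are searched alongside targets and PSMs
are filtered at 1% target-decoy FDR (q = running #decoys/#targets,
monotonized from the bottom).

Site localization over the candidate placements of the composite delta
uses a softmax of the per-placement scores (base 10, i.e. dB weighting);
sites below probability 0.75 are excluded from the site table and logged.
The 0.75 default plays the role of a localization filter comparable in
intent, not in calibration, to published class-I site thresholds.

Precursor tolerance is 4.5 ppm, fragment tolerance 0.5 Da, at most 6
variable modifications per peptide. The site table aggregates PSM
intensity per (protein, position, modification) and run by maximum.
Match-between-runs is not implemented; the identification manifest says
so explicitly.

## XIC quantification and reaction efficiency

XICs sum MS1 intensity in an inclusive m/z window; areas are trapezoidal
integrals over retention time, with optional minimum-baseline
subtraction. Reaction efficiency partitions the three form areas
(unreacted U, oxidized O, conjugated C): oxidation efficiency is
(O+C)/(U+O+C), conjugation efficiency is C/(U+O+C) by default — i.e. the
conjugated share of all material. An alternative denominator
(conjugated share of reacted material, C/(O+C)) is available via
`conjugation_of_reacted=True`; with areas 6/24/70 the two conventions
give 70% and 74.5%, and the default reproduces the benchmark pair
94%/70%. The benchmark windows are the published 2+ XIC windows of the
collagen peptide GFPGTPGLPGFKGIR with hydroxyproline at P3/P6/P9 and
5-Hyl at K12 (782.9080–782.9100, 767.3880–767.3900, 781.9005–781.9024);
the reconstruction of three hydroxyprolines and charge 2 follows from
those windows and the peptide's elemental composition.

## Differential quantification

Intensities are divided by each sample's spike-in (leupeptin-channel)
area, log2-transformed, and tested with an equal-variance two-sample t
per site; q-values are Benjamini–Hochberg by default, with an optional
permutation FDR (condition-label shuffles, expected significant in
permutations / observed, monotonized). The s0-moderated variant used by
some analysis platforms is deliberately not replicated. A one-tailed
Welch test (p < 0.05 in a stated direction) and z-score + average-linkage
Euclidean hierarchical clustering (row-minimum imputation) complete the
toolbox.

Two caveats are worth recording. First, with 3v3 replicates the plain t
statistic has 4 degrees of freedom; planted log2 fold changes near 1 are
genuinely marginal at BH 0.05, so recovery of effects drawn from
N(2, 0.5) fluctuates around 90% across simulation seeds. Second, the
simple label-shuffle FDR is contaminated by true effects (permuted splits
of a strongly changed row produce extreme statistics), which puts a floor
of a few percent on its achievable q when effects are large and common.

## Enrichment statistics

Flanking windows (default ±6, '_'-padded at termini) feed a position
frequency matrix (TSV; rows residues + padding, columns offsets) and a
motif-x-style iterative search: repeatedly fix the (offset, residue) pair
with the smallest binomial tail p-value (threshold 1e-6, minimum support
20), restrict both sets to matches, emit the motif, remove matched
windows, repeat. Ties break deterministically on (p, offset, residue).

Secondary-structure depletion compares modified sites against all
lysines in the identified background with a hypergeometric test,
one-sided in the observed direction (depleted classes get the lower
tail). Generic over-representation analysis over GMT annotation sets
uses the hypergeometric upper tail with BH adjustment.

## Synthetic data

The simulator is the package's ground-truth instrument, not a full
LC-MS/MS emulator. It models: Gaussian elution profiles (σ = 3 s,
1 s scan interval), the three reaction forms of each planted peptide at
their theoretical m/z with form fractions 0.06/0.24/0.70 (unreacted/
oxidized/conjugated), MS1 m/z jitter of 0.2 ppm (high-resolution
precursor precision; the printed XIC windows are only ~±1.3 ppm wide, so
larger jitter would leak across window edges), MS2 spectra of the
conjugated form with 5 ppm fragment jitter, 20% fragment dropout and 30
uniform noise peaks, and log-normal intensities. It does not model
isotope envelopes, co-isolation/chimeric spectra, charge-state
heterogeneity, retention-time drift between runs, or detector
saturation.

The two-condition generator draws per-site base abundances
(log2 ~ N(20, 1.5)), marks a fraction 0.1 of sites as affected, gives
each affected site a log2 fold change drawn from N(2, 0.5) in the
treated condition, adds residual log2 noise of σ = 0.25 per measurement
(3 vs 3 design), and multiplies every sample by a log-normal (σ = 0.3)
spike-in factor that is also recorded as that sample's spike-in area, so
normalization can undo it exactly. The defaults above are the study
conditions for all seeded properties; problem sizes (12 proteins of
150–300 residues, 2 sites each) are chosen so the full pipeline runs in
seconds on one CPU while still exercising every code path.
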