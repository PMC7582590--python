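# Methods

## The emulated design

The package targets stimulation time-course translatome experiments:
matched Ribo-seq, mRNA-seq and small-RNA-seq libraries from an untreated
control and two post-stimulus harvests (0 h, immediately after
stimulation, and 2 h after a rest phase), four biological replicates
each, with every treatment contrasted against control.  The simulator's
defaults encode these conditions; all analyses work equally on user
counts and read tables.

## Simulator

**Transcriptome.** Single-isoform genes with uniform region lengths
(5′UTR 100–300 nt, CDS 120–400 codons, 3′UTR 200–800 nt) and per-region
GC targets (0.55/0.52/0.45).  CDSs start with ATG, end with a stop and
contain no internal in-frame stop; internal codons are drawn base-wise at
the GC target and redrawn if they form a stop, which biases the realized
GC by well under the ±0.1 contract.  Coordinates are 0-based half-open;
all sequences are DNA, converted to/from RNA only at the small-RNA
boundary.

**Regulatory modes.** Each gene draws one of five modes; with effect
size e (default 1.0 log₂) and a per-gene sign s = ±1 the planted
(mRNA, RPF) log₂ fold changes are: homodirectional (se, se), opposite
(se, −se), transcriptional (se, 0), translational (0, se), stable (0, 0).
The default 0 h mix is transcription-heavy (0.35/0.17/0.04/0.02/0.42
for transcriptional/translational/homodirectional/opposite/stable) and
the 2 h mix translation-heavy (0.05/0.25/0.06/0.02/0.62), reproducing
the qualitative buffering asymmetry between early and late responses
without copying dataset-specific counts.

**Counts.** Gene abundances are log-normal (σ = 1) relative weights;
the expected count in a library is `baseline · 2^log2FC · depth` with
depth 10⁶ and NB dispersion φ = 0.04 (biological coefficient of
variation 0.2; φ = 0 degenerates to Poisson).  The dispersion of real
quadruplicate cell-culture libraries varies by protocol; φ is a plain
config value and the type-I calibration analysis is additionally run at
φ = 0.1.

**RPF reads.** Reads carry a fixed P-site offset (default 12 nt, the
conventional distance for ~29 nt footprints) and frame fidelity
f = 0.80 (the fraction of P-sites on codon starts; the remainder split
uniformly over frames 1–2).  A `leakage` fraction (0.05) of P-sites
falls in the UTRs, split evenly.  A fraction `init_peak` (0.08) of
CDS P-sites sits on the first codon, emulating the initiation-site
density peak characteristic of cycloheximide-arrested ribosome
profiling; without an initiation feature, start-codon cross-correlation
calibration would be unidentifiable modulo 3 on uniform coverage, so the
peak is a deliberate part of the emulated signal.  Read lengths follow a
peaked 27–32 nt distribution.

**miRNA sites.** Each gene draws a site count (default probabilities
0.55/0.20/0.15/0.10 for 0–3 sites) and a catalog miRNA; the 7-nt DNA
reverse complement of the miRNA seed (nucleotides 2–8) overwrites the
3′UTR at non-overlapping random positions.  Recorded site counts are
re-counted after planting, so chance seed matches are included — the
analysis-side counter must reproduce exactly this quantity.  In the
end-to-end experiment, upregulated miRNAs repress their targets' mRNA
(not RPF) abundance by 0.2 log₂ per site, saturating at three sites —
the canonical degradation-first mechanism.

**tsRNA reads.** Synthetic precursor tRNAs are `leader(50) + mature(73)
+ CCA` with landmarks at mature positions 13–22 (D-loop) and 31–39
(anticodon loop, anticodon pinned at 34–36).  Reads are exact substrings
cut at an origin landmark: 5′ mature (start at mature position 0),
3′ mature (end at the CCA 3′ terminus), D/anticodon loop, or contained
in the precursor leader.  tRFs draw 14–27 nt, tRHs 31–36 nt, so the
generator never emits the ambiguous 28–30 nt zone; the classifier still
resolves that zone by anticodon-loop overlap.

**What the generator does not emulate.** Sequence-dependent ligation or
PCR bias, positional ramps beyond the single initiation peak, isoforms
and overlapping genes, multi-mapping, UTR-length evolution, miRNA
expression–target co-dependence, or tRNA modifications that break
reverse transcription.  Passing tests therefore demonstrate correctness
of the statistical machinery under the stated generative model, not
robustness to every artifact of real libraries.

## Analysis choices

**Normalization.** TMM factors are computed against the sample whose
75th-percentile CPM is closest to the mean of those; M/A values over
genes positive in both samples are trimmed (30 % per M tail, 5 % per A
tail) and averaged with inverse delta-method variance weights.  Factors
here are *total* normalizers — they absorb depth and composition, are
rescaled to geometric mean 1, and normalized counts are counts divided
by the factor.  If fewer than 10 genes survive trimming the untrimmed
mean is used with a warning.

**Dispersion.** Gene-wise method-of-moments estimates on normalized
counts (pooled within-condition variance with its exact residual df),
floored at 0; the common value is the median of the positive estimates;
per-gene values are shrunk as `w·φ̂ + (1−w)·common` with
`w = n_reps/(n_reps+4)`.  Parameter-recovery tests (Poisson data →
common ≤ 0.01; φ = 0.1 data → common in [0.08, 0.12]) justify this
lighter replacement for conditional-likelihood machinery.

**Exact test.** Counts are divided by their factors (placing all samples
on the common effective library scale), rounded and summed per group; a
group sum of n libraries with per-library mean μ and dispersion φ is
NB(nμ, φ/n).  Conditional on the total, the p-value is the summed
probability of all splits no more likely than the observed one.  Ties
are included with a relative cushion of 1e-9: symmetric splits are exact
mathematical ties whose inclusion must not depend on floating-point
path.  Reported log₂ fold changes add a fixed pseudo-count of 0.125 on
the normalized per-sample scale; p-values never see the pseudo-count.
Low-expression filtering (CPM ≥ 0.5 in ≥ 4 samples by default) happens
before testing, so the BH multiplicity denominator counts only tested
genes.

**TE test.** Both assays' counts enter one NB log-linear model per gene
(IRLS with the fixed moderated dispersion; log TMM factor as offset);
Δlog₂TE is the assay×condition interaction and the p-value a 1-df LRT.
Fits that do not converge are flagged, reported with missing p, and
excluded from BH.  Because the mRNA baseline and condition effects are
absorbed by main effects, the interaction is invariant to global
scaling.

**Mode classification** uses the DE significance rule (FDR < 0.05 and
|log₂FC| > 0.5), not raw p-values; a zero fold change with a
significance flag is treated as positive and flagged in the output.

**Folding.** The minimum free energy model is a Nussinov-style DP over
pair energies (GC −3, AU −2, GU −1) with hairpin loops of at least three
unpaired bases and no pseudoknots — simple enough to verify against
exhaustive structure enumeration, which the tests do for all sequences
up to 18 nt.  NMFE is MFE divided by length.  The DP is O(n³);
`compute_features` folds regions up to 400 nt by default (longer regions
get NA) and accepts externally computed MFE values per gene/region for
users with a thermodynamic folder.  numba accelerates the DP when
available; results are identical without it.

**G-quadruplex scoring.** Run scoring: bases in G runs score
+min(run, 4), C runs −min(run, 4); 25-nt windows with mean ≥ 1.2 are
G4-positive and overlapping positive windows merge into one counted
region.

**Stratification.** Quartile edges at the empirical 25/50/75
percentiles with ties assigned to the lower bin; Kruskal–Wallis H (with
tie correction, χ² with 3 df) compares fold-change distributions across
quartiles.  Rare codons default to the bottom decile of an embedded
human codon-usage table (six codons: ACG, CCG, CGA, CGT, GTA, TCG) and
are fully user-replaceable.

**Small-RNA targets.** Seed matching is mandatory and direct (no
context scoring or thermodynamic duplex model): overlapping occurrences
of the reverse-complemented seed in the 3′UTR.  Site-count strata
{1, 2, ≥3} are compared to the zero-site background by two-sided
two-sample KS; strata under 20 genes are reported but not tested.

**tsRNA mapping.** Tiered matching — exact substring, then Hamming
distance 1, 2, 3 scanned over every gapless offset (deletions are
approximated by this offset scan; a documented simplification).  Among
equal-tier placements the first one consistent with a cleavage landmark
(valid origin and length class) wins, which resolves rare random
sequence collisions between references.  Origin rules, in order: start
at mature position 0 → 5′ mature; end at the (CCA-tailed) mature 3′
terminus → 3′ mature; contained in the leader → 5′ precursor; otherwise
inside the mature body overlapping the D- or anticodon loop → D/A loop.
Length classes: ≤27 nt tRF, ≥31 nt tRH, 28–30 nt resolved by
anticodon-loop overlap.  Species merge over (amino acid, anticodon,
origin, class) with ids like `GluTTC-tRF-3` (suffixes 1/3/5/DA for
leader, 3′ mature, 5′ mature, loops).  tsRNA DE applies a CPM > 100
robust-expression filter (above threshold in every sample of at least
one condition) before the exact-test path.

## Validation design and problem sizes

Each validation analysis isolates one mechanism under the generator
conditions relevant to it: oracle equivalence on enumerable sizes
(totals ≤ 200; sequences ≤ 18 nt); type-I error on a stable-only
simulation (2000 genes, 4 replicates, φ = 0.1, the generator's
dispersion passed to the test); KW/KS null uniformity over 200
replicates of 2000 genes; offset/fidelity recovery from 10⁵ reads over
150 transcripts; mode and TE recovery on 2000 genes at depth 10⁶ under
the transcription-heavy mix; miRNA CDF shifts on a stable background
with planted per-site repression of 0.2 log₂; and the tsRNA chain on
10⁴ exact-cut reads plus three small end-to-end experiments.  Detection
of a single planted two-fold-down tRF is a stochastic power property
(the fold-change estimator's SD at φ = 0.04 with four replicates is
≈ 0.2 log₂), so it is asserted as a majority over three seeds rather
than at a single seed.

## Known limitations

The exact test's pseudo-conditional construction (group-sum NB with
plug-in mean) is mildly conservative at small totals, like the
analogous qCML construction.  Moment dispersion estimates are noisier
than conditional-likelihood ones at four replicates; moderation toward
the common value keeps calls calibrated but per-gene φ is not reliable
on its own.  The folding model ignores stacking thermodynamics and
temperature; NMFE values are comparable within this model only.
Mismatch-only tsRNA matching under-counts reads with true indels.
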