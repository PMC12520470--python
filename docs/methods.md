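# Methods

## Glycan model and serialization

Glycans are rooted trees over five monosaccharide symbols; linkage and
anomericity are out of scope by design — every classification in this
package is purely topological. Identity below the Hex/HexNAc level is
inferred from position: core Hex residues are mannoses, the Hex child of a
branch GlcNAc is galactose, a branch-initiating HexNAc is GlcNAc, and a
HexNAc child of a branch GlcNAc is GalNAc (hence `N(N)` reads as
GalNAcβ1-4GlcNAc, LacdiNAc). The linear structure code
(`node := SYMBOL child*`, children parenthesized) is this package's own
format; upstream search-engine exports are adapted through a pluggable
text→text converter registry (`glycan.register_converter`), so the core
model never needs to know foreign dialects.

Canonicalization sorts siblings by the lexicographic order of their own
canonical serializations. Two serializations are equal exactly when the
subtrees are identical, so no further tie-break can ever fire; the
implementation therefore uses a plain text sort, and determinism is tested
over 1000 random trees with permuted sibling orders.

Composition codes use `N/H/F/S/G` with an implicit count of 1, plus the
`Man<k>` shorthand (= `N2Hk`). Structural `Man3`–`Man9` use a fixed table
of the standard mammalian processing intermediates; where several
trimming isomers exist (Man4, Man6–Man8) one representative topology is
shipped — isomer choice at that level is a convention, not data.

Strict parsing (default) requires the full core: reducing-end GlcNAc,
second core GlcNAc, β-mannose and two arm mannoses. Relaxed mode accepts
truncated/paucimannose input and flags it; classifications that need core
landmarks raise on truncated trees rather than guessing.

## Feature extraction

A *branch* is the maximal subtree rooted at a child of an arm mannose.
The bisecting GlcNAc sits on the β-mannose and is a core-level feature
(Core-III/IV), never a branch and never counted as an antenna. Bare arms
contribute the EMPTY label "⌀"; antenna count is the number of non-EMPTY
branches, so Man5 counts 2 and a bisected biantennary still counts 2.

Branch motifs are matched in three stages: (1) all-Hex subtrees →
mannose-extension ("Hex"); (2) exact canonical-code lookup in the motif
table — 11 built-in HexNAc-initiated motifs, with Lewis^x/a^ vs ^y/b^ and
sLewis pairs collapsed because linkage is unavailable, and user extensions
(label → pattern code) taking priority; (3) a polyLacNAc rule for pure
repeated `N(H(` chains of ≥ 2 units. Anything else maps to "other" with a
warning, never a crash. Decorated polyLacNAc chains (e.g. sialyl-capped
repeats) currently fall to "other"; widening the rule is a config-level
change. The motif vocabulary is deliberately extensible because upstream
engines ship larger branch databases than the named motifs here.

Subtype: oligo-mannose iff no arm mannose carries a HexNAc-initiated
branch; complex iff at least one HexNAc-initiated branch exists and no
mannose-extension branch remains; hybrid otherwise. A bare core (all arms
empty) is classed oligo-mannose. For single-armed truncation-like cases
the same rule yields hybrid whenever a HexNAc branch coexists with a
Hex-only extension.

## Quantification

* Channel normalization divides each reporter channel by a scaling
  factor; factors are either supplied (derived from the global-proteome
  table, the default in the pipeline) or self-derived as channel totals
  scaled to their mean, which equalizes totals and makes downstream fold
  changes invariant to per-channel loading.
* PSM aggregation is the per-channel median; an even PSM count uses the
  mean of the central pair.
* The differential test is a classic pooled-variance unpaired two-sided
  *t*-test on log₂ intensities (a Welch toggle exists); the fold change is
  the ratio of group means of the normalized linear intensities (a median
  option exists). The call rule is FC > 1.5 or < 1/1.5 with *p* < 0.05;
  thresholds are configuration (an FC > 2 preset included). No
  multiple-testing correction is applied by default; Benjamini–Hochberg is
  available as an option.
* Zeros are replaced by half the smallest nonzero value in that channel
  before the log transform and flagged; an all-zero group yields an `ns`
  call with a flag instead of an error.
* Protein normalization: `norm_fc = fc / protein_fc`. IGPs without a
  protein match keep their raw fc, are flagged `no-protein`, and are
  excluded from quadrant statistics. Quadrants: Type I iff the protein
  change is significant (|log₂ FC| above the threshold, protein *p* <
  0.05) and the protein-normalized glyco change is not; Type II the
  converse (using the IGP's own *p*-value with the normalized FC); "both"
  and "unchanged" otherwise; direction suffix follows the significant
  axis.

## Feature mining

All proportions use unique IGPs — distinct (peptide, glycosite, canonical
structure, O-acetyl) keys — never PSMs. Core/subtype/antenna/fucosylation/
sialylation are partition axes (proportions sum to 1); branch proportions
count an IGP once per carried motif (presence basis), so they may sum
above 1 — a multiplicity mode divides branch-position counts by total
positions instead. The up:down ratio per feature compares the feature's
share of up-regulated versus down-regulated IGPs; the altered fraction is
(n_up + n_down)/n_total. Rankings break ties by canonical code for
determinism. Whether oligo-mannose IGPs are excluded before computing
differential proportions is exposed as a flag (both conventions are
defensible; default keeps them).

Glycan-shift sites are glycosites with at least one up- and one
down-regulated IGP; the per-site contrast statistic is the difference of
feature proportions between up and down members, with no site-level
significance test (a deliberate choice: per-site member counts are tiny).

O-acetylated sialoglycopeptides are matched to the IGP with the identical
(peptide, glycosite, structure) key and the acetyl flag off; agreement of
their fold changes is summarized by Spearman correlation over pairs
(undefined, flagged, below 3 pairs).

## Age/sex decomposition

"Excluding" the other factor is implemented as mean-centering log₂
intensities within that factor's levels, then a one-way ANOVA on the
factor of interest; η² = SS_between/SS_total of that ANOVA. This slightly
overstates residual degrees of freedom (the centering consumes some), so
null assignment rates run marginally above nominal α — acceptable for a
screening assignment and documented here rather than hidden. A stratified
alternative (per-stratum ANOVAs, Fisher-combined *p*, sample-size-weighted
η²) is available behind `method="stratified"` since the combination rule
is genuinely open. Assignment: the significant factor (*p* < 0.05) with
the larger η²; "both" when both are significant and the η² values are
within 10% relative; thresholds are config values.

## Integration

Partial Spearman is Pearson correlation of rank residuals (ranks of x and
y residualized on ranks of the control by least squares), with the *t*
approximation on *n* − 3 df — verified to agree exactly with pingouin's
implementation. Note a genuine property of this standard estimator: under
a strong common driver with weak noise, small-sample partial correlations
retain a slight positive mean; the estimator is reported as-is. The
glyco–phospho pair classifier's r-threshold is configurable with presets
at 0.5 and 0.05 (default 0.5), both kept because the two conventions
coexist in practice. Hub ranking filters edges below the combined-score
threshold 0.4, computes degree/betweenness/closeness/eigenvector
centralities, takes descending average ranks per method and aggregates by
mean rank, ties broken by node id. Annotation cross-tabulation counts a
multi-label protein's IGPs once per category, with an "unannotated"
bucket.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study *design*: 10 TMT channels, 5 vs 5
pooled samples, 3F/2M per group; log₂-normal reporter noise (sd 0.25 —
a realistic post-normalization reporter CV of ≈ 18%); 1–4 PSMs per IGP;
≈ 73.5% single-glycosite proteins; an ≈ 34% oligo-mannose share of IGP
draws; planted |log₂FC| = 1.3 feature-selected effects (elevated
sialyl-LacNAc, depressed bisected+sole-GlcNAc); a 10% protein-level
confounding fraction at log₂FC = 1 that propagates into raw IGP
intensities (so protein normalization must undo it); six designated
shift glycosites pairing an up-planted Core-I/sialylated structure with a
down-planted Core-III/sole-GlcNAc structure; O-acetyl twins on 15% of
sialylated IGPs; and shared-signal coupling between selected glyco and
phospho sites. Regular sites are constrained to one planted direction so
the designated shift sites are exactly the mixed-direction ground truth.

It does **not** emulate: missing values/interference in reporter ions,
isotope impurity, ratio compression, peptide-level misidentification,
shared peptides across proteins, or realistic intensity-dependent
variance. Passing recovery tests therefore demonstrates correctness of
the mining logic under the stated noise model, not robustness to every
artifact of real TMT data. Default problem sizes (120 proteins ≈ 380
IGPs; 900 proteins ≈ 2500 IGPs for null calibration) were chosen to give
stable recovery statistics at interactive runtimes.

## Numerical choices

TSV with header is the canonical format (CSV by extension); floats are
written with 6 significant digits, counts as integers; positions are
1-based; sequon classification uses residues N, N+1, N+2 with X ≠ Pro
enforced. Duplicate IGP keys on input are treated as PSM replicates.
Unknown configuration keys are rejected outright. CLI exit codes: 0
success, 2 configuration error, 3 data error.

## Known limitations

No linkage/anomericity, no O-glycans or glycosaminoglycans, no spectral
or B/Y-ion evidence handling, no isotope-impurity correction, no protein
inference, and no enrichment-service calls — annotation joins are against
user-supplied tables only. The branch motif table covers the motifs named
above plus "other"; real exports may require extending it via config, and
the structure-code converter for any particular engine's dialect must be
written against that engine's files.
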