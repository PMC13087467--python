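# Methods

## Transcript model and coordinates

GTF and VCF coordinates are 1-based inclusive genomic; all internal offsets
are 1-based transcript coordinates increasing 5′→3′, with explicit
bidirectional converters (`CoordinateMap`). Minus-strand transcripts are
reverse-complemented on load so every downstream module sees mRNA-sense
sequence only; a strand-symmetry test asserts that a gene and its mirrored
minus-strand encoding produce identical mature UTRs and annotations. The
coordinate map covers the concatenated 5′ UTR + CDS so that stops of
overlapping uORFs, which lie inside the CDS, stay genomically resolvable.

Transcripts are loaded from a GENCODE-dialect GTF via `gffutils`
(transcript/exon/CDS features; `gene_name`, `tag`, and an optional
`mane_id` attribute). `transcript_set="mane"` keeps transcripts carrying
the MANE tag; `"all"` keeps every transcript with an annotated CDS.
Transcripts without a CDS, or flagged CDS-incomplete (`cds_start_NF`/
`cds_end_NF`), are skipped with a logged reason rather than guessed at.
Transcripts whose CDS starts at the first transcript base (zero-length
5′ UTR) stay in the catalog but produce no annotations: there is no UTR
interval for a variant to intersect and the −3 Kozak position would lie
outside the mRNA.

## uORF scanning

Only canonical ATG starts are considered; every ATG whose A lies in the
mature 5′ UTR opens one candidate uORF (uORFs sharing a stop but differing
in start are kept distinct). The codon walk runs through the UTR and into
the CDS. Typing:

* in frame with the CDS, stop before the CDS start → **non-overlapping**;
* in frame, no stop before the CDS → **N-terminal extension** (the walk is
  not continued into the CDS, whose in-frame stop is the main stop codon);
* out of frame → walk continues into the CDS; stop inside → **overlapping**;
  stop before the UTR ends → non-overlapping; no stop anywhere in the
  annotated CDS → overlapping with stop codon `NA` (a corner the scheme
  does not otherwise define).

`uORF_LENGTH` includes the stop codon and `uORF_AA_LENGTH` excludes it, so
`length_nt = 3·(length_aa + 1)` is a testable invariant for stopped uORFs.
For N-terminal extensions the length is the uAUG-to-CDS distance (a
multiple of 3 by the frame condition) and the end coordinate is the last
UTR base (the CDS entry point). Rank 1 is the uAUG closest to the CDS
start; ties (impossible for distinct starts) would break toward the
smaller offset, making output ordering deterministic. The scanner is
validated against an independent brute-force enumerator (a plain triple
loop in the fixture module) on hundreds of randomized UTRs of 0–300 nt.

## Kozak contexts

The stored context is the 9-mer covering −4..+5 around an ATG, padded with
`N` at transcript ends. Strength uses only −3 and +4, the two positions
that dominate initiation efficiency: Strong when −3 ∈ {A,G} and +4 = G
(matching the (A/G)CCAUGG consensus), Adequate when exactly one matches,
Weak when neither, `NA` when either position is unavailable. uKozak/mKozak
consequences are called only when the strength *category* changes, not on
any substitution inside the 9-mer; this keeps calls tied to a predicted
efficiency change rather than sequence cosmetics.

## Consequence calling

Variants are applied to the concatenated UTR+CDS string (so edits spanning
the UTR/CDS boundary shift the CDS start correctly), the mutant is
re-scanned, and the two uORF landscapes are diffed. uAUGs are matched by
anchored offset outside the edited span and by nearest relative offset
inside it; unmatched mutant uAUGs are gains, unmatched wild-type uAUGs are
losses; anchored pairs are compared for stop movement (upstream =
uStop_gain, downstream or lost = uStop_loss) and Kozak category change.
One variant may yield several calls (one output row each); deduplication
for cohort summaries is a separate, configurable step with priority
uStart_gain > uStop_loss > uStop_gain > uStart_loss > uKozak > mKozak.
The re-scan strategy was chosen over positional case analysis because it
treats SNVs, small indels, and ~50-nt indels identically and makes the
reversibility property (variant + inverse variant restores the wild
landscape, gains and losses swapping) directly testable.

Scope rules: only variants whose REF interval intersects a 5′ UTR are
evaluated by the direct engine. Variants whose REF spans intronic bases,
mismatches the reference, or overlaps the main start codon itself are
skipped with a logged, counted reason — destroying the main ATG is a
start-loss, which is outside the six 5′ UTR categories.

Predicted translational direction follows ribosome-scanning logic: a new
uORF diverts scanning ribosomes (decreased; N-terminal extension when the
new start is in frame with no stop); removing a uORF releases them
(increased); a premature uORF stop shortens the uORF and permits
reinitiation (increased); a lost uORF stop lengthens it or converts it to
overlapping (decreased) or to an in-frame extension (N-terminal extension);
a strengthened uORF Kozak captures more ribosomes (decreased), a
strengthened main-CDS Kozak the opposite (increased).

## Splice module

Precomputed per-variant delta scores (four scores: acceptor/donor
gain/loss) are filtered at ≥ 0.2, a deliberately sensitive cutoff; only the
single highest-delta event per variant is reconstructed, with all
above-threshold deltas echoed in the `SpliceAI` output column. Site
conventions: a donor site is the last exonic base of its exon, an acceptor
the first. Losses become full retention of the affected 5′ UTR intron;
gains inside an exon delete the span between the new and canonical site;
gains inside an intron retain the span between the canonical site and the
new site. The mapping of gains to deletion-vs-retention purely by
exon/intron location of the new site is a design choice; both outcomes are
biologically attested and no finer rule is defensible without RNA data.
The altered exon structure keeps genuine genomic coordinates, the ALT
allele is applied wherever it is exonic in the altered transcript, and the
result is diffed through the standard engine, with two extra output
columns (`SpliceAI`, `Splicing_CSQ`) marking splice-derived records.
Reconstructions that would move or delete the CDS start are rejected.
Length bookkeeping is exact by construction (retention adds the retained
length; deletion subtracts the span) and asserted for every fixture event.

## Prioritization score

17 features per uORF-affecting record: 5′ UTR length, uAUG→CDS and
cap→uAUG distances, uORF rank, length (nt and aa), type, uStop codon,
uKozak strength, phyloP and PhastCons means over the three uAUG bases,
pLI, LOEUF, ribosome-profiling evidence, mKozak strength, per-transcript
uORF count, and the consequence type (one-hot over the five uORF
categories). The exact list is a module-level constant
(`scoring.FEATURES`). mKozak-only and splice-derived records are excluded
from training and receive `NA` scores; they are outside the model's
training domain.

Continuous missing values are imputed with training-set medians only —
scoring a held-out set never recomputes medians, which a leakage-guard test
enforces. Categoricals are label encoded with a fixed alphabetical
ordering persisted with the model; unseen levels map to a reserved −1
code. Class imbalance is corrected before fitting with SMOTE (synthetic
points are convex combinations of a minority sample and one of its k = 5
minority nearest neighbors; implemented here directly, seeded, and
property-tested for the bounding-box guarantee). The classifier is a
random forest with n_estimators = 500, class_weight = "balanced",
max_depth = None, max_features = None, min_samples_leaf = 2,
min_samples_split = 2, random_state threaded from the caller (default 42).
Performance is reported as 5-fold stratified cross-validation (balancing
applied inside each training fold); the positive-class probability is the
score in [0, 1] and 0.74 is the default high/low threshold. Training is
bit-reproducible for a fixed seed and dataset.

## Cohort statistics

Odds ratios are sample cross-product ratios (a·d)/(b·c) with a normal
approximation CI on the log scale and the exact hypergeometric p value;
the cross-product form reproduces published enrichment values under their
printed rounding and is exactly testable. Category percentages use the sum
of the reported category counts as denominator. MAF shifts use the
two-tailed Wilcoxon rank-sum test with the Hodges-Lehmann estimator
(median of all pairwise differences, checked against exhaustive
enumeration). Multiple testing uses Benjamini-Hochberg step-up.
Direction-aware validation signs the score positively for predicted
increases and negatively for predicted decreases before Spearman
correlation against effect sizes. Reporter-assay effects are
ΔMRL = log2(MRL_alt/MRL_ref).

## Synthetic data

The fixture generator emulates the shapes of the real inputs at desk scale
(a ≤ 100 kb toy genome; full pipeline runs in seconds): UTR lengths are
log-normal with median 136 nt clipped to 50–300; 38% of transcripts place
the CDS start downstream of exon 1, a fifth of those precisely at the
first base of their exon; both strands are represented; introns carry
canonical GT..AG ends and a planted mid-intron ATG so retention events
create uORFs. Conservation is baseline noise (phyloP ~ N(0, 0.5), low
PhastCons) with +3 phyloP / +0.8 PhastCons bumps at uAUGs carrying
translation evidence — a learnable planted signal. Planted variants are
constructed by local sequence rules (create/destroy an ATG or stop, flip a
−3 base) with windowed side-effect checks, and negatives are
brute-force-verified to leave the landscape and all Kozak categories
unchanged, drawing allele frequencies above 0.05. Every bundle ships a
truth sidecar produced by the independent brute-force enumerator, and all
randomness flows from one seed (byte-identical regeneration).

What the fixtures do *not* emulate: human base composition, linkage,
realistic allele-frequency spectra, alternative transcription start sites,
or noisy annotation. Passing tests therefore demonstrate algorithmic
correctness and calibration of the machinery, not real-data performance;
the planted-signal AUC (≥ 0.95 at n = 600) measures signal recovery under
a separable design, with a label-permutation null confirming the AUC
collapses to chance (0.4–0.6) when the signal is removed.

## Numerical and degenerate-input choices

Missing conservation yields missing means, never zeros. Zero-margin
contingency tables flag the OR undefined and return p = 1. Empty VCFs
produce a header-only output and exit 0. Per-variant failures (reference
mismatch, intron-spanning REF, symbolic ALT) are logged, counted in the
run manifest, and never abort a run. Problem sizes used by the default
test run and the acceptance script — 20-gene bundles, 200 oracle UTRs,
n = 600 training sets — were chosen so each stage completes in seconds
while leaving every statistical check comfortably powered.

## Known limitations

Non-AUG (near-cognate) uORF starts, IRES elements, mRNA secondary
structure, and m6A effects are out of scope. The splice module consumes
precomputed predictions and does not model branch points or cryptic exons,
and only the top event per variant is reconstructed when gains and losses
compete at one intron. CDS-internal variants that alter overlapping-uORF
stops are not evaluated by the direct engine (the scope rule requires
5′ UTR overlap). Multi-variant interplay within one UTR is not modeled.
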