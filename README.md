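# utr5var

Detection, annotation, and prioritization of 5′ UTR variants that may alter
protein translation.

The 5′ untranslated region of an mRNA is scanned by the ribosome before
initiation at the main start codon. Two classes of *cis*-elements in this
region control how efficiently initiation happens: the Kozak context around
a start codon — consensus `(A/G)CCAUGG`, with the −3 and +4 positions
carrying most of the signal — and upstream open reading frames (uORFs),
ATG-initiated ORFs that begin in the 5′ UTR. Depending on where a uORF's
stop codon falls it is **non-overlapping** (terminates before the CDS),
**overlapping** (out of frame, terminates inside the CDS), or an
**N-terminal extension** (in frame with the CDS, no intervening stop).
Variants that create or destroy uORF start/stop codons, or change Kozak
strength, shift the fraction of ribosomes reaching the main ORF and can
cause disease through protein dosage. These variants are routinely missed by
coding-sequence-focused pipelines; this package exists for human geneticists
who want to pull them out of WES/WGS VCFs, understand the predicted
mechanism, and rank candidates.

## What it does

For each VCF variant intersecting an annotated 5′ UTR, the spliced
(mature) 5′ UTR + CDS sequence is edited, re-scanned for uORFs, and the
wild-type and mutant landscapes are diffed. Each variant is classified into
six consequence categories — `uStart_gain`, `uStart_loss`, `uStop_gain`,
`uStop_loss`, `uKozak`, `mKozak` — with a predicted translational direction
(increased / decreased / N-terminal extension). Because the mutant sequence
is re-scanned rather than pattern-matched, SNVs, small indels, and large
indels are handled uniformly. A splice module converts precomputed
splice-site delta scores (four-score SpliceAI-style format, cutoff ≥ 0.2
within 100 nt of a canonical site) into intron retentions or exonic
deletions of the 5′ UTR, rebuilds the altered mature UTR, and pushes it
through the same engine. A random-forest classifier (500 trees, balanced
class weights, SMOTE oversampling, 5-fold stratified CV; probability of the
positive class is the score in [0, 1], threshold 0.74) ranks uORF-affecting
variants from 17 features spanning UTR geometry, uORF characteristics,
uAUG conservation (phyloP/PhastCons), gene constraint (pLI/LOEUF),
ribosome-profiling evidence, and consequence type. A statistics module
provides the cohort-level machinery: category summaries with deduplication,
Fisher's exact enrichment with cross-product odds ratios,
Benjamini-Hochberg correction, Wilcoxon rank-sum MAF comparisons with the
Hodges-Lehmann shift estimator, direction-signed Spearman correlation
against effect sizes, and ΔMRL = log2(MRL_alt/MRL_ref).

A synthetic-fixture generator builds complete desk-scale input bundles
(genome FASTA, GENCODE-style GTF with MANE tags, VCF with planted
consequences, conservation TSVs, uORF evidence, constraint table, splice
predictions) with machine-readable ground truth, so everything is testable
without any external download.

## Worked example

```bash
utr5var fixtures --out-dir fx --seed 7 --n-genes 12
utr5var annotate --vcf fx/variants.vcf --fasta fx/genome.fa --gtf fx/annotation.gtf \
    --uorf-catalog fx/uorf_evidence.tsv --phylop fx/phylop.tsv --phastcons fx/phastcons.tsv \
    --constraint fx/constraint.tsv --splice-scores fx/splice_predictions.tsv \
    --out out.tsv --manifest manifest.json
```

Selected columns of `out.tsv`:

```
CHROM  POS  ID  REF  ALT  CSQ         Translation           5ULTRA_Score  GENE   uORF_END  uSTOP_CODON
chr1   221  .   A    T    uStop_loss  decreased             NA            GENE0  219       TAA
chr1   668  .   C    G    uKozak      increased             NA            GENE1  565       TGA
chr1   690  .   A    T    uStop_gain  increased             NA            GENE1  689       TAG
chr1   959  .   C    T    uStop_gain  increased             NA            GENE2  961       TAG
chr1   962  .   T    A    uStop_loss  N-terminal extension  NA            GENE2  964       TAG
```

Row 1 is a variant destroying a uORF stop codon (TAA) that lengthens a
non-overlapping uORF, predicted to decrease translation of GENE0; row 5
destroys a stop of an in-frame uORF with no further stop before the CDS,
so the predicted outcome is an N-terminally extended protein. The manifest
accounts for every input variant:

```
{'variants_in': 39, 'annotated': 35, 'no_utr_overlap': 1, 'skipped': 0,
 'splice_records': 2, 'symbolic_alt_skipped': 0}
```

The score column is filled when a trained model is supplied
(`--model model.joblib`, trained with `utr5var train`); mKozak-only and
splice-derived records keep `NA` scores by design — they are outside the
model's training domain.

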