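# Methods

## The problem

Ribosome profiling (Ribo-Seq) sequences ~26–32 nt fragments of mRNA
protected by translating ribosomes. Mapping those fragments back to the
transcriptome gives, per transcript position, a count of ribosome
footprints — a positional readout of translation. The analysis task is to
decide **where translation initiates**: which nucleotide positions are
translation initiation sites (TISs), and from those, which open reading
frames (ORFs) are translated, including non-canonical ORFs in 5'UTRs
(uORFs, uoORFs), nested out-of-frame ORFs (intORFs), 3'UTR ORFs
(dORFs, doORFs), and ORFs on long non-coding RNAs.

riboscope scores every transcript position for initiation from the mapped
footprint data alone — each read contributes only its 5'-end position and
its length. No P-site/A-site offsetting is applied, no codon or ORF
candidate library is built, and the nucleotide sequence is *not* a model
input: downstream sequence only enters when a thresholded TIS is extended
to its first in-frame stop codon.

## Model

### Inputs

For one transcript of length L, the 5'-end counts form an L × 21 matrix
over read lengths 20–40 nt. Each position feeds the model two features:

* `c ∈ [0,1]` — the position's total count divided by the transcript-wide
  maximum count (0 everywhere on read-free transcripts). Normalizing per
  transcript keeps inputs bounded regardless of sequencing depth; the
  per-transcript maximum (rather than an L2 norm) preserves the
  interpretation of `c ≈ 1` as "this transcript's densest position".
* `l ∈ [0,1]^21` — the fraction of the position's reads at each read
  length; the zero vector when no reads map there.

The position embedding of width `h` is `e_c + e_l` with

    e_c = e ⊙ tanh(φ(c))       φ: two affine layers with a GELU between
    e_l = Σ_i E[i] · l_i       E: 21 learned rows, one per read length

`e` is a learned vector and `E` a learned 21 × h matrix. (A printed
summation elsewhere runs over 22 terms for these lengths; there are 21
read lengths in 20–40 inclusive and the matrix has exactly 21 rows.)
Read-free positions contribute `e_l = 0`; `c = 0` still passes through φ.

### Encoder

A pre-norm transformer (default: 4 layers, 4 heads, width 32) maps the
embedded sequence to one logit per position; a logistic function yields
TIS probabilities. Attention is exact by default; a Performer-style
positive-random-feature approximation of softmax attention
(`attention_kind="kernel-approximate"`) avoids the quadratic attention
matrix on very long transcripts and agrees with exact attention within a
small tolerance on short inputs (property-tested).

Two design elements matter for learning from small corpora:

* **Relative position bias.** The TIS signature — a sharp onset of dense,
  3-periodic coverage with a quiet upstream flank — is a *relative*
  pattern. Attention therefore carries a learned additive bias indexed by
  clipped relative offset (window ±48 nt), initialized with a local,
  3-periodic prior reflecting the triplet periodicity of ribosome
  footprints. Absolute learned positional encodings are available
  (`positional="absolute"`; required with kernel attention, which cannot
  carry an additive bias) but at desk scale they let the model memorize
  training-transcript coordinates instead of the pattern, which collapses
  held-out precision.
* **Convolutional stem.** One same-padded width-13 convolution (residual,
  GELU) over the embeddings exposes local onset/periodicity contrasts
  directly, which empirically cuts the epochs-to-convergence several-fold
  without changing what the model can express.

A 1-wide head scores TIS presence; a parallel 21-wide head predicts
read presence per read length for self-supervised pretraining. Both share
the trunk, so pretrained trunks can be fine-tuned for TIS detection.

### Training

* **Supervised objective**: per-position binary cross-entropy, positives =
  annotated start-codon positions, negatives = all other positions. The
  class imbalance (~1 positive per coding transcript vs ~10²–10³
  negatives) is countered by a positive-class weight, default the global
  negative/positive ratio of the training fold.
* **Masked pretraining**: each epoch a seeded random 15% of positions per
  transcript is masked — their embeddings replaced by a learned mask token
  (`mask_style="zero"` zeroes them instead) — and the 21-wide head
  predicts, at masked positions only, whether at least
  `read_presence_threshold` reads of each length map there. The phrase
  "more than one read" in the source method description reads literally
  as ≥ 2 but plausibly means ≥ 1; the threshold is exposed
  (default 1) rather than silently resolved.
* **Fine-tuning** is supervised training initialized from a pretrained
  checkpoint's trunk; the pretraining head is dropped automatically
  because its shape differs.
* **Early stopping** monitors a validation criterion with configurable
  patience; the best-validation weights are restored. The monitored
  quantity is selectable: validation loss (default), or validation
  average precision (`monitor="pr_auc"`), which the desk-scale
  experiments use because under a ~50–200× positive-class weight the
  weighted validation loss is dominated by a handful of confidently
  wrong positives and becomes an erratic model selector while the task
  metric is still improving. Adam is the optimizer; learning rate, batch
  size (transcripts per step) and epochs are configuration with
  desk-scale defaults (2e-3, 16, ≤18).

### Chromosome folds

To score the whole transcriptome without evaluating any transcript with a
model that trained on it, two models are trained on non-overlapping
chromosome folds; each transcript is scored by the model whose *test*
fold owns its chromosome, and the union of the two test folds covers
everything. The published human allocation is built in
(`allocate_folds(..., scheme="paper")`): model 0 trains on chromosomes
[3, 5, 7, 11, 13, 15, 19, 21, X], validates on [1, 9, 17] and is tested on
[2, 4, …, 22, Y] plus any unlisted scaffolds; model 1 trains on
[2, 6, 8, 10, 14, 16, 18, 22, Y], validates on [4, 12, 20] and is tested
on the odd chromosomes and X. `split_two_fold` produces an analogous
allocation for arbitrary (e.g. synthetic) chromosome names. Fold hygiene
is audited by id-set intersection in the test suite.

## ORF construction and filtering

Candidate TISs are positions scoring above 0.15 (the threshold applies to
the *original* predicted position; a corrected call keeps the original
position's score as its evidence). Each candidate is processed as:

1. **Neighborhood correction**: a non-ATG candidate moves to the nearest
   in-frame ATG within 9 codons (ties resolve upstream, yielding the
   longer ORF; the operation is idempotent). Predictions on sparse
   transcripts tend to miss the TIS by a multiple of three bases, which
   this repairs.
2. **Greedy stop selection**: scan codons downstream to the first
   in-frame TAA/TAG/TGA.
3. **Filters**: the start codon must match N-T-G (ATG/CTG/GTG/TTG) and an
   in-frame stop must exist on the transcript; drop reasons are recorded.
4. **Deduplication** on (transcript, TIS, stop), keeping the best score.
5. Optional **multi-sample consensus**: keep ORFs called in at least
   `min_samples` samples (default 2) with support counts attached.

No minimum ORF length is imposed beyond start + stop (6 nt).

## ORF taxonomy

Each call gets exactly one label by a fixed precedence (coding
transcripts first): annotated_CDS; N-terminal extension / truncation
(shared stop, in-frame); uORF / uoORF / intORF / dORF / doORF by position
and frame relative to the CDS footprint `[tis, stop+3)`; then, on
non-coding transcripts, CDS_variant when the ORF's genomic start or stop
coincides with any annotated CDS start/stop site on the same strand, else
lncRNA_ORF on lncRNA-tagged transcripts, else other. Decisions where the
category definitions left room:

* intORF requires a *different* frame; an in-frame ORF nested in the CDS
  without the shared stop is `other` (a truncation candidate without the
  shared stop is not an intORF).
* doORF requires the TIS inside the CDS footprint (not mere span
  overlap).
* An upstream ORF whose stop codon ends at the base before the CDS start
  is a uORF (half-open span consistency).
* Site sharing for CDS_variant is same-chromosome, same-strand, exact
  first-base equality of start or stop codons.

`lncRNA_overlap_profile` reports, over lncRNA-ORF calls, the fractions
whose genomic TIS lies inside an annotated CDS, inside a protein-coding
exon, or in neither.

## Evaluation and quantification

ROC AUC is the Mann–Whitney statistic (rank method, ties at ½); PR AUC is
average precision with step-wise interpolation — trapezoidal PR
interpolation is optimistic with few positives, and no convention was
printed for the original curves. Both are checked against brute-force
all-pairs / running-precision oracles to 1e-12 in the tests. ORF-library
benchmarking scores each library entry by the model probability at its
TIS; entries on unscored transcripts are an error, never dropped.

ORF abundance is reads-per-base (5'-end counts in `[tis, stop+3)` divided
by span length); TPM scales rates to 10⁶ per sample over the quantified
set. ncORF–CDS co-regulation uses two-sided Spearman correlation across
samples (mid-ranks for ties; constant vectors are flagged undefined, not
zero).

## The synthetic-data generator

The generator emulates what the classifier must distinguish, with known
ground truth; its defaults are the study conditions used throughout the
tests.

* **Transcriptome**: 300 transcripts over 6 chromosomes; 5'UTRs and
  3'UTRs 24–60 nt, CDSs 90–180 nt (codon-multiple), 25% two-exon, half on
  the minus strand; 15% lncRNAs. Planted per coding transcript with the
  configured rates: uORFs (0.2), uoORFs (0.1, out-of-frame by
  construction), intORFs (0.1, via out-of-frame ATG codon pairs inside
  the CDS), dORFs (0.15), doORFs (0.05). Planted ORFs are built without
  internal in-frame stops; plants whose realized geometry misses their
  intended class are re-labelled by geometry or dropped. Among lncRNAs,
  30% share a genomic stop site with a host CDS (exercising CDS_variant)
  and 25% of the rest have their TIS inside a host CDS without sharing
  sites. Only a fraction of lncRNA ORFs (``lncrna_translated_fraction``,
  default 0.35) carry ribosome occupancy; the rest see background reads
  only. This mirrors the biology — most annotated lncRNAs show no
  ribosomal engagement — and it matters for evaluation: a generator in
  which *every* lncRNA ORF is translated creates positions that are
  locally indistinguishable from annotated CDS TISs (per-transcript
  count normalization erases the depth difference) yet labeled negative,
  which caps achievable precision for reasons unrelated to the method.
  Short transcripts keep the attention cost of desk-scale training
  runs manageable; lengths are a generator property, and all coordinate
  logic is length-independent.
* **Reads**: per translated ORF and codon, footprint counts are Poisson
  with mean `3 · coverage · multiplier` (coverage 2 reads/nt for CDSs;
  multiplier 0.3 for non-canonical ORFs), boosted by `tis_enrichment`
  within ±30 nt of that ORF's TIS (1 = untreated-like; ≫1 emulates
  initiation-blocking homoharringtonine). Each footprint lands on its
  codon's frame-0 position with probability `in_frame_prob` (default 0.6,
  inside the 36–75% range of real samples), else uniformly on frame 1/2;
  lengths are drawn from a unimodal distribution peaked at 28 nt with
  support 26–32. Background reads are Poisson per position
  (0.02 reads/nt). Reads that would overhang the transcript 3' end are
  not emitted (end-to-end alignment).
* **Round trip**: the emitted SAM re-ingested through `ingest_alignments`
  reproduces the generator's internal count matrices exactly, and the
  realized in-frame occupancy recovers `in_frame_prob` to ±0.01 at ≥50k
  CDS reads.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: sequencing error, rRNA/contaminant reads, UMI
duplication structure, multi-isoform read ambiguity, fragment-length
biases coupled to position, and annotation errors. Results on the
simulator demonstrate that the method recovers planted structure under
its stated noise model, not field performance.

## Numerical choices

* All tensor math runs on an in-repo reverse-mode autodiff engine over
  numpy arrays (float32 by default; float64 available for gradient
  checks, which verify every primitive and the full model against central
  finite differences).
* Early-stopping improvement threshold 1e-6 on monitored loss; Adam
  (β₁ = 0.9, β₂ = 0.999, ε = 1e-8); positive-class weight computed once
  per fit from the training fold.
* Batches are length-bucketed (shuffle, then locally sort by length) to
  limit padding waste; padded positions are zeroed before the stem so
  batched and unbatched scoring agree, masked out of attention, and
  excluded from losses.
* Transcripts longer than `max_transcript_length` either error or, when
  `chunk_overlap` is configured, are scored in overlapping windows with
  centre-kept stitching — never silently truncated.
* Masking determinism: masked-position sets derive from
  (seed, epoch, item), so a fixed seed reproduces them bitwise.
* Seeds below 2³¹ everywhere; the CLI fans one run seed out to per-stage
  seeds via `numpy.random.SeedSequence`.

## Desk-scale problem sizes

The test suite and the reproduction script run the full protocol at
deliberately small sizes chosen as this package's standard desk-scale
experiment: ~300 transcripts (~200 nt each), coverage 2 reads/CDS-nt,
in-frame probability 0.6, TIS enrichment 5, two fold models of ~80k
parameters each, ≤18 epochs; the occupancy/depth robustness sweep uses a
120-transcript corpus, single fold models and ≤12 epochs. The published-scale regime ((~250k
transcripts, ~431M positions, 212k-parameter models, GPU training) is
reachable through the same configuration surface but is not exercised
here.

## Known limitations

* Scores are per transcript; ORF calls on transcripts sharing genomic
  regions are not collapsed into genomic ORF groups.
* NMD/retained-intron transcripts are tagged at load but not excluded;
  their ORF calls inherit whatever the model scores.
* The kernel-approximate attention path cannot use the relative position
  bias; at desk scale the exact path is both faster and better, so the
  kernel path is exercised for architectural parity, not performance.
* TPM quantification normalizes over the quantified ORF set only, so
  values are comparable within a call set, not across differently sized
  call sets.
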