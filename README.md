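# riboscope

Translation initiation site (TIS) calling from ribosome profiling data,
with open-reading-frame construction, taxonomy annotation and
benchmarking — for transcriptome-scale analysis of what is actually
translated, including non-canonical ORFs (uORFs, uoORFs, intORFs, dORFs,
doORFs, lncRNA ORFs).

Ribo-Seq maps ribosome-protected mRNA fragments (RPFs, ~26–32 nt) onto
transcripts. riboscope consumes only each mapped read's 5'-end position
and length — no P-site offsetting, no candidate ORF library, no sequence
features — and scores **every nucleotide position of every transcript**
for translation initiation with a small transformer:

* per-position embedding `e_c + e_l`, where
  `e_c = e ⊙ tanh(φ(c))` embeds the transcript-normalized read count
  `c ∈ [0,1]` and `e_l = Σᵢ Eᵢ lᵢ` embeds the read-length fraction vector
  `l ∈ [0,1]²¹` over lengths 20–40 nt;
* a self-attention encoder (exact, or Performer-style kernel-approximate
  for very long transcripts) with relative-position bias and a
  convolutional stem, producing one TIS probability per nucleotide;
* two models trained on non-overlapping chromosome folds so every
  transcript is scored by a model that never saw its chromosome
  (the published human fold allocation is built in);
* optional masked self-supervised pretraining on read-presence labels
  (15% of positions masked), fine-tuned to the TIS task.

Positions scoring above 0.15 are extended to the first in-frame stop
codon, corrected to nearby in-frame ATGs (≤ 9 codons), filtered to
valid N-T-G starts, deduplicated, optionally intersected across samples,
and classified into an 11-label taxonomy (annotated CDS, N-terminal
extension/truncation, uORF, uoORF, intORF, dORF, doORF, lncRNA-ORF,
CDS variant, other).

A synthetic Ribo-Seq generator (annotation + genome FASTA + GTF +
transcript-space SAM, with planted ground truth for every ORF class,
configurable in-frame read fidelity, TIS-proximal footprint enrichment
and background noise) makes the whole pipeline testable without any
download. Everything runs on numpy via a small in-repo autodiff engine —
no GPU or deep-learning framework required.

## Worked example

```python
import numpy as np
from riboscope import SimulationConfig, call_orfs
from riboscope.orf_annotation import annotate_calls, taxonomy_counts
from riboscope.workflows import simulated_sample, run_tis_experiment

# simulate a sample: 300 transcripts, 2 reads/nt on CDSs, 60% in-frame
# 5'-ends, 5x footprint enrichment around TISs
cfg = SimulationConfig(seed=101, tis_enrichment=5.0)
annotation, truth, profile = simulated_sample(cfg)
print(f"occupancy={profile.in_frame_occupancy:.3f}  reads={profile.mapped_reads}")

# two-fold training + held-out scoring of every transcript position
exp = run_tis_experiment(annotation, truth, profile, seed=0)
print(f"held-out PR AUC={exp.heldout_pr_auc:.3f}  ROC AUC={exp.heldout_roc_auc:.3f}")

# ORF calls from the scores
calls = annotate_calls(call_orfs(exp.scores, annotation), annotation)
print(taxonomy_counts(calls, "demo").to_string(index=False))
```

prints (seed-reproducible):

```
occupancy=0.584  reads=149566
held-out PR AUC=0.933  ROC AUC=0.998
sample              orf_type   n
  demo           CDS_variant   7
  demo N_terminal_truncation   1
  demo         annotated_CDS 242
  demo                  dORF   1
  demo            lncRNA_ORF  21
  demo                  uORF  21
  demo                 uoORF  16
```

The realized in-frame occupancy sits slightly below the nominal 0.6
because out-of-frame reads from overlapping non-canonical ORFs land
inside CDSs. The held-out PR/ROC AUC is computed only on transcripts the
scoring model never trained on: of the 255 planted canonical CDSs, 242
are recovered exactly, and the non-canonical calls (uORFs, uoORFs,
lncRNA ORFs, ...) reflect the generator's planted translation at reduced
coverage.

There is also a CLI mirroring the stages
(`riboscope simulate|ingest|pretrain|finetune|predict|call|annotate|benchmark|quantify`,
one YAML config, `--seed`, manifests next to outputs).

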