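"""Taxonomy of called ORFs relative to the annotation.

Labels, in precedence order:

1. ``annotated_CDS`` — TIS and stop both equal the transcript's CDS.
2. ``N_terminal_extension`` / ``N_terminal_truncation`` — same stop,
   in-frame, TIS upstream / downstream of the annotated TIS.
3. On coding transcripts: ``uORF`` (entirely 5' of the CDS), ``uoORF``
   (TIS 5' of the CDS, overlapping its start out of frame), ``intORF``
   (nested within the CDS span out of frame), ``dORF`` (entirely 3'),
   ``doORF`` (TIS inside the CDS span out of frame, stop 3' of it).
4. On non-coding transcripts: ``CDS_variant`` when the ORF shares its
   genomic start or stop site with any annotated CDS; otherwise
   ``lncRNA_ORF`` when the transcript carries an lncRNA tag; else ``other``.

An in-frame ORF nested inside the CDS without the shared stop is ``other``
(intORF is restricted to out-of-frame ORFs). The CDS span used for overlap
is the half-open footprint including the stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .orf_calling import OrfCall
from .transcriptome import GenomeAnnotation, TranscriptRecord

NCORF_LABELS = frozenset({"uORF", "uoORF", "intORF", "dORF", "doORF", "lncRNA_ORF"})
LNCRNA_TAGS = frozenset({"lncRNA", "lincRNA", "long_noncoding", "antisense"})


@dataclass
class OrfTaxonomy:
    label: str
    evidence: str


def classify_orf(
    call: OrfCall, t: TranscriptRecord, annotation: GenomeAnnotation
) -> OrfTaxonomy:
    if call.stop_index is None:
        return OrfTaxonomy("other", "no stop codon on transcript")
    tis, stop = call.tis_index, call.stop_index
    orf_lo, orf_hi = tis, stop + 3

    if t.cds is not None:
        c_tis, c_stop = t.cds.tis_index, t.cds.stop_index
        cds_lo, cds_hi = c_tis, c_stop + 3
        in_frame = (tis - c_tis) % 3 == 0
        if tis == c_tis and stop == c_stop:
            return OrfTaxonomy("annotated_CDS", "TIS and stop match annotated CDS")
        if stop == c_stop and in_frame:
            if tis < c_tis:
                return OrfTaxonomy("N_terminal_extension", "shared stop, upstream in-frame TIS")
            return OrfTaxonomy("N_terminal_truncation", "shared stop, downstream in-frame TIS")
        if orf_hi <= cds_lo:
            return OrfTaxonomy("uORF", "ORF entirely 5' of CDS")
        if tis < cds_lo and orf_hi > cds_lo and not in_frame:
            return OrfTaxonomy("uoORF", "TIS 5' of CDS, out-of-frame overlap of CDS start")
        if orf_lo >= cds_hi:
            return OrfTaxonomy("dORF", "ORF entirely 3' of CDS")
        if cds_lo <= tis < cds_hi and not in_frame:
            if orf_hi <= cds_hi:
                return OrfTaxonomy("intORF", "out-of-frame ORF nested in CDS")
            return OrfTaxonomy("doORF", "TIS inside CDS, out-of-frame, stop 3' of CDS")
        return OrfTaxonomy("other", "no taxonomy rule matched on coding transcript")

    # non-coding transcript
    g_tis = t.to_genomic(tis)
    g_stop = t.to_genomic(stop)
    shares_start = annotation.is_cds_start_site(t.chromosome, t.strand, g_tis)
    shares_stop = annotation.is_cds_stop_site(t.chromosome, t.strand, g_stop)
    if shares_start or shares_stop:
        which = "start" if shares_start else "stop"
        return OrfTaxonomy("CDS_variant", f"shares genomic {which} site with an annotated CDS")
    if t.biotype_tags & LNCRNA_TAGS:
        return OrfTaxonomy("lncRNA_ORF", "lncRNA-tagged transcript, no shared CDS sites")
    return OrfTaxonomy("other", "non-coding transcript without lncRNA tag")


def annotate_calls(
    calls: Sequence[OrfCall], annotation: GenomeAnnotation
) -> list[OrfCall]:
    for c in calls:
        tax = classify_orf(c, annotation[c.transcript_id], annotation)
        c.orf_type = tax.label
        c.evidence = tax.evidence
    return list(calls)


def lncRNA_overlap_profile(
    calls: Sequence[OrfCall], annotation: GenomeAnnotation
) -> dict[str, float]:
    """Overlap fractions of lncRNA-ORF TISs with coding annotation.

    Returns the (mutually non-exclusive) fractions of lncRNA-ORF calls
    whose genomic TIS lies inside an annotated CDS, inside an exon of a
    protein-coding transcript, or in neither (intergenic).
    """
    lnc = [c for c in calls if c.orf_type == "lncRNA_ORF"]
    if not lnc:
        raise ValueError("no lncRNA_ORF calls to profile")
    n_cds = n_exon = n_inter = 0
    for c in lnc:
        t = annotation[c.transcript_id]
        g = t.to_genomic(c.tis_index)
        in_cds = bool(annotation.cds_overlapping(t.chromosome, g))
        in_exon = bool(annotation.coding_exon_overlapping(t.chromosome, g))
        n_cds += in_cds
        n_exon += in_exon
        n_inter += not (in_cds or in_exon)
    n = len(lnc)
    return {
        "tis_in_cds": n_cds / n,
        "tis_in_coding_exon": n_exon / n,
        "intergenic": n_inter / n,
    }


def taxonomy_counts(calls: Sequence[OrfCall], sample_id: str = "") -> pd.DataFrame:
    """Stacked per-label call counts for one sample."""
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.orf_type or "unclassified"] = counts.get(c.orf_type or "unclassified", 0) + 1
    return pd.DataFrame(
        [{"sample": sample_id, "orf_type": k, "n": v} for k, v in sorted(counts.items())]
    )
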