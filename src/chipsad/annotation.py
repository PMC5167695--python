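"""Classification of signal areas against GenBank ORF annotation.

Each putative transcript (a signal area or a cross-experiment consensus)
is compared with the annotated coding sequences of the organism and given
exactly one class:

* ``operon``          — covers >= 2 co-oriented same-strand ORFs, each by at
                        least 30% of its length;
* ``overlapping_utr`` — spans two differently oriented ORFs whose intergenic
                        gap is under 30 bp;
* ``orf``             — covers a single same-strand ORF and stays within
                        30 bp of its boundaries;
* ``utr5`` / ``utr3`` — covers a single same-strand ORF plus a flanking
                        transcribed extension past the 5' or 3' end;
* ``antisense``       — qualifying overlap only on the opposite strand;
* ``intergenic``      — no ORF contact and shorter than 800 bases (longer
                        orphans keep the class with a ``long`` flag).

Rules are tested in the fixed precedence above; the first match wins and
the full trace of tested rules is recorded per transcript.  All interval
arithmetic is 1-based inclusive; gaps count the bases strictly between two
features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("chipsad")

TRANSCRIPT_CLASSES = (
    "orf", "operon", "antisense", "overlapping_utr", "intergenic", "utr5", "utr3",
)

#: rows of the summary table; long ORF-free areas are reported separately
SUMMARY_LABELS = (
    "orf", "operon", "antisense", "overlapping_utr", "utr5", "utr3",
    "intergenic", "intergenic_long",
)


@dataclass
class OrfFeature:
    locus_tag: str
    replicon: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"ORF {self.locus_tag}: start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotationParams:
    """Rule thresholds (overlap as a fraction of ORF length; gaps and
    lengths in bp); override only with good reason."""

    min_orf_overlap_frac: float = 0.30
    overlapping_utr_max_intergenic: int = 30
    utr_max_gap: int = 30
    intergenic_max_len: int = 800


@dataclass
class ClassifiedTranscript:
    sas: object  # SignalArea or ConsensusSAS
    transcript_class: str
    supporting_orfs: list[str]
    rule_trace: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    @property
    def display_class(self) -> str:
        if self.transcript_class == "intergenic" and "long" in self.flags:
            return "intergenic_long"
        return self.transcript_class


# ---------------------------------------------------------------------------
# GenBank parsing
# ---------------------------------------------------------------------------

def read_genbank_orfs(path) -> list[OrfFeature]:
    """Extract CDS features from a GenBank flat file as 1-based ORF intervals.

    Compound (join/complement) locations are resolved to their outermost
    span.  A CDS lacking a locus_tag gets a synthetic tag (logged).
    """
    orfs: list[OrfFeature] = []
    n_untagged = 0
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    for rec in records:
        replicon = rec.id if rec.id and rec.id != "<unknown id>" else rec.name
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            start = int(feat.location.start) + 1  # Biopython is 0-based half-open
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            tags = feat.qualifiers.get("locus_tag")
            if tags:
                tag = tags[0]
            else:
                n_untagged += 1
                tag = f"cds_{n_untagged:04d}"
                logger.warning(
                    "CDS at %s:%d-%d has no locus_tag; assigned %s",
                    replicon, start, end, tag,
                )
            orfs.append(OrfFeature(tag, replicon, strand, start, end))
    if not orfs:
        logger.warning("%s: annotation contains no CDS features", path)
    orfs.sort(key=lambda o: (o.replicon, o.start, o.end))
    return orfs


# ---------------------------------------------------------------------------
# interval arithmetic
# ---------------------------------------------------------------------------

def _overlap_bp(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def orf_overlap_fraction(sas, orf: OrfFeature) -> float:
    """Shared bases divided by ORF length; strand is deliberately ignored
    here — the classifier decides what a strand mismatch means."""
    if sas.replicon != orf.replicon:
        return 0.0
    return _overlap_bp(sas.start, sas.end, orf.start, orf.end) / orf.length


def _intergenic_gap(a: OrfFeature, b: OrfFeature) -> int:
    """Bases strictly between two ORFs; <= 0 when they touch or overlap."""
    left, right = (a, b) if a.start <= b.start else (b, a)
    return right.start - left.end - 1


# ---------------------------------------------------------------------------
# the classifier
# ---------------------------------------------------------------------------

def classify_sas(sas, orfs: list[OrfFeature], params: AnnotationParams | None = None) -> ClassifiedTranscript:
    """Assign one transcript class by the fixed-precedence rule set.

    The classifier is total: an area overlapping annotation only below the
    30% threshold falls through every primary rule and is classed
    antisense (flagged ``subthreshold_overlap`` in the trace), mirroring
    the rule set's catch-all reading of weak ORF contact.
    """
    if params is None:
        params = AnnotationParams()
    trace: list[str] = []

    hits = []  # (orf, overlap_bp, fraction, same_strand)
    for orf in orfs:
        if orf.replicon != sas.replicon:
            continue
        ov = _overlap_bp(sas.start, sas.end, orf.start, orf.end)
        if ov <= 0:
            continue
        hits.append((orf, ov, ov / orf.length, orf.strand == sas.strand))

    sense_q = [h for h in hits if h[3] and h[2] >= params.min_orf_overlap_frac]
    anti_q = [h for h in hits if not h[3] and h[2] >= params.min_orf_overlap_frac]

    # R1 operon: two or more qualifying co-oriented sense ORFs
    if len(sense_q) >= 2:
        trace.append("operon:yes")
        return ClassifiedTranscript(
            sas, "operon", [h[0].locus_tag for h in sense_q], trace
        )
    trace.append("operon:no")

    # R2 overlapping UTR: two differently oriented ORFs with a tight gap
    for i in range(len(hits)):
        for j in range(i + 1, len(hits)):
            o1, o2 = hits[i][0], hits[j][0]
            if o1.strand == o2.strand:
                continue
            if _intergenic_gap(o1, o2) < params.overlapping_utr_max_intergenic:
                trace.append("overlapping_utr:yes")
                return ClassifiedTranscript(
                    sas, "overlapping_utr",
                    sorted([o1.locus_tag, o2.locus_tag]), trace,
                )
    trace.append("overlapping_utr:no")

    # R3 single ORF / R4 UTR extension
    if len(sense_q) == 1:
        orf = sense_q[0][0]
        ext_low = max(0, orf.start - sas.start)   # toward lower coordinates
        ext_high = max(0, sas.end - orf.end)      # toward higher coordinates
        if max(ext_low, ext_high) <= params.utr_max_gap:
            trace.append("orf:yes")
            return ClassifiedTranscript(sas, "orf", [orf.locus_tag], trace)
        trace.append("orf:no")
        # 5' flank sits at lower coordinates on +, higher coordinates on -
        ext5, ext3 = (ext_low, ext_high) if sas.strand == "+" else (ext_high, ext_low)
        if ext5 > params.utr_max_gap and ext5 >= ext3:
            trace.append("utr:utr5")
            return ClassifiedTranscript(sas, "utr5", [orf.locus_tag], trace)
        trace.append("utr:utr3")
        return ClassifiedTranscript(sas, "utr3", [orf.locus_tag], trace)
    trace.append("orf:no")
    trace.append("utr:no")

    # R5 antisense: qualifying overlap only on the opposite strand
    if anti_q and not sense_q:
        trace.append("antisense:yes")
        return ClassifiedTranscript(
            sas, "antisense", [h[0].locus_tag for h in anti_q], trace
        )
    trace.append("antisense:no")

    # R6 / R7 ORF-free areas
    if not hits:
        length = sas.end - sas.start + 1
        if length < params.intergenic_max_len:
            trace.append("intergenic:yes")
            return ClassifiedTranscript(sas, "intergenic", [], trace)
        trace.append("intergenic:long")
        return ClassifiedTranscript(sas, "intergenic", [], trace, flags=["long"])
    trace.append("intergenic:no")

    # catch-all: ORF contact below every threshold
    trace.append("subthreshold_overlap")
    return ClassifiedTranscript(
        sas, "antisense", [h[0].locus_tag for h in hits], trace,
        flags=["subthreshold_overlap"],
    )


def annotate_all(
    sas_list, orfs: list[OrfFeature], params: AnnotationParams | None = None
) -> tuple[list[ClassifiedTranscript], pd.Series]:
    """Classify every area and tabulate counts per class label.

    The summary is indexed by :data:`SUMMARY_LABELS` (long ORF-free areas
    counted under ``intergenic_long``) and always sums to the input size.
    """
    if params is None:
        params = AnnotationParams()
    classified = [classify_sas(s, orfs, params) for s in sas_list]
    counts = pd.Series(0, index=list(SUMMARY_LABELS), dtype=int)
    for c in classified:
        counts[c.display_class] += 1
    return classified, counts
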