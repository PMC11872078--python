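"""cDNA isoform classification and splice-level HDR quantification.

cDNA reads are classified against the finite isoform x allele reference
set of a :class:`~ampedit.locus_model.TranscriptModel` with the same
global aligner and ambiguity rule as the genomic classifier; no spliced
alignment is performed.  Unexpected junctions surface as low-margin or
ambiguous calls and are reported, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
import pandas as pd

from .alignment import Scoring, align_global, encode, revcomp
from .locus_model import TranscriptModel

TRANSCRIPT_CALL_COLUMNS = ("read_id", "isoform", "hdr_status_in_exon", "score_margin")


@dataclass(frozen=True)
class TranscriptCall:
    read_id: str
    isoform: str  # full_length | exon_skipped | aberrant_acceptor | ambiguous
    hdr_status_in_exon: str  # wt | mut | hdr | na
    score_margin: int

    def to_row(self):
        return (self.read_id, self.isoform, self.hdr_status_in_exon, self.score_margin)


class TranscriptIndex:
    """Pre-encoded transcript references shared across a batch."""

    def __init__(self, model: TranscriptModel, scoring: Scoring = Scoring(), delta: int = 0):
        if not model.references:
            raise ValueError("transcript model has no references")
        self.model = model
        self.scoring = scoring
        self.delta = delta
        self.labels = tuple(sorted(model.references))
        self.codes = {lb: encode(model.references[lb]) for lb in self.labels}


def classify_transcript_read(read_id: str, seq: str, index: TranscriptIndex) -> TranscriptCall:
    """Best-scoring isoform x allele reference wins; ties are ambiguous."""
    codes_fwd = encode(seq)
    codes_rev = encode(revcomp(seq))
    scores = {}
    for lb in index.labels:
        sf = align_global(index.codes[lb], codes_fwd, index.scoring)
        sr = align_global(index.codes[lb], codes_rev, index.scoring)
        scores[lb] = max(sf, sr)
    order = sorted(index.labels, key=lambda lb: scores[lb], reverse=True)
    best = order[0]
    margin = scores[best] - scores[order[1]] if len(order) > 1 else scores[best]
    if len(order) > 1 and margin <= index.delta:
        return TranscriptCall(read_id, "ambiguous", "na", margin)
    isoform, allele = best.split("|")
    hdr_status = allele.lower() if allele != "na" else "na"
    return TranscriptCall(read_id, isoform, hdr_status, margin)


def classify_transcript_batch(
    reads,
    model: TranscriptModel,
    scoring: Scoring = Scoring(),
    delta: int = 0,
) -> pd.DataFrame:
    index = TranscriptIndex(model, scoring, delta)
    rows = []
    for rec in reads:
        if hasattr(rec, "read_id"):
            rid, seq = rec.read_id, rec.seq
        else:
            rid, seq = rec[0], rec[1]
        if not seq:
            continue
        rows.append(classify_transcript_read(rid, seq, index).to_row())
    return pd.DataFrame(rows, columns=list(TRANSCRIPT_CALL_COLUMNS))


def splice_report(calls: pd.DataFrame) -> dict:
    """Isoform fractions plus precise-HDR-in-exon quantification.

    Returns a dict with per-isoform percentages (summing to 100 including
    ambiguous), the HDR percentage among exon-containing transcripts
    (``None`` with ``zero_denominator`` set when no read covers the target
    exon region), and the overall correctly-spliced-and-HDR percentage.
    """
    if len(calls) == 0:
        raise ValueError("empty transcript call table")
    n = len(calls)
    isoform_pct = {
        iso: 100.0 * k / n for iso, k in calls["isoform"].value_counts().items()
    }
    exon_containing = calls[calls["hdr_status_in_exon"] != "na"]
    n_exon = len(exon_containing)
    if n_exon:
        hdr_among_exon = 100.0 * (exon_containing["hdr_status_in_exon"] == "hdr").mean()
        zero_denominator = False
    else:
        hdr_among_exon = None
        zero_denominator = True
    full_hdr = (
        (calls["isoform"] == "full_length") & (calls["hdr_status_in_exon"] == "hdr")
    ).sum()
    return {
        "n_reads": int(n),
        "isoform_pct": isoform_pct,
        "n_exon_containing": int(n_exon),
        "hdr_among_exon_containing_pct": hdr_among_exon,
        "zero_denominator": zero_denominator,
        "correctly_spliced_hdr_pct": 100.0 * full_hdr / n,
    }
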