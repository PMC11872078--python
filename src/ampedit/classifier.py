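"""Per-read outcome classification against the WT / MUT / HDR allele set.

Each read is screened for large on-target deletions against the WT
amplicon, then assigned to the best-scoring allele under global
affine-gap alignment (both orientations evaluated).  Indels overlapping
the quantification window around the cut site split each allele category
into unedited vs edited; score ties within ``delta`` are called
ambiguous.  HDR-informative columns (programmed SNPs, phasing marker)
are read directly off the winning alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import (
    OP_DEL,
    OP_INS,
    Scoring,
    align_global,
    encode,
    ops_to_indels,
    ops_to_ref2query,
    revcomp,
)
from .locus_model import AlleleSet, LocusSpec

logger = logging.getLogger(__name__)

CATEGORIES = (
    "WT_unedited",
    "WT_edited",
    "MUT_unedited",
    "MUT_edited",
    "HDR",
    "HDR_edited",
    "ambiguous",
    "large_deletion",
)

CALL_COLUMNS = (
    "read_id",
    "category",
    "best_allele",
    "score_margin",
    "indel_in_window",
    "window_indels",
    "largest_del",
    "snp_vector",
    "marker_allele",
)


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment of one read against one allele."""

    allele_id: str
    score: int
    ops: Optional[np.ndarray]  # per-column op codes, reference order
    strand: str  # "forward" | "reverse"


@dataclass(frozen=True)
class ReadCall:
    read_id: str
    category: str
    best_allele: str
    score_margin: int
    indel_in_window: bool
    window_indels: tuple  # ((pos, size, kind), ...) on the best allele frame
    largest_del: int
    snp_vector: str  # per programmed SNP: w/t/o/- (wt/template/other/missing)
    marker_allele: str  # observed base or "."
    best_scores: dict = field(default_factory=dict)

    def to_row(self):
        return (
            self.read_id,
            self.category,
            self.best_allele,
            self.score_margin,
            self.indel_in_window,
            ";".join(f"{p}:{s}:{k}" for p, s, k in self.window_indels) or ".",
            self.largest_del,
            self.snp_vector or ".",
            self.marker_allele,
        )


@dataclass(frozen=True)
class ClassifyParams:
    window: int = 2
    delta: int = 0
    min_large_del: int = 200
    scoring: Scoring = field(default_factory=Scoring)

    def __post_init__(self):
        if self.window < 0 or self.delta < 0:
            raise ValueError("window and delta must be >= 0")
        if self.min_large_del <= 0:
            raise ValueError("min_large_del must be positive")


def align_read(read: str, allele: str, scoring: Scoring = Scoring(), allele_id: str = "") -> AlignmentResult:
    """Optimal global alignment of a read against one allele.

    Both orientations are evaluated; the higher-scoring one is kept, with
    a deterministic tie-break preferring the forward strand.
    """
    fwd_score, fwd_ops = align_global(allele, read, scoring, traceback=True)
    rev_score, rev_ops = align_global(allele, revcomp(read), scoring, traceback=True)
    if rev_score > fwd_score:
        return AlignmentResult(allele_id, rev_score, rev_ops, "reverse")
    return AlignmentResult(allele_id, fwd_score, fwd_ops, "forward")


def call_indel_in_window(
    aln: AlignmentResult, cut_sites: Sequence[int], w: int = 2, ref_len: Optional[int] = None
):
    """Flag insertions/deletions overlapping the cut-site quantification window.

    The window is the closed inter-base interval ``[cut - w, cut + w]``; an
    insertion occupies a single inter-base point, a deletion of bases
    ``[s, s + L)`` the inter-base interval ``[s, s + L]``.  Substitutions
    never trigger the flag.  Returns ``(flag, window_indels)`` with indels
    as ``(pos, size, kind)`` tuples on the reference frame.
    """
    if aln.ops is None:
        raise ValueError("alignment has no operation list")
    if ref_len is not None:
        for c in cut_sites:
            if not 0 <= c <= ref_len:
                raise IndexError(f"cut site {c} outside the allele")
    insertions, deletions = ops_to_indels(aln.ops)
    hits = []
    for c in cut_sites:
        lo, hi = c - w, c + w
        for pos, size in insertions:
            if lo <= pos <= hi:
                hits.append((pos, size, "ins"))
        for pos, size in deletions:
            if pos <= hi and pos + size >= lo:
                hits.append((pos, size, "del"))
    hits = sorted(set(hits))
    return bool(hits), tuple(hits)


def detect_large_deletion(aln_to_wt: AlignmentResult, min_size: int = 200):
    """Flag reads carrying a single deletion >= ``min_size`` vs the WT amplicon."""
    if aln_to_wt.ops is None:
        raise ValueError("alignment has no operation list")
    _, deletions = ops_to_indels(aln_to_wt.ops)
    largest = max((size for _, size in deletions), default=0)
    return largest >= min_size, largest


class AlleleIndex:
    """Pre-encoded allele set shared across reads of a batch."""

    def __init__(self, alleles: AlleleSet, locus: LocusSpec, params: ClassifyParams):
        self.alleles = alleles
        self.locus = locus
        self.params = params
        self.codes = {a: encode(alleles.seq(a)) for a in AlleleSet.ALLELES}
        self.snp_positions = {a: alleles.snp_positions_on(a) for a in AlleleSet.ALLELES}
        self.marker_pos = alleles.marker_pos_per_allele
        self.cut_sites = alleles.cut_sites_per_allele
        self.template_bases = alleles.snp_template_bases
        self.wt_bases = alleles.snp_wt_bases


def _read_columns(index: AlleleIndex, allele: str, ops, oriented_read: str):
    """Read SNP and marker columns off an alignment to ``allele``."""
    ref_len = len(index.alleles.seq(allele))
    ref2q = ops_to_ref2query(ops, ref_len)
    snp_chars = []
    for p, wt_b, tpl_b in zip(
        index.snp_positions[allele], index.wt_bases, index.template_bases
    ):
        if p is None:
            snp_chars.append("-")
            continue
        q = ref2q[p]
        if q < 0:
            snp_chars.append("-")
            continue
        b = oriented_read[q]
        if b == tpl_b:
            snp_chars.append("t")
        elif b == wt_b:
            snp_chars.append("w")
        else:
            snp_chars.append("o")
    marker = "."
    mp = index.marker_pos[allele]
    if mp is not None:
        q = ref2q[mp]
        if q >= 0:
            marker = oriented_read[q]
    return "".join(snp_chars), marker


def classify_read(read_id: str, seq: str, index: AlleleIndex) -> ReadCall:
    """Assign one read to an outcome category (see module docstring)."""
    params = index.params
    scoring = params.scoring
    seq_rev = revcomp(seq)
    codes_fwd = encode(seq)
    codes_rev = encode(seq_rev)

    # large-deletion screen against the WT amplicon (needs the WT path anyway)
    wt_f_score = align_global(index.codes["WT"], codes_fwd, scoring)
    wt_r_score = align_global(index.codes["WT"], codes_rev, scoring)
    if wt_r_score > wt_f_score:
        _, ops = align_global(index.codes["WT"], codes_rev, scoring, traceback=True)
        wt_aln = AlignmentResult("WT", wt_r_score, ops, "reverse")
    else:
        _, ops = align_global(index.codes["WT"], codes_fwd, scoring, traceback=True)
        wt_aln = AlignmentResult("WT", wt_f_score, ops, "forward")
    big, largest = detect_large_deletion(wt_aln, params.min_large_del)
    if big:
        return ReadCall(
            read_id=read_id,
            category="large_deletion",
            best_allele="WT",
            score_margin=0,
            indel_in_window=False,
            window_indels=(),
            largest_del=largest,
            snp_vector="",
            marker_allele=".",
            best_scores={"WT": wt_aln.score},
        )

    scores = {"WT": wt_aln.score}
    strands = {"WT": wt_aln.strand}
    for allele in ("MUT", "HDR"):
        sf = align_global(index.codes[allele], codes_fwd, scoring)
        sr = align_global(index.codes[allele], codes_rev, scoring)
        scores[allele] = max(sf, sr)
        strands[allele] = "reverse" if sr > sf else "forward"

    order = sorted(AlleleSet.ALLELES, key=lambda a: scores[a], reverse=True)
    best, second = order[0], order[1]
    margin = scores[best] - scores[second]
    ambiguous = margin <= params.delta

    if best == "WT":
        best_aln = wt_aln
    else:
        oriented = codes_rev if strands[best] == "reverse" else codes_fwd
        _, ops = align_global(index.codes[best], oriented, scoring, traceback=True)
        best_aln = AlignmentResult(best, scores[best], ops, strands[best])

    oriented_read = seq_rev if best_aln.strand == "reverse" else seq
    flag, window_indels = call_indel_in_window(
        best_aln, index.cut_sites[best], params.window, len(index.alleles.seq(best))
    )
    snp_vector, marker = _read_columns(index, best, best_aln.ops, oriented_read)
    _, largest = detect_large_deletion(best_aln, 10**9)  # largest del, never flags

    if ambiguous:
        category = "ambiguous"
    elif best == "HDR":
        category = "HDR_edited" if flag else "HDR"
    else:
        category = f"{best}_edited" if flag else f"{best}_unedited"
    return ReadCall(
        read_id=read_id,
        category=category,
        best_allele=best,
        score_margin=margin,
        indel_in_window=flag,
        window_indels=window_indels,
        largest_del=largest,
        snp_vector=snp_vector,
        marker_allele=marker,
        best_scores=scores,
    )


def classify_batch(
    reads,
    alleles: AlleleSet,
    locus: LocusSpec,
    params: ClassifyParams = ClassifyParams(),
    progress_every: int = 0,
) -> pd.DataFrame:
    """Classify an iterable of reads; returns one row per read.

    ``reads`` yields objects with ``read_id`` and ``seq`` attributes (or
    ``(read_id, seq)`` tuples).  Unparseable/empty sequences are skipped
    with a logged warning.
    """
    index = AlleleIndex(alleles, locus, params)
    rows = []
    skipped = 0
    for n, rec in enumerate(reads, 1):
        if hasattr(rec, "read_id"):
            rid, seq = rec.read_id, rec.seq
        else:
            rid, seq = rec[0], rec[1]
        if not seq:
            skipped += 1
            logger.warning("skipping empty read %s", rid)
            continue
        rows.append(classify_read(rid, seq, index).to_row())
        if progress_every and n % progress_every == 0:
            logger.info("classified %d reads", n)
    if skipped:
        logger.warning("skipped %d unusable reads", skipped)
    df = pd.DataFrame(rows, columns=list(CALL_COLUMNS))
    return df
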