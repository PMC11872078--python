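"""Synthetic nanopore-like amplicon reads with a per-read truth table.

Generates gDNA and cDNA reads from allele/isoform mixtures under a simple
i.i.d. error model (~1%/nt by default: substitutions 0.6%, single-base
deletions 0.3%, single-base insertions 0.1%), an NHEJ indel spectrum
dominated by a +1 T insertion at the cut site, geometric HDR conversion
tracts producing distance-dependent SNP incorporation, and nickase-style
large deletions anchored at the first cut site.

All randomness flows from a single ``numpy.random.Generator`` seeded from
``SimConfig.seed``: identical configs produce byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import revcomp
from .locus_model import AlleleSet, LocusSpec

GDNA_CATEGORIES = (
    "WT_unedited",
    "MUT_unedited",
    "WT_NHEJ",
    "MUT_NHEJ",
    "HDR_perfect",
    "HDR_partial",
    "large_deletion",
)

TRUTH_COLUMNS = (
    "read_id",
    "source_allele",
    "isoform",
    "indel_pos",
    "indel_size",
    "indel_type",
    "converted_snps",
    "marker_allele",
    "n_errors",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class IndelClass:
    """One NHEJ spectrum entry: an indel size class with a sampling weight."""

    kind: str  # "ins" | "del"
    size_min: int
    size_max: int
    weight: float
    seq: Optional[str] = None  # fixed inserted bases (insertions only)

    def __post_init__(self):
        if self.kind not in ("ins", "del"):
            raise ValueError(f"bad indel kind {self.kind!r}")
        if not 1 <= self.size_min <= self.size_max:
            raise ValueError("bad size range")
        if self.weight <= 0:
            raise ValueError("weights must be positive")
        if self.seq is not None and (
            len(self.seq) != self.size_min or self.size_min != self.size_max
        ):
            raise ValueError(
                "fixed-sequence insertion requires size_min == size_max == len(seq)"
            )


def default_nhej_spectrum() -> tuple[IndelClass, ...]:
    """Dominant +1 T insertion plus three deletion size classes.

    The relative weights beyond the dominant +1 T are synthetic defaults;
    only the size-class structure (1-9 / 10-50 / >50) is meaningful.
    """
    return (
        IndelClass("ins", 1, 1, 0.45, seq="T"),
        IndelClass("del", 1, 9, 0.35),
        IndelClass("del", 10, 50, 0.15),
        IndelClass("del", 51, 120, 0.05),
    )


@dataclass(frozen=True)
class SimConfig:
    n_reads: int
    mixture: dict
    sub_rate: float = 0.006
    del_rate: float = 0.003
    ins_rate: float = 0.001
    strand_flip_prob: float = 0.5
    nhej_spectrum: tuple = field(default_factory=default_nhej_spectrum)
    tract_decay: float = 30.0  # mean scale of the geometric conversion tract
    large_del_size: int = 350
    hdr_on_wt_prob: float = 0.5  # parental allele of an HDR event
    seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise SimConfigError("n_reads must be positive")
        # category names are validated by the simulators (cDNA mixtures use
        # transcript-model labels, not the gDNA category set)
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"mixture fractions sum to {total}, not 1")
        for name, frac in self.mixture.items():
            if frac < 0:
                raise SimConfigError(f"negative fraction for {name}")
        for r in (self.sub_rate, self.del_rate, self.ins_rate, self.strand_flip_prob):
            if not 0 <= r <= 1:
                raise SimConfigError("rates must lie in [0, 1]")
        if self.tract_decay <= 1:
            raise SimConfigError("tract_decay must exceed 1")
        object.__setattr__(self, "nhej_spectrum", tuple(self.nhej_spectrum))

    @property
    def tract_continuation(self) -> float:
        """Per-base tract continuation probability p = 1 - 1/tract_decay."""
        return 1.0 - 1.0 / self.tract_decay

    def tract_coverage_prob(self, distance: int) -> float:
        """Analytic P(a SNP at `distance` bases from the cut is converted)."""
        return self.tract_continuation**distance


@dataclass
class FastqRead:
    read_id: str
    seq: str
    qual: str


def sample_nhej_indel(cfg: SimConfig, rng: np.random.Generator):
    """Draw one NHEJ indel from the spectrum: ``(size, kind, seq)``.

    The cut-site anchoring (position) is applied by the caller.
    """
    spectrum = cfg.nhej_spectrum
    if not spectrum:
        raise SimConfigError("empty NHEJ spectrum")
    w = np.array([c.weight for c in spectrum], dtype=float)
    w /= w.sum()
    cls = spectrum[rng.choice(len(spectrum), p=w)]
    size = int(rng.integers(cls.size_min, cls.size_max + 1))
    if cls.kind == "ins":
        seq = cls.seq if cls.seq is not None else "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size)
        )
        return size, "ins", seq
    return size, "del", None


def _apply_nhej_indel(seq: str, cut: int, size: int, kind: str, ins_seq):
    """Anchor an indel at an inter-base cut site; returns (seq, pos, size, kind)."""
    if kind == "ins":
        return seq[:cut] + ins_seq + seq[cut:], cut, size, "ins"
    start = max(0, cut - size // 2)
    end = min(len(seq), start + size)
    start = max(0, end - size)
    return seq[:start] + seq[end:], start, end - start, "del"


def apply_read_errors(seq: str, cfg: SimConfig, rng: np.random.Generator):
    """Apply i.i.d. substitution / deletion / insertion errors; returns (seq, n)."""
    if cfg.sub_rate == 0 and cfg.del_rate == 0 and cfg.ins_rate == 0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    L = arr.size
    n_errors = 0
    if cfg.sub_rate > 0:
        sub = rng.random(L) < cfg.sub_rate
        idx = np.nonzero(sub)[0]
        if idx.size:
            # replace with one of the three other bases
            code = np.searchsorted(_BASES, arr[idx])
            code = np.where(np.isin(arr[idx], _BASES), code, 0)
            newcode = (code + rng.integers(1, 4, idx.size)) % 4
            arr[idx] = _BASES[newcode]
            n_errors += idx.size
    keep = np.ones(L, dtype=bool)
    if cfg.del_rate > 0:
        dels = rng.random(L) < cfg.del_rate
        keep &= ~dels
        n_errors += int(dels.sum())
    if cfg.ins_rate > 0:
        ins = rng.random(L + 1) < cfg.ins_rate
        ins_pos = np.nonzero(ins)[0]
    else:
        ins_pos = np.empty(0, dtype=np.int64)
    if ins_pos.size:
        ins_bases = _BASES[rng.integers(0, 4, ins_pos.size)]
        n_errors += ins_pos.size
        pieces = []
        prev = 0
        for p, b in zip(ins_pos, ins_bases):
            pieces.append(arr[prev:p][keep[prev:p]])
            pieces.append(np.array([b], dtype=np.uint8))
            prev = p
        pieces.append(arr[prev:][keep[prev:]])
        out = np.concatenate(pieces)
    else:
        out = arr[keep]
    return out.tobytes().decode("ascii"), n_errors


def _with_base(seq: str, pos: Optional[int], base: Optional[str]) -> str:
    if pos is None or base is None:
        return seq
    return seq[:pos] + base + seq[pos + 1 :]


def _draw_tract(cfg: SimConfig, rng: np.random.Generator) -> tuple[int, int]:
    """Independent left/right tract extents (bases covered on each side).

    P(extent >= d) = p^d with p the per-base continuation probability, so
    extent = Geometric(1 - p) - 1 under numpy's >= 1 convention.
    """
    p_stop = 1.0 / cfg.tract_decay
    left = int(rng.geometric(p_stop)) - 1
    right = int(rng.geometric(p_stop)) - 1
    return left, right


def simulate_gdna_reads(
    alleles: AlleleSet,
    locus: LocusSpec,
    cfg: SimConfig,
    read_prefix: str = "read",
):
    """Simulate genomic amplicon reads; returns ``(reads, truth)``.

    ``reads`` is a list of :class:`FastqRead`; ``truth`` a DataFrame with
    one row per read (columns ``TRUTH_COLUMNS``).
    """
    bad = set(cfg.mixture) - set(GDNA_CATEGORIES)
    if bad:
        raise SimConfigError(f"unknown mixture categories: {sorted(bad)}")
    if (
        cfg.mixture.get("HDR_perfect", 0) or cfg.mixture.get("HDR_partial", 0)
    ) and not alleles.snp_positions:
        raise SimConfigError(
            "mixture contains HDR categories but the template has no programmed SNPs"
        )
    if cfg.mixture.get("large_deletion", 0):
        cut0 = alleles.cut_sites_per_allele["WT"][0]
        if cut0 + cfg.large_del_size > len(alleles.wt_seq):
            raise SimConfigError(
                "large_del_size extends past the amplicon end from the first cut site"
            )

    rng = np.random.default_rng(cfg.seed)
    cats = sorted(cfg.mixture)
    probs = np.array([cfg.mixture[c] for c in cats], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(cats), size=cfg.n_reads, p=probs)

    marker = locus.marker_snp
    mk_wt = alleles.marker_pos_per_allele["WT"]
    mk_mut = alleles.marker_pos_per_allele["MUT"]
    cut_wt = alleles.cut_sites_per_allele["WT"]
    cut_mut = alleles.cut_sites_per_allele["MUT"]
    n_snps = len(alleles.snp_positions)

    reads = []
    rows = []
    for i in range(cfg.n_reads):
        cat = cats[draws[i]]
        isoform = "."
        indel_pos = indel_size = -1
        indel_type = "."
        converted = "." if n_snps == 0 else "0" * n_snps
        marker_base = "."

        if cat in ("WT_unedited", "WT_NHEJ"):
            seq = alleles.wt_seq
            if marker is not None:
                marker_base = marker.base_on_wt_allele
                seq = _with_base(seq, mk_wt, marker_base)
            if cat == "WT_NHEJ":
                cut = cut_wt[int(rng.integers(0, len(cut_wt)))]
                size, kind, ins_seq = sample_nhej_indel(cfg, rng)
                seq, indel_pos, indel_size, indel_type = _apply_nhej_indel(
                    seq, cut, size, kind, ins_seq
                )
        elif cat in ("MUT_unedited", "MUT_NHEJ"):
            seq = alleles.mut_seq
            if marker is not None and mk_mut is not None:
                marker_base = marker.base_on_mut_allele
                seq = _with_base(seq, mk_mut, marker_base)
            if cat == "MUT_NHEJ":
                cut = cut_mut[int(rng.integers(0, len(cut_mut)))]
                size, kind, ins_seq = sample_nhej_indel(cfg, rng)
                seq, indel_pos, indel_size, indel_type = _apply_nhej_indel(
                    seq, cut, size, kind, ins_seq
                )
        elif cat in ("HDR_perfect", "HDR_partial"):
            if cat == "HDR_perfect":
                mask = [True] * n_snps
            else:
                cut = cut_wt[0]
                left, right = _draw_tract(cfg, rng)
                mask = []
                for p in alleles.snp_positions:
                    d = cut - p if p < cut else p - cut + 1
                    side = left if p < cut else right
                    mask.append(side >= d)
            s = list(alleles.wt_seq)
            for p, tb, keep in zip(
                alleles.snp_positions, alleles.snp_template_bases, mask
            ):
                if keep:
                    s[p] = tb
            seq = "".join(s)
            converted = "".join("1" if k else "0" for k in mask)
            if marker is not None:
                on_wt = rng.random() < cfg.hdr_on_wt_prob
                marker_base = (
                    marker.base_on_wt_allele if on_wt else marker.base_on_mut_allele
                )
                seq = _with_base(seq, mk_wt, marker_base)
        elif cat == "large_deletion":
            # MMEJ-style deletion extending from the first cut site
            src = "WT" if rng.random() < 0.5 else "MUT"
            seq = alleles.seq(src)
            mk = alleles.marker_pos_per_allele[src]
            if marker is not None and mk is not None:
                marker_base = (
                    marker.base_on_wt_allele
                    if src == "WT"
                    else marker.base_on_mut_allele
                )
                seq = _with_base(seq, mk, marker_base)
            cut = alleles.cut_sites_per_allele[src][0]
            size = min(cfg.large_del_size, len(seq) - cut)
            seq = seq[:cut] + seq[cut + size :]
            indel_pos, indel_size, indel_type = cut, size, "del"
            if marker is not None and mk is not None and cut <= mk < cut + size:
                marker_base = "."  # marker removed by the deletion
        else:  # pragma: no cover
            raise AssertionError(cat)

        seq, n_errors = apply_read_errors(seq, cfg, rng)
        if rng.random() < cfg.strand_flip_prob:
            seq = revcomp(seq)
        rid = f"{read_prefix}{i:06d}"
        reads.append(FastqRead(rid, seq, "5" * len(seq)))
        rows.append(
            (
                rid,
                cat,
                isoform,
                indel_pos,
                indel_size,
                indel_type,
                converted,
                marker_base,
                n_errors,
            )
        )
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return reads, truth


def simulate_cdna_reads(
    model,
    isoform_mixture: dict,
    cfg: SimConfig,
    read_prefix: str = "cdna",
):
    """Simulate cDNA reads from transcript-model references.

    ``isoform_mixture`` keys must be reference labels of the model
    (``"<isoform>|<allele>"``).  Truth records the generating label split
    into isoform and allele.
    """
    bad = set(isoform_mixture) - set(model.references)
    if bad:
        raise SimConfigError(
            f"mixture labels {sorted(bad)} not in the transcript model "
            f"({sorted(model.references)})"
        )
    total = sum(isoform_mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise SimConfigError(f"isoform mixture sums to {total}, not 1")

    rng = np.random.default_rng(cfg.seed)
    labels = sorted(isoform_mixture)
    probs = np.array([isoform_mixture[k] for k in labels], dtype=float)
    probs /= probs.sum()
    draws = rng.choice(len(labels), size=cfg.n_reads, p=probs)

    reads = []
    rows = []
    for i in range(cfg.n_reads):
        label = labels[draws[i]]
        isoform, allele = label.split("|")
        seq, n_errors = apply_read_errors(model.references[label], cfg, rng)
        if rng.random() < cfg.strand_flip_prob:
            seq = revcomp(seq)
        rid = f"{read_prefix}{i:06d}"
        reads.append(FastqRead(rid, seq, "5" * len(seq)))
        rows.append((rid, allele, isoform, -1, -1, ".", ".", ".", n_errors))
    truth = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return reads, truth


# ---------------------------------------------------------------------------
# Demo loci: deterministic synthetic stand-ins for the study's amplicons.
# Sequences are random under a fixed seed with marker/SNP reference bases
# forced to consistent values; coordinates reuse the published HGVS strings.
# ---------------------------------------------------------------------------

from .locus_model import (  # noqa: E402
    HdrTemplateSpec,
    LocusSpec,
    MarkerSnp,
    ProgrammedSnp,
    VariantSpec,
    parse_hgvs_c,
)


def _random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


def _other_base(b: str, shift: int = 1) -> str:
    return "ACGT"[("ACGT".index(b) + shift) % 4]


def _make_template(seq: str, snp_positions, coord_offset, correction) -> HdrTemplateSpec:
    snps = []
    for p in snp_positions:
        wt = seq[p]
        snps.append(
            ProgrammedSnp(
                position=p + coord_offset,
                wt_base=wt,
                template_base=_other_base(wt),
            )
        )
    return HdrTemplateSpec(correction=correction, programmed_snps=tuple(snps))


def demo_locus(
    amplicon_len: int = 240,
    specificity: str = "non_specific",
    n_snps: int = 8,
    seq_seed: int = 20,
):
    """Heterozygous nuclease-mode locus: 11-bp deletion, 8-SNP template, marker.

    Returns ``(locus, mut_variant, hdr_template)``.  The cut site sits at
    the left edge of the deletion; four programmed SNPs flank it on each
    side at increasing distances, and the phasing marker lies ~80 nt
    downstream in cis with the WT allele.
    """
    mut = parse_hgvs_c("c.8698_8708del")
    del_start = amplicon_len // 2 - 5  # 0-based amplicon position of c.8698
    coord_offset = mut.start - del_start
    cut = del_start  # guide cuts at the deletion's left edge
    seq = list(_random_sequence(amplicon_len, seq_seed))

    marker_pos = del_start + 82
    if marker_pos >= amplicon_len - 5:
        raise ValueError("amplicon too short for the demo layout")
    seq[marker_pos] = "G"
    left = [cut - d for d in (30, 20, 12, 5)]
    right = [cut + d - 1 for d in (15, 23, 31, 41)]
    snp_positions = sorted(left + right)[:n_snps]
    sequence = "".join(seq)

    locus = LocusSpec(
        amplicon_id="demo_het_locus",
        sequence=sequence,
        coord_offset=coord_offset,
        cut_sites=(cut,),
        guide_allele_specificity=specificity,
        marker_snp=MarkerSnp(
            position=marker_pos + coord_offset,
            wt_base="G",
            mut_base="A",
            phase="cis_to_WT",
        ),
    )
    template = _make_template(sequence, snp_positions, coord_offset, mut)
    return locus, mut, template


def demo_nickase_locus(amplicon_len: int = 600, seq_seed: int = 21):
    """Dual-nickase locus: two cuts 65 bp apart (PAM-out) around the deletion.

    Large ~350-bp deletions extend rightward from the first cut site.
    """
    mut = parse_hgvs_c("c.8698_8708del")
    del_start = 140
    coord_offset = mut.start - del_start
    cuts = (115, 180)
    seq = list(_random_sequence(amplicon_len, seq_seed))
    marker_pos = 222
    seq[marker_pos] = "G"
    snp_positions = [90, 100, 108, 113, 185, 195, 205, 215]
    sequence = "".join(seq)

    locus = LocusSpec(
        amplicon_id="demo_nickase_locus",
        sequence=sequence,
        coord_offset=coord_offset,
        cut_sites=cuts,
        guide_allele_specificity="non_specific",
        marker_snp=MarkerSnp(
            position=marker_pos + coord_offset,
            wt_base="G",
            mut_base="A",
            phase="cis_to_WT",
        ),
    )
    template = _make_template(sequence, snp_positions, coord_offset, mut)
    return locus, mut, template


def demo_transcript_locus(seq_seed: int = 22):
    """Three-exon gene model (50/197/60 nt) with the mutation in the middle exon.

    The aberrant-acceptor isoform truncates the first 120 nt of the target
    exon; an AG dinucleotide is planted immediately upstream of the
    truncation point.  Returns ``(locus, mut, template, truncation)``.
    """
    exons = ((0, 50), (50, 247), (247, 307))
    truncation = 120
    mut = parse_hgvs_c("c.8698_8708del")
    exon_start = exons[1][0]
    del_start = exon_start + 130  # survives the 120-nt truncation
    coord_offset = mut.start - del_start
    seq = list(_random_sequence(307, seq_seed))
    # aberrant splice acceptor: AG immediately before the truncation point
    seq[exon_start + truncation - 2] = "A"
    seq[exon_start + truncation - 1] = "G"
    snp_offsets = (60, 80, 100, 115, 150, 160, 170, 185)
    snp_positions = [exon_start + o for o in snp_offsets]
    sequence = "".join(seq)

    locus = LocusSpec(
        amplicon_id="demo_transcript_locus",
        sequence=sequence,
        coord_offset=coord_offset,
        cut_sites=(del_start,),
        guide_allele_specificity="non_specific",
        exons=exons,
    )
    template = _make_template(sequence, snp_positions, coord_offset, mut)
    return locus, mut, template, truncation
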