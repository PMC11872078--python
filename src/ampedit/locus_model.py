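"""Locus, variant and HDR-template models.

Parses the HGVS-c-style variant strings used to describe the edited locus
and materialises the concrete allele sequences (WT / MUT / HDR) and cDNA
isoform references that every downstream stage aligns against.

Coordinate conventions
----------------------
* HGVS-c strings are 1-based inclusive.
* All internal coordinates are 0-based; intervals are half-open.
* Cut sites are inter-base integers: cut site ``c`` sits between bases
  ``c-1`` and ``c``.
* ``LocusSpec.coord_offset`` maps HGVS numbering onto the amplicon:
  ``amplicon_pos = hgvs_pos - coord_offset`` (0-based result).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

VALID_KINDS = ("deletion", "substitution", "insertion")


class HgvsParseError(ValueError):
    pass


class ReferenceMismatchError(ValueError):
    pass


@dataclass(frozen=True)
class VariantSpec:
    """A single parsed variant: deletion, substitution or insertion."""

    raw: str
    kind: str
    start: int  # 1-based inclusive (HGVS frame)
    end: int  # 1-based inclusive; == start for point events
    ref: str = ""
    alt: str = ""
    intron_offset: int = 0  # nonzero marks a non-exonic (intron-offset) variant

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.end < self.start:
            raise HgvsParseError(
                f"{self.raw!r}: coordinate order error (start {self.start} > end {self.end})"
            )
        if self.kind == "substitution" and (len(self.ref) != 1 or len(self.alt) != 1):
            raise ValueError("substitution requires |ref| = |alt| = 1")

    @property
    def length(self) -> int:
        """Affected reference span in nucleotides (end - start + 1)."""
        return self.end - self.start + 1

    @property
    def is_exonic(self) -> bool:
        return self.intron_offset == 0


_DEL_RANGE = re.compile(r"^c\.(\d+)_(\d+)del$")
_DEL_SINGLE = re.compile(r"^c\.(\d+)del$")
_SUB = re.compile(r"^c\.(\d+)(?:([+-])(\d+))?([ACGT])>([ACGT])$")
_INS = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


def parse_hgvs_c(raw: str) -> VariantSpec:
    """Parse a restricted HGVS-c grammar.

    Supported forms: ``c.<n>_<m>del``, ``c.<n>del``, ``c.<n><R>><A>``,
    ``c.<n>_<m>ins<seq>`` and intron-offset substitutions
    ``c.<n>[+-]<k><R>><A>`` (parsed but flagged non-exonic).  Anything
    else is rejected.
    """
    s = raw.strip()
    m = _DEL_RANGE.match(s)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if start > end:
            raise HgvsParseError(f"{raw!r}: coordinate order error ({start} > {end})")
        return VariantSpec(raw=s, kind="deletion", start=start, end=end)
    m = _DEL_SINGLE.match(s)
    if m:
        pos = int(m.group(1))
        return VariantSpec(raw=s, kind="deletion", start=pos, end=pos)
    m = _SUB.match(s)
    if m:
        pos = int(m.group(1))
        sign, off = m.group(2), m.group(3)
        offset = 0
        if sign is not None:
            offset = int(off) * (1 if sign == "+" else -1)
        return VariantSpec(
            raw=s,
            kind="substitution",
            start=pos,
            end=pos,
            ref=m.group(4),
            alt=m.group(5),
            intron_offset=offset,
        )
    m = _INS.match(s)
    if m:
        start, end = int(m.group(1)), int(m.group(2))
        if end != start + 1:
            raise HgvsParseError(
                f"{raw!r}: insertion must be flanked by adjacent positions "
                f"(got {start}_{end})"
            )
        return VariantSpec(raw=s, kind="insertion", start=start, end=end, alt=m.group(3))
    raise HgvsParseError(f"cannot parse HGVS-c string {raw!r}")


@dataclass(frozen=True)
class MarkerSnp:
    """A heterozygous SNP used to phase reads to a parental allele.

    ``phase`` names the allele carrying the variant base (``mut_base``):
    ``cis_to_WT`` or ``cis_to_MUT``.
    """

    position: int  # HGVS frame, 1-based
    wt_base: str
    mut_base: str
    phase: str = "cis_to_WT"

    def __post_init__(self):
        if self.phase not in ("cis_to_WT", "cis_to_MUT"):
            raise ValueError(f"bad marker phase {self.phase!r}")
        if self.wt_base == self.mut_base:
            raise ValueError("marker bases must differ")

    @property
    def base_on_wt_allele(self) -> str:
        return self.mut_base if self.phase == "cis_to_WT" else self.wt_base

    @property
    def base_on_mut_allele(self) -> str:
        return self.wt_base if self.phase == "cis_to_WT" else self.mut_base


@dataclass(frozen=True)
class ProgrammedSnp:
    position: int  # HGVS frame, 1-based
    wt_base: str
    template_base: str
    role: str = "bridging"  # blocking | bridging

    def __post_init__(self):
        if self.template_base == self.wt_base:
            raise ValueError(
                f"programmed SNP at {self.position}: template base equals WT base"
            )
        if self.role not in ("blocking", "bridging"):
            raise ValueError(f"bad SNP role {self.role!r}")


@dataclass(frozen=True)
class LocusSpec:
    """The amplicon and everything anchored on it."""

    amplicon_id: str
    sequence: str
    coord_offset: int
    cut_sites: tuple[int, ...]
    guide_allele_specificity: str = "non_specific"  # MUT_specific | non_specific
    marker_snp: Optional[MarkerSnp] = None
    exons: Optional[tuple[tuple[int, int], ...]] = None  # half-open, amplicon frame

    def __post_init__(self):
        object.__setattr__(self, "sequence", self.sequence.upper())
        object.__setattr__(self, "cut_sites", tuple(self.cut_sites))
        if self.exons is not None:
            object.__setattr__(
                self, "exons", tuple((int(a), int(b)) for a, b in self.exons)
            )
        if self.guide_allele_specificity not in ("MUT_specific", "non_specific"):
            raise ValueError(
                f"bad guide_allele_specificity {self.guide_allele_specificity!r}"
            )
        L = len(self.sequence)
        for c in self.cut_sites:
            if not 0 < c < L:
                raise ValueError(f"cut site {c} not strictly inside the amplicon")
        if self.marker_snp is not None:
            p = self.hgvs_to_amplicon(self.marker_snp.position)
            if not 0 <= p < L:
                raise ValueError("marker SNP outside the amplicon")
            if self.sequence[p] != self.marker_snp.wt_base:
                raise ReferenceMismatchError(
                    f"marker SNP: amplicon has {self.sequence[p]} at HGVS "
                    f"{self.marker_snp.position}, expected {self.marker_snp.wt_base}"
                )
        if self.exons is not None:
            prev_end = -1
            for a, b in self.exons:
                if not (0 <= a < b <= L):
                    raise ValueError(f"exon ({a},{b}) outside the sequence")
                if a < prev_end:
                    raise ValueError("exons must be sorted and non-overlapping")
                prev_end = b

    def hgvs_to_amplicon(self, pos: int) -> int:
        """Map a 1-based HGVS position onto 0-based amplicon coordinates."""
        return pos - self.coord_offset

    @property
    def marker_pos(self) -> Optional[int]:
        if self.marker_snp is None:
            return None
        return self.hgvs_to_amplicon(self.marker_snp.position)


@dataclass(frozen=True)
class HdrTemplateSpec:
    """HDR donor template: the reverted mutation plus programmed silent SNPs."""

    correction: VariantSpec  # the MUT variant this template reverts
    programmed_snps: tuple[ProgrammedSnp, ...] = ()
    homology_arm_length: int = 100

    def __post_init__(self):
        object.__setattr__(self, "programmed_snps", tuple(self.programmed_snps))
        positions = [s.position for s in self.programmed_snps]
        if len(set(positions)) != len(positions):
            raise ValueError("programmed SNP positions must be distinct")


def apply_variant(seq: str, var: VariantSpec, offset: int) -> tuple[str, VariantSpec]:
    """Apply ``var`` to ``seq`` (HGVS frame shifted by ``offset``).

    Returns the edited sequence and a copy of the variant with its ``ref``
    field materialised from the sequence (so the edit is invertible).
    Raises :class:`ReferenceMismatchError` when stated reference bases
    disagree with the sequence.
    """
    a = var.start - offset
    b = var.end - offset + 1  # half-open
    if var.kind == "insertion":
        # bases inserted between positions start and end (= start + 1)
        if not (0 <= a < len(seq)):
            raise ValueError(f"{var.raw!r} maps outside the sequence")
        cut = a + 1
        return seq[:cut] + var.alt + seq[cut:], var
    if not (0 <= a < b <= len(seq)):
        raise ValueError(f"{var.raw!r} maps outside the sequence")
    found = seq[a:b]
    if var.ref and found != var.ref:
        raise ReferenceMismatchError(
            f"{var.raw!r}: sequence has {found!r} at HGVS {var.start}, "
            f"expected {var.ref!r}"
        )
    materialised = replace(var, ref=found)
    if var.kind == "deletion":
        return seq[:a] + seq[b:], materialised
    # substitution
    return seq[:a] + var.alt + seq[b:], materialised


def revert_variant(seq: str, var: VariantSpec, offset: int) -> str:
    """Invert :func:`apply_variant`; requires a materialised ``ref``."""
    a = var.start - offset
    if var.kind == "deletion":
        if not var.ref:
            raise ValueError("cannot revert a deletion without materialised ref bases")
        return seq[:a] + var.ref + seq[a:]
    if var.kind == "insertion":
        cut = a + 1
        if seq[cut : cut + len(var.alt)] != var.alt:
            raise ReferenceMismatchError("inserted bases not found at expected position")
        return seq[:cut] + seq[cut + len(var.alt) :]
    # substitution
    if seq[a] != var.alt:
        raise ReferenceMismatchError("alt base not found at substitution position")
    return seq[:a] + var.ref + seq[a + 1 :]


class Liftover:
    """Exact coordinate maps between the WT frame and a derived allele frame.

    Built from the single variant separating the two frames.  Base
    positions inside a deletion have no image and lift to ``None``;
    everything else is a bijection.
    """

    def __init__(self, var: VariantSpec, offset: int, wt_len: int):
        self.var = var
        self.offset = offset
        self.wt_len = wt_len
        a = var.start - offset
        if var.kind == "deletion":
            self._del_start, self._del_end = a, var.end - offset + 1
            self._shift = -(self._del_end - self._del_start)
        elif var.kind == "insertion":
            self._del_start = self._del_end = a + 1
            self._shift = len(var.alt)
        else:
            self._del_start = self._del_end = wt_len
            self._shift = 0

    def lift_pos(self, p: int) -> Optional[int]:
        """WT base position -> allele base position (None if deleted)."""
        if not 0 <= p < self.wt_len:
            raise IndexError(f"position {p} outside the WT frame")
        if p < self._del_start:
            return p
        if p < self._del_end:
            return None
        return p + self._shift

    def lift_interbase(self, k: int) -> int:
        """WT inter-base position -> allele inter-base position."""
        if not 0 <= k <= self.wt_len:
            raise IndexError(f"inter-base position {k} outside the WT frame")
        if k <= self._del_start:
            return k
        if k < self._del_end:
            return self._del_start
        return k + self._shift

    @property
    def allele_len(self) -> int:
        if self.var.kind == "deletion":
            return self.wt_len + self._shift
        if self.var.kind == "insertion":
            return self.wt_len + self._shift
        return self.wt_len

    def invert_pos(self, q: int) -> Optional[int]:
        """Allele base position -> WT base position (None inside an insertion)."""
        if not 0 <= q < self.allele_len:
            raise IndexError(f"position {q} outside the allele frame")
        if q < self._del_start:
            return q
        if self.var.kind == "insertion":
            if q < self._del_start + self._shift:
                return None
            return q - self._shift
        return q - self._shift  # deletion: shift is negative


@dataclass(frozen=True)
class AlleleSet:
    """Concrete WT / MUT / HDR sequences with per-allele coordinate lifts."""

    wt_seq: str
    mut_seq: str
    hdr_seq: str
    snp_positions: tuple[int, ...]  # 0-based, WT/HDR frame
    snp_wt_bases: tuple[str, ...]
    snp_template_bases: tuple[str, ...]
    cut_sites_per_allele: dict
    marker_pos_per_allele: dict  # allele -> position or None
    mut_variant: VariantSpec  # materialised ref
    liftover_wt_to_mut: Liftover

    ALLELES = ("WT", "MUT", "HDR")

    def seq(self, allele: str) -> str:
        return {"WT": self.wt_seq, "MUT": self.mut_seq, "HDR": self.hdr_seq}[allele]

    def snp_positions_on(self, allele: str):
        """Programmed-SNP positions lifted onto an allele frame (None if absent)."""
        if allele in ("WT", "HDR"):
            return tuple(self.snp_positions)
        lo = self.liftover_wt_to_mut
        return tuple(lo.lift_pos(p) for p in self.snp_positions)


def build_allele_set(
    locus: LocusSpec, mut: VariantSpec, template: HdrTemplateSpec
) -> AlleleSet:
    """Materialise WT / MUT / HDR sequences from the locus description.

    The HDR sequence is the WT backbone carrying every programmed SNP (the
    template reverts the mutation, so HDR differs from WT only at the
    programmed-SNP positions).
    """
    wt = locus.sequence
    off = locus.coord_offset
    mut_seq, mut_materialised = apply_variant(wt, mut, off)

    snp_positions = []
    snp_wt = []
    snp_tpl = []
    hdr = list(wt)
    for snp in template.programmed_snps:
        p = locus.hgvs_to_amplicon(snp.position)
        if not 0 <= p < len(wt):
            raise ValueError(f"programmed SNP at HGVS {snp.position} outside amplicon")
        if snp.wt_base and wt[p] != snp.wt_base:
            raise ReferenceMismatchError(
                f"programmed SNP at HGVS {snp.position}: amplicon has {wt[p]}, "
                f"expected {snp.wt_base}"
            )
        hdr[p] = snp.template_base
        snp_positions.append(p)
        snp_wt.append(wt[p])
        snp_tpl.append(snp.template_base)
    hdr_seq = "".join(hdr)

    lo = Liftover(mut_materialised, off, len(wt))
    cut_sites = {
        "WT": tuple(locus.cut_sites),
        "HDR": tuple(locus.cut_sites),
        "MUT": tuple(lo.lift_interbase(c) for c in locus.cut_sites),
    }
    mp = locus.marker_pos
    marker_pos = {
        "WT": mp,
        "HDR": mp,
        "MUT": None if mp is None else lo.lift_pos(mp),
    }
    return AlleleSet(
        wt_seq=wt,
        mut_seq=mut_seq,
        hdr_seq=hdr_seq,
        snp_positions=tuple(snp_positions),
        snp_wt_bases=tuple(snp_wt),
        snp_template_bases=tuple(snp_tpl),
        cut_sites_per_allele=cut_sites,
        marker_pos_per_allele=marker_pos,
        mut_variant=mut_materialised,
        liftover_wt_to_mut=lo,
    )


@dataclass(frozen=True)
class TranscriptModel:
    """Enumerable isoform x allele reference set for cDNA classification.

    ``references`` maps a label ``"<isoform>|<allele>"`` (allele ``na``
    when the isoform no longer covers the mutation site) to a sequence.
    Identical sequences arising from different allele versions are merged
    under the ``na`` allele label.
    """

    references: dict
    target_exon_index: int
    truncation: int
    exon_lengths: tuple[int, ...]

    ISOFORMS = ("full_length", "exon_skipped", "aberrant_acceptor")

    def labels(self):
        return tuple(self.references)


def build_transcript_model(
    locus: LocusSpec,
    mut: VariantSpec,
    template: HdrTemplateSpec,
    truncation: int,
    target_exon_index: Optional[int] = None,
) -> TranscriptModel:
    """Construct the isoform reference set by exon concatenation.

    ``truncation`` removes that many leading bases of the target exon in
    the aberrant-acceptor isoform.  The target exon defaults to the exon
    containing the mutation.  A warning is issued when the truncation
    point is not immediately preceded by an AG dinucleotide (the expected
    aberrant splice acceptor).
    """
    if not locus.exons:
        raise ValueError("locus has no exon annotation")
    exons = locus.exons
    mut_start = locus.hgvs_to_amplicon(mut.start)
    if target_exon_index is None:
        target_exon_index = next(
            (i for i, (a, b) in enumerate(exons) if a <= mut_start < b), None
        )
        if target_exon_index is None:
            raise ValueError("mutation does not fall inside any exon")
    tgt_a, tgt_b = exons[target_exon_index]
    exon_len = tgt_b - tgt_a
    if not 0 <= truncation < exon_len:
        raise ValueError(f"truncation {truncation} not inside the {exon_len}-nt exon")
    if truncation >= 2:
        acceptor = locus.sequence[tgt_a + truncation - 2 : tgt_a + truncation]
        if acceptor != "AG":
            warnings.warn(
                f"truncation point is preceded by {acceptor!r}, not the expected "
                "AG splice-acceptor dinucleotide",
                stacklevel=2,
            )

    alleles = build_allele_set(locus, mut, template)
    lo = alleles.liftover_wt_to_mut

    def exon_seq(allele_seq: str, a: int, b: int, allele: str) -> str:
        if allele != "MUT":
            return allele_seq[a:b]
        qa = lo.lift_interbase(a)
        qb = lo.lift_interbase(b)
        return allele_seq[qa:qb]

    # per-allele version of the target exon; flanking exons come from WT
    # (the mutation and all programmed SNPs are confined to the target exon
    # in this model; SNPs outside it are ignored with a warning)
    outside = [
        p for p in alleles.snp_positions if not tgt_a <= p < tgt_b
    ]
    if outside:
        warnings.warn(
            f"{len(outside)} programmed SNP(s) fall outside the target exon and are "
            "not represented in the transcript model",
            stacklevel=2,
        )

    def target_exon(allele: str) -> str:
        if allele == "WT":
            return alleles.wt_seq[tgt_a:tgt_b]
        if allele == "MUT":
            return exon_seq(alleles.mut_seq, tgt_a, tgt_b, "MUT")
        s = list(alleles.wt_seq[tgt_a:tgt_b])
        for p, tb in zip(alleles.snp_positions, alleles.snp_template_bases):
            if tgt_a <= p < tgt_b:
                s[p - tgt_a] = tb
        return "".join(s)

    flank_left = "".join(locus.sequence[a:b] for a, b in exons[:target_exon_index])
    flank_right = "".join(locus.sequence[a:b] for a, b in exons[target_exon_index + 1 :])

    mut_in_exon = (mut_start - tgt_a) >= truncation  # survives 5' truncation?

    raw: dict[str, str] = {}
    covers: dict[str, bool] = {}
    for allele in ("WT", "MUT", "HDR"):
        ex = target_exon(allele)
        raw[f"full_length|{allele}"] = flank_left + ex + flank_right
        covers[f"full_length|{allele}"] = True
        raw[f"aberrant_acceptor|{allele}"] = flank_left + ex[truncation:] + flank_right
        covers[f"aberrant_acceptor|{allele}"] = mut_in_exon
    raw["exon_skipped|WT"] = flank_left + flank_right
    covers["exon_skipped|WT"] = False

    # merge identical sequences: allele distinctions that truncation/skipping
    # erased collapse to an allele-agnostic label
    references: dict[str, str] = {}
    seen: dict[str, str] = {}
    for label, seq in raw.items():
        isoform, allele = label.split("|")
        if seq in seen:
            continue
        group = [l for l, s in raw.items() if s == seq]
        if len(group) > 1 or not covers[label]:
            label = f"{isoform}|na"
        references[label] = seq
        seen[seq] = label

    return TranscriptModel(
        references=references,
        target_exon_index=target_exon_index,
        truncation=truncation,
        exon_lengths=tuple(b - a for a, b in exons),
    )
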