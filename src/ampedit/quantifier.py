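"""Summary estimators over per-read calls.

Turns the classifier's call table into the reported editing metrics:
cellular-correction estimate (with the x2 MUT-allele normalisation for
allele-specific guides), total/imperfect indel rates, the cut-site indel
spectrum, the per-SNP incorporation profile, HDR-read phasing against a
heterozygous marker, and a false-indel calibration curve over a grid of
simulated error rates.

All reported fractions carry Wilson 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .classifier import CATEGORIES, ClassifyParams, classify_batch
from .locus_model import AlleleSet, LocusSpec, MarkerSnp

SPECTRUM_BINS = ("perfect_rejoin", "ins_1_9", "ins_gt9", "del_1_9", "del_10_50", "del_gt50")


class UndefinedEstimateError(ValueError):
    pass


class UndefinedPhasingError(ValueError):
    pass


@dataclass(frozen=True)
class CategoryCounts:
    counts: dict
    total: int

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("category counts do not sum to total")

    @classmethod
    def from_calls(cls, calls: pd.DataFrame) -> "CategoryCounts":
        vc = calls["category"].value_counts().to_dict()
        counts = {c: int(vc.get(c, 0)) for c in CATEGORIES}
        unknown = set(vc) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories in call table: {sorted(unknown)}")
        return cls(counts=counts, total=int(len(calls)))

    def fraction(self, category: str) -> float:
        if self.total == 0:
            raise UndefinedEstimateError("no reads")
        return self.counts.get(category, 0) / self.total


@dataclass(frozen=True)
class PhasingResult:
    freq_wt_marker_pct: float  # base in cis with the WT allele
    freq_mut_marker_pct: float
    n_wt: int
    n_mut: int
    n_missing_or_other: int
    p_value: float  # two-sided exact binomial test of the 50/50 null


@dataclass
class EditingReport:
    total_reads: int
    category_pct: dict
    hdr_pct_total: float
    cellular_correction_pct: float
    indel_pct: float
    imperfect_hdr_pct: float
    ambiguous_pct: float
    large_del_pct: float
    spectrum: dict
    snp_incorporation: list  # ordered by distance from the cut site
    phasing: Optional[PhasingResult]
    wilson_ci: dict  # metric -> (lo_pct, hi_pct)

    def to_dict(self) -> dict:
        d = {
            "total_reads": self.total_reads,
            "category_pct": self.category_pct,
            "hdr_pct_total": self.hdr_pct_total,
            "cellular_correction_pct": self.cellular_correction_pct,
            "indel_pct": self.indel_pct,
            "imperfect_hdr_pct": self.imperfect_hdr_pct,
            "ambiguous_pct": self.ambiguous_pct,
            "large_del_pct": self.large_del_pct,
            "spectrum": self.spectrum,
            "snp_incorporation": self.snp_incorporation,
            "wilson_ci": {k: list(v) for k, v in self.wilson_ci.items()},
        }
        if self.phasing is not None:
            d["phasing"] = {
                "freq_wt_marker_pct": self.phasing.freq_wt_marker_pct,
                "freq_mut_marker_pct": self.phasing.freq_mut_marker_pct,
                "n_wt": self.phasing.n_wt,
                "n_mut": self.phasing.n_mut,
                "n_missing_or_other": self.phasing.n_missing_or_other,
                "p_value": self.phasing.p_value,
            }
        else:
            d["phasing"] = None
        return d


def wilson_interval(k: int, n: int) -> tuple[float, float]:
    """Wilson score 95% interval, in percent."""
    if n == 0:
        return (0.0, 100.0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return (100.0 * lo, 100.0 * hi)


def estimate_cellular_correction(counts: CategoryCounts, specificity: str) -> float:
    """Cellular-correction percentage from the HDR category fraction.

    For a MUT-allele-specific guide the HDR fraction is normalised to the
    targeted allele (half of all reads): ``2 x HDR% `` capped at 100.  For
    a non-allele-specific guide HDR events distribute over both alleles
    and the estimate equals the HDR percentage of total reads.  Only the
    pure HDR category counts (HDR-edited and ambiguous reads excluded).
    """
    if counts.total == 0:
        raise UndefinedEstimateError("cannot estimate correction from zero reads")
    hdr_frac = counts.fraction("HDR")
    if specificity == "MUT_specific":
        return min(100.0, 200.0 * hdr_frac)
    if specificity == "non_specific":
        return 100.0 * hdr_frac
    raise ValueError(f"unknown guide specificity {specificity!r}")


def _parse_window_indels(cell: str):
    if not cell or cell == ".":
        return []
    out = []
    for item in cell.split(";"):
        pos, size, kind = item.split(":")
        out.append((int(pos), int(size), kind))
    return out


def indel_spectrum(calls: pd.DataFrame) -> dict:
    """Histogram of cut-site indels over the size bins, plus perfect rejoins.

    Each ``*_edited`` read contributes its largest window indel; unedited
    reads are tallied as ``perfect_rejoin`` (indistinguishable from never
    cut) and reported alongside.
    """
    spectrum = {b: 0 for b in SPECTRUM_BINS}
    for _, row in calls.iterrows():
        cat = row["category"]
        if cat.endswith("_unedited"):
            spectrum["perfect_rejoin"] += 1
            continue
        if not cat.endswith("_edited"):
            continue
        indels = _parse_window_indels(row["window_indels"])
        if not indels:
            continue
        pos, size, kind = max(indels, key=lambda t: t[1])
        if kind == "ins":
            spectrum["ins_1_9" if size <= 9 else "ins_gt9"] += 1
        else:
            if size <= 9:
                spectrum["del_1_9"] += 1
            elif size <= 50:
                spectrum["del_10_50"] += 1
            else:
                spectrum["del_gt50"] += 1
    return spectrum


def snp_incorporation_profile(
    calls: pd.DataFrame, alleles: AlleleSet, locus: LocusSpec
) -> list:
    """Per-programmed-SNP template-base percentage over all classified reads.

    Returned ordered by distance from the (nearest) cut site; each entry is
    ``{position, distance, pct, n_template, n_total}``.
    """
    if not alleles.snp_positions:
        raise ValueError("template has no programmed SNPs")
    vectors = [v for v in calls["snp_vector"] if isinstance(v, str) and v not in ("", ".")]
    n_total = len(calls)
    n_snps = len(alleles.snp_positions)
    n_template = np.zeros(n_snps, dtype=int)
    for v in vectors:
        for i, ch in enumerate(v):
            if ch == "t":
                n_template[i] += 1
    cuts = alleles.cut_sites_per_allele["WT"]
    entries = []
    for i, p in enumerate(alleles.snp_positions):
        dist = min((c - p) if p < c else (p - c + 1) for c in cuts)
        pct = 100.0 * n_template[i] / n_total if n_total else 0.0
        entries.append(
            {
                "position": int(p),
                "distance": int(dist),
                "pct": pct,
                "n_template": int(n_template[i]),
                "n_total": int(n_total),
            }
        )
    entries.sort(key=lambda e: (e["distance"], e["position"]))
    return entries


def phase_hdr_reads(calls: pd.DataFrame, marker: MarkerSnp) -> PhasingResult:
    """Marker-allele frequencies among pure-HDR reads, with an exact test.

    Tests the 50/50 null (equal distribution of HDR events over the two
    parental alleles) with a two-sided exact binomial test.
    """
    hdr = calls[calls["category"] == "HDR"]
    wt_base = marker.base_on_wt_allele
    mut_base = marker.base_on_mut_allele
    n_wt = int((hdr["marker_allele"] == wt_base).sum())
    n_mut = int((hdr["marker_allele"] == mut_base).sum())
    n_other = int(len(hdr) - n_wt - n_mut)
    n = n_wt + n_mut
    if n == 0:
        raise UndefinedPhasingError(
            "no HDR-classified reads with a usable marker observation"
        )
    p = stats.binomtest(n_wt, n, 0.5, alternative="two-sided").pvalue
    return PhasingResult(
        freq_wt_marker_pct=100.0 * n_wt / n,
        freq_mut_marker_pct=100.0 * n_mut / n,
        n_wt=n_wt,
        n_mut=n_mut,
        n_missing_or_other=n_other,
        p_value=float(p),
    )


def summarize(
    calls: pd.DataFrame,
    specificity: str = "non_specific",
    alleles: Optional[AlleleSet] = None,
    locus: Optional[LocusSpec] = None,
) -> tuple[CategoryCounts, EditingReport]:
    """Build the full editing report from a call table."""
    if len(calls) == 0:
        raise UndefinedEstimateError("empty call table")
    counts = CategoryCounts.from_calls(calls)
    n = counts.total

    def pct(k):
        return 100.0 * k / n

    edited = sum(counts.counts[c] for c in ("WT_edited", "MUT_edited", "HDR_edited"))
    hdr = counts.counts["HDR"]
    report = EditingReport(
        total_reads=n,
        category_pct={c: pct(k) for c, k in counts.counts.items()},
        hdr_pct_total=pct(hdr),
        cellular_correction_pct=estimate_cellular_correction(counts, specificity),
        indel_pct=pct(edited),
        imperfect_hdr_pct=pct(counts.counts["HDR_edited"]),
        ambiguous_pct=pct(counts.counts["ambiguous"]),
        large_del_pct=pct(counts.counts["large_deletion"]),
        spectrum=indel_spectrum(calls),
        snp_incorporation=[],
        phasing=None,
        wilson_ci={
            "hdr_pct_total": wilson_interval(hdr, n),
            "indel_pct": wilson_interval(edited, n),
            "imperfect_hdr_pct": wilson_interval(counts.counts["HDR_edited"], n),
            "ambiguous_pct": wilson_interval(counts.counts["ambiguous"], n),
            "large_del_pct": wilson_interval(counts.counts["large_deletion"], n),
        },
    )
    if alleles is not None and alleles.snp_positions and locus is not None:
        report.snp_incorporation = snp_incorporation_profile(calls, alleles, locus)
    if locus is not None and locus.marker_snp is not None:
        try:
            report.phasing = phase_hdr_reads(calls, locus.marker_snp)
        except UndefinedPhasingError:
            report.phasing = None
    return counts, report


def allele_frequency_table(calls: pd.DataFrame, min_pct: float = 1.0) -> pd.DataFrame:
    """Per-outcome frequency table down to ``min_pct``.

    Groups edited reads by their primary window indel (signed size), the
    style of a per-allele indel table.
    """
    n = len(calls)
    rows = []
    for (cat, allele), grp in calls.groupby(["category", "best_allele"]):
        if cat.endswith("_edited"):
            keyed = {}
            for _, row in grp.iterrows():
                indels = _parse_window_indels(row["window_indels"])
                if indels:
                    _, size, kind = max(indels, key=lambda t: t[1])
                    key = f"{'+' if kind == 'ins' else '-'}{size}"
                else:
                    key = "complex"
                keyed[key] = keyed.get(key, 0) + 1
            for key, k in keyed.items():
                rows.append((allele, cat, key, k, 100.0 * k / n))
        else:
            rows.append((allele, cat, ".", len(grp), 100.0 * len(grp) / n))
    df = pd.DataFrame(rows, columns=["allele", "category", "indel", "count", "pct"])
    df = df[df["pct"] >= min_pct].sort_values("pct", ascending=False)
    return df.reset_index(drop=True)


def false_indel_calibration(
    locus: LocusSpec,
    alleles: AlleleSet,
    error_grid: Sequence[float],
    n_reads: int = 2000,
    seed: int = 0,
    params: Optional[ClassifyParams] = None,
    error_split: tuple = (0.6, 0.3, 0.1),
) -> pd.DataFrame:
    """False-indel rate of unedited-only mixtures across total error rates.

    Each grid point simulates a 50/50 WT/MUT unedited mixture at the given
    total per-nucleotide error rate (split into substitution / deletion /
    insertion components by ``error_split``), classifies the reads, and
    reports the ``*_edited`` percentage per truth allele, per assigned
    allele, and overall.
    """
    from .synthetic_reads import SimConfig, simulate_gdna_reads

    if not error_grid:
        raise ValueError("empty error grid")
    if params is None:
        params = ClassifyParams()
    ws, wd, wi = error_split
    rows = []
    for rate in error_grid:
        cfg = SimConfig(
            n_reads=n_reads,
            mixture={"WT_unedited": 0.5, "MUT_unedited": 0.5},
            sub_rate=rate * ws,
            del_rate=rate * wd,
            ins_rate=rate * wi,
            seed=seed,
        )
        reads, truth = simulate_gdna_reads(alleles, locus, cfg)
        calls = classify_batch(reads, alleles, locus, params)
        merged = calls.merge(truth[["read_id", "source_allele"]], on="read_id")
        edited = merged["category"].str.endswith("_edited")
        overall = 100.0 * edited.mean()
        row = {"error_rate": rate, "false_indel_pct": overall}
        for allele in ("WT", "MUT"):
            m_truth = merged["source_allele"] == f"{allele}_unedited"
            m_called = merged["best_allele"] == allele
            row[f"false_indel_pct_{allele}_truth"] = (
                100.0 * edited[m_truth].mean() if m_truth.any() else float("nan")
            )
            row[f"false_indel_pct_{allele}_assigned"] = (
                100.0 * edited[m_called].mean() if m_called.any() else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
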