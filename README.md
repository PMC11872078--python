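# ampedit

Editing-outcome analysis for long-read amplicon sequencing of CRISPR-corrected
heterozygous loci, with a matched synthetic read generator for validation.

Given a locus description (amplicon sequence, the pathogenic variant in
HGVS-c style, guide cut sites, an HDR template with programmed silent SNPs,
an optional phasing marker SNP and optional exon structure), the package:

- materialises the **WT / MUT / HDR allele sequences** with exact coordinate
  liftover between allele frames (`ampedit.locus_model`);
- **simulates nanopore-like reads** with known truth: configurable category
  mixtures, ~1 %/nt i.i.d. errors, an NHEJ indel spectrum dominated by a
  +1 T insertion, geometric HDR conversion tracts giving distance-dependent
  SNP incorporation, nickase-style large deletions and cDNA isoform mixtures
  (`ampedit.synthetic_reads`);
- **classifies every read** into `WT_unedited, WT_edited, MUT_unedited,
  MUT_edited, HDR, HDR_edited, ambiguous, large_deletion` by banded global
  affine-gap alignment against the allele set, flags indels in a ±2-nt
  window around the cut site, and reads programmed-SNP and marker columns
  off the winning alignment (`ampedit.classifier`);
- **aggregates calls** into the editing report: cellular-correction estimate
  (×2 MUT-allele normalisation for allele-specific guides, capped at 100 %),
  total/imperfect indel rates, indel-size spectrum (ins/del 1–9, del 10–50,
  del >50), per-SNP incorporation profile ordered by distance from the cut,
  HDR-read phasing with an exact binomial test, and a false-indel calibration
  curve over an error-rate grid; all fractions carry Wilson 95 % intervals
  (`ampedit.quantifier`);
- **quantifies cDNA isoforms** (full-length, target-exon-skipped,
  aberrant-acceptor with a 5′-truncated exon) and precise HDR within
  exon-containing transcripts (`ampedit.splice_quant`);
- provides validated FASTA/FASTQ IO, JSON configs and an end-to-end
  pipeline with provenance tracking (`ampedit.cli_io`, `ampedit.cli`).

## CLI

All commands are subcommands of `ampedit` (see `--help` on each for flags):

```sh
# simulate reads + truth table from a config (locus + sim sections)
ampedit simulate --config sim.json --out-prefix out/run1 [--cdna]

# classify reads against the config-derived allele set
ampedit classify --reads out/run1.fastq --alleles out/run1.alleles.fasta \
    --locus locus.json --window 2 --delta 0 --min-large-del 200 --out calls.tsv

# aggregate calls into the editing report
ampedit quantify --calls calls.tsv --locus locus.json --specificity both \
    --out report.json

# cDNA isoform classification + splice report
ampedit splice --reads cdna.fastq --locus locus.json --truncation 120 \
    --out-prefix out/splice

# end-to-end: simulate -> classify -> quantify (+ provenance JSON)
ampedit run --config pipeline.json --seed 1

# false-indel calibration over an error-rate grid
ampedit calibrate --locus locus.json --rates 0,0.005,0.01,0.02 --out calib.tsv
```

## Locus config schema (JSON)

```jsonc
{
  "amplicon_id": "demo_het_locus",
  "sequence": "ACGT...",            // amplicon, uppercase ACGTN
  "coord_offset": 8583,             // amplicon_pos(0-based) = hgvs_pos - coord_offset
  "cut_sites": [115],               // inter-base (between bases k-1 and k)
  "guide_allele_specificity": "non_specific",   // or "MUT_specific"
  "mutation": "c.8698_8708del",     // the MUT-allele variant
  "hdr_template": {
    "homology_arm_length": 100,
    "programmed_snps": [
      {"hgvs_position": 8683, "wt_base": "C", "template_base": "G",
       "role": "bridging"}          // wt_base optional (read from sequence)
    ]
  },
  "marker_snp": {                   // optional phasing marker
    "hgvs_position": 8780, "wt_base": "G", "mut_base": "A",
    "phase": "cis_to_WT"            // allele carrying mut_base
  },
  "exons": [[0, 50], [50, 247], [247, 307]]   // optional, half-open
}
```

A pipeline config for `ampedit run` is a JSON object with `locus_path`,
`sim` (any `SimConfig` fields: `n_reads`, `mixture`, error rates,
`nhej_spectrum`, `tract_decay`, `large_del_size`, ...), optional `cdna`,
`isoform_mixture` and `truncation`, plus `window`, `delta`,
`min_large_del`, `outdir` and `seed`. Demo loci emulating the studied
locus are available programmatically:
`ampedit.synthetic_reads.demo_locus()` (nuclease mode, 11-bp deletion,
8-SNP template, cis-to-WT marker), `demo_nickase_locus()` (two cuts 65 bp
apart, 350-bp deletions) and `demo_transcript_locus()` (three exons
50/197/60 nt, 120-nt aberrant-acceptor truncation).

## Conventions

- HGVS-c strings are 1-based inclusive; internal coordinates 0-based
  half-open; cut sites are inter-base integers.
- Alignment: global, match +2 / mismatch −4 / gap open −4 / gap extend −2
  (a k-gap costs `open + (k−1)·extend`), both orientations evaluated,
  banded around the diagonal (band widens automatically with sequence
  length difference; `band_margin` = 30 absorbs point-error drift).
- A read is *edited* when an insertion or deletion overlaps the closed
  inter-base window `[cut − w, cut + w]` (default w = 2); substitutions
  never count. Score ties within `delta` (default 0) are *ambiguous*.
- Reads with a single deletion ≥ `min_large_del` (default 200 nt) against
  the WT amplicon are classed `large_deletion` before allele assignment.
- Exchange formats: 4-line FASTQ (gzip ok), FASTA (80-col), TSV with a
  header row and `.` for missing values, JSON reports.

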