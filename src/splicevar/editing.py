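"""A-to-I RNA-editing candidate filtering and intron-retention association.

ADAR editing deaminates adenosine to inosine, read as guanosine by reverse
transcriptase, so editing appears in RNA-seq variant calls as A>G on the
transcribed strand (T>C in genomic coordinates for minus-strand genes).
Candidates are RNA-side calls that (i) are absent from the matched genomic
variant set, (ii) read A>G on their gene's strand, and (iii) pass support
thresholds on median coverage, number of supporting samples, and call
quality.  Editing efficiency is the fraction of non-reference bases; a
site is *exhaustively* edited when that fraction exceeds 0.9.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats


class EditingError(ValueError):
    pass


@dataclass
class EditingThresholds:
    """Support filters; a candidate fails on median coverage < 10,
    supporting samples < 10, or call quality < 100."""

    min_median_coverage: float = 10
    min_supporting_samples: int = 10
    min_quality: float = 100


@dataclass
class EditingCandidate:
    chrom: str
    pos: int
    gene_strand: str
    rna_ref: str  # on the gene strand: always A for retained candidates
    rna_alt: str  # always G
    efficiency: float  # overall fraction of non-reference bases
    median_coverage: float
    supporting_samples: int
    call_quality: float
    sample_alt_fractions: list = None
    in_splice_window: bool = False
    exhaustive: bool = False


def editing_efficiency(ref_count: float, alt_count: float):
    """Fraction of non-reference bases, and the exhaustive flag (>0.9,
    strict)."""
    total = ref_count + alt_count
    if total <= 0:
        raise EditingError("zero total coverage")
    eff = alt_count / total
    return eff, eff > 0.9


def _records_from_vcf(path, ad_tag: str, dp_tag: str):
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            yield rec


def filter_editing_candidates(
    rna_variants,
    genomic_variants,
    genes,
    thresholds: EditingThresholds | None = None,
    sites=None,
    ad_tag: str = "AD",
    dp_tag: str = "DP",
) -> list:
    """Filter RNA-side variant calls down to ADAR-consistent candidates.

    ``rna_variants`` is a VCF path (with per-sample AD/DP-style fields) or
    an iterable of pre-parsed call dicts; ``genomic_variants`` a VCF path
    or a set of (chrom, pos) known genomic polymorphisms; ``genes`` an
    iterable of objects with chrom/strand/span (TranscriptModel works).
    Positions under genes of both strands are ambiguous and dropped with a
    warning.  ``sites`` (optional splice-site records) annotate window
    overlap.
    """
    thresholds = thresholds or EditingThresholds()

    # genomic exclusion set
    if isinstance(genomic_variants, (set, frozenset)):
        genomic_pos = genomic_variants
    else:
        import pysam

        genomic_pos = set()
        with pysam.VariantFile(str(genomic_variants)) as vf:
            for rec in vf:
                genomic_pos.add((rec.chrom, rec.pos))

    # strand lookup per (chrom, interval)
    gene_index: dict = {}
    for g in genes:
        lo, hi = g.span if hasattr(g, "span") else (g["start"], g["end"])
        chrom = g.chrom if hasattr(g, "chrom") else g["chrom"]
        strand = g.strand if hasattr(g, "strand") else g["strand"]
        gene_index.setdefault(chrom, []).append((lo, hi, strand))

    def strands_at(chrom, pos):
        return {s for (lo, hi, s) in gene_index.get(chrom, []) if lo <= pos <= hi}

    # normalize RNA calls into dicts
    calls = []
    if isinstance(rna_variants, (str,)) or hasattr(rna_variants, "__fspath__"):
        import pysam

        with pysam.VariantFile(str(rna_variants)) as vf:
            for rec in vf:
                if not rec.alts or len(rec.alts) != 1:
                    continue
                depths, alt_fracs, refs, alts = [], [], 0, 0
                for s in rec.samples.values():
                    ad = s.get(ad_tag)
                    dp = s.get(dp_tag)
                    if ad is not None and ad[0] is not None:
                        r, a = int(ad[0]), int(ad[1]) if len(ad) > 1 else 0
                        refs += r
                        alts += a
                        tot = r + a
                        if tot > 0:
                            depths.append(tot)
                            alt_fracs.append(a / tot)
                    elif dp is not None:
                        depths.append(int(dp))
                calls.append(
                    {
                        "chrom": rec.chrom,
                        "pos": rec.pos,
                        "ref": rec.ref.upper(),
                        "alt": rec.alts[0].upper(),
                        "qual": rec.qual if rec.qual is not None else 0.0,
                        "ref_count": refs,
                        "alt_count": alts,
                        "depths": depths,
                        "alt_fractions": alt_fracs,
                    }
                )
    else:
        calls = list(rna_variants)

    out = []
    for c in calls:
        chrom, pos = c["chrom"], c["pos"]
        if (chrom, pos) in genomic_pos:
            continue  # genomic polymorphism, not editing
        strands = strands_at(chrom, pos)
        if not strands:
            warnings.warn(f"{chrom}:{pos}: no gene strand available; skipped")
            continue
        if len(strands) > 1:
            warnings.warn(f"{chrom}:{pos}: ambiguous strand (antisense overlap); dropped")
            continue
        strand = strands.pop()
        ref, alt = c["ref"], c["alt"]
        if strand == "+" and (ref, alt) != ("A", "G"):
            continue
        if strand == "-" and (ref, alt) != ("T", "C"):
            continue
        depths = c.get("depths") or []
        alt_positive = sum(1 for f in c.get("alt_fractions", []) if f > 0)
        median_cov = float(np.median(depths)) if depths else 0.0
        if median_cov < thresholds.min_median_coverage:
            continue
        if alt_positive < thresholds.min_supporting_samples:
            continue
        if c.get("qual", 0.0) < thresholds.min_quality:
            continue
        eff, exhaustive = editing_efficiency(c["ref_count"], c["alt_count"])
        in_window = False
        if sites:
            for s in sites:
                lo, hi = s.window_interval or s.compute_window_interval()
                if s.chrom == chrom and lo <= pos <= hi:
                    in_window = True
                    break
        out.append(
            EditingCandidate(
                chrom=chrom,
                pos=pos,
                gene_strand=strand,
                rna_ref="A",
                rna_alt="G",
                efficiency=eff,
                median_coverage=median_cov,
                supporting_samples=alt_positive,
                call_quality=float(c.get("qual", 0.0)),
                sample_alt_fractions=list(c.get("alt_fractions", [])),
                in_splice_window=in_window,
                exhaustive=exhaustive,
            )
        )
    return out


def intron_retention_association(
    exhaustive_coverage: Sequence[float],
    partial_coverage: Sequence[float],
):
    """Two-group Mann–Whitney comparison of normalized intron coverage
    between exhaustively and partially edited disrupted sites.

    Returns ``(statistic, p_value, direction)`` where direction is
    'exhaustive_higher', 'partial_higher', or 'none'.
    """
    a = np.asarray(exhaustive_coverage, dtype=float)
    b = np.asarray(partial_coverage, dtype=float)
    if a.size < 2 or b.size < 2:
        raise EditingError("each group needs >=2 introns")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    med_a, med_b = np.median(a), np.median(b)
    if med_a > med_b:
        direction = "exhaustive_higher"
    elif med_a < med_b:
        direction = "partial_higher"
    else:
        direction = "none"
    return float(stat), float(p), direction


def normalized_intron_coverage(
    intron_read_count: float,
    intron_length: float,
    flanking_exon_coverage: float = 1.0,
) -> float:
    """Default intron coverage normalization: reads per intronic base,
    scaled by the flanking-exon coverage (a pluggable convention)."""
    if intron_length <= 0:
        raise EditingError("intron length must be positive")
    if flanking_exon_coverage <= 0:
        raise EditingError("flanking exon coverage must be positive")
    return (intron_read_count / intron_length) / flanking_exon_coverage
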