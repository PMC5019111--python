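"""Putative cleavage sites (PCSs) from poly-A-tailed reads, and poly-A
signal hexamer scanning.

Cleavage sites of poly-adenylated transcripts are rescued from unmapped
reads carrying a non-templated poly-A tail (or, for reads sequenced from
the opposite strand, a poly-T head).  The tail is trimmed allowing one
internal mismatch, the remainder is kept when longer than 25 nt and below
80% A+T content, and unique anchoring alignments of the trimmed part
pinpoint the last templated base — the PCS.  Sites supported by >=2 reads
form the conservative subset.

The poly-A signal is sought among 13 hexamer motifs ranked by their
frequency in the human transcriptome (AATAAA most frequent, AATAGA least);
a 50 nt window around the PCS is scanned top-down and the first-ranked
motif present is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .annotation_io import reverse_complement

#: CPSF-binding hexamers ranked by transcriptome frequency (rank 1 = most frequent)
POLYA_HEXAMERS = (
    "AATAAA",
    "ATTAAA",
    "TATAAA",
    "AGTAAA",
    "AAGAAA",
    "AATATA",
    "AATACA",
    "CATAAA",
    "GATAAA",
    "AATGAA",
    "TTTAAA",
    "ACTAAA",
    "AATAGA",
)
HEXAMER_RANK = {h: i + 1 for i, h in enumerate(POLYA_HEXAMERS)}

MIN_TAIL = 5
MAX_TAIL_MISMATCHES = 1
MIN_INFORMATIVE_LENGTH = 25  # keep strictly longer
MAX_AT_FRACTION = 0.8  # drop at >=80% A+T
SCAN_WINDOW = 50
CONSERVATIVE_SUPPORT = 2


class PolyAError(ValueError):
    pass


@dataclass
class PolyAReadEvidence:
    read_id: str
    raw_sequence: str
    tail_side: str  # 'A3' (poly-A tail at 3') | 'T5' (poly-T head at 5')
    tail_length: int = 0
    trimmed_sequence: str = ""
    keep: bool = False
    drop_reason: str = None


@dataclass
class PolyAMotifHit:
    hexamer: str
    rank: int
    position: int  # genomic (or window) position of the hexamer start
    distance: int  # |motif start - PCS| in nt


@dataclass
class CleavageSite:
    chrom: str
    strand: str
    position: int  # 1-based genomic position of the last templated base
    read_support: int = 1
    motif_hit: PolyAMotifHit = None

    @property
    def conservative(self) -> bool:
        return self.read_support >= CONSERVATIVE_SUPPORT


@dataclass
class MotifVariantCall:
    ref_hexamer: str
    var_hexamer: str
    status: str  # altered | degraded | unchanged


# ----------------------------------------------------------------------
# read selection and trimming
# ----------------------------------------------------------------------

def select_polya_reads(reads: Iterable) -> list:
    """Keep unmapped reads ending in AAAA (A-tail) or starting with TTTT
    (T-head).  ``reads`` yields (read_id, sequence) pairs."""
    out = []
    for read_id, seq in reads:
        seq = seq.upper()
        if seq.endswith("AAAA"):
            out.append(PolyAReadEvidence(read_id=read_id, raw_sequence=seq, tail_side="A3"))
        elif seq.startswith("TTTT"):
            out.append(PolyAReadEvidence(read_id=read_id, raw_sequence=seq, tail_side="T5"))
    return out


def _trim_terminal_run(seq: str, base: str, max_mismatches: int, min_tail: int):
    """Length of the longest terminal (3') run of ``base`` allowing up to
    ``max_mismatches`` internal non-matching bases.  The run must begin and
    end with ``base`` (a mismatch is never terminal on either side)."""
    n = len(seq)
    if n == 0 or seq[-1] != base:
        return 0
    best = 0
    mismatches = 0
    i = n - 1
    while i >= 0:
        if seq[i] == base:
            best = n - i
        else:
            mismatches += 1
            if mismatches > max_mismatches:
                break
        i -= 1
    return best if best >= min_tail else 0


def trim_tail(
    seq: str,
    tail_side: str = "A3",
    max_mismatches: int = MAX_TAIL_MISMATCHES,
    min_tail: int = MIN_TAIL,
):
    """Trim a poly-A tail (or poly-T head) of at least ``min_tail`` bases,
    tolerating ``max_mismatches`` interruptions inside the run.

    Returns ``(trimmed_sequence, tail_length)``; the read is returned
    untouched (tail length 0) when the terminal run is too short.
    """
    seq = seq.upper()
    if tail_side == "A3":
        run = _trim_terminal_run(seq, "A", max_mismatches, min_tail)
        return (seq[: len(seq) - run], run) if run else (seq, 0)
    if tail_side == "T5":
        run = _trim_terminal_run(seq[::-1], "T", max_mismatches, min_tail)
        return (seq[run:], run) if run else (seq, 0)
    raise PolyAError(f"unknown tail side {tail_side!r}")


def filter_informative(trimmed_seq: str):
    """Keep a trimmed read iff it is longer than 25 nt and its A+T content
    is below 80%.  Returns ``(keep, reason)``."""
    n = len(trimmed_seq)
    if n <= MIN_INFORMATIVE_LENGTH:
        return False, "too_short"
    at = sum(1 for b in trimmed_seq.upper() if b in "AT") / n
    if at >= MAX_AT_FRACTION:
        return False, "low_complexity"
    return True, None


def process_reads(reads: Iterable) -> list:
    """Full read-side pipeline: select, trim, filter.  Returns evidence
    records with ``keep`` set for reads usable for anchoring."""
    out = []
    for ev in select_polya_reads(reads):
        trimmed, tail_len = trim_tail(ev.raw_sequence, ev.tail_side)
        ev.trimmed_sequence = trimmed
        ev.tail_length = tail_len
        if tail_len == 0:
            ev.keep, ev.drop_reason = False, "no_tail"
        else:
            ev.keep, ev.drop_reason = filter_informative(trimmed)
        out.append(ev)
    return out


# ----------------------------------------------------------------------
# PCS calling
# ----------------------------------------------------------------------

@dataclass
class AnchoredRead:
    """A uniquely anchored alignment of a trimmed poly-A read.

    ``strand`` is the strand of the cleaved transcript; the cleavage
    position is the 3'-most templated base in transcript orientation
    (alignment end on plus, alignment start on minus).  T-head reads are
    reverse-complemented before anchoring, so they arrive here as
    minus-strand evidence.
    """

    read_id: str
    chrom: str
    strand: str
    start: int  # 1-based inclusive aligned interval
    end: int
    unique: bool = True


def call_pcs(alignments: Sequence[AnchoredRead], strict: bool = True) -> list:
    """Collapse anchored reads into cleavage sites keyed by exact
    (chrom, strand, position); support = number of reads."""
    sites: dict = {}
    for aln in alignments:
        if not aln.unique:
            if strict:
                raise PolyAError(f"{aln.read_id}: non-unique alignment in strict mode")
            continue
        position = aln.end if aln.strand == "+" else aln.start
        key = (aln.chrom, aln.strand, position)
        sites[key] = sites.get(key, 0) + 1
    return [
        CleavageSite(chrom=c, strand=s, position=p, read_support=n)
        for (c, s, p), n in sorted(sites.items())
    ]


def confirm_pcs(
    set_a: Sequence[CleavageSite],
    set_b: Sequence[CleavageSite],
    window: int = SCAN_WINDOW,
    match_strand: bool = False,
):
    """Flag each site of ``set_a`` confirmed by a ``set_b`` site within
    ±``window`` nt on the same chromosome (strand optionally required).

    Returns ``(flags, fraction)``; distance exactly ``window`` confirms.
    """
    by_chrom: dict = {}
    for s in set_b:
        key = (s.chrom, s.strand) if match_strand else s.chrom
        by_chrom.setdefault(key, []).append(s.position)
    for v in by_chrom.values():
        v.sort()
    flags = []
    for s in set_a:
        key = (s.chrom, s.strand) if match_strand else s.chrom
        positions = by_chrom.get(key, [])
        i = np.searchsorted(positions, s.position)
        confirmed = False
        for j in (i - 1, i):
            if 0 <= j < len(positions) and abs(positions[j] - s.position) <= window:
                confirmed = True
                break
        flags.append(confirmed)
    fraction = sum(flags) / len(flags) if flags else 0.0
    return flags, fraction


# ----------------------------------------------------------------------
# motif scanning
# ----------------------------------------------------------------------

def scan_polya_motif(
    window_seq: str,
    pcs_offset: int | None = None,
    hexamers: Sequence[str] = POLYA_HEXAMERS,
) -> PolyAMotifHit | None:
    """Top-down scan of a sequence window around a PCS for the ranked
    poly-A hexamers.

    The window is supplied on the transcribed strand; ``pcs_offset`` is the
    0-based index of the cleavage base within it (defaults to the window
    centre).  The present hexamer of smallest rank wins; among multiple
    occurrences the one closest to the PCS is recorded, upstream breaking
    ties.  Returns None when no listed hexamer occurs.
    """
    window_seq = window_seq.upper()
    if pcs_offset is None:
        pcs_offset = len(window_seq) // 2
    for rank, hexamer in enumerate(hexamers, 1):
        occurrences = []
        start = window_seq.find(hexamer)
        while start != -1:
            occurrences.append(start)
            start = window_seq.find(hexamer, start + 1)
        if occurrences:
            # closest to the PCS; upstream (smaller index) wins ties
            best = min(occurrences, key=lambda p: (abs(p - pcs_offset), p))
            return PolyAMotifHit(
                hexamer=hexamer,
                rank=rank,
                position=best,
                distance=abs(best - pcs_offset),
            )
    return None


def classify_motif_variant(
    ref_window: str,
    var_window: str,
    motif_position: int,
    hexamers: Sequence[str] = POLYA_HEXAMERS,
) -> MotifVariantCall:
    """Classify a variant overlapping a poly-A motif.

    Both windows are compared at the hexamer starting at
    ``motif_position``; a variant hexamer still in the ranked list is an
    *altered* motif, one outside the list a *degraded* motif.
    """
    ref_window, var_window = ref_window.upper(), var_window.upper()
    if len(ref_window) != len(var_window):
        raise PolyAError("indel inside the motif window; hexamer comparison undefined")
    span = slice(motif_position, motif_position + 6)
    ref_hex, var_hex = ref_window[span], var_window[span]
    if len(ref_hex) != 6:
        raise PolyAError("motif span extends past window end")
    if ref_hex not in hexamers:
        raise PolyAError(f"reference hexamer {ref_hex!r} is not a listed poly-A motif")
    diffs = [i for i in range(len(ref_window)) if ref_window[i] != var_window[i]]
    if diffs and all(not (span.start <= i < span.stop) for i in diffs):
        raise PolyAError("variant lies outside the motif span")
    if ref_hex == var_hex:
        status = "unchanged"
    elif var_hex in hexamers:
        status = "altered"
    else:
        status = "degraded"
    return MotifVariantCall(ref_hexamer=ref_hex, var_hexamer=var_hex, status=status)


def motif_distance_comparison(
    altered_distances: Sequence[float],
    degraded_distances: Sequence[float],
):
    """Mann–Whitney comparison of motif-to-PCS distances between altered
    and degraded motifs.  Returns ``(statistic, p, direction)``."""
    a = np.asarray(altered_distances, dtype=float)
    d = np.asarray(degraded_distances, dtype=float)
    if a.size == 0 or d.size == 0:
        raise PolyAError("both groups must be non-empty")
    stat, p = stats.mannwhitneyu(a, d, alternative="two-sided")
    med_a, med_d = np.median(a), np.median(d)
    if med_d > med_a:
        direction = "degraded_farther"
    elif med_d < med_a:
        direction = "altered_farther"
    else:
        direction = "none"
    return float(stat), float(p), direction


def pcs_to_bed(sites: Sequence[CleavageSite], path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            fh.write(
                f"{s.chrom}\t{s.position - 1}\t{s.position}\t"
                f"PCS:{s.chrom}:{s.position}\t{s.read_support}\t{s.strand}\n"
            )
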