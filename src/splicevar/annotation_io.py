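"""Annotation parsing, intron/splice-site derivation, and window extraction.

Coordinate conventions: GTF input is 1-based inclusive, VCF 1-based, BED
export half-open.  Relative positions around a splice-site boundary skip
zero (…, -2, -1, +1, +2, …): a donor window spans [-2..+7] (9 nt, the last
two exonic bases then the first seven intronic, GT at +1,+2); an acceptor
window spans [-24..+3] (27 nt, the last 24 intronic bases including the
polypyrimidine tract, AG at -2,-1, then the first three exonic bases).

The *boundary* coordinate of a site is the first (donor) or last (acceptor)
intronic base in genomic coordinates of the transcribed strand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: relative-position layout per site kind: (exonic side length, intronic side length)
DONOR_EXONIC, DONOR_INTRONIC = 2, 7
ACCEPTOR_INTRONIC, ACCEPTOR_EXONIC = 24, 3

#: introns shorter than this are flagged: their windows would overlap the
#: opposite splice site and are refused for scoring by default
MIN_SCOREABLE_INTRON = 27

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Malformed transcript structures or coordinates."""


@dataclass
class TranscriptModel:
    """A transcript as an ordered list of genomic exon intervals."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list  # of (start, end) 1-based inclusive, genomic order

    def __post_init__(self):
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: no exons")
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = None
        for s, e in self.exons:
            if s > e:
                raise AnnotationError(f"{self.transcript_id}: inverted exon {s}-{e}")
            if prev_end is not None and s <= prev_end:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
            prev_end = e

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class SpliceSiteRecord:
    """A deduplicated donor or acceptor with its scoring window."""

    chrom: str
    strand: str
    kind: str  # donor | acceptor
    boundary: int  # 1-based genomic coord of first (donor) / last (acceptor) intronic base
    window_interval: tuple = None  # (start, end) 1-based inclusive genomic
    ref_window: str = None  # transcribed-strand sequence, lazily filled
    usage: str = None  # constitutive | alternative
    supporting_transcripts: frozenset = frozenset()
    short_intron: bool = False

    @property
    def site_id(self) -> str:
        return f"{self.chrom}:{self.strand}{self.kind[0].upper()}{self.boundary}"

    @property
    def window_length(self) -> int:
        return 9 if self.kind == "donor" else 27

    def relative_position(self, genomic_pos: int) -> int:
        """Map a genomic coordinate to the site's relative scale (no zero).

        Negative positions are exonic for donors / intronic for acceptors;
        the intron starts at +1 (donor) and ends at -1 (acceptor).
        """
        b = self.boundary
        off = genomic_pos - b if self.strand == "+" else b - genomic_pos
        if self.kind == "donor":
            # off=0 is the first intronic base = +1
            return off + 1 if off >= 0 else off
        # acceptor: off=0 is the last intronic base = -1
        return off if off > 0 else off - 1

    def genomic_position(self, rel: int) -> int:
        """Inverse of :meth:`relative_position`."""
        if rel == 0:
            raise AnnotationError("relative position 0 does not exist")
        if self.kind == "donor":
            off = rel - 1 if rel > 0 else rel
        else:
            off = rel if rel > 0 else rel + 1
        return self.boundary + off if self.strand == "+" else self.boundary - off

    def window_relative_range(self) -> list:
        if self.kind == "donor":
            rels = list(range(-DONOR_EXONIC, 0)) + list(range(1, DONOR_INTRONIC + 1))
        else:
            rels = list(range(-ACCEPTOR_INTRONIC, 0)) + list(range(1, ACCEPTOR_EXONIC + 1))
        return rels

    def compute_window_interval(self) -> tuple:
        positions = [self.genomic_position(r) for r in self.window_relative_range()]
        return (min(positions), max(positions))


@dataclass
class Intron:
    donor: SpliceSiteRecord
    acceptor: SpliceSiteRecord
    length: int
    chrom: str = ""
    strand: str = ""
    start: int = 0  # genomic first intronic base
    end: int = 0  # genomic last intronic base

    @property
    def junction(self) -> tuple:
        return (self.chrom, self.strand, self.start, self.end)


# ----------------------------------------------------------------------
# GTF
# ----------------------------------------------------------------------

def read_gtf(path) -> list:
    """Parse exon features of a Gencode-dialect GTF into TranscriptModels.

    Only ``exon`` lines are used; transcripts are grouped by the
    ``transcript_id`` attribute, genes by ``gene_id``.
    """
    by_tx: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            attrs = {}
            for item in f[8].strip().strip(";").split(";"):
                item = item.strip()
                if not item:
                    continue
                key, _, val = item.partition(" ")
                attrs[key] = val.strip().strip('"')
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id", tid)
            if tid is None:
                continue
            rec = by_tx.setdefault(tid, {"gene_id": gid, "chrom": f[0], "strand": f[6], "exons": []})
            rec["exons"].append((int(f[3]), int(f[4])))
    return [
        TranscriptModel(
            gene_id=rec["gene_id"],
            transcript_id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=rec["exons"],
        )
        for tid, rec in by_tx.items()
    ]


def write_gtf(transcripts: Sequence[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("# splicevar GTF export\n")
        for tx in transcripts:
            for i, (s, e) in enumerate(tx.exons, 1):
                attrs = (
                    f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
                    f'exon_number "{i}";'
                )
                fh.write(
                    f"{tx.chrom}\tsplicevar\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )


# ----------------------------------------------------------------------
# introns and sites
# ----------------------------------------------------------------------

def _transcript_sites(tx: TranscriptModel):
    """Yield (kind, boundary, intron_start, intron_end) per intron of tx."""
    for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
        istart, iend = e1 + 1, s2 - 1
        if istart > iend:
            raise AnnotationError(
                f"{tx.transcript_id}: zero-length intron between exons {e1} and {s2}"
            )
        if tx.strand == "+":
            yield ("donor", istart, istart, iend)
            yield ("acceptor", iend, istart, iend)
        else:
            yield ("donor", iend, istart, iend)
            yield ("acceptor", istart, istart, iend)


def derive_introns(transcripts: Sequence[TranscriptModel]):
    """Derive introns and deduplicated splice sites from transcript models.

    Returns ``(introns, sites)``.  Sites are deduplicated on (chrom,
    strand, kind, boundary).  A site is *constitutive* iff every transcript
    of the same gene whose span covers the boundary uses the site;
    otherwise *alternative*.  Introns shorter than 27 nt flag both their
    sites ``short_intron`` (their windows would overlap the opposite site).
    """
    site_support: dict = {}  # key -> set of transcript ids
    site_genes: dict = {}  # key -> set of gene ids
    short_keys: set = set()
    intron_specs = []  # (key_donor, key_acceptor, chrom, strand, start, end)
    seen_introns = set()

    for tx in transcripts:
        for kind, boundary, istart, iend in _transcript_sites(tx):
            key = (tx.chrom, tx.strand, kind, boundary)
            site_support.setdefault(key, set()).add(tx.transcript_id)
            site_genes.setdefault(key, set()).add(tx.gene_id)
            if iend - istart + 1 < MIN_SCOREABLE_INTRON:
                short_keys.add(key)
        for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
            istart, iend = e1 + 1, s2 - 1
            ikey = (tx.chrom, tx.strand, istart, iend)
            if ikey in seen_introns:
                continue
            seen_introns.add(ikey)
            if tx.strand == "+":
                dkey = (tx.chrom, "+", "donor", istart)
                akey = (tx.chrom, "+", "acceptor", iend)
            else:
                dkey = (tx.chrom, "-", "donor", iend)
                akey = (tx.chrom, "-", "acceptor", istart)
            intron_specs.append((dkey, akey, tx.chrom, tx.strand, istart, iend))

    # constitutive / alternative: check all same-gene transcripts spanning the boundary
    tx_by_gene: dict = {}
    for tx in transcripts:
        tx_by_gene.setdefault(tx.gene_id, []).append(tx)
    used_by: dict = {}  # key -> usage flag
    for key, supporters in site_support.items():
        chrom, strand, kind, boundary = key
        constitutive = True
        for gid in site_genes[key]:
            for tx in tx_by_gene[gid]:
                lo, hi = tx.span
                if not (lo <= boundary <= hi):
                    continue
                if tx.transcript_id not in supporters:
                    constitutive = False
                    break
            if not constitutive:
                break
        used_by[key] = "constitutive" if constitutive else "alternative"

    sites: dict = {}
    for key in site_support:
        chrom, strand, kind, boundary = key
        rec = SpliceSiteRecord(
            chrom=chrom,
            strand=strand,
            kind=kind,
            boundary=boundary,
            usage=used_by[key],
            supporting_transcripts=frozenset(site_support[key]),
            short_intron=key in short_keys,
        )
        rec = SpliceSiteRecord(
            **{**rec.__dict__, "window_interval": rec.compute_window_interval()}
        )
        sites[key] = rec

    introns = [
        Intron(
            donor=sites[dkey],
            acceptor=sites[akey],
            length=iend - istart + 1,
            chrom=chrom,
            strand=strand,
            start=istart,
            end=iend,
        )
        for dkey, akey, chrom, strand, istart, iend in intron_specs
    ]
    return introns, sorted(sites.values(), key=lambda s: (s.chrom, s.boundary, s.kind))


# ----------------------------------------------------------------------
# sequence access
# ----------------------------------------------------------------------

class GenomeSequence:
    """Thin 1-based-inclusive accessor over a FASTA (pyfaidx) or a dict."""

    def __init__(self, source):
        if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: str(v).upper() for k, v in source.items()}

    def contig_length(self, chrom: str) -> int:
        if self._dict is not None:
            if chrom not in self._dict:
                raise AnnotationError(f"unknown contig {chrom!r}")
            return len(self._dict[chrom])
        if chrom not in self._fasta:
            raise AnnotationError(f"unknown contig {chrom!r}")
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """1-based inclusive slice on the plus strand."""
        n = self.contig_length(chrom)
        if start < 1 or end > n:
            raise AnnotationError(
                f"window {chrom}:{start}-{end} outside contig bounds (1-{n})"
            )
        if self._dict is not None:
            return self._dict[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


def extract_window(genome, site: SpliceSiteRecord, allow_short: bool = False) -> str:
    """Transcribed-strand scoring window of a splice site.

    Minus-strand windows are reverse-complemented so that the relative
    layout (donor GT at +1,+2; acceptor AG at -2,-1) reads left to right.
    Sites flagged ``short_intron`` are refused unless ``allow_short``.
    """
    if site.short_intron and not allow_short:
        raise AnnotationError(
            f"{site.site_id}: intron shorter than {MIN_SCOREABLE_INTRON} nt; "
            "window overlaps the opposite splice site (pass allow_short to force)"
        )
    if not isinstance(genome, GenomeSequence):
        genome = GenomeSequence(genome)
    start, end = site.window_interval or site.compute_window_interval()
    seq = genome.fetch(site.chrom, start, end)
    if site.strand == "-":
        seq = reverse_complement(seq)
    return seq


def attach_windows(genome, sites: Iterable[SpliceSiteRecord], allow_short: bool = False):
    """Return new records with ``ref_window`` filled from the genome."""
    genome = genome if isinstance(genome, GenomeSequence) else GenomeSequence(genome)
    out = []
    for s in sites:
        if s.short_intron and not allow_short:
            out.append(s)
            continue
        seq = extract_window(genome, s, allow_short=allow_short)
        out.append(SpliceSiteRecord(**{**s.__dict__, "ref_window": seq}))
    return out


# ----------------------------------------------------------------------
# diversity profile
# ----------------------------------------------------------------------

def site_diversity_profile(
    sites: Sequence[SpliceSiteRecord],
    variants,
    flank: int = 0,
) -> pd.Series:
    """Per-relative-position fraction of sites carrying >=1 variant.

    ``variants`` is an iterable of objects with ``chrom``/``pos`` (or
    (chrom, pos) tuples).  The profile covers each site's window extended
    by ``flank`` positions on both the exonic and intronic side; positions
    are on the no-zero relative scale, mapped strand-aware.  Empty input
    yields an all-zero profile.
    """
    var_pos: dict = {}
    for v in variants:
        chrom, pos = (v.chrom, v.pos) if hasattr(v, "chrom") else (v[0], v[1])
        var_pos.setdefault(chrom, set()).add(int(pos))

    def _extend(rels: list, flank: int) -> list:
        if flank <= 0:
            return rels
        lo, hi = min(rels), max(rels)
        left = [r for r in range(lo - flank, lo)]
        right = [r for r in range(hi + 1, hi + flank + 1)]
        return left + rels + right

    counts: dict = {}
    denominators: dict = {}
    for site in sites:
        hits = var_pos.get(site.chrom, set())
        for rel in _extend(site.window_relative_range(), flank):
            denominators[rel] = denominators.get(rel, 0) + 1
            g = site.genomic_position(rel)
            if g in hits:
                counts[rel] = counts.get(rel, 0) + 1
    if not denominators:
        return pd.Series(dtype=float, name="variant_frequency")
    rels = sorted(denominators)
    freqs = [counts.get(r, 0) / denominators[r] for r in rels]
    return pd.Series(freqs, index=pd.Index(rels, name="relative_position"),
                     name="variant_frequency")


# ----------------------------------------------------------------------
# BED export
# ----------------------------------------------------------------------

def sites_to_bed(sites: Sequence[SpliceSiteRecord], path, windows: bool = False) -> None:
    """BED6 export of site boundaries (or full windows) — half-open coords."""
    with open(path, "w") as fh:
        for s in sites:
            if windows:
                start, end = s.window_interval or s.compute_window_interval()
                fh.write(
                    f"{s.chrom}\t{start - 1}\t{end}\t{s.site_id}\t0\t{s.strand}\n"
                )
            else:
                fh.write(
                    f"{s.chrom}\t{s.boundary - 1}\t{s.boundary}\t{s.site_id}\t0\t{s.strand}\n"
                )
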