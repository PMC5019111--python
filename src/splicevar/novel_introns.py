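"""Putative novel introns (PNIs) from split-read evidence.

A PNI is a split-read-supported exon-exon junction absent from the
reference annotation.  Split mappings are filtered on mapping quality,
edit distance, proper pairing and insert size; junctions identical to
annotated introns are removed; the rest are grouped and annotated with
per-side novelty (is the donor/acceptor boundary an annotated splice
site?), proximity to the nearest annotated exon boundary (novel sides must
lie within 30 nt of one), event category (internal to an annotated
transcript vs extension beyond its extremities) and support counts by
read, individual and population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_io import Intron, SpliceSiteRecord, TranscriptModel

DEFAULT_MAX_BOUNDARY_DISTANCE = 30


class PNIError(ValueError):
    pass


@dataclass
class SplitFilters:
    """Mapping-level filters for split reads.  The mapping-quality scale is
    mapper-dependent; the default of 150 matches the original mapper's
    scale and should be adapted to the aligner in use."""

    min_mapq: int = 150
    max_edit_distance: int = 6
    require_properly_paired: bool = True
    max_insert_size: int = 1_000_000
    max_boundary_distance: int = DEFAULT_MAX_BOUNDARY_DISTANCE


@dataclass
class SplitMapping:
    """One split-read alignment spanning a candidate junction.

    The junction is (first intronic base, last intronic base) in genomic
    coordinates; on the minus strand the donor is the right boundary.
    """

    read_id: str
    sample_id: str
    population_id: str
    chrom: str
    strand: str
    junction: tuple  # (left intronic boundary, right intronic boundary), genomic
    mapq: int = 255
    edit_distance: int = 0
    properly_paired: bool = True
    insert_size: int = 300

    def __post_init__(self):
        lo, hi = self.junction
        if lo >= hi:
            raise PNIError(f"{self.read_id}: malformed junction {self.junction}")


@dataclass
class PNI:
    chrom: str
    strand: str
    junction: tuple  # (genomic start, genomic end) of the intron
    donor_novel: bool
    acceptor_novel: bool
    donor_boundary_distance: int  # to nearest annotated exon boundary
    acceptor_boundary_distance: int
    read_support: int
    individuals: int
    populations: int
    population_labels: frozenset = frozenset()
    category: str = None  # internal | extension-upstream | extension-downstream | intergenic
    pattern: str = None  # novel-combination | one-novel-donor | one-novel-acceptor | two-novel
    canonical: bool = None  # GT..AG when a genome is available

    @property
    def length(self) -> int:
        return self.junction[1] - self.junction[0] + 1

    @property
    def donor_boundary(self) -> int:
        return self.junction[0] if self.strand == "+" else self.junction[1]

    @property
    def acceptor_boundary(self) -> int:
        return self.junction[1] if self.strand == "+" else self.junction[0]


@dataclass
class AnnotationIndex:
    """Lookup structures over an annotation: intron set, splice-site set,
    exon boundaries, transcript spans."""

    introns: set = field(default_factory=set)  # (chrom, strand, start, end)
    sites: set = field(default_factory=set)  # (chrom, strand, kind, boundary)
    exon_boundaries: dict = field(default_factory=dict)  # (chrom, strand) -> sorted array
    transcript_spans: dict = field(default_factory=dict)  # (chrom, strand) -> [(lo, hi)]

    @classmethod
    def build(cls, transcripts: Sequence[TranscriptModel], introns: Sequence[Intron]):
        idx = cls()
        boundaries: dict = {}
        for tx in transcripts:
            key = (tx.chrom, tx.strand)
            idx.transcript_spans.setdefault(key, []).append(tx.span)
            for s, e in tx.exons:
                boundaries.setdefault(key, set()).update((s, e))
        for key, vals in boundaries.items():
            idx.exon_boundaries[key] = np.array(sorted(vals))
        for it in introns:
            idx.introns.add((it.chrom, it.strand, it.start, it.end))
            idx.sites.add((it.chrom, it.strand, "donor", it.donor.boundary))
            idx.sites.add((it.chrom, it.strand, "acceptor", it.acceptor.boundary))
        return idx

    def nearest_exon_boundary_distance(self, chrom: str, strand: str, pos: int) -> int:
        arr = self.exon_boundaries.get((chrom, strand))
        if arr is None or arr.size == 0:
            return np.iinfo(np.int64).max
        i = np.searchsorted(arr, pos)
        best = np.iinfo(np.int64).max
        for j in (i - 1, i):
            if 0 <= j < arr.size:
                best = min(best, abs(int(arr[j]) - pos))
        return int(best)


def rescue_pni(
    split_mappings: Sequence[SplitMapping],
    index: AnnotationIndex,
    filters: SplitFilters | None = None,
    genome=None,
) -> list:
    """Rescue PNIs from filtered split mappings.

    Mappings failing the quality filters contribute no support; junctions
    identical to annotated introns are dropped.  A junction is kept when
    each novel side lies within ``max_boundary_distance`` of an annotated
    exon boundary — for junctions with both sides novel, one side within
    range suffices.  With a genome supplied, GT..AG canonicality is
    flagged (non-canonical PNIs are retained but flagged).
    """
    filters = filters or SplitFilters()
    grouped: dict = {}
    for m in split_mappings:
        if m.mapq < filters.min_mapq:
            continue
        if m.edit_distance > filters.max_edit_distance:
            continue
        if filters.require_properly_paired and not m.properly_paired:
            continue
        if abs(m.insert_size) > filters.max_insert_size:
            continue
        key = (m.chrom, m.strand, m.junction[0], m.junction[1])
        if key in index.introns:
            continue
        g = grouped.setdefault(key, {"reads": 0, "samples": set(), "pops": set()})
        g["reads"] += 1
        g["samples"].add(m.sample_id)
        g["pops"].add(m.population_id)

    out = []
    for (chrom, strand, start, end), g in sorted(grouped.items()):
        donor_b = start if strand == "+" else end
        acceptor_b = end if strand == "+" else start
        donor_novel = (chrom, strand, "donor", donor_b) not in index.sites
        acceptor_novel = (chrom, strand, "acceptor", acceptor_b) not in index.sites
        d_dist = index.nearest_exon_boundary_distance(chrom, strand, donor_b)
        a_dist = index.nearest_exon_boundary_distance(chrom, strand, acceptor_b)
        novel_dists = []
        if donor_novel:
            novel_dists.append(d_dist)
        if acceptor_novel:
            novel_dists.append(a_dist)
        if novel_dists:
            if donor_novel and acceptor_novel:
                if min(novel_dists) > filters.max_boundary_distance:
                    continue
            elif max(novel_dists) > filters.max_boundary_distance:
                continue
        canonical = None
        if genome is not None:
            from .annotation_io import GenomeSequence, reverse_complement

            gs = genome if isinstance(genome, GenomeSequence) else GenomeSequence(genome)
            first2 = gs.fetch(chrom, start, start + 1)
            last2 = gs.fetch(chrom, end - 1, end)
            if strand == "+":
                canonical = first2 == "GT" and last2 == "AG"
            else:
                canonical = (
                    reverse_complement(last2) == "GT"
                    and reverse_complement(first2) == "AG"
                )
        out.append(
            PNI(
                chrom=chrom,
                strand=strand,
                junction=(start, end),
                donor_novel=donor_novel,
                acceptor_novel=acceptor_novel,
                donor_boundary_distance=d_dist,
                acceptor_boundary_distance=a_dist,
                read_support=g["reads"],
                individuals=len(g["samples"]),
                populations=len(g["pops"]),
                population_labels=frozenset(g["pops"]),
                canonical=canonical,
            )
        )
    return out


def classify_pni_event(pni: PNI, index: AnnotationIndex) -> PNI:
    """Assign the event category and site-novelty pattern.

    *internal*: the junction lies fully inside an annotated transcript span
    on the same strand; otherwise an *extension* beyond the transcript
    extremities (upstream of the TSS or downstream of the annotated
    cleavage end, in transcription direction), or *intergenic* when no
    same-chromosome transcript overlaps.
    """
    spans = index.transcript_spans.get((pni.chrom, pni.strand), [])
    start, end = pni.junction
    category = None
    overlapping = [(lo, hi) for lo, hi in spans if lo <= end and hi >= start]
    if any(lo <= start and end <= hi for lo, hi in overlapping):
        category = "internal"
    elif overlapping:
        lo = min(l for l, _ in overlapping)
        hi = max(h for _, h in overlapping)
        if pni.strand == "+":
            category = "extension-upstream" if start < lo else "extension-downstream"
        else:
            category = "extension-upstream" if end > hi else "extension-downstream"
    else:
        # beyond any overlap: nearest transcript decides up/downstream,
        # or intergenic when the chromosome/strand has no transcripts
        if spans:
            if pni.strand == "+":
                upstream = any(start < lo for lo, _ in spans)
            else:
                upstream = any(end > hi for _, hi in spans)
            category = "extension-upstream" if upstream else "extension-downstream"
        else:
            category = "intergenic"

    n_novel = int(pni.donor_novel) + int(pni.acceptor_novel)
    if n_novel == 0:
        pattern = "novel-combination"
    elif n_novel == 2:
        pattern = "two-novel"
    elif pni.donor_novel:
        pattern = "one-novel-donor"
    else:
        pattern = "one-novel-acceptor"
    pni.category = category
    pni.pattern = pattern
    return pni


def support_summary(
    pnis: Sequence[PNI],
    individual_thresholds: Sequence[int] = (150, 300, 450),
    all_populations: set | None = None,
) -> pd.DataFrame:
    """Tabulate PNIs exceeding individual-support thresholds and those
    seen in every population.

    ``all_populations`` defaults to every distinct label present in the
    input.  Counts are monotone non-increasing with the threshold.
    """
    if all_populations is None:
        all_populations = set()
        for p in pnis:
            all_populations |= set(p.population_labels)
    rows = [
        {
            "criterion": "all_populations",
            "count": sum(
                1
                for p in pnis
                if all_populations and set(p.population_labels) >= all_populations
            ),
        }
    ]
    for t in sorted(individual_thresholds):
        rows.append(
            {
                "criterion": f">{t}_individuals",
                "count": sum(1 for p in pnis if p.individuals > t),
            }
        )
    return pd.DataFrame(rows)


def confirm_pni(set_a: Sequence[PNI], set_b: Sequence[PNI]):
    """Exact junction-coordinate confirmation of ``set_a`` by ``set_b``.

    Returns ``(flags, fraction)`` over set_a.
    """
    b_keys = {(p.chrom, p.junction[0], p.junction[1]) for p in set_b}
    flags = [(p.chrom, p.junction[0], p.junction[1]) in b_keys for p in set_a]
    fraction = sum(flags) / len(flags) if flags else 0.0
    return flags, fraction


def pni_sites(pni: PNI) -> tuple:
    """Donor/acceptor SpliceSiteRecords of a PNI, for feeding novel sites
    back through window extraction and variant classification."""
    donor = SpliceSiteRecord(
        chrom=pni.chrom, strand=pni.strand, kind="donor", boundary=pni.donor_boundary
    )
    acceptor = SpliceSiteRecord(
        chrom=pni.chrom, strand=pni.strand, kind="acceptor", boundary=pni.acceptor_boundary
    )
    donor = SpliceSiteRecord(
        **{**donor.__dict__, "window_interval": donor.compute_window_interval(),
           "short_intron": pni.length < 27}
    )
    acceptor = SpliceSiteRecord(
        **{**acceptor.__dict__, "window_interval": acceptor.compute_window_interval(),
           "short_intron": pni.length < 27}
    )
    return donor, acceptor


def read_junction_tsv(path) -> list:
    """Load split mappings from the documented junction TSV (columns:
    read_id, sample_id, population_id, chrom, strand, junction_start,
    junction_end, mapq, edit_distance, properly_paired, insert_size)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        SplitMapping(
            read_id=str(r.read_id),
            sample_id=str(r.sample_id),
            population_id=str(r.population_id),
            chrom=str(r.chrom),
            strand=str(r.strand),
            junction=(int(r.junction_start), int(r.junction_end)),
            mapq=int(r.mapq),
            edit_distance=int(r.edit_distance),
            properly_paired=bool(r.properly_paired),
            insert_size=int(r.insert_size),
        )
        for r in df.itertuples(index=False)
    ]


def read_junctions_sam(path) -> list:
    """Extract junctions from N-CIGAR split alignments in a SAM/BAM file.

    Sample and population labels are taken from the read group (RG tag,
    ``sample.population`` convention) when present.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(str(path)) as af:
        for aln in af:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            ref_pos = aln.reference_start  # 0-based
            rg = aln.get_tag("RG") if aln.has_tag("RG") else "sample.pop"
            sample, _, pop = rg.partition(".")
            nm = aln.get_tag("NM") if aln.has_tag("NM") else 0
            for op, length in aln.cigartuples:
                if op == 3:  # N: skipped region = intron
                    start = ref_pos + 1  # first intronic base, 1-based
                    end = ref_pos + length
                    out.append(
                        SplitMapping(
                            read_id=aln.query_name,
                            sample_id=sample,
                            population_id=pop or "pop0",
                            chrom=aln.reference_name,
                            strand="-" if aln.is_reverse else "+",
                            junction=(start, end),
                            mapq=aln.mapping_quality,
                            edit_distance=int(nm),
                            properly_paired=aln.is_proper_pair,
                            insert_size=abs(aln.template_length) or 300,
                        )
                    )
                if op in (0, 2, 3, 7, 8):  # consume reference
                    ref_pos += length
    return out


def pnis_to_frame(pnis: Sequence[PNI]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "strand": p.strand,
                "start": p.junction[0],
                "end": p.junction[1],
                "length": p.length,
                "donor_novel": p.donor_novel,
                "acceptor_novel": p.acceptor_novel,
                "category": p.category,
                "pattern": p.pattern,
                "reads": p.read_support,
                "individuals": p.individuals,
                "populations": p.populations,
                "canonical": p.canonical,
            }
            for p in pnis
        ]
    )
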