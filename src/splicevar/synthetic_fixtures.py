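"""Deterministic synthetic data with planted ground truth.

Every pipeline stage is testable without external downloads: a small
genome with canonical GT..AG introns is generated whose splice-site
windows are sampled from a known positional model, so that model training,
log-odds scoring, variant classification, PNI/PCS rescue and editing
filters can all be checked against the planted truth.

The generative site model is deliberately simple: per-position base
probabilities with a 0.7-probability consensus base and 0.1 for the
alternatives (the splicing dinucleotides GT/AG are fixed).  Because the
positions are generated independently, a single-base substitution changes
the true log-odds score by exactly ln(p_new/p_old) — ±ln 7 ≈ ±1.95 between
consensus and non-consensus, 0 between two non-consensus bases — which
clears the donor (τ=1.5) and acceptor (τ=1.0) neutral bands with a margin,
or sits well inside them, by construction.  Variants of the five effect
classes are planted accordingly: *disrupting* variants break a fixed
dinucleotide base (an unseen context for any model trained on functional
windows), *activating* variants restore sites that the generated reference
genome carries in broken form, and weakening/neutral/enhancing variants
move between consensus and alternative bases.

All randomness flows from a single integer-seeded ``numpy`` generator held
in the FixtureSpec; identical specs produce identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation_io import (
    GenomeSequence,
    Intron,
    SpliceSiteRecord,
    TranscriptModel,
    derive_introns,
    extract_window,
    reverse_complement,
    write_gtf,
)
from .novel_introns import SplitMapping
from .polya import AnchoredRead
from .site_models import ALPHABET, PositionalMarkovModel
from .variant_effects import SiteVariant

_BASES = np.array(list(ALPHABET))
_IDX = {b: i for i, b in enumerate(ALPHABET)}

#: true per-class DAF distributions: (a, b) Beta parameters
DAF_BETA = {
    "disrupting": (1.0, 5.0),
    "weakening": (1.0, 3.0),
    "neutral": (1.0, 1.0),
    "enhancing": (3.0, 1.5),
    "activating": (4.0, 1.5),
}


def _consensus_probs(consensus: str, peak: float = 0.7) -> np.ndarray:
    if consensus == "=":  # fixed base marker handled by caller
        raise ValueError
    p = np.full(4, (1 - peak) / 3)
    p[_IDX[consensus]] = peak
    return p


def _fixed_probs(base: str) -> np.ndarray:
    p = np.zeros(4)
    p[_IDX[base]] = 1.0
    return p


def donor_true_probs(peak: float = 0.7) -> np.ndarray:
    """9x4 base-probability matrix of the true donor model.

    Layout [-2,-1 | +1..+7]; GT fixed at +1,+2; consensus loosely follows
    the mammalian U1-pairing profile (AG|GTAAGT).
    """
    rows = [
        _consensus_probs("A", peak),  # -2
        _consensus_probs("G", peak),  # -1
        _fixed_probs("G"),  # +1
        _fixed_probs("T"),  # +2
        _consensus_probs("A", peak),  # +3
        _consensus_probs("A", peak),  # +4
        _consensus_probs("G", peak),  # +5
        _consensus_probs("T", peak),  # +6
        _consensus_probs("C", peak),  # +7
    ]
    return np.vstack(rows)


def acceptor_true_probs(peak: float = 0.7) -> np.ndarray:
    """27x4 matrix of the true acceptor model: a pyrimidine-rich tract
    over -24..-5, branch-adjacent C's, the fixed AG, then mild exonic
    consensus ([-24..+3])."""
    rows = []
    tract = "TCTTCTTCCTTCCTTCTCTT"  # -24..-5
    for b in tract:
        rows.append(_consensus_probs(b, peak))
    rows.append(_consensus_probs("C", peak))  # -4
    rows.append(_consensus_probs("C", peak))  # -3
    rows.append(_fixed_probs("A"))  # -2
    rows.append(_fixed_probs("G"))  # -1
    rows.append(_consensus_probs("G", peak))  # +1
    rows.append(_consensus_probs("T", peak))  # +2
    rows.append(_consensus_probs("A", peak))  # +3
    return np.vstack(rows)


def true_markov_model(site_kind: str, order: int = 2, peak: float = 0.7) -> PositionalMarkovModel:
    """The generating model expressed as a positional Markov model.

    Conditionals equal the per-position marginals (generation is
    position-independent); ``seen_contexts`` contains exactly the triples
    reachable under the generator (positive base probability, context
    composed of positive-probability bases).
    """
    probs = donor_true_probs(peak) if site_kind == "donor" else acceptor_true_probs(peak)
    L = probs.shape[0]
    model = PositionalMarkovModel(site_kind=site_kind, window_length=L, order=order)
    for k in range(order + 1):
        for ctx in _all_kmers(k):
            for b in ALPHABET:
                model.background_logprob[(k, ctx, b)] = math.log(0.25)
    for pos in range(L):
        k = min(pos, order)
        ctx_positions = range(pos - k, pos)
        for ctx in _all_kmers(k):
            reachable = all(
                probs[cp, _IDX[cb]] > 0 for cp, cb in zip(ctx_positions, ctx)
            )
            for b in ALPHABET:
                p = probs[pos, _IDX[b]]
                model.site_logprob[(pos, ctx, b)] = (
                    math.log(p) if p > 0 else model.logprob_floor
                )
                if reachable and p > 0:
                    model.seen_contexts.add((pos, ctx, b))
    return model


def _all_kmers(k: int):
    if k == 0:
        return [""]
    out = [""]
    for _ in range(k):
        out = [s + b for s in out for b in ALPHABET]
    return out


def sample_windows(rng: np.random.Generator, probs: np.ndarray, n: int) -> list:
    """Draw n windows from the per-position base-probability matrix."""
    cols = [rng.choice(4, size=n, p=probs[i]) for i in range(probs.shape[0])]
    mat = np.stack(cols, axis=1)
    return ["".join(_BASES[row]) for row in mat]


# ----------------------------------------------------------------------
# spec and fixture containers
# ----------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Study conditions of the synthetic dataset."""

    seed: int = 0
    n_genes: int = 16
    exons_per_gene: int = 4  # 3 introns per gene
    exon_length: tuple = (60, 120)
    intron_length: tuple = (70, 160)
    intergenic: int = 300
    consensus_peak: float = 0.7
    n_training_windows: int = 4000
    n_background: int = 150
    background_length: int = 300
    variants_per_class: dict = field(
        default_factory=lambda: {
            "disrupting": 30,
            "weakening": 30,
            "neutral": 30,
            "enhancing": 30,
            "activating": 16,
        }
    )
    n_vcf_samples: int = 20
    # read-level designs
    n_individuals: int = 100
    psi_depth: int = 100
    psi_slope: float = 0.8
    pni_reads_per_junction: int = 4
    polya_tail_length: int = 12
    polya_anchor_length: int = 30


@dataclass
class Fixture:
    spec: FixtureSpec
    genome: dict
    transcripts: list
    introns: list
    sites: list  # with ref_window attached
    donor_true: PositionalMarkovModel
    acceptor_true: PositionalMarkovModel
    training_windows: dict  # site_kind -> list of windows
    background: list
    broken_sites: dict  # site key -> (rel, broken_base, original_base)
    variants: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)  # variant_id -> intended class

    def genome_accessor(self) -> GenomeSequence:
        return GenomeSequence(self.genome)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.genome.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    def write_gtf(self, path) -> None:
        write_gtf(self.transcripts, path)


# ----------------------------------------------------------------------
# genome + annotation
# ----------------------------------------------------------------------

def _plant_window(contig: list, site: SpliceSiteRecord, window: str) -> None:
    start, end = site.window_interval
    seq = window if site.strand == "+" else reverse_complement(window)
    contig[start - 1 : end] = list(seq)


def generate_genome_and_annotation(spec: FixtureSpec, rng: np.random.Generator | None = None) -> Fixture:
    """Generate the genome, annotation and planted site windows.

    All donors carry GT at +1,+2 and acceptors AG at -2,-1, except for the
    sites designated *broken in the reference* (reserved for activating
    variants), whose dinucleotide is damaged in the written genome.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    donor_probs = donor_true_probs(spec.consensus_peak)
    acceptor_probs = acceptor_true_probs(spec.consensus_peak)

    # gene layout on two contigs, alternating strands
    transcripts = []
    contig_seqs: dict = {}
    n_contigs = 2
    genes_per_contig = (spec.n_genes + n_contigs - 1) // n_contigs
    gi = 0
    for ci in range(n_contigs):
        chrom = f"chr{ci + 1}"
        cursor = spec.intergenic
        exon_list_all = []
        for _ in range(genes_per_contig):
            if gi >= spec.n_genes:
                break
            strand = "+" if gi % 2 == 0 else "-"
            exons = []
            pos = cursor
            for ei in range(spec.exons_per_gene):
                elen = int(rng.integers(*spec.exon_length))
                exons.append((pos, pos + elen - 1))
                pos += elen
                if ei < spec.exons_per_gene - 1:
                    ilen = int(rng.integers(*spec.intron_length))
                    pos += ilen
            transcripts.append(
                TranscriptModel(
                    gene_id=f"G{gi:03d}",
                    transcript_id=f"T{gi:03d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                )
            )
            cursor = pos + spec.intergenic
            gi += 1
        length = cursor + spec.intergenic
        contig_seqs[chrom] = list("".join(rng.choice(_BASES, size=length)))

    introns, sites = derive_introns(transcripts)

    # designate broken (activating-reserve) sites: every k-th site
    n_broken = spec.variants_per_class.get("activating", 0)
    scoreable = [s for s in sites if not s.short_intron]
    step = max(1, len(scoreable) // max(1, n_broken))
    broken_pick = scoreable[::step][:n_broken]
    broken_keys = {(s.chrom, s.strand, s.kind, s.boundary) for s in broken_pick}

    broken_sites: dict = {}
    for site in sites:
        probs = donor_probs if site.kind == "donor" else acceptor_probs
        window = sample_windows(rng, probs, 1)[0]
        key = (site.chrom, site.strand, site.kind, site.boundary)
        if key in broken_keys:
            # damage one fixed dinucleotide base in the written genome
            rel = 1 if site.kind == "donor" else -2
            widx = site.window_relative_range().index(rel)
            original = window[widx]
            alternatives = [b for b in ALPHABET if b != original]
            broken_base = alternatives[int(rng.integers(len(alternatives)))]
            window = window[:widx] + broken_base + window[widx + 1 :]
            broken_sites[key] = (rel, broken_base, original)
        _plant_window(contig_seqs[site.chrom], site, window)

    genome = {c: "".join(seq) for c, seq in contig_seqs.items()}
    from .annotation_io import attach_windows

    sites = attach_windows(genome, sites, allow_short=True)

    training = {
        "donor": sample_windows(rng, donor_probs, spec.n_training_windows),
        "acceptor": sample_windows(rng, acceptor_probs, spec.n_training_windows),
    }
    background = [
        "".join(rng.choice(_BASES, size=spec.background_length))
        for _ in range(spec.n_background)
    ]
    return Fixture(
        spec=spec,
        genome=genome,
        transcripts=transcripts,
        introns=introns,
        sites=sites,
        donor_true=true_markov_model("donor", peak=spec.consensus_peak),
        acceptor_true=true_markov_model("acceptor", peak=spec.consensus_peak),
        training_windows=training,
        background=background,
        broken_sites=broken_sites,
    )


# ----------------------------------------------------------------------
# variants
# ----------------------------------------------------------------------

def _plantable_rels(kind: str) -> list:
    if kind == "donor":
        return [-2, -1, 3, 4, 5, 6, 7]
    return [r for r in list(range(-24, 0)) + [1, 2, 3] if r not in (-2, -1)]


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def generate_variants(spec: FixtureSpec, fixture: Fixture, rng: np.random.Generator | None = None) -> Fixture:
    """Plant SNPs of the five effect classes into site windows.

    The intended class is recorded in ``fixture.truth``; DAFs are drawn
    from per-class Beta distributions and per-sample genotypes from the
    DAF under Hardy-Weinberg.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    donor_probs = donor_true_probs(spec.consensus_peak)
    acceptor_probs = acceptor_true_probs(spec.consensus_peak)
    variants: list = []
    truth: dict = {}
    counter = 0

    def add_variant(site, rel, alt_tx_base, intended):
        nonlocal counter
        gpos = site.genomic_position(rel)
        genome_base = fixture.genome[site.chrom][gpos - 1]
        alt_plus = alt_tx_base if site.strand == "+" else _COMP[alt_tx_base]
        if alt_plus == genome_base:
            return False
        counter += 1
        vid = f"v{counter:04d}_{intended[:3]}"
        daf = float(rng.beta(*DAF_BETA[intended]))
        gts = [
            tuple(int(rng.random() < daf) for _ in range(2))
            for _ in range(spec.n_vcf_samples)
        ]
        variants.append(
            SiteVariant(
                chrom=site.chrom,
                pos=gpos,
                ref=genome_base,
                alt=alt_plus,
                variant_id=vid,
                daf=daf,
                genotypes=gts,
            )
        )
        truth[vid] = intended
        return True

    # activating: restore the broken base of reserved sites
    site_by_key = {(s.chrom, s.strand, s.kind, s.boundary): s for s in fixture.sites}
    for key, (rel, broken_base, original) in fixture.broken_sites.items():
        add_variant(site_by_key[key], rel, original, "activating")

    todo = {k: n for k, n in spec.variants_per_class.items() if k != "activating"}
    broken_keys = set(fixture.broken_sites)
    candidates = [
        s
        for s in fixture.sites
        if not s.short_intron
        and (s.chrom, s.strand, s.kind, s.boundary) not in broken_keys
    ]
    order = ["disrupting", "weakening", "neutral", "enhancing"]
    ci = 0
    for intended in [cls for cls in order for _ in range(todo.get(cls, 0))]:
        planted = False
        attempts = 0
        while not planted and attempts < len(candidates):
            site = candidates[ci % len(candidates)]
            ci += 1
            attempts += 1
            probs = donor_probs if site.kind == "donor" else acceptor_probs
            rels = site.window_relative_range()
            window = site.ref_window
            if intended == "disrupting":
                rel = (1 if rng.random() < 0.5 else 2) if site.kind == "donor" else (-2 if rng.random() < 0.5 else -1)
                widx = rels.index(rel)
                cur = window[widx]
                alts = [b for b in ALPHABET if b != cur]
                planted = add_variant(site, rel, alts[int(rng.integers(3))], intended)
                continue
            plantable = _plantable_rels(site.kind)
            rng.shuffle(plantable)
            for rel in plantable:
                widx = rels.index(rel)
                cur = window[widx]
                p = probs[widx]
                consensus = ALPHABET[int(np.argmax(p))]
                others = [b for b in ALPHABET if p[_IDX[b]] > 0 and b != consensus]
                if intended == "weakening" and cur == consensus:
                    alt = others[int(rng.integers(len(others)))]
                elif intended == "enhancing" and cur != consensus:
                    alt = consensus
                elif intended == "neutral" and cur != consensus:
                    alt = [b for b in others if b != cur][int(rng.integers(2))]
                else:
                    continue
                planted = add_variant(site, rel, alt, intended)
                if planted:
                    break
    fixture.variants = variants
    fixture.truth = truth
    return fixture


def write_vcf(
    variants: Sequence[SiteVariant],
    path,
    genome: dict | None = None,
    with_genotypes: bool = True,
    daf_tag: str = "DAF",
) -> None:
    """Plain-text VCF export of planted variants (INFO DAF, FORMAT GT)."""
    sample_count = 0
    for v in variants:
        if v.genotypes:
            sample_count = max(sample_count, len(v.genotypes))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=splicevar-synthetic\n")
        if genome:
            for name, seq in genome.items():
                fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write(
            f'##INFO=<ID={daf_tag},Number=A,Type=Float,'
            'Description="Derived allele frequency">\n'
        )
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if with_genotypes and sample_count:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            cols += "\tFORMAT\t" + "\t".join(
                f"S{i:03d}" for i in range(sample_count)
            )
        fh.write(cols + "\n")
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            info = f"{daf_tag}={v.daf:.4f}" if v.daf is not None else "."
            line = f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t100\tPASS\t{info}"
            if with_genotypes and sample_count:
                gts = v.genotypes or [(0, 0)] * sample_count
                line += "\tGT\t" + "\t".join(f"{a}|{b}" for a, b in gts)
            fh.write(line + "\n")


# ----------------------------------------------------------------------
# reads: junctions, PSI response, poly-A, editing
# ----------------------------------------------------------------------

def generate_junction_reads(spec: FixtureSpec, fixture: Fixture, rng: np.random.Generator | None = None):
    """Split-read evidence: annotated introns plus planted novel junctions.

    Returns ``(mappings, planted)`` where ``planted`` lists the novel
    junction keys with their intended novelty pattern.  Low-quality decoy
    mappings (failing mapq) are included for the filter tests.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 2)
    populations = ["POP1", "POP2", "POP3"]
    mappings: list = []
    planted: list = []
    rid = 0

    def emit(chrom, strand, junction, n_reads, mapq=200, edit=1, paired=True):
        nonlocal rid
        for _ in range(n_reads):
            rid += 1
            pop = populations[rid % len(populations)]
            mappings.append(
                SplitMapping(
                    read_id=f"r{rid:06d}",
                    sample_id=f"S{rid % 40:03d}",
                    population_id=pop,
                    chrom=chrom,
                    strand=strand,
                    junction=junction,
                    mapq=mapq,
                    edit_distance=edit,
                    properly_paired=paired,
                    insert_size=300,
                )
            )

    # support for annotated introns (must be dropped by rescue)
    for it in fixture.introns[:10]:
        emit(it.chrom, it.strand, (it.start, it.end), 3)

    # planted novel junctions derived from annotated introns
    usable = [it for it in fixture.introns if it.length > 80]
    kinds = ["one-novel-donor", "one-novel-acceptor", "two-novel", "novel-combination", "extension"]
    for i, it in enumerate(usable[:12]):
        kind = kinds[i % len(kinds)]
        start, end = it.start, it.end
        shift = int(rng.integers(5, 28))
        if kind == "one-novel-donor":
            j = (start + shift, end) if it.strand == "+" else (start, end - shift)
        elif kind == "one-novel-acceptor":
            j = (start, end - shift) if it.strand == "+" else (start + shift, end)
        elif kind == "two-novel":
            j = (start + shift, end - shift)
        elif kind == "novel-combination":
            # skip an exon: donor of this intron with acceptor of the next
            nxt = next(
                (
                    o
                    for o in fixture.introns
                    if o.chrom == it.chrom and o.strand == it.strand and o.start > it.end
                ),
                None,
            )
            if nxt is None:
                continue
            j = (start, nxt.end) if it.strand == "+" else (start, nxt.end)
        else:  # extension beyond the transcript extremities (upstream of TSS)
            tx = next(
                t
                for t in fixture.transcripts
                if t.chrom == it.chrom and t.strand == it.strand
                and t.span[0] <= it.start <= t.span[1]
            )
            lo, hi = tx.span
            if it.strand == "+":
                j = (max(2, lo - 120), max(3, lo - 30))
            else:
                j = (hi + 30, hi + 120)
        if j[0] >= j[1]:
            continue
        emit(it.chrom, it.strand, j, spec.pni_reads_per_junction)
        planted.append({"chrom": it.chrom, "strand": it.strand, "junction": j, "kind": kind})

    # decoys: low mapq / high edit distance on a novel-looking junction
    if usable:
        it = usable[-1]
        emit(it.chrom, it.strand, (it.start + 3, it.end - 3), 2, mapq=50)
        emit(it.chrom, it.strand, (it.start + 4, it.end - 4), 2, edit=9)
    return mappings, planted


def write_junction_tsv(mappings: Sequence[SplitMapping], path) -> None:
    rows = [
        {
            "read_id": m.read_id,
            "sample_id": m.sample_id,
            "population_id": m.population_id,
            "chrom": m.chrom,
            "strand": m.strand,
            "junction_start": m.junction[0],
            "junction_end": m.junction[1],
            "mapq": m.mapq,
            "edit_distance": m.edit_distance,
            "properly_paired": m.properly_paired,
            "insert_size": m.insert_size,
        }
        for m in mappings
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def generate_psi_response(spec: FixtureSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Junction counts with a monotone PSI response to accumulated score
    deltas.

    Each individual carries 0..2 alleles at each of two splice-site
    variants of an alternative exon, with per-allele true score deltas of
    ±ln 7; inclusion follows a logistic response of the summed effect.
    Columns: individual, allele_effect, inc1, inc2, exc.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 3)
    delta = math.log(7.0)
    site_deltas = np.array([delta, -delta])
    base_logit = 0.0
    rows = []
    for ind in range(spec.n_individuals):
        alleles = rng.integers(0, 3, size=site_deltas.size)
        effect = float(np.dot(alleles, site_deltas))
        psi_true = 1.0 / (1.0 + math.exp(-(base_logit + spec.psi_slope * effect)))
        inc1 = int(rng.binomial(spec.psi_depth, psi_true))
        inc2 = int(rng.binomial(spec.psi_depth, psi_true))
        exc = int(rng.binomial(spec.psi_depth, 1.0 - psi_true))
        rows.append(
            {
                "individual": f"I{ind:03d}",
                "allele_effect": effect,
                "inc1": inc1,
                "inc2": inc2,
                "exc": exc,
            }
        )
    return pd.DataFrame(rows)


def generate_polya_reads(spec: FixtureSpec, fixture: Fixture, rng: np.random.Generator | None = None):
    """Poly-A-tailed reads at planted cleavage positions.

    Returns ``(raw_reads, anchored, planted)``: FASTQ-style (id, seq)
    pairs, the corresponding unique anchorings of the trimmed parts, and
    the planted PCS records (chrom, strand, position, support,
    motif_hexamer or None).  A poly-A signal hexamer is written ~20 nt
    upstream of most planted sites.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 4)
    from .polya import POLYA_HEXAMERS

    contig_list = {c: list(s) for c, s in fixture.genome.items()}
    planted = []
    raw_reads = []
    anchored = []
    rid = 0
    alen = spec.polya_anchor_length
    for gi, tx in enumerate(fixture.transcripts):
        chrom = tx.chrom
        lo, hi = tx.span
        if tx.strand == "+":
            pcs_pos = hi + 60
        else:
            pcs_pos = max(alen + 2, lo - 60)
        support = 1 + gi % 3  # 1..3 reads
        motif = None
        if gi % 4 != 3:  # three quarters of sites get a signal
            motif = POLYA_HEXAMERS[gi % 3]  # ranks 1..3
            moff = 20  # motif start 20 nt upstream of the PCS (transcribed strand)
            if tx.strand == "+":
                start = pcs_pos - moff
                contig_list[chrom][start - 1 : start + 5] = list(motif)
            else:
                start = pcs_pos + moff
                contig_list[chrom][start - 6 : start] = list(reverse_complement(motif))
        planted.append(
            {
                "chrom": chrom,
                "strand": tx.strand,
                "position": pcs_pos,
                "support": support,
                "motif": motif,
            }
        )

    # scrub chance hexamer occurrences from the scan windows so the planted
    # motif (if any) is the unique listed hexamer around each PCS
    for p in planted:
        chrom, strand, pcs_pos = p["chrom"], p["strand"], p["position"]
        contig = contig_list[chrom]
        lo = max(1, pcs_pos - 56)
        hi = min(len(contig), pcs_pos + 56)
        for _ in range(8):
            window = "".join(contig[lo - 1 : hi])
            if strand == "-":
                window = reverse_complement(window)
            planted_start = None
            if p["motif"] is not None:
                # transcribed-strand offset of the planted motif start
                pcs_off = (pcs_pos - lo) if strand == "+" else (hi - pcs_pos)
                planted_start = pcs_off - 20
            spurious = []
            for hexamer in POLYA_HEXAMERS:
                start = window.find(hexamer)
                while start != -1:
                    if start != planted_start:
                        spurious.append(start)
                    start = window.find(hexamer, start + 1)
            if not spurious:
                break
            t = spurious[0] + 3
            g = (lo + t) if strand == "+" else (hi - t)
            contig[g - 1] = "C" if strand == "+" else "G"

    fixture.genome = {c: "".join(s) for c, s in contig_list.items()}
    gs = fixture.genome_accessor()
    for p in planted:
        chrom, strand, pcs_pos = p["chrom"], p["strand"], p["position"]
        if strand == "+":
            templ = gs.fetch(chrom, pcs_pos - alen + 1, pcs_pos)
            interval = (pcs_pos - alen + 1, pcs_pos)
        else:
            templ = reverse_complement(gs.fetch(chrom, pcs_pos, pcs_pos + alen - 1))
            interval = (pcs_pos, pcs_pos + alen - 1)
        for k in range(p["support"]):
            rid += 1
            tail = "A" * (spec.polya_tail_length + int(rng.integers(0, 6)))
            if k % 2 == 0:
                raw_reads.append((f"p{rid:05d}", templ + tail))
            else:  # opposite-strand sequencing: poly-T head
                raw_reads.append((f"p{rid:05d}", reverse_complement(templ + tail)))
            anchored.append(
                AnchoredRead(
                    read_id=f"p{rid:05d}",
                    chrom=chrom,
                    strand=strand,
                    start=interval[0],
                    end=interval[1],
                )
            )
    # decoy: unmapped read without any tail
    raw_reads.append(("decoy1", "".join(rng.choice(_BASES, size=40))))
    return raw_reads, anchored, planted


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def generate_editing_calls(spec: FixtureSpec, fixture: Fixture, rng: np.random.Generator | None = None):
    """RNA-side variant calls at planted editing positions plus decoys.

    Returns ``(rna_calls, genomic_positions, planted)``; ``rna_calls`` are
    dicts consumable by :func:`splicevar.editing.filter_editing_candidates`.
    Planted true candidates edit the acceptor AG's adenosine (A>G on the
    gene strand); decoys cover each single filter: known genomic position,
    wrong substitution, low median coverage, few supporting samples, low
    quality.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 5)
    planted, calls = [], []
    genomic_positions = {(v.chrom, v.pos) for v in fixture.variants}
    acceptors = [s for s in fixture.sites if s.kind == "acceptor" and not s.short_intron]
    used = set()

    def sample_call(chrom, pos, ref, alt, qual, n_samples, depth, alt_frac):
        depths, fracs = [], []
        refs = alts = 0
        for _ in range(n_samples):
            d = max(2, int(rng.poisson(depth)))
            a = int(rng.binomial(d, alt_frac))
            depths.append(d)
            fracs.append(a / d)
            refs += d - a
            alts += a
        return {
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "qual": qual,
            "ref_count": refs,
            "alt_count": alts,
            "depths": depths,
            "alt_fractions": fracs,
        }

    i = 0
    for site in acceptors:
        if i >= 10:
            break
        gpos = site.genomic_position(-2)  # the A of the acceptor AG
        if (site.chrom, gpos) in genomic_positions:
            continue
        i += 1
        used.add((site.chrom, gpos))
        ref, alt = ("A", "G") if site.strand == "+" else ("T", "C")
        eff = 0.95 if i % 2 == 0 else 0.4  # exhaustive vs partial
        calls.append(sample_call(site.chrom, gpos, ref, alt, 150.0, 15, 25, eff))
        planted.append(
            {
                "chrom": site.chrom,
                "pos": gpos,
                "strand": site.strand,
                "true_efficiency": eff,
                "exhaustive": eff > 0.9,
            }
        )

    # decoys
    donor_sites = [s for s in fixture.sites if s.kind == "donor" and not s.short_intron]
    free_pos = [
        (s, s.genomic_position(4))
        for s in donor_sites
        if (s.chrom, s.genomic_position(4)) not in genomic_positions
    ]
    if len(free_pos) >= 5:
        (s1, p1), (s2, p2), (s3, p3), (s4, p4), (s5, p5) = free_pos[:5]
        ag = lambda s: ("A", "G") if s.strand == "+" else ("T", "C")
        genomic_positions.add((s1.chrom, p1))
        calls.append(sample_call(s1.chrom, p1, *ag(s1), 150.0, 15, 25, 0.5))  # genomic
        wrong = ("C", "T") if s2.strand == "+" else ("G", "A")
        calls.append(sample_call(s2.chrom, p2, *wrong, 150.0, 15, 25, 0.5))  # not A>G
        calls.append(sample_call(s3.chrom, p3, *ag(s3), 150.0, 15, 4, 0.5))  # cov < 10
        calls.append(sample_call(s4.chrom, p4, *ag(s4), 150.0, 5, 25, 0.5))  # <10 samples
        calls.append(sample_call(s5.chrom, p5, *ag(s5), 40.0, 15, 25, 0.5))  # qual < 100
    return calls, genomic_positions, planted


def generate_intron_coverage(
    n_exhaustive: int = 50,
    n_partial: int = 50,
    shift: float = 2.0,
    seed: int = 0,
):
    """Normalized intron-coverage vectors for the retention association:
    exhaustively edited introns get ``shift``-fold higher coverage."""
    rng = np.random.default_rng(seed)
    partial = rng.lognormal(mean=0.0, sigma=0.5, size=n_partial)
    exhaustive = rng.lognormal(mean=math.log(shift), sigma=0.5, size=n_exhaustive)
    return exhaustive, partial


def build_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Genome + annotation + planted variants in one call."""
    spec = spec or FixtureSpec()
    fixture = generate_genome_and_annotation(spec)
    return generate_variants(spec, fixture)
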