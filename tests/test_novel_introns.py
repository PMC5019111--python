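"""PNI rescue, event typing, support tabulation, confirmation."""

import numpy as np
import pytest

from splicevar.annotation_io import TranscriptModel, derive_introns
from splicevar.novel_introns import (
    PNI,
    AnnotationIndex,
    PNIError,
    SplitFilters,
    SplitMapping,
    classify_pni_event,
    confirm_pni,
    pni_sites,
    rescue_pni,
    support_summary,
)


@pytest.fixture()
def annotation():
    txs = [
        TranscriptModel(
            gene_id="G1", transcript_id="T1", chrom="chr1", strand="+",
            exons=[(101, 200), (301, 400), (501, 600)],
        )
    ]
    introns, _ = derive_introns(txs)
    return txs, introns, AnnotationIndex.build(txs, introns)


def mapping(junction, chrom="chr1", strand="+", mapq=200, edit=1, paired=True,
            insert=300, sample="S1", pop="P1", rid="r1"):
    return SplitMapping(
        read_id=rid, sample_id=sample, population_id=pop, chrom=chrom,
        strand=strand, junction=junction, mapq=mapq, edit_distance=edit,
        properly_paired=paired, insert_size=insert,
    )


class TestRescue:
    def test_annotated_junction_not_a_pni(self, annotation):
        _, _, index = annotation
        out = rescue_pni([mapping((201, 300))], index)
        assert out == []

    def test_novel_donor_near_annotated_boundary(self, annotation):
        _, _, index = annotation
        # donor shifted 10nt into the intron; acceptor annotated
        out = rescue_pni([mapping((211, 300))], index)
        assert len(out) == 1
        pni = out[0]
        assert pni.donor_novel and not pni.acceptor_novel
        assert pni.donor_boundary_distance == 11  # nearest exon boundary is 200
        assert pni.read_support == 1

    def test_low_mapq_excluded(self, annotation):
        _, _, index = annotation
        assert rescue_pni([mapping((211, 300), mapq=149)], index) == []
        assert len(rescue_pni([mapping((211, 300), mapq=150)], index)) == 1

    def test_edit_distance_pairing_insert_filters(self, annotation):
        _, _, index = annotation
        assert rescue_pni([mapping((211, 300), edit=7)], index) == []
        assert rescue_pni([mapping((211, 300), paired=False)], index) == []
        assert rescue_pni([mapping((211, 300), insert=2_000_000)], index) == []

    def test_proximity_boundary_30(self, annotation):
        _, _, index = annotation
        # novel donor 230: distance to exon boundary 200 is 30 -> kept
        assert len(rescue_pni([mapping((230, 300))], index)) == 1
        # distance 31 -> dropped
        assert rescue_pni([mapping((231, 300))], index) == []

    def test_two_novel_kept_if_either_side_within_30(self, annotation):
        _, _, index = annotation
        out = rescue_pni([mapping((211, 290))], index)
        assert len(out) == 1 and out[0].donor_novel and out[0].acceptor_novel
        # both sides far from any boundary -> dropped
        assert rescue_pni([mapping((240, 260))], index) == []

    def test_malformed_junction_rejected(self):
        with pytest.raises(PNIError):
            mapping((300, 201))

    def test_support_grouping(self, annotation):
        _, _, index = annotation
        maps = [
            mapping((211, 300), rid=f"r{i}", sample=f"S{i % 3}", pop=f"P{i % 2}")
            for i in range(6)
        ]
        out = rescue_pni(maps, index)
        assert out[0].read_support == 6
        assert out[0].individuals == 3
        assert out[0].populations == 2

    def test_no_pni_equals_annotated_intron(self, spec, fixture):
        from splicevar import synthetic_fixtures as sf

        maps, _ = sf.generate_junction_reads(spec, fixture)
        index = AnnotationIndex.build(fixture.transcripts, fixture.introns)
        for p in rescue_pni(maps, index):
            assert (p.chrom, p.strand, *p.junction) not in index.introns


class TestEventTyping:
    def test_novel_combination_internal(self, annotation):
        _, _, index = annotation
        # annotated donor 201 with annotated acceptor 500 (exon skip)
        out = rescue_pni([mapping((201, 500))], index)
        pni = classify_pni_event(out[0], index)
        assert pni.pattern == "novel-combination"
        assert pni.category == "internal"

    def test_extension_upstream_of_tss(self, annotation):
        _, _, index = annotation
        out = rescue_pni([mapping((20, 80))], index)
        pni = classify_pni_event(out[0], index)
        assert pni.category == "extension-upstream"

    def test_two_novel_internal(self, annotation):
        _, _, index = annotation
        out = rescue_pni([mapping((211, 290))], index)
        pni = classify_pni_event(out[0], index)
        assert pni.pattern == "two-novel"
        assert pni.category == "internal"

    def test_intergenic_when_no_transcript(self, annotation):
        _, _, index = annotation
        pni = PNI(
            chrom="chr9", strand="+", junction=(100, 200), donor_novel=True,
            acceptor_novel=True, donor_boundary_distance=5,
            acceptor_boundary_distance=5, read_support=1, individuals=1,
            populations=1,
        )
        assert classify_pni_event(pni, index).category == "intergenic"

    def test_planted_patterns_recovered(self, spec, fixture):
        from splicevar import synthetic_fixtures as sf

        maps, planted = sf.generate_junction_reads(spec, fixture)
        index = AnnotationIndex.build(fixture.transcripts, fixture.introns)
        rescued = {
            (p.chrom, p.strand, p.junction): classify_pni_event(p, index)
            for p in rescue_pni(maps, index)
        }
        recovered = 0
        for truth in planted:
            key = (truth["chrom"], truth["strand"], tuple(truth["junction"]))
            assert key in rescued
            pni = rescued[key]
            if truth["kind"] == "extension":
                assert pni.category.startswith("extension")
            else:
                assert pni.pattern == truth["kind"]
            recovered += 1
        assert recovered == len(planted) > 0


def _pni(individuals, pops=("P1",)):
    return PNI(
        chrom="chr1", strand="+", junction=(100, 200), donor_novel=True,
        acceptor_novel=False, donor_boundary_distance=5,
        acceptor_boundary_distance=0, read_support=individuals,
        individuals=individuals, populations=len(pops),
        population_labels=frozenset(pops),
    )


class TestSupportSummary:
    def test_hand_counted_thresholds(self):
        pnis = [_pni(n) for n in (10, 200, 400, 460)]
        df = support_summary(pnis).set_index("criterion")["count"]
        assert df[">150_individuals"] == 3
        assert df[">300_individuals"] == 2
        assert df[">450_individuals"] == 1

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(17)
        pnis = [_pni(int(n)) for n in rng.integers(1, 600, 50)]
        df = support_summary(pnis)
        counts = df[df.criterion.str.contains("individuals")]["count"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_all_populations_requires_every_label(self):
        pnis = [_pni(5, pops=("P1", "P2")), _pni(5, pops=("P1",))]
        df = support_summary(pnis).set_index("criterion")["count"]
        assert df["all_populations"] == 1

    def test_empty_input_zero_table(self):
        df = support_summary([])
        assert (df["count"] == 0).all()


class TestConfirm:
    def test_identical_sets_full_confirmation(self):
        pnis = [_pni(5)]
        assert confirm_pni(pnis, pnis) == ([True], 1.0)

    def test_disjoint_sets_zero(self):
        a = [_pni(5)]
        b = [
            PNI(chrom="chr1", strand="+", junction=(150, 250), donor_novel=True,
                acceptor_novel=True, donor_boundary_distance=1,
                acceptor_boundary_distance=1, read_support=1, individuals=1,
                populations=1)
        ]
        assert confirm_pni(a, b) == ([False], 0.0)

    def test_one_of_four_shared(self):
        def at(start):
            return PNI(chrom="chr1", strand="+", junction=(start, start + 100),
                       donor_novel=True, acceptor_novel=False,
                       donor_boundary_distance=1, acceptor_boundary_distance=0,
                       read_support=1, individuals=1, populations=1)

        a = [at(s) for s in (100, 300, 500, 700)]
        b = [at(500)]
        flags, fraction = confirm_pni(a, b)
        assert fraction == pytest.approx(0.25)
        assert flags == [False, False, True, False]


class TestNovelSiteFeedback:
    def test_pni_sites_scored_like_annotated_sites(self, spec, fixture, trained_models):
        """Novel GT/AG splice sites from PNIs flow through window extraction
        and variant classification identically to annotated sites."""
        from splicevar import synthetic_fixtures as sf
        from splicevar.annotation_io import extract_window
        from splicevar.variant_effects import SiteVariant, classify_variant

        maps, planted = sf.generate_junction_reads(spec, fixture)
        index = AnnotationIndex.build(fixture.transcripts, fixture.introns)
        pnis = rescue_pni(maps, index, genome=fixture.genome_accessor())
        assert pnis
        scored = 0
        for pni in pnis[:5]:
            donor, acceptor = pni_sites(pni)
            for site, model in ((donor, trained_models["donor"]),
                                (acceptor, trained_models["acceptor"])):
                if site.short_intron:
                    continue
                w = extract_window(fixture.genome, site)
                assert len(w) == site.window_length
                gpos = site.genomic_position(3 if site.kind == "donor" else -5)
                base = fixture.genome[site.chrom][gpos - 1]
                alt = "A" if base != "A" else "G"
                v = SiteVariant(chrom=site.chrom, pos=gpos, ref=base, alt=alt)
                c = classify_variant(model, site, v, fixture.genome)
                assert c.effect_class in {
                    "disrupting", "weakening", "neutral", "enhancing",
                    "activating", "neutral-nonfunctional",
                }
                scored += 1
        assert scored > 0
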