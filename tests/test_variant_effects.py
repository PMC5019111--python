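"""Window mutation, five-class calls, calibration, PSI and summaries."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from splicevar.annotation_io import SpliceSiteRecord, TranscriptModel, derive_introns
from splicevar.site_models import PositionalMarkovModel
from splicevar.variant_effects import (
    ClassThresholds,
    SiteVariant,
    VariantError,
    apply_variants_to_window,
    calibrate_threshold,
    classify_variant,
    compute_psi,
    summarize_class_daf,
    summarize_variant_burden,
    variants_in_window,
)


@pytest.fixture()
def donor_site():
    tx = TranscriptModel(
        gene_id="G1", transcript_id="T1", chrom="chr1", strand="+",
        exons=[(101, 200), (301, 400)],
    )
    _, sites = derive_introns([tx])
    return next(s for s in sites if s.kind == "donor")  # boundary 201


@pytest.fixture()
def genome_seq():
    rng = np.random.default_rng(11)
    return {"chr1": "".join(rng.choice(list("ACGT"), size=500))}


class TestApplyVariants:
    def test_single_snp_changes_one_position(self, donor_site, genome_seq):
        ref = genome_seq["chr1"][198:208]  # covers window [199, 207]
        pos = 200  # relative -1
        ref_base = genome_seq["chr1"][pos - 1]
        alt = "A" if ref_base != "A" else "C"
        v = SiteVariant(chrom="chr1", pos=pos, ref=ref_base, alt=alt)
        out = apply_variants_to_window(genome_seq, donor_site, [v])
        window_ref = genome_seq["chr1"][198:207]
        diffs = [i for i in range(9) if out.sequence[i] != window_ref[i]]
        assert diffs == [1]  # relative -1 is window index 1

    def test_two_snps_order_independent(self, donor_site, genome_seq):
        g = genome_seq["chr1"]
        v1 = SiteVariant(chrom="chr1", pos=203, ref=g[202], alt="A" if g[202] != "A" else "G")
        v2 = SiteVariant(chrom="chr1", pos=206, ref=g[205], alt="C" if g[205] != "C" else "T")
        a = apply_variants_to_window(genome_seq, donor_site, [v1, v2])
        b = apply_variants_to_window(genome_seq, donor_site, [v2, v1])
        assert a.sequence == b.sequence
        ref_window = g[198:207]
        assert sum(x != y for x, y in zip(a.sequence, ref_window)) == 2

    def test_deletion_draws_next_intronic_base(self, donor_site, genome_seq):
        """1-nt deletion at donor +5: window re-extracted to length 9, the
        last base drawn from the following intronic base."""
        g = genome_seq["chr1"]
        # deletion of base at 205 (relative +5): VCF style REF=bases 204-205
        v = SiteVariant(chrom="chr1", pos=204, ref=g[203:205], alt=g[203])
        out = apply_variants_to_window(genome_seq, donor_site, [v])
        expected = g[198:204] + g[205:208]  # skip deleted base, extend one base
        assert out.sequence == expected
        assert len(out.sequence) == 9

    def test_deletion_of_boundary_base_is_boundary_loss(self, donor_site, genome_seq):
        g = genome_seq["chr1"]
        v = SiteVariant(chrom="chr1", pos=200, ref=g[199:202], alt=g[199])
        out = apply_variants_to_window(genome_seq, donor_site, [v])
        assert out.boundary_loss and not out.scorable

    def test_reference_mismatch_raises(self, donor_site, genome_seq):
        wrong = "A" if genome_seq["chr1"][200] != "A" else "C"
        v = SiteVariant(chrom="chr1", pos=201, ref=wrong, alt="G")
        with pytest.raises(VariantError):
            apply_variants_to_window(genome_seq, donor_site, [v])

    def test_insertion_keeps_window_length(self, donor_site, genome_seq):
        g = genome_seq["chr1"]
        v = SiteVariant(chrom="chr1", pos=203, ref=g[202], alt=g[202] + "TT")
        out = apply_variants_to_window(genome_seq, donor_site, [v])
        assert len(out.sequence) == 9
        assert out.sequence[:5] == g[198:202] + g[202]
        assert out.sequence[5:7] == "TT"


def _delta_model(site_probs):
    """Donor model with context-independent hand-set probabilities so class
    boundaries can be engineered exactly."""
    m = PositionalMarkovModel(site_kind="donor", window_length=9, order=0)
    for pos in range(9):
        for b, p in site_probs[pos].items():
            key = (pos, "", b)
            m.site_logprob[key] = math.log(p) if p > 0 else m.logprob_floor
            if p > 0:
                m.seen_contexts.add(key)
        for b in "ACGT":
            m.background_logprob[(0, "", b)] = math.log(0.25)
    return m


class TestClassifyVariant:
    # window GTGTAAGTC planted at [199, 207]; probability design gives
    # exact deltas: A<->G at a 2:1 position = ln 2 ~ 0.69, at e2:1 = 2.0 etc.
    GENOME = {"chr1": "A" * 198 + "GTGTAAGTC" + "C" * 300}

    def _model(self):
        probs = []
        for pos, base in enumerate("GTGTAAGTC"):
            if pos == 4:  # A vs C: ratio e^2 -> delta exactly 2.0
                p = {"A": 0.5, "C": 0.5 * math.exp(-2.0), "G": 0.0, "T": 0.0}
                p["G"] = 1 - p["A"] - p["C"]
            elif pos == 5:  # A vs G: ratio e^1.4 -> delta exactly 1.4
                p = {"A": 0.5, "G": 0.5 * math.exp(-1.4), "C": 0.0, "T": 0.0}
                p["C"] = 1 - p["A"] - p["G"]
            else:
                p = {b: (0.7 if b == base else 0.1) for b in "ACGT"}
            probs.append(p)
        return _delta_model(probs)

    def _site(self):
        tx = TranscriptModel(
            gene_id="G1", transcript_id="T1", chrom="chr1", strand="+",
            exons=[(101, 200), (301, 400)],
        )
        _, sites = derive_introns([tx])
        return next(s for s in sites if s.kind == "donor")

    def test_enhancing_above_donor_tau(self):
        # C->A at window pos 4 (genomic 203): delta exactly +2.0 > 1.5
        genome = {"chr1": self.GENOME["chr1"][:202] + "C" + self.GENOME["chr1"][203:]}
        v = SiteVariant(chrom="chr1", pos=203, ref="C", alt="A")
        c = classify_variant(self._model(), self._site(), v, genome)
        assert c.delta_hmm == pytest.approx(2.0, abs=1e-9)
        assert c.effect_class == "enhancing"

    def test_neutral_inside_donor_tau(self):
        # G->A at window pos 5 (genomic 204): delta exactly +1.4 < 1.5
        genome = {"chr1": self.GENOME["chr1"][:203] + "G" + self.GENOME["chr1"][204:]}
        v = SiteVariant(chrom="chr1", pos=204, ref="G", alt="A")
        c = classify_variant(self._model(), self._site(), v, genome)
        assert c.delta_hmm == pytest.approx(1.4, abs=1e-9)
        assert c.effect_class == "neutral"

    def test_acceptor_tau_would_call_weakening(self):
        # same |delta| = 1.4 is beyond the acceptor tau of 1.0
        genome = {"chr1": self.GENOME["chr1"][:203] + "G" + self.GENOME["chr1"][204:]}
        v = SiteVariant(chrom="chr1", pos=204, ref="G", alt="A")
        thr = ClassThresholds()
        assert thr.tau("acceptor") == 1.0
        c = classify_variant(
            self._model(), self._site(), v.swapped(), genome_or_var(genome, v)
        )
        assert c.delta_hmm == pytest.approx(-1.4, abs=1e-9)
        # donor tau keeps it neutral; with the acceptor tau it would weaken
        assert abs(c.delta_hmm) > thr.tau("acceptor")

    def test_disrupting_and_activating_duality(self):
        model = self._model()
        site = self._site()
        # T at window position 4 has probability zero: absent from training
        v = SiteVariant(chrom="chr1", pos=203, ref="A", alt="T")
        c = classify_variant(model, site, v, self.GENOME)
        assert c.effect_class == "disrupting"
        # swapped view: genome carries the dead base, variant restores A
        genome2 = {"chr1": self.GENOME["chr1"][:202] + "T" + self.GENOME["chr1"][203:]}
        c2 = classify_variant(model, site, v.swapped(), genome2)
        assert c2.effect_class == "activating"

    def test_both_nonfunctional_reported_distinctly(self):
        model = self._model()
        site = self._site()
        # dead base at position 4 in both ref and var windows
        genome2 = {"chr1": self.GENOME["chr1"][:202] + "T" + self.GENOME["chr1"][203:]}
        v = SiteVariant(chrom="chr1", pos=199, ref="G", alt="C")
        c = classify_variant(model, site, v, genome2)
        assert c.effect_class == "neutral-nonfunctional"

    def test_boundary_loss_indel_reported_disrupting_with_flag(self):
        g = self.GENOME["chr1"]
        v = SiteVariant(chrom="chr1", pos=200, ref=g[199:202], alt=g[199])
        c = classify_variant(self._model(), self._site(), v, self.GENOME)
        assert c.effect_class == "disrupting" and c.boundary_loss


def genome_or_var(genome, v):
    """Genome with the variant's ALT substituted (SNP only)."""
    s = genome["chr1"]
    return {"chr1": s[: v.pos - 1] + v.alt + s[v.pos :]}


class TestVariantsInWindow:
    def test_overlap_by_span(self, donor_site):
        inside = SiteVariant(chrom="chr1", pos=203, ref="A", alt="G")
        outside = SiteVariant(chrom="chr1", pos=250, ref="A", alt="G")
        spanning = SiteVariant(chrom="chr1", pos=197, ref="AAAA", alt="A")
        hits = variants_in_window([inside, outside, spanning], donor_site)
        assert hits == [inside, spanning]


class TestCalibration:
    def test_scaled_deltas_peak_at_k_times_band(self):
        """With Markov deltas an exact multiple k of the PWM deltas, the
        chi-square peaks at tau = k * band (grid resolution 0.05)."""
        rng = np.random.default_rng(5)
        k = 0.2
        band = 6.0
        dp = rng.uniform(-12, 12, size=4000)
        dh = k * dp
        grid = np.round(np.arange(0.05, 2.51, 0.05), 10)
        cells, best = calibrate_threshold(dh, dp, tau_grid=grid, pwm_band=band)
        assert best == pytest.approx(k * band, abs=0.051)

    def test_independent_labels_have_small_residuals(self):
        rng = np.random.default_rng(6)
        dh = rng.normal(0, 3, size=10_000)
        dp = rng.normal(0, 9, size=10_000)
        cells, _ = calibrate_threshold(dh, dp, tau_grid=[1.5], pwm_band=6.0)
        diag = np.diag(cells[0].residuals.to_numpy())
        assert np.all(np.abs(diag) < 3)

    def test_concordant_pairs_positive_diagonal(self):
        rng = np.random.default_rng(7)
        dp = rng.uniform(-12, 12, size=3000)
        dh = 0.25 * dp  # perfectly concordant at tau = 1.5
        cells, _ = calibrate_threshold(dh, dp, tau_grid=[1.5], pwm_band=6.0)
        assert np.all(np.diag(cells[0].residuals.to_numpy()) > 0)

    def test_single_class_pwm_rejected(self):
        with pytest.raises(VariantError):
            calibrate_threshold([1.0, 2.0], [0.1, 0.2])

    def test_reproducible_argmax(self):
        rng = np.random.default_rng(8)
        dp = rng.uniform(-12, 12, size=1000)
        dh = 0.3 * dp + rng.normal(0, 0.5, size=1000)
        _, t1 = calibrate_threshold(dh, dp)
        _, t2 = calibrate_threshold(dh, dp)
        assert t1 == t2


class TestPsi:
    def test_balanced_counts_half(self):
        assert compute_psi(30, 30) == pytest.approx(0.5)

    def test_zero_exclusion_full_inclusion(self):
        assert compute_psi((12, 8), 0) == pytest.approx(1.0)

    def test_flank_averaging_rule(self):
        # mean inclusion (20+10)/2 = 15; PSI = 15/(15+15)
        assert compute_psi((20, 10), 15) == pytest.approx(0.5)

    def test_low_coverage_undefined(self):
        assert compute_psi((2, 2), 3) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(VariantError):
            compute_psi((5, -1), 3)


class TestDafSummary:
    def _cls(self, effect, daf):
        from splicevar.variant_effects import VariantClassification

        return VariantClassification(
            site_id="s", variant_id="v", delta_hmm=0.0, effect_class=effect, daf=daf
        )

    def test_identical_samples_ks_zero(self):
        rng = np.random.default_rng(9)
        dafs = rng.uniform(0, 1, 100)
        cls = [self._cls("neutral", d) for d in dafs] + [
            self._cls("weakening", d) for d in dafs
        ]
        df = summarize_class_daf(cls)
        row = df[df.effect_class == "weakening"].iloc[0]
        assert row.ks_stat_vs_neutral == pytest.approx(0.0)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(10)
        cls = [self._cls("neutral", d) for d in rng.uniform(0, 1, 500)]
        cls += [self._cls("disrupting", d) for d in rng.uniform(0, 0.3, 500)]
        df = summarize_class_daf(cls)
        row = df[df.effect_class == "disrupting"].iloc[0]
        assert row.ks_p_vs_neutral < 1e-6

    def test_sparse_class_skipped_with_warning(self):
        cls = [self._cls("neutral", 0.5), self._cls("neutral", 0.6),
               self._cls("disrupting", 0.1)]
        with pytest.warns(UserWarning, match="disrupting"):
            df = summarize_class_daf(cls)
        assert "disrupting" not in set(df.effect_class)


class TestBurden:
    def test_zero_variants_zero_table(self, donor_site):
        out = summarize_variant_burden([donor_site], [])
        assert out["n_polymorphic_sites"] == 0
        assert len(out["sites_with_k_variants"]) == 0

    def test_site_with_seven_variants_counted_once(self, donor_site):
        vs = [
            SiteVariant(chrom="chr1", pos=199 + i, ref="A", alt="G")
            for i in range(7)
        ]
        out = summarize_variant_burden([donor_site], vs)
        assert out["sites_with_k_variants"].loc[7] == 1
        assert out["n_polymorphic_sites"] == 1

    def test_planted_indel_fractions_recovered(self, donor_site):
        inside = [
            SiteVariant(chrom="chr1", pos=200 + (i % 7), ref="A", alt="G")
            for i in range(19)
        ] + [SiteVariant(chrom="chr1", pos=203, ref="AG", alt="A")]
        outside = [
            SiteVariant(chrom="chr1", pos=450 + i, ref="A", alt="G") for i in range(18)
        ] + [
            SiteVariant(chrom="chr1", pos=470 + i, ref="AT", alt="A") for i in range(2)
        ]
        out = summarize_variant_burden([donor_site], inside + outside)
        assert out["indel_fraction_in_windows"] == pytest.approx(0.05)
        assert out["indel_fraction_overall"] == pytest.approx(3 / 40)
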