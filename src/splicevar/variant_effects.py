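"""Variant intersection, window mutation, five-class effect calls, and
threshold calibration.

A variant hitting a splice-site window is scored by comparing the log-odds
splicing score of the reference window (RS) with the variant window (VS);
Δ = VS − RS.  Together with the functionality flags of both windows this
yields five effect classes:

====================  =============================================
class                 condition
====================  =============================================
disrupting            RS functional, VS not
activating            RS not functional, VS functional
enhancing             both functional, Δ > +τ
weakening             both functional, Δ < −τ
neutral               both functional, |Δ| ≤ τ
neutral-nonfunctional both windows non-functional (reported apart)
====================  =============================================

τ defaults to 1.5 for donors and 1.0 for acceptors, the thresholds at
which agreement with an independent PWM classification (neutral band ±6)
peaks; :func:`calibrate_threshold` recomputes that calibration on any
paired set of Markov/PWM score differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import (
    AnnotationError,
    GenomeSequence,
    SpliceSiteRecord,
    reverse_complement,
)
from .site_models import PositionalMarkovModel, Pwm, SpliceScore

EFFECT_CLASSES = (
    "disrupting",
    "weakening",
    "neutral",
    "enhancing",
    "activating",
    "neutral-nonfunctional",
)


class VariantError(ValueError):
    """Reference mismatch or unusable variant/window combination."""


@dataclass
class SiteVariant:
    """A genomic variant (VCF semantics: 1-based pos, REF/ALT strings)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."
    daf: float = None  # derived allele frequency of the non-reference allele
    genotypes: list = None  # per-sample (a0, a1) allele indices, optional

    def __post_init__(self):
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.ref or not self.alt:
            raise VariantError(f"{self.variant_id}: empty allele")
        if self.daf is not None and not (0.0 <= self.daf <= 1.0):
            raise VariantError(f"{self.variant_id}: DAF {self.daf} outside [0,1]")

    @property
    def type(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNP"
        if len(self.ref) > len(self.alt):
            return "deletion"
        if len(self.ref) < len(self.alt):
            return "insertion"
        return "MNP"

    @property
    def end(self) -> int:
        """Last reference base covered (1-based inclusive)."""
        return self.pos + len(self.ref) - 1

    def swapped(self) -> "SiteVariant":
        """Alleles exchanged (variant genome -> reference genome view)."""
        return SiteVariant(
            chrom=self.chrom,
            pos=self.pos,
            ref=self.alt,
            alt=self.ref,
            variant_id=self.variant_id,
            daf=None if self.daf is None else 1.0 - self.daf,
        )


@dataclass
class ClassThresholds:
    """Neutral-band thresholds for the five-class decision."""

    tau_donor: float = 1.5
    tau_acceptor: float = 1.0
    pwm_band: float = 6.0

    def __post_init__(self):
        if min(self.tau_donor, self.tau_acceptor, self.pwm_band) <= 0:
            raise VariantError("thresholds must be positive")

    def tau(self, site_kind: str) -> float:
        return self.tau_donor if site_kind == "donor" else self.tau_acceptor


@dataclass
class VariantClassification:
    site_id: str
    variant_id: str
    delta_hmm: float
    delta_pwm: float = None
    ref_functional: bool = None
    var_functional: bool = None
    effect_class: str = None
    boundary_loss: bool = False
    daf: float = None
    site_kind: str = None


# ----------------------------------------------------------------------
# VCF input
# ----------------------------------------------------------------------

def read_vcf(path, daf_tag: str = "DAF", with_genotypes: bool = False) -> list:
    """Load variants from a VCF via pysam; one SiteVariant per ALT allele.

    The derived allele frequency is taken from INFO tag ``daf_tag`` when
    present (AF-style lists are split per allele).
    """
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            dafs = rec.info.get(daf_tag) if daf_tag in rec.info else None
            if dafs is not None and not isinstance(dafs, (tuple, list)):
                dafs = (dafs,)
            for ai, alt in enumerate(rec.alts or ()):
                gts = None
                if with_genotypes and rec.samples:
                    gts = [tuple(s["GT"]) for s in rec.samples.values()]
                out.append(
                    SiteVariant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        variant_id=rec.id or f"{rec.chrom}:{rec.pos}",
                        daf=float(dafs[ai]) if dafs is not None and ai < len(dafs) else None,
                        genotypes=gts,
                    )
                )
    return out


def variants_in_window(
    variants: Iterable[SiteVariant], site: SpliceSiteRecord
) -> list:
    """Variants whose reference span overlaps the site's scoring window."""
    start, end = site.window_interval or site.compute_window_interval()
    return [
        v
        for v in variants
        if v.chrom == site.chrom and v.pos <= end and v.end >= start
    ]


# ----------------------------------------------------------------------
# window mutation
# ----------------------------------------------------------------------

@dataclass
class MutatedWindow:
    sequence: str  # transcribed-strand window, None when unscorable
    boundary_loss: bool = False

    @property
    def scorable(self) -> bool:
        return self.sequence is not None and not self.boundary_loss


def apply_variants_to_window(
    genome,
    site: SpliceSiteRecord,
    variants: Sequence[SiteVariant],
    allele_selector: Callable[[SiteVariant], str] | None = None,
) -> MutatedWindow:
    """Apply variants jointly to the genomic sequence and re-extract the
    fixed-length window anchored at the intron boundary.

    SNPs substitute in place; indels shift the sequence so the window is
    re-extracted to its fixed length from the mutated contig.  A deletion
    removing the anchoring boundary base makes the window unscorable
    (``boundary_loss``).  ``allele_selector`` maps a variant to the applied
    allele string (default: its ALT); returning the REF skips the variant,
    which supports haplotype-resolved application.
    """
    if not isinstance(genome, GenomeSequence):
        genome = GenomeSequence(genome)
    ws, we = site.window_interval or site.compute_window_interval()
    b = site.boundary
    pad = 10 + sum(len(v.ref) for v in variants)
    slab_start = max(1, ws - pad)
    slab_end = min(genome.contig_length(site.chrom), we + pad)
    slab = genome.fetch(site.chrom, slab_start, slab_end)

    applied = []
    for v in sorted(variants, key=lambda v: v.pos):
        allele = v.alt if allele_selector is None else allele_selector(v)
        if allele is None or allele == v.ref:
            continue
        off = v.pos - slab_start
        if off < 0 or off + len(v.ref) > len(slab):
            raise VariantError(f"{v.variant_id}: outside padded window slab")
        if slab[off : off + len(v.ref)] != v.ref:
            raise VariantError(
                f"{v.variant_id}: REF {v.ref!r} does not match genome "
                f"{slab[off:off + len(v.ref)]!r} at {v.chrom}:{v.pos}"
            )
        applied.append((v, allele))

    # boundary-loss check: boundary base removed by a deletion
    b_off = b - slab_start
    for v, allele in applied:
        if len(v.ref) > 1 and v.pos < b <= v.end:
            # bases pos+1..end are replaced; boundary survives only if the
            # replacement still covers its offset within the ref span
            if (b - v.pos) >= len(allele):
                return MutatedWindow(sequence=None, boundary_loss=True)

    # apply right-to-left so earlier offsets stay valid
    seq = slab
    for v, allele in sorted(applied, key=lambda t: -t[0].pos):
        off = v.pos - slab_start
        seq = seq[:off] + allele + seq[off + len(v.ref) :]

    # shift of the boundary offset from upstream length changes
    shift = 0
    for v, allele in applied:
        if v.end < b:
            shift += len(allele) - len(v.ref)
        elif v.pos < b <= v.end:
            # boundary inside the replaced span and retained
            shift += (b - v.pos) - (b - v.pos)  # position within allele == within ref
    new_b = b_off + shift

    lo = new_b + (ws - b)
    hi = new_b + (we - b)
    if lo < 0 or hi >= len(seq):
        return MutatedWindow(sequence=None, boundary_loss=False)
    window = seq[lo : hi + 1]
    if site.strand == "-":
        window = reverse_complement(window)
    return MutatedWindow(sequence=window)


def haplotype_selector(hap_index: int, sample_index: int) -> Callable:
    """Allele selector applying a sample's phased allele on one haplotype."""

    def _select(v: SiteVariant):
        if not v.genotypes:
            return v.ref
        gt = v.genotypes[sample_index]
        allele_idx = gt[hap_index] if hap_index < len(gt) else None
        return v.alt if allele_idx == 1 else v.ref

    return _select


# ----------------------------------------------------------------------
# classification
# ----------------------------------------------------------------------

def _decide(
    ref_score: SpliceScore, var_score: SpliceScore, tau: float
) -> str:
    if ref_score.functional and not var_score.functional:
        return "disrupting"
    if not ref_score.functional and var_score.functional:
        return "activating"
    if ref_score.functional and var_score.functional:
        delta = var_score.value - ref_score.value
        if delta > tau:
            return "enhancing"
        if delta < -tau:
            return "weakening"
        return "neutral"
    return "neutral-nonfunctional"


def classify_variant(
    model: PositionalMarkovModel,
    site: SpliceSiteRecord,
    variants,
    genome,
    pwm: Pwm | None = None,
    thresholds: ClassThresholds | None = None,
    allele_selector: Callable | None = None,
    ref_window: str | None = None,
) -> VariantClassification:
    """Five-class effect call for one or more variants applied to a site.

    ``variants`` may be a single SiteVariant or a list applied jointly.
    Boundary-loss indels are reported as disrupting with a distinct flag.
    """
    if thresholds is None:
        thresholds = ClassThresholds()
    if isinstance(variants, SiteVariant):
        variants = [variants]
    if ref_window is None:
        ref_window = site.ref_window
    if ref_window is None:
        from .annotation_io import extract_window

        ref_window = extract_window(genome, site)

    mutated = apply_variants_to_window(genome, site, variants, allele_selector)
    vid = ";".join(v.variant_id for v in variants)
    daf = variants[0].daf if len(variants) == 1 else None
    if not mutated.scorable:
        return VariantClassification(
            site_id=site.site_id,
            variant_id=vid,
            delta_hmm=float("nan"),
            ref_functional=model.score(ref_window).functional,
            var_functional=False,
            effect_class="disrupting",
            boundary_loss=True,
            daf=daf,
            site_kind=site.kind,
        )
    ref_score = model.score(ref_window)
    var_score = model.score(mutated.sequence)
    effect = _decide(ref_score, var_score, thresholds.tau(site.kind))
    delta_pwm = None
    if pwm is not None:
        delta_pwm = pwm.score_delta(ref_window, mutated.sequence)
    return VariantClassification(
        site_id=site.site_id,
        variant_id=vid,
        delta_hmm=var_score.value - ref_score.value,
        delta_pwm=delta_pwm,
        ref_functional=ref_score.functional,
        var_functional=var_score.functional,
        effect_class=effect,
        daf=daf,
        site_kind=site.kind,
    )


def classify_all(
    model: PositionalMarkovModel,
    sites: Sequence[SpliceSiteRecord],
    variants: Sequence[SiteVariant],
    genome,
    pwm: Pwm | None = None,
    thresholds: ClassThresholds | None = None,
) -> list:
    """Per-variant classification (each variant applied alone) over all
    (site, overlapping variant) pairs; skips short-intron sites."""
    out = []
    genome = genome if isinstance(genome, GenomeSequence) else GenomeSequence(genome)
    for site in sites:
        if site.short_intron:
            continue
        if site.kind == "donor" and model.site_kind != "donor":
            continue
        if site.kind == "acceptor" and model.site_kind != "acceptor":
            continue
        for v in variants_in_window(variants, site):
            out.append(
                classify_variant(
                    model, site, v, genome, pwm=pwm, thresholds=thresholds
                )
            )
    return out


def classifications_to_frame(classifications: Sequence[VariantClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "site_kind": c.site_kind,
                "variant_id": c.variant_id,
                "delta_hmm": c.delta_hmm,
                "delta_pwm": c.delta_pwm,
                "ref_functional": c.ref_functional,
                "var_functional": c.var_functional,
                "boundary_loss": c.boundary_loss,
                "effect_class": c.effect_class,
                "daf": c.daf,
            }
            for c in classifications
        ]
    )


# ----------------------------------------------------------------------
# calibration against the PWM classes
# ----------------------------------------------------------------------

_TRI = ("weakening", "neutral", "enhancing")


def _tri_class(deltas: np.ndarray, band: float) -> np.ndarray:
    out = np.full(len(deltas), "neutral", dtype=object)
    out[deltas < -band] = "weakening"
    out[deltas > band] = "enhancing"
    return out


@dataclass
class CalibrationCell:
    tau: float
    site_kind: str
    contingency: pd.DataFrame  # 3x3, Markov class (rows) x PWM class (cols)
    residuals: pd.DataFrame  # standardized (adjusted) residuals
    chisq_stat: float


def calibrate_threshold(
    delta_hmm: Sequence[float],
    delta_pwm: Sequence[float],
    site_kind: str = "donor",
    tau_grid: Sequence[float] | None = None,
    pwm_band: float = 6.0,
):
    """Sweep the Markov neutral threshold τ and cross-tabulate against the
    fixed PWM three-class call (band ±``pwm_band``).

    For each τ the 3×3 contingency of weakening/neutral/enhancing calls is
    built, the chi-square statistic computed, and agreement reported as
    standardized residuals (observed − expected over its standard
    deviation).  Returns ``(cells, best_tau)`` with ties broken toward the
    smallest τ.
    """
    dh = np.asarray(delta_hmm, dtype=float)
    dp = np.asarray(delta_pwm, dtype=float)
    if dh.shape != dp.shape or dh.size == 0:
        raise VariantError("paired non-empty delta arrays required")
    if tau_grid is None:
        tau_grid = np.round(np.arange(0.1, 2.51, 0.1), 10)
    pwm_classes = _tri_class(dp, pwm_band)
    if len(set(pwm_classes)) < 2:
        raise VariantError("degenerate PWM classification: single class")

    cells = []
    best = None
    for tau in tau_grid:
        hmm_classes = _tri_class(dh, float(tau))
        table = pd.crosstab(
            pd.Categorical(hmm_classes, categories=_TRI),
            pd.Categorical(pwm_classes, categories=_TRI),
            dropna=False,
        )
        table.index.name, table.columns.name = "markov", "pwm"
        obs = table.to_numpy(dtype=float)
        n = obs.sum()
        rows = obs.sum(axis=1)
        cols = obs.sum(axis=0)
        nz_r, nz_c = rows > 0, cols > 0
        if nz_r.sum() >= 2 and nz_c.sum() >= 2:
            chi2 = stats.chi2_contingency(obs[np.ix_(nz_r, nz_c)], correction=False)[0]
        else:
            chi2 = 0.0
        expected = np.outer(rows, cols) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            var = expected * np.outer(1 - rows / n, 1 - cols / n)
            resid = np.where(var > 0, (obs - expected) / np.sqrt(var), 0.0)
        cells.append(
            CalibrationCell(
                tau=float(tau),
                site_kind=site_kind,
                contingency=table,
                residuals=pd.DataFrame(resid, index=table.index, columns=table.columns),
                chisq_stat=float(chi2),
            )
        )
        if best is None or cells[-1].chisq_stat > best.chisq_stat + 1e-12:
            best = cells[-1]
    return cells, best.tau


# ----------------------------------------------------------------------
# PSI and summaries
# ----------------------------------------------------------------------

def compute_psi(
    inclusion_junction_reads,
    exclusion_junction_reads: float,
    min_coverage: float = 10,
) -> float | None:
    """Percent-spliced-in of an alternative exon.

    The inclusion count is the mean of the two flanking inclusion-junction
    counts (a scalar is taken as that mean); PSI = ī/(ī + e).  Returns
    None (undefined) when ī + e falls below ``min_coverage``.
    """
    if np.isscalar(inclusion_junction_reads):
        counts = [float(inclusion_junction_reads)]
    else:
        counts = [float(c) for c in inclusion_junction_reads]
    exc = float(exclusion_junction_reads)
    if any(c < 0 for c in counts) or exc < 0:
        raise VariantError("negative junction counts")
    inc = float(np.mean(counts))
    total = inc + exc
    if total < min_coverage:
        return None
    return inc / total


def summarize_class_daf(
    classifications: Sequence[VariantClassification],
    bins: int = 10,
    reference_class: str = "neutral",
) -> pd.DataFrame:
    """Per-class DAF histogram and KS test of each class vs neutral.

    Classes with fewer than 2 DAF observations are skipped with a warning.
    """
    by_class: dict = {}
    for c in classifications:
        if c.daf is not None:
            by_class.setdefault(c.effect_class, []).append(c.daf)
    ref = np.asarray(by_class.get(reference_class, []), dtype=float)
    edges = np.linspace(0, 1, bins + 1)
    rows = []
    for cls, dafs in sorted(by_class.items()):
        arr = np.asarray(dafs, dtype=float)
        if arr.size < 2:
            warnings.warn(f"class {cls!r} has <2 DAF observations; skipped")
            continue
        hist, _ = np.histogram(arr, bins=edges)
        if cls == reference_class or ref.size < 2:
            ks_stat, ks_p = (0.0, 1.0) if cls == reference_class else (np.nan, np.nan)
        else:
            ks_stat, ks_p = stats.ks_2samp(arr, ref)
        rows.append(
            {
                "effect_class": cls,
                "n": int(arr.size),
                "median_daf": float(np.median(arr)),
                "histogram": hist.tolist(),
                "ks_stat_vs_neutral": float(ks_stat),
                "ks_p_vs_neutral": float(ks_p),
            }
        )
    return pd.DataFrame(rows)


def summarize_variant_burden(
    sites: Sequence[SpliceSiteRecord],
    variants: Sequence[SiteVariant],
) -> dict:
    """Sites by number of overlapping variants, and indel fraction inside
    windows vs among all variants (Fisher exact on the 2×2)."""
    per_site = []
    in_window_ids = set()
    for site in sites:
        hits = variants_in_window(variants, site)
        if hits:
            per_site.append(len(hits))
            in_window_ids.update(id(v) for v in hits)
    burden = pd.Series(per_site, dtype=int).value_counts().sort_index()
    burden.index.name = "n_variants"

    inside = [v for v in variants if id(v) in in_window_ids]
    n_in = len(inside)
    n_all = len(variants)
    indel_in = sum(1 for v in inside if v.type in ("insertion", "deletion"))
    indel_all = sum(1 for v in variants if v.type in ("insertion", "deletion"))
    if n_in > 0 and n_all > n_in:
        outside_indel = indel_all - indel_in
        table = [[indel_in, n_in - indel_in], [outside_indel, (n_all - n_in) - outside_indel]]
        _, pvalue = stats.fisher_exact(table)
    else:
        pvalue = float("nan")
    return {
        "sites_with_k_variants": burden,
        "n_polymorphic_sites": int(len(per_site)),
        "indel_fraction_in_windows": indel_in / n_in if n_in else 0.0,
        "indel_fraction_overall": indel_all / n_all if n_all else 0.0,
        "indel_repression_p": float(pvalue),
    }


# ----------------------------------------------------------------------
# TSV output (the tool's classification table)
# ----------------------------------------------------------------------

def write_classification_tsv(
    classifications: Sequence[VariantClassification],
    path,
    thresholds: ClassThresholds | None = None,
) -> None:
    from . import __version__

    thresholds = thresholds or ClassThresholds()
    df = classifications_to_frame(classifications)
    with open(path, "w") as fh:
        fh.write(
            f"# splicevar {__version__} classification\t"
            f"tau_donor={thresholds.tau_donor}\ttau_acceptor={thresholds.tau_acceptor}\t"
            f"pwm_band={thresholds.pwm_band}\n"
        )
        df.to_csv(fh, sep="\t", index=False)
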