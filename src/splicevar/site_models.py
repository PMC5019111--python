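"""Trainable splice-site sequence models and log-odds scoring.

Two complementary models of splice-site sequence composition are provided:

* :class:`PositionalMarkovModel` — an inhomogeneous Markov chain (default
  order 2) over the fixed-length site window.  Each window position carries
  conditional probabilities of the observed base given its preceding
  context, for site sequences and for a position-independent background.
  The log-odds "splicing score" of a window is the summed log ratio of
  site to background probabilities.  The model additionally remembers which
  (position, context, base) triples were actually observed in the site
  training data: a window that uses a combination never seen among real
  sites is deemed *non-functional*, the basis of the disrupting/activating
  variant classes.

* :class:`Pwm` — an ordinary position weight matrix (order-0 log-odds
  against a fixed background composition), used as the independent scoring
  scheme against which the Markov-score classification is calibrated.

Windows are 9 nt for donors (relative positions -2..-1, +1..+7 around the
exon|intron boundary, GT at +1,+2) and 27 nt for acceptors (-24..+3,
AG at -2,-1).  Scores are natural-log units by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_BASE_SET = frozenset(ALPHABET)

#: window length per site kind: donor [-2;+7] = 9 nt, acceptor [-24;+3] = 27 nt
WINDOW_LENGTHS = {"donor": 9, "acceptor": 27}

#: default order of the positional Markov chain
DEFAULT_ORDER = 2

#: log-probability floor used when a (context, base) combination has zero
#: probability under an unsmoothed table; keeps scores finite
DEFAULT_LOGPROB_FLOOR = math.log(1e-12)


class SpliceModelError(ValueError):
    """Invalid training data, window, or model parameters."""


def _validate_window(window: str, length: int, strict: bool = True) -> str:
    window = window.upper()
    if len(window) != length:
        raise SpliceModelError(
            f"window length {len(window)} != model window length {length}"
        )
    if strict and not _BASE_SET.issuperset(window):
        bad = sorted(set(window) - _BASE_SET)
        raise SpliceModelError(f"non-ACGT symbol(s) {bad} in window {window!r}")
    return window


@dataclass
class SpliceScore:
    """A log-odds splicing score with a functionality flag.

    ``functional`` is False iff at least one scored (position, context,
    base) triple never occurred in the site training set — such a window
    is assumed not to represent a functional splice site.
    """

    value: float
    functional: bool
    scorable: bool = True

    def __float__(self) -> float:  # pragma: no cover - convenience
        return self.value


@dataclass
class PositionalMarkovModel:
    """Inhomogeneous order-k Markov model of site vs background composition.

    ``site_logprob`` and ``background_logprob`` map ``(position, context,
    base)`` to natural-log conditional probabilities.  Positions with index
    smaller than the order condition on correspondingly shorter contexts
    (order-0 at position 0, order-1 at position 1, ...).  The background is
    position-independent: the same context tables are shared by every
    position (keyed with position -1 internally, looked up per context
    length).  ``seen_contexts`` holds the raw (pre-pseudocount) site
    observations used for the functionality call.
    """

    site_kind: str
    window_length: int
    order: int = DEFAULT_ORDER
    pseudocount: float = 0.0
    site_logprob: dict = field(default_factory=dict)
    background_logprob: dict = field(default_factory=dict)
    seen_contexts: set = field(default_factory=set)
    logprob_floor: float = DEFAULT_LOGPROB_FLOOR
    log_base: float | None = None  # None = natural log; e.g. 2.0 for bits

    # -- scoring -------------------------------------------------------

    def _scale(self, x: float) -> float:
        if self.log_base is None:
            return x
        return x / math.log(self.log_base)

    def context_at(self, window: str, pos: int) -> str:
        k = min(pos, self.order)
        return window[pos - k : pos]

    def score(self, window: str, strict: bool = True) -> SpliceScore:
        """Log-odds score of ``window``; see :func:`score_site`."""
        window = window.upper()
        if len(window) != self.window_length:
            raise SpliceModelError(
                f"window length {len(window)} != {self.window_length}"
            )
        if not _BASE_SET.issuperset(window):
            if strict:
                bad = sorted(set(window) - _BASE_SET)
                raise SpliceModelError(f"non-ACGT symbol(s) {bad} in window")
            return SpliceScore(value=float("nan"), functional=False, scorable=False)
        total = 0.0
        functional = True
        for pos in range(self.window_length):
            ctx = self.context_at(window, pos)
            base = window[pos]
            key = (pos, ctx, base)
            if key not in self.seen_contexts:
                functional = False
            lp_site = self.site_logprob.get(key, self.logprob_floor)
            lp_bg = self.background_logprob.get(
                (len(ctx), ctx, base), self.logprob_floor
            )
            total += lp_site - lp_bg
        return SpliceScore(value=self._scale(total), functional=functional)

    def score_delta(self, ref_window: str, var_window: str) -> float:
        """Variant-minus-reference score difference (Δ)."""
        return self.score(var_window).value - self.score(ref_window).value

    # -- serialization -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Model tables as a tidy DataFrame (the TSV matrix format)."""
        rows = []
        for (pos, ctx, base), lp in sorted(self.site_logprob.items()):
            rows.append(
                {
                    "site_kind": self.site_kind,
                    "position": pos,
                    "context": ctx or ".",
                    "base": base,
                    "site_logprob": lp,
                    "background_logprob": self.background_logprob.get(
                        (len(ctx), ctx, base), self.logprob_floor
                    ),
                    "seen_flag": int((pos, ctx, base) in self.seen_contexts),
                }
            )
        return pd.DataFrame(rows)

    def save_tsv(self, path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(
                f"# splicevar site model\tsite_kind={self.site_kind}\t"
                f"window_length={self.window_length}\torder={self.order}\t"
                f"pseudocount={self.pseudocount}\n"
            )
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load_tsv(cls, path) -> "PositionalMarkovModel":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# splicevar site model"):
                raise SpliceModelError(f"{path}: not a splicevar model TSV")
            meta = dict(
                kv.split("=", 1) for kv in header.strip().split("\t")[1:]
            )
            df = pd.read_csv(fh, sep="\t")
        model = cls(
            site_kind=meta["site_kind"],
            window_length=int(meta["window_length"]),
            order=int(meta["order"]),
            pseudocount=float(meta["pseudocount"]),
        )
        for row in df.itertuples(index=False):
            ctx = "" if row.context == "." else str(row.context)
            key = (int(row.position), ctx, str(row.base))
            model.site_logprob[key] = float(row.site_logprob)
            model.background_logprob[(len(ctx), ctx, str(row.base))] = float(
                row.background_logprob
            )
            if row.seen_flag:
                model.seen_contexts.add(key)
        return model


# ----------------------------------------------------------------------
# training
# ----------------------------------------------------------------------

def _context_counts(
    sequences: Iterable[str], order: int, strict: bool
) -> dict:
    """Position-independent (context -> base -> count) over all positions,
    for every context length 0..order."""
    counts: dict = {}
    for seq in sequences:
        seq = seq.upper()
        if strict and not _BASE_SET.issuperset(seq):
            bad = sorted(set(seq) - _BASE_SET)
            raise SpliceModelError(f"non-ACGT symbol(s) {bad} in training sequence")
        for pos, base in enumerate(seq):
            if base not in _BASE_SET:
                continue
            for k in range(order + 1):
                if pos - k < 0:
                    continue
                ctx = seq[pos - k : pos]
                if not _BASE_SET.issuperset(ctx):
                    continue
                counts.setdefault((k, ctx), {}).setdefault(base, 0)
                counts[(k, ctx)][base] += 1
    return counts


def train_site_model(
    site_windows: Sequence[str],
    background_sequences: Sequence[str],
    site_kind: str,
    order: int = DEFAULT_ORDER,
    pseudocount: float = 0.0,
    strict: bool = True,
    window_length: int | None = None,
) -> PositionalMarkovModel:
    """Estimate a positional Markov site model from aligned site windows.

    Per-position conditional frequencies are computed with ``pseudocount``
    smoothing; positions with index < ``order`` condition on shorter
    contexts.  The background is a single position-independent model over
    ``background_sequences``.  ``seen_contexts`` records the raw (pre-
    pseudocount) site observations.
    """
    if not site_windows:
        raise SpliceModelError("empty site training set")
    if not background_sequences:
        raise SpliceModelError("empty background training set")
    if pseudocount < 0:
        raise SpliceModelError("pseudocount must be non-negative")
    if window_length is None:
        window_length = WINDOW_LENGTHS.get(site_kind, len(site_windows[0]))
    windows = [_validate_window(w, window_length, strict) for w in site_windows]

    model = PositionalMarkovModel(
        site_kind=site_kind,
        window_length=window_length,
        order=order,
        pseudocount=pseudocount,
    )

    # per-position site counts
    site_counts: dict = {}
    for w in windows:
        for pos, base in enumerate(w):
            if base not in _BASE_SET:
                continue
            ctx = w[max(0, pos - order) : pos]
            if not _BASE_SET.issuperset(ctx):
                continue
            site_counts.setdefault((pos, ctx), {}).setdefault(base, 0)
            site_counts[(pos, ctx)][base] += 1
            model.seen_contexts.add((pos, ctx, base))

    for (pos, ctx), base_counts in site_counts.items():
        total = sum(base_counts.values()) + 4 * pseudocount
        for base in ALPHABET:
            c = base_counts.get(base, 0) + pseudocount
            lp = math.log(c / total) if c > 0 else model.logprob_floor
            model.site_logprob[(pos, ctx, base)] = lp

    # position-independent background, context lengths 0..order
    bg_counts = _context_counts(background_sequences, order, strict)
    for (k, ctx), base_counts in bg_counts.items():
        total = sum(base_counts.values()) + 4 * pseudocount
        for base in ALPHABET:
            c = base_counts.get(base, 0) + pseudocount
            lp = math.log(c / total) if c > 0 else model.logprob_floor
            model.background_logprob[(k, ctx, base)] = lp
    return model


def score_site(model: PositionalMarkovModel, window: str, strict: bool = True) -> SpliceScore:
    """Log-odds splicing score of a window under a trained model.

    value = Σ over positions of log P_site(base | context) − log P_bg(base |
    context); ``functional`` is False iff any scored triple is absent from
    the site training observations.
    """
    return model.score(window, strict=strict)


def score_delta(model: PositionalMarkovModel, ref_window: str, var_window: str) -> float:
    """Δ score: score(variant window) − score(reference window)."""
    return model.score_delta(ref_window, var_window)


# ----------------------------------------------------------------------
# PWM
# ----------------------------------------------------------------------

@dataclass
class Pwm:
    """Position weight matrix: per-position log-odds vs a fixed background
    composition.  ``neutral_band`` is the |Δ| below which a PWM score
    difference is called neutral (default 6, the minima separating the
    trimodal Δ_PWM distribution)."""

    site_kind: str
    length: int
    logodds: dict = field(default_factory=dict)  # (position, base) -> log-odds
    neutral_band: float = 6.0

    def score(self, window: str) -> float:
        window = _validate_window(window, self.length)
        return sum(self.logodds[(i, b)] for i, b in enumerate(window))

    def score_delta(self, ref_window: str, var_window: str) -> float:
        return self.score(var_window) - self.score(ref_window)


def build_pwm(
    site_windows: Sequence[str],
    background_composition: Mapping[str, float] | None = None,
    site_kind: str = "donor",
    pseudocount: float = 0.5,
    neutral_band: float = 6.0,
    window_length: int | None = None,
) -> Pwm:
    """Per-position log-odds PWM from aligned site windows.

    ``background_composition`` maps base -> probability (default uniform).
    """
    if not site_windows:
        raise SpliceModelError("empty site training set")
    if window_length is None:
        window_length = WINDOW_LENGTHS.get(site_kind, len(site_windows[0]))
    windows = [_validate_window(w, window_length) for w in site_windows]
    if background_composition is None:
        background_composition = {b: 0.25 for b in ALPHABET}
    total_bg = sum(background_composition.values())
    bg = {b: background_composition[b] / total_bg for b in ALPHABET}

    pwm = Pwm(site_kind=site_kind, length=window_length, neutral_band=neutral_band)
    n = len(windows)
    for pos in range(window_length):
        counts = {b: pseudocount for b in ALPHABET}
        for w in windows:
            counts[w[pos]] += 1
        denom = n + 4 * pseudocount
        for b in ALPHABET:
            p = counts[b] / denom
            if p > 0:
                pwm.logodds[(pos, b)] = math.log(p / bg[b])
            else:
                pwm.logodds[(pos, b)] = DEFAULT_LOGPROB_FLOOR - math.log(bg[b])
    return pwm


def score_pwm(pwm: Pwm, window: str) -> float:
    """Sum of per-position log-odds of ``window`` under the PWM."""
    return pwm.score(window)
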