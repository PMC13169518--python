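"""Post-hoc statistics over predicted binders.

Three analyses run downstream of the classifier:

* **disorder enrichment** — are high-scoring proteins more often annotated
  with a disordered region than the background proteome?  Tested with
  Fisher's exact test on a 2x2 table, with the odds ratio a*d / (b*c).
* **score buckets** — how do predictions distribute over confidence bands
  (>0.95 high-likelihood, 0.5-0.95 moderate, >0.9), and what fraction of
  each band carries a given annotation?
* **composition around RG/RGG motifs** — residue frequencies in the flanks
  of (overlapping) motif matches, and overlapping amino-acid triplets, both
  expressed as log2 enrichment over a background set with a 0.5 pseudocount.
"""

from __future__ import annotations

import logging
import math
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact as _scipy_fisher

from .models import BindingPrediction
from .seq_io import STANDARD_AA, SequenceDataset

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: a/b = focal group with/without the property, c/d = background
    with/without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")


@dataclass
class CompositionReport:
    flank_freq: dict[str, float]
    background_freq: dict[str, float]
    log2_enrichment: dict[str, float]
    n_matches: int
    triplet_counts: Counter = field(default_factory=Counter)
    triplet_enrichment: list[tuple[str, float]] = field(default_factory=list)


def fisher_exact(t: ContingencyTable) -> tuple[float, float]:
    """Odds ratio a*d/(b*c) and two-sided Fisher exact p-value.

    The p-value sums hypergeometric probabilities of all tables (same
    margins) no more probable than the observed one.  An infinite odds ratio
    is returned when b*c == 0 with a*d > 0; 0/0 is reported as NaN.
    """
    ad_, bc = t.a * t.d, t.b * t.c
    if bc == 0:
        odds = math.inf if ad_ > 0 else math.nan
    else:
        odds = ad_ / bc
    _, p = _scipy_fisher([[t.a, t.b], [t.c, t.d]], alternative="two-sided")
    return odds, float(p)


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero — the convention used for the
    percentages in reports."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def score_buckets(
    predictions: list[BindingPrediction],
    annotations: dict[str, int] | None = None,
    cutoffs: tuple[float, float, float] = (0.5, 0.9, 0.95),
) -> dict[str, dict]:
    """Summarise predictions into confidence bands.

    Bands: ``>c`` for each cutoff plus the moderate band between the lowest
    and highest cutoff.  For each band: count, percent of all predictions,
    and — when ``annotations`` maps ids to 0/1 — the count and percent of
    annotated members.  Empty bands report their fractions as ``None``, not 0.
    """
    lo, _, hi = sorted(cutoffs)
    total = len(predictions)

    def summarise(members: list[BindingPrediction]) -> dict:
        out: dict = {
            "count": len(members),
            "pct_of_total": round_half_away(100 * len(members) / total) if total else None,
        }
        if annotations is not None:
            if members:
                with_prop = sum(annotations.get(p.seq_id, 0) for p in members)
                out["with_property"] = with_prop
                out["pct_with_property"] = round_half_away(100 * with_prop / len(members))
            else:
                out["with_property"] = 0
                out["pct_with_property"] = None
        return out

    buckets = {
        f">{c:g}": summarise([p for p in predictions if p.score_B > c])
        for c in sorted(cutoffs)
    }
    buckets[f"{lo:g}-{hi:g}"] = summarise(
        [p for p in predictions if lo <= p.score_B <= hi]
    )
    buckets["all"] = summarise(list(predictions))
    return buckets


def _aa_frequencies(counts: Counter, alphabet: str = STANDARD_AA) -> dict[str, float]:
    total = sum(counts[aa] for aa in alphabet)
    if total == 0:
        return {aa: 0.0 for aa in alphabet}
    return {aa: counts[aa] / total for aa in alphabet}


def _smoothed_log2(fg: Counter, bg: Counter, categories: list[str]) -> dict[str, float]:
    n_fg = sum(fg[c] for c in categories)
    n_bg = sum(bg[c] for c in categories)
    k = len(categories)
    out = {}
    for c in categories:
        p = (fg[c] + PSEUDOCOUNT) / (n_fg + PSEUDOCOUNT * k)
        q = (bg[c] + PSEUDOCOUNT) / (n_bg + PSEUDOCOUNT * k)
        out[c] = math.log2(p / q)
    return out


def motif_flank_composition(
    seqs: SequenceDataset,
    motif: str = "RGG",
    flank: int = 5,
    background: SequenceDataset | None = None,
) -> CompositionReport:
    """Residue composition of the flanks around (overlapping) motif matches.

    Flanking residues within ``flank`` positions on each side of every match
    are tallied, excluding the motif positions themselves; enrichment is the
    log2 ratio of flank to background frequency with a 0.5 pseudocount per
    residue.  Background defaults to the overall composition of ``seqs``.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    pattern = re.compile(f"(?={re.escape(motif)})")  # lookahead: overlaps allowed
    flank_counts: Counter = Counter()
    n_matches = 0
    for rec in seqs:
        s = rec.residues
        for m in pattern.finditer(s):
            i = m.start()
            n_matches += 1
            flank_counts.update(s[max(0, i - flank) : i])
            flank_counts.update(s[i + len(motif) : i + len(motif) + flank])
    if n_matches == 0:
        logger.warning("no %r matches found in any sequence", motif)

    bg_set = background if background is not None else seqs
    bg_counts: Counter = Counter()
    for rec in bg_set:
        bg_counts.update(rec.residues)

    return CompositionReport(
        flank_freq=_aa_frequencies(flank_counts),
        background_freq=_aa_frequencies(bg_counts),
        log2_enrichment=_smoothed_log2(flank_counts, bg_counts, list(STANDARD_AA)),
        n_matches=n_matches,
    )


def triplet_patterns(
    seqs: SequenceDataset, background: SequenceDataset
) -> list[tuple[str, float]]:
    """Rank all overlapping amino-acid triplets by log2 enrichment over the
    background, pseudocount 0.5 per triplet."""

    def count_triplets(ds: SequenceDataset) -> Counter:
        c: Counter = Counter()
        for rec in ds:
            s = rec.residues
            for i in range(len(s) - 2):
                c[s[i : i + 3]] += 1
        return c

    fg = count_triplets(seqs)
    bg = count_triplets(background)
    categories = sorted(set(fg) | set(bg))
    enrich = _smoothed_log2(fg, bg, categories)
    return sorted(enrich.items(), key=lambda kv: (-kv[1], kv[0]))


def write_enrichment_report(report: CompositionReport, triplets, path) -> None:
    import json

    payload = {
        "n_motif_matches": report.n_matches,
        "flank_freq": report.flank_freq,
        "background_freq": report.background_freq,
        "log2_enrichment": report.log2_enrichment,
        "top_triplets": [{"triplet": t, "log2_enrichment": e} for t, e in triplets[:25]],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
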