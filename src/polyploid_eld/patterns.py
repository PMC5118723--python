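"""Mid-parent deviation and 12-category expression-level dominance.

Two complementary analyses of the polyploid's expression relative to its
parents:

**Non-additivity.**  The additive expectation for a gene in the polyploid is
the mid-parent value MPV = (A + B)/2 of the parents' normalized expression.
A gene is non-additively expressed when the polyploid deviates from the MPV
at least two-fold with statistical support (exact test of the polyploid
count against the pooled parental counts).

**12-category classification.**  Each gene receives a trichotomous direction
call for the three pairwise comparisons A-vs-B, C-vs-A, C-vs-B
(less/equal/greater).  The 27 possible triples map onto the classical
twelve expression categories plus ``no_change``; the 14 statistically
intransitive triples (e.g. C = A, C = B but A > B) fit no coherent ordering
and are labeled ``conflicting`` and reported separately rather than silently
reassigned.  Aggregate classes:

=========  ==========  ==============================================
patterns   aggregate   meaning
=========  ==========  ==============================================
I, XII     additive            C strictly between unequal parents
II         ELD_a_up            C = A (mother), both above B
XI         ELD_a_down          C = A, both below B
IV         ELD_b_up            C = B (father), both above A
IX         ELD_b_down          C = B, both below A
V, VI, VIII transgressive_up   C above both parents
III, VII, X transgressive_down C below both parents
=========  ==========  ==============================================

Sub-numbering within two-sided groups follows the parental ordering
conventions documented in the decision table below (I: A>B; XII: A<B;
III: A>B; X: A<B; V: A<B; VI: A>B); only aggregate classes feed summaries.

Direction calls for classification default to significance-only exact-test
calls (``PATTERN_THRESHOLDS``).  A two-fold filter cannot be used here:
because the MPV always lies within two-fold of the higher parent, a
fold-filtered call can never find C significantly *below* the high parent of
an additive gene, making categories I/XII unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import pct_half_up
from .errors import ConsistencyError, DomainError
from .destats import (
    DEThresholds,
    PATTERN_THRESHOLDS,
    bh_adjust,
    fisher_two_library_batch,
    log2_ratio,
    normalize,
    run_comparison,
)
from .tables_io import ExpressionTable

DIRECTIONS = ("less", "equal", "greater")

#: decision table: (d_AB, d_CA, d_CB) -> roman-numeral pattern label.
#: d_XY is the direction of the first-named condition relative to the second.
_L, _E, _G = "less", "equal", "greater"
PATTERN_TABLE = {
    (_E, _E, _E): "no_change",
    # A > B
    (_G, _L, _G): "I",      # additive, C between
    (_G, _E, _G): "II",     # ELD-a, up relative to B
    (_G, _L, _L): "III",    # transgressive down, A > B
    (_G, _G, _G): "VI",     # transgressive up, A > B
    (_G, _L, _E): "IX",     # ELD-b, down relative to A
    # A = B
    (_E, _L, _L): "VII",    # transgressive down, parents equal
    (_E, _G, _G): "VIII",   # transgressive up, parents equal
    # A < B
    (_L, _G, _L): "XII",    # additive, C between
    (_L, _E, _L): "XI",     # ELD-a, down relative to B
    (_L, _G, _E): "IV",     # ELD-b, up relative to A
    (_L, _G, _G): "V",      # transgressive up, A < B
    (_L, _L, _L): "X",      # transgressive down, A < B
}

LABEL_TO_AGGREGATE = {
    "no_change": "no_change",
    "I": "additive",
    "XII": "additive",
    "II": "ELD_a_up",
    "XI": "ELD_a_down",
    "IV": "ELD_b_up",
    "IX": "ELD_b_down",
    "V": "transgressive_up",
    "VI": "transgressive_up",
    "VIII": "transgressive_up",
    "III": "transgressive_down",
    "VII": "transgressive_down",
    "X": "transgressive_down",
    "conflicting": "conflicting",
}


@dataclass(frozen=True)
class Category:
    label: str      # I..XII, no_change, conflicting
    aggregate: str


def classify_pattern(d_ab: str, d_ca: str, d_cb: str) -> Category:
    """Map one direction triple to its category.

    Arguments are ``less``/``equal``/``greater`` for A-vs-B, C-vs-A and
    C-vs-B respectively ("less" = first-named condition lower).
    """
    for d in (d_ab, d_ca, d_cb):
        if d not in DIRECTIONS:
            raise DomainError(f"direction must be one of {DIRECTIONS}, got {d!r}")
    label = PATTERN_TABLE.get((d_ab, d_ca, d_cb), "conflicting")
    return Category(label, LABEL_TO_AGGREGATE[label])


_CALL_TO_DIR = {"up": "greater", "down": "less", "ns": "equal"}


def calls_to_directions(calls: pd.Series) -> pd.Series:
    """Translate DE calls (up/down/ns of first-vs-second) to directions."""
    return calls.map(_CALL_TO_DIR)


def classify_all(
    de_ab: pd.DataFrame, de_ca: pd.DataFrame, de_cb: pd.DataFrame
) -> pd.DataFrame:
    """Vectorized classification from three DE-result frames.

    The frames must share a feature index and carry a ``call`` column for
    A-vs-B, C-vs-A and C-vs-B respectively.  Returns per-feature directions,
    pattern label and aggregate class.
    """
    idx = de_ab.index
    if not (idx.equals(de_ca.index) and idx.equals(de_cb.index)):
        raise ConsistencyError("DE tables must share an identical feature index")
    d_ab = calls_to_directions(de_ab["call"])
    d_ca = calls_to_directions(de_ca["call"])
    d_cb = calls_to_directions(de_cb["call"])
    key = d_ab + "|" + d_ca + "|" + d_cb
    table = {
        "|".join(k): v for k, v in PATTERN_TABLE.items()
    }
    label = key.map(lambda k: table.get(k, "conflicting"))
    return pd.DataFrame(
        {
            "d_AB": d_ab,
            "d_CA": d_ca,
            "d_CB": d_cb,
            "label": label,
            "aggregate": label.map(LABEL_TO_AGGREGATE),
        },
        index=idx,
    )


def midparent(norm_a, norm_b):
    """Mid-parent value: arithmetic mean of the parents' normalized values."""
    a = np.asarray(norm_a, dtype=float)
    b = np.asarray(norm_b, dtype=float)
    if (a < 0).any() or (b < 0).any():
        raise DomainError("normalized values must be non-negative")
    out = (a + b) / 2.0
    return out if out.ndim else float(out)


def nonadditive_test(
    table: ExpressionTable,
    mode: str = "cpm",
    pseudocount: float = 1.0,
    min_abs_log2fc: float = 1.0,
    alpha: float = 0.05,
    use_q: bool = False,
) -> pd.DataFrame:
    """Test every feature's polyploid expression against its MPV.

    The deviation is the normalized polyploid value over the MPV (with a
    pseudocount); significance comes from the exact test of the polyploid
    count against the pooled parental counts (library sizes add).  A feature
    is flagged non-additive when ``|log2 FC| >= min_abs_log2fc`` and the
    (raw or BH-adjusted) p-value is ``<= alpha``.

    Returns columns ``mpv``, ``log2fc_vs_mpv``, ``p``, ``q``, ``nonadditive``,
    ``direction`` (up/down/none).
    """
    norm = normalize(table, mode)
    mpv = midparent(norm["A"].to_numpy(), norm["B"].to_numpy())
    lfc = log2_ratio(norm["C"].to_numpy(), mpv, pseudocount)
    kC = table.counts["C"].to_numpy()
    nC = int(table.library_sizes["C"])
    kAB = table.counts["A"].to_numpy() + table.counts["B"].to_numpy()
    nAB = int(table.library_sizes["A"]) + int(table.library_sizes["B"])
    p = fisher_two_library_batch(kC, nC, kAB, nAB)
    q = bh_adjust(p)
    stat = q if use_q else p
    flag = (np.abs(lfc) >= min_abs_log2fc) & (stat <= alpha)
    direction = np.where(~flag, "none", np.where(lfc > 0, "up", "down"))
    return pd.DataFrame(
        {
            "mpv": mpv,
            "log2fc_vs_mpv": lfc,
            "p": p,
            "q": q,
            "nonadditive": flag,
            "direction": direction,
        },
        index=table.feature_ids,
    )


def pattern_calls(
    table: ExpressionTable,
    thresholds: DEThresholds = PATTERN_THRESHOLDS,
    mode: str = "cpm",
    pseudocount: float = 1.0,
    nonadditive: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the three pairwise comparisons and classify every feature.

    Convenience wrapper: produces the full per-feature PatternCall table
    (directions, pattern label, aggregate class, non-additivity overlay).
    """
    de_ab = run_comparison(table, "A-vs-B", thresholds, mode, pseudocount)
    de_ca = run_comparison(table, "C-vs-A", thresholds, mode, pseudocount)
    de_cb = run_comparison(table, "C-vs-B", thresholds, mode, pseudocount)
    out = classify_all(de_ab, de_ca, de_cb)
    if nonadditive is None:
        nonadditive = nonadditive_test(table, mode, pseudocount)
    out["nonadditive"] = nonadditive["nonadditive"].reindex(out.index)
    out["nonadditive_direction"] = nonadditive["direction"].reindex(out.index)
    return out


def summarize_patterns(calls: pd.DataFrame, deg_total: int | None = None) -> dict:
    """Aggregate counts, ELD totals, shares and the maternal-bias ratio.

    ``deg_total`` is the number of differentially expressed features used as
    the denominator of the ELD shares (the classification universe and the
    DE universe differ in general).
    """
    counts = {agg: int((calls["aggregate"] == agg).sum())
              for agg in set(LABEL_TO_AGGREGATE.values())}
    return summarize_pattern_counts(
        counts,
        deg_total=deg_total,
        nonadditive_total=int(calls.get("nonadditive", pd.Series(dtype=bool)).sum()),
        nonadditive_up=int((calls.get("nonadditive_direction", pd.Series(dtype=object)) == "up").sum()),
        nonadditive_down=int((calls.get("nonadditive_direction", pd.Series(dtype=object)) == "down").sum()),
    )


def summarize_pattern_counts(
    aggregate_counts: dict,
    deg_total: int | None = None,
    nonadditive_total: int = 0,
    nonadditive_up: int = 0,
    nonadditive_down: int = 0,
) -> dict:
    """Build the summary from per-class counts (also usable on published
    tallies, e.g. to recompute a study's headline totals and percentages)."""
    get = lambda k: int(aggregate_counts.get(k, 0))
    eld_a = get("ELD_a_up") + get("ELD_a_down")
    eld_b = get("ELD_b_up") + get("ELD_b_down")
    eld_total = eld_a + eld_b
    if deg_total is not None and deg_total == 0 and eld_total > 0:
        raise ConsistencyError("deg_total is 0 but ELD counts are non-zero")
    summary = {
        "counts": {k: get(k) for k in sorted(set(LABEL_TO_AGGREGATE.values()))},
        "eld_a_total": eld_a,
        "eld_b_total": eld_b,
        "eld_total": eld_total,
        "nonadditive_total": nonadditive_total,
        "nonadditive_up": nonadditive_up,
        "nonadditive_down": nonadditive_down,
        "maternal_bias_ratio": (eld_a / eld_b) if eld_b else float("inf") if eld_a else 0.0,
    }
    if deg_total is not None:
        summary["deg_total"] = int(deg_total)
        summary["eld_a_share_of_degs"] = pct_half_up(eld_a, deg_total)
        summary["eld_b_share_of_degs"] = pct_half_up(eld_b, deg_total)
    return summary
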