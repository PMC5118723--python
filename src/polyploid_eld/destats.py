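"""Replicate-free two-library differential expression.

The study design has exactly one sequencing library per condition (maternal
parent A, paternal parent B, allopolyploid C), so no within-condition variance
is estimable and replicate-aware models (edgeR/DESeq-style GLMs) do not apply.
Differential expression between two libraries reduces to comparing two
proportions: feature count k out of library total n.  The default test is
Fisher's exact test on the 2x2 table ``(k1, n1-k1; k2, n2-k2)``, two-sided by
summing every table (with the margins fixed) whose probability does not
exceed the observed table's — the same convention as R's ``fisher.test`` and
``scipy.stats.fisher_exact``.  A normal-approximation z-test on the log ratio
of proportions is available as a flagged alternative.

Fold changes are computed on library-size-normalized values (CPM, or RPKM
when feature lengths are known) with a pseudocount, and multiple testing is
controlled with Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import AlignmentError, ConfigurationError, DomainError
from .tables_io import ExpressionTable

#: comparison label -> (numerator role, denominator role)
COMPARISONS = {"C-vs-A": ("C", "A"), "C-vs-B": ("C", "B"), "A-vs-B": ("A", "B")}

# Relative slack when deciding which tables are "as or more extreme" than the
# observed one; guards against ties lost to floating-point (same idea as R).
_REL_TIE_EPS = 1e-7

# single-entry cache of gammaln over 0..n; library sizes repeat across the
# pipeline's comparisons, so the table is built once per run
_LGAMMA: dict[str, object] = {"n": -1, "table": None}


def _lgamma_table(max_arg: int) -> np.ndarray:
    if _LGAMMA["n"] < max_arg:
        _LGAMMA["table"] = gammaln(np.arange(max_arg + 1, dtype=np.float64))
        _LGAMMA["n"] = max_arg
    return _LGAMMA["table"]


@dataclass(frozen=True)
class DEThresholds:
    """Call thresholds for one feature type.

    ``strict`` selects exclusive comparisons (|log2FC| > cutoff, q < alpha)
    instead of the inclusive defaults (>=, <=).
    """

    min_abs_log2fc: float = 1.0
    alpha: float = 0.05
    use_q: bool = False
    strict: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ConfigurationError("min_abs_log2fc must be >= 0")
        if not (0 < self.alpha <= 1):
            raise ConfigurationError("alpha must be in (0, 1]")

    def call(self, log2_ratio: np.ndarray, p: np.ndarray, q: np.ndarray) -> np.ndarray:
        """Vector of 'up'/'down'/'ns' for the first-named condition."""
        stat = q if self.use_q else p
        if self.strict:
            sig = (np.abs(log2_ratio) > self.min_abs_log2fc) & (stat < self.alpha)
        else:
            sig = (np.abs(log2_ratio) >= self.min_abs_log2fc) & (stat <= self.alpha)
        out = np.where(sig & (log2_ratio > 0), "up", "ns")
        return np.where(sig & (log2_ratio < 0), "down", out)


#: thresholds used in the source study: genes at |log2FC|>=1 and raw p<=0.05,
#: miRNAs at |log2FC|>1 and BH q<0.01.
MRNA_THRESHOLDS = DEThresholds(min_abs_log2fc=1.0, alpha=0.05, use_q=False, strict=False)
MIRNA_THRESHOLDS = DEThresholds(min_abs_log2fc=1.0, alpha=0.01, use_q=True, strict=True)
#: significance-only calls for 12-category pattern classification (see
#: patterns module: a fold filter makes the additive categories unreachable).
PATTERN_THRESHOLDS = DEThresholds(min_abs_log2fc=0.0, alpha=0.01, use_q=False, strict=False)


def normalize(table: ExpressionTable, mode: str = "cpm") -> pd.DataFrame:
    """Normalize counts to CPM or RPKM.

    CPM = count * 1e6 / library_size;
    RPKM = count * 1e9 / (library_size * length_bp).
    """
    mode = mode.lower()
    counts = table.counts.astype(float)
    sizes = table.library_sizes.astype(float)
    if mode == "cpm":
        return counts * 1e6 / sizes
    if mode == "rpkm":
        if table.lengths is None:
            raise ConfigurationError("RPKM normalization requires feature lengths")
        return counts.mul(1e9, axis=0).div(sizes, axis=1).div(
            table.lengths.astype(float), axis=0
        )
    raise ConfigurationError(f"unknown normalization mode {mode!r}")


def log2_ratio(x1, x2, pseudocount: float = 1.0):
    """log2((x1+pseudocount)/(x2+pseudocount)) on normalized values."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if (x1 < 0).any() or (x2 < 0).any():
        raise DomainError("normalized values must be non-negative")
    if pseudocount <= 0:
        raise DomainError("pseudocount must be positive")
    out = np.log2(x1 + pseudocount) - np.log2(x2 + pseudocount)
    return out if out.ndim else float(out)


def fisher_two_library(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher exact p for one feature in two libraries."""
    p = fisher_two_library_batch(
        np.asarray([k1]), int(n1), np.asarray([k2]), int(n2)
    )
    return float(p[0])


def fisher_two_library_batch(
    k1: np.ndarray, n1: int, k2: np.ndarray, n2: int, chunk_points: int = 4_000_000
) -> np.ndarray:
    """Vectorized two-sided Fisher exact test, shared library sizes.

    For feature i the 2x2 table is ``(k1[i], n1-k1[i]; k2[i], n2-k2[i])``.
    Under the hypergeometric null (margins fixed) the support of the first
    cell is ``max(0, K-n2) .. min(K, n1)`` with ``K = k1+k2``; the two-sided p
    sums the probabilities of all support points whose pmf does not exceed
    the observed pmf (within a 1e-7 relative tie tolerance).

    The summation is exhaustive over the support — exact for any margins —
    and is evaluated in flat gammaln-space chunks so that 10^4-10^5 features
    against 10^7-read libraries stay within seconds.
    """
    k1 = np.asarray(k1, dtype=np.int64)
    k2 = np.asarray(k2, dtype=np.int64)
    n1 = int(n1)
    n2 = int(n2)
    if n1 <= 0 or n2 <= 0:
        raise DomainError("library sizes must be positive")
    if (k1 < 0).any() or (k2 < 0).any() or (k1 > n1).any() or (k2 > n2).any():
        raise DomainError("counts must satisfy 0 <= k <= library size")

    K = k1 + k2
    kmin = np.maximum(0, K - n2)
    kmax = np.minimum(K, n1)
    lens = kmax - kmin + 1
    p_out = np.ones(len(K), dtype=float)

    # log C(n1, x) + log C(n2, K-x) for support point x; per-feature constant
    # -log C(n1+n2, K) cancels in the pmf comparison and is applied at the end.
    order = np.argsort(lens)  # group features of similar support size
    todo = order[lens[order] > 1]
    start = 0
    while start < len(todo):
        stop = start
        points = 0
        while stop < len(todo) and points + lens[todo[stop]] <= chunk_points:
            points += lens[todo[stop]]
            stop += 1
        stop = max(stop, start + 1)
        idx = todo[start:stop]
        start = stop

        clens = lens[idx]
        offsets = np.concatenate([[0], np.cumsum(clens)])
        feat = np.repeat(np.arange(len(idx)), clens)
        xs = np.arange(offsets[-1]) - offsets[feat] + kmin[idx][feat]
        Kf = K[idx][feat]
        T = _lgamma_table(max(n1, n2) + 1)
        logpmf = -(T[xs + 1] + T[n1 - xs + 1] + T[Kf - xs + 1] + T[n2 - Kf + xs + 1])
        obs = logpmf[offsets[:-1] + (k1[idx] - kmin[idx])]
        keep = logpmf <= obs[feat] + np.log1p(_REL_TIE_EPS)
        # scale by the per-feature support maximum before exponentiating so
        # the sum never overflows even for observations deep in a tail
        seg_max = np.maximum.reduceat(logpmf, offsets[:-1])
        pmf = np.exp(logpmf - seg_max[feat])
        psum = np.add.reduceat(np.where(keep, pmf, 0.0), offsets[:-1])
        total = np.add.reduceat(pmf, offsets[:-1])
        p_out[idx] = psum / total
    return np.minimum(p_out, 1.0)


def ztest_log_ratio_batch(
    k1: np.ndarray, n1: int, k2: np.ndarray, n2: int
) -> np.ndarray:
    """Normal-approximation alternative: z on log(k1/n1) - log(k2/n2).

    Delta-method variance 1/k1 + 1/k2 (Poisson counts); features with a zero
    count on either side fall back to a 0.5 pseudocount.  Provided as a
    documented alternative to the exact test, not the default.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    a = np.where(k1 == 0, 0.5, k1)
    b = np.where(k2 == 0, 0.5, k2)
    z = (np.log(a / n1) - np.log(b / n2)) / np.sqrt(1.0 / a + 1.0 / b)
    return 2.0 * stats.norm.sf(np.abs(z))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values aligned to input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_comparison(
    table: ExpressionTable,
    comparison: str,
    thresholds: DEThresholds = MRNA_THRESHOLDS,
    mode: str = "cpm",
    pseudocount: float = 1.0,
    other: ExpressionTable | None = None,
    method: str = "fisher",
) -> pd.DataFrame:
    """Differential expression for one pairwise comparison.

    Returns a DataFrame indexed by feature id with columns ``log2_ratio``
    (first-named condition over second, on normalized values), ``p`` (exact
    test on raw counts), ``q`` (BH across this comparison) and ``call``
    (up/down/ns for the first-named condition).

    ``other`` optionally supplies the second condition from a separate table;
    its feature universe must match exactly.
    """
    if comparison not in COMPARISONS:
        raise ConfigurationError(
            f"comparison must be one of {sorted(COMPARISONS)}, got {comparison!r}"
        )
    num_role, den_role = COMPARISONS[comparison]
    if other is not None:
        sym = set(table.feature_ids) ^ set(other.feature_ids)
        if sym:
            raise AlignmentError(
                f"feature universes differ; symmetric difference: {sorted(sym)[:10]}"
                + ("..." if len(sym) > 10 else "")
            )
        den_table = other
    else:
        den_table = table

    norm_num = normalize(table, mode)[num_role]
    norm_den = normalize(den_table, mode)[den_role].reindex(norm_num.index)
    lfc = log2_ratio(norm_num.to_numpy(), norm_den.to_numpy(), pseudocount)

    k1 = table.counts[num_role].to_numpy()
    n1 = int(table.library_sizes[num_role])
    k2 = den_table.counts.reindex(norm_num.index)[den_role].to_numpy()
    n2 = int(den_table.library_sizes[den_role])
    if method == "fisher":
        p = fisher_two_library_batch(k1, n1, k2, n2)
    elif method == "ztest":
        p = ztest_log_ratio_batch(k1, n1, k2, n2)
    else:
        raise ConfigurationError(f"unknown method {method!r}")
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "log2_ratio": lfc,
            "p": p,
            "q": q,
            "call": thresholds.call(lfc, p, q),
        },
        index=pd.Index(norm_num.index, name="feature_id"),
    )


def de_counts(result: pd.DataFrame) -> dict[str, int]:
    """Up/down/ns tallies of one comparison's results."""
    vc = result["call"].value_counts()
    return {
        "up": int(vc.get("up", 0)),
        "down": int(vc.get("down", 0)),
        "ns": int(vc.get("ns", 0)),
        "total_de": int(vc.get("up", 0) + vc.get("down", 0)),
    }
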