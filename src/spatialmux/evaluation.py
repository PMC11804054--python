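"""Clustering agreement metrics and paired significance testing.

ARI and NMI are computed from the contingency table of two labelings over
the spots present in both (spots missing from either side are excluded with
a logged count).  Method comparisons use the two-sided Wilcoxon signed-rank
test — exact via the rank-sum distribution for up to 25 informative pairs,
normal approximation with tie and continuity corrections beyond — with
Benjamini-Hochberg control over all comparisons performed in a run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .data_model import LabelVector, ValidationError

logger = logging.getLogger(__name__)

#: largest number of informative pairs for which the exact signed-rank
#: distribution is enumerated
EXACT_WILCOXON_LIMIT = 25


@dataclass
class ContingencyTable:
    counts: np.ndarray  # (r, c) non-negative ints

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def contingency(a: np.ndarray, b: np.ndarray) -> ContingencyTable:
    """Cross-tabulate two integer label vectors of equal length."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValidationError("label vectors differ in length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    r, c = ai.max() + 1, bi.max() + 1
    counts = np.zeros((r, c), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)
    return ContingencyTable(counts)


def _align(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(a, LabelVector) and isinstance(b, LabelVector):
        shared = [i for i in a.spot_ids if i in set(b.spot_ids)]
        excluded = (len(a.spot_ids) - len(shared)) + (len(b.spot_ids) - len(shared))
        if excluded:
            logger.info("excluding %d spot(s) absent from one labeling", excluded)
        if len(shared) < 2:
            raise ValidationError("fewer than 2 shared spots between labelings")
        pa = {s: l for s, l in zip(a.spot_ids, a.labels)}
        pb = {s: l for s, l in zip(b.spot_ids, b.labels)}
        _, ca = np.unique([pa[s] for s in shared], return_inverse=True)
        _, cb = np.unique([pb[s] for s in shared], return_inverse=True)
        return ca, cb
    a = np.asarray(a)
    b = np.asarray(b)
    if a.size != b.size:
        raise ValidationError("label vectors differ in length")
    if a.size < 2:
        raise ValidationError("need at least 2 spots")
    return a, b


def adjusted_rand_index(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray) -> float:
    """Chance-corrected pair-counting agreement; 1 for identical partitions."""
    ca, cb = _align(a, b)
    t = contingency(ca, cb)

    def comb2(x: np.ndarray) -> float:
        x = x.astype(float)
        return float((x * (x - 1) / 2).sum())

    sum_ij = comb2(t.counts.ravel())
    sum_a = comb2(t.row_marginals)
    sum_b = comb2(t.col_marginals)
    n_pairs = t.n * (t.n - 1) / 2
    expected = sum_a * sum_b / n_pairs
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        # both partitions trivial (all-singletons or single-cluster): identical
        return 1.0
    return (sum_ij - expected) / (max_index - expected)


def normalized_mutual_information(a: LabelVector | np.ndarray, b: LabelVector | np.ndarray,
                                  normalization: str = "arithmetic") -> float:
    """Mutual information normalized by the mean entropy, in [0, 1].

    Two single-cluster labelings are identical (1.0); a single-cluster
    labeling against a non-trivial one carries no information (0.0).
    """
    ca, cb = _align(a, b)
    t = contingency(ca, cb)
    n = t.n
    pij = t.counts / n
    pa = t.row_marginals / n
    pb = t.col_marginals / n
    ha = -float((pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = -float((pb[pb > 0] * np.log(pb[pb > 0])).sum())
    if ha == 0 and hb == 0:
        return 1.0
    if ha == 0 or hb == 0:
        return 0.0
    nz = pij > 0
    mi = float((pij[nz] * np.log(pij[nz] / np.outer(pa, pb)[nz])).sum())
    if normalization == "arithmetic":
        denom = (ha + hb) / 2
    elif normalization == "geometric":
        denom = np.sqrt(ha * hb)
    elif normalization == "min":
        denom = min(ha, hb)
    elif normalization == "max":
        denom = max(ha, hb)
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    return max(0.0, min(1.0, mi / denom))


def _exact_signed_rank_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``ranks2`` are the midranks doubled (integers), ``w2`` the doubled
    observed positive-rank sum; the null distribution is built by dynamic
    programming over all 2^n equally likely sign assignments.
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w2))
    p_le = float(dist[: w2 + 1].sum())
    p_ge = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped; ties get midranks.  Exact distribution up
    to ``EXACT_WILCOXON_LIMIT`` informative pairs, normal approximation with
    tie and continuity corrections beyond.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("paired samples differ in length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValidationError("all paired differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_WILCOXON_LIMIT:
        p = _exact_signed_rank_p(np.round(2 * ranks), 2 * w_plus)
    else:
        mean = n * (n + 1) / 4
        _, t = np.unique(ranks, return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24 - float(((t**3 - t) / 48).sum())
        if var <= 0:
            raise ValidationError("zero variance in signed-rank statistic")
        cc = 0.5 * np.sign(w_plus - mean)
        z = (w_plus - mean - cc) / np.sqrt(var)
        p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return w_plus, p


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment: q_(i) = min_{j>=i} p_(j) * m / j, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def compare_methods(results: pd.DataFrame, method_a: str, method_b: str) -> tuple[float, float, float]:
    """Paired Wilcoxon between two method columns of a per-sample table.

    ``results`` is wide: one row per sample, one column per method.  Returns
    (W+, p, q); q equals p for a single comparison — use
    :func:`compare_all_pairs` to adjust across many.
    """
    for m in (method_a, method_b):
        if m not in results.columns:
            raise ValidationError(f"method {m!r} not in table")
    sub = results[[method_a, method_b]].dropna()
    if len(sub) < 3:
        raise ValidationError(f"need >= 3 shared samples, got {len(sub)}")
    a = sub[method_a].to_numpy()
    b = sub[method_b].to_numpy()
    if np.array_equal(a, b):
        raise ValidationError("identical methods: all paired differences are zero")
    stat, p = wilcoxon_signed_rank(a, b)
    return stat, p, p


def compare_all_pairs(results: pd.DataFrame) -> pd.DataFrame:
    """All pairwise method comparisons with BH adjustment across them."""
    methods = list(results.columns)
    rows = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            try:
                stat, p, _ = compare_methods(results, a, b)
            except ValidationError as e:
                logger.warning("skipping %s vs %s: %s", a, b, e)
                continue
            rows.append({"method_a": a, "method_b": b, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out
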