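"""Functional characterization of marker genes.

Two complementary routes: hypergeometric over-representation of a marker
list in user-supplied gene sets (with Benjamini–Hochberg adjustment and
the dual p < 0.01 / adjusted p < 0.05 significance rule), and GSEA on a
whole-transcriptome ranking by the score

    S(g) = -log10(p_g) * sign(log FC_g)

where p is the two-group Wilcoxon rank-sum p-value and FC the linear
fold change (pseudocount 1) between samples within and without a state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom, mannwhitneyu

from .containers import InputError

__all__ = [
    "GeneSetCollection",
    "hypergeometric_enrichment",
    "rank_scores",
    "gsea",
]

SET_SIZE_RANGE = (15, 500)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style), order-preserving and deduplicated."""

    sets: dict  # name -> list of gene ids
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise InputError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def filtered(self, universe, size_range=SET_SIZE_RANGE) -> "GeneSetCollection":
        """Intersect with a universe, then keep sets within the size range."""
        uni = set(universe)
        lo, hi = size_range
        out = {}
        for name, genes in self.sets.items():
            g = [x for x in genes if x in uni]
            if lo <= len(g) <= hi:
                out[name] = g
        return GeneSetCollection(sets=out, source=self.source)


def hypergeometric_enrichment(
    markers,
    collection: GeneSetCollection,
    universe,
    set_size_range=SET_SIZE_RANGE,
) -> pd.DataFrame:
    """Over-representation of a marker list in each gene set.

    Sets are intersected with the universe before size filtering
    (default 15–500). Significance uses the dual rule p < 0.01 and
    BH-adjusted p < 0.05; the table is sorted by overlap count with the
    top ten flagged.
    """
    universe = list(dict.fromkeys(universe))
    markers = [m for m in dict.fromkeys(markers) if m in set(universe)]
    if not universe or not markers:
        raise InputError("markers and universe must be non-empty")
    filt = collection.filtered(universe, set_size_range)
    if not filt.sets:
        return pd.DataFrame(
            columns=["set", "set_size", "overlap", "p", "adjusted_p",
                     "significant", "top10"]
        ).set_index("set")
    N, n = len(universe), len(markers)
    marker_set = set(markers)
    rows = []
    for name, genes in filt.sets.items():
        K = len(genes)
        x = len(marker_set.intersection(genes))
        p = float(hypergeom.sf(x - 1, N, K, n)) if x > 0 else 1.0
        rows.append({"set": name, "set_size": K, "overlap": x, "p": min(p, 1.0)})
    out = pd.DataFrame(rows).set_index("set")
    out["adjusted_p"] = false_discovery_control(out["p"].to_numpy(), method="bh")
    out["significant"] = (out["p"] < 0.01) & (out["adjusted_p"] < 0.05)
    out = out.sort_values(["overlap", "p"], ascending=[False, True])
    out["top10"] = False
    out.iloc[: min(10, len(out)), out.columns.get_loc("top10")] = True
    return out


def rank_scores(
    expression: pd.DataFrame, in_group, out_group
) -> pd.DataFrame:
    """Per-gene rank score between two sample groups.

    ``expression`` is genes x samples on the linear scale. Returns a
    frame indexed by gene with columns p, fc, S sorted by S descending
    (gene id breaks ties deterministically). Genes constant across both
    groups get p = 1, S = 0 by convention.
    """
    in_group, out_group = list(in_group), list(out_group)
    if len(in_group) < 2 or len(out_group) < 2:
        raise InputError("both groups need >= 2 samples")
    A = expression[in_group].to_numpy(dtype=float)
    B = expression[out_group].to_numpy(dtype=float)
    fc = (A.mean(axis=1) + 1.0) / (B.mean(axis=1) + 1.0)
    ps = np.ones(expression.shape[0])
    for i in range(expression.shape[0]):
        a, b = A[i], B[i]
        if np.ptp(np.concatenate([a, b])) == 0:
            continue
        ps[i] = mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
    sign = np.sign(np.log(fc))
    S = -np.log10(np.maximum(ps, 1e-300)) * sign
    out = pd.DataFrame(
        {"p": ps, "fc": fc, "S": S}, index=expression.index
    )
    out = out.sort_values("S", ascending=False, kind="stable")
    # deterministic tie-break on gene id within equal scores
    out["_g"] = out.index
    out = out.sort_values(["S", "_g"], ascending=[False, True], kind="stable")
    return out.drop(columns="_g")


def _running_es(hits: np.ndarray, scores: np.ndarray, weight: float) -> float:
    """Signed enrichment score: extremum of the weighted running sum."""
    w = np.abs(scores) ** weight
    hit_total = w[hits].sum()
    n, nh = len(hits), int(hits.sum())
    if hit_total <= 0 or nh == n:
        return 0.0
    step = np.where(hits, w / hit_total, -1.0 / (n - nh))
    run = np.cumsum(step)
    return float(run[np.argmax(np.abs(run))])


def gsea(
    ranked: pd.DataFrame,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    set_size_range=SET_SIZE_RANGE,
) -> pd.DataFrame:
    """Gene-set enrichment on a ranked score table.

    ``ranked`` is the output of :func:`rank_scores` (sorted, indexed by
    gene, column S). ES is the extremum of the weighted running sum; the
    null permutes gene labels (random hit positions); NES divides ES by
    the mean magnitude of same-sign null scores and the one-sided
    empirical p counts same-sign nulls at least as extreme.
    """
    if "S" not in ranked.columns:
        raise InputError("ranked table must carry an S column")
    genes = list(ranked.index)
    scores = ranked["S"].to_numpy(dtype=float)
    pos = {g: i for i, g in enumerate(genes)}
    filt = collection.filtered(genes, set_size_range)
    rng = np.random.default_rng([int(seed), 13])
    rows = []
    for name, members in filt.sets.items():
        hits = np.zeros(len(genes), dtype=bool)
        hits[[pos[g] for g in members]] = True
        es = _running_es(hits, scores, weight)
        null = np.empty(n_perm)
        nh = int(hits.sum())
        for b in range(n_perm):
            h = np.zeros(len(genes), dtype=bool)
            h[rng.choice(len(genes), size=nh, replace=False)] = True
            null[b] = _running_es(h, scores, weight)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) and np.mean(np.abs(same)) > 0:
            nes = es / float(np.mean(np.abs(same)))
        else:
            nes = np.nan
        p = (int((np.abs(same) >= abs(es)).sum()) + 1) / (len(same) + 1)
        rows.append(
            {"set": name, "size": nh, "ES": es, "NES": nes, "p": float(p)}
        )
    return pd.DataFrame(
        rows, columns=["set", "size", "ES", "NES", "p"]
    ).set_index("set")
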