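"""Preranked gene-set enrichment and GO-style over-representation.

GSEA follows the weighted Kolmogorov–Smirnov running-sum statistic:
walking down a ranked gene list, the running sum rises by the (normalized)
|score|^p weight at each set member and falls by 1/(N−K) at each
non-member; the enrichment score (ES) is the signed extremum. The null is
built from random same-size gene sets (the only permutation scheme a
preranked list admits); p-values follow the fgsea convention — one-sided
within the same-signed null ESs. Over-representation uses the
upper-tail hypergeometric test against an expression-defined background
(genes with TPM > 1 in at least one sample).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .riboclass import bh_adjust

__all__ = [
    "RankedList",
    "GeneSet",
    "compute_tpm",
    "build_background",
    "enrichment_score",
    "preranked_gsea",
    "go_overrepresentation",
]


@dataclass
class GeneSet:
    """A named gene set (GMT record)."""

    set_id: str
    genes: frozenset
    description: str = ""

    def __post_init__(self):
        genes = frozenset(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(self, "genes", genes)


class RankedList:
    """Genes with real scores, sorted by (score desc, gene id asc).

    The explicit tie rule matters: the ES depends on the order, so ties
    are broken deterministically by gene id.
    """

    def __init__(self, scores: pd.Series):
        scores = scores.dropna()
        if scores.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        order = sorted(scores.index, key=lambda g: (-scores[g], str(g)))
        self.genes = np.asarray(order, dtype=object)
        self.scores = scores.loc[order].to_numpy(dtype=float)

    def __len__(self):
        return len(self.genes)


def compute_tpm(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and gene lengths (bp).

    TPM_gs = 1e6 · (count/length) / Σ(count/length); each column sums to
    10⁶ (when the column has any reads).
    """
    lengths = gene_lengths.loc[counts.index].to_numpy(dtype=float)
    if np.any(lengths <= 0) or np.any(~np.isfinite(lengths)):
        raise ValueError("all gene lengths must be positive")
    rate = counts.to_numpy(dtype=float) / lengths[:, None]
    denom = rate.sum(axis=0)
    if np.any(denom == 0):
        raise ValueError("a sample has zero total counts")
    return pd.DataFrame(1e6 * rate / denom[None, :],
                        index=counts.index, columns=counts.columns)


def build_background(tpm: pd.DataFrame, threshold: float = 1.0) -> frozenset:
    """Expressed-gene background: TPM strictly above ``threshold`` in ≥ 1 sample."""
    expressed = (tpm > threshold).any(axis=1)
    return frozenset(tpm.index[expressed])


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def _running_sum(in_set: np.ndarray, scores: np.ndarray, weight_p: float):
    """Weighted KS running sum over the ranked list; returns the cumulative path."""
    N = len(in_set)
    K = int(in_set.sum())
    if K == 0 or K == N:
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    w = np.abs(scores) ** weight_p
    hit_w = np.where(in_set, w, 0.0)
    total = hit_w.sum()
    if total == 0:   # all member scores zero at weight_p > 0: fall back to equal weights
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    steps = hit_w / total - (~in_set) / (N - K)
    return np.cumsum(steps)


def enrichment_score(in_set: np.ndarray, scores: np.ndarray,
                     weight_p: float = 1.0):
    """Signed extremum of the running sum, and the leading-edge boundary index."""
    path = _running_sum(np.asarray(in_set, bool), np.asarray(scores, float),
                        weight_p)
    i_max = int(np.argmax(path))
    i_min = int(np.argmin(path))
    # an exact |max| == |min| tie resolves positive (tolerance absorbs
    # accumulation noise in the cumulative sum)
    if path[i_max] >= -path[i_min] - 1e-12:
        return float(path[i_max]), i_max, +1
    return float(path[i_min]), i_min, -1


@dataclass
class GSEAResult:
    """Enrichment results, one row per testable set (``table``)."""

    table: pd.DataFrame
    untestable: list = field(default_factory=list)

    def __getitem__(self, col):
        return self.table[col]


def preranked_gsea(ranked: RankedList, sets: list[GeneSet],
                   weight_p: float = 1.0, n_perm: int = 10000,
                   seed: int = 0) -> GSEAResult:
    """Preranked GSEA with a random-gene-set permutation null.

    For each set, the ES of ``n_perm`` random same-size subsets of the
    ranked universe forms the null; the permutation p is one-sided within
    the same-signed null ESs, p = (1 + #{same sign, |ES_null| ≥ |ES|}) /
    (1 + #same-sign nulls), so p ≥ 1/(n_perm+1) and is uniform under the
    null. NES = ES / mean|same-sign null ES|. BH adjustment across sets.
    Sets disjoint from the universe are reported in ``untestable``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    universe = {g: i for i, g in enumerate(ranked.genes)}
    N = len(ranked)
    rows = []
    untestable = []
    for gs in sets:
        members = sorted(g for g in gs.genes if g in universe)
        K = len(members)
        if K == 0 or K == N:
            untestable.append(gs.set_id)
            continue
        in_set = np.zeros(N, dtype=bool)
        idx = [universe[g] for g in members]
        in_set[idx] = True
        es, i_ext, sign = enrichment_score(in_set, ranked.scores, weight_p)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(N, dtype=bool)
            perm[rng.choice(N, size=K, replace=False)] = True
            null[b], _, _ = enrichment_score(perm, ranked.scores, weight_p)
        same = null * np.sign(es) >= 0 if es != 0 else np.ones(n_perm, bool)
        n_same = int(same.sum())
        n_extreme = int((np.abs(null[same]) >= abs(es)).sum())
        p = (1 + n_extreme) / (1 + n_same)
        denom = np.abs(null[same]).mean() if n_same else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan

        if sign > 0:
            leading = [g for g in ranked.genes[: i_ext + 1] if g in gs.genes]
        else:
            leading = [g for g in ranked.genes[i_ext:] if g in gs.genes]
        rows.append({"set": gs.set_id, "size": K, "ES": es, "NES": nes,
                     "pval": p, "leadingEdge": ",".join(map(str, leading))})
    table = pd.DataFrame(rows, columns=["set", "size", "ES", "NES", "pval",
                                        "leadingEdge"])
    if len(table):
        table["padj"] = bh_adjust(table["pval"].to_numpy())
    else:
        table["padj"] = []
    return GSEAResult(table.set_index("set"), untestable)


# ---------------------------------------------------------------------------
# over-representation
# ---------------------------------------------------------------------------

def go_overrepresentation(study: set, background: set,
                          annotation: dict) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a study set.

    For each term with K background members, the upper-tail probability of
    observing ≥ k of the n study genes in the term, drawing from the
    N-gene background. BH-adjusted across terms; ``significant`` marks
    padj < 0.05.
    """
    study = set(study)
    background = set(background)
    missing = study - background
    if missing:
        raise ValueError(
            f"{len(missing)} study genes absent from the background: "
            f"{sorted(missing)[:10]}")
    N = len(background)
    n = len(study)
    rows = []
    for term, genes in annotation.items():
        term_bg = set(genes) & background
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & study)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"term": term, "k": k, "K": K, "n": n, "N": N,
                     "pval": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "pval"])
    if len(out):
        out["padj"] = bh_adjust(out["pval"].to_numpy())
        out["significant"] = out["padj"] < 0.05
    else:
        out["padj"] = []
        out["significant"] = []
    return out.set_index("term")
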