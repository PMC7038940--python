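"""Percent Circularized-site Usage (PCU) and tissue specificity of ABS events.

For each ABS event, the predominant circRNA is the member that is the most
abundant one in the majority of tissues within a scope (a cohort such as
fetal or adult tissues, or a single individual).  PCU in a tissue is the
predominant member's share of the event's total back-splice junction
reads, in percent.  PCU is only computed where the event is eligible:
at least one member reaches the high-confidence RPM threshold in that
tissue and the event total is positive.  An event is tissue specific when
its largest pairwise PCU difference across eligible tissues (delta PCU)
reaches a cutoff in percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .events import ABSEvent
from .io import DEFAULT_MIN_RPM, acceptor_pos, donor_pos

SAME_TISSUE = "same-tissue-different-individuals"
SAME_INDIVIDUAL = "same-individual-different-tissues"


def _sort_rank(key) -> tuple:
    # deterministic tie-break: lexicographic (chrom, acceptor, donor)
    chrom, strand, start, end = key
    return (chrom, acceptor_pos(strand, start, end), donor_pos(strand, start, end))


def _member_rpms(event: ABSEvent, matrix: pd.DataFrame, scope) -> pd.DataFrame:
    members = [k for k in event.hc_members if k in matrix.index]
    sub = matrix.loc[members, scope]
    return sub


def select_predominant(
    events: Sequence[ABSEvent],
    matrix: pd.DataFrame,
    scope: Sequence[str] | None = None,
) -> dict[str, tuple]:
    """Pick the predominant circRNA per event within a tissue scope.

    For every scope tissue where the event has nonzero total RPM, the most
    abundant member wins; the predominant circRNA is the member with the
    most wins.  Ties (within a tissue, or on win counts) are broken by
    larger pooled RPM across the scope, then by genomic coordinate, so the
    choice is deterministic.  Events absent from every scope tissue are
    omitted from the result.
    """
    scope = list(matrix.columns) if scope is None else list(scope)
    out: dict[str, tuple] = {}
    for event in events:
        sub = _member_rpms(event, matrix, scope)
        if sub.empty:
            continue
        pooled = sub.sum(axis=1)
        ranks = {k: _sort_rank(k) for k in sub.index}

        def prefer(key):  # sort ascending: best member first
            return (-float(pooled[key]), ranks[key])

        wins: dict[tuple, int] = {}
        for tissue in scope:
            col = sub[tissue]
            total = float(col.sum())
            if total <= 0:
                continue
            top = col.max()
            winners = sorted((k for k in col.index if col[k] == top), key=prefer)
            wins[winners[0]] = wins.get(winners[0], 0) + 1
        if not wins:
            continue
        best = sorted(wins, key=lambda k: (-wins[k],) + tuple(prefer(k)))[0]
        out[event.event_id] = best
    return out


def compute_pcu(
    events: Sequence[ABSEvent],
    matrix: pd.DataFrame,
    predominant: Mapping[str, tuple],
    scope: Sequence[str] | None = None,
    min_rpm: float = DEFAULT_MIN_RPM,
) -> pd.DataFrame:
    """PCU matrix (events x tissues) in percent, NaN where ineligible.

    PCU(event, tissue) = 100 * RPM(predominant) / sum of member RPMs.
    Eligibility in a tissue requires >= 1 member at ``min_rpm`` and a
    positive event total.
    """
    scope = list(matrix.columns) if scope is None else list(scope)
    rows = {}
    for event in events:
        pred = predominant.get(event.event_id)
        if pred is None:
            continue
        sub = _member_rpms(event, matrix, scope)
        total = sub.sum(axis=0)
        eligible = (sub.max(axis=0) >= min_rpm) & (total > 0)
        vals = 100.0 * sub.loc[[pred]].iloc[0] / total.where(total > 0)
        rows[event.event_id] = vals.where(eligible)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=scope)
    out.index.name = "event_id"
    return out


def call_tissue_specific(
    pcu_matrix: pd.DataFrame, cutoff: float, strict_greater: bool = False
) -> pd.DataFrame:
    """Call tissue-specific events by the largest pairwise PCU difference.

    Only events eligible (non-missing PCU) in >= 2 tissues are evaluated.
    ``specific`` is delta_pcu >= cutoff (or > with ``strict_greater``).
    """
    if not 0 < cutoff <= 100:
        raise ValueError("cutoff must be in (0, 100]")
    n_elig = pcu_matrix.notna().sum(axis=1)
    evaluable = pcu_matrix[n_elig >= 2]
    delta = evaluable.max(axis=1) - evaluable.min(axis=1)
    specific = delta > cutoff if strict_greater else delta >= cutoff
    return pd.DataFrame(
        {
            "delta_pcu": delta,
            "n_eligible_tissues": n_elig[delta.index],
            "cutoff": cutoff,
            "specific": specific,
        }
    )


@dataclass
class CorrelationSummary:
    """Spearman correlations by sample-pair class plus a rank-sum contrast."""

    pairs: pd.DataFrame  # sample_a, sample_b, pair_class, n_shared, rho
    pvalue: float  # rank-sum test, same-tissue vs same-individual rho

    def mean_rho(self, pair_class: str) -> float:
        sel = self.pairs.loc[self.pairs["pair_class"] == pair_class, "rho"]
        return float(sel.mean())


def correlation_summary(
    matrix: pd.DataFrame, sample_sheet: pd.DataFrame, min_shared: int = 3
) -> CorrelationSummary:
    """Compare profile correlations within tissues vs within individuals.

    ``matrix`` has one column per sample (PCU per event, RPM per circRNA,
    or expression per host gene); rows missing in either sample of a pair
    are dropped (pairwise-complete).  Pairs sharing the tissue but not the
    individual form one class, pairs sharing the individual but not the
    tissue the other; all other pairs (including replicate pairs) are
    ignored.  Classes are contrasted with a two-sided rank-sum test.
    """
    cols = list(matrix.columns)
    meta = sample_sheet.loc[cols]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            same_t = meta.at[a, "tissue"] == meta.at[b, "tissue"]
            same_i = meta.at[a, "individual"] == meta.at[b, "individual"]
            if same_t == same_i:
                continue
            pair_class = SAME_TISSUE if same_t else SAME_INDIVIDUAL
            sub = matrix[[a, b]].dropna()
            if len(sub) < min_shared:
                warnings.warn(
                    f"pair ({a}, {b}): only {len(sub)} shared rows, skipped",
                    stacklevel=2,
                )
                continue
            rho = stats.spearmanr(sub[a], sub[b]).statistic
            rows.append(
                {
                    "sample_a": a,
                    "sample_b": b,
                    "pair_class": pair_class,
                    "n_shared": len(sub),
                    "rho": float(rho),
                }
            )
    pairs = pd.DataFrame(rows, columns=["sample_a", "sample_b", "pair_class", "n_shared", "rho"])
    g1 = pairs.loc[pairs["pair_class"] == SAME_TISSUE, "rho"]
    g2 = pairs.loc[pairs["pair_class"] == SAME_INDIVIDUAL, "rho"]
    if len(g1) and len(g2):
        pvalue = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    else:
        pvalue = float("nan")
    return CorrelationSummary(pairs=pairs, pvalue=pvalue)


@dataclass
class TissueClustering:
    linkage: np.ndarray  # scipy linkage matrix (average linkage on 1 - rho)
    labels: list[str]  # tissue names in input (alphabetical) order
    excluded: list[str]

    def newick(self) -> str:
        """Dendrogram in Newick format with branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def render(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            children = ",".join(render(c, node.dist) for c in (node.left, node.right))
            return f"({children}):{length:.6g}"

        return render(tree, tree.dist) + ";"


def cluster_tissues(pcu_matrix: pd.DataFrame, min_shared: int = 3) -> TissueClustering:
    """Average-linkage clustering of tissues on 1 - Spearman rho of PCUs.

    Correlations use pairwise-complete events.  Tissues with fewer than
    ``min_shared`` shared events with some other tissue are excluded (with
    a warning) so the distance matrix is complete.  Columns are processed
    in alphabetical order, making tie handling deterministic.
    """
    tissues = sorted(pcu_matrix.columns)
    excluded = []
    for t in tissues:
        overlap = pcu_matrix[t].notna().to_numpy()[:, None] & pcu_matrix[
            [u for u in tissues if u != t]
        ].notna().to_numpy()
        if overlap.sum(axis=0).min() < min_shared:
            excluded.append(t)
    kept = [t for t in tissues if t not in excluded]
    if excluded:
        warnings.warn(f"tissues excluded from clustering: {excluded}", stacklevel=2)
    if len(kept) < 3:
        raise ValueError("need >= 3 tissues with sufficient shared events")
    k = len(kept)
    dist = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = pcu_matrix[[kept[i], kept[j]]].dropna()
            rho = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1]).statistic
            dist[i, j] = dist[j, i] = 1.0 - float(rho)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return TissueClustering(linkage=link, labels=kept, excluded=excluded)
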