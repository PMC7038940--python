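"""Genomic features of circRNA-flanking introns.

In gene orientation, a circRNA's upstream flanking intron ends at its
acceptor (3' back-splice site) and its downstream flanking intron starts
at its donor (5' back-splice site).  Members of an A5BS event therefore
share the upstream intron and differ in the downstream one; A3BS members
share the downstream intron.  This module assigns flanking introns from
gene models, counts overlapping Alu elements, samples control introns,
runs the rank-based comparisons across complexity classes and between
predominant and other event members, and computes a CSI-style score of
the strongest inverted-repeat pairing between two flanking introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .events import ABSEvent, A5BS, A3BS, CONSTITUTIVE
from .io import GeneModel

Key = tuple
Interval = tuple[int, int]

#: Which member-specific flanking intron differs within an event.
VARIABLE_SIDE = {A5BS: "downstream", A3BS: "upstream"}

_EXACT_N_MAX = 25  # switch rank tests from exact to normal approximation


@dataclass(frozen=True)
class FlankingAssignment:
    key: Key
    gene_id: str | None
    transcript: str | None
    upstream: Interval | None  # gene-orientation upstream intron, or None at a first exon
    downstream: Interval | None
    status: str  # ok | unannotated | ambiguous

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def assign_flanking_introns(
    keys: Iterable[Key], genes: Sequence[GeneModel]
) -> dict[Key, FlankingAssignment]:
    """Assign gene-orientation flanking introns to circRNAs.

    A circRNA matches a gene model when both back-splice sites coincide
    with exon boundaries of that model (same chrom and strand).  No match
    gives an ``unannotated`` record, matches in more than one gene an
    ``ambiguous`` one; among matching isoforms of one gene the model with
    the most exons wins.
    """
    start_map: dict[tuple, list[int]] = defaultdict(list)
    end_map: dict[tuple, list[int]] = defaultdict(list)
    for gi, g in enumerate(genes):
        for s, e in g.exons:
            start_map[(g.chrom, g.strand, s)].append(gi)
            end_map[(g.chrom, g.strand, e)].append(gi)

    out: dict[Key, FlankingAssignment] = {}
    for key in keys:
        key = tuple(key)
        chrom, strand, start, end = key
        cands = set(start_map.get((chrom, strand, start), ())) & set(
            end_map.get((chrom, strand, end), ())
        )
        if not cands:
            out[key] = FlankingAssignment(key, None, None, None, None, "unannotated")
            continue
        gene_ids = {genes[gi].gene_id for gi in cands}
        if len(gene_ids) > 1:
            out[key] = FlankingAssignment(key, None, None, None, None, "ambiguous")
            continue
        gi = min(cands, key=lambda i: (-len(genes[i].exons), genes[i].name or ""))
        g = genes[gi]
        i_start = next(i for i, (s, _) in enumerate(g.exons) if s == start)
        i_end = next(i for i, (_, e) in enumerate(g.exons) if e == end)
        left = (g.exons[i_start - 1][1], start) if i_start > 0 else None
        right = (end, g.exons[i_end + 1][0]) if i_end + 1 < len(g.exons) else None
        up, down = (left, right) if strand == "+" else (right, left)
        out[key] = FlankingAssignment(key, g.gene_id, g.name, up, down, "ok")
    return out


# ---------------------------------------------------------------------------
# Alu overlap counting


def build_alu_index(repeats: pd.DataFrame) -> dict[str, IntervalTree]:
    """Interval index of repeat elements keyed by chromosome."""
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in repeats.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), st) for s, e, st in zip(sub["start"], sub["end"], sub["strand"])
        )
    return trees


def count_alu(
    chrom: str, start: int, end: int, alu_index: Mapping[str, IntervalTree]
) -> tuple[int, int, int]:
    """(total, plus-strand, minus-strand) Alu elements overlapping >= 1 bp."""
    tree = alu_index.get(chrom)
    if tree is None:
        return 0, 0, 0
    hits = tree.overlap(start, end)
    plus = sum(1 for h in hits if h.data == "+")
    return len(hits), plus, len(hits) - plus


def flanking_feature_table(
    assignments: Mapping[Key, FlankingAssignment],
    alu_index: Mapping[str, IntervalTree],
) -> pd.DataFrame:
    """Per-circRNA, per-side intron features (length, Alu counts).

    One row per defined flanking intron of every successfully assigned
    circRNA; Alu orientation is reported relative to the gene strand.
    """
    rows = []
    for key, asn in assignments.items():
        if not asn.ok:
            continue
        chrom, strand, _, _ = key
        for side in ("upstream", "downstream"):
            iv = getattr(asn, side)
            if iv is None:
                continue
            total, plus, minus = count_alu(chrom, iv[0], iv[1], alu_index)
            same, opp = (plus, minus) if strand == "+" else (minus, plus)
            rows.append(
                {
                    "key": key,
                    "gene_id": asn.gene_id,
                    "side": side,
                    "start": iv[0],
                    "end": iv[1],
                    "length": iv[1] - iv[0],
                    "alu_count": total,
                    "alu_same": same,
                    "alu_opposite": opp,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "key", "gene_id", "side", "start", "end",
            "length", "alu_count", "alu_same", "alu_opposite",
        ],
    )


def sample_control_introns(
    assignments: Mapping[Key, FlankingAssignment],
    genes: Sequence[GeneModel],
    rng: np.random.Generator | int,
) -> tuple[dict[Key, Interval], list[Key]]:
    """Draw one control intron per circRNA from its host gene.

    Controls are drawn uniformly from the host gene's introns excluding
    the circRNA's own flanking introns, independently per circRNA.
    Returns the draws plus the circRNAs excluded for lack of a remaining
    intron.  Reproducible given the seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_id = {}
    for g in genes:  # prefer the most exon-rich model per gene, as in assignment
        cur = by_id.get(g.gene_id)
        if cur is None or len(g.exons) > len(cur.exons):
            by_id[g.gene_id] = g
    controls: dict[Key, Interval] = {}
    excluded: list[Key] = []
    for key in sorted(assignments):
        asn = assignments[key]
        if not asn.ok:
            continue
        flanking = {asn.upstream, asn.downstream}
        pool = [iv for iv in by_id[asn.gene_id].introns if iv not in flanking]
        if not pool:
            excluded.append(key)
            continue
        controls[key] = pool[int(rng.integers(len(pool)))]
    return controls, excluded


# ---------------------------------------------------------------------------
# rank-based comparisons


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney); exact for small n."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    exact = max(len(x), len(y)) <= _EXACT_N_MAX and len(np.unique(np.r_[x, y])) == len(x) + len(y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def signed_rank_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired samples; exact for small n."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    d = x - y
    exact = len(d) <= _EXACT_N_MAX and not np.any(d == 0) and len(np.unique(np.abs(d))) == len(d)
    res = stats.wilcoxon(
        x, y, alternative="two-sided",
        method="exact" if exact else "approx", correction=True,
    )
    return float(res.statistic), float(res.pvalue)


def complexity_classes(
    events: Sequence[ABSEvent], etype: str, classification: pd.Series
) -> dict[Key, str]:
    """Class per circRNA for one event type: high (>=3), low (=2), constitutive.

    circRNAs that participate only in events of the other type carry no
    class here and are omitted, matching a per-type comparison.
    """
    out: dict[Key, str] = {}
    for ev in events:
        if ev.etype != etype:
            continue
        for k in ev.hc_members:
            # a circRNA has at most one event per type
            out[k] = ev.complexity_class
    for k, label in classification.items():
        if label == CONSTITUTIVE:
            out[tuple(k)] = CONSTITUTIVE
    return out


def compare_by_complexity(
    feature_table: pd.DataFrame,
    classes: Mapping[Key, str],
    controls: pd.DataFrame | None = None,
    feature: str = "length",
    min_group: int = 3,
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of a feature across complexity classes.

    Run separately for upstream and downstream flanking introns; the
    optional ``controls`` table (columns ``key, length, alu_count, ...``)
    joins each side's comparison as the "control" class.  Groups with
    fewer than ``min_group`` members are skipped.  P-values are raw (no
    multiplicity correction).
    """
    order = ["high", "low", CONSTITUTIVE, "control"]
    rows = []
    for side in ("upstream", "downstream"):
        sub = feature_table[feature_table["side"] == side]
        groups: dict[str, np.ndarray] = {}
        for cls in ("high", "low", CONSTITUTIVE):
            mask = [classes.get(tuple(k)) == cls for k in sub["key"]]
            groups[cls] = sub.loc[mask, feature].to_numpy(dtype=float)
        if controls is not None and len(controls):
            groups["control"] = controls[feature].to_numpy(dtype=float)
        names = [c for c in order if c in groups and len(groups[c]) >= min_group]
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                stat, p = rank_sum_test(groups[a], groups[b])
                rows.append(
                    {
                        "side": side,
                        "feature": feature,
                        "class_a": a,
                        "class_b": b,
                        "n_a": len(groups[a]),
                        "n_b": len(groups[b]),
                        "median_a": float(np.median(groups[a])),
                        "median_b": float(np.median(groups[b])),
                        "statistic": stat,
                        "pvalue": p,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "side", "feature", "class_a", "class_b", "n_a", "n_b",
            "median_a", "median_b", "statistic", "pvalue",
        ],
    )


@dataclass
class PairedComparison:
    etype: str
    side: str
    feature: str
    pairs: pd.DataFrame  # event_id, predominant, other
    statistic: float
    pvalue: float
    n_dropped: int

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def compare_predominant_vs_other(
    events: Sequence[ABSEvent],
    predominant: Mapping[str, Key],
    feature_table: pd.DataFrame,
    feature: str = "length",
    other: str = "mean",
) -> dict[str, PairedComparison]:
    """Paired comparison of the member-specific flanking intron feature.

    A5BS members share the upstream intron, so their downstream introns
    are compared; A3BS events mirror this.  Within each event the
    predominant member's value is paired with the mean (or max, with
    ``other="best"``) of the other members' values; events missing a
    defined intron for any member are dropped and counted.  Two-sided
    Wilcoxon signed-rank per event type.
    """
    if other not in ("mean", "best"):
        raise ValueError(f"unknown 'other' summary {other!r}")
    lookup: dict[tuple, float] = {
        (tuple(k), s): float(v)
        for k, s, v in zip(feature_table["key"], feature_table["side"], feature_table[feature])
    }
    out: dict[str, PairedComparison] = {}
    for etype, side in VARIABLE_SIDE.items():
        typed = [e for e in events if e.etype == etype]
        if not typed:
            continue  # nothing of this type to compare
        rows, dropped = [], 0
        for ev in typed:
            pred = predominant.get(ev.event_id)
            if pred is None:
                dropped += 1
                continue
            vals = {k: lookup.get((k, side)) for k in ev.hc_members}
            others = [v for k, v in vals.items() if k != pred]
            if vals.get(pred) is None or any(v is None for v in others) or not others:
                dropped += 1
                continue
            summary = float(np.mean(others)) if other == "mean" else float(np.max(others))
            rows.append(
                {"event_id": ev.event_id, "predominant": vals[pred], "other": summary}
            )
        pairs = pd.DataFrame(rows, columns=["event_id", "predominant", "other"])
        if len(pairs) < 2:
            raise ValueError(
                f"{etype}: insufficient pairs for a signed-rank test (n={len(pairs)})"
            )
        if np.allclose(pairs["predominant"], pairs["other"]):
            stat, p = float("nan"), 1.0  # all differences zero: null center
        else:
            stat, p = signed_rank_test(pairs["predominant"], pairs["other"])
        out[etype] = PairedComparison(
            etype=etype, side=side, feature=feature,
            pairs=pairs, statistic=stat, pvalue=p, n_dropped=dropped,
        )
    return out


def cumulative_frequency(values) -> pd.DataFrame:
    """Empirical cumulative frequency table for export/plotting."""
    v = np.sort(np.asarray(values, dtype=float))
    return pd.DataFrame(
        {"value": v, "cumulative_frequency": np.arange(1, len(v) + 1) / len(v)}
    )


# ---------------------------------------------------------------------------
# CSI: complementary-sequence pairing between two flanking introns

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner():
    from Bio import Align

    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


_ALIGNER = None


def pair_score(u: str, d: str) -> float:
    """Smith-Waterman local alignment score of u against revcomp(d).

    Match +1, mismatch -1, gaps -2: the score of the best contiguous
    complementary pairing between the two segments as RNA.
    """
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = _aligner()
    if not u or not d:
        return 0.0
    return float(_ALIGNER.score(u.upper(), reverse_complement(d).upper()))


@dataclass(frozen=True)
class Segment:
    start: int
    end: int
    strand: str  # annotation strand of the repeat element
    seq: str


@dataclass
class CSIScore:
    csi: float
    pair: tuple[Segment, Segment] | None  # (upstream segment, downstream segment)
    pair_score: float
    symmetry: float
    competition: float
    n_pairs: int


def alu_segments(
    chrom: str,
    intron: Interval,
    alu_index: Mapping[str, IntervalTree],
    sequences: Mapping[str, str],
    cap: int = 400,
) -> list[Segment]:
    """Alu-overlapping subsequences of an intron, capped at ``cap`` bp."""
    tree = alu_index.get(chrom)
    seq = sequences[chrom]
    if tree is None:
        return []
    segs = []
    for hit in sorted(tree.overlap(*intron)):
        s, e = max(hit.begin, intron[0]), min(hit.end, intron[1])
        segs.append(Segment(s, min(e, s + cap), hit.data, seq[s : min(e, s + cap)]))
    return segs


def compute_csi(
    chrom: str,
    upstream: Interval,
    downstream: Interval,
    alu_index: Mapping[str, IntervalTree],
    sequences: Mapping[str, str],
    cap: int = 400,
) -> CSIScore:
    """CSI-style pairing score between two flanking introns.

    Candidate pairs are (upstream segment u, downstream segment d) whose
    repeat elements lie on opposite annotation strands (inverted-repeat
    logic).  For a pair, S is the local complementary alignment score,
    the symmetry weight min(|u|,|d|)/max(|u|,|d|) penalizes asymmetric
    pairings, and the alternative partners of u and of d compete:

        CSI(u, d) = S * symmetry / max(1, 1 + competition - S)

    where competition sums the scores of the alternative pairs sharing u
    or d; a pair that outscores its competitors keeps its full weighted
    score.  The reported score is the maximum over candidate pairs; a
    single pair with no competitors reduces to S * symmetry.
    """
    us = alu_segments(chrom, upstream, alu_index, sequences, cap)
    ds = alu_segments(chrom, downstream, alu_index, sequences, cap)
    pairs = [
        (i, j)
        for i, u in enumerate(us)
        for j, d in enumerate(ds)
        if u.strand != d.strand
    ]
    if not pairs:
        return CSIScore(0.0, None, 0.0, 0.0, 0.0, 0)
    S = np.zeros((len(us), len(ds)))
    for i, j in pairs:
        S[i, j] = pair_score(us[i].seq, ds[j].seq)
    row = S.sum(axis=1)
    col = S.sum(axis=0)
    best = CSIScore(-1.0, None, 0.0, 0.0, 0.0, len(pairs))
    for i, j in pairs:
        s = S[i, j]
        sym_lens = (len(us[i].seq), len(ds[j].seq))
        symmetry = min(sym_lens) / max(sym_lens) if max(sym_lens) else 0.0
        competition = row[i] + col[j] - 2.0 * s  # partners of u plus partners of d
        csi = s * symmetry / max(1.0, 1.0 + competition - s)
        if csi > best.csi:
            best = CSIScore(
                csi=float(csi),
                pair=(us[i], ds[j]),
                pair_score=float(s),
                symmetry=float(symmetry),
                competition=float(competition),
                n_pairs=len(pairs),
            )
    return best
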