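"""Alternative back-splicing (ABS) event calling and circRNA classification.

An ABS event is a group of >=2 circRNAs sharing a back-splice site on the
same chromosome and strand: a shared 3' (acceptor) site defines an A5BS
event (alternative 5' back-splicing, several donors), a shared 5' (donor)
site an A3BS event.  Each circRNA has exactly one acceptor and one donor,
so it belongs to at most one A5BS and at most one A3BS event.

Candidate events are formed over all circRNAs, but the high-confidence
event rule and complexity consider only high-confidence members (>= 0.1
RPM in at least one tissue); low-confidence members are kept as auxiliary
context.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import defaultdict
from typing import Iterable, Sequence

import pandas as pd

from .io import acceptor_pos, donor_pos

A5BS = "A5BS"
A3BS = "A3BS"
BOTH = "A5BS&A3BS"
CONSTITUTIVE = "constitutive"

#: Classification labels, mutually exclusive per circRNA.
LABELS = (A5BS, A3BS, BOTH, CONSTITUTIVE)

Key = tuple  # (chrom, strand, start, end)


@dataclass(frozen=True)
class ABSEvent:
    """A group of circRNAs sharing one back-splice site.

    ``members`` holds every candidate member, ``hc_members`` only the
    high-confidence ones; complexity is the number of high-confidence
    members.  Event ids are deterministic: ``{type}:{chrom}:{strand}:{site}``.
    """

    etype: str
    chrom: str
    strand: str
    site: int
    members: tuple[Key, ...]
    hc_members: tuple[Key, ...]

    @property
    def event_id(self) -> str:
        return f"{self.etype}:{self.chrom}:{self.strand}:{self.site}"

    @property
    def complexity(self) -> int:
        return len(self.hc_members)

    @property
    def complexity_class(self) -> str:
        return "high" if self.complexity >= 3 else "low"


def _keys_frame(keys: Iterable[Key]) -> pd.DataFrame:
    df = pd.DataFrame(list(keys), columns=["chrom", "strand", "start", "end"])
    df["acceptor"] = [
        acceptor_pos(s, a, b) for s, a, b in zip(df["strand"], df["start"], df["end"])
    ]
    df["donor"] = [
        donor_pos(s, a, b) for s, a, b in zip(df["strand"], df["start"], df["end"])
    ]
    return df


def group_events(
    keys: Iterable[Key] | pd.Index, high_confidence: pd.Series | None = None
) -> list[ABSEvent]:
    """Group circRNAs into candidate A5BS/A3BS events by shared sites.

    ``keys`` are circRNA keys (e.g. the index of an expression matrix);
    ``high_confidence`` is an optional boolean Series over the same keys
    (default: all high-confidence).  Groups of size 1 are not events.
    """
    keys = [tuple(k) for k in keys]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate circRNA keys")
    df = _keys_frame(keys)
    if high_confidence is None:
        hc = dict.fromkeys(keys, True)
    else:
        hc = {tuple(k): bool(v) for k, v in high_confidence.items()}

    events: list[ABSEvent] = []
    for etype, site_col in ((A5BS, "acceptor"), (A3BS, "donor")):
        grouped: dict[tuple, list[Key]] = defaultdict(list)
        for row, key in zip(df.itertuples(index=False), keys):
            grouped[(row.chrom, row.strand, getattr(row, site_col))].append(key)
        for (chrom, strand, site), members in grouped.items():
            if len(members) < 2:
                continue
            members = tuple(sorted(members))
            events.append(
                ABSEvent(
                    etype=etype,
                    chrom=chrom,
                    strand=strand,
                    site=site,
                    members=members,
                    hc_members=tuple(k for k in members if hc[k]),
                )
            )
    events.sort(key=lambda e: (e.etype, e.chrom, e.strand, e.site))
    return events


def filter_high_confidence_events(events: Sequence[ABSEvent]) -> list[ABSEvent]:
    """Keep events with >=2 high-confidence members."""
    return [e for e in events if len(e.hc_members) >= 2]


def classify_circrnas(
    events: Sequence[ABSEvent], keys: Iterable[Key] | pd.Index
) -> pd.Series:
    """Label each high-confidence circRNA by ABS participation.

    ``events`` must already be high-confidence filtered; ``keys`` is the
    full set of high-confidence circRNA keys to label.  A circRNA in >=1
    A5BS and >=1 A3BS event is "A5BS&A3BS"; in only one type, that type;
    in no event, "constitutive".  The labels partition the key set.
    """
    keys = [tuple(k) for k in keys]
    in5: set[Key] = set()
    in3: set[Key] = set()
    for ev in events:
        target = in5 if ev.etype == A5BS else in3
        target.update(ev.hc_members)

    def label(k: Key) -> str:
        if k in in5 and k in in3:
            return BOTH
        if k in in5:
            return A5BS
        if k in in3:
            return A3BS
        return CONSTITUTIVE

    out = pd.Series(
        [label(k) for k in keys],
        index=pd.MultiIndex.from_tuples(keys, names=["chrom", "strand", "start", "end"]),
        name="label",
    )
    return out


def is_abs(labels: pd.Series, label_set: str = "abs") -> pd.Series:
    """Boolean mask for a label set: abs, a5bs, a3bs or both.

    "a5bs" and "a3bs" include "A5BS&A3BS" circRNAs, which belong to both.
    """
    sets = {
        "abs": {A5BS, A3BS, BOTH},
        "a5bs": {A5BS, BOTH},
        "a3bs": {A3BS, BOTH},
        "both": {BOTH},
    }
    try:
        wanted = sets[label_set]
    except KeyError:
        raise ValueError(f"unknown label set {label_set!r}") from None
    return labels.isin(wanted)


def complexity_summary(events: Sequence[ABSEvent]) -> pd.DataFrame:
    """Histogram of event complexity with low (=2) / high (>=3) classes."""
    counts = pd.Series([e.complexity for e in events]).value_counts().sort_index()
    out = counts.rename("n_events").rename_axis("complexity").reset_index()
    out["complexity_class"] = ["high" if c >= 3 else "low" for c in out["complexity"]]
    return out


def per_tissue_counts(
    matrix: pd.DataFrame, min_rpm: float = 0.1, scope: str = "per-tissue"
) -> pd.DataFrame:
    """Count ABS vs constitutive circRNAs tissue by tissue.

    ``scope="per-tissue"`` (default) re-evaluates the high-confidence rule
    within each tissue: a circRNA counts there when it reaches ``min_rpm``
    in that tissue, and an event needs two such members in that tissue.
    ``scope="global"`` uses the dataset-wide high-confidence flag and
    counts flagged circRNAs detected (RPM > 0) in the tissue.
    """
    if scope not in ("per-tissue", "global"):
        raise ValueError(f"unknown scope {scope!r}")
    global_hc = matrix.max(axis=1) >= min_rpm
    rows = []
    for tissue in matrix.columns:
        if scope == "per-tissue":
            hc = matrix[tissue] >= min_rpm
        else:
            hc = global_hc & (matrix[tissue] > 0)
        keys = matrix.index[hc]
        hc_events = filter_high_confidence_events(
            group_events(matrix.index, hc)
        )
        labels = classify_circrnas(hc_events, keys)
        n_abs = int((labels != CONSTITUTIVE).sum())
        rows.append(
            {
                "tissue": tissue,
                "n_circrnas": len(keys),
                "n_abs": n_abs,
                "n_constitutive": len(keys) - n_abs,
            }
        )
    return pd.DataFrame(rows)


def events_table(events: Sequence[ABSEvent]) -> pd.DataFrame:
    """Flatten events to a table for TSV export."""
    rows = [
        {
            "event_id": e.event_id,
            "type": e.etype,
            "chrom": e.chrom,
            "strand": e.strand,
            "shared_site": e.site,
            "complexity": e.complexity,
            "members": ";".join(f"{c}:{s}-{x}:{st}" for c, st, s, x in e.hc_members),
            "aux_members": ";".join(
                f"{c}:{s}-{x}:{st}"
                for c, st, s, x in e.members
                if (c, st, s, x) not in set(e.hc_members)
            ),
        }
        for e in events
    ]
    return pd.DataFrame(rows)
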