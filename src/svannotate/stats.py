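"""Callset-comparison statistics over merged SV events.

Four analyses: per-event support counts, per-callset type counts (every
sub-call counted separately), annotation summaries (events with at least
one annotation of a given source kind), and breakpoint concordance
(signed deviations of each callset's breakpoints from the per-event
median, for events supported by enough callsets and of a single type).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import MergedEvent, SourceKind, SVType
from .annotate import AnnotationResult
from .formats import CallSet
from .merge import reduce_caller_calls

__all__ = [
    "ConcordanceRow",
    "support_count",
    "support_histogram",
    "type_counts",
    "type_discordance",
    "annotation_summary",
    "breakpoint_concordance",
    "concordance_table",
    "deviation_histogram",
]


def support_count(event: MergedEvent) -> int:
    """Number of distinct callsets with a call in the event (type-blind)."""
    return event.support_count


def support_histogram(events: Sequence[MergedEvent]) -> pd.Series:
    """Events per support count; the values sum to ``len(events)``."""
    counts = pd.Series([ev.support_count for ev in events], dtype=int)
    hist = counts.value_counts().sort_index()
    hist.index.name = "support"
    hist.name = "n_events"
    return hist


def type_counts(callsets: Sequence[CallSet]) -> pd.DataFrame:
    """Calls per callset and SV type, each sub-call counted separately.

    Rows sum to each callset's record count.
    """
    columns = [t.value for t in SVType]
    table = pd.DataFrame(
        0, index=[cs.callset_id for cs in callsets], columns=columns, dtype=int
    )
    for cs in callsets:
        for rec in cs.records:
            table.loc[cs.callset_id, rec.svtype.value] += 1
    table.index.name = "callset_id"
    return table


def type_discordance(events: Sequence[MergedEvent]) -> tuple[int, int]:
    """Count events with conflicting SV types.

    Returns ``(n_cross_caller, n_within_caller)``: events where two
    members from *different* callsets disagree on type, and events where
    a single callset's own members span two or more types.  One event may
    count toward both.
    """
    n_cross = 0
    n_within = 0
    for ev in events:
        pairs = {(m.callset_id, m.svtype) for m in ev.members}
        if any(
            t1 != t2
            for c1, t1 in pairs
            for c2, t2 in pairs
            if c1 != c2
        ):
            n_cross += 1
        by_callset: dict[str, set[SVType]] = {}
        for cid, t in pairs:
            by_callset.setdefault(cid, set()).add(t)
        if any(len(types) > 1 for types in by_callset.values()):
            n_within += 1
    return n_cross, n_within


def annotation_summary(
    results: Sequence[AnnotationResult],
    sources: Sequence[tuple[str, SourceKind]],
) -> pd.DataFrame:
    """Events with >= 1 annotation, per source kind and per source file.

    BED/GFF sources are counted from the per-source name lists; VCF
    sources contribute through ``overlapped_vcf >= 1`` (file identity of
    VCF matches is not tracked per event, so VCF rows report the
    kind-level count).
    """
    rows = []
    kinds_seen = []
    for source_id, kind in sources:
        if kind is SourceKind.VCF:
            n = sum(1 for r in results if r.overlapped_vcf >= 1)
        else:
            n = sum(1 for r in results if r.names_by_source.get(source_id))
        rows.append({"source_id": source_id, "kind": kind.value, "n_events": n})
        kinds_seen.append(kind)
    for kind in (SourceKind.GFF, SourceKind.BED, SourceKind.VCF):
        ids = [s for s, k in sources if k is kind]
        if not ids:
            continue
        if kind is SourceKind.VCF:
            n = sum(1 for r in results if r.overlapped_vcf >= 1)
        else:
            n = sum(
                1
                for r in results
                if any(r.names_by_source.get(sid) for sid in ids)
            )
        rows.append({"source_id": "ALL", "kind": kind.value, "n_events": n})
    return pd.DataFrame(rows, columns=["source_id", "kind", "n_events"])


@dataclass(frozen=True)
class ConcordanceRow:
    """One callset's breakpoint deviation within one eligible event."""

    event_id: str
    callset_id: str
    d_start: float
    d_end: float
    svtype: SVType
    size: int  # reduced end - reduced start; not meaningful for TRA


def breakpoint_concordance(
    events: Sequence[MergedEvent],
    min_support: int = 4,
    median_over_subcalls: bool = False,
) -> list[ConcordanceRow]:
    """Per-callset signed deviations from the median event breakpoints.

    Eligible events are supported by at least ``min_support`` callsets
    with every member call of the same type.  Within an event each
    callset's sub-calls are reduced to (min start, max end); the median
    start/end are taken over the reduced per-callset pairs (even counts
    average the two middle values), and each callset contributes one row
    of signed deviations.  With ``median_over_subcalls`` the medians are
    computed over all raw sub-calls instead (the alternative reading of
    "all calls"); deviations stay per reduced callset pair.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    rows: list[ConcordanceRow] = []
    for ev in events:
        if ev.support_count < min_support or not ev.all_same_type:
            continue
        by_callset = ev.members_by_callset()
        reduced = {
            cid: reduce_caller_calls(calls) for cid, calls in by_callset.items()
        }
        if median_over_subcalls:
            med_start = float(np.median([m.start for m in ev.members]))
            med_end = float(np.median([m.end for m in ev.members]))
        else:
            med_start = float(np.median([s for s, _ in reduced.values()]))
            med_end = float(np.median([e for _, e in reduced.values()]))
        svtype = ev.members[0].svtype
        for cid in sorted(reduced):
            s, e = reduced[cid]
            rows.append(
                ConcordanceRow(
                    event_id=ev.event_id,
                    callset_id=cid,
                    d_start=s - med_start,
                    d_end=e - med_end,
                    svtype=svtype,
                    size=e - s,
                )
            )
    return rows


def concordance_table(rows: Sequence[ConcordanceRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "event_id": r.event_id,
                "callset_id": r.callset_id,
                "d_start": r.d_start,
                "d_end": r.d_end,
                "svtype": r.svtype.value,
                "size": r.size,
            }
            for r in rows
        ],
        columns=["event_id", "callset_id", "d_start", "d_end", "svtype", "size"],
    )


def deviation_histogram(
    rows: Sequence[ConcordanceRow],
    svtype: Optional[SVType] = None,
    size_range: Optional[tuple[int, int]] = None,
    callset_id: Optional[str] = None,
    bins: int | Sequence[float] = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of start deviations, filtered by type/size band/callset.

    ``size_range`` is inclusive on both ends (e.g. (400, 999) for the
    400-999 bp band); translocations are excluded whenever a size band is
    requested since no span is defined for them.  Returns numpy
    ``(counts, bin_edges)``.
    """
    selected = []
    for r in rows:
        if svtype is not None and r.svtype is not svtype:
            continue
        if callset_id is not None and r.callset_id != callset_id:
            continue
        if size_range is not None:
            if r.svtype is SVType.TRA:
                continue
            if not (size_range[0] <= r.size <= size_range[1]):
                continue
        selected.append(r.d_start)
    return np.histogram(np.asarray(selected, dtype=float), bins=bins)
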