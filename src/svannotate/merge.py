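"""Distance-based merging of SV callsets into events.

Two calls belong to the same event when they share both breakpoint
chromosomes and both breakpoints lie within ``max_dist`` of each other
(optionally also requiring the same SV type).  Events are the connected
components of this pairwise relation, so chains of mutually close calls
collapse into one event even when their extremes are further apart than
``max_dist`` — the simplest deterministic reading of a pairwise-distance
merge.
"""

from __future__ import annotations

from typing import Sequence

from .core import MergedEvent, SVRecord
from .formats import CallSet

__all__ = ["merge_callsets", "reduce_caller_calls"]


class _DisjointSet:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _median_int(values: list[int]) -> int:
    """Median of integers; even counts take the lower-rounded middle mean."""
    s = sorted(values)
    n = len(s)
    if n % 2:
        return s[n // 2]
    return (s[n // 2 - 1] + s[n // 2]) // 2


def merge_callsets(
    callsets: Sequence[CallSet],
    max_dist: int = 1000,
    type_specific: bool = False,
) -> list[MergedEvent]:
    """Merge N callsets into events.

    Calls a and b are connected iff ``chrom_a == chrom_b``,
    ``chrom2_a == chrom2_b``, ``|start_a - start_b| <= max_dist``,
    ``|end_a - end_b| <= max_dist`` and, with ``type_specific``, equal
    types (UNK only groups with UNK).  Events are connected components;
    the representative start/end are per-component medians of the member
    breakpoints (even counts round the middle mean toward the lower
    value).  Event ids are assigned in (chrom, start) order and the result
    is independent of callset input order.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    seen_ids: set[str] = set()
    for cs in callsets:
        if cs.callset_id in seen_ids:
            raise ValueError(f"duplicate callset_id {cs.callset_id!r}")
        seen_ids.add(cs.callset_id)

    records: list[SVRecord] = [r for cs in callsets for r in cs.records]
    # Canonical processing order removes any dependence on input order.
    order = sorted(
        range(len(records)),
        key=lambda i: (
            records[i].chrom,
            records[i].chrom2,
            records[i].start,
            records[i].end,
            records[i].callset_id,
            records[i].record_id,
        ),
    )

    groups: dict[tuple, list[int]] = {}
    for i in order:
        r = records[i]
        key = (r.chrom, r.chrom2) + ((r.svtype,) if type_specific else ())
        groups.setdefault(key, []).append(i)

    dsu = _DisjointSet(len(records))
    for idxs in groups.values():
        # idxs are start-sorted; only a bounded window can satisfy the
        # start condition, the end condition is checked explicitly.
        for a_pos, i in enumerate(idxs):
            ri = records[i]
            for j in idxs[a_pos + 1:]:
                rj = records[j]
                if rj.start - ri.start > max_dist:
                    break
                if abs(rj.end - ri.end) <= max_dist:
                    dsu.union(i, j)

    components: dict[int, list[int]] = {}
    for i in order:
        components.setdefault(dsu.find(i), []).append(i)

    proto: list[MergedEvent] = []
    for member_idxs in components.values():
        members = sorted(
            (records[i] for i in member_idxs),
            key=lambda m: (m.callset_id, m.start, m.end, m.svtype.value, m.record_id),
        )
        first = members[0]
        proto.append(
            MergedEvent(
                event_id="",
                chrom=first.chrom,
                chrom2=first.chrom2,
                start=_median_int([m.start for m in members]),
                end=_median_int([m.end for m in members]),
                members=tuple(members),
            )
        )

    proto.sort(
        key=lambda ev: (
            ev.chrom,
            ev.start,
            ev.end,
            ev.chrom2,
            tuple((m.callset_id, m.record_id) for m in ev.members),
        )
    )
    for i, ev in enumerate(proto):
        ev.event_id = f"event_{i:06d}"
    return proto


def reduce_caller_calls(calls: Sequence[SVRecord]) -> tuple[int, int]:
    """Collapse one callset's sub-calls in one event to a single span.

    Returns (minimum start, maximum end) over the calls — the reduction
    used before breakpoint-concordance comparisons when a single caller
    contributed several sub-calls to an event.
    """
    if not calls:
        raise ValueError("reduce_caller_calls requires at least one call")
    return min(c.start for c in calls), max(c.end for c in calls)
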