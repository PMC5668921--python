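"""Core domain model for structural-variant (SV) comparison and annotation.

Coordinate conventions
----------------------
All positions inside the package are **0-based**.  ``start`` and ``end`` on
:class:`SVRecord` and :class:`MergedEvent` are breakpoint *positions*: for a
deletion called at VCF POS=1000 with END=2000 the record carries
``start=999, end=1999`` and its reference span is the half-open interval
``[start, end + 1)``.  :class:`GenomicFeature` intervals are half-open
``[start, end)`` exactly as in BED.  Conversions from/to the 1-based VCF and
GFF representations happen only in :mod:`svannotate.formats`.

Translocations (TRA) carry two breakpoints, ``(chrom, start)`` and
``(chrom2, end)``; a reference span is undefined for them, and any operation
that would need one must work from the breakpoints alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Any, Iterable, Optional

from intervaltree import IntervalTree

__all__ = [
    "SVType",
    "SourceKind",
    "SVRecord",
    "GenomicFeature",
    "MergedEvent",
    "AnnotationConfig",
    "IntervalIndex",
    "normalize_type",
    "build_index",
]


class SVType(Enum):
    """The five SV classes distinguished by the overlap schema, plus UNK."""

    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    TRA = "TRA"
    UNK = "UNK"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class SourceKind(Enum):
    """Kind of file an annotation came from."""

    BED = "BED"
    GFF = "GFF"
    VCF = "VCF"


# Aliases keyed on the token before the first ':' of an SVTYPE/ALT string.
# BND/CTX are breakend/translocation spellings; ALU/LINE1/SVA are mobile
# element insertion classes some callers emit as types.
_TYPE_ALIASES: dict[str, SVType] = {
    "DEL": SVType.DEL,
    "DUP": SVType.DUP,
    "INS": SVType.INS,
    "ALU": SVType.INS,
    "LINE1": SVType.INS,
    "SVA": SVType.INS,
    "INV": SVType.INV,
    "TRA": SVType.TRA,
    "BND": SVType.TRA,
    "CTX": SVType.TRA,
}


def normalize_type(raw: str) -> SVType:
    """Map a caller-reported SV type string onto the canonical enum.

    The decision is case-insensitive and based on the prefix before the
    first ``':'`` (so ``"DUP:TANDEM"`` → DUP, ``"DEL:ME:ALU"`` → DEL).
    Unrecognized strings map to :attr:`SVType.UNK`; the function is total
    and never raises.
    """
    head = str(raw).strip().upper().split(":", 1)[0]
    return _TYPE_ALIASES.get(head, SVType.UNK)


@dataclass
class SVRecord:
    """One SV call from one callset.

    ``start`` and ``end`` are 0-based breakpoint positions with
    ``end >= start`` and ``chrom2 == chrom`` for every non-TRA record;
    ``end == start`` is the point-insertion case.  ``svlen`` is the signed
    length in bp (negative for deletions) when the source reported or
    implied one.
    """

    chrom: str
    start: int
    end: int
    svtype: SVType
    chrom2: str = ""
    svlen: Optional[int] = None
    record_id: str = ""
    callset_id: str = ""
    raw_info: dict[str, str] = field(default_factory=dict, compare=False)
    raw_line: Optional[str] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chrom2:
            self.chrom2 = self.chrom
        if self.start < 0:
            raise ValueError(f"negative start on record {self.record_id!r}")
        if self.svtype is not SVType.TRA:
            if self.chrom2 != self.chrom:
                raise ValueError(
                    f"non-TRA record {self.record_id!r} has chrom2 "
                    f"{self.chrom2!r} != chrom {self.chrom!r}"
                )
            if self.end < self.start:
                raise ValueError(
                    f"record {self.record_id!r} has end {self.end} < start {self.start}"
                )

    @property
    def size(self) -> int:
        """Unsigned size in bp: |svlen| when known, else end - start."""
        if self.svlen is not None:
            return abs(self.svlen)
        return self.end - self.start


@dataclass(frozen=True)
class GenomicFeature:
    """A named half-open interval from a BED/GFF/annotation-VCF source."""

    chrom: str
    start: int
    end: int
    name: str
    source_id: str
    source_kind: SourceKind

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"feature {self.name!r} has end {self.end} <= start {self.start}"
            )
        if not self.name:
            raise ValueError("feature name must be non-empty")


@dataclass
class MergedEvent:
    """A cluster of calls from >= 1 callsets treated as one variant site.

    ``start``/``end`` are the representative (median) breakpoints; members
    keep their own coordinates.  All members share ``chrom`` and ``chrom2``.
    """

    event_id: str
    chrom: str
    start: int
    end: int
    members: tuple[SVRecord, ...]
    chrom2: str = ""
    raw_line: Optional[str] = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.chrom2:
            self.chrom2 = self.chrom
        if not self.members:
            raise ValueError(f"event {self.event_id!r} has no members")
        for m in self.members:
            if (m.chrom, m.chrom2) != (self.chrom, self.chrom2):
                raise ValueError(
                    f"event {self.event_id!r}: member {m.record_id!r} chromosome "
                    "pair differs from the event's"
                )

    @property
    def support_count(self) -> int:
        """Number of distinct callsets contributing at least one member."""
        return len({m.callset_id for m in self.members})

    @property
    def callset_ids(self) -> list[str]:
        return sorted({m.callset_id for m in self.members})

    def members_by_callset(self) -> dict[str, list[SVRecord]]:
        out: dict[str, list[SVRecord]] = {}
        for m in self.members:
            out.setdefault(m.callset_id, []).append(m)
        return out

    @property
    def types(self) -> Counter:
        """Multiset of member SV types (sub-calls counted separately)."""
        return Counter(m.svtype for m in self.members)

    @property
    def modal_type(self) -> Optional[SVType]:
        """Most common member type, or None when the top count is tied."""
        ranked = self.types.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return None
        return ranked[0][0]

    @property
    def all_same_type(self) -> bool:
        return len(self.types) == 1


@dataclass
class AnnotationConfig:
    """Parameters of the annotation pass.

    wobble
        Maximum positional slack in bp when matching breakpoints or
        expanding DEL/DUP spans (default 1000, i.e. 1 kb).
    require_type_match_for_vcf
        When True, a known-SV VCF entry only matches an event of the same
        type.  Off by default: merged events are heterogeneous.
    either_breakpoint
        Relaxation: a known-SV entry matches when either breakpoint is
        within ``wobble`` instead of requiring both.
    """

    wobble: int = 1000
    require_type_match_for_vcf: bool = False
    either_breakpoint: bool = False

    def __post_init__(self) -> None:
        if self.wobble < 0:
            raise ValueError("wobble must be >= 0")


class IntervalIndex:
    """Per-chromosome balanced interval index over half-open intervals.

    Queries return the payloads of every stored interval ``[s, e)`` that
    intersects the half-open query window, sorted by
    ``(start, end, insertion order)`` so results are deterministic and
    independent of how the index was populated.  Duplicate coordinates are
    preserved.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._counter = 0

    def add(self, chrom: str, start: int, end: int, payload: Any) -> None:
        if end <= start:
            raise ValueError(
                f"invalid interval {chrom}:{start}-{end} for payload {payload!r}: "
                "end must be > start"
            )
        self._trees.setdefault(chrom, IntervalTree()).addi(
            start, end, (self._counter, payload)
        )
        self._counter += 1

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def query(self, chrom: str, start: int, end: int) -> list[Any]:
        """Payloads of stored intervals intersecting ``[start, end)``.

        A degenerate window with ``end == start`` is widened to
        ``[start, start + 1)`` (point query).  An unknown chromosome yields
        an empty list.
        """
        if end < start:
            raise ValueError(f"query end {end} < start {start}")
        if end == start:
            end = start + 1
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(
            tree.overlap(start, end), key=lambda iv: (iv.begin, iv.end, iv.data[0])
        )
        return [iv.data[1] for iv in hits]


def build_index(items: Iterable[tuple[str, int, int, Any]]) -> IntervalIndex:
    """Build an :class:`IntervalIndex` from ``(chrom, start, end, payload)``.

    Raises ``ValueError`` naming the offending item for any interval with
    ``end <= start`` (callers widen point queries, not stored intervals).
    """
    index = IntervalIndex()
    for chrom, start, end, payload in items:
        index.add(chrom, start, end, payload)
    return index
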