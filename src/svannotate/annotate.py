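"""Type-specific assignment of genomic features and known SVs to events.

The overlap schema distinguishes span types from breakpoint types:

* deletions and duplications occupy a reference span, so a feature is
  assigned when it overlaps the span widened by the wobble distance on
  both sides;
* insertions, inversions and translocations are treated through their two
  breakpoints only: a feature is assigned when it lies within the wobble
  distance of either breakpoint.

Known-SV (annotation VCF) entries are matched breakpoint-to-breakpoint:
by default both the start and the end of the annotation SV must lie
within the wobble distance of the event's breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    AnnotationConfig,
    GenomicFeature,
    IntervalIndex,
    MergedEvent,
    SVRecord,
    SVType,
)
from .formats import dedup_annotation_sites

__all__ = [
    "AnnotationResult",
    "build_feature_index",
    "build_annotation_vcf_index",
    "assign_features",
    "match_annotation_vcfs",
    "annotate_events",
]

_SPAN_TYPES = frozenset({SVType.DEL, SVType.DUP})


@dataclass
class AnnotationResult:
    """Annotation outcome for one event.

    ``names`` backs the ``overlapped_Annotations`` INFO list and
    ``total_annotations`` its count; ``overlapped_vcf`` is the number of
    annotation VCF files containing at least one matching SV.
    ``names_by_source`` retains which input file each name came from (used
    by the per-source annotation summary).
    """

    event_id: str
    overlapped_vcf: int = 0
    names: tuple[str, ...] = ()
    names_by_source: dict[str, tuple[str, ...]] = field(default_factory=dict)
    matched_sites: int = 0

    @property
    def total_annotations(self) -> int:
        return len(self.names)


def build_feature_index(
    feature_sets: Sequence[Sequence[GenomicFeature]],
) -> IntervalIndex:
    """Index features from several files; payloads keep source order."""
    index = IntervalIndex()
    order = 0
    for set_idx, features in enumerate(feature_sets):
        for feat in features:
            index.add(feat.chrom, feat.start, feat.end, (set_idx, order, feat))
            order += 1
    return index


def _event_query_windows(
    event: MergedEvent | SVRecord, wobble: int
) -> list[tuple[str, int, int]]:
    """Half-open query windows implementing the type-specific schema."""
    if isinstance(event, MergedEvent):
        svtype = event.modal_type  # tie -> None -> breakpoint-only path
    else:
        svtype = event.svtype
    if svtype in _SPAN_TYPES and event.chrom2 == event.chrom:
        # span [start, end+1) widened by the wobble on both sides
        return [(event.chrom, max(0, event.start - wobble), event.end + 1 + wobble)]
    # breakpoint windows, closed at distance `wobble` from each breakpoint
    return [
        (event.chrom, max(0, event.start - wobble), event.start + wobble + 1),
        (event.chrom2, max(0, event.end - wobble), event.end + wobble + 1),
    ]


def _hit_features(
    event: MergedEvent | SVRecord, index: IntervalIndex, wobble: int
) -> list[tuple[int, int, GenomicFeature]]:
    hits: dict[int, tuple[int, int, GenomicFeature]] = {}
    for chrom, lo, hi in _event_query_windows(event, wobble):
        for set_idx, order, feat in index.query(chrom, lo, hi):
            hits.setdefault(order, (set_idx, order, feat))
    # source-file order, then interval order within each source
    return sorted(
        hits.values(), key=lambda t: (t[0], t[2].start, t[2].end, t[1])
    )


def assign_features(
    event: MergedEvent | SVRecord, index: IntervalIndex, wobble: int
) -> list[str]:
    """Names of the features assigned to ``event`` under the type schema.

    DEL/DUP events collect features overlapping
    ``[start - wobble, end + 1 + wobble)``; all other types (including
    UNK and mixed-type events with a tied modal type) collect the union
    of features within ``wobble`` of either breakpoint.  Names are
    deduplicated, first seen in source-file then interval order.
    """
    names: list[str] = []
    seen: set[str] = set()
    for _, _, feat in _hit_features(event, index, wobble):
        if feat.name not in seen:
            seen.add(feat.name)
            names.append(feat.name)
    return names


def build_annotation_vcf_index(records: Sequence[SVRecord]) -> IntervalIndex:
    """Index one annotation VCF's sites by both breakpoints.

    Each record is inserted at ``(chrom, start)`` and ``(chrom2, end)`` so
    a windowed query around either event breakpoint finds every candidate.
    """
    unique = dedup_annotation_sites(records)
    index = IntervalIndex()
    for i, rec in enumerate(unique):
        index.add(rec.chrom, rec.start, rec.start + 1, (i, rec))
        index.add(rec.chrom2, rec.end, rec.end + 1, (i, rec))
    return index


def _vcf_site_matches(
    event: MergedEvent | SVRecord,
    rec: SVRecord,
    max_dist: int,
    require_type: bool,
    either_breakpoint: bool,
) -> bool:
    if require_type:
        types = (
            set(event.types) if isinstance(event, MergedEvent) else {event.svtype}
        )
        if rec.svtype not in types:
            return False
    start_ok = rec.chrom == event.chrom and abs(rec.start - event.start) <= max_dist
    end_ok = rec.chrom2 == event.chrom2 and abs(rec.end - event.end) <= max_dist
    if either_breakpoint:
        return start_ok or end_ok
    return start_ok and end_ok


def match_annotation_vcfs(
    event: MergedEvent | SVRecord,
    ann_indexes: Sequence[IntervalIndex],
    max_dist: int,
    require_type: bool = False,
    either_breakpoint: bool = False,
) -> tuple[int, int]:
    """Match an event against known-SV VCF files.

    Returns ``(overlapped_vcf, matched_sites)``: the number of files with
    at least one matching site and the total matching sites across files.
    A site matches when the chromosome pairs agree and both breakpoints
    (or either, with ``either_breakpoint``) lie within ``max_dist``.
    """
    n_files = 0
    n_sites = 0
    for index in ann_indexes:
        candidates: dict[int, SVRecord] = {}
        for chrom, pos in ((event.chrom, event.start), (event.chrom2, event.end)):
            lo = max(0, pos - max_dist)
            for i, rec in index.query(chrom, lo, pos + max_dist + 1):
                candidates.setdefault(i, rec)
        matches = sum(
            1
            for rec in candidates.values()
            if _vcf_site_matches(event, rec, max_dist, require_type, either_breakpoint)
        )
        if matches:
            n_files += 1
            n_sites += matches
    return n_files, n_sites


def annotate_events(
    events: Sequence[MergedEvent | SVRecord],
    feature_sets: Sequence[Sequence[GenomicFeature]] = (),
    ann_vcfs: Sequence[Sequence[SVRecord]] = (),
    config: Optional[AnnotationConfig] = None,
) -> list[AnnotationResult]:
    """Annotate every event with features and known-SV matches.

    ``feature_sets`` is one list of :class:`GenomicFeature` per BED/GFF
    input file; ``ann_vcfs`` is one list of :class:`SVRecord` per
    annotation VCF.  Results align with the input event order.
    ``total_annotations`` counts BED/GFF feature names only; VCF matches
    are reported via ``overlapped_vcf``.
    """
    config = config or AnnotationConfig()
    feat_index = build_feature_index(feature_sets)
    ann_indexes = [build_annotation_vcf_index(recs) for recs in ann_vcfs]
    results: list[AnnotationResult] = []
    for event in events:
        hits = _hit_features(event, feat_index, config.wobble)
        names: list[str] = []
        seen: set[str] = set()
        by_source: dict[str, list[str]] = {}
        for _, _, feat in hits:
            if feat.name not in seen:
                seen.add(feat.name)
                names.append(feat.name)
            src_names = by_source.setdefault(feat.source_id, [])
            if feat.name not in src_names:
                src_names.append(feat.name)
        n_files, n_sites = match_annotation_vcfs(
            event,
            ann_indexes,
            config.wobble,
            require_type=config.require_type_match_for_vcf,
            either_breakpoint=config.either_breakpoint,
        )
        event_id = (
            event.event_id if isinstance(event, MergedEvent) else event.record_id
        )
        results.append(
            AnnotationResult(
                event_id=event_id,
                overlapped_vcf=n_files,
                names=tuple(names),
                names_by_source={k: tuple(v) for k, v in by_source.items()},
                matched_sites=n_sites,
            )
        )
    return results
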