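"""Independent brute-force oracles and random-instance generators.

These implementations deliberately avoid the package's interval index and
annotation code paths: plain quadratic loops over events x annotations,
used to cross-check the indexed implementations.
"""

from __future__ import annotations

import random
from collections import Counter

from svannotate.core import GenomicFeature, MergedEvent, SourceKind, SVRecord, SVType

SPAN_TYPES = {SVType.DEL, SVType.DUP}
NON_TRA = [SVType.DEL, SVType.DUP, SVType.INS, SVType.INV, SVType.UNK]


def _event_fields(event):
    if isinstance(event, MergedEvent):
        counts = Counter(m.svtype for m in event.members).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            svtype = None  # tied modal type -> breakpoint-only path
        else:
            svtype = counts[0][0]
    else:
        svtype = event.svtype
    return svtype, event.chrom, event.start, event.chrom2, event.end


def _feature_overlaps_event(feat, event, wobble):
    svtype, chrom, start, chrom2, end = _event_fields(event)
    if svtype in SPAN_TYPES and chrom2 == chrom:
        return (
            feat.chrom == chrom
            and feat.start < end + 1 + wobble
            and feat.end > start - wobble
        )
    for c, pos in ((chrom, start), (chrom2, end)):
        if feat.chrom == c and feat.start < pos + wobble + 1 and feat.end > pos - wobble:
            return True
    return False


def brute_force_annotate(events, feature_sets, ann_vcfs, wobble):
    """All-pairs annotation: list of (names, overlapped_vcf, matched_sites)."""
    out = []
    for event in events:
        names = []
        for feats in feature_sets:
            for feat in sorted(feats, key=lambda f: (f.start, f.end)):
                if _feature_overlaps_event(feat, event, wobble):
                    if feat.name not in names:
                        names.append(feat.name)
        _, chrom, start, chrom2, end = _event_fields(event)
        n_files = n_sites = 0
        for recs in ann_vcfs:
            unique, seen = [], set()
            for r in recs:
                key = (r.chrom, r.start, r.chrom2, r.end, r.svtype)
                if key not in seen:
                    seen.add(key)
                    unique.append(r)
            matches = sum(
                1
                for r in unique
                if r.chrom == chrom
                and r.chrom2 == chrom2
                and abs(r.start - start) <= wobble
                and abs(r.end - end) <= wobble
            )
            if matches:
                n_files += 1
                n_sites += matches
        out.append((names, n_files, n_sites))
    return out


def linear_scan(items, chrom, qstart, qend):
    """Reference interval query: insertion-ordered scan, then spec order."""
    if qend == qstart:
        qend = qstart + 1
    hits = [
        (s, e, i, payload)
        for i, (c, s, e, payload) in enumerate(items)
        if c == chrom and s < qend and e > qstart
    ]
    hits.sort(key=lambda t: t[:3])
    return [payload for *_, payload in hits]


def random_event(rng: random.Random, chroms=("chr1", "chr2", "chr3")) -> MergedEvent:
    chrom = rng.choice(chroms)
    if rng.random() < 0.2:  # translocation-only event
        chrom2 = rng.choice([c for c in chroms if c != chrom])
        start = rng.randrange(0, 100_000)
        end = rng.randrange(0, 100_000)
        types = [SVType.TRA] * rng.randint(1, 3)
    else:
        chrom2 = chrom
        start = rng.randrange(0, 100_000)
        end = start + rng.randrange(0, 3000)
        types = [rng.choice(NON_TRA) for _ in range(rng.randint(1, 3))]
    members = []
    for k, t in enumerate(types):
        m_start = max(0, start + rng.randint(-200, 200))
        if t is SVType.TRA:
            m_end = max(0, end + rng.randint(-200, 200))
        else:
            m_end = max(m_start, end + rng.randint(-200, 200))
        members.append(
            SVRecord(
                chrom=chrom,
                start=m_start,
                end=m_end,
                svtype=t,
                chrom2=chrom2,
                record_id=f"m{k}",
                callset_id=f"cs{k % 2}",
            )
        )
    return MergedEvent(
        event_id=f"ev{rng.randrange(10**6)}",
        chrom=chrom,
        chrom2=chrom2,
        start=start,
        end=end,
        members=tuple(members),
    )


def random_features(rng: random.Random, n, source_id, kind, chroms=("chr1", "chr2", "chr3")):
    feats = []
    for i in range(n):
        start = rng.randrange(0, 100_000)
        feats.append(
            GenomicFeature(
                chrom=rng.choice(chroms),
                start=start,
                end=start + rng.randrange(1, 2000),
                name=f"{source_id}_f{i}",
                source_id=source_id,
                source_kind=kind,
            )
        )
    return feats


def random_ann_records(rng: random.Random, n, chroms=("chr1", "chr2", "chr3")):
    recs = []
    for i in range(n):
        chrom = rng.choice(chroms)
        t = rng.choice(NON_TRA)
        start = rng.randrange(0, 100_000)
        end = start if t is SVType.INS else start + rng.randrange(0, 3000)
        recs.append(
            SVRecord(
                chrom=chrom,
                start=start,
                end=end,
                svtype=t,
                record_id=f"a{i}",
                callset_id="ann",
            )
        )
    return recs


def random_instance(rng: random.Random, max_events=40, max_features=60):
    events = [random_event(rng) for _ in range(rng.randint(1, max_events))]
    feature_sets = [
        random_features(rng, rng.randint(1, max_features // 2), "bedA", SourceKind.BED),
        random_features(rng, rng.randint(1, max_features // 2), "gffB", SourceKind.GFF),
    ]
    ann_vcfs = [random_ann_records(rng, rng.randint(0, 30))]
    return events, feature_sets, ann_vcfs
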