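"""Synthetic SV study generator with an exact truth ledger.

Emulates, at toy scale, the inputs of a multi-caller SV comparison: a set
of true SVs on a small genome, several noisy callsets derived from them
(per-callset detection, breakpoint jitter, type confusion, false
positives), gene/repeat annotation files and a known-SV VCF.  A ledger
records which truth SVs were detected by which callset and which should
be annotated by what, so merging and annotation results can be checked
exactly.

Placement discipline is what makes the ledger exact: truth SVs keep a
minimum spacing from each other, and false positives are rejected away
from every truth breakpoint *and* every previously placed false positive
(across all callsets), so no spurious merges can occur as long as the
jitter stays well below the merge distance.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import GenomicFeature, SourceKind, SVRecord, SVType
from .formats import CallSet, dedup_annotation_sites, write_sv_vcf

__all__ = [
    "SimulationParams",
    "FeatureBundle",
    "SimulatedStudy",
    "generate_truth",
    "perturb_callset",
    "generate_features",
    "simulate",
    "write_study",
]

_NON_TRA = (SVType.DEL, SVType.DUP, SVType.INS, SVType.INV)


def _default_type_weights() -> dict[SVType, float]:
    return {
        SVType.DEL: 0.40,
        SVType.INS: 0.30,
        SVType.DUP: 0.12,
        SVType.INV: 0.12,
        SVType.TRA: 0.06,
    }


def _default_chroms() -> dict[str, int]:
    return {"chr1": 15_000_000, "chr2": 10_000_000}


@dataclass
class SimulationParams:
    """Study conditions of the synthetic multi-caller comparison.

    Defaults model a small five-callset study: 500 true SVs of 50-2000 bp
    spaced at least 5 kb apart, each callset detecting 60% of them with
    ~100 bp Gaussian breakpoint jitter, mislabelling the type of 5% of
    its detections, and adding on average 25 well-separated false calls.
    Half the truth SVs also appear (with independent jitter) in the
    known-SV VCF, 40%/30%/20% carry an on-target gene/named-repeat/
    plain-repeat feature.
    """

    chrom_lengths: dict[str, int] = field(default_factory=_default_chroms)
    n_true_svs: int = 500
    type_weights: dict[SVType, float] = field(default_factory=_default_type_weights)
    size_range: tuple[int, int] = (50, 2000)
    n_callsets: int = 5
    detection_prob: float = 0.6
    jitter_sd: float = 100.0
    type_confusion_prob: float = 0.05
    fp_rate: float = 25.0
    min_spacing: int = 5000
    seed: int = 42
    # annotation layer
    gene_prob: float = 0.4
    repeat_prob: float = 0.3
    plain_repeat_prob: float = 0.2
    known_sv_fraction: float = 0.5
    known_jitter_sd: float = 100.0
    n_background_features: int = 30

    def __post_init__(self) -> None:
        for name in (
            "detection_prob",
            "type_confusion_prob",
            "gene_prob",
            "repeat_prob",
            "plain_repeat_prob",
            "known_sv_fraction",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        total = sum(self.type_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"type_weights must sum to 1, got {total}")
        if self.size_range[0] < 1 or self.size_range[1] < self.size_range[0]:
            raise ValueError(f"invalid size_range {self.size_range}")
        if self.min_spacing < 0 or self.jitter_sd < 0 or self.fp_rate < 0:
            raise ValueError("min_spacing, jitter_sd and fp_rate must be >= 0")


class _ExclusionMap:
    """Sorted per-chromosome breakpoint positions with radius queries."""

    def __init__(self) -> None:
        self._pos: dict[str, list[int]] = {}

    def add(self, chrom: str, pos: int) -> None:
        bisect.insort(self._pos.setdefault(chrom, []), pos)

    def clear_of(self, chrom: str, pos: int, radius: int) -> bool:
        positions = self._pos.get(chrom, [])
        i = bisect.bisect_left(positions, pos - radius)
        return i >= len(positions) or positions[i] > pos + radius


def _allocate_counts(chrom_lengths: dict[str, int], n: int) -> dict[str, int]:
    """Split n among chromosomes proportionally to length, deterministically."""
    names = list(chrom_lengths)
    total = sum(chrom_lengths.values())
    counts = {c: (n * chrom_lengths[c]) // total for c in names}
    remainder = n - sum(counts.values())
    for c in sorted(names, key=lambda c: -chrom_lengths[c]):
        if remainder == 0:
            break
        counts[c] += 1
        remainder -= 1
    return counts


def generate_truth(params: SimulationParams) -> list[SVRecord]:
    """Simulate the non-overlapping true SVs (deterministic given seed).

    Starts keep a pairwise distance of at least ``min_spacing`` within
    each chromosome; sizes are uniform in ``size_range``.  Translocation
    second breakpoints land on another chromosome (the same one when the
    genome has a single chromosome), at least ``min_spacing`` away from
    every truth start.  Raises ``ValueError`` when a chromosome is too
    small for the requested count and spacing.
    """
    rng = np.random.default_rng(params.seed)
    counts = _allocate_counts(params.chrom_lengths, params.n_true_svs)
    max_size = params.size_range[1]
    starts_by_chrom: dict[str, np.ndarray] = {}
    for chrom, n in counts.items():
        if n == 0:
            starts_by_chrom[chrom] = np.empty(0, dtype=int)
            continue
        length = params.chrom_lengths[chrom]
        free = length - max_size - (n - 1) * params.min_spacing - 1
        if free <= 1:
            raise ValueError(
                f"chromosome {chrom} ({length} bp) too small for {n} SVs "
                f"with spacing {params.min_spacing}"
            )
        offsets = np.sort(rng.integers(1, free, size=n))
        starts = offsets + np.arange(n) * params.min_spacing
        starts_by_chrom[chrom] = starts

    types = list(params.type_weights)
    weights = np.array([params.type_weights[t] for t in types], dtype=float)
    chrom_names = list(params.chrom_lengths)

    truth: list[SVRecord] = []
    idx = 0
    all_starts = _ExclusionMap()
    for chrom, starts in starts_by_chrom.items():
        for s in starts:
            all_starts.add(chrom, int(s))
    for chrom in chrom_names:
        for s in starts_by_chrom[chrom]:
            s = int(s)
            svtype = types[rng.choice(len(types), p=weights)]
            size = int(rng.integers(params.size_range[0], params.size_range[1] + 1))
            if svtype is SVType.TRA:
                others = [c for c in chrom_names if c != chrom] or [chrom]
                chrom2 = others[int(rng.integers(len(others)))]
                for _ in range(10_000):
                    pos = int(rng.integers(0, params.chrom_lengths[chrom2]))
                    if all_starts.clear_of(chrom2, pos, params.min_spacing):
                        break
                else:  # pragma: no cover - genome practically full
                    raise ValueError("cannot place TRA second breakpoint")
                all_starts.add(chrom2, pos)
                rec = SVRecord(
                    chrom=chrom,
                    start=s,
                    end=pos,
                    svtype=SVType.TRA,
                    chrom2=chrom2,
                    record_id=f"t{idx}",
                    callset_id="truth",
                )
            else:
                end = s if svtype is SVType.INS else s + size
                svlen = -size if svtype is SVType.DEL else size
                rec = SVRecord(
                    chrom=chrom,
                    start=s,
                    end=end,
                    svtype=svtype,
                    svlen=svlen,
                    record_id=f"t{idx}",
                    callset_id="truth",
                )
            truth.append(rec)
            idx += 1
    return truth


def _breakpoint_exclusions(truth: Sequence[SVRecord]) -> _ExclusionMap:
    excl = _ExclusionMap()
    for rec in truth:
        excl.add(rec.chrom, rec.start)
        excl.add(rec.chrom2, rec.end)
    return excl


def perturb_callset(
    truth: Sequence[SVRecord],
    params: SimulationParams,
    callset_index: int,
    rng: Optional[np.random.Generator] = None,
    occupied: Optional[_ExclusionMap] = None,
) -> CallSet:
    """Derive one noisy callset from the truth.

    Each truth SV is detected with ``detection_prob``; detected
    breakpoints are shifted by independent rounded Normal(0, jitter_sd)
    (ends clamped to stay >= the start); with ``type_confusion_prob`` a
    non-TRA detection is relabelled with another non-TRA type.
    Poisson(fp_rate) false calls are placed away from every truth
    breakpoint (and, via ``occupied``, from other callsets' false calls).
    Detections carry ``record_id`` ``t<i>`` matching the truth; false
    calls are ``fp<k>``.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([params.seed, 1000 + callset_index])
        )
    cid = f"caller_{callset_index}"
    records: list[SVRecord] = []
    for rec in truth:
        if rng.random() >= params.detection_prob:
            continue
        j1 = int(np.round(rng.normal(0.0, params.jitter_sd)))
        j2 = int(np.round(rng.normal(0.0, params.jitter_sd)))
        start = max(0, rec.start + j1)
        svtype = rec.svtype
        if (
            svtype is not SVType.TRA
            and rng.random() < params.type_confusion_prob
        ):
            others = [t for t in _NON_TRA if t is not svtype]
            svtype = others[int(rng.integers(len(others)))]
        if svtype is SVType.TRA:
            end = max(0, rec.end + j2)
        elif svtype is SVType.INS and rec.svtype is SVType.INS:
            end = start
        else:
            end = max(start, rec.end + j2)
        records.append(
            SVRecord(
                chrom=rec.chrom,
                start=start,
                end=end,
                svtype=svtype,
                chrom2=rec.chrom2,
                svlen=rec.svlen,
                record_id=rec.record_id,
                callset_id=cid,
            )
        )
    # false positives
    exclusions = occupied if occupied is not None else _breakpoint_exclusions(truth)
    chrom_names = list(params.chrom_lengths)
    lengths = np.array([params.chrom_lengths[c] for c in chrom_names], dtype=float)
    n_fp = int(rng.poisson(params.fp_rate))
    for k in range(n_fp):
        for _ in range(10_000):
            chrom = chrom_names[
                int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
            ]
            pos = int(rng.integers(0, params.chrom_lengths[chrom]))
            if exclusions.clear_of(chrom, pos, params.min_spacing):
                break
        else:  # pragma: no cover - genome practically full
            raise ValueError("cannot place false positive away from truth")
        exclusions.add(chrom, pos)
        svtype = _NON_TRA[int(rng.integers(len(_NON_TRA)))]
        size = int(rng.integers(params.size_range[0], params.size_range[1] + 1))
        end = pos if svtype is SVType.INS else pos + size
        records.append(
            SVRecord(
                chrom=chrom,
                start=pos,
                end=end,
                svtype=svtype,
                svlen=-size if svtype is SVType.DEL else size,
                record_id=f"fp{callset_index}_{k}",
                callset_id=cid,
            )
        )
    return CallSet(callset_id=cid, records=records)


@dataclass
class FeatureBundle:
    """Annotation sources generated alongside the truth."""

    genes: list[GenomicFeature]
    repeats_named: list[GenomicFeature]
    repeats_plain: list[GenomicFeature]
    known_svs: list[SVRecord]


def generate_features(
    params: SimulationParams,
    truth: Sequence[SVRecord],
    rng: Optional[np.random.Generator] = None,
    exclusions: Optional[_ExclusionMap] = None,
) -> tuple[FeatureBundle, pd.DataFrame]:
    """Generate gene/repeat features and a known-SV VCF with a ledger.

    On-target features hug a truth SV's start breakpoint (+/- 50 bp), so
    they are assigned to the corresponding event under every type path as
    long as the annotation wobble exceeds the breakpoint jitter by a
    comfortable margin.  Background features and translocation second
    breakpoints stay at least ``min_spacing`` from every truth
    breakpoint, so they are never assigned to any event.  The ledger has
    one row per truth SV with columns ``truth_id, has_gene, has_repeat,
    has_plain_repeat, in_known_vcf, gene_name, repeat_name``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 7]))
    if exclusions is None:
        exclusions = _breakpoint_exclusions(truth)
    chrom_names = list(params.chrom_lengths)
    lengths = np.array([params.chrom_lengths[c] for c in chrom_names], dtype=float)

    genes: list[GenomicFeature] = []
    repeats_named: list[GenomicFeature] = []
    repeats_plain: list[GenomicFeature] = []
    known: list[SVRecord] = []
    ledger_rows = []
    for rec in truth:
        has_gene = rng.random() < params.gene_prob
        has_repeat = rng.random() < params.repeat_prob
        has_plain = rng.random() < params.plain_repeat_prob
        in_known = rng.random() < params.known_sv_fraction
        gene_name = repeat_name = ""
        lo, hi = max(0, rec.start - 50), rec.start + 50
        if has_gene:
            gene_name = f"GENE{rec.record_id[1:]}"
            genes.append(
                GenomicFeature(
                    rec.chrom, lo, hi, gene_name, "genes", SourceKind.GFF
                )
            )
        if has_repeat:
            repeat_name = f"rep{rec.record_id[1:]}"
            repeats_named.append(
                GenomicFeature(
                    rec.chrom, lo, hi, repeat_name, "repeats_named", SourceKind.BED
                )
            )
        if has_plain:
            repeats_plain.append(
                GenomicFeature(
                    rec.chrom, lo, hi, "lowmap", "lowmap", SourceKind.BED
                )
            )
        if in_known:
            j1 = int(np.round(rng.normal(0.0, params.known_jitter_sd)))
            j2 = int(np.round(rng.normal(0.0, params.known_jitter_sd)))
            start = max(0, rec.start + j1)
            if rec.svtype is SVType.TRA:
                end = max(0, rec.end + j2)
            elif rec.svtype is SVType.INS:
                end = start
            else:
                end = max(start, rec.end + j2)
            known.append(
                SVRecord(
                    chrom=rec.chrom,
                    start=start,
                    end=end,
                    svtype=rec.svtype,
                    chrom2=rec.chrom2,
                    svlen=rec.svlen,
                    record_id=f"known_{rec.record_id}",
                    callset_id="known_svs",
                )
            )
        ledger_rows.append(
            {
                "truth_id": rec.record_id,
                "has_gene": has_gene,
                "has_repeat": has_repeat,
                "has_plain_repeat": has_plain,
                "in_known_vcf": in_known,
                "gene_name": gene_name,
                "repeat_name": repeat_name,
            }
        )

    # background features, far from every truth breakpoint
    for group, source_id, kind, prefix in (
        (genes, "genes", SourceKind.GFF, "BGGENE"),
        (repeats_named, "repeats_named", SourceKind.BED, "bgrep"),
        (repeats_plain, "lowmap", SourceKind.BED, "lowmap"),
    ):
        for k in range(params.n_background_features):
            for _ in range(10_000):
                chrom = chrom_names[
                    int(rng.choice(len(chrom_names), p=lengths / lengths.sum()))
                ]
                pos = int(rng.integers(0, params.chrom_lengths[chrom] - 1500))
                if exclusions.clear_of(chrom, pos, params.min_spacing):
                    break
            else:  # pragma: no cover
                raise ValueError("cannot place background feature")
            length = int(rng.integers(100, 1000))
            name = "lowmap" if prefix == "lowmap" else f"{prefix}{k}"
            group.append(
                GenomicFeature(chrom, pos, pos + length, name, source_id, kind)
            )

    bundle = FeatureBundle(
        genes=genes,
        repeats_named=repeats_named,
        repeats_plain=repeats_plain,
        known_svs=dedup_annotation_sites(known),
    )
    return bundle, pd.DataFrame(ledger_rows)


@dataclass
class SimulatedStudy:
    """Everything one seeded simulation produced."""

    params: SimulationParams
    truth: list[SVRecord]
    callsets: list[CallSet]
    features: FeatureBundle
    ledger: pd.DataFrame  # annotation ledger, one row per truth SV
    detection: pd.DataFrame  # truth_id x callset_id booleans

    @property
    def n_detected_truth(self) -> int:
        """Truth SVs detected by at least one callset."""
        return int(self.detection.any(axis=1).sum())

    @property
    def n_false_calls(self) -> int:
        return sum(
            1
            for cs in self.callsets
            for r in cs.records
            if r.record_id.startswith("fp")
        )

    @property
    def expected_event_count(self) -> int:
        """Events a merge at the study distance should produce."""
        return self.n_detected_truth + self.n_false_calls

    def expected_support(self) -> dict[str, int]:
        """Per detected truth id, the number of detecting callsets."""
        det = self.detection[self.detection.any(axis=1)]
        return det.sum(axis=1).astype(int).to_dict()


def simulate(params: Optional[SimulationParams] = None) -> SimulatedStudy:
    """Run the full generator: truth, noisy callsets, features, ledgers."""
    params = params or SimulationParams()
    truth = generate_truth(params)
    occupied = _breakpoint_exclusions(truth)
    callsets = [
        perturb_callset(
            truth,
            params,
            i,
            rng=np.random.default_rng(np.random.SeedSequence([params.seed, 1000 + i])),
            occupied=occupied,
        )
        for i in range(params.n_callsets)
    ]
    # the shared exclusion map now also holds every false-positive start, so
    # background features cannot end up near a false call's event
    features, ledger = generate_features(params, truth, exclusions=occupied)
    detection = pd.DataFrame(
        False,
        index=[t.record_id for t in truth],
        columns=[cs.callset_id for cs in callsets],
    )
    for cs in callsets:
        for rec in cs.records:
            if rec.record_id.startswith("t"):
                detection.loc[rec.record_id, cs.callset_id] = True
    return SimulatedStudy(
        params=params,
        truth=truth,
        callsets=callsets,
        features=features,
        ledger=ledger,
        detection=detection,
    )


def write_study(study: SimulatedStudy, outdir: str | Path) -> dict[str, list[Path]]:
    """Write the study as files: N callset VCFs, two BEDs (4- and
    3-column, exercising both BED naming rules), a GFF with ``gene=``
    attributes, a known-SV VCF and the truth ledger TSV.

    Returns the written paths grouped by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, list[Path]] = {
        "callsets": [],
        "bed": [],
        "gff": [],
        "vcf": [],
        "ledger": [],
    }
    for cs in study.callsets:
        p = outdir / f"{cs.callset_id}.vcf"
        write_sv_vcf(cs, p, contig_lengths=study.params.chrom_lengths)
        paths["callsets"].append(p)

    named = outdir / "repeats_named.bed"
    named.write_text(
        "".join(
            f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\n"
            for f in study.features.repeats_named
        )
    )
    paths["bed"].append(named)
    plain = outdir / "lowmap.bed"
    plain.write_text(
        "".join(
            f"{f.chrom}\t{f.start}\t{f.end}\n" for f in study.features.repeats_plain
        )
    )
    paths["bed"].append(plain)

    gff = outdir / "genes.gff"
    gff.write_text(
        "".join(
            f"{f.chrom}\tsim\tgene\t{f.start + 1}\t{f.end}\t.\t+\t.\t"
            f"ID={f.name};gene={f.name}\n"
            for f in study.features.genes
        )
    )
    paths["gff"].append(gff)

    known = outdir / "known_svs.vcf"
    write_sv_vcf(
        CallSet(callset_id="known_svs", records=study.features.known_svs),
        known,
        contig_lengths=study.params.chrom_lengths,
    )
    paths["vcf"].append(known)

    ledger_path = outdir / "truth_ledger.tsv"
    study.ledger.merge(
        study.detection.rename_axis("truth_id").reset_index(), on="truth_id"
    ).to_csv(ledger_path, sep="\t", index=False)
    paths["ledger"].append(ledger_path)
    return paths
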