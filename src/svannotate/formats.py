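"""Readers and writers for SV VCF, BED and GFF files.

All coordinate conversion between on-disk conventions (1-based VCF/GFF,
0-based half-open BED) and the package's internal 0-based breakpoint
representation lives here.  Parsers never raise on a malformed *data* line:
the line is skipped, a warning is logged, and the skip count is reported on
the returned object.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .core import (
    GenomicFeature,
    MergedEvent,
    SourceKind,
    SVRecord,
    SVType,
    normalize_type,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CallSet",
    "FormatError",
    "sanitize_name",
    "read_sv_vcf",
    "read_bed",
    "read_gff",
    "dedup_annotation_sites",
    "write_sv_vcf",
    "write_annotated_vcf",
    "write_merged_vcf",
    "read_merged_vcf",
]


class FormatError(ValueError):
    """Raised when a file is structurally unreadable (not per-line issues)."""


@dataclass
class CallSet:
    """All SV calls read from one VCF, plus its header lines.

    ``callset_id`` defaults to the file's base name without extension,
    matching the convention of naming callsets after their files.
    """

    callset_id: str
    records: list[SVRecord] = field(default_factory=list)
    header_lines: list[str] = field(default_factory=list)
    n_skipped: int = 0
    n_size_filtered: int = 0


_FORBIDDEN = re.compile(r"[;,=\s]")


def sanitize_name(name: str) -> str:
    """Replace VCF-reserved characters {';' ',' '=' whitespace} with '_'."""
    return _FORBIDDEN.sub("_", name.strip())


# Breakend ALT such as  N[chr2:321682[  or  ]13:123456]T
_BND_ALT = re.compile(r"[\[\]]([^\[\]:]+):(\d+)[\[\]]")


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for part in info.split(";"):
        if not part:
            continue
        if "=" in part:
            key, _, val = part.partition("=")
            out[key] = val
        else:
            out[part] = ""
    return out


def _first_int(value: str) -> Optional[int]:
    try:
        return int(float(value.split(",")[0]))
    except (ValueError, IndexError):
        return None


def _record_from_vcf_fields(
    fields: Sequence[str], callset_id: str, raw_line: str
) -> SVRecord:
    chrom = fields[0]
    pos = int(fields[1])
    rec_id = fields[2]
    ref, alt = fields[3], fields[4].split(",")[0]
    info = _parse_info(fields[7]) if len(fields) > 7 else {}

    start = pos - 1
    if start < 0:
        raise ValueError("POS must be >= 1")

    svlen = _first_int(info["SVLEN"]) if "SVLEN" in info else None

    # Type: INFO SVTYPE, else symbolic ALT, else breakend ALT, else
    # inferred from REF/ALT length difference for indel-style lines.
    svtype: SVType
    if "SVTYPE" in info:
        svtype = normalize_type(info["SVTYPE"])
    elif alt.startswith("<") and alt.endswith(">"):
        svtype = normalize_type(alt[1:-1])
    elif _BND_ALT.search(alt):
        svtype = SVType.TRA
    elif ref and alt and re.fullmatch(r"[ACGTNacgtn]+", ref + alt):
        diff = len(alt) - len(ref)
        if diff < 0:
            svtype = SVType.DEL
            svlen = diff if svlen is None else svlen
        elif diff > 0:
            svtype = SVType.INS
            svlen = diff if svlen is None else svlen
        else:
            svtype = SVType.UNK
    else:
        svtype = SVType.UNK

    # Second breakpoint chromosome: CHR2, else breakend ALT, else chrom.
    bnd = _BND_ALT.search(alt)
    if "CHR2" in info and info["CHR2"]:
        chrom2 = info["CHR2"]
    elif bnd:
        chrom2 = bnd.group(1)
    else:
        chrom2 = chrom

    # Second breakpoint position: END (1-based) - 1, else derived.
    end: Optional[int] = None
    if "END" in info:
        end = _first_int(info["END"])
        end = None if end is None else end - 1
    if end is None and bnd:
        end = int(bnd.group(2)) - 1
    if end is None:
        if svtype in (SVType.DEL, SVType.DUP, SVType.INV) and svlen is not None:
            end = start + abs(svlen)
        else:
            end = start

    if svtype is not SVType.TRA and chrom2 == chrom and end < start:
        start, end = end, start  # repair END upstream of POS

    return SVRecord(
        chrom=chrom,
        start=start,
        end=end,
        svtype=svtype,
        chrom2=chrom2,
        svlen=svlen,
        record_id=rec_id,
        callset_id=callset_id,
        raw_info=info,
        raw_line=raw_line,
    )


def read_sv_vcf(
    path: str | Path, callset_id: Optional[str] = None, min_size: int = 0
) -> CallSet:
    """Read an SV VCF into a :class:`CallSet`.

    POS is converted to 0-based; the second breakpoint comes from INFO END
    (minus 1) when present, else from |SVLEN| for DEL/DUP/INV, else equals
    the start (INS/BND).  The type comes from INFO SVTYPE, a symbolic ALT,
    a breakend ALT, or REF/ALT length difference, in that order.  Records
    whose size (|SVLEN|, else end-start) is below ``min_size`` are dropped;
    translocations are exempt from the size filter.  Malformed data lines
    are skipped with a logged warning and counted in ``n_skipped``.
    """
    path = Path(path)
    if callset_id is None:
        callset_id = path.stem
    try:
        text = path.read_text()
    except OSError as exc:
        raise FormatError(f"cannot read VCF {path}: {exc}") from exc

    callset = CallSet(callset_id=callset_id)
    saw_chrom_header = False
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#"):
            callset.header_lines.append(line)
            if line.startswith("#CHROM"):
                saw_chrom_header = True
            continue
        if not saw_chrom_header:
            raise FormatError(f"{path}: data line before #CHROM header line")
        fields = line.split("\t")
        if len(fields) < 8:
            logger.warning("%s:%d: fewer than 8 columns, skipped", path, line_no)
            callset.n_skipped += 1
            continue
        try:
            rec = _record_from_vcf_fields(fields, callset_id, line)
        except (ValueError, IndexError) as exc:
            logger.warning("%s:%d: %s, skipped", path, line_no, exc)
            callset.n_skipped += 1
            continue
        if min_size > 0 and rec.svtype is not SVType.TRA and rec.size < min_size:
            callset.n_size_filtered += 1
            continue
        callset.records.append(rec)
    if not saw_chrom_header:
        raise FormatError(f"{path}: no #CHROM header line found")
    return callset


def read_bed(path: str | Path, source_id: Optional[str] = None) -> list[GenomicFeature]:
    """Read BED3/BED4+ features (coordinates taken verbatim, half-open).

    The fourth column names each feature; a 3-column BED names every
    feature after the file (base name without extension).  Lines with
    non-integer coordinates or ``end <= start`` are skipped with a warning.
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    default_name = sanitize_name(path.stem) or source_id
    features: list[GenomicFeature] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if (
            not stripped
            or stripped.startswith("#")
            or stripped.startswith("track")
            or stripped.startswith("browser")
        ):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 3:
            cols = stripped.split()
        if len(cols) < 3:
            logger.warning("%s:%d: fewer than 3 columns, skipped", path, line_no)
            continue
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            logger.warning("%s:%d: non-integer coordinates, skipped", path, line_no)
            continue
        if end <= start:
            logger.warning("%s:%d: end <= start, skipped", path, line_no)
            continue
        name = sanitize_name(cols[3]) if len(cols) > 3 and cols[3].strip() else ""
        features.append(
            GenomicFeature(
                chrom=cols[0],
                start=start,
                end=end,
                name=name or default_name,
                source_id=source_id,
                source_kind=SourceKind.BED,
            )
        )
    return features


_GENE_ATTR = re.compile(r"(?:^|;)\s*gene=([^;]*)")


def read_gff(path: str | Path, source_id: Optional[str] = None) -> list[GenomicFeature]:
    """Read 9-column GFF/GTF-like features.

    GFF coordinates are 1-based inclusive; internally the start is shifted
    by -1 (making the interval half-open).  The name is the value of the
    first ``gene=`` key in column 9; lines without one are named
    ``<type>:<seqid>:<start>``.  Lines with fewer than 9 columns are
    skipped with a warning.
    """
    path = Path(path)
    if source_id is None:
        source_id = path.stem
    features: list[GenomicFeature] = []
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) < 9:
            logger.warning("%s:%d: fewer than 9 columns, skipped", path, line_no)
            continue
        try:
            start, end = int(cols[3]) - 1, int(cols[4])
        except ValueError:
            logger.warning("%s:%d: non-integer coordinates, skipped", path, line_no)
            continue
        if end <= start:
            logger.warning("%s:%d: empty interval, skipped", path, line_no)
            continue
        match = _GENE_ATTR.search(cols[8])
        if match and match.group(1).strip():
            name = sanitize_name(match.group(1))
        else:
            name = sanitize_name(f"{cols[2]}:{cols[0]}:{cols[3]}")
        features.append(
            GenomicFeature(
                chrom=cols[0],
                start=start,
                end=end,
                name=name,
                source_id=source_id,
                source_kind=SourceKind.GFF,
            )
        )
    return features


def dedup_annotation_sites(records: Iterable[SVRecord]) -> list[SVRecord]:
    """Unique records by (chrom, start, chrom2, end, svtype), order kept."""
    seen: set[tuple] = set()
    out: list[SVRecord] = []
    for rec in records:
        key = (rec.chrom, rec.start, rec.chrom2, rec.end, rec.svtype)
        if key not in seen:
            seen.add(key)
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_ANNOTATION_INFO_HEADERS = [
    '##INFO=<ID=overlapped_VCF,Number=1,Type=Integer,Description='
    '"Number of annotation VCF files with at least one SV matching this site">',
    '##INFO=<ID=total_Annotations,Number=1,Type=Integer,Description='
    '"Number of distinct genomic feature names assigned to this site">',
    '##INFO=<ID=overlapped_Annotations,Number=.,Type=String,Description='
    '"Comma separated names of the assigned genomic features">',
]

_MINIMAL_CHROM_LINE = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"


def _synthesize_vcf_line(item: SVRecord | MergedEvent) -> str:
    svtype = (
        item.svtype
        if isinstance(item, SVRecord)
        else (item.modal_type or SVType.UNK)
    )
    info = f"SVTYPE={svtype.value};END={item.end + 1}"
    if item.chrom2 != item.chrom:
        info += f";CHR2={item.chrom2}"
    if isinstance(item, SVRecord) and item.svlen is not None:
        info += f";SVLEN={item.svlen}"
    ident = item.record_id if isinstance(item, SVRecord) else item.event_id
    return "\t".join(
        [
            item.chrom,
            str(item.start + 1),
            ident or ".",
            "N",
            f"<{svtype.value}>",
            ".",
            "PASS",
            info,
        ]
    )


def _merge_headers(header_lines: Optional[Sequence[str]], extra: Sequence[str]) -> list[str]:
    """Insert ``extra`` header lines just before the #CHROM line."""
    lines = list(header_lines) if header_lines else ["##fileformat=VCFv4.1"]
    existing = {ln.split(",", 1)[0] for ln in lines if ln.startswith("##INFO=<ID=")}
    additions = [ln for ln in extra if ln.split(",", 1)[0] not in existing]
    chrom_at = next(
        (i for i, ln in enumerate(lines) if ln.startswith("#CHROM")), None
    )
    if chrom_at is None:
        return lines + additions + [_MINIMAL_CHROM_LINE]
    return lines[:chrom_at] + additions + lines[chrom_at:]


def write_annotated_vcf(
    events: Sequence[SVRecord | MergedEvent],
    results: Sequence["AnnotationResult"],  # noqa: F821 - see annotate module
    path: str | Path,
    header_lines: Optional[Sequence[str]] = None,
) -> None:
    """Write the input rows back out with the three annotation INFO keys.

    Every input row is preserved byte-identically outside its INFO column
    (rows lacking original line context are synthesized).  Each INFO gains
    ``overlapped_VCF=<int>;total_Annotations=<int>`` and, only when at
    least one feature was assigned,
    ``;overlapped_Annotations=<name1>,<name2>,...``.  Matching ##INFO
    definitions are added to the header once.
    """
    if len(events) != len(results):
        raise ValueError(
            f"{len(events)} events but {len(results)} annotation results"
        )
    out_lines = _merge_headers(header_lines, _ANNOTATION_INFO_HEADERS)
    for ev, res in zip(events, results):
        line = ev.raw_line if ev.raw_line is not None else _synthesize_vcf_line(ev)
        fields = line.split("\t")
        if len(fields) < 8:
            fields += ["."] * (8 - len(fields))
        suffix = f"overlapped_VCF={res.overlapped_vcf};total_Annotations={res.total_annotations}"
        if res.names:
            suffix += ";overlapped_Annotations=" + ",".join(res.names)
        info = fields[7]
        fields[7] = suffix if info in (".", "") else f"{info};{suffix}"
        out_lines.append("\t".join(fields))
    Path(path).write_text("\n".join(out_lines) + "\n")


def write_sv_vcf(
    callset: CallSet,
    path: str | Path,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a callset as a minimal, standard-conformant SV VCF 4.1."""
    lines = ["##fileformat=VCFv4.1"]
    if contig_lengths:
        lines += [
            f"##contig=<ID={name},length={length}>"
            for name, length in contig_lengths.items()
        ]
    lines += [
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Signed length of the variant">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of the second breakpoint">',
        _MINIMAL_CHROM_LINE,
    ]
    for rec in callset.records:
        lines.append(_synthesize_vcf_line(rec))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Merged multi-sample VCF (one column per callset)
# ---------------------------------------------------------------------------

_MERGED_FORMAT = "TY:CO"
_CO_RE = re.compile(r"^(.+)_(\d+)-(.+)_(\d+)$")


def _co_encode(rec: SVRecord) -> str:
    return f"{rec.chrom}_{rec.start + 1}-{rec.chrom2}_{rec.end + 1}"


def write_merged_vcf(
    events: Sequence[MergedEvent], callset_ids: Sequence[str], path: str | Path
) -> None:
    """Write merged events as a multi-sample VCF.

    One sample column per callset ('.' where the callset has no call);
    per-callset sub-calls are encoded in FORMAT ``TY:CO`` as comma
    separated type and ``chrom_start-chrom2_end`` (1-based) lists.  INFO
    carries ``SUPP`` (distinct supporting callsets), SVTYPE, END and CHR2.
    """
    lines = [
        "##fileformat=VCFv4.1",
        '##INFO=<ID=SUPP,Number=1,Type=Integer,Description="Number of callsets supporting the event">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Modal type among member calls">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="Representative end breakpoint">',
        '##INFO=<ID=CHR2,Number=1,Type=String,Description="Chromosome of the second breakpoint">',
        '##FORMAT=<ID=TY,Number=.,Type=String,Description="Types of this callset member calls">',
        '##FORMAT=<ID=CO,Number=.,Type=String,Description="Coordinates of this callset member calls (chrom_start-chrom2_end, 1-based)">',
        _MINIMAL_CHROM_LINE + "\tFORMAT\t" + "\t".join(callset_ids),
    ]
    for ev in events:
        modal = ev.modal_type or SVType.UNK
        info = (
            f"SUPP={ev.support_count};SVTYPE={modal.value};"
            f"END={ev.end + 1};CHR2={ev.chrom2}"
        )
        by_callset = ev.members_by_callset()
        cols = [
            ev.chrom,
            str(ev.start + 1),
            ev.event_id or ".",
            "N",
            f"<{modal.value}>",
            ".",
            "PASS",
            info,
            _MERGED_FORMAT,
        ]
        for cid in callset_ids:
            members = by_callset.get(cid)
            if not members:
                cols.append(".")
            else:
                ty = ",".join(m.svtype.value for m in members)
                co = ",".join(_co_encode(m) for m in members)
                cols.append(f"{ty}:{co}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n")


def read_merged_vcf(path: str | Path) -> tuple[list[MergedEvent], list[str]]:
    """Read a multi-sample merged VCF written by :func:`write_merged_vcf`.

    Reconstructs every per-callset sub-call from the FORMAT ``TY:CO``
    columns.  Returns the events (with their raw lines for later
    re-writing) and the callset ids in column order.
    """
    path = Path(path)
    callset_ids: list[str] = []
    events: list[MergedEvent] = []
    saw_header = False
    for line_no, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("#CHROM"):
            saw_header = True
            cols = line.split("\t")
            callset_ids = cols[9:] if len(cols) > 9 else []
            continue
        if line.startswith("#"):
            continue
        if not saw_header:
            raise FormatError(f"{path}: data line before #CHROM header line")
        fields = line.split("\t")
        if len(fields) < 10:
            logger.warning("%s:%d: no sample columns, skipped", path, line_no)
            continue
        info = _parse_info(fields[7])
        chrom = fields[0]
        start = int(fields[1]) - 1
        end = (_first_int(info.get("END", "")) or int(fields[1])) - 1
        chrom2 = info.get("CHR2") or chrom
        event_id = fields[2]
        fmt_keys = fields[8].split(":")
        try:
            ty_at, co_at = fmt_keys.index("TY"), fmt_keys.index("CO")
        except ValueError:
            raise FormatError(f"{path}:{line_no}: FORMAT lacks TY:CO") from None
        members: list[SVRecord] = []
        for cid, val in zip(callset_ids, fields[9:]):
            if val in (".", "./.", ""):
                continue
            parts = val.split(":")
            tys = parts[ty_at].split(",")
            cos = parts[co_at].split(",")
            for k, (ty, co) in enumerate(zip(tys, cos)):
                m = _CO_RE.match(co)
                if not m:
                    logger.warning("%s:%d: bad CO field %r, skipped", path, line_no, co)
                    continue
                members.append(
                    SVRecord(
                        chrom=m.group(1),
                        start=int(m.group(2)) - 1,
                        end=int(m.group(4)) - 1,
                        svtype=normalize_type(ty),
                        chrom2=m.group(3),
                        record_id=f"{event_id}.{cid}.{k}",
                        callset_id=cid,
                    )
                )
        if not members:
            logger.warning("%s:%d: event without members, skipped", path, line_no)
            continue
        events.append(
            MergedEvent(
                event_id=event_id,
                chrom=chrom,
                start=start,
                end=end,
                chrom2=chrom2,
                members=tuple(members),
                raw_line=line,
            )
        )
    if not saw_header:
        raise FormatError(f"{path}: no #CHROM header line found")
    return events, callset_ids
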