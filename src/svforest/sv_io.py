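"""Read, normalize, filter and write structural-variant records.

Internal coordinates are 0-based half-open everywhere ([start, end), BED
arithmetic); VCF POS is converted on read and write. Only deletions and
duplications are modelled: copy-number loss maps to DEL, copy-number gain to
DUP, and every other SV class is dropped with a logged count.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger(__name__)

#: SVTYPE / variant-class spellings accepted on input, mapped to the internal enum.
SVTYPE_ALIASES = {
    "DEL": "DEL",
    "DELETION": "DEL",
    "CNV:LOSS": "DEL",
    "COPY_NUMBER_LOSS": "DEL",
    "COPY NUMBER LOSS": "DEL",
    "DUP": "DUP",
    "DUPLICATION": "DUP",
    "CNV:GAIN": "DUP",
    "COPY_NUMBER_GAIN": "DUP",
    "COPY NUMBER GAIN": "DUP",
}

VALID_LABELS = ("pathogenic", "benign", "unlabeled")


class SVParseError(ValueError):
    """Malformed input that prevents reading a record at all."""


@dataclass
class SVRecord:
    """One deletion or duplication in 0-based half-open coordinates."""

    id: str
    chrom: str
    start: int
    end: int
    svtype: str
    maf: float | None = None
    n_homalt: int | None = None
    label: str = "unlabeled"
    source: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"SV {self.id!r}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.svtype not in ("DEL", "DUP"):
            raise ValueError(f"SV {self.id!r}: svtype must be DEL or DUP, got {self.svtype!r}")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"SV {self.id!r}: MAF {self.maf} outside [0, 1]")
        if self.n_homalt is not None and self.n_homalt < 0:
            raise ValueError(f"SV {self.id!r}: negative homozygote count")
        if self.label not in VALID_LABELS:
            raise ValueError(f"SV {self.id!r}: unknown label {self.label!r}")

    @property
    def size(self) -> int:
        return self.end - self.start

    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class ReadReport:
    """Per-file tally of records dropped or rejected during reading."""

    n_read: int = 0
    n_kept: int = 0
    dropped_svtype: int = 0
    record_errors: list[str] = field(default_factory=list)


def normalize_chrom(chrom: str, style: str = "bare") -> str:
    """Normalize a chromosome name to ``bare`` ('1') or ``chr`` ('chr1') style."""
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if style == "bare":
        return bare
    if style == "chr":
        return "chr" + bare
    raise ValueError(f"unknown chromosome style {style!r}")


def _info_get(info, *keys):
    for key in keys:
        if key in info:
            value = info[key]
            if isinstance(value, tuple):
                value = value[0]
            return value
    return None


def read_sv_vcf(
    path: str | Path,
    chrom_style: str = "bare",
    report: ReadReport | None = None,
) -> list[SVRecord]:
    """Read DEL/DUP records from a VCF (4.x) file.

    SVTYPE is taken from INFO; the end coordinate from INFO/END, else from
    SVLEN. VCF POS (1-based) becomes the 0-based start. AF (or MAF) and
    N_HOMALT are captured when present. Non-DEL/DUP records are dropped and
    counted; records with no resolvable end or zero size are collected as
    record-level errors on ``report`` rather than raised.
    """
    report = report if report is not None else ReadReport()
    records: list[SVRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for idx, rec in enumerate(vcf, start=1):
            report.n_read += 1
            try:
                raw_type = _info_get(rec.info, "SVTYPE")
                svtype = SVTYPE_ALIASES.get(str(raw_type).upper()) if raw_type else None
                if svtype is None:
                    report.dropped_svtype += 1
                    continue
                start = rec.start  # pysam: already 0-based
                ref_len = len(rec.ref or "N")
                # pysam folds INFO/END into rec.stop; when neither END nor a
                # multi-base REF is present, stop degenerates to start + 1.
                if "SVLEN" in rec.info:
                    end = start + abs(int(_info_get(rec.info, "SVLEN")))
                elif rec.stop is not None and (rec.stop != start + ref_len or ref_len > 1):
                    end = int(rec.stop)
                else:
                    report.record_errors.append(
                        f"record {idx} ({rec.id or rec.chrom + ':' + str(rec.pos)}): "
                        "no resolvable end (END/SVLEN absent or zero size)"
                    )
                    continue
                if end <= start:
                    report.record_errors.append(
                        f"record {idx} ({rec.id or '?'}): zero or negative size "
                        f"(start={start}, end={end})"
                    )
                    continue
                maf = _info_get(rec.info, "AF", "MAF")
                n_homalt = _info_get(rec.info, "N_HOMALT", "NHOMALT")
                records.append(
                    SVRecord(
                        id=rec.id or f"sv{idx}",
                        chrom=normalize_chrom(rec.chrom, chrom_style),
                        start=start,
                        end=end,
                        svtype=svtype,
                        maf=float(maf) if maf is not None else None,
                        n_homalt=int(n_homalt) if n_homalt is not None else None,
                    )
                )
            except (ValueError, KeyError, TypeError) as exc:
                raise SVParseError(f"malformed VCF record {idx} in {path}: {exc}") from exc
    report.n_kept = len(records)
    if report.dropped_svtype:
        logger.info("%s: dropped %d non-DEL/DUP records", path, report.dropped_svtype)
    for msg in report.record_errors:
        logger.warning("%s: %s", path, msg)
    return records


TSV_COLUMNS = ("chrom", "start", "end", "svtype", "id", "label", "source", "maf", "n_homalt")


def read_sv_tsv(path: str | Path, chrom_style: str = "bare") -> list[SVRecord]:
    """Read SVs from a headered TSV (0-based half-open, BED-like).

    Required columns: chrom, start, end, svtype. Optional: id, label, source,
    maf, n_homalt.
    """
    records: list[SVRecord] = []
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"chrom", "start", "end", "svtype"} <= set(
            reader.fieldnames
        ):
            raise SVParseError(f"{path}: TSV must have columns chrom,start,end,svtype")
        for idx, row in enumerate(reader, start=1):
            try:
                maf = row.get("maf")
                n_hom = row.get("n_homalt")
                records.append(
                    SVRecord(
                        id=row.get("id") or f"sv{idx}",
                        chrom=normalize_chrom(row["chrom"], chrom_style),
                        start=int(row["start"]),
                        end=int(row["end"]),
                        svtype=SVTYPE_ALIASES[row["svtype"].upper()],
                        maf=float(maf) if maf not in (None, "", "NA") else None,
                        n_homalt=int(n_hom) if n_hom not in (None, "", "NA") else None,
                        label=row.get("label") or "unlabeled",
                        source=row.get("source") or "",
                    )
                )
            except (KeyError, ValueError) as exc:
                raise SVParseError(f"{path} line {idx + 1}: {exc}") from exc
    return records


def write_sv_tsv(svs: Iterable[SVRecord], path: str | Path) -> None:
    """Write SVs as headered TSV (0-based half-open)."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for sv in svs:
            writer.writerow(
                [
                    sv.chrom,
                    sv.start,
                    sv.end,
                    sv.svtype,
                    sv.id,
                    sv.label,
                    sv.source,
                    "" if sv.maf is None else repr(sv.maf),
                    "" if sv.n_homalt is None else sv.n_homalt,
                ]
            )


def filter_by_size(svs: Sequence[SVRecord], min_bp: int = 50, max_bp: int = 3_000_000) -> list[SVRecord]:
    """Retain SVs with min_bp <= size <= max_bp, preserving order.

    Defaults implement the standard working range for exon-altering CNVs:
    events between 50 bp and 3 Mb.
    """
    if min_bp < 1:
        raise ValueError("min_bp must be >= 1")
    if max_bp < min_bp:
        raise ValueError("max_bp must be >= min_bp")
    return [sv for sv in svs if min_bp <= sv.size <= max_bp]


def write_scored_output(
    svs: Sequence[SVRecord],
    scores: Sequence[float],
    path: str | Path,
    format: str = "tsv",
    vcf_template: str | Path | None = None,
) -> None:
    """Write one pathogenicity score per SV.

    ``tsv``: columns chrom,start,end,svtype,id,score (0-based half-open).
    ``vcf``: copies the template VCF, annotating each record that matches a
    scored SV by id with an INFO field SVFOREST.
    """
    if len(svs) != len(scores):
        raise ValueError(f"{len(svs)} records but {len(scores)} scores")
    if format == "tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["chrom", "start", "end", "svtype", "id", "score"])
            for sv, score in zip(svs, scores):
                writer.writerow([sv.chrom, sv.start, sv.end, sv.svtype, sv.id, repr(float(score))])
    elif format == "vcf":
        if vcf_template is None:
            raise ValueError("vcf output requires the input VCF as template")
        by_id = {sv.id: s for sv, s in zip(svs, scores)}
        with pysam.VariantFile(str(vcf_template)) as vin:
            header = vin.header.copy()
            if "SVFOREST" not in header.info:
                header.info.add("SVFOREST", 1, "Float", "svforest pathogenicity score in [0,1]")
            with pysam.VariantFile(str(path), "w", header=header) as vout:
                for rec in vin:
                    out = rec.copy()
                    out.translate(header)
                    if rec.id in by_id:
                        out.info["SVFOREST"] = float(by_id[rec.id])
                    vout.write(out)
    else:
        raise ValueError(f"unknown output format {format!r}")


def read_scored_tsv(path: str | Path) -> list[tuple[SVRecord, float]]:
    """Read back a scored TSV written by :func:`write_scored_output`."""
    out: list[tuple[SVRecord, float]] = []
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            sv = SVRecord(
                id=row["id"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                svtype=row["svtype"],
            )
            out.append((sv, float(row["score"])))
    return out
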