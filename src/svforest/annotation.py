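"""Gene/transcript/exon models, per-base tracks, and interval queries.

Gene models come from an Ensembl-dialect GTF (or an equivalent flat TSV).
For every gene one *principal* transcript is selected by best (lowest) APPRIS
rank, ties broken by greatest summed exon length; genes without any APPRIS
annotation are dropped. Per-nucleotide signals (phyloP conservation, exon
expression, exon inclusion) are held run-length encoded: sorted,
non-overlapping (interval, value) runs per chromosome, with adjacent
equal-valued runs merged. Querying an uncovered base yields no value.
"""

from __future__ import annotations

import csv
import logging
import re
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from svforest.sv_io import SVRecord, normalize_chrom

logger = logging.getLogger(__name__)

Interval = tuple[int, int]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class TranscriptModel:
    """A transcript with exons and CDS in transcript (5'->3') order.

    Intervals are genomic 0-based half-open; on the minus strand transcript
    order is reversed genomic order.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval]
    appris_rank: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        self.exons = _transcript_order(self.exons, self.strand)
        self.cds = _transcript_order(self.cds, self.strand)
        _check_disjoint(self.exons, self.transcript_id)
        for c in self.cds:
            if not any(e[0] <= c[0] and c[1] <= e[1] for e in self.exons):
                raise ValueError(
                    f"transcript {self.transcript_id}: CDS interval {c} outside every exon"
                )

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    def start_codon_base(self) -> int | None:
        """Genomic position of the first CDS base (transcript orientation)."""
        if not self.cds:
            return None
        s, e = self.cds[0]
        return s if self.strand == "+" else e - 1

    def stop_codon_base(self) -> int | None:
        """Genomic position of the last CDS base (transcript orientation)."""
        if not self.cds:
            return None
        s, e = self.cds[-1]
        return e - 1 if self.strand == "+" else s


@dataclass
class GeneModel:
    gene_id: str
    symbol: str
    transcripts: list[TranscriptModel]
    pli: float | None = None
    loeuf: float | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id}: no transcripts")
        self.principal = select_principal(self.transcripts)

    @property
    def chrom(self) -> str:
        return self.principal.chrom

    @property
    def strand(self) -> str:
        return self.principal.strand


@dataclass
class BoundaryRecord:
    """A TAD-boundary interval with an insulation-strength value."""

    chrom: str
    start: int
    end: int
    strength: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.strength):
            raise ValueError("boundary strength must be finite")


def _transcript_order(intervals: Sequence[Interval], strand: str) -> list[Interval]:
    return sorted(intervals, reverse=(strand == "-"))


def _check_disjoint(intervals: Sequence[Interval], name: str) -> None:
    ordered = sorted(intervals)
    for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise ValueError(f"{name}: overlapping intervals {(s1, e1)} and {(s2, e2)}")


def select_principal(transcripts: Sequence[TranscriptModel]) -> TranscriptModel:
    """Best APPRIS rank wins; ties go to greatest exonic length, then id."""
    return min(transcripts, key=lambda t: (t.appris_rank, -t.length, t.transcript_id))


# ---------------------------------------------------------------------------
# per-base track


class PerBaseTrack:
    """Run-length encoded per-nucleotide signal.

    Per chromosome: parallel sorted arrays (starts, ends, values) with
    non-overlapping intervals and adjacent equal values merged.
    """

    def __init__(self, runs: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self._runs = dict(runs)

    @classmethod
    def from_intervals(cls, rows: Iterable[tuple[str, int, int, float]]) -> "PerBaseTrack":
        """Build from (chrom, start, end, value) rows in any order.

        Overlapping intervals with differing values are an error; equal-valued
        overlaps/adjacencies are merged.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in rows:
            if end <= start:
                raise ValueError(f"empty track interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end, float(value)))
        runs = {}
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            merged: list[list[float]] = []
            for s, e, v in ivals:
                if merged and s < merged[-1][1]:
                    if v != merged[-1][2]:
                        raise ValueError(
                            f"overlapping track intervals with different values at "
                            f"{chrom}:{s} ({merged[-1][2]} vs {v})"
                        )
                    merged[-1][1] = max(merged[-1][1], e)
                elif merged and s == merged[-1][1] and v == merged[-1][2]:
                    merged[-1][1] = e
                else:
                    merged.append([s, e, v])
            arr = np.asarray(merged, dtype=float)
            runs[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return cls(runs)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._runs.values())

    def iter_runs(self) -> Iterable[tuple[str, int, int, float]]:
        for chrom in self.chroms:
            starts, ends, values = self._runs[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def segments(self, chrom: str, qstart: int, qend: int) -> list[tuple[int, int, float]]:
        """Covered (start, end, value) runs clipped to [qstart, qend)."""
        if chrom not in self._runs or qend <= qstart:
            return []
        starts, ends, values = self._runs[chrom]
        lo = bisect_right(ends, qstart)  # first run ending after qstart
        out = []
        for i in range(lo, len(starts)):
            if starts[i] >= qend:
                break
            out.append((int(max(starts[i], qstart)), int(min(ends[i], qend)), float(values[i])))
        return out

    def restrict(self, chrom: str, intervals: Sequence[Interval]) -> list[tuple[int, float]]:
        """Run-length (length, value) pieces covered within the merged interval set."""
        out: list[tuple[int, float]] = []
        for qs, qe in merge_intervals(intervals):
            for s, e, v in self.segments(chrom, qs, qe):
                out.append((e - s, v))
        return out

    def value_at(self, chrom: str, pos: int) -> float | None:
        seg = self.segments(chrom, pos, pos + 1)
        return seg[0][2] if seg else None


def merge_intervals(intervals: Sequence[Interval]) -> list[Interval]:
    """Union of half-open intervals, sorted and merged (abutting joined)."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def intersect(a: Interval, b: Interval) -> int:
    """Shared bp between two half-open intervals."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


# ---------------------------------------------------------------------------
# loaders


_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')
_APPRIS_TAG = re.compile(r"appris_(principal|alternative)_(\d+)")


def _parse_appris(attrs: dict[str, str]) -> int | None:
    """APPRIS rank: explicit appris_rank attribute, else Ensembl-style tag.

    principal_N maps to rank N, alternative_N to 10+N (principal always wins).
    """
    if "appris_rank" in attrs:
        return int(attrs["appris_rank"])
    m = _APPRIS_TAG.search(attrs.get("tag", ""))
    if m:
        kind, n = m.groups()
        return int(n) if kind == "principal" else 10 + int(n)
    return None


def load_gene_models(path: str | Path, chrom_style: str = "bare") -> dict[str, GeneModel]:
    """Load gene models from GTF (Ensembl attribute dialect) or flat TSV.

    The TSV dialect has columns
    gene_id, symbol, transcript_id, chrom, strand, feature (exon|CDS),
    start, end, appris_rank  (0-based half-open coordinates).
    GTF coordinates are 1-based inclusive per the format.
    """
    path = Path(path)
    rows: list[dict] = []
    if path.suffix.lower() in (".tsv", ".txt"):
        with open(path, newline="") as handle:
            for row in csv.DictReader(handle, delimiter="\t"):
                rows.append(
                    dict(
                        gene_id=row["gene_id"],
                        symbol=row.get("symbol", row["gene_id"]),
                        transcript_id=row["transcript_id"],
                        chrom=normalize_chrom(row["chrom"], chrom_style),
                        strand=row["strand"],
                        feature=row["feature"],
                        start=int(row["start"]),
                        end=int(row["end"]),
                        appris=int(row["appris_rank"]) if row.get("appris_rank") else None,
                    )
                )
    else:
        with open(path) as handle:
            for lineno, line in enumerate(handle, start=1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    raise ValueError(f"{path} line {lineno}: expected 9 GTF columns")
                feature = fields[2]
                if feature not in ("exon", "CDS"):
                    continue
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                if "gene_id" not in attrs or "transcript_id" not in attrs:
                    raise ValueError(f"{path} line {lineno}: missing gene_id/transcript_id")
                rows.append(
                    dict(
                        gene_id=attrs["gene_id"],
                        symbol=attrs.get("gene_name", attrs["gene_id"]),
                        transcript_id=attrs["transcript_id"],
                        chrom=normalize_chrom(fields[0], chrom_style),
                        strand=fields[6],
                        feature=feature,
                        start=int(fields[3]) - 1,  # GTF 1-based inclusive -> half-open
                        end=int(fields[4]),
                        appris=_parse_appris(attrs),
                    )
                )

    # group rows into transcripts, then genes
    tx_rows: dict[str, list[dict]] = {}
    for row in rows:
        tx_rows.setdefault(row["transcript_id"], []).append(row)

    genes: dict[str, list[TranscriptModel]] = {}
    symbols: dict[str, str] = {}
    n_dropped = 0
    for tx_id, trows in sorted(tx_rows.items()):
        appris = next((r["appris"] for r in trows if r["appris"] is not None), None)
        if appris is None:
            n_dropped += 1
            continue
        exons = [(r["start"], r["end"]) for r in trows if r["feature"] == "exon"]
        cds = [(r["start"], r["end"]) for r in trows if r["feature"] == "CDS"]
        first = trows[0]
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=first["gene_id"],
            chrom=first["chrom"],
            strand=first["strand"],
            exons=exons,
            cds=cds,
            appris_rank=appris,
        )
        genes.setdefault(first["gene_id"], []).append(tx)
        symbols[first["gene_id"]] = first["symbol"]

    if n_dropped:
        logger.info("%s: dropped %d transcripts without APPRIS annotation", path, n_dropped)
    return {
        gid: GeneModel(gene_id=gid, symbol=symbols[gid], transcripts=txs)
        for gid, txs in sorted(genes.items())
    }


def attach_gene_scores(models: Mapping[str, GeneModel], path: str | Path) -> None:
    """Attach pLI/LOEUF from a TSV with columns gene_id, pli, loeuf (blank = absent)."""
    with open(path, newline="") as handle:
        for row in csv.DictReader(handle, delimiter="\t"):
            gene = models.get(row["gene_id"])
            if gene is None:
                continue
            gene.pli = float(row["pli"]) if row.get("pli") not in (None, "", "NA") else None
            gene.loeuf = float(row["loeuf"]) if row.get("loeuf") not in (None, "", "NA") else None


def load_track(path: str | Path, chrom_style: str = "bare") -> PerBaseTrack:
    """Load a bedGraph-dialect per-base track (chrom, start, end, value)."""
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            rows.append((normalize_chrom(chrom, chrom_style), int(start), int(end), float(value)))
    return PerBaseTrack.from_intervals(rows)


def load_boundaries(path: str | Path, chrom_style: str = "bare") -> list[BoundaryRecord]:
    """Load TAD boundaries from BED4 (4th column = strength)."""
    out = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, strength = line.split("\t")[:4]
            out.append(
                BoundaryRecord(normalize_chrom(chrom, chrom_style), int(start), int(end), float(strength))
            )
    return out


# ---------------------------------------------------------------------------
# expression tracks


def load_tpm_table(path: str | Path) -> pd.DataFrame:
    """TSV with a transcript_id column and one column per tissue (TPM)."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("transcript_id")


def build_expression_tracks(
    transcript_tpm: pd.DataFrame,
    models: Mapping[str, GeneModel],
    reduce: str = "sum",
) -> tuple[PerBaseTrack, PerBaseTrack]:
    """Per-base exon expression and exon inclusion tracks.

    Expression at a nucleotide is the summed TPM of every transcript (any
    gene) with an exon covering it; TPM per transcript is first pooled across
    tissues (``sum`` by default, ``mean`` optionally). Inclusion is that
    coverage divided by the total TPM of the containing gene — the estimated
    proportion of the gene's transcripts that include the nucleotide. Where
    exons of two genes overlap, the maximum per-gene inclusion is stored.
    Bases of genes whose total TPM is zero get no inclusion value.
    """
    if reduce == "sum":
        tpm = transcript_tpm.sum(axis=1)
    elif reduce == "mean":
        tpm = transcript_tpm.mean(axis=1)
    else:
        raise ValueError(f"unknown tissue reduction {reduce!r}")

    # transcripts grouped per chromosome, with per-gene totals
    gene_total: dict[str, float] = {}
    by_chrom: dict[str, list[tuple[TranscriptModel, float]]] = {}
    for gene in models.values():
        total = 0.0
        for tx in gene.transcripts:
            if tx.transcript_id not in tpm.index:
                raise KeyError(f"transcript {tx.transcript_id} missing from TPM table")
            total += float(tpm[tx.transcript_id])
            by_chrom.setdefault(tx.chrom, []).append((tx, float(tpm[tx.transcript_id])))
        gene_total[gene.gene_id] = total

    expr_rows: list[tuple[str, int, int, float]] = []
    incl_rows: list[tuple[str, int, int, float]] = []
    for chrom, txs in by_chrom.items():
        cuts = sorted({p for tx, _ in txs for s, e in tx.exons for p in (s, e)})
        if len(cuts) < 2:
            continue
        pos = np.asarray(cuts, dtype=np.int64)
        nseg = len(pos) - 1
        coverage = np.zeros(nseg)  # number of covering exons (any TPM)
        expr = np.zeros(nseg)
        gene_cov: dict[str, np.ndarray] = {}
        for tx, weight in txs:
            g = gene_cov.setdefault(tx.gene_id, np.zeros(nseg))
            for s, e in tx.exons:
                i, j = np.searchsorted(pos, [s, e])
                coverage[i:j] += 1
                expr[i:j] += weight
                g[i:j] += weight
        incl = np.full(nseg, np.nan)
        for gid, cov in gene_cov.items():
            total = gene_total[gid]
            if total <= 0:
                continue
            frac = cov / total
            mask = cov > 0
            incl[mask] = np.fmax(incl[mask], frac[mask])  # fmax ignores NaN
        for i in range(nseg):
            if coverage[i] > 0:
                expr_rows.append((chrom, int(pos[i]), int(pos[i + 1]), float(expr[i])))
                if np.isfinite(incl[i]):
                    incl_rows.append((chrom, int(pos[i]), int(pos[i + 1]), float(incl[i])))
    return PerBaseTrack.from_intervals(expr_rows), PerBaseTrack.from_intervals(incl_rows)


# ---------------------------------------------------------------------------
# bundle + exon overlap


@dataclass
class AnnotationBundle:
    """All annotation resources needed to featurize an SV."""

    genes: dict[str, GeneModel]
    conservation: PerBaseTrack
    expression: PerBaseTrack
    inclusion: PerBaseTrack
    boundaries: list[BoundaryRecord]
    _exon_index: dict[str, IntervalTree] = field(default=None, repr=False, compare=False)

    def exon_index(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree of principal-transcript exons."""
        if self._exon_index is None:
            trees: dict[str, IntervalTree] = {}
            for gene in self.genes.values():
                tree = trees.setdefault(gene.chrom, IntervalTree())
                for idx, (s, e) in enumerate(gene.principal.exons):
                    tree.addi(s, e, (gene.gene_id, idx))
            self._exon_index = trees
        return self._exon_index


def exon_overlap(
    sv: SVRecord, bundle: AnnotationBundle
) -> list[tuple[GeneModel, list[int]]]:
    """Genes whose principal transcript shares >= 1 bp of exon with the SV.

    Returns (gene, transcript-order exon indices overlapped), sorted by
    gene_id; exon indices sorted ascending. Empty for wholly intronic or
    intergenic SVs.
    """
    tree = bundle.exon_index().get(sv.chrom)
    if tree is None:
        return []
    hits: dict[str, set[int]] = {}
    for iv in tree.overlap(sv.start, sv.end):
        gid, exon_idx = iv.data
        hits.setdefault(gid, set()).add(exon_idx)
    return [(bundle.genes[gid], sorted(idxs)) for gid, idxs in sorted(hits.items())]


def load_bundle(directory: str | Path, chrom_style: str = "bare") -> AnnotationBundle:
    """Load a full annotation bundle from a directory.

    Expected files: gene_models.gtf (or .tsv), gene_scores.tsv,
    conservation.bedgraph, tpm.tsv, tad_boundaries.bed.
    """
    directory = Path(directory)
    gtf = directory / "gene_models.gtf"
    if not gtf.exists():
        gtf = directory / "gene_models.tsv"
    genes = load_gene_models(gtf, chrom_style)
    attach_gene_scores(genes, directory / "gene_scores.tsv")
    conservation = load_track(directory / "conservation.bedgraph", chrom_style)
    tpm = load_tpm_table(directory / "tpm.tsv")
    expression, inclusion = build_expression_tracks(tpm, genes)
    boundaries = load_boundaries(directory / "tad_boundaries.bed", chrom_style)
    return AnnotationBundle(
        genes=genes,
        conservation=conservation,
        expression=expression,
        inclusion=inclusion,
        boundaries=boundaries,
    )
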