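"""Synthetic annotation bundles and labeled SV sets.

Everything the scorer consumes — gene models with APPRIS-ranked transcripts,
a conservation track, transcript TPMs, gene constraint scores, TAD
boundaries, and labeled DEL/DUP sets — can be generated from a seed, so the
whole pipeline runs end to end with no external downloads. The labeled sets
carry a *planted* signal whose strength is controlled by effect-size
parameters: pathogenic SVs preferentially hit constrained genes (high pLI,
low LOEUF, conservation-boosted exons) and cover start codons, while benign
SVs land uniformly on exonic space. With all effect sizes at zero the two
classes are generated identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from tempfile import TemporaryDirectory
from typing import Sequence

import numpy as np
import pandas as pd

from svforest.annotation import AnnotationBundle, load_bundle
from svforest.features import FEATURE_NAMES, FeatureVector, assemble_features, NotScoreableError
from svforest.sv_io import SVRecord

__all__ = [
    "FixtureSpec",
    "generate_annotation_bundle",
    "generate_labeled_svs",
    "random_sv_set",
    "worked_feature_case",
    "planted_training_frame",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic genome and labeled SV sets.

    Geometry: ``n_genes`` spread round-robin over ``n_chromosomes`` of
    ``chrom_length`` bp; per gene ``exons_per_gene`` exons with lengths and
    intron gaps drawn uniformly from the stated ranges. Conservation is
    normal per short run (``phylop_mean``/``phylop_sd``), boosted additively
    by ``phylop_boost`` on constrained genes' exons. Constraint scores are a
    two-component mixture (``constrained_fraction`` of genes strongly
    constrained), absent with ``missing_score_prob``. Labeled SV sizes are
    log-uniform over ``sv_size_range`` (bp); pathogenic placement follows the
    effect sizes ``p_constrained_target`` (probability of targeting a
    constrained gene) and ``p_cover_start`` (probability of covering that
    gene's start codon).
    """

    n_genes: int = 80
    n_chromosomes: int = 8
    chrom_length: int = 2_500_000
    exons_per_gene: tuple[int, int] = (3, 12)
    exon_length: tuple[int, int] = (60, 300)
    intron_length: tuple[int, int] = (500, 5000)
    no_cds_prob: float = 0.05
    max_alt_transcripts: int = 2
    exon_skip_prob: float = 0.3
    phylop_mean: float = 1.0
    phylop_sd: float = 1.5
    phylop_boost: float = 2.0
    phylop_run_length: tuple[int, int] = (3, 15)
    constrained_fraction: float = 0.25
    missing_score_prob: float = 0.1
    n_tissues: int = 3
    tad_per_chrom: int = 20
    tad_length: tuple[int, int] = (5_000, 20_000)
    n_pathogenic: int = 500
    n_benign_per_tier: tuple[int, ...] = (700,)
    sv_size_range: tuple[int, int] = (50, 100_000)
    p_constrained_target: float = 0.85
    p_cover_start: float = 0.7
    del_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_chromosomes", "chrom_length", "n_pathogenic"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in (
            "no_cds_prob",
            "exon_skip_prob",
            "constrained_fraction",
            "missing_score_prob",
            "p_constrained_target",
            "p_cover_start",
            "del_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sv_size_range[0] < 1 or self.sv_size_range[1] < self.sv_size_range[0]:
            raise ValueError("invalid sv_size_range")


# ---------------------------------------------------------------------------
# internal genome synthesis


def _uniform_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def _synthesize_genes(spec: FixtureSpec, rng: np.random.Generator) -> list[dict]:
    """Plan genes as plain dicts (gene_id, chrom, strand, transcripts, scores)."""
    genes: list[dict] = []
    chroms = [str(c + 1) for c in range(spec.n_chromosomes)]
    per_chrom = {c: 10_000 for c in chroms}  # placement cursor
    for g in range(spec.n_genes):
        chrom = chroms[g % spec.n_chromosomes]
        n_ex = _uniform_int(rng, spec.exons_per_gene)
        lengths = [_uniform_int(rng, spec.exon_length) for _ in range(n_ex)]
        gaps = [_uniform_int(rng, spec.intron_length) for _ in range(n_ex - 1)]
        span = sum(lengths) + sum(gaps)
        start = per_chrom[chrom]
        if start + span > spec.chrom_length - 10_000:
            raise ValueError(
                f"infeasible geometry: gene {g} does not fit on chromosome {chrom} "
                f"(cursor {start}, span {span}, length {spec.chrom_length})"
            )
        exons = []
        pos = start
        for i, length in enumerate(lengths):
            exons.append((pos, pos + length))
            pos += length + (gaps[i] if i < n_ex - 1 else 0)
        per_chrom[chrom] = pos + _uniform_int(rng, (20_000, 120_000))
        strand = "+" if rng.random() < 0.5 else "-"

        if rng.random() < spec.no_cds_prob:
            cds: list[tuple[int, int]] = []
        else:
            lo_off = int(rng.integers(0, max(1, lengths[0] - 3)))
            hi_off = int(rng.integers(0, max(1, lengths[-1] - 3)))
            cds_lo = exons[0][0] + lo_off
            cds_hi = exons[-1][1] - hi_off
            cds = [
                (max(s, cds_lo), min(e, cds_hi))
                for s, e in exons
                if min(e, cds_hi) > max(s, cds_lo)
            ]

        gene_id = f"G{g:04d}"
        transcripts = [
            dict(transcript_id=f"{gene_id}.t1", appris_rank=1, exons=list(exons), cds=list(cds))
        ]
        n_alt = int(rng.integers(0, spec.max_alt_transcripts + 1)) if n_ex > 2 else 0
        for a in range(n_alt):
            keep = [exons[0]]
            dropped = False
            for e in exons[1:-1]:
                if rng.random() < spec.exon_skip_prob:
                    dropped = True
                    continue
                keep.append(e)
            keep.append(exons[-1])
            if not dropped:  # force a distinct isoform
                drop_idx = int(rng.integers(1, n_ex - 1))
                keep = [e for i, e in enumerate(exons) if i != drop_idx]
            alt_cds = [
                (max(s, c0), min(e, c1))
                for s, e in keep
                for c0, c1 in cds
                if min(e, c1) > max(s, c0)
            ]
            transcripts.append(
                dict(transcript_id=f"{gene_id}.t{a+2}", appris_rank=a + 2, exons=keep, cds=alt_cds)
            )

        constrained = rng.random() < spec.constrained_fraction
        if rng.random() < spec.missing_score_prob:
            pli, loeuf = None, None
        elif constrained:
            pli = round(float(rng.beta(8, 1)), 4)
            loeuf = round(float(rng.uniform(0.1, 0.35)), 4)
        else:
            pli = round(float(rng.beta(1, 8)), 4)
            loeuf = round(float(rng.uniform(0.8, 1.8)), 4)
        genes.append(
            dict(
                gene_id=gene_id,
                symbol=f"SYN{g:04d}",
                chrom=chrom,
                strand=strand,
                transcripts=transcripts,
                constrained=constrained,
                pli=pli,
                loeuf=loeuf,
            )
        )
    return genes


def _write_gtf(genes: Sequence[dict], path: Path) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene["transcripts"]:
                attrs = (
                    f'gene_id "{gene["gene_id"]}"; gene_name "{gene["symbol"]}"; '
                    f'transcript_id "{tx["transcript_id"]}"; appris_rank "{tx["appris_rank"]}";'
                )
                for feature, ivals in (("exon", tx["exons"]), ("CDS", tx["cds"])):
                    for s, e in sorted(ivals):
                        fh.write(
                            f'{gene["chrom"]}\tsvforest_fixture\t{feature}\t{s + 1}\t{e}\t.\t'
                            f'{gene["strand"]}\t.\t{attrs}\n'
                        )


def generate_annotation_bundle(spec: FixtureSpec, out_dir: str | Path) -> AnnotationBundle:
    """Write a synthetic annotation bundle into ``out_dir`` and load it back.

    Files: gene_models.gtf, gene_scores.tsv, conservation.bedgraph, tpm.tsv,
    tad_boundaries.bed. Byte-identical for the same spec (including seed).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    genes = _synthesize_genes(spec, rng)
    _write_gtf(genes, out_dir / "gene_models.gtf")

    with open(out_dir / "gene_scores.tsv", "w") as fh:
        fh.write("gene_id\tpli\tloeuf\n")
        for gene in genes:
            pli = "" if gene["pli"] is None else f'{gene["pli"]:.4f}'
            loeuf = "" if gene["loeuf"] is None else f'{gene["loeuf"]:.4f}'
            fh.write(f'{gene["gene_id"]}\t{pli}\t{loeuf}\n')

    with open(out_dir / "conservation.bedgraph", "w") as fh:
        for gene in genes:
            boost = spec.phylop_boost if gene["constrained"] else 0.0
            for s, e in sorted(gene["transcripts"][0]["exons"]):
                pos = s
                while pos < e:
                    run = min(_uniform_int(rng, spec.phylop_run_length), e - pos)
                    value = rng.normal(spec.phylop_mean + boost, spec.phylop_sd)
                    fh.write(f'{gene["chrom"]}\t{pos}\t{pos + run}\t{value:.3f}\n')
                    pos += run

    tissues = [f"tissue{i+1}" for i in range(spec.n_tissues)]
    with open(out_dir / "tpm.tsv", "w") as fh:
        fh.write("transcript_id\t" + "\t".join(tissues) + "\n")
        for gene in genes:
            for tx in gene["transcripts"]:
                tpms = rng.lognormal(0.5, 1.0, size=spec.n_tissues)
                fh.write(tx["transcript_id"] + "\t" + "\t".join(f"{t:.3f}" for t in tpms) + "\n")

    with open(out_dir / "tad_boundaries.bed", "w") as fh:
        for c in range(spec.n_chromosomes):
            chrom = str(c + 1)
            for _ in range(spec.tad_per_chrom):
                length = _uniform_int(rng, spec.tad_length)
                start = int(rng.integers(0, spec.chrom_length - length))
                strength = rng.uniform(0, 1)
                fh.write(f"{chrom}\t{start}\t{start + length}\t{strength:.3f}\n")

    return load_bundle(out_dir)


# ---------------------------------------------------------------------------
# labeled SV generation


def _log_uniform_size(rng: np.random.Generator, size_range: tuple[int, int]) -> int:
    lo, hi = size_range
    return int(np.clip(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))), lo, hi))


def _exon_catalog(bundle: AnnotationBundle) -> tuple[list[tuple[str, int, int, str]], np.ndarray]:
    """Principal exons of every gene with length weights for uniform-by-base picks."""
    exons = []
    for gene in bundle.genes.values():
        for s, e in gene.principal.exons:
            exons.append((gene.chrom, s, e, gene.gene_id))
    weights = np.array([e - s for _, s, e, _ in exons], dtype=float)
    return exons, weights / weights.sum()


def _place_over_anchor(
    rng: np.random.Generator, anchor: int, size: int, chrom_length: int
) -> tuple[int, int]:
    """Random [start, end) of the given size guaranteed to cover ``anchor``."""
    start = int(rng.integers(anchor - size + 1, anchor + 1))
    start = max(0, min(start, chrom_length - size))
    return start, start + size


def generate_labeled_svs(
    spec: FixtureSpec, bundle: AnnotationBundle, seed: int | None = None
) -> tuple[list[SVRecord], list[list[SVRecord]]]:
    """Pathogenic SVs plus tiered benign SV sets over an existing bundle.

    Every emitted SV overlaps >= 1 principal exon by construction and sizes
    are log-uniform over ``spec.sv_size_range``. Benign records carry a small
    random MAF and Poisson homozygote counts; pathogenic records carry none.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    exons, weights = _exon_catalog(bundle)
    constrained = [
        g for g in bundle.genes.values() if g.pli is not None and g.pli > 0.5 and g.principal.cds
    ]

    def benign_style(sv_id: str, label: str, source: str) -> SVRecord:
        idx = int(rng.choice(len(exons), p=weights))
        chrom, s, e, _ = exons[idx]
        size = _log_uniform_size(rng, spec.sv_size_range)
        anchor = int(rng.integers(s, e))
        start, end = _place_over_anchor(rng, anchor, size, spec.chrom_length)
        svtype = "DEL" if rng.random() < spec.del_fraction else "DUP"
        maf = float(rng.uniform(0, 0.009)) if label == "benign" else None
        n_hom = int(rng.poisson(0.5)) if label == "benign" else None
        return SVRecord(sv_id, chrom, start, end, svtype, maf, n_hom, label, source)

    pathogenic: list[SVRecord] = []
    for i in range(spec.n_pathogenic):
        sv_id = f"path{i:05d}"
        if constrained and rng.random() < spec.p_constrained_target:
            gene = constrained[int(rng.choice(len(constrained)))]
            size = _log_uniform_size(rng, spec.sv_size_range)
            if rng.random() < spec.p_cover_start:
                anchor = gene.principal.start_codon_base()
            else:
                s, e = gene.principal.exons[int(rng.choice(len(gene.principal.exons)))]
                anchor = int(rng.integers(s, e))
            start, end = _place_over_anchor(rng, anchor, size, spec.chrom_length)
            svtype = "DEL" if rng.random() < spec.del_fraction else "DUP"
            pathogenic.append(
                SVRecord(sv_id, gene.chrom, start, end, svtype, None, None, "pathogenic", "planted")
            )
        else:
            sv = benign_style(sv_id, "pathogenic", "planted")
            pathogenic.append(sv)

    tiers: list[list[SVRecord]] = []
    for t, count in enumerate(spec.n_benign_per_tier):
        tiers.append(
            [benign_style(f"ben{t}_{i:05d}", "benign", f"tier{t + 1}") for i in range(count)]
        )
    return pathogenic, tiers


def random_sv_set(
    n: int,
    seed: int,
    size_range: tuple[int, int] = (50, 3_000_000),
    n_chromosomes: int = 4,
    span: int = 50_000_000,
    svtype: str | None = None,
    label: str = "unlabeled",
    prefix: str = "sv",
) -> list[SVRecord]:
    """Plain random SVs (no annotation constraint) for interval-algebra tests.

    Sizes log-uniform over ``size_range``; starts uniform over ``span``;
    DEL/DUP alternating at random unless ``svtype`` pins one type.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        size = _log_uniform_size(rng, size_range)
        chrom = str(int(rng.integers(1, n_chromosomes + 1)))
        start = int(rng.integers(0, span - size))
        t = svtype or ("DEL" if rng.random() < 0.5 else "DUP")
        out.append(SVRecord(f"{prefix}{i:05d}", chrom, start, start + size, t, label=label))
    return out


# ---------------------------------------------------------------------------
# worked golden case


def worked_feature_case(out_dir: str | Path | None = None):
    """A hand-constructed single-gene case with closed-form feature values.

    One plus-strand gene on chromosome 1 with five exons
    [100,200) [300,390) [500,620) [700,790) [900,1000), CDS running from 150
    to 950 (total 400 coding bases), a principal transcript carrying all five
    exons and one alternative transcript skipping exon 3. The deletion
    [300,620) removes exons 2 and 3 entirely. Expected features (exact):

    - cds_frac_from_start  = 50/400  (coding bases 5' of position 300)
    - cds_frac_from_stop   = 140/400 (coding bases 3' of position 619)
    - cds_frac_overlapped  = 210/400
    - phylop_top400        = mean(2.0, 3.0, 1.0) = 2.0   (3 runs < 400)
    - exon_expression_top400 = mean(8.0, 6.0) = 7.0      (TPM 6 + 2 on exon 2)
    - exon_inclusion_top400  = mean(1.0, 0.75) = 0.875
    - tad_strength_max     = 0.7  (the 0.95 boundary lies outside the SV)
    - loeuf_min = loeuf_high_impact_min = 0.3  (52.5% CDS > 50% trigger)
    - pli_max = pli_high_impact_max = 0.9
    - all_exons_inframe_skippable = True  (lengths 90 and 120, both internal)
    - any_exon_constitutive = True        (exon 2 is in both transcripts)
    - min_exon_order = 1; min_exons_in_gene = 5; max_exons_overlapped = 2
    - is_deletion = True

    Returns (bundle, sv, expected FeatureVector). Files are written into
    ``out_dir`` (a temporary directory by default) and loaded back through
    the standard loaders.
    """
    ctx = None
    if out_dir is None:
        ctx = TemporaryDirectory()
        out_dir = ctx.name
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    exons = [(100, 200), (300, 390), (500, 620), (700, 790), (900, 1000)]
    cds = [(150, 200), (300, 390), (500, 620), (700, 790), (900, 950)]
    alt_exons = [exons[0], exons[1], exons[3], exons[4]]
    alt_cds = [cds[0], cds[1], cds[3], cds[4]]
    genes = [
        dict(
            gene_id="GCASE",
            symbol="CASE1",
            chrom="1",
            strand="+",
            transcripts=[
                dict(transcript_id="GCASE.t1", appris_rank=1, exons=exons, cds=cds),
                dict(transcript_id="GCASE.t2", appris_rank=2, exons=alt_exons, cds=alt_cds),
            ],
        )
    ]
    _write_gtf(genes, out_dir / "gene_models.gtf")
    (out_dir / "gene_scores.tsv").write_text("gene_id\tpli\tloeuf\nGCASE\t0.9\t0.3\n")
    conservation = [
        ("1", 100, 200, 0.5),
        ("1", 300, 390, 2.0),
        ("1", 500, 560, 3.0),
        ("1", 560, 620, 1.0),
        ("1", 700, 790, 0.5),
        ("1", 900, 1000, 0.5),
    ]
    (out_dir / "conservation.bedgraph").write_text(
        "".join(f"{c}\t{s}\t{e}\t{v}\n" for c, s, e, v in conservation)
    )
    (out_dir / "tpm.tsv").write_text(
        "transcript_id\ttissueA\ttissueB\nGCASE.t1\t4\t2\nGCASE.t2\t1\t1\n"
    )
    (out_dir / "tad_boundaries.bed").write_text("1\t580\t600\t0.7\n1\t2000\t2100\t0.95\n")

    bundle = load_bundle(out_dir)
    sv = SVRecord("case_del", "1", 300, 620, "DEL", label="pathogenic")
    expected = FeatureVector(
        cds_frac_from_start=50 / 400,
        cds_frac_from_stop=140 / 400,
        cds_frac_overlapped=210 / 400,
        phylop_top400=2.0,
        exon_expression_top400=7.0,
        exon_inclusion_top400=0.875,
        tad_strength_max=0.7,
        loeuf_min=0.3,
        loeuf_high_impact_min=0.3,
        pli_max=0.9,
        pli_high_impact_max=0.9,
        all_exons_inframe_skippable=True,
        any_exon_constitutive=True,
        min_exon_order=1,
        min_exons_in_gene=5,
        max_exons_overlapped=2,
        is_deletion=True,
    )
    if ctx is not None:
        bundle._tmpdir = ctx  # keep the backing directory alive with the bundle
    return bundle, sv, expected


# ---------------------------------------------------------------------------
# convenience: planted training data as a feature frame


def planted_training_frame(
    spec: FixtureSpec | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Generate bundle + labeled SVs and featurize them into one DataFrame.

    Columns: the 17 features (NaN = missing) plus id, chrom, size, svtype and
    label. Pathogenic records come first, then benign tiers in order.
    """
    spec = spec or FixtureSpec()
    if seed is not None:
        spec = replace(spec, seed=seed)
    ctx = None
    if out_dir is None:
        ctx = TemporaryDirectory()
        out_dir = ctx.name
    try:
        bundle = generate_annotation_bundle(spec, out_dir)
        pathogenic, tiers = generate_labeled_svs(spec, bundle)
        rows = []
        for sv in pathogenic + [sv for tier in tiers for sv in tier]:
            try:
                vec = assemble_features(sv, bundle)
            except NotScoreableError:  # pragma: no cover - construction prevents this
                continue
            row = dict(zip(FEATURE_NAMES, vec.to_array()))
            row.update(id=sv.id, chrom=sv.chrom, size=sv.size, svtype=sv.svtype, label=sv.label)
            rows.append(row)
        return pd.DataFrame(rows)
    finally:
        if ctx is not None:
            ctx.cleanup()
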