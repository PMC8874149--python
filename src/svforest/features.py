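"""The 17 annotation features for one exon-altering SV.

Feature groups: coding-sequence disruption (3), conservation (1), expression
(3, counting TAD boundary strength), gene importance (4), and exon structure
(6, counting the DEL/DUP indicator). When an SV spans several genes each
feature is aggregated toward the most severely impacted gene (min or max as
appropriate); missing values are filled by training-set medians at inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from svforest.annotation import (
    AnnotationBundle,
    BoundaryRecord,
    GeneModel,
    PerBaseTrack,
    exon_overlap,
    intersect,
    merge_intervals,
)
from svforest.sv_io import SVRecord

logger = logging.getLogger(__name__)

#: Canonical feature order; the trained model stores and enforces it.
FEATURE_NAMES = (
    "cds_frac_from_start",
    "cds_frac_from_stop",
    "cds_frac_overlapped",
    "phylop_top400",
    "exon_expression_top400",
    "exon_inclusion_top400",
    "tad_strength_max",
    "loeuf_min",
    "loeuf_high_impact_min",
    "pli_max",
    "pli_high_impact_max",
    "all_exons_inframe_skippable",
    "any_exon_constitutive",
    "min_exon_order",
    "min_exons_in_gene",
    "max_exons_overlapped",
    "is_deletion",
)

BOOLEAN_FEATURES = ("all_exons_inframe_skippable", "any_exon_constitutive", "is_deletion")

#: Number of highest-valued track units averaged for conservation/expression.
TOP_N = 400


class NotScoreableError(ValueError):
    """Raised for SVs that do not alter any exon (the score is undefined)."""


@dataclass
class FeatureVector:
    """One SV's 17 features; ``None`` marks a missing (unimputed) value."""

    cds_frac_from_start: float | None = None
    cds_frac_from_stop: float | None = None
    cds_frac_overlapped: float | None = None
    phylop_top400: float | None = None
    exon_expression_top400: float | None = None
    exon_inclusion_top400: float | None = None
    tad_strength_max: float | None = None
    loeuf_min: float | None = None
    loeuf_high_impact_min: float | None = None
    pli_max: float | None = None
    pli_high_impact_max: float | None = None
    all_exons_inframe_skippable: bool | None = None
    any_exon_constitutive: bool | None = None
    min_exon_order: int | None = None
    min_exons_in_gene: int | None = None
    max_exons_overlapped: int | None = None
    is_deletion: bool | None = None

    def to_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    @property
    def missing_mask(self) -> dict[str, bool]:
        return {name: getattr(self, name) is None for name in FEATURE_NAMES}

    def to_array(self) -> np.ndarray:
        """Numeric vector in canonical order; missing values become NaN."""
        out = np.empty(len(FEATURE_NAMES))
        for i, name in enumerate(FEATURE_NAMES):
            v = getattr(self, name)
            out[i] = np.nan if v is None else float(v)
        return out

    def imputed(self, medians: Mapping[str, float]) -> "FeatureVector":
        """Copy with missing fields replaced by the supplied training medians."""
        values = self.to_dict()
        for name, v in values.items():
            if v is None:
                if name not in medians:
                    raise KeyError(f"no imputation value for feature {name!r}")
                fill = medians[name]
                values[name] = bool(fill) if name in BOOLEAN_FEATURES else fill
        return FeatureVector(**values)


# ---------------------------------------------------------------------------
# per-feature computations


def _disrupted_span(sv: SVRecord, cds: Sequence[tuple[int, int]]) -> tuple[int, int] | None:
    """Genomic [min, max] positions of CDS bases inside the SV, or None."""
    gmin, gmax = None, None
    for s, e in cds:
        if intersect((s, e), sv.interval()) > 0:
            lo = max(s, sv.start)
            hi = min(e, sv.end) - 1
            gmin = lo if gmin is None else min(gmin, lo)
            gmax = hi if gmax is None else max(gmax, hi)
    return None if gmin is None else (gmin, gmax)


def cds_triple_for_gene(sv: SVRecord, gene: GeneModel) -> tuple[float, float, float] | None:
    """(frac_from_start, frac_from_stop, frac_overlapped) on the principal CDS.

    frac_from_start is the fraction of CDS 5' of the first disrupted coding
    base (1.0 when nothing coding is disrupted); frac_from_stop the symmetric
    3' fraction; frac_overlapped the fraction of coding bases inside the SV.
    Strand-aware. Returns None for genes without CDS.
    """
    tx = gene.principal
    cds = tx.cds
    L = tx.cds_length
    if L == 0:
        return None
    overlapped = sum(intersect(c, sv.interval()) for c in cds)
    if overlapped == 0:
        return (1.0, 1.0, 0.0)
    gmin, gmax = _disrupted_span(sv, cds)
    bp_below = sum(max(0, min(e, gmin) - s) for s, e in cds)  # genomic < gmin
    bp_above = sum(max(0, e - max(s, gmax + 1)) for s, e in cds)  # genomic > gmax
    if tx.strand == "+":
        from_start, from_stop = bp_below, bp_above
    else:
        from_start, from_stop = bp_above, bp_below
    return (from_start / L, from_stop / L, overlapped / L)


def cds_features(
    sv: SVRecord, genes: Sequence[GeneModel]
) -> tuple[float | None, float | None, float | None]:
    """Aggregate the per-gene CDS triple: min, min, max over overlapped genes."""
    triples = [t for g in genes if (t := cds_triple_for_gene(sv, g)) is not None]
    if not triples:
        return (None, None, None)
    return (
        min(t[0] for t in triples),
        min(t[1] for t in triples),
        max(t[2] for t in triples),
    )


def top400_track_mean(
    track: PerBaseTrack,
    chrom: str,
    exon_space: Sequence[tuple[int, int]],
    n_top: int = TOP_N,
    unit: str = "interval",
) -> float | None:
    """Mean of the highest-valued track units overlapping the SV's exonic span.

    The track is restricted to ``exon_space`` (SV ∩ exons) and decomposed into
    run-length intervals. With ``unit='interval'`` (default) each run counts
    once regardless of length: the mean of the ``n_top`` highest-valued runs,
    or of all runs when fewer than ``n_top`` are covered. ``unit='nucleotide'``
    weights runs by length and averages the ``n_top`` highest-valued bases.
    Uncovered bases contribute nothing; no coverage at all yields None.
    """
    runs = track.restrict(chrom, exon_space)
    if not runs:
        return None
    if unit == "interval":
        values = np.sort(np.array([v for _, v in runs]))[::-1]
        take = values[:n_top] if len(values) >= n_top else values
        return float(np.mean(take))
    if unit == "nucleotide":
        lengths = np.array([l for l, _ in runs], dtype=float)
        values = np.array([v for _, v in runs])
        order = np.argsort(values)[::-1]
        lengths, values = lengths[order], values[order]
        total = lengths.sum()
        budget = float(min(n_top, total))
        taken = np.minimum(lengths, np.maximum(0.0, budget - np.concatenate(([0.0], np.cumsum(lengths)[:-1]))))
        return float(np.sum(taken * values) / budget)
    raise ValueError(f"unknown top-400 unit {unit!r}")


def _covers_base(sv: SVRecord, base: int | None) -> bool:
    return base is not None and sv.start <= base < sv.end


def high_impact(sv: SVRecord, gene: GeneModel, codon: str) -> bool:
    """A gene is highly impacted when the SV covers its principal start (for
    pLI) or stop (for LOEUF) codon, or overlaps > 50% of its CDS."""
    tx = gene.principal
    base = tx.start_codon_base() if codon == "start" else tx.stop_codon_base()
    if _covers_base(sv, base):
        return True
    triple = cds_triple_for_gene(sv, gene)
    return triple is not None and triple[2] > 0.5


def gene_importance_features(
    sv: SVRecord, genes: Sequence[GeneModel]
) -> tuple[float | None, float | None, float | None, float | None]:
    """(loeuf_min, loeuf_high_impact_min, pli_max, pli_high_impact_max)."""
    loeufs = [g.loeuf for g in genes if g.loeuf is not None]
    plis = [g.pli for g in genes if g.pli is not None]
    hi_loeufs = [g.loeuf for g in genes if g.loeuf is not None and high_impact(sv, g, "stop")]
    hi_plis = [g.pli for g in genes if g.pli is not None and high_impact(sv, g, "start")]
    return (
        min(loeufs) if loeufs else None,
        min(hi_loeufs) if hi_loeufs else None,
        max(plis) if plis else None,
        max(hi_plis) if hi_plis else None,
    )


def is_constitutive(gene: GeneModel, exon: tuple[int, int]) -> bool:
    """An exon is constitutive when its exact coordinates appear in every
    annotated transcript of its gene."""
    return all(exon in tx.exons for tx in gene.transcripts)


def exon_structure_features(
    sv: SVRecord, gene_hits: Sequence[tuple[GeneModel, Sequence[int]]]
) -> tuple[bool, bool, int, int, int]:
    """(all_exons_inframe_skippable, any_exon_constitutive, min_exon_order,
    min_exons_in_gene, max_exons_overlapped).

    Exon order counts the exons preceding a given exon in its principal
    transcript (0 for the first exon). An exon is in-frame skippable when its
    length is a multiple of 3 and it is internal (neither first nor last).
    """
    if not gene_hits:
        raise ValueError("exon_structure_features requires >=1 overlapped exon")
    inframe = True
    constitutive = False
    min_order: int | None = None
    min_exons: int | None = None
    max_overlapped = 0
    for gene, idxs in gene_hits:
        exons = gene.principal.exons
        n = len(exons)
        min_exons = n if min_exons is None else min(min_exons, n)
        max_overlapped = max(max_overlapped, len(idxs))
        for idx in idxs:
            min_order = idx if min_order is None else min(min_order, idx)
            s, e = exons[idx]
            if (e - s) % 3 != 0 or idx == 0 or idx == n - 1:
                inframe = False
            if is_constitutive(gene, (s, e)):
                constitutive = True
    return (inframe, constitutive, min_order, min_exons, max_overlapped)


def tad_feature(sv: SVRecord, boundaries: Sequence[BoundaryRecord]) -> float | None:
    """Maximum strength among TAD boundaries intersecting the SV (half-open)."""
    strengths = [
        b.strength
        for b in boundaries
        if b.chrom == sv.chrom and intersect((b.start, b.end), sv.interval()) > 0
    ]
    return max(strengths) if strengths else None


# ---------------------------------------------------------------------------
# assembly


def sv_exon_space(
    sv: SVRecord, gene_hits: Sequence[tuple[GeneModel, Sequence[int]]]
) -> list[tuple[int, int]]:
    """SV ∩ principal-transcript exons, merged across overlapped genes."""
    pieces = []
    for gene, _ in gene_hits:
        for s, e in gene.principal.exons:
            lo, hi = max(s, sv.start), min(e, sv.end)
            if hi > lo:
                pieces.append((lo, hi))
    return merge_intervals(pieces)


def assemble_features(
    sv: SVRecord,
    bundle: AnnotationBundle,
    medians: Mapping[str, float] | None = None,
    top400_unit: str = "interval",
) -> FeatureVector:
    """Compute all 17 features for one SV against an annotation bundle.

    SVs that do not overlap any principal-transcript exon are refused: the
    score is defined for exon-altering SVs only. When ``medians`` is given
    (inference), missing values are imputed; otherwise they remain ``None``
    (training-median computation).
    """
    hits = exon_overlap(sv, bundle)
    if not hits:
        raise NotScoreableError(
            f"SV {sv.id} ({sv.chrom}:{sv.start}-{sv.end}) not scoreable; "
            "exon-altering SVs only"
        )
    genes = [g for g, _ in hits]
    exon_space = sv_exon_space(sv, hits)
    from_start, from_stop, overlapped = cds_features(sv, genes)
    loeuf_min, loeuf_hi, pli_max, pli_hi = gene_importance_features(sv, genes)
    inframe, constitutive, min_order, min_exons, max_overlap = exon_structure_features(sv, hits)
    vec = FeatureVector(
        cds_frac_from_start=from_start,
        cds_frac_from_stop=from_stop,
        cds_frac_overlapped=overlapped,
        phylop_top400=top400_track_mean(bundle.conservation, sv.chrom, exon_space, unit=top400_unit),
        exon_expression_top400=top400_track_mean(bundle.expression, sv.chrom, exon_space, unit=top400_unit),
        exon_inclusion_top400=top400_track_mean(bundle.inclusion, sv.chrom, exon_space, unit=top400_unit),
        tad_strength_max=tad_feature(sv, bundle.boundaries),
        loeuf_min=loeuf_min,
        loeuf_high_impact_min=loeuf_hi,
        pli_max=pli_max,
        pli_high_impact_max=pli_hi,
        all_exons_inframe_skippable=inframe,
        any_exon_constitutive=constitutive,
        min_exon_order=min_order,
        min_exons_in_gene=min_exons,
        max_exons_overlapped=max_overlap,
        is_deletion=(sv.svtype == "DEL"),
    )
    if medians is not None:
        vec = vec.imputed(medians)
    return vec


def features_to_frame(
    vectors: Iterable[FeatureVector], ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Stack FeatureVectors into a DataFrame (NaN = missing), canonical order."""
    vectors = list(vectors)
    data = np.vstack([v.to_array() for v in vectors]) if vectors else np.empty((0, len(FEATURE_NAMES)))
    return pd.DataFrame(data, columns=list(FEATURE_NAMES), index=ids)


def compute_medians(vectors: Sequence[FeatureVector]) -> dict[str, float]:
    """Per-feature imputation values from a training set.

    Numeric features use the median of observed values; boolean features use
    the majority value (the median of a 0/1 variable), ties going to False.
    Features missing everywhere fall back to 0.
    """
    df = features_to_frame(vectors)
    out: dict[str, float] = {}
    for name in FEATURE_NAMES:
        col = df[name].dropna()
        if col.empty:
            out[name] = 0.0
        elif name in BOOLEAN_FEATURES:
            out[name] = 1.0 if col.mean() > 0.5 else 0.0
        else:
            out[name] = float(col.median())
    return out


#: Features whose sign is reversed before correlation so that related features
#: correlate positively (lower LOEUF and larger undisrupted CDS fractions mean
#: *more* severe on the flipped scale).
DEFAULT_SIGN_FLIPS = (
    "loeuf_min",
    "loeuf_high_impact_min",
    "cds_frac_from_start",
    "cds_frac_from_stop",
)


def feature_correlation_matrix(
    vectors: Sequence[FeatureVector] | pd.DataFrame,
    sign_flips: Sequence[str] = DEFAULT_SIGN_FLIPS,
) -> pd.DataFrame:
    """17x17 Spearman rank correlation, rows/columns ordered by clustering.

    Pairwise-complete Spearman correlations; the configured features are
    sign-flipped first to reduce negative correlation. Rows and columns are
    reordered by average-linkage agglomerative clustering on correlation
    distance (1 - rho). Constant features get correlation 0 with a warning.
    """
    df = vectors.copy() if isinstance(vectors, pd.DataFrame) else features_to_frame(list(vectors))
    if len(df) < 3:
        raise ValueError("need >= 3 feature vectors for a correlation matrix")
    for name in sign_flips:
        df[name] = -df[name]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant columns raise spurious warnings
        corr = df.corr(method="spearman")
    if corr.isna().any().any():
        logger.warning("constant feature(s): undefined correlations reported as 0")
        corr = corr.fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    dist = squareform(np.clip(1.0 - corr.values, 0.0, 2.0), checks=False)
    order = leaves_list(linkage(dist, method="average"))
    names = [corr.columns[i] for i in order]
    return corr.loc[names, names]
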