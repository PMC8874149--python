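"""Training/test-set construction for rare structural variants.

Implements the curation pipeline: frequency computation and rarity
categories, reciprocal-overlap deduplication, removal of SVs matching common
variation, tiered size matching of pathogenic to benign SVs, removal of
feature-identical records, and chromosome-based train/test splits.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from svforest.sv_io import SVRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# reciprocal overlap & dedup


def reciprocal_overlap(a: SVRecord, b: SVRecord) -> float:
    """min(shared/size_a, shared/size_b); 0 across chromosomes."""
    if a.chrom != b.chrom:
        return 0.0
    shared = max(0, min(a.end, b.end) - max(a.start, b.start))
    return min(shared / a.size, shared / b.size)


def dedup_by_overlap(
    svs: Sequence[SVRecord],
    threshold: float = 0.9,
    keep: str = "first",
) -> list[SVRecord]:
    """Greedy near-duplicate removal by reciprocal overlap.

    Sweeps records in input order (``keep='first'``) or size-ascending
    (``keep='smallest'``); a record is retained iff its reciprocal overlap
    with every previously retained record is <= ``threshold`` (RO at or above
    the threshold counts as duplicate). DEL and DUP should be deduplicated
    separately by the caller.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if keep == "first":
        ordered = list(svs)
    elif keep == "smallest":
        ordered = sorted(svs, key=lambda sv: sv.size)
    else:
        raise ValueError(f"unknown keep mode {keep!r}")
    kept: list[SVRecord] = []
    trees: dict[str, IntervalTree] = {}
    for sv in ordered:
        tree = trees.setdefault(sv.chrom, IntervalTree())
        dup = any(
            reciprocal_overlap(sv, iv.data) >= threshold
            for iv in tree.overlap(sv.start, sv.end)
        )
        if not dup:
            kept.append(sv)
            tree.addi(sv.start, sv.end, sv)
    if keep == "smallest":
        order = {id(sv): i for i, sv in enumerate(svs)}
        kept.sort(key=lambda sv: order[id(sv)])
    return kept


# ---------------------------------------------------------------------------
# allele frequency & rarity


def dgv_maf(observed_events: int, samplesize: int) -> float:
    """Allele frequency of a CNV from event counts: observed / (2 x samplesize).

    Values above 1 are capped to 1.0 with a warning (count inconsistencies in
    source tables).
    """
    if samplesize <= 0:
        raise ValueError("samplesize must be positive")
    if observed_events < 0:
        raise ValueError("observed event count must be non-negative")
    maf = observed_events / (2 * samplesize)
    if maf > 1.0:
        logger.warning("MAF %.3f > 1 capped to 1.0", maf)
        maf = 1.0
    return maf


def classify_rarity(sv: SVRecord, maf_threshold: float = 0.01) -> str:
    """'common' (MAF > 1%), 'rare_benign' (rare with >= 1 homozygote), or
    'rare_unlabeled' (rare, no homozygotes)."""
    if sv.maf is None:
        raise ValueError(f"SV {sv.id}: MAF required for rarity classification")
    if sv.maf > maf_threshold:
        return "common"
    if sv.n_homalt is None:
        raise ValueError(f"SV {sv.id}: homozygote count required for rare SVs")
    return "rare_benign" if sv.n_homalt >= 1 else "rare_unlabeled"


def remove_common(
    svs: Sequence[SVRecord],
    exact_sources: Sequence[Sequence[SVRecord]] = (),
    ro_sources: Sequence[Sequence[SVRecord]] = (),
    ro_threshold: float = 0.9,
) -> list[SVRecord]:
    """Drop SVs matching common variation.

    Exact match = identical (chrom, start, end, svtype) against any record in
    ``exact_sources``; additionally any SV with reciprocal overlap above
    ``ro_threshold`` (strictly greater) to a record of the same type in
    ``ro_sources`` is dropped.
    """
    exact = {
        (c.chrom, c.start, c.end, c.svtype) for src in exact_sources for c in src
    }
    trees: dict[tuple[str, str], IntervalTree] = {}
    for src in ro_sources:
        for c in src:
            trees.setdefault((c.chrom, c.svtype), IntervalTree()).addi(c.start, c.end, c)
    out = []
    for sv in svs:
        if (sv.chrom, sv.start, sv.end, sv.svtype) in exact:
            continue
        tree = trees.get((sv.chrom, sv.svtype))
        if tree is not None and any(
            reciprocal_overlap(sv, iv.data) > ro_threshold
            for iv in tree.overlap(sv.start, sv.end)
        ):
            continue
        out.append(sv)
    return out


# ---------------------------------------------------------------------------
# size matching


@dataclass
class MatchConfig:
    """Size-window and tier configuration for pathogenic/benign matching.

    A pathogenic SV of size N accepts benign sizes in
    [N/alpha - slack_bp, N*alpha + slack_bp].
    """

    alpha: float = 1.06101
    slack_bp: int = 20
    tiers: Sequence[str] = ("tier1",)
    order: str = "input"  # or "size"

    def __post_init__(self) -> None:
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if self.slack_bp < 0:
            raise ValueError("slack_bp must be >= 0")
        if not self.tiers:
            raise ValueError("at least one benign tier required")

    def window(self, size: int) -> tuple[float, float]:
        return (size / self.alpha - self.slack_bp, size * self.alpha + self.slack_bp)


@dataclass
class MatchReport:
    n_pathogenic: int = 0
    n_matched: int = 0
    matched_per_tier: dict[str, int] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)


class _TierPool:
    """Benign SVs of one tier and one svtype, consumable by size queries."""

    def __init__(self, svs: Iterable[SVRecord]):
        self._items: list[tuple[int, int, SVRecord]] = sorted(
            (sv.size, i, sv) for i, sv in enumerate(svs)
        )

    def take_closest(self, size: int, lo: float, hi: float) -> SVRecord | None:
        """Consume the size-closest available SV within [lo, hi]; ties to smaller."""
        if not self._items:
            return None
        sizes = [it[0] for it in self._items]
        i0 = bisect_left(sizes, lo)
        i1 = bisect_right(sizes, hi)
        if i0 >= i1:
            return None
        best = min(
            range(i0, i1),
            key=lambda i: (abs(self._items[i][0] - size), self._items[i][0], self._items[i][1]),
        )
        return self._items.pop(best)[2]


def size_match(
    pathogenic: Sequence[SVRecord],
    benign_tiers: Sequence[Sequence[SVRecord]],
    cfg: MatchConfig | None = None,
) -> tuple[list[tuple[SVRecord, SVRecord]], MatchReport]:
    """Match each pathogenic SV by size and type to a benign SV.

    Pathogenic SVs are processed one at a time (input order by default); each
    walks the benign tiers in order and consumes the first tier's size-closest
    same-type SV inside its window. A benign SV matches at most once.
    Pathogenic SVs with no match in any tier are dropped and reported.
    """
    cfg = cfg or MatchConfig(tiers=[f"tier{i+1}" for i in range(len(benign_tiers))])
    if len(benign_tiers) == 0:
        raise ValueError("at least one benign tier required")
    if len(cfg.tiers) != len(benign_tiers):
        raise ValueError("cfg.tiers length must equal number of benign tier lists")
    pools = {
        (tier_name, svtype): _TierPool(sv for sv in tier if sv.svtype == svtype)
        for tier_name, tier in zip(cfg.tiers, benign_tiers)
        for svtype in ("DEL", "DUP")
    }
    ordered = (
        sorted(pathogenic, key=lambda sv: sv.size) if cfg.order == "size" else list(pathogenic)
    )
    report = MatchReport(n_pathogenic=len(ordered))
    pairs: list[tuple[SVRecord, SVRecord]] = []
    for sv in ordered:
        lo, hi = cfg.window(sv.size)
        match = None
        for tier_name in cfg.tiers:
            match = pools[(tier_name, sv.svtype)].take_closest(sv.size, lo, hi)
            if match is not None:
                report.matched_per_tier[tier_name] = report.matched_per_tier.get(tier_name, 0) + 1
                break
        if match is None:
            report.unmatched.append(sv.id)
        else:
            pairs.append((sv, match))
    report.n_matched = len(pairs)
    return pairs, report


# ---------------------------------------------------------------------------
# feature-identical dedup


def dedup_feature_identical(features: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Collapse feature-identical SVs within a label; drop cross-label clashes.

    ``features`` has one row per SV: feature columns plus ``label``
    (pathogenic/benign). Within each label the first row of every
    identical-feature group is kept; any feature pattern occurring under both
    labels is removed entirely from both.
    """
    feat_cols = [c for c in features.columns if c != label_col]
    keys = [tuple(row) for row in features[feat_cols].itertuples(index=False)]
    labels_by_key: dict[tuple, set[str]] = {}
    for key, lab in zip(keys, features[label_col]):
        labels_by_key.setdefault(key, set()).add(lab)
    seen: set[tuple[tuple, str]] = set()
    keep_rows = []
    for idx, (key, lab) in enumerate(zip(keys, features[label_col])):
        if len(labels_by_key[key]) > 1:
            continue  # pattern occurs as both pathogenic and benign
        if (key, lab) in seen:
            continue
        seen.add((key, lab))
        keep_rows.append(idx)
    return features.iloc[keep_rows]


# ---------------------------------------------------------------------------
# splits


def chromosome_split(
    svs: Sequence[SVRecord], held_out: Iterable[str] = ("1", "3", "5", "7")
) -> tuple[list[SVRecord], list[SVRecord]]:
    """(train, test): test = records on the held-out chromosomes."""
    held = set(held_out)
    chroms = {sv.chrom for sv in svs}
    if chroms and chroms <= held:
        raise ValueError("held-out set covers every chromosome: empty training set")
    train = [sv for sv in svs if sv.chrom not in held]
    test = [sv for sv in svs if sv.chrom in held]
    return train, test


def loco_folds(
    svs: Sequence[SVRecord],
) -> list[tuple[str, list[SVRecord], list[SVRecord]]]:
    """Leave-one-chromosome-out folds: (chrom, train, test) per chromosome."""
    chroms = sorted({sv.chrom for sv in svs})
    if len(chroms) < 2:
        raise ValueError("leave-one-chromosome-out needs >= 2 chromosomes")
    return [
        (c, [sv for sv in svs if sv.chrom != c], [sv for sv in svs if sv.chrom == c])
        for c in chroms
    ]


def one_sv_per_gene_subsample(
    svs: Sequence[SVRecord],
    gene_sets: Mapping[str, frozenset[str] | set[str]],
    seed: int,
) -> list[SVRecord]:
    """Random subsample in which every gene is overlapped by at most one SV.

    SVs are visited in random order (without replacement); an SV is retained
    iff its overlapped gene set is disjoint from the genes of every previously
    retained SV. ``gene_sets`` maps SV id to overlapped gene ids.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(svs))
    used: set[str] = set()
    kept = []
    for i in order:
        sv = svs[i]
        genes = set(gene_sets.get(sv.id, ()))
        if genes & used:
            continue
        used |= genes
        kept.append(sv)
    return kept
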