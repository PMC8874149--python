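"""Independent brute-force reference implementations used only by tests.

Everything here recomputes quantities per-nucleotide (or by exhaustive
pairwise loops), deliberately avoiding the interval algebra and run-length
shortcuts of the package. Only suitable for small fixtures.
"""

from __future__ import annotations

import numpy as np

from svforest.features import FeatureVector


def base_values(track, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Per-base track values over [lo, hi); NaN where uncovered."""
    out = np.full(hi - lo, np.nan)
    for c, s, e, v in track.iter_runs():
        if c != chrom:
            continue
        a, b = max(s, lo), min(e, hi)
        if b > a:
            out[a - lo : b - lo] = v
    return out


def _runs_from_bases(values: np.ndarray, mask: np.ndarray) -> list[tuple[int, float]]:
    """Maximal stretches of contiguous masked bases with equal covered value."""
    runs: list[tuple[int, float]] = []
    prev_val, prev_idx, length = None, None, 0
    for i in range(len(values)):
        if not mask[i] or np.isnan(values[i]):
            if length:
                runs.append((length, prev_val))
            prev_val, prev_idx, length = None, None, 0
            continue
        if prev_idx is not None and i == prev_idx + 1 and values[i] == prev_val:
            length += 1
        else:
            if length:
                runs.append((length, prev_val))
            prev_val, length = values[i], 1
        prev_idx = i
    if length:
        runs.append((length, prev_val))
    return runs


def _top400_from_runs(runs: list[tuple[int, float]], n_top: int = 400) -> float | None:
    if not runs:
        return None
    vals = sorted((v for _, v in runs), reverse=True)
    take = vals[:n_top] if len(vals) >= n_top else vals
    return float(np.mean(take))


def oracle_features(sv, bundle) -> FeatureVector | None:
    """All 17 features recomputed per-nucleotide. None if no exon overlap."""
    sv_bases = set(range(sv.start, sv.end))

    # gene / exon overlap by exhaustive base intersection
    hits = []  # (gene, [overlapped principal exon indices])
    for gene in bundle.genes.values():
        if gene.chrom != sv.chrom:
            continue
        idxs = [
            i
            for i, (s, e) in enumerate(gene.principal.exons)
            if set(range(s, e)) & sv_bases
        ]
        if idxs:
            hits.append((gene, idxs))
    if not hits:
        return None
    hits.sort(key=lambda h: h[0].gene_id)

    # CDS features: walk coding bases in transcript order
    triples = []
    for gene, _ in hits:
        tx = gene.principal
        coding = []
        for s, e in sorted(c for c in tx.cds):
            coding.extend(range(s, e))
        if tx.strand == "-":
            coding = coding[::-1]
        if not coding:
            continue
        L = len(coding)
        inside = [i for i, pos in enumerate(coding) if pos in sv_bases]
        if not inside:
            triples.append((1.0, 1.0, 0.0))
        else:
            triples.append((min(inside) / L, (L - 1 - max(inside)) / L, len(inside) / L))
    cds_from_start = min(t[0] for t in triples) if triples else None
    cds_from_stop = min(t[1] for t in triples) if triples else None
    cds_overlapped = max(t[2] for t in triples) if triples else None

    # exon space = bases of any overlapped gene's principal exons inside the SV
    lo, hi = sv.start, sv.end
    mask = np.zeros(hi - lo, dtype=bool)
    for gene, _ in hits:
        for s, e in gene.principal.exons:
            a, b = max(s, lo), min(e, hi)
            if b > a:
                mask[a - lo : b - lo] = True

    def top400(track):
        return _top400_from_runs(_runs_from_bases(base_values(track, sv.chrom, lo, hi), mask))

    # gene importance with per-base trigger evaluation
    loeufs, plis, hi_loeufs, hi_plis = [], [], [], []
    for gene, _ in hits:
        tx = gene.principal
        coding = set()
        for s, e in tx.cds:
            coding.update(range(s, e))
        frac = len(coding & sv_bases) / len(coding) if coding else 0.0
        start_base = tx.start_codon_base()
        stop_base = tx.stop_codon_base()
        if gene.loeuf is not None:
            loeufs.append(gene.loeuf)
            if (stop_base in sv_bases if stop_base is not None else False) or frac > 0.5:
                hi_loeufs.append(gene.loeuf)
        if gene.pli is not None:
            plis.append(gene.pli)
            if (start_base in sv_bases if start_base is not None else False) or frac > 0.5:
                hi_plis.append(gene.pli)

    # exon structure
    inframe = True
    constitutive = False
    orders, exon_counts, overlapped_counts = [], [], []
    for gene, idxs in hits:
        exons = gene.principal.exons
        exon_counts.append(len(exons))
        overlapped_counts.append(len(idxs))
        for idx in idxs:
            orders.append(idx)
            s, e = exons[idx]
            if (e - s) % 3 != 0 or idx in (0, len(exons) - 1):
                inframe = False
            if all((s, e) in t.exons for t in gene.transcripts):
                constitutive = True

    # TAD: per-base strength profile over the SV window, then the max
    tad_profile = np.full(hi - lo, np.nan)
    for b in bundle.boundaries:
        if b.chrom != sv.chrom:
            continue
        a, z = max(b.start, lo), min(b.end, hi)
        if z > a:
            tad_profile[a - lo : z - lo] = np.fmax(tad_profile[a - lo : z - lo], b.strength)
    tad = tad_profile[~np.isnan(tad_profile)]

    return FeatureVector(
        cds_frac_from_start=cds_from_start,
        cds_frac_from_stop=cds_from_stop,
        cds_frac_overlapped=cds_overlapped,
        phylop_top400=top400(bundle.conservation),
        exon_expression_top400=top400(bundle.expression),
        exon_inclusion_top400=top400(bundle.inclusion),
        tad_strength_max=float(tad.max()) if len(tad) else None,
        loeuf_min=min(loeufs) if loeufs else None,
        loeuf_high_impact_min=min(hi_loeufs) if hi_loeufs else None,
        pli_max=max(plis) if plis else None,
        pli_high_impact_max=max(hi_plis) if hi_plis else None,
        all_exons_inframe_skippable=inframe,
        any_exon_constitutive=constitutive,
        min_exon_order=min(orders),
        min_exons_in_gene=min(exon_counts),
        max_exons_overlapped=max(overlapped_counts),
        is_deletion=(sv.svtype == "DEL"),
    )


def oracle_greedy_dedup(svs, threshold: float, keep: str) -> list:
    """O(n^2) greedy reciprocal-overlap dedup with an inline RO formula."""
    ordered = sorted(svs, key=lambda sv: sv.end - sv.start) if keep == "smallest" else list(svs)
    kept = []
    for sv in ordered:
        dup = False
        for other in kept:
            if sv.chrom != other.chrom:
                continue
            shared = max(0, min(sv.end, other.end) - max(sv.start, other.start))
            ro = min(shared / (sv.end - sv.start), shared / (other.end - other.start))
            if ro >= threshold:
                dup = True
                break
        if not dup:
            kept.append(sv)
    if keep == "smallest":
        pos = {id(sv): i for i, sv in enumerate(svs)}
        kept.sort(key=lambda sv: pos[id(sv)])
    return kept


def oracle_mann_whitney_auc(scores, labels) -> float:
    """AUC as the pairwise win fraction with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def oracle_expression_at(models, tpm: dict[str, float], chrom: str, pos: int):
    """(expression, inclusion) at one base by looping every transcript."""
    expr = 0.0
    covered = False
    incl_candidates = []
    for gene in models.values():
        gene_total = sum(tpm[t.transcript_id] for t in gene.transcripts)
        cov = 0.0
        gene_covers = False
        for tx in gene.transcripts:
            if tx.chrom == chrom and any(s <= pos < e for s, e in tx.exons):
                covered = True
                gene_covers = True
                expr += tpm[tx.transcript_id]
                cov += tpm[tx.transcript_id]
        if gene_covers and gene_total > 0:
            incl_candidates.append(cov / gene_total)
    if not covered:
        return None, None
    return expr, (max(incl_candidates) if incl_candidates else None)
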