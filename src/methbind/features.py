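"""Static genomic features joined to methylation scores for classification.

Each candidate site gets: its motif log-odds score, one methylation score
per available context, mean conservation over the motif, distance from the
motif midpoint to the nearest TSS, distance to the nearest other candidate,
and 0/1 indicators for overlap with TSS, TES, exons, introns, CpG islands
and repeats.  Distances use the motif midpoint as anchor; overlap means at
least one shared base under half-open semantics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import ConservationTrack, GenomicInterval
from .scan import CandidateSite

logger = logging.getLogger(__name__)

#: sentinel for distances with an empty reference set (lone site, no TSS)
MISSING_DISTANCE = np.nan

#: column order of the mandatory features; optional context scores are
#: inserted after meth_score_cg
BASE_SCHEMA = [
    "motif_score",
    "meth_score_cg",
    "conservation_mean",
    "dist_tss",
    "dist_nearest_candidate",
    "overlap_tss",
    "overlap_tes",
    "overlap_exon",
    "overlap_intron",
    "overlap_cpg_island",
    "overlap_repeat",
]

CONTEXT_COLUMNS = {"CG": "meth_score_cg", "CH": "meth_score_ch", "hmC": "meth_score_hmc"}


@dataclass
class AnnotationSet:
    """Annotation intervals per feature class (TSS/TES as 1-bp point intervals)."""

    tss: list[GenomicInterval] = field(default_factory=list)
    tes: list[GenomicInterval] = field(default_factory=list)
    exon: list[GenomicInterval] = field(default_factory=list)
    intron: list[GenomicInterval] = field(default_factory=list)
    cpg_island: list[GenomicInterval] = field(default_factory=list)
    repeat: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def class_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]


def conservation_mean(site: CandidateSite, track: ConservationTrack | None) -> float:
    """Mean per-base conservation over the motif interval; missing bases count as 0."""
    iv = site.interval
    if track is None:
        return 0.0
    total = sum(track.get(iv.chrom, pos, 0.0) for pos in range(iv.start, iv.end))
    return total / iv.width


def distance_to_nearest(
    site: CandidateSite, references: Sequence[GenomicInterval]
) -> float:
    """Distance (bp) from the motif midpoint to the nearest reference interval.

    Point references are 1-bp intervals.  A midpoint inside a reference gives
    0; otherwise the distance to the closest edge.  An empty reference set
    yields the missing-value sentinel (NaN) and a log record.
    """
    mid = site.interval.midpoint
    best = np.inf
    for ref in references:
        if ref.chrom != site.interval.chrom:
            continue
        if ref.start <= mid < ref.end:
            return 0.0
        best = min(best, abs(mid - ref.start), abs(mid - (ref.end - 1)))
    if not np.isfinite(best):
        logger.info(
            "no reference on %s for site %s; distance set to missing",
            site.interval.chrom,
            site.site_id,
        )
        return MISSING_DISTANCE
    return float(best)


def binary_overlap(site: CandidateSite, annotations: Sequence[GenomicInterval]) -> int:
    """1 iff the motif interval shares at least one base with any annotation."""
    return int(any(site.interval.overlaps(a) for a in annotations))


def nearest_candidate_distance(sites: Sequence[CandidateSite]) -> np.ndarray:
    """Per-site midpoint distance to the closest other candidate on the same chromosome.

    A chromosome's lone candidate gets the missing-value sentinel (NaN).
    """
    result = np.full(len(sites), MISSING_DISTANCE)
    by_chrom: dict[str, list[int]] = {}
    for idx, site in enumerate(sites):
        by_chrom.setdefault(site.interval.chrom, []).append(idx)
    for indices in by_chrom.values():
        if len(indices) < 2:
            continue
        mids = np.array([sites[i].interval.midpoint for i in indices], dtype=float)
        order = np.argsort(mids, kind="stable")
        sorted_mids = mids[order]
        gaps_left = np.full(len(indices), np.inf)
        gaps_right = np.full(len(indices), np.inf)
        gaps_left[1:] = np.diff(sorted_mids)
        gaps_right[:-1] = np.diff(sorted_mids)
        nearest = np.minimum(gaps_left, gaps_right)
        for rank, original in enumerate(order):
            result[indices[original]] = nearest[rank]
    return result


def _overlap_column(
    sites: Sequence[CandidateSite], annotations: Sequence[GenomicInterval]
) -> np.ndarray:
    trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        trees.setdefault(ann.chrom, IntervalTree()).addi(ann.start, ann.end)
    out = np.zeros(len(sites), dtype=int)
    for idx, site in enumerate(sites):
        tree = trees.get(site.interval.chrom)
        if tree is not None and tree.overlaps(site.interval.start, site.interval.end):
            out[idx] = 1
    return out


def feature_schema(contexts: Sequence[str]) -> list[str]:
    """Ordered feature names for the given methylation contexts."""
    schema = list(BASE_SCHEMA)
    insert_at = schema.index("meth_score_cg") + 1
    for ctx in ("CG", "CH", "hmC"):  # canonical order regardless of input order
        if ctx in contexts:
            col = CONTEXT_COLUMNS[ctx]
            if col not in schema:
                schema.insert(insert_at, col)
                insert_at += 1
    return schema


def assemble_feature_table(
    sites: Sequence[CandidateSite],
    meth_scores: Mapping[str, Mapping[str, float]],
    conservation: ConservationTrack | None,
    annotations: AnnotationSet,
) -> pd.DataFrame:
    """Build the per-site feature table, indexed and sorted by ``site_id``.

    ``meth_scores`` maps context ("CG", optionally "CH"/"hmC") to a
    per-site-id score mapping; the CG context is mandatory.  Optional
    contexts that are absent are simply excluded from the schema — never
    imputed.  A site missing a mandatory score raises a ``KeyError`` naming
    site and feature.
    """
    if "CG" not in meth_scores:
        raise KeyError("meth_scores must include the mandatory 'CG' context")
    unknown = set(meth_scores) - set(CONTEXT_COLUMNS)
    if unknown:
        raise KeyError(f"unknown methylation context(s): {sorted(unknown)}")
    order = np.argsort([s.site_id for s in sites], kind="stable")
    sites = [sites[i] for i in order]
    ids = [s.site_id for s in sites]

    data: dict[str, np.ndarray] = {}
    data["motif_score"] = np.array([s.motif_score for s in sites])
    for ctx, mapping in meth_scores.items():
        col = CONTEXT_COLUMNS[ctx]
        values = np.empty(len(sites))
        for i, site in enumerate(sites):
            if site.site_id not in mapping:
                raise KeyError(
                    f"site {site.site_id} is missing mandatory feature {col}"
                )
            values[i] = mapping[site.site_id]
        data[col] = values
    data["conservation_mean"] = np.array(
        [conservation_mean(s, conservation) for s in sites]
    )
    data["dist_tss"] = np.array(
        [distance_to_nearest(s, annotations.tss) for s in sites]
    )
    data["dist_nearest_candidate"] = nearest_candidate_distance(sites)
    for name in AnnotationSet.class_names():
        data[f"overlap_{name}"] = _overlap_column(sites, getattr(annotations, name))

    schema = feature_schema(list(meth_scores))
    return pd.DataFrame({col: data[col] for col in schema}, index=pd.Index(ids, name="site_id"))
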