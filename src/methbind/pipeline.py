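"""End-to-end training and prediction over an in-memory dataset.

The CLI builds a :class:`Dataset` from files and calls these functions; tests
and the synthetic generator hand one over directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    DEFAULT_N_TREES,
    TrainedModel,
    gini_importance,
    predict_proba,
    train_rf,
)
from .features import CONTEXT_COLUMNS, AnnotationSet, assemble_feature_table
from .io import ConservationTrack, CpGTable, GenomicInterval, PFM
from .meth_model import (
    MethylationModel,
    WindowCounts,
    aggregate_counts,
    build_windows,
    fit_methylation_model,
    methylation_score,
    qc_filter_training,
)
from .scan import BOUND, CandidateSite

logger = logging.getLogger(__name__)


@dataclass
class Dataset:
    """All inputs one sample contributes: genome, methylation, peaks, annotations."""

    genome: dict[str, str]
    cpg: dict[str, CpGTable]
    peaks: list[GenomicInterval] = field(default_factory=list)
    annotations: AnnotationSet = field(default_factory=AnnotationSet)
    conservation: ConservationTrack | None = None
    pfm: PFM | None = None

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.genome.items()}

    @property
    def contexts(self) -> list[str]:
        order = {"CG": 0, "CH": 1, "hmC": 2}
        return sorted(self.cpg, key=lambda c: order.get(c, 99))


def site_window_counts(
    sites: Sequence[CandidateSite],
    dataset: Dataset,
    window_size: int = 30,
    n_flank: int = 10,
) -> list[dict[str, WindowCounts]]:
    """Window layouts + per-context aggregated counts for each site."""
    lengths = dataset.chrom_lengths
    out: list[dict[str, WindowCounts]] = []
    for site in sites:
        layout = build_windows(
            site,
            window_size=window_size,
            n_flank=n_flank,
            chrom_length=lengths[site.interval.chrom],
        )
        out.append(
            {
                ctx: aggregate_counts(layout, dataset.cpg[ctx], context=ctx)
                for ctx in dataset.contexts
            }
        )
    return out


def score_sites(
    sites: Sequence[CandidateSite],
    counts: Sequence[Mapping[str, WindowCounts]],
    meth_models: Mapping[str, MethylationModel],
) -> dict[str, dict[str, float]]:
    """Per-context methylation scores keyed by site id."""
    scores: dict[str, dict[str, float]] = {ctx: {} for ctx in meth_models}
    for site, per_ctx in zip(sites, counts):
        for ctx, model in meth_models.items():
            scores[ctx][site.site_id] = methylation_score(per_ctx[ctx], model)
    return scores


def train_pipeline(
    dataset: Dataset,
    train_sites: Sequence[CandidateSite],
    window_size: int = 30,
    n_flank: int = 10,
    min_reads: int = 5,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    balanced: bool = False,
    metadata: Mapping | None = None,
) -> tuple[TrainedModel, dict]:
    """Fit methylation models and the random forest from labeled candidates.

    ``train_sites`` must already carry bound/unbound labels (from
    :func:`methbind.scan.label_candidates`).  Training QC masks windows with
    fewer than ``min_reads`` reads and drops CpG-island candidates; the
    methylation scores entering the forest are computed from the freshly
    fitted models.  Returns the trained model and a run report.
    """
    labels_present = {s.label for s in train_sites}
    if None in labels_present:
        raise ValueError("training sites must be labeled")
    counts = site_window_counts(train_sites, dataset, window_size, n_flank)
    qc_sites, qc_counts = qc_filter_training(
        train_sites, counts, dataset.annotations.cpg_island, min_reads=min_reads
    )
    if not qc_sites:
        raise ValueError("no candidates survive training QC")
    meth_models: dict[str, MethylationModel] = {}
    for ctx in dataset.contexts:
        bound = [c[ctx] for s, c in zip(qc_sites, qc_counts) if s.label == BOUND]
        unbound = [c[ctx] for s, c in zip(qc_sites, qc_counts) if s.label != BOUND]
        meth_models[ctx] = fit_methylation_model(
            bound, unbound, window_size=window_size, n_flank=n_flank, context=ctx
        )
    meth_scores = score_sites(qc_sites, qc_counts, meth_models)
    features = assemble_feature_table(
        qc_sites, meth_scores, dataset.conservation, dataset.annotations
    )
    label_by_id = {s.site_id: s.label for s in qc_sites}
    labels = [label_by_id[sid] for sid in features.index]
    meta = dict(metadata or {})
    meta.update(window_size=window_size, n_flank=n_flank, min_reads=min_reads,
                contexts=dataset.contexts)
    model = train_rf(
        features,
        labels,
        n_trees=n_trees,
        seed=seed,
        balanced=balanced,
        meth_models=meth_models,
        metadata=meta,
    )
    report = {
        "n_train_sites": len(train_sites),
        "n_after_qc": len(qc_sites),
        "n_bound": int(sum(s.label == BOUND for s in qc_sites)),
        "oob_error": model.metadata["oob_error"],
        "gini_importance": gini_importance(model).to_dict(),
        "contexts": dataset.contexts,
    }
    logger.info(
        "trained on %d sites (%d bound) after QC; OOB error %.4f",
        report["n_after_qc"], report["n_bound"], report["oob_error"],
    )
    return model, report


def predict_pipeline(
    dataset: Dataset,
    model: TrainedModel,
    sites: Sequence[CandidateSite],
) -> pd.DataFrame:
    """Score candidates with a trained model.

    Returns one row per site (sorted by site id): BED6 columns, the
    per-context methylation scores, and the class probability of binding.
    No training QC is applied at prediction time.
    """
    if not sites:
        logger.warning("empty candidate set; returning empty prediction table")
        return pd.DataFrame(
            columns=["chrom", "start", "end", "name", "score", "strand", "probability"]
        )
    window_size = model.metadata.get("window_size", 30)
    n_flank = model.metadata.get("n_flank", 10)
    model_contexts = sorted(model.meth_models)
    missing = [c for c in model_contexts if c not in dataset.cpg]
    if missing:
        raise ValueError(
            f"model requires methylation context(s) {missing} absent from the dataset"
        )
    counts = site_window_counts(sites, dataset, window_size, n_flank)
    meth_scores = score_sites(sites, counts, model.meth_models)
    features = assemble_feature_table(
        sites, meth_scores, dataset.conservation, dataset.annotations
    )
    proba = predict_proba(model, features)
    by_id = {s.site_id: s for s in sites}
    rows = []
    for sid, p in zip(features.index, proba):
        site = by_id[sid]
        row = {
            "chrom": site.interval.chrom,
            "start": site.interval.start,
            "end": site.interval.end,
            "name": sid,
            "score": site.motif_score,
            "strand": site.interval.strand,
        }
        for ctx in model_contexts:
            row[CONTEXT_COLUMNS[ctx]] = meth_scores[ctx][sid]
        row["probability"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)
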