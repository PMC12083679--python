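"""End-to-end orchestration: patches → scaling → QC → split → statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .io import Cohort
from .patches import (
    PatchTable,
    analysis_view,
    extract_cohort_patches,
    flag_low_signal,
    flag_outliers,
    scale_patches,
)
from .split import SplitResult, split_patches
from .stats import GroupComparison, grade_summary

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    table: PatchTable  # QC-passing, scaled, group-labeled patches
    split: SplitResult
    comparisons: list
    summary: pd.DataFrame
    qc_counts: dict
    config: PipelineConfig


def run_analysis(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full patch analysis on a loaded cohort."""
    config = config or PipelineConfig()
    table = extract_cohort_patches(cohort, patch_size_um=config.patch_size_um)
    log.info("extracted %d patches from %d images", len(table), len(cohort))
    table = scale_patches(
        table,
        markers=config.markers,
        percentile=config.percentile,
        pooled=config.pooled_scaling,
    )
    table = flag_outliers(table, markers=config.markers)
    table = flag_low_signal(table, dna_threshold=config.dna_threshold)
    view, qc_counts = analysis_view(table)
    labeled, split = split_patches(
        view,
        bandwidth=config.bandwidth,
        search_range=config.search_range,
        fallback=config.fallback_threshold,
    )
    log.info("split at %.4f (%s): %d high / %d low",
             split.threshold, split.method, split.n_high, split.n_low)
    comparisons, summary = grade_summary(
        labeled, test=config.test, per_sample=config.per_sample, correction=config.correction
    )
    return PipelineResult(
        table=labeled,
        split=split,
        comparisons=comparisons,
        summary=summary,
        qc_counts=qc_counts,
        config=config,
    )
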