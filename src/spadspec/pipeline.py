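"""End-to-end orchestration: screening → preprocessing → indices →
correlation screening → single-index and random-forest SPAD models.

Produces three report tables mirroring the standard presentation of a
leaf-SPAD calibration study: a per-group SPAD summary, a per-group
optimal chain × index selection, and a per-group × per-chain
random-forest train/test metric table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import metrics, models, outliers, preprocess, screening
from .indices import compute_index_table
from .io import SampleSet
from .preprocess import PreprocessingChain


@dataclass
class PipelineConfig:
    """Knobs for one full pipeline run; defaults follow the study design."""

    chains: tuple = ("SG-SNV", "SG-SNV-DT", "SG-MSC")
    single_index_forms: tuple = models.SINGLE_INDEX_FORMS
    test_fraction: float = 0.2
    screen_outliers: bool = True
    mc_iterations: int = 1000
    rf_n_trees_grid: tuple = models.DEFAULT_N_TREES_GRID
    rf_groups: tuple | None = None  # None = all groups
    seed: int = 0


@dataclass
class PipelineResult:
    group_summary: pd.DataFrame
    outlier_report: outliers.OutlierReport | None
    correlations: pd.DataFrame
    optimal_selection: pd.DataFrame
    single_index_reports: list
    rf_table: pd.DataFrame
    rf_reports: list = field(default_factory=list)
    log: list = field(default_factory=list)


def run_full_pipeline(raw: SampleSet, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the whole calibration pipeline on a raw SampleSet."""
    log: list[str] = []

    if config.screen_outliers:
        cleaned, report = outliers.screen_sample_set(
            raw, n_iter=config.mc_iterations, seed=config.seed
        )
        log.append(
            f"screening removed {len(report.removed_ids)} of {report.n_before} samples"
        )
    else:
        cleaned, report = raw, None

    summary = metrics.group_summary(cleaned)

    # per-chain preprocessing, indices and correlation screening
    corr_frames = []
    index_tables: dict = {}  # (chain, group) -> (IndexTable, spad)
    for tag in config.chains:
        chain = PreprocessingChain.from_tag(tag)
        processed = preprocess.apply_chain(cleaned, chain, per_group=True)
        for key, group in processed.groupby_position():
            table = compute_index_table(group)
            index_tables[(tag, key)] = (table, group.spad)
            corr_frames.append(screening.correlate_indices(table, group.spad, key))
    correlations = pd.concat(corr_frames, ignore_index=True)
    optimal = screening.select_optimal(correlations)

    # single-index function fits on each group's optimal chain × index
    single_reports = []
    for _, row in optimal.iterrows():
        key = (row["stage"], row["leaf_position"])
        table, spad = index_tables[(row["chain"], key)]
        vi = table.column(row["feature"])
        for form in config.single_index_forms:
            single_reports.append(
                models.fit_single_index(vi, spad, form, chain=row["chain"], group=key)
            )

    # SPXY + random forest per group × chain
    rf_rows, rf_reports = [], []
    groups = config.rf_groups
    for (tag, key), (table, spad) in index_tables.items():
        if groups is not None and key not in groups:
            continue
        X = table.values.dropna(axis=1).to_numpy()
        split = models.spxy_split(
            X, spad, config.test_fraction, ids=list(table.values.index)
        )
        rep = models.fit_rf(
            table,
            spad,
            split,
            n_trees_grid=config.rf_n_trees_grid,
            seed=config.seed,
            group=key,
        )
        rf_reports.append(rep)
        rf_rows.append(
            {
                "stage": key[0],
                "leaf_position": key[1],
                "chain": tag,
                "n_trees": rep.params["n_trees"],
                "mtry": rep.params["mtry"],
                "train_r2": rep.train_metrics.r2,
                "train_rmse": rep.train_metrics.rmse,
                "train_rpd": rep.train_metrics.rpd,
                "test_r2": rep.test_metrics.r2,
                "test_rmse": rep.test_metrics.rmse,
                "test_rpd": rep.test_metrics.rpd,
                "test_rpd_class": rep.test_metrics.rpd_class,
            }
        )

    return PipelineResult(
        group_summary=summary,
        outlier_report=report,
        correlations=correlations,
        optimal_selection=optimal,
        single_index_reports=single_reports,
        rf_table=pd.DataFrame(rf_rows),
        rf_reports=rf_reports,
        log=log,
    )
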