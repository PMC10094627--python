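"""End-to-end convenience wrapper: peak table in, screening report out."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from . import multivariate, quantify, reporting, screening
from .datamodel import PeakTable, RunConfig

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All stage outputs of one full run."""

    conc: pd.DataFrame
    group_means: pd.DataFrame
    class_profile: pd.DataFrame
    model: multivariate.PlsdaModel
    vip: pd.Series
    permutation: Optional[multivariate.PermutationReport]
    screening: screening.ScreeningReport
    heatmap: reporting.HeatmapData
    summary: reporting.RunSummary


def run_pipeline(
    table: PeakTable,
    config: Optional[RunConfig] = None,
    run_permutation: bool = True,
) -> PipelineResult:
    """Semi-quantify, profile, fit PLS-DA, screen, and summarize.

    The permutation validation (the slowest stage; ``config.n_permutations``
    model refits) can be skipped with ``run_permutation=False``.
    """
    config = config or RunConfig(group_labels=table.groups)
    conc = quantify.semi_quantify(table)
    group_means = quantify.group_mean_concentrations(conc)
    class_profile = quantify.class_proportions(group_means, table.catalog)

    groups = list(conc.index.get_level_values("group"))
    Y = multivariate.one_hot(groups, config.group_labels)
    model = multivariate.fit_plsda(conc, Y, "auto", cv_folds=config.cv_folds)
    vip = multivariate.compute_vip(model)

    permutation = None
    if run_permutation:
        permutation = multivariate.permutation_test(
            conc,
            groups,
            model.n_components,
            n_permutations=config.n_permutations,
            seed=config.seed,
            folds=config.cv_folds,
            group_labels=config.group_labels,
        )

    screen = screening.build_screening_report(
        conc, group_means, table.catalog, vip, config
    )
    selected = list(vip.index[vip > config.vip_cutoff])
    heatmap = reporting.build_heatmap_data(conc, selected, clip=config.heat_clip)
    summary = reporting.summarize_run(
        class_profile=class_profile,
        model=model,
        permutation=permutation,
        vip=vip,
        screening=screen,
        vip_cutoff=config.vip_cutoff,
    )
    return PipelineResult(
        conc=conc,
        group_means=group_means,
        class_profile=class_profile,
        model=model,
        vip=vip,
        permutation=permutation,
        screening=screen,
        heatmap=heatmap,
        summary=summary,
    )
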