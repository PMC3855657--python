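"""End-to-end orchestration of the array analysis stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import signal_qc as qc
from .events import classify_events
from .genemodel import GeneModel, annotate_probesets
from .noise import NoiseModel, fit_noise
from .signal_qc import SampleSheet, SignalMatrix
from .tiv import (
    DECall,
    DeviationStats,
    FoldChangeTable,
    GeneFC,
    TIVEvent,
    call_de_genes,
    call_tiv,
    deviation_stats,
    fold_changes,
    gene_fc,
)


@dataclass
class PipelineResult:
    annotations: pd.DataFrame
    true_exon_ps: pd.Index
    reclassified_ps: pd.Index
    presence: pd.DataFrame
    noise_model: NoiseModel
    fc_table: FoldChangeTable
    gene_fc: GeneFC
    de_calls: list[DECall]
    de_table: pd.DataFrame
    dev_stats: DeviationStats
    tiv_events: list[TIVEvent]
    q_table: pd.DataFrame

    @property
    def tiv_genes(self) -> set[str]:
        return {e.gene_id for e in self.tiv_events}

    @property
    def de_genes(self) -> set[str]:
        return {c.gene_id for c in self.de_calls}


def run_pipeline(
    models: Mapping[str, GeneModel],
    ps_table: pd.DataFrame,
    matrix: SignalMatrix,
    samplesheet: SampleSheet,
    alpha_detect: float = 0.05,
    q_int: float = 0.95,
    fc_min: float = 1.5,
    alpha: float = 0.05,
    min_adjacent: int = 2,
    n_noise_bins: int = 50,
    classify: bool = True,
) -> PipelineResult:
    """Annotation -> QC -> noise -> fold changes -> DE + TIV calls."""
    annotations = annotate_probesets(ps_table, models)
    presence = qc.presence_mask(matrix, samplesheet, alpha_detect)
    background = qc.intron_background(matrix, annotations)
    true_exon, reclassified = qc.refine_exons(
        matrix, samplesheet, annotations, background, q_int
    )
    retained = qc.retained_probesets(presence)
    true_exon = pd.Index([p for p in true_exon if p in retained])

    noise_model = fit_noise(matrix, samplesheet, n_bins=n_noise_bins)
    fc_table = fold_changes(matrix, samplesheet, presence, noise_model)
    gfc = gene_fc(fc_table, annotations, true_exon)
    de_calls, de_table = call_de_genes(gfc, fc_min=fc_min, alpha=alpha)
    dev = deviation_stats(fc_table, gfc)
    events, q_table = call_tiv(dev, alpha=alpha, min_adjacent=min_adjacent)
    if classify:
        classify_events(events, models, annotations)
    return PipelineResult(
        annotations=annotations,
        true_exon_ps=true_exon,
        reclassified_ps=reclassified,
        presence=presence,
        noise_model=noise_model,
        fc_table=fc_table,
        gene_fc=gfc,
        de_calls=de_calls,
        de_table=de_table,
        dev_stats=dev,
        tiv_events=events,
        q_table=q_table,
    )
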