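"""Fold changes, differential-expression calls and TIV event calling.

The per-time statistic for a probe set is its log2 fold change versus the
pre-stimulus time point; the gene-level fold change is the median over the
gene's true-exonic probe sets.  A TIV event is a run of >= ``min_adjacent``
consecutive time points at which a probe set's fold change deviates from
the gene-level fold change with a consistent sign, significant after
Benjamini-Hochberg FDR adjustment pooled across all (probe set, time) tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .noise import NoiseModel, fc_variance
from .signal_qc import SampleSheet, SignalMatrix, timepoint_means

# Asymptotic variance inflation of the median vs the mean (pi/2).
MEDIAN_VAR_INFLATION = math.pi / 2.0

MIN_PS_PER_GENE = 3


@dataclass
class FoldChangeTable:
    """PS x time log2 fold changes vs t = 0 with propagated variances.

    Cells are NaN where the probe set is not 'present' at both the time
    point and t = 0.
    """

    fc: pd.DataFrame
    var: pd.DataFrame
    times: list[int]

    @property
    def nonzero_times(self) -> list[int]:
        return [t for t in self.times if t != 0]


def fold_changes(
    matrix: SignalMatrix,
    samplesheet: SampleSheet,
    presence: pd.DataFrame,
    noise_model: NoiseModel,
) -> FoldChangeTable:
    """Replicate-mean log2 FC per probe set and time vs t = 0."""
    times = samplesheet.times
    if 0 not in times:
        raise ValueError("no t = 0 samples")
    means = timepoint_means(matrix, samplesheet)
    R = samplesheet.n_replicates
    base = means[0]
    fc = means.sub(base, axis=0)
    var = pd.DataFrame(
        {
            t: fc_variance(noise_model, means[t].to_numpy(), base.to_numpy(), R)
            for t in times
        },
        index=means.index,
    )
    # defined only where present at both t and t = 0
    defined = presence.mul(presence[0], axis=0)
    fc = fc.where(defined)
    var = var.where(defined)
    fully_masked = fc.isna().all(axis=1)
    if fully_masked.any():
        import logging

        logging.getLogger(__name__).info(
            "fold_changes: %d probe sets fully masked (absent at t = 0)",
            int(fully_masked.sum()),
        )
    return FoldChangeTable(fc=fc, var=var, times=list(times))


@dataclass
class GeneFC:
    """Gene x time median exonic fold change.

    ``n_ps`` counts contributing probe sets; cells with fewer than
    ``MIN_PS_PER_GENE`` contributors are masked.  ``var_basis`` is the
    median contributing per-PS FC variance (basis for the median's variance
    approximation)."""

    fc: pd.DataFrame
    n_ps: pd.DataFrame
    var_basis: pd.DataFrame
    gene_of_ps: pd.Series  # ps_id -> gene_id for the true-exon PS used

    def median_variance(self) -> pd.DataFrame:
        """Approximate variance of the gene median: (pi/2) * var_basis / m."""
        return MEDIAN_VAR_INFLATION * self.var_basis / self.n_ps


def gene_fc(
    fc_table: FoldChangeTable,
    annotations: pd.DataFrame,
    true_exon_ps,
    min_ps: int = MIN_PS_PER_GENE,
) -> GeneFC:
    """Median fold change over each gene's unmasked true-exon probe sets."""
    true_exon_ps = pd.Index(true_exon_ps)
    ann = annotations[annotations["ps_id"].isin(true_exon_ps)]
    ann = ann[ann["ps_id"].isin(fc_table.fc.index)]
    gene_of_ps = ann.set_index("ps_id")["gene_id"]
    fc = fc_table.fc.loc[gene_of_ps.index]
    var = fc_table.var.loc[gene_of_ps.index]
    grouped_fc = fc.groupby(gene_of_ps)
    med = grouped_fc.median()
    n = grouped_fc.count()
    var_basis = var.groupby(gene_of_ps).median()
    mask = n >= min_ps
    return GeneFC(
        fc=med.where(mask),
        n_ps=n.where(mask),
        var_basis=var_basis.where(mask),
        gene_of_ps=gene_of_ps,
    )


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


@dataclass
class DECall:
    gene_id: str
    directions: dict[int, str]  # time -> up / down / none
    max_abs_linear_fc: float
    q_value: float


def call_de_genes(
    gfc: GeneFC,
    fc_min: float = 1.5,
    alpha: float = 0.05,
) -> tuple[list[DECall], pd.DataFrame]:
    """Differentially expressed genes: BH-FDR over all gene x time (t > 0)
    tests; a gene is DE iff q < alpha AND |linear FC| >= fc_min at >= 1 time
    point.  Directions are reported per time point (a gene may be up at some
    times and down at others).

    Returns the calls plus a tidy per gene-time table
    (gene_id, time, fc, z, p, q, direction).
    """
    times = [t for t in gfc.fc.columns if t != 0]
    fc = gfc.fc[times]
    var = gfc.median_variance()[times]
    z = fc / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = pd.DataFrame(p, index=fc.index, columns=times)

    long = (
        pd.DataFrame(
            {
                "gene_id": np.repeat(fc.index.to_numpy(), len(times)),
                "time": np.tile(np.asarray(times), len(fc.index)),
                "fc": fc.to_numpy().ravel(),
                "z": z.to_numpy().ravel(),
                "p": p.to_numpy().ravel(),
            }
        )
    )
    long["q"] = _bh_qvalues(long["p"].to_numpy())
    log2_min = np.log2(fc_min)
    sig = (long["q"] < alpha) & (long["fc"].abs() >= log2_min)
    long["direction"] = np.where(
        sig & (long["fc"] > 0), "up", np.where(sig & (long["fc"] < 0), "down", "none")
    )

    calls = []
    for gene_id, sub in long.groupby("gene_id", sort=True):
        hit = sub[sub["direction"] != "none"]
        if hit.empty:
            continue
        calls.append(
            DECall(
                gene_id=str(gene_id),
                directions={int(r.time): r.direction for r in sub.itertuples()},
                max_abs_linear_fc=float(2.0 ** sub["fc"].abs().max()),
                q_value=float(hit["q"].min()),
            )
        )
    return calls, long


@dataclass
class DeviationStats:
    """Per (true-exon PS, time > 0) deviation from the gene-level FC."""

    delta: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame
    gene_of_ps: pd.Series
    times: list[int]


def deviation_stats(
    fc_table: FoldChangeTable, gfc: GeneFC, noise_model: NoiseModel | None = None
) -> DeviationStats:
    """delta = FC_ps - FC_gene; var(delta) = var(FC_ps) + var(gene median)."""
    gene_of_ps = gfc.gene_of_ps
    times = fc_table.nonzero_times
    ps_fc = fc_table.fc.loc[gene_of_ps.index, times]
    ps_var = fc_table.var.loc[gene_of_ps.index, times]
    gene_fc_rows = gfc.fc.reindex(gene_of_ps.to_numpy())[times]
    gene_fc_rows.index = gene_of_ps.index
    gene_var_rows = gfc.median_variance().reindex(gene_of_ps.to_numpy())[times]
    gene_var_rows.index = gene_of_ps.index

    delta = ps_fc - gene_fc_rows
    var = ps_var + gene_var_rows
    z = delta / np.sqrt(var)
    p = pd.DataFrame(
        2.0 * stats.norm.sf(np.abs(z)), index=z.index, columns=z.columns
    )
    p = p.where(z.notna())
    return DeviationStats(delta=delta, z=z, p=p, gene_of_ps=gene_of_ps, times=times)


@dataclass
class TIVEvent:
    gene_id: str
    ps_ids: tuple[str, ...]
    run_start: int  # index into the ordered non-zero time points
    run_end: int  # inclusive
    times: tuple[int, ...]  # supporting time points (minutes)
    sign: int
    q_min: float
    max_abs_delta: float
    switch_like: bool
    event_type: str = "unclassified"

    @property
    def run_length(self) -> int:
        return self.run_end - self.run_start + 1


def _runs(flags: np.ndarray, signs: np.ndarray, min_adjacent: int):
    """Maximal runs of consecutive flagged indices with constant sign."""
    runs = []
    start = None
    cur_sign = 0
    for i, f in enumerate(flags):
        s = signs[i] if f else 0
        if f and s != 0 and s == cur_sign:
            continue
        if start is not None and i - start >= min_adjacent:
            runs.append((start, i - 1, cur_sign))
        if f and s != 0:
            start, cur_sign = i, s
        else:
            start, cur_sign = None, 0
    if start is not None and len(flags) - start >= min_adjacent:
        runs.append((start, len(flags) - 1, cur_sign))
    return runs


def call_tiv(
    dev: DeviationStats,
    alpha: float = 0.05,
    min_adjacent: int = 2,
) -> tuple[list[TIVEvent], pd.DataFrame]:
    """Call TIV events from deviation statistics.

    BH-FDR is pooled across all finite (PS, time > 0) tests.  A probe set is
    flagged at a time point iff q < alpha; events are maximal runs of
    >= ``min_adjacent`` consecutive flagged time points with consistent
    deviation sign.  Flagged probe sets of the same gene and sign with
    overlapping runs are merged into a single event.  Returns the events and
    the PS x time q-value table.
    """
    times = dev.times
    p_flat = dev.p[times].to_numpy().ravel()
    q_flat = _bh_qvalues(p_flat)
    q = pd.DataFrame(
        q_flat.reshape(dev.p[times].shape), index=dev.p.index, columns=times
    )
    flags = (q < alpha).to_numpy()
    signs = np.sign(np.nan_to_num(dev.delta[times].to_numpy()))
    abs_delta = np.abs(dev.delta[times].to_numpy())

    # per-PS candidate runs
    candidates: dict[str, list[tuple[str, int, int, int, float, float]]] = {}
    ps_index = list(dev.p.index)
    for row, ps in enumerate(ps_index):
        ps_runs = _runs(flags[row], signs[row].astype(int), min_adjacent)
        if not ps_runs:
            continue
        gene = dev.gene_of_ps[ps]
        for start, end, sign in ps_runs:
            qmin = float(np.nanmin(q.iloc[row, start : end + 1]))
            dmax = float(np.nanmax(abs_delta[row, start : end + 1]))
            candidates.setdefault(gene, []).append((ps, start, end, sign, qmin, dmax))

    events: list[TIVEvent] = []
    for gene in sorted(candidates):
        for sign in (-1, 1):
            runs = sorted(
                [c for c in candidates[gene] if c[3] == sign], key=lambda c: (c[1], c[2])
            )
            if not runs:
                continue
            # merge overlapping [start, end] index intervals
            cluster: list[tuple[str, int, int, int, float, float]] = []
            lo = hi = None
            for c in runs + [None]:
                if c is not None and (lo is None or c[1] <= hi):
                    cluster.append(c)
                    lo = c[1] if lo is None else lo
                    hi = c[2] if hi is None else max(hi, c[2])
                else:
                    events.append(
                        TIVEvent(
                            gene_id=str(gene),
                            ps_ids=tuple(sorted({x[0] for x in cluster})),
                            run_start=lo,
                            run_end=hi,
                            times=tuple(times[lo : hi + 1]),
                            sign=sign,
                            q_min=min(x[4] for x in cluster),
                            max_abs_delta=max(x[5] for x in cluster),
                            switch_like=(hi - lo + 1) >= 3,
                        )
                    )
                    if c is not None:
                        cluster, lo, hi = [c], c[1], c[2]
    return events, q


def switch_like_filter(events: list[TIVEvent], min_adjacent: int = 3) -> list[TIVEvent]:
    """Keep events supported by >= ``min_adjacent`` adjacent time points."""
    return [e for e in events if e.run_length >= min_adjacent]


def events_to_frame(events: list[TIVEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in events],
            "ps_ids": [",".join(e.ps_ids) for e in events],
            "run_start_min": [e.times[0] for e in events],
            "run_end_min": [e.times[-1] for e in events],
            "sign": [e.sign for e in events],
            "q_min": [e.q_min for e in events],
            "max_abs_delta": [e.max_abs_delta for e in events],
            "switch_like": [e.switch_like for e in events],
            "event_type": [e.event_type for e in events],
        }
    )
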