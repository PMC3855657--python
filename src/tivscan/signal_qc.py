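"""Detection-call filtering, intron background estimation and exon refinement."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genemodel import LABEL_EXON, LABEL_INTRON

logger = logging.getLogger(__name__)

MIN_INTRON_PS = 50


@dataclass
class SampleSheet:
    """Maps sample ids to (time_minutes, replicate).

    Requires a t = 0 (pre-stimulus) time point and an equal replicate count
    at every time point.
    """

    table: pd.DataFrame  # index sample_id, columns time_minutes, replicate

    def __post_init__(self) -> None:
        t = self.table
        if not {"time_minutes", "replicate"}.issubset(t.columns):
            raise ValueError("sample sheet needs time_minutes and replicate columns")
        if (t["time_minutes"] < 0).any():
            raise ValueError("negative time points")
        if 0 not in set(t["time_minutes"]):
            raise ValueError("no pre-stimulus (t = 0) samples")
        counts = t.groupby("time_minutes").size()
        if counts.nunique() != 1:
            raise ValueError(f"unequal replicate counts per time point: {dict(counts)}")

    @property
    def times(self) -> list[int]:
        return sorted(self.table["time_minutes"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.table.groupby("time_minutes").size().iloc[0])

    def samples_at(self, time: int) -> list[str]:
        sub = self.table[self.table["time_minutes"] == time]
        return list(sub.sort_values("replicate").index)

    @classmethod
    def from_tsv(cls, path: str) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t").set_index("sample_id")
        return cls(df)

    def to_tsv(self, path: str) -> None:
        self.table.rename_axis("sample_id").reset_index().to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SignalMatrix:
    """Probe set x sample log2 intensities with matching detection p-values."""

    values: pd.DataFrame
    detection_p: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.detection_p.index) or not (
            self.values.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("values and detection_p must share both axes")
        if self.values.isna().any().any() or self.detection_p.isna().any().any():
            raise ValueError("missing entries in signal matrix")
        dp = self.detection_p.to_numpy()
        if (dp < 0).any() or (dp > 1).any():
            raise ValueError("detection p-values outside [0, 1]")

    @classmethod
    def from_tsv(cls, values_path: str, detp_path: str) -> "SignalMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        detp = pd.read_csv(detp_path, sep="\t", index_col=0)
        return cls(values, detp)

    def to_tsv(self, values_path: str, detp_path: str) -> None:
        self.values.rename_axis("ps_id").to_csv(values_path, sep="\t")
        self.detection_p.rename_axis("ps_id").to_csv(detp_path, sep="\t")


@dataclass
class BackgroundDistribution:
    """Empirical distribution of constitutive-intron probe-set signal."""

    samples: np.ndarray
    pooled: bool = True

    def __post_init__(self) -> None:
        self.samples = np.sort(np.asarray(self.samples, dtype=float))
        if self.samples.size == 0:
            raise ValueError("empty background distribution")

    def quantile(self, q) -> float | np.ndarray:
        return np.quantile(self.samples, q)


def presence_mask(
    matrix: SignalMatrix, samplesheet: SampleSheet, alpha_detect: float = 0.05
) -> pd.DataFrame:
    """Per (probe set, time) 'present' call: detection p < alpha in ALL
    replicates of that time point."""
    if not 0 < alpha_detect < 1:
        raise ValueError("alpha_detect must be in (0, 1)")
    cols = {}
    for t in samplesheet.times:
        samples = samplesheet.samples_at(t)
        missing = [s for s in samples if s not in matrix.detection_p.columns]
        if missing:
            raise ValueError(f"samples missing from matrix: {missing}")
        cols[t] = (matrix.detection_p[samples] < alpha_detect).all(axis=1)
    return pd.DataFrame(cols)


def retained_probesets(presence: pd.DataFrame) -> pd.Index:
    """Probe sets present at >= 1 time point."""
    return presence.index[presence.any(axis=1)]


def intron_background(
    matrix: SignalMatrix, annotations: pd.DataFrame
) -> BackgroundDistribution:
    """Pooled empirical distribution over all (intron PS, sample) values."""
    intron_ps = annotations.loc[annotations["label"] == LABEL_INTRON, "ps_id"]
    intron_ps = [p for p in intron_ps if p in matrix.values.index]
    if len(intron_ps) < MIN_INTRON_PS:
        raise ValueError(
            f"only {len(intron_ps)} constitutive-intron probe sets retained "
            f"(need >= {MIN_INTRON_PS}); background unidentifiable"
        )
    vals = matrix.values.loc[intron_ps].to_numpy().ravel()
    return BackgroundDistribution(vals, pooled=True)


def timepoint_means(matrix: SignalMatrix, samplesheet: SampleSheet) -> pd.DataFrame:
    """PS x time table of replicate-mean log2 signal."""
    return pd.DataFrame(
        {t: matrix.values[samplesheet.samples_at(t)].mean(axis=1) for t in samplesheet.times}
    )


def refine_exons(
    matrix: SignalMatrix,
    samplesheet: SampleSheet,
    annotations: pd.DataFrame,
    background: BackgroundDistribution,
    q_int: float = 0.95,
) -> tuple[pd.Index, pd.Index]:
    """Split putative-exon probe sets into true exons and intron-like decoys.

    A putative-exon PS is a true exon iff its log2 signal exceeds the
    background quantile ``q_int`` in ALL replicates of >= 1 time point
    (mirroring the presence-call idiom).  Constitutive intron PS are never
    touched.  Returns (true_exon ids, reclassified ids).
    """
    if not 0 < q_int < 1:
        raise ValueError("q_int must be in (0, 1)")
    threshold = float(background.quantile(q_int))
    putative = annotations.loc[annotations["label"] == LABEL_EXON, "ps_id"]
    putative = pd.Index([p for p in putative if p in matrix.values.index])
    is_true = pd.Series(False, index=putative)
    for t in samplesheet.times:
        sub = matrix.values.loc[putative, samplesheet.samples_at(t)]
        is_true |= (sub > threshold).all(axis=1)
    return putative[is_true], putative[~is_true]


def apply_refinement(annotations: pd.DataFrame, reclassified: pd.Index) -> pd.DataFrame:
    """Annotation table with reclassified putative exons relabeled intron-like."""
    out = annotations.copy()
    mask = out["ps_id"].isin(reclassified) & (out["label"] == LABEL_EXON)
    out.loc[mask, "label"] = "intron_like"
    return out


def exon_intron_differences(
    matrix: SignalMatrix, annotations: pd.DataFrame
) -> pd.Series:
    """Per-gene mean exon signal minus mean intron signal.

    Genes lacking either exon-labeled or intron-labeled probe sets are
    excluded (count logged).
    """
    in_matrix = annotations["ps_id"].isin(matrix.values.index)
    ann = annotations.loc[in_matrix]
    ps_mean = matrix.values.mean(axis=1)
    diffs = {}
    n_skipped = 0
    for gene_id, sub in ann.groupby("gene_id", sort=False):
        exon_ps = sub.loc[sub["label"] == LABEL_EXON, "ps_id"]
        intron_ps = sub.loc[sub["label"] == LABEL_INTRON, "ps_id"]
        if len(exon_ps) == 0 or len(intron_ps) == 0:
            n_skipped += 1
            continue
        diffs[gene_id] = ps_mean[exon_ps].mean() - ps_mean[intron_ps].mean()
    if n_skipped:
        logger.info(
            "exon_intron_differences: %d genes lacked exon or intron PS", n_skipped
        )
    return pd.Series(diffs, dtype=float)


@dataclass
class QCSummary:
    n_ps_before: int
    n_ps_after: int
    n_reclassified: int
    fraction_positive_before: float
    fraction_positive_after: float
    diffs_before: pd.Series
    diffs_after: pd.Series

    def to_tsv(self, path: str) -> None:
        pd.DataFrame(
            {
                "metric": [
                    "n_ps_before",
                    "n_ps_after",
                    "n_reclassified",
                    "fraction_positive_before",
                    "fraction_positive_after",
                ],
                "value": [
                    self.n_ps_before,
                    self.n_ps_after,
                    self.n_reclassified,
                    self.fraction_positive_before,
                    self.fraction_positive_after,
                ],
            }
        ).to_csv(path, sep="\t", index=False)


def qc_summary(
    matrix: SignalMatrix,
    annotations_before: pd.DataFrame,
    annotations_after: pd.DataFrame,
) -> QCSummary:
    """Counts and per-gene exon-minus-intron difference fractions for the
    annotation state before vs after exon refinement."""
    diffs_before = exon_intron_differences(matrix, annotations_before)
    diffs_after = exon_intron_differences(matrix, annotations_after)
    n_before = int((annotations_before["label"] == LABEL_EXON).sum())
    n_after = int((annotations_after["label"] == LABEL_EXON).sum())
    return QCSummary(
        n_ps_before=n_before,
        n_ps_after=n_after,
        n_reclassified=n_before - n_after,
        fraction_positive_before=float((diffs_before > 0).mean()) if len(diffs_before) else float("nan"),
        fraction_positive_after=float((diffs_after > 0).mean()) if len(diffs_after) else float("nan"),
        diffs_before=diffs_before,
        diffs_after=diffs_after,
    )
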