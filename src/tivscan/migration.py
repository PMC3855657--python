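"""Scratch-assay image quantification and siRNA screen statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage import filters, morphology
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CONTROL_CLASS = "control"
GENE_LEVEL = "gene_level"


@dataclass
class TileGrid:
    """rows x cols grid of same-shape grayscale tiles for one acquisition."""

    tiles: np.ndarray  # (rows, cols, h, w)
    time_hours: float

    def __post_init__(self) -> None:
        self.tiles = np.asarray(self.tiles, dtype=float)
        if self.tiles.ndim != 4:
            raise ValueError("tiles must be a (rows, cols, h, w) array")


def merge_tiles(grid: TileGrid) -> np.ndarray:
    """Row-major mosaic of the tile grid, intensity-rescaled to [0, 1]."""
    t = grid.tiles
    rows, cols, h, w = t.shape
    mosaic = t.transpose(0, 2, 1, 3).reshape(rows * h, cols * w)
    lo, hi = mosaic.min(), mosaic.max()
    if hi > lo:
        mosaic = (mosaic - lo) / (hi - lo)
    else:
        mosaic = np.zeros_like(mosaic)
    return mosaic


def segment_gap(
    image: np.ndarray,
    crop_frac: float = 0.15,
    smooth_sigma: float = 4.0,
    closing_radius: int = 5,
    band_frac: float = 0.5,
    min_foreground: float = 0.05,
) -> tuple[float, bool]:
    """Mean width (px) of the cell-free gap between two cell sheets.

    The top and bottom ``crop_frac`` of rows are discarded; the image is
    Gaussian-smoothed, Otsu-thresholded into cell foreground, and closed
    with a disk.  Per remaining row, the gap is the longest background run
    that intersects the central column band; the width is the mean over
    rows.  Returns ``(width, closed_flag)``.
    """
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    img = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)

    n_rows = img.shape[0]
    crop = int(round(crop_frac * n_rows))
    if crop > 0:
        img = img[crop : n_rows - crop]
    sm = filters.gaussian(img, sigma=smooth_sigma)
    thr = filters.threshold_otsu(sm)
    fg = sm > thr
    if fg.mean() < min_foreground:
        raise ValueError("no cells detected (foreground below threshold)")
    fg = morphology.closing(fg, morphology.disk(closing_radius))

    w = img.shape[1]
    band_lo = int(round(w * (0.5 - band_frac / 2)))
    band_hi = int(round(w * (0.5 + band_frac / 2)))
    widths = np.zeros(fg.shape[0])
    run_starts, run_ends = [], []
    bg = ~fg
    for r in range(fg.shape[0]):
        row = bg[r]
        # background runs
        padded = np.concatenate(([False], row, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(int)))
        starts, ends = edges[::2], edges[1::2]
        best, best_se = 0, None
        for s, e in zip(starts, ends):
            if e > band_lo and s < band_hi:  # intersects central band
                if e - s > best:
                    best, best_se = e - s, (s, e)
        widths[r] = best
        if best_se is not None:
            run_starts.append(best_se[0])
            run_ends.append(best_se[1])

    # A genuine scratch gap is a connected vertical corridor: the per-row
    # runs must (robustly) share a common column interval.  Scattered
    # inter-cell background in a confluent sheet fails this check.
    if len(run_starts) < 0.5 * fg.shape[0]:
        return 0.0, True
    if np.quantile(run_ends, 0.1) - np.quantile(run_starts, 0.9) <= 0:
        return 0.0, True
    width = float(widths.mean())
    return width, width == 0.0


@dataclass
class WellTrace:
    """Per-well gap widths and derived average migration distance (AMD)."""

    well_id: str
    times: np.ndarray  # hours
    widths: np.ndarray  # px
    amd: np.ndarray  # px (or fraction in 'fraction_closed' mode)
    pixel_size: float | None = None
    amd_mode: str = "per_front"


def amd_trace(
    well_id: str,
    widths_by_time: dict[float, float],
    amd_mode: str = "per_front",
    pixel_size: float | None = None,
) -> WellTrace:
    """AMD(t) from gap widths: per-front closure (w0 - w(t))/2 floored at 0,
    or the fraction closed (w0 - w(t))/w0 in ``fraction_closed`` mode."""
    if 0 not in widths_by_time and 0.0 not in widths_by_time:
        raise ValueError("missing t = 0 gap width")
    times = np.array(sorted(widths_by_time), dtype=float)
    widths = np.array([widths_by_time[t] for t in sorted(widths_by_time)], dtype=float)
    w0 = widths[times == 0][0]
    if w0 <= 0:
        raise ValueError("initial gap width must be positive")
    if amd_mode == "per_front":
        amd = np.maximum(0.0, (w0 - widths) / 2.0)
    elif amd_mode == "fraction_closed":
        amd = np.maximum(0.0, (w0 - widths) / w0)
    else:
        raise ValueError(f"unknown amd_mode {amd_mode!r}")
    return WellTrace(well_id, times, widths, amd, pixel_size, amd_mode)


@dataclass
class PlateMap:
    """well_id -> (oligo_id, gene_id, target class)."""

    table: pd.DataFrame  # index well_id; columns oligo_id, gene_id, target

    def __post_init__(self) -> None:
        need = {"oligo_id", "gene_id", "target"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"plate map needs columns {sorted(need)}")
        if not (self.table["target"] == CONTROL_CLASS).any():
            raise ValueError("plate map has no negative-control wells")

    @property
    def control_wells(self) -> list[str]:
        return list(self.table.index[self.table["target"] == CONTROL_CLASS])

    @classmethod
    def from_csv(cls, path: str) -> "PlateMap":
        return cls(pd.read_csv(path).set_index("well_id"))

    def to_csv(self, path: str) -> None:
        self.table.rename_axis("well_id").reset_index().to_csv(path, index=False)


@dataclass
class ScreenResult:
    oligo_id: str
    gene_id: str
    target: str
    mean_relative_amd: float
    se: float
    p_value: float
    q_value: float
    significant: bool
    direction: str  # up / down / none
    n_replicates: int


def screen_statistics(
    well_amd: pd.Series,
    platemap: PlateMap,
    alpha_q: float = 0.01,
    test: str = "welch",
) -> list[ScreenResult]:
    """Per-oligo screen statistics against negative-control wells.

    AMDs are normalized to the mean of the control wells (relative AMD,
    control average = 1 by construction); per oligo the mean and standard
    error over replicates are reported, the p-value is a two-sided Welch t
    test vs the control wells, and BH-FDR is applied across oligos.
    """
    ctrl_wells = [w for w in platemap.control_wells if w in well_amd.index]
    if not ctrl_wells:
        raise ValueError("no control wells with AMD measurements")
    ctrl_mean = well_amd[ctrl_wells].mean()
    if ctrl_mean <= 0:
        raise ValueError("non-positive mean control AMD")
    rel = well_amd / ctrl_mean
    ctrl = rel[ctrl_wells].to_numpy()

    rows = []
    table = platemap.table[platemap.table["target"] != CONTROL_CLASS]
    for oligo_id, sub in table.groupby("oligo_id", sort=True):
        wells = [w for w in sub.index if w in rel.index]
        if len(wells) < 2:
            raise ValueError(f"oligo {oligo_id}: fewer than 2 replicate wells")
        vals = rel[wells].to_numpy()
        if test == "welch":
            stat = stats.ttest_ind(vals, ctrl, equal_var=False)
        elif test == "mannwhitney":
            stat = stats.mannwhitneyu(vals, ctrl, alternative="two-sided")
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "oligo_id": str(oligo_id),
                "gene_id": str(sub["gene_id"].iloc[0]),
                "target": str(sub["target"].iloc[0]),
                "mean": float(vals.mean()),
                "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
                "p": float(stat.pvalue),
                "n": len(vals),
            }
        )
    qvals = multipletests([r["p"] for r in rows], method="fdr_bh")[1]
    results = []
    for row, q in zip(rows, qvals):
        sig = bool(q < alpha_q)
        direction = "none"
        if sig:
            direction = "up" if row["mean"] > 1 else "down"
        results.append(
            ScreenResult(
                oligo_id=row["oligo_id"],
                gene_id=row["gene_id"],
                target=row["target"],
                mean_relative_amd=row["mean"],
                se=row["se"],
                p_value=row["p"],
                q_value=float(q),
                significant=sig,
                direction=direction,
                n_replicates=row["n"],
            )
        )
    return results


def results_to_frame(results: list[ScreenResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "oligo_id": [r.oligo_id for r in results],
            "gene_id": [r.gene_id for r in results],
            "target": [r.target for r in results],
            "mean_relative_amd": [r.mean_relative_amd for r in results],
            "se": [r.se for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "significant": [r.significant for r in results],
            "direction": [r.direction for r in results],
        }
    )


@dataclass
class IsoformHit:
    gene_id: str
    isoform: str
    hit: bool
    direction: str
    evaluable: bool
    reason: str = ""


def isoform_hit_call(results: list[ScreenResult]) -> list[IsoformHit]:
    """Per-isoform hit calls within each gene.

    An isoform is a hit iff BOTH of its oligos are significant in the same
    direction AND no alternate isoform of the gene has both its oligos
    significant in that direction AND the gene-level pool is not significant
    in that direction.  Isoforms with a missing oligo are unevaluable.
    """
    by_gene: dict[str, list[ScreenResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene_id, []).append(r)

    hits: list[IsoformHit] = []
    for gene_id in sorted(by_gene):
        rs = by_gene[gene_id]
        isoforms: dict[str, list[ScreenResult]] = {}
        gene_level = [r for r in rs if r.target == GENE_LEVEL]
        for r in rs:
            if r.target != GENE_LEVEL:
                isoforms.setdefault(r.target, []).append(r)

        def pair_direction(oligos: list[ScreenResult]) -> str:
            """'up'/'down' if both oligos significant in that direction."""
            if len(oligos) != 2:
                return ""
            dirs = {o.direction for o in oligos}
            if dirs == {"up"}:
                return "up"
            if dirs == {"down"}:
                return "down"
            return "none"

        pair_dirs = {iso: pair_direction(olist) for iso, olist in isoforms.items()}
        for iso in sorted(isoforms):
            if pair_dirs[iso] == "":
                hits.append(
                    IsoformHit(gene_id, iso, False, "none", False, "missing oligo")
                )
                continue
            d = pair_dirs[iso]
            if d == "none":
                hits.append(IsoformHit(gene_id, iso, False, "none", True))
                continue
            alt_conflict = any(
                pair_dirs[other] == d for other in isoforms if other != iso
            )
            gl_conflict = any(g.direction == d for g in gene_level)
            hit = not alt_conflict and not gl_conflict
            hits.append(IsoformHit(gene_id, iso, hit, d if hit else "none", True))
    return hits
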