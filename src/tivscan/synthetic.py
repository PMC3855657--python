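"""Ground-truthed synthetic inputs for every pipeline stage.

Generates gene models with engineered region classes, probe-set layouts,
signal time courses with injected differential expression and TIV, scratch
assay tile series with known gap trajectories, and screen plates with known
oligo effects.  Everything is a deterministic function of the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
import pandas as pd

from . import events as ev
from .genemodel import GeneModel, GenomicInterval, Isoform
from .migration import CONTROL_CLASS, GENE_LEVEL, PlateMap, TileGrid
from .signal_qc import SampleSheet, SignalMatrix

PS_LENGTH = 25

DEFAULT_EVENT_TYPES = (
    ev.ALT_FIRST_EXON,
    ev.CASSETTE_EXON,
    ev.ALT_5SS,
    ev.ALT_3SS,
    ev.INTRON_RETENTION,
    ev.ALT_LAST_EXON,
)


@dataclass
class SimulationSpec:
    seed: int = 0
    # --- arrays ---
    n_genes: int = 200
    times: tuple[int, ...] = (0, 20, 40, 60, 120, 240, 480)
    n_replicates: int = 3
    exonic_ps_per_gene: int = 8
    intronic_ps_per_gene: int = 3
    event_ps_per_gene: int = 3
    baseline_mean: float = 8.0
    baseline_sd: float = 0.4
    ps_jitter_sd: float = 0.25
    intron_offset: float = -3.0
    # intensity-dependent noise curve sigma(I) (logistic, decreasing);
    # constant_noise overrides with a flat sigma
    noise_sd_low: float = 0.2
    noise_sd_high: float = 0.75
    noise_mid: float = 5.5
    noise_width: float = 0.6
    constant_noise: float | None = None
    # injected effects
    de_fraction: float = 0.0
    de_log2fc: float = 1.0
    tiv_fraction: float = 0.0
    tiv_delta: float = 1.0
    tiv_run_length: int = 3
    tiv_event_types: tuple[str, ...] = DEFAULT_EVENT_TYPES
    decoy_fraction: float = 0.0
    # detection p-value link
    detect_margin: float = 0.5
    detect_sd: float = 0.25
    # --- scratch assay ---
    tile_rows: int = 6
    tile_cols: int = 4
    tile_height: int = 100
    tile_width: int = 150
    gap_width: float = 300.0
    closure_speed: float = 7.5  # px/h per front
    scratch_times_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    blob_density: float = 0.07
    blob_sigma: float = 2.5
    blob_amp: tuple[float, float] = (0.6, 1.0)
    bg_level: float = 0.05
    bg_noise_sd: float = 0.02
    edge_inset: float = 0.0
    # --- screen ---
    n_screen_genes: int = 35
    screen_isoforms_per_gene: int = 2
    # optional (count, isoforms) mix overriding the uniform isoform count,
    # e.g. ((29, 2), (5, 3), (1, 4)) gives 154 isoform oligos for 35 genes
    screen_isoform_mix: tuple[tuple[int, int], ...] = ()
    screen_oligos_per_isoform: int = 2
    screen_replicates: int = 11
    n_control_wells: int = 12
    amd_mean: float = 150.0
    amd_sd: float = 10.0

    def __post_init__(self) -> None:
        for frac in (self.de_fraction, self.tiv_fraction, self.decoy_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if 0 not in self.times:
            raise ValueError("time grid must include 0")

    def sigma(self, intensity) -> np.ndarray:
        """True replicate-noise SD as a function of log2 intensity."""
        intensity = np.asarray(intensity, dtype=float)
        if self.constant_noise is not None:
            return np.full_like(intensity, self.constant_noise)
        return self.noise_sd_low + (self.noise_sd_high - self.noise_sd_low) / (
            1.0 + np.exp((intensity - self.noise_mid) / self.noise_width)
        )


def _rng(spec: SimulationSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, salt])


# ---------------------------------------------------------------------------
# Gene models + probe layout
# ---------------------------------------------------------------------------

def _mirror(exon_lists: list[list[tuple[int, int]]], span_end: int):
    """Reflect coordinates so transcript order maps onto the '-' strand."""
    return [
        sorted((span_end - e, span_end - s) for s, e in exons)
        for exons in exon_lists
    ]


def _build_gene_structure(
    rng: np.random.Generator, event_type: str | None
) -> tuple[list[list[tuple[int, int]]], tuple[int, int] | None]:
    """Exon coordinate lists per isoform (transcript orientation, '+' axis)
    and the event-region interval, if any."""
    n_shared = 4
    exon_lens = rng.integers(120, 200, size=n_shared)
    intron_lens = rng.integers(300, 700, size=n_shared - 1)
    cursor = 1000
    shared: list[tuple[int, int]] = []
    for i in range(n_shared):
        shared.append((cursor, cursor + int(exon_lens[i])))
        cursor = shared[-1][1] + (int(intron_lens[i]) if i < n_shared - 1 else 0)

    iso_a = list(shared)
    event_region: tuple[int, int] | None = None

    if event_type is None:
        isoforms = [iso_a]
        if rng.random() < 0.3:
            isoforms.append(list(iso_a))
    elif event_type == ev.ALT_FIRST_EXON:
        u1 = (100, 100 + int(rng.integers(100, 160)))
        f1_start = u1[1] + int(rng.integers(150, 250))
        f1 = (f1_start, f1_start + int(rng.integers(100, 160)))
        assert f1[1] < shared[0][0] - 50
        isoforms = [[u1] + list(shared), [f1] + list(shared)]
        event_region = f1
    elif event_type == ev.CASSETTE_EXON:
        a, b = shared[0][1], shared[1][0]
        mid = (a + b) // 2
        half = int(rng.integers(48, 76))
        cx = (mid - half, mid + half)
        isoforms = [[shared[0], cx] + shared[1:], list(shared)]
        event_region = cx
    elif event_type == ev.ALT_5SS:
        ext = int(rng.integers(95, 140))
        s2 = shared[1]
        region = (s2[1], s2[1] + ext)
        iso_b = [shared[0], (s2[0], s2[1] + ext)] + shared[2:]
        isoforms = [iso_a, iso_b]
        event_region = region
    elif event_type == ev.ALT_3SS:
        ext = int(rng.integers(95, 140))
        s2 = shared[1]
        region = (s2[0] - ext, s2[0])
        iso_b = [shared[0], (s2[0] - ext, s2[1])] + shared[2:]
        isoforms = [iso_a, iso_b]
        event_region = region
    elif event_type == ev.INTRON_RETENTION:
        region = (shared[1][1], shared[2][0])
        iso_b = [shared[0], (shared[1][0], shared[2][1]), shared[3]]
        isoforms = [iso_a, iso_b]
        event_region = region
    elif event_type == ev.ALT_LAST_EXON:
        d1_start = shared[-1][1] + int(rng.integers(200, 350))
        d1 = (d1_start, d1_start + int(rng.integers(100, 160)))
        d2_start = d1[1] + int(rng.integers(150, 250))
        d2 = (d2_start, d2_start + int(rng.integers(100, 160)))
        isoforms = [list(shared) + [d1], list(shared) + [d2]]
        event_region = d2
    else:
        raise ValueError(f"unknown event type {event_type!r}")
    return isoforms, event_region


def _place_ps(
    rng: np.random.Generator,
    intervals: list[tuple[int, int]],
    n: int,
    margin: int = 5,
) -> list[tuple[int, int]]:
    """Spread n probe sets of PS_LENGTH bp round-robin across intervals."""
    out: list[tuple[int, int]] = []
    slots: list[list[tuple[int, int]]] = []
    for s, e in intervals:
        usable = e - s - 2 * margin
        k = max(0, usable // (PS_LENGTH + margin))
        positions = []
        for j in range(k):
            start = s + margin + j * (PS_LENGTH + margin)
            positions.append((start, start + PS_LENGTH))
        slots.append(positions)
    # round-robin over intervals, first slot of each, then second, ...
    depth = 0
    while len(out) < n:
        placed = False
        for positions in slots:
            if len(out) >= n:
                break
            if depth < len(positions):
                out.append(positions[depth])
                placed = True
        if not placed:
            raise ValueError("not enough room to place probe sets")
        depth += 1
    return out[:n]


@dataclass
class ArrayTruth:
    """Ground truth emitted with a simulated array experiment."""

    genes: pd.DataFrame  # gene_id, strand, event_type, de, de_sign, tiv, run_start, run_len, tiv_sign
    probesets: pd.DataFrame  # ps_id, gene_id, role (constitutive/event/intron/decoy)


def simulate_gene_models(
    spec: SimulationSpec,
) -> tuple[dict[str, GeneModel], pd.DataFrame, ArrayTruth]:
    """Gene models engineered per assigned event type, probe-set annotation
    table (unlabeled) and per-gene/per-PS ground truth."""
    rng = _rng(spec, 1)
    n_tiv = int(round(spec.tiv_fraction * spec.n_genes))
    event_assignment: list[str | None] = [
        spec.tiv_event_types[i % len(spec.tiv_event_types)] for i in range(n_tiv)
    ] + [None] * (spec.n_genes - n_tiv)

    n_de = int(round(spec.de_fraction * spec.n_genes))
    de_genes = set(rng.choice(spec.n_genes, size=n_de, replace=False).tolist())

    models: dict[str, GeneModel] = {}
    ps_rows = []
    gene_rows = []
    ps_truth_rows = []
    time_indices = np.arange(len(spec.times))
    nz = len(spec.times) - 1

    for g in range(spec.n_genes):
        gene_id = f"G{g:05d}"
        chrom = f"chr_{gene_id}"
        strand = "+" if rng.random() < 0.5 else "-"
        etype = event_assignment[g]
        exon_lists, event_region = _build_gene_structure(rng, etype)
        if strand == "-":
            span_end = max(e for exons in exon_lists for _, e in exons) + 100
            if event_region is not None:
                event_region = (span_end - event_region[1], span_end - event_region[0])
            exon_lists = _mirror(exon_lists, span_end)

        isoforms = tuple(
            Isoform(
                f"{gene_id}.{k+1}",
                gene_id,
                tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
            )
            for k, exons in enumerate(exon_lists)
        )
        model = GeneModel(gene_id, isoforms)
        models[gene_id] = model

        # probe placement: constitutive exonic PS in bases exonic in ALL
        # isoforms, event PS inside the event region, intron PS inside
        # constitutive introns.
        n_event_ps = spec.event_ps_per_gene if etype is not None else 0
        n_const_ps = spec.exonic_ps_per_gene - n_event_ps
        const_regions = _constitutive_exon_intervals(model)
        const_ps = _place_ps(rng, const_regions, n_const_ps)
        event_ps = (
            _place_ps(rng, [event_region], n_event_ps, margin=3)
            if n_event_ps
            else []
        )
        introns = [(iv.start, iv.end) for iv in model.constitutive_introns]
        intron_ps = _place_ps(rng, introns, spec.intronic_ps_per_gene)

        n_decoy = int(round(spec.decoy_fraction * n_const_ps))
        decoy_idx = set(
            rng.choice(n_const_ps, size=n_decoy, replace=False).tolist()
        )

        counter = 0
        for kind, positions in (
            ("constitutive", const_ps),
            ("event", event_ps),
            ("intron", intron_ps),
        ):
            for j, (s, e) in enumerate(positions):
                ps_id = f"{gene_id}:PS{counter:03d}"
                counter += 1
                role = kind
                if kind == "constitutive" and j in decoy_idx:
                    role = "decoy"
                ps_rows.append(
                    (ps_id, gene_id, chrom, s, e, strand, "full")
                )
                ps_truth_rows.append((ps_id, gene_id, role))

        # TIV run placement among non-zero time indices
        if etype is not None:
            max_start = nz - spec.tiv_run_length
            run_start = 1 + int(rng.integers(0, max_start + 1))
            tiv_sign = 1 if rng.random() < 0.5 else -1
        else:
            run_start, tiv_sign = -1, 0
        gene_rows.append(
            (
                gene_id,
                strand,
                etype if etype is not None else "none",
                g in de_genes,
                (1 if rng.random() < 0.5 else -1) if g in de_genes else 0,
                etype is not None,
                run_start,
                spec.tiv_run_length if etype is not None else 0,
                tiv_sign,
            )
        )

    ps_table = pd.DataFrame(
        ps_rows,
        columns=["ps_id", "gene_id", "chrom", "start", "end", "strand", "tier"],
    )
    truth = ArrayTruth(
        genes=pd.DataFrame(
            gene_rows,
            columns=[
                "gene_id",
                "strand",
                "event_type",
                "de",
                "de_sign",
                "tiv",
                "run_start",
                "run_len",
                "tiv_sign",
            ],
        ).set_index("gene_id"),
        probesets=pd.DataFrame(
            ps_truth_rows, columns=["ps_id", "gene_id", "role"]
        ).set_index("ps_id"),
    )
    return models, ps_table, truth


def _constitutive_exon_intervals(model: GeneModel) -> list[tuple[int, int]]:
    """Maximal intervals exonic in every isoform."""
    from .genemodel import _membership_segments  # shared partition helper

    all_ids = frozenset(iso.isoform_id for iso in model.isoforms)
    return [
        (a, b) for a, b, pat in _membership_segments(model) if pat == all_ids
    ]


# ---------------------------------------------------------------------------
# Signal time course
# ---------------------------------------------------------------------------

def simulate_timecourse(
    models: Mapping[str, GeneModel],
    ps_table: pd.DataFrame,
    truth: ArrayTruth,
    spec: SimulationSpec,
) -> tuple[SignalMatrix, SampleSheet]:
    """Log2 signal matrix + detection p-values for the simulated design.

    Baselines are gene-level with per-PS jitter; intron and decoy probe sets
    sit ``intron_offset`` below the gene baseline; DE genes shift every
    expressed exonic PS from the first post-stimulus time point on; TIV
    genes shift only their event probe sets over the assigned run; replicate
    noise is Gaussian with intensity-dependent SD.
    """
    rng = _rng(spec, 2)
    times = list(spec.times)
    R = spec.n_replicates
    ps_ids = ps_table["ps_id"].to_numpy()
    gene_ids = ps_table["gene_id"].to_numpy()
    roles = truth.probesets.loc[ps_ids, "role"].to_numpy()
    gtruth = truth.genes

    unique_genes = gtruth.index.to_numpy()
    gene_base = pd.Series(
        rng.normal(spec.baseline_mean, spec.baseline_sd, size=len(unique_genes)),
        index=unique_genes,
    )
    base = gene_base[gene_ids].to_numpy() + rng.normal(
        0.0, spec.ps_jitter_sd, size=len(ps_ids)
    )
    background_like = np.isin(roles, ("intron", "decoy"))
    base = base + np.where(background_like, spec.intron_offset, 0.0)

    de = gtruth.loc[gene_ids, "de"].to_numpy()
    de_sign = gtruth.loc[gene_ids, "de_sign"].to_numpy()
    run_start = gtruth.loc[gene_ids, "run_start"].to_numpy()
    run_len = gtruth.loc[gene_ids, "run_len"].to_numpy()
    tiv_sign = gtruth.loc[gene_ids, "tiv_sign"].to_numpy()
    is_event_ps = roles == "event"
    expressed_exonic = np.isin(roles, ("constitutive", "event"))

    true_means = np.empty((len(ps_ids), len(times)))
    for k, _t in enumerate(times):
        mean_k = base.copy()
        if k > 0:
            mean_k = mean_k + np.where(
                de & expressed_exonic, de_sign * spec.de_log2fc, 0.0
            )
            in_run = (run_start <= k) & (k < run_start + run_len)
            mean_k = mean_k + np.where(
                is_event_ps & in_run, tiv_sign * spec.tiv_delta, 0.0
            )
        true_means[:, k] = mean_k

    sample_ids = []
    sheet_rows = []
    values = {}
    detp = {}
    mu_detect = spec.baseline_mean + spec.intron_offset + spec.detect_margin
    from scipy.stats import norm

    for k, t in enumerate(times):
        sd = spec.sigma(true_means[:, k])
        for r in range(1, R + 1):
            sid = f"t{t}_r{r}"
            sample_ids.append(sid)
            sheet_rows.append((sid, t, r))
            x = true_means[:, k] + rng.normal(0.0, 1.0, size=len(ps_ids)) * sd
            values[sid] = x
            detp[sid] = np.clip(
                norm.sf((x - mu_detect) / spec.detect_sd), 1e-300, 1.0
            )

    values_df = pd.DataFrame(values, index=ps_ids)
    detp_df = pd.DataFrame(detp, index=ps_ids)
    sheet = SampleSheet(
        pd.DataFrame(
            sheet_rows, columns=["sample_id", "time_minutes", "replicate"]
        ).set_index("sample_id")
    )
    return SignalMatrix(values_df, detp_df), sheet


def simulate_arrays(
    spec: SimulationSpec,
) -> tuple[dict[str, GeneModel], pd.DataFrame, SignalMatrix, SampleSheet, ArrayTruth]:
    """Convenience: models + probe table + signals + sample sheet + truth."""
    models, ps_table, truth = simulate_gene_models(spec)
    matrix, sheet = simulate_timecourse(models, ps_table, truth, spec)
    return models, ps_table, matrix, sheet, truth


# ---------------------------------------------------------------------------
# Scratch-assay images
# ---------------------------------------------------------------------------

@dataclass
class ScratchTruth:
    times_h: np.ndarray
    gap_widths: np.ndarray  # true gap width per time (px)
    closure_speed: float  # px/h per front


def simulate_scratch(
    spec: SimulationSpec, well_salt: int = 0
) -> tuple[list[TileGrid], list[np.ndarray], ScratchTruth]:
    """Tile-grid series for one well plus full-scene renders and truth.

    Two textured sheets (Poisson-scattered Gaussian blobs) flank a central
    vertical gap whose half-width shrinks at ``closure_speed`` px/h.  Cells
    are static; new cells appear as each front advances, so a zero-speed
    well yields identical images at every time point.
    """
    rng = _rng(spec, 1000 + well_salt)
    H = spec.tile_rows * spec.tile_height
    W = spec.tile_cols * spec.tile_width
    cx = W / 2.0
    half0 = spec.gap_width / 2.0

    times = np.asarray(spec.scratch_times_h, dtype=float)
    halves = np.maximum(0.0, half0 - spec.closure_speed * times)

    noise = spec.bg_level + rng.normal(0.0, spec.bg_noise_sd, size=(H, W))

    # static blob field covering the maximal sheet extents (up to the centre)
    def _blobs(x_lo: float, x_hi: float) -> np.ndarray:
        area = (x_hi - x_lo) * H
        n = rng.poisson(spec.blob_density * area)
        xs = rng.uniform(x_lo, x_hi, size=n)
        ys = rng.uniform(0, H, size=n)
        amps = rng.uniform(*spec.blob_amp, size=n)
        return np.column_stack([xs, ys, amps])

    left = _blobs(-3 * spec.blob_sigma, cx)
    right = _blobs(cx, W + 3 * spec.blob_sigma)

    rad = int(np.ceil(3 * spec.blob_sigma))
    ax = np.arange(-rad, rad + 1)
    kernel = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * spec.blob_sigma**2))

    def _render(half: float) -> np.ndarray:
        img = noise.copy()
        edge_l = cx - half - spec.edge_inset
        edge_r = cx + half + spec.edge_inset
        for blobs, keep in (
            (left, lambda x: x <= edge_l),
            (right, lambda x: x >= edge_r),
        ):
            sel = blobs[keep(blobs[:, 0])]
            for x, y, amp in sel:
                ix, iy = int(round(x)), int(round(y))
                x0, x1 = max(0, ix - rad), min(W, ix + rad + 1)
                y0, y1 = max(0, iy - rad), min(H, iy + rad + 1)
                if x0 >= x1 or y0 >= y1:
                    continue
                img[y0:y1, x0:x1] += (
                    amp
                    * kernel[
                        y0 - (iy - rad) : y1 - (iy - rad),
                        x0 - (ix - rad) : x1 - (ix - rad),
                    ]
                )
        return img

    grids, scenes = [], []
    for t, half in zip(times, halves):
        scene = _render(half)
        tiles = scene.reshape(
            spec.tile_rows, spec.tile_height, spec.tile_cols, spec.tile_width
        ).transpose(0, 2, 1, 3)
        grids.append(TileGrid(tiles.copy(), time_hours=float(t)))
        scenes.append(scene)
    truth = ScratchTruth(times, 2.0 * halves, spec.closure_speed)
    return grids, scenes, truth


# ---------------------------------------------------------------------------
# Screen plates
# ---------------------------------------------------------------------------

@dataclass
class ScreenTruth:
    effects: pd.Series  # oligo_id -> true multiplicative AMD effect


def simulate_screen(
    spec: SimulationSpec,
    effects: Mapping[str, float] | None = None,
) -> tuple[pd.Series, PlateMap, ScreenTruth]:
    """Well AMD table + plate map + per-oligo truth.

    Control wells draw AMD ~ N(amd_mean, amd_sd); each oligo's wells draw
    from N(effect * amd_mean, amd_sd) with ``screen_replicates`` wells.
    """
    rng = _rng(spec, 3)
    effects = dict(effects or {})
    if spec.screen_isoform_mix:
        iso_counts = [
            k for count, k in spec.screen_isoform_mix for _ in range(count)
        ]
    else:
        iso_counts = [spec.screen_isoforms_per_gene] * spec.n_screen_genes
    rows = []
    oligo_ids = []
    for g, n_iso in enumerate(iso_counts):
        gene = f"SG{g:03d}"
        for i in range(1, n_iso + 1):
            for o in range(1, spec.screen_oligos_per_isoform + 1):
                oligo_ids.append((f"{gene}_i{i}_o{o}", gene, f"isoform_{i}"))
        oligo_ids.append((f"{gene}_GL", gene, GENE_LEVEL))

    well_amd = {}
    for w in range(spec.n_control_wells):
        well = f"CTRL_w{w:02d}"
        rows.append((well, "control", "control", CONTROL_CLASS))
        well_amd[well] = rng.normal(spec.amd_mean, spec.amd_sd)
    for oligo_id, gene, target in oligo_ids:
        eff = float(effects.get(oligo_id, 1.0))
        for w in range(spec.screen_replicates):
            well = f"{oligo_id}_w{w:02d}"
            rows.append((well, oligo_id, gene, target))
            well_amd[well] = rng.normal(eff * spec.amd_mean, spec.amd_sd)

    platemap = PlateMap(
        pd.DataFrame(
            rows, columns=["well_id", "oligo_id", "gene_id", "target"]
        ).set_index("well_id")
    )
    truth = ScreenTruth(
        effects=pd.Series(
            {oid: float(effects.get(oid, 1.0)) for oid, _, _ in oligo_ids}
        )
    )
    return pd.Series(well_amd, name="amd"), platemap, truth
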