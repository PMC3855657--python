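"""TIV event-type classification and isoform-ratio profiles."""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import genemodel as gm
from .tiv import FoldChangeTable, TIVEvent

# Event types
ALT_FIRST_EXON = "alt_first_exon"
CASSETTE_EXON = "cassette_exon"
ALT_5SS = "alt_5ss"
ALT_3SS = "alt_3ss"
INTRON_RETENTION = "intron_retention"
ALT_LAST_EXON = "alt_last_exon"
UNCLASSIFIED = "unclassified"

EVENT_TYPES = (
    ALT_FIRST_EXON,
    CASSETTE_EXON,
    ALT_5SS,
    ALT_3SS,
    INTRON_RETENTION,
    ALT_LAST_EXON,
    UNCLASSIFIED,
)

_REGION_TO_EVENT = {
    gm.ALT_FIRST_EXON_REGION: ALT_FIRST_EXON,
    gm.CASSETTE_EXON: CASSETTE_EXON,
    gm.ALT_5SS_EXTENSION: ALT_5SS,
    gm.ALT_3SS_EXTENSION: ALT_3SS,
    gm.RETAINED_INTRON: INTRON_RETENTION,
    gm.ALT_LAST_EXON_REGION: ALT_LAST_EXON,
}


def probeset_region_class(
    partition, start: int, end: int
) -> str | None:
    """Majority region class over the bases of [start, end); None on a tie."""
    votes: Counter[str] = Counter()
    for a, b, cls in partition:
        ov = min(b, end) - max(a, start)
        if ov > 0:
            votes[cls] += ov
    if not votes:
        return None
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return None
    return top[0][0]


def classify_event(
    event: TIVEvent,
    model: gm.GeneModel,
    annotations: pd.DataFrame,
) -> str:
    """Event type by majority vote over the deviating probe sets' region
    classes (PS-count vote; ties -> unclassified; probe sets in constitutive
    regions contribute no vote)."""
    partition = gm.region_classes(model)
    ann = annotations.set_index("ps_id")
    votes: Counter[str] = Counter()
    for ps in event.ps_ids:
        if ps not in ann.index:
            continue
        row = ann.loc[ps]
        cls = probeset_region_class(partition, int(row["start"]), int(row["end"]))
        if cls in _REGION_TO_EVENT:
            votes[_REGION_TO_EVENT[cls]] += 1
    if not votes:
        return UNCLASSIFIED
    top = votes.most_common()
    if len(top) > 1 and top[0][1] == top[1][1]:
        return UNCLASSIFIED
    return top[0][0]


def classify_events(
    events: list[TIVEvent],
    models,
    annotations: pd.DataFrame,
) -> list[TIVEvent]:
    """Assign ``event_type`` in place for each event; returns the list."""
    for ev in events:
        ev.event_type = classify_event(ev, models[ev.gene_id], annotations)
    return events


@dataclass
class IsoformRatioProfile:
    """log2 short/long isoform-abundance ratio over time.

    ratio(t) = median FC over short-specific PS - median FC over
    long-specific PS; identically 0 at t = 0.
    """

    gene_id: str
    short_ps: tuple[str, ...]
    long_ps: tuple[str, ...]
    ratio: pd.Series  # indexed by time (minutes)


def isoform_ratio(
    fc_table: FoldChangeTable,
    gene_id: str,
    short_ids,
    long_ids,
) -> IsoformRatioProfile:
    short_ids = [p for p in short_ids if p in fc_table.fc.index]
    long_ids = [p for p in long_ids if p in fc_table.fc.index]
    if not short_ids or not long_ids:
        raise ValueError("empty isoform-specific probe-set group")
    if set(short_ids) & set(long_ids):
        raise ValueError("short and long probe-set groups overlap")
    short_med = fc_table.fc.loc[short_ids].median(axis=0)
    long_med = fc_table.fc.loc[long_ids].median(axis=0)
    ratio = short_med - long_med
    ratio[0] = 0.0
    return IsoformRatioProfile(
        gene_id=gene_id,
        short_ps=tuple(sorted(short_ids)),
        long_ps=tuple(sorted(long_ids)),
        ratio=ratio,
    )


def rank_events(events: list[TIVEvent]) -> list[TIVEvent]:
    """Order by minimal q, then |delta| descending, then gene id."""
    return sorted(
        events, key=lambda e: (e.q_min, -e.max_abs_delta, e.gene_id)
    )
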