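"""Gene/isoform structures, probe-set annotation and region classes.

Coordinates are 0-based, half-open throughout.  Strand affects only the
orientation of "first"/"last" (5'/3') decisions, never interval arithmetic.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

# Region classes: every base of a gene span belongs to exactly one.
CONSTITUTIVE_EXON = "constitutive_exon"
ALT_FIRST_EXON_REGION = "alt_first_exon_region"
CASSETTE_EXON = "cassette_exon"
ALT_5SS_EXTENSION = "alt_5ss_extension"
ALT_3SS_EXTENSION = "alt_3ss_extension"
RETAINED_INTRON = "retained_intron"
ALT_LAST_EXON_REGION = "alt_last_exon_region"
CONSTITUTIVE_INTRON = "constitutive_intron"
UNCLASSIFIED_REGION = "unclassified_region"

REGION_CLASSES = (
    CONSTITUTIVE_EXON,
    ALT_FIRST_EXON_REGION,
    CASSETTE_EXON,
    ALT_5SS_EXTENSION,
    ALT_3SS_EXTENSION,
    RETAINED_INTRON,
    ALT_LAST_EXON_REGION,
    CONSTITUTIVE_INTRON,
    UNCLASSIFIED_REGION,
)

# Probe-set labels
LABEL_INTRON = "constitutive_intron"
LABEL_EXON = "putative_exon"
LABEL_AMBIGUOUS = "ambiguous"


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on a fixed strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Isoform:
    """One transcript isoform: ordered, disjoint exons on the gene strand."""

    isoform_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"isoform {self.isoform_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(
                    f"isoform {self.isoform_id}: overlapping exons "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.exons[0].chrom, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def first_exon(self) -> GenomicInterval:
        """5'-most exon (strand-aware)."""
        return self.exons[0] if self.strand == "+" else self.exons[-1]

    @property
    def last_exon(self) -> GenomicInterval:
        """3'-most exon (strand-aware)."""
        return self.exons[-1] if self.strand == "+" else self.exons[0]

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, a.strand))
        return out

    def covers(self, pos: int) -> bool:
        return any(e.start <= pos < e.end for e in self.exons)


@dataclass
class GeneModel:
    """A gene as a set of isoforms plus derived structural regions."""

    gene_id: str
    isoforms: tuple[Isoform, ...]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"gene {self.gene_id}: no isoforms")
        strands = {iso.strand for iso in self.isoforms}
        if len(strands) != 1:
            raise ValueError(f"gene {self.gene_id}: mixed strands")
        chroms = {iso.span.chrom for iso in self.isoforms}
        if len(chroms) != 1:
            raise ValueError(f"gene {self.gene_id}: isoforms on multiple chromosomes")
        self.isoforms = tuple(self.isoforms)

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    @property
    def chrom(self) -> str:
        return self.isoforms[0].span.chrom

    @property
    def span(self) -> GenomicInterval:
        start = min(iso.span.start for iso in self.isoforms)
        end = max(iso.span.end for iso in self.isoforms)
        return GenomicInterval(self.chrom, start, end, self.strand)

    @property
    def exon_union(self) -> list[GenomicInterval]:
        """Merged intervals exonic in at least one isoform."""
        return merge_intervals(
            [e for iso in self.isoforms for e in iso.exons]
        )

    @property
    def constitutive_introns(self) -> list[GenomicInterval]:
        return constitutive_introns(self)

    @property
    def first_exons(self) -> dict[str, GenomicInterval]:
        return {iso.isoform_id: iso.first_exon for iso in self.isoforms}

    @property
    def last_exons(self) -> dict[str, GenomicInterval]:
        return {iso.isoform_id: iso.last_exon for iso in self.isoforms}


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as maximal, sorted, disjoint intervals."""
    ivs = sorted(intervals, key=lambda e: (e.start, e.end))
    if not ivs:
        return []
    out = [ivs[0]]
    for iv in ivs[1:]:
        last = out[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                out[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            out.append(iv)
    return out


def constitutive_introns(model: GeneModel) -> list[GenomicInterval]:
    """Maximal intervals within the gene span that are exonic in no isoform.

    Equivalent to the base-wise intersection of all isoforms' non-exonic
    bases inside the gene span (vacuously intronic for isoforms whose span
    does not reach a base).
    """
    span = model.span
    union = model.exon_union
    out = []
    cursor = span.start
    for iv in union:
        if iv.start > cursor:
            out.append(GenomicInterval(span.chrom, cursor, iv.start, span.strand))
        cursor = max(cursor, iv.end)
    if cursor < span.end:
        out.append(GenomicInterval(span.chrom, cursor, span.end, span.strand))
    return out


# ---------------------------------------------------------------------------
# Region classes
# ---------------------------------------------------------------------------

def _membership_segments(model: GeneModel) -> list[tuple[int, int, frozenset[str]]]:
    """Partition the gene span into maximal segments of constant
    isoform-membership pattern (which isoforms are exonic there)."""
    span = model.span
    bounds = {span.start, span.end}
    for iso in model.isoforms:
        for e in iso.exons:
            bounds.add(e.start)
            bounds.add(e.end)
    edges = sorted(b for b in bounds if span.start <= b <= span.end)
    segs: list[tuple[int, int, frozenset[str]]] = []
    for a, b in zip(edges, edges[1:]):
        pattern = frozenset(
            iso.isoform_id for iso in model.isoforms if iso.covers(a)
        )
        if segs and segs[-1][2] == pattern and segs[-1][1] == a:
            segs[-1] = (segs[-1][0], b, pattern)
        else:
            segs.append((a, b, pattern))
    return segs


def _shared_limits(iso: Isoform, others: Sequence[Isoform]) -> tuple[int | None, int | None]:
    """Genomic (min, max) coordinates of bases exonic both in `iso` and in at
    least one of `others`; (None, None) if nothing is shared."""
    lo: int | None = None
    hi: int | None = None
    for e in iso.exons:
        for other in others:
            for f in other.exons:
                if e.overlaps(f):
                    s = max(e.start, f.start)
                    t = min(e.end, f.end)
                    lo = s if lo is None else min(lo, s)
                    hi = t if hi is None else max(hi, t)
    return lo, hi


def _classify_segment(
    a: int,
    b: int,
    pattern: frozenset[str],
    left: frozenset[str] | None,
    right: frozenset[str] | None,
    model: GeneModel,
) -> str:
    all_ids = frozenset(iso.isoform_id for iso in model.isoforms)
    if not pattern:
        return CONSTITUTIVE_INTRON
    if pattern == all_ids:
        return CONSTITUTIVE_EXON
    by_id = {iso.isoform_id: iso for iso in model.isoforms}
    members = [by_id[i] for i in sorted(pattern)]
    excluded = [by_id[i] for i in sorted(all_ids - pattern)]

    left_sup = left is not None and left > pattern
    right_sup = right is not None and right > pattern

    if left_sup and right_sup:
        # Exonic in a subset, and in every excluded isoform [a,b) is exactly
        # the interval between two consecutive exons -> retained intron.
        if all(
            any(x.end == a and y.start == b for x, y in zip(j.exons, j.exons[1:]))
            for j in excluded
        ):
            return RETAINED_INTRON
        return UNCLASSIFIED_REGION
    if left_sup or right_sup:
        # Extension of a shared exon boundary.  A rightward extension
        # (shared bases on the left) lengthens the exon's 3' end on '+'
        # (alternative donor / 5' splice site) and its 5' end on '-'.
        rightward = left_sup
        if (rightward and model.strand == "+") or (not rightward and model.strand == "-"):
            return ALT_5SS_EXTENSION
        return ALT_3SS_EXTENSION

    # Not contiguous with shared exonic sequence: whole-exon alternatives.
    # Cassette: [a,b) is a complete exon of every member isoform and both
    # flanking exons are exonic in every excluded isoform.
    def _is_cassette(iso: Isoform) -> bool:
        for k, e in enumerate(iso.exons):
            if e.start == a and e.end == b:
                if k == 0 or k == len(iso.exons) - 1:
                    return False
                prev_e, next_e = iso.exons[k - 1], iso.exons[k + 1]
                return all(
                    any(f.overlaps(prev_e) for f in j.exons)
                    and any(f.overlaps(next_e) for f in j.exons)
                    for j in excluded
                )
        return False

    if all(_is_cassette(iso) for iso in members):
        return CASSETTE_EXON

    # Alternative first/last exon regions: the segment lies strictly 5' (3')
    # of every member isoform's first (last) base shared with an excluded
    # isoform.  Vacuously true when nothing is shared.
    def _is_alt_first(iso: Isoform) -> bool:
        lo, hi = _shared_limits(iso, excluded)
        if lo is None:
            return True
        return b <= lo if model.strand == "+" else a >= hi

    def _is_alt_last(iso: Isoform) -> bool:
        lo, hi = _shared_limits(iso, excluded)
        if lo is None:
            return True
        return a >= hi if model.strand == "+" else b <= lo

    if all(_is_alt_first(iso) for iso in members):
        return ALT_FIRST_EXON_REGION
    if all(_is_alt_last(iso) for iso in members):
        return ALT_LAST_EXON_REGION
    return UNCLASSIFIED_REGION


def region_classes(model: GeneModel) -> list[tuple[int, int, str]]:
    """Deterministic partition of the gene span into region classes.

    Returns maximal ``(start, end, class)`` segments that tile the span.
    """
    segs = _membership_segments(model)
    out: list[tuple[int, int, str]] = []
    for i, (a, b, pat) in enumerate(segs):
        left = segs[i - 1][2] if i > 0 else None
        right = segs[i + 1][2] if i + 1 < len(segs) else None
        cls = _classify_segment(a, b, pat, left, right, model)
        if out and out[-1][2] == cls and out[-1][1] == a:
            out[-1] = (out[-1][0], b, cls)
        else:
            out.append((a, b, cls))
    return out


def region_class_at(partition: Sequence[tuple[int, int, str]], pos: int) -> str | None:
    for a, b, cls in partition:
        if a <= pos < b:
            return cls
    return None


# ---------------------------------------------------------------------------
# Probe-set annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeSetAnnotation:
    ps_id: str
    gene_id: str
    interval: GenomicInterval
    tier: str
    label: str


PS_TABLE_COLUMNS = ["ps_id", "gene_id", "chrom", "start", "end", "strand", "tier"]


def annotate_probesets(
    ps_table: pd.DataFrame, models: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Label each probe set against its gene model.

    Labels: ``constitutive_intron`` (interval within a constitutive intron),
    ``putative_exon`` (every base exonic in >=1 isoform), ``ambiguous``
    (straddles a boundary or lies outside the gene span).  Probe sets mapped
    to unknown genes are dropped (counted in a log message).
    """
    missing = ~ps_table["gene_id"].isin(models.keys())
    if missing.any():
        logger.warning(
            "annotate_probesets: dropping %d probe sets mapped to unknown genes",
            int(missing.sum()),
        )
    table = ps_table.loc[~missing].copy()

    labels = []
    for gene_id, sub in table.groupby("gene_id", sort=False):
        model = models[gene_id]
        span = model.span
        union = model.exon_union
        introns = model.constitutive_introns
        for row in sub.itertuples():
            s, e = int(row.start), int(row.end)
            if not (span.start <= s and e <= span.end) or row.chrom != span.chrom:
                labels.append((row.Index, LABEL_AMBIGUOUS))
            elif any(iv.start <= s and e <= iv.end for iv in union):
                labels.append((row.Index, LABEL_EXON))
            elif any(iv.start <= s and e <= iv.end for iv in introns):
                labels.append((row.Index, LABEL_INTRON))
            else:
                labels.append((row.Index, LABEL_AMBIGUOUS))
    lab = pd.Series(dict(labels), name="label")
    table["label"] = lab
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_gene_models(path: str) -> dict[str, GeneModel]:
    """Load gene models from simplified JSON (``.json``) or GTF."""
    if str(path).endswith(".json"):
        return _load_json(path)
    return _load_gtf(path)


def _load_json(path: str) -> dict[str, GeneModel]:
    with open(path) as fh:
        doc = json.load(fh)
    models: dict[str, GeneModel] = {}
    for gene in doc["genes"]:
        gene_id = gene["gene_id"]
        chrom = gene["chrom"]
        strand = gene["strand"]
        isoforms = []
        for iso in gene["isoforms"]:
            exons = tuple(
                GenomicInterval(chrom, int(s), int(e), strand)
                for s, e in iso["exons"]
            )
            try:
                isoforms.append(Isoform(iso["isoform_id"], gene_id, exons))
            except ValueError as err:
                logger.warning("rejecting isoform %s: %s", iso["isoform_id"], err)
        if not isoforms:
            raise ValueError(f"gene {gene_id}: no valid isoforms")
        models[gene_id] = GeneModel(gene_id, tuple(isoforms))
    return models


def _load_gtf(path: str) -> dict[str, GeneModel]:
    exons: dict[tuple[str, str], list[GenomicInterval]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, start, end, strand = fields[0], fields[3], fields[4], fields[6]
            attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
            key = (attrs["gene_id"], attrs["transcript_id"])
            # GTF is 1-based inclusive
            exons.setdefault(key, []).append(
                GenomicInterval(chrom, int(start) - 1, int(end), strand)
            )
    per_gene: dict[str, list[Isoform]] = {}
    for (gene_id, tx_id), ivs in exons.items():
        try:
            per_gene.setdefault(gene_id, []).append(Isoform(tx_id, gene_id, tuple(ivs)))
        except ValueError as err:
            logger.warning("rejecting transcript %s: %s", tx_id, err)
    models = {}
    for gene_id, isoforms in per_gene.items():
        if not isoforms:
            raise ValueError(f"gene {gene_id}: no valid isoforms")
        models[gene_id] = GeneModel(gene_id, tuple(isoforms))
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str) -> None:
    """Serialize models to the simplified JSON dialect."""
    doc = {
        "genes": [
            {
                "gene_id": m.gene_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "isoforms": [
                    {
                        "isoform_id": iso.isoform_id,
                        "exons": [[e.start, e.end] for e in iso.exons],
                    }
                    for iso in m.isoforms
                ],
            }
            for m in models.values()
        ]
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
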