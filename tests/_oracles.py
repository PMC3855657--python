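"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid the package's interval arithmetic: everything is
computed base-wise on numpy arrays over the gene span.
"""

from __future__ import annotations

import numpy as np

from tivscan import genemodel as gm


def basewise_exon_masks(model: gm.GeneModel):
    """(span_start, per-isoform boolean base arrays over the span)."""
    span = model.span
    n = span.end - span.start
    masks = {}
    for iso in model.isoforms:
        m = np.zeros(n, dtype=bool)
        for e in iso.exons:
            m[e.start - span.start : e.end - span.start] = True
        masks[iso.isoform_id] = m
    return span.start, masks


def brute_constitutive_introns(model: gm.GeneModel) -> list[tuple[int, int]]:
    """Maximal runs of bases exonic in no isoform, via base-wise scan."""
    offset, masks = basewise_exon_masks(model)
    any_exonic = np.logical_or.reduce(list(masks.values()))
    out = []
    start = None
    for i, covered in enumerate(any_exonic):
        if not covered and start is None:
            start = i
        elif covered and start is not None:
            out.append((offset + start, offset + i))
            start = None
    if start is not None:
        out.append((offset + start, offset + len(any_exonic)))
    return out


def brute_region_classes(model: gm.GeneModel) -> np.ndarray:
    """Per-base region class over the gene span (array of class strings)."""
    offset, masks = basewise_exon_masks(model)
    ids = sorted(masks)
    mat = np.stack([masks[i] for i in ids])  # isoform x base
    n = mat.shape[1]
    all_set = frozenset(ids)
    by_id = {iso.isoform_id: iso for iso in model.isoforms}

    # pattern id per base
    patterns = [frozenset(np.array(ids)[mat[:, b]]) for b in range(n)]
    classes = np.empty(n, dtype=object)

    # segment boundaries by naive scan
    b = 0
    while b < n:
        e = b
        while e < n and patterns[e] == patterns[b]:
            e += 1
        pat = patterns[b]
        classes[b:e] = _brute_classify(
            b, e, pat, patterns, mat, ids, all_set, by_id, model, offset, n
        )
        b = e
    return classes


def _brute_classify(b, e, pat, patterns, mat, ids, all_set, by_id, model, offset, n):
    if not pat:
        return gm.CONSTITUTIVE_INTRON
    if pat == all_set:
        return gm.CONSTITUTIVE_EXON
    excluded = sorted(all_set - pat)
    members = sorted(pat)
    left = patterns[b - 1] if b > 0 else None
    right = patterns[e] if e < n else None
    left_sup = left is not None and left > pat
    right_sup = right is not None and right > pat

    if left_sup and right_sup:
        ok = True
        for j in excluded:
            iso = by_id[j]
            match = any(
                x.end == offset + b and y.start == offset + e
                for x, y in zip(iso.exons, iso.exons[1:])
            )
            ok = ok and match
        return gm.RETAINED_INTRON if ok else gm.UNCLASSIFIED_REGION
    if left_sup or right_sup:
        rightward = left_sup
        if (rightward and model.strand == "+") or (
            not rightward and model.strand == "-"
        ):
            return gm.ALT_5SS_EXTENSION
        return gm.ALT_3SS_EXTENSION

    # cassette: whole exon of each member, flanks overlap all excluded
    def is_cassette(i):
        iso = by_id[i]
        for k, ex in enumerate(iso.exons):
            if ex.start == offset + b and ex.end == offset + e:
                if k == 0 or k == len(iso.exons) - 1:
                    return False
                prev_e, next_e = iso.exons[k - 1], iso.exons[k + 1]
                for j in excluded:
                    jm = np.zeros(n, dtype=bool)
                    for f in by_id[j].exons:
                        jm[f.start - offset : f.end - offset] = True
                    if not jm[prev_e.start - offset : prev_e.end - offset].any():
                        return False
                    if not jm[next_e.start - offset : next_e.end - offset].any():
                        return False
                return True
        return False

    if all(is_cassette(i) for i in members):
        return gm.CASSETTE_EXON

    exc_any = np.zeros(n, dtype=bool)
    for j in excluded:
        exc_any |= mat[ids.index(j)]

    def shared_limits(i):
        both = mat[ids.index(i)] & exc_any
        where = np.flatnonzero(both)
        if where.size == 0:
            return None, None
        return int(where[0]), int(where[-1]) + 1  # [lo, hi) base offsets

    def is_alt_first(i):
        lo, hi = shared_limits(i)
        if lo is None:
            return True
        return e <= lo if model.strand == "+" else b >= hi

    def is_alt_last(i):
        lo, hi = shared_limits(i)
        if lo is None:
            return True
        return b >= hi if model.strand == "+" else e <= lo

    if all(is_alt_first(i) for i in members):
        return gm.ALT_FIRST_EXON_REGION
    if all(is_alt_last(i) for i in members):
        return gm.ALT_LAST_EXON_REGION
    return gm.UNCLASSIFIED_REGION


def brute_majority_class(classes: np.ndarray, offset: int, start: int, end: int):
    """Majority base class of [start, end) from a per-base class array."""
    from collections import Counter

    votes = Counter(classes[start - offset : end - offset].tolist())
    top = votes.most_common()
    if not top or (len(top) > 1 and top[0][1] == top[1][1]):
        return None
    return top[0][0]


def brute_isoform_hit_rule(
    iso_dirs: dict[str, tuple[str, str]], gene_level_dir: str
) -> dict[str, bool]:
    """Literal restatement of the isoform hit rule for enumeration tests.

    iso_dirs: isoform -> (oligo1 direction, oligo2 direction), directions in
    {'up', 'down', 'none'}; gene_level_dir likewise.
    """
    out = {}
    for iso, (d1, d2) in iso_dirs.items():
        hit = False
        if d1 == d2 and d1 in ("up", "down"):
            d = d1
            others_conflict = any(
                o1 == o2 == d
                for other, (o1, o2) in iso_dirs.items()
                if other != iso
            )
            hit = (not others_conflict) and gene_level_dir != d
        out[iso] = hit
    return out
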