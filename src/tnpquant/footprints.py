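"""Footprint construction and greedy transposase call resolution.

A translated search of a contig against a transposase protein database
typically yields several overlapping hits over the same nucleotide
stretch.  The stretch covered by a connected set of hits is a
*footprint*; it is resolved into one or more transposase calls by
repeatedly assigning the highest-scoring hit that still intersects the
unassigned part of the footprint, until no meaningful residual remains.
Resolved segments are then filtered: a call must be supported by a hit
with E-value strictly below ``max_evalue`` and must cover at least
``min_orf_coverage`` (default 30%) of the reference transposase ORF's
amino-acid length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from .hits import AlignmentHit, TransposaseRef

__all__ = [
    "Footprint",
    "TransposaseCall",
    "CallerConfig",
    "build_footprints",
    "resolve_footprint",
    "filter_calls",
    "call_transposases",
]

logger = logging.getLogger(__name__)

LINEAGE_RANKS = ("phylum", "class", "order", "genus")


@dataclass
class Footprint:
    """Maximal contig stretch covered by overlap-chained hits on one strand."""

    contig_id: str
    strand: str
    start: int
    end: int
    hit_ids: list[int]  # indices into the hit list the footprint was built from

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class TransposaseCall:
    """A resolved footprint segment assigned to one reference transposase."""

    contig_id: str
    strand: str
    start: int
    end: int
    ref_id: str
    family: str
    bitscore: float
    evalue: float
    aa_covered: float = 0.0
    aa_coverage_fraction: float = 0.0
    lineage: tuple[str, str, str, str] = ("unclassified",) * 4

    @property
    def taxon(self) -> str:
        return self.lineage[-1]


@dataclass
class CallerConfig:
    max_evalue: float = 1e-6
    min_orf_coverage: float = 0.30
    min_residual_nt: int = 30
    merge_across_strands: bool = False
    # coverage computed on the assigned segment (default) or the full source hit
    coverage_mode: str = "segment"

    def __post_init__(self) -> None:
        if not (0 < self.min_orf_coverage <= 1):
            raise ValueError("min_orf_coverage must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        if self.coverage_mode not in ("segment", "full_hit"):
            raise ValueError(f"unknown coverage_mode {self.coverage_mode!r}")


def _overlaps(a0: int, a1: int, b0: int, b1: int) -> bool:
    return min(a1, b1) - max(a0, b0) > 0


def build_footprints(
    hits: Sequence[AlignmentHit], config: CallerConfig | None = None
) -> list[Footprint]:
    """Merge hits into footprints: connected components of interval overlap.

    Hits are grouped per (contig, strand) — or per contig only when
    ``merge_across_strands`` — and intervals that transitively overlap
    form one footprint whose span is their union extent.
    """
    config = config or CallerConfig()
    groups: dict[tuple[str, str], list[int]] = {}
    for i, h in enumerate(hits):
        key = (h.query_id, "." if config.merge_across_strands else h.strand)
        groups.setdefault(key, []).append(i)

    footprints: list[Footprint] = []
    for (contig_id, strand), idxs in sorted(groups.items()):
        idxs.sort(key=lambda i: (hits[i].q_start, hits[i].q_end))
        cur: list[int] = []
        cur_end = -1
        for i in idxs:
            h = hits[i]
            if cur and h.q_start < cur_end:
                cur.append(i)
                cur_end = max(cur_end, h.q_end)
            else:
                if cur:
                    footprints.append(
                        Footprint(contig_id, strand,
                                  hits[cur[0]].q_start, cur_end, cur)
                    )
                cur = [i]
                cur_end = h.q_end
        if cur:
            footprints.append(
                Footprint(contig_id, strand, hits[cur[0]].q_start, cur_end, cur)
            )
    return footprints


def _subtract(intervals: list[tuple[int, int]], cut: tuple[int, int]) -> list[tuple[int, int]]:
    """Remove ``cut`` from a sorted disjoint interval list."""
    out = []
    c0, c1 = cut
    for a0, a1 in intervals:
        if a1 <= c0 or a0 >= c1:
            out.append((a0, a1))
            continue
        if a0 < c0:
            out.append((a0, c0))
        if a1 > c1:
            out.append((c1, a1))
    return out


def _intersect(intervals: list[tuple[int, int]], iv: tuple[int, int]) -> list[tuple[int, int]]:
    out = []
    for a0, a1 in intervals:
        lo, hi = max(a0, iv[0]), min(a1, iv[1])
        if hi > lo:
            out.append((lo, hi))
    return out


def _hit_sort_key(h: AlignmentHit):
    # highest bitscore, then lowest evalue, then longest query span, then ref_id
    return (-h.bitscore, h.evalue, -(h.q_end - h.q_start), h.ref_id)


def resolve_footprint(
    fp: Footprint,
    hits: Sequence[AlignmentHit],
    refs: Mapping[str, TransposaseRef],
    config: CallerConfig | None = None,
) -> list[TransposaseCall]:
    """Resolve a footprint into calls by iterative highest-score assignment.

    Greedy loop: among hits intersecting the still-unassigned region of
    the footprint (restricted to residual pieces of at least
    ``min_residual_nt``), pick the best-ranked hit (bitscore, then
    E-value, then query-span length, then ref id), assign its
    intersection with the unassigned region as call segments, subtract
    it, and repeat.
    """
    config = config or CallerConfig()
    if not fp.hit_ids:
        raise RuntimeError("footprint with no hits (violated precondition)")
    pool = list(fp.hit_ids)
    unassigned: list[tuple[int, int]] = [(fp.start, fp.end)]
    calls: list[TransposaseCall] = []

    while pool and unassigned:
        eligible = [
            (a0, a1) for a0, a1 in unassigned if a1 - a0 >= config.min_residual_nt
        ]
        candidates = [
            i
            for i in pool
            if any(_overlaps(hits[i].q_start, hits[i].q_end, a0, a1)
                   for a0, a1 in eligible)
        ]
        if not candidates:
            break
        best = min(candidates, key=lambda i: _hit_sort_key(hits[i]))
        h = hits[best]
        pieces = _intersect(unassigned, (h.q_start, h.q_end))
        for p0, p1 in pieces:
            ref = refs.get(h.ref_id)
            family = ref.family if ref is not None else "unknown"
            if config.coverage_mode == "full_hit":
                aa = float(h.s_len)
            else:
                # aa residues of the reference aligned within this segment,
                # proportional along the source hit
                aa = (p1 - p0) / h.q_len * h.s_len
            calls.append(
                TransposaseCall(
                    contig_id=fp.contig_id,
                    strand=h.strand,
                    start=p0,
                    end=p1,
                    ref_id=h.ref_id,
                    family=family,
                    bitscore=h.bitscore,
                    evalue=h.evalue,
                    aa_covered=aa,
                )
            )
        unassigned = _subtract(unassigned, (h.q_start, h.q_end))
        pool.remove(best)

    calls.sort(key=lambda c: (c.start, c.end))
    return calls


def filter_calls(
    calls: Sequence[TransposaseCall],
    refs: Mapping[str, TransposaseRef],
    config: CallerConfig | None = None,
) -> list[TransposaseCall]:
    """Apply the ORF-coverage rule: keep calls covering ≥ 30% of the reference.

    Coverage is the number of reference amino-acid residues aligned
    within the call's segment divided by the reference ORF length;
    the boundary value (exactly ``min_orf_coverage``) is retained.
    """
    config = config or CallerConfig()
    kept = []
    for c in calls:
        ref = refs.get(c.ref_id)
        if ref is None:
            raise KeyError(f"call references unknown reference id {c.ref_id!r}")
        c.aa_coverage_fraction = c.aa_covered / ref.aa_len
        if c.aa_coverage_fraction >= config.min_orf_coverage:
            kept.append(c)
    return kept


def call_transposases(
    hits: Sequence[AlignmentHit],
    refs: Mapping[str, TransposaseRef] | Sequence[TransposaseRef],
    taxonomy: Mapping[str, Sequence[str]] | None = None,
    config: CallerConfig | None = None,
) -> list[TransposaseCall]:
    """Full identification: E-value filter → footprints → resolution → coverage filter.

    ``taxonomy`` maps contig id to a (phylum, class, order, genus)
    lineage; contigs without taxonomy are annotated "unclassified" with a
    logged warning.
    """
    config = config or CallerConfig()
    if not isinstance(refs, Mapping):
        refs = {r.ref_id: r for r in refs}
    passing = [h for h in hits if h.evalue < config.max_evalue]
    footprints = build_footprints(passing, config)
    all_calls: list[TransposaseCall] = []
    for fp in footprints:
        resolved = resolve_footprint(fp, passing, refs, config)
        all_calls.extend(filter_calls(resolved, refs, config))
    if taxonomy is not None:
        missing = set()
        for c in all_calls:
            lin = taxonomy.get(c.contig_id)
            if lin is None:
                missing.add(c.contig_id)
                c.lineage = ("unclassified",) * 4
            else:
                c.lineage = tuple(lin)
        if missing:
            logger.warning(
                "no taxonomy for %d contig(s): %s",
                len(missing), ", ".join(sorted(missing)[:5]),
            )
    all_calls.sort(key=lambda c: (c.contig_id, c.start, c.end, c.strand))
    return all_calls
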