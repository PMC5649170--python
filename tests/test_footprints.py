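"""Footprint merging, greedy resolution and the coverage/e-value filters."""

import numpy as np
import pytest

from tnpquant.footprints import (CallerConfig, TransposaseCall,
                                 build_footprints, call_transposases,
                                 filter_calls, resolve_footprint)
from tnpquant.hits import AlignmentHit, TransposaseRef


def mkhit(q0, q1, bitscore, ref="R1", evalue=1e-30, strand="+", contig="c1",
          s0=0, s1=None):
    if s1 is None:
        s1 = s0 + max((q1 - q0) // 3, 1)
    return AlignmentHit(query_id=contig, ref_id=ref, q_start=q0, q_end=q1,
                        strand=strand, s_start=s0, s_end=s1,
                        bitscore=bitscore, evalue=evalue)


REFS = {
    "R1": TransposaseRef("R1", "IS3", "M" + "A" * 299),
    "R2": TransposaseRef("R2", "IS5", "M" + "C" * 299),
    "R3": TransposaseRef("R3", "IS256", "M" + "D" * 199),
}


class TestBuildFootprints:
    def test_overlapping_hits_merge(self):
        fps = build_footprints([mkhit(0, 300, 100), mkhit(200, 500, 90)])
        assert len(fps) == 1
        assert fps[0].span == (0, 500)
        assert sorted(fps[0].hit_ids) == [0, 1]

    def test_disjoint_hits_stay_separate(self):
        fps = build_footprints([mkhit(0, 300, 100), mkhit(400, 700, 90)])
        assert [fp.span for fp in fps] == [(0, 300), (400, 700)]

    def test_strands_not_merged_by_default(self):
        fps = build_footprints([mkhit(0, 300, 100), mkhit(100, 400, 90, strand="-")])
        assert len(fps) == 2

    def test_merge_across_strands_option(self):
        cfg = CallerConfig(merge_across_strands=True)
        fps = build_footprints(
            [mkhit(0, 300, 100), mkhit(100, 400, 90, strand="-")], cfg
        )
        assert len(fps) == 1 and fps[0].span == (0, 400)

    def test_components_match_union_find_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = int(rng.integers(1, 21))
            hits = []
            for _ in range(n):
                a = int(rng.integers(0, 1500))
                hits.append(mkhit(a, a + int(rng.integers(30, 400)), 50.0))
            fps = build_footprints(hits)
            # union-find oracle over the pairwise overlap graph
            parent = list(range(n))

            def find(i):
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(n):
                for j in range(i + 1, n):
                    hi, hj = hits[i], hits[j]
                    if min(hi.q_end, hj.q_end) > max(hi.q_start, hj.q_start):
                        parent[find(i)] = find(j)
            comps = {}
            for i in range(n):
                comps.setdefault(find(i), set()).add(i)
            assert sorted(map(sorted, (set(fp.hit_ids) for fp in fps))) == \
                sorted(map(sorted, comps.values()))


def greedy_oracle(span, hits, min_residual=30):
    """Position-set re-scan implementation of footprint resolution."""
    unassigned = set(range(*span))
    pool = list(range(len(hits)))
    segments = []
    while True:
        # residual runs of length >= min_residual
        runs = []
        cur = []
        for p in sorted(unassigned):
            if cur and p == cur[-1] + 1:
                cur.append(p)
            else:
                if len(cur) >= min_residual:
                    runs.append(set(cur))
                cur = [p]
        if len(cur) >= min_residual:
            runs.append(set(cur))
        eligible = set().union(*runs) if runs else set()
        cands = [i for i in pool
                 if set(range(hits[i].q_start, hits[i].q_end)) & eligible]
        if not cands:
            break
        best = min(cands, key=lambda i: (-hits[i].bitscore, hits[i].evalue,
                                         -(hits[i].q_end - hits[i].q_start),
                                         hits[i].ref_id))
        h = hits[best]
        inter = sorted(set(range(h.q_start, h.q_end)) & unassigned)
        run = [inter[0]]
        for p in inter[1:]:
            if p == run[-1] + 1:
                run.append(p)
            else:
                segments.append((run[0], run[-1] + 1, h.ref_id))
                run = [p]
        segments.append((run[0], run[-1] + 1, h.ref_id))
        unassigned -= set(inter)
        pool.remove(best)
    return sorted(segments)


class TestResolveFootprint:
    def test_single_hit_yields_single_call(self):
        hits = [mkhit(10, 310, 120)]
        (fp,) = build_footprints(hits)
        calls = resolve_footprint(fp, hits, REFS)
        assert len(calls) == 1
        assert (calls[0].start, calls[0].end) == (10, 310)
        assert calls[0].ref_id == "R1"

    def test_highest_score_takes_overlap_lower_gets_residual(self):
        # A covers the left 60%, B the right 60%; A wins the middle overlap
        hits = [mkhit(0, 600, 200, ref="R1"), mkhit(400, 1000, 150, ref="R2")]
        (fp,) = build_footprints(hits)
        calls = resolve_footprint(fp, hits, REFS)
        assert [(c.start, c.end, c.ref_id) for c in calls] == [
            (0, 600, "R1"), (600, 1000, "R2"),
        ]

    def test_small_residual_terminates_loop(self):
        # the uncovered 20 nt residual is below min_residual_nt=30
        hits = [mkhit(0, 500, 200, ref="R1"), mkhit(480, 520, 10, ref="R2")]
        (fp,) = build_footprints(hits)
        calls = resolve_footprint(fp, hits, REFS)
        assert [(c.start, c.end) for c in calls] == [(0, 500)]

    def test_matches_bruteforce_rescan_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(1, 11))
            hits = []
            base = int(rng.integers(0, 200))
            for k in range(n):
                a = base + int(rng.integers(0, 400))
                b = a + int(rng.integers(30, 500))
                hits.append(mkhit(
                    a, b,
                    bitscore=float(rng.integers(10, 60)) * 5,  # ties likely
                    ref=f"R{int(rng.integers(1, 4))}",
                    evalue=float(10.0 ** -rng.integers(7, 30)),
                ))
            for fp in build_footprints(hits):
                fp_hits = hits
                got = sorted((c.start, c.end, c.ref_id)
                             for c in resolve_footprint(fp, fp_hits, REFS))
                sub = [hits[i] for i in fp.hit_ids]
                exp = greedy_oracle(fp.span, sub)
                assert got == exp

    def test_empty_footprint_is_an_error(self):
        from tnpquant.footprints import Footprint

        with pytest.raises(RuntimeError):
            resolve_footprint(Footprint("c1", "+", 0, 100, []), [], REFS)


class TestFilterCalls:
    def _call(self, aa_covered, ref="R1"):
        return TransposaseCall("c1", "+", 0, 3 * int(aa_covered), ref,
                               REFS[ref].family, 100.0, 1e-20,
                               aa_covered=aa_covered)

    def test_boundary_coverage_exactly_30_percent_retained(self):
        kept = filter_calls([self._call(90.0)], REFS)  # 90 / 300
        assert len(kept) == 1
        assert kept[0].aa_coverage_fraction == pytest.approx(0.30)

    def test_just_below_boundary_removed(self):
        assert filter_calls([self._call(89.0)], REFS) == []  # 89/300 = 0.2967

    def test_full_length_call_retained(self):
        kept = filter_calls([self._call(300.0)], REFS)
        assert kept[0].aa_coverage_fraction == pytest.approx(1.0)

    def test_unknown_reference_is_an_error(self):
        with pytest.raises(KeyError, match="RX"):
            filter_calls([self._call(90.0, ref="RX")], {"R1": REFS["R1"]})


class TestCallTransposases:
    def test_empty_hit_list_gives_empty_calls(self):
        assert call_transposases([], REFS, {}) == []

    def test_evalue_exactly_at_threshold_excluded(self):
        hits = [mkhit(0, 900, 100, evalue=1e-6),
                mkhit(0, 900, 100, evalue=0.99e-6)]
        calls = call_transposases(hits, REFS)
        assert len(calls) == 1
        assert calls[0].evalue < 1e-6

    def test_taxonomy_annotation_and_unclassified_fallback(self, caplog):
        hits = [mkhit(0, 900, 100), mkhit(0, 900, 90, contig="c2")]
        tax = {"c1": ("Cyanobacteria", "Cyanophyceae", "Chroococcales",
                      "Synechococcus")}
        import logging

        with caplog.at_level(logging.WARNING):
            calls = call_transposases(hits, REFS, tax)
        by_contig = {c.contig_id: c for c in calls}
        assert by_contig["c1"].taxon == "Synechococcus"
        assert by_contig["c2"].taxon == "unclassified"
        assert "c2" in caplog.text

    def test_deterministic_ordering(self):
        rng = np.random.default_rng(3)
        hits = []
        for _ in range(30):
            a = int(rng.integers(0, 2000))
            hits.append(mkhit(a, a + int(rng.integers(90, 600)),
                              float(rng.integers(50, 300)),
                              ref=f"R{int(rng.integers(1, 4))}",
                              contig=f"c{int(rng.integers(1, 4))}"))
        one = call_transposases(hits, REFS)
        two = call_transposases(list(hits), REFS)
        assert [(c.contig_id, c.start, c.end, c.ref_id) for c in one] == \
            [(c.contig_id, c.start, c.end, c.ref_id) for c in two]
        assert one == sorted(one, key=lambda c: (c.contig_id, c.start, c.end,
                                                 c.strand))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(23)
        hits = []
        for _ in range(40):
            a = int(rng.integers(0, 3000))
            ln = int(rng.integers(60, 900))
            hits.append(mkhit(a, a + ln, float(rng.integers(30, 300)),
                              ref=f"R{int(rng.integers(1, 4))}",
                              evalue=float(10.0 ** -rng.integers(3, 40)),
                              s0=0, s1=ln // 3))
        n_calls = []
        for cov in (0.1, 0.3, 0.6, 0.9):
            cfg = CallerConfig(min_orf_coverage=cov)
            n_calls.append(len(call_transposases(hits, REFS, config=cfg)))
        assert n_calls == sorted(n_calls, reverse=True)
        # a stricter e-value bound propagates to every retained call
        # (the call *count* is not monotone: dropping a dominating hit can
        # split a footprint into several calls)
        for ev in (1e-4, 1e-6, 1e-12, 1e-25):
            cfg = CallerConfig(max_evalue=ev)
            assert all(c.evalue < ev
                       for c in call_transposases(hits, REFS, config=cfg))

    def test_segments_disjoint_within_contig_strand(self):
        rng = np.random.default_rng(29)
        hits = []
        for _ in range(50):
            a = int(rng.integers(0, 2500))
            hits.append(mkhit(a, a + int(rng.integers(90, 700)),
                              float(rng.integers(50, 300)),
                              ref=f"R{int(rng.integers(1, 4))}"))
        calls = call_transposases(hits, REFS)
        segs = sorted((c.start, c.end) for c in calls)
        for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
            assert a1 <= b0

    def test_truncated_orf_found_but_coverage_filtered(self):
        # hit covering only 25% of a 300-aa reference: passes the e-value
        # threshold, removed by the 30% ORF-coverage rule
        hits = [mkhit(0, 225, 120, ref="R1", s0=0, s1=75)]
        assert call_transposases(hits, REFS) == []
        cfg = CallerConfig(min_orf_coverage=0.2)
        assert len(call_transposases(hits, REFS, config=cfg)) == 1
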