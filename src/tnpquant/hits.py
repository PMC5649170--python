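"""Translated-search hits: BLAST tabular I/O and a built-in six-frame search.

Transposase genes are located on assembled contigs by comparing the
nucleotide sequence against a curated database of transposase proteins
(an ISfinder-style reference set) in translated (blastx-like) mode.
This module provides the two routes to such hits:

* :func:`read_blast_tab` ingests hit tables produced by an external
  BLAST run (12-column ``outfmt 6``);
* :func:`builtin_search` is a self-contained translated search —
  six-frame translation plus word-seeded Smith–Waterman — adequate for
  desk-scale synthetic communities (≲1 Mb of contig per run).

All coordinates inside the package are 0-based half-open on the forward
strand with an explicit strand flag; conversion from BLAST's 1-based
inclusive, orientation-encoded coordinates is confined to the parser.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "TransposaseRef",
    "AlignmentHit",
    "read_blast_tab",
    "write_blast_tab",
    "read_reference_fasta",
    "six_frame_translate",
    "builtin_search",
    "SearchParams",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (gap open 11, extend 1).
KA_LAMBDA = 0.267
KA_K = 0.041
LN2 = math.log(2.0)


@dataclass(frozen=True)
class TransposaseRef:
    """One curated transposase ORF from the reference protein database."""

    ref_id: str
    family: str
    aa_seq: str

    @property
    def aa_len(self) -> int:
        return len(self.aa_seq)

    def __post_init__(self) -> None:
        if not self.aa_seq:
            raise ValueError(f"reference {self.ref_id!r} has empty sequence")


@dataclass
class AlignmentHit:
    """One local translated alignment between a contig interval and a reference.

    ``q_start``/``q_end`` are 0-based half-open nucleotide coordinates on
    the forward strand of the contig regardless of ``strand``;
    ``s_start``/``s_end`` are 0-based half-open amino-acid coordinates on
    the reference protein.
    """

    query_id: str
    ref_id: str
    q_start: int
    q_end: int
    strand: str
    s_start: int
    s_end: int
    bitscore: float
    evalue: float
    pident: float = 100.0
    aln_len: int = 0
    mismatch: int = 0
    gapopen: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.q_start < self.q_end):
            raise ValueError(f"bad query interval [{self.q_start},{self.q_end})")
        if not (0 <= self.s_start < self.s_end):
            raise ValueError(f"bad subject interval [{self.s_start},{self.s_end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def q_len(self) -> int:
        return self.q_end - self.q_start

    @property
    def s_len(self) -> int:
        return self.s_end - self.s_start


class BlastTabError(ValueError):
    """Malformed BLAST tabular input."""


def read_blast_tab(path: str | Path) -> list[AlignmentHit]:
    """Parse a 12-column BLAST tabular (outfmt 6) file into hits.

    Columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore.  blastx encodes a reverse-strand hit as
    qstart > qend; such rows are normalized to forward coordinates with
    ``strand='-'``.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise BlastTabError(
                    f"{path}:{lineno}: expected 12 columns, got {len(cols)}"
                )
            try:
                pident = float(cols[2])
                length = int(cols[3])
                mismatch = int(cols[4])
                gapopen = int(cols[5])
                qstart, qend = int(cols[6]), int(cols[7])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise BlastTabError(f"{path}:{lineno}: non-numeric field ({exc})")
            if qstart <= qend:
                strand, q0, q1 = "+", qstart - 1, qend
            else:
                strand, q0, q1 = "-", qend - 1, qstart
            s0, s1 = min(sstart, send) - 1, max(sstart, send)
            try:
                hits.append(
                    AlignmentHit(
                        query_id=cols[0],
                        ref_id=cols[1],
                        q_start=q0,
                        q_end=q1,
                        strand=strand,
                        s_start=s0,
                        s_end=s1,
                        bitscore=bitscore,
                        evalue=evalue,
                        pident=pident,
                        aln_len=length,
                        mismatch=mismatch,
                        gapopen=gapopen,
                    )
                )
            except ValueError as exc:
                raise BlastTabError(f"{path}:{lineno}: {exc}")
    return hits


def _fmt_evalue(e: float) -> str:
    if e == 0:
        return "0.0"
    return format(e, ".2e")


def write_blast_tab(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits back to 12-column BLAST tabular, restoring BLAST conventions."""
    with open(path, "w") as fh:
        for h in hits:
            if h.strand == "+":
                qs, qe = h.q_start + 1, h.q_end
            else:
                qs, qe = h.q_end, h.q_start + 1
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.ref_id,
                        format(h.pident, ".2f"),
                        str(h.aln_len),
                        str(h.mismatch),
                        str(h.gapopen),
                        str(qs),
                        str(qe),
                        str(h.s_start + 1),
                        str(h.s_end),
                        _fmt_evalue(h.evalue),
                        format(h.bitscore, ".1f"),
                    ]
                )
                + "\n"
            )


def read_reference_fasta(path: str | Path) -> list[TransposaseRef]:
    """Load reference proteins; IS family parsed from a ``family=`` header tag."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        family = "unknown"
        for tok in rec.description.split():
            if tok.startswith("family="):
                family = tok[len("family="):]
        refs.append(TransposaseRef(ref_id=rec.id, family=family, aa_seq=str(rec.seq)))
    return refs


def six_frame_translate(contig: str) -> list[tuple[str, int, str]]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns ``(frame_label, nt_offset, peptide)`` triples for frames
    +1..+3 and -1..-3.  Stop codons are rendered as ``*``, codons with
    ambiguous bases as ``X``.  ``nt_offset`` is the offset into the
    translated strand (forward sequence for + frames, reverse complement
    for - frames).
    """
    if not contig:
        raise ValueError("cannot translate an empty sequence")
    fwd = contig.upper()
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for label_sign, seq in (("+", fwd), ("-", rev)):
        for off in range(3):
            sub = seq[off : off + 3 * ((len(seq) - off) // 3)]
            pep = str(Seq(sub).translate()) if sub else ""
            frames.append((f"{label_sign}{off + 1}", off, pep))
    return frames


@dataclass
class SearchParams:
    """Tunables of the built-in translated search."""

    max_evalue: float | None = 1e-6
    min_bitscore: float | None = None
    word_size: int | None = 6  # None disables seeding (exhaustive mode)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    ka_lambda: float = KA_LAMBDA
    ka_k: float = KA_K
    window_pad: int = 25
    matrix: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.max_evalue is None and self.min_bitscore is None:
            raise ValueError("one of max_evalue / min_bitscore is required")


def _make_aligner(params: SearchParams) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    return aligner


def bitscore_from_raw(raw: float, params: SearchParams) -> float:
    return (params.ka_lambda * raw - math.log(params.ka_k)) / LN2


def evalue_from_bitscore(bits: float, m: int, n: int) -> float:
    # E = m * n * 2^-bits; guard against overflow of 2^bits for weak scores
    log2e = math.log2(max(m, 1)) + math.log2(max(n, 1)) - bits
    if log2e > 300:
        return math.inf
    return 2.0 ** log2e


def _seed_clusters(
    peptide: str, ref_index: dict[str, list[tuple[int, int]]], k: int
) -> dict[int, list[tuple[int, int]]]:
    """Exact k-mer seeds between peptide and references, grouped per reference.

    Returns {ref_idx: [(q_pos, s_pos), ...]}.
    """
    seeds: dict[int, list[tuple[int, int]]] = {}
    for q in range(len(peptide) - k + 1):
        word = peptide[q : q + k]
        if "*" in word or "X" in word:
            continue
        for ref_idx, s in ref_index.get(word, ()):
            seeds.setdefault(ref_idx, []).append((q, s))
    return seeds


def _cluster_by_diagonal(
    seeds: list[tuple[int, int]], ref_len: int
) -> list[tuple[int, int]]:
    """Collapse seeds into candidate peptide windows (q_lo, q_hi per cluster).

    Seeds are grouped when close both along the peptide and in diagonal;
    each group yields one window wide enough to hold a full reference
    alignment around its seeds.
    """
    pts = sorted(seeds, key=lambda t: (t[0] - t[1], t[0]))
    clusters: list[list[tuple[int, int]]] = []
    for q, s in pts:
        d = q - s
        placed = False
        for cl in clusters:
            q0, s0 = cl[-1]
            if abs(d - (q0 - s0)) <= 2 * ref_len and abs(q - q0) <= 2 * ref_len:
                cl.append((q, s))
                placed = True
                break
        if not placed:
            clusters.append([(q, s)])
    windows = []
    for cl in clusters:
        qmin = min(q for q, _ in cl)
        qmax = max(q for q, _ in cl)
        smin = min(s for _, s in cl)
        smax = max(s for _, s in cl)
        lo = qmin - smin
        hi = qmax + (ref_len - smax)
        windows.append((lo, hi))
    return windows


def _frame_to_contig_coords(
    frame_label: str, nt_offset: int, contig_len: int, aa_start: int, aa_end: int
) -> tuple[int, int, str]:
    nt0 = nt_offset + 3 * aa_start
    nt1 = nt_offset + 3 * aa_end
    if frame_label.startswith("+"):
        return nt0, nt1, "+"
    return contig_len - nt1, contig_len - nt0, "-"


def builtin_search(
    contigs: dict[str, str],
    refs: Sequence[TransposaseRef],
    params: SearchParams | None = None,
) -> list[AlignmentHit]:
    """Six-frame translated local-alignment search of contigs against references.

    Each frame's peptide is aligned locally (BLOSUM62, affine gaps)
    against each reference; candidate (frame, reference) pairs are
    pre-selected by exact ``word_size``-mer seeding, and the alignment is
    run on a peptide window around the seeds.  Bitscores derive from the
    raw score via the Karlin–Altschul transform, E-values use the total
    reference database size (in aa) and the frame peptide length.  Only
    hits strictly below ``max_evalue`` (or at/above ``min_bitscore``) are
    returned.
    """
    if not contigs or not refs:
        raise ValueError("builtin_search requires nonempty contigs and references")
    params = params or SearchParams()
    aligner = _make_aligner(params)
    db_size = sum(r.aa_len for r in refs)
    ref_lens = [r.aa_len for r in refs]

    ref_index: dict[str, list[tuple[int, int]]] = {}
    if params.word_size is not None:
        k = params.word_size
        for idx, ref in enumerate(refs):
            for s in range(ref.aa_len - k + 1):
                ref_index.setdefault(ref.aa_seq[s : s + k], []).append((idx, s))

    hits: list[AlignmentHit] = []
    for contig_id in sorted(contigs):
        seq = contigs[contig_id].upper()
        if not seq:
            raise ValueError(f"contig {contig_id!r} is empty")
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"contig {contig_id!r} has non-ACGTN characters {bad}")
        for frame_label, off, pep in six_frame_translate(seq):
            if not pep:
                continue
            if params.word_size is None:
                candidates = {i: [(0, len(pep))] for i in range(len(refs))}
            else:
                seeds = _seed_clusters(pep, ref_index, params.word_size)
                candidates = {
                    idx: _cluster_by_diagonal(s, ref_lens[idx])
                    for idx, s in seeds.items()
                }
            for ref_idx, windows in sorted(candidates.items()):
                ref = refs[ref_idx]
                seen_spans: set[tuple[int, int]] = set()
                for lo, hi in windows:
                    lo = max(0, lo - params.window_pad)
                    hi = min(len(pep), hi + params.window_pad)
                    if hi - lo < 1:
                        continue
                    window = pep[lo:hi]
                    alns = aligner.align(window, ref.aa_seq)
                    if len(alns) == 0:
                        continue
                    aln = alns[0]
                    raw = aln.score
                    bits = bitscore_from_raw(raw, params)
                    ev = evalue_from_bitscore(bits, len(pep), db_size)
                    if params.max_evalue is not None and not (ev < params.max_evalue):
                        continue
                    if params.min_bitscore is not None and bits < params.min_bitscore:
                        continue
                    t_blocks, s_blocks = aln.aligned  # window space / ref space
                    qa0 = int(t_blocks[0][0]) + lo
                    qa1 = int(t_blocks[-1][1]) + lo
                    sa0 = int(s_blocks[0][0])
                    sa1 = int(s_blocks[-1][1])
                    if (qa0, qa1) in seen_spans:
                        continue
                    seen_spans.add((qa0, qa1))
                    ident = 0
                    aln_cols = 0
                    for (t0, t1), (s0, s1) in zip(t_blocks, s_blocks):
                        for i in range(t1 - t0):
                            aln_cols += 1
                            if window[t0 + i] == ref.aa_seq[s0 + i]:
                                ident += 1
                    gapopens = len(t_blocks) - 1
                    gap_cols = (qa1 - qa0 - aln_cols) + (sa1 - sa0 - aln_cols)
                    total_cols = aln_cols + gap_cols
                    q0, q1, strand = _frame_to_contig_coords(
                        frame_label, off, len(seq), qa0, qa1
                    )
                    hits.append(
                        AlignmentHit(
                            query_id=contig_id,
                            ref_id=ref.ref_id,
                            q_start=q0,
                            q_end=q1,
                            strand=strand,
                            s_start=sa0,
                            s_end=sa1,
                            bitscore=round(bits, 1),
                            evalue=ev,
                            pident=round(100.0 * ident / max(aln_cols, 1), 2),
                            aln_len=total_cols,
                            mismatch=aln_cols - ident,
                            gapopen=gapopens,
                        )
                    )
    hits.sort(key=lambda h: (h.query_id, h.q_start, h.q_end, h.ref_id, h.strand))
    return hits
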