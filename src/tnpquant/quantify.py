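"""Normalized transposase abundance statistics from calls and read maps.

All quantities derive from per-sample :class:`SampleProfile` counts:

* transposase fraction — transposase reads / total bacterial reads;
* per-taxon fraction — the same quotient restricted to one taxon's reads;
* per-genome count — transposase reads divided by the mean hit count of
  35 single-copy marker gene families (a genome-equivalent estimate);
* transcript:gene expression ratio — RNA-sample fraction over the
  matched DNA-sample fraction, aggregated across sample pairs by median;
* transposases per Mbp — a reference-genome normalization for strain
  tables;
* genome-size proxy — total reads over mean single-copy marker hits
  (arbitrary units, comparable across samples of a study).

A mapped read interval is attributed to transposases when at least half
of its length (configurable) overlaps the union of called segments on
its contig, strand-agnostically; its IS family is the family of the call
with the largest overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .footprints import TransposaseCall

__all__ = [
    "SampleProfile",
    "UndefinedValueError",
    "calls_to_frame",
    "assign_reads",
    "build_profiles",
    "fraction_of_bacterial_reads",
    "per_taxon_fraction",
    "per_genome_count",
    "expression_ratio",
    "transposases_per_mbp",
    "genome_size_proxy",
    "abundance_table",
]


class UndefinedValueError(ZeroDivisionError):
    """A normalization with an empty or all-zero denominator."""


@dataclass
class SampleProfile:
    """Per-sample counts from which all normalized statistics derive."""

    sample_id: str
    station: str
    depth_m: float
    fraction: str
    molecule: str
    total_bacterial_reads: int = 0
    transposase_reads: int = 0
    per_taxon_reads: dict[str, int] = field(default_factory=dict)
    per_taxon_transposase_reads: dict[str, int] = field(default_factory=dict)
    per_family_transposase_reads: dict[str, int] = field(default_factory=dict)
    single_copy_hits: dict[str, int] = field(default_factory=dict)
    per_taxon_marker_hits: dict[str, dict[str, int]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.transposase_reads > self.total_bacterial_reads:
            raise ValueError(
                f"{self.sample_id}: transposase reads exceed bacterial reads"
            )
        for t, c in self.per_taxon_transposase_reads.items():
            if c > self.per_taxon_reads.get(t, 0):
                raise ValueError(
                    f"{self.sample_id}: taxon {t} transposase reads exceed taxon reads"
                )
        for m in (self.per_taxon_reads, self.per_taxon_transposase_reads,
                  self.per_family_transposase_reads, self.single_copy_hits):
            if any(v < 0 for v in m.values()):
                raise ValueError(f"{self.sample_id}: negative count")


def calls_to_frame(calls: Sequence[TransposaseCall]) -> pd.DataFrame:
    """Tidy frame of transposase calls (one row per resolved segment)."""
    return pd.DataFrame(
        [
            {
                "contig_id": c.contig_id,
                "strand": c.strand,
                "start": c.start,
                "end": c.end,
                "ref_id": c.ref_id,
                "family": c.family,
                "phylum": c.lineage[0],
                "class": c.lineage[1],
                "order": c.lineage[2],
                "genus": c.lineage[3],
                "coverage": c.aa_coverage_fraction,
                "bitscore": c.bitscore,
                "evalue": c.evalue,
            }
            for c in calls
        ],
        columns=[
            "contig_id", "strand", "start", "end", "ref_id", "family",
            "phylum", "class", "order", "genus", "coverage", "bitscore", "evalue",
        ],
    )


def _overlap_with_segments(
    reads: pd.DataFrame, segments: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Per read: total overlap with the segment union, and best family.

    ``reads``/``segments`` are restricted to a single contig.  Segment
    union overlap uses merged intervals; family attribution uses the raw
    per-family overlaps with a (max overlap, lexicographic) tie-break.
    """
    r0 = reads["start"].to_numpy()
    r1 = reads["end"].to_numpy()
    n = len(reads)
    union_ov = np.zeros(n)
    fams = sorted(segments["family"].unique())
    fam_ov = np.zeros((n, len(fams)))
    # merged union intervals (strand-agnostic)
    ivs = sorted(zip(segments["start"], segments["end"]))
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for s, e in merged:
        union_ov += np.clip(np.minimum(r1, e) - np.maximum(r0, s), 0, None)
    for fi, fam in enumerate(fams):
        sub = segments[segments["family"] == fam]
        for s, e in zip(sub["start"], sub["end"]):
            fam_ov[:, fi] += np.clip(np.minimum(r1, e) - np.maximum(r0, s), 0, None)
    best = np.argmax(fam_ov, axis=1) if fams else np.zeros(n, dtype=int)
    best_family = np.array(fams)[best] if fams else np.array([""] * n)
    return union_ov, best_family


def assign_reads(
    read_map: pd.DataFrame,
    calls: pd.DataFrame,
    contig_lengths: Mapping[str, int] | None = None,
    min_read_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Label each read-map row as transposase-derived or not.

    Returns the read map with ``is_tnp`` and ``family`` columns.  A read
    counts as transposase when the overlap between its interval and the
    union of call segments on its contig is at least
    ``min_read_overlap_frac`` of its length (any positive overlap when
    the threshold is 0).
    """
    out = read_map.copy()
    if contig_lengths is not None:
        for row in out.itertuples():
            clen = contig_lengths.get(row.contig_id)
            if clen is not None and (row.start < 0 or row.end > clen):
                raise ValueError(
                    f"read interval [{row.start},{row.end}) outside contig "
                    f"{row.contig_id} (length {clen})"
                )
    out["is_tnp"] = False
    out["family"] = ""
    if calls.empty or out.empty:
        return out
    for contig_id, seg in calls.groupby("contig_id"):
        mask = out["contig_id"] == contig_id
        if not mask.any():
            continue
        reads = out.loc[mask]
        ov, fam = _overlap_with_segments(reads, seg)
        lengths = (reads["end"] - reads["start"]).to_numpy()
        if min_read_overlap_frac > 0:
            is_tnp = ov >= min_read_overlap_frac * lengths
        else:
            is_tnp = ov > 0
        out.loc[mask, "is_tnp"] = is_tnp
        out.loc[mask, "family"] = np.where(is_tnp, fam, "")
    return out


def _marker_hits(
    read_map: pd.DataFrame,
    markers: pd.DataFrame,
    min_read_overlap_frac: float = 0.5,
) -> pd.DataFrame:
    """Read counts per (sample, taxon, marker) under the same overlap rule."""
    rows = []
    for contig_id, mk in markers.groupby("contig_id"):
        reads = read_map[read_map["contig_id"] == contig_id]
        if reads.empty:
            continue
        r0 = reads["start"].to_numpy()
        r1 = reads["end"].to_numpy()
        lengths = r1 - r0
        for row in mk.itertuples():
            ov = np.clip(np.minimum(r1, row.end) - np.maximum(r0, row.start), 0, None)
            sel = ov >= min_read_overlap_frac * lengths
            if sel.any():
                counted = reads.loc[sel].groupby("sample_id")["read_count"].sum()
                for sid, cnt in counted.items():
                    rows.append({
                        "sample_id": sid, "taxon": row.taxon,
                        "marker": row.marker, "count": int(cnt),
                    })
    return pd.DataFrame(rows, columns=["sample_id", "taxon", "marker", "count"])


def build_profiles(
    read_map: pd.DataFrame,
    calls: pd.DataFrame,
    taxonomy: pd.DataFrame,
    samples: pd.DataFrame,
    markers: pd.DataFrame | None = None,
    n_markers: int = 35,
    min_read_overlap_frac: float = 0.5,
    taxon_rank: str = "genus",
) -> dict[str, SampleProfile]:
    """Aggregate a read map into per-sample profiles.

    ``taxon_rank`` selects the taxonomy column used for the per-taxon
    breakdown.  Reads on contigs without taxonomy are excluded from the
    bacterial-read denominator (they are unclassified).
    """
    tagged = assign_reads(read_map, calls,
                          min_read_overlap_frac=min_read_overlap_frac)
    tax = taxonomy.set_index("contig_id")[taxon_rank]
    tagged = tagged.join(tax.rename("taxon"), on="contig_id")
    tagged = tagged[tagged["taxon"].notna()]

    mk = None
    if markers is not None and not markers.empty:
        mk = _marker_hits(read_map, markers, min_read_overlap_frac)
        # translate marker taxon labels to the requested rank via taxonomy
        if taxon_rank != "taxon_label":
            label_map = {}
            for row in markers.itertuples():
                label_map[row.taxon] = None
            first_contig = markers.groupby("taxon")["contig_id"].first()
            rank_of = taxonomy.set_index("contig_id")[taxon_rank]
            label_map = {
                lbl: rank_of.get(cid, lbl) for lbl, cid in first_contig.items()
            }
            mk["taxon"] = mk["taxon"].map(label_map)

    profiles: dict[str, SampleProfile] = {}
    marker_labels = (
        sorted(markers["marker"].unique()) if markers is not None and not markers.empty
        else [f"M{i + 1:02d}" for i in range(n_markers)]
    )
    for row in samples.itertuples():
        sub = tagged[tagged["sample_id"] == row.sample_id]
        prof = SampleProfile(
            sample_id=row.sample_id,
            station=row.station,
            depth_m=float(row.depth_m),
            fraction=row.fraction,
            molecule=row.molecule,
        )
        prof.total_bacterial_reads = int(sub["read_count"].sum())
        tnp = sub[sub["is_tnp"]]
        prof.transposase_reads = int(tnp["read_count"].sum())
        prof.per_taxon_reads = (
            sub.groupby("taxon")["read_count"].sum().astype(int).to_dict()
        )
        prof.per_taxon_transposase_reads = (
            tnp.groupby("taxon")["read_count"].sum().astype(int).to_dict()
        )
        prof.per_family_transposase_reads = (
            tnp.groupby("family")["read_count"].sum().astype(int).to_dict()
        )
        prof.single_copy_hits = {m: 0 for m in marker_labels}
        if mk is not None and not mk.empty:
            smk = mk[mk["sample_id"] == row.sample_id]
            for m, cnt in smk.groupby("marker")["count"].sum().items():
                prof.single_copy_hits[m] = int(cnt)
            for t, g in smk.groupby("taxon"):
                d = {m: 0 for m in marker_labels}
                for m, cnt in g.groupby("marker")["count"].sum().items():
                    d[m] = int(cnt)
                prof.per_taxon_marker_hits[t] = d
        prof.validate()
        profiles[row.sample_id] = prof
    return profiles


# ---------------------------------------------------------------------------
# normalized metrics


def fraction_of_bacterial_reads(profile: SampleProfile) -> float:
    """Transposase reads as a quotient of all bacterial reads in the sample."""
    if profile.total_bacterial_reads <= 0:
        raise UndefinedValueError(
            f"{profile.sample_id}: no bacterial reads to normalize by"
        )
    return profile.transposase_reads / profile.total_bacterial_reads


def per_taxon_fraction(profile: SampleProfile, taxon: str) -> float:
    """Transposase reads of one taxon over that taxon's total reads."""
    denom = profile.per_taxon_reads.get(taxon, 0)
    if denom <= 0:
        raise UndefinedValueError(
            f"{profile.sample_id}: taxon {taxon!r} has no reads"
        )
    return profile.per_taxon_transposase_reads.get(taxon, 0) / denom


def per_genome_count(profile: SampleProfile, scope: str = "all") -> float:
    """Transposase reads per genome equivalent.

    Divides the scope's transposase read count by the mean hit count
    over the single-copy marker families (zero-hit markers included in
    the mean, which keeps the fixed marker denominator).  ``scope`` is
    ``"all"`` or a taxon label.
    """
    if scope == "all":
        hits = profile.single_copy_hits
        tnp = profile.transposase_reads
    else:
        hits = profile.per_taxon_marker_hits.get(scope, {})
        tnp = profile.per_taxon_transposase_reads.get(scope, 0)
    if not hits or all(v == 0 for v in hits.values()):
        raise UndefinedValueError(
            f"{profile.sample_id}: all single-copy markers have zero hits "
            f"in scope {scope!r}"
        )
    mean_hits = sum(hits.values()) / len(hits)
    return tnp / mean_hits


def _scope_fraction(profile: SampleProfile, scope: tuple[str, str]) -> float:
    kind, label = scope
    if kind == "all":
        return fraction_of_bacterial_reads(profile)
    if kind == "taxon":
        return per_taxon_fraction(profile, label)
    if kind == "family":
        if profile.total_bacterial_reads <= 0:
            raise UndefinedValueError(f"{profile.sample_id}: no bacterial reads")
        return (
            profile.per_family_transposase_reads.get(label, 0)
            / profile.total_bacterial_reads
        )
    raise ValueError(f"unknown scope kind {kind!r}")


def expression_ratio(
    dna_profiles: Iterable[SampleProfile],
    rna_profiles: Iterable[SampleProfile],
    scope: tuple[str, str] = ("all", ""),
) -> float:
    """Median transcript:gene ratio over matched DNA/RNA sample pairs.

    Samples pair on (station, depth, size fraction).  For each pair the
    ratio is the scope's transposase fraction in the RNA sample over the
    same fraction in the DNA sample; pairs with a zero DNA-side fraction
    are excluded (undefined ratio).
    """
    dna = {(p.station, p.depth_m, p.fraction): p for p in dna_profiles}
    rna = {(p.station, p.depth_m, p.fraction): p for p in rna_profiles}
    ratios = []
    for key in sorted(set(dna) & set(rna), key=str):
        try:
            d = _scope_fraction(dna[key], scope)
            r = _scope_fraction(rna[key], scope)
        except UndefinedValueError:
            continue
        if d <= 0:
            continue
        ratios.append(r / d)
    if not ratios:
        raise UndefinedValueError(
            f"no matched DNA/RNA pair with nonzero DNA fraction for scope {scope}"
        )
    return float(np.median(ratios))


def transposases_per_mbp(tnp_count: int, genome_size_mbp: float) -> float:
    """Transposase genes per Mbp of genome, reported to one decimal."""
    if genome_size_mbp <= 0:
        raise ValueError("genome size must be positive")
    if tnp_count < 0:
        raise ValueError("transposase count must be nonnegative")
    return round(tnp_count / genome_size_mbp, 1)


def genome_size_proxy(profile: SampleProfile, scope: str = "all") -> float:
    """Relative genome-size proxy: total reads over mean single-copy hits."""
    if scope == "all":
        hits = profile.single_copy_hits
        total = profile.total_bacterial_reads
    else:
        hits = profile.per_taxon_marker_hits.get(scope, {})
        total = profile.per_taxon_reads.get(scope, 0)
    if not hits or all(v == 0 for v in hits.values()):
        raise UndefinedValueError(
            f"{profile.sample_id}: zero marker mean in scope {scope!r}"
        )
    mean_hits = sum(hits.values()) / len(hits)
    return total / mean_hits


def abundance_table(profiles: Mapping[str, SampleProfile]) -> pd.DataFrame:
    """Tidy long-format abundance records for all samples and scopes."""
    rows = []
    for sid in sorted(profiles):
        p = profiles[sid]
        meta = {
            "sample_id": sid, "station": p.station, "depth_m": p.depth_m,
            "fraction": p.fraction, "molecule": p.molecule,
        }
        if p.total_bacterial_reads > 0:
            rows.append({**meta, "scope": "all-bacteria", "scope_label": "",
                         "metric": "fraction_of_bacterial_reads",
                         "value": fraction_of_bacterial_reads(p)})
        for t in sorted(p.per_taxon_reads):
            if p.per_taxon_reads[t] > 0:
                rows.append({**meta, "scope": "taxon", "scope_label": t,
                             "metric": "fraction_of_scope_reads",
                             "value": per_taxon_fraction(p, t)})
        for f in sorted(p.per_family_transposase_reads):
            rows.append({**meta, "scope": "family", "scope_label": f,
                         "metric": "fraction_of_bacterial_reads",
                         "value": _scope_fraction(p, ("family", f))})
        try:
            rows.append({**meta, "scope": "all-bacteria", "scope_label": "",
                         "metric": "per_genome_count",
                         "value": per_genome_count(p, "all")})
            rows.append({**meta, "scope": "all-bacteria", "scope_label": "",
                         "metric": "genome_size_proxy",
                         "value": genome_size_proxy(p, "all")})
        except UndefinedValueError:
            pass
        for t in sorted(p.per_taxon_marker_hits):
            try:
                rows.append({**meta, "scope": "taxon", "scope_label": t,
                             "metric": "per_genome_count",
                             "value": per_genome_count(p, t)})
            except UndefinedValueError:
                pass
    return pd.DataFrame(rows, columns=[
        "sample_id", "station", "depth_m", "fraction", "molecule",
        "scope", "scope_label", "metric", "value",
    ])
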