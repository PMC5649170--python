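"""Synthetic size-fractionated community generator with known ground truth.

The generator emulates the sampling design of a brackish-to-marine
transect study: several stations sampled at one or more depths, serially
filtered into three cell-size fractions (small 0.1–0.8, medium 0.8–3.0,
large 3.0–200 µm), each yielding a DNA (metagenome) and an RNA
(metatranscriptome) sample.  A taxon-structured contig pool carries

* planted transposase ORFs — exact reverse-translated copies of entries
  from a generated ISfinder-like reference protein database, on either
  strand, at configurable per-sample read fractions (the study regime is
  roughly 0.1–2% of bacterial reads);
* single-copy marker genes — 35 labelled intervals, exactly one per
  marker per simulated genome, standing in for single-copy orthologous
  gene families;
* i.i.d. uniform ACGT background, which keeps spurious translated-search
  hits negligible at desk scale.

Read "sequencing" is interval-based: each sample is a table of mapped
read intervals (contig, start, end, count) rather than base calls,
because the downstream analysis consumes counts only.  RNA samples scale
the read intensity of planted transposase regions by configurable
per-(family, taxon) expression multipliers, so transcript:gene ratios
have a known truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .hits import TransposaseRef

__all__ = [
    "Taxon",
    "SimConfig",
    "GroundTruth",
    "Community",
    "IS_FAMILY_NAMES",
    "generate_reference_db",
    "generate_community",
    "reverse_translate",
    "write_reference_fasta",
    "evaluate_calls",
]


class ConfigurationError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


# Canonical prokaryotic IS family names (ISfinder nomenclature); the pool
# is larger than 30 so that a 30-family database draws real names only.
IS_FAMILY_NAMES = [
    "IS3", "IS5", "IS200/IS605", "IS256", "IS66", "IS1", "IS4", "IS6",
    "IS21", "IS30", "IS91", "IS110", "IS481", "IS630", "IS701", "IS982",
    "IS1182", "IS1380", "IS1595", "IS1634", "ISAs1", "ISAzo13", "ISH3",
    "ISKra4", "ISL3", "ISLre2", "ISNCY", "IS607", "IS1202", "IS1247",
    "IS1town", "ISH6",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Fixed reverse-translation table (standard code, one codon per residue)
# so a planted protein is recoverable exactly by the built-in search.
PREFERRED_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC",
    "G": "GGT", "H": "CAT", "I": "ATC", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACC", "V": "GTT", "W": "TGG", "Y": "TAC",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_translate(aa_seq: str) -> str:
    """Deterministic nucleotide sequence coding for ``aa_seq``."""
    return "".join(PREFERRED_CODON[a] for a in aa_seq)


@dataclass(frozen=True)
class Taxon:
    label: str
    phylum: str
    klass: str
    order: str
    genus: str
    weight: float

    @property
    def lineage(self) -> tuple[str, str, str, str]:
        return (self.phylum, self.klass, self.order, self.genus)


def _default_taxa() -> list[Taxon]:
    return [
        Taxon("Synechococcus_BS", "Cyanobacteria", "Cyanophyceae",
              "Chroococcales", "Synechococcus", 0.20),
        Taxon("Pelagibacter_BS", "Proteobacteria", "Alphaproteobacteria",
              "Pelagibacterales", "Pelagibacter", 0.30),
        Taxon("Flavobacterium_BS", "Bacteroidetes", "Flavobacteriia",
              "Flavobacteriales", "Flavobacterium", 0.20),
        Taxon("Ilumatobacter_BS", "Actinobacteria", "Acidimicrobiia",
              "Acidimicrobiales", "Ilumatobacter", 0.15),
        Taxon("Rubritalea_BS", "Verrucomicrobia", "Verrucomicrobiae",
              "Verrucomicrobiales", "Rubritalea", 0.10),
        Taxon("Alteromonas_BS", "Proteobacteria", "Gammaproteobacteria",
              "Alteromonadales", "Alteromonas", 0.05),
    ]


def _default_expression_multiplier() -> dict[tuple[str, str], float]:
    # transcript:gene ratios by phylum observed in brackish communities:
    # strong cyanobacterial over-expression, mild in Verrucomicrobia,
    # under-expression in Actinobacteria
    return {
        ("*", "Synechococcus_BS"): 2.3,
        ("*", "Rubritalea_BS"): 1.2,
        ("*", "Ilumatobacter_BS"): 0.24,
    }


@dataclass
class SimConfig:
    """Full parameterization of a synthetic study; defaults are the study design."""

    seed: int = 0
    stations: list[str] = field(default_factory=lambda: [
        "GS665", "GS670", "GS675", "GS679", "GS684", "GS694", "GS695",
    ])
    marine_stations: list[str] = field(default_factory=lambda: ["GS694", "GS695"])
    depths: list[float] = field(default_factory=lambda: [5.0])
    fractions: list[str] = field(default_factory=lambda: ["small", "medium", "large"])
    molecules: list[str] = field(default_factory=lambda: ["DNA", "RNA"])
    taxa: list[Taxon] = field(default_factory=_default_taxa)
    n_contigs_per_taxon: int | dict[str, int] = 6
    contig_length_range: tuple[int, int] = (10000, 16000)
    n_ref_families: int = 6
    refs_per_family: int = 3
    ref_aa_length_range: tuple[int, int] = (280, 380)
    within_family_divergence: float = 0.15
    tnp_copies_per_taxon: dict[str, int] | int = 3
    # per-sample planted transposase read fraction; None -> built from the
    # brackish/marine × size-fraction design below
    planted_tnp_read_fraction: dict[str, float] | None = None
    brackish_base_fraction: float = 0.007
    marine_base_fraction: float = 0.002
    fraction_multipliers: dict[str, float] = field(
        default_factory=lambda: {"small": 0.5, "medium": 1.0, "large": 1.6}
    )
    # RNA read-intensity multipliers keyed (family, taxon); "*" wildcards
    expression_multiplier: dict[tuple[str, str], float] = field(
        default_factory=_default_expression_multiplier
    )
    # multiplier on a taxon's transposase read mass in samples of a given
    # size fraction, keyed (taxon, fraction); default 1
    tnp_sample_weight: dict[tuple[str, str], float] = field(default_factory=dict)
    reads_per_sample: int = 10000
    read_length: int = 100
    n_single_copy_markers: int = 35
    marker_length: int = 990
    min_feature_gap: int = 150
    read_mode: str = "planted_fraction"  # or "uniform"

    def __post_init__(self) -> None:
        if abs(sum(t.weight for t in self.taxa) - 1.0) > 1e-9:
            raise ConfigurationError("taxon weights must sum to 1")
        for name in ("contig_length_range", "ref_aa_length_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ConfigurationError(f"{name} must be a nonempty positive range")
        if self.n_ref_families < 1 or self.refs_per_family < 1:
            raise ConfigurationError("need at least one family and one ref per family")
        if self.planted_tnp_read_fraction is not None:
            for s, p in self.planted_tnp_read_fraction.items():
                if not (0.0 <= p <= 1.0):
                    raise ConfigurationError(f"planted fraction for {s} outside [0,1]")
        if self.read_mode not in ("planted_fraction", "uniform"):
            raise ConfigurationError(f"unknown read_mode {self.read_mode!r}")
        n_min = (self.n_contigs_per_taxon
                 if isinstance(self.n_contigs_per_taxon, int)
                 else min(self.n_contigs_per_taxon.values(), default=0))
        if self.reads_per_sample < 1 or n_min < 1:
            raise ConfigurationError("reads_per_sample and n_contigs_per_taxon must be positive")

    # -- sample bookkeeping ------------------------------------------------

    def sample_sheet(self) -> pd.DataFrame:
        rows = []
        for station in self.stations:
            for depth in self.depths:
                for fraction in self.fractions:
                    for mol in self.molecules:
                        rows.append({
                            "sample_id": f"{station}_d{depth:g}_{fraction}_{mol}",
                            "station": station,
                            "depth_m": depth,
                            "fraction": fraction,
                            "molecule": mol,
                        })
        return pd.DataFrame(rows)

    def planted_fraction_for(self, station: str, fraction: str, sample_id: str) -> float:
        if self.planted_tnp_read_fraction is not None:
            return self.planted_tnp_read_fraction.get(sample_id, 0.0)
        base = (self.marine_base_fraction if station in self.marine_stations
                else self.brackish_base_fraction)
        return base * self.fraction_multipliers.get(fraction, 1.0)

    def copies_for(self, taxon_label: str) -> int:
        if isinstance(self.tnp_copies_per_taxon, int):
            return self.tnp_copies_per_taxon
        return self.tnp_copies_per_taxon.get(taxon_label, 0)

    def contigs_for(self, taxon_label: str) -> int:
        if isinstance(self.n_contigs_per_taxon, int):
            return self.n_contigs_per_taxon
        return self.n_contigs_per_taxon[taxon_label]

    def multiplier_for(self, family: str, taxon_label: str) -> float:
        em = self.expression_multiplier
        for key in ((family, taxon_label), ("*", taxon_label), (family, "*")):
            if key in em:
                return em[key]
        return 1.0

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taxa"] = [dataclasses.asdict(t) for t in self.taxa]
        d["expression_multiplier"] = [
            {"family": k[0], "taxon": k[1], "multiplier": v}
            for k, v in self.expression_multiplier.items()
        ]
        d["tnp_sample_weight"] = [
            {"taxon": k[0], "fraction": k[1], "weight": v}
            for k, v in self.tnp_sample_weight.items()
        ]
        d["contig_length_range"] = list(self.contig_length_range)
        d["ref_aa_length_range"] = list(self.ref_aa_length_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "taxa" in d:
            d["taxa"] = [Taxon(**t) if not isinstance(t, Taxon) else t
                         for t in d["taxa"]]
        if "expression_multiplier" in d and isinstance(d["expression_multiplier"], list):
            d["expression_multiplier"] = {
                (e["family"], e["taxon"]): float(e["multiplier"])
                for e in d["expression_multiplier"]
            }
        if "tnp_sample_weight" in d and isinstance(d["tnp_sample_weight"], list):
            d["tnp_sample_weight"] = {
                (e["taxon"], e["fraction"]): float(e["weight"])
                for e in d["tnp_sample_weight"]
            }
        for name in ("contig_length_range", "ref_aa_length_range"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What was planted and what was sampled, for validating the pipeline."""

    planted: pd.DataFrame      # contig_id start end strand ref_id family taxon
    markers: pd.DataFrame      # contig_id start end marker taxon
    sample_counts: pd.DataFrame  # sample_id true_tnp_reads true_bacterial_reads
    category_counts: pd.DataFrame  # sample_id taxon family tnp_reads


@dataclass
class Community:
    config: SimConfig
    contigs: dict[str, str]
    taxonomy: pd.DataFrame     # contig_id phylum class order genus
    samples: pd.DataFrame
    read_map: pd.DataFrame     # contig_id start end sample_id read_count
    truth: GroundTruth

    def taxonomy_map(self) -> dict[str, tuple[str, str, str, str]]:
        return {
            r.contig_id: (r.phylum, r["class"], r.order, r.genus)
            for _, r in self.taxonomy.iterrows()
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["contigs"] = outdir / "contigs.fasta"
        with open(paths["contigs"], "w") as fh:
            for cid in sorted(self.contigs):
                fh.write(f">{cid}\n")
                seq = self.contigs[cid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        for name, df in [
            ("taxonomy", self.taxonomy),
            ("samples", self.samples),
            ("read_map", self.read_map),
            ("truth_planted", self.truth.planted),
            ("truth_markers", self.truth.markers),
            ("truth_sample_counts", self.truth.sample_counts),
            ("truth_category_counts", self.truth.category_counts),
        ]:
            paths[name] = outdir / f"{name}.tsv"
            df.to_csv(paths[name], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# reference database


def generate_reference_db(config: SimConfig) -> tuple[list[TransposaseRef], pd.DataFrame]:
    """Generate an ISfinder-like curated transposase protein database.

    ``n_ref_families`` families are drawn from the canonical IS family
    name pool; each family holds ``refs_per_family`` proteins derived
    from a common ancestor by point substitution at
    ``within_family_divergence``, so that family members cross-match in a
    translated search the way real IS family entries do.
    """
    rng = np.random.default_rng([config.seed, 11])
    lo, hi = config.ref_aa_length_range
    names = list(IS_FAMILY_NAMES)
    if config.n_ref_families > len(names):
        names += [f"ISX{i}" for i in range(config.n_ref_families - len(names))]
    families = names[: config.n_ref_families]
    refs: list[TransposaseRef] = []
    rows = []
    for family in families:
        length = int(rng.integers(lo, hi + 1))
        ancestor = "M" + "".join(
            rng.choice(list(AMINO_ACIDS), size=length - 1)
        )
        fam_id = family.replace("/", "-")
        for j in range(config.refs_per_family):
            seq = list(ancestor)
            if j > 0:
                for pos in range(1, length):
                    if rng.random() < config.within_family_divergence:
                        choices = [a for a in AMINO_ACIDS if a != seq[pos]]
                        seq[pos] = choices[int(rng.integers(len(choices)))]
            ref_id = f"{fam_id}_r{j + 1}"
            refs.append(TransposaseRef(ref_id=ref_id, family=family,
                                       aa_seq="".join(seq)))
            rows.append({"ref_id": ref_id, "family": family, "aa_len": length})
    return refs, pd.DataFrame(rows)


def write_reference_fasta(refs: Sequence[TransposaseRef], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in refs:
            fh.write(f">{r.ref_id} family={r.family}\n")
            for i in range(0, len(r.aa_seq), 80):
                fh.write(r.aa_seq[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# community


def _random_dna(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


_BASES = np.array(list("ACGT"))


def _layout_taxon_contigs(
    config: SimConfig,
    rng: np.random.Generator,
    taxon: Taxon,
    planted_specs: list[tuple[TransposaseRef, str]],
) -> tuple[dict[str, str], list[dict], list[dict]]:
    """Build one taxon's contigs with placed markers and transposase ORFs."""
    n = config.contigs_for(taxon.label)
    lengths = rng.integers(config.contig_length_range[0],
                           config.contig_length_range[1] + 1, size=n)
    # features: (kind, label/ref, length_nt, payload)
    feats: list[tuple[str, object, int]] = []
    for m in range(config.n_single_copy_markers):
        feats.append(("marker", f"M{m + 1:02d}", config.marker_length))
    for ref, strand in planted_specs:
        feats.append(("tnp", (ref, strand), 3 * ref.aa_len))
    order = rng.permutation(len(feats))
    per_contig: list[list[tuple[str, object, int]]] = [[] for _ in range(n)]
    for pos, fi in enumerate(order):
        per_contig[pos % n].append(feats[fi])

    contigs: dict[str, str] = {}
    planted_rows: list[dict] = []
    marker_rows: list[dict] = []
    gap = config.min_feature_gap
    for ci in range(n):
        cid = f"{taxon.label}_c{ci + 1:02d}"
        clen = int(lengths[ci])
        cfeats = per_contig[ci]
        total = sum(f[2] for f in cfeats)
        slack = clen - total - gap * (len(cfeats) + 1)
        if slack < 0:
            raise GenerationError(
                f"contig {cid} (length {clen}) too short to host its "
                f"{len(cfeats)} features ({total} nt plus gaps)"
            )
        extra = rng.multinomial(slack, np.full(len(cfeats) + 1, 1.0 / (len(cfeats) + 1))) \
            if cfeats else np.array([slack])
        seq = _BASES[_random_dna(rng, clen)].copy()
        cursor = 0
        for k, feat in enumerate(cfeats):
            cursor += gap + int(extra[k])
            kind, payload, flen = feat
            if kind == "marker":
                marker_rows.append({
                    "contig_id": cid, "start": cursor, "end": cursor + flen,
                    "marker": payload, "taxon": taxon.label,
                })
            else:
                ref, strand = payload
                nt = reverse_translate(ref.aa_seq)
                if strand == "-":
                    nt = nt.translate(_COMPLEMENT)[::-1]
                seq[cursor : cursor + flen] = list(nt)
                planted_rows.append({
                    "contig_id": cid, "start": cursor, "end": cursor + flen,
                    "strand": strand, "ref_id": ref.ref_id,
                    "family": ref.family, "taxon": taxon.label,
                })
            cursor += flen
        contigs[cid] = "".join(seq)
    return contigs, planted_rows, marker_rows


def _sample_background_reads(
    rng: np.random.Generator,
    n_reads: int,
    contig_ids: list[str],
    contig_lens: np.ndarray,
    planted_by_contig: dict[str, np.ndarray],
    read_len: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform background read starts avoiding ≥50% overlap with planted ORFs."""
    if n_reads == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    probs = contig_lens / contig_lens.sum()
    cidx = rng.choice(len(contig_ids), size=n_reads, p=probs)
    starts = np.empty(n_reads, dtype=int)
    for i, ci in enumerate(cidx):
        clen = int(contig_lens[ci])
        ivs = planted_by_contig.get(contig_ids[ci])
        for _ in range(200):
            s = int(rng.integers(0, max(clen - read_len, 0) + 1))
            if ivs is None or ivs.size == 0:
                break
            ov = np.minimum(ivs[:, 1], s + read_len) - np.maximum(ivs[:, 0], s)
            if ov.max(initial=0) < 0.5 * read_len:
                break
        starts[i] = s
    return cidx, starts


def generate_community(
    config: SimConfig, refs: Sequence[TransposaseRef]
) -> Community:
    """Generate contigs, taxonomy, sample sheet, read map and ground truth.

    In ``planted_fraction`` mode (default) the number of transposase
    reads per sample is drawn so the realized transposase read fraction
    matches the configured per-sample fraction up to multinomial error;
    transposase reads are allocated across planted copies in proportion
    to host-taxon weight and copy length (times the RNA expression
    multiplier for RNA samples), background reads across taxa in
    proportion to taxon weight.  In ``uniform`` mode reads fall uniformly
    along each taxon's genome (transposase regions weighted by the RNA
    multiplier), so copy-number and genome-size proxies have known truth.
    """
    rng = np.random.default_rng([config.seed, 23])

    # plant copies per taxon
    contigs: dict[str, str] = {}
    planted_rows: list[dict] = []
    marker_rows: list[dict] = []
    for taxon in config.taxa:
        k = config.copies_for(taxon.label)
        specs = []
        for _ in range(k):
            ref = refs[int(rng.integers(len(refs)))]
            strand = "+" if rng.random() < 0.5 else "-"
            specs.append((ref, strand))
        t_contigs, t_planted, t_markers = _layout_taxon_contigs(
            config, rng, taxon, specs
        )
        contigs.update(t_contigs)
        planted_rows.extend(t_planted)
        marker_rows.extend(t_markers)

    planted = pd.DataFrame(
        planted_rows,
        columns=["contig_id", "start", "end", "strand", "ref_id", "family", "taxon"],
    )
    markers = pd.DataFrame(
        marker_rows, columns=["contig_id", "start", "end", "marker", "taxon"]
    )
    taxonomy = pd.DataFrame(
        [
            {
                "contig_id": cid,
                "phylum": t.phylum,
                "class": t.klass,
                "order": t.order,
                "genus": t.genus,
            }
            for t in config.taxa
            for cid in sorted(c for c in contigs if c.startswith(t.label + "_"))
        ]
    )

    samples = config.sample_sheet()
    rl = config.read_length
    by_taxon_contigs: dict[str, tuple[list[str], np.ndarray]] = {}
    for t in config.taxa:
        ids = sorted(c for c in contigs if c.startswith(t.label + "_"))
        by_taxon_contigs[t.label] = (ids, np.array([len(contigs[c]) for c in ids]))
    planted_by_contig = {
        cid: g[["start", "end"]].to_numpy()
        for cid, g in planted.groupby("contig_id")
    }

    map_rows: list[tuple[str, int, int, str, int]] = []
    count_rows = []
    cat_rows = []
    for si, srow in samples.iterrows():
        sample_rng = np.random.default_rng([config.seed, 37, int(si)])
        sid = srow.sample_id
        n_reads = config.reads_per_sample
        is_rna = srow.molecule == "RNA"
        p = config.planted_fraction_for(srow.station, srow.fraction, sid)

        if config.read_mode == "planted_fraction":
            reads = _reads_planted_fraction(
                config, sample_rng, srow, p, is_rna, planted,
                by_taxon_contigs, planted_by_contig, rl,
            )
        else:
            reads = _reads_uniform(
                config, sample_rng, srow, is_rna, planted,
                by_taxon_contigs, planted_by_contig, rl,
            )
        tnp_total = 0
        for (cid, start, is_tnp, taxon_label, family) in reads:
            map_rows.append((cid, int(start), int(start) + rl, sid, 1))
            tnp_total += int(is_tnp)
        count_rows.append({
            "sample_id": sid,
            "true_tnp_reads": tnp_total,
            "true_bacterial_reads": len(reads),
        })
        cat = {}
        for (_, _, is_tnp, taxon_label, family) in reads:
            if is_tnp:
                cat[(taxon_label, family)] = cat.get((taxon_label, family), 0) + 1
        for (taxon_label, family), cnt in sorted(cat.items()):
            cat_rows.append({
                "sample_id": sid, "taxon": taxon_label,
                "family": family, "tnp_reads": cnt,
            })

    read_map = (
        pd.DataFrame(
            map_rows, columns=["contig_id", "start", "end", "sample_id", "read_count"]
        )
        .groupby(["contig_id", "start", "end", "sample_id"], as_index=False)["read_count"]
        .sum()
        .sort_values(["sample_id", "contig_id", "start", "end"])
        .reset_index(drop=True)
    )
    truth = GroundTruth(
        planted=planted,
        markers=markers,
        sample_counts=pd.DataFrame(count_rows),
        category_counts=pd.DataFrame(
            cat_rows, columns=["sample_id", "taxon", "family", "tnp_reads"]
        ),
    )
    return Community(
        config=config, contigs=contigs, taxonomy=taxonomy,
        samples=samples, read_map=read_map, truth=truth,
    )


def _reads_planted_fraction(
    config, rng, srow, p, is_rna, planted, by_taxon_contigs, planted_by_contig, rl
):
    """Draw reads so the transposase fraction matches the planted fraction."""
    taxa = config.taxa
    # transposase read-mass allocation over planted copies
    copies = []
    base_alloc = []
    weights = {t.label: t.weight for t in taxa}
    for row in planted.itertuples():
        w = weights[row.taxon]
        w *= config.tnp_sample_weight.get((row.taxon, srow.fraction), 1.0)
        copies.append(row)
        base_alloc.append(w * (row.end - row.start))
    base_alloc = np.array(base_alloc, dtype=float)
    masses = [t.weight for t in taxa]  # background mass per taxon
    if p > 0 and base_alloc.sum() > 0:
        alloc = base_alloc / base_alloc.sum()
        mult = np.array([
            config.multiplier_for(c.family, c.taxon) if is_rna else 1.0
            for c in copies
        ])
        tnp_mass = (p / (1.0 - p)) * alloc * mult
    else:
        tnp_mass = np.zeros(len(copies))
    probs = np.array(masses + list(tnp_mass))
    probs = probs / probs.sum()
    counts = rng.multinomial(config.reads_per_sample, probs)

    reads = []
    label_of = {t.label: t for t in taxa}
    for ti, t in enumerate(taxa):
        ids, lens = by_taxon_contigs[t.label]
        cidx, starts = _sample_background_reads(
            rng, int(counts[ti]), ids, lens, planted_by_contig, rl
        )
        for ci, s in zip(cidx, starts):
            reads.append((ids[int(ci)], int(s), False, t.label, ""))
    for k, row in enumerate(copies):
        c = int(counts[len(taxa) + k])
        if c == 0:
            continue
        span = row.end - row.start - rl
        if span < 0:
            raise GenerationError(
                f"planted ORF on {row.contig_id} shorter than the read length"
            )
        starts = rng.integers(row.start, row.start + span + 1, size=c)
        for s in starts:
            reads.append((row.contig_id, int(s), True, row.taxon, row.family))
    return reads


def _reads_uniform(
    config, rng, srow, is_rna, planted, by_taxon_contigs, planted_by_contig, rl
):
    """Uniform-depth reads along each taxon genome; RNA scales planted regions."""
    taxa = config.taxa
    probs = np.array([t.weight for t in taxa])
    probs = probs / probs.sum()
    counts = rng.multinomial(config.reads_per_sample, probs)
    reads = []
    for ti, t in enumerate(taxa):
        ids, lens = by_taxon_contigs[t.label]
        n_t = int(counts[ti])
        if n_t == 0:
            continue
        # piecewise start-position weights: per contig the non-planted span
        # at weight 1, each planted copy at its expression multiplier
        seg_contig = []
        seg_iv = []
        seg_w = []
        seg_tnp = []
        for cid, clen in zip(ids, lens):
            ivs = planted.loc[planted.contig_id == cid]
            prev = 0
            for row in ivs.sort_values("start").itertuples():
                if row.start > prev:
                    seg_contig.append(cid); seg_iv.append((prev, row.start))
                    seg_w.append(row.start - prev); seg_tnp.append(None)
                m = config.multiplier_for(row.family, row.taxon) if is_rna else 1.0
                seg_contig.append(cid); seg_iv.append((row.start, row.end))
                seg_w.append((row.end - row.start) * m); seg_tnp.append(row)
                prev = row.end
            if prev < clen:
                seg_contig.append(cid); seg_iv.append((prev, int(clen)))
                seg_w.append(int(clen) - prev); seg_tnp.append(None)
        w = np.array(seg_w, dtype=float)
        len_map = dict(zip(ids, (int(x) for x in lens)))
        seg_idx = rng.choice(len(w), size=n_t, p=w / w.sum())
        for gi in seg_idx:
            lo, hi = seg_iv[int(gi)]
            cid = seg_contig[int(gi)]
            clen = len_map[cid]
            s = int(rng.integers(lo, hi))
            s = min(s, clen - rl)
            # truth by the ≥50%-overlap rule against planted intervals
            ivs = planted_by_contig.get(cid)
            is_tnp = False
            family = ""
            taxon_label = t.label
            if ivs is not None and ivs.size:
                ov = np.minimum(ivs[:, 1], s + rl) - np.maximum(ivs[:, 0], s)
                j = int(np.argmax(ov))
                if ov[j] >= 0.5 * rl:
                    is_tnp = True
                    sub = planted.loc[planted.contig_id == cid].iloc[j]
                    family = sub.family
            reads.append((cid, s, is_tnp, taxon_label, family))
    return reads


# ---------------------------------------------------------------------------
# evaluation against ground truth


def evaluate_calls(
    calls_df: pd.DataFrame, planted: pd.DataFrame, min_jaccard: float = 0.8
) -> dict[str, float]:
    """Interval-level precision/recall of transposase calls vs planted truth.

    A call matches a planted interval when they share a contig and their
    Jaccard overlap is at least ``min_jaccard``; matching is greedy by
    decreasing overlap, one call per planted interval.
    """
    calls = calls_df.reset_index(drop=True)
    truth = planted.reset_index(drop=True)
    matched_calls: set[int] = set()
    matched_truth: set[int] = set()
    pairs = []
    for ti, trow in truth.iterrows():
        sel = calls[calls.contig_id == trow.contig_id]
        for ci, crow in sel.iterrows():
            inter = min(crow.end, trow.end) - max(crow.start, trow.start)
            if inter <= 0:
                continue
            union = max(crow.end, trow.end) - min(crow.start, trow.start)
            j = inter / union
            if j >= min_jaccard:
                pairs.append((j, ci, ti))
    for j, ci, ti in sorted(pairs, reverse=True):
        if ci in matched_calls or ti in matched_truth:
            continue
        matched_calls.add(ci)
        matched_truth.add(ti)
    precision = len(matched_calls) / len(calls) if len(calls) else 0.0
    recall = len(matched_truth) / len(truth) if len(truth) else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "n_calls": float(len(calls)),
        "n_planted": float(len(truth)),
    }
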