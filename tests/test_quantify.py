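"""Read attribution and the normalized abundance metrics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from tnpquant.quantify import (SampleProfile, UndefinedValueError, assign_reads,
                               build_profiles, expression_ratio,
                               fraction_of_bacterial_reads, genome_size_proxy,
                               per_genome_count, per_taxon_fraction,
                               transposases_per_mbp)
from tnpquant.simulate import generate_community
from tests.conftest import small_sim_config


def _profile(**kw):
    base = dict(sample_id="s1", station="GS665", depth_m=5.0,
                fraction="medium", molecule="DNA")
    base.update(kw)
    return SampleProfile(**base)


def _calls_df(rows):
    return pd.DataFrame(rows, columns=["contig_id", "start", "end", "family"])


def _read_map(rows):
    return pd.DataFrame(
        rows, columns=["contig_id", "start", "end", "sample_id", "read_count"]
    )


class TestAssignReads:
    CALLS = _calls_df([("c1", 1000, 2000, "IS3")])

    def test_read_inside_call_counted(self):
        rm = _read_map([("c1", 1200, 1300, "s1", 1)])
        out = assign_reads(rm, self.CALLS)
        assert out["is_tnp"].tolist() == [True]
        assert out["family"].tolist() == ["IS3"]

    def test_ten_percent_overlap_not_counted_at_default(self):
        rm = _read_map([("c1", 990, 1090, "s1", 1)])  # 90/100 inside? no: 90 nt
        # interval [990,1090) overlaps [1000,2000) by 90 nt = 90% -> counted;
        # use [910,1010): 10 nt overlap = 10% -> not counted
        rm = _read_map([("c1", 910, 1010, "s1", 1)])
        out = assign_reads(rm, self.CALLS)
        assert out["is_tnp"].tolist() == [False]

    def test_any_overlap_mode(self):
        rm = _read_map([("c1", 910, 1010, "s1", 1)])
        out = assign_reads(rm, self.CALLS, min_read_overlap_frac=0.0)
        assert out["is_tnp"].tolist() == [True]

    def test_exactly_half_overlap_counted(self):
        rm = _read_map([("c1", 950, 1050, "s1", 1)])
        out = assign_reads(rm, self.CALLS)
        assert out["is_tnp"].tolist() == [True]

    def test_family_majority_attribution(self):
        calls = _calls_df([("c1", 0, 100, "IS5"), ("c1", 100, 300, "IS3")])
        rm = _read_map([("c1", 50, 250, "s1", 1)])
        out = assign_reads(rm, calls)
        assert out["family"].tolist() == ["IS3"]  # 150 nt vs 50 nt overlap

    def test_off_contig_read_rejected(self):
        rm = _read_map([("c1", 900, 1100, "s1", 1)])
        with pytest.raises(ValueError, match="outside contig"):
            assign_reads(rm, self.CALLS, contig_lengths={"c1": 1000})


class TestFractions:
    def test_fraction_of_bacterial_reads(self):
        p = _profile(transposase_reads=7, total_bacterial_reads=1000)
        assert fraction_of_bacterial_reads(p) == pytest.approx(0.007)

    def test_zero_transposase_reads(self):
        p = _profile(transposase_reads=0, total_bacterial_reads=500)
        assert fraction_of_bacterial_reads(p) == 0.0

    def test_zero_denominator_error(self):
        with pytest.raises(UndefinedValueError):
            fraction_of_bacterial_reads(_profile())

    def test_per_taxon_fraction(self):
        p = _profile(per_taxon_reads={"Synechococcus": 1000},
                     per_taxon_transposase_reads={"Synechococcus": 50})
        assert per_taxon_fraction(p, "Synechococcus") == pytest.approx(0.05)

    def test_per_taxon_zero_transposases(self):
        p = _profile(per_taxon_reads={"Pelagibacter": 800})
        assert per_taxon_fraction(p, "Pelagibacter") == 0.0

    def test_absent_taxon_error(self):
        with pytest.raises(UndefinedValueError):
            per_taxon_fraction(_profile(), "Nobody")

    def test_taxon_fractions_conserve_total(self):
        rng = np.random.default_rng(0)
        taxa = [f"t{i}" for i in range(6)]
        totals = {t: int(rng.integers(100, 2000)) for t in taxa}
        tnp = {t: int(rng.integers(0, totals[t] // 10)) for t in taxa}
        p = _profile(per_taxon_reads=totals, per_taxon_transposase_reads=tnp,
                     total_bacterial_reads=sum(totals.values()),
                     transposase_reads=sum(tnp.values()))
        recovered = sum(per_taxon_fraction(p, t) * totals[t] for t in taxa)
        assert recovered == pytest.approx(p.transposase_reads)


class TestPerGenome:
    def test_uniform_marker_depth(self):
        p = _profile(transposase_reads=54, total_bacterial_reads=10000,
                     single_copy_hits={f"M{i:02d}": 2 for i in range(35)})
        assert per_genome_count(p) == pytest.approx(27.0)

    def test_unit_marker_depth(self):
        p = _profile(transposase_reads=58, total_bacterial_reads=10000,
                     single_copy_hits={f"M{i:02d}": 1 for i in range(35)})
        assert per_genome_count(p) == pytest.approx(58.0)

    def test_zero_markers_error(self):
        p = _profile(transposase_reads=5, total_bacterial_reads=100,
                     single_copy_hits={f"M{i:02d}": 0 for i in range(35)})
        with pytest.raises(UndefinedValueError):
            per_genome_count(p)

    def test_zero_hit_markers_dilute_the_mean(self):
        hits = {f"M{i:02d}": (4 if i < 10 else 0) for i in range(35)}
        p = _profile(transposase_reads=40, total_bacterial_reads=1000,
                     single_copy_hits=hits)
        assert per_genome_count(p) == pytest.approx(40 / (40 / 35))

    def test_depth_rescaling_invariance(self):
        hits = {f"M{i:02d}": 3 for i in range(35)}
        p1 = _profile(transposase_reads=30, total_bacterial_reads=1000,
                      single_copy_hits=hits)
        p2 = _profile(transposase_reads=300, total_bacterial_reads=10000,
                      single_copy_hits={k: 10 * v for k, v in hits.items()})
        assert per_genome_count(p1) == pytest.approx(per_genome_count(p2))


class TestExpressionRatio:
    def _pair(self, dna_frac, rna_frac, n=10000):
        dna = _profile(molecule="DNA", total_bacterial_reads=n,
                       transposase_reads=int(dna_frac * n))
        rna = _profile(molecule="RNA", sample_id="s1r",
                       total_bacterial_reads=n,
                       transposase_reads=int(rna_frac * n))
        return dna, rna

    def test_identity(self):
        dna, rna = self._pair(0.010, 0.010)
        assert expression_ratio([dna], [rna]) == pytest.approx(1.0)

    def test_twofold(self):
        dna, rna = self._pair(0.0023, 0.0046)
        assert expression_ratio([dna], [rna]) == pytest.approx(2.0)

    def test_zero_dna_fraction_excluded(self):
        dna, rna = self._pair(0.0, 0.01)
        with pytest.raises(UndefinedValueError):
            expression_ratio([dna], [rna])

    def test_median_across_pairs(self):
        pairs = [self._pair(0.01, r) for r in (0.01, 0.02, 0.04)]
        # distinct stations so the pairs don't collide
        for i, (d, r) in enumerate(pairs):
            d.station = r.station = f"S{i}"
        ratio = expression_ratio([d for d, _ in pairs], [r for _, r in pairs])
        assert ratio == pytest.approx(2.0)


class TestPerMbp:
    @pytest.mark.parametrize("count,size,expected", [
        (15, 2.7, 5.6),
        (22, 2.6, 8.5),
        (0, 2.3, 0.0),
    ])
    def test_strain_normalization(self, count, size, expected):
        assert transposases_per_mbp(count, size) == expected

    def test_nonpositive_size_error(self):
        with pytest.raises(ValueError):
            transposases_per_mbp(5, 0.0)


class TestGenomeSizeProxy:
    def test_equal_inputs_equal_proxies(self):
        hits = {f"M{i:02d}": 5 for i in range(35)}
        p1 = _profile(total_bacterial_reads=5000, single_copy_hits=dict(hits))
        p2 = _profile(sample_id="s2", total_bacterial_reads=5000,
                      single_copy_hits=dict(hits))
        assert genome_size_proxy(p1) == genome_size_proxy(p2)

    def test_scale_invariance(self):
        hits = {f"M{i:02d}": 5 for i in range(35)}
        p1 = _profile(total_bacterial_reads=5000, single_copy_hits=hits)
        p2 = _profile(total_bacterial_reads=10000,
                      single_copy_hits={k: 2 * v for k, v in hits.items()})
        assert genome_size_proxy(p1) == pytest.approx(genome_size_proxy(p2))


class TestGroundTruthRecovery:
    """Metrics recovered from simulated read maps using planted calls."""

    def _profiles(self, cfg, refs, truth_as_calls=True, rank="genus"):
        com = generate_community(cfg, refs)
        calls = com.truth.planted.rename(columns={})[
            ["contig_id", "start", "end", "family"]
        ]
        return com, build_profiles(com.read_map, calls, com.taxonomy,
                                   com.samples, com.truth.markers,
                                   taxon_rank=rank)

    def test_per_genome_copy_number_recovery(self, small_refs):
        """Uniform-depth sampling recovers planted copies per genome."""
        refs, _ = small_refs
        ests = []
        for seed in range(5):
            cfg = small_sim_config(
                seed=seed, stations=["GS665"], marine_stations=[],
                molecules=["DNA"], fractions=["medium"],
                read_mode="uniform", reads_per_sample=30000,
                n_contigs_per_taxon=6, contig_length_range=(9000, 14000),
                marker_length=750,
                ref_aa_length_range=(240, 260),  # ~750 nt, matches markers
                tnp_copies_per_taxon={"Synechococcus_BS": 12,
                                      "Pelagibacter_BS": 0,
                                      "Flavobacterium_BS": 0},
            )
            com, profiles = self._profiles(cfg, refs)
            p = next(iter(profiles.values()))
            ests.append(per_genome_count(p, "Synechococcus"))
        assert np.mean(ests) == pytest.approx(12, rel=0.15)

    def test_genome_size_proxy_recovers_length_ratio(self, small_refs):
        """Two taxa with 2:1 genome length at equal depth per genome."""
        refs, _ = small_refs
        from tnpquant.simulate import Taxon

        ratios = []
        for seed in range(5):
            taxa = [
                Taxon("Big_BS", "PhA", "ClA", "OrA", "Big", 2 / 3),
                Taxon("Small_BS", "PhB", "ClB", "OrB", "Small", 1 / 3),
            ]
            # Big has twice the contigs (twice the genome length); read
            # weight 2:1 keeps per-genome depth equal (equal cell abundance)
            cfg = small_sim_config(
                seed=100 + seed, stations=["GS665"], marine_stations=[],
                molecules=["DNA"], fractions=["medium"], taxa=taxa,
                read_mode="uniform", reads_per_sample=30000,
                tnp_copies_per_taxon=0, n_single_copy_markers=10,
                n_contigs_per_taxon={"Big_BS": 4, "Small_BS": 2},
            )
            com = generate_community(cfg, refs)
            profiles = build_profiles(
                com.read_map, _calls_df([]), com.taxonomy, com.samples,
                com.truth.markers,
            )
            p = next(iter(profiles.values()))
            ratios.append(genome_size_proxy(p, "Big")
                          / genome_size_proxy(p, "Small"))
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.15)

    def test_expression_ratio_recovery(self, small_refs):
        """A configured 2.3× RNA multiplier is recovered as the median ratio."""
        refs, _ = small_refs
        ests = []
        for seed in range(5):
            cfg = small_sim_config(
                seed=200 + seed, reads_per_sample=20000,
                expression_multiplier={("*", "Synechococcus_BS"): 2.3},
            )
            com, profiles = self._profiles(cfg, refs, rank="phylum")
            dna = [p for p in profiles.values() if p.molecule == "DNA"]
            rna = [p for p in profiles.values() if p.molecule == "RNA"]
            ests.append(expression_ratio(dna, rna, ("taxon", "Cyanobacteria")))
        assert np.median(ests) == pytest.approx(2.3, rel=0.12)
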