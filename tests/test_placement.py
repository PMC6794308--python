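import dataclasses
import math

import numpy as np
import pytest

from odzflux import (
    FilterConfig,
    GeneMeta,
    MetagenomeSample,
    PeptideObservation,
    PlacementRead,
    ScenarioConfig,
    compare_proportions,
    composition_fractions,
    filter_reads,
    make_peptide_tables,
    make_placement_table,
    normalize_abundance,
    peptide_overlap,
    shared_fraction,
    virus_host_ratio,
)
from odzflux.io import write_jplace
from odzflux.placement import read_jplace


def _read(i, clade="A", gene="ITS", bl=0.5, length=150, sample="s1", **kw):
    return PlacementRead(
        read_id=f"r{i}", gene=gene, clade=clade, branch_length=bl,
        read_len=length, sample_id=sample, **kw
    )


class TestFilterReads:
    def test_clean_input_removes_nothing(self):
        reads = [_read(i) for i in range(50)]
        kept, removed, frac = filter_reads(reads)
        assert (len(kept), len(removed), frac) == (50, 0, 0.0)

    def test_counting_oracle_long_branches(self):
        reads = [_read(i) for i in range(988)] + [
            _read(1000 + i, bl=3.0) for i in range(12)
        ]
        kept, removed, frac = filter_reads(reads)
        assert len(removed) == 12
        assert frac == pytest.approx(0.012)

    def test_short_read_removed_regardless_of_branch(self):
        kept, removed, _ = filter_reads([_read(0, bl=0.1, length=90)])
        assert not kept and len(removed) == 1

    def test_kept_and_removed_partition_input(self):
        reads = [_read(i, bl=0.5 if i % 3 else 2.5) for i in range(60)]
        kept, removed, _ = filter_reads(reads)
        assert sorted(r.read_id for r in kept + removed) == sorted(
            r.read_id for r in reads
        )
        assert not {r.read_id for r in kept} & {r.read_id for r in removed}


class TestNormalizeAbundance:
    SAMPLES = [MetagenomeSample("s1", 1_000_000)]
    GENES = [GeneMeta(gene="ITS", ref_length=500.0, length_unit="nt")]

    def test_arithmetic_oracle(self):
        reads = [_read(i) for i in range(50)]
        table = normalize_abundance(reads, self.SAMPLES, self.GENES)
        assert table.data.loc[0, "abundance"] == pytest.approx(1e-5)
        assert table.data.loc[0, "raw_count"] == 50

    def test_copy_number_halves_two_copy_clade(self):
        genes = [
            GeneMeta(
                gene="ITS", ref_length=500.0, length_unit="nt",
                copy_number={"Synechococcus": 2.0},
            )
        ]
        reads = [_read(i, clade="Synechococcus") for i in range(40)] + [
            _read(100 + i, clade="NC2") for i in range(40)
        ]
        table = normalize_abundance(reads, self.SAMPLES, genes)
        ab = dict(zip(table.data["clade"], table.data["abundance"]))
        assert ab["Synechococcus"] == pytest.approx(ab["NC2"] / 2.0)

    def test_copy_number_round_trip(self):
        genes = [
            GeneMeta(gene="ITS", ref_length=500.0, copy_number={"A": 2.0})
        ]
        reads = [_read(i) for i in range(30)]
        corrected = normalize_abundance(reads, self.SAMPLES, genes)
        uncorrected = normalize_abundance(reads, self.SAMPLES, self.GENES)
        assert corrected.data.loc[0, "abundance"] * 2.0 == pytest.approx(
            uncorrected.data.loc[0, "abundance"]
        )

    def test_doubling_library_halves_abundance(self):
        reads = [_read(i) for i in range(50)]
        small = normalize_abundance(reads, [MetagenomeSample("s1", 500_000)], self.GENES)
        big = normalize_abundance(reads, [MetagenomeSample("s1", 1_000_000)], self.GENES)
        assert big.data.loc[0, "abundance"] == pytest.approx(
            small.data.loc[0, "abundance"] / 2.0
        )

    def test_order_invariant_and_additive(self):
        reads = [_read(i, clade="A" if i % 2 else "B") for i in range(80)]
        fwd = normalize_abundance(reads, self.SAMPLES, self.GENES)
        rev = normalize_abundance(reads[::-1], self.SAMPLES, self.GENES)
        assert fwd.data.equals(rev.data)
        half1 = normalize_abundance(reads[:40], self.SAMPLES, self.GENES)
        half2 = normalize_abundance(reads[40:], self.SAMPLES, self.GENES)
        merged = (
            half1.data.set_index("clade")["abundance"]
            .add(half2.data.set_index("clade")["abundance"], fill_value=0.0)
        )
        total = fwd.data.set_index("clade")["abundance"]
        assert np.allclose(merged.sort_index(), total.sort_index())

    def test_paired_records_count_once(self):
        pair = [
            _read(0, paired=True, weight=0.9),
            dataclasses.replace(_read(0, paired=True, weight=0.4), clade="B"),
        ]
        table = normalize_abundance(pair, self.SAMPLES, self.GENES)
        assert table.data["raw_count"].sum() == 1
        assert table.data.loc[0, "clade"] == "A"  # higher placement weight wins

    def test_missing_metadata_is_hard_error(self):
        with pytest.raises(KeyError, match="s2"):
            normalize_abundance([_read(0, sample="s2")], self.SAMPLES, self.GENES)


class TestRatiosAndFractions:
    def _table(self, v_counts, h_counts):
        samples = [MetagenomeSample("s1", 100_000)]
        genes = [
            GeneMeta(gene="vpol", ref_length=700.0),
            GeneMeta(gene="rpoB", ref_length=1100.0),
        ]
        reads = [_read(f"v{i}", clade="myo", gene="vpol") for i in range(v_counts)] + [
            _read(f"h{i}", clade="cyano", gene="rpoB") for i in range(h_counts)
        ]
        return normalize_abundance(reads, samples, genes)

    def test_equal_normalized_abundance_gives_unit_ratio(self):
        # counts proportional to gene length → equal normalized abundances
        table = self._table(700, 1100)
        assert virus_host_ratio(table, "vpol", "rpoB", "s1") == pytest.approx(1.0)

    def test_zero_host_is_undefined_not_infinite(self):
        table = self._table(10, 0)
        assert virus_host_ratio(table, "vpol", "rpoB", "s1") is None

    def test_single_clade_fraction_one(self):
        table = self._table(10, 5)
        assert composition_fractions(table, "vpol", "s1") == {"myo": 1.0}

    def test_two_equal_clades_split_evenly(self):
        samples = [MetagenomeSample("s1", 1000)]
        genes = [GeneMeta(gene="ITS", ref_length=500.0)]
        reads = [_read(i, clade="A" if i % 2 else "B") for i in range(40)]
        fr = composition_fractions(normalize_abundance(reads, samples, genes), "ITS", "s1")
        assert fr == {"A": pytest.approx(0.5), "B": pytest.approx(0.5)}

    def test_identical_samples_sit_on_the_1_1_line(self):
        samples = [MetagenomeSample("s1", 1000), MetagenomeSample("s2", 1000)]
        genes = [GeneMeta(gene="ITS", ref_length=500.0)]
        reads = []
        for s in ("s1", "s2"):
            reads += [_read(f"{s}_{i}", clade="A" if i % 2 else "B", sample=s) for i in range(40)]
        df = compare_proportions(normalize_abundance(reads, samples, genes), "ITS", "s1", "s2")
        assert df.attrs["max_abs_dev"] == 0.0
        assert df.attrs["rms_dev"] == 0.0

    def test_disjoint_clades_max_deviation_is_largest_proportion(self):
        samples = [MetagenomeSample("s1", 1000), MetagenomeSample("s2", 1000)]
        genes = [GeneMeta(gene="ITS", ref_length=500.0)]
        reads = [_read(i, clade="A", sample="s1") for i in range(10)] + [
            _read(100 + i, clade="B", sample="s2") for i in range(10)
        ]
        df = compare_proportions(normalize_abundance(reads, samples, genes), "ITS", "s1", "s2")
        assert df.attrs["max_abs_dev"] == pytest.approx(1.0)

    def test_rms_deviation_shrinks_with_sequencing_depth(self):
        devs = []
        for depth in (2000, 32_000):
            tables = []
            for seed in (1, 2):
                cfg = ScenarioConfig(seed=seed, marker_reads=depth, contaminant_fraction=0.0)
                reads, samples, genes, _ = make_placement_table(cfg)
                sample = dataclasses.replace(samples[0], sample_id=f"s{seed}")
                reads = [
                    dataclasses.replace(r, sample_id=f"s{seed}")
                    for r in reads
                    if r.gene == "ITS"
                ]
                tables.append((reads, sample))
            all_reads = tables[0][0] + tables[1][0]
            table = normalize_abundance(all_reads, [tables[0][1], tables[1][1]], genes)
            df = compare_proportions(table, "ITS", "s1", "s2")
            devs.append(df.attrs["rms_dev"])
        # 16× the depth → RMS deviation ≈ 4× smaller; allow generous slack
        assert devs[1] < devs[0] / 2.0


class TestGeneratorRecovery:
    def test_community_fractions_within_multinomial_error(self):
        cfg = ScenarioConfig(seed=11, marker_reads=100_000, contaminant_fraction=0.0)
        reads, samples, genes, truth = make_placement_table(cfg)
        kept, _, _ = filter_reads(reads)
        table = normalize_abundance(kept, samples, genes)
        fr = composition_fractions(table, "ITS", samples[0].sample_id)
        n = cfg.marker_reads
        for clade, p in truth["community"].items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(fr[clade] - p) < 3 * se, clade

    def test_even_two_clade_community(self):
        cfg = ScenarioConfig(
            seed=3,
            community={"A": 0.5, "B": 0.5},
            marker_reads=100_000,
            contaminant_fraction=0.0,
        )
        reads, samples, genes, _ = make_placement_table(cfg)
        table = normalize_abundance(reads, samples, genes)
        fr = composition_fractions(table, "ITS", samples[0].sample_id)
        assert fr["A"] == pytest.approx(0.5, abs=0.02)

    def test_copy_number_correction_recovers_composition(self):
        cfg = ScenarioConfig(
            seed=5,
            community={"Synechococcus": 0.5, "other": 0.5},
            marker_reads=100_000,
            contaminant_fraction=0.0,
        )
        cn = {"Synechococcus": 2.0}
        reads, samples, genes, _ = make_placement_table(cfg, copy_number=cn)
        table = normalize_abundance(reads, samples, genes)
        raw = dict(zip(table.data[table.data.gene == "ITS"]["clade"],
                       table.data[table.data.gene == "ITS"]["raw_count"]))
        # 2-copy clade draws ≈ 2× the reads of the 1-copy clade...
        assert raw["Synechococcus"] / raw["other"] == pytest.approx(2.0, rel=0.05)
        # ...but corrected abundances recover the even community
        fr = composition_fractions(table, "ITS", samples[0].sample_id)
        assert fr["Synechococcus"] == pytest.approx(0.5, abs=0.02)

    def test_contaminant_fraction_flagged_exactly(self):
        cfg = ScenarioConfig(seed=2, marker_reads=10_000, contaminant_fraction=0.1)
        reads, _, _, truth = make_placement_table(cfg)
        its = [r for r in reads if r.gene == "ITS"]
        _, removed, frac = filter_reads(its)
        assert frac == pytest.approx(truth["contaminant_fraction"])
        assert len(removed) == round(0.1 * 10_000)

    def test_virus_host_ratio_recovered(self):
        cfg = ScenarioConfig(seed=8, virus_host_ratio=35.0)
        reads, samples, genes, _ = make_placement_table(cfg)
        table = normalize_abundance(reads, samples, genes)
        ratio = virus_host_ratio(table, "viral_DNApol", "rpoB", samples[0].sample_id)
        # Poisson sampling error on ~4.5e4 virus reads is ≈0.5%
        assert ratio == pytest.approx(35.0, rel=0.02)


class TestPeptides:
    def _obs(self, cfg=None, overlap=0.67):
        cfg = cfg or ScenarioConfig()
        return make_peptide_tables(
            cfg,
            sizes={"trap": 100, "water100": 150, "water50": 120},
            overlaps={("trap", "water100"): overlap},
        )

    def test_configured_overlap_recovered_exactly(self):
        obs = self._obs()
        assert shared_fraction(obs, "trap", "water100") == pytest.approx(0.67)

    def test_identical_sets_share_everything(self):
        obs = make_peptide_tables(
            ScenarioConfig(), sizes={"a": 80, "b": 80}, overlaps={("a", "b"): 1.0}
        )
        assert shared_fraction(obs, "a", "b") == 1.0

    def test_unlisted_pairs_are_disjoint(self):
        obs = self._obs()
        assert shared_fraction(obs, "trap", "water50") == 0.0

    def test_partition_fractions_sum_to_one(self):
        obs = self._obs()
        parts = peptide_overlap(obs, "trap", ["water100", "water50"])
        assert sum(parts.values()) == pytest.approx(1.0)
        assert parts[frozenset(["water100"])] == pytest.approx(0.67)

    def test_taxon_filter_restricts_universe(self):
        obs = self._obs() + [
            PeptideObservation("trap", "XTRA1", taxon="Eukaryota"),
        ]
        cyano_only = shared_fraction(obs, "trap", "water100", taxon_filter="Cyanobacteria")
        assert cyano_only == pytest.approx(0.67)

    def test_oversized_intersection_rejected(self):
        with pytest.raises(ValueError, match="intersection"):
            make_peptide_tables(
                ScenarioConfig(), sizes={"a": 100, "b": 30}, overlaps={("a", "b"): 0.8}
            )

    def test_empty_focal_sample_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            peptide_overlap(self._obs(), "missing", ["trap"])


class TestJplaceRoundTrip:
    def test_jplace_written_then_read_back(self, tmp_path):
        reads = [
            _read(0, clade="LLIV", bl=0.3, weight=0.8),
            _read(1, clade="LLI", bl=1.2, weight=0.6),
        ]
        path = tmp_path / "placements.jplace"
        write_jplace(reads, {"LLIV": 4, "LLI": 7}, path)
        back = read_jplace(path, {4: "LLIV", 7: "LLI"}, gene="ITS", sample_id="s1")
        assert {(r.read_id, r.clade) for r in back} == {("r0", "LLIV"), ("r1", "LLI")}
        assert {r.branch_length for r in back} == {0.3, 1.2}

    def test_unmapped_edge_rejected(self, tmp_path):
        path = tmp_path / "p.jplace"
        write_jplace([_read(0, clade="X")], {"X": 9}, path)
        with pytest.raises(KeyError, match="edge 9"):
            read_jplace(path, {1: "Y"}, gene="ITS", sample_id="s1")
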