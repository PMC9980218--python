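"""Synthetic-data generator: determinism, IR structure, planted fractions."""

import numpy as np
import pytest

from plastedit.quant import build_pileup
from plastedit.reference import PlastomeReference, revcomp
from plastedit.simulate import (ChannelPeaks, SimConfig, plant_editing_sites,
                                simulate_plastome, simulate_reads,
                                simulate_trace, truth_to_tsv)


class TestSimulatePlastome:
    def test_deterministic_under_seed(self, tmp_path):
        cfgs = [SimConfig(seed=1), SimConfig(seed=1)]
        fastas = []
        for i, cfg in enumerate(cfgs):
            ref = simulate_plastome(cfg)
            p = tmp_path / f"ref{i}.fa"
            ref.to_fasta(p)
            fastas.append(p.read_bytes())
        assert fastas[0] == fastas[1]
        other = simulate_plastome(SimConfig(seed=2))
        assert other.seq != simulate_plastome(SimConfig(seed=1)).seq

    def test_zero_genes_still_emits_genome(self, tmp_path):
        ref = simulate_plastome(SimConfig(n_genes=0, ir_gene=False))
        assert len(ref.seq) == 20_000 and ref.genes == []
        ref.to_gff3(tmp_path / "g.gff3")
        body = [l for l in (tmp_path / "g.gff3").read_text().splitlines()
                if not l.startswith("#")]
        assert body == []

    def test_ir_gene_is_reverse_complement_duplicate(self, plastome):
        dups = [g for g in plastome.genes if g.copy_of]
        assert len(dups) == 1
        dup = dups[0]
        template = plastome.gene(dup.copy_of)
        a = plastome.seq[template.start - 1 : template.end]
        b = plastome.seq[dup.start - 1 : dup.end]
        assert b == revcomp(a)
        assert dup.strand != template.strand

    def test_genes_non_overlapping(self, plastome):
        intervals = sorted((g.start, g.end) for g in plastome.genes)
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            assert e1 < s2

    def test_infeasible_packing_raises(self):
        with pytest.raises(ValueError, match="pack"):
            simulate_plastome(SimConfig(genome_length=1000, n_genes=10))

    @pytest.mark.parametrize("kwargs", [
        {"genome_length": 500},
        {"error_rate": 0.5},
        {"read_length": 30_000},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestPlantEditingSites:
    def test_planted_fraction_recorded(self, tmp_path):
        ref = simulate_plastome(SimConfig(seed=4, ir_gene=False))
        truth = plant_editing_sites(ref, [("rpoA", 50, {"control": 1.0})])
        assert truth[0].fractions["control"] == 1.0
        truth_to_tsv(truth, tmp_path / "t.tsv")
        lines = (tmp_path / "t.tsv").read_text().splitlines()
        assert lines[1].split("\t") == [
            "rpoA", "rpoA", str(truth[0].position), truth[0].strand,
            "control", "1",
        ]

    def test_minus_strand_gene_shows_forward_g(self):
        ref = simulate_plastome(SimConfig(seed=0, ir_gene=False))
        minus = next(g for g in ref.genes if g.strand == "-")
        truth = plant_editing_sites(ref, [(minus.name, 10, {"control": 0.5})])
        assert ref.seq[truth[0].position - 1] == "G"

    def test_plus_strand_gene_shows_forward_c(self):
        ref = simulate_plastome(SimConfig(seed=0, ir_gene=False))
        plus = next(g for g in ref.genes if g.strand == "+")
        truth = plant_editing_sites(ref, [(plus.name, 10, {"control": 0.5})])
        assert ref.seq[truth[0].position - 1] == "C"

    def test_low_fraction_magnitude(self):
        # sites as weakly edited as ~5% occur in real plastomes
        ref = simulate_plastome(SimConfig(seed=0, ir_gene=False))
        truth = plant_editing_sites(ref, [("rpoA", 88, {"control": 0.0543})])
        assert truth[0].fractions["control"] == pytest.approx(0.0543)

    def test_offset_outside_gene_raises(self):
        ref = simulate_plastome(SimConfig(seed=0, ir_gene=False))
        with pytest.raises(ValueError, match="outside"):
            plant_editing_sites(ref, [("rpoA", 10**6, {"control": 0.5})])

    def test_non_c_without_substitution_raises(self):
        ref = simulate_plastome(SimConfig(seed=0, ir_gene=False))
        gene = ref.genes[0]
        coding = ref.gene_sequence(gene.name)
        offset = coding.index("A") + 1
        with pytest.raises(ValueError, match="not C"):
            plant_editing_sites(ref, [(gene.name, offset, {"control": 0.5})],
                                substitute=False)

    def test_ir_sites_mirrored_with_same_fractions(self, plastome):
        import copy
        ref = copy.deepcopy(plastome)
        dup = next(g for g in ref.genes if g.copy_of)
        truth = plant_editing_sites(
            ref, [(dup.copy_of, 33, {"control": 0.7})])
        assert {t.gene for t in truth} == {dup.copy_of, dup.name}
        assert all(t.fractions["control"] == 0.7 for t in truth)
        assert len({t.position for t in truth}) == 2


class TestSimulateReads:
    def test_zero_fraction_zero_error_no_edited_bases(self, tmp_path):
        cfg = SimConfig(genome_length=2000, n_genes=1, ir_gene=False,
                        mean_depth=200, error_rate=0.0, seed=5)
        ref = simulate_plastome(cfg)
        gene = ref.genes[0]
        truth = plant_editing_sites(ref, [(gene.name, 50, {"control": 0.0})])
        reads = simulate_reads(ref, truth, cfg, outdir=tmp_path, seed=11)
        pileup = build_pileup(reads.sam, ref)
        site = pileup.at(truth[0].position)
        edited = site.t if truth[0].strand == "+" else site.a
        assert edited == 0 and site.depth > 0

    def test_planted_fraction_recovered_binomially(self, tmp_path):
        cfg = SimConfig(genome_length=2000, n_genes=1, ir_gene=False,
                        mean_depth=2000, error_rate=0.0, seed=6)
        ref = simulate_plastome(cfg)
        gene = ref.genes[0]
        truth = plant_editing_sites(ref, [(gene.name, 120, {"control": 0.5})])
        reads = simulate_reads(ref, truth, cfg, outdir=tmp_path, seed=12)
        site = build_pileup(reads.sam, ref).at(truth[0].position)
        if truth[0].strand == "+":
            edited, unedited = site.t, site.c
        else:
            edited, unedited = site.a, site.g
        n = edited + unedited
        assert n > 1000
        sd = np.sqrt(0.25 / n)
        assert abs(edited / n - 0.5) < 3 * sd

    def test_read_length_and_depth(self, tmp_path):
        cfg = SimConfig(mean_depth=50, error_rate=0.0, seed=7)
        ref = simulate_plastome(cfg)
        reads = simulate_reads(ref, [], cfg, outdir=tmp_path, seed=1)
        first = (tmp_path / "reads_R1.fastq").read_text().splitlines()[1]
        assert len(first) == 250
        depth = build_pileup(reads.sam, ref, include_multimapped=False).depth
        assert abs(depth.mean() - 50) / 50 < 0.10

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = SimConfig(genome_length=2000, n_genes=1, ir_gene=False,
                        mean_depth=30, seed=8)
        ref = simulate_plastome(cfg)
        truth = plant_editing_sites(ref, [(ref.genes[0].name, 10,
                                           {"control": 0.4})])
        r1 = simulate_reads(ref, truth, cfg, outdir=tmp_path / "a", seed=3)
        r2 = simulate_reads(ref, truth, cfg, outdir=tmp_path / "b", seed=3)
        assert r1.sam.read_bytes() == r2.sam.read_bytes()
        assert r1.fastq1.read_bytes() == r2.fastq1.read_bytes()
        assert r1.fastq2.read_bytes() == r2.fastq2.read_bytes()

    def test_ir_reads_multimapped(self, tmp_path, plastome, sim_config):
        import copy
        import pysam
        ref = copy.deepcopy(plastome)
        reads = simulate_reads(ref, [], sim_config, outdir=tmp_path, seed=2)
        dup = next(g for g in ref.genes if g.copy_of)
        with pysam.AlignmentFile(str(reads.sam), "r", check_sq=False) as fh:
            records = [r for r in fh
                       if dup.start - 1 <= r.reference_start
                       and r.reference_end <= dup.end]
        assert records, "no reads fully inside the IR copy"
        assert all(r.mapping_quality == 0 for r in records)
        by_name: dict[str, int] = {}
        for r in records:
            by_name[r.query_name] = by_name.get(r.query_name, 0) + 1
        # each IR-internal read appears here either as its primary or as the
        # mirrored secondary of a read from the other copy
        secondaries = [r for r in records if r.is_secondary]
        assert secondaries

    def test_nonpositive_depth_raises(self, tmp_path, plastome):
        cfg = SimConfig(mean_depth=0.0)
        with pytest.raises(ValueError, match="mean_depth"):
            simulate_reads(plastome, [], cfg, outdir=tmp_path)


class TestSimulateTrace:
    def test_noise_free_examples(self):
        half = simulate_trace(0.5, 0.0)
        assert half.c == half.t > 0
        full = simulate_trace(1.0, 0.0)
        assert full.c == 0 and full.t > 0

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            simulate_trace(0.5, -0.1)
        with pytest.raises(ValueError):
            simulate_trace(1.5, 0.0)

    def test_monte_carlo_recovery(self):
        rng = np.random.default_rng(7)
        fracs = [
            (lambda p: p.t / (p.t + p.c))(simulate_trace(0.25, 0.01, rng))
            for _ in range(100)
        ]
        assert abs(np.mean(fracs) - 0.25) < 0.05
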