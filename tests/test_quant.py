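"""Pileup construction, site calling, naming and Sanger quantification."""

import copy

import numpy as np
import pandas as pd
import pytest

from plastedit.quant import (CallThresholds, UndefinedEfficiencyError,
                             build_pileup, call_editing_sites,
                             editing_efficiency, format_percent, name_sites,
                             sanger_efficiency)
from plastedit.reference import Gene, PlastomeReference
from plastedit.simulate import (ChannelPeaks, SimConfig, plant_editing_sites,
                                simulate_plastome, simulate_reads,
                                simulate_trace)

from .conftest import flip_reference, flip_sam, write_sam


@pytest.fixture()
def tiny_ref() -> PlastomeReference:
    # 60 bp, one + gene and one - gene
    seq = "ACGTACGTACCTTTGGGCCCAAATTTGGGCCCAAATTTGGGTTTAAACCCGGGTTTAAAC"
    genes = [Gene("plusg", 5, 30, "+"), Gene("minusg", 35, 55, "-")]
    return PlastomeReference(seq=seq, genes=genes, name="tiny")


class TestBuildPileup:
    def test_empty_sam(self, tmp_path, tiny_ref):
        sam = write_sam(tmp_path / "e.sam", "tiny", 60, [])
        pileup = build_pileup(sam, tiny_ref)
        assert pileup.depth.sum() == 0
        assert pileup.to_frame().empty

    def test_hand_enumerated_counts(self, tmp_path, tiny_ref):
        # three reads over position 10 (ref C): two read T, one reads C
        sam = write_sam(tmp_path / "t.sam", "tiny", 60, [
            ("r1", 0, 8, 60, "5M", "ACTTT"),
            ("r2", 0, 10, 60, "5M", "TTTGG"),
            ("r3", 0, 6, 60, "5M", "GTACC"),
        ])
        site = build_pileup(sam, tiny_ref).at(10)
        assert (site.t, site.c, site.depth) == (2, 1, 3)

    def test_soft_clips_and_unmapped_excluded(self, tmp_path, tiny_ref):
        sam = write_sam(tmp_path / "s.sam", "tiny", 60, [
            ("r1", 0, 10, 60, "2S3M", "GGTTT"),   # clip must not count
            ("r2", 4, 0, 0, "*", "ACGTA"),        # unmapped
        ])
        pileup = build_pileup(sam, tiny_ref)
        assert pileup.depth.sum() == 3
        assert pileup.at(10).t == 1  # first M base lands at pos 10

    def test_multimapped_toggle(self, tmp_path, tiny_ref):
        records = [
            ("u1", 0, 10, 60, "5M", "TTTGG"),
            ("m1", 0, 10, 0, "5M", "TTTGG"),
            ("m2", 256, 10, 0, "5M", "CTTGG"),
        ]
        sam = write_sam(tmp_path / "m.sam", "tiny", 60, records)
        with_mm = build_pileup(sam, tiny_ref, include_multimapped=True)
        without = build_pileup(sam, tiny_ref, include_multimapped=False)
        assert with_mm.at(10).depth == 3
        assert without.at(10).depth == 1
        assert with_mm.at(10).n_multimapped == 2

    def test_reference_name_mismatch(self, tmp_path, tiny_ref):
        sam = write_sam(tmp_path / "x.sam", "other", 60,
                        [("r1", 0, 1, 60, "3M", "ACG")])
        with pytest.raises(ValueError, match="other.*tiny|tiny.*other"):
            build_pileup(sam, tiny_ref)

    def test_tally_conservation(self, tmp_path):
        # error-free simulated SAM: total depth == sum of aligned bases
        cfg = SimConfig(genome_length=3000, n_genes=2, ir_gene=False,
                        mean_depth=20, error_rate=0.0, seed=9)
        ref = simulate_plastome(cfg)
        reads = simulate_reads(ref, [], cfg, outdir=tmp_path, seed=4)
        pileup = build_pileup(reads.sam, ref)
        assert pileup.depth.sum() == reads.n_fragments * 2 * cfg.read_length


class TestEditingEfficiency:
    @pytest.mark.parametrize("edited,unedited,expect", [
        (50, 50, 0.5), (0, 10, 0.0), (10, 0, 1.0),
    ])
    def test_fraction(self, edited, unedited, expect):
        assert editing_efficiency(edited, unedited) == expect

    def test_zero_zero_is_undefined_not_zero(self):
        with pytest.raises(UndefinedEfficiencyError):
            editing_efficiency(0, 0)

    def test_percent_rendering(self):
        assert format_percent(0.0543) == "5.43%"
        assert format_percent(1.0) == "100.00%"


class TestCallEditingSites:
    def test_called_efficiency_matches_pileup_tallies(self, tmp_path):
        cfg = SimConfig(genome_length=3000, n_genes=2, ir_gene=False,
                        mean_depth=100, error_rate=0.0, seed=10)
        ref = simulate_plastome(cfg)
        truth = plant_editing_sites(
            ref, [(ref.genes[0].name, 60, {"control": 0.5})])
        reads = simulate_reads(ref, truth, cfg, outdir=tmp_path, seed=5)
        pileup = build_pileup(reads.sam, ref)
        sites = call_editing_sites(pileup, ref)
        assert list(sites["position"]) == [truth[0].position]
        row = sites.iloc[0]
        # the called efficiency is exactly the tally ratio from the truth SAM
        assert row["efficiency"] == row["edited_count"] / (
            row["edited_count"] + row["unedited_count"])
        sd = np.sqrt(0.25 / (row["edited_count"] + row["unedited_count"]))
        assert abs(row["efficiency"] - 0.5) < 3 * sd

    def test_fully_edited_site(self, tmp_path):
        cfg = SimConfig(genome_length=4000, n_genes=2, ir_gene=False,
                        mean_depth=100, error_rate=0.0, seed=11)
        ref = simulate_plastome(cfg)
        truth = plant_editing_sites(
            ref, [(ref.genes[1].name, 42, {"control": 1.0})])
        reads = simulate_reads(ref, truth, cfg, outdir=tmp_path, seed=6)
        sites = call_editing_sites(build_pileup(reads.sam, ref), ref)
        assert sites.iloc[0]["efficiency"] == 1.0

    def test_depth_threshold_suppresses_site(self, tmp_path, tiny_ref):
        # 5 reads < min_depth 10 at a + gene C position (pos 10)
        records = [(f"r{i}", 0, 10, 60, "3M", "TTT") for i in range(5)]
        sam = write_sam(tmp_path / "d.sam", "tiny", 60, records)
        sites = call_editing_sites(build_pileup(sam, tiny_ref), tiny_ref)
        assert sites.empty

    def test_no_false_positives_without_editing(self, tmp_path):
        cfg = SimConfig(genome_length=5000, n_genes=3, ir_gene=False,
                        mean_depth=100, error_rate=0.0, seed=12)
        ref = simulate_plastome(cfg)
        reads = simulate_reads(ref, [], cfg, outdir=tmp_path, seed=7)
        sites = call_editing_sites(build_pileup(reads.sam, ref), ref)
        assert sites.empty

    def test_strand_invariance(self, tmp_path):
        # calling on the reverse-complemented genome with flipped annotation
        # and mirrored alignments yields the same sites and efficiencies
        cfg = SimConfig(genome_length=4000, n_genes=3, ir_gene=False,
                        mean_depth=150, error_rate=0.0, seed=13)
        ref = simulate_plastome(cfg)
        truth = plant_editing_sites(ref, [
            (ref.genes[0].name, 30, {"control": 0.6}),
            (ref.genes[1].name, 75, {"control": 0.3}),
            (ref.genes[1].name, 40, {"control": 0.9}),
        ])
        reads = simulate_reads(ref, truth, cfg, outdir=tmp_path, seed=8)
        fwd = name_sites(
            call_editing_sites(build_pileup(reads.sam, ref), ref), ref)

        flipped = flip_reference(ref)
        fsam = flip_sam(reads.sam, tmp_path / "flipped.sam", len(ref.seq))
        rev = name_sites(
            call_editing_sites(build_pileup(fsam, flipped), flipped), flipped)

        f = fwd.sort_values("site_id")[["site_id", "efficiency",
                                        "edited_count", "unedited_count"]]
        r = rev.sort_values("site_id")[["site_id", "efficiency",
                                        "edited_count", "unedited_count"]]
        pd.testing.assert_frame_equal(f.reset_index(drop=True),
                                      r.reset_index(drop=True))

    def test_exclusion_mask(self, tmp_path, tiny_ref):
        records = [(f"r{i}", 0, 10, 60, "3M", "TTT") for i in range(12)]
        sam = write_sam(tmp_path / "b.sam", "tiny", 60, records)
        pileup = build_pileup(sam, tiny_ref)
        open_calls = call_editing_sites(pileup, tiny_ref)
        assert 10 in set(open_calls["position"])
        masked = call_editing_sites(pileup, tiny_ref, exclude=[(10, 10)])
        assert 10 not in set(masked["position"])


class TestNameSites:
    def _mk(self, gene, positions, strand):
        return pd.DataFrame({
            "gene": gene, "position": positions, "strand": strand,
            "edited_count": 1, "unedited_count": 1, "efficiency": 0.5,
            "depth": 2, "n_multimapped": 0,
        })

    def test_plus_strand_ascending(self):
        ref = PlastomeReference("A" * 100, [Gene("ndhD", 1, 90, "+")])
        named = name_sites(self._mk("ndhD", [40, 10], "+"), ref)
        assert dict(zip(named["position"], named["site_id"])) == {
            10: "ndhD-1", 40: "ndhD-2"}

    def test_minus_strand_descending(self):
        ref = PlastomeReference("A" * 100, [Gene("ndhB", 1, 90, "-")])
        named = name_sites(self._mk("ndhB", [10, 40], "-"), ref)
        assert dict(zip(named["position"], named["site_id"])) == {
            40: "ndhB-1", 10: "ndhB-2"}

    def test_single_site_gene_bare_name(self):
        ref = PlastomeReference("A" * 100, [Gene("psbL", 1, 90, "+")])
        named = name_sites(self._mk("psbL", [33], "+"), ref)
        assert list(named["site_id"]) == ["psbL"]


class TestSangerEfficiency:
    def test_equal_channels(self):
        assert sanger_efficiency(ChannelPeaks(0, 100, 0, 100)) == 0.5

    def test_inverse_of_noise_free_trace(self):
        for f in (0.0, 0.25, 0.0543, 1.0):
            assert sanger_efficiency(simulate_trace(f, 0.0)) == pytest.approx(f)

    def test_antisense_channels(self):
        assert sanger_efficiency(ChannelPeaks(70, 0, 30, 0), "-") == 0.7

    def test_zero_channels_undefined(self):
        with pytest.raises(UndefinedEfficiencyError):
            sanger_efficiency(ChannelPeaks(10, 0, 10, 0), "+")
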