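"""Panel design: target loading, tiling, arm selection, oligo assembly, I/O."""

import math

import pytest
from hypothesis import given, strategies as st

from mipseq.panel import (
    ArmRejection,
    DesignParams,
    MipProbe,
    SnpRecord,
    TargetRegion,
    arm_copy_count,
    assemble_oligo,
    design_panel,
    export_panel,
    load_targets,
    min_window_count,
    pick_arms,
    read_panel,
    tile_region,
    validate_panel,
)
from mipseq.seqs import revcomp

PARAMS = DesignParams()


def write_bed(tmp_path, rows):
    path = tmp_path / "targets.bed"
    path.write_text("".join(f"{c}\t{s}\t{e}\t{n}\n" for c, s, e, n in rows))
    return str(path)


class TestLoadTargets:
    def test_symmetric_padding(self, tmp_path):
        bed = write_bed(tmp_path, [("chr1", 100, 200, "G1|e1")])
        (region,) = load_targets(bed, pad=20)
        assert (region.start, region.end) == (80, 220)
        assert (region.gene, region.exon) == ("G1", "e1")

    def test_overlapping_padded_records_merge(self, tmp_path):
        bed = write_bed(tmp_path, [("chr1", 100, 200, "G1|e1"), ("chr1", 210, 300, "G1|e2")])
        (region,) = load_targets(bed, pad=20)
        assert (region.start, region.end) == (80, 320)
        assert region.exon == "e1,e2"

    def test_merged_region_joins_unique_gene_labels(self, tmp_path):
        bed = write_bed(tmp_path, [("chr1", 100, 200, "G1|e1"), ("chr1", 150, 300, "G2|e1")])
        (region,) = load_targets(bed, pad=0)
        assert region.gene == "G1,G2"

    def test_zero_pad_is_identity(self, tmp_path):
        bed = write_bed(tmp_path, [("chr1", 50, 90, "G1|e1")])
        (region,) = load_targets(bed, pad=0)
        assert (region.start, region.end) == (50, 90)

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\tG1|e1\nchr1\tfoo\t300\tG1|e2\n")
        with pytest.raises(ValueError, match="line 2"):
            load_targets(str(path))

    def test_out_of_bounds_region_rejected(self, tmp_path):
        bed = write_bed(tmp_path, [("chr1", 100, 5000, "G1|e1")])
        with pytest.raises(ValueError, match="outside"):
            load_targets(bed, reference={"chr1": "A" * 1000})


class TestTiling:
    @pytest.mark.parametrize(
        "length,expected_windows",
        [(220, 1), (440, 2), (650, 3)],
    )
    def test_window_counts_match_closed_form(self, length, expected_windows):
        region = TargetRegion("chr1", 1000, 1000 + length)
        windows = tile_region(region, PARAMS)
        assert len(windows) == expected_windows

    def test_single_window_fits_short_region(self):
        region = TargetRegion("chr1", 1000, 1220)
        (w,) = tile_region(region, PARAMS)
        assert w == (1000, 1220)

    def test_short_region_covered_by_flank_extension(self):
        region = TargetRegion("chr1", 1000, 1050)
        (w,) = tile_region(region, PARAMS)
        assert w[1] - w[0] == PARAMS.gap_fill_range[0]
        assert w[0] <= 1000 and w[1] >= 1050

    @given(length=st.integers(min_value=1, max_value=2000))
    def test_tiling_covers_region_with_min_overlap(self, length):
        region = TargetRegion("chr1", 5000, 5000 + length)
        windows = tile_region(region, PARAMS)
        lo, hi = PARAMS.gap_fill_range
        assert all(lo <= e - s <= hi for s, e in windows)
        assert windows[0][0] <= region.start and windows[-1][1] >= region.end
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            assert s2 > s1
            assert e1 - s2 >= PARAMS.tile_overlap
        assert len(windows) == min_window_count(length, hi, PARAMS.tile_overlap)
        expected = 1 if length <= hi else math.ceil((length - 20) / (hi - 20))
        assert len(windows) == expected


class TestArmCopyCount:
    def test_unique_arm_counted_once(self):
        ref = {"chr1": "AAAAAAACGTACGTTTGCAAAAAAA"}
        assert arm_copy_count("ACGTACGTTTGC", ref) == 1

    def test_reverse_complement_occurrences_counted(self):
        arm = "ACCGTTGCAC"
        ref = {"chr1": "TTTT" + arm + "TTTT" + revcomp(arm) + "TTTT"}
        assert arm_copy_count(arm, ref) == 2

    def test_palindromic_arm_at_one_locus_counted_once(self):
        arm = "ACGCGT"  # own reverse complement
        assert revcomp(arm) == arm
        ref = {"chr1": "TTTTTT" + arm + "TTTTTT"}
        assert arm_copy_count(arm, ref) == 1

    def test_agrees_with_naive_scan_oracle(self):
        import numpy as np

        rng = np.random.default_rng(5)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=5000))
        ref = {"c1": seq[:3000], "c2": seq[2000:]}
        arm = seq[100:116]

        def oracle():
            hits = set()
            for name, s in ref.items():
                for q in {arm, revcomp(arm)}:
                    for i in range(len(s) - len(q) + 1):
                        if s[i : i + len(q)] == q:
                            hits.add((name, i))
            return len(hits)

        assert arm_copy_count(arm, ref) == oracle()

    def test_repetitive_arm_excluded_by_designer(self):
        arm = "ACGGATCCGTAACGTG"
        ref = {"chr1": ("TTTTT" + arm) * 6 + "T" * 600}
        assert arm_copy_count(arm, ref) == 6
        choice = pick_arms(("chr1", 30, 60), ref, PARAMS)
        if isinstance(choice, ArmRejection):
            assert any("copy count" in r for r in choice.reasons)
        else:  # any accepted arm pair must itself pass the copy-count bound
            assert arm_copy_count(choice.ext_seq, ref) <= PARAMS.max_arm_copy_count
            assert arm_copy_count(choice.lig_seq, ref) <= PARAMS.max_arm_copy_count

    def test_non_acgt_arm_rejected(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            arm_copy_count("ACGTN", {"chr1": "ACGTACGT"})


@pytest.fixture(scope="module")
def unique_ref():
    import numpy as np

    rng = np.random.default_rng(11)
    return {"chr1": "".join("ACGT"[i] for i in rng.integers(0, 4, size=2000))}


class TestPickArms:
    def test_deterministic_tie_break_optimum(self, unique_ref):
        from mipseq.seqs import gc_fraction

        window = ("chr1", 500, 725)
        choice = pick_arms(window, unique_ref, PARAMS)
        assert not isinstance(choice, ArmRejection)
        # exhaustive scan over the 5x5 grid reproduces the same optimum
        best = None
        seq = unique_ref["chr1"]
        for el in range(16, 21):
            for ll in range(20, 25):
                ext, lig = seq[500 - el : 500], seq[725 : 725 + ll]
                key = (abs(gc_fraction(ext) - 0.5) + abs(gc_fraction(lig) - 0.5), -(el + ll), -el)
                if best is None or key < best[0]:
                    best = (key, ext, lig)
        assert (choice.ext_seq, choice.lig_seq) == (best[1], best[2])
        assert pick_arms(window, unique_ref, PARAMS).ext_seq == choice.ext_seq

    def test_low_maf_snp_not_excluded(self, unique_ref):
        snps = [SnpRecord("chr1", 495, "A", "G", 0.005)]
        choice = pick_arms(("chr1", 500, 725), unique_ref, PARAMS, snps)
        assert not isinstance(choice, ArmRejection)
        assert choice.arm_snps == []

    def test_unavoidable_snp_yields_allele_specific_duplicates(self, unique_ref):
        # a common SNP 5 bases into the ligation arm sits inside every candidate
        seq = unique_ref["chr1"]
        pos = 730
        snps = [SnpRecord("chr1", pos, seq[pos], "A" if seq[pos] != "A" else "C", 0.02)]
        choice = pick_arms(("chr1", 500, 725), unique_ref, PARAMS, snps)
        assert not isinstance(choice, ArmRejection)
        assert len(choice.arm_snps) == 1
        region = TargetRegion("chr1", 520, 700, "G1", "e1")
        panel, _ = design_panel(unique_ref, [region], PARAMS, snps)
        notes = sorted(p.allele_note.split("[")[0] for p in panel)
        assert notes == ["variant", "wildtype"]
        wt, var = sorted(panel, key=lambda p: p.allele_note)[::-1]
        assert wt.lig_arm_seq != var.lig_arm_seq

    def test_insufficient_flank_rejected(self, unique_ref):
        rej = pick_arms(("chr1", 5, 230), unique_ref, PARAMS)
        assert isinstance(rej, ArmRejection)
        assert rej.reasons


class TestAssembleOligo:
    def test_lengths_sum(self):
        oligo, warn = assemble_oligo("A" * 20, "C" * 24)
        assert len(oligo) == 79 and not warn

    def test_short_arms_flagged_below_range(self):
        oligo, warn = assemble_oligo("A" * 16, "C" * 20)
        assert len(oligo) == 71 and warn

    def test_empty_arm_is_config_error(self):
        with pytest.raises(ValueError, match="empty arm"):
            assemble_oligo("", "C" * 20)

    def test_linker_without_umi_placeholders_rejected(self):
        with pytest.raises(ValueError, match="N placeholder"):
            assemble_oligo("A" * 20, "C" * 24, linker="G" * 35)


def _probe(chrom, gs, ge, pid="P1", gene="G1"):
    return MipProbe(pid, gene, chrom, "+", "A" * 18, gs - 18, gs, "C" * 22, ge, ge + 22, gs, ge)


class TestValidatePanel:
    def test_complete_tiling_fraction_one(self):
        targets = [TargetRegion("chr1", 100, 300, "G1", "e1")]
        panel = [_probe("chr1", 90, 320)]
        report = validate_panel(panel, targets)
        assert report.covered_fraction == 1.0 and report.uncovered == []

    def test_deleted_window_reported_uncovered(self):
        targets = [TargetRegion("chr1", 0, 660, "G1", "e1")]
        windows = [(0, 230), (215, 445), (430, 660)]
        panel = [_probe("chr1", s, e, pid=f"P{i}") for i, (s, e) in enumerate(windows)]
        report = validate_panel(panel[:1] + panel[2:], targets)
        assert report.uncovered == [("chr1", 230, 430)]

    def test_empty_panel_fraction_zero(self):
        targets = [TargetRegion("chr1", 100, 300, "G1", "e1")]
        report = validate_panel([], targets)
        assert report.covered_fraction == 0.0
        assert report.uncovered == [("chr1", 100, 300)]


class TestPanelIO:
    def test_round_trip_identity(self, sim_reference, sim_panel, tmp_path):
        panel, _ = sim_panel
        tsv = tmp_path / "panel.tsv"
        export_panel(panel, str(tsv), str(tmp_path / "panel.bed"))
        assert read_panel(str(tsv)) == panel

    def test_bed_record_count_equals_probe_count(self, sim_panel, tmp_path):
        panel, _ = sim_panel
        bed = tmp_path / "panel.bed"
        export_panel(panel, str(tmp_path / "panel.tsv"), str(bed))
        assert len(bed.read_text().splitlines()) == len(panel)

    def test_dosage_defaults_to_one(self, sim_panel, tmp_path):
        panel, _ = sim_panel
        tsv = tmp_path / "panel.tsv"
        export_panel(panel, str(tsv))
        assert all(p.dosage == 1.0 for p in read_panel(str(tsv)))

    def test_design_is_deterministic_byte_identical(self, sim_reference, tmp_path):
        ref, bed = sim_reference
        targets = load_targets(bed, pad=20, reference=ref)
        files = []
        for i in (1, 2):
            panel, _ = design_panel(ref, targets)
            path = tmp_path / f"panel{i}.tsv"
            export_panel(panel, str(path))
            files.append(path.read_bytes())
        assert files[0] == files[1]


def test_designed_panel_respects_geometry(sim_reference, sim_panel):
    """Every probe: gap fill in range, arms flanking without overlap, full target cover."""
    ref, _ = sim_reference
    panel, targets = sim_panel
    for p in panel:
        assert 220 <= p.gap_len <= 230
        assert p.ext_end == p.gap_start and p.lig_start == p.gap_end
        assert 16 <= len(p.ext_arm_seq) <= 20 and 20 <= len(p.lig_arm_seq) <= 24
    report = validate_panel(panel, targets, reference=ref)
    assert report.covered_fraction == 1.0
    assert all(max(cc) <= 5 for cc in report.arm_copy_counts.values())
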