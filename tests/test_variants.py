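"""Variant calling, filters, normalization, cohort filter, VCF I/O."""

import pytest

from mipseq.pipeline import UmiFamily
from mipseq.variants import (
    COHORT_ARTIFACT,
    LOW_DEPTH,
    LOW_VAF,
    FilterConfig,
    VariantCall,
    call_sample,
    cohort_filter,
    normalize_variant,
    read_vcf,
    write_vcf,
)

REF = {"g1": "ACGTACGTAA" * 40}  # 400 bp
GAP = (100, 330)


def fams(n_ref, n_alt, alt_consensus, ref_consensus=None):
    """n_ref reference families + n_alt families with the given consensus."""
    gs, ge = GAP
    ref_cons = ref_consensus or REF["g1"][gs:ge]
    out = []
    for i in range(n_ref):
        out.append(UmiFamily("P1", f"R{i:04d}", 2, ref_cons, "g1", gs, ge))
    for i in range(n_alt):
        out.append(UmiFamily("P1", f"A{i:04d}", 2, alt_consensus, "g1", gs, ge))
    return out


def with_sub(pos, base):
    gs, ge = GAP
    cons = REF["g1"][gs:ge]
    off = pos - gs
    assert cons[off] != base
    return cons[:off] + base + cons[off + 1 :]


class TestCallSample:
    def test_midrange_het_passes(self):
        calls = call_sample(fams(20, 20, with_sub(150, "C")), REF, FilterConfig(), "S1")
        (call,) = calls
        assert (call.pos, call.ref, call.alt) == (151, REF["g1"][150], "C")
        assert call.depth == 40 and call.alt_count == 20
        assert call.zygosity == "het" and call.passed

    def test_low_depth_flagged(self):
        calls = call_sample(fams(0, 29, with_sub(150, "C")), REF, FilterConfig(), "S1")
        (call,) = calls
        assert call.depth == 29 and LOW_DEPTH in call.filters
        assert call.zygosity == "hom"

    def test_sub_threshold_fraction_not_reportable(self):
        calls = call_sample(fams(81, 19, with_sub(150, "C")), REF, FilterConfig(), "S1")
        assert all(not c.passed for c in calls)
        assert not any(c.passed for c in calls if c.pos == 151)

    def test_sub_threshold_allele_at_reportable_site_flagged_low_vaf(self):
        families = fams(0, 35, with_sub(150, "C")) + fams(0, 5, with_sub(150, "G"))[0:5]
        # relabel the G families with fresh UMIs so they form distinct families
        for i, f in enumerate(families[35:]):
            f.umi = f"G{i:04d}"
        calls = call_sample(families, REF, FilterConfig(), "S1")
        by_alt = {c.alt: c for c in calls}
        assert by_alt["C"].passed
        assert LOW_VAF in by_alt["G"].filters

    def test_hom_boundary(self):
        calls = call_sample(fams(20, 80, with_sub(150, "C")), REF, FilterConfig(), "S1")
        assert calls[0].zygosity == "hom"
        calls = call_sample(fams(21, 79, with_sub(150, "C")), REF, FilterConfig(), "S1")
        assert calls[0].zygosity == "het"

    def test_consensus_n_excluded_from_depth(self):
        gs, _ = GAP
        cons_n = "N" + REF["g1"][gs + 1 : GAP[1]]
        families = fams(0, 15, with_sub(150, "C")) + [
            UmiFamily("P1", f"N{i:04d}", 1, cons_n, "g1", gs, GAP[1]) for i in range(30)
        ]
        calls = call_sample(families, REF, FilterConfig(), "S1")
        site = [c for c in calls if c.pos == gs + 1]
        assert not site  # no alt at that position, and N bases carry no depth

    def test_empty_pileup_empty_calls(self):
        assert call_sample([], REF, FilterConfig(), "S1") == []

    def test_deletion_called_and_left_aligned(self):
        # delete 2 bases inside the gap fill; anchor precedes the deletion
        gs, ge = GAP
        ref_gap = REF["g1"][gs:ge]
        off = 57
        cons = ref_gap[:off] + ref_gap[off + 2 :]
        calls = call_sample(fams(18, 18, cons), REF, FilterConfig(), "S1")
        indel = [c for c in calls if len(c.ref) > len(c.alt)]
        assert len(indel) == 1
        c = indel[0]
        assert len(c.ref) - len(c.alt) == 2
        assert c.zygosity == "het" and c.passed
        # left-aligned: the base before the reported position differs from
        # the last deleted base (no further left shift possible)
        pos0 = c.pos - 1
        assert normalize_variant(REF["g1"], pos0, c.ref, c.alt) == (pos0, c.ref, c.alt)

    def test_insertion_called(self):
        gs, ge = GAP
        ref_gap = REF["g1"][gs:ge]
        off = 111
        cons = ref_gap[:off] + "TTG" + ref_gap[off:]
        calls = call_sample(fams(0, 40, cons), REF, FilterConfig(), "S1")
        ins = [c for c in calls if len(c.alt) > len(c.ref)]
        assert len(ins) == 1 and ins[0].zygosity == "hom" and ins[0].passed


class TestFilterMonotonicity:
    def test_raising_thresholds_never_adds_pass_calls(self):
        families = fams(25, 10, with_sub(150, "C")) + fams(0, 12, with_sub(280, "G"))
        for f in families[35:]:
            f.umi = "X" + f.umi
        base = {c.key for c in call_sample(families, REF, FilterConfig(), "S") if c.passed}
        for cfg in (FilterConfig(min_depth=40), FilterConfig(min_alt_fraction=0.4)):
            stricter = {c.key for c in call_sample(families, REF, cfg, "S") if c.passed}
            assert stricter <= base


class TestNormalization:
    @pytest.mark.parametrize(
        "seq,pos,ref,alt,expected",
        [
            # repeat region: AC deletion shifts fully left (bcftools norm
            # agrees: g1:3 GCA>G in 1-based coordinates)
            ("GGGCACACACT", 7, "CAC", "C", (2, "GCA", "G")),
            ("GGGCACACACT", 6, "ACA", "A", (2, "GCA", "G")),
            # parsimony: shared suffix and prefix trimmed
            ("ACGTACGT", 2, "GTA", "GCA", (3, "T", "C")),
            # SNV untouched
            ("ACGTACGT", 4, "A", "G", (4, "A", "G")),
        ],
    )
    def test_left_align_parsimonious(self, seq, pos, ref, alt, expected):
        assert normalize_variant(seq, pos, ref, alt) == expected


def mk_call(sid, pos=151, alt="C", filters=()):
    return VariantCall(sid, "g1", pos, "A", alt, 50, 25, "het", set(filters))


class TestCohortFilter:
    def test_above_ninety_percent_flagged(self):
        calls = {f"S{i}": [mk_call(f"S{i}")] for i in range(150)}
        calls.update({f"S{i}": [] for i in range(150, 166)})
        cohort_filter(calls, FilterConfig(), n_samples=166)
        assert all(COHORT_ARTIFACT in c.filters for cs in calls.values() for c in cs)

    def test_below_boundary_kept(self):
        calls = {f"S{i}": [mk_call(f"S{i}")] for i in range(149)}
        calls.update({f"S{i}": [] for i in range(149, 166)})
        cohort_filter(calls, FilterConfig(), n_samples=166)
        assert all(COHORT_ARTIFACT not in c.filters for cs in calls.values() for c in cs)

    def test_single_sample_degenerate_case_flagged(self):
        calls = {"S1": [mk_call("S1")]}
        cohort_filter(calls, FilterConfig())
        assert COHORT_ARTIFACT in calls["S1"][0].filters

    def test_permutation_invariant(self):
        def build():
            return {f"S{i}": [mk_call(f"S{i}")] for i in range(10)}

        a = build()
        b = dict(reversed(list(build().items())))
        cohort_filter(a, FilterConfig())
        cohort_filter(b, FilterConfig())
        assert {s: [sorted(c.filters) for c in cs] for s, cs in a.items()} == {
            s: [sorted(c.filters) for c in cs] for s, cs in b.items()
        }


class TestVcfIO:
    def test_pass_records_round_trip(self, tmp_path):
        calls = [mk_call("S1", pos=p) for p in (151, 201, 251)]
        path = str(tmp_path / "s1.vcf")
        write_vcf(calls, REF, path, "S1")
        text = open(path).read()
        assert text.count("PASS") >= 3
        back = read_vcf(path)
        assert [(c.chrom, c.pos, c.ref, c.alt, c.depth, c.alt_count, c.zygosity) for c in back] == [
            (c.chrom, c.pos, c.ref, c.alt, c.depth, c.alt_count, c.zygosity) for c in calls
        ]

    def test_filters_in_filter_column(self, tmp_path):
        calls = [mk_call("S1", filters=[LOW_DEPTH, LOW_VAF])]
        path = str(tmp_path / "s1.vcf")
        write_vcf(calls, REF, path, "S1")
        (back,) = read_vcf(path)
        assert back.filters == {LOW_DEPTH, LOW_VAF}

    def test_unsorted_input_sorted_on_write(self, tmp_path):
        calls = [mk_call("S1", pos=251), mk_call("S1", pos=151)]
        path = str(tmp_path / "s1.vcf")
        write_vcf(calls, REF, path, "S1")
        back = read_vcf(path)
        assert [c.pos for c in back] == [151, 251]


def test_filter_config_invariants():
    with pytest.raises(ValueError):
        FilterConfig(min_alt_fraction=0.9, het_hom_boundary=0.8)
    with pytest.raises(ValueError):
        FilterConfig(min_depth=0)
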