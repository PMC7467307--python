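"""Variant calling from unique-molecule (UMI-family) pileups.

Substitutions are called from per-position base counts over family consensus
sequences; short indels (<=3 bp) from families whose reconstructed molecule
length differs from the gap fill, identified by exact alternate-fragment
matching. Three filters guard against artifacts:

    LOW_DEPTH        site covered by fewer than 30 unique molecules
    LOW_VAF          allele supported by fewer than 20% of molecules
    COHORT_ARTIFACT  variant present in more than 90% of batch samples

Zygosity is inferred from the allele fraction: heterozygous between the VAF
threshold and the het/hom boundary (default 0.80), homozygous above it.
Internal coordinates are 0-based half-open; VCF output is 1-based, converted
only at the writer boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from mipseq.pipeline import MAX_INDEL, UmiFamily, _encode
from mipseq.seqs import get_chrom_seq

#: Families whose consensus disagrees with the reference at more positions
#: than this are treated as uninterpretable (chimeric capture, multi-indel
#: molecules, or gross misassignment) and contribute no evidence.
MAX_FAMILY_MISMATCHES = 10

LOW_DEPTH = "LOW_DEPTH"
LOW_VAF = "LOW_VAF"
COHORT_ARTIFACT = "COHORT_ARTIFACT"

_BASE = "ACGT"


@dataclass(frozen=True)
class FilterConfig:
    min_depth: int = 30
    min_alt_fraction: float = 0.20
    max_cohort_fraction: float = 0.90
    het_hom_boundary: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.min_alt_fraction < self.het_hom_boundary <= 1:
            raise ValueError("need 0 < min_alt_fraction < het_hom_boundary <= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0 < self.max_cohort_fraction <= 1:
            raise ValueError("max_cohort_fraction must be in (0, 1]")


@dataclass
class VariantCall:
    sample_id: str
    chrom: str
    pos: int  # 1-based (VCF convention)
    ref: str
    alt: str
    depth: int
    alt_count: int
    zygosity: str  # het | hom
    filters: set[str] = field(default_factory=set)

    @property
    def alt_fraction(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def passed(self) -> bool:
        return not self.filters

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def normalize_variant(
    chrom_seq: str, pos0: int, ref: str, alt: str
) -> tuple[int, str, str]:
    """Left-align and make parsimonious a variant against its chromosome."""
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            if len(ref) == 1 or len(alt) == 1:
                if pos0 == 0:
                    break
                base = chrom_seq[pos0 - 1]
                ref = base + ref[:-1]
                alt = base + alt[:-1]
                pos0 -= 1
            else:
                ref, alt = ref[:-1], alt[:-1]
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos0 += 1
    return pos0, ref, alt


def _match_with_n(cons: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Elementwise match allowing N (code 4) in the consensus as a wildcard."""
    return (cons == ref) | (cons == 4)


def _indel_from_family(
    cons: np.ndarray, ref: np.ndarray, consensus: str
) -> tuple[int, str, str] | None:
    """Interpret a length-discordant family consensus as one <=3 bp indel.

    Returns (offset-in-gap-fill, ref_allele, alt_allele) without anchor base,
    using the leftmost exact interpretation, or None if the fragment admits
    no single-indel explanation.
    """
    g, m = len(ref), len(cons)
    k = g - m
    if k == 0 or abs(k) > MAX_INDEL:
        return None
    if k > 0:  # deletion of k ref bases
        pm = np.concatenate(([True], np.cumprod(_match_with_n(cons, ref[:m])).astype(bool)))
        tail = _match_with_n(cons, ref[k:])
        sm = np.concatenate((np.cumprod(tail[::-1]).astype(bool)[::-1], [True]))
        ok = np.nonzero(pm[: m + 1] & sm)[0]
        if len(ok) == 0:
            return None
        p = int(ok[0])
        return p, "".join(_BASE[c] for c in ref[p : p + k]), ""
    k = -k  # insertion of k bases
    pm = np.concatenate(([True], np.cumprod(_match_with_n(cons[:g], ref)).astype(bool)))
    tail = _match_with_n(cons[k:], ref)
    sm = np.concatenate((np.cumprod(tail[::-1]).astype(bool)[::-1], [True]))
    ok = np.nonzero(pm[: g + 1] & sm)[0]
    if len(ok) == 0:
        return None
    p = int(ok[0])
    ins = consensus[p : p + k]
    if "N" in ins:
        return None
    return p, "", ins


def call_sample(
    families: Sequence[UmiFamily],
    reference: Mapping[str, object],
    config: FilterConfig = FilterConfig(),
    sample_id: str = "sample",
) -> list[VariantCall]:
    """Call substitutions and short indels from one sample's UMI families.

    A site is reported when some non-reference allele reaches the VAF
    threshold; sub-threshold alleles at reported sites are emitted flagged
    LOW_VAF. Consensus N bases do not count toward substitution depth.
    """
    if not families:
        return []
    chroms = sorted({f.chrom for f in families})
    seqs = {c: get_chrom_seq(reference, c) for c in chroms}
    enc_ref = {c: _encode(seqs[c]) for c in chroms}
    counts = {c: np.zeros((4, len(seqs[c])), dtype=np.int32) for c in chroms}
    span = {c: np.zeros(len(seqs[c]), dtype=np.int32) for c in chroms}
    indel_obs: dict[tuple[str, int, str, str], int] = {}

    for fam in families:
        cons = _encode(fam.consensus)
        gref = enc_ref[fam.chrom][fam.gap_start : fam.gap_end]
        if fam.molecule_len == fam.gap_len:
            mask = cons < 4
            if int(((cons != gref) & mask).sum()) > MAX_FAMILY_MISMATCHES:
                continue  # uninterpretable fragment; contributes no evidence
            span[fam.chrom][fam.gap_start : fam.gap_end] += 1
            pos = np.arange(fam.gap_start, fam.gap_end)[mask]
            np.add.at(counts[fam.chrom], (cons[mask], pos), 1)
            continue
        hit = _indel_from_family(cons, gref, fam.consensus)
        if hit is None:
            continue  # uninterpretable fragment; contributes no evidence
        span[fam.chrom][fam.gap_start : fam.gap_end] += 1
        off, dref, dalt = hit
        # substitution-space evidence from the aligned (non-indel) portion
        k = len(dref) - len(dalt)
        if k > 0:  # deletion: cons[off:] maps k bases downstream
            pos = np.concatenate(
                (np.arange(fam.gap_start, fam.gap_start + off),
                 np.arange(fam.gap_start + off + k, fam.gap_end))
            )
            aligned = cons
        else:  # insertion: skip the inserted bases
            pos = np.arange(fam.gap_start, fam.gap_end)
            aligned = np.concatenate((cons[:off], cons[off - k :]))
        mask = aligned < 4
        np.add.at(counts[fam.chrom], (aligned[mask], pos[mask]), 1)
        pos0 = fam.gap_start + off
        # anchor on the preceding reference base (VCF style)
        if pos0 > 0:
            anchor = seqs[fam.chrom][pos0 - 1]
            vref, valt, vpos = anchor + dref, anchor + dalt, pos0 - 1
        else:
            anchor = seqs[fam.chrom][pos0 + len(dref)]
            vref, valt, vpos = dref + anchor, dalt + anchor, pos0
        vpos, vref, valt = normalize_variant(seqs[fam.chrom], vpos, vref, valt)
        indel_obs[(fam.chrom, vpos, vref, valt)] = (
            indel_obs.get((fam.chrom, vpos, vref, valt), 0) + 1
        )

    calls: list[VariantCall] = []
    cfg = config
    for c in chroms:
        depth = counts[c].sum(axis=0)
        ref_codes = enc_ref[c]
        with np.errstate(divide="ignore", invalid="ignore"):
            fracs = counts[c] / np.maximum(depth, 1)
        alt_mask = np.zeros(len(depth), dtype=bool)
        for b in range(4):
            alt_mask |= (ref_codes != b) & (fracs[b] >= cfg.min_alt_fraction) & (counts[c][b] > 0)
        for pos in np.nonzero(alt_mask & (depth > 0))[0]:
            d = int(depth[pos])
            rb = _BASE[ref_codes[pos]] if ref_codes[pos] < 4 else "N"
            for b in range(4):
                n_alt = int(counts[c][b, pos])
                if b == ref_codes[pos] or n_alt == 0:
                    continue
                f = n_alt / d
                filters: set[str] = set()
                if d < cfg.min_depth:
                    filters.add(LOW_DEPTH)
                if f < cfg.min_alt_fraction:
                    filters.add(LOW_VAF)
                zyg = "hom" if f >= cfg.het_hom_boundary else "het"
                calls.append(
                    VariantCall(sample_id, c, int(pos) + 1, rb, _BASE[b], d, n_alt, zyg, filters)
                )

    for (c, pos0, vref, valt), n_alt in sorted(indel_obs.items()):
        d = int(span[c][pos0])
        f = n_alt / d if d else 0.0
        if f < cfg.min_alt_fraction:
            continue
        filters = set()
        if d < cfg.min_depth:
            filters.add(LOW_DEPTH)
        zyg = "hom" if f >= cfg.het_hom_boundary else "het"
        calls.append(VariantCall(sample_id, c, pos0 + 1, vref, valt, d, n_alt, zyg, filters))

    calls.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    return calls


def cohort_filter(
    calls_by_sample: Mapping[str, list[VariantCall]],
    config: FilterConfig = FilterConfig(),
    n_samples: int | None = None,
) -> Mapping[str, list[VariantCall]]:
    """Flag variants present in more than max_cohort_fraction of samples.

    Presence means the variant was emitted for the sample (any filter
    status). The flag is added in place in every carrying sample; the result
    is permutation-invariant in sample order.
    """
    n = n_samples if n_samples is not None else len(calls_by_sample)
    if n < 1:
        raise ValueError("n_samples must be >= 1")
    carriers: dict[tuple, set[str]] = {}
    for sid, calls in calls_by_sample.items():
        for call in calls:
            carriers.setdefault(call.key, set()).add(sid)
    artifacts = {k for k, s in carriers.items() if len(s) > config.max_cohort_fraction * n}
    for calls in calls_by_sample.values():
        for call in calls:
            if call.key in artifacts:
                call.filters.add(COHORT_ARTIFACT)
    return calls_by_sample


# ---------------------------------------------------------------------------
# VCF I/O


def write_vcf(
    calls: Sequence[VariantCall],
    reference: Mapping[str, object],
    path: str,
    sample_id: str | None = None,
) -> None:
    """Write calls as VCF 4.2 with DP/AD/VAF FORMAT fields."""
    import pysam

    header = pysam.VariantHeader()
    for chrom in _chrom_names(reference):
        header.contigs.add(chrom, length=len(get_chrom_seq(reference, chrom)))
    for flt, desc in [
        (LOW_DEPTH, "Unique-molecule depth below threshold"),
        (LOW_VAF, "Allele fraction below threshold"),
        (COHORT_ARTIFACT, "Present in more than the allowed fraction of cohort samples"),
    ]:
        header.filters.add(flt, None, None, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Unique-molecule depth")
    header.formats.add("AD", "R", "Integer", "Allele depths (unique molecules)")
    header.formats.add("VAF", 1, "Float", "Alternate allele fraction")
    sid = sample_id or (calls[0].sample_id if calls else "sample")
    header.add_sample(sid)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for call in sorted(calls, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
            rec = vf.new_record(
                contig=call.chrom,
                start=call.pos - 1,
                alleles=(call.ref, call.alt),
            )
            if call.filters:
                for flt in sorted(call.filters):
                    rec.filter.add(flt)
            else:
                rec.filter.add("PASS")
            rec.samples[sid]["GT"] = (1, 1) if call.zygosity == "hom" else (0, 1)
            rec.samples[sid]["DP"] = call.depth
            rec.samples[sid]["AD"] = (call.depth - call.alt_count, call.alt_count)
            rec.samples[sid]["VAF"] = call.alt_fraction
            vf.write(rec)


def read_vcf(path: str) -> list[VariantCall]:
    import pysam

    out = []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            sid = samples[0] if samples else "sample"
            filters = {f for f in rec.filter.keys() if f != "PASS"}
            fmt = rec.samples[sid] if samples else {}
            dp = int(fmt.get("DP") or 0)
            ad = fmt.get("AD") or (0, 0)
            gt = fmt.get("GT") or (0, 1)
            zyg = "hom" if tuple(gt) == (1, 1) else "het"
            for alt in rec.alts or ():
                out.append(
                    VariantCall(
                        sid, rec.chrom, rec.pos, rec.ref, alt, dp,
                        int(ad[1]) if len(ad) > 1 else 0, zyg, set(filters),
                    )
                )
    return out


def _chrom_names(reference: Mapping[str, object]):
    keys = getattr(reference, "keys", None)
    return list(keys()) if keys is not None else list(reference)
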