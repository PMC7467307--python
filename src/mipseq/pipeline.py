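"""MIP read processing: arm matching, trimming, UMI de-duplication, coverage.

Reads are assigned to probes by matching the extension arm at its known
offset in read1 (after the 5-nt UMI) and confirming the ligation arm at the
start of read2 — no genome alignment is involved; the arms are sequence-exact
anchors, so the remaining bases map to gap-fill coordinates by offset.
Read pairs sharing a (probe, UMI) pair are collapsed into one UMI family
whose consensus is the strict per-position majority; families — not raw
reads — are the unit of coverage and of variant evidence.

Short insertions/deletions change the captured fragment's length, so the
family consensus is built at the molecule length (gap-fill length +/- up to
3 bp) that makes the two mates agree in their overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from mipseq.panel import MipProbe
from mipseq.seqs import hamming, revcomp

MAX_INDEL = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.frombuffer(b"ACGTN", dtype="S1")
_ENC = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENC[ord(_b)] = _c
    _ENC[ord(_b.lower())] = _c


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class Assignment:
    """One read pair assigned to a probe: UMI plus offset-mapped fragment halves."""

    probe_id: str
    umi: str
    left_frag: str  # read1 bases after UMI+arm, left-anchored at gap-fill start
    right_frag: str  # read2-derived bases, right-anchored at gap-fill end


@dataclass
class UmiFamily:
    """Reads sharing (probe, UMI), collapsed to one consensus molecule."""

    probe_id: str
    umi: str
    read_count: int
    consensus: str
    chrom: str
    gap_start: int
    gap_end: int

    @property
    def molecule_len(self) -> int:
        return len(self.consensus)

    @property
    def gap_len(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class CoverageProfile:
    """Per-base unique-molecule depth over targets plus per-probe summaries."""

    depth: dict[str, np.ndarray]
    target_intervals: list[tuple[str, int, int]]
    per_probe: dict[str, int]
    probe_stats: dict[str, tuple[float, float]]  # probe_id -> (mean, median)

    def depth_at(self, chrom: str, pos: int) -> int:
        arr = self.depth.get(chrom)
        if arr is None or pos >= len(arr):
            return 0
        return int(arr[pos])


@dataclass
class ProbePerformance:
    probe_id: str
    unique_reads: int
    category: str  # failed | poor | adequate
    recommendation: str  # replace | boost_5x | none
    new_dosage: float


class ArmIndex:
    """Lookup from extension-arm sequence (at read1 offset umi_len) to probes.

    Duplicate arm sequences across probes are kept as ambiguous keys; the
    assignment step disambiguates via the ligation arm, then the smallest
    probe id.
    """

    def __init__(self, panel: Sequence[MipProbe]):
        ids = [p.probe_id for p in panel]
        if len(set(ids)) != len(ids):
            raise ValueError("panel contains duplicate probe ids")
        self.probes: dict[str, MipProbe] = {p.probe_id: p for p in panel}
        self.exact: dict[str, list[MipProbe]] = {}
        self.arm_lengths: list[int] = sorted({len(p.ext_arm_seq) for p in panel})
        self.umi_len: int = panel[0].umi_len if panel else 5
        for p in sorted(panel, key=lambda p: p.probe_id):
            self.exact.setdefault(p.ext_arm_seq.upper(), []).append(p)

    def __len__(self) -> int:
        return len(self.exact)

    def candidates(self, read1: str, max_mismatch: int = 0) -> list[MipProbe]:
        u = self.umi_len
        out: list[MipProbe] = []
        for length in self.arm_lengths:
            key = read1[u : u + length].upper()
            out.extend(self.exact.get(key, ()))
        if out or max_mismatch == 0:
            return out
        for probe in self.probes.values():
            arm = probe.ext_arm_seq
            if hamming(read1[u : u + len(arm)].upper(), arm.upper()) <= max_mismatch:
                out.append(probe)
        return sorted(out, key=lambda p: p.probe_id)


def build_arm_index(panel: Sequence[MipProbe]) -> ArmIndex:
    return ArmIndex(panel)


def assign_and_trim(
    read1: str, read2: str, index: ArmIndex, max_mismatch: int = 1
) -> Assignment | None:
    """Assign a read pair to a probe and trim UMI + arms.

    Returns None (unassigned) when no probe's two arms both match within
    ``max_mismatch`` — this includes chimeric pairs whose mates match
    different probes.
    """
    u = index.umi_len
    if len(read1) <= u + (index.arm_lengths[-1] if index.arm_lengths else 0):
        return None
    umi = read1[:u].upper()
    exact = assign_candidates = index.candidates(read1, 0)
    if not assign_candidates and max_mismatch > 0:
        assign_candidates = index.candidates(read1, max_mismatch)
    best: MipProbe | None = None
    for probe in sorted(assign_candidates, key=lambda p: (p not in exact, p.probe_id)):
        lig_rc = revcomp(probe.lig_arm_seq).upper()
        if hamming(read2[: len(lig_rc)].upper(), lig_rc) <= max_mismatch:
            best = probe
            break
    if best is None:
        return None
    left = read1[u + len(best.ext_arm_seq) :].upper()
    rc2 = revcomp(read2).upper()
    right = rc2[: len(rc2) - len(best.lig_arm_seq)]
    return Assignment(best.probe_id, umi, left, right)


# ---------------------------------------------------------------------------
# UMI de-duplication and consensus


def _vote_counts(frags: list[str], anchor_left: bool, width: int) -> np.ndarray:
    """5 x width matrix of base votes; fragments anchored left or right."""
    counts = np.zeros((5, width), dtype=np.int32)
    for frag in frags:
        arr = _encode(frag)
        if len(arr) > width:
            arr = arr[:width] if anchor_left else arr[-width:]
        pos = np.arange(len(arr)) if anchor_left else np.arange(width - len(arr), width)
        np.add.at(counts, (arr, pos), 1)
    return counts


def _majority(counts: np.ndarray) -> np.ndarray:
    """Strict-majority base per column among non-N votes; tie or no votes -> N."""
    base_counts = counts[:4]
    totals = base_counts.sum(axis=0)
    best = base_counts.argmax(axis=0)
    best_n = base_counts.max(axis=0)
    maj = np.where((totals > 0) & (best_n * 2 > totals), best, 4)
    return maj.astype(np.uint8)


def _family_consensus(
    lefts: list[str], rights: list[str], gap_len: int
) -> tuple[str, int]:
    """Consensus sequence and chosen molecule length for one UMI family.

    The molecule length is gap_len unless shifting by up to MAX_INDEL bases
    makes the two mates' overlap agree better (evidence of a short indel).
    """
    max_l = max((len(s) for s in lefts), default=0)
    max_r = max((len(s) for s in rights), default=0)
    lcounts = _vote_counts(lefts, True, max_l)
    rcounts = _vote_counts(rights, False, max_r)
    lmaj = _majority(lcounts)
    rmaj = _majority(rcounts)

    def conflicts(m: int) -> int:
        r_off = m - max_r  # molecule position of rights[0]
        lo, hi = max(0, r_off), min(max_l, m)
        if lo >= hi:
            return 0
        lseg = lmaj[lo:hi]
        rseg = rmaj[lo - r_off : hi - r_off]
        both = (lseg != 4) & (rseg != 4)
        return int(((lseg != rseg) & both).sum())

    m = gap_len
    if conflicts(gap_len) > 0:
        cands = sorted(
            range(max(1, gap_len - MAX_INDEL), gap_len + MAX_INDEL + 1),
            key=lambda x: (conflicts(x), abs(x - gap_len), x),
        )
        m = cands[0]

    counts = np.zeros((5, m), dtype=np.int32)
    w_l = min(max_l, m)
    counts[:, :w_l] += lcounts[:, :w_l]
    r_off = m - max_r
    if r_off >= 0:
        counts[:, r_off:] += rcounts
    else:
        counts += rcounts[:, -r_off:]
    return _DECODE[_majority(counts)].tobytes().decode(), m


def dedup(
    assignments: Iterable[Assignment], panel: Sequence[MipProbe] | Mapping[str, MipProbe]
) -> list[UmiFamily]:
    """Collapse assigned read pairs into UMI families.

    One family per distinct (probe_id, UMI); consensus by strict per-position
    majority, ties encoded as N. Output order is (probe_id, umi), independent
    of input order.
    """
    probes = panel if isinstance(panel, Mapping) else {p.probe_id: p for p in panel}
    groups: dict[tuple[str, str], tuple[list[str], list[str]]] = {}
    for a in assignments:
        lefts, rights = groups.setdefault((a.probe_id, a.umi), ([], []))
        lefts.append(a.left_frag)
        rights.append(a.right_frag)
    families = []
    for (probe_id, umi), (lefts, rights) in sorted(groups.items()):
        probe = probes[probe_id]
        consensus, _ = _family_consensus(lefts, rights, probe.gap_len)
        families.append(
            UmiFamily(
                probe_id=probe_id,
                umi=umi,
                read_count=len(lefts),
                consensus=consensus,
                chrom=probe.chrom,
                gap_start=probe.gap_start,
                gap_end=probe.gap_end,
            )
        )
    return families


def process_fastq(
    fq1_path: str,
    fq2_path: str,
    panel: Sequence[MipProbe],
    max_mismatch: int = 1,
) -> tuple[list[Assignment], int]:
    """Assign every read pair in a FASTQ pair; returns (assignments, n_unassigned)."""
    import pysam

    index = build_arm_index(panel)
    assigned: list[Assignment] = []
    unassigned = 0
    with pysam.FastxFile(fq1_path) as f1, pysam.FastxFile(fq2_path) as f2:
        for r1, r2 in zip(f1, f2):
            a = assign_and_trim(r1.sequence, r2.sequence, index, max_mismatch)
            if a is None:
                unassigned += 1
            else:
                assigned.append(a)
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Coverage


def coverage(
    families: Sequence[UmiFamily],
    panel: Sequence[MipProbe],
    targets: Sequence,
) -> CoverageProfile:
    """Per-base unique-molecule depth and per-probe family counts.

    A family covers every base of its probe's gap fill; depth at a base is
    the number of families spanning it.
    """
    sizes: dict[str, int] = {}
    for p in panel:
        sizes[p.chrom] = max(sizes.get(p.chrom, 0), p.gap_end)
    t_iv = [(t.chrom, t.start, t.end) for t in targets]
    for chrom, s, e in t_iv:
        sizes[chrom] = max(sizes.get(chrom, 0), e)
    depth = {chrom: np.zeros(n, dtype=np.int32) for chrom, n in sizes.items()}
    per_probe = {p.probe_id: 0 for p in panel}
    for fam in families:
        depth[fam.chrom][fam.gap_start : fam.gap_end] += 1
        per_probe[fam.probe_id] = per_probe.get(fam.probe_id, 0) + 1
    stats = {}
    for p in panel:
        d = depth[p.chrom][p.gap_start : p.gap_end]
        stats[p.probe_id] = (float(d.mean()), float(np.median(d)))
    return CoverageProfile(depth, t_iv, per_probe, stats)


def pct_covered(profile: CoverageProfile, threshold: int = 30) -> float:
    """Percentage of target bases with unique-molecule depth strictly above
    the threshold (the ">30x per bp" criterion is read strictly)."""
    total = 0
    above = 0
    for chrom, s, e in profile.target_intervals:
        d = profile.depth[chrom][s:e]
        total += e - s
        above += int((d > threshold).sum())
    return 100.0 * above / total if total else 0.0


def write_bedgraph(profile: CoverageProfile, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(profile.depth):
            d = profile.depth[chrom]
            edges = np.nonzero(np.diff(d))[0] + 1
            starts = np.concatenate(([0], edges))
            ends = np.concatenate((edges, [len(d)]))
            for s, e in zip(starts, ends):
                if d[s]:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(d[s])}\n")


# ---------------------------------------------------------------------------
# Probe performance / rebalancing


def probe_performance(
    counts: Mapping[str, int], boost_mode: str = "augment"
) -> list[ProbePerformance]:
    """Classify probes from a pilot batch and recommend rebalancing.

    0 unique reads -> failed/replace; 1-30 -> poor/boost_5x (a 5-fold
    concentration of the probe is added to the pool, so its dosage becomes
    6x in augment mode, 5x in replace mode); >30 -> adequate.
    """
    if boost_mode not in ("augment", "replace"):
        raise ValueError("boost_mode must be 'augment' or 'replace'")
    boosted = 6.0 if boost_mode == "augment" else 5.0
    out = []
    for probe_id in sorted(counts):
        n = counts[probe_id]
        if n < 0:
            raise ValueError(f"negative unique-read count for {probe_id}")
        if n == 0:
            cat, rec, dose = "failed", "replace", 1.0
        elif n <= 30:
            cat, rec, dose = "poor", "boost_5x", boosted
        else:
            cat, rec, dose = "adequate", "none", 1.0
        out.append(ProbePerformance(probe_id, n, cat, rec, dose))
    return out


def apply_rebalance(
    panel: Sequence[MipProbe], performances: Sequence[ProbePerformance]
) -> list[MipProbe]:
    """Return a new panel with boosted dosages applied (failed probes kept
    at dosage 1; physically they would be replaced by redesigned probes)."""
    from dataclasses import replace as dc_replace

    doses = {p.probe_id: p.new_dosage for p in performances}
    return [dc_replace(p, dosage=doses.get(p.probe_id, p.dosage)) for p in panel]


def write_families(families: Sequence[UmiFamily], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("probe_id\tumi\tread_count\tchrom\tgap_start\tgap_end\tconsensus\n")
        for f in families:
            fh.write(
                f"{f.probe_id}\t{f.umi}\t{f.read_count}\t{f.chrom}\t"
                f"{f.gap_start}\t{f.gap_end}\t{f.consensus}\n"
            )


def read_families(path: str) -> list[UmiFamily]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["probe_id", "umi"]:
            raise ValueError("not a families TSV")
        for line in fh:
            pid, umi, rc, chrom, gs, ge, cons = line.rstrip("\n").split("\t")
            out.append(UmiFamily(pid, umi, int(rc), cons, chrom, int(gs), int(ge)))
    return out
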