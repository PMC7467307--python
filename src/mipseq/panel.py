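"""MIP panel design.

A molecular inversion probe (MIP) is a single-stranded oligo whose two
targeting arms — an extension arm and a ligation arm — hybridize immediately
flanking a genomic region of interest (the *gap fill*, here 220–230 nt).
The arms are joined by a common linker carrying a 5-nt unique molecular
identifier (UMI). Panel design tiles every padded target exon with gap-fill
windows (>=20 bp overlap between neighbours), picks arm lengths from the
admissible ranges (extension 16–20 nt, ligation 20–24 nt), and excludes
probes whose arms are repetitive in the reference (copy count > 5) or
contain a common SNP (population minor allele frequency > 1%). Where a
common SNP in an arm is unavoidable, two allele-specific probes are emitted,
one matching each allele.

All genomic coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from mipseq.seqs import (
    VALID_BASES,
    gc_fraction,
    get_chrom_seq,
    merge_intervals,
    revcomp,
    subtract_intervals,
)

logger = logging.getLogger(__name__)

#: Common linker backbone joining the two arms, with the 5-nt UMI as N
#: placeholders. The backbone carries the two universal PCR primer sites.
DEFAULT_LINKER = "CTTCAGCTTCCCGATATCCGACGGTAGTGT" + "NNNNN"

PANEL_COLUMNS = [
    "probe_id",
    "gene",
    "chrom",
    "strand",
    "ext_arm_seq",
    "ext_start",
    "ext_end",
    "lig_arm_seq",
    "lig_start",
    "lig_end",
    "gap_start",
    "gap_end",
    "oligo",
    "umi_len",
    "dosage",
    "allele_note",
]


@dataclass(frozen=True)
class TargetRegion:
    """A padded target interval (typically an exon ±20 bp of flanking intron)."""

    chrom: str
    start: int
    end: int
    gene: str = ""
    exon: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid target interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class DesignParams:
    """Probe-geometry and exclusion parameters for panel design."""

    ext_arm_len_range: tuple[int, int] = (16, 20)
    lig_arm_len_range: tuple[int, int] = (20, 24)
    linker_len: int = 30
    umi_len: int = 5
    gap_fill_range: tuple[int, int] = (220, 230)
    tile_overlap: int = 20
    max_arm_copy_count: int = 5
    snp_maf_threshold: float = 0.01
    oligo_len_range: tuple[int, int] = (77, 80)

    def __post_init__(self) -> None:
        for name in ("ext_arm_len_range", "lig_arm_len_range", "gap_fill_range", "oligo_len_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise ValueError(f"empty or invalid range for {name}: ({lo}, {hi})")
        if not 0 < self.snp_maf_threshold < 1:
            raise ValueError("snp_maf_threshold must be in (0, 1)")
        if self.tile_overlap >= self.gap_fill_range[0]:
            raise ValueError("tile_overlap must be smaller than the minimum gap fill")


@dataclass
class MipProbe:
    """A designed probe: arms, gap fill, assembled oligo, pool dosage."""

    probe_id: str
    gene: str
    chrom: str
    strand: str
    ext_arm_seq: str
    ext_start: int
    ext_end: int
    lig_arm_seq: str
    lig_start: int
    lig_end: int
    gap_start: int
    gap_end: int
    oligo: str = ""
    umi_len: int = 5
    dosage: float = 1.0
    allele_note: str = ""

    @property
    def gap_len(self) -> int:
        return self.gap_end - self.gap_start


@dataclass
class SnpRecord:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    maf: float


@dataclass
class ArmRejection:
    """No admissible arm pair for a window; carries the failing constraints."""

    window: tuple[str, int, int]
    reasons: list[str] = field(default_factory=list)


@dataclass
class PanelValidationReport:
    covered_fraction: float
    uncovered: list[tuple[str, int, int]]
    arm_copy_counts: dict[str, tuple[int, int]]
    snp_flags: dict[str, bool]

    @property
    def fully_covered(self) -> bool:
        return not self.uncovered


# ---------------------------------------------------------------------------
# Targets


def load_targets(
    bed_path: str,
    pad: int = 20,
    reference: Mapping[str, object] | None = None,
) -> list[TargetRegion]:
    """Read a BED of target exons, pad symmetrically, and merge overlaps.

    The BED name column (4th) is expected to follow the ``gene|exon``
    convention. Padded records on the same chromosome that overlap or are
    bookended are merged; the merged gene/exon labels are the comma-joined
    unique labels. With a reference given, out-of-bounds records raise.
    """
    if pad < 0:
        raise ValueError("pad must be >= 0")
    raw: list[TargetRegion] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}: expected >=3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise ValueError(f"malformed BED line {lineno}: invalid interval {start}-{end}")
            name = fields[3] if len(fields) > 3 else f"region{lineno}"
            gene, _, exon = name.partition("|")
            if reference is not None:
                if chrom not in reference:
                    raise ValueError(f"BED line {lineno}: unknown sequence {chrom!r}")
                seqlen = len(reference[chrom])
                if end > seqlen:
                    raise ValueError(
                        f"BED line {lineno}: interval {start}-{end} outside {chrom} (len {seqlen})"
                    )
            pstart = max(0, start - pad)
            pend = end + pad
            if reference is not None:
                pend = min(pend, len(reference[chrom]))
            raw.append(TargetRegion(chrom, pstart, pend, gene, exon))

    merged: list[TargetRegion] = []
    for region in sorted(raw, key=lambda r: (r.chrom, r.start, r.end)):
        if merged and region.chrom == merged[-1].chrom and region.start <= merged[-1].end:
            prev = merged[-1]
            genes = list(dict.fromkeys(g for g in (prev.gene + "," + region.gene).split(",") if g))
            exons = list(dict.fromkeys(e for e in (prev.exon + "," + region.exon).split(",") if e))
            merged[-1] = TargetRegion(
                prev.chrom,
                prev.start,
                max(prev.end, region.end),
                ",".join(genes),
                ",".join(exons),
            )
        else:
            merged.append(region)
    return merged


# ---------------------------------------------------------------------------
# Tiling


def min_window_count(length: int, gap_max: int, overlap: int) -> int:
    """Closed-form minimum number of tiling windows for a region."""
    if length <= gap_max:
        return 1
    return math.ceil((length - overlap) / (gap_max - overlap))


def tile_region(region: TargetRegion, params: DesignParams) -> list[tuple[int, int]]:
    """Gap-fill windows covering the region with >=tile_overlap bp overlap.

    The number of windows is the minimum possible given the maximum gap-fill
    length; windows are spread evenly so overlaps are balanced. Regions
    shorter than the minimum gap fill get one window extending symmetrically
    into the flanks.
    """
    gap_min, gap_max = params.gap_fill_range
    length = len(region)
    if length <= gap_max:
        win = max(gap_min, length)
        extra = win - length
        start = region.start - extra // 2
        return [(start, start + win)]
    n = min_window_count(length, gap_max, params.tile_overlap)
    win = gap_max
    span = length - win  # distance between first and last window starts
    starts = [region.start + round(i * span / (n - 1)) for i in range(n)]
    return [(s, s + win) for s in starts]


# ---------------------------------------------------------------------------
# Arm selection


def arm_copy_count(arm_seq: str, reference: Mapping[str, object]) -> int:
    """Exact occurrences of an arm and its reverse complement in the reference.

    Overlapping occurrences are counted; a palindromic arm occurring at one
    locus is counted once (forward and reverse hits at identical positions
    collapse).
    """
    arm = arm_seq.upper()
    if not arm:
        raise ValueError("empty arm sequence")
    if set(arm) - VALID_BASES:
        raise ValueError(f"arm contains non-ACGT symbols: {arm_seq!r}")
    queries = {arm, revcomp(arm)}
    hits: set[tuple[str, int]] = set()
    for chrom in _chrom_names(reference):
        seq = get_chrom_seq(reference, chrom)
        for q in queries:
            i = seq.find(q)
            while i != -1:
                hits.add((chrom, i))
                i = seq.find(q, i + 1)
    return len(hits)


def _chrom_names(reference: Mapping[str, object]) -> Iterable[str]:
    keys = getattr(reference, "keys", None)
    return list(keys()) if keys is not None else list(reference)


@dataclass
class ArmChoice:
    ext_seq: str
    ext_start: int
    ext_end: int
    lig_seq: str
    lig_start: int
    lig_end: int
    #: SNPs (>= MAF threshold) inside the chosen arms; non-empty means the
    #: caller should emit allele-specific duplicate probes.
    arm_snps: list[SnpRecord] = field(default_factory=list)


def _snps_in(snp_table: Sequence[SnpRecord], chrom: str, start: int, end: int, maf: float) -> list[SnpRecord]:
    return [
        s
        for s in snp_table
        if s.chrom == chrom and start <= s.pos < end and s.maf >= maf and len(s.ref) == 1
    ]


def pick_arms(
    window: tuple[str, int, int],
    reference: Mapping[str, object],
    params: DesignParams,
    snp_table: Sequence[SnpRecord] | None = None,
) -> ArmChoice | ArmRejection:
    """Choose extension/ligation arm lengths for one gap-fill window.

    All (ext, lig) length pairs on the 5x5 grid are scanned. Candidates whose
    arms are repetitive (copy count above threshold) or contain ambiguous
    bases are discarded. Among the survivors, SNP-free pairs are preferred;
    the winner minimizes |GC(ext)-0.5| + |GC(lig)-0.5|, ties broken by longer
    total arm length, then longer extension arm — a deterministic
    melting-temperature-balancing proxy. If every admissible pair contains a
    common SNP, the best pair is returned with the SNPs attached so the
    caller can emit allele-specific duplicates.
    """
    chrom, wstart, wend = window
    seq = get_chrom_seq(reference, chrom)
    snp_table = snp_table or []
    reasons: list[str] = []
    clean: list[tuple[tuple, ArmChoice]] = []
    snpful: list[tuple[tuple, ArmChoice]] = []
    max_ext = params.ext_arm_len_range[1]
    max_lig = params.lig_arm_len_range[1]
    if wstart - max_ext < 0 or wend + max_lig > len(seq):
        return ArmRejection(window, ["insufficient flanking sequence for arms"])
    for el in range(params.ext_arm_len_range[0], params.ext_arm_len_range[1] + 1):
        for ll in range(params.lig_arm_len_range[0], params.lig_arm_len_range[1] + 1):
            ext = seq[wstart - el : wstart]
            lig = seq[wend : wend + ll]
            if set(ext) - VALID_BASES or set(lig) - VALID_BASES:
                reasons.append(f"ambiguous bases in arms (ext={el}, lig={ll})")
                continue
            cc_ext = arm_copy_count(ext, reference)
            cc_lig = arm_copy_count(lig, reference)
            if cc_ext > params.max_arm_copy_count or cc_lig > params.max_arm_copy_count:
                reasons.append(
                    f"arm copy count ext={cc_ext} lig={cc_lig} exceeds {params.max_arm_copy_count}"
                )
                continue
            snps = _snps_in(snp_table, chrom, wstart - el, wstart, params.snp_maf_threshold)
            snps += _snps_in(snp_table, chrom, wend, wend + ll, params.snp_maf_threshold)
            choice = ArmChoice(ext, wstart - el, wstart, lig, wend, wend + ll, snps)
            key = (
                abs(gc_fraction(ext) - 0.5) + abs(gc_fraction(lig) - 0.5),
                -(el + ll),
                -el,
            )
            (clean if not snps else snpful).append((key, choice))
    if clean:
        return min(clean, key=lambda kc: kc[0])[1]
    if snpful:
        return min(snpful, key=lambda kc: kc[0])[1]
    return ArmRejection(window, reasons or ["no admissible arm pair"])


# ---------------------------------------------------------------------------
# Oligo assembly


def assemble_oligo(ext_seq: str, lig_seq: str, linker: str = DEFAULT_LINKER,
                   params: DesignParams = DesignParams()) -> tuple[str, bool]:
    """Assemble the probe oligo: extension arm + linker (with UMI Ns) + ligation arm.

    The linker is the common backbone plus the UMI placeholder positions
    (``N``); its length must be linker_len + umi_len with exactly umi_len Ns.
    Returns the oligo and a flag that is True when the total length falls
    outside the nominal oligo length range (a warning, not a rejection).
    """
    if not ext_seq or not lig_seq:
        raise ValueError("empty arm sequence")
    if len(linker) != params.linker_len + params.umi_len:
        raise ValueError(
            f"linker must be {params.linker_len + params.umi_len} nt "
            f"(backbone {params.linker_len} + {params.umi_len} UMI placeholders)"
        )
    if linker.count("N") != params.umi_len:
        raise ValueError(f"linker must contain exactly {params.umi_len} N placeholder positions")
    oligo = ext_seq + linker + lig_seq
    lo, hi = params.oligo_len_range
    out_of_range = not lo <= len(oligo) <= hi
    if out_of_range:
        logger.warning("oligo length %d outside nominal range [%d, %d]", len(oligo), lo, hi)
    return oligo, out_of_range


# ---------------------------------------------------------------------------
# Panel design driver


def design_panel(
    reference: Mapping[str, object],
    targets: Sequence[TargetRegion],
    params: DesignParams = DesignParams(),
    snp_table: Sequence[SnpRecord] | None = None,
    linker: str = DEFAULT_LINKER,
) -> tuple[list[MipProbe], list[ArmRejection]]:
    """Design probes for every target; returns (panel, rejected windows).

    Windows with an unavoidable common SNP in the arms yield two probes, one
    matching each allele (wild-type and variant-matched duplicate).
    """
    panel: list[MipProbe] = []
    rejections: list[ArmRejection] = []
    counter = 0
    for region in targets:
        for wstart, wend in tile_region(region, params):
            choice = pick_arms((region.chrom, wstart, wend), reference, params, snp_table)
            if isinstance(choice, ArmRejection):
                rejections.append(choice)
                continue
            counter += 1
            base_id = f"MIP{counter:04d}_{region.gene or region.chrom}"
            variants = _allele_variants(choice)
            for suffix, ext_seq, lig_seq, note in variants:
                oligo, _ = assemble_oligo(ext_seq, lig_seq, linker, params)
                panel.append(
                    MipProbe(
                        probe_id=base_id + suffix,
                        gene=region.gene,
                        chrom=region.chrom,
                        strand="+",
                        ext_arm_seq=ext_seq,
                        ext_start=choice.ext_start,
                        ext_end=choice.ext_end,
                        lig_arm_seq=lig_seq,
                        lig_start=choice.lig_start,
                        lig_end=choice.lig_end,
                        gap_start=wstart,
                        gap_end=wend,
                        oligo=oligo,
                        umi_len=params.umi_len,
                        dosage=1.0,
                        allele_note=note,
                    )
                )
    return panel, rejections


def _allele_variants(choice: ArmChoice) -> list[tuple[str, str, str, str]]:
    """Wild-type arm pair plus, when arm SNPs are unavoidable, the variant-matched pair."""
    if not choice.arm_snps:
        return [("", choice.ext_seq, choice.lig_seq, "")]
    ext_var, lig_var = choice.ext_seq, choice.lig_seq
    labels = []
    for snp in choice.arm_snps:
        if len(snp.alt) != 1:
            continue
        if choice.ext_start <= snp.pos < choice.ext_end:
            off = snp.pos - choice.ext_start
            ext_var = ext_var[:off] + snp.alt + ext_var[off + 1 :]
        elif choice.lig_start <= snp.pos < choice.lig_end:
            off = snp.pos - choice.lig_start
            lig_var = lig_var[:off] + snp.alt + lig_var[off + 1 :]
        labels.append(f"{snp.chrom}:{snp.pos + 1}{snp.ref}>{snp.alt}")
    note = ";".join(labels)
    return [
        ("", choice.ext_seq, choice.lig_seq, f"wildtype[{note}]"),
        ("v", ext_var, lig_var, f"variant[{note}]"),
    ]


# ---------------------------------------------------------------------------
# Validation and I/O


def validate_panel(
    panel: Sequence[MipProbe],
    targets: Sequence[TargetRegion],
    reference: Mapping[str, object] | None = None,
    snp_table: Sequence[SnpRecord] | None = None,
    params: DesignParams = DesignParams(),
) -> PanelValidationReport:
    """Check that every target base lies under at least one gap fill."""
    total = sum(len(r) for r in targets)
    covered = 0
    uncovered: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in panel:
        by_chrom.setdefault(p.chrom, []).append((p.gap_start, p.gap_end))
    for region in targets:
        gaps = subtract_intervals(
            (region.start, region.end), by_chrom.get(region.chrom, [])
        )
        gap_bases = sum(e - s for s, e in gaps)
        covered += len(region) - gap_bases
        uncovered.extend((region.chrom, s, e) for s, e in gaps)
    copy_counts: dict[str, tuple[int, int]] = {}
    snp_flags: dict[str, bool] = {}
    for p in panel:
        if reference is not None:
            copy_counts[p.probe_id] = (
                arm_copy_count(p.ext_arm_seq, reference)
                if set(p.ext_arm_seq) <= VALID_BASES
                else -1,
                arm_copy_count(p.lig_arm_seq, reference)
                if set(p.lig_arm_seq) <= VALID_BASES
                else -1,
            )
        if snp_table is not None:
            flag = bool(
                _snps_in(snp_table, p.chrom, p.ext_start, p.ext_end, params.snp_maf_threshold)
                or _snps_in(snp_table, p.chrom, p.lig_start, p.lig_end, params.snp_maf_threshold)
            )
            snp_flags[p.probe_id] = flag
    fraction = covered / total if total else 0.0
    return PanelValidationReport(fraction, uncovered, copy_counts, snp_flags)


def export_panel(panel: Sequence[MipProbe], tsv_path: str, bed_path: str | None = None) -> None:
    """Write the probe table (TSV) and optionally a BED of gap fills."""
    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PANEL_COLUMNS)
        for p in panel:
            writer.writerow(
                [
                    p.probe_id, p.gene, p.chrom, p.strand,
                    p.ext_arm_seq, p.ext_start, p.ext_end,
                    p.lig_arm_seq, p.lig_start, p.lig_end,
                    p.gap_start, p.gap_end, p.oligo, p.umi_len,
                    f"{p.dosage:g}", p.allele_note,
                ]
            )
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for p in panel:
                fh.write(f"{p.chrom}\t{p.gap_start}\t{p.gap_end}\t{p.probe_id}\n")


def read_panel(tsv_path: str) -> list[MipProbe]:
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(PANEL_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"panel TSV missing columns: {sorted(missing)}")
        panel = []
        for row in reader:
            panel.append(
                MipProbe(
                    probe_id=row["probe_id"],
                    gene=row["gene"],
                    chrom=row["chrom"],
                    strand=row["strand"],
                    ext_arm_seq=row["ext_arm_seq"],
                    ext_start=int(row["ext_start"]),
                    ext_end=int(row["ext_end"]),
                    lig_arm_seq=row["lig_arm_seq"],
                    lig_start=int(row["lig_start"]),
                    lig_end=int(row["lig_end"]),
                    gap_start=int(row["gap_start"]),
                    gap_end=int(row["gap_end"]),
                    oligo=row["oligo"],
                    umi_len=int(row["umi_len"]),
                    dosage=float(row["dosage"]),
                    allele_note=row["allele_note"],
                )
            )
    return panel


def read_snp_table(path: str) -> list[SnpRecord]:
    """Read a SNP table: VCF (AF INFO tag) or TSV (chrom, pos, ref, alt, maf).

    TSV positions are 1-based, matching VCF.
    """
    if path.endswith((".vcf", ".vcf.gz")):
        import pysam

        snps = []
        with pysam.VariantFile(path) as vf:
            for rec in vf:
                afs = rec.info.get("AF", ())
                if not isinstance(afs, (tuple, list)):
                    afs = (afs,)
                for alt, af in zip(rec.alts or (), afs):
                    snps.append(SnpRecord(rec.chrom, rec.start, rec.ref, alt, float(af)))
        return snps
    snps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("chrom"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 5:
                raise ValueError(f"malformed SNP table line {lineno}")
            snps.append(
                SnpRecord(fields[0], int(fields[1]) - 1, fields[2], fields[3], float(fields[4]))
            )
    return snps
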