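"""Synthetic references, diploid samples, and MIP capture reads.

The generator emulates a small multi-gene panel experiment: a reference with
one contig per gene and exon annotations, per-sample diploid variants
(substitutions and indels up to 3 bp), and MIP capture with the read anatomy
the pipeline expects:

    read1 = UMI + extension arm + gap-fill prefix
    read2 = reverse complement of (gap-fill suffix + ligation arm)

Each captured molecule draws a distinct random 5-nt UMI and is emitted one
or more times (PCR duplicates share the UMI, geometric copy counts).
Per-base substitution errors are applied at a constant rate, and probes
whose gap fill is GC-rich (above a threshold) have their capture efficiency
scaled by a multiplier — high-GC first exons are the classic failure mode of
circularization capture.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from mipseq.panel import MipProbe
from mipseq.seqs import gc_fraction, get_chrom_seq, revcomp

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class PlantedVariant:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    zygosity: str  # "het" | "hom"

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het or hom, got {self.zygosity!r}")


@dataclass
class SampleSpec:
    sample_id: str
    variants: list[PlantedVariant] = field(default_factory=list)


@dataclass
class SimulationCounts:
    """Ground truth per probe: molecules captured and distinct UMIs drawn.

    UMI collisions (two molecules drawing the same 5-nt tag) are modeled, so
    the pipeline's family count recovers ``distinct_umis``, not
    ``molecules``, when they differ.
    """

    molecules: dict[str, int]
    distinct_umis: dict[str, int]


@dataclass
class CaptureModel:
    """Stochastic model of one MIP capture + sequencing experiment.

    lam: mean unique molecules per probe per sample (Poisson).
    dup_mean: mean number of extra PCR copies per molecule (geometric).
    error_rate: per-base substitution error probability.
    gc_threshold / gc_multiplier: probes whose gap-fill GC fraction exceeds
        the threshold have their expected molecule count multiplied.
    """

    lam: float = 100.0
    dup_mean: float = 1.0
    error_rate: float = 0.002
    gc_threshold: float = 0.5
    gc_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lam must be > 0")
        if not 0 <= self.error_rate < 0.01:
            raise ValueError("error_rate must be in [0, 0.01)")
        if not 0 <= self.gc_multiplier <= 1:
            raise ValueError("gc_multiplier must be in [0, 1]")
        if self.dup_mean < 0:
            raise ValueError("dup_mean must be >= 0")


def make_reference(
    out_dir: str,
    n_genes: int = 9,
    exons_per_gene: int = 3,
    exon_len_range: tuple[int, int] = (100, 300),
    intron_len: int = 400,
    flank: int = 300,
    seed: int = 0,
    gc: float = 0.42,
    first_exon_gc: float | None = None,
) -> tuple[str, str]:
    """Write a synthetic multi-gene reference FASTA and exon BED.

    One contig per gene named ``gene1..geneN``; BED names follow the
    ``gene|exon`` convention. With ``first_exon_gc`` set, the first exon of
    every gene is drawn at that GC content (to emulate GC-rich first exons).
    Deterministic for a fixed seed.
    """
    if n_genes <= 0 or exons_per_gene <= 0:
        raise ValueError("n_genes and exons_per_gene must be positive")
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta_path = out / "reference.fa"
    bed_path = out / "targets.bed"

    def draw(n: int, gc_frac: float) -> str:
        p_gc = gc_frac / 2
        p_at = (1 - gc_frac) / 2
        idx = rng.choice(4, size=n, p=[p_at, p_gc, p_gc, p_at])
        return BASES[idx].tobytes().decode()

    with open(fasta_path, "w") as fa, open(bed_path, "w") as bed:
        for g in range(1, n_genes + 1):
            gene = f"gene{g}"
            parts: list[str] = [draw(flank, gc)]
            pos = flank
            exons: list[tuple[int, int]] = []
            for e in range(1, exons_per_gene + 1):
                elen = int(rng.integers(exon_len_range[0], exon_len_range[1] + 1))
                egc = first_exon_gc if (e == 1 and first_exon_gc is not None) else gc
                parts.append(draw(elen, egc))
                exons.append((pos, pos + elen))
                pos += elen
                if e < exons_per_gene:
                    parts.append(draw(intron_len, gc))
                    pos += intron_len
            parts.append(draw(flank, gc))
            seq = "".join(parts)
            fa.write(f">{gene}\n")
            for i in range(0, len(seq), 80):
                fa.write(seq[i : i + 80] + "\n")
            for e, (s, t) in enumerate(exons, start=1):
                bed.write(f"{gene}\t{s}\t{t}\t{gene}|exon{e}\n")
    return str(fasta_path), str(bed_path)


def _apply_variants(
    fragment: str,
    gap_start: int,
    variants: Sequence[PlantedVariant],
    chrom: str,
    rng: np.random.Generator,
) -> str:
    """Apply a sample's variants falling inside [gap_start, gap_start+len) to
    the fragment. Het variants are carried by each molecule with probability
    0.5; applied right-to-left so indel shifts do not disturb coordinates."""
    gap_end = gap_start + len(fragment)
    hits = [
        v
        for v in variants
        if v.chrom == chrom and gap_start <= v.pos and v.pos + len(v.ref) <= gap_end
    ]
    for v in sorted(hits, key=lambda v: -v.pos):
        if v.zygosity == "het" and rng.random() >= 0.5:
            continue
        off = v.pos - gap_start
        if fragment[off : off + len(v.ref)] != v.ref:
            raise ValueError(
                f"planted variant {v.chrom}:{v.pos + 1} ref {v.ref!r} does not match reference"
            )
        fragment = fragment[:off] + v.alt + fragment[off + len(v.ref) :]
    return fragment


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n == 0:
        return seq
    # substitute with a uniformly random *different* base
    for i in np.nonzero(hit)[0]:
        choices = [b for b in BASES if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode()


def simulate_reads(
    panel: Sequence[MipProbe],
    reference: Mapping[str, object],
    sample: SampleSpec,
    model: CaptureModel,
    fq1_path: str,
    fq2_path: str,
    read_len: int = 150,
    seed: int = 0,
) -> SimulationCounts:
    """Simulate one sample's paired FASTQ; returns per-probe ground-truth
    molecule and distinct-UMI counts (what UMI de-duplication recovers).
    """
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    umi_counts: dict[str, int] = {}
    qual = "I" * read_len
    open1 = gzip.open if str(fq1_path).endswith(".gz") else open
    open2 = gzip.open if str(fq2_path).endswith(".gz") else open
    with open1(fq1_path, "wt") as f1, open2(fq2_path, "wt") as f2:
        for probe in sorted(panel, key=lambda p: p.probe_id):
            seq = get_chrom_seq(reference, probe.chrom)
            if probe.gap_end > len(seq) or probe.ext_start < 0:
                raise ValueError(f"probe {probe.probe_id} outside reference {probe.chrom}")
            gap_ref = seq[probe.gap_start : probe.gap_end]
            gc = gc_fraction(gap_ref)
            mult = model.gc_multiplier if gc > model.gc_threshold else 1.0
            lam = model.lam * probe.dosage * mult
            n_mol = int(rng.poisson(lam)) if lam > 0 else 0
            counts[probe.probe_id] = n_mol
            umis_seen: set[str] = set()
            for m in range(n_mol):
                umi = BASES[rng.integers(0, 4, size=probe.umi_len)].tobytes().decode()
                umis_seen.add(umi)
                fragment = _apply_variants(
                    gap_ref, probe.gap_start, sample.variants, probe.chrom, rng
                )
                r1_full = umi + probe.ext_arm_seq + fragment
                r2_full = revcomp(fragment + probe.lig_arm_seq)
                if model.dup_mean > 0:
                    copies = int(rng.geometric(1.0 / (1.0 + model.dup_mean)))
                else:
                    copies = 1
                for c in range(copies):
                    r1 = _mutate(r1_full[:read_len], model.error_rate, rng)
                    r2 = _mutate(r2_full[:read_len], model.error_rate, rng)
                    name = f"{sample.sample_id}:{probe.probe_id}:{m}:{c}"
                    f1.write(f"@{name}/1\n{r1}\n+\n{qual[: len(r1)]}\n")
                    f2.write(f"@{name}/2\n{r2}\n+\n{qual[: len(r2)]}\n")
            umi_counts[probe.probe_id] = len(umis_seen)
    return SimulationCounts(counts, umi_counts)


def write_truth(samples: Sequence[SampleSpec], path: str) -> None:
    """Truth-set TSV: one record per planted variant (positions 1-based)."""
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tpos\tref\talt\tzygosity\n")
        for spec in samples:
            for v in spec.variants:
                fh.write(
                    f"{spec.sample_id}\t{v.chrom}\t{v.pos + 1}\t{v.ref}\t{v.alt}\t{v.zygosity}\n"
                )


def write_sample_sheet(samples: Sequence[SampleSpec], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tn_variants\n")
        for spec in samples:
            fh.write(f"{spec.sample_id}\t{len(spec.variants)}\n")


def read_truth(path: str) -> list[tuple[str, str, int, str, str, str]]:
    """Read the truth TSV back as (sample_id, chrom, pos1, ref, alt, zygosity)."""
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sample_id"):
            raise ValueError("truth TSV must start with a sample_id header line")
        for line in fh:
            if not line.strip():
                continue
            s, c, p, r, a, z = line.rstrip("\n").split("\t")
            out.append((s, c, int(p), r, a, z))
    return out
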