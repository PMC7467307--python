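"""End-to-end validation studies on fully synthetic data.

These drivers exercise the whole toolkit — reference synthesis, panel
design, capture simulation, read processing, calling, filtering — and score
recovery of the planted ground truth. They are the package's substitute for
cohort-level re-sequencing metrics that depend on patient samples: they
measure whether the method recovers what was put in, under stated capture
and noise conditions.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pyfaidx

from mipseq.panel import DesignParams, TargetRegion, design_panel, load_targets, validate_panel
from mipseq.pipeline import coverage, dedup, probe_performance, process_fastq
from mipseq.simulate import CaptureModel, PlantedVariant, SampleSpec, make_reference, simulate_reads
from mipseq.seqs import gc_fraction
from mipseq.variants import FilterConfig, call_sample, cohort_filter, normalize_variant


@dataclass
class RecoveryResult:
    """Outcome of a planted-variant recovery study."""

    n_samples: int
    n_planted: int
    n_detected_pass: int
    n_zygosity_match: int
    n_false_pass: int
    n_unassigned_reads: int
    sensitivity_pct: float
    zygosity_agreement_pct: float
    false_positive_rate_pct: float
    dedup_exact: bool = True
    details: list = field(default_factory=list)


def build_study_panel(
    work_dir: str,
    seed: int,
    n_genes: int = 9,
    exons_per_gene: int = 2,
    exon_len_range: tuple[int, int] = (150, 260),
    first_exon_gc: float | None = None,
):
    """Synthesize a multi-gene reference and design its MIP panel."""
    fa, bed = make_reference(
        work_dir,
        n_genes=n_genes,
        exons_per_gene=exons_per_gene,
        exon_len_range=exon_len_range,
        seed=seed,
        first_exon_gc=first_exon_gc,
    )
    reference = pyfaidx.Fasta(fa)
    targets = load_targets(bed, pad=20, reference=reference)
    panel, rejections = design_panel(reference, targets, DesignParams())
    report = validate_panel(panel, targets)
    if rejections or report.covered_fraction < 1.0:
        raise RuntimeError("study panel failed to cover its targets")
    return reference, targets, panel


def plant_cohort(
    reference,
    targets: list[TargetRegion],
    n_samples: int,
    seed: int,
    p_variant_per_gene: float = 0.5,
    indel_fraction: float = 0.3,
) -> list[SampleSpec]:
    """Per-sample diploid variants: at most one per gene, placed centrally
    in a random exon so substitution and indel evidence never mix on the
    same captured fragment."""
    rng = np.random.default_rng(seed)
    seqs = {c: str(reference[c][:]).upper() for c in reference.keys()}
    by_gene: dict[str, list[TargetRegion]] = {}
    for t in targets:
        by_gene.setdefault(t.gene.split(",")[0], []).append(t)
    samples = []
    for i in range(n_samples):
        variants = []
        for gene in sorted(by_gene):
            if rng.random() >= p_variant_per_gene:
                continue
            region = by_gene[gene][int(rng.integers(len(by_gene[gene])))]
            seq = seqs[region.chrom]
            margin = 30
            pos = int(rng.integers(region.start + margin, region.end - margin))
            zyg = "het" if rng.random() < 0.5 else "hom"
            if rng.random() < indel_fraction:
                k = int(rng.integers(1, 4))
                if rng.random() < 0.5:  # deletion of k bases after pos
                    ref_a, alt_a = seq[pos : pos + k + 1], seq[pos]
                else:  # insertion of k random bases after pos
                    ins = "".join("ACGT"[j] for j in rng.integers(0, 4, size=k))
                    ref_a, alt_a = seq[pos], seq[pos] + ins
            else:
                ref_a = seq[pos]
                alt_a = "ACGT"[int(rng.integers(0, 4))]
                while alt_a == ref_a:
                    alt_a = "ACGT"[int(rng.integers(0, 4))]
            variants.append(PlantedVariant(region.chrom, pos, ref_a, alt_a, zyg))
        samples.append(SampleSpec(f"S{i + 1:03d}", variants))
    return samples


def run_recovery_study(
    seed: int,
    n_samples: int = 20,
    lam: float = 100.0,
    error_rate: float = 0.002,
    dup_mean: float = 1.0,
    n_genes: int = 9,
    work_dir: str | None = None,
    config: FilterConfig = FilterConfig(),
) -> RecoveryResult:
    """Simulate a cohort, run the full pipeline, and score recovery.

    Every planted variant lies in a covered gap fill, so the expected
    outcome under adequate depth is full sensitivity with matching zygosity
    and no PASS calls at non-planted sites.
    """
    with tempfile.TemporaryDirectory() as tmp:
        root = Path(work_dir or tmp)
        reference, targets, panel = build_study_panel(str(root / "ref"), seed, n_genes=n_genes)
        samples = plant_cohort(reference, targets, n_samples, seed + 1)
        model = CaptureModel(lam=lam, dup_mean=dup_mean, error_rate=error_rate)
        seqs = {c: str(reference[c][:]).upper() for c in reference.keys()}
        calls_by_sample = {}
        truth_by_sample = {}
        unassigned_total = 0
        for i, spec in enumerate(samples):
            fq1 = str(root / f"{spec.sample_id}_R1.fastq.gz")
            fq2 = str(root / f"{spec.sample_id}_R2.fastq.gz")
            simulate_reads(panel, reference, spec, model, fq1, fq2, seed=seed + 100 + i)
            assigned, unassigned = process_fastq(fq1, fq2, panel)
            unassigned_total += unassigned
            families = dedup(assigned, panel)
            calls_by_sample[spec.sample_id] = call_sample(families, reference, config, spec.sample_id)
            truth_by_sample[spec.sample_id] = {
                _normalized_key(seqs, v): v.zygosity for v in spec.variants
            }
        cohort_filter(calls_by_sample, config)

        n_planted = n_detected = n_zyg = n_false = 0
        details = []
        for sid, truth in truth_by_sample.items():
            pass_calls = {c.key: c for c in calls_by_sample[sid] if c.passed}
            n_planted += len(truth)
            for key, zyg in truth.items():
                call = pass_calls.get(key)
                if call is not None:
                    n_detected += 1
                    n_zyg += call.zygosity == zyg
                else:
                    details.append(("missed", sid, key, zyg))
            for key, call in pass_calls.items():
                if key not in truth:
                    n_false += 1
                    details.append(("false", sid, key, call.zygosity))
        n_calls_pass = sum(
            sum(c.passed for c in calls) for calls in calls_by_sample.values()
        )
        from mipseq.concordance import pct

        return RecoveryResult(
            n_samples=n_samples,
            n_planted=n_planted,
            n_detected_pass=n_detected,
            n_zygosity_match=n_zyg,
            n_false_pass=n_false,
            n_unassigned_reads=unassigned_total,
            sensitivity_pct=pct(n_detected, n_planted) if n_planted else 100.0,
            zygosity_agreement_pct=pct(n_zyg, n_detected) if n_detected else 100.0,
            false_positive_rate_pct=pct(n_false, n_calls_pass) if n_calls_pass else 0.0,
            details=details,
        )


def _normalized_key(seqs, v: PlantedVariant):
    pos0, ref_a, alt_a = normalize_variant(seqs[v.chrom], v.pos, v.ref, v.alt)
    return (v.chrom, pos0 + 1, ref_a, alt_a)


def run_dedup_oracle_study(seed: int, lam: float = 10.0, n_genes: int = 3):
    """Noise-off capture: pipeline family counts must equal the simulator's
    distinct-UMI draws per probe, exactly."""
    with tempfile.TemporaryDirectory() as tmp:
        reference, targets, panel = build_study_panel(str(Path(tmp) / "ref"), seed, n_genes=n_genes)
        model = CaptureModel(lam=lam, dup_mean=0.0, error_rate=0.0)
        fq1, fq2 = str(Path(tmp) / "r1.fq"), str(Path(tmp) / "r2.fq")
        sim = simulate_reads(panel, reference, SampleSpec("S1", []), model, fq1, fq2, seed=seed + 1)
        assigned, unassigned = process_fastq(fq1, fq2, panel)
        families = dedup(assigned, panel)
        per_probe: dict[str, int] = {}
        for f in families:
            per_probe[f.probe_id] = per_probe.get(f.probe_id, 0) + 1
        expected = {k: v for k, v in sim.distinct_umis.items() if v}
        return per_probe, expected, unassigned


def run_gc_dropout_study(seed: int, n_genes: int = 4, lam: float = 50.0):
    """GC-rich first exons with capture multiplier 0: the probes must be
    reported failed/replace and their bases surface as uncovered."""
    with tempfile.TemporaryDirectory() as tmp:
        reference, targets, panel = build_study_panel(
            str(Path(tmp) / "ref"), seed, n_genes=n_genes, first_exon_gc=0.75
        )
        gc_rich = {
            p.probe_id
            for p in panel
            if gc_fraction(str(reference[p.chrom][p.gap_start : p.gap_end])) > 0.5
        }
        model = CaptureModel(lam=lam, dup_mean=0.0, error_rate=0.0, gc_multiplier=0.0)
        fq1, fq2 = str(Path(tmp) / "r1.fq"), str(Path(tmp) / "r2.fq")
        simulate_reads(panel, reference, SampleSpec("S1", []), model, fq1, fq2, seed=seed + 1)
        assigned, _ = process_fastq(fq1, fq2, panel)
        families = dedup(assigned, panel)
        profile = coverage(families, panel, targets)
        perfs = {p.probe_id: p for p in probe_performance(profile.per_probe)}
        uncovered = []
        for chrom, s, e in profile.target_intervals:
            d = profile.depth[chrom][s:e]
            edges = np.nonzero(np.diff((d == 0).astype(np.int8)))[0] + 1
            bounds = np.concatenate(([0], edges, [len(d)]))
            for a, b in zip(bounds[:-1], bounds[1:]):
                if d[a] == 0:
                    uncovered.append((chrom, s + int(a), s + int(b)))
        return panel, targets, gc_rich, perfs, uncovered, profile
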