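"""Evaluation statistics for targeted capture panels.

Capture efficiency, sensitivity against a Sanger-style truth set,
cross-platform concordance of call sets, per-gene performance tables,
Sanger-follow-up accounting for uncovered bases, and a per-sample cost
model. Percentages are reported to one decimal, half-up, and computed with
exact rational arithmetic before rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from importlib import resources
from typing import Callable, Iterable, Sequence

import pandas as pd

from mipseq.variants import VariantCall


def round1(x: float | Fraction) -> float:
    """Round to one decimal, half-up (matching printed-table conventions)."""
    if isinstance(x, Fraction):
        d = Decimal(x.numerator) / Decimal(x.denominator)
    else:
        d = Decimal(repr(float(x)))
    return float(d.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def pct(numerator: int, denominator: int) -> float:
    """Exact percentage rounded to one decimal half-up."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return round1(Fraction(100 * numerator, denominator))


def capture_efficiency(n_working_probes: int, n_total_probes: int) -> float:
    """Percentage of panel probes producing usable sequence reads."""
    if n_total_probes == 0:
        raise ValueError("capture efficiency undefined for an empty panel")
    return pct(n_working_probes, n_total_probes)


# ---------------------------------------------------------------------------
# Truth-set sensitivity


@dataclass
class TruthVariant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    zygosity: str = ""
    sample_id: str = ""

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class ConcordanceResult:
    n_truth: int
    n_detected: int
    n_missed_in_uncovered: int
    sensitivity_pct: float | None
    sensitivity_covered_only_pct: float | None
    zygosity_agreement_pct: float | None
    false_positive_rate_pct: float | None


def sensitivity(
    truth_set: Sequence[TruthVariant],
    call_set: Sequence[VariantCall],
    coverage_mask: Callable[[str, int], bool] | None = None,
) -> ConcordanceResult:
    """Sensitivity of a call set against a truth set.

    Overall sensitivity counts every truth variant; covered-only sensitivity
    excludes truth variants whose site fails the coverage mask (a callable
    of (chrom, 1-based pos) -> covered). Zygosity agreement is computed over
    jointly detected variants; the false-positive rate is the fraction of
    calls absent from the truth set, restricted to covered sites.
    """
    covered = coverage_mask or (lambda chrom, pos: True)
    call_keys = {c.key: c for c in call_set}
    n_truth = len(truth_set)
    detected = [t for t in truth_set if t.key in call_keys]
    missed = [t for t in truth_set if t.key not in call_keys]
    missed_uncov = [t for t in missed if not covered(t.chrom, t.pos)]
    truth_cov = [t for t in truth_set if covered(t.chrom, t.pos)]
    det_cov = [t for t in truth_cov if t.key in call_keys]
    zyg_pairs = [(t, call_keys[t.key]) for t in detected if t.zygosity]
    zyg_ok = sum(1 for t, c in zyg_pairs if t.zygosity == c.zygosity)
    truth_keys = {t.key for t in truth_set}
    calls_cov = [c for c in call_set if covered(c.chrom, c.pos)]
    fps = [c for c in calls_cov if c.key not in truth_keys]
    return ConcordanceResult(
        n_truth=n_truth,
        n_detected=len(detected),
        n_missed_in_uncovered=len(missed_uncov),
        sensitivity_pct=pct(len(detected), n_truth) if n_truth else None,
        sensitivity_covered_only_pct=pct(len(det_cov), len(truth_cov)) if truth_cov else None,
        zygosity_agreement_pct=pct(zyg_ok, len(zyg_pairs)) if zyg_pairs else None,
        false_positive_rate_pct=pct(len(fps), len(calls_cov)) if calls_cov else None,
    )


# ---------------------------------------------------------------------------
# Cross-platform comparison


@dataclass
class Disagreement:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    present_in: str  # "A" | "B"
    cause: str  # "low coverage" | "below threshold"


@dataclass
class CrossComparison:
    n_concordant: int
    n_dissimilar: int
    true_positive_pct: float | None
    dissimilar_pct: float | None
    disagreements: list[Disagreement] = field(default_factory=list)


def _sample_key(call: VariantCall) -> tuple:
    return (call.sample_id, call.chrom, call.pos, call.ref, call.alt)


def cross_compare(
    calls_a: Sequence[VariantCall],
    calls_b: Sequence[VariantCall],
    depth_a: Callable[[str, str, int], int] | None = None,
    depth_b: Callable[[str, str, int], int] | None = None,
    min_depth: int = 30,
) -> CrossComparison:
    """Concordance of two platforms' call sets over the same samples.

    Calls match on (sample, chrom, pos, ref, alt). Each dissimilar call is
    annotated with its likely cause by inspecting the *other* platform's
    unique-molecule depth at the site (a callable of (sample, chrom, 1-based
    pos) -> depth): below min_depth -> "low coverage", else "below
    threshold".
    """
    a = {_sample_key(c): c for c in calls_a}
    b = {_sample_key(c): c for c in calls_b}
    concordant = a.keys() & b.keys()
    only_a = a.keys() - b.keys()
    only_b = b.keys() - a.keys()
    disagreements = []
    for keys, label, other_depth in ((only_a, "A", depth_b), (only_b, "B", depth_a)):
        for k in sorted(keys):
            sid, chrom, pos, ref, alt = k
            cause = "unknown"
            if other_depth is not None:
                d = other_depth(sid, chrom, pos)
                cause = "low coverage" if d < min_depth else "below threshold"
            disagreements.append(Disagreement(sid, chrom, pos, ref, alt, label, cause))
    n_con, n_dis = len(concordant), len(only_a) + len(only_b)
    total = n_con + n_dis
    return CrossComparison(
        n_concordant=n_con,
        n_dissimilar=n_dis,
        true_positive_pct=pct(n_con, total) if total else None,
        dissimilar_pct=pct(n_dis, total) if total else None,
        disagreements=disagreements,
    )


# ---------------------------------------------------------------------------
# Per-gene performance table


def gene_report(
    panel: Sequence,
    profiles: Sequence,
    targets: Sequence,
    threshold: int = 30,
) -> pd.DataFrame:
    """Per-gene performance table from a batch of coverage profiles.

    Columns: targeted bp, probe count, % of bases with depth > threshold
    (averaged over samples), probes with no reads in any sample. A totals
    row sums bp and probe counts and averages the percentage weighted by bp.
    """
    import numpy as np

    genes = list(dict.fromkeys(t.gene.split(",")[0] for t in targets))
    rows = []
    for gene in genes:
        g_targets = [t for t in targets if t.gene.split(",")[0] == gene]
        g_probes = [p for p in panel if p.gene.split(",")[0] == gene]
        bp = sum(len(t) for t in g_targets)
        pcts = []
        failed_sets = []
        for prof in profiles:
            above = total = 0
            for t in g_targets:
                d = prof.depth[t.chrom][t.start : t.end]
                total += len(d)
                above += int((d > threshold).sum())
            pcts.append(100 * above / total if total else 0.0)
            failed_sets.append({p.probe_id for p in g_probes if prof.per_probe.get(p.probe_id, 0) == 0})
        no_reads = len(set.intersection(*failed_sets)) if failed_sets else 0
        rows.append(
            {
                "gene": gene,
                "targeted_bp": bp,
                "n_probes": len(g_probes),
                "pct_gt_threshold": round1(float(np.mean(pcts))) if pcts else None,
                "probes_no_reads": no_reads,
            }
        )
    df = pd.DataFrame(rows)
    return append_totals(df, bp_col="targeted_bp", pct_cols=["pct_gt_threshold"])


def append_totals(df: pd.DataFrame, bp_col: str, pct_cols: Sequence[str] = ()) -> pd.DataFrame:
    """Append a Total row: sums for count columns, bp-weighted means for
    percentage columns."""
    totals: dict[str, object] = {"gene": "Total"}
    for col in df.columns:
        if col == "gene":
            continue
        if col in pct_cols:
            w = df[bp_col if bp_col in df.columns else df.columns[1]]
            totals[col] = round1(float((df[col] * w).sum() / w.sum()))
        else:
            totals[col] = df[col].sum()
    return pd.concat([df, pd.DataFrame([totals])], ignore_index=True)


def load_sodium_channel_panel_summary() -> pd.DataFrame:
    """Published per-gene summary of the nine-gene sodium-channel MIP panel
    and its amplicon-capture comparator: targeted bp, probe counts, fraction
    of bases above 30x, and probes yielding no reads."""
    with resources.files("mipseq.data").joinpath("sodium_channel_panel_summary.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Sanger follow-up and costs


def sanger_followup(
    flagged_regions: Iterable[tuple[str, int, int]] | int,
    total_targeted_bp: int,
) -> tuple[int, float]:
    """Bases needing orthogonal (Sanger) confirmation and their panel share.

    ``flagged_regions`` is either an explicit list of (chrom, start, end)
    intervals flagged uncovered/low-quality, or a pre-summed base count.
    """
    if total_targeted_bp <= 0:
        raise ValueError("total_targeted_bp must be positive")
    bp = flagged_regions if isinstance(flagged_regions, int) else sum(
        e - s for _, s, e in flagged_regions
    )
    bp = min(bp, total_targeted_bp)
    return bp, pct(bp, total_targeted_bp)


@dataclass(frozen=True)
class CostParams:
    """Per-sample cost model parameters (euros)."""

    probe_unit_cost: float = 5.6
    n_probes: int = 276
    reagent_cost_per_sample: float = 1.8
    fixed_setup_cost: float = 1575.0
    sequencing_run_cost: float = 1073.0
    samples_per_run: int = 384

    def __post_init__(self) -> None:
        if self.samples_per_run < 1:
            raise ValueError("samples_per_run must be >= 1")
        for f in ("probe_unit_cost", "reagent_cost_per_sample", "fixed_setup_cost", "sequencing_run_cost"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be non-negative")


def per_sample_cost(params: CostParams, n_samples: int) -> float:
    """Amortized cost per sample: one-off probe synthesis and setup spread
    over the cohort, per-sample reagents, and whole sequencing runs."""
    import math

    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    runs = math.ceil(n_samples / params.samples_per_run)
    return (
        (params.n_probes * params.probe_unit_cost + params.fixed_setup_cost) / n_samples
        + params.reagent_cost_per_sample
        + params.sequencing_run_cost * runs / n_samples
    )


# ---------------------------------------------------------------------------
# Truth-set reader


def read_truth_variants(path: str) -> list[TruthVariant]:
    """Read a truth set from the simulator's TSV or from a VCF."""
    if path.endswith((".vcf", ".vcf.gz")):
        from mipseq.variants import read_vcf

        return [
            TruthVariant(c.chrom, c.pos, c.ref, c.alt, c.zygosity, c.sample_id)
            for c in read_vcf(path)
        ]
    from mipseq.simulate import read_truth

    return [
        TruthVariant(chrom, pos, ref, alt, zyg, sid)
        for sid, chrom, pos, ref, alt, zyg in read_truth(path)
    ]
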