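# Methods

## The capture model

A molecular inversion probe targets one 220–230 nt gap fill. Its extension
arm (16–20 nt) and ligation arm (20–24 nt) hybridize immediately 3' and 5'
of the gap fill; polymerase fills the gap, ligase closes the circle, and
the circularized copy is amplified with universal primers sitting in the
30-nt common linker. A 5-nt fully random UMI in the linker tags each
successful capture event, so reads sharing a (probe, UMI) pair are PCR
copies of one molecule. The toolkit's unit of evidence throughout is the
*unique molecule* (UMI family), not the raw read: depth thresholds,
coverage percentages, and allele fractions are all family-level.

Coordinates are 0-based half-open (BED convention) everywhere except the
VCF boundary, where the writer converts to 1-based.

## Panel design

Targets are exons padded ±20 bp of flanking intron (UTRs are never added).
Overlapping or bookended padded records merge; merged gene labels are the
comma-joined unique labels.

Tiling places the minimum number of gap-fill windows, `ceil((L−20)/(g−20))`
with `g = 230` for region length `L > g` and one window otherwise, spread
evenly so consecutive windows overlap ≥20 bp. Regions shorter than 220 bp
get one window extended symmetrically into the flanks, so every target base
is under at least one gap fill by construction; `validate_panel` verifies
this and enumerates any uncovered intervals.

Arm selection scans the full 5×5 grid of (extension, ligation) length
pairs. A pair is inadmissible when either arm occurs more than 5 times in
the reference (exact occurrences of the arm and its reverse complement,
palindromic hits at one locus counted once) or contains ambiguous bases.
Among admissible pairs, SNP-free pairs (no population SNP with MAF ≥ 1% in
either arm) are preferred; the winner minimizes
`|GC(ext) − 0.5| + |GC(lig) − 0.5|`, ties broken by longer total arm
length, then longer extension arm. This GC-balance objective is a
deterministic melting-temperature proxy chosen in place of a learned probe
score; it makes the design byte-reproducible. When every admissible pair
contains a common SNP, two probes are emitted — wild-type and
variant-matched arms — so either allele can be captured.

The assembled oligo is `extension arm + linker + ligation arm`, where the
linker is the 30-nt backbone plus the 5 UMI placeholder (`N`) positions
(default backbone `CTTCAGCTTCCCGATATCCGACGGTAGTGT`, configurable). Arm
ranges allow totals of 71–80 nt; totals outside the nominal 77–80 window
are flagged with a warning rather than rejected, since nothing about a
shorter oligo is invalid — the nominal window reflects synthesis
conventions, not chemistry.

## Synthetic data

The generator emulates a small multi-gene panel experiment: one contig per
gene (default GC 0.42) with exons separated by 400-bp introns; per-sample
diploid variants; and capture with, per probe,

* unique molecules ~ Poisson(λ · dosage · m), with m the GC multiplier
  applied when the gap-fill GC fraction exceeds 0.5 — GC-rich first exons
  are the classic circularization-capture failure mode, and m = 0
  reproduces complete first-exon dropout;
* a distinct random 5-nt UMI per molecule (collisions possible by design
  and not prevented — the pipeline must tolerate them);
* 1 + Geometric PCR copies per molecule (mean extra copies `dup_mean`);
* per-base substitution errors at rate `e` on each read independently;
* heterozygous variants carried per molecule with probability 0.5.

Reads are 2×150: `read1 = UMI + extension arm + gap-fill prefix`,
`read2 = revcomp(gap-fill suffix + ligation arm)`; with 220–230 nt gap
fills the mates overlap in the middle, which the consensus builder exploits.

What the generator does **not** emulate: indels longer than 3 bp,
position- or context-dependent error profiles, quality-score variation
(constant Q40), chimeric capture, off-target capture, coverage
autocorrelation between neighbouring probes, and contamination. Passing
recovery studies therefore demonstrate the pipeline's correctness under
its own stated model, not performance on real instrument data.

## Read processing

Assignment needs no aligner: the UMI is the first 5 nt of read1, the
extension arm is matched at the following offset (exact dictionary lookup
first, then a ≤1-mismatch scan), and the candidate is confirmed by the
ligation arm's reverse complement at the start of read2 (≤1 mismatch).
Pairs whose two arms do not both match one probe — including chimeras whose
mates match different probes — are unassigned; unassigned is a category,
not an error. When two probes share an extension arm the ligation arm
disambiguates, then the lexicographically smallest probe id. Remaining
bases map to gap-fill coordinates by offset; there is no gapped alignment.

UMI families take a strict per-position majority consensus over all reads
(both mates vote; ties and vote-free positions become `N`). The UMI itself
is never error-corrected: families differing by one UMI base stay
separate, which slightly inflates family counts at high error rates and is
the conservative choice.

Because an indel changes the fragment length, the consensus is built at
the molecule length (gap-fill length ±3) that minimizes disagreement
between the left-anchored read1 votes and right-anchored read2 votes in
the mate overlap; the gap-fill length is accepted outright when it
produces zero conflicts.

## Variant calling

Substitutions come from per-position base counts over length-concordant
family consensi; `N` bases contribute no depth. Length-discordant families
are interpreted as a single ≤3 bp indel by exact alternate-fragment
matching (consensus `N`s act as wildcards): the leftmost offset whose
deletion/insertion reproduces the consensus exactly. Interpreted indel
families also contribute reference-aligned substitution evidence outside
the indel. Families admitting no single-indel interpretation — and
length-concordant families mismatching the reference at more than 10
positions, the signature of multi-indel molecules or chimeric capture —
are dropped from the pileup entirely (no depth, no alleles).

A site is reported when some non-reference allele reaches the 20% fraction
threshold; sub-threshold alleles at reported sites are emitted flagged
`LOW_VAF`. `LOW_DEPTH` flags sites under 30 unique molecules — the depth
threshold is applied to de-duplicated molecules, since that is the unit an
accurate genotype call needs. The cohort filter flags any unique variant
present in more than 90% of batch samples in every carrier (with one
sample, a present variant is 100% > 90% and is flagged; documented
degenerate case). Zygosity: heterozygous for fractions in [0.20, 0.80),
homozygous at ≥0.80; the boundary is exposed in `FilterConfig` because the
underlying validation data reported zygosity agreement without stating one.
Variants are left-aligned and parsimonious before writing or comparing
(checked against `bcftools norm` on repeat fixtures).

## Probe performance and rebalancing

From a pilot batch: 0 unique reads → failed → replace; 1–30 → poor → add a
5-fold concentration of the probe to the pool; >30 → adequate. The 1–14
band is classified poor because such probes perform worse than the 15–30
band the rebalancing rule was written for. Boosting is additive by default
(original 1× stays in the pool, so dosage becomes 6×); a `replace` mode
(5×) is exposed since the wet-lab accounting is ambiguous.

## Evaluation statistics

All percentages are computed with exact rational arithmetic and rounded to
one decimal, half-up. Sensitivity against a truth set is reported both
over all truth variants and restricted to sites passing a coverage mask;
zygosity agreement is computed over jointly detected variants.
Cross-platform concordance matches calls on (sample, chrom, pos, ref, alt)
after identical filtering, and annotates each dissimilar call by the other
platform's depth at the site (< 30 → low coverage, else below threshold).
Per-gene tables sum targeted bp and probe counts exactly and weight
percentage averages by bp. The per-sample cost model amortizes probe
synthesis and setup over the cohort and whole sequencing runs over their
occupants:

    cost(n) = (n_probes·probe_cost + setup)/n + reagents + run_cost·ceil(n/per_run)/n

The model is deliberately not fitted to any published price table — run
accounting in such tables is underdetermined — and defaults (€5.6/probe,
€1.8 reagents, €1575 setup, €1073/run, 384 samples/run) are exposed in
`CostParams`.

## Validation studies and problem sizes

`mipseq.study` drives three end-to-end studies, used by both the test
suite and `scripts/acceptance.py`:

* **Recovery**: 20 samples on a 9-gene panel (2 exons of 150–260 bp per
  gene, ~30 probes), λ = 100 molecules/probe, duplication mean 1, error
  rate 0.002 — roughly 5,000 read pairs per sample. Planted variants (≤1
  per gene, 70% substitutions / 30% indels of 1–3 bp, het:hom 1:1) must
  all PASS with matching zygosity, with no PASS call at any non-planted
  site. These sizes keep the full study under a minute on one CPU while
  leaving Poisson depth far above every filter threshold.
* **Dedup oracle**: noise off (e = 0, no duplicates), λ = 10 — per-probe
  family counts must equal the simulator's distinct-UMI draws exactly.
* **GC dropout**: first exons drawn at GC 0.75 with capture multiplier 0 —
  every silenced probe must be classified failed/replace and its exclusive
  target bases must surface as uncovered intervals.

## Known limitations

* Substitution-only offset mapping: one indel per fragment, ≤3 bp;
  molecules carrying an indel together with another variant on the same
  fragment are dropped as uninterpretable, which can suppress calls when
  two variants co-occur within one gap fill.
* Indel interpretation requires the consensus to match an alternate
  fragment exactly, so single-read indel families carrying a sequencing
  error are discarded; at the default error rate this mildly depresses
  indel allele fractions (numerator and denominator both exclude them).
* Arm matching tolerates one mismatch per arm; arms with two or more
  errors make the pair unassigned rather than recovered.
* The GC dropout rule is a step function at GC 0.5; real capture
  efficiency degrades continuously.
* No CNV analysis, no annotation against population databases, and no
  real-aligner mode: arm-offset mapping deliberately replaces genome
  alignment and is only valid for reads produced by MIP capture.
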