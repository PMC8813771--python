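# Methods

This note documents the models behind `saltil`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices that matter.

## Transcriptome-based genotyping

### Classification

Each transcript carries two non-negative integers: v_test, the number of
sequence variants the introgression line's reads show against the
reference genome, and v_control, the recurrent parent's natural variation
against the same reference. The origin call is a hard threshold on the raw
excess, Δv = v_test − v_control ≥ T → donor, with T = 10 by default and a
non-strict "≥" at the boundary. The excess is an absolute count, not a
per-kilobase rate; a `per_kb` option normalises by transcript length for
users who prefer a rate, but it is off by default because the raw-count
rule is the one the threshold was calibrated for. Transcripts with no
variant information at all (both counts zero, e.g. not expressed) are
classified recurrent and flagged in a `no_information` column — an
RNA-based genotyper is blind to silent loci, and the flag keeps that
visible.

### Segmentation

Within a chromosome, transcripts are sorted by start coordinate and donor
calls are grouped into runs: two donor transcripts belong to the same run
when at most G consecutive recurrent-labelled transcripts (default G = 2)
— and optionally at most `max_gap_bp` base pairs — separate them. Runs
with at least K donor transcripts (default K = 5) become blocks; smaller
runs contribute their donors to the dispersed list, so isolated donor
genes remain reportable rather than being swallowed or discarded. Block
coordinates span the first to the last donor member. K and G are this
package's choices: the run/gap family is the standard way to delimit
ancestry blocks when only an ordered sequence of binary calls is
available, K = 5 suppresses spurious blocks from chance clusters of false
donor calls, and G = 2 bridges the occasional under-detected donor
transcript (see the error model below) without fusing distinct blocks
across real gaps. Both are configurable, and the implementation is checked
against an independent brute-force enumeration of maximal qualifying runs.

### Error model and recovery benchmarking

Under the default divergence model (donor mean 18 variants, detection
probability 0.9, recurrent mean 2), the probability that a true donor
transcript falls below the threshold is irreducibly ≈ 0.15 — even a
Poisson-tight donor distribution leaves ≈ 0.12 — because the threshold
(10) sits only ~1σ below the thinned donor mean (16.2). Gap bridging
exists precisely to absorb these misses, and recovery is therefore scored
at the region level: a truth-donor transcript counts as recovered when it
lies within a called block's span (whether as a donor member or a bridged
gap transcript) or is called dispersed. This matches how a block inventory
is read — every gene between the boundaries belongs to the introgression.
Sensitivity is the recovered fraction of truth-donor transcripts, FDR the
truth-recurrent fraction of assigned-donor transcripts, and boundary
offsets are signed distances, in transcript positions, between each truth
block's ends and those of the best-overlapping called block. A run of
three or more consecutive missed donors (probability ≈ p³ per interior
position) splits a block; with ~200 interior donor transcripts in the
default scenario this happens in a sizeable minority of seeds, which is
why the called block count is reported alongside the recovery metrics
rather than asserted unconditionally.

## Synthetic line generator

The genome is 12 chromosomes at rice-like physical lengths with 2,000
genes by default, allocated proportionally to length and placed one per
equal-width slot (jittered within the slot), which guarantees sorted,
non-overlapping intervals. The default truth mosaic carries two large
homozygous donor blocks on chromosome 1 (1–13 Mb and 16–30 Mb), one on
chromosome 3 (5–23 Mb) and 28 dispersed donor genes — the architecture of
a well-characterised *Saltol* introgression line, scaled to the 2,000-gene
genome. Heterozygous introgressions are out of scope; advanced inbred
lines are homozygous by construction.

Variant counts are negative binomial for donor transcripts (mean 18,
dispersion 0.02) and Poisson for the recurrent background (mean 2), both
thinned binomially by a per-variant detection probability (0.9) that
stands in for coverage-dependent variant discovery. The donor dispersion
is deliberately mild: large between-transcript variance would make the
fixed-threshold rule inoperable at any threshold, whereas 0.02 yields a
separable-but-imperfect regime (per-transcript miss rate ≈ 0.15) in which
the segmentation rules do real work.

What the generator does **not** emulate: read-level noise and alignment
artifacts, reference bias, linkage disequilibrium within blocks beyond the
block structure itself, transcript-length-dependent variant counts, and
expression-level-dependent detection. Passing the recovery benchmarks
therefore shows that the classification/segmentation logic is correct
under the stated error model, not that the thresholds are optimal for any
particular sequencing protocol.

## Breeding simulation

Meiosis uses the Haldane (no-interference) map function: between adjacent
markers at distance d Morgans the gamete switches parental homolog with
probability r = (1 − e^(−2d))/2, and each chromosome starts from a fair
homolog choice. Interference is not modelled — nothing in the accounting
depends on it, and the closed-form expectations used for validation hold
either way. The default map spreads 68 background SNPs over the 12
chromosomes in proportion to physical length at 4 cM/Mb, plus three
foreground markers on chromosome 1 at 9.06, 11.2 and 13.34 Mb (the
*Saltol*-flanking positions and one midway).

The scheme is one F1, `n_backcrosses` = 3 backcrosses to the recurrent
parent, then `n_selfings` = 3 selfings. Foreground positivity means
carrying the donor allele at every foreground marker during backcrossing
and being homozygous donor from the first selfing selection on; background
selection keeps, per family and generation, the foreground-positive
progeny with the highest background RPG (top-1; family sizes
configurable, default 24). Families with no acceptable progeny in a
generation are reported as extinct rather than silently resampled. Embryo
rescue is treated as guaranteed progeny viability — it has no
computational content.

RPG is allele-counted: RPG% = 100(2n_RR + n_RD)/(2n). Whether
heterozygotes should count half or be excluded is a reporting convention;
allele counting is the standard MABC accounting, is the only convention
under which 100 % coincides with a fully recurrent-homozygous line, and
makes RPG equal 100 minus the donor allele frequency percentage — which is
what the closed form 93.75 % at BC3 refers to. The no-selection validation
arm disables foreground selection too, since forcing the QTL heterozygous
would lift the donor allele frequency above 2⁻⁴.

Founder grouping fingerprints each line by its set of donor-carrying
markers and merges lines with identical fingerprints, or with Jaccard
distance ≤ 0.2 as a noise tolerance. Nested-fingerprint merging was
considered and rejected: every line shares the forced foreground core, so
small fingerprints nest inside larger ones and nestedness would collapse
unrelated founders. When founders have overlapping or minimal donor
patterns (high-RPG populations), fingerprints are genuinely ambiguous and
the method can only refine, not resolve, the founder partition.

## Phenotype model and indices

The generator drives every salt response from a latent tolerance τ ∈ [0,1]
per line (1 = damage-free). Control-condition traits sit at seedling-stage
baselines (FW 2.5 g, DW 0.35 g, SL 35 cm, RL 12 cm, CV 8 %); under salt
each trait mean shrinks by a trait-specific maximal loss (70/60/50/40 %)
scaled by 1 − τ. Electrolyte leakage is generated as a leaked fraction
0.08 + 0.70(1 − τ) of a conductivity Ec2 ≈ 1500 μS/cm, so 0 ≤ Ec1 ≤ Ec2
always holds. SES scores cut a Gaussian latent damage score 8(1 − τ) + ε
at thresholds 2/4/6/8 into the ordinal {1,3,5,7,9} scale; SES is treated
as ordinal throughout and only distributions (category percentages) are
computed, never parametric statistics. Tissue Na⁺/K⁺ ratios interpolate,
in τ, between published tolerant-parent and sensitive-parent anchor values
per tissue, with log-normal replicate noise around a potassium content of
600 mmol/kg DW.

Indices follow the standard definitions: EL = 100·Ec1/Ec2 (scale
invariant; Ec1 > Ec2 yields a value > 100 with a warning rather than an
error, since it can only arise from measurement problems the caller should
see); relative trait = 100·salt/control on grand means per line and
condition (per-tank pairing is not modelled); check normalisation divides
by the sensitive check's relative value, making the check's own fold
exactly 1. Mass-based ion inputs convert with atomic masses Na 22.990 and
K 39.098 g/mol. Line contrasts use pooled-variance Student's t by default
(a `welch` flag drops the equal-variance assumption), with stars at
P < 0.05 and P < 0.01.

## Differential expression

FPKM[g,s] = counts·10⁹/(length·libsize). The two-group test is an
exact-style conditional NB test: group sums are NB (a sum of n iid
NB(μ, φ) is NB(nμ, φ/n)), and the two-sided p-value is the probability,
under the conditional law of one group's sum given the total, of outcomes
no more likely than the one observed. For balanced designs the conditional
law is symmetric and the p-value is twice the lower tail; totals above
20,000 switch to the normal limit of the same law (continuity-corrected),
where enumeration would be slow and adds nothing. The common dispersion is
estimated by pooled method of moments with a small-sample correction:
φ̂ = Σ(v − m)/Σ(m² − v/n), which is close to unbiased at three replicates
(naïve per-gene ratios underestimate φ and inflate the type-I error above
nominal). All-zero genes get p = 1 with a flag. When known effective
library sizes are available (the generator records them), counts are
rescaled to the geometric-mean depth before testing — the exact test
assumes equal sizes — and FPKMs use those sizes; depth-normalisation
estimation (TMM and relatives) is out of scope.

DEG calling applies the printed operators literally: log₂FC strictly
greater than 0.5 (or strictly less than −0.5), P ≤ 0.05 non-strict, mean
FPKM ≥ 25 non-strict over the contrast's samples. log₂FC is computed on
group-mean FPKMs with a pseudo-count of 0.01 to guard empty groups. No
multiple-testing correction is applied by default, matching the raw-P
criterion; a Benjamini–Hochberg flag exists but is off. An
`inclusive_lfc` flag makes the fold-change bound non-strict for users
whose upstream tool behaved that way.

The overlap statistic is pct_common = 100·(common_up + common_down)/union.
With gene sets, the union is exact and a gene up in one genotype but down
in the other stays in the union without joining the common pool. With only
published totals, union = n_A + n_B − common, which presumes no such
opposite-direction genes among the common pool.

The expression generator draws log-normal relative abundances (σ = 1.2),
multiplies salt-condition means of responsive genes by 2^±effect, and does
**not** renormalise to a fixed total: responsive genes add or remove reads
at a known effective depth. This emulates ideally depth-normalised
libraries and keeps non-responsive genes' expected counts constant across
conditions; real libraries would additionally need composition-robust
normalisation, which is exactly the step left out of scope. Defaults
(11 %/13 % responsive per genotype, 2 % common, NB dispersion 0.1, three
replicates, 18–22 M reads) give a designed commonly-regulated percentage
of ≈ 9 %, the same order as the study system this package emulates.

## Problem sizes and determinism

Default problem sizes — 2,000 transcripts for mapping, 5,000 genes for
expression, 1,000 families for the backcross accounting, 2,000 genes for
the null calibration — are large enough for the Monte-Carlo checks to be
decisive (3-standard-error bands) while keeping any single stage in
seconds. All generators take explicit integer seeds and derive independent
streams from (seed, stream-id) tuples; identical seeds give bit-identical
outputs, and the pipeline manifest records SHA-256 digests so end-to-end
reproducibility is checkable.

## Known limitations

- The origin classifier needs expressed transcripts; silent donor loci are
  invisible and blocks spanning expression deserts will fragment.
- The fixed excess threshold presumes the donor/recurrent divergence of an
  *indica* × *japonica* cross; closer crosses need a recalibrated T.
- The NB test is a two-group test without covariates, shrinkage across
  genes, or normalisation estimation; it is a documented stand-in for a
  full count-model framework, validated by calibration rather than by
  numeric replication of any particular tool.
- Founder grouping is identifiability-limited: distinct founders with
  near-identical retained donor patterns cannot be separated by any
  fingerprint method.
- The phenotype generator produces exchangeable replicates; tank, batch
  and position effects present in real hydroponic assays are not
  modelled.
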