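"""Synthetic data with known ground truth for introgression-line analyses.

This module fabricates every input the rest of the package consumes: a
transcript annotation for a 12-chromosome rice-like genome, a haplotype
mosaic of homozygous *indica* donor segments inside a *japonica* recurrent
background, per-transcript variant-count profiles (test line and recurrent
control, both against the reference), negative-binomial expression counts
for a 2 genotypes x 2 conditions x 3 replicates design, and replicate-level
salt-stress phenotypes driven by a latent tolerance variable.

Ground truth (donor/recurrent label per transcript, differential-expression
gene sets, founder identities) is returned alongside the data so recovery of
the analysis stages can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a generator configuration violates its invariants."""


#: Approximate IRGSP-1.0 rice chromosome lengths (bp), chr1..chr12.
RICE_CHROM_BP: tuple[int, ...] = (
    43_270_000, 35_940_000, 36_410_000, 35_500_000,
    29_960_000, 31_250_000, 29_700_000, 28_440_000,
    23_010_000, 23_210_000, 29_020_000, 27_530_000,
)

#: SES ordinal categories (IRRI standard evaluation system for salt injury).
SES_LEVELS: tuple[int, ...] = (1, 3, 5, 7, 9)

PHENO_TRAITS: tuple[str, ...] = ("FW", "DW", "SL", "RL")

ION_TISSUES: tuple[str, ...] = (
    "young leaves", "old leaves", "sheath and stem", "shoot", "root",
)


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the simulated genome: chromosomes and gene intervals."""

    chrom_lengths_bp: tuple[int, ...] = RICE_CHROM_BP
    genes_per_chromosome: tuple[int, ...] = ()
    gene_length_bp: tuple[int, int] = (1_000, 6_000)

    def __post_init__(self) -> None:
        if not self.chrom_lengths_bp:
            raise ConfigurationError("at least one chromosome is required")
        if any(length <= 0 for length in self.chrom_lengths_bp):
            raise ConfigurationError("chromosome lengths must be positive")
        if not self.genes_per_chromosome:
            object.__setattr__(
                self, "genes_per_chromosome",
                _proportional_allocation(self.chrom_lengths_bp, 2_000),
            )
        if len(self.genes_per_chromosome) != len(self.chrom_lengths_bp):
            raise ConfigurationError(
                "genes_per_chromosome must match chromosome count")
        if any(n < 0 for n in self.genes_per_chromosome):
            raise ConfigurationError("gene counts must be non-negative")
        lo, hi = self.gene_length_bp
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid gene length range")
        for length, n in zip(self.chrom_lengths_bp, self.genes_per_chromosome):
            if n > 0 and length // n < hi:
                raise ConfigurationError(
                    "gene density too high for the maximum gene length")

    @property
    def n_chromosomes(self) -> int:
        return len(self.chrom_lengths_bp)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    @staticmethod
    def rice_like(n_genes: int = 2_000) -> "GenomeSpec":
        """Twelve rice-sized chromosomes with ``n_genes`` genes allocated
        proportionally to physical length."""
        return GenomeSpec(
            chrom_lengths_bp=RICE_CHROM_BP,
            genes_per_chromosome=_proportional_allocation(RICE_CHROM_BP, n_genes),
        )


def _proportional_allocation(lengths: Sequence[int], total: int) -> tuple[int, ...]:
    """Largest-remainder apportionment of ``total`` genes by chromosome length."""
    lengths = np.asarray(lengths, dtype=float)
    quota = total * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:remainder]] += 1
    return tuple(int(c) for c in counts)


@dataclass(frozen=True)
class DivergenceModel:
    """Per-transcript variant-count distributions versus the reference.

    Donor-origin transcripts carry many divergent sites against the
    *japonica* reference (negative binomial, mean ``mu_donor``); transcripts
    from the recurrent background show only natural variation (Poisson,
    mean ``mu_recurrent``). Each variant is observed with probability
    ``detection_prob`` (binomial thinning), modelling coverage-dependent
    variant discovery.
    """

    mu_donor: float = 18.0
    mu_recurrent: float = 2.0
    dispersion: float = 0.02
    detection_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.mu_donor < 0 or self.mu_recurrent < 0:
            raise ConfigurationError("means must be non-negative")
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")
        if not (0 <= self.detection_prob <= 1):
            raise ConfigurationError("detection_prob must lie in (0, 1]")


@dataclass(frozen=True)
class TruthMosaicConfig:
    """True architecture of the simulated line: homozygous donor blocks plus
    isolated donor genes scattered outside them."""

    donor_blocks: tuple[tuple[str, int, int], ...] = (
        ("chr1", 1_000_000, 13_000_000),
        ("chr1", 16_000_000, 30_000_000),
        ("chr3", 5_000_000, 23_000_000),
    )
    dispersed_donor_genes: int = 28
    zygosity: str = "homozygous"

    def __post_init__(self) -> None:
        if self.dispersed_donor_genes < 0:
            raise ConfigurationError("dispersed gene count must be >= 0")
        if self.zygosity != "homozygous":
            raise ConfigurationError("only homozygous donor segments are modelled")
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.donor_blocks:
            if start > end or start < 1:
                raise ConfigurationError(f"invalid block interval {start}-{end}")
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, intervals in by_chrom.items():
            intervals.sort()
            for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
                if s2 <= e1:
                    raise ConfigurationError(
                        f"overlapping donor blocks on {chrom}")


@dataclass(frozen=True)
class SaltTreatmentConfig:
    """Salt-stress treatment applied in the emulated hydroponic assay."""

    nacl_mM: float = 80.0
    duration_days_phenotype: int = 14
    duration_h_transcriptome: int = 24

    def __post_init__(self) -> None:
        if self.nacl_mM <= 0:
            raise ConfigurationError("NaCl concentration must be positive")


@dataclass(frozen=True)
class ExpressionDesign:
    """2 genotypes x 2 conditions x n replicates negative-binomial design.

    ``fraction_salt_responsive`` gives, per genotype, the fraction of genes
    whose salt-condition mean is shifted by ``effect_size_log2FC``;
    ``fraction_common_responsive`` of all genes respond in both genotypes
    (same direction). Defaults echo the magnitude of salt response observed
    in the IL/parent contrast this package emulates (~10 % of expressed
    genes responsive per genotype, a small commonly regulated core).
    """

    n_genes: int = 5_000
    replicates: int = 3
    fraction_salt_responsive: tuple[float, float] = (0.11, 0.13)
    fraction_common_responsive: float = 0.02
    effect_size_log2FC: float = 2.0
    nb_dispersion: float = 0.1
    library_size: tuple[int, int] = (18_000_000, 22_000_000)
    gene_length_bp: tuple[int, int] = (1_000, 6_000)
    genotypes: tuple[str, str] = ("IL", "parent")
    conditions: tuple[str, str] = ("control", "salt")

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ConfigurationError("at least two replicates are required")
        fa, fb = self.fraction_salt_responsive
        fc = self.fraction_common_responsive
        if not (0 <= fa <= 1 and 0 <= fb <= 1 and 0 <= fc <= 1):
            raise ConfigurationError("fractions must lie in [0, 1]")
        if fc > min(fa, fb):
            raise ConfigurationError(
                "common fraction cannot exceed either per-genotype fraction")
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("dispersion must be non-negative")


@dataclass(frozen=True)
class PhenotypeNoise:
    """Noise scales for the phenotype generator (coefficients of variation)."""

    trait_cv: float = 0.08
    el_sd: float = 0.03
    ses_sd: float = 1.2
    ion_cv: float = 0.10


# ---------------------------------------------------------------------------
# truth line + annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LineTruth:
    """Ground-truth description of a simulated introgression line."""

    donor_blocks: tuple[tuple[str, int, int], ...]
    labels: pd.Series  # transcript_id -> 'donor' | 'recurrent'
    dispersed_transcripts: tuple[str, ...]
    block_transcripts: tuple[tuple[str, ...], ...]  # per donor block, position sorted

    @property
    def donor_transcripts(self) -> frozenset[str]:
        return frozenset(self.labels.index[self.labels == "donor"])


def gen_annotation(genome: GenomeSpec, rng_seed: int) -> pd.DataFrame:
    """Place non-overlapping genes along each chromosome.

    Each chromosome is divided into equal slots, one gene per slot, jittered
    uniformly inside its slot, so intervals are sorted and disjoint by
    construction. Coordinates are 1-based inclusive (GFF3 convention).
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = genome.gene_length_bp
    records = []
    for chrom, chrom_len, n in zip(
            genome.chrom_names, genome.chrom_lengths_bp,
            genome.genes_per_chromosome):
        if n == 0:
            continue
        slot = chrom_len // n
        lengths = rng.integers(lo, hi + 1, size=n)
        offsets = rng.integers(0, np.maximum(slot - lengths, 1))
        starts = np.arange(n) * slot + offsets + 1
        ends = starts + lengths - 1
        strands = rng.choice(["+", "-"], size=n)
        for i in range(n):
            records.append((f"{chrom}g{i + 1:04d}", chrom,
                            int(starts[i]), int(ends[i]), strands[i]))
    ann = pd.DataFrame(
        records, columns=["transcript_id", "chrom", "start", "end", "strand"])
    return ann


def gen_truth_line(
    genome: GenomeSpec,
    mosaic_cfg: TruthMosaicConfig,
    rng_seed: int,
) -> tuple[pd.DataFrame, LineTruth]:
    """Generate an annotation and the true donor/recurrent label per transcript.

    A transcript is donor-origin when its interval overlaps a donor block;
    ``dispersed_donor_genes`` additional transcripts outside every block are
    flipped to donor, emulating isolated introgressed genes.
    """
    chrom_len = dict(zip(genome.chrom_names, genome.chrom_lengths_bp))
    for chrom, start, end in mosaic_cfg.donor_blocks:
        if chrom not in chrom_len:
            raise ConfigurationError(f"block chromosome {chrom!r} not in genome")
        if end > chrom_len[chrom]:
            raise ConfigurationError(
                f"block {chrom}:{start}-{end} exceeds chromosome length")

    ann = gen_annotation(genome, rng_seed)
    rng = np.random.default_rng((rng_seed, 1))

    labels = pd.Series("recurrent", index=ann["transcript_id"], name="label")
    block_members: list[tuple[str, ...]] = []
    in_any_block = np.zeros(len(ann), dtype=bool)
    for chrom, bstart, bend in mosaic_cfg.donor_blocks:
        hit = (
            (ann["chrom"] == chrom)
            & (ann["start"] <= bend)
            & (ann["end"] >= bstart)
        ).to_numpy()
        members = ann.loc[hit].sort_values("start")["transcript_id"]
        block_members.append(tuple(members))
        labels.loc[members] = "donor"
        in_any_block |= hit

    outside = ann.loc[~in_any_block, "transcript_id"].to_numpy()
    if mosaic_cfg.dispersed_donor_genes > len(outside):
        raise ConfigurationError(
            "not enough genes outside donor blocks for the dispersed count")
    dispersed = rng.choice(
        outside, size=mosaic_cfg.dispersed_donor_genes, replace=False)
    dispersed = tuple(sorted(dispersed))
    labels.loc[list(dispersed)] = "donor"

    truth = LineTruth(
        donor_blocks=mosaic_cfg.donor_blocks,
        labels=labels,
        dispersed_transcripts=dispersed,
        block_transcripts=tuple(block_members),
    )
    return ann, truth


# ---------------------------------------------------------------------------
# variant profiles
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mu: float, dispersion: float,
               size: int) -> np.ndarray:
    if mu == 0:
        return np.zeros(size, dtype=int)
    if dispersion <= 0:
        return rng.poisson(mu, size)
    shape = 1.0 / dispersion
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p, size)


def gen_variant_profiles(
    annotation: pd.DataFrame,
    labels: pd.Series,
    model: DivergenceModel,
    rng_seed: int,
) -> pd.DataFrame:
    """Draw per-transcript variant counts for the test line and the recurrent
    control, both against the reference.

    ``v_test`` follows the donor distribution for donor-labelled transcripts
    and the recurrent distribution otherwise; ``v_control`` always follows
    the recurrent distribution. Both are binomially thinned by the per-variant
    detection probability.
    """
    missing = set(annotation["transcript_id"]) - set(labels.index)
    if missing:
        raise ConfigurationError(
            f"{len(missing)} transcripts lack a truth label")
    rng = np.random.default_rng((rng_seed, 2))
    ids = annotation["transcript_id"].to_numpy()
    is_donor = (labels.loc[ids] == "donor").to_numpy()
    n = len(ids)

    v_test = np.empty(n, dtype=int)
    v_test[is_donor] = _nb_counts(
        rng, model.mu_donor, model.dispersion, int(is_donor.sum()))
    v_test[~is_donor] = rng.poisson(model.mu_recurrent, int((~is_donor).sum()))
    v_control = rng.poisson(model.mu_recurrent, n)

    v_test = rng.binomial(v_test, model.detection_prob)
    v_control = rng.binomial(v_control, model.detection_prob)

    out = annotation[["transcript_id", "chrom", "start", "end"]].copy()
    out["v_test"] = v_test
    out["v_control"] = v_control
    return out


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """True differential-expression sets used to build the count matrix."""

    up: Mapping[str, frozenset[str]]    # genotype -> up-regulated genes
    down: Mapping[str, frozenset[str]]  # genotype -> down-regulated genes

    def responsive(self, genotype: str) -> frozenset[str]:
        return self.up[genotype] | self.down[genotype]

    def common_percentage(self) -> float:
        """100 * |common up or down| / |union of responsive genes|."""
        genos = list(self.up)
        a, b = genos[0], genos[1]
        common = (self.up[a] & self.up[b]) | (self.down[a] & self.down[b])
        union = self.responsive(a) | self.responsive(b)
        if not union:
            return float("nan")
        return 100.0 * len(common) / len(union)


def gen_expression(
    design: ExpressionDesign,
    rng_seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, ExpressionTruth]:
    """Generate a genes x samples count matrix with known salt-responsive sets.

    Returns ``(counts, metadata, gene_lengths, truth)``. Baseline per-gene
    abundances are log-normal; responsive genes have their salt-condition
    mean multiplied by ``2**effect_size_log2FC`` (up) or its inverse (down)
    in the genotype(s) where they respond. Counts are negative binomial with
    a common dispersion.
    """
    rng = np.random.default_rng((rng_seed, 3))
    n = design.n_genes
    genes = np.array([f"gene{i + 1:05d}" for i in range(n)])
    lengths = pd.Series(
        rng.integers(design.gene_length_bp[0], design.gene_length_bp[1] + 1, n),
        index=genes, name="length_bp")

    # relative abundances (log-normal), normalised to sum to 1
    abundance = rng.lognormal(mean=0.0, sigma=1.2, size=n)
    abundance /= abundance.sum()

    g_a, g_b = design.genotypes
    fa, fb = design.fraction_salt_responsive
    n_common = round(design.fraction_common_responsive * n)
    n_a_only = round(fa * n) - n_common
    n_b_only = round(fb * n) - n_common
    if design.effect_size_log2FC == 0:
        n_common = n_a_only = n_b_only = 0
    picks = rng.choice(n, size=n_common + n_a_only + n_b_only, replace=False)
    common = picks[:n_common]
    a_only = picks[n_common:n_common + n_a_only]
    b_only = picks[n_common + n_a_only:]

    direction = {}  # gene index -> +1 up / -1 down, shared for common genes
    for idx in np.concatenate([common, a_only, b_only]):
        direction[int(idx)] = 1 if rng.random() < 0.5 else -1

    responsive = {g_a: np.concatenate([common, a_only]).astype(int),
                  g_b: np.concatenate([common, b_only]).astype(int)}
    up = {g: frozenset(genes[i] for i in responsive[g] if direction[int(i)] > 0)
          for g in (g_a, g_b)}
    down = {g: frozenset(genes[i] for i in responsive[g] if direction[int(i)] < 0)
            for g in (g_a, g_b)}
    truth = ExpressionTruth(up=up, down=down)

    fold = 2.0 ** design.effect_size_log2FC
    samples, columns = [], []
    cols = []
    for genotype in design.genotypes:
        for condition in design.conditions:
            mult = np.ones(n)
            if condition == design.conditions[1]:  # salt
                for idx in responsive[genotype]:
                    mult[int(idx)] = fold if direction[int(idx)] > 0 else 1 / fold
            for rep in range(1, design.replicates + 1):
                lib = int(rng.integers(design.library_size[0],
                                       design.library_size[1] + 1))
                # no renormalisation: responsive genes add or remove reads,
                # non-responsive genes keep identical expected counts at a
                # given depth (the data emulate ideally depth-normalised
                # libraries, with `lib` the known effective library size)
                mu = abundance * mult * lib
                if design.nb_dispersion <= 0:
                    col = rng.poisson(mu)
                else:
                    shape = 1.0 / design.nb_dispersion
                    p = shape / (shape + mu)
                    col = rng.negative_binomial(shape, p)
                cols.append(col)
                sample_id = f"{genotype}_{condition}_r{rep}"
                samples.append((sample_id, genotype, condition, rep, lib))
                columns.append(sample_id)
    counts = pd.DataFrame(
        np.column_stack(cols), index=genes, columns=columns)
    counts.index.name = "gene_id"
    metadata = pd.DataFrame(
        samples, columns=["sample_id", "genotype", "condition", "replicate",
                          "library_size"])
    return counts, metadata, lengths, truth


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

#: Control-condition trait baselines for a two-leaf-stage rice seedling.
TRAIT_BASELINE = {"FW": 2.5, "DW": 0.35, "SL": 35.0, "RL": 12.0}
#: Maximal fractional loss of each trait under salt for a fully sensitive line.
TRAIT_MAX_LOSS = {"FW": 0.70, "DW": 0.60, "SL": 0.50, "RL": 0.40}

#: Tissue Na+/K+ molar ratios under salt, anchored to the tolerant (FL478-like,
#: tolerance=1) and sensitive (OLESA-like, tolerance=0) parents.
ION_RATIO_TOLERANT = {"young leaves": 0.22, "old leaves": 1.19,
                      "sheath and stem": 1.21, "shoot": 0.90, "root": 1.89}
ION_RATIO_SENSITIVE = {"young leaves": 1.94, "old leaves": 2.92,
                       "sheath and stem": 5.33, "shoot": 3.29, "root": 1.72}
#: Typical tissue K+ content, mmol per kg dry weight.
ION_K_BASE = 600.0


def gen_phenotypes(
    tolerances: Mapping[str, float],
    treatment: SaltTreatmentConfig = SaltTreatmentConfig(),
    rng_seed: int = 0,
    n_replicates: int = 3,
    noise: PhenotypeNoise = PhenotypeNoise(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate replicate phenotype and ion tables for lines with latent
    tolerance in [0, 1] (1 = fully tolerant, damage-free).

    Returns ``(phenotypes, ions)``. Salt-condition trait means shrink
    monotonically as tolerance decreases; electrolyte-leakage conductivities
    satisfy 0 <= Ec1 <= Ec2; SES scores are produced by thresholding a
    Gaussian latent damage score into the ordinal {1,3,5,7,9} scale; ion
    amounts are positive, reported on a molar basis.
    """
    for line, tol in tolerances.items():
        if not (0.0 <= tol <= 1.0):
            raise ConfigurationError(f"tolerance of {line!r} outside [0, 1]")
    if n_replicates < 1:
        raise ConfigurationError("need at least one replicate")
    rng = np.random.default_rng((rng_seed, 4))

    pheno_rows = []
    ion_rows = []
    for line, tol in tolerances.items():
        damage = 1.0 - tol
        for rep in range(1, n_replicates + 1):
            control_vals = {
                t: TRAIT_BASELINE[t]
                * max(0.0, 1.0 + noise.trait_cv * rng.standard_normal())
                for t in PHENO_TRAITS}
            # control-condition electrolyte leakage is low and damage-free
            ec2_c = max(200.0, 1_500.0 + 150.0 * rng.standard_normal())
            el_c = np.clip(0.08 + noise.el_sd * rng.standard_normal(), 0.0, 1.0)
            pheno_rows.append(
                dict(line_id=line, replicate=rep, condition="control",
                     **{t: control_vals[t] for t in PHENO_TRAITS},
                     Ec1=el_c * ec2_c, Ec2=ec2_c, SES=np.nan))

            salt_vals = {}
            for t in PHENO_TRAITS:
                shrink = 1.0 - TRAIT_MAX_LOSS[t] * damage
                eps = noise.trait_cv * rng.standard_normal()
                salt_vals[t] = max(0.0, control_vals[t] * shrink * (1.0 + eps))
            ec2_s = max(200.0, 1_500.0 + 150.0 * rng.standard_normal())
            el_s = np.clip(
                0.08 + 0.70 * damage + noise.el_sd * rng.standard_normal(),
                0.0, 1.0)
            latent = 8.0 * damage + noise.ses_sd * rng.standard_normal()
            ses = SES_LEVELS[int(np.digitize(latent, [2.0, 4.0, 6.0, 8.0]))]
            pheno_rows.append(
                dict(line_id=line, replicate=rep, condition="salt",
                     **{t: salt_vals[t] for t in PHENO_TRAITS},
                     Ec1=el_s * ec2_s, Ec2=ec2_s, SES=ses))

            for tissue in ION_TISSUES:
                ratio = (ION_RATIO_TOLERANT[tissue]
                         + damage * (ION_RATIO_SENSITIVE[tissue]
                                     - ION_RATIO_TOLERANT[tissue]))
                k_amt = ION_K_BASE * np.exp(
                    noise.ion_cv * rng.standard_normal())
                na_amt = ratio * k_amt * np.exp(
                    noise.ion_cv * rng.standard_normal())
                ion_rows.append(
                    dict(line_id=line, tissue=tissue, replicate=rep,
                         na_amount=na_amt, k_amount=k_amt, unit="mol"))

    phenotypes = pd.DataFrame(pheno_rows)
    ions = pd.DataFrame(ion_rows)
    return phenotypes, ions
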