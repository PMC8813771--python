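"""Generator correctness: truth-label bookkeeping, distributional targets,
phenotype monotonicity and reproducibility."""

import numpy as np
import pandas as pd
import pytest

from saltil import synth
from saltil.synth import (
    ConfigurationError,
    DivergenceModel,
    ExpressionDesign,
    GenomeSpec,
    PhenotypeNoise,
    SES_LEVELS,
    TruthMosaicConfig,
    gen_expression,
    gen_phenotypes,
    gen_truth_line,
    gen_variant_profiles,
)

from conftest import SEED


class TestTruthLine:
    def test_no_donor_blocks_labels_everything_recurrent(self):
        cfg = TruthMosaicConfig(donor_blocks=(), dispersed_donor_genes=0)
        _, truth = gen_truth_line(GenomeSpec.rice_like(300), cfg, SEED)
        assert (truth.labels == "recurrent").all()

    def test_block_spanning_whole_chromosome_saturates_it(self):
        genome = GenomeSpec.rice_like(300)
        cfg = TruthMosaicConfig(
            donor_blocks=(("chr2", 1, genome.chrom_lengths_bp[1]),),
            dispersed_donor_genes=0)
        ann, truth = gen_truth_line(genome, cfg, SEED)
        on_chr2 = ann.loc[ann["chrom"] == "chr2", "transcript_id"]
        assert (truth.labels.loc[on_chr2] == "donor").all()
        off_chr2 = ann.loc[ann["chrom"] != "chr2", "transcript_id"]
        assert (truth.labels.loc[off_chr2] == "recurrent").all()

    def test_donor_count_matches_independent_interval_scan(self, default_scenario):
        """Donor labels = genes overlapping a block (brute-force scan) + 28."""
        annotation, truth, _ = default_scenario
        blocks = TruthMosaicConfig().donor_blocks
        in_block = 0
        for row in annotation.itertuples(index=False):
            if any(row.chrom == c and row.start <= e and row.end >= s
                   for c, s, e in blocks):
                in_block += 1
        n_donor = int((truth.labels == "donor").sum())
        assert n_donor == in_block + 28
        assert len(truth.dispersed_transcripts) == 28
        assert sum(len(b) for b in truth.block_transcripts) == in_block

    def test_dispersed_genes_lie_outside_every_block(self, default_scenario):
        annotation, truth, _ = default_scenario
        ann = annotation.set_index("transcript_id")
        for t in truth.dispersed_transcripts:
            row = ann.loc[t]
            assert not any(
                row["chrom"] == c and row["start"] <= e and row["end"] >= s
                for c, s, e in truth.donor_blocks)

    def test_annotation_intervals_sorted_and_disjoint(self, default_scenario):
        annotation, _, _ = default_scenario
        for _, sub in annotation.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] > ends[:-1]).all()
            assert (ends >= starts).all()

    def test_overlapping_blocks_rejected(self):
        with pytest.raises(ConfigurationError):
            TruthMosaicConfig(donor_blocks=(
                ("chr1", 100, 2_000_000), ("chr1", 1_000_000, 3_000_000)))

    def test_block_outside_chromosome_rejected(self):
        cfg = TruthMosaicConfig(
            donor_blocks=(("chr1", 1, 99_000_000),), dispersed_donor_genes=0)
        with pytest.raises(ConfigurationError):
            gen_truth_line(GenomeSpec.rice_like(100), cfg, SEED)


class TestVariantProfiles:
    def test_zero_detection_probability_zeroes_all_counts(self, default_scenario):
        annotation, truth, _ = default_scenario
        model = DivergenceModel(detection_prob=0.0)
        prof = gen_variant_profiles(annotation, truth.labels, model, SEED)
        assert (prof[["v_test", "v_control"]] == 0).all().all()

    def test_equal_means_give_zero_mean_excess(self):
        """With mu_donor == mu_recurrent the expected excess is 0; the
        empirical mean over >= 10,000 recurrent transcripts agrees within
        3 standard errors."""
        genome = GenomeSpec.rice_like(12_000)
        cfg = TruthMosaicConfig(donor_blocks=(), dispersed_donor_genes=0)
        ann, truth = gen_truth_line(genome, cfg, SEED)
        model = DivergenceModel(mu_donor=2.0, mu_recurrent=2.0)
        prof = gen_variant_profiles(ann, truth.labels, model, SEED)
        delta = (prof["v_test"] - prof["v_control"]).to_numpy(dtype=float)
        se = delta.std(ddof=1) / np.sqrt(len(delta))
        assert abs(delta.mean()) <= 3 * se

    def test_donor_mean_matches_thinning_expectation(self, default_scenario):
        """Donor transcripts: E[v_test] = 18 * 0.9 = 16.2 after thinning."""
        annotation, truth, profiles = default_scenario
        donors = truth.labels == "donor"
        v = profiles.set_index("transcript_id").loc[
            truth.labels.index[donors], "v_test"].to_numpy(dtype=float)
        se = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean() - 16.2) <= 3 * se

    def test_counts_non_negative_integers(self, default_scenario):
        _, _, profiles = default_scenario
        assert (profiles[["v_test", "v_control"]] >= 0).all().all()
        assert profiles["v_test"].dtype.kind in "iu"

    def test_negative_mean_rejected(self):
        with pytest.raises(ConfigurationError):
            DivergenceModel(mu_donor=-1.0)


class TestExpression:
    def test_zero_effect_size_empties_truth_sets(self):
        design = ExpressionDesign(n_genes=200, effect_size_log2FC=0.0)
        _, _, _, truth = gen_expression(design, SEED)
        assert truth.common_percentage() != truth.common_percentage()  # NaN
        assert all(not truth.responsive(g) for g in ("IL", "parent"))

    def test_identical_responsive_sets_give_100_percent_overlap(self):
        design = ExpressionDesign(
            n_genes=500, fraction_salt_responsive=(0.1, 0.1),
            fraction_common_responsive=0.1)
        _, _, _, truth = gen_expression(design, SEED)
        assert truth.responsive("IL") == truth.responsive("parent")
        assert truth.common_percentage() == pytest.approx(100.0)

    def test_truth_percentage_matches_direct_set_arithmetic(self):
        design = ExpressionDesign(
            n_genes=5_000, fraction_salt_responsive=(0.10, 0.12),
            fraction_common_responsive=0.01)
        _, _, _, truth = gen_expression(design, SEED)
        common = ((truth.up["IL"] & truth.up["parent"])
                  | (truth.down["IL"] & truth.down["parent"]))
        union = truth.responsive("IL") | truth.responsive("parent")
        assert truth.common_percentage() == pytest.approx(
            100.0 * len(common) / len(union))

    def test_design_shapes_and_metadata(self):
        design = ExpressionDesign(n_genes=300)
        counts, meta, lengths, _ = gen_expression(design, SEED)
        assert counts.shape == (300, 12)
        assert set(meta["genotype"]) == {"IL", "parent"}
        assert set(meta["condition"]) == {"control", "salt"}
        assert (lengths > 0).all()
        assert (counts >= 0).all().all()

    def test_single_replicate_rejected(self):
        with pytest.raises(ConfigurationError):
            ExpressionDesign(replicates=1)

    def test_common_fraction_cannot_exceed_per_genotype(self):
        with pytest.raises(ConfigurationError):
            ExpressionDesign(fraction_salt_responsive=(0.05, 0.2),
                             fraction_common_responsive=0.1)


class TestPhenotypes:
    def test_full_tolerance_and_zero_noise_means_no_damage(self):
        noise = PhenotypeNoise(trait_cv=0.0, el_sd=0.0, ses_sd=0.0, ion_cv=0.0)
        pheno, _ = gen_phenotypes({"T": 1.0}, rng_seed=SEED, noise=noise)
        means = pheno.groupby("condition")[["FW", "DW", "SL", "RL"]].mean()
        for trait in ("FW", "DW", "SL", "RL"):
            assert means.loc["salt", trait] == pytest.approx(
                means.loc["control", trait])

    def test_sensitive_line_leaks_more_electrolytes(self):
        pheno, _ = gen_phenotypes(
            {"tolerant": 0.9, "sensitive": 0.1}, rng_seed=SEED,
            n_replicates=100)
        salt = pheno[pheno["condition"] == "salt"]
        el = salt.groupby("line_id").apply(
            lambda s: (100 * s["Ec1"] / s["Ec2"]).mean(), include_groups=False)
        assert el["sensitive"] > el["tolerant"]

    def test_ses_scores_restricted_to_odd_scale(self):
        pheno, _ = gen_phenotypes(
            {"a": 0.8, "b": 0.4, "c": 0.0}, rng_seed=SEED, n_replicates=50)
        ses = pheno.loc[pheno["condition"] == "salt", "SES"]
        assert set(ses.astype(int)) <= set(SES_LEVELS)
        assert pheno.loc[pheno["condition"] == "control", "SES"].isna().all()

    def test_conductivity_ordering_and_positive_ions(self):
        pheno, ions = gen_phenotypes({"x": 0.5}, rng_seed=SEED, n_replicates=20)
        assert (pheno["Ec1"] <= pheno["Ec2"]).all()
        assert (pheno["Ec1"] >= 0).all()
        assert (ions[["na_amount", "k_amount"]] > 0).all().all()

    def test_out_of_range_tolerance_rejected(self):
        with pytest.raises(ConfigurationError):
            gen_phenotypes({"bad": 1.5}, rng_seed=SEED)


class TestReproducibility:
    def test_same_seed_bit_identical_different_seed_differs(self):
        genome = GenomeSpec.rice_like(300)
        cfg = TruthMosaicConfig(donor_blocks=(("chr1", 1, 10_000_000),),
                                dispersed_donor_genes=5)
        a1, t1 = gen_truth_line(genome, cfg, 7)
        a2, t2 = gen_truth_line(genome, cfg, 7)
        a3, _ = gen_truth_line(genome, cfg, 8)
        pd.testing.assert_frame_equal(a1, a2)
        pd.testing.assert_series_equal(t1.labels, t2.labels)
        assert not a1.equals(a3)

        p1 = gen_variant_profiles(a1, t1.labels, DivergenceModel(), 7)
        p2 = gen_variant_profiles(a1, t1.labels, DivergenceModel(), 7)
        p3 = gen_variant_profiles(a1, t1.labels, DivergenceModel(), 8)
        pd.testing.assert_frame_equal(p1, p2)
        assert not p1.equals(p3)
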