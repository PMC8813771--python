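"""Meiosis model, MABC scheme, RPG accounting, marker filtering and founder
grouping, checked against closed-form genetics where available."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saltil import breeding as br
from saltil.breeding import (
    BreedingError,
    GeneticMap,
    Individual,
    LineGenotype,
    SelectionConfig,
    default_genetic_map,
    filter_markers,
    group_by_founder,
    rpg_percent,
    run_mabc,
    simulate_gamete,
)

from conftest import SEED


def two_marker_map(cm_distance: float) -> GeneticMap:
    return GeneticMap(pd.DataFrame({
        "chrom": ["chr1", "chr1"],
        "marker_id": ["m1", "m2"],
        "pos_bp": [1_000_000, 2_000_000],
        "pos_cM": [0.0, cm_distance],
    }))


class TestGameteSimulation:
    def test_homozygous_parent_transmits_itself(self):
        gmap, _, _ = default_genetic_map()
        h = np.zeros(gmap.n_markers, dtype=np.int8)
        h[5:20] = 1
        parent = Individual(h0=h.copy(), h1=h.copy())
        rng = np.random.default_rng(SEED)
        for _ in range(5):
            assert np.array_equal(simulate_gamete(parent, gmap, rng), h)

    def test_tightly_linked_markers_co_inherited(self):
        """At ~0 cM distance the two markers never recombine."""
        gmap = two_marker_map(1e-9)
        parent = Individual(h0=np.array([1, 1], dtype=np.int8),
                            h1=np.array([0, 0], dtype=np.int8))
        rng = np.random.default_rng(SEED)
        gametes = br._gametes_batch(parent, gmap, rng, 10_000)
        assert (gametes[:, 0] == gametes[:, 1]).all()

    def test_haldane_recombinant_fraction_at_10_cM(self):
        """r = (1 - exp(-0.2))/2 = 0.0906 for 10 cM, within 3 binomial SE."""
        gmap = two_marker_map(10.0)
        parent = Individual(h0=np.array([1, 1], dtype=np.int8),
                            h1=np.array([0, 0], dtype=np.int8))
        rng = np.random.default_rng(SEED)
        n = 100_000
        gametes = br._gametes_batch(parent, gmap, rng, n)
        recomb = (gametes[:, 0] != gametes[:, 1]).mean()
        expected = 0.5 * (1.0 - np.exp(-0.2))
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recomb - expected) <= 3 * se

    @given(seed=st.integers(0, 1_000))
    @settings(derandomize=True, max_examples=25)
    def test_gamete_conserves_markers_and_alleles(self, seed):
        gmap, _, _ = default_genetic_map()
        rng = np.random.default_rng(seed)
        h0 = rng.integers(0, 2, gmap.n_markers).astype(np.int8)
        h1 = rng.integers(0, 2, gmap.n_markers).astype(np.int8)
        gamete = simulate_gamete(Individual(h0=h0, h1=h1), gmap, rng)
        assert gamete.shape == (gmap.n_markers,)
        ok = (gamete == h0) | (gamete == h1)
        assert ok.all()

    def test_map_requires_strictly_increasing_positions(self):
        with pytest.raises(BreedingError):
            GeneticMap(pd.DataFrame({
                "chrom": ["chr1", "chr1"], "marker_id": ["a", "b"],
                "pos_bp": [200, 100], "pos_cM": [0.0, 1.0]}))


class TestRpg:
    def test_all_recurrent_homozygous_is_100(self):
        assert rpg_percent(np.zeros(68, dtype=int)) == 100.0

    def test_all_heterozygous_is_50(self):
        assert rpg_percent(np.full(68, br.RD)) == 50.0

    def test_two_donor_homozygotes_of_68(self):
        states = np.zeros(68, dtype=int)
        states[:2] = br.DD
        assert rpg_percent(states) == pytest.approx(97.06, abs=0.005)

    def test_empty_panel_rejected(self):
        with pytest.raises(BreedingError):
            rpg_percent(np.array([], dtype=int))

    @given(seed=st.integers(0, 500))
    @settings(derandomize=True, max_examples=30)
    def test_invariant_under_marker_reordering(self, seed):
        rng = np.random.default_rng(seed)
        states = rng.integers(0, 3, 68)
        shuffled = rng.permutation(states)
        assert rpg_percent(states) == pytest.approx(rpg_percent(shuffled))
        donor_freq = 100.0 * states.sum() / (2 * len(states))
        assert rpg_percent(states) == pytest.approx(100.0 - donor_freq)


class TestMabc:
    def test_no_selection_matches_closed_form(self):
        """Mean RPG at BC3 with single progeny and no selection is
        100*(1 - (1/2)^4) = 93.75 % in expectation."""
        gmap, bg, fg = default_genetic_map()
        cfg = SelectionConfig(
            foreground_markers=fg, background_panel=bg, progeny_per_cross=1,
            n_selfings=0, selection="none", n_families=1_000)
        table = run_mabc(cfg, gmap, SEED).rpg_table(bg)
        se = table["rpg"].sem()
        assert abs(table["rpg"].mean() - 93.75) <= 3 * se

    def test_retained_lines_homozygous_donor_at_foreground(self):
        gmap, bg, fg = default_genetic_map()
        cfg = SelectionConfig(
            foreground_markers=fg, background_panel=bg, progeny_per_cross=24,
            selection="background", n_families=8)
        result = run_mabc(cfg, gmap, SEED)
        assert result.lines
        for line in result.lines:
            assert (line.state_of(fg) == br.DD).all()
            assert line.generation == "BC3F4"

    def test_background_selection_beats_no_selection_paired(self):
        """Paired-seed comparison: selecting the best-RPG foreground-positive
        progeny strictly raises the mean final RPG."""
        gmap, bg, fg = default_genetic_map()
        base = dict(foreground_markers=fg, background_panel=bg,
                    n_selfings=0, n_families=150)
        sel = run_mabc(SelectionConfig(
            progeny_per_cross=24, selection="background", **base), gmap, SEED)
        none = run_mabc(SelectionConfig(
            progeny_per_cross=1, selection="none", **base), gmap, SEED)
        assert (sel.rpg_table(bg)["rpg"].mean()
                > none.rpg_table(bg)["rpg"].mean())

    def test_selfing_halves_heterozygosity_in_expectation(self):
        """Without selection the expected heterozygote fraction halves per
        selfing generation (1/2 at F2, 1/4 at F3 from an all-het F1)."""
        gmap, bg, fg = default_genetic_map()
        rng = np.random.default_rng(SEED)
        f1 = Individual(h0=np.ones(gmap.n_markers, dtype=np.int8),
                        h1=np.zeros(gmap.n_markers, dtype=np.int8))
        n = 2_000
        het_f2, het_f3 = [], []
        for _ in range(n):
            f2 = Individual(h0=simulate_gamete(f1, gmap, rng),
                            h1=simulate_gamete(f1, gmap, rng))
            f3 = Individual(h0=simulate_gamete(f2, gmap, rng),
                            h1=simulate_gamete(f2, gmap, rng))
            het_f2.append((f2.states == br.RD).mean())
            het_f3.append((f3.states == br.RD).mean())
        assert np.mean(het_f2) == pytest.approx(0.5, abs=3 * np.std(het_f2) / np.sqrt(n))
        assert np.mean(het_f3) == pytest.approx(0.25, abs=3 * np.std(het_f3) / np.sqrt(n))

    def test_extinction_reported_not_silent(self):
        """With one progeny per cross, foreground selection usually fails in
        some generation; extinct lineages are recorded."""
        gmap, bg, fg = default_genetic_map()
        cfg = SelectionConfig(
            foreground_markers=fg, background_panel=bg, progeny_per_cross=1,
            selection="foreground", n_families=40)
        result = run_mabc(cfg, gmap, SEED)
        assert len(result.lines) + len(result.extinct_families) >= 40
        assert result.extinct_families  # essentially certain at 40 families

    def test_unknown_marker_rejected(self):
        gmap, bg, _ = default_genetic_map()
        cfg = SelectionConfig(foreground_markers=("nope",), background_panel=bg)
        with pytest.raises(BreedingError):
            run_mabc(cfg, gmap, SEED)


class TestFilterMarkers:
    def test_monomorphic_and_het_rate_rules(self):
        """Markers: one monomorphic, het rates 0/.10/.39/.40/.80 over 100
        lines; survivors are the polymorphic ones with het rate < 0.40."""
        rng = np.random.default_rng(SEED)
        markers = ["mono", "h00", "h10", "h39", "h40", "h80"]
        parents = pd.DataFrame(
            {"parent_a": ["A"] * 6, "parent_b": ["A", "B", "B", "B", "B", "B"]},
            index=markers)
        n = 100
        pop = {}
        for marker, n_het in [("mono", 0), ("h00", 0), ("h10", 10),
                              ("h39", 39), ("h40", 40), ("h80", 80)]:
            col = np.array(["A"] * (n - n_het) + ["H"] * n_het)
            pop[marker] = rng.permutation(col)
        population = pd.DataFrame(pop, index=[f"L{i}" for i in range(n)])
        kept = filter_markers(parents, population)
        assert set(kept) == {"h00", "h10", "h39"}

    def test_exact_threshold_marker_removed(self):
        parents = pd.DataFrame({"parent_a": ["A"], "parent_b": ["B"]},
                               index=["m"])
        population = pd.DataFrame({"m": ["H", "A", "A", "A", "A"]})  # 20 %
        assert filter_markers(parents, population, max_het=0.40) == ("m",)
        population = pd.DataFrame({"m": ["H", "H", "A", "A", "B"]})  # 40 %
        assert filter_markers(parents, population, max_het=0.40) == ()

    def test_parent_missing_marker_rejected(self):
        parents = pd.DataFrame({"parent_a": ["A"], "parent_b": ["B"]},
                               index=["m1"])
        population = pd.DataFrame({"m2": ["A", "A"]})
        with pytest.raises(BreedingError):
            filter_markers(parents, population)


def make_line(line_id, donor_markers, all_markers, founder=""):
    states = np.array([br.DD if m in donor_markers else br.RR
                       for m in all_markers], dtype=np.int8)
    return LineGenotype(line_id=line_id, marker_ids=tuple(all_markers),
                        states=states, founder_id=founder)


class TestFounderGrouping:
    MARKERS = [f"S{i}" for i in range(40)]

    def test_identical_lines_form_one_group(self):
        lines = [make_line(f"L{i}", {"S1", "S2"}, self.MARKERS)
                 for i in range(6)]
        assert len(group_by_founder(lines)) == 1

    def test_disjoint_donor_patterns_split(self):
        a = make_line("a", {"S1", "S2", "S3"}, self.MARKERS)
        b = make_line("b", {"S10", "S11", "S12"}, self.MARKERS)
        assert len(group_by_founder([a, b])) == 2

    def test_thirty_lines_from_four_founders_recovered(self):
        """Four founders with distinct introgression patterns, 30 descendant
        lines with ~10 % marker dropout: the founder partition is recovered
        exactly."""
        rng = np.random.default_rng(SEED)
        founders = {
            "f1": {"S0", "S1", "S2", "S3", "S4", "S5", "S6", "S7"},
            "f2": {"S10", "S11", "S12", "S13", "S14", "S15", "S16", "S17"},
            "f3": {"S20", "S21", "S22", "S23", "S24", "S25", "S26", "S27"},
            "f4": {"S30", "S31", "S32", "S33", "S34", "S35", "S36", "S37"},
        }
        lines = []
        truth = {}
        for i in range(30):
            founder = list(founders)[i % 4]
            pattern = {m for m in founders[founder] if rng.random() > 0.1}
            line = make_line(f"L{i:02d}", pattern, self.MARKERS, founder)
            lines.append(line)
            truth.setdefault(founder, set()).add(line.line_id)
        groups = group_by_founder(lines)
        assert len(groups) == 4
        assert {frozenset(g) for g in groups} == {
            frozenset(v) for v in truth.values()}

    def test_empty_population_rejected(self):
        with pytest.raises(BreedingError):
            group_by_founder([])
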