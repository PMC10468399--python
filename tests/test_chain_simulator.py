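"""Mayo-Lewis closed form, terminal-model kinetics and drift simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhpkit.chain_simulator import (
    ChainEnsemble,
    DriftConfig,
    FeedComposition,
    ReactivityMatrix,
    RHP_FEED_PRESETS,
    block_length_distribution,
    block_permutation_library,
    ensemble_composition,
    mayo_lewis_F1,
    propagation_probs,
    read_ensemble,
    simulate_ensemble,
    write_ensemble,
)


class TestMayoLewis:
    @pytest.mark.parametrize(
        "f1,r1,r2,expected",
        [
            (0.5, 1.0, 1.0, 0.5),            # ideal: F1 = f1
            (1.0, 2.0, 0.5, 1.0),            # single-monomer limit
            (0.0, 2.0, 0.5, 0.0),
            (0.5, 2.0, 0.5, 0.75 / 1.125),   # hand arithmetic
        ],
    )
    def test_closed_form(self, f1, r1, r2, expected):
        assert mayo_lewis_F1(f1, r1, r2) == pytest.approx(expected)

    def test_nonpositive_ratio_errors(self):
        with pytest.raises(ValueError):
            mayo_lewis_F1(0.5, 0.0, 1.0)
        with pytest.raises(ValueError):
            mayo_lewis_F1(0.5, 1.0, -1.0)

    @given(
        f1=st.floats(min_value=0.0, max_value=1.0),
        r1=st.floats(min_value=0.01, max_value=100.0),
        r2=st.floats(min_value=0.01, max_value=100.0),
    )
    @settings(deadline=None, max_examples=200)
    def test_bounded(self, f1, r1, r2):
        assert 0.0 <= mayo_lewis_F1(f1, r1, r2) <= 1.0

    def test_ideal_case_identity(self):
        for f1 in np.linspace(0, 1, 11):
            assert mayo_lewis_F1(f1, 1.0, 1.0) == pytest.approx(f1)


class TestPropagationProbs:
    def test_ideal_kinetics_reproduce_feed(self):
        feed = FeedComposition({"A": 0.3, "B": 0.5, "C": 0.2})
        r = ReactivityMatrix.ideal(("A", "B", "C"))
        probs = propagation_probs("A", feed, r)
        assert probs == pytest.approx(feed.fractions)

    def test_two_monomer_hand_value(self):
        # f = (0.5, 0.5), r12 = 2 -> weights (0.5, 0.25) -> (2/3, 1/3)
        feed = FeedComposition({"A": 0.5, "B": 0.5})
        r = ReactivityMatrix(("A", "B"), {("A", "B"): 2.0})
        probs = propagation_probs("A", feed, r)
        assert probs["A"] == pytest.approx(2 / 3)
        assert probs["B"] == pytest.approx(1 / 3)

    def test_exhausted_monomer_gets_zero(self):
        feed = {"A": 1.0, "B": 0.0}
        r = ReactivityMatrix(("A", "B"))
        assert propagation_probs("A", feed, r)["B"] == 0.0

    def test_all_zero_feed_errors(self):
        r = ReactivityMatrix(("A", "B"))
        with pytest.raises(ValueError):
            propagation_probs("A", {"A": 0.0, "B": 0.0}, r)

    def test_probabilities_sum_to_one(self):
        feed = RHP_FEED_PRESETS["RHP4"]
        r = ReactivityMatrix.ideal(feed.monomers)
        for m in feed.monomers:
            assert sum(propagation_probs(m, feed, r).values()) == pytest.approx(1.0)


def _markov_expected_fraction(f1, r1, r2, dp):
    """Enumeration oracle: expected fraction of monomer 1 in a chain grown
    at fixed feed, with the first unit drawn from the feed and subsequent
    units from the terminal-model transition matrix."""
    feed = {"A": f1, "B": 1 - f1}
    r = ReactivityMatrix(("A", "B"), {("A", "B"): r1, ("B", "A"): r2})
    P = np.array(
        [
            [propagation_probs(m, feed, r)["A"], propagation_probs(m, feed, r)["B"]]
            for m in "AB"
        ]
    )
    pi = np.array([f1, 1 - f1])
    total = 0.0
    for _ in range(dp):
        total += pi[0]
        pi = pi @ P
    return total / dp


class TestSimulateEnsemble:
    def test_homopolymer_feed(self):
        feed = FeedComposition({"A": 1.0})
        r = ReactivityMatrix(("A",))
        e = simulate_ensemble(("A",), feed, r, DriftConfig(n_chains=5, dp=10, seed=0))
        assert e.chains == ["A" * 10] * 5

    def test_seeded_determinism(self):
        feed = RHP_FEED_PRESETS["RHP4"]
        r = ReactivityMatrix.ideal(feed.monomers)
        cfg = DriftConfig(n_chains=50, dp=50, seed=42)
        e1 = simulate_ensemble(feed.monomers, feed, r, cfg)
        e2 = simulate_ensemble(feed.monomers, feed, r, cfg)
        assert e1.chains == e2.chains

    def test_chain_lengths(self):
        feed = FeedComposition({"A": 0.5, "B": 0.5})
        r = ReactivityMatrix(("A", "B"))
        e = simulate_ensemble(("A", "B"), feed, r, DriftConfig(n_chains=20, dp=37, seed=1))
        assert all(len(c) == 37 for c in e.chains)

    def test_full_conversion_composition_conservation(self):
        # at conversion 1 the chains consume the entire pool, so the
        # ensemble composition equals the feed up to integer rounding
        feed = RHP_FEED_PRESETS["RHP4"]
        r = ReactivityMatrix.ideal(feed.monomers)
        cfg = DriftConfig(n_chains=200, dp=50, conversion=1.0, seed=5)
        e = simulate_ensemble(feed.monomers, feed, r, cfg)
        comp = ensemble_composition(e)
        total_units = 200 * 50
        for m, f in feed.fractions.items():
            assert comp[m] == pytest.approx(f, abs=1.5 / total_units * len(feed.monomers))

    def test_low_conversion_matches_markov_oracle(self):
        # Monte-Carlo mean chain composition vs the exact Markov-chain
        # expectation (enumeration oracle), within 3 standard errors
        for f1, r1, r2, seed in [(0.5, 2.0, 0.5, 1), (0.7, 0.5, 2.0, 3)]:
            feed = FeedComposition({"A": f1, "B": 1 - f1})
            r = ReactivityMatrix(("A", "B"), {("A", "B"): r1, ("B", "A"): r2})
            cfg = DriftConfig(n_chains=2000, dp=50, conversion=0.02, seed=seed)
            e = simulate_ensemble(("A", "B"), feed, r, cfg)
            fr = np.array([c.count("A") / len(c) for c in e.chains])
            se = fr.std(ddof=1) / math.sqrt(len(fr))
            expected = _markov_expected_fraction(f1, r1, r2, 50)
            assert abs(fr.mean() - expected) < 3 * se

    def test_no_drift_with_ideal_ratios_at_low_conversion(self):
        # per-position monomer frequency is position-independent
        feed = FeedComposition({"A": 0.5, "B": 0.5})
        r = ReactivityMatrix(("A", "B"))
        cfg = DriftConfig(n_chains=3000, dp=50, conversion=0.01, seed=9)
        e = simulate_ensemble(("A", "B"), feed, r, cfg)
        by_pos = np.array(
            [[c[k] == "A" for k in range(50)] for c in e.chains], dtype=float
        ).mean(axis=0)
        se = 0.5 / math.sqrt(3000)
        assert np.all(np.abs(by_pos - 0.5) < 4 * se)

    def test_depleted_monomer_drops_out_gracefully(self):
        # a rare monomer with strongly favouring cross-propagation is
        # consumed early; once its pool empties its probability is zero
        # and chains finish from the remaining monomers
        feed = FeedComposition({"A": 0.99, "B": 0.01})
        r = ReactivityMatrix(("A", "B"), {("A", "B"): 0.001, ("B", "A"): 1000.0})
        cfg = DriftConfig(n_chains=100, dp=50, conversion=1.0, seed=0)
        e = simulate_ensemble(("A", "B"), feed, r, cfg)
        comp = ensemble_composition(e)
        # entire B pool (1% of 5000 units) ends up in the chains
        assert comp["B"] == pytest.approx(0.01, abs=1e-9)
        assert all(len(c) == 50 for c in e.chains)

    def test_subsample(self):
        feed = FeedComposition({"A": 1.0})
        r = ReactivityMatrix(("A",))
        e = simulate_ensemble(("A",), feed, r, DriftConfig(n_chains=30, dp=5, seed=0))
        sub = e.subsample(10, seed=1)
        assert len(sub) == 10


class TestEnsembleComposition:
    def test_homopolymer(self):
        assert ensemble_composition(["AAAA", "AAAA"]) == {"A": 1.0}

    def test_fractions_sum_to_one(self):
        comp = ensemble_composition(["AABB", "ABAB", "BBBB"])
        assert sum(comp.values()) == pytest.approx(1.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            ensemble_composition([])


class TestBlockLengths:
    def test_simple_runs(self):
        hist = block_length_distribution(["PPPHH"])
        assert hist == {"P": {3: 1}, "H": {2: 1}}

    def test_alternating_runs(self):
        hist = block_length_distribution(["PHPH"])
        assert hist == {"P": {1: 2}, "H": {1: 2}}

    def test_run_lengths_conserve_sequence_length(self):
        rng = np.random.default_rng(3)
        seqs = ["".join(rng.choice(list("PHVC"), size=60)) for _ in range(20)]
        hist = block_length_distribution(seqs)
        total = sum(n * c for runs in hist.values() for n, c in runs.items())
        assert total == 20 * 60

    def test_by_class_reduction(self):
        hist = block_length_distribution(["MME"], class_map={"M": "H", "E": "V"})
        assert hist == {"H": {2: 1}, "V": {1: 1}}

    def test_interior_runs_match_enumeration_oracle(self):
        # ideal kinetics at vanishing conversion give i.i.d. letters; the
        # pooled mean length of interior maximal A-runs in fixed-length
        # chains was computed exactly by enumerating all 2^10 strings of
        # length 10 at p = 0.5 (boundary truncation shifts it below the
        # unconstrained geometric mean 1/(1-p) = 2)
        exact_pooled_mean = 1.7200223089793643
        feed = FeedComposition({"A": 0.5, "B": 0.5})
        r = ReactivityMatrix(("A", "B"))
        cfg = DriftConfig(n_chains=4000, dp=10, conversion=0.01, seed=13)
        e = simulate_ensemble(("A", "B"), feed, r, cfg)
        runs = []
        for chain in e.chains:
            for part in chain.split("B")[1:-1]:
                if part:
                    runs.append(len(part))
        runs = np.array(runs, dtype=float)
        se = runs.std(ddof=1) / math.sqrt(len(runs))
        assert abs(runs.mean() - exact_pooled_mean) < 3 * se


class TestBlockPermutationLibrary:
    @pytest.mark.parametrize(
        "blocks,n_expected",
        [
            (["PP", "HH", "VV", "CC"], 24),   # 4 distinct blocks -> 4!
            (["PPHH"], 1),
            (["PP", "HH", "VV"], 6),
        ],
    )
    def test_counts(self, blocks, n_expected):
        lib = block_permutation_library(blocks)
        assert len(lib) == n_expected
        assert len(set(lib)) == n_expected
        # every entry is a concatenation of all blocks
        total = sum(len(b) for b in blocks)
        assert all(len(s) == total for s in lib)

    def test_duplicate_blocks_deduplicated(self):
        lib = block_permutation_library(["PP", "PP", "HH"])
        assert len(lib) == 3  # 3!/2! distinct orderings

    def test_block_count_limits(self):
        with pytest.raises(ValueError):
            block_permutation_library([])
        with pytest.raises(ValueError):
            block_permutation_library(["P"] * 7)


class TestEnsembleIO:
    def test_round_trip(self, tmp_path):
        feed = FeedComposition({"A": 0.5, "B": 0.5})
        r = ReactivityMatrix(("A", "B"), {("A", "B"): 2.0, ("B", "A"): 0.5})
        cfg = DriftConfig(n_chains=10, dp=20, conversion=0.5, seed=7)
        e = simulate_ensemble(("A", "B"), feed, r, cfg)
        path = tmp_path / "ens.txt"
        write_ensemble(path, e)
        back = read_ensemble(path)
        assert back.chains == e.chains
        assert back.feed.fractions == pytest.approx(e.feed.fractions)
        assert back.config.seed == 7
        assert back.reactivity[("A", "B")] == pytest.approx(2.0)


class TestValidation:
    def test_feed_must_sum_to_one(self):
        with pytest.raises(ValueError):
            FeedComposition({"A": 0.5, "B": 0.6})

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            FeedComposition({"A": -0.1, "B": 1.1})

    def test_reactivity_diagonal_fixed(self):
        with pytest.raises(ValueError):
            ReactivityMatrix(("A", "B"), {("A", "A"): 2.0})

    def test_drift_config_bounds(self):
        with pytest.raises(ValueError):
            DriftConfig(n_chains=0)
        with pytest.raises(ValueError):
            DriftConfig(conversion=0.0)
        with pytest.raises(ValueError):
            DriftConfig(conversion=1.2)
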