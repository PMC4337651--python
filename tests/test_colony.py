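"""Colony branching-process simulator: classes, invariants, backends."""

import numpy as np
import pytest

import episwitch as ep
from episwitch.colony import PATTERN_NUMBERS, classify_by_fraction
from episwitch.errors import ParameterError, UnsupportedTimingModelError


@pytest.mark.parametrize(
    "kwargs",
    [
        {"p_div": -0.1},
        {"p_div": 1.5},
        {"p_div": 0.1, "q_pre": 2.0},
        {"p_div": 0.1, "generations": 0},
        {"p_div": 0.1, "timing_model": "bogus"},
        {"p_div": 0.1, "f_pre_replication": -0.2},
    ],
)
def test_invalid_parameters_rejected(kwargs):
    with pytest.raises(ParameterError):
        ep.SwitchParams(**kwargs)


def test_explicit_seed_required():
    with pytest.raises(ValueError, match="explicit seed"):
        ep.simulate_colony(ep.SwitchParams(p_div=0.1), None)


@pytest.mark.parametrize("generations", [1, 5, 10])
def test_zero_rate_colony_stays_red(generations):
    out = ep.simulate_colony(ep.SwitchParams(p_div=0.0, generations=generations), 7)
    assert out.colony_class == "red"
    assert out.green_fraction == 0.0
    assert out.events == ()


def test_forced_first_division_event_makes_half_sector():
    out = ep.simulate_colony(ep.SwitchParams(p_div=1.0, generations=1), 3)
    assert out.colony_class == "half_sector"
    assert out.green_fraction == 0.5
    assert len(out.events) == 1 and out.events[0].generation == 1
    assert out.events[0].affected in ("mother", "daughter")


def test_pre_switched_founder_is_fully_green():
    out = ep.simulate_colony(ep.SwitchParams(p_div=0.5, q_pre=1.0, generations=4), 5)
    assert out.colony_class == "full_green"
    assert out.founder_pre_switched
    assert out.green_fraction == 1.0


@pytest.mark.parametrize("timing_model", ["simple", "cell_cycle"])
def test_switched_state_is_heritable_and_irreversible(timing_model):
    """Every descendant of a switched cell is switched, in every generation."""
    params = ep.SwitchParams(p_div=0.25, generations=6, timing_model=timing_model)
    rng = np.random.default_rng(42)
    for _ in range(20):
        out, tree = ep.simulate_colony(params, rng, return_tree=True)
        for parents, children in zip(tree[:-1], tree[1:]):
            idx = np.flatnonzero(parents)
            assert children[2 * idx].all() and children[2 * idx + 1].all()
        # green_fraction is the switched share of the final generation
        assert out.green_fraction == pytest.approx(tree[-1].mean())


def test_population_zero_rate_all_red():
    tally = ep.simulate_population(ep.SwitchParams(p_div=0.0), 1000, 11)
    assert tally.total_colonies == 1000
    assert tally.half_sectored == 0 and tally.fully_green == 0
    assert tally.red == 1000


def test_population_pre_switched_binomial():
    n = 100_000
    tally = ep.simulate_population(ep.SwitchParams(p_div=0.0, q_pre=0.05), n, 13)
    sd = np.sqrt(n * 0.05 * 0.95)
    assert abs(tally.fully_green - 0.05 * n) <= 3 * sd


def test_half_sector_tally_tracks_rate():
    n, p = 100_000, 0.01
    tally = ep.simulate_population(ep.SwitchParams(p_div=p, generations=8), n, 17)
    sd = np.sqrt(n * p * (1 - p))
    assert abs(tally.half_sectored - n * p) <= 3 * sd


@pytest.mark.parametrize("timing_model", ["simple", "cell_cycle"])
def test_thinned_and_tree_backends_agree(timing_model):
    """Class frequencies from both backends differ by <= 3 pooled SE."""
    params = ep.SwitchParams(p_div=0.02, generations=8, timing_model=timing_model)
    n = 10_000
    thinned = ep.simulate_colony_table(params, n, 101, method="thinned")
    tree = ep.simulate_colony_table(params, n, 202, method="tree")
    for cls in ("red", "half_sector", "partial_sector", "full_green"):
        f1 = (thinned["class"] == cls).mean()
        f2 = (tree["class"] == cls).mean()
        pooled = (f1 + f2) / 2
        se = np.sqrt(2 * pooled * (1 - pooled) / n) or 1 / n
        assert abs(f1 - f2) <= 3 * se + 1e-12, (cls, f1, f2)


def test_half_sector_frequency_monotone_in_rate():
    """Common random numbers: half-sector frequency and green fraction both
    non-decreasing across a 1000-fold range of switching rates."""
    freqs, greens = [], []
    for p in (1e-4, 1e-3, 1e-2, 1e-1):
        table = ep.simulate_colony_table(ep.SwitchParams(p_div=p), 20_000, 99)
        freqs.append((table["class"] == "half_sector").mean())
        greens.append(table["green_fraction"].mean())
    assert freqs == sorted(freqs)
    assert greens == sorted(greens)


def test_colony_table_schema_and_determinism():
    params = ep.SwitchParams(p_div=0.05, generations=6)
    a = ep.simulate_colony_table(params, 500, 8)
    b = ep.simulate_colony_table(params, 500, 8)
    assert list(a.columns) == [
        "colony_id", "class", "green_fraction", "n_events", "first_event_generation"
    ]
    assert a.equals(b)
    # colonies without events report first_event_generation 0 and stay red
    no_events = a[a["n_events"] == 0]
    assert (no_events["class"] == "red").all()
    assert (no_events["first_event_generation"] == 0).all()


def test_both_progeny_switches_only_before_replication():
    params = ep.SwitchParams(p_div=0.3, generations=5, timing_model="cell_cycle")
    rng = np.random.default_rng(55)
    seen = set()
    for _ in range(60):
        out = ep.simulate_colony(params, rng)
        for e in out.events:
            seen.add(e.phase)
            if e.affected == "both":
                assert e.phase == "pre_replication"
            else:
                assert e.phase == "post_replication"
    assert seen == {"pre_replication", "post_replication"}


def test_event_invariant_enforced():
    with pytest.raises(ParameterError):
        ep.SwitchEvent(generation=2, lineage="0", affected="both", phase="post_replication")


class TestPatternClassifier:
    params = ep.SwitchParams(p_div=0.1, timing_model="cell_cycle", gfp_delay=0.5)

    def classify(self, affected, phase, t):
        e = ep.SwitchEvent(generation=2, lineage="1", affected=affected, phase=phase, time_in_cycle=t)
        return ep.classify_switch_pattern(e, self.params)

    def test_pre_replication_small_bud_detection_is_pattern_6(self):
        pat = self.classify("both", "pre_replication", 0.1)  # detect at 0.6
        assert pat.bud_stage == "small_budded" and pat.progeny == "both"
        assert pat.number == 6

    def test_post_replication_large_bud_mother_is_pattern_7(self):
        pat = self.classify("mother", "post_replication", 0.4)  # detect at 0.9
        assert pat.bud_stage == "large_budded" and pat.number == 7

    def test_post_replication_large_bud_daughter_is_pattern_8(self):
        assert self.classify("daughter", "post_replication", 0.45).number == 8

    def test_detection_after_cytokinesis_scores_unbudded(self):
        pat = self.classify("mother", "post_replication", 0.9)  # detect at 1.4
        assert pat.bud_stage == "unbudded" and pat.number == 2
        assert self.classify("daughter", "post_replication", 0.95).number == 1

    def test_no_event_returns_none(self):
        assert ep.classify_switch_pattern(None, self.params) is None

    def test_simple_mode_event_unsupported(self):
        e = ep.SwitchEvent(generation=1, lineage="", affected="mother")
        with pytest.raises(UnsupportedTimingModelError):
            ep.classify_switch_pattern(e, self.params)

    def test_taxonomy_separates_progeny_by_phase(self):
        """Both-progeny patterns arise only from pre-replication events and
        single-progeny patterns only from post-replication events."""
        params = ep.SwitchParams(
            p_div=0.3, generations=5, timing_model="cell_cycle", f_pre_replication=0.5
        )
        rng = np.random.default_rng(77)
        n_both = n_single = 0
        for _ in range(60):
            for e in ep.simulate_colony(params, rng).events:
                pat = ep.classify_switch_pattern(e, params)
                both_pattern = pat.progeny == "both"
                if both_pattern:
                    n_both += 1
                    assert e.phase == "pre_replication"
                    assert pat.number in (3, 6, None)
                else:
                    n_single += 1
                    assert e.phase == "post_replication"
                    assert pat.number in (1, 2, 4, 5, 7, 8)
        assert n_both > 0 and n_single > 0


@pytest.mark.parametrize(
    "fraction,expected",
    [
        (0.0, "red"),
        (0.03, "red"),
        (0.47, "half_sector"),
        (0.54, "half_sector"),
        (0.7, "partial_sector"),
        (0.2, "partial_sector"),
        (0.98, "full_green"),
        (1.0, "full_green"),
    ],
)
def test_fraction_classifier_bands(fraction, expected):
    assert classify_by_fraction(fraction) == expected


def test_pattern_table_is_complete():
    stages = {s for s, _ in PATTERN_NUMBERS}
    progeny = {p for _, p in PATTERN_NUMBERS}
    assert len(PATTERN_NUMBERS) == len(stages) * len(progeny)
    numbers = [n for n in PATTERN_NUMBERS.values() if n is not None]
    assert sorted(numbers) == list(range(1, 9))
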