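"""Branching-process simulator of colony growth with rare irreversible switching.

A colony grows from a single founder cell by synchronous binary divisions.
At each division of an unswitched cell, a loss-of-silencing event occurs with
probability ``p_div`` and permanently switches the reporter cassette in one
(or, before DNA replication, both) of the two progeny. Switched state is
heritable and irreversible, so each event founds a green sector whose size
records how early in colony growth the event happened. A switch at the very
first division produces a half-red/half-green colony; the frequency of such
colonies estimates the per-division switching rate.

Two simulation backends are provided:

* an explicit lineage tree (``method="tree"``), which records every event with
  its lineage address and supports the cell-cycle-resolved pattern classifier;
* a generation-wise binomial-thinning sampler (``method="thinned"``), which
  tracks only the number of unswitched cells per generation and is O(generations)
  per colony batch, enabling population-scale runs (10^5-10^6 colonies).

The two backends sample the same distribution over colony classes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from ._rng import ensure_rng
from .errors import ParameterError, UnsupportedTimingModelError

__all__ = [
    "SwitchParams",
    "SwitchEvent",
    "ColonyOutcome",
    "SwitchPattern",
    "simulate_colony",
    "simulate_population",
    "simulate_colony_table",
    "classify_switch_pattern",
    "classify_by_fraction",
    "PATTERN_NUMBERS",
]

ColonyClass = Literal["red", "half_sector", "partial_sector", "full_green"]

#: Bud-stage-at-detection x surviving-green-progeny taxonomy. Nine combinations
#: exist; only eight carry a number (a large-budded cell whose mother and
#: daughter both remain green falls outside the numbered set).
PATTERN_NUMBERS: dict[tuple[str, str], int | None] = {
    ("unbudded", "daughter"): 1,
    ("unbudded", "mother"): 2,
    ("unbudded", "both"): 3,
    ("small_budded", "mother"): 4,
    ("small_budded", "daughter"): 5,
    ("small_budded", "both"): 6,
    ("large_budded", "mother"): 7,
    ("large_budded", "daughter"): 8,
    ("large_budded", "both"): None,
}


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0) or not np.isfinite(value):
        raise ParameterError(f"{name} must be in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SwitchParams:
    """Generative parameters of the silencing-loss / recombination process.

    Parameters
    ----------
    p_div : float
        Probability per cell division that a loss-of-silencing event produces
        a permanent reporter switch.
    q_pre : float
        Probability the founder cell is already switched at plating (escape
        from drug pre-selection). Default 0.
    generations : int
        Number of division generations simulated per colony. Default 14
        (~1.6e4 final cells, past the point where new sectors are scoreable).
    timing_model : {"simple", "cell_cycle"}
        ``simple``: each event switches exactly one progeny of the division.
        ``cell_cycle``: the event time is drawn uniformly within the cycle; an
        event before DNA replication switches both progeny, after replication
        exactly one.
    f_pre_replication : float
        In ``cell_cycle`` mode, probability the recombination acts before DNA
        replication. Unused in ``simple`` mode.
    gfp_delay : float
        Lag, in fractions of a cell cycle, between recombination and first
        detectable reporter signal. Used only by the pattern classifier.
    visible_horizon : int
        Events after this generation do not affect the colony class (the
        sectors they found are too small to score). Default 6.
    half_sector_tolerance : float
        Tolerance of the fraction-based classifier
        (:func:`classify_by_fraction`) used for rendered colony images; the
        generative classifier is event-based and does not use it. Default 0.05.
    large_bud_fraction : float
        Cycle fraction at which a small bud becomes a large bud, for the
        pattern classifier. Bud emergence coincides with the start of DNA
        replication (``f_pre_replication``).
    """

    p_div: float
    q_pre: float = 0.0
    generations: int = 14
    timing_model: str = "simple"
    f_pre_replication: float = 0.25
    gfp_delay: float = 0.5
    visible_horizon: int = 6
    half_sector_tolerance: float = 0.05
    large_bud_fraction: float = 0.7

    def __post_init__(self) -> None:
        _check_prob("p_div", self.p_div)
        _check_prob("q_pre", self.q_pre)
        _check_prob("f_pre_replication", self.f_pre_replication)
        _check_prob("half_sector_tolerance", self.half_sector_tolerance)
        if self.timing_model not in ("simple", "cell_cycle"):
            raise ParameterError(
                f"timing_model must be 'simple' or 'cell_cycle', got {self.timing_model!r}"
            )
        if int(self.generations) != self.generations or self.generations < 1:
            raise ParameterError(f"generations must be an integer >= 1, got {self.generations!r}")
        if int(self.visible_horizon) != self.visible_horizon or self.visible_horizon < 1:
            raise ParameterError("visible_horizon must be an integer >= 1")
        if self.gfp_delay < 0:
            raise ParameterError("gfp_delay must be non-negative")
        if not (0.0 < self.large_bud_fraction < 1.0):
            raise ParameterError("large_bud_fraction must be in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SwitchParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ParameterError(f"unknown switch parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class SwitchEvent:
    """One loss-of-silencing event at a particular division.

    ``lineage`` is the binary address of the dividing cell ("" = founder; at
    each division the mother appends '0' and the daughter '1').
    """

    generation: int
    lineage: str
    affected: Literal["mother", "daughter", "both"]
    phase: Literal["pre_replication", "post_replication", "not_applicable"] = "not_applicable"
    time_in_cycle: float | None = None

    def __post_init__(self) -> None:
        if self.generation < 1:
            raise ParameterError("event generation must be >= 1")
        if self.affected == "both" and self.phase != "pre_replication":
            raise ParameterError("'both' progeny can only be switched by a pre-replication event")


@dataclass(frozen=True)
class ColonyOutcome:
    """Per-colony record of switch events and the resulting fluorescence class."""

    events: tuple[SwitchEvent, ...]
    founder_pre_switched: bool
    green_fraction: float
    colony_class: ColonyClass


@dataclass(frozen=True)
class SwitchPattern:
    """Cell-cycle-resolved switch pattern: bud stage at first detectable
    signal x which progeny remain green. ``number`` follows the live-imaging
    taxonomy (1-8); combinations outside it carry ``number=None``."""

    bud_stage: Literal["unbudded", "small_budded", "large_budded"]
    progeny: Literal["mother", "daughter", "both"]
    number: int | None


# ---------------------------------------------------------------------------
# explicit-tree backend


def _simulate_tree(params: SwitchParams, rng: np.random.Generator):
    """Simulate one explicit lineage tree.

    Returns ``(events, founder_pre, switched_by_generation)`` where the last
    item is a list of boolean arrays (generation g has 2**g cells; children of
    cell i are 2i [mother] and 2i+1 [daughter]).
    """
    founder_pre = bool(rng.random() < params.q_pre)
    cell_cycle = params.timing_model == "cell_cycle"
    events: list[SwitchEvent] = []
    s = np.array([founder_pre])
    switched_by_gen = [s]
    for g in range(1, params.generations + 1):
        n_parents = s.size
        child = np.repeat(s, 2)  # heritable, irreversible
        hit = (~s) & (rng.random(n_parents) < params.p_div)
        for i in np.flatnonzero(hit):
            lineage = format(i, f"0{g - 1}b") if g > 1 else ""
            if cell_cycle:
                t = float(rng.random())
                if t < params.f_pre_replication:
                    affected, phase = "both", "pre_replication"
                    child[2 * i] = child[2 * i + 1] = True
                else:
                    phase = "post_replication"
                    affected = "mother" if rng.random() < 0.5 else "daughter"
                    child[2 * i + (0 if affected == "mother" else 1)] = True
            else:
                t, phase = None, "not_applicable"
                affected = "mother" if rng.random() < 0.5 else "daughter"
                child[2 * i + (0 if affected == "mother" else 1)] = True
            events.append(
                SwitchEvent(generation=g, lineage=lineage, affected=affected, phase=phase, time_in_cycle=t)
            )
        s = child
        switched_by_gen.append(s)
    return events, founder_pre, switched_by_gen


def _classify(
    params: SwitchParams,
    founder_pre: bool,
    first_div_affected: str | None,
    green_at_horizon: float,
    any_event_in_horizon: bool,
) -> ColonyClass:
    """Event-based colony classification at the visible horizon.

    A half-sectored colony is defined by its generative signature — a switch
    in exactly one progeny of the first division — so the expected half-sector
    frequency equals p_div at every rate. Later events add small sectors to
    the red half but do not remove the half-green/half-red signature; a colony
    entirely green by the horizon is scored fully green instead.
    """
    if founder_pre or green_at_horizon >= 1.0:
        return "full_green"
    if first_div_affected in ("mother", "daughter"):
        return "half_sector"
    if any_event_in_horizon:
        return "partial_sector"
    return "red"


def classify_by_fraction(green_fraction: float, tolerance: float = 0.05) -> ColonyClass:
    """Fraction-based classifier for rendered or measured colony images.

    ``red`` below ``tolerance`` green, ``full_green`` above ``1 - tolerance``,
    ``half_sector`` within ``0.5 +/- tolerance``, otherwise ``partial_sector``.
    """
    if not (0 <= green_fraction <= 1):
        raise ParameterError("green_fraction must be in [0, 1]")
    if green_fraction <= tolerance:
        return "red"
    if green_fraction >= 1 - tolerance:
        return "full_green"
    if abs(green_fraction - 0.5) <= tolerance:
        return "half_sector"
    return "partial_sector"


def simulate_colony(
    params: SwitchParams,
    seed: int | np.random.Generator,
    return_tree: bool = False,
) -> ColonyOutcome | tuple[ColonyOutcome, list[np.ndarray]]:
    """Simulate one colony with an explicit lineage tree.

    Cost is O(2**generations); use :func:`simulate_population` for large runs.
    """
    rng = ensure_rng(seed)
    events, founder_pre, switched = _simulate_tree(params, rng)
    h = min(params.visible_horizon, params.generations)
    green_fraction = float(switched[-1].mean())
    first = next((e for e in events if e.generation == 1), None)
    outcome = ColonyOutcome(
        events=tuple(events),
        founder_pre_switched=founder_pre,
        green_fraction=green_fraction,
        colony_class=_classify(
            params,
            founder_pre,
            None if first is None else first.affected,
            float(switched[h].mean()),
            any(e.generation <= h for e in events),
        ),
    )
    if return_tree:
        return outcome, switched
    return outcome


# ---------------------------------------------------------------------------
# thinned backend


def _population_thinned(params: SwitchParams, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Vectorized generation-wise binomial thinning over unswitched-cell counts.

    Only the number of unswitched cells per generation is tracked; switched
    lineages double freely, so with ``u_G`` unswitched cells at the final
    generation the green fraction is ``1 - u_G / 2**G``.
    """
    G, h, p = params.generations, min(params.visible_horizon, params.generations), params.p_div
    cc = params.timing_model == "cell_cycle"
    founder_pre = rng.random(n) < params.q_pre
    u = (~founder_pre).astype(np.int64)

    n_events = np.zeros(n, dtype=np.int64)
    first_gen = np.zeros(n, dtype=np.int64)  # 0 = no event
    events_in_h = np.zeros(n, dtype=bool)
    first_div_single = np.zeros(n, dtype=bool)
    u_h = None
    for g in range(1, G + 1):
        k = rng.binomial(u, p)
        b = rng.binomial(k, params.f_pre_replication) if cc else np.zeros_like(k)
        if g == 1:
            first_div_single = (k - b) == 1
        u = 2 * u - k - b
        n_events += k
        np.copyto(first_gen, g, where=(first_gen == 0) & (k > 0))
        if g <= h:
            events_in_h |= k > 0
        if g == h:
            u_h = u.copy()
    assert u_h is not None
    green_h = 1.0 - u_h / float(2**h)
    green_final = 1.0 - u / float(2**G)

    classes = np.full(n, "red", dtype=object)
    full = founder_pre | (u_h == 0)
    half = (~full) & first_div_single
    partial = (~full) & (~half) & events_in_h
    classes[partial] = "partial_sector"
    classes[half] = "half_sector"
    classes[full] = "full_green"
    return {
        "colony_class": classes,
        "green_fraction": green_final,
        "n_events": n_events,
        "first_event_generation": first_gen,
        "founder_pre_switched": founder_pre,
    }


def simulate_colony_table(
    params: SwitchParams,
    n_colonies: int,
    seed: int | np.random.Generator,
    method: str = "thinned",
) -> pd.DataFrame:
    """Simulate a population and return one row per colony.

    Columns: ``colony_id, class, green_fraction, n_events, first_event_generation``.
    """
    if n_colonies < 1:
        raise ParameterError("n_colonies must be >= 1")
    rng = ensure_rng(seed)
    if method == "thinned":
        res = _population_thinned(params, n_colonies, rng)
        return pd.DataFrame(
            {
                "colony_id": np.arange(n_colonies),
                "class": res["colony_class"],
                "green_fraction": res["green_fraction"],
                "n_events": res["n_events"],
                "first_event_generation": res["first_event_generation"],
            }
        )
    if method == "tree":
        rows = []
        for i in range(n_colonies):
            out = simulate_colony(params, rng)
            rows.append(
                (
                    i,
                    out.colony_class,
                    out.green_fraction,
                    len(out.events),
                    min((e.generation for e in out.events), default=0),
                )
            )
        return pd.DataFrame(
            rows, columns=["colony_id", "class", "green_fraction", "n_events", "first_event_generation"]
        )
    raise ParameterError(f"method must be 'thinned' or 'tree', got {method!r}")


def simulate_population(
    params: SwitchParams,
    n_colonies: int,
    seed: int | np.random.Generator,
    method: str = "thinned",
    replicate_id: str = "",
):
    """Simulate ``n_colonies`` colonies and tally fluorescence classes.

    Returns a :class:`episwitch.sector_stats.SectorCounts` carrying the half-
    sectored / fully-green / partial / red tallies with ``total = n_colonies``.
    """
    from .sector_stats import SectorCounts  # estimator-side container

    table = simulate_colony_table(params, n_colonies, seed, method=method)
    counts = table["class"].value_counts()
    return SectorCounts(
        total_colonies=n_colonies,
        half_sectored=int(counts.get("half_sector", 0)),
        fully_green=int(counts.get("full_green", 0)),
        replicate_id=replicate_id,
        partial_sectored=int(counts.get("partial_sector", 0)),
        red=int(counts.get("red", 0)),
    )


# ---------------------------------------------------------------------------
# pattern classifier


def classify_switch_pattern(event: SwitchEvent | None, params: SwitchParams) -> SwitchPattern | None:
    """Classify a cell-cycle-mode event into the live-imaging pattern taxonomy.

    The reporter becomes detectable ``gfp_delay`` cycle fractions after the
    event. If detection falls past cytokinesis the cell pair is scored
    unbudded; otherwise the bud stage follows the cycle position at detection
    (bud emergence at the start of replication, large bud from
    ``large_bud_fraction`` onward). Returns ``None`` for ``event=None``
    (no switch: the cell simply remains red).
    """
    if event is None:
        return None
    if event.phase == "not_applicable" or event.time_in_cycle is None:
        raise UnsupportedTimingModelError(
            "pattern classification requires an event from a cell_cycle-mode simulation"
        )
    t_detect = event.time_in_cycle + params.gfp_delay
    if t_detect >= 1.0:
        stage = "unbudded"
    elif t_detect < params.f_pre_replication:
        stage = "unbudded"
    elif t_detect < params.large_bud_fraction:
        stage = "small_budded"
    else:
        stage = "large_budded"
    return SwitchPattern(bud_stage=stage, progeny=event.affected, number=PATTERN_NUMBERS[(stage, event.affected)])


def iter_events(outcomes: Iterable[ColonyOutcome]):
    """Yield every switch event across a collection of colony outcomes."""
    for out in outcomes:
        yield from out.events
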