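"""Walk dynamics: steps, lateral selection, merges, stopping, undo, replay."""

import itertools
import json
import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fiberwalk as fw
from fiberwalk.errors import (
    ContractForbiddenError,
    IllegalStateError,
    InvalidConfigurationError,
    InvalidLabelError,
    UnresolvableWalkError,
)

SQ2 = math.sqrt(2.0)
SQ5 = math.sqrt(5.0)


# ----------------------------------------------------------------------
# label combination
# ----------------------------------------------------------------------
def test_combine_label_entries_exhaustive():
    """All nine input pairs agree with the sign-of-sum oracle and stay in range."""
    for a, b in itertools.product((-1, 0, 1), repeat=2):
        got = fw.combine_label_entries(a, b)
        assert got == int(np.sign(a + b))
        assert got in (-1, 0, 1)


def test_combine_label_entries_rejects_out_of_range():
    with pytest.raises(InvalidLabelError):
        fw.combine_label_entries(2, 0)


# ----------------------------------------------------------------------
# stepping
# ----------------------------------------------------------------------
def test_first_step_uniform_monte_carlo():
    """Each of the 4 first steps has frequency 1/4 within 3 sigma (n=40,000)."""
    n = 40_000
    counts = Counter()
    for i in range(n):
        cfg = fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=1,
                            seed=fw.derive_walk_seed(17, i))
        state = fw.WalkState(cfg)
        counts[state.step().to] += 1
    sigma = math.sqrt(n * 0.25 * 0.75)
    assert set(counts) == {(1, 0), (-1, 0), (0, 1), (0, -1)}
    for c in counts.values():
        assert abs(c - n / 4) < 3 * sigma


def test_step_on_stopped_state_raises():
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=300, seed=11))
    assert state.stopped
    with pytest.raises(IllegalStateError):
        state.step()


def test_growing_saw_emits_no_merges():
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="growing_saw", max_steps=50, seed=4))
    assert all(not ev.merges for ev in state.event_log)
    assert all(length == 1.0 for length in state.fiber.step_lengths)


def test_seeded_runs_are_bit_reproducible():
    cfg = fw.WalkConfig(dimension=3, mode="fiber_walk", max_steps=40, seed=123)
    assert fw.simulate_walk(cfg).to_json() == fw.simulate_walk(cfg).to_json()


# ----------------------------------------------------------------------
# lateral selection (the contraction rule)
# ----------------------------------------------------------------------
def _gsaw_state(dim=2):
    return fw.WalkState(fw.WalkConfig(dimension=dim, mode="growing_saw",
                                      max_steps=20, seed=0))


def test_lateral_selection_fresh_2d():
    state = _gsaw_state()
    state.step(forced_choice=(1, 0))
    labels = {lab for _e, _n, lab in state.select_lateral_edges()}
    assert labels == {(0, 1), (0, -1)}


def test_lateral_selection_excludes_self_avoiding():
    """Rule 2: a side neighbor already joined to the fiber is not merged."""
    state = _gsaw_state()
    for target in [(0, 1), (1, 1), (1, 0)]:
        state.step(forced_choice=target)
    # tip (1,0) reached with growth label (0,-1); side edge to (0,0) is
    # self-avoiding (fiber vertex), so only the (1,0)-labelled edge remains
    sel = state.select_lateral_edges()
    assert [(n, lab) for _e, n, lab in sel] == [((2, 0), (1, 0))]


def test_lateral_selection_fresh_3d():
    state = _gsaw_state(dim=3)
    state.step(forced_choice=(0, 0, 1))
    labels = {lab for _e, _n, lab in state.select_lateral_edges()}
    assert labels == {(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0)}


def test_contract_free_straight_step_2d():
    state = fw.WalkState(fw.WalkConfig(dimension=2, mode="fiber_walk",
                                       max_steps=5, seed=0))
    ev = state.step(forced_choice=(1, 0))
    assert len(ev.merges) == 2
    assert {m.removed for m in ev.merges} == {(1, 1), (1, -1)}


def test_contract_free_step_4d():
    state = fw.WalkState(fw.WalkConfig(dimension=4, mode="fiber_walk",
                                       max_steps=5, seed=0))
    ev = state.step(forced_choice=(1, 0, 0, 0))
    assert len(ev.merges) == 6  # 2(d-1)


def test_contract_blocked_corridor_yields_no_merges():
    """With both lateral edges self-avoiding nothing is merged (rule 2)."""
    state = _gsaw_state()
    state.step(forced_choice=(1, 0))
    lat = state.lattice
    for nbr in [(1, 1), (1, -1)]:
        lat.set_self_avoiding(lat.edge_between((1, 0), nbr), True, None)
    assert state.select_lateral_edges() == []
    assert state.contract() == []


# ----------------------------------------------------------------------
# merges
# ----------------------------------------------------------------------
def test_merge_inherits_expected_geometry():
    """Merging the upper side vertex creates steps of length sqrt(2) and 2."""
    state = _gsaw_state()
    state.step(forced_choice=(1, 0))
    tip = (1, 0)
    via = state.lattice.edge_between(tip, (1, 1))
    ev = state.merge_vertices(tip, (1, 1), via)
    inherited = {t: (round(ln, 6), lab, cc) for t, lab, ln, cc, _sa in ev.inherited}
    assert inherited == {
        (0, 1): (round(SQ2, 6), (-1, 1), 1),
        (2, 1): (round(SQ2, 6), (1, 1), 1),
        (1, 2): (2.0, (0, 1), 1),
    }


def test_merge_both_sides_gives_seven_targets():
    """After contracting both laterals the tip sees 7 follow-up choices."""
    state = fw.WalkState(fw.WalkConfig(dimension=2, mode="fiber_walk",
                                       max_steps=5, seed=0))
    state.step(forced_choice=(1, 0))
    feasible = state.feasible_edges()
    lengths = sorted(round(e.length, 6) for e, _t in feasible)
    assert lengths == [1.0] + [round(SQ2, 6)] * 4 + [2.0] * 2
    back = state.lattice.edge_between((1, 0), (0, 0))
    assert back.self_avoiding and back.in_fiber


def test_merge_across_self_avoiding_edge_forbidden():
    state = _gsaw_state()
    state.step(forced_choice=(1, 0))
    edge = state.lattice.edge_between((1, 0), (0, 0))  # fiber edge, self-avoiding
    with pytest.raises(ContractForbiddenError):
        state.merge_vertices((1, 0), (0, 0), edge)


def test_inherited_edge_to_fiber_vertex_is_self_avoiding():
    """Double merges create self-avoiding edges of length sqrt(5) or 3."""
    found = set()
    for seed in range(60):
        state = fw.simulate_walk(fw.WalkConfig(dimension=2, mode="fiber_walk",
                                               max_steps=60, seed=seed))
        for e in state.lattice.edges():
            if e.self_avoiding and not e.in_fiber:
                found.add(round(e.length, 6))
    assert round(SQ5, 6) in found
    assert 3.0 in found


# ----------------------------------------------------------------------
# invariants over random walks
# ----------------------------------------------------------------------
@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**20), dim=st.sampled_from([2, 3, 4]))
def test_walk_invariants(seed, dim):
    """Path simplicity, 2D length classes, merge caps, monotone merge counts."""
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=dim, mode="fiber_walk", max_steps=40, seed=seed))
    seq = state.fiber.vertex_sequence
    assert len(seq) == len(set(seq))
    cap = 2 * (dim - 1)
    assert all(len(ev.merges) <= cap for ev in state.event_log)
    cum = np.cumsum([len(ev.merges) for ev in state.event_log])
    assert (np.diff(cum) >= 0).all()
    if dim == 2:
        classes = {round(x, 6) for x in state.fiber.step_lengths}
        assert classes <= {1.0, round(SQ2, 6), 2.0}
        sa = {round(e.length, 6) for e in state.lattice.edges()
              if e.self_avoiding and not e.in_fiber}
        assert sa <= {1.0, round(SQ2, 6), 2.0, round(SQ5, 6), 3.0}


def test_stopping_configuration_definition():
    """Stopped exactly when every tip-incident edge is self-avoiding."""
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=300, seed=11))
    assert state.stopped
    tip_edges = state.lattice.incident_edges(state.fiber.tip)
    assert all(e.self_avoiding for e, _n, _lab in tip_edges)


# ----------------------------------------------------------------------
# undo / backtracking
# ----------------------------------------------------------------------
def test_undo_restores_serialized_state_bit_exactly():
    cfg = fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=30, seed=21)
    state = fw.WalkState(cfg)
    snapshots = [state.to_json()]
    while state.n_steps < 12 and state.feasible_edges():
        state.step()
        snapshots.append(state.to_json())
    while state.n_steps:
        snapshots.pop()
        state.undo_last_step()
        assert state.to_json() == snapshots[-1]


def test_undo_on_fresh_state_raises():
    state = fw.WalkState(fw.WalkConfig(dimension=2, seed=0))
    with pytest.raises(IllegalStateError):
        state.undo_last_step()


def test_backtrack_reaches_requested_length():
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=60, seed=8,
                      restart_policy="backtrack"))
    assert state.n_steps == 60
    seq = state.fiber.vertex_sequence
    assert len(seq) == len(set(seq))


def test_backtrack_budget_exhaustion_raises():
    with pytest.raises(UnresolvableWalkError):
        # seed 11 traps naturally well before 300 steps; a zero budget
        # turns the first trap into an unresolvable walk
        fw.simulate_walk(fw.WalkConfig(dimension=2, mode="fiber_walk",
                                       max_steps=300, seed=11,
                                       restart_policy="backtrack",
                                       max_backtracks=0))


def test_rejection_policy_reaches_length():
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=15, seed=5,
                      restart_policy="rejection"))
    assert state.n_steps == 15


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------
def test_json_round_trip_identical_event_log():
    state = fw.simulate_walk(
        fw.WalkConfig(dimension=2, mode="fiber_walk", max_steps=25, seed=6))
    clone = fw.WalkState.from_json(state.to_json())
    assert clone.to_dict() == state.to_dict()
    assert json.loads(state.to_json())["schema"] == 1


def test_invalid_configs_rejected():
    with pytest.raises(InvalidConfigurationError):
        fw.WalkConfig(dimension=1)
    with pytest.raises(InvalidConfigurationError):
        fw.WalkConfig(mode="levy_flight")
    with pytest.raises(InvalidConfigurationError):
        fw.WalkConfig(max_steps=0)
    with pytest.raises(InvalidConfigurationError):
        fw.WalkConfig(restart_policy="teleport")


# ----------------------------------------------------------------------
# agreement with exhaustive enumeration (growing SAW)
# ----------------------------------------------------------------------
def _enumerate_gsaw(length):
    """Independent oracle: exact configuration probabilities of the growing
    SAW, from a plain set-based recursion (uniform choice over unvisited
    axis neighbors)."""
    probs = {}

    def rec(path, visited, p):
        if len(path) - 1 == length:
            probs[tuple(path)] = p
            return
        x, y = path[-1]
        free = [q for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1))
                if q not in visited]
        if not free:  # trapped early (cannot happen below length 7)
            return
        for q in free:
            rec(path + [q], visited | {q}, p / len(free))

    rec([(0, 0)], {(0, 0)}, 1.0)
    return probs


def test_gsaw_matches_exhaustive_enumeration_chi_square():
    """MC frequencies of all length-6 configurations agree with exact
    enumeration (chi-square, alpha = 0.01)."""
    from scipy import stats

    length, n = 6, 20_000
    exact = _enumerate_gsaw(length)
    assert abs(sum(exact.values()) - 1.0) < 1e-12
    counts = Counter()
    for i in range(n):
        state = fw.simulate_walk(
            fw.WalkConfig(dimension=2, mode="growing_saw", max_steps=length,
                          seed=fw.derive_walk_seed(99, i)))
        counts[tuple(state.fiber.vertex_sequence)] += 1
    assert set(counts) <= set(exact)
    observed = np.array([counts.get(k, 0) for k in exact], dtype=float)
    expected = np.array([n * p for p in exact.values()])
    chi2, p = stats.chisquare(observed, expected)
    assert p > 0.01


def test_minimum_stopping_length_matches_enumeration():
    """The shortest trapped configuration has 7 steps, both by independent
    enumeration and by exhaustive traversal of the simulator's choices."""

    # oracle: recursively explore all SAW paths, find earliest trap
    best = [math.inf]

    def rec(path, visited):
        if len(path) - 1 >= min(best[0], 8):
            return
        x, y = path[-1]
        free = [q for q in ((x + 1, y), (x - 1, y), (x, y + 1), (x, y - 1))
                if q not in visited]
        if not free:
            best[0] = min(best[0], len(path) - 1)
            return
        for q in free:
            rec(path + [q], visited | {q})

    rec([(0, 0)], {(0, 0)})
    assert best[0] == 7

    # simulator: exhaustive depth-first traversal via step/undo
    state = fw.WalkState(fw.WalkConfig(dimension=2, mode="growing_saw",
                                       max_steps=8, seed=0))
    sim_best = [math.inf]

    def walk():
        if state.n_steps >= min(sim_best[0], 8):
            return
        feasible = state.feasible_edges()
        if not feasible:
            sim_best[0] = min(sim_best[0], state.n_steps)
            return
        for _e, target in list(feasible):
            state.step(forced_choice=target)
            walk()
            state.undo_last_step()

    walk()
    assert sim_best[0] == 7


def test_derive_walk_seed_distinct_and_deterministic():
    seeds = {fw.derive_walk_seed(1, i) for i in range(100)}
    assert len(seeds) == 100
    assert fw.derive_walk_seed(1, 5) == fw.derive_walk_seed(1, 5)
    assert fw.derive_walk_seed(1, 5, 1) != fw.derive_walk_seed(1, 5)
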