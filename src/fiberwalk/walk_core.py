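"""Growing self-avoiding walks and fiber walks (elongation + contraction).

A *growing SAW* (kinetic growth walk) extends step by step, choosing
uniformly at random among the edges at its tip that do not lead back to a
visited vertex.  A *fiber walk* is a growing SAW in which every elongation
step additionally triggers a lateral contraction of the lattice around the
new tip: the unvisited neighbors "incident from the side" of the growth
direction are merged into the tip, modeling the space consumed by lateral
expansion of the growing fiber.

A merge absorbs a lateral vertex ``w`` into the tip ``t``: ``t`` inherits
all of ``w``'s edges (with recalculated labels, recomputed Euclidean
lengths, and contraction counts incremented by one) and the merge edge
itself is discarded.  Inherited edges that end at a fiber vertex become
*self-avoiding*: directions permanently blocked to further growth.  The walk
stops when every edge at the tip is self-avoiding.

Every mutation of the state is journaled, so a step (including its merges)
can be undone bit-exactly; this supports the depth-first backtracking used
to push trapped walks to a prescribed length for scaling ensembles.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import (
    ContractForbiddenError,
    IllegalStateError,
    InvalidConfigurationError,
    InvalidInputError,
    InvalidLabelError,
    UnresolvableWalkError,
)
from .lattice import Edge, Label, Lattice, Vid, euclidean

GROWING_SAW = "growing_saw"
FIBER_WALK = "fiber_walk"
_MODE_ALIASES = {
    "gsaw": GROWING_SAW, "growing_saw": GROWING_SAW, "saw": GROWING_SAW,
    "fiber": FIBER_WALK, "fiber_walk": FIBER_WALK,
}

RESTART_NONE = "none"
RESTART_BACKTRACK = "backtrack"
RESTART_REJECTION = "rejection"


def combine_label_entries(a: int, b: int) -> int:
    """Combine two direction-label entries: the sign of their sum.

    This is the entrywise recalculation applied when a merge turns the label
    of an inherited edge into the label of the newly created edge; clamping
    to the sign keeps every entry in {-1, 0, 1} (opposite directions cancel,
    zero is the identity).
    """
    if a not in (-1, 0, 1) or b not in (-1, 0, 1):
        raise InvalidLabelError(f"label entries must be in {{-1,0,1}}, got {a}, {b}")
    s = a + b
    return (s > 0) - (s < 0)


def combine_labels(merge_label: Label, inherited_label: Label) -> Label:
    """Entrywise combination of a merge-edge label with an inherited label."""
    return tuple(combine_label_entries(a, b)
                 for a, b in zip(merge_label, inherited_label, strict=True))


@dataclass(frozen=True)
class WalkConfig:
    """Configuration of a single walk.

    Parameters
    ----------
    dimension : lattice dimension d >= 2.
    mode : ``"growing_saw"`` or ``"fiber_walk"`` (aliases gsaw / fiber).
    max_steps : maximum walk length in steps.
    seed : seed of the per-walk random number generator.
    restart_policy : ``"none"`` (stop naturally), ``"backtrack"`` (undo
        trapped steps depth-first until ``max_steps`` is reached) or
        ``"rejection"`` (discard trapped walks and retry with fresh seeds).
    max_backtracks : budget of undo events before the walk is declared
        unresolvable.
    max_rejections : retry budget for the rejection policy.
    """

    dimension: int = 2
    mode: str = FIBER_WALK
    max_steps: int = 300
    seed: int = 0
    restart_policy: str = RESTART_NONE
    max_backtracks: int = 15_000
    max_rejections: int = 100_000

    def __post_init__(self):
        if self.dimension < 2:
            raise InvalidConfigurationError("dimension must be >= 2")
        if self.max_steps < 1:
            raise InvalidConfigurationError("max_steps must be >= 1")
        mode = _MODE_ALIASES.get(self.mode)
        if mode is None:
            raise InvalidConfigurationError(f"unknown mode {self.mode!r}")
        object.__setattr__(self, "mode", mode)
        if self.restart_policy not in (RESTART_NONE, RESTART_BACKTRACK,
                                       RESTART_REJECTION):
            raise InvalidConfigurationError(
                f"unknown restart policy {self.restart_policy!r}")


@dataclass
class MergeEvent:
    """One vertex merge performed during a contraction."""

    step_index: int
    kept: Vid
    removed: Vid
    via_label: Label
    #: (target, label(kept->target), length, contraction_count, self_avoiding)
    inherited: list[tuple]


@dataclass
class StepEvent:
    """One elongation step, with the merges it triggered (fiber mode)."""

    index: int          # 1-based step number
    frm: Vid
    to: Vid
    label: Label        # outgoing label of the traversed edge
    length: float
    n_feasible: int     # size of the feasible set the choice was drawn from
    merges: list[MergeEvent] = field(default_factory=list)


class Fiber:
    """The directed simple path built by the walk."""

    __slots__ = ("vertex_sequence", "edge_sequence", "step_lengths", "_vset")

    def __init__(self, origin: Vid):
        self.vertex_sequence: list[Vid] = [origin]
        self.edge_sequence: list[Edge] = []
        self.step_lengths: list[float] = []
        self._vset: set[Vid] = {origin}

    def __len__(self) -> int:
        return len(self.edge_sequence)

    @property
    def tip(self) -> Vid:
        return self.vertex_sequence[-1]

    @property
    def origin(self) -> Vid:
        return self.vertex_sequence[0]

    def __contains__(self, vid: Vid) -> bool:
        return vid in self._vset

    def push(self, vid: Vid, edge: Edge) -> None:
        self.vertex_sequence.append(vid)
        self._vset.add(vid)
        self.edge_sequence.append(edge)
        self.step_lengths.append(edge.length)

    def pop(self) -> Vid:
        vid = self.vertex_sequence.pop()
        self._vset.discard(vid)
        self.edge_sequence.pop()
        self.step_lengths.pop()
        return vid


class WalkState:
    """Lattice + fiber + event log of one walk, with undo support."""

    def __init__(self, config: WalkConfig, lattice: Optional[Lattice] = None):
        self.config = config
        self.lattice = lattice if lattice is not None else Lattice(config.dimension)
        if self.lattice.dimension != config.dimension:
            raise InvalidConfigurationError("lattice/config dimension mismatch")
        self.fiber = Fiber(self.lattice.origin)
        self.mode = config.mode
        self.rng = random.Random(config.seed)
        self.last_incoming_label: Optional[Label] = None
        self.event_log: list[StepEvent] = []
        self._journal: list = []
        # per step: (journal length at step start, previous incoming label)
        self._undo_stack: list[tuple[int, Optional[Label]]] = []
        self.lattice.materialize(self.lattice.origin, None)

    # ------------------------------------------------------------------
    @property
    def n_steps(self) -> int:
        return len(self.fiber)

    @property
    def tip(self) -> Vid:
        return self.fiber.tip

    def feasible_edges(self) -> list[tuple[Edge, Vid]]:
        """Tip edges whose far endpoint is still open to the walk.

        These are exactly the non-self-avoiding edges at the tip (edges to
        visited vertices are marked self-avoiding as soon as they appear).
        An empty list means the walk is in a stopping configuration.
        """
        tip = self.fiber.tip
        return [(e, nbr)
                for e, nbr, _lab in self.lattice.incident_edges(tip, self._journal)
                if not e.self_avoiding]

    @property
    def stopped(self) -> bool:
        return not self.feasible_edges()

    # ------------------------------------------------------------------
    def step(self, forced_choice: Optional[Vid] = None) -> StepEvent:
        """Take one elongation step (and, in fiber mode, contract).

        The step is drawn uniformly at random from the feasible edges unless
        ``forced_choice`` names the target vertex (used for replay and
        backtracking, which manage their own randomness).
        """
        feasible = self.feasible_edges()
        if not feasible:
            raise IllegalStateError("cannot step: walk is stopped")
        if forced_choice is None:
            edge, target = feasible[self.rng.randrange(len(feasible))]
        else:
            for edge, target in feasible:
                if target == forced_choice:
                    break
            else:
                raise InvalidInputError(
                    f"forced choice {forced_choice} is not feasible")
        frm = self.fiber.tip
        prev_label = self.last_incoming_label
        self._undo_stack.append((len(self._journal), prev_label))
        journal = self._journal

        self.lattice.materialize(target, journal)
        self.lattice.set_in_fiber(edge, True, journal)
        self.fiber.push(target, edge)
        # the traversed edge and every edge from the new tip to a previously
        # visited vertex become self-avoiding
        for nbr, e in self.lattice._adj[target].items():
            if not e.self_avoiding and nbr in self.fiber:
                self.lattice.set_self_avoiding(e, True, journal)
        self.last_incoming_label = edge.label_from(frm)

        event = StepEvent(index=self.n_steps, frm=frm, to=target,
                          label=self.last_incoming_label, length=edge.length,
                          n_feasible=len(feasible))
        if self.mode == FIBER_WALK:
            event.merges = self.contract()
        self.event_log.append(event)
        return event

    # ------------------------------------------------------------------
    def select_lateral_edges(self) -> list[tuple[Edge, Vid, Label]]:
        """Tip edges incident from the side, eligible for contraction.

        An outgoing tip edge is selected iff it is not self-avoiding, its
        label has no entry opposite in sign to a nonzero entry of the last
        incoming label (no movement against the growth direction), and its
        label differs from the incoming label (not the elongation step
        itself).  Returned in label-lexicographic order.
        """
        g = self.last_incoming_label
        if g is None:
            raise IllegalStateError("no incoming label: walk has not stepped yet")
        out = []
        tip = self.fiber.tip
        for e, nbr, lab in self.lattice.incident_edges(tip, self._journal):
            if e.self_avoiding or lab == g:
                continue
            if any(gi * li < 0 for gi, li in zip(g, lab)):
                continue
            out.append((e, nbr, lab))
        return out

    def merge_vertices(self, keep: Vid, remove: Vid, via: Edge) -> MergeEvent:
        """Merge ``remove`` into ``keep`` across the non-self-avoiding ``via``.

        ``keep`` inherits every edge of ``remove`` except ``via``, which is
        discarded.  Inherited edges get entrywise-combined labels, Euclidean
        lengths recomputed from positions, and contraction counts one above
        their source edge.  If ``keep`` already has an edge to an inherited
        target, the edges collapse onto one (max contraction count,
        self-avoiding if either was).
        """
        if via.self_avoiding:
            raise ContractForbiddenError(
                f"edge {keep}-{remove} is self-avoiding (rule 2)")
        journal = self._journal
        lat = self.lattice
        m = via.label_from(keep)
        inherited: list[tuple] = []
        keep_nbrs = lat._adj[keep]
        # sorted incidence (which also materializes `remove`) keeps event
        # logs identical between lazily grown and pre-built lattices
        for e, nbr, _lab in lat.incident_edges(remove, journal):
            if nbr == keep:
                continue
            new_label = combine_labels(m, e.label_from(remove))
            new_cc = e.contraction_count + 1
            sa = e.self_avoiding or nbr in self.fiber
            lat.del_edge(remove, nbr, journal)
            existing = keep_nbrs.get(nbr)
            if existing is not None:
                if new_cc > existing.contraction_count:
                    lat.set_contraction_count(existing, new_cc, journal)
                if sa and not existing.self_avoiding:
                    lat.set_self_avoiding(existing, True, journal)
                rec = existing
            else:
                rec = lat.add_edge(keep, nbr, new_label, euclidean(keep, nbr),
                                   new_cc, sa, journal)
            inherited.append((nbr, rec.label_from(keep), rec.length,
                              rec.contraction_count, rec.self_avoiding))
        lat.del_edge(keep, remove, journal)
        lat.del_vertex(remove, journal)
        lat.record_merge(remove, keep, journal)
        return MergeEvent(step_index=self.n_steps, kept=keep, removed=remove,
                          via_label=m, inherited=inherited)

    def contract(self) -> list[MergeEvent]:
        """Contract the lattice around the tip after an elongation step.

        Applies one merge per selected lateral edge, in label-lexicographic
        order; yields between 0 and 2(d-1) merge events.
        """
        selected = self.select_lateral_edges()
        tip = self.fiber.tip
        return [self.merge_vertices(tip, nbr, e) for e, nbr, _lab in selected]

    # ------------------------------------------------------------------
    def undo_last_step(self) -> StepEvent:
        """Undo the last step, including its merges, bit-exactly."""
        if not self._undo_stack:
            raise IllegalStateError("nothing to undo")
        mark, prev_label = self._undo_stack.pop()
        journal = self._journal
        lat = self.lattice
        while len(journal) > mark:
            lat.undo_op(journal.pop())
        self.fiber.pop()
        self.last_incoming_label = prev_label
        return self.event_log.pop()

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        """JSON-serializable record of the walk (config + event history)."""
        return {
            "schema": 1,
            "config": {
                "dimension": self.config.dimension,
                "mode": self.config.mode,
                "max_steps": self.config.max_steps,
                "seed": self.config.seed,
                "restart_policy": self.config.restart_policy,
            },
            "origin": list(self.fiber.origin),
            "steps": [
                {
                    "to": list(ev.to),
                    "label": list(ev.label),
                    "length": ev.length,
                    "n_feasible": ev.n_feasible,
                    "merges": [
                        {
                            "removed": list(me.removed),
                            "via_label": list(me.via_label),
                            "inherited": [
                                {"target": list(t), "label": list(lab),
                                 "length": ln, "contraction_count": cc,
                                 "self_avoiding": sa}
                                for t, lab, ln, cc, sa in me.inherited
                            ],
                        }
                        for me in ev.merges
                    ],
                }
                for ev in self.event_log
            ],
            "stopped": self.stopped,
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "WalkState":
        """Rebuild a walk by replaying its recorded steps."""
        cfg = data["config"]
        config = WalkConfig(dimension=cfg["dimension"], mode=cfg["mode"],
                            max_steps=cfg["max_steps"], seed=cfg["seed"],
                            restart_policy=cfg.get("restart_policy", RESTART_NONE))
        state = cls(config)
        for step in data["steps"]:
            state.step(forced_choice=tuple(step["to"]))
        return state

    @classmethod
    def from_json(cls, text: str) -> "WalkState":
        return cls.from_dict(json.loads(text))


# ----------------------------------------------------------------------
# simulation drivers
# ----------------------------------------------------------------------
def _run_plain(config: WalkConfig, lattice: Optional[Lattice] = None) -> WalkState:
    state = WalkState(config, lattice)
    while state.n_steps < config.max_steps and state.feasible_edges():
        state.step()
    return state


def _run_backtrack(config: WalkConfig, lattice: Optional[Lattice] = None) -> WalkState:
    """Depth-first search for a walk of exactly ``max_steps`` steps.

    When the walk traps, the last step (with its merges) is undone via the
    journal, the undone choice is excluded at that depth, and a fresh
    uniform choice is drawn among the remaining feasible edges.  Exclusion
    sets are cleared whenever a depth is re-entered along a new prefix.
    """
    state = WalkState(config, lattice)
    excluded: dict[int, set[Vid]] = {}
    backtracks = 0
    while state.n_steps < config.max_steps:
        depth = state.n_steps
        excl = excluded.get(depth)
        feasible = state.feasible_edges()
        if excl:
            allowed = [t for _e, t in feasible if t not in excl]
        else:
            allowed = [t for _e, t in feasible]
        if allowed:
            target = allowed[state.rng.randrange(len(allowed))]
            state.step(forced_choice=target)
            excluded.pop(state.n_steps, None)  # stale exclusions of old subtree
        else:
            if depth == 0:
                raise UnresolvableWalkError(
                    "backtracking exhausted all alternatives at the origin")
            backtracks += 1
            if backtracks > config.max_backtracks:
                raise UnresolvableWalkError(
                    f"backtrack budget ({config.max_backtracks}) exhausted")
            undone = state.undo_last_step()
            excluded.setdefault(state.n_steps, set()).add(undone.to)
    return state


def simulate_walk(config: WalkConfig,
                  lattice: Optional[Lattice] = None) -> WalkState:
    """Run one walk to its natural stop, to ``max_steps``, or per restart policy."""
    if config.restart_policy == RESTART_NONE:
        return _run_plain(config, lattice)
    if config.restart_policy == RESTART_BACKTRACK:
        return _run_backtrack(config, lattice)
    # rejection: discard trapped walks, retry with derived fresh seeds
    seeder = random.Random(config.seed)
    for _attempt in range(config.max_rejections):
        sub = WalkConfig(dimension=config.dimension, mode=config.mode,
                         max_steps=config.max_steps,
                         seed=seeder.getrandbits(48),
                         restart_policy=RESTART_NONE)
        state = _run_plain(sub)
        if state.n_steps == config.max_steps:
            return state
    raise UnresolvableWalkError(
        f"rejection budget ({config.max_rejections}) exhausted")


def derive_walk_seed(ensemble_seed: int, index: int, attempt: int = 0) -> int:
    """Deterministic per-walk seed from (ensemble seed, walk index, attempt)."""
    ss = np.random.SeedSequence((ensemble_seed, index, attempt))
    a, b = ss.generate_state(2)
    return (int(a) << 32) | int(b)
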