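"""Parsimony reconstruction of PAS evolution on a species tree.

Two characters are traced across primates: presence of the repeat element
that hosts the polyadenylation signals, and the number of overlapping PAS
hexamers it carries.

- Element presence follows *Dollo parsimony*: a retrotransposon insertion at
  one orthologous position is a unique event, so a single gain is allowed
  and absence below it is explained by losses.  Tips may be scored
  ``present``, ``absent``, or ``lost`` — the last meaning "absent with
  independent evidence of secondary deletion" (e.g. deletion breakpoints),
  which forces the gain above that lineage too.
- PAS count follows *Sankoff parsimony* with a linear cost |i - j| (each
  substitution creates or destroys one hexamer); a unit-cost matrix is
  available by flag.  Tips where the element is absent carry NA and
  contribute zero cost in any state.

Events are reported per branch; a branch carries a *certain* event only
when parent and child states differ in every minimum-cost assignment,
otherwise the change is listed as possible.  Node ages (Mya) date events to
the [child age, parent age] interval of their branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

NodeKey = tuple[str, ...]  # sorted tip labels of the clade below the node


@dataclass
class SpeciesTree:
    """A rooted species tree with optional node ages in Mya."""

    tree: dendropy.Tree
    ultrametric: bool = False

    def __post_init__(self) -> None:
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate tip labels: {', '.join(dupes)}")
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.clade = (node.taxon.label,)
            else:
                tips: list[str] = []
                for ch in node.child_nodes():
                    tips.extend(ch.clade)
                node.clade = tuple(sorted(tips))
        self._ages: dict[NodeKey, float] | None = None
        if self.ultrametric:
            self._compute_ages()

    def _compute_ages(self) -> None:
        depth = {self.tree.seed_node: 0.0}
        for node in self.tree.preorder_node_iter():
            if node.parent_node is not None:
                depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        height = max(depth.values())
        self._ages = {n.clade: height - d for n, d in depth.items()}

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def age(self, key: NodeKey) -> float | None:
        if self._ages is None:
            return None
        return self._ages.get(key)

    def mrca_key(self, labels) -> NodeKey:
        wanted = set(labels)
        for node in self.tree.postorder_node_iter():
            if wanted <= set(node.clade):
                return node.clade
        raise ValueError("labels not found in tree")


def parse_newick(text: str, ultrametric: bool = False) -> SpeciesTree:
    """Parse a rooted Newick tree; with ``ultrametric=True`` branch lengths
    are read as durations and node ages (Mya) are derived from tree height."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise ValueError(f"malformed Newick: {exc}") from exc
    tree.is_rooted = True
    return SpeciesTree(tree=tree, ultrametric=ultrametric)


@dataclass(frozen=True)
class BranchEvent:
    """A state change on the branch *above* the named clade."""

    child: NodeKey
    kind: str  # "gain", "loss", "insertion", "deletion"
    delta: int | None = None
    certain: bool = True


@dataclass
class EventReconstruction:
    """Ancestral states and per-branch events for one character."""

    node_states: dict[NodeKey, frozenset]
    events: list[BranchEvent]
    possible_events: list[BranchEvent] = field(default_factory=list)
    total_cost: float = 0.0


@dataclass(frozen=True)
class EventDate:
    """Age interval of an event's branch: [child age, parent age] in Mya."""

    branch: NodeKey
    age_young: float | None
    age_old: float | None


def linear_cost(n_states: int) -> np.ndarray:
    i = np.arange(n_states)
    return np.abs(i[:, None] - i[None, :]).astype(float)


def unit_cost(n_states: int) -> np.ndarray:
    return 1.0 - np.eye(n_states)


def sankoff(
    stree: SpeciesTree,
    tip_states: dict[str, int | None],
    cost: np.ndarray | str = "linear",
) -> EventReconstruction:
    """Minimum-cost ancestral PAS counts by Sankoff dynamic programming.

    ``tip_states`` maps tip label -> integer state or ``None`` (NA: the tip
    is free to take any state at zero cost).  Bottom-up cost vectors give
    the optimal total cost; an outside pass then yields, for every node,
    the set of states attained in at least one globally optimal assignment,
    and for every branch the set of optimal (parent, child) state pairs —
    a branch carries a certain event iff no optimal pair leaves the state
    unchanged.
    """
    observed = [s for s in tip_states.values() if s is not None]
    if not observed:
        raise ValueError("all tips are NA; nothing to reconstruct")
    if min(observed) < 0:
        raise ValueError("states must be non-negative integers")
    n_states = max(observed) + 1
    if isinstance(cost, str):
        C = linear_cost(n_states) if cost == "linear" else unit_cost(n_states)
    else:
        C = np.asarray(cost, dtype=float)
        if C.shape[0] < n_states:
            raise ValueError(
                f"state {n_states - 1} outside the cost-matrix alphabet "
                f"(size {C.shape[0]})"
            )
        n_states = C.shape[0]

    tree = stree.tree
    INF = float("inf")

    up: dict = {}  # node -> cost vector over states (subtree below)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in tip_states:
                raise ValueError(f"tip {label!r} has no character state")
            s = tip_states[label]
            vec = np.zeros(n_states) if s is None else np.full(n_states, INF)
            if s is not None:
                if s >= n_states:
                    raise ValueError(f"state {s} outside cost-matrix alphabet")
                vec[s] = 0.0
        else:
            vec = np.zeros(n_states)
            for ch in node.child_nodes():
                # cost of child subtree given parent state a: min_b C[a,b]+up[ch][b]
                vec += (C + up[ch][None, :]).min(axis=1)
        up[node] = vec

    root = tree.seed_node
    total = float(up[root].min())

    # outside pass: down[node][a] = best cost of everything outside node's
    # subtree when node takes state a (cost of node's own branch included).
    down: dict = {root: np.zeros(n_states)}
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            contrib = (C + up[ch][None, :]).min(axis=1)
            rest = down[node] + up[node] - contrib  # parent total minus this child
            down[ch] = (rest[:, None] + C).min(axis=0)

    node_states: dict[NodeKey, frozenset] = {}
    for node in tree.preorder_node_iter():
        tot = up[node] + down[node]
        node_states[node.clade] = frozenset(np.flatnonzero(tot <= tot.min() + 1e-9))

    events: list[BranchEvent] = []
    possible: list[BranchEvent] = []
    for node in tree.preorder_node_iter():
        for ch in node.child_nodes():
            contrib = (C + up[ch][None, :]).min(axis=1)
            rest = down[node] + up[node] - contrib
            pair_cost = rest[:, None] + C + up[ch][None, :]
            opt = np.argwhere(pair_cost <= pair_cost.min() + 1e-9)
            deltas = {int(b - a) for a, b in opt}
            if 0 not in deltas:
                delta = deltas.pop() if len(deltas) == 1 else None
                kind = "gain" if (delta or 0) > 0 else "loss"
                if delta is None:
                    kind = "change"
                events.append(
                    BranchEvent(child=ch.clade, kind=kind, delta=delta, certain=True)
                )
            elif deltas != {0}:
                for d in sorted(deltas - {0}):
                    possible.append(
                        BranchEvent(
                            child=ch.clade,
                            kind="gain" if d > 0 else "loss",
                            delta=d,
                            certain=False,
                        )
                    )
    return EventReconstruction(
        node_states=node_states,
        events=events,
        possible_events=possible,
        total_cost=total,
    )


_PRESENCE_STATES = {"present", "absent", "lost"}


def dollo_presence(
    stree: SpeciesTree, tip_presence: dict[str, str | bool]
) -> EventReconstruction:
    """Dollo reconstruction of element presence: one insertion, many losses.

    The single insertion is placed on the branch above the most recent
    common ancestor of all tips scored ``present`` or ``lost`` (a ``lost``
    tip asserts secondary deletion, i.e. ancestral presence on its path).
    Losses are the stems of the maximal clades below the gain containing no
    ``present`` tip.
    """
    states: dict[str, str] = {}
    for tip, v in tip_presence.items():
        if isinstance(v, bool):
            v = "present" if v else "absent"
        if v not in _PRESENCE_STATES:
            raise ValueError(f"presence state must be one of {_PRESENCE_STATES}")
        states[tip] = v
    anchors = [t for t, v in states.items() if v in ("present", "lost")]
    if not any(states.get(t) == "present" for t in states):
        raise ValueError("at least one tip must be present")

    gain_key = stree.mrca_key(anchors)
    tree = stree.tree
    gain_node = next(
        n for n in tree.postorder_node_iter() if n.clade == gain_key
    )

    node_states: dict[NodeKey, frozenset] = {}
    losses: list[BranchEvent] = []

    def has_present(node) -> bool:
        return any(states.get(t) == "present" for t in node.clade)

    def walk(node, ancestral_present: bool) -> None:
        if not ancestral_present:
            node_states[node.clade] = frozenset({"absent"})
            for ch in node.child_nodes():
                walk(ch, False)
            return
        if not has_present(node):
            losses.append(BranchEvent(child=node.clade, kind="loss"))
            node_states[node.clade] = frozenset({"absent"})
            for ch in node.child_nodes():
                walk(ch, False)
            return
        node_states[node.clade] = frozenset({"present"})
        for ch in node.child_nodes():
            walk(ch, True)

    # everything outside the gain clade is ancestrally absent
    for node in tree.preorder_node_iter():
        if not (set(gain_key) <= set(node.clade)) and not (
            set(node.clade) <= set(gain_key)
        ):
            node_states.setdefault(node.clade, frozenset({"absent"}))
    for node in tree.preorder_node_iter():
        if set(gain_key) < set(node.clade):
            node_states[node.clade] = frozenset({"absent"})
    walk(gain_node, True)

    insertion = BranchEvent(child=gain_key, kind="insertion")
    return EventReconstruction(
        node_states=node_states,
        events=[insertion] + losses,
        total_cost=1.0 + len(losses),
    )


def date_event(event: BranchEvent, stree: SpeciesTree) -> EventDate:
    """Date an event to its branch's [child age, parent age] interval."""
    child_age = stree.age(event.child)
    parent_key = _parent_key(stree, event.child)
    parent_age = stree.age(parent_key) if parent_key is not None else None
    if child_age is None or parent_age is None:
        warnings.warn("tree has no node ages; event left undated")
        return EventDate(branch=event.child, age_young=None, age_old=None)
    lo, hi = sorted([child_age, parent_age])
    return EventDate(branch=event.child, age_young=lo, age_old=hi)


def _parent_key(stree: SpeciesTree, child_key: NodeKey) -> NodeKey | None:
    for node in stree.tree.preorder_node_iter():
        if node.clade == child_key:
            return node.parent_node.clade if node.parent_node else None
    raise ValueError(f"no node with clade {child_key}")
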