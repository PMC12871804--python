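"""Sankoff / Dollo parsimony, event detection and dating."""

import itertools

import numpy as np
import pytest

from ipastrace import pas_evolution as pe
from ipastrace import synthetic_data as sd
from tests.conftest import random_tree_newick


def brute_force_cost(stree, tip_states, C):
    """Minimum total cost over every ancestral state assignment (oracle)."""
    tree = stree.tree
    internals = [n for n in tree.preorder_node_iter() if not n.is_leaf()]
    n_states = C.shape[0]
    best = float("inf")
    for assign in itertools.product(range(n_states), repeat=len(internals)):
        state = {n: s for n, s in zip(internals, assign)}
        for leaf in tree.leaf_node_iter():
            state[leaf] = tip_states[leaf.taxon.label]
        cost = 0.0
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            a, b = state[node.parent_node], state[node]
            if b is None:
                continue  # NA tip: any state, zero cost -> skip its branch
            if a is None:
                a = b
            cost += C[a, b]
        best = min(best, cost)
    return best


class TestParseNewick:
    def test_basic_topology(self):
        t = pe.parse_newick("((A,B),C);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]

    def test_ultrametric_ages(self):
        t = pe.parse_newick("((A:1,B:1):4,C:5);", ultrametric=True)
        assert t.age(("A", "B", "C")) == pytest.approx(5.0)
        assert t.age(("A", "B")) == pytest.approx(1.0)
        assert t.age(("A",)) == pytest.approx(0.0)

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            pe.parse_newick("((A,A),B);")

    def test_malformed(self):
        with pytest.raises(ValueError, match="Newick"):
            pe.parse_newick("((A,B;")


class TestSankoff:
    def test_constant_character_no_events(self):
        t = pe.parse_newick("((A,B),(C,D));")
        rec = pe.sankoff(t, {x: 1 for x in "ABCD"})
        assert rec.total_cost == 0 and rec.events == []
        assert all(s == frozenset({1}) for s in rec.node_states.values())

    def test_four_taxon_single_change(self):
        t = pe.parse_newick("((A,B),(C,D));")
        rec = pe.sankoff(t, {"A": 0, "B": 0, "C": 1, "D": 1})
        assert rec.total_cost == 1
        # exactly one certain or a pair of possible changes on internal branches
        assert len(rec.events) + len(rec.possible_events) >= 1

    def test_na_tip_never_increases_cost(self):
        t = pe.parse_newick("((A,B),(C,D));")
        base = pe.sankoff(t, {"A": 0, "B": 0, "C": 2, "D": 2}).total_cost
        t2 = pe.parse_newick("(((A,B),(C,D)),E);")
        with_na = pe.sankoff(t2, {"A": 0, "B": 0, "C": 2, "D": 2, "E": None}).total_cost
        assert with_na <= base

    def test_state_outside_alphabet_rejected(self):
        t = pe.parse_newick("(A,B);")
        with pytest.raises(ValueError, match="alphabet"):
            pe.sankoff(t, {"A": 0, "B": 5}, cost=np.zeros((2, 2)))

    @pytest.mark.parametrize("cost_kind", ["linear", "unit"])
    def test_matches_exhaustive_enumeration(self, cost_kind):
        """Sankoff total cost equals brute-force enumeration on random trees
        with <= 8 tips and <= 4 states."""
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_tips = int(rng.integers(3, 9))
            n_states = int(rng.integers(2, 5))
            t = pe.parse_newick(random_tree_newick(rng, n_tips))
            tip_states = {
                f"T{i}": (None if rng.random() < 0.15 else int(rng.integers(n_states)))
                for i in range(n_tips)
            }
            if all(v is None for v in tip_states.values()):
                tip_states["T0"] = 0
            C = (
                pe.linear_cost(n_states)
                if cost_kind == "linear"
                else pe.unit_cost(n_states)
            )
            rec = pe.sankoff(t, tip_states, cost=C)
            assert rec.total_cost == pytest.approx(
                brute_force_cost(t, tip_states, C)
            )

    def test_event_deltas_sum_consistent(self):
        """On the primate fixture the certain event deltas are +2, +1, -1."""
        stree = sd.load_primate_tree()
        chars = sd.load_primate_characters()
        rec = pe.sankoff(stree, {t: c for t, (_, c) in chars.items()})
        assert sorted(e.delta for e in rec.events) == [-1, 1, 2]
        assert rec.total_cost == 4

    def test_simulated_history_recovered(self, primate_tree):
        """Planted low-rate count histories with <= 3 events are recovered
        on the same branches in >= 95% of replicates."""
        clade_gib = primate_tree.mrca_key(
            ["Symphalangus_syndactylus", "Hoolock_hoolock"]
        )
        clade_homo = primate_tree.mrca_key(["Homo_sapiens", "Homo_neanderthalensis"])
        hits = 0
        n = 40
        for s in range(n):
            sim = sd.gen_tree_characters(
                s,
                primate_tree,
                insertion_clade=primate_tree.mrca_key(primate_tree.tip_labels),
                planted_count_events={clade_homo: 2, clade_gib: 1},
            )
            rec = pe.sankoff(
                primate_tree, {t: c for t, (_, c) in sim.characters.items()}
            )
            found = {(e.child, e.delta) for e in rec.events}
            if {(clade_homo, 2), (clade_gib, 1)} <= found:
                hits += 1
        assert hits / n >= 0.95


class TestDollo:
    def test_all_present_insertion_at_root(self):
        t = pe.parse_newick("((A,B),C);")
        rec = pe.dollo_presence(t, {"A": True, "B": True, "C": True})
        (ins,) = [e for e in rec.events if e.kind == "insertion"]
        assert set(ins.child) == {"A", "B", "C"}
        assert not [e for e in rec.events if e.kind == "loss"]

    def test_single_present_tip(self):
        t = pe.parse_newick("((A,B),C);")
        rec = pe.dollo_presence(t, {"A": True, "B": False, "C": False})
        (ins,) = [e for e in rec.events if e.kind == "insertion"]
        assert ins.child == ("A",)

    def test_plain_absence_minimizes_losses(self):
        # without deletion evidence the gain sits on the smallest clade
        t = pe.parse_newick("(((A,B),C),D);")
        rec = pe.dollo_presence(t, {"A": True, "B": True, "C": False, "D": False})
        (ins,) = [e for e in rec.events if e.kind == "insertion"]
        assert set(ins.child) == {"A", "B"}
        assert len([e for e in rec.events if e.kind == "loss"]) == 0

    def test_lost_state_forces_deeper_gain(self):
        # 'lost' (deletion evidence) pulls the gain above that lineage
        t = pe.parse_newick("(((A,B),C),D);")
        rec = pe.dollo_presence(t, {"A": True, "B": True, "C": "lost", "D": False})
        (ins,) = [e for e in rec.events if e.kind == "insertion"]
        assert set(ins.child) == {"A", "B", "C"}
        losses = [e for e in rec.events if e.kind == "loss"]
        assert [set(e.child) for e in losses] == [{"C"}]

    def test_unique_minimum_over_single_gain_scenarios(self):
        """Dollo's gain placement minimizes losses over all single-gain
        scenarios (checked by enumeration on a small tree)."""
        t = pe.parse_newick("(((A,B),(C,D)),(E,F));")
        presence = {"A": True, "B": True, "C": True, "D": False, "E": False, "F": False}
        rec = pe.dollo_presence(t, presence)
        n_losses = len([e for e in rec.events if e.kind == "loss"])
        # enumerate: gain on each clade containing all present tips
        present = {x for x, v in presence.items() if v}
        best = min(
            sum(
                1
                for _ in _min_loss_branches(t, clade, present)
            )
            for clade in _clades(t)
            if present <= set(clade)
        )
        assert n_losses == best

    def test_insertion_recovered_from_simulation(self, primate_tree):
        clade = primate_tree.mrca_key(["Homo_sapiens", "Macaca_mulatta"])
        sim = sd.gen_tree_characters(0, primate_tree, insertion_clade=clade)
        rec = pe.dollo_presence(
            primate_tree, {t: p for t, (p, _) in sim.characters.items()}
        )
        (ins,) = [e for e in rec.events if e.kind == "insertion"]
        assert ins.child == clade


def _clades(stree):
    return [n.clade for n in stree.tree.preorder_node_iter()]


def _min_loss_branches(stree, gain_clade, present):
    """Maximal clades under the gain containing no present tip."""
    gain_node = next(
        n for n in stree.tree.preorder_node_iter() if n.clade == gain_clade
    )
    losses = []

    def walk(node, alive):
        if not alive:
            return
        if not (set(node.clade) & present):
            losses.append(node.clade)
            return
        for ch in node.child_nodes():
            walk(ch, True)

    walk(gain_node, True)
    return losses


class TestDating:
    def test_homo_branch_interval(self, primate_tree, primate_characters):
        rec = pe.sankoff(
            primate_tree, {t: c for t, (_, c) in primate_characters.items()}
        )
        homo = next(e for e in rec.events if e.delta == 2)
        date = pe.date_event(homo, primate_tree)
        assert date.age_young == pytest.approx(0.5)
        assert date.age_old == pytest.approx(6.5)

    def test_terminal_branch_to_extant_tip(self):
        t = pe.parse_newick("(A:43,B:43);", ultrametric=True)
        date = pe.date_event(pe.BranchEvent(child=("A",), kind="loss"), t)
        assert (date.age_young, date.age_old) == (0.0, 43.0)

    def test_unaged_tree_warns(self):
        t = pe.parse_newick("(A,B);")
        with pytest.warns(UserWarning):
            date = pe.date_event(pe.BranchEvent(child=("A",), kind="loss"), t)
        assert date.age_young is None and date.age_old is None
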