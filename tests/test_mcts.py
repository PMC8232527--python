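"""Tree-search mechanics: UCT, reconstruction, invariants, convergence."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from aptasearch.mcts import (
    ALL_DIRECTIONAL_BASES,
    Candidate,
    DirectionalBase,
    MctsAptamerSampler,
    SamplerConfig,
    TreeNode,
    backpropagate,
    expand,
    reconstruct,
    run_round,
    select_path,
    simulate,
    uct,
)

from .oracles import reconstruct_deque


def test_directional_base_alphabet():
    assert len(ALL_DIRECTIONAL_BASES) == 8
    assert [db.label for db in ALL_DIRECTIONAL_BASES] == [
        "A_", "C_", "G_", "U_", "_A", "_C", "_G", "_U",
    ]
    assert DirectionalBase.from_label("G_").apply("AU") == "GAU"
    assert DirectionalBase.from_label("_G").apply("AU") == "AUG"


def test_uct_values():
    assert uct(1.0, 1, 1, 12.0) == 1.0  # ln 1 = 0
    assert uct(3.0, 2, 10, 12.0) == pytest.approx(1.5 + 12 * math.sqrt(math.log(10) / 2))
    assert uct(0.0, 0, 5, 12.0) == math.inf  # unvisited children first
    # C = 0 orders purely by mean score
    assert uct(4.0, 5, 100, 0.0) == pytest.approx(0.8)


def test_reconstruct_worked_example():
    out = reconstruct("GAU", ["_U", "_C", "A_", "G_"])
    assert out == "GAGAUUC"
    assert len(out) == 7


def test_reconstruct_trivial_cases():
    assert reconstruct("", ["_A"]) == "A"
    assert reconstruct("", []) == ""


@given(st.integers(0, 2**31 - 1))
def test_reconstruct_matches_deque_oracle(seed):
    rng = np.random.default_rng(seed)
    core = "".join("ACGU"[i] for i in rng.integers(0, 4, rng.integers(0, 6)))
    labels = [ALL_DIRECTIONAL_BASES[i].label for i in rng.integers(0, 8, 12)]
    got = reconstruct(core, labels)
    assert got == reconstruct_deque(core, labels)
    assert len(got) == len(core) + 12
    assert sorted(got) == sorted(core + "".join(l.strip("_") for l in labels))


def _random_two_level_tree(rng):
    root = TreeNode()
    for db in ALL_DIRECTIONAL_BASES:
        child = TreeNode(label=db, depth=1)
        child.n = int(rng.integers(1, 20))
        child.s = float(rng.random() * child.n)
        root.children[db] = child
        for db2 in ALL_DIRECTIONAL_BASES:
            g = TreeNode(label=db2, depth=2)
            g.n = int(rng.integers(1, 5))
            g.s = float(rng.random() * g.n)
            child.children[db2] = g
    root.n = sum(c.n for c in root.children.values())
    for child in root.children.values():
        child.n = max(child.n, sum(g.n for g in child.children.values()))
    return root


def test_select_path_equals_per_level_uct_argmax():
    rng = np.random.default_rng(99)
    for _ in range(25):
        root = _random_two_level_tree(rng)
        c = float(rng.choice([0.0, 1.0, 12.0]))
        path = select_path(root, c, np.random.default_rng(1), depth_limit=2)
        node = root
        for chosen in path[1:]:
            scores = {
                db: uct(ch.s, ch.n, node.n, c) for db, ch in node.children.items()
            }
            best = max(scores.values())
            assert scores[chosen.label] == best
            node = chosen
        assert path[-1].depth == 2


def test_select_path_stops_at_partially_expanded_node():
    root = TreeNode()
    assert select_path(root, 12.0, np.random.default_rng(0), depth_limit=5) == [root]


def test_expand_forced_choice_and_errors():
    rng = np.random.default_rng(0)
    node = TreeNode()
    for db in ALL_DIRECTIONAL_BASES[:-1]:
        node.children[db] = TreeNode(label=db, depth=1)
    child = expand(node, rng)
    assert child.label == ALL_DIRECTIONAL_BASES[-1]
    assert (child.s, child.n) == (0.0, 0)
    with pytest.raises(ValueError):
        expand(node, rng)  # now fully expanded
    with pytest.raises(ValueError):
        expand(TreeNode(label=None, depth=3), rng, depth_limit=3)


def test_expand_label_choice_is_uniform():
    rng = np.random.default_rng(2024)
    counts = {db: 0 for db in ALL_DIRECTIONAL_BASES}
    for _ in range(8000):
        node = TreeNode()
        counts[expand(node, rng).label] += 1
    chi2 = stats.chisquare(list(counts.values()))
    assert chi2.pvalue > 1e-3


def test_simulate_lengths_and_uniformity():
    rng = np.random.default_rng(7)
    assert simulate(4, 4, rng) == []
    assert len(simulate(2, 7, rng)) == 5
    draws = [db.label for _ in range(1000) for db in simulate(0, 8, rng)]
    counts = [draws.count(db.label) for db in ALL_DIRECTIONAL_BASES]
    assert stats.chisquare(counts).pvalue > 1e-3
    with pytest.raises(ValueError):
        simulate(5, 4, rng)


def test_backpropagate_additivity():
    root = TreeNode()
    child = TreeNode(label=ALL_DIRECTIONAL_BASES[0], depth=1)
    root.children[child.label] = child
    backpropagate([root, child], 0.7)
    assert (root.n, root.s) == (1, 0.7)
    for _ in range(9):
        backpropagate([root, child], 0.7)
    assert root.s == pytest.approx(7.0)
    assert child.n == 10


def _walk(node):
    yield node
    for ch in node.children.values():
        yield from _walk(ch)


def test_run_round_visit_conservation_and_candidates():
    cfg = SamplerConfig(length=6, iterations=50, exploration=12.0, seed=0)
    rng = np.random.default_rng(3)
    best, cands, root = run_round("", "PROTEIN", lambda s, p: 0.5, cfg, rng)
    assert root.n == 50
    assert len(cands) == 50
    assert all(len(c.sequence) == 6 for c in cands)
    for node in _walk(root):
        assert node.n >= sum(ch.n for ch in node.children.values())
        if node.n:
            assert 0.0 <= node.s / node.n <= 1.0
    assert best in ALL_DIRECTIONAL_BASES


def test_run_round_rejects_out_of_range_scores():
    cfg = SamplerConfig(length=4, iterations=5, seed=0)
    with pytest.raises(ValueError, match="outside"):
        run_round("", "P", lambda s, p: 1.5, cfg, np.random.default_rng(0))


def test_last_round_degeneracy():
    cfg = SamplerConfig(length=4, iterations=30, seed=0)
    rng = np.random.default_rng(5)
    _, cands, root = run_round("ACG", "P", lambda s, p: 0.5, cfg, rng)
    assert all(len(c.sequence) == 4 for c in cands)
    assert all(ch.depth == 1 and not ch.children for ch in root.children.values())


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_exploitation_only_commits_the_rewarded_base(seed):
    # scorer strictly prefers sequences starting with G; from core "AU" the
    # single remaining position makes G_ the unique optimal commitment
    cfg = SamplerConfig(length=3, iterations=200, exploration=0.0, seed=seed)
    scorer = lambda s, p: 1.0 if s.startswith("G") else 0.0
    best, _, root = run_round("AU", "P", scorer, cfg, np.random.default_rng(seed))
    assert best.label == "G_"
    audited = max(root.children.values(), key=lambda ch: ch.mean_score)
    assert audited.label.label == "G_"


def test_prefix_rigged_round_from_empty_core():
    # from an empty core, prepend-G and append-G both realize a leading G;
    # the committed child must agree with the audited mean-score argmax
    cfg = SamplerConfig(length=4, iterations=400, exploration=12.0, seed=0)
    scorer = lambda s, p: 1.0 if s.startswith("G") else 0.0
    best, _, root = run_round("", "P", scorer, cfg, np.random.default_rng(0))
    assert best.base == "G"
    best_mean = max(ch.mean_score for ch in root.children.values())
    assert root.children[best].mean_score == best_mean


def test_generate_counts_lengths_and_determinism():
    sampler = MctsAptamerSampler(length=4, iterations=50, seed=12)
    scorer = lambda s, p: 0.25
    c1 = sampler.generate("PROT", scorer)
    c2 = MctsAptamerSampler(length=4, iterations=50, seed=12).generate("PROT", scorer)
    assert len(c1) == 4 * 50  # N*M raw candidates
    assert all(len(c.sequence) == 4 for c in c1)
    assert c1 == c2
    assert len({c.sequence for c in c1}) <= 4**4
    c3 = MctsAptamerSampler(length=4, iterations=50, seed=13).generate("PROT", scorer)
    assert c3 != c1


def test_generate_multi_gives_independent_candidate_sets():
    sampler = MctsAptamerSampler(length=3, iterations=20, seed=1)
    sets = sampler.generate_multi("PROT", [lambda s, p: 0.5, lambda s, p: 0.5])
    assert len(sets) == 2
    assert all(len(cs) == 60 for cs in sets)


def test_sampler_config_validation():
    with pytest.raises(ValueError):
        SamplerConfig(length=0)
    with pytest.raises(ValueError):
        SamplerConfig(length=5, iterations=0)
    with pytest.raises(ValueError):
        SamplerConfig(length=5, exploration=-1.0)
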