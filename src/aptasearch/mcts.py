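"""Iterative forward sequence sampling by Monte Carlo tree search.

A candidate aptamer of target length N is built one base at a time over N
rounds. Each round runs M iterations of UCT-guided tree search over
*directional bases* -- a nucleotide tagged with the side at which it
extends the partial sequence, giving an 8-way branching factor (A_, C_,
G_, U_ prepend; _A, _C, _G, _U append). Every iteration completes a full-
length sequence (selection path plus random playout), scores it with the
interaction classifier, collects it as a candidate, and backs the score up
the tree. After M iterations the root child with the highest mean score is
committed to the growing core, and the next round searches the remaining
positions. A full run therefore emits N*M scored candidates.

The score function is any callable ``(rna_sequence, protein) -> [0, 1]``;
fitted :class:`~aptasearch.classifier.InteractionClassifier` instances are
adapted automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .sequences import RNA_ALPHABET

__all__ = [
    "DirectionalBase",
    "ALL_DIRECTIONAL_BASES",
    "TreeNode",
    "Candidate",
    "SamplerConfig",
    "uct",
    "reconstruct",
    "select_path",
    "expand",
    "simulate",
    "backpropagate",
    "run_round",
    "MctsAptamerSampler",
    "generate",
]


@dataclass(frozen=True, order=True)
class DirectionalBase:
    """A nucleotide plus the side at which it extends the sequence."""

    sort_index: str = field(init=False, repr=False)
    base: str = "A"
    side: str = "prepend"  # "prepend" places the base on the left

    def __post_init__(self):
        if self.base not in RNA_ALPHABET:
            raise ValueError(f"invalid base {self.base!r}")
        if self.side not in ("prepend", "append"):
            raise ValueError(f"invalid side {self.side!r}")
        object.__setattr__(self, "sort_index", self.label)

    @property
    def label(self) -> str:
        return self.base + "_" if self.side == "prepend" else "_" + self.base

    @classmethod
    def from_label(cls, label: str) -> "DirectionalBase":
        if len(label) == 2 and label[1] == "_":
            return cls(base=label[0], side="prepend")
        if len(label) == 2 and label[0] == "_":
            return cls(base=label[1], side="append")
        raise ValueError(f"invalid directional-base label {label!r}")

    def apply(self, seq: str) -> str:
        return self.base + seq if self.side == "prepend" else seq + self.base


#: The 8 directional bases in lexicographic label order
#: (A_, C_, G_, U_, _A, _C, _G, _U).
ALL_DIRECTIONAL_BASES: tuple[DirectionalBase, ...] = tuple(
    sorted(
        DirectionalBase(base=b, side=s)
        for b in RNA_ALPHABET
        for s in ("prepend", "append")
    )
)


class TreeNode:
    """Search-tree node: cumulative score ``s``, visit count ``n``."""

    __slots__ = ("label", "depth", "s", "n", "children")

    def __init__(self, label: DirectionalBase | None = None, depth: int = 0):
        self.label = label
        self.depth = depth
        self.s = 0.0
        self.n = 0
        self.children: dict[DirectionalBase, TreeNode] = {}

    @property
    def mean_score(self) -> float:
        return self.s / self.n if self.n else 0.0

    def __repr__(self):  # pragma: no cover - debugging aid
        lab = self.label.label if self.label else "root"
        return f"TreeNode({lab}, n={self.n}, s={self.s:.3f})"


@dataclass(frozen=True)
class Candidate:
    """A generated full-length sequence with its interaction score."""

    sequence: str
    score: float
    round_index: int
    iteration_index: int


@dataclass(frozen=True)
class SamplerConfig:
    """Sampler settings: target length N, iterations per round M, and the
    UCT exploration constant C (defaults M=5000, C=12)."""

    length: int
    iterations: int = 5000
    exploration: float = 12.0
    seed: int = 0

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("target length must be >= 1")
        if self.iterations < 1:
            raise ValueError("iterations per round must be >= 1")
        if self.exploration < 0:
            raise ValueError("exploration constant must be >= 0")


def uct(s: float, n: int, n_parent: int, c: float) -> float:
    """Upper-confidence score s/n + c*sqrt(ln(N_parent)/n).

    Unvisited nodes (n = 0) score +inf so each instantiated child is tried
    before any sibling is re-exploited.
    """
    if n == 0:
        return math.inf
    return s / n + c * math.sqrt(math.log(n_parent) / n)


def reconstruct(core: str, path: Sequence[DirectionalBase | str]) -> str:
    """Apply directional bases in order to the core sequence.

    Append-side bases concatenate on the right, prepend-side on the left;
    e.g. core ``GAU`` with path ``[_U, _C, A_, G_]`` builds
    GAU -> GAUU -> GAUUC -> AGAUUC -> GAGAUUC.
    Labels may be given as strings (``"G_"``, ``"_U"``).
    """
    seq = core
    for step in path:
        if isinstance(step, str):
            step = DirectionalBase.from_label(step)
        seq = step.apply(seq)
    return seq


def _uct_argmax(
    node: TreeNode, c: float, rng: np.random.Generator
) -> TreeNode:
    children = list(node.children.values())
    scores = [uct(ch.s, ch.n, node.n, c) for ch in children]
    best = max(scores)
    tied = [i for i, v in enumerate(scores) if v == best]
    pick = tied[0] if len(tied) == 1 else int(rng.choice(tied))
    return children[pick]


def select_path(
    root: TreeNode,
    c: float,
    rng: np.random.Generator,
    depth_limit: int | None = None,
) -> list[TreeNode]:
    """Descend by UCT-maximal child until a node with an uninstantiated
    child (or the depth limit) is reached; ties break uniformly at random."""
    path = [root]
    node = root
    while (
        len(node.children) == len(ALL_DIRECTIONAL_BASES)
        and (depth_limit is None or node.depth < depth_limit)
    ):
        node = _uct_argmax(node, c, rng)
        path.append(node)
    return path


def expand(node: TreeNode, rng: np.random.Generator, depth_limit: int | None = None) -> TreeNode:
    """Instantiate one uniformly random missing child (s = 0, n = 0)."""
    if depth_limit is not None and node.depth >= depth_limit:
        raise ValueError("cannot expand a node at the depth limit")
    missing = [db for db in ALL_DIRECTIONAL_BASES if db not in node.children]
    if not missing:
        raise ValueError("node is fully expanded")
    label = missing[0] if len(missing) == 1 else missing[int(rng.integers(len(missing)))]
    child = TreeNode(label=label, depth=node.depth + 1)
    node.children[label] = child
    return child


def simulate(
    from_depth: int, depth_limit: int, rng: np.random.Generator
) -> list[DirectionalBase]:
    """Uniform random walk of directional bases down to the depth limit."""
    if from_depth > depth_limit:
        raise ValueError("from_depth exceeds depth_limit")
    draws = rng.integers(0, len(ALL_DIRECTIONAL_BASES), size=depth_limit - from_depth)
    return [ALL_DIRECTIONAL_BASES[int(i)] for i in draws]


def backpropagate(path: Sequence[TreeNode], score: float) -> None:
    """Add the playout score to every node on the path (root included)."""
    for node in path:
        node.n += 1
        node.s += score


def _commit_best(root: TreeNode) -> DirectionalBase:
    """Root child with highest mean score; ties to larger n, then to the
    lexicographically smallest label."""
    best = min(
        root.children.values(),
        key=lambda ch: (-ch.mean_score, -ch.n, ch.label.label),
    )
    return best.label


def run_round(
    core: str,
    protein: str,
    scorer: Callable[[str, str], float],
    cfg: SamplerConfig,
    rng: np.random.Generator,
    round_index: int = 0,
) -> tuple[DirectionalBase, list[Candidate], TreeNode]:
    """One position-selection round: M search iterations, one committed base.

    Every iteration runs selection, expansion and simulation down to the
    round's depth limit ``N - len(core)``, reconstructs the implied full-
    length sequence, scores it, records it as a :class:`Candidate` and
    backpropagates the score. Returns the committed directional base, the
    M candidates, and the search tree root (for auditing).
    """
    depth_limit = cfg.length - len(core)
    if depth_limit < 1:
        raise ValueError("core is already at the target length")
    root = TreeNode()
    candidates: list[Candidate] = []
    for it in range(cfg.iterations):
        path = select_path(root, cfg.exploration, rng, depth_limit)
        node = path[-1]
        if node.depth < depth_limit:
            node = expand(node, rng, depth_limit)
            path.append(node)
        playout = simulate(node.depth, depth_limit, rng)
        labels = [n.label for n in path[1:]]
        seq = reconstruct(core, labels + playout)
        score = scorer(seq, protein)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"scorer returned {score!r}, outside [0, 1]")
        backpropagate(path, score)
        candidates.append(
            Candidate(sequence=seq, score=score, round_index=round_index, iteration_index=it)
        )
    return _commit_best(root), candidates, root


def _as_score_fn(scorer, protein: str) -> Callable[[str, str], float]:
    """Adapt classifiers and bare callables to the (seq, protein) contract."""
    if hasattr(scorer, "make_scorer"):
        fn = scorer.make_scorer(protein)
        return lambda seq, _protein: fn(seq)
    return scorer


class MctsAptamerSampler(BaseEstimator):
    """Generates candidate aptamers of a chosen length for a target protein.

    Parameters
    ----------
    length : int
        Target aptamer length N; the sampler runs N rounds.
    iterations : int, default 5000
        Search iterations M per round; each emits one scored candidate.
    exploration : float, default 12.0
        UCT exploration constant C.
    seed : int, default 0
        Root seed; per-round generators are derived deterministically, so
        the full candidate list is reproducible from this one integer.
    """

    def __init__(self, length: int = 30, iterations: int = 5000, exploration: float = 12.0, seed: int = 0):
        self.length = length
        self.iterations = iterations
        self.exploration = exploration
        self.seed = seed

    def _config(self) -> SamplerConfig:
        return SamplerConfig(
            length=self.length,
            iterations=self.iterations,
            exploration=self.exploration,
            seed=self.seed,
        )

    def generate(self, protein: str, scorer, trace: list | None = None) -> list[Candidate]:
        """Run all N rounds for one scorer; returns the N*M raw candidates.

        ``scorer`` is a fitted classifier or a callable
        ``(sequence, protein) -> [0, 1]``. If ``trace`` is a list, one dict
        per round is appended with the committed base and the root-child
        audit table (label, n, mean score).
        """
        cfg = self._config()
        score_fn = _as_score_fn(scorer, protein)
        round_seeds = np.random.SeedSequence(self.seed).spawn(cfg.length)
        core = ""
        out: list[Candidate] = []
        for r in range(cfg.length):
            rng = np.random.default_rng(round_seeds[r])
            best, cands, root = run_round(
                core, protein, score_fn, cfg, rng, round_index=r
            )
            out.extend(cands)
            core = reconstruct(core, [best])
            if trace is not None:
                trace.append(
                    {
                        "round": r,
                        "committed": best.label,
                        "core": core,
                        "children": {
                            ch.label.label: (ch.n, ch.mean_score)
                            for ch in sorted(
                                root.children.values(), key=lambda c: c.label.label
                            )
                        },
                    }
                )
        return out

    def generate_multi(self, protein: str, scorers: Sequence) -> list[list[Candidate]]:
        """Independent runs for several score functions (same root seed
        spawns one seed branch per scorer)."""
        branches = np.random.SeedSequence(self.seed).spawn(len(scorers))
        results = []
        for scorer, branch in zip(scorers, branches):
            sub = MctsAptamerSampler(
                length=self.length,
                iterations=self.iterations,
                exploration=self.exploration,
                seed=int(branch.generate_state(1)[0] % (2**31)),
            )
            results.append(sub.generate(protein, scorer))
        return results


def generate(
    protein: str,
    scorer,
    length: int,
    iterations: int = 5000,
    exploration: float = 12.0,
    seed: int = 0,
) -> list[Candidate]:
    """Functional wrapper over :class:`MctsAptamerSampler.generate`."""
    return MctsAptamerSampler(
        length=length, iterations=iterations, exploration=exploration, seed=seed
    ).generate(protein, scorer)
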