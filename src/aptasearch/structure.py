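"""RNA secondary structure prediction and structure-based deduplication.

The sampler emits N*M raw candidates, many of which fold into the same
secondary structure. Candidates whose dot-bracket strings are exactly
identical are collapsed to the single highest-scoring representative, and
the surviving set is sorted by interaction score.

Two folding backends are available. The builtin backend is a
Nussinov-style maximum base-pairing dynamic program (Watson-Crick plus
G-U wobble pairs, minimum hairpin loop of 3 unpaired bases, deterministic
traceback that prefers pairing and the leftmost pairing partner). The
external backend delegates to ViennaRNA (python bindings or the RNAfold
executable) and produces minimum-free-energy structures; the two backends
generally give different structures, which only changes how candidates
merge, never the set invariants. Structure identity is used solely for
deduplication -- no affinity meaning is attached to it.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, replace
from typing import Sequence

from .mcts import Candidate
from .sequences import check_rna

__all__ = [
    "StructureBackendError",
    "fold",
    "pair_count",
    "is_valid_dot_bracket",
    "FoldedCandidate",
    "CandidateSet",
    "dedup",
    "top_k",
]

_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)
MIN_LOOP = 3  # unpaired bases required inside a hairpin


class StructureBackendError(RuntimeError):
    """The requested folding backend is unavailable or misbehaved."""


def is_valid_dot_bracket(notation: str) -> bool:
    """Balanced, properly nested (pseudoknot-free) dot-bracket string."""
    depth = 0
    for ch in notation:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                return False
        elif ch != ".":
            return False
    return depth == 0


def pair_count(notation: str) -> int:
    return notation.count("(")


def _fold_nussinov(seq: str) -> str:
    n = len(seq)
    if n <= MIN_LOOP + 1:
        return "." * n
    table = [[0] * n for _ in range(n)]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            row_i1 = table[i + 1]
            best = row_i1[j]
            ci = seq[i]
            for k in range(i + MIN_LOOP + 1, j + 1):
                if (ci, seq[k]) in _PAIRS:
                    v = 1 + row_i1[k - 1] + (table[k + 1][j] if k < j else 0)
                    if v > best:
                        best = v
            table[i][j] = best
    struct = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = table[i][j]
        if target == 0:
            continue
        ci = seq[i]
        paired = False
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (ci, seq[k]) in _PAIRS:
                v = 1 + table[i + 1][k - 1] + (table[k + 1][j] if k < j else 0)
                if v == target:
                    struct[i], struct[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    if k < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(struct)


def _fold_vienna(seq: str) -> str:
    try:
        import RNA  # ViennaRNA python bindings

        return RNA.fold(seq)[0]
    except ImportError:
        pass
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=seq + "\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        raise StructureBackendError(
            "ViennaRNA backend unavailable: neither the RNA python module "
            f"nor a working RNAfold executable was found ({exc})"
        ) from exc
    lines = proc.stdout.strip().splitlines()
    if len(lines) < 2:
        raise StructureBackendError(f"unparsable RNAfold output: {proc.stdout!r}")
    notation = lines[1].split()[0]
    if not is_valid_dot_bracket(notation) or len(notation) != len(seq):
        raise StructureBackendError(f"invalid RNAfold structure {notation!r}")
    return notation


def fold(seq: str, backend: str = "builtin") -> str:
    """Dot-bracket secondary structure of an RNA sequence.

    ``backend="builtin"`` runs the deterministic maximum-pairing dynamic
    program; ``backend="vienna"`` requires ViennaRNA and raises
    :class:`StructureBackendError` if it is missing (never a silent
    fallback).
    """
    seq = check_rna(seq)
    if backend == "builtin":
        return _fold_nussinov(seq)
    if backend == "vienna":
        return _fold_vienna(seq)
    raise ValueError(f"unknown folding backend {backend!r}")


@dataclass(frozen=True)
class FoldedCandidate:
    """A candidate annotated with its dot-bracket structure."""

    sequence: str
    score: float
    dot_bracket: str
    round_index: int = -1
    iteration_index: int = -1


@dataclass(frozen=True)
class CandidateSet:
    """Deduplicated, score-sorted candidates plus their provenance."""

    candidates: tuple[FoldedCandidate, ...]
    scorer_id: str = ""
    backend: str = "builtin"

    def __len__(self) -> int:
        return len(self.candidates)

    def __iter__(self):
        return iter(self.candidates)


def _sort_key(c: FoldedCandidate):
    return (-c.score, c.sequence)


def dedup(
    candidates: Sequence[Candidate | FoldedCandidate],
    backend: str = "builtin",
    scorer_id: str = "",
) -> CandidateSet:
    """Collapse candidates with identical dot-bracket structures.

    Within each structure group the maximum-score candidate is kept (score
    ties go to the lexicographically smallest sequence); the result is
    sorted by score descending. Folding is cached per distinct sequence.
    """
    fold_cache: dict[str, str] = {}
    best_by_struct: dict[str, FoldedCandidate] = {}
    for idx, cand in enumerate(candidates):
        db = fold_cache.get(cand.sequence)
        if db is None:
            try:
                db = fold(cand.sequence, backend=backend)
            except Exception as exc:
                raise type(exc)(f"candidate {idx}: {exc}") from exc
            fold_cache[cand.sequence] = db
        folded = FoldedCandidate(
            sequence=cand.sequence,
            score=cand.score,
            dot_bracket=db,
            round_index=getattr(cand, "round_index", -1),
            iteration_index=getattr(cand, "iteration_index", -1),
        )
        held = best_by_struct.get(db)
        # strictly higher score wins; equal scores keep the
        # lexicographically smaller sequence
        if (
            held is None
            or folded.score > held.score
            or (folded.score == held.score and folded.sequence < held.sequence)
        ):
            best_by_struct[db] = folded
    ordered = tuple(sorted(best_by_struct.values(), key=_sort_key))
    return CandidateSet(candidates=ordered, scorer_id=scorer_id, backend=backend)


def top_k(cset: CandidateSet, k: int) -> CandidateSet:
    """First min(k, size) candidates of the score-sorted set."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return replace(cset, candidates=cset.candidates[:k])
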