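"""Seeded synthetic aptamer-protein interaction data with known ground truth.

Real interaction benchmarks are external downloads, so every part of the
pipeline must also be exercisable on data we can regenerate from a seed.
The generator emulates the benchmarks' shape -- RNA aptamers of 20-90 nt,
proteins of 50-400 aa, roughly 1 positive to 3 negatives -- and plants a
recoverable interaction rule: each protein deterministically maps (via a
hash of its first ``motif_length`` residues) to an RNA motif; positive
pairs carry the motif at a uniform position, negative aptamers are
non-binders for the whole panel: they contain no length-3 substring of
any pool protein's motif, so the true labelling rule is exactly
representable by trinucleotide-level aptamer features. Optional label
noise flips training labels to make learnability degrade gracefully.

A rigged scorer (reward iff a motif is present) is also provided as a test
double for the classifier inside the tree search.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .sequences import PROTEIN_ALPHABET, RNA_ALPHABET

__all__ = [
    "SyntheticConfig",
    "motif_for_protein",
    "generate_dataset",
    "generate_train_test",
    "make_rigged_scorer",
]

Record = tuple[str, str, int]  # (aptamer, protein, label)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the benchmark datasets."""

    n_pos: int = 200
    n_neg: int = 600
    aptamer_length_range: tuple[int, int] = (20, 90)
    protein_length_range: tuple[int, int] = (50, 400)
    motif_length: int = 4
    noise_rate: float = 0.0
    n_proteins: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("class counts must be >= 1")
        if self.motif_length > self.aptamer_length_range[0]:
            raise ValueError(
                "motif longer than the shortest admissible aptamer"
            )
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if self.n_proteins < 1:
            raise ValueError("protein pool must be non-empty")
        for low, high in (self.aptamer_length_range, self.protein_length_range):
            if low > high or low < 1:
                raise ValueError("invalid length range")


def motif_for_protein(protein: str, motif_length: int = 4) -> str:
    """The RNA motif a protein's aptamers carry: a pure hash of its first
    ``motif_length`` residues, so ground truth needs no side file and any
    oracle can recompute it."""
    digest = hashlib.sha256(protein[:motif_length].encode("ascii")).digest()
    return "".join(RNA_ALPHABET[b % 4] for b in digest[:motif_length])


def _random_seq(rng: np.random.Generator, alphabet: str, length: int) -> str:
    return "".join(
        alphabet[i] for i in rng.integers(0, len(alphabet), size=length)
    )


def _forbidden_trigrams(motifs: Iterable[str]) -> frozenset[str]:
    """Every length-3 substring of every motif in the panel vocabulary."""
    out = set()
    for motif in motifs:
        out.update(motif[i : i + 3] for i in range(len(motif) - 2))
    return frozenset(out)


def _motif_free(
    rng: np.random.Generator,
    length: int,
    forbidden: frozenset[str],
    max_tries: int = 1000,
) -> str:
    """An RNA sequence containing none of the forbidden trigrams.

    Built base by base, drawing uniformly among the bases that do not
    complete a forbidden trigram (restarting on the rare dead end); any
    motif of the panel needs its trigrams, so none can occur.
    """
    for _ in range(max_tries):
        chars: list[str] = []
        ok = True
        for _pos in range(length):
            if len(chars) >= 2:
                context = chars[-2] + chars[-1]
                allowed = [b for b in RNA_ALPHABET if context + b not in forbidden]
            else:
                allowed = list(RNA_ALPHABET)
            if not allowed:
                ok = False
                break
            chars.append(allowed[int(rng.integers(len(allowed)))])
        if ok:
            return "".join(chars)
    raise RuntimeError(
        f"could not sample a motif-free aptamer of length {length}"
    )


def _positive_aptamer(rng: np.random.Generator, length: int, motif: str) -> str:
    seq = list(_random_seq(rng, RNA_ALPHABET, length))
    start = int(rng.integers(0, length - len(motif) + 1))
    seq[start : start + len(motif)] = motif
    return "".join(seq)


def _draw_pool(cfg: SyntheticConfig, rng: np.random.Generator) -> list[str]:
    low, high = cfg.protein_length_range
    return [
        _random_seq(rng, PROTEIN_ALPHABET, int(rng.integers(low, high + 1)))
        for _ in range(cfg.n_proteins)
    ]


def _draw_records(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    pool: list[str],
    n_pos: int,
    n_neg: int,
    noise_rate: float,
) -> list[Record]:
    apt_low, apt_high = cfg.aptamer_length_range
    forbidden = _forbidden_trigrams(
        motif_for_protein(p, cfg.motif_length) for p in pool
    )
    records: list[Record] = []
    for label, count in ((1, n_pos), (0, n_neg)):
        for _ in range(count):
            protein = pool[int(rng.integers(len(pool)))]
            motif = motif_for_protein(protein, cfg.motif_length)
            length = int(rng.integers(apt_low, apt_high + 1))
            if label:
                aptamer = _positive_aptamer(rng, length, motif)
            else:
                aptamer = _motif_free(rng, length, forbidden)
            records.append((aptamer, protein, label))
    if noise_rate > 0:
        flips = rng.random(len(records)) < noise_rate
        records = [
            (a, p, 1 - lab if flip else lab)
            for (a, p, lab), flip in zip(records, flips)
        ]
    return records


def generate_dataset(cfg: SyntheticConfig) -> tuple[list[Record], dict[str, str]]:
    """One labelled dataset plus the protein-to-motif ground-truth map.

    Emits exactly ``n_pos`` positives followed by ``n_neg`` negatives
    (before noise); fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _draw_pool(cfg, rng)
    records = _draw_records(cfg, rng, pool, cfg.n_pos, cfg.n_neg, cfg.noise_rate)
    truth = {p: motif_for_protein(p, cfg.motif_length) for p in pool}
    return records, truth


def generate_train_test(
    cfg: SyntheticConfig,
    n_test_pos: int | None = None,
    n_test_neg: int | None = None,
    test_noise_rate: float = 0.0,
) -> tuple[list[Record], list[Record], dict[str, str]]:
    """Train and held-out splits over a shared protein pool.

    Test sizes default to a quarter of the training counts, mirroring the
    benchmark splits. ``cfg.noise_rate`` applies to the training labels
    only; the held-out labels stay clean (configurable via
    ``test_noise_rate``) so held-out metrics measure recovery of the true
    rule rather than the noise floor.
    """
    n_test_pos = n_test_pos if n_test_pos is not None else max(1, cfg.n_pos // 4)
    n_test_neg = n_test_neg if n_test_neg is not None else max(1, cfg.n_neg // 4)
    rng = np.random.default_rng(cfg.seed)
    pool = _draw_pool(cfg, rng)
    train = _draw_records(cfg, rng, pool, cfg.n_pos, cfg.n_neg, cfg.noise_rate)
    test = _draw_records(cfg, rng, pool, n_test_pos, n_test_neg, test_noise_rate)
    truth = {p: motif_for_protein(p, cfg.motif_length) for p in pool}
    return train, test, truth


def make_rigged_scorer(motif: str, reward: float = 1.0) -> Callable[[str, str], float]:
    """A deterministic test-double score function: ``reward`` if the motif
    occurs in the aptamer, else 0."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if not 0 < reward <= 1:
        raise ValueError("reward must lie in (0, 1]")

    def scorer(seq: str, protein: str | None = None) -> float:
        return reward if motif in seq else 0.0

    return scorer
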