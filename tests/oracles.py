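"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity from first principles (sliding windows,
direct summation, exhaustive enumeration) without calling the package code
path it checks.
"""

from __future__ import annotations

import itertools
import math
from pathlib import Path

import numpy as np

_DATA = Path(__file__).resolve().parents[1] / "src" / "aptasearch" / "data"

RNA_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def kmer_count_vector(seq: str, k: int, alphabet: str) -> np.ndarray:
    """Naive sliding-window k-mer frequencies in lexicographic order."""
    units = ["".join(u) for u in itertools.product(sorted(alphabet), repeat=k)]
    counts = {u: 0 for u in units}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    total = len(seq) - k + 1
    return np.array([counts[u] / total for u in units])


def load_standardized_table(name: str) -> dict[str, np.ndarray]:
    """Re-read a shipped property TSV and standardize it independently."""
    lines = (_DATA / f"{name}.tsv").read_text().splitlines()
    rows = [l.split("\t") for l in lines[2:] if l.strip()]
    units = [r[0] for r in rows]
    mat = np.array([[float(v) for v in r[1:]] for r in rows])
    z = (mat - mat.mean(axis=0)) / mat.std(axis=0)
    return {u: z[i] for i, u in enumerate(units)}


def profile_of(seq: str, table: dict[str, np.ndarray], k: int) -> np.ndarray:
    return np.array([table[seq[i : i + k]] for i in range(len(seq) - k + 1)])


def auto_cov_direct(seq: str, table_name: str, unit: int, max_lag: int) -> np.ndarray:
    table = load_standardized_table(table_name)
    prof = profile_of(seq, table, unit)
    n, p = prof.shape
    means = prof.mean(axis=0)
    out = []
    for j in range(p):
        for lag in range(1, max_lag + 1):
            acc = 0.0
            for i in range(n - lag):
                acc += (prof[i, j] - means[j]) * (prof[i + lag, j] - means[j])
            out.append(acc / (n - lag))
    return np.array(out)


def cross_cov_direct(seq: str, table_name: str, unit: int, max_lag: int) -> np.ndarray:
    table = load_standardized_table(table_name)
    prof = profile_of(seq, table, unit)
    n, p = prof.shape
    means = prof.mean(axis=0)
    out = []
    for j in range(p):
        for m in range(p):
            if m == j:
                continue
            for lag in range(1, max_lag + 1):
                acc = 0.0
                for i in range(n - lag):
                    acc += (prof[i, j] - means[j]) * (prof[i + lag, m] - means[m])
                out.append(acc / (n - lag))
    return np.array(out)


def pseknc_direct(seq: str, k: int, lam: int, w: float) -> np.ndarray:
    table_name = "rna_dinucleotide" if k == 2 else "rna_trinucleotide"
    table = load_standardized_table(table_name)
    prof = profile_of(seq, table, k)
    n = prof.shape[0]
    thetas = []
    for j in range(1, lam + 1):
        vals = []
        for i in range(n - j):
            vals.append(np.mean((prof[i] - prof[i + j]) ** 2))
        thetas.append(float(np.mean(vals)))
    freqs = kmer_count_vector(seq, k, "ACGU")
    denom = 1.0 + w * sum(thetas)
    return np.concatenate([freqs / denom, w * np.array(thetas) / denom])


def pseaac_direct(seq: str, lam: int, w: float) -> np.ndarray:
    table = load_standardized_table("amino_acid")
    prof = np.array([table[c] for c in seq])
    n = len(seq)
    thetas = []
    for j in range(1, lam + 1):
        vals = [np.mean((prof[i] - prof[i + j]) ** 2) for i in range(n - j)]
        thetas.append(float(np.mean(vals)))
    freqs = kmer_count_vector(seq, 1, "ACDEFGHIKLMNPQRSTVWY")
    denom = 1.0 + w * sum(thetas)
    return np.concatenate([freqs / denom, w * np.array(thetas) / denom])


def triad_direct(seq: str, classes: list[str]) -> np.ndarray:
    cls = {}
    for i, members in enumerate(classes):
        for ch in members:
            cls[ch] = i
    c = len(classes)
    counts = np.zeros(c**3)
    for i in range(len(seq) - 2):
        counts[cls[seq[i]] * c * c + cls[seq[i + 1]] * c + cls[seq[i + 2]]] += 1
    return (counts - counts.min()) / counts.max()


def ctd_direct(seq: str, groups: dict[str, tuple[str, str, str]]) -> np.ndarray:
    """Positional-scan recomputation of the 147-dim CTD descriptor."""
    n = len(seq)
    out = []
    for g1, g2, g3 in groups.values():
        lab = ["123"[(ch in g2) + 2 * (ch in g3)] for ch in seq]
        for g in "123":
            out.append(lab.count(g) / n)
        pairs = list(zip(lab, lab[1:]))
        for a, b in (("1", "2"), ("1", "3"), ("2", "3")):
            out.append((pairs.count((a, b)) + pairs.count((b, a))) / (n - 1))
        for g in "123":
            pos = [i + 1 for i, l in enumerate(lab) if l == g]
            if not pos:
                out.extend([0.0] * 5)
                continue
            m = len(pos)
            for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
                rank = max(1, math.ceil(frac * m))
                out.append(pos[rank - 1] / n)
    return np.array(out)


def max_pairs_enumerate(seq: str, min_loop: int = 3) -> int:
    """Exhaustive enumeration of every nested pairing (no memoization)."""

    def best(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        # position i unpaired
        options = [best(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in RNA_PAIRS:
                options.append(1 + best(i + 1, k - 1) + best(k + 1, j))
        return max(options)

    return best(0, len(seq) - 1)


def reconstruct_deque(core: str, labels: list[str]) -> str:
    """Double-ended-queue simulation of directional-base reconstruction."""
    from collections import deque

    dq = deque(core)
    for lab in labels:
        if lab.endswith("_"):
            dq.appendleft(lab[0])
        else:
            dq.append(lab[1])
    return "".join(dq)
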