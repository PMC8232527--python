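"""Readers and writers for the package's plain-text interchange formats.

Dataset TSV dialect: header ``aptamer_sequence  protein_sequence  label``
with labels ``1``/``0`` or ``positive``/``negative``; the reader folds T
into U and validates both alphabets, reporting the offending line number.
Candidate output comes as TSV (rank, sequence, score, dot_bracket,
scorer_id), FASTA, and Vienna-style two-line records. Every
artifact-producing command also writes a YAML manifest with the resolved
configuration, seeds and input checksums, sufficient to reproduce the run
bit for bit.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .sequences import check_protein, normalize_rna
from .structure import CandidateSet

__all__ = [
    "read_pairs_tsv",
    "write_pairs_tsv",
    "write_truth_tsv",
    "read_protein_fasta",
    "write_leaderboard_tsv",
    "write_candidates_tsv",
    "write_candidates_fasta",
    "write_candidates_vienna",
    "write_manifest",
    "file_sha256",
]

DATASET_HEADER = ("aptamer_sequence", "protein_sequence", "label")
_LABELS = {"1": 1, "0": 0, "positive": 1, "negative": 0}


def read_pairs_tsv(path) -> tuple[list[tuple[str, str]], np.ndarray]:
    """Load labelled pairs; returns (pairs, labels) with labels as 0/1."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty dataset file")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != DATASET_HEADER:
        raise ValueError(
            f"{path}:1: expected header {'	'.join(DATASET_HEADER)!r}"
        )
    pairs: list[tuple[str, str]] = []
    labels: list[int] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
        apt_raw, prot_raw, label_raw = parts
        try:
            apt = normalize_rna(apt_raw)
            prot = check_protein(prot_raw)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        label = _LABELS.get(label_raw.strip().lower())
        if label is None:
            raise ValueError(f"{path}:{lineno}: unrecognized label {label_raw!r}")
        pairs.append((apt, prot))
        labels.append(label)
    if not pairs:
        raise ValueError(f"{path}: no records")
    return pairs, np.array(labels, dtype=int)


def write_pairs_tsv(records: Iterable[tuple[str, str, int]], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(DATASET_HEADER) + "\n")
        for apt, prot, label in records:
            fh.write(f"{apt}\t{prot}\t{int(label)}\n")


def write_truth_tsv(truth: dict[str, str], path) -> None:
    """Protein-to-motif ground truth map of a synthetic dataset."""
    with Path(path).open("w") as fh:
        fh.write("protein_sequence\tmotif\n")
        for prot in sorted(truth):
            fh.write(f"{prot}\t{truth[prot]}\n")


def read_protein_fasta(path) -> tuple[str, str]:
    """Load the single protein record of a FASTA file as (id, sequence)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ValueError(
            f"{path}: {len(records)} records found; provide exactly one "
            "target protein per run"
        )
    rec = records[0]
    return rec.id, check_protein(str(rec.seq))


def write_leaderboard_tsv(leaderboard: pd.DataFrame, path) -> None:
    leaderboard.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_candidates_tsv(cset: CandidateSet, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("rank\tsequence\tscore\tdot_bracket\tscorer_id\n")
        for rank, cand in enumerate(cset, start=1):
            fh.write(
                f"{rank}\t{cand.sequence}\t{cand.score:.6f}\t"
                f"{cand.dot_bracket}\t{cset.scorer_id}\n"
            )


def write_candidates_fasta(cset: CandidateSet, path) -> None:
    with Path(path).open("w") as fh:
        for rank, cand in enumerate(cset, start=1):
            fh.write(f">{rank}_{cand.score:.6f}\n{cand.sequence}\n")


def write_candidates_vienna(cset: CandidateSet, path) -> None:
    """Two-line sequence/structure records, RNAfold style."""
    with Path(path).open("w") as fh:
        for rank, cand in enumerate(cset, start=1):
            fh.write(f">{rank}_{cand.score:.6f}\n{cand.sequence}\n{cand.dot_bracket}\n")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, payload: dict) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
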