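"""Physicochemical property and residue-group tables.

The covariance and pseudo-composition encoders weight sequence positions by
numeric physicochemical indices of their constituent units (dinucleotides,
trinucleotides or amino acids). Those indices are not part of the model --
they are reference data -- so they ship as versioned TSV files under
``aptasearch/data`` and can be overridden with user files of the same
schema.

Schema: first line is a ``#``-prefixed version header, second line the
column header (``unit`` followed by property names), then one row per unit.
Group tables (CTD attributes, conjoint-triad classes) follow analogous
layouts.

Property values are standardized to mean 0 / variance 1 across units before
entering any correlation or covariance term, so the choice of measurement
units in the files cannot change encoder semantics.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

_DATA_PACKAGE = "aptasearch.data"


def _data_path(name: str) -> Path:
    return Path(str(resources.files(_DATA_PACKAGE).joinpath(name)))


def table_checksum(name: str) -> str:
    """SHA-256 of a shipped data file (recorded in model archives)."""
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


@dataclass(frozen=True)
class PropertyTable:
    """Numeric properties for every unit (k-mer or residue) of an alphabet.

    ``values[u]`` is the raw property vector for unit ``u``;
    ``standardized[u]`` the mean-0 / variance-1 version used by encoders.
    """

    table_id: str
    unit_length: int
    property_names: tuple[str, ...]
    values: dict[str, np.ndarray]
    standardized: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self):
        units = sorted(self.values)
        mat = np.array([self.values[u] for u in units], dtype=float)
        mean = mat.mean(axis=0)
        std = mat.std(axis=0)
        if np.any(std == 0):
            raise ValueError(
                f"constant property column in table {self.table_id!r}"
            )
        z = (mat - mean) / std
        object.__setattr__(
            self, "standardized", {u: z[i] for i, u in enumerate(units)}
        )

    @property
    def n_properties(self) -> int:
        return len(self.property_names)

    def profile(self, seq: str, standard: bool = True) -> np.ndarray:
        """(n_units, n_properties) property matrix of overlapping units."""
        source = self.standardized if standard else self.values
        k = self.unit_length
        if len(seq) < k:
            raise ValueError(f"sequence shorter than unit length {k}")
        return np.array([source[seq[i : i + k]] for i in range(len(seq) - k + 1)])


def _parse_property_tsv(path: Path, table_id: str) -> PropertyTable:
    lines = path.read_text().splitlines()
    header_idx = 0
    if lines and lines[0].startswith("#"):
        header_idx = 1
    cols = lines[header_idx].split("\t")
    if cols[0] != "unit":
        raise ValueError(f"{path}: expected 'unit' as first column")
    names = tuple(cols[1:])
    values: dict[str, np.ndarray] = {}
    unit_len = None
    for line in lines[header_idx + 1 :]:
        if not line.strip():
            continue
        parts = line.split("\t")
        unit = parts[0]
        if unit_len is None:
            unit_len = len(unit)
        elif len(unit) != unit_len:
            raise ValueError(f"{path}: inconsistent unit length at {unit!r}")
        values[unit] = np.array([float(v) for v in parts[1:]], dtype=float)
    if not values:
        raise ValueError(f"{path}: no rows")
    return PropertyTable(table_id, unit_len, names, values)


def load_property_table(table_id: str, path: str | Path | None = None) -> PropertyTable:
    """Load a property table by id; ``path`` overrides the shipped file."""
    p = Path(path) if path is not None else _data_path(f"{table_id}.tsv")
    return _parse_property_tsv(p, table_id)


# Shipped table ids
RNA_DINUCLEOTIDE = "rna_dinucleotide"
RNA_TRINUCLEOTIDE = "rna_trinucleotide"
AMINO_ACID = "amino_acid"


def load_ctd_groups(path: str | Path | None = None) -> dict[str, tuple[str, str, str]]:
    """The 7-attribute, 3-group residue partitions for CTD descriptors."""
    p = Path(path) if path is not None else _data_path("ctd_groups.tsv")
    lines = [l for l in p.read_text().splitlines() if l.strip()]
    if lines[0].startswith("#"):
        lines = lines[1:]
    out: dict[str, tuple[str, str, str]] = {}
    for line in lines[1:]:
        name, g1, g2, g3 = line.split("\t")
        out[name] = (g1, g2, g3)
    return out


def load_triad_classes(path: str | Path | None = None) -> list[str]:
    """The 7 amino-acid classes used by protein conjoint-triad encoding."""
    p = Path(path) if path is not None else _data_path("triad_classes.tsv")
    lines = [l for l in p.read_text().splitlines() if l.strip()]
    if lines[0].startswith("#"):
        lines = lines[1:]
    return [line.split("\t")[1] for line in lines[1:]]
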