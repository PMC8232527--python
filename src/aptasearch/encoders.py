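"""Fixed-length feature encoders for RNA aptamer and protein sequences.

Machine-learning models need fixed-size inputs while aptamers and proteins
vary in length, so every encoder here maps a sequence to a vector whose
dimension depends only on the encoder's parameters, never on sequence
length. Nine aptamer families (dinucleotide/trinucleotide auto-, cross-
and combined covariance, pseudo k-tuple composition for k = 2 and 3, and a
conjoint-triad variant over the four bases) and six protein families
(amino-acid/dipeptide/tripeptide composition, pseudo amino-acid
composition, composition-transition-distribution, conjoint triad) are
provided, plus the pair encoder that concatenates one aptamer vector with
one protein vector for the interaction classifier.

All encoders are scikit-learn transformers: stateless, ``fit`` is a no-op
returning ``self``, and ``transform`` accepts an iterable of sequence
strings. Unit order within every vector is lexicographic over the
alphabet, so serialized models are portable.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import tables
from .sequences import PROTEIN_ALPHABET, RNA_ALPHABET, check_protein, check_rna
from .tables import PropertyTable, load_property_table

__all__ = [
    "SequenceEncoder",
    "KmerComposition",
    "AutoCovariance",
    "CrossCovariance",
    "AutoCrossCovariance",
    "PseKNC",
    "PseAAC",
    "ConjointTriad",
    "CTD",
    "PairEncoder",
    "kmer_frequencies",
    "auto_covariance",
    "cross_covariance",
    "pseknc",
    "pseaac",
    "conjoint_triad",
    "ctd",
    "encode_pair",
    "aptamer_encoder",
    "protein_encoder",
    "APTAMER_ENCODER_NAMES",
    "PROTEIN_ENCODER_NAMES",
    "default_grid",
    "encoder_from_spec",
]


def _alphabet_of(kind: str) -> str:
    if kind == "rna":
        return RNA_ALPHABET
    if kind == "protein":
        return PROTEIN_ALPHABET
    raise ValueError(f"unknown alphabet kind {kind!r}")


def _check(kind: str, seq: str) -> str:
    return check_rna(seq) if kind == "rna" else check_protein(seq)


class SequenceEncoder(TransformerMixin, BaseEstimator):
    """Base class: a pure, fixed-dimension map from sequence to vector."""

    alphabet: str = "rna"  # overridden per subclass instance

    @property
    def dimension(self) -> int:
        raise NotImplementedError

    @property
    def min_length(self) -> int:
        """Shortest admissible sequence length."""
        raise NotImplementedError

    def encode(self, seq: str) -> np.ndarray:
        raise NotImplementedError

    # sklearn plumbing -------------------------------------------------
    def fit(self, X: Iterable[str] | None = None, y=None):
        return self

    def transform(self, X: Iterable[str]) -> np.ndarray:
        return np.vstack([self.encode(s) for s in X])

    def get_feature_names_out(self, input_features=None):
        return np.array([f"{type(self).__name__}_{i}" for i in range(self.dimension)])

    # spec serialization ----------------------------------------------
    def to_spec(self) -> dict:
        spec = {"encoder": type(self).__name__}
        spec.update(self.get_params())
        return spec


def _validate_len(seq: str, min_length: int, what: str) -> None:
    if len(seq) < min_length:
        raise ValueError(
            f"sequence of length {len(seq)} too short for {what} "
            f"(minimum {min_length})"
        )


class KmerComposition(SequenceEncoder):
    """Relative frequencies of overlapping k-mers in lexicographic order.

    Covers amino-acid composition (k=1), dipeptide composition (k=2) and
    tripeptide composition (k=3) on proteins, and plain nucleotide k-mer
    composition on RNA. Entries are counts divided by L-k+1 and sum to 1.
    """

    def __init__(self, k: int = 1, alphabet: str = "protein"):
        self.k = k
        self.alphabet = alphabet

    @property
    def _letters(self) -> str:
        return _alphabet_of(self.alphabet)

    @property
    def dimension(self) -> int:
        return len(self._letters) ** self.k

    @property
    def min_length(self) -> int:
        return self.k

    def encode(self, seq: str) -> np.ndarray:
        if not 1 <= self.k <= 3:
            raise ValueError("k must be in {1, 2, 3}")
        seq = _check(self.alphabet, seq)
        _validate_len(seq, self.k, f"{self.k}-mer composition")
        letters = self._letters
        index = {c: i for i, c in enumerate(letters)}
        base = len(letters)
        counts = np.zeros(base**self.k)
        for i in range(len(seq) - self.k + 1):
            code = 0
            for ch in seq[i : i + self.k]:
                code = code * base + index[ch]
            counts[code] += 1
        return counts / (len(seq) - self.k + 1)


class _CovarianceBase(SequenceEncoder):
    alphabet = "rna"

    def __init__(self, unit_size: int = 2, max_lag: int = 2, table_path=None):
        self.unit_size = unit_size
        self.max_lag = max_lag
        self.table_path = table_path

    @property
    def table(self) -> PropertyTable:
        table_id = (
            tables.RNA_DINUCLEOTIDE if self.unit_size == 2 else tables.RNA_TRINUCLEOTIDE
        )
        return load_property_table(table_id, self.table_path)

    @property
    def min_length(self) -> int:
        return self.unit_size + self.max_lag + 1

    def _profile(self, seq: str) -> np.ndarray:
        if self.unit_size not in (2, 3):
            raise ValueError("unit_size must be 2 or 3")
        seq = check_rna(seq)
        _validate_len(seq, self.min_length, "covariance encoding")
        return self.table.profile(seq)


def _auto_cov(profile: np.ndarray, max_lag: int) -> np.ndarray:
    """Property-major, lag-minor auto-covariance of a property profile."""
    n, p = profile.shape
    centered = profile - profile.mean(axis=0)
    out = np.empty(p * max_lag)
    for j in range(p):
        for lag in range(1, max_lag + 1):
            out[j * max_lag + lag - 1] = (
                centered[: n - lag, j] @ centered[lag:, j]
            ) / (n - lag)
    return out


def _cross_cov(profile: np.ndarray, max_lag: int) -> np.ndarray:
    n, p = profile.shape
    centered = profile - profile.mean(axis=0)
    out = np.empty(p * (p - 1) * max_lag)
    idx = 0
    for j, m in itertools.permutations(range(p), 2):
        for lag in range(1, max_lag + 1):
            out[idx] = (centered[: n - lag, j] @ centered[lag:, m]) / (n - lag)
            idx += 1
    return out


class AutoCovariance(_CovarianceBase):
    """Lagged self-correlation of each physicochemical property signal.

    With unit_size 2 this is dinucleotide auto-covariance, with 3 the
    trinucleotide form; the property signal is the standardized table value
    of each overlapping unit along the sequence.
    """

    @property
    def dimension(self) -> int:
        return self.table.n_properties * self.max_lag

    def encode(self, seq: str) -> np.ndarray:
        return _auto_cov(self._profile(seq), self.max_lag)


class CrossCovariance(_CovarianceBase):
    """Lagged covariance between every ordered pair of distinct properties."""

    @property
    def dimension(self) -> int:
        p = self.table.n_properties
        return p * (p - 1) * self.max_lag

    def encode(self, seq: str) -> np.ndarray:
        if self.table.n_properties < 2:
            raise ValueError("cross-covariance needs at least two properties")
        return _cross_cov(self._profile(seq), self.max_lag)


class AutoCrossCovariance(_CovarianceBase):
    """Concatenation of the auto- and cross-covariance vectors."""

    @property
    def dimension(self) -> int:
        p = self.table.n_properties
        return p * self.max_lag + p * (p - 1) * self.max_lag

    def encode(self, seq: str) -> np.ndarray:
        profile = self._profile(seq)
        return np.concatenate(
            [_auto_cov(profile, self.max_lag), _cross_cov(profile, self.max_lag)]
        )


class PseKNC(SequenceEncoder):
    """Pseudo k-tuple nucleotide composition.

    The first 4**k entries are the k-mer frequencies and the last ``lam``
    entries are sequence-order correlation factors theta_j, both divided by
    ``1 + w * sum(theta)`` so the vector sums to 1. theta_j averages, over
    all unit pairs j apart, the mean squared difference between the
    standardized property vectors of the two units.
    """

    alphabet = "rna"

    def __init__(self, k: int = 2, lam: int = 2, w: float = 0.05, table_path=None):
        self.k = k
        self.lam = lam
        self.w = w
        self.table_path = table_path

    @property
    def table(self) -> PropertyTable:
        table_id = tables.RNA_DINUCLEOTIDE if self.k == 2 else tables.RNA_TRINUCLEOTIDE
        return load_property_table(table_id, self.table_path)

    @property
    def dimension(self) -> int:
        return 4**self.k + self.lam

    @property
    def min_length(self) -> int:
        return self.k + self.lam

    def encode(self, seq: str) -> np.ndarray:
        if self.k not in (2, 3):
            raise ValueError("PseKNC k must be 2 or 3")
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        seq = check_rna(seq)
        _validate_len(seq, self.min_length, f"PseKNC(k={self.k}, lambda={self.lam})")
        freqs = KmerComposition(k=self.k, alphabet="rna").encode(seq)
        profile = self.table.profile(seq)
        n_units = profile.shape[0]
        thetas = np.empty(self.lam)
        for j in range(1, self.lam + 1):
            diffs = profile[: n_units - j] - profile[j:]
            thetas[j - 1] = np.mean(np.mean(diffs**2, axis=1))
        denom = 1.0 + self.w * thetas.sum()
        return np.concatenate([freqs / denom, self.w * thetas / denom])


class PseAAC(SequenceEncoder):
    """Classic type-I pseudo amino-acid composition.

    Twenty weighted composition terms plus ``lam`` sequence-order
    correlation factors computed from standardized hydrophobicity,
    hydrophilicity and side-chain mass; the vector sums to 1.
    """

    alphabet = "protein"

    def __init__(self, lam: int = 10, w: float = 0.05, table_path=None):
        self.lam = lam
        self.w = w
        self.table_path = table_path

    @property
    def table(self) -> PropertyTable:
        return load_property_table(tables.AMINO_ACID, self.table_path)

    @property
    def dimension(self) -> int:
        return 20 + self.lam

    @property
    def min_length(self) -> int:
        return self.lam + 1

    def encode(self, seq: str) -> np.ndarray:
        if not 0 <= self.w <= 1:
            raise ValueError("w must lie in [0, 1]")
        seq = check_protein(seq)
        if len(seq) <= self.lam:
            raise ValueError(
                f"PseAAC lambda={self.lam} needs sequence length > {self.lam}, "
                f"got {len(seq)}"
            )
        freqs = KmerComposition(k=1, alphabet="protein").encode(seq)
        profile = self.table.profile(seq)
        thetas = np.empty(self.lam)
        n = len(seq)
        for j in range(1, self.lam + 1):
            diffs = profile[: n - j] - profile[j:]
            thetas[j - 1] = np.mean(np.mean(diffs**2, axis=1))
        denom = 1.0 + self.w * thetas.sum()
        return np.concatenate([freqs / denom, self.w * thetas / denom])


class ConjointTriad(SequenceEncoder):
    """Class-mapped triad counts with min-max normalization.

    Residues are first mapped to physicochemical classes (the canonical
    7-class partition for proteins; each base its own class for RNA), all
    overlapping class triads are counted, and counts are rescaled as
    (f - f_min) / f_max so entries lie in [0, 1].
    """

    def __init__(self, alphabet: str = "protein", classes_path=None):
        self.alphabet = alphabet
        self.classes_path = classes_path

    @property
    def _classes(self) -> list[str]:
        if self.alphabet == "rna":
            return list(RNA_ALPHABET)
        return tables.load_triad_classes(self.classes_path)

    @property
    def dimension(self) -> int:
        return len(self._classes) ** 3

    @property
    def min_length(self) -> int:
        return 3

    def encode(self, seq: str) -> np.ndarray:
        seq = _check(self.alphabet, seq)
        _validate_len(seq, 3, "conjoint triad")
        classes = self._classes
        cls = {}
        for i, group in enumerate(classes):
            for ch in group:
                cls[ch] = i
        n_cls = len(classes)
        counts = np.zeros(n_cls**3)
        for i in range(len(seq) - 2):
            a, b, c = (cls[seq[i]], cls[seq[i + 1]], cls[seq[i + 2]])
            counts[(a * n_cls + b) * n_cls + c] += 1
        return (counts - counts.min()) / counts.max()


# Canonical distribution percentiles of the CTD descriptor.
_CTD_FRACTIONS = (0.0, 0.25, 0.50, 0.75, 1.0)


class CTD(SequenceEncoder):
    """Composition-transition-distribution protein descriptor (147-dim).

    For each of 7 physicochemical attributes the 20 residues fall into 3
    groups; the descriptor records per attribute the 3 group fractions
    (composition), the 3 cross-group adjacent-pair frequencies
    (transition), and for each group the sequence positions of its first,
    25%, 50%, 75% and last occurrence as fractions of the length
    (distribution; zeros for absent groups).
    """

    alphabet = "protein"

    def __init__(self, groups_path=None):
        self.groups_path = groups_path

    @property
    def _groups(self) -> dict[str, tuple[str, str, str]]:
        return tables.load_ctd_groups(self.groups_path)

    @property
    def dimension(self) -> int:
        return 21 * len(self._groups)

    @property
    def min_length(self) -> int:
        return 2

    def encode(self, seq: str) -> np.ndarray:
        seq = check_protein(seq)
        _validate_len(seq, 2, "CTD")
        n = len(seq)
        blocks = []
        for groups in self._groups.values():
            gidx = {}
            for g, members in enumerate(groups):
                for ch in members:
                    gidx[ch] = g
            labels = [gidx[ch] for ch in seq]
            comp = np.bincount(labels, minlength=3) / n
            trans = np.zeros(3)
            for a, b in zip(labels, labels[1:]):
                if a != b:
                    # pair order (0,1) -> slot 0, (0,2) -> 1, (1,2) -> 2
                    trans[a + b - 1] += 1
            trans /= n - 1
            dist = np.zeros(15)
            for g in range(3):
                positions = [i + 1 for i, lab in enumerate(labels) if lab == g]
                if not positions:
                    continue
                m = len(positions)
                for fi, frac in enumerate(_CTD_FRACTIONS):
                    rank = max(1, int(np.ceil(frac * m)))
                    dist[g * 5 + fi] = positions[rank - 1] / n
            blocks.append(np.concatenate([comp, trans, dist]))
        return np.concatenate(blocks)


class PairEncoder(TransformerMixin, BaseEstimator):
    """Concatenate an aptamer encoding with a protein encoding.

    ``transform`` takes an iterable of ``(aptamer, protein)`` string pairs;
    this is the feature map the interaction classifier trains on.
    """

    def __init__(self, aptamer_encoder: SequenceEncoder, protein_encoder: SequenceEncoder):
        self.aptamer_encoder = aptamer_encoder
        self.protein_encoder = protein_encoder

    @property
    def dimension(self) -> int:
        return self.aptamer_encoder.dimension + self.protein_encoder.dimension

    def encode(self, aptamer: str, protein: str) -> np.ndarray:
        return np.concatenate(
            [self.aptamer_encoder.encode(aptamer), self.protein_encoder.encode(protein)]
        )

    def fit(self, X=None, y=None):
        return self

    def transform(self, X: Iterable[tuple[str, str]]) -> np.ndarray:
        return np.vstack([self.encode(a, p) for a, p in X])


# ---------------------------------------------------------------------------
# Functional wrappers (one per operation) and the named-encoder registry.
# ---------------------------------------------------------------------------

def kmer_frequencies(seq: str, k: int, alphabet: str = "rna") -> np.ndarray:
    return KmerComposition(k=k, alphabet=alphabet).encode(seq)


def auto_covariance(seq: str, unit_size: int = 2, max_lag: int = 2, table_path=None) -> np.ndarray:
    return AutoCovariance(unit_size=unit_size, max_lag=max_lag, table_path=table_path).encode(seq)


def cross_covariance(seq: str, unit_size: int = 2, max_lag: int = 2, table_path=None) -> np.ndarray:
    return CrossCovariance(unit_size=unit_size, max_lag=max_lag, table_path=table_path).encode(seq)


def pseknc(seq: str, k: int = 2, lam: int = 2, w: float = 0.05, table_path=None) -> np.ndarray:
    return PseKNC(k=k, lam=lam, w=w, table_path=table_path).encode(seq)


def pseaac(seq: str, lam: int = 10, w: float = 0.05, table_path=None) -> np.ndarray:
    return PseAAC(lam=lam, w=w, table_path=table_path).encode(seq)


def conjoint_triad(seq: str, alphabet: str = "protein") -> np.ndarray:
    return ConjointTriad(alphabet=alphabet).encode(seq)


def ctd(seq: str) -> np.ndarray:
    return CTD().encode(seq)


def encode_pair(aptamer: str, protein: str, apt_encoder: SequenceEncoder, prot_encoder: SequenceEncoder) -> np.ndarray:
    return PairEncoder(apt_encoder, prot_encoder).encode(aptamer, protein)


_APTAMER_FACTORIES = {
    "DAC": lambda **kw: AutoCovariance(unit_size=2, **kw),
    "DCC": lambda **kw: CrossCovariance(unit_size=2, **kw),
    "DACC": lambda **kw: AutoCrossCovariance(unit_size=2, **kw),
    "TAC": lambda **kw: AutoCovariance(unit_size=3, **kw),
    "TCC": lambda **kw: CrossCovariance(unit_size=3, **kw),
    "TACC": lambda **kw: AutoCrossCovariance(unit_size=3, **kw),
    "PseKNC-2": lambda **kw: PseKNC(k=2, **kw),
    "PseKNC-3": lambda **kw: PseKNC(k=3, **kw),
    "iCTF": lambda **kw: ConjointTriad(alphabet="rna", **kw),
}

_PROTEIN_FACTORIES = {
    "AAC": lambda **kw: KmerComposition(k=1, alphabet="protein", **kw),
    "DPC": lambda **kw: KmerComposition(k=2, alphabet="protein", **kw),
    "TPC": lambda **kw: KmerComposition(k=3, alphabet="protein", **kw),
    "PseAAC": lambda **kw: PseAAC(**kw),
    "CTD": lambda **kw: CTD(**kw),
    "iCTF": lambda **kw: ConjointTriad(alphabet="protein", **kw),
}

APTAMER_ENCODER_NAMES: tuple[str, ...] = tuple(_APTAMER_FACTORIES)
PROTEIN_ENCODER_NAMES: tuple[str, ...] = tuple(_PROTEIN_FACTORIES)


def aptamer_encoder(name: str, **overrides) -> SequenceEncoder:
    """Instantiate one of the 9 named aptamer encoders."""
    try:
        return _APTAMER_FACTORIES[name](**overrides)
    except KeyError:
        raise ValueError(
            f"unknown aptamer encoder {name!r}; choose from {APTAMER_ENCODER_NAMES}"
        ) from None


def protein_encoder(name: str, **overrides) -> SequenceEncoder:
    """Instantiate one of the 6 named protein encoders."""
    try:
        return _PROTEIN_FACTORIES[name](**overrides)
    except KeyError:
        raise ValueError(
            f"unknown protein encoder {name!r}; choose from {PROTEIN_ENCODER_NAMES}"
        ) from None


def default_grid() -> list[tuple[str, str]]:
    """All aptamer-by-protein encoder name combinations (9 x 6 = 54)."""
    return [
        (a, p)
        for a in APTAMER_ENCODER_NAMES
        for p in PROTEIN_ENCODER_NAMES
    ]


_CLASSES = {
    cls.__name__: cls
    for cls in (
        KmerComposition,
        AutoCovariance,
        CrossCovariance,
        AutoCrossCovariance,
        PseKNC,
        PseAAC,
        ConjointTriad,
        CTD,
    )
}


def encoder_from_spec(spec: dict) -> SequenceEncoder:
    """Rebuild an encoder from the flat dict produced by ``to_spec``."""
    spec = dict(spec)
    cls_name = spec.pop("encoder")
    try:
        cls = _CLASSES[cls_name]
    except KeyError:
        raise ValueError(f"unknown encoder class {cls_name!r}") from None
    return cls(**spec)
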