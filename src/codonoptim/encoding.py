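"""Residue feature encodings and codon class labels.

Two per-residue encodings feed the recurrent classifier: a 26-symbol
one-hot (20 standard amino acids, selenocysteine U, pyrrolysine O,
ambiguity codes B/Z/X, and the stop symbol; Alanine occupies feature 0) and
an 18-dimensional real-valued physicochemical descriptor ("NLF"-style).

The 18-feature table here is a synthetic stand-in constructed in-code: six
published residue scales (Kyte-Doolittle hydropathy, molecular weight,
residue volume, Grantham polarity, isoelectric point, net charge at pH 7)
are z-scored and expanded with square and tanh nonlinearities. It is an
encoding choice, not learned, and is deterministic.

Supervision targets are codon class indices over the full 64-codon
lexicographic label space; constrained decoding masks non-synonymous
classes downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from codonoptim.errors import AlphabetError, InvalidCDSError
from codonoptim.genetic_code import (
    CODON_INDEX,
    CODONS,
    STANDARD_CODE,
    GeneticCode,
    split_codons,
    strip_terminal_stop,
    validate_cds,
)

#: Alanine first (feature 0); the rest of the 26 symbols alphabetical with
#: the stop symbol last.
DEFAULT_ALPHABET = "ABCDEFGHIKLMNOPQRSTUVWXYZ*"


@dataclass(frozen=True)
class AlphabetSpec:
    """Ordered residue alphabet defining one-hot feature positions."""

    symbols: str = DEFAULT_ALPHABET
    index: Mapping[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        object.__setattr__(
            self, "index", {s: i for i, s in enumerate(self.symbols)}
        )

    def __len__(self) -> int:
        return len(self.symbols)


DEFAULT_ALPHABET_SPEC = AlphabetSpec()

# Six residue scales (order: hydropathy, MW, volume, polarity, pI, charge).
_SCALES = {
    #      KD     MW     vol    pol    pI    q
    "A": (1.8,  89.1,  88.6,  8.1, 6.00,  0.0),
    "R": (-4.5, 174.2, 173.4, 10.5, 10.76, 1.0),
    "N": (-3.5, 132.1, 114.1, 11.6, 5.41,  0.0),
    "D": (-3.5, 133.1, 111.1, 13.0, 2.77, -1.0),
    "C": (2.5, 121.2, 108.5,  5.5, 5.07,  0.0),
    "Q": (-3.5, 146.2, 143.8, 10.5, 5.65,  0.0),
    "E": (-3.5, 147.1, 138.4, 12.3, 3.22, -1.0),
    "G": (-0.4,  75.1,  60.1,  9.0, 5.97,  0.0),
    "H": (-3.2, 155.2, 153.2, 10.4, 7.59,  0.1),
    "I": (4.5, 131.2, 166.7,  5.2, 6.02,  0.0),
    "L": (3.8, 131.2, 166.7,  4.9, 5.98,  0.0),
    "K": (-3.9, 146.2, 168.6, 11.3, 9.74,  1.0),
    "M": (1.9, 149.2, 162.9,  5.7, 5.74,  0.0),
    "F": (2.8, 165.2, 189.9,  5.2, 5.48,  0.0),
    "P": (-1.6, 115.1, 112.7,  8.0, 6.30,  0.0),
    "S": (-0.8, 105.1,  89.0,  9.2, 5.68,  0.0),
    "T": (-0.7, 119.1, 116.1,  8.6, 5.60,  0.0),
    "W": (-0.9, 204.2, 227.8,  5.4, 5.89,  0.0),
    "Y": (-1.3, 181.2, 193.6,  6.2, 5.66,  0.0),
    "V": (4.2, 117.1, 140.0,  5.9, 5.96,  0.0),
}


def _build_nlf_table() -> dict[str, np.ndarray]:
    aas = sorted(_SCALES)
    raw = np.array([_SCALES[a] for a in aas], dtype=float)
    z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    feats = np.concatenate([z, z**2, np.tanh(z)], axis=1)  # 18 columns
    return {a: feats[i].copy() for i, a in enumerate(aas)}


NLF_TABLE: dict[str, np.ndarray] = _build_nlf_table()
NLF_DIM = 18


def one_hot_encode(
    aa_seq: str, alphabet: AlphabetSpec = DEFAULT_ALPHABET_SPEC
) -> np.ndarray:
    """Encode a protein as a T x 26 one-hot matrix."""
    aa_seq = aa_seq.upper()
    mat = np.zeros((len(aa_seq), len(alphabet)), dtype=np.float64)
    for t, aa in enumerate(aa_seq):
        if aa not in alphabet.index:
            raise AlphabetError(
                f"unknown symbol {aa!r} at position {t + 1}"
            )
        mat[t, alphabet.index[aa]] = 1.0
    return mat


def nlft_encode(aa_seq: str) -> np.ndarray:
    """Encode a protein as a T x 18 physicochemical descriptor matrix.

    Standard amino acids only: the descriptor table covers the 20 canonical
    residues.
    """
    aa_seq = aa_seq.upper()
    rows = []
    for t, aa in enumerate(aa_seq):
        if aa not in NLF_TABLE:
            raise AlphabetError(f"unknown symbol {aa!r} at position {t + 1}")
        rows.append(NLF_TABLE[aa])
    if not rows:
        return np.zeros((0, NLF_DIM))
    return np.stack(rows)


def encode(aa_seq: str, encoding: str = "onehot",
           alphabet: AlphabetSpec = DEFAULT_ALPHABET_SPEC) -> np.ndarray:
    """Dispatch on encoding name: ``onehot`` (T x 26) or ``nlft`` (T x 18)."""
    if encoding == "onehot":
        return one_hot_encode(aa_seq, alphabet)
    if encoding == "nlft":
        return nlft_encode(aa_seq)
    raise ValueError(f"unknown encoding {encoding!r}")


def codon_labels(nt_seq: str, code: GeneticCode = STANDARD_CODE) -> np.ndarray:
    """Map a CDS to per-position codon class indices in [0, 63].

    Indices follow the fixed lexicographic codon order (AAA=0 ... TTT=63); a
    terminal stop codon is dropped so labels align with the protein.
    """
    report = validate_cds(nt_seq, code)
    if not report.is_clean:
        raise InvalidCDSError("input is not a valid CDS")
    seq = strip_terminal_stop(nt_seq, code)
    return np.array([CODON_INDEX[c] for c in split_codons(seq)], dtype=np.int64)


def decode_labels(labels: np.ndarray) -> str:
    """Inverse of :func:`codon_labels`: restore the CDS from class indices."""
    return "".join(CODONS[int(i)] for i in labels)


@dataclass(frozen=True)
class EncodedGene:
    """Per-position feature matrix (T x 26 or T x 18) with optional codon
    class labels (length T, values in [0, 63])."""

    features: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.labels is not None and len(self.labels) != len(self.features):
            raise InvalidCDSError(
                f"feature length {len(self.features)} != label length "
                f"{len(self.labels)}"
            )

    def __len__(self) -> int:
        return len(self.features)


def encode_gene(record, encoding: str = "onehot",
                alphabet: AlphabetSpec = DEFAULT_ALPHABET_SPEC,
                code: GeneticCode = STANDARD_CODE) -> EncodedGene:
    """Encode a :class:`~codonoptim.seqio.GeneRecord` for training.

    Labels are attached when the record carries a CDS.
    """
    aa = record.protein(code)
    feats = encode(aa, encoding, alphabet)
    labels = codon_labels(record.nt_seq, code) if record.nt_seq else None
    return EncodedGene(features=feats, labels=labels)
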