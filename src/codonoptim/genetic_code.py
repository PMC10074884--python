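"""Genetic-code tables, translation, synonymous-codon lookup and CDS validation.

The standard genetic code (NCBI translation table 1) is the sole built-in,
but :class:`GeneticCode` is data-driven so alternate tables can be
constructed. Codons are uppercase DNA (``T`` not ``U``) everywhere; inputs
are normalized on entry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

from codonoptim.errors import AlphabetError, InvalidCDSError

STOP_SYMBOL = "*"

#: All 64 codons in lexicographic order; the fixed label space of the classifier.
CODONS: tuple[str, ...] = tuple("".join(c) for c in product("ACGT", repeat=3))

#: codon -> index in [0, 63] under lexicographic ordering (AAA=0 ... TTT=63).
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

# NCBI translation table 1, written out by amino acid.
_TABLE1 = {
    "A": ("GCA", "GCC", "GCG", "GCT"),
    "C": ("TGC", "TGT"),
    "D": ("GAC", "GAT"),
    "E": ("GAA", "GAG"),
    "F": ("TTC", "TTT"),
    "G": ("GGA", "GGC", "GGG", "GGT"),
    "H": ("CAC", "CAT"),
    "I": ("ATA", "ATC", "ATT"),
    "K": ("AAA", "AAG"),
    "L": ("CTA", "CTC", "CTG", "CTT", "TTA", "TTG"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCA", "CCC", "CCG", "CCT"),
    "Q": ("CAA", "CAG"),
    "R": ("AGA", "AGG", "CGA", "CGC", "CGG", "CGT"),
    "S": ("AGC", "AGT", "TCA", "TCC", "TCG", "TCT"),
    "T": ("ACA", "ACC", "ACG", "ACT"),
    "V": ("GTA", "GTC", "GTG", "GTT"),
    "W": ("TGG",),
    "Y": ("TAC", "TAT"),
    STOP_SYMBOL: ("TAA", "TAG", "TGA"),
}


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and map RNA ``U`` to DNA ``T``."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class GeneticCode:
    """A codon <-> amino-acid mapping.

    ``aa_to_codons`` is the exact inverse partition of ``codon_to_aa``
    restricted to sense codons; families are kept in lexicographic order.
    """

    codon_to_aa: Mapping[str, str]
    aa_to_codons: Mapping[str, tuple[str, ...]] = field(init=False)
    stop_codons: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64 or set(self.codon_to_aa) != set(CODONS):
            raise ValueError("a genetic code must map exactly the 64 codons")
        fam: dict[str, list[str]] = {}
        stops: list[str] = []
        for codon in CODONS:  # lexicographic family order
            aa = self.codon_to_aa[codon]
            if aa == STOP_SYMBOL:
                stops.append(codon)
            else:
                fam.setdefault(aa, []).append(codon)
        object.__setattr__(
            self, "aa_to_codons", {aa: tuple(cs) for aa, cs in fam.items()}
        )
        object.__setattr__(self, "stop_codons", tuple(stops))

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.codon_to_aa[c] != STOP_SYMBOL)

    def translate(self, nt_seq: str) -> str:
        """Translate a CDS into an amino-acid string (stops render as ``*``)."""
        seq = normalize_nt(nt_seq)
        if len(seq) % 3 != 0:
            raise InvalidCDSError(
                f"sequence length {len(seq)} is not divisible by 3"
            )
        bad = set(seq) - set("ACGT")
        if bad:
            raise AlphabetError(f"non-ACGT characters in CDS: {sorted(bad)}")
        return "".join(
            self.codon_to_aa[seq[i : i + 3]] for i in range(0, len(seq), 3)
        )

    def synonymous_codons(self, aa: str) -> tuple[str, ...]:
        """The full synonymous family of ``aa``, in lexicographic order."""
        aa = aa.upper()
        if aa == STOP_SYMBOL:
            return self.stop_codons
        if aa not in self.aa_to_codons:
            raise AlphabetError(f"unknown amino-acid symbol {aa!r}")
        return self.aa_to_codons[aa]

    def family_size(self, aa: str) -> int:
        return len(self.synonymous_codons(aa))


#: The standard genetic code (NCBI table 1).
STANDARD_CODE = GeneticCode(
    codon_to_aa={c: aa for aa, cs in _TABLE1.items() for c in cs}
)


def translate(nt_seq: str, code: GeneticCode = STANDARD_CODE) -> str:
    return code.translate(nt_seq)


def synonymous_codons(aa: str, code: GeneticCode = STANDARD_CODE) -> tuple[str, ...]:
    return code.synonymous_codons(aa)


@dataclass
class CDSValidationReport:
    """Outcome of :func:`validate_cds`; empty flag lists mean a clean CDS."""

    bad_length: bool = False
    bad_alphabet_positions: list[int] = field(default_factory=list)
    internal_stop_codons: list[int] = field(default_factory=list)

    @property
    def bad_alphabet(self) -> bool:
        return bool(self.bad_alphabet_positions)

    @property
    def internal_stop(self) -> bool:
        return bool(self.internal_stop_codons)

    @property
    def is_clean(self) -> bool:
        return not (self.bad_length or self.bad_alphabet or self.internal_stop)


def validate_cds(nt_seq: str, code: GeneticCode = STANDARD_CODE) -> CDSValidationReport:
    """Report every CDS rule violated by ``nt_seq``.

    A terminal stop codon is allowed; internal stops are flagged with their
    1-based codon positions. This never raises — it is a reporting operation.
    """
    seq = normalize_nt(nt_seq)
    report = CDSValidationReport()
    if len(seq) % 3 != 0:
        report.bad_length = True
    report.bad_alphabet_positions = [
        i + 1 for i, ch in enumerate(seq) if ch not in "ACGT"
    ]
    if not report.bad_length and not report.bad_alphabet_positions:
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            if code.codon_to_aa[codon] == STOP_SYMBOL and i < n_codons - 1:
                report.internal_stop_codons.append(i + 1)
    return report


def split_codons(nt_seq: str) -> list[str]:
    """Split a normalized CDS into its codons (no validation beyond length)."""
    seq = normalize_nt(nt_seq)
    if len(seq) % 3 != 0:
        raise InvalidCDSError(f"sequence length {len(seq)} is not divisible by 3")
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def strip_terminal_stop(nt_seq: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Drop a trailing stop codon if present."""
    seq = normalize_nt(nt_seq)
    if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in code.stop_codons:
        return seq[:-3]
    return seq
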