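"""Sequence and codon-usage I/O: the boundary where external data enters.

FASTA parsing/writing is delegated to Biopython; codon-usage tables use a
simple two-column text dialect (``codon value``), with values auto-detected
as raw counts or per-thousand frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from codonoptim.errors import (
    AlphabetError,
    DataError,
    InvalidCDSError,
    ParseError,
)
from codonoptim.genetic_code import (
    CODONS,
    STANDARD_CODE,
    GeneticCode,
    normalize_nt,
    split_codons,
    strip_terminal_stop,
    validate_cds,
)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBZXUO*")


@dataclass
class GeneRecord:
    """One sequence entry: identifier plus nucleotide CDS and/or protein."""

    id: str
    description: str = ""
    nt_seq: str | None = None
    aa_seq: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise DataError("GeneRecord id must be non-empty")
        if self.nt_seq is not None:
            self.nt_seq = normalize_nt(self.nt_seq)
        if self.aa_seq is not None:
            self.aa_seq = self.aa_seq.upper()

    def protein(self, code: GeneticCode = STANDARD_CODE) -> str:
        """The protein sequence, derived from the CDS when not stored."""
        if self.aa_seq is not None:
            return self.aa_seq
        if self.nt_seq is None:
            raise DataError(f"record {self.id!r} carries no sequence")
        return code.translate(strip_terminal_stop(self.nt_seq, code))


@dataclass
class CodonUsageTable:
    """Per-codon counts, genome-wide frequencies and within-family fractions.

    ``freq`` sums to 1 over the 61 sense codons; ``family_fraction`` sums to
    1 within each synonymous family. Stop codons carry no usage mass.
    """

    counts: dict[str, float]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)
    freq: dict[str, float] = field(init=False)
    family_fraction: dict[str, float] = field(init=False)
    undefined: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        sense = self.code.sense_codons
        counts = {c: float(self.counts.get(c, 0.0)) for c in sense}
        for c, v in counts.items():
            if v < 0:
                raise DataError(f"negative usage count for codon {c}")
        self.counts = counts
        total = sum(counts.values())
        if total <= 0:
            self.undefined = True
            self.freq = {c: 0.0 for c in sense}
            self.family_fraction = {c: 0.0 for c in sense}
            return
        self.freq = {c: v / total for c, v in counts.items()}
        self.family_fraction = {}
        for aa, family in self.code.aa_to_codons.items():
            fam_total = sum(counts[c] for c in family)
            for c in family:
                self.family_fraction[c] = (
                    counts[c] / fam_total if fam_total > 0 else 0.0
                )

    def family_mass(self, aa: str) -> float:
        return sum(self.counts[c] for c in self.code.synonymous_codons(aa))


def _validate_record_alphabet(name: str, seq: str, alphabet: str) -> None:
    if alphabet == "dna":
        bad = set(seq) - set("ACGT")
        if bad:
            raise AlphabetError(
                f"record {name!r}: non-ACGT characters {sorted(bad)}"
            )
    elif alphabet == "protein":
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise AlphabetError(
                f"record {name!r}: invalid amino-acid symbols {sorted(bad)}"
            )
    else:
        raise ValueError(f"alphabet must be 'dna' or 'protein', got {alphabet!r}")


def read_fasta(path: str | Path, alphabet: str = "dna") -> list[GeneRecord]:
    """Read a FASTA file into :class:`GeneRecord` objects, order preserved.

    DNA records are normalized (uppercase, U->T); each record is validated
    against the requested alphabet.
    """
    path = Path(path)
    records: list[GeneRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not rec.id:
            raise ParseError(f"{path}: record with empty identifier")
        if not seq:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if alphabet == "dna":
            seq = normalize_nt(seq)
        else:
            seq = seq.upper()
        _validate_record_alphabet(rec.id, seq, alphabet)
        records.append(
            GeneRecord(
                id=rec.id,
                description=rec.description,
                nt_seq=seq if alphabet == "dna" else None,
                aa_seq=seq if alphabet == "protein" else None,
            )
        )
    return records


def write_fasta(
    records: Iterable[GeneRecord],
    path: str | Path,
    line_width: int = 60,
    prefer: str = "auto",
) -> None:
    """Write records to FASTA, wrapping sequence lines at ``line_width``.

    ``prefer`` selects which sequence to emit when a record carries both:
    ``"nt"``, ``"aa"``, or ``"auto"`` (nucleotide wins when present).
    """
    path = Path(path)
    out: list[SeqRecord] = []
    for rec in records:
        if prefer == "aa" or (prefer == "auto" and rec.nt_seq is None):
            seq = rec.aa_seq
        else:
            seq = rec.nt_seq if rec.nt_seq is not None else rec.aa_seq
        if seq is None:
            raise DataError(f"record {rec.id!r} carries no sequence to write")
        out.append(SeqRecord(Seq(seq), id=rec.id, description=rec.description))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=line_width)
        writer.write_file(out)


def usage_from_sequences(
    records: Sequence[GeneRecord], code: GeneticCode = STANDARD_CODE
) -> CodonUsageTable:
    """Tally codon usage over a collection of CDS records.

    Stop codons are excluded from the counts: downstream metrics (CAI, CFD)
    are defined over sense codons only.
    """
    counts = {c: 0.0 for c in code.sense_codons}
    for rec in records:
        if rec.nt_seq is None:
            raise InvalidCDSError(f"record {rec.id!r} has no nucleotide sequence")
        report = validate_cds(rec.nt_seq, code)
        if not report.is_clean:
            raise InvalidCDSError(f"record {rec.id!r} is not a valid CDS")
        for codon in split_codons(rec.nt_seq):
            if codon not in code.stop_codons:
                counts[codon] += 1
    return CodonUsageTable(counts=counts, code=code)


def read_usage_table(
    path: str | Path, code: GeneticCode = STANDARD_CODE
) -> CodonUsageTable:
    """Read a two-column ``codon value`` usage table.

    Values whose total is ~1000 are interpreted as per-thousand frequencies,
    otherwise as raw counts; either way all 61 sense codons are present after
    loading (missing codons get zero).
    """
    path = Path(path)
    values: dict[str, float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 'codon value'")
            codon = normalize_nt(parts[0])
            if codon not in CODONS:
                raise ParseError(f"{path}:{lineno}: {parts[0]!r} is not a codon")
            if codon in values:
                raise ParseError(f"{path}:{lineno}: duplicate codon {codon}")
            try:
                values[codon] = float(parts[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: {parts[1]!r} is not a number"
                ) from exc
    total = sum(v for c, v in values.items() if c not in code.stop_codons)
    # per-thousand tables sum to ~1000 over sense codons
    if math.isclose(total, 1000.0, rel_tol=0.12):
        values = {c: v for c, v in values.items()}
    return CodonUsageTable(
        counts={c: v for c, v in values.items() if c not in code.stop_codons},
        code=code,
    )


def write_usage_table(table: CodonUsageTable, path: str | Path) -> None:
    """Write a usage table in the two-column dialect (counts as stored)."""
    with open(path, "w") as fh:
        for codon in table.code.sense_codons:
            fh.write(f"{codon} {table.counts[codon]:g}\n")


def default_usage_table() -> CodonUsageTable:
    """The bundled representative E. coli K-12 usage table."""
    ref = resources.files("codonoptim.data").joinpath("ecoli_k12_usage.txt")
    with resources.as_file(ref) as p:
        return read_usage_table(p)
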