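"""Evaluation suite for optimized coding sequences.

Implements the Codon Adaptation Index (Sharp & Li convention: geometric mean
of relative adaptiveness over sense codons, single-codon families and stops
excluded), GC-content, the codon frequency distribution (fraction of codons
with relative adaptiveness below a rarity threshold), repeat-element and
cis-regulatory-motif counters, mutational rate under back-translation, and a
report builder comparing optimization methods.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from codonoptim.errors import (
    DataError,
    DegenerateUsageError,
    UndefinedMetricError,
)
from codonoptim.genetic_code import (
    STANDARD_CODE,
    STOP_SYMBOL,
    GeneticCode,
    normalize_nt,
    split_codons,
    strip_terminal_stop,
)
from codonoptim.seqio import CodonUsageTable, GeneRecord

#: Floor applied to the relative adaptiveness of codons never observed in the
#: host, so the geometric mean stays defined.
W_FLOOR = 1e-4

#: Default motifs counted as negative cis-regulatory elements: internal
#: Shine-Dalgarno sites, the sigma-70 -10 box, the chi recombination site and
#: long homopolymer runs. IUPAC degenerate symbols are accepted.
DEFAULT_CIS_MOTIFS: tuple[str, ...] = (
    "AGGAGG",  # strong internal Shine-Dalgarno
    "GGAGG",  # minimal Shine-Dalgarno core
    "TATAAT",  # sigma-70 -10 promoter box
    "GCTGGTGG",  # chi site
    "AAAAAAAA",  # homopolymer A >= 8
    "TTTTTTTT",  # homopolymer T >= 8
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class AdaptivenessWeights:
    """Relative adaptiveness w per sense codon: family fraction over the
    family's maximal fraction, floored at :data:`W_FLOOR` for unseen codons."""

    w: Mapping[str, float]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)


def relative_adaptiveness(usage: CodonUsageTable) -> AdaptivenessWeights:
    """Compute w(c) = family_fraction(c) / max family_fraction in c's family."""
    code = usage.code
    w: dict[str, float] = {}
    for aa, family in code.aa_to_codons.items():
        fracs = [usage.family_fraction[c] for c in family]
        best = max(fracs)
        if best <= 0:
            raise DegenerateUsageError(
                f"synonymous family of {aa!r} has zero total usage"
            )
        for c, f in zip(family, fracs):
            w[c] = max(f / best, W_FLOOR)
    return AdaptivenessWeights(w=w, code=code)


def _scorable_codons(nt_seq: str, code: GeneticCode) -> list[str]:
    """Sense codons of a CDS excluding single-codon families and stops."""
    seq = strip_terminal_stop(normalize_nt(nt_seq), code)
    out = []
    for codon in split_codons(seq):
        aa = code.codon_to_aa[codon]
        if aa == STOP_SYMBOL:
            continue
        if len(code.aa_to_codons[aa]) == 1:
            continue
        out.append(codon)
    return out


def cai(nt_seq: str, weights: AdaptivenessWeights) -> float:
    """Codon Adaptation Index: geometric mean of w over scorable codons.

    Codons from single-codon families (ATG, TGG) and stop codons carry no
    information about synonymous choice and are excluded.
    """
    codons = _scorable_codons(nt_seq, weights.code)
    if not codons:
        raise UndefinedMetricError("no scorable codons for CAI")
    log_sum = sum(math.log(weights.w[c]) for c in codons)
    return math.exp(log_sum / len(codons))


def gc_content(nt_seq: str) -> float:
    """GC-content as a percentage of sequence length."""
    seq = normalize_nt(nt_seq)
    if not seq:
        raise UndefinedMetricError("GC-content undefined for empty sequence")
    gc = sum(1 for ch in seq if ch in "GC")
    return 100.0 * gc / len(seq)


def sliding_gc(nt_seq: str, window: int = 60, step: int = 3) -> np.ndarray:
    """GC% over sliding windows; flags local peaks the global value hides."""
    seq = normalize_nt(nt_seq)
    if len(seq) < window:
        return np.array([gc_content(seq)]) if seq else np.array([])
    is_gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = ((is_gc == ord("G")) | (is_gc == ord("C"))).astype(float)
    csum = np.concatenate([[0.0], np.cumsum(is_gc)])
    starts = np.arange(0, len(seq) - window + 1, step)
    return 100.0 * (csum[starts + window] - csum[starts]) / window


def cfd(nt_seq: str, weights: AdaptivenessWeights, threshold: float = 0.30) -> float:
    """Codon frequency distribution: percent of sense codons with w strictly
    below ``threshold`` (rare codons in the host)."""
    code = weights.code
    seq = strip_terminal_stop(normalize_nt(nt_seq), code)
    sense = [
        c for c in split_codons(seq) if code.codon_to_aa[c] != STOP_SYMBOL
    ]
    if not sense:
        raise UndefinedMetricError("no sense codons for CFD")
    rare = sum(1 for c in sense if weights.w[c] < threshold)
    return 100.0 * rare / len(sense)


def negative_repeats(nt_seq: str, min_len: int = 10) -> int:
    """Count distinct maximal repeated substrings of length >= ``min_len``.

    A substring counts when it occurs at least twice on the direct strand
    (occurrences may overlap) and cannot be extended: it is not itself a
    substring of a longer repeated substring.
    """
    seq = normalize_nt(nt_seq)
    n = len(seq)
    if n < min_len:
        return 0
    repeated: set[str] = set()
    # collect all repeated substrings of length >= min_len, longest first
    by_len: dict[int, set[str]] = {}
    for length in range(min_len, n):
        seen: dict[str, int] = {}
        reps: set[str] = set()
        for i in range(n - length + 1):
            s = seq[i : i + length]
            if s in seen:
                reps.add(s)
            else:
                seen[s] = i
        if not reps:
            break
        by_len[length] = reps
    maximal: set[str] = set()
    longer: set[str] = set()
    for length in sorted(by_len, reverse=True):
        for s in by_len[length]:
            if not any(s in t for t in longer):
                maximal.add(s)
        longer |= by_len[length]
    return len(maximal)


def _compile_motif(motif: str) -> str:
    motif = normalize_nt(motif)
    for ch in motif:
        if ch not in _IUPAC:
            raise DataError(f"invalid IUPAC symbol {ch!r} in motif {motif!r}")
    return motif


def _count_occurrences(seq: str, motif: str) -> int:
    m = len(motif)
    count = 0
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in _IUPAC[motif[j]] for j in range(m)):
            count += 1
    return count


def negative_cis_elements(
    nt_seq: str, motifs: Iterable[str] = DEFAULT_CIS_MOTIFS
) -> int:
    """Total motif matches on the forward and reverse-complement strands.

    Overlapping matches all count. Motifs may use IUPAC degenerate symbols.
    """
    seq = normalize_nt(nt_seq)
    rc = seq.translate(_COMPLEMENT)[::-1]
    total = 0
    for motif in motifs:
        m = _compile_motif(motif)
        total += _count_occurrences(seq, m) + _count_occurrences(rc, m)
    return total


def mutational_rate(
    reference_aa: str, optimized_nt: str, code: GeneticCode = STANDARD_CODE
) -> float:
    """Percent of amino-acid positions altered by an optimizer.

    Back-translates ``optimized_nt`` and counts mismatches against the input
    protein; a synonymous-only optimizer scores exactly 0.0.
    """
    reference_aa = reference_aa.upper()
    nt = strip_terminal_stop(normalize_nt(optimized_nt), code)
    if len(nt) != 3 * len(reference_aa):
        raise DataError(
            f"CDS length {len(nt)} does not match protein length "
            f"{len(reference_aa)} x 3"
        )
    if not reference_aa:
        return 0.0
    observed = code.translate(nt)
    mismatches = sum(1 for a, b in zip(reference_aa, observed) if a != b)
    return 100.0 * mismatches / len(reference_aa)


def mean_degeneracy(aa_seq: str, code: GeneticCode = STANDARD_CODE) -> float:
    """Mean synonymous-family size across residues of a protein."""
    aa_seq = aa_seq.upper()
    if not aa_seq:
        raise UndefinedMetricError("mean degeneracy undefined for empty input")
    return float(
        np.mean([len(code.synonymous_codons(aa)) for aa in aa_seq])
    )


@dataclass
class EvaluationReport:
    """Tidy per-sequence metrics plus summaries and pairwise tests."""

    per_sequence: pd.DataFrame  # columns: sequence, method, metric, value
    summary: pd.DataFrame  # columns: method, metric, mean, sd, n
    tests: pd.DataFrame  # columns: metric, method_a, method_b, test, statistic, pvalue

    def column(self, method: str, metric: str) -> np.ndarray:
        df = self.per_sequence
        sel = df[(df["method"] == method) & (df["metric"] == metric)]
        return sel["value"].to_numpy()


_METRICS = ("cai", "gc", "cfd", "repeats", "cis_elements", "mutational_rate")


def evaluate(
    records: Sequence[GeneRecord],
    optimized: Mapping[str, Sequence[str]],
    usage: CodonUsageTable,
    motifs: Iterable[str] = DEFAULT_CIS_MOTIFS,
) -> EvaluationReport:
    """Score every method's output on every record and compare methods.

    ``optimized`` maps method name -> one CDS per input record (the method
    ``"original"`` may be included by passing the input CDS). CAI columns are
    compared with two-sample t-tests; repeat and cis-element counts with
    two-sided Mann-Whitney U tests.
    """
    weights = relative_adaptiveness(usage)
    motifs = tuple(motifs)
    rows = []
    for method, seqs in optimized.items():
        if len(seqs) != len(records):
            raise DataError(
                f"method {method!r} produced {len(seqs)} sequences for "
                f"{len(records)} records"
            )
        for rec, nt in zip(records, seqs):
            vals = {
                "cai": cai(nt, weights),
                "gc": gc_content(nt),
                "cfd": cfd(nt, weights),
                "repeats": float(negative_repeats(nt)),
                "cis_elements": float(negative_cis_elements(nt, motifs)),
                "mutational_rate": mutational_rate(rec.protein(), nt),
            }
            for metric, value in vals.items():
                rows.append(
                    {"sequence": rec.id, "method": method,
                     "metric": metric, "value": value}
                )
    per_sequence = pd.DataFrame(rows)
    summary = (
        per_sequence.groupby(["method", "metric"])["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    test_rows = []
    methods = list(optimized)
    for i, ma in enumerate(methods):
        for mb in methods[i + 1 :]:
            for metric, test_name in (
                ("cai", "t"),
                ("repeats", "mannwhitney"),
                ("cis_elements", "mannwhitney"),
            ):
                a = per_sequence.query(
                    "method == @ma and metric == @metric"
                )["value"].to_numpy()
                b = per_sequence.query(
                    "method == @mb and metric == @metric"
                )["value"].to_numpy()
                if test_name == "t":
                    with warnings.catch_warnings():
                        # constant samples (e.g. HFC CAI == 1.0 everywhere)
                        # trigger a harmless precision warning
                        warnings.simplefilter("ignore", RuntimeWarning)
                        stat, p = stats.ttest_ind(a, b)
                else:
                    try:
                        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
                    except ValueError:  # all values identical
                        stat, p = float("nan"), 1.0
                test_rows.append(
                    {"metric": metric, "method_a": ma, "method_b": mb,
                     "test": test_name, "statistic": float(stat),
                     "pvalue": float(p)}
                )
    tests = pd.DataFrame(test_rows)
    return EvaluationReport(per_sequence=per_sequence, summary=summary, tests=tests)
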