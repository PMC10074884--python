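"""Synthetic host genomes with controllable codon usage.

Generates gene sets from a parametric model of synonymous codon choice so
that curation, training and evaluation are testable without downloads. The
model draws each family's codon distribution from a Dirichlet whose
concentration is set by ``bias_strength`` (1.0 -> point mass per family,
-> 0 -> uniform); with ``context_order=1`` the distribution additionally
conditions on the previous amino acid, which a frequency-only optimizer
cannot express — the property the recurrent classifier is tested on.

The module also publishes two analytic per-position accuracy ceilings:
the best any frequency-only predictor can reach, and the best any
order-1-context predictor can reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from codonoptim.errors import ConfigError
from codonoptim.genetic_code import STANDARD_CODE, GeneticCode
from codonoptim.seqio import CodonUsageTable, GeneRecord

#: E. coli-like proteome-average amino-acid composition (normalized on use).
AA_COMPOSITION: dict[str, float] = {
    "A": 0.095, "R": 0.055, "N": 0.039, "D": 0.051, "C": 0.012,
    "Q": 0.044, "E": 0.057, "G": 0.074, "H": 0.022, "I": 0.060,
    "L": 0.105, "K": 0.044, "M": 0.028, "F": 0.039, "P": 0.044,
    "S": 0.058, "T": 0.054, "W": 0.014, "Y": 0.028, "V": 0.070,
}

#: Context symbol used for the first position of a gene (no previous residue).
START_CONTEXT = "^"


def _composition_arrays(code: GeneticCode) -> tuple[list[str], np.ndarray]:
    aas = sorted(AA_COMPOSITION)
    comp = np.array([AA_COMPOSITION[a] for a in aas])
    return aas, comp / comp.sum()


@dataclass
class GeneLengthSpec:
    """Uniform-integer gene length distribution (in amino acids)."""

    min_aa: int = 90
    max_aa: int = 600

    def __post_init__(self) -> None:
        if self.min_aa < 1 or self.max_aa < self.min_aa:
            raise ConfigError("invalid gene length bounds")


@dataclass
class SyntheticHostModel:
    """A generative model of (optionally context-dependent) codon choice.

    ``choice_tables`` maps ``(context, aa)`` to a probability vector over the
    synonymous family of ``aa`` (lexicographic codon order). For order-0
    hosts the context is always ``"*"``; for order-1 hosts it is the previous
    amino acid or :data:`START_CONTEXT` at the first position.
    """

    context_order: int
    bias_strength: float
    seed: int
    choice_tables: dict[tuple[str, str], np.ndarray]
    code: GeneticCode = field(default_factory=lambda: STANDARD_CODE)

    def codon_probs(self, aa: str, prev_aa: str | None) -> np.ndarray:
        if self.context_order == 0:
            return self.choice_tables[("*", aa)]
        ctx = prev_aa if prev_aa is not None else START_CONTEXT
        return self.choice_tables[(ctx, aa)]


def _draw_family_probs(
    rng: np.random.Generator, size: int, bias_strength: float
) -> np.ndarray:
    if size == 1:
        return np.array([1.0])
    if bias_strength >= 1.0:
        probs = np.zeros(size)
        probs[rng.integers(size)] = 1.0
        return probs
    # concentration -> 0 as bias -> 1 (near point mass), -> inf as bias -> 0
    alpha = 2.0 * max((1.0 - bias_strength) / bias_strength, 1e-3)
    return rng.dirichlet(np.full(size, alpha))


def _max_context_tv(
    host_tables: dict[tuple[str, str], np.ndarray],
    contexts: list[str],
    aas: list[str],
    code: GeneticCode,
) -> float:
    worst = 0.0
    for aa in aas:
        if len(code.synonymous_codons(aa)) < 2:
            continue
        mats = np.stack([host_tables[(c, aa)] for c in contexts])
        for i in range(len(contexts)):
            diffs = 0.5 * np.abs(mats - mats[i]).sum(axis=1)
            worst = max(worst, float(diffs.max()))
    return worst


def make_host(
    seed: int,
    context_order: int = 0,
    bias_strength: float = 0.8,
    code: GeneticCode = STANDARD_CODE,
) -> SyntheticHostModel:
    """Draw a reproducible synthetic host model.

    Order-1 hosts are redrawn (seeded, hence still deterministic) until at
    least one synonymous family shows total-variation distance > 0.2 between
    two previous-residue contexts, so the context signal is guaranteed to be
    learnable.
    """
    if context_order not in (0, 1):
        raise ConfigError(f"context_order must be 0 or 1, got {context_order}")
    if not (0.0 < bias_strength <= 1.0):
        raise ConfigError("bias_strength must be in (0, 1]")
    rng = np.random.default_rng(seed)
    aas, _ = _composition_arrays(code)
    if context_order == 0:
        tables = {
            ("*", aa): _draw_family_probs(
                rng, len(code.synonymous_codons(aa)), bias_strength
            )
            for aa in aas
        }
        return SyntheticHostModel(0, bias_strength, seed, tables, code)
    contexts = [START_CONTEXT] + aas
    for _ in range(100):
        tables = {
            (ctx, aa): _draw_family_probs(
                rng, len(code.synonymous_codons(aa)), bias_strength
            )
            for ctx in contexts
            for aa in aas
        }
        if _max_context_tv(tables, contexts, aas, code) > 0.2:
            return SyntheticHostModel(1, bias_strength, seed, tables, code)
    raise ConfigError(
        "could not draw an order-1 host with detectable context signal; "
        "increase bias_strength"
    )


def sample_genes(
    host: SyntheticHostModel,
    n: int,
    length_spec: GeneLengthSpec | None = None,
    seed: int = 0,
    id_prefix: str = "syn",
) -> list[GeneRecord]:
    """Sample ``n`` genes (CDS + protein) from the host model.

    Amino acids are drawn i.i.d. from the proteome-average composition,
    codons from the host's conditional tables; a TAA terminal stop is
    appended so records look like real coding sequences.
    """
    if length_spec is None:
        length_spec = GeneLengthSpec()
    rng = np.random.default_rng(seed)
    aas, comp = _composition_arrays(host.code)
    records = []
    for g in range(n):
        length = int(rng.integers(length_spec.min_aa, length_spec.max_aa + 1))
        aa_idx = rng.choice(len(aas), size=length, p=comp)
        protein = "".join(aas[i] for i in aa_idx)
        codons = []
        prev = None
        for aa in protein:
            family = host.code.synonymous_codons(aa)
            probs = host.codon_probs(aa, prev)
            codons.append(family[rng.choice(len(family), p=probs)])
            prev = aa
        desc = (
            f"synthetic host order={host.context_order} "
            f"bias={host.bias_strength} host_seed={host.seed} "
            f"gene_seed={seed} length={length}"
        )
        records.append(
            GeneRecord(
                id=f"{id_prefix}_{g:05d}",
                description=desc,
                nt_seq="".join(codons) + "TAA",
                aa_seq=protein,
            )
        )
    return records


def host_usage_table(host: SyntheticHostModel) -> CodonUsageTable:
    """Analytic marginal codon usage of the host.

    For order-1 hosts the previous-residue context is marginalized over the
    amino-acid composition (the interior-position marginal; the single start
    position per gene is negligible for realistic lengths).
    """
    aas, comp = _composition_arrays(host.code)
    comp_of = dict(zip(aas, comp))
    counts: dict[str, float] = {}
    for aa in aas:
        family = host.code.synonymous_codons(aa)
        if host.context_order == 0:
            marginal = host.choice_tables[("*", aa)]
        else:
            marginal = np.zeros(len(family))
            for prev in aas:
                marginal += comp_of[prev] * host.choice_tables[(prev, aa)]
        for codon, p in zip(family, marginal):
            counts[codon] = comp_of[aa] * float(p)
    return CodonUsageTable(counts=counts, code=host.code)


def frequency_ceiling(host: SyntheticHostModel) -> float:
    """Best per-position codon-match accuracy of any frequency-only
    predictor (one fixed codon per amino acid, chosen optimally)."""
    aas, comp = _composition_arrays(host.code)
    comp_of = dict(zip(aas, comp))
    usage = host_usage_table(host)
    acc = 0.0
    for aa in aas:
        family = host.code.synonymous_codons(aa)
        marg = np.array([usage.family_fraction[c] for c in family])
        best = family[int(np.argmax(marg))]
        if host.context_order == 0:
            p_correct = host.choice_tables[("*", aa)][family.index(best)]
        else:
            p_correct = sum(
                comp_of[prev] * host.choice_tables[(prev, aa)][family.index(best)]
                for prev in aas
            )
        acc += comp_of[aa] * float(p_correct)
    return acc


def context_ceiling(host: SyntheticHostModel) -> float:
    """Best accuracy of a predictor that sees the previous residue."""
    aas, comp = _composition_arrays(host.code)
    comp_of = dict(zip(aas, comp))
    acc = 0.0
    for aa in aas:
        if host.context_order == 0:
            acc += comp_of[aa] * float(host.choice_tables[("*", aa)].max())
        else:
            acc += comp_of[aa] * sum(
                comp_of[prev] * float(host.choice_tables[(prev, aa)].max())
                for prev in aas
            )
    return acc


def host_from_usage(
    usage: CodonUsageTable, seed: int = 0
) -> SyntheticHostModel:
    """An order-0 host whose codon choice reproduces a usage table's
    within-family fractions (e.g. to emulate an E. coli-like host)."""
    aas, _ = _composition_arrays(usage.code)
    tables: dict[tuple[str, str], np.ndarray] = {}
    for aa in aas:
        family = usage.code.synonymous_codons(aa)
        probs = np.array([usage.family_fraction[c] for c in family])
        if probs.sum() <= 0:
            raise ConfigError(f"usage table has no mass in family of {aa!r}")
        tables[("*", aa)] = probs / probs.sum()
    return SyntheticHostModel(0, 0.0, seed, tables, usage.code)


def make_benchmark_fixture(
    seed: int, code: GeneticCode = STANDARD_CODE
) -> list[GeneRecord]:
    """A 40-gene benchmark-shaped fixture with deliberately suboptimal codon
    usage (low-bias host), mean length ~560 amino acids."""
    host = make_host(seed=seed, context_order=0, bias_strength=0.25, code=code)
    return sample_genes(
        host,
        n=40,
        length_spec=GeneLengthSpec(min_aa=520, max_aa=600),
        seed=seed + 1,
        id_prefix="bench",
    )
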