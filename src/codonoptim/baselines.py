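"""Frequency-based baseline optimizers.

Four classical back-translation strategies against which the recurrent
classifier is compared:

* URC — uniform random choice within each synonymous family.
* BFC — background frequency choice: sample each codon with its host
  within-family fraction.
* HFC — highest frequency choice: always the family's most-used codon
  (the "CAI = 1.0" strategy).
* ERC — extended random choice: draw k URC candidates and keep the one
  with the highest CAI (a single-metric stand-in for exhaustive search
  over all synonymous combinations).

All four guarantee translation identity: the output CDS back-translates to
the input protein exactly.
"""

from __future__ import annotations

import numpy as np

from codonoptim.errors import ConfigError, DegenerateUsageError
from codonoptim.genetic_code import STANDARD_CODE, GeneticCode
from codonoptim.metrics import relative_adaptiveness
from codonoptim.seqio import CodonUsageTable


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _uniform_family_indices(
    rng: np.random.Generator, sizes: np.ndarray, k: int | None = None
) -> np.ndarray:
    """Uniform codon index per position (vectorized over positions and,
    optionally, k candidate sequences)."""
    shape = (len(sizes),) if k is None else (k, len(sizes))
    u = rng.random(shape)
    return (u * sizes).astype(np.int64)  # u < 1 so index < size


def urc_optimize(
    aa_seq: str,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Back-translate by drawing uniformly from each synonymous family."""
    rng = _rng(seed)
    aa_seq = aa_seq.upper()
    families = [code.synonymous_codons(aa) for aa in aa_seq]
    sizes = np.array([len(f) for f in families], dtype=np.int64)
    if len(sizes) == 0:
        return ""
    idx = _uniform_family_indices(rng, sizes)
    return "".join(fam[i] for fam, i in zip(families, idx))


def _family_probs(
    usage: CodonUsageTable, aa: str, code: GeneticCode
) -> tuple[tuple[str, ...], np.ndarray]:
    family = code.synonymous_codons(aa)
    probs = np.array([usage.family_fraction[c] for c in family])
    total = probs.sum()
    if total <= 0:
        raise DegenerateUsageError(
            f"usage table has zero mass in the family of {aa!r}"
        )
    return family, probs / total


def bfc_optimize(
    aa_seq: str,
    usage: CodonUsageTable,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Back-translate by sampling codons with host within-family fractions."""
    rng = _rng(seed)
    out = []
    for aa in aa_seq.upper():
        family, probs = _family_probs(usage, aa, code)
        out.append(family[rng.choice(len(family), p=probs)])
    return "".join(out)


def hfc_optimize(
    aa_seq: str, usage: CodonUsageTable, code: GeneticCode = STANDARD_CODE
) -> str:
    """Back-translate deterministically with each family's most-used codon.

    Within-family frequency ties break toward the lexicographically smaller
    codon (families are stored in lexicographic order).
    """
    out = []
    for aa in aa_seq.upper():
        family, probs = _family_probs(usage, aa, code)
        out.append(family[int(np.argmax(probs))])
    return "".join(out)


def erc_optimize(
    aa_seq: str,
    usage: CodonUsageTable,
    k: int = 10_000,
    seed: int | np.random.Generator | None = None,
    code: GeneticCode = STANDARD_CODE,
) -> str:
    """Generate ``k`` URC candidates and return the one with maximal CAI.

    Ties keep the earliest-generated candidate. Candidate scoring is
    vectorized: each candidate's CAI is the geometric mean of relative
    adaptiveness over its scorable positions (multi-codon families), which
    reduces to the arithmetic mean of log-w.
    """
    if k < 1:
        raise ConfigError(f"ERC candidate count k must be >= 1, got {k}")
    rng = _rng(seed)
    aa_seq = aa_seq.upper()
    weights = relative_adaptiveness(usage)
    families = [code.synonymous_codons(aa) for aa in aa_seq]
    sizes = np.array([len(f) for f in families], dtype=np.int64)
    if len(sizes) == 0:
        return ""
    idx = _uniform_family_indices(rng, sizes, k)  # (k, T)
    scorable = sizes > 1
    if not scorable.any():
        # every family has one codon: all candidates identical
        return "".join(fam[0] for fam in families)
    max_size = int(sizes.max())
    logw = np.zeros((len(families), max_size))
    for t, fam in enumerate(families):
        logw[t, : len(fam)] = np.log([weights.w[c] for c in fam])
    # per-candidate mean log-w over scorable positions
    picked = logw[np.arange(len(families))[None, :], idx]  # (k, T)
    mean_logw = picked[:, scorable].mean(axis=1)
    best = int(np.argmax(mean_logw))
    return "".join(fam[i] for fam, i in zip(families, idx[best]))
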