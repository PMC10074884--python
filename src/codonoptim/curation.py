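"""Training-set curation pipeline.

Host genes are length-filtered (< 90 aa removed), de-redundified with a
greedy identity-threshold clustering (CD-HIT convention: sort by length
descending, each sequence joins the first representative it matches at
over the identity threshold, identity measured over the optimal ungapped
k-mer-anchored alignment divided by the shorter length), ranked by CAI, and
the top-N split 70/10/20 into train/validation/test.

The clusterer is a self-contained approximation of CD-HIT-EST: the goal is
removing >90%-identity redundancy, not bit-exact cluster membership, so no
external binary is required. Pre-computed cluster assignments can be
injected instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from codonoptim.errors import ConfigError
from codonoptim.metrics import AdaptivenessWeights, cai, relative_adaptiveness
from codonoptim.seqio import CodonUsageTable, GeneRecord


@dataclass
class CurationConfig:
    min_aa_length: int = 90
    identity_threshold: float = 0.90
    top_n: int = 7406
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    word_size: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ConfigError("identity_threshold must be in (0, 1]")
        if any(f <= 0 for f in self.split_fractions):
            raise ConfigError("split fractions must be positive")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ConfigError("split fractions must sum to 1")


def filter_by_length(
    records: list[GeneRecord], min_aa_length: int = 90
) -> list[GeneRecord]:
    """Keep records whose protein is at least ``min_aa_length`` residues."""
    return [r for r in records if len(r.protein()) >= min_aa_length]


def ungapped_identity(a: str, b: str, word_size: int = 8) -> float:
    """Identity of the best ungapped k-mer-anchored alignment of two
    sequences, as a fraction of the shorter length.

    Candidate alignments are the diagonals on which the two sequences share
    at least one exact ``word_size``-mer; each diagonal scores its matching
    positions over the full overlap.
    """
    if not a or not b:
        return 0.0
    short = min(len(a), len(b))
    words: dict[str, list[int]] = {}
    for i in range(len(a) - word_size + 1):
        words.setdefault(a[i : i + word_size], []).append(i)
    diagonals: set[int] = set()
    for j in range(len(b) - word_size + 1):
        for i in words.get(b[j : j + word_size], ()):
            diagonals.add(i - j)
    best = 0
    for d in diagonals:
        lo_a = max(0, d)
        lo_b = max(0, -d)
        overlap = min(len(a) - lo_a, len(b) - lo_b)
        matches = sum(
            1 for k in range(overlap) if a[lo_a + k] == b[lo_b + k]
        )
        best = max(best, matches)
    return best / short


def cluster_redundant(
    records: list[GeneRecord],
    identity_threshold: float = 0.90,
    word_size: int = 8,
) -> list[GeneRecord]:
    """Greedy redundancy removal; returns cluster representatives only.

    Sequences are visited longest-first; each joins the first existing
    representative whose identity with it exceeds the threshold, otherwise
    it founds a new cluster.
    """
    if identity_threshold <= 0:
        raise ConfigError("identity_threshold must be positive")
    order = sorted(
        records, key=lambda r: (-len(r.nt_seq or ""), r.id)
    )
    reps: list[GeneRecord] = []
    for rec in order:
        seq = rec.nt_seq or ""
        joined = False
        for rep in reps:
            if ungapped_identity(rep.nt_seq, seq, word_size) > identity_threshold:
                joined = True
                break
        if not joined:
            reps.append(rec)
    # restore input order among representatives
    kept = {id(r) for r in reps}
    return [r for r in records if id(r) in kept]


def cluster_assignments(
    records: list[GeneRecord],
    identity_threshold: float = 0.90,
    word_size: int = 8,
) -> dict[str, str]:
    """Map each record id to its cluster representative's id."""
    order = sorted(records, key=lambda r: (-len(r.nt_seq or ""), r.id))
    reps: list[GeneRecord] = []
    assignment: dict[str, str] = {}
    for rec in order:
        for rep in reps:
            if ungapped_identity(rep.nt_seq, rec.nt_seq or "", word_size) > identity_threshold:
                assignment[rec.id] = rep.id
                break
        else:
            reps.append(rec)
            assignment[rec.id] = rec.id
    return assignment


def rank_and_select(
    records: list[GeneRecord],
    usage: CodonUsageTable,
    top_n: int,
    weights: AdaptivenessWeights | None = None,
) -> list[GeneRecord]:
    """Sort by CAI descending (stable; ties to longer then lexicographic id)
    and keep the first ``top_n``."""
    if top_n > len(records):
        raise ConfigError(
            f"top_n={top_n} exceeds collection size {len(records)}"
        )
    if weights is None:
        weights = relative_adaptiveness(usage)
    scored = [
        (cai(r.nt_seq, weights), len(r.nt_seq or ""), r) for r in records
    ]
    scored.sort(key=lambda t: (-t[0], -t[1], t[2].id))
    return [r for _, _, r in scored[:top_n]]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_dataset(
    records: list[GeneRecord],
    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
    seed: int = 0,
) -> tuple[list[GeneRecord], list[GeneRecord], list[GeneRecord]]:
    """Shuffle and partition into (train, validation, test).

    Validation and test sizes are the nearest integers to their fractions of
    N; train takes the remainder. This rounding reproduces a 7,406-record
    70/10/20 split as 5,184/741/1,481.
    """
    n = len(records)
    if n == 0:
        return [], [], []
    _, f_val, f_test = fractions
    n_val = _round_half_up(f_val * n)
    n_test = _round_half_up(f_test * n)
    if n_val + n_test > n:
        raise ConfigError("split fractions leave no training data")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    shuffled = [records[i] for i in order]
    val = shuffled[:n_val]
    test = shuffled[n_val : n_val + n_test]
    train = shuffled[n_val + n_test :]
    return train, val, test


@dataclass
class CurationResult:
    train: list[GeneRecord]
    validation: list[GeneRecord]
    test: list[GeneRecord]
    log: pd.DataFrame  # id, length_aa, cai, cluster, partition


def curate(
    records: list[GeneRecord],
    usage: CodonUsageTable,
    config: CurationConfig | None = None,
) -> CurationResult:
    """Run the full pipeline: length filter -> clustering -> CAI top-N ->
    seeded 70/10/20 split, with a per-record audit log."""
    if config is None:
        config = CurationConfig()
    weights = relative_adaptiveness(usage)
    kept = filter_by_length(records, config.min_aa_length)
    clusters = cluster_assignments(
        kept, config.identity_threshold, config.word_size
    )
    reps = [r for r in kept if clusters[r.id] == r.id]
    top_n = min(config.top_n, len(reps))
    selected = rank_and_select(reps, usage, top_n, weights)
    train, val, test = split_dataset(
        selected, config.split_fractions, config.seed
    )
    partition = {r.id: "train" for r in train}
    partition.update({r.id: "validation" for r in val})
    partition.update({r.id: "test" for r in test})
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "length_aa": len(r.protein()),
                "cai": cai(r.nt_seq, weights) if r.nt_seq else float("nan"),
                "cluster": clusters.get(r.id, ""),
                "partition": partition.get(r.id, "dropped"),
            }
        )
    return CurationResult(
        train=train, validation=val, test=test, log=pd.DataFrame(rows)
    )
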