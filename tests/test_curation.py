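import numpy as np
import pytest

from codonoptim.curation import (
    CurationConfig,
    cluster_redundant,
    curate,
    filter_by_length,
    rank_and_select,
    split_dataset,
    ungapped_identity,
)
from codonoptim.errors import ConfigError
from codonoptim.genetic_code import STANDARD_CODE
from codonoptim.seqio import GeneRecord

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def random_cds_record(rng, rec_id, n_aa):
    protein = "".join(rng.choice(AAS, size=n_aa))
    cds = "".join(
        rng.choice(STANDARD_CODE.synonymous_codons(aa)) for aa in protein
    )
    return GeneRecord(id=rec_id, nt_seq=cds)


class TestFilterByLength:
    def test_boundary_at_90(self, rng):
        short = random_cds_record(rng, "short", 89)
        exact = random_cds_record(rng, "exact", 90)
        out = filter_by_length([short, exact], 90)
        assert [r.id for r in out] == ["exact"]

    def test_empty_input(self):
        assert filter_by_length([], 90) == []

    def test_order_preserved(self, rng):
        recs = [random_cds_record(rng, f"g{i}", 100 + i) for i in range(5)]
        assert filter_by_length(recs, 90) == recs


def oracle_cluster(records, threshold):
    """All-pairs oracle: identity = best ungapped overlap over ALL diagonals
    (no k-mer anchoring), same longest-first greedy assignment."""

    def identity(a, b):
        best = 0
        for d in range(-(len(b) - 1), len(a)):
            lo_a, lo_b = max(0, d), max(0, -d)
            overlap = min(len(a) - lo_a, len(b) - lo_b)
            if overlap <= 0:
                continue
            matches = sum(
                1 for k in range(overlap) if a[lo_a + k] == b[lo_b + k]
            )
            best = max(best, matches)
        return best / min(len(a), len(b))

    order = sorted(records, key=lambda r: (-len(r.nt_seq), r.id))
    reps = []
    for rec in order:
        if not any(
            identity(rep.nt_seq, rec.nt_seq) > threshold for rep in reps
        ):
            reps.append(rec)
    return {r.id for r in reps}


class TestClusterRedundant:
    def test_identical_sequences_collapse(self, rng):
        rec = random_cds_record(rng, "a", 60)
        twin = GeneRecord(id="b", nt_seq=rec.nt_seq)
        assert len(cluster_redundant([rec, twin], 0.9, word_size=5)) == 1

    def test_dissimilar_sequences_both_kept(self, rng):
        a = GeneRecord(id="a", nt_seq="ATG" + "GCA" * 40)
        b = GeneRecord(id="b", nt_seq="ATG" + "TTT" * 40)
        assert len(cluster_redundant([a, b], 0.9, word_size=5)) == 2

    def test_identity_denominator_is_shorter_length(self):
        long = "ATGGCAGCAGCAGCATTTGGGCCCAAATTTGGG"
        short = long[:21]  # exact prefix
        assert ungapped_identity(long, short, word_size=5) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        """Greedy k-mer-anchored clustering reproduces the exhaustive
        all-diagonals oracle on mutated sequence families."""
        rng = np.random.default_rng(seed)
        records = []
        n_fam = rng.integers(3, 6)
        idx = 0
        for f in range(n_fam):
            base = random_cds_record(rng, f"f{f}", int(rng.integers(25, 40)))
            records.append(GeneRecord(id=f"r{idx}", nt_seq=base.nt_seq))
            idx += 1
            for _ in range(int(rng.integers(0, 4))):
                seq = list(base.nt_seq)
                n_mut = int(rng.integers(0, max(2, len(seq) // 15)))
                for _ in range(n_mut):
                    seq[rng.integers(len(seq))] = rng.choice(list("ACGT"))
                records.append(GeneRecord(id=f"r{idx}", nt_seq="".join(seq)))
                idx += 1
        got = {r.id for r in cluster_redundant(records, 0.9, word_size=5)}
        assert got == oracle_cluster(records, 0.9)

    def test_invalid_threshold(self, rng):
        with pytest.raises(ConfigError):
            cluster_redundant([random_cds_record(rng, "a", 30)], 0.0)


class TestRankAndSelect:
    def _table(self):
        from codonoptim.seqio import CodonUsageTable

        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["GAA"], counts["GAG"] = 90.0, 10.0
        return CodonUsageTable(counts=counts)

    def test_descending_cai_order(self):
        table = self._table()
        recs = [
            GeneRecord(id="low", nt_seq="GAG" * 10),
            GeneRecord(id="high", nt_seq="GAA" * 10),
            GeneRecord(id="mid", nt_seq="GAA" * 5 + "GAG" * 5),
        ]
        out = rank_and_select(recs, table, top_n=2)
        assert [r.id for r in out] == ["high", "mid"]

    def test_ties_break_longer_then_id(self):
        table = self._table()
        recs = [
            GeneRecord(id="b", nt_seq="GAA" * 10),
            GeneRecord(id="a", nt_seq="GAA" * 10),
            GeneRecord(id="c", nt_seq="GAA" * 20),
        ]
        out = rank_and_select(recs, table, top_n=3)
        assert [r.id for r in out] == ["c", "a", "b"]

    def test_top_n_zero_and_overflow(self):
        table = self._table()
        recs = [GeneRecord(id="a", nt_seq="GAA" * 10)]
        assert rank_and_select(recs, table, top_n=0) == []
        with pytest.raises(ConfigError):
            rank_and_select(recs, table, top_n=2)


class TestSplitDataset:
    def _records(self, n):
        return [GeneRecord(id=f"g{i}", aa_seq="M") for i in range(n)]

    def test_printed_partition_of_7406(self):
        train, val, test = split_dataset(self._records(7406), seed=0)
        assert (len(train), len(val), len(test)) == (5184, 741, 1481)

    def test_small_n_rounding(self):
        train, val, test = split_dataset(self._records(10), seed=0)
        assert (len(train), len(val), len(test)) == (7, 1, 2)

    def test_deterministic_and_exact_partition(self):
        recs = self._records(101)
        a = split_dataset(recs, seed=5)
        b = split_dataset(recs, seed=5)
        assert [[r.id for r in part] for part in a] == [
            [r.id for r in part] for part in b
        ]
        ids = [r.id for part in a for r in part]
        assert sorted(ids) == sorted(r.id for r in recs)

    def test_empty_input(self):
        assert split_dataset([], seed=0) == ([], [], [])


class TestPipeline:
    def test_monotone_sizes_and_audit_log(self, rng, ecoli_usage):
        records = [random_cds_record(rng, f"g{i}", 95) for i in range(30)]
        # add short and duplicate records that must be dropped
        records.append(random_cds_record(rng, "short", 50))
        records.append(GeneRecord(id="dup", nt_seq=records[0].nt_seq))
        cfg = CurationConfig(top_n=20, word_size=8, seed=1)
        result = curate(records, ecoli_usage, cfg)
        n_selected = (
            len(result.train) + len(result.validation) + len(result.test)
        )
        assert n_selected == 20 <= len(records)
        log = result.log.set_index("id")
        assert log.loc["short", "partition"] == "dropped"
        # the duplicate pair shares one cluster representative
        assert log.loc["dup", "cluster"] == log.loc["g0", "cluster"]
        parts = log["partition"].value_counts()
        assert parts.get("train", 0) == len(result.train)
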