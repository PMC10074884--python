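import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonoptim.baselines import hfc_optimize
from codonoptim.errors import DataError, UndefinedMetricError
from codonoptim.genetic_code import STANDARD_CODE
from codonoptim.metrics import (
    DEFAULT_CIS_MOTIFS,
    cai,
    cfd,
    evaluate,
    gc_content,
    mean_degeneracy,
    mutational_rate,
    negative_cis_elements,
    negative_repeats,
    relative_adaptiveness,
)
from codonoptim.seqio import CodonUsageTable, GeneRecord


def random_usage_table(rng) -> CodonUsageTable:
    counts = {
        c: float(rng.integers(1, 1000)) for c in STANDARD_CODE.sense_codons
    }
    return CodonUsageTable(counts=counts)


def random_protein(rng, length=60) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))


class TestRelativeAdaptiveness:
    def test_definition_on_two_codon_family(self):
        # cysteine family TGC/TGT with fractions 0.75/0.25
        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["TGC"] = 75.0
        counts["TGT"] = 25.0
        w = relative_adaptiveness(CodonUsageTable(counts=counts))
        assert w.w["TGC"] == pytest.approx(1.0)
        assert w.w["TGT"] == pytest.approx(1 / 3)

    def test_family_maximum_is_one(self, ecoli_usage):
        w = relative_adaptiveness(ecoli_usage)
        for fam in STANDARD_CODE.aa_to_codons.values():
            assert max(w.w[c] for c in fam) == pytest.approx(1.0)

    def test_zero_count_codon_floored(self):
        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["TGT"] = 0.0
        w = relative_adaptiveness(CodonUsageTable(counts=counts))
        assert w.w["TGT"] == pytest.approx(1e-4)


class TestCai:
    def test_two_codon_geometric_mean(self):
        # one codon at w=1 and one at w=1/3 -> sqrt(1/3)
        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["TGC"], counts["TGT"] = 75.0, 25.0
        counts["GAA"], counts["GAG"] = 50.0, 50.0
        w = relative_adaptiveness(CodonUsageTable(counts=counts))
        assert cai("GAATGT", w) == pytest.approx(math.sqrt(1 / 3))

    def test_single_codon_families_not_scorable(self, ecoli_usage):
        w = relative_adaptiveness(ecoli_usage)
        with pytest.raises(UndefinedMetricError):
            cai("ATGTGG", w)

    def test_invariant_to_codon_permutation(self, ecoli_usage, rng):
        w = relative_adaptiveness(ecoli_usage)
        codons = ["CTG", "AAA", "GCG", "TGT", "GAA"] * 4
        a = "".join(codons)
        rng.shuffle(codons)
        b = "".join(codons)
        assert cai(a, w) == pytest.approx(cai(b, w))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_hfc_scores_one_for_any_table_and_protein(self, seed):
        rng = np.random.default_rng(seed)
        table = random_usage_table(rng)
        protein = random_protein(rng)
        out = hfc_optimize(protein, table)
        w = relative_adaptiveness(table)
        assert cai(out, w) == pytest.approx(1.0)
        assert cfd(out, w) == 0.0


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected", [("ATGC", 50.0), ("GGCC", 100.0), ("ATAT", 0.0)]
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_undefined(self):
        with pytest.raises(UndefinedMetricError):
            gc_content("")


class TestCfd:
    def test_threshold_strictly_less(self):
        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["TGC"], counts["TGT"] = 100.0, 30.0  # w(TGT) = 0.30 exactly
        w = relative_adaptiveness(CodonUsageTable(counts=counts))
        assert w.w["TGT"] == pytest.approx(0.30)
        assert cfd("TGT", w) == 0.0

    def test_constructed_half_rare(self):
        counts = {c: 1.0 for c in STANDARD_CODE.sense_codons}
        counts["GAA"], counts["GAG"] = 100.0, 25.0
        w = relative_adaptiveness(CodonUsageTable(counts=counts))
        assert cfd("GAAGAG", w) == pytest.approx(50.0)


def brute_force_repeats(seq: str, min_len: int = 10) -> int:
    """Independent O(n^2) oracle: tally every substring, keep the repeated
    ones, count those not contained in a longer repeated substring."""
    n = len(seq)
    repeated = set()
    for length in range(min_len, n):
        for i in range(n - length + 1):
            s = seq[i : i + length]
            hits = sum(
                1 for j in range(n - length + 1) if seq[j : j + length] == s
            )
            if hits >= 2:
                repeated.add(s)
    return sum(
        1
        for s in repeated
        if not any(s != t and s in t for t in repeated)
    )


class TestNegativeRepeats:
    def test_short_sequence_zero(self):
        assert negative_repeats("ATGC") == 0

    def test_planted_block_counted_once(self, rng):
        block = "ACGTACGTACGT"  # 12 nt
        bg = "".join(rng.choice(list("ACGT"), size=60))
        seq = bg[:20] + block + bg[20:40] + block + bg[40:]
        if brute_force_repeats(bg) == 0:  # background must be repeat-free
            assert negative_repeats(seq) == brute_force_repeats(seq) >= 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        assert negative_repeats(seq) == brute_force_repeats(seq)

    def test_matches_brute_force_on_repeat_rich_sequences(self):
        rng = np.random.default_rng(99)
        # low-entropy alphabet guarantees repeats
        seq = "".join(rng.choice(list("AC"), size=120))
        assert negative_repeats(seq) == brute_force_repeats(seq)


class TestCisElements:
    def test_shine_dalgarno_counted(self):
        seq = "ATG" * 10 + "AGGAGG" + "CAT" * 10
        assert negative_cis_elements(seq) >= 1

    def test_empty_motif_set(self):
        assert negative_cis_elements("ATGAGGAGG", motifs=()) == 0

    def test_reverse_strand_counted_once(self):
        # reverse complement of TATAAT is ATTATA
        seq = "GGGGGG" + "ATTATA" + "GGGGGG"
        assert negative_cis_elements(seq, motifs=("TATAAT",)) == 1

    def test_iupac_degenerate_motif(self):
        # ACAT matches ACRT on the forward strand only
        assert negative_cis_elements("CCACATCC", motifs=("ACRT",)) == 1


class TestMutationalRate:
    def test_one_altered_residue_in_100(self, ecoli_usage):
        protein = "K" * 100
        nt = "AAA" * 99 + "GAA"  # last codon is Glu, not Lys
        assert mutational_rate(protein, nt) == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            mutational_rate("MK", "ATG")


class TestMeanDegeneracy:
    @pytest.mark.parametrize("aa,expected", [("M", 1.0), ("L", 6.0)])
    def test_single_residues(self, aa, expected):
        assert mean_degeneracy(aa) == expected

    def test_all_twenty_once(self):
        assert mean_degeneracy("ACDEFGHIKLMNPQRSTVWY") == pytest.approx(61 / 20)


class TestEvaluate:
    def test_micro_fixture_statistics(self, ecoli_usage):
        recs = [
            GeneRecord(id=f"g{i}", nt_seq=s)
            for i, s in enumerate(["GAAGAATGT", "GAAAAATGC", "AAAAAGTGT"])
        ]
        optimized = {
            "original": [r.nt_seq for r in recs],
            "hfc": [hfc_optimize(r.protein(), ecoli_usage) for r in recs],
        }
        report = evaluate(recs, optimized, ecoli_usage)
        # means in the summary equal recomputed column means
        for method in optimized:
            for metric in ("cai", "gc"):
                col = report.column(method, metric)
                row = report.summary.query(
                    "method == @method and metric == @metric"
                )
                assert row["mean"].iloc[0] == pytest.approx(col.mean())
        # HFC output has CFD 0 and mutational rate 0 everywhere
        assert (report.column("hfc", "cfd") == 0).all()
        assert (report.column("hfc", "mutational_rate") == 0).all()
        # pairwise tests cover the cai t-test and the count U-tests
        assert set(report.tests["test"]) == {"t", "mannwhitney"}

    def test_row_count(self, ecoli_usage):
        recs = [
            GeneRecord(id=f"g{i}", nt_seq="GAA" * 30) for i in range(5)
        ]
        report = evaluate(
            recs, {"original": [r.nt_seq for r in recs]}, ecoli_usage
        )
        assert len(report.per_sequence) == 5 * 6  # 6 metrics per record
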