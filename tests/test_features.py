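"""Codon feature encodings: identification numbers, counts, bias, matrix assembly."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonexpress import (
    ALL_CODONS,
    CodingSequence,
    ExpressionRecord,
    FeatureBlockSpec,
    InvalidSequenceError,
    assemble_feature_matrix,
    codon_bias,
    codon_count,
    codon_from_identification,
    codon_id_vector,
    codon_identification,
    restrict_bias_subset,
    standard_genetic_code,
    synonymous_groups,
)
from conftest import random_coding_sequence

# The full published identification table (codon, number), frozen verbatim.
GOLDEN_IDS = {
    "aaa": 1, "aac": 2, "aag": 3, "aat": 4, "aca": 5, "acc": 6, "acg": 7, "act": 8,
    "aga": 9, "agc": 10, "agg": 11, "agt": 12, "ata": 13, "atc": 14, "atg": 15, "att": 16,
    "caa": 17, "cac": 18, "cag": 19, "cat": 20, "cca": 21, "ccc": 22, "ccg": 23, "cct": 24,
    "cga": 25, "cgc": 26, "cgg": 27, "cgt": 28, "cta": 29, "ctc": 30, "ctg": 31, "ctt": 32,
    "gaa": 33, "gac": 34, "gag": 35, "gat": 36, "gca": 37, "gcc": 38, "gcg": 39, "gct": 40,
    "gga": 41, "ggc": 42, "ggg": 43, "ggt": 44, "gta": 45, "gtc": 46, "gtg": 47, "gtt": 48,
    "taa": 49, "tac": 50, "tag": 51, "tat": 52, "tca": 53, "tcc": 54, "tcg": 55, "tct": 56,
    "tga": 57, "tgc": 58, "tgg": 59, "tgt": 60, "tta": 61, "ttc": 62, "ttg": 63, "ttt": 64,
}

codon_lists = st.lists(st.sampled_from(ALL_CODONS), min_size=1, max_size=120)


def test_codon_identification_matches_published_table():
    for codon, number in GOLDEN_IDS.items():
        assert codon_identification(codon) == number
    # and the inverse round-trips
    for n in range(1, 65):
        assert codon_identification(codon_from_identification(n)) == n


@pytest.mark.parametrize("bad", ["AA", "AAAA", "ANA", "A-A", ""])
def test_codon_identification_rejects_invalid(bad):
    with pytest.raises((InvalidSequenceError, ValueError)):
        codon_identification(bad)


def test_codon_id_vector_examples(rng):
    assert codon_id_vector(CodingSequence("s", "ATGAAA")).tolist() == [15, 1]
    assert codon_id_vector(CodingSequence("s", "AAA")).tolist() == [1]
    seq = random_coding_sequence(rng, 30)
    expected = [GOLDEN_IDS[c.lower()] for c in seq.codons()]
    assert codon_id_vector(seq).tolist() == expected


def test_codon_count_examples(rng):
    v = codon_count(CodingSequence("s", "ATGAAA"))
    assert v[15 - 1] == 1 and v[1 - 1] == 1 and v.sum() == 2
    v = codon_count(CodingSequence("s", "AAAAAA"))
    assert v[0] == 2 and v.sum() == 2
    seq = random_coding_sequence(rng, 50)
    tally = Counter(seq.codons())
    for k, codon in enumerate(ALL_CODONS):
        assert codon_count(seq)[k] == tally.get(codon, 0)


def test_codon_bias_examples():
    # lysine codons AAA x3, AAG x1 and nothing else encoding lysine
    seq = CodingSequence("s", "AAA" * 3 + "AAG" + "TGG")
    b = codon_bias(seq)
    assert b[codon_identification("AAA") - 1] == pytest.approx(0.75)
    assert b[codon_identification("AAG") - 1] == pytest.approx(0.25)
    # no cysteine codons -> zero for the whole group
    assert b[codon_identification("TGT") - 1] == 0.0
    assert b[codon_identification("TGC") - 1] == 0.0


@given(codons=codon_lists)
@settings(max_examples=150, derandomize=True, deadline=None)
def test_count_and_bias_invariants(codons):
    """Counts sum to len/3; bias sums to 1 per amino-acid group present, 0 absent."""
    seq = CodingSequence("s", "".join(codons))
    counts = codon_count(seq)
    assert counts.sum() == seq.n_codons
    bias = codon_bias(seq)
    assert np.all((bias >= 0) & (bias <= 1))
    code = standard_genetic_code()
    present = {code[c] for c in seq.codons()}
    for aa, group in synonymous_groups(code).items():
        group_sum = sum(bias[codon_identification(c) - 1] for c in group)
        assert group_sum == pytest.approx(1.0 if aa in present else 0.0)


def test_rna_lowercase_normalization_equivalence():
    a = CodingSequence("s", "augaaa")
    b = CodingSequence("s", "ATGAAA")
    assert a.nucleotides == b.nucleotides
    assert np.array_equal(codon_id_vector(a), codon_id_vector(b))
    assert np.array_equal(codon_bias(a), codon_bias(b))


def _dataset(rng, n_codons, n_seqs=4, codon_pool=None):
    seqs, records = [], []
    for i in range(n_seqs):
        if codon_pool is None:
            seq = random_coding_sequence(rng, n_codons, f"p{i}")
        else:
            # cycle the pool so every allowed codon occurs in the dataset
            idx = (np.arange(n_codons) + i) % len(codon_pool)
            seq = CodingSequence(f"p{i}", "".join(codon_pool[j] for j in idx))
        seqs.append(seq)
        records.append(ExpressionRecord(f"p{i}", 1.0 + i, mfe_whole=-5.0 - i, mfe_window=-2.0))
    return records, seqs


def test_feature_matrix_width_288_codons_is_417(rng):
    """MFE + 64 bias + 64 count + 288 ID columns = 417 features."""
    records, seqs = _dataset(rng, 288)
    spec = FeatureBlockSpec(use_mfe="whole", use_bias="all", use_count=True, use_id=True)
    X = assemble_feature_matrix(records, seqs, spec)
    assert X.n_features == 417
    assert [s for _, s in X.blocks] == [1, 64, 64, 288]


def test_feature_matrix_width_575_codons_61_distinct_is_701(rng):
    """Dropping the 3 never-occurring codons' bias columns gives 1+61+64+575 = 701."""
    pool = [c for c in ALL_CODONS if c not in ("AAA", "CCC", "GGG")]
    records, seqs = _dataset(rng, 575, codon_pool=pool)
    spec = FeatureBlockSpec(
        use_mfe="whole", use_bias="all", drop_absent_bias_columns=True,
        use_count=True, use_id=True,
    )
    X = assemble_feature_matrix(records, seqs, spec)
    assert X.n_features == 701
    start, stop = X.block_span("bias")
    assert stop - start == 61
    assert "bias_AAA" not in X.columns


def test_feature_matrix_mfe_only(rng):
    records, seqs = _dataset(rng, 10)
    spec = FeatureBlockSpec(use_mfe="window", use_bias="off", use_count=False, use_id=False)
    X = assemble_feature_matrix(records, seqs, spec)
    assert X.n_features == 1
    assert np.all(X.values[:, 0] == -2.0)


def test_feature_matrix_errors(rng):
    records, seqs = _dataset(rng, 10)
    spec = FeatureBlockSpec(use_mfe="off", use_bias="all", use_count=True, use_id=True)
    # mismatched identifiers
    bad = [ExpressionRecord("other", 1.0)] + records[1:]
    with pytest.raises(ValueError, match="identifier"):
        assemble_feature_matrix(bad, seqs, spec)
    # unequal sequence lengths
    seqs2 = seqs[:-1] + [CodingSequence(seqs[-1].identifier, "ATG")]
    with pytest.raises(ValueError, match="length"):
        assemble_feature_matrix(records, seqs2, spec)
    # MFE requested but missing
    no_mfe = [ExpressionRecord(r.identifier, r.expression) for r in records]
    with pytest.raises(ValueError, match="MFE"):
        assemble_feature_matrix(no_mfe, seqs, FeatureBlockSpec(use_mfe="whole"))
    # at least one block must be enabled
    with pytest.raises(ValueError):
        FeatureBlockSpec(use_mfe="off", use_bias="off", use_count=False, use_id=False)


def test_restrict_bias_subset(rng):
    records, seqs = _dataset(rng, 50)
    spec = FeatureBlockSpec(use_mfe="whole", use_bias="all", use_count=True, use_id=True)
    X = assemble_feature_matrix(records, seqs, spec)

    fifteen = list(ALL_CODONS[:15])
    sub = restrict_bias_subset(X, fifteen)
    start, stop = sub.block_span("bias")
    assert stop - start == 15
    assert sub.n_features == X.n_features - 64 + 15

    identity = restrict_bias_subset(X, list(ALL_CODONS))
    assert np.array_equal(identity.values, X.values)
    assert identity.columns == X.columns

    two = restrict_bias_subset(X, ["GCG", "CTG"])
    for codon in ("GCG", "CTG"):
        orig = X.values[:, X.columns.index(f"bias_{codon}")]
        new = two.values[:, two.columns.index(f"bias_{codon}")]
        assert np.array_equal(orig, new)
    # count and id blocks untouched
    for block in ("count", "id"):
        a0, a1 = X.block_span(block)
        b0, b1 = two.block_span(block)
        assert np.array_equal(X.values[:, a0:a1], two.values[:, b0:b1])

    with pytest.raises(KeyError):
        restrict_bias_subset(two, ["AAA"])


def test_invalid_sequences_are_hard_errors():
    with pytest.raises(InvalidSequenceError):
        CodingSequence("s", "ATGN")
    with pytest.raises(InvalidSequenceError):
        CodingSequence("s", "AT")
    with pytest.raises(InvalidSequenceError):
        CodingSequence("s", "")
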