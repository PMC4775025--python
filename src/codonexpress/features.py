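"""Codon-derived feature encodings for expression prediction.

Four feature blocks are supported, concatenated in the fixed order
[MFE | bias | count | codon-ID]:

* **MFE** — one ingested folding minimum-free-energy scalar per sequence
  (whole-mRNA or a 5' window; values come from the input table, never
  computed here).
* **codon bias** — for each of the 64 codons, the frequency of that codon
  relative to all codons encoding the same amino acid in that sequence.
  Stored as fractions in [0, 1]; a codon whose amino-acid group is absent
  from the sequence gets 0.
* **codon count** — the number of occurrences of each of the 64 codons.
* **codon identification** — one integer in 1..64 per codon position,
  following a 4-ary-tree ordering over the letters A, C, G, T in which
  similar codons receive nearby numbers (AAA=1 ... TTT=64). The block
  width equals the shared codon length of the dataset, so all sequences
  must have the same length.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequences import (
    CodingSequence,
    ExpressionRecord,
    InvalidSequenceError,
    normalize_nucleotides,
    standard_genetic_code,
)

__all__ = [
    "FeatureBlockSpec",
    "FeatureMatrix",
    "ALL_CODONS",
    "codon_identification",
    "codon_from_identification",
    "codon_id_vector",
    "codon_count",
    "codon_bias",
    "assemble_feature_matrix",
    "restrict_bias_subset",
]

_LETTER_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

#: All 64 codons in identification-number order (AAA, AAC, ..., TTT).
ALL_CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)


def codon_identification(codon: str) -> int:
    """Identification number in 1..64 of a codon under the 4-ary-tree ordering.

    The number is ``1 + 16*i1 + 4*i2 + i3`` with letter indices
    A=0, C=1, G=2, T=3, i.e. base-4 interpretation of the triplet plus one.
    Accepts lowercase and RNA input.
    """
    norm = normalize_nucleotides(codon)
    if len(norm) != 3:
        raise InvalidSequenceError(f"codon must have 3 nucleotides, got {codon!r}")
    i1, i2, i3 = (_LETTER_INDEX[c] for c in norm)
    return 1 + 16 * i1 + 4 * i2 + i3


def codon_from_identification(number: int) -> str:
    """Inverse of :func:`codon_identification`."""
    if not 1 <= number <= 64:
        raise ValueError(f"identification number must be in 1..64, got {number}")
    return ALL_CODONS[number - 1]


def codon_id_vector(seq: CodingSequence) -> np.ndarray:
    """Identification number of each codon, in frame order (length = len/3)."""
    return np.array([codon_identification(c) for c in seq.codons()], dtype=np.int64)


def codon_count(seq: CodingSequence) -> np.ndarray:
    """Occurrences of each of the 64 codons, indexed by identification number - 1.

    Entries are non-negative integers summing to the sequence's codon count.
    """
    counts = np.zeros(64, dtype=np.int64)
    for c in seq.codons():
        counts[codon_identification(c) - 1] += 1
    return counts


def codon_bias(
    seq: CodingSequence, code: Mapping[str, str] | None = None
) -> np.ndarray:
    """Within-amino-acid codon frequencies, length 64 in identification order.

    Entry for codon c is count(c) divided by the total count of codons
    synonymous with c under ``code``; codons whose amino-acid group does not
    occur in the sequence get 0, so entries within each group present sum to 1.
    """
    code = standard_genetic_code() if code is None else code
    counts = codon_count(seq)
    group_totals: dict[str, int] = {}
    for codon, n in zip(ALL_CODONS, counts):
        aa = code[codon]
        group_totals[aa] = group_totals.get(aa, 0) + int(n)
    bias = np.zeros(64, dtype=float)
    for k, codon in enumerate(ALL_CODONS):
        total = group_totals[code[codon]]
        if total > 0:
            bias[k] = counts[k] / total
    return bias


@dataclass(frozen=True)
class FeatureBlockSpec:
    """Which feature blocks to assemble and how.

    Parameters
    ----------
    use_mfe : {"off", "whole", "window"}
        Which ingested MFE variant to include (one column), if any. Which
        variant predicts better is dataset-dependent, so it is a switch.
    use_bias : {"off", "all"} or sequence of codons
        Full 64-codon bias block, none, or a fixed subset of codons.
    drop_absent_bias_columns : bool
        Remove bias columns for codons absent from every sequence in the
        dataset (e.g. a 61-wide bias block when three codons never occur).
    use_count, use_id : bool
        Include the 64-codon count block / the per-position codon-ID block.
    genetic_code : mapping codon -> amino acid
        Defaults to the standard code with stops grouped under '*'.
    """

    use_mfe: str = "off"
    use_bias: str | Sequence[str] = "all"
    drop_absent_bias_columns: bool = False
    use_count: bool = True
    use_id: bool = True
    genetic_code: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.use_mfe not in ("off", "whole", "window"):
            raise ValueError(f"use_mfe must be off/whole/window, got {self.use_mfe!r}")
        if isinstance(self.use_bias, str):
            if self.use_bias not in ("off", "all"):
                raise ValueError(
                    f"use_bias must be 'off', 'all' or a codon list, got {self.use_bias!r}"
                )
        bias_on = self.use_bias != "off"
        if not (self.use_mfe != "off" or bias_on or self.use_count or self.use_id):
            raise ValueError("at least one feature block must be enabled")

    @property
    def code(self) -> Mapping[str, str]:
        return self.genetic_code if self.genetic_code is not None else standard_genetic_code()

    def bias_codons(self) -> list[str]:
        if self.use_bias == "off":
            return []
        if self.use_bias == "all":
            return list(ALL_CODONS)
        return [normalize_nucleotides(c) for c in self.use_bias]


@dataclass(frozen=True)
class FeatureMatrix:
    """Patterns x features with named blocks and column labels.

    ``blocks`` is an ordered list of (block name, column span) whose spans
    sum to the number of columns. Column names are block-prefixed
    (``mfe``, ``bias_AAA``, ``count_AAA``, ``id_pos_001`` ...).
    """

    values: np.ndarray
    columns: tuple[str, ...]
    blocks: tuple[tuple[str, int], ...]
    pattern_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if v.shape != (len(self.pattern_ids), len(self.columns)):
            raise ValueError(
                f"shape {v.shape} inconsistent with {len(self.pattern_ids)} patterns "
                f"x {len(self.columns)} columns"
            )
        if sum(span for _, span in self.blocks) != len(self.columns):
            raise ValueError("block spans must sum to the number of columns")

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_ids)

    @property
    def n_features(self) -> int:
        return len(self.columns)

    def block_span(self, name: str) -> tuple[int, int]:
        """Half-open column range [start, stop) of a named block."""
        start = 0
        for bname, span in self.blocks:
            if bname == name:
                return start, start + span
            start += span
        raise KeyError(f"no block named {name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.pattern_ids), columns=list(self.columns))

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "id"
        df.to_csv(path)


def assemble_feature_matrix(
    records: Sequence[ExpressionRecord],
    seqs: Sequence[CodingSequence],
    spec: FeatureBlockSpec,
) -> FeatureMatrix:
    """Assemble the enabled feature blocks into one patterns x features matrix.

    Records and sequences must align one-to-one by identifier (same order)
    and all sequences must share one length — the codon-ID block forbids
    mixed lengths. Columns are ordered [MFE | bias | count | codon-ID].
    """
    if len(records) != len(seqs):
        raise ValueError(f"{len(records)} records but {len(seqs)} sequences")
    for r, s in zip(records, seqs):
        if r.identifier != s.identifier:
            raise ValueError(
                f"record/sequence identifier mismatch: {r.identifier!r} vs {s.identifier!r}"
            )
    lengths = {s.n_codons for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences must share one length; found codon counts {sorted(lengths)}")
    n_codons = lengths.pop()
    code = spec.code

    cols: list[np.ndarray] = []
    names: list[str] = []
    blocks: list[tuple[str, int]] = []

    if spec.use_mfe != "off":
        attr = "mfe_whole" if spec.use_mfe == "whole" else "mfe_window"
        vals = []
        for r in records:
            v = getattr(r, attr)
            if v is None:
                raise ValueError(f"{r.identifier!r}: MFE ({spec.use_mfe}) requested but missing")
            vals.append(v)
        cols.append(np.asarray(vals, dtype=float)[:, None])
        names.append("mfe")
        blocks.append(("mfe", 1))

    if spec.use_bias != "off":
        full = np.vstack([codon_bias(s, code) for s in seqs])
        keep = spec.bias_codons()
        idx = [codon_identification(c) - 1 for c in keep]
        sub = full[:, idx]
        kept_codons = keep
        if spec.drop_absent_bias_columns:
            present = sub.sum(axis=0) > 0
            sub = sub[:, present]
            kept_codons = [c for c, p in zip(keep, present) if p]
        cols.append(sub)
        names.extend(f"bias_{c}" for c in kept_codons)
        blocks.append(("bias", sub.shape[1]))

    if spec.use_count:
        counts = np.vstack([codon_count(s) for s in seqs]).astype(float)
        cols.append(counts)
        names.extend(f"count_{c}" for c in ALL_CODONS)
        blocks.append(("count", 64))

    if spec.use_id:
        ids = np.vstack([codon_id_vector(s) for s in seqs]).astype(float)
        cols.append(ids)
        names.extend(f"id_pos_{k + 1:03d}" for k in range(n_codons))
        blocks.append(("id", n_codons))

    values = np.hstack(cols)
    return FeatureMatrix(
        values=values,
        columns=tuple(names),
        blocks=tuple(blocks),
        pattern_ids=tuple(s.identifier for s in seqs),
    )


def restrict_bias_subset(matrix: FeatureMatrix, codons: Sequence[str]) -> FeatureMatrix:
    """Reduce the bias block to the given codons, leaving other blocks untouched.

    Mirrors "selected codon bias": the configurable subset of codons whose
    bias enters the model (the exact subset of the original study is a user
    input, never a default here).
    """
    start, stop = matrix.block_span("bias")
    wanted = [f"bias_{normalize_nucleotides(c)}" for c in codons]
    bias_cols = list(matrix.columns[start:stop])
    missing = [w for w in wanted if w not in bias_cols]
    if missing:
        raise KeyError(f"codons not in bias block: {missing}")
    keep_idx = [start + bias_cols.index(w) for w in wanted]
    other_idx = [i for i in range(matrix.n_features) if not (start <= i < stop)]
    new_order = (
        list(range(start))  # blocks before bias, in place
        + keep_idx
        + [i for i in other_idx if i >= stop]
    )
    new_blocks = tuple(
        (name, len(wanted)) if name == "bias" else (name, span)
        for name, span in matrix.blocks
    )
    return FeatureMatrix(
        values=matrix.values[:, new_order],
        columns=tuple(matrix.columns[i] for i in new_order),
        blocks=new_blocks,
        pattern_ids=matrix.pattern_ids,
    )
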