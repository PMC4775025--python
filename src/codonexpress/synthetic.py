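"""Synthetic datasets of synonymous codon encodings with known expression signal.

The generator emulates the structure the pipeline assumes: many
same-length synonymous encodings of one protein, with expression driven
by a known function of codon-bias features plus an MFE-like covariate.
One random amino-acid sequence is drawn; each variant re-encodes it by
choosing uniformly at random among the synonymous codons at every
position (plus one stop codon). Expression is

    y_i = exp( sum_f w_f * x_{i,f}  +  noise ),  noise ~ N(0, noise_sd)

over codon-bias features and an MFE surrogate. The exponential link
keeps expression positive (absolute percentage error needs y > 0) and
mimics the wide dynamic ranges of real expression measurements. The MFE
surrogate is a negative scaled GC fraction of the first 42 nucleotides —
GC-rich 5' ends fold more stably (lower minimum free energy), which is
the dependency real 5'-window folding energies carry, without running a
folding engine. It is stored in the records' ``mfe_window`` slot (a
whole-sequence GC surrogate fills ``mfe_whole``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .features import (
    ALL_CODONS,
    FeatureBlockSpec,
    FeatureMatrix,
    assemble_feature_matrix,
    codon_bias,
)
from .sequences import (
    CodingSequence,
    ExpressionRecord,
    standard_genetic_code,
    synonymous_groups,
)

__all__ = [
    "GeneratorConfig",
    "DEFAULT_WEIGHTS",
    "generate_synonymous_variants",
    "mfe_surrogate",
    "generate_expression",
    "make_benchmark",
]

#: Default generating weights: bias of common leucine/alanine/arginine codons
#: plus the 5'-window MFE surrogate. Magnitudes keep the exponential link's
#: dynamic range around one decade, comparable to real expression panels.
DEFAULT_WEIGHTS: dict[str, float] = {
    "bias_CTG": 1.0,
    "bias_GCG": -1.0,
    "bias_CGT": 0.8,
    "mfe": 0.1,
}

_WINDOW_NT = 42
_MFE_SCALE = 10.0  # kcal/mol-like magnitude for the GC surrogate


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    Defaults match the scale of the larger of the two published panels the
    pipeline targets: 150 variants of a ~95-amino-acid protein, moderate
    log-scale noise.
    """

    aa_length: int = 95
    n_variants: int = 150
    seed: int = 0
    weight_spec: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    noise_sd: float = 0.3
    nonlinearity: str = "none"

    def __post_init__(self) -> None:
        if self.aa_length < 1:
            raise ValueError("aa_length must be >= 1")
        if self.n_variants < 2:
            raise ValueError("n_variants must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.nonlinearity not in ("none", "saturating"):
            raise ValueError(f"nonlinearity must be 'none' or 'saturating', got {self.nonlinearity!r}")


def generate_synonymous_variants(
    cfg: GeneratorConfig, code: Mapping[str, str] | None = None
) -> list[CodingSequence]:
    """Draw one protein and ``n_variants`` synonymous encodings of it.

    The amino-acid sequence (length ``aa_length``, uniform over the 20
    amino acids) is terminated by one stop codon; every variant picks each
    position's codon uniformly among the synonymous choices. Reproducible
    from ``cfg.seed``.
    """
    code = standard_genetic_code() if code is None else code
    groups = synonymous_groups(code)
    amino_acids = sorted(aa for aa in groups if aa != "*")
    rng = np.random.default_rng(cfg.seed)
    protein = [amino_acids[i] for i in rng.integers(0, len(amino_acids), size=cfg.aa_length)]
    protein.append("*")
    variants = []
    for v in range(cfg.n_variants):
        codons = [groups[aa][rng.integers(0, len(groups[aa]))] for aa in protein]
        variants.append(CodingSequence(f"variant_{v + 1:04d}", "".join(codons)))
    return variants


def _gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def mfe_surrogate(seq: CodingSequence, window_nt: int = _WINDOW_NT) -> float:
    """Negative scaled GC fraction of the first ``window_nt`` nucleotides."""
    window = seq.nucleotides[:window_nt]
    return -_MFE_SCALE * _gc_fraction(window)


def generate_expression(
    seqs: list[CodingSequence],
    cfg: GeneratorConfig,
    code: Mapping[str, str] | None = None,
) -> list[ExpressionRecord]:
    """Expression for each variant from the configured weights plus noise.

    ``weight_spec`` keys are bias feature names (``bias_AAA`` ...) and
    ``"mfe"`` for the 5'-window surrogate. With ``nonlinearity="saturating"``
    the linear predictor is passed through tanh before exponentiation.
    """
    code = standard_genetic_code() if code is None else code
    for name in cfg.weight_spec:
        if name != "mfe" and not (name.startswith("bias_") and name[5:] in ALL_CODONS):
            raise ValueError(f"unknown weight name {name!r}")
    codon_index = {c: i for i, c in enumerate(ALL_CODONS)}
    rng = np.random.default_rng(cfg.seed + 1)  # independent of codon choices
    noise = rng.normal(0.0, cfg.noise_sd, size=len(seqs)) if cfg.noise_sd > 0 else np.zeros(len(seqs))
    records = []
    for seq, eps in zip(seqs, noise):
        bias = codon_bias(seq, code)
        mfe_win = mfe_surrogate(seq)
        z = 0.0
        for name, w in cfg.weight_spec.items():
            if name == "mfe":
                z += w * mfe_win
            else:
                z += w * bias[codon_index[name[5:]]]
        if cfg.nonlinearity == "saturating":
            z = float(np.tanh(z))
        records.append(
            ExpressionRecord(
                identifier=seq.identifier,
                expression=float(np.exp(z + eps)),
                mfe_whole=-_MFE_SCALE * _gc_fraction(seq.nucleotides),
                mfe_window=mfe_win,
            )
        )
    return records


def make_benchmark(
    cfg: GeneratorConfig,
    feature_spec: FeatureBlockSpec | None = None,
) -> tuple[FeatureMatrix, np.ndarray, dict]:
    """End-to-end dataset plus the generating ground truth.

    Returns the assembled feature matrix (default blocks: window MFE, full
    bias, count, codon-ID), the expression vector, and a ground-truth record
    with the weights, noise level and seed, for parameter-recovery tests.
    """
    if feature_spec is None:
        feature_spec = FeatureBlockSpec(use_mfe="window", use_bias="all", use_count=True, use_id=True)
    seqs = generate_synonymous_variants(cfg)
    records = generate_expression(seqs, cfg)
    X = assemble_feature_matrix(records, seqs, feature_spec)
    y = np.array([r.expression for r in records])
    truth = {
        "weights": dict(cfg.weight_spec),
        "noise_sd": cfg.noise_sd,
        "seed": cfg.seed,
        "aa_length": cfg.aa_length,
        "n_variants": cfg.n_variants,
        "nonlinearity": cfg.nonlinearity,
        "protein": seqs[0].translate(),
    }
    return X, y, truth
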