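"""Synthetic fixtures with the statistical structure the pipeline assumes.

Protein classes differ only through a residue-composition bias, so class
signal reaches the classifier exclusively through the descriptor blocks —
exercising descriptor computation, selection and classification end to end.
Expression data emulates a paired tumour/normal microarray cohort (43 pairs
by default) with planted two-fold effects on a log-normal baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .biomarker import ExpressionMatrix
from .descriptors import DescriptorConfig, featurize
from .scales import AA_ALPHABET
from .seqio import Annotations, ProteinRecord

__all__ = [
    "SynthSpec",
    "generate_sequences",
    "generate_labeled_features",
    "generate_expression",
]

#: residues counted as hydrophobic for the default positive-class bias
HYDROPHOBIC = "AVILMFWC"


@dataclass
class SynthSpec:
    """Parameters of the synthetic corpus; all generators are pure in (spec, seed)."""

    seed: int = 0
    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (80, 600)
    pos_bias: dict[str, float] = field(default_factory=dict)
    n_families: int = 20
    # expression block
    n_genes: int = 1000
    m_pairs: int = 43
    n_de: int = 100
    true_fc: float = 2.0
    noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0 or self.n_pos + self.n_neg == 0:
            raise ValueError("need at least one sequence")
        lo, hi = self.length_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid length range")
        if any(w <= 0 for w in self.pos_bias.values()):
            raise ValueError("bias weights must be positive")
        if self.n_families < 1 or self.n_genes < 1 or self.m_pairs < 1:
            raise ValueError("counts must be positive")
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.true_fc <= 0 or self.noise_sd < 0:
            raise ValueError("invalid expression parameters")

    @staticmethod
    def hydrophobic_bias(multiplier: float = 3.0) -> dict[str, float]:
        """Convenience bias: multiply hydrophobic residue weights."""
        return {aa: multiplier for aa in HYDROPHOBIC}


def _composition(bias: dict[str, float]) -> np.ndarray:
    w = np.ones(20)
    for aa, mult in bias.items():
        w[AA_ALPHABET.index(aa)] *= mult
    return w / w.sum()


def generate_sequences(spec: SynthSpec) -> list[ProteinRecord]:
    """Sample labeled protein records; positives first, then negatives.

    Residues are drawn i.i.d. from a uniform base composition, multiplied by
    the positive-class bias for positives; lengths are uniform in
    ``length_range``. Families are assigned round-robin within each class
    (classes never share a family, mirroring the saliva-clean negative
    families); positives carry saliva evidence and all records get a plasma
    peptide count.
    """
    rng = np.random.default_rng(spec.seed)
    aas = np.array(list(AA_ALPHABET))
    comp_pos = _composition(spec.pos_bias)
    comp_neg = _composition({})
    lo, hi = spec.length_range
    n_fam_pos = max(1, spec.n_families // 2)
    n_fam_neg = max(1, spec.n_families - n_fam_pos)
    records: list[ProteinRecord] = []
    for i in range(spec.n_pos + spec.n_neg):
        positive = i < spec.n_pos
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(aas, size=L, p=comp_pos if positive else comp_neg))
        if positive:
            family = f"FP{i % n_fam_pos:04d}"
        else:
            family = f"FN{(i - spec.n_pos) % n_fam_neg:04d}"
        ann = Annotations(
            family_ids=[family],
            saliva_evidence=positive,
            peptide_count=int(rng.integers(0, 16)),
        )
        label = "P" if positive else "N"
        records.append(ProteinRecord(id=f"{label}{i:05d}", sequence=seq, annotations=ann))
    return records


@dataclass
class LabeledDataset:
    X: pd.DataFrame
    y: np.ndarray  # ±1
    ids: list[str]


def generate_labeled_features(
    spec: SynthSpec, config: DescriptorConfig | None = None
) -> LabeledDataset:
    """Sequences → descriptor matrix → ±1 labels, with no label leakage:
    class signal exists only through the residue-composition bias."""
    records = generate_sequences(spec)
    X = featurize(records, config)
    y = np.array([1 if r.id.startswith("P") else -1 for r in records])
    return LabeledDataset(X=X, y=y, ids=[r.id for r in records])


def generate_expression(spec: SynthSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Paired case/control expression with planted fold changes.

    Per-gene baselines are log-normal (meanlog 7, sdlog 1); control values
    scatter around the baseline and case values around baseline × fc_true,
    both with log-normal noise of sd ``noise_sd``. The first ``n_de`` genes
    carry the planted effect, half up-regulated at ``true_fc`` and half down
    at its reciprocal; a truth table accompanies the matrix.
    """
    rng = np.random.default_rng(spec.seed + 1)
    g, m = spec.n_genes, spec.m_pairs
    baseline = np.exp(rng.normal(7.0, 1.0, size=g))
    fc_true = np.ones(g)
    n_up = spec.n_de // 2 + spec.n_de % 2
    fc_true[:n_up] = spec.true_fc
    fc_true[n_up: spec.n_de] = 1.0 / spec.true_fc
    control = baseline[:, None] * np.exp(rng.normal(0.0, spec.noise_sd, size=(g, m)))
    case = (
        control
        * fc_true[:, None]
        * np.exp(rng.normal(0.0, spec.noise_sd, size=(g, m)))
    )
    gene_ids = [f"G{i:05d}" for i in range(g)]
    expr = ExpressionMatrix(gene_ids=gene_ids, case=case, control=control)
    truth = pd.DataFrame(
        {"gene": gene_ids, "true_fc": fc_true, "is_de": (fc_true != 1.0).astype(int)}
    )
    return expr, truth
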