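"""Sequence-derived descriptors for blood→saliva transferability prediction.

Each protein is mapped to a fixed-length real vector assembled from toggleable
blocks: amino-acid and dipeptide composition, three autocorrelation families
over eight physicochemical scales, composition/transition/distribution (CTD)
over seven 3-class groupings, global physicochemical summaries, a fold-index
disorder profile, secondary-structure content, a radius-of-gyration scaling
estimate, and a twin-arginine (TAT) motif flag. The default configuration
yields 1,302 feature elements; the breakdown is 20 (AAC) + 400 (DPC) +
3×8×30 = 720 (autocorrelation) + 7×21 = 147 (CTD) + 8 (physicochemical) +
2 (disorder) + 3 (secondary structure) + 1 (radius) + 1 (TAT).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .scales import (
    AA_ALPHABET,
    AA_INDEX,
    CHARGE,
    CHOU_FASMAN,
    DEFAULT_GROUPINGS,
    DEFAULT_SCALES,
    FOLDINDEX_CHARGE,
    KD_HYDROPHOBICITY,
    POLARITY,
    POLARIZABILITY,
    VDW_VOLUME,
    GroupingScheme,
    PropertyScale,
)
from .seqio import ProteinRecord

log = logging.getLogger(__name__)

AUTOCORR_METHODS = ("moreau_broto", "moran", "geary")

_TAT_RE = re.compile(r"[ST]RR.FLK")
_TAT_WINDOW = 35


def _seq_indices(sequence: str) -> np.ndarray:
    try:
        return np.fromiter((AA_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence))
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r} in sequence") from exc


def aa_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 20 amino acids; sums to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    idx = _seq_indices(sequence)
    counts = np.bincount(idx, minlength=20).astype(float)
    return counts / len(sequence)


def dipeptide_composition(sequence: str) -> np.ndarray:
    """Fraction of each of the 400 ordered residue pairs; sums to 1."""
    if len(sequence) < 2:
        raise ValueError("dipeptide composition requires length >= 2")
    idx = _seq_indices(sequence)
    pair = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair, minlength=400).astype(float)
    return counts / (len(sequence) - 1)


def autocorrelation(
    sequence: str, scale: PropertyScale, method: str, lag: int
) -> float:
    """Sequence-order autocorrelation of a standardized property at one lag.

    ``moreau_broto`` is the normalized Moreau–Broto product sum; ``moran``
    and ``geary`` are the spatial-statistics analogues. When every residue
    carries the same property value the Moran/Geary denominators vanish and
    0 is returned by convention.
    """
    if method not in AUTOCORR_METHODS:
        raise ValueError(f"method must be one of {AUTOCORR_METHODS}")
    L = len(sequence)
    if not 1 <= lag <= L - 1:
        raise ValueError(f"lag {lag} out of range for sequence of length {L}")
    p = scale.values(standardized=True)[_seq_indices(sequence)]
    if method == "moreau_broto":
        return float(np.dot(p[:-lag], p[lag:]) / (L - lag))
    pbar = p.mean()
    dev = p - pbar
    if method == "moran":
        denom = np.dot(dev, dev) / L
        if denom == 0.0:
            return 0.0
        num = np.dot(dev[:-lag], dev[lag:]) / (L - lag)
        return float(num / denom)
    # geary
    denom = np.dot(dev, dev) / (L - 1)
    if denom == 0.0:
        return 0.0
    diff = p[:-lag] - p[lag:]
    num = np.dot(diff, diff) / (2.0 * (L - lag))
    return float(num / denom)


def ctd(sequence: str, grouping: GroupingScheme) -> np.ndarray:
    """Composition/transition/distribution over a 3-class grouping.

    Returns 21 values: 3 class fractions, 3 unordered transition fractions
    (pairs (1,2), (1,3), (2,3), denominator L−1) and, per class, the
    chain-length fractions of its first, 25%, 50%, 75% and last occurrence.
    The k% occurrence is the ceil(k·n_c/100)-th (at least first) position of
    that class; a class absent from the sequence contributes five zeros.
    """
    if not sequence:
        raise ValueError("empty sequence")
    cls_map = grouping.class_of()
    classes = np.fromiter((cls_map[c] for c in sequence), dtype=np.intp, count=len(sequence))
    L = len(sequence)
    comp = np.bincount(classes, minlength=3).astype(float) / L

    trans = np.zeros(3)
    if L >= 2:
        a, b = classes[:-1], classes[1:]
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        pairs = {(0, 1): 0, (0, 2): 1, (1, 2): 2}
        for (i, j), slot in pairs.items():
            trans[slot] = np.sum((lo == i) & (hi == j)) / (L - 1)

    dist = np.zeros(15)
    for k in range(3):
        pos = np.flatnonzero(classes == k) + 1  # 1-based
        n_c = len(pos)
        if n_c == 0:
            continue
        for slot, frac in enumerate((0.0, 0.25, 0.50, 0.75, 1.0)):
            j = max(1, math.ceil(frac * n_c))
            dist[5 * k + slot] = pos[j - 1] / L
    return np.concatenate([comp, trans, dist])


def physico_summary(sequence: str) -> np.ndarray:
    """Global physicochemical summary (8 values).

    Mean Kyte–Doolittle hydropathy, net side-chain charge at pH 7
    (#K,R + 0.1·#H − #D,E), mean Grantham polarity, mean van der Waals
    volume, mean polarizability, isoelectric point, molecular weight (Da)
    and sequence length.
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    mean_of = lambda table: sum(table[c] for c in sequence) / L
    net_charge = sum(CHARGE[c] for c in sequence)
    pa = ProteinAnalysis(sequence)
    return np.array(
        [
            mean_of(KD_HYDROPHOBICITY),
            net_charge,
            mean_of(POLARITY),
            mean_of(VDW_VOLUME),
            mean_of(POLARIZABILITY),
            pa.isoelectric_point(),
            pa.molecular_weight(),
            float(L),
        ]
    )


def disorder_profile(sequence: str, window: int = 21) -> tuple[float, float]:
    """Fold-index disorder summary: (mean fold index, disordered fraction).

    Per residue, FI = 2.785·⟨H⟩ − |⟨q⟩| − 1.151 where ⟨H⟩ is the windowed
    mean Kyte–Doolittle hydropathy rescaled to [0,1] and ⟨q⟩ the windowed
    mean net charge per residue; windows are truncated at the termini.
    Residues with FI < 0 count as disordered.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    L = len(sequence)
    h = np.array([(KD_HYDROPHOBICITY[c] + 4.5) / 9.0 for c in sequence])
    q = np.array([FOLDINDEX_CHARGE[c] for c in sequence])
    half = window // 2
    # cumulative sums give truncated-window means in O(L)
    ch = np.concatenate([[0.0], np.cumsum(h)])
    cq = np.concatenate([[0.0], np.cumsum(q)])
    i = np.arange(L)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, L)
    n = (hi - lo).astype(float)
    mh = (ch[hi] - ch[lo]) / n
    mq = (cq[hi] - cq[lo]) / n
    fi = 2.785 * mh - np.abs(mq) - 1.151
    return float(fi.mean()), float(np.mean(fi < 0))


_SS_CLASS = {}
for _aa, (_h, _e, _c) in CHOU_FASMAN.items():
    best = max(_h, _e, _c)
    # ties resolve to coil
    if _c == best:
        _SS_CLASS[_aa] = 2
    elif _h == best and _h > _e:
        _SS_CLASS[_aa] = 0
    elif _e == best and _e > _h:
        _SS_CLASS[_aa] = 1
    else:  # helix/sheet tie
        _SS_CLASS[_aa] = 2


def ss_composition(sequence: str) -> np.ndarray:
    """Helix/sheet/coil content from per-residue Chou–Fasman propensities."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(3)
    for c in sequence:
        counts[_SS_CLASS[c]] += 1
    return counts / len(sequence)


def radius_estimate(length: int, coefficient: float = 2.2, exponent: float = 0.38) -> float:
    """Radius-of-gyration estimate (Å) from the compact-globule scaling law
    R = coefficient · L^exponent."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return coefficient * length**exponent


def tat_motif(sequence: str) -> bool:
    """True iff the twin-arginine export motif [S/T]-R-R-x-F-L-K starts
    within the first 35 residues."""
    m = _TAT_RE.search(sequence[: _TAT_WINDOW + 6])
    return bool(m and m.start() < _TAT_WINDOW)


@dataclass
class DescriptorConfig:
    """Which blocks to compute and with what parameters."""

    aac: bool = True
    dpc: bool = True
    autocorr: bool = True
    ctd: bool = True
    physico: bool = True
    disorder: bool = True
    ss: bool = True
    radius: bool = True
    tat: bool = True
    d_max: int = 30
    scales: Sequence[PropertyScale] = field(default_factory=lambda: list(DEFAULT_SCALES))
    groupings: Sequence[GroupingScheme] = field(default_factory=lambda: list(DEFAULT_GROUPINGS))

    def __post_init__(self) -> None:
        if self.d_max < 1:
            raise ValueError("d_max must be >= 1")

    def column_names(self) -> list[str]:
        names: list[str] = []
        if self.aac:
            names += [f"aac.{a}" for a in AA_ALPHABET]
        if self.dpc:
            names += [f"dpc.{a}{b}" for a in AA_ALPHABET for b in AA_ALPHABET]
        if self.autocorr:
            for method in AUTOCORR_METHODS:
                for sc in self.scales:
                    names += [f"{method}.{sc.name}.lag{d}" for d in range(1, self.d_max + 1)]
        if self.ctd:
            for g in self.groupings:
                names += [f"ctd.{g.name}.comp{k}" for k in (1, 2, 3)]
                names += [f"ctd.{g.name}.trans{p}" for p in ("12", "13", "23")]
                names += [
                    f"ctd.{g.name}.dist{k}.{pct}"
                    for k in (1, 2, 3)
                    for pct in ("first", "p25", "p50", "p75", "last")
                ]
        if self.physico:
            names += [
                "phys.mean_hydrophobicity", "phys.net_charge", "phys.mean_polarity",
                "phys.mean_vdw_volume", "phys.mean_polarizability",
                "phys.isoelectric_point", "phys.molecular_weight", "phys.length",
            ]
        if self.disorder:
            names += ["disorder.mean_fold_index", "disorder.fraction"]
        if self.ss:
            names += ["ss.helix", "ss.sheet", "ss.coil"]
        if self.radius:
            names += ["radius.gyration"]
        if self.tat:
            names += ["motif.tat"]
        return names

    @property
    def dimension(self) -> int:
        return len(self.column_names())


def _featurize_one(sequence: str, config: DescriptorConfig) -> np.ndarray:
    parts: list[np.ndarray] = []
    L = len(sequence)
    if config.aac:
        parts.append(aa_composition(sequence))
    if config.dpc:
        parts.append(dipeptide_composition(sequence))
    if config.autocorr:
        feasible = min(config.d_max, L - 1)
        if feasible < config.d_max:
            log.warning(
                "sequence of length %d shorter than d_max=%d; lags > %d set to 0",
                L, config.d_max, feasible,
            )
        for method in AUTOCORR_METHODS:
            for sc in config.scales:
                vals = np.zeros(config.d_max)
                for d in range(1, feasible + 1):
                    vals[d - 1] = autocorrelation(sequence, sc, method, d)
                parts.append(vals)
    if config.ctd:
        for g in config.groupings:
            parts.append(ctd(sequence, g))
    if config.physico:
        parts.append(physico_summary(sequence))
    if config.disorder:
        parts.append(np.array(disorder_profile(sequence)))
    if config.ss:
        parts.append(ss_composition(sequence))
    if config.radius:
        parts.append(np.array([radius_estimate(L)]))
    if config.tat:
        parts.append(np.array([float(tat_motif(sequence))]))
    return np.concatenate(parts)


def featurize(
    records: Iterable[ProteinRecord], config: DescriptorConfig | None = None
) -> pd.DataFrame:
    """Compute the descriptor matrix for a set of proteins.

    Rows follow input order (indexed by accession), columns are the stable
    self-describing names from ``DescriptorConfig.column_names``. Any
    per-record failure aborts with the offending accession.
    """
    config = config or DescriptorConfig()
    cols = config.column_names()
    ids, rows = [], []
    for rec in records:
        try:
            rows.append(_featurize_one(rec.sequence, config))
        except Exception as exc:
            raise ValueError(f"featurization failed for record {rec.id!r}: {exc}") from exc
        ids.append(rec.id)
    if not ids:
        raise ValueError("no records to featurize")
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(ids, name="id"), columns=cols)
    if not np.isfinite(X.to_numpy()).all():
        bad = X.index[~np.isfinite(X.to_numpy()).all(axis=1)].tolist()
        raise ValueError(f"non-finite descriptor values for records: {bad}")
    return X
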