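"""Training-set construction from family annotations.

Positives are expanded by recruiting, per seed family, up to five additional
low-identity (<30%) members — the most sequence-distant ones — and negatives
are drawn from families with no saliva evidence whose members have solid
plasma-detection support (peptide count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from .seqio import ProteinRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainSetSpec:
    max_per_family: int = 5
    max_identity_pct: float = 30.0
    min_peptides: int = 5
    negatives_per_family: int = 5

    def __post_init__(self) -> None:
        if self.max_per_family < 1 or self.min_peptides < 1 or self.negatives_per_family < 1:
            raise ValueError("all TrainSetSpec counts must be positive")
        if not 0 < self.max_identity_pct <= 100:
            raise ValueError("max_identity_pct must be in (0, 100]")


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="global")
    a.match_score = 1
    a.mismatch_score = 0
    a.open_gap_score = -10
    a.extend_gap_score = -0.5
    return a


_ALIGNER = _aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity over a global alignment (match +1, mismatch 0,
    gap open −10, gap extend −0.5): identical pairs / alignment columns × 100."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = aln.length
    return 100.0 * counts.identities / columns


def _families(record: ProteinRecord) -> list[str]:
    if record.annotations is None:
        return []
    return record.annotations.family_ids


def expand_positives(
    seeds: Sequence[ProteinRecord],
    pool: Sequence[ProteinRecord],
    spec: TrainSetSpec = TrainSetSpec(),
) -> list[ProteinRecord]:
    """Augment seed positives with distant same-family members.

    For each family seen among the seeds, pool members of that family whose
    identity to every seed of the family is below ``max_identity_pct`` are
    ranked by increasing maximum identity to those seeds (ties by accession)
    and the ``max_per_family`` most distant are recruited.
    """
    seed_ids = {s.id for s in seeds}
    fam_seeds: dict[str, list[ProteinRecord]] = {}
    for s in seeds:
        fams = _families(s)
        if not fams:
            log.warning("seed %s has no family annotation; kept without expansion", s.id)
        for f in fams:
            fam_seeds.setdefault(f, []).append(s)

    out = list(seeds)
    chosen: set[str] = set(seed_ids)
    for fam in fam_seeds:  # insertion order = seed order, deterministic
        fseeds = fam_seeds[fam]
        scored = []
        for cand in pool:
            if cand.id in chosen or fam not in _families(cand):
                continue
            ident = max(pairwise_identity(cand.sequence, s.sequence) for s in fseeds)
            if ident < spec.max_identity_pct:
                scored.append((ident, cand.id, cand))
        scored.sort(key=lambda t: (t[0], t[1]))
        for _, _, cand in scored[: spec.max_per_family]:
            out.append(cand)
            chosen.add(cand.id)
    return out


def select_negatives(
    pool: Sequence[ProteinRecord],
    saliva_ids: Iterable[str] = (),
    spec: TrainSetSpec = TrainSetSpec(),
) -> list[ProteinRecord]:
    """Pick negatives from families untouched by saliva evidence.

    A family is contaminated if any member is in ``saliva_ids`` or carries a
    saliva_evidence flag; proteins belonging to any contaminated family are
    excluded outright. Remaining family members with at least ``min_peptides``
    plasma peptides are taken, up to ``negatives_per_family`` per family in
    accession order.
    """
    saliva_ids = set(saliva_ids)
    members: dict[str, list[ProteinRecord]] = {}
    contaminated: set[str] = set()
    for rec in pool:
        for fam in _families(rec):
            members.setdefault(fam, []).append(rec)
            if rec.id in saliva_ids or (
                rec.annotations is not None and rec.annotations.saliva_evidence
            ):
                contaminated.add(fam)

    out: list[ProteinRecord] = []
    seen: set[str] = set()
    for fam in sorted(members):
        if fam in contaminated:
            continue
        eligible = [
            r
            for r in members[fam]
            if r.annotations is not None
            and r.annotations.peptide_count >= spec.min_peptides
            and not any(f in contaminated for f in _families(r))
        ]
        eligible.sort(key=lambda r: r.id)
        taken = 0
        for r in eligible:
            if taken >= spec.negatives_per_family:
                break
            if r.id not in seen:
                out.append(r)
                seen.add(r.id)
                taken += 1
    if not out:
        log.warning("negative selection produced an empty set")
    return out
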