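"""Redundancy removal at a pairwise sequence-identity cutoff.

Pairwise identity comes from a global alignment scored match +1,
mismatch 0, gap open -10, gap extend -1 (no substitution matrix); the
identity fraction divides the match count by, by default, the shorter
sequence's length (the CD-HIT convention). Deduplication is greedy:
records are visited longest-first (ties broken by id) and kept only if
below the threshold against every already-kept representative; absorbed
records join the first representative that matched them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from Bio import Align

from mybfam.seqio import ProteinRecord

Denominator = Literal["shorter", "alignment", "longer"]
Mode = Literal["global", "local"]


@dataclass(frozen=True)
class IdentityResult:
    id_a: str
    id_b: str
    identity: float
    aligned_length: int


def _make_aligner(mode: Mode) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -1
    return aligner


def pairwise_identity(
    a: ProteinRecord,
    b: ProteinRecord,
    denominator: Denominator = "shorter",
    mode: Mode = "global",
) -> IdentityResult:
    """Identity fraction between two proteins from one best alignment."""
    aligner = _make_aligner(mode)
    alignment = aligner.align(a.sequence, b.sequence)[0]
    matches = 0
    columns = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        for x, y in zip(a.sequence[s1:e1], b.sequence[s2:e2]):
            columns += 1
            if x == y:
                matches += 1
    aligned_length = alignment.length
    denom = {
        "shorter": min(len(a), len(b)),
        "longer": max(len(a), len(b)),
        "alignment": aligned_length,
    }[denominator]
    identity = matches / denom if denom else 0.0
    return IdentityResult(a.id, b.id, identity, aligned_length)


def dedupe(
    records: Sequence[ProteinRecord],
    threshold: float = 0.80,
    denominator: Denominator = "shorter",
    mode: Mode = "global",
    identity_fn=None,
) -> tuple[list[ProteinRecord], dict[str, list[str]]]:
    """Greedy redundancy removal at ``threshold`` identity.

    Returns the kept records (in visiting order: length-descending, ties
    by id) and a cluster map representative id -> member ids (the
    representative itself included). ``identity_fn(a, b) -> IdentityResult``
    may replace the alignment-based identity (e.g. precomputed tables).
    """
    if not records:
        raise ValueError("dedupe requires at least one record")
    if identity_fn is None:
        identity_fn = lambda a, b: pairwise_identity(a, b, denominator, mode)
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    kept: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in ordered:
        absorbed_by = None
        for rep in kept:
            res = identity_fn(rec, rep)
            if res.identity >= threshold:
                absorbed_by = rep.id
                break
        if absorbed_by is None:
            kept.append(rec)
            clusters[rec.id] = [rec.id]
        else:
            clusters[absorbed_by].append(rec.id)
    return kept, clusters


def pairwise_table(
    records: Sequence[ProteinRecord],
    denominator: Denominator = "shorter",
    mode: Mode = "global",
) -> list[IdentityResult]:
    """All pairwise identities (upper triangle), for optional export."""
    out = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            out.append(pairwise_identity(a, b, denominator, mode))
    return out
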