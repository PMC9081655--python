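"""Subfamily and type assignment for MYB proteins.

Plant MYBs fall into four subfamilies by the number of tandem R-repeats in
the DNA-binding domain: 1 (or a partial/variant repeat) = MYB-related,
2 = R2R3-MYB, 3 = 3R-MYB, 4 = 4R-MYB. MYB-related proteins are typed by
signature motifs:

* TBP-like      — LKDKW[RK][NT] (telomere-binding-like)
* Myb-CC        — SHLQ[KM]xR plus an LHEQLE coiled-coil region outside
                  the repeat
* GARP-like     — SHLQ[KM]xR alone
* R-R           — SHAQK[YF]F preceded, far upstream, by a repeat whose
                  third tryptophan is replaced by tyrosine
* CCA1-like     — SHAQK[YF]F alone

The type precedence (TBP > Myb-CC > GARP > R-R > CCA1) runs from the most
to the least constrained signature and makes the decision deterministic.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from mybfam.repeat_scan import (
    FULL_REPEAT_CLASSES,
    SIGNATURE_PATTERNS,
    MotifHit,
    RepeatHit,
    ScanConfig,
    detect_repeats,
    find_motif,
)
from mybfam.seqio import ProteinRecord

SUBFAMILIES = ("R2R3", "R3_MYB", "R4_MYB", "MYB_RELATED", "NOT_MYB")
RELATED_TYPES = (
    "CCA1_LIKE",
    "R_R",
    "TBP_LIKE",
    "MYB_CC",
    "GARP_LIKE",
    "UNCLASSIFIED",
)

# motifs that count as classification evidence (EAR is annotation only)
CLASSIFYING_MOTIFS = ("SHAQK", "TBP", "SHLQK", "LHEQLE")


@dataclass(frozen=True)
class ClassifyConfig:
    """Distance parameters for classification.

    tandem_gap
        Max residues between one repeat's end and the next repeat's start
        for the two to count as tandem (chained). Default 10.
    rr_min_separation
        Min residues between the tyrosine-anchored first repeat's end and
        the SHAQK motif's start for the R-R call ("two far apart R").
        Default 40, about one repeat length.
    """

    tandem_gap: int = 10
    rr_min_separation: int = 40
    scan: ScanConfig = field(default_factory=ScanConfig)


@dataclass(frozen=True)
class SubfamilyCall:
    """The classification decision for one protein, with evidence."""

    seq_id: str
    subfamily: str
    related_type: str | None = None
    evidence: tuple = ()
    assigned_name: str | None = None

    def __post_init__(self) -> None:
        if (self.related_type is not None) != (self.subfamily == "MYB_RELATED"):
            raise ValueError(
                "related_type must be present iff subfamily is MYB_RELATED"
            )
        if self.subfamily != "NOT_MYB" and not self.evidence:
            raise ValueError("non-NOT_MYB call requires evidence")


def scan_motifs(seq: ProteinRecord) -> dict[str, list[MotifHit]]:
    """Run all signature-motif scans (excluding EAR) on one sequence."""
    return {
        name: find_motif(seq, SIGNATURE_PATTERNS[name])
        for name in CLASSIFYING_MOTIFS
    }


def _longest_chain(repeats: Sequence[RepeatHit], gap: int) -> list[RepeatHit]:
    """Longest run of full repeats in which each next hit starts no more
    than ``gap`` residues after the previous hit's end."""
    full = [r for r in repeats if r.repeat_class in FULL_REPEAT_CLASSES]
    full.sort(key=lambda r: r.start)
    best: list[RepeatHit] = []
    chain: list[RepeatHit] = []
    for r in full:
        if chain and r.start <= chain[-1].end + gap:
            chain.append(r)
        else:
            chain = [r]
        if len(chain) > len(best):
            best = list(chain)
    return best


def classify_protein(
    seq: ProteinRecord,
    repeats: Sequence[RepeatHit] | None = None,
    motifs: Mapping[str, list[MotifHit]] | None = None,
    config: ClassifyConfig | None = None,
) -> SubfamilyCall:
    """Assign a subfamily (and, for MYB-related, a type) to one protein.

    ``repeats``/``motifs`` may be precomputed; when omitted they are
    scanned here with the config's scan parameters. The decision is a pure
    function of (sequence, config).
    """
    config = config or ClassifyConfig()
    if repeats is None:
        repeats = detect_repeats(seq, config.scan)
    if motifs is None:
        motifs = scan_motifs(seq)

    chain = _longest_chain(repeats, config.tandem_gap)
    if len(chain) >= 4:
        return SubfamilyCall(seq.id, "R4_MYB", evidence=tuple(chain))
    if len(chain) == 3:
        return SubfamilyCall(seq.id, "R3_MYB", evidence=tuple(chain))
    if len(chain) == 2:
        return SubfamilyCall(seq.id, "R2R3", evidence=tuple(chain))

    # MYB-related typing: first rule that fires wins
    def related(type_: str, *ev: object) -> SubfamilyCall:
        return SubfamilyCall(
            seq.id, "MYB_RELATED", related_type=type_, evidence=tuple(ev)
        )

    shaqk = motifs.get("SHAQK", [])
    tbp = motifs.get("TBP", [])
    shlqk = motifs.get("SHLQK", [])
    lheqle = motifs.get("LHEQLE", [])

    if tbp:
        return related("TBP_LIKE", tbp[0])
    lheqle_outside = [
        m
        for m in lheqle
        if all(m.end <= r.start or m.start >= r.end for r in repeats)
    ]
    if shlqk and lheqle_outside:
        return related("MYB_CC", shlqk[0], lheqle_outside[0])
    if shlqk:
        return related("GARP_LIKE", shlqk[0])
    if shaqk:
        rr_firsts = [r for r in repeats if r.repeat_class == "RR_FIRST"]
        for m in shaqk:
            for r in rr_firsts:
                if m.start - r.end >= config.rr_min_separation:
                    return related("R_R", r, m)
        return related("CCA1_LIKE", shaqk[0])

    all_motif_hits = [m for hits in motifs.values() for m in hits]
    if repeats or all_motif_hits:
        return related(
            "UNCLASSIFIED", *(tuple(repeats) + tuple(all_motif_hits))
        )
    return SubfamilyCall(seq.id, "NOT_MYB")


def assign_names(
    calls: Iterable[SubfamilyCall], prefix: str = "CwMYB"
) -> list[SubfamilyCall]:
    """Name members in input order following the plant-MYB convention:
    R2R3 -> ``<prefix>1..n``; MYB-related -> ``<prefix>R1..m``;
    3R -> ``<prefix>3R<k>``; 4R -> ``<prefix>4R<k>``; NOT_MYB unnamed."""
    counters = Counter()
    suffix = {"R2R3": "", "MYB_RELATED": "R", "R3_MYB": "3R", "R4_MYB": "4R"}
    out = []
    for call in calls:
        if call.subfamily in suffix:
            counters[call.subfamily] += 1
            name = f"{prefix}{suffix[call.subfamily]}{counters[call.subfamily]}"
            out.append(replace(call, assigned_name=name))
        else:
            out.append(replace(call, assigned_name=None))
    return out


def summarize_family(calls: Iterable[SubfamilyCall]) -> pd.DataFrame:
    """Family summary table: one row per subfamily / MYB-related type with
    member counts; counts sum to the number of calls."""
    calls = list(calls)
    rows = []
    for sub in SUBFAMILIES:
        members = [c for c in calls if c.subfamily == sub]
        if sub == "MYB_RELATED":
            for typ in RELATED_TYPES:
                n = sum(1 for c in members if c.related_type == typ)
                rows.append({"subfamily": sub, "related_type": typ, "count": n})
        else:
            rows.append({"subfamily": sub, "related_type": "", "count": len(members)})
    return pd.DataFrame(rows, columns=["subfamily", "related_type", "count"])


def calls_to_frame(calls: Iterable[SubfamilyCall]) -> pd.DataFrame:
    """Flatten calls to a TSV-ready table with evidence coordinates."""
    rows = []
    for c in calls:
        ev = []
        for e in c.evidence:
            if isinstance(e, RepeatHit):
                ev.append(f"{e.repeat_class}:{e.start}-{e.end}@{e.anchors}")
            elif isinstance(e, MotifHit):
                ev.append(f"{e.motif_name}:{e.start}-{e.end}")
        rows.append(
            {
                "seq_id": c.seq_id,
                "subfamily": c.subfamily,
                "related_type": c.related_type or "",
                "assigned_name": c.assigned_name or "",
                "evidence": ";".join(ev),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["seq_id", "subfamily", "related_type", "assigned_name", "evidence"],
    )
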