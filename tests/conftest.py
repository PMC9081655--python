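"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by exhaustive enumeration
(every anchor triple, every feasible subset, every sequence window) so the
production scanner is checked against logic that shares none of its code
paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from mybfam.repeat_scan import RepeatHit, ScanConfig
from mybfam.seqio import ProteinRecord

FULL_AA = "ACDEFGHIKLMNPQRSTVWY"

# anchor sets / nominal spacers restated independently of the scanner's
# config tables (priority order)
_ORACLE_CLASSES = [
    ("R2_CONSENSUS", set("W"), set("W"), set("W"), (19, 19)),
    ("R3_CONSENSUS", set("FILM"), set("W"), set("W"), (18, 18)),
    ("RR_FIRST", set("W"), set("W"), set("Y"), (19, 19)),
    ("GENERIC_R", set("WFILM"), set("W"), set("WFY"), (18, 19)),
]


def oracle_candidates(seq: str, slack: int = 1) -> list[tuple]:
    """Every (i, j, k, class) anchor triple, highest-priority class."""
    found: dict[tuple[int, int, int], str] = {}
    for name, a1, a2, a3, (s1, s2) in _ORACLE_CLASSES:
        if name == "GENERIC_R":
            r1 = r2 = range(min(s1, s2) - slack, max(s1, s2) + slack + 1)
        else:
            r1 = range(s1 - slack, s1 + slack + 1)
            r2 = range(s2 - slack, s2 + slack + 1)
        for i, ci in enumerate(seq):
            if ci not in a1:
                continue
            for j in range(i + 1, len(seq)):
                if seq[j] not in a2 or (j - i - 1) not in r1:
                    continue
                for k in range(j + 1, len(seq)):
                    if seq[k] not in a3 or (k - j - 1) not in r2:
                        continue
                    found.setdefault((i, j, k), name)
    return [(i, j, k, name) for (i, j, k), name in found.items()]


_PRIORITY = {name: r for r, (name, *_rest) in enumerate(_ORACLE_CLASSES)}


def _max_disjoint_count(cands: list[tuple]) -> int:
    """Maximum number of core-disjoint triples, by the classic
    earliest-end interval-scheduling argument (cores are [i, k])."""
    count, cursor = 0, -1
    for i, _j, k, _c in sorted(cands, key=lambda c: c[2]):
        if i > cursor:
            count += 1
            cursor = k
    return count


def oracle_select(cands: list[tuple]) -> list[tuple]:
    """Exhaustive best non-overlapping subset: maximal count, then
    lexicographically smallest starts, then highest class priority.
    Overlap is on the anchor core [i, k]. Only subsets of the provably
    maximal size are enumerated, which keeps brute force tractable."""
    size = _max_disjoint_count(cands)
    if size == 0:
        return []
    best = None
    best_key = None
    for combo in combinations(sorted(cands), size):
        ok = True
        for (i1, _, k1, _c1), (i2, _, k2, _c2) in zip(combo, combo[1:]):
            if i2 <= k1:
                ok = False
                break
        if not ok:
            continue
        key = (
            tuple(c[0] for c in combo),
            tuple(_PRIORITY[c[3]] for c in combo),
            tuple(c[:3] for c in combo),
        )
        if best is None or key < best_key:
            best, best_key = combo, key
    return list(best)


def oracle_detect(seq: str, slack: int = 1) -> set[tuple]:
    """Brute-force repeat detection; returns {(start, anchors, class)}."""
    sel = oracle_select(oracle_candidates(seq, slack))
    return {(i, (i, j, k), name) for i, j, k, name in sel}


def hits_as_tuples(hits: list[RepeatHit]) -> set[tuple]:
    return {(h.start, h.anchors, h.repeat_class) for h in hits}


def oracle_ear(seq: str, intervals: list[tuple[int, int]]) -> set[tuple[int, int]]:
    """Exhaustive LxLxL window check outside the given intervals."""
    out = set()
    for i in range(len(seq) - 4):
        if seq[i] == "L" and seq[i + 2] == "L" and seq[i + 4] == "L":
            span = (i, i + 5)
            if all(span[1] <= s or span[0] >= e for s, e in intervals):
                out.add(span)
    return out


def random_protein(rng: np.random.Generator, max_len: int = 200) -> ProteinRecord:
    n = int(rng.integers(1, max_len + 1))
    return ProteinRecord("rnd", "".join(rng.choice(list(FULL_AA), size=n)))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def scan_config() -> ScanConfig:
    return ScanConfig()
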