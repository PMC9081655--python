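"""Degenerate consensus scanning for MYB R-repeats and signature motifs.

The MYB DNA-binding domain is built from imperfect ~52-residue repeats
("R"), each carrying three regularly spaced hydrophobic anchors (usually
tryptophan). The scanner works directly from the consensus notation used in
the plant MYB literature:

* R2 repeat: ``W-x(19)-W-x(19)-W``
* R3 repeat: ``[FILM]-x(18)-W-x(18)-W``
* R-R first repeat: third anchor replaced by tyrosine (``W-x(19)-W-x(19)-Y``)
* generic repeat: first anchor in {W,F,I,L,M}, second W, third in {W,F,Y}

Spacer lengths tolerate a configurable slack (default +/-1) because real
repeats drift around the printed consensus.

Coordinates are 0-based, half-open throughout. A repeat hit's ``start`` is
its first anchor; ``end`` extends ``tail`` residues (default 12) past the
third anchor — the remainder of helix 3 of a ~52-aa repeat — clamped to the
sequence length. Overlap between repeat hits is judged on the anchor core
``[start, third_anchor]``; the tail only delimits the non-MYB region (EAR
exclusion, chaining).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

from mybfam.seqio import AMINO_ACIDS, ProteinRecord


class PatternError(ValueError):
    """Raised when a consensus pattern string cannot be parsed."""


@dataclass(frozen=True)
class Spacer:
    """A run of ``min_len``..``max_len`` arbitrary residues."""

    min_len: int
    max_len: int


@dataclass(frozen=True)
class MotifPattern:
    """A compiled degenerate consensus pattern.

    ``positions`` alternates anchor residue sets (frozensets of allowed
    letters) and :class:`Spacer` runs. ``X`` never satisfies an anchor
    position (anchor sets are subsets of the 20 standard residues) but is
    accepted inside spacers.
    """

    name: str
    positions: tuple[frozenset | Spacer, ...]
    source: str = ""

    def __post_init__(self) -> None:
        anchors = [p for p in self.positions if isinstance(p, frozenset)]
        if not anchors:
            raise PatternError(f"pattern {self.name!r} has no anchor position")
        for a in anchors:
            if not a or not a <= AMINO_ACIDS:
                raise PatternError(
                    f"pattern {self.name!r}: anchor set {sorted(a)} must be a "
                    "nonempty subset of the 20 standard residues"
                )
        for p in self.positions:
            if isinstance(p, Spacer) and not (0 <= p.min_len <= p.max_len):
                raise PatternError(
                    f"pattern {self.name!r}: bad spacer ({p.min_len},{p.max_len})"
                )


@dataclass(frozen=True)
class MotifHit:
    """A located signature-motif match."""

    seq_id: str
    motif_name: str
    start: int
    end: int
    matched: str


@dataclass(frozen=True)
class RepeatHit:
    """A located R-repeat with its three anchor coordinates."""

    seq_id: str
    start: int
    end: int
    anchors: tuple[int, int, int]
    repeat_class: str
    anchor_residues: tuple[str, str, str]

    @property
    def core_end(self) -> int:
        """Exclusive end of the anchor core (third anchor + 1)."""
        return self.anchors[2] + 1


# repeat classes in priority order (highest first)
REPEAT_CLASSES = ("R2_CONSENSUS", "R3_CONSENSUS", "RR_FIRST", "GENERIC_R")
FULL_REPEAT_CLASSES = frozenset({"R2_CONSENSUS", "R3_CONSENSUS", "GENERIC_R"})


@dataclass(frozen=True)
class RepeatClassSpec:
    """Anchor sets and nominal spacer lengths for one repeat class."""

    name: str
    anchor_sets: tuple[frozenset, frozenset, frozenset]
    spacers: tuple[int, int]


_DEFAULT_CLASS_SPECS = (
    RepeatClassSpec(
        "R2_CONSENSUS",
        (frozenset("W"), frozenset("W"), frozenset("W")),
        (19, 19),
    ),
    RepeatClassSpec(
        "R3_CONSENSUS",
        (frozenset("FILM"), frozenset("W"), frozenset("W")),
        (18, 18),
    ),
    RepeatClassSpec(
        "RR_FIRST",
        (frozenset("W"), frozenset("W"), frozenset("Y")),
        (19, 19),
    ),
    RepeatClassSpec(
        "GENERIC_R",
        (frozenset("WFILM"), frozenset("W"), frozenset("WFY")),
        # nominal span covering both R2 and R3 spacing; slack widens it
        (18, 19),
    ),
)


@dataclass(frozen=True)
class ScanConfig:
    """Tunable parameters of the repeat scanner.

    slack
        Spacer tolerance in residues around each nominal spacer length
        (for GENERIC_R the band spans both nominal lengths +/- slack).
    tail
        Residues of helix-3 remainder appended past the third anchor when
        reporting a repeat's span.
    class_specs
        Anchor sets and spacers per repeat class, priority order.
    """

    slack: int = 1
    tail: int = 12
    class_specs: tuple[RepeatClassSpec, ...] = _DEFAULT_CLASS_SPECS

    def spacer_range(self, spec: RepeatClassSpec, which: int) -> tuple[int, int]:
        if spec.name == "GENERIC_R":
            lo, hi = min(spec.spacers), max(spec.spacers)
        else:
            lo = hi = spec.spacers[which]
        return max(0, lo - self.slack), hi + self.slack


def compile_pattern(spec: str, name: str = "", source: str = "") -> MotifPattern:
    """Parse dash-separated consensus notation into a :class:`MotifPattern`.

    Grammar: ``TOKEN ("-" TOKEN)*`` where a token is a single residue
    (``W``), a residue class (``[FILM]``), or a spacer ``x(19)`` /
    ``x(18,19)``. ``x(19)`` means exactly 19 arbitrary residues.
    """
    positions: list[frozenset | Spacer] = []
    offset = 0
    for token in spec.split("-"):
        tok = token.strip()
        if not tok:
            raise PatternError(f"empty token at offset {offset} in {spec!r}")
        if tok[0] in "xX" and "(" in tok:
            body = tok[1:]
            if not (body.startswith("(") and body.endswith(")")):
                raise PatternError(f"malformed spacer {tok!r} at offset {offset}")
            nums = body[1:-1].split(",")
            try:
                vals = [int(n) for n in nums]
            except ValueError:
                raise PatternError(
                    f"malformed spacer {tok!r} at offset {offset}"
                ) from None
            if len(vals) == 1:
                positions.append(Spacer(vals[0], vals[0]))
            elif len(vals) == 2:
                positions.append(Spacer(vals[0], vals[1]))
            else:
                raise PatternError(f"malformed spacer {tok!r} at offset {offset}")
        elif tok.startswith("["):
            if not tok.endswith("]") or len(tok) < 3:
                raise PatternError(
                    f"malformed residue class {tok!r} at offset {offset}"
                )
            letters = set(tok[1:-1].upper())
            if not letters <= AMINO_ACIDS:
                raise PatternError(
                    f"unknown residue in class {tok!r} at offset {offset}"
                )
            positions.append(frozenset(letters))
        elif len(tok) == 1 and tok.upper() in AMINO_ACIDS:
            positions.append(frozenset(tok.upper()))
        elif len(tok) == 1 and tok in "xX":
            positions.append(Spacer(1, 1))
        else:
            raise PatternError(f"malformed token {tok!r} at offset {offset}")
        offset += len(token) + 1
    return MotifPattern(name or spec, tuple(positions), source)


# The signature motifs that partition the MYB-related subfamily, plus the
# EAR repression motif scanned outside the DNA-binding domain.
SIGNATURE_PATTERNS: dict[str, MotifPattern] = {
    "SHAQK": compile_pattern("S-H-A-Q-K-[YF]-F", "SHAQK", "CCA1-like signature"),
    "TBP": compile_pattern("L-K-D-K-W-[RK]-[NT]", "TBP", "TBP-like signature"),
    "SHLQK": compile_pattern("S-H-L-Q-[KM]-x(1)-R", "SHLQK", "GARP/Myb-CC signature"),
    "LHEQLE": compile_pattern("L-H-E-Q-L-E", "LHEQLE", "Myb-CC coiled-coil namesake"),
    "EAR": compile_pattern("L-x(1)-L-x(1)-L", "EAR", "EAR repression motif"),
}


def _match_from(seq: str, positions: Sequence, i: int, pos_idx: int) -> Iterator[int]:
    """Yield every exclusive end index of a match of positions[pos_idx:]
    starting at sequence offset i."""
    if pos_idx == len(positions):
        yield i
        return
    p = positions[pos_idx]
    if isinstance(p, Spacer):
        for run in range(p.min_len, p.max_len + 1):
            if i + run > len(seq):
                break
            yield from _match_from(seq, positions, i + run, pos_idx + 1)
    else:
        if i < len(seq) and seq[i] in p:
            yield from _match_from(seq, positions, i + 1, pos_idx + 1)


def find_motif(seq: ProteinRecord, pattern: MotifPattern) -> list[MotifHit]:
    """Find ALL matches of ``pattern`` in ``seq``, including overlaps.

    Hits are sorted by (start, end); deterministic.
    """
    s = seq.sequence
    hits = []
    for start in range(len(s)):
        for end in _match_from(s, pattern.positions, start, 0):
            hits.append(
                MotifHit(seq.id, pattern.name, start, end, s[start:end])
            )
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _enumerate_candidates(
    seq: str, seq_id: str, config: ScanConfig
) -> list[RepeatHit]:
    """All anchor triples satisfying any repeat class, each labelled with
    its highest-priority class."""
    n = len(seq)
    best: dict[tuple[int, int, int], int] = {}
    for rank, spec in enumerate(config.class_specs):
        a1, a2, a3 = spec.anchor_sets
        lo1, hi1 = config.spacer_range(spec, 0)
        lo2, hi2 = config.spacer_range(spec, 1)
        for i in range(n):
            if seq[i] not in a1:
                continue
            for j in range(i + 1 + lo1, min(n, i + 2 + hi1)):
                if seq[j] not in a2:
                    continue
                for k in range(j + 1 + lo2, min(n, j + 2 + hi2)):
                    if seq[k] not in a3:
                        continue
                    key = (i, j, k)
                    if key not in best or rank < best[key]:
                        best[key] = rank
    hits = []
    for (i, j, k), rank in best.items():
        spec = config.class_specs[rank]
        hits.append(
            RepeatHit(
                seq_id=seq_id,
                start=i,
                end=min(k + config.tail, n),
                anchors=(i, j, k),
                repeat_class=spec.name,
                anchor_residues=(seq[i], seq[j], seq[k]),
            )
        )
    return hits


def _class_rank(config: ScanConfig, name: str) -> int:
    for r, spec in enumerate(config.class_specs):
        if spec.name == name:
            return r
    return len(config.class_specs)


def select_hits(candidates: list[RepeatHit], config: ScanConfig) -> list[RepeatHit]:
    """Deterministic maximal non-overlapping selection.

    Preference order among feasible subsets: (i) more hits, (ii)
    lexicographically smaller start tuple, (iii) elementwise higher class
    priority. Overlap is judged on the anchor core [start, third anchor].
    """
    cands = sorted(
        candidates,
        key=lambda h: (h.start, _class_rank(config, h.repeat_class), h.anchors),
    )

    def key(sel: tuple[RepeatHit, ...]) -> tuple:
        return (
            -len(sel),
            tuple(h.start for h in sel),
            tuple(_class_rank(config, h.repeat_class) for h in sel),
            tuple(h.anchors for h in sel),
        )

    memo: dict[tuple[int, int], tuple[RepeatHit, ...]] = {}

    def best(idx: int, min_start: int) -> tuple[RepeatHit, ...]:
        if idx == len(cands):
            return ()
        mk = (idx, min_start)
        if mk in memo:
            return memo[mk]
        h = cands[idx]
        options = [best(idx + 1, min_start)]
        if h.start >= min_start:
            options.append((h,) + best(idx + 1, h.core_end))
        res = min(options, key=key)
        memo[mk] = res
        return res

    return list(best(0, 0))


def detect_repeats(seq: ProteinRecord, config: ScanConfig | None = None) -> list[RepeatHit]:
    """Detect R-repeats in a protein.

    Enumerates every anchor triple satisfying any configured repeat class
    (a triple satisfying several classes takes the highest-priority one),
    then selects a maximal set of mutually non-overlapping hits with a
    fully deterministic preference: more hits, then leftmost starts, then
    higher class priority. Returned hits are sorted by start.
    """
    config = config or ScanConfig()
    candidates = _enumerate_candidates(seq.sequence, seq.id, config)
    return select_hits(candidates, config)


def scan_ear(seq: ProteinRecord, repeats: Sequence[RepeatHit]) -> list[MotifHit]:
    """Find EAR (LxLxL) motifs lying entirely outside every repeat interval.

    Repeat intervals include the helix-3 tail (``[start, end)``); a motif
    overlapping any of them is suppressed because the EAR motif is a
    non-MYB-region feature.
    """
    hits = find_motif(seq, SIGNATURE_PATTERNS["EAR"])
    out = []
    for h in hits:
        if all(h.end <= r.start or h.start >= r.end for r in repeats):
            out.append(h)
    return out
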