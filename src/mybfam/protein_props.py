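"""Physicochemical properties: length, average molecular weight, pI.

The theoretical isoelectric point uses the Bjellqvist pKa set as
parameterized by the ExPASy Compute pI/Mw tool: a single C-terminal pKa
(3.55, with residue-specific overrides for terminal Asp/Glu),
residue-specific N-terminal pKa values, and side-chain pKa for
D, E, C, Y (acidic) and H, K, R (basic). Net charge at a given pH follows
Henderson-Hasselbalch:

    Z(pH) = sum_basic 1/(1 + 10^(pH - pKa)) - sum_acidic 1/(1 + 10^(pKa - pH))

Z is strictly decreasing in pH for any peptide (the termini always
ionize), so the pI — the root of Z — is unique and found by bisection on
[0, 14].

Molecular weight is the sum of average residue masses plus one water
(18.01528 Da). ``X`` residues are an error (mass unknown); no silent
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from mybfam.seqio import ProteinRecord

WATER = 18.01528

# average residue (monomer-minus-water) masses, Daltons
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788,
    "R": 156.1875,
    "N": 114.1038,
    "D": 115.0886,
    "C": 103.1388,
    "E": 129.1155,
    "Q": 128.1307,
    "G": 57.0519,
    "H": 137.1411,
    "I": 113.1594,
    "L": 113.1594,
    "K": 128.1741,
    "M": 131.1926,
    "F": 147.1766,
    "P": 97.1167,
    "S": 87.0782,
    "T": 101.1051,
    "W": 186.2132,
    "Y": 163.1760,
    "V": 99.1326,
}


@dataclass(frozen=True)
class PkaSet:
    """A named pKa parameterization for net-charge computation."""

    name: str = "bjellqvist"
    cterm: float = 3.55
    cterm_overrides: Mapping[str, float] = field(
        default_factory=lambda: {"D": 4.55, "E": 4.75}
    )
    nterm_default: float = 7.5
    nterm_overrides: Mapping[str, float] = field(
        default_factory=lambda: {
            "A": 7.59,
            "M": 7.0,
            "S": 6.93,
            "P": 8.36,
            "T": 6.82,
            "V": 7.44,
            "E": 7.7,
            "G": 7.5,
        }
    )
    acidic_sidechain: Mapping[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    basic_sidechain: Mapping[str, float] = field(
        default_factory=lambda: {"H": 5.98, "K": 10.0, "R": 12.0}
    )

    def nterm(self, residue: str) -> float:
        return self.nterm_overrides.get(residue, self.nterm_default)

    def cterm_pka(self, residue: str) -> float:
        return self.cterm_overrides.get(residue, self.cterm)


#: EMBOSS iep parameterization, selectable as an alternative set.
EMBOSS_PKA = PkaSet(
    name="emboss",
    cterm=3.6,
    cterm_overrides={},
    nterm_default=8.6,
    nterm_overrides={},
    acidic_sidechain={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    basic_sidechain={"H": 6.5, "K": 10.8, "R": 12.5},
)

PKA_SETS: dict[str, PkaSet] = {"bjellqvist": PkaSet(), "emboss": EMBOSS_PKA}


def _seq_of(seq: ProteinRecord | str) -> str:
    return seq.sequence if isinstance(seq, ProteinRecord) else seq


def compute_mw(seq: ProteinRecord | str) -> float:
    """Average molecular weight in Daltons (residue masses + one water)."""
    s = _seq_of(seq)
    if not s:
        raise ValueError("empty sequence")
    try:
        return sum(AVERAGE_RESIDUE_MASS[c] for c in s) + WATER
    except KeyError as exc:
        raise ValueError(
            f"cannot compute mass: unknown residue {exc.args[0]!r} "
            "(X has no defined mass)"
        ) from None


def net_charge(
    seq: ProteinRecord | str, pH: float, pka: PkaSet | None = None
) -> float:
    """Net charge in elementary charges at the given pH."""
    s = _seq_of(seq)
    if not s:
        raise ValueError("empty sequence")
    pka = pka or PkaSet()

    def pos(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pH - pk))

    def neg(pk: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (pk - pH))

    charge = pos(pka.nterm(s[0])) - neg(pka.cterm_pka(s[-1]))
    for c in s:
        if c in pka.basic_sidechain:
            charge += pos(pka.basic_sidechain[c])
        elif c in pka.acidic_sidechain:
            charge -= neg(pka.acidic_sidechain[c])
    return charge


def compute_pi(
    seq: ProteinRecord | str, pka: PkaSet | None = None, tol: float = 1e-4
) -> float:
    """Theoretical isoelectric point by bisection on the net charge."""
    pka = pka or PkaSet()
    lo, hi = 0.0, 14.0
    for _ in range(200):
        mid = (lo + hi) / 2.0
        z = net_charge(seq, mid, pka)
        if abs(z) < tol:
            return mid
        if z > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


@dataclass(frozen=True)
class PhysicoChem:
    seq_id: str
    length: int
    mw: float
    pi: float


def characterize(
    records: Iterable[ProteinRecord], pka: PkaSet | None = None
) -> pd.DataFrame:
    """Per-protein report: length, Mw (Da and kDa), pI.

    kDa and pI are rounded to two decimals as conventionally reported.
    """
    rows = []
    for rec in records:
        mw = compute_mw(rec)
        rows.append(
            {
                "seq_id": rec.id,
                "length": len(rec),
                "mw_Da": mw,
                "mw_kDa": round(mw / 1000.0, 2),
                "pI": round(compute_pi(rec, pka), 2),
            }
        )
    return pd.DataFrame(rows, columns=["seq_id", "length", "mw_Da", "mw_kDa", "pI"])
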