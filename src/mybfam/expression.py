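"""Expression screening: log2 TPM transform, DEG filter, 2^-ddCt qPCR.

The DEG screen reproduces the common transcriptome-survey filter:
expression > 0, |log2 fold change| > 1, p < 0.05 (raw, no multiple-testing
correction unless requested). Fold changes are computed on group-mean TPM
with a small pseudocount (default 0.01) so on/off genes stay finite;
p-values come from a two-sided Welch t-test on log2(TPM+1) replicate
values.

qPCR relative quantification uses the comparative 2^-ddCt method with an
internal reference gene: dCt = mean Ct(target) - mean Ct(reference) per
condition, ddCt = dCt(treated) - dCt(control), fold = 2^-ddCt, with a
two-sided t-test on per-replicate dCt values and star flags at p < 0.05
and p < 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class DegRecord:
    gene: str
    mean_a: float
    mean_b: float
    log2fc: float
    pvalue: float
    passes: bool


@dataclass(frozen=True)
class QpcrMeasurement:
    """Ct replicates for one gene under one condition/timepoint."""

    gene: str
    condition: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]
    timepoint: str = ""

    def __post_init__(self) -> None:
        if not self.ct_target or not self.ct_reference:
            raise ValueError(
                f"{self.gene}/{self.condition}: at least one target and one "
                "reference Ct replicate required"
            )
        if any(c <= 0 for c in self.ct_target + self.ct_reference):
            raise ValueError(f"{self.gene}/{self.condition}: Ct must be > 0")

    @property
    def dct_replicates(self) -> tuple[float, ...]:
        """Per-replicate dCt, pairing target and reference replicates;
        when counts differ the mean reference Ct is subtracted instead."""
        if len(self.ct_target) == len(self.ct_reference):
            return tuple(
                t - r for t, r in zip(self.ct_target, self.ct_reference)
            )
        ref = float(np.mean(self.ct_reference))
        return tuple(t - ref for t in self.ct_target)

    @property
    def dct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


@dataclass(frozen=True)
class DdctResult:
    gene: str
    condition: str
    timepoint: str
    ddct: float
    fold: float
    pvalue: float
    stars: str


def log2_matrix(m: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(TPM + pseudocount); shape and labels preserved."""
    if (m.values < 0).any():
        raise ValueError("negative TPM value in expression matrix")
    return np.log2(m + pseudocount)


def deg_screen(
    m: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fc_pseudocount: float = 0.01,
    log2fc_cutoff: float = 1.0,
    alpha: float = 0.05,
    expression_rule: str = "any_group",
    pvalues: Mapping[str, float] | None = None,
    fdr: bool = False,
) -> list[DegRecord]:
    """Screen genes for differential expression between two sample groups.

    passes = expression rule AND |log2fc| > cutoff AND p < alpha.
    ``expression_rule``: "any_group" (mean TPM > 0 in at least one group)
    or "all_samples" (every sample > 0). ``pvalues`` optionally supplies
    precomputed per-gene p-values in place of the Welch t-test. ``fdr``
    applies Benjamini-Hochberg before thresholding.
    """
    missing = [s for s in list(group_a) + list(group_b) if s not in m.columns]
    if missing:
        raise KeyError(f"unknown sample label(s): {missing}")
    if pvalues is None and (len(group_a) < 2 or len(group_b) < 2):
        raise ValueError("each group needs >=2 replicates for p-values")
    if expression_rule not in ("any_group", "all_samples"):
        raise ValueError(f"unknown expression rule {expression_rule!r}")

    a = m[list(group_a)]
    b = m[list(group_b)]
    log_a = np.log2(a + 1.0)
    log_b = np.log2(b + 1.0)

    genes = sorted(m.index)
    pvals: dict[str, float] = {}
    for g in genes:
        if pvalues is not None:
            pvals[g] = float(pvalues[g])
        else:
            xa, xb = log_a.loc[g].values, log_b.loc[g].values
            if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa.mean() == xb.mean():
                pvals[g] = 1.0
            else:
                pvals[g] = float(
                    stats.ttest_ind(xa, xb, equal_var=False).pvalue
                )
            if math.isnan(pvals[g]):
                pvals[g] = 1.0

    if fdr:
        adjusted = _benjamini_hochberg(pvals)
    else:
        adjusted = pvals

    out = []
    for g in genes:
        mean_a = float(a.loc[g].mean())
        mean_b = float(b.loc[g].mean())
        log2fc = math.log2((mean_a + fc_pseudocount) / (mean_b + fc_pseudocount))
        if expression_rule == "any_group":
            expressed = mean_a > 0 or mean_b > 0
        else:
            expressed = bool((m.loc[g] > 0).all())
        passes = (
            expressed
            and abs(log2fc) > log2fc_cutoff
            and adjusted[g] < alpha
        )
        out.append(DegRecord(g, mean_a, mean_b, log2fc, adjusted[g], passes))
    return out


def _benjamini_hochberg(pvals: Mapping[str, float]) -> dict[str, float]:
    genes = list(pvals)
    p = np.array([pvals[g] for g in genes])
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return {g: float(adj[i]) for i, g in enumerate(genes)}


def ddct(q: QpcrMeasurement, control: QpcrMeasurement) -> DdctResult:
    """Relative expression of ``q`` versus ``control`` by 2^-ddCt.

    Significance is a two-sided t-test comparing per-replicate dCt values
    between the two conditions (p = 1 when both are constant and equal).
    """
    if q.gene != control.gene:
        raise ValueError(
            f"gene mismatch: {q.gene!r} vs control {control.gene!r}"
        )
    delta = q.dct - control.dct
    fold = 2.0 ** (-delta)
    xa = np.array(q.dct_replicates, dtype=float)
    xb = np.array(control.dct_replicates, dtype=float)
    if np.ptp(xa) == 0 and np.ptp(xb) == 0:
        pvalue = 1.0 if xa.mean() == xb.mean() else 0.0
    elif len(xa) < 2 or len(xb) < 2:
        pvalue = float("nan")
    else:
        pvalue = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
    if pvalue < 0.01:
        stars_ = "**"
    elif pvalue < 0.05:
        stars_ = "*"
    else:
        stars_ = ""
    return DdctResult(q.gene, q.condition, q.timepoint, delta, fold, pvalue, stars_)


def deg_frame(records: Sequence[DegRecord]) -> pd.DataFrame:
    """DEG report as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "mean_tpm_a": r.mean_a,
                "mean_tpm_b": r.mean_b,
                "log2fc": r.log2fc,
                "pvalue": r.pvalue,
                "passes": r.passes,
            }
            for r in records
        ],
        columns=["gene", "mean_tpm_a", "mean_tpm_b", "log2fc", "pvalue", "passes"],
    )
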