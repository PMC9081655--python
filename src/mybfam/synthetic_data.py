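"""Labeled synthetic inputs for every pipeline stage.

Protein generation plants class-defining repeat blocks and signature
motifs into random backbones drawn from the 20-letter alphabet minus
every residue usable as a repeat anchor (W, Y, F and the alternative
first anchors I, L, M). Excluding the anchor residues makes spurious
repeat anchors impossible, so the planted structure is provably the only
repeat signal — tests against truth labels are exact rather than
probabilistic. (A ``realistic`` flag re-admits the full alphabet for
stress testing.)

Expression matrices are generated on the log2-TPM scale: per-gene
baselines ~ Normal(mu=5, sd=2), replicate noise Normal(0, sd) added on
the log scale, differential genes shifted by +/- the planted log2
fold-change in group A, and TPM = 2^value - 1 floored at zero. qPCR
tables fix the reference Ct and place the target Ct so the expected
2^-ddCt equals the requested fold.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from mybfam.expression import QpcrMeasurement
from mybfam.seqio import ProteinRecord

#: classes the family generator can plant, in canonical order
FAMILY_CLASSES = (
    "R2R3",
    "R3_MYB",
    "R4_MYB",
    "CCA1_LIKE",
    "R_R",
    "TBP_LIKE",
    "MYB_CC",
    "GARP_LIKE",
    "NOT_MYB",
)

# backbone alphabet: 20 residues minus every residue that can serve as a
# repeat anchor (W, Y, F, and the R3/generic first anchors I, L, M) — this
# is what makes the zero-false-anchor guarantee exact
BACKBONE_ALPHABET = tuple("ACDEGHKNPQRSTV")
FULL_ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")


def _r2_block(rng: np.random.Generator) -> str:
    return "W" + _backbone(19, rng) + "W" + _backbone(19, rng) + "W"


def _r3_block(rng: np.random.Generator) -> str:
    first = rng.choice(list("FILM"))
    return first + _backbone(18, rng) + "W" + _backbone(18, rng) + "W"


def _rr_first_block(rng: np.random.Generator) -> str:
    return "W" + _backbone(19, rng) + "W" + _backbone(19, rng) + "Y"


def _backbone(n: int, rng: np.random.Generator, realistic: bool = False) -> str:
    alphabet = FULL_ALPHABET if realistic else BACKBONE_ALPHABET
    return "".join(rng.choice(alphabet, size=n)) if n else ""


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Recipe for a labeled protein family set."""

    counts: Mapping[str, int] = field(
        default_factory=lambda: {c: 5 for c in FAMILY_CLASSES}
    )
    backbone_range: tuple[int, int] = (60, 120)
    mutation_rate: float = 0.0
    mutation_mode: str = "structure_preserving"  # or "corrupting"
    seed: int = 0
    realistic: bool = False

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("class counts must be >= 0")
        unknown = set(self.counts) - set(FAMILY_CLASSES)
        if unknown:
            raise ValueError(f"unknown class(es): {sorted(unknown)}")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if self.mutation_mode not in ("structure_preserving", "corrupting"):
            raise ValueError(f"unknown mutation mode {self.mutation_mode!r}")


def gen_myb_protein(
    class_label: str,
    rng: np.random.Generator,
    backbone_range: tuple[int, int] = (60, 120),
    realistic: bool = False,
    seq_id: str = "syn",
) -> tuple[ProteinRecord, str, set[int]]:
    """Generate one protein of the requested class.

    Returns (record, truth label, planted positions) where the planted
    positions are the indices of class-defining residues (anchors and
    motif letters) that structure-preserving mutation must not touch.
    """
    if class_label not in FAMILY_CLASSES:
        raise ValueError(f"unknown class {class_label!r}")
    lo, hi = backbone_range
    nter = _backbone(int(rng.integers(lo // 2, hi // 2 + 1)), rng, realistic)
    cter = _backbone(int(rng.integers(lo // 2, hi // 2 + 1)), rng, realistic)
    planted_blocks: list[str] = []  # blocks whose every residue is protected

    def tandem(blocks: list[str]) -> str:
        # 5-residue linkers: anchor cores stay disjoint while successive
        # hits start well within the default tandem gap
        parts = []
        for i, b in enumerate(blocks):
            if i:
                parts.append(_backbone(5, rng, realistic))
            parts.append(b)
        return "".join(parts)

    if class_label == "R2R3":
        core = tandem([_r2_block(rng), _r3_block(rng)])
    elif class_label == "R3_MYB":
        core = tandem([_r2_block(rng), _r2_block(rng), _r3_block(rng)])
    elif class_label == "R4_MYB":
        core = tandem(
            [_r2_block(rng), _r2_block(rng), _r2_block(rng), _r3_block(rng)]
        )
    elif class_label == "CCA1_LIKE":
        core = "SHAQK" + ("Y" if rng.random() < 0.5 else "F") + "F"
    elif class_label == "R_R":
        core = (
            _rr_first_block(rng)
            + _backbone(65, rng, realistic)
            + "SHAQK"
            + ("Y" if rng.random() < 0.5 else "F")
            + "F"
        )
    elif class_label == "TBP_LIKE":
        core = (
            "LKDKW"
            + ("R" if rng.random() < 0.5 else "K")
            + ("N" if rng.random() < 0.5 else "T")
        )
    elif class_label == "MYB_CC":
        core = "SHLQKAR" + _backbone(32, rng, realistic) + "LHEQLE"
    elif class_label == "GARP_LIKE":
        core = (
            "SHLQ"
            + ("K" if rng.random() < 0.5 else "M")
            + _backbone(1, rng)
            + "R"
        )
    else:  # NOT_MYB
        core = ""

    seq = nter + core + cter
    planted = set(range(len(nter), len(nter) + len(core)))
    return ProteinRecord(seq_id, seq, f"synthetic {class_label}"), class_label, planted


def _mutate(
    seq: str,
    planted: set[int],
    rate: float,
    mode: str,
    rng: np.random.Generator,
) -> str:
    if rate == 0:
        return seq
    letters = list(seq)
    for i in range(len(letters)):
        if mode == "structure_preserving" and i in planted:
            continue
        if rng.random() < rate:
            choices = [c for c in BACKBONE_ALPHABET if c != letters[i]]
            letters[i] = str(rng.choice(choices))
    return "".join(letters)


def gen_family_set(
    spec: SyntheticFamilySpec,
) -> tuple[list[ProteinRecord], dict[str, str]]:
    """Generate a labeled family set; reproducible for a fixed seed.

    Returns (records, truth) where truth maps record id -> planted class.
    """
    rng = np.random.default_rng(spec.seed)
    records: list[ProteinRecord] = []
    truth: dict[str, str] = {}
    idx = 0
    for cls in FAMILY_CLASSES:
        for _ in range(spec.counts.get(cls, 0)):
            idx += 1
            rec, label, planted = gen_myb_protein(
                cls,
                rng,
                spec.backbone_range,
                spec.realistic,
                seq_id=f"syn{idx:03d}",
            )
            mutated = _mutate(
                rec.sequence,
                planted,
                spec.mutation_rate,
                spec.mutation_mode,
                rng,
            )
            rec = ProteinRecord(rec.id, mutated, rec.description)
            records.append(rec)
            truth[rec.id] = label
    return records, truth


@dataclass(frozen=True)
class SyntheticExpressionSpec:
    """Recipe for a TPM matrix with planted differential expression."""

    n_genes: int = 100
    n_de: int = 10
    log2fc: float = 2.0
    replicates: int = 3
    noise_sd: float = 0.1
    baseline_mean: float = 5.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de > self.n_genes:
            raise ValueError("n_de cannot exceed n_genes")
        if self.replicates < 2:
            raise ValueError("need >=2 replicates per group")


def gen_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, dict[str, list[str]], dict[str, bool]]:
    """Generate (TPM matrix, group map, truth flags).

    The first ``n_de`` genes carry the planted shift (alternating sign)
    in group A; truth flags mark them.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i + 1:04d}" for i in range(spec.n_genes)]
    samples_a = [f"A{i + 1}" for i in range(spec.replicates)]
    samples_b = [f"B{i + 1}" for i in range(spec.replicates)]
    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    shift = np.zeros(spec.n_genes)
    signs = np.where(np.arange(spec.n_de) % 2 == 0, 1.0, -1.0)
    shift[: spec.n_de] = signs * spec.log2fc
    log_a = (
        baseline[:, None]
        + shift[:, None]
        + rng.normal(0, spec.noise_sd, (spec.n_genes, spec.replicates))
    )
    log_b = baseline[:, None] + rng.normal(
        0, spec.noise_sd, (spec.n_genes, spec.replicates)
    )
    tpm = np.maximum(2.0 ** np.concatenate([log_a, log_b], axis=1) - 1.0, 0.0)
    matrix = pd.DataFrame(tpm, index=genes, columns=samples_a + samples_b)
    groups = {"A": samples_a, "B": samples_b}
    truth = {g: i < spec.n_de for i, g in enumerate(genes)}
    return matrix, groups, truth


def gen_qpcr(
    true_fold: float,
    replicates: int = 3,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    gene: str = "gene",
    condition: str = "treated",
    timepoint: str = "6h",
    reference_ct: float = 15.0,
    control_dct: float = 10.0,
) -> tuple[QpcrMeasurement, QpcrMeasurement]:
    """Paired (treated, control) Ct measurements with a known fold change.

    The control dCt is fixed; the treated target Ct is placed so that
    2^-ddCt equals ``true_fold`` in expectation. Gaussian noise of sd
    ``noise_sd`` is added to every Ct replicate.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    rng = rng if rng is not None else np.random.default_rng(0)

    def noisy(center: float) -> tuple[float, ...]:
        return tuple(
            float(center + (rng.normal(0, noise_sd) if noise_sd else 0.0))
            for _ in range(replicates)
        )

    treated_dct = control_dct - np.log2(true_fold)
    treated = QpcrMeasurement(
        gene,
        condition,
        noisy(reference_ct + treated_dct),
        noisy(reference_ct),
        timepoint,
    )
    control = QpcrMeasurement(
        gene,
        "control",
        noisy(reference_ct + control_dct),
        noisy(reference_ct),
        "0h",
    )
    return treated, control
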