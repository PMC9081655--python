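# Methods

This note documents the models and procedures `mybfam` implements, the
parameters that matter, the numerical choices, and what the synthetic-data
tests do and do not demonstrate about real data.

## Repeat model and scanner

A MYB "R" repeat is modeled purely by its anchor skeleton: three anchor
residues with fixed nominal spacers, the notation used on sequence logos of
plant MYB domain surveys.

| class | anchors | nominal spacers |
|---|---|---|
| `R2_CONSENSUS` | W, W, W | 19, 19 |
| `R3_CONSENSUS` | [FILM], W, W | 18, 18 |
| `RR_FIRST` | W, W, Y | 19, 19 |
| `GENERIC_R` | [WFILM], W, [WFY] | 18–19 band |

Parameters (in `ScanConfig`):

* **slack** (residues, default 1) — tolerance around each nominal spacer.
  Real repeats are described as "approximately 52 aa" while consensus
  notation prints exact spacers; profile-based searches tolerate small
  indels, so a rigid spacer would be unrealistically strict. ±1 is the
  smallest non-rigid choice; it is configurable because the field has no
  agreed value.
* **tail** (residues, default 12) — the stretch of helix 3 past the third
  anchor included in a hit's reported span: a 40-residue anchor skeleton
  plus a 12-residue tail gives the canonical ~52-aa repeat. The tail only
  delimits the non-MYB region (EAR exclusion, tandem chaining); hit
  *selection* operates on the anchor core `[first, third]`, because the
  tail of one repeat legitimately overlaps the linker before the next.

The scanner enumerates every anchor triple `(i, j, k)` whose residues and
spacer lengths satisfy any class; a triple satisfying several classes takes
the most specific (`R2 > R3 > RR_FIRST > GENERIC_R`). It then selects a
maximal set of hits with pairwise-disjoint anchor cores, preferring (1)
more hits, (2) lexicographically smaller start tuples, (3) higher class
priority — a total order, so the output is a pure function of the sequence.
The selection is exact (memoized search over the candidate list), not a
heuristic; the test suite checks it against an independent brute-force
oracle that enumerates all candidate subsets of provably maximal size.

Degenerate positions never match `X`: anchor sets are subsets of the 20
standard residues, which is the conservative choice for a detector whose
output triggers family membership claims.

## Classification

Subfamily assignment counts tandem full repeats: the longest chain of
`R2/R3/GENERIC` hits in which each hit starts at most **tandem_gap**
(default 10) residues after the previous hit's reported end. Chain length
≥ 4 → 4R-MYB, 3 → 3R-MYB, 2 → R2R3. A chain of exactly two full repeats is
called R2R3 regardless of which consensus each repeat matched, since the
first repeat of 3R proteins also matches the W-skeleton; the per-repeat
classes stay in the evidence.

Everything else is typed by signature motifs, first rule wins:
TBP (`LKDKW[RK][NT]`) → Myb-CC (`SHLQ[KM]xR` + `LHEQLE` outside all repeat
intervals) → GARP (`SHLQ[KM]xR`) → R-R (`SHAQK[YF]F` starting at least
**rr_min_separation** = 40 residues after the end of a tyrosine-variant
repeat) → CCA1 (`SHAQK[YF]F`). The precedence runs from the most to the
least constrained signature so that a protein carrying several motifs gets
the most specific call deterministically. Sequences with some repeat or
signature evidence that fits no rule are `MYB_RELATED/UNCLASSIFIED`;
sequences with none are `NOT_MYB`.

Neither the tandem gap nor the R-R separation has an agreed literature
value ("tandem" and "far apart" are qualitative); both defaults are scaled
to the ~52-aa repeat (a gap well under one repeat; a separation of roughly
one repeat) and both are exposed in `ClassifyConfig`.

The `LHEQLE` hexapeptide stands in for the Myb-CC coiled-coil domain it
names; full profile matching of that domain is deliberately out of scope
for a desk-scale pipeline. The EAR motif (`LxLxL`) is reported as
annotation wherever it falls outside repeat spans but never influences
classification — it marks candidate repressors, not family membership.

Names are assigned in input order with per-subfamily counters
(`<prefix>1…`, `<prefix>R1…`, `<prefix>3R1…`, `<prefix>4R1…`), so permuting
the input permutes only the numbering, never the calls.

## Physicochemical properties

Average molecular weight is the sum of standard average residue masses
plus one water (18.01528 Da). `X` is an error, not an imputed average —
silent imputation would corrupt the min/max claims these reports feed.

Net charge at pH follows Henderson–Hasselbalch over ionizable groups
(N-terminus, C-terminus, side chains of D, E, C, Y, H, K, R):

    Z(pH) = Σ_basic 1/(1+10^(pH−pKa)) − Σ_acidic 1/(1+10^(pKa−pH))

with the Bjellqvist pKa set as parameterized by the ExPASy Compute pI/Mw
tool, including its residue-specific N-terminal values and C-terminal
overrides for terminal Asp/Glu (4.55/4.75). The EMBOSS set ships as an
alternative. Z is strictly decreasing in pH (every peptide has both
termini), so the pI is the unique root; it is found by bisection on
[0, 14] to |Z| < 1e−4 (≤ 200 iterations, far past float resolution).
Reports round Mw to 2 decimals in kDa and pI to 2 decimals, the precision
such tables conventionally print. Tests cross-check both quantities
against Biopython's independent implementations.

## Redundancy removal

Pairwise identity: one optimal global alignment (match +1, mismatch 0,
gap open −10, gap extend −1, no substitution matrix — identity, not
similarity, is the quantity of interest), identity = matches / length of
the shorter sequence. The shorter-sequence denominator (CD-HIT convention)
and global mode are defaults, with `alignment`/`longer` denominators and
`local` mode selectable, because published "80% identity" cutoffs rarely
state either choice. Note that in global mode a perfect substring does
*not* score identity 1.0 (end gaps are penalized); use local mode for
containment-style redundancy.

Deduplication is greedy in length-descending order (ties by id): a record
is kept iff it is < threshold identical to every already-kept
representative, else it joins the first representative that absorbed it.
Keeping the longest member retains maximal domain content for downstream
scanning. The procedure is deterministic and idempotent.

## Expression screening

* log2 transform: `log2(TPM + 1)` for heatmap-ready matrices.
* DEG screen: `passes = expressed AND |log2fc| > 1 AND p < 0.05` where
  `log2fc = log2((meanA + c)/(meanB + c))` with pseudocount `c = 0.01`
  (keeps on/off genes finite without materially shifting expressed ones),
  and p is a two-sided Welch t-test on `log2(TPM+1)` replicates.
  "Expressed" defaults to mean TPM > 0 in at least one group — the
  permissive reading that admits on/off genes — switchable to all-samples.
  P-values are raw by default, mirroring the common raw-p screen;
  Benjamini–Hochberg is available behind a flag. A precomputed p-value
  column can replace the t-test so externally produced DE results can be
  screened verbatim.
* qPCR: ΔCt per condition = mean Ct(target) − mean Ct(reference);
  ΔΔCt = ΔCt(treated) − ΔCt(control); fold = 2^−ΔΔCt. Significance is a
  two-sided t-test on per-replicate ΔCt values (replicates paired
  positionally when counts match, otherwise against the mean reference),
  with `*`/`**` flags at 0.05/0.01. Degenerate inputs are defined exactly:
  constant equal replicates give p = 1, constant unequal give p = 0.

## Synthetic data: what it emulates, what it does not

The family generator plants class-defining blocks (repeat skeletons,
signature motifs) into random backbones and records ground-truth labels.
Backbones are drawn from the 20-letter alphabet **minus every
anchor-capable residue** (W, Y, F, I, L, M): since I/L/M are valid
R3/generic first anchors, excluding only the aromatic anchors would leave
roughly half of all planted repeats with a spurious upstream anchor triple,
and the leftmost-start selection rule would then report a shifted hit.
Excluding the full anchor set makes the planted structure provably the
only repeat signal, so zero-noise recovery tests are exact. A `realistic`
flag re-admits the full alphabet for stress testing. Structure-preserving
mutation never touches planted positions (label-invariant by
construction); corrupting mutation may, and classification accuracy
degrades with its rate.

Default study conditions: 5 proteins per class × 9 classes, backbone
segments of 30–60 residues on each side, mutation 0. Expression matrices:
100 genes, 10 differential with |log2fc| = 2 (alternating sign), 3
replicates/group, log-scale noise sd 0.1, baselines log2-TPM ~ N(5, 2),
TPM = 2^value − 1 floored at 0. qPCR: reference Ct 15, control ΔCt 10,
3 replicates.

What passing these tests does **not** show about real data: real MYB
repeats carry indels and weak anchors a ±1 spacer slack may miss; real
backbones contain W/Y/F and produce occasional spurious triples; real TPM
noise is count-based and overdispersed rather than log-Gaussian
(the generator models the screened quantity, TPM, not read counts); and
the TPM floor means strongly down-shifted low-baseline genes can lose
their planted signal — a realism feature to keep in mind when choosing
baselines for simulations. The zero-noise tests certify the decision
logic, not detector sensitivity on diverged sequences.

## Problem sizes

The test suite and the acceptance script run entirely on generated data at
desk scale: 500 random sequences (length ≤ 200) for scanner checks, 45
proteins for family recovery, 30 records for redundancy, 100–1,000 genes
for the expression screens, 100 Monte-Carlo draws for qPCR recovery —
sizes at which the brute-force oracles remain exact and a full run takes
seconds.

## Known limitations

* The repeat scanner is a consensus matcher, not a profile HMM: no
  position-specific scores, no E-values, limited sensitivity to diverged
  repeats. It is the transparent, fully testable core of the pipeline, and
  externally produced hit lists can be brought in upstream.
* Redundancy filtering operates on proteins only; whether a study
  clustered transcripts before or after translation changes the outcome
  and is not modeled.
* The Myb-CC coiled-coil is approximated by its namesake hexapeptide.
* The DEG p-value is a plain Welch t-test on log TPM, not a
  count-model test (DESeq2-style shrinkage is out of scope); with 2–3
  replicates it is conservative (null p < 0.05 rate ≈ 0.03–0.05).
* pI values depend on the pKa set; alternative parameterizations shift
  results by a few hundredths of a pH unit.
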