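# Methods

This note documents the statistical and geometric procedures `qxlms`
implements, the parameters that matter, what the synthetic generators do and
do not emulate, and the design choices made where the design was genuinely
open.

## Quantification model

The unit of quantification is the **link species**: a residue-resolved
interpeptide cross-link, intra-peptide cross-link, or monolink, keyed by the
unordered residue pair (canonicalized by sorting on protein id then residue
index) or the single residue.  Input rows are peptide species — one peptide
sequence × charge × modification state per replicate — each carrying a raw
MS1 intensity.  Attachment sites are restricted to K/S/T/Y side chains or
the protein N-terminus, and every site is validated against the supplied
construct FASTA (range and residue identity).  Residue numbering is 1-based
in the construct sequence including the initiator methionine; mapping to any
other numbering (mature-chain conventions, model numbering) is a per-protein
integer offset in the run configuration, never hard-coded.

Missing intensities are explicit (`None`), never imputed as zero: a zero in
a three-replicate mean would silently shrink or inflate fold changes, which
is worse than refusing to test a link with fewer than two observations per
condition.

### Normalization

Per replicate, the loading denominator is the summed intensity of peptides
bearing **no** cross-linker modification — the large unreacted background is
an internal loading control that is insensitive to the biology being
compared.  The factor for replicate *r* is

    f_r = T_r / gmean(T_1 … T_R)

and normalized intensity is raw / f_r.  The geometric-mean anchor is a
presentation choice: it is symmetric in the replicates and keeps normalized
magnitudes near the raw scale.  It is *not* a per-replicate invariant —
multiplying one replicate's intensities by c shifts the anchor by c^(1/R) —
but the anchor is common to all replicates, so every between-replicate
ratio, fold change and p-value is exactly invariant to per-replicate
scaling.  The tests state the invariance in that form, and the anchor choice
is recorded in output metadata (any fixed anchor, including 1, gives
identical downstream statistics).

### Aggregation

"Combining" peptides that report the same link means **summing** their
normalized intensities — the only rule that conserves total signal per
replicate, and the behaviour of standard label-free summarization over
charge states.  A replicate cell of an aggregated link is missing only when
it is missing in every member peptide.  Aggregation is order-independent.

### Ambiguous attachment sites

When a peptide carries several candidate reactive residues and no
chromatographic or spectral disambiguation, the site is assigned
deterministically: lysine beats S/T/Y (NHS-ester chemistry strongly favours
primary amines); among several lysines the one participating in the most
*other* link species wins (local reactivity evidence); remaining ties break
to the lowest residue index.  Peptides flagged as chromatographically
resolved isomers are treated as pre-resolved inputs.  For distance
annotation, a link with an ambiguous residue set uses the **minimum**
distance over candidates: reachability requires only one candidate in
range.

## Differential test

Per link: a pooled-variance (homoscedastic) two-sample t-test on normalized
intensities, df = n₁ + n₂ − 2.  The one-tailed p is taken in the direction
of the observed mean difference by default (`tail="auto"`), because a single
procedure must be able to report both increases and decreases.  The cost of
that adaptivity is calibration: under the null the auto-tail rejects at
~2α, since it is two one-sided tests in disguise.  The package therefore
also exposes fixed tails (`tail="increase"/"decrease"`), which are exactly
calibrated; the acceptance suite verifies the 5% null rate on the fixed
tail and separately documents the ~10% rate of the adaptive tail.

Significance: p < 0.05 **and** fold change (mean treated / mean control)
strictly > 2 or < 0.5.  The census of links "changed at least twofold" uses
the inclusive thresholds (≥ 2, ≤ 0.5) — two deliberately distinct rules.
No multiple-testing correction is applied on the main path (raw p against
α, matching common qXL-MS practice of reporting raw P < 0.05 alongside a
hard fold-change gate); a Benjamini–Hochberg helper is available.  The test
runs on untransformed relative intensities by default; `log_scale=True` is
available but off, for parity with the relative-signal convention.

Degenerate inputs are reported with flags rather than hidden: zero pooled
variance with unequal means gives p = 0 and `degenerate_variance`; with
equal means the link is a perfect null (p = 1, direction `none`); a zero
control mean yields an infinite fold change and `zero_control_mean`.

## Head-count comparison

Per-image open vs folded-back (IHM) particle counts are compared between
conditions with a two-tailed unpaired t-test on per-image IHM percentages.
Images with fewer than 250 detected particles are excluded first (small
images give unstable percentages); at least two included images per
condition are required.  Percentages are used untransformed — with the
typical per-image fractions (20–80%, hundreds of particles) an arcsine
transform changes nothing material, and untransformed percentages are what
the standard box-plot-and-t-test workflow consumes.

## Structure mapping

Cα–Cα Euclidean distances, measured in one or more PDB/mmCIF models read
through gemmi (alternate locations resolved to highest occupancy).  The
DSBU reach criterion is 30.0 Å, **inclusive** at the boundary and
configurable — the literature quotes both "< 30 Å" and "within 30 Å", so
the boundary convention is declared once and applied uniformly.
Straight-line Cα–Cα distance is used rather than solvent-accessible surface
distance; SASD is out of scope, and the plain distance is the measurement
the reach calibration refers to.

Models carry **roles**: primary (the reference conformation pair, e.g.
drug-bound and drug-free open-head models) or alternate (a distinct
conformation, e.g. a bent-lever folded-back geometry).  Roles live in the
run configuration, not in code.  Classification of a significant link:

| direction | within reach in a primary | within reach in an alternate | category |
|---|---|---|---|
| increase | yes | — | `stabilized_state` |
| increase | no | yes | `alternate_state_sampling` |
| increase | no | no | `increased_dynamics` |
| decrease | yes | — | `redistribution` |
| decrease | no | — | `lost_exploratory` |

Non-significant links are `no_change`; links whose sites resolve in no model
are `unannotated`.  When a link maps in only some primary models, the mapped
ones decide; if no primary model maps the link, mapped alternates serve as
the reference.  This makes classification a total function of (significance,
direction, reach pattern), and category counts are independent of input
order.  Whether an alternate-conformation distance is measured on a
dedicated model or a composite is a configuration choice recorded in the
model list, not an algorithmic constant.

## Structural geometry

* **Superposition** — Kabsch least-squares rigid alignment over matched
  Cα pairs (scipy's `Rotation.align_vectors`), requiring ≥ 3 non-collinear
  pairs (collinearity detected by a rank check at 1e-6 relative tolerance).
  RMSD is reported over the alignment selection and is invariant to rigid
  pre-transformation of either model to well below 1e-9 Å away from the
  degenerate zero-RMSD case.
* **Per-residue deviation** — after aligning on a reference region (e.g. a
  helix-loop-helix actin-binding interface), the per-residue Cα displacement
  profile over all shared residues.
* **Segment rotation** — after aligning on a reference selection, the
  residual optimal rotation carrying one segment's Cα set between models,
  reported as the axis-angle magnitude in degrees with the unit axis.  This
  yields a reproducible scalar for statements like "the lever rotates N°"
  without defining a projection plane; the axis conveys the direction
  separately.  The angle is symmetric in the model order.
* **Atom-pair distances** — single distances such as a salt-bridge
  N–O pair, via `chain:residue@atom` specs.
* **Polar contacts** — all N/O heavy-atom pairs across two disjoint
  selections within a cutoff (default 3.5 Å), optionally side-chain only.
  No angular term is applied — this is a candidate-contact lister, not a
  hydrogen-bond validator — and the cutoff is recorded with the output.
  Set differences between models give "contacts unique to model X".

Selections use `chain:start-end@atom` syntax in construct numbering; each
model translates through its own offsets.

## Synthetic generators

`simulate_quant_dataset` emulates the study design the statistics assume:
two conditions × three replicates (both configurable), log-normal
multiplicative noise with declared CV (mean-one correction applied),
replicate-specific loading factors, planted log2 fold changes, a mixture of
link kinds, two charge states for a third of links, unreacted carrier
peptides supplying the normalization denominator, and an optional fraction
of ambiguous-site peptides whose planted truth is the residue the resolution
rule selects.  Defaults (100 links, CV 10%, intensities 1e5–1e7) sit in the
range a label-free MS1 experiment on a purified two-protein construct
produces.  It does **not** emulate retention-time drift, peak-integration
error, missingness mechanisms, interference, or search-engine
misidentification — so passing tests demonstrate correctness of the
*pipeline arithmetic and decision rules*, not robustness to raw-data
pathology.

`generate_toy_hinge` builds two single-chain Cα models sharing a fixed
helical "motor" arm, with a "lever" arm rotated by a planted angle about a
known hinge axis, plus three lysine probe pairs at 29.9 / 30.0 / 31.0 Å
bracketing the reach boundary.  `simulate_dynamics_benchmark` plants every
dynamics category by pairing planted fold changes with chosen distances in
two primary models and one alternate model; the zero-noise confusion matrix
of the full pipeline against this truth is diagonal.

Both generators are bit-for-bit reproducible under a seed.

## Problem sizes and numerical choices

The test and acceptance workloads use 10,000 simulated null links for the
type-I check (99% binomial band around 0.05), 1,000 simulations for power
at a planted 2.5-fold effect (CV 10%, n = 3), 100-link census datasets, and
toy structures of 40–120 residues; together they run in well under a minute
on one CPU, which makes the whole suite practical to run on every change.
Angle recovery is asserted to < 0.01° at zero noise and < 0.5° under 0.2 Å
coordinate noise.  Float comparisons of normalized intensities use relative
tolerance 1e-12 (sums and geometric means are not associative in floating
point); distance invariances use 1e-9 Å.

## Known limitations

* Peptide-level variance is not modeled (no empirical-Bayes shrinkage);
  with n = 3 the t-test is honest but low-powered for effects below ~2-fold
  at realistic CVs.
* The auto-tailed p-value is anti-conservative under the null by design
  (see above); users needing strict calibration should fix the tail or
  apply the FDR helper.
* Reach classification reduces a distance distribution to a boolean per
  model; links hovering at the boundary inherit the boundary convention.
* Polar-contact listing has no donor/acceptor chemistry or geometry beyond
  the distance cutoff.
* The synthetic benchmark plants idealized geometry; it validates decision
  logic, not model quality.
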