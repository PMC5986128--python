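# Methods

This note records the models, rules, parameters, and numerical choices
behind `qsconsensus`, and what the synthetic fixtures do and do not emulate.

## Annotation model

Stoichiometry is a letter→count composition formula.  Because every
prediction source labels subunit types independently, comparison is
label-free: formulas are canonicalized (counts sorted non-increasing,
letters reassigned from A, ties broken by original letter order for
determinism) and compared as count multisets.  Unit coefficients are
omitted when formatting ("A", "AB", "A2B2"), matching archive conventions;
the parser accepts explicit 1s.  Text-mining predictions carry only the
total subunit count (`order_only`): a "tetramer" sentence cannot
distinguish A4 from A2B2, so order-only stoichiometries compare, and vote,
by total subunit count.

Symmetry is a point-group descriptor: cyclic Cn (n ≥ 1), dihedral Dn
(n ≥ 2), tetrahedral T, octahedral O, icosahedral I.  H (helical) is an
accepted label for open helical symmetry but is never produced by the
classifier, which handles closed groups only.

Component-wise matching is tri-state (match / mismatch / unavailable); a
component absent from either side is never silently counted as agreement.

## Point-group classification from operators

Input is a set of per-chain proper rigid operators (rotation + translation).
Steps: validate (orthonormal rotation part, det +1 — reflections are
rejected because macromolecules are chiral); solve the least-squares common
fixed point of all operators and re-center, rejecting screw-like residuals
(open symmetry); deduplicate; check group closure (every pairwise product
matches a member); then read the group off the axis/fold structure.  The
finite rotation groups in 3D are completely catalogued, which makes the
decision rule exhaustive: a single axis gives C_N; an n-fold principal axis
with n perpendicular 2-folds at order 2n gives D_n; order 12 with only 2-
and 3-folds is T; order 24 with a 4-fold is O; order 60 is I.

Tolerances (all configurable): 0.05 rad for angle matching and axis
collinearity/perpendicularity, 1e-3 for closure distance.  Operators
printed in assembly XML carry ~6 decimals, so these absorb rounding while
keeping distinct crystallographic folds (≥ 30° apart) unambiguous.  They
are this package's declared defaults, not reproductions of any external
tool's settings.  The fold of a group element is inferred as the smallest
m ≤ 60 with m·θ ≡ 0 (mod 2π) within tolerance, which is robust to printed
rounding and handles non-generator elements (a 4π/5 rotation is order 5).

An assembly whose deduplicated operator set is not a closed group is
asymmetric and reported C1 (this is the normal case for, e.g., skew
dimers); a `strict` flag propagates the classification error instead, and
the PISA adapter attaches the assembly id to any such error.  Distinct
entity labels are never collapsed, so near-identical subunits give
pseudo-symmetric descriptors (hemoglobin: A2B2 with C2, not A4 with D2).

## Sequence clustering and the consistency score

Pairwise identity comes from one deterministic global Needleman–Wunsch
alignment with BLOSUM62, gap open −11 / extend −1, free end gaps; identity
is identical columns over alignment columns excluding terminal gaps, and
coverage is each sequence's aligned span over its length.  This implements
the same contract as a blastp/BLASTClust pipeline ("k% identical over 90%
of the same length") without reproducing those binaries bit-exactly.  The
"over 90% of the same length" requirement is applied to **both** sequences
so that the edge criterion, and hence the clustering, is symmetric.

Clusters are single-linkage connected components of the ≥ k% / ≥ 0.9
coverage graph.  Within an annotated cluster the empirical marginals of
stoichiometry and symmetry are formed (members lacking a component are
dropped from that marginal with renormalization), and a candidate pair is
scored by the product of marginals.  The representative state is the argmax
pair, accepted only with score strictly greater than 0.5 — a score of
exactly 0.5 is inconclusive — and only when the cluster reaches the
calibrated minimum size: 5 members at the 40% identity threshold, 3 at
70/90/95%.  The product form is implemented exactly as specified; since
the score is used only through the > 0.5 rule and the argmax, and a product
above 0.5 forces both marginal modes to coincide with the joint mode, the
product and the raw joint frequency select the same representative in the
accepted regime.

The size-sweep evaluator re-applies the rule at minimum sizes 1..50 and
tabulates correct/incorrect/inconclusive/not-available percentages,
exposing the calibration trade-off (raising the minimum converts errors
into not-available verdicts).

Heteromeric entries are clustered by the same pairwise criterion as
homomers; the synthetic fixtures keep heteromers in distinct clusters, so
tests do not depend on any particular multi-chain matching policy.

## Text mining

Pipeline: sentence splitting (terminal punctuation with an abbreviation
guard list — Fig., et al., e.g., ...); oligomer-keyword filter (monomer
through dodecamer, case-insensitive whole words with morphological
expansion: plural -s, adjectival -ic, homo-/hetero- prefixes); relevance
classification; experimental-evidence filter; strict-majority tally of the
surviving oligomer keywords mapped to an order (dimer → 2, ...).  A tied
tally is inconclusive — "majority" is undefined at a tie and the
conservative reading avoids committing to either candidate.  No surviving
sentence is inconclusive; a missing article is not available.  The evidence
filter requires the evidence phrase in the **same sentence** by default
(stricter and more precise); an `evidence_scope="article"` flag relaxes
this to anywhere in the article.

Features: tokens are lowercased with all punctuation (hyphens included)
stripped; tf-idf weight is tf · ln(N/df) with the natural log (the standard
choice where the base is a free convention; configurable corpus statistics
live in `TfIdfModel`); vectors are hashed into 2^18 buckets by MurmurHash3
with signed hashing (a second hash bit flips signs so collisions cancel in
expectation).  Unsigned hashing, which conserves total weight, is available.

Classifiers: an RBF-kernel SVM (C = 4) and a stagewise boosted
logistic-regression alternative implemented as log-loss gradient boosting
(101 rounds).  The historical caret-style RBF width sigma = 0.013 does not
map one-to-one onto scikit-learn's `gamma`, so the estimator exposes
`gamma` directly (default `'scale'`) and keeps sigma as provenance
metadata (`REPORTED_SVM_SIGMA`).  Training uses a stratified 80/20 split;
an optional grid search over gamma and cost with k-fold CV is available.
Evaluation reports accuracy, Cohen's kappa, ROC AUC, sensitivity,
specificity, PPV, NPV, F1, and Matthews correlation from the confusion
matrix.  The reference corpus on which test-set accuracies of 0.94 (SVM)
and 0.89 (boosted logistic) were originally reported is not publicly
deposited; those figures are documentation reference points, not
reproducible targets of this package.

## PISA and EPPIC adapters

The PISA-dialect XML carries, per candidate assembly, the dissociation free
energy ΔG_diss (kcal/mol), solvent-accessible and buried surface areas, and
one rotation/translation operator per chain with an entity label.
Stability: ΔG > +band is stable, ΔG < −band unstable, |ΔG| ≤ band
indeterminate ("gray").  The band defaults to 0.5 kcal/mol — the
qualitative rule is sign-based and the gray band only needs to absorb
borderline scores; it is configurable everywhere.  Selection: the stable
candidate with the largest ΔG wins (ties by larger buried area, then lower
assembly id); with no stable candidate, any gray candidate makes the call
inconclusive, and all-unstable candidates mean the dissociated state
prevails — the prediction falls back to the monomer (A, C1).  An empty
assembly list (no PISA result) is not available.  The chosen candidate is
re-characterized through the point-group classifier rather than trusting
any symmetry stated in the file.

The EPPIC adapter reads stoichiometry and symmetry directly and
canonicalizes the formula; either field may be absent.

Both dialects are defined by this package's fixture writers (documented in
`docs/formats.md`); real exports may need a thin element-renaming layer.

## Consensus and benchmarking

Votes: not-available results are excluded outright; inconclusive results
abstain (by default they are also excluded from the denominator — a
configurable choice, since a quorum rule was genuinely open).
Stoichiometry and symmetry are voted separately; each needs a strict
majority (> half) of the votes cast for that component.  TM votes only on
stoichiometry, by order: its vote supports every candidate formula with the
same total subunit count.  If that shared support lifts two distinct
formulas past half, the component is treated as tied and is inconclusive.
An empty vote set is not available; no decided component is inconclusive.
The 3-method configuration (SC, PISA, EPPIC) is the same engine with TM
excluded.

Outcomes against the reference: all compared components match → correct;
all mismatch → incorrect; one right and one wrong → inconclusive;
non-predictions keep their status.  The summary reports outcome percentages
per method and for the consensus over all entries (rows sum to 100%).  The
agreement analysis attributes each entry, per outcome category, to the
exact subset of methods sharing that outcome, so subset counts within a
category are disjoint.  An entry is an archive outlier when a conclusive
consensus disagrees with the deposited annotation on every compared
component; the outlier fraction's denominator is the number of entries with
a conclusive consensus (an inconclusive consensus is no evidence of error —
the alternative denominator, all entries, was the other defensible reading).

When merging published benchmark sets, deduplication is by entry id, not by
pairwise-overlap arithmetic: the recorded pairwise overlaps alone
over-count by one entry (one structure shared by all three sets), which the
package's composition-arithmetic checks make explicit.

## Synthetic fixtures

The generators define the conditions under which the package is tested.

* **Clusters**: members of a cluster are point-substitution mutants (no
  indels) of a shared base sequence, so pairwise identity is analytically
  bounded (≥ 1 − 2·mutations/length) and stays above the threshold by
  construction; defaults are length 120 and 10 substitutions per member at
  the 70% threshold.  Noise members carry an off-modal annotation; a spec
  whose noise outnumbers its modal members is rejected as ambiguous.  The
  expected representative is computed by the generator's own arithmetic.
* **Corpora**: templated sentences, 200+200 by default — positives state an
  oligomeric state in solution with an evidence phrase, negatives mention
  the same oligomer keywords in asymmetric-unit/crystal-packing contexts.
  A vocabulary-overlap knob moves the corpus from separable (0) toward the
  label-noise ceiling (1).  Templated prose exercises the pipeline's
  filtering, featurization, and learning machinery but is far easier than
  real articles: passing these tests shows the pipeline is implemented
  correctly, not that real-literature accuracy would match.
* **Assemblies**: operator sets are generated analytically (closure of
  standard generators) for Cn, Dn, T, O about an arbitrary center; the
  stoichiometry's total must equal the group order.
* **Benchmarks**: 543 entries by default, matching the size of the combined
  curated benchmark.  Per-method outcome categories are sampled at planted
  rates chosen once from the published qualitative facts — individual
  accuracies spanning 46–81% (SC 0.62, TM 0.46, PISA 0.75, EPPIC 0.81
  correct), not-available outcomes only for SC (small clusters, 0.08) and
  TM (no article, 0.20), TM the most abstention-heavy method, PISA with the
  largest computational-method inconclusive share (0.08, gray region).
  Archive annotations are corrupted at rate 0.14, the upper of the two
  published archive-error estimates (~7% lower bound, ~14%).  A handful of
  entries force the exclusion→not-available and tie→inconclusive paths.
  The expected consensus outcome of every entry is computed by an
  independent tally inside the generator, so the consensus engine's
  recovery of the planted summary is an exact, self-verifying check.  The
  planted rates are study conditions, not calibration dials: the resulting
  consensus percentages are whatever the rules produce.

All generators are deterministic: identical spec + seed give byte-identical
output.

## Known limitations

* Pairwise identity is alignment-based but not blastp-bit-exact; clusters
  can differ from BLASTClust output near the threshold.
* The point-group classifier handles closed rotation groups only; helical
  and other open symmetries are detected only as a failure to find a fixed
  point, and icosahedral sets are classified by order alone.
* The text-mining stage requires plain text; PDF conversion and article
  retrieval are out of scope, as is symmetry extraction from text.
* Heteromer chain-matching during clustering is not specialized; fixtures
  avoid depending on it.
* Real PISA/EPPIC exports use different element names than the fixture
  dialects and need a renaming shim.
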