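# qsconsensus

Consensus evaluation of protein quaternary-structure annotations.

## The problem

X-ray crystallography determines the asymmetric unit of a crystal, not the
biologically functional assembly, and the quaternary-structure annotation
deposited with a structure — its **stoichiometry** (a composition formula
such as A2 for a homodimer or A2B2 for the hemoglobin heterotetramer) and
its **point-group symmetry** (C*n*, D*n*, T, O, I) — is wrong for a
non-negligible fraction of archive entries.  `qsconsensus` is a toolkit for
biocurators and structural bioinformaticians that predicts the most
probable quaternary structure of an entry from four independent sources of
evidence and aggregates them by majority vote:

1. **Sequence clustering (SC)** — chains at least k% identical over 90% of
   their length (single linkage, BLASTClust-style) usually share an
   oligomeric state.  Within a cluster the two descriptors are treated as
   discrete random variables S_t (stoichiometry) and S_y (symmetry), and a
   candidate pair (t, y) is scored by the consistency score

   C(t, y) = P(S_t = t, S_y = y) = P(S_t = t) × P(S_y = y),

   the product of the empirical within-cluster marginals.  The argmax pair
   is the cluster's representative state when its score strictly exceeds
   0.5 and the cluster has enough members (≥ 5 at the 40% identity
   threshold, ≥ 3 at 70/90/95%).
2. **Text mining (TM)** — the primary publication often states the
   oligomeric state together with the solution experiment that established
   it.  Sentences pass an oligomer-keyword filter, an RBF-SVM relevance
   classifier over MurmurHash3-hashed tf-idf features
   (tf-idf(n, s) = tf(n, s) · ln(N / df(n))), and an experimental-evidence
   filter; the strict majority of surviving oligomer keywords becomes the
   predicted oligomer order.  TM predicts order only, never symmetry.
3. **PISA** — candidate assemblies scored by dissociation free energy
   ΔG_diss: the most stable candidate (largest positive ΔG) is rebuilt from
   its per-chain rotation/translation operators and re-characterized by an
   operator-based point-group classifier with group-closure validation.
4. **EPPIC** — assembly predictions parsed directly from its XML output.

The consensus votes stoichiometry and symmetry separately, excludes
not-available results, lets inconclusive results abstain, and requires a
strict majority; a benchmark evaluator scores every method and the
consensus as correct / incorrect / inconclusive / not available against a
curated reference, with agreement and archive-outlier reports.

## Worked example

Build a synthetic 543-entry benchmark with planted per-method outcome
rates, then evaluate it:

```sh
qsconsensus fixtures benchmark --seed 1 --out fx
qsconsensus benchmark --table fx/benchmark.csv --report report
```

```
           pct_correct  pct_incorrect  pct_inconclusive  pct_not_available
method
SC               61.33           3.68             26.15               8.84
TM               44.20           7.00             24.49              24.31
PISA             76.06          16.76              6.26               0.92
EPPIC            78.45          11.97              7.73               1.84
CONSENSUS        88.40           3.87              6.45               1.29
```

Each row is one prediction method; columns are the percentage of benchmark
entries it gets right, wrong, half-right-or-abstained, and could not
process.  The consensus row beats every individual method: majority voting
suppresses the independent errors of the individual predictors.

From the library, the classic deposition-error pattern — an archive entry
annotated as a monomer while every method sees a dimer — looks like this:

```python
from qsconsensus import QSAnnotation, Source, consensus_predict, \
    parse_stoichiometry, parse_symmetry
from qsconsensus.annotations import Stoichiometry

votes = [
    QSAnnotation(parse_stoichiometry("A2"), parse_symmetry("C2"), Source.SC),
    QSAnnotation(parse_stoichiometry("A2"), parse_symmetry("C2"), Source.PISA),
    QSAnnotation(parse_stoichiometry("A2"), parse_symmetry("C2"), Source.EPPIC),
    QSAnnotation(Stoichiometry({"A": 2}), source=Source.TM, order_only=True),
]
c = consensus_predict(votes)
print(f"consensus: {c.stoichiometry} / {c.symmetry} ({c.status.value})")
```

```
consensus: A2 / C2 (predicted)
```

Such an entry, where a conclusive consensus contradicts the deposited
annotation, is what `flag_outliers` reports as a probable annotation error.

## Layout

| Module | Contents |
| --- | --- |
| `qsconsensus.annotations` | stoichiometry/symmetry parsing, canonical forms, annotation records, matching |
| `qsconsensus.pointgroup` | rigid-operator point-group classification (C*n*/D*n*/T/O/I) |
| `qsconsensus.clustering` | identity clustering, consistency score, representative-state rule |
| `qsconsensus.textmining` | sentence pipeline, hashed tf-idf, SVM/boosted-logistic classifier, extraction |
| `qsconsensus.adapters` | PISA / EPPIC XML parsing, ΔG stability rule, candidate selection |
| `qsconsensus.consensus` | vote collection, majority rule, benchmark summary, agreement, outliers |
| `qsconsensus.fixtures` | synthetic generators with planted ground truth |
| `qsconsensus.cli` | `qsconsensus` command-line entry point |

See `docs/methods.md` for the model details and design decisions and
`docs/formats.md` for the file formats.
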