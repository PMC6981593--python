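# Methods

## The model

`posim` treats protein–ligand interaction prediction as a set of
independent binary classifications, one per ligand specificity class C.
The proteins annotated as binding ligand C form the class; every other
protein in the dataset forms the complement.  Pairs without a reported
interaction are treated as conditionally negative examples — a pragmatic
convention for interaction databases, where absence of evidence stands in
for evidence of absence.  Classes with fewer than `min_class_size`
(default 5) member proteins are dropped: below that size the evidence
balance is too unstable to classify reliably.  Proteins left without any
class remain in the dataset as complement-only examples.

The classifier is memory-based.  "Fitting" validates and filters the
training material and computes the per-class a priori scores; all pairwise
sequence comparison happens at prediction time.  There are no estimated
free parameters, so every prediction is exactly reproducible from the
inputs and the two configuration choices (fragment length F and the
residue similarity measure).

### Positional similarity scores

For a query Q against a training sequence K, every pair of length-F
windows (query start i, shift h) that lies fully inside both sequences
gets a rate R_ih equal to the summed residue similarity of the two
fragments; each query position p then scores

    S_p = max { R_ih : i <= p <= i+F-1 },

the best evidence among all windows covering p at any shift.  Points of
convention, each of which the tests pin down:

- **Window coverage.** A window with start i covers positions i..i+F-1;
  position p is covered by starts i in [p-F+1, p] (1-based, inclusive).
  This is the only convention under which every window "including p"
  contributes to S_p; off-by-one variants either exclude the window
  starting at p or admit one that ends before p.
- **No partial windows.** Windows never hang over a sequence end — no
  padding and no shrunken fragments.  If len(Q) < F or len(K) < F there is
  no admissible window at all and S ≡ 0: short sequences yield no
  evidence rather than evidence on a smaller scale, keeping every S_p on
  the common [0, F] scale under identity.
- **Raw sums, not normalised.** S_p is passed to the classifier as a raw
  sum in [0, F].  Normalising by F would change nothing downstream: the
  integrated score t_p is invariant under any positive rescaling of a
  score column's stack (property-tested), so the choice is cosmetic.
- **Ambiguity codes.** X, B, Z, U and O score 0 against every residue
  under identity, including an exact self-match — an uncertain residue
  carries no match evidence.  In matrix mode the file's values are used
  verbatim.

The production implementation skews the residue-pair similarity matrix so
that each diagonal (constant shift) becomes a column, obtains every R_ih
by cumulative-sum differences along columns, masks the windows that would
hang over an end, reduces over shifts, and finishes with a sliding-window
maximum over window starts: O(len(Q) * len(K)) per pair, about 10 ms for a
pair of 300-residue sequences on one CPU.  Correctness is defined by the
brute-force triple loop over (i, h, j), and the test suite requires bit
identity against that oracle on hundreds of random pairs.

### Classification statistic

With binary weights a_k (member of C) and b_k = 1 - a_k over the n
training sequences:

    t_p = sum_k S_pk (a_k - b_k) / sum_k S_pk (a_k + b_k)
    t   = sin( (1/m) sum_p arcsin(t_p) )
    t0  = ( |class| - |complement| ) / n
    B(C) = (t - t0) / (1 - t t0)

t_p is the per-position evidence balance in [-1, 1]; the arcsine average
is a variance-stabilising mean that damps the influence of saturated
positions; t0 is the value t would take on average for an uninformative
query, so B measures how far the query's evidence departs from the class
imbalance alone.  B spans [-1, +1]: +1 at the class-side pole, -1 at the
complement-side pole, 0 indefinite.

Degenerate cases, all deliberate and tested:

- A position with no evidence at all (all S_pk = 0) has t_p = 0 and is
  **included** in the average; an uninformative position contributes
  arcsin 0 = 0, pulling t toward the indefinite value rather than being
  silently dropped.
- When t and t0 sit at the same pole (|1 - t*t0| below a relative epsilon
  of 1e-12, far below any attainable score resolution), B is defined as
  0: the query is exactly as extreme as the prior, so there is no signal.
- B is clamped to [-1, 1] against floating-point overshoot.
- Substitution-matrix similarity can make individual S_pk negative, which
  would push t_p out of [-1, 1]; scores are clamped at 0 before the
  classifier and the clamping is logged.  The identity measure — the
  default and the recommended setting — never triggers this.
- Weights are binary in this version.  The low-level functions accept
  arrays so the interface can later carry graded memberships, but inputs
  are validated to be binary.
- A class whose training split has no member or no complement cannot form
  an evidence balance; it is skipped with a warning rather than given a
  default score.

Useful algebraic facts, all property-tested: every quantity stays in
[-1, 1]; swapping class and complement negates t_p, t, t0 and B; B is
strictly increasing in t for fixed t0 in (-1, 1); B(t, 0) = t and
B(t, t) = 0.

### Evaluation

Leave-one-out cross-validation removes each protein entirely — its
sequence from the training set and its row from the interaction table for
all classes at once (per-class removal would leak the held-out protein's
other labels into training).  Each valid (protein, class) fold yields one
B value paired with the held-out protein's true label, and all pairs from
all classes are pooled into a single ROC curve; per-class curves are
reported as supplementary output.  A class invalidated in a fold (empty
class or complement after removal) contributes no pair for that fold,
since any default score would distort the pooled curve.

The AUC is the tie-aware Mann–Whitney estimate computed from midranks
(ties count 1/2), so it is independent of sort stability; the curve is the
corresponding step function with one point per distinct threshold, tied
scores producing diagonal segments.  The implementation is cross-checked
in the tests against an independent pair-counting oracle and against
scikit-learn, to 1e-12.

## Synthetic data: what it emulates and what it does not

The generator builds families of diverged homologs: each family descends
from a founder drawn uniformly over the 20 standard residues, and each
member substitutes every site independently with probability
`family_divergence` (a substituted site is redrawn uniformly, so it keeps
the founder residue with probability 1/20; the expected identity between
two family members is (1-d)^2 + (2d(1-d) + d^2)/20).

Two labelling regimes mirror the two situations the classifier must
handle:

- **family-linked** (benchmark-dataset regime): families coincide with
  ligand classes, so overall sequence proximity carries the label.  The
  default test-bench condition is 4 families x 8 proteins, 300 residues,
  divergence 0.2, evaluated at F = 30.
- **motif-linked** (kinase regime): one family of diverged homologs whose
  members split into specificity groups unrelated to the phylogeny; class
  membership is carried by a class-specific motif written over the
  background at a fixed, class-specific offset.  The default condition is
  64 homologs of 300 residues at divergence 0.3, with 4 disjoint classes
  of 8 carriers each marked by a 10-residue motif and 32 complement-only
  proteins, evaluated at F = 7 with a permuted-label negative control.
  These sizes keep a full LOOCV (64 x 63 pairwise comparisons of
  300-residue sequences) under a minute on one CPU while leaving the
  motif signal small relative to the sequence (10 of 300 positions).

  Setting `n_families > 1` in motif-linked mode produces a deliberately
  phylogeny-confounded dataset: carriers are drawn across families, and
  the label-independent between-family similarity structure then dominates
  the 10-residue signal.  Exploratory runs of that setting show pooled
  AUC falling toward chance — a faithful reproduction of why
  whole-sequence similarity methods fail on such data, and a reminder
  that positional scoring narrows but does not abolish the problem when
  the confound is strong and the determinant short.

What the generator does **not** emulate: biological residue composition,
insertions and deletions (the scoring is ungapped by design, so sequences
share one coordinate frame), rate heterogeneity across sites, realistic
phylogenies with branch lengths, and multi-label correlations between
ligand classes.  Passing the synthetic recovery tests therefore shows
that the chain — scoring, integration, averaging, prior correction,
pooled ROC — extracts planted signal at realistic divergence and class
sizes; it does not certify accuracy on real interaction data, where
labels are noisy, families are unbalanced and specificity determinants
are not literal shared substrings.

## Numerical and design choices

- Fragment length F defaults to 30, which favours distant
  inter-positional dependencies; F = 7 is the documented alternative for
  residue-level signal, and both are exercised by the test bench.
- The identity similarity is the default measure; substitution matrices
  are supported but secondary.
- All randomness lives in the synthetic generator and flows through one
  `numpy.random.Generator` seeded from `SynthConfig.seed`; scoring,
  classification and evaluation are seed-free and deterministic, so fixed
  inputs give byte-identical outputs.
- Coordinates are 1-based inclusive in all user-facing contracts and
  error messages; the internal representation is 0-based.
- LOOCV recomputes each ordered (query, training) pair exactly once; no
  caching is attempted because per-position scores are asymmetric in the
  pair.

## Known limitations

- Ungapped comparison: an indel between query and training sequence
  shifts the frame and the method relies on the max-over-shifts to
  recover; long insertions inside a determinant will fragment the signal.
- Conditionally negative labels understate true interactions, biasing B
  downward for under-annotated proteins.
- Ligand classes are treated independently; shared structure between
  ligands (scaffold similarity, shared pharmacophores) is ignored.
- No probability calibration: B ranks reliably (hence ROC evaluation) but
  is not a posterior probability.
- No k-fold CV or bootstrap confidence intervals in this version.
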