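# Methods

## The representation

A molecule is a hydrogen-suppressed graph (RDKit parsing and aromaticity
perception; the perception model is recorded in every run's metadata because
MACCS-style SMARTS are dialect-sensitive). A key set is an ordered list of
SMARTS patterns with stable 0-based indices; the bundled `maccs` set is
materialised from RDKit's MACCS-166 definitions. Three of those 166 keys
(isotope count, aromatic-ring count, fragment count) are count-based and
have no single-SMARTS form; they are kept as inert never-matching
placeholder patterns so the set keeps K = 166 stable indices. Bit-level
agreement with other MACCS implementations is explicitly not a goal.

A *hit* is one match of one key, identified by its matched atom set;
symmetry-equivalent matches over the same atoms count once, matches over
distinct atom sets are distinct hits.

Two hits are **connected** iff they share an atom, or some path in the
molecular graph between their atom sets has every interior atom unmatched by
every hit. Three conventions pin the rule down:

- *Any* matched substructure blocks, including other instances of the same
  key.
- Blocking is evaluated on interior atoms only — the endpoint atoms of the
  two hits never block their own connection (otherwise atom-sharing hits
  could never connect).
- Multiplicity is discarded: however many hit pairs of keys (i, j) are
  connected, bit (i, j) is 1. A connection between two instances of the
  same key is absorbed into that key's already-set diagonal bit; there is
  no separate self-connection channel.

The implementation walks breadth-first from each hit's atoms through
unmatched atoms only. `scfp.reference` restates the rule declaratively by
exhaustive simple-path enumeration (networkx); the two are proven equal on
hundreds of generated molecules in the test suite. The BFS is linear per
hit; the reference is exponential and only used on molecules of ≤ 12 heavy
atoms.

Serializations: linear notation is the upper triangle including the
diagonal, row-major by ascending key index (length K(K+1)/2); coordinate
notation is the ascending lexicographic list of set (i, j) bits, 0-based.
Both are invertible; the ordering is fixed so files compare across runs.
Internal storage is sparse (a set of set bits) because Klekota–Roth-sized
key sets make K² dense matrices wasteful; dense export is refused above
K = 1024.

## Classifiers

**Kernels.** Tanimoto ⟨x,y⟩/(⟨x,x⟩+⟨y,y⟩−⟨x,y⟩) and Sorensen
2⟨x,y⟩/(⟨x,x⟩+⟨y,y⟩) on binary vectors, RBF exp(−γ‖x−y‖²). The 0/0 case of
TAN/SOR (two all-zero fingerprints) is defined as similarity 1 — identical
inputs are maximally similar — and logged when triggered.

**SVM and naive Bayes** are contracts over scikit-learn (SVC with
precomputed Gram matrices for TAN/SOR; BernoulliNB), with input validation
(both classes present, positive hyperparameters) at this package's surface.

**Extreme entropy machine.** The hidden representation of a sample is its
kernel similarity to `hidden_size` (default min(n_train, 300)) randomly
chosen training samples: φ(x) = exp(−d²/(2h²)) with d the base distance —
1 − Tanimoto (default) or 1 − Sorensen for binary fingerprints, Euclidean
for real-valued inputs — and h the bandwidth hyperparameter. Each class is
modelled as a Gaussian in hidden space; the weight vector is
w = (Σ₊ + Σ₋ + C·I + ε·I)⁻¹(m₊ − m₋) with maximum-likelihood covariances, a
fixed ε = 10⁻⁶ ridge so C = 0 stays solvable even with degenerate
covariances, and C the regularization hyperparameter. The decision
threshold is the crossing point of the two univariate normal densities
fitted to the class projections, restricted to lie between the projected
means; when the standard deviations are equal within a 10⁻³ relative
tolerance, or no crossing lies between the means, the midpoint of the means
is used. Training is one linear solve — no iteration — and deterministic
given the seed (which only selects the centers).

**Protocol.** Balanced accuracy ½(sensitivity + specificity) raises on an
evaluation set missing a class rather than returning a silent 0. Folds are
stratified: each class is split independently into five near-equal parts
(scikit-learn's StratifiedKFold, which satisfies the ≤ 1 size-difference
rule per class), deterministic given the fold seed (default 42, recorded in
every CVResult). The hyperparameter grids are C ∈ 10⁻³..10⁶ and
γ ∈ 10⁻³..10⁵ (powers stepped by 1) for RBF-SVM, the same C for
Tanimoto-SVM, h ∈ {0.1, 0.2, 0.5, 1.0} × C ∈ {0, 100, 1000, 100000} for
EEM, and α ∈ {0.01, 0.1, 0.2, 0.5, 1.0} for NB: 90+10+16+5 = 121
configurations. The protocol this follows reports 117 classifiers without
listing which four grid points were excluded; this package enumerates the
printed grids exactly and logs the count with a note. Ties in the grid
search prefer the simpler family (NB < EEM < SVM), then smaller C, then the
smaller secondary parameter — enforced by enumerating in exactly that order
and keeping the first strict maximum.

## Synthetic data

The generator emulates the one property under study: molecules that agree
in key occurrence but differ in connectivity. A molecule is a linear alkyl
scaffold with two terminal groups (hydroxyl, primary amine, halogen,
carboxyl, phenyl) and two in-chain groups (carbonyl, ether), separated by
1–2 CH₂ spacers (1 where molecules must stay within the path-enumeration
oracle's reach). An isomer pair is the same group multiset with the two
in-chain groups swapped: key occurrence is unchanged, but which groups can
reach each other through unmatched chain atoms changes. Every pair is
verified against the fingerprint module at generation time (identical plain
FP, different SCFP) and resampled otherwise; the carboxyl terminal
additionally overlaps the hydroxyl and carbonyl keys, so atom-sharing
connections occur alongside blocking ones (which pair exercises which case
is logged in the dataset metadata).

Benchmark sets label each molecule by a connectivity predicate (default:
amine key connected to carbonyl key). Actives and inactives are drawn as
matched arrangement pairs with the same terminal group, so the two classes
realize the same plain-fingerprint multiset — by construction the plain FP
carries no label signal — while a single SCFP bit encodes the label
exactly. Class counts are honored exactly and imbalance is configured by
the two counts. The activity-labeling rule (Ki < 100 nM active,
Ki > 1000 nM inactive, Ki = IC50/2, the 100–1000 nM band returned as
``discarded`` rather than dropped so set sizes stay auditable) is provided
for real activity tables.

What the generator does **not** emulate: the scale, scaffold diversity,
ring systems, charge states and measurement noise of real screening
collections, or duplicate/conflicting activity records. Passing benchmarks
here demonstrates that the representation and harness behave as specified —
that connectivity information is recoverable where key occurrence is
degenerate — not that any particular accuracy transfers to real compound
sets.

A side effect of the matched-pair construction worth knowing: the best
plain-fingerprint model's cross-validated BAC lands slightly *below* 0.5
(≈ 0.42 at n = 200). With zero signal and exactly balanced pairs, whatever
small class imbalance a training fold shows for one fingerprint value is
necessarily reversed in its held-out fold, so models that chase that noise
are systematically anticorrelated with the truth. This is the expected
behaviour of cross-validation on paired null data, not a defect.

## Problem sizes and determinism

Default sizes — 50 isomer pairs for degeneracy checks, ~200 molecules for
oracle equivalence, a 100/100 benchmark for the end-to-end comparison, 121
grid configurations × 5 folds — were chosen so the full suite and the
acceptance script each complete in minutes on one core while keeping the
binomial noise on BAC small relative to the asserted margins. All
randomness flows from explicit seeds (dataset generation, fold assignment,
EEM center selection); every output directory records the resolved run
configuration and toolkit versions.

## Known limitations

- Whether the original walking procedure records only the *nearest* hit per
  atom or all hits reachable through unmatched atoms is ambiguous; this
  package records all (the declarative rule above). Likewise the diagonal
  is defined as occurrence, with same-key connections absorbed into it.
- SMARTS dialect differences (RDKit vs PaDEL vs Canvas) mean key-by-key
  agreement with other toolkits is not promised.
- Typed connections (direct vs indirect vs atom-sharing), connection
  counts, and inter-substructure distances are out of scope.
- The EEM is implemented to the contract stated above; it is not a
  re-derivation of the full published theory.
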