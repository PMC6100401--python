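# scfp — substructural connectivity fingerprints

Key-based substructural fingerprints (MACCS, Klekota–Roth, PaDEL SUB, ...)
describe a molecule by which predefined SMARTS keys occur in it. They are a
workhorse of ligand-based virtual screening, but they discard how the matched
groups are arranged: two compounds built from the same functional groups in
different connectivity share an identical fingerprint and cannot be told
apart by any downstream model.

This package implements the **substructural connectivity fingerprint
(SCFP)**: for a key set of size K, a symmetric binary K×K matrix **M** with

- **M[i,i] = 1** iff key *i* matches the molecule (the plain fingerprint is
  the diagonal), and
- **M[i,j] = 1** (i ≠ j) iff some match of key *i* is *connected* to some
  match of key *j* — they share an atom, or a path in the molecular graph
  joins them whose interior atoms are matched by no key. Any intervening
  matched substructure blocks the connection; connection counts are not
  recorded (bits stay binary).

The matrix can be serialized in matrix, coordinate or linear notation (the
linear form is the upper triangle including the diagonal, row-major, length
K(K+1)/2, directly usable as a bit-vector by any fingerprint model).

Alongside the representation, the package ships the classification harness
used to evaluate it: Tanimoto, Sorensen and RBF kernels on binary
fingerprints, soft-margin SVMs, Bernoulli naive Bayes, the **extreme entropy
machine** (EEM — a closed-form classifier pairing a random kernel hidden
layer with a regularized Gaussian class-covariance discriminant), balanced
accuracy BAC = ½(TP/(TP+FN) + TN/(TN+FP)), stratified five-fold
cross-validation, and a 121-point hyperparameter grid search. A synthetic
generator produces molecule families that share a plain fingerprint while
differing in connectivity, plus labeled benchmark sets built on a
connectivity predicate, and an activity-labeling rule (actives Ki < 100 nM,
inactives Ki > 1000 nM, Ki = IC50/2).

## Worked example

```python
from scfp import key_set_from_pairs, parse_molecule, compute_scfp, compute_plain_fp

keys = key_set_from_pairs(
    [("amine", "[NX3;H2]"), ("carbonyl", "[CX3]=[OX1]"), ("hydroxyl", "[OX2H]")],
    name="demo",
)
mol = parse_molecule("NCC(=O)CO", "smiles")   # amine—CH2—C(=O)—CH2—OH

print(compute_plain_fp(mol, keys).to_bitstring())
scfp = compute_scfp(mol, keys)
print(sorted(scfp.bits))
print(scfp.to_linear().to_bitstring())
```

prints

```
111
[(0, 0), (0, 1), (1, 1), (1, 2), (2, 2)]
110111
```

All three keys occur (`111`). The amine is connected to the carbonyl, bit
(0,1), and the carbonyl to the hydroxyl, bit (1,2) — but bit (0,2) is 0:
every path from the amine to the hydroxyl passes through the matched
carbonyl carbon, so the walk is blocked. That zero is exactly the
information a plain key-based fingerprint cannot hold.

The same from the shell:

```bash
scfp generate --kind benchmark --n-active 100 --n-inactive 100 --seed 42 --out data/
scfp benchmark --input data/benchmark.smi --model grid --seed 42 --out results/
```

On this benchmark (classes differ only in whether the amine is connected to
the carbonyl) the grid-search best plain-fingerprint model stays at chance
(mean BAC ≈ 0.42) while the best SCFP model reaches mean BAC = 1.00.

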