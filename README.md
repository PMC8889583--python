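# brnib

Benchmark-driven greedy optimization of cavity **negative-image models**
(NIB models) for docking rescoring.

## The problem

Cavity-mapping tools fill a protein binding site with pseudo-atoms — neutral
(C), positive (N) and negative (O) points that together form a *negative
image* of the cavity. Docked ligand poses can then be rescored by their rigid
shape and electrostatic similarity to this image instead of by the docking
score, which often improves virtual-screening enrichment. But raw cavity
models cover the whole cavity volume, including regions actives never touch;
those surplus pseudo-atoms blur the similarity signal and let decoys score
well.

`brnib` optimizes the cavity model directly against a benchmark: starting
from the full model it repeatedly deletes the single pseudo-atom whose
removal most improves an enrichment metric on a labelled training set of
actives and decoys, and stops when no deletion helps. The greedy search is
deterministic and cheap — shrinking an *n*-atom model to *a₁* atoms costs
only Σₖ₌ₐ₁ⁿ k rescoring rounds (495 for 50 → 40) where exhaustive subset
search would need Σₖ₌ₐ₁ⁿ C(n,k) ≈ 1.3·10¹⁰.

## Scoring and metrics

* **Shape**: atoms are spherical Gaussians (amplitude p = 2.7, width matched
  to the vdW hard-sphere volume); similarity is the Hodgkin index
  2·O_AB/(O_AA + O_BB) of the two densities.
* **ESP**: softened Coulomb potentials of the partial charges, compared with
  the Hodgkin index on the union of both structures' atom centers, mapped to
  [0, 1].
* **Combined**: w·shape + (1−w)·esp, default 50/50 (or shape only). A
  compound is represented by its best-scoring pose; poses are never
  realigned.
* **Enrichment**: ROC AUC with the Hanley–McNeil/Wilcoxon standard error,
  EFd (percent of actives found when a given percent of decoys has been
  found), and BEDROC(α), default α = 20 — the default optimization target.
  Compounds skipped by docking are appended to the bottom of the ranking in
  seeded random order.

A synthetic benchmark generator produces cavity models with a planted signal
sub-pocket plus a decoy-attracting noise patch, matching active/decoy pose
libraries, and ground truth, so the whole pipeline can be exercised and
validated without any external data.

## Worked example

Generate a benchmark, split it 70:30, optimize the model on the training
set, and evaluate the result on the held-out test set:

```sh
brnib generate --outdir fixture --seed 0
brnib split --actives fixture/actives.txt --decoys fixture/decoys.txt \
            --train-fraction 0.7 --seed 0 --outdir split
brnib optimize --model fixture/model.mol2 --poses fixture/poses.mol2 \
               --actives split/train_actives.txt --decoys split/train_decoys.txt \
               --seed 0 --outdir opt
```

The optimizer prints one line per generation — index, surviving model size,
best training BEDROC(20) among the single-atom-removal variants, and the
accepted removal:

```
gen   0  size  15  best 0.0247  removed atom 11
gen   1  size  14  best 0.4294  removed atom 14
...
gen   7  size   8  best 0.9920  removed atom 8
gen   8  size   8  best 0.9920  no improvement
final size 8; bedroc:20 0.0010 -> 0.9920; 108 variant evaluations
```

The 16-atom input model is pruned to the 8 planted signal atoms; training
BEDROC(20) rises from 0.0010 to 0.9920 and the search stops after 108
variant evaluations (= 16 + 15 + … + 9 accepted rounds plus the final
8-variant round that found no improvement). Evaluating the first and last
generation models on the untouched test split:

```sh
brnib evaluate --model opt/gen_0008.mol2 --poses fixture/poses.mol2 \
               --actives split/test_actives.txt --decoys split/test_decoys.txt \
               --outdir eval
```

gives test AUC 1.00 and BEDROC(20) 1.00, against AUC 0.63 and BEDROC(20)
0.002 for the unoptimized `gen_0000.mol2` — the enrichment gain carries to
held-out compounds. Each generation's model is written as MOL2 alongside a
JSONL generation log, so any intermediate model can be inspected or reused.

Every command is seeded and deterministic; `--workers N` parallelizes
variant evaluation without changing any result.

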