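# snosite

Sequence-based prediction of cysteine **S-nitrosylation (SNO) sites**.
S-nitrosylation — the covalent attachment of nitric oxide to a cysteine
thiol — is a ubiquitous, reversible post-translational modification;
knowing *which* cysteines of a protein are modified matters for
understanding redox signalling and disease mechanisms, and experimental
site mapping is expensive. `snosite` is a library + CLI for
bioinformaticians who want to build and evaluate a sequence-only site
predictor from their own data.

## Method

Each candidate cysteine is represented by its `2ξ+1`-residue peptide
window (default ξ = 10, X-padded at protein termini) and encoded as a
**458-dimensional** feature vector:

- **400 evolutionary-conservation features** — the window's PSI-BLAST
  PSSM rows, aggregated into a 20×20 matrix *M*(i, j) = Σ E(p, j) over
  window positions p holding residue type i, flattened row-major;
- **9 secondary-structure features** — per state α ∈ {H, E, C} of the
  predicted structure in the window: Σα (total), Σα / #segments(α)
  (average run length), and Σα / window residues (composition);
- **49 physicochemical features** — per-property means over the window's
  residues.

Features are ranked by **symmetric relative entropy**
D<sub>KL</sub>(P‖Q) + D<sub>KL</sub>(Q‖P) between the class-conditional
distributions of each feature, and **incremental feature selection
(IFS)** evaluates each prefix of the ranked list by stratified 10-fold
cross-validation of a **k-nearest-neighbor** classifier (Euclidean
distance, k = 9, neighbor-fraction scores), selecting the prefix with
maximum mean Matthews correlation coefficient (MCC). See
`docs/methods.md` for the full model description and design rationale.

PSI-BLAST profiles (`-Q` ASCII PSSMs) and PSIPRED `.ss2` predictions are
*inputs*; the package does not run either program.

## Worked example

The bundled generator writes a complete synthetic input set (FASTA,
per-protein PSSMs and `.ss2` files, labelled sites), so the whole
pipeline runs with no external data:

```bash
snosite synth  --seed 7 --n-proteins 8 --out demo
snosite encode --fasta demo/proteins.fasta --pssm-dir demo/pssm \
               --ss-dir demo/ss --labels demo/sites.tsv \
               --out demo/features.tsv
snosite select --matrix demo/features.tsv --n-folds 5 --max-size 60 \
               --seed 7 --out-dir demo/sel
snosite evaluate --matrix demo/features.tsv \
                 --subset demo/sel/optimal_subset.txt \
                 --n-folds 5 --seed 7 --out demo/metrics.json
```

which logs

```
INFO snosite: wrote 43 samples x 458 features to demo/features.tsv
INFO snosite: optimal subset: 3 features (mean MCC 0.6255)
INFO snosite: mean MCC 0.6255 -> demo/metrics.json
```

The encoded matrix holds one row per labelled cysteine (43 sites here)
and 458 named feature columns. `demo/sel/ranked_features.tsv` lists the
features by descending relative-entropy score,
`demo/sel/ifs_table.tsv` holds the mean SN/SP/ACC/MCC per prefix size,
and `optimal_subset.txt` names the MCC-optimal prefix (3 features for
this seed). The final metrics JSON reports per-fold and mean values —
here mean sensitivity 0.82, specificity 0.76, accuracy 0.79 and MCC
0.626: on these synthetic labels (assigned at random to cysteines, with
no planted signal in the real encoders) the numbers merely demonstrate
the mechanics; see `docs/methods.md` for what synthetic runs do and do
not show. `snosite train` / `snosite predict` fit a reusable model
archive and score every cysteine of new proteins with
`(protein, position, peptide, score, label)` rows.

Library use mirrors the CLI:

```python
from snosite import (SynthConfig, generate_feature_dataset,
                     rank_features, ifs_search, cross_validate)

fm, informative = generate_feature_dataset(SynthConfig(seed=1, n_pos=200, n_neg=200))
ranked = rank_features(fm)                      # symmetric-KL ranking
ifs = ifs_search(fm, ranked, seed=1)            # IFS curve + optimum
cv = cross_validate(fm, ifs.optimal_subset, seed=1)
print(ifs.optimal_size, round(cv.mean.mcc, 3))
```

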