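# gatmda

Prediction of miRNA–disease associations by fusing **linear** features
(similarity matrices × lncRNA association profiles) with **non-linear**
features from a **multi-head graph attention encoder**, classified by a
**random forest**.

## The problem

Experimentally validated miRNA–disease associations are scarce (curated
catalogues cover ~3% of the miRNA × disease grid), so computational
ranking of candidate associations guides which pairs are worth testing at
the bench.  Two complementary sources of signal exist: *side information*
(how similar two miRNAs are functionally, how close two diseases sit in
the MeSH hierarchy, which lncRNAs each interacts with) and the *topology*
of the known association network itself.  This package implements a
predictor that uses both, for bioinformaticians who want a tested,
reproducible implementation that runs end-to-end on synthetic data —
no downloads required.

## The model

Given a binary association matrix `MD ∈ {0,1}^{m×n}`, miRNA/disease–lncRNA
profiles `ML ∈ {0,1}^{m×l}`, `DL ∈ {0,1}^{n×l}`, a miRNA functional
similarity `FS` and a disease semantic similarity `D_s`:

1. **Disease semantic similarity** from a MeSH-style DAG, averaging two
   models: a decay model where disease `D`'s own term contributes 1 and an
   ancestor `d` contributes `Δ·max_{d′∈children(d)∩T(D)} D1_D(d′)`
   (Δ = 0.5), and an information-content model where each term contributes
   `−log(|DAGs containing d| / n_diseases)`.  Similarity of two diseases is
   the shared-term contribution mass over the total:
   `DS(d_i,d_j) = Σ_{d∈T(i)∩T(j)} (D_{d_i}(d)+D_{d_j}(d)) / (DV(d_i)+DV(d_j))`.
2. **Linear features** `F_m = FS·ML`, `F_d = D_s·DL`, stacked to
   `F = [F_m; F_d] ∈ R^{(m+n)×l}`.
3. **Non-linear features**: one multi-head graph attention layer on the
   bipartite association graph,
   `e_ij = LeakyReLU_β(aᵀ[Wf_i ‖ Wf_j])`, `θ_ij = softmax_{N_i}(e_ij)`,
   `f′_i = LeakyReLU_β((1/K) Σ_k Σ_{t∈N_i} θ^k_it W^k f_t)`,
   with heads **averaged** (K = 4), `l′ = 40`, `β = 0.2`, dropout
   `α = 0.2`.  The encoder is trained self-supervised on link prediction
   (DistMult decoder, binary cross-entropy on observed edges vs resampled
   non-edges), in pure NumPy with analytic gradients that are verified
   against finite differences in the test suite.
4. **Fusion and classification**: each pair `(i,j)` becomes
   `[f_{m_i}, f′_{m_i}, f_{d_j}, f′_{d_j}] ∈ R^{2(l+l′)}` and a 350-tree
   random forest scores it; the score is the fraction of trees voting
   "associated" (soft voting by default, hard majority voting available).

Evaluation is repeated five-fold cross-validation over the known
positives: each held-out fold is removed from the attention graph and the
forest's training set in any role, then ranked against unlabeled pairs the
forest never saw.

## Worked example

```python
from gatmda import GATMDA, SynthConfig, generate_bundle, run_cv, CVPlan

bundle, truth = generate_bundle(SynthConfig(seed=0))
model = GATMDA(seed=0).fit(bundle)
scores = model.predict_scores()

for rank, mirna, score, known in scores.top_k("disease-003", k=5):
    print(rank, mirna, round(score, 3))

report = run_cv(bundle, CVPlan(n_folds=5, n_repeats=1, seed=0))
print(f"AUC={report.auc:.3f} AUPR={report.aupr:.3f}")
```

prints

```
bundle: m=100 miRNAs, n=80 diseases, l=20 lncRNAs, MD density 0.029
mean score, known pairs:   0.831
mean score, unknown pairs: 0.040
 1  mir-022  0.769
 2  mir-013  0.271
 3  mir-014  0.180
 4  mir-018  0.177
 5  mir-011  0.163
5-fold CV: AUC=0.862  AUPR=0.204  SPEC=0.986  REC=0.421
```

The synthetic bundle plants four miRNA–disease communities with
heavy-tailed node propensities; known pairs score an order of magnitude
above unknown ones, the top-ranked candidates for a disease are miRNAs
from its community, and held-out associations are recovered with AUC
≈ 0.86 against every unseen unlabeled pair (specificity is near 1 because
true negatives dominate the grid — the operating regime of association
screening).

## Command line

```bash
gatmda synth --out data/ --seed 0            # write a synthetic dataset
gatmda validate-data --md data/MD.tsv --ml data/ML.tsv --dl data/DL.tsv \
    --fs data/FS.csv --ds data/Ds.csv        # dataset report (m, n, l, densities)
gatmda disease-sim --dag data/dag.tsv --map data/disease_terms.tsv --out Ds.csv
gatmda cv --md ... --ml ... --dl ... --fs ... --ds ... --out report.json
gatmda predict --md ... --scores scores.csv  # full m×n score matrix
gatmda top-k --scores scores.csv --md data/MD.tsv --disease disease-003 --k 50
```

Formats are plain text: header-less TSV edge lists, dense CSV matrices
with identifier headers, and a DAG as parent/child TSV plus a
disease→term map.

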