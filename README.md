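# ecotyping

Cell-state and multicellular-ecosystem ("ecotype") profiling of bulk tumor
transcriptomes.

Bulk tumor expression is a mixture over cell types, and each cell type in a
tumor microenvironment occupies discrete transcriptional **states** (e.g. an
inflammatory vs. a matrix-remodeling fibroblast program). States of different
cell types co-occur in the same patients, forming multicellular communities —
**ecotypes** — that carry prognostic and therapy-response information. This
package implements the full workflow for going from a genes × samples bulk
matrix plus a cell-type signature matrix to states, ecotypes and their
clinical associations:

1. **Deconvolution** — per-sample cell-type fractions by non-negative least
   squares of the bulk profile on the signature matrix (fractions normalized
   to sum to 1), and per-cell-type "purified" expression matrices from a
   per-gene mixture regression with residual redistribution.
2. **State discovery** — per cell type, consensus non-negative matrix
   factorization (multiplicative updates, Frobenius loss) of z-scored,
   positive/negative-split purified expression. The number of states K is
   chosen by scanning ranks 2..20 and taking the rank whose cophenetic
   coefficient of the perturbed-consensus matrix is closest to 0.95. States
   with fewer than 10 marker genes (argmax basis loading and log2 fold-change
   ≥ 1) or with artifact-like abundance profiles are removed.
3. **State recovery** — in a held-out cohort, abundances H′ are re-solved
   jointly over all samples with the discovery basis W fixed; per-state
   recovery is scored by the correlation of marker fold-change profiles, with
   a permutation z-test (significant iff z > 1.65 and one-sided p < 0.05).
4. **Ecotype discovery** — each patient is assigned the most abundant state
   per cell type (binary matrix A, A[i,j] = 1 iff state i is assigned to
   patient j); pairwise Jaccard indices between states are gated by a
   hypergeometric co-occurrence test (α = 0.01), hierarchically clustered,
   and the cluster count is chosen by silhouette-width maximization.
5. **Clinical association** — one-vs-rest log-rank tests and single-covariate
   Cox proportional-hazards fits (Breslow ties) flag adverse (HR > 1) and
   favorable (HR < 1) states/ecotypes; responder vs. non-responder log-rank
   plus restricted-mean-survival comparison flags therapy benefit.
6. **Enrichment** — hypergeometric over-representation of marker genes in
   user-supplied GMT gene sets (set sizes 15–500; significant if p < 0.01 and
   BH-adjusted p < 0.05) and GSEA on the rank score
   S(g) = −log10(p) · sign(log FC) from a Wilcoxon rank-sum test.

A fully seeded synthetic-cohort generator (`ecotyping.synthetic`) plants
known states, communities, hazards and response effects so every stage can be
validated against ground truth.

## Worked example

Simulate a cohort of 200 patients (450 genes, 3 cell types with 3 states
each, 3 communities, 10% community noise, log2 marker effect 2.0, measurement
noise 0.5), plus a 100-patient validation cohort, then run every stage:

```bash
ecotyping simulate --out-dir ex --n-genes 450 --n-samples 200 \
    --cell-types A,B,C --k-per-type 3,3,3 --n-communities 3 \
    --noise-rate 0.1 --n-validation 100 --seed 42

ecotyping run-all --set bulk ex/bulk.tsv --set signature ex/signature.tsv \
    --set clinical ex/clinical.tsv --set gene_sets ex/gene_sets.gmt \
    --set validation_bulk ex/validation_bulk.tsv --set output_dir out_ex \
    --set seed 42 --set max_rank 8 --set n_restarts 10 --set max_genes 150
```

The run discovers 3 states for each cell type. All nine states are
significantly recovered in the held-out cohort (`recovery_stats.tsv`):

```
cell_type  state  R       z     p       significant
A          S01    0.915   4.34  0.002   True
A          S02    0.936   4.10  0.002   True
B          S03    0.892   3.32  0.002   True
C          S03    0.910   4.31  0.002   True
```

R is the correlation between discovery and validation marker fold-change
profiles; z is its distance from the permutation null in standard deviations.

Ecotype clustering groups the nine states into the three planted communities
(`ecotype_members.tsv`: `A::S01 → E1`, `A::S02 → E2`, ...), and the survival
screen (`survival_ecotypes.tsv`) recovers the planted hazard structure — the
community simulated with a 2× hazard multiplier surfaces as an adverse
ecotype and the 0.5× community as a favorable one:

```
ecotype  n_in  n_out  hazard_ratio  cox_p     direction  significant
E1       68    132    0.80          0.21      favorable  False
E2       61    139    2.76          1.0e-08   adverse    True
E3       71    129    0.58          0.0012    favorable  True
```

Every output is plain TSV/JSON, and `manifest.json` records the
configuration, seeds and SHA-256 checksums of all inputs and outputs;
rerunning the same configuration reproduces every file byte for byte.

The same steps are available as library calls (`ecotyping.deconvolution`,
`ecotyping.states.discover_states`, `ecotyping.recovery`,
`ecotyping.ecotypes.discover_ecotypes`, `ecotyping.clinical`,
`ecotyping.enrichment`) and as the subcommands `simulate`, `deconvolve`,
`discover`, `recover`, `ecotypes`, `survival`, `enrich`.

## Acceptance script

`scripts/acceptance.py` simulates a fresh synthetic cohort from the given
seed and runs the complete pipeline (deconvolution → state discovery →
held-out recovery → ecotypes → survival and benefit screens → enrichment)
end to end, writing a JSON report:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Documentation

`docs/methods.md` describes the model and all numerical choices: the mixture
model behind purification, the perturbed-consensus rank selection and its
calibration, the artifact filter, the recovery statistic, the survival
machinery, and what the synthetic generator does and does not emulate.
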