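# Methods

## Model

The observed drug × cell-line response matrix R (n drugs, m cell lines) is
modeled as a rank-k product ABᵀ fit only on observed entries, selected by
the binary mask W. The fitted objective is

    J(A, B) = ‖W ⊙ (R − ABᵀ)‖²_F
            + λ_l (‖A‖²_F + ‖B‖²_F)
            + λ_d Tr(Aᵀ L̃_d A) + λ_c Tr(Bᵀ L̃_c B).

The first term is the masked reconstruction loss; the Tikhonov term
controls overfitting of both factors; the two trace terms are graph
penalties equal to ½ Σ_{i,r} Ŝ(i,r) ‖a_i/√d_i − a_r/√d_r‖² for the
normalized Laplacian, i.e. they ask similar drugs (similar cell lines) to
have nearby latent vectors — the local-invariance assumption. The model
assumes (a) a low-rank mean structure in the responses, (b) roughly
homoscedastic residuals (the loss is unweighted squared error), and
(c) similarity matrices that are informative about latent proximity;
nothing else about the response scale, so log-IC50 and activity-area data
are handled identically up to the sensitivity orientation flag.

## Similarities and graphs

Drug similarity is the Jaccard coefficient between binary fingerprint
rows; cell-line similarity is the Pearson correlation between expression
profiles. Both outputs are symmetrized exactly ((S + Sᵀ)/2) with unit
diagonal, because the Laplacian code relies on exact symmetry. All-zero
fingerprints and zero-variance profiles are rejected by name rather than
silently patched; missing expression values are rejected (no imputation
rule is defined for them).

Sparsification: each entity keeps its p most similar peers (self
excluded); mutual neighbor pairs get weight 1, one-sided pairs 1/2,
others 0, and Ŝ = N ⊙ S. Ties in the p-largest selection break toward the
smaller index, which makes the construction deterministic and testable by
exhaustive enumeration. From Ŝ: degrees d_i = Σ_r Ŝ(i,r), L = D − Ŝ, and
L̃ = D^{−1/2} L D^{−1/2} with the convention that zero (or negative)
degrees contribute 0 to D^{−1/2}, so isolated nodes drop out of the
penalty.

Negative Pearson correlations are kept by the similarity module, but the
fitting pipeline clips them at 0 before graph construction by default
(`HyperParams.clip_negative_similarity`). With signed weights the
Laplacian can be indefinite and the penalty loses its distance
interpretation; the signed literal behavior remains available behind the
flag for inspection, and the spectral guarantees (L PSD, eigenvalues of
L̃ in [0, 2]) are only asserted in the nonnegative regime.

## Optimization

Minimization is block coordinate descent over rows. The objective
restricted to row a_i is a k-dimensional quadratic whose exact minimizer
solves

    a_i [Σ_j W(i,j) b_j b_jᵀ + (λ_l + λ_d L̃_d(i,i)) I_k]
        = Σ_j W(i,j) R(i,j) b_j − λ_d Σ_{r≠i} L̃_d(i,r) a_r,

and symmetrically for b_j. One sweep updates all rows of A then all rows
of B, Gauss–Seidel style (each update sees rows already updated in the
sweep); a Jacobi mode exists for debugging. The diagonal Laplacian term is
folded into the left-hand side deliberately: the variant that keeps
λ_d L̃_d(i,i) a_i on the right with the row's previous value has the same
fixed points (both encode ∂J/∂a_i = 0) but is only a fixed-point
iteration — on small problems with weakly observed rows it can oscillate
or diverge (we observed numeric overflow), whereas the exact per-row
minimizer makes every update non-increasing in J. An objective increase is
therefore unexpected and logged as a warning, not an error.

The k×k systems are solved with `numpy.linalg.solve`, never by forming an
inverse. A row or column with zero observed entries is permitted — its
update is driven by the graph and Tikhonov terms alone — which requires
λ_l > 0; a singular system raises an error naming that remedy.

Initialization is deterministic: unobserved entries are filled with the
mean of the observed ones, a rank-k truncated SVD UΣVᵀ is taken, and
A = U_k Σ_k^{1/2}, B = V_k Σ_k^{1/2}, with singular-vector signs fixed so
repeated runs are bit-identical. A Gaussian fallback (scale 1/√k) is
selectable. Convergence: stop when the relative objective change between
sweeps is below `tol` (default 1e-5) or after `max_sweeps` (default 200).
The trajectory of objective values (including the initial one) is kept on
the fitted result for diagnostics.

## Hyperparameters

| parameter | meaning | default | why |
|---|---|---|---|
| k | latent dimension | 10 | must be chosen per dataset; the synthetic fixture uses the generating rank 2 |
| λ_l | Tikhonov weight | 0.5 | center of the customary search range {2⁻²…2¹}; required > 0 for unobserved rows |
| λ_d, λ_c | graph weights | 0.125 | mid-range of {2⁻⁵…2¹}; 0 disables a graph |
| p_drug, p_cell | neighbor counts | 20 | standard choice at GDSC scale (~135 drugs); small fixtures use p ≈ 20% of entities |
| tol | relative objective change | 1e-5 | balances runtime against fixed-point accuracy |
| max_sweeps | sweep cap | 200 | all tested fixtures converge well before this |

`grid_search` tunes any subset by exhaustive Cartesian search scored by
drug-averaged PCC from inner cross-validation on the training data only
(nested when called inside an outer CV — the only leak-free protocol).
Ties prefer larger λ_l, then smaller k: when scores are
indistinguishable, take the more regularized model.

## Evaluation protocol

Cross-validation is entry-wise: the observed entries are partitioned into
k near-equal folds per repeat (sizes differ by at most 1), each fold's
mask bits are cleared, the model is refit on the remainder, and held-out
predictions are collected; after all folds every observed entry has been
predicted exactly once. Repeats use seeds derived from the master seed
via `numpy.random.SeedSequence.spawn`, so runs are reproducible
end-to-end. Per drug, PCC and RMSE are computed from the assembled pairs;
PCCsr/RMSEsr restrict to the union of the drug's sensitive and resistant
quartiles, each of size floor(nd/4) (the middle remainder is discarded so
both extreme groups stay equal-sized), ranked on observed responses with
ties broken by identifier order. The orientation flag declares whether
low values mean sensitive (IC50-like, default) or high values do
(activity-area-like). Drugs with fewer than 4 observed responses are
excluded from the quartile metrics with a logged notice; a drug whose
prediction (or observation) vector has zero variance yields an undefined
PCC, reported as NaN and excluded from averages with a counted warning.
Summaries are the mean ± sd over drugs of each drug's metric averaged
across repeats.

## Case-study utilities

`rank_unmeasured` orders a drug's unobserved cell lines by predicted
response, most sensitive first, under the declared orientation.
`ranksum_compare` is a two-sided Wilcoxon rank-sum test on pooled
midranks. For pooled n ≤ 20 the p-value is exact: a subset-sum dynamic
program over doubled midranks enumerates the permutation-null
distribution of the group-A rank sum (valid under ties); above 20 a
normal approximation with the standard tie correction and a 0.5
continuity correction is used. The two branches agree to well under 0.01
absolute just above the switch point. The exact two-sided p of identical
groups is 1 by symmetry; p-values are reported in (0, 1].

## Synthetic data

`generate(n=25, m=40, k_true=2, noise_sd=0.1, missing_fraction=0.2, seed)`
draws truth factors from a standard Gaussian, sets truth_R = ABᵀ, adds
N(0, (noise_sd·sd(truth_R))²) noise, hides exactly
round(missing_fraction·n·m) uniformly chosen entries, and builds both
similarity matrices as cosine similarity among the truth-factor rows
mapped to [0, 1]. Deriving similarities from the true factors (rather
than from noisy surrogate features) makes the local-invariance assumption
hold by construction, so tests on these fixtures isolate solver
correctness. What the generator does **not** emulate: realistic IC50
distributions (heavy tails, drug-specific scales), tissue or pathway
structure, fingerprint sparsity patterns, or informative missingness.
Passing tests therefore demonstrate correct optimization and protocol
mechanics, not expected accuracy on screening data. A fingerprint
emulation path (thresholded Gaussian projections of the factors, with a
guard bit against empty rows) exists solely to exercise the Jaccard
route end-to-end.

The reference fixture used in tests and the acceptance script is the
generator's default configuration with seed 0 (3 CV repeats, 10 folds;
fit with k=2, λ_l=0.25, λ_d=λ_c=0.125, p=5 — mid-grid regularization and
a neighbor fraction matching common practice at this scale). These sizes
keep the full suite in the tens of seconds while leaving the recovery
thresholds (masked-entry PCC ≥ 0.9, CV drug-averaged PCC ≥ 0.85) far from
their observed values (≈0.999 and ≈0.95–0.99).

## Numerical choices and edge cases

- Exact symmetrization of every similarity before graph construction.
- p-NN tie-break: smallest index; quartile tie-break: identifier order;
  ranking tie-break: column order. All deterministic.
- Zero-degree nodes: D^{−1/2} entry set to 0 (isolated nodes drop out).
- Model files are JSON (factors, ids, trajectory, hyperparameters);
  floats survive the round trip exactly. CSV I/O writes shortest
  round-trip representations and parses with round-trip float precision,
  so write→read is bit-identical.
- CSV/TSV dialect chosen by file extension; empty cells, `NA`, `NaN` are
  missing-value tokens in response files and errors elsewhere.
- Outputs are written atomically (temp file + rename).

## Known limitations

- The loss weights all observed entries equally; no per-entry variance
  or censoring model.
- Graph regularization helps only as much as the similarities are
  informative; on the low-noise synthetic fixture its measured benefit
  over the λ_d=λ_c=0 ablation is real but small, since the data term
  already identifies the factors.
- The objective is non-convex; coordinate descent finds a stationary
  point, verified against a generic minimizer only on small instances.
- Hyperparameter search is exhaustive; large grids on large matrices are
  costly (no surrogate-model search).
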