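# fluxsig

Flux-sampling signatures of high-producing metabolic states.

`fluxsig` is a constraint-based modeling pipeline for asking: *which
metabolic reactions are associated with high recombinant-protein
production in a cell factory?*  It was designed around fed-batch CHO
(Chinese hamster ovary) cultures producing a monoclonal antibody, where
no single objective function (growth vs. production) can be justified,
so the steady-state solution space is explored **without** an objective,
by uniform flux sampling.

## The method

A genome-scale metabolic model defines the flux polytope

```
P = { v : S v = 0,  lb <= v <= ub }
```

with `S` the stoichiometric matrix and `v` in mmol/gDW/h.  The pipeline:

1. **Adapts the model to the product.**  Antibody heavy/light-chain
   peptide sequences are converted into a translation pseudo-reaction
   consuming each amino acid by residue count plus ATP, GTP and H₂O
   (default energetics: 1 ATP→AMP+PPᵢ and 2 GTP→GDP+Pᵢ per residue,
   configurable), producing one unit of product.  Bioprocess rates α
   (pg/cell/h) convert to flux units via `(α·10⁻¹²/β)·(1000/γ)` with β
   the dry cell weight (g) and γ the metabolite Mr (g/mol).
2. **Constrains bounds from transcriptomics.**  Samples are averaged per
   culture phase (early exponential / late exponential /
   stationary-death); each reaction's expression is obtained through its
   gene-protein-reaction (GPR) rule (AND = min, OR = max) and, directed
   by reversibility, becomes a bound ceiling: reversible → `[-v', +v']`,
   irreversible → `[0, +v']`.  Reactions with genes missing from the
   data, or without a GPR, are left unconstrained.
3. **Samples the polytope uniformly** by coordinate hit-and-run with
   rounding (CHRR): an orthonormal null-space parameterization, an
   adaptive covariance-based rounding transform, and uniform draws along
   coordinate chords; every `thinning`-th point is stored, so 50,000,000
   iterations stored every 10,000 give 5000 solutions per reaction per
   model.
4. **Isolates high producers and tests for skew.**  The top 5% of
   solutions by product flux (250 of 5000) are compared against the
   solution pool with a two-sided Mann–Whitney U test per reaction;
   Benjamini–Hochberg FDR < 0.05 flags reactions whose flux distribution
   is skewed in high-producing solutions.
5. **Summarizes**: cross-phase overlap counts (upset-style), subsystem
   enrichment normalized by subsystem size, PCA of the high-producing
   solutions, and an amino-acid transport signature assembled from the
   top-50 PC1/PC2 loadings intersected with the significant transport
   reactions.

A `synthetic_data` module generates toy models with *planted* ground
truth — amino-acid importers stoichiometrically coupled to product flux,
plus uncoupled decoy pathways — so every stage is testable end to end
without any downloads.

## Worked example

```python
from fluxsig import (
    ToyModelConfig, SyntheticExpressionConfig, generate_toy_model,
    generate_synthetic_expression, build_phase_model, sample_model,
    select_high_producers, test_flux_skew, infer_transport_annotation,
    pca_solutions, extract_transport_signature,
)

model, truth = generate_toy_model(ToyModelConfig(seed=0))
table = generate_synthetic_expression(model, SyntheticExpressionConfig(seed=0))
phase_model = build_phase_model(model, table, "late_exponential")

samples = sample_model(phase_model.model, total_iterations=300_000,
                       thinning=60, seed=0, phase="late_exponential")
selection = select_high_producers(samples, truth.product_reaction_id,
                                  percentile=95.0)
print(f"{selection.n_selected} high-producing solutions out of {samples.n_stored}")

results = test_flux_skew(samples, selection, fdr_threshold=0.05)
pca = pca_solutions(samples.to_frame().iloc[selection.indices])
print(f"PC1 explains {pca.explained_variance_pct[0]:.1f}% of variance")

signature = extract_transport_signature(
    pca.loadings, results, samples, selection,
    infer_transport_annotation(model), top_k=50, phase="late_exponential",
)
print(signature[["amino_acid", "reaction", "transport_direction",
                 "mean_flux_high", "mean_flux_pool", "regulation"]].round(3))
```

prints

```
250 high-producing solutions out of 5000
PC1 explains 42.6% of variance
  amino_acid  reaction transport_direction  mean_flux_high  mean_flux_pool regulation
0          A  T_ala__L              import           5.846           3.025         up
1          C  T_cys__L              import           5.846           3.025         up
2          K  T_lys__L              import           9.744           5.041         up
3          F  T_phe__L              import           9.744           5.041         up
```

Exactly the four amino-acid importers that feed the toy product carry
higher mean flux in the high-producing selection ("up") — the planted
transport signature is recovered.  The same workflow runs from the shell:

```bash
fluxsig simulate --out demo --seed 0          # toy SBML + expression CSVs
fluxsig run --config config.yaml              # full pipeline, timestamped run dir
```

with per-stage subcommands (`constrain`, `sample`) for resumable runs.
Real inputs are an SBML (L3+fbc) model, a genes × samples expression
table (TSV/CSV) and a sample → phase CSV.

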