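# Methods

This note documents the models, numerical choices and limitations behind
`fluxsig`, in the order the pipeline runs.

## Model representation and product adaptation

A model is a stoichiometric network: metabolites with compartments
(`c` cytosol, `e` extracellular), reactions with flux bounds in
mmol/gDW/h, boolean GPR rules over gene ids, and optional subsystem
labels.  SBML Level 3 I/O uses the fbc package for bounds and
gene-product associations and the groups package for subsystems; files
without fbc bound parameters fall back to the de-facto convention of
(−1000, 1000) for reversible and (0, 1000) for irreversible reactions,
with a logged warning.  Metabolite ids follow the compartment-suffixed
BIGG style (`atp_c`, `ala__L_e`).

**Translation reaction.**  The product pseudo-reaction consumes each
amino acid by its total residue count over the configured chain copies
(2 heavy + 2 light for an IgG) and charges NTP hydrolysis per residue.
The default scheme is 1 ATP → AMP + PPᵢ (aminoacyl-tRNA charging) and
2 GTP → GDP + Pᵢ (ribosomal delivery and translocation), one H₂O
consumed and one H⁺ released per hydrolysis event — standard translation
energetics.  The exact coefficients used in published CHO models are not
generally recoverable, so the scheme is a configuration object
(`TranslationCostScheme`): per-residue ATP→AMP, ATP→ADP and GTP→GDP
counts can be set to reproduce alternative bookkeeping, including
variants that emit ADP.

**Unit conversion.**  Bioprocess rates α in pg/cell/h convert to flux by
`(α·10⁻¹²/β)·(1000/γ)` with β the dry cell weight in g/cell and γ the
metabolite molecular weight in g/mol.  This is the only dimensionally
consistent reading of the compact formula α∗10⁻¹²β∗(1000/γ): pg → g,
per cell → per g dry weight, g → mmol.  The sign convention is positive
for production, negative for consumption.  Published dry-cell-weight
values vary by cell line and condition (order 200–400 pg/cell); β is
always an explicit argument, never a constant.

## Transcriptomics integration

Expression values are normalized counts, averaged arithmetically over
each phase's replicate samples.  The default fed-batch phase grouping is
day 4 (early exponential), days 6–8 (late exponential), days 11–14
(stationary/death), with day 5 excluded as a suspected batch effect; the
grouping is plain configuration (`sample → phase` CSV).

GPR evaluation uses AND = min (a complex is limited by its scarcest
subunit) and OR = max (isozymes are redundant); OR = sum is available
via `or_mode="sum"`.  A gene absent from the table makes its leaf
"missing"; missing propagates through AND but is ignored by OR unless
all branches are missing.  Reactions with a missing evaluation or no GPR
keep their original bounds, with the reason recorded per reaction
(`gene_missing` / `no_gpr`) — removing them instead would routinely make
the model infeasible.

Expression lives on a count scale, not a flux scale.  The default
scaling maps the largest reaction-level value onto the model's largest
bound magnitude, `v' = (v / max v) · default_bound`, preserving relative
ordering — which is all the downstream rank-based statistics consume —
and the factor is exposed for sensitivity analysis.  Bounds are only
ever tightened (reversible → `[-v', v']`, irreversible → `[0, v']`,
clipped to the original interval), so constraining is monotone in
expression and idempotent.  After constraining, a feasibility LP checks
that the polytope is non-empty and raises rather than returning an
unusable model.

## Flux sampling (CHRR)

The polytope `{v : S v = 0, lb ≤ v ≤ ub}` is parameterized on an
orthonormal null-space basis of `S`; reactions fixed by `lb = ub` are
folded into the equality system so the basis spans only movable
directions (residual tolerance 1e-9).

**Anchor.**  An interior start point comes from a maximum-slack LP:
maximize Σ sⱼ subject to `lbⱼ + sⱼ ≤ vⱼ ≤ ubⱼ − sⱼ`, with every slack
capped at half the narrowest free reaction's half-span.  The uniform cap
matters: an uncapped sum objective trades narrow pathways (e.g. a
product reaction bounded at 1) away for large slacks on wide exchange
reactions and parks the anchor on a vertex, which stalls the chain.
With the cap, the optimum pulls every movable reaction strictly inside
its bounds, while conservation-blocked reactions simply get zero slack.

**Rounding.**  The rounding transform is covariance-based and adaptive:
pilot chains (20·k stored points, thinned by k) estimate the covariance
of the null-space coordinates; its Cholesky factor becomes the
coordinate transform and the anchor is re-centered at the pilot mean
(feasible by convexity).  Rounds repeat (up to 10) until the explored
scale stops growing, because a single pilot cannot discover a direction
six orders of magnitude longer than its starting neighborhood; the
identity is used for k ≤ 2 or a near-singular covariance.  Max-volume
ellipsoid rounding would be the higher-fidelity alternative behind the
same interface.

**Chain.**  Each step picks one rounded coordinate uniformly at random,
intersects the line with every bound to get the feasible chord, clips
the endpoints inward by 1e-12 (boundary sticking) and jumps to a uniform
point.  The first thinning-interval of iterations is discarded as
warm-up (configurable); thereafter every `thinning`-th point is stored,
giving exactly `floor(total/thinning)` rows — 50 M iterations stored
every 10 k give 5000 solutions, the production-scale bookkeeping.  The
kernel consumes pre-generated random streams, so results are bitwise
reproducible per seed and identical between the numba-compiled and
pure-Python implementations.  Stored rows are validated against
`‖S v‖_max ≤ 1e-6` and bounds with 1e-6 slack.

## High-producer statistics

The selection takes the top `round((1 − p/100)·n)` rows by product flux
(stable tie-break: flux descending, row index ascending), 250 of 5000 at
the default 95th percentile.  Per reaction, a two-sided Mann–Whitney U
(normal approximation with tie and continuity correction) compares the
selection against the pool; the default pool is the full solution set
(250 vs 5000, selection overlapping), matching the stated comparison of
the workflow this package operationalizes, with the statistically
cleaner disjoint variant (`pool="rest"`) behind a flag.  A reaction
constant across both groups reports p = 1, not an exception.  P-values
are Benjamini–Hochberg adjusted; direction is the sign of the *median*
difference (robust to the skewed marginals flux sampling produces) and
only assigned below the FDR threshold.

Overlap counts partition the union of per-phase significant sets over
all non-empty phase combinations.  Subsystem enrichment reports
up/down counts and proportions normalized by the subsystem's total size
in the model, with unannotated reactions tallied separately.  PCA
standardizes reactions (zero-variance reactions dropped and reported) —
whether to standardize is genuinely open; unstandardized is a flag.  The
transport signature takes the union of the top-50 loadings by
*magnitude* on PC1 and PC2 (signed "top" would discard strong negative
loadings for no reason), intersects with significant reactions, and
keeps those classified as amino-acid transport.  Classification is
derived from stoichiometry — a reaction moving a whitelisted amino acid
between `e` and `c`, import when the forward direction consumes the
extracellular species — and can be overridden by a CSV where curated
annotations exist.

## Synthetic data and what passing tests mean

The toy generator builds a miniature network with the same anatomy as
the real target: amino-acid exchanges and importers ("Transport
reactions"), a translation reaction from short random peptides, a
product demand, cofactor sinks ("Exchange/demand/sink reactions"), a
glucose chain ("Central metabolism") and a fatty-acid branch ("Fatty
acid metabolism").  Product amino acids have a single importer and no
alternative cytosolic fate, so importer flux is provably
(residue count) × (product flux) — verified by an LP oracle at both
product-flux extremes.  Decoy amino acids feed an independent demand,
giving reactions exactly uncorrelated with production under the uniform
distribution.  Expression is log-normal (baseline log-mean 5, gene
spread 1, replicate dispersion 0.25, 6 replicates per phase) with
multiplicative planted fold changes; log-normal is simple, strictly
positive and adequate for rank-based downstream statistics — a
negative-binomial count generator would be the closer emulation of
normalized RNA-seq counts and is a known gap.

Benchmark conditions (`fluxsig.experiments`): 5000 stored solutions per
run at thinning 60 (≈4× the toy polytope dimension, enough that stored
draws are effectively independent at this scale), 95th percentile,
FDR 0.05, 20 seeded replicates.  Recovery requires *every* planted
importer at q < 0.05 with direction "increased"; the null arm selects on
a decoy demand and measures the flagged fraction outside the decoy's own
three-reaction pathway.

What this does *not* show: the toy polytope is low-dimensional and
nearly a product of independent blocks, so chain mixing, test
calibration and signature recovery here do not bound behavior on a
genome-scale model with thousands of strongly coupled reactions, where
much heavier thinning (the production 10 k) and longer rounding phases
are needed.  Real-data results additionally depend on proprietary
transcriptomics and a full curated CHO reconstruction and are not
reproduced by this package; the pipeline emits the same artifact schemas
on toy inputs so that a real run is a configuration change, not a code
change.

## Known limitations

- No convergence diagnostics beyond marginal-moment checks (no formal
  potential-scale-reduction statistic).
- The expression→bound scaling is a design choice, not an identified
  quantity; only rank-based downstream conclusions are insensitive to it.
- Transport classification from stoichiometry misses transporters whose
  metabolite ids deviate from the BIGG-style whitelist (override by CSV).
- Glycosylation, thermodynamic and enzyme-capacity constraints are out
  of scope.
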