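"""Statistics on sampled flux solutions: high-producer isolation,
per-reaction flux-skew tests, overlap/enrichment summaries, PCA and the
amino-acid transport signature.

High-producing solutions are the top percentile (default 95th) of sampled
flux vectors by product-reaction flux — with 5000 stored solutions this is
250 rows.  Each reaction's flux distribution in the selection is compared
against the comparison pool with a two-sided Mann-Whitney U test (null:
the flux distribution does not change in the high-producing solutions);
p-values are Benjamini-Hochberg adjusted and reactions with FDR q below
the threshold (default 0.05) are called skewed, with the direction taken
from the median difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .model import AMINO_ACID_METABOLITES, MetabolicModel
from .sampler import FluxSampleSet

__all__ = [
    "HighProducerSelection",
    "SkewTestResult",
    "select_high_producers",
    "mann_whitney_u",
    "bh_adjust",
    "test_flux_skew",
    "skew_results_frame",
    "significant_reactions",
    "overlap_counts",
    "subsystem_enrichment",
    "PCAResult",
    "pca_solutions",
    "infer_transport_annotation",
    "extract_transport_signature",
]


@dataclass
class HighProducerSelection:
    """Indices of the top-percentile solutions by product flux, in
    decreasing product-flux order (ties broken by ascending row index)."""

    percentile: float
    indices: np.ndarray
    product_reaction_id: str

    @property
    def n_selected(self) -> int:
        return len(self.indices)


def select_high_producers(
    samples: FluxSampleSet,
    product_reaction_id: str,
    percentile: float = 95.0,
) -> HighProducerSelection:
    """Select the top (100 - percentile)% of solutions by product flux.

    Exactly ``round((1 - percentile/100) * n_stored)`` rows are selected;
    at ties the stable order (flux descending, original row index
    ascending) decides, so the selection is deterministic.
    """
    if not (0 < percentile < 100):
        raise ValueError(f"percentile must be in (0, 100), got {percentile}")
    if product_reaction_id not in samples.reaction_ids:
        raise KeyError(
            f"product reaction {product_reaction_id!r} not among sampled reactions"
        )
    flux = samples.flux(product_reaction_id)
    n_sel = int(round((1.0 - percentile / 100.0) * samples.n_stored))
    order = np.argsort(-flux, kind="stable")
    return HighProducerSelection(
        percentile=percentile,
        indices=order[:n_sel],
        product_reaction_id=product_reaction_id,
    )


@dataclass
class SkewTestResult:
    """Per-reaction association of flux with high production."""

    reaction_id: str
    U: float
    p: float
    q: float
    direction: str           # "increased" | "decreased" | "none"
    median_high: float
    median_pool: float


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U of ``x`` versus ``y`` (normal approximation
    with tie and continuity correction).  Returns (U of x, p).  Degenerate
    input with all values identical across both groups yields p = 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(np.concatenate([x, y])) == 0:
        return len(x) * len(y) / 2.0, 1.0
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def test_flux_skew(
    samples: FluxSampleSet,
    selection: HighProducerSelection,
    fdr_threshold: float = 0.05,
    pool: str = "full",
) -> list[SkewTestResult]:
    """Mann-Whitney U per reaction between the selected solutions and the
    comparison pool, with BH-FDR adjustment.

    ``pool="full"`` compares the selection against all stored solutions
    (the selection overlaps the pool, e.g. 250 vs 5000);
    ``pool="rest"`` uses the disjoint complement (250 vs 4750).
    Direction is the sign of the median difference for reactions with
    q < ``fdr_threshold``, "none" otherwise.
    """
    if pool not in ("full", "rest"):
        raise ValueError(f"pool must be 'full' or 'rest', got {pool!r}")
    sel_idx = selection.indices
    if pool == "full":
        pool_idx = np.arange(samples.n_stored)
    else:
        mask = np.ones(samples.n_stored, dtype=bool)
        mask[sel_idx] = False
        pool_idx = np.flatnonzero(mask)

    n_rxn = len(samples.reaction_ids)
    U = np.empty(n_rxn)
    pvals = np.empty(n_rxn)
    med_high = np.empty(n_rxn)
    med_pool = np.empty(n_rxn)
    for j, rid in enumerate(samples.reaction_ids):
        col = samples.samples[:, j]
        high = col[sel_idx]
        comp = col[pool_idx]
        U[j], pvals[j] = mann_whitney_u(high, comp)
        med_high[j] = np.median(high)
        med_pool[j] = np.median(comp)

    qvals = bh_adjust(pvals)
    results = []
    for j, rid in enumerate(samples.reaction_ids):
        if qvals[j] < fdr_threshold:
            diff = med_high[j] - med_pool[j]
            direction = "increased" if diff > 0 else ("decreased" if diff < 0 else "none")
        else:
            direction = "none"
        results.append(
            SkewTestResult(
                reaction_id=rid,
                U=float(U[j]),
                p=float(pvals[j]),
                q=float(qvals[j]),
                direction=direction,
                median_high=float(med_high[j]),
                median_pool=float(med_pool[j]),
            )
        )
    return results


def skew_results_frame(results: list[SkewTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.reaction_id, r.U, r.p, r.q, r.direction, r.median_high, r.median_pool)
            for r in results
        ],
        columns=["reaction", "U", "p", "q", "direction", "median_high", "median_pool"],
    )


def significant_reactions(
    results: list[SkewTestResult], fdr_threshold: float = 0.05
) -> set[str]:
    return {r.reaction_id for r in results if r.q < fdr_threshold}


def overlap_counts(per_phase_sets: dict[str, set[str]]) -> dict[tuple[str, ...], int]:
    """Upset-style membership counts: for every non-empty phase combination,
    the number of reactions significant in exactly those phases.  The
    counts partition the union of all sets."""
    if len(per_phase_sets) < 2:
        raise ValueError("need at least 2 phases to compute overlaps")
    phases = list(per_phase_sets)
    counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(phases) + 1):
        for combo in combinations(phases, r):
            counts[tuple(combo)] = 0
    union = set().union(*per_phase_sets.values())
    for rid in union:
        member = tuple(p for p in phases if rid in per_phase_sets[p])
        counts[member] += 1
    return counts


def subsystem_enrichment(
    results: list[SkewTestResult],
    model: MetabolicModel,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-subsystem counts and proportions of skewed reactions.

    ``prop_up`` / ``prop_down`` normalize by the subsystem's total reaction
    count in the model, so small and large subsystems are comparable.
    Reactions without a subsystem annotation are reported under
    "(unannotated)".
    """
    sub_of = {r.id: (r.subsystem or "(unannotated)") for r in model.reactions}
    sizes: dict[str, int] = {}
    for r in model.reactions:
        key = r.subsystem or "(unannotated)"
        sizes[key] = sizes.get(key, 0) + 1
    up: dict[str, int] = {}
    down: dict[str, int] = {}
    for res in results:
        if res.q < fdr_threshold and res.direction != "none":
            key = sub_of.get(res.reaction_id, "(unannotated)")
            target = up if res.direction == "increased" else down
            target[key] = target.get(key, 0) + 1
    rows = []
    for sub in sorted(sizes):
        n_up = up.get(sub, 0)
        n_down = down.get(sub, 0)
        size = sizes[sub]
        rows.append((sub, n_up, n_down, size, n_up / size, n_down / size))
    return pd.DataFrame(
        rows,
        columns=["subsystem", "n_up", "n_down", "subsystem_size", "prop_up", "prop_down"],
    )


@dataclass
class PCAResult:
    scores: np.ndarray                  # rows x components
    loadings: pd.DataFrame              # reactions x components, unit-norm columns
    explained_variance_pct: np.ndarray  # percentages, non-increasing
    dropped_reactions: list[str]


def pca_solutions(
    high_flux: pd.DataFrame,
    n_components: int | None = None,
    standardize: bool = True,
) -> PCAResult:
    """Principal components of the selected solutions' flux matrix.

    Zero-variance reactions are dropped (and reported); the rest are
    standardized by default so every reaction contributes on the same
    scale.  Loadings are the unit-norm principal axes.
    """
    if high_flux.shape[0] < 2:
        raise ValueError("need at least 2 solutions for PCA")
    variances = high_flux.var(axis=0, ddof=0)
    keep = variances[variances > 0].index
    dropped = [c for c in high_flux.columns if c not in set(keep)]
    X = high_flux[keep].to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 non-constant reactions for PCA")
    if standardize:
        X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    k = min(n_components or min(X.shape), min(X.shape[0] - 1, X.shape[1]))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(X)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=list(keep),
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_pct=pca.explained_variance_ratio_ * 100.0,
        dropped_reactions=dropped,
    )


def infer_transport_annotation(
    model: MetabolicModel,
    metabolite_whitelist: dict[str, str] | None = None,
) -> dict[str, tuple[str, str]]:
    """Classify amino-acid transport reactions from stoichiometry.

    A reaction moving a whitelisted metabolite between the extracellular
    ("e") and cytosolic ("c") compartments is annotated as that amino
    acid's transporter; orientation is "import" when the forward direction
    consumes the extracellular species, "export" otherwise.  The default
    whitelist maps the BIGG-style base ids of the 20 amino acids to their
    one-letter codes.  Override or extend via ``metabolite_whitelist``
    (base metabolite id -> label).
    """
    if metabolite_whitelist is None:
        metabolite_whitelist = {
            base: aa for aa, base in AMINO_ACID_METABOLITES.items()
        }
    comp_of = {m.id: m.compartment for m in model.metabolites}

    def base_id(met_id: str, comp: str) -> str:
        suffix = "_" + comp
        return met_id[: -len(suffix)] if met_id.endswith(suffix) else met_id

    annotation: dict[str, tuple[str, str]] = {}
    for rxn in model.reactions:
        for met_id, coef in rxn.stoichiometry.items():
            comp = comp_of.get(met_id, "")
            if comp != "e":
                continue
            base = base_id(met_id, comp)
            if base not in metabolite_whitelist:
                continue
            partner = base + "_c"
            if partner not in rxn.stoichiometry:
                continue
            if np.sign(rxn.stoichiometry[partner]) == np.sign(coef):
                continue
            orientation = "import" if coef < 0 else "export"
            annotation[rxn.id] = (metabolite_whitelist[base], orientation)
    return annotation


def extract_transport_signature(
    loadings: pd.DataFrame,
    results: list[SkewTestResult],
    samples: FluxSampleSet,
    selection: HighProducerSelection,
    transport_annotation: dict[str, tuple[str, str]],
    top_k: int = 50,
    fdr_threshold: float = 0.05,
    phase: str = "",
) -> pd.DataFrame:
    """Amino-acid transport signature of high-producing solutions.

    Takes the union of the ``top_k`` reactions by loading magnitude on PC1
    and PC2, intersects with the significantly skewed reactions
    (q < threshold), keeps those annotated as amino-acid transport, and
    reports mean flux in the selection versus the full pool, the
    regulation direction, and a per-amino-acid net-uptake summary
    (import minus export of selection means over the listed reactions).
    Returns an empty table when nothing qualifies.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    pcs = [c for c in ("PC1", "PC2") if c in loadings.columns]
    top: set[str] = set()
    for pc in pcs:
        ranked = loadings[pc].abs().sort_values(ascending=False, kind="stable")
        top.update(ranked.index[:top_k])

    by_id = {r.reaction_id: r for r in results}
    rows = []
    for rid in sorted(top):
        res = by_id.get(rid)
        if res is None or res.q >= fdr_threshold:
            continue
        if rid not in transport_annotation:
            continue
        aa, orientation = transport_annotation[rid]
        flux = samples.flux(rid)
        mean_high = float(flux[selection.indices].mean())
        mean_pool = float(flux.mean())
        regulation = "up" if res.direction == "increased" else (
            "down" if res.direction == "decreased" else "none"
        )
        rows.append((phase, aa, rid, orientation, mean_high, mean_pool, regulation))
    table = pd.DataFrame(
        rows,
        columns=[
            "phase", "amino_acid", "reaction", "transport_direction",
            "mean_flux_high", "mean_flux_pool", "regulation",
        ],
    )
    if len(table):
        signed = np.where(
            table["transport_direction"] == "import",
            table["mean_flux_high"],
            -table["mean_flux_high"],
        )
        net = pd.Series(signed, index=table.index).groupby(table["amino_acid"]).sum()
        table["net_uptake_high"] = table["amino_acid"].map(net)
    else:
        table["net_uptake_high"] = pd.Series(dtype=float)
    return table
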