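"""Toy metabolic models and synthetic expression tables with planted,
known ground truth.

The generated network emulates, at miniature scale, the structure the
pipeline targets in a real genome-scale model: amino-acid import from the
medium, a product translation pseudo-reaction built from short random
heavy/light peptide chains, a product demand reaction, cofactor
supply/sinks, a small central-metabolism chain and a fatty-acid reaction
— each annotated to a subsystem.  Amino acids consumed by the product have
a single importer and no alternative cytosolic fate, so importer flux is
stoichiometrically forced to ``(residue count) x (product flux)``: these
importers are the planted coupled reactions the signature pipeline must
recover.  Decoy amino acids get an importer feeding an independent demand,
so their flux is uncorrelated with production — the negative controls.

The expression generator produces phase-grouped replicate samples with
log-normal noise and planted per-phase fold changes on chosen genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    AMINO_ACID_METABOLITES,
    GPR,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_product_translation_reaction,
    validate_model,
)
from .omics import ExpressionTable

__all__ = [
    "ToyModelConfig",
    "ToyGroundTruth",
    "SyntheticExpressionConfig",
    "generate_toy_model",
    "generate_synthetic_expression",
]

SUB_TRANSPORT = "Transport reactions"
SUB_EXCHANGE = "Exchange/demand/sink reactions"
SUB_CENTRAL = "Central metabolism"
SUB_FATTY = "Fatty acid metabolism"

_COFACTORS = ("atp", "gtp", "h2o", "amp", "adp", "gdp", "pi", "ppi", "h")


@dataclass
class ToyModelConfig:
    """Knobs for the generated toy network.

    ``n_amino_acids`` amino acids feed the product (their importers are the
    planted coupled reactions); ``n_decoy_amino_acids`` get independent
    demand instead.  ``n_internal_metabolites`` sets the length of the
    central-metabolism chain.  Peptide chains are random with
    ``peptide_length`` residues each (kept short so stoichiometry stays
    hand-checkable).
    """

    n_amino_acids: int = 4
    n_decoy_amino_acids: int = 3
    n_internal_metabolites: int = 2
    include_product: bool = True
    include_biomass: bool = True
    peptide_length: int = 8
    product_flux_cap: float = 1.0
    transport_cap: float = 1000.0
    seed: int = 0


@dataclass
class ToyGroundTruth:
    """What the generator planted, for closed-loop testing."""

    coupled_reactions: dict[str, float]     # reaction id -> flux per unit product
    uncoupled_reactions: list[str]
    importer_gene: dict[str, str]           # importer reaction id -> its gene
    product_reaction_id: str | None
    decoy_demand_reactions: list[str] = field(default_factory=list)
    heavy_seq: str = ""
    light_seq: str = ""


def _random_peptides(aas: list[str], length: int, rng: np.random.Generator):
    """Two random chains over ``aas``; every amino acid appears at least
    once across the concatenated chains."""
    letters = list(aas)
    pool = rng.choice(letters, size=2 * length).tolist()
    for i, aa in enumerate(letters):
        pool[i % (2 * length)] = aa
    return "".join(pool[:length]), "".join(pool[length:])


def generate_toy_model(
    config: ToyModelConfig,
) -> tuple[MetabolicModel, ToyGroundTruth]:
    """Build the toy network; returns the model plus its ground truth.

    The model passes :func:`validate_model` and has a non-empty flux
    polytope by construction.
    """
    if config.include_product and config.n_amino_acids < 1:
        raise ValueError("a product requires at least one amino acid")
    if config.peptide_length < 1:
        raise ValueError("peptide_length must be >= 1")
    total_aas = config.n_amino_acids + config.n_decoy_amino_acids
    alphabet = sorted(AMINO_ACID_METABOLITES)
    if total_aas > len(alphabet):
        raise ValueError(f"at most {len(alphabet)} amino acids available")

    rng = np.random.default_rng(config.seed)
    chosen = list(rng.choice(alphabet, size=total_aas, replace=False))
    product_aas = chosen[: config.n_amino_acids]
    decoy_aas = chosen[config.n_amino_acids:]

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    genes: list[str] = []

    def add_gene(g: str) -> str:
        genes.append(g)
        return g

    cap = config.transport_cap
    for aa in chosen:
        base = AMINO_ACID_METABOLITES[aa]
        mets.append(Metabolite(base + "_e", name=base, compartment="e"))
        mets.append(Metabolite(base + "_c", name=base, compartment="c"))
        rxns.append(
            Reaction(f"EX_{base}_e", {base + "_e": -1.0}, -cap, cap,
                     subsystem=SUB_EXCHANGE)
        )
        g = add_gene(f"g_T_{base}")
        rxns.append(
            Reaction(
                f"T_{base}", {base + "_e": -1.0, base + "_c": 1.0}, 0.0, cap,
                gpr=GPR.parse(g), subsystem=SUB_TRANSPORT,
            )
        )
    for aa in decoy_aas:
        base = AMINO_ACID_METABOLITES[aa]
        rxns.append(
            Reaction(f"DM_{base}_c", {base + "_c": -1.0}, 0.0, 10.0,
                     subsystem=SUB_EXCHANGE)
        )

    product_id = None
    heavy = light = ""
    if config.include_product:
        heavy, light = _random_peptides(product_aas, config.peptide_length, rng)
        translation = build_product_translation_reaction(heavy, light, 2, 2)
        translation.upper_bound = config.product_flux_cap
        g1 = add_gene("g_ribo_large")
        g2 = add_gene("g_ribo_small")
        translation.gpr = GPR.parse(f"{g1} and {g2}")
        translation.subsystem = SUB_CENTRAL
        rxns.append(translation)
        mets.append(Metabolite("product_c", name="mature product", compartment="c"))
        for cf in _COFACTORS:
            mets.append(Metabolite(cf + "_c", name=cf, compartment="c"))
            rxns.append(
                Reaction(f"SK_{cf}_c", {cf + "_c": -1.0}, -cap, cap,
                         subsystem=SUB_EXCHANGE)
            )
        product_id = "product_demand"
        rxns.append(
            Reaction(product_id, {"product_c": -1.0}, 0.0, cap,
                     name="mature product demand", subsystem=SUB_EXCHANGE)
        )
    else:
        # cofactors still exist so central metabolism can run
        for cf in ("atp", "adp", "h"):
            mets.append(Metabolite(cf + "_c", name=cf, compartment="c"))
            rxns.append(
                Reaction(f"SK_{cf}_c", {cf + "_c": -1.0}, -cap, cap,
                         subsystem=SUB_EXCHANGE)
            )

    # central metabolism: glucose import + a short chain
    mets.append(Metabolite("glc__D_e", name="glucose", compartment="e"))
    mets.append(Metabolite("glc__D_c", name="glucose", compartment="c"))
    rxns.append(Reaction("EX_glc__D_e", {"glc__D_e": -1.0}, -cap, cap,
                         subsystem=SUB_EXCHANGE))
    g = add_gene("g_GLCt")
    rxns.append(
        Reaction("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0}, 0.0, 10.0,
                 gpr=GPR.parse(g), subsystem=SUB_TRANSPORT)
    )
    prev = "glc__D_c"
    for i in range(1, config.n_internal_metabolites + 1):
        mid = f"cm{i}_c"
        mets.append(Metabolite(mid, compartment="c"))
        g = add_gene(f"g_CM{i}")
        stoich = {prev: -1.0, mid: 1.0}
        if i == 1:
            stoich.update({"atp_c": -1.0, "adp_c": 1.0, "h_c": 1.0})
        rxns.append(
            Reaction(f"CM{i}", stoich, 0.0, 10.0, gpr=GPR.parse(g),
                     subsystem=SUB_CENTRAL)
        )
        prev = mid
    rxns.append(Reaction(f"DM_{prev}", {prev: -1.0}, 0.0, cap,
                         subsystem=SUB_EXCHANGE))

    biomass_id = None
    if config.include_biomass:
        biomass_id = "biomass"
        rxns.append(
            Reaction(
                biomass_id,
                {prev: -0.5, "atp_c": -2.0, "adp_c": 2.0},
                0.0, 10.0, name="biomass pseudo-reaction",
            )
        )

    # fatty acid branch
    mets.append(Metabolite("fa_c", name="fatty acid", compartment="c"))
    rxns.append(Reaction("SK_fa_c", {"fa_c": -1.0}, -cap, cap,
                         subsystem=SUB_EXCHANGE))
    g = add_gene("g_FAOX")
    rxns.append(
        Reaction("FAOX", {"fa_c": -1.0, "atp_c": -1.0, "amp_c" if config.include_product else "adp_c": 1.0},
                 0.0, 10.0, gpr=GPR.parse(g), subsystem=SUB_FATTY)
    )

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        genes=genes,
        product_reaction_id=product_id,
        biomass_reaction_id=biomass_id,
        id=f"toy_seed{config.seed}",
    )
    report = validate_model(model)
    if not report.is_valid:  # pragma: no cover - construction guarantee
        raise RuntimeError(f"generated toy model invalid:\n{report.summary()}")

    coupled: dict[str, float] = {}
    importer_gene: dict[str, str] = {}
    if config.include_product:
        translation = model.get_reaction("product_translation")
        for aa in product_aas:
            base = AMINO_ACID_METABOLITES[aa]
            coeff = -translation.stoichiometry[base + "_c"]
            coupled[f"T_{base}"] = coeff
            coupled[f"EX_{base}_e"] = -coeff
        coupled[product_id] = 1.0
        coupled["product_translation"] = 1.0
    for rid in ("T_" + AMINO_ACID_METABOLITES[aa] for aa in chosen):
        importer_gene[rid] = f"g_{rid}"
    uncoupled = [
        rid for rid in model.reaction_ids()
        if rid.startswith(("T_", "DM_", "EX_", "CM", "GLCt", "FAOX"))
        and rid not in coupled
    ]
    truth = ToyGroundTruth(
        coupled_reactions=coupled,
        uncoupled_reactions=uncoupled,
        importer_gene=importer_gene,
        product_reaction_id=product_id,
        decoy_demand_reactions=[
            f"DM_{AMINO_ACID_METABOLITES[aa]}_c" for aa in decoy_aas
        ],
        heavy_seq=heavy,
        light_seq=light,
    )
    return model, truth


@dataclass
class SyntheticExpressionConfig:
    """Phase-grouped replicate expression with planted fold changes.

    Baseline expression per gene is log-normal around
    ``baseline_log_mean`` with gene-to-gene spread ``gene_log_sd``;
    within-phase replicates add log-normal noise of dispersion
    ``noise_sd``.  ``planted_fold_changes`` multiplies (gene, phase)
    baselines.  ``omitted_genes`` are excluded from the table to exercise
    the left-unconstrained path downstream.
    """

    phases: tuple[tuple[str, int], ...] = (
        ("early_exponential", 6),
        ("late_exponential", 6),
        ("stationary_death", 6),
    )
    baseline_log_mean: float = 5.0
    gene_log_sd: float = 1.0
    noise_sd: float = 0.25
    planted_fold_changes: dict[tuple[str, str], float] = field(default_factory=dict)
    omitted_genes: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for (label, n) in self.phases:
            if n < 1:
                raise ValueError(f"phase {label!r} must have >= 1 sample")
        for key, fc in self.planted_fold_changes.items():
            if fc <= 0:
                raise ValueError(f"fold change for {key} must be > 0, got {fc}")


def generate_synthetic_expression(
    model: MetabolicModel, config: SyntheticExpressionConfig
) -> ExpressionTable:
    """Simulate a normalized-counts table for the model's genes."""
    model_genes = set(model.genes)
    for gene, _phase in config.planted_fold_changes:
        if gene not in model_genes:
            raise KeyError(f"planted fold change on unknown gene {gene!r}")
    genes = [g for g in model.genes if g not in set(config.omitted_genes)]
    rng = np.random.default_rng(config.seed)
    baseline = np.exp(
        rng.normal(config.baseline_log_mean, config.gene_log_sd, size=len(genes))
    )
    columns: dict[str, np.ndarray] = {}
    phase_of: dict[str, str] = {}
    for label, n_samples in config.phases:
        fc = np.array(
            [config.planted_fold_changes.get((g, label), 1.0) for g in genes]
        )
        for r in range(n_samples):
            noise = np.exp(rng.normal(0.0, config.noise_sd, size=len(genes))) \
                if config.noise_sd > 0 else 1.0
            sample = f"{label}_r{r + 1}"
            columns[sample] = baseline * fc * noise
            phase_of[sample] = label
    values = pd.DataFrame(columns, index=pd.Index(genes, name="gene"))
    return ExpressionTable(values=values, phase_of=phase_of)
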