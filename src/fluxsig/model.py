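"""Core data model for stoichiometric metabolic networks.

A :class:`MetabolicModel` is a plain in-memory representation of a
constraint-based model: metabolites, reactions with flux bounds
(mmol/gDW/h), boolean gene-protein-reaction (GPR) rules, and optional
subsystem/compartment metadata.  It is the polytope definition consumed by
the sampler: the feasible set is ``{v : S v = 0, lb <= v <= ub}`` where
``S`` is the stoichiometric matrix.

The module also builds the recombinant-product translation pseudo-reaction
from antibody heavy/light-chain peptide sequences and converts bioprocess
rates (pg/cell/h) to model flux units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "GPR",
    "GPRSyntaxError",
    "MetabolicModel",
    "BioprocessRate",
    "TranslationCostScheme",
    "ValidationReport",
    "AMINO_ACID_METABOLITES",
    "build_product_translation_reaction",
    "convert_rate_units",
    "validate_model",
]

# One-letter code -> BIGG-style base metabolite id (compartment suffix added
# separately, e.g. "ala__L" -> "ala__L_c").
AMINO_ACID_METABOLITES: dict[str, str] = {
    "A": "ala__L",
    "R": "arg__L",
    "N": "asn__L",
    "D": "asp__L",
    "C": "cys__L",
    "Q": "gln__L",
    "E": "glu__L",
    "G": "gly",
    "H": "his__L",
    "I": "ile__L",
    "L": "leu__L",
    "K": "lys__L",
    "M": "met__L",
    "F": "phe__L",
    "P": "pro__L",
    "S": "ser__L",
    "T": "thr__L",
    "W": "trp__L",
    "Y": "tyr__L",
    "V": "val__L",
}


class GPRSyntaxError(ValueError):
    """Malformed GPR expression string; carries the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")


def _tokenize_gpr(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise GPRSyntaxError(f"unexpected character {stripped[0]!r}", pos)
        tok = m.group(1)
        tokens.append((tok, m.start(1)))
        pos = m.end()
    return tokens


class GPR:
    """Boolean gene-protein-reaction rule over gene identifiers.

    The expression tree is stored as nested tuples: ``("gene", id)``,
    ``("and", children)`` or ``("or", children)``; ``root is None`` means no
    gene association.  Serializes to a parenthesized infix string and
    round-trips through :meth:`parse`.
    """

    __slots__ = ("root",)

    def __init__(self, root=None):
        self.root = root

    # -- parsing ---------------------------------------------------------
    @classmethod
    def parse(cls, text: str) -> "GPR":
        if text is None or not text.strip():
            return cls(None)
        tokens = _tokenize_gpr(text)
        idx = 0

        def peek():
            return tokens[idx][0] if idx < len(tokens) else None

        def expect_pos():
            return tokens[idx][1] if idx < len(tokens) else len(text)

        def parse_or():
            nonlocal idx
            children = [parse_and()]
            while peek() is not None and peek().lower() == "or":
                idx += 1
                children.append(parse_and())
            return children[0] if len(children) == 1 else ("or", tuple(children))

        def parse_and():
            nonlocal idx
            children = [parse_atom()]
            while peek() is not None and peek().lower() == "and":
                idx += 1
                children.append(parse_atom())
            return children[0] if len(children) == 1 else ("and", tuple(children))

        def parse_atom():
            nonlocal idx
            tok = peek()
            if tok is None:
                raise GPRSyntaxError("unexpected end of expression", len(text))
            if tok == "(":
                idx += 1
                node = parse_or()
                if peek() != ")":
                    raise GPRSyntaxError("expected ')'", expect_pos())
                idx += 1
                return node
            if tok == ")" or tok.lower() in ("and", "or"):
                raise GPRSyntaxError(f"unexpected token {tok!r}", expect_pos())
            idx += 1
            return ("gene", tok)

        root = parse_or()
        if idx != len(tokens):
            raise GPRSyntaxError(f"trailing token {tokens[idx][0]!r}", tokens[idx][1])
        return cls(root)

    # -- serialization ---------------------------------------------------
    def to_string(self) -> str:
        if self.root is None:
            return ""

        def render(node, parent: str | None) -> str:
            kind = node[0]
            if kind == "gene":
                return node[1]
            sep = f" {kind} "
            body = sep.join(render(c, kind) for c in node[1])
            # 'or' under 'and' needs parentheses; parenthesize composite
            # children of a different operator for readability.
            if parent is not None and parent != kind:
                return f"({body})"
            return body

        return render(self.root, None)

    # -- queries ---------------------------------------------------------
    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()

        def walk(node):
            if node is None:
                return
            if node[0] == "gene":
                out.add(node[1])
            else:
                for c in node[1]:
                    walk(c)

        walk(self.root)
        return frozenset(out)

    def evaluate(
        self,
        gene_values: Mapping[str, float],
        or_mode: str = "max",
    ) -> float | None:
        """Map gene expression values onto the rule.

        AND nodes take the minimum of their children (an enzyme complex is
        limited by its scarcest subunit); OR nodes take the maximum
        (isozymes are redundant) or, with ``or_mode="sum"``, the sum.  A
        gene absent from ``gene_values`` evaluates to missing (``None``);
        missing propagates through AND and is ignored by OR unless every
        branch is missing.  An empty rule is missing.
        """
        if or_mode not in ("max", "sum"):
            raise ValueError(f"or_mode must be 'max' or 'sum', got {or_mode!r}")

        def walk(node) -> float | None:
            kind = node[0]
            if kind == "gene":
                return gene_values.get(node[1])
            vals = [walk(c) for c in node[1]]
            if kind == "and":
                if any(v is None for v in vals):
                    return None
                return min(vals)
            present = [v for v in vals if v is not None]
            if not present:
                return None
            return max(present) if or_mode == "max" else sum(present)

        if self.root is None:
            return None
        return walk(self.root)

    def __bool__(self) -> bool:
        return self.root is not None

    def __eq__(self, other) -> bool:
        return isinstance(other, GPR) and self.root == other.root

    def __hash__(self):
        return hash(self.root)

    def __repr__(self):
        return f"GPR({self.to_string()!r})"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None

    def __post_init__(self):
        if not self.compartment:
            raise ValueError(f"metabolite {self.id!r}: compartment must be non-empty")


@dataclass
class Reaction:
    """A (pseudo-)reaction: stoichiometry, flux bounds and metadata.

    Stoichiometric coefficients are negative for consumed metabolites and
    positive for produced ones.  Bounds are in mmol/gDW/h.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -1000.0
    upper_bound: float = 1000.0
    gpr: GPR = field(default_factory=GPR)
    subsystem: str | None = None
    name: str = ""

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_boundary(self) -> bool:
        """Exchange/demand/sink pseudo-reaction (single metabolite)."""
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return replace(self, stoichiometry=dict(self.stoichiometry))


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    product_reaction_id: str | None = None
    biomass_reaction_id: str | None = None
    id: str = "model"

    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def get_reaction(self, reaction_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == reaction_id:
                return r
        raise KeyError(f"reaction {reaction_id!r} not in model {self.id!r}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S of shape (n_metabolites, n_reactions)."""
        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coef in rxn.stoichiometry.items():
                S[met_index[met_id], j] = coef
        return S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=[replace(m) for m in self.metabolites],
            reactions=[r.copy() for r in self.reactions],
            genes=list(self.genes),
            product_reaction_id=self.product_reaction_id,
            biomass_reaction_id=self.biomass_reaction_id,
            id=self.id,
        )


@dataclass
class BioprocessRate:
    """A bioreactor rate measurement with the factors needed for unit
    conversion to model flux units.

    alpha: process rate in pg/cell/h (positive = production, negative =
    consumption); beta: dry cell weight in g/cell; gamma: molecular weight
    of the metabolite in g/mol.
    """

    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"dry cell weight beta must be > 0, got {self.beta}")
        if self.gamma <= 0:
            raise ValueError(f"molecular weight gamma must be > 0, got {self.gamma}")


def convert_rate_units(rate: BioprocessRate) -> float:
    """Convert a bioprocess rate (pg/cell/h) to model flux (mmol/gDW/h).

    Computes ``(alpha * 1e-12 / beta) * (1000 / gamma)``: pg -> g, per cell
    -> per g dry weight, g of metabolite -> mmol.  The sign is preserved, so
    negative input rates (consumption) convert to negative fluxes.
    """
    return (rate.alpha * 1e-12 / rate.beta) * (1000.0 / rate.gamma)


@dataclass(frozen=True)
class TranslationCostScheme:
    """Per-residue NTP hydrolysis counts charged to protein synthesis.

    Defaults: one ATP -> AMP + PPi per residue (aminoacyl-tRNA charging)
    and two GTP -> GDP + Pi (ribosomal delivery and translocation).  Each
    hydrolysis event consumes one water and releases one proton.  The
    counts are configurable so alternative energetic bookkeeping (e.g. an
    ATP -> ADP maintenance component) can be expressed with the same
    builder.
    """

    atp_to_amp: float = 1.0
    atp_to_adp: float = 0.0
    gtp_to_gdp: float = 2.0

    @property
    def events_per_residue(self) -> float:
        return self.atp_to_amp + self.atp_to_adp + self.gtp_to_gdp


def _residue_counts(seq: str, label: str) -> dict[str, int]:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    counts: dict[str, int] = {}
    for i, ch in enumerate(seq, start=1):
        if ch not in AMINO_ACID_METABOLITES:
            raise ValueError(
                f"invalid residue {ch!r} at position {i} of {label} sequence"
            )
        counts[ch] = counts.get(ch, 0) + 1
    return counts


def build_product_translation_reaction(
    heavy_seq: str,
    light_seq: str,
    heavy_copies: int = 2,
    light_copies: int = 2,
    cost_scheme: TranslationCostScheme | None = None,
    reaction_id: str = "product_translation",
    product_metabolite_id: str = "product_c",
    compartment_suffix: str = "_c",
) -> Reaction:
    """Assemble the product translation pseudo-reaction from chain sequences.

    The reaction consumes each amino acid with a coefficient equal to its
    total residue count over ``heavy_copies`` heavy chains plus
    ``light_copies`` light chains (an IgG is 2 heavy + 2 light), consumes
    ATP, GTP and water according to ``cost_scheme``, releases the
    corresponding NDP/NMP, phosphate and protons, and produces one unit of
    the product pseudo-metabolite.  Irreversible (lb = 0).
    """
    if heavy_copies < 1 or light_copies < 1:
        raise ValueError("chain copy numbers must be >= 1")
    scheme = cost_scheme or TranslationCostScheme()

    counts: dict[str, int] = {}
    for seq, copies, label in (
        (heavy_seq, heavy_copies, "heavy-chain"),
        (light_seq, light_copies, "light-chain"),
    ):
        for aa, c in _residue_counts(seq, label).items():
            counts[aa] = counts.get(aa, 0) + copies * c

    n = heavy_copies * len(heavy_seq) + light_copies * len(light_seq)
    stoich: dict[str, float] = {}
    for aa, c in sorted(counts.items()):
        stoich[AMINO_ACID_METABOLITES[aa] + compartment_suffix] = -float(c)

    sfx = compartment_suffix
    atp = (scheme.atp_to_amp + scheme.atp_to_adp) * n
    gtp = scheme.gtp_to_gdp * n
    events = scheme.events_per_residue * n
    if atp:
        stoich["atp" + sfx] = -atp
    if gtp:
        stoich["gtp" + sfx] = -gtp
    if events:
        stoich["h2o" + sfx] = -events
        stoich["h" + sfx] = events
    if scheme.atp_to_amp:
        stoich["amp" + sfx] = scheme.atp_to_amp * n
        stoich["ppi" + sfx] = scheme.atp_to_amp * n
    if scheme.atp_to_adp:
        stoich["adp" + sfx] = scheme.atp_to_adp * n
    if scheme.gtp_to_gdp:
        stoich["gdp" + sfx] = scheme.gtp_to_gdp * n
    pi = (scheme.atp_to_adp + scheme.gtp_to_gdp) * n
    if pi:
        stoich["pi" + sfx] = pi
    stoich[product_metabolite_id] = 1.0

    return Reaction(
        id=reaction_id,
        stoichiometry=stoich,
        lower_bound=0.0,
        upper_bound=1000.0,
        name="product translation",
    )


@dataclass
class ValidationReport:
    """Structural consistency findings for a model; empty report = valid."""

    bound_violations: list[str] = field(default_factory=list)
    orphan_metabolites: list[str] = field(default_factory=list)
    unknown_genes: list[tuple[str, str]] = field(default_factory=list)
    duplicate_ids: list[str] = field(default_factory=list)
    missing_metabolites: list[tuple[str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not (
            self.bound_violations
            or self.orphan_metabolites
            or self.unknown_genes
            or self.duplicate_ids
            or self.missing_metabolites
        )

    def summary(self) -> str:
        lines = []
        for label, entries in (
            ("bound violations (lb > ub)", self.bound_violations),
            ("orphan metabolites", self.orphan_metabolites),
            ("GPR genes absent from gene list", self.unknown_genes),
            ("duplicate ids", self.duplicate_ids),
            ("unknown metabolites in stoichiometry", self.missing_metabolites),
        ):
            if entries:
                lines.append(f"{label}: {entries}")
        return "\n".join(lines) if lines else "model is valid"


def validate_model(model: MetabolicModel) -> ValidationReport:
    """Check structural invariants: bounds, orphans, GPR genes, duplicates."""
    report = ValidationReport()

    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    seen: set[str] = set()
    for mid in met_ids + rxn_ids:
        if mid in seen:
            report.duplicate_ids.append(mid)
        seen.add(mid)

    known_mets = set(met_ids)
    used_mets: set[str] = set()
    gene_set = set(model.genes)
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            report.bound_violations.append(rxn.id)
        for mid in rxn.stoichiometry:
            used_mets.add(mid)
            if mid not in known_mets:
                report.missing_metabolites.append((rxn.id, mid))
        for g in sorted(rxn.gpr.genes):
            if g not in gene_set:
                report.unknown_genes.append((rxn.id, g))

    report.orphan_metabolites = sorted(known_mets - used_mets)
    return report
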