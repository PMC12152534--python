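"""SBML Level 3 (+ fbc, + groups) reading and writing.

Flux bounds travel through the fbc package (bound parameters), gene
associations through fbc gene-product associations, and subsystem labels
through the groups package (one group per subsystem, members by idRef).
Models lacking fbc bound information fall back to the de-facto
genome-scale-model convention of (-1000, 1000) for reversible and
(0, 1000) for irreversible reactions, with a logged warning.
"""

from __future__ import annotations

import logging
import re

import libsbml

from .model import GPR, MetabolicModel, Metabolite, Reaction, validate_model

__all__ = ["read_sbml", "write_sbml", "SBMLParseError", "SBMLValidationError"]

logger = logging.getLogger(__name__)

DEFAULT_BOUND = 1000.0

_PRODUCT_RE = re.compile(r'<fluxsig:roles[^>]*?\bproduct="([^"]+)"')
_BIOMASS_RE = re.compile(r'<fluxsig:roles[^>]*?\bbiomass="([^"]+)"')


class SBMLParseError(ValueError):
    """The file is not well-formed / valid SBML."""


class SBMLValidationError(ValueError):
    """The file parsed but violates model invariants (e.g. lb > ub)."""


def _sanitize_sid(raw: str, taken: set[str]) -> str:
    sid = re.sub(r"[^A-Za-z0-9_]", "_", raw)
    if not sid or not (sid[0].isalpha() or sid[0] == "_"):
        sid = "x_" + sid
    base = sid
    k = 1
    while sid in taken:
        k += 1
        sid = f"{base}_{k}"
    taken.add(sid)
    return sid


# ---------------------------------------------------------------------------
# reading


def _assoc_to_tree(assoc, gp_names):
    if assoc is None:
        return None
    if assoc.isGeneProductRef():
        ref = assoc.getGeneProduct()
        return ("gene", gp_names.get(ref, ref))
    kind = "and" if assoc.isFbcAnd() else "or"
    children = tuple(
        _assoc_to_tree(assoc.getAssociation(i), gp_names)
        for i in range(assoc.getNumAssociations())
    )
    return (kind, children)


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML file into a :class:`MetabolicModel`.

    Raises :class:`SBMLParseError` for malformed XML/SBML (the message
    names the offending element) and :class:`SBMLValidationError` when a
    reaction's lower bound exceeds its upper bound.
    """
    doc = libsbml.readSBMLFromFile(str(path))
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            raise SBMLParseError(
                f"SBML parse error in {path}: {err.getMessage().strip()}"
            )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise SBMLParseError(f"no <model> element found in {path}")

    mplug = sbml_model.getPlugin("fbc")

    metabolites = []
    for sp in sbml_model.getListOfSpecies():
        formula = None
        splug = sp.getPlugin("fbc")
        if splug is not None and splug.isSetChemicalFormula():
            formula = splug.getChemicalFormula()
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=sp.getCompartment() or "c",
                formula=formula,
            )
        )

    # gene product SId -> preferred (label) name
    gp_names: dict[str, str] = {}
    genes: list[str] = []
    if mplug is not None:
        for gp in mplug.getListOfGeneProducts():
            name = gp.getLabel() if gp.isSetLabel() and gp.getLabel() else gp.getId()
            gp_names[gp.getId()] = name
            genes.append(name)

    def bound_value(param_id):
        if not param_id:
            return None
        p = sbml_model.getParameter(param_id)
        return p.getValue() if p is not None else None

    reactions = []
    warned_default = False
    for rxn in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for i in range(rxn.getNumReactants()):
            sr = rxn.getReactant(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for i in range(rxn.getNumProducts()):
            sr = rxn.getProduct(i)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        stoich = {k: v for k, v in stoich.items() if v != 0.0}

        rplug = rxn.getPlugin("fbc")
        lb = ub = None
        gpr = GPR()
        if rplug is not None:
            lb = bound_value(rplug.getLowerFluxBound())
            ub = bound_value(rplug.getUpperFluxBound())
            gpa = rplug.getGeneProductAssociation()
            if gpa is not None:
                gpr = GPR(_assoc_to_tree(gpa.getAssociation(), gp_names))
        if lb is None or ub is None:
            if not warned_default:
                logger.warning(
                    "%s: fbc flux bounds missing; applying default bounds "
                    "(-%g, %g) for reversible / (0, %g) for irreversible reactions",
                    path, DEFAULT_BOUND, DEFAULT_BOUND, DEFAULT_BOUND,
                )
                warned_default = True
            if rxn.getReversible():
                lb = -DEFAULT_BOUND if lb is None else lb
            else:
                lb = 0.0 if lb is None else lb
            ub = DEFAULT_BOUND if ub is None else ub

        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
            )
        )

    # subsystems from the groups package
    gplug = sbml_model.getPlugin("groups")
    if gplug is not None:
        by_id = {r.id: r for r in reactions}
        for i in range(gplug.getNumGroups()):
            group = gplug.getGroup(i)
            label = group.getName() or group.getId()
            for j in range(group.getNumMembers()):
                member = group.getMember(j)
                rid = member.getIdRef()
                if rid in by_id:
                    by_id[rid].subsystem = label

    for g in sorted({g for r in reactions for g in r.gpr.genes} - set(genes)):
        genes.append(g)

    model = MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        genes=genes,
        id=sbml_model.getId() or "model",
    )

    annot = sbml_model.getAnnotationString() or ""
    m = _PRODUCT_RE.search(annot)
    if m:
        model.product_reaction_id = m.group(1)
    m = _BIOMASS_RE.search(annot)
    if m:
        model.biomass_reaction_id = m.group(1)

    report = validate_model(model)
    if report.bound_violations:
        raise SBMLValidationError(
            "reactions with lower bound > upper bound: "
            + ", ".join(report.bound_violations)
        )
    return model


# ---------------------------------------------------------------------------
# writing


def _build_association(parent, node, gene_sids):
    if node[0] == "gene":
        ref = parent.createGeneProductRef()
        ref.setGeneProduct(gene_sids[node[1]])
        return
    container = parent.createAnd() if node[0] == "and" else parent.createOr()
    for child in node[1]:
        _build_association(container, child, gene_sids)


def write_sbml(model: MetabolicModel, path: str) -> None:
    """Write ``model`` as SBML L3V1 with fbc v2 bounds/GPRs and groups
    subsystems; the emitted file re-reads to a structurally equal model."""
    ns = libsbml.SBMLNamespaces(3, 1)
    ns.addPackageNamespace("fbc", 2)
    ns.addPackageNamespace("groups", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    doc.setPackageRequired("groups", False)

    sbml_model = doc.createModel()
    sbml_model.setId(model.id)
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(True)

    if model.product_reaction_id or model.biomass_reaction_id:
        sbml_model.appendAnnotation(
            '<fluxsig:roles xmlns:fluxsig="https://example.org/fluxsig" '
            f'product="{model.product_reaction_id or ""}" '
            f'biomass="{model.biomass_reaction_id or ""}"/>'
        )

    for comp_id in sorted({m.compartment for m in model.metabolites} or {"c"}):
        comp = sbml_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)
        comp.setSize(1.0)

    for met in model.metabolites:
        sp = sbml_model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name)
        sp.setCompartment(met.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)
        sp.setInitialConcentration(0.0)
        if met.formula:
            sp.getPlugin("fbc").setChemicalFormula(met.formula)

    taken: set[str] = set()
    gene_sids: dict[str, str] = {}
    for gene in model.genes:
        sid = _sanitize_sid("G_" + gene, taken)
        gene_sids[gene] = sid
        gp = mplug.createGeneProduct()
        gp.setId(sid)
        gp.setLabel(gene)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            p = sbml_model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    subsystems: dict[str, list[str]] = {}
    for rxn in model.reactions:
        r = sbml_model.createReaction()
        r.setId(rxn.id)
        r.setName(rxn.name)
        r.setFast(False)
        r.setReversible(rxn.lower_bound < 0)
        for met_id, coef in rxn.stoichiometry.items():
            sr = r.createReactant() if coef < 0 else r.createProduct()
            sr.setSpecies(met_id)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        rplug = r.getPlugin("fbc")
        rplug.setLowerFluxBound(bound_param(rxn.lower_bound))
        rplug.setUpperFluxBound(bound_param(rxn.upper_bound))
        if rxn.gpr:
            gpa = rplug.createGeneProductAssociation()
            _build_association(gpa, rxn.gpr.root, gene_sids)
        if rxn.subsystem:
            subsystems.setdefault(rxn.subsystem, []).append(rxn.id)

    if subsystems:
        gplug = sbml_model.getPlugin("groups")
        group_taken: set[str] = set()
        for name in sorted(subsystems):
            group = gplug.createGroup()
            group.setId(_sanitize_sid("subsystem_" + name, group_taken))
            group.setName(name)
            group.setKind("partonomy")
            for rid in subsystems[name]:
                member = group.createMember()
                member.setIdRef(rid)

    ok = libsbml.writeSBMLToFile(doc, str(path))
    if ok != 1:
        raise OSError(f"could not write SBML to {path}")
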