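import numpy as np
import pandas as pd
import pytest

from fluxsig.model import GPR, MetabolicModel, Metabolite, Reaction
from fluxsig.omics import (
    ExpressionTable,
    average_phase_expression,
    build_phase_model,
    constrain_bounds,
    evaluate_gpr,
    map_gene_ids,
    reaction_expression,
)
from fluxsig.sampler import InfeasiblePolytopeError


def make_table(values: dict, phase_of: dict) -> ExpressionTable:
    return ExpressionTable(values=pd.DataFrame(values), phase_of=phase_of)


@pytest.fixture
def table():
    frame = pd.DataFrame(
        {
            "s1": [2.0, 10.0, 0.0],
            "s2": [4.0, 20.0, 1.0],
            "s3": [6.0, 30.0, 2.0],
            "s4": [8.0, 40.0, 3.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )
    phases = {"s1": "early", "s2": "early", "s3": "early", "s4": "late"}
    return ExpressionTable(values=frame, phase_of=phases)


class TestExpressionTable:
    def test_invariants_enforced(self, table):
        with pytest.raises(ValueError, match="non-negative"):
            ExpressionTable(values=table.values - 5.0, phase_of=table.phase_of)
        with pytest.raises(ValueError, match="phase"):
            ExpressionTable(values=table.values, phase_of={"s1": "early"})

    def test_csv_roundtrip(self, table, tmp_path):
        table.to_csv(tmp_path / "e.tsv", tmp_path / "p.csv")
        back = ExpressionTable.from_csv(tmp_path / "e.tsv", tmp_path / "p.csv")
        pd.testing.assert_frame_equal(back.values, table.values)
        assert back.phase_of == table.phase_of


class TestMapGeneIds:
    def test_identity_mapping(self, table):
        mapping = pd.DataFrame({"src": ["g1", "g2", "g3"], "dst": ["g1", "g2", "g3"]})
        out = map_gene_ids(table, mapping)
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_collision_aggregated_by_sum(self, table):
        mapping = pd.DataFrame({"src": ["g1", "g2", "g3"], "dst": ["G", "G", "h3"]})
        out = map_gene_ids(table, mapping)
        assert list(out.genes) == ["G", "h3"]
        assert out.values.loc["G", "s1"] == 12.0  # 2 + 10

    def test_unmapped_gene_dropped(self, table):
        mapping = pd.DataFrame({"src": ["g1"], "dst": ["G1"]})
        out = map_gene_ids(table, mapping)
        assert out.genes == ["G1"]

    def test_empty_mapping_rejected(self, table):
        with pytest.raises(ValueError, match="empty"):
            map_gene_ids(table, pd.DataFrame(columns=["a", "b"]))


class TestPhaseAverage:
    def test_three_sample_mean(self, table):
        means = average_phase_expression(table, "early")
        assert means["g1"] == 4.0  # (2+4+6)/3

    def test_single_sample_phase(self, table):
        means = average_phase_expression(table, "late")
        assert means.equals(table.values["s4"])

    def test_matches_bruteforce_on_random_table(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.random((20, 6)) * 100,
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{j}" for j in range(6)],
        )
        phase_of = {f"s{j}": ("p0" if j < 4 else "p1") for j in range(6)}
        table = ExpressionTable(values=values, phase_of=phase_of)
        means = average_phase_expression(table, "p0")
        for g in table.genes:
            expected = sum(values.loc[g, f"s{j}"] for j in range(4)) / 4
            assert means[g] == pytest.approx(expected)

    def test_empty_phase_rejected(self, table):
        with pytest.raises(ValueError, match="no samples"):
            average_phase_expression(table, "nonexistent")


def _oracle_eval(node, values):
    """Independent recursive evaluator: AND=min, OR=max, missing=None."""
    if node is None:
        return None
    kind = node[0]
    if kind == "gene":
        return values.get(node[1])
    child = [_oracle_eval(c, values) for c in node[1]]
    if kind == "and":
        return None if any(v is None for v in child) else min(child)
    present = [v for v in child if v is not None]
    return max(present) if present else None


def _random_tree(rng, genes, depth):
    if depth == 0 or rng.random() < 0.3:
        return ("gene", str(rng.choice(genes)))
    kind = "and" if rng.random() < 0.5 else "or"
    n = int(rng.integers(2, 4))
    return (kind, tuple(_random_tree(rng, genes, depth - 1) for _ in range(n)))


class TestEvaluateGpr:
    def test_random_trees_match_recursive_oracle(self):
        rng = np.random.default_rng(42)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(200):
            tree = _random_tree(rng, genes, depth=4)
            # half the genes carry values, the rest are missing
            values = {g: float(rng.integers(0, 100)) for g in genes if rng.random() < 0.6}
            gpr = GPR(tree)
            assert evaluate_gpr(gpr, values) == _oracle_eval(tree, values)

    def test_reaction_expression_reasons(self):
        model = MetabolicModel(
            metabolites=[Metabolite("a_c")],
            reactions=[
                Reaction("R_nogpr", {"a_c": -1.0}, 0, 10),
                Reaction("R_missing", {"a_c": 1.0}, 0, 10, gpr=GPR.parse("gX")),
                Reaction("R_ok", {"a_c": 1.0}, 0, 10, gpr=GPR.parse("g1")),
            ],
            genes=["g1", "gX"],
        )
        values, reasons = reaction_expression(model, {"g1": 7.0})
        assert values == {"R_ok": 7.0}
        assert reasons == {"R_nogpr": "no_gpr", "R_missing": "gene_missing"}


def _constraint_model():
    mets = [Metabolite("m_c")]
    rxns = [
        Reaction("REV", {"m_c": 1.0}, -1000, 1000, gpr=GPR.parse("g1")),
        Reaction("IRR", {"m_c": -1.0}, 0, 1000, gpr=GPR.parse("g2")),
        Reaction("FREE", {"m_c": -1.0}, -1000, 1000),
    ]
    return MetabolicModel(metabolites=mets, reactions=rxns, genes=["g1", "g2"])


class TestConstrainBounds:
    def test_reversible_and_irreversible_rules(self):
        pm = constrain_bounds(
            _constraint_model(), {"REV": 2.0, "IRR": 2.0}, scaling=1.0
        )
        rev = pm.model.get_reaction("REV")
        irr = pm.model.get_reaction("IRR")
        assert (rev.lower_bound, rev.upper_bound) == (-2.0, 2.0)
        assert (irr.lower_bound, irr.upper_bound) == (0.0, 2.0)

    def test_missing_left_unconstrained_with_reason(self):
        pm = constrain_bounds(_constraint_model(), {"REV": 2.0, "IRR": None}, scaling=1.0)
        irr = pm.model.get_reaction("IRR")
        assert (irr.lower_bound, irr.upper_bound) == (0.0, 1000.0)
        assert pm.unconstrained_reason["IRR"] == "gene_missing"
        free = pm.model.get_reaction("FREE")
        assert (free.lower_bound, free.upper_bound) == (-1000.0, 1000.0)

    def test_never_widens(self):
        model = _constraint_model()
        model.get_reaction("REV").lower_bound = -1.0
        pm = constrain_bounds(model, {"REV": 50.0}, scaling=1.0)
        rev = pm.model.get_reaction("REV")
        assert rev.lower_bound == -1.0 and rev.upper_bound == 50.0

    def test_default_scaling_normalizes_to_bound_magnitude(self):
        pm = constrain_bounds(_constraint_model(), {"REV": 5.0, "IRR": 10.0})
        assert pm.model.get_reaction("IRR").upper_bound == pytest.approx(1000.0)
        assert pm.model.get_reaction("REV").upper_bound == pytest.approx(500.0)

    def test_monotone_in_expression(self):
        lo = constrain_bounds(_constraint_model(), {"REV": 2.0}, scaling=1.0)
        hi = constrain_bounds(_constraint_model(), {"REV": 3.0}, scaling=1.0)
        r_lo = lo.model.get_reaction("REV")
        r_hi = hi.model.get_reaction("REV")
        assert r_hi.lower_bound <= r_lo.lower_bound
        assert r_hi.upper_bound >= r_lo.upper_bound

    def test_idempotent(self):
        values = {"REV": 2.0, "IRR": 4.0}
        once = constrain_bounds(_constraint_model(), values, scaling=1.0)
        twice = constrain_bounds(once.model, values, scaling=1.0)
        for rid in ("REV", "IRR"):
            a = once.model.get_reaction(rid)
            b = twice.model.get_reaction(rid)
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)

    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            constrain_bounds(_constraint_model(), {"REV": -1.0}, scaling=1.0)

    def test_infeasible_constraint_reported(self):
        # the sink must carry at least 2 units, so choking the supply to
        # 0.5 empties the polytope
        mets = [Metabolite("m_c")]
        rxns = [
            Reaction("SRC", {"m_c": 1.0}, 0, 10, gpr=GPR.parse("g1")),
            Reaction("SNK", {"m_c": -1.0}, 2, 10),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns, genes=["g1"])
        with pytest.raises(InfeasiblePolytopeError):
            constrain_bounds(model, {"SRC": 0.5}, scaling=1.0, phase="p")


class TestBuildPhaseModel:
    def test_planted_upregulation_widens_importer_bound(self, toy_model):
        from fluxsig.synthetic import SyntheticExpressionConfig, generate_synthetic_expression

        importer = next(r.id for r in toy_model.reactions if r.id.startswith("T_"))
        gene = f"g_{importer}"
        cfg = SyntheticExpressionConfig(
            seed=3,
            noise_sd=0.0,
            planted_fold_changes={(gene, "late_exponential"): 4.0},
        )
        table = generate_synthetic_expression(toy_model, cfg)
        early = build_phase_model(toy_model, table, "early_exponential")
        late = build_phase_model(toy_model, table, "late_exponential")
        assert (
            late.model.get_reaction(importer).upper_bound
            > early.model.get_reaction(importer).upper_bound
        )
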