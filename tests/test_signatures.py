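from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from fluxsig.model import MetabolicModel, Metabolite, Reaction
from fluxsig.sampler import FluxSampleSet
from fluxsig.signatures import (
    bh_adjust,
    extract_transport_signature,
    infer_transport_annotation,
    mann_whitney_u,
    overlap_counts,
    pca_solutions,
    select_high_producers,
    significant_reactions,
    skew_results_frame,
    subsystem_enrichment,
    test_flux_skew as flux_skew_test,
)


def make_samples(matrix, reaction_ids):
    return FluxSampleSet(
        samples=np.asarray(matrix, dtype=float),
        reaction_ids=list(reaction_ids),
        seed=0, total_iterations=len(matrix), thinning=1,
    )


class TestSelection:
    def test_5000_solutions_give_250(self):
        rng = np.random.default_rng(0)
        samples = make_samples(rng.random((5000, 2)), ["prod", "other"])
        sel = select_high_producers(samples, "prod", 95.0)
        assert sel.n_selected == 250

    def test_100_solutions_give_5(self):
        samples = make_samples(np.arange(200).reshape(100, 2), ["prod", "other"])
        sel = select_high_producers(samples, "prod", 95.0)
        assert sel.n_selected == 5

    def test_selected_dominate_unselected(self):
        rng = np.random.default_rng(1)
        samples = make_samples(rng.random((400, 1)), ["prod"])
        sel = select_high_producers(samples, "prod", 95.0)
        flux = samples.flux("prod")
        unselected = np.setdiff1d(np.arange(400), sel.indices)
        assert flux[sel.indices].min() >= flux[unselected].max()

    def test_ties_resolved_by_stable_index_order(self):
        samples = make_samples(np.ones((100, 1)), ["prod"])
        sel = select_high_producers(samples, "prod", 95.0)
        assert list(sel.indices) == [0, 1, 2, 3, 4]

    def test_shuffle_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(2)
        values = rng.random((200, 1))
        perm = rng.permutation(200)
        a = select_high_producers(make_samples(values, ["prod"]), "prod", 95.0)
        b = select_high_producers(make_samples(values[perm], ["prod"]), "prod", 95.0)
        assert sorted(perm[b.indices]) == sorted(a.indices)

    def test_missing_product_reaction(self):
        samples = make_samples(np.zeros((10, 1)), ["r1"])
        with pytest.raises(KeyError, match="prod"):
            select_high_producers(samples, "prod", 95.0)

    def test_percentile_range_enforced(self):
        samples = make_samples(np.zeros((10, 1)), ["r1"])
        with pytest.raises(ValueError):
            select_high_producers(samples, "r1", 100.0)


def _bruteforce_u(x, y):
    """U of x against y by direct pair counting (ties count half)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_statistic_matches_exhaustive_pair_counting(self):
        """U agrees with the rank-enumeration definition for all small
        group sizes, with and without ties."""
        rng = np.random.default_rng(3)
        for _ in range(300):
            m = int(rng.integers(1, 9))
            n = int(rng.integers(1, 9))
            # draw from a small integer support to force ties often
            x = rng.integers(0, 6, size=m).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.ptp(np.concatenate([x, y])) == 0:
                continue
            u, p = mann_whitney_u(x, y)
            assert u == _bruteforce_u(x, y)
            assert 0 <= p <= 1

    def test_constant_input_gives_p_one(self):
        u, p = mann_whitney_u(np.ones(5), np.ones(8))
        assert p == 1.0
        assert u == 5 * 8 / 2


def _bruteforce_bh(pvals):
    """Step-up definition: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, m * pvals[idx] / rank)
        q[idx] = min(running, 1.0)
    return q


class TestBHAdjustment:
    def test_matches_bruteforce_stepup(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = int(rng.integers(1, 101))
            pvals = rng.random(m)
            np.testing.assert_allclose(bh_adjust(pvals), _bruteforce_bh(pvals), rtol=1e-12)

    def test_with_duplicated_pvalues(self):
        pvals = np.array([0.01, 0.01, 0.5, 0.5, 0.9])
        np.testing.assert_allclose(bh_adjust(pvals), _bruteforce_bh(pvals), rtol=1e-12)


class TestFluxSkew:
    def test_perfectly_coupled_reaction_flagged_increased(self):
        rng = np.random.default_rng(5)
        prod = rng.random(2000)
        other = rng.random(2000)
        samples = make_samples(np.column_stack([prod, prod * 3.0, other]),
                               ["prod", "coupled", "independent"])
        sel = select_high_producers(samples, "prod", 95.0)
        results = {r.reaction_id: r for r in flux_skew_test(samples, sel)}
        assert results["coupled"].q < 0.05
        assert results["coupled"].direction == "increased"

    def test_constant_reaction_direction_none(self):
        rng = np.random.default_rng(6)
        prod = rng.random(1000)
        samples = make_samples(np.column_stack([prod, np.full(1000, 2.0)]),
                               ["prod", "const"])
        sel = select_high_producers(samples, "prod", 95.0)
        results = {r.reaction_id: r for r in flux_skew_test(samples, sel)}
        assert results["const"].direction == "none"
        assert results["const"].p == 1.0

    def test_null_false_positive_rate(self):
        """Independent fluxes: across 20 seeded replicates the median
        flagged fraction stays at or below the FDR level."""
        fractions = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            matrix = rng.normal(size=(2000, 40))
            ids = ["prod"] + [f"r{i}" for i in range(39)]
            samples = make_samples(matrix, ids)
            sel = select_high_producers(samples, "prod", 95.0)
            results = flux_skew_test(samples, sel)
            flagged = significant_reactions(results) - {"prod"}
            fractions.append(len(flagged) / 39)
        assert np.median(fractions) <= 0.05

    def test_disjoint_pool_variant(self):
        rng = np.random.default_rng(7)
        prod = rng.random(1000)
        samples = make_samples(np.column_stack([prod, prod]), ["prod", "copy"])
        sel = select_high_producers(samples, "prod", 95.0)
        results = {r.reaction_id: r
                   for r in flux_skew_test(samples, sel, pool="rest")}
        assert results["copy"].direction == "increased"

    def test_results_frame_schema(self):
        samples = make_samples(np.random.default_rng(8).random((100, 2)), ["prod", "a"])
        sel = select_high_producers(samples, "prod", 95.0)
        frame = skew_results_frame(flux_skew_test(samples, sel))
        assert list(frame.columns) == [
            "reaction", "U", "p", "q", "direction", "median_high", "median_pool"
        ]


class TestOverlapCounts:
    def test_identical_sets_all_shared(self):
        sets = {p: {"r1", "r2"} for p in ("a", "b", "c")}
        counts = overlap_counts(sets)
        assert counts[("a", "b", "c")] == 2
        assert sum(counts.values()) == 2

    def test_disjoint_sets_unique_counts(self):
        sets = {"a": {"r1"}, "b": {"r2", "r3"}, "c": {"r4"}}
        counts = overlap_counts(sets)
        assert counts[("a",)] == 1 and counts[("b",)] == 2 and counts[("c",)] == 1
        assert counts[("a", "b", "c")] == 0

    def test_random_sets_match_membership_enumeration(self):
        rng = np.random.default_rng(9)
        universe = [f"r{i}" for i in range(40)]
        sets = {
            p: {r for r in universe if rng.random() < 0.4}
            for p in ("early", "late", "stat")
        }
        counts = overlap_counts(sets)
        union = set().union(*sets.values())
        assert sum(counts.values()) == len(union)
        for r in range(1, 4):
            for combo in combinations(sets, r):
                expected = sum(
                    1 for rid in union
                    if {p for p in sets if rid in sets[p]} == set(combo)
                )
                assert counts[tuple(combo)] == expected


class TestSubsystemEnrichment:
    def _model(self):
        mets = [Metabolite("m_c")]
        rxns = [Reaction(f"R{i}", {"m_c": (-1.0) ** i}, 0, 10,
                         subsystem="Glycolysis" if i < 10 else None)
                for i in range(12)]
        return MetabolicModel(metabolites=mets, reactions=rxns)

    def test_proportions_from_manual_tally(self):
        from fluxsig.signatures import SkewTestResult

        results = [
            SkewTestResult(f"R{i}", 0, 0.001, 0.001,
                           "increased" if i < 5 else "none", 1, 0)
            for i in range(10)
        ]
        table = subsystem_enrichment(results, self._model())
        glyc = table[table.subsystem == "Glycolysis"].iloc[0]
        assert glyc.subsystem_size == 10
        assert glyc.n_up == 5
        assert glyc.prop_up == 0.5
        assert glyc.prop_down == 0.0

    def test_no_significant_reactions(self):
        table = subsystem_enrichment([], self._model())
        assert (table.prop_up == 0).all() and (table.prop_down == 0).all()

    def test_unannotated_reported_separately(self):
        table = subsystem_enrichment([], self._model())
        row = table[table.subsystem == "(unannotated)"].iloc[0]
        assert row.subsystem_size == 2


class TestPCA:
    def test_single_direction_explains_everything(self):
        t = np.linspace(0, 1, 50)
        frame = pd.DataFrame({"a": t, "b": 2 * t, "c": -t})
        result = pca_solutions(frame)
        assert result.explained_variance_pct[0] == pytest.approx(100.0, abs=1e-6)

    def test_two_orthogonal_equal_variance_directions(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=4000)
        b = rng.normal(size=4000)
        frame = pd.DataFrame({"a": a, "b": b})
        result = pca_solutions(frame)
        assert result.explained_variance_pct[0] == pytest.approx(50.0, abs=3.0)
        assert result.explained_variance_pct[1] == pytest.approx(50.0, abs=3.0)

    def test_variances_sorted_and_bounded(self):
        rng = np.random.default_rng(11)
        frame = pd.DataFrame(rng.random((30, 6)),
                             columns=[f"r{i}" for i in range(6)])
        result = pca_solutions(frame)
        ev = result.explained_variance_pct
        assert np.all(np.diff(ev) <= 1e-9)
        assert ev.sum() <= 100.0 + 1e-6

    def test_zero_variance_reaction_dropped(self):
        rng = np.random.default_rng(12)
        frame = pd.DataFrame({"a": rng.random(20), "b": rng.random(20),
                              "flat": np.ones(20)})
        result = pca_solutions(frame)
        assert result.dropped_reactions == ["flat"]
        assert "flat" not in result.loadings.index

    def test_loadings_unit_norm(self):
        rng = np.random.default_rng(13)
        frame = pd.DataFrame(rng.random((25, 5)),
                             columns=[f"r{i}" for i in range(5)])
        result = pca_solutions(frame)
        norms = np.linalg.norm(result.loadings.to_numpy(), axis=0)
        np.testing.assert_allclose(norms, 1.0, rtol=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="2 solutions"):
            pca_solutions(pd.DataFrame({"a": [1.0]}))
        with pytest.raises(ValueError, match="non-constant"):
            pca_solutions(pd.DataFrame({"a": [1.0, 1.0], "b": [2.0, 2.0]}))


class TestTransportAnnotation:
    def test_importers_and_exporters_classified(self):
        mets = [
            Metabolite("ala__L_e", compartment="e"),
            Metabolite("ala__L_c", compartment="c"),
            Metabolite("glc__D_e", compartment="e"),
            Metabolite("glc__D_c", compartment="c"),
        ]
        rxns = [
            Reaction("ALAt_in", {"ala__L_e": -1.0, "ala__L_c": 1.0}, 0, 10),
            Reaction("ALAt_out", {"ala__L_c": -1.0, "ala__L_e": 1.0}, 0, 10),
            Reaction("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0}, 0, 10),
            Reaction("EX_ala", {"ala__L_e": -1.0}, -10, 10),
        ]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        ann = infer_transport_annotation(model)
        assert ann["ALAt_in"] == ("A", "import")
        assert ann["ALAt_out"] == ("A", "export")
        assert "GLCt" not in ann          # not an amino acid
        assert "EX_ala" not in ann        # exchange, not transport

    def test_whitelist_override(self):
        mets = [Metabolite("glc__D_e", compartment="e"),
                Metabolite("glc__D_c", compartment="c")]
        rxns = [Reaction("GLCt", {"glc__D_e": -1.0, "glc__D_c": 1.0}, 0, 10)]
        model = MetabolicModel(metabolites=mets, reactions=rxns)
        ann = infer_transport_annotation(model, {"glc__D": "glucose"})
        assert ann["GLCt"] == ("glucose", "import")


class TestTransportSignature:
    def _inputs(self):
        rng = np.random.default_rng(14)
        prod = rng.random(1000)
        importer = 2.0 * prod
        other = rng.random(1000)
        samples = make_samples(np.column_stack([prod, importer, other]),
                               ["prod", "T_ala", "free"])
        sel = select_high_producers(samples, "prod", 95.0)
        results = flux_skew_test(samples, sel)
        loadings = pd.DataFrame(
            {"PC1": [0.9, 0.43, 0.02], "PC2": [0.1, -0.3, 0.95]},
            index=["prod", "T_ala", "free"],
        )
        annotation = {"T_ala": ("A", "import")}
        return loadings, results, samples, sel, annotation

    def test_coupled_importer_reported_up(self):
        loadings, results, samples, sel, ann = self._inputs()
        table = extract_transport_signature(loadings, results, samples, sel, ann,
                                            top_k=50, phase="early")
        assert list(table.reaction) == ["T_ala"]
        row = table.iloc[0]
        assert row.regulation == "up"
        assert row.transport_direction == "import"
        assert row.mean_flux_high > row.mean_flux_pool
        assert row.net_uptake_high == pytest.approx(row.mean_flux_high)

    def test_top_k_larger_than_reaction_count(self):
        loadings, results, samples, sel, ann = self._inputs()
        full = extract_transport_signature(loadings, results, samples, sel, ann,
                                           top_k=1000)
        small = extract_transport_signature(loadings, results, samples, sel, ann,
                                            top_k=50)
        pd.testing.assert_frame_equal(full, small)

    def test_no_significant_reactions_empty_table(self):
        loadings, results, samples, sel, ann = self._inputs()
        table = extract_transport_signature(loadings, results, samples, sel, ann,
                                            top_k=50, fdr_threshold=1e-300)
        assert len(table) == 0
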