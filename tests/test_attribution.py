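"""Taylor interventions, path mediation, and attribution curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

from unitcause import attribution as attr
from unitcause.cohort import CohortTable, GroundTruthSCM, generate_cohort
from unitcause.graph import CausalGraph
from unitcause.nn import FeedforwardClassifier


class _Quadratic:
    """Stub model implementing f(x) = x_0^2 (value/hessian protocol)."""

    feature_order = ("x",)

    def value(self, point, class_index, mode="proba"):
        return float(np.asarray(point)[0] ** 2)

    def hessian(self, point, class_index, mode="proba"):
        return np.array([[2.0]])


class TestGaussianSummary:
    def test_sample_moments_symmetric(self, cohort):
        s = attr.fit_gaussian_summary(cohort)
        assert np.array_equal(s.cov, s.cov.T)
        assert s.feature_order == cohort.feature_names

    def test_iid_sample_recovers_identity(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.standard_normal((20000, 4)),
                             columns=list("abcd"))
        s = attr.fit_gaussian_summary(frame)
        off = s.cov - np.diag(np.diag(s.cov))
        assert np.abs(off).max() < 0.05
        assert np.abs(np.diag(s.cov) - 1).max() < 0.1

    def test_constant_column_warns(self):
        frame = pd.DataFrame({"a": np.zeros(100), "b": np.arange(100.0)})
        with pytest.warns(UserWarning, match="degenerate"):
            attr.fit_gaussian_summary(frame)

    def test_too_few_records_rejected(self):
        frame = pd.DataFrame(np.zeros((3, 5)), columns=list("abcde"))
        with pytest.raises(ValueError):
            attr.fit_gaussian_summary(frame)


class TestInterveneSummary:
    def test_do_pins_mean_and_kills_variance(self, cohort):
        s = attr.fit_gaussian_summary(cohort)
        s2 = attr.intervene_summary(s, "AL", 25.0)
        i = s.index("AL")
        assert s2.mean[i] == 25.0
        assert np.all(s2.cov[i, :] == 0) and np.all(s2.cov[:, i] == 0)

    def test_chain_mean_propagation(self):
        # A -> B with coefficient b: do(A=alpha) shifts B by b*(alpha-mu_A)
        mean = np.array([1.0, 2.0])
        cov = np.array([[1.0, 0.7], [0.7, 1.5]])
        s = attr.GaussianSummary(mean, cov, ("A", "B"))
        s2 = attr.intervene_summary(s, "A", 3.0, total_effects={"B": 0.7})
        assert s2.mean[1] == pytest.approx(2.0 + 0.7 * (3.0 - 1.0))

    def test_mediator_variance_reduced_by_explained_share(self):
        # B = 0.7*A + e: do(A) removes the variance A carries into B
        mean = np.zeros(2)
        cov = np.array([[1.0, 0.7], [0.7, 0.49 + 0.5]])
        s = attr.GaussianSummary(mean, cov, ("A", "B"))
        s2 = attr.intervene_summary(s, "A", 1.0, total_effects={"B": 0.7})
        assert s2.cov[1, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(10))
    def test_result_positive_semidefinite(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((6, 6))
        s = attr.GaussianSummary(rng.standard_normal(6), A @ A.T,
                                 tuple("abcdef"))
        effects = {n: float(rng.standard_normal())
                   for n in ("b", "c", "d")}
        s2 = attr.intervene_summary(s, "a", 2.0, effects)
        assert np.linalg.eigvalsh(s2.cov).min() >= -1e-9

    def test_unknown_unit_rejected(self, cohort):
        s = attr.fit_gaussian_summary(cohort)
        with pytest.raises(KeyError):
            attr.intervene_summary(s, "nope", 0.0)


class TestTaylorExpectation:
    def test_linear_output_equals_value_at_mean(self):
        # pre-softmax output of a ReLU net is piecewise linear: zero Hessian
        m = FeedforwardClassifier.random([4, 3, 2], seed=0, weight_scale=0.6)
        rng = np.random.default_rng(0)
        A = rng.standard_normal((4, 4))
        s = attr.GaussianSummary(rng.standard_normal(4), A @ A.T,
                                 tuple(m.feature_order))
        assert attr.taylor_expectation(m, s, 1, mode="logit") == \
            pytest.approx(m.value(s.mean, 1, mode="logit"), abs=1e-12)

    def test_quadratic_closed_form(self):
        # E[x^2] = mu^2 + sigma^2 is exact at second order
        s = attr.GaussianSummary(np.array([0.0]), np.array([[0.25]]), ("x",))
        assert attr.taylor_expectation(_Quadratic(), s, 0) == \
            pytest.approx(0.25)
        s = attr.GaussianSummary(np.array([2.0]), np.array([[0.25]]), ("x",))
        assert attr.taylor_expectation(_Quadratic(), s, 0) == \
            pytest.approx(4.25)

    def test_feature_order_mismatch_rejected(self, trained_model):
        s = attr.GaussianSummary(np.zeros(16), np.eye(16),
                                 tuple(f"z{i}" for i in range(16)))
        with pytest.raises(ValueError, match="order"):
            attr.taylor_expectation(trained_model, s, 0)


class TestInterventionGrid:
    def test_uniform_inclusive(self):
        g = attr.InterventionGrid("x", 0.0, 10.0, 11)
        assert g.alphas[0] == 0.0 and g.alphas[-1] == 10.0
        assert np.allclose(np.diff(g.alphas), 1.0)

    def test_from_cohort_uses_inner_percentiles(self, cohort):
        g = attr.InterventionGrid.from_cohort(cohort, "AL")
        vals = cohort.frame["AL"]
        assert vals.min() < g.low < g.high < vals.max()

    def test_binary_unit_gets_two_point_grid(self, cohort):
        g = attr.InterventionGrid.from_cohort(cohort, "GENDER")
        assert list(g.alphas) == [0.0, 1.0]

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            attr.InterventionGrid("x", 1.0, 1.0, 5)


class TestAceIsolated:
    def test_binary_grid_span_is_do_contrast(self, trained_model, cohort):
        # Eq. on binary treatments: E[y|do(1)] - E[y|do(0)]
        s = attr.fit_gaussian_summary(cohort)
        grid = attr.InterventionGrid("GENDER", 0.0, 1.0, 2)
        curve = attr.ace_isolated(trained_model, s, grid, 1, method="taylor")
        e0 = attr.taylor_expectation(
            trained_model, attr.intervene_summary(s, "GENDER", 0.0), 1)
        e1 = attr.taylor_expectation(
            trained_model, attr.intervene_summary(s, "GENDER", 1.0), 1)
        assert curve.span_effect == pytest.approx(e1 - e0, abs=1e-12)
        assert curve.ace == pytest.approx((e0 + e1) / 2, abs=1e-12)

    def test_model_ignoring_unit_gives_flat_curve(self):
        rng = np.random.default_rng(0)
        m = FeedforwardClassifier.random([3, 4, 2], seed=1, weight_scale=0.5)
        m.weights[0][2, :] = 0.0  # model is blind to the third feature
        s = attr.GaussianSummary(rng.standard_normal(3), np.eye(3) * 0.2,
                                 tuple(m.feature_order))
        grid = attr.InterventionGrid("x2", -2.0, 2.0, 7)
        for method in ("taylor", "mc"):
            curve = attr.ace_isolated(m, s, grid, 1, method=method)
            assert np.abs(curve.centered).max() < 1e-9

    def test_centered_curve_mean_zero_and_mirror_classes(
            self, trained_model, cohort):
        s = attr.fit_gaussian_summary(cohort)
        grid = attr.InterventionGrid.from_cohort(cohort, "PULSE")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yes = attr.ace_isolated(trained_model, s, grid, 1)
            no = attr.ace_isolated(trained_model, s, grid, 0)
        assert abs(yes.centered.sum()) < 1e-9
        assert np.allclose(yes.expectation + no.expectation, 1.0, atol=1e-9)

    def test_monotone_toy_net_trends_oppose(self):
        m = FeedforwardClassifier(
            weights=[np.array([[1.0]]), np.array([[0.0, 2.0]])],
            biases=[np.array([2.0]), np.array([0.0, 0.0])],
            feature_order=("x",), shift=np.zeros(1), scale=np.ones(1))
        s = attr.GaussianSummary(np.array([0.5]), np.array([[0.01]]), ("x",))
        grid = attr.InterventionGrid("x", -1.0, 1.5, 8)
        yes = attr.ace_isolated(m, s, grid, 1, method="taylor")
        no = attr.ace_isolated(m, s, grid, 0, method="taylor")
        assert np.all(np.diff(yes.expectation) >= -1e-12)
        assert np.all(np.diff(no.expectation) <= 1e-12)

    def test_refuses_non_isolated_unit(self, trained_model, cohort,
                                       paper_graph):
        s = attr.fit_gaussian_summary(cohort)
        grid = attr.InterventionGrid.from_cohort(cohort, "HEIGHT")
        with pytest.raises(ValueError, match="Pure"):
            attr.ace_isolated(trained_model, s, grid, 1, graph=paper_graph)


class TestEdgeCoefficients:
    def test_recovers_generator_truth(self, scm):
        big = generate_cohort(scm, 10000, seed=8)
        coeffs = attr.fit_edge_coefficients(big, scm.graph)
        # SE of the HEIGHT->AL slope is ~noise/(sd(HEIGHT)*sqrt(n))
        se = scm.noise_sd["AL"] / (7.0 * np.sqrt(10000))
        assert abs(coeffs[("HEIGHT", "AL")]
                   - scm.edge_coeff[("HEIGHT", "AL")]) < 3 * se

    def test_noise_free_linear_system_exact(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(500)
        frame = pd.DataFrame({"a": a, "b": 2.0 * a + 1.0,
                              "c": -1.5 * (2.0 * a + 1.0) + 0.3})
        g = CausalGraph(directed_edges=[("a", "b"), ("b", "c")])
        coeffs = attr.fit_edge_coefficients(frame, g)
        assert coeffs[("a", "b")] == pytest.approx(2.0, abs=1e-8)
        assert coeffs[("b", "c")] == pytest.approx(-1.5, abs=1e-8)

    def test_parentless_nodes_emit_nothing(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame({"a": rng.standard_normal(100),
                              "b": rng.standard_normal(100)})
        g = CausalGraph(["a", "b"])
        assert attr.fit_edge_coefficients(frame, g) == {}

    def test_collinear_parents_warn(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(300)
        frame = pd.DataFrame({"a": a, "a2": a.copy(),
                              "y": a + rng.standard_normal(300)})
        g = CausalGraph(directed_edges=[("a", "y"), ("a2", "y")])
        with pytest.warns(UserWarning, match="collinear"):
            attr.fit_edge_coefficients(frame, g)


class TestTotalEffectPure:
    def test_chain_product_rule(self):
        g = CausalGraph(directed_edges=[("a", "b"), ("b", "c")])
        eff, paths = attr.total_effect_pure(
            g, {("a", "b"): 2.0, ("b", "c"): -1.5}, "a", "c")
        assert eff == pytest.approx(-3.0)
        assert len(paths) == 1
        assert paths[0].effect == pytest.approx(paths[0].edge_coeffs[0]
                                                * paths[0].edge_coeffs[1])

    def test_two_path_sum(self):
        # direct d plus mediated a*r, the published two-path shape
        g = CausalGraph(directed_edges=[("PWG", "CR"), ("PWG", "AL"),
                                        ("AL", "CR")])
        coeffs = {("PWG", "CR"): -0.3, ("PWG", "AL"): 0.35,
                  ("AL", "CR"): -0.9}
        eff, paths = attr.total_effect_pure(g, coeffs, "PWG", "CR")
        assert eff == pytest.approx(-0.3 + 0.35 * -0.9)
        assert len(paths) == 2

    def test_no_path_gives_zero(self):
        g = CausalGraph(["a", "b"])
        eff, paths = attr.total_effect_pure(g, {}, "a", "b")
        assert eff == 0.0 and paths == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_backdoor_adjusted_regression(self, seed):
        # source unit: marginal regression of target on unit is the oracle
        scm = _random_linear_scm(seed, n_nodes=5)
        sources = [n for n in scm.graph.nodes if not scm.graph.parents(n)]
        sinks = [n for n in scm.graph.nodes if scm.graph.parents(n)]
        if not sinks:
            pytest.skip("no child nodes in this draw")
        unit, target = sorted(sources)[0], sorted(sinks)[-1]
        data = generate_cohort_generic(scm, 20000, seed)
        coeffs = attr.fit_edge_coefficients(data, scm.graph)
        eff, _ = attr.total_effect_pure(scm.graph, coeffs, unit, target)
        x = data[unit].to_numpy()
        y = data[target].to_numpy()
        X = np.column_stack([np.ones(len(x)), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt((resid @ resid / (len(y) - 2))
                     / ((x - x.mean()) @ (x - x.mean())))
        assert abs(eff - beta[1]) < max(3 * se, 1e-6)


def _random_linear_scm(seed: int, n_nodes: int = 5) -> GroundTruthSCM:
    """Random linear-Gaussian SCM over generic node names."""
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    g = CausalGraph(names)
    coeffs = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < 0.5:
                g.add_directed(names[i], names[j])
                coeffs[(names[i], names[j])] = float(
                    rng.uniform(0.3, 1.2) * rng.choice([-1, 1]))
    return GroundTruthSCM(
        graph=g, edge_coeff=coeffs,
        noise_sd={n: 1.0 for n in names if g.parents(n)},
        intercepts={n: 0.0 for n in names},
        source_dists={n: ("normal", 0.0, 1.0)
                      for n in names if not g.parents(n)},
    )


def generate_cohort_generic(scm: GroundTruthSCM, n: int, seed: int
                            ) -> pd.DataFrame:
    """Ancestral sampling for generic (non-myopia) SCMs."""
    rng = np.random.default_rng(seed)
    cols = {}
    for node in scm.graph.topological_order():
        parents = scm.graph.parents(node)
        if not parents:
            _, mu, sd = scm.source_dists[node]
            cols[node] = rng.normal(mu, sd, n)
        else:
            x = np.zeros(n)
            for p in sorted(parents):
                x += scm.edge_coeff[(p, node)] * cols[p]
            cols[node] = x + rng.normal(0, scm.noise_sd[node], n)
    return pd.DataFrame(cols)


class TestAcePure:
    def test_zero_path_coefficients_flat_curve(self, trained_model, cohort,
                                               paper_graph):
        coeffs = {e: 0.0 for e in paper_graph.directed_edges}
        grid = attr.InterventionGrid("HEIGHT", 110.0, 130.0, 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            curve = attr.ace_pure(trained_model, cohort, paper_graph,
                                  "HEIGHT", grid, 1, coeffs=coeffs,
                                  method="mc")
            base = attr.ace_isolated(
                trained_model, attr.fit_gaussian_summary(cohort), grid, 1,
                method="mc")
        # with no mediation the pure engine reduces to the isolated one
        assert np.allclose(curve.expectation, base.expectation, atol=1e-12)

    def test_linear_logit_curve_affine_in_alpha(self, cohort, paper_graph):
        # single-layer net: logit expectation is affine in the intervention
        rng = np.random.default_rng(0)
        w = rng.standard_normal((16, 2)) * 0.1
        m = FeedforwardClassifier([w], [np.zeros(2)], cohort.feature_names,
                                  np.zeros(16), np.ones(16))
        grid = attr.InterventionGrid("HEIGHT", 105.0, 135.0, 10)
        curve = attr.ace_pure(m, cohort, paper_graph, "HEIGHT", grid, 1,
                              mode="logit", method="taylor")
        fitted = np.polyfit(curve.alphas, curve.expectation, 1)
        resid = curve.expectation - np.polyval(fitted, curve.alphas)
        assert np.abs(resid).max() < 1e-6

    def test_mediated_equals_isolated_on_mediator_grid(self):
        # model reads only the mediator; mediator fully determined by unit
        m = FeedforwardClassifier(
            weights=[np.array([[0.0, 0.0], [1.0, -1.0]])],
            biases=[np.zeros(2)], feature_order=("u", "med"),
            shift=np.zeros(2), scale=np.ones(2))
        rng = np.random.default_rng(3)
        u = rng.standard_normal(4000)
        med = 1.5 * u  # noise-free mediation
        frame = pd.DataFrame({"u": u, "med": med})
        frame["Myopia"] = (med <= 0).astype(int)
        from unitcause.cohort import VariableSpec
        specs = (VariableSpec("u", "continuous", -5, 5),
                 VariableSpec("med", "continuous", -9, 9))
        ct = CohortTable(frame, specs)
        g = CausalGraph(directed_edges=[("u", "med")])
        grid_u = attr.InterventionGrid("u", -1.0, 1.0, 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pure = attr.ace_pure(m, ct, g, "u", grid_u, 1, mode="logit",
                                 method="taylor")
        # the same intervention expressed directly on the mediator
        s = attr.fit_gaussian_summary(ct)
        direct = [attr.taylor_expectation(
            m, attr.intervene_summary(s, "med", 1.5 * a,
                                      total_effects={"u": 0.0}),
            1, mode="logit") for a in grid_u.alphas]
        assert np.allclose(pure.expectation, direct, atol=1e-6)

    def test_refuses_non_pure_unit(self, trained_model, cohort, paper_graph):
        grid = attr.InterventionGrid("AL", 22.0, 26.0, 5)
        with pytest.raises(ValueError, match="Confounded"):
            attr.ace_pure(trained_model, cohort, paper_graph, "AL", grid, 1)


def test_curve_csv_export(tmp_path, trained_model, cohort):
    s = attr.fit_gaussian_summary(cohort)
    grid = attr.InterventionGrid.from_cohort(cohort, "NW")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curves = [attr.ace_isolated(trained_model, s, grid, ci)
                  for ci in (0, 1)]
    path = tmp_path / "nw.csv"
    attr.write_curves_csv(curves, path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["alpha", "expectation_no", "centered_no",
                                  "expectation_yes", "centered_yes"]
    assert np.allclose(back["expectation_yes"], curves[1].expectation)
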