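import numpy as np
import pytest

from psmreg import (
    ConfigError,
    build_graph,
    fitting_cost,
    objective,
    rerank,
    smoothing_cost,
    solve_closed_form,
    solve_iterative,
)

from conftest import TOY_SCORES, make_records, random_records


def two_node_graph():
    return build_graph(make_records([{"A"}, {"A"}]))


def dense_solution(graph, X_real, lam):
    """Independent dense-linear-algebra oracle for the closed form."""
    X = np.concatenate([X_real, np.zeros(graph.n_dummy)])
    A = np.eye(graph.n_total) - (1 - lam) * graph.S.toarray()
    return (lam * np.linalg.solve(A, X))[: graph.n_real]


def quadratic_form(graph, Y):
    """Y^T (I - S) Y, the spectral-identity oracle for the smoothing cost."""
    M = np.eye(graph.n_total) - graph.S.toarray()
    return float(Y @ M @ Y)


class TestCosts:
    def test_equal_scores_smooth_on_regular_graph(self):
        assert smoothing_cost([1.0, 1.0], two_node_graph()) == pytest.approx(0.0)

    def test_two_node_hand_value(self):
        # w=1, degrees 1: 1 * (1/1 - 0/1)^2 = 1
        g = two_node_graph()
        assert smoothing_cost([1.0, 0.0], g) == pytest.approx(1.0)
        assert quadratic_form(g, np.array([1.0, 0.0])) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_sum_equals_quadratic_form(self, seed):
        rng = np.random.default_rng(seed)
        g = build_graph(random_records(rng, int(rng.integers(2, 60))))
        Y = rng.normal(0, 3, size=g.n_total)
        assert smoothing_cost(Y, g) == pytest.approx(quadratic_form(g, Y), abs=1e-10)
        assert smoothing_cost(Y, g) >= 0

    def test_fitting_cost(self):
        assert fitting_cost([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert fitting_cost([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]) == pytest.approx(3.0)
        rng = np.random.default_rng(0)
        Y, X = rng.normal(size=10), rng.normal(size=10)
        assert fitting_cost(Y, X) == pytest.approx(sum((y - x) ** 2 for y, x in zip(Y, X)))

    def test_objective_zero_at_smooth_fit(self):
        g = two_node_graph()
        assert objective([1.0, 1.0], [1.0, 1.0], g, 0.5) == pytest.approx(0.0)

    def test_objective_weighting_direct_formula(self):
        g = two_node_graph()
        Y, X = np.array([1.0, 0.0]), np.array([0.5, 0.5])
        for lam in (0.2, 0.999):
            expected = (1 - lam) * smoothing_cost(Y, g) + lam * fitting_cost(Y, X)
            assert objective(Y, X, g, lam) == pytest.approx(expected)

    def test_objective_lambda_domain(self):
        g = two_node_graph()
        for lam in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ConfigError):
                objective([0.0, 0.0], [0.0, 0.0], g, lam)


class TestClosedForm:
    def test_two_node_hand_inversion(self):
        """lam=0.5, S=[[0,1],[1,0]], X=(1,0): solving the 2x2 system by
        hand gives Y=(2/3, 1/3)."""
        res = solve_closed_form([1.0, 0.0], two_node_graph(), 0.5)
        assert np.allclose(res.Y, [2 / 3, 1 / 3], atol=1e-12)
        assert res.method == "closed_form"
        assert res.iterations == 0

    def test_constant_vector_is_fixed_point(self):
        # On a degree-regular graph, S @ 1 = 1, so (I-(1-lam)S)1 = lam*1.
        res = solve_closed_form([1.0, 1.0], two_node_graph(), 0.3)
        assert np.allclose(res.Y, [1.0, 1.0], atol=1e-12)

    def test_lambda_near_one_recovers_initial_scores(self):
        rng = np.random.default_rng(3)
        recs = random_records(rng, 50)
        X = np.array([r.initial_score for r in recs])
        res = solve_closed_form(X, build_graph(recs), 0.999)
        assert np.max(np.abs(res.Y - X)) <= 0.01 * np.max(np.abs(X))

    def test_stationarity_residual_small(self):
        rng = np.random.default_rng(4)
        recs = random_records(rng, 80)
        X = np.array([r.initial_score for r in recs])
        res = solve_closed_form(X, build_graph(recs), 0.5)
        assert res.final_residual <= 1e-8

    def test_matches_dense_oracle(self, toy_graph):
        X = np.array(TOY_SCORES)
        res = solve_closed_form(X, toy_graph, 0.6)
        assert np.allclose(res.Y, dense_solution(toy_graph, X, 0.6), atol=1e-12)

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_boundary_lambda_rejected(self, lam):
        with pytest.raises(ConfigError, match="lambda"):
            solve_closed_form([1.0, 0.0], two_node_graph(), lam)


class TestIterative:
    def test_converges_to_closed_form_two_node(self):
        res = solve_iterative([1.0, 0.0], two_node_graph(), 0.5)
        assert np.allclose(res.Y, [2 / 3, 1 / 3], atol=1e-7)
        assert res.method == "iterative"
        assert 0 < res.iterations
        assert res.final_residual < 1e-9

    def test_higher_lambda_converges_faster(self):
        rng = np.random.default_rng(5)
        recs = random_records(rng, 60)
        g = build_graph(recs)
        X = np.array([r.initial_score for r in recs])
        fast = solve_iterative(X, g, 0.9)
        slow = solve_iterative(X, g, 0.1)
        assert fast.iterations < slow.iterations

    def test_start_point_does_not_change_fixed_point(self):
        rng = np.random.default_rng(6)
        recs = random_records(rng, 40)
        g = build_graph(recs)
        X = np.array([r.initial_score for r in recs])
        warm = solve_iterative(X, g, 0.5, tol=1e-11)
        cold = solve_iterative(X, g, 0.5, tol=1e-11, warm_start=False)
        assert np.max(np.abs(warm.Y - cold.Y)) <= 1e-10

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_closed_form_random(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, int(rng.integers(2, 200)))
        g = build_graph(recs)
        X = np.array([r.initial_score for r in recs])
        lam = float(rng.uniform(0.1, 0.9))
        it = solve_iterative(X, g, lam, tol=1e-9)
        cf = solve_closed_form(X, g, lam)
        assert np.max(np.abs(it.Y - cf.Y)) <= 1e-7


class TestMinimizer:
    @pytest.mark.parametrize("seed", range(4))
    def test_perturbations_never_improve(self, seed):
        rng = np.random.default_rng(seed)
        recs = random_records(rng, int(rng.integers(3, 50)))
        g = build_graph(recs)
        X_real = np.array([r.initial_score for r in recs])
        lam = float(rng.uniform(0.1, 0.9))
        res = solve_closed_form(X_real, g, lam)
        X = np.concatenate([X_real, np.zeros(g.n_dummy)])
        # recover the full minimizer (dummy entries included) densely
        A = np.eye(g.n_total) - (1 - lam) * g.S.toarray()
        Y = np.linalg.solve(A, lam * X)
        q_star = objective(Y, X, g, lam)
        for _ in range(100):
            V = rng.normal(size=g.n_total)
            for eps in (1e-3, 1e-2):
                assert q_star <= objective(Y + eps * V, X, g, lam) + 1e-12

    def test_minimizer_beats_initial_point(self, toy_graph):
        X = np.concatenate([np.array(TOY_SCORES), np.zeros(toy_graph.n_dummy)])
        res = solve_closed_form(np.array(TOY_SCORES), toy_graph, 0.5)
        Y = np.concatenate([res.Y, np.zeros(toy_graph.n_dummy)])
        assert objective(Y, X, toy_graph, 0.5) <= objective(X, X, toy_graph, 0.5)

    def test_gradient_of_objective_reproduces_closed_form(self):
        """Differentiating Q(Y) = (1-lam) Y'(I-S)Y + lam ||Y-X||^2
        symbolically yields Y* = lam (I-(1-lam)S)^(-1) X."""
        import sympy

        lam = sympy.Symbol("lam", positive=True)
        g = build_graph(make_records([{"A"}, {"A", "C"}, {"C"}]))
        S = sympy.Matrix(g.S.toarray()).applyfunc(sympy.nsimplify)
        X = sympy.Matrix(sympy.symbols("x0 x1 x2"))
        Y = sympy.Matrix(sympy.symbols("y0 y1 y2"))
        I = sympy.eye(3)
        Q = (1 - lam) * (Y.T * (I - S) * Y)[0] + lam * (Y - X).T.dot(Y - X)
        grad = sympy.Matrix([sympy.diff(Q, y) for y in Y])
        sol = sympy.solve(grad, list(Y), dict=True)[0]
        Y_star = sympy.Matrix([sympy.simplify(sol[y]) for y in Y])
        expected = lam * (I - (1 - lam) * S).inv() * X
        assert sympy.simplify(Y_star - expected) == sympy.zeros(3, 1)


class TestRerank:
    def test_toy_matches_dense_oracle_lambda_06(self, toy_records):
        graph, res = rerank(toy_records, lambda_=0.6)
        X = np.array(TOY_SCORES)
        assert np.allclose(res.Y, dense_solution(graph, X, 0.6), atol=1e-10)
        assert graph.n_edges() == 5

    def test_single_psm_dummy_system_closed_form(self):
        """An isolated PSM and its dummy form a 2x2 system whose
        normalized edge weight is 1 regardless of the tiny raw weight
        (w / sqrt(w*w)), so the closed form gives y = x / (2 - lam):
        ranks among isolated PSMs are preserved, values are not."""
        lam = 0.5
        _, res = rerank(make_records([{"A"}], scores=[4.0]), lambda_=lam)
        assert res.Y[0] == pytest.approx(4.0 / (2 - lam), rel=1e-9)
        # the uniform factor keeps isolated PSMs in their initial order
        _, res2 = rerank(make_records([{"A"}, {"B"}], scores=[4.0, 1.0]), lambda_=lam)
        assert res2.Y[0] > res2.Y[1]

    def test_doubling_x_doubles_y(self, toy_records):
        _, res1 = rerank(toy_records, lambda_=0.5)
        doubled = make_records(
            [set(r.proteins) for r in toy_records], [2 * s for s in TOY_SCORES]
        )
        _, res2 = rerank(doubled, lambda_=0.5)
        assert np.allclose(res2.Y, 2 * res1.Y, atol=1e-10)

    def test_linearity_in_x(self, toy_graph):
        rng = np.random.default_rng(9)
        X1, X2 = rng.normal(size=5), rng.normal(size=5)
        a, b = 1.7, -0.4
        lhs = solve_closed_form(a * X1 + b * X2, toy_graph, 0.5).Y
        rhs = a * solve_closed_form(X1, toy_graph, 0.5).Y + b * solve_closed_form(X2, toy_graph, 0.5).Y
        assert np.max(np.abs(lhs - rhs)) <= 1e-10

    def test_explicit_solver_selection(self, toy_records):
        _, cf = rerank(toy_records, solver="closed_form")
        _, it = rerank(toy_records, solver="iterative")
        assert cf.method == "closed_form" and it.method == "iterative"
        assert np.allclose(cf.Y, it.Y, atol=1e-7)

    def test_unknown_solver(self, toy_records):
        with pytest.raises(ConfigError, match="solver"):
            rerank(toy_records, solver="magic")

    def test_shrinkage_on_uniform_clique(self):
        """On a clique of identical membership sets the regularizer pulls
        every score toward the group and shrinks the spread."""
        rng = np.random.default_rng(10)
        X = rng.normal(0, 2, size=12)
        recs = make_records([{"A"}] * 12, X)
        _, res = rerank(recs, lambda_=0.5)
        assert np.all(res.Y >= X.min() - 1e-12)
        assert np.all(res.Y <= X.max() + 1e-12)
        assert res.Y.max() - res.Y.min() < X.max() - X.min()
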