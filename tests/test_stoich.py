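"""Module partitioning and the minimum-norm least-squares static solver."""

import numpy as np
import pytest

from hepaflux.stoich import (
    DYNAMIC,
    STATIC,
    FluxVector,
    StoichiometricModel,
    StoichiometryError,
    ModulePartition,
    partition_stoichiometry,
    solve_static_fluxes,
    static_residual,
)


def svd_lstsq_oracle(A, b, rcond=1e-12):
    """Independent minimum-norm least-squares via explicit dense SVD."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    cutoff = rcond * (s[0] if s.size else 0.0)
    sinv = np.array([1.0 / x if x > cutoff else 0.0 for x in s])
    return Vt.T @ (sinv * (U.T @ b))


def chain_model():
    # A -> B (dynamic), B -> C (static)
    S = np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]])
    return StoichiometricModel(("A", "B", "C"), ("r1", "r2"), S, {"r1"})


class TestPartition:
    def test_membership_rule_on_three_species_chain(self):
        part = partition_stoichiometry(chain_model())
        assert part.x_d_ids == ("A",)
        assert part.x_s_ids == ("B", "C")
        assert part.v_d_ids == ("r1",)
        assert part.v_s_ids == ("r2",)
        np.testing.assert_array_equal(part.S_dd, [[-1.0]])
        np.testing.assert_array_equal(part.S_sd, [[1.0], [0.0]])
        np.testing.assert_array_equal(part.S_ss, [[-1.0], [1.0]])

    def test_all_dynamic_degenerate_partition(self):
        S = np.array([[-1.0, 0.0], [1.0, -1.0], [0.0, 1.0]])
        model = StoichiometricModel(("A", "B", "C"), ("r1", "r2"), S, {"r1", "r2"})
        part = partition_stoichiometry(model)
        assert part.x_s_ids == ()
        assert part.v_s_ids == ()
        np.testing.assert_array_equal(part.S_dd, S)

    def test_blocks_reassemble_parent_matrix(self, rng):
        model = _random_model(rng, n=8, m=7)
        part = partition_stoichiometry(model)
        S = model.S
        for rows, cols, block in [
            (part.x_d_index, part.v_d_index, part.S_dd),
            (part.x_s_index, part.v_d_index, part.S_sd),
            (part.x_s_index, part.v_s_index, part.S_ss),
        ]:
            if len(rows) and len(cols):
                np.testing.assert_array_equal(S[np.ix_(rows, cols)], block)
        # x_d rows have no static-column entries at all
        for i in part.x_d_index:
            for j in part.v_s_index:
                assert S[i, j] == 0

    def test_orphan_species_rejected(self):
        S = np.array([[-1.0], [1.0], [0.0]])
        with pytest.raises(StoichiometryError, match="touched by no reaction"):
            StoichiometricModel(("A", "B", "C"), ("r1",), S, {"r1"})

    def test_reference_model_partition_counts(self, reference_partition):
        part = reference_partition
        assert len(part.x_d_ids) == 13
        assert len(part.v_d_ids) == 27
        assert len(part.x_s_ids) == 21
        assert len(part.v_s_ids) == 20


class TestStaticSolver:
    def test_zero_dynamic_flux_gives_zero_static_flux(self):
        part = partition_stoichiometry(chain_model())
        vs = solve_static_fluxes(part, FluxVector({"r1": 0.0}, DYNAMIC))
        assert vs.values == {"r2": 0.0}

    def test_single_balance_by_hand(self):
        # B balance: 0 = 2 (from dynamic) - v_s  ->  v_s = 2
        part = partition_stoichiometry(chain_model())
        vs = solve_static_fluxes(part, FluxVector({"r1": 2.0}, DYNAMIC))
        # chain: B: +2 - v2 = 0 and C: +v2 = 0 are inconsistent; the
        # least-squares flux splits the difference: v2 = 1
        assert vs.values["r2"] == pytest.approx(1.0)
        res = static_residual(part, FluxVector({"r1": 2.0}, DYNAMIC), vs)
        assert res == pytest.approx(np.sqrt(2.0))

    def test_one_by_one_balance(self):
        # 0 = -2 + v_s  ->  v_s = 2
        part = _raw_partition(np.array([[1.0]]), np.array([[-2.0]]))
        vs = solve_static_fluxes(part, np.array([1.0]))
        assert vs.values["s0"] == pytest.approx(2.0)

    def test_exactly_solvable_system_has_tiny_residual(self):
        # B -> C -> (drain): static chain can balance the dynamic input
        S = np.array([[-1.0, 0.0, 0.0], [1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
        model = StoichiometricModel(("A", "B", "C"), ("r1", "r2", "r3"), S, {"r1"})
        part = partition_stoichiometry(model)
        vd = FluxVector({"r1": 3.0}, DYNAMIC)
        vs = solve_static_fluxes(part, vd)
        assert static_residual(part, vd, vs) <= 1e-9
        assert vs.values["r2"] == pytest.approx(3.0)
        assert vs.values["r3"] == pytest.approx(3.0)

    def test_non_finite_input_rejected(self):
        part = partition_stoichiometry(chain_model())
        with pytest.raises(StoichiometryError):
            solve_static_fluxes(part, np.array([np.nan]))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_svd_oracle_and_minimum_norm(self, seed):
        """Random small instances: residual and norm match the oracle to 1e-9."""
        rng = np.random.default_rng(seed)
        n_s, m_s, m_d = rng.integers(2, 10), rng.integers(1, 8), rng.integers(1, 4)
        S_ss = rng.integers(-2, 3, size=(n_s, m_s)).astype(float)
        S_sd = rng.integers(-2, 3, size=(n_s, m_d)).astype(float)
        part = _raw_partition(S_ss, S_sd)
        vd = rng.normal(size=m_d)
        vs = solve_static_fluxes(part, vd).as_array(part.v_s_ids)
        b = -S_sd @ vd
        oracle = svd_lstsq_oracle(S_ss, b)
        assert np.linalg.norm(S_ss @ vs - b) <= np.linalg.norm(S_ss @ oracle - b) + 1e-9
        assert np.linalg.norm(vs) <= np.linalg.norm(oracle) + 1e-9
        np.testing.assert_allclose(vs, oracle, atol=1e-9)

    @pytest.mark.parametrize("seed", [1, 7, 42])
    def test_linearity(self, seed):
        rng = np.random.default_rng(seed)
        S_ss = rng.integers(-2, 3, size=(6, 4)).astype(float)
        S_sd = rng.integers(-2, 3, size=(6, 2)).astype(float)
        part = _raw_partition(S_ss, S_sd)
        v, w = rng.normal(size=2), rng.normal(size=2)
        a, b = 2.5, -1.25
        lhs = solve_static_fluxes(part, a * v + b * w).as_array(part.v_s_ids)
        rhs = a * solve_static_fluxes(part, v).as_array(part.v_s_ids) + \
            b * solve_static_fluxes(part, w).as_array(part.v_s_ids)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_permutation_invariance(self, rng):
        model = _random_model(rng, n=7, m=6)
        part = partition_stoichiometry(model)
        vd_vals = rng.normal(size=len(part.v_d_ids))
        vd = dict(zip(part.v_d_ids, vd_vals))
        base = solve_static_fluxes(part, FluxVector(vd, DYNAMIC)).values

        perm_s = rng.permutation(model.n_species)
        perm_r = rng.permutation(model.n_reactions)
        permuted = StoichiometricModel(
            tuple(model.species_ids[i] for i in perm_s),
            tuple(model.reaction_ids[j] for j in perm_r),
            model.S[np.ix_(perm_s, perm_r)],
            model.dynamic_reactions,
        )
        part2 = partition_stoichiometry(permuted)
        out = solve_static_fluxes(part2, FluxVector(vd, DYNAMIC)).values
        assert set(out) == set(base)
        for rid, val in base.items():
            assert out[rid] == pytest.approx(val, abs=1e-12)

    def test_empty_static_module(self):
        S = np.array([[-1.0], [1.0]])
        model = StoichiometricModel(("A", "B"), ("r1",), S, {"r1"})
        part = partition_stoichiometry(model)
        vs = solve_static_fluxes(part, FluxVector({"r1": 1.0}, DYNAMIC))
        assert vs.values == {}
        assert static_residual(part, FluxVector({"r1": 1.0}, DYNAMIC), vs) == 0.0


def test_reference_static_module_is_overdetermined(reference_partition):
    diag = reference_partition.diagnostics()
    assert diag["overdetermined"]
    assert diag["left_null_dim"] >= 1


def _raw_partition(S_ss, S_sd):
    n_s, m_s = S_ss.shape
    m_d = S_sd.shape[1]
    return ModulePartition(
        x_d_ids=(),
        x_s_ids=tuple(f"x{i}" for i in range(n_s)),
        v_d_ids=tuple(f"d{j}" for j in range(m_d)),
        v_s_ids=tuple(f"s{j}" for j in range(m_s)),
        S_dd=np.zeros((0, m_d)),
        S_sd=S_sd,
        S_ss=S_ss,
        x_d_index=(),
        x_s_index=tuple(range(n_s)),
        v_d_index=tuple(range(m_d)),
        v_s_index=tuple(range(m_d, m_d + m_s)),
    )


def _random_model(rng, n, m):
    while True:
        S = rng.integers(-2, 3, size=(n, m)).astype(float)
        if (S != 0).any(axis=1).all() and (S != 0).any(axis=0).all():
            break
    dyn = set(
        rng.choice([f"r{j}" for j in range(m)], size=max(1, m // 2), replace=False)
    )
    return StoichiometricModel(
        tuple(f"s{i}" for i in range(n)),
        tuple(f"r{j}" for j in range(m)),
        S,
        dyn,
    )
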