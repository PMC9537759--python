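"""Programmatic toy networks with known solutions.

These generators provide the oracle surface for the stoichiometric solver
and the hybrid integrator: linear mass-action chains with matrix-exponential
trajectories, a dynamic-input/static-split network whose least-squares flux
distribution can be written down by hand, and random over-determined static
blocks whose minimiser is computed by an independent normal-equation
oracle.  Generation is deterministic per seed, and every generated document
passes structural validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import expm

from .document import MetaboliteSpec, ModelDocument, ReactionSpec, validate_model
from .ratelaws import RateLaw


@dataclass
class ToyNetwork:
    """A model document plus its closed-form descriptor."""

    document: ModelDocument
    seed: int | None = None
    #: analytic state trajectory x(t) for dynamic toys
    analytic: Callable[[float], np.ndarray] | None = None
    #: hand-solved / oracle static flux distribution for MFA toys
    static_solution: dict = field(default_factory=dict)


def make_linear_chain(
    n_species: int,
    rate_constants: Sequence[float] | None = None,
    seed: int = 0,
    x0: Sequence[float] | None = None,
) -> ToyNetwork:
    """Irreversible mass-action chain A1 -> A2 -> ... -> An, all dynamic.

    The attached analytic solution is ``x(t) = expm(A t) x0`` for the linear
    rate matrix A; total mass is conserved (the terminal species has no
    outgoing reaction).
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = np.random.default_rng(seed)
    if rate_constants is None:
        rate_constants = rng.uniform(0.5, 2.0, n_species - 1)
    ks = np.asarray(rate_constants, dtype=float)
    if len(ks) != n_species - 1 or np.any(ks <= 0):
        raise ValueError("need n_species-1 positive rate constants")
    if x0 is None:
        x0 = np.zeros(n_species)
        x0[0] = 1.0
    x0 = np.asarray(x0, dtype=float)

    species = [
        MetaboliteSpec(f"s{i}", f"species {i}", initial=float(x0[i]))
        for i in range(n_species)
    ]
    reactions = [
        ReactionSpec(
            f"r{i}", {f"s{i}": -1, f"s{i+1}": 1}, "dynamic", f"step {i}",
            RateLaw("mass_action", {"k": float(ks[i])}, (f"s{i}",)),
        )
        for i in range(n_species - 1)
    ]
    doc = ModelDocument(species, reactions, metadata={"seed": seed, "kind": "linear_chain"})
    assert validate_model(doc).ok

    A = np.zeros((n_species, n_species))
    for i, k in enumerate(ks):
        A[i, i] -= k
        A[i + 1, i] += k

    def analytic(t: float) -> np.ndarray:
        return expm(A * t) @ x0

    return ToyNetwork(document=doc, seed=seed, analytic=analytic)


def make_branch_mfa(
    seed: int = 0,
    input_flux: float = 2.0,
    branch_coeffs: tuple[float, float] = (1.0, 1.0),
) -> ToyNetwork:
    """One dynamic input feeding a static two-branch split with a merge.

    Network: ``-> A`` (dynamic, zero order), then static ``A -> c1 B``,
    ``A -> c2 C``, ``B -> D``, ``C -> D``, ``D ->``.  For symmetric unit
    branches each static branch carries half the input; the general
    least-squares distribution (computed by the dense-SVD oracle on the
    assembled blocks) is attached as the descriptor.
    """
    c1, c2 = branch_coeffs
    species = [
        MetaboliteSpec(s, initial=1.0) for s in ("A", "B", "C", "D")
    ]
    reactions = [
        ReactionSpec("r_in", {"A": 1}, "dynamic", "input",
                     RateLaw("zero_order", {"rate": float(input_flux)})),
        ReactionSpec("b1", {"A": -1, "B": c1}, "static", "branch 1"),
        ReactionSpec("b2", {"A": -1, "C": c2}, "static", "branch 2"),
        ReactionSpec("m1", {"B": -1, "D": 1}, "static", "merge 1"),
        ReactionSpec("m2", {"C": -1, "D": 1}, "static", "merge 2"),
        ReactionSpec("out", {"D": -1}, "static", "efflux"),
    ]
    doc = ModelDocument(species, reactions,
                        metadata={"seed": seed, "kind": "branch_mfa"})
    assert validate_model(doc).ok

    # oracle: minimum-norm least squares via explicit SVD on the blocks
    model = doc.to_stoichiometric_model()
    from .stoich import partition_stoichiometry

    part = partition_stoichiometry(model)
    b = -part.S_sd @ np.array([input_flux])
    v = _svd_lstsq(part.S_ss, b)
    static_solution = {
        "v_s_ids": list(part.v_s_ids),
        "v_d": {"r_in": float(input_flux)},
        "v_s": dict(zip(part.v_s_ids, v)),
        "residual": float(np.linalg.norm(part.S_ss @ v - b)),
    }
    return ToyNetwork(document=doc, seed=seed, static_solution=static_solution)


def make_overdetermined_static(
    n: int, m: int, seed: int = 0, max_retries: int = 20
) -> ToyNetwork:
    """Random static block with more species than reactions (n > m >= 1).

    Builds a network whose static module has an ``n x m`` random integer
    stoichiometry (no exact pseudo-steady solution in general) driven by a
    single dynamic input on every static species.  The descriptor carries
    the oracle minimiser (normal equations when full rank, else dense SVD)
    and its residual for a unit dynamic flux.
    """
    if not (n > m >= 1):
        raise ValueError("need n > m >= 1")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        S_ss = rng.integers(-2, 3, size=(n, m)).astype(float)
        if (S_ss != 0).any(axis=0).all() and (S_ss != 0).any(axis=1).all() \
                and np.linalg.matrix_rank(S_ss) >= 1:
            break
    else:  # pragma: no cover - vanishingly unlikely
        raise RuntimeError("could not draw a usable static block")
    s_sd = rng.integers(-2, 3, size=(n, 1)).astype(float)
    s_sd[s_sd == 0] = 1.0  # keep every species coupled to the input

    species = [MetaboliteSpec(f"x{i}", initial=1.0) for i in range(n)]
    reactions = [
        ReactionSpec(
            "drive", {f"x{i}": float(s_sd[i, 0]) for i in range(n)}, "dynamic",
            "dynamic drive", RateLaw("zero_order", {"rate": 1.0}),
        )
    ]
    for j in range(m):
        st = {f"x{i}": float(S_ss[i, j]) for i in range(n) if S_ss[i, j] != 0}
        reactions.append(ReactionSpec(f"st{j}", st, "static", f"static {j}"))
    doc = ModelDocument(species, reactions,
                        metadata={"seed": seed, "kind": "overdetermined_static"})
    assert validate_model(doc).ok

    b = -s_sd[:, 0]
    if np.linalg.matrix_rank(S_ss) == m:
        # normal equations oracle
        v = np.linalg.solve(S_ss.T @ S_ss, S_ss.T @ b)
    else:
        v = _svd_lstsq(S_ss, b)
    return ToyNetwork(
        document=doc,
        seed=seed,
        static_solution={
            "S_ss": S_ss,
            "S_sd": s_sd,
            "v_s": v,
            "residual": float(np.linalg.norm(S_ss @ v - b)),
        },
    )


def _svd_lstsq(A: np.ndarray, b: np.ndarray, rcond: float = 1e-12) -> np.ndarray:
    """Minimum-norm least squares via an explicit dense SVD (oracle path)."""
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    cutoff = rcond * (s[0] if s.size else 0.0)
    sinv = np.array([1.0 / x if x > cutoff else 0.0 for x in s])
    return Vt.T @ (sinv * (U.T @ b))
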