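"""Stoichiometric bookkeeping and the static-module least-squares flux solver.

The simulator splits a metabolic network ``dx/dt = S v`` into a *dynamic*
module (bottleneck reactions with explicit rate laws) and a *static* module
(fast reactions assumed at pseudo-steady state).  Species touched only by
dynamic reactions form ``x_d``; species touched by at least one static
reaction form ``x_s``.  Writing the corresponding blocks of ``S`` as
``S_dd`` (x_d rows, dynamic columns), ``S_sd`` (x_s rows, dynamic columns)
and ``S_ss`` (x_s rows, static columns), the pseudo-steady-state condition
``0 = S_sd v_d + S_ss v_s`` is generally over-determined.  The static fluxes
are therefore estimated as the minimum-norm least-squares solution

    v_s = -pinv(S_ss) @ S_sd @ v_d

which minimises ``||S_sd v_d + S_ss v_s||^2`` and, among all minimisers,
has the smallest Euclidean norm.  The residual of that fit is exactly the
rate of change of ``x_s``: it lives in the left null space of ``S_ss``, so
only metabolite pools with an unclosed static balance actually move.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DYNAMIC = "dynamic"
STATIC = "static"

#: relative singular-value cutoff used when forming the pseudo-inverse
DEFAULT_SVD_CUTOFF = 1e-10


class StoichiometryError(ValueError):
    """Raised for structurally invalid networks or inconsistent inputs."""


@dataclass(frozen=True)
class StoichiometricModel:
    """An ordered species/reaction network with module membership.

    Parameters
    ----------
    species_ids:
        Ordered metabolite identifiers (rows of ``S``).
    reaction_ids:
        Ordered reaction identifiers (columns of ``S``).
    S:
        Signed stoichiometric coefficient matrix, shape
        ``(len(species_ids), len(reaction_ids))``.
    dynamic_reactions:
        Subset of ``reaction_ids`` integrated kinetically; the complement is
        the static (pseudo-steady-state) module.
    """

    species_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    S: np.ndarray
    dynamic_reactions: frozenset[str]

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(
            self, "dynamic_reactions", frozenset(self.dynamic_reactions)
        )
        n, m = len(self.species_ids), len(self.reaction_ids)
        if len(set(self.species_ids)) != n:
            raise StoichiometryError("duplicate species ids")
        if len(set(self.reaction_ids)) != m:
            raise StoichiometryError("duplicate reaction ids")
        if S.shape != (n, m):
            raise StoichiometryError(
                f"S has shape {S.shape}, expected {(n, m)}"
            )
        unknown = self.dynamic_reactions - set(self.reaction_ids)
        if unknown:
            raise StoichiometryError(f"unknown dynamic reactions: {sorted(unknown)}")
        orphan = [
            sid for sid, row in zip(self.species_ids, S) if not row.any()
        ]
        if orphan:
            raise StoichiometryError(
                f"species touched by no reaction: {orphan}"
            )
        empty_cols = [
            rid for rid, col in zip(self.reaction_ids, S.T) if not col.any()
        ]
        if empty_cols:
            raise StoichiometryError(
                f"reactions with empty stoichiometry: {empty_cols}"
            )

    @property
    def static_reactions(self) -> frozenset[str]:
        return frozenset(self.reaction_ids) - self.dynamic_reactions

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)


@dataclass(frozen=True)
class FluxVector:
    """Reaction rates (mM/h) for one module, keyed by reaction id."""

    values: Mapping[str, float]
    module: str  # DYNAMIC or STATIC

    def __post_init__(self) -> None:
        if self.module not in (DYNAMIC, STATIC):
            raise StoichiometryError(f"unknown module tag {self.module!r}")
        vals = dict(self.values)
        if not all(np.isfinite(list(vals.values()) or [0.0])):
            bad = [k for k, v in vals.items() if not np.isfinite(v)]
            raise StoichiometryError(f"non-finite flux entries: {bad}")
        object.__setattr__(self, "values", vals)

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        if set(order) != set(self.values):
            raise StoichiometryError(
                "flux vector keys do not match requested reaction order"
            )
        return np.array([self.values[r] for r in order], dtype=float)


@dataclass(frozen=True)
class ModulePartition:
    """The S_dd / S_sd / S_ss blocks of a partitioned network.

    ``x_d_ids`` are species touched only by dynamic reactions; ``x_s_ids``
    are species touched by at least one static reaction.  Index maps give,
    for each partition position, the corresponding row/column of the parent
    model's ``S``.
    """

    x_d_ids: tuple[str, ...]
    x_s_ids: tuple[str, ...]
    v_d_ids: tuple[str, ...]
    v_s_ids: tuple[str, ...]
    S_dd: np.ndarray
    S_sd: np.ndarray
    S_ss: np.ndarray
    x_d_index: tuple[int, ...]  # rows of S for x_d
    x_s_index: tuple[int, ...]
    v_d_index: tuple[int, ...]  # columns of S for v_d
    v_s_index: tuple[int, ...]
    svd_cutoff: float = DEFAULT_SVD_CUTOFF
    # lazily-populated solver cache (pinv of S_ss); kept out of equality
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def pinv_S_ss(self) -> np.ndarray:
        """Moore-Penrose pseudo-inverse of S_ss (SVD, relative cutoff)."""
        if "pinv" not in self._cache:
            if self.S_ss.size:
                self._cache["pinv"] = np.linalg.pinv(
                    self.S_ss, rcond=self.svd_cutoff
                )
            else:
                self._cache["pinv"] = np.zeros(self.S_ss.shape[::-1])
        return self._cache["pinv"]

    @property
    def static_gain(self) -> np.ndarray:
        """Matrix ``M = -pinv(S_ss) @ S_sd`` mapping v_d to v_s."""
        if "gain" not in self._cache:
            if self.S_ss.size:
                self._cache["gain"] = -self.pinv_S_ss @ self.S_sd
            else:
                self._cache["gain"] = np.zeros(
                    (len(self.v_s_ids), len(self.v_d_ids))
                )
        return self._cache["gain"]

    @property
    def residual_gain(self) -> np.ndarray:
        """Matrix ``R = S_sd + S_ss M``: the x_s drift per unit v_d.

        ``R v_d`` is the least-squares residual of the pseudo-steady-state
        condition, i.e. the projection of ``S_sd v_d`` onto the left null
        space of ``S_ss``.
        """
        if "rgain" not in self._cache:
            if self.S_ss.size:
                self._cache["rgain"] = self.S_sd + self.S_ss @ self.static_gain
            else:
                self._cache["rgain"] = self.S_sd.copy()
        return self._cache["rgain"]

    def diagnostics(self) -> dict:
        """Rank/consistency diagnostics of the static module."""
        n_s, m_s = self.S_ss.shape
        rank = int(np.linalg.matrix_rank(self.S_ss)) if self.S_ss.size else 0
        return {
            "n_static_species": n_s,
            "n_static_reactions": m_s,
            "rank_S_ss": rank,
            "overdetermined": n_s > m_s,
            "left_null_dim": n_s - rank,
            "right_null_dim": m_s - rank,
        }


def partition_stoichiometry(
    model: StoichiometricModel, svd_cutoff: float = DEFAULT_SVD_CUTOFF
) -> ModulePartition:
    """Split ``S`` into the S_dd, S_sd, S_ss blocks.

    A species belongs to ``x_d`` iff every reaction with a non-zero
    coefficient on it is dynamic; otherwise it belongs to ``x_s``.  Model
    ordering is preserved within each block.  An empty static module yields
    a valid degenerate partition with empty S_sd/S_ss.
    """
    S = model.S
    dyn_cols = [
        j for j, r in enumerate(model.reaction_ids) if r in model.dynamic_reactions
    ]
    stat_cols = [
        j for j, r in enumerate(model.reaction_ids) if r not in model.dynamic_reactions
    ]
    touched_static = np.zeros(model.n_species, dtype=bool)
    if stat_cols:
        touched_static = (S[:, stat_cols] != 0).any(axis=1)
    x_d_rows = [i for i in range(model.n_species) if not touched_static[i]]
    x_s_rows = [i for i in range(model.n_species) if touched_static[i]]

    part = ModulePartition(
        x_d_ids=tuple(model.species_ids[i] for i in x_d_rows),
        x_s_ids=tuple(model.species_ids[i] for i in x_s_rows),
        v_d_ids=tuple(model.reaction_ids[j] for j in dyn_cols),
        v_s_ids=tuple(model.reaction_ids[j] for j in stat_cols),
        S_dd=S[np.ix_(x_d_rows, dyn_cols)] if x_d_rows and dyn_cols
        else np.zeros((len(x_d_rows), len(dyn_cols))),
        S_sd=S[np.ix_(x_s_rows, dyn_cols)] if x_s_rows and dyn_cols
        else np.zeros((len(x_s_rows), len(dyn_cols))),
        S_ss=S[np.ix_(x_s_rows, stat_cols)] if x_s_rows and stat_cols
        else np.zeros((len(x_s_rows), len(stat_cols))),
        x_d_index=tuple(x_d_rows),
        x_s_index=tuple(x_s_rows),
        v_d_index=tuple(dyn_cols),
        v_s_index=tuple(stat_cols),
        svd_cutoff=svd_cutoff,
    )
    diag = part.diagnostics()
    logger.debug("static module diagnostics: %s", diag)
    return part


def solve_static_fluxes(
    partition: ModulePartition, v_d: FluxVector | np.ndarray
) -> FluxVector:
    """Minimum-norm least-squares static fluxes for given dynamic fluxes.

    Returns the flux vector minimising ``||S_sd v_d + S_ss v_s||_2``; among
    minimisers the one of smallest norm (Moore-Penrose property).  The
    solution is unconstrained in sign: least-squares estimates of nominally
    irreversible static reactions may come out negative, which is logged as
    a diagnostic rather than rejected.
    """
    vd = _vd_array(partition, v_d)
    if not np.all(np.isfinite(vd)):
        raise StoichiometryError("non-finite entries in v_d")
    if not partition.v_s_ids:
        return FluxVector({}, STATIC)
    vs = partition.static_gain @ vd
    return FluxVector(dict(zip(partition.v_s_ids, vs)), STATIC)


def static_residual(
    partition: ModulePartition,
    v_d: FluxVector | np.ndarray,
    v_s: FluxVector | np.ndarray,
) -> float:
    """2-norm of the pseudo-steady-state violation ``S_sd v_d + S_ss v_s``."""
    vd = _vd_array(partition, v_d)
    if isinstance(v_s, FluxVector):
        vs = v_s.as_array(partition.v_s_ids)
    else:
        vs = np.asarray(v_s, dtype=float)
        if vs.shape != (len(partition.v_s_ids),):
            raise StoichiometryError("v_s has wrong length")
    if not partition.x_s_ids:
        return 0.0
    r = partition.S_sd @ vd
    if len(partition.v_s_ids):
        r = r + partition.S_ss @ vs
    return float(np.linalg.norm(r))


def _vd_array(partition: ModulePartition, v_d) -> np.ndarray:
    if isinstance(v_d, FluxVector):
        return v_d.as_array(partition.v_d_ids)
    vd = np.asarray(v_d, dtype=float)
    if vd.shape != (len(partition.v_d_ids),):
        raise StoichiometryError(
            f"v_d has length {vd.shape}, expected {len(partition.v_d_ids)}"
        )
    return vd
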