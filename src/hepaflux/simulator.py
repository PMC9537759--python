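"""Hybrid time-evolution engine: ODE kinetics + per-step static flux solve.

At every integrator stage the dynamic fluxes ``v_d`` are evaluated from the
current state and boundary values; the static fluxes are the minimum-norm
least-squares solution ``v_s = -pinv(S_ss) S_sd v_d`` of the pseudo-steady
state condition.  The state then advances as

    dx_d/dt = S_dd v_d
    dx_s/dt = S_sd v_d + S_ss v_s

The second row equals the projection of ``S_sd v_d`` onto the left null
space of ``S_ss``: static-module species only move along directions whose
balance the fast reactions cannot close (e.g. buffer pools with no static
drain), and the imbalance is shared equally over the members of such a
pool - the defining behaviour of the pseudo-inverse estimate.

The integrator is a fixed-step explicit Runge-Kutta (RK4) scheme;
boundary-schedule breakpoints are hit exactly by restarting the integration
at each breakpoint.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .document import ModelDocument
from .ratelaws import Modifier, RateLaw, apply_zone
from .stoich import partition_stoichiometry

logger = logging.getLogger(__name__)

#: default integrator step (h); chosen well inside the stability limit of
#: the fastest kinetic time scales of the reference model (~1/200 h)
DEFAULT_STEP = 1e-3
MIN_STEP = 1e-6
#: largest tolerated single-step negative excursion before abort (mM)
DEFAULT_CLAMP_TOL = 0.05


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class PiecewiseConstant:
    """Right-continuous piecewise-constant schedule: value_i holds on
    [t_i, t_{i+1});  times must start at 0 and be strictly increasing."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.times)
        v = tuple(float(x) for x in self.values)
        if len(t) != len(v) or not t or t[0] != 0.0:
            raise ValueError("schedule needs matching times/values with times[0]=0")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("schedule breakpoints must be strictly increasing")
        if any(x < 0 for x in v):
            raise ValueError("schedule values must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @classmethod
    def constant(cls, value: float) -> "PiecewiseConstant":
        return cls((0.0,), (float(value),))

    def at(self, t: float) -> float:
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return self.values[max(idx, 0)]

    def breakpoints(self) -> tuple[float, ...]:
        return self.times[1:]


def _as_schedule(x) -> PiecewiseConstant:
    if isinstance(x, PiecewiseConstant):
        return x
    return PiecewiseConstant.constant(float(x))


@dataclass(frozen=True)
class BoundaryConditions:
    """Blood-side boundary values and the APAP dosing schedule.

    The organism outside the liver is assumed unchanged during simulation:
    boundary species are held at their scheduled values, never consumed.
    """

    external_glucose: PiecewiseConstant | float = 5.0
    external_lactate: float = 1.0
    apap_administration: PiecewiseConstant | float = 0.0
    external_cysteine: float = 0.2
    glucose_species: str = "glc_ext"
    lactate_species: str = "lac_ext"
    cysteine_species: str = "cys_ext"
    dosing_reaction: str = "v_APAP_in"

    def __post_init__(self) -> None:
        object.__setattr__(self, "external_glucose", _as_schedule(self.external_glucose))
        object.__setattr__(self, "apap_administration", _as_schedule(self.apap_administration))
        if self.external_lactate < 0 or self.external_cysteine < 0:
            raise ValueError("boundary concentrations must be >= 0")

    @classmethod
    def feeding_fasting(
        cls,
        switch_time: float,
        feeding_glucose: float = 11.0,
        fasting_glucose: float = 4.0,
        **kw,
    ) -> "BoundaryConditions":
        """Feeding state from 0 to ``switch_time`` h, fasting afterwards."""
        sched = PiecewiseConstant((0.0, switch_time), (feeding_glucose, fasting_glucose))
        return cls(external_glucose=sched, **kw)

    def breakpoints(self, horizon: float) -> list[float]:
        pts = set(self.external_glucose.breakpoints())
        pts |= set(self.apap_administration.breakpoints())
        return sorted(p for p in pts if 0.0 < p < horizon)


@dataclass
class SimulationResult:
    """Recorded trajectories of a hybrid simulation."""

    time: np.ndarray
    species_ids: list[str]
    concentrations: np.ndarray  # time x species (mM)
    v_d_ids: list[str]
    dynamic_fluxes: np.ndarray  # time x |v_d| (mM/h)
    v_s_ids: list[str]
    static_fluxes: np.ndarray  # time x |v_s| (mM/h)
    residual_trace: np.ndarray
    x_d_ids: list[str] = field(default_factory=list)
    x_s_ids: list[str] = field(default_factory=list)
    zone: str = ""
    clamped_mass: float = 0.0

    def species(self, sid: str) -> np.ndarray:
        return self.concentrations[:, self.species_ids.index(sid)]

    def flux(self, rid: str) -> np.ndarray:
        if rid in self.v_d_ids:
            return self.dynamic_fluxes[:, self.v_d_ids.index(rid)]
        return self.static_fluxes[:, self.v_s_ids.index(rid)]

    def final_state(self) -> dict[str, float]:
        return dict(zip(self.species_ids, self.concentrations[-1]))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time}
        for i, s in enumerate(self.species_ids):
            cols[s] = self.concentrations[:, i]
        for i, r in enumerate(self.v_d_ids):
            cols[r] = self.dynamic_fluxes[:, i]
        for i, r in enumerate(self.v_s_ids):
            cols[r] = self.static_fluxes[:, i]
        cols["static_residual"] = self.residual_trace
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        return {
            "zone": self.zone,
            "horizon": float(self.time[-1]),
            "n_points": int(len(self.time)),
            "max_static_residual": float(np.max(self.residual_trace)),
            "clamped_mass": float(self.clamped_mass),
            "final_state": {k: float(v) for k, v in self.final_state().items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))


# ---------------------------------------------------------------------------
# compilation of a document into fast evaluation closures


class CompiledModel:
    """A document + zone profile compiled for repeated rate evaluation."""

    def __init__(self, doc: ModelDocument, zone: str | None = None,
                 svd_cutoff: float = 1e-10):
        self.doc = doc
        self.zone = zone or ""
        self.model = doc.to_stoichiometric_model()
        self.partition = partition_stoichiometry(self.model, svd_cutoff=svd_cutoff)
        self.species_ids = list(self.model.species_ids)
        self.index = {s: i for i, s in enumerate(self.species_ids)}
        self.boundary_ids = list(doc.boundary_ids)

        profile = doc.zone_profile(zone) if zone else None
        self.laws: dict[str, RateLaw] = {}
        for rid in self.partition.v_d_ids:
            law = doc.reaction(rid).rate_law
            assert law is not None
            if profile is not None:
                law = apply_zone(law, profile, rid)
            self.laws[rid] = law
        self._funcs = [
            _compile_law(self.laws[rid], self.index)
            for rid in self.partition.v_d_ids
        ]
        self._dose_index: dict[str, int] = {
            rid: i
            for i, rid in enumerate(self.partition.v_d_ids)
            if self.laws[rid].form == "zero_order"
        }

    def v_d(self, x: np.ndarray, bvals: Mapping[str, float],
            dose_rates: Mapping[str, float] | None = None) -> np.ndarray:
        out = np.empty(len(self._funcs))
        for i, f in enumerate(self._funcs):
            out[i] = f(x, bvals)
        if dose_rates:
            for rid, rate in dose_rates.items():
                j = self._dose_index.get(rid)
                if j is None:
                    raise SimulationError(
                        f"dosing reaction {rid!r} is not a zero_order dynamic reaction"
                    )
                out[j] = rate
        return out


def _compile_law(law: RateLaw, index: Mapping[str, int]) -> Callable:
    """Build a closure evaluating one rate law on (state_vector, boundary_map).

    Non-boundary species are read from the state vector by index; boundary
    species from the mapping.  Negative state entries (transient integrator
    excursions) are clamped to 0 inside the closure.
    """

    def getter(sp: str) -> Callable:
        if sp in index:
            i = index[sp]
            return lambda x, b: x[i] if x[i] > 0.0 else 0.0
        return lambda x, b: b[sp]

    p = dict(law.parameters)
    mods = [(getter(m.species), m) for m in law.modifiers]

    def modfactor(x, b) -> float:
        f = 1.0
        for g, m in mods:
            f *= m.factor(g(x, b))
        return f

    if law.form == "zero_order":
        rate = p["rate"]
        if mods:
            return lambda x, b: rate * modfactor(x, b)
        return lambda x, b: rate

    if law.form == "mass_action":
        k = p["k"]
        gs = [getter(s) for s in law.substrates]
        if mods:
            def f(x, b, k=k, gs=gs):
                v = k
                for g in gs:
                    v *= g(x, b)
                return v * modfactor(x, b)
            return f

        def f(x, b, k=k, gs=gs):
            v = k
            for g in gs:
                v *= g(x, b)
            return v
        return f

    if law.form in ("michaelis_menten", "inhibited_mm"):
        vmax = p["Vmax"]
        terms = [(getter(s), law.km(s)) for s in law.substrates]
        kis = [(getter(name[3:]), ki) for name, ki in p.items() if name.startswith("Ki_")]

        def f(x, b, vmax=vmax, terms=terms, kis=kis):
            v = vmax
            for g, km in terms:
                c = g(x, b)
                v *= c / (km + c)
            for g, ki in kis:
                v /= 1.0 + g(x, b) / ki
            return v * modfactor(x, b) if mods else v
        return f

    if law.form == "hill":
        vmax, n = p["Vmax"], p.get("n", 1.0)
        s50n = (p.get("S50", p.get("Km"))) ** n
        g = getter(law.substrates[0])

        def f(x, b, vmax=vmax, n=n, s50n=s50n, g=g):
            c = g(x, b) ** n
            v = vmax * c / (s50n + c)
            return v * modfactor(x, b) if mods else v
        return f

    if law.form == "reversible_michaelis_menten":
        vmax, keq = p["Vmax"], p.get("keq", 1.0)
        subs = [(getter(s), law.km(s)) for s in law.substrates]
        prods = [(getter(s), law.km(s)) for s in law.products]

        def f(x, b, vmax=vmax, keq=keq, subs=subs, prods=prods):
            fwd, den_s = 1.0, 1.0
            for g, km in subs:
                r = g(x, b) / km
                fwd *= r
                den_s *= 1.0 + r
            rev, den_p = 1.0 / keq, 1.0
            for g, km in prods:
                r = g(x, b) / km
                rev *= r
                den_p *= 1.0 + r
            v = vmax * (fwd - rev) / (den_s + den_p - 1.0)
            return v * modfactor(x, b) if mods else v
        return f

    raise SimulationError(f"cannot compile form {law.form!r}")


# ---------------------------------------------------------------------------
# integration


def simulate(
    doc: ModelDocument,
    zone: str | None = None,
    boundary: BoundaryConditions | None = None,
    horizon: float = 5.0,
    step: float = DEFAULT_STEP,
    initial_state: Mapping[str, float] | None = None,
    record_interval: float | None = None,
    clamp_tolerance: float = DEFAULT_CLAMP_TOL,
    svd_cutoff: float = 1e-10,
    compiled: CompiledModel | None = None,
) -> SimulationResult:
    """Run the hybrid simulation over ``[0, horizon]`` hours.

    Boundary species follow the schedules in ``boundary`` (others stay at
    their document initial values); schedule breakpoints are hit exactly.
    Concentrations are clamped to 0 after each step; a single-step
    excursion below ``-clamp_tolerance`` aborts with a diagnostic, and the
    total clamped mass is reported in the result.
    """
    if step < MIN_STEP:
        raise SimulationError(f"step {step} below minimum {MIN_STEP}")
    if horizon < 0:
        raise SimulationError("horizon must be >= 0")

    cm = compiled if compiled is not None else CompiledModel(doc, zone, svd_cutoff)
    part = cm.partition
    state0 = doc.initial_state()
    if initial_state:
        state0.update(initial_state)
    x = np.array([max(state0[s], 0.0) for s in cm.species_ids])

    bvals = {s: state0[s] for s in cm.boundary_ids}
    dose_rates: dict[str, float] = {}

    def set_boundary(t: float) -> None:
        if boundary is None:
            return
        if boundary.glucose_species in bvals:
            bvals[boundary.glucose_species] = boundary.external_glucose.at(t)
        if boundary.lactate_species in bvals:
            bvals[boundary.lactate_species] = boundary.external_lactate
        if boundary.cysteine_species in bvals:
            bvals[boundary.cysteine_species] = boundary.external_cysteine
        if boundary.dosing_reaction in cm._dose_index:
            dose_rates[boundary.dosing_reaction] = boundary.apap_administration.at(t)

    S_dd, x_d_idx = part.S_dd, np.array(part.x_d_index, dtype=int)
    R, x_s_idx = part.residual_gain, np.array(part.x_s_index, dtype=int)
    n = len(cm.species_ids)

    def rhs(xv: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        vd = cm.v_d(xv, bvals, dose_rates)
        dx = np.zeros(n)
        if x_d_idx.size:
            dx[x_d_idx] = S_dd @ vd
        if x_s_idx.size:
            dx[x_s_idx] = R @ vd
        return dx, vd

    # output recording
    if record_interval is None:
        record_interval = max(step, horizon / 2000.0 if horizon > 0 else step)
    rec_t, rec_x, rec_vd, rec_vs, rec_res = [], [], [], [], []
    clamped_total = 0.0

    boundary_ids = list(cm.boundary_ids)

    def record(t: float) -> None:
        vd = cm.v_d(x, bvals, dose_rates)
        vs = part.static_gain @ vd if len(part.v_s_ids) else np.zeros(0)
        res = R @ vd if x_s_idx.size else np.zeros(0)
        rec_t.append(t)
        rec_x.append(np.concatenate([x, [bvals[s] for s in boundary_ids]]))
        rec_vd.append(vd)
        rec_vs.append(vs)
        rec_res.append(float(np.linalg.norm(res)))

    segments = [0.0] + (boundary.breakpoints(horizon) if boundary else []) + [horizon]
    t = 0.0
    set_boundary(0.0)
    record(0.0)
    next_record = record_interval

    for seg_start, seg_end in zip(segments, segments[1:]):
        set_boundary(seg_start)
        t = seg_start
        while t < seg_end - 1e-12:
            h = min(step, seg_end - t)
            if h < MIN_STEP:
                break
            k1, _ = rhs(x)
            k2, _ = rhs(x + 0.5 * h * k1)
            k3, _ = rhs(x + 0.5 * h * k2)
            k4, _ = rhs(x + h * k3)
            x_new = x + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            worst = float(x_new.min()) if x_new.size else 0.0
            if worst < -clamp_tolerance:
                sid = cm.species_ids[int(np.argmin(x_new))]
                raise SimulationError(
                    f"negative concentration beyond clamp tolerance at t={t + h:.4f} h: "
                    f"{sid} = {worst:.4g} mM"
                )
            neg = x_new < 0.0
            if neg.any():
                clamped_total += float(-x_new[neg].sum())
                x_new[neg] = 0.0
            if not np.all(np.isfinite(x_new)):
                raise SimulationError(f"non-finite state at t={t + h:.4f} h")
            x = x_new
            t += h
            if abs(t - seg_end) < 1e-9:
                t = seg_end
            if t >= next_record - 1e-12:
                record(t)
                next_record += record_interval
        # make sure the breakpoint state itself is recorded
        if not rec_t or abs(rec_t[-1] - t) > 1e-12:
            record(t)
            next_record = t + record_interval

    return SimulationResult(
        time=np.array(rec_t),
        species_ids=list(cm.species_ids) + boundary_ids,
        concentrations=np.array(rec_x),
        v_d_ids=list(part.v_d_ids),
        dynamic_fluxes=np.array(rec_vd),
        v_s_ids=list(part.v_s_ids),
        static_fluxes=np.array(rec_vs) if len(part.v_s_ids) else np.zeros((len(rec_t), 0)),
        residual_trace=np.array(rec_res),
        x_d_ids=list(part.x_d_ids),
        x_s_ids=list(part.x_s_ids),
        zone=cm.zone,
        clamped_mass=clamped_total,
    )


def glucose_exchange_sweep(
    doc: ModelDocument,
    zones: Sequence[str],
    glucose_values: Sequence[float],
    lactate: float = 1.0,
    window: float = 15.0,
    step: float = 2e-3,
    transporter: str = "v_GLUT2",
    rel_tol: float = 0.05,
) -> dict[str, list[tuple[float, float, bool]]]:
    """Steady glucose-transporter flux vs external glucose, per zone.

    For each zone and glucose value the model is equilibrated for ``window``
    hours (no APAP, lactate fixed); the reported exchange rate is the
    transporter flux at the end of the window (positive = uptake, negative =
    export).  An entry is flagged unconverged when the flux still changes by
    more than ``rel_tol`` (relative) over the last fifth of the window.
    """
    out: dict[str, list[tuple[float, float, bool]]] = {}
    for zone in zones:
        cm = CompiledModel(doc, zone)
        rows = []
        for g in glucose_values:
            if g < 0:
                raise ValueError("glucose values must be >= 0")
            bc = BoundaryConditions(
                external_glucose=g, external_lactate=lactate, apap_administration=0.0
            )
            res = simulate(
                doc, zone, bc, horizon=window, step=step,
                record_interval=window / 50.0, compiled=cm,
            )
            fl = res.flux(transporter)
            tail = fl[res.time >= 0.8 * window]
            rate = float(fl[-1])
            # absolute floor: near the uptake/export crossover the rate is
            # tiny but still drifts with the (slow) glycogen reservoir
            scale = max(abs(rate), 1.0)
            converged = bool(np.max(np.abs(tail - rate)) <= rel_tol * scale)
            if not converged:
                logger.warning(
                    "sweep not converged: zone=%s glucose=%.3g rate=%.4g", zone, g, rate
                )
            rows.append((float(g), rate, converged))
        out[zone] = rows
    return out


def equilibrate(
    doc: ModelDocument,
    zone: str | None,
    boundary: BoundaryConditions,
    run_in: float = 10.0,
    step: float = DEFAULT_STEP,
    compiled: CompiledModel | None = None,
) -> dict[str, float]:
    """Pre-equilibration run-in (no dosing changes applied beyond ``boundary``);
    returns the final state for use as an initial condition."""
    res = simulate(
        doc, zone, boundary, horizon=run_in, step=step,
        record_interval=run_in / 10.0 if run_in > 0 else None, compiled=compiled,
    )
    return res.final_state()
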