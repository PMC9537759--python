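"""Scenario protocols, APAP-pathway contribution accounting and presets.

A contribution run doses APAP at a constant rate for the first 30 min and
integrates the four elimination fluxes (glucuronidation, sulfation, GSH
conjugation of NAPQI, protein-adduct formation) over a 5 h window; the
report expresses each integral as a percentage of their sum.  The CYP2E1
oxidation flux itself is not a column: it splits downstream into the GSH
conjugate and the adduct, which are reported separately, so the four
columns close to 100%.

Perturbation presets rescale Vmax values of glucose-metabolism enzymes:

* ``obese`` - PEPCK and ER glucose-6-phosphatase x1.5 (both zones);
* ``infant`` - glycogen synthase up (x2.0), PEPCK (x0.5) and glycogen
  phosphorylase (x0.3) down.  Only the directions are established
  physiology; the magnitudes are calibration knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .document import DocumentError, ModelDocument
from .liver import (
    APAP_DURATION,
    DOSING_REACTION,
    FASTING_GLUCOSE,
    FEEDING_GLUCOSE,
    PATHWAY_FLUXES,
)
from .simulator import (
    BoundaryConditions,
    CompiledModel,
    PiecewiseConstant,
    SimulationResult,
    simulate,
)

GLUCOSE_STATES = {"fasting": FASTING_GLUCOSE, "feeding": FEEDING_GLUCOSE}

#: default integration window for contribution accounting (h)
CONTRIBUTION_WINDOW = 5.0
#: run-in used to settle the glucose side before dosing (h)
DEFAULT_RUN_IN = 10.0


@dataclass(frozen=True)
class Scenario:
    """One dosing/nutrition/zone condition."""

    glucose: str | float = "fasting"  # "fasting" | "feeding" | explicit mM
    apap_rate: float = 0.5  # mM/h for the dosing window
    apap_duration: float = APAP_DURATION
    zone: str = "periportal"
    horizon: float = CONTRIBUTION_WINDOW

    def __post_init__(self) -> None:
        if self.apap_rate < 0:
            raise ValueError("apap rate must be >= 0")
        if self.apap_rate > 0 and self.horizon <= self.apap_duration:
            raise ValueError("horizon must exceed the dosing window")

    @property
    def glucose_mM(self) -> float:
        if isinstance(self.glucose, str):
            return GLUCOSE_STATES[self.glucose]
        return float(self.glucose)

    @property
    def glucose_label(self) -> str:
        return self.glucose if isinstance(self.glucose, str) else f"{self.glucose:g} mM"

    def boundary(self) -> BoundaryConditions:
        if self.apap_rate > 0:
            dosing = PiecewiseConstant((0.0, self.apap_duration), (self.apap_rate, 0.0))
        else:
            dosing = PiecewiseConstant.constant(0.0)
        return BoundaryConditions(
            external_glucose=self.glucose_mM, apap_administration=dosing
        )


@dataclass(frozen=True)
class ContributionReport:
    """Integrated APAP-pathway fluxes (mM over the window) and their shares."""

    scenario: Scenario
    integrals: Mapping[str, float]  # pathway name -> mM
    window: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "integrals", dict(self.integrals))

    @property
    def total(self) -> float:
        return float(sum(self.integrals.values()))

    @property
    def no_apap(self) -> bool:
        """Flagged when no APAP was metabolised: percentages are undefined."""
        return self.total <= 0.0

    @property
    def percentages(self) -> dict[str, float]:
        if self.no_apap:
            raise ValueError("no APAP metabolism in this run: percentages undefined")
        t = self.total
        return {k: 100.0 * v / t for k, v in self.integrals.items()}

    def row(self) -> dict:
        pct = {f"{k}_pct": np.nan for k in self.integrals} if self.no_apap else {
            f"{k}_pct": round(v, 1) for k, v in self.percentages.items()
        }
        return {
            "apap_rate": self.scenario.apap_rate,
            "glucose": self.scenario.glucose_mM,
            "zone": self.scenario.zone,
            **pct,
            "total_mM": self.total,
            "no_apap": self.no_apap,
        }


def compute_contributions(
    result: SimulationResult,
    window: float = CONTRIBUTION_WINDOW,
    scenario: Scenario | None = None,
    pathways: Mapping[str, str] = PATHWAY_FLUXES,
) -> ContributionReport:
    """Trapezoidal integrals of the pathway fluxes over ``[0, window]``.

    The simulation must cover the window and expose each pathway flux.
    """
    if result.time[-1] < window - 1e-9:
        raise ValueError(
            f"result covers only {result.time[-1]:.3g} h, window is {window} h"
        )
    mask = result.time <= window + 1e-12
    t = result.time[mask]
    integrals = {}
    for name, rid in pathways.items():
        flux = result.flux(rid)[mask]
        integrals[name] = float(np.trapezoid(np.clip(flux, 0.0, None), t))
    sc = scenario if scenario is not None else Scenario(
        glucose=5.0, apap_rate=0.0, zone=result.zone or "periportal",
        horizon=float(result.time[-1]),
    )
    return ContributionReport(scenario=sc, integrals=integrals, window=window)


@dataclass(frozen=True)
class PerturbationPreset:
    """Multiplicative Vmax factors applied to named enzymes."""

    name: str
    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("preset factors must be > 0")
        object.__setattr__(self, "factors", dict(self.factors))


PRESETS: dict[str, PerturbationPreset] = {
    "healthy_adult": PerturbationPreset("healthy_adult", {}),
    "obese": PerturbationPreset("obese", {"v_PEPCK": 1.5, "v_G6P_ER": 1.5}),
    "infant": PerturbationPreset(
        "infant", {"v_GS": 2.0, "v_PEPCK": 0.5, "v_GP": 0.3}
    ),
}


def apply_preset(doc: ModelDocument, preset: PerturbationPreset | str) -> ModelDocument:
    """Return a copy of the document with the preset's Vmax factors applied
    (base parameters and every zone override)."""
    if isinstance(preset, str):
        try:
            preset = PRESETS[preset]
        except KeyError:
            raise DocumentError(f"unknown preset {preset!r}") from None
    out = doc.copy()
    for rid, factor in preset.factors.items():
        try:
            out.reaction(rid)
        except KeyError:
            raise DocumentError(f"preset enzyme {rid!r} not in model") from None
        out.scale_vmax(rid, factor)
    out.metadata = {**out.metadata, "preset": preset.name}
    return out


def run_scenario(
    doc: ModelDocument,
    scenario: Scenario,
    step: float = 1e-3,
    run_in: float = DEFAULT_RUN_IN,
    compiled: CompiledModel | None = None,
) -> tuple[SimulationResult, ContributionReport]:
    """Equilibrate the glucose side at the scenario's nutritional state,
    then dose and integrate the contribution window."""
    cm = compiled if compiled is not None else CompiledModel(doc, scenario.zone)
    bc_eq = BoundaryConditions(external_glucose=scenario.glucose_mM)
    init = None
    if run_in > 0:
        eq = simulate(doc, scenario.zone, bc_eq, horizon=run_in, step=step,
                      record_interval=run_in / 10.0, compiled=cm)
        init = eq.final_state()
    res = simulate(
        doc, scenario.zone, scenario.boundary(), horizon=scenario.horizon,
        step=step, initial_state=init,
        record_interval=min(0.01, scenario.horizon / 100) if scenario.horizon > 0 else None,
        compiled=cm,
    )
    report = compute_contributions(res, min(CONTRIBUTION_WINDOW, scenario.horizon),
                                   scenario)
    return res, report


def standard_grid(
    doses: Sequence[float] = (0.5, 6.0),
    glucose_states: Sequence[str] = ("fasting", "feeding"),
    zones: Sequence[str] = ("periportal", "pericentral"),
) -> list[Scenario]:
    """The published 2 doses x 2 glucose states x 2 zones scenario grid."""
    return [
        Scenario(glucose=g, apap_rate=d, zone=z)
        for d in doses
        for g in glucose_states
        for z in zones
    ]


def run_table(
    doc: ModelDocument,
    presets: Iterable[PerturbationPreset | str] = ("healthy_adult",),
    scenarios: Sequence[Scenario] | None = None,
    step: float = 1e-3,
    run_in: float = DEFAULT_RUN_IN,
) -> pd.DataFrame:
    """Contribution table (one row per preset x scenario).

    Columns mirror the published layout: dose, glucose, zone, then the
    glucuronidation / sulfation / GSH-conjugation / protein-adduct
    percentages.
    """
    if scenarios is None:
        scenarios = standard_grid()
    rows = []
    for preset in presets:
        pdoc = apply_preset(doc, preset)
        pname = pdoc.metadata["preset"]
        compiled: dict[str, CompiledModel] = {}
        for sc in scenarios:
            cm = compiled.get(sc.zone)
            if cm is None:
                cm = compiled[sc.zone] = CompiledModel(pdoc, sc.zone)
            _, rep = run_scenario(pdoc, sc, step=step, run_in=run_in, compiled=cm)
            rows.append({"preset": pname, **rep.row()})
    return pd.DataFrame(rows)
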