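"""Kinetic rate-law forms for dynamic-module reactions.

Units are fixed model-wide: concentrations in mM, time in hours, rates in
mM/h.  Supported forms:

``mass_action``
    ``k * prod(substrates)`` (first order in each substrate).
``michaelis_menten``
    ``Vmax * prod_i S_i/(Km_i + S_i)`` - irreversible, one Km per substrate.
``reversible_michaelis_menten``
    Convenience-kinetics form
    ``Vmax * (prod_i S_i/Km_i - (1/keq) prod_j P_j/Km_j) / (prod_i (1+S_i/Km_i)
    + prod_j (1+P_j/Km_j) - 1)``; net rate is zero when the mass-action
    ratio (scaled by the Km's) equals ``keq``.
``hill``
    ``Vmax * S^n / (S50^n + S^n)`` - single substrate, cooperativity n >= 1.
``inhibited_mm``
    Irreversible MM divided by ``(1 + I/Ki)`` for the declared inhibitor.
``zero_order``
    Constant influx ``rate`` (mM/h); used for dosing schedules.

Allosteric regulation is expressed through *modifiers*: multiplicative
factors on Vmax (activation ``1 + a*M/(Ka+M)``, inhibition ``1/(1+M/Ki)``),
keeping the zonation override mechanism (Vmax only) orthogonal to
regulation.  Zonation itself is a per-zone map of Vmax-class overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import math

FORMS = (
    "mass_action",
    "michaelis_menten",
    "reversible_michaelis_menten",
    "hill",
    "inhibited_mm",
    "zero_order",
)

ZONES = ("periportal", "intermediate", "pericentral")

#: parameters that zone profiles are allowed to override (activity scaling)
VMAX_CLASS = ("Vmax", "k", "rate")


class RateLawError(ValueError):
    """Invalid rate-law definition or evaluation input."""


@dataclass(frozen=True)
class Modifier:
    """Allosteric effector acting as a multiplicative factor on Vmax.

    ``activation``: ``1 + a*M/(Ka+M)``;
    ``activation_hill``: ``1 + a*M^n/(Ka^n+M^n)`` (switch-like response);
    ``inhibition``: ``1/(1+M/Ki)``.
    """

    species: str
    kind: str  # "activation" | "activation_hill" | "inhibition"
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("activation", "activation_hill", "inhibition"):
            raise RateLawError(f"unknown modifier kind {self.kind!r}")
        object.__setattr__(self, "params", dict(self.params))

    def factor(self, conc: float) -> float:
        if self.kind == "activation":
            a = self.params.get("a", 1.0)
            ka = self.params["Ka"]
            return 1.0 + a * conc / (ka + conc)
        if self.kind == "activation_hill":
            a = self.params.get("a", 1.0)
            n = self.params.get("n", 2.0)
            cn = conc**n
            return 1.0 + a * cn / (self.params["Ka"] ** n + cn)
        ki = self.params["Ki"]
        return 1.0 / (1.0 + conc / ki)


@dataclass(frozen=True)
class RateLaw:
    """One kinetic rate equation.

    ``substrates``/``products`` reference species ids; per-species Km's are
    stored as ``Km_<species>`` entries in ``parameters`` (a bare ``Km`` is
    accepted for single-substrate irreversible forms).
    """

    form: str
    parameters: Mapping[str, float]
    substrates: tuple[str, ...] = ()
    products: tuple[str, ...] = ()
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        if self.form not in FORMS:
            raise RateLawError(f"unknown rate-law form {self.form!r}")
        params = dict(self.parameters)
        object.__setattr__(self, "parameters", params)
        object.__setattr__(self, "substrates", tuple(self.substrates))
        object.__setattr__(self, "products", tuple(self.products))
        object.__setattr__(self, "modifiers", tuple(self.modifiers))
        for name, value in params.items():
            if name.startswith(("Km", "Ki", "Ka")) or name in ("Vmax", "S50"):
                if value <= 0:
                    raise RateLawError(f"{name} must be > 0 (got {value})")
            if name == "n" and value < 1:
                raise RateLawError(f"Hill coefficient must be >= 1 (got {value})")
        if self.form == "zero_order":
            if params.get("rate", 0.0) < 0:
                raise RateLawError("zero_order rate must be >= 0")
        elif self.form in ("hill",) and len(self.substrates) != 1:
            raise RateLawError("hill form takes exactly one substrate")
        elif not self.substrates and self.form != "zero_order":
            raise RateLawError(f"{self.form} requires at least one substrate")

    # -- parameter helpers -------------------------------------------------
    def km(self, species: str, side: str = "S") -> float:
        p = self.parameters
        if f"Km_{species}" in p:
            return p[f"Km_{species}"]
        if "Km" in p:
            return p["Km"]
        raise RateLawError(f"no Km for species {species!r}")

    def with_parameters(self, **updates: float) -> "RateLaw":
        unknown = set(updates) - set(self.parameters)
        if unknown:
            raise RateLawError(f"unknown parameters {sorted(unknown)}")
        params = {**self.parameters, **updates}
        return replace(self, parameters=params)


def evaluate_rate(law: RateLaw, concentrations: Mapping[str, float]) -> float:
    """Evaluate one rate law at the given concentrations (mM) -> mM/h.

    Missing species and negative concentrations are rejected by name.
    Irreversible forms return values >= 0; the pure function returns
    bit-identical outputs for equal inputs.
    """
    needed = set(law.substrates) | set(law.products) | {
        m.species for m in law.modifiers
    }
    for sp in needed:
        if sp not in concentrations:
            raise RateLawError(f"missing species {sp!r} in concentration map")
        c = concentrations[sp]
        if not math.isfinite(c) or c < 0:
            raise RateLawError(
                f"invalid concentration for species {sp!r}: {c}"
            )
    return _evaluate(law, concentrations)


def _evaluate(law: RateLaw, conc: Mapping[str, float]) -> float:
    p = law.parameters
    if law.form == "zero_order":
        base = p["rate"]
    elif law.form == "mass_action":
        base = p["k"]
        for s in law.substrates:
            base *= conc[s]
    elif law.form == "michaelis_menten":
        base = p["Vmax"]
        for s in law.substrates:
            cs = conc[s]
            base *= cs / (law.km(s) + cs)
    elif law.form == "inhibited_mm":
        base = p["Vmax"]
        for s in law.substrates:
            cs = conc[s]
            base *= cs / (law.km(s) + cs)
        inhibitor = law.products[0] if law.products else None
        # inhibitor declared via Ki_<species> naming
        for name, ki in p.items():
            if name.startswith("Ki_"):
                base /= 1.0 + conc[name[3:]] / ki
    elif law.form == "hill":
        s = law.substrates[0]
        n = p.get("n", 1.0)
        s50 = p.get("S50", p.get("Km"))
        cs = conc[s]
        num = cs**n
        base = p["Vmax"] * num / (s50**n + num)
    elif law.form == "reversible_michaelis_menten":
        keq = p.get("keq", 1.0)
        fwd = 1.0
        den_s = 1.0
        for s in law.substrates:
            r = conc[s] / law.km(s)
            fwd *= r
            den_s *= 1.0 + r
        rev = 1.0 / keq
        den_p = 1.0
        for q in law.products:
            r = conc[q] / law.km(q)
            rev *= r
            den_p *= 1.0 + r
        base = p["Vmax"] * (fwd - rev) / (den_s + den_p - 1.0)
    else:  # pragma: no cover - guarded in __post_init__
        raise RateLawError(f"unknown form {law.form!r}")
    for mod in law.modifiers:
        base *= mod.factor(conc[mod.species])
    return base


@dataclass(frozen=True)
class ZoneProfile:
    """Per-zone Vmax-class parameter overrides.

    Zonation is modelled purely as enzyme-activity (Vmax) differences along
    the periportal-pericentral axis; ``overrides`` maps
    ``(reaction_id, parameter_name) -> value``.
    """

    zone_id: str
    overrides: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.zone_id not in ZONES:
            raise RateLawError(f"unknown zone {self.zone_id!r}")
        ov = dict(self.overrides)
        for (rid, pname), value in ov.items():
            if pname not in VMAX_CLASS:
                raise RateLawError(
                    f"zone override on {rid}:{pname} - only Vmax-class "
                    f"parameters {VMAX_CLASS} may be zonated"
                )
            if value <= 0:
                raise RateLawError(f"zone override {rid}:{pname} must be > 0")
        object.__setattr__(self, "overrides", ov)


def apply_zone(law: RateLaw, profile: ZoneProfile, reaction_id: str) -> RateLaw:
    """Return a copy of ``law`` with the profile's overrides for this reaction.

    Parameters not named in the profile are unchanged; an override naming a
    parameter the law does not have is rejected.
    """
    updates = {
        pname: value
        for (rid, pname), value in profile.overrides.items()
        if rid == reaction_id
    }
    if not updates:
        return law
    unknown = set(updates) - set(law.parameters)
    if unknown:
        raise RateLawError(
            f"zone override for {reaction_id} targets unknown parameter(s) "
            f"{sorted(unknown)}"
        )
    return law.with_parameters(**updates)
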