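"""Declarative model documents: species, reactions, rate laws, zonation.

The on-disk format is a strict YAML dialect (one canonical layout, unknown
keys rejected) so that a transcribed network can be reviewed line by line.
A document lists metabolites (with compartment, initial concentration in mM
and a boundary flag), reactions (signed stoichiometry, dynamic/static
module membership, and a rate law for dynamic reactions only) and per-zone
Vmax overrides.  Boundary species never appear in stoichiometries - they
are inputs read by rate laws and driven by schedules at simulation time.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .ratelaws import Modifier, RateLaw, VMAX_CLASS, ZoneProfile
from .stoich import StoichiometricModel, partition_stoichiometry

FORMAT_KEY = "hepaflux_model"
FORMAT_VERSION = 1

COMPARTMENTS = ("cytosol", "endoplasmic_reticulum", "mitochondria", "blood")

#: structural counts of the reference liver document
REFERENCE_COUNTS = {
    "species": 34,
    "reactions": 47,
    "dynamic_reactions": 27,
    "static_reactions": 20,
    "x_d": 13,
    "x_s": 21,
    "zonation_overrides": 13,
}


class DocumentError(ValueError):
    """Schema violation in a model document."""

    def __init__(self, violations):
        if isinstance(violations, str):
            violations = [violations]
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class MetaboliteSpec:
    id: str
    name: str = ""
    compartment: str = "cytosol"
    initial: float = 0.0
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise DocumentError(
                f"species {self.id}: unknown compartment {self.compartment!r}"
            )
        if self.initial < 0:
            raise DocumentError(f"species {self.id}: negative initial concentration")


@dataclass(frozen=True)
class ReactionSpec:
    id: str
    stoichiometry: Mapping[str, float]
    module: str  # "dynamic" | "static"
    name: str = ""
    rate_law: RateLaw | None = None

    def __post_init__(self) -> None:
        if self.module not in ("dynamic", "static"):
            raise DocumentError(f"reaction {self.id}: unknown module {self.module!r}")
        if not self.stoichiometry:
            raise DocumentError(f"reaction {self.id}: empty stoichiometry")
        if self.module == "dynamic" and self.rate_law is None:
            raise DocumentError(f"reaction {self.id}: dynamic reaction lacks a rate law")
        if self.module == "static" and self.rate_law is not None:
            raise DocumentError(f"reaction {self.id}: static reaction must not carry a rate law")
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))


@dataclass
class ModelDocument:
    """A fully-specified metabolic network with zonation and metadata."""

    metabolites: list[MetaboliteSpec]
    reactions: list[ReactionSpec]
    zones: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    # -- convenience views -------------------------------------------------
    @property
    def species_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if not m.boundary]

    @property
    def boundary_ids(self) -> list[str]:
        return [m.id for m in self.metabolites if m.boundary]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, sid: str) -> MetaboliteSpec:
        for m in self.metabolites:
            if m.id == sid:
                return m
        raise KeyError(sid)

    def reaction(self, rid: str) -> ReactionSpec:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def initial_state(self) -> dict[str, float]:
        return {m.id: m.initial for m in self.metabolites}

    def to_stoichiometric_model(self) -> StoichiometricModel:
        sids = self.species_ids
        rids = self.reaction_ids
        S = np.zeros((len(sids), len(rids)))
        index = {s: i for i, s in enumerate(sids)}
        for j, r in enumerate(self.reactions):
            for sp, coeff in r.stoichiometry.items():
                S[index[sp], j] = coeff
        dynamic = {r.id for r in self.reactions if r.module == "dynamic"}
        return StoichiometricModel(
            species_ids=tuple(sids),
            reaction_ids=tuple(rids),
            S=S,
            dynamic_reactions=frozenset(dynamic),
        )

    def zone_profile(self, zone_id: str) -> ZoneProfile:
        """Profile for a zone; the intermediate zone is interpolated at the
        midpoint of periportal and pericentral when not declared."""
        if zone_id in self.zones:
            return ZoneProfile(zone_id, dict(self.zones[zone_id]))
        if (
            zone_id == "intermediate"
            and "periportal" in self.zones
            and "pericentral" in self.zones
        ):
            pp, pc = self.zones["periportal"], self.zones["pericentral"]
            keys = set(pp) | set(pc)
            mid = {}
            for key in keys:
                base = self._base_parameter(*key)
                lo = pp.get(key, base)
                hi = pc.get(key, base)
                mid[key] = 0.5 * (lo + hi)
            return ZoneProfile(zone_id, mid)
        raise DocumentError(f"zone {zone_id!r} not declared in document")

    def _base_parameter(self, rid: str, pname: str) -> float:
        law = self.reaction(rid).rate_law
        if law is None or pname not in law.parameters:
            raise DocumentError(f"override references unknown parameter {rid}:{pname}")
        return law.parameters[pname]

    def zonation_differences(self) -> list[tuple[str, str]]:
        """(reaction, parameter) pairs whose values differ between the
        periportal and pericentral profiles."""
        pp = self.zones.get("periportal", {})
        pc = self.zones.get("pericentral", {})
        diffs = []
        for key in sorted(set(pp) | set(pc)):
            base = self._base_parameter(*key)
            if pp.get(key, base) != pc.get(key, base):
                diffs.append(key)
        return diffs

    def copy(self) -> "ModelDocument":
        return copy.deepcopy(self)

    def scale_vmax(self, reaction_id: str, factor: float) -> None:
        """Multiply the Vmax-class parameter of a dynamic reaction (base value
        and every zone override) by ``factor`` - used by perturbation presets."""
        rxn = self.reaction(reaction_id)
        if rxn.rate_law is None:
            raise DocumentError(f"reaction {reaction_id} has no rate law to scale")
        pname = next((p for p in VMAX_CLASS if p in rxn.rate_law.parameters), None)
        if pname is None:
            raise DocumentError(f"reaction {reaction_id} has no Vmax-class parameter")
        new_law = rxn.rate_law.with_parameters(
            **{pname: rxn.rate_law.parameters[pname] * factor}
        )
        idx = self.reactions.index(rxn)
        self.reactions[idx] = replace(rxn, rate_law=new_law)
        for overrides in self.zones.values():
            key = (reaction_id, pname)
            if key in overrides:
                overrides[key] = overrides[key] * factor


# ---------------------------------------------------------------------------
# validation

@dataclass
class ValidationReport:
    counts: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)
    reference_errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    @property
    def reference_ok(self) -> bool:
        return self.ok and not self.reference_errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "reference_ok": self.reference_ok,
            "counts": self.counts,
            "diagnostics": self.diagnostics,
            "errors": self.errors,
            "reference_errors": self.reference_errors,
        }


def validate_model(doc: ModelDocument, reference: bool = False) -> ValidationReport:
    """Structural validation; with ``reference=True`` also check the liver
    document's expected counts (34/47 species/reactions, 13/27 + 21/20
    partition, 13 zonation-dependent parameters)."""
    report = ValidationReport()
    err = report.errors.append

    if not doc.metabolites:
        err("no species")
    if not doc.reactions:
        err("no reactions")

    ids = [m.id for m in doc.metabolites]
    if len(set(ids)) != len(ids):
        err("duplicate metabolite ids")
    rids = [r.id for r in doc.reactions]
    if len(set(rids)) != len(rids):
        err("duplicate reaction ids")

    known = set(ids)
    boundary = set(doc.boundary_ids)
    touched: set[str] = set()
    for r in doc.reactions:
        for sp in r.stoichiometry:
            if sp not in known:
                err(f"reaction {r.id}: unknown species {sp!r}")
            elif sp in boundary:
                err(
                    f"reaction {r.id}: boundary species {sp!r} in stoichiometry "
                    "(boundary species are schedule-driven, not balanced)"
                )
            touched.add(sp)
        if r.rate_law is not None:
            refs = (
                set(r.rate_law.substrates)
                | set(r.rate_law.products)
                | {m.species for m in r.rate_law.modifiers}
            )
            missing = refs - known
            if missing:
                err(f"reaction {r.id}: rate law references unknown species {sorted(missing)}")
    orphan = set(doc.species_ids) - touched
    if orphan:
        err(f"species touched by no reaction: {sorted(orphan)}")

    for zone, overrides in doc.zones.items():
        for (rid, pname) in overrides:
            if rid not in set(rids):
                err(f"zone {zone}: override references unknown reaction {rid!r}")
                continue
            law = doc.reaction(rid).rate_law
            if law is None:
                err(f"zone {zone}: override on static reaction {rid!r}")
            elif pname not in law.parameters:
                err(f"zone {zone}: override on unknown parameter {rid}:{pname}")
            elif pname not in VMAX_CLASS:
                err(f"zone {zone}: non-Vmax-class override {rid}:{pname}")

    report.counts = {
        "species": len(doc.species_ids),
        "boundary_species": len(doc.boundary_ids),
        "reactions": len(doc.reactions),
        "dynamic_reactions": sum(1 for r in doc.reactions if r.module == "dynamic"),
        "static_reactions": sum(1 for r in doc.reactions if r.module == "static"),
    }
    if not report.errors:
        model = doc.to_stoichiometric_model()
        part = partition_stoichiometry(model)
        report.counts["x_d"] = len(part.x_d_ids)
        report.counts["x_s"] = len(part.x_s_ids)
        try:
            report.counts["zonation_overrides"] = len(doc.zonation_differences())
        except DocumentError as exc:
            err(str(exc))
        report.diagnostics = part.diagnostics()

    if reference and not report.errors:
        for key, expected in REFERENCE_COUNTS.items():
            got = report.counts.get(key)
            if got != expected:
                label = "zonation count mismatch" if key == "zonation_overrides" else f"{key} count mismatch"
                report.reference_errors.append(f"{label}: expected {expected}, got {got}")
        missing_prov = [
            f"{r.id}.{p}"
            for r in doc.reactions
            if r.rate_law is not None
            for p in r.rate_law.parameters
            if f"{r.id}.{p}" not in doc.metadata.get("provenance", {})
        ]
        if missing_prov:
            report.reference_errors.append(
                f"parameters without provenance notes: {missing_prov[:5]}..."
                if len(missing_prov) > 5
                else f"parameters without provenance notes: {missing_prov}"
            )
    return report


# ---------------------------------------------------------------------------
# serialisation (strict YAML dialect)

_SPECIES_KEYS = {"id", "name", "compartment", "initial", "boundary"}
_REACTION_KEYS = {"id", "name", "stoichiometry", "module", "rate_law"}
_LAW_KEYS = {"form", "parameters", "substrates", "products", "modifiers"}
_MOD_KEYS = {"species", "kind", "params"}
_TOP_KEYS = {FORMAT_KEY, "metadata", "species", "reactions", "zones"}


def _check_keys(mapping: Mapping, allowed: set[str], where: str, errs: list[str]):
    unknown = set(mapping) - allowed
    if unknown:
        errs.append(f"{where}: unknown field(s) {sorted(unknown)}")


def document_to_dict(doc: ModelDocument) -> dict:
    def law_dict(law: RateLaw) -> dict:
        d: dict = {"form": law.form, "parameters": dict(law.parameters)}
        if law.substrates:
            d["substrates"] = list(law.substrates)
        if law.products:
            d["products"] = list(law.products)
        if law.modifiers:
            d["modifiers"] = [
                {"species": m.species, "kind": m.kind, "params": dict(m.params)}
                for m in law.modifiers
            ]
        return d

    return {
        FORMAT_KEY: FORMAT_VERSION,
        "metadata": dict(doc.metadata),
        "species": [
            {
                "id": m.id,
                "name": m.name,
                "compartment": m.compartment,
                "initial": m.initial,
                "boundary": m.boundary,
            }
            for m in doc.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoichiometry": dict(r.stoichiometry),
                "module": r.module,
                **({"rate_law": law_dict(r.rate_law)} if r.rate_law else {}),
            }
            for r in doc.reactions
        ],
        "zones": {
            zone: [
                {"reaction": rid, "parameter": pname, "value": value}
                for (rid, pname), value in sorted(overrides.items())
            ]
            for zone, overrides in doc.zones.items()
        },
    }


def document_from_dict(data: Mapping) -> ModelDocument:
    errs: list[str] = []
    if not isinstance(data, Mapping):
        raise DocumentError("document root must be a mapping")
    _check_keys(data, _TOP_KEYS, "document", errs)
    if data.get(FORMAT_KEY) != FORMAT_VERSION:
        errs.append(f"missing or unsupported {FORMAT_KEY} version (want {FORMAT_VERSION})")

    metabolites: list[MetaboliteSpec] = []
    for i, raw in enumerate(data.get("species", []) or []):
        where = f"species[{i}]"
        _check_keys(raw, _SPECIES_KEYS, where, errs)
        try:
            metabolites.append(
                MetaboliteSpec(
                    id=str(raw["id"]),
                    name=str(raw.get("name", "")),
                    compartment=str(raw.get("compartment", "cytosol")),
                    initial=float(raw.get("initial", 0.0)),
                    boundary=bool(raw.get("boundary", False)),
                )
            )
        except (KeyError, DocumentError, ValueError) as exc:
            errs.append(f"{where}: {exc}")

    reactions: list[ReactionSpec] = []
    for i, raw in enumerate(data.get("reactions", []) or []):
        where = f"reactions[{i}]({raw.get('id', '?')})"
        _check_keys(raw, _REACTION_KEYS, where, errs)
        law = None
        raw_law = raw.get("rate_law")
        if raw_law is not None:
            _check_keys(raw_law, _LAW_KEYS, f"{where}.rate_law", errs)
            mods = []
            for j, rm in enumerate(raw_law.get("modifiers", []) or []):
                _check_keys(rm, _MOD_KEYS, f"{where}.rate_law.modifiers[{j}]", errs)
                try:
                    mods.append(
                        Modifier(
                            species=str(rm["species"]),
                            kind=str(rm["kind"]),
                            params={k: float(v) for k, v in (rm.get("params") or {}).items()},
                        )
                    )
                except (KeyError, ValueError) as exc:
                    errs.append(f"{where}.rate_law.modifiers[{j}]: {exc}")
            try:
                law = RateLaw(
                    form=str(raw_law["form"]),
                    parameters={k: float(v) for k, v in (raw_law.get("parameters") or {}).items()},
                    substrates=tuple(raw_law.get("substrates", []) or []),
                    products=tuple(raw_law.get("products", []) or []),
                    modifiers=tuple(mods),
                )
            except (KeyError, ValueError) as exc:
                errs.append(f"{where}.rate_law: {exc}")
        try:
            reactions.append(
                ReactionSpec(
                    id=str(raw["id"]),
                    name=str(raw.get("name", "")),
                    stoichiometry={
                        str(k): float(v) for k, v in (raw.get("stoichiometry") or {}).items()
                    },
                    module=str(raw.get("module", "")),
                    rate_law=law,
                )
            )
        except (KeyError, DocumentError, ValueError) as exc:
            errs.append(f"{where}: {exc}")

    zones: dict[str, dict[tuple[str, str], float]] = {}
    for zone, raw_list in (data.get("zones") or {}).items():
        overrides: dict[tuple[str, str], float] = {}
        for j, raw in enumerate(raw_list or []):
            where = f"zones.{zone}[{j}]"
            _check_keys(raw, {"reaction", "parameter", "value"}, where, errs)
            try:
                overrides[(str(raw["reaction"]), str(raw["parameter"]))] = float(raw["value"])
            except (KeyError, ValueError) as exc:
                errs.append(f"{where}: {exc}")
        zones[str(zone)] = overrides

    if errs:
        raise DocumentError(errs)

    doc = ModelDocument(
        metabolites=metabolites,
        reactions=reactions,
        zones=zones,
        metadata=dict(data.get("metadata") or {}),
    )
    report = validate_model(doc)
    if not report.ok:
        raise DocumentError(report.errors)
    return doc


def write_model(doc: ModelDocument, path: str | Path) -> None:
    payload = document_to_dict(doc)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False, default_flow_style=None)


def load_model(path: str | Path) -> ModelDocument:
    """Load and fully validate a model document (strict dialect)."""
    path = Path(path)
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise DocumentError(f"{path}: not parseable YAML: {exc}") from exc
    try:
        return document_from_dict(data)
    except DocumentError as exc:
        raise DocumentError([f"{path}: {v}" for v in exc.violations]) from exc
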