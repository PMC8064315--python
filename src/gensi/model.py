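"""Genome-scale model container, I/O and curation patches.

The in-memory container is a :class:`cobra.Model`; this module wraps it
with the bookkeeping the integration pipeline needs — reaction-kind
classification (internal / exchange / sink / demand / biomass), the
default bounds as loaded (which fix each reaction's admissible
direction), parsed GPR trees, and the set of metabolites the source
model allows to be net exported.

Sign convention: an exchange reaction is written ``1 met ->`` (nothing),
so positive flux is secretion and negative flux is uptake; a maximal
uptake rate MUR therefore enters as lower bound ``-MUR``.

Curation patches implemented here:

* ``block_sinks_and_demands`` — sink/demand reactions bypass mass
  balance and are closed to ``[0, 0]``.
* ``patch_lipid_pool`` — merges positional acyl-pool species (Rtotal
  analogues) into a single pool and adds one reversible pooling reaction
  ``1 acyl1 + 1 acyl2 + 1 acyl3 + 1 acyl4 <-> 4 pool``, restoring lipid
  (hence biomass) synthesis in models whose acyl pools are dead ends.
* ``block_nonmedium_uptakes`` — zero the uptake (lower) bound of every
  exchange whose metabolite is absent from the growth medium; export
  bounds are untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import cobra
import cobra.io

from .gpr import EMPTY_GPR, GPRExpression, GPRParseError, parse_gpr

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .medium import MediumSpec

logger = logging.getLogger(__name__)

KINDS = ("internal", "exchange", "sink", "demand", "biomass")

#: Default flux cap for geneless, non-boundary reactions (mM per duration).
DEFAULT_BOUND = 1000.0

SINK_PREFIXES = ("sink_", "SK_")
DEMAND_PREFIXES = ("DM_",)


class GEMError(ValueError):
    """Raised on structural problems with a genome-scale model."""


@dataclass
class PatchReport:
    """Record of a model curation patch."""

    blocked_sink_ids: list[str] = field(default_factory=list)
    blocked_demand_ids: list[str] = field(default_factory=list)
    pooled_species: list[str] = field(default_factory=list)
    added_reaction_id: str = ""

    def to_dict(self) -> dict:
        return {
            "blocked_sink_ids": list(self.blocked_sink_ids),
            "blocked_demand_ids": list(self.blocked_demand_ids),
            "pooled_species": list(self.pooled_species),
            "added_reaction_id": self.added_reaction_id,
        }


def _is_boundary_like(rxn: cobra.Reaction) -> bool:
    return len(rxn.metabolites) == 1


def classify_reaction(rxn: cobra.Reaction, objective_id: str | None,
                      sink_overrides: Iterable[str] = ()) -> str:
    """Classify a reaction as internal/exchange/sink/demand/biomass.

    Boundary (single-metabolite) reactions are split by id convention:
    ``sink_``/``SK_`` prefixes are sinks, ``DM_`` demands, everything
    else an exchange.  ``sink_overrides`` may force specific ids to be
    treated as sinks regardless of prefix.
    """
    if objective_id is not None and rxn.id == objective_id:
        return "biomass"
    if rxn.id in set(sink_overrides):
        return "sink"
    if _is_boundary_like(rxn):
        if rxn.id.startswith(SINK_PREFIXES):
            return "sink"
        if rxn.id.startswith(DEMAND_PREFIXES):
            return "demand"
        return "exchange"
    return "internal"


class GEMModel:
    """A genome-scale metabolic model plus integration bookkeeping.

    Parameters
    ----------
    cobra_model:
        The underlying COBRA model.  Taken by reference; use
        :meth:`copy` for a detached instance.
    sink_overrides:
        Reaction ids to classify as sinks irrespective of naming.
    """

    def __init__(self, cobra_model: cobra.Model,
                 sink_overrides: Iterable[str] = ()) -> None:
        cobra_model.solver = "glpk"
        self.cobra_model = cobra_model
        self._sink_overrides = tuple(sink_overrides)
        self.objective_id = self._find_objective_id()
        self.kinds: dict[str, str] = {
            r.id: classify_reaction(r, self.objective_id, self._sink_overrides)
            for r in cobra_model.reactions
        }
        self.gprs: dict[str, GPRExpression] = {}
        for r in cobra_model.reactions:
            try:
                self.gprs[r.id] = parse_gpr(r.gene_reaction_rule)
            except GPRParseError as exc:
                raise GPRParseError(
                    f"reaction {r.id!r}: {exc}") from exc
        # Bounds as loaded; these fix each reaction's admissible direction
        # even after later constraining steps tighten the working bounds.
        self.default_bounds: dict[str, tuple[float, float]] = {
            r.id: (float(r.lower_bound), float(r.upper_bound))
            for r in cobra_model.reactions
        }
        ids = [r.id for r in cobra_model.reactions]
        if len(ids) != len(set(ids)):
            raise GEMError("duplicate reaction ids in model")

    # -- structure ---------------------------------------------------------

    def _find_objective_id(self) -> str | None:
        coeffs = cobra.util.solver.linear_reaction_coefficients(self.cobra_model)
        if len(coeffs) == 1:
            return next(iter(coeffs)).id
        for r in self.cobra_model.reactions:
            if "biomass" in r.id.lower():
                return r.id
        return None

    @property
    def reactions(self):
        return self.cobra_model.reactions

    @property
    def metabolites(self):
        return self.cobra_model.metabolites

    def reaction_ids(self, kind: str | None = None) -> list[str]:
        if kind is None:
            return [r.id for r in self.reactions]
        return [rid for rid, k in self.kinds.items() if k == kind]

    @property
    def exportable_ids(self) -> set[str]:
        """Metabolites whose exchange allows net export under the
        *default* bounds (positive default upper bound)."""
        out = set()
        for rid in self.reaction_ids("exchange"):
            if self.default_bounds[rid][1] > 0:
                met = next(iter(self.cobra_model.reactions.get_by_id(rid).metabolites))
                out.add(met.id)
        return out

    def exchange_for(self, metabolite_id: str) -> cobra.Reaction | None:
        """The exchange reaction touching ``metabolite_id``, if any."""
        try:
            met = self.cobra_model.metabolites.get_by_id(metabolite_id)
        except KeyError:
            return None
        for rxn in met.reactions:
            if self.kinds.get(rxn.id) == "exchange":
                return rxn
        return None

    def stoichiometric_matrix(self):
        """Dense stoichiometry matrix (metabolites x reactions)."""
        from cobra.util.array import create_stoichiometric_matrix

        return create_stoichiometric_matrix(self.cobra_model)

    def partition_counts(self) -> dict[str, int]:
        """Total and gene-associated / geneless reaction counts."""
        from .gpr import EmptyGPR

        gene_assoc = sum(
            1 for g in self.gprs.values() if not isinstance(g, EmptyGPR))
        return {
            "reactions": len(self.reactions),
            "metabolites": len(self.metabolites),
            "gene_associated": gene_assoc,
            "geneless": len(self.reactions) - gene_assoc,
        }

    def copy(self) -> "GEMModel":
        return GEMModel(self.cobra_model.copy(), self._sink_overrides)

    # -- I/O ---------------------------------------------------------------

    def save(self, path: str | Path, format: str | None = None) -> None:
        save_gem(self, path, format)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
    elif path.suffix.lower() in (".xml", ".sbml"):
        fmt = "sbml"
    elif path.suffix.lower() == ".json":
        fmt = "json"
    else:
        raise GEMError(f"cannot infer model format from {path.name!r}; "
                       "pass format='sbml' or 'json'")
    if fmt not in ("sbml", "json"):
        raise GEMError(f"unknown model format {fmt!r}")
    return fmt


def load_gem(path: str | Path, format: str | None = None,
             sink_overrides: Iterable[str] = ()) -> GEMModel:
    """Load a model from SBML (Level 3 + FBC) or COBRA community JSON.

    GPR strings are parsed into expression trees at load time; a
    malformed rule raises :class:`GPRParseError` naming the reaction.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cm = cobra.io.read_sbml_model(str(path))
    else:
        # pre-validate raw GPR strings: the JSON dialect carries them as
        # free text, and a malformed rule must be a named parse error,
        # not a silently emptied gene association
        import json

        doc = json.loads(path.read_text())
        for entry in doc.get("reactions", []):
            rule = entry.get("gene_reaction_rule") or ""
            try:
                parse_gpr(rule)
            except GPRParseError as exc:
                raise GPRParseError(
                    f"reaction {entry.get('id', '?')!r}: {exc}") from exc
        cm = cobra.io.load_json_model(str(path))
    return GEMModel(cm, sink_overrides)


def save_gem(model: GEMModel, path: str | Path, format: str | None = None) -> None:
    """Write a model to SBML L3+FBC or COBRA JSON."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cobra.io.write_sbml_model(model.cobra_model, str(path))
    else:
        cobra.io.save_json_model(model.cobra_model, str(path), sort=True)


# -- curation patches ------------------------------------------------------


def block_sinks_and_demands(model: GEMModel) -> tuple[GEMModel, PatchReport]:
    """Close every sink and demand reaction to ``[0, 0]``.

    Sink/demand reactions let metabolites bypass mass balance and can
    act as hidden sources feeding biomass; a no-op (with empty report)
    when the model has none.
    """
    patched = model.copy()
    report = PatchReport()
    for rid in patched.reaction_ids("sink"):
        patched.cobra_model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        report.blocked_sink_ids.append(rid)
    for rid in patched.reaction_ids("demand"):
        patched.cobra_model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        report.blocked_demand_ids.append(rid)
    return patched, report


def patch_lipid_pool(model: GEMModel, acyl_ids: list[str], pool_id: str,
                     pooled_ids: Iterable[str] = (),
                     reaction_id: str = "ACYL_POOL") -> tuple[GEMModel, PatchReport]:
    """Merge positional acyl-pool species and add the pooling reaction.

    Every occurrence of a species in ``pooled_ids`` is replaced by
    ``pool_id`` (coefficients preserved), then one reversible reaction
    consuming 1 of each of the four ``acyl_ids`` and producing 4 of
    ``pool_id`` is added.  This treats the four acyl-CoA tails as a
    single interchangeable pool (ratio 1:1:1:1).
    """
    if len(acyl_ids) != 4:
        raise GEMError(f"expected 4 acyl species, got {len(acyl_ids)}")
    patched = model.copy()
    cm = patched.cobra_model
    for aid in acyl_ids + [pool_id]:
        if aid not in cm.metabolites:
            raise GEMError(f"metabolite {aid!r} not in model")
    report = PatchReport(added_reaction_id=reaction_id)
    pool = cm.metabolites.get_by_id(pool_id)
    for pid in pooled_ids:
        if pid == pool_id:
            continue
        if pid not in cm.metabolites:
            raise GEMError(f"pooled species {pid!r} not in model")
        met = cm.metabolites.get_by_id(pid)
        for rxn in list(met.reactions):
            coeff = rxn.metabolites[met]
            rxn.subtract_metabolites({met: coeff})
            rxn.add_metabolites({pool: coeff})
        cm.remove_metabolites([met])
        report.pooled_species.append(pid)
    pooling = cobra.Reaction(reaction_id)
    pooling.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
    cm.add_reactions([pooling])
    pooling.add_metabolites(
        {cm.metabolites.get_by_id(a): -1.0 for a in acyl_ids})
    pooling.add_metabolites({pool: 4.0})
    # re-derive bookkeeping for the structural change
    rebuilt = GEMModel(cm, patched._sink_overrides)
    return rebuilt, report


def block_nonmedium_uptakes(model: GEMModel, medium: "MediumSpec") -> GEMModel:
    """Zero the uptake bound of exchanges for metabolites not in the medium.

    Export (upper) bounds are untouched, so metabolites the source model
    allows to be net produced remain exportable.  A medium metabolite
    with no exchange reaction is logged as a warning, not an error.
    """
    patched = model.copy()
    # a nutrient listed at 0 mM is absent: its uptake is closed here
    medium_mets = {m for m, c in medium.concentrations.items() if c > 0}
    for met_id in medium.concentrations:
        if patched.exchange_for(met_id) is None:
            logger.warning("medium metabolite %r has no exchange reaction", met_id)
    for rid in patched.reaction_ids("exchange"):
        rxn = patched.cobra_model.reactions.get_by_id(rid)
        met = next(iter(rxn.metabolites))
        if met.id not in medium_mets and rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return patched
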