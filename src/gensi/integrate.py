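"""Build GEM-RAS-MUR models: α-scaled expression bounds + medium bounds.

A GEM-RAS-MUR model is a genome-scale model whose flux bounds encode
two data sources at once: every gene-associated internal reaction i is
capped at ``b_i = α · RAS_i`` in each admissible direction, and every
exchange reaction j is capped at uptake rate ``MUR_j`` (lower bound
``-MUR_j``).  RAS (expression scale) and MUR (mM per duration) are
incommensurate; the single proportionality constant α converts between
them and is fitted downstream against observed growth — no other
normalization is applied.

Direction handling follows the source model's *default* bounds: a
reversible reaction gets ``[-b_i, +b_i]``, an irreversible-forward one
``[0, +b_i]``, an irreversible-backward one ``[-b_i, 0]``.  Geneless
reactions keep their defaults (±1000), and boundary reactions
(exchange/sink/demand) and the biomass pseudo-reaction are never
RAS-bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .expression import (AdjustedProfile, ExpressionProfile, MatchReport,
                         MicroarrayProfile, RASTable, compute_ras,
                         match_genes, zero_adjust)
from .medium import MediumSpec, MURTable, apply_murs, compute_mur
from .model import (GEMModel, PatchReport, block_nonmedium_uptakes,
                    block_sinks_and_demands, patch_lipid_pool)

RAS_EXEMPT_KINDS = ("exchange", "sink", "demand", "biomass")


@dataclass
class GensiModel:
    """A constrained GEM-RAS-MUR model plus its provenance."""

    model: GEMModel
    alpha: float
    ras: RASTable
    murs: MURTable
    medium: MediumSpec
    provenance: list[dict] = field(default_factory=list)
    reports: dict = field(default_factory=dict)

    @property
    def cobra_model(self):
        return self.model.cobra_model

    def provenance_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.provenance,
                            columns=["stage", "reaction", "old_lb", "old_ub",
                                     "new_lb", "new_ub"])

    def write_provenance(self, path: str | Path) -> None:
        self.provenance_frame().to_csv(path, sep="\t", index=False)


def apply_ras_bounds(model: GEMModel, ras: RASTable, alpha: float) -> GEMModel:
    """Cap every gene-associated reaction at ``α · RAS`` per direction.

    A RAS of 0 closes the reaction to ``[0, 0]``.  The cap *replaces*
    the default magnitude in each admissible direction (it may exceed
    ±1000 at large α), which is what makes the high-α regime of an
    α-scan equivalent to the medium-only model.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    constrained = model.copy()
    for rid, score in ras.scores.items():
        if rid not in constrained.kinds:
            continue
        if constrained.kinds[rid] in RAS_EXEMPT_KINDS:
            continue
        cap = float(alpha) * float(score)
        lb0, ub0 = constrained.default_bounds[rid]
        lb = -cap if lb0 < 0 else 0.0
        ub = cap if ub0 > 0 else 0.0
        constrained.cobra_model.reactions.get_by_id(rid).bounds = (lb, ub)
    return constrained


def _record_bound_changes(prov: list[dict], stage: str,
                          before: Mapping[str, tuple[float, float]],
                          model: GEMModel) -> None:
    for rxn in model.reactions:
        old = before.get(rxn.id)
        new = (float(rxn.lower_bound), float(rxn.upper_bound))
        if old is None or old != new:
            prov.append({"stage": stage, "reaction": rxn.id,
                         "old_lb": old[0] if old else None,
                         "old_ub": old[1] if old else None,
                         "new_lb": new[0], "new_ub": new[1]})


def _snapshot(model: GEMModel) -> dict[str, tuple[float, float]]:
    return {r.id: (float(r.lower_bound), float(r.upper_bound))
            for r in model.reactions}


def build_gensi_model(gem: GEMModel,
                      rnaseq: ExpressionProfile,
                      medium: MediumSpec,
                      alpha: float,
                      microarray: MicroarrayProfile | None = None,
                      aliases: Mapping[str, str] | None = None,
                      lipid_pool: dict | None = None) -> GensiModel:
    """Compose the full integration pipeline into one constrained model.

    Stages, in order: block sinks/demands -> lipid-pool patch (if
    ``lipid_pool`` gives ``acyl_ids``/``pool_id``/``pooled_ids``) ->
    zero-adjust TPMs (if a microarray is given) -> gene matching ->
    RAS -> block non-medium uptakes -> MUR -> exchange bounds -> α·RAS
    bounds.  Every bound change is recorded in the provenance log.
    """
    provenance: list[dict] = []
    reports: dict = {}

    snap = _snapshot(gem)
    model, sink_report = block_sinks_and_demands(gem)
    reports["sinks_demands"] = sink_report
    _record_bound_changes(provenance, "block_sinks_demands", snap, model)

    if lipid_pool:
        snap = _snapshot(model)
        model, pool_report = patch_lipid_pool(
            model, acyl_ids=list(lipid_pool["acyl_ids"]),
            pool_id=lipid_pool["pool_id"],
            pooled_ids=lipid_pool.get("pooled_ids", ()))
        reports["lipid_pool"] = pool_report
        _record_bound_changes(provenance, "patch_lipid_pool", snap, model)

    profile: ExpressionProfile | AdjustedProfile = rnaseq
    if microarray is not None:
        profile = zero_adjust(rnaseq, microarray)
        reports["zero_adjust"] = {
            "adjusted": sorted(profile.adjusted_genes),
            "unrescued": sorted(profile.unrescued_zeros),
        }
    model_genes = set()
    for expr in model.gprs.values():
        from .gpr import gpr_genes

        model_genes |= gpr_genes(expr)
    matched, match_report = match_genes(model_genes, profile, aliases)
    reports["match_genes"] = match_report
    ras = compute_ras(model, matched)

    snap = _snapshot(model)
    model = block_nonmedium_uptakes(model, medium)
    _record_bound_changes(provenance, "block_nonmedium_uptakes", snap, model)

    murs = compute_mur(medium)
    snap = _snapshot(model)
    model = apply_murs(model, murs)
    _record_bound_changes(provenance, "apply_murs", snap, model)

    snap = _snapshot(model)
    model = apply_ras_bounds(model, ras, alpha)
    _record_bound_changes(provenance, "apply_ras_bounds", snap, model)

    return GensiModel(model=model, alpha=alpha, ras=ras, murs=murs,
                      medium=medium, provenance=provenance, reports=reports)
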