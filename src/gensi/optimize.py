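"""FBA, FVA, the ATP-hydrolysis capacity probe, α-scans and α-selection.

FBA maximizes (or minimizes) an objective flux Z = c'V subject to
steady state S·V = 0 and the flux bounds.  FVA reports, per reaction,
the attainable [min, max] flux while at least a fraction γ of the
optimal biomass flux Z0 is maintained (w'V >= γ·Z0, γ = 1 by default).

The FVA loop is implemented here (fix the biomass lower bound at γ·Z0,
then iterate min/max objectives per target reaction) so the ATP probe
protocol can be honored exactly: the irreversible hydrolysis reaction
ATP + H2O -> ADP + Pi + H+ exists only while its own capacity is being
maximized and is absent during every other analysis — otherwise it
would act as an unintended maintenance drain.

The α-scan lowers the RAS-to-flux conversion factor α from a regime
where expression is not limiting (max biomass set by nutrient uptake)
into a regime where it is; ``select_alpha`` picks the largest grid α at
which a chosen set of conditions has converged to (near-)equal biomass
while still strictly dominating a second set — the calibration the
integrated model's single free constant is fitted by.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import cobra
import numpy as np
import pandas as pd

from .expression import RASTable
from .integrate import GensiModel, apply_ras_bounds
from .medium import MediumSpec, apply_murs, compute_mur
from .model import GEMModel, block_nonmedium_uptakes, block_sinks_and_demands

#: Relative slack on the γ·Z0 constraint, to keep the FVA subproblems
#: feasible against LP round-off at γ = 1.
FVA_Z0_SLACK = 1e-9

#: Default α grid: 61 log-spaced points spanning the regime transition.
DEFAULT_ALPHA_GRID = tuple(np.geomspace(3e-4, 1.6, 61))


def _cobra_of(model: GensiModel | GEMModel) -> tuple[cobra.Model, str | None]:
    if isinstance(model, GensiModel):
        return model.model.cobra_model, model.model.objective_id
    return model.cobra_model, model.objective_id


@dataclass
class FluxSolution:
    """An FBA solution; fluxes are meaningful only when optimal."""

    fluxes: pd.Series
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class FVAResult:
    """Per-reaction flux ranges at >= γ of the optimal biomass Z0."""

    frame: pd.DataFrame  # index reaction id, columns min_flux/max_flux
    z0: float
    gamma: float

    def range(self, reaction_id: str) -> tuple[float, float]:
        row = self.frame.loc[reaction_id]
        return float(row["min_flux"]), float(row["max_flux"])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.insert(0, "reaction", out.index)
        out["z0"] = self.z0
        out["gamma"] = self.gamma
        out.to_csv(path, sep="\t", index=False)


def fba(model: GensiModel | GEMModel, objective: str | None = None,
        sense: str = "max") -> FluxSolution:
    """Flux balance analysis.

    Infeasible or unbounded problems are reported through ``status``,
    not raised.
    """
    cm, default_obj = _cobra_of(model)
    objective = objective or default_obj
    if objective is None:
        raise ValueError("no objective reaction given and none set on model")
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    with cm as m:
        m.objective = objective
        m.objective_direction = "max" if sense == "max" else "min"
        sol = m.optimize(raise_error=False)
        status = sol.status
        if status == "optimal":
            return FluxSolution(fluxes=sol.fluxes.copy(),
                                objective_value=float(sol.objective_value),
                                status="optimal")
    return FluxSolution(fluxes=pd.Series(dtype=float),
                        objective_value=float("nan"), status=status)


def fva(model: GensiModel | GEMModel,
        reactions: Iterable[str] | None = None,
        gamma: float = 1.0,
        objective: str | None = None) -> FVAResult:
    """Flux variability analysis at optimality fraction γ.

    Raises
    ------
    RuntimeError
        If the base FBA problem is infeasible (before any per-reaction
        solve).
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    cm, default_obj = _cobra_of(model)
    objective = objective or default_obj
    if objective is None:
        raise ValueError("no objective reaction given and none set on model")
    base = fba(model, objective=objective, sense="max")
    if not base.optimal:
        raise RuntimeError(f"base FBA problem is {base.status}")
    z0 = base.objective_value
    targets = list(reactions) if reactions is not None \
        else [r.id for r in cm.reactions]
    rows = {}
    with cm as m:
        obj_rxn = m.reactions.get_by_id(objective)
        floor = gamma * z0 - FVA_Z0_SLACK * max(1.0, abs(z0))
        if floor > obj_rxn.lower_bound:
            obj_rxn.lower_bound = floor
        for rid in targets:
            lo, hi = None, None
            for direction in ("min", "max"):
                m.objective = rid
                m.objective_direction = direction
                val = m.slim_optimize()
                if math.isnan(val):  # pragma: no cover - guarded by base solve
                    raise RuntimeError(f"FVA subproblem for {rid!r} failed")
                if direction == "min":
                    lo = float(val)
                else:
                    hi = float(val)
            rows[rid] = (lo, hi)
    frame = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["min_flux", "max_flux"])
    return FVAResult(frame=frame, z0=z0, gamma=gamma)


#: Default cytosolic species ids for the ATP hydrolysis probe, covering
#: the toy fixture convention and common human-model dialects.
ATP_SPECIES_CANDIDATES = {
    "atp": ("atp_c", "atp[c]", "MAM01371c"),
    "h2o": ("h2o_c", "h2o[c]", "MAM02040c"),
    "adp": ("adp_c", "adp[c]", "MAM01285c"),
    "pi": ("pi_c", "pi[c]", "MAM02751c"),
    "h": ("h_c", "h[c]", "MAM02039c"),
}

ATP_PROBE_ID = "ATP_HYDROLYSIS_PROBE"


def atp_capacity(model: GensiModel | GEMModel,
                 species: Mapping[str, str] | None = None,
                 gamma: float = 1.0) -> tuple[float, float]:
    """Max/min ATP hydrolysis capacity at maximal biomass.

    Temporarily adds the irreversible probe reaction
    ``ATP + H2O -> ADP + Pi + H+``, runs FVA on it at the given γ, and
    removes it again; the probe is guaranteed absent afterwards.

    Parameters
    ----------
    species:
        Mapping of the roles atp/h2o/adp/pi/h to metabolite ids.  When
        omitted, common id dialects are tried.

    Returns
    -------
    (min_flux, max_flux) of the probe reaction.
    """
    cm, _ = _cobra_of(model)
    resolved: dict[str, str] = {}
    for role, candidates in ATP_SPECIES_CANDIDATES.items():
        if species and role in species:
            candidates = (species[role],)
        hit = next((c for c in candidates if c in cm.metabolites), None)
        if hit is None:
            raise ValueError(f"cannot identify {role!r} species in model "
                             f"(tried {', '.join(candidates)})")
        resolved[role] = hit
    probe = cobra.Reaction(ATP_PROBE_ID)
    probe.bounds = (0.0, 1000.0)
    cm.add_reactions([probe])
    try:
        probe.add_metabolites({
            cm.metabolites.get_by_id(resolved["atp"]): -1.0,
            cm.metabolites.get_by_id(resolved["h2o"]): -1.0,
            cm.metabolites.get_by_id(resolved["adp"]): 1.0,
            cm.metabolites.get_by_id(resolved["pi"]): 1.0,
            cm.metabolites.get_by_id(resolved["h"]): 1.0,
        })
        result = fva(model, reactions=[ATP_PROBE_ID], gamma=gamma)
        return result.range(ATP_PROBE_ID)
    finally:
        cm.remove_reactions([probe])


@dataclass
class AlphaScanResult:
    """Long-format α-scan: one row per (α, medium, profile)."""

    frame: pd.DataFrame  # columns alpha, medium, profile, biomass, feasible
    grid: tuple[float, ...]

    def biomass(self, alpha: float, medium: str, profile: str) -> float:
        f = self.frame
        row = f[(f["alpha"] == alpha) & (f["medium"] == medium)
                & (f["profile"] == profile)]
        return float(row["biomass"].iloc[0])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def alpha_scan(gem: GEMModel,
               ras_tables: Mapping[str, RASTable],
               media: Sequence[MediumSpec],
               alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID) -> AlphaScanResult:
    """Max biomass over an α grid for every (profile, medium) condition.

    ``ras_tables`` maps profile label -> RASTable (compute them once
    with the expression pipeline).  Sinks/demands are blocked and
    medium bounds applied per medium; an infeasible cell is recorded as
    biomass 0 with ``feasible = False``.
    """
    grid = [float(a) for a in alpha_grid]
    if any(a <= 0 for a in grid):
        raise ValueError("alpha grid must be positive")
    if sorted(grid) != grid:
        raise ValueError("alpha grid must be sorted ascending")
    base, _ = block_sinks_and_demands(gem)
    rows = []
    for medium in media:
        murd = block_nonmedium_uptakes(base, medium)
        murd = apply_murs(murd, compute_mur(medium))
        for label, ras in ras_tables.items():
            for alpha in grid:
                constrained = apply_ras_bounds(murd, ras, alpha)
                sol = fba(constrained)
                feasible = sol.optimal
                biomass = sol.objective_value if feasible else 0.0
                rows.append({"alpha": alpha, "medium": medium.name,
                             "profile": label, "biomass": float(biomass),
                             "feasible": feasible})
    frame = pd.DataFrame(rows)
    return AlphaScanResult(frame=frame, grid=tuple(grid))


def select_alpha(scan: AlphaScanResult,
                 converge_set: Iterable[str],
                 dominate_set: Iterable[str],
                 tol: float = 1e-3) -> dict:
    """Pick the largest grid α where ``converge_set`` biomasses coincide.

    Returns a dict with ``alpha`` (or None), plus a per-α diagnostic
    frame.  At the selected α, for every profile, all conditions in
    ``converge_set`` are pairwise equal within relative tolerance
    ``tol`` and each strictly exceeds every condition in
    ``dominate_set``.
    """
    converge = sorted(set(converge_set))
    dominate = sorted(set(dominate_set))
    overlap = set(converge) & set(dominate)
    if overlap:
        raise ValueError(f"converge and dominate sets overlap: {overlap}")
    f = scan.frame
    diag_rows = []
    selected = None
    for alpha in sorted(scan.grid, reverse=True):
        ok = True
        for profile in f["profile"].unique():
            sub = f[(f["alpha"] == alpha) & (f["profile"] == profile)]
            conv = sub[sub["medium"].isin(converge)]["biomass"]
            domi = sub[sub["medium"].isin(dominate)]["biomass"]
            if len(conv) < len(converge) or len(domi) < len(dominate):
                raise ValueError("scan does not cover the requested conditions")
            spread = float(conv.max() - conv.min())
            scale = max(abs(float(conv.max())), 1e-12)
            converged = spread <= tol * scale or math.isinf(tol)
            dominated = (float(conv.min()) > float(domi.max())) \
                if len(domi) else True
            diag_rows.append({"alpha": alpha, "profile": profile,
                              "rel_spread": spread / scale,
                              "converged": converged, "dominates": dominated})
            if not (converged and dominated):
                ok = False
        if ok and selected is None:
            selected = alpha
    return {"alpha": selected, "diagnostics": pd.DataFrame(diag_rows)}


@dataclass
class GrowthObservation:
    """Cell counts over time and the derived specific growth rate."""

    times_h: tuple[float, ...]
    counts: tuple[float, ...]
    rate_per_h: float = field(init=False)
    nongrowing: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.rate_per_h, self.nongrowing = _fit_growth_rate(
            self.times_h, self.counts)


def growth_rate_from_counts(times_h: Sequence[float],
                            counts: Sequence[float]) -> GrowthObservation:
    """Growth rate as the reciprocal doubling time of a linear count fit.

    A least-squares line ``N(t) = a + b·t`` is fitted; the doubling
    time is read as ``a / b`` (the time needed to add the intercept's
    worth of cells), so the rate is ``b / a`` per hour.  A flat or
    declining fit (b <= 0) yields rate 0 with the ``nongrowing`` flag.
    """
    return GrowthObservation(times_h=tuple(float(t) for t in times_h),
                             counts=tuple(float(c) for c in counts))


def _fit_growth_rate(times: Sequence[float],
                     counts: Sequence[float]) -> tuple[float, bool]:
    t = np.asarray(times, dtype=float)
    n = np.asarray(counts, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.any(n <= 0):
        raise ValueError("counts must be positive")
    b, a = np.polyfit(t, n, 1)
    # slope indistinguishable from zero at double precision counts as flat
    slope_floor = 1e-10 * float(np.mean(n)) / float(t[-1] - t[0])
    if b <= slope_floor or a <= 0:
        return 0.0, True
    return float(b / a), False
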