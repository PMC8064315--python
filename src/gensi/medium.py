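"""Medium composition -> Maximal Uptake Rates (MUR) -> exchange bounds.

The maximal uptake rate of an extracellular nutrient is the largest
amount of it a culture could possibly consume over the experiment:

    MUR_j = |[S_j](t1) - [S_j](t0)| / (t1 - t0)

By default the final concentration is assumed zero (everything offered
could be taken up), so MUR_j is numerically the starting concentration,
reported per culture duration (a 25 mM nutrient over a 48 h culture has
MUR 25 mM/2d).  All fluxes downstream are on this mM-per-duration
scale.  A MUR enters the model as the exchange lower bound ``-MUR``
(uptake-negative sign convention); a metabolite absent from the medium
gets MUR 0, which closes its uptake but does not block its transport
reaction — transport flux is zero for lack of substrate, not by bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .model import GEMModel

#: Default culture duration in hours (two days).
DEFAULT_DURATION_H = 48.0


@dataclass
class MediumSpec:
    """A named medium formulation.

    concentrations maps extracellular metabolite id -> mM at t0;
    ``duration_h`` is the culture span the rates refer to.
    """

    name: str
    concentrations: dict[str, float]
    duration_h: float = DEFAULT_DURATION_H

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ValueError("duration must be > 0")
        for met, conc in self.concentrations.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {met!r}")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "",
                 duration_h: float = DEFAULT_DURATION_H) -> "MediumSpec":
        df = pd.read_csv(path, sep="\t")
        met_col, conc_col = df.columns[:2]
        conc = dict(zip(df[met_col].astype(str), df[conc_col].astype(float)))
        return cls(name=name or Path(path).stem, concentrations=conc,
                   duration_h=duration_h)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"metabolite_id": list(self.concentrations),
                      "concentration_mM": list(self.concentrations.values())}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class MURTable:
    """Maximal uptake rates: exchange metabolite id -> mM per duration."""

    rates: dict[str, float]
    duration_h: float = DEFAULT_DURATION_H
    name: str = ""

    def __post_init__(self) -> None:
        for met, rate in self.rates.items():
            if rate < 0:
                raise ValueError(f"negative MUR for {met!r}")

    def get(self, metabolite_id: str) -> float:
        """Rate for a metabolite; absent means 0 (not in the medium)."""
        return self.rates.get(metabolite_id, 0.0)


def compute_mur(medium: MediumSpec,
                final_concentrations: Mapping[str, float] | None = None
                ) -> MURTable:
    """Convert a medium formulation into maximal uptake rates.

    With the default full-depletion assumption (final concentration 0)
    the rate equals the starting concentration, on the mM-per-duration
    scale.  Per-metabolite final concentrations may be supplied for the
    general (partial-depletion) form.
    """
    finals = dict(final_concentrations or {})
    rates = {}
    for met, c0 in medium.concentrations.items():
        c1 = finals.get(met, 0.0)
        rates[met] = abs(c0 - c1)
    return MURTable(rates=rates, duration_h=medium.duration_h,
                    name=medium.name)


def apply_murs(model: GEMModel, murs: MURTable) -> GEMModel:
    """Set exchange lower bounds to -MUR; close uptake of everything else.

    Export (upper) bounds are untouched.  Metabolites in the table
    without an exchange reaction are ignored with a warning from
    :func:`gensi.model.block_nonmedium_uptakes` semantics; a table entry
    naming a non-exchange reaction id is an error.
    """
    import logging

    logger = logging.getLogger(__name__)
    constrained = model.copy()
    exchange_ids = set(constrained.reaction_ids("exchange"))
    seen: set[str] = set()
    for met_id, rate in murs.rates.items():
        if met_id in constrained.kinds and met_id not in exchange_ids:
            raise ValueError(
                f"MUR entry {met_id!r} names a non-exchange reaction")
        rxn = constrained.exchange_for(met_id)
        if rxn is None:
            logger.warning("MUR metabolite %r has no exchange reaction", met_id)
            continue
        rxn.lower_bound = -float(rate)
        seen.add(rxn.id)
    for rid in exchange_ids - seen:
        rxn = constrained.cobra_model.reactions.get_by_id(rid)
        if rxn.lower_bound < 0:
            rxn.lower_bound = 0.0
    return constrained


def load_media_panel(path: str | Path) -> list[MediumSpec]:
    """Read a YAML panel of named media.

    Layout::

        duration_h: 48
        media:
          NA1: {glc_e: 25.0, gln_e: 4.0, phe_e: 10.0, o2_e: 3.0}
          ...
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    duration = float(doc.get("duration_h", DEFAULT_DURATION_H))
    return [MediumSpec(name=name, concentrations={k: float(v) for k, v in conc.items()},
                       duration_h=duration)
            for name, conc in doc["media"].items()]


def save_media_panel(media: list[MediumSpec], path: str | Path) -> None:
    doc = {
        "duration_h": media[0].duration_h if media else DEFAULT_DURATION_H,
        "media": {m.name: dict(m.concentrations) for m in media},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
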