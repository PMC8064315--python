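"""Deterministic toy fixtures: a small GEM plus matched synthetic data.

The toy network is a minimal cancer-cell carbon/energy metabolism:
glucose transport and glycolysis (an AND complex) feeding pyruvate,
lactate dehydrogenase (an OR isozyme pair), lumped glutaminolysis,
lumped oxidative phosphorylation (an AND complex), an essential
amino-acid (phenylalanine) supply, and a biomass pseudo-reaction that
consumes phenylalanine and ATP.  All stoichiometry is integer.  Carbon
bookkeeping is exact by construction: every glucose can become
``lactate_per_glucose`` lactates and every glutamine
``lactate_per_glutamine`` lactate, so at full nutrient uptake the
maximal lactate efflux is ``2·MUR_glc + 1·MUR_gln`` under the default
yields.

The synthetic expression profile carries fixed per-gene TPMs for the
model genes (chosen so the α-scan reproduces the qualitative regimes of
the full-scale analysis: a high-α plateau set by uptake rates, a low-α
regime where a gene-bounded step — phenylalanine transport — limits all
glucose-containing media equally) plus a log-normal background gene
population with median ~1 TPM.  Zero inflation is emulated by forcing a
seeded subset of below-median genes to TPM 0; the matched microarray
table mirrors the true expression on a different scale, so the
zero-rescue step restores the forced zeros exactly.

Media NA1–NA6 vary glucose/glutamine as (25, 4), (25, 0), (5.6, 4),
(5.6, 0), (0, 4), (0, 0) mM over 48 h, on a fixed background of
phenylalanine and oxygen.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import cobra
import numpy as np
import pandas as pd

from .expression import ExpressionProfile, MicroarrayProfile
from .medium import DEFAULT_DURATION_H, MediumSpec, save_media_panel
from .model import DEFAULT_BOUND, GEMModel, save_gem

#: ATP (and water) consumed per unit biomass flux.
ATP_PER_BIOMASS = 5
#: O2 consumed per pyruvate oxidized; CO2 produced likewise.
O2_PER_PYR = 3
#: CO2 released per glutamine entering glutaminolysis (C5 -> C3 + 2 CO2).
CO2_PER_GLN = 2
#: Lipid consumed per unit biomass flux when the dead-end variant is on.
LIPID_PER_BIOMASS = 1

#: Designed TPM values for the model genes (the "truth" the synthetic
#: RNA-seq and microarray tables are generated from).
TOY_GENE_TPMS = {
    "gGLUT1": 50.0,   # glucose transporter
    "gHK1": 40.0,     # glycolysis complex subunit
    "gPFKL": 30.0,    # glycolysis complex subunit (limiting)
    "gLDHA": 60.0,    # lactate dehydrogenase isozyme
    "gLDHB": 10.0,    # lactate dehydrogenase isozyme
    "gASCT2": 6.0,    # glutamine transporter
    "gGLS": 2.0,      # glutaminolysis
    "gCOX4": 1.5,     # oxphos complex subunit
    "gNDUFA1": 1.0,   # oxphos complex subunit (limiting)
    "gLAT1": 10.0,    # phenylalanine transporter
    "gFASN": 20.0,    # acyl-CoA synthesis (dead-end variant only)
}

#: Glucose/glutamine (mM) of the six media, mirroring a standard
#: DMEM-variation panel.
MEDIA_GLC_GLN = (
    ("NA1", 25.0, 4.0),
    ("NA2", 25.0, 0.0),
    ("NA3", 5.6, 4.0),
    ("NA4", 5.6, 0.0),
    ("NA5", 0.0, 4.0),
    ("NA6", 0.0, 0.0),
)


@dataclass(frozen=True)
class ToyConfig:
    """Parameters of the toy fixture family."""

    seed: int = 0
    glycolysis_atp_yield: int = 2
    oxphos_atp_yield: int = 15
    lactate_per_glucose: int = 2
    lactate_per_glutamine: int = 1
    zero_fraction: float = 0.1
    n_background_genes: int = 50
    with_lipid_deadend: bool = False
    with_boundary_extras: bool = False
    background_phe_mM: float = 10.0
    background_o2_mM: float = 3.0

    def __post_init__(self) -> None:
        if min(self.glycolysis_atp_yield, self.oxphos_atp_yield,
               self.lactate_per_glucose, self.lactate_per_glutamine) <= 0:
            raise ValueError("yields and lactate ratios must be positive")
        if not 0 <= self.zero_fraction < 1:
            raise ValueError("zero_fraction must lie in [0, 1)")

    @property
    def expected_reaction_count(self) -> int:
        n = 20
        if self.with_boundary_extras:
            n += 2
        if self.with_lipid_deadend:
            n += 2
        return n


def _met(mid: str) -> cobra.Metabolite:
    return cobra.Metabolite(mid, compartment=mid.rsplit("_", 1)[-1])


def make_toy_gem(config: ToyConfig = ToyConfig()) -> GEMModel:
    """Build the toy genome-scale model.

    With ``with_lipid_deadend`` the biomass additionally requires a
    lipid species whose acyl-pool precursors (Rtotal analogues) have no
    synthesis route — biomass is infeasible until
    :func:`gensi.model.patch_lipid_pool` merges the pools and adds the
    pooling reaction.  ``with_boundary_extras`` adds one sink (a hidden
    phenylalanine source when open) and one demand reaction to exercise
    the sink/demand blocking patch.
    """
    gy = config.glycolysis_atp_yield
    oy = config.oxphos_atp_yield
    lpg = config.lactate_per_glucose
    lpq = config.lactate_per_glutamine

    cm = cobra.Model("gensi_toy")
    mets = {m: _met(m) for m in (
        "glc_e", "gln_e", "phe_e", "lac_e", "pyr_e", "o2_e", "co2_e",
        "glc_c", "gln_c", "phe_c", "lac_c", "pyr_c", "o2_c", "co2_c",
        "atp_c", "adp_c", "pi_c", "h2o_c", "h_c")}
    cm.add_metabolites(list(mets.values()))

    def add(rid, stoich, lb, ub, gpr=""):
        rxn = cobra.Reaction(rid)
        rxn.bounds = (lb, ub)
        cm.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in stoich.items()})
        if gpr:
            rxn.gene_reaction_rule = gpr
        return rxn

    B = DEFAULT_BOUND
    # exchanges: positive flux = secretion, negative = uptake
    add("EX_glc", {"glc_e": -1}, -B, B)
    add("EX_gln", {"gln_e": -1}, -B, B)
    add("EX_phe", {"phe_e": -1}, -B, B)
    add("EX_lac", {"lac_e": -1}, -B, B)
    add("EX_pyr", {"pyr_e": -1}, -B, B)
    add("EX_o2", {"o2_e": -1}, -B, 0)       # not exportable
    add("EX_co2", {"co2_e": -1}, -B, B)
    add("EX_h", {"h_c": -1}, 0, B)          # proton venting, export only
    # transports
    add("GLCt", {"glc_e": -1, "glc_c": 1}, 0, B, "gGLUT1")
    add("GLNt", {"gln_e": -1, "gln_c": 1}, 0, B, "gASCT2")
    add("PHEt", {"phe_e": -1, "phe_c": 1}, 0, B, "gLAT1")
    add("LACt", {"lac_c": -1, "lac_e": 1}, -B, B)
    add("PYRt", {"pyr_c": -1, "pyr_e": 1}, 0, B)
    add("O2t", {"o2_e": -1, "o2_c": 1}, 0, B)
    add("CO2t", {"co2_c": -1, "co2_e": 1}, -B, B)
    # pathway
    add("GLYC", {"glc_c": -1, "adp_c": -gy, "pi_c": -gy,
                 "pyr_c": lpg, "atp_c": gy, "h2o_c": gy},
        0, B, "gHK1 and gPFKL")
    add("LDH", {"pyr_c": -1, "lac_c": 1}, -B, B, "gLDHA or gLDHB")
    # no net substrate-level ATP: surplus ATP would have no sink (the
    # model carries no maintenance ATPase by design)
    add("GLNLYS", {"gln_c": -1, "pyr_c": lpq, "co2_c": CO2_PER_GLN},
        0, B, "gGLS")
    add("OXPHOS", {"pyr_c": -1, "o2_c": -O2_PER_PYR, "adp_c": -oy,
                   "pi_c": -oy, "co2_c": O2_PER_PYR, "atp_c": oy,
                   "h2o_c": oy},
        0, B, "gCOX4 and gNDUFA1")
    biomass_stoich = {"phe_c": -1, "atp_c": -ATP_PER_BIOMASS,
                      "h2o_c": -ATP_PER_BIOMASS,
                      "adp_c": ATP_PER_BIOMASS, "pi_c": ATP_PER_BIOMASS}

    if config.with_lipid_deadend:
        extra = {m: _met(m) for m in (
            "acylst_c", "acylpa_c", "acylol_c", "acyloc_c",
            "rtot_c", "rtot2_c", "rtot3_c", "lipid_c")}
        cm.add_metabolites(list(extra.values()))
        mets.update(extra)
        add("FASYN", {"pyr_c": -4, "atp_c": -2, "h2o_c": -2,
                      "acylst_c": 1, "acylpa_c": 1, "acylol_c": 1,
                      "acyloc_c": 1, "adp_c": 2, "pi_c": 2},
            0, B, "gFASN")
        # rtot_c / rtot2_c / rtot3_c have no producer: a dead end until
        # the lipid-pool patch is applied.
        add("LIPSYN", {"rtot_c": -1, "rtot2_c": -1, "rtot3_c": -1,
                       "lipid_c": 3}, 0, B)
        biomass_stoich["lipid_c"] = -LIPID_PER_BIOMASS

    add("BIOMASS", biomass_stoich, 0, B)

    if config.with_boundary_extras:
        add("sink_phe_c", {"phe_c": -1}, -B, B)
        add("DM_pyr_c", {"pyr_c": -1}, 0, B)

    cm.objective = "BIOMASS"
    assert len(cm.reactions) == config.expected_reaction_count
    return GEMModel(cm)


def make_toy_expression(config: ToyConfig = ToyConfig(), label: str = "toy"
                        ) -> tuple[ExpressionProfile, MicroarrayProfile]:
    """Matched synthetic RNA-seq and microarray tables.

    The RNA-seq table holds the designed model-gene TPMs plus a seeded
    log-normal background population; ``zero_fraction`` of all genes
    (drawn from the below-median stratum, where dropouts occur) are
    forced to TPM 0.  The microarray reports the true expression of
    every gene on an arbitrary intensity scale, so zero-rescue can
    restore every forced zero.
    """
    rng = np.random.default_rng(config.seed)
    truth = dict(TOY_GENE_TPMS)
    for i in range(config.n_background_genes):
        truth[f"gBG{i:03d}"] = float(np.exp(rng.normal(0.0, 2.0)))
    genes = sorted(truth)
    values = pd.Series({g: truth[g] for g in genes}, dtype=float)

    n_zero = int(round(config.zero_fraction * len(genes)))
    median = float(values.median())
    eligible = sorted(g for g in genes if truth[g] < median and truth[g] > 0)
    n_zero = min(n_zero, len(eligible))
    zeroed = sorted(rng.choice(eligible, size=n_zero, replace=False)) \
        if n_zero else []
    rnaseq = values.copy()
    rnaseq[zeroed] = 0.0

    intensity_scale = 25.0
    microarray = values * intensity_scale

    return (ExpressionProfile(values=rnaseq, label=label),
            MicroarrayProfile(values=microarray))


def make_media_panel(config: ToyConfig = ToyConfig(),
                     duration_h: float = DEFAULT_DURATION_H
                     ) -> list[MediumSpec]:
    """The six-media glucose/glutamine panel NA1–NA6."""
    media = []
    for name, glc, gln in MEDIA_GLC_GLN:
        conc = {
            "glc_e": glc,
            "gln_e": gln,
            "phe_e": config.background_phe_mM,
            "o2_e": config.background_o2_mM,
        }
        media.append(MediumSpec(name=name, concentrations=conc,
                                duration_h=duration_h))
    return media


# -- tiny LP fixtures for oracle cross-checks ------------------------------


def make_mini_fixtures() -> list[GEMModel]:
    """A family of small models (each <= 12 reactions) with varied LP
    structure: linear chains, yield branches, reversible cycles,
    capped internal steps, and a two-substrate biomass.  Used to
    cross-check the FBA/FVA implementation against independent LP
    solvers."""
    fixtures = []

    def build(name, mets, reactions, objective):
        cm = cobra.Model(name)
        mobjs = {m: _met(m) for m in mets}
        cm.add_metabolites(list(mobjs.values()))
        for rid, stoich, lb, ub in reactions:
            rxn = cobra.Reaction(rid)
            rxn.bounds = (lb, ub)
            cm.add_reactions([rxn])
            rxn.add_metabolites({mobjs[m]: c for m, c in stoich.items()})
        cm.objective = objective
        gem = GEMModel(cm)
        assert len(cm.reactions) <= 12
        fixtures.append(gem)

    build("chain", ["a_c", "b_c"], [
        ("EX_a", {"a_c": -1}, -10, 0),
        ("CONV", {"a_c": -1, "b_c": 1}, 0, 1000),
        ("EX_b", {"b_c": -1}, 0, 1000),
    ], "EX_b")

    build("branch", ["s_c", "p_c"], [
        ("EX_s", {"s_c": -1}, -5, 0),
        ("LOWY", {"s_c": -1, "p_c": 2}, 0, 1000),
        ("HIGHY", {"s_c": -1, "p_c": 3}, 0, 2),
        ("EX_p", {"p_c": -1}, 0, 1000),
    ], "EX_p")

    build("cycle", ["a_c", "b_c", "c_c"], [
        ("EX_a", {"a_c": -1}, -4, 0),
        ("AB", {"a_c": -1, "b_c": 1}, -1000, 1000),
        ("BC", {"b_c": -1, "c_c": 1}, -1000, 1000),
        ("CA", {"c_c": -1, "a_c": 1}, -1000, 1000),
        ("EX_c", {"c_c": -1}, 0, 3),
        ("EX_b", {"b_c": -1}, 0, 1000),
    ], "EX_b")

    build("capped", ["s_c", "m_c", "p_c"], [
        ("EX_s", {"s_c": -1}, -8, 0),
        ("S2M", {"s_c": -1, "m_c": 1}, 0, 6),
        ("M2P", {"m_c": -1, "p_c": 1}, 0, 5),
        ("M2P2", {"m_c": -2, "p_c": 1}, 0, 1000),
        ("EX_p", {"p_c": -1}, 0, 1000),
    ], "EX_p")

    build("twosub", ["g_c", "q_c", "e_c", "x_c"], [
        ("EX_g", {"g_c": -1}, -10, 0),
        ("EX_q", {"q_c": -1}, -2, 0),
        ("GE", {"g_c": -1, "e_c": 2}, 0, 1000),
        ("QE", {"q_c": -1, "e_c": 1}, 0, 1000),
        ("GX", {"g_c": -1, "x_c": 1}, 0, 4),
        ("BIOM", {"x_c": -1, "e_c": -3}, 0, 1000),
    ], "BIOM")

    build("reversible", ["a_c", "b_c"], [
        ("EX_a", {"a_c": -1}, -6, 6),
        ("AB", {"a_c": -1, "b_c": 1}, -1000, 1000),
        ("EX_b", {"b_c": -1}, -2, 1000),
    ], "EX_b")

    return fixtures


# -- emission --------------------------------------------------------------


def write_toy_dir(outdir: str | Path, config: ToyConfig = ToyConfig()) -> dict:
    """Emit the toy model (SBML + JSON) and matched TSV/YAML tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gem = make_toy_gem(config)
    save_gem(gem, outdir / "toy_model.xml", "sbml")
    save_gem(gem, outdir / "toy_model.json", "json")
    rnaseq, microarray = make_toy_expression(config)
    pd.DataFrame({"gene": rnaseq.values.index, "tpm": rnaseq.values.values}
                 ).to_csv(outdir / "rnaseq_tpm.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": microarray.values.index,
                  "intensity": microarray.values.values}
                 ).to_csv(outdir / "microarray.tsv", sep="\t", index=False)
    media = make_media_panel(config)
    save_media_panel(media, outdir / "media_panel.yaml")
    for m in media:
        m.to_tsv(outdir / f"medium_{m.name}.tsv")
    return {"model_sbml": str(outdir / "toy_model.xml"),
            "model_json": str(outdir / "toy_model.json"),
            "rnaseq": str(outdir / "rnaseq_tpm.tsv"),
            "microarray": str(outdir / "microarray.tsv"),
            "media_panel": str(outdir / "media_panel.yaml"),
            "n_reactions": config.expected_reaction_count}
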