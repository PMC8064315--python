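# gensi

Simultaneous integration of **gene expression** and **nutrient
availability** into genome-scale metabolic models (GEMs), with FBA/FVA
interrogation of the resulting constrained models.

Constraint-based models predict growth and flux from stoichiometry and
flux bounds alone, but the bounds are where the biology enters.  Two
data sources constrain a cultured cell at once: what its transcriptome
says it *can* catalyze, and what its medium *lets* it take up.  `gensi`
encodes both simultaneously:

- **RAS (Reaction Activity Score).**  Each reaction's gene–protein–
  reaction (GPR) rule is evaluated quantitatively over TPM expression
  values: isozymes (`or`) contribute additively, complex subunits
  (`and`) limit through their minimum.  A reaction catalyzed by a
  single gene scores that gene's TPM; geneless reactions keep default
  bounds (±1000).
- **MUR (Maximal Uptake Rate).**  For each medium nutrient *j*,
  `MUR_j = |[S_j](t1) − [S_j](t0)| / Δt`.  With the default assumption
  that everything offered can be consumed over the culture duration
  (48 h), MUR is numerically the starting concentration in mM per two
  days, and enters as the exchange lower bound `l_j = −MUR_j`.
  Uptake of everything absent from the medium is closed.
- **The scaling factor α.**  RAS (expression scale) and MUR (mM/2d)
  are incommensurate; a single factor converts one into the other:
  every gene-associated reaction *i* is bounded by `b_i = α·RAS_i` in
  each admissible direction.  Scanning α from high (nutrient-limited)
  to low (expression-limited) values and selecting the point where
  growth predictions for designated media converge turns α into the
  model's one fitted parameter.

The constrained **GEM-RAS-MUR** model is then analyzed with FBA
(`max c'V` s.t. `S·V = 0`, bounds) and FVA (per-reaction `[min, max]`
flux while retaining a fraction γ of the optimal biomass `Z0`),
including an ATP-hydrolysis capacity probe that exists only while its
own capacity is being measured.

The package also ships the model-curation patches such an analysis
needs on real reconstructions (blocking sink/demand reactions, closing
non-medium uptakes, merging positional acyl "Rtotal" pools via a
`1+1+1+1 ↔ 4` pooling reaction) and a deterministic toy fixture family
(small GEM + matched synthetic RNA-seq/microarray/media tables) so the
whole pipeline runs and is testable without any downloads.

## Worked example

```python
import numpy as np
import gensi as G

config = G.ToyConfig(seed=0)
gem = G.make_toy_gem(config)
rnaseq, microarray = G.make_toy_expression(config)
media = G.make_media_panel(config)          # NA1..NA6, varying glc/gln

for medium in media:
    gm = G.build_gensi_model(gem, rnaseq, medium, alpha=10.0,
                             microarray=microarray)
    print(f"{medium.name}: max biomass = {G.fba(gm).objective_value:.2f} mM/2d")

na1 = G.build_gensi_model(gem, rnaseq, media[0], alpha=10.0,
                          microarray=microarray)
lo, hi = G.fva(na1, reactions=["EX_lac"]).range("EX_lac")
print(f"NA1 lactate efflux range at max growth: [{lo:.1f}, {hi:.1f}] mM/2d")
```

prints

```
NA1: max biomass = 10.00 mM/2d
NA2: max biomass = 10.00 mM/2d
NA3: max biomass = 5.24 mM/2d
NA4: max biomass = 5.24 mM/2d
NA5: max biomass = 3.00 mM/2d
NA6: max biomass = 0.00 mM/2d
NA1 lactate efflux range at max growth: [0.0, 54.0] mM/2d
```

At this (high) α only the medium limits growth: the two 25 mM-glucose
media are richest, the glutamine-only medium grows slowly, and without
any carbon source there is no growth.  The FVA range says the NA1
model may ferment *all* its carbon — 2 lactate per glucose plus 1 per
glutamine, 2·25 + 4 = 54 mM/2d — or none of it, at the same maximal
growth rate: the in-silico cells are not obligated to the Warburg
effect.  Scanning α downwards and selecting the largest grid value at
which the four glucose-containing media converge while still beating
the glucose-free ones,

```python
adjusted = G.zero_adjust(rnaseq, microarray)
genes = set().union(*(G.gpr_genes(e) for e in gem.gprs.values()))
matched, _ = G.match_genes(genes, adjusted)
ras = G.compute_ras(gem, matched)
scan = G.alpha_scan(gem, {"toy": ras}, media, sorted(np.geomspace(3e-4, 1.6, 31)))
choice = G.select_alpha(scan, ["NA1", "NA2", "NA3", "NA4"], ["NA5", "NA6"], tol=1e-6)
print(f"selected alpha* = {choice['alpha']:.4f}")   # -> 0.2876
```

fixes the expression-to-flux conversion constant for this fixture.

The same pipeline is available from the shell:

```bash
gensi toy --out toyfix/
gensi build --model toyfix/toy_model.json --expression toyfix/rnaseq_tpm.tsv \
      --microarray toyfix/microarray.tsv --medium toyfix/medium_NA1.tsv \
      --alpha 10 --out na1_model.json --provenance bounds.tsv
gensi fva --model na1_model.json --reactions EX_lac,BIOMASS --out fva.tsv
gensi scan --model toyfix/toy_model.json --expression toyfix/rnaseq_tpm.tsv \
      --microarray toyfix/microarray.tsv --media toyfix/media_panel.yaml \
      --out scan.tsv
```

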