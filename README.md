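# cfreserve

**Counterfactual protected-area network design: does it pay to protect the
forest that is actually at risk?**

Protected-area networks worldwide are biased toward "high and far" land —
steep, remote, agriculturally worthless terrain that nobody was going to
clear anyway. `cfreserve` implements a counterfactual comparison of two
philosophies for expanding a reserve network in a tropical forest landscape:

* **proactive** design: place new reserves where forest loss is imminent,
  so protection averts real loss;
* **expedient** design: place new reserves where loss risk (and hence cost)
  is low, so protection is cheap but often redundant.

Seven scenarios are compared — a no-loss baseline, proactive and expedient
designs that either retain or redistribute the existing network, the
existing network alone, and business-as-usual with ineffective reserves —
by their consequences for habitat connectivity, forest carbon, and the
demography and genetic diversity of a forest carnivore (modelled on the
Sunda clouded leopard, *Neofelis diardi*).

## The model chain

1. **Landscape.** A seeded synthetic generator produces co-registered
   rasters (elevation, land cover, loss risk, above-ground biomass, a
   protected-area mask, movement resistance) with the empirical joint
   structure the question presumes: loss risk `p = logistic(β₀ + β₁·z(elev)
   + β₂·z(dist to non-forest) + β₃·PA)` with β₁, β₂, β₃ < 0, and reserves
   biased to high, low-risk terrain. Real rasters (ESRI ASCII grids) can be
   substituted at any stage.
2. **Prioritisation.** Planning units aggregate the cell layers; a
   simulated-annealing selector minimises
   `Σ cost + BLM·boundary + Σ_f SPF·(shortfall_f/target_f)·G_f`
   with 30% targets per conservation feature, SPF = 2, BLM = 0.0015.
   Selection frequency across runs ranks units; the top 17% of the grid
   (locked units first) is the design.
3. **Loss update.** Outside each scenario's effectively protected cells,
   expected loss raises resistance, `r' = r + p·r_plantation`, and shrinks
   carbon, `c' = c·(1 − p)`; protected cells keep baseline values
   (no-leakage assumption).
4. **Connectivity.** Resistant kernels `K(x) = Σ_s max(0, 1 −
   cost_s(x)/bandwidth)` from lattice source points (least-cost Dijkstra
   costs, 8-neighbour, edge weight = step length × mean resistance);
   thresholded at the 10th percentile of positive density into core
   habitat; summarised by PLAND, NP, LPI, area-weighted mean patch size and
   correlation length (GYRATE_AM).
5. **Genetics.** A CDPOP-style individual-based simulation on fixed
   home-range points (one occupant each): cost-distance-weighted mating,
   Poisson broods, nearest-unoccupied-point dispersal within a cost budget,
   non-overlapping generations, no mutation. In the panmictic limit
   heterozygosity decays as Wright–Fisher, `H_t = H_0 (1 − 1/(2N))^t`.

## Worked example

```python
from cfreserve import PipelineConfig, relative_change, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
for s in (2, 3, 4, 5):
    print(f"S{s}: {relative_change(report, 'pland', s, 7):+.0f}%")
```

prints, for one 64 × 64 desk-scale landscape (percent of landscape
connected by dispersal, relative to business-as-usual):

```
S2: +27%
S3: +16%
S4: +12%
S5: +13%
```

Both proactive scenarios (S2, S3) out-perform their expedient counterparts
(S4, S5), and redistribution beats retention for the proactive approach —
the expedient designs largely re-protect forest that would have survived
anyway. The same run reports carbon stocks (baseline 0.0121 Gt falling to
0.0098 Gt under business-as-usual), patch structure, and final
heterozygosity, allele counts and population size from the genetic
simulation. `examples/` contains one narrative script per capability; a
thin CLI (`cfr generate|validate|select|run|report`) wraps the same
functions for shell use.

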