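# ciliatecomm

Community-ecology pipeline for **soil ciliate morphospecies surveys** —
the kind of dataset produced by non-submerged culture, live observation
and protargol staining of soils sampled across habitats and seasons:
a samples × species table of individual counts, a four-rank taxonomy,
and per-sample soil physicochemistry (SWC, pH, TN, SOM, AP, RAK, ST).

It is aimed at protistologists and soil ecologists who want the standard
analysis chain for such surveys as tested, scriptable building blocks
rather than a one-off R session:

- **α diversity** — Shannon–Wiener `H = −Σ (nᵢ/N) ln(nᵢ/N)` and Margalef
  `D = (S−1)/ln N`, per sample and as group means, with permutation/ANOVA
  group comparisons.
- **C/P bioindication** — the ratio of Colpodea species (r-selected
  colonisers of harsh soils) to Spirotrichea + Heterotrichea + Armophorea
  species (k-selected residents of stable soils); C/P ≤ 1 indicates a
  relatively benign soil habitat.
- **β diversity** — Bray–Curtis dissimilarity `d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ)`,
  non-metric multidimensional scaling (Kruskal stress-1, multi-restart),
  PERMANOVA.
- **Co-occurrence networks** — signed Spearman/Pearson correlation networks
  (|r| and BH-adjusted p thresholds), modularity-based module detection, and
  the standard topology panel (average degree 2E/N, density, clustering,
  mean path length over connected pairs, sign ratios).
- **Zi–Pi keystone analysis** — within-module degree z-score
  `Zᵢ = (Kᵢ − K̄)/σ_K` and participation coefficient
  `Pᵢ = 1 − Σₛ (K_is/kᵢ)²`; nodes with Zᵢ > 2.5 and/or Pᵢ > 0.62 are module
  hubs, connectors or network hubs — the keystone candidates.
- **Environmental drivers** — per-factor Mantel tests and distance-decay
  regressions against geographic (haversine) and environmental distances,
  with permutation significance throughout.
- **Neutral-community-model inference** — the Sloan occurrence-frequency
  fit `freq(p) = 1 − BetaCDF(d; Nm·p, Nm·(1−p))`, estimating the migration
  rate m by least squares and reporting Nm, R² and the fraction of species
  inside the 95 % envelope, to weigh stochastic against deterministic
  assembly.

A **synthetic survey generator** (`ciliatecomm.simulate`) produces
abundance/environment/metadata tables with known truth — Dirichlet-
multinomial neutral sampling at chosen N·m over a log-series
metacommunity, optionally warped by Gaussian SWC niche filtering — so
every stage is testable end to end without access to any particular
field campaign. A packaged fixture
(`ciliatecomm.datasets`) carries a published basin-wide composition table
(199 species, 89 genera, 66 family rows) for exercising the composition
and C/P machinery against printed totals.

## Worked example

```bash
python analysis/01_simulate.py
python analysis/04_beta_diversity.py
python analysis/07_neutral_model.py
```

prints (seeds fixed in the scripts):

```
sim_neutral: 60 samples x 200 species, fill 30.3%, true m=0.1, filter=0.0
sim_filtered: 60 samples x 200 species, fill 26.7%, true m=0.1, filter=6.0
NMDS k=2: stress = 0.132 (< 0.3, usable ordination)
PERMANOVA by ecosystem: pseudo-F = 10.94, p = 0.001
PERMANOVA by season: pseudo-F = 0.64, p = 0.876
sim_neutral: m = 0.101 (true 0.1), Nm = 101, R2 = 0.984, 85% of species inside the 95% envelope
sim_filtered: m = 0.074 (true 0.1), Nm = 74, R2 = 0.969, 85% of species inside the 95% envelope
```

Reading: the filtered survey ordinates cleanly (stress 0.13) and separates
by habitat but not by season, exactly as designed; the neutral fit recovers
the generating migration rate on neutral data and loses fit quality once
SWC filtering (a deterministic process) shapes the communities.

The numbered scripts under `analysis/` run the full chain (composition and
shared species, α, β, networks + keystones, environmental drivers, neutral
model), writing their tables under `results/`. The same stages are exposed
as a CLI (`ciliatecomm simulate|diversity|beta|network|keystone|drivers|ncm|run-all|fixtures`)
and as plain library calls; `ciliatecomm run-all --config cfg.yaml`
executes everything from one seeded YAML config into a single
deterministic report.

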