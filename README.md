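# inclusion-screen

Analysis pipeline for arrayed high-content imaging screens of fluorescent
protein inclusions (aggregates) in yeast, plus the companion assays used to
characterize hits. Everything runs on synthetic data with planted ground
truth, so the full chain is testable end to end with no external downloads.

Stages:

1. **synthetic** (`inclusion_screen.synthetic`) — renders 16-bit plate
   images (yeast-sized discs over a vignetted background; diffuse vs
   punctate phenotype per cell, Bernoulli-planted per strain), growth
   curves, gene→term annotation tables, and interaction edge lists, all
   deterministic in their seed and accompanied by exact ground truth.
2. **quantify** (`inclusion_screen.quantify`) — shade correction,
   background estimation, cell isolation at ≥300 grayscale units over local
   background, inclusion isolation at ≥400 units over the per-cell diffuse
   level, per-cell records and per-well phenotypes (% cells with
   inclusions, mean cellular intensity, QC gate).
3. **screen_stats** (`inclusion_screen.screen_stats`) — hit calling with
   three rules: two-sample Student's *t* on replicate inclusion
   percentages (P ≤ 0.05), a minimum effect of 25% (relative to the
   wild-type percentage by default; `absolute_points` mode also
   available), and no significant intensity change — strains failing the
   third rule are routed to an `expression_confounded` category.
   Also: WT-anchored normalization (WT = 50%), manual-confirmation rate,
   and the screening-collection background registry.
4. **enrichment** (`inclusion_screen.enrichment`) — hypergeometric
   upper-tail term enrichment against an explicit gene universe, Bonferroni
   (default) or resampling correction, relative/background frequencies and
   fold enrichment.
5. **network** (`inclusion_screen.network`) — physical-interaction-only
   subnetworks over hit genes (genetic edges filtered), connected-component
   modules, GraphML/SIF exports. Reads plain 3-column TSV or BioGRID
   TAB 3.0 headers.
6. **growth** (`inclusion_screen.growth`) — generation time as the
   reciprocal of the steepest sliding-window log2-linear slope of
   blank-subtracted OD curves (30-min sampling over 72 h), and the
   toxicity contrast: replicate-wise excess generation time of the fusion
   construct vs the expression control, mutant vs wild type, Student's *t*.

## CLI

```sh
# fully synthetic end-to-end run (simulate → quantify → call-hits →
# enrich → network → growth), config optional:
inclusion-screen run --out pipeline_out
inclusion-screen run --config my_config.toml

# individual stages:
inclusion-screen simulate  --out fixture --seed 1
inclusion-screen quantify  --images fixture/simulated/images \
                           --platemap fixture/simulated/platemap.csv \
                           --cell-delta 300 --inclusion-delta 400 --out out
inclusion-screen call-hits --wells out/wells.tsv --wt-strain WT \
                           --alpha 0.05 --min-effect 25 --out out
inclusion-screen enrich    --hits out/hits.tsv --annotation ann.tsv \
                           --universe universe.tsv --out out
inclusion-screen network   --hits out/hits.tsv --edges edges.tsv --out out
inclusion-screen growth    --od growth.csv --platemap growth_map.csv --out out
```

Config is TOML; every CLI flag overrides its config value. Defaults follow
the assay parameters: cell threshold 300, inclusion threshold 400,
α = 0.05, minimum effect 25%, OD sampling 0.5 h over 72 h.

Note on the 25% effect cutoff: the default interpretation is *relative to
the wild-type percentage* (|pct_mut − pct_wt| / pct_wt ≥ 25%); pass
`--effect-mode absolute_points` for a percentage-point reading.

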