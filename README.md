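# thiastat

Functional thiamine (B1) / riboflavin (B2) status analysis for erythrocyte
enzyme panels, built around transketolase activation kinetics:

1. **assay** — raw kinetic rates (ΔA340/min, triplicates) → specific
   activities (U/mg, ε = 6.22 mM⁻¹cm⁻¹) → activation indices
   (PAR, FAR, SAR, SAD, latency).
2. **age_models** — linear and pseudo-first-order exponential age trends
   (`value = value₀·e^(−kt)`, half-life = ln 2 / k, fitted on log values) and
   age normalization (observed / regression-predicted).
3. **distributions** — maximum-likelihood fits of a catalog (Normal,
   LogNormal, Exponential, Gamma, Weibull, sinh-arcsinh "SHASH",
   2- and 3-component normal mixtures) ranked by small-sample-corrected
   AICc.
4. **tolerance** — one-sided tolerance limits used as cutoffs: exact
   noncentral-t parametric-normal factors, and distribution-free
   order-statistic limits (binomial rule); parametric is used iff the AICc
   winner is Normal.
5. **classify** — per-animal deficiency calls over eight markers
   (age-normalized basal TKT, TKT+TDP and GR, plus PAR/latency/FAR/SAR/SAD),
   with low-TDP vs high-TDP B1 subtypes and a B2 route via GR.
6. **cluster** — endophenotype discovery: median/MAD standardization, Ward
   linkage (within-cluster-SS heights, deterministic tie-breaks), cluster
   count by Sarle's cubic clustering criterion.
7. **simulate** — a synthetic cohort generator (truncated 3-component age
   mixture, discretized SHASH body-condition scores, exponential activity
   decline at configurable half-lives, planted deficiency endophenotypes)
   so the whole pipeline is testable offline.

## CLI

```sh
# synthetic cohort (precomputed-activity schema + truth_* columns)
thiastat simulate --out cohort.csv --seed 7

# single stages
thiastat indices    --input cohort.csv --out indices.csv
thiastat thresholds --input cohort.csv --out thresholds.csv
thiastat classify   --input cohort.csv --out calls.csv
thiastat cluster    --input cohort.csv --out cluster_out/

# full pipeline -> report bundle (indices.csv, fits.json,
# distribution_ranking.csv, thresholds.csv, calls.csv, clusters.csv,
# ccc_curve.csv, cluster_summary.csv, summary.md, config.json)
thiastat run --synthetic --seed 7 --out bundle/
thiastat run --input cohort.csv --out bundle/ --content 0.90 --confidence 0.95
```

Runs are deterministic: the same inputs and `--seed` reproduce every output
byte for byte.

### Input schema

`cat_id, sex {F,M}, age_years, bcs (1–9)` plus either raw kinetics
(`tkt_rate_{0|03|3}_rep{1..3}, gr_rate_rep{1..3}, protein_mg_ml, dilution`)
or precomputed activities
(`stkt_u_mg, tkt_tdp03_u_mg, tkt_tdp3_u_mg, gr_u_mg`). Empty cells are
missing values.

## Conventions worth knowing

- Latency defaults to percent stimulation `100·(a03−a0)/a0`
  (`--latency-formula stimulated` switches the denominator to `a03`).
- Cutoff sides default to: lower for age-normalized basal TKT and GR; upper
  for age-normalized TKT+TDP and all activation indices. The upper side for
  age-normalized TKT+TDP is deliberate (it mirrors the published convention)
  even though deficiency lowers the activity itself.
- Comparisons at the cutoff are strict, so a nonparametric cutoff (an
  observed data point) never flags itself.
- Ward merge heights are increases in within-cluster sum of squares (two
  singletons at distance d merge at d²/2).

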