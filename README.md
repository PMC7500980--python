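# mothdrift

Long-term change in moth communities from incidence data: museum vouchers
and standardized light-trap surveys spanning decades are pooled into a
binary species × time-layer matrix, and the package asks whether local
extinction risk is structured by **body size** or by **ecological
specialization**, and whether community composition has shifted
directionally or merely drifted.

It is written for community ecologists working with heterogeneous long-term
occurrence data — the kind where historic decades contribute a pooled
species list and recent survey years contribute one list each — and for
anyone who wants the complete analysis chain reproducible and testable on
synthetic communities with known dynamics.

## What it computes

**Status partition.** Around a cut-year (default 1997), species are
*lost* (recorded only before), *previously unrecorded* (only from the
cut-year on) or *persistent* (both). Phenologically incomparable species
(early/late flyers, long-distance migrants, strictly diurnal) are removed
first via trait-table flags.

**Specialization register.** Three niche dimensions — larval food breadth,
northern distributional limit in Europe, habitat breadth — each scored 1
(specialist) to 4 (generalist); the total spans 3–12.

**Functional dispersion (FDis).** From a 12-trait mixed-type matrix, a
Gower dissimilarity D is embedded by principal coordinates (element-wise
√D correction for non-Euclidean D by default), and each time layer's
dispersion is the weighted mean distance to the weighted centroid:

    c = Σ aⱼxⱼ / Σ aⱼ,   zⱼ = ‖xⱼ − c‖,   FDis = Σ aⱼzⱼ / Σ aⱼ

with aⱼ = 1 for present species under incidence data. FDis reads as mean
functional specialization of the community.

**Models.** Penalized-spline GAM trends of community metrics over layer
midpoint years; a linear mixed model log(wingspan) ~ status with a
taxonomic-family random intercept (Nakagawa–Schielzeth marginal and
conditional R²); Poisson mixed models for the specialization scores; and
Sørensen-dissimilarity NMDS of time layers with envfit-style permutation
tests (999 permutations) of community descriptors.

**Scenario simulators.** Synthetic 300-species pools with occupancy
evolving as extinction/colonization Markov chains under four scenarios:
`neutral` (stationary drift), `size_filter` (extinction log-odds rise with
log wingspan), `succession` (open-habitat guild declines, forest
colonization rises) and `generalization` (late colonists' traits shrink
toward the pool centroid). These give every statistical claim a test-bed
with known truth. See `docs/methods.md` for the full model account.

## Worked example

Simulate a community undergoing succession-driven loss of the open-habitat
guild, analyze it, and summarize:

```text
$ mothdrift simulate --scenario succession --seed 42 --n-species 300 --out demo_sim
wrote synthetic succession community (300 species) to demo_sim

$ mothdrift analyze --occurrences demo_sim/occurrences.csv \
    --traits demo_sim/traits.csv --scheme demo_sim/scheme.yaml --out demo_out
{"status_counts": {"persistent": 127, "previously_unrecorded": 52, "lost": 40}, "out_dir": "demo_out"}

$ mothdrift report --dir demo_out
stages: records, traits, funcdiv, community_trends, ordination
status counts: {'persistent': 127, 'previously_unrecorded': 52, 'lost': 40}
wingspan_status_model: coefficient=-0.103 statistic=-1.47 p=0.1406
fdis_trend: coefficient=-0.883 statistic=-4.95 p=0.0002
specialization_trend: coefficient=+0.704 statistic=3.13 p=0.0107
envfit log_mean_wingspan: R2=0.498 p=0.0370
envfit mean_total_specialization: R2=0.536 p=0.0300
envfit logit_prop_open: R2=0.867 p=0.0010
```

Reading the output: of 219 species ever observed, 40 were lost and 52 are
new since the cut-year. The wingspan status model finds no body-size
structure in the losses (p = 0.14) — correctly, since this scenario filters
by habitat, not size. FDis declines strongly and significantly over the 12
layers (standardized trend coefficient −0.88, p < 0.001): the community
contracts in trait space as the open-habitat guild disappears, exactly the
functional-homogenization signature the scenario encodes. The ordination's
strongest descriptor is the logit proportion of open-habitat species
(R² = 0.87, p = 0.001, the minimum attainable with 999 permutations).

Outputs land in `demo_out/`: `incidence.csv`, `status.csv`,
`community_timeseries.csv`, `ordination_coords.csv`, `model_fits.json` and
a `manifest.json` recording seeds, options, warnings and output checksums
(re-running the same config reproduces them bit-for-bit).

The same pipeline runs on real data: point `--occurrences`, `--traits` and
`--scheme` at your own CSV/YAML files (column mapping is configurable), or
put everything in a YAML file and use `mothdrift analyze --config run.yaml`.
`mothdrift expect` replicates a scenario many times and reports summary
rates.

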