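# Cohort CSV column dictionary

One row per analyzed vessel (the per-vessel analysis unit). Files begin
with `#`-prefixed provenance lines (`seed`, `config_hash`).

| column | unit | meaning |
|---|---|---|
| `vessel_id` | — | unique vessel identifier (`V0000`, …) |
| `vessel_label` | — | coronary territory: `LAD`, `LCX` or `RCA` |
| `ct_ffr` | — | computed FFR 25 mm distal to the target lesion under the frozen boundary parameters, in (0, 1] |
| `measured_ffr` | — | emulated invasive FFR (reference model + per-vessel microvascular variability + measurement noise), in (0, 1] |
| `cta_percent_stenosis` | % | noisy CTA reading of diameter stenosis, in [0, 100) |
| `cta_ge_50` | bool | CTA reading ≥ 50% (the angiographic positivity rule) |
| `cta_ge_70` | bool | CTA reading ≥ 70% |
| `true_degree` | % | generating diameter stenosis of the target lesion (30–90) |
| `lesion_length` | mm | centerline length of the target lesion |
| `plaque_volume` | mm³ | ∫(reference − lumen) area over the lesion |
| `calcified_volume` | mm³ | calcified share of plaque volume |
| `noncalcified_volume` | mm³ | plaque volume minus calcified volume |
| `plaque_burden` | % | plaque volume / total vessel volume over the lesion |
| `lumen_area` | mm² | minimal lumen area over the lesion |
| `lumen_diameter` | mm | minimal lumen diameter over the lesion |
| `calcium_score` | — | dimensionless log-normal surrogate scaled to calcified volume (not an Agatston score) |
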