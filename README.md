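# occurate

**Sensitivity analysis of species-occurrence data curation.**

Large-scale biodiversity patterns are usually estimated from aggregated
occurrence records (GBIF-style Darwin Core tables) that carry coordinate
errors, duplicated specimens, inconsistent taxonomy and wildly uneven
sampling effort. Before analysis these records are *curated* — cleaned,
standardised and filtered — and the curation choices themselves can change
the scientific conclusion. `occurate` packages the full chain needed to
measure that sensitivity, aimed at macroecologists and biodiversity
informaticians:

1. **Pre-processing** — record-level exclusion rules (fossil specimens,
   illegitimate collection dates, zero / integer / latitude=longitude
   coordinates, country-mismatch with a 0.1° buffer, country centroids and
   institution locations from a gazetteer, identifications above species
   rank) and aggregation onto a 100-km equal-area grid (EASE-Grid 2.0
   Global, EPSG:6933) cut into 49 latitudinal bands and three regions.
2. **Consensus taxonomy** — raw names are normalised to binomials,
   standardised against five offline reference checklists, and an accepted
   name enters the consensus list when at least 3 of the 5 sources endorse
   it (majority vote).
3. **Curation scenarios** — named filter combinations (duplicate removal
   on species + coordinates + date, with or without the collector;
   preserved specimens only; temporal windows such as ≥1970) applied as
   `date-TNRS`, `date-cons`, `date-specim`, `date-1970`.
4. **Inventory completeness** — per-cell species accumulation curves by
   exact (analytic) rarefaction,

   &nbsp;&nbsp;&nbsp;&nbsp;E[S(m)] = S_obs − Σᵢ C(N−Nᵢ, m) / C(N, m),

   fitted with the rational function S(m) = (a + b·m)/(1 + c·m) whose
   asymptote b/c estimates true richness. A cell is **well-sampled** when
   N ≥ 100 records, completeness = 100·S_obs/(b/c) ≥ 70 %, N/S_obs ≥ 5 and
   the terminal slope of the curve ≤ 0.1 species per record.
5. **Latitudinal gradient** — per-band medians of observed and predicted
   richness over well-sampled cells, fitted with a single-breakpoint
   piecewise (segmented) regression
   y = β₀ + β₁x + β₂(x−ψ)·1[x>ψ]; the breakpoint ψ is read as the
   latitude of peak richness and compared across curation scenarios.

Because the real multi-million-record datasets are unwieldy and
unversioned, the package ships a first-class **synthetic-data generator**:
occurrence worlds with a known piecewise-linear richness gradient, clustered
sampling effort, rectangle countries with known centroids, and every error
class planted and ledgered, so each cleaning rule can be verified to remove
*exactly* what it should.

## Worked example

```python
from occurate import pipeline

cfg = pipeline.RunConfig(seed=1, outdir="run_out")   # synthetic world
report = pipeline.run(cfg)
```

With the default study conditions (~147k generated records including
duplicates and planted errors) this prints, via the run report:

```
pre-processing: 147168 records in, 140136 kept, 7032 removed
taxonomy: 10093 raw names -> 434 consensus species
date-TNRS:   108511 records, 168 well-sampled cells, bp_obs(all)=40.0
date-cons:   111652 records, 169 well-sampled cells, bp_obs(all)=40.0
date-specim:  61303 records,  85 well-sampled cells, bp_obs(all)=38.5
date-1970:    45504 records,  49 well-sampled cells, bp_obs(all)=40.0
```

Reading: pre-processing removed the planted coordinate/date/fossil/rank
errors (~5 % of records); the consensus checklist resolved ~10k raw name
variants to 434 accepted species; each scenario then kept a different
record subset, and the fitted breakpoint of the latitudinal richness
gradient sits at band 40 — the generator's planted richness peak — under
every scenario, with the preserved-specimen scenario slightly south
because it retains about half the data. Per-cell metrics, band series,
discard accounting and the scenario comparison table are written as CSVs
to `run_out/`, plus `run_report.json` with per-stage record conservation.

The same stages are available on the command line:

```sh
occurate generate --seed 1 --out world/
occurate preprocess --in world/occurrences.csv \
    --countries world/countries.geojson --gazetteer world/gazetteer.csv --out pre/
occurate run --seed 1 --out run_out/
```

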