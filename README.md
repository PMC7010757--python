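# macrodiv

Macrogenetic mapping of intraspecific genetic diversity from georeferenced
DNA barcodes — a tested, reusable implementation of the full analysis chain
used to relate per-grid-cell genetic diversity to species diversity and to
environmental and geographic drivers with spatially aware statistics.

## The problem

Barcode repositories hold hundreds of thousands of short mitochondrial
sequences (typically the ~650-bp COI fragment) with collection coordinates.
Aggregated over many species on a common spatial grid, they yield a
*macrogenetic* map: the average intraspecific genetic diversity of a place.
Comparing such a map with species richness and with environmental gradients
asks whether the processes that generate species diversity also shape the
diversity of genes within species — but every step hides statistical traps
(sampling imbalance, shared-site accounting in partial alignments, and
above all spatial autocorrelation, which wrecks naive significance tests).

`macrodiv` implements that chain for researchers in macroecology and
macrogenetics:

1. **Filtering** BOLD-style record tables: marker match, no IUPAC
   ambiguity, length strictly > 500 bp, no singleton species — with a
   per-step survivor report.
2. **Equal-area gridding** on a Behrmann (cylindrical equal-area,
   standard parallel 30°) world grid with 200-km cells.
3. **Nucleotide diversity** per species per cell,

   Π = (1 / n_pairs) Σ_{i<j} k_ij / m_ij,

   with k_ij the differing and m_ij the shared (both non-gap) aligned
   sites of pair (i, j); pairs with ≤ 50% shared sites are discarded.
   Per-cell genetic diversity **GD** is the unweighted mean of Π across
   species, summarized in 10° latitude bands as mean ± sd/√n_cells.
4. **Species richness** per cell from occurrence points via convex-hull
   ranges split across four world quadrants, with optional depth clipping.
5. **Spatial statistics**: Moran's I and correlograms, the modified
   (Dutilleul-corrected) t-test of association between two spatial fields,
   distance-weighted autocovariates, and permutation Moran tests on model
   residuals.
6. **Modelling**: log-transformed standardized GD regressed on
   environmental, geographic (region, spatial autocovariate residual) and
   forced sampling factors, with VIF > 5 screening, AIC-stepwise selection,
   95% CIs, and hierarchical partitioning of explained variance.
7. A **synthetic-data generator** with known ground truth (log-linear
   environmental effects on diversity, region offsets, clustered sampling,
   calibrated star-genealogy sequences), so the whole pipeline is testable
   end-to-end without any download.

## Worked example

```bash
python examples/04_full_analysis.py
```

generates a 336-cell synthetic world (200 species, positive temperature
effect and region offset on log diversity), runs the full analysis, and
prints:

```
cells analysed : 267
median GD      : 0.0111
congruence     : r = 0.420, ess = 40.6 of n = 267, p = 0.0065
selected terms : ['temperature', 'chlorophyll', 'slope', 'C(region)', 'autocor', 's_sequences', 's_species']
temperature    : 0.752 [0.637, 0.868]  (true effect is positive)
adj R^2        : 0.598
relative variance (%):
  temperature   56.2
  chlorophyll    1.4
  slope          5.0
  C(region)     14.8
  autocor        1.3
  s_sequences   11.2
  s_species     10.2
residual Moran : I = -0.033, p = 0.680 (no leftover spatial structure expected)
```

Reading this: 267 grid cells carried enough data (≥ 2 sequences and ≥ 2
species) for a GD estimate. Genetic and species diversity correlate at
r = 0.42, but the 267 cells are worth only ~41 independent observations
once both maps' autocorrelation is accounted for — the corrected p-value,
not the naive one, is reported. Stepwise selection kept temperature with a
confidently positive coefficient (the generating truth), temperature
dominates the partitioned variance, and the residuals show no leftover
spatial structure, so no major spatially structured driver is missing.

The other examples each demonstrate one capability: `01` the generator,
`02` the Π estimator and overlap rule, `03` gridding and latitude bands,
`05` why the corrected t-test matters, `06` range-based richness and the
stringent-filter robustness sweep. A thin CLI mirrors the file-based
pipeline: `macrodiv simulate`, `filter`, `richness`, `congruence`,
`model`, `robustness`, `all` (YAML-configured; see
`macrodiv --help`).

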