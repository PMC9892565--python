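# rendr

Design and analysis toolkit for **split-ribozyme RNA sensors** — systems in
which a self-splicing group I intron (the *Tetrahymena thermophila*
ribozyme) is cut into two fragments whose reassembly is templated by a
target RNA. Each fragment carries an RNA guide, the reverse complement of a
window on the RNA input; when the input is present it co-localises the
fragments, the ribozyme refolds, and splicing ligates the exons of an
output gene, so output expression reports the presence of the input
transcript.

The package is for synthetic biologists building and characterising such
sensors. It covers the four computational stages of that workflow:

* **`rendr.sequences`** — construct modelling: the 5' splice site of this
  intron family requires a uracil immediately upstream, so insertion sites
  are validated against that rule; in-silico splicing, enumeration of all
  L−1 split sites, guide/inhibitor design (including toehold-mediated RNA
  inhibitors and fractional mismatch scans), and the modular architecture
  that places the ribozyme between the RBS and an exchangeable CDS.
* **`rendr.thermo`** — a thermodynamic expression model. With the guides
  and the input folded independently (*initial state*, IS) versus fully
  hybridised (*extended duplex*, ED), the predictor is

  ```
  ΔG_Predicted = ΔG_guide1 + ΔG_guide2 + ΔG_input − ΔG_ED     [kcal/mol]
  ```

  and observed expression follows `ln(FL/OD) = a + b·ΔG_Predicted + ε`.
  Energies come from a pluggable backend — a self-contained Watson–Crick
  nearest-neighbour model, or an adapter over the ViennaRNA bindings for
  full secondary-structure MFE. The model is fitted statsmodels-style:
  `ExpressionModel(dg, fl_od).fit()` returns a results object with the
  slope, intercept, standard errors, R² and a `summary()` table.
* **`rendr.facs_seq`** — FACS-seq analysis of transposon split-site
  libraries: amplicon reads are assigned to split sites by locating the
  ribozyme-fragment/guide junction (exact seed, one-mismatch fallback,
  unique-hit rule), per-site frequencies are compared between sorted and
  unsorted libraries as a relative enrichment with a homoscedastic
  two-tailed t-test across replicates, and sites lost during selection are
  flagged. Spliced- vs unspliced-product fractions are computed from
  junction-spanning amplicons.
* **`rendr.screen`** — plate analytics: media-blank correction and FL/OD,
  the on/off distance score `(FL/OD_on − FL/OD_off)/√2`, rank-based
  tertile classification per replicate, and the functional call (top two
  tertiles in both replicates).
* **`rendr.simulate`** — seeded generators for every input: skewed
  libraries with planted functional split sites, lognormal single-cell
  fluorescence with top/bottom quantile gates over three sorting rounds,
  junction-spanning FASTQ reads with substitution errors, and plate data
  drawn from the ln-linear model.

A `rendr` command-line interface exposes the stages
(`enumerate`, `design`, `splice`, `thermo`, `enrich`, `screen`,
`simulate`); every run writes a resolved-config echo and provenance-stamped
tables.

## Worked example

```python
import pandas as pd
from rendr import simulate as sim, thermo
from rendr.sequences import design_guides, split_ribozyme, enumerate_split_sites
from rendr.screen import process_plate

rib = sim.synthetic_ribozyme()          # 420-nt synthetic ribozyme stand-in
rna = sim.synthetic_input()             # 650-nt synthetic RNA input
print(f"candidate split sites: {len(enumerate_split_sites(rib))}")

guides = design_guides(rna, (1, 82), (82, 164))   # 81+82 nt windows
design = split_ribozyme(rib, 15, guides)
print(f"split 15: 5' core {len(design.core5())} nt, "
      f"3' core {len(design.core3())} nt, "
      f"interaction {guides.interaction_length} nt")

backend = thermo.get_backend("vienna")
designs = pd.DataFrame(
    {"design_id": f"len_{t}",
     "dg_predicted": thermo.compute_thermo_states(p, rna, backend).dg_predicted}
    for t, p in sim.guide_length_panel(rna)      # lengths 0..650
)
plate = sim.simulate_plate_from_thermo(designs, sigma=0.4, seed=1)
wells = process_plate(plate)
data = wells[~wells.is_media_blank & ~wells.is_blank_cells].merge(designs, on="design_id")
fit = thermo.ExpressionModel(data.dg_predicted.to_numpy(),
                             data.fl_od.to_numpy(), floor=200.0).fit()
print(fit.summary())
```

prints

```
candidate split sites: 419
split 15: 5' core 15 nt, 3' core 405 nt, interaction 163 nt
ln-linear expression model: ln(FL/OD) = a + b * dG_Predicted
  n (fit)     : 23
  slope b     : +0.00799 +/- 0.00015  [1/(kcal/mol)]
  intercept a : +5.3715 +/- 0.0755  [ln FL/OD]
  R^2         : 0.9925
  floored pts : 1 at autofluorescence 200 (excluded)
```

The 420-nt ribozyme admits 419 candidate split sites; splitting at site 15
leaves a 15-nt 5' fragment and a 405-nt 3' fragment, each extended by one
guide of the 163-nt designed interaction. The guide-length panel's
ΔG_Predicted increases with interaction length, and the OLS fit of
ln(FL/OD) on ΔG_Predicted recovers the generating slope and intercept
(`a = ln 200 ≈ 5.30`, `b = 0.008`) within their standard errors, with one
no-guide control floored at autofluorescence and excluded.

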