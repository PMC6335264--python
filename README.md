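# nucleomorph

Quantification of nuclear-envelope pathology and nucleocytoplasmic
transport in 2D fluorescence microscopy of neurons, built for studies of
tauopathy (FTD-MAPT) phenotypes: deep infoldings (invaginations) of the
nuclear lamina, disrupted partitioning of NES/NLS transport reporters,
somatodendritic colocalization, and microtubule plus-end (EB3 comet)
trajectories that cross into the nucleus.

Because raw imaging data for such studies is rarely shareable, the package
ships a ground-truthed synthetic microscopy generator that renders
multi-channel fields (DAPI, lamin B1, NES:GFP, NLS:RFP, tubulin) with
pixel-perfect label masks and planted phenotypes, so every stage of the
measurement chain is validated end to end without any download.

## The measurements

**Invagination scoring.** The nuclear area of each cell is defined from
DAPI. Thresholded lamin-B1 signal inside a nucleus is partitioned into
*boundary* (within a rim band of width `w` = 0.5 µm of the nuclear
outline, measured on the Euclidean distance transform of the nucleus
mask) and *invaginated* (deeper inside). Two per-nucleus classifiers:

- **fraction rule** — positive iff the invaginated share of total lamin
  signal `f = I_inv / (I_inv + I_bnd)` strictly exceeds 0.3;
- **depth rule** — positive iff lamin penetrates at least 3 µm into the
  interior, i.e. `max EDT(nucleus)` over invaginated lamin pixels ≥ 3 µm.

Field-level output is the percentage of positive nuclei.

**Transport assay.** For each cell, the background-corrected
nuclear-to-cytoplasmic mean-intensity ratio of each reporter,
`N/C = (mean_nuc − bg) / (mean_cyto − bg)`, with cytoplasm = cell body
minus nucleus. Intact transport gives NES:GFP N/C « 1 and NLS:RFP N/C » 1;
both converge to 1 as compartments mix.

**Colocalization.** Pearson's R of two channels over a cell-body mask.

**Trajectories.** Given comet tracks (CSV of per-frame coordinates), a
cell is flagged as having *nuclear growth tracks* iff any track polyline
— including sub-pixel interpolation between frames — intersects its
nucleus mask; per-step speeds are reported in µm/s.

**Statistics.** Unpaired Student's t, one-way ANOVA, Tukey/Dunnett
adjusted post-hoc comparisons.

## Worked example

```python
import numpy as np
import nucleomorph as nm
from nucleomorph.segmentation import segment_cell_body

# 25 nuclei, 40% carrying deep planted lamina folds; mixing delta = 0.5
pop = nm.sample_population(25, prevalence=0.4, rng_seed=7)
field = nm.render_field(nm.make_field_spec(pop, transport_defect_delta=0.5,
                                           rng_seed=7))

nuclei = nm.segment_nuclei(field.channels["dapi"], 0.1)
measurements, excluded = nm.score_field(nuclei, field.channels["lamin"])
summary = nm.summarize_field(measurements, "fraction")
print(f"{summary.n_positive}/{summary.n_nuclei} nuclei invagination-positive "
      f"({summary.percent_positive:.1f}%) under the fraction rule")

cells = segment_cell_body(field.channels["tubulin"], nuclei)
results, _ = nm.assay_field(field.channels["nes_gfp"],
                            field.channels["nls_rfp"], cells, nuclei)
print("median N/C  NES:GFP = %.2f   NLS:RFP = %.2f"
      % (np.median([r.nc_ratio_nes for r in results]),
         np.median([r.nc_ratio_nls for r in results])))
```

prints

```
13/25 nuclei invagination-positive (52.0%) under the fraction rule
median N/C  NES:GFP = 0.55   NLS:RFP = 1.87
```

Here 13 of the 25 nuclei were planted with folds (the Bernoulli draw at
prevalence 0.4), and the pipeline recovers exactly those 13 from the
noisy rendered images. At mixing delta = 0.5 the NES reporter has leaked
halfway into the nucleus (N/C 0.55, up from ≈ 0.08 at delta = 0) and the
NLS reporter has lost about half of its nuclear enrichment (N/C 1.87,
down from ≈ 12.6) — the directional signature of a transport defect.

The same stages are exposed as a CLI (`nucleomorph simulate | segment |
score | transport | coloc | tracks | stats | run-all`); `run-all` drives
the whole chain from a YAML config and writes a manifest that records
every threshold, mode and seed.

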