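# epibind

Quantification pipeline for characterising a receptor–ligand interaction
from cell-conjugation binding screens through structural epitope mapping
to its functional readout in neuronal fluorescence images. The package
was built around the analysis needs of studies of the immunomodulatory
ligand B7-1 (CD80) binding the neurotrophin receptor p75^NTR^ and driving
dendritic-spine disassembly, but every component is generic:

- **`epibind.binding`** — quadrant gating of two-colour flow-cytometry
  event tables, percent bound (double-positive events / total events),
  relative binding of mutants vs wild type, classification of binding
  losses at the >25/>50/>70% thresholds with partner-specificity flags,
  salt-bridge suppressor-rescue detection, Hill-equation titration fits,
  and competition profiles with optional descending-4PL IC50.
- **`epibind.epitope`** — PDB structures, Shrake–Rupley solvent-accessible
  surface area, surface-residue selection for scanning mutagenesis,
  per-residue loss annotation into the B-factor column, an exact/permutation
  test for spatial clustering of loss residues, and binding-site overlap
  (Jaccard) reports.
- **`epibind.imaging`** — MAP2 continuity scoring of traced dendrite
  paths, synaptic puncta detection and per-µm densities, contact-path
  selection against a cell mask, and spine-density summaries.
- **`epibind.pipeline`** — one-way ANOVA with Bonferroni post hoc tests,
  percent-change effect sizes, and a config-driven stage runner with a
  reproducibility manifest.
- **`epibind.synthetic`** — seeded generators with ground truth for every
  input class: flow mixtures, Hill titrations, dendrite images with
  controllable MAP2 fragmentation and puncta density, Golgi spine-count
  tables, and mutant binding screens.

The central binding model is the Hill equation

    Y = B_max · X^h / (K_d^h + X^h)

fitted by multi-start nonlinear least squares; the fitted `K_d` is
reported as EC50 and `h` is the Hill coefficient. The central image
statistic is the MAP2 continuity score of a traced path on a thresholded
8-bit image,

    C = 100 · AUC / (255 · L)

with `AUC` the profile area under the curve and `L` the path length in
samples — the percent of a dendrite still carrying microtubule signal.

## Worked example

```python
import numpy as np
from epibind import binding, synthetic as syn

# a noiseless titration generated at EC50 = 16 nM, h = 2.3
conc = (0.0,) + tuple(np.geomspace(0.1, 100, 12))
data, _ = syn.gen_titration(syn.TitrationSimParams(
    bmax=100.0, kd=16.0, h=2.3, concentrations=conc, cv_noise=0.0))
fit = binding.fit_hill(data)
print(f"EC50 = {fit.ec50:.3f} nM, h = {fit.h:.3f}, Bmax = {fit.bmax:.2f}")

# a mutant screen with one partner-specific loss
screen, _ = syn.gen_mutant_screen(
    {"N82E": {"p75NTR": 10.0, "CTLA-4": 95.0}}, cv_noise=0.0)
for call in binding.classify_losses(screen):
    print(call.mutant, call.partner, f"loss={call.loss:.0f}%",
          call.category, "specific" if call.specific else "")
```

prints

```
EC50 = 16.000 nM, h = 2.300, Bmax = 100.00
N82E CTLA-4 loss=5% none 
N82E p75NTR loss=90% >70 specific
```

— the fitter recovers the generating parameters exactly on a noiseless
curve, and the classifier flags the 90% loss to one partner (exceeding
the >70 threshold) while binding to the other partner is called intact,
the signature of a true interface residue rather than a folding defect.

The same workflows are scriptable from the shell via the `epibind` CLI
(`epibind simulate …`, `epibind bind …`, `epibind epitope …`,
`epibind image …`, `epibind pipeline run`).

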