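# liquidmet

Liquid-biopsy metabolic profiling of acute myeloid leukemia (AML), as a
tested analysis pipeline: single-cell redox cytometry of circulating CD34⁺
blasts, SCENITH-derived energetic parameters, Mito-Stress bioenergetics,
multiplex extracellular-vesicle (EV) surface-marker panels with ROC
discrimination, and EV lipidomics — exercised end-to-end on seeded synthetic
cohorts with known ground truth.

It is written for researchers who analyze flow-cytometry metabolic assays
and circulating-EV readouts and want the computational layer — gating rules,
derived-parameter algebra, panel correction, lipid parsing, network scores —
as reusable, unit-tested code rather than spreadsheet arithmetic.

## The core quantities

**SCENITH.** Protein synthesis (anti-puromycin gMFI) under vehicle (Co),
2-deoxy-D-glucose (2DG), oligomycin (O) and both (DGO) yields

```
gluco_dep = 100·(Co − 2DG)/(Co − DGO)      glyco_cap = 100 − mito_dep
mito_dep  = 100·(Co − O)/(Co − DGO)        faao_cap  = 100 − gluco_dep
```

**Quadrant gating.** Each CD34⁺ cell is hi/lo on a ROS/GSH/MITO channel
pair relative to cutpoints anchored on the same sample's CD3⁺ lymphocytes
(quantile of the reference distribution, default median; ties → lo).

**EV panels.** 37-marker bead MFIs are blank-corrected
(`corrected = MFI − blank`), compared by rank-sum tests, and screened by an
empirical ROC (rank-formulation AUC, Youden-J cutoff).

**Lipidomics.** Shorthand species (`DG 18:1_20:4`, `PC O-18:1_20:4`,
`SM 18:2;2O/24:3`) are parsed into class/chain structure; classes are
aggregated into percent composition, and directed class conversions
(SM→Cer, PC→DG/LPC/FA, PI→FA) are scored by the standardized between-group
difference of per-sample log(product/reactant) ratios.

**Mito-Stress.** From a four-phase OCR trace: non-mito = min after
rotenone/antimycin A; basal = last pre-oligomycin − non-mito; ATP-linked =
basal − (post-oligomycin min − non-mito); maximal = post-FCCP max −
non-mito; SRC = maximal − basal.

## Worked example

```python
from liquidmet.scenith import ScenithGmfiSet, compute_scenith

profile = compute_scenith(ScenithGmfiSet(Co=250, twoDG=130, O=190, DGO=50))
print(profile.gluco_dep, profile.mito_dep, profile.glyco_cap, profile.faao_cap)
# 60.0 30.0 70.0 40.0
```

60% of this population's translation (ATP supply) depends on glucose and
30% on mitochondrial ATP synthesis; it could sustain up to 70% of its ATP
production by glycolysis and 40% by fatty-acid/amino-acid oxidation.

The numbered drivers under `analysis/` run the full synthetic-cohort study
(40 AML vs 12 HD, seed 1). For example:

```
$ python analysis/03_scenith_profiles.py
cohort means (percent):
        gluco_dep  mito_dep  glyco_cap  faao_cap
cohort
AML         83.59     20.09      79.91     16.41
HD          58.06     40.97      59.03     41.94

$ python analysis/04_ev_panels.py
...
CD44 ROC: AUC=0.887 (95% CI 0.783-0.963), cutoff=107.2 a.u., sens=0.72, spec=1.00
```

The AML group shows the expected high glucose dependence with low
mitochondrial dependence, and EV CD44 discriminates AML from healthy donors.
A configuration-driven CLI wraps the same stages
(`liquidmet simulate|redox|scenith|ev|lipids|correlate|run`); see
`liquidmet --help`.

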