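# mwradiomics

Multi-window CT radiomics for distinguishing **indolent** from
**aggressive** screen-detected lung nodules.

Low-dose-CT screening finds many cancers, but a sizeable minority are
slow-growing lesions for which treatment amounts to overdiagnosis. Growth
speed is quantified by the volume-doubling time over a screening interval,

```
VDT = ln 2 · T / ln(Vi / V0)        (days)
```

with the 400-day convention: `VDT ≥ 400` ⇒ indolent, `0 < VDT < 400` ⇒
aggressive (non-growing and shrinking lesions count as indolent). The
package predicts that label from baseline imaging alone using a
*multi-window* habitat decomposition: each nodule is segmented under the
lung window (WW 1500 / WL −400 HU, showing core + ground-glass rim) and
the mediastinal window (WW 400 / WL 40 HU, showing only the solid core),
and the voxelwise **difference region** `DR = LW ∧ ¬MW` isolates the
non-solid habitat. From the lung-window and difference-region masks a
364-feature radiomic signature is extracted (209 IBSI-style, 125 Laws
texture energies, 30 stationary-wavelet sub-band features), reduced by a
t-test filter → 200× bootstrap per-feature AUROC filter → Pearson
`|r| ≥ 0.8` pruning → backward-stepwise logistic elimination, and fitted as
logistic models whose linear predictors (radiomics scores) are finally
augmented with clinical covariates (sex, COPD) into a nomogram.

A synthetic phantom module generates longitudinal part-solid nodule
cohorts with assigned VDTs, planted class-conditional rim fractions and
clinical covariate imbalance, so the entire chain is testable without
clinical images. See `docs/methods.md` for the model details and the
phantoms' fidelity limits.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from mwradiomics.phantoms import PhantomConfig
from mwradiomics.pipeline import RunConfig, run_all

bundle = run_all(RunConfig(phantom=PhantomConfig(n_patients=60, seed=1),
                           seed=1, n_boot_eval=300, out_dir="demo_out"))
for fam in ("lung_window", "difference_region", "combined", "clinical"):
    p = bundle["results"][fam]["performance"]
    print(f"{fam:18s} AUROC {p['auroc']:.3f} "
          f"({p['auroc_ci'][0]:.3f}-{p['auroc_ci'][1]:.3f}) "
          f"acc {100*p['accuracy']:.1f}%")
```

prints (60 patients, 48 aggressive / 12 indolent intervals):

```
lung_window        AUROC 0.878 (0.762-0.965) acc 91.7%
difference_region  AUROC 0.861 (0.728-0.967) acc 85.0%
combined           AUROC 0.861 (0.703-0.965) acc 85.0%
clinical           AUROC 0.716 (0.590-0.845) acc 73.3%
```

Each AUROC is the rank-sum statistic of the fitted radiomics score with a
stratified-bootstrap 95% CI; accuracy is at the Youden-optimal threshold
with *aggressive* as the positive class. The backward-elimination stage
kept, e.g., `LW_F31` and `DR_F222` for the combined model — feature codes
resolve through the shipped catalogue
(`mwradiomics.radiomics.CATALOGUE["F31"].name`). Adding sex and COPD raised
the combined-model AUROC to 0.889 on this cohort. Absolute values run
higher than on clinical images because the phantom's planted effect is
clean; the package's tests assert recovery and ordering, not clinical
effect sizes.

The same run is available from the shell:

```
mwrad run --out demo_out --seed 1 --n-patients 60
```

with `mwrad simulate / segment / vdt / features / select` exposing the
individual stages.

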