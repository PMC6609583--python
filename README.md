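# wstlg

Active **whole-skeletal total lesion glycolysis (WS-TLG)** from FDG-PET/CT:
a quantitative, continuous biomarker of skeletal metastatic burden, built
for nuclear-medicine researchers who need a scriptable alternative to
category-based bone response reading.

Skeletal metastases — especially the osteolytic disease common in breast
cancer — are poorly served by size-based criteria (RECIST treats most bone
lesions as non-measurable) and by osteoblastic tracers. WS-TLG instead
quantifies the glycolytic activity of the whole skeleton in one number:

1. the **bone compartment** is segmented on CT as voxels with attenuation
   strictly above 152 HU (manual exclusion masks remove metal artefacts and
   extra-skeletal calcification);
2. within that compartment, **lesions** are the connected components of
   voxels with SUV strictly above a cutoff (default SUV = 4.0, chosen by
   Youden's J over a cutoff scan of patients with and without skeletal
   metastasis);
3. each lesion contributes its total lesion glycolysis, and the study value
   is the sum

   WS-TLG = Σ_lesions (volume above threshold, mL) × SUVmean,

   in mL·SUV. A study is *WS-TLG-positive* if the value is above 0.

The package also provides body-weight SUV / lean-body-mass SUL conversion
(Janmahasatian LBM), bone-restricted **PERCIST** (ΔSULpeak ≥ 30% *and*
≥ 0.8 SUL units, new lesion ⇒ PMD) and **EORTC** (ΔΣSUVmax ≥ 25%) response
classification, **trajectory grouping** of longitudinal WS-TLG series
(favorable / progressive / fluctuating by the signs of successive
differences), cohort cutoff-selection statistics, and a synthetic PET/CT
**phantom generator** with analytic ground truth that emulates the four CT
morphologies of bone metastasis (lytic, blastic, mixed, intertrabecular).

## Worked example

Generate a phantom with two FDG-avid lesions inside a bone sphere and run
the full pipeline on it:

```python
from wstlg import (ImageGrid, MarrowSite, LesionSpec, PhantomSpec, RunConfig,
                   generate, run_study, truth_wstlg)

grid = ImageGrid(shape=(56, 56, 56), spacing=(2.0, 2.0, 2.0))
site = MarrowSite(label="L3", center_mm=(56, 56, 56), radius_mm=36, suv=2.33)
lesions = (
    LesionSpec(center_mm=(40, 56, 56), radius_mm=10, suv=6.0, ct_type="lytic"),
    LesionSpec(center_mm=(72, 56, 56), radius_mm=8, suv=5.0, ct_type="intertrabecular"),
)
ct, pet, truth = generate(PhantomSpec(grid=grid, marrow_sites=(site,), lesions=lesions))
study, report = run_study(RunConfig(fill_bone_cavities=True), ct, pet)
print(f"analytic truth WS-TLG: {truth_wstlg(truth, 4.0):.2f}")
print(f"measured WS-TLG:       {study.ws_tlg:.2f}  ({len(study.lesions)} lesions)")
for l in study.lesions:
    print(f"  lesion {l.label}: volume {l.volume_ml:.2f} mL, "
          f"SUVmean {l.suv_mean:.2f}, SUVmax {l.suv_max:.2f}, TLG {l.tlg:.2f}")
```

prints

```
analytic truth WS-TLG: 35.86
measured WS-TLG:       35.00  (2 lesions)
  lesion 1: volume 4.12 mL, SUVmean 6.00, SUVmax 6.00, TLG 24.72
  lesion 2: volume 2.06 mL, SUVmean 5.00, SUVmax 5.00, TLG 10.28
```

The 10 mm lytic sphere (analytic volume 4.19 mL at SUV 6) and the 8 mm
marrow-confined sphere (2.14 mL at SUV 5) are recovered within voxelization
error (~2% here); the marrow background at SUV 2.33 stays below the 4.0
cutoff and contributes nothing.

The same pipeline runs from the shell on NIfTI inputs:

```sh
wstlg compute --pet pet_suv.nii.gz --ct ct.nii.gz --suv-cutoff 4.0 \
      --hu-threshold 152 --out report.json --lesion-csv lesions.csv
wstlg respond --measurements series.csv --out response.json
wstlg cutoff-scan --cohort cohort.csv --cutoffs 3.5,4.0,4.5 --out scan.json
wstlg simulate --spec phantom.yaml --out-dir sim/
```

## Documentation

`docs/methods.md` describes the measurement model, the phantom generator
and its limitations, numerical conventions, and the design decisions where
published practice left the choice open.
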