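# plaqmap

Quantitative T2 mapping of carotid atherosclerotic plaque: voxel-wise T2
relaxometry, lipid segmentation and lipid-distribution morphometry, with a
calibrated synthetic phantom cohort for end-to-end validation.

## The problem

Decisions about carotid endarterectomy in asymptomatic patients rest largely
on % luminal stenosis, which ignores the disease process in the artery
*wall*. Plaque lipid content is a key determinant of plaque behaviour, and
lipid-rich tissue has a short transverse relaxation time: on multi-echo
spin-echo (MESE) MRI, voxel-wise T2 below a validated 42 ms threshold
identifies plaque lipid without contrast agents. Beyond total lipid burden,
the *spatial arrangement* of lipid matters — a single coalesced pool behaves
differently from scattered small deposits of the same total volume.

`plaqmap` implements that analysis chain for multi-echo carotid stacks:

1. **T2 mapping** (`plaqmap.t2map`) — voxel-wise mono-exponential fit
   `S(TE) = S0 · exp(−TE/T2)` by variable projection: the amplitude is
   profiled out in closed form and the remaining 1-D problem in T2 is solved
   by a global log-grid scan, golden-section refinement and a
   derivative-bisection polish. Vectorised over voxels, deterministic,
   bounded to T2 ∈ [1, 2000] ms.
2. **Lipid segmentation** (`plaqmap.lipidseg`) — a voxel is lipid iff it is
   inside the vessel-wall mask, its fit converged, and T2 < 42 ms (strict).
   Areas and volumes are voxel-counted (0.33 × 0.33 × 2 mm by default).
3. **Deposit morphometry** (`plaqmap.deposits`) — per-slice 8-connected
   components of the lipid mask; components ≤ 1% of the slice's lipid area
   are excluded as noise; on the slice with maximal lipid volume the
   distribution indices are computed:
   - `LLD%` — the largest lipid deposit's percentage of the slice lipid,
   - `RLD% = 100·(1 − LLD%/100)/(n − 1)` — the mean share of the remaining
     deposits (n ≥ 2),
   - `LAI = LLD% / RLD%` — the lipid aggregation index; high for coalesced
     pools, low for scattered deposits.
4. **Cohort statistics** (`plaqmap.cohortstats`) — median/IQR summaries,
   Wilcoxon rank-sum comparisons (exact enumeration for small samples,
   otherwise tie/continuity-corrected normal approximation), Spearman and
   Pearson correlations with an optional base-10 log transform and 95%
   confidence bands.
5. **Synthetic phantom cohort** (`plaqmap.phantom`) — annular vessel-wall
   cross-sections with black-blood lumen, capsule-shaped lipid deposits,
   Rician acquisition noise, and a population model with bilaterally
   correlated (Gaussian-copula) lipid and wall burden, a
   symptomatic-vs-asymptomatic effect and preferential placement of the
   lipid maximum at the bifurcation slice. `calibrate_to_paper()`
   moment-matches the generator to a set of target cohort statistics.

## Worked example

```python
import numpy as np
from plaqmap import (AcquisitionConfig, TissueModel, DepositSpec, VesselSpec,
                     RoiMaskSet, render_echo_stack, add_rician_noise,
                     analyze_vessel)

acq = AcquisitionConfig()          # 14 echoes 9-127 ms, 10 x 2 mm slices, SNR 40
tissue = TissueModel()             # lipid T2 20-38 ms, fibrous 50-90 ms

weights = 0.3 + 0.7 * np.exp(-(np.arange(10) - 4) ** 2 / 8.0)
vessel = VesselSpec(
    patient_id="P000", side="left", symptomatic=True,
    bifurcation_slice=4, max_slice=4,
    lumen_radius=2.5, outer_radius=4.8,        # mm
    f_max=0.30,                                # 30% lipid at the peak slice
    slice_weights=weights,
    deposits=[DepositSpec(angle=0.3, share=0.5, t2=30.0),
              DepositSpec(angle=2.4, share=0.3, t2=25.0),
              DepositSpec(angle=4.4, share=0.2, t2=35.0)],
    seed=11,
)

stack, truth = render_echo_stack(vessel, acq, tissue)
noisy = add_rician_noise(stack, snr=acq.snr, seed=7)
rois = RoiMaskSet(wall=truth.wall, lumen=truth.lumen, geometry=acq.geometry)
summary, per_slice, t2map, lipid = analyze_vessel(noisy, rois, bifurcation_slice=4)
```

This renders a vessel whose wall carries three separated lipid deposits
(50/30/20% of the slice lipid), pushes it through noise, fitting,
segmentation and labeling, and prints:

```
mean lipid fraction : 19.5%
mean lipid volume   : 20.2 mm^3/slice
mean wall volume    : 103.7 mm^3/slice
max-lipid slice     : 4 (bifurcation: True)
max-slice lipid     : 30.0%
deposits retained   : 3
LLD%                : 49.7%
RLD%                : 25.2%
LAI                 : 1.97
```

The configured ground truth is recovered through the imaging chain: the peak
slice carries 30% lipid, the largest of the three deposits holds ~50% of it,
and `LAI ≈ 0.5·2/(1−0.5) = 2` for three deposits with a 50% leader.

Cohort-level work goes through `run_cohort` (generate → noise → fit →
segment → label → aggregate for every vessel) and `paper_analysis` (the
bundled group comparisons and correlations), or through the CLI:

```bash
plaqmap simulate --out sim/ --seed 1          # calibrated 50-patient cohort
plaqmap fit      --stack sim/P000_left/stack.nii.gz --mask sim/P000_left/wall.nii.gz --out t2/
plaqmap segment  --t2 t2/ --wall sim/P000_left/wall.nii.gz --out lipid.nii.gz
plaqmap deposits --lipid lipid.nii.gz --wall sim/P000_left/wall.nii.gz --bifurcation-slice 4 --out deposits.tsv
plaqmap cohort   --table metrics.tsv --out report.json
```

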