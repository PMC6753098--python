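# batlipid

Dynamic fat-water MRI analysis of brown adipose tissue (BAT) lipid content
during personalized cooling — as a reusable, tested pipeline with a
synthetic phantom for end-to-end validation.

Cold exposure activates human BAT, which burns and replenishes
intracellular lipid. Fat-water MRI tracks this as the voxelwise
**fat-signal fraction** (FSF, %): the share of the MR signal arising from
lipid. The experiment this package models images the supraclavicular
region once at thermoneutrality and ~20 more times during about an hour of
cooling to just above the subject's shiver threshold, then asks how lipid
content changes as a function of accumulated cold stress — and finds a
heterogeneous answer: voxels that start lipid-rich lose fat, voxels that
start lipid-poor gain it.

The package is aimed at quantitative-MRI and thermophysiology researchers
who want to prototype or validate this analysis chain without access to
raw subject data.

## What it implements

- **Phantom** (`batlipid.phantom`): a labelled neck/torso subject with
  ground-truth FSF, decade-dependent cooling response, multi-echo complex
  signal synthesis (field map, R2*, noise), inter-acquisition motion, and
  blanket-temperature / thermal-sensation logs.
- **Fat-water separation** (`batlipid.fatwater`): voxelwise variable
  projection under the signal model
  `S(TE) = (W + F·Σ α_p e^{i2π df_p TE}) e^{i2π ψ TE} e^{−R2* TE}`
  with a seven-peak fat spectrum, bounded field-map search, region-growing
  swap suppression, and dominant-signal FSF maps.
- **Registration** (`batlipid.registration`): multi-resolution demons on
  water magnitude images, FSF-map warping, nine-point fiducial validation,
  slice-range constraints.
- **ROIs and decades** (`batlipid.segmentation`, `batlipid.decades`):
  seeded delineation with a 30–80% display window, in-plane erosion,
  bilateral merging, FSF thresholds (0–100/40–100/50–100%), decade
  assignment frozen at baseline, the <60-voxel exclusion rule, and
  bootstrap ROI sizing.
- **Cooling dose** (`batlipid.cooling`): DuBois body surface area,
  cooling dose `∫ (T₀ − T(t)) dt` (°C·min) and normalized cooling dose
  (°C·min·m⁻²), log synchronization to scan midpoints.
- **Statistics** (`batlipid.stats`): exact paired Wilcoxon signed-rank
  tests by full enumeration, percentile-bootstrap CIs, Spearman ρ,
  noncentral-t power analysis, and two worked physiological computations.
- **Pipeline + CLI** (`batlipid.pipeline`, `batlipid` command): the whole
  chain with a tidy-CSV/plot report and a JSON run manifest.

## Worked example

```python
from batlipid.config import PipelineConfig
from batlipid.pipeline import run_pipeline

result = run_pipeline(PipelineConfig(), seed=0, outdir="run0")
print(result.endpoint_table[result.endpoint_table.tissue == "bat"])
```

One default run (64×64×15 voxels, 21 acquisitions, a few minutes on one
CPU) prints the per-decade endpoint comparison, here from seed 0:

```
  tissue  decade  n_voxels  mean_fsf_tn  mean_fsf_ce     change
0    bat       0       138     5.856135    15.466945   9.610811
1    bat      10       326    15.591502    22.010489   6.418986
2    bat      20       580    25.553963    29.729188   4.175224
3    bat      30       925    35.267828    37.974358   2.706529
4    bat      40      1074    45.122568    48.063207   2.940639
5    bat      50      1124    55.013439    56.496511   1.483071
6    bat      60      1122    64.963363    62.770112  -2.193251
7    bat      70       899    74.705752    68.634943  -6.070809
8    bat      80       546    84.629755    74.512200 -10.117555
9    bat      90       247    93.809691    78.940664 -14.869027
```

Each row is one FSF decade of the BAT ROI: its tracked voxel count, mean
FSF at thermoneutrality and at the cold-exposure endpoint, and the change
in percentage points — lipid-poor decades gain (+9.6 pp at 0–10%),
lipid-rich decades lose (−14.9 pp at 90–100%), the middle barely moves.
`run0/` also receives the threshold comparison, per-decade Spearman
correlations against normalized cooling dose and thermal sensation
(strongly positive below 30%, strongly negative above 50%, weak in
between), the fiducial registration report (median error falls from
1.12 px to 0.90 px here), the cooling-dose table and plots.

The same pipeline is scriptable from the shell:

```bash
batlipid run-all --seed 0 --outdir run0
batlipid simulate --seed 1 --outdir session1        # write NIfTI + logs
batlipid separate --in session1/acq01 --out maps/acq01
```

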