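# petcoloc

Intra-lesion colocalization analysis for dual-tracer PET/CT studies of
prostate cancer bone metastases.

A bone-remodeling tracer (¹⁸F-NaF) and a tumor-targeted tracer
(¹⁸F-PSMA-ligand) can light up the *same* bone metastasis in *different
places*: tumor that grows independently of the osteoblastic reaction shows
PSMA uptake displaced from the sclerotic, NaF-avid bone. This package
measures that intra-lesion discordance and tests whether it differs between
castration-sensitive (CSPC) and castration-resistant (CRPC) disease.

For each lesion it computes, after CT-driven rigid registration of the two
sessions:

- a gradient-based ROI per tracer (boundary at the maximum of the radial
  uptake gradient), with nested 60/70/80 %-of-SUVmax core ROIs and a CT
  sclerosis ROI;
- the **overlap volume** OV = |A ∩ B| / min(|A|, |B|) at every
  segmentation level, the seven-way voxel concordance categories of the
  PSMA/NaF/CT triplet, and three distances between the regions of highest
  uptake (‖x_SUVmax^PSMA − x_SUVmax^NaF‖, f80 centroid distance, mean
  pairwise f80 distance);
- cluster-aware statistics (lesions are nested in patients): a clustered
  Wilcoxon signed-rank test across levels, patient-level permutation tests
  between disease groups, patient-level bootstrap CIs, a nested linear
  mixed model of voxel HU by concordance category, and a paired-scan ICC
  as a registration-quality surrogate.

Because clinical dual-tracer imaging of this kind is not publicly
deposited, the package ships a synthetic phantom generator
(`petcoloc.synthetic_phantom`) that simulates paired PET/CT sessions with
known ground truth: osteosclerotic CT lesions, NaF-like uptake centered on
the sclerosis, PSMA-like uptake displaced by a status-dependent offset
(small in CSPC, large in CRPC), PSF blur, noise, and inter-session
repositioning. Every result below is computed on such cohorts.

## Worked example

```python
from petcoloc.pipeline import StudyConfig, run_study

cfg = StudyConfig()            # 6 CSPC + 13 CRPC patients, 5 lesions each
res = run_study(cfg)
print(res.ov_by_level[["level", "median_cspc", "median_crpc", "perm_p"]])
print(f"paired-scan ICC: {res.icc:.3f}")
```

On the default phantom cohort (95 lesions, none excluded) this prints:

```
      level  median_cspc  median_crpc  perm_p
0  gradient     0.837429     0.233333  0.0005
1       f60     0.852431     0.230769  0.0005
2       f70     0.878676     0.117647  0.0005
3       f80     0.783626     0.000000  0.0005
paired-scan ICC: 0.939
```

Reading: castration-sensitive lesions keep high tracer overlap at every
intensity level (median OV 0.78 even in the 80 %-SUVmax cores), while
castration-resistant lesions lose overlap as the threshold tightens —
their high-uptake cores are spatially disjoint (median f80 OV 0). The
patient-level permutation test rejects at every level, and the ICC of
paired HU at registered voxels (0.94) confirms the registration is tight.
Distance metrics point the same way (`res.table3_style`): median
SUVmax-to-SUVmax distance 2.5 mm in CSPC vs 7.5 mm in CRPC.

The same run is available from a shell:

```bash
petcoloc run -o results/           # simulate + analyze, write report CSVs
petcoloc simulate -o phantoms/     # just write phantom NIfTI/CSV/JSON
petcoloc report -r results/        # print the summary tables
```

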