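# vertchem

Analysis of LA-ICP-MS (laser-ablation inductively-coupled-plasma mass
spectrometry) elemental signals in shark vertebrae, built around two ideas
from elasmobranch movement ecology:

1. **Maternal elemental tags.** A placental viviparous shark nourishes her
   embryos through her blood stream, so the vertebral material an embryo
   deposits in utero records the mother's ambient water chemistry. If
   element:Ca signatures are consistent within a litter and match the
   mother's vertebral edge, the in utero record of any young-of-the-year
   (YOY) shark is a usable proxy for its mother's movements during
   gestation.
2. **Gestation migration patterns.** Sr:Ba in vertebral carbonate tracks
   the nearshore(low)–offshore(high) salinity gradient and Pb:Ca tracks
   residency in contaminated coastal habitats. Classifying the in utero
   Sr:Ba profile of a YOY vertebra (focus → birthmark) therefore classifies
   the mother's migration during pregnancy, and the distance of the
   nearshore return shift back-calculates the embryo's length at that
   moment via the Fraser–Lee model.

The package implements the complete chain — instrument-signal reduction,
multivariate tag statistics, profile classification, back-calculation —
plus a seeded synthetic-run generator with full ground truth, so every
stage is testable without instrument data.

## What the pipeline does

**Signal reduction** (`vertchem.reduction`): per ablation record, the
signal window is selected on the internal-standard (⁴³Ca) plateau,
background is subtracted from the bracketing gas blanks, per-mass spikes
are removed with an iterative two-sided Grubbs test (α = 0.05), detector
drift is corrected by linear interpolation between NIST-612 standard
brackets, and concentrations are externally calibrated and standardized to
⁴³Ca as element:Ca molar ratios (µmol·mol⁻¹). Limits of detection are
3·SD of the pooled gas blanks; elements with ≥ 10 % of measurements below
LOD are omitted; replicate spot scans with Stahel–Donoho outlyingness > 10
are excluded before averaging. Transects are reduced pointwise and mapped
to distance from the vertebral focus via the scan speed (10 µm·s⁻¹).

**Tag statistics** (`vertchem.mvstats`): one-way PERMANOVA on Euclidean
distance matrices (pseudo-F
`F = (SS_A/(a−1)) / (SS_W/(N−a))` with label-permutation p-values),
canonical analysis of principal coordinates (CAP) with leave-one-out
cross-validated classification by nearest group centroid in canonical
space, and the proportional chance criterion
`PCC = Σ (n_i/N)²` with an exact binomial significance test.

**Profiles** (`vertchem.profiles`): raw-cps Sr:Ba and Pb:Ca versus distance
from the focus, smoothed with an 11-point running average; Pattern 2
(nearshore throughout) if smoothed Sr:Ba never exceeds 200, Pattern 1
(offshore excursion, nearshore return) if it peaks ≥ 600 and its terminal
segment falls back ≤ 400; the habitat shift R_t is the first point after
the peak below 400.

**Back-calculation** (`vertchem.backcalc`): Fraser–Lee,

    L_t = (R_t / R_V) (L_C − a) + a,

with the juvenile length–radius relation `L_C = 17.349 R_V + 14.516`
(cm, R_V in mm) supplying the biological intercept a.

## Worked example

```python
import numpy as np
import vertchem as vc

design = vc.StudyDesign(seed=1)          # 4 litters (4,3,3,4), 15 young-of-the-year
run, specimens, truth = vc.make_study(design)
result = vc.reduce_run(run, vc.default_mass_config())
print("retained elements:", result.retained_elements)

cfg = vc.default_mass_config()
info = specimens.set_index("specimen_id")
els = [e for e in result.retained_elements if e != "Ca43"]
sig = {s.specimen_id: s for s in result.signatures
       if s.target == "focus" and not s.missing}
ids = sorted(sig)
X = np.array([[sig[i].ratio_umol_mol[cfg.index(e)] for e in els] for i in ids])
dm = vc.euclidean_dm(X, ids)
groups = [info.loc[i, "group"] for i in ids]
perm = vc.permanova(dm, groups, n_perm=999, seed=1)
cap = vc.cap_fit(dm, groups, n_perm=999, seed=1)
print(f"PERMANOVA pseudo-F = {perm.pseudo_f:.1f} (p = {perm.p_value:.3f})")
print(f"CAP: m = {cap.m}, LOO accuracy = {cap.loo_accuracy:.1f}% "
      f"(chance {cap.pcc.chance_accuracy:.1f}%, PCC p = {cap.pcc.p_value:.2g})")

calls = [vc.classify_pattern(vc.ratio_profiles(p))
         for p in result.profiles if info.loc[p.specimen_id, "cls"] == "yoy"]
n1 = sum(c.pattern == "1" for c in calls)
print(f"Pattern 1: {n1}/{len(calls)} young-of-the-year")
c = next(c for c in calls if c.pattern == "1")
row = info.loc[c.specimen_id]
l_t = vc.fraser_lee(c.shift_um / 1000, row.radius_mm, row.length_cm)
print(f"{c.specimen_id}: shift at {c.shift_um:.0f} um -> "
      f"back-calculated length {l_t:.1f} cm (capture {row.length_cm:.1f} cm)")
```

Output:

```
retained elements: ['Li7', 'Mg24', 'Ca43', 'Mn55', 'Fe57', 'Co59', 'Cu63', 'Rb85', 'Sr88', 'Y89', 'Cd114', 'Sn118', 'Ba137', 'Pb208']
PERMANOVA pseudo-F = 58.5 (p = 0.003)
CAP: m = 4, LOO accuracy = 100.0% (chance 25.5%, PCC p = 4.9e-09)
Pattern 1: 11/15 young-of-the-year
Y2: shift at 1602 um -> back-calculated length 42.3 cm (capture 56.4 cm)
```

Reading this: the seven trace elements dropped by the ≥ 10 %-below-LOD
rule leave 14 usable masses; litters are cleanly separated at the
vertebral focus (every embryo is re-assigned to its own litter under
leave-one-out, against a 25.5 % proportional-chance rate); 11 of the 15
YOY profiles show the offshore-excursion-and-return Pattern 1; and for Y2
the nearshore return happened when the embryo was about 42 cm long — a few
centimetres short of its length at birth.

The same chain is available as a CLI:

```sh
vertchem -v all --seed 1 --data-dir run --out-dir results
```

with stages `simulate`, `reduce`, `stats`, `profiles`, `backcalc` runnable
individually; every artifact carries a `.meta.json` sidecar with the
package version, configuration hash and root seed.

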