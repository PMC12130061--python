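# secflow

Centerline-referenced secondary-flow analysis for intracranial arteries.

Sidewall aneurysms of the internal carotid artery (ICA) tend to arise on
strongly curved bends, where the flow in a cross-section is no longer
purely axial: curvature drives Dean-type secondary (in-plane) vortices
that stress the near-wall endothelium. `secflow` implements the full
evaluation chain needed to quantify that link on a cohort of vessels:

1. **Centerline geometry** — resample a vessel centerline at uniform
   arc length (default 0.15 mm), smooth it by iterative midpoint
   relaxation, and compute discrete Frenet–Serret frames: the tangent /
   normal / binormal triad **t**, **n**, **b** with curvature
   κ = |C′×C″|/|C′|³ and torsion τ = (C′×C″)·C‴/|C′×C″|².
2. **Cross-sectional decomposition** — perpendicular slices along the
   centerline, velocity interpolated from a scattered point cloud
   (inverse-distance k-NN), and split per sample as

   v_ax = (v·t) t, v_sec = v − v_ax, v_rad = (v_sec·r̂) r̂, v_cir = v_sec − v_rad,

   with r̂ the in-plane radial unit vector — an orthogonal split, so
   |v|² = |v_ax|² + |v_rad|² + |v_cir|².
3. **Near-wall ROI averaging** — the near-wall band is where a unit
   parabolic profile falls below 50 % of its peak (normalized radius
   ρ ≥ √0.5); a 150° sector centered on the aneurysm direction
   (A-side) is compared against the opposing sector (O-side).
4. **Bend landmarking** — an arterial bend is a curvature peak flanked
   by a proximal and a distal |τ| peak; the torsion peaks partition the
   centerline into branch sections.
5. **Cohort statistics** — per-bend sectional means, case-relative
   normalization (divide by the case-wide maximum, so vessels of
   different size become comparable), grouping into the aneurysm-hosting
   bend (A-bend) vs the other bends (O-bend), and Welch t-tests with
   Welch–Satterthwaite degrees of freedom.

Patient imaging and CFD data of this kind are not publicly available,
so the package ships a first-class synthetic generator: multi-bend
ICA-like centerlines (smooth κ(s)/τ(s) profiles integrated through the
Frenet–Serret equations), parabolic axial flow scaled by the
cycle-averaged inflow law **Q = 48.21 A^1.84 T⁻¹** (Q in ml/s, inlet
area A in cm², cardiac period T in s), Murray-law outlet splits, and a
curvature-coupled vortex-pair secondary flow with amplitude
c·κ·R·U. Every stage of the pipeline is verifiable against this
generator's ground truth.

## Worked example

```python
import numpy as np
from secflow import HelixSpec, make_helix_centerline, frenet, \
    inflow_from_area, murray_split, make_population
from secflow.pipeline import run_cohort

# closed-form geometry check: helix a=3, b=4 has kappa=0.12, tau=0.16
helix = make_helix_centerline(HelixSpec(a=3.0, b=4.0, arc_length=60.0, spacing=0.15))
frames = frenet(helix)
ok = frames.valid
print(f"kappa = {frames.kappa[ok].mean():.5f} 1/mm (closed form 0.12000)")
print(f"tau   = {np.nanmean(frames.tau[ok]):.5f} 1/mm (closed form 0.16000)")

# flow parameterization for a 0.20 cm^2 ICA inlet at a 0.8 s cardiac period
print(f"Q = {inflow_from_area(A=0.20, T=0.8):.3f} ml/s")
print("outlet split:", np.round(murray_split([1.8, 1.2], exponent=3.0), 4))

# a 30-case synthetic cohort through the full pipeline
cases = make_population(30, seed=1)
norm_df, table, boxes = run_cohort(cases)
print(table[["quantity", "mean_A", "sd_A", "mean_O", "sd_O", "p", "significant"]]
      .round(4).to_string(index=False))
```

prints

```
kappa = 0.11998 1/mm (closed form 0.12000)
tau   = 0.15999 1/mm (closed form 0.16000)
Q = 3.118 ml/s
outlet split: [0.7714 0.2286]
 quantity  mean_A   sd_A  mean_O   sd_O      p  significant
    n_vec  0.8130 0.1490  0.8683 0.1456 0.0996        False
     n_ax  0.7998 0.1556  0.8682 0.1479 0.0507        False
    n_cir  0.8479 0.2114  0.6691 0.2697 0.0010         True
    n_rad  0.8917 0.1571  0.7696 0.1940 0.0020         True
   nKappa  0.3451 0.0433  0.2665 0.0911 0.0000         True
nKappaMax  0.9173 0.1378  0.6771 0.2679 0.0000         True
```

Reading the table: `n_cir`/`n_rad` are the case-normalized near-wall
circumferential and radial velocity means on the aneurysmal side. The
aneurysm-hosting bends (A) carry significantly stronger normalized
secondary flow than the other bends (O), while the axial component —
which does not depend on curvature — shows no significant difference.
`nKappa`/`nKappaMax` confirm the hosting bends are the more strongly
curved ones.

A thin CLI mirrors the library: `secflow synth-case`,
`secflow synth-population` (write .vtp/.csv/.json cases to disk) and
`secflow cohort` (generate + analyze + write the comparison tables).

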