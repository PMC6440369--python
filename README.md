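# laaoplan

Planning toolkit for **left atrial appendage occluder (LAAO) implantation**.

In atrial fibrillation, most intracardiac thrombi form in the left atrial
appendage (LAA), a blind-ended pouch of the left atrium with highly variable
morphology.  When anticoagulation is contraindicated, an occluder device
(an Amplatzer-Amulet-like lobe-and-disc occluder or a Watchman-like plug) is
implanted at the LAA ostium.  Choosing the device size and landing zone is
difficult: a poorly sized or positioned device leaves a pocket of slow,
recirculating blood between the ostium and the device where new thrombus can
form.

`laaoplan` implements the computational side of that planning problem for
interventional-imaging and cardiovascular-modeling groups:

1. **Shape analysis** — given a labeled LA/LAA surface mesh (millimetres)
   and an ostium plane, extract the LAA centreline by solving a
   sink-regularized heat-propagation field (ostium = 1, insulated walls) on
   an internal voxelization and marching along its gradient with
   isovalue-front recentring; then measure cross-sections perpendicular to
   the centreline: maximal/minimal Feret diameters D1 and D2, area,
   perimeter, and ostium metrics.
2. **Automatic device configuration** — the device centre is placed on the
   centreline at a geodesic depth of 10 mm (amulet) or 13 mm (watchman)
   with its axis along the centreline tangent.  Amulet sizing adds a
   modality-dependent oversizing offset (2–5 mm CT, 3–6 mm TEE) to
   mean(D1, D2), escalating by 2–5 mm if the target is below D1; watchman
   sizing uses the D1 chart.  Only devices compressed by ≥ 10 % of their
   nominal size at the landing zone are proposed (three amulet, two
   watchman candidates).
3. **Virtual implantation & scenarios** — parametric watertight device
   meshes are rigid-posed into the anatomy to build a two-surface CFD
   domain; scenario variants (20 %-smaller device, misplaced pose,
   interactive overrides) are generated for comparison, and a
   solver-agnostic case bundle (labeled surface + YAML boundary-condition
   manifest: systole 0.40 s with pulmonary-vein velocity inlets, diastole
   0.65 s with an 8 mmHg mitral outlet, blood ρ = 1060 kg/m³,
   μ = 0.0035 Pa·s, rigid no-slip walls) is exported for an external
   Navier–Stokes solver.
4. **Thrombus-risk indices** — external CFD output (per-node wall-shear
   time series) is post-processed into
   TAWSS = (1/T)∫₀ᵀ|τ_w| dt,
   OSI = ½(1 − |∫₀ᵀ τ_w dt| / ∫₀ᵀ|τ_w| dt) and
   ECAP = OSI / TAWSS, with region-of-interest maps between the ostium and
   the device, area- or node-weighted ECAP histograms (the `> 3 Pa⁻¹` bin
   flags high risk), velocity probes, and a ranked per-scenario report.
5. **Synthetic anatomies** — watertight labeled LA bodies with four
   pulmonary veins, a mitral outlet and a parametric (tapered / bent /
   necked / multi-lobed) LAA, plus closed-form wall-shear fields with
   analytic index ground truth, so the whole pipeline is testable without
   patient data.

The flow solve itself is out of scope: the toolkit prepares solver-agnostic
cases and consumes solver output (VTK-family surfaces, long-format CSV).

## Worked example

```python
import laaoplan as lp

mesh, ostium = lp.make_cylinder_laa(radius=10, length=40)   # 20 mm lumen
field = lp.solve_heat_field(mesh, ostium, pitch=1.0)
centreline = lp.march_centreline(field, ostium)
print(f"centreline length: {centreline.length:.1f} mm")

for family in ("amulet", "watchman"):
    for cfg in lp.propose_configuration(mesh, centreline, family, "CT"):
        print(f"{family:8s} {cfg.spec.nominal_size:4.0f} mm   "
              f"depth {cfg.pose.depth:.0f} mm   "
              f"compression {cfg.compression_pct:.1f}%")
```

prints

```
centreline length: 40.7 mm
amulet     25 mm   depth 10 mm   compression 20.0%
amulet     28 mm   depth 10 mm   compression 28.6%
amulet     31 mm   depth 10 mm   compression 35.5%
watchman   24 mm   depth 13 mm   compression 16.7%
watchman   27 mm   depth 13 mm   compression 25.9%
```

The 40 mm tube is recovered to within a millimetre; in a 20 mm lumen the
amulet target is mean(D1, D2) + 3.5 mm = 23.5 mm, escalated past D1, so the
first catalog sizes at or above it with ≥ 10 % compression are proposed;
the watchman candidates come from the D1 sizing chart.  Compression is
100 × (nominal − mean(D1, D2)) / nominal — the anchoring margin.

## Command line

The same pipeline is scriptable via the `laao` CLI, exchanging plain files
(VTP/VTK/STL/PLY/MSH meshes, YAML plans and manifests, CSV tables):

```bash
laao synth anatomy --preset bent --out-mesh anat.vtp --out-truth truth.yaml
laao plan --mesh anat.vtp --ostium truth.yaml --family watchman --out plan.yaml
laao scenarios --plan plan.yaml --out scenarios.yaml
laao implant --plan plan.yaml --out domain.vtp
laao export-cfd --domain domain.vtp --out-dir case/
laao synth wss --mesh domain.vtp --out wss.csv     # stand-in for solver output
laao indices --domain domain.vtp --wss wss.csv --plan plan.yaml --out-dir results/
```

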