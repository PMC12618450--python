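# swellanchor

Hygro-elastic finite element simulation of **swelling bone anchors** in
trabecular bone, coupled to strain-energy-density-driven **bone remodeling**
with overload resorption — with a synthetic micro-CT generator standing in
for animal scan data, so the whole pipeline runs at desk scale.

## The problem

Co-polymeric (MMA/AA) bone anchors absorb interstitial fluid after
implantation and swell in place. The constrained swelling generates
compressive radial pressure at the bone–implant interface, which (i) fixes
the anchor by Coulomb friction (expansion-fit) and (ii) acts as a mechanical
stimulus on the surrounding trabecular bone. Depending on the co-polymer
ratio, that stimulus can densify the peri-implant bone and strengthen
fixation — or overload it and resorb the interface. This package simulates
that interplay and the image-based morphometry used to assess it, for
biomechanics researchers who want a small, fully reproducible model of the
mechanism.

## The model

**Swelling.** Moisture uptake is a stress-free isotropic eigenstrain, linear
in the absorbed moisture: `eps_hs = beta_h (alpha_m − alpha_m,ref)`.
Measured parameter sets for three MMA/AA ratios are built in
(80/20: `beta_h = 1.2287 m^3/kg`, `delta_alpha = 0.1881 kg/m^3`;
85/15: `0.9920 / 0.08672`; 90/10: `0.9032 / 0.0487`). Swelling is applied at
steady state (a saturation fraction scales the moisture field); small-strain
linear elasticity gives `sigma = C (eps − eps_hs)`.

**Heterogeneous bone.** Hounsfield units map linearly to apparent density
and Young's modulus: `rho [g/m^3] = 1041395 + 1017 HU` and
`E [Pa] = −388.8 + 5925 rho`, with densities clamped to `[0.01, 2.0] g/cm^3`.
Elements can optionally be binned into discrete material types (the classic
10-type workflow).

**Remodeling.** Each element's apparent density evolves with the stimulus
`S = U / rho` (strain energy density per unit density, J/g) relative to a
reference `k`, with a lazy zone of half-width `delta·k` and a quadratic
overload term:

```
drho/dt = B (S − (1+delta) k) − D (S − (1+delta) k)^2    if S > (1+delta) k
        = 0                                              in the lazy zone
        = B (S − (1−delta) k)                            if S < (1−delta) k
```

with `B = 1.0`, `D = 60`, `k = 0.004 J/g`, `delta = 0.10`, integrated by
forward Euler (`dt = 0.01`) with clamping, alternating with FE re-solves
until the largest relative density change per window falls below 2%.
`D = 0` recovers the classical linear law. The rate curve peaks at
`S = (1+delta)k + B/2D ≈ 0.0127 J/g` and crosses zero at
`(1+delta)k + B/D ≈ 0.0211 J/g` — beyond that, loading resorbs bone.

**Analysis.** Bone volume ratio (BVR) in a hollow-cylinder ROI at the
interface vs equal-volume spherical ROIs far from it (HU band 200–1000,
paired t-test), and a Coulomb push-out estimate
`F = mu Σ max(p_i, 0) A_i` (`mu = 0.4`) from the interface normal pressure,
compared before and after remodeling.

## Worked example

The packaged 2D demo is a plane-strain transverse section of the implanted
region: a 6 mm radius disc of heterogeneous HU-mapped bone (synthetic
trabecular image, fixed seed, ~5000 voxel elements) around a press-fit 8 mm
anchor, outer boundary fixed:

```
$ swellanchor remodel --demo
swellanchor run report
config_hash: 2e665a6880f820e7
composition: 85/15 (saturation 1.0)
elements: 5024 (bone 2780, anchor 2244)
remodeling checkpoints: 17 (converged: True, euler steps: 17000)
mean interface density: 1.3139 -> 1.6514 g/cm3
floored interface elements: 0
push-out force: pre 163.650 N, post 163.888 N (+0.15%)
bone volume ratio: interface 1.0000, far 0.9152
```

The moderate 85/15 composition drives the interface stimulus into the
apposition branch: the mean density in the 1 mm interface shell rises from
1.31 to 1.65 g/cm^3, no element resorbs to the floor, and the post-remodeling
push-out force strictly exceeds the pre-remodeling one. Rerunning with
`--composition 90/10` gives only a modest response (the stimulus sits near
the lazy zone), while `--composition 80/20` overloads and fully resorbs the
interface shell — the compositional ordering the remodeling law predicts.

The free-swelling validation compares the FE solver against the closed form
`Delta d = d0 · beta_h · delta_alpha` for all three compositions:

```
$ swellanchor free-swell
composition  eigenstrain  dd_fe_mm  dd_closed_form_mm  rel_error
      80/20     0.231118  1.848948           1.848948   2.8e-14
      85/15     0.086026  0.688210           0.688210   2.9e-14
      90/10     0.043986  0.351887           0.351887   2.4e-14
```

Library use mirrors the CLI: `swellanchor.demo_config("85/15")` builds the
configuration, `swellanchor.run_pipeline(cfg)` runs it and returns the mesh,
material states, remodeling history, push-out estimates and BVR results.

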