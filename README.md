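# rodstab

Analysis toolkit for mechanostability studies of the talin rod R3 subdomain —
the four-helix bundle (mouse talin-1, residues ~795–911) that unfolds at the
lowest force of all talin rod subdomains and thereby acts as a cellular
mechanosensor. It is written for researchers who quantify the downstream
readouts of R3 (de)stabilization: steered-MD trajectory metrics, FRAP
turnover in cell–matrix adhesions, adhesion imaging on micropatterned
substrates, and thermal denaturation of purified fragments.

## What it computes

**Steered-MD pull plans and trajectory metrics.** The pull setup fixes the
α-carbons of H1 residues Q800, T804, V808 and S815 and pulls the α-carbons of
H4 residues Q888, G896, A900 and A904 at constant force (default 150 pN)
along +z, after orienting the V808–G896 vector (d3) to the z axis inside a
10 × 10 × 30 nm box. From solvated trajectories, the package computes:

- the **core water penetration count**: water oxygens within 5 Å of at least
  one heavy atom of *every* one of the four helices — the unfolding readout —
  with a KD-tree fast path verified against an all-pairs brute force;
- the four **H1–H4 displacement series** d1–d4 between α-carbon pairs
  800–904, 804–900, 808–896, 815–888;
- the 10-frame **sliding average** used for plotting and replicate averaging
  across repeat runs;
- the **refolding time**: the earliest time from which d3 stays within a
  tolerance band (default 0.05 nm) of its pre-pull baseline.

**FRAP.** Recovery traces are normalized with the double ratio
F(t) = [B(t)/⟨B⟩_pre] / [Cell(t)/⟨Cell⟩_pre] (which cancels acquisition
fading), full-scale normalized (post-bleach floor → 0, pre-bleach plateau →
1), and fitted with F(t) = M·(1 − e^{−kt}); M is the mobile fraction and
t½ = ln 2 / k the half-recovery time.

**Adhesion imaging.** Adhesion/cytosol intensity ratios, vinculin/talin
ratios, Gaussian-blur + threshold paxillin masks, the thresholded Mander's
split coefficient M1, square-lattice micropattern masks (square/pitch = 0.75
→ 56 % fibronectin coverage), the fraction of adhesion area on fibronectin,
and per-track migration speeds (path length / duration).

**Melt fitting.** Two-state van 't Hoff model with linear baselines,
signal(T) = (b_f(T) + b_u(T)·K(T)) / (1 + K(T)) with
K(T) = exp[−ΔH/R·(1/T − 1/Tm)], fitted to single-wavelength CD melts to
recover Tm.

**Synthetic data.** Every measurement type has a seeded generator with known
ground truth (opening bundle trajectories, FRAP records, micropattern scenes,
melts, persistent random walks), so generate → analyze → compare round trips
back the entire test suite.

## Worked example

```python
import rodstab as rs

# FRAP: generate a noisy recovery at a known mobile fraction and re-fit it
rec, truth = rs.gen_frap(0.33, half_time_s=10.0, noise_sigma=0.02, seed=42)
fit = rs.analyze_frap(rec)
print(f"mobile fraction: {fit.mobile_fraction:.3f}")   # 0.332
print(f"half time:       {fit.half_time_s:.2f} s")     # 9.49 s

# Thermal melt at a known midpoint
curve, _ = rs.gen_melt(66.9, noise=0.02, seed=42)
print(f"Tm: {rs.fit_melt(curve).tm_C:.1f} C")          # 67.0 C

# Micropattern scene: 26 % of adhesion area placed on fibronectin squares
scene, masks, _ = rs.gen_scene(0.26, n_adhesions=500, seed=1)
frac = rs.fn_fraction(masks["adhesion"], masks["pattern"])
print(f"Fn fraction: {100 * frac:.1f}%")               # 26.1%

# Pull plan for an oriented bundle
plan = rs.build_pull_plan(rs.orient_to_axis(rs.gen_bundle(), 808, 896), 150.0)
print([n for n, _ in plan.fixed_atoms])                # [800, 804, 808, 815]
print([n for n, _ in plan.pulled_atoms])               # [888, 896, 900, 904]
```

The FRAP fit recovers the generating mobile fraction (0.33) to within the
noise floor; the melt fit recovers the generating midpoint to 0.1 °C; the
scene quantification returns the placement fraction to well within 2
percentage points.

A `rodstab` command-line tool exposes the same operations on files
(`rodstab plan`, `conserve`, `waters`, `displace`, `frap`, `melt`, `coloc`,
`migrate`, `synth`); see `rodstab --help`.

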