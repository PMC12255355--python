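# pafluence

Depth-dependent fluence compensation for quantitative photoacoustic (PA)
imaging, without prior knowledge of tissue composition.

PA amplitude is proportional to the local optical fluence, which falls
off with depth, so raw PA images systematically understate absorbers at
depth. `pafluence` estimates the effective optical attenuation
coefficient `μeff` of the bulk tissue *in situ* — from PA amplitude
measured while the optical path length to a target changes — and uses it
to equalize amplitudes across depth. The catch is that fluence from a
real aperture also spreads geometrically; the package separates the two
effects with the generalized fluence model

    φ(r) ∝ (c/r)^b · φ0 · exp(−μeff·r),        μeff = √(3 μa (μa + (1−g) μs))

where the power-law exponent `b` is **intrinsic to the light-delivery
aperture**: 1 for a point source in scattering media, 2 in
absorption-dominant media, 0 for a plane, and ≈0.5 for a 30 × 2 mm
rectangular fiber output. One voxel Monte Carlo run in any
scattering-dominant medium fixes `b` for an aperture; every soft tissue
(μs:μa > 100:1) then shares it. With `b` known, a moving-window
log-linear fit of `P(r)·r^b` against `r` recovers `μeff`, and

    gain(r) = (r/r_ref)^b · exp(+μeff·(r − r_ref))

compensates amplitudes at depth.

The package is aimed at PA/US researchers who want (i) a CPU voxel Monte
Carlo engine for fluence profiles of point / plane / rectangular-aperture
sources, (ii) the windowed estimators for `b` and `μeff`, (iii) synthetic
generators for the two bench protocols (liquid-bath translation and
solid-tissue fiber displacement), and (iv) the compensation step itself.

## Worked example

Derive the geometry parameter of a 30 × 2 mm fiber output from a Monte
Carlo run in muscle-like tissue, then recover `μeff` from a synthetic
displacement experiment:

```python
import pafluence as pf

# 1) aperture geometry parameter from one MC run (any scattering tissue)
muscle = pf.tissue_properties("muscle", 700)     # mua=0.048, mus=8.18 mm^-1
volume = pf.homogeneous_volume((64.0, 48.0, 48.0), 0.2, muscle)
source = pf.SourceSpec(kind="rect_aperture", width=30.0, height=2.0)
fluence, ledger = pf.run_mc(volume, source, photons=600_000, seed=7)
profile = pf.extract_profile(fluence, source, mode="lateral_mean", max_r_mm=15.0)
fit = pf.estimate_b(profile, pf.effective_attenuation(muscle))
print(f"b = {fit.b_converged:.3f}")             # b = 0.537

# 2) mueff from a displacement trace (fiber pressed into tissue, 0.10 mm/s)
cfg = pf.ExperimentConfig(mode="displacement", mueff_true=0.353, b_true=0.5,
                          r_start=20.0, r_end=17.0, speed=0.10, seed=7)
trace = pf.smooth_trace(pf.generate_trace(cfg), 30)
strain = pf.strain_axis(trace, initial_length=20.0)
est = pf.estimate_mueff_windowed(trace, b=0.5, window=20, aux_axis=strain)
mueff = pf.aggregate_mueff(est, (0.02, 0.10), centers=est.aux_centers, axis="strain")
print(f"mueff = {mueff:.3f} mm^-1")             # mueff = 0.357 mm^-1
```

The first number is the aperture's geometry parameter (median of the
windowed power-law fits over the 1–10 mm valid range): close to 0.5,
between a point source's 1 and a plane's 0, because light sidescatters
past the aperture edges. The second is the attenuation recovered from
amplitude-versus-strain, within ~1.2% of the 0.353 mm⁻¹ that generated the
trace. Applying `pf.CompensationModel(b=0.5, mueff=mueff, reference_r=5.0)`
with `pf.compensate_trace` then flattens depth-dependent amplitude decay.

A command-line interface wraps the same pipeline
(`pafluence simulate-mc / fit-b / generate / estimate-mueff / compensate`);
each subcommand reads a YAML config and writes CSV/JSON plus a run
manifest. See `docs/methods.md` for the model, numerical choices, and
limitations.

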