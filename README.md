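# spheroflow

Interstitial-flow and solute-transport modelling, plus fluorescence
time-lapse quantification, for tumor-spheroid-on-chip experiments.

## What this is for

Microfluidic chips that embed a multicellular tumor spheroid (~200 µm) in a
hydrogel channel and drive a slow interstitial flow (IF) across it are a
standard platform for studying how biophysical forces shape tumor biology.
Interpreting such experiments needs two computational layers that this
package provides as a tested library:

1. **Physics of the chip.** The gel is a porous medium, so the interstitial
   velocity follows Darcy's law, `u = −(K/µ)∇p`, with hydraulic
   permeability `K` and viscosity `µ`. `spheroflow` solves the
   heterogeneous pressure equation `∇·((K/µ)∇p) = 0` on a 2D plan view of
   the gel channel with the spheroid as a low-permeability circular
   inclusion, and derives the mean IF velocity `u_m`, the hydrodynamic
   normal (compressive) stress `p − P₂` on the spheroid interface, and a
   Brinkman-style estimate of the viscous shear `µ_e γ̇` just outside it.
   A solute module then integrates `∂C/∂t + u·∇C = ∇·(D∇C)` to predict how
   an exogenous cytokine (e.g. TGF-β, ~25 kDa) penetrates the gel and when
   the spheroid interface saturates to the inlet concentration `C₀`.
2. **Quantification of the movies.** From multi-channel time-lapse stacks
   it computes ROI-integrated reporter intensity normalized to the first
   frame (`I(t)/I₀`, with the 70 h endpoint `I₇₀/I₀` as the fold-change
   statistic), azimuthal intensity profiles via a polar transform (radially
   averaged intensity vs θ, with θ = 90° at the inlet-facing pole — the
   readout in which IF imprints a top/bottom asymmetry), and per-pixel
   temporal standard-deviation maps of the bright-field channel as a proxy
   for peripheral cell motility. Welch (unequal-variance) t-tests with the
   conventional star thresholds compare conditions.

Because raw microscopy from such experiments is rarely available, the
package includes a first-class synthetic-data generator that renders
ground-truthed spheroid movies (saturating reporter kinetics, flow-imprinted
asymmetry, shot/read noise, rim-cell jitter), so every pipeline stage is
testable end to end.

## Worked example

```python
from spheroflow.geometry import build_geometry
from spheroflow.flow import (FlowBC, PorousMedium, calibrate_permeability,
                             interfacial_stress, mean_interstitial_velocity,
                             solve_flow)
from spheroflow.transport import (TransportParams, interface_probe,
                                  simulate_transport, time_to_saturation)

# 1 mm gel channel, 200 um spheroid at 1% relative permeability, 5 um grid
geom = build_geometry(width=1000, span=1000, spheroid_radius=100, grid_spacing=5)
bc = FlowBC.from_mbar(30)                      # dP = 30 mbar = 3000 Pa
K = calibrate_permeability(0.45, bc, geom)     # gel K giving u_m = 0.45 um/s
med = PorousMedium(permeability=K)
field = solve_flow(geom, med, bc)
stress = interfacial_stress(field, geom, med, bc)
series = simulate_transport(field, geom, TransportParams(duration_min=400))
sat = time_to_saturation(series, interface_probe(geom), 0.95)
```

prints, via the obvious f-strings:

```
calibrated K = 1.537e-16 m^2
u_m = 0.450 um/s
peak normal stress = 2.08 kPa
max shear stress   = 0.068 mPa
95% saturation of spheroid interface at 56 min
```

i.e. at a 30 mbar drop the spheroid feels kPa-scale compressive stress but
only sub-mPa viscous shear, and the advecting solute saturates the
interface within an hour — long before the 70 h imaging window.

The imaging side, run on a generated movie with endpoint fold change
A = 13, top/bottom asymmetry g = 1.25 and motile rim cells:

```python
from spheroflow.synth import SyntheticConfig, render_timelapse
from spheroflow import imaging as im

stack, truth = render_timelapse(SyntheticConfig(asymmetry=1.25, motile=True, seed=7))
roi = im.segment_spheroid(stack.channel("gfp")[0], polarity="bright")
series = im.intensity_timeseries(stack, roi, "gfp")
prof = im.azimuthal_profile(stack, roi, "gfp", times=[0.0, 70.0])
```

```
I70/I0 = 12.21  (generator truth 12.27)
top/bottom = 13.35/10.99 = 1.21
peripheral motility score = 1.99
```

The normalized endpoint recovers the generated kinetics to <1%, the
azimuthal ratio recovers the imposed asymmetry within 3%, and the motility
score of ~2 (peripheral temporal SD relative to background) flags the
jittering rim; a static movie scores ~1.

A `spheroflow` console script exposes the same stages
(`spheroflow run --config run.toml --stages synth,analyze,stats`), driven
by a TOML configuration; outputs are tidy CSV tables, deterministic `.npz`
field containers and a JSON manifest of artifact hashes.

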