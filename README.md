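# steamref

Reference-scheme bias analysis for diffusion-weighted stimulated-echo
(DW-STEAM) MRI.

## The problem

Diffusion-time (Δ) dependence of the apparent diffusion coefficient (ADC)
is a key probe of tissue microstructure: water confined in axons shows a
perpendicular ADC that falls with Δ, which is used to infer compartment
sizes and membrane permeability.  Long diffusion times are only practical
with stimulated echoes, which store magnetization longitudinally during
the mixing time τ_m and trade T2 decay for the slower T1 decay.

The catch is the reference ("b0") image.  In DW-STEAM, the crusher
gradients that spoil unwanted signal from the third RF pulse straddle the
mixing time, so the reference acquires a non-negligible b-value

    b = γ²δ²G²(Δ − δ/3) = q²(Δ − δ/3),   q = γδG,

that grows with Δ if the crusher area q₀ is held constant (**fixed-q₀**
design).  The two-point ADC estimate

    ADC = −ln(S/S₀) / (b − b₀)

is exact for mono-exponential decay regardless of b₀, but for *any* tissue
with more than one diffusion coefficient it decreases as b₀ increases.  A
fixed-q₀ reference schedule therefore manufactures an apparent Δ-dependence
of the ADC — mimicking restriction in a completely unrestricted system.
Holding the reference b-value constant instead (**fixed-b₀**, pinned at its
value for the longest Δ) removes the artifact at the cost of a uniformly
larger underestimation.

`steamref` implements the full quantitative argument as a tested pipeline:

- **sequence_models** — STEAM timing, q/b algebra, fixed-b₀/fixed-q₀
  reference schedules, effective gradient waveforms for the conventional
  and modified (crusher-flipped) crusher layouts, and exact piecewise
  b-matrix integration.
- **tissue_signals** — biexponential, Gaussian-tensor, and two-compartment
  restricted-cylinder signal models; the restricted propagator is a
  narrow-pulse Bessel-root eigenfunction series.
- **mc_validation** — an independent Monte Carlo random-walk oracle
  (specular reflection in the cylinder cross-section) used to validate the
  analytic series.
- **adc_analysis** — two-point ADC curves per reference scheme, percentage
  difference maps, full-b-matrix weighted tensor fits, FA/MD tissue masks,
  and short-vs-long-Δ summaries.
- **synthetic_data** — a phantom 4D DWI generator emulating a postmortem
  corpus-callosum experiment (8 diffusion times 70–400 ms, 30 directions at
  b = 3.5 ms·μm⁻², δ = 2.22 ms, TE = 16 ms, two reference series, T1 ≈ 600 ms
  STEAM amplitude weighting, Rician noise).
- **cli** — the `steamref` command-line pipeline.

## Worked example

Simulate a noiseless biexponential phantom under the default protocol and
analyze it with both reference schemes:

```sh
steamref simulate -c examples/biexp_noiseless.yaml -o out --seed 7
steamref analyze -d out/dataset -c examples/biexp_noiseless.yaml -o out --seed 7
cat out/time_dependence.csv
```

For a purely biexponential phantom (f_s = 0.3, D_s = 0.2, D_f = 1.0 μm²/ms,
noiseless) the summary reads

```
# steamref 0.1.0 config=4af6b2b2ba9d
label,dADC_pct_fixed_q0,dADC_pct_fixed_b0,added_dependence_pct
gm longitudinal,7.628284767,1.447718587e-13,5.269176508e+15
gm radial,7.628284767,9.651457244e-14,7.903764762e+15
gm md,7.628284767,1.568361802e-13,4.863855238e+15
```

i.e. the fixed-q₀ reference produces a 7.6 % apparent drop in ADC between
Δ = 70 ms and Δ = 400 ms in a system with **no** restriction whatsoever,
while fixed-b₀ yields a flat curve to numerical precision (so the added-
dependence ratio, which divides by it, is meaningless noise here).  The
same pipeline applied to the default two-compartment cylinder phantom
separates genuine restriction (present under both schemes) from the
reference-induced exaggeration.

Library-level equivalent:

```python
from steamref.sequence_models import postmortem_protocol
from steamref.tissue_signals import BiexponentialModel
from steamref.adc_analysis import adc_time_curve, adc_scheme_difference

curve = adc_time_curve(BiexponentialModel(0.3, 0.2, 1.0), postmortem_protocol())
print(adc_scheme_difference(curve))  # % of the true (b0=0) ADC, per Delta
```

Other subcommands: `design` (reference schedules and gradient strengths),
`curves` / `contours` (ADC-vs-Δ line plots and difference maps over (Δ, b)),
`seqcheck` (conventional vs modified crusher layout b-value table),
`validate` (Monte Carlo vs analytic series), `figures` (SVG plots from any
results directory).

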