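# dcmrf — dual-contrast MR fingerprinting

`dcmrf` simulates and quantifies MRI experiments in which **two paramagnetic
contrast agents are measured simultaneously**. Conventional contrast-enhanced
MRI cannot tell two co-administered agents apart, because every paramagnetic
agent shifts both relaxation times at once. But if T1 and T2 are measured
*simultaneously* — as MR fingerprinting (MRF) does — a linear two-agent
relaxation model becomes a 2×2 linear system with a closed-form solution for
the two concentrations. This package implements that method end to end for
researchers developing multi-agent ("multi-color") quantitative MRI:
simulation of the acquisitions, dictionary-based T1/T2 mapping, relaxivity
calibration, and per-agent concentration mapping, all testable against
built-in digital phantoms.

## The model

Each agent raises the relaxation rates in proportion to its concentration
(relaxivities r₁, r₂ in mM⁻¹ms⁻¹, concentrations in mM, times in ms):

    1/T1 = 1/T1₀ + r₁A·[A] + r₁B·[B]
    1/T2 = 1/T2₀ + r₂A·[A] + r₂B·[B]

Given the pre-contrast baseline (T1₀, T2₀), the four relaxivities, and one
co-registered (T1, T2) measurement, the concentrations follow analytically:

    ΔR1 = 1/T1 − 1/T1₀,  ΔR2 = 1/T2 − 1/T2₀
    [A] = (ΔR2·r₁B − ΔR1·r₂B) / (r₂A·r₁B − r₁A·r₂B)
    [B] = (ΔR2 − r₂A·[A]) / r₂B

The inversion is well-posed only when the two agents' (r₁, r₂) pairs are not
proportional — the default agent pair (a Gd chelate and MnCl₂) has strongly
contrasting r₂/r₁ ratios, and `dcmrf` raises `SingularModelError` when the
relaxivity determinant degenerates.

The package's five modules cover the full experiment:

| module | role |
|---|---|
| `dcmrf.relaxation` | dual-agent model, closed-form inversion, relaxivity calibration |
| `dcmrf.relaxometry` | benchtop IR-SE / CPMG simulation and mono-exponential fitting |
| `dcmrf.mrf` | EPG simulation of the FISP-MRF kernel, dictionary build, inner-product matching |
| `dcmrf.phantom` | digital 17-vial phantoms with ground-truth concentration maps |
| `dcmrf.quantify` | concentration maps, ROI statistics, calibration reports, t-tests, pipeline driver |

## Worked example

```python
from dcmrf import (ConcentrationPair, forward_relaxation, invert_dual_agent)
from dcmrf.presets import GD_60MHZ, MN_60MHZ, WATER_60MHZ

# A water sample doped with 0.2 mM Gd + 0.1 mM Mn, at the published
# 60 MHz relaxivities and water baseline (T1_0 = 4250 ms, T2_0 = 2760 ms):
meas = forward_relaxation(WATER_60MHZ, GD_60MHZ, MN_60MHZ,
                          ConcentrationPair(0.2, 0.1))
print(meas)
# RelaxationTimes(T1=634.8020911127708, T2=127.51330573625076)

print(invert_dual_agent(WATER_60MHZ, GD_60MHZ, MN_60MHZ, meas))
# ConcentrationPair(agent_a=0.19999999999999993, agent_b=0.09999999999999999)
```

One (T1, T2) pair — here T1 shortened mostly by the Gd, T2 dominated by the
Mn — separates cleanly into the two generating concentrations.

The CLI drives the same machinery at image scale. A quick synthetic study on
a 48×48 phantom with a 300-excitation train, the reduced dictionary grid,
1% noise and 3 repeats:

```
$ cat cfg.json
{"image_shape": [48, 48], "schedule": {"n": 300, "seed": 11},
 "grid": "coarse", "noise_sd": 0.01, "n_repeats": 3, "seed": 5}
$ dcmrf simulate --config cfg.json -o out/
Gd: slope=0.967 r2=0.9875
Mn: slope=0.982 r2=0.9898
```

The two lines are the estimated-vs-true regression over the 17 vials: an
ideal method gives slope 1 and r² = 1; this quick run is limited by the
coarse dictionary quantization. With the full grid and a 1000-excitation
train the slopes land within ~0.01 of unity (see the acceptance tests).
`out/` contains the dictionary (HDF5), concentration maps (NIfTI), per-vial
ROI and calibration tables (CSV), and a JSON-lines run log.

`dcmrf dictionary`, `dcmrf match`, `dcmrf quantify` and `dcmrf report`
expose the individual stages for externally supplied series or maps.

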