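# peritrack

Analysis pipeline for live-cell measurements of **transcription-driven
gene-locus relocation** in rod-shaped bacteria — written for
microscopists and quantitative biologists who count actively transcribing
RNA polymerases from fluorescence movies, extract transcription kinetics,
and ask whether (and how far) a transcribed locus moves toward the
nucleoid periphery.

Everything is exercisable end-to-end on synthetic data with known ground
truth; no external downloads are required.

## The models at the core

**Transcription kinetics.** The number of polymerases bound to a single
induced gene is modeled as an immigration–death process — arrivals at a
constant pseudo-first-order rate *k*<sub>on</sub> (promoter search +
initiation) and independent departures at rate *k*<sub>off</sub> (set by
the elongation duration).  The population mean after induction is

> ⟨N⟩(t) = a (1 − e^(−b t)),  a = *k*<sub>on</sub>/*k*<sub>off</sub>,  b = *k*<sub>off</sub>

and fitting (a, b) to the measured induction curve yields the elongation
rate *L*·*k*<sub>off</sub> for a gene of length *L*, the elongation time
1/*k*<sub>off</sub>, and the promoter search time 1/*k*<sub>on</sub>.

**Polymerase counting.** The focus intensity of a cell is measured by the
ROMIF — the 5×5-pixel window of maximum integrated fluorescence — as
I_max = mean(ROMIF) − mean(cellular background); the population average
above the pre-induction baseline, divided by the single-fluorophore unit
⟨Ī_single⟩ (mean integrated 5×5 dot intensity / 25), gives the mean
number of transcribing polymerases per cell.

**Locus position.** Foci are localized by sub-pixel 2D-Gaussian fitting
and expressed in cell-normalized coordinates: offsets along the short (x)
and long (y) cell axes divided by the full axis lengths (membrane at 0.5)
and folded into the first quadrant by cylindrical symmetry.

**Nucleoid-periphery Monte Carlo.** Loci start uniform on the nucleoid
cross-section disk of normalized radius *l* (default 0.35), are observed
with a 70-nm localization error, and move radially outward by a
configurable mean step.  The model maps a measured shift of the mean
folded coordinate ⟨|x|⟩ back to a 3D radial displacement in nm by
bisection with common random numbers.

## Worked example

Run the built-in demo (60 synthetic cells induced at
*k*<sub>on</sub> = 0.46 min⁻¹, *k*<sub>off</sub> = 1.12 min⁻¹, locus
relocated outward by 61 nm from t = 60 s):

```bash
peritrack run --out demo/
```

which prints a summary like

```json
{
  "kinetics": {
    "a": 0.396, "b": 0.909, "b_se": 0.276,
    "elongation_rate_bp_s": 68.2, "elongation_time_s": 66.0
  },
  "locus_position": {
    "early": {"mean_x_rel": 0.149, "n": 16},
    "late":  {"mean_x_rel": 0.201, "n": 109}
  },
  "geometry": {
    "projected_shift": 0.0699, "inverted_step_nm": 60.9,
    "percent_of_nucleoid": 20.3
  }
}
```

Reading it: the refit off-rate b = 0.91 ± 0.28 min⁻¹ brackets the
generative 1.12 min⁻¹ (a 60-cell movie is deliberately small); the mean
folded position of the locus rises from 0.149 — exactly the uniform-disk
expectation 4l/(3π) ≈ 0.1486 for l = 0.35 — to 0.201 after the 61-nm
outward step; and the cross-section Monte Carlo confirms that a 61-nm
step projects to a ≈0.07 shift of ⟨|x|⟩, inverting back to 60.9 nm,
i.e. ~20% of a 300-nm nucleoid half-width.

The same stages are available piecewise (`peritrack simulate | quantify |
localize | fit-kinetics | fit-decay | geometry | report`), and as library
calls:

```python
from peritrack import kinetics, periphery

est = kinetics.derive_rates(a=0.41, b=1.12, gene_length_bp=4500)
est.elongation_rate_bp_s   # 84.0 bp/s
est.elongation_time_s      # 53.6 s

model = periphery.CylinderModel()            # l=0.35, 70-nm error
periphery.forward_shift(model, 61.0)         # ~0.07
```

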