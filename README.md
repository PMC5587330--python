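# migetsim

Forward simulation and MIGET inversion of a five-compartment in vitro lung
model, with method-agreement statistics.

## The problem

The multiple inert gas elimination technique (MIGET) is the reference method
for quantifying ventilation–perfusion (V/Q) heterogeneity of the lung: six
inert tracer gases spanning four decades of solubility are infused at steady
state, and the distribution of perfusion over V/Q compartments is inferred
from their *retentions* — the ratio of arterial to mixed-venous partial
pressure per gas. Validating a MIGET instrument requires a gas-exchange
system whose true shunt fraction is *known*. A bench circuit of five
parallel membrane oxygenators, each ventilated with sweep gas (V) and
perfused (Q) at 500 ml/min, provides exactly that: bypassing k of the 5
units with shunt tubes presets a true shunt of k/5 while total pump flow
(2500 ml/min) is unchanged.

`migetsim` implements that validation study end-to-end as software, for
people developing or stress-testing MIGET analysis pipelines:

* a **forward model** of the circuit — each oxygenator is an ideal
  equilibrating compartment obeying the Farhi relation
  `R = λ / (λ + V/Q)`, and the circuit retention is the perfusion-weighted
  mixture `R_j = q_s + Σ_i q_i · λ_j / (λ_j + V_i/Q_i)` with shunt fraction
  `q_s`;
* a **MIGET inversion engine** — smoothed non-negative least squares over a
  50-compartment log-spaced V/Q grid, minimising
  `‖W(R − Aq)‖² + Z‖Dq‖²` subject to `q ≥ 0, Σq = 1`, with
  `A[j,k] = λ_j/(λ_j + vq_k)` and `D` a second-difference smoother; derived
  shunt (MM-S) is the recovered perfusion at `V/Q < 0.005`;
* a **synthetic-study generator** reproducing the experiment's design
  (5 shunt settings × 2 duplicates × 2 perfusates, 1% flow-meter error, 2%
  multiplicative retention noise, seeded-random setting order);
* **agreement statistics** between preset (IVLM-S) and derived (MM-S)
  shunt: OLS regression, Bland–Altman with limits of agreement at
  bias ± 2·SD, and duplicate coefficient of variation.

## Worked example

```python
import migetsim as ms

circuit = ms.bypass_units(ms.five_unit_circuit(), 2)   # 2 of 5 units shunted
panel = ms.default_panel("blood")
record = ms.predict_retentions(circuit, panel)          # noiseless retentions
dist = ms.VQDistributionModel(record, panel).fit()
print(dist.summary())
```

```
Perfusion distribution (smoothed NNLS)
--------------------------------------
compartments        : 50
shunt (V/Q < 0.005) : 0.3878
RSS                 : 9.611e-04
converged           : True
smoothing weight Z  : 40

gas     lambda    R_obs    R_fit
SF6      0.0055   0.4033   0.3938
KR        0.045   0.4258   0.4304
DES        0.45   0.5862   0.6060
ENF         1.9   0.7931   0.7801
DEE          12   0.9538   0.9369
AC          300   0.9980   0.9969
```

The true shunt is 0.40; the smoothed inversion recovers 0.388 (enforced
smoothing spreads a little shunt mass into the lowest ventilated
compartments — with `smoothing_weight=0` the recovery is 0.3999). The gas
columns show how retention rises with solubility λ from SF6, which tracks
shunt almost directly, to acetone, which is retained nearly completely.

The full synthetic replication runs from the shell:

```bash
migetsim reproduce-study --seed 42 --out out/demo
```

```
Agreement report (blood, n = 10 pairs)
-----------------------------------------------
regression : MM-S = 0.980 * IVLM-S + -0.007
             r^2 = 0.998  (p = 6.5e-12)
Bland-Altman: bias = -0.016, 2 SD = 0.030
             limits of agreement [-0.046, +0.015]
duplicate CV: 2.4%
  published : slope 0.87, r^2 0.96, bias -0.085, LoA [-0.190, +0.020]
```

With only the modelled error sources (ideal compartments, 2% retention
noise, 1% flow error) the derived shunt tracks the preset shunt more
tightly than the physical bench did — the printed side-by-side comparison
makes the gap to the published bench statistics explicit. `simulate`,
`invert` and `validate` run the three pipeline stages separately; every
command writes a `manifest.yaml` from which its outputs can be regenerated.

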