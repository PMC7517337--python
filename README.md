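# cmboot

Statistical inference for the information dynamics of symbolic time
series: ϵ-machine reconstruction by CSSR, exact computation of entropy
rate, excess entropy, and statistical complexity, and bootstrap confidence
distributions that turn those point estimates into p-values, confidence
curves, and confidence intervals.

## Who this is for

Given a single discrete-time, finite-alphabet sequence — a binarized
neural spike train, an active/inactive behavioral record, any symbolic
record of a stationary process — one often wants more than a point
estimate of its information-theoretic properties: a confidence interval
for the entropy rate, or a test of whether the memory of the process
exceeds some value. `cmboot` provides that inferential layer.

## The model and the measures

A stationary process is represented by its **ϵ-machine**: the minimal
hidden-state model whose states (the *causal states*) are equivalence
classes of pasts with identical predictive distributions, and which is
*unifilar* — state and emitted symbol determine the successor. From a
machine with stationary state distribution π three measures follow
exactly (all in bits):

- entropy rate hμ = −Σ_s π(s) Σ_x P(x|s) log₂ P(x|s) — intrinsic
  randomness per symbol;
- statistical complexity Cμ = −Σ_s π(s) log₂ π(s) — memory needed for
  optimal prediction;
- excess entropy E = Σ_L (hμ(L) − hμ) — past–future mutual information,
  computed by mixed-state (belief) propagation with truncation depth 200;
  always E ≤ Cμ.

The machine is estimated from data by **CSSR** (Causal State Splitting
Reconstruction): histories are grouped into candidate states, split when a
χ² test (α = 0.001) finds different next-symbol distributions,
determinized, and reduced to the recurrent core. The history length is
selected by BIC. Uncertainty comes from the **computational mechanics
bootstrap**: simulate B series from the fitted machine, re-fit each, and
use the empirical distribution of the re-estimated measures as a
confidence distribution C(θ) — percentile or bias-corrected — from which
p-values (two-sided: 2 min{C, 1−C}), confidence curves |2C−1|, and
equi-tailed intervals (C⁻¹(α/2), C⁻¹(1−α/2)) all follow. A Markov-model
bootstrap is included for comparison; on sofic processes (finite causal
states but no finite Markov order) it fails badly, which the test suite
reproduces.

See `docs/methods.md` for algorithmic details and numerical choices.

## Worked example

```sh
$ cmboot simulate --process even --param p=0.5 -T 10000 --seed 42 --out seq.txt
wrote 10000 symbols to seq.txt
$ cmboot infer --in seq.txt --out machine.json
BIC selected L0 = 3
2 recurrent states -> machine.json
$ cmboot measures --machine machine.json
{
 "h_mu": 0.6674645582166352,
 "E": 0.9174895522070441,
 "C_mu": 0.9174895522074329,
 "Ltr": 200
}
$ cmboot bootstrap --in seq.txt --B 200 --seed 7 --out boot.csv --cis cis.json
h_mu: 0.667465  95% CI [0.661852, 0.674644]
E: 0.917490  95% CI [0.909343, 0.922833]
C_mu: 0.917490  95% CI [0.909343, 0.922833]
```

The simulated process is the *even process* (runs of 1s of odd length
forbidden): CSSR recovers its 2-state architecture from 10⁴ symbols, the
plug-in measures land near the exact values hμ = 2/3 and
E = Cμ = 0.91829583 bits, and every 95% bootstrap interval covers the
truth. The same pipeline is available as library calls
(`cssr_estimate`, `select_model`, `measure_set`, `cm_bootstrap`,
`percentile_cd`, `confidence_interval`, ...), and `cmboot coverage` /
`cmboot nulltest` run full Monte Carlo coverage and calibration studies
from a YAML config.

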