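# trajinfo

Estimating the mutual information between a discrete environmental input and
the **time-varying, stochastic response trajectory** of a biochemical
reaction network — for systems biologists who want to know how many bits a
single cell's signaling time course carries about its environment, and for
methodologists who want calibrated benchmarks for trajectory-based
information estimators.

## The problem and the method

A cell experiences one of `q` environments `u⁽¹⁾…u⁽q⁾` (uniform prior by
default) and responds through a reaction network whose rates depend on the
input. The response is a molecule-count path `x(t)` on `[0, T]`, observed
either in continuous time or sampled at `d` uniform time points. Direct
estimation of `I(X;U)` over the path space is intractable; this package
implements the complementary routes that together bracket it:

* **Exact Monte-Carlo information** (model-based). When the network is
  known, the likelihood of any path is explicit from the chemical master
  equation: survival factors `exp(M_ss t)` and jump rates `M_{s's}` in
  continuous time (`p(x|u) = p(s₁)e^{M_{s₁s₁}t₁} ∏ᵢ M_{sᵢsᵢ₋₁}e^{M_{sᵢsᵢ}tᵢ}`),
  or products of propagator entries `W = e^{MΔt}` for discretized paths.
  Averaging exact log-likelihoods over SSA-sampled paths gives
  `Ĩ = H̃(X) − H̃(X|U)` with Monte-Carlo error only — the "gold truth".
* **Decoding bounds.** MAP decoding
  `û = argmax_u [log p(x|u) + log p_U(u)]` gives the smallest possible error
  probability; the plug-in information of the `q × q` confusion matrix,
  `I(Û;U) = Σᵢⱼ εᵢⱼ log₂ εᵢⱼ/(Σₖεₖⱼ Σₗεᵢₗ)`, lower-bounds `I(X;U)` by the
  data-processing inequality, and the same matrix yields a Feder–Merhav-type
  upper bound `I_UB = H(U) − Σ_û p_Û(û) φ(π_û)` through the floor/ceiling
  construction `φ/α`.
* **Model-free decoding estimators** for real data: linear and RBF-kernel
  SVM (multiclass via dendrogram-SVM), a diagonally regularized Gaussian
  decoder, and an MLP decoder — each evaluated on held-out stratified 70/30
  splits with replicate error bars — plus the knn (Kraskov-type) mutual
  information and the Gaussian approximation as non-decoding baselines.

Three birth-death example networks are packaged (steady-state-mean readout;
adapted transient readout; mean-matched readout where only temporal
correlations carry the input) together with a benchmark harness, multilevel
(`q = 2…5`) input variants, and per-cell extrinsic-noise perturbations.

## Worked example

```python
import numpy as np
from trajinfo import (PathLikelihoodModel, exact_info, make_example,
                      map_info_bound, estimate_info)
from trajinfo.simulate import discrete_matrix, simulate_dataset

net, ens, x0 = make_example(1)                   # alpha = 0.1 vs 0.07, beta = 0.01
model = PathLikelihoodModel(net, ens, x0, 2000.0)
data = simulate_dataset(net, ens.labels, x0, 2000.0, 300, seed=42)

i_cont = exact_info(model, data, mode="continuous")
i_disc = exact_info(model, data, mode="discrete", d=100)
i_map, i_ub, eps = map_info_bound(model, data, mode="discrete", d=100)

X, _, labels = discrete_matrix(data, 100)
i_svm, svm_std, _ = estimate_info(X, np.asarray(labels), method="svm-rbf",
                                  replicates=5, random_state=0)
```

prints (values are seed-dependent Monte-Carlo estimates):

```
exact continuous-time information : 0.953 bits
exact information at d = 100      : 0.828 bits
MAP decoding lower bound          : 0.774 bits
confusion-matrix upper bound      : 0.927 bits
RBF-SVM decoding estimate         : 0.743 +/- 0.075 bits
```

Reading: at `T = 2000` the continuous-time trajectories of example 1 carry
~0.95 of the 1-bit budget of a uniform binary input; sampling them at
`d = 100` keeps ~87% of that; optimal decoding of the sampled paths recovers
0.77 bits, bracketed above by the 0.93-bit upper bound; and the model-free
RBF-SVM — which never sees the network model, only 300 labeled paths per
input — comes within a few hundredths of a bit of the optimal decoder.

The same machinery is exposed on the command line (`trajinfo simulate`,
`exact-info`, `map-bound`, `estimate`, `benchmark`); `trajinfo estimate
--data table.csv` accepts any wide CSV of labeled single-cell time series.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline benchmark numbers
from scratch — it simulates the three example networks (N = 1000 paths per
input, T = 2000), computes the exact continuous-time information as a
percentage of the 1-bit maximum, the percentage retained after resampling
onto a d = 100 grid, and the bits extracted by the Gaussian decoder from the
pre-switch window of the adapting example — and writes them as JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
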