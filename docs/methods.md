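# Methods

## The optimizer

HOS maintains a single axis-aligned hypercube (center $x_c$, per-dimension
half-size $r_{dim}$) inside a fixed global box. Per iteration it samples a
uniform population of $N$ points in the cube, re-centers the cube on the
best point seen, and multiplies the half-size by the convergence factor
$S(d_{nn}) = 1 - 0.2 e^{-3 d_{nn}}$ whenever a displacement is registered.
$d_{nn}$ is the movement of the best point between iterations expressed in
unit coordinates (each coordinate divided by the global box width) and
divided once more by the dimension $m$; it is near 0 when the best point has
stopped moving, giving the strongest contraction $S = 0.8$, and the
no-displacement sentinel $d_{nn} = 1$ leaves the size unchanged. The
contraction is monotone: the half-size never grows, so the sampling density
around the incumbent increases over time.

Assumptions: the objective is total and finite on the box; minimization is
unconstrained apart from the box (points sampled or stepped outside are
clamped coordinate-wise); no smoothness is required for the population
stage, while the local-search stage implicitly assumes the objective is
locally well-approximated by its finite-difference slope.

### Design choices that were genuinely open

- **Local search.** The improvement step on the incumbent is specified only
  as $x_{best}^{new} = x_{best} + \rho \Delta F$ with $0 \le \rho \le 1$ and
  $\Delta F$ undefined. We implement it as a one-sided finite-difference
  slope estimate with per-coordinate probe $h_i = \texttt{step\_scale}
  \cdot r_{dim,i}$ (default `step_scale` = 0.01), followed by a backtracking
  step of initial length $\rho \lVert r_{dim} \rVert$ against the normalized
  slope, accepted only on improvement. A one-sided slope carries an $O(h)$
  bias, which stalls the polish once the distance to the optimum is of order
  $h\sqrt{m}$; when a full backtracking round fails, the probe and trial
  lengths are therefore reduced tenfold and the slope re-estimated, up to 3
  rounds. This keeps the greedy guarantee (the output is never worse than
  the input) while allowing the incumbent to be polished far below the
  sampling resolution of the shrinking cube.
- **Which $F_{best}$ enters the midpoint comparison.** The displacement test
  compares $F_{mean} = F((x_{best} + x_c^{last})/2)$ with the best fitness
  *of the current iteration's population*, which is how the per-iteration
  best is defined in the algorithm's initialization stage. Comparing against
  the running global best instead (which the local search keeps near-optimal)
  essentially never registers a displacement, the cube never shrinks, and
  the method degenerates into pure local search; under the population-best
  reading the cube contracts steadily whenever the region between the
  incumbent and the old center looks better than a fresh sample, which is
  the intended "shrinking" behavior. The midpoint itself, having been
  evaluated, becomes the incumbent when it is the best point seen so far —
  the returned solution is always the best point ever evaluated.
- **Shrink condition.** The published branch conditions are contradictory
  (both written $0 \le d_{nn} \le 1$); we shrink when $d_{nn} < 1$ and keep
  the size otherwise, which preserves the sentinel's no-shrink meaning.
- **Double normalization.** The second normalization divides the Euclidean
  displacement norm by $m$ (taken literally), not by the diagonal
  $\sqrt{m}$. Since $d_{nn}$ only enters through the monotone map $S$, the
  alternative would merely rescale the contraction schedule.
- **Termination.** `tolF` (default 1e-9) is a *relative* best-fitness
  improvement threshold over a 10-iteration window; `tolX` (default 1e-1)
  bounds the Euclidean norm of the half-size vector. A constant objective
  therefore stops via `tolF` after 11 iterations.
- **Tie-breaking and reproducibility.** Equal fitness resolves to the lowest
  row index; one seeded generator (`numpy.random.default_rng`) drives all
  stochastic stages, so a fixed seed reproduces the trace bit-exactly.
- **Floating point.** $S < 1$ holds mathematically for all finite $d_{nn}$,
  but $0.2 e^{-3 d_{nn}}$ underflows below double resolution for
  $d_{nn} \gtrsim 12$; the implementation caps $S$ one ulp below 1 so the
  documented range $[0.8, 1)$ is strict.

## The classifier

Single hidden layer, sigmoid everywhere. Hidden width $2n+1$ for $n$ inputs
(Kolmogorov sizing rule); output width equals the number of observed
classes, trained against one-hot targets, predictions by argmax with
lowest-index tie-break (a single-output mode with a 0.5 threshold exists
but is not the default). The fitness is the MSE averaged over both samples
and output neurons, which keeps its scale comparable across architectures.
Weights and biases are searched in $[-10, 10]$ per parameter — a
conventional box for sigmoid networks trained by metaheuristics, and
configurable (`weight_bound`).

## The data protocol

Features are min-max scaled to $[0,1]$. By default the transform is fitted
on the full table before splitting, mirroring the usual "standardize all
feature values" protocol of this literature; `prepare(...,
fit_on_train_only=True)` provides the leakage-safe alternative (fit on
train, replay on test). Constant columns map to 0. The stratified split
assigns each class `round(0.6666 * class_size)` training samples (round half
up); classes with a single sample are rejected. Repeated experiments reseed
both the split and the optimizer with `base_seed + i` (a fixed-split mode
reseeds only the optimizer) and are summarized as best / worst / mean
accuracy and MSE over the runs; the random-search baseline receives the
same evaluation budget as HOS's population × iteration cap.

## The synthetic generator

`make_synthetic` emulates small medical benchmark tables: a few hundred
rows, 4–9 numeric features, two (or more) classes. Each class is a
unit-variance spherical Gaussian; centers are placed along mutually
orthogonal random directions so every pair is exactly `separation` standard
deviations apart (when classes outnumber features, random directions are
used and the separation is approximate). Classes are balanced up to
rounding; `label_noise` flips that fraction of labels to a uniformly chosen
other class, so `label_noise = 0.5` with two classes leaves essentially no
mutual information between features and labels. The default fixture is 300
samples, 4 features, 2 classes, separation 6, noise 0.

What the generator does *not* emulate: correlated or heavy-tailed features,
class imbalance, missing values, mixed scales, or label noise that depends
on the features. Passing tests on this fixture show that the trainer
optimizes its objective and that the protocol is implemented correctly —
not that the classifier reaches any particular accuracy on real clinical
data.

## Problem sizes

The acceptance-level checks run the full default protocol — population 70,
up to 250 iterations, 20 reseeded runs — on the 10-D sphere and on the
300 × 4 fixture, which completes in a few minutes on one CPU. The unit
suite uses reduced budgets (population ~20, ~30 iterations) for the same
code paths. On the easy fixture HOS typically terminates via `tolX` after
30–50 iterations.

## Known limitations

- The contraction is irreversible: once the cube has collapsed around a
  basin the algorithm cannot escape it. On strongly multimodal objectives
  (e.g. Rastrigin in higher dimensions) success depends on the initial
  population catching the global basin.
- The finite-difference local search costs $m$ evaluations per slope
  estimate, which dominates the per-iteration cost when the parameter count
  is large relative to the population.
- The MSE surface of a sigmoid MLP is invariant under hidden-neuron
  permutations; HOS makes no attempt to break this symmetry, it simply
  converges to one representative.
- Min-max scaling fitted on the full table leaks test-set range information
  into training; the leakage-safe mode exists but is not the default, for
  consistency with the protocol this package reproduces.
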