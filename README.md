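# hosmlp

Hypercube optimization search (HOS) — a derivative-free, population-based
minimizer for box-bounded continuous problems — and, built on top of it, a
trainer for single-hidden-layer sigmoid MLP classifiers on tabular
(medical-style) data.

## Who this is for

Gradient-based MLP training (backpropagation) can converge slowly and stall
in local optima, which has motivated a family of metaheuristic weight
trainers (PSO, GA, ABC, ...). This package implements one such trainer end to
end: the HOS optimizer as a reusable black-box minimizer, the MLP forward
pass and flat weight encoding it searches, the data protocol (min-max
scaling, stratified splitting, repeated reseeded runs), and a random-search
baseline at matched evaluation budget for honest comparison.

## The method

**HOS.** The search region is an axis-aligned hypercube with center $x_c$
and per-dimension half-size $r_{dim}$, initially spanning the whole box
$[lb, ub]$. Each iteration:

1. *Initialization / sampling* — draw $N$ points uniformly inside the
   hypercube, evaluate the objective $F$, and keep the best point $x_{best}$;
   polish it with a greedy local-search step
   $x_{best}^{new} = x_{best} + \rho\,\Delta F$ (a normalized
   finite-difference descent step, accepted only if it improves).
2. *Displacement–shrink* — evaluate the midpoint
   $F_{mean} = F\big((x_{best} + x_c)/2\big)$. If the midpoint beats the
   population best, a displacement is registered: the movement of the best
   point between iterations is normalized per dimension by the initial
   interval and again by the dimension $m$, giving
   $d_{nn} = \lVert x_n - x_{min,n} \rVert / m$. Otherwise $d_{nn} = 1$.
3. *Search-area update* — re-center on the best point and, when a
   displacement occurred ($d_{nn} < 1$), contract the half-size by
   $S = 1 - 0.2\,e^{-3 d_{nn}} \in [0.8, 1)$: the smaller the movement,
   the stronger the contraction.

The run stops when the iteration budget is exhausted, the relative fitness
improvement over a 10-iteration window drops below `tolF`, or the half-size
norm drops below `tolX`. Defaults: $N = 70$, 250 iterations,
`tolF` $= 10^{-9}$, `tolX` $= 10^{-1}$, $\rho = 0.5$.

**HOS-MLP.** For a dataset with $n$ features and $k$ classes the network is
$n$–$(2n{+}1)$–$k$ (Kolmogorov sizing rule for the hidden layer), sigmoid
activations throughout. All weights and biases are flattened into one vector
$(W_1, \beta_1, W_2', \beta_2)$ and searched by HOS inside
$[-10, 10]^{\text{params}}$, minimizing the mean squared error between
network outputs and one-hot targets on the training set. Features are
min-max scaled to $[0,1]$, the split is stratified 66.66% / 33.33%, and
experiments are repeated over 20 reseeded runs, reported as best / worst /
mean accuracy and MSE.

## Worked example

Generate a synthetic two-class table (300 samples, 4 features, class
clusters 6 standard deviations apart), then train and evaluate one
classifier:

```sh
$ hosmlp simulate --n 300 --features 4 --seed 7 --out clinic.csv
class_0 150
class_1 150

$ hosmlp train --data clinic.csv --seed 7 --outdir run7
test_accuracy_pct       99.000
test_mse        0.010357
training_mse    0.000318
termination     tol_x
```

99% of the held-out third of the samples are classified correctly; the
training MSE of 3.2e-4 is the final fitness reached by HOS, and the run
stopped because the hypercube collapsed below `tolX` (after 35 iterations —
see `run7/trace.csv`, whose columns `iteration, best_fitness,
half_size_norm, d_nn` give the convergence curve). `run7/checkpoint.txt`
holds the trained weight vector.

The optimizer can also be run directly on named benchmark objectives:

```sh
$ hosmlp test-functions --objective sphere --dim 10 --seed 1
objective       sphere
best_fitness    5.007659e-12
iterations      25
termination     tol_fitness
```

and `hosmlp benchmark --synthetic --runs 20 --seed 0` writes the repeated-run
best/worst/mean comparison table of HOS against the random-search baseline.

The same functionality is available as a library:

```python
from hosmlp import HOSConfig, make_synthetic, prepare, train_hos_mlp, evaluate

data = make_synthetic(n_samples=300, n_features=4, separation=6.0, seed=7)
split, scaler = prepare(data, rng=7)
clf = train_hos_mlp(split, HOSConfig(seed=7))
accuracy, mse = evaluate(clf, split.test)
```

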