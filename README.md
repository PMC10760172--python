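# nichekit

Presence-background ecological niche modelling and niche-divergence testing
for hybrid zones — maximum-entropy suitability models, niche-overlap
statistics, and permutation tests — with a synthetic study-system generator
so the entire pipeline can be validated without downloading any occurrence
or climate data.

## The problem

When two partially reproductively isolated lineages meet and hybridize —
the motivating system is the western gull × glaucous-winged gull hybrid
zone of the Pacific Northwest — competing models explain why the hybrid
zone is stable. The *tension zone* model predicts niche conservation among
parents and hybrids; the *geographical selection-gradient* model predicts a
steep environmental boundary; the *bounded superiority* model predicts that
hybrids occupy a transitional niche of their own. Distinguishing them needs
three ingredients, all provided here:

1. **Ecological niche models** for each group, fitted from presence-only
   checklist records contrasted against target-group background points;
2. **Niche-overlap statistics** between the predicted suitability surfaces;
3. **Permutation tests** that ask whether the observed overlap is smaller
   than chance relabelings (niche identity test) or sharper than any
   spatially contiguous boundary (blob range-breaking test).

## The model

The niche model is the Gibbs distribution over background cells

```
q_λ(i) = exp(λ·f(i)) / Z_λ,     Z_λ = Σ_background exp(λ·f)
```

that maximizes the L1-penalized log-likelihood of the `m` presence points,

```
J(λ) = (1/m) Σ_presence λ·f(x) − log Z_λ − Σ_j β_j |λ_j|,
β_j = β · s_j / √m,
```

the maximum-entropy distribution consistent with the presence sample's
feature expectations. Features `f` are min-max-scaled linear and quadratic
terms of continuous variables plus one-hot indicators of categorical ones
(hinge and product features are available). The objective is concave and is
maximized by coordinate ascent with soft-threshold updates; the per-update
gain trace yields percent contribution, and AUC drops under per-variable
shuffling yield permutation importance.

Overlap between two normalized suitability surfaces `p_X`, `p_Y`:

```
Schoener's D :  D = 1 − ½ Σ_i |p_X,i − p_Y,i|
Hellinger    :  H = √( Σ_i (√p_X,i − √p_Y,i)² )
Warren's I   :  I = 1 − H²/2
```

Both D and I run from 0 (disjoint) to 1 (identical), with D ≤ I always.

Upstream of the models, the package reproduces standard semi-structured
checklist hygiene: protocol/duration/distance/time/observer/completeness
filters, spatial thinning to a 0.5 km minimum inter-record distance, group
balancing, and target-group background sampling; collinear environmental
variables are removed by stepwise VIF (threshold 10) and pairwise
correlation (threshold 0.9) screening.

## Worked example

```python
import numpy as np
import nichekit as nk

# 1. synthetic landscape: two autocorrelated environmental layers, r = 0.3
grid = nk.GridSpec(n_rows=50, n_cols=50, cell_size=1.0)   # 50 x 50 km
layers = [nk.LayerSpec("env1", autocorr_length=4.0),
          nk.LayerSpec("env2", autocorr_length=4.0)]
stack = nk.generate_landscape(grid, layers,
                              correlation=np.array([[1.0, 0.3], [0.3, 1.0]]),
                              seed=1)

# 2. two groups with niche optima 4 sigma apart on env1
scenario = nk.make_scenario("divergent", separation=4.0, sigma=0.5)
occ_a = nk.sample_occurrences(nk.gaussian_niche_suitability(scenario, "A", stack),
                              150, group="A", seed=2)
occ_b = nk.sample_occurrences(nk.gaussian_niche_suitability(scenario, "B", stack),
                              150, group="B", seed=3)
flat = nk.NicheScenario(groups=["bg"], optima={"bg": {"env1": 0, "env2": 0}},
                        breadths={"bg": {"env1": 1e6, "env2": 1e6}})
background = nk.sample_occurrences(nk.gaussian_niche_suitability(flat, "bg", stack),
                                   300, group="bg", seed=4)

# 3. fit a maxent model for group A and validate it
env_a = nk.extract_env(stack, occ_a).values
env_bg = nk.extract_env(stack, background).values
res = nk.Maxent(env_a, env_bg, stack.kinds).fit(beta=1.0)
cv = nk.crossvalidate(env_a, env_bg, stack.kinds, n_replicates=10, seed=5)
print(f"AUC = {cv.mean:.3f} +/- {cv.sd:.3f}")

# 4. overlap between the two groups' predicted surfaces
res_b = nk.Maxent(nk.extract_env(stack, occ_b).values, env_bg, stack.kinds).fit()
ov = nk.overlap_from_suitability(res.predict_grid(stack), res_b.predict_grid(stack))
print(f"D = {ov.D:.3f}, I = {ov.I:.3f}")

# 5. niche identity test (99 permutation replicates, refitting both models each time)
config = nk.TestConfig(n_iter=99, seed=6, metric="euclidean")
test = nk.identity_test(occ_a, occ_b, stack, background, config)
print(f"identity test: observed D = {test.observed['D']:.3f}, "
      f"null mean = {test.null['D'].mean():.3f}, p_lower = {test.p_lower['D']:.3f}")
```

Output:

```
AUC = 0.832 +/- 0.029
D = 0.242, I = 0.525
identity test: observed D = 0.242, null mean = 0.960, p_lower = 0.010
```

Read: the model discriminates presences from background well above the 0.7
reliability bar; the two groups share only ~24% of their habitat-use
distribution (D); and no random relabeling of the pooled occurrences
produced overlap as low as observed (p = 1/100, the minimum attainable with
99 replicates) — strong evidence of niche divergence.

The same analysis is available from the shell:

```bash
nichekit run --config run.yaml --seed 1 --outdir out/
```

with stage-level subcommands (`nichekit simulate|prep|select|enm|overlap|test`)
for piecemeal use; see `examples/run.yaml`.

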