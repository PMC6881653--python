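# sirna-escape

Estimate how many siRNA molecules escape the endosome during RNA
interference.

In an RNAi experiment the injected siRNA dose is known, and the amount of
siRNA present after intracellular amplification can be inferred from the
measured knockdown — but the number of molecules that actually escaped the
endosome and seeded the silencing reaction (the *bottleneck* population
`s1`) cannot be observed directly. `sirna-escape` infers it with
simulation-based Bayesian inference on a stochastic kinetic model, for
researchers designing RNAi dosing (pest control, multi-target gene
therapy) or studying endosomal-escape efficiency.

## Model and estimators

After escape, the copy number `S(t)` of one siRNA species evolves as a
Markov jump process with four reactions — amplification (`α·S`),
degradation (`λ·S`), immigration (`μ`), emigration (`σ·S`), rates per hour
— simulated exactly with the Gillespie direct method (numba-compiled,
bit-reproducible from a seed). Defaults:
`θ = (α, λ, μ, σ) = (0.6, 0.3, 0.6, 0.23)`, elapsed time `Δt = 12 h`.

Two inference routes, each for one siRNA type or for `m` co-injected
types whose escaped composition `v1` is a multivariate-hypergeometric
draw from the injected composition `v0`:

* **Grid Bayes** — for each candidate `s1`, simulate endpoints and
  estimate the likelihood `p(s2|s1)` with a k-nearest-neighbour density
  (`k/(2·n·r_k)`); normalize over a uniform prior on `1..smax`. The
  multi-type posterior averages per-type likelihood products over
  bottleneck draws.
* **ABC-MCMC** — a Metropolis-Hastings random walk on `s1` scored by one
  fresh simulation per proposal, acceptance `min{1, e^{d−d'}}` with `d`
  the distance between simulated and observed endpoints; the retained
  distance is replaced only on acceptance.

See `docs/methods.md` for the full model, the nonparametric-likelihood
choices, and known limitations (point estimates for targets below ~10
molecules are washed out by immigration).

## Worked example

Synthesize an observation from a known escape amount of 70 molecules,
then recover it with both estimators:

```python
import sirna_escape as se

# observed amount after amplification: median of 101 simulated endpoints
s2 = se.generate_observed_single(70, 12.0, se.PAPER_THETA, 101, rng=1)
# -> 171  (70 escapees grow to ~173 on average in 12 h)

grid = se.posterior_grid_single(s2, 12.0, se.PAPER_THETA, rng=2)
se.summarize(grid)
# -> {'mode': 71, 'mean': 78.7, 'variance': 874.7}

chain = se.mh_sample_single(s2, 12.0, se.PAPER_THETA, rng=3)
se.summarize(chain)
# -> {'mode': 47, 'mean': 65.8, 'variance': 448.5,
#     'burn_in': 2000, 'acceptance_rate': 0.019}
```

The grid mode (71) and the post-burn-in chain mean (65.8) both recover
the true escape amount 70 to within the sampling noise of the estimators;
the grid variance quantifies the posterior uncertainty. Estimates vary
between seeds by roughly ±30% for small targets — that spread is a
property of the nonparametric likelihood, not a convergence failure.

The same workflow from the shell:

```sh
sirna-escape observe --true-s1 70 --seed 1          # prints 171
sirna-escape infer-single-bayes --s2 171 --seed 2 --outdir out/
sirna-escape experiment --algorithm mcmc-multi --true-s1 70 --seed 4 --outdir out/
```

Subcommands write a posterior table (`posterior.tsv`: s1, probability) or
chain trace (`chain.tsv`: iteration, s1, distance, accepted) plus a
`summary.json`; `--config file.yaml` supplies any option, flags override.

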