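"""Fit the Weibull shape parameter by Monte Carlo grid search.

Simulates a median frequency matrix from W(0.14, 1) as a stand-in for an
observed dataset, then recovers the shape by minimising the Euclidean
distance between observed and simulated mf(k,M) over a grid of candidate
shapes, and derives the splicing-efficiency index.
"""

from spliceshape import fit_shape, simulate_mf, splicing_efficiency

observed = simulate_mf(0.14, reps=5000, rng=7)
fit = fit_shape(observed, reps=5000, seed=99)

print(f"fitted shape parameter a_hat = {fit.a_hat:.2f}")
print(f"distance at the minimum     = {fit.min_distance:.4f}")
eff = splicing_efficiency(fit.a_hat)
print(f"splicing efficiency 1/(1+a) = {eff:.2f}")
print(f"joint donor x acceptor efficacy at equal efficiency = {eff * eff:.4f}")
print("The distance-vs-a curve has a single minimum; its location is the")
print("shape of the Weibull law that best reproduces the frequency hierarchy.")
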