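"""Run both swarm optimizers on standard benchmark objectives.

Minimizes the 5-D sphere and Rastrigin functions with the spotted-hyena
optimizer (adaptive stopping) and the coati optimizer (with and without the
dynamic-opposite-learning stage) and prints the best values found.
"""

from swarmdx import benchmark_suite, SHOAConfig, shoa_minimize, COAConfig, mcoa_minimize

suite = benchmark_suite()
for name in ("sphere", "rastrigin"):
    b = suite[name]
    bounds = [(b.lower, b.upper)] * 5
    shoa_res = shoa_minimize(b.fn, SHOAConfig(bounds=bounds, pop_size=30, max_iter=200, seed=11))
    coa_res = mcoa_minimize(b.fn, COAConfig(bounds=bounds, pop_size=30, max_iter=200, seed=11))
    plain = mcoa_minimize(b.fn, COAConfig(bounds=bounds, pop_size=30, max_iter=200,
                                          seed=11, dol_enabled=False))
    print(f"{name:10s} global min {b.minimum_value:g}  "
          f"SHO {shoa_res.best_value:.3e}  MCOA {coa_res.best_value:.3e}  "
          f"plain COA {plain.best_value:.3e}")
# Values near zero mean the swarms located the global minimum; the
# dynamic-opposite stage typically helps on the multimodal Rastrigin surface.
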