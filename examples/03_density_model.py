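"""Fitting the Bayesian NB mixed model and reading off density ratios.

Simulates shell-count data at a reduced design (4 subjects x 2 ganglia)
with a known TH density advantage for ChAT+/NOS- cells, fits the
negative-binomial mixed model by HMC, and reports cell-type mean densities
and pairwise density ratios with 95% credible intervals.
"""

import warnings

from varishell.density_model import ModelSettings, density_ratio, fit_nb_glmm, mean_density
from varishell.synthetic import GeneratorParams, simulate_model_rows

params = GeneratorParams(n_subjects=4, cells_per_ganglion=20)
rows, truth = simulate_model_rows(params, seed=3)
print(f"model input: {len(rows)} rows (cell x marker counts with shell-volume offsets)")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    post = fit_nb_glmm(rows, ModelSettings(chains=2, warmup=400, draws=400), seed=5)
print(f"sampler: max Rhat {post.max_rhat:.3f}, {post.divergences} divergences")

print("\nposterior mean densities (per 1,000 um^3):")
for cell_type, marker in post.cells:
    md = mean_density(post, cell_type, marker)
    true_d = dict(zip(["ChAT+/NOS-", "ChAT-/NOS+", "ChAT+/NOS+"],
                      params.densities[marker][:3]))[cell_type]
    print(f"  {marker:3s} {cell_type:12s} {md['median']:6.2f} "
          f"[{md['ci_low']:.2f}, {md['ci_high']:.2f}]  (truth {true_d})")

print("\ndensity ratios (ChAT+/NOS- vs ChAT-/NOS+):")
for marker in ("TH", "ENK"):
    r = density_ratio(post, marker, "ChAT+/NOS-", "ChAT-/NOS+")
    star = "*" if r.significant else " "
    print(f"  {marker:3s} {r.median:.2f} [{r.ci_low:.2f}, {r.ci_high:.2f}]{star} "
          f"Pr(ratio>1)={r.prob_gt_1:.2f}")
print()
print("A ratio credibly above 1 (CI excluding 1, starred) indicates that this")
print("marker's varicosities are denser around the first cell type — the")
print("signature of preferential targetting.")
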