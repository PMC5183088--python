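"""Convergence diagnostics for the fitted chains.

Reads the draws stored by 02_fit_model.py, computes the Gelman-Rubin
statistic and effective sample size for every fixed effect and scale
parameter, and writes the report to results/convergence.csv.
"""

from pathlib import Path

import occudyn as od
from occudyn.model import FIXED_EFFECTS, HYPER_SDS

sample = od.PosteriorSample.from_csv("scratch/draws.csv")
report = od.gelman_rubin(sample, params=list(FIXED_EFFECTS) + list(HYPER_SDS))

Path("results").mkdir(exist_ok=True)
report.to_csv("results/convergence.csv")

print(report.table.round(3))
print(f"max R-hat: {report.max_rhat:.3f} "
      f"({'<= 1.1, converged' if report.converged else '> 1.1: not converged'})")
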