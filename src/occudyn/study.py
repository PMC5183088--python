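"""Published posterior estimates used as reference inputs.

``TABLE1`` holds the reported fixed-effect and scale-parameter posteriors of
the original two-season understory resurvey analysis (posterior mean, SD,
and 2.5/5/50/95/97.5% quantiles, logit or SD scale).  These values are
*inputs*: the synthetic-data generator uses the means as its default truth so
generated surveys statistically resemble the study, and the derived
probability worked examples plug them into the inverse logit.

``SPECIES_EFFECTS`` holds the handful of species random-effect posterior
means (and, where reported, 95% CIs) quoted in the study's results text.
"""

from __future__ import annotations

#: rows: mean, sd, q2.5, q5, q50, q95, q97.5
TABLE1 = {
    "beta_o": dict(mean=-3.25, sd=0.37, q2_5=-3.99, q5=-3.88, q50=-3.25, q95=-2.65, q97_5=-2.54),
    "beta_s": dict(mean=-2.60, sd=0.67, q2_5=-4.11, q5=-3.81, q50=-2.57, q95=-1.61, q97_5=-1.44),
    "beta_sg": dict(mean=-0.17, sd=0.65, q2_5=-1.54, q5=-1.27, q50=-0.14, q95=0.81, q97_5=1.04),
    "beta_c": dict(mean=-3.81, sd=0.32, q2_5=-4.45, q5=-4.33, q50=-3.81, q95=-3.28, q97_5=-3.18),
    "beta_cg": dict(mean=1.51, sd=0.31, q2_5=0.86, q5=0.98, q50=1.53, q95=1.99, q97_5=2.08),
    "sigma_o": dict(mean=2.27, sd=0.30, q2_5=1.76, q5=1.82, q50=2.24, q95=2.81, q97_5=2.95),
    "sigma_s": dict(mean=2.89, sd=0.57, q2_5=1.97, q5=2.07, q50=2.84, q95=3.91, q97_5=4.13),
    "sigma_sg": dict(mean=1.51, sd=0.84, q2_5=0.19, q5=0.31, q50=1.40, q95=3.07, q97_5=3.48),
    "sigma_c": dict(mean=1.89, sd=0.28, q2_5=1.43, q5=1.48, q50=1.86, q95=2.40, q97_5=2.51),
    "sigma_cg": dict(mean=1.35, sd=0.32, q2_5=0.81, q5=0.88, q50=1.32, q95=1.93, q97_5=2.07),
    "sigma_r": dict(mean=0.44, sd=0.10, q2_5=0.27, q5=0.29, q50=0.44, q95=0.60, q97_5=0.65),
}

#: Posterior means of Table 1, the default truth of the synthetic generator.
TABLE1_MEANS = {name: row["mean"] for name, row in TABLE1.items()}

#: Species random-effect posteriors quoted in the results text
#: (family -> species -> mean and, when reported, the 95% CI).
SPECIES_EFFECTS = {
    "o": {
        "Eurya japonica": dict(mean=5.71, ci=(4.85, 6.62)),
        "Quercus glauca": dict(mean=5.71),
        "Carpinus tschonoskii": dict(mean=-3.21, ci=(-6.08, -1.11)),
    },
    "s": {
        "Quercus glauca": dict(mean=5.93),
        "Aucuba japonica": dict(mean=-3.80),
        "Vaccinium bracteatum": dict(mean=-3.03),
    },
    "c": {
        "Quercus glauca": dict(mean=6.09),
        "Callicarpa mollis": dict(mean=-1.07),
    },
    "cg": {
        "Callicarpa mollis": dict(mean=2.32),
    },
}
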