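"""Posterior summaries and probability-scale derived quantities.

Reporting surfaces mirror the study conventions for this kind of analysis:
a fixed-effect/hyperparameter table with posterior mean, SD and the
{2.5, 5, 50, 95, 97.5}% quantiles; per-(family, species) random-effect
tables; and derived probabilities obtained by plugging posterior means of
logit-scale terms into the inverse logit.  The plug-in convention is the
default because it is how such worked examples are conventionally printed;
``mode="full_posterior"`` transforms draw-by-draw instead, which is the
statistically preferable alternative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import EFFECT_FAMILIES, inv_logit
from .sampler import PosteriorSample

__all__ = [
    "QUANTILES",
    "SUMMARY_COLUMNS",
    "summarize",
    "DerivedProbability",
    "derived_probability",
    "species_effect_table",
]

QUANTILES = (0.025, 0.05, 0.5, 0.95, 0.975)
SUMMARY_COLUMNS = ("mean", "sd", "2.5%", "5%", "50%", "95%", "97.5%")


def summarize(
    sample: PosteriorSample, params: list[str] | None = None
) -> pd.DataFrame:
    """Per-parameter summary table (mean, SD, five quantiles), pooled over chains.

    Quantiles use linear interpolation between order statistics (numpy's
    default, the common convention in mainstream statistical software).
    """
    names = params if params is not None else sample.parameter_names
    if sample.total_draws == 0:
        raise ValueError("sample is empty")
    rows = {}
    for name in names:
        x = sample.pooled(name)
        qs = np.quantile(x, QUANTILES, method="linear")
        sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
        rows[name] = [float(x.mean()), sd, *map(float, qs)]
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(SUMMARY_COLUMNS)
    ).loc[names]


@dataclass
class DerivedProbability:
    """A probability-scale point estimate (and optional interval) for one process."""

    process: str  # "occurrence", "survival" or "colonization"
    species: str  # species label or "overall"
    gap: bool
    point: float
    interval: tuple[float, float] | None = None


def _is_interval(c) -> bool:
    return isinstance(c, tuple)


def derived_probability(
    intercept,
    species_effect=None,
    gap_main=None,
    gap_effect=None,
    mode: str = "plug_in_mean",
    process: str = "occurrence",
    species: str = "overall",
) -> DerivedProbability:
    """Combine logit-scale terms into a probability-scale estimate.

    Each component may be a scalar (a posterior mean), a 1-D array of draws,
    or — in ``plug_in_mean`` mode only — a tuple of credible-interval
    endpoints for the single varying term: ``(lo, hi)``, or
    ``(mean, lo, hi)`` when the term's posterior mean is also known and
    should anchor the point estimate.

    In ``plug_in_mean`` mode the point estimate is ``inv_logit`` of the sum
    of the component means, and the interval (if any) applies ``inv_logit``
    to the other components' means plus the varying term's interval
    endpoints — the convention used when a single species effect's CI is
    carried through while the intercept is held at its posterior mean.  In
    ``full_posterior`` mode every component must be a scalar or aligned
    draws; each summed draw is transformed and then summarized (mean and
    central 95% interval).
    """
    comps = {
        "intercept": intercept,
        "species_effect": species_effect,
        "gap_main": gap_main,
        "gap_effect": gap_effect,
    }
    present = {k: v for k, v in comps.items() if v is not None}
    gap = gap_main is not None or gap_effect is not None

    if mode == "plug_in_mean":
        varying = [k for k, v in present.items() if _is_interval(v) or np.ndim(v) == 1]
        if len(varying) > 1:
            raise ValueError(
                "plug_in_mean allows at most one varying (interval or draws) term; "
                "use full_posterior to combine several draw vectors"
            )
        fixed_sum = sum(
            float(np.mean(v)) for k, v in present.items() if k not in varying
        )
        if not varying:
            return DerivedProbability(process, species, gap, float(inv_logit(fixed_sum)))
        v = present[varying[0]]
        if _is_interval(v):
            if len(v) == 3:
                center, lo, hi = (float(x) for x in v)
            elif len(v) == 2:
                lo, hi = (float(x) for x in v)
                center = 0.5 * (lo + hi)  # midpoint stands in for the mean
            else:
                raise ValueError("interval term must be (lo, hi) or (mean, lo, hi)")
            if not lo <= hi:
                raise ValueError("interval endpoints must satisfy lo <= hi")
        else:
            arr = np.asarray(v, dtype=float)
            lo, hi = (float(q) for q in np.quantile(arr, (0.025, 0.975)))
            center = float(arr.mean())
        point = float(inv_logit(fixed_sum + center))
        interval = (float(inv_logit(fixed_sum + lo)), float(inv_logit(fixed_sum + hi)))
        return DerivedProbability(process, species, gap, point, interval)

    if mode == "full_posterior":
        if any(_is_interval(v) for v in present.values()):
            raise ValueError(
                "interval endpoints are a plug_in_mean input; do not mix modes"
            )
        total = sum(np.asarray(v, dtype=float) for v in present.values())
        p = inv_logit(total)
        p = np.atleast_1d(p)
        lo, hi = (float(q) for q in np.quantile(p, (0.025, 0.975)))
        return DerivedProbability(process, species, gap, float(p.mean()), (lo, hi))

    raise ValueError(f"unknown mode {mode!r}")


_EPS_RE = re.compile(r"^eps_(o|s|sg|c|cg)\[(.+)\]$")


def species_effect_table(
    sample: PosteriorSample, sort_by_median: bool = False
) -> pd.DataFrame:
    """Summary of every species random effect, one row per (family, species).

    The row order follows the sampler's parameter layout (families in model
    order, species in input order); with ``sort_by_median=True`` species are
    ordered by posterior median within each family, the ordering used for
    forest-plot style displays.
    """
    matches = [(n, _EPS_RE.match(n)) for n in sample.parameter_names]
    eps_names = [n for n, m in matches if m]
    if not eps_names:
        raise ValueError("sample contains no species random effects")
    table = summarize(sample, params=eps_names)
    idx = pd.MultiIndex.from_tuples(
        [(_EPS_RE.match(n).group(1), _EPS_RE.match(n).group(2)) for n in eps_names],
        names=["family", "species"],
    )
    table.index = idx
    if sort_by_median:
        table = (
            table.sort_values("50%")
            .sort_index(level="family", kind="stable", sort_remaining=False)
        )
    else:
        # keep model-order families (o, s, sg, c, cg) grouped
        order = {f: i for i, f in enumerate(EFFECT_FAMILIES)}
        table = table.iloc[
            np.argsort([order[f] for f in table.index.get_level_values("family")],
                       kind="stable")
        ]
    return table
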