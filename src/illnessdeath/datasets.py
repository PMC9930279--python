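"""Packaged reference parameter values.

Posterior-mean Weibull PH estimates from a published Bayesian analysis of a
population-based cohort of 34,491 patients aged 65+ discharged alive after
an osteoporotic hip fracture (2008-2015, median follow-up 5.0 years; 74.8%
women, mean age 83.4). The registry microdata are not publicly available;
these printed summaries serve as the default "truth" for simulation studies
and as the plug-in parameter set for desk-scale reproduction of downstream
incidences and transition probabilities.
"""

from __future__ import annotations

from .hazards import IllnessDeathParams, WeibullPHParams

#: age-centering constant of the reference cohort (mean age, years)
REFERENCE_AGE_CENTER = 83.4

_MEANS = {
    "FR": dict(alpha=0.9198, lam=0.0279, beta_wo=0.0262, beta_age=0.0244),
    "FD": dict(alpha=0.7759, lam=0.3311, beta_wo=-0.5092, beta_age=0.0705),
    "RD": dict(alpha=0.6234, lam=0.5769, beta_wo=-0.6127, beta_age=0.0498),
}

_SDS = {
    "FR": dict(alpha=0.0157, lam=0.0013, beta_wo=0.0486, beta_age=0.0030),
    "FD": dict(alpha=0.0051, lam=0.0050, beta_wo=0.0166, beta_age=0.0012),
    "RD": dict(alpha=0.0154, lam=0.0329, beta_wo=0.0655, beta_age=0.0046),
}


def reference_params() -> IllnessDeathParams:
    """The reference posterior-mean parameter set (age centered at 83.4)."""
    return IllnessDeathParams(
        fr=WeibullPHParams(transition="FR", **_MEANS["FR"]),
        fd=WeibullPHParams(transition="FD", **_MEANS["FD"]),
        rd=WeibullPHParams(transition="RD", **_MEANS["RD"]),
        age_center=REFERENCE_AGE_CENTER,
    )


def reference_posterior_sd() -> dict[str, dict[str, float]]:
    """Reported posterior standard deviations matching :func:`reference_params`."""
    return {tr: dict(v) for tr, v in _SDS.items()}
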