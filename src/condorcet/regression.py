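"""Latent regression of person parameters on covariates, and coefficient reports.

Individual differences in the ECM live in three person parameters: ability
θ_i, willingness to guess b_i and guess bias g_i.  Each can be regressed on
standardized covariates, e.g. θ_i = β0 + β1·x_i1 + … + ε_i, with the
probability parameters regressed on the logit scale so their values stay in
(0, 1).  The regression is estimated *inside* the joint posterior (one-step),
which avoids the generated-regressor bias of first extracting point estimates
and then running an ordinary regression on them.

Inference on a coefficient is summarized by its posterior mean, posterior sd,
and the posterior probability that it is below zero; a coefficient is flagged
as relevant when that probability is ≥ 0.95 or ≤ 0.05 (threshold
configurable, intercepts excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Regression targets: the person parameters, probabilities on the logit scale.
TARGETS = ("ability", "willingness_logit", "guess_bias_logit")

#: Report labels for the targets.
TARGET_LABELS = {
    "ability": "Consensus knowledge",
    "guess_bias_logit": 'Guessing "True"',
    "willingness_logit": "Willingness to guess",
}

__all__ = [
    "TARGETS",
    "TARGET_LABELS",
    "RegressionSpec",
    "CoefficientSummary",
    "latent_mean",
    "coefficient_summary",
    "summarize_coefficients",
    "select_relevant",
]


@dataclass
class RegressionSpec:
    """Which covariates predict which latent person parameters.

    ``design`` maps a target in :data:`TARGETS` to the covariate names that
    enter its linear predictor.  An intercept is always included and never
    listed.  Targets absent from the map get an intercept-only model (the
    plain hierarchical prior).
    """

    design: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.design) - set(TARGETS)
        if unknown:
            raise ValueError(f"unknown regression targets {sorted(unknown)}; use {TARGETS}")
        for t, names in self.design.items():
            if len(set(names)) != len(names):
                raise ValueError(f"duplicate covariates for target {t!r}")

    @classmethod
    def full(cls, covariate_names: list[str]) -> "RegressionSpec":
        """Every covariate on every target."""
        return cls({t: list(covariate_names) for t in TARGETS})

    def validate_against(self, covariate_names: list[str]) -> None:
        available = set(covariate_names)
        for t, names in self.design.items():
            missing = [n for n in names if n not in available]
            if missing:
                raise ValueError(f"target {t!r} references unknown covariates {missing}")


@dataclass
class CoefficientSummary:
    """Posterior summary of one regression coefficient."""

    target: str
    predictor: str
    posterior_mean: float
    posterior_sd: float
    prob_below_zero: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob_below_zero <= 1.0:
            raise ValueError("prob_below_zero must lie in [0, 1]")

    @property
    def is_intercept(self) -> bool:
        return self.predictor == "intercept"


def latent_mean(covariate_row: np.ndarray, coefficients: np.ndarray) -> float:
    """Linear predictor β0 + Σ βp·x_p of a person's latent-parameter prior.

    ``coefficients`` is (β0, β1, …, βP); the person's actual latent value
    deviates from this location by a Normal(0, residual_sd²) residual.
    """
    x = np.asarray(covariate_row, dtype=float)
    beta = np.asarray(coefficients, dtype=float)
    if beta.shape[0] != x.shape[0] + 1:
        raise ValueError(
            f"need one coefficient per covariate plus an intercept: "
            f"got {beta.shape[0]} coefficients for {x.shape[0]} covariates"
        )
    return float(beta[0] + beta[1:] @ x)


def coefficient_summary(draws, target: str, covariate: str) -> CoefficientSummary:
    """Posterior mean, sd and P(coefficient < 0) for one named coefficient."""
    sample = draws.coefficient_draws(target, covariate)
    return CoefficientSummary(
        target=target,
        predictor=covariate,
        posterior_mean=float(sample.mean()),
        posterior_sd=float(sample.std(ddof=1)),
        prob_below_zero=float((sample < 0).mean()),
    )


def summarize_coefficients(draws, include_intercepts: bool = False) -> pd.DataFrame:
    """All coefficient summaries as a table with columns
    (parameter, predictor, mean, psd, p_below_0)."""
    rows = []
    for target, names in draws.coef_names.items():
        for name in names:
            if name == "intercept" and not include_intercepts:
                continue
            s = coefficient_summary(draws, target, name)
            rows.append(
                (
                    TARGET_LABELS.get(target, target),
                    s.predictor,
                    s.posterior_mean,
                    s.posterior_sd,
                    s.prob_below_zero,
                )
            )
    return pd.DataFrame(rows, columns=["parameter", "predictor", "mean", "psd", "p_below_0"])


def select_relevant(
    summaries: list[CoefficientSummary], threshold: float = 0.95
) -> list[CoefficientSummary]:
    """Coefficients whose posterior mass is concentrated on one side of zero.

    Keeps a (non-intercept) coefficient when P(< 0) ≥ threshold or
    P(< 0) ≤ 1 − threshold, i.e. at least ``threshold`` posterior probability
    that the effect has a definite sign.
    """
    if not 0.5 < threshold < 1.0:
        raise ValueError("threshold must lie in (0.5, 1)")
    return [
        s
        for s in summaries
        if not s.is_intercept
        and (s.prob_below_zero >= threshold or s.prob_below_zero <= 1.0 - threshold)
    ]
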