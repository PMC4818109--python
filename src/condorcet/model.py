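"""The Extended Condorcet Model: processing tree, likelihood, and conditionals.

A respondent *i* facing item *k* either knows the consensus answer Z_k — with
probability D_ik = logit⁻¹(θ_i − δ_k), a Rasch-type ability/difficulty
contrast — and reports it, or does not know it.  When not knowing, they guess
with probability b_i (willingness to guess), answering "True" with probability
g_i (guessing / acquiescence bias) and "False" otherwise; with probability
1 − b_i they mark "Don't know".  Following the branches gives the category
probabilities

    P(True)       = D·Z + (1 − D)·b·g
    P(False)      = D·(1 − Z) + (1 − D)·b·(1 − g)
    P(Don't know) = (1 − D)·(1 − b)

and the likelihood is categorical over these three probabilities, cell-wise
and conditionally independent given the parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit

from .data import DONT_KNOW, FALSE, MISSING, TRUE, ResponseMatrix

__all__ = [
    "EcmParameters",
    "EcmHyperParameters",
    "inverse_logit",
    "knowledge_probability",
    "response_probabilities",
    "category_probabilities",
    "log_likelihood",
    "consensus_conditional",
]


def inverse_logit(x):
    """Logistic function 1/(1 + exp(−x)), mapping the real line to (0, 1)."""
    return expit(x)


def knowledge_probability(theta, delta):
    """Probability D_ik of knowing the consensus answer.

    ``D = logit⁻¹(theta − delta)``: 0.5 when ability equals difficulty,
    above 0.5 when the respondent dominates the item.  Broadcasts.
    """
    return expit(np.asarray(theta, dtype=float) - np.asarray(delta, dtype=float))


@dataclass
class EcmParameters:
    """One complete configuration of the ECM latent quantities.

    consensus_key
        Binary answer key Z_k per item (1 = "True").
    ability, difficulty
        Rasch-type person ability θ_i and item difficulty δ_k on the real
        line; difficulties sum to zero (identification of the common scale).
    willingness, guess_bias
        Per-person probabilities b_i of venturing a guess and g_i of
        guessing "True", both strictly inside (0, 1).
    """

    consensus_key: np.ndarray
    ability: np.ndarray
    difficulty: np.ndarray
    willingness: np.ndarray
    guess_bias: np.ndarray

    def __post_init__(self) -> None:
        self.consensus_key = np.asarray(self.consensus_key, dtype=np.int8)
        self.ability = np.asarray(self.ability, dtype=float)
        self.difficulty = np.asarray(self.difficulty, dtype=float)
        self.willingness = np.asarray(self.willingness, dtype=float)
        self.guess_bias = np.asarray(self.guess_bias, dtype=float)
        if not np.isin(self.consensus_key, (0, 1)).all():
            raise ValueError("consensus_key must be binary")
        m = self.consensus_key.shape[0]
        n = self.ability.shape[0]
        if self.difficulty.shape != (m,):
            raise ValueError("difficulty length must match consensus_key")
        if self.willingness.shape != (n,) or self.guess_bias.shape != (n,):
            raise ValueError("willingness/guess_bias length must match ability")
        for name, arr in (("willingness", self.willingness), ("guess_bias", self.guess_bias)):
            if not ((arr > 0) & (arr < 1)).all():
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if abs(self.difficulty.sum()) > 1e-8:
            raise ValueError("difficulty must sum to 0 (scale identification)")

    @property
    def n_respondents(self) -> int:
        return self.ability.shape[0]

    @property
    def n_items(self) -> int:
        return self.consensus_key.shape[0]


@dataclass
class EcmHyperParameters:
    """Population-level locations and scales of the person/item parameters."""

    ability_mean: float = 0.0
    ability_sd: float = 1.0
    difficulty_sd: float = 1.0
    willingness_logit_mean: float = 0.0
    willingness_logit_sd: float = 1.0
    guess_logit_mean: float = 0.0
    guess_logit_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("ability_sd", "difficulty_sd", "willingness_logit_sd", "guess_logit_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def response_probabilities(z, d, b, g) -> np.ndarray:
    """Category probabilities (True, False, Don't-know) from the processing tree.

    Parameters broadcast; the returned array has a trailing axis of length 3
    and sums to 1 along it.
    """
    z, d, b, g = np.broadcast_arrays(*(np.asarray(a, dtype=float) for a in (z, d, b, g)))
    for name, arr in (("d", d), ("b", b), ("g", g)):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError(f"{name} must lie in [0, 1]")
    if ((z != 0) & (z != 1)).any():
        raise ValueError("z must be binary")
    miss = 1.0 - d
    p_true = d * z + miss * b * g
    p_false = d * (1.0 - z) + miss * b * (1.0 - g)
    p_dk = miss * (1.0 - b)
    return np.stack([p_true, p_false, p_dk], axis=-1)


def category_probabilities(params: EcmParameters) -> np.ndarray:
    """Full ``(N, M, 3)`` grid of response probabilities for one parameter draw."""
    d = knowledge_probability(params.ability[:, None], params.difficulty[None, :])
    return response_probabilities(
        params.consensus_key[None, :],
        d,
        params.willingness[:, None],
        params.guess_bias[:, None],
    )


def log_likelihood(data: ResponseMatrix, params: EcmParameters) -> float:
    """Log-likelihood of a response matrix: sum of log category probabilities.

    Missing cells are skipped.  If any observed response has probability zero
    under ``params`` the function returns ``-inf`` and warns, so degenerate
    parameter settings are visible rather than silently fatal.
    """
    if params.n_respondents != data.n_respondents or params.n_items != data.n_items:
        raise ValueError("parameter dimensions do not match the data")
    probs = category_probabilities(params)
    y = data.values
    cell = np.ones(y.shape, dtype=float)  # missing contributes log 1 = 0
    for code, j in ((TRUE, 0), (FALSE, 1), (DONT_KNOW, 2)):
        sel = y == code
        cell[sel] = probs[..., j][sel]
    if (cell == 0).any():
        warnings.warn("observed response with zero probability; log-likelihood is -inf")
        return float("-inf")
    return float(np.log(cell).sum())


def consensus_conditional(
    item_responses: np.ndarray,
    d: np.ndarray,
    b: np.ndarray,
    g: np.ndarray,
    prior_true: float = 0.5,
) -> float:
    """Posterior probability that an item's consensus answer is "True".

    Two-term Bayes rule over Z_k ∈ {0, 1} given one item's column of
    responses and the respondents' knowledge/guessing parameters — the Gibbs
    full conditional of the answer key.  Don't-know responses carry no
    information about Z (the Don't-know branch does not involve it).
    """
    if not 0.0 < prior_true < 1.0:
        raise ValueError("prior_true must lie strictly in (0, 1)")
    y = np.asarray(item_responses)
    d = np.broadcast_to(np.asarray(d, dtype=float), y.shape)
    b = np.broadcast_to(np.asarray(b, dtype=float), y.shape)
    g = np.broadcast_to(np.asarray(g, dtype=float), y.shape)
    obs = y != MISSING
    with np.errstate(divide="ignore"):
        p1 = np.log(response_probabilities(1, d, b, g))
        p0 = np.log(response_probabilities(0, d, b, g))
    idx = np.select([y == TRUE, y == FALSE, y == DONT_KNOW], [0, 1, 2], default=0)
    ll1 = p1[np.arange(y.size), idx][obs].sum()
    ll0 = p0[np.arange(y.size), idx][obs].sum()
    return float(expit(ll1 - ll0 + logit(prior_true)))
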