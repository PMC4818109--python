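"""Posterior predictive check of a single underlying consensus.

The diagnostic statistic is the eigenvalue scree of the respondent-by-
respondent Pearson correlation matrix, the consensus-analysis analogue of a
factor-analysis scree: one shared answer key makes the first eigenvalue a
large multiple of the second, after which the scree flattens into noise.
Replicated datasets are simulated from posterior draws of the fitted model;
if the observed scree (especially its first two eigenvalues) falls inside the
replicate envelope, the one-consensus model reproduces this feature of the
data.  A second eigenvalue above the envelope is the signature of more than
one "culture" in the respondents.

Responses enter the correlation numerically as True = 1, False = 0 and
Don't-know = 0.5 — the symmetric intermediate value, which keeps every
respondent's full row.  This ternary coding is a module convention (the
choice is not canonical in the consensus-analysis literature) and is
configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DONT_KNOW, FALSE, TRUE, ResponseMatrix
from .inference import PosteriorDraws
from .model import EcmParameters, category_probabilities

__all__ = [
    "DEFAULT_NUMERIC_CODING",
    "PpcResult",
    "respondent_correlation_eigenvalues",
    "generate_replicates",
    "ppc_scree",
    "write_scree_table",
    "plot_scree",
]

#: Numeric values used when correlating response vectors.
DEFAULT_NUMERIC_CODING: dict[int, float] = {TRUE: 1.0, FALSE: 0.0, DONT_KNOW: 0.5}


@dataclass
class PpcResult:
    """Observed eigenvalue scree plus the replicate envelope.

    ``replicate_eigenvalues`` is an (R, N) grid; rows of replicates that had
    to drop zero-variance respondents are padded with NaN at the tail, and
    each row sums to the number of respondents retained in that replicate.
    """

    observed_eigenvalues: np.ndarray
    replicate_eigenvalues: np.ndarray
    n_replicates: int
    first_to_second_ratio_observed: float

    def envelope(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-rank (min, max) across replicates, NaN-aware."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN ranks
            return (
                np.nanmin(self.replicate_eigenvalues, axis=0),
                np.nanmax(self.replicate_eigenvalues, axis=0),
            )

    def observed_inside_envelope(self, ranks: tuple[int, ...] = (1, 2)) -> bool:
        """Whether the observed eigenvalues fall inside the envelope at the
        given 1-based ranks — the model-adequacy verdict."""
        lo, hi = self.envelope()
        for r in ranks:
            v = self.observed_eigenvalues[r - 1]
            if not (lo[r - 1] <= v <= hi[r - 1]):
                return False
        return True


def _numeric_rows(
    data: ResponseMatrix, coding: dict[int, float]
) -> tuple[np.ndarray, list[str]]:
    values = np.full(data.values.shape, np.nan)
    for code, num in coding.items():
        values[data.values == code] = num
    # missing cells: impute the respondent's own mean so they do not distort
    # the correlation (complete data is untouched)
    if np.isnan(values).any():
        row_mean = np.nanmean(values, axis=1)
        idx = np.argwhere(np.isnan(values))
        values[idx[:, 0], idx[:, 1]] = row_mean[idx[:, 0]]
    keep = values.std(axis=1) > 0
    if not keep.all():
        dropped = [data.respondent_ids[i] for i in np.flatnonzero(~keep)]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance respondent(s) from the "
            f"correlation: {dropped[:5]}"
        )
    return values[keep], [r for r, k in zip(data.respondent_ids, keep) if k]


def respondent_correlation_eigenvalues(
    data: ResponseMatrix, coding: dict[int, float] | None = None
) -> np.ndarray:
    """Descending eigenvalues of the respondent-by-respondent correlation matrix.

    Respondents whose (numerically coded) response vector has zero variance
    are excluded with a warning, so the eigenvalues sum to the number of
    retained respondents.
    """
    rows, kept = _numeric_rows(data, coding or DEFAULT_NUMERIC_CODING)
    if len(kept) < 2:
        raise ValueError("need at least 2 respondents with response variance")
    corr = np.corrcoef(rows)
    eig = np.linalg.eigvalsh(corr)[::-1]
    return eig


def generate_replicates(
    draws: PosteriorDraws,
    n_replicates: int = 500,
    seed: int = 0,
) -> list[ResponseMatrix]:
    """Simulate replicated response matrices from posterior draws.

    Draws are taken evenly across the pooled chains/iterations (one
    parameter configuration per replicate) and responses are sampled
    cell-wise from the processing-tree category probabilities.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    total = draws.n_chains * draws.n_samples
    picks = np.linspace(0, total - 1, n_replicates).round().astype(int)
    z = draws.stacked("z")
    theta = draws.stacked("theta")
    delta = draws.stacked("delta")
    b = draws.stacked("b")
    g = draws.stacked("g")
    replicates = []
    for j, t in enumerate(picks):
        params = EcmParameters(
            consensus_key=z[t],
            ability=theta[t],
            difficulty=delta[t] - delta[t].mean(),
            willingness=np.clip(b[t], 1e-12, 1 - 1e-12),
            guess_bias=np.clip(g[t], 1e-12, 1 - 1e-12),
        )
        probs = category_probabilities(params)
        u = rng.random(probs.shape[:2])
        cat = (u[..., None] > probs.cumsum(axis=-1)).sum(axis=-1)
        codes = np.select([cat == 0, cat == 1], [TRUE, FALSE], default=DONT_KNOW)
        replicates.append(
            ResponseMatrix(
                codes.astype(np.int8),
                respondent_ids=list(draws.respondent_ids),
                item_ids=list(draws.item_ids),
            )
        )
    return replicates


def ppc_scree(
    observed: ResponseMatrix,
    draws: PosteriorDraws,
    n_replicates: int = 500,
    seed: int = 0,
    coding: dict[int, float] | None = None,
) -> PpcResult:
    """Observed scree versus replicate screes from the fitted model."""
    obs = respondent_correlation_eigenvalues(observed, coding)
    reps = generate_replicates(draws, n_replicates, seed)
    grid = np.full((n_replicates, observed.n_respondents), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # replicate-level zero-variance drops
        for j, rep in enumerate(reps):
            eig = respondent_correlation_eigenvalues(rep, coding)
            grid[j, : eig.size] = eig
    return PpcResult(
        observed_eigenvalues=obs,
        replicate_eigenvalues=grid,
        n_replicates=n_replicates,
        first_to_second_ratio_observed=float(obs[0] / obs[1]),
    )


def write_scree_table(result: PpcResult, path: str | Path, sep: str = ",") -> None:
    """Export (rank, observed, replicate min, replicate max) as delimited text."""
    lo, hi = result.envelope()
    n = result.observed_eigenvalues.size
    frame = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "observed": result.observed_eigenvalues,
            "replicate_min": lo[:n],
            "replicate_max": hi[:n],
        }
    )
    frame.to_csv(path, sep=sep, index=False)


def plot_scree(result: PpcResult, path: str | Path, max_rank: int | None = None) -> None:
    """Scree plot: observed eigenvalues over the replicate envelope."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = result.observed_eigenvalues.size if max_rank is None else max_rank
    ranks = np.arange(1, n + 1)
    lo, hi = result.envelope()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.fill_between(ranks, lo[:n], hi[:n], color="0.8", label="replicate envelope")
    ax.plot(ranks, result.observed_eigenvalues[:n], "k-", lw=2, label="observed")
    ax.set_xlabel("eigenvalue rank")
    ax.set_ylabel("eigenvalue")
    ax.set_title("Respondent-correlation scree: observed vs model replicates")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
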