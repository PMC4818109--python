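"""Ternary response matrices and person covariates.

Responses are stored as an ``int8`` grid with four codes: ``TRUE``, ``FALSE``,
``DONT_KNOW`` and ``MISSING``.  ``MISSING`` cells are dropped from the
likelihood; the distinction between "Don't know" (an observed response the
model explains through the guessing branch) and a missing cell matters and is
kept throughout.

Files are plain delimited tables: a header row of item ids, a first column of
respondent ids, one token per cell.  The default token set is
``True``/``False``/``DontKnow`` (case-insensitive, with ``NA`` or an empty
cell for missing); a custom token-to-code map can be supplied for numerically
coded exports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

# Cell codes.  FALSE/TRUE double as the 0/1 numeric coding of the consensus key.
FALSE: int = 0
TRUE: int = 1
DONT_KNOW: int = 2
MISSING: int = -1

_CODE_NAMES = {TRUE: "TRUE", FALSE: "FALSE", DONT_KNOW: "DONT_KNOW", MISSING: "MISSING"}

#: Default file-token coding (matched case-insensitively).
DEFAULT_CODING: dict[str, int] = {
    "true": TRUE,
    "false": FALSE,
    "dontknow": DONT_KNOW,
    "na": MISSING,
    "": MISSING,
}


class DataError(ValueError):
    """Raised when an input table violates the response/covariate contracts."""


@dataclass
class ResponseMatrix:
    """An N-respondents × M-items grid of ternary responses.

    Parameters
    ----------
    values
        ``(N, M)`` integer array over {TRUE, FALSE, DONT_KNOW, MISSING}.
    respondent_ids, item_ids
        Unique opaque labels for rows and columns.
    item_texts
        Optional item wording, parallel to ``item_ids``.
    """

    values: np.ndarray
    respondent_ids: list[str]
    item_ids: list[str]
    item_texts: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.respondent_ids = [str(r) for r in self.respondent_ids]
        self.item_ids = [str(k) for k in self.item_ids]
        if self.values.ndim != 2:
            raise DataError("response values must be a 2-d grid")
        n, m = self.values.shape
        if n < 2 or m < 2:
            raise DataError(f"need at least 2 respondents and 2 items, got {n}x{m}")
        if len(self.respondent_ids) != n or len(self.item_ids) != m:
            raise DataError("id lists do not match the grid shape")
        if len(set(self.respondent_ids)) != n:
            raise DataError("respondent ids are not unique")
        if len(set(self.item_ids)) != m:
            raise DataError("item ids are not unique")
        valid = np.isin(self.values, (TRUE, FALSE, DONT_KNOW, MISSING))
        if not valid.all():
            i, k = np.argwhere(~valid)[0]
            raise DataError(
                f"invalid code {self.values[i, k]} at respondent "
                f"{self.respondent_ids[i]!r}, item {self.item_ids[k]!r}"
            )
        all_missing = (self.values == MISSING).all(axis=1)
        if all_missing.any():
            i = int(np.argmax(all_missing))
            raise DataError(f"respondent {self.respondent_ids[i]!r} has only missing cells")
        if self.item_texts is not None and len(self.item_texts) != m:
            raise DataError("item_texts does not match the number of items")

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> np.ndarray:
        """Boolean ``(N, M)`` mask of non-missing cells."""
        return self.values != MISSING


@dataclass
class CovariateTable:
    """An N × P table of real person covariates aligned with a ResponseMatrix.

    ``standardized`` records whether each column has been centered to mean 0
    and scaled to unit sample standard deviation (``ddof=1``), the scale on
    which regression coefficients are reported.
    """

    values: np.ndarray
    covariate_names: list[str]
    respondent_ids: list[str]
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("covariate values must be a 2-d grid")
        n, p = self.values.shape
        if len(self.covariate_names) != p:
            raise DataError("covariate_names does not match the number of columns")
        if len(set(self.covariate_names)) != p:
            raise DataError("covariate names are not unique")
        if len(self.respondent_ids) != n:
            raise DataError("respondent_ids does not match the number of rows")
        if not np.isfinite(self.values).all():
            raise DataError("covariates must be finite")
        if self.standardized:
            mean = self.values.mean(axis=0)
            sd = self.values.std(axis=0, ddof=1)
            if np.abs(mean).max() > 1e-8 or np.abs(sd - 1.0).max() > 1e-8:
                raise DataError("standardized flag set but columns are not standardized")

    @property
    def n_covariates(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.covariate_names.index(name)
        except ValueError:
            raise DataError(f"unknown covariate {name!r}") from None
        return self.values[:, j]


def _normalize_coding(coding: dict[str, int] | None) -> dict[str, int]:
    coding = DEFAULT_CODING if coding is None else coding
    out = {str(tok).strip().lower(): code for tok, code in coding.items()}
    if len(out) != len(coding):
        raise DataError("coding tokens collide after case-folding")
    return out


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep, header=0, index_col=0, dtype=str, keep_default_na=False)
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise DataError(f"{path}: empty table")
    return frame


def read_responses(
    path: str | Path,
    coding: dict[str, int] | None = None,
    sep: str | None = None,
) -> ResponseMatrix:
    """Read a delimited response table into a validated :class:`ResponseMatrix`.

    ``coding`` maps file tokens to cell codes (default
    ``True``/``False``/``DontKnow``/``NA``, case-insensitive).  Unrecognized
    tokens raise :class:`DataError` naming the offending cell.
    """
    cmap = _normalize_coding(coding)
    frame = _read_table(path, sep)
    values = np.empty(frame.shape, dtype=np.int8)
    raw = frame.to_numpy(dtype=str)
    for (i, k), tok in np.ndenumerate(raw):
        key = tok.strip().lower()
        if key not in cmap:
            raise DataError(
                f"unrecognized token {tok!r} at respondent {frame.index[i]!r}, "
                f"item {frame.columns[k]!r}"
            )
        values[i, k] = cmap[key]
    return ResponseMatrix(values, list(frame.index), list(frame.columns))


def write_responses(
    data: ResponseMatrix,
    path: str | Path,
    coding: dict[str, int] | None = None,
    sep: str | None = None,
) -> None:
    """Write a response matrix using the inverse of the token coding.

    Round-trips bit-exactly through :func:`read_responses` under the same
    coding.  When several tokens map to one code, the first wins.
    """
    cmap = _normalize_coding(coding)
    inverse: dict[int, str] = {}
    for tok, code in cmap.items():
        inverse.setdefault(code, tok if tok else "NA")
    missing_codes = set(np.unique(data.values)) - set(inverse)
    if missing_codes:
        raise DataError(f"coding has no token for codes {sorted(missing_codes)}")
    if sep is None:
        sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    tokens = np.vectorize(inverse.__getitem__)(data.values)
    frame = pd.DataFrame(tokens, index=data.respondent_ids, columns=data.item_ids)
    frame.to_csv(path, sep=sep, index_label="respondent")


def read_covariates(
    path: str | Path,
    responses: ResponseMatrix | None = None,
    sep: str | None = None,
) -> CovariateTable:
    """Read a person-covariate table keyed by respondent id.

    When ``responses`` is given, rows are reordered to match its respondent
    order and every respondent must be present.
    """
    frame = _read_table(path, sep)
    if frame.index.has_duplicates:
        raise DataError("duplicate respondent ids in covariate table")
    if responses is not None:
        missing = [r for r in responses.respondent_ids if r not in frame.index]
        if missing:
            raise DataError(f"covariate table lacks respondents {missing[:5]}")
        frame = frame.loc[responses.respondent_ids]
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError as exc:
        raise DataError(f"non-numeric covariate value: {exc}") from None
    return CovariateTable(values, list(frame.columns), list(frame.index))


def write_covariates(table: CovariateTable, path: str | Path, sep: str | None = None) -> None:
    if sep is None:
        sep = "\t" if Path(path).suffix.lower() in {".tsv", ".tab"} else ","
    frame = pd.DataFrame(table.values, index=table.respondent_ids, columns=table.covariate_names)
    frame.to_csv(path, sep=sep, index_label="respondent")


def standardize_covariates(raw: CovariateTable) -> CovariateTable:
    """Center each column and scale to unit sample sd (``ddof=1``).

    Regression coefficients are interpreted per standard deviation of the
    predictor, so covariates are standardized before entering the latent
    regression.  Zero-variance columns are rejected.  Idempotent on already
    standardized input.
    """
    sd = raw.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [raw.covariate_names[j] for j in zero]
        raise DataError(f"zero-variance covariate column(s): {names}")
    values = (raw.values - raw.values.mean(axis=0)) / sd
    return replace(raw, values=values, standardized=True)


def raw_item_means(data: ResponseMatrix) -> np.ndarray:
    """Per-item mean of True(=1)/False(=0) responses.

    Don't-know and missing cells are excluded from both numerator and
    denominator: a Don't-know signals uncertainty, not disagreement, and
    counting it as False could not produce the near-1.0 means seen on heavily
    endorsed items.  Items with no True/False response at all get ``nan`` and
    a warning.
    """
    is_true = (data.values == TRUE).astype(float)
    is_tf = np.isin(data.values, (TRUE, FALSE)).astype(float)
    counts = is_tf.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, is_true.sum(axis=0) / np.maximum(counts, 1), np.nan)
    if (counts == 0).any():
        bad = [data.item_ids[k] for k in np.flatnonzero(counts == 0)]
        warnings.warn(f"items with no True/False responses, raw mean undefined: {bad}")
    return means
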