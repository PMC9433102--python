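"""Age-slope inference for longitudinal repertoire measures.

Responses such as richness and ISI span decades across donors, so they
are log10-transformed and modelled with a linear mixed model: fixed
effects age and sex, random intercept per donor (each donor contributes
two visits). The age coefficient S_old (per-year slope on the log10
scale) is converted to percent change of the raw response per year via

    S_new = (10^S_old − 1) × 100.

Per-donor change classification follows the replicate-variability rule:
technical replicates of the same blood draw yield a between-aliquot SD
of the (log10) richness estimate per cell type; a donor's visit-2 value
must move by strictly more than 1 SD to count as increased or decreased.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

SIGNIFICANCE_LEVEL = 0.05


class LongitudinalError(ValueError):
    pass


@dataclass
class SlopeResult:
    response: str
    s_old: float  # per-year slope on the log10 (or raw) scale
    s_new: float  # %/year (meaningful when the response was log10)
    p_value: float
    n_donors: int
    model: str  # "mixed" | "linear"


def slope_to_percent(s_old: float) -> float:
    """(10^S_old − 1) × 100: log10-scale slope → percent change per year."""
    if not np.isfinite(s_old):
        raise LongitudinalError("slope must be finite")
    return (10.0 ** s_old - 1.0) * 100.0


def percent_to_slope(s_new: float) -> float:
    """Inverse conversion: %/year → log10-scale per-year slope."""
    if s_new <= -100.0:
        raise LongitudinalError("percent change must exceed -100")
    return float(np.log10(1.0 + s_new / 100.0))


def fit_mixed_model(data: pd.DataFrame, response: str = "response",
                    log10: bool = True) -> SlopeResult:
    """Random-intercept mixed model of a response on age and sex.

    ``data`` is long-format with columns ``donor``, ``age``, ``sex`` and
    the response. The response is log10-transformed by default. If the
    mixed fit is singular or yields non-finite statistics (e.g. noise-free
    synthetic data), an ordinary linear regression on age + sex is used
    instead, with a logged warning.
    """
    required = {"donor", "age", "sex", response}
    missing = required - set(data.columns)
    if missing:
        raise LongitudinalError(f"data lacks columns {missing}")
    df = data.copy()
    if log10:
        if (df[response] <= 0).any():
            raise LongitudinalError(
                "log10 transform requires a positive response")
        df["_y"] = np.log10(df[response])
    else:
        df["_y"] = df[response]
    n_donors = df["donor"].nunique()

    s_old = p_value = np.nan
    model_used = "mixed"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("_y ~ age + C(sex)", df,
                              groups=df["donor"]).fit(reml=True)
        s_old = float(fit.params["age"])
        p_value = float(fit.pvalues["age"])
    except (np.linalg.LinAlgError, ValueError):
        pass
    if not (np.isfinite(s_old) and np.isfinite(p_value)):
        logger.warning("mixed model singular/non-finite; falling back to "
                       "ordinary linear regression")
        model_used = "linear"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.ols("_y ~ age + C(sex)", df).fit()
        s_old = float(fit.params["age"])
        p_value = float(fit.pvalues["age"])
    s_new = slope_to_percent(s_old) if log10 else float("nan")
    return SlopeResult(response=response, s_old=s_old, s_new=s_new,
                       p_value=p_value, n_donors=n_donors,
                       model=model_used)


def replicate_sd(replicates: Sequence[float], log10: bool = True) -> float:
    """Sample SD of replicate richness estimates (log10 scale by default).

    Replicate aliquots of the same sorted cell population quantify the
    technical spread of the richness estimate for that cell type.
    """
    values = np.asarray(list(replicates), dtype=float)
    if values.size < 2:
        raise LongitudinalError("need >= 2 replicates")
    if log10:
        if (values <= 0).any():
            raise LongitudinalError("log10 requires positive replicates")
        values = np.log10(values)
    return float(np.std(values, ddof=1))


def classify_change(visit1: float, visit2: float, sd: float,
                    log10: bool = True) -> str:
    """Classify a donor's richness change against replicate variability.

    Returns ``"decreased"`` / ``"increased"`` when the visit-2 value moves
    strictly more than 1 SD below/above visit 1, else ``"no_change"``
    (a move of exactly 1 SD is not a change). Comparison is on the log10
    scale by default, matching :func:`replicate_sd`.
    """
    if sd < 0:
        raise LongitudinalError("sd must be >= 0")
    v1, v2 = float(visit1), float(visit2)
    if log10:
        if v1 <= 0 or v2 <= 0:
            raise LongitudinalError("log10 requires positive estimates")
        v1, v2 = np.log10(v1), np.log10(v2)
    if v2 < v1 - sd:
        return "decreased"
    if v2 > v1 + sd:
        return "increased"
    return "no_change"


def classify_cohort(estimates: pd.DataFrame, sd_by_type: dict,
                    log10: bool = True) -> pd.DataFrame:
    """Apply :func:`classify_change` across a cohort.

    ``estimates`` has columns ``donor``, ``cell_type``, ``visit1``,
    ``visit2``; ``sd_by_type`` maps cell type → replicate SD. Returns the
    per-donor classifications plus cohort percentages per category.
    """
    rows = []
    for row in estimates.itertuples(index=False):
        sd = sd_by_type[row.cell_type]
        rows.append((row.donor, row.cell_type,
                     classify_change(row.visit1, row.visit2, sd,
                                     log10=log10)))
    out = pd.DataFrame(rows, columns=["donor", "cell_type", "change"])
    return out


def change_percentages(classified: pd.DataFrame) -> dict:
    """Percent of donor×cell-type entries per change category."""
    counts = classified["change"].value_counts()
    total = counts.sum()
    return {cat: 100.0 * counts.get(cat, 0) / total
            for cat in ("decreased", "no_change", "increased")}
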