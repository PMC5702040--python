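"""Cluster-robust statistics for session risk indicators.

Risk indicators (SPL_max, SEL_cum, R_min) are analysed with saturated
factor models estimated under an independence working correlation — the
generalized-estimating-equation point estimates, which for a saturated
design are the per-cell sample means regardless of family (Gaussian for
the level indicators, gamma with log link for the range). Uncertainty
comes from a leave-one-cluster-out jackknife over the blocking unit
(whale group), which is less biased than the sandwich estimator at the
sample sizes typical of at-sea exposure experiments. Contrasts between
factor-level combinations use a parametric bootstrap on the jackknife
covariance (5000 draws, 95% percentile intervals); a contrast is
significant when its interval excludes zero.

Also provided: two-sided Wald tests, Barnard's unconditional 2x2 test
(pooled-variance score statistic maximised over a nuisance grid), Pearson
correlation and classification of weighted SEL_cum against hearing-risk
thresholds (TTS onset 179, PTS 199 dB re. 1 µPa² s for low-frequency
cetaceans; the auditory weighting is 0 dB in the 1.3-2.0 kHz band, so
unweighted sonar SEL_cum compares directly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

TTS_THRESHOLD_DB = 179.0
PTS_THRESHOLD_DB = 199.0

INDICATOR_COLUMNS = [
    "whale_id",
    "group_id",
    "session_type",
    "avoided",
    "feeding",
    "SPL_max_dB",
    "SEL_cum_dB",
    "R_min_m",
]


@dataclass
class FactorModelFit:
    """A fitted saturated factor model with jackknife covariance."""

    family: str
    response: str
    factors: list[str]
    levels: list[tuple]  # cell identifiers, one per coefficient
    coef_: np.ndarray  # Gaussian: cell means; gamma: log cell means
    cov_: np.ndarray  # jackknife covariance of coef_
    n_clusters: int
    n_obs: int

    def cell_index(self, combo: tuple) -> int:
        combo = combo if isinstance(combo, tuple) else (combo,)
        try:
            return self.levels.index(combo)
        except ValueError:
            raise KeyError(f"no cell {combo!r} in fitted levels {self.levels}")

    def predict_cell(self, combo) -> float:
        """Fitted mean response for one factor-level combination."""
        c = self.coef_[self.cell_index(combo)]
        return float(np.exp(c)) if self.family == "gamma" else float(c)

    @property
    def predictions(self) -> dict:
        return {lv: self.predict_cell(lv) for lv in self.levels}


def _cells(records: pd.DataFrame, factors: list[str]) -> list[tuple]:
    keys = records.groupby(factors, sort=True).groups.keys()
    return sorted(
        (k if isinstance(k, tuple) else (k,) for k in keys),
        key=lambda k: tuple(str(x) for x in k),
    )


def fit_factor_model(
    records: pd.DataFrame,
    response: str,
    factors: Sequence[str],
    family: str = "gaussian",
    cluster: str = "group_id",
) -> FactorModelFit:
    """Fit a saturated factor model with independence working correlation.

    Point estimates are the per-cell quasi-likelihood solutions: sample
    means (Gaussian identity is ordinary least squares on the cell-means
    design; gamma log link gives log cell means, link-independent for a
    saturated design). The covariance is the delete-one-cluster jackknife

        V = (G - 1) / G * sum_g (b_(g) - b_bar)(b_(g) - b_bar)'

    over the G leave-one-cluster-out coefficient vectors b_(g).
    """
    if family not in ("gaussian", "gamma"):
        raise ValueError(f"family must be 'gaussian' or 'gamma', got {family!r}")
    factors = list(factors)
    df = records.dropna(subset=[response])
    cells = _cells(df, factors)
    for combo in cells:
        sub = _cell_rows(df, factors, combo)
        if sub.empty:
            raise ValueError(f"factor level {combo!r} is empty")
    if family == "gamma" and (df[response] <= 0).any():
        raise ValueError("gamma family requires a strictly positive response")

    coef = _fit_cells(df, response, factors, cells, family)

    clusters = df[cluster].unique()
    if len(clusters) < 2:
        raise ValueError("need at least two clusters for the jackknife")
    reps = []
    for g in clusters:
        sub = df[df[cluster] != g]
        try:
            reps.append(_fit_cells(sub, response, factors, cells, family))
        except ValueError:
            warnings.warn(
                f"cluster {g!r} removal empties a cell; jackknife replicate skipped"
            )
    reps = np.asarray(reps)
    if len(reps) < 2:
        raise ValueError("too few jackknife replicates to estimate a covariance")
    centred = reps - reps.mean(axis=0)
    G = len(reps)
    cov = (G - 1) / G * centred.T @ centred
    return FactorModelFit(
        family=family,
        response=response,
        factors=factors,
        levels=cells,
        coef_=coef,
        cov_=cov,
        n_clusters=len(clusters),
        n_obs=len(df),
    )


def _cell_rows(df: pd.DataFrame, factors: list[str], combo: tuple) -> pd.DataFrame:
    combo = combo if isinstance(combo, tuple) else (combo,)
    m = np.ones(len(df), dtype=bool)
    for f, v in zip(factors, combo):
        m &= (df[f] == v).to_numpy()
    return df[m]


def _fit_cells(
    df: pd.DataFrame, response: str, factors: list[str], cells: list[tuple], family: str
) -> np.ndarray:
    coef = np.empty(len(cells))
    for k, combo in enumerate(cells):
        vals = _cell_rows(df, factors, combo)[response].to_numpy(dtype=float)
        if vals.size == 0:
            raise ValueError(f"cell {combo!r} empty")
        mean = vals.mean()
        coef[k] = np.log(mean) if family == "gamma" else mean
    return coef


@dataclass(frozen=True)
class ContrastResult:
    difference: float
    ci_low: float
    ci_high: float
    significant: bool
    n_boot: int


def bootstrap_contrast(
    fit: FactorModelFit,
    level_combo_A,
    level_combo_B,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
) -> ContrastResult:
    """Parametric bootstrap of a prediction difference A - B.

    Coefficient vectors are drawn from N(coef, jackknife covariance);
    predictions are formed per draw (exponentiated for the gamma family)
    and the 2.5th/97.5th percentiles of the A - B differences give the 95%
    interval. Significant iff the interval excludes zero.
    """
    ia, ib = fit.cell_index(level_combo_A), fit.cell_index(level_combo_B)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        draws = rng.multivariate_normal(fit.coef_, fit.cov_, size=n_boot, method="svd")
    except np.linalg.LinAlgError as err:
        raise ValueError("singular jackknife covariance") from err
    if fit.family == "gamma":
        diffs = np.exp(draws[:, ia]) - np.exp(draws[:, ib])
    else:
        diffs = draws[:, ia] - draws[:, ib]
    lo, hi = np.percentile(diffs, [2.5, 97.5])
    point = fit.predict_cell(level_combo_A) - fit.predict_cell(level_combo_B)
    return ContrastResult(
        difference=float(point),
        ci_low=float(lo),
        ci_high=float(hi),
        significant=bool(lo > 0 or hi < 0),
        n_boot=n_boot,
    )


def wald_test(coefficient: float, variance: float) -> tuple[float, float]:
    """Two-sided Wald test: Z = estimate / sqrt(variance), normal p.

    The equivalent chi-square statistic on 1 d.f. is Z².
    """
    if variance <= 0:
        raise ValueError("variance must be positive")
    z = coefficient / np.sqrt(variance)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def wald_contrast(fit: FactorModelFit, level_combo_A, level_combo_B) -> dict:
    """Wald test of a cell contrast on the coefficient scale."""
    ia, ib = fit.cell_index(level_combo_A), fit.cell_index(level_combo_B)
    c = np.zeros(len(fit.coef_))
    c[ia], c[ib] = 1.0, -1.0
    est = float(c @ fit.coef_)
    var = float(c @ fit.cov_ @ c)
    z, p = wald_test(est, var)
    return {"estimate": est, "Z": z, "chi2": z * z, "p": p}


# ---------------------------------------------------------------------------
# Barnard's unconditional test


def _score_statistic(x1, n1, x2, n2) -> np.ndarray:
    """Pooled-variance score statistic for two binomial proportions."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (p1 - p2) / np.sqrt(var)
    return np.where(var > 0, z, 0.0)


def barnard_test(
    table: Sequence[Sequence[int]], nuisance_grid_size: int = 1001
) -> tuple[float, float]:
    """Barnard's unconditional two-sided test on a 2x2 table.

    ``table`` rows are arms, columns (responders, non-responders). The
    statistic is the pooled-variance score Z; the p-value maximises, over a
    uniform grid of the common success probability, the probability under
    independent binomials of |Z| >= |Z_observed|.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        raise ValueError("both arms must be non-empty")
    z_obs = float(_score_statistic(a, n1, c, n2))

    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    zz = _score_statistic(x1[:, None], n1, x2[None, :], n2)
    region = np.abs(zz) >= abs(z_obs) - 1e-12

    pis = np.linspace(0.0, 1.0, nuisance_grid_size)
    pmf1 = stats.binom.pmf(x1[:, None], n1, pis[None, :])  # (n1+1, grid)
    pmf2 = stats.binom.pmf(x2[:, None], n2, pis[None, :])
    # P(region | pi) = sum over rejected (x1, x2) of pmf1 * pmf2
    probs = np.einsum("ij,ig,jg->g", region.astype(float), pmf1, pmf2)
    return z_obs, float(probs.max())


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class HearingRisk:
    category: str  # below_TTS | TTS_range | above_PTS
    margin_to_TTS_dB: float  # threshold minus exposure (positive = below)
    margin_to_PTS_dB: float


def hearing_risk(SEL_cum_weighted_dB: float) -> HearingRisk:
    """Classify a weighted SEL_cum against TTS/PTS onset thresholds.

    Boundary convention: a value exactly at a threshold falls in the higher
    risk category (>= comparison).
    """
    v = SEL_cum_weighted_dB
    if v >= PTS_THRESHOLD_DB:
        cat = "above_PTS"
    elif v >= TTS_THRESHOLD_DB:
        cat = "TTS_range"
    else:
        cat = "below_TTS"
    return HearingRisk(cat, TTS_THRESHOLD_DB - v, PTS_THRESHOLD_DB - v)


def read_indicator_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in INDICATOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"indicator table missing columns {missing}")
    return df
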