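"""Mutation-rate regression with age and downstream aging statistics.

The central fit is a robust mixed model: mutation count (optionally
normalized to the callable autosome fraction) regressed on donor age with
a donor-level random intercept, made resistant to outlying clones by
Huber-type winsorization of the working response.  The module also derives
the cell-division rate implied by a per-division mutation rate, the
proliferation threshold from the days-in-culture band of young clones
intersected with the old-clone regression, per-clone aggregation of
PHRED-scaled deleteriousness scores, and the allele-to-cell fraction
conversion for heterozygous variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .regions import RegionSet

__all__ = [
    "CloneMetadata",
    "RateFit",
    "ThresholdResult",
    "fit_rate",
    "divisions_per_year",
    "derive_threshold",
    "aggregate_deleteriousness",
    "allele_to_cell_fraction",
]

HUBER_C = 1.345  # standard 95%-efficiency Huber tuning constant


@dataclass(frozen=True)
class CloneMetadata:
    """Per-clone study metadata."""

    clone: str
    donor: str
    age: float
    days_in_culture: float
    group: str  # "young" | "old"
    callable_fraction: float = 1.0
    mutation_count: int = 0
    indel_count: int = 0

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.days_in_culture <= 0:
            raise ValueError("days_in_culture must be positive")


def metadata_frame(metadata) -> pd.DataFrame:
    if isinstance(metadata, pd.DataFrame):
        return metadata.copy()
    return pd.DataFrame([vars(m) for m in metadata])


@dataclass
class RateFit:
    """Result of the age-rate regression."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    method: str  # "robust_mixed" | "mixed" | "robust_simple"
    random_effects: dict = field(default_factory=dict)

    def ci(self, z: float = 1.96):
        return (self.slope - z * self.slope_se, self.slope + z * self.slope_se)


@dataclass
class ThresholdResult:
    """Proliferation threshold from days-in-culture vs. mutation burden."""

    young_mean_days: float
    young_sd_days: float
    band: tuple  # (lower, upper) days
    old_slope: float
    old_intercept: float
    threshold: float | None  # mutations; None when old slope <= 0
    healthy_old: list = field(default_factory=list)
    diseased_old: list = field(default_factory=list)


def _fit_mixed(endog: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """Fit a random-intercept MixedLM, trying several optimizers."""
    model = sm.MixedLM(endog, exog, groups=groups)
    last_exc = None
    for method in ("lbfgs", "bfgs", "powell"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return model.fit(reml=True, method=method)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_exc = exc
    raise RuntimeError("mixed model failed to converge") from last_exc


def _robust_mixed(df: pd.DataFrame, response: str,
                  max_iter: int = 20, tol: float = 1e-8):
    """Huber-winsorized iterative fit of a random-intercept mixed model.

    Repeatedly fits ``response ~ age`` with a donor random intercept, then
    winsorizes residuals beyond ``HUBER_C`` robust standard deviations and
    refits on the cleaned working response until the coefficients settle.
    """
    y = df[response].to_numpy(dtype=float)
    X = sm.add_constant(df["age"].to_numpy(float))
    work = y.copy()
    result = None
    prev = None
    for _ in range(max_iter):
        result = _fit_mixed(work, X, df["donor"].to_numpy())
        # residuals against the fixed-effect fit: outlying clones must not be
        # absorbed into their donor's random intercept
        fitted = X @ np.asarray(result.fe_params)
        resid = y - fitted
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad
        if scale <= 0:
            break
        work = fitted + np.clip(resid, -HUBER_C * scale, HUBER_C * scale)
        params = np.asarray(result.params[:2])
        if prev is not None and np.max(np.abs(params - prev)) < tol * max(1.0, np.max(np.abs(prev))):
            break
        prev = params
    # M-estimation consistency correction: the winsorized-response fit
    # understates the estimator's sampling variance by E[psi'(u)]
    se_factor = 1.0
    fitted = X @ np.asarray(result.fe_params)
    resid = y - fitted
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale > 0:
        epsi_prime = float(np.mean(np.abs(resid / scale) <= HUBER_C))
        if epsi_prime > 0:
            se_factor = 1.0 / epsi_prime
    return result, se_factor


def fit_rate(metadata, response: str = "mutation_count",
             normalize: bool = False, fnr: float | None = None,
             method: str = "robust_mixed",
             se_method: str = "jackknife") -> RateFit:
    """Fit the yearly mutation accumulation rate.

    ``metadata`` is a clone-level table (or list of :class:`CloneMetadata`)
    with columns ``donor``, ``age`` and the response.  With
    ``normalize=True`` the response is divided by ``callable_fraction``
    first; with ``fnr`` given, counts are FNR-corrected before fitting.

    ``method``: ``"robust_mixed"`` (default) is the Huber-winsorized
    random-intercept model; ``"mixed"`` the plain mixed model;
    ``"robust_simple"`` a Huber M-estimator without donor structure.
    Designs with fewer than two donors fall back to the robust simple
    regression with a warning.

    ``se_method``: with few donors the model-based slope SE understates
    between-donor sampling variance, so the default is a leave-one-donor-
    out jackknife (``"jackknife"``, used when >= 3 donors); ``"model"``
    reports the mixed-model SE with the M-estimation consistency
    correction.
    """
    df = metadata_frame(metadata)
    if df["age"].nunique() < 2:
        raise ValueError("need at least two distinct ages to fit a rate")
    y = df[response].astype(float)
    if fnr is not None:
        y = y / (1.0 - fnr)
    if normalize:
        y = y / df["callable_fraction"].astype(float)
    df = df.assign(_y=y)

    n_donors = df["donor"].nunique()
    if method in ("robust_mixed", "mixed") and n_donors < 2:
        warnings.warn("single donor: falling back to robust simple regression")
        method = "robust_simple"

    if method == "robust_simple":
        X = sm.add_constant(df["age"].to_numpy(float))
        res = sm.RLM(df["_y"].to_numpy(), X, M=sm.robust.norms.HuberT(t=HUBER_C)).fit()
        return RateFit(slope=float(res.params[1]), intercept=float(res.params[0]),
                       slope_se=float(res.bse[1]), p_value=float(res.pvalues[1]),
                       method="robust_simple")

    se_factor = 1.0
    try:
        if method == "mixed":
            res = _fit_mixed(df["_y"].to_numpy(),
                             sm.add_constant(df["age"].to_numpy(float)),
                             df["donor"].to_numpy())
        else:
            res, se_factor = _robust_mixed(df, "_y")
    except RuntimeError:
        warnings.warn("mixed model did not converge; "
                      "falling back to robust simple regression")
        return fit_rate(df, response="_y", method="robust_simple")

    ranef = {}
    try:
        ranef = {g: float(np.asarray(v)[0]) for g, v in res.random_effects.items()}
    except Exception:
        pass
    slope = float(res.params[1])
    if se_method == "jackknife" and n_donors >= 3:
        donors = df["donor"].unique()
        jack = []
        for d in donors:
            sub = df[df["donor"] != d]
            if sub["age"].nunique() < 2:
                continue
            jack.append(fit_rate(sub, response="_y", method=method,
                                 se_method="model").slope)
        jack = np.asarray(jack)
        g = len(jack)
        slope_se = float(np.sqrt((g - 1) / g * ((jack - jack.mean()) ** 2).sum()))
        dfree = g - 1
    else:
        slope_se = float(res.bse[1]) * se_factor
        dfree = max(1, n_donors - 2)
    if not np.isfinite(slope_se):
        slope_se = 0.0
    if slope_se > 0:
        from scipy.stats import t as t_dist
        p_value = float(2 * t_dist.sf(abs(slope / slope_se), dfree))
    else:
        p_value = float(res.pvalues[1]) if np.isfinite(res.pvalues[1]) else 0.0
    return RateFit(slope=slope, intercept=float(res.params[0]),
                   slope_se=slope_se, p_value=p_value,
                   method="robust_mixed" if method == "robust_mixed" else "mixed",
                   random_effects=ranef)


def divisions_per_year(yearly_rate: float, per_division_rate: float = 2.5) -> float:
    """Cell divisions per year implied by the yearly SNV rate.

    E.g. 13.1 SNVs/genome/year at 2.5 SNVs/genome/division gives 5.24
    divisions per year.  Reported to two decimals.
    """
    if per_division_rate <= 0:
        raise ValueError("per-division rate must be positive")
    return round(yearly_rate / per_division_rate, 2)


def derive_threshold(metadata, sd_mode: str = "sample") -> ThresholdResult:
    """Mutation threshold above which proliferation is compromised.

    The healthy band is mean +/- SD of days in culture of the young clones
    (sample SD by default).  Days in culture of old clones are regressed on
    mutation count by ordinary least squares; the threshold is the mutation
    count at which that regression crosses the band's upper edge.  Old
    clones are then partitioned into healthy (below threshold) and diseased
    (above).  A non-positive old slope leaves the threshold undefined.
    """
    df = metadata_frame(metadata)
    young = df[df["group"] == "young"]
    old = df[df["group"] == "old"].sort_values("clone")
    if not len(young) or not len(old):
        raise ValueError("both young and old groups must be non-empty")
    if old["mutation_count"].nunique() < 2:
        raise ValueError("old group needs at least two distinct mutation counts")

    ddof = 1 if sd_mode == "sample" else 0
    mean_days = float(young["days_in_culture"].mean())
    sd_days = float(young["days_in_culture"].std(ddof=ddof))
    band = (mean_days - sd_days, mean_days + sd_days)

    X = sm.add_constant(old["mutation_count"].to_numpy(float))
    res = sm.OLS(old["days_in_culture"].to_numpy(float), X).fit()
    intercept, slope = float(res.params[0]), float(res.params[1])

    # guard against numerically-zero slopes from flat designs
    scale = np.std(old["days_in_culture"]) / max(np.std(old["mutation_count"]), 1e-12)
    if slope <= max(1e-12, 1e-9 * scale):
        return ThresholdResult(mean_days, sd_days, band, slope, intercept, None)
    threshold = (band[1] - intercept) / slope
    diseased = old[old["mutation_count"] > threshold]["clone"].tolist()
    healthy = old[old["mutation_count"] <= threshold]["clone"].tolist()
    return ThresholdResult(mean_days, sd_days, band, slope, intercept,
                           threshold, healthy, diseased)


def aggregate_deleteriousness(catalog: pd.DataFrame,
                              scores: pd.DataFrame | None = None,
                              scope: RegionSet | None = None) -> dict:
    """Per-clone global deleteriousness score.

    The global score is the sum of PHRED-scaled per-variant scores over the
    variants in scope (whole catalog, or those inside ``scope``).  Scores
    may be a ``score`` column of the catalog or a separate table keyed by
    (chrom, pos, ref, alt).  Unscored variants are excluded and counted.
    """
    df = catalog.copy()
    if scores is not None:
        df = df.merge(scores[["chrom", "pos", "ref", "alt", "score"]],
                      on=["chrom", "pos", "ref", "alt"], how="left")
    if "score" not in df.columns:
        raise ValueError("no per-variant scores available")
    if scope is not None:
        in_scope = [scope.contains(c, int(p) - 1)
                    for c, p in zip(df["chrom"], df["pos"])]
        df = df[np.asarray(in_scope, bool)]
    n_unscored = int(df["score"].isna().sum())
    scored = df.dropna(subset=["score"])
    totals = scored.groupby("clone")["score"].sum()
    return {"per_clone": totals, "n_unscored": n_unscored}


def allele_to_cell_fraction(vaf: float, ploidy: int = 2) -> float:
    """Cell fraction carrying a heterozygous variant at the given VAF.

    A heterozygous variant on a diploid genome occupies one of ``ploidy``
    alleles per cell, so VAF 0.013 corresponds to 2.6% of cells; the result
    is capped at 1.
    """
    if not 0 <= vaf <= 1:
        raise ValueError("VAF must lie in [0, 1]")
    return min(1.0, ploidy * vaf)
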