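"""Posterior summaries: standardized event probabilities, RR/RD/OR, interactions.

Every fitted model is summarized the same way: for each posterior draw the
linear predictor is evaluated at a fixed covariate profile (each adjustment
variable at its most common level, the modal site contributing its own
posterior intercept draw) under both arms, giving per-draw event
probabilities ``(p0, p1)`` for the higher-target (reference) and
lower-target arms.  Per draw,

    RD = p1 - p0,   RR = p1 / p0,   OR = [p1/(1-p1)] / [p0/(1-p0)]

hold exactly; medians, percentile 95% credible intervals and threshold
probabilities (e.g. P(RR < 0.80), the a-priori hypothesised 20% relative
mortality reduction) are empirical functionals of the draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, InputError
from .models import ModelSpec, PosteriorDraws
from .synthetic import TrialDataset

__all__ = [
    "CovariateProfile",
    "EffectSummary",
    "InteractionSummary",
    "most_common_profile",
    "standardized_event_probs",
    "effect_summary",
    "interaction_summary",
    "subgroup_effect_table",
    "DEFAULT_RR_THRESHOLDS",
    "DEFAULT_RD_THRESHOLDS",
]

#: P(RR < c) is reported for these ratios; the protocol's printed set is not
#: public, so the defaults bracket the hypothesised 20% relative reduction.
DEFAULT_RR_THRESHOLDS = (0.67, 0.80, 0.90, 1.00, 1.11, 1.25, 1.50)
#: P(RD < c) thresholds, in percentage points of absolute mortality.
DEFAULT_RD_THRESHOLDS = (-5.0, -2.0, 0.0, 2.0, 5.0)


@dataclass(frozen=True)
class CovariateProfile:
    """One value per adjustment term; the standardization target."""

    values: Mapping[str, object]

    def __getitem__(self, key):
        return self.values[key]

    def __contains__(self, key):
        return key in self.values


def most_common_profile(dataset: TrialDataset, model: PosteriorDraws | ModelSpec,
                        ) -> CovariateProfile:
    """Modal level of every adjustment variable of the fitted model.

    Ties are broken towards the reference level: 0 for binary variables and
    the smallest site ID.  The oxygen-system variable is included only when
    the model adjusted for it.
    """
    df = dataset.df
    if isinstance(model, PosteriorDraws):
        adjust_open = bool(model.meta.get("adjust_open_system", False))
    else:
        adjust_open = model.adjust_open_system
    if len(df) == 0:
        raise InputError("cannot take modal covariate values of an empty dataset")

    def modal_binary(col: str) -> int:
        counts = df[col].value_counts()
        top = counts.max()
        return int(min(v for v, c in counts.items() if c == top))

    values: dict[str, object] = {
        "copd": modal_binary("copd"),
        "haem": modal_binary("haem"),
    }
    if adjust_open:
        values["open_system"] = modal_binary("open_system")
    site_counts = df["site_id"].value_counts()
    top = site_counts.max()
    values["site"] = min(s for s, c in site_counts.items() if c == top)
    return CovariateProfile(values=values)


def _profile_offset(draws: PosteriorDraws, profile: CovariateProfile) -> np.ndarray:
    """Per-draw contribution of the fixed profile to the linear predictor."""
    get = draws.param
    offset = get("alpha").copy()
    for var, coef in (("copd", "gamma_copd"), ("haem", "gamma_haem")):
        if var not in profile:
            raise ContractError(f"covariate profile lacks a value for {var!r}")
        offset += float(profile[var]) * get(coef)
    if "gamma_open_system" in draws.columns:
        if "open_system" not in profile:
            raise ContractError("covariate profile lacks a value for 'open_system'")
        offset += float(profile["open_system"]) * get("gamma_open_system")
    site_levels = draws.meta.get("site_levels", [])
    if len(site_levels) > 1:
        if "site" not in profile:
            raise ContractError("covariate profile lacks a value for 'site'")
        col = f"u_site[{profile['site']}]"
        if col not in draws.columns:
            raise ContractError(f"draws contain no site intercept {col!r}")
        offset += get(col)
    return offset


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def standardized_event_probs(
    draws: PosteriorDraws,
    profile: CovariateProfile,
    subgroup: int | None = None,
    at_value: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-draw adjusted event probabilities ``(p0, p1)`` at the profile.

    ``p0`` is the higher-oxygenation (reference) arm, ``p1`` the lower.  For
    subgroup models pass the group index: the group's intercept ``a_g`` and
    treatment deviation ``b_g`` enter the two linear predictors.  For
    interaction models ``at_value`` evaluates both arms at a covariate value
    (default: the variable's mean, where the centred terms vanish).
    """
    lp0 = _profile_offset(draws, profile)
    lp1 = lp0 + draws.param("beta")
    kind = draws.meta.get("kind")
    if subgroup is not None:
        if kind != "subgroup":
            raise ContractError("subgroup index supplied for a non-subgroup model")
        labels = draws.meta["subgroup_labels"]
        a_col = f"a_subgroup[{labels[subgroup]}]"
        if a_col in draws.columns:
            a = draws.param(a_col)
            lp0, lp1 = lp0 + a, lp1 + a
        lp1 = lp1 + draws.param(f"b_subgroup[{labels[subgroup]}]")
    elif kind == "subgroup":
        raise ContractError("subgroup model summarized without a subgroup index")
    if at_value is not None:
        if kind != "interaction":
            raise ContractError("at_value supplied for a non-interaction model")
        x_c = at_value - draws.meta["x_mean"]
        lp0 = lp0 + draws.param("delta") * x_c
        lp1 = lp1 + (draws.param("delta") + draws.param("eta")) * x_c
    return _expit(lp0), _expit(lp1)


def _med_cri(x: np.ndarray) -> tuple[float, float, float]:
    lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
    return float(med), float(lo), float(hi)


@dataclass(frozen=True)
class EffectSummary:
    """Adjusted per-arm probabilities and derived effect measures."""

    p0: tuple[float, float, float]  # (median, 2.5%, 97.5%) — higher target
    p1: tuple[float, float, float]  # lower target
    rr: tuple[float, float, float]
    rd: tuple[float, float, float]
    or_: tuple[float, float, float]
    prob_rr_below: Mapping[float, float]
    prob_rd_below: Mapping[float, float]  # thresholds in percentage points
    n_draws: int
    label: str = "all patients"
    n_patients: int | None = None

    def to_row(self) -> dict:
        fmt = lambda t: {"median": t[0], "cri_low": t[1], "cri_high": t[2]}
        row = {"group": self.label, "n": self.n_patients, "draws": self.n_draws}
        for name, t in (("p_lower", self.p1), ("p_higher", self.p0),
                        ("rr", self.rr), ("rd_pct", self.rd), ("or", self.or_)):
            for k, v in fmt(t).items():
                row[f"{name}_{k}"] = v
        for c, p in self.prob_rr_below.items():
            row[f"P(RR<{c:g})"] = p
        for c, p in self.prob_rd_below.items():
            row[f"P(RD<{c:g}pp)"] = p
        return row


def effect_summary(
    p0: np.ndarray,
    p1: np.ndarray,
    rr_thresholds: Sequence[float] = DEFAULT_RR_THRESHOLDS,
    rd_thresholds: Sequence[float] = DEFAULT_RD_THRESHOLDS,
    label: str = "all patients",
    n_patients: int | None = None,
) -> EffectSummary:
    """Summarize per-draw arm probabilities into RR/RD/OR with 95% CrIs.

    RD is reported in percentage points.  Threshold probabilities are
    empirical fractions of draws strictly below each threshold (equality,
    of measure zero for continuous posteriors, counts to the lower side).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    if p0.size == 0 or p0.shape != p1.shape:
        raise InputError("need matching non-empty p0/p1 draw vectors")
    if np.any(p0 <= 0.0):
        raise InputError("p0 contains zero draws: RR undefined")
    rr = p1 / p0
    rd = p1 - p0
    or_ = (p1 / (1 - p1)) / (p0 / (1 - p0))
    return EffectSummary(
        p0=_med_cri(p0), p1=_med_cri(p1), rr=_med_cri(rr),
        rd=_med_cri(100.0 * rd), or_=_med_cri(or_),
        prob_rr_below={float(c): float(np.mean(rr < c)) for c in rr_thresholds},
        prob_rd_below={float(c): float(np.mean(100.0 * rd < c)) for c in rd_thresholds},
        n_draws=int(p0.size), label=label, n_patients=n_patients,
    )


@dataclass(frozen=True)
class InteractionSummary:
    """Interaction OR per original unit, directional probabilities, curves."""

    variable: str
    or_per_unit: tuple[float, float, float]
    prob_below_1: float
    prob_above_1: float
    prob_equal_1: float  # degenerate point mass at exactly OR = 1
    curve: pd.DataFrame = field(repr=False)  # columns: x, arm, median, cri_low, cri_high
    n_draws: int = 0

    def to_row(self) -> dict:
        return {
            "variable": self.variable,
            "or_median": self.or_per_unit[0],
            "or_cri_low": self.or_per_unit[1],
            "or_cri_high": self.or_per_unit[2],
            "P(OR<1)": self.prob_below_1,
            "P(OR>1)": self.prob_above_1,
            "draws": self.n_draws,
        }


def interaction_summary(
    draws: PosteriorDraws,
    grid: Sequence[float],
    profile: CovariateProfile,
) -> InteractionSummary:
    """Summarize an interaction model: OR per unit and conditional-effect curves.

    The curve gives, for each grid value of the baseline variable and each
    arm, the median and 95% CrI of the standardized event probability with
    all other adjustment terms fixed at the profile.
    """
    if draws.meta.get("kind") != "interaction":
        raise ContractError("interaction_summary requires draws from an interaction model")
    eta = draws.param("eta")
    lo_obs, hi_obs = draws.meta.get("x_range", (-np.inf, np.inf))
    grid = np.asarray(list(grid), dtype=float)
    if grid.size and (grid.min() < lo_obs or grid.max() > hi_obs):
        warnings.warn(
            f"{draws.meta.get('variable')}: grid extends beyond the observed "
            f"range [{lo_obs:g}, {hi_obs:g}]", stacklevel=2)
    rows = []
    for xv in grid:
        p0, p1 = standardized_event_probs(draws, profile, at_value=float(xv))
        for arm, p in (("higher", p0), ("lower", p1)):
            med, lo, hi = _med_cri(p)
            rows.append({"x": float(xv), "arm": arm, "median": med,
                         "cri_low": lo, "cri_high": hi})
    curve = pd.DataFrame(rows, columns=["x", "arm", "median", "cri_low", "cri_high"])
    return InteractionSummary(
        variable=str(draws.meta.get("variable")),
        or_per_unit=_med_cri(np.exp(eta)),
        prob_below_1=float(np.mean(eta < 0)),
        prob_above_1=float(np.mean(eta > 0)),
        prob_equal_1=float(np.mean(eta == 0)),
        curve=curve, n_draws=int(eta.size),
    )


def subgroup_effect_table(
    draws: PosteriorDraws,
    profile: CovariateProfile,
    rr_thresholds: Sequence[float] = DEFAULT_RR_THRESHOLDS,
    rd_thresholds: Sequence[float] = DEFAULT_RD_THRESHOLDS,
) -> tuple[list[EffectSummary], pd.DataFrame]:
    """One EffectSummary per subgroup plus the combined tabular view."""
    if draws.meta.get("kind") != "subgroup":
        raise ContractError("subgroup_effect_table requires a subgroup model")
    labels = draws.meta["subgroup_labels"]
    counts = draws.meta.get("subgroup_counts", [None] * len(labels))
    summaries = []
    for g, (lbl, n_g) in enumerate(zip(labels, counts)):
        p0, p1 = standardized_event_probs(draws, profile, subgroup=g)
        summaries.append(effect_summary(p0, p1, rr_thresholds, rd_thresholds,
                                        label=str(lbl), n_patients=n_g))
    table = pd.DataFrame([s.to_row() for s in summaries])
    return summaries, table
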