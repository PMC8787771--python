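"""Prior families for the treatment effect on the log-odds-ratio scale.

Three normal priors on the treatment log-OR drive the primary analysis and
its two pre-specified sensitivity analyses:

* **weak** — Normal(0, 1): centred on no difference, wide enough that 95% of
  prior mass covers ORs from 0.14 to 7.10, so the trial data dominate.
* **evidence** — the predictive distribution of a new trial's effect from a
  DerSimonian-Laird random-effects meta-analysis of earlier oxygenation-target
  trials: Normal(mu, sqrt(se_mu^2 + tau^2)).
* **sceptic** — Normal(0, 0.355): centred on no difference and sceptical of
  large effects (95% of prior mass within ORs 0.50-2.01).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import log, sqrt

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError

__all__ = [
    "PriorSpec",
    "StudyTable",
    "MetaAnalysisResult",
    "weakly_informative_prior",
    "sceptic_prior",
    "random_effects_meta",
    "evidence_based_prior",
    "read_study_tables",
    "illustrative_study_tables",
]

#: Default sceptic-prior SD on the log-OR scale; places 95% of prior mass on
#: ORs within roughly [0.50, 2.01] — the conventional sceptical calibration.
DEFAULT_SCEPTIC_SD = 0.355


@dataclass(frozen=True)
class PriorSpec:
    """A normal prior on the treatment log-odds-ratio."""

    label: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0):
            raise ConfigurationError(f"prior sd must be > 0, got {self.sd}")

    def or_interval(self, mass: float = 0.95) -> tuple[float, float]:
        """Central credible interval on the OR scale."""
        z = stats.norm.ppf(0.5 + mass / 2.0)
        return (float(np.exp(self.mean - z * self.sd)),
                float(np.exp(self.mean + z * self.sd)))

    def prob_or_below(self, threshold: float) -> float:
        """Prior probability that the OR is below ``threshold``."""
        return float(stats.norm.cdf(log(threshold), loc=self.mean, scale=self.sd))


def weakly_informative_prior() -> PriorSpec:
    """Normal(0, 1) on the log-OR: 95% prior mass on ORs in [0.14, 7.10]."""
    return PriorSpec(label="weak", mean=0.0, sd=1.0)


def sceptic_prior(sd: float = DEFAULT_SCEPTIC_SD) -> PriorSpec:
    """Normal(0, sd) on the log-OR, sceptical of large effects."""
    return PriorSpec(label="sceptic", mean=0.0, sd=sd)


@dataclass(frozen=True)
class StudyTable:
    """One trial's 2x2 mortality table (intervention vs control arm)."""

    study: str
    events_intervention: int
    n_intervention: int
    events_control: int
    n_control: int

    def __post_init__(self) -> None:
        for arm in ("intervention", "control"):
            e = getattr(self, f"events_{arm}")
            n = getattr(self, f"n_{arm}")
            if n < 1:
                raise InputError(f"{self.study}: {arm} arm has n={n} (need >= 1)")
            if not (0 <= e <= n):
                raise InputError(f"{self.study}: {arm} events {e} outside [0, {n}]")

    def log_or(self) -> tuple[float, float]:
        """(log-OR, variance) with a 0.5 continuity correction applied to all
        four cells when any cell is zero (Woolf correction)."""
        a = float(self.events_intervention)
        b = float(self.n_intervention - self.events_intervention)
        c = float(self.events_control)
        d = float(self.n_control - self.events_control)
        if min(a, b, c, d) == 0:
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        y = log(a * d / (b * c))
        v = 1 / a + 1 / b + 1 / c + 1 / d
        return y, v


@dataclass(frozen=True)
class MetaAnalysisResult:
    """DerSimonian-Laird random-effects pooling on the log-OR scale."""

    mu: float
    se_mu: float
    tau2: float
    study_labels: tuple[str, ...]
    study_log_ors: tuple[float, ...]
    study_variances: tuple[float, ...]
    weights: tuple[float, ...]  # normalized random-effects weights; sum to 1

    @property
    def k(self) -> int:
        return len(self.study_labels)


def random_effects_meta(tables: list[StudyTable]) -> MetaAnalysisResult:
    """DerSimonian-Laird random-effects meta-analysis of 2x2 tables.

    Per-study log-ORs and variances feed the moment estimator
    ``tau2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` with
    fixed-effect weights ``w = 1/v``; the pooled mean uses random-effects
    weights ``w* = 1/(v + tau2)``.
    """
    if not tables:
        raise InputError("meta-analysis requires at least one study table")
    ys, vs, labels = [], [], []
    for t in tables:
        y, v = t.log_or()
        ys.append(y)
        vs.append(v)
        labels.append(t.study)
    y = np.asarray(ys)
    v = np.asarray(vs)
    w = 1.0 / v
    mu_fixed = float(np.sum(w * y) / np.sum(w))
    q = float(np.sum(w * (y - mu_fixed) ** 2))
    k = len(tables)
    if k > 1:
        denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (q - (k - 1)) / denom)
    else:
        tau2 = 0.0
    w_star = 1.0 / (v + tau2)
    mu = float(np.sum(w_star * y) / np.sum(w_star))
    se_mu = float(np.sum(w_star) ** -0.5)
    weights = w_star / np.sum(w_star)
    return MetaAnalysisResult(
        mu=mu, se_mu=se_mu, tau2=tau2,
        study_labels=tuple(labels),
        study_log_ors=tuple(float(x) for x in y),
        study_variances=tuple(float(x) for x in v),
        weights=tuple(float(x) for x in weights),
    )


def evidence_based_prior(result: MetaAnalysisResult) -> PriorSpec:
    """Predictive distribution of a new trial's log-OR: Normal(mu, sqrt(se^2 + tau^2)).

    Between-study heterogeneity widens the prior, reflecting that the new
    trial's true effect is itself a draw from the random-effects distribution.
    """
    return PriorSpec(label="evidence", mean=result.mu,
                     sd=sqrt(result.se_mu**2 + result.tau2))


def read_study_tables(path) -> list[StudyTable]:
    """Read study 2x2 tables from a CSV with columns study, e_int, n_int, e_ctl, n_ctl."""
    df = pd.read_csv(path)
    required = ["study", "e_int", "n_int", "e_ctl", "n_ctl"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"study table CSV lacks columns: {missing}")
    return [
        StudyTable(study=str(r.study),
                   events_intervention=int(r.e_int), n_intervention=int(r.n_int),
                   events_control=int(r.e_ctl), n_control=int(r.n_ctl))
        for r in df.itertuples()
    ]


def illustrative_study_tables() -> list[StudyTable]:
    """The packaged *illustrative* three-trial fixture for the evidence-based prior.

    Arm counts are synthetic placeholders of realistic magnitude, not
    transcriptions of the cited trials' published results; replace the CSV
    with transcribed values for a real analysis.
    """
    ref = resources.files("bayeshte.data") / "illustrative_meta_trials.csv"
    with resources.as_file(ref) as path:
        return read_study_tables(path)
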