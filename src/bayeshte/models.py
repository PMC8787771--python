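"""Bayesian logistic regression models for the trial analyses.

Three model families share one machinery — a logistic likelihood with normal
priors on fixed effects and non-centered, partially pooled normal random
effects with half-normal scale priors:

* **primary**: ``logit P(death) = alpha + beta*T + gamma_copd*copd +
  gamma_haem*haem + u_site``, with ``u_s ~ Normal(0, sigma_site)`` and the
  supplied prior on the treatment log-OR ``beta`` (T = 1 for the lower
  oxygenation target).
* **subgroup**: adds partially pooled subgroup intercepts ``a_g`` and
  subgroup-specific treatment-effect deviations ``b_g`` so the treatment
  log-OR in group g is ``beta + b_g`` — small groups are shrunk towards the
  overall effect.
* **interaction**: adds a continuous baseline variable and its product with
  treatment, ``... + delta*x + eta*(T*x)``; ``x`` is standardized internally
  for sampler geometry and ``delta``/``eta`` are reported per original unit.

Sampling uses the in-package adaptive NUTS sampler; diagnostics (split R-hat,
bulk/tail effective sample size, divergences) come from arviz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .priors import PriorSpec, weakly_informative_prior
from .sampler import nuts_sample
from .subgroups import SubgroupScheme
from .synthetic import TrialDataset

__all__ = [
    "ModelSpec",
    "PosteriorDraws",
    "fit_primary",
    "fit_subgroup_hte",
    "fit_continuous_interaction",
    "diagnostics",
    "DiagnosticsReport",
    "INTERACTION_VARIABLES",
]

INTERACTION_VARIABLES = ("sofa", "pf_ratio", "lactate", "norepi_dose")


def _default_nuisance_scales() -> dict[str, float]:
    return {
        "intercept": 2.5,  # weakly informative at centred covariates
        "binary_coef": 1.0,
        "continuous_coef": 1.0,  # per SD of the standardized variable
        "sigma_site": 1.0,  # half-normal scales for pooling SDs
        "sigma_subgroup_intercept": 0.5,
        "sigma_subgroup_effect": 0.5,
    }


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one analysis model and its sampler settings."""

    kind: str = "primary"  # primary | subgroup | interaction
    prior: PriorSpec = field(default_factory=weakly_informative_prior)
    adjust_open_system: bool = False
    include_subgroup_intercepts: bool = True
    nuisance_scales: Mapping[str, float] = field(default_factory=_default_nuisance_scales)
    chains: int = 4
    warmup: int = 5000
    draws: int = 5000
    seed: int = 0
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.kind not in ("primary", "subgroup", "interaction"):
            raise ConfigurationError(f"unknown analysis kind {self.kind!r}")
        if self.chains < 2:
            raise ConfigurationError("chains must be >= 2")
        if self.draws < 1 or self.warmup < 1:
            raise ConfigurationError("warmup and draws must be >= 1")

    def scale(self, key: str) -> float:
        return dict(_default_nuisance_scales(), **dict(self.nuisance_scales))[key]


@dataclass
class PosteriorDraws:
    """Posterior draws on the natural (constrained, per-unit) scale.

    ``values`` has shape (chains, draws_per_chain, n_params); ``columns``
    names the parameters.  ``meta`` carries everything the summary stage
    needs: model kind, site levels, subgroup labels, and the centring used
    for a continuous interaction variable.
    """

    values: np.ndarray
    columns: list[str]
    divergences: int
    meta: dict

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.values.shape[1]

    @property
    def n_draws(self) -> int:
        return self.values.shape[0] * self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        flat = self.values.reshape(-1, self.values.shape[2])
        df = pd.DataFrame(flat, columns=self.columns)
        df.insert(0, "chain", np.repeat(np.arange(self.n_chains), self.n_draws_per_chain))
        df.insert(1, "draw", np.tile(np.arange(self.n_draws_per_chain), self.n_chains))
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, meta: dict | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        chains = int(df["chain"].max()) + 1
        per_chain = int(df["draw"].max()) + 1
        cols = [c for c in df.columns if c not in ("chain", "draw")]
        values = df[cols].to_numpy().reshape(chains, per_chain, len(cols))
        return cls(values=values, columns=cols, divergences=0, meta=meta or {})

    def param(self, name: str) -> np.ndarray:
        """Flattened draws of one named parameter."""
        return self.values[:, :, self.columns.index(name)].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        data = {c: self.values[:, :, i] for i, c in enumerate(self.columns)}
        return az.from_dict(posterior=data)


# ---------------------------------------------------------------------------
# Generic logistic model with non-centered random-effect blocks
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    name: str  # parameter base name, e.g. "u_site"
    sigma_name: str
    index: np.ndarray  # (n,) int level of each observation
    n_levels: int
    scale: float  # half-normal prior scale on sigma
    multiplier: np.ndarray | None = None  # (n,) e.g. treatment indicator
    level_labels: Sequence | None = None


class _LogisticModel:
    """Joint log density and gradient on the unconstrained scale.

    Parameter vector: fixed-effect coefficients, then for each block its
    standard-normal deviates z and the log of the pooling SD.
    """

    def __init__(self, X, y, coef_names, prior_mean, prior_sd, blocks):
        self.X = np.ascontiguousarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.coef_names = list(coef_names)
        self.prior_mean = np.asarray(prior_mean, dtype=float)
        self.prior_sd = np.asarray(prior_sd, dtype=float)
        self.blocks = blocks
        self.p = self.X.shape[1]
        self.dim = self.p + sum(b.n_levels + 1 for b in blocks)

    def logp_grad(self, q):
        p = self.p
        theta = q[:p]
        lp = self.X @ theta
        pos = p
        sigmas, zs = [], []
        for b in self.blocks:
            z = q[pos:pos + b.n_levels]
            zeta = q[pos + b.n_levels]
            sigma = np.exp(zeta)
            contrib = sigma * z[b.index]
            if b.multiplier is not None:
                contrib = contrib * b.multiplier
            lp = lp + contrib
            sigmas.append(sigma)
            zs.append(z)
            pos += b.n_levels + 1

        # One exp serves both the logistic mean and log1pexp:
        # with a = exp(-|lp|), expit(lp) = {1/(1+a) if lp>=0 else a/(1+a)} and
        # log(1+exp(lp)) = max(lp, 0) + log1p(a).
        a = np.exp(-np.abs(lp))
        denom = 1.0 + a
        mu = np.where(lp >= 0, 1.0 / denom, a / denom)
        logp = float(np.sum(self.y * lp) - np.sum(np.maximum(lp, 0.0) + np.log1p(a)))
        resid = (theta - self.prior_mean) / self.prior_sd
        logp -= 0.5 * float(np.sum(resid**2))

        grad = np.empty_like(q)
        r = self.y - mu
        grad[:p] = self.X.T @ r - resid / self.prior_sd

        pos = p
        for b, sigma, z in zip(self.blocks, sigmas, zs):
            w = r if b.multiplier is None else r * b.multiplier
            sum_w = np.bincount(b.index, weights=w, minlength=b.n_levels)
            grad[pos:pos + b.n_levels] = sigma * sum_w - z
            logp -= 0.5 * float(np.sum(z**2))
            # half-Normal(0, scale) prior on sigma, log transform Jacobian
            # (log sigma == the unconstrained parameter itself)
            logp += -0.5 * (sigma / b.scale) ** 2 + q[pos + b.n_levels]
            grad[pos + b.n_levels] = (
                sigma * float(np.dot(sum_w, z)) - (sigma / b.scale) ** 2 + 1.0)
            pos += b.n_levels + 1
        return logp, grad

    def constrain(self, raw: np.ndarray) -> tuple[np.ndarray, list[str]]:
        """Map unconstrained draws (C, D, dim) to natural-scale named draws."""
        chains, draws_, _ = raw.shape
        cols = list(self.coef_names)
        pieces = [raw[:, :, :self.p]]
        pos = self.p
        for b in self.blocks:
            z = raw[:, :, pos:pos + b.n_levels]
            sigma = np.exp(raw[:, :, pos + b.n_levels])
            pieces.append(z * sigma[:, :, None])
            pieces.append(sigma[:, :, None])
            labels = b.level_labels if b.level_labels is not None else range(b.n_levels)
            cols += [f"{b.name}[{lbl}]" for lbl in labels]
            cols.append(b.sigma_name)
            pos += b.n_levels + 1
        return np.concatenate(pieces, axis=2), cols


def _complete_cases(dataset: TrialDataset, variables: list[str]) -> pd.DataFrame:
    df = dataset.df
    if len(df) == 0:
        return df
    missing = [v for v in variables if v not in df.columns]
    if missing:
        raise InputError(f"dataset lacks required columns: {missing}")
    keep = df[variables].notna().all(axis=1)
    return df.loc[keep]


def _check_outcome(df: pd.DataFrame) -> np.ndarray:
    y = df["dead_90d"].to_numpy(dtype=float) if len(df) else np.zeros(0)
    if len(y) and not np.isin(y, (0.0, 1.0)).all():
        raise InputError("dead_90d must be binary 0/1")
    return y


def _site_block(df: pd.DataFrame, spec: ModelSpec) -> tuple[list[_Block], list]:
    """Partially pooled site intercepts; omitted for a single (or no) site."""
    if len(df) == 0:
        return [], []
    levels = np.sort(df["site_id"].unique())
    if len(levels) < 2:
        return [], list(levels)
    idx = np.searchsorted(levels, df["site_id"].to_numpy())
    block = _Block(name="u_site", sigma_name="sigma_site", index=idx,
                   n_levels=len(levels), scale=spec.scale("sigma_site"),
                   level_labels=[str(l) for l in levels])
    return [block], list(levels)


def _sample(model: _LogisticModel, spec: ModelSpec, meta: dict) -> PosteriorDraws:
    res = nuts_sample(
        model.logp_grad, model.dim,
        chains=spec.chains, warmup=spec.warmup, draws=spec.draws,
        seed=spec.seed, target_accept=spec.target_accept)
    values, cols = model.constrain(res.draws)
    if int(res.divergences.sum()) > 0:
        warnings.warn(f"{int(res.divergences.sum())} divergent transitions "
                      "after warm-up; check diagnostics", stacklevel=3)
    return PosteriorDraws(values=values, columns=cols,
                          divergences=int(res.divergences.sum()), meta=meta)


def fit_primary(dataset: TrialDataset, spec: ModelSpec | None = None) -> PosteriorDraws:
    """Fit the overall treatment-effect model (adjusted for copd, haem, site)."""
    spec = spec or ModelSpec(kind="primary")
    required = ["dead_90d", "allocation", "copd", "haem", "site_id"]
    if spec.adjust_open_system:
        required.append("open_system")
    df = _complete_cases(dataset, required)
    y = _check_outcome(df)
    n = len(df)

    treat = (df["allocation"] == "lower").to_numpy(dtype=float) if n else np.zeros(0)
    cols = {"alpha": np.ones(n), "beta": treat,
            "gamma_copd": df["copd"].to_numpy(dtype=float) if n else np.zeros(0),
            "gamma_haem": df["haem"].to_numpy(dtype=float) if n else np.zeros(0)}
    if spec.adjust_open_system:
        cols["gamma_open_system"] = df["open_system"].to_numpy(dtype=float) if n else np.zeros(0)
    X = np.column_stack(list(cols.values())) if n else np.zeros((0, len(cols)))
    prior_mean = np.array([0.0, spec.prior.mean] + [0.0] * (len(cols) - 2))
    prior_sd = np.array([spec.scale("intercept"), spec.prior.sd]
                        + [spec.scale("binary_coef")] * (len(cols) - 2))
    blocks, site_levels = _site_block(df, spec)
    model = _LogisticModel(X, y, list(cols), prior_mean, prior_sd, blocks)
    meta = {"kind": "primary", "n": n, "site_levels": site_levels,
            "prior": spec.prior.label, "adjust_open_system": spec.adjust_open_system}
    return _sample(model, spec, meta)


def fit_subgroup_hte(dataset: TrialDataset, scheme: SubgroupScheme,
                     spec: ModelSpec | None = None) -> PosteriorDraws:
    """Fit the hierarchical subgroup model with partial pooling.

    Subgroup intercepts ``a_g`` and treatment-effect deviations ``b_g`` are
    each pooled with half-normal scale priors; group g's treatment log-OR is
    ``beta + b_g``.
    """
    spec = spec or ModelSpec(kind="subgroup")
    spec = replace(spec, kind="subgroup")
    required = ["dead_90d", "allocation", "copd", "haem", "site_id"]
    if spec.adjust_open_system:
        required.append("open_system")
    if len(scheme.assignments) != len(dataset.df):
        raise InputError("subgroup scheme was not built on this dataset "
                         f"({len(scheme.assignments)} assignments vs {len(dataset.df)} rows)")
    df = dataset.df.assign(_group=scheme.assignments)
    df = TrialDataset(df=df, config=dataset.config).df
    keep = df[required].notna().all(axis=1) & (df["_group"] >= 0)
    df = df.loc[keep]
    y = _check_outcome(df)
    n = len(df)
    if n == 0:
        raise InputError("no complete cases for the subgroup analysis")

    treat = (df["allocation"] == "lower").to_numpy(dtype=float)
    group = df["_group"].to_numpy(dtype=int)
    for g in range(scheme.n_groups):
        arms = treat[group == g]
        if len(arms) == 0 or arms.min() == arms.max():
            warnings.warn(
                f"subgroup {scheme.labels[g]!r} lacks patients in one arm; "
                "its effect is informed by pooling alone", stacklevel=2)

    cols = {"alpha": np.ones(n), "beta": treat,
            "gamma_copd": df["copd"].to_numpy(dtype=float),
            "gamma_haem": df["haem"].to_numpy(dtype=float)}
    if spec.adjust_open_system:
        cols["gamma_open_system"] = df["open_system"].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    prior_mean = np.array([0.0, spec.prior.mean] + [0.0] * (len(cols) - 2))
    prior_sd = np.array([spec.scale("intercept"), spec.prior.sd]
                        + [spec.scale("binary_coef")] * (len(cols) - 2))

    blocks, site_levels = _site_block(df, spec)
    if spec.include_subgroup_intercepts:
        blocks.append(_Block(name="a_subgroup", sigma_name="sigma_a", index=group,
                             n_levels=scheme.n_groups,
                             scale=spec.scale("sigma_subgroup_intercept"),
                             level_labels=scheme.labels))
    blocks.append(_Block(name="b_subgroup", sigma_name="sigma_b", index=group,
                         n_levels=scheme.n_groups,
                         scale=spec.scale("sigma_subgroup_effect"),
                         multiplier=treat, level_labels=scheme.labels))
    model = _LogisticModel(X, y, list(cols), prior_mean, prior_sd, blocks)
    meta = {"kind": "subgroup", "n": n, "site_levels": site_levels,
            "variable": scheme.variable, "subgroup_labels": list(scheme.labels),
            "subgroup_counts": [int((group == g).sum()) for g in range(scheme.n_groups)],
            "prior": spec.prior.label, "adjust_open_system": spec.adjust_open_system}
    return _sample(model, spec, meta)


def fit_continuous_interaction(dataset: TrialDataset, variable: str,
                               spec: ModelSpec | None = None) -> PosteriorDraws:
    """Fit the treatment-by-covariate interaction model on the continuous scale.

    ``delta`` (covariate slope) and ``eta`` (interaction) are sampled on the
    standardized scale and reported per original unit; the PaO2:FiO2 model is
    additionally adjusted for the oxygen-system type (closed = reference).
    """
    if variable not in INTERACTION_VARIABLES:
        raise InputError(f"interaction variable must be one of {INTERACTION_VARIABLES}, "
                         f"got {variable!r}")
    spec = spec or ModelSpec(kind="interaction")
    adjust_open = spec.adjust_open_system or variable == "pf_ratio"
    spec = replace(spec, kind="interaction", adjust_open_system=adjust_open)
    required = ["dead_90d", "allocation", "copd", "haem", "site_id", variable]
    if adjust_open:
        required.append("open_system")
    df = _complete_cases(dataset, required)
    y = _check_outcome(df)
    n = len(df)
    if n == 0:
        raise InputError("no complete cases for the interaction analysis")

    x = df[variable].to_numpy(dtype=float)
    x_mean, x_sd = float(x.mean()), float(x.std(ddof=0))
    if x_sd == 0:
        raise InputError(f"{variable} is constant; the interaction is unidentifiable")
    x_std = (x - x_mean) / x_sd
    treat = (df["allocation"] == "lower").to_numpy(dtype=float)

    cols = {"alpha": np.ones(n), "beta": treat, "delta": x_std,
            "eta": treat * x_std,
            "gamma_copd": df["copd"].to_numpy(dtype=float),
            "gamma_haem": df["haem"].to_numpy(dtype=float)}
    if adjust_open:
        cols["gamma_open_system"] = df["open_system"].to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    c = spec.scale("continuous_coef")
    prior_mean = np.array([0.0, spec.prior.mean, 0.0, 0.0]
                          + [0.0] * (len(cols) - 4))
    prior_sd = np.array([spec.scale("intercept"), spec.prior.sd, c, c]
                        + [spec.scale("binary_coef")] * (len(cols) - 4))
    blocks, site_levels = _site_block(df, spec)
    model = _LogisticModel(X, y, list(cols), prior_mean, prior_sd, blocks)
    draws = _sample(model, spec, {})
    # Rescale delta and eta to per-original-unit effects.
    for name in ("delta", "eta"):
        draws.values[:, :, draws.columns.index(name)] /= x_sd
    draws.meta.update({
        "kind": "interaction", "n": n, "variable": variable,
        "site_levels": site_levels, "x_mean": x_mean, "x_sd": x_sd,
        "x_range": (float(x.min()), float(x.max())),
        "prior": spec.prior.label, "adjust_open_system": adjust_open,
    })
    return draws


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticsReport:
    """Per-parameter convergence diagnostics with an overall verdict."""

    table: pd.DataFrame  # index: parameter; columns: rhat, ess_bulk, ess_tail
    divergences: int
    acceptable: bool
    note: str = ""

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.attrs = {}
        out.to_csv(path, index_label="parameter")


def diagnostics(draws: PosteriorDraws, rhat_threshold: float = 1.01) -> DiagnosticsReport:
    """Split R-hat, bulk/tail ESS and divergence count for every parameter.

    The verdict is acceptable iff every R-hat is below ``rhat_threshold`` and
    no post-warm-up divergences occurred.  With a single chain R-hat is
    undefined and the verdict is based on divergences alone, with a note.
    """
    idata = draws.to_inference_data()
    single_chain = draws.n_chains < 2
    constant = [c for c in draws.columns
                if np.allclose(draws.values[:, :, draws.columns.index(c)].var(), 0.0)]
    live = [c for c in draws.columns if c not in constant]
    table = pd.DataFrame(index=draws.columns,
                         columns=["rhat", "ess_bulk", "ess_tail"], dtype=float)
    if live:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if not single_chain:
                rh = az.rhat(idata, var_names=live)
                table.loc[live, "rhat"] = [float(rh[c].item()) for c in live]
            eb = az.ess(idata, var_names=live, method="bulk")
            et = az.ess(idata, var_names=live, method="tail")
        table.loc[live, "ess_bulk"] = [float(eb[c].item()) for c in live]
        table.loc[live, "ess_tail"] = [float(et[c].item()) for c in live]
    if constant and not single_chain:
        # Degenerate (constant) parameters: chains agree exactly.
        table.loc[constant, "rhat"] = 1.0
    if single_chain:
        acceptable = draws.divergences == 0
        note = "single chain: R-hat undefined; verdict based on divergences only"
    else:
        max_rhat = float(np.nanmax(table["rhat"].to_numpy())) if len(table) else 1.0
        acceptable = max_rhat < rhat_threshold and draws.divergences == 0
        note = ""
    return DiagnosticsReport(table=table, divergences=draws.divergences,
                             acceptable=bool(acceptable), note=note)
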