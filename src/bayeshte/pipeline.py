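"""End-to-end orchestration: data in (or synthesized), missingness gate,
model fits, summaries, report bundle.

A :class:`RunConfig` describes one complete analysis run — where the patient
table comes from, which prior family to use, which analyses to run
(primary, subgroup-based heterogeneity, continuous interactions), the
sampler budget and the output directory.  :func:`run_analysis` executes the
stages in order, writing draw files, diagnostics, summary tables, figures
and a manifest.

Complete-case gate: an analysis proceeds only if every variable it uses has
under 5% missingness; otherwise the run aborts loudly — multiple imputation
is deliberately not implemented (the emulated trial never needed it), and
the error says so.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError, MissingnessGateError
from .models import (INTERACTION_VARIABLES, ModelSpec, diagnostics,
                     fit_continuous_interaction, fit_primary, fit_subgroup_hte)
from .priors import (PriorSpec, evidence_based_prior, illustrative_study_tables,
                     random_effects_meta, read_study_tables, sceptic_prior,
                     weakly_informative_prior, DEFAULT_SCEPTIC_SD)
from .reporting import (ReportBundle, render_conditional_effects,
                        render_posterior_plot, render_subgroup_densities)
from .subgroups import quintile_subgroups
from .summaries import (DEFAULT_RD_THRESHOLDS, DEFAULT_RR_THRESHOLDS,
                        effect_summary, interaction_summary, most_common_profile,
                        standardized_event_probs, subgroup_effect_table)
from .synthetic import GeneratorConfig, TrialDataset, generate_trial

__all__ = ["RunConfig", "missingness_gate", "run_analysis"]

MISSINGNESS_THRESHOLD = 0.05

#: Variables every outcome model needs.
_CORE_VARIABLES = ["dead_90d", "allocation", "copd", "haem", "site_id"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative description of one full analysis run."""

    input_csv: str | None = None  # external patient table; otherwise synthesize
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    prior: str = "weak"  # weak | evidence | sceptic
    sceptic_sd: float = DEFAULT_SCEPTIC_SD
    study_tables_csv: str | None = None  # basis of the evidence-based prior
    analyses: tuple[str, ...] = ("primary",)
    subgroup_variables: tuple[str, ...] = ("sofa", "pf_ratio", "lactate", "norepi_dose")
    interaction_variables: tuple[str, ...] = INTERACTION_VARIABLES
    chains: int = 4
    warmup: int = 5000
    draws: int = 5000
    seed: int = 0
    rr_thresholds: tuple[float, ...] = DEFAULT_RR_THRESHOLDS
    rd_thresholds: tuple[float, ...] = DEFAULT_RD_THRESHOLDS
    out_dir: str = "bayeshte_run"

    def __post_init__(self) -> None:
        if not self.analyses:
            raise ConfigurationError("at least one analysis must be requested")
        for a in self.analyses:
            if a not in ("primary", "subgroup", "interaction"):
                raise ConfigurationError(f"unknown analysis {a!r}")
        if self.prior not in ("weak", "evidence", "sceptic"):
            raise ConfigurationError(f"unknown prior label {self.prior!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "generator" in d and isinstance(d["generator"], dict):
            d["generator"] = GeneratorConfig(**d["generator"])
        for key in ("analyses", "subgroup_variables", "interaction_variables",
                    "rr_thresholds", "rd_thresholds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dict__") or hasattr(o, "__dataclass_fields__"):
                return asdict(o) if hasattr(o, "__dataclass_fields__") else vars(o)
            return str(o)
        d = asdict(self)
        d.pop("out_dir", None)  # analytically irrelevant to the run
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def resolve_prior(self) -> PriorSpec:
        if self.prior == "weak":
            return weakly_informative_prior()
        if self.prior == "sceptic":
            return sceptic_prior(self.sceptic_sd)
        tables = (read_study_tables(self.study_tables_csv)
                  if self.study_tables_csv else illustrative_study_tables())
        return evidence_based_prior(random_effects_meta(tables))


def missingness_gate(dataset: TrialDataset, analysis_variables: Sequence[str],
                     threshold: float = MISSINGNESS_THRESHOLD,
                     ) -> tuple[TrialDataset, dict]:
    """Complete-case gate for one analysis.

    Every variable the analysis uses must have a missing fraction strictly
    below ``threshold`` (5%); then incomplete rows are dropped and counts
    logged.  Otherwise the gate fails loudly: multiple imputation would be
    required and is out of scope here.
    """
    if not analysis_variables:
        raise InputError("analysis variable list must be non-empty")
    df = dataset.df
    fractions = {}
    for var in analysis_variables:
        if var not in df.columns:
            raise InputError(f"analysis variable {var!r} not in dataset")
        fractions[var] = float(df[var].isna().mean()) if len(df) else 0.0
    offenders = {v: f for v, f in fractions.items() if f >= threshold}
    if offenders:
        desc = ", ".join(f"{v}: {100 * f:.1f}%" for v, f in offenders.items())
        raise MissingnessGateError(
            f"missingness at or above {100 * threshold:.0f}% for {desc}; "
            "complete-case analysis not permitted — multiple imputation would "
            "be required, which this pipeline does not implement")
    keep = df[list(analysis_variables)].notna().all(axis=1) if len(df) else slice(None)
    kept = df.loc[keep]
    log = {"n_total": len(df), "n_complete": len(kept),
           "n_dropped": len(df) - len(kept), "missing_fractions": fractions}
    return TrialDataset(df=kept, config=dataset.config, seed=dataset.seed,
                        created=dataset.created), log


def _load_dataset(config: RunConfig) -> TrialDataset:
    if config.input_csv:
        return TrialDataset.from_csv(config.input_csv)
    gen = replace(config.generator, seed=config.generator.seed or config.seed)
    return generate_trial(gen)


def _spec(config: RunConfig, prior: PriorSpec, kind: str, seed: int) -> ModelSpec:
    return ModelSpec(kind=kind, prior=prior, chains=config.chains,
                     warmup=config.warmup, draws=config.draws, seed=seed)


def run_analysis(config: RunConfig) -> ReportBundle:
    """Execute every requested analysis stage and write the report bundle."""
    bundle = ReportBundle(out_dir=Path(config.out_dir))
    out = bundle.out_dir
    prior = config.resolve_prior()
    dataset = _load_dataset(config)
    seeds = np.random.SeedSequence(config.seed).generate_state(
        1 + len(config.subgroup_variables) + len(config.interaction_variables))
    seeds = [int(s % (2**31 - 1)) for s in seeds]
    gate_logs: dict[str, dict] = {}
    diag_flags: dict[str, bool] = {}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise type(exc)(f"[stage {name}] {exc}") from exc

    # Primary analysis also underlies the subgroup overlay figure.
    primary_rr = None
    need_primary = "primary" in config.analyses or "subgroup" in config.analyses
    if need_primary:
        gated, gate_logs["primary"] = _stage(
            "primary/gate", missingness_gate, dataset, _CORE_VARIABLES)
        draws = _stage("primary/fit", fit_primary, gated,
                       _spec(config, prior, "primary", seeds[0]))
        rep = diagnostics(draws)
        diag_flags["primary"] = rep.acceptable
        profile = most_common_profile(gated, draws)
        p0, p1 = standardized_event_probs(draws, profile)
        summ = effect_summary(p0, p1, config.rr_thresholds, config.rd_thresholds,
                              n_patients=gated.n)
        primary_rr = p1 / p0
        draws.to_csv(out / "primary_draws.csv")
        bundle.register("draw_files", "primary", out / "primary_draws.csv")
        rep.to_csv(out / "primary_diagnostics.csv")
        bundle.register("tables", "primary_diagnostics", out / "primary_diagnostics.csv")
        pd.DataFrame([summ.to_row()]).to_csv(out / "primary_summary.csv", index=False)
        bundle.register("tables", "primary_summary", out / "primary_summary.csv")
        if "primary" in config.analyses:
            render_posterior_plot(primary_rr, out / "primary_posterior.png", summary=summ)
            bundle.register("figures", "primary_posterior", out / "primary_posterior.png")

    if "subgroup" in config.analyses:
        per_scheme = {}
        for i, var in enumerate(config.subgroup_variables):
            name = f"subgroup_{var}"
            gated, gate_logs[name] = _stage(
                f"{name}/gate", missingness_gate, dataset, _CORE_VARIABLES + [var])
            scheme = _stage(f"{name}/scheme", quintile_subgroups,
                            gated.df[var], zero_mass_group=(var == "norepi_dose"),
                            variable=var)
            spec = _spec(config, prior, "subgroup", seeds[1 + i])
            if var == "pf_ratio":
                spec = replace(spec, adjust_open_system=True)
            draws = _stage(f"{name}/fit", fit_subgroup_hte, gated, scheme, spec)
            rep = diagnostics(draws)
            diag_flags[name] = rep.acceptable
            profile = most_common_profile(gated, draws)
            summaries, table = subgroup_effect_table(
                draws, profile, config.rr_thresholds, config.rd_thresholds)
            draws.to_csv(out / f"{name}_draws.csv")
            bundle.register("draw_files", name, out / f"{name}_draws.csv")
            rep.to_csv(out / f"{name}_diagnostics.csv")
            bundle.register("tables", f"{name}_diagnostics", out / f"{name}_diagnostics.csv")
            table.to_csv(out / f"{name}_summary.csv", index=False)
            bundle.register("tables", f"{name}_summary", out / f"{name}_summary.csv")
            scheme.to_csv(out / f"{name}_scheme.csv")
            bundle.register("tables", f"{name}_scheme", out / f"{name}_scheme.csv")
            rr_by_group = {}
            for g, s in enumerate(summaries):
                p0_g, p1_g = standardized_event_probs(draws, profile, subgroup=g)
                rr_by_group[s.label] = p1_g / p0_g
            per_scheme[var] = rr_by_group
        render_subgroup_densities(per_scheme, primary_rr,
                                  out / "subgroup_densities.png")
        bundle.register("figures", "subgroup_densities", out / "subgroup_densities.png")

    if "interaction" in config.analyses:
        inter_summaries = []
        offset = 1 + len(config.subgroup_variables)
        rows = []
        for i, var in enumerate(config.interaction_variables):
            name = f"interaction_{var}"
            gated, gate_logs[name] = _stage(
                f"{name}/gate", missingness_gate, dataset,
                _CORE_VARIABLES + [var] + (["open_system"] if var == "pf_ratio" else []))
            draws = _stage(f"{name}/fit", fit_continuous_interaction, gated, var,
                           _spec(config, prior, "interaction", seeds[offset + i]))
            rep = diagnostics(draws)
            diag_flags[name] = rep.acceptable
            profile = most_common_profile(gated, draws)
            x = gated.df[var].dropna()
            grid = np.linspace(float(x.min()), float(x.quantile(0.95)), 40)
            summ = _stage(f"{name}/summary", interaction_summary, draws, grid, profile)
            inter_summaries.append(summ)
            rows.append(summ.to_row())
            draws.to_csv(out / f"{name}_draws.csv")
            bundle.register("draw_files", name, out / f"{name}_draws.csv")
            rep.to_csv(out / f"{name}_diagnostics.csv")
            bundle.register("tables", f"{name}_diagnostics", out / f"{name}_diagnostics.csv")
            summ.curve.to_csv(out / f"{name}_curve.csv", index=False)
            bundle.register("tables", f"{name}_curve", out / f"{name}_curve.csv")
        pd.DataFrame(rows).to_csv(out / "interaction_summary.csv", index=False)
        bundle.register("tables", "interaction_summary", out / "interaction_summary.csv")
        render_conditional_effects(inter_summaries, out / "conditional_effects.png")
        bundle.register("figures", "conditional_effects", out / "conditional_effects.png")

    bundle.write_manifest(
        config_hash=config.config_hash(), seed=config.seed,
        extra={"prior": {"label": prior.label, "mean": prior.mean, "sd": prior.sd},
               "gate_logs": gate_logs,
               "diagnostics_acceptable": diag_flags})
    return bundle
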