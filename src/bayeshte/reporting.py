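"""Figure and table output: posterior distributions, subgroup densities,
conditional-effect curves, and a run manifest tying every file to its inputs.

Display convention: relative risks and odds ratios to two decimals,
percentages to one decimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import InputError
from .summaries import EffectSummary, InteractionSummary

__all__ = [
    "ReportBundle",
    "render_posterior_plot",
    "render_subgroup_densities",
    "render_conditional_effects",
]

_MIN_DRAWS = 100


@dataclass
class ReportBundle:
    """Output directory with the emitted files and a manifest."""

    out_dir: Path
    tables: dict[str, Path] = field(default_factory=dict)
    figures: dict[str, Path] = field(default_factory=dict)
    draw_files: dict[str, Path] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)

    def register(self, kind: str, name: str, path: Path) -> None:
        getattr(self, kind)[name] = Path(path)

    def write_manifest(self, config_hash: str = "", seed: int | None = None,
                       extra: Mapping | None = None) -> Path:
        files = {}
        for kind in ("tables", "figures", "draw_files"):
            for name, path in getattr(self, kind).items():
                digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
                files[f"{kind}/{name}"] = {"path": str(path), "sha256_16": digest}
        import arviz

        self.manifest = {
            "config_hash": config_hash,
            "seed": seed,
            "backend": f"bayeshte-nuts; arviz {arviz.__version__}; numpy {np.__version__}",
            "files": files,
            **(dict(extra) if extra else {}),
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))
        return path


def _check_draws(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < _MIN_DRAWS:
        raise InputError(f"need at least {_MIN_DRAWS} draws to render, got {x.size}")
    return x


def render_posterior_plot(rr_draws, path, summary: EffectSummary | None = None,
                          label: str = "RR") -> Path:
    """Two-panel posterior display: cumulative P(RR <= x) and the density with
    the median line and shaded 95% CrI."""
    rr = _check_draws(rr_draws)
    path = Path(path)
    lo, med, hi = np.percentile(rr, [2.5, 50.0, 97.5])
    if summary is not None:
        med, lo, hi = summary.rr

    fig, (ax_cdf, ax_pdf) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    xs = np.sort(rr)
    ax_cdf.step(xs, np.arange(1, rr.size + 1) / rr.size, where="post", lw=1.5)
    ax_cdf.axvline(1.0, color="grey", ls=":")
    ax_cdf.set_ylabel(f"P({label} ≤ x)")
    ax_cdf.set_title(f"Posterior {label}: median {med:.2f} "
                     f"(95% CrI {lo:.2f}–{hi:.2f})")

    if np.ptp(rr) < 1e-12:  # degenerate posterior: render a spike
        ax_pdf.axvline(float(rr[0]), color="C0", lw=2)
    else:
        counts, edges = np.histogram(rr, bins=80, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ax_pdf.plot(centers, counts, lw=1.5)
        in_cri = (centers >= lo) & (centers <= hi)
        ax_pdf.fill_between(centers[in_cri], counts[in_cri], alpha=0.35)
    ax_pdf.axvline(med, color="k", lw=1.5)
    ax_pdf.set_xlabel(label)
    ax_pdf.set_ylabel("posterior density")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_subgroup_densities(per_scheme: Mapping[str, Mapping[str, np.ndarray]],
                              overall_draws, path) -> Path:
    """One panel per subgrouping scheme: every subgroup's posterior RR density
    overlaid with the all-patients density from the primary analysis."""
    overall = _check_draws(overall_draws)
    path = Path(path)
    n_panels = len(per_scheme)
    if n_panels == 0:
        raise InputError("no subgroup schemes supplied")
    fig, axes = plt.subplots(n_panels, 1, figsize=(7, 3.2 * n_panels), squeeze=False)
    grid = np.linspace(min(overall.min(), 0.5), max(overall.max(), 1.6), 300)
    for ax, (scheme_name, groups) in zip(axes.ravel(), per_scheme.items()):
        for lbl, rr in groups.items():
            rr = _check_draws(rr)
            counts, edges = np.histogram(rr, bins=60, density=True)
            ax.plot(0.5 * (edges[:-1] + edges[1:]), counts, lw=1.0, label=str(lbl))
        counts, edges = np.histogram(overall, bins=60, density=True)
        ax.plot(0.5 * (edges[:-1] + edges[1:]), counts, "k--", lw=1.8,
                label="all patients")
        ax.axvline(1.0, color="grey", ls=":")
        ax.set_title(scheme_name)
        ax.set_xlim(grid[0], grid[-1])
        ax.legend(fontsize=7)
        ax.set_ylabel("density")
    axes.ravel()[-1].set_xlabel("RR")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def render_conditional_effects(summaries: Sequence[InteractionSummary], path,
                               x_limits: Mapping[str, tuple[float, float]] | None = None,
                               ) -> Path:
    """Conditional-effect panels: event probability vs the baseline variable by
    arm, annotated with the interaction OR, CrI and directional probabilities.

    ``x_limits`` optionally truncates a panel's x-range (e.g. to the central
    95% of the observed variable) without refitting.
    """
    if not summaries:
        raise InputError("no interaction summaries supplied")
    path = Path(path)
    n = len(summaries)
    fig, axes = plt.subplots(n, 1, figsize=(7, 3.2 * n), squeeze=False)
    for ax, s in zip(axes.ravel(), summaries):
        for arm, color in (("lower", "C0"), ("higher", "C1")):
            sub = s.curve[s.curve["arm"] == arm]
            ax.plot(sub["x"], sub["median"], color=color, label=f"{arm} target")
            ax.fill_between(sub["x"], sub["cri_low"], sub["cri_high"],
                            color=color, alpha=0.25)
        med, lo, hi = s.or_per_unit
        ax.set_title(
            f"{s.variable}: interaction OR {med:.2f} (95% CrI {lo:.2f}–{hi:.2f}); "
            f"P(OR<1) {100 * s.prob_below_1:.1f}%, P(OR>1) {100 * s.prob_above_1:.1f}%",
            fontsize=9)
        if x_limits and s.variable in x_limits:
            ax.set_xlim(*x_limits[s.variable])
        ax.set_ylabel("P(death by day 90)")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=7)
    axes.ravel()[-1].set_xlabel("baseline value")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
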