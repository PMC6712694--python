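"""Orchestrate the four-model comparison on one profile/outcome dataset.

Given per-participant intensity profiles (traditional 4-bin or 23-bin
spectrum description) and a single outcome, run: bivariate correlations,
multiple linear regression on raw minutes, multiple linear regression on
pivot-coordinate ilr data, and PLS multivariate pattern analysis on raw and
on clr-transformed data.  Also emit the correlation-structure diagnostics
(raw vs clr Pearson matrices and their distortion) that explain *why* the
approaches disagree.  Any model that fails — e.g. MLR on closed proportions,
which is singular by construction — is recorded with its reason and the rest
of the comparison proceeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coda import CLRTransform, ClosureReport, closure_correlation_report
from .healthscore import composite_score
from .patterns import (
    AssociationPattern,
    bivariate_correlations,
    fit_ilr_mlr,
    fit_mlr,
    fit_mpa,
)
from .simulate import SyntheticConfig, attach_panel, generate_spectrum_dataset

ALL_MODELS = ("bivariate", "mlr_raw", "mlr_ilr", "mpa_raw", "mpa_clr")

DEFAULT_CONFIG = {
    "description": "spectrum",  # traditional | spectrum
    "models": list(ALL_MODELS),
    "reps": 1000,  # Monte Carlo repetitions (CV and SR CIs)
    "holdout": 0.5,  # validation fraction per repetition
    "max_components": 10,
    "seed": 0,
    "zero_delta": None,  # zero replacement for log-ratio transforms
    "insulin_units": "pmol",
    "use_proportions": False,  # analyze proportions of wear time instead of min/day
    "wear_covariate": False,  # add wear time to the raw MLR
    "outcome": "direct",  # direct | panel (recompute composite from a panel)
    "n_participants": 841,
    "noise_sd": 4.5,
}

# offsets fanning one master seed out to the stages, so each stage is
# independently reproducible
_SEED_OFFSETS = {"generate": 11, "mpa_raw": 23, "mpa_clr": 37, "panel": 53}


@dataclass
class ComparisonReport:
    """Everything one comparison run produces."""

    patterns: dict  # model_tag -> AssociationPattern
    failures: dict  # model_tag -> reason string
    correlation_report: ClosureReport
    provenance: dict = field(default_factory=dict)

    def combined_table(self) -> pd.DataFrame:
        frames = []
        for tag, pat in self.patterns.items():
            t = pat.table.copy()
            t["model_tag"] = tag
            t["model_r2"] = pat.model_r2
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) * 1009 + _SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


def run_comparison(profiles: pd.DataFrame, outcome, config: dict | None = None) -> ComparisonReport:
    """Run every requested model on one profiles/outcome pair.

    ``profiles`` has an ``id`` column, one column per intensity bin, and
    optionally ``wear_minutes``; ``outcome`` is aligned by position.
    """
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    drop = {"id", "wear_minutes", "n_valid_days", "valid", "overall_cpm", "outcome"}
    bin_cols = [c for c in profiles.columns if c not in drop and not c.startswith("truth_")]
    X = profiles[bin_cols].to_numpy(dtype=float)
    y = np.asarray(outcome, dtype=float).ravel()
    if cfg["use_proportions"]:
        X = X / X.sum(axis=1, keepdims=True)
    clr_X = CLRTransform(delta=cfg["zero_delta"]).fit(X).transform(X)
    patterns: dict = {}
    failures: dict = {}
    seed = cfg["seed"]
    for tag in cfg["models"]:
        try:
            if tag == "bivariate":
                patterns[tag] = bivariate_correlations(X, y, names=bin_cols)
            elif tag == "mlr_raw":
                Xr, names = X, list(bin_cols)
                if cfg["wear_covariate"] and "wear_minutes" in profiles:
                    Xr = np.column_stack([X, profiles["wear_minutes"].to_numpy()])
                    names = names + ["wear_minutes"]
                pat = fit_mlr(Xr, y, names=names)
                pat.table = pat.table[pat.table["bin"].isin(bin_cols)].reset_index(drop=True)
                patterns[tag] = pat
            elif tag == "mlr_ilr":
                patterns[tag] = fit_ilr_mlr(X, y, names=bin_cols, delta=cfg["zero_delta"])
            elif tag == "mpa_raw":
                pat, _ = fit_mpa(
                    X,
                    y,
                    names=bin_cols,
                    tag=tag,
                    reps=cfg["reps"],
                    holdout=cfg["holdout"],
                    max_components=cfg["max_components"],
                    seed=_stage_seed(seed, "mpa_raw"),
                )
                patterns[tag] = pat
            elif tag == "mpa_clr":
                pat, _ = fit_mpa(
                    clr_X,
                    y,
                    names=bin_cols,
                    tag=tag,
                    reps=cfg["reps"],
                    holdout=cfg["holdout"],
                    max_components=cfg["max_components"],
                    seed=_stage_seed(seed, "mpa_clr"),
                )
                patterns[tag] = pat
            else:
                failures[tag] = f"unknown model tag {tag!r}"
        except Exception as exc:  # record and continue with the other models
            failures[tag] = f"{type(exc).__name__}: {exc}"
    corr = closure_correlation_report(X, clr_X, names=bin_cols)
    return ComparisonReport(
        patterns=patterns,
        failures=failures,
        correlation_report=corr,
        provenance={"config": cfg, "software_version": __version__},
    )


def render_report(report: ComparisonReport, out_dir, plots: bool = False) -> dict:
    """Write the report surfaces: per-pattern CSVs, combined CSV, summary text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for tag, pat in report.patterns.items():
        p = out / f"pattern_{tag}.csv"
        pat.table.assign(model_tag=tag, model_r2=pat.model_r2).to_csv(p, index=False)
        paths[tag] = p
    combined = out / "patterns_combined.csv"
    report.combined_table().to_csv(combined, index=False)
    paths["combined"] = combined
    report.correlation_report.corr_raw.to_csv(out / "correlations_raw.csv")
    report.correlation_report.corr_transformed.to_csv(out / "correlations_clr.csv")
    lines = [f"actipattern comparison (version {report.provenance.get('software_version')})"]
    for tag, pat in report.patterns.items():
        lines.append(
            f"  {tag}: R2={pat.model_r2:.4f} Q2={pat.cv_q2:.4f} bins={len(pat.table)}"
        )
    for tag, reason in report.failures.items():
        lines.append(f"  {tag}: FAILED ({reason})")
    cr = report.correlation_report
    lines.append(
        f"  clr distortion: mean |delta r| = {cr.mean_abs_change:.4f}, "
        f"sign flips = {cr.n_sign_flips}"
    )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    paths["summary"] = out / "summary.txt"
    if plots:
        paths.update(_render_plots(report, out))
    return paths


def _render_plots(report: ComparisonReport, out: Path) -> dict:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = {}
    for tag, pat in report.patterns.items():
        fig, ax = plt.subplots(figsize=(8, 3.2))
        x = np.arange(len(pat.table))
        est = pat.table["estimate"]
        ax.errorbar(
            x,
            est,
            yerr=[est - pat.table["ci_low"], pat.table["ci_high"] - est],
            fmt="o-",
            capsize=2,
        )
        ax.axhline(0, color="grey", lw=0.8)
        ax.set_xticks(x)
        ax.set_xticklabels(pat.table["bin"], rotation=90, fontsize=6)
        ax.set_title(f"{tag} (R2={pat.model_r2:.3f})")
        ax.set_ylabel("estimate (95% CI)")
        fig.tight_layout()
        p = out / f"pattern_{tag}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"plot_{tag}"] = p
    return paths


def end_to_end(config: dict | None = None) -> ComparisonReport:
    """Simulate a cohort, derive the outcome, and run the full comparison."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    from .actigraphy import get_scheme

    gen_cfg = SyntheticConfig(
        n_participants=int(cfg["n_participants"]),
        bin_scheme=get_scheme(cfg["description"]),
        noise_sd=float(cfg["noise_sd"]),
        seed=_stage_seed(cfg["seed"], "generate"),
    )
    data = generate_spectrum_dataset(gen_cfg)
    if cfg["outcome"] == "panel":
        data = attach_panel(data, seed=_stage_seed(cfg["seed"], "panel"))
        scores = composite_score(data.panel, insulin_units=cfg["insulin_units"])
        y = scores["composite"].to_numpy()
    else:
        y = data.outcome.to_numpy()
    report = run_comparison(data.profiles, y, cfg)
    report.provenance["truth"] = {
        "effect_vector": data.truth["effect_vector"].tolist(),
        "generator_seed": data.truth["seed"],
    }
    return report
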