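"""Pipeline orchestration and report bundles.

``run_pipeline`` executes the enabled analysis stages in dependency order
on supplied (or synthetic) inputs and returns a bundle of tables shaped
like the study's outputs: a conversion table, a growth model-selection
table, a cross-region comparison table, maturity estimates, a survival
posterior summary and a mortality comparison.  Numeric outputs are pure
functions of the configuration, so re-running an identical config
reproduces them byte-for-byte; an optional output directory receives the
bundle as JSON plus plain-text tables and figure files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import growth as gr
from . import maturity as mat
from . import mortality as mort
from . import simulate as sim
from . import survival as surv
from . import vbgf

__all__ = ["RunConfig", "run_pipeline", "DEFAULT_GROWTH_LADDER"]

#: Stepwise free-parameter ladder for growth model selection: measurement
#: error only; + growth variability; + error mean; + outliers; + seasonality.
DEFAULT_GROWTH_LADDER: tuple[tuple[str, ...], ...] = (
    ("g_alpha", "g_beta", "s"),
    ("g_alpha", "g_beta", "nu", "s"),
    ("g_alpha", "g_beta", "nu", "s", "m"),
    ("g_alpha", "g_beta", "nu", "s", "m", "p"),
    ("g_alpha", "g_beta", "nu", "s", "m", "p", "u", "w"),
)

_ALL_STAGES = ("growth", "conversions", "maturity", "survival", "mortality", "comparison")


@dataclass
class RunConfig:
    """What to run, on what inputs, with which seeds."""

    seed: int
    stages: tuple[str, ...] = _ALL_STAGES
    increments: object | None = None  # IncrementDataset; default synthetic stand-in
    maturity_obs: Sequence | None = None
    lengths: pd.DataFrame | None = None
    histories: object | None = None  # CaptureHistoryMatrix
    js: surv.JSModelConfig | None = None
    growth_ladder: tuple[tuple[str, ...], ...] = DEFAULT_GROWTH_LADDER
    bootstrap_reps: int = 10_000
    tmax_source: str = "printed"  # "printed" (18.06 yr) or "formula" (5 ln2 / k)
    out_dir: str | Path | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(_ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if "survival" in self.stages and self.js is None:
            raise ValueError("survival stage enabled but no JSModelConfig (with seed) given")
        if self.tmax_source not in ("printed", "formula"):
            raise ValueError("tmax_source must be 'printed' or 'formula'")
        if "mortality" in self.stages and "growth" not in self.stages:
            raise ValueError("mortality stage needs the growth stage for longevity")


def _fingerprint(cfg: RunConfig) -> str:
    parts = [
        str(cfg.seed),
        ",".join(cfg.stages),
        ";".join("+".join(f) for f in cfg.growth_ladder),
        str(cfg.bootstrap_reps),
        cfg.tmax_source,
    ]
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the enabled stages and return (and optionally write) the bundle.

    A stage failure does not abort the rest: the bundle is marked partial
    and the failing stage's diagnostics are recorded under ``failures``.
    """
    truth = sim.SyntheticTruth(seed=cfg.seed)
    bundle: dict = {
        "provenance": {
            "config_hash": _fingerprint(cfg),
            "seed": cfg.seed,
            "stages": list(cfg.stages),
            "synthetic_inputs": {
                "increments": cfg.increments is None,
                "maturity": cfg.maturity_obs is None,
                "lengths": cfg.lengths is None,
                "histories": cfg.histories is None,
            },
        },
        "tables": {},
        "fits": {},
        "failures": {},
        "partial": False,
    }

    def guard(stage, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - stage isolation is the contract
            bundle["failures"][stage] = f"{type(exc).__name__}: {exc}"
            bundle["partial"] = True

    best_fit: gr.FrancisFit | None = None

    def do_growth():
        nonlocal best_fit
        ds = cfg.increments if cfg.increments is not None else sim.synthetic_s1_table()
        fits = [
            gr.fit(ds, free=free, seed=cfg.seed, n_starts=3) for free in cfg.growth_ladder
        ]
        sel = gr.compare_models(fits)
        best_fit = fits[sel["best_index"]]
        rows = []
        for i, f in enumerate(fits):
            row = {"model": i + 1, "loglik": f.loglik, "aic": f.aic}
            for name in gr.PARAM_NAMES:
                row[name] = getattr(f.params, name)
                row[f"se_{name}"] = f.se.get(name, np.nan)
            row["tl_inf"] = f.vbgf.l_inf
            row["k"] = f.vbgf.k
            row["best"] = i == sel["best_index"]
            rows.append(row)
        bundle["tables"]["growth_models"] = pd.DataFrame(rows)
        bundle["fits"]["growth"] = best_fit
        bundle["fits"]["growth_selection"] = sel
        bundle["fits"]["growth_diagnostics"] = {
            k: v
            for k, v in gr.residual_diagnostics(best_fit).items()
            if k.startswith("rho_")
        }

    def do_conversions():
        lengths = (
            cfg.lengths
            if cfg.lengths is not None
            else sim.simulate_length_table(truth, 1392, seed=cfg.seed + 1)
        )
        res = mat.fit_conversions(lengths, compare_sex="sex" in lengths.columns)
        bundle["fits"]["conversions"] = res["models"]
        bundle["tables"]["conversions"] = pd.DataFrame(
            [
                {
                    "x": m.from_measure,
                    "y": m.to_measure,
                    "b0": m.b0,
                    "b1": m.b1,
                    "se_b0": m.se_b0,
                    "se_b1": m.se_b1,
                    "r2": m.r2,
                    "df": m.df,
                }
                for m in res["models"].values()
            ]
        )
        if res["aic_table"] is not None:
            bundle["tables"]["conversions_sex_aic"] = res["aic_table"]

    def do_maturity():
        obs = (
            cfg.maturity_obs
            if cfg.maturity_obs is not None
            else sim.simulate_maturity(truth, 429, seed=cfg.seed + 2)
        )
        fit = mat.fit_ogive(obs, bootstrap_reps=cfg.bootstrap_reps, seed=cfg.seed + 3)
        tl_max = max(o.tl for o in obs)
        bundle["fits"]["maturity"] = fit
        bundle["tables"]["maturity"] = pd.DataFrame(
            [
                {
                    "estimate": "L50 (clasper ogive)",
                    "value": fit.l50,
                    "ci2.5": fit.ci95[0],
                    "ci97.5": fit.ci95[1],
                },
                {
                    "estimate": "TL_m from max length",
                    "value": mat.maturity_from_lmax(tl_max),
                    "ci2.5": np.nan,
                    "ci97.5": np.nan,
                },
            ]
        )

    def do_survival():
        chm = cfg.histories
        if chm is None:
            chm, _ = sim.simulate_capture_histories(truth, seed=cfg.seed + 4)
        post = surv.fit_js(chm, cfg.js)
        bundle["fits"]["survival"] = post
        bundle["tables"]["survival"] = post.summary.reset_index()

    def do_mortality():
        if best_fit is None:
            raise RuntimeError("growth stage did not produce a fit")
        k = best_fit.vbgf.k
        tmax = vbgf.PRINTED_TMAX if cfg.tmax_source == "printed" else vbgf.longevity(k)
        indirect = [
            ("teleost", mort.hoenig_z(tmax, mort.TELEOST)),
            ("cetacean", mort.hoenig_z(tmax, mort.CETACEAN)),
        ]
        post = bundle["fits"].get("survival")
        phi = post.mean("phi") if post is not None else 0.74
        table = mort.compare_mortality(phi, indirect)
        table.attrs["t_max_years"] = tmax
        table.attrs["t_max_source"] = cfg.tmax_source
        bundle["tables"]["mortality"] = table

    def do_comparison():
        entries = vbgf.load_study_table()
        res = vbgf.comparison_table(entries, conversions=mat.study_conversions())
        bundle["tables"]["growth_comparison"] = res["table"]
        bundle["fits"]["comparison_curves"] = res["curves"]

    stage_order = [
        ("growth", do_growth),
        ("conversions", do_conversions),
        ("maturity", do_maturity),
        ("survival", do_survival),
        ("mortality", do_mortality),
        ("comparison", do_comparison),
    ]
    for name, fn in stage_order:
        if name in cfg.stages:
            guard(name, fn)

    if cfg.out_dir is not None:
        _write_bundle(bundle, cfg)
    return bundle


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="records", double_precision=10))
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_bundle(bundle: dict, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": bundle["provenance"],
        "partial": bundle["partial"],
        "failures": bundle["failures"],
        "tables": {k: _jsonable(v) for k, v in bundle["tables"].items()},
    }
    (out / "results.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    for name, table in bundle["tables"].items():
        (out / f"{name}.txt").write_text(table.to_string(index=False, float_format="%.4f") + "\n")
    if cfg.make_plots:
        _write_plots(bundle, out)


def _write_plots(bundle: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fit = bundle["fits"].get("growth")
    if fit is not None:
        fig, axes = plt.subplots(1, 2, figsize=(9, 4))
        axes[0].scatter(fit.expected, fit.residuals, s=12)
        axes[0].set_xlabel("predicted growth (cm)")
        axes[0].set_ylabel("residual (cm)")
        axes[1].scatter(fit.release_tl, fit.residuals, s=12)
        axes[1].set_xlabel("length at release (cm)")
        fig.tight_layout()
        fig.savefig(out / "fig_growth_residuals.svg")
        plt.close(fig)
    mfit = bundle["fits"].get("maturity")
    if mfit is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        tl = np.linspace(80, 180, 200)
        ax.plot(tl, mfit.proportion_mature(tl))
        ax.axvline(mfit.l50, ls="--", color="grey")
        ax.set_xlabel("total length (cm)")
        ax.set_ylabel("P(mature)")
        fig.tight_layout()
        fig.savefig(out / "fig_maturity_ogive.svg")
        plt.close(fig)
    curves = bundle["fits"].get("comparison_curves")
    if curves:
        fig, ax = plt.subplots(figsize=(6, 4))
        for loc, (ages, lengths) in curves.items():
            ax.plot(ages, lengths, label=loc)
        ax.set_xlabel("age (yr)")
        ax.set_ylabel("total length (cm)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "fig_growth_curves.svg")
        plt.close(fig)
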