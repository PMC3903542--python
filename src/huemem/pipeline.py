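"""Simulate -> fit -> analyze -> report, reproducibly.

This module strings the synthetic observer, the two-phase experiment
engine, the psychometric fits, and the independence analysis into one
seeded pipeline.  Every stage is a pure function of its inputs and the
seed, so a full run regenerates byte-identically, and trial counts are
audited so no cell is silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import experiment, io, psychometric
from .exceptions import (
    EmptyCellError,
    ExtrapolationError,
    HuememError,
    InvalidParameterError,
    NonIdentifiableError,
)
from .experiment import CONDITIONS, Condition
from .independence import (
    IndependenceResult,
    MatchSet,
    central_tendency_slope,
    summarize_independence,
)
from .observer import BayesianObserver, ObserverParams, params_for_block
from .psychometric import CellKey, bias, fit_pmf, pool_and_bin, threshold

__all__ = [
    "PipelineConfig",
    "AnalysisResult",
    "generate_dataset",
    "simulate",
    "analyze",
    "write_analysis",
    "load_analysis",
    "report",
    "run",
]

logger = logging.getLogger(__name__)

BASELINE = "baseline"
CONSTANCY = "constancy"

#: (variant label, memory condition, joint condition)
_VARIANTS = (
    ("blank", "memory", "joint"),
    ("distractors", "memory_distractors", "joint_distractors"),
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one synthetic experiment.

    The defaults are the standard study design: three similar reference
    hues on the equiluminant circle (yellowish-green to bluish-green), six
    blocked conditions, four 20-trial staircases per cell, and five MOCS
    levels repeated 10 times, with an optional range-adjusted second MOCS
    pass.
    """

    observer: ObserverParams = field(default_factory=ObserverParams)
    reference_hues: tuple[float, ...] = (2.9, 3.2, 3.5)
    conditions: tuple[str, ...] = CONDITIONS
    trials_per_staircase: int = 20
    staircase_final_step: float = 0.06
    staircase_initial_factor: float = 3.0
    staircase_start_offset: float = 0.3
    mocs_levels: int = 5
    mocs_repetitions: int = 10
    mocs_second_pass: bool = True
    distractor_sd: float = 0.067
    distractor_offset: float = 0.2
    update_priors_per_block: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise InvalidParameterError("design must name at least one condition")
        for name in self.conditions:
            Condition.blocks_for(name)  # validates the name
        if len(self.reference_hues) != 3:
            raise InvalidParameterError("design requires exactly three reference hues")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_hues"] = list(self.reference_hues)
        d["conditions"] = list(self.conditions)
        return d

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        observer = data.pop("observer", {})
        if not isinstance(observer, ObserverParams):
            observer = ObserverParams(**observer)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("reference_hues", "conditions"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(observer=observer, **data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _fallback_levels(config: PipelineConfig, reference_hue: float) -> np.ndarray:
    off = config.staircase_start_offset
    return reference_hue + np.linspace(-off, off, config.mocs_levels)


def _staircase_levels(
    config: PipelineConfig, trials: pd.DataFrame
) -> dict[tuple[float, str], np.ndarray]:
    """Pick MOCS levels per cell from fits to the staircase-phase data."""
    levels: dict[tuple[float, str], np.ndarray] = {}
    for cell, binned in pool_and_bin(trials).items():
        key = (cell.reference_hue, cell.reference_background)
        try:
            fit = fit_pmf(binned)
            levels[key] = experiment.select_mocs_levels(fit, config.mocs_levels)
        except (NonIdentifiableError, InvalidParameterError):
            logger.warning("staircase fit failed for %s; using default level span", cell)
            levels[key] = _fallback_levels(config, cell.reference_hue)
    return levels


def _simulate_block(
    config: PipelineConfig,
    block: Condition,
    seed_seq: np.random.SeedSequence,
) -> pd.DataFrame:
    seed_label = int(seed_seq.generate_state(1)[0] % np.int64(2**31))
    rng = np.random.default_rng(seed_seq)
    params = config.observer
    if config.update_priors_per_block:
        params = params_for_block(
            params,
            block.block_background,
            config.reference_hues,
            distractors=block.distractors == "present",
            distractor_offset=config.distractor_offset,
        )
    observer = BayesianObserver(params)
    common = dict(
        distractor_sd=config.distractor_sd,
        distractor_offset=config.distractor_offset,
        seed_label=seed_label,
    )

    stair = experiment.run_staircase_block(
        observer,
        block,
        config.reference_hues,
        rng,
        trials_per_staircase=config.trials_per_staircase,
        final_step=config.staircase_final_step,
        initial_factor=config.staircase_initial_factor,
        start_offset=config.staircase_start_offset,
        **common,
    )
    levels = _staircase_levels(config, stair)
    frames = [stair]
    mocs1 = experiment.run_mocs_block(
        observer, block, levels, config.mocs_repetitions, rng,
        trial_index_start=len(stair), **common,
    )
    frames.append(mocs1)

    if config.mocs_second_pass:
        # a second MOCS run is always collected; its range is re-derived from
        # the pooled data only for cells whose extreme levels failed to pin
        # down the tails
        pooled = pd.concat(frames, ignore_index=True)
        mocs_binned = pool_and_bin(mocs1)
        pooled_binned = pool_and_bin(pooled)
        second: dict[tuple[float, str], np.ndarray] = dict(levels)
        for cell, binned in mocs_binned.items():
            if experiment.mocs_needs_adjustment(
                binned.test_hues, binned.n_trials, binned.n_test_bluer
            ):
                key = (cell.reference_hue, cell.reference_background)
                try:
                    refit = fit_pmf(pooled_binned[cell])
                    second[key] = experiment.select_mocs_levels(refit, config.mocs_levels)
                except (NonIdentifiableError, InvalidParameterError):
                    second[key] = _fallback_levels(config, cell.reference_hue)
        frames.append(
            experiment.run_mocs_block(
                observer, block, second, config.mocs_repetitions, rng,
                trial_index_start=len(stair) + len(mocs1), **common,
            )
        )
    return pd.concat(frames, ignore_index=True)


def _simulate_condition(
    config: PipelineConfig, name: str, seed_seq: np.random.SeedSequence
) -> pd.DataFrame:
    blocks = Condition.blocks_for(name)
    children = seed_seq.spawn(len(blocks))
    frames = [_simulate_block(config, b, s) for b, s in zip(blocks, children)]
    table = pd.concat(frames, ignore_index=True)
    table["trial_index"] = np.arange(len(table))
    return table


def generate_dataset(
    params: ObserverParams,
    design: PipelineConfig | Mapping | None,
    seed: int,
) -> pd.DataFrame:
    """Generate a complete trial table for one synthetic observer.

    ``design`` is a :class:`PipelineConfig` (or mapping of its fields, or
    None for the default design); its ``observer`` and ``seed`` fields are
    overridden by ``params`` and ``seed``.  Deterministic given the seed.
    """
    if design is None:
        design = PipelineConfig()
    elif not isinstance(design, PipelineConfig):
        design = PipelineConfig.from_dict(design)
    config = dataclasses.replace(design, observer=params, seed=int(seed))
    tables = simulate(config)
    return pd.concat(tables.values(), ignore_index=True)


def simulate(config: PipelineConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Run every condition in the design; optionally write tables to disk.

    Returns ``{condition name: trial table}``.  With ``outdir`` set, one
    CSV per condition plus a ``metadata.json`` sidecar (config, seeds, row
    counts, schema version) are written.
    """
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(len(config.conditions))
    tables = {
        name: _simulate_condition(config, name, child)
        for name, child in zip(config.conditions, children)
    }
    for name, table in tables.items():
        logger.info("simulated %-20s %5d trials", name, len(table))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            io.write_trials(table, outdir / f"trials_{name}.csv")
        meta = {
            "schema_version": io.SCHEMA_VERSION,
            "config": config.to_dict(),
            "row_counts": {name: len(t) for name, t in tables.items()},
            "block_seeds": {
                name: sorted(map(int, t["seed"].unique())) for name, t in tables.items()
            },
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return tables


# ---------------------------------------------------------------------------
# Analysis
# ---------------------------------------------------------------------------


@dataclass
class AnalysisResult:
    """Fits, biases, and independence summaries for one dataset."""

    fits: pd.DataFrame
    biases: pd.DataFrame
    independence: dict[str, IndependenceResult]
    slopes: pd.DataFrame
    failures: list[dict]
    n_trials: int
    threshold_ratios: dict[str, float]

    def summary_dict(self) -> dict:
        out = {
            "n_trials": int(self.n_trials),
            "n_cells_fit": int(len(self.fits)),
            "n_cells_failed": int(len(self.failures)),
            "failures": self.failures,
            "threshold_ratios": self.threshold_ratios,
            "central_tendency_slopes": self.slopes.to_dict(orient="records"),
            "independence": {
                variant: {
                    "mean_non_additivity_index": res.mean_ni,
                    "sign_test_p_subadditive": res.sign_test_p,
                    "measured_over_predicted_ratio": res.subadditivity_ratio,
                    "n_cells": res.n_cells,
                }
                for variant, res in self.independence.items()
            },
        }
        return out


def _mean_threshold(fits: pd.DataFrame, conditions: tuple[str, ...]) -> float:
    sel = fits[fits["condition"].isin(conditions)]
    return float(sel["threshold"].mean()) if len(sel) else float("nan")


def analyze(trials) -> AnalysisResult:
    """Fit every cell, compute baseline-subtracted biases, test additivity.

    ``trials`` is one concatenated trial table or a mapping of condition
    name to table.  Cells whose fits fail are listed in ``failures`` (with
    their trial counts) rather than silently dropped, and the trial-count
    audit ``n_trials == sum(cell n) `` is enforced.
    """
    if isinstance(trials, Mapping):
        trials = pd.concat(trials.values(), ignore_index=True)
    if trials.empty:
        raise EmptyCellError("no trials to analyze")

    cells = pool_and_bin(trials)
    fits: dict[CellKey, psychometric.PmfFit] = {}
    failures: list[dict] = []
    for cell, binned in cells.items():
        try:
            fits[cell] = fit_pmf(binned)
        except (NonIdentifiableError, InvalidParameterError) as exc:
            failures.append(
                {"cell": list(cell), "n": binned.n_total, "error": str(exc)}
            )

    accounted = sum(f.n_total for f in fits.values()) + sum(f["n"] for f in failures)
    if accounted != len(trials):
        raise HuememError(
            f"trial-count audit failed: {len(trials)} in, {accounted} accounted for"
        )

    fit_rows = [
        {
            "condition": c.condition,
            "reference_hue": c.reference_hue,
            "reference_background": c.reference_background,
            "location": f.location,
            "spread": f.spread,
            "lapse": f.lapse,
            "threshold": threshold(f),
            "log_likelihood": f.log_likelihood,
            "n": f.n_total,
            "converged": f.converged,
        }
        for c, f in fits.items()
    ]
    fits_df = pd.DataFrame(fit_rows).sort_values(
        ["condition", "reference_background", "reference_hue"], ignore_index=True
    )

    bias_rows = []
    for cell, f in fits.items():
        base_cell = CellKey(BASELINE, cell.reference_hue, cell.reference_background)
        if base_cell not in fits:
            continue
        bias_rows.append(
            {
                "condition": cell.condition,
                "reference_hue": cell.reference_hue,
                "reference_background": cell.reference_background,
                "bias": bias(f, fits[base_cell]),
                "threshold": threshold(f),
                "n": f.n_total,
            }
        )
    biases_df = pd.DataFrame(bias_rows).sort_values(
        ["condition", "reference_background", "reference_hue"], ignore_index=True
    )

    def _cond_bias(condition: str, background: str) -> pd.DataFrame | None:
        sel = biases_df[
            (biases_df["condition"] == condition)
            & (biases_df["reference_background"] == background)
        ].sort_values("reference_hue")
        return sel if len(sel) >= 2 else None

    independence: dict[str, IndependenceResult] = {}
    slope_rows = []
    backgrounds = sorted(biases_df["reference_background"].unique()) if len(biases_df) else []
    for variant, memory_name, joint_name in _VARIANTS:
        match_sets = []
        for background in backgrounds:
            mem = _cond_bias(memory_name, background)
            con = _cond_bias(CONSTANCY, background)
            joi = _cond_bias(joint_name, background)
            if mem is None or con is None or joi is None:
                continue
            r = mem["reference_hue"].to_numpy()
            if not (
                np.array_equal(r, con["reference_hue"].to_numpy())
                and np.array_equal(r, joi["reference_hue"].to_numpy())
            ):
                continue
            match_sets.append(
                MatchSet(
                    reference_hues=r,
                    memory_matches=r + mem["bias"].to_numpy(),
                    constancy_matches=r + con["bias"].to_numpy(),
                    joint_matches=r + joi["bias"].to_numpy(),
                    reference_background=background,
                )
            )
            slope_rows.append(
                {
                    "variant": variant,
                    "reference_background": background,
                    "slope": central_tendency_slope(mem["bias"].to_numpy(), r),
                }
            )
        if match_sets:
            try:
                independence[variant] = summarize_independence(match_sets)
            except ExtrapolationError as exc:
                logger.warning("independence analysis (%s) skipped: %s", variant, exc)
                failures.append({"cell": [variant, "independence"], "n": 0, "error": str(exc)})

    slopes_df = pd.DataFrame(slope_rows, columns=["variant", "reference_background", "slope"])

    threshold_ratios = {}
    if len(fits_df):
        no_mem = _mean_threshold(fits_df, (BASELINE, CONSTANCY))
        mem = _mean_threshold(fits_df, ("memory", "joint"))
        sym = _mean_threshold(fits_df, (BASELINE, "memory"))
        asym = _mean_threshold(fits_df, (CONSTANCY, "joint"))
        threshold_ratios = {
            "memory_over_no_memory": mem / no_mem,
            "constancy_over_no_constancy": asym / sym,
        }

    return AnalysisResult(
        fits=fits_df,
        biases=biases_df,
        independence=independence,
        slopes=slopes_df,
        failures=failures,
        n_trials=len(trials),
        threshold_ratios=threshold_ratios,
    )


def write_analysis(result: AnalysisResult, outdir) -> None:
    """Write fit/bias/independence tables and a JSON summary to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.fits.to_csv(outdir / "fits.csv", index=False, float_format="%.17g")
    result.biases.to_csv(outdir / "biases.csv", index=False, float_format="%.17g")
    tables = [
        res.table.assign(variant=variant)
        for variant, res in result.independence.items()
    ]
    ind = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "reference_background", "reference_hue", "measured_joint_bias",
                "predicted_joint_bias", "non_additivity_index", "variant",
            ]
        )
    )
    ind.to_csv(outdir / "independence.csv", index=False, float_format="%.17g")
    result.slopes.to_csv(outdir / "slopes.csv", index=False, float_format="%.17g")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary_dict(), indent=2, sort_keys=True)
    )


def load_analysis(outdir) -> AnalysisResult:
    """Rebuild an :class:`AnalysisResult` from :func:`write_analysis` output."""
    outdir = Path(outdir)
    fits = pd.read_csv(outdir / "fits.csv")
    biases = pd.read_csv(outdir / "biases.csv")
    ind = pd.read_csv(outdir / "independence.csv")
    slopes = pd.read_csv(outdir / "slopes.csv")
    summary = json.loads((outdir / "summary.json").read_text())
    independence = {}
    for variant, s in summary.get("independence", {}).items():
        table = ind[ind["variant"] == variant].drop(columns=["variant"]).reset_index(drop=True)
        independence[variant] = IndependenceResult(
            table=table,
            mean_ni=s["mean_non_additivity_index"],
            sign_test_p=s["sign_test_p_subadditive"],
            subadditivity_ratio=s["measured_over_predicted_ratio"],
            n_cells=s["n_cells"],
        )
    return AnalysisResult(
        fits=fits,
        biases=biases,
        independence=independence,
        slopes=slopes,
        failures=summary.get("failures", []),
        n_trials=summary.get("n_trials", int(fits["n"].sum()) if len(fits) else 0),
        threshold_ratios=summary.get("threshold_ratios", {}),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

_CONDITION_COLORS = {
    "baseline": "black",
    "constancy": "tab:green",
    "memory": "tab:blue",
    "joint": "tab:red",
    "memory_distractors": "tab:cyan",
    "joint_distractors": "tab:orange",
}


def _plot_biases(result: AnalysisResult, path) -> None:
    import matplotlib.pyplot as plt

    backgrounds = sorted(result.biases["reference_background"].unique())
    fig, axes = plt.subplots(1, max(len(backgrounds), 1), figsize=(9, 4), sharey=True)
    axes = np.atleast_1d(axes)
    for ax, background in zip(axes, backgrounds):
        sel = result.biases[result.biases["reference_background"] == background]
        for condition, grp in sel.groupby("condition"):
            grp = grp.sort_values("reference_hue")
            ax.plot(
                grp["reference_hue"], grp["bias"], "o-",
                color=_CONDITION_COLORS.get(condition, "gray"), label=condition,
            )
        for variant, res in result.independence.items():
            tab = res.table[res.table["reference_background"] == background]
            if len(tab):
                tab = tab.sort_values("reference_hue")
                ax.plot(
                    tab["reference_hue"], tab["predicted_joint_bias"], "--",
                    color="pink", lw=3, alpha=0.9,
                    label=f"predicted joint ({variant})",
                )
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_title(f"reference on {background}")
        ax.set_xlabel("reference hue (rad)")
    axes[0].set_ylabel("bias re baseline (rad, + = bluer)")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_additivity(result: AnalysisResult, path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    nis = []
    for variant, res in result.independence.items():
        ax.scatter(
            res.table["predicted_joint_bias"], res.table["measured_joint_bias"],
            label=variant, alpha=0.8,
        )
        nis.extend(res.table["non_additivity_index"].tolist())
    lim = 1.05 * max(
        [0.1] + [
            float(np.abs(res.table[c]).max())
            for res in result.independence.values()
            for c in ("predicted_joint_bias", "measured_joint_bias")
        ]
    )
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8, label="full additivity")
    ax.set_xlabel("predicted joint bias (rad)")
    ax.set_ylabel("measured joint bias (rad)")
    ax.legend(fontsize=8)
    if nis:
        inset = ax.inset_axes([0.62, 0.08, 0.33, 0.28])
        inset.hist(np.clip(nis, -1, 1), bins=np.linspace(-1, 1, 21), color="gray")
        inset.axvline(0.0, color="k", lw=0.8)
        inset.set_xlim(-1, 1)
        inset.set_title("non-additivity index", fontsize=7)
        inset.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _plot_thresholds(result: AnalysisResult, path) -> None:
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    means = result.fits.groupby("condition")["threshold"].mean()
    order = [c for c in _CONDITION_COLORS if c in means.index]
    ax.bar(
        range(len(order)), [means[c] for c in order],
        color=[_CONDITION_COLORS[c] for c in order],
    )
    ax.set_xticks(range(len(order)))
    ax.set_xticklabels(order, rotation=30, ha="right", fontsize=8)
    ax.set_ylabel("mean discrimination threshold (rad)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report(result: AnalysisResult, outdir) -> list[Path]:
    """Render figures and a human-readable summary from analysis outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    if len(result.biases):
        _plot_biases(result, outdir / "bias_by_reference.png")
        written.append(outdir / "bias_by_reference.png")
    if result.independence:
        _plot_additivity(result, outdir / "joint_additivity.png")
        written.append(outdir / "joint_additivity.png")
    if len(result.fits):
        _plot_thresholds(result, outdir / "thresholds.png")
        written.append(outdir / "thresholds.png")

    lines = ["# huemem analysis summary", ""]
    lines.append(f"- trials analyzed: {result.n_trials}")
    lines.append(f"- cells fit: {len(result.fits)}; cells failed: {len(result.failures)}")
    for failure in result.failures:
        lines.append(f"  - FAILED {failure['cell']} (n={failure['n']}): {failure['error']}")
    for key, value in result.threshold_ratios.items():
        lines.append(f"- threshold ratio {key}: {value:.3f}")
    if len(result.slopes):
        for row in result.slopes.itertuples():
            lines.append(
                f"- central-tendency slope ({row.variant}, ref on {row.reference_background}): "
                f"{row.slope:+.3f}"
            )
    if not result.independence:
        lines.append("- independence analysis: no complete memory/constancy/joint cells")
    for variant, res in result.independence.items():
        lines.append(
            f"- independence ({variant}): mean NI {res.mean_ni:+.3f} over {res.n_cells} cells, "
            f"one-tailed sign test p={res.sign_test_p:.4g}, "
            f"measured/predicted bias ratio {res.subadditivity_ratio:.2f}"
        )
    summary_path = outdir / "summary.md"
    summary_path.write_text("\n".join(lines) + "\n")
    written.append(summary_path)
    return written


def run(config: PipelineConfig, outdir) -> AnalysisResult:
    """Full pipeline: simulate, analyze, write tables and report."""
    outdir = Path(outdir)
    tables = simulate(config, outdir / "trials")
    result = analyze(tables)
    write_analysis(result, outdir / "analysis")
    report(result, outdir / "report")
    return result
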