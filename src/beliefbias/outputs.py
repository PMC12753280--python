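"""Serialization of run results: trajectory/endpoint tables, figures and a
replayable run manifest."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .core import BiasPolicy, run_sequence
from .reporting import reported_percent
from .scenarios import ScenarioResult, endpoint_table

__all__ = ["run_config", "trajectory_table", "write_outputs"]

TRAJECTORY_COLUMNS = [
    "scenario",
    "condition",
    "trial_index",
    "likelihood_ratio",
    "classification",
    "weight_applied",
    "pre_belief",
    "post_belief",
]


def run_config(config: RunConfig) -> list[ScenarioResult]:
    """Execute a run configuration: each archetype under both conditions.

    Every archetype gets its own stream built from the config's stream spec,
    with a per-archetype ``lr`` override applied when present; the unbiased
    and biased rows of an archetype share the identical stream.
    """
    results: list[ScenarioResult] = []
    for arch in config.archetypes:
        spec = config.stream
        if arch.lr is not None and spec.mode in ("fixed", "mixed"):
            spec = type(spec)(
                n_trials=spec.n_trials,
                mode=spec.mode,
                lr=arch.lr,
                n_favoring_A=spec.n_favoring_A,
                n_favoring_B=spec.n_favoring_B,
                design=spec.design,
                true_hypothesis=spec.true_hypothesis,
                seed=spec.seed,
            )
        stream = spec.build()
        for condition, policy in (
            ("unbiased", BiasPolicy.unbiased(config.policy.threshold)),
            ("biased", config.policy),
        ):
            traj = run_sequence(arch.prior, stream, policy)
            results.append(
                ScenarioResult(
                    archetype=arch.name,
                    condition=condition,
                    trajectory=traj,
                    final_percent_reported=reported_percent(traj.final_belief),
                )
            )
    return results


def trajectory_table(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """One row per update record; fixed, documented column order."""
    frames = []
    for r in results:
        df = r.trajectory.to_frame().drop(columns=["trial_id"])
        df.insert(0, "scenario", r.archetype)
        df.insert(1, "condition", r.condition)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)[TRAJECTORY_COLUMNS]


def _comparison_figure(results: Sequence[ScenarioResult], ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    colors = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    names = list(dict.fromkeys(r.archetype for r in results))
    for r in results:
        color = colors[names.index(r.archetype) % len(colors)]
        style = "-" if r.condition == "unbiased" else "--"
        ax.plot(
            range(len(r.trajectory.beliefs)),
            r.trajectory.beliefs,
            style,
            color=color,
            label=f"{r.archetype} ({r.condition})",
        )
    ax.set_xlabel("trial")
    ax.set_ylabel("P(treatment A superior)")
    ax.set_ylim(0, 1)
    ax.axhline(0.5, color="grey", lw=0.5)
    ax.legend(fontsize=7)
    return ax


def write_outputs(
    results: Sequence[ScenarioResult], config: RunConfig, out_dir: str | Path | None = None
) -> dict[str, Path]:
    """Write the full artifact set for one run.

    Emits the trajectory table (CSV), the endpoint summary (CSV and JSON),
    an all-archetype comparison figure and a focus figure on the archetype
    with the largest biased/unbiased endpoint gap (PNG and SVG each), and a
    manifest echoing the config plus the package version.  Filenames embed
    the scenario name and seed.  Returns a name → path mapping.
    """
    if not results:
        raise ValueError("results must be non-empty")
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{config.name}_seed{config.seed}"
    paths: dict[str, Path] = {}

    traj = trajectory_table(results)
    paths["trajectories"] = out / f"{stem}_trajectories.csv"
    traj.to_csv(paths["trajectories"], index=False)

    endpoints = endpoint_table(results)
    paths["endpoints_csv"] = out / f"{stem}_endpoints.csv"
    endpoints.to_csv(paths["endpoints_csv"], index=False)
    paths["endpoints_json"] = out / f"{stem}_endpoints.json"
    paths["endpoints_json"].write_text(
        json.dumps(endpoints.to_dict(orient="records"), indent=2) + "\n"
    )

    fig, ax = plt.subplots(figsize=(7, 4.5))
    _comparison_figure(results, ax)
    ax.set_title("Biased vs. unbiased belief updating, all archetypes")
    for ext in ("png", "svg"):
        paths[f"comparison_{ext}"] = out / f"{stem}_comparison.{ext}"
        fig.savefig(paths[f"comparison_{ext}"], dpi=150)
    plt.close(fig)

    # focus figure: the archetype where bias moved the endpoint the most
    by_name: dict[str, dict[str, ScenarioResult]] = {}
    for r in results:
        by_name.setdefault(r.archetype, {})[r.condition] = r
    focus = max(
        by_name,
        key=lambda n: abs(
            by_name[n]["biased"].final_belief - by_name[n]["unbiased"].final_belief
        ),
    )
    fig, ax = plt.subplots(figsize=(7, 4.5))
    _comparison_figure([r for r in results if r.archetype == focus], ax)
    ax.set_title(f"Focused comparison: {focus}")
    slug = focus.lower().replace(" ", "-")
    for ext in ("png", "svg"):
        paths[f"focus_{ext}"] = out / f"{stem}_focus_{slug}.{ext}"
        fig.savefig(paths[f"focus_{ext}"], dpi=150)
    plt.close(fig)

    manifest = {"package_version": __version__, "config": config.to_dict()}
    paths["manifest"] = out / f"{stem}_manifest.yaml"
    paths["manifest"].write_text(yaml.safe_dump(manifest, sort_keys=False))
    return paths
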