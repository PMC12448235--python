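"""Parameter-grid runner and tabular exports.

Sweeps the model's parameter grid — by default priors {0.5, 0.7, 0.9},
cue reliabilities {0.55, 0.75, 0.95}, ontogeny durations {5, 10, 20},
the three action regimes, and the linear/linear reward-penalty mapping —
and regenerates the model's result surfaces as tidy tables:

* per-cell decision-space JSON (state values, tied optimal action sets,
  reach probabilities, posteriors);
* a fitness-comparison table (optimal policy vs construction-only policy
  vs specialist vs generalist);
* clone-separation plasticity curves (three measures per separation time);
* a deconstruction-prevalence table (fraction of simulated organisms whose
  history contains at least one deconstruct action).

Every run writes a manifest listing parameters, seed, version and the files
produced; reruns with the same grid and seed are byte-identical (float
formatting is pinned).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .baselines import compare_strategies
from .policy import Mode, ModelParams, solve
from .simulate import SeparationScheme, clone_experiment, mature_phenotype_distribution

__all__ = ["GridSpec", "run_grid", "load_config", "plot_plasticity_curves"]

log = logging.getLogger("replast")

_FLOAT_FMT = "%.10g"


@dataclass(frozen=True)
class GridSpec:
    """The explored parameter combinations; defaults follow the model's grid."""

    priors: tuple[float, ...] = (0.5, 0.7, 0.9)
    reliabilities: tuple[float, ...] = (0.55, 0.75, 0.95)
    durations: tuple[int, ...] = (5, 10, 20)
    modes: tuple[Mode, ...] = (Mode.NONE, Mode.INCREMENTAL, Mode.COMPLETE)
    mappings: tuple[tuple[str, str], ...] = (("linear", "linear"),)
    n_agents: int = 10_000
    seed: int = 0

    def cells(self):
        for rk, pk in self.mappings:
            for T in self.durations:
                for prior in self.priors:
                    for rel in self.reliabilities:
                        for mode in self.modes:
                            yield ModelParams.make(
                                prior=prior,
                                reliability=rel,
                                t_ont=T,
                                reward_kind=rk,
                                penalty_kind=pk,
                                mode=mode,
                            )

    def to_dict(self) -> dict:
        return {
            "priors": list(self.priors),
            "reliabilities": list(self.reliabilities),
            "durations": list(self.durations),
            "modes": [m.value for m in self.modes],
            "mappings": [list(m) for m in self.mappings],
            "n_agents": self.n_agents,
            "seed": self.seed,
        }


def _cell_id(p: ModelParams) -> str:
    return (
        f"p{p.prior.p_e1:g}_r{p.cues.reliability:g}_T{p.t_ont}"
        f"_{p.mode.value}_{p.fitness.reward.kind}-{p.fitness.penalty.kind}"
    )


def _cell_columns(p: ModelParams) -> dict:
    return {
        "prior": p.prior.p_e1,
        "reliability": p.cues.reliability,
        "t_ont": p.t_ont,
        "mode": p.mode.value,
        "reward_mapping": p.fitness.reward.kind,
        "penalty_mapping": p.fitness.penalty.kind,
    }


def run_grid(
    grid: GridSpec,
    outdir: str | Path,
    scheme: SeparationScheme = SeparationScheme(),
    with_plasticity: bool = True,
    progress: bool = False,
) -> dict:
    """Solve, simulate and export every grid cell; returns the manifest.

    Writes ``policies/*.json``, ``fitness_comparison.csv``,
    ``plasticity_curves.csv``, ``prevalence.csv`` and ``manifest.json`` under
    ``outdir``. Invalid cells are reported and skipped; the sweep continues.
    ``with_plasticity=False`` skips the (comparatively expensive)
    clone-separation assay.
    """
    outdir = Path(outdir)
    (outdir / "policies").mkdir(parents=True, exist_ok=True)
    fitness_rows: list[dict] = []
    plasticity_rows: list[dict] = []
    prevalence_rows: list[dict] = []
    files: list[dict] = []
    errors: list[dict] = []
    cells = list(grid.cells())
    iterator = cells
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(cells, desc="grid")
        except ImportError:  # pragma: no cover
            pass
    for p in iterator:
        cid = _cell_id(p)
        try:
            log.info("solving cell %s", cid)
            policy = solve(p)
            pol_path = outdir / "policies" / f"policy_{cid}.json"
            policy.to_json(pol_path)
            files.append({"path": str(pol_path.relative_to(outdir)), **_cell_columns(p)})

            for row in compare_strategies(p):
                fitness_rows.append(
                    {
                        **_cell_columns(p),
                        "strategy": row.strategy,
                        "expected_fitness": row.expected_fitness,
                        "normalized_fitness": row.normalized_fitness,
                    }
                )

            dist = mature_phenotype_distribution(
                policy, n=grid.n_agents, seed=grid.seed
            )
            prevalence_rows.append(
                {
                    **_cell_columns(p),
                    "fraction_deconstructed": dist.fraction_deconstructed,
                    "n_agents": grid.n_agents,
                }
            )

            if with_plasticity and p.mode != Mode.NONE:
                curve = clone_experiment(
                    policy, n=grid.n_agents, seed=grid.seed, scheme=scheme
                )
                for _, r in curve.iterrows():
                    plasticity_rows.append(
                        {
                            **_cell_columns(p),
                            "separation_time": int(r["separation_time"]),
                            "total": r["total"],
                            "construction": r["construction"],
                            "deconstruction": r["deconstruction"],
                        }
                    )
        except (ValueError, KeyError) as exc:
            log.warning("cell %s failed: %s", cid, exc)
            errors.append({"cell": cid, "error": str(exc)})

    def _write(name: str, rows: list[dict]) -> None:
        path = outdir / name
        pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
        files.append({"path": name})

    _write("fitness_comparison.csv", fitness_rows)
    _write("prevalence.csv", prevalence_rows)
    if with_plasticity:
        _write("plasticity_curves.csv", plasticity_rows)

    manifest = {
        "version": __version__,
        "grid": grid.to_dict(),
        "scheme": {
            "window": scheme.window,
            "measure": scheme.measure,
            "normalizer": scheme.normalizer,
        },
        "files": files,
        "errors": errors,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_config(path: str | Path) -> dict:
    """Read a flat key-value YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat key-value mapping")
    return cfg


def plot_plasticity_curves(curves: pd.DataFrame, path: str | Path) -> None:
    """Minimal static rendering of a plasticity-curve table (one panel)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for measure, style in (("total", "-o"), ("construction", ":*"), ("deconstruction", "-.s")):
        ax.plot(curves["separation_time"], curves[measure], style, label=measure)
    ax.set_xlabel("separation time")
    ax.set_ylabel("mean normalized distance")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
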