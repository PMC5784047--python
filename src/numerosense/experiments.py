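"""Reproducible experiment recipes: configuration, seeding, manifests.

Each named experiment reproduces one family of results end-to-end at a
``full`` or ``scaled`` profile and writes tab-separated tables, PNG plots
and a JSON manifest sufficient to re-run it bit-identically. All stage
seeds are derived deterministically from a single master seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from . import evolife, network, neural_analysis, psychophysics, stimuli
from .stimuli import COMPARISON_RATIOS

EXPERIMENTS = ("acuity_trajectory", "feedback_regimes", "congruency",
               "coding_census", "evolution")

#: fixed stage order for sub-seed derivation (never reorder: seeds depend on it)
_STAGES = ("corpus", "layer_init", "unsupervised", "train_pairs", "eval_pairs",
           "congruency", "readout", "probe", "evolife", "battery", "misc")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved parameters for every pipeline stage."""

    profile: str = "scaled"
    seed: int = 0
    # stimulus / corpus
    image_side: int = 30
    numerosity_range: tuple[int, int] = (1, 32)
    area_levels: tuple[int, ...] = stimuli.AREA_LEVELS
    corpus_size: int = 5000
    # network
    stride: int = 2
    n_hidden: int = 400
    epochs: int = 150
    checkpoint_interval: int = 30
    feedback_fraction: float = 0.25
    readout_epochs: int = 40
    readout_lr: float = 0.1
    # comparison task
    ratios: tuple = COMPARISON_RATIOS
    train_pairs_per_ratio: int = 400
    eval_pairs_per_ratio: int = 200
    congruency_pairs_per_ratio: int = 200
    # coding probes
    summation_numerosities: tuple[int, ...] = tuple(range(1, 33))
    summation_areas: tuple[int, ...] = (32, 64)
    summation_replicates: int = 20
    selective_numerosities: tuple[int, ...] = (1, 2, 3, 4, 5)
    selective_areas: tuple[int, ...] = (16, 32)
    selective_replicates: int = 50
    # artificial life
    evolife_iterations: int = 200_000
    battery_agents: int | None = None     # None = whole population
    battery_repetitions: int = 50


def make_config(profile: str = "scaled", seed: int = 0,
                **overrides) -> ExperimentConfig:
    base = {"scaled": {}, "full": {
        "corpus_size": 51_200,
        "epochs": 300,
        "train_pairs_per_ratio": 2000,
        "eval_pairs_per_ratio": 500,
        "evolife_iterations": 3_000_000,
    }}
    if profile not in base:
        raise ValueError(f"unknown profile {profile!r}; use 'full' or 'scaled'")
    params = dict(base[profile])
    params.update(overrides)
    return ExperimentConfig(profile=profile, seed=seed, **params)


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage integer seeds (< 2**31) from the master seed."""
    seeds = {}
    for k, name in enumerate(_STAGES):
        ss = np.random.SeedSequence([int(master_seed), k])
        seeds[name] = int(ss.generate_state(1)[0] % (2 ** 31))
    return seeds


# ---------------------------------------------------------------------------
# pipeline building blocks (shared by recipes and the acceptance script)
# ---------------------------------------------------------------------------

@dataclass
class NetworkBundle:
    """Everything the deep-network experiments share."""

    config: ExperimentConfig
    seeds: dict
    bank: network.FilterBank
    corpus: list
    initial_layer: network.GenerativeLayer
    train_pairs: list
    eval_pairs: list
    trajectory: network.TrainingTrajectory | None = None

    @property
    def mature_layer(self) -> network.GenerativeLayer:
        if self.trajectory is None:
            raise RuntimeError("unsupervised training has not been run")
        return self.trajectory.final


def build_network_bundle(config: ExperimentConfig,
                         with_corpus: bool = True) -> NetworkBundle:
    seeds = derive_seeds(config.seed)
    bank = network.build_filterbank(side=config.image_side,
                                    stride=config.stride)
    corpus = []
    if with_corpus:
        corpus = stimuli.generate_corpus(stimuli.CorpusSpec(
            image_count=config.corpus_size,
            numerosity_range=config.numerosity_range,
            image_side=config.image_side,
            area_levels=config.area_levels,
            seed=seeds["corpus"],
        ))
    layer = network.GenerativeLayer.initialize(
        bank.n_features, config.n_hidden,
        rng=np.random.default_rng(seeds["layer_init"]),
    )
    train_pairs = stimuli.generate_comparison_pairs(
        config.ratios, config.train_pairs_per_ratio, "uncontrolled",
        rng=np.random.default_rng(seeds["train_pairs"]),
        side=config.image_side,
    )
    eval_pairs = stimuli.generate_comparison_pairs(
        config.ratios, config.eval_pairs_per_ratio, "uncontrolled",
        rng=np.random.default_rng(seeds["eval_pairs"]),
        side=config.image_side,
    )
    return NetworkBundle(config=config, seeds=seeds, bank=bank, corpus=corpus,
                         initial_layer=layer, train_pairs=train_pairs,
                         eval_pairs=eval_pairs)


def run_unsupervised(bundle: NetworkBundle) -> network.TrainingTrajectory:
    cfg = bundle.config
    layer = bundle.initial_layer.copy()
    bundle.trajectory = network.train_unsupervised(
        bundle.corpus, bundle.bank, layer, epochs=cfg.epochs,
        checkpoint_interval=cfg.checkpoint_interval,
        rng=np.random.default_rng(bundle.seeds["unsupervised"]),
    )
    return bundle.trajectory


def fit_network_acuity(bundle: NetworkBundle,
                       layer: network.GenerativeLayer,
                       condition: str = "",
                       feedback_fraction: float | None = None):
    """Train the read-out, evaluate held-out pairs, fit the Weber fraction."""
    cfg = bundle.config
    frac = cfg.feedback_fraction if feedback_fraction is None else feedback_fraction
    head = network.train_readout(
        bundle.train_pairs, bundle.bank, layer, feedback_fraction=frac,
        rng=np.random.default_rng(bundle.seeds["readout"]),
        learning_rate=cfg.readout_lr, epochs=cfg.readout_epochs,
    )
    outcomes = network.evaluate_pairs(bundle.eval_pairs, bundle.bank, layer,
                                      head)
    table = psychophysics.accuracy_by_ratio(outcomes)
    result = psychophysics.fit_weber(table, condition=condition)
    return head, table, result


def congruency_tables(bundle: NetworkBundle, layer, head,
                      ratios=None) -> dict[str, pd.DataFrame]:
    """Accuracy-by-ratio tables on congruent and incongruent pair sets."""
    cfg = bundle.config
    ratios = ratios if ratios is not None else cfg.ratios
    out = {}
    for congruency in ("congruent", "incongruent"):
        rng = np.random.default_rng(bundle.seeds["congruency"])
        pairs = stimuli.generate_comparison_pairs(
            ratios, cfg.congruency_pairs_per_ratio, congruency,
            rng=rng, side=cfg.image_side,
        )
        outcomes = network.evaluate_pairs(pairs, bundle.bank, layer, head)
        out[congruency] = psychophysics.accuracy_by_ratio(outcomes)
    return out


def coding_profiles(bundle: NetworkBundle, layer):
    """Summation-coding and selectivity classifications for one layer."""
    cfg = bundle.config
    rng = np.random.default_rng(bundle.seeds["probe"])
    probe_sum = neural_analysis.probe_corpus(
        cfg.summation_numerosities, cfg.summation_areas,
        cfg.summation_replicates, rng, side=cfg.image_side,
    )
    table_sum = neural_analysis.build_tuning_table(
        bundle.bank, layer, probe_sum,
        min_per_cell=cfg.summation_replicates,
    )
    summation = neural_analysis.classify_summation(table_sum)
    probe_sel = neural_analysis.probe_corpus(
        cfg.selective_numerosities, cfg.selective_areas,
        cfg.selective_replicates, rng, side=cfg.image_side,
    )
    table_sel = neural_analysis.build_tuning_table(
        bundle.bank, layer, probe_sel,
        min_per_cell=cfg.selective_replicates,
    )
    selective = neural_analysis.classify_selective(table_sel)
    pooled = neural_analysis.pool_tuning_curves(selective, table_sel)
    return summation, selective, pooled, table_sel


# ---------------------------------------------------------------------------
# experiment recipes
# ---------------------------------------------------------------------------

def _write_tables(outdir: Path, tables: dict[str, pd.DataFrame]) -> None:
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                  float_format="%.6g")


def _write_manifest(outdir: Path, name: str, config: ExperimentConfig) -> None:
    from . import __version__

    manifest = {
        "experiment": name,
        "package_version": __version__,
        "config": dataclasses.asdict(config),
        "stage_seeds": derive_seeds(config.seed),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))


def _plot_lines(outdir: Path, fname: str, frames, x, y, labels,
                xlabel: str, ylabel: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for df, label in zip(frames, labels):
        ax.plot(df[x], df[y], marker="o", label=label)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if any(labels):
        ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / fname, dpi=120)
    plt.close(fig)


def _exp_acuity_trajectory(config: ExperimentConfig, outdir: Path) -> dict:
    bundle = build_network_bundle(config)
    run_unsupervised(bundle)
    _, _, initial = fit_network_acuity(bundle, bundle.initial_layer,
                                       condition="initial")
    traj = psychophysics.learning_trajectory(
        bundle.trajectory, bundle.bank, bundle.train_pairs, bundle.eval_pairs,
        feedback_fraction=config.feedback_fraction,
        readout_seed=bundle.seeds["readout"],
        readout_kwargs={"learning_rate": config.readout_lr,
                        "epochs": config.readout_epochs},
    )
    first = pd.DataFrame([{"epoch": 0, "w": initial.w,
                           "reliable": initial.reliable,
                           "rmse": initial.rmse}])
    table = pd.concat([first, traj], ignore_index=True)
    tables = {"weber_trajectory": table}
    _write_tables(outdir, tables)
    _plot_lines(outdir, "weber_trajectory.png", [table], "epoch", "w", [""],
                "unsupervised epochs", "Weber fraction")
    return tables


def _exp_feedback_regimes(config: ExperimentConfig, outdir: Path) -> dict:
    bundle = build_network_bundle(config)
    run_unsupervised(bundle)
    tables = {}
    for frac, tag in ((0.25, "25pct"), (0.01, "1pct")):
        for label, layer in (("initial", bundle.initial_layer),
                             ("mature", bundle.mature_layer)):
            _, table, result = fit_network_acuity(
                bundle, layer, condition=f"{label}/{tag}",
                feedback_fraction=frac,
            )
            table = table.assign(network=label, feedback=tag, w=result.w)
            tables[f"accuracy_{label}_{tag}"] = table
    _write_tables(outdir, tables)
    _plot_lines(
        outdir, "accuracy_by_ratio.png",
        [tables["accuracy_initial_25pct"], tables["accuracy_mature_25pct"]],
        "ratio", "accuracy", ["initial", "mature"],
        "numerical ratio", "accuracy",
    )
    return tables


def _exp_congruency(config: ExperimentConfig, outdir: Path) -> dict:
    bundle = build_network_bundle(config)
    run_unsupervised(bundle)
    tables = {}
    for label, layer in (("initial", bundle.initial_layer),
                         ("mature", bundle.mature_layer)):
        head, _, _ = fit_network_acuity(bundle, layer, condition=label)
        cond = congruency_tables(bundle, layer, head)
        cost = psychophysics.congruency_cost(cond)
        tables[f"congruency_{label}"] = cost
    _write_tables(outdir, tables)
    _plot_lines(outdir, "congruency_cost.png",
                [tables["congruency_initial"], tables["congruency_mature"]],
                "ratio", "cost", ["initial", "mature"],
                "numerical ratio", "incongruency cost")
    return tables


def _exp_coding_census(config: ExperimentConfig, outdir: Path) -> dict:
    bundle = build_network_bundle(config)
    run_unsupervised(bundle)
    tables = {}
    for label, layer in (("initial", bundle.initial_layer),
                         ("mature", bundle.mature_layer)):
        summation, selective, pooled, _ = coding_profiles(bundle, layer)
        tables[f"summation_{label}"] = summation
        tables[f"selective_{label}"] = selective
        tables[f"pooled_curves_{label}"] = pooled.by_preferred
        tables[f"distance_curves_{label}"] = pooled.by_distance
        tables[f"preferred_counts_{label}"] = (
            pooled.preferred_counts.rename("count").reset_index()
        )
    summary = pd.DataFrame(
        [
            {
                "network": label,
                "n_sensitive": int(
                    tables[f"summation_{label}"]["coding_class"]
                    .str.startswith("sensitive").sum()),
                "n_sensitive_neg": int(
                    (tables[f"summation_{label}"]["coding_class"]
                     == "sensitive-").sum()),
                "n_selective": int(
                    (tables[f"selective_{label}"]["coding_class"]
                     == "selective").sum()),
            }
            for label in ("initial", "mature")
        ]
    )
    tables["coding_summary"] = summary
    _write_tables(outdir, tables)
    return tables


def _exp_evolution(config: ExperimentConfig, outdir: Path) -> dict:
    seeds = derive_seeds(config.seed)
    eco = evolife.Ecosystem.initialize(evolife.EvoConfig(),
                                       seed=seeds["evolife"])
    trace = evolife.evolve(eco, config.evolife_iterations)
    rng = np.random.default_rng(seeds["battery"])
    indices = None
    if config.battery_agents is not None:
        indices = rng.choice(eco.population.size,
                             size=config.battery_agents, replace=False)
    trials = evolife.comparison_battery(
        eco.population, agent_indices=indices,
        repetitions=config.battery_repetitions, rng=rng,
    )
    by_distance, by_size = evolife.distance_size_effects(trials)
    best = int(np.argmax(eco.population.fitness()))
    profiles, _ = evolife.analyze_hidden_units(eco.population, best, rng=rng)
    summary = pd.DataFrame([{
        "chance_proportion": evolife.chance_proportion(trials),
        "mean_fitness_final": trace["mean_fitness"].iloc[-1] if len(trace) else 0.0,
        "n_agents_tested": trials["agent"].nunique(),
    }])
    tables = {"fitness_trace": trace, "accuracy_by_distance": by_distance,
              "accuracy_by_size": by_size,
              "hidden_unit_profiles": profiles, "summary": summary}
    _write_tables(outdir, tables)
    _plot_lines(outdir, "distance_effect.png", [by_distance], "distance",
                "accuracy", [""], "numerical distance", "accuracy")
    return tables


_RECIPES: dict[str, Callable] = {
    "acuity_trajectory": _exp_acuity_trajectory,
    "feedback_regimes": _exp_feedback_regimes,
    "congruency": _exp_congruency,
    "coding_census": _exp_coding_census,
    "evolution": _exp_evolution,
}


def run_experiment(name: str, config: ExperimentConfig,
                   outdir="results") -> dict:
    """Run one named experiment; writes tables, plots and a manifest."""
    if name not in _RECIPES:
        raise ValueError(
            f"unknown experiment {name!r}; choose from {sorted(_RECIPES)}"
        )
    outdir = Path(outdir) / name
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        tables = _RECIPES[name](config, outdir)
    except Exception as err:
        raise RuntimeError(
            f"experiment {name} failed (seed {config.seed}): {err}"
        ) from err
    _write_manifest(outdir, name, config)
    return tables


def run_from_manifest(manifest_path, outdir="results") -> dict:
    """Re-run an experiment exactly as recorded in its manifest."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_dict = manifest["config"]
    # JSON round-trips tuples as lists; restore hashable field types
    for key, val in cfg_dict.items():
        if isinstance(val, list):
            cfg_dict[key] = tuple(tuple(v) if isinstance(v, list) else v
                                  for v in val)
    config = ExperimentConfig(**cfg_dict)
    return run_experiment(manifest["experiment"], config, outdir)
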