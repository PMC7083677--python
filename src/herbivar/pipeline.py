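"""End-to-end orchestration: simulate -> preprocess -> fit -> transform -> compare.

A run writes a self-contained directory:

    run_dir/
      manifest.json                     config, derived seeds, versions
      data.csv (+ .provenance.json)     observation table
      groups/<origin>_<garden>/posterior/   latent posterior CSVs
      groups/<origin>_<garden>/observed_G.csv, observed_summary.csv
      comparisons/<name>.json           Krzanowski subspace results
      report.md, eigenvalues.png        via make_report

The four comparisons mirror the reciprocal-transplant contrasts: plants of
one origin across garden countries (environment effect) and plant origins
within one garden country (origin effect).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignSpec, TrueParams
from .preprocess import ALL_GROUP_KEYS, GroupKey, partition_groups, read_observations, DEFAULT_WEIGHTS
from .synthetic import simulate_dataset, write_dataset
from .animal_model import ChainConfig, PosteriorSet, PriorSpec, fit_bivariate_animal_model
from .scale_transform import summarize_observed_G, transform_posterior
from .subspace import SubspaceResult, compare_groups

#: (name, group A, group B) for the four reported contrasts.
COMPARISONS = (
    ("US_plants_US_vs_JP_gardens", GroupKey("US", "US"), GroupKey("US", "JP")),
    ("US_vs_JP_plants_US_gardens", GroupKey("US", "US"), GroupKey("JP", "US")),
    ("JP_plants_US_vs_JP_gardens", GroupKey("JP", "US"), GroupKey("JP", "JP")),
    ("US_vs_JP_plants_JP_gardens", GroupKey("US", "JP"), GroupKey("JP", "JP")),
)


def _version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    output_dir: str
    seed: int
    design: DesignSpec = field(default_factory=DesignSpec)
    true_params: TrueParams = field(default_factory=TrueParams)
    #: when set, load this observation CSV instead of simulating.
    data_path: str | None = None
    priors: PriorSpec = field(default_factory=PriorSpec)
    #: demo-scale schedule by default so a full run finishes in minutes;
    #: the full 65,000/15,000/50 schedule is available via configuration.
    chain: ChainConfig = field(
        default_factory=lambda: ChainConfig(n_iter=6_500, burn_in=1_500, thin=5)
    )
    weights: tuple = DEFAULT_WEIGHTS
    pin_offset: bool = False
    k: int = 1
    n_shuffles: int = 1
    hpd_prob: float = 0.95
    #: sub-thinning for the observed-scale transform (100 on 1,000 draws
    #: emulates a ten-matrix observed-scale posterior).
    observed_subthin: int = 1
    #: compare subspaces on "latent" or "observed" scale G draws.
    compare_scale: str = "latent"

    def __post_init__(self):
        if self.compare_scale not in ("latent", "observed"):
            raise ValueError("compare_scale must be 'latent' or 'observed'")
        if self.seed is None:
            raise ValueError("a master seed is required")

    def to_dict(self) -> dict:
        return {
            "output_dir": str(self.output_dir),
            "seed": self.seed,
            "design": self.design.to_dict(),
            "true_params": self.true_params.to_dict(),
            "data_path": self.data_path,
            "priors": self.priors.to_dict(),
            "chain": self.chain.to_dict(),
            "weights": list(self.weights),
            "pin_offset": self.pin_offset,
            "k": self.k,
            "n_shuffles": self.n_shuffles,
            "hpd_prob": self.hpd_prob,
            "observed_subthin": self.observed_subthin,
            "compare_scale": self.compare_scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "design" in d and isinstance(d["design"], dict):
            d["design"] = DesignSpec.from_dict(d["design"])
        if "true_params" in d and isinstance(d["true_params"], dict):
            d["true_params"] = TrueParams.from_dict(d["true_params"])
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PriorSpec.from_dict(d["priors"])
        if "chain" in d and isinstance(d["chain"], dict):
            d["chain"] = ChainConfig.from_dict(d["chain"])
        if "weights" in d:
            d["weights"] = tuple(d["weights"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path


def derive_seeds(master_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    names = ["simulate"] + [f"fit_{key}" for key in map(str, ALL_GROUP_KEYS)] + [
        f"compare_{name}" for name, _, _ in COMPARISONS
    ]
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def group_dir(run_dir: Path, key: GroupKey) -> Path:
    return Path(run_dir) / "groups" / str(key)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline, returning the run directory."""
    run_dir = Path(config.output_dir)
    if run_dir.exists() and any(run_dir.iterdir()):
        raise FileExistsError(f"run directory {run_dir} already exists and is not empty")
    run_dir.mkdir(parents=True, exist_ok=True)
    seeds = derive_seeds(config.seed)

    manifest = {
        "package_version": _version(),
        "config": config.to_dict(),
        "derived_seeds": seeds,
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    stage = "simulate"
    try:
        if config.data_path is not None:
            data = read_observations(config.data_path)
            data.to_csv(run_dir / "data.csv", index=False)
        else:
            data = simulate_dataset(config.design, config.true_params, seeds["simulate"])
            write_dataset(
                data,
                run_dir / "data.csv",
                design=config.design,
                params=config.true_params,
                seed=seeds["simulate"],
            )
    except Exception as exc:  # noqa: BLE001 - stage name is part of the contract
        raise PipelineError(stage, exc) from exc

    stage = "fit"
    posteriors: dict[GroupKey, PosteriorSet] = {}
    observed_draws: dict[GroupKey, np.ndarray] = {}
    try:
        groups = partition_groups(data)
        for key in ALL_GROUP_KEYS:
            sub = groups[key]
            if len(sub) == 0:
                raise ValueError(f"group {key} has no observations")
            chain = ChainConfig(
                **{**config.chain.to_dict(), "seed": seeds[f"fit_{key}"]}
            )
            ps = fit_bivariate_animal_model(
                sub,
                priors=config.priors,
                chain=chain,
                weights=config.weights,
                pin_offset=config.pin_offset,
            )
            ps.save(group_dir(run_dir, key) / "posterior")
            posteriors[key] = ps
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "transform"
    try:
        for key, ps in posteriors.items():
            G_obs, kept = transform_posterior(ps, sub_thin=config.observed_subthin)
            gdir = group_dir(run_dir, key)
            pd.DataFrame(
                {
                    "draw_index": kept,
                    "v11": G_obs[:, 0, 0],
                    "cov": G_obs[:, 0, 1],
                    "v22": G_obs[:, 1, 1],
                }
            ).to_csv(gdir / "observed_G.csv", index=False, float_format="%.10g")
            summarize_observed_G(G_obs, prob=config.hpd_prob).to_csv(
                gdir / "observed_summary.csv", index=False, float_format="%.10g"
            )
            observed_draws[key] = G_obs
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    stage = "compare"
    try:
        cdir = run_dir / "comparisons"
        cdir.mkdir(exist_ok=True)
        for name, key_a, key_b in COMPARISONS:
            kwargs = {}
            if config.compare_scale == "observed":
                kwargs = {
                    "g_draws_a": observed_draws[key_a],
                    "g_draws_b": observed_draws[key_b],
                }
            result = compare_groups(
                posteriors[key_a],
                posteriors[key_b],
                k=config.k,
                n_shuffles=config.n_shuffles,
                seed=seeds[f"compare_{name}"],
                prob=config.hpd_prob,
                **kwargs,
            )
            result.save(cdir / f"{name}.json")
            pd.DataFrame(
                {
                    "h1_observed": result.observed[:, 0],
                    "h2_observed": result.observed[:, 1],
                }
            ).to_csv(cdir / f"{name}_observed_eigenvalues.csv", index=False, float_format="%.10g")
            pd.DataFrame(
                {
                    "h1_randomized": result.randomized[:, 0],
                    "h2_randomized": result.randomized[:, 1],
                }
            ).to_csv(cdir / f"{name}_randomized_eigenvalues.csv", index=False, float_format="%.10g")
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    return run_dir


def _require(path: Path, missing: list[str]) -> bool:
    if not path.exists():
        missing.append(str(path))
        return False
    return True


def make_report(run_dir: str | Path) -> Path:
    """Assemble a human-readable report from a completed run directory."""
    run_dir = Path(run_dir)
    missing: list[str] = []
    _require(run_dir / "manifest.json", missing)
    _require(run_dir / "data.csv", missing)
    for key in ALL_GROUP_KEYS:
        _require(group_dir(run_dir, key) / "observed_summary.csv", missing)
    for name, _, _ in COMPARISONS:
        _require(run_dir / "comparisons" / f"{name}.json", missing)
    if missing:
        raise FileNotFoundError("incomplete run; missing artifacts:\n" + "\n".join(missing))

    lines = [
        "# G-matrix analysis report",
        "",
        "## Observed-scale genetic covariance matrices",
        "",
        "Posterior median (95% HPD) per group; variances on the diagonal.",
        "",
        "| group | lace-bug variance | covariance | other variance |",
        "|---|---|---|---|",
    ]
    for key in ALL_GROUP_KEYS:
        summ = pd.read_csv(group_dir(run_dir, key) / "observed_summary.csv").set_index("entry")

        def cell(entry):
            r = summ.loc[entry]
            return f"{r['median']:.4g} ({r['hpd_lower']:.4g}, {r['hpd_upper']:.4g})"

        lines.append(
            f"| {key} | {cell('lace_variance')} | {cell('covariance')} | {cell('other_variance')} |"
        )

    lines += [
        "",
        "## Krzanowski shared-subspace comparisons",
        "",
        "| comparison | h1 observed HPD | h1 randomized HPD | h2 observed HPD | h2 randomized HPD | verdict |",
        "|---|---|---|---|---|---|",
    ]
    results = {}
    for name, _, _ in COMPARISONS:
        d = json.loads((run_dir / "comparisons" / f"{name}.json").read_text())
        results[name] = d

        def iv(pair):
            return f"({pair[0]:.4g}, {pair[1]:.4g})"

        lines.append(
            f"| {name} | {iv(d['observed_hpd'][0])} | {iv(d['randomized_hpd'][0])} "
            f"| {iv(d['observed_hpd'][1])} | {iv(d['randomized_hpd'][1])} | {d['verdict']} |"
        )
    lines.append("")

    report = run_dir / "report.md"
    report.write_text("\n".join(lines))

    # eigenvalue HPD comparison figure (observed vs randomized, 4 panels)
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(9, 7), sharey=True)
    for ax, (name, _, _) in zip(axes.ravel(), COMPARISONS):
        d = results[name]
        for j, (label, color) in enumerate((("observed", "k"), ("randomized", "0.6"))):
            med = d[f"{label}_median"]
            hpd = d[f"{label}_hpd"]
            x = np.array([0, 1]) + (j - 0.5) * 0.15
            ax.errorbar(
                x,
                med,
                yerr=[
                    [med[i] - hpd[i][0] for i in range(2)],
                    [hpd[i][1] - med[i] for i in range(2)],
                ],
                fmt="o",
                color=color,
                label=label,
                capsize=3,
            )
        ax.set_xticks([0, 1], ["h1", "h2"])
        ax.set_ylim(-0.1, 2.1)
        ax.set_title(f"{name}\n({d['verdict']})", fontsize=9)
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(run_dir / "eigenvalues.png", dpi=120)
    plt.close(fig)
    return report
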