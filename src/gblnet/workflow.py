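"""End-to-end orchestration: sample → simulate → score → enrich from one config.

A run is described by a JSON :class:`RunConfig` (scenario subset, ensemble
size, seed, prior table, targets or synthetic-study settings, growth data or
parameters, solver settings, output directory).  :func:`run` executes the
pipeline, writes tidy CSV/TSV outputs, figures and a manifest recording the
config, seeds and a content hash of the prior table — score tables produced
under different priors are never comparable, so the hash guards against
accidental mixing.  Completed scenarios (their per-scenario score files) are
skipped on re-run, making runs resumable and idempotent.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BaranyiGrowthModel
from .network import ScenarioConfig
from .priors import default_priors, read_priors, sample_ensemble, write_priors
from .scoring import PASS_THRESHOLD, TargetFeatures, predictive_density, score_ensemble
from .simulate import default_grid, run_ensemble
from .synth import make_study
from . import enrichment as enr

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]

_VALID_LABELS = set("ABCDEFGH")


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    out_dir: str
    scenarios: list = field(default_factory=lambda: list("ABCDEFGH"))
    n_members: int = 500
    seed: int = 0
    prior_table: str | None = None        # TSV path; None = package defaults
    targets_path: str | None = None       # TSV path; None = synthetic study
    growth_obs_path: str | None = None    # TSV path; None = synthetic study
    synth_noise_sd: float = 0.1
    synth_scenario: str = "C"
    tll_threshold: float = PASS_THRESHOLD
    rtol: float = 1e-6
    atol: float = 1e-9
    grid_step: float = 5.0
    growth_n_starts: int = 40
    enrich_params: list = field(default_factory=lambda: ["d_A", "k_C", "chi"])
    n_bins: int = 20

    def __post_init__(self) -> None:
        bad = [s for s in self.scenarios if s not in _VALID_LABELS]
        if bad:
            raise ValueError(f"invalid scenario label(s): {bad}")
        if len(set(self.scenarios)) != len(self.scenarios):
            raise ValueError("duplicate scenario labels")
        if self.n_members < 1:
            raise ValueError("n_members must be >= 1")
        for path_attr in ("prior_table", "targets_path", "growth_obs_path"):
            p = getattr(self, path_attr)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{path_attr} does not exist: {p}")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig) -> Path:
    """Execute the full pipeline; returns the output directory.

    Deterministic given (config, seed); per-member solver failures are
    recorded in the score table, never fatal; scenarios whose score files
    already exist are skipped (resumable).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    priors = read_priors(config.prior_table) if config.prior_table \
        else default_priors()
    prior_file = out / "priors.tsv"
    if not prior_file.exists():
        write_priors(priors, prior_file)

    # --- inputs: measured or synthetic -----------------------------------
    study = None
    if config.targets_path:
        targets = TargetFeatures.from_frame(
            pd.read_csv(config.targets_path, sep="\t"))
    else:
        study = make_study(seed=config.seed, noise_sd=config.synth_noise_sd,
                           scenario=config.synth_scenario)
        targets = study.targets
        study.write(out / "synthetic_study")
    targets.to_frame().to_csv(out / "targets.tsv", sep="\t", index=False)

    if config.growth_obs_path:
        growth_obs = pd.read_csv(config.growth_obs_path, sep="\t")
    elif study is not None:
        growth_obs = study.growth_obs
    else:
        raise ValueError("growth_obs_path required when targets are supplied")

    gfit = BaranyiGrowthModel.from_dataframe(growth_obs).fit(
        n_starts=config.growth_n_starts, seed=config.seed)
    (out / "growth_fit.json").write_text(json.dumps({
        "best": dict(zip(("K", "N0", "mu_max", "v", "m", "lam"),
                         gfit.params.to_array().tolist())),
        "sse_log": gfit.sse,
        "confidence_set_size": len(gfit.confidence_set),
    }, indent=2))
    gp = gfit.params

    # --- ensemble, shared across scenarios --------------------------------
    ens = sample_ensemble(priors, config.n_members, config.seed)
    ens.to_frame().to_csv(out / "ensemble.csv", index=False)
    grid = default_grid(config.grid_step)

    score_frames = []
    for label in config.scenarios:
        score_file = out / f"scores_{label}.csv"
        if score_file.exists():
            logger.info("scenario %s already scored; skipping", label)
            score_frames.append(pd.read_csv(score_file, float_precision="round_trip"))
            continue
        sims = run_ensemble(ens, [ScenarioConfig.from_label(label)], gp, grid,
                            rtol=config.rtol, atol=config.atol)
        scores = score_ensemble(sims, targets, ens,
                                threshold=config.tll_threshold)
        scores.to_csv(score_file, index=False, float_format="%.17g")
        score_frames.append(scores)
    all_scores = pd.concat(score_frames, ignore_index=True)
    all_scores.to_csv(out / "scores.csv", index=False, float_format="%.17g")

    # --- summaries ---------------------------------------------------------
    pass_counts = (all_scores[all_scores["tll"] > config.tll_threshold]
                   .groupby("scenario").size()
                   .reindex(config.scenarios, fill_value=0))
    pass_counts.rename("passing").to_csv(out / "pass_counts.csv")
    predictive_density(all_scores).to_csv(out / "predictive_density.csv")

    # --- enrichment --------------------------------------------------------
    ks_rows, bin_frames = [], []
    for label in config.scenarios:
        sub = all_scores[all_scores["scenario"] == label]
        members = sub[sub["tll"] > config.tll_threshold]["member"].to_numpy()
        if len(members) == 0 or len(members) >= ens.n:
            logger.info("scenario %s: %d passing members; enrichment skipped",
                        label, len(members))
            continue
        ks = enr.ks_enrichment(ens, members).reset_index()
        ks.insert(0, "scenario", label)
        ks_rows.append(ks)
        for param in config.enrich_params:
            if param == "chi":
                full = ens.column("k_FR") / ens.column("k_FA")
            else:
                full = ens.column(param)
            try:
                bins = enr.bin_enrichment(full, full[members],
                                          n_bins=config.n_bins)
            except ValueError as exc:
                logger.warning("bin enrichment %s/%s skipped: %s",
                               label, param, exc)
                continue
            bins.insert(0, "parameter", param)
            bins.insert(0, "scenario", label)
            bin_frames.append(bins)
    if ks_rows:
        pd.concat(ks_rows, ignore_index=True).to_csv(
            out / "enrichment_ks.csv", index=False)
    if bin_frames:
        pd.concat(bin_frames, ignore_index=True).to_csv(
            out / "enrichment_bins.csv", index=False)

    # --- figures -----------------------------------------------------------
    try:
        import matplotlib.pyplot as plt
        from .plotting import plot_growth_fit, plot_likelihood_profiles
        profiles = {label: np.sort(
            all_scores[all_scores["scenario"] == label]["tll"].to_numpy())[::-1]
            for label in config.scenarios}
        ax = plot_likelihood_profiles(profiles, config.tll_threshold)
        ax.figure.savefig(out / "likelihood_profiles.svg")
        plt.close(ax.figure)
        ax = plot_growth_fit(gfit)
        ax.figure.savefig(out / "growth_fit.svg")
        plt.close(ax.figure)
    except Exception as exc:  # pragma: no cover - plotting is best-effort
        logger.warning("figure generation failed: %s", exc)

    manifest = {
        "config": asdict(config),
        "prior_table_sha256": _hash_file(prior_file),
        "n_scenarios": len(config.scenarios),
        "n_members": ens.n,
        "seed": config.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
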