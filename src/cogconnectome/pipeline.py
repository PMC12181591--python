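"""End-to-end orchestration: cohort → preprocessing → connectomes →
measures → permutation comparisons → cohort statistics.

Every run resolves a :class:`RunConfig`, validates it before any
computation, and writes all stage outputs plus a machine-readable manifest
into one run directory.  Per-stage randomness derives from the master seed
through a fixed keying scheme (see :func:`cogconnectome.permutation.derive_seed`),
so runs with the same configuration are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .connectome import build_connectome, density_grid
from .dataset import CognitiveDataset
from .design import GROUPS, group_label
from .measures import MEASURES, compute_measures
from .permutation import (
    DEFAULT_ALPHA,
    DEFAULT_MIN_DENSITIES,
    DEFAULT_N_PERM,
    DEFAULT_SW_ENSEMBLE_PERM,
    comparisons_to_frame,
    run_design,
    summary_dict,
)
from .preprocess import (
    eligibility_filter,
    group_score_matrix,
    invert_scores,
    module_composites,
    stratify,
    zscore_cohort,
)
from .roster import Roster, DEFAULT as DEFAULT_ROSTER
from .simulate import fixture_config, generate_cohort
from .stats import descriptives, followup_anovas, manova_interaction

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    #: CSV path of an existing cohort, or a fixture scenario name
    #: ('null', 'dedifferentiation', 'stable_reserve') to simulate one.
    input: str = "null"
    n_per_group: int = 40  # only for simulated input
    roster_path: str | None = None
    d_min: float = 0.20
    d_max: float = 0.60
    step: float = 0.01
    measures: tuple[str, ...] = MEASURES
    n_perm: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PERM))
    alpha: float = DEFAULT_ALPHA
    min_densities: int = DEFAULT_MIN_DENSITIES
    sw_ensemble: int = DEFAULT_SW_ENSEMBLE_PERM
    reserve_threshold: float | None = None  # None = cohort median
    zscore_ddof: int = 1
    master_seed: int = 0
    output_dir: str = "runs/run"
    make_plots: bool = False

    def validate(self) -> None:
        if not (0 < self.d_min < self.d_max <= 1) or self.step <= 0:
            raise ValueError("invalid density grid")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.min_densities < 1:
            raise ValueError("min_densities must be >= 1")
        unknown = [m for m in self.measures if m not in MEASURES]
        if unknown:
            raise ValueError(f"unknown measures {unknown}")
        from .simulate import FIXTURES

        if self.input not in FIXTURES and not Path(self.input).exists():
            raise FileNotFoundError(
                f"input {self.input!r} is neither a fixture scenario nor a CSV path"
            )
        if self.roster_path is not None and not Path(self.roster_path).exists():
            raise FileNotFoundError(f"roster file {self.roster_path!r} not found")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        cfg = cls(**payload)
        cfg.validate()
        return cfg

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["measures"] = list(self.measures)
        payload["n_perm"] = dict(self.n_perm)
        Path(path).write_text(json.dumps(payload, indent=2))


def _load_roster(config: RunConfig) -> Roster:
    if config.roster_path is None:
        return DEFAULT_ROSTER
    path = str(config.roster_path)
    return Roster.from_json(path) if path.endswith(".json") else Roster.from_csv(path)


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cogconnectome")
    root.addHandler(handler)
    stage = "input"
    try:
        roster = _load_roster(config)
        from .simulate import FIXTURES

        if config.input in FIXTURES:
            sim = fixture_config(
                config.input, seed=config.master_seed, n_per_group=config.n_per_group
            )
            cohort = generate_cohort(sim)
            sim.to_json(out / "sim_config.json")
        else:
            cohort = CognitiveDataset.from_csv(config.input, roster=roster)
        cohort.to_csv(out / "cohort.csv")

        stage = "preprocess"
        included, excluded = eligibility_filter(cohort)
        pd.DataFrame(excluded, columns=["participant_id", "reason"]).to_csv(
            out / "excluded.csv", index=False
        )
        z = invert_scores(zscore_cohort(included, ddof=config.zscore_ddof))
        strat = stratify(z, threshold=config.reserve_threshold)
        strat.to_frame().to_csv(out / "stratification.csv", index=False)

        stage = "connectome"
        connectomes = {}
        for group in GROUPS:
            m = group_score_matrix(z, strat, group)
            if m.shape[0] < 3:
                raise ValueError(f"cell {group_label(group)} has < 3 participants")
            conn = build_connectome(m, node_labels=roster.names, group=group)
            conn.to_csv(out / f"connectome_{group_label(group)}.csv")
            connectomes[group] = conn

        stage = "measures"
        frames = []
        for group, conn in connectomes.items():
            curves = compute_measures(
                conn,
                config.d_min,
                config.d_max,
                config.step,
                measures=config.measures,
                seed=config.master_seed,
                sw_ensemble=max(config.sw_ensemble, 20),
            )
            frames.extend(c.to_frame() for c in curves.values())
        measures_frame = pd.concat(frames, ignore_index=True)
        measures_frame.to_csv(out / "measures.csv", index=False)

        stage = "compare"
        results = run_design(
            z,
            strat,
            measures=config.measures,
            master_seed=config.master_seed,
            n_perm=config.n_perm,
            densities=density_grid(config.d_min, config.d_max, config.step),
            alpha=config.alpha,
            min_densities=config.min_densities,
            sw_ensemble=config.sw_ensemble,
            keep_null_quantiles=config.make_plots,
        )
        comparisons_to_frame(results).to_csv(out / "comparisons.csv", index=False)
        (out / "comparisons_summary.json").write_text(
            json.dumps(summary_dict(results), indent=2)
        )
        if config.make_plots:
            from .plotting import plot_difference_curves

            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            for r in results:
                if not r.is_scalar:
                    a, b = (group_label(g) for g in r.group_pair)
                    plot_difference_curves(
                        r, plot_dir / f"diff_{a}_vs_{b}_{r.measure_name}.png"
                    )

        stage = "stats"
        composites = module_composites(z)
        sframe = strat.to_frame().set_index("participant_id")
        order = z.data["participant_id"]
        age = sframe.loc[order, "age_group"].reset_index(drop=True)
        reserve = sframe.loc[order, "reserve_group"].reset_index(drop=True)
        manova = manova_interaction(composites, age, reserve)
        anovas = followup_anovas(composites, age, reserve)
        desc = descriptives(z, strat, composites=composites)
        desc["table"].to_csv(out / "descriptives.csv", index=False)
        stats_payload = {
            "manova": {
                "wilks_lambda": manova.wilks_lambda,
                "F": manova.f_stat,
                "df": list(manova.df),
                "p": manova.p_value,
            },
            "followup_anovas": anovas.to_dict(orient="records"),
            "spearman": desc["spearman"],
            "chi2_sex": desc["chi2_sex"],
            "reserve_threshold": strat.split_threshold,
        }
        (out / "stats.json").write_text(json.dumps(stats_payload, indent=2))
        if config.make_plots:
            from .plotting import plot_canonical_means

            plot_canonical_means(manova, out / "plots" / "canonical_means.png")

        manifest = {
            "package_version": __version__,
            "numpy_version": np.__version__,
            "master_seed": config.master_seed,
            "n_participants": len(cohort),
            "n_included": len(included),
            "n_excluded": len(excluded),
            "groups": {group_label(g): n for g, n in strat.counts().items()},
            "stages": [
                "input", "preprocess", "connectome", "measures", "compare", "stats",
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    except Exception:
        logger.exception("pipeline failed at stage %r; partial outputs kept in %s",
                         stage, out)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
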