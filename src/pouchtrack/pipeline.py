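"""End-to-end reproducible pipeline: simulate → metrics → statistics → scores.

A :class:`PipelineConfig` fully determines a run: one master seed is split
deterministically into per-generator seeds, every artifact is written
into the output directory, and a manifest records the echoed
configuration, package version and a content hash of every file, so a
rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import __version__
from .errors import ConfigurationError
from .io import (
    write_metrics,
    write_phenotypes,
    write_timeline,
    write_tracks,
)
from .scoring import scores_by_genotype, summarize_scores
from .simulate import (
    SimulationConfig,
    default_class_params,
    simulate_contribution_table,
    simulate_phenotypes,
    simulate_pouch_timeline,
    simulate_tracks,
)
from .stats import (
    compare_angle_distributions,
    fisher_exact,
    tukey_kramer,
    welch_t_one_tailed,
)
from .tracks import (
    bin_angles,
    compute_track_metrics,
    filter_complete_tracks,
    pooled_group_angles,
    summarize_group_metrics,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Serializable description of one full pipeline run."""

    seed: int = 0
    output_dir: str = "pouchtrack_run"
    window_min: tuple[float, float] = (0.0, 360.0)
    n_bins: int = 8
    alpha: float = 0.05
    # one-tailed direction for the reference-vs-mutant Welch tests;
    # the conventional alternative is mutant < wild type
    velocity_tail: str = "two_tailed"
    persistence_tail: str = "one_tailed_less"
    reference_class: str = "wild_type"
    track_classes: list[dict] = field(
        default_factory=lambda: [
            {"class_name": "wild_type", "n_cells": 30,
             "kappa_bias": 5.0, "kappa_persist": 1.0, "dropout_prob": 0.2},
            {"class_name": "fgf8a_mut", "n_cells": 30,
             "kappa_bias": 0.0, "kappa_persist": 1.0, "dropout_prob": 0.2},
        ]
    )
    phenotype_classes: list[dict] = field(
        default_factory=lambda: [
            {"class_name": "wild_type", "n_embryos": 30},
            {"class_name": "tbx1", "n_embryos": 30},
            {"class_name": "single_mutant", "n_embryos": 30},
            {"class_name": "double_mutant", "n_embryos": 30},
        ]
    )
    timeline: dict = field(
        default_factory=lambda: {
            "classes": ["wild_type", "tbx1"],
            "start_hpf": 26.0,
            "window_h": 10.0,
        }
    )
    contribution: dict = field(
        default_factory=lambda: {
            "n_pos": 60, "n_neg": 60, "p_pos": 0.8, "p_neg": 0.3,
        }
    )

    def validate(self) -> None:
        lo, hi = self.window_min
        if hi <= lo:
            raise ConfigurationError(f"window_min: end {hi} must exceed start {lo}")
        if self.n_bins < 2 or 360 % self.n_bins != 0:
            raise ConfigurationError(
                f"n_bins: must be >= 2 and divide 360, got {self.n_bins}"
            )
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError(f"alpha: must be in (0, 1), got {self.alpha}")
        names = [c.get("class_name") for c in self.track_classes]
        if len(names) < 2:
            raise ConfigurationError("track_classes: need at least 2 classes")
        if self.reference_class not in names:
            raise ConfigurationError(
                f"reference_class: {self.reference_class!r} not among "
                f"track_classes {names}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_min"] = list(self.window_min)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        kwargs = dict(data)
        if "window_min" in kwargs:
            kwargs["window_min"] = tuple(kwargs["window_min"])
        return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a pipeline config from a YAML or JSON file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return PipelineConfig.from_dict(data)


def _child_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-generator seeds below 2**31 derived from one master."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump_json(data: dict, path: Path) -> None:
    path.write_text(
        json.dumps(data, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def _test_result_dict(res) -> dict:
    return {
        "test": res.test_name,
        "statistic": res.statistic,
        "df": res.df,
        "p_value": res.p_value,
        "tail": res.tail,
        "degenerate": res.degenerate,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a full run and return the report dictionary.

    Writes into ``config.output_dir``: the simulated track/phenotype/
    timeline tables, the per-track metrics table, ``report.json`` with
    group summaries and every statistical comparison, the echoed config,
    and ``manifest.json`` with a SHA-256 hash of each output file.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not out.is_dir():
        raise ConfigurationError(f"output_dir: {out} is not a writable directory")

    n_track = len(config.track_classes)
    n_pheno = len(config.phenotype_classes)
    seeds = _child_seeds(config.seed, n_track + n_pheno + 1)
    track_seeds = seeds[:n_track]
    pheno_seeds = seeds[n_track:n_track + n_pheno]
    contrib_seed = seeds[-1]

    # --- tracks -> metrics -> group stats
    lo, hi = config.window_min
    all_tracks = []
    for spec_dict, seed in zip(config.track_classes, track_seeds):
        cfg = SimulationConfig(**{**spec_dict, "seed": seed})
        all_tracks.extend(simulate_tracks(cfg))
    write_tracks(all_tracks, out / "tracks.csv")

    kept = filter_complete_tracks(all_tracks, lo, hi)
    metrics = [compute_track_metrics(tr) for tr in kept]
    write_metrics(metrics, out / "metrics.csv")
    group_summary = summarize_group_metrics(metrics)

    angles = pooled_group_angles(metrics)
    histograms = {
        g: bin_angles(a, config.n_bins, group=g) for g, a in angles.items()
    }

    ref = config.reference_class
    comparisons: dict[str, dict] = {}
    for other in sorted(angles):
        if other == ref:
            continue
        vel_ref = [m.velocity_um_per_min for m in metrics if m.group == ref]
        vel_oth = [m.velocity_um_per_min for m in metrics if m.group == other]
        per_ref = [
            m.persistence for m in metrics
            if m.group == ref and m.persistence_defined
        ]
        per_oth = [
            m.persistence for m in metrics
            if m.group == other and m.persistence_defined
        ]
        comparisons[f"{other}_vs_{ref}"] = {
            "velocity": _test_result_dict(
                welch_t_one_tailed(vel_oth, vel_ref, config.velocity_tail)
            ),
            "persistence": _test_result_dict(
                welch_t_one_tailed(per_oth, per_ref, config.persistence_tail)
            ),
            "angles": _test_result_dict(
                compare_angle_distributions(histograms[other], histograms[ref])
            ),
        }

    # --- phenotypes -> scores -> Tukey–Kramer
    records = []
    for spec_dict, seed in zip(config.phenotype_classes, pheno_seeds):
        spec_dict = dict(spec_dict)
        n_embryos = int(spec_dict.pop("n_embryos", 30))
        sides = tuple(spec_dict.pop("sides", ("left", "right")))
        params = default_class_params(spec_dict.pop("class_name"))
        if spec_dict:
            params = dataclasses.replace(params, **spec_dict)
        params = dataclasses.replace(params, seed=seed)
        records.extend(simulate_phenotypes(params, n_embryos, sides=sides))
    write_phenotypes(records, out / "phenotypes.csv")

    score_summary = [dataclasses.asdict(s) for s in summarize_scores(records)]
    tukey = {}
    for metric in ("pouch_score", "cb_score"):
        by_gen = scores_by_genotype(records, metric=metric)
        tukey[metric] = [
            dataclasses.asdict(c) for c in tukey_kramer(by_gen)
        ]

    # --- timelines
    tl_cfg = config.timeline
    timeline_section = {}
    all_events = []
    for cls in tl_cfg.get("classes", []):
        events = simulate_pouch_timeline(
            cls,
            start_hpf=float(tl_cfg.get("start_hpf", 26.0)),
            window_h=float(tl_cfg.get("window_h", 10.0)),
        )
        timeline_section[cls] = {
            "n_events": len(events),
            "events": [dataclasses.asdict(e) for e in events],
        }
        all_events.extend(events)
    write_timeline(all_events, out / "timeline.csv")

    # --- contribution table -> Fisher
    table = simulate_contribution_table(
        **{**config.contribution, "seed": contrib_seed}
    )
    fisher = fisher_exact(table, "two_tailed")

    report = {
        "seed": config.seed,
        "n_tracks_simulated": len(all_tracks),
        "n_tracks_complete": len(kept),
        "group_metrics": group_summary,
        "angle_histograms": {
            g: {"bin_edges_deg": h.bin_edges_deg.tolist(),
                "counts": h.counts.tolist()}
            for g, h in histograms.items()
        },
        "comparisons": comparisons,
        "phenotype_summary": score_summary,
        "tukey_kramer": tukey,
        "timeline": timeline_section,
        "contribution_table": table.tolist(),
        "fisher_contributions": _test_result_dict(fisher),
        "alpha": config.alpha,
    }
    _dump_json(report, out / "report.json")

    # echoed config + manifest (hash every artifact, manifest last)
    (out / "config.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )
    artifacts = [
        "tracks.csv", "metrics.csv", "phenotypes.csv", "timeline.csv",
        "report.json", "config.yaml",
    ]
    manifest = {
        "package": "pouchtrack",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": {name: _sha256(out / name) for name in artifacts},
    }
    _dump_json(manifest, out / "manifest.json")
    logger.info("pipeline run complete: %s", out)
    return report
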