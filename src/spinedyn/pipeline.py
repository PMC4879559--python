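"""End-to-end orchestration: simulate → detect/classify → turnover → stats.

A :class:`PipelineConfig` describes a multi-condition synthetic experiment
(e.g. a vehicle-infused control arm, an activity-blockade arm with calcium
signaling silenced, and an enriched-environment arm with elevated spine
generation).  ``run_pipeline`` executes the full chain per condition and
writes plain-text outputs plus a manifest sufficient to re-run
bit-identically: all randomness derives from the single top-level seed via
named substreams, and no output embeds wall-clock state.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from spinedyn import __version__
from spinedyn.events import (
    DendriteClass,
    DetectionParams,
    classify_dendrite,
    summarize_classification,
    classification_percentages,
)
from spinedyn.io import write_results
from spinedyn.simulate import SimParams, simulate_spine_population, simulate_trace_set
from spinedyn.stats import fisher_exact_rc, kruskal_wallis, steel_test
from spinedyn.turnover import aggregate_group, turnover_over_sessions

__all__ = ["ConditionConfig", "PipelineConfig", "run_pipeline", "classify_events_table"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental arm: a label plus generator-parameter overrides."""

    label: str
    sim: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PipelineConfig:
    """Full parameterization of a synthetic multi-condition experiment."""

    conditions: tuple[ConditionConfig, ...]
    seed: int = 0
    n_dendrites_per_condition: int = 20
    n_populations_per_condition: int = 5
    detection: DetectionParams = field(default_factory=DetectionParams)
    matching_tolerance_um: float = 1.0
    control_label: str | None = None
    alpha: float = 0.05
    n_mc: int = 10_000
    run_calcium: bool = True
    run_turnover: bool = True

    def __post_init__(self) -> None:
        labels = [c.label for c in self.conditions]
        if len(labels) != len(set(labels)):
            raise ValueError("condition labels must be unique")
        if not labels:
            raise ValueError("at least one condition is required")
        if self.control_label is not None and self.control_label not in labels:
            raise ValueError(f"control label {self.control_label!r} not a condition")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        conditions = tuple(
            ConditionConfig(label=c["label"], sim=dict(c.get("sim", {})))
            for c in d["conditions"]
        )
        det = DetectionParams(**d.get("detection", {}))
        stats_cfg = d.get("stats", {})
        return cls(
            conditions=conditions,
            seed=int(d.get("seed", 0)),
            n_dendrites_per_condition=int(d.get("n_dendrites_per_condition", 20)),
            n_populations_per_condition=int(d.get("n_populations_per_condition", 5)),
            detection=det,
            matching_tolerance_um=float(d.get("matching_tolerance_um", 1.0)),
            control_label=stats_cfg.get("control"),
            alpha=float(stats_cfg.get("alpha", 0.05)),
            n_mc=int(stats_cfg.get("n_mc", 10_000)),
            run_calcium=bool(d.get("run_calcium", True)),
            run_turnover=bool(d.get("run_turnover", True)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_dict(self) -> dict:
        return {
            "conditions": [{"label": c.label, "sim": c.sim} for c in self.conditions],
            "seed": self.seed,
            "n_dendrites_per_condition": self.n_dendrites_per_condition,
            "n_populations_per_condition": self.n_populations_per_condition,
            "detection": {
                "sd_multiplier": self.detection.sd_multiplier,
                "min_run_frames": self.detection.min_run_frames,
                "active_spine_min_exceedances": self.detection.active_spine_min_exceedances,
                "mode_bin_rule": self.detection.mode_bin_rule,
                "mode_min_bins": self.detection.mode_min_bins,
            },
            "matching_tolerance_um": self.matching_tolerance_um,
            "stats": {
                "control": self.control_label,
                "alpha": self.alpha,
                "n_mc": self.n_mc,
            },
            "run_calcium": self.run_calcium,
            "run_turnover": self.run_turnover,
        }

    def sha256(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _sub_seed(ss: np.random.SeedSequence) -> int:
    # SimParams carries a plain integer seed; fold a spawned sequence into one
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def classify_events_table(events: pd.DataFrame, params: DetectionParams) -> pd.DataFrame:
    """Classify dendrites from a detected-events table.

    A dendrite is ``dendritic_plus_synaptic`` when any of its spine ROIs
    has at least ``active_spine_min_exceedances`` spine-specific events,
    ``dendritic_only`` when only shaft events exist, else ``none``.
    Dendrites present in the table with zero rows cannot be represented;
    the events writer emits all dendrites it analyzed, so absence of rows
    means no events.
    """
    records = []
    for dend, sub in events.groupby("dendrite_id", sort=True):
        spine_counts = (
            sub[sub["source"] == "spine_specific"].groupby("roi_id").size()
        )
        if (spine_counts >= params.active_spine_min_exceedances).any():
            cls = DendriteClass.DENDRITIC_PLUS_SYNAPTIC
        elif (sub["source"] == "shaft").any():
            cls = DendriteClass.DENDRITIC_ONLY
        else:
            cls = DendriteClass.NONE
        records.append({"dendrite_id": dend, "classification": cls.value})
    return pd.DataFrame(records, columns=["dendrite_id", "classification"])


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def _stage(name: str, detail: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed on {detail}: {exc}") from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full synthetic experiment and write a run directory.

    Per condition: simulate dendrite trace sets and classify them; simulate
    longitudinal populations and compute 2-day turnover.  Across
    conditions: Fisher exact on the classification contingency table,
    Kruskal–Wallis on interval rates, and Steel's test against the control
    condition when one is named.  Returns the manifest (also written to
    ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.sha256()
    header = f"# config_sha256={cfg_hash} seed={config.seed}\n"
    root_ss = np.random.SeedSequence(config.seed)
    cond_streams = dict(zip([c.label for c in config.conditions], root_ss.spawn(len(config.conditions))))
    outputs: list[str] = []
    results: dict = {"config_sha256": cfg_hash, "seed": config.seed}

    def write_csv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
        outputs.append(name)

    # ---- calcium stage ----------------------------------------------------
    if config.run_calcium:
        class_rows = []
        classes, labels = [], []
        for cond in config.conditions:
            streams = cond_streams[cond.label].spawn(
                config.n_dendrites_per_condition + 1
            )
            for i in range(config.n_dendrites_per_condition):
                params = SimParams(**cond.sim).with_(seed=_sub_seed(streams[i]))
                with _stage("simulate_traces", f"condition {cond.label!r} dendrite {i}"):
                    traces, _ = simulate_trace_set(params)
                with _stage("classify", f"condition {cond.label!r} dendrite {i}"):
                    cls = classify_dendrite(traces, config.detection)
                classes.append(cls)
                labels.append(cond.label)
                class_rows.append(
                    {
                        "condition": cond.label,
                        "dendrite_id": f"{cond.label}_{i:03d}",
                        "classification": cls.value,
                    }
                )
        write_csv(pd.DataFrame(class_rows), "classification.csv")
        table = summarize_classification(classes, labels)
        pct = classification_percentages(table)
        contingency = {
            "config_sha256": cfg_hash,
            "seed": config.seed,
            "counts": {c: table[c].to_dict() for c in table.columns},
            "percentages": {c: pct[c].to_dict() for c in pct.columns},
        }
        write_results(contingency, out / "contingency.json")
        outputs.append("contingency.json")
        results["n_dendrites"] = len(classes)
        if len(config.conditions) >= 2:
            with _stage("fisher_exact", "classification contingency table"):
                fisher = fisher_exact_rc(
                    table.to_numpy(), seed=_sub_seed(root_ss.spawn(1)[0])
                )
            results["fisher"] = {
                "p_value": fisher.p_value,
                "settings": fisher.settings,
            }

    # ---- turnover stage ---------------------------------------------------
    if config.run_turnover:
        turnover_rows = []
        rates_by_cond: dict[str, dict[str, list[float]]] = {}
        summaries = {}
        for cond in config.conditions:
            streams = cond_streams[cond.label].spawn(
                config.n_populations_per_condition + 1000
            )
            gen_rates, elim_rates = [], []
            intervals_all = []
            for i in range(config.n_populations_per_condition):
                params = SimParams(**cond.sim).with_(
                    seed=_sub_seed(streams[500 + i])
                )
                with _stage("simulate_population", f"condition {cond.label!r} series {i}"):
                    sessions, _ = simulate_spine_population(params)
                with _stage("turnover", f"condition {cond.label!r} series {i}"):
                    intervals = turnover_over_sessions(
                        sessions, config.matching_tolerance_um
                    )
                logger.info(
                    "condition %s series %d: %d intervals", cond.label, i, len(intervals)
                )
                for k, iv in enumerate(intervals):
                    turnover_rows.append(
                        {
                            "condition": cond.label,
                            "dendrite_id": f"{cond.label}_{i:03d}",
                            "interval_start_day": 1 + 2 * k,
                            "n_before": iv.n_before,
                            "n_after": iv.n_after,
                            "n_generated": iv.n_generated,
                            "n_eliminated": iv.n_eliminated,
                            "gen_rate_pct": iv.gen_rate_pct,
                            "elim_rate_pct": iv.elim_rate_pct,
                        }
                    )
                    gen_rates.append(iv.gen_rate_pct)
                    elim_rates.append(iv.elim_rate_pct)
                intervals_all.extend(intervals)
            rates_by_cond[cond.label] = {"gen": gen_rates, "elim": elim_rates}
            g = aggregate_group(intervals_all)
            summaries[cond.label] = {
                "mean_gen_pct": g.mean_gen_pct,
                "sem_gen_pct": g.sem_gen_pct,
                "mean_elim_pct": g.mean_elim_pct,
                "sem_elim_pct": g.sem_elim_pct,
                "n_intervals": g.n_intervals,
            }
        write_csv(pd.DataFrame(turnover_rows), "turnover.csv")
        write_results(
            {"config_sha256": cfg_hash, "seed": config.seed, "groups": summaries},
            out / "group_summaries.json",
        )
        outputs.append("group_summaries.json")
        results["group_summaries"] = summaries

        if len(config.conditions) >= 2:
            for which in ("gen", "elim"):
                groups = [rates_by_cond[c.label][which] for c in config.conditions]
                with _stage("kruskal_wallis", f"{which} rates"):
                    kw = kruskal_wallis(groups)
                results[f"kruskal_wallis_{which}"] = {
                    "H": kw.statistic,
                    "p_value": kw.p_value,
                }
            if config.control_label is not None and len(config.conditions) >= 2:
                control = config.control_label
                treat_labels = [
                    c.label for c in config.conditions if c.label != control
                ]
                for which in ("gen", "elim"):
                    with _stage("steel_test", f"{which} rates vs {control}"):
                        st = steel_test(
                            rates_by_cond[control][which],
                            [rates_by_cond[t][which] for t in treat_labels],
                            alpha=config.alpha,
                            n_mc=config.n_mc,
                            seed=_sub_seed(cond_streams[control].spawn(1)[0]),
                        )
                    results[f"steel_{which}"] = {
                        "treatments": treat_labels,
                        "adjusted_p": st.adjusted_p,
                        "statistic": st.statistic,
                    }

    write_results(results, out / "stats.json")
    outputs.append("stats.json")
    manifest = {
        "config": config.to_dict(),
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "spinedyn_version": __version__,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
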