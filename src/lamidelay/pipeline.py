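"""End-to-end driver: generation/ingest -> delays -> controls -> inference.

The pipeline mirrors the analysis sequence of a laminar propagation study:
epoch-limited next-spike delay matrices per animal and regime, collapse of
the two spike hemispheres, triangle and interhemispheric summaries, the
label-shuffle rate control (evoked activity), animal-level bootstrap
contrasts, upward-velocity fits, and layer-vs-depth Bayes factors. Every
run is reproducible bit-for-bit at the serialized-output level from
(config, seed); outputs embed the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .delays import (
    DEFAULT_MAX_DELAY_MS,
    average_matrices,
    collapse_references,
    delay_matrices,
    delay_ratio,
    summarize,
)
from .io import config_hash, write_events, write_json
from .propagate import bayes_factors, fit_velocities
from .resample import bootstrap_diff, shuffle_labels
from .synthgen import ScenarioConfig, generate_events, paper_like_config
from .types import DelayMatrix, LayerGeometry

REGIMES = ("evoked", "spontaneous")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    scenario_evoked: ScenarioConfig | None = None
    scenario_spontaneous: ScenarioConfig | None = None
    events_paths: dict[str, str] | None = None  # regime -> TSV, bypasses synthesis
    max_delay_ms: float = DEFAULT_MAX_DELAY_MS
    n_shuffles: int = 1000
    n_boot: int = 5000
    geometry: LayerGeometry = field(default_factory=LayerGeometry)
    write_event_tables: bool = False

    def scenarios(self) -> dict[str, ScenarioConfig]:
        ev = self.scenario_evoked or paper_like_config("evoked", seed=self.seed)
        sp = self.scenario_spontaneous or paper_like_config("spontaneous", seed=self.seed)
        ev = dataclasses.replace(ev, seed=self.seed)
        sp = dataclasses.replace(sp, seed=self.seed)
        return {"evoked": ev, "spontaneous": sp}


@dataclass
class RunReport:
    """All pipeline results plus provenance."""

    per_animal_matrices: dict  # (regime, animal) -> {"same": DelayMatrix, "other": DelayMatrix}
    grand_matrices: dict  # regime -> {"same": DelayMatrix, "other": DelayMatrix}
    summaries: dict  # regime -> per-animal list of DelaySummary
    shuffle_ratios: dict  # animal -> (mean ratio_same, mean ratio_other)
    bootstrap: dict  # contrast name -> BootstrapResult
    velocities: pd.DataFrame
    bayes: pd.DataFrame
    provenance: dict
    timings_s: dict


def _shuffle_seed(seed: int, animal: int) -> int:
    return int((seed * 100003 + 7919 * animal + 1) % (2**31))


def _mean(values: list[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return float(np.nanmean(arr)) if arr.size else float("nan")


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunReport:
    """Execute all analysis stages; optionally write artifacts to ``out_dir``."""
    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    scenarios = config.scenarios()

    # ---- stage: acquire events -------------------------------------------
    events_by_regime: dict[str, pd.DataFrame] = {}
    if config.events_paths:
        from .io import read_events

        for regime, path in config.events_paths.items():
            events_by_regime[regime] = read_events(path)
    else:
        for regime, scen in scenarios.items():
            events_by_regime[regime], _ = generate_events(scen)
    timings["events"] = time.perf_counter() - t0

    animals = sorted(
        set().union(*(set(ev["animal_id"].unique()) for ev in events_by_regime.values()))
    )

    # ---- stage: delay matrices + summaries -------------------------------
    t1 = time.perf_counter()
    per_animal: dict = {}
    summaries: dict[str, list] = {r: [] for r in events_by_regime}
    for regime, events in events_by_regime.items():
        for animal in animals:
            ev = events[events["animal_id"] == animal]
            mats = delay_matrices(ev, config.max_delay_ms)
            same = collapse_references(mats[("contra", "same_S1")], mats[("ipsi", "same_S1")])
            other = collapse_references(mats[("contra", "other_S1")], mats[("ipsi", "other_S1")])
            per_animal[(regime, animal)] = {"same": same, "other": other}
            summaries[regime].append(summarize(same, other))
    grand = {
        regime: {
            ref: average_matrices([per_animal[(regime, a)][ref] for a in animals])
            for ref in ("same", "other")
        }
        for regime in events_by_regime
    }
    timings["delays"] = time.perf_counter() - t1

    # ---- stage: shuffle rate control (evoked) ----------------------------
    t2 = time.perf_counter()
    shuffle_ratios: dict[int, tuple[float, float]] = {}
    if "evoked" in events_by_regime and config.n_shuffles > 0:
        events = events_by_regime["evoked"]
        for animal in animals:
            ev = events[events["animal_id"] == animal]
            res = shuffle_labels(
                ev,
                n_shuffles=config.n_shuffles,
                seed=_shuffle_seed(config.seed, animal),
                max_delay_ms=config.max_delay_ms,
            )
            shuffle_ratios[animal] = (
                float(np.nanmean(res.ratio_same)),
                float(np.nanmean(res.ratio_other)),
            )
    timings["shuffle"] = time.perf_counter() - t2

    # ---- stage: bootstrap contrasts --------------------------------------
    t3 = time.perf_counter()
    boot: dict = {}
    bseed = int(config.seed % (2**31))

    def contrast(name: str, a: list[float], b: list[float]) -> None:
        a = np.asarray(a, float)
        b = np.asarray(b, float)
        if len(a) >= 2 and np.isfinite(a).all() and np.isfinite(b).all():
            boot[name] = bootstrap_diff(a, b, n_boot=config.n_boot, seed=bseed)

    for regime, summ in summaries.items():
        contrast(
            f"{regime}_upward_vs_downward",
            [s.upward_mean_ms for s in summ],
            [s.downward_mean_ms for s in summ],
        )
        contrast(
            f"{regime}_other_superficial_vs_deep",
            [s.superficial_mean_ms for s in summ],
            [s.deep_mean_ms for s in summ],
        )
    if shuffle_ratios and "evoked" in summaries:
        contrast(
            "evoked_ratio_vs_shuffled_same",
            [s.delay_ratio_same for s in summaries["evoked"]],
            [shuffle_ratios[a][0] for a in animals],
        )
        contrast(
            "evoked_ratio_vs_shuffled_other",
            [s.delay_ratio_other for s in summaries["evoked"]],
            [shuffle_ratios[a][1] for a in animals],
        )
    if shuffle_ratios and "spontaneous" in summaries:
        contrast(
            "spontaneous_ratio_vs_shuffled_same",
            [s.delay_ratio_same for s in summaries["spontaneous"]],
            [shuffle_ratios[a][0] for a in animals],
        )
    if set(summaries) >= {"evoked", "spontaneous"}:
        contrast(
            "spontaneous_vs_evoked_upward",
            [s.upward_mean_ms for s in summaries["spontaneous"]],
            [s.upward_mean_ms for s in summaries["evoked"]],
        )
    timings["bootstrap"] = time.perf_counter() - t3

    # ---- stage: velocities and Bayes factors -----------------------------
    t4 = time.perf_counter()
    vel_rows = []
    bf_rows = []
    for (regime, animal), mats in per_animal.items():
        for ref_key, ref_name in (("same", "same_S1"), ("other", "other_S1")):
            mat: DelayMatrix = mats[ref_key]
            for fit in fit_velocities(mat, config.geometry):
                vel_rows.append(
                    {
                        "regime": regime,
                        "animal_id": animal,
                        "reference": ref_name,
                        "spike_layer": fit.spike_layer,
                        "slope_ms_per_mm": fit.slope_ms_per_mm,
                        "velocity_m_per_s": fit.velocity_m_per_s,
                        "n_points": fit.n_points,
                    }
                )
            for bf in bayes_factors(mat, config.geometry):
                bf_rows.append(
                    {
                        "regime": regime,
                        "animal_id": animal,
                        "reference": ref_name,
                        "spike_layer": bf.spike_layer,
                        "bic_layer": bf.bic_layer,
                        "bic_depth": bf.bic_depth,
                        "bf": bf.bf,
                    }
                )
    velocities = pd.DataFrame(vel_rows)
    bayes = pd.DataFrame(bf_rows)
    timings["propagate"] = time.perf_counter() - t4
    timings["total"] = time.perf_counter() - t0

    provenance = {
        "seed": config.seed,
        "version": __version__,
        "n_animals": len(animals),
        "max_delay_ms": config.max_delay_ms,
        "n_shuffles": config.n_shuffles,
        "n_boot": config.n_boot,
        "config_hash": config_hash(
            {
                "scenarios": {r: dataclasses.asdict(s) for r, s in scenarios.items()},
                "max_delay_ms": config.max_delay_ms,
                "n_shuffles": config.n_shuffles,
                "n_boot": config.n_boot,
                "seed": config.seed,
            }
        ),
        "event_counts": {r: int(len(ev)) for r, ev in events_by_regime.items()},
    }

    report = RunReport(
        per_animal_matrices=per_animal,
        grand_matrices=grand,
        summaries=summaries,
        shuffle_ratios=shuffle_ratios,
        bootstrap=boot,
        velocities=velocities,
        bayes=bayes,
        provenance=provenance,
        timings_s=timings,
    )
    if out_dir is not None:
        write_report(report, out_dir, events_by_regime if config.write_event_tables else None)
    return report


def report_dict(report: RunReport) -> dict:
    """JSON-serialisable digest of a run (grand averages and inference)."""
    out: dict = {"provenance": report.provenance}
    for regime, summ in report.summaries.items():
        out[regime] = {
            "upward_mean_ms": _mean([s.upward_mean_ms for s in summ]),
            "downward_mean_ms": _mean([s.downward_mean_ms for s in summ]),
            "other_deep_mean_ms": _mean([s.deep_mean_ms for s in summ]),
            "other_superficial_mean_ms": _mean([s.superficial_mean_ms for s in summ]),
            "delay_ratio_same": _mean([s.delay_ratio_same for s in summ]),
            "delay_ratio_other": _mean([s.delay_ratio_other for s in summ]),
        }
    if report.shuffle_ratios:
        out["shuffled"] = {
            "delay_ratio_same": _mean([v[0] for v in report.shuffle_ratios.values()]),
            "delay_ratio_other": _mean([v[1] for v in report.shuffle_ratios.values()]),
        }
    out["bootstrap"] = {
        name: {
            "mean_difference": r.mean_difference,
            "ci_95": list(r.ci_95),
            "significant": r.significant,
            "n_boot": r.n_boot,
        }
        for name, r in report.bootstrap.items()
    }
    if len(report.velocities):
        vel = (
            report.velocities.groupby(["regime", "reference"])["velocity_m_per_s"]
            .mean()
            .to_dict()
        )
        out["velocity_m_per_s"] = {f"{r}_{ref}": v for (r, ref), v in vel.items()}
    if len(report.bayes):
        bf = (
            report.bayes.groupby(["regime", "reference", "spike_layer"])["bf"]
            .mean()
            .to_dict()
        )
        out["mean_bf"] = {f"{r}_{ref}_L{s}": v for (r, ref, s), v in bf.items()}
    return out


def write_report(
    report: RunReport,
    out_dir: str | Path,
    events_by_regime: dict[str, pd.DataFrame] | None = None,
) -> None:
    """Serialise all artifacts (TSV/CSV/JSON) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = []
    for (regime, animal), mats in sorted(report.per_animal_matrices.items()):
        for mat in mats.values():
            d = mat.to_long()
            d.insert(0, "regime", regime)
            d.insert(1, "animal_id", animal)
            long.append(d)
    for regime, mats in sorted(report.grand_matrices.items()):
        for mat in mats.values():
            d = mat.to_long()
            d.insert(0, "regime", regime)
            d.insert(1, "animal_id", -1)  # grand average
            long.append(d)
    if long:
        pd.concat(long, ignore_index=True).to_csv(
            out / "delay_matrices.tsv", sep="\t", index=False, float_format="%.6f"
        )
    if len(report.velocities):
        report.velocities.to_csv(out / "velocities.csv", index=False, float_format="%.6f")
    if len(report.bayes):
        report.bayes.to_csv(out / "bayes_factors.csv", index=False, float_format="%.6f")
    write_json(report_dict(report), out / "report.json")
    if events_by_regime:
        for regime, ev in events_by_regime.items():
            write_events(ev, out / f"events_{regime}.tsv")
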