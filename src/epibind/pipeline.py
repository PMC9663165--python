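"""End-to-end orchestration and group statistics.

``group_compare`` runs a classical fixed-effects one-way ANOVA with
Bonferroni-adjusted pairwise comparisons; ``percent_change`` expresses a
treatment effect as percent reduction versus control; ``run_pipeline``
executes configured simulate/analyse stages in order, deterministically,
and writes a manifest tying every output to its config entry and seed.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import binding, imaging, synthetic

__all__ = ["ComparisonReport", "group_compare", "percent_change",
           "run_pipeline"]


@dataclass(frozen=True)
class ComparisonReport:
    """One-way ANOVA with Bonferroni post hoc pairwise tests."""

    group_means: dict[str, float]
    group_sems: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    pairwise: dict[tuple[str, str], float]          # raw p
    pairwise_adjusted: dict[tuple[str, str], float]  # Bonferroni, capped at 1


def group_compare(groups: dict[str, np.ndarray]) -> ComparisonReport:
    """Classical one-way ANOVA across named groups.

    Pairwise two-sample t-test p-values are Bonferroni-multiplied by the
    number of comparisons and capped at 1.  Every group needs >= 2
    observations for variance estimation.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    values = list(arrays.values())
    f_stat, p = stats.f_oneway(*values)
    n_total = sum(v.size for v in values)
    if not np.isfinite(f_stat):  # all values identical across groups
        f_stat, p = 0.0, 1.0
    names = list(arrays)
    pairs = list(itertools.combinations(names, 2))
    raw, adjusted = {}, {}
    for a, b in pairs:
        _, pv = stats.ttest_ind(arrays[a], arrays[b])
        if not np.isfinite(pv):
            pv = 1.0
        raw[(a, b)] = float(pv)
        adjusted[(a, b)] = float(min(1.0, pv * len(pairs)))
    return ComparisonReport(
        group_means={k: float(v.mean()) for k, v in arrays.items()},
        group_sems={k: float(stats.sem(v)) for k, v in arrays.items()},
        group_ns={k: int(v.size) for k, v in arrays.items()},
        f_statistic=float(f_stat),
        df_between=len(arrays) - 1,
        df_within=n_total - len(arrays),
        p_value=float(p),
        pairwise=raw,
        pairwise_adjusted=adjusted,
    )


def percent_change(treated_mean: float, control_mean: float) -> float:
    """Percent reduction vs control: 100 * (1 - treated/control)."""
    if control_mean <= 0:
        raise ValueError("control mean must be > 0")
    return 100.0 * (1.0 - treated_mean / control_mean)


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_SIM_STAGES = {"simulate_flow", "simulate_titration", "simulate_image",
               "simulate_spines", "simulate_screen"}
_ANALYSIS_STAGES = {"gate_percent", "fit_hill", "classify", "continuity",
                    "puncta", "spines", "compare_groups"}


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute configured stages in order and write CSV/JSON outputs.

    ``config`` is ``{"seed": int, "stages": [{"name": ..., "stage": ...,
    "params": {...}, "input": <name of an upstream stage>}, ...]}``.
    Stage outputs land in ``out_dir`` as ``<name>.csv`` / ``<name>.json``;
    a ``manifest.json`` records the config hash, seed and per-stage files.
    Identical config + seed gives byte-identical outputs.  Unknown stages
    or dangling ``input`` references fail before anything runs.
    """
    out_dir = Path(out_dir)
    stages = config.get("stages", [])
    seed = int(config.get("seed", 0))
    known: set[str] = set()
    for st in stages:
        if st["stage"] not in _SIM_STAGES | _ANALYSIS_STAGES:
            raise ValueError(f"unknown stage {st['stage']!r}")
        if "input" in st and st["input"] not in known:
            raise ValueError(
                f"stage {st['name']!r} depends on missing input "
                f"{st['input']!r}")
        known.add(st["name"])

    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, object] = {}
    manifest = {"config_hash": _config_hash(config), "seed": seed,
                "stages": []}

    for st in stages:
        name, stage = st["name"], st["stage"]
        params = dict(st.get("params", {}))
        files: list[str] = []

        if stage == "simulate_flow":
            p = synthetic.FlowSimParams(seed=params.pop("seed", seed), **params)
            table, truth = synthetic.gen_flow_events(p)
            results[name] = table
            table.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "simulate_titration":
            params.setdefault("seed", seed)
            if "concentrations" in params:
                params["concentrations"] = tuple(params["concentrations"])
            p = synthetic.TitrationSimParams(**params)
            table, _ = synthetic.gen_titration(p)
            results[name] = table
            table.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "simulate_image":
            params.setdefault("seed", seed)
            if "shape" in params:
                params["shape"] = tuple(params["shape"])
            p = synthetic.DendriteSimParams(**params)
            channels, paths, truth = synthetic.gen_dendrite_image(p)
            results[name] = (channels, paths, p)
        elif stage == "simulate_spines":
            params.setdefault("seed", seed)
            p = synthetic.SpineSimParams(**params)
            table, _ = synthetic.gen_spine_counts(p)
            results[name] = table
            table.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "simulate_screen":
            truth_table = params["truth"]
            table, _ = synthetic.gen_mutant_screen(
                truth_table, cv_noise=params.get("cv_noise", 0.0),
                seed=params.get("seed", seed))
            results[name] = table
            table.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "gate_percent":
            events = results[st["input"]]
            gate = binding.GateSpec(**params)
            counts = binding.gate_events(events, gate)
            report = {"percent_bound": binding.percent_bound(counts),
                      "n_total": counts.n_total,
                      "n_double_positive": counts.n_double_positive}
            results[name] = report
            (out_dir / f"{name}.json").write_text(json.dumps(report, indent=2))
            files.append(f"{name}.json")
        elif stage == "fit_hill":
            fit = binding.fit_hill(results[st["input"]])
            report = {"bmax": fit.bmax, "ec50_nM": fit.kd, "h": fit.h,
                      "rss": fit.rss, "converged": fit.converged}
            results[name] = report
            (out_dir / f"{name}.json").write_text(json.dumps(report, indent=2))
            files.append(f"{name}.json")
        elif stage == "classify":
            calls = binding.classify_losses(results[st["input"]], **params)
            frame = binding.losses_to_frame(calls)
            results[name] = frame
            frame.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "continuity":
            channels, paths, p = results[st["input"]]
            binary = imaging.threshold_channel(
                imaging.subtract_background(
                    channels["MAP2"], params.get("radius", 50)).astype(np.uint8),
                params.get("threshold", "otsu"))
            rows = []
            for i, path in enumerate(paths):
                prof = imaging.sample_profile(binary, path)
                sc = imaging.map2_continuity(prof, path_id=i,
                                             pixel_size_um=p.pixel_size_um)
                rows.append((i, sc.score, sc.auc, sc.n_samples, sc.length_um))
            frame = pd.DataFrame(rows, columns=["path_id", "continuity",
                                                "auc", "n_samples",
                                                "length_um"])
            results[name] = frame
            frame.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "puncta":
            channels, paths, p = results[st["input"]]
            marker = params.get("marker", "PSD95")
            binary = imaging.threshold_channel(
                imaging.subtract_background(
                    channels[marker], params.get("radius", 50)).astype(np.uint8),
                params.get("threshold", "otsu"))
            puncta = imaging.detect_puncta(binary)
            rows = []
            for i, path in enumerate(paths):
                rec = imaging.puncta_density(puncta, path, p.pixel_size_um,
                                             marker=marker, path_id=i)
                rows.append((i, marker, rec.count, rec.length_um,
                             rec.density_per_um))
            frame = pd.DataFrame(rows, columns=["path_id", "marker", "count",
                                                "length_um", "density_per_um"])
            results[name] = frame
            frame.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "spines":
            per_neuron, per_group = imaging.spine_density(results[st["input"]])
            results[name] = per_neuron
            per_neuron.to_csv(out_dir / f"{name}.csv", index=False)
            files.append(f"{name}.csv")
        elif stage == "compare_groups":
            frame = results[st["input"]]
            col = params.get("value_column", "density_per_um")
            groups = {g: sub[col].to_numpy()
                      for g, sub in frame.groupby(params.get("group_column",
                                                             "group"))}
            rep = group_compare(groups)
            report = {
                "means": rep.group_means, "sems": rep.group_sems,
                "f": rep.f_statistic, "p": rep.p_value,
                "pairwise_adjusted": {f"{a}|{b}": v for (a, b), v
                                      in rep.pairwise_adjusted.items()},
            }
            control = params.get("control")
            if control is not None:
                for g, m in rep.group_means.items():
                    if g != control:
                        report[f"percent_change_{g}"] = percent_change(
                            m, rep.group_means[control])
            results[name] = report
            (out_dir / f"{name}.json").write_text(json.dumps(report, indent=2))
            files.append(f"{name}.json")

        manifest["stages"].append({"name": name, "stage": stage,
                                   "files": files})

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return results
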