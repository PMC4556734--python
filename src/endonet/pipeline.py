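"""End-to-end pipeline: simulate -> preprocess -> connect -> metrics -> QC -> stats.

A single :class:`RunConfig` drives all stages for each experimental
condition. Every random stage consumes a seed derived deterministically
from the master seed and the stage name, so identical configs yield
byte-identical reports and changing, say, the permutation count never
perturbs cohort generation. When the filter includes a low-pass, a paired
run without it can be executed to check robustness of the findings to that
preprocessing choice.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import stage_seed
from .cohort import (
    CohortDesign,
    SubjectRecord,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .connectivity import correlation_matrix, mean_connectivity, proportional_threshold
from .metrics import (
    clustering_coefficient,
    global_efficiency,
    group_template,
    hub_profile,
    network_block_weights,
    node_disruption_index,
    node_strengths,
    normalize_metric,
    null_ensemble,
)
from .motion import (
    distance_profile,
    edgewise_motion_correlation,
    motion_summary,
    permutation_null,
)
from .parcellation import ANALYZED_NETWORKS, Parcellation, load_default_parcellation
from .preprocess import FilterSpec, preprocess_timeseries
from .stats import endophenotype_pattern

SCALAR_METRICS = ("mean_connectivity", "C_raw", "C_norm", "E_raw", "E_norm", "ndi")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of a full pipeline run.

    Defaults follow the analysis conventions: 20% edge density, 20% hub
    fraction, 100-network null ensembles, 100 QC permutations, alpha 0.05.
    """

    design: CohortDesign = field(default_factory=CohortDesign)
    parcellation: Parcellation | None = None
    conditions: tuple[str, ...] = ("rest",)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    density: float = 0.2
    hub_fraction: float = 0.2
    n_null: int = 100
    n_permutations: int = 100
    motion_scalar: str = "max_fd"
    mean_mode: str = "retained"
    alpha: float = 0.05
    seed: int = 0
    output_dir: str | None = None
    compare_no_lowpass: bool = False


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return repr(obj)
    return obj


def _config_echo(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["design"]["global_coupling"] = dict(config.design.global_coupling)
    out["parcellation"] = (
        "default_258" if config.parcellation is None else "custom"
    )
    return _jsonify(out)


def _get_cohort(
    config: RunConfig, parc: Parcellation, condition: str
) -> list[SubjectRecord]:
    """Generate the condition's cohort, or reuse a cached one on disk."""
    seed = stage_seed(config.seed, f"cohort:{condition}")
    design = replace(config.design, seed=seed, condition=condition)
    if config.output_dir is not None:
        cohort_dir = Path(config.output_dir) / f"cohort_{condition}"
        manifest = cohort_dir / "manifest.json"
        if manifest.exists():
            cached = json.loads(manifest.read_text())
            if cached.get("seed") == seed:
                return read_cohort(cohort_dir)[0]
        subjects = generate_cohort(parc, design)
        write_cohort(cohort_dir, subjects, parc, design)
        # consume the cohort as written so that cached reruns are identical
        return read_cohort(cohort_dir)[0]
    return generate_cohort(parc, design)


def subject_metrics(
    subject: SubjectRecord,
    parc: Parcellation,
    config: RunConfig,
    filter_spec: FilterSpec,
    null_seed: int,
) -> dict:
    """All per-subject quantities except NDI (which needs the group template)."""
    confound_base = subject.realignment
    if "confounds" in subject.truth:
        confound_base = np.hstack([confound_base, subject.truth["confounds"]])
    clean = preprocess_timeseries(subject.timeseries, confound_base, filter_spec)
    fc = correlation_matrix(clean)
    net = proportional_threshold(fc, config.density)
    strengths = node_strengths(net)
    row: dict = {
        "subject_id": subject.subject_id,
        "group": subject.group,
        "condition": subject.condition,
        "mean_connectivity": mean_connectivity(net, config.mean_mode),
    }
    if config.n_null > 0:
        ensemble = null_ensemble(net, config.n_null, null_seed)
        c = normalize_metric(clustering_coefficient, net, ensemble)
        e = normalize_metric(global_efficiency, net, ensemble)
        row.update(C_raw=c.raw, C_norm=c.normalized, E_raw=e.raw, E_norm=e.normalized)
    else:
        row.update(
            C_raw=clustering_coefficient(net),
            C_norm=float("nan"),
            E_raw=global_efficiency(net),
            E_norm=float("nan"),
        )
    hubs = hub_profile(net, parc, config.hub_fraction)
    for network in ANALYZED_NETWORKS:
        if network in hubs.counts:
            row[f"hubs_{network}"] = hubs.counts[network]
    blocks = network_block_weights(net, parc)
    for network, vals in blocks.iterrows():
        row[f"intra_{network}"] = vals["intra"]
        row[f"inter_{network}"] = vals["inter"]
    row["_strengths"] = strengths
    row["_fc_upper"] = fc.values[np.triu_indices(parc.n_nodes, k=1)]
    return row


def _qc_block(
    subjects: Sequence[SubjectRecord],
    rows: list[dict],
    parc: Parcellation,
    config: RunConfig,
    condition: str,
) -> dict:
    summaries = [motion_summary(s.realignment) for s in subjects]
    motion = np.array([m.scalar(config.motion_scalar) for m in summaries])
    fc_stack = np.vstack([row["_fc_upper"] for row in rows])
    distances = parc.distance_matrix()[np.triu_indices(parc.n_nodes, k=1)]
    edge_r = edgewise_motion_correlation(fc_stack, motion)
    profile = distance_profile(edge_r, distances)
    perm = permutation_null(
        fc_stack,
        motion,
        distances,
        n_perm=config.n_permutations,
        seed=stage_seed(config.seed, f"qc:{condition}"),
    )
    return {
        "per_subject": [
            {
                "subject_id": s.subject_id,
                "mean_fd": m.mean_fd,
                "max_fd": m.max_fd,
                "max_spike": m.max_spike,
            }
            for s, m in zip(subjects, summaries)
        ],
        "motion_scalar": config.motion_scalar,
        "mean_r": profile.mean_r,
        "slope_per_m": profile.slope_per_m,
        "p_mean": perm.p_mean,
        "p_slope": perm.p_slope,
        "n_permutations": perm.n_permutations,
        "moving_average": {
            "distance_mm": profile.distances,
            "value": profile.moving_average,
        },
    }


def _stats_block(rows: list[dict], config: RunConfig) -> list[dict]:
    frame = pd.DataFrame([{k: v for k, v in r.items() if not k.startswith("_")} for r in rows])
    metrics = [m for m in SCALAR_METRICS if m in frame.columns]
    metrics += [c for c in frame.columns if c.startswith(("hubs_", "intra_", "inter_"))]
    out = []
    for metric in metrics:
        sub = frame[["group", metric]].dropna()
        sample = {g: sub.loc[sub["group"] == g, metric].to_numpy() for g in ("CON", "SIB", "ASC")}
        if any(v.size < 2 for v in sample.values()):
            continue
        if any(np.ptp(v) == 0 for v in sample.values()) and metric.startswith(
            ("C_norm", "E_norm")
        ):
            continue
        pattern = endophenotype_pattern(sample, config.alpha)
        out.append(
            {
                "metric": metric,
                "F": pattern.anova.F,
                "df_between": pattern.anova.df_between,
                "df_within": pattern.anova.df_within,
                "p": pattern.anova.p,
                "t_ASC_CON": pattern.t_asc_con.t,
                "p_ASC_CON": pattern.t_asc_con.p,
                "t_SIB_CON": pattern.t_sib_con.t,
                "p_SIB_CON": pattern.t_sib_con.p,
                "pattern": pattern.label,
                "means": pattern.means,
            }
        )
    return out


def _run_one_filter(
    config: RunConfig, parc: Parcellation, filter_spec: FilterSpec
) -> dict:
    conditions_report: dict = {}
    per_condition_mean_fc: dict[str, dict[str, float]] = {}
    subject_groups: dict[str, str] = {}
    lp_tag = "lp" if filter_spec.lowpass_hz is not None else "nolp"
    for condition in config.conditions:
        subjects = _get_cohort(config, parc, condition)
        rows = []
        for i, subject in enumerate(subjects):
            null_seed = stage_seed(config.seed, f"null:{lp_tag}:{condition}:{i}")
            rows.append(subject_metrics(subject, parc, config, filter_spec, null_seed))
        # NDI against the control-group average strength template
        con_strengths = [r["_strengths"] for r in rows if r["group"] == "CON"]
        template = group_template(con_strengths)
        for row in rows:
            ndi = node_disruption_index(row["_strengths"], template, template_id="CON")
            row["ndi"] = ndi.slope
            row["ndi_intercept"] = ndi.intercept
        qc = _qc_block(subjects, rows, parc, config, condition)
        stats = _stats_block(rows, config)
        for row in rows:
            per_condition_mean_fc.setdefault(condition, {})[row["subject_id"]] = row[
                "mean_connectivity"
            ]
            subject_groups[row["subject_id"]] = row["group"]
        conditions_report[condition] = {
            "subjects": [
                {k: v for k, v in r.items() if not k.startswith("_")} for r in rows
            ],
            "qc": qc,
            "stats": stats,
            "n_tests": len(stats) * 3,  # ANOVA + two planned t-tests per metric
        }
    report = {"conditions": conditions_report}

    # collapsed-across-conditions analysis of whole-brain connectivity
    table = pd.DataFrame(per_condition_mean_fc)
    collapsed = table.mean(axis=1)
    sample = {
        g: collapsed[[s for s, gg in subject_groups.items() if gg == g]].to_numpy()
        for g in ("CON", "SIB", "ASC")
    }
    if all(v.size >= 2 for v in sample.values()):
        pattern = endophenotype_pattern(sample, config.alpha)
        report["collapsed"] = {
            "metric": "mean_connectivity",
            "F": pattern.anova.F,
            "df_between": pattern.anova.df_between,
            "df_within": pattern.anova.df_within,
            "p": pattern.anova.p,
            "t_ASC_CON": pattern.t_asc_con.t,
            "p_ASC_CON": pattern.t_asc_con.p,
            "t_SIB_CON": pattern.t_sib_con.t,
            "p_SIB_CON": pattern.t_sib_con.p,
            "pattern": pattern.label,
            "means": pattern.means,
        }
    if len(config.conditions) >= 2:
        from .stats import condition_correlation

        r, p = condition_correlation(table)
        report["condition_correlation"] = {
            "r": r.to_dict(),
            "p": p.to_dict(),
        }
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return (and optionally write) the report."""
    parc = (
        config.parcellation
        if config.parcellation is not None
        else load_default_parcellation()
    )
    report: dict = {"config": _config_echo(config)}
    main = _run_one_filter(config, parc, config.filter_spec)
    if config.compare_no_lowpass and config.filter_spec.lowpass_hz is not None:
        no_lp = replace(config.filter_spec, lowpass_hz=None)
        report["lowpass_on"] = main
        report["lowpass_off"] = _run_one_filter(config, parc, no_lp)
    else:
        report.update(main)
    report = _jsonify(report)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        _write_tables(report, out)
    return report


def _write_tables(report: dict, out: Path) -> None:
    blocks = (
        [("", report)]
        if "conditions" in report
        else [("lowpass_on_", report.get("lowpass_on", {})), ("lowpass_off_", report.get("lowpass_off", {}))]
    )
    for prefix, block in blocks:
        for condition, payload in block.get("conditions", {}).items():
            pd.DataFrame(payload["subjects"]).to_csv(
                out / f"{prefix}subjects_{condition}.tsv", sep="\t", index=False
            )
            if payload["stats"]:
                pd.DataFrame(payload["stats"]).drop(columns=["means"]).to_csv(
                    out / f"{prefix}stats_{condition}.tsv", sep="\t", index=False
                )
            ma = payload["qc"]["moving_average"]
            pd.DataFrame(
                {"distance_mm": ma["distance_mm"], "moving_average_r": ma["value"]}
            ).to_csv(out / f"{prefix}qc_moving_average_{condition}.tsv", sep="\t", index=False)
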