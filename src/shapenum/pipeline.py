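"""End-to-end orchestration: simulate -> preprocess -> ERP statistics ->
TANOVA -> microstates -> report, reproducible from a single seed.

Two simulation routes are provided. The continuous route generates full
1 kHz multichannel recordings per subject and runs the complete
preprocessing chain; the subject-ERP route draws per-subject average ERPs
directly (evoked truth + between-subject amplitude variability + averaging
noise), which is the appropriate scale for repeated group-level power and
recovery studies.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import anova, erp, microstates, preprocess, simulate, stimuli, topography
from .montage import GroundTruth, make_ground_truth


@dataclass
class PipelineConfig:
    experiment: int = 1
    n_subjects: int = 19
    trials_per_condition: int = 100
    seed: int = 0
    mode: str = "subject_erp"            # "subject_erp" | "continuous"
    filter_low_hz: float = 0.1
    filter_high_hz: float = 30.0
    reject_threshold_uv: float = 75.0
    tanova_permutations: int = 5000
    tanova_alpha: float = 0.05
    tanova_min_duration_ms: float = 10.0
    microstate_q_range: tuple[int, int] = (1, 12)
    microstate_downsample: int = 4       # segment every n-th sample
    noise_sigma_uv: float = 8.0
    amp_scale_sd: float = 0.15
    amp_shift_sd_uv: float = 0.8
    out_dir: str | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


@dataclass
class RunReport:
    config: PipelineConfig
    behavior_anova: dict
    component_anovas: dict
    posthoc: dict
    tanova_windows: dict
    segmentation: dict
    gev_anovas: dict
    recovery: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "behavior_anova": self.behavior_anova,
            "component_anovas": self.component_anovas,
            "posthoc": self.posthoc,
            "tanova_windows": self.tanova_windows,
            "segmentation": self.segmentation,
            "gev_anovas": self.gev_anovas,
            "recovery": self.recovery,
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=_coerce)


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(type(x))


def _anova_dict(res: anova.AnovaResult) -> dict:
    return {
        name: {"F": e.F, "df_num": e.df_num, "df_den": e.df_den,
               "epsilon": e.epsilon, "p": e.p,
               "partial_eta_sq": e.partial_eta_sq}
        for name, e in res.effects.items()
    }


def simulate_subject_erps(config: PipelineConfig, gt: GroundTruth,
                          ) -> dict[int, dict[str, preprocess.SubjectERP]]:
    """Subject-ERP route: per-subject, per-condition average ERPs."""
    ss = np.random.SeedSequence(config.seed)
    t_ms = np.arange(simulate.EPOCH_TMIN_MS, simulate.EPOCH_TMAX_MS + 1)
    out: dict[int, dict[str, preprocess.SubjectERP]] = {}
    for subj, child in enumerate(ss.spawn(config.n_subjects)):
        epochs = simulate.simulate_subject_erp(
            gt, int(child.generate_state(1)[0] % 2**31),
            n_trials=config.trials_per_condition,
            sigma_uv=config.noise_sigma_uv,
            amp_scale_sd=config.amp_scale_sd,
            amp_shift_sd_uv=config.amp_shift_sd_uv,
        )
        erps = {}
        for label, data in epochs.items():
            e = preprocess.SubjectERP(subj, label, data, t_ms,
                                      list(gt.montage.ch_names), "Cz",
                                      config.trials_per_condition)
            erps[label] = preprocess.rereference_average(e)
        out[subj] = erps
    return out


def simulate_continuous_subjects(config: PipelineConfig, gt: GroundTruth,
                                 ) -> dict[int, dict[str, preprocess.SubjectERP]]:
    """Continuous route: full recordings through the preprocessing chain."""
    ss = np.random.SeedSequence(config.seed)
    out = {}
    for subj, child in enumerate(ss.spawn(config.n_subjects)):
        s1, s2 = child.spawn(2)
        sched = stimuli.build_schedule(config.experiment,
                                       config.trials_per_condition,
                                       int(s1.generate_state(1)[0] % 2**31))
        rec = simulate.simulate_recording(
            sched, gt, simulate.NoiseSpec(sigma_uv=config.noise_sigma_uv),
            int(s2.generate_state(1)[0] % 2**31))
        erps = preprocess.preprocess_subject(rec, subj)
        out[subj] = {lab: preprocess.rereference_average(e)
                     for lab, e in erps.items()}
    return out


def _condition_groups(experiment: int) -> tuple[list[str], list[str]]:
    """The two grouped TANOVA contrasts: configuration (or polarity) and
    low {3,4} vs high {5,6} numerosity."""
    conds = stimuli.conditions_for_experiment(experiment)
    labels = [c.label for c in conds]
    group_a = [l for l in labels if l.startswith("S")]
    group_b = [l for l in labels if not l.startswith("S")]
    return group_a, group_b


def run(config: PipelineConfig, gt: GroundTruth | None = None) -> RunReport:
    gt = gt or make_ground_truth(config.experiment)
    ss = np.random.SeedSequence(config.seed + 1_000_003)

    # --- behaviour
    behavior = simulate.simulate_experiment_behavior(
        config.experiment, config.n_subjects, config.trials_per_condition,
        int(ss.generate_state(1)[0] % 2**31), gt)
    beh = anova.behavior_stats(behavior)
    beh_posthoc = anova.bonferroni_posthoc(
        behavior.assign(n_elements=behavior["condition"].str[1:].astype(int))
        .groupby(["subject", "n_elements"], as_index=False)["rt_ms"].mean(),
        "rt_ms", "subject", "n_elements")

    # --- ERPs
    if config.mode == "continuous":
        erps = simulate_continuous_subjects(config, gt)
    else:
        erps = simulate_subject_erps(config, gt)
    table = erp.amplitude_table(erps)
    component_anovas, posthocs = {}, {}
    for comp in ("N1", "N2", "LMF"):
        cell = erp.component_cell_means(table, comp)
        component_anovas[comp] = _anova_dict(
            anova.rm_anova(cell, "amplitude_uv", "subject",
                           ["configuration", "n_elements"]))
        posthocs[comp] = anova.bonferroni_posthoc(
            cell, "amplitude_uv", "subject", "n_elements"
        ).to_dict(orient="records")

    # --- TANOVA
    times = next(iter(erps[0].values())).times_ms
    post = times >= 0
    ga, gb = _condition_groups(config.experiment)
    maps_a = topography.grouped_condition_maps(erps, ga)[:, post, :]
    maps_b = topography.grouped_condition_maps(erps, gb)[:, post, :]
    low = [l for l in ga + gb if int(l[1:]) in (3, 4)]
    high = [l for l in ga + gb if int(l[1:]) in (5, 6)]
    maps_low = topography.grouped_condition_maps(erps, low)[:, post, :]
    maps_high = topography.grouped_condition_maps(erps, high)[:, post, :]
    t_post = times[post]
    tan_cfg = topography.tanova(
        maps_a, maps_b, t_post, config.tanova_permutations,
        config.tanova_alpha, config.tanova_min_duration_ms,
        config.seed + 17)
    tan_num = topography.tanova(
        maps_low, maps_high, t_post, config.tanova_permutations,
        config.tanova_alpha, config.tanova_min_duration_ms, config.seed + 31)
    tanova_windows = {"configuration": tan_cfg.windows,
                      "numerosity_low_vs_high": tan_num.windows}

    # --- microstates
    step = max(1, config.microstate_downsample)
    grand = {}
    for label in ga + gb:
        g = preprocess.grand_average([erps[s][label] for s in erps])
        grand[label] = g.data[:, post].T[::step]
    seg = microstates.segment(
        grand, range(config.microstate_q_range[0],
                     config.microstate_q_range[1] + 1),
        min_segment_ms=config.tanova_min_duration_ms, sample_ms=float(step))
    fit = microstates.microstate_fit_table(erps, seg.templates, gt.windows)
    gev_anovas = {}
    for wname in gt.windows:
        try:
            gev_anovas[wname] = _anova_dict(
                microstates.microstate_anova(fit, wname))
        except anova.UnbalancedDesignError:
            gev_anovas[wname] = {}

    report = RunReport(
        config=config,
        behavior_anova={dv: _anova_dict(res) for dv, res in beh.items()},
        component_anovas=component_anovas,
        posthoc={"rt_n_elements": beh_posthoc.to_dict(orient="records"),
                 **{f"{c}_n_elements": posthocs[c] for c in posthocs}},
        tanova_windows=tanova_windows,
        segmentation=seg.summary(),
        gev_anovas=gev_anovas,
    )
    report.recovery = validate_recovery(report, gt, table, seg)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json())
        table.to_csv(out / "amplitudes.csv", index=False)
        fit.to_csv(out / "microstate_gev.csv", index=False)
        behavior.to_csv(out / "behavior.csv", index=False)
    return report


def validate_recovery(report: RunReport, gt: GroundTruth,
                      table: pd.DataFrame,
                      seg: microstates.SegmentationResult | None = None,
                      ) -> dict:
    """Compare extracted statistics against the planted ground truth:
    component effect directions, the 5-vs-6 LMF null, and (when a
    segmentation is supplied) template recovery correlations."""
    out: dict = {}
    n2 = erp.component_cell_means(table, "N2")
    lmf = erp.component_cell_means(table, "LMF")
    shape_mask = n2["configuration"] == "S"
    n2_shape = n2.loc[shape_mask, "amplitude_uv"].mean()
    n2_random = n2.loc[~shape_mask, "amplitude_uv"].mean()
    out["n2_shape_minus_random_uv"] = float(n2_shape - n2_random)
    if report.config.experiment == 3:
        # different-polarity (D) conditions carry the larger N2 negativity
        out["n2_direction_ok"] = bool(n2_random < n2_shape)
        lmf_anova = anova.rm_anova(lmf, "amplitude_uv", "subject",
                                   ["configuration", "n_elements"])
        out["lmf_polarity_p"] = float(lmf_anova["configuration"].p)
        out["lmf_polarity_null_ok"] = bool(out["lmf_polarity_p"] > 0.05)
    else:
        out["n2_direction_ok"] = bool(n2_shape < n2_random)

    lmf_means = lmf.groupby("n_elements")["amplitude_uv"].mean()
    out["lmf_means_by_n"] = {int(k): float(v) for k, v in lmf_means.items()}
    out["lmf_ordering_3_4_5"] = bool(
        lmf_means[3] > lmf_means[4] > lmf_means[5])
    ph = anova.bonferroni_posthoc(lmf, "amplitude_uv", "subject", "n_elements")
    ph = ph.set_index(["level_a", "level_b"])
    out["lmf_3v4_p_bonf"] = float(ph.loc[(3, 4), "p_bonferroni"])
    out["lmf_5v6_p_bonf"] = float(ph.loc[(5, 6), "p_bonferroni"])
    out["lmf_5v6_nonsignificant"] = bool(out["lmf_5v6_p_bonf"] > 0.05)
    out["lmf_3v4_significant"] = bool(out["lmf_3v4_p_bonf"] < 0.05)

    if seg is not None:
        from .topography import spatial_correlation

        corrs = {}
        for comp, tmpl in gt.templates.items():
            best = max(
                abs(spatial_correlation(tmpl, rec)) for rec in seg.templates
            )
            corrs[comp] = float(best)
        out["template_recovery_abs_corr"] = corrs
    return out
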