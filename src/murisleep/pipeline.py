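"""End-to-end study replica on synthetic data.

Simulate a two-group trauma cohort with EEG/EMG recordings on the study
schedule (baseline, shock day 0, day 1, day 55), score every recording
with the automatic threshold pipeline, quantify sleep architecture per
Zeitgeber phase (from both the ground-truth and the scored hypnograms,
so scoring error stays visible), normalize post-shock values to the
baseline group means, compute the behavioral endpoints, and run the
group/day statistics and REMS-continuity correlations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as msio
from .architecture import normalize_to_baseline, summarize_architecture
from .core import Hypnogram, Recording
from .staging import Thresholds, mark_microarousals, score_recording
from .stats import RMAnalysis, correlation, rm_group_day_analysis, variance_explained
from .synthetic import CohortParams, SimParams, simulate_cohort

log = logging.getLogger(__name__)

STUDY_DAYS = ("baseline", "day0", "day1", "day55")


@dataclass
class StudyConfig:
    """Everything a full synthetic-study run depends on."""

    sim: SimParams = field(default_factory=SimParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    days: tuple[str, ...] = STUDY_DAYS
    thresholds: Thresholds | None = None
    analysis_variables: tuple[str, ...] = ("occupancy_pct",)
    analysis_states: tuple[str, ...] = ("WAKE", "NREMS", "REMS")
    analysis_phase: str = "IV"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        bad = set(self.days) - set(STUDY_DAYS)
        if bad:
            raise ValueError(f"unknown study days: {sorted(bad)}")
        # one master seed drives every stage
        self.sim = self.sim.copy_with(seed=self.seed)
        object.__setattr__(self.cohort, "seed", self.seed)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimParams(**raw.get("sim", {}))
        cohort = CohortParams(**raw.get("cohort", {}))
        kwargs = {k: v for k, v in raw.items() if k not in ("sim", "cohort")}
        if "days" in kwargs:
            kwargs["days"] = tuple(kwargs["days"])
        return cls(sim=sim, cohort=cohort, **kwargs)


@dataclass
class StudyResult:
    """Outputs of one synthetic study run."""

    cohort: pd.DataFrame
    architecture: pd.DataFrame     # tidy: animal, group, day, provenance, phase, state, metric, value, normalized
    analysis_table: pd.DataFrame   # long table fed to the repeated-measures analysis
    rm_analysis: RMAnalysis | None
    correlations: pd.DataFrame
    thresholds: dict

    def report(self) -> str:
        lines = ["Synthetic PTSD sleep study", "=" * 30]
        lines.append(f"animals: {len(self.cohort)}; days: "
                     f"{sorted(self.architecture['day'].unique())}")
        lines.append("")
        lines.append("REMS-continuity correlations (baseline phase IV vs 115-dB startle):")
        for _, r in self.correlations.iterrows():
            lines.append(
                f"  {r['group']:>12s} {r['parameter']:<32s} {r['method']:>8s} "
                f"r={r['r']:+.3f} p={r['p']:.3f} r2={r['r2']:.3f}"
            )
        if self.rm_analysis is not None:
            lines.append("")
            lines.append(self.rm_analysis.summary())
        return "\n".join(lines)


def _architecture_rows(
    animal: str, group: str, day: str, hyp: Hypnogram, provenance: str,
    spectra=None,
) -> pd.DataFrame:
    df = summarize_architecture(hyp, spectra=spectra, exclude_phase_I=(day == "day0"))
    df.insert(0, "animal", animal)
    df.insert(1, "group", group)
    df.insert(2, "day", day)
    df.insert(3, "provenance", provenance)
    return df


def run_study(cfg: StudyConfig) -> StudyResult:
    """Run the full synthetic study and return (and optionally write) results."""
    log.info("simulating cohort: %d per group, days %s, seed %d",
             cfg.cohort.n_per_group, cfg.days, cfg.seed)
    table, recordings = simulate_cohort(
        cfg.cohort, cfg.sim, days=cfg.days, make_recordings=True
    )

    arch_frames = []
    thresholds: dict = {}
    scored: dict[tuple[str, str], Hypnogram] = {}
    for (animal, day), (rec, true_hyp) in recordings.items():
        group = table.loc[table["animal"] == animal, "group"].iloc[0]
        hyp4, thr, spectra = score_recording(rec, cfg.thresholds)
        scored[(animal, day)] = hyp4
        thresholds[f"{animal}/{day}"] = {
            "emg_thr": thr.emg_thr, "delta_thr": thr.delta_thr,
            "theta_thr": thr.theta_thr, "method": thr.method,
        }
        arch_frames.append(_architecture_rows(animal, group, day,
                                              mark_microarousals(true_hyp), "true"))
        arch_frames.append(_architecture_rows(animal, group, day, hyp4, "scored",
                                              spectra=spectra))
    arch = pd.concat(arch_frames, ignore_index=True)

    # baseline normalization: per group, provenance, phase, state, metric
    if "baseline" in cfg.days:
        base = (
            arch[arch["day"] == "baseline"]
            .groupby(["group", "provenance", "phase", "state", "metric"])["value"]
            .mean()
            .rename("baseline_mean")
        )
        arch = arch.join(base, on=["group", "provenance", "phase", "state", "metric"])
        arch["normalized"] = [
            normalize_to_baseline(v, b) if np.isfinite(b) and b > 0 else np.nan
            for v, b in zip(arch["value"], arch["baseline_mean"])
        ]
    else:
        arch["baseline_mean"] = np.nan
        arch["normalized"] = np.nan

    # long table for the repeated-measures analysis (scored hypnograms)
    mask = (
        (arch["provenance"] == "scored")
        & (arch["phase"] == cfg.analysis_phase)
        & (arch["metric"].isin(cfg.analysis_variables))
        & (arch["state"].isin(cfg.analysis_states))
    )
    long_tbl = arch.loc[mask, ["animal", "group", "day", "state", "metric", "value"]].copy()
    long_tbl["variable"] = long_tbl["state"] + "_" + long_tbl["metric"]
    long_tbl = long_tbl[["animal", "group", "day", "variable", "value"]]

    rm_res = None
    if len(cfg.days) >= 2 and "baseline" in cfg.days:
        try:
            rm_res = rm_group_day_analysis(long_tbl)
        except ValueError as exc:  # e.g. too few animals for the multivariate test
            log.warning("repeated-measures analysis skipped: %s", exc)

    corr_rows = []
    for group in ("shocked", "non_shocked"):
        sub = table[table["group"] == group]
        if len(sub) < 3:
            log.warning("group %s has n=%d < 3; correlation analysis skipped", group, len(sub))
            continue
        for param in ("rems_episodes_iv", "nrems_to_rems_transitions_iv"):
            for method in ("pearson", "spearman"):
                res = correlation(sub[param], sub["asr_115"], method=method)
                corr_rows.append({
                    "group": group, "parameter": param, "method": method,
                    "r": res.statistic, "p": res.p,
                    "r2": variance_explained(sub[param], sub["asr_115"])
                    if method == "pearson" else res.statistic**2,
                })
    correlations = pd.DataFrame(corr_rows)

    result = StudyResult(
        cohort=table, architecture=arch, analysis_table=long_tbl,
        rm_analysis=rm_res, correlations=correlations, thresholds=thresholds,
    )

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "cohort.csv", index=False)
        arch.to_csv(out / "architecture.csv", index=False)
        long_tbl.to_csv(out / "analysis_table.csv", index=False)
        correlations.to_csv(out / "correlations.csv", index=False)
        with open(out / "thresholds.json", "w") as fh:
            json.dump(thresholds, fh, indent=2, sort_keys=True)
        hyp_dir = out / "hypnograms"
        hyp_dir.mkdir(exist_ok=True)
        for (animal, day), hyp in scored.items():
            msio.write_hypnogram_csv(hyp, hyp_dir / f"{animal}_{day}_scored.csv")
        for (animal, day), (_, true_hyp) in recordings.items():
            msio.write_hypnogram_csv(true_hyp, hyp_dir / f"{animal}_{day}_true.csv")
        with open(out / "report.txt", "w") as fh:
            fh.write(result.report() + "\n")
        log.info("study outputs written to %s", out)
    return result
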