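"""Parameter-recovery benchmarks on calibrated synthetic data.

These routines re-measure, from scratch, the quantities the analysis is
designed to recover: baseline occupancies through the full scoring
pipeline, and the REMS-continuity/startle correlation structure from
simulated cohorts.  They are what the acceptance checks and the worked
examples run.
"""

from __future__ import annotations

import numpy as np

from .architecture import split_phases, state_occupancy
from .core import DARK_PHASES, LIGHT_PHASES
from .staging import score_recording
from .stats import correlation, fisher_z_mean, variance_explained
from .synthetic import CohortParams, SimParams, simulate_recording, simulate_cohort


def _phase_mean(hyp, phases, state) -> float:
    sl = split_phases(hyp)
    return float(np.mean([state_occupancy(sl[p], merge_ma=True)[state] for p in phases]))


def baseline_staging_benchmark(n_animals: int = 8, seed: int = 0) -> dict:
    """Simulate one 24-h baseline day per animal and score it end to end.

    Returns cohort means of light-phase NREMS/REMS and dark-phase WAKE
    occupancy (in %) from the scored hypnograms, the same quantities from
    the ground-truth hypnograms, and the mean epoch-wise scoring accuracy.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) for s in ss.spawn(n_animals)]
    scored_vals = {"light_nrems": [], "light_rems": [], "dark_wake": []}
    true_vals = {"light_nrems": [], "light_rems": [], "dark_wake": []}
    accuracy = []
    for s in seeds:
        params = SimParams(seed=s)
        rec, truth = simulate_recording(params, n_days=1)
        scored, _, _ = score_recording(rec)
        pred3 = np.where(scored.states == "MA", "WAKE", scored.states)
        accuracy.append(float(np.mean(pred3 == truth.states)))
        for key, (hyp, store) in {
            "scored": (scored, scored_vals), "true": (truth, true_vals)
        }.items():
            store["light_nrems"].append(_phase_mean(hyp, LIGHT_PHASES, "NREMS"))
            store["light_rems"].append(_phase_mean(hyp, LIGHT_PHASES, "REMS"))
            store["dark_wake"].append(_phase_mean(hyp, DARK_PHASES, "WAKE"))
    out = {f"scored_{k}": float(np.mean(v)) for k, v in scored_vals.items()}
    out.update({f"true_{k}": float(np.mean(v)) for k, v in true_vals.items()})
    out["accuracy"] = float(np.mean(accuracy))
    out["n_animals"] = n_animals
    return out


def cohort_correlation_benchmark(
    n_per_group: int = 2000, replicates: int = 20, seed: int = 0,
    cp: CohortParams | None = None,
) -> dict:
    """Recover the cohort generator's correlation structure at large n.

    Pearson correlations (episode count and NREMS-to-REMS transitions vs
    115-dB startle; shocked and control groups) are Fisher-z averaged
    over ``replicates`` independent cohorts of ``n_per_group`` animals
    per group; r-squared values derive from the averaged correlations.
    """
    base = cp if cp is not None else CohortParams()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 2)) for s in ss.spawn(replicates)]
    r_epi, r_tra, r_ctl, r_per = [], [], [], []
    for s in seeds:
        cp_rep = CohortParams(
            **{**base.__dict__, "n_per_group": n_per_group, "seed": s}
        )
        tbl, _ = simulate_cohort(cp_rep)
        sh = tbl[tbl.group == "shocked"]
        ct = tbl[tbl.group == "non_shocked"]
        r_epi.append(correlation(sh.rems_episodes_iv, sh.asr_115).statistic)
        r_tra.append(correlation(sh.nrems_to_rems_transitions_iv, sh.asr_115).statistic)
        r_ctl.append(correlation(ct.rems_episodes_iv, ct.asr_115).statistic)
        r_per.append(correlation(sh.rems_change_day1, sh.rems_change_day55).statistic)
    r_episodes = fisher_z_mean(r_epi)
    return {
        "r_episodes_asr": r_episodes,
        "r_transitions_asr": fisher_z_mean(r_tra),
        "r_controls": fisher_z_mean(r_ctl),
        "r2_ols_pct": 100.0 * r_episodes**2,
        "r2_persistence": fisher_z_mean(r_per) ** 2,
        "n_per_group": n_per_group,
        "replicates": replicates,
    }


def null_type_one_error(
    n_sims: int = 1000, n_per_group: int = 8, seed: int = 0, alpha: float = 0.05
) -> dict:
    """Rejection rate of the multivariate group test under the null.

    Gaussian noise for 2 variables x 4 days x 2 groups, run through the
    full repeated-measures analysis; the reported rate should sit at the
    nominal level within Monte-Carlo error.
    """
    import pandas as pd

    from .stats import rm_group_day_analysis

    rng = np.random.default_rng(seed)
    days = ("baseline", "day0", "day1", "day55")
    variables = ("v1", "v2")
    rejections = 0
    for _ in range(n_sims):
        rows = []
        for group in ("shocked", "non_shocked"):
            for i in range(n_per_group):
                vals = rng.standard_normal(len(days) * len(variables))
                k = 0
                for day in days:
                    for v in variables:
                        rows.append((f"{group}_{i}", group, day, v, vals[k]))
                        k += 1
        tbl = pd.DataFrame(rows, columns=["animal", "group", "day", "variable", "value"])
        res = rm_group_day_analysis(tbl)
        rejections += res.multivariate["other"]["group"].p < alpha
    rate = rejections / n_sims
    return {
        "rejection_rate": rate,
        "nominal_alpha": alpha,
        "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_sims)),
        "n_sims": n_sims,
    }
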