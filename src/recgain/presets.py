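"""Preconfigured experiment drivers at desk scale.

These functions reproduce the headline experiments of the study — long-term
phenotypic and genomic selection under 2/4/8-fold recombination increases,
first-cycle prediction accuracy, and training-cadence effects — at problem
sizes chosen to run on a single CPU in minutes.  Phenotypic-selection and
first-cycle-accuracy runs use the full programme size (3,000 DH lines); the
long-term genomic-selection arms, whose per-cycle RRBLUP refit dominates the
cost, run at half population size (1,500 DH = 30 crosses x 50 DH, still
selecting 30 parents) with fewer replicates.  Problem sizes are stated in
docs/methods.md; every driver takes a single integer seed.
"""
from __future__ import annotations

import numpy as np

from .metrics import replicate_variance
from .scheme import (
    Arm,
    ScenarioConfig,
    gain_ratio,
    run_first_cycle_accuracy,
    run_scenario_arms,
)

__all__ = [
    "DEFAULT_SCENARIO",
    "ps_long_term",
    "gs_long_term",
    "first_cycle_accuracy",
]

#: the study's default trait/selection landscape: 100 QTL per chromosome,
#: h2 = 0.5, 500 markers per chromosome when genotyping.
DEFAULT_SCENARIO = dict(n_qtl_per_chr=100, h2=0.5, markers_per_chr=500)


def ps_long_term(
    seed: int,
    paired_replicates: int = 36,
    f8_replicates: int = 100,
    factors=(1.0, 4.0, 8.0),
) -> dict:
    """Long-term phenotypic selection at full programme size.

    All factor arms run seed-paired for ``paired_replicates`` replicates
    (shared burn-in per replicate); the 8x arm is extended with further
    replicates up to ``f8_replicates`` so its across-replicate gain variance
    is estimated on the larger sample.  Returns the arm results plus the
    headline summaries: replicate-mean cycle-15 gains per factor, the 4x/1x
    gain ratio, and the across-replicate variance of the cycle-15 gain.
    """
    cfg = ScenarioConfig(
        selection_mode="phenotypic",
        n_replicates=paired_replicates,
        rng_seed=seed,
        **DEFAULT_SCENARIO,
    )
    arms = [Arm(f"ps_f{f:g}", f, "phenotypic", 1) for f in factors]
    results = run_scenario_arms(cfg, arms)
    if f8_replicates > paired_replicates and 8.0 in factors:
        extra = run_scenario_arms(
            cfg,
            [Arm("ps_f8", 8.0, "phenotypic", 1)],
            n_replicates=f8_replicates,
            rep_start=paired_replicates,
        )
        results["ps_f8"].records.extend(extra["ps_f8"].records)
    out = {"results": results}
    for f in factors:
        gains = results[f"ps_f{f:g}"].final_gains()
        out[f"gain_f{f:g}"] = float(gains.mean())
        out[f"var_f{f:g}"] = replicate_variance(gains)
        out[f"n_f{f:g}"] = int(gains.size)
    if 4.0 in factors and 1.0 in factors:
        out["ratio_f4_f1"] = gain_ratio(results["ps_f4"], results["ps_f1"])
    return out


def gs_long_term(
    seed: int,
    n_replicates: int = 7,
    pop_size: int = 1500,
    n_crosses: int = 30,
) -> dict:
    """Long-term genomic selection with per-cycle and reduced-cadence training.

    Four seed-paired arms from a shared burn-in: factor 1 and factor 4 with
    training every cycle, and factor 4 retrained every second and every
    fourth cycle.  Run at half population size (see module docstring).
    """
    cfg = ScenarioConfig(
        selection_mode="genomic",
        pop_size=pop_size,
        n_crosses=n_crosses,
        dh_per_f2=pop_size // n_crosses,
        n_replicates=n_replicates,
        rng_seed=seed,
        **DEFAULT_SCENARIO,
    )
    arms = [
        Arm("gs_f1_t1", 1.0, "genomic", 1),
        Arm("gs_f4_t1", 4.0, "genomic", 1),
        Arm("gs_f4_t2", 4.0, "genomic", 2),
        Arm("gs_f4_t4", 4.0, "genomic", 4),
    ]
    results = run_scenario_arms(cfg, arms)
    return {
        "results": results,
        "gain_f1": float(results["gs_f1_t1"].final_gains().mean()),
        "gain_f4": float(results["gs_f4_t1"].final_gains().mean()),
        "ratio_f4_f1": gain_ratio(results["gs_f4_t1"], results["gs_f1_t1"]),
        "gain_f4_every2": float(results["gs_f4_t2"].final_gains().mean()),
        "gain_f4_every4": float(results["gs_f4_t4"].final_gains().mean()),
    }


def first_cycle_accuracy(seed: int, n_replicates: int = 24, factors=(2.0, 4.0, 8.0)) -> dict:
    """First-cycle RRBLUP accuracy at full programme size.

    The factor-1 value is the fitted accuracy on the burn-in-end generation;
    each rescaled arm retrains on its first post-change generation.  Returns
    the factor-1 accuracy and the mean over the rescaled arms.
    """
    cfg = ScenarioConfig(
        selection_mode="genomic", n_replicates=n_replicates, rng_seed=seed, **DEFAULT_SCENARIO
    )
    table = run_first_cycle_accuracy(cfg, factors=factors)
    by_factor = table.groupby("factor")["accuracy"].mean()
    return {
        "table": table,
        "accuracy_f1": float(by_factor.loc[1.0]),
        "accuracy_scaled_mean": float(np.mean([by_factor.loc[f] for f in factors])),
    }
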