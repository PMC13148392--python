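"""Derived statistics and tabular summaries of simulation runs.

The Bulmer effect is reported as the genetic variance divided by half the
genic variance; the factor 1/2 corrects the Hardy-Weinberg expectation for
the fully inbred state of doubled-haploid lines, in which the additive
variance at linkage equilibrium is twice the outbred genic variance.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "bulmer_effect",
    "replicate_variance",
    "gain_per_variance_lost",
    "build_summary",
    "write_summary_csv",
    "plot_trajectories",
]


def bulmer_effect(genetic_var: float, genic_var: float) -> float:
    """genetic variance / (genic variance / 2); NaN at fixation (genic 0)."""
    if genetic_var < 0:
        raise ValueError("genetic variance must be >= 0")
    if genic_var == 0.0:
        return float("nan")
    return float(genetic_var / (genic_var / 2.0))


def replicate_variance(final_gains) -> float:
    """Sample variance (denominator n-1) of per-replicate final gains."""
    g = np.asarray(final_gains, dtype=np.float64)
    if g.size < 2:
        return 0.0 if g.size == 1 else float("nan")
    return float(g.var(ddof=1))


def gain_per_variance_lost(gain, genetic_var) -> np.ndarray:
    """Cumulative standardised gain per unit of genetic variance depleted.

    (gain_t - gain_0) / (var_0 - var_t); reported missing wherever the
    variance has not decreased below its cycle-0 level.
    """
    gain = np.asarray(gain, dtype=np.float64)
    var = np.asarray(genetic_var, dtype=np.float64)
    lost = var[0] - var
    out = np.full(gain.shape, np.nan)
    ok = lost > 0
    out[ok] = (gain[ok] - gain[0]) / lost[ok]
    return out


def build_summary(results, baseline: str | None = None) -> pd.DataFrame:
    """Per-cycle replicate means for a set of runs, keyed by scenario.

    ``results`` maps scenario ids to RunResult-like objects (anything with
    ``cycle_means``, ``final_gains``).  If ``baseline`` names one of them,
    a gain-ratio column (cycle-15 replicate-mean gain over the baseline's)
    is attached to every scenario's rows.
    """
    if not isinstance(results, dict):
        results = {r.scenario_id: r for r in results}
    frames = []
    base_gain = results[baseline].final_gains().mean() if baseline is not None else None
    for sid, res in results.items():
        df = res.cycle_means().copy()
        df.insert(0, "scenario", sid)
        df["var_final_gain"] = replicate_variance(res.final_gains())
        df["gain_per_variance_lost"] = gain_per_variance_lost(
            df["mean_genetic_value"].to_numpy(), df["genetic_variance"].to_numpy()
        )
        if base_gain is not None:
            df["gain_ratio"] = res.final_gains().mean() / base_gain
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def write_summary_csv(summary: pd.DataFrame, path) -> None:
    summary.to_csv(path, index=False)


def plot_trajectories(summary: pd.DataFrame, path, metric: str = "mean_genetic_value") -> None:
    """Cosmetic per-cycle trajectory plot (one line per scenario)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, df in summary.groupby("scenario"):
        ax.plot(df["cycle"], df[metric], marker="o", ms=3, label=sid)
    ax.set_xlabel("breeding cycle after burn-in")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
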