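"""Recurrent doubled-haploid selection programmes with tunable recombination.

One breeding cycle: truncation-select the best 30 of 3,000 DH lines, make 60
random crosses among them, self each F1 once, and derive 50 doubled haploids
from each F2 — giving the next generation of 3,000 DH lines.  A programme is
initialised by 10 burn-in cycles of phenotypic selection on the founders (the
founder selection counts as the first burn-in cycle); reported genetic gains
are raw mean genetic values on the founder sigma_A^2 = 1 scale offset to zero
at burn-in end, and variance trajectories are scaled so burn-in-end genetic
variance is 1.  After burn-in the genetic map may be rescaled (2-, 4-, 8-fold)
to emulate an increased recombination rate, and selection proceeds either
phenotypically or genomically (RRBLUP on a SNP chip, retrained every
``training_interval`` cycles).

Populations track only the loci a scenario needs (QTL, plus chip markers for
genomic selection); because crossovers are generated on the true chromosome
lengths and then applied to the tracked positions, this is exactly
equivalent to simulating all 10,000 loci per chromosome.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .founders import DEFAULT_LANDSCAPE, SORGHUM_CHROM_LENGTHS_CM, founders_on_map, make_map
from .genome import (
    GeneticMap,
    MeiosisParams,
    Population,
    cross_batch,
    dh_batch,
    self_batch,
)
from .gs import (
    GsModel,
    TrainingSet,
    accuracy,
    genotype_chip,
    predict_gebv,
    rolling_training_set,
    select_top,
    train_rrblup,
)
from .metrics import bulmer_effect, replicate_variance
from .traits import (
    SnpChip,
    TraitArchitecture,
    calibrate_architecture,
    genetic_values,
    genic_variance,
    phenotypes,
    sample_chip,
    sample_qtl,
)

__all__ = [
    "ScenarioConfig",
    "Arm",
    "CycleRecord",
    "RunResult",
    "BurnInState",
    "run_cycle",
    "run_burn_in",
    "run_scenario_arms",
    "run_long_term",
    "replicate_and_summarize",
    "gain_ratio",
    "run_model_reuse",
    "run_first_cycle_accuracy",
    "run_merged_training",
    "summarize_model_reuse",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one breeding-programme scenario.

    The study grid is n_qtl_per_chr in {10,100,1000}, h2 in {0.2,0.5,0.8},
    map_factor in {1,2,4,8}, markers_per_chr in {100,200,500,1000},
    training_interval in {1,2,4}; other values are accepted so that reduced
    desk-scale runs remain possible.
    """

    n_qtl_per_chr: int = 100
    h2: float = 0.5
    map_factor: float = 1.0
    markers_per_chr: int = 500
    selection_mode: str = "phenotypic"  # or "genomic"
    training_interval: int = 1
    n_select: int = 30
    n_crosses: int = 60
    dh_per_f2: int = 50
    pop_size: int = 3000
    burn_in_cycles: int = 10
    post_cycles: int = 15
    n_replicates: int = 100
    rng_seed: int = 0
    # genome / founder-generator parameters
    n_loci_per_chr: int = 10000
    chrom_lengths_cm: tuple | None = None  # None = the 10 sorghum lengths
    map_landscape: tuple | None = DEFAULT_LANDSCAPE  # None = uniform cM placement
    n_ancestral_haplotypes: int = 298
    mixing_generations: int = 50
    maf_floor: float = 0.01
    founder_spectrum: str = "neutral"
    interference_nu: float = 2.6
    obligate_crossover: bool = False

    def __post_init__(self):
        if self.pop_size != self.n_crosses * self.dh_per_f2:
            raise ValueError("pop_size must equal n_crosses * dh_per_f2")
        if not 1 <= self.n_select <= self.pop_size:
            raise ValueError("n_select must lie in [1, pop_size]")
        if self.n_select < 2:
            raise ValueError("need at least 2 selected parents to cross")
        if self.selection_mode not in ("phenotypic", "genomic"):
            raise ValueError("selection_mode must be 'phenotypic' or 'genomic'")
        if self.training_interval < 1:
            raise ValueError("training_interval must be >= 1")
        if self.map_factor <= 0:
            raise ValueError("map_factor must be positive")

    @property
    def meiosis_params(self) -> MeiosisParams:
        return MeiosisParams(self.interference_nu, self.obligate_crossover)

    def lengths(self) -> np.ndarray:
        if self.chrom_lengths_cm is None:
            return np.array(list(SORGHUM_CHROM_LENGTHS_CM.values()))
        return np.asarray(self.chrom_lengths_cm, dtype=np.float64)


@dataclass(frozen=True)
class Arm:
    """One treatment arm run from a shared burn-in state."""

    label: str
    map_factor: float = 1.0
    selection_mode: str = "phenotypic"
    training_interval: int = 1


@dataclass
class CycleRecord:
    """Per-cycle population metrics (cycle 0 = burn-in end)."""

    cycle: int
    mean_genetic_value: float  # gain: raw mean genetic value, 0 at cycle 0
    genetic_variance: float  # scaled to 1 at cycle 0
    genic_variance: float  # same scaling as genetic_variance
    bulmer: float
    accuracy: float  # NaN under phenotypic selection
    trained_this_cycle: bool


@dataclass
class RunResult:
    """Replicate-by-cycle records for one scenario arm."""

    scenario_id: str
    config: ScenarioConfig
    arm: Arm
    records: list  # [replicate][cycle] -> CycleRecord
    summary: pd.DataFrame | None = None

    @property
    def n_replicates(self) -> int:
        return len(self.records)

    def final_gains(self) -> np.ndarray:
        return np.array([rep[-1].mean_genetic_value for rep in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, rep in enumerate(self.records):
            for rec in rep:
                rows.append(
                    {
                        "scenario": self.scenario_id,
                        "replicate": r,
                        "cycle": rec.cycle,
                        "mean_genetic_value": rec.mean_genetic_value,
                        "genetic_variance": rec.genetic_variance,
                        "genic_variance": rec.genic_variance,
                        "bulmer": rec.bulmer,
                        "accuracy": rec.accuracy,
                        "trained_this_cycle": rec.trained_this_cycle,
                    }
                )
        return pd.DataFrame(rows)

    def cycle_means(self) -> pd.DataFrame:
        df = self.to_frame()
        return (
            df.groupby("cycle")[
                ["mean_genetic_value", "genetic_variance", "genic_variance", "bulmer", "accuracy"]
            ]
            .mean()
            .reset_index()
        )


@dataclass
class BurnInState:
    """Everything a post-burn-in experiment needs, per replicate."""

    pop: Population  # burn-in-end DH generation (cycle 0), factor-1 map
    arch: TraitArchitecture
    chip: SnpChip | None
    base_map: GeneticMap
    mean0: float
    var0: float
    history: list = field(default_factory=list)  # [(label, chip dosages, phenos)]

    @property
    def sd0(self) -> float:
        return float(np.sqrt(self.var0))


# ---------------------------------------------------------------------------
# cycle and burn-in


def run_cycle(
    pop: Population,
    selection_values: np.ndarray,
    cfg: ScenarioConfig,
    params: MeiosisParams,
    rng: np.random.Generator,
    generation: str = "",
) -> Population:
    """Select, cross, self and derive DHs: one full breeding cycle."""
    sel = select_top(selection_values, cfg.n_select)
    pair_choices = np.empty((cfg.n_crosses, 2), dtype=np.int64)
    for j in range(cfg.n_crosses):  # distinct parents per cross, repeats allowed across crosses
        pair_choices[j] = rng.choice(cfg.n_select, size=2, replace=False)
    mothers = sel[pair_choices[:, 0]]
    fathers = sel[pair_choices[:, 1]]
    f1 = cross_batch(pop, mothers, fathers, params, rng, generation="F1")
    f2 = self_batch(f1, params, rng, generation="F2")
    dh_parents = np.repeat(np.arange(cfg.n_crosses, dtype=np.int64), cfg.dh_per_f2)
    return dh_batch(f2, dh_parents, params, rng, generation=generation)


def _init_replicate(cfg: ScenarioConfig, full_map: GeneticMap, rng, need_chip: bool):
    """Sample QTL (and chip), subset the map, generate founders, calibrate."""
    qtl_full = sample_qtl(full_map, cfg.n_qtl_per_chr, rng)
    if need_chip:
        chip_full = sample_chip(full_map, cfg.markers_per_chr, rng, exclude=qtl_full)
        tracked = np.union1d(qtl_full, chip_full.marker_idx)
    else:
        chip_full = None
        tracked = qtl_full
    sub_map = full_map.subset(tracked)
    qtl_idx = np.searchsorted(tracked, qtl_full)
    chip = SnpChip(np.searchsorted(tracked, chip_full.marker_idx)) if need_chip else None
    founders = founders_on_map(
        sub_map,
        cfg.pop_size,
        cfg.n_ancestral_haplotypes,
        cfg.mixing_generations,
        cfg.maf_floor,
        rng,
        params=cfg.meiosis_params,
        spectrum=cfg.founder_spectrum,
    )
    arch = calibrate_architecture(qtl_idx, cfg.h2, founders, rng)
    return founders, arch, chip, sub_map


def run_burn_in(
    cfg: ScenarioConfig,
    rng: np.random.Generator | None = None,
    full_map: GeneticMap | None = None,
    need_chip: bool | None = None,
    keep_history: bool = False,
    history_window: int = 3,
) -> BurnInState:
    """Founders plus ``burn_in_cycles`` cycles of phenotypic selection.

    Returns the burn-in-end DH population together with the architecture and
    the standardisation constants (mean and variance of genetic values at
    burn-in end).  With ``keep_history`` the chip dosages and phenotypes of
    the last ``history_window`` DH generations (including burn-in end) are
    retained for merged-training experiments.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    if full_map is None:
        full_map = make_map(cfg.lengths(), cfg.n_loci_per_chr, rng, landscape=cfg.map_landscape)
    if need_chip is None:
        need_chip = cfg.selection_mode == "genomic"
    params = cfg.meiosis_params
    founders, arch, chip, sub_map = _init_replicate(cfg, full_map, rng, need_chip or keep_history)
    pop = founders
    history: list = []
    for c in range(1, cfg.burn_in_cycles + 1):
        g_c, _ = _qtl_stats(pop, arch)
        ph = phenotypes(pop, arch, rng, genetic=g_c)
        if keep_history and c > cfg.burn_in_cycles - history_window:
            history.append((pop.generation, genotype_chip(pop, chip), ph))
        pop = run_cycle(pop, ph, cfg, params, rng, generation=f"burnin{c}")
    g = genetic_values(pop, arch)
    var0 = float(g.var())
    if var0 == 0.0:
        raise RuntimeError("burn-in ended with zero genetic variance; cannot standardise")
    if keep_history:
        ph0 = phenotypes(pop, arch, rng)
        history.append((pop.generation, genotype_chip(pop, chip), ph0))
        history = history[-history_window:]
    pop.generation = "cycle0"
    return BurnInState(
        pop=pop,
        arch=arch,
        chip=chip,
        base_map=sub_map,
        mean0=float(g.mean()),
        var0=var0,
        history=history,
    )


# ---------------------------------------------------------------------------
# long-term experiment (experiment 1)


def _qtl_stats(pop: Population, arch: TraitArchitecture):
    """One dosage pass per cycle: genetic values and genic variance."""
    dq = pop.dosages(arch.qtl_idx).astype(np.float64)
    g = dq @ arch.effects
    p = dq.mean(axis=0) / 2.0
    genic = float(np.sum(2.0 * p * (1.0 - p) * arch.effects**2))
    return g, genic


def _standardised_record(
    t: int, g: np.ndarray, genic: float, burn: BurnInState, acc: float, trained: bool
) -> CycleRecord:
    """Post-burn-in reporting convention: the genetic gain is the raw mean
    genetic value (on the founder sigma_A^2 = 1 scale) offset to zero at
    burn-in end; the variance columns are scaled so burn-in-end genetic
    variance is 1."""
    gv = float(g.var())
    return CycleRecord(
        cycle=t,
        mean_genetic_value=float(g.mean()) - burn.mean0,
        genetic_variance=gv / burn.var0,
        genic_variance=genic / burn.var0,
        bulmer=bulmer_effect(gv, genic),
        accuracy=acc,
        trained_this_cycle=trained,
    )


def _run_arm(burn: BurnInState, cfg: ScenarioConfig, arm: Arm, rng) -> list:
    """Run ``cfg.post_cycles`` cycles of one arm from a shared burn-in state."""
    params = cfg.meiosis_params
    gmap = burn.base_map.scaled(arm.map_factor)
    pop = Population(burn.pop.haplotypes, gmap, generation="cycle0")
    arch = burn.arch
    model: GsModel | None = None
    records = []
    for t in range(cfg.post_cycles + 1):
        g, genic = _qtl_stats(pop, arch)
        acc = float("nan")
        trained = False
        sel_values = None
        if arm.selection_mode == "genomic":
            dos = genotype_chip(pop, burn.chip)
            if t % arm.training_interval == 0:
                ph = phenotypes(pop, arch, rng, genetic=g)
                ts = TrainingSet(dos, ph, np.full(pop.n, pop.generation, dtype=object))
                model = train_rrblup(ts, map_factor_at_training=arm.map_factor)
                trained = True
            gebv = predict_gebv(model, dos)
            acc = accuracy(gebv, g)
            sel_values = gebv
        records.append(_standardised_record(t, g, genic, burn, acc, trained))
        if t < cfg.post_cycles:
            if arm.selection_mode != "genomic":
                sel_values = phenotypes(pop, arch, rng, genetic=g)
            pop = run_cycle(pop, sel_values, cfg, params, rng, generation=f"cycle{t + 1}")
    return records


def _rep_seedseq(base_seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(1 + rep,))


def _experiment_map(cfg: ScenarioConfig, base_seed: int) -> GeneticMap:
    """The base map is drawn once per experiment and shared by replicates."""
    map_rng = np.random.default_rng(np.random.SeedSequence(entropy=base_seed, spawn_key=(0,)))
    return make_map(cfg.lengths(), cfg.n_loci_per_chr, map_rng, landscape=cfg.map_landscape)


def run_scenario_arms(
    cfg: ScenarioConfig,
    arms,
    n_replicates: int | None = None,
    base_seed: int | None = None,
    full_map: GeneticMap | None = None,
    rep_start: int = 0,
) -> dict:
    """Run several treatment arms from seed-paired, shared burn-in states.

    Every replicate generates one founder population and one burn-in
    trajectory, from which all arms depart with independent spawned random
    streams; arms are therefore seed-paired, as required for gain-ratio
    statistics.  ``rep_start`` skips the first replicates of the seed tree
    (so a run can be extended without repeating earlier replicates).
    """
    arms = list(arms)
    if len({a.label for a in arms}) != len(arms):
        raise ValueError("arm labels must be unique")
    reps = cfg.n_replicates if n_replicates is None else n_replicates
    seed = cfg.rng_seed if base_seed is None else base_seed
    if full_map is None:
        full_map = _experiment_map(cfg, seed)
    need_chip = any(a.selection_mode == "genomic" for a in arms)
    records = {a.label: [] for a in arms}
    for r in range(rep_start, reps):
        streams = _rep_seedseq(seed, r).spawn(1 + len(arms))
        burn = run_burn_in(cfg, np.random.default_rng(streams[0]), full_map, need_chip=need_chip)
        for k, arm in enumerate(arms):
            records[arm.label].append(_run_arm(burn, cfg, arm, np.random.default_rng(streams[1 + k])))
    return {
        a.label: RunResult(scenario_id=a.label, config=cfg, arm=a, records=records[a.label])
        for a in arms
    }


def run_long_term(
    cfg: ScenarioConfig,
    n_replicates: int | None = None,
    base_seed: int | None = None,
    full_map: GeneticMap | None = None,
) -> RunResult:
    """Single-arm long-term experiment defined directly by ``cfg``."""
    arm = Arm(
        label=f"{cfg.selection_mode}_f{cfg.map_factor:g}_t{cfg.training_interval}",
        map_factor=cfg.map_factor,
        selection_mode=cfg.selection_mode,
        training_interval=cfg.training_interval,
    )
    return run_scenario_arms(cfg, [arm], n_replicates, base_seed, full_map)[arm.label]


def replicate_and_summarize(cfg: ScenarioConfig, **kwargs) -> RunResult:
    """Run the configured scenario and attach the per-cycle summary table."""
    res = run_long_term(cfg, **kwargs)
    summary = res.cycle_means()
    summary["var_final_gain"] = replicate_variance(res.final_gains())
    res.summary = summary
    return res


def gain_ratio(increased: RunResult, baseline: RunResult, method: str = "ratio_of_means") -> float:
    """Cycle-15 gain of an increased-recombination arm over the baseline arm.

    ``ratio_of_means`` divides the replicate-mean final gains (the default);
    ``mean_of_ratios`` averages per-replicate ratios of seed-paired arms.
    """
    gi = increased.final_gains()
    gb = baseline.final_gains()
    if method == "ratio_of_means":
        return float(gi.mean() / gb.mean())
    if method == "mean_of_ratios":
        if gi.size != gb.size:
            raise ValueError("mean_of_ratios needs seed-paired replicates")
        return float(np.mean(gi / gb))
    raise ValueError("method must be 'ratio_of_means' or 'mean_of_ratios'")


# ---------------------------------------------------------------------------
# model maintenance across a recombination change (experiment 2)


def _train_on_population(burn: BurnInState, pop: Population, rng, map_factor: float):
    """Phenotype a DH generation, fit RRBLUP on it, return (model, gebv, acc)."""
    dos = genotype_chip(pop, burn.chip)
    ph = phenotypes(pop, burn.arch, rng)
    ts = TrainingSet(dos, ph, np.full(pop.n, pop.generation, dtype=object))
    model = train_rrblup(ts, map_factor_at_training=map_factor)
    gebv = predict_gebv(model, dos)
    return model, gebv, accuracy(gebv, genetic_values(pop, burn.arch))


def run_model_reuse(
    cfg: ScenarioConfig,
    factors=(1.0, 2.0, 4.0, 8.0),
    n_replicates: int | None = None,
    base_seed: int | None = None,
    full_map: GeneticMap | None = None,
) -> pd.DataFrame:
    """Reapply a pre-change RRBLUP model one generation after a map rescale.

    Per replicate: train at burn-in end (factor 1), select on GEBV, rescale
    the map by each factor, complete one cycle, and reapply the *old* model
    to the new generation.  Returns one row per (replicate, factor) with the
    training-generation accuracy, next-generation accuracy, and their
    difference (next minus training).
    """
    reps = cfg.n_replicates if n_replicates is None else n_replicates
    seed = cfg.rng_seed if base_seed is None else base_seed
    if full_map is None:
        full_map = _experiment_map(cfg, seed)
    rows = []
    for r in range(reps):
        streams = _rep_seedseq(seed, r).spawn(1 + len(factors))
        rng0 = np.random.default_rng(streams[0])
        burn = run_burn_in(cfg, rng0, full_map, need_chip=True)
        model0, gebv0, acc0 = _train_on_population(burn, burn.pop, rng0, map_factor=1.0)
        for k, factor in enumerate(factors):
            rng_a = np.random.default_rng(streams[1 + k])
            gmap = burn.base_map.scaled(factor)
            pop0 = Population(burn.pop.haplotypes, gmap, generation="cycle0")
            pop1 = run_cycle(pop0, gebv0, cfg, cfg.meiosis_params, rng_a, generation="cycle1")
            gebv1 = predict_gebv(model0, genotype_chip(pop1, burn.chip))
            acc1 = accuracy(gebv1, genetic_values(pop1, burn.arch))
            rows.append(
                {
                    "replicate": r,
                    "factor": factor,
                    "accuracy_at_training": acc0,
                    "accuracy_next_gen": acc1,
                    "delta": acc1 - acc0,
                    "map_factor_at_training": model0.map_factor_at_training,
                }
            )
    return pd.DataFrame(rows)


def summarize_model_reuse(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate means of the model-reuse accuracies per map factor."""
    return (
        table.groupby("factor")[["accuracy_at_training", "accuracy_next_gen", "delta"]]
        .mean()
        .reset_index()
    )


def run_first_cycle_accuracy(
    cfg: ScenarioConfig,
    factors=(2.0, 4.0, 8.0),
    n_replicates: int | None = None,
    base_seed: int | None = None,
    full_map: GeneticMap | None = None,
) -> pd.DataFrame:
    """First-cycle prediction accuracy under normal and rescaled maps.

    The factor-1 accuracy is that of the model fitted on the burn-in-end DH
    generation (evaluated there); each rescaled arm selects on that model's
    GEBVs, completes one cycle under the rescaled map, retrains on the new
    generation and reports the fitted accuracy — the accuracy of the first
    genomic-selection cycle after the recombination change.
    """
    reps = cfg.n_replicates if n_replicates is None else n_replicates
    seed = cfg.rng_seed if base_seed is None else base_seed
    if full_map is None:
        full_map = _experiment_map(cfg, seed)
    rows = []
    for r in range(reps):
        streams = _rep_seedseq(seed, r).spawn(1 + len(factors))
        rng0 = np.random.default_rng(streams[0])
        burn = run_burn_in(cfg, rng0, full_map, need_chip=True)
        _, gebv0, acc0 = _train_on_population(burn, burn.pop, rng0, map_factor=1.0)
        rows.append({"replicate": r, "factor": 1.0, "accuracy": acc0})
        for k, factor in enumerate(factors):
            rng_a = np.random.default_rng(streams[1 + k])
            gmap = burn.base_map.scaled(factor)
            pop0 = Population(burn.pop.haplotypes, gmap, generation="cycle0")
            pop1 = run_cycle(pop0, gebv0, cfg, cfg.meiosis_params, rng_a, generation="cycle1")
            _, _, acc1 = _train_on_population(burn, pop1, rng_a, map_factor=factor)
            rows.append({"replicate": r, "factor": factor, "accuracy": acc1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# merged (rolling-window) training sets across a recombination change


def run_merged_training(
    cfg: ScenarioConfig,
    n_replicates: int | None = None,
    base_seed: int | None = None,
    full_map: GeneticMap | None = None,
    window: int = 3,
    post_cycles: int = 3,
    benchmark: bool = True,
) -> dict:
    """Rolling multi-generation training sets spanning a recombination change.

    The last ``window`` burn-in DH generations are merged to train the model
    used at burn-in end; after the map rescale each new DH generation
    replaces the oldest one in the window and the model is retrained every
    cycle.  The benchmark arm runs the same scheme without the rescale.
    """
    reps = cfg.n_replicates if n_replicates is None else n_replicates
    seed = cfg.rng_seed if base_seed is None else base_seed
    if full_map is None:
        full_map = _experiment_map(cfg, seed)
    factors = [cfg.map_factor] + ([1.0] if benchmark and cfg.map_factor != 1.0 else [])
    labels = [f"merged_f{f:g}" for f in factors]
    arms = {
        lab: Arm(lab, f, "genomic", 1) for lab, f in zip(labels, factors)
    }
    records = {lab: [] for lab in labels}
    for r in range(reps):
        streams = _rep_seedseq(seed, r).spawn(1 + len(factors))
        burn = run_burn_in(
            cfg,
            np.random.default_rng(streams[0]),
            full_map,
            need_chip=True,
            keep_history=True,
            history_window=window,
        )
        for k, (lab, factor) in enumerate(zip(labels, factors)):
            rng = np.random.default_rng(streams[1 + k])
            gmap = burn.base_map.scaled(factor)
            pop = Population(burn.pop.haplotypes, gmap, generation="cycle0")
            hist = list(burn.history)
            recs = []
            for t in range(post_cycles + 1):
                g, genic = _qtl_stats(pop, burn.arch)
                if t > 0:
                    dos = genotype_chip(pop, burn.chip)
                    ph = phenotypes(pop, burn.arch, rng, genetic=g)
                    hist.append((pop.generation, dos, ph))
                else:
                    dos = hist[-1][1]
                ts = rolling_training_set(hist, window=window)
                model = train_rrblup(ts, map_factor_at_training=factor)
                gebv = predict_gebv(model, dos)
                recs.append(
                    _standardised_record(t, g, genic, burn, accuracy(gebv, g), True)
                )
                if t < post_cycles:
                    pop = run_cycle(
                        pop, gebv, cfg, cfg.meiosis_params, rng, generation=f"cycle{t + 1}"
                    )
            records[lab].append(recs)
    return {
        lab: RunResult(scenario_id=lab, config=cfg, arm=arms[lab], records=records[lab])
        for lab in labels
    }
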