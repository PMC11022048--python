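"""The four numeric studies as reproducible, seeded pipelines.

* :func:`percolation_study` — chance that a signal entering at the
  peripheral cytoplasm can reach the central organelle through a uniform
  random cytoskeleton fill, swept over the fill fraction.
* :func:`noise_study` — robustness of the four readout layers when
  Gaussian noise corrupts a cosine perturbation, for sine and square
  target responses and both source kinds.
* :func:`waveform_task_run` — a single waveform-learning run (train on
  the first quarter of the series, test on the rest).
* :func:`immune_workflow` — learning T-cell activation frequencies from a
  (ligand concentration, extracellular K+) table by driving the reservoir
  with δq = [K+]in − [K+]ex sequences, with an elastic-net ANN readout and
  a statistical ensemble for uncertainty.
* :func:`synth_immune_table` — synthetic generator for tables of the
  immune-workflow shape (activation rises with ligand, falls with K+).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics, geometry, readout, reservoir
from .dynamics import NoSignalError, make_source, propagate_to_saturation, run_sequence
from .electrochem import k_sequence_to_charges
from .geometry import Region, build_cell, generate_cytoskeleton
from .readout import ReadoutModel, concat_aux, ensemble_predict, train
from .reservoir import assign_conductance, build_graph

# sweep and study defaults (reference study conditions)
DEFAULT_FRACTIONS = tuple(f / 100 for f in range(1, 16))   # 1%..15% step 1%
DEFAULT_SIGMAS = (0.05, 0.1, 0.25, 0.5, 1.0)
DEFAULT_N_TRIALS = 100
DEFAULT_ENSEMBLE = 20
REFERENCE_GEOMETRY = dict(voxel_size=0.5, r_cm=10.0, r_pc=9.0, r_co=2.5)
DEFAULT_FILL = 0.20
#: memory retention: short (timescale ~2 steps) so the organelle state
#: tracks the drive; see the waveform-task docstring for why.
DEFAULT_BETA = 0.5


def _spawn_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# percolation
# ---------------------------------------------------------------------------

def percolates(graph: reservoir.ReservoirGraph) -> bool:
    """Reachability oracle: can any organelle voxel receive information
    originating at the peripheral cytoplasm?

    True iff a 26-connected component of the conducting voxels contains
    both a PC voxel and a CO voxel.  Source placement is irrelevant: the
    PC shell itself conducts, so point and spherical sources reach exactly
    the same set.
    """
    from scipy.ndimage import label

    lab, _ = label(graph.occupied, structure=np.ones((3, 3, 3), bool))
    labels = graph.geom.labels
    pc_labels = np.unique(lab[(labels == Region.PC) & (lab > 0)])
    co_labels = np.unique(lab[(labels == Region.CO) & (lab > 0)])
    return bool(np.intersect1d(pc_labels, co_labels, assume_unique=True).size)


def percolates_dynamics(graph: reservoir.ReservoirGraph, source_kind: str = "spherical") -> bool:
    """Percolation decided by the stepping engine (front to saturation)."""
    src = make_source(graph.geom, source_kind)
    state, _ = propagate_to_saturation(graph, src)
    return state.co_arrival is not None


@dataclass
class PercolationResult:
    fractions: np.ndarray
    n_trials: int
    n_percolating: np.ndarray
    seeds: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def probability(self) -> np.ndarray:
        return self.n_percolating / self.n_trials

    def crossing_fraction(self, level: float = 0.5) -> float:
        """Fill fraction where percolation probability crosses ``level``,
        by linear interpolation between the bracketing sweep points."""
        p = self.probability
        f = self.fractions
        above = np.flatnonzero(p >= level)
        if above.size == 0:
            raise ValueError("probability never reaches the requested level")
        j = above[0]
        if j == 0:
            return float(f[0])
        f0, f1, p0, p1 = f[j - 1], f[j], p[j - 1], p[j]
        return float(f0 + (level - p0) * (f1 - f0) / (p1 - p0))

    def min_guaranteed_fraction(self) -> float:
        """Smallest swept fraction at and above which every trial percolates."""
        p = self.probability
        below = np.flatnonzero(p < 1.0)
        j = 0 if below.size == 0 else below[-1] + 1
        if j >= len(self.fractions):
            raise ValueError("no swept fraction guarantees percolation")
        return float(self.fractions[j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.fractions,
                "n_trials": self.n_trials,
                "n_percolating": self.n_percolating,
                "probability": self.probability,
            }
        )


def percolation_study(
    fractions=DEFAULT_FRACTIONS,
    n_trials: int = DEFAULT_N_TRIALS,
    base_seed: int = 0,
    geometry_kwargs: dict | None = None,
    method: str = "reachability",
    source_kind: str = "spherical",
) -> PercolationResult:
    """Monte-Carlo sweep of percolation probability over fill fraction.

    Per (fraction, trial) a fresh uniform cytoskeleton is generated with
    its own derived seed and tested for PC→CO connectivity.  ``method`` is
    ``"reachability"`` (component labeling, the fast oracle) or
    ``"dynamics"`` (the stepping engine); the two agree exactly.
    """
    fractions = np.asarray(sorted(fractions), dtype=float)
    geom = build_cell(**(geometry_kwargs or REFERENCE_GEOMETRY))
    seeds = _spawn_seeds(base_seed, len(fractions) * n_trials).reshape(
        len(fractions), n_trials
    )
    hits = np.zeros(len(fractions), dtype=int)
    for i, frac in enumerate(fractions):
        for j in range(n_trials):
            generate_cytoskeleton(geom, frac, int(seeds[i, j]))
            graph = build_graph(geom)
            if method == "reachability":
                ok = percolates(graph)
            elif method == "dynamics":
                ok = percolates_dynamics(graph, source_kind)
            else:
                raise ValueError(f"unknown method {method!r}")
            hits[i] += ok
    return PercolationResult(fractions, n_trials, hits, seeds)


# ---------------------------------------------------------------------------
# arrival / saturation timing
# ---------------------------------------------------------------------------

@dataclass
class ArrivalResult:
    """First organelle arrival and saturation step per seed and source."""

    table: pd.DataFrame  # columns: seed, source, co_arrival, saturation_step

    def mean_arrival(self, source: str | None = None) -> float:
        df = self.table if source is None else self.table[self.table.source == source]
        return float(df.co_arrival.mean())

    def mean_saturation(self, source: str) -> float:
        df = self.table[self.table.source == source]
        return float(df.saturation_step.mean())


def arrival_study(
    n_seeds: int = 20,
    cs_fraction: float = DEFAULT_FILL,
    base_seed: int = 0,
    geometry_kwargs: dict | None = None,
    sources: tuple[str, ...] = ("point", "spherical"),
) -> ArrivalResult:
    """Front-timing study on the reference geometry with 20% fill.

    For each geometry seed and source kind, propagate the front to
    saturation and record the first step at which any organelle-surface
    vertex is informed and the step at which no new vertex is informed.
    Non-percolating draws (rare at 20% fill) are recorded with NaN arrival.
    """
    geom = build_cell(**(geometry_kwargs or REFERENCE_GEOMETRY))
    seeds = _spawn_seeds(base_seed, n_seeds)
    rows = []
    for s in seeds:
        generate_cytoskeleton(geom, cs_fraction, int(s))
        graph = build_graph(geom)
        for kind in sources:
            state, counts = propagate_to_saturation(graph, make_source(geom, kind))
            rows.append(
                {
                    "seed": int(s),
                    "source": kind,
                    "co_arrival": state.co_arrival if state.co_arrival is not None else np.nan,
                    "saturation_step": len(counts) - 1,
                }
            )
    return ArrivalResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# waveform tasks
# ---------------------------------------------------------------------------

@dataclass
class WaveformTask:
    """Cosine perturbation with a sine or square target response.

    The sine target is the delayed-response benchmark: ``sin(ωt)`` is the
    input cosine delayed by a quarter period, and with ``period = None``
    (the default) the period resolves to four times the reservoir's own
    organelle-arrival delay δt, so the demanded response delay equals the
    cell's physical signal-travel time.  The square target is the binary
    (threshold) response: ``sign(sin(ωt))``, 50% duty cycle, amplitude 1.
    ``n_samples = None`` resolves to ten periods.
    """

    target: str = "sine"            # "sine" | "square"
    n_samples: int | None = None
    period: float | None = None
    amplitude: float = 1.0
    split: float = 0.25

    def resolved(self, delta_t: int) -> "WaveformTask":
        """Concrete task for a reservoir with organelle delay ``delta_t``."""
        period = self.period if self.period is not None else 4.0 * delta_t
        n = self.n_samples if self.n_samples is not None else int(round(10 * period))
        return WaveformTask(self.target, n, period, self.amplitude, self.split)

    def waves(self) -> tuple[np.ndarray, np.ndarray]:
        if self.period is None or self.n_samples is None:
            raise ValueError("task is unresolved: call resolved(delta_t) first")
        t = np.arange(self.n_samples)
        phase = 2.0 * np.pi * t / self.period
        x = self.amplitude * np.cos(phase)
        if self.target == "sine":
            y = self.amplitude * np.sin(phase)
        elif self.target == "square":
            y = np.where(np.sin(phase) >= 0, 1.0, -1.0) * self.amplitude
        else:
            raise ValueError(f"unknown target {self.target!r}")
        return x, y


def measure_delay(graph: reservoir.ReservoirGraph, source_kind: str) -> int:
    """Organelle-surface arrival delay δt (steps) of a reservoir.

    Connectivity-driven, hence independent of charge and of β.  Raises
    :class:`NoSignalError` on a non-percolating geometry.
    """
    state, _ = propagate_to_saturation(graph, make_source(graph.geom, source_kind))
    if state.co_arrival is None:
        raise NoSignalError("no signal reached organelle: geometry does not percolate")
    return int(state.co_arrival)


def build_reservoir(
    cs_fraction: float = DEFAULT_FILL,
    geometry_seed: int = 0,
    conductance_seed: int = 1,
    conductance_mean: float = 0.1,
    conductance_sd: float = 0.5,
    geometry_kwargs: dict | None = None,
) -> reservoir.ReservoirGraph:
    """Reference reservoir: 41^3 cell, 20% fill, log-normal conductances."""
    geom = build_cell(**(geometry_kwargs or REFERENCE_GEOMETRY))
    generate_cytoskeleton(geom, cs_fraction, geometry_seed)
    graph = build_graph(geom)
    assign_conductance(graph, conductance_mean, conductance_sd, conductance_seed)
    return graph


def reservoir_features(
    graph: reservoir.ReservoirGraph,
    source_kind: str,
    inputs: np.ndarray,
    beta: float = DEFAULT_BETA,
    debye_length: float = 1.0,
) -> np.ndarray:
    """Run the reservoir on an input series; return δt-aligned CO-surface
    memory states (one row per input sample).  Raises
    :class:`NoSignalError` on a non-percolating geometry."""
    source = make_source(graph.geom, source_kind)
    traj = run_sequence(
        graph, source, inputs, beta=beta, debye_length=debye_length,
        require_percolation=True,
    )
    return traj.feature_matrix()


@dataclass
class WaveformRunResult:
    task: WaveformTask
    source_kind: str
    readout_kind: str
    sigma: float
    train_rmse: float
    test_rmse: float
    diverged: bool
    model: ReadoutModel = field(repr=False, default=None)  # type: ignore[assignment]


def waveform_task_run(
    graph: reservoir.ReservoirGraph,
    task: WaveformTask,
    readout_kind: str = "ann",
    source_kind: str = "spherical",
    sigma: float = 0.0,
    noise_seed: int = 0,
    readout_seed: int = 0,
    beta: float = DEFAULT_BETA,
    features: np.ndarray | None = None,
    **readout_kwargs,
) -> WaveformRunResult:
    """One waveform-learning run.

    Gaussian N(0, σ²) noise is added to the input wave (the perturbation),
    never to the target; the error is always reported against the clean
    target.  ``features`` short-circuits the reservoir run when the caller
    already computed them for this (source, σ, seed) cell.
    """
    if task.period is None or task.n_samples is None:
        task = task.resolved(measure_delay(graph, source_kind))
    x, y = task.waves()
    if features is None:
        if sigma > 0:
            x = x + np.random.default_rng(noise_seed).normal(0.0, sigma, size=x.shape)
        features = reservoir_features(graph, source_kind, x, beta=beta)
    model = ReadoutModel(readout_kind, seed=readout_seed, **readout_kwargs)
    res = train(model, features, y, split=task.split)
    return WaveformRunResult(
        task, source_kind, readout_kind, sigma,
        res.train_rmse, res.test_rmse, res.diverged, model,
    )


@dataclass
class NoiseResult:
    """Grid of RMSEs over (source, target, readout, σ, noise seed)."""

    table: pd.DataFrame

    def mean_test_rmse(self, source: str, target: str, readout_kind: str) -> pd.Series:
        df = self.table
        sel = df[(df.source == source) & (df.target == target) & (df.readout == readout_kind)]
        return sel.groupby("sigma").test_rmse.mean()


def noise_study(
    graph: reservoir.ReservoirGraph,
    sigmas=DEFAULT_SIGMAS,
    targets: tuple[str, ...] = ("sine", "square"),
    readout_kinds: tuple[str, ...] = readout.READOUT_KINDS,
    sources: tuple[str, ...] = ("point", "spherical"),
    n_noise_seeds: int = 1,
    base_seed: int = 0,
    task_kwargs: dict | None = None,
    beta: float = DEFAULT_BETA,
    **readout_kwargs,
) -> NoiseResult:
    """Noise-robustness grid.

    One reservoir run per (source, σ, noise seed) — both targets and all
    four readouts share the same noisy input, so its features are reused
    across the inner grid.  A readout that blows up (non-finite RMSE) is
    recorded with ``diverged=True``, not raised.
    """
    rows = []
    seeds = _spawn_seeds(base_seed, n_noise_seeds)
    for source_kind in sources:
        base_task = WaveformTask(**(task_kwargs or {}))
        if base_task.period is None or base_task.n_samples is None:
            base_task = base_task.resolved(measure_delay(graph, source_kind))
        for sigma in sigmas:
            for ns in seeds:
                x, _ = base_task.waves()
                if sigma > 0:
                    x = x + np.random.default_rng(int(ns)).normal(0.0, sigma, size=x.shape)
                feats = reservoir_features(graph, source_kind, x, beta=beta)
                for target in targets:
                    task = WaveformTask(
                        target=target, n_samples=base_task.n_samples,
                        period=base_task.period, amplitude=base_task.amplitude,
                        split=base_task.split,
                    )
                    for rk in readout_kinds:
                        run = waveform_task_run(
                            graph, task, rk, source_kind, sigma,
                            noise_seed=int(ns), readout_seed=int(ns),
                            features=feats, **readout_kwargs,
                        )
                        rows.append(
                            {
                                "source": source_kind,
                                "target": target,
                                "readout": rk,
                                "sigma": sigma,
                                "noise_seed": int(ns),
                                "train_rmse": run.train_rmse,
                                "test_rmse": run.test_rmse,
                                "diverged": run.diverged,
                            }
                        )
    return NoiseResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# ionic immune-suppression workflow
# ---------------------------------------------------------------------------

IMMUNE_COLUMNS = ("activation", "ligand_mM", "k_ex_mM", "frequency_pct")
DEFAULT_K_LEVELS = (0.0, 10.0, 20.0, 40.0)


def synth_immune_table(
    ligand_levels=(0.5, 1.0, 2.0, 3.5, 5.0),
    k_levels=DEFAULT_K_LEVELS,
    activation: str = "CD3",
    max_frequency: float = 60.0,
    ec50: float = 1.5,
    hill: float = 2.0,
    k_suppression: float = 0.6,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic stand-in for a flow-cytometry activation summary.

    Response frequency (% of parent cells producing IFN-γ and IL-2) rises
    with ligand concentration as a Hill curve and declines linearly with
    extracellular K+ (fractional suppression ``k_suppression`` at the top
    of the sweep), plus optional Gaussian noise, clipped to [0, 100].
    With ``k_suppression = 0`` and ``noise_sd = 0`` the frequencies are
    constant across the K+ sweep.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k_max = max(max(k_levels), 1e-12)
    for c in ligand_levels:
        base = max_frequency * c**hill / (c**hill + ec50**hill)
        for k in k_levels:
            f = base * (1.0 - k_suppression * k / k_max)
            if noise_sd > 0:
                f += rng.normal(0.0, noise_sd)
            rows.append(
                {
                    "activation": activation,
                    "ligand_mM": float(c),
                    "k_ex_mM": float(k),
                    "frequency_pct": float(np.clip(f, 0.0, 100.0)),
                }
            )
    return pd.DataFrame(rows)


def validate_immune_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in IMMUNE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"immune table is missing columns: {missing}")
    if ((table.frequency_pct < 0) | (table.frequency_pct > 100)).any():
        raise ValueError("frequencies must lie in [0, 100] percent")
    return table


@dataclass
class ImmuneResult:
    activation: str
    train_rmse: float                      # percentage points
    ensemble: readout.EnsemblePrediction
    features: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    query: pd.DataFrame | None = None
    predictions: pd.DataFrame | None = None


def _immune_features(
    graph: reservoir.ReservoirGraph,
    k_levels: np.ndarray,
    ligand_levels: np.ndarray,
    source_kind: str,
    beta: float,
    k_in: float,
    charge_scale: float | None,
) -> tuple[np.ndarray, np.ndarray]:
    """CO-surface states for the ascending K+ sequence, concatenated with
    each ligand concentration.  The reservoir run depends only on the K+
    sequence, so it is executed once and reused across ligand levels."""
    charges = k_sequence_to_charges(np.sort(k_levels), k_in=k_in, scale=charge_scale)
    states = reservoir_features(graph, source_kind, charges, beta=beta)
    X, keys = [], []
    for c in ligand_levels:
        for i, k in enumerate(np.sort(k_levels)):
            X.append(concat_aux(states[i], c))
            keys.append((float(c), float(k)))
    return np.asarray(X), np.asarray(keys)


def immune_workflow(
    table: pd.DataFrame,
    graph: reservoir.ReservoirGraph,
    n_ensemble: int = DEFAULT_ENSEMBLE,
    base_seed: int = 0,
    source_kind: str = "spherical",
    beta: float = DEFAULT_BETA,
    k_in: float = 150.0,
    charge_scale: float | None = None,
    l1: float = 1e-4,
    l2: float = 1e-4,
    query_k: np.ndarray | None = None,
    query_ligand: np.ndarray | None = None,
    epochs: int = 3000,
) -> ImmuneResult:
    """Learn activation frequency from (ligand, [K+]ex) conditions.

    The four [K+]ex conditions are treated as a length-4 ascending input
    sequence with δq_t = [K+]in − [K+]ex; the organelle-surface state for
    each condition is concatenated with a replicated copy of the ligand
    concentration and fed to an elastic-net ANN (both L1 and L2 norms).
    Uncertainty comes from a statistical ensemble of independently
    initialized readouts (default 20 trials).  Predictions are produced
    for interpolated/extrapolated (K+, ligand) grids when given.
    """
    table = validate_immune_table(table)
    acts = table.activation.unique()
    if len(acts) != 1:
        raise ValueError("immune_workflow expects a single activation type per call")
    # replicate means: average duplicate (ligand, K) rows
    agg = (
        table.groupby(["ligand_mM", "k_ex_mM"], as_index=False)
        .frequency_pct.mean()
        .sort_values(["ligand_mM", "k_ex_mM"])
    )
    k_levels = np.sort(agg.k_ex_mM.unique())
    ligand_levels = np.sort(agg.ligand_mM.unique())
    X, keys = _immune_features(
        graph, k_levels, ligand_levels, source_kind, beta, k_in, charge_scale
    )
    lookup = {(r.ligand_mM, r.k_ex_mM): r.frequency_pct for r in agg.itertuples()}
    y = np.array([lookup[(c, k)] for c, k in keys])

    def factory(seed: int) -> ReadoutModel:
        return ReadoutModel("ann", l1=l1, l2=l2, seed=seed, epochs=epochs)

    query_df = None
    X_query = None
    if query_k is not None or query_ligand is not None:
        qk = np.sort(np.asarray(query_k if query_k is not None else k_levels, float))
        ql = np.asarray(query_ligand if query_ligand is not None else ligand_levels, float)
        Xq, qkeys = _immune_features(graph, qk, ql, source_kind, beta, k_in, charge_scale)
        X_query = Xq
        query_df = pd.DataFrame(qkeys, columns=["ligand_mM", "k_ex_mM"])

    ens = ensemble_predict(
        factory, X, y, X_query=X_query, n_trials=n_ensemble, base_seed=base_seed, split=1.0
    )
    pred_df = None
    if query_df is not None:
        pred_df = query_df.assign(mean=ens.mean, sd=ens.sd)
    return ImmuneResult(
        activation=str(acts[0]),
        train_rmse=float(ens.train_rmses.mean()),
        ensemble=ens,
        features=X,
        query=query_df,
        predictions=pred_df,
    )
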