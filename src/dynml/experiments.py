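"""Experiment drivers: benchmark prediction, size sweeps, entropy studies.

A master seed spawns independent named substreams (dataset / split / params
/ projection) through numpy's SeedSequence, so changing e.g. only the split
seed leaves the sampled reservoir parameters untouched and every run is
bitwise reproducible from its master seed.

Scaling convention (applies to every driver): inputs are standardized with
one per-variable scaler fitted on pooled training rows; targets are
standardized per (variable, transition) on training rows, which gives every
task slice unit variance and hence equal weight in the pooled Frobenius
objective — without it, near-constant slices (e.g. the Rössler z variable
between spikes) are ignored by the global readout. One global readout is
still fitted on all pooled transitions. Reported MSE is in original target
units; Pearson r is affine-invariant and unaffected by the inverse
transform.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .chaos_benchmarks import (
    PendulumProtocol,
    RosslerProtocol,
    TransitionDataset,
    assemble_transitions,
    simulate_ensemble,
    split_train_test,
)
from .core_dynamics import (
    DEFAULT_TAU_RANGE,
    IntegratorConfig,
    evolve_ensemble,
    sample_lorenz_params,
    sample_rossler_params,
)
from .embedding_readout import (
    TrainingBatch,
    accuracy,
    apply_scaler,
    embed_dataset,
    evaluate,
    fit_classifier_readout,
    fit_readout,
    fit_scaler,
    invert_scaler,
    make_projection,
    predict,
    predict_labels,
)
from .entropy import finite_time_entropy

__all__ = [
    "ExperimentConfig",
    "FitResult",
    "seed_streams",
    "run_benchmark",
    "fit_transition_model",
    "scaling_study",
    "entropy_performance_study",
    "classify_demo",
]

_STREAMS = ("dataset", "split", "params", "projection", "noise")


def seed_streams(master_seed: int) -> dict[str, np.random.Generator]:
    """Independent named RNG substreams spawned from one master seed."""
    seqs = np.random.SeedSequence(master_seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(seq)
            for name, seq in zip(_STREAMS, seqs)}


@dataclass
class ExperimentConfig:
    """Configuration shared by the experiment drivers."""

    N: int = 200
    reservoir_kind: str = "lorenz"
    tau_range: tuple = DEFAULT_TAU_RANGE
    projection_scale: float = 1.0
    split_frac: float = 0.8
    master_seed: int = 0
    integ: IntegratorConfig = field(default_factory=IntegratorConfig)
    per_transition_readout: bool = False

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.split_frac < 1:
            raise ValueError("split_frac must be in (0, 1)")


@dataclass
class FitResult:
    """Everything one pooled fit produces, for evaluation and auditing."""

    results: pd.DataFrame          # one row per (task, split)
    readouts: dict                 # transition -> ReadoutMatrix (0 = pooled)
    input_scaler: object
    target_scalers: dict           # transition -> Scaler
    params: object
    projection: object
    train_rows: np.ndarray
    test_rows: np.ndarray
    predictions: np.ndarray        # (D, P) in original units
    features: np.ndarray | None = None  # (3N, D) reservoir states


def _target_scalers(ds: TransitionDataset, train_mask: np.ndarray) -> dict:
    scalers = {}
    for k in np.unique(ds.transition_index):
        rows = train_mask & (ds.transition_index == k)
        scalers[int(k)] = fit_scaler(ds.targets[rows], fitted_on="train")
    return scalers


def fit_transition_model(
    ds: TransitionDataset,
    config: ExperimentConfig,
    streams: dict | None = None,
    keep_features: bool = False,
) -> FitResult:
    """Split, scale, embed, fit the global readout and evaluate per task.

    The dataset must not be pre-split; splitting is driven by the "split"
    stream so it is reproducible and independent of parameter sampling.
    """
    streams = streams or seed_streams(config.master_seed)
    ds = split_train_test(ds, config.split_frac, streams["split"])
    tr = ds.split == "train"
    te = ~tr

    in_scaler = fit_scaler(ds.inputs[tr], fitted_on="train")
    U = apply_scaler(in_scaler, ds.inputs)
    t_scalers = _target_scalers(ds, tr)
    Ys = np.empty_like(ds.targets)
    for k, sc in t_scalers.items():
        m = ds.transition_index == k
        Ys[m] = apply_scaler(sc, ds.targets[m])

    if config.reservoir_kind == "lorenz":
        params = sample_lorenz_params(config.N, streams["params"],
                                      tau_range=config.tau_range)
    else:
        params = sample_rossler_params(config.N, streams["params"],
                                       tau_range=config.tau_range)
    proj = make_projection(U.shape[1], config.N, streams["projection"],
                           scale=config.projection_scale)
    X = embed_dataset(U, proj, params, config.integ)

    readouts = {}
    pred_s = np.empty_like(Ys)
    if config.per_transition_readout:
        for k in t_scalers:
            m = ds.transition_index == k
            batch = TrainingBatch(X=X[:, m & tr], Y=Ys[m & tr].T)
            readouts[k] = fit_readout(batch)
            pred_s[m] = predict(readouts[k], X[:, m]).T
    else:
        readouts[0] = fit_readout(TrainingBatch(X=X[:, tr], Y=Ys[tr].T))
        pred_s = predict(readouts[0], X).T

    # back to original units for MSE reporting
    pred = np.empty_like(pred_s)
    for k, sc in t_scalers.items():
        m = ds.transition_index == k
        pred[m] = invert_scaler(sc, pred_s[m])

    rows = []
    for split_name, mask in (("train", tr), ("test", te)):
        for k in t_scalers:
            m = mask & (ds.transition_index == k)
            for v, vname in enumerate(ds.var_names):
                r, p, mse = evaluate(pred[m, v], ds.targets[m, v])
                rows.append({
                    "N": config.N,
                    "seed": config.master_seed,
                    "task": f"{vname}:t{k}->t{k + 1}",
                    "variable": vname,
                    "transition": k,
                    "split": split_name,
                    "pearson_r": r,
                    "p_value": p,
                    "mse": mse,
                    "n": int(m.sum()),
                })
    return FitResult(
        results=pd.DataFrame(rows),
        readouts=readouts,
        input_scaler=in_scaler,
        target_scalers=t_scalers,
        params=params,
        projection=proj,
        train_rows=np.flatnonzero(tr),
        test_rows=np.flatnonzero(te),
        predictions=pred,
        features=X if keep_features else None,
    )


def make_benchmark_dataset(system: str, n_traj: int = 2000,
                           seed: int = 0) -> TransitionDataset:
    """Simulate a named benchmark and pool its transitions."""
    if system == "rossler":
        proto = RosslerProtocol(n_traj=n_traj, seed=seed)
    elif system == "pendulum":
        proto = PendulumProtocol(n_traj=n_traj, seed=seed)
    else:
        raise ValueError(f"unknown benchmark system {system!r}")
    return assemble_transitions(simulate_ensemble(proto))


def run_benchmark(system: str, config: ExperimentConfig,
                  n_traj: int = 2000) -> FitResult:
    """Full protocol for one benchmark: simulate, fit, evaluate per task.

    Defaults follow the benchmark protocols: 2000 perturbed trajectories,
    7 sampled timepoints, 80/20 trajectory-level split; N=30 is the
    reference ensemble size for the Rössler system and N=200 for the
    double pendulum.
    """
    streams = seed_streams(config.master_seed)
    dataset_seed = int(streams["dataset"].integers(2**31))
    ds = make_benchmark_dataset(system, n_traj=n_traj, seed=dataset_seed)
    return fit_transition_model(ds, config, streams=streams)


def scaling_study(
    ds: TransitionDataset,
    N_grid=None,
    seeds=(0, 1, 2, 3, 4),
    config: ExperimentConfig | None = None,
) -> pd.DataFrame:
    """Mean/sd of test and train r (and wall time) across seeds per N.

    Default grid is 2..130 in steps of 4 (33 sizes). Wall time is recorded
    for reporting only.
    """
    if N_grid is None:
        N_grid = list(range(2, 131, 4))
    base = config or ExperimentConfig()
    rows = []
    for N in N_grid:
        for seed in seeds:
            cfg = ExperimentConfig(
                N=int(N), reservoir_kind=base.reservoir_kind,
                tau_range=base.tau_range,
                projection_scale=base.projection_scale,
                split_frac=base.split_frac, master_seed=int(seed),
                integ=base.integ,
            )
            t0 = time.perf_counter()
            res = fit_transition_model(ds, cfg)
            wall = time.perf_counter() - t0
            for split in ("train", "test"):
                sub = res.results[res.results.split == split]
                rows.append({
                    "N": int(N), "seed": int(seed), "split": split,
                    "mean_r": sub.pearson_r.mean(),
                    "min_r": sub.pearson_r.min(),
                    "mean_mse": sub.mse.mean(),
                    "wall_time": wall,
                })
    per_run = pd.DataFrame(rows)
    agg = (per_run.groupby(["N", "split"])
           .agg(mean_r=("mean_r", "mean"), sd_r=("mean_r", "std"),
                min_r=("min_r", "mean"), mean_wall_time=("wall_time", "mean"))
           .reset_index())
    agg.attrs["per_run"] = per_run
    return agg


def entropy_performance_study(
    ds: TransitionDataset,
    N_grid=(4, 8, 16, 32, 64, 128),
    seeds=(0, 1, 2, 3, 4, 5, 6),
    epsilon: float = 0.5,
    n_entropy_inputs: int = 10,
    config: ExperimentConfig | None = None,
) -> dict:
    """Paired entropy/performance sweep and its log-linear fits.

    Per (N, seed): fit the model on ``ds`` and estimate the input-averaged
    finite-time entropy of the same reservoir on the first
    ``n_entropy_inputs`` scaled training inputs. Returns the per-N
    aggregated table plus least-squares lines of mean entropy and mean
    test r against ln N.
    """
    base = config or ExperimentConfig()
    rows = []
    for N in N_grid:
        for seed in seeds:
            cfg = ExperimentConfig(
                N=int(N), reservoir_kind=base.reservoir_kind,
                tau_range=base.tau_range,
                projection_scale=base.projection_scale,
                split_frac=base.split_frac, master_seed=int(seed),
                integ=base.integ,
            )
            streams = seed_streams(cfg.master_seed)
            res = fit_transition_model(ds, cfg, streams=streams)
            # entropy of this very reservoir on its own training inputs
            U = apply_scaler(res.input_scaler, ds.inputs)
            take = res.train_rows[:n_entropy_inputs]
            x0 = U[take] @ res.projection.R.T
            _, trajs = evolve_ensemble(x0, res.params, cfg.integ,
                                       want_trajectory=True)
            hs = [finite_time_entropy(tr, epsilon).h for tr in trajs]
            for split in ("train", "test"):
                sub = res.results[res.results.split == split]
                rows.append({
                    "N": int(N), "seed": int(seed), "split": split,
                    "mean_r": sub.pearson_r.mean(),
                    "mean_h": float(np.mean(hs)),
                })
    per_run = pd.DataFrame(rows)
    agg = (per_run.groupby(["N", "split"])
           .agg(mean_r=("mean_r", "mean"), sd_r=("mean_r", "std"),
                mean_h=("mean_h", "mean"), sd_h=("mean_h", "std"))
           .reset_index())

    test = agg[agg.split == "test"].sort_values("N")
    lnN = np.log(test.N.to_numpy(dtype=float))
    fits = {}
    for col in ("mean_h", "mean_r"):
        y = test[col].to_numpy()
        slope, intercept, r, p, _ = stats.linregress(lnN, y)
        fits[col] = {"slope": slope, "intercept": intercept,
                     "pearson_r": r, "p_value": p}
    h_r_corr = float(np.corrcoef(test.mean_h, test.mean_r)[0, 1])
    return {"table": agg, "per_run": per_run, "fits": fits,
            "entropy_performance_corr": h_r_corr, "epsilon": epsilon}


def classify_demo(
    features: np.ndarray,
    labels: np.ndarray,
    config: ExperimentConfig | None = None,
    test_frac: float = 0.2,
) -> dict:
    """Static classification through a Rössler ensemble + logistic readout.

    Features are any (D, M) vectors (e.g. flattened images) supplied by the
    caller; nothing is downloaded. Returns train/test accuracy and the
    per-sample test predictions.
    """
    config = config or ExperimentConfig(N=100, reservoir_kind="rossler")
    if config.reservoir_kind != "rossler":
        raise ValueError("the classification demo uses a Rössler core")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on sample count")
    streams = seed_streams(config.master_seed)
    D = features.shape[0]
    perm = streams["split"].permutation(D)
    n_test = int(round(test_frac * D))
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    sc = fit_scaler(features[train_idx], fitted_on="train")
    F = apply_scaler(sc, features)
    params = sample_rossler_params(config.N, streams["params"],
                                   tau_range=config.tau_range)
    proj = make_projection(F.shape[1], config.N, streams["projection"],
                           scale=config.projection_scale)
    X = embed_dataset(F, proj, params, config.integ)
    clf = fit_classifier_readout(X[:, train_idx], labels[train_idx],
                                 seed=config.master_seed)
    pred = predict_labels(clf, X)
    return {
        "train_accuracy": accuracy(pred[train_idx], labels[train_idx]),
        "test_accuracy": accuracy(pred[test_idx], labels[test_idx]),
        "test_predictions": pd.DataFrame({
            "index": test_idx,
            "label": labels[test_idx],
            "predicted": pred[test_idx],
        }),
    }
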