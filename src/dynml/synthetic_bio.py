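"""Synthetic biological datasets with smooth nonlinear temporal structure.

Two generators emulate the *shapes* and temporal character of the
biological applications the pipeline targets, so the full train/predict
stack can be exercised without external downloads:

* ``generate_embryo_like`` — an early-embryo expression atlas: n_cells
  cells, each with 3-D spatial coordinates and n_genes gene levels tracked
  over n_timepoints developmental stages. Each cell carries a latent 3-D
  state that evolves under a slow, contracting nonlinear flow whose initial
  condition depends smoothly on the cell's position; genes are nonlinear
  (softplus) readouts of the latent state modulated by smooth spatial
  gradients. Expression is therefore non-negative, smooth in time and
  spatially structured.
* ``generate_regeneration_like`` — a regeneration time course: gene
  *clusters* share a smooth mean trajectory over ordinal stages; each
  sample draws one gene per cluster, giving a (n_samples, n_clusters,
  n_timepoints) panel with strong within-cluster correlation.

These are stand-ins constructed by this package, not fits to any real
atlas; they reproduce dimensionality, smoothness and cluster structure but
not the measured biology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chaos_benchmarks import TransitionDataset

__all__ = [
    "EmbryoLikeDataset",
    "RegenerationLikeDataset",
    "generate_embryo_like",
    "prepare_transition_samples",
    "filter_complete_genes",
    "generate_regeneration_like",
    "select_transition",
]


@dataclass(frozen=True)
class EmbryoLikeDataset:
    """expression: (n_cells, n_genes, n_timepoints); coords: (n_cells, 3)."""

    expression: np.ndarray
    coords: np.ndarray
    gene_names: tuple
    cell_ids: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.expression.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.expression.shape[2]


@dataclass(frozen=True)
class RegenerationLikeDataset:
    """panel: (n_samples, n_clusters, n_timepoints); stages are ordinal."""

    panel: np.ndarray
    cluster_ids: tuple
    timepoint_labels: tuple

    @property
    def n_samples(self) -> int:
        return self.panel.shape[0]

    @property
    def n_clusters(self) -> int:
        return self.panel.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.panel.shape[2]


def _softplus(x):
    return np.logaddexp(0.0, x)


def generate_embryo_like(
    n_cells: int = 500,
    n_genes: int = 27,
    n_timepoints: int = 6,
    seed: int = 0,
    noise_sd: float = 0.05,
) -> EmbryoLikeDataset:
    """Latent-flow embryo-like atlas; deterministic per seed.

    The latent state of each cell follows dl/dt = rate * (tanh(W l + c) - l)
    (a smooth contracting flow, rate 0.4), initialized from a smooth
    function of the cell's coordinates, and is read out into genes through
    random loadings, a spatial-gradient gain and a softplus nonlinearity.
    """
    if min(n_cells, n_genes, n_timepoints) < 1:
        raise ValueError("dimensions must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-1.0, 1.0, size=(n_cells, 3))

    # latent flow shared by all cells
    W = rng.normal(0, 1.2, size=(3, 3))
    c = rng.normal(0, 0.5, size=3)
    B = rng.normal(0, 1.0, size=(3, 3))
    lat = np.tanh(coords @ B.T)  # initial latent state, smooth in space
    rate, t_span, dt = 0.4, 5.0, 0.05
    n_steps_between = int(round(t_span / dt / max(n_timepoints - 1, 1)))

    def flow(l):
        return rate * (np.tanh(l @ W.T + c) - l)

    latents = np.empty((n_timepoints, n_cells, 3))
    latents[0] = lat
    for t in range(1, n_timepoints):
        for _ in range(n_steps_between):
            k1 = flow(lat)
            k2 = flow(lat + 0.5 * dt * k1)
            k3 = flow(lat + 0.5 * dt * k2)
            k4 = flow(lat + dt * k3)
            lat = lat + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        latents[t] = lat

    # gene readout: loadings on latent state, spatial gain, softplus
    loadings = rng.normal(0, 1.0, size=(n_genes, 3))
    bias = rng.normal(0.5, 0.3, size=n_genes)
    spatial_w = rng.normal(0, 0.8, size=(n_genes, 3))
    gain = 1.0 + 0.5 * np.tanh(coords @ spatial_w.T)  # (n_cells, n_genes)

    expr = np.empty((n_cells, n_genes, n_timepoints))
    for t in range(n_timepoints):
        pre = latents[t] @ loadings.T + bias  # (n_cells, n_genes)
        expr[:, :, t] = _softplus(pre * gain)
    if noise_sd > 0:
        expr = _softplus(
            np.log(np.expm1(np.clip(expr, 1e-12, None)))
            + rng.normal(0, noise_sd, size=expr.shape)
        )
    return EmbryoLikeDataset(
        expression=expr,
        coords=coords,
        gene_names=tuple(f"g{i:02d}" for i in range(n_genes)),
        cell_ids=np.arange(n_cells),
    )


def prepare_transition_samples(ds: EmbryoLikeDataset) -> TransitionDataset:
    """Cell-transition pairs: input = genes at t plus the cell's (x, y, z);
    target = genes at t+1. All transitions of a cell share its trajectory
    id, so trajectory-level splitting is cell-level splitting."""
    if ds.n_timepoints < 2:
        raise ValueError("need at least two timepoints")
    n_trans = ds.n_timepoints - 1
    genes_t = ds.expression[:, :, :-1]   # (cells, genes, trans)
    genes_t1 = ds.expression[:, :, 1:]
    inputs = np.concatenate(
        [
            genes_t.transpose(0, 2, 1).reshape(-1, ds.n_genes),
            np.repeat(ds.coords, n_trans, axis=0),
        ],
        axis=1,
    )
    targets = genes_t1.transpose(0, 2, 1).reshape(-1, ds.n_genes)
    return TransitionDataset(
        inputs=inputs,
        targets=targets,
        transition_index=np.tile(np.arange(1, n_trans + 1), ds.n_cells),
        trajectory_id=np.repeat(ds.cell_ids, n_trans),
        var_names=ds.gene_names,
        input_names=ds.gene_names + ("x", "y", "z"),
    )


def filter_complete_genes(expression: np.ndarray):
    """Keep genes with no missing (NaN) value at any timepoint in any cell.

    Returns (mask, filtered) where mask is a boolean per-gene vector on
    axis 1 of a (cells, genes, timepoints) array.
    """
    expression = np.asarray(expression, dtype=float)
    if expression.ndim != 3:
        raise ValueError("expected (cells, genes, timepoints)")
    mask = ~np.isnan(expression).any(axis=(0, 2))
    return mask, expression[:, mask, :]


def generate_regeneration_like(
    n_samples: int = 6000,
    n_clusters: int = 15,
    n_timepoints: int = 13,
    genes_per_cluster: int = 40,
    seed: int = 0,
) -> RegenerationLikeDataset:
    """Cluster-representative panel; deterministic per seed.

    Each cluster's mean time course is a smooth random curve (a low-order
    cosine series over the ordinal stages). Member genes follow the shared
    program of their cluster: gene = mean + (gene-specific scale) x
    (cluster-level deviation shape) + a small smooth gene-specific wiggle
    plus light observation noise — so a gene's level at one stage carries
    the information needed to anticipate the next stage, as co-expression
    cluster membership does in real regeneration time courses. Each sample
    picks one member gene per cluster.
    """
    if min(n_samples, n_clusters, n_timepoints, genes_per_cluster) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_timepoints)
    n_harm = 3
    basis = np.stack(
        [np.cos(np.pi * (k + 1) * t) for k in range(n_harm)], axis=0
    )  # (n_harm, T)

    cluster_means = rng.normal(0, 1.0, (n_clusters, n_harm)) @ basis
    cluster_means += rng.normal(0, 0.5, (n_clusters, 1))
    # one deviation shape per cluster, offset so no stage is a zero crossing
    shapes = rng.normal(0, 0.6, (n_clusters, n_harm)) @ basis
    shapes += np.sign(rng.normal(size=(n_clusters, 1))) * 1.0
    scale = rng.normal(0, 0.5, (n_clusters, genes_per_cluster))
    wiggle = rng.normal(0, 0.05, (n_clusters, genes_per_cluster,
                                  n_harm)) @ basis
    genes = (cluster_means[:, None, :]
             + scale[:, :, None] * shapes[:, None, :] + wiggle)
    genes += rng.normal(0, 0.02, genes.shape)

    choice = rng.integers(0, genes_per_cluster, size=(n_samples, n_clusters))
    panel = genes[np.arange(n_clusters)[None, :], choice, :]
    return RegenerationLikeDataset(
        panel=panel,
        cluster_ids=tuple(f"c{i:02d}" for i in range(n_clusters)),
        timepoint_labels=tuple(f"stage{i:02d}" for i in range(n_timepoints)),
    )


def select_transition(ds: RegenerationLikeDataset, from_idx: int,
                      to_idx: int) -> TransitionDataset:
    """One named stage transition as a sample-level transition dataset."""
    T = ds.n_timepoints
    for idx in (from_idx, to_idx):
        if not 0 <= idx < T:
            raise ValueError(f"stage index {idx} outside [0, {T - 1}]")
    return TransitionDataset(
        inputs=ds.panel[:, :, from_idx],
        targets=ds.panel[:, :, to_idx],
        transition_index=np.ones(ds.n_samples, dtype=int),
        trajectory_id=np.arange(ds.n_samples),
        var_names=ds.cluster_ids,
        input_names=ds.cluster_ids,
    )
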