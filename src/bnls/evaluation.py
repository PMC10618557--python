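"""Replication harness: classification/MSE metrics over simulated datasets.

``replicate_study`` runs simulate -> fit -> summarize -> score for a grid of
scenarios and averages the metrics over datasets, mirroring the layout of the
simulation-study tables: voxel (activation region, "AR") and variant
("GV") accuracy / sensitivity / specificity plus MSE of the posterior-mean
eta and mu.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Callable, Optional, Sequence

import numpy as np

from .forward_model import Dataset
from .gp_basis import Grid, KernelSpec, build_basis
from .mcmc import PosteriorDraws, RunConfig, run_chain
from .selection import (
    select_snps_ci,
    select_snps_ssvs,
    select_voxels,
    voxel_inclusion_map,
)
from .simulator import SimConfig, SimTruth, simulate_dataset

__all__ = ["MetricsRow", "confusion_metrics", "mse", "replicate_study",
           "evaluate_fit"]


@dataclass
class MetricsRow:
    """Averaged metrics for one simulation scenario."""

    shape: str
    snr_beta: Optional[float]
    snr_eta: Optional[float]
    prior_variant: str
    acc_ar: float
    tpr_ar: float
    tnr_ar: float
    acc_gv: float
    tpr_gv: float
    tnr_gv: float
    mse_eta: float
    mse_mu: float
    n_datasets: int
    seeds: list
    diverged: int = 0


def confusion_metrics(selected, truth, universe_size: int):
    """(accuracy, sensitivity, specificity) of an index-set classification.

    TPR is NaN when the truth set is empty, TNR is NaN when the truth covers
    the whole universe.
    """
    selected = np.asarray(selected, dtype=int)
    truth = np.asarray(truth, dtype=int)
    for idx in (selected, truth):
        if idx.size and (idx.min() < 0 or idx.max() >= universe_size):
            raise ValueError("indices outside the universe")
    sel = np.zeros(universe_size, dtype=bool)
    sel[selected] = True
    tru = np.zeros(universe_size, dtype=bool)
    tru[truth] = True
    tp = int(np.sum(sel & tru))
    tn = int(np.sum(~sel & ~tru))
    n_pos = int(tru.sum())
    n_neg = universe_size - n_pos
    acc = (tp + tn) / universe_size
    tpr = tp / n_pos if n_pos else float("nan")
    tnr = tn / n_neg if n_neg else float("nan")
    return acc, tpr, tnr


def mse(estimate, truth) -> float:
    """Mean squared componentwise error."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if estimate.shape != truth.shape:
        raise ValueError("length mismatch")
    return float(np.mean((estimate - truth) ** 2))


def evaluate_fit(draws: PosteriorDraws, truth: SimTruth, basis,
                 voxel_threshold: float = 0.5,
                 variant_threshold: float = 0.02) -> dict:
    """Score one fitted dataset against its ground truth."""
    p = truth.phi.shape[0]
    m = truth.eta.shape[0]
    inc = voxel_inclusion_map(draws, basis)
    vox_sel = select_voxels(inc, voxel_threshold)
    vox_truth = np.flatnonzero(truth.labels > 0)
    acc_ar, tpr_ar, tnr_ar = confusion_metrics(vox_sel, vox_truth, p)

    out = dict(acc_ar=acc_ar, tpr_ar=tpr_ar, tnr_ar=tnr_ar,
               mse_mu=mse(draws.mu.mean(axis=0), truth.mu))
    if m:
        if draws.prior_variant == "spike_slab":
            res = select_snps_ssvs(draws, threshold=variant_threshold)
        else:
            res = select_snps_ci(draws)
        acc_gv, tpr_gv, tnr_gv = confusion_metrics(res.selected, truth.active, m)
        out.update(acc_gv=acc_gv, tpr_gv=tpr_gv, tnr_gv=tnr_gv,
                   mse_eta=mse(draws.eta.mean(axis=0), truth.eta))
    else:
        out.update(acc_gv=float("nan"), tpr_gv=float("nan"),
                   tnr_gv=float("nan"), mse_eta=float("nan"))
    return out


def _scenario_seed(base_seed: int, scenario_idx: int, dataset_idx: int) -> int:
    return int((base_seed * 1_000_003 + scenario_idx * 10_007
                + dataset_idx * 101 + 7) % (2**31 - 1))


def replicate_study(scenarios: Sequence[SimConfig], n_datasets: int,
                    run_config: RunConfig, base_seed: int = 0,
                    prior_variant: Optional[str] = None,
                    variant_threshold: float = 0.02,
                    fitter: Optional[Callable] = None) -> list[MetricsRow]:
    """Run each scenario ``n_datasets`` times and average the metrics.

    ``fitter(data, basis, config)`` may replace the default ``run_chain`` (for
    harness tests).  A diverged chain is recorded and skipped in the averages.
    Basis expansions are cached per (grid, kernel) combination.
    """
    if n_datasets < 1:
        raise ValueError("need at least one dataset per scenario")
    variant = prior_variant or run_config.prior_variant
    fit = fitter or (lambda data, basis, cfg: run_chain(data, basis, cfg))
    basis_cache: dict = {}
    rows = []
    for s_idx, scen in enumerate(scenarios):
        per_ds = []
        seeds = []
        diverged = 0
        for d_idx in range(n_datasets):
            seed = _scenario_seed(base_seed, s_idx, d_idx)
            seeds.append(seed)
            data, truth = simulate_dataset(dc_replace(scen, seed=seed))
            key = (scen.grid_shape, run_config.hyper.alpha,
                   scen.kernel.inverse_scale, scen.kernel.variance)
            if key not in basis_cache:
                basis_cache[key] = build_basis(
                    data.grid, scen.kernel, run_config.hyper.alpha)
            basis = basis_cache[key]
            cfg = dc_replace(run_config, seed=seed + 1, prior_variant=variant)
            try:
                draws = fit(data, basis, cfg)
            except RuntimeError:
                diverged += 1
                continue
            per_ds.append(evaluate_fit(draws, truth, basis,
                                       variant_threshold=variant_threshold))
        if not per_ds:
            raise RuntimeError(
                f"all chains diverged in scenario {s_idx} ({scen.shape_kind})")

        def avg(key):
            vals = np.array([d[key] for d in per_ds], dtype=float)
            return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")

        rows.append(MetricsRow(
            shape=scen.shape_kind, snr_beta=scen.snr_beta,
            snr_eta=scen.snr_eta, prior_variant=variant,
            acc_ar=avg("acc_ar"), tpr_ar=avg("tpr_ar"), tnr_ar=avg("tnr_ar"),
            acc_gv=avg("acc_gv"), tpr_gv=avg("tpr_gv"), tnr_gv=avg("tnr_gv"),
            mse_eta=avg("mse_eta"), mse_mu=avg("mse_mu"),
            n_datasets=len(per_ds), seeds=seeds, diverged=diverged,
        ))
    return rows
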