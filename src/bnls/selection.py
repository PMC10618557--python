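"""Posterior summaries: voxel inclusion-probability maps and variant selection.

Voxels are summarized by the posterior inclusion probability z_j, the
posterior frequency of phi_j = (Psi beta)_j > 0 across saved draws, and
selected by thresholding the map (0.5 by default).  Variants are selected
either from the spike-and-slab indicators (PIP = posterior frequency of the
slab; threshold 0.02 in the simulation profile, 0.5 in the stringent profile)
or, for the normal-prior variant, by a 99% equal-tailed credible-interval
rule: a variant is flagged when its interval excludes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .gp_basis import BasisExpansion, Grid
from .mcmc import PosteriorDraws

__all__ = [
    "InclusionMap",
    "SelectionResult",
    "voxel_inclusion_map",
    "select_voxels",
    "select_snps_ssvs",
    "select_snps_ci",
]

# PIP thresholds: the simulation profile replicates the simulation-study rule
# (> 0.02); the stringent profile is the real-data rule (> 0.5).
SSVS_THRESHOLD_SIMULATION = 0.02
SSVS_THRESHOLD_STRINGENT = 0.5
VOXEL_THRESHOLD = 0.5


@dataclass
class InclusionMap:
    """Per-voxel posterior inclusion probabilities on a grid."""

    probs: np.ndarray
    grid: Optional[Grid] = field(default=None, repr=False)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("inclusion probabilities must be a vector in [0, 1]")


@dataclass
class SelectionResult:
    """Selected index sets with the per-variant summaries behind them."""

    selected: np.ndarray
    pip: np.ndarray
    threshold: float
    ci_low: Optional[np.ndarray] = None
    ci_high: Optional[np.ndarray] = None


def voxel_inclusion_map(draws: PosteriorDraws, basis: BasisExpansion) -> InclusionMap:
    """z_j = fraction of saved draws with (Psi beta^(t))_j > 0."""
    if draws.n_saved == 0:
        raise ValueError("no saved draws")
    Phi = draws.beta @ basis.Psi.T
    return InclusionMap(probs=np.mean(Phi > 0, axis=0), grid=basis.grid)


def select_voxels(inc_map: InclusionMap, threshold: float = VOXEL_THRESHOLD,
                  strict: bool = True) -> np.ndarray:
    """Indices of voxels whose inclusion probability passes the threshold.

    ``strict=True`` uses z_j > threshold (the simulation-study rule);
    ``strict=False`` uses z_j >= threshold (the real-data rule).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if strict:
        return np.flatnonzero(inc_map.probs > threshold)
    return np.flatnonzero(inc_map.probs >= threshold)


def select_snps_ssvs(draws: PosteriorDraws,
                     threshold: float = SSVS_THRESHOLD_SIMULATION) -> SelectionResult:
    """Spike-and-slab selection: PIP_k = posterior frequency of gamma_k = 1,
    select variants with PIP > threshold."""
    if draws.prior_variant != "spike_slab":
        raise ValueError("SSVS selection requires spike-and-slab draws")
    if draws.n_saved == 0 or draws.gamma.shape[1] == 0:
        raise ValueError("no spike-and-slab draws present")
    pip = np.mean(draws.gamma == 1.0, axis=0)
    return SelectionResult(selected=np.flatnonzero(pip > threshold),
                           pip=pip, threshold=threshold)


def select_snps_ci(draws: PosteriorDraws, level: float = 0.99,
                   pip_threshold: float = 0.01) -> SelectionResult:
    """Credible-interval rule for the normal-prior variant.

    A single equal-tailed ``level`` interval per variant is formed from all
    post-burn-in draws of eta_k; the variant's indicator is 1 when the
    interval excludes zero, so the PIP is binary and the default threshold
    0.01 reduces to the exclusion test itself.
    """
    if draws.prior_variant != "normal":
        raise ValueError("credible-interval selection requires normal-prior draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    if draws.n_saved == 0 or draws.eta.shape[1] == 0:
        raise ValueError("no eta draws present")
    tail = 0.5 * (1.0 - level)
    lo = np.quantile(draws.eta, tail, axis=0)
    hi = np.quantile(draws.eta, 1.0 - tail, axis=0)
    excl = ((lo > 0) | (hi < 0)).astype(float)
    return SelectionResult(selected=np.flatnonzero(excl > pip_threshold),
                           pip=excl, threshold=pip_threshold,
                           ci_low=lo, ci_high=hi)
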