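"""Haploid Li & Stephens copying HMM over grids, for one read-label class.

The hidden state at grid ``g`` is which of K conditioning reference
haplotypes the target haplotype copies there. Transitions are allowed only
between grids (a grid being 32 consecutive SNPs); within a grid the copied
haplotype is fixed. Emissions come from the fragments currently assigned to
the class: a fragment contributes its per-site match/mismatch factors to the
grid each site belongs to, so a fragment spanning several grids factorizes
across them.

``haploid_alt_posterior`` converts state posteriors into the per-SNP
probability that the class haplotype carries the alternate allele:
``p_t = sum_k theta[t, k] * gamma[g_t, k]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .panel_io import GridPanel, HaplotypePanel
from .read_model import ReadFragment, error_probs

THETA_FLOOR = 1e-4
N_GEN_DEFAULT = 100.0


@dataclass
class ModelParams:
    """Parameters of one copying HMM: the conditioning sub-panel and rates."""

    K: int
    subpanel: np.ndarray     # (K,) row indices into the full panel
    sigma: np.ndarray        # (G-1,) inter-grid switch probabilities
    theta: np.ndarray        # (M, K) P(hap k carries alt at SNP t), floored
    n_gen: float = N_GEN_DEFAULT

    def __post_init__(self):
        if np.any(self.sigma < 0) or np.any(self.sigma >= 1):
            raise ValueError("sigma must lie in [0, 1)")


def make_params(panel: HaplotypePanel, grids: GridPanel, subpanel: np.ndarray,
                n_gen: float = N_GEN_DEFAULT,
                theta_floor: float = THETA_FLOOR) -> ModelParams:
    """Bundle a conditioning subset into HMM parameters.

    theta maps the sub-panel's 0/1 alleles to {floor, 1 - floor}, tolerating
    panel genotyping error.
    """
    subpanel = np.asarray(subpanel, dtype=np.int64)
    alleles = panel.alleles[subpanel].T.astype(np.float64)  # (M, K)
    theta = alleles * (1.0 - 2.0 * theta_floor) + theta_floor
    sigma = transition_probs(grids.grid_cm, len(subpanel), n_gen)
    return ModelParams(K=len(subpanel), subpanel=subpanel, sigma=sigma,
                       theta=theta, n_gen=n_gen)


@dataclass
class GridPosterior:
    """gamma[g, k] = P(copied haplotype at grid g is k | class observations)."""

    gamma: np.ndarray  # (G, K), rows sum to 1


def transition_probs(grid_cm: np.ndarray, K: int,
                     n_gen: float = N_GEN_DEFAULT) -> np.ndarray:
    """Per-interval switch probability sigma = 1 - exp(-n_gen * d_cM / 100).

    The full kernel is: stay with 1 - sigma + sigma/K, switch to each other
    state with sigma/K (rows sum to 1 for any sigma and K).
    """
    grid_cm = np.asarray(grid_cm, dtype=np.float64)
    if np.any(grid_cm < 0):
        raise ValueError("negative genetic distance")
    return 1.0 - np.exp(-n_gen * grid_cm / 100.0)


def class_log_emissions(fragments: list[ReadFragment], params: ModelParams,
                        grids: GridPanel,
                        seq_error_floor: float | None = None) -> np.ndarray:
    """Accumulate per-grid per-state log emissions for a set of fragments."""
    G, K = grids.G, params.K
    logem = np.zeros((G, K))
    for frag in fragments:
        if frag.n_covered == 0:
            continue
        e = error_probs(frag.quals) if seq_error_floor is None \
            else error_probs(frag.quals, seq_error_floor)
        th = params.theta[frag.sites]  # (n, K)
        obs = frag.alleles[:, None].astype(np.float64)
        e = e[:, None]
        # P(obs | state k) marginalizing the panel allele through theta
        p = np.where(obs == 1, th * (1 - e) + (1 - th) * e,
                     th * e + (1 - th) * (1 - e))
        lp = np.log(p)
        np.add.at(logem, grids.snp_to_grid[frag.sites], lp)
    return logem


def forward_backward(fragments: list[ReadFragment], params: ModelParams,
                     grids: GridPanel) -> GridPosterior:
    """State posteriors for one label class given its fragments.

    With no fragments the posterior is uniform 1/K at every grid.
    """
    logem = class_log_emissions(fragments, params, grids)
    gamma = _kernels.forward_backward(logem, params.sigma)
    return GridPosterior(gamma=gamma)


def class_log_likelihood(fragments: list[ReadFragment], params: ModelParams,
                         grids: GridPanel) -> float:
    logem = class_log_emissions(fragments, params, grids)
    return float(_kernels.forward_ll(logem, params.sigma))


def haploid_alt_posterior(gamma: GridPosterior | np.ndarray, theta: np.ndarray,
                          snp_to_grid: np.ndarray) -> np.ndarray:
    """Per-SNP alternate-allele posterior: p_t = sum_k theta[t,k] gamma[g_t,k]."""
    g = gamma.gamma if isinstance(gamma, GridPosterior) else np.asarray(gamma)
    p = np.einsum("mk,mk->m", theta, g[snp_to_grid])
    return np.clip(p, 0.0, 1.0)
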