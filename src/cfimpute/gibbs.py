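"""The read-label Gibbs sampler: diploid and NIPT (cell-free DNA) imputation.

Each sequencing fragment carries a latent label: which underlying haplotype
it came from. Diploid samples have two labels; cfDNA from a pregnancy has
three (1 = maternal transmitted, 2 = maternal untransmitted, 3 = paternal
transmitted) with prior (0.5, 0.5 - FF/2, FF/2) set by the fetal fraction
FF. Given a labelling, the fragments of each class drive an independent
haploid copying HMM; the sampler alternates per-fragment label updates,
block updates that swap labels downstream of a grid boundary (repairing
phase switch errors), and refreshes of the conditioning haplotype subset via
msPBWT queries against the full panel.

Imputation runs in two stages: stage 1 iterates sampling + refresh using
only common SNPs and the reads intersecting them; stage 2 restores all sites
and fragments, initializes labels from the current haplotype estimates, and
averages the per-SNP alternate-allele posteriors over the final sweeps into
dosages. Maternal genotype dosage sums classes 1 and 2; fetal, classes 1
and 3.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import RunConfig
from .ls_hmm import ModelParams, make_params, haploid_alt_posterior
from .mspbwt import (MsPbwtIndex, insert_target, scan_neighbours,
                     select_conditioning_haps)
from .panel_io import GridPanel, HaplotypePanel, SiteRecord, pack_allele_vector, split_sites
from .read_model import ReadSet, error_probs

logger = logging.getLogger(__name__)

NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# Label prior (the heart of the NIPT mode)
# ---------------------------------------------------------------------------

@dataclass
class NiptConfig:
    """Mode and fetal fraction for one imputation run."""

    mode: str = "diploid"
    ff: float | None = None

    def __post_init__(self):
        if self.mode not in ("diploid", "nipt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "nipt":
            if self.ff is None:
                raise ValueError("nipt mode requires a fetal fraction")
            if not 0.0 <= self.ff <= 1.0:
                raise ValueError("ff must be in [0, 1]")
            if not 0.04 <= self.ff <= 0.5:
                logger.warning("fetal fraction %.3f outside the typical [0.04, 0.5] range",
                               self.ff)

    @property
    def n_labels(self) -> int:
        return 3 if self.mode == "nipt" else 2


def label_prior(cfg: NiptConfig) -> np.ndarray:
    """Prior probability of a fragment's haplotype-of-origin label.

    NIPT: (0.5, 0.5 - FF/2, FF/2) over (maternal transmitted, maternal
    untransmitted, paternal transmitted); diploid: (0.5, 0.5).
    """
    if cfg.mode == "nipt":
        ff = float(cfg.ff)
        return np.array([0.5, 0.5 - ff / 2.0, ff / 2.0])
    return np.array([0.5, 0.5])


def _log_prior(prior: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.where(prior > 0, np.log(np.maximum(prior, 1e-300)), NEG_INF)


# ---------------------------------------------------------------------------
# Sampler state
# ---------------------------------------------------------------------------

@dataclass
class GibbsState:
    """Labels plus the per-class HMM emission caches they imply."""

    labels: np.ndarray              # (V,) int64 0-based class of each fragment
    E: np.ndarray                   # (n_lab, G, K) accumulated log emissions
    fptr: np.ndarray                # (V+1,) CSR pointers into fgrid/flog
    fgrid: np.ndarray               # (n_entries,) grid of each entry
    flog: np.ndarray                # (n_entries, K) log emission contribution
    frag_first_grid: np.ndarray     # (V,) first covered grid (or G for empty)
    params: ModelParams
    grids: GridPanel
    logprior: np.ndarray            # (n_lab,)
    n_sweeps_done: int = 0

    @property
    def n_labels(self) -> int:
        return self.E.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.labels.size


def build_obs_layout(reads: ReadSet, params: ModelParams, grids: GridPanel,
                     site_mask: np.ndarray | None = None):
    """CSR layout of per-fragment per-grid log emission contributions.

    ``site_mask`` (boolean over sites) restricts the observations used, e.g.
    to common SNPs in stage 1; fragments keep their slots but may have zero
    entries (and then always resample from the prior).
    """
    V = len(reads)
    K = params.K
    frag_rows = []
    for v, frag in enumerate(reads.fragments):
        if frag.n_covered == 0:
            continue
        sel = np.ones(frag.n_covered, dtype=bool) if site_mask is None \
            else site_mask[frag.sites]
        if not sel.any():
            continue
        sites = frag.sites[sel]
        e = error_probs(frag.quals[sel])[:, None]
        th = params.theta[sites]
        obs = frag.alleles[sel][:, None].astype(np.float64)
        p = np.where(obs == 1, th * (1 - e) + (1 - th) * e,
                     th * e + (1 - th) * (1 - e))
        lp = np.log(p)  # (n, K)
        gr = grids.snp_to_grid[sites].astype(np.int64)
        # aggregate per grid within the fragment
        ug, inv = np.unique(gr, return_inverse=True)
        acc = np.zeros((ug.size, K))
        np.add.at(acc, inv, lp)
        frag_rows.append((v, ug, acc))
    fptr = np.zeros(V + 1, dtype=np.int64)
    for v, ug, _ in frag_rows:
        fptr[v + 1] = ug.size
    fptr = np.cumsum(fptr)
    n_entries = int(fptr[-1])
    fgrid = np.zeros(n_entries, dtype=np.int64)
    flog = np.zeros((n_entries, K))
    frag_first_grid = np.full(V, grids.G, dtype=np.int64)
    for v, ug, acc in frag_rows:
        a, b = fptr[v], fptr[v + 1]
        fgrid[a:b] = ug
        flog[a:b] = acc
        frag_first_grid[v] = ug[0]
    return fptr, fgrid, flog, frag_first_grid


def init_state(reads: ReadSet, params: ModelParams, grids: GridPanel,
               cfg: NiptConfig, labels: np.ndarray,
               site_mask: np.ndarray | None = None) -> GibbsState:
    fptr, fgrid, flog, ffg = build_obs_layout(reads, params, grids, site_mask)
    n_lab = cfg.n_labels
    E = np.zeros((n_lab, grids.G, params.K))
    for v in range(len(reads)):
        a, b = fptr[v], fptr[v + 1]
        if a < b:
            np.add.at(E[labels[v]], fgrid[a:b], flog[a:b])
    return GibbsState(labels=np.asarray(labels, dtype=np.int64), E=E,
                      fptr=fptr, fgrid=fgrid, flog=flog, frag_first_grid=ffg,
                      params=params, grids=grids,
                      logprior=_log_prior(label_prior(cfg)))


# ---------------------------------------------------------------------------
# Conditional and sweeps
# ---------------------------------------------------------------------------

def label_conditional(v: int, state: GibbsState) -> np.ndarray:
    """Exact Gibbs conditional P(h_v = i | other labels, observations, FF).

    Proportional to the prior times the ratio of the class likelihood with
    fragment v included vs excluded; the prior does not cancel when it is
    non-uniform (NIPT).
    """
    a, b = state.fptr[v], state.fptr[v + 1]
    n_lab = state.n_labels
    sigma = state.params.sigma
    old = state.labels[v]
    if a == b:
        p = np.exp(state.logprior - state.logprior.max())
        return p / p.sum()
    # remove v from its class
    np.subtract.at(state.E[old], state.fgrid[a:b], state.flog[a:b])
    logp = np.empty(n_lab)
    for c in range(n_lab):
        if state.logprior[c] == NEG_INF:
            logp[c] = NEG_INF
            continue
        base = _kernels.forward_ll(state.E[c], sigma)
        np.add.at(state.E[c], state.fgrid[a:b], state.flog[a:b])
        with_v = _kernels.forward_ll(state.E[c], sigma)
        np.subtract.at(state.E[c], state.fgrid[a:b], state.flog[a:b])
        logp[c] = state.logprior[c] + with_v - base
    np.add.at(state.E[old], state.fgrid[a:b], state.flog[a:b])
    p = np.exp(logp - logp.max())
    return p / p.sum()


def gibbs_sweep(state: GibbsState, rng: np.random.Generator,
                greedy: bool = False) -> GibbsState:
    """Resample every fragment's label once, in a seeded random order.

    ``greedy=True`` takes the argmax of each conditional instead of sampling
    (an iterated-conditional-modes step used to polish the final state).
    """
    V = state.n_fragments
    order = rng.permutation(V).astype(np.int64)
    unif = rng.random(V)
    _kernels.gibbs_sweep_kernel(state.labels, state.E, state.fptr, state.fgrid,
                                state.flog, state.params.sigma, state.logprior,
                                order, unif, greedy)
    state.n_sweeps_done += 1
    return state


def joint_log_prob(state: GibbsState) -> float:
    """log P(O, H) up to a constant: class likelihoods plus label priors."""
    ll = sum(_kernels.forward_ll(state.E[c], state.params.sigma)
             for c in range(state.n_labels))
    counts = np.bincount(state.labels, minlength=state.n_labels)
    for c in range(state.n_labels):
        if counts[c] > 0:
            ll += counts[c] * state.logprior[c]
    return float(ll)


def _label_permutations(n_lab: int) -> list[tuple[int, ...]]:
    if n_lab == 2:
        return [(0, 1), (1, 0)]
    # identity plus the three transpositions
    return [(0, 1, 2), (1, 0, 2), (2, 1, 0), (0, 2, 1)]


def block_gibbs_pairs(state: GibbsState, rng: np.random.Generator,
                      greedy: bool = False) -> GibbsState:
    """Block update at every sequential grid-pair boundary.

    At each boundary the labels of all fragments starting at or after it are
    jointly relabelled by one of the label permutations (identity included),
    sampled from the exact conditional over that proposal set - a proper
    Gibbs draw that identifies and repairs phase switch errors. The boundary
    before the first grid is included, so a global label permutation (which
    resolves a genome-wide transmitted/untransmitted misassignment against
    the non-uniform NIPT prior) is proposed as well.
    """
    G = state.grids.G
    if G < 2:
        return state
    n_lab = state.n_labels
    perms = _label_permutations(n_lab)
    sigma = state.params.sigma
    V = state.n_fragments

    # E split into upstream/downstream-of-boundary parts, walked left to right
    E_down = state.E.copy()
    E_up = np.zeros_like(state.E)
    counts_down = np.bincount(state.labels, minlength=n_lab).astype(np.int64)
    by_first_grid: dict[int, list[int]] = {}
    for v in range(V):
        by_first_grid.setdefault(int(state.frag_first_grid[v]), []).append(v)
    down_mask = np.ones(V, dtype=bool)

    for b in range(0, G):
        for v in by_first_grid.get(b - 1, []) if b > 0 else []:
            c = state.labels[v]
            a0, a1 = state.fptr[v], state.fptr[v + 1]
            if a0 < a1:
                np.add.at(E_up[c], state.fgrid[a0:a1], state.flog[a0:a1])
                np.subtract.at(E_down[c], state.fgrid[a0:a1], state.flog[a0:a1])
            counts_down[c] -= 1
            down_mask[v] = False
        logw = np.empty(len(perms))
        for pi, perm in enumerate(perms):
            inv = np.argsort(np.array(perm))
            ll = 0.0
            ok = True
            for c in range(n_lab):
                if counts_down[inv[c]] > 0 and state.logprior[perm[inv[c]]] == NEG_INF:
                    ok = False
                    break
            if not ok:
                logw[pi] = NEG_INF
                continue
            for c in range(n_lab):
                ll += _kernels.forward_ll(E_up[c] + E_down[inv[c]], sigma)
            for lab in range(n_lab):
                if counts_down[lab] > 0:
                    ll += counts_down[lab] * state.logprior[perm[lab]]
            logw[pi] = ll
        if greedy:
            choice = int(np.argmax(logw))
        else:
            w = np.exp(logw - logw.max())
            w /= w.sum()
            choice = int(rng.choice(len(perms), p=w))
        perm = perms[choice]
        if perm != perms[0]:
            inv = np.argsort(np.array(perm))
            E_down = E_down[inv]
            counts_down = counts_down[inv]
            perm_arr = np.array(perm, dtype=np.int64)
            state.labels[down_mask] = perm_arr[state.labels[down_mask]]
    state.E[:] = E_up + E_down
    return state


# ---------------------------------------------------------------------------
# Conditioning-set refresh via msPBWT
# ---------------------------------------------------------------------------

def refresh_conditioning_set(hap_posteriors: list[np.ndarray],
                             panel: HaplotypePanel, grids: GridPanel,
                             index: MsPbwtIndex, K: int, min_len: int,
                             rng: np.random.Generator, L: int = 8) -> np.ndarray:
    """New conditioning subset from the current per-class haploid dosages.

    Each class's dosages are rounded to a hard haplotype, packed into grid
    words, and queried against the msPBWT; per-class selections are merged
    round-robin, de-duplicated and truncated/padded to K rows.
    """
    enc = index.enc
    per_class: list[list[int]] = []
    for p in hap_posteriors:
        hard = (np.asarray(p) >= 0.5).astype(np.uint32)
        words = pack_allele_vector(hard, grids.G)
        f = insert_target(index, enc, words)
        neigh = scan_neighbours(index, enc, f, L, words)
        sel = select_conditioning_haps(neigh, K, min_len, panel.n_haps, rng)
        per_class.append([int(r) for r in sel])
    chosen: list[int] = []
    for group in itertools.zip_longest(*per_class):
        for r in group:
            if r is not None and r not in chosen:
                chosen.append(r)
        if len(chosen) >= K:
            break
    chosen = chosen[:K]
    if len(chosen) < K:
        pool = np.setdiff1d(np.arange(panel.n_haps), np.array(chosen, dtype=np.int64))
        n_fill = min(K - len(chosen), pool.size)
        chosen.extend(int(r) for r in rng.choice(pool, size=n_fill, replace=False))
    return np.array(chosen, dtype=np.int64)


# ---------------------------------------------------------------------------
# The two-stage imputation driver
# ---------------------------------------------------------------------------

@dataclass
class ImputationResult:
    """Dosages and phased best-guess genotypes from one run."""

    hap_dosage: np.ndarray          # (n_lab, M) per-class alt posteriors
    maternal_dosage: np.ndarray     # (M,) in [0, 2]
    fetal_dosage: np.ndarray | None  # (M,) nipt only
    maternal_haps: np.ndarray       # (2, M) phased best guess
    fetal_haps: np.ndarray | None   # (2, M) nipt only
    mode: str
    ff: float | None = None
    log: dict = field(default_factory=dict)

    @property
    def maternal_gt(self) -> np.ndarray:
        return self.maternal_haps.sum(axis=0)

    @property
    def fetal_gt(self) -> np.ndarray | None:
        return None if self.fetal_haps is None else self.fetal_haps.sum(axis=0)


def _class_posteriors(state: GibbsState, reads: ReadSet,
                      site_mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Per-class haploid alt posteriors at all SNPs from the current labels."""
    out = []
    for c in range(state.n_labels):
        logem = np.zeros((state.grids.G, state.params.K))
        for v in np.flatnonzero(state.labels == c):
            a, b = state.fptr[v], state.fptr[v + 1]
            if a < b:
                np.add.at(logem, state.fgrid[a:b], state.flog[a:b])
        gamma = _kernels.forward_backward(logem, state.params.sigma)
        out.append(haploid_alt_posterior(gamma, state.params.theta,
                                         state.grids.snp_to_grid))
    return out


def _round_ties_het(dosage: np.ndarray) -> np.ndarray:
    """Genotype best guess from a [0,2] dosage; exact .5 ties go to het."""
    g = np.floor(dosage + 0.5)
    ties = np.mod(dosage, 1.0) == 0.5
    g[ties] = 1.0
    return np.clip(g, 0, 2).astype(np.int64)


def impute(reads: ReadSet, panel: HaplotypePanel, grids: GridPanel,
           index: MsPbwtIndex, cfg: NiptConfig, run: RunConfig) -> ImputationResult:
    """Two-stage read-label Gibbs imputation of one sample (or cfDNA mixture).

    Stage 1 iterates {sweeps, block updates, msPBWT conditioning refresh}
    over common SNPs in ``run.n_chains`` independent chains and keeps the
    chain with the highest joint log probability; stage 2 restores all sites,
    initializes labels from the stage-1 haplotype estimates, and averages the
    last ``run.n_sample`` sweeps' posteriors into dosages.
    """
    n_lab = cfg.n_labels
    M = panel.n_sites
    ss = np.random.SeedSequence(run.seed)
    chain_seeds = ss.spawn(run.n_chains + 1)
    prior = label_prior(cfg)

    common, _rare = split_sites(panel, run.maf_threshold)
    common_mask = np.zeros(M, dtype=bool)
    common_mask[common] = True

    V = len(reads)
    if V == 0:
        rng = np.random.default_rng(chain_seeds[-1])
        sub = rng.choice(panel.n_haps, size=min(run.K, panel.n_haps), replace=False)
        params = make_params(panel, grids, sub, n_gen=run.n_gen)
        hap = np.tile(params.theta.mean(axis=1), (n_lab, 1))
        return _finalize(hap, cfg, log={"note": "no reads; prior dosages"})

    K = min(run.K, panel.n_haps)
    best = None
    for chain in range(run.n_chains):
        rng = np.random.default_rng(chain_seeds[chain])
        sub = rng.choice(panel.n_haps, size=K, replace=False)
        params = make_params(panel, grids, sub, n_gen=run.n_gen)
        labels = rng.choice(n_lab, size=V, p=prior)
        state = None
        for outer in range(run.n_outer):
            state = init_state(reads, params, grids, cfg, labels, common_mask)
            for _ in range(run.sweeps):
                gibbs_sweep(state, rng)
                block_gibbs_pairs(state, rng)
            labels = state.labels
            ps = _class_posteriors(state, reads)
            params = make_params(
                panel, grids,
                refresh_conditioning_set(ps, panel, grids, index, K,
                                         run.min_match_grids, rng,
                                         L=run.scan_L),
                n_gen=run.n_gen)
        score = joint_log_prob(state)
        logger.info("chain %d stage-1 joint log-prob %.3f, label counts %s",
                    chain, score, np.bincount(labels, minlength=n_lab).tolist())
        if best is None or score > best[0]:
            best = (score, params, labels.copy(), chain_seeds[chain])
    _score, params, labels, _ = best

    # ---- stage 2: all sites, labels re-initialized from haplotype estimates
    rng2 = np.random.default_rng(chain_seeds[-1])
    state = init_state(reads, params, grids, cfg, labels)  # full observations
    ps = _class_posteriors(state, reads)
    hhat = [(p >= 0.5).astype(np.uint8) for p in ps]
    new_labels = np.empty(V, dtype=np.int64)
    for v, frag in enumerate(reads.fragments):
        e = error_probs(frag.quals)
        lls = np.empty(n_lab)
        for c in range(n_lab):
            match = frag.alleles == hhat[c][frag.sites]
            lls[c] = np.sum(np.log(np.where(match, 1 - e, e))) if frag.n_covered \
                else 0.0
        lls = np.where(prior > 0, lls, NEG_INF)  # zero-prior labels excluded
        if np.all(lls[prior > 0] == lls.max()):
            new_labels[v] = rng2.choice(n_lab, p=prior)  # tie -> prior draw
        else:
            new_labels[v] = int(np.argmax(lls))
    # Anti-sticking: label classes are identified only through the non-
    # uniform prior (and, for the paternal class, its distinct haplotype),
    # and globally permuted labellings are well-separated modes that single-
    # site and block updates cross rarely. Burn in from every global label
    # permutation of the stage-1 labelling and keep the chain with the
    # highest joint log probability (diploid mode is label-symmetric; only
    # the identity is run).
    if cfg.mode == "nipt":
        inits = [np.array(p, dtype=np.int64)[new_labels]
                 for p in itertools.permutations(range(3))]
    else:
        inits = [new_labels]
    cand = []
    init_seeds = chain_seeds[-1].spawn(len(inits))
    for i, lab0 in enumerate(inits):
        rng_c = np.random.default_rng(init_seeds[i])
        st = init_state(reads, params, grids, cfg, lab0)
        for _ in range(run.burn_in):
            gibbs_sweep(st, rng_c)
            block_gibbs_pairs(st, rng_c)
        cand.append((joint_log_prob(st), i, st, rng_c))
    cand.sort(key=lambda x: (-x[0], x[1]))
    _, _, state, rng2 = cand[0]
    acc = np.zeros((n_lab, M))
    for _ in range(run.n_sample):
        gibbs_sweep(state, rng2)
        block_gibbs_pairs(state, rng2)
        for c, p in enumerate(_class_posteriors(state, reads)):
            acc[c] += p
    hap_dosage = acc / run.n_sample
    # Phase comes from the final state, not the sweep average: averaging
    # across label modes would smear the phased best guess. The final state
    # is first polished by a few iterated-conditional-modes passes (greedy
    # label argmax + greedy boundary permutations), which removes residual
    # phase switches the sampler visits but rarely leaves.
    for _ in range(3):
        gibbs_sweep(state, rng2, greedy=True)
        block_gibbs_pairs(state, rng2, greedy=True)
    final_haps = np.stack([(p >= 0.5).astype(np.uint8)
                           for p in _class_posteriors(state, reads)])
    if cfg.mode == "nipt":
        perm = _maternal_orientation(final_haps, reads)
        hap_dosage = hap_dosage[perm]
        final_haps = final_haps[perm]
    return _finalize(hap_dosage, cfg, final_haps=final_haps,
                     log={"stage1_joint_log_prob": _score,
                          "label_counts": np.bincount(state.labels,
                                                      minlength=n_lab).tolist()})


_ORIENT_LOG_PIN = 2.0  # nats a read must prefer one maternal haplotype by


def _maternal_orientation(final_haps: np.ndarray,
                          reads: ReadSet) -> np.ndarray:
    """Index permutation fixing which maternal class is the transmitted one.

    The two maternal classes are distinguished only by read share: the
    transmitted haplotype generates 0.5 of the cfDNA fragments (maternal
    plus fetal-maternal) versus 0.5 - FF/2 for the untransmitted one. Count
    the fragments decisively preferring each maternal haplotype estimate and
    swap the classes if the untransmitted slot won more reads - a maximum a
    posteriori correction that is robust to prior-driven drift of
    uninformative fragments during sampling.
    """
    h0, h1 = final_haps[0], final_haps[1]
    n0 = n1 = 0
    for frag in reads.fragments:
        if frag.n_covered == 0:
            continue
        e = error_probs(frag.quals)
        l0 = float(np.sum(np.log(np.where(frag.alleles == h0[frag.sites], 1 - e, e))))
        l1 = float(np.sum(np.log(np.where(frag.alleles == h1[frag.sites], 1 - e, e))))
        if l0 - l1 > _ORIENT_LOG_PIN:
            n0 += 1
        elif l1 - l0 > _ORIENT_LOG_PIN:
            n1 += 1
    if n1 > n0:
        logger.info("maternal classes swapped post hoc (informative reads %d vs %d)",
                    n0, n1)
        return np.array([1, 0, 2])
    return np.array([0, 1, 2])


def _finalize(hap_dosage: np.ndarray, cfg: NiptConfig, log: dict,
              final_haps: np.ndarray | None = None) -> ImputationResult:
    d = np.clip(hap_dosage, 0.0, 1.0)
    hard = (d >= 0.5).astype(np.uint8) if final_haps is None else final_haps
    if cfg.mode == "nipt":
        maternal = d[0] + d[1]
        fetal = d[0] + d[2]
        return ImputationResult(hap_dosage=d, maternal_dosage=maternal,
                                fetal_dosage=fetal,
                                maternal_haps=hard[[0, 1]],
                                fetal_haps=hard[[0, 2]],
                                mode="nipt", ff=cfg.ff, log=log)
    maternal = d[0] + d[1]
    return ImputationResult(hap_dosage=d, maternal_dosage=maternal,
                            fetal_dosage=None, maternal_haps=hard[[0, 1]],
                            fetal_haps=None, mode="diploid", log=log)


# ---------------------------------------------------------------------------
# Output VCF
# ---------------------------------------------------------------------------

def write_output_vcf(result: ImputationResult, sites: list[SiteRecord],
                     path: str, sample_name: str = "SAMPLE") -> None:
    """Write the imputation result as a VCF.

    Diploid mode emits FORMAT GT (phased best guess) and DS (genotype dosage,
    3 decimals); NIPT mode emits MGT/MDS for the mother and FGT/FDS for the
    fetus. Phase separators are always '|'.
    """
    chrom = sites[0].chrom
    lines = ["##fileformat=VCFv4.2",
             "##source=cfimpute",
             f"##contig=<ID={chrom}>"]
    if result.mode == "nipt":
        lines += [
            '##FORMAT=<ID=MGT,Number=1,Type=String,Description="Maternal phased genotype">',
            '##FORMAT=<ID=MDS,Number=1,Type=Float,Description="Maternal genotype dosage">',
            '##FORMAT=<ID=FGT,Number=1,Type=String,Description="Fetal phased genotype">',
            '##FORMAT=<ID=FDS,Number=1,Type=Float,Description="Fetal genotype dosage">',
        ]
        fmt = "MGT:MDS:FGT:FDS"
    else:
        lines += [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Genotype dosage">',
        ]
        fmt = "GT:DS"
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name)
    mh = result.maternal_haps
    for t, s in enumerate(sites):
        if result.mode == "nipt":
            fh_ = result.fetal_haps
            sample = (f"{mh[0, t]}|{mh[1, t]}:{result.maternal_dosage[t]:.3f}:"
                      f"{fh_[0, t]}|{fh_[1, t]}:{result.fetal_dosage[t]:.3f}")
        else:
            sample = f"{mh[0, t]}|{mh[1, t]}:{result.maternal_dosage[t]:.3f}"
        lines.append(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t"
                     f"AF={s.panel_af:.6g}\t{fmt}\t{sample}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote %d records to %s", len(sites), path)
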