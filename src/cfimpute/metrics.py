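"""Imputation evaluation statistics.

Accuracy of imputed genotypes against truth is summarized per allele-
frequency bin by three concordance measures:

* r2 - squared Pearson correlation between imputed dosage and truth
  genotype (0/1/2), pooling all (site, sample) pairs in the bin;
* NRC - non-reference concordance, 1 - (e0+e1+e2)/(e0+e1+e2+m1+m2), where
  e_g counts mismatches at truth genotype g and m1/m2 count matches at
  heterozygous and homozygous-alternate truth sites;
* F1 = 2TP/(2TP+FP+FN) over non-reference calls: TP = matches at truth 1/2,
  FP = non-reference calls that mismatch, FN = truth 1/2 called otherwise.

Phasing accuracy is the phase switch error (PSE) rate over adjacent truth-
heterozygous site pairs, with flipped sites (two consecutive switches)
excluded. Polygenic scores are weighted dosage sums, and relative
incremental r2 compares the regression-r2 gain of two PRS sources.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# very rare (0.01-0.02%), rare (0.1-0.2%) and common (10-20%) exemplar bins
DEFAULT_MAF_BINS = (0.0, 1e-4, 2e-4, 1e-3, 2e-3, 1e-2, 0.1, 0.2, 0.5)


@dataclass
class ConcordanceCounts:
    e0: int = 0
    e1: int = 0
    e2: int = 0
    m1: int = 0
    m2: int = 0

    @property
    def tp(self) -> int:
        return self.m1 + self.m2

    def nrc(self) -> float:
        denom = self.e0 + self.e1 + self.e2 + self.m1 + self.m2
        return np.nan if denom == 0 else 1.0 - (self.e0 + self.e1 + self.e2) / denom


def concordance_counts(test_gt: np.ndarray, truth_gt: np.ndarray) -> ConcordanceCounts:
    test_gt = np.asarray(test_gt).ravel()
    truth_gt = np.asarray(truth_gt).ravel()
    ok = _valid_mask(test_gt, truth_gt)
    test_gt, truth_gt = test_gt[ok], truth_gt[ok]
    match = test_gt == truth_gt
    return ConcordanceCounts(
        e0=int(np.sum((truth_gt == 0) & ~match)),
        e1=int(np.sum((truth_gt == 1) & ~match)),
        e2=int(np.sum((truth_gt == 2) & ~match)),
        m1=int(np.sum((truth_gt == 1) & match)),
        m2=int(np.sum((truth_gt == 2) & match)),
    )


def _valid_mask(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    va = ~np.isnan(a.astype(np.float64)) & (a >= 0)
    vb = ~np.isnan(b.astype(np.float64)) & (b >= 0)
    return va & vb


def nonref_concordance(test_gt: np.ndarray, truth_gt: np.ndarray) -> float:
    """NRC = 1 - (e0+e1+e2)/(e0+e1+e2+m1+m2); NaN when the denominator is 0."""
    return concordance_counts(test_gt, truth_gt).nrc()


def f1_score(test_gt: np.ndarray, truth_gt: np.ndarray) -> float:
    """F1 = 2TP/(2TP+FP+FN) over non-reference genotype calls."""
    test_gt = np.asarray(test_gt).ravel()
    truth_gt = np.asarray(truth_gt).ravel()
    ok = _valid_mask(test_gt, truth_gt)
    test_gt, truth_gt = test_gt[ok], truth_gt[ok]
    match = test_gt == truth_gt
    tp = int(np.sum(np.isin(truth_gt, (1, 2)) & match))
    fp = int(np.sum(np.isin(test_gt, (1, 2)) & ~match))
    fn = int(np.sum(np.isin(truth_gt, (1, 2)) & ~match))
    denom = 2 * tp + fp + fn
    return np.nan if denom == 0 else 2.0 * tp / denom


def pearson_r2(test: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation; NaN if either side has zero variance."""
    test = np.asarray(test, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    ok = ~np.isnan(test) & ~np.isnan(truth) & (truth >= 0)
    test, truth = test[ok], truth[ok]
    if test.size < 2 or np.std(test) == 0 or np.std(truth) == 0:
        return np.nan
    r = np.corrcoef(test, truth)[0, 1]
    return float(r * r)


def genotype_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """Best-guess 0/1/2 from a [0,2] dosage; exact .5 ties go to het."""
    dosage = np.asarray(dosage, dtype=np.float64)
    g = np.floor(dosage + 0.5)
    g[np.mod(dosage, 1.0) == 0.5] = 1.0
    return np.clip(g, 0, 2).astype(np.int64)


def dosage_r2_by_bin(test_dosages: np.ndarray, truth_gt: np.ndarray,
                     af: np.ndarray,
                     bin_edges=DEFAULT_MAF_BINS) -> pd.DataFrame:
    """Accuracy table per folded-MAF bin.

    ``test_dosages`` / ``truth_gt`` may be 1-D (one sample) or 2-D
    (samples x sites); ``af`` is per-site alternate allele frequency. Within
    each bin all (site, sample) pairs are pooled for one r2, and NRC/F1 are
    computed on the rounded best-guess genotypes. Missing truth (NaN or
    negative) is dropped; bins with zero truth variance report r2 as NaN.
    """
    test = np.atleast_2d(np.asarray(test_dosages, dtype=np.float64))
    truth = np.atleast_2d(np.asarray(truth_gt, dtype=np.float64))
    if test.shape != truth.shape:
        raise ValueError("test/truth shape mismatch")
    af = np.asarray(af, dtype=np.float64)
    if af.size != test.shape[1]:
        raise ValueError("af length must match number of sites")
    maf = np.minimum(af, 1.0 - af)
    edges = np.asarray(bin_edges, dtype=np.float64)
    which = np.digitize(maf, edges[1:-1], right=False)
    rows = []
    for b in range(edges.size - 1):
        sel = which == b
        if not sel.any():
            continue
        t, tr = test[:, sel], truth[:, sel]
        gt = genotype_from_dosage(t)
        rows.append({
            "maf_lo": edges[b], "maf_hi": edges[b + 1],
            "n_sites": int(sel.sum()),
            "n_pairs": int(np.sum(~np.isnan(tr) & (tr >= 0))),
            "r2": pearson_r2(t, tr),
            "nrc": nonref_concordance(gt, tr),
            "f1": f1_score(gt, tr),
        })
    return pd.DataFrame(rows)


def per_sample_concordance(test_gt: np.ndarray, truth_gt: np.ndarray
                           ) -> pd.DataFrame:
    """NRC/F1 aggregated per sample (rows of samples x sites matrices)."""
    test = np.atleast_2d(test_gt)
    truth = np.atleast_2d(truth_gt)
    rows = [{"sample": i,
             "nrc": nonref_concordance(test[i], truth[i]),
             "f1": f1_score(test[i], truth[i])}
            for i in range(test.shape[0])]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Phasing
# ---------------------------------------------------------------------------

def phase_switch_error(test_haps: np.ndarray, truth_haps: np.ndarray
                       ) -> tuple[float, int, int, int]:
    """PSE rate between phased test and truth haplotypes over shared sites.

    Restricted to truth-heterozygous sites; test sites not heterozygous
    there are discordant and excluded. A switch is a disagreement in
    phase change between adjacent retained het sites; sites yielding two
    consecutive switches are flips and are removed before the final count.
    Returns (pse_rate, n_pairs_examined, n_discordant, n_flips); the rate is
    NaN with fewer than two usable het sites.
    """
    test = np.asarray(test_haps)
    truth = np.asarray(truth_haps)
    if test.shape != truth.shape or test.ndim != 2 or test.shape[0] != 2:
        raise ValueError("haplotypes must both be (2, n_sites)")
    het = truth[0] != truth[1]
    t_het = test[0] != test[1]
    usable = het & t_het
    n_disc = int(np.sum(het & ~t_het))
    idx = np.flatnonzero(usable)
    if idx.size < 2:
        return np.nan, 0, n_disc, 0

    def switches(sites: np.ndarray) -> np.ndarray:
        # phase at a het site: which haplotype carries the alt allele
        tr = truth[0][sites]
        te = test[0][sites]
        return (np.diff(tr) != 0) != (np.diff(te) != 0)

    sw = switches(idx)
    flip_sites = np.flatnonzero(sw[:-1] & sw[1:]) + 1  # interior site of a pair
    n_flips = int(flip_sites.size)
    if n_flips:
        keep = np.ones(idx.size, dtype=bool)
        keep[flip_sites] = False
        idx = idx[keep]
        if idx.size < 2:
            return np.nan, 0, n_disc, n_flips
        sw = switches(idx)
    n_pairs = int(sw.size)
    return float(sw.sum() / n_pairs), n_pairs, n_disc, n_flips


# ---------------------------------------------------------------------------
# Polygenic scores
# ---------------------------------------------------------------------------

@dataclass
class PrsInputs:
    """Aligned effect sizes and dosages (plus covariates for incremental r2)."""

    weights: np.ndarray     # (n_snps,)
    dosages: np.ndarray     # (n_individuals, n_snps), values in [0, 2]

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.dosages = np.atleast_2d(np.asarray(self.dosages, dtype=np.float64))
        if self.dosages.shape[1] != self.weights.size:
            raise ValueError("weights/dosages SNP dimension mismatch")


def align_prs_inputs(weight_table: pd.DataFrame, dosage_table: pd.DataFrame
                     ) -> PrsInputs:
    """Match weight and dosage SNPs on (chrom, pos, ref, alt); unmatched SNPs
    are skipped with a logged match rate."""
    key = ["chrom", "pos", "ref", "alt"]
    merged = weight_table.merge(dosage_table, on=key, how="inner")
    n_w = len(weight_table)
    logger.info("PRS SNP match: %d/%d (%.1f%%)", len(merged), n_w,
                100.0 * len(merged) / max(n_w, 1))
    dos_cols = [c for c in dosage_table.columns if c not in key]
    return PrsInputs(weights=merged["beta"].to_numpy(),
                     dosages=merged[dos_cols].to_numpy().T)


def prs_score(inputs: PrsInputs) -> np.ndarray:
    """PRS_i = sum_j beta_j * G_ij."""
    return inputs.dosages @ inputs.weights


def incremental_r2(prs: np.ndarray, phenotype: np.ndarray,
                   covariates: np.ndarray | None = None) -> float:
    """r2(pheno ~ covariates + PRS) - r2(pheno ~ covariates), via OLS."""
    import statsmodels.api as sm

    prs = np.asarray(prs, dtype=np.float64)
    y = np.asarray(phenotype, dtype=np.float64)
    if covariates is None:
        covariates = np.empty((y.size, 0))
    X0 = sm.add_constant(np.asarray(covariates, dtype=np.float64), has_constant="add")
    X1 = np.column_stack([X0, prs])
    r2_0 = sm.OLS(y, X0).fit().rsquared if X0.shape[1] > 1 else 0.0
    r2_1 = sm.OLS(y, X1).fit().rsquared
    return float(r2_1 - r2_0)


def relative_incremental_r2(prs_test: np.ndarray, prs_ref: np.ndarray,
                            phenotype: np.ndarray,
                            covariates: np.ndarray | None = None) -> float:
    """Ratio of the incremental r2 of the test PRS to the reference PRS.

    NaN (with a warning) when the reference incremental r2 is <= 0.
    """
    ir2_test = incremental_r2(prs_test, phenotype, covariates)
    ir2_ref = incremental_r2(prs_ref, phenotype, covariates)
    if ir2_ref <= 0:
        logger.warning("reference incremental r2 <= 0 (%.3g); RIR2 undefined", ir2_ref)
        return np.nan
    return ir2_test / ir2_ref
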