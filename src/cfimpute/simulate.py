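"""Synthetic data: mosaic haplotype panels, family trios, and mixed cfDNA
read sets with known truth labels.

The panel is a mosaic-of-founders model: founder haplotypes are drawn with a
Beta(0.2, 0.2) allele-frequency spectrum (both rare and common sites), and
the remaining haplotypes copy founders with a small per-interval switch
probability plus per-site flip noise, producing realistic linkage. A family
is drawn as fresh mosaics of the panel (related to, but not identical to,
panel rows; an exact-rows mode exists for oracle tests), and the child
inherits the mother's first and the father's first haplotype verbatim - no
intra-region recombination, matching the three-fixed-haplotypes assumption
of the NIPT model.

cfDNA reads are contiguous-site fragments whose source haplotype is drawn
from the label prior (0.5, 0.5 - FF/2, FF/2) over (maternal transmitted,
maternal untransmitted, paternal transmitted); diploid reads use (0.5, 0.5)
over the target's two haplotypes.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np

from .panel_io import HaplotypePanel, SiteRecord
from .read_model import ReadFragment, ReadSet, write_readset, BASEQ_CAP

logger = logging.getLogger(__name__)

SITE_SPACING_BP = 100  # synthetic SNP spacing
CM_PER_MB = 1.0


@dataclass
class SimPanelConfig:
    n_founders: int = 40
    n_haps: int = 200
    n_snps: int = 1000
    recomb_per_snp: float = 1e-3   # founder copy-switch probability per interval
    mut_rate: float = 2e-4         # per-site flip probability in mosaics
    maf_min: float = 0.002         # realized folded MAF floor
    seed: int = 0

    def __post_init__(self):
        if not 2 <= self.n_founders <= self.n_haps:
            raise ValueError("need n_haps >= n_founders >= 2")
        for p in (self.recomb_per_snp, self.mut_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")


@dataclass
class FamilyHaplotypes:
    """Mother (h1, h2), father (h3, h4); the child carries copies of h1, h3."""

    mother: np.ndarray  # (2, M)
    father: np.ndarray  # (2, M)

    @property
    def child(self) -> np.ndarray:
        return np.stack([self.mother[0], self.father[0]])

    @property
    def mother_gt(self) -> np.ndarray:
        return self.mother.sum(axis=0)

    @property
    def child_gt(self) -> np.ndarray:
        return self.child.sum(axis=0)


@dataclass
class SimReadConfig:
    coverage: float = 1.0
    read_len: int = 4              # mean fragment length, in covered SNPs
    err: float = 0.001             # per-base error probability
    ff: float = 0.1                # fetal fraction (nipt mode)
    seed: int = 0

    def __post_init__(self):
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.err < 0.5:
            raise ValueError("err must be in [0, 0.5)")
        if not 0.0 <= self.ff <= 1.0:
            raise ValueError("ff must be in [0, 1]")


def _mosaic(founders: np.ndarray, n_out: int, recomb: float, mut: float,
            rng: np.random.Generator) -> np.ndarray:
    """Haplotypes copying a founder with switch prob per interval + flips."""
    n_f, m = founders.shape
    out = np.empty((n_out, m), dtype=np.uint8)
    for i in range(n_out):
        cur = rng.integers(n_f)
        switch = rng.random(m) < recomb
        idx = np.empty(m, dtype=np.int64)
        for t in range(m):
            if t > 0 and switch[t]:
                cur = rng.integers(n_f)
            idx[t] = cur
        hap = founders[idx, np.arange(m)].copy()
        flips = rng.random(m) < mut
        hap[flips] ^= 1
        out[i] = hap
    return out


def simulate_panel(cfg: SimPanelConfig) -> HaplotypePanel:
    """Mosaic-of-founders reference panel with a Beta(0.2, 0.2) AF spectrum.

    After the mosaic step, any column whose realized folded MAF falls below
    ``maf_min`` has alleles of seeded-random rows flipped up to the floor, so
    the constraint holds in the emitted panel.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    af = rng.beta(0.2, 0.2, size=m)
    af = np.clip(af, cfg.maf_min, 1 - cfg.maf_min)
    founders = (rng.random((cfg.n_founders, m)) < af).astype(np.uint8)
    n_extra = cfg.n_haps - cfg.n_founders
    if n_extra > 0:
        extra = _mosaic(founders, n_extra, cfg.recomb_per_snp, cfg.mut_rate, rng)
        alleles = np.vstack([founders, extra])
    else:
        alleles = founders
    # enforce the realized MAF floor (no-op when maf_min == 0)
    n = cfg.n_haps
    min_count = int(np.ceil(cfg.maf_min * n)) if cfg.maf_min > 0 else 0
    for t in range(m if min_count else 0):
        col = alleles[:, t]
        ones = int(col.sum())
        if ones < min_count:
            flip = rng.choice(np.flatnonzero(col == 0), size=min_count - ones,
                              replace=False)
            col[flip] = 1
        elif n - ones < min_count:
            flip = rng.choice(np.flatnonzero(col == 1),
                              size=min_count - (n - ones), replace=False)
            col[flip] = 0
    if cfg.n_haps % 2:
        raise ValueError("n_haps must be even (two haplotypes per donor)")
    sites = [SiteRecord("chr1", SITE_SPACING_BP * (t + 1), "A", "C",
                        float(alleles[:, t].mean())) for t in range(m)]
    names = [f"donor{i:04d}" for i in range(cfg.n_haps // 2)]
    return HaplotypePanel(alleles, sites, names)


def simulate_family(panel: HaplotypePanel, seed: int = 0,
                    exact_rows: bool = False,
                    recomb_per_snp: float = 1e-3,
                    mut_rate: float = 2e-4) -> FamilyHaplotypes:
    """Mother/father haplotypes related to the panel; child = (h1, h3).

    ``exact_rows=True`` draws the four parental haplotypes as distinct panel
    rows verbatim (for exact-recovery oracles); otherwise they are fresh
    mosaics of the panel.
    """
    if panel.n_haps < 4:
        raise ValueError("panel must have >= 4 haplotypes")
    rng = np.random.default_rng(seed)
    if exact_rows:
        rows = rng.choice(panel.n_haps, size=4, replace=False)
        haps = panel.alleles[rows].copy()
    else:
        haps = _mosaic(panel.alleles, 4, recomb_per_snp, mut_rate, rng)
    return FamilyHaplotypes(mother=haps[:2], father=haps[2:])


def simulate_reads(family: FamilyHaplotypes, mode: str, cfg: SimReadConfig,
                   sites: list[SiteRecord] | int) -> ReadSet:
    """Fragments with truth labels, mixed per the label prior.

    The number of fragments is set so the expected per-site depth equals
    ``cfg.coverage``. Fragment sources in nipt mode are (h1, h2, child
    paternal) with probabilities (0.5, 0.5 - FF/2, FF/2); diploid mode mixes
    the mother's two haplotypes equally. Bases are copied from the source
    haplotype and flipped independently with probability ``err``; base
    qualities are set to -10 log10(err), capped at Q40.
    """
    if mode not in ("diploid", "nipt"):
        raise ValueError(f"unknown mode {mode!r}")
    m = sites if isinstance(sites, int) else len(sites)
    rng = np.random.default_rng(cfg.seed)
    if mode == "nipt":
        sources = np.stack([family.mother[0], family.mother[1], family.child[1]])
        probs = np.array([0.5, 0.5 - cfg.ff / 2.0, cfg.ff / 2.0])
    else:
        sources = family.mother
        probs = np.array([0.5, 0.5])
    mean_len = max(1, cfg.read_len)
    n_frags = int(round(cfg.coverage * m / mean_len))
    if n_frags == 0:
        return ReadSet([])
    labels = rng.choice(len(probs), size=n_frags, p=probs)
    starts = rng.integers(0, m, size=n_frags)
    lens = np.maximum(1, rng.poisson(mean_len, size=n_frags))
    qual = min(BASEQ_CAP, -10.0 * np.log10(cfg.err)) if cfg.err > 0 else BASEQ_CAP
    frags = []
    for i in range(n_frags):
        lo = int(starts[i])
        hi = min(m, lo + int(lens[i]))
        sl = np.arange(lo, hi)
        alleles = sources[labels[i], sl].copy()
        if cfg.err > 0:
            flips = rng.random(sl.size) < cfg.err
            alleles = alleles ^ flips.astype(np.uint8)
        frags.append(ReadFragment(id=f"frag{i:07d}", sites=sl, alleles=alleles,
                                  quals=np.full(sl.size, qual),
                                  source_label=int(labels[i]) + 1))
    return ReadSet(frags)


# ---------------------------------------------------------------------------
# End-to-end dataset emission
# ---------------------------------------------------------------------------

def _write_vcf(path: str, sites: list[SiteRecord], sample_gts: dict[str, np.ndarray]
               ) -> None:
    """Phased VCF from (2, M) haplotype arrays, one column per sample."""
    chrom = sites[0].chrom
    names = list(sample_gts)
    lines = ["##fileformat=VCFv4.2",
             "##source=cfimpute-simulate",
             f"##contig=<ID={chrom}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Phased genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(names)]
    for t, s in enumerate(sites):
        cols = "\t".join(f"{sample_gts[n][0, t]}|{sample_gts[n][1, t]}" for n in names)
        lines.append(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\tPASS\t.\tGT\t{cols}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    gts = {name: panel.alleles[2 * i:2 * i + 2]
           for i, name in enumerate(panel.sample_names)}
    _write_vcf(path, panel.sites, gts)


def write_genetic_map(sites: list[SiteRecord], path: str,
                      cm_per_mb: float = CM_PER_MB) -> None:
    with open(path, "w") as fh:
        fh.write("pos\tcm\n")
        p0 = sites[0].pos
        for s in sites:
            fh.write(f"{s.pos}\t{(s.pos - p0) * cm_per_mb / 1e6:.8f}\n")


def simulate_nipt_dataset(panel_cfg: SimPanelConfig, read_cfg: SimReadConfig,
                          out_dir: str, mode: str = "nipt",
                          family_seed: int | None = None,
                          exact_rows: bool = False) -> dict:
    """Emit a complete synthetic dataset: panel VCF, truth VCF (mother and
    child, phased), genetic map, ReadSet table and a JSON manifest.

    Returns the manifest dict; re-running with the same manifest parameters
    reproduces every file byte-identically.
    """
    os.makedirs(out_dir, exist_ok=True)
    panel = simulate_panel(panel_cfg)
    fam_seed = panel_cfg.seed + 1 if family_seed is None else family_seed
    family = simulate_family(panel, seed=fam_seed, exact_rows=exact_rows)
    reads = simulate_reads(family, mode, read_cfg, panel.sites)

    paths = {k: os.path.join(out_dir, v) for k, v in
             [("panel_vcf", "panel.vcf"), ("truth_vcf", "truth.vcf"),
              ("genetic_map", "map.txt"), ("readset", "reads.tsv"),
              ("manifest", "manifest.json")]}
    write_panel_vcf(panel, paths["panel_vcf"])
    _write_vcf(paths["truth_vcf"], panel.sites,
               {"MOTHER": family.mother, "CHILD": family.child})
    write_genetic_map(panel.sites, paths["genetic_map"])
    write_readset(reads, paths["readset"])
    manifest = {
        "mode": mode,
        "panel_config": asdict(panel_cfg),
        "read_config": asdict(read_cfg),
        "family_seed": fam_seed,
        "exact_rows": exact_rows,
        "n_fragments": len(reads),
        "files": {k: os.path.basename(v) for k, v in paths.items() if k != "manifest"},
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("wrote synthetic %s dataset to %s (%d fragments)",
                mode, out_dir, len(reads))
    return manifest
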