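"""Reference panel representation: phased VCF loading, genetic maps, and the
32-SNP grid encoding.

The imputation model treats a block of 32 consecutive SNPs as one HMM
position (a *grid*); each haplotype's alleles within a grid are packed into a
single 32-bit word (bit ``j`` of grid ``g`` is the allele at SNP ``32*g+j``).
Recombination is only allowed between grids, with inter-grid genetic
distances taken from a genetic map.

All coordinates are 1-based inclusive (VCF convention).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

GRID_SIZE = 32


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteRecord:
    """One biallelic SNP of the panel."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    panel_af: float

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.panel_af <= 1.0:
            raise ValueError(f"panel_af out of [0,1] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class HaplotypePanel:
    """N_haps x M_sites binary matrix of phased reference haplotypes.

    Row ``2*s`` and ``2*s+1`` are the two haplotypes of donor ``s``.
    """

    alleles: np.ndarray  # (N, M) uint8 in {0,1}
    sites: list[SiteRecord]
    sample_names: list[str]

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        n, m = self.alleles.shape
        if m != len(self.sites):
            raise ValueError("alleles/sites shape mismatch")
        if n != 2 * len(self.sample_names):
            raise ValueError("N_haps must equal 2 x donors")
        pos = self.positions
        if m > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("site positions must be strictly increasing")

    @property
    def n_haps(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    @property
    def panel_af(self) -> np.ndarray:
        return np.array([s.panel_af for s in self.sites], dtype=np.float64)

    @property
    def chrom(self) -> str:
        return self.sites[0].chrom


@dataclass
class GeneticMap:
    """Cumulative genetic map: bp position -> centimorgans.

    ``cm`` is non-decreasing; interpolation is linear inside the mapped span
    and flat (constant) outside it.
    """

    positions: np.ndarray  # 1-based bp, increasing
    cm: np.ndarray  # cumulative cM, non-decreasing

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions.size != self.cm.size or self.positions.size < 1:
            raise ValueError("map positions/cm length mismatch or empty")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("map cm must be non-decreasing")

    def interpolate(self, bp: np.ndarray, warn: bool = True) -> np.ndarray:
        """cM at arbitrary bp; flat extrapolation beyond the mapped span."""
        bp = np.asarray(bp, dtype=np.float64)
        if warn and (bp.min() < self.positions[0] or bp.max() > self.positions[-1]):
            logger.warning(
                "genetic map does not cover panel span [%d, %d]; extrapolating flat",
                int(bp.min()), int(bp.max()),
            )
        return np.interp(bp, self.positions, self.cm)

    @classmethod
    def uniform(cls, start_bp: int, end_bp: int, cm_per_mb: float = 1.0) -> "GeneticMap":
        """Constant-rate map over [start_bp, end_bp]."""
        pos = np.array([start_bp, end_bp], dtype=np.float64)
        return cls(pos, (pos - pos[0]) * cm_per_mb / 1e6)


@dataclass
class GridPanel:
    """Panel packed into 32-bit words, one word per haplotype per grid."""

    words: np.ndarray  # (N, G) uint32
    G: int
    snp_to_grid: np.ndarray  # (M,) int32
    grid_cm: np.ndarray  # (G-1,) inter-grid genetic distances, cM
    n_sites: int
    grid_n_snps: np.ndarray = field(default=None)  # (G,) real SNPs per grid

    def __post_init__(self):
        if self.grid_n_snps is None:
            counts = np.full(self.G, GRID_SIZE, dtype=np.int32)
            counts[-1] = self.n_sites - GRID_SIZE * (self.G - 1)
            self.grid_n_snps = counts

    def decode(self) -> np.ndarray:
        """Unpack words back to the (N, M) allele matrix (drops pad bits)."""
        n = self.words.shape[0]
        bits = np.zeros((n, self.G * GRID_SIZE), dtype=np.uint8)
        for j in range(GRID_SIZE):
            bits[:, j::GRID_SIZE] = ((self.words >> np.uint32(j)) & np.uint32(1)).astype(np.uint8)
        return bits[:, : self.n_sites]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def pack_allele_vector(alleles: np.ndarray, g_count: int) -> np.ndarray:
    """Pack one haplotype's 0/1 alleles into per-grid 32-bit words (pad 0)."""
    alleles = np.asarray(alleles, dtype=np.uint32)
    padded = np.zeros(g_count * GRID_SIZE, dtype=np.uint32)
    padded[: alleles.size] = alleles
    words = np.zeros(g_count, dtype=np.uint32)
    for j in range(GRID_SIZE):
        words |= padded[j::GRID_SIZE] << np.uint32(j)
    return words


_REGION_RE = re.compile(r"^([^:]+)(?::(\d+)-(\d+))?$")


def parse_region(region: str) -> tuple[str, int | None, int | None]:
    m = _REGION_RE.match(region)
    if not m:
        raise ValueError(f"malformed region string: {region!r}")
    chrom, start, end = m.groups()
    return chrom, (int(start) if start else None), (int(end) if end else None)


def load_panel_vcf(path: str, region: str | None = None) -> HaplotypePanel:
    """Load a phased biallelic-SNP reference panel from a VCF.

    Every sample must carry a phased GT at every retained record; an unphased
    or missing genotype is a hard error naming the offending record.
    Multiallelic and non-SNP records are skipped (counted in the log).
    """
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in {path}")
    want_chrom = want_start = want_end = None
    if region is not None:
        want_chrom, want_start, want_end = parse_region(region)

    rows: list[np.ndarray] = []
    sites: list[SiteRecord] = []
    n_skipped = 0
    for v in vcf:
        if want_chrom is not None:
            if v.CHROM != want_chrom:
                continue
            if want_start is not None and not (want_start <= v.POS <= want_end):
                continue
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        hap = np.empty(2 * len(samples), dtype=np.uint8)
        for s, g in enumerate(v.genotypes):
            # cyvcf2 genotype: [allele0, allele1, phased]
            if len(g) < 3 or g[0] < 0 or g[1] < 0:
                raise ValueError(f"missing GT at {v.CHROM}:{v.POS} sample {samples[s]}")
            if not g[2]:
                raise ValueError(f"unphased GT at {v.CHROM}:{v.POS} sample {samples[s]}")
            hap[2 * s] = g[0]
            hap[2 * s + 1] = g[1]
        rows.append(hap)
        sites.append(SiteRecord(v.CHROM, v.POS, v.REF, v.ALT[0], float(hap.mean())))
    if n_skipped:
        logger.info("skipped %d multiallelic/non-SNP records in %s", n_skipped, path)
    if not sites:
        raise ValueError(f"no usable biallelic SNP records in {path}"
                         + (f" for region {region}" if region else ""))
    alleles = np.stack(rows, axis=1)
    logger.info("loaded panel: %d haplotypes x %d sites from %s",
                alleles.shape[0], alleles.shape[1], path)
    return HaplotypePanel(alleles, sites, samples)


def load_genetic_map(path: str) -> GeneticMap:
    """Plain-text genetic map with header ``pos cm`` (tab/space delimited)."""
    import pandas as pd

    df = pd.read_csv(path, sep=r"\s+")
    cols = [c.lower() for c in df.columns]
    if "pos" not in cols or "cm" not in cols:
        raise ValueError(f"genetic map {path} must have 'pos' and 'cm' columns")
    df.columns = cols
    logger.info("loaded genetic map: %d entries from %s", len(df), path)
    return GeneticMap(df["pos"].to_numpy(), df["cm"].to_numpy())


def split_sites(panel: HaplotypePanel, maf_threshold: float = 0.01
                ) -> tuple[np.ndarray, np.ndarray]:
    """Partition site indices into common (folded MAF >= threshold) and rare."""
    if not 0.0 <= maf_threshold <= 0.5:
        raise ValueError("maf_threshold must be in [0, 0.5]")
    af = panel.panel_af
    maf = np.minimum(af, 1.0 - af)
    common = np.flatnonzero(maf >= maf_threshold)
    rare = np.flatnonzero(maf < maf_threshold)
    if common.size == 0:
        raise ValueError("no common sites at this MAF threshold; model cannot initialize")
    return common, rare


def encode_grids(panel: HaplotypePanel, gmap: GeneticMap | None = None) -> GridPanel:
    """Pack the panel into 32-SNP grids.

    Word bits are little-endian in SNP order within the grid; pad bits of the
    last grid are 0 (reference) and are masked out of every downstream
    likelihood by construction (no observation is ever assigned to them).
    ``grid_cm[g]`` is the genetic distance between the median-bp SNP of grid
    ``g+1`` and that of grid ``g``.
    """
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    n, m = panel.alleles.shape
    g_count = -(-m // GRID_SIZE)
    padded = np.zeros((n, g_count * GRID_SIZE), dtype=np.uint32)
    padded[:, :m] = panel.alleles
    words = np.zeros((n, g_count), dtype=np.uint32)
    for j in range(GRID_SIZE):
        words |= padded[:, j::GRID_SIZE] << np.uint32(j)
    snp_to_grid = (np.arange(m) // GRID_SIZE).astype(np.int32)

    pos = panel.positions
    rep_bp = np.array([np.median(pos[snp_to_grid == g]) for g in range(g_count)])
    if gmap is None:
        gmap = GeneticMap.uniform(int(pos[0]), max(int(pos[-1]), int(pos[0]) + 1))
    cm = gmap.interpolate(rep_bp)
    grid_cm = np.maximum(np.diff(cm), 0.0)
    return GridPanel(words=np.ascontiguousarray(words), G=g_count,
                     snp_to_grid=snp_to_grid, grid_cm=grid_cm, n_sites=m)
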