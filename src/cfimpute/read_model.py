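"""Sequencing fragments as the observation unit.

A *fragment* is one sequenced molecule: a single read, or both mates of a
pair merged (mates share one haplotype-of-origin label). Each fragment is
reduced to the panel sites it covers, the observed allele (0 = ref, 1 = alt)
and the base quality at each. Bases matching neither allele, low-quality
bases, and indels are discarded at extraction, so downstream emission is a
simple biallelic match/mismatch model:

    P(obs | hap allele) = 1 - e on match, e on mismatch,
    e = max(10^(-q/10), seq_error_floor), q capped at Q40.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel_io import SiteRecord

logger = logging.getLogger(__name__)

BASEQ_CAP = 40
SEQ_ERROR_FLOOR = 1e-4


@dataclass
class ReadFragment:
    """One sequenced molecule reduced to covered panel sites."""

    id: str
    sites: np.ndarray      # (n,) int64 site indices, strictly increasing
    alleles: np.ndarray    # (n,) uint8 in {0,1}
    quals: np.ndarray      # (n,) float64 Phred
    source_label: int | None = None  # truth label, simulator only

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype=np.int64)
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        self.quals = np.asarray(self.quals, dtype=np.float64)
        if not (self.sites.size == self.alleles.size == self.quals.size):
            raise ValueError(f"fragment {self.id}: ragged arrays")
        if self.sites.size > 1 and not np.all(np.diff(self.sites) > 0):
            raise ValueError(f"fragment {self.id}: site indices must be strictly increasing")

    @property
    def n_covered(self) -> int:
        return int(self.sites.size)


@dataclass
class ReadSet:
    """All fragments of one sample, with a site -> fragments reverse map."""

    fragments: list[ReadFragment]
    site_index: dict[int, list[int]] = field(default=None, repr=False)

    def __post_init__(self):
        if self.site_index is None:
            idx: dict[int, list[int]] = {}
            for i, frag in enumerate(self.fragments):
                for t in frag.sites:
                    idx.setdefault(int(t), []).append(i)
            self.site_index = idx

    def __len__(self) -> int:
        return len(self.fragments)

    def subset_to_sites(self, keep: np.ndarray) -> "ReadSet":
        """Restrict observations to a site subset (fragments left with zero
        observations are dropped)."""
        keep = np.asarray(keep)
        frags = []
        for frag in self.fragments:
            mask = np.isin(frag.sites, keep)
            if mask.any():
                frags.append(ReadFragment(frag.id, frag.sites[mask],
                                          frag.alleles[mask], frag.quals[mask],
                                          frag.source_label))
        return ReadSet(frags)


# ---------------------------------------------------------------------------
# Extraction from alignments
# ---------------------------------------------------------------------------

def extract_reads(path: str, sites: list[SiteRecord], min_mapq: int = 10,
                  min_baseq: int = 10) -> ReadSet:
    """Extract per-fragment observations from a coordinate-sorted SAM/BAM.

    Mates of a pair are merged into one fragment; where mates overlap the
    same site with conflicting bases the higher-quality base wins and a tie
    drops the site. Secondary, supplementary and duplicate records and
    alignments below ``min_mapq`` are excluded. Bases matching neither
    ref nor alt, or with quality below ``min_baseq``, are skipped.
    """
    import pysam

    chroms = {s.chrom for s in sites}
    if len(chroms) != 1:
        raise ValueError("sites must be on a single chromosome")
    chrom = next(iter(chroms))
    pos_to_idx = {s.pos: i for i, s in enumerate(sites)}
    ref_alt = {s.pos: (s.ref.upper(), s.alt.upper()) for s in sites}

    mode = "rb" if path.endswith(".bam") else "r"
    af = pysam.AlignmentFile(path, mode)
    so = (af.header.to_dict().get("HD") or {}).get("SO")
    if so != "coordinate":
        raise ValueError(f"{path}: alignments must be coordinate-sorted (SO={so})")

    # qname -> {site_pos: (allele, qual)}
    frag_obs: dict[str, dict[int, tuple[int, float]]] = {}  # insertion-ordered
    last_pos = -1
    n_records = 0
    for aln in af.fetch(until_eof=True):
        if aln.is_unmapped or aln.is_secondary or aln.is_supplementary or aln.is_duplicate:
            continue
        if aln.reference_name != chrom:
            raise ValueError(f"{path}: alignment on {aln.reference_name}, "
                             f"sites on {chrom}")
        if aln.reference_start < last_pos:
            raise ValueError(f"{path}: alignments not coordinate-sorted")
        last_pos = aln.reference_start
        if aln.mapping_quality < min_mapq:
            continue
        n_records += 1
        seq = aln.query_sequence
        quals = aln.query_qualities
        if seq is None:
            continue
        obs = frag_obs.setdefault(aln.query_name, {})
        for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
            pos1 = rpos + 1  # pysam is 0-based
            if pos1 not in pos_to_idx:
                continue
            q = float(quals[qpos]) if quals is not None else BASEQ_CAP
            if q < min_baseq:
                continue
            base = seq[qpos].upper()
            ref, alt = ref_alt[pos1]
            if base == ref:
                allele = 0
            elif base == alt:
                allele = 1
            else:
                continue
            if pos1 in obs:
                prev_allele, prev_q = obs[pos1]
                if prev_allele != allele:
                    # overlapping-mate conflict: higher quality wins, tie drops
                    if q > prev_q:
                        obs[pos1] = (allele, q)
                    elif q == prev_q:
                        obs[pos1] = (None, q)
                else:
                    obs[pos1] = (allele, max(prev_q, q))
            else:
                obs[pos1] = (allele, q)
    af.close()

    fragments = []
    for name in frag_obs:
        obs = {p: v for p, v in frag_obs[name].items() if v[0] is not None}
        if not obs:
            continue
        pos_sorted = sorted(obs)
        fragments.append(ReadFragment(
            id=name,
            sites=np.array([pos_to_idx[p] for p in pos_sorted], dtype=np.int64),
            alleles=np.array([obs[p][0] for p in pos_sorted], dtype=np.uint8),
            quals=np.minimum([obs[p][1] for p in pos_sorted], BASEQ_CAP),
        ))
    logger.info("extracted %d fragments (from %d alignment records) covering >=1 of %d sites",
                len(fragments), n_records, len(sites))
    return ReadSet(fragments)


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def error_probs(quals: np.ndarray, seq_error_floor: float = SEQ_ERROR_FLOOR) -> np.ndarray:
    """Per-base error probability from Phred quality, floored and Q40-capped."""
    q = np.minimum(np.asarray(quals, dtype=np.float64), BASEQ_CAP)
    return np.maximum(np.power(10.0, -q / 10.0), seq_error_floor)


def fragment_emission(frag: ReadFragment, hap_alleles: np.ndarray,
                      seq_error_floor: float = SEQ_ERROR_FLOOR) -> float:
    """P(fragment observations | haplotype alleles at its covered sites).

    Product over covered sites of (1-e) on match, e on mismatch; the empty
    product is 1.
    """
    hap_alleles = np.asarray(hap_alleles)
    if hap_alleles.size != frag.n_covered:
        raise ValueError(f"fragment {frag.id}: haplotype alleles length mismatch")
    if frag.n_covered == 0:
        return 1.0
    e = error_probs(frag.quals, seq_error_floor)
    match = frag.alleles == hap_alleles
    return float(np.prod(np.where(match, 1.0 - e, e)))


# ---------------------------------------------------------------------------
# Tabular text serialization (simulator interchange)
# ---------------------------------------------------------------------------

READSET_HEADER = "fragment_id\tsite\tallele\tqual\tsource_label"


def write_readset(readset: ReadSet, path: str) -> None:
    """Write a ReadSet as a TSV (one row per covered site)."""
    with open(path, "w") as fh:
        fh.write(READSET_HEADER + "\n")
        for frag in readset.fragments:
            lab = "." if frag.source_label is None else str(frag.source_label)
            for t, a, q in zip(frag.sites, frag.alleles, frag.quals):
                fh.write(f"{frag.id}\t{t}\t{a}\t{q:.6g}\t{lab}\n")


def read_readset(path: str) -> ReadSet:
    rows: dict[str, list[tuple[int, int, float, int | None]]] = {}
    order: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != READSET_HEADER:
            raise ValueError(f"{path}: unexpected ReadSet header {header!r}")
        for line in fh:
            fid, t, a, q, lab = line.rstrip("\n").split("\t")
            if fid not in rows:
                rows[fid] = []
                order.append(fid)
            rows[fid].append((int(t), int(a), float(q),
                              None if lab == "." else int(lab)))
    frags = []
    for fid in order:
        entries = sorted(rows[fid])
        frags.append(ReadFragment(
            id=fid,
            sites=np.array([e[0] for e in entries], dtype=np.int64),
            alleles=np.array([e[1] for e in entries], dtype=np.uint8),
            quals=np.array([e[2] for e in entries], dtype=np.float64),
            source_label=entries[0][3],
        ))
    return ReadSet(frags)
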