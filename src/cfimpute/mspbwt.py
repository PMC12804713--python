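"""Multi-symbol positional Burrows-Wheeler transform (msPBWT) over grid words.

A classic PBWT sorts binary haplotypes by reversed prefixes, one allele at a
time. Here each position is a *grid* of 32 SNPs packed into one 32-bit word,
and each grid column is recoded into at most 256 symbols: the 255 most
frequent words get symbols 1..255 (descending frequency, ties broken by
ascending word value) and every remaining word maps to the catch-all symbol
0, with the actual (row, word) pairs kept in a per-grid rare store so exact
word comparisons remain possible.

Two indices are built: ``A`` (per grid, the permutation placing panel rows
in reverse sorted prefix order) and ``U`` (per grid, prefix-count tables that
advance an insertion position from one grid to the next in O(1)). A target
haplotype is located by computing its insertion-position trace ``f`` and then
scanning up/down around ``f`` to collect the closest ``L`` rows with their
exact match lengths (in grids). Per-target insertion cost is O(G) table
lookups, independent of panel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .panel_io import GridPanel

logger = logging.getLogger(__name__)

MAX_RANKED_SYMBOLS = 255  # symbols 1..255; 0 is the catch-all

INDEX_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# Symbol encoding
# ---------------------------------------------------------------------------

@dataclass
class SymbolEncoding:
    """Per-grid word -> symbol recoding of a grid panel."""

    sym: np.ndarray               # (N, G) uint8, symbol of each row at each grid
    n_symbols: np.ndarray         # (G,) int32, number of distinct symbols used
    ranked_words: list[np.ndarray]  # per grid, words of symbols 1..S (index 0 -> symbol 1)
    rare_store: list[list[tuple[int, int]]]  # per grid, (row, word) for symbol-0 rows
    words: np.ndarray             # (N, G) uint32, the raw panel words

    @property
    def n_haps(self) -> int:
        return self.sym.shape[0]

    @property
    def G(self) -> int:
        return self.sym.shape[1]

    def target_symbols(self, target_words: np.ndarray) -> np.ndarray:
        """Map a length-G word vector through the encoding (unseen -> 0)."""
        target_words = np.asarray(target_words, dtype=np.uint32)
        if target_words.shape != (self.G,):
            raise ValueError("target must have one word per grid")
        out = np.zeros(self.G, dtype=np.int64)
        for g in range(self.G):
            rw = self.ranked_words[g]
            hit = np.flatnonzero(rw == target_words[g])
            out[g] = hit[0] + 1 if hit.size else 0
        return out


def build_symbol_encoding(grids: GridPanel) -> SymbolEncoding:
    """Rank each grid's words by descending panel frequency (ties by ascending
    word value); the top 255 get symbols 1..255, the rest symbol 0."""
    words = grids.words
    n, g_count = words.shape
    if n == 0 or g_count == 0:
        raise ValueError("empty grid panel")
    sym = np.zeros((n, g_count), dtype=np.uint8)
    n_symbols = np.zeros(g_count, dtype=np.int32)
    ranked_words: list[np.ndarray] = []
    rare_store: list[list[tuple[int, int]]] = []
    for g in range(g_count):
        col = words[:, g]
        uniq, counts = np.unique(col, return_counts=True)
        # descending count, then ascending word value (np.unique gives ascending words)
        order = np.lexsort((uniq, -counts))
        ranked = uniq[order][:MAX_RANKED_SYMBOLS]
        ranked_words.append(ranked.astype(np.uint32))
        word_to_sym = {int(w): s + 1 for s, w in enumerate(ranked)}
        col_sym = np.array([word_to_sym.get(int(w), 0) for w in col], dtype=np.uint8)
        sym[:, g] = col_sym
        rare = [(int(r), int(col[r])) for r in np.flatnonzero(col_sym == 0)]
        rare_store.append(rare)
        n_symbols[g] = len(ranked) + (1 if rare else 0)
    return SymbolEncoding(sym=sym, n_symbols=n_symbols, ranked_words=ranked_words,
                          rare_store=rare_store, words=np.ascontiguousarray(words))


# ---------------------------------------------------------------------------
# Index build
# ---------------------------------------------------------------------------

@dataclass
class MsPbwtIndex:
    """The A / U indices of the msPBWT.

    ``A[g]`` sorts panel rows by their reversed symbol prefix over grids
    ``< g`` (ascending, stable; ``A[0]`` is the identity). ``occ[g][s, i]``
    counts occurrences of symbol ``s`` among the first ``i`` rows of
    ``A[g]``'s order at grid ``g``, and ``C[g][s]`` counts rows with symbol
    ``< s`` at grid ``g``; together they advance insertion positions.
    """

    A: np.ndarray                 # (G+1, N) int32
    occ: list[np.ndarray]         # per grid, (S_g, N+1) int32 cumulative counts
    C: list[np.ndarray]           # per grid, (S_g + 1,) int32 symbol offsets
    enc: SymbolEncoding
    n_lookups: int = field(default=0, compare=False)

    @property
    def n_haps(self) -> int:
        return self.A.shape[1]

    @property
    def G(self) -> int:
        return self.A.shape[0] - 1

    def advance(self, g: int, s: int, i: int) -> int:
        """Next-grid insertion position for symbol ``s`` inserted at ``i``."""
        self.n_lookups += 1
        return int(self.C[g][s] + self.occ[g][s, i])


def build_index(enc: SymbolEncoding) -> MsPbwtIndex:
    n, g_count = enc.sym.shape
    a = np.empty((g_count + 1, n), dtype=np.int32)
    a[0] = np.arange(n, dtype=np.int32)
    occ: list[np.ndarray] = []
    offsets: list[np.ndarray] = []
    for g in range(g_count):
        col = enc.sym[a[g], g].astype(np.int64)
        s_max = int(col.max()) + 1
        one_hot = np.zeros((s_max, n + 1), dtype=np.int32)
        one_hot[col, np.arange(1, n + 1)] = 1
        occ_g = np.cumsum(one_hot, axis=1, dtype=np.int32)
        occ.append(occ_g)
        c_g = np.zeros(s_max + 1, dtype=np.int32)
        c_g[1:] = np.cumsum(occ_g[:, n])
        offsets.append(c_g)
        # stable counting sort of A[g] keyed on the symbol at grid g
        order = np.argsort(col, kind="stable")
        a[g + 1] = a[g][order]
    return MsPbwtIndex(A=a, occ=occ, C=offsets, enc=enc)


# ---------------------------------------------------------------------------
# Target queries
# ---------------------------------------------------------------------------

def insert_target(index: MsPbwtIndex, enc: SymbolEncoding,
                  target_words: np.ndarray) -> np.ndarray:
    """Insertion-position trace of a target haplotype.

    ``f[g]`` is the number of panel rows whose reversed symbol prefix over
    grids ``<= g`` sorts strictly before the target's, i.e. the position at
    which the target would be inserted into ``A[g+1]``. Exactly G table
    lookups are performed.
    """
    if index.n_haps == 0:
        raise ValueError("empty panel index")
    syms = enc.target_symbols(target_words)
    f = np.empty(index.G, dtype=np.int64)
    cur = 0
    for g in range(index.G):
        # target symbols are always within the grid's occ table: ranked
        # symbols come from the column itself, and unseen words map to 0,
        # whose (possibly all-zero) occ row always exists
        cur = index.advance(g, int(syms[g]), cur)
        f[g] = cur
    return f


@dataclass
class NeighbourSet:
    """Closest-L rows per grid with exact match lengths (in grids)."""

    neighbours: list[list[tuple[int, int]]]  # per grid, (row, match_length)
    f: np.ndarray

    @property
    def G(self) -> int:
        return len(self.neighbours)


def _word_match_len(words: np.ndarray, row: int, target_words: np.ndarray,
                    g: int, bound: int) -> int:
    """Consecutive grids ending at g where the row's word equals the target's,
    checked at most ``bound`` grids back."""
    ml = 0
    while ml < bound and words[row, g - ml] == target_words[g - ml]:
        ml += 1
    return ml


def _sym_match_len(sym: np.ndarray, row: int, target_syms: np.ndarray,
                   g: int, bound: int) -> int:
    ml = 0
    while ml < bound and sym[row, g - ml] == target_syms[g - ml]:
        ml += 1
    return ml


def scan_neighbours(index: MsPbwtIndex, enc: SymbolEncoding, f: np.ndarray,
                    L: int, target_words: np.ndarray) -> NeighbourSet:
    """Scan up and down around each insertion position to collect the closest
    L rows and their exact match lengths.

    Scan order gives priority to rows above the insertion point (closest
    first), then rows below (closest first); ties in match length go to the
    earlier scan position. Because ``A`` sorts by symbol prefixes, the symbol
    match length is non-increasing moving away from ``f``, which bounds the
    scan; exact lengths compare raw words, so symbol-0 collisions are
    resolved against the stored words.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    target_words = np.asarray(target_words, dtype=np.uint32)
    target_syms = enc.target_symbols(target_words)
    words = enc.words
    sym = enc.sym
    g_count = index.G
    out: list[list[tuple[int, int]]] = []
    for g in range(g_count):
        a1 = index.A[g + 1]
        pos = int(f[g])
        candidates: list[tuple[int, int]] = []  # (row, wml) in scan order

        def side_scan(indices):
            collected = []
            cap = g + 1
            wmls = []
            for i in indices:
                if cap == 0:
                    break
                row = int(a1[i])
                sml = _sym_match_len(sym, row, target_syms, g, cap)
                cap = sml
                if sml == 0:
                    break
                wml = _word_match_len(words, row, target_words, g, sml)
                if wml >= 1:
                    collected.append((row, wml))
                    wmls.append(wml)
                if len(collected) >= L:
                    kth = sorted(wmls, reverse=True)[L - 1]
                    if cap <= kth:
                        break
            return collected

        candidates.extend(side_scan(range(pos - 1, -1, -1)))
        candidates.extend(side_scan(range(pos, len(a1))))
        # stable sort by decreasing match length; scan order breaks ties
        ranked = sorted(range(len(candidates)),
                        key=lambda i: (-candidates[i][1], i))[:L]
        out.append([candidates[i] for i in ranked])
    return NeighbourSet(neighbours=out, f=np.asarray(f))


def default_uniqueness_scorer(neigh: NeighbourSet, min_len: int) -> dict[int, float]:
    """Match length summed over grids, each grid's contribution divided by the
    number of candidates covering it (uniqueness weighting)."""
    scores: dict[int, float] = {}
    for entries in neigh.neighbours:
        kept = [(row, ml) for row, ml in entries if ml >= min_len]
        if not kept:
            continue
        w = 1.0 / len(kept)
        for row, ml in kept:
            scores[row] = scores.get(row, 0.0) + ml * w
    return scores


def select_conditioning_haps(neigh: NeighbourSet, K: int, min_len: int,
                             n_haps: int, rng: np.random.Generator,
                             scorer=default_uniqueness_scorer) -> np.ndarray:
    """Pick at most K distinct rows, ranked by the uniqueness-weighted match
    score; candidates shorter than ``min_len`` everywhere are dropped, and a
    shortfall is filled with seeded-random panel rows."""
    if K < 1:
        raise ValueError("K must be >= 1")
    scores = scorer(neigh, min_len)
    ranked = sorted(scores, key=lambda r: (-scores[r], r))[:K]
    chosen = list(ranked)
    if len(chosen) < K:
        pool = np.setdiff1d(np.arange(n_haps), np.array(chosen, dtype=np.int64))
        n_fill = min(K - len(chosen), pool.size)
        if n_fill > 0:
            chosen.extend(int(r) for r in rng.choice(pool, size=n_fill, replace=False))
    return np.array(chosen, dtype=np.int64)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def save_index(path: str, panel, grids: GridPanel, index: MsPbwtIndex) -> None:
    """Serialize panel metadata + GridPanel + msPBWT index to one .npz
    archive (version-tagged); the allele matrix is recovered by decoding the
    grid words."""
    enc = index.enc
    rw_flat = (np.concatenate(enc.ranked_words)
               if enc.ranked_words else np.empty(0, dtype=np.uint32))
    rw_off = np.cumsum([0] + [len(r) for r in enc.ranked_words])
    rs = [(g, r, w) for g, lst in enumerate(enc.rare_store) for r, w in lst]
    rs_arr = (np.array(rs, dtype=np.int64).reshape(-1, 3)
              if rs else np.empty((0, 3), dtype=np.int64))
    occ_flat = np.concatenate([o.ravel() for o in index.occ])
    occ_shapes = np.array([o.shape for o in index.occ], dtype=np.int64)
    c_flat = np.concatenate(index.C)
    c_off = np.cumsum([0] + [len(c) for c in index.C])
    np.savez(path,
             version=np.int64(INDEX_FORMAT_VERSION),
             chrom=np.str_(panel.chrom),
             pos=panel.positions,
             ref=np.array([s.ref for s in panel.sites]),
             alt=np.array([s.alt for s in panel.sites]),
             sample_names=np.array(panel.sample_names),
             words=grids.words, snp_to_grid=grids.snp_to_grid,
             grid_cm=grids.grid_cm, n_sites=np.int64(grids.n_sites),
             sym=enc.sym, n_symbols=enc.n_symbols,
             rw_flat=rw_flat, rw_off=np.asarray(rw_off, dtype=np.int64),
             rs_arr=rs_arr,
             A=index.A, occ_flat=occ_flat, occ_shapes=occ_shapes,
             c_flat=c_flat, c_off=np.asarray(c_off, dtype=np.int64))


def load_index(path: str):
    try:
        z = np.load(path)
        version = int(z["version"])
    except Exception as exc:  # noqa: BLE001 - surface as a clear format error
        raise ValueError(f"cannot parse index file {path}: {exc}") from exc
    if version != INDEX_FORMAT_VERSION:
        raise ValueError(f"index file {path} has format version {version}; "
                         f"expected {INDEX_FORMAT_VERSION}")
    words = z["words"]
    grids = GridPanel(words=words, G=words.shape[1], snp_to_grid=z["snp_to_grid"],
                      grid_cm=z["grid_cm"], n_sites=int(z["n_sites"]))
    g_count = grids.G
    rw_off = z["rw_off"]
    ranked_words = [z["rw_flat"][rw_off[g]:rw_off[g + 1]].astype(np.uint32)
                    for g in range(g_count)]
    rare_store: list[list[tuple[int, int]]] = [[] for _ in range(g_count)]
    for g, r, w in z["rs_arr"]:
        rare_store[int(g)].append((int(r), int(w)))
    enc = SymbolEncoding(sym=z["sym"], n_symbols=z["n_symbols"],
                         ranked_words=ranked_words, rare_store=rare_store,
                         words=words)
    occ = []
    off = 0
    for s, n1 in z["occ_shapes"]:
        occ.append(z["occ_flat"][off:off + s * n1].reshape(int(s), int(n1)))
        off += s * n1
    c_off = z["c_off"]
    offsets = [z["c_flat"][c_off[g]:c_off[g + 1]] for g in range(g_count)]
    index = MsPbwtIndex(A=z["A"], occ=occ, C=offsets, enc=enc)

    from .panel_io import HaplotypePanel, SiteRecord
    alleles = grids.decode()
    chrom = str(z["chrom"])
    af = alleles.mean(axis=0)
    sites = [SiteRecord(chrom, int(p), str(r), str(a), float(f))
             for p, r, a, f in zip(z["pos"], z["ref"], z["alt"], af)]
    panel = HaplotypePanel(alleles, sites, [str(s) for s in z["sample_names"]])
    return panel, grids, index
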