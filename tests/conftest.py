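import numpy as np
import pytest

import cfimpute as cf


@pytest.fixture(scope="session")
def small_panel() -> cf.HaplotypePanel:
    """Mosaic panel shared by read-model / sampler tests."""
    return cf.simulate_panel(cf.SimPanelConfig(n_haps=60, n_snps=160, seed=11))


@pytest.fixture(scope="session")
def small_grids(small_panel):
    return cf.encode_grids(small_panel)


@pytest.fixture(scope="session")
def small_index(small_grids):
    return cf.build_index(cf.build_symbol_encoding(small_grids))


def write_vcf_text(path, records, samples=("S0", "S1"), chrom="chr1"):
    """Minimal phased VCF writer for hand-constructed fixtures.

    records: list of (pos, ref, alt, [gt strings per sample])
    """
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={chrom}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)]
    for pos, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def random_grid_panel(rng, n, g, n_words=None):
    """GridPanel with words drawn from a limited alphabet (forces matches)."""
    if n_words is None:
        n_words = max(2, n // 3)
    vocab = rng.integers(0, 2**32, size=n_words, dtype=np.uint64).astype(np.uint32)
    words = vocab[rng.integers(0, n_words, size=(n, g))]
    return cf.GridPanel(words=np.ascontiguousarray(words), G=g,
                        snp_to_grid=(np.arange(g * 32) // 32).astype(np.int32),
                        grid_cm=np.full(g - 1, 0.01), n_sites=g * 32)
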