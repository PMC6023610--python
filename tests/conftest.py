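import numpy as np
import pytest

from talegrn.peaks import Peak, PeakSet
from talegrn.synthetic import SyntheticConfig, generate_dataset


def make_peak(chrom="chr1", summit=500, fe=20.0, pid="p1", half=200):
    return Peak(chrom=chrom, start=summit - half, end=summit + half,
                summit=summit, fold_enrichment=fe, id=pid)


def random_peakset(rng, n, chroms=("chr1", "chr2"), chrom_len=100_000,
                   label="set", half=50):
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        summit = int(rng.integers(half, chrom_len - half))
        peaks.append(Peak(chrom, summit - half, summit + half, summit,
                          float(rng.uniform(0, 40)), f"{label}{i:04d}"))
    return PeakSet(label=label, peaks=peaks,
                   genome={c: chrom_len for c in chroms})


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """One modest synthetic dataset shared by tests that only read it."""
    out = tmp_path_factory.mktemp("synth")
    cfg = SyntheticConfig(seed=11, n_early_peaks=400, n_late_only_peaks=400)
    manifest = generate_dataset(cfg, out)
    return {"dir": out, "config": cfg, "manifest": manifest}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
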