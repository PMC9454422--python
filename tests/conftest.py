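import numpy as np
import pytest

from rohscope.genotype_io import GenotypeMatrix
from rohscope.synthetic_data import SimConfig, simulate_cohort


def make_gm(dosages, pos=None, chrom=None, samples=None, populations=None,
            ref=None, alt=None):
    """Hand-build a GenotypeMatrix from a dosage array (-1 = missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    pos = np.arange(1, m + 1, dtype=np.int64) * 1000 if pos is None else np.asarray(pos, np.int64)
    chrom = np.array(["1"] * m, object) if chrom is None else np.asarray(chrom, object)
    samples = [f"s{i}" for i in range(n)] if samples is None else list(samples)
    ref = np.array(["A"] * m, object) if ref is None else np.asarray(ref, object)
    alt = np.array(["G"] * m, object) if alt is None else np.asarray(alt, object)
    gm = GenotypeMatrix(
        samples=samples, chrom=chrom, pos=pos, ref=ref, alt=alt,
        dosages=dosages, populations=dict(populations or {}),
    )
    gm.validate()
    return gm


@pytest.fixture(scope="session")
def small_cohort():
    """Two populations x 10 individuals, 4000 sites; session-wide reuse."""
    cfg = SimConfig(n_pops=2, n_per_pop=10, n_sites=4000, fst=0.1, seed=11)
    return simulate_cohort(cfg)
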