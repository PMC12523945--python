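import numpy as np
import pytest

from gbtskit.io import GenotypeMatrix
from gbtskit.simulate import PopulationSpec, simulate_cohort


def make_matrix(
    dosage,
    pos=None,
    seq_id=None,
    qual=None,
    depth=None,
    ref=None,
    alt=None,
    n_alt=None,
    is_snp=None,
    groups=None,
    samples=None,
):
    """Build a GenotypeMatrix from a dosage array with sensible defaults."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000, dtype=np.int64)
    return GenotypeMatrix(
        samples=samples or [f"s{i + 1}" for i in range(n)],
        seq_id=np.asarray(seq_id if seq_id is not None else ["seq1"] * m, dtype=object),
        pos=pos,
        ref=np.asarray(ref if ref is not None else ["A"] * m, dtype=object),
        alt=np.asarray(alt if alt is not None else ["C"] * m, dtype=object),
        n_alt=np.asarray(n_alt if n_alt is not None else [1] * m, dtype=np.int32),
        is_snp=np.asarray(is_snp if is_snp is not None else [True] * m, dtype=bool),
        qual=np.asarray(qual if qual is not None else [50.0] * m, dtype=float),
        dosage=dosage,
        depth=np.asarray(depth if depth is not None else np.full((n, m), 10), dtype=np.int32),
        groups=groups,
    )


def build_crafted_cascade_matrix():
    """Nine loci engineering one failure per screening rule plus two survivors.

    L1 fails QUAL (10 < 20); L2 is an indel; L3 has mean depth 60x against a
    cohort average of 100/9 ~ 11.1x (above the 5x-average ceiling); L4 has
    MAF 0.02; L5 has missing rate 0.4; L6 has heterozygote rate 0.9; L7/L8
    sit 3 bp apart so the lower-MAF one loses the spacing rule; L9 is clean.
    """
    n = 25

    def col(n_het=0, n_hom_alt=0, n_missing=0):
        c = np.zeros(n, dtype=np.int8)
        c[:n_het] = 1
        c[n_het : n_het + n_hom_alt] = 2
        if n_missing:
            c[n - n_missing :] = -1
        return c

    cols = [
        col(n_het=10, n_hom_alt=5),               # L1 qual fail
        col(n_het=10, n_hom_alt=5),               # L2 indel
        col(n_het=10, n_hom_alt=5),               # L3 depth 60x
        col(n_het=1),                             # L4 maf 0.02
        col(n_het=5, n_missing=10),               # L5 missing 0.4
        col(n_het=18, n_hom_alt=2, n_missing=5),  # L6 het 0.9
        col(n_het=10, n_hom_alt=5),               # L7 maf 0.4 (spacing winner)
        col(n_het=11, n_hom_alt=2),               # L8 maf 0.3, 3 bp away
        col(n_het=10),                            # L9 maf 0.2
    ]
    dosage = np.stack(cols, axis=1)
    depth = np.full((n, 9), 5, dtype=np.int32)
    depth[:, 2] = 60
    return make_matrix(
        dosage,
        pos=[1000, 2000, 3000, 4000, 5000, 6000, 7000, 7003, 9000],
        qual=[10.0] + [50.0] * 8,
        alt=["C", "CT"] + ["C"] * 7,
        is_snp=[True, False] + [True] * 7,
        depth=depth,
    )


@pytest.fixture(scope="session")
def two_pop_cohort():
    """Two well-differentiated populations (F = 0.2), 30 + 30 samples."""
    spec = PopulationSpec(
        n_pops=2, n_per_pop=30, fst=0.2, n_loci=2000,
        seq_lengths=(200_000,) * 3, missing_rate=0.02,
        qual_low_fraction=0.0, seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """Three populations, modest size, with QUAL/missingness realism."""
    spec = PopulationSpec(
        n_pops=3, n_per_pop=10, fst=0.2, n_loci=800,
        seq_lengths=(100_000,) * 3, missing_rate=0.05,
        qual_low_fraction=0.05, seed=7,
    )
    return simulate_cohort(spec)
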