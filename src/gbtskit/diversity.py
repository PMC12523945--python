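"""Per-locus and per-group genetic diversity statistics.

For a biallelic locus with ALT frequency ``p`` (estimated from non-missing
calls) and ``q = 1 - p``:

    MAF = min(p, q)
    He  = 1 - p^2 - q^2              (expected heterozygosity, plug-in)
    PIC = 1 - p^2 - q^2 - 2 p^2 q^2  (Botstein polymorphism information content)
    Ao  = number of observed alleles (2 if 0 < p < 1 else 1)
    Ae  = 1 / (p^2 + q^2)            (effective allele number; = 1/(1 - He))
    Ho  = heterozygote fraction among non-missing calls

He uses the plug-in estimator with no small-sample (2n/(2n-1)) correction
by default, matching common chip-analysis toolchains; pass
``unbiased=True`` for the corrected variant.  Group summaries are
unweighted means of per-locus values over loci with at least one called
genotype in the group.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

STAT_COLUMNS = ["maf", "pic", "ao", "ae", "ho", "he"]


def locus_stats_table(
    matrix: GenotypeMatrix, unbiased: bool = False
) -> pd.DataFrame:
    """Per-locus MAF/PIC/Ao/Ae/Ho/He for every locus with >= 1 call.

    All-missing loci yield NaN rows (excluded from group means).
    """
    called = matrix.called
    n_called = called.sum(axis=0).astype(float)
    dos = np.where(called, matrix.dosage, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_called)
        ho = ((matrix.dosage == 1) & called).sum(axis=0) / n_called
    q = 1.0 - p
    he = 1.0 - p * p - q * q
    if unbiased:
        nn = 2.0 * n_called
        with np.errstate(invalid="ignore", divide="ignore"):
            he = np.where(nn > 1, he * nn / (nn - 1.0), he)
    pic = 1.0 - p * p - q * q - 2.0 * p * p * q * q
    with np.errstate(divide="ignore", invalid="ignore"):
        ae = 1.0 / (p * p + q * q)
    ao = np.where(np.isnan(p), np.nan, np.where((p > 0) & (p < 1), 2.0, 1.0))
    empty = n_called == 0
    out = pd.DataFrame(
        {
            "seq_id": matrix.seq_id,
            "pos": matrix.pos,
            "maf": np.minimum(p, q),
            "pic": pic,
            "ao": ao,
            "ae": ae,
            "ho": ho,
            "he": he,
            "n_called": n_called.astype(int),
        }
    )
    out.loc[empty, STAT_COLUMNS] = np.nan
    return out


def locus_stats(dosages: np.ndarray, unbiased: bool = False) -> dict[str, float]:
    """Statistics of a single locus from a dosage vector (-1 = missing)."""
    dosages = np.asarray(dosages)
    if not np.any(dosages >= 0):
        raise ValueError("locus has no called genotypes")
    from .io import GenotypeMatrix

    n = len(dosages)
    m = GenotypeMatrix(
        samples=[f"s{i}" for i in range(n)],
        seq_id=np.asarray(["x"], dtype=object),
        pos=np.asarray([1], dtype=np.int64),
        ref=np.asarray(["A"], dtype=object),
        alt=np.asarray(["C"], dtype=object),
        n_alt=np.asarray([1], dtype=np.int32),
        is_snp=np.asarray([True]),
        qual=np.asarray([50.0]),
        dosage=dosages.reshape(n, 1).astype(np.int8),
        depth=np.full((n, 1), 10, dtype=np.int32),
    )
    row = locus_stats_table(m, unbiased=unbiased).iloc[0]
    return {k: float(row[k]) for k in STAT_COLUMNS + ["n_called"]}


def group_diversity(
    matrix: GenotypeMatrix,
    groups: list[str] | None = None,
    unbiased: bool = False,
) -> pd.DataFrame:
    """Mean diversity per group plus a pooled "All" row.

    Frequencies are re-estimated within each group's samples; cells are
    unweighted means over loci with at least one called genotype in that
    group.  Rows: "All" first, then groups in alphabetical order.
    """
    if groups is not None:
        matrix = GenotypeMatrix(**{**matrix.__dict__, "groups": list(groups)})
    if matrix.groups is None:
        raise ValueError("no group labels provided")
    if len(matrix.groups) != matrix.n_samples:
        raise ValueError("one group label per sample required")

    rows = {}
    rows["All"] = locus_stats_table(matrix, unbiased=unbiased)[STAT_COLUMNS].mean()
    for g, idx in matrix.group_indices().items():
        if len(idx) == 0:
            raise ValueError(f"empty group {g!r}")
        sub = matrix.take_samples(idx)
        rows[g] = locus_stats_table(sub, unbiased=unbiased)[STAT_COLUMNS].mean()
    order = ["All"] + sorted(g for g in rows if g != "All")
    table = pd.DataFrame([rows[g] for g in order], index=order)
    table.index.name = "group"
    table.columns = ["MAF", "PIC", "Ao", "Ae", "Ho", "He"]
    return table


def write_diversity_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", float_format="%.4f")
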