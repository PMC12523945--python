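"""VCF / FASTA / TSV input-output and the in-memory genotype data model.

Genotypes are stored as minor... strictly: ALT-allele *dosages* (0, 1, 2)
with -1 marking a missing call, in a dense ``(n_samples, n_loci)`` int8
array.  Coordinates mirror VCF: 1-based, inclusive.  Genotypes are treated
as unphased throughout; a phase separator in the input is accepted and
ignored, since none of the downstream statistics use phase.

Multi-allelic records are retained on read but flagged (``n_alt > 1``);
dosage then counts copies of the *first* ALT allele.  The biallelic-SNP
filter in :mod:`gbtskit.panel` removes such records before any statistic
is computed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MISSING = -1  # dosage sentinel


@dataclasses.dataclass
class GenotypeMatrix:
    """Samples x loci dosage matrix plus per-locus metadata.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, in column order of the source VCF.
    seq_id, pos : ndarray
        Per-locus sequence name and 1-based position, sorted by
        ``(seq_id, pos)`` with no duplicates.
    ref, alt : ndarray of str
        REF allele and *first* ALT allele per locus.
    n_alt : ndarray of int
        Number of ALT alleles in the source record (>1 flags multi-allelic).
    is_snp : ndarray of bool
        True iff REF and every ALT allele have length 1.
    qual : ndarray of float
        Site QUAL.
    dosage : ndarray, shape (n_samples, n_loci), int8
        ALT-allele dosage; -1 = missing.
    depth : ndarray, shape (n_samples, n_loci), int32
        Per-sample read depth (DP).
    groups : list of str or None
        Per-sample group labels, aligned with ``samples``.
    seq_lengths : dict or None
        Reference sequence lengths, when known (used for contig headers).
    """

    samples: list[str]
    seq_id: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    n_alt: np.ndarray
    is_snp: np.ndarray
    qual: np.ndarray
    dosage: np.ndarray
    depth: np.ndarray
    groups: list[str] | None = None
    seq_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} samples but dosage has {n} rows")
        for name in ("seq_id", "pos", "ref", "alt", "n_alt", "is_snp", "qual"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"per-locus field {name!r} length != {m}")
        key = list(zip(self.seq_id.tolist(), self.pos.tolist()))
        if sorted(key) != key:
            raise ValueError("loci must be sorted by (seq_id, pos)")
        if len(set(key)) != m:
            raise ValueError("duplicate (seq_id, pos) locus")

    # -- shape -----------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True where the call is missing."""
        return self.dosage == MISSING

    @property
    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def locus_mean_depth(self) -> np.ndarray:
        """Mean DP per locus over samples with a called genotype."""
        called = self.called
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            out = np.where(n > 0, (self.depth * called).sum(axis=0) / np.maximum(n, 1), np.nan)
        return out

    # -- subsetting ------------------------------------------------------
    def take_loci(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=self.samples,
            seq_id=self.seq_id[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            n_alt=self.n_alt[idx],
            is_snp=self.is_snp[idx],
            qual=self.qual[idx],
            dosage=self.dosage[:, idx],
            depth=self.depth[:, idx],
            groups=self.groups,
            seq_lengths=self.seq_lengths,
        )

    def take_samples(self, idx: np.ndarray | Sequence[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in idx],
            seq_id=self.seq_id,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            n_alt=self.n_alt,
            is_snp=self.is_snp,
            qual=self.qual,
            dosage=self.dosage[idx, :],
            depth=self.depth[idx, :],
            groups=None if self.groups is None else [self.groups[i] for i in idx],
            seq_lengths=self.seq_lengths,
        )

    def group_indices(self) -> dict[str, np.ndarray]:
        if self.groups is None:
            raise ValueError("no group labels attached")
        out: dict[str, list[int]] = {}
        for i, g in enumerate(self.groups):
            out.setdefault(g, []).append(i)
        return {g: np.asarray(ix) for g, ix in sorted(out.items())}

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Structural equality on samples, loci, dosages, depths, QUAL (2 dp)."""
        return (
            self.samples == other.samples
            and np.array_equal(self.seq_id, other.seq_id)
            and np.array_equal(self.pos, other.pos)
            and np.array_equal(self.ref, other.ref)
            and np.array_equal(self.alt, other.alt)
            and np.array_equal(self.dosage, other.dosage)
            and np.array_equal(self.depth, other.depth)
            and np.allclose(np.round(self.qual, 2), np.round(other.qual, 2))
        )


def _sort_loci(order_key: list[tuple[str, int]]) -> np.ndarray:
    return np.asarray(sorted(range(len(order_key)), key=order_key.__getitem__))


def read_groups(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, group) TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "group"], dtype=str)
    return dict(zip(df["sample"], df["group"]))


def write_groups(samples: Sequence[str], groups: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s, g in zip(samples, groups):
            fh.write(f"{s}\t{g}\n")


def read_vcf(
    path: str | Path,
    groups_path: str | Path | None = None,
    on_unsorted: str = "sort",
) -> GenotypeMatrix:
    """Read a VCF v4.x into a :class:`GenotypeMatrix`.

    Parameters
    ----------
    path : path to a (plain or bgzipped) VCF.
    groups_path : optional sample->group TSV; every VCF sample must be
        mapped or a ``KeyError`` is raised.
    on_unsorted : "sort" (canonicalize) or "error".
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)

    seq_ids, poss, refs, alts, n_alts, snps, quals = [], [], [], [], [], [], []
    dos_cols, dp_cols = [], []
    try:
        seq_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lengths
        seq_lengths = None

    for v in vcf:
        alt_list = v.ALT or []
        seq_ids.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(alt_list[0] if alt_list else ".")
        n_alts.append(len(alt_list))
        snps.append(len(v.REF) == 1 and bool(alt_list) and all(len(a) == 1 for a in alt_list))
        quals.append(v.QUAL if v.QUAL is not None else 0.0)

        gts = v.genotypes  # [[a1, a2, phased], ...]
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                col[i] = MISSING
            else:
                col[i] = sum(1 for a in alleles if a == 1)
        dos_cols.append(col)
        try:
            dp = v.format("DP")
            dp_col = np.where(dp is None, 0, np.asarray(dp).reshape(-1)).astype(np.int32)
            dp_col = np.where(dp_col < 0, 0, dp_col)
        except Exception:
            dp_col = np.zeros(len(samples), dtype=np.int32)
        dp_cols.append(dp_col)

    mat = _build_sorted(
        samples, seq_ids, poss, refs, alts, n_alts, snps, quals, dos_cols, dp_cols,
        seq_lengths, on_unsorted,
    )

    if groups_path is not None:
        mapping = read_groups(groups_path)
        unknown = [s for s in samples if s not in mapping]
        if unknown:
            raise KeyError(f"samples absent from group mapping: {unknown[:5]}")
        mat.groups = [mapping[s] for s in samples]
    return mat


def _build_sorted(samples, seq_ids, poss, refs, alts, n_alts, snps, quals,
                  dos_cols, dp_cols, seq_lengths, on_unsorted) -> GenotypeMatrix:
    m = len(poss)
    key = list(zip(seq_ids, poss))
    order = np.arange(m)
    if sorted(key) != key:
        if on_unsorted == "error":
            raise ValueError("VCF records are not sorted by (CHROM, POS)")
        order = _sort_loci(key)

    def pick(lst, dtype):
        return np.asarray([lst[i] for i in order], dtype=dtype)

    return GenotypeMatrix(
        samples=samples,
        seq_id=pick(seq_ids, object),
        pos=pick(poss, np.int64),
        ref=pick(refs, object),
        alt=pick(alts, object),
        n_alt=pick(n_alts, np.int32),
        is_snp=pick(snps, bool),
        qual=pick(quals, float),
        dosage=(
            np.stack([dos_cols[i] for i in order], axis=1)
            if m else np.zeros((len(samples), 0), dtype=np.int8)
        ),
        depth=(
            np.stack([dp_cols[i] for i in order], axis=1)
            if m else np.zeros((len(samples), 0), dtype=np.int32)
        ),
        seq_lengths=seq_lengths,
    )


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCF v4.2 with GT:DP sample fields.

    Field ordering and float formatting are fixed (QUAL to 2 decimals) so
    that identical matrices always produce byte-identical files.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gbtskit\n")
        if matrix.seq_lengths:
            for sid, length in matrix.seq_lengths.items():
                fh.write(f"##contig=<ID={sid},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_loci):
            cells = [
                f"{_GT_STR[int(matrix.dosage[i, j])]}:{int(matrix.depth[i, j])}"
                for i in range(matrix.n_samples)
            ]
            fh.write(
                f"{matrix.seq_id[j]}\t{matrix.pos[j]}\t.\t{matrix.ref[j]}\t"
                f"{matrix.alt[j]}\t{matrix.qual[j]:.2f}\t.\t.\tGT:DP\t"
                + "\t".join(cells)
                + "\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into an ordered {id: uppercase sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
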