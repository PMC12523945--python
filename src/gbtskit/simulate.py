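"""Synthetic reference genomes and structured diploid populations.

The generator emulates the kind of multi-breed resource population a
genotyping panel is designed from: ``n_pops`` drift-differentiated
populations whose allele frequencies follow the Balding-Nichols model.
For each locus an ancestral frequency ``p`` is drawn from
``Uniform(0.05, 0.95)``; population *k* then draws its frequency from

    p_k ~ Beta(p (1 - F_k) / F_k,  (1 - p)(1 - F_k) / F_k)

so that ``E[p_k] = p`` and ``Var[p_k] = F_k p (1 - p)`` -- ``F_k`` is the
population's FST-like differentiation parameter.  Unadmixed individuals
draw genotypes Binomial(2, p_k); admixed individuals draw each of their
two allele copies from population *k* with probability ``q_k`` (their
ancestry proportion).  Per-site QUAL, per-sample Poisson depth, and
Bernoulli missingness give the marker-screening cascade realistic inputs.

All randomness flows from a single integer seed: the same
:class:`PopulationSpec` always yields byte-identical FASTA and VCF output.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import MISSING, GenotypeMatrix, write_fasta, write_groups, write_vcf

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclasses.dataclass
class PopulationSpec:
    """Parameters of a simulated structured population.

    Defaults emulate a ten-breed resource cohort (~14 birds per breed)
    genotyped at candidate loci spread over six reference sequences.
    """

    n_pops: int = 10
    n_per_pop: int = 14
    fst: float | Sequence[float] = 0.1
    n_loci: int = 10_000
    seq_lengths: Sequence[int] = (500_000,) * 6
    admixed_fraction: float = 0.0
    missing_rate: float = 0.05
    mean_depth: float = 10.0
    qual_low_fraction: float = 0.05
    min_qual: float = 20.0
    seed: int = 0
    # optional distortions for exercising the filter cascade
    indel_fraction: float = 0.0
    multiallelic_fraction: float = 0.0
    # optional block-copy LD: loci are chained in blocks of `ld_block_size`,
    # each locus copying the previous one's allele copies with per-copy flip
    # probability `ld_flip_prob` (a testing device, not a coalescent model)
    ld_block_size: int = 1
    ld_flip_prob: float = 0.05
    # placement margins
    edge_margin_bp: int = 200
    min_placement_gap_bp: int = 1

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        fst = self.fst_array
        if np.any(fst <= 0) or np.any(fst >= 1):
            raise ValueError("fst must lie strictly in (0, 1)")
        for name in ("admixed_fraction", "missing_rate", "qual_low_fraction",
                     "indel_fraction", "multiallelic_fraction", "ld_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if any(L <= 0 for L in self.seq_lengths):
            raise ValueError("sequence lengths must be positive")
        if sum(self.seq_lengths) < self.n_loci * 10:
            raise ValueError("total reference length < 10 bp per locus; too dense")

    @property
    def fst_array(self) -> np.ndarray:
        fst = np.asarray(self.fst, dtype=float)
        if fst.ndim == 0:
            fst = np.repeat(fst, self.n_pops)
        if fst.shape != (self.n_pops,):
            raise ValueError("fst must be scalar or one value per population")
        return fst

    @property
    def n_samples(self) -> int:
        return self.n_pops * self.n_per_pop


@dataclasses.dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    ancestral_freqs: np.ndarray  # (n_loci,)
    pop_freqs: np.ndarray  # (n_pops, n_loci)
    q_true: np.ndarray  # (n_samples, n_pops)
    groups: list[str]  # per sample

    def __post_init__(self) -> None:
        if not np.allclose(self.q_true.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("q_true rows must sum to 1")
        for arr in (self.ancestral_freqs, self.pop_freqs, self.q_true):
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError("frequencies / proportions must be in [0, 1]")

    def write_tsv(self, path: str | Path, samples: Sequence[str]) -> None:
        k = self.q_true.shape[1]
        with open(path, "w") as fh:
            fh.write("sample\tgroup\t" + "\t".join(f"q{j + 1}" for j in range(k)) + "\n")
            for i, s in enumerate(samples):
                qs = "\t".join(f"{v:.6f}" for v in self.q_true[i])
                fh.write(f"{s}\t{self.groups[i]}\t{qs}\n")


def simulate_reference(spec: PopulationSpec) -> dict[str, str]:
    """Simulate uppercase ACGT reference sequences (uniform base model)."""
    rng = np.random.default_rng([spec.seed, 0])
    out: dict[str, str] = {}
    for i, length in enumerate(spec.seq_lengths, start=1):
        idx = rng.integers(0, 4, size=int(length))
        out[f"seq{i}"] = _BASES[idx].tobytes().decode("ascii")
    return out


def _place_loci(spec: PopulationSpec, ref: dict[str, str], rng: np.random.Generator):
    """Assign loci to sequences (proportional to length) at unique positions.

    Positions are 1-based, at least ``edge_margin_bp`` from either end and
    ``min_placement_gap_bp`` apart (gap 1 = merely unique).
    """
    lengths = np.array([len(s) for s in ref.values()], dtype=float)
    names = list(ref)
    counts = np.floor(spec.n_loci * lengths / lengths.sum()).astype(int)
    for i in np.argsort(-lengths):  # distribute the remainder to longest first
        if counts.sum() >= spec.n_loci:
            break
        counts[i] += spec.n_loci - counts.sum()

    seq_ids, positions = [], []
    gap = max(1, spec.min_placement_gap_bp)
    for name, L, c in zip(names, lengths.astype(int), counts):
        if c == 0:
            continue
        lo, hi = spec.edge_margin_bp + 1, L - spec.edge_margin_bp
        n_slots = (hi - lo) // gap + 1 if hi >= lo else 0
        if n_slots < c:
            raise ValueError(
                f"cannot place {c} loci on sequence {name!r}: only {n_slots} "
                f"positions available at gap {gap} with margin {spec.edge_margin_bp}"
            )
        slots = rng.choice(n_slots, size=c, replace=False)
        pos = np.sort(lo + slots * gap)
        seq_ids.extend([name] * c)
        positions.extend(pos.tolist())
    return np.asarray(seq_ids, dtype=object), np.asarray(positions, dtype=np.int64)


_ALT_OF = {
    "A": ("C", "G", "T"), "C": ("A", "G", "T"),
    "G": ("A", "C", "T"), "T": ("A", "C", "G"),
}


def simulate_population(
    spec: PopulationSpec, ref: dict[str, str]
) -> tuple[GenotypeMatrix, TruthSet]:
    """Simulate genotypes at placed loci; returns the matrix and its truth."""
    rng = np.random.default_rng([spec.seed, 1])
    n, k, m = spec.n_samples, spec.n_pops, spec.n_loci
    fst = spec.fst_array

    seq_ids, positions = _place_loci(spec, ref, rng)

    # Balding-Nichols population frequencies around a uniform ancestral MAF
    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = p_anc[None, :] * ((1 - fst) / fst)[:, None]
    b = (1 - p_anc)[None, :] * ((1 - fst) / fst)[:, None]
    pop_freqs = rng.beta(a, b)

    # ancestry proportions: one-hot per population, Dirichlet(1) for admixed
    groups = [f"pop{p + 1}" for p in range(k) for _ in range(spec.n_per_pop)]
    pop_of = np.repeat(np.arange(k), spec.n_per_pop)
    q = np.zeros((n, k))
    q[np.arange(n), pop_of] = 1.0
    if spec.admixed_fraction > 0 and k > 1:
        n_adm = int(round(spec.admixed_fraction * n))
        adm_idx = rng.choice(n, size=n_adm, replace=False)
        q[adm_idx] = rng.dirichlet(np.ones(k), size=n_adm)

    # draw each of the two allele copies: source population, then allele
    cum_q = np.cumsum(q, axis=1)
    u = rng.random(size=(2, n, m))
    src = (u[..., None] > cum_q[None, :, None, :]).sum(axis=-1)  # (2, n, m)
    alleles = (rng.random(size=(2, n, m)) < pop_freqs[src, np.arange(m)[None, None, :]])

    if spec.ld_block_size > 1:
        # chain-copy allele states along blocks of consecutive loci
        flip = rng.random(size=(2, n, m)) < spec.ld_flip_prob
        alleles = alleles.copy()
        for j in range(1, m):
            if j % spec.ld_block_size != 0 and seq_ids[j] == seq_ids[j - 1]:
                alleles[..., j] = alleles[..., j - 1] ^ flip[..., j]

    dosage = alleles.sum(axis=0).astype(np.int8)

    depth = rng.poisson(spec.mean_depth, size=(n, m)).astype(np.int32)
    miss = rng.random(size=(n, m)) < spec.missing_rate
    dosage[miss] = MISSING
    depth[miss] = 0

    low = rng.random(size=m) < spec.qual_low_fraction
    qual = np.where(
        low,
        rng.uniform(2.0, max(2.0, spec.min_qual - 0.5), size=m),
        rng.uniform(spec.min_qual + 10.0, 900.0, size=m),
    )
    qual = np.round(qual, 2)

    # alleles: REF read off the reference sequence, ALT a different base
    ref_allele = np.empty(m, dtype=object)
    alt_allele = np.empty(m, dtype=object)
    n_alt = np.ones(m, dtype=np.int32)
    is_snp = np.ones(m, dtype=bool)
    alt_pick = rng.integers(0, 3, size=m)
    extra_pick = rng.integers(0, 2, size=m)
    u_kind = rng.random(size=m)
    for j in range(m):
        base = ref[seq_ids[j]][positions[j] - 1]
        choices = _ALT_OF[base]
        ref_allele[j] = base
        alt_allele[j] = choices[alt_pick[j]]
        if u_kind[j] < spec.indel_fraction:
            alt_allele[j] = base + choices[alt_pick[j]]  # 1 bp insertion
            is_snp[j] = False
        elif u_kind[j] < spec.indel_fraction + spec.multiallelic_fraction:
            n_alt[j] = 2
            is_snp[j] = True  # both ALTs are single bases

    order = np.asarray(
        sorted(range(m), key=lambda j: (seq_ids[j], int(positions[j])))
    )
    matrix = GenotypeMatrix(
        samples=[f"S{i + 1:03d}" for i in range(n)],
        seq_id=seq_ids[order],
        pos=positions[order],
        ref=ref_allele[order],
        alt=alt_allele[order],
        n_alt=n_alt[order],
        is_snp=is_snp[order],
        qual=qual[order],
        dosage=dosage[:, order],
        depth=depth[:, order],
        groups=groups,
        seq_lengths={name: len(s) for name, s in ref.items()},
    )
    truth = TruthSet(
        ancestral_freqs=p_anc[order],
        pop_freqs=pop_freqs[:, order],
        q_true=q,
        groups=groups,
    )
    return matrix, truth


def simulate_cohort(spec: PopulationSpec):
    """Convenience: reference plus population in one call."""
    ref = simulate_reference(spec)
    matrix, truth = simulate_population(spec, ref)
    return ref, matrix, truth


def write_cohort(spec: PopulationSpec, out_prefix: str | Path) -> dict[str, Path]:
    """Simulate and write <prefix>.fasta/.vcf/.truth.tsv/.groups.tsv."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ref, matrix, truth = simulate_cohort(spec)
    paths = {
        "fasta": prefix.with_suffix(".fasta"),
        "vcf": prefix.with_suffix(".vcf"),
        "truth": Path(str(prefix) + ".truth.tsv"),
        "groups": Path(str(prefix) + ".groups.tsv"),
    }
    write_fasta(ref, paths["fasta"])
    write_vcf(matrix, paths["vcf"])
    truth.write_tsv(paths["truth"], matrix.samples)
    write_groups(matrix.samples, truth.groups, paths["groups"])
    return paths
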