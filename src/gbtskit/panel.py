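"""Marker screening cascade and ranked selection of a fixed-size panel.

Candidate variants pass through an ordered cascade of retention rules:

1. ``qual``        site QUAL >= 20 (drop calls whose quality implies a
                   sequencing error rate above 1%);
2. ``biallelic``   SNPs only (indels removed) with exactly two alleles;
3. ``depth``       per-locus mean depth within [1/3, 5] x the cohort
                   average depth, and >= 5x absolute;
4. ``maf``         minor allele frequency >= 0.05;
5. ``missing``     missing rate < 0.25 (strict);
6. ``het``         heterozygote fraction <= 0.5 (configurable direction --
                   see FilterParams.het_rule);
7. ``spacing``     retained loci on the same sequence >= 5 bp apart,
                   conflicts resolved in favour of the higher-ranked locus.

Survivors are then ranked lexicographically -- high MAF, then low missing
rate, then low heterozygosity, then (seq_id, pos) as a deterministic
tiebreak -- and selected greedily under the spacing constraint until the
target panel size is reached.

The average depth used by rule 3 is the grand mean of per-locus mean
depths over the *pre-filter* input, computed once.  MAF and heterozygosity
use non-missing calls as denominator; the missing rate uses all samples.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

RULES = ("qual", "biallelic", "depth", "maf", "missing", "het", "spacing")


@dataclasses.dataclass
class FilterParams:
    """Thresholds of the screening cascade (defaults per the 5 K design)."""

    min_qual: float = 20.0
    min_spacing_bp: int = 5
    depth_window: tuple[float, float] = (1.0 / 3.0, 5.0)
    min_site_depth: float = 5.0
    min_maf: float = 0.05
    max_missing: float = 0.25
    max_het_rate: float = 0.5
    target_size: int = 5000
    het_rule: str = "max"  # "max": drop het > threshold; "min": drop het < threshold

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ValueError("max_missing must be in [0, 1]")
        low, high = self.depth_window
        if not low < high:
            raise ValueError("depth_window low multiplier must be < high")
        if self.het_rule not in ("max", "min"):
            raise ValueError("het_rule must be 'max' or 'min'")


@dataclasses.dataclass
class FilterReport:
    """Ordered per-rule attrition and the first rule failed by each locus."""

    rules: list[tuple[str, int, int, int]]  # (name, n_in, n_removed, n_out)
    first_fail: np.ndarray  # per input locus: rule name or '' if survived

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rules, columns=["rule", "n_in", "n_removed", "n_out"])

    def validate_chain(self) -> None:
        for (na, _, _, out_a), (nb, in_b, _, _) in zip(self.rules, self.rules[1:]):
            if out_a != in_b:
                raise AssertionError(f"report chain broken between {na} and {nb}")

    @property
    def n_out(self) -> int:
        return self.rules[-1][3]

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def locus_summaries(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus MAF, missing rate, het rate and mean depth.

    MAF and het rate are over non-missing calls; missing rate over all
    samples.  Loci with zero calls get NaN MAF/het.
    """
    called = matrix.called
    n_called = called.sum(axis=0)
    dos = np.where(called, matrix.dosage, 0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = dos.sum(axis=0) / (2.0 * n_called)
        het = ((matrix.dosage == 1) & called).sum(axis=0) / n_called
    maf = np.minimum(p_alt, 1.0 - p_alt)
    missing_rate = 1.0 - n_called / matrix.n_samples
    return pd.DataFrame(
        {
            "seq_id": matrix.seq_id,
            "pos": matrix.pos,
            "maf": maf,
            "missing_rate": missing_rate,
            "het_rate": het,
            "mean_depth": matrix.locus_mean_depth(),
            "n_called": n_called,
        }
    )


def _rank_order(summ: pd.DataFrame, idx: np.ndarray) -> np.ndarray:
    """Indices `idx` sorted by (MAF desc, missing asc, het asc, seq, pos)."""
    sub = summ.iloc[idx]
    order = np.lexsort(
        (
            sub["pos"].to_numpy(),
            sub["seq_id"].to_numpy(),
            sub["het_rate"].to_numpy(),
            sub["missing_rate"].to_numpy(),
            -sub["maf"].to_numpy(),
        )
    )
    return np.asarray(idx)[order]


def _greedy_spacing(
    seq_id: np.ndarray, pos: np.ndarray, ranked: np.ndarray, min_spacing: int,
    limit: int | None = None,
) -> tuple[list[int], list[int]]:
    """Accept loci in rank order unless within `min_spacing` of an accepted one."""
    accepted: list[int] = []
    rejected: list[int] = []
    taken: dict[str, list[int]] = {}
    import bisect

    for j in ranked:
        if limit is not None and len(accepted) >= limit:
            break
        s, p = seq_id[j], int(pos[j])
        lst = taken.setdefault(s, [])
        i = bisect.bisect_left(lst, p)
        if (i > 0 and p - lst[i - 1] < min_spacing) or (
            i < len(lst) and lst[i] - p < min_spacing
        ):
            rejected.append(j)
            continue
        bisect.insort(lst, p)
        accepted.append(j)
    return accepted, rejected


def filter_candidates(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the screening cascade; returns survivors and the attrition report."""
    params = params or FilterParams()
    if matrix.n_loci == 0:
        raise ValueError("empty input matrix")

    summ = locus_summaries(matrix)
    grand_mean_depth = float(np.nanmean(summ["mean_depth"].to_numpy()))

    alive = np.arange(matrix.n_loci)
    first_fail = np.full(matrix.n_loci, "", dtype=object)
    rules: list[tuple[str, int, int, int]] = []

    def apply(name: str, keep_mask: np.ndarray) -> None:
        nonlocal alive
        removed = alive[~keep_mask]
        first_fail[removed] = name
        rules.append((name, len(alive), int((~keep_mask).sum()), int(keep_mask.sum())))
        alive = alive[keep_mask]

    apply("qual", matrix.qual[alive] >= params.min_qual)
    apply("biallelic", matrix.is_snp[alive] & (matrix.n_alt[alive] == 1))

    md = summ["mean_depth"].to_numpy()[alive]
    low, high = params.depth_window
    keep = (
        (md >= low * grand_mean_depth)
        & (md <= high * grand_mean_depth)
        & (md >= params.min_site_depth)
    )
    apply("depth", keep)

    maf = summ["maf"].to_numpy()
    apply("maf", np.nan_to_num(maf[alive], nan=-1.0) >= params.min_maf)

    apply("missing", summ["missing_rate"].to_numpy()[alive] < params.max_missing)

    het = summ["het_rate"].to_numpy()[alive]
    if params.het_rule == "max":
        apply("het", np.nan_to_num(het, nan=1.0) <= params.max_het_rate)
    else:
        apply("het", np.nan_to_num(het, nan=-1.0) >= params.max_het_rate)

    ranked = _rank_order(summ, alive)
    kept, dropped = _greedy_spacing(
        matrix.seq_id, matrix.pos, ranked, params.min_spacing_bp
    )
    first_fail[dropped] = "spacing"
    rules.append(("spacing", len(alive), len(dropped), len(kept)))
    alive = np.asarray(sorted(kept), dtype=int)

    if len(alive) == 0:
        warnings.warn("all loci removed by the filter cascade", stacklevel=2)
    report = FilterReport(rules=rules, first_fail=first_fail)
    report.validate_chain()
    return matrix.take_loci(alive), report


@dataclasses.dataclass
class Panel:
    """A selected locus set with rank scores and (optionally) probe pairs."""

    matrix: GenotypeMatrix  # selected loci only, canonically sorted
    scores: pd.DataFrame  # seq_id, pos, maf, missing_rate, het_rate, rank
    min_spacing_bp: int
    reserve: pd.DataFrame | None = None  # ranked non-selected candidates
    reserve_matrix: GenotypeMatrix | None = None
    probes: "pd.DataFrame | None" = None  # filled by probe evaluation

    @property
    def size(self) -> int:
        return self.matrix.n_loci

    def spacing_violations(self) -> int:
        """Number of adjacent same-sequence pairs closer than min_spacing_bp."""
        v = 0
        same = self.matrix.seq_id[1:] == self.matrix.seq_id[:-1]
        gaps = np.diff(self.matrix.pos)
        v = int(np.sum(same & (gaps < self.min_spacing_bp)))
        return v

    def write_bed(self, path: str | Path) -> None:
        """0-based half-open single-base intervals of the panel loci."""
        with open(path, "w") as fh:
            for s, p in zip(self.matrix.seq_id, self.matrix.pos):
                fh.write(f"{s}\t{p - 1}\t{p}\n")

    def write_scores(self, path: str | Path) -> None:
        self.scores.to_csv(path, sep="\t", index=False, float_format="%.6f")


def rank_and_select(
    candidates: GenotypeMatrix, params: FilterParams | None = None
) -> Panel:
    """Greedy rank-ordered selection of up to ``target_size`` loci.

    ``candidates`` must already have passed :func:`filter_candidates`;
    selection enforces the spacing constraint again so that the panel
    remains valid even for hand-built inputs.
    """
    params = params or FilterParams()
    if params.target_size <= 0:
        raise ValueError("target_size must be positive")
    summ = locus_summaries(candidates)
    ranked = _rank_order(summ, np.arange(candidates.n_loci))
    kept, _ = _greedy_spacing(
        candidates.seq_id, candidates.pos, ranked, params.min_spacing_bp,
        limit=params.target_size,
    )
    kept_set = set(kept)
    rank_of = {j: r for r, j in enumerate(ranked)}
    sel = np.asarray(sorted(kept), dtype=int)

    scores = summ.iloc[sel][["seq_id", "pos", "maf", "missing_rate", "het_rate"]].copy()
    scores["rank"] = [rank_of[j] for j in sel]
    scores = scores.reset_index(drop=True)

    reserve_idx = [j for j in ranked if j not in kept_set]
    reserve = summ.iloc[reserve_idx][
        ["seq_id", "pos", "maf", "missing_rate", "het_rate"]
    ].copy()
    reserve["rank"] = [rank_of[j] for j in reserve_idx]
    reserve = reserve.reset_index(drop=True)

    return Panel(
        matrix=candidates.take_loci(sel),
        scores=scores,
        min_spacing_bp=params.min_spacing_bp,
        reserve=reserve,
        reserve_matrix=candidates.take_loci(np.asarray(sorted(reserve_idx), dtype=int))
        if reserve_idx
        else None,
    )


def design_panel(
    matrix: GenotypeMatrix, params: FilterParams | None = None
) -> tuple[Panel, FilterReport]:
    """Full screening: filter cascade followed by ranked selection."""
    params = params or FilterParams()
    survivors, report = filter_candidates(matrix, params)
    panel = rank_and_select(survivors, params)
    return panel, report
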