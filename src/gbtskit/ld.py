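"""Pairwise linkage disequilibrium (r^2) and distance-binned decay curves.

r^2 is the squared Pearson correlation of genotype *dosage* vectors over
samples called at both loci -- the composite (unphased) LD statistic used
by genotype-file LD tools.  Pairs are restricted to the same sequence and
a maximum physical distance; pairs with fewer than 4 complete
observations, or with a monomorphic member among those observations, are
skipped (counted, not raised).

The decay curve bins pairs by distance, averages r^2 per bin, smooths the
binned means with a centred 3-bin moving average, and reports the
half-decay distance: the distance at which the smoothed curve first falls
to half its maximum (linear interpolation between bin centres).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


def pairwise_r2(
    matrix: GenotypeMatrix,
    max_dist_bp: int = 300_000,
    min_maf: float = 0.0,
    min_pair_obs: int = 4,
) -> pd.DataFrame:
    """All same-sequence locus pairs within ``max_dist_bp``.

    Returns a DataFrame (seq_id, pos1, pos2, dist, r2, n) sorted by
    (seq_id, pos1, pos2); monomorphic / under-observed pairs are omitted.
    """
    if min_maf > 0:
        from .panel import locus_summaries

        maf = locus_summaries(matrix)["maf"].to_numpy()
        matrix = matrix.take_loci(np.flatnonzero(np.nan_to_num(maf) >= min_maf))

    D = matrix.dosage.astype(float)
    W = matrix.called.astype(float)
    Dw = D * W

    rows = []
    for seq in pd.unique(matrix.seq_id):
        idx = np.flatnonzero(matrix.seq_id == seq)
        pos = matrix.pos[idx]
        d, w = Dw[:, idx], W[:, idx]
        # pairwise sums over jointly-called samples
        n = w.T @ w
        s1 = d.T @ w  # sum of x over joint mask, per (i, j)
        s2 = w.T @ d
        ss1 = (d * d).T @ w
        ss2 = w.T @ (d * d)
        sxy = d.T @ d
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = sxy - s1 * s2 / n
            var1 = ss1 - s1 * s1 / n
            var2 = ss2 - s2 * s2 / n
            r2 = (cov * cov) / (var1 * var2)
        m = len(idx)
        iu, ju = np.triu_indices(m, k=1)
        dist = pos[ju] - pos[iu]
        keep = dist <= max_dist_bp
        iu, ju, dist = iu[keep], ju[keep], dist[keep]
        nn = n[iu, ju]
        v1, v2 = var1[iu, ju], var2[iu, ju]
        ok = (nn >= min_pair_obs) & (v1 > 0) & (v2 > 0)
        rows.append(
            pd.DataFrame(
                {
                    "seq_id": seq,
                    "pos1": pos[iu[ok]],
                    "pos2": pos[ju[ok]],
                    "dist": dist[ok],
                    "r2": np.clip(r2[iu[ok], ju[ok]], 0.0, 1.0),
                    "n": nn[ok].astype(int),
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["seq_id", "pos1", "pos2", "dist", "r2", "n"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["seq_id", "pos1", "pos2"], ignore_index=True)


@dataclasses.dataclass
class LDDecayCurve:
    """Binned mean r^2 against physical distance for one sample group."""

    group: str
    bin_edges: np.ndarray  # len = n_bins + 1, strictly increasing
    mean_r2: np.ndarray  # NaN for empty bins
    pair_counts: np.ndarray
    half_decay_bp: float  # NaN if the curve never falls to half-max

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        return pd.DataFrame(
            {
                "group": self.group,
                "bin_start": self.bin_edges[:-1],
                "bin_end": self.bin_edges[1:],
                "bin_center": centers,
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_counts,
            }
        )


def _moving_average3(y: np.ndarray) -> np.ndarray:
    """Centred 3-point moving average over the occupied entries."""
    out = np.full_like(y, np.nan)
    occ = np.flatnonzero(~np.isnan(y))
    vals = y[occ]
    for t, _ in enumerate(occ):
        lo, hi = max(0, t - 1), min(len(occ), t + 2)
        out[occ[t]] = vals[lo:hi].mean()
    return out


def decay_curve(
    pairs: pd.DataFrame, bin_width_bp: int = 1000, group: str = "All"
) -> LDDecayCurve:
    """Bin pairwise r^2 by distance and locate the half-decay distance."""
    if bin_width_bp <= 0:
        raise ValueError("bin width must be positive")
    if len(pairs) == 0:
        raise ValueError("empty pair list")
    dist = pairs["dist"].to_numpy(dtype=float)
    r2 = pairs["r2"].to_numpy(dtype=float)
    n_bins = int(np.ceil(dist.max() / bin_width_bp)) or 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_bp
    which = np.minimum((dist // bin_width_bp).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=r2, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    smooth = _moving_average3(mean_r2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    occ = np.flatnonzero(~np.isnan(smooth))
    half_decay = float("nan")
    if len(occ) > 0:
        y, x = smooth[occ], centers[occ]
        target = y.max() / 2.0
        below = np.flatnonzero(y <= target)
        if below.size:
            t = below[0]
            if t == 0:
                half_decay = float(x[0])
            else:
                x0, x1, y0, y1 = x[t - 1], x[t], y[t - 1], y[t]
                half_decay = float(x0 + (y0 - target) / (y0 - y1) * (x1 - x0))
    return LDDecayCurve(
        group=group,
        bin_edges=edges,
        mean_r2=mean_r2,
        pair_counts=counts,
        half_decay_bp=half_decay,
    )


def group_decay_curves(
    matrix: GenotypeMatrix,
    max_dist_bp: int = 300_000,
    bin_width_bp: int = 1000,
    min_maf: float = 0.0,
) -> dict[str, LDDecayCurve]:
    """One decay curve per sample group (requires group labels)."""
    out = {}
    for g, idx in matrix.group_indices().items():
        pairs = pairwise_r2(matrix.take_samples(idx), max_dist_bp, min_maf)
        if len(pairs):
            out[g] = decay_curve(pairs, bin_width_bp, group=g)
    return out


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, sep="\t", index=False, float_format="%.6f")


def write_curves_tsv(curves: dict[str, LDDecayCurve], path: str | Path) -> None:
    pd.concat([c.to_frame() for c in curves.values()], ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
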