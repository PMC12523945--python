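"""In-solution capture probe design for a selected SNP panel.

Each panel locus gets a pair of 110 bp probes whose 60-70% overlap window
contains the SNP.  A probe pair passes when both probes have GC content in
[0.30, 0.70], the SNP sits at least 10 bp from every probe end, and the
number of homologous regions in the reference does not exceed 5.

"Homologous region" is operationalized as a merged k-mer seed-hit window:
the reference is indexed by canonical (strand-collapsed) k-mers, probe
k-mers are looked up, hit positions on each sequence are clustered within
one probe length, and clusters reached by at least ``min_seed_hits`` seeds
are counted -- the probe's own source window always contributes one count.
Defaults (k = 15, min_seed_hits = 5) are exposed in :class:`ProbeParams`.

Probe coordinates are 0-based half-open internally; the TSV report and
FASTA identifiers use 1-based inclusive coordinates.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import Panel

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of a nucleotide string; N bases are excluded entirely.

    Returns NaN for an all-N sequence; raises on an empty string.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    if acgt == 0:
        return float("nan")
    return gc / acgt


@dataclasses.dataclass
class ProbeParams:
    """Probe geometry and pass thresholds."""

    probe_length: int = 110
    overlap_target: float = 0.65
    overlap_range: tuple[float, float] = (0.60, 0.70)
    gc_range: tuple[float, float] = (0.30, 0.70)
    max_homologous_regions: int = 5
    kmer_length: int = 15
    min_seed_hits: int = 5
    probes_per_locus: int = 2  # pair design
    evaluation_window_bp: int = 120  # context window centred on the SNP
    min_end_distance_bp: int = 10  # SNP kept this far from each probe end


@dataclasses.dataclass
class ProbePair:
    """Two overlapping probes covering one SNP."""

    seq_id: str
    pos: int  # 1-based SNP position
    start_a: int  # 0-based probe starts
    start_b: int
    probe_a: str
    probe_b: str
    overlap_fraction: float
    gc_a: float
    gc_b: float
    homology_count: int | None = None
    passed: bool = False
    fail_reasons: tuple[str, ...] = ()


class HomologyIndex:
    """Canonical k-mer -> reference positions, covering both strands."""

    def __init__(self, ref: dict[str, str], k: int = 15):
        if k < 11:
            raise ValueError("k-mer length must be >= 11")
        self.k = k
        self.index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in ref.items():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                rc = revcomp(kmer)
                canon = kmer if kmer <= rc else rc
                self.index.setdefault(canon, []).append((name, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        rc = revcomp(kmer)
        canon = kmer if kmer <= rc else rc
        return self.index.get(canon, [])


def count_homologous_regions(
    probe: str, index: HomologyIndex, min_seed_hits: int = 5
) -> int:
    """Distinct genomic windows sharing >= min_seed_hits k-mers with the probe.

    Hit positions are merged per sequence when closer than the probe length,
    so a run of overlapping seed matches counts as one region.
    """
    k = index.k
    probe = probe.upper()
    if k > len(probe):
        raise ValueError("k-mer length exceeds probe length")
    hits: dict[str, list[int]] = {}
    for i in range(len(probe) - k + 1):
        for name, p in index.lookup(probe[i : i + k]):
            hits.setdefault(name, []).append(p)
    count = 0
    span = len(probe)
    for name, positions in sorted(hits.items()):
        positions.sort()
        cluster = 1
        prev = positions[0]
        for p in positions[1:]:
            if p - prev >= span:
                if cluster >= min_seed_hits:
                    count += 1
                cluster = 0
            cluster += 1
            prev = p
        if cluster >= min_seed_hits:
            count += 1
    return count


def extract_probe_pair(
    ref: dict[str, str],
    seq_id: str,
    pos: int,
    params: ProbeParams | None = None,
) -> ProbePair:
    """Place a pair of overlapping probes around a SNP (1-based ``pos``).

    Probe B starts ``L - round(L * overlap_target)`` bases after probe A;
    the pair is centred so the SNP falls mid-overlap, sliding to fit near
    sequence ends.  Fails with reason "edge" when no placement keeps the
    SNP inside the overlap window.
    """
    params = params or ProbeParams()
    L = params.probe_length
    overlap_len = round(L * params.overlap_target)
    shift = L - overlap_len
    seq = ref[seq_id]
    z = pos - 1  # 0-based SNP index

    # ideal: SNP centred in the shared window [a+shift, a+L)
    a = z - shift - (L - shift) // 2
    lo, hi = 0, len(seq) - (L + shift)  # valid range of probe-A starts
    a = min(max(a, lo), max(hi, lo))

    def fail(reason: str) -> ProbePair:
        return ProbePair(seq_id, pos, -1, -1, "", "", 0.0, float("nan"),
                         float("nan"), passed=False, fail_reasons=(reason,))

    if hi < lo or not (a + shift <= z < a + L) or z >= len(seq):
        return fail("edge")

    b = a + shift
    probe_a = seq[a : a + L]
    probe_b = seq[b : b + L]
    pair = ProbePair(
        seq_id=seq_id,
        pos=pos,
        start_a=a,
        start_b=b,
        probe_a=probe_a,
        probe_b=probe_b,
        overlap_fraction=overlap_len / L,
        gc_a=gc_content(probe_a),
        gc_b=gc_content(probe_b),
    )
    # SNP must keep clear of probe ends
    d = params.min_end_distance_bp
    if min(z - a, a + L - 1 - z, z - b, b + L - 1 - z) < d:
        pair.fail_reasons = ("edge",)
    return pair


def _check_pair(pair: ProbePair, params: ProbeParams) -> ProbePair:
    reasons = list(pair.fail_reasons)
    glo, ghi = params.gc_range
    if not (glo <= pair.gc_a <= ghi and glo <= pair.gc_b <= ghi):
        reasons.append("gc")
    olo, ohi = params.overlap_range
    if not (olo <= pair.overlap_fraction <= ohi):
        reasons.append("overlap")
    if pair.homology_count is not None and pair.homology_count > params.max_homologous_regions:
        reasons.append("homology")
    pair.fail_reasons = tuple(dict.fromkeys(reasons))
    pair.passed = not pair.fail_reasons
    return pair


def design_probe_pair(
    ref: dict[str, str],
    seq_id: str,
    pos: int,
    index: HomologyIndex | None = None,
    params: ProbeParams | None = None,
) -> ProbePair:
    """Extract and fully validate one probe pair."""
    params = params or ProbeParams()
    pair = extract_probe_pair(ref, seq_id, pos, params)
    if pair.probe_a and index is not None:
        pair.homology_count = max(
            count_homologous_regions(pair.probe_a, index, params.min_seed_hits),
            count_homologous_regions(pair.probe_b, index, params.min_seed_hits),
        )
    return _check_pair(pair, params)


def evaluate_panel_probes(
    panel: Panel,
    ref: dict[str, str],
    params: ProbeParams | None = None,
    index: HomologyIndex | None = None,
    replace_failures: bool = True,
) -> Panel:
    """Attach probe pairs to every panel locus, replacing failures.

    Loci whose probe pair fails any constraint are dropped and replaced by
    the next-ranked reserve candidate whose probes pass and which respects
    the spacing constraint, until the panel regains its size or the
    reserve is exhausted.  Failures are recorded as data (the returned
    ``panel.probes`` table), never raised.
    """
    params = params or ProbeParams()
    if panel.size == 0:
        raise ValueError("empty panel")
    if index is None:
        index = HomologyIndex(ref, k=params.kmer_length)

    rows: list[dict] = []
    kept: list[tuple[str, int]] = []
    target = panel.size

    def evaluate(seq_id: str, pos: int) -> ProbePair:
        return design_probe_pair(ref, seq_id, pos, index=index, params=params)

    import bisect

    taken: dict[str, list[int]] = {}

    def record(pair: ProbePair, selected: bool) -> None:
        rows.append(
            {
                "seq_id": pair.seq_id,
                "pos": pair.pos,
                "start_a": pair.start_a + 1,
                "end_a": pair.start_a + params.probe_length,
                "start_b": pair.start_b + 1,
                "end_b": pair.start_b + params.probe_length,
                "probe_a": pair.probe_a,
                "probe_b": pair.probe_b,
                "overlap_fraction": pair.overlap_fraction,
                "gc_a": pair.gc_a,
                "gc_b": pair.gc_b,
                "homology_count": pair.homology_count,
                "passed": pair.passed,
                "fail_reasons": ",".join(pair.fail_reasons),
                "selected": selected,
            }
        )

    for seq_id, pos in zip(panel.matrix.seq_id, panel.matrix.pos):
        pair = evaluate(str(seq_id), int(pos))
        ok = pair.passed
        record(pair, ok)
        if ok:
            kept.append((str(seq_id), int(pos)))
            bisect.insort(taken.setdefault(str(seq_id), []), int(pos))

    if replace_failures and panel.reserve is not None and len(kept) < target:
        for _, row in panel.reserve.iterrows():
            if len(kept) >= target:
                break
            s, p = str(row["seq_id"]), int(row["pos"])
            lst = taken.setdefault(s, [])
            i = bisect.bisect_left(lst, p)
            if (i > 0 and p - lst[i - 1] < panel.min_spacing_bp) or (
                i < len(lst) and lst[i] - p < panel.min_spacing_bp
            ):
                continue
            pair = evaluate(s, p)
            record(pair, pair.passed)
            if pair.passed:
                kept.append((s, p))
                bisect.insort(lst, p)

    probes = pd.DataFrame(rows)
    kept_set = set(kept)

    # rebuild the selected matrix from panel + reserve loci
    source = panel.matrix
    sel_idx = [
        j
        for j in range(source.n_loci)
        if (str(source.seq_id[j]), int(source.pos[j])) in kept_set
    ]
    new_matrix = source.take_loci(np.asarray(sel_idx, dtype=int))
    if panel.reserve_matrix is not None:
        rm = panel.reserve_matrix
        extra_idx = [
            j
            for j in range(rm.n_loci)
            if (str(rm.seq_id[j]), int(rm.pos[j])) in kept_set
        ]
        if extra_idx:
            new_matrix = _concat_loci(new_matrix, rm.take_loci(np.asarray(extra_idx)))

    return Panel(
        matrix=new_matrix,
        scores=panel.scores,
        min_spacing_bp=panel.min_spacing_bp,
        reserve=panel.reserve,
        reserve_matrix=panel.reserve_matrix,
        probes=probes,
    )


def _concat_loci(a, b):
    from .io import GenotypeMatrix

    order_key = list(zip(np.concatenate([a.seq_id, b.seq_id]).tolist(),
                         np.concatenate([a.pos, b.pos]).tolist()))
    order = np.asarray(sorted(range(len(order_key)), key=order_key.__getitem__))

    def cat(x, y):
        return np.concatenate([x, y])[order]

    return GenotypeMatrix(
        samples=a.samples,
        seq_id=cat(a.seq_id, b.seq_id),
        pos=cat(a.pos, b.pos),
        ref=cat(a.ref, b.ref),
        alt=cat(a.alt, b.alt),
        n_alt=cat(a.n_alt, b.n_alt),
        is_snp=cat(a.is_snp, b.is_snp),
        qual=cat(a.qual, b.qual),
        dosage=np.concatenate([a.dosage, b.dosage], axis=1)[:, order],
        depth=np.concatenate([a.depth, b.depth], axis=1)[:, order],
        groups=a.groups,
        seq_lengths=a.seq_lengths,
    )


def write_probe_fasta(probes: pd.DataFrame, path: str | Path) -> None:
    """Two records per selected locus, IDs ``<seq>_<pos>_A`` / ``_B``."""
    with open(path, "w") as fh:
        for _, row in probes[probes["selected"]].iterrows():
            fh.write(f">{row['seq_id']}_{row['pos']}_A\n{row['probe_a']}\n")
            fh.write(f">{row['seq_id']}_{row['pos']}_B\n{row['probe_b']}\n")


def write_probe_tsv(probes: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in probes.columns if c not in ("probe_a", "probe_b")]
    probes[cols].to_csv(path, sep="\t", index=False, float_format="%.4f")
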