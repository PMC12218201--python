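"""Gametolog synonymous divergence (NG86 + JC69) and evolutionary strata.

Ks between an X-linked and a Y-linked gametolog proxies the time since
recombination stopped at that position, so the along-chromosome profile of
block-mean Ks segments the sex-linked region into evolutionary strata:
contiguous runs of synteny blocks sharing a divergence level, each run
recording one episode of recombination suppression.

The Nei–Gojobori (1986) counting method is implemented in full: per-codon
synonymous site fractions by single-mutation enumeration over the standard
genetic code, sites averaged between the two sequences, multi-position
codon differences averaged with equal weight over all minimal mutational
pathways (pathways through stop codons excluded), and the Jukes–Cantor
correction d = -3/4 ln(1 - 4p/3) applied to the observed proportions.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .formats_io import GenomicInterval

BASES = "TCAG"
_CODON_TABLE: dict[str, str] = {}
for _b1 in BASES:
    for _b2 in BASES:
        for _b3 in BASES:
            _CODON_TABLE[_b1 + _b2 + _b3] = ""
# standard genetic code via Biopython
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables  # noqa: E402

_STD = _tables[1]
STOP_CODONS = frozenset(_STD.stop_codons)
for _codon in list(_CODON_TABLE):
    _CODON_TABLE[_codon] = "*" if _codon in STOP_CODONS else _STD.forward_table[_codon]

SENSE_CODONS = tuple(c for c in sorted(_CODON_TABLE) if c not in STOP_CODONS)


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under the standard code ('*' for stop)."""
    return _CODON_TABLE[codon]


@lru_cache(maxsize=None)
def syn_site_fraction(codon: str) -> float:
    """NG86 synonymous site count of one sense codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that preserve the amino acid; changes to stop codons count as
    nonsynonymous.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _CODON_TABLE[mut] == aa:  # stop translates to '*' != aa
                syn += 1
        s += syn / 3
    return s


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    Codons differing at k positions are resolved over all k! orderings of
    the single-base steps, weighted equally; orderings passing through a
    stop codon are excluded (if every ordering is blocked, all are used).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if _CODON_TABLE[nxt] == "*":
                blocked = True
            cur = nxt
        paths.append((blocked, steps))
    usable = [steps for blocked, steps in paths if not blocked]
    if not usable:
        usable = [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _CODON_TABLE[a] == _CODON_TABLE[b]:
                sd += 1
            else:
                nd += 1
    return sd / len(usable), nd / len(usable)


def jc69(p: float) -> tuple[float, bool]:
    """Jukes–Cantor distance for an observed proportion p; flag=False if undefined."""
    arg = 1 - 4 * p / 3
    if arg <= 0:
        return math.nan, False
    return -0.75 * math.log(arg) + 0.0, True


@dataclass
class NG86Result:
    ks: float
    ka: float
    ps: float
    pn: float
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ks_defined: bool = True
    ka_defined: bool = True
    codons_skipped: int = 0


def ng86_rates(x_cds: str, y_cds: str) -> NG86Result:
    """Nei–Gojobori (1986) Ks/Ka between two aligned gap-free codon sequences.

    Codons containing ambiguous bases or gaps in either sequence are skipped
    (counted in ``codons_skipped``); internal stop codons are skipped with a
    warning. Ks/Ka are flagged undefined when the JC69 log argument is <= 0.
    """
    x_cds, y_cds = x_cds.upper(), y_cds.upper()
    if len(x_cds) != len(y_cds):
        raise ValueError(f"length mismatch: {len(x_cds)} vs {len(y_cds)}")
    if len(x_cds) % 3:
        raise ValueError("alignment length must be divisible by 3")
    s_x = s_y = 0.0
    sd = nd = 0.0
    n_codons = 0
    skipped = 0
    stop_skipped = 0
    valid = set("TCAG")
    for i in range(0, len(x_cds), 3):
        cx, cy = x_cds[i: i + 3], y_cds[i: i + 3]
        if not (set(cx) <= valid and set(cy) <= valid):
            skipped += 1
            continue
        if cx in STOP_CODONS or cy in STOP_CODONS:
            stop_skipped += 1
            continue
        s_x += syn_site_fraction(cx)
        s_y += syn_site_fraction(cy)
        d_s, d_n = codon_pair_differences(cx, cy)
        sd += d_s
        nd += d_n
        n_codons += 1
    if stop_skipped:
        warnings.warn(f"skipped {stop_skipped} codon(s) with internal stops")
    if n_codons == 0:
        raise ValueError("no analyzable codons")
    s_sites = (s_x + s_y) / 2
    n_sites = 3 * n_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks, ks_ok = jc69(ps)
    ka, ka_ok = jc69(pn)
    return NG86Result(
        ks=ks, ka=ka, ps=ps, pn=pn, s_sites=s_sites, n_sites=n_sites,
        sd=sd, nd=nd, ks_defined=ks_ok, ka_defined=ka_ok,
        codons_skipped=skipped + stop_skipped,
    )


# ---------------------------------------------------------------------------
# Pairs, blocks, strata
# ---------------------------------------------------------------------------

@dataclass
class GametologPair:
    """One X/Y gametolog codon alignment with its rate estimates."""

    pair_id: str
    x_seq: str
    y_seq: str
    y_position: float | None = None  # bp midpoint on the Y-SLR
    block_id: str | None = None
    rates: NG86Result | None = None

    def estimate(self) -> "GametologPair":
        self.rates = ng86_rates(self.x_seq, self.y_seq)
        return self

    @property
    def ks(self) -> float | None:
        if self.rates is None or not self.rates.ks_defined:
            return None
        return self.rates.ks


@dataclass
class SyntenyBlock:
    """One collinear block on the Y-SLR."""

    block_id: str
    y_interval: GenomicInterval
    orientation: str = "+"  # {+, -, variable}
    mean_ks: float | None = None
    n_pairs: int = 0


@dataclass
class Stratum:
    """A contiguous run of blocks sharing one divergence level."""

    label: str
    block_ids: list[str]
    y_interval: GenomicInterval
    n_pairs: int
    mean_ks: float | None


def strip_gap_columns(x_seq: str, y_seq: str) -> tuple[str, str]:
    """Drop codon columns containing a gap in either sequence."""
    xs, ys = [], []
    for i in range(0, min(len(x_seq), len(y_seq)) // 3 * 3, 3):
        cx, cy = x_seq[i: i + 3], y_seq[i: i + 3]
        if "-" in cx or "-" in cy:
            continue
        xs.append(cx)
        ys.append(cy)
    return "".join(xs), "".join(ys)


def assign_blocks(
    pairs: list[GametologPair], blocks: list[SyntenyBlock]
) -> list[GametologPair]:
    """Assign each pair to the block containing its Y position (<=1 block)."""
    for p in pairs:
        if p.y_position is None:
            continue
        hits = [b for b in blocks if b.y_interval.contains(p.y_position)]
        if len(hits) > 1:
            raise ValueError(
                f"pair {p.pair_id} at {p.y_position} falls in overlapping blocks "
                f"{[b.block_id for b in hits]}"
            )
        p.block_id = hits[0].block_id if hits else p.block_id
    return pairs


def block_mean_ks(
    pairs: list[GametologPair], blocks: list[SyntenyBlock]
) -> tuple[list[SyntenyBlock], list[str]]:
    """Arithmetic mean Ks per block over member pairs (undefined Ks excluded).

    Pairs are matched to blocks by ``block_id`` (use :func:`assign_blocks`
    first when only positions are known). Returns the filled blocks plus the
    block ranking by mean Ks, highest (oldest) first.
    """
    by_block: dict[str, list[float]] = {b.block_id: [] for b in blocks}
    counts: dict[str, int] = {b.block_id: 0 for b in blocks}
    for p in pairs:
        if p.block_id is None or p.block_id not in by_block:
            continue
        counts[p.block_id] += 1
        if p.rates is None:
            p.estimate()
        if p.ks is not None:
            by_block[p.block_id].append(p.ks)
    for b in blocks:
        b.n_pairs = counts[b.block_id]
        vals = by_block[b.block_id]
        b.mean_ks = float(np.mean(vals)) if vals else None
    ranking = [
        b.block_id
        for b in sorted(
            (b for b in blocks if b.mean_ks is not None),
            key=lambda b: b.mean_ks,
            reverse=True,
        )
    ]
    return blocks, ranking


def _segment_sse(values: list[float | None]) -> float:
    defined = [v for v in values if v is not None]
    if not defined:
        return 0.0
    m = sum(defined) / len(defined)
    return sum((v - m) ** 2 for v in defined)


def _dp_partition(values: list[float | None], m: int) -> tuple[list[int], float]:
    """Optimal partition of ordered values into m contiguous segments.

    Minimizes total within-segment sum of squares over defined values.
    Returns (boundaries, cost) where boundaries are segment start indices
    (first is always 0).
    """
    n = len(values)
    if not (1 <= m <= n):
        raise ValueError(f"cannot split {n} blocks into {m} segments")
    sse = [[0.0] * (n + 1) for _ in range(n + 1)]
    for i in range(n):
        for j in range(i + 1, n + 1):
            sse[i][j] = _segment_sse(values[i:j])
    INF = float("inf")
    cost = [[INF] * (m + 1) for _ in range(n + 1)]
    back = [[0] * (m + 1) for _ in range(n + 1)]
    cost[0][0] = 0.0
    for j in range(1, n + 1):
        for k in range(1, min(j, m) + 1):
            for i in range(k - 1, j):
                c = cost[i][k - 1] + sse[i][j]
                if c < cost[j][k] - 1e-15:
                    cost[j][k] = c
                    back[j][k] = i
    bounds = []
    j, k = n, m
    while k > 0:
        i = back[j][k]
        bounds.append(i)
        j, k = i, k - 1
    return sorted(bounds), cost[n][m]


def _choose_m_elbow(values: list[float | None], m_max: int) -> int:
    """Pick the segment count at the elbow of the DP cost curve."""
    n = len(values)
    m_max = min(m_max, n)
    costs = [_dp_partition(values, m)[1] for m in range(1, m_max + 1)]
    if costs[0] < 1e-12:  # already homogeneous: one segment
        return 1
    if len(costs) <= 2:
        return len(costs)
    # elbow = largest drop in marginal gain (max second difference)
    best_m, best_curv = 1, -float("inf")
    for i in range(1, len(costs) - 1):
        curv = (costs[i - 1] - costs[i]) - (costs[i] - costs[i + 1])
        if curv > best_curv:
            best_curv, best_m = curv, i + 1
    return best_m


def _collapse_levels(seg_means: list[float], k_levels: int) -> list[int]:
    """Group segment means into k levels by splitting at the largest gaps.

    Returns, per segment, its level rank: 0 = highest-mean (oldest) level.
    """
    order = sorted(range(len(seg_means)), key=lambda i: seg_means[i], reverse=True)
    k = min(k_levels, len(seg_means))
    gaps = [
        (seg_means[order[i]] - seg_means[order[i + 1]], i)
        for i in range(len(order) - 1)
    ]
    cut_after = {i for _, i in sorted(gaps, reverse=True)[: k - 1]}
    levels = [0] * len(seg_means)
    level = 0
    for rank, idx in enumerate(order):
        levels[idx] = level
        if rank in cut_after:
            level += 1
    return levels


def segment_strata(
    blocks: list[SyntenyBlock],
    k_levels: int = 2,
    anchors: set[str] | None = None,
    n_segments: int | None = None,
    ks_offsets: dict[str, float] | None = None,
) -> list[Stratum]:
    """Segment ordered synteny blocks into evolutionary strata.

    Blocks (sorted by Y interval) are partitioned into contiguous segments
    by dynamic programming minimizing the within-segment variance of block
    mean Ks; segment means are then collapsed into ``k_levels`` divergence
    levels (split at the largest gaps between sorted means) and labelled
    "1" (oldest = highest Ks) downwards, with positional suffixes ("2-1",
    "2-2") when one level holds several segments.

    ``anchors`` names a contiguous run of blocks forced to be their own
    segment and assigned to the oldest level regardless of their Ks — the
    structural-variation / fusion-point override. ``ks_offsets`` adds a
    recorded per-block adjustment to mean Ks before segmentation (no silent
    adjustment). ``n_segments`` overrides the data-driven segment count
    (default: flank|anchor|flank structure when anchors are given, else the
    elbow of the DP cost curve).
    """
    if not blocks:
        return []
    blocks = sorted(blocks, key=lambda b: (b.y_interval.start, b.y_interval.end))
    for a, b in zip(blocks, blocks[1:]):
        if a.y_interval.overlap(b.y_interval):
            raise ValueError(f"blocks {a.block_id} and {b.block_id} overlap on Y")
    values = [
        None if b.mean_ks is None
        else b.mean_ks + (ks_offsets or {}).get(b.block_id, 0.0)
        for b in blocks
    ]
    n_defined = sum(v is not None for v in values)
    if k_levels > n_defined:
        raise ValueError(
            f"k_levels={k_levels} exceeds blocks with defined mean Ks ({n_defined})"
        )
    ids = [b.block_id for b in blocks]
    anchor_idx: list[int] = []
    if anchors:
        missing = set(anchors) - set(ids)
        if missing:
            raise ValueError(f"anchor blocks not found: {sorted(missing)}")
        anchor_idx = sorted(i for i, bid in enumerate(ids) if bid in anchors)
        if anchor_idx != list(range(anchor_idx[0], anchor_idx[-1] + 1)):
            raise ValueError("anchor blocks must form a contiguous run")

    n = len(blocks)
    if anchor_idx:
        lo, hi = anchor_idx[0], anchor_idx[-1] + 1
        left, right = values[:lo], values[hi:]
        if n_segments is None:
            m_left = 1 if left else 0
            m_right = 1 if right else 0
        else:
            extra = n_segments - 1 - (1 if left else 0) - (1 if right else 0)
            if extra < 0:
                raise ValueError("n_segments too small for the anchor structure")
            # give extra segments to the longer flank first
            m_left = (1 if left else 0)
            m_right = (1 if right else 0)
            for _ in range(extra):
                if len(left) - m_left >= len(right) - m_right and len(left) > m_left:
                    m_left += 1
                elif len(right) > m_right:
                    m_right += 1
        seg_bounds = {lo}
        if left and m_left:
            seg_bounds |= set(_dp_partition(left, m_left)[0])
        if right and m_right:
            seg_bounds |= {hi + b for b in _dp_partition(right, m_right)[0]}
        if hi < n:
            seg_bounds.add(hi)
        seg_bounds = sorted(b for b in seg_bounds | {0} if b < n)
    else:
        if n_segments is None:
            n_segments = _choose_m_elbow(values, m_max=max(k_levels + 2, 3))
            n_segments = max(n_segments, min(k_levels, n))
        seg_bounds = _dp_partition(values, n_segments)[0]

    seg_bounds = sorted(set(seg_bounds))
    segments = [
        (s, e) for s, e in zip(seg_bounds, seg_bounds[1:] + [n])
    ]
    seg_means = []
    for s, e in segments:
        defined = [v for v in values[s:e] if v is not None]
        seg_means.append(sum(defined) / len(defined) if defined else -math.inf)
    levels = _collapse_levels(seg_means, k_levels)
    if anchor_idx:
        anchor_seg = next(
            i for i, (s, e) in enumerate(segments) if s <= anchor_idx[0] < e
        )
        levels[anchor_seg] = -1  # force oldest; re-rank below
    # re-rank levels to consecutive 0..k-1 preserving order (anchor first)
    uniq = sorted(set(levels))
    remap = {lv: i for i, lv in enumerate(uniq)}
    levels = [remap[lv] for lv in levels]

    # labels: "<level+1>" or "<level+1>-<j>" positionally within a level
    per_level_count: dict[int, int] = {}
    for lv in levels:
        per_level_count[lv] = per_level_count.get(lv, 0) + 1
    per_level_seen: dict[int, int] = {lv: 0 for lv in per_level_count}
    strata: list[Stratum] = []
    for (s, e), lv in zip(segments, levels):
        per_level_seen[lv] += 1
        if per_level_count[lv] == 1:
            label = str(lv + 1)
        else:
            label = f"{lv + 1}-{per_level_seen[lv]}"
        members = blocks[s:e]
        n_pairs = sum(b.n_pairs for b in members)
        weighted = [
            (b.mean_ks, b.n_pairs) for b in members
            if b.mean_ks is not None and b.n_pairs > 0
        ]
        tot = sum(w for _, w in weighted)
        mean_ks = sum(v * w for v, w in weighted) / tot if tot else None
        strata.append(
            Stratum(
                label=label,
                block_ids=[b.block_id for b in members],
                y_interval=GenomicInterval(
                    members[0].y_interval.chrom,
                    members[0].y_interval.start,
                    members[-1].y_interval.end,
                ),
                n_pairs=n_pairs,
                mean_ks=mean_ks,
            )
        )
    return strata


def pairs_to_frame(pairs: list[GametologPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        r = p.rates
        rows.append(
            {
                "pair_id": p.pair_id,
                "block_id": p.block_id,
                "y_position": p.y_position,
                "ks": r.ks if r and r.ks_defined else None,
                "ka": r.ka if r and r.ka_defined else None,
                "ps": r.ps if r else None,
                "pn": r.pn if r else None,
                "s_sites": r.s_sites if r else None,
                "n_sites": r.n_sites if r else None,
                "flags": "" if (r and r.ks_defined and r.ka_defined) else "undefined",
            }
        )
    return pd.DataFrame(rows)


def strata_to_frame(strata: list[Stratum]) -> pd.DataFrame:
    from .formats_io import mb

    return pd.DataFrame(
        [
            {
                "stratum": s.label,
                "blocks": ",".join(s.block_ids),
                "start": s.y_interval.start,
                "end": s.y_interval.end,
                "start_mb": mb(s.y_interval.start),
                "end_mb": mb(s.y_interval.end),
                "n_pairs": s.n_pairs,
                "mean_ks": s.mean_ks,
            }
            for s in strata
        ]
    )
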