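"""Sliding-window detection of X-/Y-linked regions from pooled read depth.

A hemizygous (male-specific, Y-linked) region shows male pooled coverage at
about half the genome-wide average and essentially no female coverage; an
X-linked region shows normal female coverage and half-depth male coverage;
pseudoautosomal regions show balanced full coverage in both sexes. Windows
of fixed size (default 50 kb) advance by a fixed step (default 5 kb); per
window, each pool's mean depth is divided by that pool's genome-wide
normalizer, the window is classified from the two relative depths, and
maximal same-class runs are merged into region calls with flanking
pseudoautosomal regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats_io import DepthTrack, GeneRecord, GenomicInterval

WINDOW_CLASSES = ("Y_linked", "X_linked", "balanced", "ambiguous")


@dataclass
class WindowConfig:
    """Windowing and classification parameters.

    Bands are relative-depth intervals: ``y_male_band`` is the half-coverage
    band expected of a single-copy region in the male pool (and of the male
    pool over an X-linked region); ``x_female_band`` is the balanced
    full-coverage band; ``absent_max`` is the ceiling for "negligible"
    female coverage over a hemizygous region.
    """

    window: int = 50_000
    step: int = 5_000
    min_region: int = 500_000
    max_gap: int = 50_000  # bp bridged between same-class runs (10 steps)
    y_male_band: tuple[float, float] = (0.3, 0.7)
    x_female_band: tuple[float, float] = (0.75, 1.25)
    absent_max: float = 0.10

    def __post_init__(self):
        if not (0 < self.step <= self.window):
            raise ValueError("require 0 < step <= window")
        for band in (self.y_male_band, self.x_female_band):
            if not (0 <= band[0] <= band[1] <= 3):
                raise ValueError(f"band {band} outside [0, 3]")
        if not self.absent_max < self.y_male_band[0]:
            raise ValueError("absent_max must be below y_male_band.low")


@dataclass
class SLRCall:
    """One called sex-linked region with its flanking PARs."""

    slr_type: str  # {"Y", "X"}
    interval: GenomicInterval
    span_bp: int
    fraction_of_chromosome: float
    pars: list[GenomicInterval] = field(default_factory=list)
    par_total_bp: int = 0
    n_windows: int = 0
    n_genes: int | None = None
    repeat_fraction: float | None = None


def window_depths(track: DepthTrack, cfg: WindowConfig) -> pd.DataFrame:
    """Mean depth per sliding window; trailing partial window dropped.

    Window i covers [i*step, i*step + window); the window count for a
    chromosome of length L >= window is floor((L - window)/step) + 1.
    """
    L = track.length
    if L < cfg.window:
        warnings.warn(
            f"chromosome {track.chrom} ({L} bp) shorter than one window "
            f"({cfg.window} bp); empty window table"
        )
        return pd.DataFrame(columns=["chrom", "start", "end", "mean_depth"])
    n = (L - cfg.window) // cfg.step + 1
    starts = np.arange(n, dtype=np.int64) * cfg.step
    ends = starts + cfg.window
    sums = track._cum_at(ends) - track._cum_at(starts)
    return pd.DataFrame(
        {
            "chrom": track.chrom,
            "start": starts,
            "end": ends,
            "mean_depth": sums / cfg.window,
        }
    )


def build_window_table(
    male: DepthTrack, female: DepthTrack, cfg: WindowConfig
) -> pd.DataFrame:
    """Joint male/female window means on one chromosome."""
    if male.chrom != female.chrom or male.length != female.length:
        raise ValueError("male and female tracks must cover the same chromosome")
    m = window_depths(male, cfg)
    f = window_depths(female, cfg)
    out = m.rename(columns={"mean_depth": "male_depth"})
    out["female_depth"] = f["mean_depth"].to_numpy() if len(f) else []
    return out


def _normalizer(values: np.ndarray, how: str) -> float:
    if how == "median":
        return float(np.median(values))
    if how == "mean":
        return float(np.mean(values))
    raise ValueError(f"unknown normalizer {how!r}")


def normalize(
    table: pd.DataFrame,
    normalizer: str = "median",
    exclude: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Add ``male_rel``/``female_rel``: depth over the pool's genome-wide normalizer.

    The normalizer for each pool is computed over windows that do not overlap
    any ``exclude`` interval (e.g. a provisional SLR, which would otherwise
    depress the pool mean). Normalizer values are recorded in ``df.attrs``.
    """
    out = table.copy()
    keep = np.ones(len(out), dtype=bool)
    for iv in exclude or []:
        keep &= ~(
            (out["chrom"] == iv.chrom)
            & (out["start"].to_numpy() < iv.end)
            & (out["end"].to_numpy() > iv.start)
        )
    if not keep.any():
        raise ValueError("no windows left outside the excluded intervals")
    norms = {}
    for pool in ("male", "female"):
        norm = _normalizer(out.loc[keep, f"{pool}_depth"].to_numpy(), normalizer)
        if norm == 0:
            raise ValueError(f"{pool} normalizer is zero (empty pool?)")
        out[f"{pool}_rel"] = out[f"{pool}_depth"] / norm
        norms[pool] = norm
    out.attrs["normalizer"] = normalizer
    out.attrs["normalizer_values"] = norms
    return out


def classify_windows(table: pd.DataFrame, cfg: WindowConfig) -> pd.DataFrame:
    """Assign each window exactly one class from its two relative depths.

    Y_linked: male in the half-coverage band, female negligible.
    X_linked: female in the balanced band, male in the half-coverage band.
    balanced: both pools in the balanced band. Anything else: ambiguous.
    """
    out = table.copy()
    m = out["male_rel"].to_numpy()
    f = out["female_rel"].to_numpy()
    ylo, yhi = cfg.y_male_band
    xlo, xhi = cfg.x_female_band
    male_half = (m >= ylo) & (m <= yhi)
    male_full = (m >= xlo) & (m <= xhi)
    female_full = (f >= xlo) & (f <= xhi)
    cls = np.full(len(out), "ambiguous", dtype=object)
    cls[male_half & (f <= cfg.absent_max)] = "Y_linked"
    cls[male_half & female_full] = "X_linked"
    cls[male_full & female_full] = "balanced"
    out["window_class"] = cls
    return out


def call_regions(
    labeled: pd.DataFrame, cfg: WindowConfig, chrom_length: int
) -> list[SLRCall]:
    """Merge same-class window runs into SLR calls; report flanking PARs.

    Interior gaps of other-class windows up to ``max_gap`` bp are bridged;
    merged regions shorter than ``min_region`` are dropped. A region's
    interval is the union of its member windows (outermost edges). The
    remaining chromosome, outside all calls, is reported as PARs attached to
    every call.
    """
    if not labeled["start"].is_monotonic_increasing:
        raise ValueError("windows must be sorted by start")
    calls: list[SLRCall] = []
    for wclass, slr_type in (("Y_linked", "Y"), ("X_linked", "X")):
        rows = labeled[labeled["window_class"] == wclass]
        if rows.empty:
            continue
        starts = rows["start"].to_numpy()
        ends = rows["end"].to_numpy()
        run_start, run_end, run_n = starts[0], ends[0], 1
        merged: list[tuple[int, int, int]] = []
        for s, e in zip(starts[1:], ends[1:]):
            if s - run_end <= cfg.max_gap:
                run_end = max(run_end, e)
                run_n += 1
            else:
                merged.append((run_start, run_end, run_n))
                run_start, run_end, run_n = s, e, 1
        merged.append((run_start, run_end, run_n))
        chrom = str(labeled["chrom"].iloc[0])
        for s, e, n in merged:
            if e - s < cfg.min_region:
                continue
            calls.append(
                SLRCall(
                    slr_type=slr_type,
                    interval=GenomicInterval(chrom, int(s), int(e)),
                    span_bp=int(e - s),
                    fraction_of_chromosome=(e - s) / chrom_length,
                    n_windows=n,
                )
            )
    calls.sort(key=lambda c: c.interval.start)
    for a, b in zip(calls, calls[1:]):
        if a.interval.overlap(b.interval) and a.slr_type != b.slr_type:
            raise ValueError(
                "overlapping Y and X calls on one haplotype — inconsistent input"
            )
    # PARs: chromosome complement of all calls
    pars: list[GenomicInterval] = []
    cursor = 0
    chrom = str(labeled["chrom"].iloc[0]) if len(labeled) else "?"
    for c in calls:
        if c.interval.start > cursor:
            pars.append(GenomicInterval(chrom, cursor, c.interval.start))
        cursor = max(cursor, c.interval.end)
    if cursor < chrom_length:
        pars.append(GenomicInterval(chrom, cursor, chrom_length))
    if not calls and len(labeled):
        # no SLR: the whole chromosome is one pseudoautosomal/balanced block
        pars = [GenomicInterval(chrom, 0, chrom_length)]
    par_total = sum(len(p) for p in pars)
    for c in calls:
        c.pars = pars
        c.par_total_bp = par_total
    if not calls:
        return [
            SLRCall(
                slr_type="none",
                interval=GenomicInterval(chrom, 0, chrom_length),
                span_bp=0,
                fraction_of_chromosome=0.0,
                pars=pars,
                par_total_bp=par_total,
            )
        ] if len(labeled) else []
    return calls


def detect_slr(
    male: DepthTrack,
    female: DepthTrack,
    cfg: WindowConfig | None = None,
    normalizer: str = "median",
) -> tuple[list[SLRCall], pd.DataFrame]:
    """Two-pass SLR detection on one chromosome.

    Pass 1 normalizes over all windows to get provisional calls; pass 2
    recomputes the normalizer excluding provisional SLR windows (which would
    bias a mean normalizer downward) and re-calls. Returns (calls, labeled
    window table).
    """
    cfg = cfg or WindowConfig()
    table = build_window_table(male, female, cfg)
    if table.empty:
        return [], table
    labeled = classify_windows(normalize(table, normalizer), cfg)
    provisional = [
        c.interval for c in call_regions(labeled, cfg, male.length) if c.slr_type != "none"
    ]
    if provisional:
        labeled = classify_windows(
            normalize(table, normalizer, exclude=provisional), cfg
        )
    calls = call_regions(labeled, cfg, male.length)
    return calls, labeled


def repeat_fraction(
    interval: GenomicInterval, repeats: list[GenomicInterval]
) -> float:
    """Fraction of ``interval`` covered by the union of ``repeats``.

    Overlapping repeat records are unioned before intersecting, so no base
    is counted twice.
    """
    if len(interval) == 0:
        raise ValueError("interval has length 0")
    clipped = sorted(
        (max(r.start, interval.start), min(r.end, interval.end))
        for r in repeats
        if r.chrom == interval.chrom and r.start < interval.end and r.end > interval.start
    )
    covered = 0
    cur_s, cur_e = None, None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered / len(interval)


def annotate_calls(
    calls: list[SLRCall],
    genes: list[GeneRecord] | None = None,
    repeats: list[GenomicInterval] | None = None,
) -> list[SLRCall]:
    """Fill ``n_genes`` (gene midpoint within the call) and ``repeat_fraction``."""
    for c in calls:
        if c.slr_type == "none":
            continue
        if genes is not None:
            c.n_genes = sum(
                1
                for g in genes
                if g.interval.chrom == c.interval.chrom
                and c.interval.contains(g.interval.midpoint)
            )
        if repeats is not None:
            c.repeat_fraction = repeat_fraction(c.interval, repeats)
    return calls


def calls_to_frame(calls: list[SLRCall]) -> pd.DataFrame:
    """Tabular report of calls (full-precision bp plus 2-dp Mb columns)."""
    from .formats_io import mb

    rows = []
    for c in calls:
        rows.append(
            {
                "chrom": c.interval.chrom,
                "type": c.slr_type,
                "start": c.interval.start,
                "end": c.interval.end,
                "span_bp": c.span_bp,
                "span_mb": mb(c.span_bp),
                "fraction": round(c.fraction_of_chromosome, 4),
                "par_total_bp": c.par_total_bp,
                "par_total_mb": mb(c.par_total_bp),
                "n_genes": c.n_genes,
                "repeat_fraction": c.repeat_fraction,
            }
        )
    return pd.DataFrame(rows)
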