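"""Truth-labelled synthetic datasets with the structure the pipeline assumes.

The generator emulates, at desk scale, the observable signatures the
analysis inverts:

* pooled read depth — Poisson counts at a configurable tile resolution with
  copy number 2 on autosomal/pseudoautosomal segments for both sexes; a
  planted Y-linked region is hemizygous (male copy 1, female 0) and a
  planted X-linked region has male copy 1, female 2; a mismapping leak
  ``mismap_rate`` adds a small depth floor so "absent" is never exactly 0;
* gametolog codon pairs — stop-free CDSs built from fourfold-degenerate
  codon families so that every codon carries exactly one synonymous site;
  third positions are substituted per-site Bernoulli with the JC69-inverted
  probability p = 3/4 (1 - exp(-4 Ks / 3)), making the realized NG86
  synonymous divergence unbiased for the target Ks;
* gene trees realizing the ancestral / recent / chaotic topology patterns;
* TPM matrices with planted male-specific genes.

Every generator is deterministic given the config seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .formats_io import DepthTrack, GenomicInterval
from .ks_strata import GametologPair, SyntenyBlock

KS_SATURATION = 0.75  # JC69 expected proportion approaches 3/4

# fourfold-degenerate codon family prefixes (third position always synonymous,
# first/second positions never synonymous, no stop codons in the family)
FOURFOLD_PREFIXES = ("TC", "CC", "AC", "GC", "GT", "GG")


@dataclass
class SimConfig:
    """Study conditions for the synthetic datasets.

    Defaults mirror the study design the pipeline targets: pooled depth
    around 30x with a small mismapping leak, one Mb-scale hemizygous region
    on a single chromosome, per-stratum gametolog divergences at the
    published stratum means, and an 11-gene male-specific set among a few
    hundred Y-region genes.
    """

    chrom: str = "Chr02"
    chrom_length: int = 12_000_000
    slr_start: int = 3_000_000
    slr_end: int = 7_500_000
    slr_type: str = "Y"
    mean_depth: float = 30.0
    mismap_rate: float = 0.02
    depth_tile_bp: int = 1_000
    # strata in chromosome order: young | old (anchored) | young
    stratum_labels: tuple = ("2-1", "1", "2-2")
    stratum_ks: tuple = (0.0574, 0.1041, 0.0418)
    n_pairs_per_stratum: tuple = (19, 43, 48)
    n_codons: int = 500
    target_ka: float = 0.01
    n_genes: int = 300
    n_male_specific: int = 11
    n_male_samples: int = 3
    n_female_samples: int = 3
    male_tpm_floor: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if not (0 <= self.mismap_rate < 0.1):
            raise ValueError("mismap_rate must be in [0, 0.1)")
        if not (0 <= self.slr_start < self.slr_end <= self.chrom_length):
            raise ValueError("slr interval must lie inside [0, chrom_length)")
        if self.slr_type not in ("Y", "X"):
            raise ValueError("slr_type must be Y or X")
        for ks in self.stratum_ks:
            if not (0 <= ks < 0.74):
                raise ValueError(f"stratum Ks {ks} outside the JC69 domain [0, 0.74)")
        if len(self.stratum_ks) != len(self.n_pairs_per_stratum):
            raise ValueError("stratum_ks and n_pairs_per_stratum lengths differ")

    @property
    def slr_interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.slr_start, self.slr_end)


@dataclass
class SimTruth:
    """Ground-truth labels attached to one generated dataset."""

    slr_interval: tuple | None = None  # (chrom, start, end, type)
    gene_origins: dict = field(default_factory=dict)  # gene_id -> category
    pair_truth: dict = field(default_factory=dict)  # pair_id -> {ks, stratum}
    tree_patterns: dict = field(default_factory=dict)  # gene_group_id -> pattern
    male_specific_genes: list = field(default_factory=list)
    final_candidates: list = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=str)


def _rng(cfg_or_seed) -> np.random.Generator:
    seed = cfg_or_seed.seed if isinstance(cfg_or_seed, SimConfig) else cfg_or_seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Depth tracks
# ---------------------------------------------------------------------------

def simulate_depth_tracks(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DepthTrack, DepthTrack, SimTruth]:
    """Male and female pooled depth tracks with one planted SLR.

    Depth is drawn one Poisson value per ``depth_tile_bp`` tile with mean
    copy_number/2 * mean_depth + mismap_rate * mean_depth and held constant
    across the tile.
    """
    rng = rng or _rng(cfg)
    n_tiles = math.ceil(cfg.chrom_length / cfg.depth_tile_bp)
    edges = np.minimum(
        np.arange(n_tiles + 1, dtype=np.int64) * cfg.depth_tile_bp, cfg.chrom_length
    )
    mid = (edges[:-1] + edges[1:]) / 2
    in_region = (mid >= cfg.slr_start) & (mid < cfg.slr_end)

    copy_m = np.where(in_region, 1.0, 2.0)
    copy_f = np.where(in_region, 0.0 if cfg.slr_type == "Y" else 2.0, 2.0)
    leak = cfg.mismap_rate * cfg.mean_depth

    tracks = []
    for copy, label in ((copy_m, "male"), (copy_f, "female")):
        mean = copy / 2.0 * cfg.mean_depth + np.where(copy == 0, leak, 0.0)
        # the mismapping leak applies only where the pool has no true copy;
        # elsewhere true coverage dominates and the leak is absorbed in λ
        vals = rng.poisson(mean)
        dense_rle = _tiles_to_track(cfg.chrom, edges, vals, label)
        tracks.append(dense_rle)
    truth = SimTruth(
        slr_interval=(cfg.chrom, cfg.slr_start, cfg.slr_end, cfg.slr_type)
    )
    return tracks[0], tracks[1], truth


def _tiles_to_track(chrom, edges, vals, label) -> DepthTrack:
    vals = np.asarray(vals, dtype=np.int64)
    change = np.flatnonzero(np.diff(vals)) + 1
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(vals)]])
    starts = edges[run_starts]
    ends = edges[run_ends]
    depths = vals[run_starts]
    keep = depths != 0
    return DepthTrack(chrom, int(edges[-1]), starts[keep], ends[keep],
                      depths[keep], label)


# ---------------------------------------------------------------------------
# Gametolog codon pairs
# ---------------------------------------------------------------------------

def jc69_p(ks: float) -> float:
    """Expected proportion of differing sites under JC69 at distance ks."""
    if not (0 <= ks < 0.74):
        raise ValueError(f"Ks {ks} outside the JC69 domain [0, 0.74)")
    return 0.75 * (1.0 - math.exp(-4.0 * ks / 3.0))


_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def simulate_codon_pair(
    n_codons: int, ks: float, ka: float, rng: np.random.Generator
) -> tuple[str, str]:
    """One ancestral/derived CDS pair targeting per-site divergences (ks, ka).

    The ancestral CDS is built from fourfold-degenerate codon families, so
    third positions are synonymous sites (exactly one per codon) and
    first/second positions are nonsynonymous. Substitutions are applied to
    the derived copy per site with the JC69-inverted probability; a
    nonsynonymous substitution that would create a stop codon is resampled.
    """
    p_s = jc69_p(ks)
    p_a = jc69_p(ka)
    prefixes = rng.choice(len(FOURFOLD_PREFIXES), size=n_codons)
    thirds = rng.choice(4, size=n_codons)
    x_codons = [
        FOURFOLD_PREFIXES[pi] + _BASES[ti] for pi, ti in zip(prefixes, thirds)
    ]
    y_codons = []
    for codon in x_codons:
        c = list(codon)
        if rng.random() < p_s:  # synonymous: third position, any other base
            c[2] = rng.choice([b for b in _BASES if b != c[2]])
        for pos in (0, 1):
            if p_a > 0 and rng.random() < p_a:
                options = [
                    b for b in _BASES
                    if b != c[pos]
                    and "".join(c[:pos] + [b] + c[pos + 1:]) not in _STOPS
                ]
                if options:
                    c[pos] = rng.choice(options)
        y_codons.append("".join(c))
    return "".join(x_codons), "".join(y_codons)


def simulate_gametolog_pairs(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GametologPair], list[SyntenyBlock], SimTruth]:
    """Gametolog pairs per stratum, laid along the planted SLR.

    Each stratum occupies an equal share of the SLR, holds one synteny block
    by default, and its pairs' Y positions are spread evenly within it.
    """
    rng = rng or _rng(cfg)
    truth = SimTruth()
    pairs: list[GametologPair] = []
    blocks: list[SyntenyBlock] = []
    n_strata = len(cfg.stratum_ks)
    span = cfg.slr_end - cfg.slr_start
    for i, (label, ks, n) in enumerate(
        zip(cfg.stratum_labels, cfg.stratum_ks, cfg.n_pairs_per_stratum)
    ):
        lo = cfg.slr_start + round(i * span / n_strata)
        hi = cfg.slr_start + round((i + 1) * span / n_strata)
        block_id = f"blk_{label}"
        blocks.append(
            SyntenyBlock(block_id, GenomicInterval(cfg.chrom, lo, hi))
        )
        for j in range(n):
            x_seq, y_seq = simulate_codon_pair(cfg.n_codons, ks, cfg.target_ka, rng)
            pid = f"pair_{label}_{j:03d}"
            pos = lo + (j + 0.5) / n * (hi - lo)
            pairs.append(
                GametologPair(pid, x_seq, y_seq, y_position=pos, block_id=block_id)
            )
            truth.pair_truth[pid] = {"ks": ks, "stratum": label}
    return pairs, blocks, truth


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

def _random_resolved_newick(leaves: list[str], rng: np.random.Generator) -> str:
    """Random fully-resolved subtree over the given leaf names (no ';')."""
    nodes = list(leaves)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        bl1, bl2 = rng.uniform(0.01, 0.2, size=2)
        nodes.append(f"({a}:{bl1:.4f},{b}:{bl2:.4f})")
    return nodes[0]


def simulate_gene_trees(
    n_per_pattern: dict[str, int],
    species: list[str],
    rng: np.random.Generator | int | None = None,
    outgroup: str | None = "out",
    max_tries: int = 2000,
) -> tuple[list, SimTruth]:
    """Labeled trees realizing the requested topology patterns.

    ancestral: all X leaves form a clade and all Y leaves form a clade;
    recent: each species' {X, Y} pair forms a clade; chaotic: rejection
    sampling of random topologies satisfying neither. Raises if a requested
    pattern cannot be realized for the given species set.
    """
    from .formats_io import read_labeled_tree
    from .gametolog_trees import classify_topology

    if len(species) < 2:
        raise ValueError("need >= 2 ingroup species")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x_leaves = [f"{sp}|X" for sp in species]
    y_leaves = [f"{sp}|Y" for sp in species]
    trees = []
    truth = SimTruth()
    counter = 0
    for pattern, n in n_per_pattern.items():
        if pattern not in ("ancestral", "recent", "chaotic"):
            raise ValueError(f"unknown pattern {pattern!r}")
        for _ in range(n):
            if pattern == "ancestral":
                core = (
                    f"({_random_resolved_newick(x_leaves, rng)}:0.05,"
                    f"{_random_resolved_newick(y_leaves, rng)}:0.05)"
                )
            elif pattern == "recent":
                cherries = [
                    f"({sp}|X:0.02,{sp}|Y:0.02)" for sp in species
                ]
                core = _random_resolved_newick(cherries, rng)
            else:
                core = None
                for _try in range(max_tries):
                    cand = _random_resolved_newick(x_leaves + y_leaves, rng)
                    lt = read_labeled_tree(f"{cand};")
                    if classify_topology(lt) == "chaotic":
                        core = cand
                        break
                if core is None:
                    raise ValueError(
                        f"cannot realize a chaotic topology for species {species}"
                    )
            if outgroup:
                newick = f"({core}:0.05,{outgroup}|A:0.3);"
            else:
                newick = f"{core};"
            gid = f"tree_{pattern}_{counter:03d}"
            counter += 1
            lt = read_labeled_tree(newick, gene_group_id=gid)
            trees.append(lt)
            truth.tree_patterns[gid] = pattern
    return trees, truth


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def simulate_expression(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """TPM matrix (genes x samples) with planted male-specific genes.

    Background genes are log-normally expressed in every bud sample of both
    sexes (floored at 1 TPM); planted male-specific genes sit above
    ``male_tpm_floor`` in all male bud samples and below 0.1 TPM in female
    samples. Columns are renormalized to sum to 1e6. Returns (tpm, sample
    metadata, truth).
    """
    rng = rng or _rng(cfg)
    if cfg.n_male_samples < 1 or cfg.n_female_samples < 1:
        raise ValueError("need >= 1 male and >= 1 female sample")
    genes = [f"g{i:04d}" for i in range(cfg.n_genes)]
    male_cols = [f"male_bud_{i + 1}" for i in range(cfg.n_male_samples)]
    female_cols = [f"female_bud_{i + 1}" for i in range(cfg.n_female_samples)]
    cols = male_cols + female_cols
    target_total = 1e6
    # background log-normal centred so the raw column total is near 1e6
    mu = math.log(target_total / cfg.n_genes) - 0.5
    raw = rng.lognormal(mean=mu, sigma=1.0, size=(cfg.n_genes, len(cols)))
    raw = np.maximum(raw, 1.0)
    ms_idx = rng.choice(cfg.n_genes, size=cfg.n_male_specific, replace=False)
    ms_idx.sort()
    for i in ms_idx:
        raw[i, : cfg.n_male_samples] = cfg.male_tpm_floor * rng.uniform(
            1.0, 10.0, size=cfg.n_male_samples
        )
        noise = rng.uniform(0.0, 0.04, size=cfg.n_female_samples)
        raw[i, cfg.n_male_samples:] = np.where(
            rng.random(cfg.n_female_samples) < 0.5, 0.0, noise
        )
    tpm = raw * (target_total / raw.sum(axis=0, keepdims=True))
    df = pd.DataFrame(tpm, index=genes, columns=cols)
    df.index.name = "gene_id"
    meta = pd.DataFrame(
        {
            "sample": cols,
            "sex": ["male"] * cfg.n_male_samples + ["female"] * cfg.n_female_samples,
            "tissue": "bud",
            "species": "simulated",
        }
    )
    truth = SimTruth(male_specific_genes=[genes[i] for i in ms_idx])
    return df, meta, truth


# ---------------------------------------------------------------------------
# Whole-study simulation
# ---------------------------------------------------------------------------

def simulate_study(cfg: SimConfig, out_dir) -> SimTruth:
    """Generate a complete, internally consistent study into ``out_dir``.

    Writes depth tracks, a gene annotation, repeat intervals, homology and
    paralog tables realizing known origin categories, gametolog pair
    sequences with block coordinates, per-gene gametolog trees, a TPM
    matrix with planted male-specific genes, screen attribute tables, and a
    ``truth.json`` sidecar with every planted label.

    The planted screen narrative: of the male-specific genes, 5 lack a
    congener homolog; of the rest, 2 carry an X-SLR homolog with a recent
    (species-pairing) topology, one carries an X-SLR homolog with the
    ancestral topology, and the remainder are autosomal duplicates without
    X homologs; the final candidates are the selected genes lying in the
    oldest stratum.
    """
    import os

    from .formats_io import (
        GeneRecord,
        HomologyHit,
        write_bed_intervals,
        write_depth_track,
        write_gff3_genes,
        write_homology_table,
        write_labeled_tree,
        write_pair_fasta,
    )

    os.makedirs(out_dir, exist_ok=True)
    os.makedirs(os.path.join(out_dir, "trees"), exist_ok=True)
    rng = _rng(cfg)
    truth = SimTruth(
        slr_interval=(cfg.chrom, cfg.slr_start, cfg.slr_end, cfg.slr_type)
    )

    # --- depth ---
    male, female, _ = simulate_depth_tracks(cfg, rng)
    write_depth_track(male, os.path.join(out_dir, "male.depth"), "bedgraph")
    write_depth_track(female, os.path.join(out_dir, "female.depth"), "bedgraph")
    with open(os.path.join(out_dir, "genome_lengths.tsv"), "w") as fh:
        fh.write(f"{cfg.chrom}\t{cfg.chrom_length}\n")

    # --- genes: one third inside the SLR, the rest in the PARs ---
    n_slr = max(cfg.n_male_specific + 9, cfg.n_genes // 3)
    n_par = cfg.n_genes - n_slr
    genes: list[GeneRecord] = []
    slr_span = cfg.slr_end - cfg.slr_start
    gene_len = 3000
    for i in range(n_slr):
        start = cfg.slr_start + 1000 + round(i * (slr_span - gene_len - 2000) / n_slr)
        genes.append(
            GeneRecord(
                f"g{i:04d}",
                GenomicInterval(cfg.chrom, start, start + gene_len, "+"),
            )
        )
    par_len = cfg.slr_start + (cfg.chrom_length - cfg.slr_end)
    for j in range(n_par):
        off = round(j * (par_len - gene_len - 2000) / max(n_par, 1)) + 1000
        if off < cfg.slr_start - gene_len - 1000:
            start = off
        else:
            start = cfg.slr_end + (off - (cfg.slr_start - gene_len - 1000))
        start = min(start, cfg.chrom_length - gene_len - 1)
        genes.append(
            GeneRecord(
                f"g{n_slr + j:04d}",
                GenomicInterval(cfg.chrom, start, start + gene_len, "+"),
            )
        )
    genes.sort(key=lambda g: g.interval.start)
    write_gff3_genes(genes, os.path.join(out_dir, "genes.gff3"))
    slr_genes = [g for g in genes if cfg.slr_interval.contains(g.interval.midpoint)]

    # --- repeats: dense inside the SLR, sparser outside ---
    repeats = []
    pos = 0
    while pos < cfg.chrom_length - 2000:
        inside = cfg.slr_start <= pos < cfg.slr_end
        rep = int(rng.integers(800, 1600)) if inside else int(rng.integers(200, 600))
        gap = int(rng.integers(100, 400)) if inside else int(rng.integers(500, 1500))
        repeats.append(
            GenomicInterval(cfg.chrom, pos, min(pos + rep, cfg.chrom_length))
        )
        pos += rep + gap
    write_bed_intervals(repeats, os.path.join(out_dir, "repeats.bed"))

    # --- origins: planted categories with noiseless evidence ---
    ancestral_chroms = {"Chr02_ancA", "Chr02_ancB"}
    syn_hits, blast_hits, paralog_pairs = [], [], []
    base_cats = ["ancestral", "acquired", "specific"]
    ordered = sorted(slr_genes, key=lambda g: g.interval.start)
    dup_every = 4  # every 4th gene becomes a duplicate of its predecessor
    for k, g in enumerate(ordered):
        if k % dup_every == 3:
            keeper = ordered[k - 1]
            paralog_pairs.append((keeper.gene_id, g.gene_id))
            truth.gene_origins[g.gene_id] = "duplicated"
            continue
        cat = base_cats[k % len(base_cats)]
        truth.gene_origins[g.gene_id] = cat
        if cat == "ancestral":
            syn_hits.append(
                HomologyHit(g.gene_id, f"anc_{g.gene_id}", "Chr02_ancA", 92.0, "synteny")
            )
        elif cat == "acquired":
            blast_hits.append(
                HomologyHit(g.gene_id, f"auto_{g.gene_id}", "Chr05", 85.0, "blast")
            )
    write_homology_table(syn_hits, os.path.join(out_dir, "synteny.tsv"))
    write_homology_table(blast_hits, os.path.join(out_dir, "blast.tsv"))
    with open(os.path.join(out_dir, "paralogs.tsv"), "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in paralog_pairs:
            fh.write(f"{a}\t{b}\n")
    with open(os.path.join(out_dir, "ancestral_chroms.txt"), "w") as fh:
        fh.write("\n".join(sorted(ancestral_chroms)) + "\n")

    # --- gametolog pairs and blocks ---
    pairs, blocks, pair_truth = simulate_gametolog_pairs(cfg, rng)
    truth.pair_truth = pair_truth.pair_truth
    write_pair_fasta(
        {p.pair_id: {"X": p.x_seq, "Y": p.y_seq} for p in pairs},
        os.path.join(out_dir, "pairs.fasta"),
    )
    with open(os.path.join(out_dir, "pairs_meta.tsv"), "w") as fh:
        fh.write("pair_id\ty_position\tblock_id\n")
        for p in pairs:
            fh.write(f"{p.pair_id}\t{p.y_position}\t{p.block_id}\n")
    with open(os.path.join(out_dir, "blocks.tsv"), "w") as fh:
        fh.write("block_id\tchrom\tstart\tend\torientation\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.y_interval.chrom}\t{b.y_interval.start}"
                f"\t{b.y_interval.end}\t{b.orientation}\n"
            )
    anchor_label = cfg.stratum_labels[
        int(np.argmax(cfg.stratum_ks))
    ]
    with open(os.path.join(out_dir, "anchors.txt"), "w") as fh:
        fh.write(f"blk_{anchor_label}\n")

    # --- screen narrative ---
    strata_bounds = []
    n_strata = len(cfg.stratum_ks)
    for i, lab in enumerate(cfg.stratum_labels):
        lo = cfg.slr_start + round(i * slr_span / n_strata)
        hi = cfg.slr_start + round((i + 1) * slr_span / n_strata)
        strata_bounds.append((lab, lo, hi))
    anchor_iv = next((lo, hi) for lab, lo, hi in strata_bounds if lab == anchor_label)
    young_iv = next(
        (lo, hi) for lab, lo, hi in strata_bounds if lab != anchor_label
    )

    def genes_in(lo, hi):
        return [g for g in slr_genes if lo <= g.interval.midpoint < hi]

    in_anchor = genes_in(*anchor_iv)
    in_young = genes_in(*young_iv)
    n_ms = cfg.n_male_specific
    # roles: 1 ancestral-route + 2 duplication-route in the old stratum,
    # 1 duplication-route in a young stratum, 2 recent-topology drops,
    # the rest lack a congener homolog
    picks_anchor = [g.gene_id for g in in_anchor[:3]]
    picks_young = [g.gene_id for g in in_young[:3]]
    roles: dict[str, str] = {}
    if len(picks_anchor) >= 3 and len(picks_young) >= 3 and n_ms >= 7:
        roles[picks_anchor[0]] = "ancestral_route"
        roles[picks_anchor[1]] = "dup_route"
        roles[picks_anchor[2]] = "dup_route"
        roles[picks_young[0]] = "dup_route_young"
        roles[picks_young[1]] = "recent_drop"
        roles[picks_young[2]] = "recent_drop"
        remaining = [
            g.gene_id for g in slr_genes if g.gene_id not in roles
        ][: n_ms - len(roles)]
        for gid in remaining:
            roles[gid] = "no_homolog"
    else:  # tiny configs: everything male-specific lacks a homolog
        for g in slr_genes[:n_ms]:
            roles[g.gene_id] = "no_homolog"
    ms_gene_ids = sorted(roles)
    truth.male_specific_genes = ms_gene_ids
    truth.final_candidates = sorted(
        g for g, r in roles.items() if r in ("ancestral_route", "dup_route")
    )

    homolog_rows = []
    tree_trees = []
    for gid, role in roles.items():
        has_homolog = role != "no_homolog"
        has_x = role in ("ancestral_route", "recent_drop")
        has_auto = role in ("dup_route", "dup_route_young")
        homolog_rows.append((gid, int(has_homolog), int(has_x), int(has_auto)))
        if has_x:
            pattern = "ancestral" if role == "ancestral_route" else "recent"
            trees, ttruth = simulate_gene_trees(
                {pattern: 1}, ["salicifolia", "gyantsensis"], rng
            )
            trees[0].gene_group_id = gid
            truth.tree_patterns[gid] = pattern
            tree_trees.append(trees[0])
    with open(os.path.join(out_dir, "homologs.tsv"), "w") as fh:
        fh.write(
            "gene_id\thas_gyantsensis_homolog\thas_x_slr_homolog"
            "\thas_autosomal_homolog\n"
        )
        for row in homolog_rows:
            fh.write("\t".join(str(v) for v in row) + "\n")
    for lt in tree_trees:
        write_labeled_tree(
            lt, os.path.join(out_dir, "trees", f"{lt.gene_group_id}.nwk")
        )

    # --- expression: remap simulated ids so planted = the chosen ms genes ---
    tpm, meta, _ = simulate_expression(
        SimConfig(
            n_genes=cfg.n_genes,
            n_male_specific=0,
            n_male_samples=cfg.n_male_samples,
            n_female_samples=cfg.n_female_samples,
            male_tpm_floor=cfg.male_tpm_floor,
            seed=cfg.seed,
        ),
        rng,
    )
    tpm.index = [g.gene_id for g in genes][: len(tpm)]
    male_cols = meta.loc[meta["sex"] == "male", "sample"].tolist()
    female_cols = meta.loc[meta["sex"] == "female", "sample"].tolist()
    for gid in ms_gene_ids:
        tpm.loc[gid, male_cols] = cfg.male_tpm_floor * rng.uniform(
            1.0, 10.0, size=len(male_cols)
        )
        tpm.loc[gid, female_cols] = rng.uniform(0.0, 0.04, size=len(female_cols))
    tpm = tpm * (1e6 / tpm.sum(axis=0))
    tpm.to_csv(os.path.join(out_dir, "tpm.tsv"), sep="\t")
    meta.to_csv(os.path.join(out_dir, "samples.tsv"), sep="\t", index=False)

    truth.to_json(os.path.join(out_dir, "truth.json"))
    return truth
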