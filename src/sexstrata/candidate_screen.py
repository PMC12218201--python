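"""Male-specific expression screen and the candidate-gene filter cascade.

A sex-determining gene on a young plant Y chromosome is expected to be
expressed in male flower buds and silent in female ones, to be conserved in
a second dioecious congener, and either to descend from the ancestral
gametolog pair (X and Y copies clustering by gametolog across species) or
to have been copied in from an autosome (no X-linked homolog at all).
Genes meeting all of that *and* lying in the oldest evolutionary stratum
are the final candidates.

Stages (monotone — every survivor set is nested in the previous one):

1. specificity — TPM >= tau_on in every male bud sample and <= tau_off in
   every female bud sample;
2. homolog presence — a homologous counterpart in the male congener;
3. topology — either no X-SLR homolog but an autosomal homolog
   (duplication-origin route), or an X-SLR homolog whose gametolog tree
   shows the ancestral pattern; species-pairing (recent) topologies are
   dropped;
4. stratum — survivors inside the oldest stratum are final candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

STAGES = (
    "excluded_specificity",
    "excluded_homolog",
    "excluded_topology",
    "selected",
    "final_candidate",
)

HIGH_EXPRESSION_TPM = 100.0  # "highly and specifically expressed" threshold


@dataclass
class SpecificityResult:
    male_specific: set
    flags: pd.DataFrame  # per gene: male_specific, high_expression, max TPMs
    missing: list


def male_specific_genes(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    region_genes: set,
    tau_on: float = 1.0,
    tau_off: float = 0.5,
) -> SpecificityResult:
    """Flag region genes expressed in every male bud and silent in female buds.

    ``tpm`` is genes x samples; ``meta`` carries columns sample/sex/tissue.
    Only bud samples participate. Genes absent from the matrix are listed in
    ``missing``, never silently dropped.
    """
    buds = meta[meta["tissue"] == "bud"]
    male_cols = buds.loc[buds["sex"] == "male", "sample"].tolist()
    female_cols = buds.loc[buds["sex"] == "female", "sample"].tolist()
    if not male_cols or not female_cols:
        raise ValueError("need at least one male and one female bud sample")
    present = [g for g in sorted(region_genes) if g in tpm.index]
    missing = [g for g in sorted(region_genes) if g not in tpm.index]
    sub = tpm.loc[present]
    min_male = sub[male_cols].min(axis=1)
    max_male = sub[male_cols].max(axis=1)
    max_female = sub[female_cols].max(axis=1)
    is_ms = (min_male >= tau_on) & (max_female <= tau_off)
    flags = pd.DataFrame(
        {
            "gene_id": present,
            "male_specific": is_ms.to_numpy(),
            "high_expression": (is_ms & (max_male > HIGH_EXPRESSION_TPM)).to_numpy(),
            "min_male_bud_tpm": min_male.to_numpy(),
            "max_male_bud_tpm": max_male.to_numpy(),
            "max_female_bud_tpm": max_female.to_numpy(),
        }
    )
    return SpecificityResult(
        male_specific=set(flags.loc[flags["male_specific"], "gene_id"]),
        flags=flags,
        missing=missing,
    )


def screen_cascade(
    candidates: set,
    homolog_presence: dict,
    topologies: dict,
    x_homolog: dict,
    autosome_homolog: dict,
    strata_membership: dict,
    ancient_stratum: str = "1",
) -> pd.DataFrame:
    """Apply the four-stage filter cascade to the male-specific gene set.

    All lookup tables must cover every candidate (missing entries raise,
    listing the genes). A gene flagged as having no X-SLR homolog but still
    given a tree topology is inconsistent input: warned, topology ignored.
    Returns one row per gene with all flags and ``stage_reached``.
    """
    missing: dict[str, list] = {}
    for name, table in (
        ("homolog_presence", homolog_presence),
        ("x_homolog", x_homolog),
        ("autosome_homolog", autosome_homolog),
        ("strata_membership", strata_membership),
    ):
        absent = sorted(g for g in candidates if g not in table)
        if absent:
            missing[name] = absent
    if missing:
        raise ValueError(f"candidates missing from lookup tables: {missing}")

    rows = []
    for g in sorted(candidates):
        has_homolog = bool(homolog_presence[g])
        has_x = bool(x_homolog[g])
        has_auto = bool(autosome_homolog[g])
        stratum = strata_membership[g]
        pattern = topologies.get(g)
        if not has_x and pattern is not None:
            warnings.warn(
                f"gene {g} has no X-SLR homolog but carries a tree topology; ignored"
            )
            pattern = None
        if has_x and pattern is None:
            raise ValueError(f"gene {g} has an X-SLR homolog but no topology entry")

        if not has_homolog:
            stage = "excluded_homolog"
        elif has_x:
            stage = "selected" if pattern == "ancestral" else "excluded_topology"
        else:
            stage = "selected" if has_auto else "excluded_topology"
        if stage == "selected" and stratum == ancient_stratum:
            stage = "final_candidate"
        rows.append(
            {
                "gene_id": g,
                "male_specific": True,
                "has_gyantsensis_homolog": has_homolog,
                "has_x_slr_homolog": has_x,
                "has_autosomal_homolog": has_auto,
                "topology_pattern": pattern if pattern is not None else "no_x_homolog",
                "stratum": stratum,
                "stage_reached": stage,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "male_specific",
            "has_gyantsensis_homolog",
            "has_x_slr_homolog",
            "has_autosomal_homolog",
            "topology_pattern",
            "stratum",
            "stage_reached",
        ],
    )


def run_screen(
    tpm: pd.DataFrame,
    meta: pd.DataFrame,
    region_genes: set,
    homolog_presence: dict,
    topologies: dict,
    x_homolog: dict,
    autosome_homolog: dict,
    strata_membership: dict,
    tau_on: float = 1.0,
    tau_off: float = 0.5,
    ancient_stratum: str = "1",
) -> pd.DataFrame:
    """Full screen: specificity flags for every region gene, cascade for the rest.

    Region genes failing the specificity rule get ``excluded_specificity``;
    male-specific genes carry the cascade's stage. High-expression flags are
    merged into the report.
    """
    spec = male_specific_genes(tpm, meta, region_genes, tau_on, tau_off)
    cascade = screen_cascade(
        spec.male_specific,
        homolog_presence,
        topologies,
        x_homolog,
        autosome_homolog,
        strata_membership,
        ancient_stratum,
    )
    non_ms = spec.flags.loc[~spec.flags["male_specific"], "gene_id"]
    extra = pd.DataFrame(
        {
            "gene_id": non_ms,
            "male_specific": False,
            "stage_reached": "excluded_specificity",
        }
    )
    report = pd.concat([cascade, extra], ignore_index=True)
    report = report.merge(
        spec.flags[["gene_id", "high_expression", "max_male_bud_tpm"]],
        on="gene_id",
        how="left",
    )
    return report.sort_values("gene_id", ignore_index=True)
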