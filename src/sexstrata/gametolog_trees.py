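"""Classification of gametolog gene trees into phylogenetic patterns.

For a dioecious genus where recombination stopped before speciation, X and
Y gametologs split first, so X copies of all species cluster together and Y
copies cluster together (the *ancestral* pattern). Where recombination
stopped after speciation, each species' X and Y copies are each other's
closest relatives (the *recent* pattern). Trees satisfying neither are
*chaotic*; trees where some species lacks one copy are *unclassifiable*.

Monophyly is judged on leaf sets: a set of leaves is a clade iff some
edge-induced split of the (outgroup-pruned, unrooted) tree separates it
exactly, so polytomies and paralog duplicates are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PATTERNS = ("ancestral", "recent", "chaotic", "unclassifiable")
COPY_CODES = {"X": "X", "Y": "Y", "A": "outgroup"}


class LabelingError(ValueError):
    """A leaf name that does not match the species/copy pattern."""


def parse_leaf_label(name: str, pattern: str = "SPECIES|COPY") -> tuple[str, str]:
    """Split a leaf name into (species, copy) per the label pattern.

    The default pattern splits on ``|``; the trailing field must be one of
    ``X``, ``Y`` (gametologs) or ``A`` (autosomal/outgroup copy).
    """
    if pattern != "SPECIES|COPY":
        raise ValueError(f"unsupported label pattern {pattern!r}")
    if "|" not in name:
        raise LabelingError(f"leaf {name!r} does not match SPECIES|COPY")
    species, code = name.rsplit("|", 1)
    if code not in COPY_CODES:
        raise LabelingError(
            f"leaf {name!r}: copy code {code!r} not in {sorted(COPY_CODES)}"
        )
    return species, COPY_CODES[code]


@dataclass
class LabeledTree:
    """A dendropy tree plus per-leaf (species, copy) labels."""

    tree: "object"  # dendropy.Tree
    labels: dict[str, tuple[str, str]]  # leaf name -> (species, copy)
    gene_group_id: str | None = None
    stratum: str | None = None
    y_position: float | None = None

    def leaf_names(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    def ingroup_leaves(self) -> list[str]:
        return [n for n in self.leaf_names() if self.labels[n][1] in ("X", "Y")]

    def outgroup_leaves(self) -> list[str]:
        return [n for n in self.leaf_names() if self.labels[n][1] == "outgroup"]


def _clade_sets(tree, keep: set[str], min_support: float | None) -> set[frozenset]:
    """Descendant leaf sets (restricted to ``keep``) of all internal nodes.

    Branches with support below ``min_support`` are treated as collapsed
    (their clade set is simply not trusted/emitted).
    """
    out: set[frozenset] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            continue
        if min_support is not None:
            sup = node.label
            try:
                sup_val = float(sup) if sup is not None else None
            except (TypeError, ValueError):
                sup_val = None
            if sup_val is not None and sup_val < min_support:
                continue
        leaves = frozenset(
            lf.taxon.label for lf in node.leaf_iter() if lf.taxon.label in keep
        )
        if leaves:
            out.add(leaves)
    return out


def _is_clade(s: frozenset, all_leaves: frozenset, sets: set[frozenset],
              rooted: bool) -> bool:
    if len(s) <= 1 or s == all_leaves:
        return True
    if s in sets:
        return True
    if not rooted and (all_leaves - s) in sets:
        return True
    return False


def classify_topology(lt: LabeledTree, min_support: float | None = None) -> str:
    """Classify one labeled gametolog tree.

    If an outgroup leaf is present the tree is rooted on it (clades are
    rooted clades of the pruned tree); otherwise monophyly is judged on
    unrooted bipartitions. ``min_support`` optionally collapses
    weakly-supported branches before judging.
    """
    for name in lt.leaf_names():
        if name not in lt.labels:
            raise LabelingError(f"leaf {name!r} has no species/copy label")
    ingroup = lt.ingroup_leaves()
    outgroup = lt.outgroup_leaves()
    species: dict[str, dict[str, set[str]]] = {}
    for n in ingroup:
        sp, copy = lt.labels[n]
        species.setdefault(sp, {"X": set(), "Y": set()})[copy].add(n)
    if len(species) < 2:
        return "unclassifiable"
    if any(not d["X"] or not d["Y"] for d in species.values()):
        return "unclassifiable"

    keep = frozenset(ingroup)
    rooted = bool(outgroup)
    if rooted:
        # S (ingroup-only) is a clade of the outgroup-rooted tree iff the
        # unrooted split S | rest exists, the outgroup lying in `rest`.
        # Splits of the full tree are node leaf sets under any rooting, with
        # either orientation accepted — so keep all leaves and test both
        # sides, which is exactly the unrooted check over the full leaf set.
        keep = frozenset(lt.leaf_names())
        rooted = False
    sets = _clade_sets(lt.tree, set(keep), min_support)

    x_set = frozenset(n for n in ingroup if lt.labels[n][1] == "X")
    y_set = frozenset(n for n in ingroup if lt.labels[n][1] == "Y")
    ancestral = _is_clade(x_set, keep, sets, rooted) and _is_clade(
        y_set, keep, sets, rooted
    )
    recent = all(
        _is_clade(frozenset(d["X"] | d["Y"]), keep, sets, rooted)
        for d in species.values()
    )
    # a tree of >=2 species cannot satisfy both definitions at once
    assert not (ancestral and recent), "ancestral and recent patterns coincide"
    if ancestral:
        return "ancestral"
    if recent:
        return "recent"
    return "chaotic"


def tally_by_stratum(trees: list[LabeledTree], strata: list) -> pd.DataFrame:
    """Pattern counts per stratum (rows) with an ``unassigned`` row.

    Each tree is mapped by its ``stratum`` label if set, else by containment
    of its ``y_position`` in a stratum's Y interval. Counts are conserved:
    they sum to the number of input trees.
    """
    labels = [s.label for s in strata]
    counts = {
        lab: {p: 0 for p in PATTERNS} for lab in labels + ["unassigned"]
    }
    for lt in trees:
        lab = lt.stratum
        if lab is None and lt.y_position is not None:
            hits = [s.label for s in strata if s.y_interval.contains(lt.y_position)]
            if len(hits) > 1:
                raise ValueError(
                    f"tree {lt.gene_group_id} maps to overlapping strata {hits}"
                )
            lab = hits[0] if hits else None
        if lab is None or lab not in counts:
            lab = "unassigned"
        counts[lab][classify_topology(lt)] += 1
    df = pd.DataFrame.from_dict(counts, orient="index")[list(PATTERNS)]
    df.index.name = "stratum"
    df["total"] = df.sum(axis=1)
    return df.reset_index()


def patterns_to_frame(trees: list[LabeledTree]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_group_id": lt.gene_group_id,
                "pattern": classify_topology(lt),
                "stratum": lt.stratum,
                "y_position": lt.y_position,
            }
            for lt in trees
        ]
    )
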