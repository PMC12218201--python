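"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities through different code paths than
the package (naive accumulation, exhaustive enumeration, exact rational
arithmetic) so agreement is evidence, not tautology.
"""

from fractions import Fraction
from itertools import permutations

BASES = "TCAG"

_CODON_AA = {}
_STOPS = {"TAA", "TAG", "TGA"}
_TABLE = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
_i = 0
for b1 in BASES:
    for b2 in BASES:
        for b3 in BASES:
            _CODON_AA[b1 + b2 + b3] = _TABLE[_i]
            _i += 1


def aa(codon: str) -> str:
    return _CODON_AA[codon]


def syn_sites_exact(codon: str) -> Fraction:
    """Exact NG86 synonymous site count of one sense codon."""
    total = Fraction(0)
    for pos in range(3):
        syn = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if aa(mut) == aa(codon) and mut not in _STOPS:
                syn += 1
        total += Fraction(syn, 3)
    return total


def codon_diffs_exact(c1: str, c2: str) -> tuple[Fraction, Fraction]:
    """Exact (syn, nonsyn) differences via exhaustive pathway enumeration."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return Fraction(0), Fraction(0)
    all_paths = []
    open_paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            steps.append((cur, nxt))
            if nxt in _STOPS:
                through_stop = True
            cur = nxt
        all_paths.append(steps)
        if not through_stop:
            open_paths.append(steps)
    use = open_paths or all_paths
    sd = nd = Fraction(0)
    for steps in use:
        for a, b in steps:
            if aa(a) == aa(b):
                sd += 1
            else:
                nd += 1
    return sd / len(use), nd / len(use)


def tree_splits(newick: str) -> set:
    """All non-trivial leaf-set splits of a newick tree, via dendropy's
    bipartition machinery (a different path than the package's traversal)."""
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.encode_bipartitions()
    taxa = {t.label for t in tree.taxon_namespace}
    out = set()
    for bp in tree.bipartition_encoding:
        side = {
            t.label
            for t in tree.taxon_namespace
            if bp.leafset_bitmask & tree.taxon_namespace.taxon_bitmask(t)
        }
        if 1 < len(side) < len(taxa):
            out.add(frozenset(side))
            out.add(frozenset(taxa - side))
    return out


def classify_topology_oracle(newick: str) -> str:
    """Brute-force pattern classification from raw bipartitions.

    Tests every split for the X-vs-Y separation and every species for the
    monophyly of its {X, Y} pair, on the outgroup-retained unrooted tree.
    """
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    species = {}
    ingroup = []
    for name in leaves:
        sp, code = name.rsplit("|", 1)
        if code in ("X", "Y"):
            species.setdefault(sp, set()).add(name)
            ingroup.append(name)
    if len(species) < 2:
        return "unclassifiable"
    for sp in species:
        codes = {n.rsplit("|", 1)[1] for n in species[sp]}
        if codes != {"X", "Y"}:
            return "unclassifiable"
    splits = tree_splits(newick)
    all_set = frozenset(leaves)

    def is_clade(s):
        s = frozenset(s)
        return len(s) <= 1 or s in splits or (all_set - s) in splits or s == all_set

    x_set = {n for n in ingroup if n.endswith("|X")}
    y_set = {n for n in ingroup if n.endswith("|Y")}
    if is_clade(x_set) and is_clade(y_set):
        return "ancestral"
    if all(is_clade(members) for members in species.values()):
        return "recent"
    return "chaotic"


def exhaustive_best_partition(values, m):
    """Minimum within-segment SSE over all contiguous partitions (exact)."""
    from itertools import combinations

    n = len(values)

    def sse(seg):
        vals = [v for v in seg if v is not None]
        if not vals:
            return 0.0
        mean = sum(vals) / len(vals)
        return sum((v - mean) ** 2 for v in vals)

    best = None
    for cuts in combinations(range(1, n), m - 1):
        bounds = [0, *cuts, n]
        cost = sum(sse(values[a:b]) for a, b in zip(bounds, bounds[1:]))
        if best is None or cost < best - 1e-15:
            best = cost
    return best
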