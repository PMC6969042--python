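"""Distance-based phylogenetics: Poisson-corrected NJ trees with bootstrap.

Trees are neighbor-joining (Saitou-Nei) on Poisson-corrected protein
p-distances, with a deterministic lexicographic tie-break so runs are
reproducible.  Nodal support is the Felsenstein column bootstrap: alignment
columns are resampled with replacement, trees rebuilt, and bipartition
frequencies (0-100) mapped onto the full-data tree.  Rooting is by a
designated outgroup (a non-OR rhodopsin-family GPCR in the study design).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .io import SequenceRecord


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.isfinite(m).all():
            raise ValueError("non-finite distances")
        self.matrix = m


def _encode_msa(msa: list[SequenceRecord]) -> np.ndarray:
    width = len(msa[0].seq)
    if any(len(r.seq) != width for r in msa):
        raise ValueError("ragged alignment")
    arr = np.frombuffer("".join(r.seq.upper() for r in msa).encode(), dtype=np.uint8)
    arr = arr.reshape(len(msa), width).copy()
    return arr


def protein_distance(msa: list[SequenceRecord], model: str = "poisson",
                     saturation_p: float = 0.95) -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns.

    ``model="p"`` gives raw p-distances; ``"poisson"`` applies the Poisson
    correction d = -ln(1 - p).  Saturated pairs (p >= 0.95) are flagged and
    set to the largest finite corrected distance observed.
    """
    if len(msa) < 3:
        raise ValueError("need at least 3 sequences")
    arr = _encode_msa(msa)
    is_res = (arr != ord("-")) & (arr != ord("."))
    n = len(msa)
    p = np.zeros((n, n))
    for i in range(n):
        shared = is_res[i] & is_res
        nshared = shared.sum(axis=1)
        if (nshared[np.arange(n) != i] == 0).any():
            j = int(np.flatnonzero((nshared == 0) & (np.arange(n) != i))[0])
            raise ValueError(
                f"no shared columns between {msa[i].id!r} and {msa[j].id!r}"
            )
        diff = (arr[i] != arr) & shared
        p[i] = diff.sum(axis=1) / np.maximum(nshared, 1)
    np.fill_diagonal(p, 0.0)
    if model == "p":
        d = p.copy()
        saturated = np.zeros_like(p, dtype=bool)
    elif model == "poisson":
        saturated = p >= saturation_p
        np.fill_diagonal(saturated, False)
        safe = np.where(saturated, 0.0, p)
        d = -np.log1p(-safe)
        if saturated.any():
            cap = d.max()
            d[saturated] = cap
    else:
        raise ValueError(f"unknown model {model!r}")
    d = (d + d.T) / 2
    return DistanceMatrix(labels=[r.id for r in msa], matrix=d, saturated=saturated)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic lexicographic tie-break.

    Negative branch lengths are clamped to 0 with the deficit moved to the
    sibling branch.  The returned tree is unrooted (trifurcating root).
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    D = dm.matrix.copy()
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=ns.get_taxon(lab))
        nodes.append(nd)
    names = list(labels)  # lexicographic identity of each cluster (min leaf label)

    def clamp(li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        pairs = sorted(
            (tuple(sorted((names[i], names[j]))), (i, j))
            for i, j in cand if i < j
        )
        _, (i, j) = pairs[0]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = clamp(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        newd = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newd[keep]
        D2[:-1, -1] = newd[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    root = dendropy.Node()
    if len(nodes) == 3:
        d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
        ls = [0.5 * (d01 + d02 - d12), 0.5 * (d01 + d12 - d02), 0.5 * (d02 + d12 - d01)]
        for nd, l in zip(nodes, ls):
            root.add_child(nd)
            nd.edge.length = max(l, 0.0)
    else:  # exactly 2 clusters remain (possible only for n == 2 input, guarded)
        root.add_child(nodes[0])
        nodes[0].edge.length = D[0, 1] / 2
        root.add_child(nodes[1])
        nodes[1].edge.length = D[0, 1] / 2
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def tree_from_msa(msa: list[SequenceRecord], model: str = "poisson") -> dendropy.Tree:
    return nj_tree(protein_distance(msa, model=model))


def _bipartition_keys(tree: dendropy.Tree) -> dict:
    """Map internal edges to frozenset bipartition keys (smaller side)."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    keys = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        other = leaves - below
        key = min(below, other, key=lambda s: (len(s), sorted(s)))
        keys[node] = frozenset(key)
    return keys


def bootstrap_support(msa: list[SequenceRecord], n_reps: int = 100, seed: int = 0,
                      model: str = "poisson", outgroup: str | None = None) -> dendropy.Tree:
    """Column-resampling bootstrap; supports (%) on the full-data NJ tree.

    Bipartition keys are rooting-invariant, but node->support association is
    not; if an ``outgroup`` is given the tree is rooted *before* supports are
    attached, so monophyly queries on the returned tree read correct values.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if len(msa) < 4:
        raise ValueError("bootstrap support needs at least 4 taxa")
    rng = np.random.default_rng(seed)
    full = tree_from_msa(msa, model=model)
    if outgroup is not None:
        full = root_with_outgroup(full, outgroup)
    width = len(msa[0].seq)
    counts: dict[frozenset, int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep = [SequenceRecord(id=r.id, seq="".join(r.seq[c] for c in cols),
                              alphabet="protein") for r in msa]
        rep_tree = tree_from_msa(rep, model=model)
        for key in set(_bipartition_keys(rep_tree).values()):
            counts[key] = counts.get(key, 0) + 1
    for node, key in _bipartition_keys(full).items():
        node.support = 100.0 * counts.get(key, 0) / n_reps
    return full


def nj_patristic(D: np.ndarray) -> np.ndarray:
    """Patristic (tree path) distances implied by NJ on ``D``.

    Lean numpy implementation used inside the breakpoint scan's permutation
    loop; ties break by first minimum, negative branch lengths clamp to 0
    with the deficit moved to the sibling (as in :func:`nj_tree`).
    """
    n = D.shape[0]
    if n < 3:
        raise ValueError("need at least 3 taxa")
    pat = np.zeros((n, n))
    depth = np.zeros(n)
    members: list[np.ndarray] = [np.array([i]) for i in range(n)]
    D = D.copy()

    def join(i, j, li, lj):
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        A, B = members[i], members[j]
        depth[A] += li
        depth[B] += lj
        pat[np.ix_(A, B)] = depth[A][:, None] + depth[B][None, :]
        pat[np.ix_(B, A)] = pat[np.ix_(A, B)].T
        return np.concatenate((A, B))

    while len(members) > 3:
        m = len(members)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        idx = int(Q.argmin())
        i, j = divmod(idx, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        merged = join(i, j, li, lj)
        newd = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = newd[keep]
        D2[:-1, -1] = newd[keep]
        D2[-1, -1] = 0.0
        D = D2
        members = [members[k] for k in keep] + [merged]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    ls = [max(0.5 * (d01 + d02 - d12), 0.0),
          max(0.5 * (d01 + d12 - d02), 0.0),
          max(0.5 * (d02 + d12 - d01), 0.0)]
    for a in range(3):
        depth[members[a]] += ls[a]
    for a in range(3):
        for b in range(a + 1, 3):
            A, B = members[a], members[b]
            pat[np.ix_(A, B)] = depth[A][:, None] + depth[B][None, :]
            pat[np.ix_(B, A)] = pat[np.ix_(A, B)].T
    return pat


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root on the edge leading to the outgroup leaf (support values kept)."""
    og = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup:
            og = lf
            break
    if og is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    bl = og.edge.length or 0.0
    tree.reroot_at_edge(og.edge, length1=bl / 2, length2=bl / 2,
                        update_bipartitions=False)
    tree.is_rooted = True
    return tree


def is_monophyletic(tree: dendropy.Tree, taxa_subset) -> tuple[bool, float | None]:
    """Whether the subset is exactly the leaf set of some node, and its support.

    The tree should already be rooted (e.g. with the outgroup).
    """
    want = set(taxa_subset)
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = want - leaves
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    for node in tree.preorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == want:
            return True, getattr(node, "support", None)
    return False, None


def root_to_tip_lengths(tree: dendropy.Tree) -> dict[str, float]:
    """Per-leaf root-to-tip path length (long-branch / pseudogene diagnostic)."""
    out = {}
    for lf in tree.leaf_node_iter():
        d = 0.0
        nd = lf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        out[lf.taxon.label] = d
    return out
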