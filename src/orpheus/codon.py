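"""MG94-style codon model: rate matrices, pruning likelihood, simulation.

The state space is the 61 sense codons of the standard genetic code.  Rates
for single-nucleotide changes are kappa-weighted (transition/transversion)
and scaled by a synonymous rate alpha or a nonsynonymous rate beta; the
site-wise ratio omega = beta/alpha is the dN/dS measure of selection.  Codon
frequencies are equal by default, which makes Q symmetric and lets the
likelihood machinery run on fast symmetric eigendecompositions; the
decomposition of rho*S_syn + S_nonsyn depends only on rho = alpha/beta up to
an overall scale, so per-site rate optimization reuses cached spectra.

Branch lengths are in expected substitutions per codon at omega = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

_BASES = "ACGT"
CODONS: list[str] = sorted(
    c for c in (a + b + d for a in _BASES for b in _BASES for d in _BASES)
    if c not in standard_dna_table.stop_codons
)
NCODON = len(CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
CODON_AA = np.array([standard_dna_table.forward_table[c] for c in CODONS])

_TRANSITIONS = {frozenset("AG"), frozenset("CT")}


def _pair_class() -> tuple[np.ndarray, np.ndarray]:
    """Symmetric (syn, nonsyn) exchangeability matrices for 1-nt changes."""
    syn = np.zeros((NCODON, NCODON))
    non = np.zeros((NCODON, NCODON))
    for i, ci in enumerate(CODONS):
        for j in range(i + 1, NCODON):
            cj = CODONS[j]
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            rate = 1.0
            if frozenset(diff[0]) in _TRANSITIONS:
                rate = np.nan  # placeholder, filled with kappa later
            tgt = syn if CODON_AA[i] == CODON_AA[j] else non
            tgt[i, j] = tgt[j, i] = rate
    return syn, non


_SYN_TEMPLATE, _NON_TEMPLATE = _pair_class()


def encode_codon_seq(nt_seq: str) -> np.ndarray:
    """Codon string -> indices into CODONS; gaps/ambiguous/stop -> -1."""
    n = len(nt_seq) // 3
    out = np.full(n, -1, dtype=np.int32)
    for k in range(n):
        out[k] = CODON_INDEX.get(nt_seq[3 * k : 3 * k + 3].upper(), -1)
    return out


@dataclass
class LikelihoodTree:
    """Postorder array encoding of a dendropy tree for pruning."""

    taxa: list[str]
    # per internal node (postorder): list of (child_node_index, branch_length)
    children: list[list[tuple[int, float]]]
    n_leaves: int

    @property
    def n_nodes(self) -> int:
        return self.n_leaves + len(self.children)

    @property
    def branch_lengths(self) -> list[float]:
        return [bl for kids in self.children for _, bl in kids]

    @property
    def total_length(self) -> float:
        return float(sum(self.branch_lengths))


def build_likelihood_tree(tree: dendropy.Tree, taxa: list[str] | None = None) -> LikelihoodTree:
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if taxa is None:
        taxa = sorted(leaves)
    if set(taxa) != set(leaves):
        raise ValueError("tree leaves do not match the alignment's taxa")
    index = {t: i for i, t in enumerate(taxa)}
    node_ids: dict[int, int] = {}
    children: list[list[tuple[int, float]]] = []
    next_id = len(taxa)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node_ids[id(node)] = index[node.taxon.label]
        else:
            kids = []
            for ch in node.child_nodes():
                bl = ch.edge.length if ch.edge.length is not None else 0.0
                kids.append((node_ids[id(ch)], max(float(bl), 0.0)))
            node_ids[id(node)] = next_id
            children.append(kids)
            next_id += 1
    return LikelihoodTree(taxa=list(taxa), children=children, n_leaves=len(taxa))


class MG94:
    """Equal-frequency MG94xHKY codon process with syn/nonsyn rate scaling.

    The generator is Q(alpha, beta) = alpha*S_syn + beta*S_nonsyn (diagonal
    completing rows to zero), normalized so the expected substitution rate
    at alpha = beta = 1 is one per codon.
    """

    def __init__(self, kappa: float = 2.0):
        if kappa < 0:
            raise ValueError("kappa must be nonnegative")
        self.kappa = kappa
        syn = np.where(np.isnan(_SYN_TEMPLATE), kappa, _SYN_TEMPLATE)
        non = np.where(np.isnan(_NON_TEMPLATE), kappa, _NON_TEMPLATE)
        q1 = syn + non
        rate = q1.sum() / NCODON  # mean leaving rate at alpha=beta=1, pi uniform
        self.S_syn = syn / rate
        self.S_nonsyn = non / rate
        self._eig_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def rate_matrix(self, alpha: float, beta: float) -> np.ndarray:
        Q = alpha * self.S_syn + beta * self.S_nonsyn
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def _eig(self, rho: float) -> tuple[np.ndarray, np.ndarray]:
        key = round(float(rho), 12)
        hit = self._eig_cache.get(key)
        if hit is not None:
            return hit
        M = rho * self.S_syn + self.S_nonsyn
        np.fill_diagonal(M, 0.0)
        np.fill_diagonal(M, -M.sum(axis=1))
        w, V = np.linalg.eigh(M)
        if len(self._eig_cache) > 4096:
            self._eig_cache.clear()
        self._eig_cache[key] = (w, V)
        return w, V

    def transition_matrix(self, t: float, alpha: float = 1.0, beta: float = 1.0) -> np.ndarray:
        beta = max(beta, 1e-12)
        w, V = self._eig(alpha / beta)
        P = (V * np.exp(beta * t * w)) @ V.T
        np.clip(P, 0.0, None, out=P)
        P /= P.sum(axis=1, keepdims=True)
        return P

    # ------------------------------------------------------------------
    # pruning likelihood
    # ------------------------------------------------------------------

    def site_logliks(self, ltree: LikelihoodTree, codes: np.ndarray,
                     alpha: float = 1.0, beta: float = 1.0,
                     scale: float = 1.0) -> np.ndarray:
        """Per-site log-likelihoods for an N x S codon-index matrix.

        ``alpha``/``beta`` may be scalars (shared across sites).  Branch
        lengths are multiplied by ``scale``.  Gaps (-1) are missing data.
        """
        n_sites = codes.shape[1]
        partials = np.empty((ltree.n_nodes, n_sites, NCODON))
        scaler = np.zeros(n_sites)
        for i in range(ltree.n_leaves):
            partials[i] = 0.0
            obs = codes[i]
            ok = obs >= 0
            partials[i][ok, obs[ok]] = 1.0
            partials[i][~ok] = 1.0
        Ps = {}
        for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
            acc = np.ones((n_sites, NCODON))
            for child, bl in kids:
                key = round(bl * scale, 15)
                P = Ps.get(key)
                if P is None:
                    P = self.transition_matrix(bl * scale, alpha, beta)
                    Ps[key] = P
                acc *= partials[child] @ P.T
            m = acc.max(axis=1)
            m = np.where(m > 0, m, 1.0)
            acc /= m[:, None]
            scaler += np.log(m)
            partials[node_i] = acc
        root = partials[-1]
        lik = root.mean(axis=1)  # uniform root frequencies 1/61
        with np.errstate(divide="ignore"):
            return np.log(lik) + scaler

    def loglik(self, ltree: LikelihoodTree, codes: np.ndarray,
               alpha: float = 1.0, beta: float = 1.0, scale: float = 1.0) -> float:
        return float(self.site_logliks(ltree, codes, alpha, beta, scale).sum())

    def site_kernel(self, ltree: LikelihoodTree, scale: float = 1.0) -> "SiteKernel":
        return SiteKernel(self, ltree, scale)

    def site_loglik_single(self, ltree: LikelihoodTree, site: np.ndarray,
                           alpha: float, beta: float, scale: float = 1.0) -> float:
        """Fast single-site log-likelihood via the eigen-apply trick."""
        beta = max(beta, 1e-12)
        w, V = self._eig(alpha / beta)
        partials = [None] * ltree.n_nodes
        for i in range(ltree.n_leaves):
            v = np.ones(NCODON) if site[i] < 0 else None
            if v is None:
                v = np.zeros(NCODON)
                v[site[i]] = 1.0
            partials[i] = v
        logscale = 0.0
        for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
            acc = np.ones(NCODON)
            for child, bl in kids:
                x = V.T @ partials[child]
                x *= np.exp(beta * bl * scale * w)
                y = V @ x
                np.clip(y, 0.0, None, out=y)
                acc *= y
            m = acc.max()
            if m > 0:
                acc /= m
                logscale += np.log(m)
            partials[node_i] = acc
        lik = partials[-1].mean()
        if lik <= 0:
            return -1e30
        return float(np.log(lik) + logscale)


class SiteKernel:
    """Fast per-site likelihood evaluator for one tree and branch scale.

    Exploits the equal-frequency factorization Q(alpha, beta) =
    beta * M(alpha/beta): the symmetric eigendecomposition of M depends only
    on rho = alpha/beta, while beta just rescales eigenvalues, so nested
    1-D optimization over (rho, beta) reuses each spectrum.
    """

    def __init__(self, model: MG94, ltree: LikelihoodTree, scale: float = 1.0):
        self.model = model
        self.ltree = ltree
        self.scale = scale
        # flatten the postorder into (child, parent_slot, branch_length)
        self.edges: list[tuple[int, int, float]] = []
        for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
            for child, bl in kids:
                self.edges.append((child, node_i, bl * scale))

    def loglik(self, site: np.ndarray, rho: float, beta: float) -> float:
        """log P(site | alpha = rho*beta, beta) with branch lengths scaled."""
        beta = max(beta, 1e-12)
        w, V = self.model._eig(rho)
        lt = self.ltree
        acc: list[np.ndarray | None] = [None] * lt.n_nodes
        logscale = 0.0
        bw = beta * w
        for child, parent, bl in self.edges:
            if child < lt.n_leaves:
                c = site[child]
                if c < 0:
                    continue  # missing leaf: all-ones partial is a no-op
                x = V[c] * np.exp(bw * bl)
            else:
                v = acc[child]
                if v is None:
                    continue  # subtree entirely missing
                m = v.max()
                if m <= 0:
                    return -1e30
                v = v / m
                logscale += np.log(m)
                x = (v @ V) * np.exp(bw * bl)
            y = V @ x
            np.maximum(y, 0.0, out=y)
            a = acc[parent]
            acc[parent] = y if a is None else a * y
        root = acc[lt.n_nodes - 1]
        if root is None:
            return 0.0  # no data at this site
        lik = root.mean()
        if lik <= 0:
            return -1e30
        return float(np.log(lik) + logscale)


@dataclass
class CodonAlignment:
    """Codon-resolution alignment: N taxa x S sites over the 61 sense codons.

    ``codes[i, s]`` indexes into :data:`CODONS`; -1 marks a gap/missing
    codon.  ``protein_columns`` optionally maps each codon site to the
    protein-MSA column it was threaded from.
    """

    taxa: list[str]
    codes: np.ndarray
    protein_columns: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int32)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be an N_taxa x S matrix")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def codon_string(self, i: int) -> str:
        return "".join(CODONS[c] if c >= 0 else "---" for c in self.codes[i])

    def translation(self, i: int) -> str:
        return "".join(CODON_AA[c] if c >= 0 else "-" for c in self.codes[i])

    def subset_sites(self, sites: np.ndarray) -> "CodonAlignment":
        pc = self.protein_columns[sites] if self.protein_columns is not None else None
        return CodonAlignment(self.taxa, self.codes[:, sites], pc)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_codon_states(model: MG94, tree: dendropy.Tree,
                          site_omega: np.ndarray, rng: np.random.Generator,
                          root_states: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Evolve codon states down ``tree`` with per-site omega; returns leaf states."""
    S = len(site_omega)
    omegas = np.asarray(site_omega, dtype=float)
    if (omegas < 0).any():
        raise ValueError("site omegas must be nonnegative")
    uniq = np.unique(omegas)
    site_group = np.searchsorted(uniq, omegas)
    if root_states is None:
        root_states = rng.integers(0, NCODON, size=S)
    states = {id(tree.seed_node): np.asarray(root_states)}
    out: dict[str, np.ndarray] = {}
    if tree.seed_node.is_leaf():
        raise ValueError("tree must have at least one internal node")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = max(float(node.edge.length or 0.0), 0.0)
        parent_states = states[id(node.parent_node)]
        child_states = parent_states.copy()
        if bl > 0:
            for g, om in enumerate(uniq):
                P = model.transition_matrix(bl, 1.0, float(om))
                cum = P.cumsum(axis=1)
                sites = np.flatnonzero(site_group == g)
                u = rng.random(len(sites))
                rows = cum[parent_states[sites]]
                child_states[sites] = (u[:, None] > rows).sum(axis=1)
        states[id(node)] = child_states
        if node.is_leaf():
            out[node.taxon.label] = child_states
    return out
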