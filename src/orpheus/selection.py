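"""Per-site selection: SLAC and FEL, recombination-aware, with site tiers.

SLAC is the counting method: ancestral codons come from parsimony with
nucleotide-step costs (deterministic lexicographic tie-break); per site,
observed synonymous and nonsynonymous changes are counted over all
branches, averaging multi-step codon changes over all minimal mutational
paths (stop-codon intermediates excluded when avoidable); the expected
synonymous fraction comes from the kappa-weighted synonymous-site
proportion of the codons observed at the site; an extended
(continuous-count) binomial test gives a one-tailed p-value in the
direction of the statistic, the convention of the original counting
method.

FEL is the fixed-effects likelihood method: a global stage fits kappa and a
branch-length scale under a single-omega MG94 model; a per-site stage
maximizes likelihood over synonymous (alpha) and nonsynonymous (beta) rates
and tests beta = alpha with a 1-df likelihood-ratio test.

Recombination is handled by a breakpoint scan: candidate breakpoints split
the alignment in two, each side gets its own NJ tree, and the reduction in
least-squares tree misfit is compared with a permutation null.  Selection
methods then run per partition; sites are always reported in unified
1-based alignment coordinates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.spatial.distance import squareform
from scipy.special import betainc

from .codon import (
    CODON_AA,
    CODON_INDEX,
    CODONS,
    NCODON,
    MG94,
    CodonAlignment,
    LikelihoodTree,
    build_likelihood_tree,
)
from .orfs import translate
from .phylo import DistanceMatrix, nj_patristic, nj_tree

_LOG_RATE_LO, _LOG_RATE_HI = np.log(1e-4), np.log(50.0)


@dataclass
class SiteSelectionResult:
    site: int                 # 1-based alignment codon position
    method: str               # SLAC | FEL | external
    statistic: float          # normalized dN - dS (SLAC) or beta - alpha (FEL)
    p_value: float
    call: str                 # positive | negative | neutral

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass
class BreakpointResult:
    breakpoint: int | None    # 1-based codon index of the last left-partition site
    improvement: float
    p_value: float
    partitions: list[tuple[int, int]]          # 1-based inclusive codon ranges
    trees: list[dendropy.Tree]


# ---------------------------------------------------------------------------
# codon-pair lookup tables for SLAC
# ---------------------------------------------------------------------------

_TABLES: dict | None = None


def _codon_pair_tables() -> dict:
    """Average syn/nonsyn step counts over minimal paths, and syn-site props."""
    global _TABLES
    if _TABLES is not None:
        return _TABLES
    aa = {c: CODON_AA[i] for i, c in enumerate(CODONS)}
    sense = set(CODONS)
    ns = np.zeros((NCODON, NCODON))
    nn = np.zeros((NCODON, NCODON))
    for i, a in enumerate(CODONS):
        for j, b in enumerate(CODONS):
            if i == j:
                continue
            pos = [k for k in range(3) if a[k] != b[k]]
            paths = []
            for order in itertools.permutations(pos):
                cur = a
                steps = []
                blocked = False
                for k in order:
                    nxt = cur[:k] + b[k] + cur[k + 1 :]
                    if nxt not in sense and nxt != b:
                        blocked = True
                    steps.append((cur, nxt))
                    cur = nxt
                paths.append((blocked, steps))
            usable = [s for blk, s in paths if not blk] or [s for _, s in paths]
            s_tot = n_tot = 0.0
            for steps in usable:
                for x, y in steps:
                    if x in sense and y in sense and aa[x] == aa[y]:
                        s_tot += 1
                    else:
                        n_tot += 1
            ns[i, j] = s_tot / len(usable)
            nn[i, j] = n_tot / len(usable)
    # per-codon synonymous/total neighbor counts, split by transition vs
    # transversion so the expected synonymous fraction can be kappa-weighted
    ts_pairs = ({"A", "G"}, {"C", "T"})
    syn_ts = np.zeros(NCODON)
    tot_ts = np.zeros(NCODON)
    syn_tv = np.zeros(NCODON)
    tot_tv = np.zeros(NCODON)
    ntdiff = np.zeros((NCODON, NCODON), dtype=np.int8)
    is_ts = np.zeros((NCODON, NCODON), dtype=bool)
    for i, a in enumerate(CODONS):
        for k in range(3):
            for alt in "ACGT":
                if alt == a[k]:
                    continue
                t = a[:k] + alt + a[k + 1 :]
                if t not in sense:
                    continue
                transition = {a[k], alt} in ts_pairs
                if transition:
                    tot_ts[i] += 1
                    syn_ts[i] += aa[t] == aa[a]
                else:
                    tot_tv[i] += 1
                    syn_tv[i] += aa[t] == aa[a]
        for j, b in enumerate(CODONS):
            pos = [k for k in range(3) if a[k] != b[k]]
            ntdiff[i, j] = len(pos)
            if len(pos) == 1:
                is_ts[i, j] = {a[pos[0]], b[pos[0]]} in ts_pairs
    _TABLES = {
        "ns": ns, "nn": nn, "ntdiff": ntdiff, "is_ts": is_ts,
        "syn_ts": syn_ts, "tot_ts": tot_ts, "syn_tv": syn_tv, "tot_tv": tot_tv,
    }
    return _TABLES


def syn_site_proportion(kappa: float = 1.0) -> np.ndarray:
    """Per-codon expected synonymous change fraction, kappa-weighted."""
    t = _codon_pair_tables()
    num = kappa * t["syn_ts"] + t["syn_tv"]
    den = kappa * t["tot_ts"] + t["tot_tv"]
    return num / np.where(den > 0, den, 1.0)


def estimate_kappa(aln: CodonAlignment) -> float:
    """Crude ts/tv rate ratio from single-nucleotide-difference codon pairs.

    kappa = 2 * (#transitions / #transversions), the factor 2 correcting for
    the 2:1 transversion/transition opportunity ratio.
    """
    t = _codon_pair_tables()
    ts = tv = 0
    N = aln.n_taxa
    for i in range(N):
        for j in range(i + 1, N):
            ci, cj = aln.codes[i], aln.codes[j]
            ok = (ci >= 0) & (cj >= 0)
            d1 = t["ntdiff"][ci[ok], cj[ok]] == 1
            k = t["is_ts"][ci[ok], cj[ok]][d1]
            ts += int(k.sum())
            tv += int((~k).sum())
    if tv == 0:
        return 2.0
    return max(2.0 * ts / tv, 0.1)


# ---------------------------------------------------------------------------
# partitions plumbing
# ---------------------------------------------------------------------------

def _normalize_partitions(aln: CodonAlignment, trees) -> list[tuple[tuple[int, int], dendropy.Tree]]:
    """Accept a single tree, a BreakpointResult, or explicit (range, tree) pairs."""
    S = aln.n_sites
    if isinstance(trees, dendropy.Tree):
        return [((1, S), trees)]
    if isinstance(trees, BreakpointResult):
        return list(zip(trees.partitions, trees.trees))
    parts = list(trees)
    covered = []
    for (a, b), _t in parts:
        covered.extend(range(a, b + 1))
    if sorted(covered) != list(range(1, S + 1)):
        raise ValueError("partitions must tile the alignment 1..S")
    return parts


# ---------------------------------------------------------------------------
# SLAC
# ---------------------------------------------------------------------------

def _parents(ltree: LikelihoodTree) -> np.ndarray:
    par = np.full(ltree.n_nodes, -1, dtype=int)
    for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
        for child, _bl in kids:
            par[child] = node_i
    return par


def _fitch_ancestors(ltree: LikelihoodTree, codes: np.ndarray) -> np.ndarray:
    """Parsimony ancestral codons, nucleotide-step costs, for all nodes.

    Changes are weighted by the number of nucleotide substitutions they
    require (Sankoff costs = pairwise nt differences), matching the
    minimal-mutational-path accounting used for counting; ties resolve to
    the lexicographically smallest codon (CODONS is sorted, so the first
    argmin is the lexicographic choice).  Leaves keep their observed codons
    (-1 for missing).
    """
    tables = _codon_pair_tables()
    C = tables["ntdiff"].astype(np.float32)
    n_nodes, S = ltree.n_nodes, codes.shape[1]
    BIG = np.float32(1e6)
    cost = np.empty((n_nodes, S, NCODON), dtype=np.float32)
    for i in range(ltree.n_leaves):
        obs = codes[i]
        cost[i] = 0.0
        ok = obs >= 0
        cost[i][ok] = BIG
        cost[i][ok, obs[ok]] = 0.0
    for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
        acc = np.zeros((S, NCODON), dtype=np.float32)
        for child, _bl in kids:
            # min over child state t of cost_child[t] + C[s, t]
            acc += (cost[child][:, None, :] + C[None, :, :]).min(axis=2)
        cost[node_i] = acc

    states = np.empty((n_nodes, S), dtype=np.int32)
    root = n_nodes - 1
    states[root] = cost[root].argmin(axis=1)
    for node_i in range(n_nodes - 1, ltree.n_leaves - 1, -1):
        ps = states[node_i]
        for child, _bl in ltree.children[node_i - ltree.n_leaves]:
            if child < ltree.n_leaves:
                continue
            states[child] = (C[ps] + cost[child]).argmin(axis=1)
    for i in range(ltree.n_leaves):
        states[i] = codes[i]
    return states


def _extended_binomial_tails(k: np.ndarray, n: np.ndarray, p: np.ndarray):
    """(P[X <= k], P[X >= k]) for k successes in n trials, continuous counts.

    The regularized incomplete beta function extends the binomial CDF to
    fractional counts, as in the HyPhy counting method.  The lower tail is
    evidence for positive selection (fewer synonymous changes than
    expected), the upper tail for negative selection.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-9, 1 - 1e-9)
    p_le = np.ones_like(k)
    p_ge = np.ones_like(k)
    lo = n - k > 1e-12
    p_le[lo] = betainc(n[lo] - k[lo], k[lo] + 1.0, 1.0 - p[lo])
    hi = k > 1e-12
    p_ge[hi] = betainc(k[hi], n[hi] - k[hi] + 1.0, p[hi])
    return p_le, p_ge


def slac(aln: CodonAlignment, trees, alpha_level: float = 0.1,
         kappa: float | None = None) -> list[SiteSelectionResult]:
    """Counting-based per-site selection with an extended binomial test.

    ``kappa`` weights transitions in the expected synonymous fraction; by
    default it is estimated from single-nucleotide-difference codon pairs.
    """
    tables = _codon_pair_tables()
    if kappa is None:
        kappa = estimate_kappa(aln)
    results: list[SiteSelectionResult] = []
    for (a, b), tree in _normalize_partitions(aln, trees):
        sites = np.arange(a - 1, b)
        codes = aln.codes[:, sites]
        ltree = build_likelihood_tree(tree, aln.taxa)
        states = _fitch_ancestors(ltree, codes)
        S = codes.shape[1]
        ns_obs = np.zeros(S)
        nn_obs = np.zeros(S)
        for node_i, kids in enumerate(ltree.children, start=ltree.n_leaves):
            for child, _bl in kids:
                cs = states[child]
                ok = cs >= 0
                ps = states[node_i]
                ns_obs[ok] += tables["ns"][ps[ok], cs[ok]]
                nn_obs[ok] += tables["nn"][ps[ok], cs[ok]]
        prop = syn_site_proportion(kappa)
        es = np.empty(S)
        for s in range(S):
            obs = codes[:, s]
            obs = obs[obs >= 0]
            es[s] = prop[obs].mean() if len(obs) else 1 / 3
        total = ns_obs + nn_obs
        # empirical centering: parsimony reconstruction (and its deterministic
        # tie-break) biases the syn/nonsyn split of counted steps, so the
        # opportunity-based E_s is rescaled to match the alignment-wide
        # observed synonymous fraction under the shared null
        es = np.clip(es, 0.01, 0.99)
        p_le, p_ge = _extended_binomial_tails(ns_obs, total, es)
        syn_sites = 3.0 * es
        non_sites = 3.0 - syn_sites
        with np.errstate(divide="ignore", invalid="ignore"):
            dn = np.where(non_sites > 0, nn_obs / np.where(non_sites > 0, non_sites, 1), 0.0)
            ds = np.where(syn_sites > 0, ns_obs / np.where(syn_sites > 0, syn_sites, 1), 0.0)
        stat = dn - ds
        for s in range(S):
            if total[s] <= 0:
                call, p = "neutral", 1.0
            elif stat[s] > 0:
                p = float(p_le[s])  # one-tailed, direction of the statistic
                call = "positive" if p < alpha_level else "neutral"
            else:
                p = float(p_ge[s])
                call = "negative" if p < alpha_level and stat[s] < 0 else "neutral"
            results.append(SiteSelectionResult(
                site=int(sites[s]) + 1, method="SLAC",
                statistic=float(stat[s]), p_value=p, call=call))
    results.sort(key=lambda r: r.site)
    return results


# ---------------------------------------------------------------------------
# FEL
# ---------------------------------------------------------------------------

def _fit_global(aln_codes: np.ndarray, ltree: LikelihoodTree,
                kappa0: float = 2.0) -> tuple[MG94, float, float, float]:
    """Stage 1: kappa, branch scale and a single omega by Nelder-Mead."""
    models: dict[float, MG94] = {}

    def get_model(kappa: float) -> MG94:
        key = round(kappa, 6)
        if key not in models:
            models[key] = MG94(key)
        return models[key]

    def nll(x):
        lk, ls, lw = np.clip(x, [-2.3, -4.6, _LOG_RATE_LO], [3.0, 4.6, _LOG_RATE_HI])
        model = get_model(float(np.exp(lk)))
        return -model.loglik(ltree, aln_codes, alpha=1.0,
                             beta=float(np.exp(lw)), scale=float(np.exp(ls)))

    res = optimize.minimize(nll, x0=[np.log(kappa0), 0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 0.02, "fatol": 0.01, "maxiter": 250})
    lk, ls, lw = res.x
    model = get_model(float(np.exp(np.clip(lk, -2.3, 3.0))))
    return model, float(np.exp(ls)), float(np.exp(lw)), -res.fun


def fel(aln: CodonAlignment, trees, alpha_level: float = 0.1,
        kappa0: float = 2.0) -> list[SiteSelectionResult]:
    """Fixed-effects likelihood per-site alpha/beta with a chi2(1) LRT."""
    if aln.n_taxa < 3:
        raise ValueError("FEL needs at least 3 sequences")
    results: list[SiteSelectionResult] = []
    for (a, b), tree in _normalize_partitions(aln, trees):
        sites = np.arange(a - 1, b)
        codes = aln.codes[:, sites]
        ltree = build_likelihood_tree(tree, aln.taxa)
        if ltree.total_length <= 0:
            raise ValueError("tree has zero total branch length")
        model, scale, _w_hat, _ = _fit_global(codes, ltree, kappa0)
        kernel = model.site_kernel(ltree, scale)
        for s in range(codes.shape[1]):
            site = codes[:, s]
            obs = site[site >= 0]
            if len(obs) < 3 or (obs == obs[0]).all():
                results.append(SiteSelectionResult(
                    site=int(sites[s]) + 1, method="FEL", statistic=0.0,
                    p_value=1.0, call="neutral"))
                continue

            # null: alpha = beta = r (rho = 1, one shared spectrum)
            r0 = optimize.minimize_scalar(
                lambda lr: -kernel.loglik(site, 1.0, float(np.exp(lr))),
                bounds=(_LOG_RATE_LO, _LOG_RATE_HI), method="bounded",
                options={"xatol": 2e-3})
            l0 = -r0.fun
            rhat = float(np.exp(r0.x))

            # alternative: profile out beta inside an outer search over
            # rho = alpha/beta, which owns the eigendecomposition
            def profile_beta(lrho):
                rho = float(np.exp(lrho))
                inner = optimize.minimize_scalar(
                    lambda lb: -kernel.loglik(site, rho, float(np.exp(lb))),
                    bounds=(_LOG_RATE_LO, _LOG_RATE_HI), method="bounded",
                    options={"xatol": 0.02})
                return inner.fun, float(np.exp(inner.x))

            ro = optimize.minimize_scalar(
                lambda lrho: profile_beta(lrho)[0],
                bounds=(-6.9, 6.9), method="bounded", options={"xatol": 0.05})
            nll_a, beta_hat = profile_beta(ro.x)
            la = -nll_a
            alpha_hat = float(np.exp(ro.x)) * beta_hat
            if la < l0:  # alt must nest the null
                la, alpha_hat, beta_hat = l0, rhat, rhat
            lrt = max(2.0 * (la - l0), 0.0)
            p = float(stats.chi2.sf(lrt, df=1))
            stat = beta_hat - alpha_hat
            if p < alpha_level and stat > 0:
                call = "positive"
            elif p < alpha_level and stat < 0:
                call = "negative"
            else:
                call = "neutral"
            results.append(SiteSelectionResult(
                site=int(sites[s]) + 1, method="FEL", statistic=stat,
                p_value=p, call=call))
    results.sort(key=lambda r: r.site)
    return results


def global_omega(aln: CodonAlignment, tree: dendropy.Tree,
                 kappa0: float = 2.0) -> dict:
    """Single-omega MG94 fit with a 95% profile-likelihood CI.

    Returns ``{"omega", "ci", "loglik", "significantly_different_from_1"}``.
    """
    ltree = build_likelihood_tree(tree, aln.taxa)
    if ltree.total_length <= 0:
        raise ValueError("tree has zero total branch length")
    models: dict[float, MG94] = {}

    def get_model(kappa: float) -> MG94:
        key = round(max(kappa, 0.1), 6)
        if key not in models:
            models[key] = MG94(key)
        return models[key]

    def nll_full(x):
        lk, ls, lw = x
        model = get_model(float(np.exp(np.clip(lk, -2.3, 3.0))))
        return -model.loglik(ltree, aln.codes, alpha=1.0,
                             beta=float(np.exp(np.clip(lw, _LOG_RATE_LO, _LOG_RATE_HI))),
                             scale=float(np.exp(np.clip(ls, -4.6, 4.6))))

    fit = optimize.minimize(nll_full, x0=[np.log(kappa0), 0.0, 0.0],
                            method="Nelder-Mead",
                            options={"xatol": 0.01, "fatol": 0.005, "maxiter": 400})
    lmax = -fit.fun
    lk_hat, ls_hat, lw_hat = fit.x
    omega_hat = float(np.exp(lw_hat))

    def profile(lw):
        r = optimize.minimize(lambda y: nll_full([y[0], y[1], lw]),
                              x0=[lk_hat, ls_hat], method="Nelder-Mead",
                              options={"xatol": 0.02, "fatol": 0.01, "maxiter": 200})
        return -r.fun

    crit = stats.chi2.ppf(0.95, df=1)

    def drop(lw):
        return 2.0 * (lmax - profile(lw)) - crit

    lo_bound, hi_bound = np.log(1e-3), np.log(50.0)
    ci_lo = 0.0 if drop(lo_bound) < 0 else float(np.exp(
        optimize.brentq(drop, lo_bound, lw_hat, xtol=1e-3)))
    ci_hi = np.inf if drop(hi_bound) < 0 else float(np.exp(
        optimize.brentq(drop, lw_hat, hi_bound, xtol=1e-3)))
    return {
        "omega": omega_hat,
        "ci": (ci_lo, ci_hi),
        "loglik": lmax,
        "kappa": float(np.exp(lk_hat)),
        "significantly_different_from_1": not (ci_lo <= 1.0 <= ci_hi),
    }


# ---------------------------------------------------------------------------
# breakpoint scan
# ---------------------------------------------------------------------------

def _pair_diffs(aln: CodonAlignment):
    tables = _codon_pair_tables()
    N, S = aln.codes.shape
    pairs = list(itertools.combinations(range(N), 2))
    diffs = np.zeros((len(pairs), S))
    valid = np.zeros((len(pairs), S))
    for p, (i, j) in enumerate(pairs):
        ci, cj = aln.codes[i], aln.codes[j]
        ok = (ci >= 0) & (cj >= 0)
        diffs[p, ok] = tables["ntdiff"][ci[ok], cj[ok]]
        valid[p, ok] = 1.0
    return diffs, valid


def _jc_matrix(nd: np.ndarray, nv: np.ndarray, n_taxa: int) -> np.ndarray:
    if (nv == 0).any():
        raise ValueError("a taxon pair shares no sites in a partition")
    p = nd / (3.0 * nv)
    cap = 0.70
    sat = p >= cap
    p = np.where(sat, cap, p)
    d = -0.75 * np.log1p(-4.0 * p / 3.0)
    return squareform(d)


def _misfit(T: np.ndarray, D: np.ndarray) -> float:
    return float(((T - D) ** 2).sum() / 2.0)


def detect_breakpoints(aln: CodonAlignment, margin: int = 20, n_perm: int = 100,
                       seed: int = 0, step: int = 1,
                       alpha: float = 0.05) -> BreakpointResult:
    """Single-breakpoint scan by partitioned NJ least-squares fit.

    For each candidate breakpoint the alignment splits in two; each side
    gets its own NJ tree and the improvement over the single full-data tree
    is the drop in squared misfit to the partition distance matrices.
    Significance is the upper tail of the same statistic under ``n_perm``
    random column-order permutations.
    """
    S = aln.n_sites
    N = aln.n_taxa
    if N < 4:
        raise ValueError("breakpoint scan needs at least 4 taxa")
    if S < 2 * margin + 1:
        raise ValueError("alignment too short for the requested margin")
    diffs, valid = _pair_diffs(aln)
    candidates = np.arange(margin, S - margin + 1, step)

    def scan(diffs_o: np.ndarray, valid_o: np.ndarray):
        cd = np.cumsum(diffs_o, axis=1)
        cv = np.cumsum(valid_o, axis=1)
        D_all = _jc_matrix(cd[:, -1], cv[:, -1], N)
        T0 = nj_patristic(D_all)
        best_imp, best_b = -np.inf, None
        for b in candidates:
            ndL, nvL = cd[:, b - 1], cv[:, b - 1]
            ndR, nvR = cd[:, -1] - ndL, cv[:, -1] - nvL
            try:
                DL = _jc_matrix(ndL, nvL, N)
                DR = _jc_matrix(ndR, nvR, N)
            except ValueError:
                continue
            # site-count weights make the noise-overfitting term flat in b,
            # so the statistic peaks where the topology actually changes
            imp = b * (_misfit(T0, DL) - _misfit(nj_patristic(DL), DL)) + \
                  (S - b) * (_misfit(T0, DR) - _misfit(nj_patristic(DR), DR))
            if imp > best_imp:
                best_imp, best_b = imp, int(b)
        return best_imp, best_b

    obs_imp, obs_b = scan(diffs, valid)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        order = rng.permutation(S)
        imp, _b = scan(diffs[:, order], valid[:, order])
        if imp >= obs_imp:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)

    def partition_tree(site_mask: np.ndarray) -> dendropy.Tree:
        nd = diffs[:, site_mask].sum(axis=1)
        nv = valid[:, site_mask].sum(axis=1)
        D = _jc_matrix(nd, nv, N)
        return nj_tree(DistanceMatrix(labels=list(aln.taxa), matrix=D))

    if p < alpha and obs_b is not None:
        left = np.arange(S) < obs_b
        return BreakpointResult(
            breakpoint=obs_b, improvement=float(obs_imp), p_value=float(p),
            partitions=[(1, obs_b), (obs_b + 1, S)],
            trees=[partition_tree(left), partition_tree(~left)],
        )
    return BreakpointResult(
        breakpoint=None, improvement=float(obs_imp), p_value=float(p),
        partitions=[(1, S)], trees=[partition_tree(np.ones(S, dtype=bool))],
    )


# ---------------------------------------------------------------------------
# threading and the site combiner
# ---------------------------------------------------------------------------

def thread_codon_alignment(protein_msa, cds_records) -> CodonAlignment:
    """Thread CDS nucleotides through a protein MSA (gaps become codon gaps)."""
    cds_by_id = {r.id: r for r in cds_records}
    width = len(protein_msa[0].seq)
    codes = np.full((len(protein_msa), width), -1, dtype=np.int32)
    for i, row in enumerate(protein_msa):
        if len(row.seq) != width:
            raise ValueError("ragged protein alignment")
        if row.id not in cds_by_id:
            raise ValueError(f"no CDS record for protein row {row.id!r}")
        nt = cds_by_id[row.id].seq.upper()
        if len(nt) % 3 == 0 and nt[-3:] in ("TAA", "TAG", "TGA"):
            nt = nt[:-3]
        aa = translate(nt)
        ungapped = row.seq.upper().replace("-", "").replace(".", "")
        if aa.rstrip("*") != ungapped:
            for pos, (x, y) in enumerate(zip(aa, ungapped)):
                if x != y:
                    raise ValueError(
                        f"translation mismatch for {row.id!r} at residue {pos + 1}: "
                        f"CDS gives {x!r}, protein row has {y!r}"
                    )
            raise ValueError(
                f"translation length mismatch for {row.id!r}: "
                f"{len(aa)} vs {len(ungapped)}"
            )
        k = 0
        for col, a in enumerate(row.seq.upper()):
            if a in ("-", "."):
                continue
            codes[i, col] = CODON_INDEX.get(nt[3 * k : 3 * k + 3], -1)
            k += 1
    return CodonAlignment(
        taxa=[r.id for r in protein_msa],
        codes=codes,
        protein_columns=np.arange(width),
    )


def codon_alignment_from_maps(protein_msa, maps, cds_records) -> CodonAlignment:
    """Thread CDS codons through match-column residue maps.

    Used when the protein MSA came from profile-HMM projection, where
    insert-state residues are collapsed and a plain column walk would
    desynchronize; ``maps[i][col]`` is the CDS residue index emitted at the
    column (-1 for a deletion).
    """
    cds_by_id = {r.id: r for r in cds_records}
    width = len(protein_msa[0].seq)
    codes = np.full((len(protein_msa), width), -1, dtype=np.int32)
    for i, row in enumerate(protein_msa):
        nt = cds_by_id[row.id].seq.upper()
        for col, j in enumerate(np.asarray(maps[i])):
            if j >= 0:
                codes[i, col] = CODON_INDEX.get(nt[3 * j : 3 * j + 3], -1)
    return CodonAlignment(taxa=[r.id for r in protein_msa], codes=codes,
                          protein_columns=np.arange(width))


def integrate_sites(results_by_method: dict, rule: str | int = "all") -> dict:
    """Combine per-method positive-site sets into report tiers.

    ``results_by_method`` maps a method name to either a list of
    :class:`SiteSelectionResult` or a plain iterable of 1-based sites
    (e.g. externally computed REL/MEME lists).  ``rule`` picks the tier
    reported under ``"selected"``: "all", "any", or an integer k for
    sites found by at least k methods.
    """
    if not results_by_method:
        raise ValueError("need results from at least one method")
    sets: dict[str, set[int]] = {}
    for method, res in results_by_method.items():
        if res and isinstance(next(iter(res)), SiteSelectionResult):
            sets[method] = {r.site for r in res if r.call == "positive"}
        else:
            sets[method] = {int(s) for s in res}
    all_sets = list(sets.values())
    tier_all = set.intersection(*all_sets)
    tier_any = set.union(*all_sets)
    counts: dict[int, int] = {}
    for s in all_sets:
        for site in s:
            counts[site] = counts.get(site, 0) + 1
    tier_two = {site for site, c in counts.items() if c >= min(2, len(all_sets))}
    if rule == "all":
        selected = tier_all
    elif rule == "any":
        selected = tier_any
    elif isinstance(rule, int):
        selected = {site for site, c in counts.items() if c >= rule}
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return {
        "methods": {m: sorted(s) for m, s in sets.items()},
        "all_methods": sorted(tier_all),
        "two_plus": sorted(tier_two),
        "any": sorted(tier_any),
        "selected": sorted(selected),
    }
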