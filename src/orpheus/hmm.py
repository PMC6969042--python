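"""Profile hidden Markov models for OR homology search.

A profile is built from a seed alignment of reference OR proteins: columns
with <50% gaps become match states; emissions are pseudocount-smoothed
residue counts; transitions among match/insert/delete states are counted
along each seed row and smoothed with a sparse-gap prior whose delete state
is cheap to extend, so that edge-truncated gene fragments can traverse the
full match path without being priced out.

Scoring is glocal: the whole match path M1..ML must be traversed (via match
or delete states) while flanking sequence is absorbed by free flank states.
Scores are log-odds in bits against a background of amino-acid frequencies
implied by uniform usage of the 61 sense codons.  Significance comes from a
Gumbel (EVD) fit to Viterbi scores of random background sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .orfs import OrfRecord

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
_NEG = -1e30

# transition priors per from-state
_PRIOR = {
    "MM": 0.90, "MD": 0.05, "MI": 0.05,
    "IM": 0.50, "II": 0.50,
    "DM": 0.10, "DD": 0.90,
}


def codon_background() -> np.ndarray:
    """Amino-acid frequencies under uniform codon usage (61 sense codons)."""
    from Bio.Data.CodonTable import standard_dna_table

    counts = np.zeros(20)
    for codon, aa in standard_dna_table.forward_table.items():
        if set(codon) <= set("ACGT"):
            counts[_AA_INDEX[aa]] += 1
    return counts / counts.sum()


def encode_protein(seq: str) -> np.ndarray:
    """Residues -> indices 0..19; X/unknown -> 20 (scored as neutral)."""
    out = np.full(len(seq), 20, dtype=np.int16)
    for i, a in enumerate(seq.upper()):
        out[i] = _AA_INDEX.get(a, 20)
    return out


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with log-odds scores in bits.

    Transition arrays have length L+1 and are indexed by *from*-position
    ``j``: ``t["MM"][j]`` is M_j -> M_{j+1} (position 0 is the begin/flank
    state, position L exits freely).
    """

    L: int
    match_probs: np.ndarray          # L x 20
    background: np.ndarray           # 20
    match_scores: np.ndarray         # L x 21 log2(e/bg); col 20 = 0 for X
    t: dict[str, np.ndarray]         # each length L+1, log2 probabilities
    match_columns: np.ndarray        # seed-alignment columns kept as match states
    calibration: tuple[float, float] | None = None   # Gumbel (loc, scale)

    def consensus(self) -> str:
        return "".join(AA_ORDER[i] for i in self.match_probs.argmax(axis=1))


def build_profile_hmm(seed_msa, pseudocount_weight: float = 1.0) -> ProfileHMM:
    """Build a profile from gapped protein records (<50%-gap columns match)."""
    rows = [r.seq.upper().replace(".", "-") for r in seed_msa]
    if len(rows) < 2:
        raise ValueError("profile needs at least 2 aligned sequences")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged seed alignment")
    mat = np.array([list(r) for r in rows])
    gap_frac = (mat == "-").mean(axis=0)
    match_cols = np.flatnonzero(gap_frac < 0.5)
    L = len(match_cols)
    if L == 0:
        raise ValueError("no column with <50% gaps; cannot define match states")

    bg = codon_background()
    counts = np.zeros((L, 20))
    for j, col in enumerate(match_cols):
        for r in rows:
            a = r[col]
            if a in _AA_INDEX:
                counts[j, _AA_INDEX[a]] += 1
    probs = counts + pseudocount_weight * bg
    probs /= probs.sum(axis=1, keepdims=True)
    msc = np.zeros((L, 21))
    with np.errstate(divide="ignore"):
        msc[:, :20] = np.where(probs > 0, np.log2(np.where(probs > 0, probs, 1) / bg), _NEG)

    # transition counts along each row's implied state path
    pos_of_col = np.zeros(width, dtype=int)  # match position 1..L, 0 = insert col
    pos_of_col[match_cols] = np.arange(1, L + 1)
    tc = {k: np.zeros(L + 1) for k in _PRIOR}
    for r in rows:
        prev_state, prev_k = "M", 0  # begin state behaves like M_0
        for col in range(width):
            k = pos_of_col[col]
            if k:
                state = "D" if r[col] == "-" else "M"
                key = prev_state + state
                if key not in tc:  # I->D (no such edge in the state graph):
                    key = "II"     # fold into insert extension
                tc[key][prev_k] += 1
                prev_state, prev_k = state, k
            elif r[col] != "-":
                if prev_k == 0:
                    continue  # N-terminal overhang: absorbed by the free flank
                key = prev_state + "I" if prev_state != "D" else "II"
                tc[key][prev_k] += 1
                prev_state = "I"
    # smooth with priors and normalize per from-state
    w = max(pseudocount_weight, 0.0)
    t_log: dict[str, np.ndarray] = {}
    valid = {
        "MM": np.arange(0, L), "MD": np.arange(0, L), "MI": np.arange(1, L),
        "IM": np.arange(1, L), "II": np.arange(1, L),
        "DM": np.arange(1, L), "DD": np.arange(1, L),
    }
    masks = {k: np.zeros(L + 1, dtype=bool) for k in _PRIOR}
    for k, idx in valid.items():
        masks[k][idx] = True
    for keys in (["MM", "MD", "MI"], ["IM", "II"], ["DM", "DD"]):
        tot = np.zeros(L + 1)
        for k in keys:
            tot += np.where(masks[k], tc[k] + w * _PRIOR[k], 0.0)
        for k in keys:
            num = np.where(masks[k], tc[k] + w * _PRIOR[k], 0.0)
            p = num / np.where(tot > 0, tot, 1.0)
            out = np.full(L + 1, _NEG)
            ok = masks[k] & (p > 0)
            out[ok] = np.log2(p[ok])
            t_log[k] = out
    return ProfileHMM(
        L=L,
        match_probs=probs,
        background=bg,
        match_scores=msc,
        t=t_log,
        match_columns=match_cols,
    )


def viterbi(hmm: ProfileHMM, seq: str, want_path: bool = False):
    """Best glocal alignment score (bits); optionally the match-state path.

    Returns ``score`` or ``(score, row, envelope)`` where ``row`` is the
    gapped string over match states and ``envelope`` is ``(seq_start,
    seq_end, prof_start, prof_end)`` (half-open on the sequence, inclusive
    1-based match positions on the profile).
    """
    L = hmm.L
    enc = encode_protein(seq)
    n = len(enc)
    tMM, tMD, tMI = hmm.t["MM"], hmm.t["MD"], hmm.t["MI"]
    tIM, tII = hmm.t["IM"], hmm.t["II"]
    tDM, tDD = hmm.t["DM"], hmm.t["DD"]
    msc = hmm.match_scores
    cdd = np.concatenate(([0.0], np.cumsum(tDD[1:L])))  # length L, index k-1
    kidx = np.arange(L)

    def d_row(Mrow, store_i=None):
        cand = Mrow[:-1] + tMD[:-1]
        A = cand - cdd
        run = np.maximum.accumulate(A)
        if store_i is not None:
            idx = np.where(A >= run, kidx, 0)
            Didx[store_i] = np.maximum.accumulate(idx)
        out = np.empty(L + 1)
        out[0] = _NEG
        out[1:] = run + cdd
        return out

    if want_path:
        Mptr = np.zeros((n + 1, L), dtype=np.int8)
        Iptr = np.zeros((n + 1, L), dtype=np.int8)
        Didx = np.zeros((n + 1, L), dtype=np.int32)
    else:
        Didx = None

    M = np.full(L + 1, _NEG)
    I = np.full(L + 1, _NEG)
    M[0] = 0.0
    D = d_row(M, 0 if want_path else None)
    finalM = np.empty(n + 1)
    finalD = np.empty(n + 1)
    finalM[0], finalD[0] = M[L], D[L]

    for i in range(1, n + 1):
        e = msc[:, enc[i - 1]]
        candM = np.stack((M[:-1] + tMM[:-1], I[:-1] + tIM[:-1], D[:-1] + tDM[:-1]))
        newM = np.empty(L + 1)
        newM[0] = 0.0
        newM[1:] = e + candM.max(axis=0)
        candI = np.stack((M[1:] + tMI[1:], I[1:] + tII[1:]))
        newI = np.empty(L + 1)
        newI[0] = _NEG
        newI[1:] = candI.max(axis=0)  # insert emissions are background: 0 bits
        if want_path:
            Mptr[i] = candM.argmax(axis=0)
            Iptr[i] = candI.argmax(axis=0)
        newD = d_row(newM, i if want_path else None)
        M, I, D = newM, newI, newD
        finalM[i], finalD[i] = M[L], D[L]

    finals = np.maximum(finalM, finalD)
    best_i = int(finals.argmax())  # residues after best_i are free C-flank
    score = float(finals[best_i])
    if not want_path:
        return score

    row = ["-"] * L
    match_map = np.full(L, -1, dtype=np.int32)  # residue index per match column
    i, k = best_i, L
    state = "M" if finalM[best_i] >= finalD[best_i] else "D"
    prof_hit: list[int] = []
    seq_hit: list[int] = []
    while k > 0:
        if state == "M":
            row[k - 1] = seq[i - 1] if i >= 1 else "-"
            match_map[k - 1] = i - 1
            prof_hit.append(k)
            seq_hit.append(i - 1)
            p = Mptr[i, k - 1]
            i -= 1
            k -= 1
            state = "MID"[p]
        elif state == "D":
            j = int(Didx[i, k - 1])  # delete run D_{j+1}..D_k entered from M_j
            k = j
            state = "M"
        else:  # insert at position k, consumes residue i
            p = Iptr[i, k - 1]
            i -= 1
            state = "M" if p == 0 else "I"
    envelope = (
        min(seq_hit) if seq_hit else 0,
        (max(seq_hit) + 1) if seq_hit else 0,
        min(prof_hit) if prof_hit else 1,
        max(prof_hit) if prof_hit else 0,
    )
    return score, "".join(row), envelope, match_map


@dataclass
class HmmHit:
    """A significant profile match to one ORF."""

    orf_id: str
    bit_score: float
    e_value: float
    envelope: tuple[int, int, int, int]  # seq_start, seq_end, prof_start, prof_end
    implied_alignment_row: str
    hmm_id: str = "full"


def calibrate(hmm: ProfileHMM, n_null: int = 1000, seed: int = 0,
              length: int | None = None) -> tuple[float, float]:
    """Fit a Gumbel EVD to Viterbi scores of random background sequences."""
    rng = np.random.default_rng(seed)
    length = length or hmm.L
    aas = np.array(list(AA_ORDER))
    scores = np.empty(n_null)
    for i in range(n_null):
        s = "".join(rng.choice(aas, size=length, p=hmm.background))
        scores[i] = viterbi(hmm, s)
    loc, scale = stats.gumbel_r.fit(scores)
    hmm.calibration = (float(loc), float(scale))
    return hmm.calibration


def score_to_evalue(hmm: ProfileHMM, score: float, n_targets: int) -> float:
    if hmm.calibration is None:
        raise ValueError("HMM is not calibrated; call calibrate() first")
    loc, scale = hmm.calibration
    return float(n_targets * stats.gumbel_r.sf(score, loc=loc, scale=scale))


def search_orfs(hmm: ProfileHMM, orfs: list[OrfRecord], e_cutoff: float = 1e-10,
                n_null: int = 1000, seed: int = 0, hmm_id: str = "full") -> list[HmmHit]:
    """Score every ORF against the profile; return hits with E <= cutoff."""
    if not orfs:
        raise ValueError("empty ORF set")
    if hmm.calibration is None:
        calibrate(hmm, n_null=n_null, seed=seed)
    n_targets = len(orfs)
    hits: list[HmmHit] = []
    for orf in orfs:
        score, row, env, _map = viterbi(hmm, orf.aa_seq, want_path=True)
        e = score_to_evalue(hmm, score, n_targets)
        if e <= e_cutoff:
            hits.append(HmmHit(orf.orf_id, score, e, env, row, hmm_id=hmm_id))
    hits.sort(key=lambda h: -h.bit_score)
    return hits


def align_to_hmm(hmm: ProfileHMM, proteins, return_maps: bool = False):
    """Project each protein's Viterbi path onto match states (one MSA row each).

    Insertions are recorded in the path but collapsed from the reported MSA,
    so every row has exactly ``hmm.L`` columns.  With ``return_maps`` the
    per-row arrays mapping each match column to the emitting residue index
    (-1 for deletions) are returned too, which codon threading needs when
    insert-state residues were collapsed away.
    """
    from .io import SequenceRecord

    rows, maps = [], []
    for p in proteins:
        score, row, env, match_map = viterbi(hmm, p.seq, want_path=True)
        if set(row) == {"-"}:
            raise ValueError(f"sequence {p.id} is unalignable (all-delete path)")
        rows.append(SequenceRecord(id=p.id, seq=row, alphabet="protein"))
        maps.append(match_map)
    return (rows, maps) if return_maps else rows
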