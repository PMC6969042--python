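"""OR-specific annotation: motifs, family assignment, conservation, topology.

Motif scanning reports the canonical OR motifs with a small mismatch
tolerance; family assignment is by best global-alignment identity against a
family-tagged reference panel; conservation profiles summarize per-column
amino-acid frequencies and information content (the quantities a sequence
logo displays); transmembrane segments come from Kyte-Doolittle sliding
window hydropathy with class-A GPCR loop labeling (extracellular
N-terminus).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .hmm import AA_ORDER, _AA_INDEX
from .io import SequenceRecord
from .simulate import KYTE_DOOLITTLE


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    motif: str
    position: int       # 0-based start
    mismatches: int


@dataclass
class MotifReport:
    dry_hits: list[MotifHit]        # MAYDRYVAIC, <=2 mismatches
    ic3_hits: list[MotifHit]        # FSTC(L|P)H, <=1 mismatch outside [LP]
    cysteines: list[int]
    has_dry: bool = field(init=False)
    has_ic3: bool = field(init=False)

    def __post_init__(self) -> None:
        self.has_dry = bool(self.dry_hits)
        self.has_ic3 = bool(self.ic3_hits)


def scan_motifs(protein: SequenceRecord | str) -> MotifReport:
    """Locate the canonical OR motifs and all cysteines (0-based positions)."""
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    seq = seq.upper()
    dry = "MAYDRYVAIC"
    dry_hits = []
    for i in range(len(seq) - len(dry) + 1):
        mm = sum(1 for a, b in zip(seq[i : i + len(dry)], dry) if a != b)
        if mm <= 2:
            dry_hits.append(MotifHit("MAYDRYVAIC", i, mm))
    ic3_hits = []
    fixed = "FSTC H"  # position 4 is the (L|P) bracket
    for i in range(len(seq) - 6 + 1):
        win = seq[i : i + 6]
        if win[4] not in "LP":
            continue
        mm = sum(1 for j in (0, 1, 2, 3, 5) if win[j] != fixed[j])
        if mm <= 1:
            ic3_hits.append(MotifHit("FSTC(LP)H", i, mm))
    cys = [i for i, a in enumerate(seq) if a == "C"]
    return MotifReport(dry_hits=dry_hits, ic3_hits=ic3_hits, cysteines=cys)


# ---------------------------------------------------------------------------
# family assignment
# ---------------------------------------------------------------------------

def _panel_family(rec: SequenceRecord) -> str:
    for tok in (rec.description or "").replace(";", " ").split():
        if tok.startswith("family="):
            return tok[len("family="):]
    return rec.id


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    return aligner


def global_identity(a: str, b: str, aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity over aligned residue pairs of the best global alignment."""
    aligner = aligner or _make_aligner()
    aln = aligner.align(a.replace("*", ""), b.replace("*", ""))[0]
    matches = aligned = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        aligned += e1 - s1
        matches += sum(1 for x, y in zip(a[s1:e1], b[s2:e2]) if x == y)
    if aligned == 0:
        return 0.0
    return matches / aligned


def assign_family(protein: SequenceRecord | str, reference_panel: list[SequenceRecord],
                  min_identity: float = 0.4) -> str:
    """Family of the best-identity panel member, or "unknown" below threshold.

    Ties break deterministically by panel order.
    """
    if not reference_panel:
        raise ValueError("empty reference panel")
    seq = protein.seq if isinstance(protein, SequenceRecord) else protein
    aligner = _make_aligner()
    best_fam, best_id = "unknown", -1.0
    for rec in reference_panel:
        ident = global_identity(seq, rec.seq, aligner)
        if ident > best_id:
            best_fam, best_id = _panel_family(rec), ident
    return best_fam if best_id >= min_identity else "unknown"


# ---------------------------------------------------------------------------
# conservation profile
# ---------------------------------------------------------------------------

@dataclass
class ConservationProfile:
    """Per-column residue frequencies and information content in bits."""

    frequencies: np.ndarray          # n_cols x 20, rows sum to 1 (or 0 if all-gap)
    information: np.ndarray          # n_cols, in [0, log2 20]
    all_gap: np.ndarray              # boolean flags for undefined columns
    domain_labels: list[str] | None = None


def conservation_profile(msa: list[SequenceRecord],
                         domains: list[tuple[str, int, int]] | None = None) -> ConservationProfile:
    """Column frequencies (gaps ignored) and information = log2(20) - H."""
    if len(msa) < 2:
        raise ValueError("conservation profile needs at least 2 rows")
    rows = [r.seq.upper() for r in msa]
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment")
    freqs = np.zeros((width, 20))
    for r in rows:
        for j, a in enumerate(r):
            k = _AA_INDEX.get(a)
            if k is not None:
                freqs[j, k] += 1
    totals = freqs.sum(axis=1)
    all_gap = totals == 0
    freqs[~all_gap] /= totals[~all_gap, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    info = np.where(all_gap, np.nan, np.log2(20.0) + plogp.sum(axis=1))
    labels = None
    if domains is not None:
        labels = ["?"] * width
        for name, a, b in domains:
            for j in range(a, min(b, width)):
                labels[j] = name
    return ConservationProfile(frequencies=freqs, information=info,
                               all_gap=all_gap, domain_labels=labels)


# ---------------------------------------------------------------------------
# transmembrane topology
# ---------------------------------------------------------------------------

@dataclass
class TmAnnotation:
    segments: list[tuple[int, int]]   # 0-based half-open TM spans, N->C order
    labels: list[str]                 # per-residue domain label (TM1.., IC.., EC.., N, C)


def predict_tm_domains(protein: SequenceRecord | str, window: int = 19,
                       threshold: float = 1.6) -> TmAnnotation:
    """Kyte-Doolittle TM segments with class-A GPCR loop labeling.

    Maximal runs of window centers above threshold become TM segments,
    expanded or split so every segment spans 17-25 residues.  Loops
    alternate EC/IC assuming an extracellular N-terminus.
    """
    seq = (protein.seq if isinstance(protein, SequenceRecord) else protein).upper()
    n = len(seq)
    if n <= window:
        raise ValueError(f"sequence length {n} must exceed the window {window}")
    kd = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in seq])
    half = window // 2
    means = np.convolve(kd, np.ones(window) / window, mode="valid")  # centers half..n-half-1
    above = means > threshold
    # maximal center runs, merging gaps of <= 2 centers
    runs: list[list[int]] = []
    i = 0
    while i < len(above):
        if above[i]:
            j = i
            while j + 1 < len(above) and above[j + 1]:
                j += 1
            if runs and i - runs[-1][1] - 1 <= 2:
                runs[-1][1] = j
            else:
                runs.append([i, j])
            i = j + 1
        else:
            i += 1
    segments: list[tuple[int, int]] = []
    for i0, i1 in runs:
        a, b = i0 + half, i1 + half + 1  # residue span of the center run
        length = b - a
        if length < 17:
            grow = 17 - length
            a = max(0, a - grow // 2 - grow % 2)
            b = min(n, a + 17)
            a = max(0, b - 17)
        elif length > 25:
            pieces = int(np.ceil(length / 25))
            if (b - a) / pieces >= 17:
                cuts = np.linspace(a, b, pieces + 1).round().astype(int)
                for p in range(pieces):
                    segments.append((int(cuts[p]), int(cuts[p + 1])))
                continue
            mid = (a + b) // 2
            a, b = mid - 12, mid + 13
        segments.append((int(a), int(b)))
    segments.sort()
    labels = ["?"] * n
    n_ic = n_ec = 0
    prev_end = 0
    for t, (a, b) in enumerate(segments, start=1):
        if t == 1:
            lab = "N"
        elif t % 2 == 0:  # loop after an odd-numbered TM is intracellular
            n_ic += 1
            lab = f"IC{n_ic}"
        else:
            n_ec += 1
            lab = f"EC{n_ec}"
        for j in range(prev_end, a):
            labels[j] = lab
        for j in range(a, b):
            labels[j] = f"TM{t}"
        prev_end = b
    for j in range(prev_end, n):
        labels[j] = "C" if segments else "?"
    return TmAnnotation(segments=segments, labels=labels)
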