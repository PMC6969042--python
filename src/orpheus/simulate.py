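"""Synthetic genomes, gene repertoires and codon alignments with known truth.

The generator emulates the study system: single-exon olfactory-receptor
genes of ~312 amino acids carrying the canonical motifs (MAYDRYVAIC at the
TM3/IC2 boundary, FSTC(L|P)H at the end of IC3, conserved cysteines in EC1
and EC2, prolines in TM7), planted in assembly contigs as intact genes,
pseudogenes (premature stop or 1-2 nt frameshift), partial genes (missing
start or stop but internal to the contig), contig-edge-truncated fragments,
and non-OR decoys.  Every planted locus is recorded in a truth table so
recovery can be scored exactly.

Design choices that keep the printed classification rules identifiable at
low divergence: planted loci get an in-frame stop codon 0-9 codons upstream
(ordinary stop context a real locus would have); divergence substitutions
never create new methionines, and the template carries no Met outside the
start codon and the MAYDRYVAIC motif, so the first-ATG rule lands on the
intended start; disruptions are placed in the codon window [110, 200] so
both fragments of a broken gene pass the 75-aa ORF filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .codon import MG94, CODONS, CodonAlignment, simulate_codon_states
from .io import GenomicInterval, SequenceRecord, reverse_complement

# Kyte-Doolittle hydropathy (shared with TM prediction)
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

_TM_AAS = list("IVLFA")
_LOOP_AAS = list("DEKRNQSTG")
_SUB_AAS = [a for a in "ACDEFGHIKLNPQRSTVWY"]  # substitutions never create Met

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    if set(_codon) <= set("ACGT"):
        _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _v in _AA_TO_CODONS.values():
    _v.sort()

_STOPS = sorted(standard_dna_table.stop_codons)
_SAFE_CODONS = [c for c in CODONS if c != "ATG"]  # sense, non-start

# domain layout of the 312-aa template (0-based half-open); the C tail
# stretches to the requested length
_CORE_SEGMENTS = [
    ("N", 0, 20), ("TM1", 20, 41), ("IC1", 41, 56), ("TM2", 56, 77),
    ("EC1", 77, 93), ("TM3", 93, 114), ("IC2", 114, 129), ("TM4", 129, 150),
    ("EC2", 150, 166), ("TM5", 166, 187), ("IC3", 187, 209), ("TM6", 209, 230),
    ("EC3", 230, 253), ("TM7", 253, 274), ("C", 274, None),
]
_MOTIF_DRY = ("MAYDRYVAIC", 104)      # ends flush with TM3
_MOTIF_IC3 = ("FSTCLH", 203)          # ends flush with IC3
_CYS_POSITIONS = (85, 157)            # EC1, EC2
_PRO_POSITIONS = (260, 265)           # TM7


def template_domains(length_aa: int = 312) -> list[tuple[str, int, int]]:
    """Domain layout (label, start, end) of the synthetic OR template."""
    segs = []
    for label, a, b in _CORE_SEGMENTS:
        segs.append((label, a, length_aa if b is None else b))
    return segs


def conserved_positions(length_aa: int = 312) -> set[int]:
    pos = {0}
    pos.update(range(_MOTIF_DRY[1], _MOTIF_DRY[1] + len(_MOTIF_DRY[0])))
    pos.update(range(_MOTIF_IC3[1], _MOTIF_IC3[1] + len(_MOTIF_IC3[0])))
    pos.update(_CYS_POSITIONS)
    pos.update(_PRO_POSITIONS)
    return pos


def make_or_template(seed: int, length_aa: int = 312):
    """A synthetic OR protein with 7 TM stretches and the canonical motifs.

    Returns ``(SequenceRecord, motif_map)`` where the motif map records each
    motif's 0-based start plus the domain segmentation.
    """
    if length_aa < 276:
        raise ValueError(
            f"length_aa={length_aa} is too short to host the 7-TM architecture "
            "and both canonical motifs (need >= 276)"
        )
    rng = np.random.default_rng(seed)
    aa = [""] * length_aa
    for label, a, b in template_domains(length_aa):
        pool = _TM_AAS if label.startswith("TM") else _LOOP_AAS
        for i in range(a, b):
            aa[i] = pool[rng.integers(len(pool))]
    aa[0] = "M"
    for motif, start in (_MOTIF_DRY, _MOTIF_IC3):
        aa[start : start + len(motif)] = list(motif)
    for p in _CYS_POSITIONS:
        aa[p] = "C"
    for p in _PRO_POSITIONS:
        aa[p] = "P"
    seq = "".join(aa)
    motif_map = {
        "MAYDRYVAIC": _MOTIF_DRY[1],
        "FSTCLH": _MOTIF_IC3[1],
        "cysteines": list(_CYS_POSITIONS),
        "prolines": list(_PRO_POSITIONS),
        "segments": {label: (a, b) for label, a, b in template_domains(length_aa)},
    }
    return SequenceRecord(id="or_template", seq=seq, alphabet="protein"), motif_map


def diverge_protein(aa_seq: str, divergence: float, rng: np.random.Generator,
                    frozen: set[int] | None = None) -> str:
    """i.i.d. substitutions at rate ``divergence`` outside frozen positions."""
    frozen = frozen if frozen is not None else conserved_positions(len(aa_seq))
    out = list(aa_seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < divergence:
            choices = [a for a in _SUB_AAS if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def backtranslate(aa_seq: str, rng: np.random.Generator) -> str:
    """Uniform-codon-usage back-translation (no codon bias model)."""
    return "".join(
        _AA_TO_CODONS[a][rng.integers(len(_AA_TO_CODONS[a]))] for a in aa_seq
    )


def make_seed_msa(seed: int, n_seqs: int = 12, divergence: float = 0.05,
                  length_aa: int = 312) -> list[SequenceRecord]:
    """Ungapped alignment of template variants, the input for profile building."""
    template, _ = make_or_template(seed, length_aa)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    return [
        SequenceRecord(id=f"seedvar{i:02d}",
                       seq=diverge_protein(template.seq, divergence, rng),
                       alphabet="protein")
        for i in range(n_seqs)
    ]


def make_family_templates(seed: int, families: list[str] | None = None,
                          spread: float = 0.35, length_aa: int = 312):
    """Family-tagged reference templates; later families diverge by ``spread``."""
    families = families or ["14j1-like", "5v1-like"]
    base, motif_map = make_or_template(seed, length_aa)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    out = {}
    for i, fam in enumerate(families):
        seq = base.seq if i == 0 else diverge_protein(base.seq, spread, rng)
        out[fam] = SequenceRecord(id=f"panel_{fam}", seq=seq, alphabet="protein",
                                  description=f"family={fam}")
    return out, motif_map


# ---------------------------------------------------------------------------
# gene planting
# ---------------------------------------------------------------------------

@dataclass
class PlantedGeneTruth:
    """One row of ground truth per planted gene."""

    gene_id: str
    contig_id: str
    interval: GenomicInterval
    true_class: str          # intact | partial | pseudogene | truncated | decoy
    family: str
    disruption: dict | None = None


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _safe_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), size=n))


def _stop(rng: np.random.Generator) -> str:
    return _STOPS[rng.integers(len(_STOPS))]


def plant_genes(n_intact: int, n_pseudo: int, n_partial: int, n_truncated: int,
                n_decoys: int, contig_len: int = 5000, divergence: float = 0.05,
                seed: int = 0, gammac_fraction: float = 0.85):
    """Plant OR genes of every integrity class, one locus per contig.

    Returns ``(contigs, truths)``.  Gene families mirror the repertoire's
    composition: most genes derive from the gamma-c-like template, the rest
    from a second, 35%-diverged gamma-like template.  Decoys are random-codon
    ORFs with no OR motifs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    fam_templates, _ = make_family_templates(seed)
    fam_names = list(fam_templates)
    length_aa = len(next(iter(fam_templates.values())).seq)
    gene_nt_len = 3 * length_aa + 3
    min_len = gene_nt_len + 2 * 1000 + 60
    if contig_len < min_len:
        raise ValueError(
            f"infeasible packing: contig_len={contig_len} cannot host a "
            f"{gene_nt_len} nt gene with 1 kb flanks (need >= {min_len})"
        )
    frozen = conserved_positions(length_aa)

    contigs: list[SequenceRecord] = []
    truths: list[PlantedGeneTruth] = []
    counter = 0

    def new_ids():
        nonlocal counter
        counter += 1
        return f"gene{counter:04d}", f"contig{counter:04d}"

    def sample_family() -> str:
        return fam_names[0] if rng.random() < gammac_fraction or len(fam_names) == 1 \
            else fam_names[1 + rng.integers(len(fam_names) - 1)]

    def gene_nt(family: str) -> str:
        aa = diverge_protein(fam_templates[family].seq, divergence, rng, frozen)
        return backtranslate(aa, rng) + _stop(rng)

    def build_contig(cassette: str, gene_span: tuple[int, int],
                     strand: str, edge: str | None = None):
        """Embed a cassette; ``edge`` pins it to a contig boundary."""
        if edge is None:
            room = contig_len - len(cassette)
            left = int(rng.integers(1000, room - 1000 + 1))
            right = contig_len - len(cassette) - left
        elif edge == "left":
            left, right = 0, contig_len - len(cassette)
        else:
            left, right = contig_len - len(cassette), 0
        seq = _random_dna(rng, left) + cassette + _random_dna(rng, right)
        a, b = gene_span
        fwd_start, fwd_end = left + a, left + b
        if strand == "-":
            seq = reverse_complement(seq)
            fwd_start, fwd_end = len(seq) - (left + b), len(seq) - (left + a)
        return seq, fwd_start, fwd_end

    def plant(true_class: str, variant: int):
        gene_id, contig_id = new_ids()
        strand = "+" if rng.random() < 0.5 else "-"
        family = sample_family() if true_class != "decoy" else "decoy"
        disruption = None
        edge = None
        if true_class == "decoy":
            from .orfs import translate

            while True:
                nt = "ATG" + _safe_codons(rng, length_aa - 1) + _stop(rng)
                if "MAYDRYVAIC" not in translate(nt):
                    break
        else:
            nt = gene_nt(family)

        upstream = _stop(rng) + _safe_codons(rng, int(rng.integers(0, 10)))
        downstream = ""

        if true_class == "pseudogene":
            k = int(rng.integers(110, 201))  # both fragments pass the 75-aa filter
            if variant % 2 == 0:
                nt = nt[: 3 * k] + _stop(rng) + nt[3 * k + 3 :]
                disruption = {"type": "premature_stop", "codon": k}
            else:
                j = 3 * k + int(rng.integers(0, 3))
                ndel = int(rng.integers(1, 3))
                nt = nt[:j] + nt[j + ndel :]
                disruption = {"type": "frameshift", "nt": j, "indel": -ndel}
        elif true_class == "partial":
            if variant % 2 == 0:
                nt = "CTG" + nt[3:]
                disruption = {"type": "missing_start"}
            else:
                nt = nt[:-3]  # drop the stop; read-through continues downstream
                downstream = "".join(
                    c for c in (_SAFE_CODONS[i] for i in
                                rng.integers(0, len(_SAFE_CODONS),
                                             size=int(rng.integers(40, 51))))
                ) + _stop(rng)
                disruption = {"type": "missing_stop"}
        elif true_class == "truncated":
            keep = int(rng.integers(90, 241))  # retained codons
            if variant % 2 == 0:  # 5' end cut by the boundary
                nt = nt[len(nt) - 3 * keep - 3 :]
                upstream = ""
                edge = "left"
                disruption = {"type": "edge_cut", "side": 5}
            else:                 # 3' end cut
                nt = nt[: 3 * keep]
                downstream = ""
                edge = "right"
                disruption = {"type": "edge_cut", "side": 3}

        if edge == "left":
            cassette = nt + downstream
            span = (0, len(nt))
        elif edge == "right":
            cassette = upstream + nt
            span = (len(upstream), len(upstream) + len(nt))
        else:
            cassette = upstream + nt + downstream
            span = (len(upstream), len(upstream) + len(nt))
        seq, s, e = build_contig(cassette, span, strand, edge)
        contigs.append(SequenceRecord(id=contig_id, seq=seq, alphabet="dna"))
        truths.append(
            PlantedGeneTruth(
                gene_id=gene_id,
                contig_id=contig_id,
                interval=GenomicInterval(contig_id, s, e, strand),
                true_class=true_class,
                family=family,
                disruption=disruption,
            )
        )

    for i in range(n_intact):
        plant("intact", i)
    for i in range(n_pseudo):
        plant("pseudogene", i)
    for i in range(n_partial):
        plant("partial", i)
    for i in range(n_truncated):
        plant("truncated", i)
    for i in range(n_decoys):
        plant("decoy", i)
    return contigs, truths


def truth_table(truths: list[PlantedGeneTruth]):
    import pandas as pd

    rows = []
    for t in truths:
        rows.append(
            {
                "gene_id": t.gene_id,
                "contig_id": t.contig_id,
                "start": t.interval.start,
                "end": t.interval.end,
                "strand": t.interval.strand,
                "true_class": t.true_class,
                "family": t.family,
                "disruption": "" if t.disruption is None else
                              ";".join(f"{k}={v}" for k, v in t.disruption.items()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# codon alignments with known site-wise omega
# ---------------------------------------------------------------------------

@dataclass
class SimulatedAlignmentTruth:
    """Ground truth for one simulated codon alignment."""

    tree: str                      # newick
    site_omega: np.ndarray         # per-codon-site omega, length S
    kappa: float = 2.0
    breakpoint: int | None = None  # 1-based codon index; sites > breakpoint use tree2
    tree2: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.site_omega = np.asarray(self.site_omega, dtype=float)
        if (self.site_omega < 0).any():
            raise ValueError("site omegas must be nonnegative")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")
        if self.breakpoint is not None:
            if not (0 < self.breakpoint < len(self.site_omega)):
                raise ValueError("breakpoint outside the alignment")
            if self.tree2 is None:
                raise ValueError("a breakpoint requires a second topology (tree2)")


def balanced_tree(n_taxa: int, total_length: float = 5.0,
                  labels: list[str] | None = None) -> str:
    """Symmetric tree with uniform branch lengths (newick).

    The standard layout for per-site selection calibration and power
    studies: signal is spread evenly over branches, so counting methods see
    as many reconstructable changes as the total depth allows.
    """
    labels = labels or [f"t{i:02d}" for i in range(n_taxa)]

    def build(ls):
        if len(ls) == 1:
            return ls[0]
        mid = len(ls) // 2
        return f"({build(ls[:mid])}:BL,{build(ls[mid:])}:BL)"

    s = build(labels) + ";"
    bl = total_length / s.count(":BL")
    return s.replace("BL", f"{bl:.8f}")


def random_coalescent_tree(n_taxa: int, seed: int, total_length: float = 5.0,
                           labels: list[str] | None = None) -> str:
    """Random Kingman-style tree as newick, scaled to a total branch length."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    labels = labels or [f"t{i:02d}" for i in range(n_taxa)]
    nodes = [(lab, 0.0) for lab in labels]  # (newick, height)
    while len(nodes) > 1:
        k = len(nodes)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        dt = rng.exponential(2.0 / (k * (k - 1)))
        h = max(nodes[i][1], nodes[j][1]) + dt
        (si, hi), (sj, hj) = nodes[i], nodes[j]
        merged = (f"({si}:{h - hi:.10f},{sj}:{h - hj:.10f})", h)
        nodes = [nodes[m] for m in range(k) if m not in (i, j)] + [merged]
    newick = nodes[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tl = sum(e.length or 0.0 for e in tree.preorder_edge_iter())
    f = total_length / tl
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= f
    return tree.as_string(schema="newick", suppress_rooting=True,
                          unquoted_underscores=True).strip()


def simulate_codon_alignment(truth: SimulatedAlignmentTruth,
                             n_taxa: int | None = None) -> CodonAlignment:
    """Evolve a codon alignment under the truth's trees/kappa/site omegas."""
    tree1 = dendropy.Tree.get(data=truth.tree, schema="newick")
    leaves = sorted(lf.taxon.label for lf in tree1.leaf_node_iter())
    if n_taxa is not None and len(leaves) != n_taxa:
        raise ValueError(f"tree has {len(leaves)} leaves, expected {n_taxa}")
    for e in tree1.preorder_edge_iter():
        if e.length is not None and e.length < 0:
            raise ValueError("branch lengths must be positive")
    model = MG94(truth.kappa)
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 505]))
    S = len(truth.site_omega)
    if truth.breakpoint is None:
        parts = [(tree1, np.arange(S))]
    else:
        tree2 = dendropy.Tree.get(data=truth.tree2, schema="newick")
        b = truth.breakpoint
        parts = [(tree1, np.arange(b)), (tree2, np.arange(b, S))]
    codes = np.empty((len(leaves), S), dtype=np.int32)
    order = {t: i for i, t in enumerate(leaves)}
    for tree, sites in parts:
        leaf_states = simulate_codon_states(model, tree, truth.site_omega[sites], rng)
        for taxon, states in leaf_states.items():
            codes[order[taxon], sites] = states
    return CodonAlignment(taxa=leaves, codes=codes)
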