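"""Integrity classification of OR-positive loci and repertoire bookkeeping.

Classification follows explicit precedence rules on each locus:

1. *truncated* — the reading stretch is cut by a contig boundary;
2. *pseudogene* — a premature in-frame stop interrupts an otherwise
   full-span homology envelope, or a frameshift is inferred from two
   same-strand profile hits in different frames within 100 nt whose
   envelopes tile the profile (the partners are merged into one record);
3. *intact* — start and stop codons present and the translated length falls
   within [0.9, 1.1] x profile length;
4. *partial* — an incomplete coding region internal to the contig.

The module also summarizes a repertoire as a family-by-integrity count
table (with clade totals and per-scaffold locus spacing) and ships the
published family-level counts of the Cory's shearwater OR repertoire as a
fixture for bookkeeping checks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import HmmHit
from .io import GenomicInterval
from .orfs import OrfRecord

MERGE_WINDOW_NT = 100
INTACT_LENGTH_TOL = 0.10
TILE_COVERAGE = 0.80


@dataclass
class ORGene:
    """An OR-positive locus with its integrity call.

    A frameshift pseudogene merges two ORFs; ``orf`` is then the 5'-most
    piece in gene orientation and ``partner_orfs`` holds the rest.
    """

    gene_id: str
    orf: OrfRecord
    family: str
    integrity: str                 # intact | partial | pseudogene | truncated
    disruptions: list[dict]
    interval: GenomicInterval
    bit_score: float
    e_value: float
    partner_orfs: list[OrfRecord] = field(default_factory=list)

    @property
    def contig_id(self) -> str:
        return self.interval.contig_id


def _coverage(envs: list[tuple[int, int, int, int]], L: int) -> float:
    covered = np.zeros(L + 1, dtype=bool)
    for _, _, p0, p1 in envs:
        covered[p0 : p1 + 1] = True
    return covered[1:].sum() / L


def _cluster_entries(entries: list[tuple[OrfRecord, HmmHit]], L: int,
                     window: int = MERGE_WINDOW_NT):
    """Group same-strand hit ORFs whose envelopes tile the profile.

    ``entries`` must share contig and strand.  Consecutive ORFs (by forward
    coordinate) are chained when they are within ``window`` nt and the
    combined envelope coverage reaches the tiling threshold.
    """
    entries = sorted(entries, key=lambda eo: (eo[0].interval.start, eo[0].interval.end))
    clusters: list[list[tuple[OrfRecord, HmmHit]]] = []
    for ent in entries:
        if clusters:
            prev = clusters[-1]
            gap = ent[0].interval.start - max(o.interval.end for o, _ in prev)
            cov = _coverage([o_h[1].envelope for o_h in prev] + [ent[1].envelope], L)
            if gap <= window and cov >= TILE_COVERAGE:
                prev.append(ent)
                continue
        clusters.append([ent])
    return clusters


def _classify_cluster(cluster: list[tuple[OrfRecord, HmmHit]], L: int):
    """(integrity, disruptions, interval, members) for one locus cluster."""
    orfs = [o for o, _ in cluster]
    strand = orfs[0].interval.strand
    contig = orfs[0].interval.contig_id
    start = min(o.interval.start for o in orfs)
    end = max(o.interval.end for o in orfs)
    interval = GenomicInterval(contig, start, end, strand)
    disruptions: list[dict] = []

    if any(o.edge5 or o.edge3 for o in orfs):
        side = 5 if any(o.edge5 for o in orfs) else 3
        return "truncated", [{"type": "edge_cut", "side": side}], interval

    if len(cluster) > 1:
        # order pieces 5'->3' in gene orientation
        ordered = sorted(cluster, key=lambda oh: oh[0].interval.start,
                         reverse=(strand == "-"))
        frames = {o.frame for o, _ in cluster}
        if len(frames) > 1:
            for (a, _), (b, _) in zip(ordered, ordered[1:]):
                disruptions.append({"type": "frameshift", "between": (a.orf_id, b.orf_id)})
        else:
            for (a, ha), _ in zip(ordered, ordered[1:]):
                disruptions.append({"type": "premature_stop", "codon": ha.envelope[3]})
        return "pseudogene", disruptions, interval

    orf = orfs[0]
    aa_len = len(orf.aa_seq)
    if orf.has_start and orf.has_stop and \
            (1 - INTACT_LENGTH_TOL) * L <= aa_len <= (1 + INTACT_LENGTH_TOL) * L:
        return "intact", [], interval
    hit = cluster[0][1]
    if not orf.has_start or hit.envelope[2] > 1 + 0.05 * L:
        disruptions.append({"type": "missing_start"})
    if not orf.has_stop or aa_len > (1 + INTACT_LENGTH_TOL) * L:
        disruptions.append({"type": "missing_stop"})
    if not disruptions:
        disruptions.append({"type": "incomplete"})
    return "partial", disruptions, interval


def classify_repertoire(orfs: list[OrfRecord], hits: list[HmmHit], profile_len: int,
                        families: dict[str, str] | None = None,
                        window: int = MERGE_WINDOW_NT) -> list[ORGene]:
    """Turn hit-bearing ORFs into classified ORGene loci (one per cluster)."""
    omap = {o.orf_id: o for o in orfs}
    best: dict[str, HmmHit] = {}
    for h in hits:
        if h.orf_id not in best or h.bit_score > best[h.orf_id].bit_score:
            best[h.orf_id] = h
    groups: dict[tuple[str, str], list[tuple[OrfRecord, HmmHit]]] = {}
    for orf_id, h in best.items():
        o = omap[orf_id]
        groups.setdefault((o.interval.contig_id, o.interval.strand), []).append((o, h))
    genes: list[ORGene] = []
    for (contig, strand), entries in sorted(groups.items()):
        for cluster in _cluster_entries(entries, profile_len, window):
            integrity, disruptions, interval = _classify_cluster(cluster, profile_len)
            ordered = sorted(cluster, key=lambda oh: oh[0].interval.start,
                             reverse=(strand == "-"))
            lead_orf, lead_hit = ordered[0]
            fam = (families or {}).get(lead_orf.orf_id, "unknown")
            genes.append(
                ORGene(
                    gene_id="",
                    orf=lead_orf,
                    family=fam,
                    integrity=integrity,
                    disruptions=disruptions,
                    interval=interval,
                    bit_score=max(h.bit_score for _, h in cluster),
                    e_value=min(h.e_value for _, h in cluster),
                    partner_orfs=[o for o, _ in ordered[1:]],
                )
            )
    genes.sort(key=lambda g: (g.contig_id, g.interval.start))
    for i, g in enumerate(genes, start=1):
        g.gene_id = f"ORgene{i:04d}"
    return genes


def classify_integrity(orf: OrfRecord, hit: HmmHit, sibling_orfs_on_contig, profile_len: int):
    """Classify one OR-positive ORF given its hit-bearing contig siblings.

    ``sibling_orfs_on_contig`` is a list of (OrfRecord, HmmHit) pairs on the
    same contig (the ORF itself may be included or not).  Returns
    ``(integrity, disruptions)``.
    """
    if hit is None:
        raise ValueError(f"classify_integrity called on non-OR ORF {orf.orf_id}")
    entries = [(orf, hit)]
    for o, h in sibling_orfs_on_contig:
        if o.orf_id != orf.orf_id and o.interval.strand == orf.interval.strand:
            entries.append((o, h))
    for cluster in _cluster_entries(entries, profile_len):
        if any(o.orf_id == orf.orf_id for o, _ in cluster):
            integrity, disruptions, _ = _classify_cluster(cluster, profile_len)
            return integrity, disruptions
    raise AssertionError("unreachable: ORF not in any cluster")


# ---------------------------------------------------------------------------
# repertoire summaries
# ---------------------------------------------------------------------------

INTEGRITY_CLASSES = ("intact", "partial", "pseudogene", "truncated")


def round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class RepertoireSummary:
    by_family: pd.DataFrame          # family x integrity counts
    totals: dict[str, int]           # per integrity class + "total"
    by_clade: dict[str, int]
    intact_share_pct: int | None     # of non-edge loci, round-half-up
    broken_to_intact_ratio: float | None
    loci_per_scaffold: pd.DataFrame
    inter_locus_distances: pd.DataFrame


def loci_per_scaffold(genes: list[ORGene]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-scaffold locus counts and inter-ORF gaps on multi-locus scaffolds."""
    per: dict[str, list[ORGene]] = {}
    for g in genes:
        per.setdefault(g.contig_id, []).append(g)
    count_rows, dist_rows = [], []
    for contig in sorted(per):
        gs = sorted(per[contig], key=lambda g: g.interval.start)
        count_rows.append({
            "contig_id": contig,
            "n_loci": len(gs),
            "integrities": ",".join(g.integrity for g in gs),
        })
        for a, b in zip(gs, gs[1:]):
            dist_rows.append({
                "contig_id": contig,
                "gene_a": a.gene_id,
                "gene_b": b.gene_id,
                "distance_bp": b.interval.start - a.interval.end,
            })
    return (pd.DataFrame(count_rows, columns=["contig_id", "n_loci", "integrities"]),
            pd.DataFrame(dist_rows, columns=["contig_id", "gene_a", "gene_b", "distance_bp"]))


def summarize_repertoire(genes: list[ORGene],
                         clade_map: dict[str, str] | None = None) -> RepertoireSummary:
    clade_map = clade_map or {}
    rows = [{"family": g.family, "integrity": g.integrity} for g in genes]
    df = pd.DataFrame(rows, columns=["family", "integrity"])
    by_family = (
        df.pivot_table(index="family", columns="integrity", aggfunc="size", fill_value=0)
        .reindex(columns=list(INTEGRITY_CLASSES), fill_value=0)
        if len(df) else
        pd.DataFrame(columns=list(INTEGRITY_CLASSES))
    )
    totals = {c: int((df["integrity"] == c).sum()) for c in INTEGRITY_CLASSES}
    totals["total"] = len(genes)
    by_clade: dict[str, int] = {}
    for g in genes:
        clade = clade_map.get(g.family, "unknown")
        by_clade[clade] = by_clade.get(clade, 0) + 1
    non_edge = totals["intact"] + totals["partial"] + totals["pseudogene"]
    share = round_half_up(100 * totals["intact"] / non_edge) if non_edge else None
    ratio = ((totals["partial"] + totals["pseudogene"]) / totals["intact"]
             if totals["intact"] else None)
    counts, dists = loci_per_scaffold(genes)
    return RepertoireSummary(
        by_family=by_family,
        totals=totals,
        by_clade=by_clade,
        intact_share_pct=share,
        broken_to_intact_ratio=ratio,
        loci_per_scaffold=counts,
        inter_locus_distances=dists,
    )


# ---------------------------------------------------------------------------
# published counts fixture
# ---------------------------------------------------------------------------

def load_published_repertoire() -> pd.DataFrame:
    """Family-level integrity counts of the published shearwater OR repertoire."""
    with importlib.resources.files("orpheus.data").joinpath("repertoire_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def published_bookkeeping() -> dict[str, float]:
    """Arithmetic checks over the published per-family counts.

    The total comes from the gene-count column; intact/pseudogene totals and
    the intact gamma-c count come from the integrity breakdown.  The
    non-edge arithmetic uses the published non-edge class counts (20 intact,
    15 pseudogene, 21 partial).
    """
    df = load_published_repertoire()
    out = {
        "total_or_genes": int(df["n_genes"].sum()),
        "intact_total": int(df["intact"].sum()),
        "pseudogene_total": int(df["pseudogene"].sum()),
        "intact_gamma_c": int(df.loc[df["clade"] == "gamma-c", "intact"].sum()),
    }
    n_intact, n_pseudo, n_partial = 20, 15, 21
    non_edge = n_intact + n_pseudo + n_partial
    out["non_edge_total"] = non_edge
    out["intact_share_pct"] = round_half_up(100 * n_intact / non_edge)
    out["pseudo_share_pct"] = round_half_up(100 * n_pseudo / non_edge)
    out["partial_share_pct"] = round_half_up(100 * n_partial / non_edge)
    out["broken_to_intact_ratio"] = (n_pseudo + n_partial) / n_intact
    return out
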