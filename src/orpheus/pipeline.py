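"""End-to-end orchestration: contigs -> ORFs -> OR genes -> trees -> selection.

The pipeline mirrors the study design: mine ORFs from assembly contigs,
identify OR genes with profile HMMs, classify their integrity, align the
intact genes, profile conservation and topology, build a bootstrapped NJ
tree, and run recombination-aware per-site selection on the intact-gene
codon alignment.  A single seed fans out to per-stage seeds by fixed
offsets, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, hmm as hmm_mod, integrity, io as io_mod, orfs as orfs_mod
from . import phylo, selection, simulate

log = logging.getLogger("orpheus")

STAGE_SEED_OFFSETS = {"simulate": 11, "search": 23, "bootstrap": 37, "gard": 53}


@dataclass
class PipelineConfig:
    """Paths, thresholds and toggles for one pipeline run."""

    outdir: str = "orpheus_out"
    contigs: str | None = None          # FASTA; None -> simulate a genome
    seed_msa: str | None = None         # gapped FASTA seed alignment
    partial_seed_msa: str | None = None # optional second (partial-gene) profile seed
    panel: str | None = None            # family-tagged reference proteins
    clade_map: dict[str, str] = field(default_factory=dict)
    external_sites: dict[str, list[int]] = field(default_factory=dict)

    min_aa: int = 75
    evalue: float = 1e-10
    n_null: int = 1000
    identity: float = 0.4
    alpha: float = 0.1
    bootstrap_reps: int = 100
    gard: bool = True
    gard_margin: int = 20
    gard_perm: int = 50
    gard_step: int = 4
    methods: list[str] = field(default_factory=lambda: ["slac", "fel"])
    seed: int = 0

    # synthetic-genome settings used when no contig FASTA is given
    sim_intact: int = 10
    sim_pseudo: int = 6
    sim_partial: int = 6
    sim_truncated: int = 12
    sim_decoys: int = 10
    sim_contig_len: int = 5000
    sim_divergence: float = 0.05

    def __post_init__(self) -> None:
        if self.min_aa <= 0 or self.evalue <= 0 or self.alpha <= 0 or self.identity <= 0:
            raise ValueError("thresholds must be positive")
        for name in ("contigs", "seed_msa", "partial_seed_msa", "panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    return (config.seed * 1009 + STAGE_SEED_OFFSETS[stage]) % (2**31 - 1)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; write per-stage outputs; return the run report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        log.info("stage: %s", name)
        report["stages"][name] = {}
        return report["stages"][name]

    # ------------------------------------------------------------------ inputs
    st = stage("inputs")
    truths = None
    if config.contigs is not None:
        contigs = io_mod.read_fasta(config.contigs, alphabet="dna")
    else:
        contigs, truths = simulate.plant_genes(
            config.sim_intact, config.sim_pseudo, config.sim_partial,
            config.sim_truncated, config.sim_decoys,
            contig_len=config.sim_contig_len, divergence=config.sim_divergence,
            seed=_stage_seed(config, "simulate"),
        )
        io_mod.write_fasta(contigs, out / "contigs.fa")
        simulate.truth_table(truths).to_csv(out / "truth.tsv", sep="\t", index=False)
    st["n_contigs"] = len(contigs)

    if config.seed_msa is not None:
        seed_msa = io_mod.read_fasta(config.seed_msa, alphabet="protein")
    else:
        seed_msa = simulate.make_seed_msa(_stage_seed(config, "simulate"))
    if config.panel is not None:
        panel = io_mod.read_fasta(config.panel, alphabet="protein")
    else:
        fam_templates, _ = simulate.make_family_templates(_stage_seed(config, "simulate"))
        panel = list(fam_templates.values())

    # ------------------------------------------------------------------- orfs
    st = stage("orfs")
    orf_list = orfs_mod.find_orfs_many(contigs, min_aa=config.min_aa)
    st["n_orfs"] = len(orf_list)

    # --------------------------------------------------------------- annotate
    st = stage("annotate")
    profile = hmm_mod.build_profile_hmm(seed_msa)
    hits = hmm_mod.search_orfs(profile, orf_list, e_cutoff=config.evalue,
                               n_null=config.n_null,
                               seed=_stage_seed(config, "search"), hmm_id="full")
    if config.partial_seed_msa is not None:
        partial_profile = hmm_mod.build_profile_hmm(
            io_mod.read_fasta(config.partial_seed_msa, alphabet="protein"))
        hits += hmm_mod.search_orfs(partial_profile, orf_list,
                                    e_cutoff=config.evalue, n_null=config.n_null,
                                    seed=_stage_seed(config, "search"),
                                    hmm_id="partial")
    st["n_hits"] = len(hits)
    orf_by_id = {o.orf_id: o for o in orf_list}
    families = {
        h.orf_id: annotate.assign_family(orf_by_id[h.orf_id].aa_seq, panel,
                                         min_identity=config.identity)
        for h in hits
    }

    # --------------------------------------------------------------- classify
    st = stage("classify")
    genes = integrity.classify_repertoire(orf_list, hits, profile.L,
                                          families=families)
    summary = integrity.summarize_repertoire(genes, config.clade_map)
    st["totals"] = summary.totals
    st["intact_share_pct"] = summary.intact_share_pct
    pd.DataFrame(
        [{"gene_id": g.gene_id, "contig": g.contig_id, "start": g.interval.start,
          "end": g.interval.end, "strand": g.interval.strand, "family": g.family,
          "integrity": g.integrity, "bit_score": g.bit_score, "e_value": g.e_value}
         for g in genes]
    ).to_csv(out / "genes.tsv", sep="\t", index=False)
    io_mod.write_gff3(genes, out / "genes.gff3",
                      contig_lengths={c.id: len(c.seq) for c in contigs})
    summary.by_family.to_csv(out / "repertoire_by_family.tsv", sep="\t")
    summary.loci_per_scaffold.to_csv(out / "loci_per_scaffold.tsv", sep="\t", index=False)

    # ------------------------------------------------- align intact genes only
    st = stage("align")
    intact = [g for g in genes if g.integrity == "intact"]
    st["n_intact"] = len(intact)
    if len(intact) < 4:
        report["warning"] = "fewer than 4 intact genes; tree/selection stages skipped"
        _write_report(report, out)
        return report
    proteins = [io_mod.SequenceRecord(id=g.gene_id, seq=g.orf.aa_seq,
                                      alphabet="protein") for g in intact]
    msa, residue_maps = hmm_mod.align_to_hmm(profile, proteins, return_maps=True)
    io_mod.write_fasta(msa, out / "intact_alignment.afa")
    profile_cons = annotate.conservation_profile(
        msa, domains=simulate.template_domains(profile.L) if profile.L >= 276 else None)
    np.savetxt(out / "conservation_information.tsv",
               profile_cons.information, fmt="%.4f")
    tm = annotate.predict_tm_domains(profile.consensus())
    st["n_tm_segments"] = len(tm.segments)
    motif_counts = {"MAYDRYVAIC": 0, "FSTC(LP)H": 0}
    for p in proteins:
        rep = annotate.scan_motifs(p)
        motif_counts["MAYDRYVAIC"] += rep.has_dry
        motif_counts["FSTC(LP)H"] += rep.has_ic3
    st["motif_counts"] = motif_counts

    # ------------------------------------------------------------------- tree
    st = stage("tree")
    tree = phylo.bootstrap_support(msa, n_reps=config.bootstrap_reps,
                                   seed=_stage_seed(config, "bootstrap"))
    io_mod.write_newick(tree, out / "intact_nj.nwk")
    st["root_to_tip"] = phylo.root_to_tip_lengths(tree)

    # -------------------------------------------------------------- selection
    st = stage("selection")
    cds = [io_mod.SequenceRecord(id=g.gene_id, seq=g.orf.nt_seq, alphabet="dna")
           for g in intact]
    aln = selection.codon_alignment_from_maps(msa, residue_maps, cds)
    if config.gard:
        bp = selection.detect_breakpoints(aln, margin=config.gard_margin,
                                          n_perm=config.gard_perm,
                                          seed=_stage_seed(config, "gard"),
                                          step=config.gard_step)
        partitions = bp
        st["breakpoint"] = bp.breakpoint
        st["breakpoint_p"] = bp.p_value
        (out / "breakpoints.json").write_text(json.dumps(
            {"breakpoint": bp.breakpoint, "improvement": bp.improvement,
             "p_value": bp.p_value, "partitions": bp.partitions}, indent=2))
    else:
        partitions = phylo.tree_from_msa(msa)
    site_results: dict[str, list] = {}
    if "slac" in config.methods:
        site_results["SLAC"] = selection.slac(aln, partitions, config.alpha)
    if "fel" in config.methods:
        site_results["FEL"] = selection.fel(aln, partitions, config.alpha)
    for name, sites in (config.external_sites or {}).items():
        site_results[name] = sites
    rows = []
    for method, res in site_results.items():
        if res and isinstance(res[0], selection.SiteSelectionResult):
            rows += [{"site": r.site, "method": r.method, "statistic": r.statistic,
                      "p_value": r.p_value, "call": r.call} for r in res]
    pd.DataFrame(rows).to_csv(out / "site_selection.tsv", sep="\t", index=False)
    tiers = selection.integrate_sites(site_results) if site_results else None
    if tiers:
        (out / "selection_tiers.json").write_text(json.dumps(tiers, indent=2))
        st["tiers"] = tiers

    if truths is not None:
        from collections import Counter

        planted = Counter(t.true_class for t in truths if t.true_class != "decoy")
        recovered = Counter(g.integrity for g in genes)
        report["recovery"] = {"planted": dict(planted), "recovered": dict(recovered)}
    _write_report(report, out)
    return report


def _write_report(report: dict, out: Path) -> None:
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
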