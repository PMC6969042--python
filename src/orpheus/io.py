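"""Sequence, interval and tree I/O with the pipeline's coordinate conventions.

All internal coordinates are 0-based half-open on the forward strand of the
contig; reverse-strand features carry ``strand == "-"`` and are translated
from the reverse complement.  Conversion to 1-based inclusive coordinates
happens only when GFF3 is emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = set("ACGTNacgtn")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*acdefghiklmnpqrstvwyx")


@dataclass
class SequenceRecord:
    """A named DNA or protein sequence."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = "dna"  # "dna" | "protein"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record has an empty id")
        if not self.seq:
            raise ValueError(f"sequence record {self.id!r} has an empty sequence")
        allowed = DNA_ALPHABET if self.alphabet == "dna" else PROTEIN_ALPHABET
        bad = set(self.seq) - allowed - {"-", "."}
        if bad:
            raise ValueError(
                f"record {self.id!r}: characters {sorted(bad)} not allowed for "
                f"alphabet {self.alphabet!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a contig, with strand."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def guess_alphabet(seq: str) -> str:
    return "dna" if set(seq.upper()) <= set("ACGTN") else "protein"


def read_fasta(path: str | Path, alphabet: str | None = None) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords, enforcing unique non-empty ids."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"record {rec.id!r} in {path} has an empty sequence")
        records.append(
            SequenceRecord(
                id=rec.id,
                seq=seq,
                description=rec.description[len(rec.id):].strip(),
                alphabet=alphabet or guess_alphabet(seq.replace("-", "").replace(".", "")),
            )
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    recs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def write_gff3(genes: Sequence, path: str | Path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write ORGene-like objects as GFF3 ``gene`` features.

    Input intervals are internal (0-based half-open); columns 4/5 are emitted
    1-based inclusive.  ``genes`` may be any objects exposing ``gene_id``,
    ``interval`` (GenomicInterval), ``family``, ``integrity`` and
    ``disruptions``.
    """
    lines = ["##gff-version 3"]
    for g in genes:
        iv: GenomicInterval = g.interval
        if contig_lengths is not None:
            clen = contig_lengths.get(iv.contig_id)
            if clen is not None and iv.end > clen:
                raise ValueError(
                    f"gene {g.gene_id}: interval end {iv.end} exceeds contig "
                    f"{iv.contig_id} length {clen}"
                )
        disruptions = getattr(g, "disruptions", []) or []
        dis = ",".join(str(d) for d in disruptions) if disruptions else "none"
        attrs = (
            f"ID={g.gene_id};family={getattr(g, 'family', 'unknown')};"
            f"integrity={getattr(g, 'integrity', 'NA')};disruptions={dis}"
        )
        lines.append(
            "\t".join(
                [
                    iv.contig_id,
                    "orpheus",
                    "gene",
                    str(iv.start + 1),
                    str(iv.end),
                    ".",
                    iv.strand,
                    ".",
                    attrs,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (path or literal string) into a dendropy Tree.

    Internal-node labels are interpreted as support values, the convention
    used for bootstrap percentages on major clades.
    """
    text = None
    if isinstance(source, Path) or (isinstance(source, str) and not source.lstrip().startswith("(")):
        text = Path(source).read_text()
    else:
        text = str(source)
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in Newick input")
    tree = dendropy.Tree.get(
        data=text,
        schema="newick",
        suppress_internal_node_taxa=True,
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length} in Newick input")
    # internal labels -> numeric supports where possible
    for node in tree.internal_nodes():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                node.support = None
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree with branch lengths and internal support labels."""
    for node in tree.internal_nodes():
        sup = getattr(node, "support", None)
        if sup is not None:
            node.label = f"{sup:g}"
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".9g",
    ).strip()
    if not text.endswith(";"):
        text += ";"
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
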