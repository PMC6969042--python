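"""Six-frame ORF discovery on assembly contigs.

An ORF is a maximal stop-free reading stretch (getorf-style).  The reported
CDS starts at the first ATG of the stretch when one exists; stretches cut by
the 5' contig boundary are reported from the cut so that edge-truncated gene
fragments keep their full homologous span.  Codons containing N translate to
X and never count as stop codons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .io import GenomicInterval, SequenceRecord, reverse_complement

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate("ACGT"):
    _BASE_CODE[ord(b)] = i
    _BASE_CODE[ord(b.lower())] = i

_STOP_CODONS = set(standard_dna_table.stop_codons)  # TAA, TAG, TGA

# 65-entry lookup: 0..63 = codon index (A=0,C=1,G=2,T=3), 64 = any-N codon
_AA_LUT = np.empty(65, dtype="U1")
for i0 in range(4):
    for i1 in range(4):
        for i2 in range(4):
            codon = "ACGT"[i0] + "ACGT"[i1] + "ACGT"[i2]
            idx = 16 * i0 + 4 * i1 + i2
            _AA_LUT[idx] = "*" if codon in _STOP_CODONS else standard_dna_table.forward_table[codon]
_AA_LUT[64] = "X"

_ATG_IDX = 16 * 0 + 4 * 3 + 2  # 14
_STOP_IDX = frozenset(
    16 * "ACGT".index(c[0]) + 4 * "ACGT".index(c[1]) + "ACGT".index(c[2])
    for c in _STOP_CODONS
)


def translate(nt_seq: str) -> str:
    """Translate DNA in frame 0; N-containing codons give X, stops give '*'."""
    codes = _codon_codes(nt_seq)
    return "".join(_AA_LUT[codes])


def _codon_codes(nt_seq: str) -> np.ndarray:
    arr = _BASE_CODE[np.frombuffer(nt_seq.encode(), dtype=np.uint8)]
    n_codon = len(arr) // 3
    arr = arr[: 3 * n_codon].reshape(n_codon, 3)
    codes = (16 * arr[:, 0] + 4 * arr[:, 1] + arr[:, 2]).astype(np.int16)
    codes[(arr == 4).any(axis=1)] = 64
    return codes


@dataclass
class OrfRecord:
    """A reported open reading frame in forward-contig coordinates."""

    orf_id: str
    interval: GenomicInterval
    frame: int
    nt_seq: str
    aa_seq: str
    has_start: bool
    has_stop: bool
    edge5: bool
    edge3: bool

    @property
    def strand(self) -> str:
        return self.interval.strand


def find_orfs(contig: SequenceRecord, min_aa: int = 75) -> list[OrfRecord]:
    """Enumerate ORFs with translated length >= ``min_aa`` in all six frames.

    Returned coordinates are always in forward-contig space; reverse-strand
    records carry strand '-' and their ``nt_seq`` is the reading-direction
    (reverse-complemented) sequence.
    """
    if contig.alphabet != "dna":
        raise ValueError(f"find_orfs requires a DNA contig, got {contig.alphabet!r}")
    L = len(contig.seq)
    results: list[OrfRecord] = []
    for strand in "+-":
        seq = contig.seq if strand == "+" else reverse_complement(contig.seq)
        for frame in range(3):
            sub = seq[frame:]
            codes = _codon_codes(sub)
            n = len(codes)
            if n == 0:
                continue
            is_stop = np.isin(codes, list(_STOP_IDX))
            stop_pos = np.flatnonzero(is_stop)
            # stretch boundaries in codon units: [b, e) stop-free
            starts = np.concatenate(([0], stop_pos + 1))
            ends = np.concatenate((stop_pos, [n]))
            for b, e in zip(starts, ends):
                if e - b < min_aa:
                    continue
                terminated = e < n and is_stop[e]
                edge5 = b == 0  # no upstream in-frame stop: cut by (or at) the boundary
                edge3 = not terminated
                if edge5:
                    cds_b = b
                    has_start = False
                else:
                    atg = np.flatnonzero(codes[b:e] == _ATG_IDX)
                    if atg.size:
                        cds_b = b + int(atg[0])
                        has_start = True
                    else:
                        cds_b = b
                        has_start = False
                aa_len = e - cds_b
                if aa_len < min_aa:
                    continue
                aa = "".join(_AA_LUT[codes[cds_b:e]])
                nt_end = int(frame + 3 * (e + (1 if terminated else 0)))
                nt_b = int(frame + 3 * cds_b)
                nt = sub[nt_b - frame : nt_end - frame]
                if strand == "+":
                    iv = GenomicInterval(contig.id, nt_b, nt_end, "+")
                else:
                    iv = GenomicInterval(contig.id, L - nt_end, L - nt_b, "-")
                results.append(
                    OrfRecord(
                        orf_id="",
                        interval=iv,
                        frame=frame,
                        nt_seq=nt,
                        aa_seq=aa,
                        has_start=has_start,
                        has_stop=terminated,
                        edge5=edge5,
                        edge3=edge3,
                    )
                )
    results.sort(key=lambda o: (o.interval.start, o.interval.end, o.interval.strand, o.frame))
    for i, o in enumerate(results):
        o.orf_id = f"{contig.id}_orf{i:04d}"
    return results


def find_orfs_many(contigs, min_aa: int = 75) -> list[OrfRecord]:
    out: list[OrfRecord] = []
    for c in contigs:
        out.extend(find_orfs(c, min_aa=min_aa))
    return out
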