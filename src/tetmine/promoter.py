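"""Promoter window extraction and IUPAC cis-element scanning.

Windows are anchored at the translation start (ATG), not the TSS: the
1 kb immediately upstream of the first CDS base, reverse-complemented for
minus-strand genes so the stored sequence reads 5'→3' relative to the
gene. Scanning reports every (overlapping) occurrence of every pattern on
one or both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

from .io import FormatError, GeneModel, MotifDictionary, SequenceRecord

IUPAC_EXPAND = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    parts = []
    for code in pattern.upper():
        try:
            bases = IUPAC_EXPAND[code]
        except KeyError:
            raise FormatError(f"invalid IUPAC code {code!r} in pattern {pattern!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


@dataclass(frozen=True)
class PromoterWindow:
    """Upstream sequence of one gene, 5'→3' relative to the gene."""

    gene_id: str
    chromosome: str
    strand: str
    start: int  # genomic, 1-based inclusive
    end: int
    sequence: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifHit:
    gene_id: str
    motif_id: str
    offset: int  # 1-based on the promoter's own 5'->3' axis
    strand: str  # relative to the promoter: + or -
    matched: str


def extract_promoter(
    genome: dict[str, str] | list[SequenceRecord],
    gene_model: GeneModel,
    length: int = 1000,
) -> PromoterWindow:
    """Extract the window upstream of the translation start.

    Plus strand: genomic ``[coding_start - length, coding_start - 1]``;
    minus strand: ``[coding_start + 1, coding_start + length]`` reverse
    complemented. Windows partially off-contig are truncated and flagged;
    fully off-contig is an error.
    """
    if isinstance(genome, list):
        genome = {r.id: r.residues for r in genome}
    cs = gene_model.coding_start
    if cs is None:
        raise ValueError(f"{gene_model.transcript_id}: gene model has no CDS")
    try:
        contig = genome[gene_model.chromosome]
    except KeyError:
        raise ValueError(f"chromosome {gene_model.chromosome!r} not in genome") from None
    clen = len(contig)
    if gene_model.strand == "+":
        start, end = cs - length, cs - 1
    else:
        start, end = cs + 1, cs + length
    t_start, t_end = max(1, start), min(clen, end)
    if t_end < t_start:
        raise ValueError(
            f"{gene_model.transcript_id}: promoter window {start}-{end} entirely off contig"
        )
    seq = contig[t_start - 1 : t_end].upper()
    if gene_model.strand == "-":
        seq = revcomp(seq)
    return PromoterWindow(
        gene_id=gene_model.gene_id,
        chromosome=gene_model.chromosome,
        strand=gene_model.strand,
        start=t_start,
        end=t_end,
        sequence=seq,
        truncated=(t_start, t_end) != (start, end),
    )


def scan(
    window: PromoterWindow,
    motifs: MotifDictionary,
    strands: str = "both",
    overlaps: bool = True,
) -> list[MotifHit]:
    """All occurrences of every motif in a promoter window.

    Minus-strand hits are occurrences of a pattern's reverse complement in
    the window sequence; offsets always refer to the window's own 5'→3'
    axis (leftmost base of the matched text). With ``overlaps=False``
    matches per motif/strand collapse leftmost-greedy.
    """
    if len(motifs) == 0:
        raise ValueError("empty motif dictionary")
    if strands not in ("+", "-", "both"):
        raise ValueError(f"bad strands {strands!r}")
    hits: list[MotifHit] = []
    seq = window.sequence
    for motif_id, pattern, _category in motifs:
        for strand in ("+", "-"):
            if strands != "both" and strand != strands:
                continue
            pat = pattern if strand == "+" else revcomp(pattern)
            rx = re.compile(iupac_to_regex(pat))
            if overlaps:
                matches = [(m.start(1), m.group(1))
                           for m in re.finditer(f"(?=({rx.pattern}))", seq)]
            else:
                matches = [(m.start(), m.group()) for m in rx.finditer(seq)]
            for pos, text in matches:
                hits.append(
                    MotifHit(gene_id=window.gene_id, motif_id=motif_id,
                             offset=pos + 1, strand=strand, matched=text)
                )
    hits.sort(key=lambda h: (h.offset, h.motif_id, h.strand))
    return hits


def element_matrix(
    windows: list[PromoterWindow],
    motifs: MotifDictionary,
    strands: str = "both",
    overlaps: bool = True,
) -> pd.DataFrame:
    """Genes × motifs count table of cis-element occurrences."""
    counts = pd.DataFrame(
        0, index=[w.gene_id for w in windows], columns=motifs.ids, dtype=int
    )
    for window in windows:
        for hit in scan(window, motifs, strands=strands, overlaps=overlaps):
            counts.at[window.gene_id, hit.motif_id] += 1
    return counts


def genes_with_at_least(matrix: pd.DataFrame, motif_id: str, k: int) -> list[str]:
    """Genes carrying at least ``k`` copies of a motif."""
    return sorted(matrix.index[matrix[motif_id] >= k])
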