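"""Readers and writers for every external format the pipeline touches.

All other modules consume only the domain types defined here. Genomic
coordinates are 1-based inclusive throughout (GFF3 convention); any
conversion happens inside the readers.
"""

from __future__ import annotations

import io as _io
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Phylo, SeqIO


class FormatError(ValueError):
    """A file violated the syntax or invariants of its declared format."""


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """A single FASTA record: amino acids or nucleotides, uppercased."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a protein or nucleotide FASTA file.

    Residues are uppercased and whitespace-stripped; one record per header.
    Raises :class:`FormatError` (naming the offending line) for malformed
    headers, empty files, or duplicate ids.
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    first_content = next(
        ((i, ln) for i, ln in enumerate(lines, 1) if ln.strip()), None
    )
    if first_content is None:
        raise FormatError(f"{path}: empty FASTA file")
    if not first_content[1].lstrip().startswith(">"):
        raise FormatError(
            f"{path}: line {first_content[0]}: expected FASTA header '>'"
        )
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA header with empty id")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = "".join(str(rec.seq).split()).upper()
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# transmembrane topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyRecord:
    """Ordered TM segments plus sidedness of the N-terminus.

    Segments are 1-based inclusive intervals on the protein, sorted and
    non-overlapping. ``n_terminus_side`` is ``"inside"``, ``"outside"`` or
    ``"unknown"`` (scored under both orientations downstream).
    """

    protein_id: str
    length: int
    tm_segments: tuple[tuple[int, int], ...]
    n_terminus_side: str = "inside"

    def __post_init__(self):
        if self.length < 1:
            raise FormatError(f"{self.protein_id}: non-positive length")
        if self.n_terminus_side not in ("inside", "outside", "unknown"):
            raise FormatError(
                f"{self.protein_id}: bad n_terminus_side {self.n_terminus_side!r}"
            )
        prev_end = 0
        for start, end in self.tm_segments:
            if start < 1 or end > self.length:
                raise FormatError(
                    f"{self.protein_id}: TM segment {start}-{end} outside [1, {self.length}]"
                )
            if end < start:
                raise FormatError(f"{self.protein_id}: TM segment {start}-{end} empty")
            if start <= prev_end:
                raise FormatError(
                    f"{self.protein_id}: TM segments overlap or are unsorted at {start}-{end}"
                )
            prev_end = end

    @property
    def n_tm(self) -> int:
        return len(self.tm_segments)


def _parse_segment_field(text: str) -> tuple[tuple[int, int], ...]:
    segs = []
    text = text.strip()
    if text in ("", "-"):
        return ()
    for token in text.split(";"):
        m = re.fullmatch(r"\s*(\d+)\s*-\s*(\d+)\s*", token)
        if not m:
            raise FormatError(f"bad TM segment token {token!r}")
        segs.append((int(m.group(1)), int(m.group(2))))
    return tuple(segs)


def read_topology(path, dialect: str = "tsv") -> list[TopologyRecord]:
    """Read per-protein topology predictions.

    ``tsv`` is the canonical exchange dialect with columns
    ``protein_id  length  segments  n_terminus_side`` where segments is a
    ``;``-separated list of ``start-end``. ``tmhmm_long`` is a best-effort
    importer for TMHMM v2.0 long-format output; sidedness is taken from the
    first non-TM region label.
    """
    if dialect == "tsv":
        return _read_topology_tsv(path)
    if dialect == "tmhmm_long":
        return _read_topology_tmhmm_long(path)
    raise ValueError(f"unknown topology dialect {dialect!r}")


def _read_topology_tsv(path) -> list[TopologyRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = re.split(r"\t|\s{2,}", line)
            parts = [p for p in parts if p.strip()]
            if len(parts) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 columns, got {len(parts)}")
            pid, length, segs, side = parts
            if pid == "protein_id":  # optional header
                continue
            try:
                length_i = int(length)
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: non-integer length {length!r}") from None
            records.append(
                TopologyRecord(
                    protein_id=pid.strip(),
                    length=length_i,
                    tm_segments=_parse_segment_field(segs),
                    n_terminus_side=side.strip(),
                )
            )
    return records


def write_topology_tsv(records: Iterable[TopologyRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tlength\tsegments\tn_terminus_side\n")
        for rec in records:
            segs = ";".join(f"{s}-{e}" for s, e in rec.tm_segments) or "-"
            fh.write(f"{rec.protein_id}\t{rec.length}\t{segs}\t{rec.n_terminus_side}\n")


def _read_topology_tmhmm_long(path) -> list[TopologyRecord]:
    # TMHMM v2.0 long format: comment lines "# <id> Length: <n>" followed by
    # body lines "<id>  TMHMM2.0  <inside|outside|TMhelix>  <start>  <end>".
    lengths: dict[str, int] = {}
    regions: dict[str, list[tuple[str, int, int]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*(\S+)\s+Length:\s+(\d+)", line)
                if m:
                    lengths[m.group(1)] = int(m.group(2))
                continue
            parts = line.split()
            if len(parts) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 fields")
            pid, _src, label, start, end = parts
            if label not in ("inside", "outside", "TMhelix"):
                raise FormatError(f"{path}: line {lineno}: unknown region label {label!r}")
            if pid not in regions:
                regions[pid] = []
                order.append(pid)
            regions[pid].append((label, int(start), int(end)))
    records = []
    for pid in order:
        body = regions[pid]
        segs = tuple((s, e) for lab, s, e in body if lab == "TMhelix")
        non_tm = [lab for lab, _s, _e in body if lab != "TMhelix"]
        side = non_tm[0] if non_tm else "unknown"
        length = lengths.get(pid, max(e for _l, _s, e in body))
        records.append(
            TopologyRecord(protein_id=pid, length=length, tm_segments=segs, n_terminus_side=side)
        )
    return records


# ---------------------------------------------------------------------------
# gene models (GFF3)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneModel:
    """Exon/CDS structure of one transcript.

    Intervals are 1-based inclusive genomic coordinates, sorted by genomic
    position and non-overlapping. ``coding_start`` is the genomic coordinate
    of the first CDS base (the 'A' of ATG on the plus strand; the highest
    CDS coordinate on the minus strand).
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.transcript_id}: unknown strand {self.strand!r}")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for start, end in ivs:
                if start < 1 or end < start:
                    raise FormatError(
                        f"{self.transcript_id}: bad {name} interval {start}-{end}"
                    )
                if start <= prev_end:
                    raise FormatError(
                        f"{self.transcript_id}: overlapping/unsorted {name} at {start}-{end}"
                    )
                prev_end = end

    @property
    def coding_start(self) -> int | None:
        if not self.cds:
            return None
        return self.cds[0][0] if self.strand == "+" else self.cds[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def cds_complete(self) -> bool:
        """True when total CDS length is divisible by 3 (not fatal otherwise)."""
        return self.cds_length % 3 == 0

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exons_transcript_order(self) -> tuple[tuple[int, int], ...]:
        """Exons in 5'→3' transcript order (reversed for minus strand)."""
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))


def read_gff3(path) -> list[GeneModel]:
    """Read a GFF3 file into one :class:`GeneModel` per transcript.

    Expects the standard gene→mRNA→exon/CDS hierarchy. Transcripts without
    exon features but with CDS features use the CDS intervals as exons.
    Orphan CDS/exon features (parent not an mRNA in the file) are an error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    mrna_ids = {f.id for f in db.features_of_type(("mRNA", "transcript"))}
    for child_type in ("exon", "CDS"):
        for feat in db.features_of_type(child_type):
            parents = feat.attributes.get("Parent", [])
            if not parents:
                raise FormatError(f"{path}: orphan {child_type} feature (no Parent)")
            for p in parents:
                if p not in mrna_ids:
                    raise FormatError(
                        f"{path}: {child_type} feature with unknown parent {p!r}"
                    )
    models = []
    for mrna in db.features_of_type(("mRNA", "transcript")):
        parents = list(db.parents(mrna, featuretype="gene"))
        gene_id = parents[0].id if parents else mrna.attributes.get("Parent", [mrna.id])[0]
        exons = sorted(
            (f.start, f.end) for f in db.children(mrna, featuretype="exon")
        )
        cds = sorted((f.start, f.end) for f in db.children(mrna, featuretype="CDS"))
        if not exons:
            exons = cds
        if not exons:
            continue
        models.append(
            GeneModel(
                gene_id=gene_id,
                transcript_id=mrna.id,
                chromosome=mrna.seqid,
                strand=mrna.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return models


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def write_newick(tree) -> str:
    """Serialize a :class:`tetmine.phylo.PhyloTree` (or Bio.Phylo tree) to
    strict Newick with branch lengths and internal support labels."""
    from . import phylo as _phylo

    if isinstance(tree, _phylo.PhyloTree):
        return tree.to_newick()
    buf = _io.StringIO()
    Phylo.write(tree, buf, "newick")
    return buf.getvalue().strip()


def read_newick(text: str):
    """Parse a Newick string into a :class:`tetmine.phylo.PhyloTree`."""
    from . import phylo as _phylo

    return _phylo.PhyloTree.from_newick(text)


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

CQ_COLUMNS = ["gene_id", "condition", "timepoint", "bio_rep", "tech_rep", "cq"]


def validate_cq(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"Cq table missing columns: {missing}")
    if df["cq"].isna().any() or not df["cq"].map(math.isfinite).all():
        bad = df.index[~df["cq"].map(lambda v: isinstance(v, (int, float)) and math.isfinite(v))]
        raise FormatError(f"non-finite cq values at rows {list(bad[:5])}")
    return df


def read_cq(path) -> pd.DataFrame:
    """Read a Cq CSV with header row into a validated long-format table."""
    try:
        df = pd.read_csv(path, dtype={"gene_id": str, "condition": str, "timepoint": str})
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if not pd.api.types.is_numeric_dtype(df.get("cq", pd.Series(dtype=float))):
        raise FormatError(f"{path}: non-numeric cq column")
    return validate_cq(df)


def write_cq(df: pd.DataFrame, path) -> None:
    validate_cq(df).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# motif dictionaries
# ---------------------------------------------------------------------------

IUPAC_CODES = set("ACGTRYSWKMBDHVN")

MOTIF_CATEGORIES = ("hormone", "stress", "tissue")


@dataclass(frozen=True)
class MotifDictionary:
    """Named IUPAC patterns grouped into hormone/stress/tissue classes."""

    entries: tuple[tuple[str, str, str], ...]  # (motif_id, iupac_pattern, category)

    def __post_init__(self):
        seen = set()
        for motif_id, pattern, category in self.entries:
            if motif_id in seen:
                raise FormatError(f"duplicate motif id {motif_id!r}")
            seen.add(motif_id)
            bad = set(pattern.upper()) - IUPAC_CODES
            if bad:
                raise FormatError(
                    f"motif {motif_id!r}: non-IUPAC characters {sorted(bad)}"
                )
            if category not in MOTIF_CATEGORIES:
                raise FormatError(f"motif {motif_id!r}: unknown category {category!r}")

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    @property
    def ids(self) -> list[str]:
        return [m for m, _p, _c in self.entries]

    def pattern(self, motif_id: str) -> str:
        for m, p, _c in self.entries:
            if m == motif_id:
                return p
        raise KeyError(motif_id)


def read_motifs(path) -> MotifDictionary:
    """Read a motif TSV (columns motif_id, iupac_pattern, category)."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "motif_id":
                continue
            if len(parts) != 3:
                raise FormatError(f"{path}: line {lineno}: expected 3 columns")
            entries.append((parts[0], parts[1].upper(), parts[2]))
    return MotifDictionary(entries=tuple(entries))


def write_motifs(motifs: MotifDictionary, path) -> None:
    with open(path, "w") as fh:
        fh.write("motif_id\tiupac_pattern\tcategory\n")
        for motif_id, pattern, category in motifs:
            fh.write(f"{motif_id}\t{pattern}\t{category}\n")


def default_motifs() -> MotifDictionary:
    """The bundled cis-element dictionary (PLACE consensus strings for the
    six element classes: ABRE, HSE, LTR, MeJA-response pair, root motif,
    POLLEN1LELAT52)."""
    from importlib.resources import files

    return read_motifs(files("tetmine").joinpath("data/motifs.tsv"))
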