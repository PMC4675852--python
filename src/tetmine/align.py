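"""Pairwise and progressive protein alignment with SIAS-style
identity/similarity percentages and per-domain conservation.

Pairwise optimal global alignment (affine gaps) is delegated to
Bio.Align.PairwiseAligner; the progressive multiple aligner builds a
neighbor-joining guide tree on pairwise p-distances and merges profiles
with sum-of-pairs scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

GAP = "-"

AA20 = "ARNDCQEGHILKMFPSTWYV"


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows over an ordered id list."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def column_map(self, i: int) -> dict[int, int]:
        """1-based residue position -> 0-based alignment column for row i."""
        out = {}
        pos = 0
        for col, ch in enumerate(self.rows[i]):
            if ch != GAP:
                pos += 1
                out[pos] = col
        return out


@lru_cache(maxsize=4)
def _submat(name: str):
    mat = substitution_matrices.load(name)
    # unknown residues (mapped to X) score neutral rather than BLOSUM's -1
    if "X" in mat.alphabet:
        for aa in mat.alphabet:
            mat["X", aa] = 0.0
            mat[aa, "X"] = 0.0
    return mat


def _sanitize(residues: str, alphabet: str) -> str:
    out = []
    warned = False
    for aa in residues:
        if aa in alphabet:
            out.append(aa)
        else:
            if not warned:
                warnings.warn(f"unknown residue {aa!r} scored as neutral (X)")
                warned = True
            out.append("X")
    return "".join(out)


def align_pair(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Optimal global alignment of two proteins under affine gap penalties.

    Deterministic: the first alignment in Biopython's canonical traceback
    order is taken. Residues outside the substitution matrix alphabet are
    mapped to X (neutral) with a warning.
    """
    if not a.residues or not b.residues:
        raise ValueError("align_pair requires non-empty sequences")
    mat = _submat(matrix_name)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    ra = _sanitize(a.residues, mat.alphabet)
    rb = _sanitize(b.residues, mat.alphabet)
    aln = aligner.align(ra, rb)[0]
    rows = str(aln).strip("\n").split("\n")
    # Bio.Align pretty format: target / pattern / query blocks; use indices
    ga, gb = aln[0], aln[1]
    # restore any original (sanitized) residues
    ga = _restore(ga, a.residues)
    gb = _restore(gb, b.residues)
    return Alignment(ids=(a.id, b.id), rows=(ga, gb))


def _restore(gapped: str, original: str) -> str:
    out = []
    it = iter(original)
    for ch in gapped:
        out.append(GAP if ch == GAP else next(it))
    return "".join(out)


def percent_identity_similarity(
    aln: Alignment,
    denominator: str = "alignment_length",
    matrix_name: str = "BLOSUM62",
) -> tuple[float, float]:
    """SIAS-style identity and similarity percentages for a 2-row alignment.

    Identity counts identical residue columns; similarity additionally
    counts columns whose residue pair has a positive substitution score.
    Columns with a gap are never identical or similar. Denominators:
    ``alignment_length``, ``shorter_seq``, or ``mean_length``.
    """
    if len(aln.rows) != 2:
        raise ValueError("percent_identity_similarity requires a 2-row alignment")
    mat = _submat(matrix_name)
    ra, rb = aln.rows
    ident = simil = 0
    for x, y in zip(ra, rb):
        if x == GAP or y == GAP:
            continue
        if x == y:
            ident += 1
            simil += 1
        else:
            try:
                score = mat[x, y]
            except (KeyError, IndexError):
                score = 0.0
            if score > 0:
                simil += 1
    la, lb = len(ra.replace(GAP, "")), len(rb.replace(GAP, ""))
    if denominator == "alignment_length":
        denom = aln.ncols
    elif denominator == "shorter_seq":
        denom = min(la, lb)
    elif denominator == "mean_length":
        denom = (la + lb) / 2
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0, 0.0
    return 100.0 * ident / denom, 100.0 * simil / denom


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise identity and similarity percentage matrices."""

    ids: tuple[str, ...]
    identity: np.ndarray
    similarity: np.ndarray

    def mean_offdiagonal(self) -> tuple[float, float]:
        n = len(self.ids)
        mask = ~np.eye(n, dtype=bool)
        return float(self.identity[mask].mean()), float(self.similarity[mask].mean())

    def lookup(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.identity[i, j]), float(self.similarity[i, j])


def similarity_matrix(
    seqs: list[SequenceRecord],
    denominator: str = "alignment_length",
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> SimilarityMatrix:
    """All-vs-all pairwise identity/similarity percentages."""
    n = len(seqs)
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = align_pair(seqs[i], seqs[j], matrix_name, gap_open, gap_extend)
            pi, ps = percent_identity_similarity(aln, denominator, matrix_name)
            ident[i, j] = ident[j, i] = pi
            simil[i, j] = simil[j, i] = ps
    return SimilarityMatrix(ids=tuple(s.id for s in seqs), identity=ident,
                            similarity=simil)


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str], mat, alphabet: str) -> np.ndarray:
    """Column frequency matrix (ncols x len(alphabet)); gaps excluded."""
    idx = {aa: k for k, aa in enumerate(alphabet)}
    ncols = len(rows[0])
    counts = np.zeros((ncols, len(alphabet)))
    for row in rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                counts[c, idx.get(ch, idx.get("X", 0))] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def _blosum_array(mat, alphabet: str) -> np.ndarray:
    B = np.zeros((len(alphabet), len(alphabet)))
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            try:
                B[i, j] = mat[a, b]
            except (KeyError, IndexError):
                B[i, j] = 0.0
    return B


def _profile_align(rows_a: list[str], rows_b: list[str], mat,
                   gap_open: float, gap_extend: float) -> tuple[list[str], list[str]]:
    """Global affine profile–profile alignment with sum-of-pairs scoring.

    Traceback prefers diagonal, then the gap-in-B (up) state, then
    gap-in-A (left), matching the pairwise convention.
    """
    alphabet = AA20 + "X"
    B = _blosum_array(mat, alphabet)
    pa = _profile(rows_a, mat, alphabet)
    pb = _profile(rows_b, mat, alphabet)
    S = pa @ B @ pb.T  # expected pair score per column pair
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in B (consume A column)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in A (consume B column)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = -gap_open - gap_extend * (j - 1)
    # traceback pointers: 0=M,1=Ix,2=Iy source state
    tb_m = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_x = np.zeros((n + 1, m + 1), dtype=np.int8)
    tb_y = np.zeros((n + 1, m + 1), dtype=np.int8)
    for i in range(1, n + 1):
        Mi1, Ix1, Iy1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            # M: diagonal from any state; prefer M, Ix, Iy on ties
            best, src = Mi1[j - 1], 0
            if Ix1[j - 1] > best:
                best, src = Ix1[j - 1], 1
            if Iy1[j - 1] > best:
                best, src = Iy1[j - 1], 2
            M[i, j] = best + s
            tb_m[i, j] = src
            # Ix: consume column of A (gap in B)
            open_x = M[i - 1][j] - gap_open
            ext_x = Ix[i - 1][j] - gap_extend
            if open_x >= ext_x:
                Ix[i, j], tb_x[i, j] = open_x, 0
            else:
                Ix[i, j], tb_x[i, j] = ext_x, 1
            # Iy: consume column of B (gap in A)
            open_y = M[i][j - 1] - gap_open
            ext_y = Iy[i][j - 1] - gap_extend
            if open_y >= ext_y:
                Iy[i, j], tb_y[i, j] = open_y, 0
            else:
                Iy[i, j], tb_y[i, j] = ext_y, 1
    # terminal state: prefer M, Ix, Iy on ties
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    i, j = n, m
    ops: list[str] = []  # 'D' diag, 'U' up (A col), 'L' left (B col)
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            state = int(tb_m[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("U")
            state = int(tb_x[i, j])
            i -= 1
        else:
            ops.append("L")
            state = int(tb_y[i, j])
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    ops.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op in ("D", "U"):
            for k, row in enumerate(rows_a):
                out_a[k] += row[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += GAP
        if op in ("D", "L"):
            for k, row in enumerate(rows_b):
                out_b[k] += row[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += GAP
    return out_a, out_b


def align_progressive(
    seqs: list[SequenceRecord],
    guide=None,
    matrix_name: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Progressive multiple alignment.

    The guide tree is built by neighbor joining on pairwise p-distances
    unless supplied; profiles are merged bottom-up with sum-of-pairs
    scoring. Column order is deterministic given the inputs.
    """
    from .phylo import PhyloTree, nj_tree

    if not seqs:
        raise ValueError("align_progressive requires at least one sequence")
    if len(seqs) == 1:
        return Alignment(ids=(seqs[0].id,), rows=(seqs[0].residues,))
    mat = _submat(matrix_name)
    by_id = {s.id: s for s in seqs}
    if len(seqs) == 2:
        return align_pair(seqs[0], seqs[1], matrix_name, gap_open, gap_extend)

    if guide is None:
        import pandas as pd

        ids = [s.id for s in seqs]
        D = np.zeros((len(seqs), len(seqs)))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                aln = align_pair(seqs[i], seqs[j], matrix_name, gap_open, gap_extend)
                pi, _ = percent_identity_similarity(aln, "alignment_length", matrix_name)
                D[i, j] = D[j, i] = 1.0 - pi / 100.0
        guide = nj_tree(pd.DataFrame(D, index=ids, columns=ids))

    def merge(node) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            seq = by_id[node.name]
            return [node.name], [seq.residues]
        parts = [merge(child) for child, _bl in node.children]
        ids, rows = parts[0]
        for other_ids, other_rows in parts[1:]:
            rows, other_rows = _profile_align(rows, other_rows, mat, gap_open, gap_extend)
            ids = ids + other_ids
            rows = rows + other_rows
        return ids, rows

    ids, rows = merge(guide.root)
    return Alignment(ids=tuple(ids), rows=tuple(rows))


def domain_identity(
    aln: Alignment,
    region_models: dict[str, "RegionModel"],
    regions: tuple[str, ...] = ("Ntail", "TM1", "EC1", "TM2", "ICL", "TM3", "EC2", "TM4", "Ctail"),
) -> dict[str, tuple[float, int]]:
    """Mean pairwise percent identity per canonical region.

    Region intervals are mapped through the alignment to columns; each
    region is scored on the union of its columns over all sequences.
    Pairs lacking the region in either protein are skipped (the returned
    pair count reflects this). Returns region -> (mean identity %, n pairs).
    """
    col_maps = {aln.ids[i]: aln.column_map(i) for i in range(len(aln.ids))}
    out: dict[str, tuple[float, int]] = {}
    for region in regions:
        cols: set[int] = set()
        have: list[str] = []
        for sid in aln.ids:
            model = region_models.get(sid)
            if model is None:
                continue
            iv = model.regions.get(region)
            if iv is None or iv[1] < iv[0]:
                continue
            have.append(sid)
            cmap = col_maps[sid]
            for pos in range(iv[0], iv[1] + 1):
                if pos in cmap:
                    cols.add(cmap[pos])
        if not cols or len(have) < 2:
            continue
        col_list = sorted(cols)
        vals = []
        for i in range(len(have)):
            for j in range(i + 1, len(have)):
                ra = aln.row(have[i])
                rb = aln.row(have[j])
                ident = sum(
                    1 for c in col_list
                    if ra[c] == rb[c] and ra[c] != GAP
                )
                vals.append(100.0 * ident / len(col_list))
        out[region] = (float(np.mean(vals)), len(vals))
    return out
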