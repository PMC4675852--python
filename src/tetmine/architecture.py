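"""Intron statistics and phases, intron-to-domain mapping, and tandem /
segmental duplication classification.

Intron phase is the cumulative CDS length 5' of the intron modulo 3:
phase 0 falls between codons, phase 1 after the first codon base, phase 2
after the second. Tandem duplicates are family members on one chromosome
separated by at most ``max_intervening`` unrelated genes; segmental
duplicates sit inside colinear anchor chains whose consecutive anchors are
within ``max_span`` on both chromosomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import GeneModel
from .topology import RegionModel


@dataclass(frozen=True)
class IntronRecord:
    gene_id: str
    transcript_id: str
    index: int  # 1..n in 5'->3' transcript order
    start: int  # genomic, 1-based inclusive
    end: int
    length: int
    phase: int | None  # None for UTR introns
    protein_position: int | None  # codon index of the interrupted/adjacent codon
    domain_label: str | None = None


def introns_of(model: GeneModel) -> list[IntronRecord]:
    """Introns of one transcript, in 5'→3' order, with phases.

    Introns are the gaps between consecutive exons. Phases are computed
    from CDS only; introns lying outside the CDS span (UTR introns) get
    phase ``None``.
    """
    exons = model.exons
    if len(exons) < 2:
        return []
    gaps = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1 + 1:
            raise ValueError(f"{model.transcript_id}: exons touch or overlap at {s2}")
        gaps.append((e1 + 1, s2 - 1))
    if model.strand == "-":
        gaps = list(reversed(gaps))
    total_cds = model.cds_length
    records = []
    for idx, (gs, ge) in enumerate(gaps, 1):
        if model.strand == "+":
            upstream = sum(min(e, gs - 1) - s + 1 for s, e in model.cds if s < gs)
        else:
            upstream = sum(e - max(s, ge + 1) + 1 for s, e in model.cds if e > ge)
        if total_cds == 0 or upstream == 0 or upstream >= total_cds:
            phase = None
            ppos = None
        else:
            phase = upstream % 3
            ppos = upstream // 3 + 1
        records.append(
            IntronRecord(
                gene_id=model.gene_id,
                transcript_id=model.transcript_id,
                index=idx,
                start=gs,
                end=ge,
                length=ge - gs + 1,
                phase=phase,
                protein_position=ppos,
            )
        )
    return records


def phase_census(models: list[GeneModel]) -> dict:
    """Counts of phase 0/1/2 plus undefined, with a per-gene breakdown."""
    totals = Counter({0: 0, 1: 0, 2: 0, "undefined": 0})
    per_gene: dict[str, list] = {}
    for model in models:
        phases = [r.phase if r.phase is not None else "undefined"
                  for r in introns_of(model)]
        per_gene[model.transcript_id] = phases
        totals.update(phases)
    return {"totals": dict(totals), "per_gene": per_gene}


def map_intron_to_domain(
    intron: IntronRecord, gene_model: GeneModel, region_model: RegionModel,
) -> str | None:
    """Canonical region containing the residue the intron interrupts.

    The protein position is ``floor(cumulative CDS / 3) + 1``. Raises when
    the position exceeds the protein length implied by the region model.
    """
    if intron.protein_position is None:
        return None
    if intron.protein_position > region_model.length:
        raise ValueError(
            f"{intron.transcript_id}: intron protein position {intron.protein_position} "
            f"beyond protein length {region_model.length}"
        )
    return region_model.region_of(intron.protein_position)


@dataclass(frozen=True)
class DuplicationCall:
    gene_a: str
    gene_b: str
    type: str  # tandem | segmental | none
    evidence: dict


def _position_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"gene_id", "chromosome", "start", "end", "family_member"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"position table missing columns {sorted(missing)}")
    return table


def call_tandem(table: pd.DataFrame, max_intervening: int = 10) -> list[DuplicationCall]:
    """Tandem duplication calls from a gene position table.

    Every family pair on one chromosome separated by at most
    ``max_intervening`` unrelated (non-family) genes is tandem. The bound
    is inclusive (10 intervening genes still qualifies by default).
    """
    table = _position_table(table)
    calls = []
    for _chrom, sub in table.groupby("chromosome", sort=True):
        sub = sub.sort_values(["start", "end", "gene_id"]).reset_index(drop=True)
        fam_idx = sub.index[sub["family_member"].astype(bool)].tolist()
        for ii in range(len(fam_idx)):
            for jj in range(ii + 1, len(fam_idx)):
                i, j = fam_idx[ii], fam_idx[jj]
                between = sub.iloc[i + 1 : j]
                n_unrelated = int((~between["family_member"].astype(bool)).sum())
                if n_unrelated <= max_intervening:
                    a, b = sorted((sub.at[i, "gene_id"], sub.at[j, "gene_id"]))
                    calls.append(
                        DuplicationCall(
                            gene_a=a, gene_b=b, type="tandem",
                            evidence={"intervening_genes": n_unrelated},
                        )
                    )
    return sorted(calls, key=lambda c: (c.gene_a, c.gene_b))


def _chain_members(anchors: pd.DataFrame, max_span: int, min_anchors: int) -> list[bool]:
    """For anchors on one chromosome pair: whether each anchor belongs to
    some colinear chain of length >= min_anchors.

    A chain is a subsequence with strictly increasing pos_a, strictly
    monotone pos_b, and consecutive gaps <= max_span on both chromosomes.
    """
    n = len(anchors)
    pa = anchors["pos_a"].to_numpy()
    pb = anchors["pos_b"].to_numpy()
    order = sorted(range(n), key=lambda k: (pa[k], pb[k]))
    member = [False] * n
    for direction in (1, -1):
        def ok(i, j):  # can j follow i
            if pa[j] <= pa[i]:
                return False
            if direction * (pb[j] - pb[i]) <= 0:
                return False
            return (pa[j] - pa[i]) <= max_span and abs(pb[j] - pb[i]) <= max_span

        f = [1] * n  # longest chain ending at k
        g = [1] * n  # longest chain starting at k
        for oi in range(n):
            i = order[oi]
            for oj in range(oi):
                j = order[oj]
                if ok(j, i) and f[j] + 1 > f[i]:
                    f[i] = f[j] + 1
        for oi in range(n - 1, -1, -1):
            i = order[oi]
            for oj in range(oi + 1, n):
                j = order[oj]
                if ok(i, j) and g[j] + 1 > g[i]:
                    g[i] = g[j] + 1
        for k in range(n):
            if f[k] + g[k] - 1 >= min_anchors:
                member[k] = True
    return member


def call_segmental(
    anchors: pd.DataFrame,
    family: set[str],
    max_span: int = 500_000,
    min_anchors: int = 3,
) -> list[DuplicationCall]:
    """Segmental duplication calls from homolog anchor pairs.

    ``anchors`` needs columns gene_a, chrom_a, pos_a, gene_b, chrom_b,
    pos_b. Anchors belonging to a colinear chain of at least
    ``min_anchors`` (consecutive anchors within ``max_span`` on both
    chromosomes) whose gene pair lies in ``family`` are called segmental.
    """
    required = {"gene_a", "chrom_a", "pos_a", "gene_b", "chrom_b", "pos_b"}
    missing = required - set(anchors.columns)
    if missing:
        raise ValueError(f"anchor table missing columns {sorted(missing)}")
    calls = []
    for _key, sub in anchors.groupby(["chrom_a", "chrom_b"], sort=True):
        sub = sub.reset_index(drop=True)
        member = _chain_members(sub, max_span, min_anchors)
        for k, is_member in enumerate(member):
            ga, gb = sub.at[k, "gene_a"], sub.at[k, "gene_b"]
            if is_member and ga in family and gb in family:
                a, b = sorted((ga, gb))
                calls.append(
                    DuplicationCall(
                        gene_a=a, gene_b=b, type="segmental",
                        evidence={"n_anchors_in_block": int(sum(member))},
                    )
                )
    return sorted(calls, key=lambda c: (c.gene_a, c.gene_b))


def intergenic_distance(table: pd.DataFrame, a: str, b: str) -> int:
    """Bases strictly between two genes on one chromosome (0 if they
    overlap or touch), under the 1-based inclusive convention."""
    table = _position_table(table)
    rows = {g: table[table["gene_id"] == g] for g in (a, b)}
    for g, r in rows.items():
        if len(r) != 1:
            raise ValueError(f"gene {g!r} not uniquely present in position table")
    ra, rb = rows[a].iloc[0], rows[b].iloc[0]
    if ra["chromosome"] != rb["chromosome"]:
        raise ValueError(f"{a} and {b} are on different chromosomes")
    gap = max(int(ra["start"]), int(rb["start"])) - min(int(ra["end"]), int(rb["end"])) - 1
    return max(0, gap)
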