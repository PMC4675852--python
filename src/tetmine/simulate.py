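"""Seeded synthetic-data generators.

Every other module's assumptions are realized here with known ground
truth, so the full pipeline is testable without downloads: proteomes with
planted 4-TM tetraspanins among rule-violating decoys, gene models with
known intron phases, promoters with planted cis-elements, colinear anchor
blocks, and Cq tables with known log2 fold changes.

The generated family emulates the shape of a small plant tetraspanin
family: ~15 members of 270–380 aa, four strongly hydrophobic 22-residue
TM helices, a small EC1 (~15 aa, one cysteine), a large EC2 (~90 aa, nine
cysteines, embedded SGCC[KR]PP), short cytoplasmic tails, mostly
single-intron gene models with the intron in the EC2-coding span, and
3 biological × 2 technical qPCR replicates with Gaussian Cq noise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    GeneModel,
    MotifDictionary,
    SequenceRecord,
    TopologyRecord,
    default_motifs,
)
from .promoter import extract_promoter, iupac_to_regex, revcomp

HYDROPHILIC = "DENQKRSTHGPY"  # loop/tail alphabet: no Cys, no strong hydrophobics
HYDROPHOBIC = "LIVF"

#: decoy class -> the single classifier rule it violates by construction
DECOY_RULES = {
    "wrong_tm_count": "four_tm",
    "missing_motif": "signature",
    "ec2_smaller": "ec2_longer_than_ec1",
    "long_tails": "short_tails",
    "few_cys": "ec2_cysteines",
}


@dataclass
class ExpressionPlan:
    genes: tuple[str, ...] = tuple(f"g{i:02d}" for i in range(1, 13))
    reference_gene: str = "eEF1a"
    pairing: dict = field(default_factory=lambda: {
        "control": "control", "heat": "control", "salt": "control",
        "cold": "control", "drought": "control", "oxidative": "control",
    })
    true_log2fc: pd.DataFrame | None = None  # genes x conditions; generated if None
    cq_sd: float = 0.1
    n_bio: int = 3
    n_tech: int = 2


@dataclass
class GeneratorSpec:
    """One seed drives every artifact; per-artifact streams are derived by
    fixed offsets so the artifacts are independently reproducible."""

    seed: int = 0
    n_tetraspanins: int = 15
    decoys: dict = field(default_factory=lambda: {
        "wrong_tm_count": 100, "missing_motif": 100, "ec2_smaller": 100,
        "long_tails": 100, "few_cys": 100,
    })
    gene_plans: list | None = None  # default family plans when None
    anchor_blocks: list | None = None
    expression: ExpressionPlan = field(default_factory=ExpressionPlan)
    promoter_length: int = 1000


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _rand_seq(rng, n: int, alphabet: str) -> str:
    return "".join(rng.choice(list(alphabet), size=n)) if n > 0 else ""


# ---------------------------------------------------------------------------
# proteome
# ---------------------------------------------------------------------------

@dataclass
class ProteomeBundle:
    sequences: list[SequenceRecord]
    topologies: list[TopologyRecord]
    truth: pd.DataFrame  # protein_id, kind, is_tetraspanin, violated_rule


def _place_cys(rng, seq: list[str], n_extra: int, forbidden: set[int],
               allow_adjacent: bool = False) -> None:
    """Plant extra cysteines; by default at positions not adjacent to any
    existing C (no new CC pair, hence no spurious GCC[KR]P core).
    Adjacency is harmless when the signature is planted anyway."""
    placed = 0
    attempts = 0
    while placed < n_extra:
        attempts += 1
        if attempts > 10_000:
            raise RuntimeError("could not place cysteines")
        i = int(rng.integers(0, len(seq)))
        if i in forbidden:
            continue
        if seq[i] == "C":
            continue
        if not allow_adjacent and any(
            0 <= j < len(seq) and seq[j] == "C" for j in (i - 1, i + 1)
        ):
            continue
        seq[i] = "C"
        placed += 1


def _build_parts(rng, kind: str) -> dict[str, str]:
    """Region sequences for one synthetic protein of the given class."""
    ntail = _rand_seq(rng, int(rng.integers(12, 31)), HYDROPHILIC)
    ctail = _rand_seq(rng, int(rng.integers(15, 36)), HYDROPHILIC)
    tms = [_rand_seq(rng, 22, HYDROPHOBIC) for _ in range(4)]
    ec1 = list(_rand_seq(rng, int(rng.integers(12, 19)), HYDROPHILIC))
    ec1[int(rng.integers(0, len(ec1)))] = "C"  # the conserved EC1 cysteine
    icl = _rand_seq(rng, int(rng.integers(10, 16)), HYDROPHILIC)

    def ec2_with_motif(length: int, n_cys_total: int) -> str:
        motif = "SGCC" + ("K" if rng.random() < 0.5 else "R") + "PP"
        body = list(_rand_seq(rng, length, HYDROPHILIC))
        off = int(rng.integers(0, length - len(motif) + 1))
        body[off : off + len(motif)] = list(motif)
        forbidden = set(range(off, off + len(motif)))
        # adjacency is fine once the signature is planted
        _place_cys(rng, body, n_cys_total - 2, forbidden, allow_adjacent=True)
        return "".join(body)

    if kind in ("tetraspanin", "long_tails", "few_cys"):
        n_cys = 9 if kind != "few_cys" else 7
        ec2 = ec2_with_motif(int(rng.integers(80, 101)), n_cys)
        if kind == "long_tails":
            ctail = _rand_seq(rng, int(rng.integers(70, 91)), HYDROPHILIC)
    elif kind == "missing_motif":
        body = list(_rand_seq(rng, int(rng.integers(80, 101)), HYDROPHILIC))
        _place_cys(rng, body, 9, set())
        ec2 = "".join(body)
        assert not re.search(r"GCC[KR]P", ec2)
    elif kind == "ec2_smaller":
        ec2 = ec2_with_motif(15, 9)
        ec1 = list(_rand_seq(rng, 40, HYDROPHILIC))
        ec1[int(rng.integers(0, len(ec1)))] = "C"
    elif kind == "wrong_tm_count":
        # content rules are inapplicable without the canonical 4-TM model
        ec2 = ec2_with_motif(int(rng.integers(80, 101)), 9)
    else:
        raise ValueError(f"unknown protein class {kind!r}")

    return {
        "Ntail": ntail, "TM1": tms[0], "EC1": "".join(ec1), "TM2": tms[1],
        "ICL": icl, "TM3": tms[2], "EC2": ec2, "TM4": tms[3], "Ctail": ctail,
    }


def _assemble(pid: str, parts: dict[str, str], n_tm: int = 4) -> tuple[SequenceRecord, TopologyRecord]:
    order = ["Ntail", "TM1", "EC1", "TM2", "ICL", "TM3", "EC2", "TM4", "Ctail"]
    if n_tm == 3:
        order = ["Ntail", "TM1", "EC1", "TM2", "ICL", "TM3", "Ctail"]
    seq = ""
    segments = []
    for name in order:
        part = parts[name]
        if name.startswith("TM"):
            segments.append((len(seq) + 1, len(seq) + len(part)))
        seq += part
    rec = SequenceRecord(id=pid, residues=seq)
    topo = TopologyRecord(protein_id=pid, length=len(seq),
                          tm_segments=tuple(segments), n_terminus_side="inside")
    return rec, topo


def make_proteome(spec: GeneratorSpec) -> ProteomeBundle:
    """Planted tetraspanins among decoys, with per-protein topology and a
    ground-truth table; each decoy class violates exactly one rule."""
    rng = _rng(spec, 1)
    sequences, topologies, rows = [], [], []
    for i in range(spec.n_tetraspanins):
        pid = f"tet{i + 1:03d}"
        parts = _build_parts(rng, "tetraspanin")
        rec, topo = _assemble(pid, parts)
        sequences.append(rec)
        topologies.append(topo)
        rows.append((pid, "tetraspanin", True, ""))
    for kind in sorted(spec.decoys):
        rule = DECOY_RULES[kind]
        for i in range(spec.decoys[kind]):
            pid = f"{kind}{i + 1:03d}"
            parts = _build_parts(rng, kind)
            rec, topo = _assemble(pid, parts, n_tm=3 if kind == "wrong_tm_count" else 4)
            sequences.append(rec)
            topologies.append(topo)
            rows.append((pid, kind, False, rule))
    truth = pd.DataFrame(rows, columns=["protein_id", "kind", "is_tetraspanin",
                                        "violated_rule"])
    return ProteomeBundle(sequences=sequences, topologies=topologies, truth=truth)


# ---------------------------------------------------------------------------
# genome annotation: gene models, positions, promoters, anchors
# ---------------------------------------------------------------------------

@dataclass
class GenePlan:
    gene_id: str
    exon_lengths: tuple[int, ...]  # fully-coding exons, 5'->3'
    intron_lengths: tuple[int, ...] = ()
    strand: str = "+"
    family_member: bool = True
    promoter_motifs: dict = field(default_factory=dict)  # motif_id -> [offsets]


@dataclass
class ChromosomePlan:
    name: str
    # entries: (n_filler_genes_before, GenePlan)
    entries: list


@dataclass
class AnchorBlock:
    chrom_a: str
    chrom_b: str
    positions_a: tuple[int, ...]
    positions_b: tuple[int, ...]
    family_pair_index: int | None  # which anchor is the family gene pair
    family_genes: tuple[str, str] | None
    is_segmental_truth: bool = True


@dataclass
class AnnotationBundle:
    genome: dict
    gene_models: list
    gff3: str
    position_table: pd.DataFrame
    anchor_table: pd.DataFrame
    family: set
    truth: dict  # phases, intron_lengths, motif_offsets, tandem, not_tandem, segmental, not_segmental


def default_chromosome_plans(rng) -> list[ChromosomePlan]:
    """A family layout exercising every architecture rule boundary: an
    adjacent tandem pair, a 10-intervening tandem pair (inclusive
    boundary), an 11-intervening non-tandem pair, a multiset of intron
    phases {0,0,1,2}, an intronless gene, a 10-intron gene, and intron
    lengths spanning 95–4200 bp."""

    def motifs_for(*items):
        return {m: list(offs) for m, offs in items}

    plans = [
        ChromosomePlan("chr1", [
            (0, GenePlan("fam01", (186, 680), (250,),
                         promoter_motifs=motifs_for(("ABRE", (120, 340, 650)),
                                                    ("ROOTMOTIF", (50,))))),
            (0, GenePlan("fam02", (96, 762), (4200,), strand="-",
                         promoter_motifs=motifs_for(("ABRE", (200,)),
                                                    ("HSE", (400,))))),
        ]),
        ChromosomePlan("chr2", [
            (0, GenePlan("fam03", (99, 99, 100, 100, 298), (150, 220, 310, 95),
                         promoter_motifs=motifs_for(("LTR", (100, 800)),))),
            (10, GenePlan("fam04", (300, 513), (180,),
                          promoter_motifs=motifs_for(("ROOTMOTIF",
                                                      (30, 110, 190, 270, 350,
                                                       430, 510, 590, 670, 750)),))),
        ]),
        ChromosomePlan("chr3", [
            (0, GenePlan("fam05", (813,),
                         promoter_motifs=motifs_for(("MeJA_CGTCA", (500,)),))),
            (11, GenePlan("fam06", (120, 702), (400,), strand="-",
                          promoter_motifs=motifs_for(("POLLEN1LELAT52", (640,)),))),
        ]),
        ChromosomePlan("chr4", [
            (0, GenePlan("fam07", tuple([75] * 11), tuple([100 + 30 * k for k in range(10)]),
                         promoter_motifs=motifs_for(("ABRE", (250, 610)),))),
        ]),
    ]
    return plans


def default_anchor_blocks() -> list[AnchorBlock]:
    return [
        AnchorBlock(  # clean 5-anchor colinear block within 100 kb steps
            chrom_a="chr2", chrom_b="chr6",
            positions_a=(100_000, 180_000, 260_000, 340_000, 420_000),
            positions_b=(500_000, 570_000, 650_000, 720_000, 800_000),
            family_pair_index=2, family_genes=("fam03", "fam08"),
            is_segmental_truth=True,
        ),
        AnchorBlock(  # 600-kb gap splits the chain; family side too short
            chrom_a="chr3", chrom_b="chr7",
            positions_a=(100_000, 200_000, 800_000, 900_000, 1_000_000),
            positions_b=(100_000, 200_000, 800_000, 900_000, 1_000_000),
            family_pair_index=0, family_genes=("fam05", "fam09"),
            is_segmental_truth=False,
        ),
    ]


def _gene_coordinates(plan: GenePlan, start: int) -> tuple[tuple[tuple[int, int], ...], int]:
    """Genomic exon intervals for a plan laid left-to-right from start.

    For minus-strand genes the 5'->3' exon/intron plan is mirrored so the
    first planned exon sits rightmost.
    """
    exons = plan.exon_lengths
    introns = plan.intron_lengths
    if len(introns) != max(0, len(exons) - 1):
        raise ValueError(f"{plan.gene_id}: {len(exons)} exons need {len(exons) - 1} introns")
    ex_iter = exons if plan.strand == "+" else tuple(reversed(exons))
    in_iter = introns if plan.strand == "+" else tuple(reversed(introns))
    ivs = []
    pos = start
    for k, elen in enumerate(ex_iter):
        ivs.append((pos, pos + elen - 1))
        pos += elen
        if k < len(in_iter):
            pos += in_iter[k]
    return tuple(ivs), pos - 1  # intervals, genomic end


_IUPAC_CHOICES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def _resolve_instance(rng, pattern: str, motifs: MotifDictionary) -> str:
    """Pick concrete bases for a degenerate pattern such that the instance
    contains no forward occurrence of any other dictionary pattern (so
    planting one motif cannot smuggle in another)."""
    for _ in range(500):
        inst = "".join(str(rng.choice(list(_IUPAC_CHOICES[b]))) for b in pattern.upper())
        clean = True
        for mid, other, _cat in motifs:
            rx = re.compile(iupac_to_regex(other))
            for m in re.finditer(f"(?=({rx.pattern}))", inst):
                if other == pattern.upper() and m.start(1) == 0:
                    continue  # the planted motif itself
                clean = False
                break
            if not clean:
                break
        if clean:
            return inst
    raise RuntimeError(f"could not resolve a clean instance of {pattern!r}")


def _scrub_windows(genome: dict, models: list, plans: dict, motifs: MotifDictionary,
                   rng, promoter_length: int) -> None:
    """Mutate promoter bases until the only motif hits (either strand) are
    the planted ones."""
    patterns = [(mid, re.compile(iupac_to_regex(p)), re.compile(iupac_to_regex(revcomp(p))),
                 len(p)) for mid, p, _c in motifs]
    for model in models:
        plan = plans[model.gene_id]
        planted: set[int] = set()  # promoter-axis 0-based positions covered
        for mid, offs in plan.promoter_motifs.items():
            plen = len(motifs.pattern(mid))
            for off in offs:
                planted.update(range(off - 1, off - 1 + plen))
        for _ in range(200):
            window = extract_promoter(genome, model, length=promoter_length)
            seq = window.sequence
            planted_hits = {
                (mid, off) for mid, offs in plan.promoter_motifs.items() for off in offs
            }
            offender = None
            for mid, rx_f, rx_r, plen in patterns:
                for rx in (rx_f, rx_r):
                    for m in re.finditer(f"(?=({rx.pattern}))", seq):
                        pos = m.start(1)
                        if rx is rx_f and (mid, pos + 1) in planted_hits:
                            continue
                        span = set(range(pos, pos + plen))
                        free = sorted(span - planted)
                        if not free:
                            continue  # unavoidable overlap within planted bases
                        offender = free[0]
                        break
                    if offender is not None:
                        break
                if offender is not None:
                    break
            if offender is None:
                break
            current = seq[offender]
            new = rng.choice([b for b in "ACGT" if b != current])
            # map promoter-axis position back to the genome
            if model.strand == "+":
                gpos = window.start + offender
                base = new
            else:
                gpos = window.end - offender
                base = revcomp(new)
            contig = genome[model.chromosome]
            genome[model.chromosome] = contig[: gpos - 1] + base + contig[gpos:]
        else:
            raise RuntimeError(f"{model.gene_id}: promoter scrub did not converge")


def make_annotation(spec: GeneratorSpec,
                    motifs: MotifDictionary | None = None) -> AnnotationBundle:
    """Genome FASTA + GFF3 + position and anchor tables realizing the
    planned intron phases, duplication outcomes, and promoter motifs."""
    rng = _rng(spec, 2)
    motifs = motifs or default_motifs()
    if spec.gene_plans is None:
        chrom_plans = default_chromosome_plans(rng)
    else:
        chrom_plans = [
            cp if isinstance(cp, ChromosomePlan) else ChromosomePlan(*cp)
            for cp in spec.gene_plans
        ]
    anchor_blocks = spec.anchor_blocks or default_anchor_blocks()
    L = spec.promoter_length

    genome: dict[str, str] = {}
    models: list[GeneModel] = []
    plan_by_gene: dict[str, GenePlan] = {}
    pos_rows = []
    truth_phases: dict[str, list] = {}
    truth_intron_lengths: dict[str, list] = {}
    filler_n = 0

    for cp in chrom_plans:
        cursor = 101
        placements = []  # (plan | None, exons, end)
        for n_fillers, plan in cp.entries:
            for _ in range(n_fillers):
                filler_n += 1
                fid = f"filler{filler_n:03d}"
                placements.append((None, ((cursor, cursor + 199),), cursor + 199))
                pos_rows.append((fid, cp.name, cursor, cursor + 199, False))
                cursor += 260
            if plan.strand == "+":
                cursor += L  # promoter room upstream
                exons, gend = _gene_coordinates(plan, cursor)
            else:
                exons, gend = _gene_coordinates(plan, cursor)
            placements.append((plan, exons, gend))
            pos_rows.append((plan.gene_id, cp.name, exons[0][0], gend, plan.family_member))
            cursor = gend + (L if plan.strand == "-" else 0) + 300
        length = cursor + 100
        genome[cp.name] = _rand_seq(rng, length, "ACGT")
        for plan, exons, _gend in placements:
            if plan is None:
                continue
            model = GeneModel(
                gene_id=plan.gene_id, transcript_id=f"{plan.gene_id}.1",
                chromosome=cp.name, strand=plan.strand, exons=exons, cds=exons,
            )
            models.append(model)
            plan_by_gene[plan.gene_id] = plan
            # truth phases from the 5'->3' cumulative exon sums (mod 3)
            cums = np.cumsum(plan.exon_lengths)[:-1] if len(plan.exon_lengths) > 1 else []
            truth_phases[plan.gene_id] = [int(c % 3) for c in cums]
            truth_intron_lengths[plan.gene_id] = list(plan.intron_lengths)
            # plant promoter motifs on the promoter's own 5'->3' axis
            axis = list(_rand_seq(rng, L, "ACGT"))
            for mid, offs in plan.promoter_motifs.items():
                pat = motifs.pattern(mid)
                for off in offs:
                    inst = _resolve_instance(rng, pat, motifs)
                    axis[off - 1 : off - 1 + len(pat)] = list(inst)
            axis_seq = "".join(axis)
            contig = genome[cp.name]
            cs = model.coding_start
            if plan.strand == "+":
                gs, ge = cs - L, cs - 1
                genome[cp.name] = contig[: gs - 1] + axis_seq + contig[ge:]
            else:
                gs, ge = cs + 1, cs + L
                genome[cp.name] = contig[: gs - 1] + revcomp(axis_seq) + contig[ge:]

    _scrub_windows(genome, models, plan_by_gene, motifs, rng, L)

    position_table = pd.DataFrame(
        pos_rows, columns=["gene_id", "chromosome", "start", "end", "family_member"]
    )

    anchor_rows = []
    segmental, not_segmental = [], []
    for bi, block in enumerate(anchor_blocks):
        for k, (pa, pb) in enumerate(zip(block.positions_a, block.positions_b)):
            if block.family_pair_index is not None and k == block.family_pair_index:
                ga, gb = block.family_genes
            else:
                ga, gb = f"anc{bi}_{k}a", f"anc{bi}_{k}b"
            anchor_rows.append((ga, block.chrom_a, pa, gb, block.chrom_b, pb))
        if block.family_genes:
            pair = tuple(sorted(block.family_genes))
            (segmental if block.is_segmental_truth else not_segmental).append(pair)
    anchor_table = pd.DataFrame(
        anchor_rows, columns=["gene_a", "chrom_a", "pos_a", "gene_b", "chrom_b", "pos_b"]
    )

    family = {p.gene_id for p in plan_by_gene.values() if p.family_member}
    family |= {g for pair in segmental + not_segmental for g in pair}

    # tandem truth from the layout plans (pairs and their intervening counts)
    tandem, not_tandem = [], []
    for cp in chrom_plans:
        fam_entries = [(n, p) for n, p in cp.entries if p.family_member]
        running = []
        for n_fillers, plan in cp.entries:
            running.append((n_fillers, plan))
        fams = [i for i, (_n, p) in enumerate(running) if p.family_member]
        for a_i in range(len(fams)):
            for b_i in range(a_i + 1, len(fams)):
                i, j = fams[a_i], fams[b_i]
                intervening = sum(running[k][0] for k in range(i + 1, j + 1))
                pair = tuple(sorted((running[i][1].gene_id, running[j][1].gene_id)))
                (tandem if intervening <= 10 else not_tandem).append(pair)

    gff3 = _write_gff3_text(models)
    truth = {
        "phases": truth_phases,
        "intron_lengths": truth_intron_lengths,
        "motif_offsets": {g: dict(p.promoter_motifs) for g, p in plan_by_gene.items()},
        "tandem": sorted(tandem),
        "not_tandem": sorted(not_tandem),
        "segmental": sorted(segmental),
        "not_segmental": sorted(not_segmental),
    }
    return AnnotationBundle(
        genome=genome, gene_models=models, gff3=gff3,
        position_table=position_table, anchor_table=anchor_table,
        family=family, truth=truth,
    )


def _write_gff3_text(models: list) -> str:
    lines = ["##gff-version 3"]
    for m in models:
        gstart, gend = m.span
        lines.append(
            f"{m.chromosome}\ttetmine\tgene\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
            f"ID={m.gene_id}"
        )
        lines.append(
            f"{m.chromosome}\ttetmine\tmRNA\t{gstart}\t{gend}\t.\t{m.strand}\t.\t"
            f"ID={m.transcript_id};Parent={m.gene_id}"
        )
        for s, e in m.exons:
            lines.append(
                f"{m.chromosome}\ttetmine\texon\t{s}\t{e}\t.\t{m.strand}\t.\t"
                f"Parent={m.transcript_id}"
            )
        for s, e in m.cds:
            lines.append(
                f"{m.chromosome}\ttetmine\tCDS\t{s}\t{e}\t.\t{m.strand}\t0\t"
                f"Parent={m.transcript_id}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# qPCR Cq tables
# ---------------------------------------------------------------------------

@dataclass
class CqBundle:
    cq: pd.DataFrame
    truth_log2fc: pd.DataFrame  # genes x conditions
    pairing: dict
    reference_gene: str


def make_cq(spec: GeneratorSpec) -> CqBundle:
    """Cq table whose ΔΔCT analysis recovers a planted log2fc matrix.

    Model: Cq = gene baseline − true log2fc(condition) + condition shift
    (shared with the reference gene, so normalization removes it) +
    Normal(0, sd) noise; the reference gene is baseline + shift + noise.
    """
    plan = spec.expression
    rng = _rng(spec, 3)
    conditions = list(plan.pairing)
    if plan.true_log2fc is None:
        vals = rng.uniform(-4.0, 4.0, size=(len(plan.genes), len(conditions)))
        truth = pd.DataFrame(vals, index=list(plan.genes), columns=conditions)
        for cond, control in plan.pairing.items():
            if cond == control:
                truth[cond] = 0.0
    else:
        truth = plan.true_log2fc.copy()
    baselines = {g: float(rng.uniform(22.0, 30.0)) for g in plan.genes}
    baselines[plan.reference_gene] = 18.0
    shifts = {c: float(rng.normal(0.0, 0.5)) for c in conditions}
    rows = []
    for cond in conditions:
        for bio in range(1, plan.n_bio + 1):
            for tech in range(1, plan.n_tech + 1):
                for gene in plan.genes:
                    mu = baselines[gene] - float(truth.at[gene, cond]) + shifts[cond]
                    cqv = mu + float(rng.normal(0.0, plan.cq_sd)) if plan.cq_sd > 0 else mu
                    rows.append((gene, cond, "t0", bio, tech, cqv))
                mu = baselines[plan.reference_gene] + shifts[cond]
                cqv = mu + float(rng.normal(0.0, plan.cq_sd)) if plan.cq_sd > 0 else mu
                rows.append((plan.reference_gene, cond, "t0", bio, tech, cqv))
    cq = pd.DataFrame(rows, columns=["gene_id", "condition", "timepoint",
                                     "bio_rep", "tech_rep", "cq"])
    return CqBundle(cq=cq, truth_log2fc=truth, pairing=dict(plan.pairing),
                    reference_gene=plan.reference_gene)


# ---------------------------------------------------------------------------
# phylogeny and gene-model inputs with known truth
# ---------------------------------------------------------------------------

def make_additive_matrix(seed: int, n_taxa: int) -> pd.DataFrame:
    """Leaf path-length matrix of a random binary tree with strictly
    positive branch lengths — an additive (tree) metric by construction."""
    from .phylo import PhyloTree, TreeNode

    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng([seed, 4])
    labels = [f"t{i}" for i in range(n_taxa)]

    def build(names: list[str]) -> TreeNode:
        if len(names) == 1:
            return TreeNode(name=names[0])
        k = int(rng.integers(1, len(names)))
        left, right = names[:k], names[k:]
        node = TreeNode()
        node.children = [
            (build(left), float(rng.uniform(0.1, 2.0))),
            (build(right), float(rng.uniform(0.1, 2.0))),
        ]
        return node

    shuffled = list(labels)
    rng.shuffle(shuffled)
    tree = PhyloTree(root=build(shuffled))
    return tree.path_length_matrix().loc[labels, labels]


def make_planted_alignment(
    seed: int, n_informative: int = 200, noise: float = 0.05,
):
    """4-taxon protein alignment with a planted AB|CD split.

    Informative columns give A,B one residue and C,D another; with
    probability ``noise`` a column is replaced by independent random
    residues. Returns (alignment, planted bipartition frozenset({C, D})).
    """
    from .align import Alignment

    rng = np.random.default_rng([seed, 5])
    aas = list("ARNDCQEGHILKMFPSTWYV")
    cols = []
    for _ in range(n_informative):
        if rng.random() < noise:
            cols.append([str(rng.choice(aas)) for _ in range(4)])
        else:
            x1, x2 = rng.choice(aas, size=2, replace=False)
            cols.append([str(x1), str(x1), str(x2), str(x2)])
    rows = tuple("".join(col[i] for col in cols) for i in range(4))
    aln = Alignment(ids=("A", "B", "C", "D"), rows=rows)
    return aln, frozenset({"C", "D"})


def make_random_gene_models(seed: int, n: int) -> list[GeneModel]:
    """Random multi-exon all-coding gene models on both strands, for
    exercising intron/phase logic against an independent oracle."""
    rng = np.random.default_rng([seed, 6])
    models = []
    for i in range(n):
        n_exons = int(rng.integers(1, 7))
        exon_lengths = [int(rng.integers(20, 400)) for _ in range(n_exons)]
        intron_lengths = [int(rng.integers(60, 800)) for _ in range(n_exons - 1)]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, 5000))
        ivs = []
        pos = start
        for k, el in enumerate(exon_lengths):
            ivs.append((pos, pos + el - 1))
            pos += el
            if k < len(intron_lengths):
                pos += intron_lengths[k]
        models.append(
            GeneModel(
                gene_id=f"rg{i:03d}", transcript_id=f"rg{i:03d}.1",
                chromosome="chrR", strand=strand,
                exons=tuple(ivs), cds=tuple(ivs),
            )
        )
    return models
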