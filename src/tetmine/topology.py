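"""Tetraspanin region model and rule-cascade identification.

A tetraspanin has four transmembrane helices (TM1–TM4) with cytoplasmic
N- and C-termini, so the TM1–TM2 loop (EC1) and the TM3–TM4 loop (EC2) are
extracellular and the TM2–TM3 loop (ICL) is intracellular. EC2 is larger
than EC1 and carries the conserved cysteines and the plant signature motif
GCC[KR]P (long form SGCC[KR]PP).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .io import SequenceRecord, TopologyRecord

CANONICAL_REGIONS = ("Ntail", "TM1", "EC1", "TM2", "ICL", "TM3", "EC2", "TM4", "Ctail")

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

SIGNATURE_LONG = re.compile(r"SGCC[KR]PP")
SIGNATURE_CORE = re.compile(r"GCC[KR]P")
SEQUON = re.compile(r"N(?=[^P][ST])")  # N-{P}-[ST], overlaps allowed


@dataclass(frozen=True)
class RegionModel:
    """Region intervals tiling [1, length] on the protein.

    For a 4-TM protein with the N-terminus inside, loops are labeled
    EC1/ICL/EC2 by the canonical alternation. With the N-terminus outside,
    extracellular loops receive EC labels in order of occurrence and
    intracellular loops ICL labels; ``orientation_ok`` is False. For other
    TM counts EC/ICL labels are withheld (generic ``loopN`` keys).
    Empty regions are stored as ``(start, start - 1)``.
    """

    protein_id: str
    length: int
    n_tm: int
    n_terminus_side: str
    regions: dict[str, tuple[int, int]]
    orientation_ok: bool
    zero_length: tuple[str, ...] = ()

    def region_len(self, name: str) -> int:
        iv = self.regions.get(name)
        if iv is None:
            return 0
        return max(0, iv[1] - iv[0] + 1)

    def region_seq(self, name: str, seq: SequenceRecord) -> str:
        iv = self.regions.get(name)
        if iv is None or iv[1] < iv[0]:
            return ""
        return seq.residues[iv[0] - 1 : iv[1]]

    def region_of(self, residue: int) -> str | None:
        """Name of the region containing a 1-based residue position."""
        for name, (start, end) in self.regions.items():
            if start <= residue <= end:
                return name
        return None


def derive_regions(seq: SequenceRecord, topo: TopologyRecord) -> RegionModel:
    """Assign region intervals by alternating sidedness from the N-terminus.

    Requires ``topo.protein_id == seq.id`` and matching lengths. With
    ``n_terminus_side='unknown'`` the inside orientation is assumed here;
    use :func:`best_region_model` to score both.
    """
    if topo.protein_id != seq.id:
        raise ValueError(f"topology {topo.protein_id!r} does not match sequence {seq.id!r}")
    if topo.length != len(seq):
        raise ValueError(
            f"{seq.id}: sequence length {len(seq)} != topology length {topo.length}"
        )
    side = topo.n_terminus_side if topo.n_terminus_side != "unknown" else "inside"
    n = topo.n_tm
    segs = topo.tm_segments
    regions: dict[str, tuple[int, int]] = {}
    zero: list[str] = []

    def put(name: str, start: int, end: int):
        regions[name] = (start, end)
        if end < start:
            zero.append(name)

    if n == 0:
        put("Ntail", 1, len(seq))
        return RegionModel(
            protein_id=seq.id, length=len(seq), n_tm=0, n_terminus_side=side,
            regions=regions, orientation_ok=False, zero_length=tuple(zero),
        )

    # loop sides alternate, flipping across each TM
    loop_sides = []
    s = side
    for _ in range(n - 1):
        s = "outside" if s == "inside" else "inside"
        loop_sides.append(s)
    canonical = n == 4
    if canonical and side == "inside":
        loop_names = ["EC1", "ICL", "EC2"]
    elif canonical:
        # sidedness-based labels: EC to extracellular loops in order, ICL to
        # intracellular ones
        loop_names = []
        n_ec = n_ic = 0
        for ls in loop_sides:
            if ls == "outside":
                n_ec += 1
                loop_names.append(f"EC{n_ec}")
            else:
                n_ic += 1
                loop_names.append("ICL" if n_ic == 1 else f"ICL{n_ic}")
    else:
        loop_names = [f"loop{i}" for i in range(1, n)]

    put("Ntail", 1, segs[0][0] - 1)
    for i, (start, end) in enumerate(segs, 1):
        put(f"TM{i}", start, end)
    for i in range(n - 1):
        put(loop_names[i], segs[i][1] + 1, segs[i + 1][0] - 1)
    put("Ctail", segs[-1][1] + 1, len(seq))

    return RegionModel(
        protein_id=seq.id,
        length=len(seq),
        n_tm=n,
        n_terminus_side=side,
        regions=regions,
        orientation_ok=(canonical and side == "inside"),
        zero_length=tuple(zero),
    )


@dataclass(frozen=True)
class FeatureReport:
    """All measured features plus the classification verdict."""

    protein_id: str
    n_tm: int
    ntail_len: int
    ctail_len: int
    ec1_len: int
    ec2_len: int
    icl_len: int
    ec1_cys: int
    ec2_cys: int
    signature: str  # "SGCC[KR]PP", "GCC[KR]P", or "absent"
    signature_position: int | None  # 1-based protein position of match start
    sequons: tuple[int, ...]  # N positions of N-{P}-[ST] in EC2
    juxtamembrane_cys: tuple[int, ...]
    orientation_ok: bool
    verdict: str = "rejected"
    failed_rules: tuple[str, ...] = ()
    orientation_assumed: bool = False


def score_features(model: RegionModel, seq: SequenceRecord, jm_window: int = 5) -> FeatureReport:
    """Measure region lengths, EC cysteines, the EC2 signature motif,
    glycosylation sequons in EC2, and juxtamembrane cysteines.

    The signature search runs over EC2 only. Juxtamembrane cysteines are
    cysteines within ``jm_window`` residues of a TM boundary on the
    cytoplasmic side (a heuristic stand-in for palmitoylation-site
    prediction; so is the sequon scan for N-glycosylation).
    """
    ec1 = model.region_seq("EC1", seq)
    ec2 = model.region_seq("EC2", seq)
    ec2_iv = model.regions.get("EC2")
    ec2_offset = ec2_iv[0] - 1 if ec2_iv else 0

    signature = "absent"
    sig_pos = None
    m = SIGNATURE_LONG.search(ec2)
    if m:
        signature = "SGCC[KR]PP"
        sig_pos = ec2_offset + m.start() + 1
    else:
        m = SIGNATURE_CORE.search(ec2)
        if m:
            signature = "GCC[KR]P"
            sig_pos = ec2_offset + m.start() + 1

    sequons = tuple(ec2_offset + m.start() + 1 for m in SEQUON.finditer(ec2))

    # cytoplasmic regions flanking a TM, canonical orientation only
    jm: list[int] = []
    if model.orientation_ok:
        cyto = [model.regions.get(k) for k in ("Ntail", "ICL", "Ctail")]
        boundaries = [b for s, e in (model.regions[f"TM{i}"] for i in range(1, model.n_tm + 1))
                      for b in (s, e)]
        for iv in cyto:
            if iv is None or iv[1] < iv[0]:
                continue
            for pos in range(iv[0], iv[1] + 1):
                if seq.residues[pos - 1] != "C":
                    continue
                if any(abs(pos - b) <= jm_window for b in boundaries):
                    jm.append(pos)

    return FeatureReport(
        protein_id=seq.id,
        n_tm=model.n_tm,
        ntail_len=model.region_len("Ntail"),
        ctail_len=model.region_len("Ctail"),
        ec1_len=model.region_len("EC1"),
        ec2_len=model.region_len("EC2"),
        icl_len=model.region_len("ICL"),
        ec1_cys=ec1.count("C"),
        ec2_cys=ec2.count("C"),
        signature=signature,
        signature_position=sig_pos,
        sequons=sequons,
        juxtamembrane_cys=tuple(sorted(jm)),
        orientation_ok=model.orientation_ok,
    )


@dataclass(frozen=True)
class RuleConfig:
    """The identification cascade, each rule independently switchable.

    Rules: four TM helices; EC2 longer than EC1; at least ``cys_min``
    cysteines in EC2; signature motif present (``strict_signature`` demands
    the long SGCC[KR]PP form, default accepts the GCC[KR]P core); N- and
    C-tails at most ``tail_max`` residues; canonical membrane orientation.
    """

    require_four_tm: bool = True
    require_ec2_longer: bool = True
    cys_min: int | None = 9
    require_signature: bool = True
    strict_signature: bool = False
    tail_max: int | None = 60
    require_orientation: bool = True


RULE_NAMES = (
    "four_tm", "ec2_longer_than_ec1", "ec2_cysteines",
    "signature", "short_tails", "orientation",
)


def classify(report: FeatureReport, rules: RuleConfig | None = None) -> FeatureReport:
    """Apply the rule cascade; returns the report with verdict and the
    ordered list of failed rules filled in.

    EC2-dependent rules (EC2>EC1, cysteine count, signature) are evaluated
    only when the canonical 4-TM inside-N region model exists — otherwise a
    single topological defect would surface as four failures.
    """
    rules = rules or RuleConfig()
    failed: list[str] = []
    canonical = report.n_tm == 4 and report.orientation_ok

    if rules.require_four_tm and report.n_tm != 4:
        failed.append("four_tm")
    if rules.require_orientation and report.n_tm == 4 and not report.orientation_ok:
        failed.append("orientation")
    if canonical:
        if rules.require_ec2_longer and not report.ec2_len > report.ec1_len:
            failed.append("ec2_longer_than_ec1")
        if rules.cys_min is not None and report.ec2_cys < rules.cys_min:
            failed.append("ec2_cysteines")
        if rules.require_signature:
            ok = (report.signature == "SGCC[KR]PP") if rules.strict_signature else (
                report.signature != "absent"
            )
            if not ok:
                failed.append("signature")
    if rules.tail_max is not None and (
        report.ntail_len > rules.tail_max or report.ctail_len > rules.tail_max
    ):
        failed.append("short_tails")

    verdict = "tetraspanin" if not failed else "rejected"
    return replace(report, verdict=verdict, failed_rules=tuple(failed))


def best_region_model(seq: SequenceRecord, topo: TopologyRecord,
                      rules: RuleConfig | None = None) -> tuple[RegionModel, FeatureReport]:
    """Score a protein; with unknown N-terminus sidedness both orientations
    are scored and the verdict with fewer failed rules kept (flagged)."""
    if topo.n_terminus_side != "unknown":
        model = derive_regions(seq, topo)
        return model, classify(score_features(model, seq), rules)
    best = None
    for side in ("inside", "outside"):
        t = TopologyRecord(topo.protein_id, topo.length, topo.tm_segments, side)
        model = derive_regions(seq, t)
        rep = classify(score_features(model, seq), rules)
        rep = replace(rep, orientation_assumed=True)
        if best is None or len(rep.failed_rules) < len(best[1].failed_rules):
            best = (model, rep)
    return best


@dataclass
class MiningResult:
    """Outcome of screening a proteome: candidates, per-protein reports,
    and the funnel of counts at each filtering stage."""

    candidates: list[str]
    reports: dict[str, FeatureReport]
    funnel: dict[str, int]
    keyword_intersection: list[str] | None = None


def mine_proteome(
    seqs: list[SequenceRecord],
    topos: list[TopologyRecord],
    rules: RuleConfig | None = None,
    keyword_ids: set[str] | None = None,
) -> MiningResult:
    """Screen a proteome through the identification cascade.

    Funnel stages: total → has topology and ≥1 TM → exactly 4 TM → passes
    the cascade. Proteins with no topology record are excluded at stage 1.
    When ``keyword_ids`` (an annotation-text track) is provided, the
    intersection with the cascade's candidates is reported as well.
    """
    rules = rules or RuleConfig()
    topo_by_id = {t.protein_id: t for t in topos}
    funnel = {"total": len(seqs), "with_tm": 0, "four_tm": 0, "passed": 0}
    reports: dict[str, FeatureReport] = {}
    candidates: list[str] = []
    for seq in seqs:
        topo = topo_by_id.get(seq.id)
        if topo is None or topo.n_tm == 0:
            continue
        funnel["with_tm"] += 1
        if topo.n_tm == 4:
            funnel["four_tm"] += 1
        _model, report = best_region_model(seq, topo, rules)
        reports[seq.id] = report
        if report.verdict == "tetraspanin":
            funnel["passed"] += 1
            candidates.append(seq.id)
    candidates.sort()
    inter = sorted(set(candidates) & keyword_ids) if keyword_ids is not None else None
    return MiningResult(candidates=candidates, reports=reports, funnel=funnel,
                        keyword_intersection=inter)


def predict_tm_hydropathy(
    seq: SequenceRecord, window: int = 19, threshold: float = 1.6,
    merge_gap: int = 3,
) -> TopologyRecord:
    """Simple sliding-window Kyte–Doolittle TM predictor.

    Maximal-scoring non-overlapping windows with mean hydropathy above
    ``threshold`` become TM segments (greedy by score, leftmost on ties),
    merged when within ``merge_gap`` residues. N-terminus sidedness follows
    the positive-inside heuristic: the terminus flanking the more basic
    (K/R-rich) tail is placed inside. Sequences shorter than the window get
    an empty segment list.
    """
    n = len(seq)
    if n < window:
        return TopologyRecord(protein_id=seq.id, length=n, tm_segments=(),
                              n_terminus_side="unknown")
    kd = [KYTE_DOOLITTLE.get(aa, 0.0) for aa in seq.residues]
    # prefix sums -> window means
    prefix = [0.0]
    for v in kd:
        prefix.append(prefix[-1] + v)
    scores = [(prefix[i + window] - prefix[i]) / window for i in range(n - window + 1)]

    taken: list[tuple[int, int]] = []  # 0-based inclusive
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    for i in order:
        if scores[i] <= threshold:
            break
        s, e = i, i + window - 1
        if any(not (e < ts or s > te) for ts, te in taken):
            continue
        taken.append((s, e))
    taken.sort()
    merged: list[list[int]] = []
    for s, e in taken:
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    segs = tuple((s + 1, e + 1) for s, e in merged)

    if segs:
        nt = seq.residues[: segs[0][0] - 1]
        ct = seq.residues[segs[-1][1]:]
    else:
        nt, ct = seq.residues, ""
    basic = lambda s: s.count("K") + s.count("R")
    if basic(nt) >= basic(ct):
        side = "inside"
    else:
        # C-terminus inside; N shares its side iff the TM count is even
        side = "inside" if len(segs) % 2 == 0 else "outside"
    return TopologyRecord(protein_id=seq.id, length=n, tm_segments=segs,
                          n_terminus_side=side)
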