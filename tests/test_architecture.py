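"""Intron inference and phases, domain mapping, and duplication calls,
each checked against independent oracles (per-base spliced walk,
coordinate mirroring, brute-force chaining)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tetmine.architecture import (
    _chain_members,
    call_segmental,
    call_tandem,
    intergenic_distance,
    introns_of,
    map_intron_to_domain,
    phase_census,
)
from tetmine.io import GeneModel, SequenceRecord, TopologyRecord
from tetmine.simulate import make_random_gene_models
from tetmine.topology import derive_regions


def gene(exons, strand="+", cds=None, gid="g1"):
    return GeneModel(
        gene_id=gid, transcript_id=f"{gid}.1", chromosome="chr1",
        strand=strand, exons=tuple(exons), cds=tuple(cds or exons),
    )


def spliced_walk_oracle(model):
    """Independent phase oracle: walk the spliced CDS base by base in
    transcript order, recording the codon offset at each intron start."""
    exons = list(model.exons)
    introns = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        introns.append((e1 + 1, s2 - 1))
    cds_bases = []
    for s, e in model.cds:
        cds_bases.extend(range(s, e + 1))
    cds_set = set(cds_bases)
    if model.strand == "-":
        introns = list(reversed(introns))
        cds_bases = list(reversed(cds_bases))
    phases = []
    for gs, ge in introns:
        # count coding bases 5' of the intron in transcript order
        if model.strand == "+":
            upstream = sum(1 for b in cds_bases if b < gs)
        else:
            upstream = sum(1 for b in cds_bases if b > ge)
        if upstream == 0 or upstream >= len(cds_bases) or not cds_bases:
            phases.append(None)
        else:
            phases.append(upstream % 3)
    return phases


class TestIntrons:
    def test_single_exon_gene_has_no_introns(self):
        assert introns_of(gene([(100, 400)])) == []

    def test_plus_strand_phase_arithmetic(self):
        # exon CDS lengths 100 then 200 -> one intron, phase 100 mod 3 = 1
        m = gene([(1, 100), (201, 400)])
        (rec,) = introns_of(m)
        assert rec.length == 100
        assert rec.phase == 1
        assert rec.protein_position == 100 // 3 + 1

    def test_intron_lengths_sum_with_exons_to_span(self):
        m = gene([(1, 100), (201, 400), (501, 600)])
        recs = introns_of(m)
        span = m.span[1] - m.span[0] + 1
        total = sum(e - s + 1 for s, e in m.exons) + sum(r.length for r in recs)
        assert total == span

    def test_minus_strand_mirror_preserves_lengths_and_phases(self):
        """Mirroring a gene onto the minus strand (reflected coordinates)
        keeps intron lengths and phases identical."""
        plus = gene([(1, 100), (201, 400), (501, 600)])
        L = 1000
        mirrored = tuple(
            sorted((L - e + 1, L - s + 1) for s, e in plus.exons)
        )
        minus = gene(mirrored, strand="-")
        p_recs = introns_of(plus)
        m_recs = introns_of(minus)
        assert [r.length for r in p_recs] == [r.length for r in m_recs]
        assert [r.phase for r in p_recs] == [r.phase for r in m_recs]

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            introns_of(gene([(1, 100), (50, 200)]))

    @pytest.mark.parametrize("seed", range(4))
    def test_phases_match_spliced_walk_oracle(self, seed):
        for m in make_random_gene_models(seed, 50):
            got = [r.phase for r in introns_of(m)]
            assert got == spliced_walk_oracle(m), m.transcript_id

    def test_utr_intron_has_undefined_phase(self):
        # second exon entirely non-coding: the intron before it is 3' UTR
        m = gene([(1, 99), (200, 300)], cds=[(1, 99)])
        (rec,) = introns_of(m)
        assert rec.phase is None
        assert rec.protein_position is None


class TestPhaseCensus:
    def test_phase_multiset_for_five_exon_fixture(self):
        # cumulative CDS 99, 198, 298, 398 -> phases 0, 0, 1, 2
        m = gene([(1, 99), (200, 298), (400, 499), (600, 699), (800, 1097)])
        census = phase_census([m])
        assert census["per_gene"]["g1.1"] == [0, 0, 1, 2]
        assert census["totals"] == {0: 2, 1: 1, 2: 1, "undefined": 0}

    def test_exon_lengths_multiple_of_three_give_phase_zero(self):
        m = gene([(1, 99), (200, 298 + 2), (500, 599 + 1)])
        m = gene([(1, 99), (200, 301), (500, 601)])  # lengths 99, 102, 102
        census = phase_census([m])
        assert census["per_gene"]["g1.1"] == [0, 0]

    def test_empty_model_list(self):
        census = phase_census([])
        assert census["totals"] == {0: 0, 1: 0, 2: 0, "undefined": 0}
        assert census["per_gene"] == {}


class TestDomainMapping:
    def _region_model(self):
        seq = SequenceRecord(id="p1", residues="A" * 220)
        topo = TopologyRecord("p1", 220, ((11, 32), (41, 62), (81, 102), (171, 192)),
                              "inside")
        return derive_regions(seq, topo)

    def test_intron_after_300_cds_bases_maps_to_ec2(self):
        # EC2 spans residues 90-170 here; 300 CDS bases -> residue 101
        seq = SequenceRecord(id="p1", residues="A" * 220)
        topo = TopologyRecord("p1", 220, ((11, 32), (41, 62), (71, 89), (171, 192)),
                              "inside")
        model = derive_regions(seq, topo)
        assert model.regions["EC2"] == (90, 170)
        m = gene([(1, 300), (401, 700)])
        (rec,) = introns_of(m)
        assert rec.protein_position == 101
        assert map_intron_to_domain(rec, m, model) == "EC2"

    def test_intron_after_three_cds_bases_maps_to_ntail(self):
        model = self._region_model()
        m = gene([(1, 3), (101, 760)])
        (rec,) = introns_of(m)
        assert rec.protein_position == 2
        assert map_intron_to_domain(rec, m, model) == "Ntail"

    def test_position_beyond_protein_rejected(self):
        model = self._region_model()
        m = gene([(1, 3000), (3101, 3400)])
        (rec,) = introns_of(m)
        with pytest.raises(ValueError, match="beyond"):
            map_intron_to_domain(rec, m, model)


def positions(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end",
                                       "family_member"])


def layout(n_intervening):
    rows = [("famA", "chr1", 1000, 2000, True)]
    pos = 3000
    for i in range(n_intervening):
        rows.append((f"x{i}", "chr1", pos, pos + 500, False))
        pos += 1000
    rows.append(("famB", "chr1", pos, pos + 1000, True))
    return positions(rows)


class TestTandem:
    def test_ten_intervening_is_tandem(self):
        calls = call_tandem(layout(10))
        assert [(c.gene_a, c.gene_b) for c in calls] == [("famA", "famB")]
        assert calls[0].evidence["intervening_genes"] == 10

    def test_eleven_intervening_is_not(self):
        assert call_tandem(layout(11)) == []

    def test_adjacent_pair_is_tandem(self):
        calls = call_tandem(layout(0))
        assert [(c.gene_a, c.gene_b) for c in calls] == [("famA", "famB")]
        assert calls[0].evidence["intervening_genes"] == 0

    def test_different_chromosomes_never_tandem(self):
        table = positions([
            ("famA", "chr1", 1000, 2000, True),
            ("famB", "chr2", 3000, 4000, True),
        ])
        assert call_tandem(table) == []

    def test_intervening_family_genes_do_not_count(self):
        rows = [("famA", "chr1", 1000, 2000, True),
                ("famM", "chr1", 3000, 4000, True),
                ("famB", "chr1", 5000, 6000, True)]
        calls = call_tandem(positions(rows))
        pairs = {(c.gene_a, c.gene_b) for c in calls}
        assert ("famA", "famB") in pairs  # famM is related, not intervening


def anchors(rows):
    return pd.DataFrame(rows, columns=["gene_a", "chrom_a", "pos_a",
                                       "gene_b", "chrom_b", "pos_b"])


def brute_force_members(pa, pb, max_span, min_anchors):
    """Enumerate all subsets as candidate chains (ordered by pos_a) and
    mark anchors lying in some valid chain of sufficient length."""
    n = len(pa)
    member = [False] * n
    idx = sorted(range(n), key=lambda k: (pa[k], pb[k]))
    for r in range(min_anchors, n + 1):
        for combo in itertools.combinations(idx, r):
            ok = True
            for u, v in zip(combo, combo[1:]):
                if not (pa[v] > pa[u] and abs(pa[v] - pa[u]) <= max_span
                        and abs(pb[v] - pb[u]) <= max_span):
                    ok = False
                    break
            if not ok:
                continue
            diffs = [pb[v] - pb[u] for u, v in zip(combo, combo[1:])]
            if all(d > 0 for d in diffs) or all(d < 0 for d in diffs):
                for k in combo:
                    member[k] = True
    return member


class TestSegmental:
    def test_five_colinear_anchors_call_the_family_pair(self):
        rows = [(f"a{k}" if k != 2 else "famA", "chr1", 100_000 + 80_000 * k,
                 f"b{k}" if k != 2 else "famB", "chr2", 500_000 + 70_000 * k)
                for k in range(5)]
        calls = call_segmental(anchors(rows), family={"famA", "famB"})
        assert [(c.gene_a, c.gene_b, c.type) for c in calls] == [
            ("famA", "famB", "segmental")
        ]

    def test_large_gap_splits_chain_and_short_side_dropped(self):
        ps = [100_000, 200_000, 800_000, 900_000, 1_000_000]
        rows = [(f"a{k}" if k else "famA", "chr1", ps[k],
                 f"b{k}" if k else "famB", "chr2", ps[k]) for k in range(5)]
        calls = call_segmental(anchors(rows), family={"famA", "famB"})
        assert calls == []

    def test_empty_anchor_list(self):
        assert call_segmental(anchors([]), family={"x"}) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_chain_membership_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        pa = rng.integers(0, 1_500_000, size=n).tolist()
        pb = rng.integers(0, 1_500_000, size=n).tolist()
        df = anchors([(f"a{k}", "c1", pa[k], f"b{k}", "c2", pb[k]) for k in range(n)])
        got = _chain_members(df, max_span=500_000, min_anchors=3)
        want = brute_force_members(pa, pb, 500_000, 3)
        assert got == want


class TestIntergenicDistance:
    def test_gap_counts_bases_strictly_between(self):
        table = positions([
            ("a", "chr1", 100, 200, True), ("b", "chr1", 300, 400, True),
        ])
        assert intergenic_distance(table, "a", "b") == 99

    def test_overlapping_genes_have_zero_gap(self):
        table = positions([
            ("a", "chr1", 100, 250, True), ("b", "chr1", 200, 400, True),
        ])
        assert intergenic_distance(table, "a", "b") == 0

    def test_different_chromosomes_rejected(self):
        table = positions([
            ("a", "chr1", 100, 200, True), ("b", "chr2", 300, 400, True),
        ])
        with pytest.raises(ValueError, match="different chromosomes"):
            intergenic_distance(table, "a", "b")
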