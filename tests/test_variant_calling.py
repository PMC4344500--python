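"""Pileup construction, the four-filter variant caller, substitution
spectrum and the residual error bound."""

import itertools

import numpy as np
import pytest
from scipy import stats

import heteroseek as hs
from heteroseek.read_processing import Alignment
from heteroseek.variant_calling import CallerConfig


def mk_read(rid, seq):
    return hs.Read(id=rid, sequence=seq, qualities=np.full(len(seq), 35, dtype=np.int16))


def reads_covering(ref, pos, n, alt=None, strand="+", length=100, offset=50, id_prefix="r"):
    """n reads covering `pos` with the site `offset` bases from the read
    start (mid-read by default); optionally carrying `alt` at the site."""
    reads, alignments = [], []
    for i in range(n):
        start = pos - offset
        seq = ref.fetch(start, length)
        if alt is not None:
            seq = seq[:offset] + alt + seq[offset + 1:]
        oriented = seq if strand == "+" else hs.revcomp(seq)
        rid = f"{id_prefix}{i}"
        reads.append(mk_read(rid, oriented))
        alignments.append(
            Alignment(read_id=rid, maps_to="mtDNA", ref_start=start, strand=strand,
                      matched_length=length)
        )
    return reads, alignments


class TestBuildPileup:
    def test_error_free_column(self, small_ref):
        reads, alignments = reads_covering(small_ref, 500, 10)
        col = hs.build_pileup(alignments, reads, small_ref).column(500)
        assert col.depth == 10
        assert sum(col.counts[small_ref.base(500)]) == 10

    def test_end_proximal_definition(self, small_ref):
        """A base <10 nt from a read end is end-proximal; mid-read is not."""
        reads, alignments = reads_covering(small_ref, 105, 1, offset=4)  # read 101..200
        pileup = hs.build_pileup(alignments, reads, small_ref)
        assert pileup.column(105).end_proximal[small_ref.base(105)] == 1
        assert pileup.column(150).end_proximal[small_ref.base(150)] == 0
        assert pileup.column(195).end_proximal[small_ref.base(195)] == 1

    def test_planted_variant_counts(self, small_ref):
        """30% variant at depth 1,000: alt count within 3 binomial sigma."""
        pool = hs.make_haplotype_pool(small_ref, [(0, 0.7), (1, 0.3)], seed=2)
        (pos, _, alt), = pool.haplotypes[1].variants
        cfg = hs.ReadSimConfig(depth=1000, per_base_error=0.0, seed=3)
        reads, _ = hs.simulate_reads(pool, None, cfg)
        alignments = hs.map_reads(reads, small_ref)
        col = hs.build_pileup(alignments, reads, small_ref).column(pos)
        f_hat = sum(col.counts[alt]) / col.depth
        assert abs(f_hat - 0.3) <= 3 * np.sqrt(0.3 * 0.7 / col.depth)


class TestCallerFilters:
    """Each of the four filters flips its boundary fixture exactly."""

    def _call(self, small_ref, reads, alignments, **cfg_kwargs):
        pileup = hs.build_pileup(alignments, reads, small_ref)
        return hs.call_variants(pileup, CallerConfig(**cfg_kwargs))

    def test_three_mid_read_supports_called(self, small_ref):
        pos, ref_base = 500, small_ref.base(500)
        alt = "A" if ref_base != "A" else "G"
        r1, a1 = reads_covering(small_ref, pos, 2, alt=alt, strand="+", id_prefix="p")
        r2, a2 = reads_covering(small_ref, pos, 1, alt=alt, strand="-", id_prefix="m", offset=49)
        r3, a3 = reads_covering(small_ref, pos, 7, strand="+", id_prefix="w", offset=48)
        calls = self._call(small_ref, r1 + r2 + r3, a1 + a2 + a3)
        (c,) = calls
        assert (c.pos, c.alt, c.frequency) == (pos, alt, pytest.approx(0.30))
        assert (c.support_forward, c.support_reverse) == (2, 1)

    def test_two_supports_not_called(self, small_ref):
        pos, ref_base = 500, small_ref.base(500)
        alt = "A" if ref_base != "A" else "G"
        r1, a1 = reads_covering(small_ref, pos, 2, alt=alt, id_prefix="p")
        r2, a2 = reads_covering(small_ref, pos, 98, id_prefix="w", offset=48)
        assert self._call(small_ref, r1 + r2, a1 + a2) == []

    def test_coverage_below_ten_not_called(self, small_ref):
        pos, ref_base = 500, small_ref.base(500)
        alt = "A" if ref_base != "A" else "G"
        r1, a1 = reads_covering(small_ref, pos, 2, alt=alt, strand="+", id_prefix="p")
        r2, a2 = reads_covering(small_ref, pos, 1, alt=alt, strand="-", id_prefix="m", offset=49)
        r3, a3 = reads_covering(small_ref, pos, 6, id_prefix="w", offset=48)
        assert self._call(small_ref, r1 + r2 + r3, a1 + a2 + a3) == []  # depth 9
        r4, a4 = reads_covering(small_ref, pos, 7, id_prefix="w", offset=48)
        assert len(self._call(small_ref, r1 + r2 + r4, a1 + a2 + a4)) == 1  # depth 10

    def test_single_strand_support_excluded(self, small_ref):
        """5 alt reads all forward: strand fraction 1.0 > 0.80 -> excluded;
        4+/1- (0.8, not strictly above) -> called."""
        pos, ref_base = 500, small_ref.base(500)
        alt = "A" if ref_base != "A" else "G"
        plus5, ap5 = reads_covering(small_ref, pos, 5, alt=alt, strand="+", id_prefix="p")
        wt, aw = reads_covering(small_ref, pos, 10, id_prefix="w", offset=48)
        assert self._call(small_ref, plus5 + wt, ap5 + aw) == []
        plus4, ap4 = reads_covering(small_ref, pos, 4, alt=alt, strand="+", id_prefix="p")
        minus1, am1 = reads_covering(small_ref, pos, 1, alt=alt, strand="-", id_prefix="m", offset=49)
        (c,) = self._call(small_ref, plus4 + minus1 + wt, ap4 + am1 + aw)
        assert (c.support_forward, c.support_reverse) == (4, 1)

    def test_end_proximal_support_ineligible(self, small_ref):
        """3 alt reads whose variant base sits <10 nt from a read end do not
        make a call, even though depth is ample."""
        pos, ref_base = 500, small_ref.base(500)
        alt = "A" if ref_base != "A" else "G"
        r1, a1 = reads_covering(small_ref, pos, 2, alt=alt, strand="+", offset=5, id_prefix="p")
        r2, a2 = reads_covering(small_ref, pos, 1, alt=alt, strand="-", offset=95, id_prefix="m")
        r3, a3 = reads_covering(small_ref, pos, 20, id_prefix="w", offset=48)
        assert self._call(small_ref, r1 + r2 + r3, a1 + a2 + a3) == []

    def test_homoplasmic_variant_frequency_exactly_one(self, small_ref):
        pool = hs.make_haplotype_pool(small_ref, [(2, 1.0)], seed=6)
        cfg = hs.ReadSimConfig(depth=60, per_base_error=0.0, seed=7)
        reads, _ = hs.simulate_reads(pool, None, cfg)
        alignments = hs.map_reads(reads, small_ref)
        nonclonal, _ = hs.collapse_clonal(alignments, reads)
        calls = hs.call_variants(hs.build_pileup(nonclonal, reads, small_ref))
        assert {c.key for c in calls} == set(pool.truth_variants())
        assert all(c.frequency == 1.0 for c in calls)

    def test_calls_invariant_to_read_order_and_duplication(self, small_ref):
        """Clonal collapse upstream makes calls invariant to input order and
        to duplication of reads."""
        pool = hs.make_haplotype_pool(small_ref, [(0, 0.5), (2, 0.5)], seed=8)
        cfg = hs.ReadSimConfig(depth=80, per_base_error=0.0, seed=9)
        reads, _ = hs.simulate_reads(pool, None, cfg)

        def run(rs):
            al = hs.map_reads(rs, small_ref)
            nc, _ = hs.collapse_clonal(al, rs)
            return hs.call_variants(hs.build_pileup(nc, rs, small_ref))

        base = run(reads)
        shuffled = run(reads[::-1])
        duplicated = run(reads + [hs.Read(r.id + "x", r.sequence, r.qualities.copy())
                                  for r in reads[:50]])
        key = lambda cs: sorted((c.key, round(c.frequency, 9)) for c in cs)
        assert key(base) == key(shuffled) == key(duplicated)


class TestSubstitutionClasses:
    def test_exhaustive_enumeration(self):
        """All 12 ordered pairs: 4 transitions, 8 transversions."""
        classes = [
            hs.classify_substitution(a, b)
            for a, b in itertools.permutations("ACGT", 2)
        ]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8

    def test_identical_alleles_rejected(self):
        with pytest.raises(ValueError):
            hs.classify_substitution("A", "A")

    def test_spectrum_counts(self):
        call = lambda ref, alt: hs.VariantCall(
            pos=1, ref=ref, alt=alt, frequency=0.5, support_forward=2,
            support_reverse=2, depth=8,
        )
        s = hs.mutation_spectrum([call("A", "G"), call("C", "T"), call("C", "A")])
        assert (s.n_transitions, s.n_transversions) == (2, 1)
        assert s.transition_fraction == pytest.approx(2 / 3)
        single = hs.mutation_spectrum([call("A", "G")])
        assert single.transition_fraction == 1.0
        empty = hs.mutation_spectrum([])
        assert empty.empty and np.isnan(empty.transition_fraction)


class TestResidualErrorBound:
    def test_three_read_rule_at_q30(self):
        """error 1e-3, depth 50, support 3: residual well under 1e-6."""
        p = hs.residual_error_bound(1e-3, 50, 3)
        assert p == pytest.approx(7.3e-7, rel=0.05)
        assert p < 1e-6

    def test_single_read_closed_form(self):
        e, C = 1e-3, 30
        q = e / 3
        assert hs.residual_error_bound(e, C, 1) == pytest.approx(1 - (1 - q) ** C)

    def test_zero_error(self):
        assert hs.residual_error_bound(0.0, 50, 3) == 0.0

    @pytest.mark.parametrize("args", [(-0.1, 50, 3), (1e-3, 2, 3), (1e-3, 50, 0)])
    def test_invalid_parameters(self, args):
        with pytest.raises(ValueError):
            hs.residual_error_bound(*args)
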