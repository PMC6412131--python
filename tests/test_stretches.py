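import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csckit import (
    GeneSequence,
    HalfLifeTable,
    SENSE_CODONS,
    filter_for_metagene,
    find_stretches,
    make_genome,
    position_halflife_association,
    stretch_position_histogram,
    window_sums,
)
from csckit.stretches import StretchHit
from conftest import make_csc


def naive_window_sums(gene, csc, w):
    sense = gene.sense_codons
    return [sum(csc.values[c] for c in sense[k : k + w]) for k in range(len(sense) - w + 1)]


def naive_find(genes, csc, w, lo, hi, merge=True):
    """Independent scanner: enumerate windows, then merge qualifying runs."""
    hits = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        sums = naive_window_sums(gene, csc, w)
        li = gene.n_sense
        for polarity, qualifies, pick in (
            ("non_optimal", lambda s: s <= lo, min),
            ("optimal", lambda s: s >= hi, max),
        ):
            starts = [k + 1 for k, s in enumerate(sums) if qualifies(s)]
            if not starts:
                continue
            if not merge:
                for s in starts:
                    hits.append((gene.gene_id, s, polarity, sums[s - 1]))
                continue
            run = [starts[0]]
            for s in starts[1:]:
                if s <= run[-1] + w:
                    run.append(s)
                else:
                    hits.append((gene.gene_id, run[0], polarity, pick(sums[k - 1] for k in run)))
                    run = [s]
            hits.append((gene.gene_id, run[0], polarity, pick(sums[k - 1] for k in run)))
    return sorted(hits)


class TestWindowSums:
    def test_constant_case_hits_threshold(self):
        table = make_csc(fill=-0.128)
        gene = GeneSequence("g", tuple(SENSE_CODONS[:10]), False)
        sums = window_sums(gene, table, w=10)
        assert sums.shape == (1,)
        assert sums[0] == pytest.approx(-1.28)

    def test_full_length_window_equals_length_times_cscg(self, small_genome, random_csc):
        from csckit import codon_frequencies, compute_cscg

        gene = small_genome[0]
        sums = window_sums(gene, random_csc, w=gene.n_sense)
        cscg = compute_cscg(codon_frequencies(gene), random_csc)
        assert sums[0] == pytest.approx(gene.n_sense * cscg, abs=1e-10)

    def test_matches_naive_recomputation(self, small_genome, random_csc):
        for gene in small_genome:
            got = window_sums(gene, random_csc, w=10)
            expected = naive_window_sums(gene, random_csc, 10)
            assert np.allclose(got, expected, atol=1e-12)

    def test_short_gene_gives_empty_vector(self, random_csc):
        gene = GeneSequence("g", ("ATG", "GCT"), False)
        assert window_sums(gene, random_csc, w=10).size == 0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 1000), w=st.integers(2, 15))
    def test_prefix_sum_identity(self, seed, w):
        """sum(k+1) - sum(k) == CSC(codon k+w) - CSC(codon k)."""
        rng = np.random.default_rng(seed)
        codons = tuple(SENSE_CODONS[i] for i in rng.integers(0, 61, 40))
        gene = GeneSequence("g", codons, False)
        table = make_csc(
            {c: float(v) for c, v in zip(SENSE_CODONS, rng.uniform(-1, 1, 61))}
        )
        sums = window_sums(gene, table, w=w)
        vals = [table.values[c] for c in codons]
        for k in range(len(sums) - 1):
            assert sums[k + 1] - sums[k] == pytest.approx(
                vals[k + w] - vals[k], abs=1e-12
            )


class TestFindStretches:
    def test_single_qualifying_window(self):
        table = make_csc(fill=0.0, values={"GCG": -0.2})
        codons = ("ATG",) * 5 + ("GCG",) * 10 + ("ATG",) * 5
        gene = GeneSequence("g", codons, False)
        hits = find_stretches([gene], table, lo=-1.9, hi=1.9)
        assert len(hits) == 1
        assert hits[0].start_codon == 6
        assert hits[0].polarity == "non_optimal"
        assert hits[0].sum_csc == pytest.approx(-2.0)
        assert hits[0].relative_position == pytest.approx(6 / 20)

    def test_adjacent_windows_merge_to_leftmost(self):
        table = make_csc(fill=0.0, values={"GCG": -0.2})
        codons = ("ATG",) * 3 + ("GCG",) * 11 + ("ATG",) * 3
        gene = GeneSequence("g", codons, False)
        hits = find_stretches([gene], table, lo=-1.99, hi=1.99)
        assert len(hits) == 1
        assert hits[0].start_codon == 4
        no_merge = find_stretches([gene], table, lo=-1.99, hi=1.99, merge=False)
        assert [h.start_codon for h in no_merge] == [4, 5]

    @pytest.mark.parametrize("merge", [True, False])
    def test_matches_brute_force_scanner(self, merge, random_csc):
        genes = make_genome(200, (20, 120), seed=11)
        hits = find_stretches(genes, random_csc, w=10, lo=-1.0, hi=1.0, merge=merge)
        got = sorted((h.gene_id, h.start_codon, h.polarity, h.sum_csc) for h in hits)
        expected = naive_find(genes, random_csc, 10, -1.0, 1.0, merge=merge)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:3] == e[:3]
            assert g[3] == pytest.approx(e[3], abs=1e-12)

    def test_gene_order_invariance(self, random_csc):
        genes = make_genome(50, (20, 80), seed=13)
        fwd = find_stretches(genes, random_csc, lo=-1.0, hi=1.0)
        rev = find_stretches(list(reversed(genes)), random_csc, lo=-1.0, hi=1.0)
        assert [(h.gene_id, h.start_codon) for h in fwd] == [
            (h.gene_id, h.start_codon) for h in rev
        ]

    def test_merged_hits_do_not_overlap(self, random_csc):
        genes = make_genome(100, (50, 150), seed=17)
        hits = find_stretches(genes, random_csc, lo=-0.8, hi=0.8)
        by_key = {}
        for h in hits:
            by_key.setdefault((h.gene_id, h.polarity), []).append(h)
        for group in by_key.values():
            group.sort(key=lambda h: h.start_codon)
            for a, b in zip(group, group[1:]):
                assert b.start_codon > a.end_codon

    def test_every_hit_satisfies_its_threshold(self, random_csc):
        genes = make_genome(100, (50, 150), seed=19)
        for h in find_stretches(genes, random_csc, lo=-0.8, hi=0.8):
            if h.polarity == "non_optimal":
                assert h.sum_csc <= -0.8
            else:
                assert h.sum_csc >= 0.8


def hit(gene_id, start, li=400, polarity="non_optimal"):
    return StretchHit(gene_id, start, start + 9, 10, -1.5, polarity, start / li)


class TestFilterForMetagene:
    def test_filtering_order_and_counts(self):
        hl = HalfLifeTable({"a": 10.0, "c": 12.0})
        hits = [
            hit("a", 50), hit("b", 40), hit("b", 120),  # b: multi-stretch
            hit("c", 250),                              # c: too far from ATG
            hit("d", 30),                               # d: no half-life
        ]
        kept, removed = filter_for_metagene(hits, hl)
        assert [h.gene_id for h in kept] == ["a"]
        assert removed == {"multi_stretch": 2, "position": 1, "no_half_life": 1}

    def test_polarity_counted_separately(self):
        hits = [hit("a", 50), hit("a", 120, polarity="optimal")]
        kept, removed = filter_for_metagene(hits, None)
        assert len(kept) == 2 and removed["multi_stretch"] == 0

    def test_boundary_position_strict(self):
        kept, removed = filter_for_metagene([hit("a", 200)], None)
        assert kept == [] and removed["position"] == 1


class TestPositionHistogram:
    def test_single_bin_mass(self):
        hits = [hit("a", 20), hit("b", 20)]
        freqs, edges = stretch_position_histogram(hits, mode="relative", bins=10)
        assert freqs.sum() == pytest.approx(1.0)
        assert freqs[0] == 1.0  # 20/400 = 0.05 -> first decile

    def test_uniform_positions_fill_bins_evenly(self):
        rng = np.random.default_rng(23)
        hits = [
            StretchHit(f"g{i}", 1, 10, 10, -1.5, "non_optimal", float(p))
            for i, p in enumerate(rng.uniform(0, 1, 10000))
        ]
        freqs, _ = stretch_position_histogram(hits, mode="relative", bins=10)
        assert np.all(np.abs(freqs - 0.1) < 0.01)

    def test_order_invariance(self):
        rng = np.random.default_rng(29)
        hits = [hit(f"g{i}", int(s)) for i, s in enumerate(rng.integers(1, 390, 100))]
        f1, _ = stretch_position_histogram(hits, mode="absolute", bins=8)
        f2, _ = stretch_position_histogram(list(reversed(hits)), mode="absolute", bins=8)
        assert np.array_equal(f1, f2)


class TestPositionHalflifeAssociation:
    def test_monotone_gives_rho_one(self):
        hits = [hit(f"g{i}", 10 * (i + 1)) for i in range(5)]
        hl = HalfLifeTable({f"g{i}": float(10 + i) for i in range(5)})
        rho, p, n = position_halflife_association(hits, hl)
        assert rho == pytest.approx(1.0)
        assert n == 5

    def test_null_simulation_stays_small(self):
        rng = np.random.default_rng(31)
        rhos = []
        for _ in range(100):
            hits = [hit(f"g{i}", int(s)) for i, s in enumerate(rng.integers(1, 390, 300))]
            hl = HalfLifeTable({f"g{i}": float(v) for i, v in enumerate(rng.uniform(1, 60, 300))})
            rho, _, _ = position_halflife_association(hits, hl)
            rhos.append(abs(rho))
        assert np.quantile(rhos, 0.95) < 0.15

    def test_constant_halflife_undefined(self):
        hits = [hit(f"g{i}", 10 * (i + 1)) for i in range(5)]
        hl = HalfLifeTable({f"g{i}": 10.0 for i in range(5)})
        rho, p, n = position_halflife_association(hits, hl)
        assert np.isnan(rho)

    def test_too_few_pairs_rejected(self):
        hl = HalfLifeTable({"g0": 10.0})
        with pytest.raises(ValueError):
            position_halflife_association([hit("g0", 5)], hl)
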