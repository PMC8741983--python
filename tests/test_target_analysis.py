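"""Seed sites, duplex energies, interaction filters and targeting statistics."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirwave import synthetic_data as sim
from mirwave import target_analysis as ta
from mirwave.synthetic_data import reverse_complement


MIR = "UGAGGUAGUAGGUUGUAUAGUU"  # a let-7-like 22-mer


def embed(core, rng, length=200, at=None):
    at = at if at is not None else length // 2
    seq = "".join(rng.choice(list("ACGU"), length))
    return seq[:at] + core + seq[at + len(core):]


class TestFindSeedSites:
    def test_site_type_classification(self, rng):
        seed6 = reverse_complement(MIR[1:7])
        m8 = reverse_complement(MIR[7])
        cases = {
            "6mer": "G" + seed6 + "G",
            "7mer-m8": m8 + seed6 + "G",
            "7mer-A1": "G" + seed6 + "A",
            "8mer": m8 + seed6 + "A",
        }
        for expected, core in cases.items():
            utr = embed(core, rng)
            hits = [s for s in ta.find_seed_sites(MIR, utr)]
            assert [s.site_type for s in hits] == [expected], expected

    def test_site_span_covers_typed_extent(self, rng):
        core = reverse_complement(MIR[7]) + reverse_complement(MIR[1:7]) + "A"
        utr = embed(core, rng, at=80)
        (site,) = ta.find_seed_sites(MIR, utr)
        assert (site.start, site.end) == (80, 88)
        assert site.site_type == "8mer"

    def test_matches_exhaustive_scan(self, rng):
        mirnas = ["".join(rng.choice(list("ACGU"), 22)) for _ in range(10)]
        utr = "".join(rng.choice(list("ACGU"), 2000))
        for m in mirnas:
            found = {s.start if s.site_type in ("6mer", "7mer-A1") else s.start + 1
                     for s in ta.find_seed_sites(m, utr)}
            word = reverse_complement(m[1:7])
            expected = {i for i in range(len(utr) - 5) if utr[i:i + 6] == word}
            assert found == expected

    def test_clean_background_has_no_sites(self):
        cfg = sim.SimulationConfig(rng_seed=3)
        rng = np.random.default_rng(8)
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 22)) for i in range(10)}
        utrs, _ = sim.gen_utr_targets(cfg, mirnas, plan=[], utr_ids=["u"],
                                      utr_length=2000)
        for mid, seq in mirnas.items():
            assert ta.find_seed_sites(seq, utrs["u"], mid, "u") == []

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            ta.find_seed_sites(MIR, "ACGTXACGT")


class TestDuplexEnergy:
    def test_full_complement_sums_stack_table(self):
        target = reverse_complement(MIR)
        expected = sum(
            ta.STACK_TABLE[(MIR[i], MIR[i + 1], target[::-1][i], target[::-1][i + 1])]
            for i in range(len(MIR) - 1)
        )
        assert ta.duplex_energy(MIR, target) == pytest.approx(expected)
        assert ta.duplex_energy(MIR, target) < -20

    def test_no_pairing_possible_gives_zero(self):
        assert ta.duplex_energy("AAAAAAAAAA", "AAAAAAAAAA") == 0.0
        assert ta.duplex_energy("ACACACAC", "AAAAAAAA") == 0.0

    def test_strand_swap_invariance(self, rng):
        # the duplex does not care which strand is called the miRNA;
        # (reverse-complement relabeling is only a symmetry of pure
        # Watson-Crick duplexes - it destroys G:U pairs)
        for _ in range(5):
            a = "".join(rng.choice(list("ACGU"), 18))
            b = "".join(rng.choice(list("ACGU"), 25))
            assert ta.duplex_energy(a, b) == pytest.approx(ta.duplex_energy(b, a))

    def test_energy_never_positive(self, rng):
        for _ in range(20):
            a = "".join(rng.choice(list("ACGU"), 20))
            b = "".join(rng.choice(list("ACGU"), 30))
            assert ta.duplex_energy(a, b) <= 0.0

    def test_stack_table_symmetry(self):
        for (w, x, z, y), v in ta.STACK_TABLE.items():
            assert ta.STACK_TABLE[(y, z, x, w)] == v


class TestFilterInteractions:
    def expr(self, ids, value=100.0):
        return pd.DataFrame({"tp1": value}, index=pd.Index(ids))

    def site(self, start):
        return ta.SeedSite("u1", "m1", "8mer", start, start + 8)

    def run(self, energies_list, expr_val=100.0, **kwargs):
        sites = [self.site(10 * (i + 1)) for i in range(len(energies_list))]
        energies = {("u1", "m1", s.start): e
                    for s, e in zip(sites, energies_list)}
        return ta.filter_interactions(
            sites, energies, self.expr(["m1"], expr_val), self.expr(["u1"]),
            **kwargs)[0]

    def test_two_strong_sites_pass(self):
        assert self.run([-15.0, -15.0]).passes_filters

    def test_weak_site_drops_below_min_sites(self):
        inter = self.run([-15.0, -9.5])
        assert inter.n_sites == 1 and not inter.passes_filters

    def test_boundary_energy_is_excluded(self):
        # strictly below -10: a site at exactly -10.0 fails
        inter = self.run([-10.0, -15.0])
        assert inter.n_sites == 1 and not inter.passes_filters

    def test_unexpressed_partner_fails(self):
        assert not self.run([-15.0, -15.0], expr_val=5.0).passes_filters

    def test_relaxing_cutoff_is_monotone(self):
        for cutoff in (-14.0, -12.0, -10.0, -8.0):
            strict = self.run([-13.0, -13.0], energy_cutoff=cutoff)
            loose = self.run([-13.0, -13.0], energy_cutoff=cutoff + 1.0)
            assert not strict.passes_filters or loose.passes_filters

    def test_planted_interactions_recovered(self, rng):
        cfg = sim.SimulationConfig(rng_seed=31)
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGU"), 22)) for i in range(3)}
        plan = [sim.SitePlant("m0", "u0", n_sites=2, perfect=True),
                sim.SitePlant("m1", "u1", n_sites=1, perfect=True),
                sim.SitePlant("m2", "u2", n_sites=2, perfect=False)]
        utrs, truth = sim.gen_utr_targets(cfg, mirnas, plan)
        expr_m = self.expr(list(mirnas))
        expr_u = self.expr(list(utrs))
        _, _, interactions = ta.predict_interactions(mirnas, utrs, expr_m, expr_u)
        passing = {(i.mirna_id, i.mrna_id) for i in interactions if i.passes_filters}
        assert ("m0", "u0") in passing          # two perfect sites
        assert ("m1", "u1") not in passing      # single site


class TestHypergeometric:
    def test_worked_example_exact(self):
        # m=5 targeted, n=5 not, cluster k=4 with q=3
        expected = Fraction(comb(5, 3) * comb(5, 1) + comb(5, 4) * comb(5, 0),
                            comb(10, 4))
        assert ta.hypergeom_upper(3, 5, 5, 4) == pytest.approx(float(expected),
                                                               abs=1e-12)
        assert float(expected) == pytest.approx(55 / 210)

    def test_matches_exact_enumeration_small_populations(self, rng):
        for _ in range(50):
            m = int(rng.integers(1, 30))
            n = int(rng.integers(1, 30))
            k = int(rng.integers(1, m + n))
            q = int(rng.integers(0, min(m, k) + 1))
            total = comb(m + n, k)
            upper = sum(comb(m, x) * comb(n, k - x)
                        for x in range(q, min(m, k) + 1)
                        if 0 <= k - x <= n)
            assert ta.hypergeom_upper(q, m, n, k) == pytest.approx(
                upper / total, abs=1e-12)

    def test_tails_overlap_at_observation(self):
        for q, m, n, k in [(2, 6, 7, 5), (0, 3, 3, 2), (4, 9, 2, 6)]:
            assert (ta.hypergeom_upper(q, m, n, k)
                    + ta.hypergeom_lower(q, m, n, k)) >= 1.0


class TestMannWhitney:
    def test_identical_multisets_give_unit_p(self):
        _, p = ta.mann_whitney_test([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_worked_example(self):
        u, p = ta.mann_whitney_test([1, 1, 2], [5, 6, 7])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_matches_permutation_oracle(self, rng):
        for trial in range(100):
            nx, ny = int(rng.integers(2, 9)), int(rng.integers(2, 9))
            x = rng.integers(0, 6, nx).astype(float)  # heavy ties
            y = rng.integers(0, 6, ny).astype(float)
            _, p = ta.mann_whitney_test(x, y)
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            u_obs = ta.mann_whitney_u(x, y)
            lower = upper = total = 0
            for idx in itertools.combinations(range(len(pooled)), nx):
                r1 = ranks[list(idx)].sum()
                u = r1 - nx * (nx + 1) / 2
                total += 1
                lower += u <= u_obs + 1e-9
                upper += u >= u_obs - 1e-9
            expected = min(1.0, 2 * min(lower, upper) / total)
            assert p == pytest.approx(expected, abs=1e-12), (x, y)


class TestEnrichmentAndBurden:
    def interactions(self, pairs):
        return [ta.Interaction(m, g, [], -15.0, 2, True) for m, g in pairs]

    def test_planted_overtargeting_flagged(self, rng):
        # cluster c1 three-fold enriched in targeted mRNAs
        genes = [f"g{i}" for i in range(2000)]
        clusters = {g: ("c1" if i < 400 else f"c{2 + i % 4}")
                    for i, g in enumerate(genes)}
        targeted = [g for i, g in enumerate(genes)
                    if (i < 400 and rng.random() < 0.3)
                    or (i >= 400 and rng.random() < 0.1)]
        inter = self.interactions([("m1", g) for g in targeted])
        results = ta.targeting_enrichment(inter, clusters, {g: True for g in genes})
        by_cluster = {r.cluster: r for r in results}
        assert by_cluster["c1"].direction == "over"
        assert by_cluster["c1"].padj < 0.05

    def test_central_cluster_not_significant(self):
        genes = [f"g{i}" for i in range(10)]
        clusters = {g: ("c1" if i < 4 else "c2") for i, g in enumerate(genes)}
        targeted = ["g0", "g1", "g4", "g5", "g6"]
        inter = self.interactions([("m1", g) for g in targeted])
        results = ta.targeting_enrichment(inter, clusters, {g: True for g in genes})
        assert all(r.pvalue >= 0.3 for r in results)

    def test_burden_identical_clusters_unit_p(self):
        pairs = [(f"m{j}", f"g{i}") for i in range(6) for j in range(i % 3 + 1)]
        inter = self.interactions(pairs)
        clusters = {f"g{i}": ("c1" if i < 3 else "c2") for i in range(6)}
        out = ta.targeting_burden_tests(inter, clusters)
        assert (out["padj"] == 1.0).all()

    def test_burden_skips_tiny_clusters_with_note(self):
        inter = self.interactions([("m1", "g1"), ("m1", "g2"), ("m2", "g2"),
                                   ("m1", "g3")])
        clusters = {"g1": "c1", "g2": "c1", "g3": "c2"}
        out = ta.targeting_burden_tests(inter, clusters)
        assert (out["note"] != "").all()
        assert out["pvalue"].isna().all()
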