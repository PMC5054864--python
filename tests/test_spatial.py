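import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from myxogeo.design import SCALES, Scale, sample_sheet_from_ids
from myxogeo.spatial import (
    clade_absence_test,
    clade_frequency_test,
    geographic_distance_matrix,
    mantel_test,
    nearest_st_concordance,
    scale_distance_curve,
    st_clade_map,
    st_site_map,
    within_vs_among_site_test,
)


def random_distance_matrix(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestMantel:
    def test_perfect_linear_relationship(self, rng):
        geo = random_distance_matrix(rng, 10)
        gen = 2.0 * geo + 0.5
        np.fill_diagonal(gen, 0.0)
        res = mantel_test(geo, gen, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)  # resolution floor

    def test_size_mismatch_is_error(self, rng):
        with pytest.raises(ValueError, match="sizes differ"):
            mantel_test(random_distance_matrix(rng, 5), random_distance_matrix(rng, 6))

    def test_constant_matrix_is_error(self):
        ones = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(ValueError, match="constant"):
            mantel_test(ones, ones)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_enumeration_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        geo = random_distance_matrix(rng, 4)
        gen = random_distance_matrix(rng, 4)
        res = mantel_test(geo, gen, n_perm="exact")
        # independent oracle: full 4! enumeration with plain pearson r
        iu = np.triu_indices(4, 1)
        r_obs = stats.pearsonr(geo[iu], gen[iu]).statistic
        count = 0
        for perm in itertools.permutations(range(4)):
            idx = np.array(perm)
            rp = stats.pearsonr(geo[np.ix_(idx, idx)][iu], gen[iu]).statistic
            if abs(rp) >= abs(r_obs) - 1e-12:
                count += 1
        assert res.r == pytest.approx(r_obs)
        assert res.p == pytest.approx(count / 24)

    def test_invariant_under_common_relabeling(self, rng):
        geo = random_distance_matrix(rng, 8)
        gen = random_distance_matrix(rng, 8)
        perm = rng.permutation(8)
        r1 = mantel_test(geo, gen, n_perm=9, seed=0).r
        r2 = mantel_test(geo[np.ix_(perm, perm)], gen[np.ix_(perm, perm)], n_perm=9, seed=0).r
        assert r1 == pytest.approx(r2)

    def test_seeded_reproducibility(self, rng):
        geo = random_distance_matrix(rng, 8)
        gen = random_distance_matrix(rng, 8)
        a = mantel_test(geo, gen, n_perm=199, seed=5)
        b = mantel_test(geo, gen, n_perm=199, seed=5)
        assert a.p == b.p

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel

        geo = random_distance_matrix(rng, 12)
        gen = 0.7 * geo + 0.3 * random_distance_matrix(rng, 12)
        np.fill_diagonal(gen, 0.0)
        gen = (gen + gen.T) / 2
        mine = mantel_test(geo, gen, n_perm=999, seed=0)
        r_ref, p_ref, _ = mantel(
            DistanceMatrix(geo), DistanceMatrix(gen), permutations=999, alternative="two-sided"
        )
        assert mine.r == pytest.approx(float(r_ref))
        assert abs(mine.p - float(p_ref)) < 0.05  # same test, independent permutations


class TestScaleDistanceCurve:
    def make_sheet(self):
        ids = [
            "SA1.1.1A", "SA1.1.1B", "SA1.1.2A", "SA1.2.1A", "SA2.1.1A",
            "SB1.1.1A", "SB1.1.1B", "SB1.1.2A", "SB1.2.1A", "SB2.1.1A",
        ]
        return sample_sheet_from_ids(ids)

    def test_identical_sequences_give_zero_curve(self):
        sheet = self.make_sheet()
        ids = list(sheet["isolate_id"])
        dmat = pd.DataFrame(np.zeros((10, 10)), index=ids, columns=ids)
        curve = scale_distance_curve(dmat, sheet)
        assert all(v == 0.0 for v in curve.means.values())

    @pytest.mark.parametrize("seed", [0, 1])
    def test_means_match_double_loop_oracle(self, seed):
        from myxogeo.design import addresses_from_sheet, pair_scale

        rng = np.random.default_rng(seed)
        sheet = self.make_sheet()
        ids = list(sheet["isolate_id"])
        dmat = pd.DataFrame(random_distance_matrix(rng, 10), index=ids, columns=ids)
        curve = scale_distance_curve(dmat, sheet)
        addrs = addresses_from_sheet(sheet)
        sums = {s: [] for s in SCALES}
        for a, b in itertools.combinations(ids, 2):
            sums[pair_scale(addrs[a], addrs[b])].append(dmat.loc[a, b])
        for scale in SCALES:
            if sums[scale]:
                assert curve.means[scale] == pytest.approx(float(np.mean(sums[scale])))
            else:
                assert scale in curve.omitted

    def test_clade_scope_restricts_pairs(self, rng):
        sheet = self.make_sheet()
        ids = list(sheet["isolate_id"])
        dmat = pd.DataFrame(random_distance_matrix(rng, 10), index=ids, columns=ids)
        clades = {i: ("1" if i.startswith("SA") else "2") for i in ids}
        curve = scale_distance_curve(dmat, sheet, scope="1", clades=clades)
        assert curve.n_pairs[Scale.KILOMETRE] == 0
        assert Scale.KILOMETRE in curve.omitted


class TestCladeBinomialTests:
    def make_inputs(self, site_clades):
        ids, clades = [], {}
        for s, (site, labels) in enumerate(site_clades.items()):
            for k, lab in enumerate(labels):
                name = f"{site}1.1.{k + 1}A"
                ids.append(name)
                clades[name] = lab
        return clades, sample_sheet_from_ids(ids)

    def test_absence_probability_half_cubed(self):
        # pooled frequency 1/2, three isolates at the focal site, none of them
        # the focal clade -> (1/2)^3
        clades, sheet = self.make_inputs(
            {"GH": ["2", "2", "2"], "KF": ["1", "1", "1"]}
        )
        assert clade_absence_test(clades, sheet, clade="1", site="GH") == pytest.approx(0.125)

    def test_absence_closed_form_tail(self):
        # f = 0.2 pooled, 10 at focal site with 0 observed -> 0.8^10
        clades, sheet = self.make_inputs(
            {"GH": ["2"] * 10, "KF": ["1", "1", "1", "2", "2", "1", "2", "2", "2", "2"][:5]}
        )
        # adjust: KF has 5 isolates; make 15 total with 3 of clade 1
        f = 3 / 15
        clades2, sheet2 = self.make_inputs(
            {"GH": ["2"] * 10, "KF": ["1", "1", "1", "2", "2"]}
        )
        assert clade_absence_test(clades2, sheet2, clade="1", site="GH") == pytest.approx(
            (1 - f) ** 10
        )

    def test_absence_of_unseen_clade_is_undefined(self):
        clades, sheet = self.make_inputs({"GH": ["1", "1"], "KF": ["1"]})
        with pytest.raises(ValueError, match="absent"):
            clade_absence_test(clades, sheet, clade="9", site="GH")

    def test_observed_at_expectation_has_high_p(self):
        clades, sheet = self.make_inputs(
            {"GH": ["1", "1", "2", "2"], "KF": ["1", "1", "2", "2"]}
        )
        p = clade_absence_test(clades, sheet, clade="1", site="GH")
        assert p > 0.5

    def test_frequency_test_extreme_site(self):
        # pooled 50:50; focal site 0 of 10 clade-1 -> p = 2 * 0.5^10
        clades, sheet = self.make_inputs(
            {"GH": ["2"] * 10, "KF": ["1"] * 10}
        )
        p = clade_frequency_test(clades, sheet, site="GH", clade_pair=("1", "2"))
        assert p == pytest.approx(2 * 0.5**10)

    def test_frequency_test_balanced_site_is_one(self):
        clades, sheet = self.make_inputs(
            {"GH": ["1", "1", "2", "2"], "KF": ["1", "1", "2", "2"]}
        )
        assert clade_frequency_test(clades, sheet, site="GH", clade_pair=("1", "2")) == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_binomial_p_matches_mass_summation(self, seed):
        # oracle: direct summation of the binomial mass function
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 50))
        f = float(rng.uniform(0.05, 0.95))
        k = int(rng.integers(0, n + 1))
        oracle = sum(math.comb(n, i) * f**i * (1 - f) ** (n - i) for i in range(k + 1))
        assert float(stats.binom.cdf(k, n, f)) == pytest.approx(oracle)


class TestNearestSTConcordance:
    def test_all_sts_one_site(self):
        d = pd.DataFrame(
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]], index=[1, 2, 3], columns=[1, 2, 3]
        )
        sites = {1: {"GH"}, 2: {"GH"}, 3: {"GH"}}
        res = nearest_st_concordance(d, sites, seed=0, n_perm=None)
        assert res.observed_fraction == 1.0
        assert res.expected_fraction == 1.0
        assert res.p_binomial == 1.0

    def test_pairing_matches_brute_force_scan(self):
        d = pd.DataFrame(
            [
                [0.0, 0.1, 0.5, 0.9],
                [0.1, 0.0, 0.4, 0.8],
                [0.5, 0.4, 0.0, 0.2],
                [0.9, 0.8, 0.2, 0.0],
            ],
            index=list("wxyz"),
            columns=list("wxyz"),
        )
        sites = {"w": {"A"}, "x": {"A"}, "y": {"B"}, "z": {"B"}}
        res = nearest_st_concordance(d, sites, seed=0, n_perm=None)
        assert dict(res.pairings) == {"w": "x", "x": "w", "y": "z", "z": "y"}
        assert res.observed_fraction == 1.0
        # 2 of 6 unordered pairs share a site
        assert res.expected_fraction == pytest.approx(2 / 6)
        assert res.p_binomial < 0.05

    def test_structured_landscape_shows_excess_concordance(self, default_sim):
        from myxogeo.genotypes import distance_matrix

        st = default_sim.true_st
        reps = {}
        for iso, lab in st.st_of.items():
            reps.setdefault(lab, iso)
        ids = [reps[lab] for lab in sorted(reps)]
        dmat = distance_matrix({i: default_sim.concatemers[i] for i in ids})
        dmat.index = dmat.columns = sorted(reps)
        sites = st_site_map(st, default_sim.sample_sheet)
        res = nearest_st_concordance(dmat, sites, seed=1, n_perm=999)
        assert res.observed_fraction > res.expected_fraction
        assert res.p_binomial < 0.05
        assert res.p_permutation < 0.05

    def test_single_st_is_error(self):
        d = pd.DataFrame([[0.0]], index=[1], columns=[1])
        with pytest.raises(ValueError, match="two sequence types"):
            nearest_st_concordance(d, {1: {"GH"}})


class TestWithinVsAmongSites:
    def make_st_inputs(self, rng, n_per_site=4, shift=0.0):
        sts = [f"st{i}" for i in range(2 * n_per_site)]
        sites = {st: {"A"} if i < n_per_site else {"B"} for i, st in enumerate(sts)}
        clades = {st: "1" for st in sts}
        n = len(sts)
        m = rng.random((n, n)) * 0.01
        m = (m + m.T) / 2
        for i in range(n):
            for j in range(n):
                if sites[sts[i]] != sites[sts[j]]:
                    m[i, j] += shift
        np.fill_diagonal(m, 0.0)
        d = pd.DataFrame(m, index=sts, columns=sts)
        return d, sites, clades

    def test_complete_separation_minimal_exact_p(self, rng):
        d, sites, clades = self.make_st_inputs(rng, n_per_site=4, shift=1.0)
        res = within_vs_among_site_test(d, sites, clades, clade="1", n_draws=4, seed=0)
        # minimal two-sided exact rank-sum p for 4 vs 4: 2 / C(8,4)
        assert res["p"] == pytest.approx(2 / math.comb(8, 4))
        assert res["among_mean"] > res["within_mean"]

    def test_exact_p_matches_rank_enumeration(self, rng):
        d, sites, clades = self.make_st_inputs(rng, n_per_site=4, shift=0.004)
        res = within_vs_among_site_test(d, sites, clades, clade="1", n_draws=4, seed=3)
        # reconstruct the drawn samples to enumerate the exact null
        rng2 = np.random.default_rng(3)
        members = [st for st in d.index]
        within = [
            (a, b)
            for a, b in itertools.combinations(members, 2)
            if sites[a] & sites[b]
        ]
        among = [
            (a, b)
            for a, b in itertools.combinations(members, 2)
            if not (sites[a] & sites[b])
        ]
        wi = [within[k] for k in rng2.choice(len(within), 4, replace=False)]
        am = [among[k] for k in rng2.choice(len(among), 4, replace=False)]
        x = [d.loc[a, b] for a, b in wi]
        y = [d.loc[a, b] for a, b in am]
        # enumeration oracle over all C(8,4) allocations of ranks
        pooled = x + y
        u_obs = sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
            1 for xi in x for yi in y if xi == yi
        )
        count = total = 0
        for combo in itertools.combinations(range(8), 4):
            xs = [pooled[i] for i in combo]
            ys = [pooled[i] for i in range(8) if i not in combo]
            u = sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
                1 for xi in xs for yi in ys if xi == yi
            )
            if abs(u - 8) >= abs(u_obs - 8) - 1e-9:  # |U - n1 n2 / 2|
                count += 1
            total += 1
        assert res["p"] == pytest.approx(count / total)

    def test_insufficient_pairs_reports_capacity(self, rng):
        d, sites, clades = self.make_st_inputs(rng, n_per_site=2)
        with pytest.raises(ValueError, match="insufficient"):
            within_vs_among_site_test(d, sites, clades, clade="1", n_draws=10, seed=0)

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(99)
        ps = []
        for _ in range(200):
            d, sites, clades = self.make_st_inputs(rng, n_per_site=4, shift=0.0)
            res = within_vs_among_site_test(
                d, sites, clades, clade="1", n_draws=4, seed=int(rng.integers(2**31))
            )
            ps.append(res["p"])
        # discrete exact test: check the empirical CDF is not wildly off
        assert 0.2 < np.mean(np.array(ps) <= 0.5) < 0.8


class TestGeographicMatrix:
    def test_entries_are_representative_distances(self):
        sheet = sample_sheet_from_ids(["SA1.1.1A", "SA1.1.1B", "SB1.1.1A"])
        geo = geographic_distance_matrix(sheet)
        assert geo.loc["SA1.1.1A", "SA1.1.1B"] == pytest.approx(100e-6 / 3)
        assert geo.loc["SA1.1.1A", "SB1.1.1A"] == pytest.approx(11000.0)

    def test_st_clade_map_conflict_detection(self, default_sim):
        st = default_sim.true_st
        clades = {i: "1" for i in st.st_of}
        mapping = st_clade_map(st, clades)
        assert set(mapping.values()) == {"1"}
        # force a conflict
        first_st = next(iter(st.st_of.values()))
        members = st.members(first_st)
        if len(members) >= 2:
            clades[members[0]] = "2"
            with pytest.raises(ValueError, match="conflicting"):
                st_clade_map(st, clades)
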