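"""Crosslink-to-structure distances, occurrence counts, model ranking."""

import numpy as np
import pytest

from nuclink.simdata import apply_rigid_transform, simulate_structure
from nuclink.structmap import (
    DEFAULT_SLACKS,
    MissingAtomError,
    ModelScore,
    StructureModel,
    XLSiteRecord,
    count_occurrences,
    filter_sites,
    median_site_distance,
    rank_models,
    read_sites,
    site_distance,
    site_nucleotide_distances,
    write_sites,
)


class TestSiteDistance:
    def test_three_four_five_triangle(self):
        model, sites = simulate_structure([("UV", [5.0])], seed=0)
        dist, nuc = site_distance(model, sites[0], mode="n3n7")
        assert dist == pytest.approx(5.0, abs=1e-9)
        assert nuc.startswith("B/U")

    def test_returns_nearest_of_two_nucleotides(self):
        model, sites = simulate_structure([("UV", [8.0, 12.0])], seed=1)
        dist, _ = site_distance(model, sites[0], mode="n3n7")
        assert dist == pytest.approx(8.0, abs=1e-9)

    def test_closest_atom_mode_at_most_n3n7(self):
        model, sites = simulate_structure([("DEB", [9.0])], seed=2)
        d_n, _ = site_distance(model, sites[0], mode="n3n7")
        d_c, _ = site_distance(model, sites[0], mode="closest_atom")
        assert d_c <= d_n

    def test_brute_force_oracle_on_random_cloud(self):
        import gemmi

        rng = np.random.default_rng(3)
        st = gemmi.Structure()
        model = gemmi.Model("1")
        chain = gemmi.Chain("A")
        res = gemmi.Residue(); res.name = "ALA"; res.seqid = gemmi.SeqId(1, " ")
        ca = gemmi.Atom(); ca.name = "CA"; ca.element = gemmi.Element("C")
        ca_pos = rng.uniform(-10, 10, 3)
        ca.pos = gemmi.Position(*ca_pos)
        res.add_atom(ca); chain.add_residue(res); model.add_chain(chain)
        nchain = gemmi.Chain("B")
        coords = []
        for i in range(10):
            r = gemmi.Residue(); r.name = "G"; r.seqid = gemmi.SeqId(i + 1, " ")
            for j in range(5):
                a = gemmi.Atom(); a.name = "N7" if j == 0 else f"C{j}"
                a.element = gemmi.Element("N" if j == 0 else "C")
                p = rng.uniform(-20, 20, 3)
                a.pos = gemmi.Position(*p)
                coords.append(p)
                r.add_atom(a)
            nchain.add_residue(r)
        model.add_chain(nchain); st.add_model(model)
        wrapped = StructureModel(st, "toy")
        site = XLSiteRecord("A", 1, "A", "DEB", csm_count=3)
        dist, _ = site_distance(wrapped, site, mode="closest_atom")
        brute = min(np.linalg.norm(ca_pos - p) for p in coords)
        assert dist == pytest.approx(brute, abs=1e-9)

    def test_no_nucleotides_raises(self):
        with pytest.raises(ValueError):
            simulate_structure([("UV", [-1.0])], seed=0)
        model, sites = simulate_structure([("UV", [5.0])], seed=0)
        # strip nucleotide chain
        bare = StructureModel(model.structure.clone(), "bare")
        bare._nucleotides = []
        with pytest.raises(MissingAtomError):
            site_distance(bare, sites[0], mode="n3n7")


class TestCountOccurrences:
    def test_hand_counted_uv_geometry(self):
        """UV sites at 8 and 12 A against the 10 A threshold."""
        model, sites = simulate_structure([("UV", [8.0]), ("UV", [12.0])], seed=4)
        score = count_occurrences(model, sites, mode="n3n7")
        assert [score.single[s] for s in DEFAULT_SLACKS] == [1, 2, 2, 2]
        assert [score.all_[s] for s in DEFAULT_SLACKS] == [1, 2, 2, 2]

    def test_all_counts_every_nucleotide_within_threshold(self):
        model, sites = simulate_structure([("UV", [6.0, 7.0, 9.0])], seed=5)
        score = count_occurrences(model, sites, mode="n3n7")
        assert score.single[0.0] == 1
        assert score.all_[0.0] == 3

    def test_no_sites_all_zero(self):
        model, _ = simulate_structure([("UV", [5.0])], seed=6)
        score = count_occurrences(model, [], mode="n3n7")
        assert all(v == 0 for v in score.single.values())
        assert all(v == 0 for v in score.all_.values())

    def test_monotone_in_slack_and_all_ge_single(self):
        rng = np.random.default_rng(7)
        planted = [(xl, list(rng.uniform(3, 25, rng.integers(1, 4))))
                   for xl in ("UV", "DEB", "NM") for _ in range(3)]
        model, sites = simulate_structure(planted, seed=8)
        score = count_occurrences(model, sites, mode="n3n7")
        singles = [score.single[s] for s in DEFAULT_SLACKS]
        alls = [score.all_[s] for s in DEFAULT_SLACKS]
        assert singles == sorted(singles)
        assert alls == sorted(alls)
        assert all(a >= s for a, s in zip(alls, singles))

    def test_distances_invariant_under_rigid_transform(self):
        model, sites = simulate_structure([("UV", [8.0]), ("NM", [14.0])], seed=9)
        moved = apply_rigid_transform(model, seed=10)
        a = count_occurrences(model, sites, mode="n3n7")
        b = count_occurrences(moved, sites, mode="n3n7")
        assert a.single == b.single and a.all_ == b.all_


class TestRankModels:
    def _score(self, mid, singles, alls):
        return ModelScore(mid, dict(zip(DEFAULT_SLACKS, singles)), dict(zip(DEFAULT_SLACKS, alls)))

    def test_single_model_matches_all_maxima(self):
        (ranked,) = rank_models([self._score("m", [1, 2, 3, 4], [2, 3, 4, 5])])
        assert ranked.rank_score == 8

    def test_dominating_model_ranks_first(self):
        a = self._score("a", [5, 6, 7, 8], [6, 7, 8, 9])
        b = self._score("b", [1, 2, 3, 8], [2, 3, 4, 9])
        ranked = rank_models([a, b])
        assert ranked[0].model_id == "a" and ranked[0].rank_score == 8
        assert ranked[1].rank_score == 2  # ties a's maxima in d5 and ALLd5

    def test_order_invariance(self):
        scores = [
            self._score("a", [5, 6, 7, 8], [6, 7, 8, 9]),
            self._score("b", [1, 2, 3, 8], [2, 3, 4, 9]),
            self._score("c", [5, 5, 5, 5], [9, 9, 9, 9]),
        ]
        ids_fwd = [s.model_id for s in rank_models(list(scores))]
        ids_rev = [s.model_id for s in rank_models(list(reversed(scores)))]
        assert ids_fwd == ids_rev

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rank_models([])


class TestMedianDistance:
    def test_median_of_three(self):
        model, sites = simulate_structure(
            [("UV", [4.0]), ("UV", [6.0]), ("UV", [8.0])], seed=11)
        df = median_site_distance(model, sites, mode="n3n7")
        assert df.groupby("crosslinker")["distance"].median()["UV"] == pytest.approx(6.0, abs=1e-9)

    def test_single_site_is_its_own_median(self):
        model, sites = simulate_structure([("NM", [13.0])], seed=12)
        df = median_site_distance(model, sites, mode="n3n7")
        assert df["distance"].median() == pytest.approx(13.0, abs=1e-9)

    def test_matches_sort_and_pick_oracle_and_flags_outliers(self):
        dists = [3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0]
        model, sites = simulate_structure([("UV", [d]) for d in dists], seed=13)
        df = median_site_distance(model, sites, mode="n3n7")
        assert sorted(df["distance"]) == pytest.approx(sorted(dists), abs=1e-9)
        assert df["distance"].median() == pytest.approx(np.median(dists), abs=1e-9)
        assert df["beyond_cap"].sum() == 3  # 11, 13, 15 exceed the 10 A UV cap


class TestSiteTableIO:
    def test_round_trip(self, tmp_path):
        sites = [XLSiteRecord("A", 10, "K", "UV", 5, 2.0),
                 XLSiteRecord("A", 20, "M", "NM", 3, 1.0)]
        path = tmp_path / "sites.tsv"
        write_sites(str(path), sites)
        assert read_sites(str(path)) == sites

    def test_filters(self):
        sites = [XLSiteRecord("A", 1, "K", "UV", 2, 0.0),
                 XLSiteRecord("A", 2, "K", "UV", 5, 0.5),
                 XLSiteRecord("A", 3, "K", "UV", 5, 1.5)]
        assert len(filter_sites(sites, min_csm_count=3)) == 2
        assert len(filter_sites(sites, min_csm_count=3, min_loc_score=1.0)) == 1
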