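"""Survey quality rules against hand-coded oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_survey_records
from riversdm import survey_prep
from riversdm.survey_prep import (
    build_occurrence_matrix,
    completeness_filter,
    dedupe_sites,
    min_potential_richness,
    select_species,
    snap_sites_to_reaches,
)


def recs(*rows):
    return make_survey_records([("s1", "2016-01-01", *r) for r in rows])


class TestMinPotentialRichness:
    def test_species_plus_uncovered_genus_and_family(self):
        """2 species + genus not covering them + family not covering any
        genus = 4."""
        r = recs(
            ("A", "species", "g1", "f1"),
            ("B", "species", "g2", "f1"),
            ("g3", "genus", "g3", "f2"),
            ("f3", "family", None, "f3"),
        )
        assert min_potential_richness(r) == 4

    def test_species_only(self):
        r = recs(*[(f"S{i}", "species", f"g{i}", "f1") for i in range(5)])
        assert min_potential_richness(r) == 5

    def test_covered_genus_and_family_contribute_nothing(self):
        """A genus record whose genus already holds an identified species,
        and a family record containing that genus, add zero."""
        r = recs(
            ("A", "species", "g1", "f1"),
            ("g1", "genus", "g1", "f1"),
            ("f1", "family", None, "f1"),
        )
        assert min_potential_richness(r) == 1

    def test_family_covered_by_genus_record(self):
        r = recs(
            ("g1", "genus", "g1", "f1"),
            ("f1", "family", None, "f1"),
        )
        assert min_potential_richness(r) == 1

    def test_random_surveys_match_set_oracle(self, rng):
        """Exhaustive set-logic oracle on random small surveys."""
        genera = {f"g{i}": f"f{i % 3}" for i in range(6)}
        for _ in range(50):
            rows = []
            for i in range(rng.integers(1, 8)):
                g = f"g{rng.integers(0, 6)}"
                rows.append((f"S{i}", "species", g, genera[g]))
            for g in rng.choice(list(genera), size=rng.integers(0, 4), replace=False):
                rows.append((g, "genus", g, genera[g]))
            for f in rng.choice(["f0", "f1", "f2"], size=rng.integers(0, 3), replace=False):
                rows.append((f, "family", None, f))
            r = recs(*rows)
            # oracle: literal set arithmetic
            sp = [(t, g, f) for t, rk, g, f in rows if rk == "species"]
            ge = [(t, f) for t, rk, g, f in rows if rk == "genus"]
            fa = [t for t, rk, g, f in rows if rk == "family"]
            s = len({t for t, _, _ in sp})
            sp_genera = {g for _, g, _ in sp}
            g_new = len({t for t, _ in ge if t not in sp_genera})
            id_families = {f for _, _, f in sp} | {f for _, f in ge}
            f_new = len({t for t in fa if t not in id_families})
            assert min_potential_richness(r) == s + g_new + f_new

    def test_unresolvable_lineage_fails(self):
        r = recs(("A", "species", None, "f1"))
        with pytest.raises(ValueError, match="lineage"):
            min_potential_richness(r)


class TestCompletenessFilter:
    def survey(self, site, date, n_species, n_extra_genus):
        rows = [
            (site, date, f"S{i}", "species", f"g{i}", "f1") for i in range(n_species)
        ] + [
            (site, date, f"gx{j}", "genus", f"gx{j}", "f2") for j in range(n_extra_genus)
        ]
        return make_survey_records(rows)

    def test_half_complete_survey_discarded(self):
        surveys = self.survey("s1", "2016-01-01", 2, 2)  # S=2, M=4 -> 0.5
        kept, report = completeness_filter(surveys)
        assert len(kept) == 0
        assert report.loc[0, "completeness"] == pytest.approx(0.5)
        assert not report.loc[0, "kept"]

    def test_fully_identified_survey_kept(self):
        surveys = self.survey("s1", "2016-01-01", 4, 0)
        kept, report = completeness_filter(surveys)
        assert len(kept) == 4
        assert report.loc[0, "completeness"] == pytest.approx(1.0)

    def test_boundary_inclusive_at_threshold(self):
        surveys = self.survey("s1", "2016-01-01", 7, 3)  # 7/10 = 0.70 exactly
        kept, _ = completeness_filter(surveys, threshold=0.70)
        assert len(kept) == 10

    def test_filter_is_idempotent(self, surveys):
        once, _ = completeness_filter(surveys.records)
        twice, _ = completeness_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_adding_covered_species_increases_completeness(self, rng):
        """(S+1)/(M+1) > S/M whenever S < M: identifying one more species in
        an already-recorded genus strictly helps."""
        for _ in range(20):
            s, extra = int(rng.integers(1, 6)), int(rng.integers(1, 5))
            base = self.survey("s1", "2016-01-01", s, extra)
            _, rep0 = completeness_filter(base, threshold=0.01)
            extra_row = make_survey_records(
                [("s1", "2016-01-01", "Snew", "species", "gx0", "f2")]
            )
            _, rep1 = completeness_filter(pd.concat([base, extra_row]), threshold=0.01)
            assert rep1.loc[0, "completeness"] > rep0.loc[0, "completeness"]

    def test_invalid_threshold(self, surveys):
        with pytest.raises(ValueError):
            completeness_filter(surveys.records, threshold=0.0)


class TestDedupeSites:
    def two_surveys(self, completeness_pair, dates=("2016-05-01", "2016-09-01")):
        rows = []
        for (n_sp, n_ge), date in zip(completeness_pair, dates):
            rows += [("s1", date, f"S{i}", "species", f"g{i}", "f1") for i in range(n_sp)]
            rows += [("s1", date, f"gx{j}", "genus", f"gx{j}", "f2") for j in range(n_ge)]
        return make_survey_records(rows)

    def test_highest_completeness_wins(self):
        surveys = self.two_surveys([(4, 1), (19, 1)])  # 0.8 vs 0.95
        out = dedupe_sites(surveys)
        assert set(out["date"]) == {"2016-09-01"}

    def test_single_survey_unchanged(self):
        surveys = self.two_surveys([(3, 0)], dates=("2016-05-01",))
        pd.testing.assert_frame_equal(dedupe_sites(surveys), surveys)

    def test_tie_broken_by_latest_date(self):
        surveys = self.two_surveys([(9, 1), (9, 1)])  # both 0.9
        out = dedupe_sites(surveys)
        assert set(out["date"]) == {"2016-09-01"}

    def test_matches_exhaustive_oracle(self, rng):
        """Brute-force oracle: enumerate surveys per site, pick max
        (completeness, date)."""
        rows = []
        for site in ["a", "b", "c"]:
            for k, date in enumerate(["2016-03-01", "2016-06-01", "2016-09-01"]):
                n_sp = int(rng.integers(1, 6))
                n_ge = int(rng.integers(0, 3))
                rows += [(site, date, f"S{i}", "species", f"g{i}", "f1") for i in range(n_sp)]
                rows += [(site, date, f"gx{j}", "genus", f"gx{j}", "f2") for j in range(n_ge)]
        surveys = make_survey_records(rows)
        out = dedupe_sites(surveys)
        for site, grp in surveys.groupby("site_id"):
            best = max(
                grp.groupby("date"),
                key=lambda kv: (survey_prep.survey_completeness(kv[1])[2], kv[0]),
            )[0]
            assert set(out[out["site_id"] == site]["date"]) == {best}
        # dedupe never drops a site
        assert set(out["site_id"]) == set(surveys["site_id"])


class TestSnapping:
    def test_site_on_reach_maps_at_distance_zero(self):
        reaches = pd.DataFrame({"reach_id": ["r1", "r2"], "x": [0.0, 100.0], "y": [0.0, 0.0]})
        sites = pd.DataFrame({"site_id": ["s1"], "x": [0.0], "y": [0.0]})
        mapped, dropped = snap_sites_to_reaches(sites, reaches)
        assert mapped.loc[0, "reach_id"] == "r1"
        assert mapped.loc[0, "distance"] == 0.0
        assert len(dropped) == 0

    def test_site_beyond_tolerance_dropped(self):
        reaches = pd.DataFrame({"reach_id": ["r1"], "x": [0.0], "y": [0.0]})
        sites = pd.DataFrame({"site_id": ["far", "edge"], "x": [31.0, 30.0], "y": [0.0, 0.0]})
        mapped, dropped = snap_sites_to_reaches(sites, reaches, tolerance=30.0)
        assert list(dropped["site_id"]) == ["far"]
        assert list(mapped["site_id"]) == ["edge"]  # inclusive at exactly 30 m

    def test_matches_brute_force_nearest_neighbour(self, rng):
        reaches = pd.DataFrame(
            {
                "reach_id": [f"r{i}" for i in range(40)],
                "x": rng.uniform(0, 1000, 40),
                "y": rng.uniform(0, 1000, 40),
            }
        )
        sites = pd.DataFrame(
            {
                "site_id": [f"s{i}" for i in range(60)],
                "x": rng.uniform(0, 1000, 60),
                "y": rng.uniform(0, 1000, 60),
            }
        )
        mapped, dropped = snap_sites_to_reaches(sites, reaches, tolerance=120.0)
        result = dict(zip(mapped["site_id"], mapped["reach_id"]))
        for _, s in sites.iterrows():
            d = np.hypot(reaches["x"] - s["x"], reaches["y"] - s["y"])
            j = int(np.argmin(d))
            if d[j] <= 120.0:
                assert result[s["site_id"]] == reaches.loc[j, "reach_id"]
            else:
                assert s["site_id"] not in result

    def test_empty_reach_set_fails(self):
        sites = pd.DataFrame({"site_id": ["s1"], "x": [0.0], "y": [0.0]})
        with pytest.raises(ValueError, match="empty"):
            snap_sites_to_reaches(sites, sites.iloc[:0].assign(reach_id=None))


class TestSelectSpecies:
    def matrix(self, counts, n_sites=60):
        m = pd.DataFrame(
            0,
            index=[f"s{i}" for i in range(n_sites)],
            columns=[f"sp{j}" for j in range(len(counts))],
        )
        for j, c in enumerate(counts):
            m.iloc[:c, j] = 1
        return survey_prep.OccurrenceMatrix(
            matrix=m, site_meta=pd.DataFrame(index=m.index), species_meta=survey_prep._species_meta(m)
        )

    def test_species_below_threshold_removed(self):
        occ = select_species(self.matrix([24, 25, 30]), min_occurrences=25)
        assert list(occ.matrix.columns) == ["sp1", "sp2"]

    def test_zero_threshold_is_identity(self):
        base = self.matrix([5, 10])
        occ = select_species(base, min_occurrences=0)
        pd.testing.assert_frame_equal(occ.matrix, base.matrix)

    def test_matches_brute_force_filter(self, rng):
        counts = rng.integers(0, 50, 15)
        occ = self.matrix(list(counts))
        kept = select_species(occ, min_occurrences=20)
        expected = [f"sp{j}" for j, c in enumerate(counts) if c >= 20]
        assert list(kept.matrix.columns) == expected
        np.testing.assert_allclose(
            kept.species_meta["prevalence"], kept.matrix.mean(axis=0)
        )

    def test_no_survivors_fails(self):
        with pytest.raises(ValueError, match="no species"):
            select_species(self.matrix([1, 2]), min_occurrences=25)


class TestOccurrenceMatrixBuild:
    def test_binary_matrix_from_species_records(self, surveys):
        occ = build_occurrence_matrix(surveys.records)
        occ.validate()
        sp_records = surveys.records[surveys.records["rank"] == "species"]
        assert occ.matrix.to_numpy().sum() == len(
            sp_records.drop_duplicates(["site_id", "taxon"])
        )
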