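"""Pedigree validation, the tabular relationship matrix and the
four-grandparent eligibility filter, checked against independent
recursive-kinship and path-counting oracles."""

import numpy as np
import pytest
from fractions import Fraction

from floaterqg.pedigree import (
    Pedigree,
    PedigreeError,
    additive_relationship,
    four_grandparent_filter,
    read_pedigree,
    validate_pedigree,
    write_pedigree,
)
from oracles import (
    inbreeding_oracle_kinship,
    kinship_oracle,
    random_pedigree,
    wright_paths_inbreeding,
)


class TestValidation:
    def test_minimal_trio_is_clean(self, trio_pedigree):
        rep = validate_pedigree(trio_pedigree)
        assert rep.ok and not rep.warnings

    def test_self_parentage_is_fatal(self):
        ped = Pedigree.from_records([("X", "X", None, 2000, "M")])
        rep = validate_pedigree(ped)
        assert not rep.ok and any("own sire" in e for e in rep.errors)

    def test_two_cycle_is_fatal(self):
        ped = Pedigree.from_records(
            [("A", "B", None, None, "M"), ("B", "A", None, None, "M")]
        )
        rep = validate_pedigree(ped)
        assert not rep.ok and any("cycle" in e for e in rep.errors)

    def test_duplicate_ids_and_absent_parents_reported(self):
        ped = Pedigree.from_records(
            [("A", None, None, 2000, "M"), ("B", "Z", None, 2001, "F")]
        )
        rep = validate_pedigree(ped)
        assert any("absent" in e for e in rep.errors)
        dup = Pedigree.from_records([("A", None, None, 2000, "M")] * 2)
        assert any("duplicated" in e for e in validate_pedigree(dup).errors)

    def test_parent_younger_than_offspring_is_reported(self):
        ped = Pedigree.from_records(
            [("A", None, None, 2005, "M"), ("B", "A", None, 2001, "F")]
        )
        assert any("not older" in e for e in validate_pedigree(ped).errors)

    def test_missing_birth_year_is_only_a_warning(self):
        ped = Pedigree.from_records([("A", None, None, None, "M")])
        rep = validate_pedigree(ped)
        assert rep.ok and rep.warnings


class TestTabularMethod:
    def test_founders_only_gives_identity(self):
        ped = Pedigree.from_records(
            [(f"F{i}", None, None, 2000, "M") for i in range(5)]
        )
        res = additive_relationship(ped)
        assert np.array_equal(res.A, np.eye(5))
        assert np.all(res.f == 0.0)

    @pytest.mark.parametrize(
        "records, focal, expected_f",
        [
            # full-sib mating
            ([("A", None, None, 0, "M"), ("B", None, None, 0, "F"),
              ("C", "A", "B", 1, "M"), ("D", "A", "B", 1, "F"),
              ("X", "C", "D", 2, "M")], "X", 0.25),
            # half-sib mating (shared sire)
            ([("A", None, None, 0, "M"), ("B", None, None, 0, "F"),
              ("E", None, None, 0, "F"),
              ("C", "A", "B", 1, "M"), ("D", "A", "E", 1, "F"),
              ("X", "C", "D", 2, "M")], "X", 0.125),
            # parent-offspring mating
            ([("A", None, None, 0, "M"), ("B", None, None, 0, "F"),
              ("C", "A", "B", 1, "F"), ("X", "A", "C", 2, "M")], "X", 0.25),
        ],
        ids=["full-sib", "half-sib", "parent-offspring"],
    )
    def test_classical_inbreeding_values(self, records, focal, expected_f):
        res = additive_relationship(Pedigree.from_records(records))
        assert res.f_of(focal) == expected_f

    def test_diagonal_is_one_plus_f_and_matrix_is_psd(self, rng):
        ped = random_pedigree(rng, 50)
        res = additive_relationship(ped)
        assert np.allclose(np.diag(res.A), 1.0 + res.f)
        assert np.allclose(res.A, res.A.T)
        assert np.linalg.eigvalsh(res.A).min() > -1e-10
        assert np.all((res.f >= 0) & (res.f <= 0.5))

    def test_f_matches_wright_path_counting_on_random_pedigree(self, rng):
        """Tabular f equals the path-counting oracle exactly (rationals)."""
        ped = random_pedigree(rng, 40)
        res = additive_relationship(ped, exact=True)
        oracle = wright_paths_inbreeding(ped)
        for k, iid in enumerate(res.ids):
            assert res.f[k] == oracle[iid]

    def test_A_is_twice_recursive_kinship(self, rng):
        """A_ij == 2 phi(i, j) from the independent recursive oracle."""
        for _ in range(5):
            ped = random_pedigree(rng, int(rng.integers(20, 61)))
            res = additive_relationship(ped, exact=True)
            phi = kinship_oracle(ped)
            for a in range(len(res.ids)):
                for b in range(a, len(res.ids)):
                    assert res.A[a, b] == 2 * phi(res.ids[a], res.ids[b])

    def test_deleting_childless_individual_preserves_f(self, rng):
        ped = random_pedigree(rng, 45)
        parents = {p for i in ped.ids for p in ped.parents(i) if p is not None}
        childless = [i for i in ped.ids if i not in parents]
        assert childless, "fixture should contain childless individuals"
        drop = childless[0]
        res_full = additive_relationship(ped)
        kept = [i for i in ped.ids if i != drop]
        sub = Pedigree.from_records(
            [(i, ped.sire[i], ped.dam[i], ped.birth_year[i], ped.sex[i]) for i in kept]
        )
        res_sub = additive_relationship(sub)
        for i in kept:
            assert res_full.f_of(i) == res_sub.f_of(i)

    def test_cycle_rejected_before_computation(self):
        ped = Pedigree.from_records(
            [("A", "B", None, None, "M"), ("B", "A", None, None, "M")]
        )
        with pytest.raises(PedigreeError):
            additive_relationship(ped)


class TestFourGrandparentFilter:
    def test_one_unknown_grandsire_excludes(self):
        recs = [("GS", None, None, 0, "M"), ("GD", None, None, 0, "F"),
                ("GD2", None, None, 0, "F"),
                ("S", "GS", "GD", 1, "M"), ("D", None, "GD2", 1, "F"),
                ("X", "S", "D", 2, "M")]
        ped = Pedigree.from_records(recs)
        assert "X" not in four_grandparent_filter(ped)

    def test_f2_of_four_founders_included(self):
        recs = [("G1", None, None, 0, "M"), ("G2", None, None, 0, "F"),
                ("G3", None, None, 0, "M"), ("G4", None, None, 0, "F"),
                ("S", "G1", "G2", 1, "M"), ("D", "G3", "G4", 1, "F"),
                ("X", "S", "D", 2, "M")]
        ped = Pedigree.from_records(recs)
        assert "X" in four_grandparent_filter(ped)
        assert additive_relationship(ped).f_of("X") == 0.0

    def test_matches_brute_force_scan_on_simulated_pedigree(self, rng):
        ped = random_pedigree(rng, 300, missing_rate=0.2)
        got = four_grandparent_filter(ped)
        expected = set()
        for i in ped.ids:
            s, d = ped.parents(i)
            if s is None or d is None:
                continue
            gps = [ped.sire[s], ped.dam[s], ped.sire[d], ped.dam[d]]
            if all(g is not None for g in gps):
                expected.add(i)
        assert got == expected


class TestFileFormats:
    def test_csv_round_trip(self, tmp_path, rng):
        ped = random_pedigree(rng, 30)
        p = tmp_path / "ped.csv"
        write_pedigree(ped, p)
        back = read_pedigree(p)
        assert back.ids == ped.ids
        assert back.sire == ped.sire and back.dam == ped.dam
        assert back.birth_year == ped.birth_year and back.sex == ped.sex

    @pytest.mark.parametrize("token", ["", "NA", "0"])
    def test_missing_parent_spellings_accepted(self, tmp_path, token):
        p = tmp_path / "ped.csv"
        p.write_text(f"id,sire,dam,birth_year,sex\nA,{token},{token},2000,M\n")
        ped = read_pedigree(p)
        assert ped.parents("A") == (None, None)
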