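"""Restraint building, encounter filtering, validation and serialization."""

import math

import numpy as np
import pytest

from pre2restraints.pre_extraction import PREMeasurement
from pre2restraints.restraints import (
    DistanceRestraint,
    LINKER_MAX,
    PPANT_ACTIVE_SITE_MAX,
    PPANT_UNFURL_BOUNDS,
    ProxyMapping,
    STATUS_ELIMINATED,
    STATUS_FILTERED,
    STATUS_RETAINED,
    add_connectivity_restraints,
    build_pre_restraints,
    check_violations,
    filter_encounter_satisfiable,
    read_restraints_tbl,
    write_restraints,
)
from pre2restraints.sbmf import SBMFParameters, gamma2_from_distance
from pre2restraints.structure import Atom, StructureModel


MAPPING = ProxyMapping(tag_attachments={"A36C": ("A", 36)})


def _measurement(gamma, ratio, probe=("B", 7, "N"), tag="A36C"):
    return PREMeasurement(
        probe_id=probe, tag_site=tag, i_para=ratio * 1000.0, i_dia=1000.0,
        gamma2_h=gamma,
    )


class TestBuildRestraints:
    def test_ratio_above_cutoff_filtered(self, sbmf_params):
        restraints, _ = build_pre_restraints(
            [_measurement(2.0, 0.9)], sbmf_params, MAPPING
        )
        assert restraints[0].status == STATUS_FILTERED
        assert not np.isfinite(restraints[0].upper_bound)

    def test_padding_added_to_derived_distance(self, sbmf_params):
        gamma = gamma2_from_distance(20.0, sbmf_params)
        restraints, _ = build_pre_restraints(
            [_measurement(gamma, 0.5)], sbmf_params, MAPPING, padding=6.0
        )
        r = restraints[0]
        assert r.derived_distance == pytest.approx(20.0, rel=1e-9)
        assert r.upper_bound == pytest.approx(26.0, rel=1e-9)
        assert r.lower_bound == 0.0

    def test_count_conservation(self, sbmf_params):
        ms = [
            _measurement(30.0, 0.3, probe=("B", i, "N")) for i in range(1, 15)
        ]
        restraints, n_bleached = build_pre_restraints(ms, sbmf_params, MAPPING)
        assert len(restraints) == 14 and n_bleached == 0
        assert all(r.status == STATUS_RETAINED for r in restraints)

    def test_bleached_excluded_and_counted(self, sbmf_params):
        bad = _measurement(float("nan"), 0.0)
        bad.status = "bleached"
        restraints, n_bleached = build_pre_restraints(
            [bad, _measurement(30.0, 0.3)], sbmf_params, MAPPING
        )
        assert len(restraints) == 1 and n_bleached == 1

    def test_proxy_atoms(self, sbmf_params):
        amide = _measurement(30.0, 0.3, probe=("B", 7, "H"))
        methyl = _measurement(30.0, 0.3, probe=("B", 9, "CD1"))
        restraints, _ = build_pre_restraints([amide, methyl], sbmf_params, MAPPING)
        assert restraints[0].atom_a == ("B", 7, "N")
        assert restraints[1].atom_a == ("B", 9, "CD1")
        assert restraints[0].atom_b == ("A", 36, "CB")

    def test_unknown_tag_site_named(self, sbmf_params):
        with pytest.raises(KeyError, match="Z99C"):
            build_pre_restraints(
                [_measurement(30.0, 0.3, tag="Z99C")], sbmf_params, MAPPING
            )


def _pair_models(distances, model_id="m"):
    """One model per distance list entry is NOT wanted here: build a single
    model realising the given atom-pair distances for restraints 1..n."""
    atoms = []
    for i, d in enumerate(distances, start=1):
        z = 1000.0 * i
        atoms.append(Atom("A", i, "ALA", "CB", "C", (0.0, 0.0, z)))
        atoms.append(Atom("B", i, "ALA", "N", "N", (float(d), 0.0, z)))
    return StructureModel(model_id, atoms)


class TestEncounterFilter:
    def _restraints(self, uppers):
        return [
            DistanceRestraint(
                atom_a=("B", i, "N"), atom_b=("A", i, "CB"), upper_bound=u
            )
            for i, u in enumerate(uppers, start=1)
        ]

    def test_six_of_fourteen_eliminated(self):
        # 14 restraints, 6 satisfiable (distance <= upper) in the ensemble
        uppers = [20.0] * 14
        distances = [15.0] * 6 + [30.0] * 8
        ensemble = [_pair_models(distances)]
        restraints = self._restraints(uppers)
        retained, eliminated = filter_encounter_satisfiable(restraints, ensemble)
        assert len(eliminated) == 6
        assert len(retained) == 8
        assert all(r.status == STATUS_ELIMINATED for r in eliminated)
        assert len(retained) + len(eliminated) == 14

    def test_all_retained_when_nothing_satisfiable(self):
        restraints = self._restraints([10.0, 12.0])
        ensemble = [_pair_models([50.0, 60.0])]
        retained, eliminated = filter_encounter_satisfiable(restraints, ensemble)
        assert len(retained) == 2 and not eliminated

    def test_any_member_rule(self):
        restraints = self._restraints([20.0])
        far = _pair_models([50.0], "far")
        close = _pair_models([15.0], "close")
        retained, eliminated = filter_encounter_satisfiable(
            restraints, [far, far, close, far, far]
        )
        assert len(eliminated) == 1 and not retained

    def test_loosening_bounds_grows_eliminated_set(self):
        distances = [15.0, 25.0, 35.0]
        ensemble = [_pair_models(distances)]
        tight, _ = self._count(ensemble, [20.0, 20.0, 20.0])
        loose, _ = self._count(ensemble, [30.0, 30.0, 30.0])
        assert loose >= tight

    def _count(self, ensemble, uppers):
        retained, eliminated = filter_encounter_satisfiable(
            self._restraints(uppers), ensemble
        )
        return len(eliminated), len(retained)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            filter_encounter_satisfiable(self._restraints([10.0]), [])


class TestConnectivityRestraints:
    def _build(self, model=None):
        return add_connectivity_restraints(
            linker_ca_a=("A", 77, "CA"), linker_ca_b=("C", 94, "CA"),
            thiol_s=("B", 37, "S43"), phosphate_p=("B", 37, "P"),
            his_ce1=("C", 223, "CE1"), model=model,
        )

    def test_linker_upper_bound(self):
        linker = self._build()[0]
        assert linker.upper_bound == LINKER_MAX == 59.5
        assert linker.lower_bound == 0.0

    def test_ppant_unfurl_bounds(self):
        unfurl = self._build()[1]
        assert (unfurl.lower_bound, unfurl.upper_bound) == PPANT_UNFURL_BOUNDS == (14.0, 16.5)

    def test_active_site_reach(self):
        reach = self._build()[2]
        assert reach.upper_bound == PPANT_ACTIVE_SITE_MAX == 8.0
        assert reach.lower_bound == 0.0

    def test_missing_atom_rejected(self):
        model = StructureModel("tiny", [Atom("A", 1, "ALA", "CA", "C", (0, 0, 0))])
        with pytest.raises(Exception):
            self._build(model)


class TestViolations:
    @pytest.mark.parametrize(
        "d, lower, upper, expected",
        [
            (10.0, 0.0, 12.0, 0.0),
            (15.0, 0.0, 12.0, 3.0),
            (13.0, 14.0, 16.5, 1.0),
        ],
    )
    def test_violation_rules(self, d, lower, upper, expected):
        model = _pair_models([d])
        r = DistanceRestraint(
            atom_a=("B", 1, "N"), atom_b=("A", 1, "CB"),
            upper_bound=upper, lower_bound=lower,
        )
        report = check_violations([r], model)
        assert report["violation"].iloc[0] == pytest.approx(expected)

    def test_unresolvable_atom_reported_nan(self):
        model = _pair_models([10.0])
        r = DistanceRestraint(atom_a=("Z", 9, "N"), atom_b=("A", 1, "CB"), upper_bound=5.0)
        report = check_violations([r], model)
        assert math.isnan(report["violation"].iloc[0])


class TestSerialization:
    def test_upper_only_encoding(self, tmp_path):
        r = DistanceRestraint(atom_a=("B", 7, "N"), atom_b=("A", 36, "CB"),
                              upper_bound=26.0, lower_bound=0.0)
        p = tmp_path / "r.tbl"
        write_restraints([r], p)
        line = [l for l in p.read_text().splitlines() if l.startswith("assign")][0]
        assert line.endswith("26.000 26.000 0.000")

    def test_two_sided_encoding(self, tmp_path):
        r = DistanceRestraint(atom_a=("B", 37, "S43"), atom_b=("B", 37, "P"),
                              upper_bound=16.5, lower_bound=14.0)
        p = tmp_path / "r.tbl"
        write_restraints([r], p)
        line = [l for l in p.read_text().splitlines() if l.startswith("assign")][0]
        assert line.endswith("16.500 2.500 0.000")

    def test_round_trip_preserves_bounds(self, tmp_path):
        rs = [
            DistanceRestraint(atom_a=("B", 7, "N"), atom_b=("A", 36, "CB"),
                              upper_bound=26.0, lower_bound=0.0),
            DistanceRestraint(atom_a=("B", 37, "S43"), atom_b=("B", 37, "P"),
                              upper_bound=16.5, lower_bound=14.0),
        ]
        p = tmp_path / "rt.tbl"
        write_restraints(rs, p)
        back = read_restraints_tbl(p)
        for orig, rec in zip(rs, back):
            assert rec.upper_bound == pytest.approx(orig.upper_bound)
            assert rec.lower_bound == pytest.approx(orig.lower_bound)
            assert rec.atom_a == orig.atom_a and rec.atom_b == orig.atom_b

    def test_json_dialect(self, tmp_path):
        import json

        r = DistanceRestraint(atom_a=("B", 7, "N"), atom_b=("A", 36, "CB"),
                              upper_bound=26.0, derived_distance=20.0, padding=6.0)
        p = tmp_path / "r.json"
        write_restraints([r], p, dialect="json")
        data = json.loads(p.read_text())
        assert data[0]["derived_distance"] == 20.0

    def test_unknown_dialect(self, tmp_path):
        with pytest.raises(ValueError):
            write_restraints([], tmp_path / "x", dialect="nope")
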