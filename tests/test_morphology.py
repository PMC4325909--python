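"""Morphology I/O, resegmentation, the d_lambda rule, and morphometrics."""

import math

import numpy as np
import pytest

from axosoma.morphology import (
    Morphology, Section, StructureError, SWCParseError,
    _parse_swc, check_d_lambda, morphometrics, read_swc, resegment, write_swc,
)

from conftest import BRANCHED_SWC, THREE_POINT_SWC


class TestReadSWC:
    def test_three_point_fixture(self):
        m = _parse_swc(THREE_POINT_SWC)
        mm = morphometrics(m)
        assert mm.soma_diameter == pytest.approx(50.0)
        assert mm.n_sections == 1
        assert mm.n_primary_dendrites == 1
        # single-sample soma expands to two cylinders: surface pi*d^2
        assert mm.soma_surface == pytest.approx(math.pi * 50.0**2)

    def test_branch_split_into_unbranched_sections(self):
        m = _parse_swc(BRANCHED_SWC)
        mm = morphometrics(m)
        # chain 2-3 splits at 3; children 4 (continuing to 6) and 5
        assert mm.n_sections == 3
        assert mm.n_primary_dendrites == 1

    @pytest.mark.parametrize("bad, err", [
        ("1 1 0 0 0 25 -1\n2 3 x 0 0 2 1\n", SWCParseError),
        ("1 1 0 0 0 25 -1\n2 3 1 0 0 2\n", SWCParseError),
        ("1 1 0 0 0 -3 -1\n", SWCParseError),
        ("1 1 0 0 0 25 -1\n2 3 1 0 0 2 9\n", StructureError),
        ("1 1 0 0 0 25 2\n2 3 1 0 0 2 1\n", StructureError),  # cycle
    ])
    def test_malformed_inputs(self, bad, err):
        with pytest.raises(err):
            _parse_swc(bad)

    def test_roundtrip_preserves_geometry(self, tmp_path):
        m = _parse_swc(BRANCHED_SWC)
        p = tmp_path / "out.swc"
        write_swc(m, p)
        m2 = read_swc(p)
        assert len(m2.sections) == len(m.sections)
        for a, b in zip(m.sections, m2.sections):
            assert a.region == b.region
            np.testing.assert_allclose(a.points, b.points, atol=1e-5)
            assert a.parent == b.parent


class TestResegment:
    def test_100um_branch_gets_5_compartments(self):
        m = _parse_swc(THREE_POINT_SWC)  # dendrite is 100 um
        m2 = resegment(m, 20.0)
        assert m2.sections[1].nseg == 5

    def test_short_branch_unchanged(self):
        soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                        [0, 25, 0, 50.]]),
                       parent=None, region="soma", nseg=2)
        d = Section(points=np.array([[0, 0, 0, 2.], [19, 0, 0, 2.]]),
                    parent=0, parent_pos=0.5, region="dendrite")
        m = Morphology(sections=[soma, d], soma_sections=[0])
        assert resegment(m).sections[1].nseg == 1

    def test_geometry_preserved_and_idempotent(self):
        m = _parse_swc(BRANCHED_SWC)
        before = morphometrics(m)
        m2 = resegment(m)
        after = morphometrics(m2)
        assert after.dendrite_surface == pytest.approx(
            before.dendrite_surface, rel=1e-9)
        assert after.mean_terminal_distance == pytest.approx(
            before.mean_terminal_distance, rel=1e-9)
        m3 = resegment(m2)
        assert [s.nseg for s in m3.sections] == [s.nseg for s in m2.sections]

    def test_invalid_max_length(self):
        m = _parse_swc(THREE_POINT_SWC)
        with pytest.raises(ValueError):
            resegment(m, 0.0)


class TestDLambda:
    def test_matches_closed_form(self):
        # cylinder d=2 um, L=500 um, Ri=70, cm=1, f=100
        soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                        [0, 25, 0, 50.]]),
                       parent=None, region="soma", nseg=2)
        d = Section(points=np.array([[0, 0, 0, 2.], [500, 0, 0, 2.]]),
                    parent=0, parent_pos=0.5, region="dendrite")
        m = Morphology(sections=[soma, d], soma_sections=[0])
        lam = 1e5 * 0.5 * math.sqrt(2.0 / (math.pi * 100.0 * 70.0 * 1.0))
        want = math.ceil(500.0 / (0.1 * lam))
        if want % 2 == 0:
            want += 1
        assert check_d_lambda(m)[1] == want

    def test_zero_length_stub(self):
        soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                        [0, 25, 0, 50.]]),
                       parent=None, region="soma", nseg=2)
        stub = Section(points=np.array([[0, 0, 0, 2.], [0, 0, 0, 2.]]),
                       parent=0, parent_pos=0.5, region="dendrite")
        m = Morphology(sections=[soma, stub], soma_sections=[0])
        assert check_d_lambda(m)[1] == 1

    def test_required_nseg_monotone_in_diameter(self):
        def nseg_for(diam):
            soma = Section(points=np.array([[0, -25, 0, 50.], [0, 0, 0, 50.],
                                            [0, 25, 0, 50.]]),
                           parent=None, region="soma", nseg=2)
            d = Section(points=np.array([[0, 0, 0, diam], [500, 0, 0, diam]]),
                        parent=0, parent_pos=0.5, region="dendrite")
            m = Morphology(sections=[soma, d], soma_sections=[0])
            return check_d_lambda(m)[1]

        diams = [8.0, 4.0, 2.0, 1.0, 0.5]
        nsegs = [nseg_for(d) for d in diams]
        assert nsegs == sorted(nsegs)

    def test_invalid_frequency(self):
        m = _parse_swc(THREE_POINT_SWC)
        with pytest.raises(ValueError):
            check_d_lambda(m, f=0.0)


class TestMorphometrics:
    def test_single_cylinder_surface(self):
        m = _parse_swc(THREE_POINT_SWC)
        # dendrite: d=4 (radius 2), L=100 -> pi*d*L
        assert morphometrics(m).dendrite_surface == pytest.approx(
            math.pi * 4.0 * 100.0)

    def test_brute_force_oracle(self, mini_morph):
        mm = morphometrics(mini_morph)
        total = 0.0
        for sec in mini_morph.sections:
            if sec.region != "dendrite":
                continue
            pts = sec.points
            for a, b in zip(pts[:-1], pts[1:]):
                L = np.linalg.norm(a[:3] - b[:3])
                r1, r2 = a[3] / 2, b[3] / 2
                total += math.pi * (r1 + r2) * math.sqrt(L**2 + (r1 - r2)**2)
        assert mm.dendrite_surface == pytest.approx(total, rel=1e-12)

    def test_rigid_motion_invariance(self, mini_morph):
        base = morphometrics(mini_morph)
        th = 0.7
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0],
                      [0, 0, 1.0]])
        shift = np.array([10.0, -40.0, 7.0])
        secs = []
        for s in mini_morph.sections:
            pts = s.points.copy()
            pts[:, :3] = pts[:, :3] @ R.T + shift
            secs.append(Section(points=pts, parent=s.parent,
                                parent_pos=s.parent_pos, region=s.region,
                                nseg=s.nseg))
        rot = morphometrics(Morphology(sections=secs, soma_sections=[0]))
        assert rot.dendrite_surface == pytest.approx(base.dendrite_surface,
                                                     rel=1e-9)
        assert rot.mean_terminal_distance == pytest.approx(
            base.mean_terminal_distance, rel=1e-9)
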