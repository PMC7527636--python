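"""Morphology: SWC parsing, d_lambda discretization, areas, H_dist selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olmcell.morphology import (
    Morphology,
    PS_PER_UM2_TO_S_PER_CM2,
    REGION_AXON,
    REGION_DEND,
    REGION_SOMA,
    Section,
    SWCError,
    discretize,
    distribute_conductance,
    lambda_f,
    load_swc,
    save_swc,
    select_by_hdist,
    surface_area,
)

def _ball_and_stick() -> Morphology:
    soma = Section(
        region=REGION_SOMA,
        points=np.array([[0.0, 0.0, 0.0, 20.0], [20.0, 0.0, 0.0, 20.0]]),
    )
    dend = Section(
        region=REGION_DEND,
        points=np.array([[20.0, 0.0, 0.0, 2.0], [220.0, 0.0, 0.0, 2.0]]),
        parent=0,
    )
    return Morphology([soma, dend])


MINIMAL_SWC = """\
1 1 0 0 0 10 -1
2 1 10 0 0 10 1
3 1 20 0 0 10 2
4 3 20 0 0 1 3
5 3 120 0 0 1 4
"""


class TestLoadSwc:
    def test_minimal_soma_plus_dendrite(self, tmp_path):
        path = tmp_path / "cell.swc"
        path.write_text(MINIMAL_SWC)
        m = load_swc(path)
        assert len(m.sections) == 2
        regions = sorted(s.region for s in m.sections)
        assert regions == [REGION_SOMA, REGION_DEND]

    def test_orphan_parent_is_structural_error(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 3 10 0 0 1 9\n")
        with pytest.raises(SWCError, match="missing parent"):
            load_swc(path)

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 3 x 0 0 1 1\n")
        with pytest.raises(SWCError, match="line 2"):
            load_swc(path)

    def test_wrong_column_count(self, tmp_path):
        path = tmp_path / "bad.swc"
        path.write_text("1 1 0 0 0 5\n")
        with pytest.raises(SWCError, match="7 columns"):
            load_swc(path)

    def test_unknown_type_code_maps_to_dendrite_with_warning(self, tmp_path):
        path = tmp_path / "odd.swc"
        path.write_text("1 1 0 0 0 5 -1\n2 7 10 0 0 1 1\n3 7 60 0 0 1 2\n")
        with pytest.warns(UserWarning, match="unknown SWC type"):
            m = load_swc(path)
        assert any(s.region == REGION_DEND for s in m.sections)

    def test_ball_and_stick_roundtrip_preserves_geometry(self, ball_and_stick, tmp_path):
        path = tmp_path / "bs.swc"
        save_swc(ball_and_stick, path)
        m2 = load_swc(path)
        assert len(m2.sections) == 2
        dend = next(s for s in m2.sections if s.region == REGION_DEND)
        assert dend.length == pytest.approx(200.0)


class TestDiscretize:
    def test_short_cylinder_is_single_compartment(self):
        sec = Section(
            region=REGION_DEND,
            points=np.array([[0, 0, 0, 2.0], [5.0, 0, 0, 2.0]]),
        )
        soma = Section(
            region=REGION_SOMA, points=np.array([[0, 0, 0, 10.0], [10, 0, 0, 10.0]])
        )
        sec.parent = 0
        model = discretize(Morphology([soma, sec]), 0.1, 100.0, 150.0, 1.0)
        assert np.sum(model.section == 1) == 1

    def test_compartment_counts_match_rounding_formula(self):
        # dendrite d=2 um, L=400 um, Ra=150, Cm=1, f=100
        soma = Section(
            region=REGION_SOMA, points=np.array([[0, 0, 0, 10.0], [10, 0, 0, 10.0]])
        )
        dend = Section(
            region=REGION_DEND,
            points=np.array([[10, 0, 0, 2.0], [410, 0, 0, 2.0]]),
            parent=0,
        )
        model = discretize(Morphology([soma, dend]), 0.1, 100.0, 150.0, 1.0)
        lam = lambda_f(2.0, 100.0, 150.0, 1.0)
        expected = 2 * int((400.0 / (0.1 * lam) + 0.9) / 2.0) + 1
        assert np.sum(model.section == 1) == expected
        assert expected % 2 == 1

    def test_halving_fraction_never_reduces_counts(self, ball_and_stick):
        coarse = discretize(ball_and_stick, 0.2, 100.0, 150.0, 1.0)
        fine = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        for sec in range(2):
            assert np.sum(fine.section == sec) >= np.sum(coarse.section == sec)

    def test_odd_counts_everywhere(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.05, 100.0, 100.0, 1.5)
        for sec in np.unique(model.section):
            assert np.sum(model.section == sec) % 2 == 1

    def test_path_distance_increases_toward_tips(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        dend = model.compartments_of(REGION_DEND)
        d = model.path_distance[dend]
        assert np.all(np.diff(d) > 0)

    def test_invalid_inputs(self, ball_and_stick):
        with pytest.raises(ValueError):
            discretize(ball_and_stick, 0.0, 100.0, 150.0, 1.0)
        with pytest.raises(ValueError):
            discretize(ball_and_stick, 0.1, 100.0, -5.0, 1.0)


class TestSurfaceArea:
    def test_cylinder_area(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        dend = model.compartments_of(REGION_DEND)
        assert surface_area(model, dend) == pytest.approx(math.pi * 2.0 * 200.0, rel=1e-9)

    def test_whole_cell_additivity(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        total = surface_area(model)
        parts = sum(
            surface_area(model, model.compartments_of(r))
            for r in (REGION_SOMA, REGION_DEND)
        )
        assert total == pytest.approx(parts, rel=1e-12)

    def test_tapered_frustum_closed_form(self):
        soma = Section(
            region=REGION_SOMA, points=np.array([[0, 0, 0, 10.0], [10, 0, 0, 10.0]])
        )
        frustum = Section(
            region=REGION_DEND,
            points=np.array([[10, 0, 0, 4.0], [20, 0, 0, 2.0]]),
            parent=0,
        )
        model = discretize(Morphology([soma, frustum]), 0.1, 100.0, 150.0, 1.0)
        # lateral area of a frustum: pi * (r1 + r2) * slant
        slant = math.hypot(10.0, 1.0)
        expected = math.pi * (2.0 + 1.0) * slant
        got = surface_area(model, model.compartments_of(REGION_DEND))
        assert got == pytest.approx(expected, rel=1e-3)

    def test_empty_selection_raises(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        with pytest.raises(ValueError, match="empty"):
            surface_area(model, np.array([], dtype=int))


class TestHdistSelection:
    @pytest.fixture()
    def model(self, ball_and_stick):
        return discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)

    def test_zero_selects_soma_only(self, model):
        sel = select_by_hdist(model, 0.0)
        assert set(model.region[sel]) == {REGION_SOMA}

    def test_one_selects_all_somatodendritic(self, model):
        sel = select_by_hdist(model, 1.0)
        n_somadend = np.sum(np.isin(model.region, [REGION_SOMA, REGION_DEND]))
        assert len(sel) == n_somadend

    def test_axon_always_excluded(self):
        soma = Section(
            region=REGION_SOMA, points=np.array([[0, 0, 0, 10.0], [10, 0, 0, 10.0]])
        )
        axon = Section(
            region=REGION_AXON,
            points=np.array([[10, 0, 0, 1.0], [210, 0, 0, 1.0]]),
            parent=0,
        )
        model = discretize(Morphology([soma, axon]), 0.1, 100.0, 150.0, 1.0)
        sel = select_by_hdist(model, 1.0)
        assert REGION_AXON not in set(model.region[sel])

    @settings(max_examples=25, deadline=None)
    @given(
        h1=st.floats(0.0, 1.0, allow_nan=False),
        h2=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_selection_monotone_in_hdist(self, h1, h2):
        model = discretize(_ball_and_stick(), 0.1, 100.0, 150.0, 1.0)
        lo, hi = sorted((h1, h2))
        s_lo = set(select_by_hdist(model, lo))
        s_hi = set(select_by_hdist(model, hi))
        assert s_lo <= s_hi

    def test_out_of_range_rejected(self, model):
        with pytest.raises(ValueError):
            select_by_hdist(model, 1.5)


class TestDistributeConductance:
    def test_printed_density_conversions(self, ball_and_stick):
        # the division is pure arithmetic: total G_h over published areas
        assert 4.17e3 / 7651.0 == pytest.approx(0.546, abs=1e-3)
        assert 4.17e3 / 29378.0 == pytest.approx(0.142, abs=1e-3)

    def test_zero_conductance_gives_zero_density(self, ball_and_stick):
        model = discretize(ball_and_stick, 0.1, 100.0, 150.0, 1.0)
        sel = select_by_hdist(model, 1.0)
        assert distribute_conductance(model, 0.0, sel) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(
        h=st.floats(0.0, 1.0, allow_nan=False),
        gh=st.floats(0.01, 20.0, allow_nan=False),
    )
    def test_conservation_density_times_area(self, h, gh):
        model = discretize(_ball_and_stick(), 0.1, 100.0, 150.0, 1.0)
        sel = select_by_hdist(model, h)
        dens = distribute_conductance(model, gh, sel)
        recovered = dens * surface_area(model, sel) * 1e-3  # pS -> nS
        assert recovered == pytest.approx(gh, rel=1e-9)

    def test_unit_roundtrip_ps_per_um2(self):
        dens = 0.142  # pS/um^2
        s_cm2 = dens * PS_PER_UM2_TO_S_PER_CM2
        assert s_cm2 == pytest.approx(1.42e-5, rel=1e-12)
        assert s_cm2 / PS_PER_UM2_TO_S_PER_CM2 == pytest.approx(dens, rel=1e-12)
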