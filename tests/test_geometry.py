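import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from minicirc import geometry as geo
from minicirc.errors import (
    GeometryError,
    LabelingError,
    SequenceError,
    StructuralInputError,
    TopologyError,
)


# ---------------------------------------------------------------------------
# quantize_twist
# ---------------------------------------------------------------------------

class TestQuantizeTwist:
    def test_105_bp_canonical(self):
        assert geo.quantize_twist(34.3, 105) == pytest.approx(10 * 360 / 105,
                                                              abs=1e-12)

    def test_already_commensurate_unchanged(self):
        tw = 10 * 360 / 105
        assert geo.quantize_twist(tw, 105) == pytest.approx(tw, abs=1e-12)

    def test_exact_ten_turns(self):
        assert geo.quantize_twist(36.0, 100) == pytest.approx(36.0, abs=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 360.0, -5.0])
    def test_invalid_twist(self, bad):
        with pytest.raises(ValueError):
            geo.quantize_twist(bad, 105)

    def test_too_few_bp(self):
        with pytest.raises(ValueError):
            geo.quantize_twist(34.3, 2)

    @given(twist=st.floats(5.0, 60.0), n_bp=st.integers(10, 500))
    @settings(max_examples=100, deadline=None)
    def test_result_commensurate(self, twist, n_bp):
        q = geo.quantize_twist(twist, n_bp)
        turns = q * n_bp / 360.0
        assert turns == pytest.approx(round(turns), abs=1e-9)


# ---------------------------------------------------------------------------
# build_ideal_linear
# ---------------------------------------------------------------------------

class TestBuildIdealLinear:
    def test_n0_atom_at_formula_value(self, params):
        model = geo.build_ideal_linear("ACGT", params)
        for cls in geo.CLASS_ORDER:
            r = params.radius_nm[cls]
            th0 = math.radians(params.theta0_deg[cls])
            idx = model.atom_index(0, cls[0], cls[1])
            np.testing.assert_allclose(
                model.positions[idx],
                [r * math.cos(th0), r * math.sin(th0), params.z0_nm[cls]],
                atol=1e-12)

    def test_sugar_chord_length_constant(self, params):
        # closed form: sqrt(2 r^2 (1 - cos dtheta) + dz^2)
        model = geo.build_ideal_linear("A" * 40, params)
        r = params.radius_nm[("S", 1)]
        dth = math.radians(params.twist_deg)
        expected = math.sqrt(2 * r * r * (1 - math.cos(dth)) + params.rise_nm ** 2)
        sugars = model.positions[0::6]
        chords = np.linalg.norm(np.diff(sugars, axis=0), axis=1)
        np.testing.assert_allclose(chords, expected, atol=1e-10)

    def test_total_twist_quantized_is_full_turns(self, params):
        twist = geo.quantize_twist(34.3, 105)
        assert 105 * twist == pytest.approx(3600.0, abs=1e-9)
        model = geo.build_ideal_linear("A" * 105, params, twist_override=twist)
        sugars = model.positions[0::6]
        phi = np.unwrap(np.arctan2(sugars[:, 1], sugars[:, 0]))
        total = math.degrees(phi[-1] - phi[0]) + twist  # 104 steps + closing step
        assert total == pytest.approx(3600.0, abs=1e-6)

    def test_invalid_base_raises(self, params):
        with pytest.raises(SequenceError):
            geo.build_ideal_linear("ACGX", params)

    def test_empty_sequence_raises(self, params):
        with pytest.raises(SequenceError):
            geo.build_ideal_linear("", params)

    def test_atom_count_and_layout(self, params):
        model = geo.build_ideal_linear("ACGTACGT", params)
        assert model.n_atoms == 6 * 8
        assert model.atom_class(0) == (0, "S", 1)
        assert model.atom_class(6 * 3 + 4) == (3, "P", 2)


# ---------------------------------------------------------------------------
# derive_helix_parameters
# ---------------------------------------------------------------------------

def _independent_class_fit(model, cls):
    """Oracle: per-class least-squares helix fit (angle/z linear in n)."""
    pos = model.positions[geo.CLASS_ORDER.index(cls)::6]
    n = np.arange(len(pos), dtype=float)
    phi = np.unwrap(np.arctan2(pos[:, 1], pos[:, 0]))
    design = np.column_stack([n, np.ones_like(n)])
    (slope_a, icpt_a), res_a, *_ = np.linalg.lstsq(design, phi, rcond=None)
    (slope_z, icpt_z), res_z, *_ = np.linalg.lstsq(design, pos[:, 2], rcond=None)
    dof = max(len(n) - 2, 1)
    gram = np.linalg.inv(design.T @ design)
    se_icpt_a = math.sqrt(float(res_a[0]) / dof * gram[1, 1]) if len(res_a) else 0.0
    se_icpt_z = math.sqrt(float(res_z[0]) / dof * gram[1, 1]) if len(res_z) else 0.0
    radius = float(np.mean(np.hypot(pos[:, 0], pos[:, 1])))
    se_radius = float(np.std(np.hypot(pos[:, 0], pos[:, 1]), ddof=1) / math.sqrt(len(n)))
    return {
        "twist_deg": math.degrees(slope_a),
        "theta0_deg": math.degrees(icpt_a), "se_theta0_deg": math.degrees(se_icpt_a),
        "z0_nm": icpt_z, "se_z0_nm": se_icpt_z,
        "radius_nm": radius, "se_radius_nm": se_radius,
    }


class TestDeriveHelixParameters:
    def test_exact_round_trip(self, params):
        model = geo.build_ideal_linear("A" * 50, params)
        rec = geo.derive_helix_parameters(model)
        assert rec.twist_deg == pytest.approx(params.twist_deg, abs=1e-9)
        assert rec.rise_nm == pytest.approx(params.rise_nm, abs=1e-9)
        for cls in geo.CLASS_ORDER:
            assert rec.radius_nm[cls] == pytest.approx(params.radius_nm[cls], abs=1e-9)
            assert math.isclose(
                (rec.theta0_deg[cls] - params.theta0_deg[cls] + 180) % 360 - 180,
                0.0, abs_tol=1e-9)
            assert rec.z0_nm[cls] == pytest.approx(params.z0_nm[cls], abs=1e-9)

    def test_round_trip_other_parameter_sets(self, params):
        for twist, rise in ((30.0, 0.30), (36.0, 0.40)):
            p = geo.HelixParameters(twist, rise, params.radius_nm,
                                    params.theta0_deg, params.z0_nm)
            rec = geo.derive_helix_parameters(geo.build_ideal_linear("A" * 20, p))
            assert rec.twist_deg == pytest.approx(twist, abs=1e-9)
            assert rec.rise_nm == pytest.approx(rise, abs=1e-9)

    def test_noisy_recovery_vs_per_class_oracle(self, params, rng):
        model = geo.build_ideal_linear("A" * 105, params)
        model.positions = model.positions + rng.normal(0.0, 0.01,
                                                       model.positions.shape)
        rec = geo.derive_helix_parameters(model)
        for cls in geo.CLASS_ORDER:
            oracle = _independent_class_fit(model, cls)
            tol_th = max(3 * oracle["se_theta0_deg"], 0.25)
            tol_z = max(3 * oracle["se_z0_nm"], 0.005)
            tol_r = max(3 * oracle["se_radius_nm"], 0.005)
            d_th = (rec.theta0_deg[cls] - oracle["theta0_deg"] + 180) % 360 - 180
            assert abs(d_th) < tol_th
            assert abs(rec.z0_nm[cls] - oracle["z0_nm"]) < tol_z
            assert abs(rec.radius_nm[cls] - oracle["radius_nm"]) < tol_r
        # and the truth is recovered to well inside the noise scale
        assert rec.twist_deg == pytest.approx(params.twist_deg, abs=0.1)
        assert rec.rise_nm == pytest.approx(params.rise_nm, abs=0.001)

    def test_minimum_three_bp(self, params):
        rec = geo.derive_helix_parameters(geo.build_ideal_linear("ACG", params))
        assert math.isfinite(rec.twist_deg)
        assert rec.twist_deg == pytest.approx(params.twist_deg, abs=1e-9)

    def test_two_bp_rejected(self, params):
        with pytest.raises(StructuralInputError):
            geo.derive_helix_parameters(geo.build_ideal_linear("AC", params))

    def test_missing_atom_class_rejected(self, params):
        model = geo.build_ideal_linear("ACGT", params)
        model.positions = model.positions[:-1]  # drop one atom
        with pytest.raises(LabelingError):
            geo.derive_helix_parameters(model)


# ---------------------------------------------------------------------------
# circularize / wrap map
# ---------------------------------------------------------------------------

class TestCircularize:
    def test_z_zero_fixed_point(self):
        R = 5.0
        out = geo.wrap_cylinder(np.array([[1.3, R, 0.0]]), R)
        np.testing.assert_allclose(out[0], [1.3, R, 0.0], atol=1e-15)

    def test_quarter_turn_maps_y_to_z(self):
        R = 5.0
        for mode in ("centerline", "per-atom"):
            out = geo.wrap_cylinder(np.array([[0.0, R, math.pi * R / 2]]), R, mode)
            np.testing.assert_allclose(out[0], [0.0, 0.0, R], atol=1e-12)

    @pytest.mark.parametrize("mode", ["centerline", "per-atom"])
    def test_radial_distance_preserved(self, params, mode):
        twist = geo.quantize_twist(34.3, 105)
        linear = geo.build_ideal_linear("A" * 105, params, twist_override=twist)
        R = 105 * params.rise_nm / (2 * math.pi)
        translated = linear.positions + (np.array([0.0, R, 0.0])
                                         - linear.positions.mean(axis=0))
        mini = geo.circularize(linear, angle_mode=mode)
        np.testing.assert_allclose(
            np.hypot(mini.positions[:, 1], mini.positions[:, 2]),
            translated[:, 1], atol=1e-12)
        # x coordinates untouched by the wrap
        np.testing.assert_allclose(mini.positions[:, 0], translated[:, 0],
                                   atol=1e-12)

    def test_per_atom_mode_arc_length(self, params):
        # per-atom wrap: each atom's own arc (y * angle) equals its z coordinate
        twist = geo.quantize_twist(34.3, 105)
        linear = geo.build_ideal_linear("A" * 12, params, twist_override=twist)
        R = 50.0  # generous radius keeps |z/y| < pi so atan2 recovers the angle
        translated = linear.positions + (np.array([0.0, R, 0.0])
                                         - linear.positions.mean(axis=0))
        bent = geo.wrap_cylinder(translated, R, "per-atom")
        angle = np.arctan2(bent[:, 2], bent[:, 1])
        np.testing.assert_allclose(translated[:, 1] * angle, translated[:, 2],
                                   atol=1e-9)

    def test_default_radius_closes_centerline(self, make_circle, params):
        mini = make_circle(105)
        assert mini.radius_nm == pytest.approx(105 * params.rise_nm / (2 * math.pi))

    @pytest.mark.parametrize("n_bp", [90, 100, 105])
    def test_closure_gap_commensurate(self, make_circle, n_bp):
        mini = make_circle(n_bp)
        assert geo.closure_gap(mini) < 1e-6

    def test_closure_gap_noncommensurate_positive_and_monotone(self, params):
        base = geo.quantize_twist(34.3, 105)
        gaps = []
        for mismatch in (0.05, 0.2, 0.5):
            linear = geo.build_ideal_linear("A" * 105, params,
                                            twist_override=base + mismatch)
            mini = geo.circularize(linear)
            gaps.append(geo.closure_gap(mini))
        assert gaps[0] > 1e-3
        assert gaps == sorted(gaps)

    def test_atom_on_axis_rejected(self, params):
        # 8 bp circle radius ~0.43 nm < helix radii -> atoms cross the axis
        linear = geo.build_ideal_linear("A" * 8, params,
                                        twist_override=geo.quantize_twist(34.3, 8))
        with pytest.raises(GeometryError):
            geo.circularize(linear)


# ---------------------------------------------------------------------------
# close_topology
# ---------------------------------------------------------------------------

def _term_bps(model, term):
    return {model.atom_class(a)[0] for a in term.atoms}


class TestCloseTopology:
    def test_closure_counts(self, closed105):
        closure_bonds = [t for t in closed105.bonds if t.closure]
        closure_angles = [t for t in closed105.angles if t.closure]
        closure_dihedrals = [t for t in closed105.dihedrals if t.closure]
        assert len(closure_bonds) == 6
        assert len(closure_angles) == 6
        assert len(closure_dihedrals) == 16
        assert len(closed105.closure_terms) == 28

    def test_closure_type_multisets(self, closed105):
        def label_counts(terms):
            out: dict[str, int] = {}
            for t in terms:
                if t.closure:
                    out[t.label] = out.get(t.label, 0) + 1
            return out

        assert label_counts(closed105.bonds) == {"SP": 2, "PS": 2, "BB-intra": 2}
        assert label_counts(closed105.angles) == {"SPS": 2, "3PSB5": 2, "5PSB3": 2}
        assert label_counts(closed105.dihedrals) == {
            "SPSP": 4, "PSPS": 4, "SPSB53": 2, "SPSB35": 2,
            "PSBB53": 2, "PSBB35": 2}

    def test_total_term_increase_is_28(self, make_circle):
        mini = make_circle(105)
        before = len(mini.all_terms())
        closed = geo.close_topology(mini)
        assert len(closed.all_terms()) == before + 28

    def test_closure_terms_span_junction(self, closed105):
        # junction phosphates (each strand's dangling 5' P) sit between the
        # last and first base pair, so they count toward both terminal regions
        n = closed105.n_bp
        junction = {closed105.atom_index(0, "P", 1),
                    closed105.atom_index(n - 1, "P", 2)}
        low, high = {0, 1}, {n - 2, n - 1}
        for term in closed105.closure_terms:
            bps = _term_bps(closed105, term)
            touches_low = bool(bps & low) or any(a in junction for a in term.atoms)
            touches_high = bool(bps & high) or any(a in junction for a in term.atoms)
            assert touches_low and touches_high
            # and never reaches beyond the two terminal base pairs of each end
            assert bps <= (low | high)

    def test_double_closure_rejected(self, closed105):
        with pytest.raises(TopologyError):
            geo.close_topology(closed105)

    def test_uniform_bonded_degree_after_closure(self, closed105):
        degree = np.zeros(closed105.n_atoms, dtype=int)
        for bond in closed105.bonds:
            for a in bond.atoms:
                degree[a] += 1
        sites = closed105.site_labels
        for site, expected in (("S", 3), ("P", 2), ("B", 4)):
            degrees = degree[sites == site]
            assert (degrees == expected).all(), f"non-uniform degree for {site}"

    def test_closure_references_valid_atoms(self, closed105):
        closed105.validate()


# ---------------------------------------------------------------------------
# round-trip property
# ---------------------------------------------------------------------------

@given(
    twist=st.floats(20.0, 40.0),
    rise=st.floats(0.25, 0.45),
    phase=st.floats(-180.0, 180.0),
)
@settings(max_examples=25, deadline=None)
def test_build_derive_round_trip_property(twist, rise, phase):
    base = geo.default_helix_parameters()
    p = geo.HelixParameters(
        twist, rise, base.radius_nm,
        {k: v + phase for k, v in base.theta0_deg.items()}, base.z0_nm)
    rec = geo.derive_helix_parameters(geo.build_ideal_linear("A" * 15, p))
    assert rec.twist_deg == pytest.approx(twist, abs=1e-9)
    assert rec.rise_nm == pytest.approx(rise, abs=1e-9)
    for cls in geo.CLASS_ORDER:
        d = (rec.theta0_deg[cls] - p.theta0_deg[cls] + 180) % 360 - 180
        assert abs(d) < 1e-9
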