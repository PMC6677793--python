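"""Crick builder, overlap assembly, threading and terminal extension."""
import numpy as np
import pytest

from tpmkit.coilgeom import fit_local_axes, local_axis_points, radius_profile, superpose
from tpmkit.errors import (
    AlignmentError,
    GeometryError,
    InsufficientInputError,
    LengthError,
    ParameterError,
)
from tpmkit.modeler import (
    AssemblySpec,
    CrickParameters,
    assemble_overlap,
    build_ideal_coiled_coil,
    extend_termini,
    thread_sequence,
)


class TestBuilder:
    def test_zero_superhelical_radius_gives_straight_helix(self):
        st = build_ideal_coiled_coil(CrickParameters(r0=0.0, n_chains=1), 50)
        pts = local_axis_points(st.chain("A").ca_coords())
        # fitted axis is a line: residuals of a total-least-squares fit vanish
        centered = pts - pts.mean(axis=0)
        s = np.linalg.svd(centered, compute_uv=False)
        assert s[1] < 1e-6

    def test_end_to_end_axis_length_matches_rise(self):
        st = build_ideal_coiled_coil(CrickParameters(n_chains=1, r0=0.0), 100)
        ca = st.chain("A").ca_coords()
        assert ca[-1, 2] - ca[0, 2] == pytest.approx(99 * 1.495, abs=1e-9)

    def test_dimer_chains_related_by_c2_rotation(self, dimer):
        a = dimer.chain("A").ca_coords()
        b = dimer.chain("B").ca_coords()
        flip = np.diag([-1.0, -1.0, 1.0])
        assert np.sqrt(np.mean(np.sum((a @ flip.T - b) ** 2, axis=1))) < 1e-6

    def test_ca_spacing_in_physical_window(self, dimer):
        for cid in "AB":
            sp = np.linalg.norm(np.diff(dimer.chain(cid).ca_coords(), axis=0), axis=1)
            assert sp.min() > 3.6 and sp.max() < 4.0

    def test_unphysical_parameters_rejected(self):
        with pytest.raises(GeometryError):
            build_ideal_coiled_coil(CrickParameters(rise=3.0), 20)
        with pytest.raises(ParameterError):
            CrickParameters(r1=-1.0)
        with pytest.raises(InsufficientInputError):
            build_ideal_coiled_coil(CrickParameters(), 3)

    def test_deterministic(self):
        a = build_ideal_coiled_coil(CrickParameters(), 30).chain("A").ca_coords()
        b = build_ideal_coiled_coil(CrickParameters(), 30).chain("A").ca_coords()
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("r0", [3.0, 4.9, 6.0])
    def test_measure_round_trip(self, r0):
        from tpmkit.coilgeom import _tls_line, central_axis

        st = build_ideal_coiled_coil(CrickParameters(r0=r0), 70)
        prof = radius_profile(st, ["A", "B"])
        np.testing.assert_allclose(prof.helix_averaged, r0, atol=0.1)
        center = central_axis([fit_local_axes(st.chain(c)) for c in "AB"])
        c0, d = _tls_line(center.points)
        s = np.sort((center.points - c0) @ d)
        assert np.diff(s).mean() == pytest.approx(1.495, abs=0.01)


def _shifted_fragment(scaffold, rng):
    """Rigidly displaced copy of the scaffold restricted to chains A/B."""
    frag = scaffold.copy()
    from scipy.spatial.transform import Rotation

    rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
    for ch in frag.model(0):
        for r in ch.residues:
            for a in r.atoms:
                a.coords = rot @ a.coords + np.array([5.0, -3.0, 8.0])
    return frag


class TestAssemble:
    def test_fragment_already_in_frame_is_identity_splice(self, dimer):
        spec = AssemblySpec(
            fragment=dimer.copy(),
            scaffold=dimer.copy(),
            chain_map={"A": "A", "B": "B"},
            source_window=(6, 34),
            target_window=(6, 34),
            replace_side="n",
        )
        out = assemble_overlap(spec)
        assert out.metadata["assembly"]["window_rmsd_A"] == pytest.approx(0.0, abs=1e-9)
        for cid in "AB":
            np.testing.assert_allclose(
                out.chain(cid).ca_coords(), dimer.chain(cid).ca_coords(), atol=1e-9
            )

    def test_rotated_fragment_superposed_back(self, dimer, rng):
        frag = _shifted_fragment(dimer, rng)
        spec = AssemblySpec(
            fragment=frag,
            scaffold=dimer.copy(),
            chain_map={"A": "A", "B": "B"},
            source_window=(6, 34),
            target_window=(6, 34),
        )
        out = assemble_overlap(spec)
        assert out.metadata["assembly"]["window_rmsd_A"] < 1e-6
        np.testing.assert_allclose(
            out.chain("A").ca_coords(), dimer.chain("A").ca_coords(), atol=1e-6
        )

    def test_window_offset_renumbers_fragment(self, dimer):
        # map fragment residues 6-34 onto scaffold 1-29: 29 residues each
        spec = AssemblySpec(
            fragment=dimer.copy(),
            scaffold=dimer.copy(),
            chain_map={"A": "A", "B": "B"},
            source_window=(6, 34),
            target_window=(1, 29),
        )
        out = assemble_overlap(spec)
        assert out.chain("A").residues[0].seq_id == 1 - 5  # fragment residue 1 -> -4
        assert out.metadata["assembly"]["target_window"] == (1, 29)

    def test_unequal_windows_rejected(self, dimer):
        with pytest.raises(AlignmentError):
            AssemblySpec(
                fragment=dimer,
                scaffold=dimer,
                chain_map={"A": "A"},
                source_window=(6, 34),
                target_window=(1, 30),
            )

    def test_four_helix_junction_output(self):
        from tpmkit.synth import gen_overlap_bundle

        bundle, _ = gen_overlap_bundle(seed=0)
        frag = bundle.copy()
        frag.models[0] = [ch for ch in frag.model(0) if ch.chain_id in ("A", "B")]
        spec = AssemblySpec(
            fragment=frag,
            scaffold=bundle.copy(),
            chain_map={"A": "A", "B": "B"},
            source_window=(11, 39),
            target_window=(11, 39),
        )
        out = assemble_overlap(spec)
        assert sorted(ch.chain_id for ch in out.model(0)) == ["A", "B", "C", "D"]

    def test_large_misfit_recorded_as_warning(self, dimer):
        frag = dimer.copy()
        for ch in frag.model(0):
            for r in ch.residues:
                for a in r.atoms:
                    a.coords = a.coords + np.array([0.0, 0.0, 40.0]) * (r.seq_id % 2)
        spec = AssemblySpec(
            fragment=frag,
            scaffold=dimer.copy(),
            chain_map={"A": "A", "B": "B"},
            source_window=(6, 34),
            target_window=(6, 34),
        )
        out = assemble_overlap(spec)
        assert "warning" in out.metadata["assembly"]


class TestThreading:
    def test_identity_threading_changes_nothing_but_metadata(self, dimer):
        seq = "A" * 60
        out = thread_sequence(dimer, seq)
        for cid in "AB":
            np.testing.assert_array_equal(
                out.chain(cid).ca_coords(), dimer.chain(cid).ca_coords()
            )
            assert all(r.name == "ALA" for r in out.chain(cid).residues)
        assert "threading" in out.metadata

    def test_sequence_applied_at_register(self, dimer):
        seq = "G" * 5 + "LEVKQ" * 12
        out = thread_sequence(dimer, seq, register=5)
        names = [r.name for r in out.chain("A").residues[:5]]
        assert names == ["LEU", "GLU", "VAL", "LYS", "GLN"]

    def test_never_moves_an_atom(self, dimer):
        out = thread_sequence(dimer, "K" * 80, register=3)
        np.testing.assert_array_equal(
            out.chain("B").ca_coords(), dimer.chain("B").ca_coords()
        )

    def test_short_sequence_rejected(self, dimer):
        with pytest.raises(LengthError):
            thread_sequence(dimer, "A" * 59)
        with pytest.raises(LengthError):
            thread_sequence(dimer, "A" * 62, register=5)

    def test_invalid_letters_rejected(self, dimer):
        with pytest.raises(ParameterError):
            thread_sequence(dimer, "A" * 59 + "X")


class TestExtend:
    def test_zero_extension_is_identity(self, dimer, dimer_params):
        out = extend_termini(dimer, dimer_params, 0)
        for cid in "AB":
            np.testing.assert_array_equal(
                out.chain(cid).ca_coords(), dimer.chain(cid).ca_coords()
            )

    def test_numbering_continues_at_c_terminus(self, dimer, dimer_params):
        out = extend_termini(dimer, dimer_params, 10, end="c")
        ids = [r.seq_id for r in out.chain("A").residues]
        assert ids == list(range(1, 71))

    def test_numbering_continues_at_n_terminus(self, dimer, dimer_params):
        out = extend_termini(dimer, dimer_params, 4, end="n")
        ids = [r.seq_id for r in out.chain("A").residues]
        assert ids == list(range(-3, 61))

    def test_extension_radius_matches_body(self, dimer, dimer_params):
        out = extend_termini(dimer, dimer_params, 20, end="c")
        prof = radius_profile(out, ["A", "B"])
        body = prof.mean[:, prof.residue_ids <= 55]
        ext = prof.mean[:, prof.residue_ids > 62]
        assert abs(body.mean() - ext.mean()) < 0.1

    def test_splice_continuity_recorded(self, dimer, dimer_params):
        out = extend_termini(dimer, dimer_params, 8, end="c")
        for cid in "AB":
            splice = out.metadata["extension"][cid]["splice_ca_ca_A"]
            assert 3.0 < splice < 4.5

    def test_too_short_terminus_rejected(self, dimer_params):
        short = build_ideal_coiled_coil(dimer_params, 4)
        with pytest.raises(InsufficientInputError):
            extend_termini(short, dimer_params, 5, overlap=5)
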