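import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from histofold.fixture_forge import (
    ALPHA3_PRESET,
    NUCLEOSOMAL_PRESET,
    AssemblySpec,
    FlankSpec,
    assemble_oligomer,
    build_fold_monomer,
    helix_points,
)
from histofold.fold_detect import detect_histone_fold
from histofold.quaternary_classify import (
    CategoryInputs,
    assign_category,
    classify_tetramer_topology,
    detect_extra_domains,
    detect_handshake_dimer,
    estimate_wrapped_diameter,
    find_interchain_contacts,
    interface_confidence,
)
from histofold.structure_io import Chain, PaeMatrix, Residue, StructureModel


def _model_from_chains(**coords):
    chains = {}
    for cid, xyz in coords.items():
        residues = [
            Residue(i + 1, "ALA", {"CA": np.asarray(c, dtype=float)}, 90.0)
            for i, c in enumerate(xyz)
        ]
        chains[cid] = Chain(cid, residues)
    return StructureModel(chains)


def _anns(model):
    return {cid: detect_histone_fold(model, cid) for cid in model.chain_ids}


class TestContacts:
    def test_far_chains_empty(self):
        a = np.zeros((10, 3)) + np.arange(10)[:, None] * [3.8, 0, 0]
        b = a + np.array([0.0, 50.0, 0.0])
        cm = find_interchain_contacts(_model_from_chains(A=a, B=b))
        assert cm.pairs == []

    def test_parallel_helices_match_brute_force(self):
        a = helix_points(15, np.zeros(3), [1, 0, 0], [0, 0, 1])
        b = helix_points(15, np.array([0.0, 5.0, 0.0]), [1, 0, 0], [0, 0, 1])
        cm = find_interchain_contacts(_model_from_chains(A=a, B=b), cutoff=8.0)
        brute = sum(
            1
            for p in a
            for q in b
            if np.linalg.norm(p - q) <= 8.0
        )
        assert len(cm.pairs) == brute > 0

    def test_zero_cutoff_empty(self):
        a = helix_points(10, np.zeros(3), [1, 0, 0], [0, 0, 1])
        b = a + np.array([0.0, 5.0, 0.0])
        assert find_interchain_contacts(_model_from_chains(A=a, B=b), cutoff=0.0).pairs == []

    def test_single_chain_rejected(self):
        a = helix_points(10, np.zeros(3), [1, 0, 0], [0, 0, 1])
        with pytest.raises(ValueError, match="monomer"):
            find_interchain_contacts(_model_from_chains(A=a))


class TestHandshake:
    def test_fixture_dimer_angle_band(self, nuc_dimer):
        model, _ = nuc_dimer
        ok, angle = detect_handshake_dimer(model, _anns(model))
        assert ok
        assert 25.0 <= angle <= 35.0

    def test_separated_chains_false(self, nuc_monomer):
        model, _ = nuc_monomer
        a = model.chains["A"].ca_coords()
        m = _model_from_chains(A=a, B=a + np.array([0.0, 0.0, 60.0]))
        ok, angle = detect_handshake_dimer(m, _anns(m))
        assert not ok and angle is None

    def test_monomer_input_error(self, nuc_monomer):
        model, _ = nuc_monomer
        with pytest.raises(ValueError, match="2 chains"):
            detect_handshake_dimer(model, _anns(model))

    def test_missing_annotation_error(self, nuc_dimer):
        model, _ = nuc_dimer
        with pytest.raises(ValueError, match="annotation"):
            detect_handshake_dimer(model, {"A": None, "B": None})


class TestInterfaceConfidence:
    def _pae(self, ab, ba, n=3):
        values = np.full((2 * n, 2 * n), 1.0)
        values[:n, n:] = ab
        values[n:, :n] = ba
        return PaeMatrix(values, {"A": (0, n), "B": (n, 2 * n)})

    def test_low_pae_high_quality(self):
        # interfaces with PAE below 10 Å count as high quality
        mean, quality = interface_confidence(self._pae(5.0, 5.0), "A", "B")
        assert (mean, quality) == (5.0, "high")

    def test_high_pae_low_quality(self):
        mean, quality = interface_confidence(self._pae(25.0, 25.0), "A", "B")
        assert (mean, quality) == (25.0, "low")

    def test_asymmetric_blocks_hand_mean(self):
        mean, quality = interface_confidence(self._pae(4.0, 8.0), "A", "B")
        assert mean == pytest.approx(6.0)
        assert quality == "high"

    def test_boundary_exactly_ten_is_low(self):
        mean, quality = interface_confidence(self._pae(10.0, 10.0), "A", "B")
        assert mean == pytest.approx(10.0)
        assert quality == "low"

    def test_unknown_chain(self):
        with pytest.raises(KeyError):
            interface_confidence(self._pae(5.0, 5.0), "A", "Q")

    def test_quality_monotone_in_entries(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 20, size=(6, 6))
        pae = PaeMatrix(base, {"A": (0, 3), "B": (3, 6)})
        m0, q0 = interface_confidence(pae, "A", "B")
        for i, j in itertools.product(range(6), repeat=2):
            bumped = base.copy()
            bumped[i, j] += 5.0
            m1, q1 = interface_confidence(
                PaeMatrix(bumped, {"A": (0, 3), "B": (3, 6)}), "A", "B"
            )
            assert m1 >= m0
            assert not (q0 == "low" and q1 == "high")


class TestTetramerTopology:
    def test_ftf_fixture_two_interfaces(self, a3_ftf_tetramer):
        model, _ = a3_ftf_tetramer
        call = classify_tetramer_topology(model, _anns(model))
        assert call.topology == "ftf_torus"
        assert len(call.interfaces) == 2

    def test_cc_fixture_bundle(self, nuc_cc_tetramer):
        model, _ = nuc_cc_tetramer
        call = classify_tetramer_topology(model, _anns(model))
        assert call.topology == "cc_bundle"

    def test_separated_dimers_none(self, nuc_dimer):
        model, _ = nuc_dimer
        a = model.chains["A"].ca_coords()
        b = model.chains["B"].ca_coords()
        far = np.array([0.0, 0.0, 80.0])
        m = _model_from_chains(A=a, B=b, C=a + far, D=b + far)
        call = classify_tetramer_topology(m, _anns(m))
        assert call.topology == "none"

    def test_invariant_under_relabeling_and_rigid_motion(self, a3_ftf_tetramer):
        model, _ = a3_ftf_tetramer
        rot = Rotation.from_euler("xyz", [0.5, -0.3, 1.7]).as_matrix()
        moved = model.transformed(rot, np.array([11.0, -7.0, 3.0]))
        relabeled = _model_from_chains(
            **{
                new: moved.chains[old].ca_coords()
                for new, old in zip("ABCD", ["D", "B", "A", "C"])
            }
        )
        call = classify_tetramer_topology(relabeled, _anns(relabeled))
        assert call.topology == "ftf_torus"

    def test_wrong_chain_count(self, nuc_dimer):
        model, _ = nuc_dimer
        with pytest.raises(ValueError, match="4 chains"):
            classify_tetramer_topology(model, _anns(model))


class TestExtraDomains:
    def test_compact_n_domain_reported(self):
        from dataclasses import replace

        arch = replace(ALPHA3_PRESET, n_flank=FlankSpec(60, "compact_domain"))
        model, _ = build_fold_monomer(arch)
        ann = detect_histone_fold(model, "A")
        domains = detect_extra_domains(model, ann)
        assert domains == [("N", 60, True)]

    def test_bare_fold_empty(self, nuc_monomer):
        model, _ = nuc_monomer
        ann = detect_histone_fold(model, "A")
        assert detect_extra_domains(model, ann) == []

    def test_short_extension_below_threshold(self):
        from dataclasses import replace

        arch = replace(NUCLEOSOMAL_PRESET, c_flank=FlankSpec(20, "charged_tail", sign=1))
        model, _ = build_fold_monomer(arch)
        ann = detect_histone_fold(model, "A")
        assert detect_extra_domains(model, ann) == []


class TestWrappedDiameter:
    def _tetramer_cloud(self, extent):
        # flat disc in xy: max in-plane extent = `extent`, thin in z
        pts = np.array(
            [[0.0, 0, 0], [extent, 0, 0], [extent / 2, extent / 3, 1.0],
             [extent / 2, -extent / 3, -1.0]]
        )
        return _model_from_chains(A=pts[:1], B=pts[1:2], C=pts[2:3], D=pts[3:4])

    def test_43_angstrom_extent_gives_8_3_nm(self):
        model = self._tetramer_cloud(43.0)
        assert estimate_wrapped_diameter(model, 2.0) == pytest.approx(8.3, abs=0.01)

    def test_degenerate_cloud_gives_4_nm(self):
        pts = np.zeros((1, 3))
        model = _model_from_chains(A=pts, B=pts, C=pts, D=pts)
        assert estimate_wrapped_diameter(model, 2.0) == pytest.approx(4.0)

    def test_dna_diameter_additivity_exact(self, a3_ftf_tetramer):
        model, _ = a3_ftf_tetramer
        assert estimate_wrapped_diameter(model, 0.0) + 4.0 == estimate_wrapped_diameter(
            model, 2.0
        )

    def test_requires_tetramer(self, nuc_dimer):
        with pytest.raises(ValueError):
            estimate_wrapped_diameter(nuc_dimer[0])


class TestAssignCategory:
    def test_ftf_high_confidence(self):
        call = assign_category(
            CategoryInputs(
                fold_family="alpha3",
                dimer_is_handshake=True,
                dimer_confidence="high",
                tetramer_topology="ftf_torus",
                tetramer_confidence="high",
            )
        )
        assert call.category == "ftf"

    def test_low_pae_torus_skipped(self):
        # the torus rule must not fire on a low-confidence interface
        call = assign_category(
            CategoryInputs(
                fold_family="alpha3",
                dimer_is_handshake=True,
                dimer_confidence="high",
                tetramer_topology="ftf_torus",
                tetramer_confidence="low",
            )
        )
        assert call.category == "bacterial_dimer"

    def test_low_pae_everywhere_undefined(self):
        call = assign_category(
            CategoryInputs(
                fold_family="alpha3",
                dimer_is_handshake=True,
                dimer_confidence="low",
                tetramer_topology="ftf_torus",
                tetramer_confidence="low",
            )
        )
        assert call.category == "undefined"
        assert call.confidence == "low"

    def test_cc_bundle_with_long_helix_flags_rdgc(self):
        call = assign_category(
            CategoryInputs(
                fold_family="nucleosomal",
                tetramer_topology="cc_bundle",
                tetramer_confidence="high",
                cterm_helix_len=32,
            )
        )
        assert call.category == "coiled_coil"
        assert "rdgc_like" in call.flags

    def test_mc_like(self):
        call = assign_category(
            CategoryInputs(
                fold_family="nucleosomal",
                tetramer_topology="ctail_tetramer",
                tetramer_confidence="high",
            )
        )
        assert call.category == "mc_like"

    def test_phage_like(self):
        call = assign_category(
            CategoryInputs(
                fold_family="alpha3",
                tetramer_topology="ctail_tetramer",
                tetramer_confidence="high",
            )
        )
        assert call.category == "phage_like"

    def test_transmembrane_beats_everything(self):
        call = assign_category(
            CategoryInputs(
                fold_family="nucleosomal",
                tm_segments=[(10, 35)],
                basic_alpha1_positions=[],
            )
        )
        assert call.category == "transmembrane"

    def test_tm_with_alpha1_basics_not_transmembrane(self):
        call = assign_category(
            CategoryInputs(
                fold_family="nucleosomal",
                tm_segments=[(10, 35)],
                basic_alpha1_positions=[3, 7],
            )
        )
        assert call.category != "transmembrane"

    def test_ihf_like(self):
        call = assign_category(
            CategoryInputs(
                fold_family="nucleosomal",
                dimer_is_handshake=True,
                dimer_confidence="high",
                dimer_has_dimerizing_ctail=True,
            )
        )
        assert call.category == "ihf_like"

    def test_no_fold_undefined(self):
        assert assign_category(CategoryInputs()).category == "undefined"
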