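"""Dihedral computation, redundancy filtering, aggregation, extraction."""

import numpy as np
import pytest

from conftest import build_backbone, place_atom, write_pdb
from ramacodon.dataset import (
    ResidueObservation,
    aggregate_records,
    compute_backbone_dihedrals,
    extract_codon_samples,
    fps_filter,
    normalized_similarity,
    parse_dssp,
    parse_ss_table,
    read_records,
    read_structure_backbone,
    write_records,
)
from ramacodon.genetics import AMBIGUOUS, UNASSIGNED


class TestBackboneDihedrals:
    def test_two_residue_chain_boundary_rule(self):
        atoms = build_backbone([0.0, -60.0], [-45.0, 0.0])
        d = compute_backbone_dihedrals(atoms)
        assert np.isnan(d[0, 0]) and np.isnan(d[1, 1])
        assert np.isfinite(d[0, 1]) and np.isfinite(d[1, 0])

    def test_round_trip_through_constructed_coordinates(self):
        # backbone built from prescribed torsions must return them exactly
        phis = [0.0, -60.0, -75.0, 60.0, -120.0]
        psis = [-45.0, -40.0, 150.0, 30.0, 0.0]
        atoms = build_backbone(phis, psis)
        d = compute_backbone_dihedrals(atoms)
        np.testing.assert_allclose(d[1:, 0], phis[1:], atol=1e-6)
        np.testing.assert_allclose(d[:-1, 1], psis[:-1], atol=1e-6)

    def test_agrees_with_independent_library_oracle(self, rng):
        import biotite.structure as struc

        from ramacodon.dataset import _dihedral

        for _ in range(50):
            pts = rng.normal(0, 3, (4, 3))
            ours = _dihedral(*pts)
            theirs = np.degrees(struc.dihedral(*pts))
            # the library evaluates in single precision
            assert ours == pytest.approx(theirs, abs=1e-4)

    def test_mirror_image_negates_dihedrals(self):
        atoms = build_backbone([0.0, -60.0, 70.0], [-45.0, 120.0, 0.0])
        mirrored = atoms.copy()
        mirrored[:, :, 2] *= -1
        d = compute_backbone_dihedrals(atoms)
        dm = compute_backbone_dihedrals(mirrored)
        mask = np.isfinite(d)
        np.testing.assert_allclose(dm[mask], -d[mask], atol=1e-6)

    def test_chain_break_treated_as_termini(self):
        atoms = build_backbone([0.0, -60.0, 70.0, -80.0],
                               [-45.0, 120.0, 40.0, 0.0])
        atoms[2:] += 100.0  # break between residues 1 and 2
        d = compute_backbone_dihedrals(atoms)
        assert np.isnan(d[2, 0]) and np.isnan(d[1, 1])
        assert np.isfinite(d[1, 0]) and np.isfinite(d[2, 1])

    def test_missing_atom_undefines_affected_dihedrals(self):
        atoms = build_backbone([0.0, -60.0, 70.0], [-45.0, 120.0, 0.0])
        atoms[1, 1] = np.nan  # CA of residue 1
        d = compute_backbone_dihedrals(atoms)
        assert np.isnan(d[1]).all()


class TestNormalizedSimilarity:
    def test_self_similarity_is_one(self):
        sim = normalized_similarity(["MKVL", "AAAA", "WYW"])
        np.testing.assert_allclose(np.diag(sim.s_tilde), 1.0)

    def test_disjoint_alphabets_give_zero(self):
        sim = normalized_similarity(["MMMM", "KKK"])
        assert sim.s_tilde[0, 1] == 0

    def test_hand_worked_example(self):
        sim = normalized_similarity(["MKVL", "MVL"])
        assert sim.s_tilde[0, 1] == pytest.approx(3 / np.sqrt(12))

    def test_matches_lcs_dynamic_programming_oracle(self, rng):
        def lcs(a, b):
            dp = np.zeros((len(a) + 1, len(b) + 1), dtype=int)
            for i in range(1, len(a) + 1):
                for j in range(1, len(b) + 1):
                    dp[i, j] = (dp[i - 1, j - 1] + 1 if a[i - 1] == b[j - 1]
                                else max(dp[i - 1, j], dp[i, j - 1]))
            return dp[-1, -1]

        alphabet = list("ACDEFG")
        for _ in range(20):
            a = "".join(rng.choice(alphabet, rng.integers(1, 10)))
            b = "".join(rng.choice(alphabet, rng.integers(1, 10)))
            sim = normalized_similarity([a, b])
            assert sim.s_tilde[0, 1] == pytest.approx(
                lcs(a, b) / np.sqrt(len(a) * len(b)))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError):
            normalized_similarity(["MK", ""])


class TestFpsFilter:
    def _sim(self, mat, ids=None):
        from ramacodon.dataset import SimilarityMatrix

        mat = np.asarray(mat, dtype=float)
        return SimilarityMatrix(ids or list(range(len(mat))), mat)

    def test_all_similar_keeps_only_start(self):
        mat = np.full((4, 4), 0.9)
        np.fill_diagonal(mat, 1.0)
        assert fps_filter(self._sim(mat), tau=0.7) == [0]

    def test_all_dissimilar_keeps_everything(self):
        assert fps_filter(self._sim(np.eye(5)), tau=0.7) == [0, 1, 2, 3, 4]

    def test_guarantee_and_greedy_oracle(self, rng):
        def oracle(s, tau, start=0):
            n = len(s)
            sel = [start]
            rem = [i for i in range(n) if i != start]
            while rem:
                best_j, best_v = None, None
                for j in rem:
                    v = max(s[j][i] for i in sel)
                    if best_v is None or v < best_v:
                        best_j, best_v = j, v
                if best_v > tau:
                    break
                sel.append(best_j)
                rem.remove(best_j)
            return sel

        for _ in range(50):
            n = rng.integers(2, 8)
            m = rng.uniform(0, 1, (n, n))
            m = 0.5 * (m + m.T)
            np.fill_diagonal(m, 1.0)
            tau = float(rng.uniform(0.2, 0.9))
            out = fps_filter(self._sim(m), tau=tau)
            assert out == oracle(m.tolist(), tau)
            idx = np.array(out)
            if len(idx) > 1:
                off = m[np.ix_(idx, idx)].copy()
                np.fill_diagonal(off, 0.0)
                assert off.max() <= tau


class TestAggregation:
    def _obs(self, chain, idx, phi, psi, ss="E", codon="GCA", acc="P1"):
        return ResidueObservation(chain, acc, idx, phi, psi, ss, codon)

    def test_single_chain_identity(self):
        recs, report = aggregate_records([self._obs("c1", 0, -60.0, -45.0)])
        row = recs[0].residues.iloc[0]
        assert (row.phi, row.psi) == (-60.0, -45.0)
        assert row.codon == "GCA" and row.ss == "E" and row.n_chains == 1

    def test_two_chain_torus_mean_worked_example(self):
        recs, _ = aggregate_records([
            self._obs("c1", 0, 170.0, 170.0),
            self._obs("c2", 0, -170.0, -130.0),
        ])
        row = recs[0].residues.iloc[0]
        assert row.phi == pytest.approx(180.0)
        assert row.psi == pytest.approx(-160.0)
        assert row.n_chains == 2

    def test_secondary_structure_disagreement_drops_label(self):
        recs, report = aggregate_records([
            self._obs("c1", 0, -60, -45, ss="E"),
            self._obs("c2", 0, -60, -45, ss="H"),
        ])
        assert recs[0].residues.iloc[0].ss == ""
        assert report["ss_conflict"] == 1

    def test_codon_disagreement_marks_ambiguous(self):
        recs, report = aggregate_records([
            self._obs("c1", 0, -60, -45, codon="GCA"),
            self._obs("c2", 0, -60, -45, codon="GCT"),
        ])
        assert recs[0].residues.iloc[0].codon == AMBIGUOUS
        assert report["codon_conflict"] == 1

    def test_report_counts_all_inputs(self):
        obs = [self._obs("c1", i, -60, -45) for i in range(3)]
        obs += [self._obs("c2", 10, np.nan, np.nan)]
        recs, report = aggregate_records(obs)
        assert report["input_observations"] == 4
        assert report["no_defined_dihedral"] == 1


class TestExtractCodonSamples:
    def _record(self, rows):
        recs, _ = aggregate_records(rows)
        return recs

    def test_only_strand_and_helix_labels_contribute(self):
        rows = [ResidueObservation("c", "P1", i, -60.0, -45.0, ss, "GCA")
                for i, ss in enumerate("EHTC")]
        pools = extract_codon_samples(self._record(rows))
        assert set(pools) == {("GCA", "E"), ("GCA", "H")}
        assert len(pools[("GCA", "E")]) == 1

    def test_ambiguous_codons_yield_empty_collection(self):
        rows = [ResidueObservation("c", "P1", i, -60.0, -45.0, "E", AMBIGUOUS)
                for i in range(5)]
        assert extract_codon_samples(self._record(rows)) == {}

    def test_surviving_row_count_on_toy_record(self):
        # 10 residues: 4 strand with valid codons, the rest excluded for
        # various reasons; the E-mode pool must contain exactly 4 points
        rows = []
        for i in range(4):
            rows.append(ResidueObservation("c", "P1", i, -120.0, 130.0, "E", "GTT"))
        rows.append(ResidueObservation("c", "P1", 4, -120.0, 130.0, "E", UNASSIGNED))
        rows.append(ResidueObservation("c", "P1", 5, -120.0, 130.0, "E", AMBIGUOUS))
        rows.append(ResidueObservation("c", "P1", 6, np.nan, np.nan, "E", "GTT"))
        for i in range(7, 10):
            rows.append(ResidueObservation("c", "P1", i, -60.0, -45.0, "T", "GTT"))
        pools = extract_codon_samples(self._record(rows))
        assert sum(len(s) for (c, ss), s in pools.items() if ss == "E") == 4


def test_records_tsv_round_trip(tmp_path):
    obs = [ResidueObservation("c1", "P1", i, -60.0 + i, -45.0, "E", "GCA")
           for i in range(3)]
    obs.append(ResidueObservation("c1", "P2", 0, np.nan, np.nan, "H", UNASSIGNED))
    recs, _ = aggregate_records(obs)
    path = tmp_path / "records.tsv"
    write_records(recs, path, header_lines=["# test"])
    back = read_records(path)
    assert [r.accession for r in back] == ["P1", "P2"]
    np.testing.assert_allclose(back[0].residues.phi, [-60.0, -59.0, -58.0])
    assert np.isnan(back[1].residues.phi.iloc[0])


def test_parse_dssp_minimal_body():
    text = (
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC\n"
        "    1    2 A M  H  >  S+\n"
        "    2    3 A K  E     S-\n"
        "    3        !*            \n"
        "    4    9 A V     >  S+\n"
    )
    labels = parse_dssp(text)
    assert labels == {("A", 2): "H", ("A", 3): "E", ("A", 9): "C"}


def test_parse_ss_table(tmp_path):
    p = tmp_path / "ss.tsv"
    p.write_text("# comment\nchainA\t0\tE\nchainA\t1\tH\n")
    assert parse_ss_table(p) == {("chainA", 0): "E", ("chainA", 1): "H"}


def test_read_structure_backbone_from_written_pdb(tmp_path):
    phis = [0.0, -60.0, -75.0]
    psis = [-45.0, -40.0, 0.0]
    atoms = build_backbone(phis, psis)
    pdb = tmp_path / "toy.pdb"
    write_pdb(pdb, "MKV", atoms)
    chains = read_structure_backbone(pdb)
    assert set(chains) == {"A"}
    seq, coords = chains["A"]
    assert seq == "MKV"
    d = compute_backbone_dihedrals(coords)
    # PDB coordinates carry 3 decimals, so torsions round-trip to ~0.1 deg
    np.testing.assert_allclose(d[1:, 0], phis[1:], atol=0.2)
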