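"""PDB parsing, curation rules and ensemble congruence."""

import numpy as np
import pytest

from pocketome.structure_io import (
    ChainLookupError,
    CongruenceError,
    EmptyStructureError,
    PDBParseError,
    clean_structure,
    combine,
    read_structure,
    read_trajectory,
    split_complex,
    write_structure,
)


def _pdb_line(serial, name, resname, chain, resseq, x, y, z,
              record="ATOM", altloc=" ", occ=1.0, element=None):
    element = element or name[0]
    nm = name if len(name) == 4 else f" {name:<3s}"
    return (f"{record:<6s}{serial:>5d} {nm:<4s}{altloc}{resname:>3s} {chain}"
            f"{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}  0.00"
            f"          {element:>2s}")


class TestReadStructure:
    def test_parses_toy_file(self, toy_pdb):
        s = read_structure(toy_pdb)
        assert s.n_atoms == 3
        assert s.models == 1
        assert [a.name for a in s.atoms()] == ["N", "CA", "CB"]
        np.testing.assert_allclose(next(s.atoms()).coords,
                                   [11.104, 6.134, -6.504])

    def test_multi_model_counts(self, tmp_path):
        lines = []
        for m in (1, 2):
            lines.append(f"MODEL     {m}")
            for i in range(5):
                lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1,
                                       float(i), float(m), 0.0))
            lines.append("ENDMDL")
        p = tmp_path / "mm.pdb"
        p.write_text("\n".join(lines) + "\n")
        s = read_structure(p)
        assert s.models == 2
        assert s.n_atoms == 10

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(p)

    def test_malformed_line_strict_mode_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.pdb"
        p.write_text(_pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0) + "\n"
                     + "ATOM      2  CA  GLY A   2      xxxxxxx   0.000   0.000\n")
        with pytest.raises(PDBParseError, match="line 2"):
            read_structure(p, permissive=False)
        # permissive mode skips the bad record
        assert read_structure(p, permissive=True).n_atoms == 1

    def test_round_trip_preserves_geometry(self, fx_complex, tmp_path):
        s = fx_complex.complex
        p = tmp_path / "rt.pdb"
        write_structure(s, p)
        s2 = read_structure(p)
        assert s2.n_atoms == s.n_atoms
        assert [a.name for a in s2.atoms()] == [a.name for a in s.atoms()]
        assert [r.chain for r in s2.residues] == [r.chain for r in s.residues]
        np.testing.assert_allclose(s2.coords(), s.coords(), atol=5.1e-4)
        # second round trip is exact: coordinates are already quantized
        p3 = tmp_path / "rt2.pdb"
        write_structure(s2, p3)
        assert read_structure(p3).coords() == pytest.approx(s2.coords())


class TestCleanStructure:
    def test_keeps_first_model_only(self, tmp_path):
        lines = []
        for m in (1, 2):
            lines.append(f"MODEL     {m}")
            for i in range(4):
                lines.append(_pdb_line(i + 1, "CA", "GLY", "A", i + 1,
                                       float(i), float(m), 0.0))
            lines.append("ENDMDL")
        p = tmp_path / "mm.pdb"
        p.write_text("\n".join(lines) + "\n")
        c = clean_structure(read_structure(p))
        assert c.models == 1
        assert c.n_atoms == 4
        assert all(a.coords[1] == 1.0 for a in c.atoms())

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join([
            _pdb_line(1, "CA", "SER", "A", 1, 1.0, 0, 0, altloc="A", occ=0.6),
            _pdb_line(2, "CA", "SER", "A", 1, 2.0, 0, 0, altloc="B", occ=0.4),
        ]) + "\n")
        c = clean_structure(read_structure(p))
        assert c.n_atoms == 1
        atom = next(c.atoms())
        assert atom.coords[0] == pytest.approx(1.0)
        assert atom.altloc == ""

    def test_altloc_tie_takes_smallest_code(self, tmp_path):
        p = tmp_path / "alt.pdb"
        p.write_text("\n".join([
            _pdb_line(1, "CA", "SER", "A", 1, 2.0, 0, 0, altloc="B", occ=0.5),
            _pdb_line(2, "CA", "SER", "A", 1, 1.0, 0, 0, altloc="A", occ=0.5),
        ]) + "\n")
        c = clean_structure(read_structure(p))
        assert next(c.atoms()).coords[0] == pytest.approx(1.0)

    def test_drops_hetatm(self, tmp_path):
        p = tmp_path / "het.pdb"
        p.write_text("\n".join([
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "A", 2, 1, 0, 0),
            _pdb_line(3, "CA", "GLY", "A", 3, 2, 0, 0),
            _pdb_line(4, "O", "HOH", "A", 101, 9, 9, 9, record="HETATM"),
            _pdb_line(5, "O", "HOH", "A", 102, 8, 8, 8, record="HETATM"),
        ]) + "\n")
        c = clean_structure(read_structure(p))
        assert c.n_atoms == 3
        assert all(a.record_kind == "ATOM" for a in c.atoms())

    def test_idempotent_and_preserves_coordinates(self, fx_complex):
        s = fx_complex.complex
        once = clean_structure(s)
        twice = clean_structure(once)
        assert once.n_atoms == twice.n_atoms
        np.testing.assert_array_equal(once.coords(), twice.coords())
        # surviving atoms keep their original coordinates
        np.testing.assert_array_equal(once.coords(), s.coords())

    def test_organism_filter_with_table(self, tmp_path):
        p = tmp_path / "chim.pdb"
        p.write_text("\n".join([
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "B", 1, 5, 0, 0),
        ]) + "\n")
        s = read_structure(p)
        c = clean_structure(s, allowed_organism="homo sapiens",
                            chain_organisms={"A": "Homo sapiens", "B": "Mus musculus"})
        assert [r.chain for r in c.residues] == ["A"]

    def test_organism_filter_unknown_chain(self, tmp_path):
        p = tmp_path / "chim.pdb"
        p.write_text(_pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0) + "\n")
        s = read_structure(p)
        with pytest.warns(UserWarning):
            kept = clean_structure(s, allowed_organism="homo sapiens")
        assert kept.n_atoms == 1
        with pytest.raises(ValueError, match="organism"):
            clean_structure(s, allowed_organism="homo sapiens",
                            on_unknown_organism="error")


class TestSplitComplex:
    def test_basic_split(self, fx_complex):
        receptor, ligand = split_complex(fx_complex.complex, "A", "L")
        assert all(r.chain == "A" for r in receptor.residues)
        assert len(ligand) == 1 and ligand[0].resname == "LIG"

    def test_missing_chain_lists_available(self, fx_complex):
        with pytest.raises(ChainLookupError, match=r"'X'.*\['A', 'L'\]"):
            split_complex(fx_complex.complex, "A", "X")

    def test_overlap_rejected(self, fx_complex):
        with pytest.raises(ValueError, match="overlap"):
            split_complex(fx_complex.complex, "A,L", "L")

    def test_multi_chain_receptor(self, tmp_path):
        p = tmp_path / "two.pdb"
        p.write_text("\n".join([
            _pdb_line(1, "CA", "GLY", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "B", 1, 5, 0, 0),
            _pdb_line(3, "C1", "LIG", "L", 1, 2, 2, 2, record="HETATM"),
        ]) + "\n")
        receptor, ligand = split_complex(read_structure(p), "A,B", "L")
        assert sorted(receptor.chains()) == ["A", "B"]
        assert len(ligand) == 1


class TestReadTrajectory:
    def _write_frames(self, tmp_path, topo, coords_list, drop_atom_in=None):
        lines = []
        for m, xyz in enumerate(coords_list, start=1):
            lines.append(f"MODEL     {m}")
            i = 0
            for r in topo.residues:
                for a in r.atoms:
                    if drop_atom_in == m and i == 0:
                        i += 1
                        continue
                    lines.append(_pdb_line(i + 1, a.name, r.resname, r.chain,
                                           r.resseq, *xyz[i], element=a.element))
                    i += 1
            lines.append("ENDMDL")
        p = tmp_path / "traj.pdb"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_one_frame_per_model(self, fx_complex, tmp_path):
        topo = fx_complex.complex
        base = topo.coords()
        frames = [np.round(base + i, 3) for i in range(5)]
        p = self._write_frames(tmp_path, topo, frames)
        ens = read_trajectory(topo, p)
        assert ens.frame_count == 5
        np.testing.assert_allclose(ens.frames[3], frames[3], atol=5.1e-4)

    def test_atom_count_mismatch_names_model(self, fx_complex, tmp_path):
        topo = fx_complex.complex
        base = topo.coords()
        p = self._write_frames(tmp_path, topo, [base] * 4, drop_atom_in=3)
        with pytest.raises(CongruenceError, match="model 3"):
            read_trajectory(topo, p)

    def test_single_model_identity(self, fx_complex, tmp_path):
        topo = fx_complex.complex
        p = tmp_path / "one.pdb"
        write_structure(topo, p)
        ens = read_trajectory(topo, p)
        assert ens.frame_count == 1
        np.testing.assert_allclose(ens.frames[0], topo.coords(), atol=5.1e-4)
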