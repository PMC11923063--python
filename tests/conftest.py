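"""Shared fixtures: toy kinetic tables, a PSI-BLAST-style PSSM and a toy
PDB structure, all generated programmatically."""

from __future__ import annotations

import pytest

from enzkin.engineering import AMINO_ACIDS

#: Standard PSI-BLAST column order.
PSSM_COLUMNS = list("ARNDCQEGHILKMFPSTWYV")


def pssm_score(pos: int, aa: str) -> int:
    """Deterministic toy score: varies with position and residue."""
    return ((pos * 3 + AMINO_ACIDS.index(aa) * 7) % 13) - 6


def make_pssm_text(sequence: str, columns: list[str] | None = None) -> str:
    """Render a PSI-BLAST ASCII PSSM for a query sequence."""
    cols = columns or PSSM_COLUMNS
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(cols),
    ]
    for pos, aa in enumerate(sequence, start=1):
        scores = "  ".join(f"{pssm_score(pos, c):3d}" for c in cols)
        lines.append(f"{pos:5d} {aa}   {scores}")
    lines.append("")
    lines.append("                      K         Lambda")
    return "\n".join(lines) + "\n"


@pytest.fixture
def pssm_file(tmp_path):
    """A 12-residue toy PSSM on disk, plus its query sequence."""
    sequence = "MKTAYIAKQRLM"
    path = tmp_path / "toy.pssm"
    path.write_text(make_pssm_text(sequence))
    return path, sequence


def pdb_atom(serial: int, name: str, resname: str, resseq: int,
             x: float, y: float, z: float, element: str,
             record: str = "ATOM") -> str:
    return (
        f"{record:<6}{serial:>5} {name:^4} {resname:<3} A{resseq:>4}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{element:>2}"
    )


@pytest.fixture
def toy_pdb(tmp_path):
    """Three alanine residues at 5/10/14 Å from a one-atom ligand (LIG)."""
    lines = [
        pdb_atom(1, "CA", "ALA", 1, 5.0, 0.0, 0.0, "C"),
        pdb_atom(2, "CB", "ALA", 1, 6.0, 0.0, 0.0, "C"),
        pdb_atom(3, "CA", "ALA", 2, 10.0, 0.0, 0.0, "C"),
        pdb_atom(4, "CA", "ALA", 3, 14.0, 0.0, 0.0, "C"),
        pdb_atom(5, "C1", "LIG", 90, 0.0, 0.0, 0.0, "C", record="HETATM"),
        "END",
    ]
    path = tmp_path / "toy.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def raw_table(tmp_path):
    """A small raw kinetic CSV exercising all the curation drop rules."""
    rows = [
        "enzyme_id,sequence,substrate_name,smiles,param,value,unit",
        "P00001,MKTAYIAKQR,ethanol,CCO,kcat,10,s^(-1)",
        "P00001,MKTAYIAKQR,ethanol,CCO,kcat,6000,min^(-1)",
        "P00002,MKTAYIAKQW,ethanol,CCO,kcat,5,s^(-1)",
        "P00001;P00009,MKTAYIAKQR,ethanol,CCO,kcat,1,s^(-1)",
        "P00003,MKTAYIAKQY,phenol,,kcat,2,s^(-1)",
        "P00001,MKTAYIAKQR,ethanol,CCO,km,0.001,M",
        "P00001,MKTAYIAKQR,ethanol,CCO,km,2.0,mM",
        "P00002,MKTAYIAKQW,ethanol,CCO,km,500,uM",
        "P00004,MKTAYIAKQV,ethanol,CCO,kcat,3,furlongs",
    ]
    path = tmp_path / "raw.csv"
    path.write_text("\n".join(rows) + "\n")
    return path
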