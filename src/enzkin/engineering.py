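"""Enzyme mining and in-silico directed evolution.

The workflow mirrors a practical enzyme-discovery campaign: candidate
homologs of a reference enzyme are length-filtered (length difference
> 20 residues removed), ranked by predicted catalytic efficiency
(log10 kcat − log10 Km) and truncated to the top 150.  For engineering,
pocket residues within 12 Å of the bound substrate are saturated — each
site mutated to the 19 alternative standard residues — the top half of
mutants by predicted kcat/Km is retained, and of those only mutations
whose ΔPSSM (target-residue PSSM score minus wild-type-residue score at
the site) exceeds 7 survive, keeping proposals consistent with the
evolutionary record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS", "PSSM", "MutantSpec", "CandidateEnzyme",
    "parse_pssm", "delta_pssm", "enumerate_mutants", "pocket_sites",
    "mine_homologs", "screen_mutants",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class PSSM:
    """Position-specific scoring matrix (PSI-BLAST ASCII layout).

    ``scores[n-1][aa]`` is the integer score of residue ``aa`` at 1-based
    position ``n``; ``query`` is the query residue per position.
    """

    scores: list[dict[str, int]]
    query: str

    @property
    def length(self) -> int:
        return len(self.scores)

    def score(self, site: int, aa: str) -> int:
        if not 1 <= site <= self.length:
            raise IndexError(
                f"site {site} outside PSSM positions 1..{self.length}")
        if aa not in AMINO_ACIDS:
            raise ValueError(f"nonstandard residue {aa!r}")
        return self.scores[site - 1][aa]


def parse_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM (header line of residue letters, then
    one row per position: index, query residue, 20 integer scores).

    Scores are keyed by the residue letters of the header, so a permuted
    column order parses identically.  A data row with fewer than 20 scores
    raises with its line number.
    """
    lines = Path(path).read_text().splitlines()
    header: list[str] | None = None
    scores: list[dict[str, int]] = []
    query_chars: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if header is None:
            if len(tokens) >= 20 and all(
                    len(t) == 1 and t in AMINO_ACIDS for t in tokens[:20]):
                header = tokens[:20]
                if len(set(header)) != 20:
                    raise ValueError(
                        f"line {lineno}: PSSM header repeats residues")
            continue
        if not tokens:
            break  # blank line ends the score block
        if not tokens[0].isdigit():
            break  # trailing statistics
        if int(tokens[0]) != expected_pos:
            raise ValueError(
                f"line {lineno}: expected position {expected_pos}, "
                f"got {tokens[0]}")
        if len(tokens) < 2 or len(tokens[1]) != 1:
            raise ValueError(f"line {lineno}: missing query residue")
        row_scores = tokens[2:2 + 20]
        if len(row_scores) < 20:
            raise ValueError(
                f"line {lineno}: expected 20 scores, got {len(row_scores)}")
        try:
            values = [int(t) for t in row_scores]
        except ValueError as err:
            raise ValueError(f"line {lineno}: non-integer score: {err}")
        scores.append(dict(zip(header, values)))
        query_chars.append(tokens[1])
        expected_pos += 1
    if header is None:
        raise ValueError(f"{path}: no PSSM header line found")
    if not scores:
        raise ValueError(f"{path}: no PSSM score rows found (truncated?)")
    return PSSM(scores=scores, query="".join(query_chars))


def delta_pssm(pssm: PSSM, site: int, from_aa: str, to_aa: str) -> int:
    """ΔPSSM of a mutation: score(to) − score(from) at the site.

    Positive values mean the mutation moves toward the evolutionary
    consensus; antisymmetric by construction.
    """
    return pssm.score(site, to_aa) - pssm.score(site, from_aa)


@dataclass(frozen=True)
class MutantSpec:
    """A single-point mutant: wild-type residue → mutant residue at a site."""

    site: int  # 1-based
    wt_aa: str
    mut_aa: str
    sequence: str
    delta_pssm: int | None = None
    model_score: float | None = None

    @property
    def label(self) -> str:
        return f"{self.wt_aa}{self.site}{self.mut_aa}"


def enumerate_mutants(sequence: str, sites: Sequence[int]) -> list[MutantSpec]:
    """All single-point mutants at the given 1-based sites: 19 per site.

    The wild-type residue is excluded at each site, so the count is exactly
    19 × |sites| and every derived sequence differs from the wild-type at
    one position.
    """
    if len(set(sites)) != len(sites):
        raise ValueError("duplicate sites in mutation-site list")
    mutants: list[MutantSpec] = []
    for site in sites:
        if not 1 <= site <= len(sequence):
            raise IndexError(
                f"site {site} outside sequence positions 1..{len(sequence)}")
        wt = sequence[site - 1]
        if wt not in AMINO_ACIDS:
            raise ValueError(
                f"nonstandard wild-type residue {wt!r} at site {site}")
        for aa in AMINO_ACIDS:
            if aa == wt:
                continue
            mutated = sequence[:site - 1] + aa + sequence[site:]
            mutants.append(MutantSpec(site=site, wt_aa=wt, mut_aa=aa,
                                      sequence=mutated))
    return mutants


def pocket_sites(
    structure_path: str | Path,
    ligand_resname: str,
    radius: float = 12.0,
    excluded_sites: Iterable[int] = (),
) -> list[int]:
    """Residues with any heavy atom within ``radius`` Å of any ligand heavy
    atom, minus explicit exclusions; sorted by residue number.

    The ligand is selected by residue name among the heteroatom records of
    the PDB file.  Hydrogens are ignored on both sides.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(structure_path))
    model = next(structure.get_models())

    ligand_coords = []
    residue_atoms: dict[int, list[np.ndarray]] = {}
    for chain in model:
        for residue in chain:
            hetflag = residue.id[0].strip()
            heavy = [a.coord for a in residue
                     if (a.element or "").upper() != "H"]
            if hetflag and residue.resname.strip() == ligand_resname:
                ligand_coords.extend(heavy)
            elif not hetflag:
                if not heavy:
                    raise ValueError(
                        f"residue {residue.resname} {residue.id[1]} has no "
                        f"heavy atoms")
                residue_atoms.setdefault(residue.id[1], []).extend(heavy)
    if not ligand_coords:
        raise ValueError(
            f"no heavy atoms found for ligand residue {ligand_resname!r}")
    ligand = np.asarray(ligand_coords, dtype=float)
    excluded = set(excluded_sites)
    sites = []
    for resnum, coords in residue_atoms.items():
        if resnum in excluded:
            continue
        atoms = np.asarray(coords, dtype=float)
        dmin = np.sqrt(
            ((atoms[:, None, :] - ligand[None, :, :]) ** 2).sum(-1)).min()
        if dmin <= radius:
            sites.append(resnum)
    return sorted(sites)


@dataclass
class CandidateEnzyme:
    """A mined homolog with predicted kinetics and its ranking score."""

    id: str
    sequence: str
    length: int
    length_diff: int
    kcat_pred: float
    km_pred: float

    @property
    def rank_score(self) -> float:
        """Efficiency proxy: predicted log10 kcat − log10 Km."""
        return self.kcat_pred - self.km_pred


def mine_homologs(
    reference_seq: str,
    candidates: Mapping[str, str],
    predict_kcat: Callable[[str], float],
    predict_km: Callable[[str], float],
    max_len_diff: int = 20,
    top_k: int = 150,
) -> list[CandidateEnzyme]:
    """Length-filter and rank candidate homologs of a reference enzyme.

    Candidates whose length differs from the reference by *strictly more*
    than ``max_len_diff`` residues are removed (a difference of exactly
    ``max_len_diff`` is kept); survivors are ranked by predicted
    log10 kcat − log10 Km descending and truncated to ``top_k``.
    ``predict_kcat`` / ``predict_km`` map a sequence to its predicted
    log10 parameter (typically a trained model behind a featurizer with
    the target substrate fixed).
    """
    ref_len = len(reference_seq)
    kept: list[CandidateEnzyme] = []
    for cid, seq in candidates.items():
        diff = abs(len(seq) - ref_len)
        if diff > max_len_diff:
            continue
        kept.append(CandidateEnzyme(
            id=cid, sequence=seq, length=len(seq), length_diff=diff,
            kcat_pred=float(predict_kcat(seq)),
            km_pred=float(predict_km(seq)),
        ))
    if not kept:
        import warnings

        warnings.warn("no candidates survive the length filter")
        return []
    kept.sort(key=lambda c: (-c.rank_score, c.id))
    return kept[:top_k]


def screen_mutants(
    mutants: Sequence[MutantSpec],
    score_fn: Callable[[str], float],
    pssm: PSSM,
    top_fraction: float = 0.5,
    delta_min: int = 7,
) -> pd.DataFrame:
    """Model-score + ΔPSSM screen of enumerated single-point mutants.

    First the top ⌈top_fraction·M⌉ mutants by predicted log10(kcat/Km) are
    retained; of those, only mutants with ΔPSSM *strictly greater* than
    ``delta_min`` are proposed.  The returned table lists every mutant with
    both scores and its kept/dropped reason, sorted by model score
    descending.
    """
    scored = []
    for m in mutants:
        if m.site > pssm.length:
            raise ValueError(
                f"mutant site {m.site} beyond PSSM length {pssm.length}")
        score = m.model_score if m.model_score is not None \
            else float(score_fn(m.sequence))
        dp = delta_pssm(pssm, m.site, m.wt_aa, m.mut_aa)
        scored.append(replace(m, model_score=score, delta_pssm=dp))
    scored.sort(key=lambda m: (-m.model_score, m.site, m.mut_aa))
    n_top = math.ceil(top_fraction * len(scored))
    rows = []
    for rank, m in enumerate(scored):
        in_top = rank < n_top
        if not in_top:
            status, reason = "dropped", "bottom half by model score"
        elif m.delta_pssm <= delta_min:
            status, reason = "dropped", f"ΔPSSM {m.delta_pssm} ≤ {delta_min}"
        else:
            status, reason = "kept", ""
        rows.append({
            "mutant": m.label, "site": m.site, "wt_aa": m.wt_aa,
            "mut_aa": m.mut_aa, "model_score": m.model_score,
            "delta_pssm": m.delta_pssm, "status": status, "reason": reason,
        })
    return pd.DataFrame(rows)
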