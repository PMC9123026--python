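"""Building codon- and structure-annotated per-residue protein records.

The pipeline goes from raw inputs to pooled per-codon dihedral samples:

1. backbone (phi, psi) dihedrals per chain residue from structure files
   (mmCIF/PDB), with chain breaks treated as termini;
2. redundancy filtering of the reference sequences by farthest-first
   traversal on length-normalized alignment scores, capping pairwise
   similarity at tau (default 0.7);
3. aggregation of chains mapping to the same reference sequence position:
   dihedrals are combined with the torus mean, while codon and secondary
   structure must be unanimous across chains or the annotation is dropped;
4. extraction of per-(codon, secondary structure) observation pools,
   restricted to the extended-strand (E) and alpha-helix (H) DSSP classes.

Every exclusion is counted in a run report so the pipeline is lossless in
count: input residues = retained + sum of exclusion reasons.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import Align

from .genetics import AMBIGUOUS, UNASSIGNED
from .inference import CodonSample
from .torus import DegenerateMeanError, torus_mean, wrap_angle

__all__ = [
    "ResidueObservation",
    "ProteinRecord",
    "SimilarityMatrix",
    "compute_backbone_dihedrals",
    "read_structure_backbone",
    "parse_dssp",
    "parse_ss_table",
    "normalized_similarity",
    "fps_filter",
    "aggregate_records",
    "extract_codon_samples",
    "write_records",
    "read_records",
]

logger = logging.getLogger(__name__)

CHAIN_BREAK_DISTANCE = 2.5  # Angstrom; C(i)-N(i+1) beyond this ends a segment


@dataclass
class ResidueObservation:
    """One residue of one experimental chain, mapped to a reference position."""

    chain_id: str
    accession: str
    accession_index: int
    phi: float  # degrees or NaN when undefined
    psi: float
    ss_label: str | None
    codon: str  # trinucleotide, AMBIGUOUS or UNASSIGNED


@dataclass
class ProteinRecord:
    """Aggregated per-residue table for one reference accession."""

    accession: str
    residues: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: accession_index, phi, psi, codon, ss, n_chains


# ---------------------------------------------------------------------------
# dihedral geometry


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees for four points (IUPAC convention)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def compute_backbone_dihedrals(backbone_atoms) -> np.ndarray:
    """Per-residue (phi, psi) from ordered N/CA/C coordinates.

    ``backbone_atoms`` is an (n_residues, 3, 3) array of N, CA, C positions
    in Angstrom; missing atoms are NaN.  phi_i uses (C_{i-1}, N_i, CA_i,
    C_i) and psi_i uses (N_i, CA_i, C_i, N_{i+1}); the first residue has no
    phi and the last no psi.  A C(i)-N(i+1) distance above 2.5 A is a chain
    break and both dihedrals across it are undefined.  Undefined entries
    are NaN, never exceptions.
    """
    atoms = np.asarray(backbone_atoms, dtype=float)
    if atoms.ndim != 3 or atoms.shape[1:] != (3, 3):
        raise ValueError("expected (n_residues, 3, 3) N/CA/C coordinates")
    n = len(atoms)
    out = np.full((n, 2), np.nan)
    N, CA, C = atoms[:, 0], atoms[:, 1], atoms[:, 2]
    # peptide bond intact between i and i+1?
    linked = np.zeros(max(n - 1, 0), dtype=bool)
    for i in range(n - 1):
        if np.all(np.isfinite(C[i])) and np.all(np.isfinite(N[i + 1])):
            linked[i] = np.linalg.norm(N[i + 1] - C[i]) <= CHAIN_BREAK_DISTANCE
    for i in range(n):
        if i > 0 and linked[i - 1]:
            quad = (C[i - 1], N[i], CA[i], C[i])
            if all(np.all(np.isfinite(p)) for p in quad):
                out[i, 0] = _dihedral(*[np.asarray(p) for p in quad])
        if i < n - 1 and linked[i]:
            quad = (N[i], CA[i], C[i], N[i + 1])
            if all(np.all(np.isfinite(p)) for p in quad):
                out[i, 1] = _dihedral(*[np.asarray(p) for p in quad])
    return out


def read_structure_backbone(path):
    """Read N/CA/C coordinates and sequences from an mmCIF or PDB file.

    Returns a dict chain_name -> (sequence, coords) with ``sequence`` the
    one-letter amino-acid string and ``coords`` an (n, 3, 3) array (NaN for
    missing atoms).  For duplicated atoms (altlocs) the highest-occupancy
    conformer is taken.  Only amino-acid residues are considered.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.setup_entities()
    chains = {}
    for chain in st[0]:
        seq = []
        coords = []
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is None or not info.is_amino_acid():
                continue
            one = info.one_letter_code.upper()
            xyz = np.full((3, 3), np.nan)
            for k, name in enumerate(("N", "CA", "C")):
                best = None
                for atom in res:
                    if atom.name == name and (best is None
                                              or atom.occ > best.occ):
                        best = atom
                if best is not None:
                    xyz[k] = (best.pos.x, best.pos.y, best.pos.z)
            seq.append(one)
            coords.append(xyz)
        if seq:
            chains[chain.name] = ("".join(seq), np.array(coords))
    return chains


# ---------------------------------------------------------------------------
# secondary structure annotations


def parse_dssp(path_or_text) -> dict[tuple[str, int], str]:
    """Parse a classic DSSP output file into (chain, residue_number) -> label.

    Residues without an assigned class get the coil label 'C'; chain-break
    marker lines ('!') are skipped.
    """
    text = path_or_text
    if isinstance(text, (str, Path)) and Path(str(text)).exists():
        text = Path(text).read_text()
    labels: dict[tuple[str, int], str] = {}
    in_body = False
    for line in str(text).splitlines():
        if line.lstrip().startswith("#  RESIDUE"):
            in_body = True
            continue
        if not in_body or len(line) < 17:
            continue
        if line[13] == "!":
            continue
        resnum = line[5:10].strip()
        chain = line[11].strip()
        ss = line[16].strip() or "C"
        if resnum:
            labels[(chain, int(resnum))] = ss
    return labels


def parse_ss_table(path) -> dict[tuple[str, int], str]:
    """Parse a 3-column tab-delimited table: chain_id, residue_index, label."""
    labels = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        chain, idx, lab = line.split("\t")
        labels[(chain, int(idx))] = lab
    return labels


# ---------------------------------------------------------------------------
# redundancy filtering


@dataclass
class SimilarityMatrix:
    ids: list
    s_tilde: np.ndarray


def normalized_similarity(sequences, ids=None) -> SimilarityMatrix:
    """Length-normalized pairwise alignment similarity.

    The raw score s_ij is the optimal alignment score with match score 1
    and all penalties zero — equal to the longest-common-subsequence
    length, with s_ii the sequence length — and the normalized score is
    s_ij / sqrt(s_ii * s_jj), so the diagonal is exactly 1 and every entry
    lies in [0, 1].
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences")
    if any(len(s) == 0 for s in sequences):
        raise ValueError("empty sequence")
    ids = list(ids) if ids is not None else list(range(len(sequences)))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    n = len(sequences)
    s = np.zeros((n, n))
    for i in range(n):
        s[i, i] = len(sequences[i])
        for j in range(i + 1, n):
            s[i, j] = s[j, i] = aligner.score(sequences[i], sequences[j])
    s_tilde = s / np.sqrt(np.outer(np.diag(s), np.diag(s)))
    return SimilarityMatrix(ids, s_tilde)


def fps_filter(sim: SimilarityMatrix, tau: float = 0.7,
               start_index: int = 0) -> list:
    """Farthest-first traversal capping pairwise similarity at tau.

    Starting from ``start_index``, each step selects the unselected
    sequence whose greatest similarity S_k(j) to the selected set is lowest
    (ties broken by lowest index); the traversal stops when the selected
    sequence's S_k(j) exceeds tau, and that sequence is not retained.  The
    output set has max pairwise normalized similarity <= tau.
    """
    n = len(sim.ids)
    if n == 0:
        return []
    selected = [start_index]
    max_sim = sim.s_tilde[start_index].copy()
    remaining = set(range(n)) - {start_index}
    while remaining:
        j = min(remaining, key=lambda k: (max_sim[k], k))
        if max_sim[j] > tau:
            break
        selected.append(j)
        remaining.discard(j)
        max_sim = np.maximum(max_sim, sim.s_tilde[j])
    return [sim.ids[i] for i in selected]


# ---------------------------------------------------------------------------
# aggregation and sample extraction


def aggregate_records(observations) -> tuple[list[ProteinRecord], Counter]:
    """Aggregate chain-level residues into one record per accession.

    Per (accession, accession_index): dihedrals are the torus mean over
    chains with both angles defined; the codon is retained only when all
    contributing chains agree on a single unambiguous codon; the secondary
    structure label is retained only when unanimous.  Dropped annotations
    are replaced by NaN / AMBIGUOUS / None and counted in the report.
    """
    grouped: dict[str, dict[int, list[ResidueObservation]]] = defaultdict(
        lambda: defaultdict(list))
    for obs in observations:
        grouped[obs.accession][obs.accession_index].append(obs)

    report: Counter = Counter()
    records = []
    for accession in sorted(grouped):
        rows = []
        for idx in sorted(grouped[accession]):
            group = grouped[accession][idx]
            report["input_observations"] += len(group)
            defined = [(o.phi, o.psi) for o in group
                       if np.isfinite(o.phi) and np.isfinite(o.psi)]
            if defined:
                try:
                    phi, psi = torus_mean(defined)
                except DegenerateMeanError:
                    phi = psi = np.nan
                    report["degenerate_mean"] += 1
            else:
                phi = psi = np.nan
                report["no_defined_dihedral"] += 1

            codons = {o.codon for o in group}
            if AMBIGUOUS in codons or len(codons - {UNASSIGNED}) > 1:
                codon = AMBIGUOUS
                report["codon_conflict"] += 1
            elif codons == {UNASSIGNED}:
                codon = UNASSIGNED
                report["codon_unassigned"] += 1
            else:
                (codon,) = codons - {UNASSIGNED}
                if UNASSIGNED in codons:
                    report["codon_partial_agreement"] += 1

            ss_set = {o.ss_label for o in group}
            ss = ss_set.pop() if len(ss_set) == 1 else None
            if ss is None:
                report["ss_conflict"] += 1

            rows.append({
                "accession_index": idx, "phi": phi, "psi": psi,
                "codon": codon, "ss": ss if ss is not None else "",
                "n_chains": len(group),
            })
        records.append(ProteinRecord(accession, pd.DataFrame(rows)))
    return records, report


def extract_codon_samples(records, ss_classes=("E", "H")) -> dict:
    """Pool (phi, psi) observations per (codon, secondary structure).

    Only residues with both dihedrals defined, an unambiguous assigned
    codon, and a secondary-structure label in ``ss_classes`` (default: the
    extended-strand and alpha-helix classes) contribute.  Returns a dict
    (codon, ss) -> CodonSample.
    """
    pools: dict[tuple[str, str], list] = defaultdict(list)
    for rec in records:
        for row in rec.residues.itertuples():
            if not (np.isfinite(row.phi) and np.isfinite(row.psi)):
                continue
            if row.codon in (AMBIGUOUS, UNASSIGNED) or len(row.codon) != 3:
                continue
            if row.ss not in ss_classes:
                continue
            pools[(row.codon, row.ss)].append((row.phi, row.psi))
    return {
        key: CodonSample(key[0], key[1], np.array(obs))
        for key, obs in sorted(pools.items())
    }


def write_records(records, path, header_lines=()) -> None:
    """Serialize aggregated records to a tab-delimited file."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        fh.write("accession\taccession_index\tphi\tpsi\tcodon\tss\tn_chains\n")
        for rec in records:
            for row in rec.residues.itertuples():
                fh.write(
                    f"{rec.accession}\t{row.accession_index}\t{row.phi!r}\t"
                    f"{row.psi!r}\t{row.codon}\t{row.ss}\t{row.n_chains}\n"
                )


def read_records(path) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"codon": str, "ss": str}, keep_default_na=False,
                     na_values=["nan"])
    records = []
    for accession, sub in df.groupby("accession", sort=True):
        sub = sub.drop(columns=["accession"]).reset_index(drop=True)
        records.append(ProteinRecord(str(accession), sub))
    return records
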