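"""Genetic-code bookkeeping and codon assignment to structure residues.

Structure databases rarely record the exact coding sequence a protein was
expressed from, so codons are re-assigned: every candidate coding sequence
(e.g. the nucleotide records cross-referenced from the protein's sequence
database entry) is translated and globally aligned to the structure chain's
amino-acid sequence, and the codon aligned to each residue is collected.
A residue keeps its codon only when all candidate sequences agree; distinct
variants make it AMBIGUOUS and it is excluded downstream; an alignment gap
leaves it UNASSIGNED.  A codon aligned against a mismatched amino acid is
not trusted and contributes nothing (mismatch guard).

Alignment uses the Gotoh global algorithm with BLOSUM80, gap opening -10
and gap extension -0.5.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

__all__ = [
    "AMBIGUOUS",
    "UNASSIGNED",
    "GeneticCode",
    "CodonAssignment",
    "TranslationError",
    "translate",
    "enumerate_synonymous_pairs",
    "global_align",
    "assign_codons",
]

logger = logging.getLogger(__name__)

AMBIGUOUS = "AMBIGUOUS"
UNASSIGNED = "UNASSIGNED"

_NUCLEOTIDES = set("ACGT")


class TranslationError(ValueError):
    pass


class GeneticCode:
    """A codon -> amino-acid table (standard code by default).

    ``table_id`` is an NCBI translation-table number.  The standard table
    has 61 sense codons mapping to 20 amino acids.
    """

    def __init__(self, table_id: int = 1):
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        self.table_id = table_id
        self.forward: dict[str, str] = dict(tbl.forward_table)
        self.stop_codons = set(tbl.stop_codons)

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.forward)

    def synonymous_groups(self) -> dict[str, list[str]]:
        """Amino acid -> sorted list of its codons."""
        groups: dict[str, list[str]] = {}
        for codon, aa in self.forward.items():
            groups.setdefault(aa, []).append(codon)
        return {aa: sorted(cs) for aa, cs in groups.items()}


@dataclass(frozen=True)
class CodonAssignment:
    residue_index: int
    codon: str  # a trinucleotide, AMBIGUOUS, or UNASSIGNED


def translate(nt_sequence: str, code: GeneticCode | None = None) -> str:
    """Translate a coding sequence, trimming a terminal stop codon.

    Raises TranslationError on a length not divisible by 3, a non-ACGT
    symbol, or an internal stop codon (reported with its position).
    """
    code = code or GeneticCode()
    seq = nt_sequence.upper()
    bad = set(seq) - _NUCLEOTIDES
    if bad:
        raise TranslationError(f"non-ACGT symbols in sequence: {sorted(bad)}")
    if len(seq) % 3 != 0:
        raise TranslationError(f"length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in code.stop_codons:
        codons = codons[:-1]
    out = []
    for i, codon in enumerate(codons):
        if codon in code.stop_codons:
            raise TranslationError(f"internal stop codon {codon} at codon {i}")
        out.append(code.forward[codon])
    return "".join(out)


def enumerate_synonymous_pairs(
    code: GeneticCode | None = None, include_self: bool = False
) -> dict[str, list[tuple[str, str]]]:
    """Unordered codon pairs per amino acid; 87 for the standard code.

    With ``include_self`` the 61 (c, c) control pairs are included as well.
    """
    code = code or GeneticCode()
    out: dict[str, list[tuple[str, str]]] = {}
    for aa, codons in sorted(code.synonymous_groups().items()):
        pairs: list[tuple[str, str]] = []
        if include_self:
            pairs.extend((c, c) for c in codons)
        pairs.extend(itertools.combinations(codons, 2))
        out[aa] = pairs
    return out


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    pairs: tuple  # aligned (index_a, index_b) residue pairs


def global_align(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM80",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> AlignmentResult:
    """Gotoh global alignment of two amino-acid strings under affine gaps.

    Terminal gaps are penalized like internal ones.  Returns the optimal
    score and the aligned index pairs of a deterministic optimal traceback.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix_name, gap_open, gap_extend)
    alphabet = set(str(aligner.substitution_matrix.alphabet))
    bad = (set(a) | set(b)) - alphabet
    if bad:
        raise ValueError(f"symbols absent from {matrix_name}: {sorted(bad)}")
    aln = aligner.align(a, b)[0]
    pairs = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        pairs.extend(zip(range(a0, a1), range(b0, b1)))
    return AlignmentResult(float(aln.score), tuple(pairs))


def assign_codons(
    chain_sequence: str,
    coding_sequences,
    code: GeneticCode | None = None,
) -> list[CodonAssignment]:
    """Assign one codon per chain residue from candidate coding sequences.

    Each coding sequence is translated (untranslatable ones are skipped
    with a warning) and globally aligned to the chain sequence; codons
    aligned to a residue with a matching amino acid are collected.  A
    singleton codon set is assigned; distinct variants yield AMBIGUOUS;
    an empty set yields UNASSIGNED.
    """
    code = code or GeneticCode()
    assigned: dict[int, set[str]] = {i: set() for i in range(len(chain_sequence))}
    usable = 0
    for nt in coding_sequences:
        try:
            protein = translate(nt, code)
        except TranslationError as err:
            logger.warning("skipping untranslatable coding sequence: %s", err)
            continue
        if not protein:
            logger.warning("skipping empty translation")
            continue
        usable += 1
        aln = global_align(chain_sequence, protein)
        nt = nt.upper()
        for chain_i, prot_j in aln.pairs:
            if chain_sequence[chain_i] != protein[prot_j]:
                continue  # substitution in the alignment: do not trust the codon
            assigned[chain_i].add(nt[3 * prot_j:3 * prot_j + 3])
    if usable == 0:
        raise ValueError("no usable coding sequence")
    out = []
    for i in range(len(chain_sequence)):
        codons = assigned[i]
        if len(codons) == 1:
            codon = next(iter(codons))
            # mismatch guard: an assigned codon must translate to the residue
            if code.forward.get(codon) != chain_sequence[i]:
                codon = UNASSIGNED
        elif len(codons) > 1:
            codon = AMBIGUOUS
        else:
            codon = UNASSIGNED
        out.append(CodonAssignment(i, codon))
    return out
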