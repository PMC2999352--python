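"""Knowledge-based contact scoring matrices and substitution matrices.

Four 20x20 log-odds matrices are derived from the contact pairs of a training
library of dimer interfaces: sidechain–sidechain and sidechain–backbone van
der Waals matrices (all contacts) and the corresponding special-bond matrices
(contacts forming a hydrogen bond, salt bridge or disulfide).  Each entry is

    S_ij = ln(q_ij / e_ij)

with q_ij the observed probability of the residue pair (i, j) at interfaces
and e_ij = p_i * p_j the product of the interface residue marginals.
Sidechain–sidechain tables are symmetric; sidechain–backbone tables index the
sidechain-contributing residue on rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import AA_ALPHABET
from .structures import TemplateInterface

MATRIX_CLASSES = ("ss_vdw", "sb_vdw", "ss_special", "sb_special")


class EmptyLibraryError(ValueError):
    """Raised when a count table or training library has no contacts."""


@dataclass
class PairCountTable:
    """Raw residue-pair contact counts per interaction class.

    Counts are stored on ordered (row, col) cells: a symmetric-class contact
    (i, j) increments both (i, j) and (j, i) when i != j, so that observed
    probabilities and marginals are consistent over the full table.
    """

    alphabet: str = AA_ALPHABET
    counts: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.alphabet)
        for cls in MATRIX_CLASSES:
            self.counts.setdefault(cls, np.zeros((n, n), dtype=float))

    def index(self, aa: str) -> int:
        return self.alphabet.index(aa)

    def add_symmetric(self, cls: str, aa_i: str, aa_j: str, weight: float = 1.0):
        i, j = self.index(aa_i), self.index(aa_j)
        self.counts[cls][i, j] += weight
        if i != j:
            self.counts[cls][j, i] += weight

    def add_directional(self, cls: str, aa_side: str, aa_back: str, weight: float = 1.0):
        self.counts[cls][self.index(aa_side), self.index(aa_back)] += weight

    def observed(self, cls: str, pseudocount: float = 0.0) -> np.ndarray:
        c = self.counts[cls] + pseudocount
        total = c.sum()
        if total == 0:
            raise EmptyLibraryError(f"no counts for class {cls!r}")
        return c / total

    def interface_background(self) -> np.ndarray:
        """Residue frequencies over all van der Waals interface contacts."""
        c = self.counts["ss_vdw"] + self.counts["sb_vdw"]
        marg = c.sum(axis=1) + c.sum(axis=0)
        if marg.sum() == 0:
            raise EmptyLibraryError("empty count table")
        return marg / marg.sum()


@dataclass
class PairScoringMatrix:
    cls: str
    scores: np.ndarray
    alphabet: str = AA_ALPHABET
    symmetric: bool = True

    def lookup(self, aa_row: str, aa_col: str) -> float:
        return float(
            self.scores[self.alphabet.index(aa_row), self.alphabet.index(aa_col)]
        )

    def to_tsv(self, pseudocount: float | None = None) -> str:
        lines = [f"# class\t{self.cls}"]
        if pseudocount is not None:
            lines.append(f"# pseudocount\t{pseudocount}")
        lines.append("# log_base\te")
        lines.append("\t".join([""] + list(self.alphabet)))
        for i, aa in enumerate(self.alphabet):
            row = "\t".join(f"{v:.6g}" for v in self.scores[i])
            lines.append(f"{aa}\t{row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PairScoringMatrix":
        meta = {}
        rows = []
        alphabet = None
        for line in text.splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("\t")
                meta[key] = val
                continue
            fields = line.split("\t")
            if alphabet is None:
                alphabet = "".join(fields[1:])
                continue
            rows.append([float(v) for v in fields[1:]])
        scores = np.array(rows)
        mat_cls = meta.get("class", "ss_vdw")
        return cls(cls=mat_cls, scores=scores, alphabet=alphabet,
                   symmetric=mat_cls.startswith("ss"))


class SubstitutionMatrix:
    """A residue substitution matrix (BLOSUM62 by default) with K(x, y) lookups."""

    def __init__(self, array) -> None:
        self._array = array
        self.alphabet = str(array.alphabet)

    def K(self, x: str, y: str) -> float:
        x, y = x.upper(), y.upper()
        if x not in self.alphabet or y not in self.alphabet:
            raise KeyError(f"unknown residue code {x!r}/{y!r}")
        return float(self._array[x, y])

    def diagonal(self, x: str) -> float:
        return self.K(x, x)


def load_substitution_matrix(name: str = "BLOSUM62") -> SubstitutionMatrix:
    """Load a named matrix (Biopython registry) or an NCBI-layout file path."""
    from Bio.Align import substitution_matrices

    path = Path(name)
    if path.suffix or path.exists():
        array = substitution_matrices.read(str(path))
    else:
        array = substitution_matrices.load(name)
    return SubstitutionMatrix(array)


def count_pairs(library: list[TemplateInterface],
                alphabet: str = AA_ALPHABET) -> PairCountTable:
    """Accumulate per-class residue-pair counts over a template library.

    ss contacts are symmetrised; sb/bs contacts are directional with the
    sidechain residue on rows; special tables are incremented only for pairs
    whose template special bond is set.
    """
    if not library:
        raise EmptyLibraryError("empty training library")
    table = PairCountTable(alphabet=alphabet)
    for template in library:
        for pair in template.contact_pairs:
            special = pair.special_bond != "none"
            if "ss" in pair.classes:
                table.add_symmetric("ss_vdw", pair.aa_a, pair.aa_b)
                if special:
                    table.add_symmetric("ss_special", pair.aa_a, pair.aa_b)
            if "sb" in pair.classes:
                table.add_directional("sb_vdw", pair.aa_a, pair.aa_b)
                if special:
                    table.add_directional("sb_special", pair.aa_a, pair.aa_b)
            if "bs" in pair.classes:
                table.add_directional("sb_vdw", pair.aa_b, pair.aa_a)
                if special:
                    table.add_directional("sb_special", pair.aa_b, pair.aa_a)
    return table


def derive_matrix(table: PairCountTable, cls: str,
                  pseudocount: float = 0.5) -> PairScoringMatrix:
    """Log-odds matrix S_ij = ln(q_ij / e_ij) for one interaction class.

    q is the pseudocounted observed pair probability; e_ij = p_i p_j from the
    row/column marginals of q.  For special-bond classes, cells with zero raw
    count are reset to 0 after derivation (the bond chemistry cannot form),
    matching the zero-for-impossible-pairs convention.
    """
    raw = table.counts[cls]
    if raw.sum() == 0:
        raise EmptyLibraryError(f"all-zero count table for class {cls!r}")
    q = table.observed(cls, pseudocount=pseudocount)
    p_row = q.sum(axis=1)
    p_col = q.sum(axis=0)
    e = np.outer(p_row, p_col)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(q > 0, np.log(np.where(q > 0, q, 1.0) / e), -np.inf)
    if cls.endswith("special"):
        scores = np.where(raw > 0, scores, 0.0)
    return PairScoringMatrix(
        cls=cls, scores=scores, alphabet=table.alphabet,
        symmetric=cls.startswith("ss"),
    )


@dataclass
class MatrixSet:
    """The four knowledge-based contact matrices plus a substitution matrix."""

    ss_vdw: PairScoringMatrix
    sb_vdw: PairScoringMatrix
    ss_special: PairScoringMatrix
    sb_special: PairScoringMatrix
    substitution: SubstitutionMatrix

    def matrix(self, cls: str) -> PairScoringMatrix:
        try:
            return getattr(self, cls)
        except AttributeError:
            raise KeyError(f"unknown matrix class {cls!r}") from None


def derive_matrix_set(
    library: list[TemplateInterface],
    pseudocount: float = 0.5,
    substitution: SubstitutionMatrix | None = None,
) -> tuple[MatrixSet, PairCountTable]:
    """Derive all four matrices from a training library (vdW classes use the
    pseudocount; special classes use raw counts with the zero-out rule).

    A class with no observed contacts at all (e.g. a library without any
    special bonds) yields an all-zero matrix: no evidence, no preference.
    """
    table = count_pairs(library)

    def derive_or_zero(cls: str, pc: float) -> PairScoringMatrix:
        if table.counts[cls].sum() == 0:
            n = len(table.alphabet)
            return PairScoringMatrix(
                cls=cls, scores=np.zeros((n, n)), alphabet=table.alphabet,
                symmetric=cls.startswith("ss"),
            )
        return derive_matrix(table, cls, pseudocount=pc)

    ms = MatrixSet(
        ss_vdw=derive_or_zero("ss_vdw", pseudocount),
        sb_vdw=derive_or_zero("sb_vdw", pseudocount),
        ss_special=derive_or_zero("ss_special", 0.0),
        sb_special=derive_or_zero("sb_special", 0.0),
        substitution=substitution or load_substitution_matrix("BLOSUM62"),
    )
    return ms, table
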