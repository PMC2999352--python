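"""Dimer structure parsing, inter-chain contact extraction and template library.

A template is a solved heterodimer whose inter-chain interface — every residue
pair with heavy atoms within 4.5 Å — defines the contact topology on which
candidate protein pairs are scored.  This module parses PDB-format text into a
light-weight :class:`Structure`, extracts :class:`ContactPair` lists with
interaction classes (sidechain/backbone) and special-bond annotations
(hydrogen bond, salt bridge, disulfide), and validates/deduplicates template
libraries under the published filters (chains >= 30 residues, >= 5 contact
residues per side, > 25 contact pairs, < 98 % sequence identity between
retained templates).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .constants import (
    BACKBONE_ATOMS,
    CHARGED_N_ATOMS,
    CHARGED_O_ATOMS,
    NONSTANDARD_PARENT,
    THREE_TO_ONE,
)

logger = logging.getLogger(__name__)

# interaction classes for a contact pair:
#   ss = sidechain–sidechain, sb = sidechain(A)–backbone(B),
#   bs = backbone(A)–sidechain(B), bb = backbone-only contact (not scored)
CONTACT_CLASSES = ("ss", "sb", "bs", "bb")

SPECIAL_BONDS = ("none", "hydrogen_bond", "salt_bridge", "disulfide")


class PDBParseError(ValueError):
    """Raised for malformed or empty PDB input; names the offending line."""


class ChainLookupError(KeyError):
    """Raised when a requested chain id is absent from a structure."""


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coord: tuple[float, float, float]


@dataclass
class Residue:
    chain_id: str
    position: int          # 1-based index in the chain's extracted sequence
    resname: str           # original 3-letter code
    aa: str                # mapped 1-letter code, 'X' if unmapped
    standard: bool
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    id: str
    chains: dict[str, Chain] = field(default_factory=dict)

    def chain(self, chain_id: str) -> Chain:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise ChainLookupError(
                f"chain {chain_id!r} not in structure {self.id!r} "
                f"(has {sorted(self.chains)})"
            ) from None

    def residue(self, chain_id: str, position: int) -> Residue:
        return self.chain(chain_id).residues[position - 1]


@dataclass(frozen=True)
class ContactPair:
    """One inter-chain residue pair in contact (any heavy atoms <= cutoff)."""

    pos_a: int
    pos_b: int
    aa_a: str
    aa_b: str
    classes: frozenset[str]
    min_distance: float
    special_bond: str = "none"


@dataclass
class TemplateInterface:
    template_id: str
    chain_a_id: str
    chain_b_id: str
    chain_a_seq: str
    chain_b_seq: str
    contact_residues_a: tuple[int, ...]
    contact_residues_b: tuple[int, ...]
    contact_pairs: list[ContactPair]

    @property
    def cp(self) -> int:
        """Number of contact residue pairs (the CP of the scoring function)."""
        return len(self.contact_pairs)

    def to_dict(self) -> dict:
        return {
            "template_id": self.template_id,
            "chain_a_id": self.chain_a_id,
            "chain_b_id": self.chain_b_id,
            "chain_a_seq": self.chain_a_seq,
            "chain_b_seq": self.chain_b_seq,
            "contact_residues_a": list(self.contact_residues_a),
            "contact_residues_b": list(self.contact_residues_b),
            "contact_pairs": [
                {
                    "pos_a": p.pos_a,
                    "pos_b": p.pos_b,
                    "aa_a": p.aa_a,
                    "aa_b": p.aa_b,
                    "classes": sorted(p.classes),
                    "special_bond": p.special_bond,
                    "min_distance": round(p.min_distance, 4),
                }
                for p in self.contact_pairs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TemplateInterface":
        pairs = [
            ContactPair(
                pos_a=p["pos_a"],
                pos_b=p["pos_b"],
                aa_a=p["aa_a"],
                aa_b=p["aa_b"],
                classes=frozenset(p["classes"]),
                min_distance=p["min_distance"],
                special_bond=p["special_bond"],
            )
            for p in d["contact_pairs"]
        ]
        return cls(
            template_id=d["template_id"],
            chain_a_id=d["chain_a_id"],
            chain_b_id=d["chain_b_id"],
            chain_a_seq=d["chain_a_seq"],
            chain_b_seq=d["chain_b_seq"],
            contact_residues_a=tuple(d["contact_residues_a"]),
            contact_residues_b=tuple(d["contact_residues_b"]),
            contact_pairs=pairs,
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TemplateInterface":
        return cls.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# PDB parsing


def _map_resname(resname: str) -> tuple[str, bool]:
    resname = resname.strip().upper()
    if resname in THREE_TO_ONE:
        return THREE_TO_ONE[resname], True
    if resname in NONSTANDARD_PARENT:
        return THREE_TO_ONE[NONSTANDARD_PARENT[resname]], True
    return "X", False


def _guess_element(name: str) -> str:
    stripped = name.strip()
    # two-letter elements in protein context
    if stripped[:2].upper() in {"SE", "FE", "ZN", "MG", "MN", "CL", "BR"}:
        return stripped[:2].capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def parse_structure(pdb_text: str, structure_id: str = "structure") -> Structure:
    """Parse PDB-format text into a :class:`Structure` of heavy atoms.

    Hydrogens (and deuterium) are dropped; alternate locations are resolved to
    the highest-occupancy conformer (ties: first listed); residues are keyed by
    (chain, resSeq, iCode) with insertion codes collapsed in order of
    appearance, so positions are 1-based indices into the extracted sequence.
    Only the first MODEL of a multi-model file is read.
    """
    # (chain) -> ordered {(resseq, icode) -> {"resname":..., "atoms": {name: [(occ, order, Atom)]}}}
    chains: dict[str, dict] = {}
    chain_order: list[str] = []
    n_atoms = 0
    in_model = 0
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        rec = line[:6]
        if rec.startswith("MODEL"):
            in_model += 1
            if in_model > 1:
                break
            continue
        if rec.startswith("ENDMDL"):
            break
        if not (rec.startswith("ATOM") or rec.startswith("HETATM")):
            continue
        if len(line) < 54:
            raise PDBParseError(f"line {lineno}: ATOM record too short: {line!r}")
        try:
            name = line[12:16].strip()
            altloc = line[16]
            resname = line[17:20].strip()
            chain_id = line[21].strip() or " "
            resseq = int(line[22:26])
            icode = line[26]
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: malformed ATOM record: {exc}") from None
        element = line[76:78].strip().capitalize() if len(line) >= 78 else ""
        if not element:
            element = _guess_element(name)
        if element in ("H", "D"):
            continue
        aa, standard = _map_resname(resname)
        if rec.startswith("HETATM") and resname not in NONSTANDARD_PARENT \
                and resname not in THREE_TO_ONE:
            continue  # waters, ligands
        if chain_id not in chains:
            chains[chain_id] = {}
            chain_order.append(chain_id)
        reskey = (resseq, icode)
        cres = chains[chain_id]
        if reskey not in cres:
            cres[reskey] = {"resname": resname, "aa": aa, "standard": standard,
                            "atoms": {}}
        slot = cres[reskey]["atoms"].setdefault(name, [])
        slot.append((occupancy, len(slot), altloc, Atom(name, element, (x, y, z))))
        n_atoms += 1

    if n_atoms == 0:
        raise PDBParseError("no protein chains: input contains no usable ATOM records")

    structure = Structure(id=structure_id)
    for chain_id in chain_order:
        chain = Chain(id=chain_id)
        for pos, (reskey, rdata) in enumerate(chains[chain_id].items(), start=1):
            atoms = []
            for name, variants in rdata["atoms"].items():
                # highest occupancy wins; tie -> first listed (stable order key)
                best = max(variants, key=lambda v: (v[0], -v[1]))
                atoms.append(best[3])
            if not rdata["standard"]:
                logger.info(
                    "structure %s chain %s residue %s: non-standard %s excluded "
                    "from contact scoring", structure_id, chain_id, reskey,
                    rdata["resname"],
                )
            chain.residues.append(
                Residue(
                    chain_id=chain_id,
                    position=pos,
                    resname=rdata["resname"],
                    aa=rdata["aa"],
                    standard=rdata["standard"],
                    atoms=atoms,
                )
            )
        structure.chains[chain_id] = chain
    return structure


# ---------------------------------------------------------------------------
# contact extraction


def _atom_arrays(chain: Chain) -> tuple[np.ndarray, list[tuple[int, Atom]]]:
    atoms = [(res.position, atom) for res in chain.residues for atom in res.atoms]
    coords = np.array([a.coord for _, a in atoms], dtype=float).reshape(len(atoms), 3)
    return coords, atoms


def _atom_class(name: str) -> str:
    return "b" if name in BACKBONE_ATOMS else "s"


def extract_contacts(
    s: Structure, chain_a: str, chain_b: str, cutoff: float = 4.5
) -> list[ContactPair]:
    """All inter-chain residue pairs with any heavy-atom distance <= ``cutoff``.

    Interaction classes are assigned per contributing atom pair: a sidechain
    atom is any heavy atom outside the backbone set {N, CA, C, O, OXT} (CB is
    sidechain); glycine therefore contributes backbone-only classes.  Pairs
    whose only contacts are backbone–backbone carry the internal class "bb"
    and are not scored by the pair matrices.
    """
    ca, atoms_a = _atom_arrays(s.chain(chain_a))
    cb, atoms_b = _atom_arrays(s.chain(chain_b))
    if len(atoms_a) == 0 or len(atoms_b) == 0:
        return []
    dist = cdist(ca, cb)
    ia, ib = np.nonzero(dist <= cutoff)
    found: dict[tuple[int, int], dict] = {}
    for k in range(len(ia)):
        pa, atom_a = atoms_a[ia[k]]
        pb, atom_b = atoms_b[ib[k]]
        d = float(dist[ia[k], ib[k]])
        key = (pa, pb)
        entry = found.setdefault(key, {"classes": set(), "min": math.inf})
        cls_a = _atom_class(atom_a.name)
        cls_b = _atom_class(atom_b.name)
        entry["classes"].add(
            {"ss": "ss", "sb": "sb", "bs": "bs", "bb": "bb"}[cls_a + cls_b]
        )
        entry["min"] = min(entry["min"], d)
    pairs = []
    for (pa, pb), entry in sorted(found.items()):
        res_a = s.residue(chain_a, pa)
        res_b = s.residue(chain_b, pb)
        if not (res_a.standard and res_b.standard):
            logger.info(
                "contact %s:%d – %s:%d skipped (non-standard residue)",
                chain_a, pa, chain_b, pb,
            )
            continue
        pairs.append(
            ContactPair(
                pos_a=pa,
                pos_b=pb,
                aa_a=res_a.aa,
                aa_b=res_b.aa,
                classes=frozenset(entry["classes"]),
                min_distance=entry["min"],
            )
        )
    return pairs


def _min_atomset_distance(
    res_x: Residue, res_y: Residue, names_x, names_y
) -> float:
    ax = [a.coord for a in res_x.atoms if a.name in names_x]
    ay = [a.coord for a in res_y.atoms if a.name in names_y]
    if not ax or not ay:
        return math.inf
    return float(cdist(np.array(ax), np.array(ay)).min())


def _min_element_distance(res_x: Residue, res_y: Residue, elements) -> float:
    ax = [a.coord for a in res_x.atoms if a.element in elements]
    ay = [a.coord for a in res_y.atoms if a.element in elements]
    if not ax or not ay:
        return math.inf
    return float(cdist(np.array(ax), np.array(ay)).min())


def detect_special_bonds(
    pairs: list[ContactPair],
    s: Structure,
    chain_a: str,
    chain_b: str,
    hbond_cutoff: float = 3.5,
    salt_bridge_cutoff: float = 4.0,
    disulfide_cutoff: float = 2.5,
) -> list[ContactPair]:
    """Annotate contact pairs with hydrogen bond / salt bridge / disulfide.

    Geometric criteria (precedence disulfide > salt bridge > hydrogen bond):
    disulfide — Cys SG–SG <= 2.5 Å; salt bridge — a charged sidechain N of
    Arg/Lys/His within 4.0 Å of a charged sidechain O of Asp/Glu; hydrogen
    bond — any donor/acceptor N/O atom pair across the chains <= 3.5 Å.
    """
    annotated = []
    for pair in pairs:
        res_a = s.residue(chain_a, pair.pos_a)
        res_b = s.residue(chain_b, pair.pos_b)
        bond = "none"
        if pair.aa_a == "C" and pair.aa_b == "C":
            if _min_atomset_distance(res_a, res_b, {"SG"}, {"SG"}) <= disulfide_cutoff:
                bond = "disulfide"
        if bond == "none":
            d_salt = math.inf
            if pair.aa_a in CHARGED_N_ATOMS and pair.aa_b in CHARGED_O_ATOMS:
                d_salt = _min_atomset_distance(
                    res_a, res_b, CHARGED_N_ATOMS[pair.aa_a], CHARGED_O_ATOMS[pair.aa_b]
                )
            if pair.aa_b in CHARGED_N_ATOMS and pair.aa_a in CHARGED_O_ATOMS:
                d_salt = min(
                    d_salt,
                    _min_atomset_distance(
                        res_a, res_b, CHARGED_O_ATOMS[pair.aa_a],
                        CHARGED_N_ATOMS[pair.aa_b],
                    ),
                )
            if d_salt <= salt_bridge_cutoff:
                bond = "salt_bridge"
        if bond == "none":
            if _min_element_distance(res_a, res_b, {"N", "O"}) <= hbond_cutoff:
                bond = "hydrogen_bond"
        annotated.append(replace(pair, special_bond=bond))
    return annotated


def build_template(
    s: Structure,
    chain_a: str,
    chain_b: str,
    cutoff: float = 4.5,
    hbond_cutoff: float = 3.5,
    salt_bridge_cutoff: float = 4.0,
    disulfide_cutoff: float = 2.5,
    template_id: str | None = None,
) -> TemplateInterface:
    """Extract contacts + special bonds and assemble a template interface."""
    pairs = extract_contacts(s, chain_a, chain_b, cutoff=cutoff)
    pairs = detect_special_bonds(
        pairs, s, chain_a, chain_b,
        hbond_cutoff=hbond_cutoff,
        salt_bridge_cutoff=salt_bridge_cutoff,
        disulfide_cutoff=disulfide_cutoff,
    )
    return TemplateInterface(
        template_id=template_id or f"{s.id}_{chain_a}{chain_b}",
        chain_a_id=chain_a,
        chain_b_id=chain_b,
        chain_a_seq=s.chain(chain_a).sequence,
        chain_b_seq=s.chain(chain_b).sequence,
        contact_residues_a=tuple(sorted({p.pos_a for p in pairs})),
        contact_residues_b=tuple(sorted({p.pos_b for p in pairs})),
        contact_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# template validation and deduplication


@dataclass
class ValidationResult:
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.accepted


def validate_template(
    t: TemplateInterface,
    min_chain_len: int = 30,
    min_contact_residues: int = 5,
    min_contact_pairs: int = 25,
) -> ValidationResult:
    """Apply the template-library filters; CP must strictly exceed 25."""
    reasons = []
    if len(t.chain_a_seq) < min_chain_len:
        reasons.append(f"chain A shorter than {min_chain_len} residues")
    if len(t.chain_b_seq) < min_chain_len:
        reasons.append(f"chain B shorter than {min_chain_len} residues")
    if len(t.contact_residues_a) < min_contact_residues:
        reasons.append(f"fewer than {min_contact_residues} contact residues on chain A")
    if len(t.contact_residues_b) < min_contact_residues:
        reasons.append(f"fewer than {min_contact_residues} contact residues on chain B")
    if t.cp <= min_contact_pairs:
        reasons.append(f"contact pairs {t.cp} not more than {min_contact_pairs}")
    return ValidationResult(accepted=not reasons, reasons=reasons)


def _global_identity(seq1: str, seq2: str) -> float:
    """Fraction of identical columns in a global alignment (NW, match-count)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(seq1, seq2)[0]
    matches = sum(
        a == b
        for a, b in zip(str(aln[0]), str(aln[1]))
        if a != "-" and b != "-"
    )
    return matches / max(len(seq1), len(seq2))


def deduplicate_library(
    templates: list[TemplateInterface], identity_threshold: float = 0.98
) -> list[TemplateInterface]:
    """Remove duplicate templates (> 98 % identity on both chains).

    Duplicates are clustered transitively; each cluster keeps the template
    with the largest CP (ties: lexicographically smallest template_id).
    """
    n = len(templates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = templates[i], templates[j]
            id_a = _global_identity(ti.chain_a_seq, tj.chain_a_seq)
            id_b = _global_identity(ti.chain_b_seq, tj.chain_b_seq)
            if id_a > identity_threshold and id_b > identity_threshold:
                parent[find(i)] = find(j)
    clusters: dict[int, list[TemplateInterface]] = {}
    for i, t in enumerate(templates):
        clusters.setdefault(find(i), []).append(t)
    kept = [
        max(members, key=lambda t: (t.cp, _NegStr(t.template_id)))
        for members in clusters.values()
    ]
    return sorted(kept, key=lambda t: t.template_id)


class _NegStr(str):
    """Inverts string comparison so max() prefers the lexicographically smaller id."""

    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
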