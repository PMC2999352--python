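"""Synthetic fixtures: toy dimers, homolog families, alanine-scan tables.

Every stage of the pipeline can be exercised without external downloads:

* :func:`make_toy_dimer` writes a PDB-format heterodimer whose residues sit
  on a lattice so that the planned contacts are the only heavy-atom pairs
  within the 4.5 Å cutoff, with special bonds (disulfide, salt bridge,
  hydrogen bond) placed with compliant geometry, and emits the ground-truth
  contact list alongside.
* :func:`make_homolog_family` derives species-tagged homolog FASTA families
  from a template chain at controlled identity, holding planned
  couple-conserved positions fixed.
* :func:`make_alascan_set` builds a synthetic alanine-scan ddG table from the
  model's own residue contributions plus Gaussian noise.
* :func:`calcineurin_search_rows` returns the published worked-example search
  result for the human calcineurin heterodimer query (19 candidate rows with
  Z, per-species rank and GO-similarity annotations) as structured records.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AA_ALPHABET, ONE_TO_THREE
from .matrices import MatrixSet
from .profiles import ChainProfile, _COND
from .scoring import AlaScanRecord, residue_contribution
from .structures import TemplateInterface


class FixturePlanError(ValueError):
    """Raised for geometrically or combinatorially infeasible fixture plans."""


@dataclass
class ToyDimerSpec:
    seed: int = 0
    n_contacts: int = 26
    len_a: int = 40
    len_b: int = 40
    #: map contact index (0-based) -> bond plan, one of
    #: {"disulfide", "salt_bridge", "hydrogen_bond", "hydrogen_bond_sb"}
    special_bond_plan: dict[int, str] = field(default_factory=dict)


# lattice geometry (Å): per-contact column spacing keeps cross-column atom
# pairs > 5.6 Å apart, so planned contacts are exclusive by construction
_X_SPACING = 8.0
_BACKBONE_A_Y = -1.0

#: representative sidechain atom per planned bond type: (aa_a, atom_a, y_a,
#: aa_b, atom_b, y_b, backbone_b_y)
_SPECIAL_GEOMETRY = {
    "disulfide": ("C", "SG", 3.0, "C", "SG", 5.05, 10.0),
    "salt_bridge": ("K", "NZ", 3.0, "E", "OE1", 6.0, 11.0),
    "hydrogen_bond": ("S", "OG", 3.0, "T", "OG1", 6.4, 11.0),
}

_PLAIN_CONTACT = (None, "CB", 3.0, None, "CB", 7.2, 11.8)
_FILLER_A_SIDE_Y = 0.2
_FILLER_B_SIDE_Y = 10.6
_FILLER_B_BACKBONE_Y = 11.8

# residues eligible for plain contact / filler positions (sidechain present,
# chemically inert CB representative, never triggering special-bond geometry)
_PLAIN_AA = "".join(a for a in AA_ALPHABET if a != "G")


def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resseq: int, x: float, y: float, z: float,
                   occupancy: float = 1.0, element: str | None = None) -> str:
    element = element or name[0]
    padded = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {padded:<4s} {resname:<3s} {chain}{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}  0.00          {element:>2s}"
    )


def _residue_atoms(aa: str, x: float, backbone_y: float,
                   side: tuple[str, float] | None,
                   backbone_o_y: float | None = None) -> list[tuple[str, float, float]]:
    """(atom name, x, y) for one residue: 4 backbone atoms + optional sidechain."""
    if backbone_o_y is None:
        backbone_o_y = backbone_y + (1.2 if backbone_y > 0 else -1.2)
    atoms = [
        ("N", x - 1.2, backbone_y),
        ("CA", x, backbone_y),
        ("C", x + 1.2, backbone_y),
        ("O", x + 1.2, backbone_o_y),
    ]
    if side is not None and aa != "G":
        name, y = side
        atoms.append((name, x, y))
    return atoms


def make_toy_dimer(spec: ToyDimerSpec) -> tuple[str, list[dict], str, str]:
    """Generate PDB text for a two-chain toy dimer plus ground-truth contacts.

    Contact k (0-based) pairs chain A residue k+1 with chain B residue k+1 on
    its own lattice column; remaining residues are non-contacting fillers.
    Returns (pdb_text, ground_truth, seq_a, seq_b) where ground_truth lists
    dicts with pos_a, pos_b, classes, special_bond.
    """
    if spec.n_contacts < 1:
        raise FixturePlanError("n_contacts must be >= 1")
    if spec.n_contacts > min(spec.len_a, spec.len_b):
        raise FixturePlanError(
            f"plan needs {spec.n_contacts} contacts but chains have only "
            f"{spec.len_a}/{spec.len_b} residues"
        )
    for idx, bond in spec.special_bond_plan.items():
        if idx < 0 or idx >= spec.n_contacts:
            raise FixturePlanError(f"special-bond index {idx} out of range")
        if bond not in _SPECIAL_GEOMETRY and bond != "hydrogen_bond_sb":
            raise FixturePlanError(f"unknown special-bond plan {bond!r}")

    rng = np.random.default_rng(spec.seed)
    seq_a = [str(_PLAIN_AA[i]) for i in rng.integers(0, len(_PLAIN_AA), spec.len_a)]
    seq_b = [str(_PLAIN_AA[i]) for i in rng.integers(0, len(_PLAIN_AA), spec.len_b)]

    # per-residue atom plans: chain -> position(0-based) -> list of atoms
    atoms_a: dict[int, list[tuple[str, float, float]]] = {}
    atoms_b: dict[int, list[tuple[str, float, float]]] = {}
    ground_truth = []
    for k in range(spec.n_contacts):
        x = k * _X_SPACING
        bond = spec.special_bond_plan.get(k)
        if bond == "hydrogen_bond_sb":
            # Ser OG (sidechain A) to backbone O of B at 2.9 Å
            seq_a[k] = "S"
            atoms_a[k] = _residue_atoms("S", x, _BACKBONE_A_Y, ("OG", 3.0))
            atoms_b[k] = _residue_atoms(seq_b[k], x, 7.1, ("CB", 8.3),
                                        backbone_o_y=None)
            # override O to hang toward chain A
            atoms_b[k] = [
                (name, ax, 5.9 if name == "O" else ay)
                for name, ax, ay in atoms_b[k]
            ]
            classes = {"sb"}
            special = "hydrogen_bond"
        elif bond in _SPECIAL_GEOMETRY:
            aa_a, atom_a, y_a, aa_b, atom_b, y_b, bb_y = _SPECIAL_GEOMETRY[bond]
            seq_a[k] = aa_a
            seq_b[k] = aa_b
            atoms_a[k] = _residue_atoms(aa_a, x, _BACKBONE_A_Y, (atom_a, y_a))
            atoms_b[k] = _residue_atoms(aa_b, x, bb_y, (atom_b, y_b))
            classes = {"ss"}
            special = bond
        else:
            _, atom_a, y_a, _, atom_b, y_b, bb_y = _PLAIN_CONTACT
            atoms_a[k] = _residue_atoms(seq_a[k], x, _BACKBONE_A_Y, (atom_a, y_a))
            atoms_b[k] = _residue_atoms(seq_b[k], x, bb_y, (atom_b, y_b))
            classes = {"ss"}
            special = "none"
        ground_truth.append(
            {"pos_a": k + 1, "pos_b": k + 1, "classes": classes,
             "special_bond": special}
        )
    for k in range(spec.n_contacts, spec.len_a):
        x = k * _X_SPACING
        atoms_a[k] = _residue_atoms(seq_a[k], x, _BACKBONE_A_Y,
                                    ("CB", _FILLER_A_SIDE_Y))
    for k in range(spec.n_contacts, spec.len_b):
        x = k * _X_SPACING
        atoms_b[k] = _residue_atoms(seq_b[k], x, _FILLER_B_BACKBONE_Y,
                                    ("CB", _FILLER_B_SIDE_Y))

    lines = []
    serial = 1
    for chain, seqs, atom_map in (("A", seq_a, atoms_a), ("B", seq_b, atoms_b)):
        for k, aa in enumerate(seqs):
            resname = ONE_TO_THREE[aa]
            for name, x, y in atom_map[k]:
                element = "S" if name.startswith("S") else name[0]
                lines.append(
                    _pdb_atom_line(serial, name, resname, chain, k + 1,
                                   x, y, 0.0, element=element)
                )
                serial += 1
        lines.append(f"TER   {serial:5d}      {ONE_TO_THREE[seqs[-1]]:<3s} "
                     f"{chain}{len(seqs):4d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n", ground_truth, "".join(seq_a), "".join(seq_b)


# ---------------------------------------------------------------------------
# homolog families


def _sample_substitution(wild: str, rng: np.random.Generator,
                         mode: str = "blosum") -> str:
    """Draw a replacement residue != wild type.

    ``blosum`` draws BLOSUM62-conditionally likely substitutions (keeps
    alignments unambiguous, emulates accepted point mutations); ``uniform``
    draws any other residue uniformly (disruptive, for decoy interfaces).
    """
    j = AA_ALPHABET.index(wild)
    if mode == "uniform":
        probs = np.ones(len(AA_ALPHABET))
    else:
        probs = _COND[:, j].copy()
    probs[j] = 0.0
    probs /= probs.sum()
    return AA_ALPHABET[int(rng.choice(len(AA_ALPHABET), p=probs))]


def make_homolog_family(
    template_seq: str,
    species_plan: dict[str, list[float]],
    conserved_positions=frozenset(),
    contact_positions=frozenset(),
    contact_policy: str = "free",
    substitution: str = "blosum",
    seed: int = 0,
    id_prefix: str = "HOM",
) -> str:
    """FASTA text (headers ``>ID|SPECIES``) of homologs at target identities.

    ``species_plan`` maps species name to a list of identity targets, one per
    family member.  Planned conserved positions (1-based) are never mutated;
    ``contact_policy`` steers mutations away from ("avoid") or into
    ("prefer") the given contact positions.  Realised identity is
    1 - round((1 - target) * L) / L, within ±0.03 of the target for chains of
     17+ residues.
    """
    L = len(template_seq)
    conserved = {p - 1 for p in conserved_positions}
    contacts = {p - 1 for p in contact_positions}
    rng = np.random.default_rng(seed)
    records = []
    member_no = 1
    for species in sorted(species_plan):
        for target in species_plan[species]:
            if not 0.0 < target <= 1.0:
                raise FixturePlanError(f"identity target {target} outside (0, 1]")
            n_mut = round((1.0 - target) * L)
            mutable = [p for p in range(L) if p not in conserved]
            if contact_policy == "avoid":
                preferred = [p for p in mutable if p not in contacts]
                fallback = [p for p in mutable if p in contacts]
            elif contact_policy == "prefer":
                preferred = [p for p in mutable if p in contacts]
                fallback = [p for p in mutable if p not in contacts]
            else:
                preferred, fallback = mutable, []
            if n_mut > len(mutable):
                raise FixturePlanError(
                    f"identity target {target} needs {n_mut} mutations but the "
                    f"conserved plan leaves only {len(mutable)} mutable positions"
                )
            pool = list(preferred)
            rng.shuffle(pool)
            extra = list(fallback)
            rng.shuffle(extra)
            positions = (pool + extra)[:n_mut]
            seq = list(template_seq)
            for p in positions:
                seq[p] = _sample_substitution(seq[p], rng, mode=substitution)
            records.append(
                f">{id_prefix}{member_no:03d}|{species}\n{''.join(seq)}"
            )
            member_no += 1
    return "\n".join(records) + "\n"


# ---------------------------------------------------------------------------
# synthetic alanine scan


def make_alascan_set(
    t: TemplateInterface,
    matrices: MatrixSet,
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    n: int,
    noise_sd: float,
    seed: int = 0,
    w: float = 3.0,
) -> list[AlaScanRecord]:
    """Synthetic ddG table: model residue contributions plus Gaussian noise.

    ``n`` contact residues are drawn (seeded, without replacement) from the
    pooled interface; each record's ddG is the model contribution plus
    N(0, noise_sd) noise, in the ASEdb-style layout the evaluator reads.
    """
    positions = [("A", p) for p in t.contact_residues_a] + [
        ("B", p) for p in t.contact_residues_b
    ]
    if n > len(positions):
        raise FixturePlanError(
            f"requested {n} records but template has only {len(positions)} "
            "contact residues"
        )
    rng = np.random.default_rng(seed)
    chosen = [positions[int(i)] for i in
              rng.choice(len(positions), size=n, replace=False)]
    records = []
    for chain, pos in chosen:
        rec = residue_contribution(t, chain, pos, matrices,
                                   profile_a, profile_b, w=w)
        rec.ddg = rec.contribution + float(rng.normal(0.0, noise_sd))
        records.append(rec)
    return records


def alascan_to_tsv(records: list[AlaScanRecord]) -> str:
    lines = ["template_id\tchain\tposition\twild_type\tddg"]
    for r in records:
        lines.append(
            f"{r.template_id}\t{r.chain}\t{r.position}\t{r.wild_type}"
            f"\t{r.ddg:.6f}"
        )
    return "\n".join(lines) + "\n"


def alascan_from_tsv(text: str) -> list[AlaScanRecord]:
    records = []
    lines = text.strip().splitlines()
    for line in lines[1:]:
        template_id, chain, position, wild_type, ddg = line.split("\t")
        records.append(
            AlaScanRecord(
                template_id=template_id, chain=chain, position=int(position),
                wild_type=wild_type, contribution=math.nan, ddg=float(ddg),
            )
        )
    return records


# ---------------------------------------------------------------------------
# published worked example: calcineurin heterodimer search results


@dataclass(frozen=True)
class SearchResultRow:
    interactor1: str
    interactor2: str
    species: str
    z: float
    rank: int
    label: str           # "P" (recorded interaction) or "N" (CC RSS < 0.4)
    bp_rss: float | None
    cc_rss: float | None


#: The 19 reported candidate rows for the human calcineurin heterodimer
#: (catalytic/regulatory subunit) query, with per-species ranks, Z-values and
#: GO relative-specificity-similarity scores ("-" = not computable).
_CALCINEURIN_ROWS: tuple[tuple, ...] = (
    ("P48456", "P48451", "Fruit fly", 8.98, 1, "P", 0.89, 0.85),
    ("P23287", "P25296", "Yeast", 8.25, 1, "P", 0.88, 1.00),
    ("P14747", "P25296", "Yeast", 7.95, 2, "P", 0.88, 1.00),
    ("Q12705", "Q9UU93", "Yeast", 7.94, 1, "P", None, 0.78),
    ("P48456", "P47948", "Fruit fly", 4.42, 16, "N", 0.41, 0.30),
    ("P48456", "P47949", "Fruit fly", 4.38, 17, "N", 0.41, 0.30),
    ("P48456", "P49258", "Fruit fly", 3.99, 23, "P", 0.41, 0.56),
    ("P48456", "Q9VQH2", "Fruit fly", 3.94, 25, "N", 0.49, 0.33),
    ("Q8IAM8", "P62203", "Plasmodium falciparum", 3.79, 2, "P", None, None),
    ("P48456", "P48593", "Fruit fly", 3.72, 31, "P", 0.35, 0.56),
    ("P48456", "A1ZAE1", "Fruit fly", 3.59, 34, "N", 0.00, 0.30),
    ("Q27889", "P48593", "Fruit fly", 3.42, 40, "P", None, None),
    ("P23287", "P06787", "Yeast", 3.36, 5, "P", 0.61, 0.88),
    ("P48456", "Q9VMT2", "Fruit fly", 3.03, 50, "N", 0.41, 0.30),
    ("P48456", "Q7K860", "Fruit fly", 2.99, 53, "N", 0.41, 0.30),
    ("P14747", "P06787", "Yeast", 2.86, 6, "P", 0.61, 0.88),
    ("P48454", "Q9NP86", "Human", 2.33, 90, "N", None, 0.00),
    ("Q08209", "Q9NP86", "Human", 2.31, 91, "N", 0.41, 0.00),
    ("P16298", "Q9NP86", "Human", 2.31, 91, "N", None, 0.00),
)


def calcineurin_search_rows() -> list[SearchResultRow]:
    """The calcineurin worked-example search rows as structured records."""
    return [SearchResultRow(*row) for row in _CALCINEURIN_ROWS]


def calcineurin_rss_table() -> dict[tuple[str, str], tuple[float | None, float | None]]:
    """RSS lookup (BP, CC) keyed by interactor pair for the worked example."""
    return {
        (r.interactor1, r.interactor2): (r.bp_rss, r.cc_rss)
        for r in calcineurin_search_rows()
    }


# ---------------------------------------------------------------------------
# planted-signal benchmark replicate


def planted_replicate(seed: int, null_n: int = 200) -> dict[str, bool]:
    """One planted-signal pipeline replicate at default thresholds.

    Builds a toy template, plants one true interolog pair per species
    (homologs at ~60 % identity with the interface spared) alongside three
    decoys — a low-identity homolog, an interface-truncated fragment and an
    interface-scrambled pair (uniform substitutions concentrated at contact
    residues) — runs the full mapping and reports whether the true pair was
    accepted and each decoy rejected.
    """
    from .config import RunConfig
    from .mapping import parse_fasta_db
    from .pipeline import run_mapping
    from .structures import build_template, parse_structure

    spec = ToyDimerSpec(
        seed=seed, n_contacts=26,
        special_bond_plan={0: "disulfide", 1: "salt_bridge",
                           2: "hydrogen_bond"},
    )
    pdb_text, _, seq_a, seq_b = make_toy_dimer(spec)
    t = build_template(parse_structure(pdb_text), "A", "B",
                       template_id=f"toy{seed}")
    contacts_a = set(t.contact_residues_a)
    contacts_b = set(t.contact_residues_b)
    fasta = (
        make_homolog_family(seq_a, {"fly": [0.6]},
                            contact_positions=contacts_a,
                            contact_policy="avoid", seed=seed * 4 + 1,
                            id_prefix="TRUEA")
        + make_homolog_family(seq_b, {"fly": [0.6]},
                              contact_positions=contacts_b,
                              contact_policy="avoid", seed=seed * 4 + 2,
                              id_prefix="TRUEB")
        + make_homolog_family(seq_a, {"fly": [0.2]}, seed=seed * 4 + 3,
                              id_prefix="LOWIDA")
        + f">TAILA001|fly\n{seq_a[26:]}\n"
        + make_homolog_family(seq_a, {"fly": [0.55]},
                              contact_positions=contacts_a,
                              contact_policy="prefer",
                              substitution="uniform", seed=seed * 4 + 4,
                              id_prefix="LOWZA")
        + make_homolog_family(seq_b, {"fly": [0.55]},
                              contact_positions=contacts_b,
                              contact_policy="prefer",
                              substitution="uniform", seed=seed * 4 + 5,
                              id_prefix="LOWZB")
    )
    db = parse_fasta_db(fasta)
    result = run_mapping([t], db, RunConfig(seed=seed), null_n=null_n)
    accepted = {(c.id_a, c.id_b) for c in result.accepted}
    return {
        "true_pair_accepted": ("TRUEA001", "TRUEB001") in accepted,
        "low_identity_rejected": not any("LOWIDA001" in pair
                                         for pair in accepted),
        "truncated_rejected": not any("TAILA001" in pair
                                      for pair in accepted),
        "scrambled_rejected": ("LOWZA001", "LOWZB001") not in accepted,
    }
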