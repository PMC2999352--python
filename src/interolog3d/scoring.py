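"""The four-term interface scoring function and its randomized-interface null.

A candidate protein pair aligned onto a template interface is scored as

    E_tot = E_vdw + E_SF + E_sim + w * E_cons        (w = 3 by default)

where E_vdw and E_SF sum knowledge-based van der Waals and special-bond
matrix lookups at the candidate residues aligned to each template contact
pair, E_sim is the BLOSUM62 template-interface similarity
sum_{(i,j)} (K_ii' + K_jj') / (K_ii + K_jj), and E_cons is the
couple-conserved residue score sum_{(i,j)} (M_i'p + M_j'p') / (K_ii + K_jj)
from the two template-chain profiles.  Statistical significance is a Z-value
against a null of randomized interfaces in which 60 % of contact residues
are mutated according to interface background frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .matrices import MatrixSet, SubstitutionMatrix
from .profiles import ChainAlignment, ChainProfile, self_alignment
from .structures import TemplateInterface


class DegenerateModelError(ValueError):
    """Raised when a null model has zero variance (no usable Z statistic)."""


@dataclass
class EnergyBreakdown:
    e_vdw: float
    e_sf: float
    e_sim: float
    e_cons: float
    w: float = 3.0

    @property
    def e_tot(self) -> float:
        return self.e_vdw + self.e_sf + self.e_sim + self.w * self.e_cons


def _pair_residues(
    pair, aln_a: ChainAlignment, aln_b: ChainAlignment
) -> tuple[str | None, str | None]:
    return aln_a.residue_at(pair.pos_a), aln_b.residue_at(pair.pos_b)


def _matrix_sum(pair, aa_a: str, aa_b: str, ss, sb) -> float:
    """Sum matrix lookups over the pair's scored interaction classes."""
    total = 0.0
    if "ss" in pair.classes:
        total += ss.lookup(aa_a, aa_b)
    if "sb" in pair.classes:  # sidechain of A against backbone of B
        total += sb.lookup(aa_a, aa_b)
    if "bs" in pair.classes:  # sidechain of B against backbone of A
        total += sb.lookup(aa_b, aa_a)
    return total


def score_vdw(
    t: TemplateInterface,
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    matrices: MatrixSet,
) -> float:
    """Van der Waals term: V-matrix lookups at the candidate residues aligned
    to every template contact pair; a pair with a gapped position scores 0."""
    total = 0.0
    for pair in t.contact_pairs:
        aa_a, aa_b = _pair_residues(pair, aln_a, aln_b)
        if aa_a is None or aa_b is None:
            continue
        total += _matrix_sum(pair, aa_a, aa_b, matrices.ss_vdw, matrices.sb_vdw)
    return total


def score_special(
    t: TemplateInterface,
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    matrices: MatrixSet,
) -> float:
    """Special-bond term: T-matrix lookups over template pairs that form a
    hydrogen bond, salt bridge or disulfide in the template structure."""
    total = 0.0
    for pair in t.contact_pairs:
        if pair.special_bond == "none":
            continue
        aa_a, aa_b = _pair_residues(pair, aln_a, aln_b)
        if aa_a is None or aa_b is None:
            continue
        total += _matrix_sum(pair, aa_a, aa_b, matrices.ss_special,
                             matrices.sb_special)
    return total


def score_sim(
    t: TemplateInterface,
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    blosum: SubstitutionMatrix,
    average: bool = False,
) -> float:
    """Template-interface similarity from BLOSUM62.

    Each contact pair (i, j) contributes (K_ii' + K_jj') / (K_ii + K_jj)
    where i', j' are the candidate residues aligned at the pair's positions;
    a gapped position contributes 0 to its K term.  Self-alignment therefore
    scores exactly 1 per pair (E_sim = CP).  With ``average`` the sum is
    divided by CP.
    """
    total = 0.0
    for pair in t.contact_pairs:
        aa_a, aa_b = _pair_residues(pair, aln_a, aln_b)
        denom = blosum.diagonal(pair.aa_a) + blosum.diagonal(pair.aa_b)
        num = 0.0
        if aa_a is not None:
            num += blosum.K(pair.aa_a, aa_a)
        if aa_b is not None:
            num += blosum.K(pair.aa_b, aa_b)
        total += num / denom
    if average and t.cp:
        total /= t.cp
    return total


def score_cons(
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    t: TemplateInterface,
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    blosum: SubstitutionMatrix,
    average: bool = False,
) -> float:
    """Couple-conserved residue score from the two template-chain profiles.

    Each contact pair contributes (M_i'p + M_j'p') / (K_ii + K_jj): the
    profile scores of the candidate residues at the template contact
    positions, normalised by the BLOSUM62 diagonal of the template residues.
    """
    for profile, chain_seq, label in (
        (profile_a, t.chain_a_seq, "A"),
        (profile_b, t.chain_b_seq, "B"),
    ):
        if profile.length != len(chain_seq):
            raise ValueError(
                f"profile {label} length {profile.length} != chain length "
                f"{len(chain_seq)}"
            )
    total = 0.0
    for pair in t.contact_pairs:
        aa_a, aa_b = _pair_residues(pair, aln_a, aln_b)
        denom = blosum.diagonal(pair.aa_a) + blosum.diagonal(pair.aa_b)
        num = 0.0
        if aa_a is not None:
            num += profile_a.score(pair.pos_a, aa_a)
        if aa_b is not None:
            num += profile_b.score(pair.pos_b, aa_b)
        total += num / denom
    if average and t.cp:
        total /= t.cp
    return total


def total_score(e_vdw: float, e_sf: float, e_sim: float, e_cons: float,
                w: float = 3.0) -> EnergyBreakdown:
    """Assemble the exact weighted sum E_tot = E_vdw + E_SF + E_sim + w E_cons."""
    return EnergyBreakdown(e_vdw=e_vdw, e_sf=e_sf, e_sim=e_sim, e_cons=e_cons, w=w)


def score_candidate(
    t: TemplateInterface,
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    matrices: MatrixSet,
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    w: float = 3.0,
    average_sim_cons: bool = False,
) -> EnergyBreakdown:
    """All four terms for one candidate pair on one template."""
    return total_score(
        e_vdw=score_vdw(t, aln_a, aln_b, matrices),
        e_sf=score_special(t, aln_a, aln_b, matrices),
        e_sim=score_sim(t, aln_a, aln_b, matrices.substitution,
                        average=average_sim_cons),
        e_cons=score_cons(profile_a, profile_b, t, aln_a, aln_b,
                          matrices.substitution, average=average_sim_cons),
        w=w,
    )


@dataclass
class NullModel:
    """Mean/sd of E_tot over randomized interfaces of one template."""

    template_id: str
    n_samples: int
    mutation_fraction: float
    mean: float
    sd: float
    seed: int


def _mutated_alignments(
    t: TemplateInterface,
    rng: np.random.Generator,
    mutated_positions,
    background: np.ndarray,
    alphabet: str,
) -> tuple[ChainAlignment, ChainAlignment]:
    seq_a = list(t.chain_a_seq)
    seq_b = list(t.chain_b_seq)
    for chain, pos in mutated_positions:
        seq = seq_a if chain == "A" else seq_b
        wild = seq[pos - 1]
        probs = background.copy()
        if wild in alphabet:
            probs[alphabet.index(wild)] = 0.0
        probs /= probs.sum()
        seq[pos - 1] = alphabet[int(rng.choice(len(alphabet), p=probs))]
    base_a = _identity_alignment("A", t.chain_a_seq, "".join(seq_a))
    base_b = _identity_alignment("B", t.chain_b_seq, "".join(seq_b))
    return base_a, base_b


def _identity_alignment(chain_id: str, template_seq: str,
                        query_seq: str) -> ChainAlignment:
    pairs = {p: p for p in range(1, len(template_seq) + 1)}
    matches = sum(a == b for a, b in zip(template_seq, query_seq))
    return ChainAlignment(
        chain_id=chain_id, query_id="randomized", species="null",
        template_seq=template_seq, query_seq=query_seq, pairs=pairs,
        score=0.0, identity=matches / len(template_seq), cr=1.0,
    )


def build_null_model(
    t: TemplateInterface,
    matrices: MatrixSet,
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    background: np.ndarray,
    n_samples: int = 10000,
    mutation_fraction: float = 0.6,
    seed: int = 0,
    w: float = 3.0,
) -> NullModel:
    """Randomized-interface null: mutate a fraction of the pooled contact
    residues per sample and score the mutated pair with the full E_tot.

    Each sample draws ceil(fraction * total contact residues) positions
    uniformly without replacement from the union of both chains' contact
    residues and replaces each with a background-distributed residue other
    than the wild type.  The sample mean and (ddof=1) standard deviation of
    E_tot define the normal null for Z-values.  Fully reproducible from
    ``seed``.
    """
    alphabet = matrices.ss_vdw.alphabet
    positions = [("A", p) for p in t.contact_residues_a] + [
        ("B", p) for p in t.contact_residues_b
    ]
    if not positions:
        raise DegenerateModelError(f"template {t.template_id} has no contacts")
    k = math.ceil(mutation_fraction * len(positions))
    rng = np.random.default_rng(seed)
    scores = np.empty(n_samples)
    for s in range(n_samples):
        if k:
            chosen_idx = rng.choice(len(positions), size=k, replace=False)
            chosen = [positions[int(i)] for i in chosen_idx]
        else:
            chosen = []
        aln_a, aln_b = _mutated_alignments(t, rng, chosen, background, alphabet)
        scores[s] = score_candidate(
            t, aln_a, aln_b, matrices, profile_a, profile_b, w=w
        ).e_tot
    sd = float(np.std(scores, ddof=1)) if n_samples > 1 else 0.0
    if sd == 0.0:
        raise DegenerateModelError(
            f"degenerate null model for template {t.template_id} (sd = 0)"
        )
    return NullModel(
        template_id=t.template_id, n_samples=n_samples,
        mutation_fraction=mutation_fraction, mean=float(np.mean(scores)),
        sd=sd, seed=seed,
    )


def z_value(score: float, null: NullModel) -> float:
    """Standardised interface score (score - mean) / sd under the null."""
    if null.sd <= 0:
        raise DegenerateModelError(
            f"null model for {null.template_id} has sd = {null.sd}"
        )
    return (score - null.mean) / null.sd


@dataclass
class AlaScanRecord:
    template_id: str
    chain: str
    position: int
    wild_type: str
    contribution: float
    ddg: float | None = None


def residue_contribution(
    t: TemplateInterface,
    chain: str,
    position: int,
    matrices: MatrixSet,
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    w: float = 3.0,
) -> AlaScanRecord:
    """Predicted binding contribution of one contact residue.

    E_tot(self) minus E_tot of the self pair with that residue computationally
    mutated to alanine, all four terms recomputed — the in-silico analogue of
    an alanine-scanning ddG.
    """
    contact_set = (
        t.contact_residues_a if chain == "A" else t.contact_residues_b
    )
    if position not in contact_set:
        raise ValueError(
            f"position {chain}:{position} is not a contact residue of "
            f"{t.template_id}"
        )
    aln_a = self_alignment(profile_a)
    aln_b = self_alignment(profile_b)
    wild = score_candidate(t, aln_a, aln_b, matrices, profile_a, profile_b, w=w)
    seq_a, seq_b = list(t.chain_a_seq), list(t.chain_b_seq)
    wt = (seq_a if chain == "A" else seq_b)[position - 1]
    (seq_a if chain == "A" else seq_b)[position - 1] = "A"
    mut_a = _identity_alignment("A", t.chain_a_seq, "".join(seq_a))
    mut_b = _identity_alignment("B", t.chain_b_seq, "".join(seq_b))
    mutant = score_candidate(t, mut_a, mut_b, matrices, profile_a, profile_b, w=w)
    return AlaScanRecord(
        template_id=t.template_id, chain=chain, position=position,
        wild_type=wt, contribution=wild.e_tot - mutant.e_tot,
    )
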