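"""Position-specific profiles for template chains and profile-to-sequence alignment.

A template chain's homolog family is summarised as a PSSM-style profile:
M[p, x] is the score for residue type x at template position p, on the
BLOSUM62 half-bit scale.  Profiles can be built in-house from a star-format
MSA (template first) with Henikoff sequence weighting and BLOSUM-mixture
pseudocounts, or imported from PSI-BLAST ASCII PSSM files.  Candidates are
aligned to a profile with a Smith–Waterman/Gotoh local alignment and filtered
on sequence identity (> 30 %) and aligned contact residue ratio (CR > 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import AA_ALPHABET, AA_INDEX, BACKGROUND_FREQS

#: Karlin–Altschul constants for BLOSUM62 with affine gaps 11/1.
KA_LAMBDA = 0.267
KA_K = 0.041

_HALF_BIT = 2.0 / math.log(2.0)  # nats -> half-bits


class ProfileError(ValueError):
    """Raised for malformed MSAs or PSSM files."""


def _blosum_conditional() -> tuple[np.ndarray, np.ndarray]:
    """P(x | y) implied by BLOSUM62 half-bit scores and background frequencies.

    The implied joint is Q_xy ∝ p_x p_y 2^(S_xy / 2); returns (conditional
    matrix with columns y, marginal background of the normalised joint).
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET)
    s = np.empty((n, n))
    for i, x in enumerate(AA_ALPHABET):
        for j, y in enumerate(AA_ALPHABET):
            s[i, j] = blosum[x, y]
    joint = np.outer(BACKGROUND_FREQS, BACKGROUND_FREQS) * np.power(2.0, s / 2.0)
    joint /= joint.sum()
    marginal = joint.sum(axis=1)
    conditional = joint / joint.sum(axis=0, keepdims=True)
    return conditional, marginal


_COND, _COND_BG = _blosum_conditional()


@dataclass
class ChainProfile:
    chain_id: str
    template_seq: str
    M: np.ndarray  # (length, 20) scores, half-bit scale
    source: str = "in-house"

    @property
    def length(self) -> int:
        return len(self.template_seq)

    def score(self, position: int, aa: str) -> float:
        """Profile score for residue ``aa`` at 1-based template ``position``."""
        return float(self.M[position - 1, AA_INDEX[aa]])


def henikoff_weights(rows: list[str]) -> np.ndarray:
    """Henikoff & Henikoff position-based sequence weights (sum to 1)."""
    n = len(rows)
    weights = np.zeros(n)
    for col in zip(*rows):
        types: dict[str, int] = {}
        for ch in col:
            if ch != "-":
                types[ch] = types.get(ch, 0) + 1
        r = len(types)
        if r == 0:
            continue
        for i, ch in enumerate(col):
            if ch != "-":
                weights[i] += 1.0 / (r * types[ch])
    if weights.sum() == 0:
        weights[:] = 1.0
    return weights / weights.sum()


def build_profile(
    msa: list[str],
    chain_id: str = "A",
    pseudocount_weight: float = 10.0,
) -> ChainProfile:
    """Build a profile from a star-format MSA whose first row is the template.

    Columns where the template row is gapped are dropped.  Column residue
    frequencies are Henikoff-weighted and mixed with BLOSUM62-conditional
    pseudocounts: f' = (alpha f + beta g) / (alpha + beta) with
    alpha = (mean distinct residue types per column) - 1 and beta the
    ``pseudocount_weight``.  Scores are half-bit log-odds against the
    background, so a single-sequence MSA degenerates to (approximately
    rescaled) BLOSUM62 rows.
    """
    if not msa:
        raise ProfileError("empty MSA")
    width = len(msa[0])
    for k, row in enumerate(msa):
        if len(row) != width:
            raise ProfileError(
                f"MSA row {k} has length {len(row)}, expected {width}"
            )
    template_cols = [i for i, ch in enumerate(msa[0]) if ch != "-"]
    template_seq = "".join(msa[0][i] for i in template_cols)
    if not template_seq:
        raise ProfileError("template row is all gaps")
    weights = henikoff_weights(msa)

    distinct = []
    for i in template_cols:
        col = {row[i] for row in msa if row[i] != "-"}
        distinct.append(len(col))
    alpha = max(float(np.mean(distinct)) - 1.0, 0.0)
    beta = pseudocount_weight

    n = len(AA_ALPHABET)
    M = np.zeros((len(template_cols), n))
    for p, i in enumerate(template_cols):
        f = np.zeros(n)
        for row, w in zip(msa, weights):
            ch = row[i]
            if ch != "-" and ch in AA_INDEX:
                f[AA_INDEX[ch]] += w
        if f.sum() == 0:
            raise ProfileError(f"column {i} has no residues")
        f /= f.sum()
        g = _COND @ f  # BLOSUM-mixture pseudocount distribution
        f_star = (alpha * f + beta * g) / (alpha + beta)
        M[p] = _HALF_BIT * np.log(f_star / BACKGROUND_FREQS)
    return ChainProfile(chain_id=chain_id, template_seq=template_seq, M=M,
                        source="in-house")


def import_pssm(text: str, chain_id: str = "A") -> ChainProfile:
    """Import a PSI-BLAST ASCII PSSM, preserving the integer scores exactly.

    The first 20 numeric columns of each position row (the log-odds block)
    are read; the residue-order header line defines the column alphabet.
    """
    lines = text.splitlines()
    alphabet: list[str] | None = None
    rows: list[tuple[int, str, list[int]]] = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if alphabet is None:
            if len(fields) >= 20 and all(
                len(f) == 1 and f.upper() in AA_ALPHABET for f in fields[:20]
            ):
                alphabet = [f.upper() for f in fields[:20]]
            continue
        if len(fields) >= 2 and fields[0].isdigit():
            if len(fields) < 2 + 20:
                raise ProfileError(
                    f"line {lineno}: ragged PSSM row ({len(fields) - 2} scores)"
                )
            try:
                scores = [int(v) for v in fields[2 : 2 + 20]]
            except ValueError:
                raise ProfileError(f"line {lineno}: non-integer PSSM score") from None
            rows.append((int(fields[0]), fields[1].upper(), scores))
    if alphabet is None or not rows:
        raise ProfileError("not a PSI-BLAST ASCII PSSM (no header/rows found)")
    template_seq = "".join(r[1] for r in rows)
    M = np.zeros((len(rows), len(AA_ALPHABET)))
    for p, (_, _, scores) in enumerate(rows):
        for col_aa, v in zip(alphabet, scores):
            M[p, AA_INDEX[col_aa]] = v
    return ChainProfile(chain_id=chain_id, template_seq=template_seq, M=M,
                        source="imported")


@dataclass
class ChainAlignment:
    """A candidate sequence locally aligned to a template-chain profile."""

    chain_id: str
    query_id: str
    species: str
    template_seq: str
    query_seq: str
    pairs: dict[int, int]  # template position -> candidate position (1-based)
    score: float
    identity: float        # over aligned (non-gap) columns
    cr: float | None = None

    def residue_at(self, template_pos: int) -> str | None:
        qpos = self.pairs.get(template_pos)
        return None if qpos is None else self.query_seq[qpos - 1]


def self_alignment(profile: ChainProfile, query_id: str = "self",
                   species: str = "template") -> ChainAlignment:
    """The identity alignment of the template chain to its own profile."""
    seq = profile.template_seq
    pairs = {p: p for p in range(1, len(seq) + 1)}
    score = sum(profile.score(p, seq[p - 1]) for p in pairs)
    return ChainAlignment(
        chain_id=profile.chain_id, query_id=query_id, species=species,
        template_seq=seq, query_seq=seq, pairs=pairs, score=score,
        identity=1.0, cr=1.0,
    )


def align_profile(
    profile: ChainProfile,
    seq: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    species: str = "unknown",
) -> ChainAlignment:
    """Smith–Waterman/Gotoh local alignment of a sequence to a profile.

    Affine gap cost open + k*extend for a gap of length k (BLAST 11/1
    convention on the half-bit score scale).  Traceback is deterministic:
    the highest-scoring end cell with the smallest (p, q) index is chosen and
    ties are resolved diagonal > up (gap in candidate) > left (gap in
    template).
    """
    if not seq:
        raise ProfileError("empty candidate sequence")
    seq = seq.upper()
    L = profile.length
    n = len(seq)
    seq_idx = np.array([AA_INDEX.get(ch, -1) for ch in seq])
    # substitution score of template position p vs seq position q
    sub = np.zeros((L, n))
    for q in range(n):
        if seq_idx[q] >= 0:
            sub[:, q] = profile.M[:, seq_idx[q]]
        else:
            sub[:, q] = -4.0  # non-standard residue: flat mismatch penalty
    neg = -1e18
    H = np.zeros((L + 1, n + 1))
    E = np.full((L + 1, n + 1), neg)  # gap in template (left)
    F = np.full((L + 1, n + 1), neg)  # gap in candidate (up)
    for p in range(1, L + 1):
        Hp, Hm = H[p], H[p - 1]
        Ep = E[p]
        Fp, Fm = F[p], F[p - 1]
        srow = sub[p - 1]
        for q in range(1, n + 1):
            e = max(Hp[q - 1] - gap_open - gap_extend, Ep[q - 1] - gap_extend)
            f = max(Hm[q] - gap_open - gap_extend, Fm[q] - gap_extend)
            h = max(0.0, Hm[q - 1] + srow[q - 1], f, e)
            Ep[q] = e
            Fp[q] = f
            Hp[q] = h
    best = float(H.max())
    p, q = map(int, np.unravel_index(int(H.argmax()), H.shape))
    pairs: dict[int, int] = {}
    matches = 0
    state = "H"
    while p > 0 and q > 0:
        if state == "H":
            h = H[p, q]
            if h == 0.0:
                break
            if h == H[p - 1, q - 1] + sub[p - 1, q - 1]:
                pairs[p] = q
                if profile.template_seq[p - 1] == seq[q - 1]:
                    matches += 1
                p -= 1
                q -= 1
            elif h == F[p, q]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in candidate, consume template
            if F[p, q] == H[p - 1, q] - gap_open - gap_extend:
                state = "H"
            p -= 1
        else:  # gap in template, consume candidate
            if E[p, q] == H[p, q - 1] - gap_open - gap_extend:
                state = "H"
            q -= 1
    identity = matches / len(pairs) if pairs else 0.0
    return ChainAlignment(
        chain_id=profile.chain_id, query_id=query_id, species=species,
        template_seq=profile.template_seq, query_seq=seq,
        pairs=dict(sorted(pairs.items())), score=best, identity=identity,
    )


def alignment_evalue(score: float, m: int, n: int,
                     ka_lambda: float = KA_LAMBDA, ka_k: float = KA_K) -> float:
    """Karlin–Altschul E-value for a local alignment raw score (half-bit scale)."""
    return ka_k * m * n * math.exp(-ka_lambda * score)


def contact_ratio(alignment: ChainAlignment, contact_positions) -> float:
    """Fraction of template contact positions aligned to a candidate residue."""
    positions = set(contact_positions)
    if not positions:
        raise ValueError("empty contact-position set")
    covered = sum(1 for p in positions if p in alignment.pairs)
    return covered / len(positions)


@dataclass
class FilterResult:
    passed: bool
    reasons: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def candidate_filter(
    aln_a: ChainAlignment,
    aln_b: ChainAlignment,
    min_identity: float = 0.30,
    min_cr: float = 0.5,
) -> FilterResult:
    """Interolog candidate filter: identity > 30 % and CR > 0.5, both chains.

    Both inequalities are strict; each alignment's ``cr`` must already be set
    (via :func:`contact_ratio`).
    """
    reasons = []
    for label, aln in (("A", aln_a), ("B", aln_b)):
        if aln.cr is None:
            raise ValueError(f"alignment {label} has no contact ratio set")
        if not aln.identity > min_identity:
            reasons.append(
                f"chain {label} identity {aln.identity:.3f} not above {min_identity}"
            )
        if not aln.cr > min_cr:
            reasons.append(f"chain {label} CR {aln.cr:.3f} not above {min_cr}")
    return FilterResult(passed=not reasons, reasons=reasons)
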