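"""3D-domain interolog mapping: candidate enumeration, ranking and acceptance.

For a template heterodimer, every same-species pair between the homolog
families of its two chains is an interaction candidate.  Candidates passing
the identity/CR filter are scored with the four-term energy and a Z-value;
within each (template, species) partition they are ranked by Z, and a
candidate is accepted as a predicted physical interaction if Z >= 3.0 and it
ranks in the top 25 of its species — the top-rank strategy that suppresses
out-paralog false positives.  Optional GO-similarity (RSS) tables label
accepted pairs for precision/recall evaluation (negative iff CC RSS < 0.4).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

from .matrices import MatrixSet
from .profiles import (
    ChainAlignment,
    ChainProfile,
    align_profile,
    alignment_evalue,
    candidate_filter,
    contact_ratio,
)
from .scoring import EnergyBreakdown, NullModel, score_candidate, z_value
from .structures import TemplateInterface

logger = logging.getLogger(__name__)

#: Default FASTA header convention: ``>ID|SPECIES description``.
DEFAULT_HEADER_REGEX = r"^(?P<id>[^|\s]+)\|(?P<species>[^|\s]+)"


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    species: str
    seq: str


def parse_fasta_db(text: str,
                   header_regex: str = DEFAULT_HEADER_REGEX) -> list[SequenceRecord]:
    """Read a FASTA database whose headers carry species tags."""
    import io

    from Bio import SeqIO

    pattern = re.compile(header_regex)
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        header = rec.description
        m = pattern.match(header)
        if not m:
            logger.warning("header %r does not match species regex; skipped", header)
            continue
        records.append(
            SequenceRecord(id=m.group("id"), species=m.group("species"),
                           seq=str(rec.seq).upper())
        )
    return records


@dataclass
class ScoredCandidate:
    template_id: str
    id_a: str
    id_b: str
    species: str
    aln_a: ChainAlignment
    aln_b: ChainAlignment
    energy: EnergyBreakdown
    z: float
    species_rank: int | None = None


def _family_hits(
    profile: ChainProfile,
    t: TemplateInterface,
    contact_positions,
    db: list[SequenceRecord],
    gap_open: float,
    gap_extend: float,
    evalue_max: float,
) -> dict[str, ChainAlignment]:
    hits = {}
    for rec in db:
        aln = align_profile(profile, rec.seq, gap_open=gap_open,
                            gap_extend=gap_extend, query_id=rec.id,
                            species=rec.species)
        if not aln.pairs:
            continue
        evalue = alignment_evalue(aln.score, profile.length, len(rec.seq))
        if evalue > evalue_max:
            continue
        aln.cr = contact_ratio(aln, contact_positions)
        hits[rec.id] = aln
    return hits


def enumerate_candidates(
    t: TemplateInterface,
    db: list[SequenceRecord],
    profile_a: ChainProfile,
    profile_b: ChainProfile,
    matrices: MatrixSet,
    null: NullModel,
    min_identity: float = 0.30,
    min_cr: float = 0.5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    evalue_max: float = 1e-10,
    w: float = 3.0,
) -> list[ScoredCandidate]:
    """All same-species pairs between the two chains' homolog families,
    filtered by identity/CR and scored with E_tot and Z (unranked).

    A protein may pair with itself only by matching both chains (i.e. it
    appears in both homolog families).
    """
    species_map: dict[str, str] = {rec.id: rec.species for rec in db}
    hits_a = _family_hits(profile_a, t, t.contact_residues_a, db,
                          gap_open, gap_extend, evalue_max)
    hits_b = _family_hits(profile_b, t, t.contact_residues_b, db,
                          gap_open, gap_extend, evalue_max)
    if not hits_a or not hits_b:
        logger.info(
            "template %s: empty homolog family (|A'|=%d, |B'|=%d)",
            t.template_id, len(hits_a), len(hits_b),
        )
        return []
    candidates = []
    for id_a, aln_a in hits_a.items():
        for id_b, aln_b in hits_b.items():
            if species_map[id_a] != species_map[id_b]:
                continue
            if not candidate_filter(aln_a, aln_b, min_identity=min_identity,
                                    min_cr=min_cr):
                continue
            energy = score_candidate(t, aln_a, aln_b, matrices,
                                     profile_a, profile_b, w=w)
            candidates.append(
                ScoredCandidate(
                    template_id=t.template_id, id_a=id_a, id_b=id_b,
                    species=species_map[id_a], aln_a=aln_a, aln_b=aln_b,
                    energy=energy, z=z_value(energy.e_tot, null),
                )
            )
    return candidates


def rank_within_species(cands: list[ScoredCandidate]) -> list[ScoredCandidate]:
    """Assign dense 1-based ranks within each (template, species) partition.

    Sort key: Z descending, ties by E_tot descending, then lexicographic
    (id_a, id_b) — deterministic and reproducible.
    """
    groups: dict[tuple[str, str], list[ScoredCandidate]] = {}
    for c in cands:
        groups.setdefault((c.template_id, c.species), []).append(c)
    ranked: list[ScoredCandidate] = []
    for key in sorted(groups):
        members = sorted(
            groups[key],
            key=lambda c: (-c.z, -c.energy.e_tot, c.id_a, c.id_b),
        )
        for rank, c in enumerate(members, start=1):
            c.species_rank = rank
        ranked.extend(members)
    return ranked


def apply_acceptance(
    cands: list[ScoredCandidate],
    z_min: float = 3.0,
    rank_max: int = 25,
    strict_z: bool = False,
) -> list[ScoredCandidate]:
    """Accept candidates with Z >= z_min (or > with ``strict_z``) and
    species rank <= rank_max."""
    accepted = []
    for c in cands:
        if c.species_rank is None:
            raise ValueError("candidates must be ranked before acceptance")
        z_ok = c.z > z_min if strict_z else c.z >= z_min
        if z_ok and c.species_rank <= rank_max:
            accepted.append(c)
    return accepted


# ---------------------------------------------------------------------------
# evaluation against RSS / gold-standard labels


@dataclass
class RssAnnotation:
    id_a: str
    id_b: str
    bp_rss: float | None
    cc_rss: float | None
    label: str  # positive | negative | unknown


def label_by_rss(
    pairs: list[tuple[str, str]],
    rss_table: dict[tuple[str, str], tuple[float | None, float | None]],
    positives: set[tuple[str, str]] = frozenset(),
    cc_threshold: float = 0.4,
) -> list[RssAnnotation]:
    """Label pairs: negative iff CC RSS < threshold; positive iff in the
    gold-standard reference list; else unknown (missing scores stay unknown)."""
    annotations = []
    for id_a, id_b in pairs:
        bp, cc = rss_table.get((id_a, id_b), (None, None))
        if cc is not None and cc < cc_threshold:
            label = "negative"
        elif (id_a, id_b) in positives or (id_b, id_a) in positives:
            label = "positive"
        else:
            label = "unknown"
        annotations.append(RssAnnotation(id_a=id_a, id_b=id_b, bp_rss=bp,
                                         cc_rss=cc, label=label))
    return annotations


@dataclass
class Evaluation:
    precision: float
    recall: float
    hits_positive: int
    hits_negative: int
    total_positives: int


def evaluate_precision_recall(
    accepted_pairs: list[tuple[str, str]],
    labels: list[RssAnnotation],
    total_positives: int | None = None,
) -> Evaluation:
    """Precision = hit positives / (hit positives + hit negatives); recall =
    hit positives / total positives.  Unknown-labelled hits are excluded from
    the precision denominator; with no accepted hits precision is NaN."""
    by_pair = {(a.id_a, a.id_b): a.label for a in labels}
    by_pair.update({(a.id_b, a.id_a): a.label for a in labels})
    hit_pos = sum(1 for p in accepted_pairs if by_pair.get(p) == "positive")
    hit_neg = sum(1 for p in accepted_pairs if by_pair.get(p) == "negative")
    if total_positives is None:
        total_positives = sum(1 for a in labels if a.label == "positive")
    if total_positives == 0:
        raise ValueError("recall undefined: zero gold-standard positives")
    denominator = hit_pos + hit_neg
    precision = hit_pos / denominator if denominator else math.nan
    return Evaluation(
        precision=precision,
        recall=hit_pos / total_positives,
        hits_positive=hit_pos,
        hits_negative=hit_neg,
        total_positives=total_positives,
    )


def sweep_thresholds(
    cands: list[ScoredCandidate],
    labels: list[RssAnnotation],
    z_grid,
    rank_max: int = 25,
    total_positives: int | None = None,
) -> list[dict]:
    """Precision/recall over a grid of z_min thresholds at fixed rank_max
    (acceptance sets are nested, so recall is non-increasing in z_min)."""
    rows = []
    for z_min in z_grid:
        accepted = apply_acceptance(cands, z_min=z_min, rank_max=rank_max)
        ev = evaluate_precision_recall(
            [(c.id_a, c.id_b) for c in accepted], labels,
            total_positives=total_positives,
        )
        rows.append(
            {"z_min": z_min, "rank_max": rank_max, "precision": ev.precision,
             "recall": ev.recall, "n_accepted": len(accepted)}
        )
    return rows


@dataclass
class PredictionTable:
    """Flat TSV view of scored candidates (sorted template, species, rank)."""

    candidates: list[ScoredCandidate] = field(default_factory=list)

    COLUMNS = (
        "template_id", "id_a", "id_b", "species", "identity_a", "identity_b",
        "cr_a", "cr_b", "e_vdw", "e_sf", "e_sim", "e_cons", "e_tot", "z",
        "rank",
    )

    def to_tsv(self) -> str:
        lines = ["\t".join(self.COLUMNS)]
        for c in sorted(
            self.candidates,
            key=lambda c: (c.template_id, c.species, c.species_rank or 0),
        ):
            e = c.energy
            lines.append("\t".join([
                c.template_id, c.id_a, c.id_b, c.species,
                f"{c.aln_a.identity:.4f}", f"{c.aln_b.identity:.4f}",
                f"{c.aln_a.cr:.4f}", f"{c.aln_b.cr:.4f}",
                f"{e.e_vdw:.4f}", f"{e.e_sf:.4f}", f"{e.e_sim:.4f}",
                f"{e.e_cons:.4f}", f"{e.e_tot:.4f}", f"{c.z:.4f}",
                str(c.species_rank),
            ]))
        return "\n".join(lines) + "\n"
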