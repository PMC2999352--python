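"""Interface-evolution reports: star alignments across species and
contact-position annotation.

For each template chain, the highest-Z accepted candidate of every species is
projected onto the template coordinates (star alignment with the template as
center), and each contact position is categorised by whether it participates
in a hydrogen bond/salt bridge in the template and whether it is conserved
across the interologs.  Residues are coloured by seven physicochemical
groups (polar positive/negative/neutral, cysteine, non-polar aliphatic,
non-polar aromatic, others).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .constants import RESIDUE_GROUPS
from .mapping import ScoredCandidate
from .structures import TemplateInterface

logger = logging.getLogger(__name__)

CATEGORIES = ("hbond", "conserved", "hbond_and_conserved", "other")

_CATEGORY_COLORS = {
    "hbond": "green",
    "conserved": "orange",
    "hbond_and_conserved": "yellow",
    "other": "gray",
}

_GROUP_COLORS = {
    "polar_positive": "blue",
    "polar_negative": "red",
    "polar_neutral": "green",
    "cysteine": "yellow",
    "nonpolar_aliphatic": "gray",
    "nonpolar_aromatic": "pink",
    "others": "brown",
}


def residue_group(aa: str) -> str:
    """Physicochemical group of a standard residue (7-group partition)."""
    aa = aa.upper()
    for group, members in RESIDUE_GROUPS.items():
        if aa in members:
            return group
    raise ValueError(f"non-standard residue {aa!r}")


@dataclass
class InterologMSA:
    """Star alignment of per-species best interologs to one template chain."""

    chain_id: str
    template_seq: str
    rows: dict[str, str] = field(default_factory=dict)  # species -> projected seq

    @property
    def length(self) -> int:
        return len(self.template_seq)

    def column(self, position: int) -> list[str]:
        """Residues at a 1-based template position across species rows."""
        return [row[position - 1] for row in self.rows.values()]


def build_interolog_msa(
    t: TemplateInterface, accepted: list[ScoredCandidate]
) -> tuple[InterologMSA, InterologMSA]:
    """Project each species' highest-Z accepted pair onto template coordinates.

    Columns are exactly the template positions; candidate insertions relative
    to the template are dropped (and logged).  Returns one MSA per chain.
    """
    best: dict[str, ScoredCandidate] = {}
    for c in accepted:
        if c.species not in best or c.z > best[c.species].z:
            best[c.species] = c
    msa_a = InterologMSA(chain_id=t.chain_a_id, template_seq=t.chain_a_seq)
    msa_b = InterologMSA(chain_id=t.chain_b_id, template_seq=t.chain_b_seq)
    for species in sorted(best):
        c = best[species]
        for msa, aln in ((msa_a, c.aln_a), (msa_b, c.aln_b)):
            projected = []
            for pos in range(1, msa.length + 1):
                aa = aln.residue_at(pos)
                projected.append(aa if aa is not None else "-")
            n_insertions = len(aln.query_seq) - sum(1 for ch in projected
                                                    if ch != "-")
            if n_insertions > 0:
                logger.info(
                    "species %s chain %s: %d candidate positions outside the "
                    "template frame dropped from the star projection",
                    species, msa.chain_id, n_insertions,
                )
            msa.rows[species] = "".join(projected)
    return msa_a, msa_b


@dataclass
class ContactAnnotation:
    chain_id: str
    position: int
    template_aa: str
    category: str
    conservation: float  # fraction of non-gap rows matching the template
    groups: dict[str, str] = field(default_factory=dict)  # species -> group


def classify_positions(
    msa: InterologMSA,
    t: TemplateInterface,
    conservation_threshold: float = 0.7,
) -> list[ContactAnnotation]:
    """Annotate each contact position of one chain.

    A position is conserved iff at least ``conservation_threshold`` of the
    non-gap rows carry the template residue; it is an hbond position iff it
    participates in a template contact pair whose special bond is a hydrogen
    bond or salt bridge.  Categories combine the two flags.
    """
    if msa.chain_id == t.chain_a_id:
        contact_positions = t.contact_residues_a
        hbond_positions = {
            p.pos_a for p in t.contact_pairs
            if p.special_bond in ("hydrogen_bond", "salt_bridge")
        }
    else:
        contact_positions = t.contact_residues_b
        hbond_positions = {
            p.pos_b for p in t.contact_pairs
            if p.special_bond in ("hydrogen_bond", "salt_bridge")
        }
    annotations = []
    for pos in contact_positions:
        template_aa = msa.template_seq[pos - 1]
        column = msa.column(pos)
        non_gap = [ch for ch in column if ch != "-"]
        if non_gap:
            conservation = sum(ch == template_aa for ch in non_gap) / len(non_gap)
        else:
            conservation = 0.0
        conserved = conservation >= conservation_threshold
        hbond = pos in hbond_positions
        if hbond and conserved:
            category = "hbond_and_conserved"
        elif hbond:
            category = "hbond"
        elif conserved:
            category = "conserved"
        else:
            category = "other"
        groups = {}
        for species, row in msa.rows.items():
            ch = row[pos - 1]
            if ch != "-" and ch != "X":
                groups[species] = residue_group(ch)
        annotations.append(
            ContactAnnotation(
                chain_id=msa.chain_id, position=pos, template_aa=template_aa,
                category=category, conservation=conservation, groups=groups,
            )
        )
    return annotations


def group_composition(msa: InterologMSA, positions) -> dict[int, dict[str, int]]:
    """Per-column counts of the 7 physicochemical groups (co-variation view)."""
    composition = {}
    for pos in positions:
        counts: dict[str, int] = {}
        for ch in msa.column(pos):
            if ch in ("-", "X"):
                continue
            g = residue_group(ch)
            counts[g] = counts.get(g, 0) + 1
        composition[pos] = counts
    return composition


# ---------------------------------------------------------------------------
# report writers


def write_report(
    msas: tuple[InterologMSA, InterologMSA],
    annotations: list[ContactAnnotation],
    fmt: str = "tsv",
) -> str:
    """Render the interface-evolution report as TSV (bit-stable) or HTML."""
    if fmt == "tsv":
        return _report_tsv(annotations)
    if fmt == "html":
        return _report_html(msas, annotations)
    raise ValueError(f"unknown report format {fmt!r}")


def _report_tsv(annotations: list[ContactAnnotation]) -> str:
    lines = ["chain\tposition\ttemplate_aa\tcategory\tconservation\tgroups"]
    for a in sorted(annotations, key=lambda a: (a.chain_id, a.position)):
        groups = ",".join(
            f"{species}:{group}" for species, group in sorted(a.groups.items())
        )
        lines.append(
            f"{a.chain_id}\t{a.position}\t{a.template_aa}\t{a.category}"
            f"\t{a.conservation:.4f}\t{groups}"
        )
    return "\n".join(lines) + "\n"


_HTML_PAGE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Interface evolution report</title>
<style>
td.pos {{ font-family: monospace; padding: 1px 3px; }}
{styles}
</style></head><body>
<h1>Interface evolution report</h1>
{chains}
</body></html>
"""


def _report_html(
    msas: tuple[InterologMSA, InterologMSA],
    annotations: list[ContactAnnotation],
) -> str:
    styles = "\n".join(
        f"td.cat-{cat} {{ background: {color}; }}"
        for cat, color in _CATEGORY_COLORS.items()
    ) + "\n" + "\n".join(
        f"td.grp-{grp} {{ color: {color}; }}"
        for grp, color in _GROUP_COLORS.items()
    )
    by_chain_pos = {(a.chain_id, a.position): a for a in annotations}
    sections = []
    for msa in msas:
        header = "".join(
            "<th>{}</th>".format(p) for p in range(1, msa.length + 1)
        )
        rows_html = []
        template_cells = []
        for pos in range(1, msa.length + 1):
            a = by_chain_pos.get((msa.chain_id, pos))
            cat = f" cat-{a.category}" if a else ""
            template_cells.append(
                f'<td class="pos{cat}">{msa.template_seq[pos - 1]}</td>'
            )
        rows_html.append(
            f"<tr><th>template</th>{''.join(template_cells)}</tr>"
        )
        for species in sorted(msa.rows):
            cells = []
            for pos, ch in enumerate(msa.rows[species], start=1):
                grp = ""
                if ch not in ("-", "X"):
                    grp = f" grp-{residue_group(ch)}"
                cells.append(f'<td class="pos{grp}">{ch}</td>')
            rows_html.append(f"<tr><th>{species}</th>{''.join(cells)}</tr>")
        sections.append(
            f"<h2>Chain {msa.chain_id}</h2>\n<table>"
            f"<tr><th></th>{header}</tr>\n" + "\n".join(rows_html) + "</table>"
        )
    return _HTML_PAGE.format(styles=styles, chains="\n".join(sections))
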