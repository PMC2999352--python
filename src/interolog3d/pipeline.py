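"""End-to-end orchestration: template build → matrices → profiles → scan →
score → rank → accept → report.

:func:`run_mapping` is the in-memory core used by tests and the acceptance
script; :func:`run_pipeline` is the file-based wrapper behind the CLI.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .config import RunConfig, version_manifest
from .evolution import build_interolog_msa, classify_positions, write_report
from .mapping import (
    PredictionTable,
    ScoredCandidate,
    SequenceRecord,
    apply_acceptance,
    enumerate_candidates,
    parse_fasta_db,
    rank_within_species,
)
from .matrices import MatrixSet, derive_matrix_set
from .profiles import ChainProfile, build_profile
from .scoring import NullModel, build_null_model
from .structures import (
    TemplateInterface,
    build_template,
    deduplicate_library,
    parse_structure,
    validate_template,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and input context."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class MappingResult:
    templates: list[TemplateInterface]
    matrices: MatrixSet
    profiles: dict[str, tuple[ChainProfile, ChainProfile]]
    nulls: dict[str, NullModel]
    candidates: list[ScoredCandidate] = field(default_factory=list)
    accepted: list[ScoredCandidate] = field(default_factory=list)


def build_template_library(
    pdb_texts: list[tuple[str, str, str, str]],  # (id, pdb_text, chainA, chainB)
    config: RunConfig,
) -> list[TemplateInterface]:
    """Parse, extract interfaces, validate and deduplicate a template library."""
    templates = []
    for template_id, text, chain_a, chain_b in pdb_texts:
        structure = parse_structure(text, structure_id=template_id)
        t = build_template(
            structure, chain_a, chain_b,
            cutoff=config.contact_cutoff,
            hbond_cutoff=config.hbond_cutoff,
            salt_bridge_cutoff=config.salt_bridge_cutoff,
            disulfide_cutoff=config.disulfide_cutoff,
            template_id=template_id,
        )
        verdict = validate_template(
            t,
            min_chain_len=config.min_chain_len,
            min_contact_residues=config.min_contact_residues,
            min_contact_pairs=config.min_contact_pairs,
        )
        if verdict:
            templates.append(t)
        else:
            logger.info("template %s rejected: %s", template_id,
                        "; ".join(verdict.reasons))
    return deduplicate_library(templates, identity_threshold=config.dedup_identity)


def run_mapping(
    templates: list[TemplateInterface],
    db: list[SequenceRecord],
    config: RunConfig,
    matrices: MatrixSet | None = None,
    training_library: list[TemplateInterface] | None = None,
    profiles: dict[str, tuple[ChainProfile, ChainProfile]] | None = None,
    null_n: int | None = None,
) -> MappingResult:
    """Score every template against the sequence database and apply the
    Z / top-rank acceptance cascade.

    Matrices default to being derived from ``training_library`` (or the
    query templates themselves at desk scale); profiles default to
    single-sequence profiles of the template chains.
    """
    if matrices is None:
        matrices, table = derive_matrix_set(
            training_library or templates, pseudocount=config.pseudocount
        )
    else:
        table = None
    from .matrices import count_pairs

    background = (table or count_pairs(training_library or templates)
                  ).interface_background()
    if profiles is None:
        profiles = {
            t.template_id: (
                build_profile([t.chain_a_seq], chain_id=t.chain_a_id),
                build_profile([t.chain_b_seq], chain_id=t.chain_b_id),
            )
            for t in templates
        }
    nulls: dict[str, NullModel] = {}
    candidates: list[ScoredCandidate] = []
    for i, t in enumerate(templates):
        profile_a, profile_b = profiles[t.template_id]
        nulls[t.template_id] = build_null_model(
            t, matrices, profile_a, profile_b, background,
            n_samples=null_n if null_n is not None else config.null_n,
            mutation_fraction=config.null_fraction,
            seed=config.template_seed(i),
            w=config.w,
        )
        candidates.extend(
            enumerate_candidates(
                t, db, profile_a, profile_b, matrices, nulls[t.template_id],
                min_identity=config.min_identity, min_cr=config.min_cr,
                gap_open=config.gap_open, gap_extend=config.gap_extend,
                evalue_max=config.evalue_max, w=config.w,
            )
        )
    if config.rank_by == "e_tot":
        for c in candidates:
            c.z, c._z_backup = c.energy.e_tot, c.z  # rank key switch
        candidates = rank_within_species(candidates)
        for c in candidates:
            c.z = c._z_backup
    else:
        candidates = rank_within_species(candidates)
    accepted = apply_acceptance(
        candidates, z_min=config.z_min, rank_max=config.rank_max,
        strict_z=config.strict_z,
    )
    return MappingResult(
        templates=templates, matrices=matrices, profiles=profiles,
        nulls=nulls, candidates=candidates, accepted=accepted,
    )


def run_pipeline(
    template_specs: list[tuple[str, Path, str, str]],  # (id, pdb path, chainA, chainB)
    db_fasta: Path,
    out_dir: Path,
    config: RunConfig,
) -> MappingResult:
    """File-based pipeline: read PDBs and a FASTA db, write prediction and
    report artifacts plus a provenance manifest into ``out_dir``."""
    t0 = time.time()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    pdb_texts = []
    for template_id, path, chain_a, chain_b in template_specs:
        path = Path(path)
        if not path.exists():
            raise PipelineError("read-input", f"missing PDB file: {path}")
        pdb_texts.append((template_id, path.read_text(), chain_a, chain_b))
    db_fasta = Path(db_fasta)
    if not db_fasta.exists():
        raise PipelineError("read-input", f"missing FASTA file: {db_fasta}")

    try:
        templates = build_template_library(pdb_texts, config)
    except Exception as exc:
        raise PipelineError("build-template", str(exc)) from exc
    if not templates:
        raise PipelineError("build-template", "no template passed validation")

    try:
        db = parse_fasta_db(db_fasta.read_text(),
                            header_regex=config.header_regex)
    except Exception as exc:
        raise PipelineError("read-db", f"{db_fasta}: {exc}") from exc

    try:
        result = run_mapping(templates, db, config)
    except Exception as exc:
        raise PipelineError("scan-score", str(exc)) from exc

    (out_dir / "templates.json").write_text(
        json.dumps([t.to_dict() for t in result.templates], indent=1,
                   sort_keys=True)
    )
    matrix_tsvs = {
        cls: result.matrices.matrix(cls).to_tsv()
        for cls in ("ss_vdw", "sb_vdw", "ss_special", "sb_special")
    }
    for cls, text in matrix_tsvs.items():
        (out_dir / f"matrix_{cls}.tsv").write_text(text)
    (out_dir / "predictions.tsv").write_text(
        PredictionTable(result.candidates).to_tsv()
    )
    (out_dir / "accepted.tsv").write_text(
        PredictionTable(result.accepted).to_tsv()
    )
    for t in result.templates:
        accepted_t = [c for c in result.accepted
                      if c.template_id == t.template_id]
        if not accepted_t:
            continue
        msa_a, msa_b = build_interolog_msa(t, accepted_t)
        annotations = classify_positions(
            msa_a, t, conservation_threshold=config.conservation_threshold
        ) + classify_positions(
            msa_b, t, conservation_threshold=config.conservation_threshold
        )
        (out_dir / f"report_{t.template_id}.tsv").write_text(
            write_report((msa_a, msa_b), annotations, fmt="tsv")
        )
    manifest = version_manifest(
        config, matrix_tsvs=matrix_tsvs,
        extra={
            "n_templates": len(result.templates),
            "n_db_sequences": len(db),
            "n_candidates": len(result.candidates),
            "n_accepted": len(result.accepted),
            "null_seeds": {tid: nm.seed for tid, nm in result.nulls.items()},
            "elapsed_s": round(time.time() - t0, 3),
        },
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return result
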