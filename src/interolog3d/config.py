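"""Run configuration and provenance manifests.

The defaults reproduce every published pipeline threshold: 4.5 Å contact
cutoff, 30-residue minimum chain length, >= 5 contact residues and > 25
contact pairs per template, identity > 30 % and CR > 0.5 candidate filters,
w = 3, Z >= 3.0 with top-25 per-species rank acceptance, and a 10,000-sample
null with 60 % of contact residues mutated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .mapping import DEFAULT_HEADER_REGEX


@dataclass
class RunConfig:
    # template library
    contact_cutoff: float = 4.5
    min_chain_len: int = 30
    min_contact_residues: int = 5
    min_contact_pairs: int = 25
    dedup_identity: float = 0.98
    hbond_cutoff: float = 3.5
    salt_bridge_cutoff: float = 4.0
    disulfide_cutoff: float = 2.5
    # candidate filter
    min_identity: float = 0.30
    min_cr: float = 0.5
    evalue_max: float = 1e-10
    gap_open: float = 11.0
    gap_extend: float = 1.0
    # scoring
    w: float = 3.0
    pseudocount: float = 0.5
    average_sim_cons: bool = False
    # acceptance
    z_min: float = 3.0
    rank_max: int = 25
    strict_z: bool = False
    rank_by: str = "z"  # or "e_tot"
    # null model
    null_n: int = 10000
    null_fraction: float = 0.6
    # evaluation / report
    cc_threshold: float = 0.4
    conservation_threshold: float = 0.7
    # misc
    seed: int = 0
    header_regex: str = DEFAULT_HEADER_REGEX

    def __post_init__(self) -> None:
        for name in (
            "contact_cutoff", "min_chain_len", "min_contact_residues",
            "min_contact_pairs", "min_identity", "min_cr", "w", "z_min",
            "rank_max", "null_n", "null_fraction",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        """Load overrides from a TOML file; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def template_seed(self, index: int) -> int:
        """Stable per-template RNG seed derived from the run seed."""
        return (self.seed * 10007 + index) % (2**31 - 1)


def version_manifest(config: RunConfig, matrix_tsvs: dict[str, str] | None = None,
                     extra: dict | None = None) -> dict:
    """Provenance record: config + hash, seeds, matrix content hashes."""
    from . import __version__

    manifest = {
        "package": "interolog3d",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    if matrix_tsvs:
        manifest["matrix_hashes"] = {
            cls: hashlib.sha256(text.encode()).hexdigest()[:16]
            for cls, text in sorted(matrix_tsvs.items())
        }
    if extra:
        manifest.update(extra)
    return manifest
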