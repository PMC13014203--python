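"""Run configuration shared by the CLI and the pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError


@dataclass
class RunConfig:
    """All tunable constants of the analysis protocol, with their defaults.

    Defaults are the values used throughout: heavy-atom contact cutoff
    0.45 nm, ligand-mediated cutoff 0.6 nm, twin-cutoff hysteresis
    0.45/0.6 nm, periodic-image QC threshold 0.3 nm, sequence-separation
    floor |i-j| >= 4, four blocks for R_g errors, and a fixed 0.55 nm Flory
    prefactor.
    """

    contact_cutoff: float = 0.45      # nm
    mediated_cutoff: float = 0.6      # nm
    r_on: float = 0.45                # nm, twin-cutoff inner threshold
    r_off: float = 0.6                # nm, twin-cutoff outer threshold
    qc_threshold: float = 0.3         # nm, periodic-image minimum distance
    min_separation: int = 4           # sequence-separation floor
    n_blocks: int = 4                 # R_g block averaging
    flory_prefactor: float = 0.55     # nm
    flory_fit_range: tuple[int, int] | None = None
    sign_threshold: float = 0.0       # k_ij classification threshold
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    seed: int = 0
    qc_filter: bool = True            # drop QC-flagged frames per frame
    out_dir: str = "fibrilmod_out"

    def validate(self) -> None:
        if self.r_on >= self.r_off:
            raise ValidationError("r_on must be < r_off")
        if self.min_separation < 1:
            raise ValidationError("min_separation must be >= 1")
        for v in ("contact_cutoff", "mediated_cutoff", "qc_threshold"):
            if getattr(self, v) <= 0:
                raise ValidationError(f"{v} must be positive")

    def to_json(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        doc = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "flory_fit_range" in doc and doc["flory_fit_range"] is not None:
            doc["flory_fit_range"] = tuple(doc["flory_fit_range"])
        if "regions" in doc:
            doc["regions"] = {k: tuple(v) for k, v in doc["regions"].items()}
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def header_lines(self) -> list[str]:
        """Config block embedded at the top of every numeric output file."""
        return [
            f"# contact_cutoff_nm={self.contact_cutoff}",
            f"# mediated_cutoff_nm={self.mediated_cutoff}",
            f"# r_on_nm={self.r_on}\tr_off_nm={self.r_off}",
            f"# qc_threshold_nm={self.qc_threshold}\tqc_filter={self.qc_filter}",
            f"# min_separation={self.min_separation}",
            f"# n_blocks={self.n_blocks}",
            f"# flory_prefactor_nm={self.flory_prefactor}",
            f"# seed={self.seed}",
        ]
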