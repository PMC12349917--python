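"""Run-time configuration shared by the scoring pipeline and the CLI."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """Tunable thresholds of the scoring/ranking pipeline.

    interface_cutoff
        Heavy-atom contact distance (Å) defining interface residues.
    clash_distance
        Heavy-atom distance (Å) below which a cross-chain atom pair
        counts as a steric clash.
    clash_count_threshold / clash_fraction_threshold
        A model is flagged as clashing when the number of clashing atom
        pairs exceeds the absolute count, or when for some chain pair it
        exceeds the given fraction of the smaller chain's atom count.
    penalty
        Ranking deduction applied to clashing models; large enough that
        any clashing model ranks below any clash-free one.
    protein_only
        Score protein chains only, excluding nucleic-acid residues.
    """

    interface_cutoff: float = 4.5
    clash_distance: float = 1.1
    clash_count_threshold: int = 100
    clash_fraction_threshold: float = 0.5
    penalty: float = 100.0
    protein_only: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "interface_cutoff",
            "clash_distance",
            "clash_count_threshold",
            "clash_fraction_threshold",
            "penalty",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a flat key-value JSON config; keyword overrides win."""
        doc = json.loads(Path(path).read_text())
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def to_file(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
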