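"""Design configuration: thresholds for arm trimming, barcodes, and screening.

All thresholds live here and round-trip through YAML so a pool design is
fully reproducible from its config file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .thermo import DuplexParams


@dataclass(frozen=True)
class DesignConfig:
    """Thresholds and conditions for ligamer pool design.

    tm_max : °C, terminal-arm ceiling — arms are trimmed until Tm <= tm_max.
    arm_tm_target / arm_tm_tolerance : °C, internal arms must fall in
        target ± tolerance (default 60 ± 5).
    max_len : nt, total internal ligamer length cap (arms + barcode).
    barcode_length : nt, default barcode width.
    min_hamming : minimum pairwise Hamming distance among barcodes.
    dg_gap_min : kcal/mol, cognate/near-cognate ΔG gap below which a ligamer
        is flagged in the specificity screen.
    min_arm_length : nt, shortest arm considered during design.
    tm_floor : °C, arms below this Tm get a "low_tm" warning flag.
    primer_tail_fwd / primer_tail_rev : amplification tails carried verbatim
        on the terminal ligamers.
    duplex : thermodynamic conditions (salt, strand conc, ΔG temperature).
    """

    tm_max: float = 65.0
    arm_tm_target: float = 60.0
    arm_tm_tolerance: float = 5.0
    max_len: int = 60
    barcode_length: int = 7
    min_hamming: int = 3
    dg_gap_min: float = 5.0
    min_arm_length: int = 8
    tm_floor: float = 40.0
    primer_tail_fwd: str = "ACACGACGCTCTTCCGATCT"
    primer_tail_rev: str = "AGATCGGAAGAGCACACGTC"
    duplex: DuplexParams = field(default_factory=DuplexParams)

    @property
    def arm_tm_window(self) -> tuple[float, float]:
        """Internal-arm Tm window [low, high] in °C (high also capped by tm_max)."""
        low = self.arm_tm_target - self.arm_tm_tolerance
        high = min(self.arm_tm_target + self.arm_tm_tolerance, self.tm_max)
        return low, high

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesignConfig":
        data = yaml.safe_load(Path(path).read_text())
        duplex = data.pop("duplex", None)
        cfg = cls(**data) if duplex is None else cls(duplex=DuplexParams(**duplex), **data)
        return cfg
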