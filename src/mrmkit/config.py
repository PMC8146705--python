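"""Run configuration: every stage's tunable parameters in one serializable
object, with defaults matching the published nine-legume assay conventions
(tryptic digestion with no missed cleavages under the Keil rule; 6–20 aa
cysteine-free markers; product ions above m/z 250, five candidates narrowed
to three scheduled transitions in a 40 s window; S/N ≥ 3 detection with the
strict all-three-markers species rule; 80–120 % recovery band)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .digestion import DigestParams
from .selection import SelectionCriteria

__all__ = ["TransitionRules", "QuantOptions", "Config"]


@dataclass(frozen=True)
class TransitionRules:
    min_product_mz: float = 250.0
    candidates_per_marker: int = 5
    transitions_per_marker: int = 3
    window_s: float = 40.0


@dataclass(frozen=True)
class QuantOptions:
    band_low: float = 80.0
    band_high: float = 120.0
    snr_threshold: float = 3.0
    species_rule: str = "all3"  # or "any1"
    signal_mode: str = "top"  # or "sum"


@dataclass
class Config:
    digestion: DigestParams = field(default_factory=DigestParams)
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    transitions: TransitionRules = field(default_factory=TransitionRules)
    quant: QuantOptions = field(default_factory=QuantOptions)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection"]["forbidden_residues"] = sorted(
            self.selection.forbidden_residues
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Config":
        sel = dict(d.get("selection", {}))
        if "forbidden_residues" in sel:
            sel["forbidden_residues"] = frozenset(sel["forbidden_residues"])
        return cls(
            digestion=DigestParams(**d.get("digestion", {})),
            selection=SelectionCriteria(**sel),
            transitions=TransitionRules(**d.get("transitions", {})),
            quant=QuantOptions(**d.get("quant", {})),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "Config":
        if hasattr(source, "read"):
            data = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(source)
        return cls.from_dict(data or {})
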