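"""Audit log of per-arm scoring decisions.

Value-framework scores are only as trustworthy as their provenance, so the
engines never substitute a default or an override silently: every such
decision lands here, one section per scored arm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class RunLog:
    rule_table_version: str = "unversioned"
    fixture_phase: str = ""
    sections: dict[str, list[str]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def note(self, arm_id: str, message: str) -> None:
        self.sections.setdefault(arm_id, []).append(message)

    def warn(self, message: str) -> None:
        self.warnings.append(message)

    def to_dict(self) -> dict:
        return {
            "rule_table_version": self.rule_table_version,
            "fixture_phase": self.fixture_phase,
            "sections": self.sections,
            "warnings": self.warnings,
        }

    def to_text(self) -> str:
        lines = [f"rule table: {self.rule_table_version}"]
        if self.fixture_phase:
            lines.append(f"fixture phase: {self.fixture_phase}")
        for arm, notes in self.sections.items():
            lines.append(f"[{arm}]")
            lines.extend(f"  - {n}" for n in notes)
        if self.warnings:
            lines.append("[warnings]")
            lines.extend(f"  ! {w}" for w in self.warnings)
        return "\n".join(lines) + "\n"

    def write(self, path: str | Path, format: str = "json") -> None:
        path = Path(path)
        if format == "json":
            path.write_text(json.dumps(self.to_dict(), indent=1) + "\n")
        else:
            path.write_text(self.to_text())
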