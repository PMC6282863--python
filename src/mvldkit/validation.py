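"""Structured validation reporting.

Validators in this package never raise on rule violations; they return a
:class:`ValidationReport` listing every finding with a stable rule
identifier, a severity, and the dotted path of the offending field, so a
curator (or the CLI) sees all problems at once.
"""

from __future__ import annotations

from pydantic import BaseModel, Field


class Issue(BaseModel):
    """One rule violation or advisory finding."""

    rule_id: str
    severity: str  # "error" | "warning"
    field_path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.rule_id} {self.field_path}: {self.message}"


class ValidationReport(BaseModel):
    """All findings for one entity; valid iff no error-severity issue."""

    issues: list[Issue] = Field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def add(self, rule_id: str, severity: str, field_path: str, message: str) -> None:
        self.issues.append(
            Issue(rule_id=rule_id, severity=severity, field_path=field_path, message=message)
        )

    def error(self, rule_id: str, field_path: str, message: str) -> None:
        self.add(rule_id, "error", field_path, message)

    def warning(self, rule_id: str, field_path: str, message: str) -> None:
        self.add(rule_id, "warning", field_path, message)
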