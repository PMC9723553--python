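"""Record- and table-level conformance checking against the registry.

Severity policy: a missing mandatory (M) term is an ERROR; a missing
conditional (C) term is INFO by default — "conditional" conventionally means
mandatory-when-applicable and applicability is study-specific — upgradable to
ERROR globally (``strict_conditional``) or per applicability rule; attributes
unknown to the registry are WARNINGs, mirroring archive practice of accepting
extra attributes; attributes that belong only to other packages are WARNINGs.
The two core terms apply to records of every package: they are recognized and
syntax-checked wherever they appear, and their absence is never an issue.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from .errors import PackageNotFoundError, ValueSyntaxError
from .records import RELATIONSHIP_TERM, MetadataTable, SampleRecord, parse_value
from .registry import CORE_PACKAGE, Registry

__all__ = [
    "ValidationIssue",
    "ValidationReport",
    "ValidatorConfig",
    "ApplicabilityRule",
    "validate_record",
    "validate_table",
    "summarize_report",
    "ISSUE_CODES",
]

SEVERITIES = ("ERROR", "WARNING", "INFO")

#: Closed set of issue codes a report may contain.
ISSUE_CODES = frozenset(
    {
        "MISSING_MANDATORY",
        "MISSING_CONDITIONAL",
        "UNKNOWN_TERM",
        "PACKAGE_MISMATCH",
        "VALUE_SYNTAX",
        "NOT_IN_ENUMERATION",
        "HOST_OF_HOST_ID_INCOMPLETE",
        "DUPLICATE_SAMPLE",
        "PACKAGE_NOT_FOUND",
        # graph-level codes merged in when a graph check runs
        "BAD_PREDICATE",
        "BAD_TARGET",
        "SELF_RELATION",
        "DANGLING_REFERENCE",
        "CONTAINMENT_CYCLE",
        "TEMPORAL_CYCLE",
        "CONTRADICTORY_RELATION",
        "REPLICATE_PACKAGE_MISMATCH",
    }
)


@dataclass(frozen=True)
class ValidationIssue:
    severity: str
    code: str
    sample_id: str | None
    term: str | None
    message: str

    def sort_key(self) -> tuple:
        return (
            SEVERITIES.index(self.severity),
            self.sample_id or "",
            self.term or "",
            self.code,
            self.message,
        )


@dataclass(frozen=True)
class ApplicabilityRule:
    """'term must be present when <when_term> equals <equals>' — promotes a
    conditional term to mandatory for matching records."""

    term: str
    when_term: str
    equals: str


@dataclass
class ValidatorConfig:
    strict_conditional: bool = False
    #: canonical term name -> allowed values, for free-text terms a study
    #: wants to pin to a controlled vocabulary.
    enumerations: dict[str, list[str]] = field(default_factory=dict)
    applicability: list[ApplicabilityRule] = field(default_factory=list)


@dataclass
class ValidationReport:
    issues: list[ValidationIssue]

    def __post_init__(self) -> None:
        self.issues = sorted(self.issues, key=ValidationIssue.sort_key)

    @property
    def counts(self) -> dict[str, int]:
        return {s: sum(1 for i in self.issues if i.severity == s) for s in SEVERITIES}

    @property
    def valid(self) -> bool:
        return self.counts["ERROR"] == 0

    def to_tsv(self) -> str:
        out = io.StringIO()
        out.write("severity\tcode\tsample_id\tterm\tmessage\n")
        for i in self.issues:
            out.write(
                f"{i.severity}\t{i.code}\t{i.sample_id or ''}\t{i.term or ''}\t{i.message}\n"
            )
        return out.getvalue()


def _conditional_is_required(
    record: SampleRecord, term_name: str, config: ValidatorConfig
) -> bool:
    if config.strict_conditional:
        return True
    for rule in config.applicability:
        if rule.term == term_name and record.attributes.get(rule.when_term) == rule.equals:
            return True
    return False


def validate_record(
    record: SampleRecord,
    registry: Registry,
    config: ValidatorConfig | None = None,
) -> list[ValidationIssue]:
    """Check one record against its package's checklist.

    Raises ``PACKAGE_NOT_FOUND`` if the record's package is unknown (no report
    can be produced without a checklist to check against).
    """
    config = config or ValidatorConfig()
    package = registry.get_package(record.package)
    issues: list[ValidationIssue] = []

    present = set(record.attributes)
    if record.relationship_entries:
        present.add(RELATIONSHIP_TERM)

    for term in registry.terms_for_package(package.name):
        level = term.requirement(package.name)
        if term.canonical_name in present:
            continue
        if level == "M":
            issues.append(
                ValidationIssue(
                    "ERROR",
                    "MISSING_MANDATORY",
                    record.sample_id,
                    term.canonical_name,
                    f"mandatory term '{term.display_name}' absent from "
                    f"{package.name} record",
                )
            )
        elif level == "C":
            required = _conditional_is_required(record, term.canonical_name, config)
            issues.append(
                ValidationIssue(
                    "ERROR" if required else "INFO",
                    "MISSING_CONDITIONAL",
                    record.sample_id,
                    term.canonical_name,
                    f"conditional term '{term.display_name}' absent"
                    + (" (required by applicability rule)" if required else ""),
                )
            )

    for attr, raw in record.attributes.items():
        if not registry.has_term(attr):
            issues.append(
                ValidationIssue(
                    "WARNING",
                    "UNKNOWN_TERM",
                    record.sample_id,
                    attr,
                    f"attribute {attr!r} is not a registered term",
                )
            )
            continue
        term = registry.get_term(attr)
        if package.name not in term.packages and CORE_PACKAGE not in term.packages:
            issues.append(
                ValidationIssue(
                    "WARNING",
                    "PACKAGE_MISMATCH",
                    record.sample_id,
                    term.canonical_name,
                    f"term '{term.display_name}' belongs to "
                    f"{'/'.join(term.packages)}, not to {package.name}",
                )
            )
        try:
            parse_value(term, raw)
        except ValueSyntaxError as exc:
            issues.append(
                ValidationIssue(
                    "ERROR",
                    "VALUE_SYNTAX",
                    record.sample_id,
                    term.canonical_name,
                    str(exc),
                )
            )
            continue
        allowed = config.enumerations.get(term.canonical_name)
        if allowed is not None and raw not in allowed:
            issues.append(
                ValidationIssue(
                    "ERROR",
                    "NOT_IN_ENUMERATION",
                    record.sample_id,
                    term.canonical_name,
                    f"value {raw!r} not in configured vocabulary {allowed}",
                )
            )

    # advisory nudge: the host-of-host taxon id and subject id identify the
    # same organism two ways; reporting only one is suspicious but legal.
    pair = ("host_of_the_symbiotic_host_taxon_id", "host_of_the_symbiotic_host_subject_id")
    present_pair = [t for t in pair if t in record.attributes]
    if len(present_pair) == 1:
        issues.append(
            ValidationIssue(
                "WARNING",
                "HOST_OF_HOST_ID_INCOMPLETE",
                record.sample_id,
                present_pair[0],
                "only one of host-of-host taxon id / subject id is reported",
            )
        )
    return issues


def validate_table(
    table: MetadataTable,
    registry: Registry,
    config: ValidatorConfig | None = None,
    with_graph: bool = False,
) -> ValidationReport:
    """Validate every record, plus table-level checks.

    With ``with_graph``, the relationship graph is built and structurally
    validated and its issues merged into the same report.
    """
    issues: list[ValidationIssue] = []
    seen: set[str] = set()
    for record in table.records:
        if record.sample_id in seen:
            issues.append(
                ValidationIssue(
                    "ERROR",
                    "DUPLICATE_SAMPLE",
                    record.sample_id,
                    None,
                    f"sample_id {record.sample_id!r} appears more than once",
                )
            )
        seen.add(record.sample_id)
        try:
            issues.extend(validate_record(record, registry, config))
        except PackageNotFoundError as exc:
            # table-level validation degrades the hard error to a reportable
            # issue so the rest of the table is still checked
            issues.append(
                ValidationIssue(
                    "ERROR", "PACKAGE_NOT_FOUND", record.sample_id, None, str(exc)
                )
            )
    if with_graph:
        from . import relgraph  # local import: relgraph depends on this module

        graph = relgraph.build_graph(table)
        issues.extend(graph.issues)
        issues.extend(relgraph.validate_graph(graph))
    return ValidationReport(issues)


def summarize_report(report: ValidationReport) -> str:
    """One deterministic line per severity, or 'valid' for an empty report."""
    if not report.issues:
        return "valid"
    lines = [f"{severity}: {report.counts[severity]}" for severity in SEVERITIES]
    lines.append("valid" if report.valid else "invalid")
    return "\n".join(lines)
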