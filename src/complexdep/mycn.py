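"""Rule-based MYCN amplification-status classifier for neuroblastoma lines.

Each cell line is classified from three pieces of evidence: MYCN copy number
on the log2(CN/2 + 1) scale, MYCN expression on the log2(TPM + 1) scale, and
an optional previously reported status from the literature. Four rules are
evaluated in order; the first match wins:

1. High copy number (cn >= 3) calls ``amplified`` — unless the line was
   reported ``not_amplified``, which makes the evidence ``inconsistent``.
2. Medium copy number (1.10 <= cn < 3) with high expression (expr >= 5)
   or a reported ``amplified`` status calls ``amplified``.
3. Medium copy number with low expression (expr < 3) or a reported
   ``not_amplified`` status calls ``not_amplified``.
4. Low copy number (cn < 1.10) with high expression (expr >= 5) and a
   reported ``not_amplified`` status is ``inconsistent``.

Evidence matching no rule (e.g. medium copy number with intermediate
expression and no report) is ``undetermined`` rather than guessed.

Boundary conventions: the medium-copy-number interval is closed on the left
and open on the right, [1.10, 3), so rules 1 and 2 are disjoint and cn = 3
falls under rule 1. When medium-copy-number evidence conflicts (expr >= 5
together with a reported ``not_amplified``), rule order decides — rule 2
fires — and the call carries a warning.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "MycnEvidence",
    "MycnCall",
    "classify_mycn",
    "classify_mycn_table",
    "CN_HIGH",
    "CN_MEDIUM_LOW",
    "EXPR_HIGH",
    "EXPR_LOW",
]

# log2(CN/2 + 1) and log2(TPM + 1) thresholds of the four rules.
CN_HIGH = 3.0
CN_MEDIUM_LOW = 1.10
EXPR_HIGH = 5.0
EXPR_LOW = 3.0

_STATUSES = ("amplified", "not_amplified", "none")


@dataclass(frozen=True)
class MycnEvidence:
    """Per-line classifier input.

    Parameters
    ----------
    line
        Cell-line identifier.
    cn
        MYCN copy number, log2(CN/2 + 1); must be >= 0.
    expr
        MYCN expression, log2(TPM + 1); must be >= 0.
    reported_status
        Literature-reported status: ``amplified``, ``not_amplified`` or
        ``none`` when no report exists.
    """

    line: str
    cn: float
    expr: float
    reported_status: str = "none"

    def __post_init__(self) -> None:
        if self.cn < 0:
            raise ValueError(f"{self.line}: copy number must be >= 0, got {self.cn}")
        if self.expr < 0:
            raise ValueError(f"{self.line}: expression must be >= 0, got {self.expr}")
        if self.reported_status not in _STATUSES:
            raise ValueError(
                f"{self.line}: reported_status must be one of {_STATUSES}, "
                f"got {self.reported_status!r}"
            )


@dataclass(frozen=True)
class MycnCall:
    """Classifier verdict: status, the rule that fired, and any warning."""

    line: str
    status: str  # amplified | not_amplified | inconsistent | undetermined
    rule_fired: int | None  # 1..4, or None when no rule matched
    warning: str | None = None


def classify_mycn(evidence: MycnEvidence) -> MycnCall:
    """Classify one cell line's MYCN status by the four ordered rules."""
    cn, expr, reported = evidence.cn, evidence.expr, evidence.reported_status

    # Rule 1: high copy number.
    if cn >= CN_HIGH:
        if reported == "not_amplified":
            return MycnCall(evidence.line, "inconsistent", 1)
        return MycnCall(evidence.line, "amplified", 1)

    medium = CN_MEDIUM_LOW <= cn < CN_HIGH
    # Rule 2: medium copy number, high expression and/or reported amplified.
    if medium and (expr >= EXPR_HIGH or reported == "amplified"):
        warning = None
        if expr >= EXPR_HIGH and reported == "not_amplified":
            warning = (
                "expression >= 5 conflicts with reported not_amplified; "
                "rule order resolves in favor of rule 2 (amplified)"
            )
        return MycnCall(evidence.line, "amplified", 2, warning)

    # Rule 3: medium copy number, low expression and/or reported not amplified.
    if medium and (expr < EXPR_LOW or reported == "not_amplified"):
        return MycnCall(evidence.line, "not_amplified", 3)

    # Rule 4: low copy number but high expression, despite a not-amplified report.
    if cn < CN_MEDIUM_LOW and expr >= EXPR_HIGH and reported == "not_amplified":
        return MycnCall(evidence.line, "inconsistent", 4)

    return MycnCall(evidence.line, "undetermined", None)


def classify_mycn_table(annotations: pd.DataFrame) -> pd.DataFrame:
    """Classify every line of an annotation table.

    Parameters
    ----------
    annotations
        DataFrame indexed by cell line with columns ``mycn_cn`` (log2(CN/2+1)),
        ``mycn_expr`` (log2(TPM+1)) and optionally ``reported_mycn_status``.

    Returns
    -------
    DataFrame indexed like the input with columns ``status``, ``rule_fired``
    and ``warning``.
    """
    rows = []
    for line, row in annotations.iterrows():
        ev = MycnEvidence(
            line=str(line),
            cn=float(row["mycn_cn"]),
            expr=float(row["mycn_expr"]),
            reported_status=str(row.get("reported_mycn_status", "none") or "none"),
        )
        call = classify_mycn(ev)
        rows.append((line, call.status, call.rule_fired, call.warning))
    out = pd.DataFrame(rows, columns=["line", "status", "rule_fired", "warning"])
    return out.set_index("line")
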