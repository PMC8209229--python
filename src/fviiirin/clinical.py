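"""Clinical hemophilia A mutation-table sanitation and enrichment tests.

Raw exports of hemophilia A missense-variant tables mix numeric FVIII:C
activities with ranges ("10 to 24"), bound strings ("< 1", "> 5"),
duplicated assays and ambiguous severity labels.  :func:`sanitize_records`
applies, in a fixed order, the curation rules needed to obtain one finite
FVIII:C percentage per record, logging the rule that removed or transformed
each record.  :func:`fisher_association` links residue-position groups to
the presence of reported disease mutations with a two-sided Fisher exact
test.  :func:`legacy_to_hgvs` converts legacy mature-protein numbering to
HGVS numbering (which counts the 19-residue signal peptide).
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

SIGNAL_PEPTIDE_OFFSET = 19
MATURE_LENGTH = 2332  # residues in the mature FVIII protein

#: conventional FVIII:C severity bands (% of normal), used only to detect
#: ranges that straddle a diagnostic boundary
SEVERITY_BANDS = {"severe": (0.0, 1.0), "moderate": (1.0, 5.0),
                  "mild": (5.0, 40.0)}
SEVERITY_BOUNDARIES = (1.0, 5.0, 40.0)

KEEP_MUTATION_TYPES = {"point", "polymorphism"}
KEEP_VARIANT_EFFECTS = {"missense"}
VALID_SEVERITIES = {"mild", "moderate", "severe"}

SCHEMA_COLUMNS = ["mutation_type", "variant_effect", "position_legacy",
                  "fviii_c_raw", "severity_reported"]

#: substitution rules for bound strings, applied before range parsing
BOUND_SUBSTITUTIONS = [
    (re.compile(r"^>\s*5$"), 5.0),
    (re.compile(r"^<\s*10$"), 10.0),
    (re.compile(r"^<\s*11$"), 11.0),
    (re.compile(r"^<\s*1$"), 0.0),
]

_RANGE_RE = re.compile(r"^(\S+)\s+to\s+(\S+)$", re.IGNORECASE)


def _clean(text) -> str:
    """Whitespace/unicode-tolerant normalisation of a raw cell."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return ""
    s = unicodedata.normalize("NFKC", str(text))
    return re.sub(r"\s+", " ", s).strip()


def _parse_number(token: str) -> Optional[float]:
    try:
        return float(token)
    except ValueError:
        return None


def parse_fviii_c(raw) -> Tuple[Optional[float], str]:
    """Parse one FVIII:C cell.

    Returns ``(value, rule)`` where rule names the transformation applied,
    or ``(None, rule)`` when the cell must be dropped.
    """
    s = _clean(raw)
    if not s:
        return None, "missing_activity"
    for pattern, value in BOUND_SUBSTITUTIONS:
        if pattern.match(s):
            return value, "bound_substitution"
    m = _RANGE_RE.match(s)
    if m:
        a, b = _parse_number(m.group(1)), _parse_number(m.group(2))
        if a is None or b is None:
            return None, "ambiguous_range"
        lo, hi = min(a, b), max(a, b)
        if any(lo < cut < hi for cut in SEVERITY_BOUNDARIES):
            return None, "ambiguous_range"  # spans a diagnostic boundary
        return (a + b) / 2.0, "range_average"
    v = _parse_number(s)
    if v is None:
        return None, "non_numeric_activity"
    return v, "numeric"


def sanitize_records(raw: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Sanitize a raw clinical mutation table.

    Returns ``(clean, log)``; the log has one row per input record with the
    rule that excluded it (or the transformation applied when kept).
    Running the sanitizer on its own output is a no-op.
    """
    for col in SCHEMA_COLUMNS:
        if col not in raw.columns:
            raise KeyError(f"missing schema column {col!r}")
    kept_rows: List[dict] = []
    log_rows: List[dict] = []

    def exclude(idx, rule, value):
        log_rows.append({"record_id": idx, "action": "excluded",
                         "rule": rule, "raw_value": value})

    for idx, row in raw.iterrows():
        mtype = _clean(row["mutation_type"]).lower()
        effect = _clean(row["variant_effect"]).lower()
        if mtype not in KEEP_MUTATION_TYPES or effect not in KEEP_VARIANT_EFFECTS:
            exclude(idx, "type_effect_filter", f"{mtype}/{effect}")
            continue
        try:
            pos = int(row["position_legacy"])
        except (TypeError, ValueError):
            exclude(idx, "unparseable_position", row["position_legacy"])
            continue
        if pos < 1 or pos > MATURE_LENGTH:
            exclude(idx, "signal_peptide_or_out_of_mature", pos)
            continue
        sev = _clean(row["severity_reported"]).lower()
        if sev not in VALID_SEVERITIES:
            exclude(idx, "ambiguous_severity", row["severity_reported"])
            continue
        change = _clean(row.get("protein_change", ""))
        if change and (change.endswith("*") or change.lower().endswith("ter")
                       or "stop" in change.lower()):
            exclude(idx, "stop_codon", change)
            continue
        raw_act = row["fviii_c_raw"]
        value, rule = parse_fviii_c(raw_act)
        if value is None:
            exclude(idx, rule, raw_act)
            continue
        if value > 100.0:
            exclude(idx, "activity_above_100", raw_act)
            continue
        # duplicated assays must agree when both present
        first = _clean(row.get("fviii_c_1st", ""))
        second = _clean(row.get("fviii_c_2st", ""))
        if first and second:
            v1, _ = parse_fviii_c(first)
            v2, _ = parse_fviii_c(second)
            if v1 is not None and v2 is not None and abs(v1 - v2) > 1e-9:
                exclude(idx, "assay_discrepancy", f"{first} vs {second}")
                continue
        out = dict(row)
        out["fviii_c_value"] = float(value)
        out["fviii_c_raw"] = str(value) if rule != "numeric" else _clean(raw_act)
        out["severity_reported"] = sev
        kept_rows.append({"record_id": idx, **out})
        log_rows.append({"record_id": idx, "action": "kept", "rule": rule,
                         "raw_value": raw_act})

    clean = pd.DataFrame(kept_rows)
    if len(clean):
        clean = clean.set_index("record_id")
    log = pd.DataFrame(log_rows)
    return clean, log


def fisher_association(group_a_positions: Set[int], group_b_positions: Set[int],
                       reported_positions: Set[int]) -> dict:
    """2x2 Fisher exact association of two position groups with disease.

    Rows are the groups, columns whether a position has at least one
    reported mutation; the p-value is the two-sided exact hypergeometric
    tail, the odds ratio the cross-product estimate (infinity on a zero
    denominator cell).  A zero margin yields p = 1 with a warning.
    """
    import warnings

    if not group_a_positions or not group_b_positions:
        raise ValueError("both groups must be nonempty")
    if group_a_positions & group_b_positions:
        raise ValueError("groups must be disjoint")
    a_hit = len(group_a_positions & reported_positions)
    a_miss = len(group_a_positions) - a_hit
    b_hit = len(group_b_positions & reported_positions)
    b_miss = len(group_b_positions) - b_hit
    table = [[a_hit, a_miss], [b_hit, b_miss]]
    if min(a_hit + b_hit, a_miss + b_miss) == 0:
        warnings.warn("degenerate margin; association undefined, p = 1")
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    if a_miss * b_hit == 0:
        odds = math.inf if a_hit * b_miss > 0 else 1.0
    else:
        odds = (a_hit * b_miss) / (a_miss * b_hit)
    return {"table": table, "odds_ratio": odds, "p_value": float(p),
            "test_name": "fisher_exact_two_sided"}


def legacy_to_hgvs(position_legacy: int) -> int:
    """Legacy mature-protein position -> HGVS position (+19 signal peptide)."""
    if position_legacy < 1:
        raise ValueError("legacy position must be >= 1")
    return position_legacy + SIGNAL_PEPTIDE_OFFSET
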