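"""Group summaries (mean +/- SEM), Student's t-test and report assembly.

The two-sample test is implemented from the closed-form pooled-variance
formula (Welch's variant available by flag), with the p-value from the t
distribution; both variants are two-sided.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
from scipy import stats as _sps


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float  # sample sd / sqrt(n); NaN at n = 1
    values: np.ndarray = field(repr=False, default=None)


@dataclass
class ComparisonResult:
    group_a: GroupSummary
    group_b: GroupSummary
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str = "pooled"


def summarise(values, label: str = "") -> GroupSummary:
    """Mean and standard error of the mean (sample sd, n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarise an empty sample")
    n = v.size
    sem = float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(label=label, n=n, mean=float(v.mean()), sem=sem, values=v)


def students_t_test(a, b, variant: str = "pooled") -> ComparisonResult:
    """Two-sided two-sample t-test.

    ``variant="pooled"`` is the classic Student test (equal-variance
    pooling, df = n_a + n_b - 2); ``variant="welch"`` uses separate
    variances with Welch-Satterthwaite degrees of freedom.  Two groups
    with zero variance and equal means give t = 0, p = 1.
    """
    ga = summarise(a, "a")
    gb = summarise(b, "b")
    if ga.n < 2 or gb.n < 2:
        raise ValueError("each group needs at least 2 values")
    va = ga.values.var(ddof=1)
    vb = gb.values.var(ddof=1)
    diff = ga.mean - gb.mean
    if variant == "pooled":
        df = ga.n + gb.n - 2
        sp2 = ((ga.n - 1) * va + (gb.n - 1) * vb) / df
        se = math.sqrt(sp2 * (1 / ga.n + 1 / gb.n))
    elif variant == "welch":
        se2a, se2b = va / ga.n, vb / gb.n
        se = math.sqrt(se2a + se2b)
        if se > 0:
            df = (se2a + se2b) ** 2 / (
                se2a ** 2 / (ga.n - 1) + se2b ** 2 / (gb.n - 1)
            )
        else:
            df = ga.n + gb.n - 2
    else:
        raise ValueError("variant must be 'pooled' or 'welch'")
    if se == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = math.copysign(math.inf, diff)
            p = 0.0
    else:
        t_stat = diff / se
        p = 2.0 * float(_sps.t.sf(abs(t_stat), df))
    return ComparisonResult(
        group_a=ga,
        group_b=gb,
        t_statistic=float(t_stat),
        degrees_of_freedom=float(df),
        p_value=p,
        variant=variant,
    )


def round_report(value: float, kind: str = "value") -> float:
    """Report-time rounding: percentages to the nearest percent, other
    quantities to 3 significant figures.  Raw precision always stays in
    the machine-readable output."""
    if np.isnan(value):
        return value
    if kind == "percent":
        return float(round(value))
    if value == 0:
        return 0.0
    digits = 2 - int(math.floor(math.log10(abs(value))))
    return float(round(value, digits))


DEFAULT_SECTIONS = (
    "expression",
    "cilia",
    "scratch",
    "migration",
    "force_features",
)


def build_report(
    stages: Mapping[str, Any],
    expected_sections: tuple[str, ...] = DEFAULT_SECTIONS,
    reference: Mapping[str, float] | None = None,
    rel_flag: float = 0.10,
) -> tuple[str, dict]:
    """Assemble the cross-stage reproduction report.

    ``stages`` maps section names to dicts of quantity name -> computed
    value (floats); a missing or None section is rendered as *absent*,
    never silently skipped.  ``reference`` optionally maps
    ``"section.quantity"`` to an expected value; computed values within
    ``rel_flag`` relative difference are marked ``ok``, others ``flag``.

    Returns (markdown document, machine-readable dict).  Deterministic
    given the inputs.
    """
    reference = reference or {}
    lines = ["# Reproduction report", ""]
    payload: dict[str, Any] = {}
    for section in expected_sections:
        data = stages.get(section)
        lines.append(f"## {section}")
        if data is None:
            lines.append("")
            lines.append("*absent* — stage output missing")
            lines.append("")
            payload[section] = None
            continue
        payload[section] = {}
        lines.append("")
        lines.append("| quantity | computed | reference | status |")
        lines.append("|---|---|---|---|")
        for name, value in data.items():
            key = f"{section}.{name}"
            ref = reference.get(key)
            if ref is None:
                status = ""
                ref_txt = ""
            else:
                ok = (
                    abs(value - ref) <= rel_flag * abs(ref)
                    if ref != 0
                    else abs(value) <= rel_flag
                )
                status = "ok" if ok else "flag"
                ref_txt = f"{ref:g}"
            lines.append(f"| {name} | {value:.6g} | {ref_txt} | {status} |")
            payload[section][name] = {
                "value": float(value),
                "reference": ref,
                "status": status or None,
            }
        lines.append("")
    return "\n".join(lines), payload


def report_to_json(payload: dict) -> str:
    return json.dumps(payload, indent=2, sort_keys=True)
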