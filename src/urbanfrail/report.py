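"""Assemble the study-shaped analysis report.

The report mirrors the result surface of a quartile-stratified urban-quality
study: demographics and cluster distribution by frailty status (table2),
frailty metrics by index quartile with top-vs-bottom contrasts (table3), the
analyte-vs-index Spearman panel on the lab subset (table4), facility-distance
contrasts by frailty status (fig3), index-vs-frailty-score regressions and
the index contrast by status (fig4), and the CONUT contrast and fit (fig6).

Every cell is traceable to a StatResult/CorrelationResult; report assembly is
deterministic and invariant to participant row order. Contrasts that cannot
be computed (e.g. an empty group) are emitted as ``"not computable"`` rather
than failing the whole report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats as sps

from .facilities import FacilityType
from .index import QUARTILE_NAMES
from .stats import correlate, linear_fit, proportion_compare, two_group_compare

NOT_COMPUTABLE = "not computable"

REQUIRED_COLUMNS = (
    "participant_id", "age", "sex", "bmi", "handgrip_kg", "gait_speed_ms",
    "fts5_total", "frail", "index", "quartile", "cluster",
)

LAB_COLUMNS = (
    "bilirubin", "serum_iron", "transferrin_sat", "rbc", "rdw",
    "albumin", "lymphocytes", "cholesterol", "conut_total",
)


@dataclass
class AnalysisReport:
    table2: dict[str, Any] = field(default_factory=dict)
    table3: dict[str, Any] = field(default_factory=dict)
    table4: dict[str, Any] = field(default_factory=dict)
    fig3: dict[str, Any] = field(default_factory=dict)
    fig4: dict[str, Any] = field(default_factory=dict)
    fig6: dict[str, Any] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _mean_sd(x) -> dict[str, float]:
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"n": 0}
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
        "n": int(x.size),
    }


def _try_contrast(x, y, **kw) -> Any:
    try:
        return asdict(two_group_compare(x, y, **kw))
    except ValueError:
        return NOT_COMPUTABLE


def _try_proportions(k1, n1, k2, n2) -> Any:
    try:
        return asdict(proportion_compare(k1, n1, k2, n2))
    except ValueError:
        return NOT_COMPUTABLE


def build_report(frame: pd.DataFrame, test_method: str = "auto") -> AnalysisReport:
    """Build the full report from an analysis frame.

    ``frame`` must carry the scored, indexed cohort (one row per
    participant): demographics, ``fts5_total``/``frail``, ``index``/
    ``quartile``, per-facility ``dist_*`` columns and, for lab-subset rows,
    the analyte panel plus ``conut_total`` (others NaN or absent).
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    df = frame.sort_values("participant_id").reset_index(drop=True)
    rep = AnalysisReport()

    frail = df[df["frail"] == 1]
    nonfrail = df[df["frail"] == 0]

    # --- table 2: demographics + cluster distribution by frailty status
    t2: dict[str, Any] = {
        "n_nonfrail": int(len(nonfrail)),
        "n_frail": int(len(frail)),
    }
    t2["female"] = _try_proportions(
        int((nonfrail["sex"] == "F").sum()), len(nonfrail),
        int((frail["sex"] == "F").sum()), len(frail),
    )
    for var in ("age", "bmi"):
        t2[var] = {
            "nonfrail": _mean_sd(nonfrail[var]),
            "frail": _mean_sd(frail[var]),
            "test": _try_contrast(nonfrail[var], frail[var], method=test_method),
        }
    clusters: dict[str, Any] = {}
    for c in sorted(df["cluster"].unique()):
        clusters[f"cluster_{int(c)}"] = _try_proportions(
            int((nonfrail["cluster"] == c).sum()), max(len(nonfrail), 1),
            int((frail["cluster"] == c).sum()), max(len(frail), 1),
        )
    t2["clusters"] = clusters
    rep.table2 = t2

    # --- table 3: metrics by index quartile + Q4-vs-Q1 contrasts
    groups = {q: df[df["quartile"] == q] for q in QUARTILE_NAMES}
    t3: dict[str, Any] = {"edges": {}, "quartiles": {}}
    for q, g in groups.items():
        entry: dict[str, Any] = {"n": int(len(g))}
        if len(g):
            entry["index_range"] = [float(g["index"].min()), float(g["index"].max())]
            entry["frail_pct"] = float(100 * g["frail"].mean())
            for var in ("fts5_total", "handgrip_kg", "gait_speed_ms", "bmi"):
                entry[var] = _mean_sd(g[var])
        t3["quartiles"][q] = entry
    # omnibus ANOVA across quartiles with >= 2 members
    t3["anova"] = {}
    for var in ("fts5_total", "handgrip_kg", "gait_speed_ms", "bmi"):
        samples = [g[var].to_numpy(float) for g in groups.values() if len(g) >= 2]
        if len(samples) >= 2:
            f, p = sps.f_oneway(*samples)
            t3["anova"][var] = {"F": float(f), "p_value": float(p)}
        else:
            t3["anova"][var] = NOT_COMPUTABLE
    q1, q4 = groups["Q1"], groups["Q4"]
    t3["q4_vs_q1"] = {
        "frail": _try_proportions(
            int(q4["frail"].sum()), max(len(q4), 1), int(q1["frail"].sum()), max(len(q1), 1)
        )
        if len(q1) and len(q4)
        else NOT_COMPUTABLE,
    }
    for var in ("fts5_total", "handgrip_kg", "gait_speed_ms", "bmi"):
        t3["q4_vs_q1"][var] = (
            _try_contrast(q4[var], q1[var], method=test_method)
            if len(q1) and len(q4)
            else NOT_COMPUTABLE
        )
    rep.table3 = t3

    # --- table 4: Spearman panel (lab subset only)
    lab = df[df.get("in_lab_subset", pd.Series(1, index=df.index)) == 1]
    t4: dict[str, Any] = {"n": int(len(lab)), "correlations": {}}
    for col in LAB_COLUMNS:
        if col not in lab.columns:
            continue
        vals = lab[col].to_numpy(float)
        keep = np.isfinite(vals)
        if keep.sum() < 3:
            t4["correlations"][col] = NOT_COMPUTABLE
            continue
        try:
            t4["correlations"][col] = asdict(
                correlate(lab["index"].to_numpy(float)[keep], vals[keep], "spearman")
            )
        except ValueError:
            t4["correlations"][col] = NOT_COMPUTABLE
    rep.table4 = t4

    # --- fig 3: distance to each facility by frailty status
    f3: dict[str, Any] = {}
    for ftype in FacilityType:
        col = f"dist_{ftype.value}"
        if col not in df.columns:
            continue
        f3[ftype.value] = {
            "nonfrail": _mean_sd(nonfrail[col]),
            "frail": _mean_sd(frail[col]),
            "test": _try_contrast(nonfrail[col], frail[col], method=test_method),
        }
    rep.fig3 = f3

    # --- fig 4: index vs frailty scores
    f4: dict[str, Any] = {}
    for name, col in (("fts5", "fts5_total"), ("fts3", "fts3")):
        if col in df.columns:
            fit = linear_fit(df["index"], df[col])
            f4[f"{name}_fit"] = asdict(fit)
    f4["index_by_status"] = {
        "nonfrail": _mean_sd(nonfrail["index"]),
        "frail": _mean_sd(frail["index"]),
        "test": _try_contrast(nonfrail["index"], frail["index"], method=test_method),
    }
    rep.fig4 = f4

    # --- fig 6: CONUT by status and vs index (lab subset)
    if "conut_total" in lab.columns:
        lf, ln = lab[lab["frail"] == 1], lab[lab["frail"] == 0]
        f6: dict[str, Any] = {
            "conut_by_status": {
                "nonfrail": _mean_sd(ln["conut_total"]),
                "frail": _mean_sd(lf["conut_total"]),
                "test": _try_contrast(ln["conut_total"], lf["conut_total"], method=test_method),
            }
        }
        try:
            f6["conut_fit"] = asdict(linear_fit(lab["index"], lab["conut_total"]))
            f6["conut_spearman"] = asdict(
                correlate(lab["index"], lab["conut_total"], "spearman")
            )
        except ValueError:
            f6["conut_fit"] = NOT_COMPUTABLE
            f6["conut_spearman"] = NOT_COMPUTABLE
        rep.fig6 = f6

    if len(frail) == 0 or len(nonfrail) == 0:
        rep.notes.append("one frailty group is empty; group contrasts not computable")
    return rep
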