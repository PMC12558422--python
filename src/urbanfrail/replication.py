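"""Replication metrics over repeated synthetic studies.

Runs the full generator -> index -> scoring chain for a batch of seeds and
summarises the quantities the default configuration is calibrated to:
frailty prevalence, frail-group BMI, handgrip by urban-quality quartile, and
the lab-subset Spearman correlations of the index with bilirubin and the
CONUT total.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .index import assign_quartiles
from .scoring import LabPanel, score_conut
from .simulate import CityConfig, CohortConfig, simulate_study
from .stats import correlate


def study_metrics(seed: int, city_config: CityConfig | None = None,
                  cohort_config: CohortConfig | None = None) -> dict[str, float]:
    """Calibration metrics of one seeded synthetic study."""
    _, cohort = simulate_study(seed, city_config, cohort_config)
    f = cohort.frame
    out: dict[str, float] = {
        "prevalence_pct": 100.0 * f["frail"].mean(),
        "bmi_frail": f.loc[f["frail"] == 1, "bmi"].mean(),
    }
    qa = assign_quartiles(f["index"].to_numpy(float))
    hg = f["handgrip_kg"].to_numpy(float)
    for q in ("Q1", "Q4"):
        members = qa.members(q)
        out[f"handgrip_{q.lower()}"] = float(hg[members].mean()) if len(members) else np.nan
    sub = cohort.lab_frame
    out["rho_bilirubin"] = correlate(sub["index"], sub["bilirubin"], "spearman").coefficient
    conut = [
        score_conut(
            LabPanel(albumin=r.albumin, lymphocytes=r.lymphocytes,
                     total_cholesterol=r.cholesterol)
        ).total
        for r in sub.itertuples()
    ]
    out["rho_conut"] = correlate(sub["index"], conut, "spearman").coefficient
    return out


def batch_metrics(seeds: Iterable[int], city_config: CityConfig | None = None,
                  cohort_config: CohortConfig | None = None) -> dict[str, float]:
    """Across-seed means of :func:`study_metrics`.

    Handgrip quartile means use a NaN-aware mean: with an integer-valued
    index a rare seed can produce an empty quartile bin.
    """
    rows = [study_metrics(s, city_config, cohort_config) for s in seeds]
    keys = rows[0].keys()
    return {k: float(np.nanmean([r[k] for r in rows])) for k in keys}
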