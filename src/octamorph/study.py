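"""Study-level orchestration: cohort summaries, comparisons, sensitivity.

Reproduces the shape of the published results: a per-parameter × per-type
summary table (min, Q1, median, Q3, max, mean, SD), boxplot statistics
(whiskers at 1.5 × IQR) as numbers, the full set of group-comparison
results, and the detection-sensitivity arithmetic.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .io import read_metrics_csv
from .stats import PARAMETERS, compare_types
from .synth import sample_cohort

__all__ = ["sensitivity", "summary_table", "boxplot_stats", "run_study"]


def sensitivity(assessed: int, excluded_quality: int, undetected: int) -> float:
    """Detection sensitivity in percent, rounded to one decimal.

    Of ``assessed`` eyes, ``excluded_quality`` are removed for inadequate
    image quality before sensitivity is judged; of the remainder,
    ``undetected`` had no delineable lesion.  Sensitivity is
    100·(assessed − excluded − undetected)/(assessed − excluded).
    """
    if excluded_quality + undetected > assessed:
        raise ValueError("exclusions exceed the assessed count")
    denom = assessed - excluded_quality
    if denom <= 0:
        raise ValueError("no eyes left after quality exclusion (zero denominator)")
    return round(100.0 * (assessed - excluded_quality - undetected) / denom, 1)


def summary_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Min/Q1/median/Q3/max/mean/SD per parameter, pooled and per type."""
    rows = []
    groups = [("total", cohort)] + [
        (str(t), cohort[cohort["mnv_type"] == t]) for t in (1, 2, 3)
    ]
    for param in [p for p in PARAMETERS if p in cohort.columns]:
        for label, sub in groups:
            x = sub[param].dropna().to_numpy(np.float64)
            rows.append({
                "parameter": param, "classification": label, "n": x.size,
                "min": x.min(), "q1": np.percentile(x, 25),
                "median": np.median(x), "q3": np.percentile(x, 75),
                "max": x.max(), "mean": x.mean(), "sd": x.std(ddof=1),
            })
    return pd.DataFrame(rows)


def boxplot_stats(cohort: pd.DataFrame) -> pd.DataFrame:
    """Boxplot numbers per parameter × type: quartiles plus 1.5×IQR whiskers.

    The whisker is the most extreme observation within 1.5 interquartile
    ranges of the box, as in the published figures.
    """
    rows = []
    for param in [p for p in PARAMETERS if p in cohort.columns]:
        for t in (1, 2, 3):
            x = np.sort(cohort.loc[cohort["mnv_type"] == t, param].dropna().to_numpy())
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            iqr = q3 - q1
            lo = x[x >= q1 - 1.5 * iqr].min()
            hi = x[x <= q3 + 1.5 * iqr].max()
            rows.append({
                "parameter": param, "mnv_type": t, "whisker_low": lo, "q1": q1,
                "median": med, "q3": q3, "whisker_high": hi, "mean": x.mean(),
                "n_outliers": int(((x < lo) | (x > hi)).sum()),
            })
    return pd.DataFrame(rows)


def run_study(
    cohort_source: str | Path,
    config: Optional[RunConfig] = None,
    out_dir: str | Path = "study_out",
) -> dict:
    """End-to-end cohort analysis; ``cohort_source`` is ``"simulate"`` or a CSV.

    Writes the cohort metrics CSV, the summary table, boxplot statistics and
    the comparison JSON under ``out_dir``; every file carries the config
    hash, seed and software version.  Deterministic given the config.
    """
    cfg = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if str(cohort_source) == "simulate":
        cohort = sample_cohort(seed=cfg.seed)
    else:
        cohort = read_metrics_csv(cohort_source)
    if cohort.empty:
        raise ValueError("empty cohort")

    provenance = {"config_hash": cfg.hash, "seed": cfg.seed, "version": __version__}
    summary = summary_table(cohort)
    boxes = boxplot_stats(cohort)
    results = compare_types(cohort, alpha=cfg.alpha)

    cohort.to_csv(out / "cohort_metrics.csv", index=False, float_format="%.17g")
    summary.to_csv(out / "summary_table.csv", index=False, float_format="%.10g")
    boxes.to_csv(out / "boxplot_stats.csv", index=False, float_format="%.10g")
    payload = {
        "provenance": provenance,
        "comparisons": [r.to_dict() for r in results],
    }
    (out / "comparisons.json").write_text(json.dumps(payload, sort_keys=True, indent=2) + "\n")
    (out / "provenance.json").write_text(json.dumps(provenance, sort_keys=True, indent=2) + "\n")
    return {"cohort": cohort, "summary": summary, "boxplots": boxes,
            "comparisons": results, "provenance": provenance}
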