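"""Group summaries and the study's statistical comparisons.

Hierarchical (nested) designs — neurons within dishes, tracks within
fields of view — are handled by aggregating to one mean per replicate unit
first, then running ordinary one-way ANOVA on the unit means, matching
per-dish-average plotting.  Post-hoc pairwise comparisons use Bonferroni
(pairwise t-tests scaled by the number of comparisons) or Tukey's HSD
(studentized range).  Two-group comparisons use the classical
equal-variance Student t-test, with Welch's correction available.

The ANOVA and t statistics are computed from the classical sums-of-squares
and pooled-variance formulas directly; p-values come from the
corresponding scipy.stats distributions.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: float
    p_value: float


def nest_aggregate(data: pd.DataFrame) -> pd.DataFrame:
    """Collapse nested observations to one mean per replicate unit.

    `data` needs columns ``group, unit, value`` (e.g. condition, dish,
    neuron amplitude).  Returns one row per (group, unit) with the unit
    mean; group labels are preserved.
    """
    required = {"group", "unit", "value"}
    if not required.issubset(data.columns):
        raise ValueError(f"nested data needs columns {sorted(required)}")
    if not np.all(np.isfinite(data["value"])):
        raise ValueError("values must be finite")
    out = (
        data.groupby(["group", "unit"], sort=True)["value"]
        .mean()
        .reset_index()
    )
    return out


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA: F = MS_between / MS_within.

    Every group needs at least two values.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, a in arrays.items():
        if a.size < 2:
            raise ValueError(f"group {k!r} has fewer than two values")
        if not np.all(np.isfinite(a)):
            raise ValueError(f"group {k!r} has non-finite values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(arrays)
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        # all groups internally constant: F is 0 when means agree, infinite otherwise
        f = 0.0 if ss_between == 0 else math.inf
    else:
        f = ms_b / ms_w
    p = float(sps.f.sf(f, df_b, df_w)) if math.isfinite(f) else 0.0
    return AnovaResult(f_statistic=float(f), df_between=df_b, df_within=df_w, p_value=p)


def two_sample_test(
    a: Sequence[float],
    b: Sequence[float],
    welch: bool = False,
) -> TTestResult:
    """Unpaired two-sample t-test (equal-variance Student by default)."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least two values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if welch:
        se2 = vx / x.size + vy / y.size
        if se2 == 0:
            raise ValueError("both samples are constant; t undefined")
        df = se2**2 / (
            (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
        )
    else:
        pooled = ((x.size - 1) * vx + (y.size - 1) * vy) / (x.size + y.size - 2)
        if pooled == 0:
            raise ValueError("zero pooled variance; t undefined")
        se2 = pooled * (1 / x.size + 1 / y.size)
        df = float(x.size + y.size - 2)
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    p = 2 * float(sps.t.sf(abs(t), df))
    return TTestResult(t_statistic=float(t), df=df, p_value=p)


def pairwise_posthoc(
    groups: Mapping[str, Sequence[float]],
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Adjusted pairwise p-values after one-way ANOVA.

    ``bonferroni``: each pairwise Student t p-value is multiplied by the
    number of comparisons (capped at 1).  ``tukey``: Tukey's honestly
    significant difference via the studentized range distribution.
    Returns columns ``group_a, group_b, p_raw, p_adjusted, method``.
    """
    one_way_anova(groups)  # validates the design
    names = sorted(groups)
    pairs = list(itertools.combinations(names, 2))
    rows = []
    if method == "bonferroni":
        m = len(pairs)
        for a, b in pairs:
            res = two_sample_test(groups[a], groups[b])
            rows.append((a, b, res.p_value, min(1.0, res.p_value * m)))
    elif method == "tukey":
        arrays = [np.asarray(groups[n], dtype=float) for n in names]
        res = sps.tukey_hsd(*arrays)
        raw = {}
        for (a, b) in pairs:
            # scipy has no unadjusted p here; reuse the pairwise t for the raw column
            raw[(a, b)] = two_sample_test(groups[a], groups[b]).p_value
        for (a, b) in pairs:
            i, j = names.index(a), names.index(b)
            rows.append((a, b, raw[(a, b)], float(res.pvalue[i, j])))
    else:
        raise ValueError("method must be 'bonferroni' or 'tukey'")
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "p_raw", "p_adjusted"])
    out["method"] = method
    return out


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean with n-1 denominator for the SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("SEM needs at least two values")
    return float(x.std(ddof=1) / math.sqrt(x.size))


def group_summary(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Per-group n, mean and SEM."""
    rows = [
        (name, len(vals), float(np.mean(vals)), sem(vals))
        for name, vals in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem"])


# ---------------------------------------------------------------------------
# Run report
# ---------------------------------------------------------------------------

class MissingInputError(FileNotFoundError):
    """An expected upstream artifact is absent."""


def _round_floats(obj, ndigits=10):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def build_report(
    classification: pd.DataFrame | None = None,
    fov_summary: pd.DataFrame | None = None,
    calcium_dish: pd.DataFrame | None = None,
    tests: Mapping[str, Mapping[str, float]] | None = None,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Assemble a deterministic structured run summary.

    The returned dict serializes to byte-identical JSON for identical
    inputs (sorted keys, floats rounded to 10 digits).
    """
    from . import __version__

    report: dict = {"software_version": __version__}
    if seed is not None:
        report["seed"] = seed
    if config is not None:
        report["config"] = dict(config)
    if classification is not None:
        by_behavior = classification.groupby("behavior")
        report["tracks"] = {
            "n_tracks": int(len(classification)),
            "per_behavior_counts": {
                k: int(len(g)) for k, g in by_behavior
            },
            "median_total_um": float(classification["total_um"].median()),
            "median_net_um": float(classification["net_um"].median()),
        }
    if fov_summary is not None:
        report["fov_summaries"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in row.items()}
            for row in fov_summary.to_dict(orient="records")
        ]
    if calcium_dish is not None:
        report["calcium_dishes"] = [
            {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
             for k, v in row.items()}
            for row in calcium_dish.to_dict(orient="records")
        ]
    if tests:
        report["tests"] = {name: dict(res) for name, res in tests.items()}
    return _round_floats(report)


def write_report(report: dict, path: str | Path) -> None:
    """Serialize the report with stable key order."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")


def report_from_dir(in_dir: str | Path, out_path: str | Path, seed: int | None = None) -> dict:
    """Build and write a report from a directory of pipeline outputs.

    Expects at least one of ``classification.csv``, ``fov_summary.csv``,
    ``calcium_dish.csv`` in `in_dir`; raises :class:`MissingInputError`
    listing absent files when none is present.
    """
    in_dir = Path(in_dir)
    candidates = {
        "classification": in_dir / "classification.csv",
        "fov_summary": in_dir / "fov_summary.csv",
        "calcium_dish": in_dir / "calcium_dish.csv",
    }
    found = {k: pd.read_csv(p) for k, p in candidates.items() if p.exists()}
    if not found:
        raise MissingInputError(
            "no pipeline outputs found; looked for: "
            + ", ".join(str(p) for p in candidates.values())
        )
    report = build_report(
        classification=found.get("classification"),
        fov_summary=found.get("fov_summary"),
        calcium_dish=found.get("calcium_dish"),
        seed=seed,
    )
    write_report(report, out_path)
    return report
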