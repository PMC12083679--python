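"""Grade-stratified comparison of Shh between TGF-β-high and -low patches.

The default test is Student's unpaired two-tailed t-test (pooled variance)
on scaled Shh patch values; Welch's t and Mann-Whitney are selectable since
patch intensities can be skewed. The unit of analysis is the patch; an
optional per-sample aggregation mode (mean per sample and group, then a test
across samples) avoids pseudo-replication within images at the cost of power
and is off by default.

Strata emitted by :func:`grade_summary`:

* one high-vs-low comparison per fibrosis grade present;
* ``"MF_vs_control"`` — scaled Shh inside TGF-β-high patches, myelofibrosis
  cases (G1-G3) versus controls (G0); here "high"/"low" fields hold the
  case/control groups respectively;
* ``"MF_high_vs_low"`` — the high-vs-low comparison pooled over G1-G3 cases.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import ConfigurationError
from .io import GRADES
from .patches import PatchTable
from .split import SplitResult

log = logging.getLogger(__name__)

TESTS = ("student_t", "welch_t", "mann_whitney")


@dataclass
class GroupComparison:
    stratum: str
    n_high: int
    n_low: int
    mean_shh_high: float
    mean_shh_low: float
    difference: float  # mean_shh_high - mean_shh_low
    statistic: float
    p_value: float
    test: str
    status: str = "ok"  # "ok" | "insufficient patches"

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, float) and math.isnan(v):
                d[k] = None
        return d


def _run_test(a: np.ndarray, b: np.ndarray, test: str):
    if test == "student_t":
        res = sps.ttest_ind(a, b, equal_var=True)
    elif test == "welch_t":
        res = sps.ttest_ind(a, b, equal_var=False)
    elif test == "mann_whitney":
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
    else:
        raise ConfigurationError(f"unknown test {test!r}; choose from {TESTS}")
    return float(res.statistic), float(res.pvalue)


def _comparison(stratum, high, low, test, per_sample=False, samples_high=None, samples_low=None):
    if per_sample:
        high = pd.Series(high).groupby(pd.Series(samples_high)).mean().to_numpy()
        low = pd.Series(low).groupby(pd.Series(samples_low)).mean().to_numpy()
    high = np.asarray(high, dtype=float)
    low = np.asarray(low, dtype=float)
    mean_high = float(high.mean()) if high.size else float("nan")
    mean_low = float(low.mean()) if low.size else float("nan")
    if high.size < 2 or low.size < 2:
        return GroupComparison(
            stratum=stratum, n_high=high.size, n_low=low.size,
            mean_shh_high=mean_high, mean_shh_low=mean_low,
            difference=mean_high - mean_low,
            statistic=float("nan"), p_value=float("nan"), test=test,
            status="insufficient patches",
        )
    statistic, p = _run_test(high, low, test)
    return GroupComparison(
        stratum=stratum, n_high=high.size, n_low=low.size,
        mean_shh_high=mean_high, mean_shh_low=mean_low,
        difference=mean_high - mean_low,
        statistic=statistic, p_value=p, test=test,
    )


def compare_shh(
    table: PatchTable,
    stratum: str,
    test: str = "student_t",
    per_sample: bool = False,
) -> GroupComparison:
    """One two-sided comparison of scaled Shh for the named stratum.

    ``stratum`` is a grade label (high vs low within that grade),
    ``"MF_vs_control"`` (Shh in high-TGF-β patches, cases vs controls), or
    ``"MF_high_vs_low"`` (high vs low pooled over cases). A positive
    ``difference`` means Shh is higher where TGF-β is high (or in cases,
    for the case/control stratum).
    """
    df = table.df
    if "group" not in df.columns:
        raise ConfigurationError("table has no group labels; run the density split first")
    if stratum == "MF_vs_control":
        sel = df[df["group"] == "high"]
        a, b = sel[sel["is_case"]], sel[~sel["is_case"]]
    elif stratum == "MF_high_vs_low":
        sel = df[df["is_case"]]
        a, b = sel[sel["group"] == "high"], sel[sel["group"] == "low"]
    else:
        sel = df[df["grade"] == stratum]
        a, b = sel[sel["group"] == "high"], sel[sel["group"] == "low"]
    return _comparison(
        stratum,
        a["scaled_Shh"].to_numpy(), b["scaled_Shh"].to_numpy(),
        test, per_sample, a["sample_id"].to_numpy(), b["sample_id"].to_numpy(),
    )


def grade_summary(
    table: PatchTable,
    test: str = "student_t",
    per_sample: bool = False,
    correction: str | None = None,
):
    """All stratified comparisons plus a tidy per-stratum summary table.

    Returns ``(comparisons, summary_df)``. ``correction="bonferroni"``
    multiplies the per-grade p-values by the number of per-grade tests
    (capped at 1); no correction is applied by default.
    """
    strata = [g for g in GRADES if (table.df["grade"] == g).any()]
    comparisons = [compare_shh(table, g, test=test, per_sample=per_sample) for g in strata]
    if correction == "bonferroni":
        m = sum(1 for c in comparisons if c.status == "ok")
        for c in comparisons:
            if c.status == "ok":
                c.p_value = min(1.0, c.p_value * m)
    elif correction is not None:
        raise ConfigurationError(f"unknown correction {correction!r}")
    comparisons.append(compare_shh(table, "MF_vs_control", test=test, per_sample=per_sample))
    comparisons.append(compare_shh(table, "MF_high_vs_low", test=test, per_sample=per_sample))

    rows = []
    for (grade, group), sub in table.df.groupby(["grade", "group"], sort=True):
        vals = sub["scaled_Shh"].to_numpy(dtype=float)
        rows.append(
            {
                "grade": grade,
                "group": group,
                "n": len(vals),
                "mean_shh": vals.mean(),
                "median_shh": np.median(vals),
                "q1_shh": np.percentile(vals, 25),
                "q3_shh": np.percentile(vals, 75),
            }
        )
    return comparisons, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def render_report(
    results,
    split: SplitResult | None,
    qc_counts: dict,
    out_dir,
    config: dict | None = None,
    table: PatchTable | None = None,
) -> dict:
    """Write results.json, summary.csv, the density curve, and figures.

    Returns the JSON payload that was written. Figures (density curve with
    the threshold marked; scaled Shh by grade and group) are emitted only
    when the corresponding inputs are present.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "comparisons": [c.to_dict() for c in results],
        "split": None if split is None else split.to_dict(),
        "qc_counts": qc_counts,
        "config": config,
        "config_hash": None if config is None else config_hash(config),
        "status": "ok" if results else "no comparisons computed",
    }
    (out_dir / "results.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    pd.DataFrame([c.to_dict() for c in results]).to_csv(out_dir / "summary.csv", index=False)

    if split is not None and split.curve is not None:
        pd.DataFrame({"grid": split.curve.grid, "density": split.curve.density}).to_csv(
            out_dir / "density_curve.csv", index=False
        )
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(split.curve.grid, split.curve.density, color="tab:blue")
        ax.axvline(split.threshold, color="tab:red", linestyle="--",
                   label=f"threshold {split.threshold:.3f} ({split.method})")
        ax.set_xlabel("scaled TGF-β")
        ax.set_ylabel("density")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out_dir / "tgfb_density.png", dpi=150)
        plt.close(fig)

    if table is not None and "group" in table.df.columns and len(table.df):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        grades = [g for g in GRADES if (table.df["grade"] == g).any()]
        fig, ax = plt.subplots(figsize=(6, 3.5))
        positions, data, labels = [], [], []
        pos = 0
        for g in grades:
            for group, offset in (("low", 0.0), ("high", 0.7)):
                vals = table.df.loc[
                    (table.df["grade"] == g) & (table.df["group"] == group), "scaled_Shh"
                ].to_numpy()
                if len(vals):
                    positions.append(pos + offset)
                    data.append(vals)
                    labels.append(f"{g}\n{group}")
            pos += 2.0
        if data:
            ax.boxplot(data, positions=positions, widths=0.5, tick_labels=labels)
            ax.set_ylabel("scaled Shh")
        fig.tight_layout()
        fig.savefig(out_dir / "shh_by_grade.png", dpi=150)
        plt.close(fig)
    return payload
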