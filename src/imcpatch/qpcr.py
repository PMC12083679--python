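"""Relative qPCR quantification by the ΔΔCt method.

Expression is normalized to a reference gene (β-actin in the source assays)
and to a control condition: ΔΔCt = (Ct_target − Ct_ref)_sample −
(Ct_target − Ct_ref)_control, fold change = 2^(−ΔΔCt). A reaction is called
negative for expression when its Ct exceeds 40 cycles (strictly) or the
instrument reports it undetermined; no fold change is computed from negative
inputs. Replicate Cts are averaged per (sample, condition, gene) before the
ΔΔCt arithmetic — Ct is already a log-scale quantity, so the arithmetic mean
of Cts is a geometric mean of expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import FormatError, NotExpressed

log = logging.getLogger(__name__)

CT_NEGATIVE_CUTOFF = 40.0
_UNDETERMINED = {"undetermined", "undet", "na", "nan", ""}


def parse_ct(value) -> float:
    """Ct as float; 'undetermined'-style strings and NaN become +inf."""
    if value is None:
        return float("inf")
    if isinstance(value, str):
        if value.strip().lower() in _UNDETERMINED:
            return float("inf")
        value = float(value)
    value = float(value)
    return float("inf") if np.isnan(value) else value


def flag_negative(ct) -> bool:
    """True iff the Ct calls the reaction negative: strictly above 40 cycles,
    or undetermined."""
    return parse_ct(ct) > CT_NEGATIVE_CUTOFF


def fold_change(ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control) -> float:
    """2^(−ΔΔCt) fold change of the target in the sample relative to control.

    Raises :class:`NotExpressed` when any of the four Cts is flagged negative.
    """
    cts = (ct_target_sample, ct_ref_sample, ct_target_control, ct_ref_control)
    if any(flag_negative(ct) for ct in cts):
        raise NotExpressed(f"negative-flagged Ct among inputs {cts}; no fold change")
    ddct = (parse_ct(ct_target_sample) - parse_ct(ct_ref_sample)) - (
        parse_ct(ct_target_control) - parse_ct(ct_ref_control)
    )
    return float(2.0 ** (-ddct))


def ddct_table(
    ct_df: pd.DataFrame,
    ref_gene: str = "Actb",
    control_condition: str = "control",
) -> pd.DataFrame:
    """Per-sample ΔΔCt and fold change from a long Ct table.

    Input columns: ``sample_id, condition, gene, ct`` (replicate rows
    allowed). The control ΔCt per gene is the mean ΔCt over control-condition
    samples. Output: one row per (sample, target gene) with ``ddct``,
    ``fold`` and ``status`` ("ok" / "not_expressed").
    """
    required = {"sample_id", "condition", "gene", "ct"}
    missing = required - set(ct_df.columns)
    if missing:
        raise FormatError(f"Ct table lacks columns {sorted(missing)}")
    df = ct_df.copy()
    df["ct"] = df["ct"].map(parse_ct)
    # mean of replicates; an undetermined replicate (inf) poisons the mean,
    # correctly propagating to a negative call
    mean_ct = df.groupby(["sample_id", "condition", "gene"])["ct"].mean().reset_index()

    wide = mean_ct.pivot_table(index=["sample_id", "condition"], columns="gene",
                               values="ct", aggfunc="first")
    if ref_gene not in wide.columns:
        raise FormatError(f"reference gene {ref_gene!r} absent from Ct table")
    if wide[ref_gene].isna().any():
        bad = wide.index[wide[ref_gene].isna()].tolist()
        raise FormatError(f"reference gene {ref_gene!r} missing for samples {bad}")

    targets = [g for g in wide.columns if g != ref_gene]
    controls = wide[wide.index.get_level_values("condition") == control_condition]
    if controls.empty:
        raise FormatError(f"no rows with control condition {control_condition!r}")

    rows = []
    for (sample, condition), row in wide.iterrows():
        for gene in targets:
            ct_t, ct_r = row[gene], row[ref_gene]
            ctrl_dcts = (controls[gene] - controls[ref_gene]).dropna()
            ctrl_dcts = ctrl_dcts[np.isfinite(ctrl_dcts)]
            negative = (
                pd.isna(ct_t)
                or flag_negative(ct_t)
                or flag_negative(ct_r)
                or len(ctrl_dcts) == 0
            )
            if negative:
                rows.append({"sample_id": sample, "condition": condition, "gene": gene,
                             "ddct": np.nan, "fold": np.nan, "status": "not_expressed"})
                continue
            ddct = (ct_t - ct_r) - float(ctrl_dcts.mean())
            rows.append({"sample_id": sample, "condition": condition, "gene": gene,
                         "ddct": ddct, "fold": float(2.0 ** -ddct), "status": "ok"})
    return pd.DataFrame(rows)
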