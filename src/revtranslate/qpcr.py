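"""qPCR relative quantification by the delta-delta-Ct method.

Target cycle thresholds are normalized to a housekeeping gene within each
sample (dCt = Ct_target - Ct_housekeeping) and to a per-plate calibrator
cDNA (ddCt = dCt_sample - dCt_calibrator); relative expression is
2^(-ddCt), so the calibrator sits at 1 and each extra cycle halves
expression (amplification efficiency fixed at 2).  Technical replicates
are averaged on the Ct scale before any differencing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "validate_ct_table",
    "relative_expression",
    "relative_expression_table",
    "expression_call_filter",
]

REQUIRED_COLUMNS = ("sample_id", "target", "ct", "plate_id", "role")


def validate_ct_table(ct: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    bad_roles = set(ct["role"]) - {"sample", "calibrator"}
    if bad_roles:
        raise ValueError(f"unknown roles: {sorted(bad_roles)}")
    ok = ct["ct"].isna() | (ct["ct"] > 0)
    if not ok.all():
        raise ValueError("Ct values must be positive or missing")


def _mean_ct(ct: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale."""
    return (
        ct.groupby(["plate_id", "role", "sample_id", "target"], dropna=False)["ct"]
        .mean()
        .reset_index()
    )


def relative_expression(
    ct: pd.DataFrame, target: str, housekeeping: str
) -> pd.Series:
    """Per-sample relative expression of ``target`` vs the plate calibrator.

    Requires the housekeeping Ct for each sample and a calibrator row for
    both genes on every plate carrying sample rows; samples with missing
    Ct get a missing value (logged), a plate without calibrator is an
    error naming the plate.
    """
    validate_ct_table(ct)
    averaged = _mean_ct(ct)
    relevant = averaged[averaged["target"].isin([target, housekeeping])]

    wide = relevant.pivot_table(
        index=["plate_id", "role", "sample_id"],
        columns="target",
        values="ct",
        aggfunc="mean",
    ).reset_index()

    results: dict[str, float] = {}
    for plate, plate_rows in wide.groupby("plate_id"):
        samples = plate_rows[plate_rows["role"] == "sample"]
        if samples.empty:
            continue
        calib = plate_rows[plate_rows["role"] == "calibrator"]
        if calib.empty or calib[[target, housekeeping]].isna().to_numpy().any():
            raise ValueError(
                f"plate {plate!r} lacks calibrator Ct for {target!r}/{housekeeping!r}"
            )
        dct_cal = float(calib[target].iloc[0] - calib[housekeeping].iloc[0])
        for _, row in samples.iterrows():
            sid = row["sample_id"]
            if pd.isna(row.get(target)) or pd.isna(row.get(housekeeping)):
                logger.info("missing Ct for sample %s target %s; value left missing", sid, target)
                results[sid] = np.nan
                continue
            ddct = (row[target] - row[housekeeping]) - dct_cal
            results[sid] = float(2.0 ** (-ddct))
    return pd.Series(results, name=target)


def relative_expression_table(
    ct: pd.DataFrame, targets, housekeeping: str
) -> pd.DataFrame:
    """Samples x markers table of relative expression (calibrator = 1)."""
    return pd.DataFrame(
        {t: relative_expression(ct, t, housekeeping) for t in targets}
    )


def expression_call_filter(
    ct: pd.DataFrame, target: str, ct_max: float = 29.0
) -> pd.Series:
    """Expressed flag per sample: Ct <= ct_max (strictly >ct_max = not expressed).

    Missing Ct yields a missing flag.  Technical replicates are averaged
    before thresholding.
    """
    validate_ct_table(ct)
    averaged = _mean_ct(ct)
    rows = averaged[(averaged["target"] == target) & (averaged["role"] == "sample")]
    flags = {}
    for _, row in rows.iterrows():
        flags[row["sample_id"]] = (
            pd.NA if pd.isna(row["ct"]) else bool(row["ct"] <= ct_max)
        )
    return pd.Series(flags, name=f"{target}_expressed", dtype="boolean")
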