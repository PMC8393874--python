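"""Confusion-matrix validation of the readmission-probability target.

The readmission policy penalizes a hospital for a condition when its
excess readmission ratio (ERR) exceeds the median ERR of its peer group.
The care-strategy model instead targets the peer group's *mean
readmission probability*, which — unlike ERR — maps directly onto
treatment-plan decisions.  This module quantifies how well the
probability target stands in for the ERR rule: within each (peer group,
condition) stratum, the *actual* penalty flag is ERR > stratum median
ERR and the *predicted* flag is readmission probability > stratum mean
probability; agreement is summarized per peer group as a confusion
matrix with accuracy and misclassification rates.

Works on any records table in the public supplemental-file layout
(hospital_id, peer_group, condition, err, readmission_prob, cases); a
synthetic generator emulates that layout so no download is needed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "validate_peer_records",
    "label_records",
    "confusion_summary",
    "synth_peer_records",
    "read_peer_records",
]

REQUIRED_COLUMNS = (
    "hospital_id",
    "peer_group",
    "condition",
    "err",
    "readmission_prob",
    "cases",
)

HRRP_CONDITIONS = ("AMI", "PN", "HF", "HK", "COPD", "CABG")


def validate_peer_records(table: pd.DataFrame) -> pd.DataFrame:
    errors = []
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peer records missing columns: {missing}")
    if len(table) == 0:
        errors.append("peer records table is empty")
    else:
        if (table["err"] <= 0).any():
            errors.append("err must be > 0 for every record")
        probs = table["readmission_prob"]
        if ((probs <= 0) | (probs >= 1)).any():
            errors.append("readmission_prob must lie strictly in (0, 1)")
        if (table["cases"] < 0).any():
            errors.append("cases must be non-negative")
        if table.duplicated(["hospital_id", "condition"]).any():
            errors.append("duplicate (hospital_id, condition) pairs")
    if errors:
        raise ValueError("invalid peer records:\n  - " + "\n  - ".join(errors))
    return table


def label_records(
    table: pd.DataFrame, case_weighted_mean: bool = False
) -> pd.DataFrame:
    """Add ``actual`` and ``predicted`` penalty flags per record.

    Flags use strict inequality against the (peer group, condition)
    stratum median ERR / mean readmission probability, so a hospital
    exactly at the threshold is not flagged.  Strata with fewer than two
    records are excluded and marked in the ``excluded`` column.
    """
    validate_peer_records(table)
    out = table.copy()
    out["actual"] = False
    out["predicted"] = False
    out["excluded"] = False
    for _, idx in out.groupby(["peer_group", "condition"]).groups.items():
        sub = out.loc[idx]
        if len(sub) < 2:
            out.loc[idx, "excluded"] = True
            continue
        out.loc[idx, "actual"] = sub["err"] > sub["err"].median()
        if case_weighted_mean:
            mean = np.average(sub["readmission_prob"], weights=sub["cases"])
        else:
            mean = sub["readmission_prob"].mean()
        out.loc[idx, "predicted"] = sub["readmission_prob"] > mean
    return out


def confusion_summary(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-peer-group TP/FP/FN/TN counts with accuracy percentages.

    accuracy = (TP + TN)/N · 100 and misclassification = (FP + FN)/N ·
    100; the two always sum to exactly 100.
    """
    for col in ("actual", "predicted"):
        if col not in labeled.columns:
            raise ValueError("table must be labeled first (see label_records)")
    if "excluded" in labeled.columns:
        use = labeled[~labeled["excluded"]]
    else:
        use = labeled
    rows = []
    for group, sub in use.groupby("peer_group"):
        a = sub["actual"].to_numpy(dtype=bool)
        p = sub["predicted"].to_numpy(dtype=bool)
        tp = int(np.sum(a & p))
        fp = int(np.sum(~a & p))
        fn = int(np.sum(a & ~p))
        tn = int(np.sum(~a & ~p))
        n = len(sub)
        rows.append(
            {
                "peer_group": group,
                "TP": tp,
                "FP": fp,
                "FN": fn,
                "TN": tn,
                "n": n,
                "accuracy_pct": 100.0 * (tp + tn) / n,
                "misclassification_pct": 100.0 * (fp + fn) / n,
            }
        )
    return pd.DataFrame(rows)


def synth_peer_records(
    n_hospitals: int,
    rho: float,
    seed: int,
    peer_group_mix: dict[int, float] | None = None,
    conditions: tuple[str, ...] = HRRP_CONDITIONS,
    err_sigma: float = 0.15,
    prob_range: tuple[float, float] = (0.03, 0.40),
) -> pd.DataFrame:
    """Synthetic records table standing in for the public supplemental file.

    Per (hospital, condition): ERR is lognormal around 1 (log-sd
    ``err_sigma``) and the readmission probability comes from a Gaussian
    copula with latent correlation ``rho`` to ERR, mapped affinely into
    ``prob_range``.  ρ = 1 makes the two comonotone; ρ = 0 independent.
    Fully reproducible from ``seed``.
    """
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [-1, 1], got {rho}")
    if n_hospitals < 2:
        raise ValueError("need at least 2 hospitals per stratum")
    mix = peer_group_mix or {g: 0.2 for g in range(1, 6)}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("peer_group_mix must sum to 1")
    rng = np.random.default_rng(seed)
    groups = rng.choice(
        list(mix.keys()), size=n_hospitals, p=list(mix.values())
    )
    rows = []
    lo, hi = prob_range
    from scipy.stats import norm

    for h in range(n_hospitals):
        for cond in conditions:
            z1 = rng.standard_normal()
            z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
            err = float(np.exp(err_sigma * z1))
            prob = float(lo + (hi - lo) * norm.cdf(z2))
            rows.append(
                {
                    "hospital_id": f"H{h:04d}",
                    "peer_group": int(groups[h]),
                    "condition": cond,
                    "err": err,
                    "readmission_prob": prob,
                    "cases": int(rng.poisson(90) + 25),
                }
            )
    return validate_peer_records(pd.DataFrame(rows))


def read_peer_records(path: str | Path) -> pd.DataFrame:
    """Load and validate a records CSV in the supplemental-file layout."""
    return validate_peer_records(pd.read_csv(path))
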