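"""Per-feature robustness of delineation variants against Baseline via the
intra-class correlation coefficient.

Each variant is compared with Baseline as a pair of interchangeable "raters"
measuring the same feature on the same subjects.  The default form is
ICC(2,1) — two-way random effects, absolute agreement, single measurement —
so a systematic shift introduced by the perturbation penalizes robustness;
ICC(3,1) (consistency) is available for comparison.  Features with
ICC >= 0.9 are counted as excellently robust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class IccResult:
    feature_name: str
    variant: str
    icc: float          # NaN when undefined
    n_subjects: int
    status: str         # "ok" | "constant" | "too_few_subjects"

    @property
    def defined(self) -> bool:
        return self.status == "ok"


def icc_two_way(x_baseline, x_variant, form: str = "icc2") -> float:
    """ICC between two measurement vectors over the same subjects.

    ``icc2`` = ICC(2,1): (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))
    with k = 2 raters and mean squares from the two-way ANOVA decomposition.
    ``icc3`` = ICC(3,1): (MS_R - MS_E) / (MS_R + (k-1) MS_E).

    Raises ``ValueError`` on fewer than 3 subjects or a constant vector
    (undefined agreement — callers flag such features explicitly rather than
    scoring them 0).
    """
    x = np.asarray(x_baseline, dtype=np.float64)
    y = np.asarray(x_variant, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measurement vectors must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("ICC requires at least 3 subjects")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite measurements")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant measurement vector; ICC undefined")

    data = np.stack([x, y], axis=1)  # subjects x raters
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_rows = k * np.sum((subj_means - grand) ** 2)
    ss_cols = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    if form == "icc2":
        denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    elif form == "icc3":
        denom = ms_r + (k - 1) * ms_e
    else:
        raise ValueError(f"unknown ICC form {form!r}")
    if denom == 0:
        raise ValueError("zero denominator; ICC undefined")
    return float((ms_r - ms_e) / denom)


def icc_table(baseline_table: pd.DataFrame, variant_tables: dict[str, pd.DataFrame],
              feature_names: list[str] | None = None, form: str = "icc2") -> pd.DataFrame:
    """Long-format ICC results (feature, variant, icc, n_subjects, status)
    comparing each variant's feature table with Baseline over the common
    subjects."""
    if feature_names is None:
        feature_names = [c for c in baseline_table.columns if c not in ("label", "split")]
    records = []
    for variant, table in variant_tables.items():
        common = baseline_table.index.intersection(table.index)
        for feat in feature_names:
            x = baseline_table.loc[common, feat].to_numpy(dtype=np.float64)
            y = table.loc[common, feat].to_numpy(dtype=np.float64)
            try:
                val = icc_two_way(x, y, form=form)
                status = "ok"
            except ValueError as exc:
                val = np.nan
                status = "too_few_subjects" if "at least 3" in str(exc) else "constant"
            records.append(IccResult(feat, variant, val, len(common), status))
    return pd.DataFrame(
        [(r.feature_name, r.variant, r.icc, r.n_subjects, r.status) for r in records],
        columns=["feature", "variant", "icc", "n_subjects", "status"],
    )


def count_robust(results: pd.DataFrame, threshold: float = 0.9) -> pd.DataFrame:
    """Per-variant counts of robust features (ICC >= threshold); undefined
    ICCs are excluded from the count and reported separately."""
    if len(results) == 0:
        raise ValueError("no ICC results")
    rows = []
    for variant, grp in results.groupby("variant", sort=False):
        ok = grp[grp["status"] == "ok"]
        rows.append({
            "variant": variant,
            "n_robust": int((ok["icc"] >= threshold).sum()),
            "n_defined": int(len(ok)),
            "n_undefined": int(len(grp) - len(ok)),
            "median_icc": float(ok["icc"].median()) if len(ok) else np.nan,
        })
    return pd.DataFrame(rows)
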