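"""Treatment-effect statistics on organoid size tables.

The unit of analysis is the organoid: per-object pixel areas from all
images of an arm are pooled, objects dosed at 1 mM or 3 mM are labelled
"treated", and for each timepoint an ordinary least-squares regression of
size on the binary treatment indicator estimates the mean size difference
(its two-sided t test is the treatment effect test, alpha = 0.05).  Size
is raw pixel area by default; a log-area option is provided because size
distributions are right-skewed.  A per-image-mean unit of analysis is
available behind a flag for users worried about within-image correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_TREATED_DOSES",
    "RegressionResult",
    "InsufficientDataError",
    "label_treatment",
    "fit_size_regression",
    "fit_all_days",
    "size_class_counts",
    "default_class_edges",
    "summarize_distributions",
    "tumour_volume",
]

DEFAULT_TREATED_DOSES = frozenset({"1 mM", "3 mM"})

REQUIRED_COLUMNS = {"image_id", "arm", "dose", "day", "area_px"}


class InsufficientDataError(ValueError):
    """A regression cell has an empty or singleton treatment group."""


@dataclass(frozen=True)
class RegressionResult:
    """Per-timepoint OLS of size on the binary treatment indicator.

    ``beta0`` is the untreated mean size; ``beta1`` the treated-minus-
    untreated difference (px for raw area).
    """

    day: int | str
    n_objects: int
    beta0: float
    beta1: float
    se_beta1: float
    t_stat: float
    p_value: float
    ci95: tuple[float, float]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ci95"] = list(d["ci95"])
        return d


def _check_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"size table is missing columns: {sorted(missing)}")


def label_treatment(
    table: pd.DataFrame, treated_doses: "set[str] | frozenset[str]" = DEFAULT_TREATED_DOSES
) -> pd.DataFrame:
    """Set the ``treated`` flag row-wise by dose-label membership.

    Idempotent.  If a non-empty ``treated_doses`` shares no dose with the
    table's dose vocabulary the call raises (catches configuration typos
    early); doses beyond the vocabulary are otherwise allowed so the
    default set works for cohorts that use only one of its dose levels.
    """
    _check_table(table)
    vocab = set(table["dose"].unique())
    if treated_doses and len(table) and not (set(treated_doses) & vocab):
        raise ValueError(
            f"none of the treated doses {sorted(treated_doses)} appear in the "
            f"manifest's dose vocabulary {sorted(vocab)}"
        )
    out = table.copy()
    out["treated"] = out["dose"].isin(treated_doses)
    return out


def _prepare_values(
    table: pd.DataFrame,
    value_col: str,
    log_transform: bool,
    per_image: bool,
) -> pd.DataFrame:
    df = table.copy()
    if log_transform:
        if (df[value_col] <= 0).any():
            raise ValueError("log transform requires strictly positive sizes")
        df[value_col] = np.log(df[value_col].astype(float))
    if per_image:
        df = (
            df.groupby(["image_id", "treated", "day"], as_index=False)[value_col]
            .mean()
        )
    return df


def fit_size_regression(
    table: pd.DataFrame,
    day: "int | str",
    value_col: str = "area_px",
    log_transform: bool = False,
    per_image: bool = False,
) -> RegressionResult:
    """OLS of size on treatment for one timepoint.

    With a binary regressor the intercept is the untreated group mean and
    the slope the treated-minus-untreated mean difference; inference is
    the classical two-sided t test on the slope.
    """
    _check_table(table)
    if "treated" not in table.columns:
        raise ValueError("table has no 'treated' column; run label_treatment first")
    sub = table[table["day"] == day]
    df = _prepare_values(sub, value_col, log_transform, per_image)
    for flag, name in ((True, "treated"), (False, "untreated")):
        if (df["treated"] == flag).sum() < 2:
            raise InsufficientDataError(
                f"day {day}: {name} group has fewer than 2 observations"
            )
    y = df[value_col].astype(float).to_numpy()
    x = sm.add_constant(df["treated"].astype(float).to_numpy())
    fit = sm.OLS(y, x).fit()
    ci = fit.conf_int(alpha=0.05)[1]
    return RegressionResult(
        day=day,
        n_objects=int(len(df)),
        beta0=float(fit.params[0]),
        beta1=float(fit.params[1]),
        se_beta1=float(fit.bse[1]),
        t_stat=float(fit.tvalues[1]),
        p_value=float(fit.pvalues[1]),
        ci95=(float(ci[0]), float(ci[1])),
    )


def fit_all_days(
    table: pd.DataFrame,
    value_col: str = "area_px",
    log_transform: bool = False,
    per_image: bool = False,
) -> dict:
    """One size-on-treatment regression per timepoint present in the table."""
    days = sorted(pd.unique(table["day"]))
    return {
        d: fit_size_regression(table, d, value_col, log_transform, per_image)
        for d in days
    }


def default_class_edges(table: pd.DataFrame) -> tuple[float, float]:
    """Terciles of the pooled untreated distribution at the earliest day.

    These two edges split sizes into small/medium/large classes anchored
    on the untreated baseline, so class shifts under treatment are read
    against a fixed reference.
    """
    _check_table(table)
    if "treated" not in table.columns:
        raise ValueError("table has no 'treated' column; run label_treatment first")
    day0 = sorted(pd.unique(table["day"]))[0]
    ref = table[(table["day"] == day0) & (~table["treated"])]["area_px"]
    if ref.empty:
        raise ValueError("no untreated objects at the earliest day")
    e1, e2 = np.quantile(ref.astype(float), [1 / 3, 2 / 3])
    return float(e1), float(e2)


def size_class_counts(
    table: pd.DataFrame, class_edges: tuple[float, float]
) -> pd.DataFrame:
    """Small/medium/large counts and fractions per (arm, day).

    Classes: small ``area <= e1``; medium ``e1 < area <= e2``; large
    ``area > e2``.
    """
    _check_table(table)
    e1, e2 = class_edges
    if not 0 < e1 < e2:
        raise ValueError("class edges must satisfy 0 < e1 < e2")
    df = table.copy()
    a = df["area_px"].astype(float)
    df["size_class"] = np.where(a <= e1, "small", np.where(a <= e2, "medium", "large"))
    counts = (
        df.groupby(["arm", "day", "size_class"], observed=True)
        .size()
        .unstack("size_class", fill_value=0)
        .reindex(columns=["small", "medium", "large"], fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    total = counts[["small", "medium", "large"]].sum(axis=1)
    for c in ("small", "medium", "large"):
        counts[f"frac_{c}"] = counts[c] / total.where(total > 0, other=np.nan)
    counts["n"] = total
    counts["edge_small_medium"] = e1
    counts["edge_medium_large"] = e2
    return counts


def summarize_distributions(table: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-ready five-number summaries of size per (arm, day).

    Whiskers extend to the most extreme observations within 1.5 IQR of
    the quartiles; values beyond them are counted as outliers.
    """
    _check_table(table)
    if table.empty:
        raise ValueError("size table is empty")
    rows = []
    for (arm, day), grp in table.groupby(["arm", "day"], observed=True):
        a = np.sort(grp["area_px"].astype(float).to_numpy())
        if a.size == 0:  # pragma: no cover - groupby yields non-empty groups
            continue
        q1, med, q3 = np.quantile(a, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = a[(a >= lo_fence) & (a <= hi_fence)]
        rows.append(
            {
                "arm": arm,
                "day": day,
                "n": int(a.size),
                "min": float(a[0]),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(a[-1]),
                "whisker_low": float(inside[0]),
                "whisker_high": float(inside[-1]),
                "n_outliers": int(a.size - inside.size),
            }
        )
    return pd.DataFrame(rows)


def boxplot_sizes(table: pd.DataFrame, path: str) -> None:
    """Write a size-by-(arm, day) boxplot figure (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = sorted(
        ((arm, day) for (arm, day), _ in table.groupby(["arm", "day"], observed=True)),
        key=lambda t: (str(t[1]), str(t[0])),
    )
    data = [
        table[(table["arm"] == arm) & (table["day"] == day)]["area_px"].to_numpy()
        for arm, day in cells
    ]
    fig, ax = plt.subplots(figsize=(1.5 * max(len(cells), 2), 4))
    ax.boxplot(data, tick_labels=[f"{arm}\nday {day}" for arm, day in cells])
    ax.set_ylabel("organoid area (px)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def tumour_volume(
    long_diameter: float, short_diameter: float, convention: str = "as-printed"
) -> float:
    """Xenograft tumour volume from caliper diameters.

    ``"as-printed"`` returns ``0.5 * L * S``, the formula taken at face
    value as many protocols print it.  ``"ellipsoid"`` returns
    ``0.5 * L * S**2``, the common modified-ellipsoid xenograft formula;
    it is offered for explicit comparison, never silently substituted.
    """
    if long_diameter < 0 or short_diameter < 0:
        raise ValueError("diameters must be non-negative")
    if short_diameter > long_diameter:
        raise ValueError("short diameter exceeds long diameter; check argument order")
    if convention == "as-printed":
        return 0.5 * long_diameter * short_diameter
    if convention == "ellipsoid":
        return 0.5 * long_diameter * short_diameter**2
    raise ValueError("convention must be 'as-printed' or 'ellipsoid'")
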