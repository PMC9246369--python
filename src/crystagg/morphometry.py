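"""Statistics on aggregate-particle morphometry tables.

Particles traced from electron micrographs are classified as
``extended`` (short irregular fibril-like chains, measured by length)
or ``globular`` (collapsed/coalesced particles, measured by a
characteristic size).  The module computes class-wise rank-size
distributions, per-image counts and combined lengths, and two-sample
Kolmogorov–Smirnov and t tests between treatment groups.  Sizes are
unit-agnostic; units travel as column metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["rank_size", "per_image_stats", "ks_two_sample", "t_two_sample",
           "CLASSES", "MorphometryError"]

CLASSES = ("extended", "globular")


class MorphometryError(ValueError):
    pass


def _select(records: pd.DataFrame, particle_class: str | None,
            treatment=None) -> pd.DataFrame:
    df = records
    if particle_class is not None:
        if particle_class not in CLASSES:
            raise MorphometryError(f"unknown class {particle_class!r}")
        df = df[df["class"] == particle_class]
    if treatment is not None:
        df = df[df["treatment"] == treatment]
    return df


def rank_size(records: pd.DataFrame, particle_class: str,
              treatment=None) -> pd.DataFrame:
    """Sizes ranked largest-first for one class (and optional treatment).

    Returns a frame with columns ``rank`` (1-based) and ``size``; ties
    keep their input order (stable sort).
    """
    df = _select(records, particle_class, treatment)
    if df.empty:
        raise MorphometryError(
            f"no records for class={particle_class!r}, treatment={treatment!r}")
    sizes = df["size"].to_numpy(dtype=float)
    order = np.argsort(-sizes, kind="stable")
    return pd.DataFrame({"rank": np.arange(1, sizes.size + 1),
                         "size": sizes[order]})


def per_image_stats(records: pd.DataFrame) -> pd.DataFrame:
    """Per-image counts per class and combined extended length.

    One row per (treatment, image); images listed in the table but with
    no particles of a class get zeros.  Columns: n_extended,
    n_globular, combined_extended_length.
    """
    if records.empty:
        return pd.DataFrame(columns=["treatment", "image_id", "n_extended",
                                     "n_globular", "combined_extended_length"])
    out = []
    for (trt, img), grp in records.groupby(["treatment", "image_id"], sort=True):
        ext = grp[grp["class"] == "extended"]
        glob = grp[grp["class"] == "globular"]
        out.append({
            "treatment": trt,
            "image_id": img,
            "n_extended": len(ext),
            "n_globular": len(glob),
            "combined_extended_length": float(ext["size"].sum()),
        })
    return pd.DataFrame(out)


def group_summary(per_image: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± S.E.M. of the per-image statistics by treatment."""
    stats_cols = ["n_extended", "n_globular", "combined_extended_length"]
    rows = []
    for trt, grp in per_image.groupby("treatment"):
        row = {"treatment": trt, "n_images": len(grp)}
        for c in stats_cols:
            v = grp[c].to_numpy(dtype=float)
            row[f"{c}_mean"] = float(v.mean())
            row[f"{c}_sem"] = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def ks_two_sample(x, y, mode: str = "auto") -> dict:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    ``mode='exact_small'`` forces exact p-value computation (used
    automatically when |x|·|y| ≤ 10⁴); ``'asymptotic'`` uses the
    Kolmogorov limit distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise MorphometryError("KS test needs >= 2 observations per sample")
    if mode == "auto":
        mode = "exact_small" if x.size * y.size <= 10_000 else "asymptotic"
    if mode == "exact_small":
        res = stats.ks_2samp(x, y, alternative="two-sided", method="exact")
        return {"D": float(res.statistic), "p": float(res.pvalue), "mode": mode}
    if mode == "asymptotic":
        d = float(stats.ks_2samp(x, y, alternative="two-sided",
                                 method="asymp").statistic)
        en = x.size * y.size / (x.size + y.size)
        p = float(stats.kstwobign.sf(np.sqrt(en) * d))  # Kolmogorov limit
        return {"D": d, "p": min(max(p, 0.0), 1.0), "mode": mode}
    raise MorphometryError(f"unknown mode {mode!r}")


def t_two_sample(x, y, equal_variance: bool = True) -> dict:
    """Two-sided two-sample t test (Student pooled-variance by default,
    Welch when ``equal_variance=False``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise MorphometryError("t test needs >= 2 observations per sample")
    if equal_variance:
        sp2 = (((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1))
               / (x.size + y.size - 2))
        if sp2 == 0:
            raise MorphometryError("zero pooled variance")
        df = x.size + y.size - 2
    else:
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        if vx + vy == 0:
            raise MorphometryError("zero variance in both samples")
        df = (vx + vy) ** 2 / (vx ** 2 / (x.size - 1) + vy ** 2 / (y.size - 1))
    res = stats.ttest_ind(x, y, equal_var=equal_variance)
    return {"t": float(res.statistic), "df": float(df), "p": float(res.pvalue)}
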