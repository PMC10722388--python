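"""KO/WT metabolite-ratio summaries and fractional isotope-labeling vectors.

The default ratio convention divides each knockout replicate by the
wild-type mean, giving a mean ± sample SD over the KO replicates (the
"mean ± SD (n = 6)" convention of replicate metabolomics panels).  A
ratio-of-means alternative with first-order error propagation is available.
Fractional labeling normalises isotopologue intensities (M+0 .. M+k) of a
metabolite to sum to one; no natural-abundance correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _normalised(table: pd.DataFrame) -> pd.DataFrame:
    out = table.copy()
    if "normalizer" in out.columns:
        if (out["normalizer"] <= 0).any():
            raise ValueError("normalizer values must be > 0")
        out["intensity"] = out["intensity"] / out["normalizer"]
    return out


def ko_wt_ratio(table: pd.DataFrame, method: str = "per_replicate") -> pd.DataFrame:
    """Per-metabolite KO/WT ratio summary.

    ``table`` is long format with columns ``metabolite, genotype (WT/KO),
    replicate, intensity`` (isotopologue-resolved rows are summed per
    replicate first; an optional ``normalizer`` column divides intensities,
    e.g. per-cell normalisation).

    With ``method="per_replicate"`` (default) the per-replicate ratios are
    ``r_j = KO_j / mean(WT)`` and the summary is their mean and sample SD
    with ``n`` = number of KO replicates.  ``method="ratio_of_means"``
    reports ``mean(KO)/mean(WT)`` with first-order propagated SD.  A zero
    wild-type mean yields an undefined (NaN) ratio flagged in the
    ``undefined`` column.
    """
    if method not in ("per_replicate", "ratio_of_means"):
        raise ValueError(f"unknown method {method!r}")
    table = _normalised(table)
    if "isotopologue" in table.columns:
        table = (
            table.groupby(["metabolite", "genotype", "replicate"], observed=True)[
                "intensity"
            ]
            .sum()
            .reset_index()
        )
    rows = []
    for met, grp in table.groupby("metabolite", sort=True, observed=True):
        wt = grp.loc[grp["genotype"] == "WT", "intensity"].to_numpy(float)
        ko = grp.loc[grp["genotype"] == "KO", "intensity"].to_numpy(float)
        if wt.size == 0 or ko.size == 0:
            raise ValueError(f"{met}: both genotypes are required")
        wt_mean = wt.mean()
        if wt_mean == 0:
            rows.append((met, np.nan, np.nan, ko.size, True))
            continue
        if method == "per_replicate":
            r = ko / wt_mean
            mean, sd = r.mean(), r.std(ddof=1) if r.size > 1 else 0.0
        else:
            mean = ko.mean() / wt_mean
            sd = mean * np.sqrt(
                (ko.std(ddof=1) / ko.mean()) ** 2 + (wt.std(ddof=1) / wt_mean) ** 2
            )
        rows.append((met, float(mean), float(sd), ko.size, False))
    return pd.DataFrame(
        rows, columns=["metabolite", "ratio_mean", "ratio_sd", "n", "undefined"]
    )


def fractional_labeling(intensities) -> np.ndarray:
    """Normalise an isotopologue intensity vector to fractions summing to 1.

    ``intensities`` is the M+0 .. M+k vector for one metabolite (and one
    sample); entries must be non-negative with a positive sum.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("expected a nonempty 1-D intensity vector")
    if (arr < 0).any():
        raise ValueError("isotopologue intensities must be >= 0")
    total = arr.sum()
    if total == 0:
        raise ValueError("all-zero isotopologue vector")
    return arr / total


def fractional_labeling_table(table: pd.DataFrame) -> pd.DataFrame:
    """Fractional-labeling vectors for an isotopologue-resolved table.

    Requires columns ``metabolite, isotopologue, intensity`` and optionally
    ``genotype`` / ``replicate``; fractions are computed within each
    (metabolite, genotype, replicate) group and returned in long format with
    a ``fraction`` column summing to one per group.
    """
    if "isotopologue" not in table.columns:
        raise ValueError("table has no isotopologue column")
    table = _normalised(table)
    keys = [k for k in ("metabolite", "genotype", "replicate") if k in table.columns]
    out = table.copy()
    totals = out.groupby(keys, observed=True)["intensity"].transform("sum")
    if (totals == 0).any():
        bad = out.loc[totals == 0, keys[0]].iloc[0]
        raise ValueError(f"{bad}: all-zero isotopologue vector")
    out["fraction"] = out["intensity"] / totals
    return out[keys + ["isotopologue", "fraction"]]
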