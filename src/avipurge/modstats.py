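"""Module-level and family-level gene-loss statistics.

Per-module loss fractions (purged members / scored members, as a
percentage), their cross-module mean and sample standard deviation, and
3-standard-deviation outlier flags; plus the integer loss percentages
reported for explicitly listed gene families (ABC transporters, SLC9A
exchangers, SCN channels, ...).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import ModuleSet
from .purge import DEFAULT_PARAMS, CallerParams


@dataclass(frozen=True)
class ModuleLossSummary:
    """Per-module loss percentages and cross-module statistics.

    ``per_module`` has one row per module: ``module, n_members, n_lost,
    loss_percent, outlier``.  ``mean_percent`` / ``sd_percent`` are computed
    over modules with at least one scored member using the sample SD (n-1
    denominator); a module is an outlier when its loss percentage is more
    than ``n_sd`` (default 3) sample SDs from the mean.
    ``nonredundant_union`` counts distinct genes across all modules.
    """

    per_module: pd.DataFrame
    mean_percent: float
    sd_percent: float
    lower_bound: float
    upper_bound: float
    nonredundant_union: int
    n_sd: float = 3.0


def module_loss(
    calls: pd.DataFrame, modules: ModuleSet, n_sd: float = 3.0
) -> ModuleLossSummary:
    """Summarise clade calls per module.

    ``calls`` needs columns ``gene`` and ``call``.  Module members missing
    from the call table are excluded from the member count with a warning
    (they were never scored).  Loss percent is ``100 * n_lost / n_members``
    where lost means a clade call of ``purged``.
    """
    if not modules.modules:
        raise ValueError("empty module set")
    call_of = calls.set_index("gene")["call"]
    if call_of.index.has_duplicates:
        raise ValueError("duplicate gene rows in call table")
    rows = []
    missing_total = 0
    for name, members in modules.modules.items():
        scored = [g for g in members if g in call_of.index]
        missing_total += len(members) - len(scored)
        n_lost = int((call_of.loc[scored] == "purged").sum()) if scored else 0
        percent = 100.0 * n_lost / len(scored) if scored else math.nan
        rows.append((name, len(scored), n_lost, percent))
    if missing_total:
        warnings.warn(
            f"{missing_total} module member(s) had no clade call and were "
            "excluded from member counts",
            stacklevel=2,
        )
    per_module = pd.DataFrame(
        rows, columns=["module", "n_members", "n_lost", "loss_percent"]
    )
    scored_pct = per_module.loc[per_module["n_members"] >= 1, "loss_percent"]
    mean = float(scored_pct.mean())
    sd = float(scored_pct.std(ddof=1)) if len(scored_pct) > 1 else 0.0
    per_module["outlier"] = (per_module["loss_percent"] - mean).abs() > n_sd * sd
    per_module.loc[per_module["n_members"] == 0, "outlier"] = False
    return ModuleLossSummary(
        per_module=per_module,
        mean_percent=mean,
        sd_percent=sd,
        lower_bound=mean - n_sd * sd,
        upper_bound=mean + n_sd * sd,
        nonredundant_union=modules.nonredundant_union,
        n_sd=n_sd,
    )


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (9/14 -> 64%)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def family_loss_percent(
    calls: pd.DataFrame,
    family: Iterable[str],
    params: CallerParams = DEFAULT_PARAMS,
) -> int:
    """Integer loss percentage for an explicitly listed gene family.

    A member counts as lost when its clade call is ``purged`` or when it was
    absent or truncated in more than ``params.neoave_majority`` of Neoave
    species (the caller's lost predicate, regardless of outgroup support —
    matching family tallies phrased as "absent or severely truncated").
    The percentage is rounded half-away-from-zero to the nearest integer.
    """
    family = list(dict.fromkeys(family))
    if not family:
        raise ValueError("empty family")
    sub = calls[calls["gene"].isin(family)]
    missing = set(family) - set(sub["gene"])
    if missing:
        raise KeyError(f"family member(s) without a clade call: {sorted(missing)}")
    lost = (sub["call"] == "purged") | (
        sub["neoave_lost_fraction"] > params.neoave_majority
    )
    return round_half_away(100.0 * int(lost.sum()) / len(family))


def plot_module_loss(summary: ModuleLossSummary, path: str) -> None:
    """Bar plot of per-module loss percentages with dashed n-SD bounds."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = summary.per_module.sort_values("loss_percent", ascending=False)
    fig, ax = plt.subplots(figsize=(max(6, 0.22 * len(data)), 4))
    colors = np.where(data["outlier"], "firebrick", "steelblue")
    ax.bar(data["module"], data["loss_percent"], color=colors)
    for bound in (summary.lower_bound, summary.upper_bound):
        ax.axhline(bound, linestyle="--", color="grey", linewidth=1)
    ax.axhline(summary.mean_percent, linestyle="-", color="grey", linewidth=1)
    ax.set_ylabel("genes lost (%)")
    ax.set_xticks(range(len(data)), data["module"], rotation=90, fontsize=6)
    ax.set_title(
        f"mean {summary.mean_percent:.1f}% ± {summary.sd_percent:.2f} "
        f"(±{summary.n_sd:g} SD dashed)"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
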