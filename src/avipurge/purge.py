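"""Clade-level purge calling: aggregate per-species statuses per gene.

A gene is called *purged* from the focal Neoave clade when either

* it is not found (no present or truncated hit) in any sampled avian
  species, or
* it is present largely in the extant-Aves outgroups (full-length in at
  least ``outgroup_present_min`` of sampled Galloanserae + Palaeognathae
  species) while absent or severely truncated in a strict majority — more
  than ``neoave_majority`` (default 70%) — of sampled Neoave species.

A gene found somewhere in Aves whose Neoave lost fraction does not exceed
the majority threshold is *retained*; a gene lost in most Neoaves but
without sufficient outgroup presence is *ambiguous*.  Denominators count
only species with a row for that gene, so unsampled species are never
treated as absences.  Species with several paralog rows contribute their
best status (present > truncated > absent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import OUTGROUP_CLADES

CALLS = ("purged", "retained", "ambiguous")

_STATUS_RANK = {"absent": 0, "truncated": 1, "present": 2}


@dataclass(frozen=True)
class CallerParams:
    """Clade-caller thresholds.

    ``neoave_majority``: fraction of Neoave species that must be lost
    (absent or truncated), compared with strict inequality (default 0.70, so
    exactly 70% lost is still retained).  ``outgroup_present_min``: minimum
    fraction of outgroup species with a full-length hit for the gene to
    count as "present largely in extant Aves" (default 0.50).
    """

    neoave_majority: float = 0.70
    outgroup_present_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("neoave_majority", "outgroup_present_min"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")


DEFAULT_PARAMS = CallerParams()


@dataclass(frozen=True)
class CladeCall:
    """Clade-level decision for one gene with its supporting fractions."""

    gene: str
    call: str
    neoave_lost_fraction: float
    outgroup_present_fraction: float
    n_neoaves: int
    n_outgroup: int


def _species_status(status_rows: pd.DataFrame) -> pd.DataFrame:
    """Collapse paralog rows to one best status per species."""
    rank = status_rows["status"].map(_STATUS_RANK)
    best = rank.groupby(
        [status_rows["species"], status_rows["clade"]], observed=True
    ).max()
    inv = {v: k for k, v in _STATUS_RANK.items()}
    return best.map(inv).rename("status").reset_index()


def call_clade(
    status_rows: pd.DataFrame, params: CallerParams = DEFAULT_PARAMS
) -> CladeCall:
    """Call one gene from its per-species status rows.

    ``status_rows`` needs columns ``species, clade, status`` (and is usually
    one gene's slice of :func:`avipurge.classify.classify_table` output).
    At least one Neoave row is required.
    """
    genes = set(status_rows["gene"]) if "gene" in status_rows.columns else {""}
    if len(genes) != 1:
        raise ValueError(f"status rows span multiple genes: {sorted(genes)}")
    gene = genes.pop()

    per_species = _species_status(status_rows)
    neo = per_species[per_species["clade"] == "neoaves"]
    if neo.empty:
        raise ValueError(f"{gene or 'gene'}: no Neoave species rows")
    out = per_species[per_species["clade"].isin(OUTGROUP_CLADES)]

    lost_frac = float((neo["status"].isin(["absent", "truncated"])).mean())
    present_frac = float((out["status"] == "present").mean()) if len(out) else 0.0

    found_in_aves = bool((per_species["status"] != "absent").any())
    if not found_in_aves:
        call = "purged"
    elif present_frac >= params.outgroup_present_min and lost_frac > params.neoave_majority:
        call = "purged"
    elif lost_frac <= params.neoave_majority:
        call = "retained"
    else:
        call = "ambiguous"
    return CladeCall(
        gene=gene,
        call=call,
        neoave_lost_fraction=lost_frac,
        outgroup_present_fraction=present_frac,
        n_neoaves=len(neo),
        n_outgroup=len(out),
    )


def call_clades(
    status_table: pd.DataFrame, params: CallerParams = DEFAULT_PARAMS
) -> pd.DataFrame:
    """Call every gene in a status table; returns one row per gene.

    Columns: ``gene, call, neoave_lost_fraction, outgroup_present_fraction,
    n_neoaves, n_outgroup``.
    """
    best = (
        status_table.assign(_rank=status_table["status"].map(_STATUS_RANK))
        .groupby(["gene", "species", "clade"], observed=True)["_rank"]
        .max()
        .reset_index()
    )
    is_neo = best["clade"] == "neoaves"
    is_out = best["clade"].isin(OUTGROUP_CLADES)
    per_gene = pd.DataFrame(
        {
            "n_neoaves": is_neo.groupby(best["gene"], observed=True).sum(),
            "neo_lost": (is_neo & (best["_rank"] < 2)).groupby(best["gene"], observed=True).sum(),
            "n_outgroup": is_out.groupby(best["gene"], observed=True).sum(),
            "out_present": (is_out & (best["_rank"] == 2)).groupby(best["gene"], observed=True).sum(),
            "found": (best["_rank"] > 0).groupby(best["gene"], observed=True).any(),
        }
    )
    if (per_gene["n_neoaves"] == 0).any():
        missing = per_gene.index[per_gene["n_neoaves"] == 0][:5].tolist()
        raise ValueError(f"gene(s) with no Neoave species rows: {missing}")
    lost_frac = per_gene["neo_lost"] / per_gene["n_neoaves"]
    present_frac = (per_gene["out_present"] / per_gene["n_outgroup"]).fillna(0.0)
    purged = ~per_gene["found"] | (
        (present_frac >= params.outgroup_present_min)
        & (lost_frac > params.neoave_majority)
    )
    retained = ~purged & (lost_frac <= params.neoave_majority)
    out = pd.DataFrame(
        {
            "gene": per_gene.index,
            "call": np.select([purged, retained], ["purged", "retained"], "ambiguous"),
            "neoave_lost_fraction": lost_frac.to_numpy(),
            "outgroup_present_fraction": present_frac.to_numpy(),
            "n_neoaves": per_gene["n_neoaves"].to_numpy(),
            "n_outgroup": per_gene["n_outgroup"].to_numpy(),
        }
    ).sort_values("gene", ignore_index=True)
    return out
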