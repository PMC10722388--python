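"""Per-species, per-gene status classification: present / truncated / absent.

A best hit is called *present* when its length reaches a configurable
fraction of the reference canonical length (default 0.70), *truncated* when a
hit exists but falls short of that fraction, and *absent* when there is no
hit at all.  The screen this implements treats truncation as N-terminal loss
(the retained fragment is C-terminal), which is what makes counting removed
transmembrane domains well defined; a C-terminal interpretation is available
and changes only the TM count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .catalog import GeneRecord, SpeciesHit

STATUSES = ("present", "truncated", "absent")


@dataclass(frozen=True)
class ClassifierParams:
    """Status-classifier parameters.

    ``present_threshold`` is the minimum hit-length / reference-length
    fraction called present.  The default 0.70 separates the screen's worked
    truncation cases (retained fractions up to ~0.65) from full-length hits
    with margin; hits *longer* than the reference (isoform or annotation
    slack) are classified present.
    """

    present_threshold: float = 0.70
    n_terminal_truncation: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.present_threshold <= 1:
            raise ValueError("present_threshold must lie in (0, 1]")


DEFAULT_PARAMS = ClassifierParams()


@dataclass(frozen=True)
class StatusCall:
    """One species x gene status call.

    ``length_fraction`` is hit_length / ref_length (None for absent);
    ``tm_removed`` counts reference TM spans lying entirely in the lost
    region (None when the gene has no TM annotation or there is no hit).
    """

    species: str
    gene: str
    status: str
    length_fraction: float | None = None
    tm_removed: int | None = None


def count_tm_removed(
    gene: GeneRecord, hit_length: int, n_terminal: bool = True
) -> int:
    """Count TM spans removed entirely by truncating to ``hit_length``.

    With N-terminal truncation the retained region is
    ``[ref_length - hit_length + 1, ref_length]`` and a span is removed when
    it ends before that region; with C-terminal truncation the retained
    region is ``[1, hit_length]`` and a span is removed when it starts after
    it.  A hit longer than the reference yields 0 with a warning (no removal
    inferable).
    """
    if hit_length > gene.ref_length:
        warnings.warn(
            f"{gene.symbol}: hit ({hit_length} aa) longer than reference "
            f"({gene.ref_length} aa); no TM removal inferable",
            stacklevel=2,
        )
        return 0
    if n_terminal:
        retained_start = gene.ref_length - hit_length + 1
        return sum(1 for _, end in gene.tm_spans if end < retained_start)
    return sum(1 for start, _ in gene.tm_spans if start > hit_length)


def classify_status(
    hit: SpeciesHit, gene: GeneRecord, params: ClassifierParams = DEFAULT_PARAMS
) -> StatusCall:
    """Classify one hit as present, truncated or absent.

    Exactly one status results: absent iff there is no hit, present iff the
    length fraction reaches ``params.present_threshold``, truncated
    otherwise.
    """
    if hit.gene != gene.symbol:
        raise ValueError(f"hit is for {hit.gene!r}, record is {gene.symbol!r}")
    if hit.hit_length is None:
        return StatusCall(hit.species, hit.gene, "absent")
    fraction = hit.hit_length / gene.ref_length
    status = "present" if fraction >= params.present_threshold else "truncated"
    tm = None
    if gene.tm_spans and status == "truncated":
        tm = count_tm_removed(gene, hit.hit_length, params.n_terminal_truncation)
    return StatusCall(hit.species, hit.gene, status, fraction, tm)


def classify_table(
    hits: pd.DataFrame,
    catalog: Mapping[str, GeneRecord],
    params: ClassifierParams = DEFAULT_PARAMS,
) -> pd.DataFrame:
    """Vectorised classification of a hit table.

    Returns one row per input row with columns ``species, clade, gene,
    paralog_index, status, length_fraction``.  Genes missing from the
    catalogue are rejected.
    """
    unknown = set(hits["gene"]) - set(catalog)
    if unknown:
        raise KeyError(f"gene(s) not in catalogue: {sorted(unknown)[:5]}")
    ref = hits["gene"].map({g: r.ref_length for g, r in catalog.items()})
    fraction = hits["hit_length"].astype(float) / ref
    status = np.where(
        hits["hit_length"].isna(),
        "absent",
        np.where(fraction >= params.present_threshold, "present", "truncated"),
    )
    out = hits[["species", "clade", "gene", "paralog_index"]].copy()
    out["status"] = status
    out["length_fraction"] = fraction
    return out
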