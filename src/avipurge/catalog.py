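"""Readers and writers for gene catalogues, hit tables, GMT gene sets and sequences.

The on-disk formats are deliberately plain: tab-separated tables for the
reference catalogue and per-species best-hit tables, the standard GMT dialect
for gene sets (module/family membership), FASTA for protein sequences and CSV
for metabolite tables.  All parsing is locale-independent (tabs and decimal
points only).

Gene matching across species is by shared symbol in the hit table; orthology
resolution is assumed to have happened upstream (or in the simulator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Allowed clade labels for a species row.  ``neoaves`` is the focal clade;
#: ``galloanserae`` and ``palaeognathae`` are the extant-Aves outgroups used
#: as the "present largely in extant Aves" reference; ``other`` covers avian
#: species outside those three groups.
CLADES = ("neoaves", "galloanserae", "palaeognathae", "other")

#: Clades used in the outgroup-presence denominator.
OUTGROUP_CLADES = ("galloanserae", "palaeognathae")

HIT_COLUMNS = ["species", "clade", "gene", "hit_length", "paralog_index", "sequence"]


class CatalogParseError(ValueError):
    """Raised when a catalogue / hit-table / GMT file fails validation."""


@dataclass(frozen=True)
class GeneRecord:
    """One reference gene: symbol, canonical protein length and annotations.

    Parameters
    ----------
    symbol : str
        Gene symbol (e.g. ``SLC3A2``); the join key across all tables.
    ref_length : int
        Canonical protein length in amino acids; anchors the truncation rule.
    tm_spans : tuple of (int, int)
        Optional transmembrane spans as 1-based inclusive residue intervals,
        sorted and non-overlapping, within ``[1, ref_length]``.
    modules : frozenset of str
        Module identifiers this gene belongs to.
    """

    symbol: str
    ref_length: int
    tm_spans: tuple[tuple[int, int], ...] = ()
    modules: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.symbol:
            raise CatalogParseError("gene symbol must be nonempty")
        if self.ref_length < 1:
            raise CatalogParseError(
                f"{self.symbol}: ref_length must be >= 1, got {self.ref_length}"
            )
        prev_end = 0
        for start, end in self.tm_spans:
            if start < 1 or end > self.ref_length or start > end:
                raise CatalogParseError(
                    f"{self.symbol}: TM span ({start},{end}) outside "
                    f"[1,{self.ref_length}]"
                )
            if start <= prev_end:
                raise CatalogParseError(
                    f"{self.symbol}: TM spans must be sorted and non-overlapping"
                )
            prev_end = end


@dataclass(frozen=True)
class SpeciesHit:
    """One species x gene observation from a best-hit search.

    ``hit_length is None`` encodes an explicit no-hit row (the gene was
    searched for in that species and not found).  When a sequence is carried
    its length must equal ``hit_length``.  ``paralog_index`` numbers multiple
    hits of the same gene within one species from 1.
    """

    species: str
    clade: str
    gene: str
    hit_length: int | None = None
    sequence: str | None = None
    paralog_index: int = 1

    def __post_init__(self) -> None:
        if self.clade not in CLADES:
            raise CatalogParseError(
                f"unknown clade {self.clade!r}; allowed: {', '.join(CLADES)}"
            )
        if self.hit_length is None and self.sequence is not None:
            raise CatalogParseError(
                f"{self.species}/{self.gene}: sequence given for a no-hit row"
            )
        if self.hit_length is not None and self.hit_length < 1:
            raise CatalogParseError(
                f"{self.species}/{self.gene}: hit_length must be >= 1 or absent"
            )
        if self.sequence is not None and len(self.sequence) != self.hit_length:
            raise CatalogParseError(
                f"{self.species}/{self.gene}: sequence length "
                f"{len(self.sequence)} != hit_length {self.hit_length}"
            )
        if self.paralog_index < 1:
            raise CatalogParseError("paralog_index must be >= 1")


@dataclass(frozen=True)
class ModuleSet:
    """Named gene sets (KEGG modules, transporter families, ...).

    ``modules`` maps module id to its member-symbol set (duplicates within a
    module collapsed).  ``universe`` is the union of all members unless a
    wider gene universe is supplied explicitly.
    """

    modules: Mapping[str, frozenset]
    universe: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        union = frozenset().union(*self.modules.values()) if self.modules else frozenset()
        if not self.universe:
            object.__setattr__(self, "universe", union)
        for name, members in self.modules.items():
            if any(not m for m in members):
                raise CatalogParseError(f"module {name}: empty member symbol")

    @property
    def nonredundant_union(self) -> int:
        """Count of distinct gene symbols across all modules."""
        if not self.modules:
            return 0
        return len(frozenset().union(*self.modules.values()))


# ---------------------------------------------------------------------------
# catalogue TSV
# ---------------------------------------------------------------------------

def _parse_spans(text: str, line_no: int) -> tuple[tuple[int, int], ...]:
    if not text or text == "NA":
        return ()
    spans = []
    for token in text.split(";"):
        try:
            start, _, end = token.partition("-")
            spans.append((int(start), int(end)))
        except ValueError as exc:
            raise CatalogParseError(
                f"line {line_no}: malformed TM interval {token!r}"
            ) from exc
    return tuple(spans)


def read_catalog(path: str | Path) -> dict[str, GeneRecord]:
    """Read a reference-gene catalogue TSV into ``{symbol: GeneRecord}``.

    Expected columns: ``symbol``, ``ref_length`` and optionally ``tm_spans``
    (semicolon-separated ``start-end`` 1-based inclusive intervals) and
    ``modules`` (semicolon-separated identifiers).  Duplicate symbols and
    non-positive lengths are rejected with the offending line number.
    """
    records: dict[str, GeneRecord] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i_sym = header.index("symbol")
            i_len = header.index("ref_length")
        except ValueError as exc:
            raise CatalogParseError(f"{path}: missing required column: {exc}") from exc
        i_tm = header.index("tm_spans") if "tm_spans" in header else None
        i_mod = header.index("modules") if "modules" in header else None
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            symbol = parts[i_sym]
            if symbol in records:
                raise CatalogParseError(f"line {line_no}: duplicate symbol {symbol!r}")
            try:
                ref_length = int(parts[i_len])
            except ValueError as exc:
                raise CatalogParseError(
                    f"line {line_no}: unparseable ref_length {parts[i_len]!r}"
                ) from exc
            spans = _parse_spans(parts[i_tm], line_no) if i_tm is not None and len(parts) > i_tm else ()
            mods: frozenset = frozenset()
            if i_mod is not None and len(parts) > i_mod and parts[i_mod]:
                mods = frozenset(parts[i_mod].split(";"))
            try:
                records[symbol] = GeneRecord(symbol, ref_length, spans, mods)
            except CatalogParseError as exc:
                raise CatalogParseError(f"line {line_no}: {exc}") from exc
    return records


def write_catalog(records: Mapping[str, GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("symbol\tref_length\ttm_spans\tmodules\n")
        for rec in records.values():
            spans = ";".join(f"{s}-{e}" for s, e in rec.tm_spans)
            mods = ";".join(sorted(rec.modules))
            fh.write(f"{rec.symbol}\t{rec.ref_length}\t{spans}\t{mods}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> ModuleSet:
    """Read gene sets in the standard GMT dialect (name, description, members).

    A module with zero members triggers a warning and is kept empty;
    duplicate members within a module are collapsed.
    """
    modules: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CatalogParseError(
                    f"line {line_no}: GMT rows need at least name and description"
                )
            name = parts[0]
            members = frozenset(m for m in parts[2:] if m)
            if not members:
                warnings.warn(f"GMT module {name!r} has no members", stacklevel=2)
            modules[name] = members
    return ModuleSet(modules)


def write_gmt(module_set: ModuleSet, path: str | Path, description: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in module_set.modules.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# hit tables
# ---------------------------------------------------------------------------

def hits_to_frame(hits: Iterable[SpeciesHit]) -> pd.DataFrame:
    """Tabulate :class:`SpeciesHit` rows (``hit_length`` as nullable Int64)."""
    rows = [
        (h.species, h.clade, h.gene, h.hit_length, h.paralog_index, h.sequence)
        for h in hits
    ]
    frame = pd.DataFrame(rows, columns=HIT_COLUMNS)
    frame["hit_length"] = frame["hit_length"].astype("Int64")
    return frame


def frame_to_hits(frame: pd.DataFrame) -> list[SpeciesHit]:
    hits = []
    has_seq = "sequence" in frame.columns
    for row in frame.itertuples(index=False):
        length = None if pd.isna(row.hit_length) else int(row.hit_length)
        seq = getattr(row, "sequence", None) if has_seq else None
        if seq is not None and (pd.isna(seq) or seq == ""):
            seq = None
        hits.append(
            SpeciesHit(
                species=row.species,
                clade=row.clade,
                gene=row.gene,
                hit_length=length,
                sequence=seq,
                paralog_index=int(row.paralog_index),
            )
        )
    return hits


def _validate_hit_frame(frame: pd.DataFrame) -> pd.DataFrame:
    bad = set(frame["clade"]) - set(CLADES)
    if bad:
        raise CatalogParseError(
            f"unknown clade label(s) {sorted(bad)}; allowed: {', '.join(CLADES)}"
        )
    if "sequence" in frame.columns:
        seq = frame["sequence"]
        with_seq = seq.notna() & (seq != "")
        mismatch = with_seq & (
            frame["hit_length"].isna()
            | (seq.where(with_seq, "").str.len() != frame["hit_length"])
        )
        if mismatch.any():
            first = frame[mismatch].iloc[0]
            raise CatalogParseError(
                f"{first['species']}/{first['gene']}: sequence length does not "
                "match hit_length"
            )
    return frame


def read_hits(path: str | Path) -> pd.DataFrame:
    """Read a hit table TSV.

    ``hit_length`` of ``NA`` (or empty) marks an explicit no-hit row.  Clade
    labels outside the fixed vocabulary are rejected with the allowed values.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        dtype={"species": str, "clade": str, "gene": str, "sequence": str},
        na_values=["NA", ""],
        keep_default_na=False,
    )
    missing = [c for c in ("species", "clade", "gene", "hit_length") if c not in frame.columns]
    if missing:
        raise CatalogParseError(f"{path}: missing hit-table column(s) {missing}")
    frame["hit_length"] = frame["hit_length"].astype("Int64")
    if "paralog_index" not in frame.columns:
        frame["paralog_index"] = 1
    frame["paralog_index"] = frame["paralog_index"].astype(int)
    if "sequence" not in frame.columns:
        frame["sequence"] = pd.Series([pd.NA] * len(frame), dtype=object)
    return _validate_hit_frame(frame[HIT_COLUMNS])


def write_hits(frame: pd.DataFrame | Iterable[SpeciesHit], path: str | Path) -> None:
    """Write a hit table TSV; ``write_hits`` then ``read_hits`` is the identity."""
    if not isinstance(frame, pd.DataFrame):
        frame = hits_to_frame(frame)
    _validate_hit_frame(frame)
    out = frame.copy()
    cols = [c for c in HIT_COLUMNS if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(hits: pd.DataFrame | Iterable[SpeciesHit], path: str | Path) -> int:
    """Write hit sequences as FASTA with ``species|gene|paralog_index`` headers.

    Rows without a sequence are skipped; returns the number written.
    """
    if isinstance(hits, pd.DataFrame):
        hits = frame_to_hits(hits)
    records = [
        SeqRecord(Seq(h.sequence), id=f"{h.species}|{h.gene}|{h.paralog_index}",
                  description="")
        for h in hits
        if h.sequence
    ]
    return SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{header_id: sequence}`` preserving file order."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# metabolite tables
# ---------------------------------------------------------------------------

def read_metabolites(path: str | Path) -> pd.DataFrame:
    """Read a long-format metabolite CSV.

    Required columns: ``metabolite``, ``genotype`` (WT/KO), ``replicate``,
    ``intensity``; optional ``isotopologue`` (M+i index) and ``normalizer``
    (e.g. cell count) columns are preserved.
    """
    frame = pd.read_csv(path)
    required = ["metabolite", "genotype", "replicate", "intensity"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CatalogParseError(f"{path}: missing metabolite column(s) {missing}")
    if (frame["intensity"] < 0).any():
        raise CatalogParseError(f"{path}: negative intensities")
    return frame
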