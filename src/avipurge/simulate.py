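"""Forward simulator of gene retention, truncation, loss and duplication.

The panel simulator emulates a best-hit protein screen across a two-clade
bird panel (a focal Neoave clade versus extant-Aves outgroups, i.e.
Galloanserae/Palaeognathae).  For every species x gene pair exactly one event
is drawn — retain, truncate, lose or duplicate — and both the resulting hit
table and the ground-truth event log are returned, so that downstream
classifiers and clade callers can be tested for parameter recovery.

Truncation is modeled as N-terminal loss: the retained fragment is the
C-terminal part of the protein, which makes counting removed transmembrane
domains well defined.  Per-event probabilities may be scalars or per-gene
arrays, which supports gene-level regimes (e.g. a subset of genes purged
clade-wide while the rest are retained everywhere).

Randomness uses one global seed with an independent child stream per species
(and per gene for reference sequences), so results are reproducible and
insensitive to panel-size changes elsewhere in the panel.

The metabolite generator produces replicate intensity tables for a WT/KO
genotype pair with known fold changes under multiplicative log-normal noise,
optionally resolved into isotopologues with known fractional-labeling
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import GeneRecord, ModuleSet

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

EVENTS = ("retain", "truncate", "lose", "duplicate")


class SimulationError(ValueError):
    """Raised when a simulation configuration is invalid."""


def _as_gene_array(value, n_genes: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_genes,)).copy()
    if np.any((arr < 0) | (arr > 1)):
        raise SimulationError(f"{name} must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a two-clade gene retention/loss/duplication panel.

    Probabilities apply per Neoave species and per gene and may be scalars or
    length-``n_genes`` sequences; outgroup species use the ``*_outgroup``
    rates (default 0, i.e. the outgroup retains everything).  Exactly one
    event is drawn per species x gene, so ``p_loss + p_trunc + p_dup <= 1``
    must hold gene-wise; the remainder is the retain probability.

    ``trunc_frac_range`` is the (low, high) interval of the retained length
    fraction for truncation events; the default upper bound 0.65 mirrors the
    most extreme retained fragment still counted as truncated in the screen
    this emulates (roughly two-thirds of the reference length), and stays
    below the default present-threshold of the status classifier so that
    simulated truncations always classify as truncated.

    ``paralog_identity`` is the expected percent identity (0-1 scale) between
    duplicate paralogs of a gene; ``species_identity`` the expected identity
    between orthologous copies in two species.
    """

    n_neoaves: int = 150
    n_outgroup: int = 8
    n_genes: int = 100
    p_loss: float | Sequence[float] = 0.0
    p_trunc: float | Sequence[float] = 0.0
    p_dup: float | Sequence[float] = 0.0
    p_loss_outgroup: float | Sequence[float] = 0.0
    p_trunc_outgroup: float | Sequence[float] = 0.0
    trunc_frac_range: tuple[float, float] = (0.10, 0.65)
    dup_paralogs: tuple[int, int] = (2, 3)
    paralog_identity: float = 0.70
    species_identity: float = 0.95
    ref_length_range: tuple[int, int] = (300, 800)
    with_sequences: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_neoaves", "n_outgroup", "n_genes"):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be >= 1")
        low, high = self.trunc_frac_range
        if not (0 < low < high < 1):
            raise SimulationError("trunc_frac_range must satisfy 0 < low < high < 1")
        kmin, kmax = self.dup_paralogs
        if not (2 <= kmin <= kmax):
            raise SimulationError("dup_paralogs must satisfy 2 <= kmin <= kmax")
        for name in ("paralog_identity", "species_identity"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} must lie in [0, 1]")
        if not (1 <= self.ref_length_range[0] <= self.ref_length_range[1]):
            raise SimulationError("ref_length_range must be increasing and >= 1")
        # triggers range validation for every probability field
        neo = sum(
            _as_gene_array(getattr(self, n), self.n_genes, n)
            for n in ("p_loss", "p_trunc", "p_dup")
        )
        if np.any(neo > 1 + 1e-12):
            raise SimulationError("p_loss + p_trunc + p_dup must be <= 1 per gene")
        out = sum(
            _as_gene_array(getattr(self, n), self.n_genes, n)
            for n in ("p_loss_outgroup", "p_trunc_outgroup")
        )
        if np.any(out > 1 + 1e-12):
            raise SimulationError(
                "p_loss_outgroup + p_trunc_outgroup must be <= 1 per gene"
            )


@dataclass(frozen=True)
class SimulatedPanel:
    """Simulator output: reference catalogue, hit table and truth event log.

    ``hits`` has one row per species x gene x paralog (explicit no-hit rows
    carry a null ``hit_length``); ``truth`` has exactly one event row per
    species x gene with the drawn retained fraction (truncations) or paralog
    count (duplications).
    """

    catalog: dict[str, GeneRecord]
    hits: pd.DataFrame
    truth: pd.DataFrame


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``."""
    out = seq.copy()
    hit = rng.random(seq.size) < rate
    if hit.any():
        # draw a uniformly random *different* residue at each mutated site
        offsets = rng.integers(1, AMINO_ACIDS.size, size=int(hit.sum()))
        idx = np.searchsorted(AMINO_ACIDS, out[hit])
        out[hit] = AMINO_ACIDS[(idx + offsets) % AMINO_ACIDS.size]
    return out


def _gene_rng(seed: int, gene_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, 1, gene_idx])


def _species_rng(seed: int, species_idx: int) -> np.random.Generator:
    return np.random.default_rng([seed, 2, species_idx])


def simulate_panel(cfg: SimulationConfig) -> SimulatedPanel:
    """Simulate a two-clade hit table with ground truth.

    Returns a :class:`SimulatedPanel`; identical configurations (including
    the seed) give identical output.  Truncated hits have length
    ``max(1, round(frac * ref_length))`` with ``frac`` drawn uniformly from
    ``trunc_frac_range``; duplicated genes yield ``k`` full-length paralog
    rows.  When ``with_sequences`` is set, sequences are attached: a random
    reference per gene, per-paralog base sequences diverged to
    ``paralog_identity``, and per-species copies diverged so that two species
    sit near ``species_identity``.
    """
    n_genes = cfg.n_genes
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    p_loss = _as_gene_array(cfg.p_loss, n_genes, "p_loss")
    p_trunc = _as_gene_array(cfg.p_trunc, n_genes, "p_trunc")
    p_dup = _as_gene_array(cfg.p_dup, n_genes, "p_dup")
    p_loss_out = _as_gene_array(cfg.p_loss_outgroup, n_genes, "p_loss_outgroup")
    p_trunc_out = _as_gene_array(cfg.p_trunc_outgroup, n_genes, "p_trunc_outgroup")

    # per-gene reference lengths and (optionally) sequences from gene streams
    ref_lengths = np.empty(n_genes, dtype=int)
    ref_seqs: list[np.ndarray] = []
    paralog_bases: list[list[np.ndarray]] = []
    kmin, kmax = cfg.dup_paralogs
    for g in range(n_genes):
        grng = _gene_rng(cfg.rng_seed, g)
        ref_lengths[g] = grng.integers(cfg.ref_length_range[0], cfg.ref_length_range[1] + 1)
        if cfg.with_sequences:
            ref = AMINO_ACIDS[grng.integers(0, AMINO_ACIDS.size, size=ref_lengths[g])]
            ref_seqs.append(ref)
            bases = [ref]
            for _ in range(2, kmax + 1):
                bases.append(_mutate(ref, 1.0 - cfg.paralog_identity, grng))
            paralog_bases.append(bases)
    catalog = {g: GeneRecord(g, int(ref_lengths[i])) for i, g in enumerate(genes)}

    species = [(f"neoave_{i + 1:03d}", "neoaves", i) for i in range(cfg.n_neoaves)]
    out_clades = ["galloanserae", "palaeognathae"]
    species += [
        (f"outgroup_{i + 1:03d}", out_clades[i % 2], cfg.n_neoaves + i)
        for i in range(cfg.n_outgroup)
    ]

    # per-species divergence rate chosen so two independently mutated copies
    # agree at about species_identity
    sp_rate = (1.0 - cfg.species_identity) / 2.0

    hit_rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for name, clade, sp_idx in species:
        rng = _species_rng(cfg.rng_seed, sp_idx)
        is_neo = clade == "neoaves"
        lo = p_loss if is_neo else p_loss_out
        tr = p_trunc if is_neo else p_trunc_out
        du = p_dup if is_neo else np.zeros(n_genes)
        u = rng.random(n_genes)
        fracs = rng.uniform(*cfg.trunc_frac_range, size=n_genes)
        ks = rng.integers(kmin, kmax + 1, size=n_genes)
        for g, gene in enumerate(genes):
            if u[g] < lo[g]:
                truth_rows.append((name, clade, gene, "lose", np.nan, np.nan))
                hit_rows.append((name, clade, gene, None, 1, None))
            elif u[g] < lo[g] + tr[g]:
                frac = fracs[g]
                length = max(1, round(frac * ref_lengths[g]))
                seq = None
                if cfg.with_sequences:
                    full = _mutate(ref_seqs[g], sp_rate, rng)
                    seq = "".join(full[ref_lengths[g] - length:])  # C-terminal fragment
                truth_rows.append((name, clade, gene, "truncate", frac, np.nan))
                hit_rows.append((name, clade, gene, length, 1, seq))
            elif u[g] < lo[g] + tr[g] + du[g]:
                k = int(ks[g])
                truth_rows.append((name, clade, gene, "duplicate", np.nan, k))
                for p in range(1, k + 1):
                    seq = None
                    if cfg.with_sequences:
                        seq = "".join(_mutate(paralog_bases[g][p - 1], sp_rate, rng))
                    hit_rows.append((name, clade, gene, int(ref_lengths[g]), p, seq))
            else:
                seq = None
                if cfg.with_sequences:
                    seq = "".join(_mutate(ref_seqs[g], sp_rate, rng))
                truth_rows.append((name, clade, gene, "retain", np.nan, np.nan))
                hit_rows.append((name, clade, gene, int(ref_lengths[g]), 1, seq))

    hits = pd.DataFrame(
        hit_rows,
        columns=["species", "clade", "gene", "hit_length", "paralog_index", "sequence"],
    )
    hits["hit_length"] = hits["hit_length"].astype("Int64")
    truth = pd.DataFrame(
        truth_rows, columns=["species", "clade", "gene", "event", "frac", "k"]
    )
    return SimulatedPanel(catalog=catalog, hits=hits, truth=truth)


def simulate_modular_panel(
    n_modules: int,
    genes_per_module: int,
    p_gene_purge: float,
    *,
    n_neoaves: int = 150,
    n_outgroup: int = 8,
    purged_p_loss: float = 0.7,
    purged_p_trunc: float = 0.3,
    rng_seed: int = 0,
) -> tuple[SimulatedPanel, ModuleSet, np.ndarray]:
    """Simulate a panel organised into disjoint modules with gene-level purges.

    Each of the ``n_modules * genes_per_module`` genes is independently
    purged clade-wide with probability ``p_gene_purge``; a purged gene is
    lost or severely truncated in every Neoave species (loss vs truncation in
    ``purged_p_loss`` : ``purged_p_trunc`` proportion) and retained in the
    outgroup, while a non-purged gene is retained everywhere.  Returns the
    panel, the module set and the boolean truth vector of purged genes.
    """
    if not 0 <= p_gene_purge <= 1:
        raise SimulationError("p_gene_purge must lie in [0, 1]")
    n_genes = n_modules * genes_per_module
    rng = np.random.default_rng([rng_seed, 3])
    purged = rng.random(n_genes) < p_gene_purge
    cfg = SimulationConfig(
        n_neoaves=n_neoaves,
        n_outgroup=n_outgroup,
        n_genes=n_genes,
        p_loss=np.where(purged, purged_p_loss, 0.0),
        p_trunc=np.where(purged, purged_p_trunc, 0.0),
        rng_seed=rng_seed,
    )
    panel = simulate_panel(cfg)
    genes = list(panel.catalog)
    modules = {
        f"M{m + 1:03d}": frozenset(genes[m * genes_per_module:(m + 1) * genes_per_module])
        for m in range(n_modules)
    }
    return panel, ModuleSet(modules), purged


@dataclass(frozen=True)
class MetabSimConfig:
    """Configuration of a replicate WT/KO metabolite-intensity table.

    ``fold_changes`` are true KO/WT ratios, scalar or per metabolite; when
    omitted they are drawn log2-uniformly in [-3, 3].  Noise is
    multiplicative log-normal with parameter ``sigma`` (sigma = 0 gives
    noiseless tables).  ``n_isotopologues > 0`` adds an isotopologue column
    (M+0 .. M+k) with Dirichlet-distributed true fractional-labeling vectors.
    """

    n_metabolites: int = 10
    n_replicates: int = 6
    fold_changes: float | Sequence[float] | None = None
    sigma: float = 0.2
    baseline: float = 1e6
    n_isotopologues: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_metabolites < 1:
            raise SimulationError("n_metabolites must be >= 1")
        if self.n_replicates < 2:
            raise SimulationError("n_replicates must be >= 2")
        if self.sigma < 0:
            raise SimulationError("sigma must be >= 0")
        if self.baseline <= 0:
            raise SimulationError("baseline must be > 0")
        if self.fold_changes is not None:
            fc = np.broadcast_to(
                np.asarray(self.fold_changes, dtype=float), (self.n_metabolites,)
            )
            if np.any(fc <= 0):
                raise SimulationError("fold_changes must be > 0")


@dataclass(frozen=True)
class SimulatedMetabolites:
    """Long-format metabolite table plus the generating truth."""

    table: pd.DataFrame
    fold_changes: pd.Series
    labeling_fractions: pd.DataFrame | None = None


def simulate_metab(cfg: MetabSimConfig) -> SimulatedMetabolites:
    """Simulate a WT/KO metabolite table with known fold changes.

    Intensities are strictly positive: ``baseline * fold^(genotype==KO) *
    exp(sigma * Z)`` per replicate.  With ``n_isotopologues`` set, each
    metabolite's intensity is split across isotopologues by its true
    fractional-labeling vector before noise is applied.
    """
    rng = np.random.default_rng([cfg.rng_seed, 4])
    mets = [f"met_{i + 1:03d}" for i in range(cfg.n_metabolites)]
    if cfg.fold_changes is None:
        folds = 2.0 ** rng.uniform(-3, 3, size=cfg.n_metabolites)
    else:
        folds = np.broadcast_to(
            np.asarray(cfg.fold_changes, dtype=float), (cfg.n_metabolites,)
        ).copy()

    labeling = None
    if cfg.n_isotopologues > 0:
        fracs = rng.dirichlet(np.ones(cfg.n_isotopologues + 1), size=cfg.n_metabolites)
        labeling = pd.DataFrame(
            fracs, index=mets,
            columns=[f"M+{i}" for i in range(cfg.n_isotopologues + 1)],
        )

    rows = []
    for m, met in enumerate(mets):
        for genotype, level in (("WT", cfg.baseline), ("KO", cfg.baseline * folds[m])):
            for rep in range(1, cfg.n_replicates + 1):
                noise = float(np.exp(cfg.sigma * rng.standard_normal()))
                total = level * noise
                if labeling is None:
                    rows.append((met, genotype, rep, total))
                else:
                    for i in range(cfg.n_isotopologues + 1):
                        rows.append(
                            (met, genotype, rep, f"M+{i}", total * labeling.iloc[m, i])
                        )
    if labeling is None:
        table = pd.DataFrame(rows, columns=["metabolite", "genotype", "replicate", "intensity"])
    else:
        table = pd.DataFrame(
            rows, columns=["metabolite", "genotype", "replicate", "isotopologue", "intensity"]
        )
    return SimulatedMetabolites(
        table=table,
        fold_changes=pd.Series(folds, index=mets, name="fold_change"),
        labeling_fractions=labeling,
    )
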