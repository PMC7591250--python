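"""Synthetic reference catalogs, genomes and spike-in communities.

The simulator is the fixture generator for the whole pipeline: it builds a
miniature reference catalog (25 universal marker families, the five merged
phenazine biosynthesis families, the two degradation genes), a panel of
synthetic species genomes that embed those genes in single copy, and
shotgun communities in which producer and degrader read fractions are known
exactly.

Catalog-vs-genome divergence emulates environmental sequence variation:
the catalog carries one sequence per marker family (the family ancestor)
and one variant per producer/degrader species for trait families, while
each species' genomic gene copy is mutated at ``divergence`` amino-acid
positions, so reads map at approximately ``100 * (1 - divergence)``
percent identity.  Trait variants of different species are separated by an
additional inter-species divergence so that reads resolve to the correct
producer at the species level.

Abundance is defined as read (DNA) fraction; reads are allocated per
species by largest-remainder rounding so ground truth is exact, and reads
are error-free 150 nt fragments sampled uniformly from both strands.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from . import _align
from .catalog import (
    DEGRADATION_FAMILIES,
    PHZ_FAMILIES,
    ReferenceCatalog,
    ReferenceProtein,
)

_NT = np.frombuffer(b"ACGTN", dtype=np.uint8)

_PRODUCER_POOL = [
    ("Pseudomonas_sim_A", "Pseudomonadales", "Pseudomonas"),
    ("Streptomyces_sim_B", "Streptomycetales", "Streptomyces"),
    ("Dyella_sim_C", "Xanthomonadales", "Dyella"),
    ("Brevibacterium_sim_D", "Micrococcales", "Brevibacterium"),
]
_DEGRADER_POOL = [
    ("Mycobacterium_sim_X", "Mycobacteriales", "Mycobacterium"),
    ("Rhodococcus_sim_Y", "Mycobacteriales", "Rhodococcus"),
]
_BACKGROUND_ORDERS = [
    "Bacillales",
    "Rhizobiales",
    "Burkholderiales",
    "Sphingomonadales",
    "Actinomycetales",
    "Clostridiales",
    "Cytophagales",
]


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLocus:
    family: str
    start: int
    end: int  # exclusive
    strand: int  # +1 forward, -1 reverse


@dataclass
class SyntheticSpecies:
    """A synthetic genome with known embedded gene loci."""

    species_id: str
    role: str  # producer | degrader | background
    genome_codes: np.ndarray  # uint8 nucleotide codes
    embedded_families: list[GeneLocus]
    order: str
    genus: str

    @property
    def genome(self) -> str:
        return _NT[self.genome_codes].tobytes().decode("ascii")

    @property
    def genome_length(self) -> int:
        return len(self.genome_codes)


@dataclass(frozen=True)
class GroundTruth:
    total_producer_fraction: float
    producer_fractions: Mapping[str, float]
    degrader_fraction: float
    degrader_fractions: Mapping[str, float]


@dataclass
class CommunitySpec:
    """Ground-truth description of one simulated community."""

    community_id: str
    members: list[tuple[str, float]]  # (species_id, read_fraction)
    library_size: int
    read_length: int
    seed: int
    ground_truth: GroundTruth
    condition: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SimulatorConfig:
    """Study-condition defaults for the synthetic reference generator."""

    n_markers: int = 25
    phz_families: Sequence[str] = PHZ_FAMILIES
    degradation_families: Sequence[str] = DEGRADATION_FAMILIES
    n_background: int = 28
    n_producers: int = 2
    n_degraders: int = 1
    divergence: float = 0.10
    species_divergence: float = 0.20
    gene_length_range: tuple[int, int] = (150, 450)
    genome_length: int = 100_000
    working_identity_threshold: float = 80.0


# -- sequence helpers ----------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, _align.N_AA, size=length).astype(np.uint8)


def _mutate_protein(rng: np.random.Generator, codes: np.ndarray, divergence: float) -> np.ndarray:
    out = codes.copy()
    hit = rng.random(len(codes)) < divergence
    if hit.any():
        shift = rng.integers(1, _align.N_AA, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % _align.N_AA
    return out


def _codon_choices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per amino acid: (offsets, counts, flat codon array of nt-code triples)."""
    by_aa: dict[int, list[tuple[int, int, int]]] = {a: [] for a in range(_align.N_AA)}
    for i0 in range(4):
        for i1 in range(4):
            for i2 in range(4):
                aa = int(_align.CODON_TABLE[i0 * 25 + i1 * 5 + i2])
                if aa < _align.N_AA:
                    by_aa[aa].append((i0, i1, i2))
    offsets = np.zeros(_align.N_AA + 1, dtype=np.int64)
    flat = []
    for a in range(_align.N_AA):
        offsets[a + 1] = offsets[a] + len(by_aa[a])
        flat.extend(by_aa[a])
    counts = np.diff(offsets)
    return offsets, counts, np.array(flat, dtype=np.uint8)


_CODON_OFF, _CODON_N, _CODON_FLAT = _codon_choices()


def _reverse_translate(rng: np.random.Generator, aa_codes: np.ndarray) -> np.ndarray:
    """Pick a random synonymous codon per residue; returns nt codes."""
    pick = _CODON_OFF[aa_codes] + rng.integers(0, 1 << 30, size=len(aa_codes)) % _CODON_N[aa_codes]
    return _CODON_FLAT[pick].reshape(-1)


def _revcomp(codes: np.ndarray) -> np.ndarray:
    return np.where(codes < 4, 3 - codes, codes)[::-1]


def _aa_string(codes: np.ndarray) -> str:
    return "".join(_align.AA_ALPHABET[c] for c in codes)


# -- reference generation ------------------------------------------------

def make_synthetic_references(
    seed: int, config: SimulatorConfig = SimulatorConfig()
) -> tuple[ReferenceCatalog, list[SyntheticSpecies]]:
    """Generate a synthetic reference catalog and matching species panel.

    Every species embeds one copy of each marker family; producers embed
    one copy of each phenazine family and degraders one copy of each
    degradation gene.  Background species carry no trait genes, so a
    community without producers contains no reads overlapping trait loci.
    """
    cfg = config
    if not 0.0 <= cfg.divergence <= 0.2:
        raise SimulationError("divergence must be in [0, 0.2]")
    if cfg.n_producers > len(_PRODUCER_POOL) or cfg.n_degraders > len(_DEGRADER_POOL):
        raise SimulationError("too many producers/degraders requested")
    mapped_identity = 100.0 * (1.0 - cfg.divergence)
    if mapped_identity < cfg.working_identity_threshold:
        warnings.warn(
            f"divergence {cfg.divergence} puts expected mapped identity "
            f"({mapped_identity:.0f}%) below the working threshold "
            f"({cfg.working_identity_threshold:.0f}%); reads will largely be filtered",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lo, hi = cfg.gene_length_range

    marker_names = [f"marker_{i + 1:02d}" for i in range(cfg.n_markers)]
    ancestors: dict[str, np.ndarray] = {}
    for name in marker_names + list(cfg.phz_families) + list(cfg.degradation_families):
        ancestors[name] = _random_protein(rng, int(rng.integers(lo, hi + 1)))

    producers = [_PRODUCER_POOL[i] for i in range(cfg.n_producers)]
    degraders = [_DEGRADER_POOL[i] for i in range(cfg.n_degraders)]

    # catalog-side sequences
    proteins: list[ReferenceProtein] = []
    for name in marker_names:
        proteins.append(
            ReferenceProtein(
                protein_id=f"{name}|ref",
                family=name,
                category="marker",
                species="marker_reference",
                order="NA",
                genus="NA",
                sequence=_aa_string(ancestors[name]),
            )
        )
    trait_variants: dict[tuple[str, str], np.ndarray] = {}
    for fam in cfg.phz_families:
        for sp, order, genus in producers:
            var = _mutate_protein(rng, ancestors[fam], cfg.species_divergence)
            trait_variants[(fam, sp)] = var
            proteins.append(
                ReferenceProtein(
                    protein_id=f"{fam}|{sp}",
                    family=fam,
                    category="trait_biosynthesis",
                    species=sp,
                    order=order,
                    genus=genus,
                    sequence=_aa_string(var),
                )
            )
    for fam in cfg.degradation_families:
        for sp, order, genus in degraders:
            var = _mutate_protein(rng, ancestors[fam], cfg.species_divergence)
            trait_variants[(fam, sp)] = var
            proteins.append(
                ReferenceProtein(
                    protein_id=f"{fam}|{sp}",
                    family=fam,
                    category="trait_degradation",
                    species=sp,
                    order=order,
                    genus=genus,
                    sequence=_aa_string(var),
                )
            )
    catalog = ReferenceCatalog(proteins)

    # species genomes
    species: list[SyntheticSpecies] = []

    def build_species(species_id: str, role: str, order: str, genus: str,
                      trait_fams: Sequence[str]) -> SyntheticSpecies:
        genes: list[tuple[str, np.ndarray]] = []
        for name in marker_names:
            genes.append((name, _mutate_protein(rng, ancestors[name], cfg.divergence)))
        for fam in trait_fams:
            genes.append(
                (fam, _mutate_protein(rng, trait_variants[(fam, species_id)], cfg.divergence))
            )
        order_idx = rng.permutation(len(genes))
        nt_genes = [(genes[i][0], _reverse_translate(rng, genes[i][1])) for i in order_idx]
        total_nt = sum(len(g) for _, g in nt_genes)
        padding = cfg.genome_length - total_nt
        if padding < 0:
            raise SimulationError(
                f"genome_length {cfg.genome_length} too short for {total_nt} nt of genes"
            )
        gaps = rng.multinomial(padding, np.full(len(nt_genes) + 1, 1.0 / (len(nt_genes) + 1)))
        parts: list[np.ndarray] = []
        loci: list[GeneLocus] = []
        pos = 0
        for gi, (fam, gene_nt) in enumerate(nt_genes):
            gap = rng.integers(0, 4, size=gaps[gi]).astype(np.uint8)
            parts.append(gap)
            pos += len(gap)
            strand = 1 if rng.random() < 0.5 else -1
            placed = gene_nt if strand == 1 else _revcomp(gene_nt)
            parts.append(placed.astype(np.uint8))
            loci.append(GeneLocus(fam, pos, pos + len(placed), strand))
            pos += len(placed)
        parts.append(rng.integers(0, 4, size=gaps[-1]).astype(np.uint8))
        genome = np.concatenate(parts)
        return SyntheticSpecies(species_id, role, genome, loci, order, genus)

    for sp, order, genus in producers:
        species.append(build_species(sp, "producer", order, genus, list(cfg.phz_families)))
    for sp, order, genus in degraders:
        species.append(build_species(sp, "degrader", order, genus, list(cfg.degradation_families)))
    for i in range(cfg.n_background):
        order = _BACKGROUND_ORDERS[i % len(_BACKGROUND_ORDERS)]
        species.append(
            build_species(f"background_{i + 1:02d}", "background", order, f"genus_{i + 1:02d}", [])
        )
    return catalog, species


# -- community composition ----------------------------------------------

def compose_community(
    species: Sequence[SyntheticSpecies],
    producer_fractions: float | Mapping[str, float],
    degrader_fraction: float = 0.0,
    seed: int = 0,
    library_size: int = 1_000_000,
    read_length: int = 150,
    community_id: str = "community",
) -> CommunitySpec:
    """Compose a community with exact producer/degrader read fractions.

    ``producer_fractions`` is either a mapping of producer species id to
    fraction (used as given) or a total that is split uniformly at random
    among the producer species present.  The remaining mass is distributed
    over background species via a symmetric Dirichlet(1) draw.
    """
    rng = np.random.default_rng([seed, 0])
    by_role: dict[str, list[SyntheticSpecies]] = {"producer": [], "degrader": [], "background": []}
    for sp in species:
        by_role[sp.role].append(sp)
    if not by_role["background"]:
        raise SimulationError("community needs at least one background species")

    if isinstance(producer_fractions, Mapping):
        prod = {k: float(v) for k, v in producer_fractions.items()}
        known = {sp.species_id for sp in by_role["producer"]}
        unknown = set(prod) - known
        if unknown:
            raise SimulationError(f"unknown producer species: {sorted(unknown)}")
    else:
        total = float(producer_fractions)
        prods = by_role["producer"]
        if total > 0 and not prods:
            raise SimulationError("producer fraction requested but no producer species")
        if total > 0:
            split = rng.dirichlet(np.ones(len(prods)))
            prod = {sp.species_id: total * s for sp, s in zip(prods, split)}
        else:
            prod = {}
    total_producer = sum(prod.values())

    degr: dict[str, float] = {}
    if degrader_fraction > 0:
        dgs = by_role["degrader"]
        if not dgs:
            raise SimulationError("degrader fraction requested but no degrader species")
        split = rng.dirichlet(np.ones(len(dgs)))
        degr = {sp.species_id: degrader_fraction * s for sp, s in zip(dgs, split)}

    spoken = total_producer + degrader_fraction
    if spoken >= 1.0:
        raise SimulationError(f"producer + degrader fractions sum to {spoken} >= 1")
    if min([*prod.values(), *degr.values()], default=0.0) < 0:
        raise SimulationError("fractions must be non-negative")

    bg = by_role["background"]
    bg_fracs = rng.dirichlet(np.ones(len(bg))) * (1.0 - spoken)

    members: list[tuple[str, float]] = []
    for sp in species:
        if sp.role == "producer":
            members.append((sp.species_id, prod.get(sp.species_id, 0.0)))
        elif sp.role == "degrader":
            members.append((sp.species_id, degr.get(sp.species_id, 0.0)))
    members.extend((sp.species_id, f) for sp, f in zip(bg, bg_fracs))

    return CommunitySpec(
        community_id=community_id,
        members=members,
        library_size=int(library_size),
        read_length=int(read_length),
        seed=int(seed),
        ground_truth=GroundTruth(
            total_producer_fraction=total_producer,
            producer_fractions=prod,
            degrader_fraction=float(degrader_fraction),
            degrader_fractions=degr,
        ),
    )


def largest_remainder_counts(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer read counts summing to ``total``, closest to ``fractions * total``."""
    exact = np.asarray(fractions, dtype=float) * total
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(exact - base), kind="stable")
        base[order[:short]] += 1
    return base


@njit(cache=False)
def _extract_reads(genome, starts, flips, read_length, out, row0):
    """Copy fragments (reverse-complemented where flagged) into ``out``."""
    for i in range(starts.shape[0]):
        s = starts[i]
        if flips[i]:
            for p in range(read_length):
                b = genome[s + read_length - 1 - p]
                out[row0 + i, p] = 3 - b if b < 4 else b
        else:
            for p in range(read_length):
                out[row0 + i, p] = genome[s + p]


def draw_reads(
    spec: CommunitySpec,
    species: Sequence[SyntheticSpecies],
    counts_mode: str = "largest_remainder",
    error_rate: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Sample a community's reads in memory.

    Returns ``(read_matrix, species_index, realized_counts)`` where
    ``read_matrix`` is a (library_size, read_length) uint8 code matrix and
    ``species_index`` maps each read row to its position in ``spec.members``.
    """
    by_id = {sp.species_id: sp for sp in species}
    rng = np.random.default_rng([spec.seed, 1])
    fracs = np.array([f for _, f in spec.members])
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise SimulationError(f"member fractions sum to {fracs.sum()}, expected 1")
    if counts_mode == "largest_remainder":
        counts = largest_remainder_counts(fracs, spec.library_size)
    elif counts_mode == "multinomial":
        counts = rng.multinomial(spec.library_size, fracs)
    else:
        raise SimulationError(f"unknown counts_mode {counts_mode!r}")

    L = spec.read_length
    mat = np.empty((spec.library_size, L), dtype=np.uint8)
    sp_idx = np.empty(spec.library_size, dtype=np.int32)
    row = 0
    realized: dict[str, int] = {}
    for mi, ((sid, _), cnt) in enumerate(zip(spec.members, counts)):
        realized[sid] = int(cnt)
        if cnt == 0:
            continue
        genome = by_id[sid].genome_codes
        if len(genome) < L:
            raise SimulationError(f"genome of {sid!r} shorter than read length {L}")
        starts = rng.integers(0, len(genome) - L + 1, size=cnt)
        flip = rng.random(cnt) < 0.5
        _extract_reads(genome, starts, flip, L, mat, row)
        if error_rate > 0:
            block = mat[row : row + cnt]
            err = rng.random(block.shape) < error_rate
            if err.any():
                block[err] = (block[err] + rng.integers(1, 4, size=int(err.sum()))) % 4
        sp_idx[row : row + cnt] = mi
        row += cnt
    assert row == spec.library_size
    return mat, sp_idx, realized


def sample_reads(
    spec: CommunitySpec,
    species: Sequence[SyntheticSpecies],
    reads_path: str | Path,
    truth_path: str | Path | None = None,
    counts_mode: str = "largest_remainder",
    error_rate: float = 0.0,
    format: str = "fasta",
) -> tuple[Path, Path]:
    """Write a community's reads plus a ground-truth sidecar TSV.

    ``format`` is ``"fasta"`` (default) or ``"fastq"`` (uniform Q40
    qualities, reads being error-free by default).
    """
    if format not in ("fasta", "fastq"):
        raise SimulationError(f"unknown reads format {format!r}")
    mat, sp_idx, realized = draw_reads(spec, species, counts_mode, error_rate)
    reads_path = Path(reads_path)
    member_ids = [sid for sid, _ in spec.members]
    qual = b"I" * spec.read_length  # Q40
    with open(reads_path, "wb") as fh:
        for i in range(mat.shape[0]):
            name = f"{spec.community_id}_r{i:07d} {member_ids[sp_idx[i]]}"
            if format == "fasta":
                fh.write(f">{name}\n".encode())
                fh.write(_NT[mat[i]].tobytes())
                fh.write(b"\n")
            else:
                fh.write(f"@{name}\n".encode())
                fh.write(_NT[mat[i]].tobytes())
                fh.write(b"\n+\n")
                fh.write(qual)
                fh.write(b"\n")
    truth_path = Path(truth_path) if truth_path else reads_path.with_suffix(".truth.tsv")
    by_id = {sp.species_id: sp for sp in species}
    pd.DataFrame(
        [
            {
                "species_id": sid,
                "role": by_id[sid].role,
                "requested_fraction": frac,
                "realized_reads": realized[sid],
            }
            for sid, frac in spec.members
        ]
    ).to_csv(truth_path, sep="\t", index=False)
    return reads_path, truth_path


# -- factorial benchmark design -----------------------------------------

#: Library coverages used in the full validation design (reads per community).
FULL_COVERAGES = (5_000_000, 10_000_000, 15_000_000, 20_000_000)
#: Spiked total producer abundances (read fractions).
FULL_ABUNDANCES = (0.0, 0.001, 0.0025, 0.005, 0.01, 0.015, 0.025, 0.035, 0.05)
#: Producer combinations: first producer alone, second alone, or both mixed.
DEFAULT_COMBOS = ("producer_a", "producer_b", "both")

#: Desk-scale defaults: small enough to run on one CPU in minutes.
DESK_COVERAGES = (500_000, 1_000_000)
DESK_ABUNDANCES = (0.0, 0.001, 0.0025, 0.005, 0.01, 0.025, 0.05)

#: Degrader spike-in range (log-uniform), emulating a gradient of known levels.
DEGRADER_RANGE = (0.0005, 0.05)


def factorial_design(
    species: Sequence[SyntheticSpecies],
    coverages: Sequence[int] = FULL_COVERAGES,
    abundances: Sequence[float] = FULL_ABUNDANCES,
    combos: Sequence[str] = DEFAULT_COMBOS,
    replicates: int = 12,
    seed: int = 0,
    read_length: int = 150,
    degrader_range: tuple[float, float] = DEGRADER_RANGE,
) -> list[CommunitySpec]:
    """Full factorial of coverage x abundance x producer-combo x replicate.

    Background composition and the degrader frequency are re-randomized in
    every replicate; the design is deterministic given ``seed``.
    """
    if not (coverages and abundances and combos and replicates > 0):
        raise SimulationError("design axes must be non-empty")
    producers = [sp.species_id for sp in species if sp.role == "producer"]
    combo_map: dict[str, tuple[str, ...]] = {}
    for combo in combos:
        if combo == "both":
            combo_map[combo] = tuple(producers)
        elif combo.startswith("producer_"):
            idx = ord(combo[-1].lower()) - ord("a")
            if idx >= len(producers):
                raise SimulationError(f"combo {combo!r} exceeds available producers")
            combo_map[combo] = (producers[idx],)
        else:
            if combo not in producers:
                raise SimulationError(f"unknown combo {combo!r}")
            combo_map[combo] = (combo,)

    rng = np.random.default_rng(seed)
    lo, hi = math.log(degrader_range[0]), math.log(degrader_range[1])
    design: list[CommunitySpec] = []
    for cov in coverages:
        for ab in abundances:
            for combo in combos:
                for rep in range(replicates):
                    cseed = int(rng.integers(2 ** 31))
                    degr = float(math.exp(rng.uniform(lo, hi)))
                    chosen = combo_map[combo]
                    fractions: float | Mapping[str, float]
                    if ab == 0:
                        fractions = {}
                    elif len(chosen) == 1:
                        fractions = {chosen[0]: ab}
                    else:
                        split = np.random.default_rng([cseed, 2]).dirichlet(
                            np.ones(len(chosen))
                        )
                        fractions = {sp: ab * s for sp, s in zip(chosen, split)}
                    spec = compose_community(
                        species,
                        fractions,
                        degrader_fraction=degr,
                        seed=cseed,
                        library_size=int(cov),
                        read_length=read_length,
                        community_id=f"cov{int(cov)}_ab{ab:g}_{combo}_rep{rep + 1}",
                    )
                    spec.condition = {
                        "coverage": int(cov),
                        "abundance": float(ab),
                        "combo": combo,
                        "replicate": rep + 1,
                    }
                    design.append(spec)
    return design


# -- persistence ---------------------------------------------------------

def save_species(species: Sequence[SyntheticSpecies], out_dir: str | Path) -> None:
    """Write genomes FASTA plus species and gene-locus TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genomes.fasta", "wb") as fh:
        for sp in species:
            fh.write(f">{sp.species_id} {sp.role}\n".encode())
            fh.write(_NT[sp.genome_codes].tobytes())
            fh.write(b"\n")
    pd.DataFrame(
        [
            {"species_id": sp.species_id, "role": sp.role, "order": sp.order, "genus": sp.genus}
            for sp in species
        ]
    ).to_csv(out / "species.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "species_id": sp.species_id,
                "family": loc.family,
                "start": loc.start,
                "end": loc.end,
                "strand": loc.strand,
            }
            for sp in species
            for loc in sp.embedded_families
        ]
    ).to_csv(out / "gene_loci.tsv", sep="\t", index=False)


def load_species(in_dir: str | Path) -> list[SyntheticSpecies]:
    """Load a species panel written by :func:`save_species`."""
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "species.tsv", sep="\t").set_index("species_id")
    loci = pd.read_csv(in_dir / "gene_loci.tsv", sep="\t")
    genomes: dict[str, np.ndarray] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(in_dir / "genomes.fasta"), "fasta"):
        genomes[rec.id] = _align.encode_nt(str(rec.seq))
    species = []
    for sid, row in meta.iterrows():
        sp_loci = [
            GeneLocus(r.family, int(r.start), int(r.end), int(r.strand))
            for r in loci[loci["species_id"] == sid].itertuples()
        ]
        species.append(
            SyntheticSpecies(
                species_id=str(sid),
                role=row["role"],
                genome_codes=genomes[str(sid)],
                embedded_families=sp_loci,
                order=row["order"],
                genus=row["genus"],
            )
        )
    return species
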