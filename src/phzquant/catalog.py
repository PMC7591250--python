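"""Reference catalog of trait and marker protein families.

A catalog groups reference proteins into gene families belonging to one of
three categories:

``trait_biosynthesis``
    The core phenazine biosynthesis genes.  ``phzA`` and ``phzB`` share
    highly similar sequences and are merged into a single ``phzA_B`` family,
    giving five quantified families (``phzA_B``, ``phzD``, ``phzE``,
    ``phzF``, ``phzG``).  ``phzC`` is excluded altogether: near-identical
    copies occur in non-producer genomes and would inflate the signal.
``trait_degradation``
    Phenazine biodegradation genes, quantified one family per gene
    (``phdA`` for PCA degradation, ``podA`` for pyocyanin demethylation).
``marker``
    Universal single-copy marker genes (default 25) used as the
    "total-bacteria" baseline for normalization.

The catalog is read from a protein FASTA plus a sidecar metadata TSV
(columns: ``protein_id``, ``family``, ``category``, ``species``, ``order``,
``genus``).  The FASTA record order defines the catalog's deterministic
total order, which is also the tie-breaking order for equal-scoring hits
during translated search.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("trait_biosynthesis", "trait_degradation", "marker")
#: Quantified phenazine biosynthesis families (phzA/phzB merged, phzC excluded).
PHZ_FAMILIES = ("phzA_B", "phzD", "phzE", "phzF", "phzG")
#: Biodegradation gene families, each quantified on its own.
DEGRADATION_FAMILIES = ("phdA", "podA")
#: Families that must never appear in a catalog.
EXCLUDED_FAMILIES = ("phzC",)

METADATA_COLUMNS = ("protein_id", "family", "category", "species", "order", "genus")


class CatalogError(ValueError):
    """Raised for malformed or rule-violating reference catalogs."""


@dataclass(frozen=True)
class ReferenceProtein:
    """A single reference protein sequence with its family and taxonomy."""

    protein_id: str
    family: str
    category: str
    species: str
    order: str
    genus: str
    sequence: str

    @property
    def length_aa(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFamily:
    """Summary statistics for one gene family."""

    name: str
    category: str
    mean_length_aa: float
    n_members: int


@dataclass
class ValidationReport:
    """Report-only outcome of :func:`validate_catalog`."""

    passed: bool
    issues: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


class ReferenceCatalog:
    """Indexed protein reference set defining trait and marker families.

    Parameters
    ----------
    proteins:
        Reference proteins in database order.  The order of this sequence is
        the catalog ordering used for best-hit tie-breaking.
    """

    def __init__(self, proteins: Iterable[ReferenceProtein]):
        self.proteins: list[ReferenceProtein] = list(proteins)
        if not self.proteins:
            raise CatalogError("catalog must contain at least one protein")
        ids = [p.protein_id for p in self.proteins]
        dupes = [i for i, n in collections.Counter(ids).items() if n > 1]
        if dupes:
            raise CatalogError(f"duplicate protein ids: {sorted(dupes)[:5]}")
        self._by_id: dict[str, ReferenceProtein] = {p.protein_id: p for p in self.proteins}
        self._index: dict[str, int] = {pid: i for i, pid in enumerate(ids)}

        fam_cat: dict[str, str] = {}
        fam_members: dict[str, list[ReferenceProtein]] = collections.defaultdict(list)
        for p in self.proteins:
            if p.category not in CATEGORIES:
                raise CatalogError(
                    f"unknown category {p.category!r} for protein {p.protein_id!r}; "
                    f"expected one of {CATEGORIES}"
                )
            if p.family in EXCLUDED_FAMILIES:
                raise CatalogError(
                    f"family {p.family!r} is excluded by catalog rules: highly similar "
                    "copies occur in non-producer genomes (protein "
                    f"{p.protein_id!r})"
                )
            prev = fam_cat.setdefault(p.family, p.category)
            if prev != p.category:
                raise CatalogError(
                    f"family {p.family!r} assigned to both {prev!r} and {p.category!r}"
                )
            fam_members[p.family].append(p)

        self.families: dict[str, GeneFamily] = {
            name: GeneFamily(
                name=name,
                category=fam_cat[name],
                mean_length_aa=float(np.mean([m.length_aa for m in members])),
                n_members=len(members),
            )
            for name, members in fam_members.items()
        }
        if not self.families_in_category("marker"):
            raise CatalogError("catalog has no marker-category families")

    # -- lookups ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self._by_id

    def protein(self, protein_id: str) -> ReferenceProtein:
        try:
            return self._by_id[protein_id]
        except KeyError:
            raise CatalogError(f"protein {protein_id!r} not in catalog") from None

    def position(self, protein_id: str) -> int:
        """Zero-based catalog (database) position of ``protein_id``."""
        return self._index[protein_id]

    @property
    def ordering(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    def families_in_category(self, category: str) -> list[str]:
        return sorted(f.name for f in self.families.values() if f.category == category)

    @property
    def marker_families(self) -> list[str]:
        return self.families_in_category("marker")

    @property
    def phz_families(self) -> list[str]:
        return self.families_in_category("trait_biosynthesis")

    @property
    def degradation_families(self) -> list[str]:
        return self.families_in_category("trait_degradation")


def load_catalog(protein_fasta: str | Path, metadata_tsv: str | Path) -> ReferenceCatalog:
    """Load a reference catalog from a protein FASTA and a metadata TSV.

    Every FASTA record id must have a metadata row; catalog ordering is the
    order of appearance in the FASTA.
    """
    meta = pd.read_csv(metadata_tsv, sep="\t", dtype=str)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise CatalogError(f"metadata is missing columns: {sorted(missing_cols)}")
    bad_fams = set(meta["family"]) & set(EXCLUDED_FAMILIES)
    if bad_fams:
        raise CatalogError(
            f"metadata contains excluded families {sorted(bad_fams)}: catalog rules "
            "remove genes with near-identical copies in non-trait genomes"
        )
    rows: Mapping[str, pd.Series] = {r.protein_id: r for r in meta.itertuples()}

    proteins = []
    for rec in SeqIO.parse(str(protein_fasta), "fasta"):
        if rec.id not in rows:
            raise CatalogError(f"FASTA record {rec.id!r} has no metadata row")
        row = rows[rec.id]
        seq = str(rec.seq).upper()
        if not seq:
            raise CatalogError(f"protein {rec.id!r} has an empty sequence")
        proteins.append(
            ReferenceProtein(
                protein_id=rec.id,
                family=row.family,
                category=row.category,
                species=row.species,
                order=row.order,
                genus=row.genus,
                sequence=seq,
            )
        )
    if not proteins:
        raise CatalogError(f"no FASTA records found in {protein_fasta}")
    return ReferenceCatalog(proteins)


def catalog_metadata_frame(catalog: ReferenceCatalog) -> pd.DataFrame:
    """Metadata table for ``catalog`` in catalog order (round-trips via TSV)."""
    return pd.DataFrame(
        [
            {
                "protein_id": p.protein_id,
                "family": p.family,
                "category": p.category,
                "species": p.species,
                "order": p.order,
                "genus": p.genus,
            }
            for p in catalog.proteins
        ],
        columns=list(METADATA_COLUMNS),
    )


def write_catalog(catalog: ReferenceCatalog, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write the catalog FASTA plus its sidecar metadata TSV."""
    write_search_fasta(catalog, fasta_path)
    catalog_metadata_frame(catalog).to_csv(metadata_path, sep="\t", index=False)


def write_search_fasta(catalog: ReferenceCatalog, out: str | Path) -> Path:
    """Export the catalog proteins as a FASTA in catalog order.

    The output is suitable as the subject database of an external translated
    aligner; ids round-trip through :func:`load_catalog`.
    """
    if len(catalog) == 0:  # pragma: no cover - constructor forbids this
        raise CatalogError("cannot export an empty catalog")
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in catalog.proteins
    ]
    out = Path(out)
    SeqIO.write(records, str(out), "fasta")
    return out


def validate_catalog(
    catalog: ReferenceCatalog,
    expected_markers: int = 25,
    expected_trait_families: Iterable[str] = PHZ_FAMILIES + DEGRADATION_FAMILIES,
    max_strain_variants: int = 10,
) -> ValidationReport:
    """Check a catalog against the database construction rules.

    The report flags (without raising): marker family count different from
    ``expected_markers``, missing configured trait families, more than
    ``max_strain_variants`` variants of one family for a single species, and
    duplicate sequences within a family.
    """
    issues: list[str] = []
    n_markers = len(catalog.marker_families)
    if n_markers != expected_markers:
        issues.append(f"expected {expected_markers} marker families, found {n_markers}")

    present = set(catalog.families)
    for fam in expected_trait_families:
        if fam not in present:
            issues.append(f"configured trait family {fam!r} is absent")

    variants: collections.Counter[tuple[str, str]] = collections.Counter(
        (p.species, p.family) for p in catalog.proteins
    )
    for (species, fam), n in sorted(variants.items()):
        if n > max_strain_variants:
            issues.append(
                f"species {species!r} has {n} variants of {fam!r} "
                f"(limit {max_strain_variants})"
            )

    seen: dict[tuple[str, str], str] = {}
    for p in catalog.proteins:
        key = (p.family, p.sequence)
        if key in seen:
            issues.append(
                f"duplicate sequence in family {p.family!r}: "
                f"{seen[key]!r} == {p.protein_id!r}"
            )
        else:
            seen[key] = p.protein_id

    return ValidationReport(passed=not issues, issues=issues)
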