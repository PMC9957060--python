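"""Species x gene-family count-matrix construction.

Pipeline stage upstream of feature selection: starting from per-species
genome assemblies, keep only species whose scaffold N50 clears a
contiguity threshold (default 400 kb), reduce each protein-coding gene to
its longest mRNA isoform, and tabulate homology-based gene -> family
assignments (e.g. TreeFam accessions, consumed here as a TSV) into an
integer copy-number matrix with one row per species and one column per
family.  Family inference itself (homology search, tree building) is out
of scope; its output table is an input.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .matrix import LabeledMatrix

__all__ = [
    "AssemblyRecord",
    "GeneFamilyMatrix",
    "filter_assemblies",
    "read_assembly_stats",
    "select_longest_isoform",
    "read_assignments",
    "build_matrix",
    "DEFAULT_MIN_N50",
]

logger = logging.getLogger(__name__)

# assemblies with scaffold N50 below 400 kb are considered too fragmented
DEFAULT_MIN_N50 = 400_000


@dataclass(frozen=True)
class AssemblyRecord:
    """One genome assembly: species identifier and scaffold N50 in bases."""

    species_id: str
    scaffold_n50: int


def filter_assemblies(
    records: list[AssemblyRecord], min_n50: int = DEFAULT_MIN_N50
) -> list[AssemblyRecord]:
    """Drop assemblies with scaffold N50 strictly below ``min_n50``.

    The boundary is retained: only ``scaffold_n50 < min_n50`` is
    eliminated.  Order is preserved and the operation is idempotent.
    """
    if min_n50 <= 0:
        raise ValueError(f"min_n50 must be positive, got {min_n50}")
    for i, rec in enumerate(records):
        if rec.scaffold_n50 <= 0:
            raise ValueError(
                f"row {i} ({rec.species_id!r}): scaffold N50 must be a positive "
                f"integer, got {rec.scaffold_n50}"
            )
    return [rec for rec in records if rec.scaffold_n50 >= min_n50]


def read_assembly_stats(path) -> list[AssemblyRecord]:
    """Read a two-column TSV ``species_id\\tscaffold_n50`` (header optional)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["species_id", "scaffold_n50"]:
        df = pd.read_csv(path, sep="\t", header=None, names=["species_id", "scaffold_n50"], dtype=str)
    records = []
    for i, row in df.iterrows():
        try:
            n50 = int(row["scaffold_n50"])
        except (TypeError, ValueError):
            raise ValueError(
                f"row {i} ({row['species_id']!r}): malformed scaffold N50 "
                f"{row['scaffold_n50']!r}"
            ) from None
        records.append(AssemblyRecord(str(row["species_id"]), n50))
    seen: set[str] = set()
    for rec in records:
        if rec.species_id in seen:
            raise ValueError(f"duplicate species_id {rec.species_id!r} in {path}")
        seen.add(rec.species_id)
    return records


# ---------------------------------------------------------------------------
# longest-isoform selection


def _transcript_length(db, mrna, seq_lengths: dict[str, int]) -> int:
    """Length of one mRNA: FASTA sequence if present, else spliced exon sum,
    else the genomic span (GFF3 coordinates are 1-based inclusive)."""
    if mrna.id in seq_lengths:
        return seq_lengths[mrna.id]
    exon_total = sum(e.end - e.start + 1 for e in db.children(mrna, featuretype="exon"))
    if exon_total > 0:
        return exon_total
    return mrna.end - mrna.start + 1


def select_longest_isoform(gff3_path, fasta_path=None) -> dict[str, str]:
    """Pick one transcript per gene: the longest mRNA isoform.

    Alternative splicing yields several mRNAs per gene; downstream family
    counting uses exactly one, the longest.  Length is the transcript
    sequence length when ``fasta_path`` provides it, otherwise the sum of
    exon lengths, otherwise the mRNA genomic span.  Equal-length ties go
    to the lexicographically smallest transcript id, so the result does
    not depend on record order in the GFF3.

    Returns a mapping ``gene_id -> transcript_id``; genes without any mRNA
    are omitted, and mRNAs without a parent gene are skipped with a
    warning.
    """
    seq_lengths: dict[str, int] = {}
    if fasta_path is not None:
        seq_lengths = {rec.id: len(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}

    with tempfile.NamedTemporaryFile(suffix=".db") as tmp:
        db = gffutils.create_db(
            str(gff3_path),
            tmp.name,
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        best: dict[str, tuple[int, str]] = {}
        for mrna in db.features_of_type("mRNA"):
            parents = [p for p in db.parents(mrna, level=1) if p.featuretype == "gene"]
            if not parents:
                logger.warning("mRNA %s has no parent gene; skipped", mrna.id)
                continue
            length = _transcript_length(db, mrna, seq_lengths)
            for gene in parents:
                # longer wins; on a tie the lexicographically smaller id wins
                cur = best.get(gene.id)
                if (
                    cur is None
                    or length > cur[0]
                    or (length == cur[0] and mrna.id < cur[1])
                ):
                    best[gene.id] = (length, mrna.id)
    return {gene: tid for gene, (_, tid) in best.items()}


# ---------------------------------------------------------------------------
# family counting


def read_assignments(path) -> pd.DataFrame:
    """Read a gene->family table: ``species_id\\tgene_id\\tfamily_id``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = ["species_id", "gene_id", "family_id"]
    if list(df.columns[:3]) != expected:
        df = pd.read_csv(path, sep="\t", header=None, names=expected, dtype=str)
    return df


@dataclass
class GeneFamilyMatrix:
    """Integer copy-number matrix: rows species, columns gene families."""

    species: list[str]
    families: list[str]
    counts: np.ndarray  # (n_species, n_families), nonnegative ints
    labels: dict[str, str] | None = None  # optional class label per species

    def to_labeled_matrix(self) -> LabeledMatrix:
        """View as features x samples: families are features, species samples."""
        labels = None
        if self.labels is not None:
            labels = np.array([self.labels.get(sp) for sp in self.species])
        return LabeledMatrix(self.counts.T.astype(float), list(self.families), list(self.species), labels)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=self.species, columns=self.families)
        df.index.name = "species_id"
        if self.labels is not None:
            df.insert(0, "label", [self.labels.get(sp, "") for sp in self.species])
        df.to_csv(path, sep="\t")


def build_matrix(
    assignments: pd.DataFrame,
    species_order: list[str],
    family_order: list[str] | None = None,
    labels: dict[str, str] | None = None,
) -> GeneFamilyMatrix:
    """Tabulate assignment rows into a species x family count matrix.

    ``counts[s, f]`` is the number of genes of species ``s`` assigned to
    family ``f``; a species' row sum therefore equals its number of
    assigned genes.  Families observed nowhere are dropped unless an
    explicit ``family_order`` pins the columns.  Species listed in
    ``species_order`` but absent from the table get all-zero rows; genes
    with no assignment simply do not appear.
    """
    dup = assignments.duplicated(subset=["species_id", "gene_id"])
    if dup.any():
        row = assignments[dup].iloc[0]
        raise ValueError(
            f"duplicate assignment for (species {row['species_id']!r}, "
            f"gene {row['gene_id']!r}): one family per gene"
        )
    unknown = set(assignments["species_id"]) - set(species_order)
    if unknown:
        raise ValueError(f"assignment species not in species_order: {sorted(unknown)}")

    if family_order is None:
        family_order = sorted(assignments["family_id"].unique())
    if len(assignments):
        counts = pd.crosstab(assignments["species_id"], assignments["family_id"])
        counts = counts.reindex(index=species_order, columns=family_order, fill_value=0)
    else:
        counts = pd.DataFrame(0, index=species_order, columns=family_order)
    return GeneFamilyMatrix(
        list(species_order),
        list(family_order),
        counts.to_numpy(dtype=int),
        labels,
    )
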