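"""Reading and writing the package's standard file formats.

Alignments travel as plain FASTA (via Biopython); genotypes as a TSV with
columns ``individual, locus, allele1, allele2`` where a missing genotype
has both allele cells equal to ``NA``.  Writing then reading reproduces
the in-memory object exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import MISSING, GenotypeMatrix, SequenceAlignment

__all__ = ["read_fasta", "write_fasta", "read_genotypes", "write_genotypes"]

GENOTYPE_COLUMNS = ["individual", "locus", "allele1", "allele2"]


def read_fasta(path) -> SequenceAlignment:
    """Load an aligned FASTA file, enforcing alignment invariants."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    labels = [r.id for r in records]
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"{path}: duplicate labels {sorted(dupes)}")
    seqs = [str(r.seq).upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        offender = next(r.id for r in records if len(r.seq) != len(seqs[0]))
        raise ValueError(
            f"{path}: ragged alignment (record {offender!r} differs in length)"
        )
    return SequenceAlignment(labels, seqs)


def write_fasta(alignment: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for lab, s in zip(alignment.labels, alignment.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_genotypes(path) -> GenotypeMatrix:
    """Load a genotype TSV; a row with any NA allele is marked missing."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "locus": str})
    missing_cols = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    ind_idx = {x: i for i, x in enumerate(individuals)}
    loc_idx = {x: i for i, x in enumerate(loci)}
    alleles = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    seen = np.zeros((len(individuals), len(loci)), dtype=bool)
    for row in df.itertuples(index=False):
        i, l = ind_idx[row.individual], loc_idx[row.locus]
        if seen[i, l]:
            raise ValueError(
                f"{path}: duplicate genotype row for ({row.individual}, {row.locus})"
            )
        seen[i, l] = True
        a1, a2 = row.allele1, row.allele2
        if pd.isna(a1) or pd.isna(a2):
            continue  # stays MISSING
        for a in (a1, a2):
            if float(a) != int(float(a)):
                raise ValueError(
                    f"{path}: non-integer allele {a!r} for "
                    f"({row.individual}, {row.locus})"
                )
        alleles[i, l] = (int(float(a1)), int(float(a2)))
    return GenotypeMatrix(individuals, loci, alleles)


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    rows = []
    for i, ind in enumerate(genotypes.individuals):
        for l, loc in enumerate(genotypes.loci):
            a1, a2 = genotypes.alleles[i, l]
            rows.append(
                {
                    "individual": ind,
                    "locus": loc,
                    "allele1": "NA" if a1 == MISSING else int(a1),
                    "allele2": "NA" if a2 == MISSING else int(a2),
                }
            )
    pd.DataFrame(rows, columns=GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)


def write_trace(samples, path) -> None:
    """One-column TSV trace of posterior draws (readable by MCMC tools)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"theta": np.asarray(samples)}).to_csv(path, sep="\t", index=False)
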