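"""Core marker-data containers shared across the pipeline.

Two kinds of marker data flow through the package: a haploid
multiple-sequence alignment (mitochondrial control-region haplotypes) and a
diploid microsatellite genotype table (allele repeat counts per individual
per locus).  Both are small, validated, immutable-by-convention containers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SequenceAlignment", "GenotypeMatrix", "MISSING"]

#: Sentinel for a missing allele in a genotype matrix.
MISSING = -1

_ALLOWED_CHARS = frozenset("ACGTN-")


@dataclass(frozen=True)
class SequenceAlignment:
    """An aligned set of equal-length haploid sequences.

    Parameters
    ----------
    labels
        Unique sample identifiers, one per sequence.
    sequences
        Upper-case sequence strings over ``ACGTN-``; all the same length.
        Only ``ACGT`` columns enter per-site statistics downstream.
    """

    labels: tuple[str, ...]
    sequences: tuple[str, ...]

    def __init__(self, labels, sequences):
        object.__setattr__(self, "labels", tuple(str(x) for x in labels))
        object.__setattr__(self, "sequences", tuple(str(s).upper() for s in sequences))
        self._validate()

    def _validate(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences must have equal length")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("duplicate sequence labels")
        if not self.sequences:
            raise ValueError("alignment must contain at least one sequence")
        L = len(self.sequences[0])
        for lab, s in zip(self.labels, self.sequences):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: sequence {lab!r} has length {len(s)}, expected {L}"
                )
            bad = set(s) - _ALLOWED_CHARS
            if bad:
                raise ValueError(f"sequence {lab!r} contains invalid symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, L) array of single characters."""
        return np.array([list(s) for s in self.sequences], dtype="U1")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Diploid allele-size genotypes for ``n`` individuals at ``m`` loci.

    ``alleles`` has shape (n, m, 2) and holds integer repeat counts; a
    genotype with any allele unobserved is stored as (MISSING, MISSING).
    """

    individuals: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: np.ndarray = field(repr=False)

    def __init__(self, individuals, loci, alleles):
        object.__setattr__(self, "individuals", tuple(str(x) for x in individuals))
        object.__setattr__(self, "loci", tuple(str(x) for x in loci))
        arr = np.asarray(alleles, dtype=np.int64)
        object.__setattr__(self, "alleles", arr)
        self._validate()

    def _validate(self) -> None:
        n, m = len(self.individuals), len(self.loci)
        if len(set(self.individuals)) != n:
            raise ValueError("duplicate individual identifiers")
        if len(set(self.loci)) != m:
            raise ValueError("duplicate locus names")
        if self.alleles.shape != (n, m, 2):
            raise ValueError(
                f"alleles must have shape ({n}, {m}, 2), got {self.alleles.shape}"
            )
        # a genotype is either fully observed (both alleles >= 1) or fully missing
        a = self.alleles
        obs = a >= 1
        miss = a == MISSING
        if not np.all(obs | miss):
            raise ValueError("allele sizes must be positive integers or MISSING")
        half = obs[..., 0] ^ obs[..., 1]
        if np.any(half):
            raise ValueError("half-missing genotype: mark both alleles MISSING")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def typed_mask(self, locus_index: int) -> np.ndarray:
        """Boolean mask of individuals with a complete genotype at a locus."""
        return self.alleles[:, locus_index, 0] != MISSING

    def locus_alleles(self, locus_index: int) -> np.ndarray:
        """All observed allele copies at a locus (flat array, 2 per typed individual)."""
        mask = self.typed_mask(locus_index)
        return self.alleles[mask, locus_index, :].ravel()

    def n_typed(self, locus_index: int) -> int:
        return int(self.typed_mask(locus_index).sum())
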