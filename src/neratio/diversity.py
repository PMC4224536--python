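"""Standard diversity indices for microsatellite and sequence data.

Conventions follow the classical population-genetics estimators: unbiased
expected heterozygosity (Nei) per microsatellite locus, haplotype (gene)
diversity with its sampling SD, per-site nucleotide diversity with the
total-variance SD, and a per-site mutation-type summary.  Alignment columns
containing any non-ACGT symbol are excluded from per-site statistics.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np

from .datatypes import GenotypeMatrix, SequenceAlignment

__all__ = [
    "expected_heterozygosity",
    "haplotype_diversity",
    "nucleotide_diversity",
    "site_summary",
    "DiversitySummary",
    "summarize_diversity",
]

_ACGT = frozenset("ACGT")
_TI_PAIRS = {frozenset("AG"), frozenset("CT")}


def expected_heterozygosity(genotypes: GenotypeMatrix, unbiased: bool = True):
    """Per-locus expected heterozygosity with mean and range across loci.

    With allele frequencies p_k estimated from 2n observed gene copies, the
    unbiased estimator is (2n / (2n - 1)) * (1 - sum p_k^2); the plain
    1 - sum p_k^2 form is returned when ``unbiased=False``.  Loci with
    fewer than two typed individuals are excluded with a warning.

    Returns a dict with ``per_locus`` (locus -> H), ``mean`` and ``range``.
    """
    per_locus: dict[str, float] = {}
    for l, name in enumerate(genotypes.loci):
        copies = genotypes.locus_alleles(l)
        if copies.size < 4:  # fewer than 2 typed diploids
            warnings.warn(f"locus {name!r} has <2 typed individuals; excluded")
            continue
        _, counts = np.unique(copies, return_counts=True)
        p = counts / copies.size
        h = 1.0 - float(np.sum(p * p))
        if unbiased:
            h *= copies.size / (copies.size - 1.0)
        per_locus[name] = h
    if not per_locus:
        raise ValueError("no locus with enough data for heterozygosity")
    vals = np.array(list(per_locus.values()))
    return {
        "per_locus": per_locus,
        "mean": float(vals.mean()),
        "range": (float(vals.min()), float(vals.max())),
    }


def _haplotype_counts(alignment: SequenceAlignment) -> np.ndarray:
    counts = Counter(alignment.sequences)
    return np.array(sorted(counts.values(), reverse=True), dtype=float)


def haplotype_diversity(alignment: SequenceAlignment) -> tuple[float, float]:
    """Gene (haplotype) diversity Hs and its sampling SD.

    Identical sequences are collapsed into haplotypes with frequencies p_i;
    Hs = n/(n-1) * (1 - sum p_i^2).  The SD uses Nei's (1987) variance
        V = 2/(n(n-1)) * [2(n-2)(sum p^3 - (sum p^2)^2) + sum p^2 - (sum p^2)^2].
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("haplotype diversity needs at least 2 sequences")
    p = _haplotype_counts(alignment) / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    hs = n / (n - 1.0) * (1.0 - s2)
    var = 2.0 / (n * (n - 1.0)) * (2.0 * (n - 2.0) * (s3 - s2 * s2) + s2 - s2 * s2)
    return hs, float(np.sqrt(max(var, 0.0)))


def _valid_columns(arr: np.ndarray) -> np.ndarray:
    """Mask of alignment columns containing only ACGT."""
    ok = np.isin(arr, list(_ACGT))
    return ok.all(axis=0)


def nucleotide_diversity(alignment: SequenceAlignment) -> tuple[float, float]:
    """Per-site nucleotide diversity pi and its SD.

    pi is the mean proportion of differing sites over all unordered
    sequence pairs, computed over ACGT-only columns.  The SD follows the
    standard total-variance approximation (Nei 1987, eq. 10.7):
        V = (n+1)/(3(n-1)L) * pi + 2(n^2+n+3)/(9n(n-1)) * pi^2.
    """
    n = alignment.n_sequences
    if n < 2:
        raise ValueError("nucleotide diversity needs at least 2 sequences")
    arr = alignment.to_array()
    arr = arr[:, _valid_columns(arr)]
    L = arr.shape[1]
    if L == 0:
        raise ValueError("no ACGT-only columns in alignment")
    total = 0
    for i in range(n):
        total += int(np.sum(arr[i + 1 :] != arr[i]))
    n_pairs = n * (n - 1) // 2
    pi = total / (n_pairs * L)
    var = (n + 1) / (3.0 * (n - 1) * L) * pi + (
        2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    ) * pi * pi
    return float(pi), float(np.sqrt(var))


def site_summary(alignment: SequenceAlignment) -> dict:
    """Polymorphic-site and haplotype summary of an alignment.

    Returns segregating sites S, transition / transversion counts over
    biallelic variable columns, the number of multiallelic (>2 base)
    columns, and the number of distinct haplotypes.
    """
    if alignment.n_sequences < 2:
        raise ValueError("site summary needs at least 2 sequences")
    arr = alignment.to_array()
    arr = arr[:, _valid_columns(arr)]
    s = 0
    n_ti = 0
    n_tv = 0
    n_multi = 0
    for col in arr.T:
        bases = set(col.tolist())
        if len(bases) < 2:
            continue
        s += 1
        if len(bases) == 2:
            if frozenset(bases) in _TI_PAIRS:
                n_ti += 1
            else:
                n_tv += 1
        else:
            n_multi += 1
    return {
        "segregating_sites": s,
        "transitions": n_ti,
        "transversions": n_tv,
        "multiallelic_sites": n_multi,
        "n_haplotypes": len(set(alignment.sequences)),
        "n_sites_used": int(arr.shape[1]),
    }


@dataclass
class DiversitySummary:
    """Joint diversity report for the two marker types (either optional)."""

    heterozygosity: dict | None = None
    haplotype_diversity: tuple[float, float] | None = None
    nucleotide_diversity: tuple[float, float] | None = None
    sites: dict | None = None
    allele_counts: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = ["Diversity summary", "================="]
        if self.heterozygosity is not None:
            h = self.heterozygosity
            lines.append(
                f"Expected heterozygosity: mean {h['mean']:.3f} "
                f"(range {h['range'][0]:.3f}-{h['range'][1]:.3f})"
            )
            for name, v in h["per_locus"].items():
                k = self.allele_counts.get(name)
                extra = f", {k} alleles" if k is not None else ""
                lines.append(f"  {name}: H = {v:.3f}{extra}")
        if self.haplotype_diversity is not None:
            hs, sd = self.haplotype_diversity
            lines.append(f"Haplotype diversity Hs: {hs:.3f} +/- {sd:.3f}")
        if self.nucleotide_diversity is not None:
            pi, sd = self.nucleotide_diversity
            lines.append(f"Nucleotide diversity pi/site: {pi:.4f} +/- {sd:.4f}")
        if self.sites is not None:
            st = self.sites
            lines.append(
                f"Segregating sites: {st['segregating_sites']} "
                f"({st['transitions']} transitions, {st['transversions']} transversions, "
                f"{st['multiallelic_sites']} multiallelic); "
                f"{st['n_haplotypes']} haplotypes"
            )
        return "\n".join(lines)


def summarize_diversity(
    alignment: SequenceAlignment | None = None,
    genotypes: GenotypeMatrix | None = None,
    unbiased: bool = True,
) -> DiversitySummary:
    """Compute all applicable indices for whichever inputs are given."""
    if alignment is None and genotypes is None:
        raise ValueError("need an alignment and/or a genotype matrix")
    out = DiversitySummary()
    if genotypes is not None:
        out.heterozygosity = expected_heterozygosity(genotypes, unbiased=unbiased)
        out.allele_counts = {
            name: int(np.unique(genotypes.locus_alleles(l)).size)
            for l, name in enumerate(genotypes.loci)
            if genotypes.n_typed(l) > 0
        }
    if alignment is not None:
        out.haplotype_diversity = haplotype_diversity(alignment)
        out.nucleotide_diversity = nucleotide_diversity(alignment)
        out.sites = site_summary(alignment)
    return out
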