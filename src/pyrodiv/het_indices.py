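"""Per-individual heterozygosity indices (the five GENHET measures).

Given an individual's multilocus genotype and a population frequency
reference, computes:

* ``PHt`` — proportion of heterozygous loci among typed loci;
* ``Hs_obs`` / ``Hs_exp`` — PHt standardized by the mean per-locus
  reference H_O (resp. H_E) over the individual's typed loci;
* ``IR`` — internal relatedness, ``(2H - sum f) / (2N - sum f)`` with N
  typed loci, H homozygous loci, and sum f the summed reference frequency
  of every allele copy carried. Shared rare alleles weigh more than shared
  common ones; fully homozygous individuals score 1, heterozygotes at
  even-frequency loci score below 0;
* ``HL`` — homozygosity by locus, the H_E-weighted proportion of
  homozygous loci: ``sum(E_hom) / (sum(E_hom) + sum(E_het))`` where E is
  the reference expected heterozygosity of each typed locus.

The frequency reference is a free choice of reference individuals; for
progeny analyses it defaults to the maternal plants (offspring genotypes
are non-independent draws from them).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeTable, allele_frequencies
from . import diversity_stats

INDEX_NAMES = ("pht", "hs_obs", "hs_exp", "ir", "hl")


@dataclass
class FrequencyReference:
    """Per-locus allele frequencies plus population H_O and H_E."""

    loci: list[str]
    freqs: dict[str, dict[int, float]]
    h_obs: dict[str, float]
    h_exp: dict[str, float]

    @classmethod
    def from_table(cls, table: GenotypeTable) -> "FrequencyReference":
        freqs = allele_frequencies(table, "all")["all"]
        per_locus, _ = diversity_stats.heterozygosity(table, "all")
        h_obs = dict(zip(per_locus["locus"], per_locus["h_obs"]))
        h_exp = dict(zip(per_locus["locus"], per_locus["h_exp"]))
        return cls(list(table.loci), freqs, h_obs, h_exp)

    def freq_of(self, locus: str, allele: int) -> float:
        """Reference frequency of an allele (0 if unseen in the reference)."""
        return self.freqs.get(locus, {}).get(int(allele), 0.0)


@dataclass
class HetIndexSet:
    """The five indices for one individual (NaN where undefined)."""

    pht: float
    hs_obs: float
    hs_exp: float
    ir: float
    hl: float
    n_typed: int
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in INDEX_NAMES}


def _typed_het(genotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    genotype = np.asarray(genotype)
    typed = (genotype != MISSING).all(axis=1)
    het = typed & (genotype[:, 0] != genotype[:, 1])
    return typed, het


def pht(genotype: np.ndarray) -> float:
    """Proportion of heterozygous loci among typed loci (NaN if none typed)."""
    typed, het = _typed_het(genotype)
    n = typed.sum()
    return float(het.sum() / n) if n else float("nan")


def hs_obs(genotype: np.ndarray, ref: FrequencyReference) -> float:
    """PHt standardized by mean reference H_O over the typed loci."""
    return _hs(genotype, ref, ref.h_obs)


def hs_exp(genotype: np.ndarray, ref: FrequencyReference) -> float:
    """PHt standardized by mean reference H_E over the typed loci."""
    return _hs(genotype, ref, ref.h_exp)


def _hs(genotype: np.ndarray, ref: FrequencyReference, table: dict[str, float]) -> float:
    typed, het = _typed_het(genotype)
    if not typed.any():
        return float("nan")
    denom = float(np.nanmean([table[ref.loci[j]] for j in np.flatnonzero(typed)]))
    if not denom > 0:
        return float("nan")
    return float(het.sum() / typed.sum() / denom)


def internal_relatedness(genotype: np.ndarray, ref: FrequencyReference) -> float:
    """Amos internal relatedness; 1 iff fully homozygous (denominator > 0)."""
    typed, het = _typed_het(genotype)
    n = int(typed.sum())
    if n == 0:
        return float("nan")
    h = n - int(het.sum())
    sum_f = 0.0
    for j in np.flatnonzero(typed):
        locus = ref.loci[j]
        sum_f += ref.freq_of(locus, genotype[j, 0]) + ref.freq_of(locus, genotype[j, 1])
    denom = 2 * n - sum_f
    if denom <= 0:
        # only reachable when every carried allele is fixed: degenerate, IR := 1
        return 1.0
    return float((2 * h - sum_f) / denom)


def homozygosity_by_locus(genotype: np.ndarray, ref: FrequencyReference) -> float:
    """Aparicio HL: H_E-weighted homozygosity, in [0, 1]."""
    typed, het = _typed_het(genotype)
    if not typed.any():
        return float("nan")
    e = np.array([ref.h_exp[ref.loci[j]] for j in np.flatnonzero(typed)])
    is_het = het[typed]
    total = e.sum()
    if not total > 0:
        return float("nan")
    return float(e[~is_het].sum() / total)


def index_set(genotype: np.ndarray, ref: FrequencyReference) -> HetIndexSet:
    """All five indices for one individual's ``(n_loci, 2)`` genotype."""
    typed, _ = _typed_het(genotype)
    n = int(typed.sum())
    flags = [] if n else ["no_typed_loci"]
    return HetIndexSet(
        pht=pht(genotype),
        hs_obs=hs_obs(genotype, ref),
        hs_exp=hs_exp(genotype, ref),
        ir=internal_relatedness(genotype, ref),
        hl=homozygosity_by_locus(genotype, ref),
        n_typed=n,
        flags=flags,
    )


def table_index_sets(table: GenotypeTable, ref: FrequencyReference) -> pd.DataFrame:
    """Per-individual index rows for a whole table (locus order must match)."""
    if list(table.loci) != list(ref.loci):
        raise ValueError("table and reference locus sets differ")
    rows = []
    for i in range(table.n_individuals):
        s = index_set(table.calls[i], ref)
        rows.append({"id": table.individuals["id"].iat[i], **s.as_dict(),
                     "n_typed": s.n_typed})
    return pd.DataFrame(rows)


def dataset_means(per_individual: pd.DataFrame) -> dict[str, float]:
    """Arithmetic mean of each index over individuals with defined values."""
    return {k: float(per_individual[k].mean()) for k in INDEX_NAMES}
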