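"""Progeny-array mating-system inference.

Open-pollinated seed genotypes are compared with their maternal plant's
genotype. Each seed allele copy that cannot have been inherited from the
mother is evidence of a pollen donor; seeds fall into three categories
(zero, one, or two-plus non-maternal copies). Observed seed heterozygosity
is then tested against a Monte-Carlo null of pure selfing: selfed seed
datasets are simulated by Mendelian gamete draws from each mother, the
five per-individual heterozygosity indices are averaged per simulated
dataset, and the observed dataset means are compared with the central
quantile band (default 95 %) of the simulated means. Observed PHt/Hs above
the band, or IR/HL below it, indicates outcrossing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeTable
from .het_indices import (
    INDEX_NAMES,
    FrequencyReference,
    dataset_means,
    table_index_sets,
)


@dataclass
class ProgenyArray:
    """One maternal genotype plus its seed genotypes (shared locus order)."""

    mother_id: str
    loci: list[str]
    mother: np.ndarray  # (n_loci, 2)
    seed_ids: list[str]
    seeds: np.ndarray  # (n_seeds, n_loci, 2)
    qc_flags: dict[str, str] = field(default_factory=dict)

    @property
    def n_seeds(self) -> int:
        return len(self.seed_ids)


def build_progeny_arrays(
    mothers: GenotypeTable, seeds: GenotypeTable, mother_column: str = "block"
) -> list[ProgenyArray]:
    """Pair seeds with mothers via the seed table's ``mother_column`` label."""
    if list(mothers.loci) != list(seeds.loci):
        raise ValueError("mother and seed tables have different locus sets")
    by_mother = seeds.individuals.groupby(mother_column, sort=False).indices
    mother_ids = list(mothers.individuals["id"].astype(str))
    arrays = []
    for mid, rows in by_mother.items():
        mid = str(mid)
        if mid not in mother_ids:
            raise ValueError(f"seed group {mid!r} has no matching mother id")
        mi = mother_ids.index(mid)
        arrays.append(
            ProgenyArray(
                mother_id=mid,
                loci=list(mothers.loci),
                mother=mothers.calls[mi].copy(),
                seed_ids=list(seeds.individuals["id"].iloc[rows].astype(str)),
                seeds=seeds.calls[rows].copy(),
            )
        )
    return arrays


# ------------------------------------------------------------------ QC


def _cotyped(mother: np.ndarray, seed: np.ndarray) -> np.ndarray:
    return (mother != MISSING).all(axis=1) & (seed != MISSING).all(axis=1)


def qc_progeny(array: ProgenyArray) -> tuple[ProgenyArray, list[str]]:
    """Remove seeds that are Mendelian-impossible offspring of the mother.

    A seed is removed if at any co-typed locus it carries no maternal
    allele (genotyping error under strict maternity). Seeds with no
    co-typed locus at all are removed as genotyping failures. Reasons are
    recorded per removed seed in ``qc_flags``.
    """
    keep, flags = [], {}
    for s, sid in enumerate(array.seed_ids):
        co = _cotyped(array.mother, array.seeds[s])
        if not co.any():
            flags[sid] = "no_cotyped_loci"
            continue
        mismatch = False
        for j in np.flatnonzero(co):
            if not set(array.seeds[s, j]) & set(array.mother[j]):
                mismatch = True
                break
        if mismatch:
            flags[sid] = "maternal_mismatch"
        else:
            keep.append(s)
    kept = ProgenyArray(
        mother_id=array.mother_id,
        loci=array.loci,
        mother=array.mother,
        seed_ids=[array.seed_ids[s] for s in keep],
        seeds=array.seeds[keep],
        qc_flags=flags,
    )
    return kept, list(flags)


# ------------------------------------------------------- classification


def count_non_maternal(mother: np.ndarray, seed: np.ndarray) -> int | None:
    """Number of seed allele copies that cannot be of maternal origin.

    Per co-typed locus, one seed copy matching a maternal allele is set
    aside as the maternal contribution (choosing the assignment that
    minimizes the count); remaining copies absent from the maternal
    genotype are counted. Returns ``None`` when no locus is co-typed.
    """
    co = _cotyped(mother, seed)
    if not co.any():
        return None
    total = 0
    for j in np.flatnonzero(co):
        m = set(int(a) for a in mother[j])
        x, y = int(seed[j, 0]), int(seed[j, 1])
        if x in m or y in m:
            # one matching copy is the maternal contribution
            other = y if x in m else x
            total += 0 if other in m else 1
        else:
            total += 2
    return total


CATEGORIES = ("maternal_only", "single_non_maternal", "multi_non_maternal")


def classify_seeds(array: ProgenyArray) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each seed by its total non-maternal allele count."""
    rows = []
    for s, sid in enumerate(array.seed_ids):
        n = count_non_maternal(array.mother, array.seeds[s])
        if n is None:
            cat = "unclassified"
        elif n == 0:
            cat = "maternal_only"
        elif n == 1:
            cat = "single_non_maternal"
        else:
            cat = "multi_non_maternal"
        rows.append({"seed_id": sid, "n_non_maternal": n, "category": cat})
    df = pd.DataFrame(rows, columns=["seed_id", "n_non_maternal", "category"])
    totals = {c: int((df["category"] == c).sum()) for c in CATEGORIES}
    return df, totals


def classify_all(arrays: list[ProgenyArray]) -> tuple[pd.DataFrame, dict[str, int]]:
    """Pooled classification over a list of progeny arrays."""
    frames, totals = [], dict.fromkeys(CATEGORIES, 0)
    for arr in arrays:
        df, t = classify_seeds(arr)
        df.insert(0, "mother_id", arr.mother_id)
        frames.append(df)
        for c in CATEGORIES:
            totals[c] += t[c]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["mother_id", "seed_id", "n_non_maternal", "category"])
    )
    return out, totals


# ------------------------------------------------------------- simulation


def mothers_table(arrays: list[ProgenyArray]) -> GenotypeTable:
    """The maternal genotypes as a GenotypeTable (frequency-reference set)."""
    if not arrays:
        raise ValueError("no progeny arrays")
    loci = arrays[0].loci
    individuals = pd.DataFrame(
        {
            "id": [a.mother_id for a in arrays],
            "block": "mothers",
            "plot": "mothers",
            "timepoint": "none",
        }
    )
    calls = np.stack([a.mother for a in arrays])
    return GenotypeTable(individuals, loci, calls)


def seeds_table(arrays: list[ProgenyArray]) -> GenotypeTable:
    """All seed genotypes pooled into one GenotypeTable."""
    loci = arrays[0].loci
    frames, calls = [], []
    for a in arrays:
        frames.append(
            pd.DataFrame(
                {"id": a.seed_ids, "block": a.mother_id, "plot": a.mother_id,
                 "timepoint": "none"}
            )
        )
        calls.append(a.seeds)
    return GenotypeTable(pd.concat(frames), loci, np.concatenate(calls))


def simulate_selfed_dataset(
    arrays: list[ProgenyArray],
    seeds_per_mother: int | list[int] | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypeTable:
    """Simulate one dataset of Mendelian-selfed seeds.

    Each simulated seed receives, at every maternally typed locus, two
    allele copies drawn independently and uniformly from the mother's two
    copies; maternally missing loci are missing in the seed. By default
    the per-mother seed counts match the observed (post-QC) counts, so the
    null dataset mirrors the analysed one; pass an integer for a uniform
    design (5 seeds per mother corresponds to sampling 10 alleles per
    locus per parent).
    """
    rng = np.random.default_rng() if rng is None else rng
    counts = _seed_counts(arrays, seeds_per_mother)
    frames, calls = [], []
    for arr, c in zip(arrays, counts):
        typed = (arr.mother != MISSING).all(axis=1)
        picks = rng.integers(0, 2, size=(c, len(arr.loci), 2))
        sim = np.take_along_axis(
            np.broadcast_to(arr.mother, (c, *arr.mother.shape)), picks, axis=2
        ).copy()
        sim[:, ~typed, :] = MISSING
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{arr.mother_id}_sim{k + 1}" for k in range(c)],
                    "block": arr.mother_id,
                    "plot": arr.mother_id,
                    "timepoint": "none",
                }
            )
        )
        calls.append(sim)
    return GenotypeTable(pd.concat(frames), arrays[0].loci, np.concatenate(calls))


def _seed_counts(arrays, seeds_per_mother) -> list[int]:
    if seeds_per_mother is None:
        counts = [a.n_seeds for a in arrays]
    elif np.isscalar(seeds_per_mother):
        counts = [int(seeds_per_mother)] * len(arrays)
    else:
        counts = [int(c) for c in seeds_per_mother]
    if any(c <= 0 for c in counts):
        raise ValueError("seeds_per_mother must be positive")
    return counts


@dataclass
class SelfingNull:
    """Monte-Carlo null distribution of dataset-mean indices under selfing."""

    n_replicates: int
    coverage: float
    replicate_means: pd.DataFrame  # one row per replicate, one col per index
    bands: dict[str, tuple[float, float]]
    rng_seed: int | None = None


def build_selfing_null(
    arrays: list[ProgenyArray],
    n_replicates: int = 1000,
    rng: np.random.Generator | None = None,
    coverage: float = 0.95,
    ref: FrequencyReference | None = None,
    seeds_per_mother: int | list[int] | None = None,
) -> SelfingNull:
    """Simulate ``n_replicates`` pure-selfing seed datasets and band them.

    The frequency reference is fixed across replicates (default: built from
    the maternal genotypes). The band is the central ``coverage`` empirical
    quantile interval of the per-replicate dataset means, per index.

    The simulation is vectorised over replicates: gamete picks for all
    replicates are drawn as one array and the five indices are evaluated
    with array arithmetic (identical in law to repeated
    :func:`simulate_selfed_dataset` + per-individual index calls).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if ref is None:
        ref = FrequencyReference.from_table(mothers_table(arrays))
    counts = _seed_counts(arrays, seeds_per_mother)
    loci = arrays[0].loci
    n_loci = len(loci)
    mothers = np.stack([a.mother for a in arrays])  # (M, L, 2)
    idx = np.repeat(np.arange(len(arrays)), counts)  # seed -> mother
    s_total = len(idx)

    typed_m = (mothers != MISSING).all(axis=2)  # (M, L)
    freq_m = np.zeros_like(mothers, dtype=float)
    for m in range(len(arrays)):
        for j in range(n_loci):
            if typed_m[m, j]:
                freq_m[m, j, 0] = ref.freq_of(loci[j], mothers[m, j, 0])
                freq_m[m, j, 1] = ref.freq_of(loci[j], mothers[m, j, 1])
    e_exp = np.array([ref.h_exp[l] for l in loci])
    e_obs = np.array([ref.h_obs[l] for l in loci])

    mom = mothers[idx]  # (S, L, 2)
    typed_s = typed_m[idx]  # (S, L)
    fmom = freq_m[idx]
    n_typed = typed_s.sum(axis=1).astype(float)  # (S,)
    if np.any(n_typed == 0):
        raise ValueError("a mother has no typed loci")
    # per-seed standardization denominators (depend on typed loci only)
    with np.errstate(invalid="ignore"):
        mho = (e_obs * typed_s).sum(axis=1) / n_typed
        mhe = (e_exp * typed_s).sum(axis=1) / n_typed
    sum_e_typed = (e_exp * typed_s).sum(axis=1)  # (S,)

    r = n_replicates
    picks = rng.integers(0, 2, size=(r, s_total, n_loci, 2))
    alleles = np.take_along_axis(np.broadcast_to(mom, (r, *mom.shape)), picks, axis=3)
    f = np.take_along_axis(np.broadcast_to(fmom, (r, *fmom.shape)), picks, axis=3)
    het = (alleles[..., 0] != alleles[..., 1]) & typed_s  # (R, S, L)

    n_het = het.sum(axis=2)  # (R, S)
    pht_rs = n_het / n_typed
    with np.errstate(invalid="ignore", divide="ignore"):
        hs_obs_rs = np.where(mho > 0, pht_rs / mho, np.nan)
        hs_exp_rs = np.where(mhe > 0, pht_rs / mhe, np.nan)
    n_hom = n_typed - n_het
    sum_f = (f * typed_s[None, :, :, None]).sum(axis=(2, 3))
    denom = 2 * n_typed - sum_f
    ir_rs = np.where(denom > 0, (2 * n_hom - sum_f) / np.where(denom > 0, denom, 1), 1.0)
    sum_e_het = (het * e_exp).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        hl_rs = np.where(sum_e_typed > 0, (sum_e_typed - sum_e_het) / sum_e_typed, np.nan)

    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Mean of empty slice")
        means = pd.DataFrame(
            {
                "pht": pht_rs.mean(axis=1),
                "hs_obs": np.nanmean(hs_obs_rs, axis=1),
                "hs_exp": np.nanmean(hs_exp_rs, axis=1),
                "ir": ir_rs.mean(axis=1),
                "hl": np.nanmean(hl_rs, axis=1),
            }
        )
    lo, hi = (1 - coverage) / 2, 1 - (1 - coverage) / 2
    bands = {
        k: (float(np.quantile(means[k], lo)), float(np.quantile(means[k], hi)))
        for k in INDEX_NAMES
    }
    return SelfingNull(n_replicates, coverage, means, bands)


def observed_means(
    arrays: list[ProgenyArray], ref: FrequencyReference | None = None
) -> dict[str, float]:
    """Dataset-mean indices of the observed (post-QC) seeds."""
    if ref is None:
        ref = FrequencyReference.from_table(mothers_table(arrays))
    return dataset_means(table_index_sets(seeds_table(arrays), ref))


def selfing_test(
    observed: dict[str, float], null: SelfingNull
) -> dict[str, str]:
    """Compare observed dataset means with the selfing-null bands.

    Verdicts per index: ``below_band``, ``above_band`` or ``consistent``.
    Outcrossing is indicated by PHt/Hs above the band and IR/HL below it.
    """
    verdicts = {}
    for k, value in observed.items():
        if k not in null.bands:
            raise ValueError(f"index {k!r} absent from the null")
        lo, hi = null.bands[k]
        if value < lo:
            verdicts[k] = "below_band"
        elif value > hi:
            verdicts[k] = "above_band"
        else:
            verdicts[k] = "consistent"
    return verdicts
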