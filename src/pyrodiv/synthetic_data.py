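"""Synthetic microsatellite data with the structure the analyses assume.

Generates hierarchically structured, partially selfing populations and
progeny arrays so that every analysis stage is testable without external
data. Allele frequencies follow a hierarchical Balding–Nichols model:
ancestral frequencies are Dirichlet draws; block frequencies are drawn
around them with differentiation ``theta_block``; plot frequencies around
those with ``theta_plot``. Individuals are formed either at selfing
equilibrium — inbreeding coefficient ``F = s/(2-s)`` imposed by drawing a
single allele with probability F and duplicating it — or by iterating
``selfing_generations`` rounds of partial selfing at rate ``s`` from
plot-HWE founders. Observed genotypes are then corrupted in a fixed
order: null-allele masking (a heterozygote carrying a null appears
homozygous; a null homozygote is missing), single-allele genotyping error
(replacement with a uniform random allele), and missingness.

Default parameters mirror the regime of a fire-adapted, highly selfing
herb sampled in 20 plots nested in 3 blocks: 11 loci, equilibrium
inbreeding F near 0.8 (selfing rate s approx. 0.89), strong block/plot
differentiation, ~25 % outcrossing in open-pollinated progeny arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genotype_core import MISSING, GenotypeTable
from .mating_inference import ProgenyArray
from .structure_summary import QMatrix


@dataclass
class SimConfig:
    """Generator parameters (defaults: the target study regime, pre-fire)."""

    n_blocks: int = 3
    plots_per_block: tuple[int, ...] = (8, 4, 8)
    n_ind_per_plot: int = 9
    n_loci: int = 11
    n_alleles_per_locus: int = 6
    theta_block: float = 0.22
    theta_plot: float = 0.42
    selfing_rate: float = 8.0 / 9.0  # equilibrium F = s/(2-s) = 0.8
    selfing_generations: int | str = "equilibrium"
    outcross_rate: float = 0.25
    missing_rate: float = 0.02
    null_allele_freq: float = 0.05
    genotyping_error_rate: float = 0.01
    ancestral_dirichlet: float = 0.2  # sparse: 1-2 common + rare alleles per locus
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if isinstance(self.plots_per_block, int):
            self.plots_per_block = (self.plots_per_block,) * self.n_blocks
        if len(self.plots_per_block) != self.n_blocks:
            raise ValueError("plots_per_block must have one entry per block")
        for name in (
            "theta_block",
            "theta_plot",
            "selfing_rate",
            "outcross_rate",
            "missing_rate",
            "null_allele_freq",
            "genotyping_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_alleles_per_locus < 1 or self.n_loci < 1 or self.n_ind_per_plot < 1:
            raise ValueError("counts must be >= 1")

    @property
    def equilibrium_f(self) -> float:
        return self.selfing_rate / (2.0 - self.selfing_rate)


@dataclass
class SimOutput:
    """A simulated table plus the latent truth behind it."""

    table: GenotypeTable
    true_calls: np.ndarray  # pre-corruption genotypes
    ancestral_freqs: np.ndarray  # (L, A)
    block_freqs: np.ndarray  # (B, L, A)
    plot_freqs: np.ndarray  # (P, L, A)
    config: SimConfig
    plot_of_individual: np.ndarray = field(default=None)


def _bn_child(parent: np.ndarray, theta: float, rng: np.random.Generator) -> np.ndarray:
    """Balding–Nichols draw of a daughter frequency vector."""
    if theta <= 0:
        return parent.copy()
    alpha = parent * (1.0 - theta) / theta
    return rng.dirichlet(np.maximum(alpha, 1e-6))


def _allele_labels(n_alleles: int) -> np.ndarray:
    # fragment-size-like labels; opaque integers downstream
    return 100 + 2 * np.arange(n_alleles)


def simulate_population(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> SimOutput:
    """Simulate one hierarchically structured, partially selfing population."""
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    a = cfg.n_alleles_per_locus
    labels = _allele_labels(a)
    anc = np.stack([rng.dirichlet(np.full(a, cfg.ancestral_dirichlet)) for _ in range(cfg.n_loci)])
    block_freqs = np.stack(
        [
            np.stack([_bn_child(anc[j], cfg.theta_block, rng) for j in range(cfg.n_loci)])
            for _ in range(cfg.n_blocks)
        ]
    )
    plot_list, plot_block_idx = [], []
    for b, n_plots in enumerate(cfg.plots_per_block):
        for _ in range(n_plots):
            plot_list.append(
                np.stack(
                    [
                        _bn_child(block_freqs[b, j], cfg.theta_plot, rng)
                        for j in range(cfg.n_loci)
                    ]
                )
            )
            plot_block_idx.append(b)
    plot_freqs = np.stack(plot_list)
    n_plots_total = len(plot_list)
    n = n_plots_total * cfg.n_ind_per_plot

    plot_of_ind = np.repeat(np.arange(n_plots_total), cfg.n_ind_per_plot)
    true_calls = np.empty((n, cfg.n_loci, 2), dtype=np.int64)
    if cfg.selfing_generations == "equilibrium":
        f = cfg.equilibrium_f
        for p in range(n_plots_total):
            rows = np.flatnonzero(plot_of_ind == p)
            for j in range(cfg.n_loci):
                pj = plot_freqs[p, j]
                draws = rng.choice(a, size=(len(rows), 2), p=pj)
                ibd = rng.random(len(rows)) < f
                draws[ibd, 1] = draws[ibd, 0]
                true_calls[rows, j] = labels[draws]
    else:
        gens = int(cfg.selfing_generations)
        for p in range(n_plots_total):
            rows = np.flatnonzero(plot_of_ind == p)
            m = len(rows)
            pop = np.empty((m, cfg.n_loci, 2), dtype=np.int64)
            for j in range(cfg.n_loci):
                pop[:, j] = labels[rng.choice(a, size=(m, 2), p=plot_freqs[p, j])]
            for _ in range(gens):
                mothers = rng.integers(0, m, size=m)
                fathers = np.where(
                    rng.random(m) < cfg.selfing_rate,
                    mothers,
                    rng.integers(0, m, size=m),
                )
                picks_m = rng.integers(0, 2, size=(m, cfg.n_loci))
                picks_f = rng.integers(0, 2, size=(m, cfg.n_loci))
                nxt = np.empty_like(pop)
                nxt[:, :, 0] = np.take_along_axis(
                    pop[mothers], picks_m[:, :, None], axis=2
                )[:, :, 0]
                nxt[:, :, 1] = np.take_along_axis(
                    pop[fathers], picks_f[:, :, None], axis=2
                )[:, :, 0]
                pop = nxt
            true_calls[rows] = pop

    observed = corrupt_genotypes(true_calls, cfg, rng, labels)

    block_names = [f"B{b + 1}" for b in range(cfg.n_blocks)]
    plot_names = []
    counter: dict[int, int] = {}
    for b in plot_block_idx:
        counter[b] = counter.get(b, 0) + 1
        plot_names.append(f"P{sum(cfg.plots_per_block[:b]) + counter[b]}")
    individuals = pd.DataFrame(
        {
            "id": [f"ind{i + 1}" for i in range(n)],
            "block": [block_names[plot_block_idx[p]] for p in plot_of_ind],
            "plot": [plot_names[p] for p in plot_of_ind],
            "timepoint": "none",
        }
    )
    table = GenotypeTable(
        individuals, [f"L{j + 1}" for j in range(cfg.n_loci)], observed
    )
    return SimOutput(
        table=table,
        true_calls=true_calls,
        ancestral_freqs=anc,
        block_freqs=block_freqs,
        plot_freqs=plot_freqs,
        config=cfg,
        plot_of_individual=plot_of_ind,
    )


def corrupt_genotypes(
    calls: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
    labels: np.ndarray | None = None,
) -> np.ndarray:
    """Apply null alleles, genotyping error and missingness (in that order)."""
    out = calls.copy()
    n, n_loci, _ = out.shape
    if labels is None:
        labels = _allele_labels(cfg.n_alleles_per_locus)
    if cfg.null_allele_freq > 0:
        null = rng.random(out.shape) < cfg.null_allele_freq
        one_null = null[:, :, 0] ^ null[:, :, 1]
        both_null = null[:, :, 0] & null[:, :, 1]
        # a single null copy hides behind the visible one: apparent homozygote
        visible = np.where(null[:, :, 0], out[:, :, 1], out[:, :, 0])
        for k in (0, 1):
            out[:, :, k] = np.where(one_null, visible, out[:, :, k])
            out[:, :, k] = np.where(both_null, MISSING, out[:, :, k])
    if cfg.genotyping_error_rate > 0:
        err = rng.random((n, n_loci)) < cfg.genotyping_error_rate
        which = rng.integers(0, 2, size=(n, n_loci))
        rand_allele = labels[rng.integers(0, len(labels), size=(n, n_loci))]
        for k in (0, 1):
            hit = err & (which == k) & (out[:, :, k] != MISSING)
            out[:, :, k] = np.where(hit, rand_allele, out[:, :, k])
    if cfg.missing_rate > 0:
        miss = rng.random((n, n_loci)) < cfg.missing_rate
        out[miss] = MISSING
    return out


# ------------------------------------------------------------ progeny arrays


def simulate_progeny_arrays(
    cfg: SimConfig,
    n_mothers: int = 10,
    seeds_per_mother: int = 5,
    rng: np.random.Generator | None = None,
    population: SimOutput | None = None,
    corrupt_seeds: bool = True,
) -> tuple[list[ProgenyArray], pd.DataFrame]:
    """Simulate open-pollinated progeny arrays with outcrossing rate ``t``.

    Mothers are drawn without replacement from a simulated population
    (generated on the fly from ``cfg`` if not supplied); their true
    genotypes are used. Each seed is selfed with probability ``1 - t``
    (both copies Mendelian from the mother) or outcrossed with probability
    ``t`` (one maternal gamete plus one gamete from a random plot-mate).
    Seeds are then corrupted per ``cfg`` (set ``corrupt_seeds=False`` for
    clean Mendelian data). Returns the arrays and a truth frame with
    per-seed outcrossed flags and father ids.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    if population is None:
        population = simulate_population(cfg, rng)
    calls = population.true_calls
    plot_of = population.plot_of_individual
    n = len(calls)
    if n_mothers > n:
        raise ValueError("more mothers requested than individuals available")
    mothers = rng.choice(n, size=n_mothers, replace=False)
    labels = _allele_labels(cfg.n_alleles_per_locus)
    seed_cfg = replace(cfg, null_allele_freq=0.0)  # seeds share the mothers' loci
    arrays, truth_rows = [], []
    for m in mothers:
        mom = calls[m]
        mates = np.flatnonzero((plot_of == plot_of[m]) & (np.arange(n) != m))
        if len(mates) == 0:
            mates = np.array([m])
        seeds = np.empty((seeds_per_mother, cfg.n_loci, 2), dtype=np.int64)
        for s in range(seeds_per_mother):
            outcrossed = rng.random() < cfg.outcross_rate
            father = int(rng.choice(mates)) if outcrossed else int(m)
            dad = calls[father]
            pm = rng.integers(0, 2, size=cfg.n_loci)
            pf = rng.integers(0, 2, size=cfg.n_loci)
            seeds[s, :, 0] = mom[np.arange(cfg.n_loci), pm]
            seeds[s, :, 1] = dad[np.arange(cfg.n_loci), pf]
            truth_rows.append(
                {
                    "mother_id": f"M{m}",
                    "seed_id": f"M{m}_s{s + 1}",
                    "outcrossed": bool(outcrossed),
                    "father_index": father,
                }
            )
        if corrupt_seeds:
            seeds = corrupt_genotypes(seeds, seed_cfg, rng, labels)
        arrays.append(
            ProgenyArray(
                mother_id=f"M{m}",
                loci=[f"L{j + 1}" for j in range(cfg.n_loci)],
                mother=mom.copy(),
                seed_ids=[f"M{m}_s{s + 1}" for s in range(seeds_per_mother)],
                seeds=seeds,
            )
        )
    return arrays, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------- Q matrices


def simulate_qmatrix(
    table: GenotypeTable,
    k: int | None = None,
    concentration: float = 8.0,
    rng: np.random.Generator | None = None,
) -> QMatrix:
    """Synthetic cluster-membership matrix consistent with the hierarchy.

    Each block anchors one cluster (cycling if K < blocks); individuals
    get Dirichlet memberships concentrated on their block's cluster.
    Stands in for the output of an external Bayesian clustering run.
    """
    rng = np.random.default_rng() if rng is None else rng
    blocks = list(dict.fromkeys(table.group_labels("block")))
    if k is None:
        k = len(blocks)
    anchor = {b: i % k for i, b in enumerate(blocks)}
    alpha_base = 0.4
    q = np.empty((table.n_individuals, k))
    for i, b in enumerate(table.group_labels("block")):
        alpha = np.full(k, alpha_base)
        alpha[anchor[b]] += concentration
        q[i] = rng.dirichlet(alpha)
    return QMatrix(table.individuals.copy(), q)


# ------------------------------------------------------------------ fixtures


def fixture_suite(seed: int = 0) -> dict[str, object]:
    """Deterministic tiny datasets with hand-checkable statistics.

    Keys: ``two_fixed_blocks`` (all variance among blocks),
    ``hw_panmictic`` (F near 0), ``selfed_arrays`` (pure-selfed progeny,
    100 % maternal-only).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, object] = {}

    # two blocks fixed for different alleles, two plots each
    n_per_plot, n_loci = 3, 2
    rows, calls = [], []
    for b, allele in (("B1", 100), ("B2", 200)):
        for p in (1, 2):
            for i in range(n_per_plot):
                rows.append(
                    {"id": f"{b}p{p}i{i}", "block": b, "plot": f"{b}-{p}",
                     "timepoint": "none"}
                )
                calls.append(np.full((n_loci, 2), allele))
    out["two_fixed_blocks"] = GenotypeTable(
        pd.DataFrame(rows), [f"L{j + 1}" for j in range(n_loci)], np.stack(calls)
    )

    # Hardy-Weinberg panmictic sample, two equifrequent alleles, 5 loci
    n, n_loci = 24, 5
    hw = 100 + 2 * rng.integers(0, 2, size=(n, n_loci, 2))
    out["hw_panmictic"] = GenotypeTable(
        pd.DataFrame(
            {"id": [f"hw{i}" for i in range(n)], "block": "B1", "plot": "P1",
             "timepoint": "none"}
        ),
        [f"L{j + 1}" for j in range(n_loci)],
        hw,
    )

    # three mothers, four selfed seeds each, no corruption
    loci = [f"L{j + 1}" for j in range(4)]
    arrays = []
    for m in range(3):
        mom = 100 + 2 * rng.integers(0, 3, size=(4, 2))
        picks = rng.integers(0, 2, size=(4, 4, 2))
        seeds = np.take_along_axis(np.broadcast_to(mom, (4, 4, 2)), picks, axis=2)
        arrays.append(
            ProgenyArray(
                mother_id=f"M{m}",
                loci=loci,
                mother=mom,
                seed_ids=[f"M{m}_s{s}" for s in range(4)],
                seeds=seeds.copy(),
            )
        )
    out["selfed_arrays"] = arrays
    return out
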