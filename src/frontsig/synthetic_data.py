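"""Synthetic paired-cohort generator.

Emulates the statistical structure of a matched two-region tumor expression
study: every patient contributes a bulk-tumor profile and (for most
patients) an invasion-front profile from the same tumor, with the two
regions coupled through a shared latent component.  Outcome groups are
"early relapse" versus "no relapse"; differential signal is planted in a
chosen subset of gene sets with per-gene signed mean shifts, so that signed
gene modules with mixed directions arise downstream.

The default configuration mirrors the cohort the pipeline targets: 19
early-relapse and 20 no-relapse patients, four of whom lack an
invasion-front profile (39 bulk / 35 front columns), log-intensity-like
values with unit residual standard deviation, and a modest between-region
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import EARLY_RELAPSE, NO_RELAPSE


@dataclass
class SimulationConfig:
    """Parameters of the paired-cohort simulation.

    Attributes
    ----------
    n_genes, n_sets, genes_per_set:
        Size of the gene universe and of the gene-set collection drawn
        from it (sets may overlap).
    n_early, n_no:
        Per-group sample sizes (early relapse / no relapse).
    planted_sets:
        Names of gene sets whose member genes receive a differential
        mean shift between outcome groups.
    effect_size:
        Absolute per-gene mean shift (log-units) for planted genes.
    frac_negative:
        Fraction of planted genes shifted *down* in the early-relapse
        group (the rest shift up), producing mixed module directions.
    region_correlation:
        Correlation, in [0, 1], between a patient's bulk and
        invasion-front value of the same gene, induced by a shared
        latent draw.
    noise_sd:
        Residual standard deviation of each expression value.
    missing_if:
        Number of patients without an invasion-front profile.
    seed:
        Seed for the single random generator driving the simulation.
    """

    n_genes: int = 2000
    n_sets: int = 30
    genes_per_set: int = 25
    n_early: int = 19
    n_no: int = 20
    planted_sets: tuple[str, ...] = ()
    effect_size: float = 1.0
    frac_negative: float = 0.25
    region_correlation: float = 0.5
    noise_sd: float = 1.0
    missing_if: int = 4
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_sets", "genes_per_set", "n_early", "n_no"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.missing_if < 0:
            raise ValueError("missing_if must be >= 0")
        if self.missing_if >= self.n_early + self.n_no:
            raise ValueError("missing_if must be smaller than the cohort size")
        if not 0.0 <= self.region_correlation <= 1.0:
            raise ValueError("region_correlation must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.frac_negative <= 1.0:
            raise ValueError("frac_negative must lie in [0, 1]")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set cannot exceed n_genes")


def gene_universe(n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes)))
    return [f"G{i:0{width}d}" for i in range(1, n_genes + 1)]


def generate_gene_sets(n_sets: int, genes_per_set: int, n_genes: int,
                       seed: int) -> dict[str, list[str]]:
    """Draw ``n_sets`` possibly-overlapping gene sets from the universe.

    Deterministic for a fixed seed; raises if a set cannot fit in the
    universe.
    """
    if genes_per_set > n_genes:
        raise ValueError(
            f"genes_per_set={genes_per_set} exceeds n_genes={n_genes}"
        )
    if n_sets < 1 or genes_per_set < 1:
        raise ValueError("n_sets and genes_per_set must be >= 1")
    rng = np.random.default_rng(seed)
    universe = np.asarray(gene_universe(n_genes))
    collection: dict[str, list[str]] = {}
    for i in range(1, n_sets + 1):
        members = rng.choice(universe, size=genes_per_set, replace=False)
        collection[f"SET{i:02d}"] = sorted(members.tolist())
    return collection


def _sample_ids(config: SimulationConfig) -> tuple[list[str], list[str]]:
    early = [f"P{i:03d}" for i in range(1, config.n_early + 1)]
    no = [f"P{i:03d}" for i in range(config.n_early + 1,
                                     config.n_early + config.n_no + 1)]
    return early, no


def _dropped_front_samples(early: list[str], no: list[str],
                           missing_if: int) -> list[str]:
    # Alternate between the two groups, dropping from the end of each,
    # so 4 missing profiles turn 19/20 into 17/18.
    dropped, e, n = [], list(early), list(no)
    for k in range(missing_if):
        pool = e if (k % 2 == 0 and e) or not n else n
        dropped.append(pool.pop())
    return dropped


def simulate_study(config: SimulationConfig):
    """Run the full simulation.

    Returns ``(bulk, invasion_front, phenotype, gene_sets)`` where the two
    expression matrices are genes x samples DataFrames, the phenotype is a
    Series of group labels indexed by sample, and ``gene_sets`` is the
    collection the planted sets refer to.
    """
    config.validate()
    gene_sets = generate_gene_sets(config.n_sets, config.genes_per_set,
                                   config.n_genes, config.seed)
    unknown = set(config.planted_sets) - set(gene_sets)
    if unknown:
        raise ValueError(f"planted_sets not in the collection: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    genes = gene_universe(config.n_genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    early_ids, no_ids = _sample_ids(config)
    samples = early_ids + no_ids
    n_samples = len(samples)

    # log-intensity-like per-gene baselines
    baseline = rng.uniform(4.0, 12.0, size=config.n_genes)

    # planted signed shifts: exact frac_negative fraction shifted down
    shift = np.zeros(config.n_genes)
    planted = sorted({g for s in config.planted_sets for g in gene_sets[s]})
    if planted and config.effect_size > 0:
        order = rng.permutation(len(planted))
        n_neg = int(round(config.frac_negative * len(planted)))
        signs = np.ones(len(planted))
        signs[order[:n_neg]] = -1.0
        for g, s in zip(planted, signs):
            shift[gene_pos[g]] = s * config.effect_size

    # group means: half the shift up in one group, half down in the other
    mean = np.tile(baseline[:, None], (1, n_samples))
    is_early = np.array([s in set(early_ids) for s in samples])
    mean[:, is_early] += shift[:, None] / 2.0
    mean[:, ~is_early] -= shift[:, None] / 2.0

    # paired regions share a latent draw; mixing weight gives the target
    # correlation: x_r = mu + sqrt(rho)*L + sqrt(1-rho)*e_r
    rho = config.region_correlation
    shape = (config.n_genes, n_samples)
    latent = rng.normal(0.0, config.noise_sd, size=shape)
    eps_bulk = rng.normal(0.0, config.noise_sd, size=shape)
    eps_front = rng.normal(0.0, config.noise_sd, size=shape)
    w_shared, w_own = np.sqrt(rho), np.sqrt(1.0 - rho)
    bulk_values = mean + w_shared * latent + w_own * eps_bulk
    front_values = mean + w_shared * latent + w_own * eps_front

    bulk = pd.DataFrame(bulk_values, index=genes, columns=samples)
    front = pd.DataFrame(front_values, index=genes, columns=samples)
    dropped = _dropped_front_samples(early_ids, no_ids, config.missing_if)
    front = front.drop(columns=dropped)

    phenotype = pd.Series(
        [EARLY_RELAPSE] * len(early_ids) + [NO_RELAPSE] * len(no_ids),
        index=samples, name="group",
    )
    return bulk, front, phenotype, gene_sets


def simulate_cohort(config: SimulationConfig):
    """Like :func:`simulate_study` but without the gene-set collection."""
    bulk, front, phenotype, _ = simulate_study(config)
    return bulk, front, phenotype
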