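"""Stepwise exploration of four nested search spaces.

The design question: how much realism do genetic constraints buy when
searching for fruit-quality ideotypes?  Four spaces are explored, each by
uniform random draws and by NSGA-II optimization:

1. ``parameters_obs-bounds`` — the box spanned by the extreme parameter
   values observed in the real progeny (packaged constants);
2. ``parameters_restricted`` — the box attainable under the additive QTL
   model (recomputed from the packaged model coefficients);
3. ``alleles`` — the 2^31 binary allele space, parameters derived through
   the genetic model;
4. ``alleles_with_linkage`` — the allele space with inseparable-pair
   constraints (2^17 feasible haplotype combinations).

Objectives throughout: maximize fruit dry mass ``DM``, minimize stone ratio
``SR``, maximize sugar concentration ``SU`` — i.e. minimize
``(-DM, SR, -SU)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import genetic_model as gm
from . import moea
from .fruit_model import PARAMETER_NAMES, GrowthConfig, WeatherSeries, simulate_phenotypes

__all__ = [
    "SPACE_NAMES",
    "OBS_BOUNDS",
    "SpaceDefinition",
    "Dataset",
    "obs_bounds_space",
    "restricted_space_from_model",
    "allele_space",
    "draw_random_parameters",
    "draw_random_alleles",
    "optimize_space",
    "enumerate_feasible_front",
    "dominance_report",
    "run_study",
]

SPACE_NAMES = ("parameters_obs-bounds", "parameters_restricted", "alleles",
               "alleles_with_linkage")

#: Observed extreme parameter values in the 159-individual progeny.  These
#: are data (field measurements), not derivable from the genetic model.
OBS_BOUNDS: dict[str, tuple[float, float]] = {
    "A": (0.771, 64.147),
    "B": (0.01, 2.348),
    "RGRini": (0.001, 0.008),
    "P3": (1203.528, 2991.884),
    "kstone": (0.036, 0.378),
    "Wstone": (2.355, 12.885),
    "SLA": (0.013, 0.021),
}

TRAIT_NAMES = ("DM", "SR", "SU")


@dataclass(frozen=True)
class SpaceDefinition:
    """One of the four nested search spaces."""

    name: str
    bounds: Mapping[str, tuple[float, float]] | None = None   # box spaces
    model: gm.GeneticModel | None = None                      # allele spaces
    pairs: gm.InseparablePairs | None = None                  # linkage constraints

    def __post_init__(self) -> None:
        if self.bounds is not None:
            for p, (lo, hi) in self.bounds.items():
                if lo >= hi:
                    raise ValueError(f"empty range for parameter {p}: ({lo}, {hi})")
        elif self.model is None:
            raise ValueError("a space needs either box bounds or a genetic model")

    @property
    def is_allelic(self) -> bool:
        return self.bounds is None

    def box_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lower = np.array([self.bounds[p][0] for p in PARAMETER_NAMES])
        upper = np.array([self.bounds[p][1] for p in PARAMETER_NAMES])
        return lower, upper


@dataclass
class Dataset:
    """A named collection of individuals with decisions, parameters, phenotypes."""

    name: str
    decisions: pd.DataFrame      # loc1..loc31 or the seven parameter columns
    parameters: pd.DataFrame     # seven parameter columns
    phenotypes: pd.DataFrame     # DM, SR, SU
    provenance: str              # "random" | "optimized"
    seed: int

    def __post_init__(self) -> None:
        n = len(self.decisions)
        if len(self.parameters) != n or len(self.phenotypes) != n:
            raise ValueError("decision, parameter and phenotype tables must align")
        if self.provenance not in ("random", "optimized"):
            raise ValueError("provenance must be 'random' or 'optimized'")

    def __len__(self) -> int:
        return len(self.decisions)

    def objectives(self) -> np.ndarray:
        """Minimization objectives (-DM, SR, -SU) for every individual."""
        ph = self.phenotypes
        return np.column_stack([-ph["DM"], ph["SR"], -ph["SU"]])

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat(
            [self.decisions.reset_index(drop=True),
             self.parameters.reset_index(drop=True).add_prefix("param_"),
             self.phenotypes.reset_index(drop=True)], axis=1)
        out.insert(0, "dataset", self.name)
        return out


def obs_bounds_space() -> SpaceDefinition:
    return SpaceDefinition(name="parameters_obs-bounds", bounds=dict(OBS_BOUNDS))


def restricted_space_from_model(m: gm.GeneticModel | None = None) -> SpaceDefinition:
    """Box whose faces are the per-parameter extremes of the genetic model."""
    m = m or gm.default_genetic_model()
    return SpaceDefinition(name="parameters_restricted", bounds=gm.parameter_bounds(m))


def allele_space(m: gm.GeneticModel | None = None,
                 pairs: gm.InseparablePairs | None = None) -> SpaceDefinition:
    m = m or gm.default_genetic_model()
    name = "alleles_with_linkage" if pairs is not None else "alleles"
    return SpaceDefinition(name=name, model=m, pairs=pairs)


def _phenotype_frame(P: np.ndarray, c: GrowthConfig, w: WeatherSeries) -> pd.DataFrame:
    return pd.DataFrame(simulate_phenotypes(P, c, w), columns=list(TRAIT_NAMES))


def _param_frame(P: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(P, columns=list(PARAMETER_NAMES))


def _genotype_frame(G: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(G, columns=[f"loc{i}" for i in range(1, gm.N_LOCI + 1)])


def draw_random_parameters(space: SpaceDefinition, c: GrowthConfig, w: WeatherSeries,
                           n: int = 500, seed: int = 0) -> Dataset:
    """``n`` i.i.d. uniform parameter draws in the box, with simulated traits."""
    if space.is_allelic:
        raise ValueError("draw_random_parameters needs a box space")
    rng = np.random.default_rng(seed)
    lower, upper = space.box_arrays()
    P = lower + rng.random((n, 7)) * (upper - lower)
    return Dataset(name=f"{space.name}:random", decisions=_param_frame(P),
                   parameters=_param_frame(P),
                   phenotypes=_phenotype_frame(P, c, w) if n else
                   pd.DataFrame(columns=list(TRAIT_NAMES)),
                   provenance="random", seed=seed)


def draw_random_alleles(c: GrowthConfig, w: WeatherSeries, n: int = 500, seed: int = 0,
                        m: gm.GeneticModel | None = None,
                        pairs: gm.InseparablePairs | None = None) -> Dataset:
    """Fair-coin allele draws (per locus, or per haplotype block when ``pairs``
    is given, so linkage is never violated), mapped through the genetic model."""
    m = m or gm.default_genetic_model()
    rng = np.random.default_rng(seed)
    if pairs is not None:
        blocks = gm.build_blocks(pairs)
        bits = rng.integers(0, 2, size=(n, blocks.n_free))
        G = gm.decode_blocks_batch(bits, blocks)
        name = "alleles_with_linkage:random"
    else:
        G = rng.integers(0, 2, size=(n, gm.N_LOCI)).astype(np.int8)
        name = "alleles:random"
    P = gm.predict_parameters_batch(G, m)
    return Dataset(name=name, decisions=_genotype_frame(G), parameters=_param_frame(P),
                   phenotypes=_phenotype_frame(P, c, w) if n else
                   pd.DataFrame(columns=list(TRAIT_NAMES)),
                   provenance="random", seed=seed)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _make_problem(space: SpaceDefinition, c: GrowthConfig, w: WeatherSeries,
                  cfg: moea.NsgaConfig):
    """Wrap a space as an evaluable NSGA-II problem.

    Returns the problem plus a decoder mapping decision rows to
    (genotypes or None, parameter matrix).
    """
    if not space.is_allelic:
        lower, upper = space.box_arrays()

        def evaluate(X):
            F = simulate_phenotypes(X, c, w) * np.array([-1.0, 1.0, -1.0])
            return F, np.zeros(X.shape[0])

        problem = moea.Problem(n_var=7, evaluate=evaluate, lower=lower, upper=upper)
        return problem, lambda X: (None, np.asarray(X, dtype=float))

    m = space.model
    if space.pairs is not None and cfg.constraint_mode == "block_encoding":
        blocks = gm.build_blocks(space.pairs)

        def decode(X):
            G = gm.decode_blocks_batch(X, blocks)
            return G, gm.predict_parameters_batch(G, m)

        def evaluate(X):
            _, P = decode(X)
            F = simulate_phenotypes(P, c, w) * np.array([-1.0, 1.0, -1.0])
            return F, np.zeros(X.shape[0])

        return moea.Problem(n_var=blocks.n_free, evaluate=evaluate, binary=True), decode

    pairs = space.pairs

    def decode31(X):
        G = gm.as_genotype_matrix(X)
        return G, gm.predict_parameters_batch(G, m)

    def evaluate31(X):
        G, P = decode31(X)
        F = simulate_phenotypes(P, c, w) * np.array([-1.0, 1.0, -1.0])
        if pairs is None:
            V = np.zeros(X.shape[0])
        else:
            V = gm.linkage_violations_batch(G, pairs).astype(float)
        return F, V

    return moea.Problem(n_var=gm.N_LOCI, evaluate=evaluate31, binary=True), decode31


def optimize_space(space: SpaceDefinition, c: GrowthConfig, w: WeatherSeries,
                   cfg: moea.NsgaConfig) -> Dataset:
    """NSGA-II over one space; the dataset is the distinct non-dominated archive."""
    problem, decode = _make_problem(space, c, w, cfg)
    result = moea.evolve(problem, cfg)
    G, P = decode(result.archive_X)
    ph = pd.DataFrame(result.archive_F * np.array([-1.0, 1.0, -1.0]),
                      columns=list(TRAIT_NAMES))
    decisions = _genotype_frame(G) if G is not None else _param_frame(P)
    return Dataset(name=f"{space.name}:optim", decisions=decisions,
                   parameters=_param_frame(P), phenotypes=ph,
                   provenance="optimized", seed=cfg.seed)


def enumerate_feasible_front(c: GrowthConfig, w: WeatherSeries,
                             m: gm.GeneticModel | None = None,
                             pairs: gm.InseparablePairs | None = None,
                             chunk: int = 8192):
    """Exhaustive Pareto front over all linkage-feasible block genotypes.

    Enumerates every 2^n_free haplotype combination (2^17 = 131072 with the
    printed pairs), simulates each phenotype in chunks, and brute-force
    Pareto-filters the minimization objectives.  Returns
    ``(front_bits, front_F)`` with ``front_F`` the ``(-DM, SR, -SU)`` rows.
    """
    m = m or gm.default_genetic_model()
    pairs = pairs or gm.default_inseparable_pairs()
    blocks = gm.build_blocks(pairs)
    nf = blocks.n_free
    total = 1 << nf
    codes = np.arange(total, dtype=np.int64)
    bits_all = ((codes[:, None] >> np.arange(nf)[None, :]) & 1).astype(np.int8)
    F_parts = []
    for start in range(0, total, chunk):
        bits = bits_all[start:start + chunk]
        P = gm.predict_parameters_batch(gm.decode_blocks_batch(bits, blocks), m)
        F_parts.append(simulate_phenotypes(P, c, w) * np.array([-1.0, 1.0, -1.0]))
    F = np.vstack(F_parts)
    mask = moea.pareto_mask(F)
    front_bits, front_F = bits_all[mask], F[mask]
    keep = moea._dedup_rows(front_bits, binary=True)
    return front_bits[keep], front_F[keep]


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def dominance_report(random_ds: Dataset, optimized_ds: Dataset) -> dict:
    """How thoroughly the optimized archive beats the random cloud.

    Returns the fraction of random individuals strictly dominated by at
    least one optimized solution, the reverse fraction, and per-trait
    min/median/max summaries for both datasets.
    """
    summary = {}
    for label, ds in (("random", random_ds), ("optimized", optimized_ds)):
        ph = ds.phenotypes
        summary[label] = {
            t: {"min": float(ph[t].min()), "median": float(ph[t].median()),
                "max": float(ph[t].max())} if len(ph) else {}
            for t in TRAIT_NAMES
        }
    return {
        "dominated_fraction": _dominated_fraction(random_ds.objectives(),
                                                  optimized_ds.objectives()),
        "reverse_dominated_fraction": _dominated_fraction(optimized_ds.objectives(),
                                                          random_ds.objectives()),
        "n_random": len(random_ds),
        "n_optimized": len(optimized_ds),
        "traits": summary,
    }


def _dominated_fraction(F_target: np.ndarray, F_by: np.ndarray) -> float:
    """Fraction of ``F_target`` rows strictly dominated by some ``F_by`` row."""
    if F_target.shape[0] == 0 or F_by.shape[0] == 0:
        return 0.0
    dominated = np.zeros(F_target.shape[0], dtype=bool)
    for f in F_by:
        dominated |= (F_target >= f).all(axis=1) & (F_target > f).any(axis=1)
        if dominated.all():
            break
    return float(dominated.mean())


def dominance_summary_frame(report: dict) -> pd.DataFrame:
    rows = []
    for label, traits in report["traits"].items():
        for trait, stats in traits.items():
            rows.append({"dataset": label, "trait": trait, **stats})
    return pd.DataFrame(rows)


def run_study(c: GrowthConfig, w: WeatherSeries, cfg: moea.NsgaConfig,
              n_random: int = 500, seed: int = 0,
              m: gm.GeneticModel | None = None,
              pairs: gm.InseparablePairs | None = None) -> dict[str, Dataset]:
    """Run random draws and optimization in all four spaces.

    All datasets share one growth config and weather series so phenotypes
    are comparable.  Seeds for the sub-runs are derived deterministically
    from ``seed``.
    """
    m = m or gm.default_genetic_model()
    pairs = pairs or gm.default_inseparable_pairs()
    sub = np.random.SeedSequence(seed).spawn(8)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in sub]
    spaces = {"obs-bounds": obs_bounds_space(), "restricted": restricted_space_from_model(m)}
    out: dict[str, Dataset] = {}
    for i, (suffix, space) in enumerate(spaces.items()):
        out[f"parameters_random_{suffix}"] = draw_random_parameters(
            space, c, w, n=n_random, seed=seeds[2 * i])
        out[f"parameters_optim_{suffix}"] = optimize_space(
            space, c, w, _with_seed(cfg, seeds[2 * i + 1]))
    out["alleles_random"] = draw_random_alleles(c, w, n=n_random, seed=seeds[4], m=m)
    out["alleles_optim"] = optimize_space(allele_space(m), c, w, _with_seed(cfg, seeds[5]))
    out["alleles_random_with-linkage"] = draw_random_alleles(
        c, w, n=n_random, seed=seeds[6], m=m, pairs=pairs)
    out["alleles_optim_with-linkage"] = optimize_space(
        allele_space(m, pairs), c, w, _with_seed(cfg, seeds[7]))
    return out


def _with_seed(cfg: moea.NsgaConfig, seed: int) -> moea.NsgaConfig:
    from dataclasses import replace
    return replace(cfg, seed=seed)
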