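"""Additive QTL allele-effect model for the seven fruit-model parameters.

A genotype is a binary vector over 31 loci (0 = wild *P. davidiana* D allele,
1 = cultivated *P. persica* S allele; loci are numbered 1..31).  Each model
parameter is an intercept (the all-D genotype) plus a sum of signed additive
locus effects; five loci are pleiotropic.  Loci closer than 12.5 cM on the
genetic map are treated as inseparable, which partitions the loci into
haplotype blocks and shrinks the feasible allele space from 2^31 to 2^17.

The printed model ships with the package (``data/genetic_model.json``) and is
loaded by :func:`default_genetic_model`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .fruit_model import PARAMETER_NAMES, FruitParameters

__all__ = [
    "N_LOCI",
    "QtlEffect",
    "GeneticModel",
    "InseparablePairs",
    "HaplotypeBlocks",
    "CollinearLociError",
    "as_genotype",
    "as_genotype_matrix",
    "default_genetic_model",
    "default_inseparable_pairs",
    "load_genetic_model",
    "save_genetic_model",
    "predict_parameters",
    "predict_parameters_batch",
    "parameter_bounds",
    "linkage_violations",
    "build_blocks",
    "encode_blocks",
    "decode_blocks",
    "estimate_allele_effects",
    "read_genotypes_csv",
    "write_genotypes_csv",
]

#: Number of loci in the allele space.
N_LOCI = 31


class CollinearLociError(ValueError):
    """Raised when a regression design contains perfectly collinear loci."""

    def __init__(self, parameter: str, loci: Sequence[object]):
        self.parameter = parameter
        self.loci = tuple(loci)
        super().__init__(
            f"design matrix for parameter {parameter!r} is rank-deficient; "
            f"collinear columns involve loci {self.loci}")


def as_genotype(g, n_loci: int = N_LOCI) -> np.ndarray:
    """Validate and return a genotype as an int8 array of 0/1 of length ``n_loci``."""
    arr = np.asarray(g)
    if arr.shape != (n_loci,):
        raise ValueError(f"genotype must have exactly {n_loci} loci, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("genotype entries must be 0 (D allele) or 1 (S allele)")
    return arr.astype(np.int8)


def as_genotype_matrix(G, n_loci: int = N_LOCI) -> np.ndarray:
    """Validate a stack of genotypes, shape ``(n, n_loci)``."""
    arr = np.asarray(G)
    if arr.ndim != 2 or arr.shape[1] != n_loci:
        raise ValueError(f"genotype matrix must have shape (n, {n_loci})")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("genotype entries must be 0 or 1")
    return arr.astype(np.int8)


@dataclass(frozen=True)
class QtlEffect:
    """One additive locus effect: parameter units per copy of the S allele."""

    locus: int
    parameter: str
    effect: float

    def __post_init__(self) -> None:
        if not 1 <= self.locus <= N_LOCI:
            raise ValueError(f"locus must be in 1..{N_LOCI}, got {self.locus}")
        if self.parameter not in PARAMETER_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.effect == 0:
            raise ValueError("effect must be non-zero")


class GeneticModel:
    """Intercepts plus additive locus effects mapping genotype -> parameters."""

    def __init__(self, intercepts: Mapping[str, float], effects: Iterable[QtlEffect]):
        missing = set(PARAMETER_NAMES) - set(intercepts)
        if missing:
            raise ValueError(f"missing intercepts for {sorted(missing)}")
        self.intercepts = {name: float(intercepts[name]) for name in PARAMETER_NAMES}
        self.effects = tuple(effects)
        seen = set()
        for e in self.effects:
            if (e.locus, e.parameter) in seen:
                raise ValueError(f"duplicate effect for locus {e.locus}, parameter {e.parameter}")
            seen.add((e.locus, e.parameter))
        # (31, 7) coefficient matrix in PARAMETER_NAMES column order.
        coef = np.zeros((N_LOCI, len(PARAMETER_NAMES)))
        for e in self.effects:
            coef[e.locus - 1, PARAMETER_NAMES.index(e.parameter)] = e.effect
        self._coef = coef
        self._intercept_vec = np.array([self.intercepts[p] for p in PARAMETER_NAMES])

    @property
    def coefficient_matrix(self) -> np.ndarray:
        """Copy of the (31, 7) effect matrix, columns in ``PARAMETER_NAMES`` order."""
        return self._coef.copy()

    @property
    def intercept_vector(self) -> np.ndarray:
        return self._intercept_vec.copy()

    def loci_for(self, parameter: str) -> tuple[int, ...]:
        """Loci carrying a non-zero effect on ``parameter``, ascending."""
        return tuple(sorted(e.locus for e in self.effects if e.parameter == parameter))

    @property
    def loci(self) -> tuple[int, ...]:
        return tuple(sorted({e.locus for e in self.effects}))

    @property
    def pleiotropic_loci(self) -> tuple[int, ...]:
        """Loci with effects on two or more parameters."""
        counts: dict[int, int] = {}
        for e in self.effects:
            counts[e.locus] = counts.get(e.locus, 0) + 1
        return tuple(sorted(l for l, c in counts.items() if c >= 2))

    def structure_summary(self) -> dict:
        return {
            "n_loci": len(self.loci),
            "n_effects": len(self.effects),
            "n_pleiotropic": len(self.pleiotropic_loci),
            "effects_per_parameter": {p: len(self.loci_for(p)) for p in PARAMETER_NAMES},
        }

    def to_dict(self) -> dict:
        params = {}
        for p in PARAMETER_NAMES:
            params[p] = {
                "intercept": self.intercepts[p],
                "effects": {str(e.locus): e.effect for e in self.effects if e.parameter == p},
            }
        return {"parameters": params}

    @classmethod
    def from_dict(cls, payload: Mapping) -> "GeneticModel":
        intercepts = {}
        effects = []
        for name, block in payload["parameters"].items():
            intercepts[name] = float(block["intercept"])
            for locus, effect in block.get("effects", {}).items():
                effects.append(QtlEffect(locus=int(locus), parameter=name, effect=float(effect)))
        return cls(intercepts, effects)


@dataclass(frozen=True)
class InseparablePairs:
    """Unordered pairs of loci treated as a single inherited unit."""

    pairs: tuple[tuple[int, int], ...]
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        norm = []
        for i, j in self.pairs:
            if not (1 <= i <= N_LOCI and 1 <= j <= N_LOCI) or i == j:
                raise ValueError(f"invalid locus pair ({i}, {j})")
            norm.append((min(i, j), max(i, j)))
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate pairs")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        object.__setattr__(self, "pairs", tuple(norm))


@dataclass(frozen=True)
class HaplotypeBlocks:
    """Partition of the 31 loci into co-inherited groups (sorted by smallest member)."""

    blocks: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        flat = [l for b in self.blocks for l in b]
        if sorted(flat) != list(range(1, N_LOCI + 1)):
            raise ValueError("blocks must partition loci 1..31 exactly")

    @property
    def n_free(self) -> int:
        """Number of free binary dimensions (one per block)."""
        return len(self.blocks)

    def block_of(self, locus: int) -> int:
        for idx, b in enumerate(self.blocks):
            if locus in b:
                return idx
        raise KeyError(locus)


# ---------------------------------------------------------------------------
# Packaged printed model
# ---------------------------------------------------------------------------

def _packaged_payload() -> dict:
    with resources.files("ideopeach.data").joinpath("genetic_model.json").open() as fh:
        return json.load(fh)


def default_genetic_model() -> GeneticModel:
    """The printed 31-locus, 37-effect model shipped with the package."""
    return GeneticModel.from_dict(_packaged_payload())


def default_inseparable_pairs() -> InseparablePairs:
    """The 14 printed inseparable locus pairs (loci closer than 12.5 cM)."""
    payload = _packaged_payload()
    return InseparablePairs(pairs=tuple(tuple(p) for p in payload["inseparable_pairs"]),
                            epsilon=float(payload.get("epsilon", 1e-9)))


def load_genetic_model(path) -> GeneticModel:
    """Load a genetic model from a structured JSON text file."""
    with open(path) as fh:
        return GeneticModel.from_dict(json.load(fh))


def save_genetic_model(model: GeneticModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Prediction and bounds
# ---------------------------------------------------------------------------

def predict_parameters(g, m: GeneticModel) -> FruitParameters:
    """Predict the seven parameters for one genotype (intercept + Σ effect·allele)."""
    g = as_genotype(g)
    values = m.intercept_vector + g @ m.coefficient_matrix
    return FruitParameters.from_array(values)


def predict_parameters_batch(G, m: GeneticModel) -> np.ndarray:
    """Vectorized prediction; returns ``(n, 7)`` in ``PARAMETER_NAMES`` order."""
    G = as_genotype_matrix(G)
    return m.intercept_vector[None, :] + G @ m.coefficient_matrix


def parameter_bounds(m: GeneticModel, return_genotypes: bool = False):
    """Per-parameter (min, max) attainable over all 2^31 allele combinations.

    Effects are additive and independent, so each extreme is attained by the
    sign-determined genotype: allele 1 at every locus whose effect pushes the
    parameter in the wanted direction, 0 elsewhere.
    """
    coef = m.coefficient_matrix
    bounds = {}
    genos = {}
    for j, name in enumerate(PARAMETER_NAMES):
        col = coef[:, j]
        lo = m.intercepts[name] + col[col < 0].sum()
        hi = m.intercepts[name] + col[col > 0].sum()
        bounds[name] = (float(lo), float(hi))
        if return_genotypes:
            genos[name] = ((col < 0).astype(np.int8), (col > 0).astype(np.int8))
    return (bounds, genos) if return_genotypes else bounds


# ---------------------------------------------------------------------------
# Linkage constraints
# ---------------------------------------------------------------------------

def linkage_violations(g, p: InseparablePairs) -> int:
    """Number of inseparable pairs whose two loci carry different alleles."""
    g = as_genotype(g)
    return int(sum(g[i - 1] != g[j - 1] for i, j in p.pairs))


def linkage_violations_batch(G, p: InseparablePairs) -> np.ndarray:
    G = as_genotype_matrix(G)
    idx_i = np.array([i - 1 for i, _ in p.pairs])
    idx_j = np.array([j - 1 for _, j in p.pairs])
    if idx_i.size == 0:
        return np.zeros(G.shape[0], dtype=int)
    return (G[:, idx_i] != G[:, idx_j]).sum(axis=1)


def build_blocks(p: InseparablePairs) -> HaplotypeBlocks:
    """Haplotype blocks as the transitive closure (union-find) of the pairs."""
    parent = list(range(N_LOCI + 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in p.pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for locus in range(1, N_LOCI + 1):
        groups.setdefault(find(locus), []).append(locus)
    blocks = tuple(tuple(sorted(v)) for _, v in sorted(groups.items()))
    return HaplotypeBlocks(blocks=blocks)


def encode_blocks(g, b: HaplotypeBlocks) -> np.ndarray:
    """Collapse a linkage-feasible genotype to one bit per haplotype block."""
    g = as_genotype(g)
    bits = np.empty(b.n_free, dtype=np.int8)
    for idx, block in enumerate(b.blocks):
        vals = {int(g[l - 1]) for l in block}
        if len(vals) != 1:
            raise ValueError(f"genotype is not constant on block {block}; cannot encode")
        bits[idx] = vals.pop()
    return bits


def decode_blocks(bits, b: HaplotypeBlocks) -> np.ndarray:
    """Expand block bits to a full genotype (always linkage-feasible)."""
    bits = np.asarray(bits)
    if bits.shape != (b.n_free,) or not np.isin(bits, (0, 1)).all():
        raise ValueError(f"expected {b.n_free} binary block bits")
    g = np.empty(N_LOCI, dtype=np.int8)
    for idx, block in enumerate(b.blocks):
        for locus in block:
            g[locus - 1] = bits[idx]
    return g


def decode_blocks_batch(Bits, b: HaplotypeBlocks) -> np.ndarray:
    """Vectorized :func:`decode_blocks` for a ``(n, n_free)`` bit matrix."""
    Bits = np.asarray(Bits)
    if Bits.ndim != 2 or Bits.shape[1] != b.n_free:
        raise ValueError(f"expected shape (n, {b.n_free})")
    expand = np.zeros((b.n_free, N_LOCI), dtype=np.int8)
    for idx, block in enumerate(b.blocks):
        for locus in block:
            expand[idx, locus - 1] = 1
    return (Bits.astype(np.int8) @ expand).astype(np.int8)


# ---------------------------------------------------------------------------
# Allele-effect estimation
# ---------------------------------------------------------------------------

def estimate_allele_effects(genotypes, values, loci_per_parameter: Mapping[str, Sequence[int]],
                            ) -> GeneticModel:
    """Re-estimate intercepts and allele effects by ordinary least squares.

    For each parameter, fits ``value ~ intercept + Σ effect·allele`` restricted
    to the given loci.  Parameters absent from ``loci_per_parameter`` get an
    intercept-only fit (their mean).

    Parameters
    ----------
    genotypes:
        ``(n, 31)`` binary matrix.
    values:
        Mapping or DataFrame of per-individual parameter values, keyed by
        parameter name.
    loci_per_parameter:
        Which loci to include per parameter.

    Raises
    ------
    CollinearLociError
        If the design matrix for some parameter is rank-deficient; the error
        names the loci involved in the collinearity.
    """
    G = as_genotype_matrix(genotypes)
    n = G.shape[0]
    if isinstance(values, pd.DataFrame):
        values = {name: values[name].to_numpy() for name in values.columns}
    intercepts: dict[str, float] = {}
    effects: list[QtlEffect] = []
    for name in PARAMETER_NAMES:
        y = np.asarray(values[name], dtype=float)
        if y.shape != (n,):
            raise ValueError(f"values for {name} must have length {n}")
        loci = tuple(loci_per_parameter.get(name, ()))
        X = np.column_stack([np.ones(n)] + [G[:, l - 1].astype(float) for l in loci])
        if n < X.shape[1]:
            raise ValueError(
                f"need at least {X.shape[1]} individuals to fit parameter {name}")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise CollinearLociError(name, _collinear_loci(X[:, 1:], loci))
        coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercepts[name] = float(coefs[0])
        for locus, effect in zip(loci, coefs[1:]):
            if effect != 0:
                effects.append(QtlEffect(locus=locus, parameter=name, effect=float(effect)))
    return GeneticModel(intercepts, effects)


def _collinear_loci(X: np.ndarray, loci: Sequence[int]) -> tuple[int, ...]:
    """Identify loci involved in exact collinearity (identical/constant columns)."""
    bad: set[int] = set()
    for a in range(X.shape[1]):
        if np.ptp(X[:, a]) == 0:
            bad.add(loci[a])
        for b in range(a + 1, X.shape[1]):
            if np.array_equal(X[:, a], X[:, b]) or np.array_equal(X[:, a], 1 - X[:, b]):
                bad.update((loci[a], loci[b]))
    return tuple(sorted(bad)) if bad else tuple(loci)


# ---------------------------------------------------------------------------
# Genotype IO
# ---------------------------------------------------------------------------

def write_genotypes_csv(G, path) -> None:
    """One row per individual, columns ``loc1..loc31``."""
    G = as_genotype_matrix(G)
    pd.DataFrame(G, columns=[f"loc{i}" for i in range(1, N_LOCI + 1)]).to_csv(path, index=False)


def read_genotypes_csv(path) -> np.ndarray:
    frame = pd.read_csv(path)
    cols = [f"loc{i}" for i in range(1, N_LOCI + 1)]
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"genotype file missing columns {missing}")
    return as_genotype_matrix(frame[cols].to_numpy())
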