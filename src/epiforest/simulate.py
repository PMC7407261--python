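"""Synthetic genotypes and phenotypes with full truth bookkeeping.

Three generators cover the study designs used throughout the package:

* :func:`gen_features` — independent bi-allelic genotypes at random allele
  frequencies (the genotype half of a fully synthetic benchmark);
* :func:`gen_label` — an additive (polygenic) binary phenotype driven by a
  handful of causal variants plus many weakly weighted noise variants;
* :func:`gen_epistatic_label` — a polygenic-epistatic phenotype built from
  n-way "truth-variables": each variable is a disjoint set of n variants
  whose parity of dominance indicators drives the liability.  For n >= 2 and
  a carrier probability of 1/2 every member variant is marginally independent
  of its variable's value, so the interaction is invisible to single-variant
  tests by construction.

A :class:`TruthSet` records which variants drive the phenotype (the
"truth-variants") so that recovery can be scored afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genodata import GenotypeMatrix, PhenotypeVector

__all__ = [
    "LabelSimSpec",
    "EpistasisSpec",
    "TruthVariable",
    "TruthSet",
    "gen_features",
    "gen_label",
    "gen_epistatic_label",
    "truth_counts",
    "maf_for_carrier_prob",
    "simulate_epistatic_dataset",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _median_dichotomize(liability: np.ndarray) -> np.ndarray:
    """Binary labels by median threshold: cases are ``liability >= median``.

    For a continuous liability this is exactly balanced.  When the liability
    is discrete the inclusive rule can be badly unbalanced (or degenerate),
    so the strict rule ``liability > median`` is used instead whenever it is
    strictly closer to a 50/50 split; ties prefer the inclusive rule.
    """
    n = liability.size
    med = np.median(liability)
    incl = liability >= med
    strict = liability > med
    half = n / 2.0
    chosen = strict if abs(strict.sum() - half) < abs(incl.sum() - half) else incl
    return chosen.astype(np.int64)


# ---------------------------------------------------------------------------
# specs and truth bookkeeping


@dataclass
class LabelSimSpec:
    """Design of an additive phenotype.

    ``k_causal`` variants (default 5, all with weight 1.0) carry the signal;
    a fraction ``gvf`` of all variants act as noise variants whose per-variant
    weights are drawn once from Normal(``gm``, ``gs``).  ``gvf=None`` resolves
    to ``100 / n_variants`` at generation time, i.e. 100 noise variants.
    """

    k_causal: int = 5
    weights: Sequence[float] | None = None
    gm: float = 0.5
    gs: float = 0.5
    gvf: float | None = None
    seed: int | None = None

    def resolved_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.k_causal)
        w = np.asarray(self.weights, dtype=float)
        if w.size != self.k_causal:
            raise ValueError(
                f"{w.size} weights for k_causal={self.k_causal}"
            )
        return w

    def resolved_gvf(self, n_variants: int) -> float:
        gvf = 100.0 / n_variants if self.gvf is None else float(self.gvf)
        if not 0.0 <= gvf <= 1.0:
            raise ValueError(f"gvf must be in [0, 1], got {gvf}")
        return gvf

    def validate(self, n_variants: int) -> None:
        if self.k_causal < 1:
            raise ValueError("k_causal must be >= 1")
        if self.gs < 0:
            raise ValueError("gs must be >= 0")
        n_noise = round(self.resolved_gvf(n_variants) * n_variants)
        if self.k_causal + n_noise > n_variants:
            raise ValueError(
                f"k_causal={self.k_causal} plus {n_noise} noise variants "
                f"exceeds n_variants={n_variants}"
            )
        self.resolved_weights()


@dataclass
class EpistasisSpec:
    """Design of a polygenic-epistatic phenotype.

    ``counts_by_order`` maps interaction order n (1..5 in the standard
    designs) to the number of n-way truth-variables.  ``carrier_prob`` is the
    designed probability that a variant's dominance indicator ``[g >= 1]``
    equals 1; at 0.5 the parity of an n-way set (n >= 2) is marginally
    independent of every member.  ``noise_sd`` scales Gaussian liability
    noise added on top of the variable sum.
    """

    counts_by_order: Mapping[int, int]
    carrier_prob: float = 0.5
    noise_sd: float = 0.5
    weights: Mapping[int, float] | None = None
    seed: int | None = None

    def validate(self) -> None:
        for n, c in self.counts_by_order.items():
            if int(n) < 1:
                raise ValueError(f"interaction order must be >= 1, got {n}")
            if int(c) < 0:
                raise ValueError(f"negative count for order {n}")
        if not 0.0 < self.carrier_prob < 1.0:
            raise ValueError("carrier_prob must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class TruthVariable:
    """One driver of the phenotype: n member variants acting jointly."""

    order: int
    members: tuple  # global variant indices, sorted
    member_ids: tuple  # variant ids matching `members`
    weight: float = 1.0


@dataclass
class TruthSet:
    """The simulated drivers and the union of their member variants."""

    variables: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for var in self.variables:
            members = set(var.members)
            if len(members) != len(var.members):
                raise ValueError("repeated variant inside a truth-variable")
            if members & seen:
                raise ValueError("truth-variables must be pairwise disjoint")
            seen |= members

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def truth_variants(self) -> tuple:
        """Sorted global indices of all member variants."""
        out: set[int] = set()
        for var in self.variables:
            out.update(var.members)
        return tuple(sorted(out))

    @property
    def truth_variant_ids(self) -> tuple:
        pairs = sorted(
            (idx, vid)
            for var in self.variables
            for idx, vid in zip(var.members, var.member_ids)
        )
        return tuple(vid for _, vid in pairs)

    @property
    def n_truth_variants(self) -> int:
        return len(self.truth_variants)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "variables": [
                {
                    "order": v.order,
                    "members": list(v.members),
                    "member_ids": list(v.member_ids),
                    "weight": v.weight,
                }
                for v in self.variables
            ],
            "metadata": self.metadata,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TruthSet":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        doc = json.loads(text)
        variables = [
            TruthVariable(
                order=int(v["order"]),
                members=tuple(int(m) for m in v["members"]),
                member_ids=tuple(v["member_ids"]),
                weight=float(v.get("weight", 1.0)),
            )
            for v in doc["variables"]
        ]
        return cls(variables, metadata=doc.get("metadata", {}))


# ---------------------------------------------------------------------------
# generators


def gen_features(
    n_samples: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Simulate independent genotypes at random allele frequencies.

    Each variant draws an alternate-allele frequency uniformly from
    ``maf_range`` and genotypes are Binomial(2, freq) per sample,
    independently across variants.  A degenerate range like ``(0.3, 0.3)``
    fixes the frequency.
    """
    if n_samples < 1 or n_variants < 1:
        raise ValueError("n_samples and n_variants must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")
    rng = _rng(seed)
    freqs = rng.uniform(lo, hi, size=n_variants)
    values = rng.binomial(2, freqs, size=(n_samples, n_variants)).astype(np.int8)
    width_v = max(1, len(str(n_variants - 1)))
    width_s = max(1, len(str(n_samples - 1)))
    variant_ids = tuple(f"v{j:0{width_v}d}" for j in range(n_variants))
    sample_ids = tuple(f"s{i:0{width_s}d}" for i in range(n_samples))
    return GenotypeMatrix(np.asfortranarray(values), variant_ids, sample_ids)


def gen_label(
    matrix: GenotypeMatrix, spec: LabelSimSpec
) -> tuple[PhenotypeVector, TruthSet]:
    """Additive phenotype: weighted causal genotypes plus weighted noise variants.

    ``k_causal`` causal variants are drawn uniformly without replacement,
    then ``round(gvf * n_variants)`` noise variants from the remainder.  One
    weight per noise variant is drawn from Normal(gm, gs) — drawn once, not
    per sample, so noise variants carry weak but real association.  The
    liability is the weighted genotype sum and labels are thresholded at the
    liability median.  Only the causal variants enter the
    :class:`TruthSet` (as 1-way variables).
    """
    n_v = matrix.n_variants
    spec.validate(n_v)
    rng = _rng(spec.seed)
    weights = spec.resolved_weights()
    n_noise = round(spec.resolved_gvf(n_v) * n_v)

    causal = np.sort(rng.choice(n_v, size=spec.k_causal, replace=False))
    remainder = np.setdiff1d(np.arange(n_v), causal)
    noise = np.sort(rng.choice(remainder, size=n_noise, replace=False)) if n_noise else np.empty(0, dtype=int)
    noise_w = rng.normal(spec.gm, spec.gs, size=n_noise)

    g = matrix.values
    liability = g[:, causal].astype(float) @ weights
    if n_noise:
        liability = liability + g[:, noise].astype(float) @ noise_w
    labels = _median_dichotomize(liability)

    phenotype = PhenotypeVector(labels, ("control", "case"), sample_ids=matrix.sample_ids)
    variables = [
        TruthVariable(
            order=1,
            members=(int(c),),
            member_ids=(matrix.variant_ids[int(c)],),
            weight=float(w),
        )
        for c, w in zip(causal, weights)
    ]
    truth = TruthSet(
        variables,
        metadata={
            "model": "additive",
            "k_causal": spec.k_causal,
            "gm": spec.gm,
            "gs": spec.gs,
            "gvf": spec.resolved_gvf(n_v),
            "n_noise_variants": int(n_noise),
            "noise_variants": [int(i) for i in noise],
            "seed": spec.seed,
        },
    )
    return phenotype, truth


def gen_epistatic_label(
    matrix: GenotypeMatrix, spec: EpistasisSpec
) -> tuple[PhenotypeVector, TruthSet]:
    """Polygenic-epistatic phenotype from parity-of-dominance truth-variables.

    Disjoint member sets are sampled for every variable; the value of a
    variable is the parity (XOR) of its members' dominance indicators
    ``[g >= 1]`` (a 1-way variable reduces to the indicator itself).  The
    liability is the weighted variable sum plus Normal(0, noise_sd) noise,
    dichotomized at the median.
    """
    spec.validate()
    n_v = matrix.n_variants
    orders = sorted(int(n) for n in spec.counts_by_order)
    total_members = sum(int(n) * int(spec.counts_by_order[n]) for n in orders)
    if total_members > n_v:
        raise ValueError(
            f"spec needs {total_members} distinct variants but only {n_v} exist"
        )
    rng = _rng(spec.seed)
    pool = rng.permutation(n_v)
    cursor = 0
    variables: list[TruthVariable] = []
    for n in orders:
        weight = 1.0 if spec.weights is None else float(spec.weights.get(n, 1.0))
        for _ in range(int(spec.counts_by_order[n])):
            members = tuple(sorted(int(i) for i in pool[cursor : cursor + n]))
            cursor += n
            variables.append(
                TruthVariable(
                    order=n,
                    members=members,
                    member_ids=tuple(matrix.variant_ids[m] for m in members),
                    weight=weight,
                )
            )

    dominance = matrix.values >= 1
    liability = np.zeros(matrix.n_samples)
    for var in variables:
        parity = dominance[:, list(var.members)].sum(axis=1) % 2
        liability += var.weight * parity
    if spec.noise_sd > 0:
        liability = liability + rng.normal(0.0, spec.noise_sd, size=matrix.n_samples)
    labels = _median_dichotomize(liability)

    phenotype = PhenotypeVector(labels, ("control", "case"), sample_ids=matrix.sample_ids)
    truth = TruthSet(
        variables,
        metadata={
            "model": "parity-epistasis",
            "counts_by_order": {str(n): int(spec.counts_by_order[n]) for n in orders},
            "carrier_prob": spec.carrier_prob,
            "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    )
    return phenotype, truth


def truth_counts(spec: EpistasisSpec) -> tuple[int, int]:
    """Totals implied by a design: (truth-variables, truth-variants)."""
    spec.validate()
    n_variables = sum(int(c) for c in spec.counts_by_order.values())
    n_variants = sum(int(n) * int(c) for n, c in spec.counts_by_order.items())
    return n_variables, n_variants


def maf_for_carrier_prob(carrier_prob: float) -> float:
    """Allele frequency at which P(genotype >= 1) equals ``carrier_prob``.

    For Hardy-Weinberg genotypes Binomial(2, f): P(g >= 1) = 1 - (1-f)^2.
    """
    if not 0.0 < carrier_prob < 1.0:
        raise ValueError("carrier_prob must be in (0, 1)")
    return 1.0 - float(np.sqrt(1.0 - carrier_prob))


def simulate_epistatic_dataset(
    n_samples: int,
    n_variants: int,
    spec: EpistasisSpec,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, PhenotypeVector, TruthSet]:
    """Genotypes plus an epistatic phenotype in one call.

    Genotypes are drawn at the fixed allele frequency that realises the
    spec's ``carrier_prob``, so the parity-nullity property holds for the
    generated data.  ``seed`` overrides ``spec.seed`` when given.
    """
    master = np.random.SeedSequence(spec.seed if seed is None else seed)
    geno_ss, label_ss = master.spawn(2)
    maf = maf_for_carrier_prob(spec.carrier_prob)
    matrix = gen_features(
        n_samples, n_variants, maf_range=(maf, maf), seed=np.random.default_rng(geno_ss)
    )
    label_spec = EpistasisSpec(
        counts_by_order=spec.counts_by_order,
        carrier_prob=spec.carrier_prob,
        noise_sd=spec.noise_sd,
        weights=spec.weights,
        seed=None,
    )
    # route the label stream through the spec's validate/sampling path
    rng = np.random.default_rng(label_ss)
    return (matrix,) + _gen_epistatic_with_rng(matrix, label_spec, rng)


def _gen_epistatic_with_rng(matrix, spec, rng):
    spec = EpistasisSpec(
        counts_by_order=spec.counts_by_order,
        carrier_prob=spec.carrier_prob,
        noise_sd=spec.noise_sd,
        weights=spec.weights,
        seed=rng,
    )
    return gen_epistatic_label(matrix, spec)
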