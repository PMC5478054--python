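"""Synthetic data with known ground truth for every pipeline stage.

Three generators mirror the three kinds of experimental input:

* mating trials — each replicate of a two-strain choice test draws its four
  mating counts from a multinomial over a 4-class propensity vector
  (p11, p12, p21, p22).  The trial conditions this emulates are chambers of
  five pairs per strain observed until n matings are scored, so the model
  conditions on the total count rather than simulating latencies.  Under
  this model E[I] = p11 + p22 - p12 - p21 and Var(I) = (1 - E[I]^2)/n
  exactly, which is what makes the generator useful for validating the
  sqrt((1 - I^2)/n) standard error.
* crosses — offspring sex is binomial(n_offspring, prop_female); each
  dissected F1 male independently lacks motile sperm with probability
  sterility_p.
* alignments — a random ancestral sequence evolves along a user-specified
  group tree; each branch places its requested number of substitutions at
  sites drawn without replacement from a global pool (infinite-sites at this
  scale), so realized Hamming distances equal the sums of branch lengths
  exactly and network-recovery checks can be exact.  Within-group
  polymorphism defaults to zero and can be requested per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AlignmentRecord,
    AlignmentSet,
    CrossRecord,
    MatingTrialRow,
    MatingTrialTable,
    ValidationError,
)

__all__ = [
    "MatingModel",
    "CrossModel",
    "SequenceModel",
    "simulate_mating_trials",
    "simulate_cross",
    "simulate_alignment",
]

_ROOT = "root"
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class MatingModel:
    """Multinomial model of one two-strain choice test."""

    p11: float
    p12: float
    p21: float
    p22: float
    n_matings: int
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (self.p11, self.p12, self.p21, self.p22)
        if any(p < 0 for p in probs):
            raise ValidationError("mating propensities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValidationError("mating propensities must sum to 1")
        if self.n_matings <= 0 or self.replicates <= 0:
            raise ValidationError("n_matings and replicates must be positive")

    @property
    def expected_joint_index(self) -> float:
        return self.p11 + self.p22 - self.p12 - self.p21


@dataclass(frozen=True)
class CrossModel:
    """Binomial model of one directed cross."""

    prop_female: float
    sterility_p: float
    n_offspring: int
    n_dissected: int
    seed: int = 0
    mother: str = "A"
    father: str = "B"

    def __post_init__(self) -> None:
        for name in ("prop_female", "sterility_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        if self.n_offspring <= 0:
            raise ValidationError("n_offspring must be positive")
        if self.n_dissected < 0:
            raise ValidationError("n_dissected must be non-negative")


@dataclass(frozen=True)
class SequenceModel:
    """Group tree with fixed per-branch substitution counts.

    ``groups`` lists (label, n_individuals); ``tree`` lists branches
    (parent_label, child_label, substitutions) where the parent is another
    group label or ``"root"`` for the ancestral sequence.  Groups absent from
    the tree sit at the root.  ``within_group`` optionally maps a group label
    to a per-individual substitution count.
    """

    groups: tuple[tuple[str, int], ...]
    tree: tuple[tuple[str, str, int], ...]
    length: int
    seed: int = 0
    within_group: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValidationError("alignment length must be positive")
        total = sum(s for _, _, s in self.tree)
        total += sum(
            n * self.within_group.get(g, 0) for g, n in self.groups
        )
        if total > self.length:
            raise ValidationError(
                f"requested {total} substitution sites exceed length {self.length}"
            )
        labels = [g for g, _ in self.groups]
        if len(labels) != len(set(labels)):
            raise ValidationError("duplicate group labels")
        for parent, child, steps in self.tree:
            if child not in labels:
                raise ValidationError(f"tree child {child!r} is not a group")
            if steps < 0:
                raise ValidationError("branch substitutions must be >= 0")


def simulate_mating_trials(model: MatingModel) -> MatingTrialTable:
    """Draw one mating-trial table row per replicate, reproducibly."""
    rng = np.random.default_rng(model.seed)
    p = [model.p11, model.p12, model.p21, model.p22]
    rows = []
    for rep in range(1, model.replicates + 1):
        n11, n12, n21, n22 = (int(x) for x in rng.multinomial(model.n_matings, p))
        rows.append(
            MatingTrialRow(
                strain_a=f"A{rep}", strain_b=f"B{rep}",
                n11=n11, n12=n12, n21=n21, n22=n22,
            )
        )
    return MatingTrialTable(rows)


def simulate_cross(model: CrossModel) -> CrossRecord:
    """Draw one cross record, reproducibly."""
    rng = np.random.default_rng(model.seed)
    females = int(rng.binomial(model.n_offspring, model.prop_female))
    males = model.n_offspring - females
    motile = int(rng.binomial(model.n_dissected, 1.0 - model.sterility_p))
    return CrossRecord(
        mother=model.mother, father=model.father, replicates=1,
        females=females, males=males,
        males_dissected=model.n_dissected, males_motile=motile,
    )


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for site in sites:
        current = out[site]
        choices = _BASES[_BASES != current]
        out[site] = rng.choice(choices)
    return out


def simulate_alignment(model: SequenceModel) -> AlignmentSet:
    """Evolve group consensus sequences along the model tree and emit copies.

    All substitution sites (between- and within-group) are drawn without
    replacement from one global site pool, so no site mutates twice and
    pairwise Hamming distances equal path sums in the tree exactly.
    """
    rng = np.random.default_rng(model.seed)
    ancestral = rng.choice(_BASES, size=model.length)
    pool = list(rng.permutation(model.length))

    def take(k: int) -> np.ndarray:
        sites = np.array([pool.pop() for _ in range(k)], dtype=int)
        return sites

    consensus: dict[str, np.ndarray] = {_ROOT: ancestral}
    pending = list(model.tree)
    while pending:
        progressed = False
        for branch in list(pending):
            parent, child, steps = branch
            if parent in consensus:
                consensus[child] = _mutate(consensus[parent], take(steps), rng)
                pending.remove(branch)
                progressed = True
        if not progressed:
            missing = sorted({p for p, _, _ in pending})
            raise ValidationError(
                f"tree parents never resolved: {missing} (cycle or typo?)"
            )
    records = []
    for group, n_individuals in model.groups:
        base = consensus.get(group, ancestral)
        poly = model.within_group.get(group, 0)
        for i in range(1, n_individuals + 1):
            seq = _mutate(base, take(poly), rng) if poly else base
            records.append(
                AlignmentRecord(
                    id=f"{group}_{i}", group=group,
                    sequence=seq.tobytes().decode("ascii"),
                )
            )
    return AlignmentSet(records=records, length=model.length)
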