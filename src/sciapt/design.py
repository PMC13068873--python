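"""Greedy ABB selection, candidate enumeration, categorization and ranking.

The designer walks the screening orders of a target-aptamer lattice one at a
time.  At order 0 each of the five nucleotides is scored against the target
on the fine-grained pair lattice; at every later order i the prefix chosen
so far is extended by each candidate nucleotide on the coarse-grained chain
lattice and scored at order i.  At each order every nucleotide whose
log-energy ties the minimum (within a relative tolerance) is kept, so the
result is a matrix of per-order candidate sets rather than a single
sequence.  Enumerating the matrix, dropping T/U hybrids if asked, yields the
candidate aptamers, which are then categorized (universal / DNA / RNA /
hybrid), measured, and ranked by energy per unit length within category.

A calibration mode accepts an externally supplied candidate matrix (e.g. a
published one), so the combinatorial stages can be exercised and
regression-tested independently of the energy model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .charge_models import BiomoleculeChargeModel, ModelRegistry
from .geometry import (
    AptamerSequence,
    LengthModel,
    aptamer_length,
    build_chain_lattice,
    build_pair_lattice,
)
from .sci_energy import (
    ScreeningParams,
    energy_profile,
    transition_extremes,
)

__all__ = [
    "CandidateMatrix",
    "AptamerCandidate",
    "select_abbs_at_order",
    "greedy_design",
    "enumerate_candidates",
    "categorize",
    "shell_capacity",
    "rank_by_energy_per_length",
    "nucleic_specificity_onset",
    "pair_score",
    "chain_order_score",
    "score_candidate",
]

CATEGORIES = ("universal", "dna", "rna", "hybrid")


@dataclass(frozen=True)
class CandidateMatrix:
    """Per-order candidate nucleotide sets; index = SCI order."""

    per_order: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if not self.per_order:
            raise ValueError("candidate matrix must have at least one order")
        for i, opts in enumerate(self.per_order):
            if not opts:
                raise ValueError(f"order {i}: candidate set is empty")

    @property
    def n_orders(self) -> int:
        return len(self.per_order)

    def product_size(self) -> int:
        return math.prod(len(s) for s in self.per_order)


@dataclass(frozen=True)
class AptamerCandidate:
    """An enumerated aptamer with its category, length and energy score."""

    seq: AptamerSequence
    category: str
    length_nm: float
    total_log_energy: float

    @property
    def score(self) -> float:
        """Summed log-energy per nm of aptamer; ranking compares |score|."""
        return self.total_log_energy / self.length_nm


def select_abbs_at_order(
    energies: Mapping[str, float],
    tie_tol: float = 0.01,
    alphabet: Sequence[str] = ("A", "G", "C", "T", "U"),
) -> tuple[str, ...]:
    """All ABBs whose log-energy lies within ``tie_tol`` (relative) of the minimum.

    Returned in alphabet order so downstream choices are deterministic.  A
    zero minimum falls back to an absolute comparison at ``tie_tol``.
    """
    if not energies:
        raise ValueError("empty energy mapping")
    if tie_tol < 0:
        raise ValueError("tie_tol must be >= 0")
    vals = {a: energies[a] for a in alphabet if a in energies}
    if not vals:
        raise ValueError("energies cover none of the alphabet")
    m = min(vals.values())
    denom = abs(m) if m != 0 else 1.0
    return tuple(a for a in alphabet if a in vals and (vals[a] - m) / denom <= tie_tol)


def pair_score(
    target: BiomoleculeChargeModel,
    abb: BiomoleculeChargeModel,
    sp: ScreeningParams,
    lm: LengthModel | None = None,
    scale_grid=None,
    gap: float | None = None,
) -> float:
    """Order-0 selection score: summed log G_I over the pair lattice's
    target-ABB orders (intra-target orders are skipped — the target-ABB
    interaction only switches on once the origin charge reaches the
    partner's sites)."""
    lat = build_pair_lattice(target, abb, lm=lm, gap=gap)
    total = 0.0
    for order in lat.partner_orders():
        ext = transition_extremes(energy_profile(lat, order, sp, scale_grid))
        total += ext.log_dg
    return total


def chain_order_score(
    target: BiomoleculeChargeModel,
    prefix: Sequence[str],
    abb: str,
    registry: ModelRegistry,
    sp: ScreeningParams,
    lm: LengthModel | None = None,
    scale_grid=None,
    gap: float | None = None,
) -> float:
    """log G_I of the chain lattice prefix + abb at order len(prefix)."""
    seq = AptamerSequence(tuple(prefix) + (abb,))
    lat = build_chain_lattice(target, seq, registry, lm=lm, gap=gap)
    order = len(prefix)
    ext = transition_extremes(energy_profile(lat, order, sp, scale_grid))
    return ext.log_dg


def greedy_design(
    target: BiomoleculeChargeModel,
    n: int,
    registry: ModelRegistry,
    sp: ScreeningParams | None = None,
    lm: LengthModel | None = None,
    tie_tol: float = 0.01,
    scale_grid=None,
    gap: float | None = None,
) -> CandidateMatrix:
    """Greedy per-order candidate selection for an ``n``-ABB aptamer.

    Order 0 scores every nucleotide on the fine-grained pair lattice; each
    later order extends a representative prefix (the alphabet-first
    candidate at every earlier order) with each nucleotide on the
    coarse-grained chain lattice.  Ties within ``tie_tol`` are all kept.
    Fully deterministic.
    """
    if n < 1:
        raise ValueError("aptamer length n must be >= 1")
    sp = sp or ScreeningParams()
    lm = lm or LengthModel()
    alphabet = registry.alphabet

    per_order: list[tuple[str, ...]] = []
    scores0 = {
        a: pair_score(target, registry[a], sp, lm=lm, scale_grid=scale_grid, gap=gap)
        for a in alphabet
    }
    per_order.append(select_abbs_at_order(scores0, tie_tol, alphabet))

    for i in range(1, n):
        prefix = [opts[0] for opts in per_order]  # alphabet-first representative
        scores = {
            a: chain_order_score(
                target, prefix, a, registry, sp, lm=lm, scale_grid=scale_grid, gap=gap
            )
            for a in alphabet
        }
        per_order.append(select_abbs_at_order(scores, tie_tol, alphabet))

    return CandidateMatrix(per_order=tuple(per_order))


def _is_hybrid(symbols: Iterable[str]) -> bool:
    s = set(symbols)
    return "T" in s and "U" in s


def enumerate_candidates(
    matrix: CandidateMatrix,
    exclude_hybrids: bool = True,
    alphabet: Sequence[str] = ("A", "G", "C", "T", "U"),
) -> list[AptamerSequence]:
    """Cartesian product of the per-order candidate sets.

    Sequences come out in lexicographic order of alphabet indices; with
    ``exclude_hybrids`` any sequence containing both T and U is dropped.
    """
    rank = {a: k for k, a in enumerate(alphabet)}
    ordered = [sorted(opts, key=lambda a: rank[a]) for opts in matrix.per_order]
    out = []
    for combo in itertools.product(*ordered):
        if exclude_hybrids and _is_hybrid(combo):
            continue
        out.append(AptamerSequence(tuple(combo)))
    return out


def categorize(seq: AptamerSequence) -> str:
    """universal (no T/U), dna (T only), rna (U only), hybrid (both)."""
    has_t = "T" in seq.symbols
    has_u = "U" in seq.symbols
    if has_t and has_u:
        return "hybrid"
    if has_t:
        return "dna"
    if has_u:
        return "rna"
    return "universal"


def shell_capacity(order: int) -> int:
    """Number of ABB assignments the shell model accommodates at ``order``.

    With a five-letter alphabet, shell i holds 5**(i+1) assignments
    (5, 25, 125, ... for orders 0, 1, 2, ...).
    """
    if order < 0:
        raise ValueError("order must be non-negative")
    return 5 ** (order + 1)


def score_candidate(
    seq: AptamerSequence,
    target: BiomoleculeChargeModel,
    registry: ModelRegistry,
    sp: ScreeningParams | None = None,
    lm: LengthModel | None = None,
    scale_grid=None,
    gap: float | None = None,
) -> AptamerCandidate:
    """Measure a sequence: category, length, and summed chain log-energy.

    The total log-energy sums log G_I over all screening orders of the
    full-sequence chain lattice (order i = target vs. nucleotide i+1).
    """
    sp = sp or ScreeningParams()
    lm = lm or LengthModel()
    lat = build_chain_lattice(target, seq, registry, lm=lm, gap=gap)
    total = 0.0
    for order in range(len(seq)):
        ext = transition_extremes(energy_profile(lat, order, sp, scale_grid))
        total += ext.log_dg
    return AptamerCandidate(
        seq=seq,
        category=categorize(seq),
        length_nm=aptamer_length(seq, lm),
        total_log_energy=total,
    )


def rank_by_energy_per_length(
    cands: Sequence[AptamerCandidate],
    tie_tol: float = 0.01,
) -> dict[str, list[AptamerCandidate]]:
    """Per-category minima of |energy per length|.

    Within each category present, keeps every candidate whose |score| is
    within ``tie_tol`` (relative) of the category minimum; the union across
    categories is the finalized set.
    """
    if not cands:
        raise ValueError("no candidates to rank")
    for c in cands:
        if c.length_nm <= 0:
            raise ValueError(f"{c.seq}: non-positive length")
    out: dict[str, list[AptamerCandidate]] = {}
    for cat in CATEGORIES:
        members = [c for c in cands if c.category == cat]
        if not members:
            continue
        best = min(abs(c.score) for c in members)
        denom = best if best > 0 else 1.0
        out[cat] = [c for c in members if (abs(c.score) - best) / denom <= tie_tol]
    return out


def nucleic_specificity_onset(seqs: Sequence[AptamerSequence]) -> int | None:
    """Smallest 0-based position (= SCI order) where any sequence has T or U.

    Returns None when no position is nucleic-acid-type specific.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs[0])
    if any(len(s) != n for s in seqs):
        raise ValueError("sequences must have equal length")
    for pos in range(n):
        if any(s.symbols[pos] in ("T", "U") for s in seqs):
            return pos
    return None
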