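"""1D charge lattices and the aptamer length model.

Short aptamers are treated as rigid 1D rods of nucleotides.  Each purine
(A, G) contributes an axial size ``a_Pu`` (default 0.34 nm, the B-DNA axial
rise) and each pyrimidine (C, T, U) an axial size ``a_Py`` (default 0.30 nm),
so an aptamer of n_Pu purines and n_Py pyrimidines has length

    l_Apt = n_Pu * a_Pu + n_Py * a_Py.

Two lattice granularities are built here:

* a fine-grained *pair* lattice, laying out every functional charge of the
  target followed by every charge of a single nucleotide — the geometry for
  the direct (0th-order) target-ABB interaction, where the leftmost target
  charge interacts with each subsequent charge at successive screening
  orders; and
* a coarse-grained *chain* lattice, with one net-charge site for the target
  and one per nucleotide of the aptamer, each nucleotide carrying its
  functional-charge count as a screening multiplicity.

Coordinates are continuous nanometres on a half-line starting at the
target's first charge; site index j interacts with the origin at screening
order j - 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charge_models import (
    BiomoleculeChargeModel,
    nucleotide_class,
)

__all__ = [
    "LengthModel",
    "Lattice1D",
    "AptamerSequence",
    "aptamer_length",
    "build_pair_lattice",
    "build_chain_lattice",
]


@dataclass(frozen=True)
class LengthModel:
    """Axial sizes of the two nucleotide classes, in nm."""

    a_Pu: float = 0.34
    a_Py: float = 0.30

    def __post_init__(self) -> None:
        if self.a_Pu <= 0 or self.a_Py <= 0:
            raise ValueError("axial sizes must be positive")
        if self.a_Py > self.a_Pu:
            raise ValueError("a_Py must not exceed a_Pu")

    def size_of(self, symbol: str) -> float:
        return self.a_Pu if nucleotide_class(symbol) == "purine" else self.a_Py


@dataclass(frozen=True)
class AptamerSequence:
    """An ordered nucleotide sequence over the five-letter alphabet."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("aptamer sequence must be non-empty")
        for s in self.symbols:
            nucleotide_class(s)  # raises KeyError on unknown symbols

    @classmethod
    def from_string(cls, s: str) -> "AptamerSequence":
        return cls(tuple(s.upper()))

    def __str__(self) -> str:
        return "".join(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_Pu(self) -> int:
        return sum(1 for s in self.symbols if nucleotide_class(s) == "purine")

    @property
    def n_Py(self) -> int:
        return sum(1 for s in self.symbols if nucleotide_class(s) == "pyrimidine")

    @property
    def n_ABB(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class Lattice1D:
    """Ordered point charges on a line.

    ``positions`` are strictly increasing coordinates in nm with the
    reference (target) charge at index 0; ``charges`` are in e.  The site at
    index j interacts with the origin at screening order j - 1, so the
    highest order probed is ``len(positions) - 2``.  ``multiplicities``
    scale each site's screening weight (used by the coarse-grained chain
    lattice, where one site stands in for several functional charges).
    ``partner_start`` is the index of the first site belonging to the
    interaction partner (None for single-molecule or coarse lattices).
    """

    positions: tuple[float, ...]
    charges: tuple[float, ...]
    labels: tuple[str, ...]
    multiplicities: tuple[int, ...] = field(default=())
    partner_start: int | None = None

    def __post_init__(self) -> None:
        n = len(self.positions)
        if n < 2:
            raise ValueError("lattice requires at least 2 sites")
        if len(self.charges) != n or len(self.labels) != n:
            raise ValueError("positions, charges and labels must have equal length")
        if not self.multiplicities:
            object.__setattr__(self, "multiplicities", (1,) * n)
        elif len(self.multiplicities) != n:
            raise ValueError("multiplicities length mismatch")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def max_order(self) -> int:
        return self.n_sites - 2

    def order_of_index(self, j: int) -> int:
        """Screening order at which site j interacts with the origin."""
        if not 1 <= j < self.n_sites:
            raise IndexError(f"site index {j} out of range 1..{self.n_sites - 1}")
        return j - 1

    def partner_orders(self) -> range:
        """Orders at which the origin interacts with partner (not own) sites."""
        if self.partner_start is None:
            return range(0, self.max_order + 1)
        return range(self.partner_start - 1, self.max_order + 1)

    def scaled(self, factor: float) -> "Lattice1D":
        """Return the lattice with all coordinates multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return Lattice1D(
            positions=tuple(p * factor for p in self.positions),
            charges=self.charges,
            labels=self.labels,
            multiplicities=self.multiplicities,
            partner_start=self.partner_start,
        )

    def to_table(self) -> str:
        """Columnar text dump (position_nm, charge_e, label, sci_order)."""
        lines = ["position_nm\tcharge_e\tlabel\tsci_order"]
        for j, (p, q, lab) in enumerate(zip(self.positions, self.charges, self.labels)):
            order = "-" if j == 0 else str(j - 1)
            lines.append(f"{p:.6f}\t{q:+.3f}\t{lab}\t{order}")
        return "\n".join(lines) + "\n"


def aptamer_length(seq: AptamerSequence, lm: LengthModel | None = None) -> float:
    """Aptamer length l_Apt = n_Pu * a_Pu + n_Py * a_Py, in nm."""
    lm = lm or LengthModel()
    return seq.n_Pu * lm.a_Pu + seq.n_Py * lm.a_Py


def _site_positions(n: int, span: float, start: float) -> list[float]:
    # n sites spread evenly across the molecule's axial extent; a lone site
    # sits at the segment midpoint
    if n == 1:
        return [start + span / 2.0]
    return list(start + np.linspace(0.0, span, n))


def _oriented_sites(model: BiomoleculeChargeModel, phosphate: str):
    """Order sites so the backbone phosphate faces the interaction partner.

    ``phosphate`` is "last" for the target (partner on its right) or "first"
    for the nucleotide (partner on its left).  The listed order is reversed
    when that moves the PO4 site to the required end; a model without a PO4
    site keeps its listed order.
    """
    sites = list(model.sites)
    idx = next((k for k, s in enumerate(sites) if s.label.upper().startswith("PO4")), None)
    if idx is None:
        return sites
    want = len(sites) - 1 if phosphate == "last" else 0
    if idx == want:
        return sites
    mirrored = list(reversed(sites))
    if next(k for k, s in enumerate(mirrored) if s.label.upper().startswith("PO4")) == want:
        return mirrored
    site = sites.pop(idx)
    sites.insert(want, site)
    return sites


def build_pair_lattice(
    target: BiomoleculeChargeModel,
    abb: BiomoleculeChargeModel,
    lm: LengthModel | None = None,
    gap: float | None = None,
    orient_phosphate_inward: bool = True,
) -> Lattice1D:
    """Fine-grained lattice of every charge in a target-nucleotide pair.

    The target's sites are spread evenly over its axial extent starting at
    the origin, followed after ``gap`` nm by the nucleotide's sites spread
    over its class axial size.  ``gap`` defaults to the mean of the two
    molecules' internal site spacings, keeping the lattice-constant scale
    homogeneous across the complex.
    """
    lm = lm or LengthModel()
    if abb.mol_class not in ("purine", "pyrimidine"):
        raise ValueError(f"{abb.name}: pair partner must be a nucleotide model")
    abb_span = lm.a_Pu if abb.mol_class == "purine" else lm.a_Py

    t_sites = _oriented_sites(target, "last") if orient_phosphate_inward else list(target.sites)
    a_sites = _oriented_sites(abb, "first") if orient_phosphate_inward else list(abb.sites)

    t_spacing = target.axial_size / max(len(t_sites) - 1, 1)
    a_spacing = abb_span / max(len(a_sites) - 1, 1)
    if gap is None:
        gap = 0.5 * (t_spacing + a_spacing)
    if gap <= 0:
        raise ValueError("gap must be positive")

    t_pos = _site_positions(len(t_sites), target.axial_size, 0.0) if len(t_sites) > 1 else [0.0]
    a_start = t_pos[-1] + gap
    a_pos = list(a_start + np.linspace(0.0, abb_span, len(a_sites))) if len(a_sites) > 1 else [a_start]

    return Lattice1D(
        positions=tuple(t_pos + a_pos),
        charges=tuple(s.charge for s in t_sites) + tuple(s.charge for s in a_sites),
        labels=tuple(f"{target.name}:{s.label}" for s in t_sites)
        + tuple(f"{abb.name}:{s.label}" for s in a_sites),
        partner_start=len(t_sites),
    )


def build_chain_lattice(
    target: BiomoleculeChargeModel,
    seq: AptamerSequence,
    registry,
    lm: LengthModel | None = None,
    gap: float | None = None,
) -> Lattice1D:
    """Coarse-grained lattice of the target facing a chain of nucleotides.

    The target is collapsed to a single site of its net charge at the
    origin.  Nucleotide k sits at the midpoint of its axial segment, i.e. at
    gap + (sum of preceding axial sizes) + a_k / 2, carries its net charge
    (-1 e) and a screening multiplicity equal to its functional-charge
    count.  Site k (1-based) interacts with the target at screening order
    k - 1.  ``gap`` defaults to the mean of the target's axial extent and
    the first nucleotide's axial size, halved — i.e. half the sum of the two
    flanking half-widths.
    """
    lm = lm or LengthModel()
    first_size = lm.size_of(seq.symbols[0])
    if gap is None:
        gap = 0.5 * (target.axial_size / 2.0 + first_size / 2.0)
    if gap <= 0:
        raise ValueError("gap must be positive")

    positions = [0.0]
    charges = [target.net_charge]
    labels = [f"{target.name}:net"]
    mults = [1]
    cursor = gap
    for k, sym in enumerate(seq.symbols, start=1):
        model = registry[sym]
        size = lm.size_of(sym)
        positions.append(cursor + size / 2.0)
        charges.append(model.net_charge)
        labels.append(f"{sym}[{k}]")
        mults.append(model.n_sites)
        cursor += size

    return Lattice1D(
        positions=tuple(positions),
        charges=tuple(charges),
        labels=tuple(labels),
        multiplicities=tuple(mults),
        partner_start=1,
    )
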