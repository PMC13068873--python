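# Methods

## Model

The package designs short single-stranded aptamers by electrostatics alone.
Both the target lipid and the nucleotides are reduced to *functional charge
sites*: ionized groups carrying a full ±1 e (the backbone phosphate PO₄⁻,
the amine NH₃⁺, the carboxylate CO₂⁻) and polarized H/N/O atoms carrying a
partial charge of magnitude δ. The packaged models give phosphatidylserine
three sites (PO₄⁻, NH₃⁺, CO₂⁻; net −1 e) and split the nucleotides into two
charge-distribution classes: G and C carry four functional charges, A, T
and U three. T and U are electrostatically identical in this description
(same site multiset, same axial size), which is what ultimately makes DNA
and RNA variants of a design interchangeable until a type-specific position
appears.

Because the aptamers of interest are short (≤ 10 nucleotides), the complex
is modeled as a 1D rod: charges on a line, the target's charges first, the
aptamer's after a gap. The reference (leftmost) charge interacts with the
(i+1)-th subsequent charge at *screening order i*. Order 0 is the direct
pair interaction attenuated only by the solvent; each higher order is
further attenuated by the intervening charges. The adopted energy
functional is a Yukawa pair energy with an order-dependent effective
screening length:

    E_i = k_e q_0 q_{i+1} / (ε_r r) · exp(−r / λ_eff(i)),
    λ_eff(i) = λ_D / (1 + Σ_{j=1..i} |q_j| · m_j).

This is a *documented reconstruction*: it is consistent with the screened
Coulomb framework (it is the inverse Fourier transform of the
momentum-space propagator ∝ 1/(k² + λ_eff⁻²), verified numerically by
`fourier_oracle`), reduces to the bare Coulomb interaction as λ_D → ∞,
and attenuates monotonically with order. It is isolated behind
`sci_energy_at_order` so an alternative functional can be swapped in.
Because only relative energies enter selection, the absolute calibration
of E never matters.

Two lattice granularities are used. The *pair* lattice (target + one
nucleotide) resolves every functional charge, spreads each molecule's sites
evenly over its axial extent, and orients both molecules so their backbone
phosphates face each other; with a 3-site target the target-nucleotide
interaction only switches on at order 2 (orders 0–1 are internal to the
target). The *chain* lattice (target + whole aptamer) collapses each
molecule to one site — the target at the origin with its net charge, each
nucleotide at its segment midpoint with its net charge and a screening
multiplicity m equal to its functional-charge count (4 for G/C, 3 for
A/T/U). The multiplicity is the only coarse-grained trace of the two charge
classes and is what differentiates prefixes during selection.

## Selection and finalization

Energies are swept over a lattice-constant scale factor (default 0.5–5.0,
181 points); each order's profile is summarized by the magnitudes at the
transition ends, G_I (high) and G_II (low). G_II is orders of magnitude
below G_I on all defaults (asserted in tests), so the selection score is
log₁₀ G_I ≈ log ΔG.

Greedy design keeps, at each order, every nucleotide within a relative tie
tolerance (default 1%) of the lowest score; later orders extend the
alphabet-first representative of each earlier tie. Order 0 is scored on the
pair lattice by summing log₁₀ G_I over the target-nucleotide orders; with
the packaged models G wins order 0 uniquely, because the purine's larger
axial span weakens its pair energies relative to the equally-charged C.
Enumerating the per-order sets in alphabet order gives the candidates;
sequences containing both T and U ("hybrids") are dropped by default (the
published PS candidate set contains none; the sibling
phosphatidylcholine study reports a hybrid category, so the rule is
exposed as a flag).

Each candidate is then scored on its full-sequence chain lattice: total
log-energy = Σ over orders of log₁₀ G_I, length by
l_Apt = n_Pu·a_Pu + n_Py·a_Py, and within each category (universal / DNA /
RNA / hybrid) the candidates with the lowest |total log-energy| / l_Apt are
finalized (ties kept). The magnitude is compared, not the signed ratio,
because the log aggregate's sign depends on the uncalibrated overall energy
scale; the convention reproduces the published direction — at equal totals
the longer aptamer wins, and the two all-purine-tail universal candidates
GGCGGCGAAG / GGCGGCGGAG tie best.

Calibration mode injects an externally supplied per-order matrix (the
published PS matrix ships as package data), so enumeration, categorization,
lengths, specificity onset and counts are exercised independently of the
reconstructed energy functional. The DNA/RNA per-category finalists under
the reconstruction form a 4-way tie that includes the published picks but
is not asserted to equal them: they depend on energy tables published only
as images.

## Defaults and parameters

| parameter | default | units | rationale |
|---|---|---|---|
| δ (partial charge) | 0.2 | e | typical polarized-site scale; never quantified by the source method, only relative energies matter |
| a_Pu | 0.34 | nm | B-DNA axial rise per base |
| a_Py | 0.30 | nm | judicious single-ring size, ≈ 0.9 a_Pu |
| PS headgroup span | 0.90 | nm | headgroup extent; configurable |
| ε_r | 80 | — | bulk water |
| λ_D | 1.0 | nm | ≈ 100 mM monovalent salt |
| sweep | 0.5–5.0 × spacing, 181 pts | — | brackets every transition on defaults |
| tie tolerance | 1% | relative on log G_I | ties are reported by the method without a stated tolerance |
| gap (pair) | mean of the two molecules' internal site spacings | nm | keeps one homogeneous lattice-constant scale |
| gap (chain) | mean of the two flanking half-widths | nm | same rationale, coarse scale |

All defaults are configurable through `RunConfig`, the charge-model YAML,
and CLI flags, and every value that affects a run is recorded in the output
manifest.

## Numerical choices

- Energies in eV (k_e = e²/4πε₀ = 1.43996 eV·nm) or k_BT at 298 K.
- Decadic logs of energy magnitudes; the raw sign is carried separately.
- The Fourier oracle integrates k sin(kr)/(k²+κ²) on [0, ∞) with
  oscillatory-tail quadrature (QAWF); it warns if its error estimate
  exceeds 0.1% of the value. It exists solely to certify the closed form.
- Zero-minimum tie selection falls back to an absolute tolerance; all-zero
  energy profiles raise rather than yield −∞ logs.
- No randomness anywhere: identical configurations give byte-identical
  CSV/FASTA/manifest outputs.

## What a green test establishes — and what it does not

The combinatorial layer (enumeration, categorization, shell capacities
5^(i+1), lengths, the order-7 specificity onset, the 13-candidate count) is
checked against published values exactly. The energy layer is checked for
its *properties* — Fourier/closed-form equivalence to 1%, monotone
attenuation with order, the unscreened Coulomb limit, linearity in the
terminal charges, determinism — not against the published per-order energy
tables, which exist only as images and rest on a supplementary derivation
and supplementary lattice constants that are not available. The per-order
greedy selections from the reconstructed functional therefore need not, and
beyond order 0 do not, reproduce the published matrix; that matrix is
exercised via calibration mode.

## Known limitations

- Strictly 1D and linear: no lateral contacts, no secondary/tertiary
  structure, no multi-lipid coverage by long aptamers.
- No quantum-chemistry charges, pH-dependent protonation, or van der Waals
  terms; temperature enters only through the energy unit.
- Even intra-molecular site spacing and the phosphate-inward orientation
  are least-assumption stand-ins for unpublished placement details.
- The energy functional is a reconstruction (see above); absolute binding
  free energies are out of scope by design.
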