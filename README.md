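# sciapt

Energy-based design of short nucleic-acid aptamers against charged membrane
lipids, built around screened Coulomb interaction (SCI) energetics on 1D
charge lattices. The packaged target is phosphatidylserine (PS), the
net-negative phospholipid externalized during apoptosis and a recognized
diagnostic/therapeutic target; any user-defined charge model can stand in
for it.

## The method

A drug-target complex is treated as a many-charge system. Each molecule is
reduced to its functional charge sites — full charges of ±1 e (PO₄⁻, NH₃⁺,
CO₂⁻) and partial charges of magnitude δ (default 0.2 e) on polarized
H/N/O sites. Laid out on a 1D axis, the reference charge of the target
interacts with the (i+1)-th subsequent charge at *SCI order i*: a
Debye-screened (Yukawa) pair energy whose effective screening length is
shortened by the i intervening charges,

    E_i = k_e q₀ q_{i+1} / (ε_r r) · exp(−r / λ_eff(i)),
    λ_eff(i) = λ_D / (1 + Σ_{j=1..i} |q_j| m_j),

with λ_D the solvent Debye length and m_j a site's screening multiplicity.
Sweeping a scale factor over the lattice spacings traces each order's
energy transition; its high extreme G_I (the low extreme G_II is
negligible) gives the selection score log₁₀ G_I ≈ log ΔG.

Design proceeds greedily over orders: at every order each of the five
nucleotides A, G, C, T, U is scored and all ties at the lowest log-energy
are kept, giving a per-order candidate matrix. Enumerating the matrix
(optionally dropping T/U hybrids) yields candidate aptamers, which are
categorized (universal / DNA / RNA / hybrid), measured via
l_Apt = n_Pu·0.34 nm + n_Py·0.30 nm, and finalized by the lowest
|summed log energy| per unit length within each category. A shell model
bounds the unpruned search space at 5^(i+1) assignments through order i.

## Worked example

Running the pipeline on the published 10-order PS candidate matrix
(calibration mode), with hybrid sequences excluded:

```
$ sciapt design --target PS --n 10 --calibration packaged:PS
candidate matrix (10 orders):
  order 0: G
  order 1: G
  order 2: C
  order 3: G
  order 4: G
  order 5: C
  order 6: G
  order 7: A/G/C/T/U
  order 8: A/T/U
  order 9: G
13 candidate sequences
best universal: GGCGGCGAAG, GGCGGCGGAG
best dna: GGCGGCGATG, GGCGGCGGTG, GGCGGCGTAG, GGCGGCGTTG
best rna: GGCGGCGAUG, GGCGGCGGUG, GGCGGCGUAG, GGCGGCGUUG
```

The matrix encodes 15 raw combinations; dropping the two sequences that mix
T and U leaves 13 candidates in three categories (3 universal, 5 DNA,
5 RNA). The two best universal aptamers, GGCGGCGAAG and GGCGGCGGAG, tie at
the lowest energy per length: their all-purine tails make them the longest
candidates (3.32 nm) at near-identical total log-energy. Type-specific
nucleotides (T or U) first appear at position 7 (0-based, = SCI order 7),
so nucleic-acid specificity requires designing beyond 8 nucleotides.

A fully ab-initio run (`sciapt design --target PS --n 10`, no calibration)
uses the reconstructed energy functional throughout; `sciapt shell
--order 2` prints the shell capacity (125), and `sciapt enumerate --matrix
packaged:PS` lists the 13 sequences.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the calibration-mode pipeline from scratch and reports the
hybrid-excluded candidate count, the order-2 shell capacity, and the
specificity-onset order, as a JSON object. The pipeline is deterministic;
the seed only fixes the interface.

## Layout

- `src/sciapt/charge_models.py` — functional-charge models, YAML registry
- `src/sciapt/geometry.py` — length model, pair and chain lattices
- `src/sciapt/sci_energy.py` — screened Coulomb energetics + Fourier oracle
- `src/sciapt/design.py` — selection, enumeration, categorization, ranking
- `src/sciapt/pipeline.py`, `src/sciapt/cli.py` — configuration, outputs, CLI
- `docs/methods.md` — model assumptions, defaults, and limitations
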