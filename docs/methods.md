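# Methods

## Model

A DNA sequence is represented as four "massive" point clouds on the Fermat
spiral, one per base. Position `i` (1-based) maps to polar angle
`θ = 2π(i−1)/(L−1)` and radius `ρ = √θ`; both are strictly increasing in
position, so the embedding is injective and order-preserving — the global
position information of the sequence survives the reduction. `L` is a
reference length shared across a comparison set; position `L` completes one
full turn and later positions continue outward (no wrapping).

Local information enters as a mass per point. The context of a nucleotide is
the window over positions (i−1, i, i+1, i+2); each slot scores 1 when it
carries the focal base, 0 otherwise (out-of-range slots score 0, so boundary
positions are massed rather than skipped). The focal slot always scores 1,
leaving eight patterns grouped into six situations by repeat count and then
compactness, massed 1/6 … 6/6:

| pattern(s) | mass |
|---|---|
| 0100 | 1/6 |
| 0101 | 2/6 |
| 1100, 0110 | 3/6 |
| 1101 | 4/6 |
| 1110, 0111 | 5/6 |
| 1111 | 1 |

Positions beyond `L` are restrained: by default `m′ = m·exp(−ε(i−L))` with
ε = 0.0375. The intent is asymmetric treatment of length differences — a long
tail sits at large radius but near-zero mass, so gross length differences
between distant species are suppressed while small differences between close
species still move the descriptor.

Each sub-curve is summarized by its normalized moment of inertia
`r = √(Σ mᵢdᵢ² / Σ mᵢ)` about its center of mass — the mass-weighted RMS
spread — giving the 4-vector `[r_A, r_C, r_G, r_T]`. Species are compared by
the Euclidean distance between these vectors; the matrix is optionally
rescaled so a chosen reference pair (conventionally Human–Gallus on the
β-globin benchmark) has unit distance, and clustered by average linkage
(UPGMA).

## Parameters

- **L** (integer ≥ 2, default `auto` = shortest sequence in the set; 86 on
  the β-globin benchmark). All descriptors in one comparison must share L —
  the transformer fixes it at `fit` and stamps it into every output.
- **ε** (≥ 0, default 0.0375): restraint scale. ε = 0 disables the restraint;
  very large ε converges to analysing only the first L positions.
- **restraint_variant** (`exp-decay` default, `linear-floor`, `none`): the
  available reference account of this representation records only ε, not the
  functional form of the restraint, so the form is a package-level choice.
  Exponential decay is the default because it is smooth, strictly positive
  (the normalization divides by total mass, which must stay > 0) and strictly
  decreasing beyond L. `linear-floor` (`max(m(1−ε(i−L)), 10⁻⁶)`) is the
  obvious alternative; `none` disables the restraint independently of ε. The
  variant used is recorded in every descriptor table, and
  `benchmark.screen_restraint_variants` compares all variants against
  reference descriptor values for a user-supplied sequence set.
- **com_variant** (`as-printed` default, `true-com`): the centroid as printed
  in the reference descriptor tables divides the mass-weighted coordinate
  sums by the point count N rather than by the total mass — not a physical
  center of mass. `as-printed` reproduces that convention exactly and is the
  default for comparability with published values; `true-com` divides by Σm
  and is the convention under which r is exactly invariant to uniform mass
  rescaling. Both are first-class and fingerprinted.

## Synthetic data

`generate_synthetic_set` draws one uniform-random ancestor, derives each
clade ancestor by independent per-site substitution at rate
`divergence_between` (uniform over the three alternative bases), and each
leaf from its clade ancestor at rate `divergence_within`. There are no
indels, so sequence length is exact and controlled — length is itself a
parameter of the method, and the generator deliberately isolates
substitution divergence from length variation. The default study conditions
(3 clades × 3 leaves, 90 nt, 0.02 within / 0.30 between) give a clear
within/between Hamming separation at the documented seed.

What passing tests on this generator show: the pipeline converts controlled
substitution divergence into descriptor distances that recover clade
structure under UPGMA. What they do not show: robustness to indels, length
heterogeneity beyond the restraint's reach, base-composition skew, or real
evolutionary rate variation — real-data performance is benchmarked only
through the bundled β-globin reference values.

## Numerical choices

- Moments are accumulated with numpy float64 sums; descriptor components are
  stable to point-order permutation below 1e-10 and serialized at full
  precision (reports round to 4 decimals).
- Comparisons against the bundled published values must account for their
  4-decimal printing: a Euclidean distance of two 4-dp-rounded 4-vectors can
  deviate from the distance of the unrounded vectors by up to
  2·√(4·(5·10⁻⁵)²) = 2·10⁻⁴, plus 5·10⁻⁵ half-ulp in the printed distance
  itself. The regression suite therefore checks entrywise agreement within
  2.5·10⁻⁴ (the recomputed matrix in fact agrees within 1.2·10⁻⁴).
- A base that never occurs in a sequence has an empty sub-curve; its
  descriptor component is defined as 0 (the continuous completion —
  single-point curves already give r = 0) with a logged warning, keeping
  vectors 4-D.
- Clustering uses scipy's agglomerative implementation; merge heights are
  cluster distances and the exported ultrametric tree places each merge at
  half its height. Tie-breaking among equal-distance candidates follows
  scipy's deterministic agglomeration order for a fixed input, so trees are
  reproducible; no additional index-order tie rule is imposed.
- FASTA validation is strict by default: silent removal of ambiguity codes
  would renumber positions and corrupt the embedding, so `skip-ambiguous` is
  an explicit opt-in that logs per-record removal counts.

## Limitations

- The exact restraint form and centroid convention behind the published
  benchmark descriptors cannot be confirmed without the original exon
  sequences, which users must supply (accessions are bundled, sequences are
  not). The published distance matrix and cluster statements, which depend
  only on the published descriptors, are reproduced unconditionally.
- Descriptors are 4 numbers per sequence: collisions are possible in
  principle (different sequences, same moments), so the method is a
  similarity heuristic, not a distance on sequence space.
- Single-strand only; no reverse-complement awareness, no RNA/protein
  alphabets, and no treatment of indels beyond the length restraint.
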