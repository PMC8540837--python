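# Methods

`peatmox` implements the computational chain used to study how
methane-oxidizing bacteria (MOB) in Arctic peat respond to CH₄
concentration and temperature: closed-bottle oxidation kinetics, absolute
pmoA transcript quantification, pmoA amplicon community filtering,
indicator-OTU permutation analysis, and distance-based phylogenetics. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic-data generators do and do not emulate.

## Gas mass balance and kinetics

A sealed serum bottle holds a headspace (volume `V_h = V_total − V_liq`,
mL) over soil or cell suspension. Headspace CH₄ is measured as a mixing
ratio x (ppm v/v). Amounts follow from:

- **Ideal gas (headspace):** `n_h = P · V_h · x·10⁻⁶ / (R·T)` with
  `R = 0.082057 L·atm·mol⁻¹·K⁻¹`, P in atm, T in Kelvin.
- **Henry's law (dissolved):** `C = k_H(T) · P · x·10⁻⁶` (mol L⁻¹), with a
  van 't Hoff temperature correction
  `k_H(T) = k_H,ref · exp(B · (1/T − 1/T_ref))`. Defaults:
  `k_H,ref = 1.4·10⁻³ mol·L⁻¹·atm⁻¹` at 298.15 K, `B = 1750 K` —
  mid-literature values for CH₄ in water; under a 0.1 % headspace they give
  2.0 µM dissolved CH₄ at 8 °C and 1.7 µM at 15 °C. Both constants are
  configurable (`HenryParams`).
- **Injection:** injecting volume v of a gas with CH₄ purity q into the
  bottle gives `x = 10⁶ · v·q / (V_h + v)` — ideal mixing into the
  expanded gas phase, overpressure ignored (pressure is taken as 1 atm
  throughout; the data carry no pressure information).

Oxidation is modelled as first order in CH₄: `C(t) = C₀·e^(−kt)`. The rate
constant is estimated by ordinary least squares of `ln x` on time
(natural log, intercept included); `k = −slope`, with the ordinary R² as
the fit diagnostic. Conventions: a zero-variance series reports `k = 0`,
`R² = 0`, and a degenerate-fit flag; negative slopes (net CH₄ production)
are reported as negative k with a warning rather than clamped, because
production can exceed oxidation in real incubations.

**Sampling corrections.** Each measurement withdraws `v_g` mL of headspace
(carrying `v_g/V_h` of the headspace CH₄ at uniform mixing) and `v_l` mL
of medium (carrying `v_l/V_liq` of the dissolved CH₄). The decline between
consecutive measurements net of these known removals is attributed to
oxidation, so the balance

    oxidized(t_i) + removed(t_i) + residual(t_i) = initial mass

holds exactly by construction, and the corrected ("oxidation-only") mass
series is the measured mass plus cumulative removals. The phase shares
used for removal accounting are constant per bottle because both phase
amounts are linear in the mixing ratio.

**Normalizations.** Rates convert to µg CH₄ g⁻¹ dry soil d⁻¹ via the CH₄
molar mass (16.04 g mol⁻¹), 24 h d⁻¹, and the gravimetric dry mass
`m_dry = m_fresh·(1 − w)`. Culture rates normalize to µmol per 10⁸ cells
per hour through a linear OD410→cell-count standard; predictions below
zero cells are clamped to 0 with a warning. Equal-dissolved-CH₄ rate
comparisons across temperatures use the mixing ratio scaled by
`k_H(T_ref)/k_H(T)` (≈1.16 from 8 to 15 °C with the defaults).

## qPCR quantification

The standard curve is OLS of mean Cq per level on log₁₀(copies) over a
dilution series (default range 7.15·10⁶ down to 7.15 copies per reaction,
seven decades). Replicates are averaged per level before fitting, so
replicated and pre-averaged inputs give identical curves. Amplification
efficiency is `E = 10^(−1/slope) − 1`; the ideal decadal slope
−log₂10 ≈ −3.3219 gives E = 1. A non-negative slope flags the curve
invalid. Quantification inverts the mean sample Cq,
`copies = 10^((Cq − intercept)/slope)`, multiplies by a single
user-supplied elution-and-dilution factor (the extraction-chain
conversion from reaction to gram of soil is not derivable from the assay
itself), and divides by dry mass. Results outside the standard's range are
returned but flagged extrapolated. No-template controls must be non-detect
or above a configurable Cq cutoff (default 35), else a contamination
warning is issued.

## Amplicon filtering and normalization

- **Quality window:** a read is discarded iff any sliding 50-nt window
  (step 1) has mean Phred < 20; reads shorter than 50 nt are judged on
  their full-length mean. The decision is strict (`< 20` discards, mean
  exactly 20 keeps).
- **Frame/stop screen:** pmoA is protein coding, so a correct
  primer-trimmed amplicon has length divisible by three (from the frame
  offset, default 0) and no in-frame stop codon (TAA/TAG/TGA, bacterial
  code). Codons containing ambiguity codes are not counted as stops.
- **Length windows** (dominant OTU sequence, inclusive): 465–474 nt for
  mb661R, 492–495 nt for A682R. Inclusive because both window edges are
  multiples of three and observed amplicon lengths.
- **Taxonomy:** global pairwise alignment (match 5, mismatch −4, gap open
  −10, extend −0.5) of the dominant sequence against every reference;
  highest score wins; percent identity is matches over alignment columns.
  Exact score ties keep the first database entry and set a tie flag.
- **Relative abundance:** per-sample row normalization; all-zero samples
  stay zero and are flagged.
- **Denoising:** within each sample, any OTU with relative abundance
  strictly below 10⁻³ is treated as absent (count zeroed); relative
  abundances are then recomputed on the survivors and the removed read
  fraction is reported. Denoising is idempotent unless renormalization
  pushes an entry across the threshold, which is logged.
- **Log transform (pre-ordination):** `x → log_b(x) + 1` for x > 0, 0 → 0,
  base 2 by default. The transform is applied to whatever matrix is
  supplied (counts or relative abundances — the choice is a logged config
  item); inputs below 1/b produce negative outputs, which triggers a
  warning rather than rescaling.

## Indicator-value analysis

For OTU i and group j (two groups: 0.1 % and 1 % CH₄ within one grazing
treatment; temperatures pooled, as composition shows no temperature
effect):

    A_ij = mean abundance of i in j / Σ_k mean abundance of i in k
    B_ij = fraction of group-j samples with i present (> 0)
    IndVal_ij = A_ij · B_ij

The per-OTU statistic is `max_j IndVal_ij`. Significance comes from
uniform random shuffles of the group labels (default 10,000), with the
+1-corrected estimate `p = (#{permuted ≥ observed} + 1)/(N + 1)`; the ≥
comparison and the +1 correction are the defaults (both switchable),
avoiding p = 0 and making p-values valid under ties. Fixed seeds give
bit-identical p-values; permutations are vectorized in batches.

OTUs with p < α (default 0.01, no multiplicity correction — the design
fixes a single α) are "responding bioindicators", labelled by their best
group. "Unconditional bioindicators" combine two treatments: (1) OTUs
responding to the same CH₄ level in both treatments ("peat soil
independent"), and (2) OTUs responding in one treatment while absent —
zero counts in every sample after denoising — from the other (labelled by
the treatment where they respond).

Note on invariances: the observed statistics are exactly invariant to
within-group sample reordering and to OTU column order; Monte-Carlo
p-values are exactly invariant to column order, and invariant in
distribution (not bit-wise) to row reordering.

## Phylogenetics

Pairwise distances from a fixed alignment use the Jukes–Cantor
correction `d = −(3/4)·ln(1 − 4p/3)`, with p the mismatch fraction over
pairwise-comparable columns (gaps/N excluded per pair; complete deletion
available by flag). Pairs at p ≥ 3/4 are saturated: flagged and set NaN.
The point-estimate tree refuses saturated pairs; inside bootstrap
replicates a saturated pair's distance is replaced by twice the
replicate's largest finite distance (deterministic, logged).

Neighbor joining is the classic Saitou–Nei agglomeration on the Q
criterion; ties in Q are broken by the lowest index pair in the current
node order (documented for reproducibility); negative branch-length
estimates are clamped to 0 with a log entry. On additive matrices the
generating topology and branch lengths are recovered exactly. Bootstrap
support resamples alignment columns with replacement (default 500
replicates), rebuilds the JC+NJ tree, and reports for each internal
bipartition of the point tree the percentage of replicates containing it;
supports above 80 carry a presentational annotation flag. Trees are
scikit-bio `TreeNode` objects; Newick round trips preserve topology,
lengths, labels, and supports (written as internal node labels).
Maximum-likelihood and minimum-evolution estimators are out of scope; NJ
is the implemented estimator.

## Synthetic-data generators

All generators are pure functions of their parameters and seed
(bit-identical outputs under identical inputs) and return truth records
sufficient to score the downstream stage.

- **Gas series:** `C(t) = C₀·e^(−kt)·(1+ε)`, ε ~ N(0, σ). Noise is
  multiplicative because GC-FID error scales with concentration; σ
  defaults to 5 %. Optional sampling-loss bookkeeping removes each
  measurement's gas/liquid shares so the correction step can be tested
  against a known zero-oxidation series.
- **Communities:** Dirichlet-multinomial counts (a standard overdispersed
  count model; the field's analyses assume no explicit model — this is the
  stand-in structure). Per group, sample proportions are drawn from
  Dirichlet(α_g) and counts from a multinomial at fixed depth (default
  10,000 reads). Planted indicators multiply their Dirichlet parameter by
  the fold effect in their target group and are present within that group
  with the stated occupancy. The default base concentration is 3.0 per
  OTU: a moderately overdispersed community in which a planted ≥4-fold
  mean-abundance effect at full occupancy is reliably detectable at
  n = 8 per group — the regime the planted-recovery scenario specifies.
  Demo scenarios place planted responders in the rare tail (base 0.5)
  because boosting an abundant OTU compositionally depresses every
  background OTU in its group and manufactures genuine opposite-level
  indicators; responders that are small community fractions keep the
  closure distortion below detection.
- **Amplicons:** reads copied from synthetic stop-free pmoA-like ORFs
  (random non-stop codons, length 465 by default) with mutually exclusive
  planted defects — an in-frame stop substitution, a single-nucleotide
  deletion (frameshift), or a 50-nt low-quality window — at stated rates.
  The filters must recover the planted pass/fail partition exactly.
- **qPCR:** `Cq = intercept + slope·log₁₀(copies) + N(0, σ_Cq)` over the
  default seven-decade range.
- **Sequence evolution:** root sequence uniform over ACGT; along each
  branch of length d every site changes with the exact JC transition
  probability `(3/4)(1 − e^(−4d/3))`, uniformly to one of the other three
  bases (equivalent in distribution to Poisson substitution events).

What the generators do **not** emulate: Illumina error profiles beyond the
planted defect classes, chimeras, primer-site variation, compositional
correlations between taxa beyond Dirichlet closure, pore-water CH₄
dynamics, or inter-block spatial structure. Passing tests therefore show
that the algorithms are correct under the stated statistical structure,
not that real Arctic peat data satisfy that structure.

## Problem sizes

The test suite and demonstration drivers use desk-scale sizes chosen to
exercise every code path with stable statistics: 192-bottle rate
campaigns, 1,000-OTU null communities at 1,999 permutations for the
uniformity check, 10,000 permutations for planted-recovery scenarios, and
500-replicate bootstraps on 6–8-taxon alignments of 452 columns (the
alignment length used for the mb661R dataset).

## Known limitations

- Headspace pressure is fixed at 1 atm; injections and sampling do not
  track overpressure (the closed-bottle arithmetic of large injections is
  therefore approximate).
- Soil bottles default to zero liquid volume: pore-water dissolved CH₄ is
  not subtracted from microcosm rate constants.
- The qPCR module does not model touchdown cycles, melting curves, or raw
  fluorescence.
- Read merging, chimera removal, OTU clustering, and multiple-sequence
  alignment are upstream tools whose outputs (or synthetic equivalents)
  this package consumes.
- RDA ordination and mixed-model rate comparisons are delegated to
  standard statistical libraries and not part of the package surface.
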