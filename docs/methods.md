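# Methods

`markerkit` implements the standard desk analysis of a small-panel plant
genetic-profiling study: dominant-marker fingerprinting statistics
(ISSR/RAPD band matrices), similarity clustering, population-diversity
estimation for dominant data, DNA-barcode alignment diagnostics with
distance-based phylogeny, and an in-silico SCAR-marker workflow. This note
records the models, the defaults and why, and what the synthetic
generators do and do not emulate.

## Dominant-marker model

A scored band is treated as a dominant biallelic locus: band presence is
the dominant phenotype, so only the presence frequency
`f = (taxa showing the band) / (taxa)` is observable. The per-primer
summary statistics are

- **PIC** per band `2f(1 − f)` (maximal 0.5 at `f = 0.5`), averaged over
  the primer's bands with monomorphic bands contributing 0. This is the
  dominant-marker form; the heterozygosity-based (Botstein) form does not
  apply to presence/absence data.
- **EMR** `n_poly · (n_poly / n_total)` — the polymorphic-band yield of a
  single assay, discounted by its polymorphic fraction; equals `n_poly`
  at 100 % polymorphism.
- **MI** `PIC · EMR`, computed exactly; published tables often multiply
  *rounded* PIC, so regression checks against printed values carry a
  rounding-sized tolerance.
- **RP** `Σ_b (1 − 2|0.5 − f_b|)` — each band contributes 1 when present
  in exactly half the taxa and 0 when fixed.

With 4 taxa the only admissible polymorphic frequencies are 1/4, 1/2 and
3/4, so per-band PIC ∈ {0.375, 0.5} and band informativeness ∈ {0.5, 1}.
This discreteness makes a printed primer mean invertible: given band
counts and the mean PIC there is (generically) a unique split between
`f = 1/2` and `f = 1/4 (or 3/4)` bands (`marker_stats.invert_band_profile`),
which is how the bundled panel rows are reconstructed for end-to-end
recomputation. One bundled row's printed PIC lies below the 0.375 floor
and admits no 4-taxon profile; six rows' printed RP cells contradict the
profile implied by their own PIC. These are recorded in
`datasets.RP_INCONSISTENT` / `datasets.PROFILE_NOT_INVERTIBLE` and
excluded from profile-based regression, not patched.

Replicate rows (`species/population` labels) collapse to a per-species
consensus by majority vote (ties → present) before frequency computation;
`level="replicate"` computes over rows as scored instead.

## Clustering

Jaccard similarity `J = a/(a + b + c)` ignores co-absences, which carry
no signal for dominant markers; an empty union is defined as `J = 0` with
a warning. UPGMA runs on `d = 1 − J` with size-weighted arithmetic-mean
linkage; node height is half the merge distance, so trees are ultrametric
by construction. Ties in the minimum linkage break on the
lexicographically lowest pair of cluster representative labels — an
arbitrary but deterministic rule. `discrimination_report` answers the
operational question "does this taxon form its own clade directly under
the root?" (complete discrimination) and names its cophenetically nearest
neighbour.

## Diversity for dominant data

Allele frequencies come from the square-root estimator `q = √(1 − f)`
(Hardy–Weinberg assumed), the classic default for dominant data; the
Lynch–Milligan Taylor bias correction is available
(`method="lynch-milligan"`, requires the group sample size) but off by
default because small panels (3 replicate rows/species) do not support
the variance estimate well. Per-locus indices: `Na` (1 or 2 observed
alleles), `Ne = 1/(p² + q²)`, Nei's `H = 1 − p² − q²`, Shannon's
`I = −p ln p − q ln q`; group means run over *all* loci, so the identity
`Na = 1 + PL/n_loci = 1 + PPL/100` holds exactly under two-allele coding
and is used as a cross-check.

## Barcode alignment diagnostics and trees

Site classes follow the usual convention: over gap-free, unambiguous
columns, conserved = one state, parsimony-informative = ≥ 2 states each
in ≥ 2 sequences, singleton = the rest; columns containing a gap count as
indel sites and, together with ambiguous columns, are excluded
(complete-deletion). Transition (A↔G, C↔T) and transversion pair counts
sum over all sequence pairs and retained columns; `R = si/sv` is reported
as undefined (not infinity) when `sv = 0`.

Distances: p-distance, K2P
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)`, and T3P
`d = −h ln(1 − P/h − Q) − ½(1 − h) ln(1 − 2Q)` with `h = 2θ(1 − θ)` and
θ the mean GC content of the pair over retained columns (T3P equals K2P
at θ = 0.5). A non-positive log argument raises an explicit saturation
error rather than returning NaN. Trees use Saitou–Nei neighbor joining
with the Q criterion; the last three clusters are resolved by the
three-point formulas, so additive matrices are reproduced exactly.
Negative branch lengths are clamped to 0 with a warning. Trees are
distance-based only: likelihood optimisation, rate heterogeneity and
bootstrap are out of scope.

## In-silico SCAR workflow

Coordinates are 1-based inclusive on the supplied strand; a predicted
product spans from the plus-strand primer's 5′ end to the minus-strand
primer site's far end inclusive, matching gel-estimated sizes
(`length = forward + spacer + reverse` for constructed templates). Primer
IUPAC codes match as character classes. Defaults are stringent —
0 mismatches, 3-nt exact 3′ zone, 5 kb product cap — mirroring a binary
band/no-band readout. Both pair orientations are searched, so prediction
is invariant under template reverse-complementation.

Internal primer design for a cloned fragment (which begins with its RAPD
decamer and ends with the decamer's reverse complement) draws candidates
strictly inside the region between the terminal decamers: length 18–20 nt,
GC 40–60 %, Wallace-rule Tm (`2(A+T) + 4(G+C)`, a screening heuristic —
no thermodynamic nearest-neighbour model, since assay salt/primer
concentrations are not part of the data model) within 45–65 °C, product
within `[100, fragment length]`. Pairs rank by Tm balance, then longer
product, then position; per side only the `max_candidates_per_side`
candidates nearest the Tm-window centre are paired, keeping design
O(competitive) on kilobase fragments while staying deterministic.

## Synthetic generators

- `gen_band_matrix` realises per-band presence counts **exactly** (taxa
  chosen pseudo-randomly from the seed), so panel statistics computed
  from a generated matrix are deterministic functions of the profile;
  replicate expansion copies the species pattern and flips cells at the
  noise rate (a column zeroed everywhere by noise has one carrier cell
  restored, because a never-observed band cannot be scored).
- `gen_alignment` evolves a root sequence (i.i.d. with the requested GC)
  down a Newick tree; substitution events per branch are Poisson with
  mean `branch_length × L`, each a transition with probability
  `κ/(1 + κ)` — κ is thus the *nominal* si/sv ratio and the counted R
  converges to it at low divergence (measured R = 3.9 at κ = 4, length
  10⁴, total tree depth ≈ 0.03). Indel events delete single columns for
  the subtree below the branch.
- `gen_pcr_template` embeds a forward site and the reverse-complemented
  reverse site at a prescribed spacer inside random flanks that are
  re-drawn until free of spurious exact sites; decoys are near-match
  copies with mismatches confined to the 5′ half.

What the generators do **not** emulate: genomic priming-site structure
(bands are abstract loci, not genome coordinates), codominant allele
sizes, alignment context-dependence (indels are single columns, rates are
site-homogeneous), or PCR kinetics. Green tests therefore demonstrate the
correctness of the statistics and algorithms under the stated models, not
robustness to real-gel scoring noise or model misspecification.

## Problem sizes and numerics

Test and acceptance runs use the study-scale inputs throughout: 4 taxa,
5 + 27 primer profiles (41 and 212 bands), 3 replicate rows per species
for diversity, 4-taxon alignments of 10⁴ sites for ratio recovery, and
4–8 taxon matrices for tree-recovery properties. Internal values are kept
exact (floats, no premature rounding); table output uses half-up rounding
at the caller's precision. Ultrametricity and additivity are asserted to
1e−9; UPGMA/NJ tie-breaks are deterministic as described above.
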