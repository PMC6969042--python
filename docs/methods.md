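# Methods

This note documents the models, conventions and design decisions behind
`orpheus`, in the spirit of a methods supplement.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinates and formats

All internal coordinates are 0-based half-open on the forward contig
strand; reverse-strand features carry a strand flag and are translated
from the reverse complement.  GFF3 output converts to 1-based inclusive at
the boundary and nowhere else.  Codons containing N translate to X, never
count as stop codons, and are treated as missing data by the codon-model
machinery.  FASTA, Newick and tree handling are delegated to Biopython and
dendropy.

## ORF model

An ORF is a maximal stop-free reading stretch in one of the six frames
(getorf-like, stop-to-stop).  The reported CDS starts at the first ATG of
the stretch when one exists; a stretch cut by the 5' contig boundary is
reported from the cut instead, because an edge-truncated gene fragment has
lost its true start and trimming to an arbitrary internal ATG would
discard homologous sequence (and can push real fragments under the length
filter).  `has_start`/`has_stop` record ATG/stop presence and
`edge5`/`edge3` record boundary cuts.  The 75-aa minimum applies to the
reported CDS translation.  Only the standard nuclear code is supported
(the target genes are single-exon avian ORs).

## Profile HMM

Match states are seed-alignment columns with <50% gaps.  Emissions are
pseudocount-smoothed counts, `(c + w*bg) / (n + w)`, against a background
of amino-acid frequencies implied by uniform usage of the 61 sense codons
(the same null the decoy generator and shuffled-sequence calibration use).
Transitions are counted along each seed row and smoothed with a prior
whose delete state is cheap to extend (M→M 0.90, M→D 0.05, M→I 0.05;
D→D 0.90, D→M 0.10; I→I = I→M 0.50).  The cheap delete extension is what
lets a 75-aa fragment of a 312-state profile traverse the full match path
at a total penalty of tens of bits instead of hundreds — scoring is
glocal: the whole match path must be traversed (via match or delete
states) while flanking sequence is absorbed by free flank states.

Significance: a Gumbel EVD is fitted (maximum likelihood) to Viterbi
scores of `n_null` random background sequences of profile length, once per
model; `E = n_targets * SF(score)`.  Per-target-length calibration would
cost `n_null` extra Viterbi runs per ORF and change nothing at the score
separations involved (true hits score hundreds of bits above the null
mean; the 1e-10 cutoff sits ~30 bits above it).  The projected MSA keeps
one column per match state; insert-state residues are recorded in the
alignment path but collapsed from the reported rows, and codon threading
therefore uses the per-row match-column → residue maps rather than a
column walk.

## Integrity classification

Precedence, per OR-positive locus: (1) *truncated* if the reading stretch
is cut by a contig boundary; (2) *pseudogene* if two same-strand hits
within 100 nt have profile envelopes that together tile ≥80% of the
profile — same frame implies a premature stop (recorded at the 5' piece's
envelope end), different frames imply a frameshift; the pieces merge into
one record; (3) *intact* if start and stop are present and the translated
length is within ±10% of the profile length; (4) *partial* otherwise.
"Edge of a contig" is operationalized as the stretch being cut by the
boundary (no in-frame stop context before the end), since no distance
threshold is published.  The merge window (100 nt), tiling threshold
(0.80) and length tolerance (±10%) are package defaults; repertoire
percentages round half-up so that 20/56 prints as 36%.

## Synthetic data

The generator emulates the study system rather than arbitrary sequence:
a 312-aa, 7-TM template with MAYDRYVAIC ending flush with TM3, FSTC(L)H
ending IC3, conserved cysteines in EC1/EC2 and prolines in TM7; TM
segments are drawn from strongly hydrophobic residues and loops from
hydrophilic ones so Kyte–Doolittle segmentation recovers exactly seven
helices on the template.  Genes are back-translated with uniform codon
usage (the counting and likelihood methods assume no codon bias) and
diverged by i.i.d. substitutions outside the motif positions.

Choices that keep the printed classification rules identifiable at low
divergence, made once and documented here:

- every planted locus gets an in-frame stop 0–9 codons upstream (ordinary
  stop context; it also pins the ORF boundary);
- the template carries no Met outside position 0 and the motif Met, and
  divergence never substitutes *into* Met, so the first-ATG rule lands on
  the intended start;
- premature stops and frameshift indels (1–2 nt) are planted in codons
  110–200 so both fragments clear the 75-aa filter;
- partial genes are missing_start *or* missing_stop, not both: removing
  both lets the first internal ATG plus downstream read-through land back
  inside the intact ±10% window, making the published rules
  non-identifiable by construction;
- missing-stop genes read through 40–50 extra codons before a planted
  stop, placing them outside the intact window;
- truncated fragments retain 90–240 codons and abut the contig edge at a
  codon boundary; decoys are length-matched random sense-codon ORFs
  (checked free of MAYDRYVAIC).

What the generator does **not** emulate: repeats, sequencing error,
assembly chimerism, codon bias, indel divergence between family members.
Passing recovery tests therefore demonstrate the correctness of the
classification logic under clean conditions, not robustness to assembly
artifacts.

The codon simulator evolves sites independently under MG94×HKY with
per-site ω on a supplied tree (two trees left/right of a planted
breakpoint), drawing root codons uniformly from the 61 sense codons; stop
codons are outside the state space by construction.

## Phylogenetics

Distances are p-distances over shared non-gap columns with Poisson
correction `d = -ln(1-p)`; pairs with `p ≥ 0.95` are flagged saturated and
set to the largest finite corrected distance.  NJ follows Saitou–Nei with
the standard Q-criterion, a deterministic lexicographic tie-break, and
negative branch lengths clamped to zero with the deficit moved to the
sibling.  Supports are Felsenstein column bootstraps mapped onto the
full-data tree as bipartition frequencies (0–100).  Rooting happens
*before* support mapping when an outgroup is given: rerooting inverts the
node↔bipartition association along the outgroup path, so attaching
supports first and rerooting later would mislabel clades.

## Selection

**Breakpoint scan.**  For each candidate breakpoint the alignment splits
in two; each side gets its own NJ tree from Jukes–Cantor-corrected
nucleotide distances, and the statistic is the site-count-weighted drop in
squared misfit, `Σ_parts n_part (mis(T_single, D_part) − mis(T_part,
D_part))`, maximized over candidates.  The weighting matters: unweighted,
the overfitting term scales as the inverse partition size and the
statistic peaks at the scan edges regardless of signal.  Significance is
the upper tail under random column-order permutations (the same scan on
permuted columns); a breakpoint is reported at p < 0.05 and never inside
the margin.  Defaults used in the studies: margin 20, step 4, 50
permutations (minimum attainable p ≈ 0.02).

**SLAC.**  Ancestral codons come from parsimony with nucleotide-step
costs (pairwise nt differences as Sankoff costs, lexicographically
smallest codon on ties).  Unit-cost Fitch was rejected: it freely picks
ancestors 2–3 nt away from their children, and the minimal-path averaging
of those spurious multi-step changes injects ~1–2 synonymous counts into
every rapidly evolving site, destroying the test's centering.  Observed
changes are counted over all branches, multi-step changes averaged over
all minimal mutational paths with stop-codon intermediates excluded when
any stop-free path exists.  The expected synonymous fraction `E_s` is the
κ-weighted synonymous-neighbor proportion averaged over the codons
observed at the site (κ estimated as 2·ts/tv over single-nt-difference
codon pairs); unweighted proportions are miscentered whenever transitions
are enriched, because third-position transitions are predominantly
synonymous.  The test is the extended (continuous-count) binomial via the
regularized incomplete beta, reported **one-tailed in the direction of
the statistic** and called at p < α with the matching sign — the
convention of the original counting method; a two-tailed version was
implemented first and measured essentially powerless at this design size
(the lower tail cannot reach p < 0.1 two-tailed with the ~10 countable
changes per site that parsimony delivers from 18 sequences).

**FEL.**  Stage 1 fits κ, a branch-length scale and a single ω by
Nelder-Mead on the full partition.  Stage 2 per site: the equal-frequency
MG94 generator factorizes as `Q(α, β) = β·M(α/β)`, so the symmetric
eigendecomposition depends only on ρ = α/β while β rescales eigenvalues;
the site optimizer is therefore a nested 1-D search (outer over log ρ,
which owns the spectrum; inner over log β, which reuses it), and the
likelihood-ratio statistic 2Δℓ is referred to χ²₁ (slightly conservative
at the β = α boundary).  Codon frequencies are equal by default, matching
the uniform-codon simulator.  Invariant sites short-circuit to neutral.

**Global ω.**  Single-ω MG94 fit with a 95% profile-likelihood interval
(κ and scale re-optimized at each profiled ω); "significantly different
from 1" means 1 outside the interval.

**Site tiers.**  The combiner intersects/unions per-method positive-site
sets (externally computed REL/MEME site lists are accepted as plain
sets), reporting all-methods, ≥2-methods and any-method tiers in unified
1-based alignment coordinates; it deliberately exposes explicit rules
rather than imitating any webserver's undocumented aggregation.

## Study conditions for the calibration/power/breakpoint suites

18 taxa × 312 codons, matching the design size of the intact-gene
analysis; a **balanced tree with uniform branch lengths, total length 5
expected substitutions per codon (at ω = 1), κ = 2** — the symmetric-tree
design used in the original per-site selection power studies.  Coalescent
trees at equal total length concentrate branch length deep in the tree
where parsimony counting saturates, and counting-method power collapses;
this is a property of tree shape, not of the implementation, and the
shape chosen is the appropriate one for measuring a method's operating
characteristics.  Positive selection is planted as ω = 5 at a random 10%
of sites; recombination as one breakpoint at codon 150 between two
random-label balanced topologies.  Replicate counts (20 for calibration,
power and breakpoint recovery; 10 for the no-recombination control) keep
the full suite within a practical single-CPU budget.

## Known limitations

- The E-value calibration extrapolates a Gumbel tail fitted from 10³
  samples to 1e-10; this is adequate here only because true and false
  scores are separated by hundreds of bits.
- SLAC power depends strongly on tree shape (see above); on star-like or
  very deep phylogenies the counting method is much weaker than FEL.
- The breakpoint scan fits one breakpoint; multiple breakpoints are
  reported only as the single best split.
- Family assignment uses global-alignment identity against a panel; it is
  not a phylogenetic placement and labels diverged queries "unknown"
  rather than guessing.
- The FEL χ²₁ null is conservative at the boundary; no mixture-χ²
  refinement is applied.
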