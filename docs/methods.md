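# Methods

`caverelax` analyses the molecular-evolutionary signature of regressive
trait loss in a cave-dwelling fish lineage: relaxation of purifying
selection on pigmentation genes, the timing of that relaxation, and the
transcript-level consequences of two loss-of-function mutations
(a splice-donor replacement in *mitfa* and a premature stop in
*tyrp1a*). Everything runs on synthetic data generated by the package
itself; this note records the models, the defaults, and the reasoning
behind the open design choices.

## The codon substitution model

All ω estimation happens on a fixed unrooted three-taxon star tree with
named branches **cave**, **surface** and **outgroup**. The substitution
process is a Goldman–Yang-style codon model over the 61 sense codons of
the standard nuclear genetic code. Off-diagonal rates for
single-nucleotide changes are

    q_ij = π_j · κ^[transition] · ω^[nonsynonymous],

zero for multi-nucleotide changes, with the generator rescaled so that
the expected substitution rate at equilibrium is one — branch lengths
are therefore expected substitutions per codon. Each branch carries an
ω class label; the branch model fits one ω per label, which is how the
cave and surface lineages get separate dN/dS estimates against a shared
κ and codon frequency vector.

Likelihoods use Felsenstein pruning, which on a three-taxon star
reduces to `Σ_x π_x Π_b P_b(x → tip_b)` per site; site patterns are
compressed before evaluation. Transition matrices come from SciPy's
Padé scaling-and-squaring matrix exponential rather than from
reconstruction via the π-symmetrized eigendecomposition: the latter
controls only absolute error (~1e-15), which is a poor *relative*
bound for the tiny transition probabilities of short branches, and
those entries can dominate a site's likelihood. Padé is componentwise
accurate in this regime and measured faster at 61×61.

Maximization is bounded quasi-Newton (L-BFGS-B) in log-parameter space,
bounds κ ∈ [0.1, 20], ω ∈ [1e-4, 10], lengths ∈ [1e-6, 10], with three
starts: one informed by NG86 counting estimates, two randomly jittered
from it (deterministically seeded). Codon frequencies are fixed at
their empirical F3x4 estimate by default (uniform and raw-count
empirical are available). An alignment with no variable sites returns
`converged=False` with all lengths zero and undefined ω rather than
exercising the optimizer.

The ML estimates also report model-based Ka and Ks per branch: branch
length × the class-conditional synonymous (nonsynonymous) share of
substitution flow, divided by mutational-opportunity site counts
(flows at ω = 1, normalized to 3 sites per codon). With this
bookkeeping Ka/Ks equals the fitted ω identically.

## NG86 counting estimator

The Nei–Gojobori (1986) method provides a fast, assumption-light
cross-check and the optimizer's starting values. Site counts award each
codon position (synonymous single-nucleotide neighbours)/3, with
changes to stop codons counted as nonsynonymous. Multi-hit codon pairs
average synonymous/nonsynonymous difference counts over all orderings
of single steps, excluding pathways through stop codons and
re-weighting the remainder equally; pairs with every pathway blocked
are skipped and noted. Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3); p ≥ 0.75 is reported as a flagged undefined
value, never as a silent NaN, and Ks = 0 yields an explicitly undefined
ω (distinct from ω = 0) so that downstream distribution statistics
exclude rather than absorb it.

Per-branch NG86 values use the relative-rate decomposition of the three
pairwise distances (d_cave = (d_cs + d_co − d_so)/2, separately for Ka
and Ks, clamped at zero). NG86 assumes no transition/transversion bias;
under κ > 1 it is conservatively biased downward relative to the ML
branch model, which is why cross-method agreement is checked at κ = 1
and the ML path is authoritative everywhere else.

## Mixed-branch dating

A lineage that evolved under purifying selection (ω_f) for part of its
history and neutrally (ω_n, default 1) for the final stretch shows a
single fitted ω that is the time-weighted mixture

    ω_m = ((T − t)·ω_f + t·ω_n) / T,

because synonymous substitutions accrue clock-like while nonsynonymous
ones switch rate at the transition. Inverting gives the relaxation time
t = T·(ω_m − ω_f)/(ω_n − ω_f). With the surface lineage supplying ω_f,
the concatenated pigmentation-specific genes supplying ω_m on the cave
branch, ω_n = 1 and T = 21.3 My, this dates the onset of relaxation;
the result carries an upper-bound flag whenever complete neutrality is
assumed, since any residual constraint in the relaxed phase would push
the true t later. The strict inverter raises on out-of-order inputs
(ω_m < ω_f or ω_m > ω_n); the alignment-driven path instead clamps to
the [0, T] boundary and flags the result, because sampling noise in
fitted ω must not crash a pipeline.

T itself is a user input (the package takes the 21.3-My lineage age as
a constant, not something it can estimate), and whether that age is a
stem or crown age is the caller's interpretation.

## The synthetic-data generator

`simulate_codon_alignment` draws the unobserved central node from the
equilibrium codon distribution and each tip from the exact transition
matrix of its branch — exact CTMC sampling, no per-site Bernoulli
approximation, so long branches are handled correctly. Defaults:
κ = 2, uniform codon frequencies (F3x4 accepted anywhere a frequency
vector is), branch lengths cave = surface = 0.09 and outgroup = 0.7
substitutions per codon. The in-group lengths put roughly Ks ≈ 0.1
between the two loaches, a desk-scale stand-in for their divergence;
the outgroup branch is long because the zebrafish lineage split far
earlier (~97 Ma vs ~21 Ma).

The mixed-branch simulator evolves the cave branch piecewise —
duration T − t at ω_f (ancestral), then t at ω_n — converting My to
substitution lengths through a synonymous clock: `clock_rate` is
synonymous substitutions per codon per My, constant across regimes, so
total branch length scales with the nonsynonymous share of flow at the
phase's ω. The default 0.0033 again calibrates to surface Ks ≈ 0.1
over 21.3 My.

Gene sets mirror the observed class contrast: pigmentation-specific
genes relaxed on the cave branch (ω 0.55 cave vs 0.25 surface),
pigmentation-related genes constrained in both lineages (0.25/0.19),
background in between (0.29/0.26) — values echoing the reported class
means. Per-gene seeds spawn from one `SeedSequence`, so a (config,
seed) pair reproduces the whole set byte-for-byte.

What the generator does *not* emulate: indels and alignment error,
rate variation across sites and genes beyond the class regimes,
codon-frequency heterogeneity, selection on synonymous sites, and any
expression-level signal. Passing recovery tests therefore shows the
estimators are correct under their own model assumptions at realistic
divergences — not that the real data's alignment, orthology and
filtering steps are error-free.

## Gene-model fixtures

The fixtures are explicitly synthetic toy genes, built deterministically
(fixed internal seed) on the + strand, 0-based half-open coordinates,
exons codon-aligned, canonical GT…AG introns, CDS spanning the whole
transcript (ATG … terminal stop).

The splice fixture places the donor-replacement variant (default
CGG → TATATA) across the affected 5′ splice site: the reference span
covers the exon's last two nucleotides ("CG") plus the first intronic
"G" of the canonical "GT". The replacement destroys the donor and
leaves the mutant intron starting "TATAT…". The scanned suffix of the
affected exon is rebuilt from C/A filler (no stop codon contains C, so
the region is stop-proof) carrying exactly one GT dinucleotide at
`alt_donor_offset` from the exon's 3′ end. Offset 3 is a special case
— the replacement's own "TA" completes a pre-placed G into the new
donor — and offsets 1–2 are rejected as impossible. Offsets that are
not multiples of 3 deliberately produce a frameshift downstream.

Variant application treats positions as reference-genome coordinates
(so non-overlapping variants commute), shifts every downstream
gene-model boundary by the length difference, and lets a boundary
strictly inside an edited span keep its offset from the span start
(clamped to the replacement length) — the rule that keeps the affected
exon's length unchanged when the edit straddles the junction.

Re-splicing uses each intron's first dinucleotide: GT canonical, GC
accepted (flagged non-canonical when found by rescue), anything else
triggers a 3′→5′ scan of the upstream exon within `scan_window`
(default 200 nt, about the scale over which real cryptic donors are
reported) for the nearest GT, then — only if no GT exists at any
distance — the nearest GC. No candidate at all yields a flagged
intron-retention outcome rather than an error; that convention (and
not exon skipping) is this package's choice for an unmodelled case.
Acceptor mutations, donor strength scoring and branch-point effects
are out of scope.

NMD uses the classical 50-nt rule only: a premature stop is a predicted
decay substrate when its last nucleotide lies more than 50 nt upstream
of the final exon–exon junction of the transcript as actually spliced;
single-exon transcripts and last-exon stops are never substrates.
Start-proximal and long-3′-UTR exceptions are not modelled.

Provenance headers: TSV, GFF3 and JSON outputs carry `#` header lines
(tool version, seed, config hash); FASTA has no legal comment syntax,
so its provenance rides in the first record's description.

## Problem sizes used by the test suite

Recovery checks run at the scales the analyses are specified at:
ω recovery on 5,000-codon alignments over 10 seeds (mean absolute
error per branch below 0.05), mixed-branch dating on 20,000-codon
alignments over 10 seeds (mean t within 25% of truth), gene-class
ordering on 30 genes × 2,000 codons over 10 seeds, and oracle
equivalence on 100 random ≤50-codon alignments (pruning vs direct
enumeration, 1e-8) plus all 61×61 codon pairs (NG86 vs pathway
enumeration, exact). The demo pipeline defaults to 24 genes of 300
codons, small enough to re-run interactively.

## Known limitations

* Three taxa only; no site- or branch-site models, no rate variation
  across sites. ω per branch is a single average.
* The dating equation assumes an abrupt switch to a single relaxed ω;
  gradual relaxation would be absorbed into t as a weighted blur, and
  with ω_n = 1 the estimate is an upper bound by construction.
* NG86 and the GY94 fits share the alignment-cleaning convention
  (columns with gaps/ambiguity/stops dropped); heavily gapped real
  alignments would lose signal silently beyond the logged counts.
* The rank-sum comparison treats per-gene ω values as exchangeable
  observations; genes differ in length and information content, which
  a weighted test would acknowledge.
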