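# caverelax

Molecular-evolution analyses behind depigmentation in a cave-dwelling
loach: when a lineage moves into permanent darkness, purifying
selection on its pigmentation genes relaxes, and individual genes pick
up loss-of-function mutations. This package implements the three
quantitative pieces of that story for a cave / surface / outgroup
species trio, exercised end to end on synthetic data:

1. **Branch-specific dN/dS (ω = Ka/Ks).** A Goldman–Yang codon model
   on the fixed three-taxon star tree, with one ω per branch
   (rates `q_ij = π_j · κ^[ts] · ω^[nonsyn]`), fitted by maximum
   likelihood via Felsenstein pruning — plus the Nei–Gojobori (1986)
   counting estimator with pathway averaging and Jukes–Cantor
   correction as a fast cross-check. Gene sets
   (pigmentation-specific / pigmentation-related / background) are
   compared between lineages with the two-sided Wilcoxon rank-sum
   test.
2. **Mixed-branch dating.** A cave branch that spent T − t My under
   purifying selection (ω_f) and t My evolving neutrally (ω_n) shows
   the time-weighted ω_m = ((T − t)·ω_f + t·ω_n)/T; inverting,
   t = T·(ω_m − ω_f)/(ω_n − ω_f) dates the onset of relaxation. With
   the reported lineage values ω_f = 0.215, ω_m = 0.413, ω_n = 1 and
   T = 21.3 My this gives t ≈ 5.37 Ma (25.2 % of the lineage's
   history), an upper bound under the complete-neutrality assumption.
3. **Variant consequences.** Toy gene models carrying the two observed
   mutation archetypes: a 5′ splice-donor replacement (CGG → TATATA)
   rescued by the single upstream in-exon GT — shortening the
   transcript by 63 nt and the protein by 21 in-frame residues
   (the *mitfa* event) — and a single T→A change creating a premature
   stop, classified as a nonsense-mediated-decay substrate by the
   50-nt rule (the *tyrp1a* event).

Who it is for: anyone who wants a compact, tested, pure-Python
implementation of branch-model ω estimation, relaxation dating, or
splice/PTC consequence calling — or a simulation harness to probe how
well those estimators recover known truths at realistic divergences.

## Worked example

The one-command demonstration simulates labelled gene sets, estimates
per-gene per-branch ω, compares lineages, dates relaxation, and calls
the two fixture variants:

```bash
$ caverelax demo --out demo_out --seed 1
# caverelax 0.1.0
# seed: 1
# config: 010007bed581

genes simulated: 24
dating (printed constants): t = 5.37 Ma, fraction = 25.2%
dating (synthetic data): t = 9.95 Ma (omega_m 0.615, omega_f 0.277)
mitfa_like: in_frame_deletion nt_delta=-63 aa_deleted=21 nmd=None
tyrp1a_like: premature_stop nt_delta=0 aa_deleted=0 nmd=True
checks: dating_t_near_5.37=pass, mitfa_in_frame_deletion_21aa=pass, tyrp1a_nmd_positive=pass
```

Reading the output:

* The printed-constants line is the headline dating result: feeding the
  reported surface/cave ω pair (0.215 / 0.413) and lineage age
  (21.3 My) into the mixture inversion yields t = 5.37 Ma, i.e. the
  pigmentation-specific genes have evolved nearly neutrally for about a
  quarter of the cave lineage's history.
* The synthetic-data line re-estimates ω from the demo's own simulated
  pigmentation-specific genes (8 genes × 300 codons, constant cave
  ω = 0.55 regime) and inverts the same equation. Its expectation is
  t ≈ 21.3·(0.55 − 0.25)/(1 − 0.25) ≈ 8.5 Ma — the demo regime is a
  constant-ω cartoon, not the reported mixture — and the 9.95 Ma here
  is that value plus small-sample noise. The 10-seed, 20,000-codon
  recovery test in the suite runs the true piecewise scenario and
  recovers t = 5.37 within a few percent on average.
* The two fixture lines are the mutation archetypes: the splice fixture
  loses exactly 63 nt / 21 amino acids in frame; the premature-stop
  fixture is flagged as an NMD substrate (stop > 50 nt upstream of the
  final exon junction).

The same stages are available piecemeal (`caverelax simulate | fit |
compare | date | consequences`); for instance the dating step alone:

```bash
$ caverelax date --omega-m 0.413 --omega-f 0.215 --t-total 21.3
{
  "t_ma": 5.37248407643312,
  "fraction": 0.25222929936305727,
  "upper_bound": true,
  ...
}
```

Or from Python:

```python
from caverelax import MixedBranchInputs, estimate_relaxation_time

result = estimate_relaxation_time(
    MixedBranchInputs(omega_m=0.413, omega_f=0.215, T=21.3)
)
print(result.t, result.fraction)   # 5.372... 0.2522...
```

## Layout

| module | contents |
|---|---|
| `caverelax.codon_evolution` | genetic code, NG86, GY94 branch model, pruning likelihood, ML fitting |
| `caverelax.synthetic_data` | codon-alignment simulator, mixed-branch scenario, gene sets, gene-model fixtures |
| `caverelax.selection_comparison` | gene-set partition, ω summaries, rank-sum comparison, concatenation |
| `caverelax.relaxation_dating` | mixed-branch equation, inversion, alignment-driven dating |
| `caverelax.variant_consequences` | variant application, re-splicing with donor rescue, translation, NMD, protein diff |
| `caverelax.pipeline_io` | FASTA/GFF3/Newick/TSV adapters, provenance, the demo pipeline |

`docs/methods.md` documents the models, defaults and numerical choices
in detail.
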