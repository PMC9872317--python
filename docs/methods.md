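# Methods

## The contribution model

Before embryonic genome activation the zygote transcribes nothing of its own,
so for any RNA element (RE) the zygotic abundance *Z* is modelled as the sum
of a paternal part Pc and a maternal part Mc delivered by the gametes. Given
sperm abundance *s* and oocyte abundance *o* (RPKM, aggregated across
biological replicates), the split assumes the gametes contribute in
proportion to their own abundances:

    Pc = Z − Z / (1 + s/o) = Z·s/(s+o),     Mc = Z − Pc.

Two boundary rules complete the model. When `Z > s + o` the proportional
split would credit each gamete with more than it measurably carries, so the
contributions are capped at the gamete abundances themselves (`Pc = s`,
`Mc = o`; the excess is left unattributed). When `o = 0` the formula is taken
in the limit `Pc = Z` (all paternal); `Z > 0` with `s = o = 0` has no defined
decomposition and raises an error rather than silently producing one.

The model is exactly conservative (`Pc + Mc = Z` whenever uncapped), scale
equivariant, and monotone in *s*; the test suite asserts all three to 1e-9.

## Thresholds and classification

All abundance thresholds are strict inequalities, exactly as published, and
every one is a named, overridable field of `Thresholds`:

| parameter | default | meaning |
|---|---|---|
| `sperm_min_5x` | 25 RPKM | sperm median floor for fivefold enrichment |
| `oocyte_max_5x` | 5 RPKM | oocyte median ceiling for fivefold enrichment |
| `zygote_min` | 10 RPKM | zygote presence gate for any paternal class |
| `fold_2x` | 2 | Pc must exceed `fold_2x`·Mc for twofold enrichment |
| `oocyte_absent` | 2 RPKM | oocyte abundance below which presence is unconfirmed |
| `sperm_specific_2x_lower/upper` | 2 / 25 RPKM | sperm window of the sperm-specific clause |
| `rerna_present` | 5 RPKM | gene-level presence gate |

Per-tissue medians across replicates are computed before any threshold is
applied (configurable to means); the aggregation is applied uniformly to both
the fivefold and the twofold inputs. REs absent from the sperm or oocyte
matrix are treated as undetected (0 RPKM) in that tissue, whereas a missing
cell *inside* a matrix is an error — silent zero-filling would corrupt
threshold decisions. The twofold rule is evaluated only outside the supplied
prior fivefold/maternal sets; when no prior fivefold list is supplied the
fivefold set is computed first and excluded, mirroring the two-stage
definition. The twofold criterion is the disjunction `Pc > 2·Mc` **or**
(`o < 2` and `2 < s < 25`): the second clause admits sperm-specific REs whose
oocyte abundance sits below the presence floor, and the two clauses are
combined with OR because either condition alone marks a paternally dominated
RE. The sperm-specific flag is set for any classified paternal RE with
`o < 2`. The gene-level (> 5 RPKM) presence gate used by `zygote_excess` is
applied to both sperm and zygote abundance.

RE identifiers are treated as 1-based inclusive intervals (genome-browser
display convention; the ids in the source tables accompany browser
screenshots); BED export converts to 0-based half-open. Chromosome names may
contain underscores, so ids are parsed from the final two integer tokens
only. Gene symbols are compared after uppercasing both sides.

## Overlap statistics

Overlap between gene lists of sizes n1 and n2 in a universe of N genes is
scored by the hypergeometric distribution: `p_over = P[X ≥ x]` (the observed
overlap included), `p_under = P[X ≤ x]`, reported one-sided and never
doubled, alongside the representation factor `x/(n1·n2/N)`. The
`normal_approx` method uses the hypergeometric mean and variance with a ±0.5
continuity correction (disable with `continuity_correction=False`). The
universe is an explicit argument everywhere; the pipeline's default is the
set of genes with at least one detected RE in the zygote input.

The approximation's pointwise tail error depends on the expected overlap
n1·n2/N: measured against the exact distribution it is ≈0.10 at expected
overlap 0.5, ≈0.02 at 5, and below 0.01 once the expected overlap reaches
about 30 — the regime of whole-list comparisons (hundreds of genes), which is
where the method is used. The acceptance suite asserts the ≤ 0.01 bound over
all feasible x on grids in that regime and separately asserts that the error
shrinks as the expected overlap grows. For small problems use the exact
method, which the tests verify against integer-arithmetic enumeration for
every feasible configuration with N ≤ 60.

## Movement patterns and consistent responders

For each arm of the crossover–crossback design (B1HB2 with segments B1H and
HB2; H1BH2 with H1B and BH2), an RE's movement is rendered
`First—second` with values Up/Down/Same per segment. A segment is Up or Down
only if that segment's differential comparison flagged the RE significant
(membership in the segment's responsive list — the pipeline never re-tests);
otherwise it is Same. A significant segment with exactly equal means is an
error, not a silent Same. Labels are normalized to capitalized-first form
("Down—same").

A gene is a consistent responder when it has at least one significant move
under DBP addition (B1H or BH2) and one under withdrawal (H1B or HB2), each
side is internally unanimous, and the two sides are opposite — i.e. abundance
tracks the exposure in both directions. Genes observed in a single
comparison carry no cross-condition evidence and are excluded.

Welch's unequal-variance two-tailed t test is provided for
contribution-fold-change comparisons; both samples constant is rejected as
degenerate.

## Empirical-p partition and over-representation

Responsive-RE lists are partitioned into six groups at the printed boundaries
0.013, 0.023, 0.032, 0.041, 0.045, 0.05. Group 1 is the open interval
(0, 0.013); groups 2–6 are closed on both ends with first-match assignment,
so a p exactly on a boundary lands in the earlier eligible group and the
partition exhausts (0, 0.05] without gaps or double-assignment (the published
description leaves boundary membership ambiguous; this resolution is
configurable via the boundary vector). Each group's recognized-gene count —
its genes intersected with the supplied symbol universe, standing in for a
web service's recognizer — must not exceed the 500-gene analysis cap; a
violation raises an error naming the group rather than silently truncating.

ORA scores every non-empty set of a GMT collection with the hypergeometric
upper tail (query and sets intersected with an explicit universe), adjusts
within the collection by Benjamini–Hochberg, and reports at most the top 100
sets with q < 0.05 and ≥ 2-gene overlap, sorted by p with a deterministic
name tiebreak. Collections are always scored separately. Set names map to
five biological-process categories (cellular stress, cell cycle, apoptosis,
DNA damage response, gene regulation) through an ordered regex keyword map;
the shipped default is an editable reconstruction of a manual curation, not
an authoritative ontology, and the first matching pattern wins (DNA-damage
patterns are ordered before the generic stress patterns so UV/radiation
signatures are not swallowed).

## Coverage QC

The Transcript Integrity Index scores a sample by the fraction of a
stable-transcript panel (supplied by the user as a BED of exons; 22
transcripts in the reference workflow) that passes the coverage rule: at
least 50% of exon bases at ≥ 5 RPM. Both comparisons are inclusive (≥) —
"at least" reads as ≥, and the fraction side follows the same convention.
Samples strictly below the linear-interpolation 25th percentile of TII
scores are fourth-quartile and removed; ties at the percentile are kept, so
the filter never removes more than half the samples and always keeps the
top-scoring sample. The per-sample aggregate (pass fraction) and the
percentile estimator are stated choices, since the upstream definition of
the sample-level score is external to this package; both are configurable.

Full-length calls: a sample covers a transcript when every exon base reaches
5 RPKM (the strictest reading of full coverage; a `min_fraction` relaxation
is available because visual inspection tolerates small gaps). A transcript
is FULL_LENGTH when all assessed samples cover it, PARTIAL when some do
(rendered "Full-length (≥ 1 < n samples)"), FAIL when none does. The call is
monotone in coverage depth.

## Synthetic data

The generator emulates the statistical shape of the real inputs, not raw
sequencing. Per-sample abundances are log-normal (σ = 0.35) around a
class-specific target median — strictly positive with a heavy right tail —
and each RE's realized per-tissue median is rescaled to equal its target, so
planted margins from every threshold are exact rather than probabilistic.
Defaults: 2,000 REs in blocks of 3 per gene (class-pure genes, so gene-level
rollups have unambiguous truth), 7 sperm / 3 oocyte / 3 zygote replicates,
class fractions 10% fivefold, 10% twofold, 5% sperm-specific, 15% maternal,
the rest null, margin δ = 0.2, and a 5% capping-contamination rate
(`Z > s + o`) so both branches of the contribution model are exercised in
every run. Responsive lists carry 150 REs per segment with a 30% planted
paternal overlap and Uniform(0, 0.05] empirical p values; 12 genes are
planted as consistent responders appearing in all four segments, while every
other responsive gene appears in exactly one segment so the consistency rule
recovers precisely the planted set. Coverage tracks are full-length
(uniform 6–15 RPM/RPKM) or degraded with the 3'-most 60% of bases below
threshold; the TII study plants 3 poor-quality samples among 12. The planted
GMT set is drawn from the paternal/responsive overlap genes and named so the
default keyword map categorizes it.

What the generator does **not** emulate: read-level noise, library-size and
gene-length effects inside RPKM, batch effects, correlated expression between
genes, or bootstrap-derived p-value distributions. Passing tests therefore
demonstrate the correctness of the decision rules and statistics under the
stated abundance model, not robustness to those real-data artefacts.

Everything is a pure function of (config, seed): identical configs write
byte-identical files.

## Numerical choices and degenerate inputs

* Contribution conservation is asserted to 1e-9 relative; the capped branch
  returns `s` and `o` exactly.
* Exact hypergeometric tails come from `scipy.stats.hypergeom`; tests verify
  them against independent integer enumeration.
* BH q-values come from `statsmodels` and are verified against a hand-rolled
  step-up in the tests.
* Empty panels, empty gene sets, infeasible overlaps, fewer than 4 samples
  for quartiling, inconsistent exon models, and `Z > 0` with `s = o = 0` are
  all errors, never silent defaults.
* Ties: at the Q4 percentile samples are kept; at p-group boundaries entries
  go to the earlier group; ORA sorts by (p, set name) for determinism.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
classification recovery at 5,000 REs, exact-tail verification over all
configurations with N ≤ 60, approximation error on N = 5,000–10,000 grids,
200 ORA replicates on a 2,000-gene universe, and 12-sample TII studies.
These sizes exercise every code path and keep a full run in minutes on one
core; all generators scale to larger runs through `SimulationConfig`.

## Known limitations

* The headline counts of the motivating study depend on external sequencing
  data and an unstated overlap universe, so they are not reproduced here;
  the universe is always an explicit input.
* The recognized-gene counts of a web-service symbol recognizer (aliasing
  rules included) cannot be reproduced exactly; recognition here is plain
  intersection with a supplied symbol universe.
* Visual full-length inspection has no exact programmatic equivalent; the
  strict every-base rule plus the `min_fraction` relaxation bracket it.
* The sample-level TII aggregate and quartile estimator are stand-ins for an
  upstream definition that lives outside this package.
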