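# Methods

## The procedure

The analysis assumes that subunits of a stable protein complex are
co-regulated, so their relative abundances move together across growth
conditions, and that a physiological partner (e.g. an electron-donating
enzyme feeding a membrane-bound oxidoreductase) shares that movement. The
pipeline therefore:

1. **Standardises** each protein's profile: `z_i = (x_i − μ)/σ` over its
   non-missing samples, with σ the *sample* (n−1) standard deviation by
   default. Standardisation removes per-protein location and scale, so two
   proteins are compared only by the *shape* of their response to the
   conditions. Any per-row affine rescaling `x → αx + β` (α > 0) of the
   input leaves the result unchanged — a tested invariant.
2. **Builds a consensus** as the per-sample median of the reference
   subunits' Z-scores. The median (midpoint convention for even counts) is
   robust to one or two divergent subunits, which real complexes have.
3. **Ranks** every retained protein by the Euclidean distance of its
   Z-profile to the consensus, ties broken lexicographically by protein ID
   so ranks are reproducible across platforms.
4. **Selects candidates.** In *auto* mode the threshold is the distance of
   the most divergent reference subunit and selection uses `≤`, so the full
   reference set always qualifies — the reference dispersion itself defines
   "close enough". In *fixed* mode a user threshold is applied strictly
   (`<`), the reading of a published cut-off phrased as "distance smaller
   than". The two agree whenever no protein falls strictly between the
   extreme reference distance and the fixed cut. Reference subunits are
   excluded from the candidate list by default (they are the query, not a
   discovery) and reported separately; a flag includes them.
5. **Completes partners.** A user-supplied map of (trigger, partner) pairs
   encodes manual curation: when a trigger is selected and its known
   operonic/functional partner is not, the partner is appended to a separate
   `partner_completed` list with its distance and trigger recorded — it
   never enters `selected_ids`, keeping the automatic and curated parts of
   the result distinguishable.
6. **Screens for redox plausibility** with a local, deterministic rule set:
   case-insensitive description keywords (ferredoxin, rubredoxin,
   rubrerythrin, hydrogenase, oxidoreductase, dehydrogenase) and optional
   sequence motifs — a 4Fe-4S ferredoxin-type cysteine spacing
   `C..C..C...C` and a rubredoxin-like pair of CxxC knuckles
   `C..C.{10,40}C..C`. This approximates what a curator does with homology
   and domain services; it is a stand-in for such services, not a
   reimplementation, and both rule lists are user-overridable (YAML).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `transform` | `none` | optional `log2`/`log10` before Z-scoring; Z-scores are computed on the abundances as given by default, since processed relative-abundance tables are already on the scale their producers intended. Under a log transform zeros become missing (log undefined), with a logged count. |
| `sd_convention` | `sample` | n−1 denominator, matching the default of the statistical environments these distances are usually computed in; `population` available for comparison against tables produced with n. |
| `min_present_fraction` | 0.5 | rows with fewer non-missing samples are excluded (`excess-missing`). 0.5 keeps proteins quantified in at least half the samples — enough to estimate μ, σ sensibly — while any protein still missing *any* sample is excluded from ranking (`missing-profile`), because an 18-dimensional distance is incomparable with a 17-dimensional one. |
| threshold mode | `auto` | see step 4. |

Simulation (`SimulationConfig`) defaults describe a 6-condition × 3-replicate
experiment: 10 reference subunits at coupling ρ = 0.95, 5 planted partners at
ρ = 0.9, 2000 background proteins at ρ = 0, replicate noise σ_rep = 0.5 on the
log2 scale (≈ 40 % CV, typical of label-free quantification), per-protein
log2 baseline ~ N(20, 2²) and positive signal loading ~ N(1, 0.1²)
(truncated by redraw). On the log2 scale the abundance of protein p in
sample (condition k, replicate r) is

    b_p + s_p (ρ_p a_k + √(1−ρ_p²) u_{p,k}) + ε_{p,k,r}

with a_k ~ N(0,1) the latent complex activity shared by all coupled
proteins, u_{p,k} ~ N(0,1) a protein-specific condition response shared by
replicates, and ε ~ N(0, σ_rep²). A single latent factor per *condition*
(not per sample) mirrors the observation that complex subunits move together
across conditions while replicates scatter independently. Emitted abundances
are 2^(log2 value): strictly positive, linear scale. The RNG stream is
consumed in a fixed order (baselines, loadings, latents, condition effects,
noise; sequences on a separate derived stream), so a (config, seed) pair is
fully reproducible.

### What the generator does and does not emulate

It reproduces the covariance structure the method relies on: condition-level
block correlation among reference subunits and partners, replicate noise,
positive abundances spanning orders of magnitude, and annotations/sequences
that exercise the redox screen. It does **not** emulate peptide-level
quantification, intensity-dependent missingness (only
missing-completely-at-random via explicit NA cells in hand-built fixtures),
batch effects, or compositional normalisation artefacts. Passing tests
therefore demonstrate that the statistics are computed correctly and that
the method recovers planted structure of the assumed form — not that the
method is robust to real-data pathologies outside that form.

### Recovery at the default conditions

`analysis/04_recovery_benchmark.py` and the acceptance script measure, over
20 seeds at the defaults, mean partner recall ≈ 0.75 and mean background
false-positive rate ≈ 0.11 at the auto threshold (≈ 0.71 / 0.08 after log2).
Two effects dominate: with only six conditions a 2000-protein background
produces many profiles that align with the consensus by chance, and the
max-over-10-subunits threshold is itself a noisy statistic that widens in
seeds where the realised condition contrast is weak. This is a property of
the study geometry (6 conditions, 18 samples), not of the implementation —
the noise-free limit and the formula oracles confirm the statistics are
exact — and it is why a distance cut-off alone should be read as a screen
that still requires annotation-level filtering, exactly as the procedure
prescribes.

## Numerical choices

- Tolerances: oracle agreement and the mean-0/sd-1 invariant are asserted at
  1e-9; the noise-free partner distance is asserted ≤ 1e-9 rather than
  exactly 0, because abundances round-trip through `2**x` and `log2` in
  floating point (observed ≈ 3e-14).
- Tie-breaks: ranking sorts by (distance, protein_id) with a stable sort.
- Decimal commas (`1,20`) are auto-detected per file — a column is treated
  as comma-decimal when all its non-missing cells are integers or
  `^-?\d+,\d+$` and at least one has a comma — overridable with
  `--decimal`. Missing cells are empty or `NA` and stay missing; zero is a
  legal abundance and is never conflated with missing.
- Degenerate inputs: constant rows are excluded (`zero-variance`, Z
  undefined); a reference subunit excluded at any stage is a hard error
  naming it, because the consensus is defined over the full detected set;
  an empty selection is a valid result.
- Reported distances are rounded to 2 decimals in output tables with a
  full-precision column alongside.

## Problem sizes

Tests run the full chain on 2015 × 18 matrices (20 seeds for the recovery
and expectation-ordering checks, smaller backgrounds of 100–500 where only
ordering is at stake); property tests use 30–200 random instances each. The
whole suite completes in well under a minute; the acceptance script in a few
seconds.

## Known limitations

- The redox screen is lexical/regex-based; it cannot detect redox proteins
  with uninformative annotations and motif-free sequences, and random
  sequences occasionally match a motif by chance (one background protein in
  the worked example).
- Distances require complete Z-profiles; datasets with widespread
  missingness lose proteins to the `missing-profile` rule rather than being
  imputed.
- The Euclidean-on-Z statistic is the method's definition; correlation- or
  rank-based alternatives are deliberately not offered in the main path.
- Whether deposited abundance tables were log-transformed upstream is often
  undocumented; the `transform` option exists for exactly that ambiguity,
  and real-data comparisons should try both σ conventions (the optional
  integration test does).
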