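# Methods

This note documents the statistical model, the estimation choices, the
synthetic-data generator, and the limitations of `gdvprof`. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Shotgun metagenomic reads are mapped against a collection of reference
genomes with a mapper that reports multiple placements per read. Because
reference databases are incomplete, the organism in the sample is often
*not* the organism in the database: reads recruit to the closest sequenced
relative. The package therefore treats each reference genome as a
*measuring instrument* rather than an answer, and reports, per reference,
how much of it the data actually supports (GDV), at what local depth (λ),
and then groups references into candidate organisms.

All estimation happens after grouping multiple reference sequences
(chromosomes, plasmids) of one organism into a single unit, and after two
early filters: reads hitting more than `max_targets` (default 50) distinct
organisms are discarded as conserved-region noise (rRNA-like reads carry no
organism-level signal and can swamp low-abundance candidates), and
organisms with fewer than `min_unique_reads` (default 10) uniquely mapping
reads are dropped. Both filters run once, in that order; unique-read counts
are not iterated to a fixpoint. The promiscuity filter counts *organisms*,
not sequences — a read hitting five plasmids of one genome has one target.

## Coverage mixture (depth ≥ 1×)

Let `x` be the coverage depth at a genome position. The depth histogram is
modelled as

    f(x | α, λ) = α₁ z(x) + α₂ Pois(x | λ) + α₃ T_λ(x),

with `z` a point mass at 0, and the tail defined as the normalized Poisson
survival mass

    T_λ(x) = Pr(Pois(λ) ≥ x) / λ,   x ≥ 1,   T_λ(0) = 0,

whose normalizer is exactly λ since Σ_{x≥1} Pr(X ≥ x) = E[X]. The tail is
deliberately heavier than the Poisson it shadows: it absorbs repeat
pile-ups and mapping skews so that λ stays an honest estimate of depth in
the genuinely shared regions. GDV = 1 − α₁ clipped to [0, 1].

Numerical choices:

* **Truncation.** Depths above the 99.9th percentile are pooled into the
  percentile bin before fitting (`truncate_histogram`); extreme repeat
  towers otherwise dominate the tail component. The reported log-likelihood
  refers to the truncated histogram.
* **EM.** Initialization: α = (zero fraction, ½·rest, ½·rest), λ = mean of
  nonzero depths. The weight update is the standard closed form; λ is
  updated by exact bounded 1-D maximization of the expected complete-data
  log-likelihood over the Poisson *and* tail terms (a generalized EM step,
  guarded to never decrease it), so the observed log-likelihood is
  non-decreasing at every iteration — asserted in code. Convergence:
  relative change < 1e-8, at most 2000 iterations.
* **Polish.** With near-redundant components (e.g. data that is almost
  exactly Poisson), EM creeps along a likelihood ridge and a
  relative-change stopping rule can stop short of the maximum. After EM, a
  Nelder–Mead refinement of (logit α₁, logit split, log λ) is run from the
  EM point and accepted only if the likelihood improves; the test suite
  checks the final fit against an exhaustive grid search.
* α components are kept ≥ 0 and renormalized each step; an all-zero
  histogram raises a "no coverage evidence" error which the profile layer
  maps to GDV 0 with a `fit_failed` flag.

## Spacing mixture (depth < 1×)

Below 1× the depth histogram is almost entirely {0, 1} and cannot separate
α₁ from λ. The model switches to the distances between consecutive read
start positions (computed per member sequence, pooled; duplicate starts
yield distance 0 and are clamped to 1, the smallest value in the geometric
support). Read starts inside shared regions form a discretized Poisson
process with per-base rate ρ, so spacings are Geometric(p) with
p = 1 − e^(−ρ); spacings that jump across unshared regions are far longer.
A three-component geometric mixture is fitted by EM (closed-form M-step,
same stopping rule, same monotonicity assertion), components sorted by
decreasing success probability.

Estimates are read off a *pooled* within-shared regime rather than a single
component: the pool is anchored on the largest-weight component and
includes every component whose mean spacing is within 5× of the anchor's.
Two facts force the pooling: (i) on data that is a single geometric, EM
splits the weight across near-identical components, and any single
component underestimates the regime's weight; (ii) a near-zero-weight
component can latch onto a few coincidentally adjacent starts and would
hijack a tightest-component rule. With pooled weight w and mean spacing m:

* depth: ρ = −ln(1 − 1/m), times the mean aligned read length;
* GDV: (n_spacings · w · m) / genome length, clipped to [0, 1] — the
  expected total genomic span of the within-shared spacing regime.

Dispatch between the two variants uses the naive depth (total aligned bases
over genome length), since the model-based λ does not exist before fitting.
Fewer than 10 spacings raises an "insufficient reads" error, reported like
other fit failures.

## Homogeneity check

Per reference, a one-sample Kolmogorov–Smirnov test compares read-start
positions against the uniform distribution *restricted to the covered
regions* (the union of alignment intervals, concatenated across member
sequences). The restriction makes the test a within-shared-regions check,
so a reference sharing only part of its sequence is not rejected merely for
its unshared half. p ≥ 0.05 is read as "homogeneously distributed"; small
values flag uneven recruitment (e.g. a single conserved operon). With
fewer than two reads the statistic is undefined and `None` is reported.

## Core reads and clustering

A read r with target depths D_r is a core read (CR) iff
(max D_r − min D_r)/mean D_r ≤ t (default t = 0.2; higher t tolerates
noisier depth estimates). Depths enter at the organism level; reads with
any target whose fit failed are excluded (the criterion is a depth
comparison). The criterion is scale-invariant and monotone in t, both
property-tested.

Clustering is greedy. References are processed in order of descending total
mapped reads (ties lexicographic; an optional taxonomy hint reorders ties
only). Each reference joins the best existing cluster with shared-CR
fraction |CR_ref ∩ CR_cluster| / |CR_ref| ≥ 20%, else the best cluster with
shared-read fraction ≥ 60%, else founds a new cluster; cluster sets are
unions over members. The two denominators follow the stated per-genome
defaults ("20% of all CR", "60% of all reads"). The shared-read stage gets
the stricter default because plain shared reads discriminate less than
shared CR. Ties between clusters go to the earliest-created one, making the
procedure fully deterministic. The candidate's depth is the
read-count-weighted mean of member depths (members describe one organism,
so their depths agree by construction of CR), its taxon is the LCA of its
members in the optional 4-column taxonomy table, and its abundance is
depth_i / Σ depth_j — read counts scale with genome length × cell
abundance, and depth divides the genome length back out. Raw read counts
are reported alongside.

## Synthetic-data generator

The simulator emulates the study conditions every test runs under:

* **Genomes**: i.i.d. uniform nucleotides (so references share no homology
  unless planted). Default read length 100 bp; default base error rate
  0.005 (a typical Illumina substitution rate); both per-organism.
* **References**: same length as the source genome; a set of contiguous
  blocks totaling exactly ⌊f·L⌋ bases is copied in place (so coordinates
  agree), with substitutions at rate `divergence` (default 0.02); the
  complement is fresh random sequence. f is the reference's true GDV.
  Default 10 blocks; gap lengths are drawn from a Dirichlet(1) split so
  independent references' layouts are uncorrelated (near-equal gaps would
  place every reference's blocks at the same periodic positions). A
  `block_seed` lets two references share one layout, emulating
  near-identical database strains.
* **Reads**: count ~ Poisson(depth·L/read length), starts uniform,
  substitution errors i.i.d. per base (offsets drawn with replacement —
  duplicate offsets are negligible at realistic rates).
* **Alignments**: produced by coordinate bookkeeping, not by a mapper: a
  read is placed on every reference where ≥ 90% of it (configurable) lies
  inside a single shared block, clipped to the block, with NM = planted
  substitutions + read errors in the aligned span (coincidences between the
  two are not deconvolved). SAM output carries @SQ lengths, soft-clip
  CIGARs and NM tags; SEQ is `*` (sequences live in the FASTA).

What the generator does *not* emulate — GC bias, indels, quality-dependent
errors, chimeras, real mapper heuristics — bounds what passing tests show:
recovery results demonstrate correctness of the estimators under the
model's own assumptions (homogeneous depth, substitution-only divergence),
not robustness to real-library artifacts. The coverage model itself assumes
homogeneous depth apart from such biases.

## Problem sizes in tests and acceptance runs

Recovery checks use 1 Mb genomes for the depth × shared-fraction grid
({0.05, 0.5, 2, 10}× × {0.5, 1.0}), 300 kb genomes for the 3-organism
clustering community (depths 8/2/0.5), 500 kb for the known/unknown
contrast (f = 0.99 vs 0.30 at 5×), and 2000-position histograms for the 20
EM-vs-grid-oracle comparisons. These sizes put Monte-Carlo noise well
inside the asserted tolerances (|GDV − f| ≤ 0.1, relative depth error
≤ 0.3) while keeping a full run in tens of seconds.

## Known limitations

* Organisms with (near-)equal sequencing depth can exchange false core
  reads; the CR-overlap threshold mitigates but cannot resolve highly
  similar organisms at equal depth — by design, such pairs merge into one
  candidate.
* The greedy clustering outcome depends on the processing order; the order
  is fixed (and documented) to keep results deterministic, not because it
  is optimal.
* The geometric-variant GDV depends on the 5× pooling factor; communities
  whose unshared gaps are not much longer than within-shared spacings
  (i.e. very fragmented sharing at very low depth) blur the two regimes.
* Abundances are organism-count fractions over *detected* candidates;
  unmapped reads and database imbalance shift them exactly as they do for
  any reference-based profiler.
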