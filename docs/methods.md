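# Methods

This note records the models implemented in `mmcsig`, the assumptions behind
them, the parameters that matter, and the design choices made where the
design was genuinely open. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates

Internal coordinates are 1-based inclusive everywhere; a deletion's size is
`end − start + 1`. Conversion happens only at format boundaries: BED output
is 0-based half-open, and VCF deletions are left-anchored (POS is the base
before the deleted segment, REF spans anchor + deleted bases, ALT is the
anchor), so REF `ATTT` / ALT `A` at POS *p* denotes the inclusive interval
[*p*+1, *p*+3].

## Balancer-screen statistics

The mapping cross scores surviving progeny only. With recombination
fraction *p* between a recessive lethal and the *dpy-5 unc-13* marker pair
(lethal outside the marker interval), zygote classes are: wild-type-appearing
3/4, viable Dpy-Unc recombinants *p*/2 − *p*²/4, dead lethal homozygotes
((1−*p*)/2)². These three terms sum to 1, so the single-marker Dpy and Unc
classes carry zero mass in this model; they are accepted in `BroodCount` but
ignored by the estimator, which uses only Dpy-Unc and wild-type counts.
Writing R = 2·DpyUnc/((4/3)·WT) gives E[R] = *p* − *p*²/2, and
1 − 2(*p* − *p*²/2) = (1 − *p*)², so `p = 1 − sqrt(1 − 2R)` inverts the
model exactly. The dead class is simulated and then discarded, which is
precisely what the estimator's 4/3 correction accounts for.

Confidence limits use the exact Clopper–Pearson interval (via the beta
quantile) on the recombinant count out of `round((4/3)·WT)` trials, each
bound transformed through R′ = 2·bound and the same *p* formula. The exact
interval was chosen over a normal approximation because recombinant counts
in this design are routinely below 20. Broods with raw R > 0.5 (unlinked or
mis-scored) are clamped to R = 0.5 and flagged rather than rejected.
Positions exactly on a marker classify as "between" (deterministic
tie-break).

## Variant filtering

Zygosity is called from read counts alone: homozygous at variant fraction
≥ 0.90 (inclusive — 0.9 is the usual caller parameter), heterozygous within
[0.35, 0.65] (operationalising "approximately 50%", the balancer's
signature), reference at ≤ 0.10, otherwise ambiguous. The coverage filter
for SNVs is depth ≥ 8, i.e. strictly more than seven reads.

Strain-uniqueness for SNVs is keyed by (chrom, pos, alt): a key homozygous in
more than one cohort strain is removed from every strain, and keys present in
the composite parental are removed. The composite parental is modelled at
call level as the union of its constituent variant keys. For deletions,
exact-coordinate matching is too brittle against caller jitter, so two
deletions are "the same event" when they share a chromosome and overlap
reciprocally by ≥ 80% (configurable). Deletions whose deleted segment is a
single-base run contained in a reference homopolymer of ≥ 6 bp (configurable)
are rejected as caller artifacts.

Lethal candidates for a strain are deletions that are heterozygous, overlap
the physical interval implied by that strain's three-factor mapping, and are
strain-unique. Spectra use the six complementary-base-pair classes; a
substitution and its reverse complement always land in the same class.
Spectrum comparison is a Pearson chi-square on the 2×6 table without
continuity correction; classes empty in both spectra are dropped with the
degrees of freedom reduced, and a flag marks expected counts below 5. Only
the single comparison's exact p-value is reported; no multiple-testing
correction is applied.

## Sequence context

Flanks of 15 nt (more than one helical turn) are taken immediately adjacent
to the deletion and truncated, not padded, at chromosome ends. Dinucleotides
are counted on the given strand as 16 separate categories in overlapping
windows, never across sequence boundaries; windows containing N are skipped
(real references contain N; the simulator never emits it). Tallies are
pooled across all deletions before proportions are computed, so every window
counts equally. Fold-enrichment is the ratio of CG proportions
(target/background) and is scale-free by construction.

Microhomology scores the two alignments consistent with end-joining: longest
common prefix of (deleted segment, right flank) and longest common suffix of
(deleted segment, left flank), case-insensitive, reporting both and their
maximum. The cap defaults to 25 bp because observed junction homology can
exceed the 15-nt display flank; when the deletion comes with reference
coordinates the pipeline re-extracts flanks at the cap length so long
homologies are never truncated by the display convention.

## Breakpoint detection

A boundary before bin *i* qualifies when the median of the next `min_run`
bins (default 3) is below `drop_ratio` (default 0.6) times the median of the
previous `min_run` bins. Medians, not means, so a single dropped-out bin can
neither fake nor mask a boundary. Runs of consecutive qualifying boundaries
merge to the boundary with the most extreme post/pre ratio; exact ratio ties
(noiseless step tracks) resolve to the sharpest single-bin step, then
leftmost. Both thresholds are configurable because no published criterion
exists for what counts as a "major" drop. An optional `search_interval`
restricts scanning to the genetically mapped region, which is how the
detector is meant to be used: it suppresses spurious candidates in distant,
noisier regions. Calls are reported at bin-edge resolution; base-pair
refinement requires read alignments and is out of scope.

## Synthetic cohorts

The generator reproduces the statistical structure the analysis assumes,
with ground truth for every event. Its defaults are the package's study
conditions: a 1-Mb single chromosome, 10 strains, 20 deletions and 25 SNVs
per strain, mean depth 30, per-read error 0.01, one heterozygous
balancer-maintained deletion per strain, 20 shared parental-background SNVs,
and a coverage track with a 50% drop at position 650,001 in 5-kb bins.

**Genome.** A first-order Markov chain over ACGT whose transition matrix
derives from the target dinucleotide proportions. A single sequence's
realised pair distribution necessarily has equal row and column marginals;
arbitrary targets need not, so targets are first projected onto that
constraint set by iterated least squares weighted by squared cell values
(minimal *relative* change). This keeps small, distinctive cells — a
depleted CG — nearly fixed in absolute terms, which is what makes the
realised CG proportion track a low target closely. The default composition
is AT-rich (A = T = 0.32) with the CG cell scaled to a quarter of its
product expectation (≈ 0.8% CG): a scarce CpG background is what makes
crosslink-driven CpG targeting statistically identifiable at realistic
deletion counts. The alphabet is strictly ACGT; analysis operations, not the
generator, tolerate N.

**Deletions.** Sizes come from a configurable named distribution
(default lognormal, median 50 bp, σ_log 1.5, clipped to [2, 20000] — the
true biological size distribution is unknown and deliberately left as
configuration). Candidate intervals containing ≥ 1 CG are accepted
outright; CG-free candidates with probability 1/`cpg_bias` (default 10), so
CpG-containing segments carry relative weight `cpg_bias`. Deletions are
non-overlapping across the whole cohort with a 40-bp margin, keeping truth
unambiguous and flank edits independent; placement retries are bounded
(default 1000) and exhaustion raises a simulation error. Engineered
microhomology of length *k* is created by copying the deleted segment's
first *k* bases into the start of the right flank — the construction
guarantees ≥ *k* bases of junction homology on the 5′ side (chance sequence
may extend it), whereas searching for naturally matching placements does not
terminate reliably for *k* ≥ 5. The microhomology-length distribution
defaults to a categorical over 0–6 bp with ~31% zeros, echoing the observed
roughly-two-thirds-with-homology pattern. Truth records carry zygosity so
heterozygous balancer-maintained events can be generated alongside
homozygous ones.

**Read counts.** Depth is Poisson(`mean_depth`) (or fixed, for noiseless
studies); variant reads are Binomial(depth, f) with f = 1 − error at
homozygous sites, 0.5 at heterozygous sites, and the error rate at
non-carrier sites. Every strain's SNV table carries a row at every cohort
SNV site, so absence is evidenced, not implied; deletion tables carry only
each strain's own called events, as real callers emit. The parental table
contains only the shared background variants.

**What the simulator does not model:** reads, alignment artifacts,
error-haplotype structure, indel-realignment ambiguity, GC-coverage bias,
or the balancer's actual translocation sequence. Passing recovery tests
therefore demonstrates the correctness of the filtering and measurement
logic under the stated statistical model, not robustness to alignment-level
pathology in real data.

## Determinism and problem sizes

Every stochastic entry point takes an explicit integer seed or a
`numpy.random.Generator`; `simulate_cohort` derives per-stage sub-streams
from one seed via `SeedSequence.spawn`, so a fixed seed reproduces every
output byte-for-byte, and pipeline reports embed no timestamps. The test
suite exercises statistical properties at sizes chosen to make the checks
sharp yet quick: CG-enrichment monotonicity on 200 × 50-bp deletions over a
1-Mb genome, interval coverage over 500 broods of 2000 zygotes, breakpoint
recovery over 200 noisy 400-bin tracks, microhomology against a brute-force
oracle on 10,000 random junctions, and chi-square type-I error over 1000
null replicates at 245 SNVs per arm.

## Known limitations

Bin-edge breakpoint resolution; call-level (not alignment-level) parental
subtraction; the heterozygous-candidate filter inherits the binomial
variability of the 0.35–0.65 band, so a het event with an unlucky read draw
can be missed at moderate depth; and the two internally inconsistent entries
in the bundled deletion-size table are flagged, never resolved.
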