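# Methods

This note defines the generative model behind `capture_eval.simulate`, the
analytical models in `dedup` and `variants`, the conventions all modules
share, and the rationale for the default parameter values. Problem sizes
quoted here are this package's own choices for its test and demonstration
regimes.

## Conventions

* **Coordinates** are 0-based, half-open (`[start, end)`), the BED
  convention, everywhere in the API. SAM and VCF files written or read by
  the package use the 1-based conventions of those formats; conversion
  happens only at the I/O boundary.
* **Determinism**: every stochastic routine takes a seed (or a
  `numpy.random.Generator`); identical seeds give byte-identical outputs.
* **Median** uses the lower central order statistic for even-length
  vectors (`sorted(x)[(n-1)//2]`), so a reported median is always an
  observed value.

## Interval operations

`pad_to_min_length(iv, min_len, chrom_len)` extends an interval
symmetrically to at least `min_len` bases; an odd deficit puts the extra
base on the right, and a side hitting a chromosome edge shifts its
remaining deficit to the other side. `pad_flanks` adds fixed flanks (for
short features such as miRNAs). `consolidate` merges overlapping **and
abutting** intervals into a sorted, disjoint `TargetSet`.

`tile_probes(targets, probe_len, step)` places probes at
`target_start + k*step`; a final probe that would overhang the target is
right-aligned to the target end instead, and targets shorter than
`probe_len` get a single target-sized probe. Every target base is therefore
covered and no probe base leaves its target. Example: a 160 bp target with
75 bp probes at step 34 yields probe starts 0, 34, 68, 85 (the last
right-aligned), median inter-probe spacing 34 bp.

## Library simulation

A run draws, in order:

1. **Genome**: i.i.d. bases on one synthetic chromosome with the given GC
   content (`gc_content`, default 0.41, roughly mammalian).
2. **Targets**: `n_targets` intervals of `target_length` bp placed on an
   even pitch with uniform jitter, guaranteeing disjointness.
3. **Truth variants**: each target base mutates to a uniformly chosen
   different base with probability `variant_density`; a fraction
   `het_fraction` (default 0.7) are heterozygous (planted on one of two
   haplotype copies, chosen at random), the rest homozygous; a fraction
   `known_fraction` (default 0.9) is flagged "known", a stand-in for
   presence in a variant catalogue.
4. **Capture efficiencies**: each target gets weight `w = 10^z`,
   `z ~ Normal(0, efficiency_sigma)`. `efficiency_sigma` is the standard
   deviation of **log10** weight; the default 0.5 puts ~95% of targets
   within a 10-fold band around the median, a realistic hybrid-capture
   spread. (The natural-log reading was rejected because it is
   inconsistent with the replicate-reproducibility regime the package
   itself advertises; see the correlation analysis below.)
5. **Molecules**: `n_molecules` fragments. Each is on-target with
   probability `on_target_fraction` (rho). On-target fragments pick a
   target proportionally to its weight and place their midpoint uniformly
   within it (start = midpoint − L//2, clamped to the genome). Off-target
   fragments are placed uniformly over the *complement* of the target
   space by rejection sampling, so rho is exactly the probability that a
   fragment overlaps a target — the quantity the `reads_on_target` metric
   estimates. Fragment length is Normal(`fragment_mean`, `fragment_sd`),
   truncated below at `read_length`.
6. **PCR duplication**: each molecule is sequenced `1 + G` times,
   `G ~ Geometric(pcr_extra_copy_prob)` on {0, 1, 2, ...} with
   `P(k) = (1-p)p^k`; mean copies `1/(1-p)`, and `p = 0` means every
   molecule appears exactly once. Copies share coordinates, haplotype and
   strand but draw independent base errors.
7. **Reads**: in `frag` mode one read of `read_length` from the fragment
   5' end on a random strand; in `PE` mode a forward read at the fragment
   start and a reverse read ending at the fragment end (FR orientation).
   Each base is miscalled (uniform choice among the three other bases)
   with probability `base_error_rate`; the uniform Phred quality is
   `-10*log10(base_error_rate)` (1% error ↔ Q20). Reads carry truth tags
   (molecule id `MI`, PCR copy index `PC`) in SAM output for debugging;
   no analysis code reads them.

## Duplicate marking and decomposition

Keys: in **frag** mode a read's key is `(chrom, 5'-most position, strand)`
— alignment start for forward reads, alignment end for reverse reads. In
**PE** mode the fragment key is `(chrom, min start, max end, orientation)`,
symmetric in mate order, and both mates are flagged together. Within a key
group the record with the highest base-quality sum is kept, ties broken by
lexicographically smallest read name. Frag-mode analysis of paired data
collapses distinct fragments sharing one endpoint and therefore always
reports a rate at least as high as PE-mode analysis; the gap widens with
depth.

**Occupancy model.** If `N` fragments fall independently and uniformly on
`P` equally likely start sites, the expected number of occupied sites is
`P(1-(1-1/P)^N)`, so the expected number of *natural* (non-PCR) duplicates
is `N - P(1-(1-1/P)^N)`. The package evaluates this per stratum (on-target
fragments over the target key space, off-target fragments over the
complement key space) and sums. `simulate_natural_dup` is an independent
Monte-Carlo of the same process returning a mean and standard error; the
closed form is kept numerically stable for large `P` via
`expm1`/`log1p`. `decompose_duplicates(observed, natural)` splits an
observed duplicate fraction into PCR-attributable
`(observed - natural)/observed` and natural `natural/observed` shares.
The uniformity assumption is an approximation for on-target fragments
(efficiencies make targets unequally likely), so decompositions under
strong efficiency spread are indicative rather than exact.

## Variant calling

Pileups count bases per strand per target position using only duplicates'
surviving reads and bases at or above a minimum quality. At each site the
caller compares three genotypes — hom-ref, het (alt fraction 1/2), hom-alt
— under a per-base model `P(base | f) = f(1-eps) + (1-f) eps/3` for the
alt allele (mirrored for ref), with `eps` taken from the mean base quality.
`LOD = log10( max(L_het, L_hom) / L_homref )` and the variant score is
`max(0, 10*LOD)`. Sites with positive LOD and a non-reference maximum-
likelihood genotype become candidate calls with depth, VAF and
strands-seen annotations.

Two filter profiles reflect the two historical chemistry/caller styles:

* `solid`: pass iff (score >= 40, or score >= 30 with the variant on both
  strands) and VAF >= 0.15.
* `illumina`: LOD >= 5 (`illumina-strict`: 8), heterozygote allele balance
  within [0.25, 0.75], and rejection of clusters of >= 3 otherwise-passing
  calls within 10 bp.

`evaluate_calls` reports concordance of passing calls against truth:
overall (zero-coverage truth sites count as missed), within the stratum of
truth sites above a post-deduplication depth threshold (default > 9x,
where the missing-at-low-depth effect is removed), the fraction of passing
calls hitting "known" truth sites, and a by-depth-bin table.

## Validation regimes

`tests/test_acceptance.py` and `scripts/acceptance.py` pin the model's
headline behavior:

* **Replicate reproducibility**: 10 Mb genome, 2000 x 160 bp targets,
  rho = 0.5, sigma = 0.5, 500k single 50 bp reads per replicate
  (fragment = read so placement is exact), shared efficiencies: Pearson r
  of normalized per-target coverage ≈ 0.99.
* **Variant recovery**: 2 Mb genome, 250 x 400 bp targets, paired-end
  2x50 on 200±20 bp fragments, 35k molecules (≈20x raw on-target depth),
  30% PCR extra-copy probability, 1% base error, ~500 planted SNVs:
  ≥ 95% (observed ≈ 99%) of truth sites with > 9x post-dedup depth are
  recovered by the `solid` profile.
* Duplicate marking is checked against an O(n²) pairwise brute force in
  both modes; the occupancy closed form against exhaustive enumeration and
  Monte-Carlo; rho and the PCR copy mean are recovered within tight
  confidence bands; interval operations against per-base bitmap oracles;
  filter rules against full truth tables.

## Limitations

The generator is deliberately idealized: one chromosome, uniform base
quality, no indels, no mapping ambiguity or soft-clipping, error-free
alignment (reads are placed, not mapped), fragment-level capture with no
probe-position effects within a target, and no GC-dependent efficiency.
These choices keep every metric analytically checkable; they also mean
absolute values (e.g. duplicate rates) should be read as model quantities,
not predictions for a specific instrument.
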