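# Methods

This note records the models, conventions and design choices behind
`ptscope`, and what the synthetic benchmark does and does not establish.

## Background and scope

DNA phosphorothioation (PT) replaces a non-bridging oxygen of an
internucleotide phosphate with sulfur. It is installed by Dnd/Ssp/BREX-family
systems at short consensus motifs (e.g. G\*AAC/G\*TTC on both strands,
C\*CA on one strand), at partial occupancy — characterized systems modify
only ~10–15% of available consensus sites. Two complementary assays measure
PT in a mixed community such as the gut microbiome:

* **LC–MS of limit digests.** The PT diester resists nuclease P1, so
  digestion releases each modified linkage as an intact dinucleotide
  d(N1\*N2) (16 combinations). Dinucleotides are quantified by MRM against
  synthetic standards; canonical nucleosides by UV-260. Levels are reported
  per 10⁶ nucleotides.
* **Cleavage sequencing ("PT-seq").** Iodine cleaves the backbone at PT
  sites; captured fragments' 5′ ends pile up one position 3′ of each
  modified linkage, locating sites at base resolution.

The package implements both quantification paths, the statistics used to
compare and follow them over time, and a synthetic community generator that
provides ground truth for every stage.

## Mass reference

Compositions are built from integer atom counts: dinucleotide =
nucleoside₁ + nucleoside₂ + H₃PO₄ − 2 H₂O, with one O→S exchange.
Monoisotopic atomic masses: ¹H 1.0078250319, ¹²C 12, ¹⁴N 14.0030740,
¹⁶O 15.9949146, ³¹P 30.9737615, ³²S 31.9720707; proton 1.00727646 Da.
Reported "exact mass" is the [M+H]⁺ m/z (positive-mode MRM), rounded
half-even to 5 decimals; precursor = 1 decimal. Product ions are the
protonated nucleobases (A 136.1, G 152.1, T 127.1, C 112.1). Retention-time
windows, collision energies and cell-accelerator voltages are measured
instrument parameters shipped as package data, not computed.

Two consistency checks are built in: the per-pair linkage shift
(dinucleotide [M+H]⁺ minus both nucleoside [M+H]⁺) is the constant
76.92564 Da across all 16 pairs, and the published panel is re-verified at
table build time. That verification flags the d(A\*T)/d(T\*A) exact-mass
entries as exactly +1.00000 Da above the computed mass while their published
precursor (572.1) matches the computation — a misprint; the computed value
is emitted with a warning. Rp/Sp stereochemistry is carried as metadata only
(natural PTs are Rp); isotope patterns are out of scope.

## LC–MS quantification

Calibration is a single response factor per analyte and channel: the
least-squares slope of area on pmol constrained through the origin
(RF = Σxy/Σx²), because areas are blank-subtracted and zero analyte gives
zero signal. Manual "distinct peak shape" review is replaced by a
programmatic surrogate: S/N ≥ 3 and retention time within ±0.2 min of the
analyte's reference window (both configurable; the S/N value is a surrogate
choice, not a published rule). Levels: level(d) = pmol(d) / Σ canonical
pmol × 10⁶, one PT linkage per dinucleotide; dinucleotide nucleotides are
neglected in the denominator (≤ ~10⁻⁴ of the pool). Chromatographically
unresolved analytes (G\*A and A\*G) are merged by summation under a joined
label, conserving the total exactly.

The PT-carrier fraction estimator divides a community-wide level by the
density a PT-positive genome carries (default 100 per 10⁶ nt, i.e. ~1 PT
per 10⁴ nt), capping at 1. It assumes each dinucleotide class tags a
distinct genome class. The packaged limit-of-detection table uses a baseline
of 1 per 10⁶ nt with G\*C at 5× baseline (its MRM sensitivity is about
five-fold lower than G\*A's).

## Synthetic community generator

The generator reproduces the statistical structure the analysis assumes; it
is first-class, tested code.

**Defaults (the study conditions).** 20 genomes × 200 kb of i.i.d. bases at
50% GC; log-normal relative abundances (σ = 1, a realistic spread for gut
communities); 10% of genomes carry a PT system — one single-strand C\*AG
carrier and one bistranded G\*AAC/G\*TTC carrier — at occupancy 0.125 (the
middle of the characterized 10–15% range); 200,000 reads of 150 nt; 20% of
reads are background nicks.

**Coordinates.** 0-based; a linkage between positions p and p+1 on a strand
is recorded at p (the 5′ base of its dinucleotide). Cleavage puts a read 5′
end one position 3′ of the linkage: forward coordinate p+1 on the plus
strand, p−1 on the minus strand; reads extend 3′ (downstream) from the
break. Minus-strand sites are stored in forward coordinates with a strand
flag; their dinucleotides and 13-nt windows read from the reverse
complement. This makes the pileup dinucleotide identical to the LC–MS
dinucleotide (pileup after the C of CAG ↔ C\*A). Which fragment of the
break the library captures is a modeling choice; the downstream convention
is self-consistent with that correspondence.

**Planting.** All motif occurrences are enumerated (IUPAC-aware, overlap
tolerant); single-strand systems treat each stranded occurrence
independently, bistranded systems modify the duplex pair jointly; each unit
is modified with probability = occupancy. Genomes are linear; occurrences
whose cleavage read or 13-nt window would run off an end are excluded at
enumeration, so every planted site is observable and recall is measured
against realizable sites (excludes ~0.1% of occurrences at the defaults).

**Reads.** A read is a captured cleavage fragment with probability
(1 − background rate) × capture probability, drawn from a PT carrier
∝ abundance and a planted site uniformly; otherwise it is a background
nick at a uniform position on a genome drawn ∝ abundance. Qualities are
constant; no sequencing errors, PCR duplicates or chimeras are simulated,
and the tailing/biotin chemistry is not modeled at sequence level.

**Matched truth.** The profile both assays should report is
level(d) = 10⁶ × Σ_g abundance_g × planted_g(d) / (2 × length_g) —
per-strand site counts over double-stranded nucleotide content. Simulated
LC–MS peak tables invert the quantification (areas = level/10⁶ × injected
pool × RF, optional multiplicative Gaussian noise), so the zero-noise round
trip is exact to numerical precision.

**Time series.** Per species, levels are i.i.d. log-normal with distribution
mean m and variance V = a·m^b (σ² = ln(1 + V/m²), μ = ln m − σ²/2); b = 2
implies constant CV √a. Parameter combinations with m ≤ 0 or a ≤ 0 are
rejected.

## PT-seq pipeline

**Alignment** is exact full-length placement over the genomes and their
reverse complements — adequate for error-free synthetic reads (real-data
alignment is delegated to a proper aligner). A read with n optimal
placements contributes fractional depth 1/n to each, so total weighted depth
equals the number of mapped reads exactly.

**Triage.** Each genome is summarized by coverage (fraction of bases with
positive weighted depth), median depth over covered bases, and dispersion of
depth. "Dispersion" is the variance-to-mean ratio of per-base weighted depth
over covered bases — scale-free and robust to depth differences. Features
enter a diagonal-covariance Gaussian mixture (k = 3, 10 restarts, tol 1e-6,
variance floor 1e-6, mandatory seed) as coverage log-odds, log median depth
and log dispersion.

**Carrier selection.** The most populous cluster calibrates the null: its
median dispersion is what abundance-driven uniform nicks produce (VMR near
or below 1). Genomes whose dispersion exceeds 10× that null and whose
coverage exceeds 15% are selected. The order-of-magnitude factor is a scale
separation, not a tuned constant: site-concentrated capture inflates VMR by
2–3 orders of magnitude at the defaults. Median depth is deliberately not
the selection statistic — it is abundance-confounded (a high-abundance
carrier's covered-base median is set by its background nicks), which k=3
mixtures on these features cannot untangle when only two genomes of twenty
are carriers. Note the orientation differs from real-data practice, where
high dispersion can instead mark false alignments to regions shared between
related genomes; the generator's genomes are homology-free, so that failure
mode does not exist here (a documented limitation of the benchmark).

**Site calling.** Weighted 5′-end depth is accumulated per (position,
strand); sites at or above the cutoff (default 15, swept 1–25 to trade
sensitivity against target-dinucleotide specificity) are emitted with the
linkage position, dinucleotide, and the 13-nt window centered on the
cleavage point (linkage dinucleotide at window columns 5–6,
strand-oriented). Sites within 6 nt of a contig end are skipped and counted.
Output positions use BED convention (0-based, half-open).

**Motif discovery** replaces de-novo ZOOPS search with anchored enumeration:
because the linkage is pinned at window columns 5–6, every candidate is a
k-mer (k = 3–6) at an offset covering both columns. Counts across windows
are tested against the genome's two-strand background k-mer frequency with a
binomial tail, Bonferroni-corrected over the full (k, offset, k-mer)
hypothesis space (α = 0.05); accepted motifs greedily explain their windows
(zero-or-one occurrence per window) before the next round, up to 5 motifs.
Where the binomial tail underflows past log space, the log-pmf at the
observed count preserves the ranking (it decides only among candidates far
beyond significance). Deterministic and exhaustive at these k.

**Equivalent PTs.** level(d) = 10⁶ × Σ_g abundance_g × sites_g(d) /
(2 × length_g). The 2L denominator counts both strands of the genome,
putting per-strand site counts on the double-stranded nucleotide scale of
LC–MS; abundance weighting is multiplicative. This is the same definition as
the generator's expected profile, so truth-level agreement is exact by
construction — the meaningful test is that *called* sites and *quantified*
peaks both recover it. Cross-validation reports per-dinucleotide ratios and
absolute differences, flagging sequencing-only detections below the LC–MS
LOD as "below-LOD" rather than discordant.

## Temporal statistics

* **Taylor's law:** per species, sample mean m and sample variance V (n−1);
  OLS of ln V on ln m gives slope b and intercept ln a. Species with m = 0
  or V = 0 are excluded (log undefined) and logged; ≥ 3 usable species
  required. The fit is exact on noiseless power-law points.
* **Mann–Whitney U:** mid-ranks for ties; U₁ = R₁ − n₁(n₁+1)/2; reported
  U = min(U₁, U₂) — the convention needed to reproduce published tables
  from mean ranks (mean ranks 13.2/7.8 at n = 10/10 give U₁ = 77, reported
  23). Two-sided p by exact enumeration when n₁+n₂ ≤ 20 without ties,
  otherwise the normal approximation with tie and continuity corrections.
  `u_from_mean_ranks` validates the rank-sum identity
  Σ nᵢ·mean_rankᵢ = N(N+1)/2 (±0.5 for printed rounding) before inverting.
* **BH adjustment:** step-up q-values across the dinucleotide test family.
  Published q-values computed from unrounded p-values will not reproduce
  exactly from rounded ones; they are treated as approximate.
* **Autocorrelation:** Pearson r between mean-centered overlapping segments
  at lags 1..L; constant series are an error; r(0) = 1 on request.

## Problem sizes and determinism

The default benchmark (20 × 200 kb genomes, 200k × 150 nt reads) runs the
full pipeline in well under a minute on one core; the oracle suite uses a
≤ 50 kb community where brute-force per-position counting is feasible at
every cutoff. All stochastic stages take explicit seeds; a single master
seed derives per-stage sub-seeds via `numpy.random.SeedSequence`.

## What the benchmark does and does not show

Passing tests establish internal correctness: coordinate conventions,
conservation identities, calibration round trips, motif recovery and the
commensurability of the two assays under the generator's assumptions. The
generator omits sequencing errors, genome homology and shared regions,
dereplication artifacts, taxonomic misassignment, chromatographic
interference and matrix effects — so performance here is an upper bound,
not a prediction, for real fecal-DNA data. Real-data alignment, taxonomy
(Kraken2/Bracken-style), dereplication and de-novo MEME motif search are
explicitly out of scope.
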