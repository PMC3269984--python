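# Methods

This note records the models, thresholds and design decisions behind
`mlncforge`, and what the synthetic benchmark does and does not show.

## Unigene classification

The decision tree takes each transcript through four tests in a fixed
order: protein homology, minimum length, coding potential, housekeeping
homology. The defaults are the standard desk values for EST-scale
surveys: minimum length 300 bp, coding-potential cutoff 100 aa, and an
E-value cutoff of 10⁻⁵ for both homology screens.

*ORF definition.* ORFs are ATG-initiated and stop-terminated, scanned
exhaustively on both strands in all three frames; a maximal ORF starts at
the first ATG after the previous in-frame stop. 3′-open partials (ATG to
sequence end, no stop) are reported and, by default, count toward the
100-aa test because 454 unigenes are frequently truncated at the 3′ end
(`ClassifyParams.count_partial_orfs` disables this). `aa_length` excludes
the stop codon, matching the usual protein-length convention.
Probabilistic frameshift-tolerant ORF calling is deliberately not
implemented: the exhaustive scan is deterministic and oracle-testable.

*Protein homology.* Six-frame translations are split at stops; stop-free
segments of ≥ 15 aa are aligned locally (BLOSUM62, gap open −11 /
extend −1) against the supplied protein set, with ungapped Karlin–
Altschul constants K = 0.134, λ = 0.3176 for the E-value. A precomputed
annotation table may replace the search entirely. Both stand in for a
full-scale Nr search, which is out of scope at desk scale.

*Ordering.* The housekeeping screen runs after the ORF test, so a
long-ORF transcript is never called a housekeeping npcRNA; housekeeping
transcripts are a subset of the non-coding branch.

## Local alignment and E-values

The nucleotide search engine is optimal Smith–Waterman local alignment
(Biopython's PairwiseAligner core) under match +2 / mismatch −3, affine
gaps costing −5 for the first gap position and −2 for each further one.
E-values use `E = K·m·n·e^{−λS}` with K = 0.41 and λ = 0.625 — standard
ungapped-approximation constants for this scoring, applied to gapped
scores as a desk-scale approximation. Nothing downstream depends on
absolute E-values, only on threshold behaviour at 10⁻⁵; the constants are
config-exposed (`NucleotideScoring`). The subject database length `n` is
the total length of the searched set, mirroring an all-vs-all search
context. Among co-optimal alignments the engine's first traceback is
reported; scores (and therefore all clustering decisions) are unaffected
by the tie-break.

Family clustering is single linkage on the graph of all-vs-all hits with
E ≤ cutoff, components of size ≥ 2 forming families numbered by their
lexicographically smallest member. Single linkage makes the partition
independent of merge order.

*Relations.* For mlncRNA ↔ coding-gene relations, each coding transcript
is searched on both strands; the hit strand gives the orientation (sense /
antisense) and the subject interval is localised against the ORF
coordinates: contained in the ORF → CDS; contained in an untranslated
interval → UTR5 or UTR3 (swapped if the ORF is on the minus strand);
anything else → junction. The three region calls plus junction are
exhaustive and mutually exclusive for any interval.

## RNA folding

`mirna.fold` is a Zuker-style minimum-free-energy dynamic program:
stacking energies for Watson–Crick and G:U pairs, size-dependent hairpin,
bulge and internal-loop penalties (internal loops carry an asymmetry term
of 0.5 kcal/mol per unpaired-base difference, capped at 3.0), an affine
multiloop cost (closing 3.4, per branch 0.4, unpaired free), a minimum
hairpin loop of 3 nt, and the usual 30-nt interior-loop cap. Loop tables
extrapolate beyond their last entry as `E(max) + 1.75·RT·ln(n/max)` with
RT = 0.616 kcal/mol (37 °C). There are no dangles, terminal-AU penalties,
special tetraloops or pseudoknots.

The parameter table is bundled as editable JSON
(`data/rna_energy_params.json`) with values in the range of the Turner
nearest-neighbour sets. It is intentionally a simplified set: the
procedure — MFE decomposition, acceptance criteria, MFEI — is the
scientific content, and published MFEI values are sensitive to the exact
parameter file version, so small systematic offsets against other folding
engines are expected. `energy_of_structure` evaluates any dot-bracket
structure under the same decomposition, which is what the exhaustive
enumeration oracle uses to certify DP optimality on short sequences; the
open chain (energy 0) is always admissible, so the reported MFE is ≤ 0.
Ties in the traceback resolve in a fixed decision order (hairpin, then
interior loops by increasing 5′ position, then multiloop splits), making
the returned structure deterministic.

## miRNA precursor annotation

The mature-sequence scan finds every equal-length window on either strand
within 3 mismatches of a known mature (G:U counts as a mismatch here —
the scan is sequence-level, folding is structure-level). Exact 4-mer
seeding is provably lossless for matures ≥ 19 nt at ≤ 3 mismatches
(pigeonhole: the mismatches split the window into at most four runs, the
longest of which is ≥ ⌈16/4⌉ = 4), so the seeded scan equals a full
sliding-Hamming comparison. Overlapping windows for the same mature
collapse to the minimum-mismatch one.

Each hit is folded in a ±150-nt context and accepted when: the mature has
no intra-mature pairs and all partners on one side (it lies on one arm,
5p or 3p, and does not span the terminal loop); ≤ 4 mature bases are
unpaired; no bulge or internal-loop side in the mature:star duplex
exceeds 2 nt; and the enclosing stem-loop contains a single terminal
loop. These are the widely used plant-miRNA annotation thresholds, all
config-exposed (`PrecursorCriteria`).

MFEI is `(|MFE| / L × 100) / GC%`. Because the literature is ambiguous
about whether the folded region or the whole transcript defines L,
both modes are provided (`mfei_region='hairpin'` trims to the
first-to-last paired base of the mature's stem-loop, extended outward
along the enclosing helix, and re-evaluates the substructure's energy;
`'full'` uses the whole folded window). The hairpin mode is the default.
Mature families are single-linkage groups at Hamming distance ≤ 3 after
the best ungapped offset, with length differences counted as mismatches.

## Target prediction

A target site is scored as the minimum-penalty anti-parallel gapped
pairing of the miRNA against a transcript window: Watson–Crick 0, G:U
0.5, mismatch 1.0, each gap position 2.0, with penalties at miRNA
positions 2–13 (1-based from the 5′ end) doubled, at most 2 gap
positions, and a reporting cutoff of 3. These weights follow the classic
plant-target scoring lineage and are fully config-exposed
(`PenaltySchema`); the published descriptions fix only the ~20-base
window and the 0–3 cutoff, so the remaining weights are declared choices,
not reconstructions. Windows slide by 1 nt and take the miRNA's own
length (nominally 20), so a perfect reverse-complement site scores
exactly 0. The threshold is exact: the emitted set is precisely the
windows scoring ≤ cutoff, with overlapping qualifying windows collapsed
to the local minimum. Gap positions are weighted by the miRNA position
being skipped (for a bulged site base: the next unconsumed miRNA
position, or 1.0 past the 3′ end). Target-site accessibility and
translation-inhibition calls are out of scope.

## Expression analytics

Relative expression is `2^{−ΔΔCq}` with ΔCq = Cq(target) − Cq(reference)
and the calibrator sample fixed at fold 1. Undetected means no
amplification by cycle 40; an undetected target yields NaN, never 0.
geNorm M converts Cq to relative quantities `2^{Cq_min − Cq}` per gene and
takes, for each candidate, the mean over partners of the standard
deviation (ddof = 1) of log2 ratios across samples; per-gene constants and
per-sample plate shifts cancel exactly.

The stress-response rules quantify the qualitative time-course types at
0/1/5/10/24 h. Responsive: max/min fold ratio > 2 over any pair of
time-points (the published 2-fold criterion, read literally as any pair).
Cold: A = not responsive; B = fold(1 h) ≤ ½; C = peak ≥ 2 at 1, 5 or
10 h with fold(24 h) below the peak. Dehydration: II = fold(1 h) ≤ ½;
III = fold(1 h) ≥ 2 and fold(24 h) < fold(1 h)/2; I = folds at 1–10 h
inside (½, 2) and fold(24 h) ≥ 2. Rules are checked B/II before C/III
(documented tie-break: an immediate decrease wins over a later rise);
responsive series matching no rule are reported responsive-unclassified.
The exact boundaries are this package's formalisation of qualitative
descriptions and are config-visible in the rule functions. Pair
correlation is Pearson's r on log2 folds over a chosen time subset, with
|r| < 0.5 reported as "none" (threshold configurable) and zero-variance
series as undefined.

## Synthetic benchmark

The generator emulates a 454-style unigene survey at desk scale
(defaults: 60 coding transcripts, half with their protein in the
reference set; 70 singleton mlncRNAs of 300–700 bp; five families of
sizes 2/3/4/5/8 built by mutating a seed sequence at 5 % per base; 25
short transcripts of 100–299 bp; 5 housekeeping transcripts embedding a
bundled synthetic tRNA/snoRNA stand-in; 8 hairpin precursors embedding
bundled mature miRNAs; 10 target transcripts with planted penalties on
the 0.5 grid from 0 to 3; GC drawn from 0.35–0.55). Sizes mirror the
source survey's contig-length distribution; the total (200) keeps the
all-vs-all stages to seconds.

Construction guarantees, enforced at generation time with the package's
own primitives: no non-coding transcript contains a ≥ 100-aa ORF
(rejection sampling); every planted precursor passes the default
acceptance criteria (fold-and-check with bounded retries); every planted
target site scores exactly its planned penalty (sites are written
backwards from the schema using non-seed positions, then verified).
Hairpin decoys for specificity checks keep the mature in place and
permute its context, destroying the star arm. Cq courses add iid
Gaussian noise (default sd 0.2 cycles) to triplicate wells around
subclass templates whose margins to the rule boundaries are ≥ 1 log2
unit wherever a threshold is crossed.

What passing these benchmarks shows: the decision logic, scoring
arithmetic and recovery machinery are correct under the stated model.
What it does not show: robustness to assembly artefacts, chimeric reads,
sequencing error, homopolymer indels typical of 454 data, paralogy at
family boundaries, or real secondary-structure context around miRNA
hairpins — planted hairpins are near-perfect duplexes, so their MFEI
(~1.4–1.9) runs higher than typical genuine precursors (~0.85–1.3).

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open; every user-facing table is
1-based inclusive. RNA inputs are normalised to the DNA alphabet
internally and rendered back as RNA in miRNA reports. GC fraction
excludes N from numerator and denominator and is undefined on all-N
input. Folding traceback compares recomputed decision values at 10⁻⁶
tolerance. ΔΔCq is validated to 10⁻¹² relative error against direct
formula evaluation. The fold engine and target-scan kernels are JIT
compiled (numba); identical pure-Python recurrences back the public
single-duplex API and the test oracles.

## Known limitations

- E-values are calibrated for threshold behaviour, not BLAST parity.
- The folding parameter set is simplified; absolute MFE/MFEI values are
  engine-specific even though orderings and acceptance decisions are
  stable.
- The housekeeping screen is plain nucleotide homology; covariance-model
  searches (Rfam-style) are out of scope.
- Species-specific (non-conserved) miRNA discovery is impossible by
  construction: the scan is anchored to known matures.
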