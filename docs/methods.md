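# Methods

## Coordinate model

Coordinates are 1-based and fully inclusive (the GenBank convention); a
feature on a circular genome that spans the origin is written with
`start > stop` and has length `(L − start + 1) + stop`. Junctions are
formed between consecutive features in ascending-start order, regardless of
strand, because that is how annotation tables lay out their intergenic
column: `gap = start(downstream) − stop(upstream) − 1`, negative values
being overlaps. The junction across the origin (control region back to the
first tRNA) is excluded by default — published tables do not report it —
and can be included with a flag; overlap and spacer totals are invariant
under any rotation of the origin that splits no feature, which the tests
check.

Declared annotation values (size, intergenic, codon labels) are stored
verbatim and never recomputed in place. All cross-checking lives in
`validate_table`, which reports findings without mutating the table. This
matters because published tables contain internal inconsistencies; the
packaged reference transcription (O. lepturum, MT258556) has two that the
validator surfaces: the intergenic value upstream of tRNA-Ile is printed as
4 where the coordinates give 5, and COIII carries a complete `TAA` stop
label although its 785 bp length (mod 3 = 2) forces an incomplete `TA-`
stop (the same source's cross-species codon matrix indeed prints `TA-`
there). The toolkit treats the printed table as canonical fixture data and
reports the conflicts rather than guessing intent. Consequently the
published positive intergenic entries sum to 67 bp over 11 regions while
the coordinate-derived spacer total is 68 bp.

## Composition and skews

AT-skew = (A − T)/(A + T), GC-skew = (G − C)/(G + C), computed on raw
counts (both are scale-invariant, so percentages give identical values). A
zero denominator yields an undefined marker rather than an exception;
ambiguous bases (N) are excluded from numerator and denominator. Reporting
precision is 1 decimal for percentages and 3 for skews; internal arithmetic
is full precision.

Partitions: the whole genome is counted on the reference (heavy) strand as
deposited, while gene partitions (PCGs, rRNA, tRNA) are strand-corrected to
coding sense before counting — gene rows describe gene sequences, the
genome row describes the strand. Codon positions are assigned 1,2,3
cyclically from each PCG's annotated first base, so genes ending on
incomplete terminal codons contribute their 1–2 trailing nucleotides to
positions 1 (and 2) only. On the reference layout this yields position
lengths 3807/3802/3800 (five genes end on a 1 nt tail, two on a 2 nt tail),
summing to the 11,409 bp PCG total.

## Codon usage

The vertebrate mitochondrial code (NCBI translation table 2) is taken from
Biopython. Two codon totals are reported, as both conventions circulate:
`total_codons = floor(Σ PCG lengths / 3)` on the concatenation (3,803 for
the reference layout — the number genome announcements quote, counting
incomplete terminal codons), and the tally of complete sense codons used
for RSCU/CDpT, which excludes stop triplets and 1–2 nt tails. Initiator
triplets are counted literally (GTG under Val) by default, since literal
counting needs no translation heuristics; `initiator_as_met=True` switches
to the re-assignment convention. RSCU families are the synonymous families
of the code; CDpT families split Ser into TCN and AGY classes, the
convention for mitogenome codon-distribution plots. Families with zero
usage report RSCU 0. Internal stop codons are findings, not errors, so
misannotated records remain analyzable.

Stop labels are assigned from the CDS length mod 3: remainder 1 is `T-`,
remainder 2 is `TA-`, otherwise the final triplet is the label. The
validator additionally checks a declared label against this arithmetic and,
when a sequence is present, against the observed bases.

## K2P distances, NJ, bootstrap

P and Q are the observed transition (A↔G, C↔T) and transversion proportions
over the sites where both sequences carry a plain A/C/G/T — pairwise
deletion, the common default of distance-matrix programs and configurable
nowhere else. The distance is d = −½ ln((1 − 2P − Q)√(1 − 2Q)), defined
only for 1 − 2P − Q > 0 and 1 − 2Q > 0; outside that domain the pair is
reported saturated by an exception naming it.

Neighbor-joining follows Saitou–Nei with the rate-corrected criterion
Q(i,j) = (m − 2)d(i,j) − r(i) − r(j). Ties are broken on the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest leaf), making the algorithm deterministic. Negative
branch-length estimates are clamped to zero with the deficit shifted to the
sister branch so path lengths are preserved, matching common tool behavior;
`allow_negative_branches=True` disables the clamp. The tree is left
unrooted (final degree-3 junction); outgroup rooting is a display concern.
NJ is exact on additive matrices — topology and branch lengths — which the
test suite verifies on 200 random trees of 4–8 taxa via the patristic
metric.

Bootstrap: columns resampled with replacement, the full K2P+NJ pipeline run
per replicate, and each internal bipartition of the original tree supported
by the percentage of completed replicates containing it. Replicates that
saturate are skipped with a warning and the denominator adjusted. The seed
fixes the entire procedure. An all-zero distance matrix produces a
degenerate-tree warning, since the topology is then decided by tie-breaking
alone.

## Synthetic data

`generate_genome` turns a layout (coordinates, strands, desired codon
labels) plus base-composition targets into a self-consistent annotated
circular genome. Start codons and stops (literal `T`/`TA` tails for
incomplete stops) become hard position constraints, translated through the
strand; overlapping genes must agree on shared constrained positions or the
spec is rejected before generation — a real layout is always consistent,
because the real overlapping sequences are shared. All other positions are
drawn from the composition target, then an iterative repair pass resamples
unconstrained bases until no PCG contains an in-frame internal stop; since
overlapping frames interact, the pass re-checks all genes until fixation
(converges in a handful of iterations; a generous cap guards the loop).
Declared size and intergenic columns of the emitted table mirror the
coordinate arithmetic, so generated records validate with zero findings.
Infeasible specs — a stop label incompatible with the gene length mod 3 —
raise before generation; deriving a spec from the packaged reference table
therefore substitutes the one length-inconsistent published stop label
(COIII `TAA` → `TA-`) with its length-consistent form.

The default composition target is the published whole-genome base
frequencies (A 31.3%, C 28.6%, T 24.0%, G 16.2%); at 16.6 kb the generated
A+T content lands within binomial tolerance (±3 pp) of the 55.3% target.
What the generator does **not** emulate: real codon-usage bias (codons are
composition-random, so RSCU hovers near 1 instead of showing the strong
CUA/ACA preferences of real mitogenomes), strand-asymmetric mutation
pressure within genes, tRNA secondary structure, and control-region tandem
repeats. Tests passing on generated genomes therefore establish the
bookkeeping (lengths, frames, labels, strand handling), not biological
realism of the sequence content.

`simulate_alignment` evolves a uniform-composition root sequence down a
Newick tree under the two-rate model with transition rate α and
per-transversion rate β, using the exact transition kernel per branch
(P(same) = ¼ + ¼e^{−4βt} + ½e^{−2(α+β)t}, and so on). Defaults α = 0.5,
β = 0.25 make the total rate 1, so branch lengths are expected
substitutions per site and E[d_K2P] equals the path length — the model is
exactly the one the K2P distance inverts, with no among-site rate
variation. The Monte-Carlo check at 60 kb recovers the generating
divergence within a few percent.

## Problem sizes and determinism

The test and acceptance workloads are sized for interactive runs: 200
random additive matrices of 4–8 taxa for exact NJ recovery, 40 simulated
4-taxon alignments of 5 kb (internal branch 0.05 substitutions/site) for
the ≥95% topology-recovery rate, and 100 bootstrap replicates on 5 kb for
the clean-split support; the whole battery completes in seconds. Every
stochastic component takes an explicit seed (numpy `default_rng`);
identical seeds give bit-identical outputs, including the generated
genomes, simulated alignments, bootstrap supports and CLI output files.

## Known limitations

No maximum-likelihood or Bayesian inference, no model selection, no
sequence alignment (alignments are inputs), no tRNA structure prediction,
and no plotting — tabular output is intended for external plotting tools.
GenBank support covers the feature keys mitogenome announcement records
use (gene/CDS/tRNA/rRNA/D-loop/misc_feature); EMBL/GFF3 are out of scope.
Ambiguity codes beyond N map to N with a warning.
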