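# Methods

## Scope and data model

All coordinates are 0-based half-open; SAM, GFF3 and RepeatMasker `.out`
inputs are converted on ingest, BED is native. A read's 5′ end is `start` on
the plus strand and `end − 1` on the minus strand; this single accessor
drives window assignment, overlap math and feature attribution, which
removes the usual off-by-one ambiguity among the conventions. Sequences are
kept in DNA space (U ↦ T) and in read orientation (minus-strand reads
reverse-complemented). A collapsed read carries a `count` (collapse
multiplicity) and `copies` (number of best genomic mapping positions);
multi-mappers appear as one record per position and weigh `count/copies`
wherever normalization requires it, or are excluded entirely where an
analysis is defined on uniquely mapping reads (cluster discovery, the
stage-wise signature). Adapter trimming and genome alignment are upstream
concerns: rRNA/tRNA removal is implemented as interval masking against a
user-supplied annotation, not re-alignment.

The BED dialect is BED6 plus `count` and `copies` columns, with an optional
ninth column carrying the read sequence so a library round-trips losslessly;
when absent, sequences can be filled from a genome FASTA.

## Cluster discovery

Windows (default 10 kb) tile each chromosome from zero; the default step
equals the window size. A non-overlapping tiling is deterministic, and
because passing windows within the merge distance (20 kb) are fused anyway,
a sub-window step changes little; the step is configurable for users who
want a true sliding scan, and the brute-force oracle tests cover both. A
window passes when it holds at least `min_reads` (1000) unique 25–35-nt
read counts **and** at least `min_fraction` (10⁻⁴, i.e. 0.01 %) of the
pooled unique piRNA total — the absolute cut-off governs small libraries,
the relative one deep ones. Cluster strand counts are re-tallied from reads
whose 5′ end lies in the merged span; a read overhanging the boundary with
its 5′ end inside is counted, one with only its 3′ portion inside is not.
Dominance ties break toward `+` and are flagged; ranking ties break by
genomic order for determinism.

## Nucleotide matrices

Frequencies are count-weighted by default (library-level logos); an
unweighted mode treats each distinct sequence once. Reads shorter than a
position leave its denominator (no padding), and zero-support rows are
flagged rather than NaN-propagated. Reads containing N are counted
everywhere else but excluded from matrices to keep a four-letter alphabet.
Information content is `2 + Σ f log₂ f` with `0·log 0 := 0`, bounded in
[0, 2] bits.

## Ping-pong signature

The 5′–5′ overlap of a plus/minus pair is `o = 5′(−) − 5′(+) + 1`, so
coincident 5′ ends give o = 1 and the ping-pong configuration gives o = 10:
positions 1–10 of the two reads are base-paired, putting the 10A of one
opposite the 1U of the other. The 3′–3′ convention is the mirror image on
3′ ends and is computed for completeness but not used in headline metrics.

Descriptions of the scaled signature in the literature — scaling pair
counts by each read's count and by its partners' counts relative to all of
that read's partners, symmetrically over both strands — admit several
readings. The definition fixed
here: for each partnered read `s` with summed partner counts `A_o(s)` at
offset `o`, the contribution to `o` is `count(s) · A_o(s) / Σ_o′ A_o′(s)`;
contributions are accumulated over the reads of both strands and the vector
is normalized to sum to one. This makes the signature invariant to uniform
count rescaling and bounded per read, and it reduces to the intuitive "each
read votes with its count, split by where its partners sit". The simpler
percentage-of-partnered-reads vector is always emitted alongside for
comparability with other tools. Two implementations exist — an explicit
pair-list route and an anchor-indexed vectorised route — and the test suite
requires them (and an O(n²) enumeration oracle) to agree exactly.

## TE enrichment

TE annotations are merged before computing per-window covered fractions so
overlapping entries are not double-counted; windows shorter than 1 kb at
region ends are dropped to keep denominators comparable. Permutations draw
cluster-set-sized window samples without replacement from the genome-wide
tiling (which may include cluster windows, mirroring unrestricted random
sampling); the cluster-excluded background mean is reported separately as a
baseline. The empirical p-value uses the add-one rule, so its floor is
`1/(n_perm+1)` and it is never zero; calibration under an exchangeable null
is covered by a dedicated test (uniformity of p on its attainable grid).

## Feature coverage and maternal/zygotic pooling

A read assigns to the features containing its 5′ end; when several
same-eligibility features overlap there, its count is split equally among
them, which conserves totals by construction. RPKM is
`counts / (library_total/10⁶) / (length/10³)` with the 25–35-nt unique
total as denominator. Maternal = {oocyte, 0–5 h}; zygotic = every stage
from 8 h on. Fold changes use a pseudocount of 1 normalized unit (the
data leave zero-handling open; the pseudocount keeps features absent from
one pool finite and barely perturbs well-covered ones) and classify at
2× / 0.5× thresholds. Spearman correlation of log₂ fold changes uses
mid-ranked ties and the t-approximation p-value (scipy). Gene-level TE
relatedness is reduced to "a TE annotation overlaps the gene span";
homology- and GO-based criteria are accepted as a precomputed flag column
since they depend on external annotation pipelines.

## The simulator

`simulate_genome` draws an i.i.d. uniform background genome (default 4 × 
1.25 Mb), plants 8 non-overlapping clusters (lengths U(60, 120) kb, random
dominant strand, lognormal expression weight) and, per cluster, 8 copies of
~1.5-kb TE consensus sequences with 1 % per-copy substitution, always
oriented antisense to the dominant strand. Each insertion gets a one-exon
TE-ORF gene annotation extended by 500 bp of flanking sequence on each side
— the transcript read-through that real elements show — which also places a
realistic share of secondary piRNAs on uniquely mapping sequence. Each gene
carries a maternal transcript level (lognormal) and an activation factor
(~4× lognormal for the 70 % of genes planted as zygotically activated,
≈ 1 otherwise).

`simulate_libraries` generates, per stage: primary piRNAs (5′ ends inside
clusters, dominant strand with probability 0.8 — a 4:1 strand bias — and a
5′-U with probability exactly `p_1U = 0.8`, implemented as a mixture over
U-start and non-U-start positions so the planted fraction is exact; lengths
⌊N(28, 1.5)⌉ clipped to [25, 35]); secondary piRNAs in ping-pong-active
stages only (12 % of piRNA-class reads), each anchored at a 5′–5′ offset of
exactly 10 from a sampled primary template inside a TE gene, genes drawn in
proportion to their zygotic transcript level — so the 10A bias *emerges*
from complementarity with the template's 1U rather than being a parameter;
22-nt miRNA-like reads from fixed non-cluster loci (15 %); and uniform
degradation background (10 %). Reads are collapsed by sequence; mapping
positions are recovered by exact sequence re-lookup restricted to TE
neighbourhoods (the i.i.d. background makes off-TE 25-mer collisions
vanishingly rare, ~5·10⁶ positions against 4²⁵ possible words), giving a
realistic mixture of unique and multi-mapping records. Consensus-space TE
alignments are generated directly with a planted pooled antisense share of
0.75 (maternal stages antisense-heavier, zygotic sense-heavier by ±0.10),
since in the intended workflow consensus alignment is an upstream input,
not something derived from genome mappings. All randomness flows from one
root seed through named substreams; identical parameters and seed reproduce
every file byte-for-byte.

What the simulator does **not** model: indels and sequencing errors, TE
phylogeny and age structure, RNA secondary structure, length-dependent
ligation biases, and chimeric/junction reads. Passing the recovery tests
therefore demonstrates the correctness of the pipeline's logic under the
stated generative assumptions, not robustness to every artefact of real
libraries.

### Default scale and calibration

The default study design — ≈ 5 Mb genome, 8 clusters, four stages (two
maternal, two ping-pong-active) at 200 000 reads each — keeps a full
end-to-end run around a minute on one CPU while leaving every per-window
and per-gene statistic deeply sampled. Cluster lengths of 60–120 kb make
base-level recovery meaningful against 10-kb window quantization (an edge
window passes only where the planted cluster contributes ≥ `min_reads`, so
boundary overhang costs a few kb per edge). The secondary rate (0.12) and
the gene expression spreads were chosen so that the planted contrasts are
unambiguous at this depth: offset-10 participation among unique cluster
reads roughly doubles at activation, and zygotically activated genes gain
enough sense piRNA to clear the 2× classification threshold. Tests scale
the genome and depth down further where full scale adds nothing.

## Numerical conventions

Empirical p-values use the add-one rule; normalized signature vectors sum
to 1 ± 10⁻⁹ when any pair exists and are flagged (not NaN) otherwise;
degenerate inputs (zero sense reads for a locus fraction, empty TE
orientation input, sub-3-pair correlations) return flagged/None results
rather than raising; dominance and ranking tie-breaks are deterministic as
described above.

## Known limitations

Real multi-mapper handling depends on the upstream aligner's best-hit
policy, which the BED/SAM ingester takes at face value (NH tags or the
`copies` column). The per-gene mRNA quantification is consumed as a
normalized table; no variance model or replicate-aware differential test is
applied, matching the descriptive fold-change analysis this package
implements. Uni- vs dual-stranded cluster classification is deliberately
not automated: the evidence comes from the bias and overlap signatures,
which are reported per cluster strand instead.
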