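# Methods

## Problem and model

Oxford Nanopore library preparation ligates short synthetic adapters to
both ends of each DNA/cDNA fragment, so raw reads carry a full or
partial adapter at their extremities. When the adapter sequences are
undocumented (old kits, custom protocols, public data without
metadata), database-driven trimmers have nothing to look for.
`nanoadapt` infers the adapters from the reads alone, exploiting one
signal only: at the read extremities, adapter-derived k-mers are
massively over-represented relative to the biological background, even
under ONT error rates.

The method runs in four stages:

1. **Sampling.** Draw `n_samples` (default 10) independent read samples
   of `sample_size` (default 40 000) reads, uniformly without
   replacement within a sample; samples may overlap each other. From
   every sampled read take the first and last `region_len` (default
   100) bases. Reads shorter than the region contribute whole;
   discarding them would bias small datasets and adapters on short
   reads are still informative.
2. **Approximate k-mer counting.** For each sample and each end, count
   for every k-mer (default k=16, small enough to fit inside every
   known adapter) the number of start positions where a substring
   aligns to it within `max_edits` edits (default 1, ≈6% tolerance —
   within ONT error rates). Each position counts once regardless of how
   many distances or substring lengths realize the match. The candidate
   universe is the set of k-mers occurring exactly at least once.
3. **Assembly.** The `graph_limit` (default 500) highest-count k-mers
   form a directed overlap graph (edges = k−1 overlaps, node weight =
   approximate count). The per-sample candidate adapter is spelled from
   a greedy bidirectional heaviest simple path: seed at the heaviest
   node, repeatedly extend the end whose best unvisited neighbor is
   heavier. Greedy extension is linear and deterministic where a
   maximum-weight simple path would be NP-hard (the graph can contain
   homopolymer self-loops and cycles); the no-revisit rule bounds the
   candidate length by `graph_limit + k − 1`.
4. **Consensus.** The per-sample candidates of each end are clustered
   by single-linkage under pairwise global-alignment identity ≥
   `cluster_identity` (default 0.75; identity = matched columns /
   alignment length). Each cluster is summarized by a progressive
   multiple alignment (longest member guides) with column-majority
   voting, and scored with `support` = members / `n_samples`. Clusters
   with support < `min_support` (default 0.3, low enough to admit a
   three-adapter mixture while suppressing singleton noise) are
   dropped.

All ties anywhere (k-mer ranking, seed choice, neighbor choice, column
votes) break lexicographically, so the whole pipeline is
bit-reproducible for a fixed seed.

## The no-adapter decision

A dataset without adapters must yield nothing. Assembly always returns
*some* path, so the pipeline measures what a path weight looks like on
adapter-free data with the same composition: each end's background is
estimated by running counting + assembly on dinucleotide-preserving
shuffles (random Eulerian walk on the dinucleotide transition graph) of
the first sample's regions, averaged over `background_replicates`
(default 3). A cluster is reported only when its members' mean path
weight exceeds `background_factor` (default 10) × the background. The
margin in practice is enormous: a planted start adapter at 90%
prevalence gives path weights around 10^5 against backgrounds of a few
tens; even the sparse signal of a half-prevalent, 80%-truncated end
adapter sits an order of magnitude above threshold. The factor 10 was
chosen as a round number comfortably above the ~3× run-to-run spread of
background weights and far below any real signal observed.

## Counting backend

Counting is contract-driven; the backend is an engineering choice. For
`max_edits ≤ 1` the regions (split at N — an alignment substring may
never contain N, since N carries no base information) are 2-bit packed,
and all windows of length k−1, k and k+1 are indexed in sorted arrays.
A position matches a query at ≤1 edit iff its window of one of those
three lengths is the query, a substitution, a deletion or an insertion
of it. Substitution-class matches are disjoint by construction and are
counted with array lookups; for the (few) queries with non-empty
deletion/insertion classes the per-position sets are merged exactly, so
nothing is double-counted. For `max_edits ≥ 2` a per-position banded
edit-distance scan (edlib, prefix mode) is used instead. Both paths are
verified against a naive per-position DP oracle on random instances.

One consequence of per-start-position counting worth knowing: a
position adjacent to an exact occurrence also matches at one edit (the
"indel shadow"), so interior k-mers of a frequent motif count roughly
three times its occurrence number, while the motif's terminal k-mers
count roughly twice. This does not disturb which k-mers reach the top
of the table, but it explains why assembled candidates often carry one
or a few extra flanking bases: single-base extensions of the true
adapter inherit most of its count through the deletion route. The
cross-sample consensus trims ragged ends carried by fewer than half of
the members, and the per-position counts make the artifact stable,
small (1–4 nt) and harmless to trimming.

For large samples the pipeline evaluates approximate counts only for
the `candidate_limit` (default 2000) k-mers with the highest exact
counts and ranks those; a 40 000-read sample holds ~3.4M distinct
16-mers, almost all singletons, and no k-mer outside the exact top
2000 can reach the approximate top 500 in practice (adapter k-mers
have exact counts in the thousands; background ones a handful).
`candidate_limit=None` evaluates every exactly-occurring k-mer and is
the reference behavior.

## Trimming

Inferred (or user-supplied) adapters are placed in a `search_len`
(default 150 nt, Porechop's window) window at the relevant read end by
overlap alignment (match/mismatch/gap = +1/−1/−1, end gaps free on both
sequences), so a partial adapter may overhang the read boundary — the
footprint of an incompletely sequenced end adapter. A hit requires
identity ≥ `identity_threshold` (default 0.75, Porechop's default) over
the aligned columns **and** at least `min_overlap` (default 18) adapter
bases aligned. The overlap guard is needed because identity alone over
a short aligned region is weak evidence: a random 150-nt window matches
some ≤8-nt adapter fragment at its edge with high probability, and even
at 14 aligned bases the 0.75 bar admits 3 edits, which random windows
clear about 0.3% of the time. At 18 nt the edit ball is a vanishing
fraction of sequence space (~10⁻⁵ false placements per read end), so
adapter-free data is left untouched and a second trimming pass removes
<0.5% additional bases.
Cuts remove `extra` = 2 nt beyond the hit (Porechop's default); reads
shorter than `min_len` after trimming are dropped.

## Synthetic data

The simulator emulates the footprint of BadRead-style ONT reads: a
start adapter on 90% of reads; an end adapter on 50% of reads, retained
from its 5′ side (the side adjacent to the insert — the read simply
stops partway through the adapter) with retained length drawn from a
truncated geometric distribution whose mean is exactly
`end_retained_mean_frac` (default 20%) of the adapter; uniform random
inserts of 300–2000 nt (long enough that the two 100-nt regions are
disjoint and carry biological flank), or substrings of a user FASTA;
then per-base edit noise at `error_rate` (default 5%), split equally
between mismatch, insertion and deletion. True adapter intervals are
mapped through the indels. Flat quality strings.

What the simulator does **not** model: position-dependent and
homopolymer-correlated ONT errors, quality values, chimeras, barcodes,
non-uniform (transcriptome-like) insert composition with its repeated
sequences. Passing tests therefore demonstrate the machinery under the
stated prevalence/noise conditions, not performance on arbitrary real
libraries — in particular, highly repetitive biological content near
read ends could raise the background in ways uniform inserts do not.

Negative datasets come in the two standard flavors: i.i.d. uniform
reads matching an input's length distribution, and input reads with
both 100-nt extremity regions removed (reads ≤200 nt dropped).

## Problem sizes and determinism

The shipped end-to-end checks use a 100 000-read simulation (10
samples of 40 000 reads drawn from it) for the single-adapter
experiment, a 400 000-read simulation for the two-adapter mixture,
10 000-read datasets for the 20+20 negative controls, and a fixed seed
throughout; every random draw flows from `numpy.random.default_rng`
seeded explicitly. The mixture needs the larger dataset: with two
equal-frequency adapters, which adapter a sample's candidate follows
is decided by counting noise, and only samples that barely overlap
(40k of 400k reads) make that an unbiased coin flip per sample — on a
heavily re-sampled small dataset the samples share their noise and all
collapse onto one adapter. The two consensus supports then scatter
binomially around 50%, and their mean is the stable summary.

The mixture uses a random 30-mer and its reverse as the two adapters.
This is deliberate: approximate counts are not composition-neutral
(k-mers containing low-complexity runs survive edit noise at slightly
higher rates), so for an arbitrary random pair one adapter's k-mers
out-count the other's *systematically* and that adapter wins every
sample, collapsing the mixture to a single 100%-support consensus. A
sequence and its reverse share base composition and run-length
profile, so both adapters are equally countable — the situation real
mixed libraries present, where the co-occurring adapters are composite
variants from the same kit family.

## Known limitations

- Middle-of-read adapters (chimera splitting) and barcode
  demultiplexing are out of scope.
- Adapters shorter than k (16 nt) cannot be assembled from 16-mers;
  lower k for such cases.
- The candidate-per-sample step returns one path, so more than ~3
  distinct adapters per end (each below the default `min_support`)
  would be under-reported; lower `min_support` and raise `n_samples`
  for exotic mixtures.
- Support counts cluster membership of per-sample candidates; it is not
  a per-read prevalence estimate.
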