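# Methods

## The measurement being modelled

A tagged non-LTR retrotransposon is mobilised in *D. discoideum* cells;
clones that completed a retrotransposition cycle are selected and pooled.
LAM-PCR extends a biotinylated primer from the element's marked ORF1 across
the element 5′ end into flanking genomic DNA, so each amplicon spans
`[primer … element 5′ part | extra nucleotides | genomic flank | library
primer]`.  Two library designs bound the genomic side: parallel PCRs with
tRNA-gene-family primers ("tdna") or second-strand synthesis from an
adapter-linked random hexamer ("adapter").  The quantity of interest per
read is the junction: which Pol III target was hit, at what distance from
its +1 nucleotide, with what 5′ truncation of the element and what
non-templated extra bases.

Integration is orientation-specific: the element 5′ end faces the 5′ end of
the targeted gene.  On a plus-strand target the element therefore sits in
minus orientation immediately upstream, and the merged read (element
strand) reads `revcomp(gene…spacer) + extras + element`.

## Coordinate and distance conventions

* All coordinates are 1-based, both-ends-inclusive, plus-strand; BED output
  converts to 0-based half-open at the file boundary only.
* A/B-box spacing is counted as bases strictly between the A-box end and
  the B-box start (the functional range used is 30–60 bp; planted tRNA
  genes use 32–57 bp).  The spacing convention is recorded in the catalog
  header so alternative conventions remain comparable.
* The +1 lies `plus_one_offset` (default 7) bp upstream of the A-box start
  on the target strand; the A box of a tRNA gene is fixed at +8.
* Integration distance is the number of genomic bases strictly between the
  element's 5′-terminal nucleotide and the target's +1.  Extra nucleotides
  are element-side: they are excluded from the distance.  Target-site
  duplications are not separately called; TSD bases count as genomic.
  These two choices are configurable conventions; distances under a
  different convention shift by the extras/TSD length.

## Catalog construction

B boxes are found by IUPAC scan (`GTTCRANNC`), on both strands; a reference
`N` matches only a motif `N` by default.  For each B box, permissive A-box
matches (`TNNNNNANNNG`) upstream at functional spacing are collected and
labelled stringent when they also match `TRRYNNARYNG`.  One target is
emitted per B box with at least one partner: the stringent partner if any,
else the permissive partner nearest the spacing midpoint.  Solo B boxes are
recorded but are not targets — a bare B box binds TFIIIC but is a poor
integration target; a flag can promote them for sensitivity studies.
Targets whose upstream flanks (default 200 bp) are identical strings share
a duplicate group; placements tied across one group are reported on the
group, mirroring how mirrored palindrome loci are indistinguishable.

## Alignment and hit acceptance

The seeded aligner collects exact k-mer seeds (k = 11), clusters them by
diagonal, and extends each cluster window with full affine Smith–Waterman
(match +1, mismatch −1, gap open −2, gap extend −1).  The horizontal gap
term is computed with a prefix-max scan, which is exact for affine scoring
because re-opening a gap immediately after closing one is never optimal
when the open penalty is at least the extend penalty.  Clusters need at
least two seeds (a clean 12-mer) before extension; this suppresses chance
single-k-mer windows in A+T-rich DNA and is the sense in which "no hit
above seed threshold" is meant.

Acceptance: unique hits pass; with multiple hits the best passes iff the
second-best score is ≤ 75% of the best ("not exceed" read as inclusive) and
the fragment aligns over ≥ 95% of its length (inclusive; applied to unique
hits as well, switchable).  The 75% ratio is scheme-relative — it operates
on whatever score the aligner reports.  Up to 8 unaligned bases at the
junction end of the fragment are exempt from the coverage denominator:
they are candidate non-templated extras, which are element-side rather than
genomic.  Without this exemption a 40-nt genomic part carrying 3 extras
could never reach 95% coverage, and short-distance junctions would be
unrecoverable by construction.

## Synthetic data: what it emulates, what it does not

The generator plants, at desk scale, the features the pipeline must
resolve: an A+T-rich background (GC 0.25); tRNA genes with +1 G, a
stringent A box at +8, and a B box at 32–57 bp spacing, grouped into
families that share the gene sequence (so family primers cross-map) while
flanks stay unique; a two-arm mirror palindrome with stringent and
permissive-only A/B-box loci, solo B boxes, and a 5S-like gene (duplicate
groups arise from the mirror symmetry); a 300-bp element analog carrying a
42-bp retained 5′-UTR and nested/LAM primer sites; and a plasmid context
emulating the transformed copy, whose reads form the *actin6*-promoter
accounting category.

Defaults are the study conditions where stated: integration distances are
integer-Gaussian (mean 47, sd 2) truncated to 23–181 bp; pseudoreads carry
a 42-bp retained UTR; reads are 300 bp paired-end; extra nucleotides are
1–3 bp (probability 0.4); 5′ truncations are geometric (p 0.3, probability
0.3, capped at 40 bp); TSDs are uniform 0–15 bp (lengths are not reported
in the source system; the range is configurable); substitution error rate
0.005; 2–8 reads per event; 5% background split evenly between plasmid and
unrelated genome.  Scale parameters are the package's own choice: a 120-kb
chromosome with 40 tRNA genes in 20 families, 9-kb palindrome arms, 500
events per run.  The generator does not model PCR chimeras, quality decay,
indel sequencing errors, or hot-spot amplification bias (the bias summary
is computed downstream, not planted), so passing tests demonstrate correct
junction arithmetic and filtering — not robustness to artifact structure in
real libraries.

### Exact-recovery construction

A junction is only identifiable if its boundary bases do not, by chance,
match their neighbours: a truncated element base matching the adjacent
extra/genomic base lets the element match over-extend, and an extra base
matching the displaced reference base lets the genomic alignment cross the
junction.  The generator therefore re-samples candidate events until a
gapless prefix check *and* a self-check with the actual aligner (element
side and genome side) recover the planted (distance, truncation, extras)
exactly; a complete 5′ end with no extras is provably always recoverable
and skips the aligner check.  Event keys (target group, distance,
truncation, extras) are unique per run.  This makes "error-free recovery
is exact" a well-defined property; at 0.5% error, recall stays ≥ 0.95 and
precision over events with ≥ 2 supporting reads ≥ 0.99 (single-read events
are kept but flagged; sequencing errors adjacent to the junction surface
as spurious singletons).

## Numerical and degenerate-input choices

* Merging: best overlap by lowest mismatch rate, ties to the longer
  overlap; conflicting bases take the higher-quality call; minimum overlap
  10 bp at ≤ 10% mismatches; merged reads < 100 nt are rejected.
* Primer matching allows 1 substitution (exact matching via config).
* Element location: best local alignment of either read orientation
  against the element (≥ 20 bp, ≤ 10% divergence); a cheap shared-k-mer
  count picks the orientation first.  Reads with no element segment are
  categorised, not errors.
* Ties in alignment score resolve to the first-encountered cell
  (row-major), making every stage deterministic; `argmax` order, sort keys
  and event keys are all total orders.
* Empty inputs: empty event tables produce empty histograms and an
  undefined (None) window fraction; an empty reference set is a
  configuration error.
* The hot-spot "expected average" keeps its exact value internally and a
  rounded value for display (506 for 205,020 reads over 405 targets);
  "above average" is strict inequality.

## Stage accounting

Every assembled pseudoread ends in exactly one terminal category
(no element / no nested primer / too short / unplaced / plasmid-promoter /
assigned to a chromosomal target / assigned on the palindrome / remaining),
so terminal counts sum to the number of assembled pseudoreads on every run;
the ordered stage table mirrors the accounting used for such experiments.

## Known limitations

* The aligner only reports hits reachable from two exact k-mer seeds;
  heavily mutated fragments (no clean 12-mer) are unplaced rather than
  rescued.
* Chimeric/split placements are rejected, not called (such reads are
  treated as PCR artifacts).
* Whether reported distances include extras or TSD bases differs between
  conventions; this package's convention is internally consistent but may
  differ by 1–2 bp from others.
* Desk-scale defaults do not reproduce genome-scale target counts; scale
  parameters are exposed for larger runs.
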