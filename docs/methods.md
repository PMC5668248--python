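# Methods

This note documents the models behind each pipeline stage, the
parameters that matter, the numerical choices, and what the synthetic
data generator does and does not emulate.

## RNA secondary-structure model

The hairpin criteria need a ranking of candidate stem-loops against a
single free-energy bound, not Turner-accurate thermodynamics, so the
built-in folder uses a deliberately compact nearest-neighbor model:

* Pairs: Watson–Crick (A:U, G:C) and wobble (G:U); N never pairs.
* Nested structures only (no pseudoknots); hairpin loops keep ≥ 3
  unpaired bases.
* Energy = stacking terms for adjacent pairs + fixed loop penalties.
  Stacking is a 16-entry table keyed by the 5′-side dinucleotide step
  of the two stacked pairs (values in `rna_fold.STACKING_KCAL`,
  −0.2 to −1.3 kcal/mol); loop penalties are +3.0 per hairpin loop,
  +2.0 per bulge/internal loop, +3.0 per multiloop, 0 for the exterior
  loop. Bulge/internal loops are capped at 10 unpaired bases in total;
  larger two-loops are simply not formed.
* The table's scale was chosen so that random background windows
  (~100 nt) fold around −5 to −13 kcal/mol while genuine precursor-like
  duplexes (a ~21-bp stem on a G/C-anchored base) fold well below −30.
  With a more literally thermodynamic scale, random windows alone cross
  the −20 kcal/mol acceptance bound and the criterion stops
  discriminating; absolute MFE values are model-dependent, which is
  also why the bound itself is configurable. The nonzero multiloop
  penalty keeps the minimum-energy structure from splitting an
  interrupted stem into free multi-branch detours.

The minimization is an interval dynamic programme (V/WM1/WM2/W tables,
O(n³)); energies are carried as integers in tenths of kcal/mol so tie
detection is exact, and ties break toward fewer pairs, then the
lexicographically smaller dot-bracket, making every fold deterministic.
The engine is validated against exhaustive enumeration of all nested
structures for every sequence up to 8 nt and hundreds of random 9–12-mers
(energy and tie-broken structure both equal). Any external folder that
prints a dot-bracket plus energy (ViennaRNA's `RNAfold --noPS`, for
example) can replace the built-in model through the command-backend
contract; the acceptance properties in the test suite are stated against
the built-in model only.

Hairpin anatomy: the *maximal stem* is the hairpin whose chain of
single-branch enclosing pairs contains the most pairs (ties: leftmost).
Positions are classified as 5′ arm, 3′ arm, terminal loop, or unpaired
tail relative to that stem. Duplex mismatches of a mature span are the
positions unpaired or paired outside the opposite arm; a span reaching
into the terminal loop or across both arms is a one-arm violation, not
a mismatch count.

## miRNA identification

Homology search is a direct Hamming scan of every transcript window
(both strands) against each mature sequence, with two tiers: matches at
0 mismatches keep the reference family name; matches with 1–4 mismatches
are retained as putative/novel candidates and renamed miR-f\<digits\>.
The e-value is a plain occurrence expectation,
`db_length × transcript_length × 4^(−matched_positions)`, filtered at
1e-5 by default — a monotone chance-occurrence filter, not a
Karlin–Altschul statistic.

The six acceptance criteria are evaluated on the folded precursor
window (default flank 120 nt each side of the mature; the synthetic
test path uses 80 nt, which fully covers the engineered precursors at
~180-nt windows):

1. `is_candidate` — the window was selected;
2. `has_hairpin` — the maximal stem has ≥ 12 pairs (enough to host a
   ~21-nt mature at < 7 mismatches) enclosing one terminal loop;
3. `mature_in_one_arm` — every mature position classifies to the same
   arm;
4. `duplex_mismatch_ok` — duplex mismatches < 7 (strict);
5. `no_loop_or_break` — no mature base in the terminal loop and no
   unpaired run ≥ 3 strictly inside the mature pairing block;
6. `mfe_ok` — window MFE ≤ −20 kcal/mol.

A candidate is accepted exactly when all six hold. The "no loop or
break" phrase is qualitative in origin; the run-of-three
operationalization is this package's reading, and the leading/trailing
unpaired mature positions count toward criterion 4 but not 5 (they do
not "split" the block). The two mismatch numbers in circulation (100%
homology vs ≤ 4 mismatches) are reconciled as the two tiers above;
criterion 4's "< 7" applies to the hairpin duplex, not to reference
homology.

## Target prediction

Scoring follows the psRNATarget convention: the miRNA binds the site
antiparallel (miRNA position 1 faces the site's 3′ end); penalties are
match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, doubled over the core
(miRNA positions 2–13); only the first `upsize` = 20 positions are
scored; at most one gap per duplex (plant targeting is near-contiguous).
The per-site expectation is the minimal total over all gap placements,
found by exhaustive scan and verified against a brute-force recursive
aligner. Defaults: expectation cutoff 3, top 200 sites per miRNA, site
flanks 17 nt upstream / 13 nt downstream for the accessibility hook.
Overlapping hits collapse to the locally best site; on exact expectation
ties the gap-free site length wins (an unscored gap beyond position 20
must not displace a perfect site by one base), then transcript id and
start.

A *mismatch* state at miRNA positions 9–11 calls translational
inhibition; everything else is cleavage. A wobble at 9–11 does not
trigger the call by default (`wobble_counts` flips this), since the
penalty scheme treats wobbles as partial pairing.

Target-site accessibility (the "energy to unpair the site" criterion)
is implemented as an optional hook that folds the flanked window freely
and with the site masked to N, reporting the energy difference. It is
OFF by default: the built-in model's absolute energy scale is not
comparable to RNAup-style thresholds, so the 25 kcal/mol default would
be meaningless; when off, that parameter is ignored.

## Networks

The interaction matrix has A_ij = 1 exactly when miRNA i targets
transcript j; the bipartite graph draws directed miRNA→target edges and
drops isolated labels. Degrees, p(k) and the degree correlation use the
undirected view (neighborhood size has no direction). The degree
correlation is the standard endpoint-degree (assortativity) form

r = [⟨jk⟩ − ⟨(j+k)/2⟩²] / [⟨(j²+k²)/2⟩ − ⟨(j+k)/2⟩²]

with each undirected edge contributing both orderings of its endpoint
degrees; r is NaN when endpoint-degree variance is zero (regular
graphs). The implementation is checked against an independent
exact-rational evaluator on every connected graph with ≤ 6 nodes and
against networkx's assortativity coefficient.

Expression correlation has two modes: per-transcript (Pearson r between
a transcript's replicate FPKM vectors in the two conditions; requires
≥ 3 replicates) and cross-transcript (r between condition-mean vectors
over a transcript set). Published two-condition tables with one FPKM
per condition cannot support the per-transcript mode, which is why the
packaged fixture path selects its co-expression query genes by the
packaged rule: membership of a common-miRNA target in the packaged
query-gene table, joined through the symbol synonym table. That synonym
table (CMO, RPS5, … mapped to the long target names) is this package's
transcription; no FPKM/PCC threshold reproduces the published gene set,
so the packaged rule is membership itself, with `all` and `min_fpkm`
rules available for real data. Fixture regulation arrows are stored as
printed; validation reports rows whose arrow contradicts its own FPKM
values rather than silently correcting them.

## GO node scores

score(g) = Σ_{g_a ∈ desc(g)} gp(g_a) · α^dist(g, g_a), where desc(g)
includes g itself at distance 0 (otherwise a leaf's own annotations
would never count), gp is the number of transcripts directly annotated
to a term, dist is the shortest descending is_a path (DAGs can offer
several), and α ∈ (0, 1] decays distant descendants. α has no published
value; the default is 0.6 and it is surfaced prominently in the CLI.
Only is_a edges are traversed. At α = 1 the score collapses to the
subtree annotation total, which the tests verify on random DAGs.
Transcript scores sum the node scores of their direct annotations;
equal-score transcripts (relative tolerance 1e-9) form clusters, and
cluster pairs are linked with weight = number of distinct GO terms
annotating members on both sides (shared-ancestry weighting; the
alternative score-difference weighting was considered and not used).

## Co-expression

Component scores per query/candidate pair, each normalized to [0, 1]:
abundance = candidate mean FPKM rank-normalized over the candidate pool
(average ranks on ties; a singleton pool scores 1); GO = Jaccard overlap
of direct annotations; PCC = (r + 1)/2 over the genes' replicate FPKM
profiles (zero-variance profiles contribute r = 0). The combined score
is the weighted sum with defaults 0.4/0.3/0.3 (weights must sum to 1),
so an all-maximal candidate scores exactly 1. Per query the top k = 20
candidates by (descending combined, ascending gene id) become
neighbors; the published weighting reading "abundance value capped at
0.4" was rejected in favor of the weighted sum, which is the only
reading consistent with a total score of 1. How each component is
normalized is not published; the three choices above are this package's
defaults and are pluggable.

## Synthetic data

The generator emulates the study's inputs at desk scale: transcriptomes
of ~10 × 350–450 nt with planted precursors and target sites, layered
GO DAGs (single root, 1–2 parents per term from the layer above,
acyclic by construction, annotations on leaves), and log-normal
replicate FPKM tables (baseline ≈ 100 FPKM, 1.0 log-spread across
genes, per-condition mean shifts) with planted co-expressed groups.
Grouped genes share a latent log-scale factor with idiosyncratic noise
calibrated so the latent correlation equals the requested ρ; at ρ = 1
profiles are exact scalar multiples and the Pearson correlation is
exactly 1. Grouped genes carry no independent condition effect — an
uncorrelated condition shift would attenuate the planted correlation
below its nominal value.

Planted precursors are engineered hairpins
`[base clamp] mature [top clamp] loop [rc top] star [rc base]` with
G/C clamps (14 bp) anchoring the intended stem. The compliance profiles
are: `all_pass` (perfect duplex, both clamps); `fail_mfe` (A/U-only
mature, 4-bp top clamp, no base clamp — a genuine but weak hairpin);
`fail_arm` (star complements only the mature's 3′ 15 nt, leaving six 5′
bases outside the stem); `fail_mismatches` (seven 1:1 internal-loop
substitutions in runs ≤ 2); `fail_loop` (star omits four central
complements, an unpaired run of 4). Three engineering rules keep each
profile's verdict exact under energy minimization: profiles whose
verdict depends on weak or absent pairing are hosted in A/C-only
background transcripts (A and C cannot pair with themselves, so the
background can neither invade the weak stem nor capture the dangling
tail, and the tail is all-A so nothing in an A/C host pairs it); the
mismatch profile uses a U-free mature whose substituted star positions
all face A (A pairs only U, so the mismatch faces cannot re-pair at any
register) and is rejection-sampled so each paired segment between
mismatch clusters carries enough G/C stacking to pay its loop
penalties; and both arms keep equal length there so the clamps lock the
register. Closed-loop tests assert, from the truth table, that every
`all_pass` plant is accepted and every single-violation plant is
rejected with exactly its intended flag false.

What the generator does **not** emulate: sequencing reads and their
error profiles, expression-dependent transcript coverage, isoforms and
UTR structure, realistic GO term depth/annotation sparsity, genome-scale
transcript counts, or miRNA families with multiple loci. Passing the
planted-recovery tests therefore shows the pipeline's logic is faithful
to its stated criteria on inputs where ground truth is known — not that
the criteria themselves recover real miRNAs at any particular
sensitivity on field data.

## Problem sizes and determinism

Test and acceptance runs use the generator defaults above with
precursor flank 80 nt (windows ≈ 180 nt, ~0.5 s per fold), 50 replicates
for correlation-recovery checks, and 100 random DAGs for the α = 1
closed form. All randomness flows from integer seeds through
`random.Random` / `numpy.random.default_rng`; identical seeds reproduce
byte-identical FASTA/TSV outputs, and pipeline runs write their config
digest into the manifest so a run is reproducible from the manifest
alone.

## Known limitations

* The folding model is intentionally coarse: absolute MFE values are
  not comparable to mfold/ViennaRNA, only the ranking and the
  configurable bound are meaningful. Use the command backend for
  thermodynamic accuracy (and recalibrate the MFE bound accordingly).
* The homology scan is O(transcripts × length × matures); fine at
  desk scale, but genome-scale inputs would want a seeded index.
* The e-value is an occurrence expectation, not a BLAST statistic;
  cutoffs are not transferable between the two.
* Per-transcript PCC needs replicate FPKM; one-value-per-condition
  tables must use the cross-transcript mode or the packaged selection
  rule.
* GO scoring traverses is_a only; part_of and regulates edges are out
  of scope.
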