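# Methods

This note documents the models, conventions and numerical choices behind
`famflux`, and what the simulator-backed tests do and do not establish.

## Dollo parsimony reconstruction

Gene presence/absence on a rooted species tree is reconstructed under the
Dollo model: one gain, unlimited losses. The gain is placed at the MRCA of
the present leaves; below it a node is present iff its subtree contains a
present leaf; every present→absent edge is a loss. Minimality argument:
below the gain, every maximal subtree containing no present leaf must be
severed by at least one loss on its entering edge, and the construction
spends exactly one loss per such subtree. The test suite nevertheless
checks equality against a brute-force enumeration of all single-gain
ancestral labelings on every rooted topology up to four leaves (all
presence patterns) and on random eight-leaf topologies (all 255 patterns).

Branch lengths are ignored (the reconstruction is purely topological), and
the result is invariant under child reordering. Presence is thresholded at
count ≥ 1; whether pseudogenes count as present is a property of the input
matrix, not of the algorithm — the packaged count table preserves the
published entries as printed, including entries that disagree with the
original running text (channel catfish taar13 is 8 in the table but
"seven" in the text; the table wins).

The manual-override hook (`apply_override`) relocates the gain to a chosen
ancestor of the inferred gain and recomputes losses, recording the original
gain and the cost delta. This mirrors survey practice when a small clade's
tree position is suspected to be distorted (classically: a handful of
cartilaginous-fish class II sequences grouping inside a derived subfamily
when they should sit ancestral to the class II duplication) — the analyst
prefers maximal parsimony on the species tree over the literal gene-tree
position, and the audit trail keeps that decision explicit.

## The species-tree fixture

The packaged Newick topology covers exactly the 76 species of the count
table and was encoded by hand from the published ordinal-level fish
phylogeny that repertoire surveys of this kind draw their species trees
from. It carries no branch lengths — every quantity computed from it is
topological — and labels the major clades (Percomorphaceae, Ovalentaria,
Eupercaria, Euteleosteomorpha, ...) on internal nodes so subtrees can be
extracted by name. Fine-grained arrangements inside clades where every
species has the same presence state (e.g. within Ovalentaria, where taar13
is absent throughout) cannot affect loss counts.

## Birth-death simulator

`simulate_family` runs a linear birth-death process along each branch:
every gene lineage independently duplicates at rate λ and dies at rate μ
per unit branch length (exponential waiting times), starting from `n0`
genes at the root. Lineages do not interact. At speciation nodes each
surviving lineage enters every daughter branch. The simulator emits the
complete event log, the genealogy of surviving genes (unifurcations
suppressed), and per-species counts; replaying the event log reproduces
the counts exactly, which the suite asserts across seeds.

Families have exactly one origin (the root), so the Dollo single-gain
assumption holds on simulated data by construction, making `min_losses ≤
true losses` a theorem the tests exercise rather than an approximation.
Equality can fail only when a branch hides events from presence data
(e.g. a duplication whose descendants all die on the same branch).

Default study conditions used by the calibration checks: λ = 0.5, μ = 0.25,
n0 = 2 on a unit branch for the closed-form mean comparison
(E[N(t)] = n0·e^{(λ−μ)t}, 2000 replicates, three-standard-error band);
λ = 0.4, μ = 0.5 on a six-species clock-like tree for the loss-bound check,
chosen so that losses are frequent but extinction is not near-certain.
These sizes keep the whole suite in the tens of seconds while leaving the
Monte-Carlo bands narrow enough to be informative.

## Sequence evolution and the fingerprint motif

Protein sequences evolve along the simulated genealogy under a uniform
replacement model: a site substitutes with probability 1 − e^{−rt} on a
branch of length t and the replacement is drawn uniformly from all 20
amino acids (so 1/20 of events are silent). This gives the closed-form
per-site match probability e^{−2rt} + (1 − e^{−2rt})/20 for two leaves at
path distance 2t, which the suite checks by Monte-Carlo.

Three regions are held invariant, emulating the conservation structure of
the receptor C-terminus: a 12-residue TM7 block (conserved in all
classes), the 14-column fingerprint motif whose two critical positions
carry the class-defining residues (Y/W for TAAR, N/S for jawed-fish TARL,
N/other for non-TAAR aminergic-type receptors), and a 6-residue C-terminal
cap. The initial methionine is also fixed so every simulated protein is a
complete ORF. The block and cap are not decorative: they pin the global
alignment to the profile anchor on both sides of the motif, so the
column map through which the critical residues are read is stable even
though the rest of a simulated sequence is random background. Without
them, tail noise can buy an alignment gap that shifts the critical columns
— a failure mode real receptor homologs do not exhibit, because their
conservation extends around the motif exactly as emulated here.

What the simulator does **not** model: indels, rate heterogeneity across
sites or lineages, codon usage (back-translation uses the alphabetically
first codon per residue), GC content, splice structure, or correlated
gene-family dynamics. Perfect classification and round-trip results on
simulated data therefore demonstrate the correctness of the pipeline's
logic, not its robustness to alignment-scale sequence artefacts in real
genomes.

## Candidate mining conventions

* E-value stopping: "e-value of −10" is read as the threshold 1e-10 and
  applied strictly-greater-than — a hit at exactly 1e-10 is retained.
* Hits flagged UNKNOWN are retained as candidates (downstream phylogeny
  decides) but break runs of consecutive off-target hits.
* ORF completion takes the reading frame from the hit-interval start,
  chooses the **farthest** in-frame ATG within the 2 kb upstream window not
  preceded (in frame, within the window) by a stop codon — the maximal
  open frame — and the first in-frame stop downstream. The translated
  protein includes the initial Met and excludes the stop, so a complete
  CDS of length L nt yields (L−3)/3 residues.
* The genomic embedding generator excludes in-frame ATG as well as stop
  codons from the flank within the extension window; excluding only stops
  would let a chance upstream ATG win the farthest-start rule and break
  the round-trip identity the generator is designed to guarantee.
* The 200-aa length filter is inclusive (≥ 200), with stop symbols not
  counted.
* Reverse-strand intervals are stored in forward coordinates with a strand
  flag; completion operates on the reverse complement.

## Alignment and identity

All identity percentages come from one fixed semi-global scheme: BLOSUM62,
affine gaps (first gap residue −10, each further −1), terminal gaps free.
Identity = matching columns / aligned columns, excluding columns inside a
terminal-gap overhang of either sequence, so identical sequences score
exactly 100 regardless of terminal trimming. Traceback ties resolve
diagonal > up > left; because that preference is directional, symmetry of
`percent_identity` is enforced by canonically ordering the two sequences
before aligning. The DP is compiled with numba; the suite checks the
optimal score against Biopython's `PairwiseAligner` under identical
scoring and the full (score, identity) pair against a separately written
plain-Python implementation.

The classifier's UNALIGNABLE floor is 3% of the anchor self-score
(≈ 20 for the packaged anchor). It is a coarse screen for garbage input
(short or low-complexity peptides score ≤ 9), not a homology test: a
full-length sequence passes the floor and is then judged solely by the
residues at the critical columns.

## Placement and naming

Placement walks from the candidate leaf rootward to the first enclosing
clade containing a reference leaf. A unique reference label is assigned
directly; mixed labels fall back to the patristically nearest reference in
that clade (missing branch lengths count as unit edges), and an exact
distance tie between distinct labels yields UNKNOWN — deterministic, and
invariant under ladderization and uniform branch scaling. Reference leaves
pass through with their own labels.

The identity shortcut for jawed-fish TARLs (best identity ≥ 85% against
any reference) is a screening pre-label only; placement always decides.
When motif and placement labels disagree, both are reported — the package
deliberately does not arbitrate.

Gene naming follows phylogenetic position: subfamilies numbered from
least-derived (shortest root path of their ancestral node), genes lettered
a, b, c, ... by divergence order within the subfamily, formatted
`<SpeciesPrefix>-<family><number><letter>` (e.g. `Lec-tarl1a` for the
least-derived gene of subfamily 1). Ties break on the lexicographically
smallest leaf, names are injective within species × family, and adding a
new most-derived gene never renames existing ones. Automatic subfamily
delimitation (cutting at nodes whose children's species sets overlap,
i.e. ancient duplications) is available but flagged experimental;
curated partitions take precedence.

## Degenerate inputs and edge conventions

Empty FASTA files parse to empty collections; an empty count matrix
(header only) is valid. A family absent from every leaf is an error for
Dollo (there is nothing to reconstruct). Relative repertoire differences
with a zero denominator are reported as undefined (NA), not raised.
A single-leaf family tree names its gene `<prefix>-<family>1a`.

## Supplementary re-analysis

The ortholog-identity re-analysis of the published lamprey sequences
(mean best-hit identity 98% river-vs-arctic, 94% arctic-vs-sea) requires
the supplementary sequence file, which is third-party data and not
shipped. The machinery (`ortholog_stats`) is fully implemented and tested
on synthetic orthologs; placing the supplementary FASTA at
`si_data/si_file2.fasta` enables the corresponding test.

## Known limitations

* No probabilistic gene-tree/species-tree reconciliation: duplication
  counts are read from the count matrix, not from topology mapping.
* The placement classifier assumes the input tree is correctly rooted on
  an out-group reference.
* The NJ builder exists as test plumbing (placement tests run without
  external tree software); it is not a substitute for ML tree inference
  in a real survey.
* Desk-scale only: genome-scale homology search (tBLASTn), MSA
  construction (MAFFT) and ML tree building (PhyML) are upstream tools
  whose outputs this package consumes.
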