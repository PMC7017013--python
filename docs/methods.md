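# Methods

This note documents the models, conventions and numerical choices behind
`prodomainkit`, in the order the pipeline runs.

## Coordinates and ingest

Residue positions are 1-based inclusive everywhere; alignment columns are
1-based. FASTA/Clustal parsing is delegated to Biopython. On ingest,
sequences are uppercased, `*` stop characters are stripped, and the
ambiguity letters B, Z, U, O, J are mapped to X (with a warning) so that
every downstream scoring step is total. X scores at the substitution-matrix
floor and, like a gap, excludes its column from informative-site counting.

## Cleavage-site model (`cleave`)

The consensus proprotein-convertase site is the tetrapeptide R-X-[R/K]-R.
All (possibly overlapping) matches are enumerated; cleavage is placed
C-terminal to the motif's final arginine, so the prodomain retains the
motif. This choice is consistent with Furin biochemistry; the alternative
convention only shifts every boundary by four residues.

The cystine knot is located without any external annotation: scanning from
the C-terminus, the maximal run of ≥ 6 cysteines in which consecutive
cysteines are ≤ 50 residues apart; the knot starts at that run's first
cysteine. Both parameters are exposed (`min_cys`, `max_gap`); the defaults
accommodate knots with 7 or 9 cysteines and the long loops of outliers
without absorbing distant prodomain cysteines.

Among candidate sites, the one whose final R lies closest upstream of the
knot wins; consensus matches always outrank the single-arginine fallback,
and a fallback R must lie within 100 residues of the knot (logged). A
per-record override supports manually curated sites. The spacer —
everything between the chosen R and the first knot cysteine — must be
cysteine-free; a cysteine there indicates an inconsistent knot call and is
an error, not silently absorbed.

Spacer analytics: per-record lengths, the acidic-upstream flag (is the
residue immediately N-terminal of the first knot cysteine D or E),
min/max with argmin/argmax ids, and per-subfamily acidic tallies. Pairwise
spacer similarity uses the package's global aligner; identity% and
similarity% are computed over **all** alignment columns (gap columns count
in the denominator), similarity per the BoxShade groups below. Containment
("how many of spacer A's residues appear in window B") uses multiset
semantics: duplicated residues count once per copy.

## Alignment (`align`)

The pipeline is self-contained: pairwise alignment is affine-gap
Needleman–Wunsch (Gotoh three-state DP) with BLOSUM62, gap open −10 for the
first gapped column and −1 per extension, terminal gaps penalised.
Traceback tie-breaking is fixed — match/mismatch preferred over a gap in
the first sequence, preferred over a gap in the second — so alignments are
deterministic. The DP is verified against an exhaustive alignment
enumerator for short sequences in the test suite.

Multiple alignment is progressive: a guide tree is built by neighbor
joining on k-mer distances (k = 3, multiset-shared fraction), midpoint
rooted, and profiles are merged bottom-up with average sum-of-pairs column
scoring. Output row order equals input order, and every row is asserted to
ungap back to its input. Externally computed alignments can be supplied in
place of the built-in aligner for study-scale work.

Parsimony-informative sites follow the standard criterion under complete
deletion: columns containing any gap or X are excluded; a retained column
is informative iff ≥ 2 distinct residues each occur ≥ 2 times. The looser
prose definition sometimes used ("a residue in virtually every member…")
is deliberately not implemented; the strict rule is reproducible and
matches what standard phylogenetics software reports.

## Subfamily assignment (`classify`)

Cores must be user-specified and contain ≥ 4 members (informativeness is
undefined below 4 rows; note that a seed core of 2, as a strict reading of
"recent duplications" sometimes yields, is below this floor — the package
requires the user to widen such a core). Each round evaluates every
remaining (candidate, subfamily) pair: the candidate is aligned into the
core from raw sequences (alignments are cached by membership, never
edited), and the reduction

```
delta = informative(core) − informative(core + candidate)
```

is computed. The globally best pair — smallest delta, an *increase*
counting as a negative reduction that sorts first — is committed; ties
break by fewer gap characters in the core+1 alignment, then shorter
alignment, then lexicographic subfamily name, then candidate id, giving a
total deterministic order. A step whose top two deltas differ by ≤ 1
(configurable) is flagged ambiguous, surfacing candidates with similar
effects on multiple subfamilies.

Two signals make the statistic work, and both require realistic family
structure: a candidate from the right subfamily completes residue pairs at
columns where a core sub-clade carries derived states (raising the
informative count), while a wrong-subfamily candidate brings
differently-sized loops whose gap columns destroy informative sites under
complete deletion. With gap-free, homogeneous families the statistic loses
its meaning — which is why the synthetic generator puts indel-prone loops
between conserved anchors (below).

## Conservation and cysteine motifs (`conserve`)

Shading follows BoxShade semantics at a cutoff of half the sequences
(inclusive; ceiling for odd N): a column is *identical* when one residue's
own count reaches the cutoff, else *similar* when a residue plus its
similarity-group partners reach it, using the disjoint groups
D/E, K/R/H, N/Q, S/T, I/L/V, F/W/Y, A/G. Gaps never count toward any
group. Group ties resolve to the first group in the configured order.

Structural features are supplied as an editable config of 1-based residue
ranges on a named reference sequence — the package ships no hard-coded
coordinates for real proteins, since exact boundaries belong to the
structure literature; ranges must be non-overlapping and are mapped to the
columns holding the reference residues. The cysteine scanner reads each
row's **ungapped** text within a mapped region (so an alignment gap inside
a motif cannot break it), classifies solo / CxC / CxxC with the longest
match preferred, anchors each motif at the alignment column of its first
cysteine, and groups rows sharing an anchor column — the operational
signature of a conserved, alignable cysteine pair.

## Trees (`trees`)

Distances use pairwise deletion (per-pair ungapped, non-X columns) —
prodomain alignments are gap-rich and complete deletion would discard most
of them — with either p-distance or a normalised BLOSUM score distance
(1 − 2S(a,b)/(S(a,a)+S(b,b)), floored at 0). Neighbor joining is
implemented directly (deterministic tie-breaking by lowest index pair;
negative branch lengths clamped to zero with the deficit logged) and is
cross-checked against an independent implementation in the tests. Support
values are nonparametric bootstrap proportions over column-resampled
replicates, deterministic given a seed; they occupy the tree's support slot
in place of Bayesian posteriors, so support-based statements are treated as
qualitative cluster statements rather than numeric reproductions.

The significance-threshold table maps the informative-position count of the
underlying alignment to the support needed to call a node significant:
> 150 → 0.95, 100–150 → 0.85, 50–100 → 0.65, 25–50 → 0.50; fewer than 25
informative positions is an error. Exact boundary counts (50, 100, 150)
take the lower band's threshold, logged — the published ranges overlap at
their boundaries and the lenient reading is the conservative one for
significance claims.

Trees are rooted on the outgroup leaf's edge. A clade query asks whether a
taxa set is exactly the leaf set of a rooted clade (singletons are present
with support 1.0 by convention); cross-partition comparison tabulates each
named cluster over the prodomain / ligand / full-length / cystine-knot
trees and flags clusters present in the prodomain tree but absent from both
the ligand and full-length trees. The cystine-knot partition is the ligand
truncated to start at the knot's first cysteine, computed from the cleavage
split.

## Synthetic families (`synth`)

The generator emulates a three-subfamily TGF-β-like family. The ancestral
proprotein is a segment plan: leader; an LTBP-like region; the straitjacket
(α1, Latency Lasso, α2, β1; rate multiplier 0.1); arm anchors (β2…β10,
multipliers 0.1–0.25) alternating with four fast, indel-prone loops
(multiplier 1.0); the invariant cleavage tetrapeptide; a cysteine-free
spacer; and a 100-residue knot with six invariant cysteines (spacings
15–18, all ≤ 50). Defaults: 3 subfamilies × 10 members plus one outgroup,
sequence length ≈ 400–500 aa.

Evolution is site-independent substitution with per-site gamma rates
(shape 1.0) times the segment multiplier; replacements are drawn from
BLOSUM62-conditioned frequencies (∝ exp(score/2)). Substitutions never
create or destroy cysteines: planted cysteines are invariant and C is
excluded from the replacement alphabet, i.e. cysteine turnover is modelled
as absent. This is the generator's strongest idealisation — real families
do gain and lose cysteines — so motif-recovery tests certify the scanner,
not robustness to cysteine turnover. Indels are confined to the leader,
spacer and loops, so every planted coordinate remains derivable; truth
stores post-indel coordinates.

Subfamily ancestors sit at the end of long stem branches (length 2.5) that
also carry heavy loop indels (sizes up to 25), making cross-subfamily
prodomain alignments gap-rich — the property the informative-sites
statistic depends on. Within a subfamily, the tree has a shallow
"recent duplication" core clade of 4 (branches 0.15–0.4) — the seed core
the assignment procedure starts from — plus deeper remaining members
(branches 0.1–0.3). Each subfamily template plants its own cleavage
tetrapeptide and cysteine motifs (CxxC / CxC / solo, first cysteine at the
same segment offset so anchors align across subfamilies). After evolution,
any spurious consensus motif upstream of the knot is neutralised by
mutating one constrained position of the match, guaranteeing the planted
site is the unique consensus site upstream of the knot.

An optional convergent pair (default on) copies 80% of the non-invariant
prodomain residues of one subfamily's designated leaf onto another
subfamily's leaf; both leaves attach basally in their subfamily trees, and
both are excluded from classification cores and pools. The fraction sits
in the window where the pair forms a clade in the prodomain tree but not in
the ligand or full-length trees, which is what the cross-partition
comparison is built to flag. The synthetic feature table gives the two
cysteine scan regions an 8-residue flank (their neighbours are
cysteine-free by construction) so loop-length jitter cannot push a row's
cysteines outside the mapped window.

Measured on these defaults across 12–20 seeds: cleavage-site and
cysteine-motif recovery are 100% in every realisation (they are structural
guarantees of the generator plus exact algorithms); subfamily-label
recovery of 15 withheld members is 100% in most realisations with
occasional drops to ~0.87 (one near-tie mis-assignment can cascade into a
poisoned core); the convergent pair was flagged prodomain-only in every
seed tested. The acceptance script therefore averages three replicate
families per run.

## Pipeline and reproducibility

`run_pipeline` orchestrates split → align → (optional classify) →
conserve → trees → compare for five grouping levels (each subfamily,
Activin+TGFB combined, all members), carrying the outgroup into every
grouping for rooting. All outputs are plain text (TSV, FASTA, Newick,
JSON); a manifest records the seed, bootstrap replicates and grouping
membership, and rerunning with the same inputs and seed reproduces every
output byte-identically (all randomness flows from `numpy`
`default_rng(seed)`; no iteration over unordered containers feeds the rng).
On stage failure, partial outputs are kept next to a `FAILED_<stage>`
marker.

Problem sizes used in the tests and the acceptance script — families of
31 records of ~400–500 aa, 10–100 bootstrap replicates, three acceptance
replicates — keep a full run in the minutes range on a single CPU while
exercising every code path at realistic divergence.

## Known limitations

- The aligner is a plain progressive profile aligner; it does not iterate,
  use sequence weighting, or model terminal-gap-free overhangs, and will
  not match the output of production aligners on hard cases. Study-scale
  work can import external alignments instead.
- Bootstrap proportions are not posterior probabilities; the significance
  table is applied to them by analogy, and per-node support values from
  Bayesian analyses are not reproducible here.
- The substitution model is not a reversible rate matrix; branch lengths
  are not interpretable as expected substitutions per site, only
  monotonically related.
- `greedy_assign` realigns cores each round; its cost grows roughly as
  (pool size)² × alignment cost, fine for tens of sequences but not for
  thousands.
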