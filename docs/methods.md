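# Methods

## Overview

`fragrank` matches tandem mass spectra to small-molecule structures in four
stages: (1) condense each molecule into a *metabolite graph*, (2) enumerate
its fragments into a budgeted *fragmentation graph*, (3) score each
candidate spectrum–molecule pair with a log-likelihood ratio over
peak-intensity ranks, (4) estimate false discovery rates against
mass-shuffled decoys. This note records the model assumptions, the
parameters that matter, the numerical conventions, and what the synthetic
data used for validation does and does not establish.

## Metabolite graphs

Only N–C, O–C and C–C single bonds are treated as breakable; they are the
frequent single bonds that contain no hydrogen atom, so their cleavage is
the dominant dissociation channel the model covers. Aromatic systems are
kekulized before the breakability test, so a benzene ring contributes
alternating single (breakable) and double (intact) carbon–carbon bonds.
Kekulization is made deterministic by renumbering atoms canonically first;
the same structure therefore always receives the same single/double
assignment regardless of input atom order. S–C, O–P and P–C cleavage is
supported behind the `breakable` parameter but disabled by default; in our
reading of the literature the expected gain is marginal and the smaller
label alphabet keeps the probability tables dense.

Monoisotopic atomic masses come from an embedded table (six decimals) rather
than from the chemistry toolkit, so masses are bit-stable across toolkit
versions. Records containing elements outside the table are rejected
explicitly, as are disconnected (multi-component) records.

## Fragmentation graphs

A fragment is a connected induced substructure of the metabolite graph,
encoded as a bitvector over graph nodes. Children of a fragment are the two
sides of each *bridge* and each *2-cut* of its induced subgraph. A 2-cut is
defined as an unordered pair of non-bridge edges whose joint removal
disconnects the fragment; pairs containing a bridge are excluded because
they are compositions of sequential bridge cuts and would double-count
depth. Each root-to-fragment path may use at most `max_bridges` (default 2)
bridge cuts and `max_two_cuts` (default 1) 2-cuts, in any order. Because a
fragment can be reachable under different budget splits (e.g. two bridges
vs one 2-cut), the search keeps the Pareto-minimal set of (bridges used,
2-cuts used) states per bitvector; fragments are deduplicated at their
minimum depth, ties between cut labels broken lexicographically.

Bridges and the component each bridge cuts off are obtained in one
iterative depth-first pass (Hopcroft–Tarjan lowpoints with DFS-subtree
bitmasks); parallel edges are handled by tracking the incoming edge index,
so a doubled edge is never a bridge. 2-cuts are found by deleting each
non-bridge edge and re-running bridge detection; this is quadratic in edge
count but metabolite graphs of real molecules are small. Subgraphs with
|E| = |V| − 1 are trees and skip the 2-cut search entirely, which keeps
construction on acyclic molecules quadratic overall — the fragment set of a
chain of n nodes is all ~n²/2 contiguous intervals, so output size itself
is the lower bound and "near-linear" scaling can only be meant per
fragment produced. Fragment masses for all bitvectors are computed in one
vectorized pass. A configurable cap (default 100,000 fragments) guards
against pathological ring systems.

Hydrogen rearrangement is data, not code: a rule table maps each bond label
to a (heteroatom-side, other-side) mass offset per severed edge. The
default moves one hydrogen (+1.007825 Da) to the N/O side of severed
N–C/O–C bonds and leaves C–C cuts unadjusted — a deliberately simple
default chosen because cleavage heterolysis at heteroatoms typically
retains the proton on the more basic side; users with better rule sets can
supply their own, and every cache and model file records a digest of the
active table so mismatched artifacts are refused. Mass is computed from a
fragment's boundary edges, so it is independent of the path by which the
fragment was reached.

Decoys shuffle the non-root fragment masses of a target graph with a seeded
permutation, preserving topology, depths, bond labels and the precursor
mass. For very small or highly symmetric molecules many fragments share
masses, so a decoy can resemble its target and the FDR estimate becomes
conservative; this is inherent to mass-shuffling decoys, not an artifact.

## Probabilistic model

Peak abundance is summarized by intensity rank (1 = most intense), then
binned: logRank = min(⌊log₂ rank⌋ + 1, 6) for ranks 1..64, so bins hold
1, 2, 4, 8, 16 and 33 ranks respectively; the top bin is widened to rank 64
to respect the fixed endpoints (rank 1 → bin 1, ranks ≤ 64 → bins 1..6).
Intensity ties are broken by ascending m/z then input order, making ranking
deterministic and idempotent. Peaks ranked past 64 are treated as
unmatchable background. A fragment is annotated with the logRank of a peak
within 0.01 Da of its m/z (neutral mass + z protons over z), else 7.

Model assumptions: (i) a fragment's logRank depends only on its bond type
and its parent's logRank — grandparent conditioning is rejected because it
multiplies the parameter count roughly eightfold and overfits; (ii) peak
logRanks are otherwise independent (knowingly approximate: only one peak
can hold logRank 1); (iii) the root has logRank 0. Annotation resolves
multi-fragment conflicts on one peak in favour of the lowest depth, equal
depths by a seeded uniform draw; each peak annotates at most one fragment
and vice versa. A fragment's logRank_pa is the smallest logRank among its
minimum-depth parents — the most informative parent, and deterministic.

Training counts fragments per (bondType, logRank_pa) cell and normalizes
with a pseudocount (default 1.0; the source model leaves smoothing
unspecified, but zero cells would make the score undefined). The null row
for logRanks 1..6 is the smoothed logRank distribution of all training
peaks, scaled by (1 − p₇) where p₇, the null probability of logRank 7, is
the global fraction of training fragments that found no peak; this keeps
the null a proper distribution over all seven outcomes so the ratio in the
score is always defined. The score is the sum over non-root fragments of
log(conditional/null); unmatched peaks cancel.

## Search and FDR

Candidates are database molecules whose neutral mass under an allowed
adduct lies within `precursor_tolerance` (default 0.02 Da) of the observed
neutral mass (precursor m/z × z − adduct offset), found through a sorted
mass index. Multiple adducts may be allowed per spectrum; the best-scoring
adduct is reported per (spectrum, molecule). Each molecule carries one
decoy, seeded from a hash of the global seed and the molecule id so it is
identical across spectra and runs. FDR(t) = N_decoy(≥t)/N_target(≥t) at
each row's own score; zero decoys above a cutoff give FDR 0 by convention.
By default the counts run over all reported rows, with a best-hit-per-
spectrum mode behind a flag (`--fdr-mode best`), since either convention is
defensible. Output rows are canonically sorted, so input order and thread
count never change the bytes.

## Synthetic data: what it shows and what it does not

The generator emulates the generative model exactly: it walks the DAG
top-down, samples each fragment's logRank from the conditional table given
its bond type and its parent's sampled logRank, places sampled fragments on
uniformly drawn free rank slots inside their bins, fills every remaining
rank with background peaks kept ≥ 0.05 Da away from all fragment masses,
and converts ranks to a strictly decreasing exponential intensity ladder.
Because total peak count (default 70–110) always exceeds 64, fragment peaks
keep exactly their sampled ranks and re-ranking inverts the simulation. Two
deliberate design consequences: (a) bin overflow (more sampled fragments
than rank slots, e.g. two fragments sampling the single rank-1 slot) spills
to the next free rank — the default generating tables put little mass on
the narrow low bins, so this is rare enough to sit inside the confidence
intervals used in validation; (b) random metabolite graphs used for
parameter recovery are redrawn until all fragment masses are ≥ 0.05 Da
apart, so annotation is unambiguous. Default study conditions: 12 graphs of
4–7 nodes with up to 2 extra edges, bond frequencies CC:NC:OC = 2:1:1, node
masses uniform on 40–160 Da.

The generating conditional tables encode the qualitative chemistry the
scoring model is meant to exploit — heteroatom bridges fragment more
readily than C–C, bridges more readily than 2-cuts, intense parents beget
intense children — with observed-bin mass rising toward the wide high bins
as real rank distributions do.

What passing tests therefore show: the enumeration is exactly correct
(against brute force), the estimator recovers the model family it assumes,
the score arithmetic and FDR bookkeeping are right, and the pipeline is
deterministic. What they do not show: that real spectra follow the model.
The simulator has no isotope envelopes, no chimeric spectra, no mass error
beyond the tolerance window, no adduct mixtures, no correlated noise; real
performance claims require real annotated data.

## Numerical conventions and degenerate inputs

- Masses in Da throughout; proton 1.007276 Da; tolerances are absolute.
- MGF numeric output is fixed at six decimals; reading then rewriting a
  file produced by the writer is byte-stable.
- All-zero-intensity spectra cannot be ranked and are rejected; malformed
  MGF blocks are skipped with a per-block error carrying the line number.
- Graphs with fewer than two non-root fragments return their decoy
  unchanged with a warning flag (a shuffle would be the identity anyway).
- Every random choice (annotation ties, decoy permutation, simulation) is
  seeded; library entry points take explicit seeds and the CLI requires
  `--seed` for train/search.

## Known limitations

- Fragment ion chemistry is limited to the rule table's hydrogen offsets;
  no other rearrangements, no 3-cuts, no double ring cleavage beyond the
  2-cut model.
- Charge 2 is supported only in m/z computation; the conditional tables
  are trained on singly-charged annotations. Negative mode is handled as a
  mass offset ([M−H]−) with the positive-mode model.
- The 2-cut search is quadratic per fragment; molecules whose metabolite
  graphs are large and densely cyclic can hit the fragment cap and are
  skipped (reported, not fatal) during search.
- Validation problem sizes (500 oracle graphs, 10,000 simulated training
  spectra, chains up to 100 nodes) were chosen to exercise every code path
  at desk scale; they are the package's own study conditions, not external
  benchmarks.
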