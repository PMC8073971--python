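# Methods

## Setting

`omseval` studies open-modification search (OMS) behaviour in a fully
controlled setting: every spectrum is a *theoretical* spectrum derived
from a peptide sequence, and a proteome is compared against itself (plus
its reversed decoy). Because the "experimental" spectrum (the **bait**)
is itself generated from a known peptide, the correctness of every
peptide-spectrum match (PSM) against a database peptide (the **hit**)
can be judged exactly, which is impossible with real MS/MS data. PSMs
with a precursor mass difference Δm = mass(bait) − mass(hit) ≠ 0 can
only be explained by sequence editing operations (insertions, deletions,
substitutions), making Δm interpretation a sharply posed problem.

## Proteome processing

* **Digestion**: trypsin cleaves after every K and R, no exceptions (in
  particular, no "not before proline" rule). Missed cleavages are
  supported generically but the study conditions fix them at 0.
  Peptides outside 7–30 residues or containing `X` are discarded.
* **Decoys**: each *protein* is reversed before digestion, so decoy
  peptides are generally not reversals of target peptides (cleavage
  sites move). Decoy accessions get a configurable `DECOY_` prefix.
* **Deduplication** is by exact sequence within each origin, merging
  parent accessions; a sequence present in both origins keeps one entry
  per origin. The bait set is the deduplicated target peptides; the
  searched database is target ∪ decoy. I and L are distinct letters for
  all sequence identity tests (they collide only in mass).

## Theoretical spectra and mass arithmetic

A peptide of length n yields 2n singly protonated fragments: b_i =
(residues 1..i) + proton and y_i = (residues n−i+1..n) + water + proton,
i = 1..n, full-length ions included. Intensities are conceptually unit
valued and not stored. Monoisotopic residue masses are tabulated to
5 decimals; all sums are carried in integer units of 1e-5 Da so that
equal residue multisets give bitwise-equal masses — the Δm = 0 (G1)
group test is therefore exact, not tolerance-based.

Two masses are *shared* iff they discretize to the same key,
key = round(mass / precision), default precision 0.001 Da. This
preserves exact-composition coincidences (GG vs N, GA vs Q, KE vs GVT)
while avoiding float-equality fragility. The precision is a config key;
its value is a package choice, as the reference engine's internal
discretization is unpublished.

## Search

The shared peaks count (SPC) between two spectra is the multiset
intersection size of their discretized mass keys. Candidate PSMs are all
(bait, hit) pairs with SPC ≥ threshold (default 7), excluding pairs with
identical sequences; they are found with an inverted index from mass key
to (spectrum, multiplicity) postings, which reproduces exactly the
output of an all-pairs scan (property-tested against a brute-force
double loop).

**Strategy1** selects, per bait, the candidate with maximal raw SPC.
**Strategy2** first realigns every Δm ≠ 0 candidate: the hit's fragment
masses are shifted by Δm on one side of a single location, for every
location, and the location with the highest realigned SPC ("shift SPC")
is retained; the best PSM is then chosen on shift SPC (raw SPC for
Δm = 0 candidates, where no realignment is possible).

### Shift location convention

Locations are 1-based positions p ∈ [1, n_hit + 1], meaning "the mass
difference sits at the boundary before hit residue p": b-ions with index
≥ p and y-ions with index ≥ n_hit − p + 1 receive +Δm — exactly the
fragments whose mass changes when residues of total mass Δm are inserted
at that boundary (note the y-ion that starts immediately after the
boundary also realigns, since the inserted interval extends its suffix).
p = 1 and p = n_hit + 1 are the N- and C-terminal cases. Ties between
locations go to the smallest position. In the worked example (bait
EAEDISEK, hit EAEISEK, Δm = mass(D)) two adjacent labellings score the
same 14 because shifting the b3 = EAE prefix by mass(D) coincides with
the EAED prefix; the smallest-position rule reports position 3, the
first b-ion index affected by the insertion.

The identity (no-shift) alignment is always kept as a candidate, so
shift SPC ≥ raw SPC structurally. In practice the identity never wins
for Δm ≠ 0: the shifted full-length ions b_n + Δm and y_n + Δm land
exactly on the bait's full-length ion masses, so some shift always gains
at least two matches. Only one shift site per PSM is modelled;
multi-site Δm decomposition is out of scope.

### Tie-breaking

Best-PSM ties are resolved deterministically: higher score, then smaller
|Δm|, then target before decoy, then lexicographically smaller hit
sequence. The chain is a documented convention (the reference engine's
tie-breaking is unpublished), so full-scale counts may deviate
marginally from published ones.

## Quality measures

* **FDR** at a score cutoff s: #decoy / (#target + #decoy) over best
  PSMs with score ≥ s. The denominator includes decoys; this is
  validated against published count/FDR pairs, which are inconsistent
  with D/T. `threshold_at_fdr` returns the smallest s with FDR < α
  (default α = 0.01).
* **Δm groups**: G1 (Δm = 0, exact), G2 (Δm > 0), G3 (Δm < 0).
* **Green/Orange/Red**: how hard the bait is to reconstruct from hit +
  Δm. The bait/hit difference is decomposed with a unit-cost alignment
  DP that, among all minimal-edit-distance alignments, picks one with
  the fewest contiguous difference blocks (an arbitrary optimal path can
  split one long deletion into two blocks around a coincidentally
  matching residue, which would miscount edit locations). Verdicts:
  * Δm = 0 → **Red** (the sequences differ but no realignment exists).
  * ≥ 2 difference blocks, or block mass inconsistent with Δm → **Red**.
  * one block: single-residue insertion whose Δm matches exactly one
    residue letter → **Green**; contiguous deletion of any length →
    **Green** (the deleted content is read off the hit, so there is no
    ambiguity); 1↔1 substitution with a unique replacement mass →
    **Green**; everything else at that one location (multi-residue
    insertion — order undetermined —, I/L-degenerate residue, compound
    local edit) → **Orange**.
  The ambiguity test treats two residues as indistinguishable when their
  masses differ by at most the discretization precision (at 0.001 Da:
  exactly the I/L pair). The classification is sequence-driven; the
  Strategy2 alignment is accepted for interface symmetry but the
  decomposition does not depend on it.
* **LIPR** (Low Information Peaks Rate): the fraction of a PSM's shared
  masses whose generating fragment subsequences differ — mass matches
  carrying no sequence evidence. Unshifted matched pairs are concordant
  iff their subsequences are identical strings. Shifted pairs (Strategy2)
  are concordant iff the bait fragment equals the hit fragment with an
  interval of mass Δm inserted/excised exactly at the shift boundary:
  the residues outside the boundary must agree and the contested
  interval's mass difference must equal Δm, so a correctly realigned
  single-edit PSM scores LIPR = 0. When one shared mass is generated by
  several fragments, one concordant pairing marks all its copies as
  informative; both shifted-pair rules are package choices (the measure
  is published only for unshifted interpretation) and are applied
  uniformly. Strategy1 PSMs are evaluated under the raw alignment,
  Strategy2 PSMs under their recorded shift alignment.

## Synthetic data

`generate_proteome` draws residues i.i.d., uniform except K and R which
together get 0.12 of the mass (mean tryptic fragment length ≈ 8, so most
peptides fall in the 7–30 window); protein lengths are uniform in
150–600 residues, human-like protein sizes. `plant_edits` derives bait
peptides from database peptides by known edits (single-residue
insertion, multi-residue insertion, deletion, substitution, or two
separated substitutions), records ground truth (site, content, Δm,
expected color, expected coincidence-free shift SPC = 2·min of the two
lengths), keeps baits inside the 7–30 window and away from every
database sequence, and constrains sites so the true pair stays above the
SPC ≥ 7 candidate threshold (a substitution in a length-n hit leaves
only n−1 raw matches, hence substitution sources need n ≥ 8). Planted
baits are extra experimental baits only — never database entries — so
the self-match exclusion cannot remove the true hit. Everything is
deterministic under the seed.

What the generator does **not** emulate: the enormous peptide-space
density of a real proteome (isoforms, paralogs, hundreds of thousands of
peptides, of which a large majority share ≥ 7 masses with some other
peptide). At desk scale (~50 proteins) a planted bait's only candidate
is almost always its true source, so both strategies recover ~100% of
planted edits and the raw-SPC strategy is *not* handicapped; the
advantage of Δm-aware selection (Strategy2) over raw-SPC selection
(Strategy1) emerges only when dense same-mass neighbourhoods let
Δm = 0 candidates out-score modified true sources on raw SPC. Passing
the desk-scale recovery tests therefore demonstrates correctness of the
machinery, not the full-scale strategy ranking; the unit test
`test_shifted_candidate_overtakes_higher_raw_delta_zero` reproduces the
ranking phenomenon on a constructed neighbourhood.

## Problem sizes and runtime

Default test and acceptance runs use a 50-protein synthetic proteome
(~1000 bait / ~1800 database peptides) with 100 planted edits, and
200-peptide brute-force cross-checks; the whole suite completes in well
under a minute. Full-proteome runs are supported through the CLI but are
a multi-hour computation and are not part of the test suite.

## Degenerate inputs and numerical choices

* Empty digestion output raises an error naming the responsible filter.
* FDR over an empty PSM restriction is reported as absent, not 0.
* LIPR requires ≥ 1 shared mass (always true for candidates, SPC ≥ 7).
* Δm comparisons in classification and concordance use the
  discretization precision as tolerance; Δm = 0 tests are exact thanks
  to integer-unit mass sums.
* `minimumScore` and `maxMassesCount` are carried in the run
  configuration for fidelity with the reference engine's parameter
  block; `maxMassesCount` is validated as ≥ 2·max peptide length and
  `minimumScore` is inert.

## Known limitations

* Singly charged b/y ions only: no intensities, neutral losses, a/c/x/z
  ions, charge states, isotopes, or experimental-spectrum noise.
* One shift site per PSM; no multi-site Δm decomposition.
* Tie-breaking convention may differ from the reference engine's
  unpublished one, so full-scale headline counts are expected to agree
  only approximately.
* The Green/Orange/Red decomposition relies on a canonical run-minimal
  alignment; pathological equal-cost decompositions with the same run
  count are resolved arbitrarily (verdicts are unaffected in all tested
  constructions).
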