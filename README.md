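# omseval

Evaluation of open-modification-search (OMS) strategies on theoretical
mass spectra.

In OMS, an experimental MS/MS spectrum may be matched to a peptide of a
*different* precursor mass; the difference Δm is attributed to a
modification. `omseval` studies how well such peptide-spectrum matches
(PSMs) can be interpreted, in a fully controlled setting where *every*
spectrum is theoretical: tryptic peptides are generated in silico from a
protein FASTA (plus a reversed-protein decoy database), each peptide
becomes its b/y fragment-mass spectrum, and the peptide set is searched
against itself. Because the generating peptide of every "experimental"
spectrum (the **bait**) is known, the quality of each match to a
database peptide (the **hit**) can be judged exactly.

The package is aimed at computational proteomics researchers who want a
transparent, fully reproducible sandbox for OMS scoring questions.

## Model and scores

For a peptide of length n, the theoretical spectrum holds 2n singly
protonated fragments, b_i = Σ(residues 1..i) + H⁺ and
y_i = Σ(residues n−i+1..n) + H₂O + H⁺. Similarity between two spectra is
the **shared peaks count** (SPC): the multiset intersection size of
their discretized fragment masses (0.001 Da grid). All (bait, hit) pairs
with SPC ≥ 7 are candidate PSMs (self-matches forbidden), and one best
PSM is kept per bait under either of two selection strategies:

* **Strategy1** — highest raw SPC, ignoring Δm;
* **Strategy2** — for every Δm ≠ 0 candidate, the hit's masses are
  shifted by Δm at each possible single location (b-ions with index ≥ p,
  y-ions with index ≥ n−p+1, for boundary positions p = 1..n+1) and the
  best realigned score, the **shift SPC**, replaces the raw SPC.

Result quality is measured three ways:

* **target/decoy FDR** = #decoy / (#target + #decoy) above a score
  cutoff, with the smallest cutoff reaching FDR < 1%;
* a **Green/Orange/Red** classification of each best PSM — Green when
  one unambiguous editing operation (a single-residue insertion with a
  unique residue mass, a contiguous deletion, a substitution with a
  unique replacement) turns the hit into the bait; Orange when the
  location is known but the content is ambiguous (e.g. a VH vs HV
  insertion, or I vs L); Red otherwise (in particular every Δm = 0 PSM
  and edits at ≥ 2 separate locations);
* **LIPR**, the Low Information Peaks Rate: the fraction of a PSM's
  shared masses whose generating subsequences differ, i.e. mass matches
  that carry no sequence evidence.

See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

The bundled worked example plants an aspartate insertion:
bait `EAEDISEK` derives from hit `EAEISEK` with Δm = mass(D) =
115.02694 Da.

```sh
printf '>BAIT_PROT\nEAEDISEK\n>HIT_PROT\nEAEISEK\n' > worked_example.fasta
omseval run --fasta worked_example.fasta --strategy 2 --out-dir s2
omseval evaluate --psms s2/best_psms.tsv --out-dir s2
```

prints `2 best PSMs` and `FDR < 1% at min score 14 (2 PSMs)`, and the
reports contain:

```text
# s2/best_psms.tsv
bait      hit       hit_origin  score  raw_spc  delta_m    strategy  position
EAEDISEK  EAEISEK   target      14     7        115.02694  2         3
EAEISEK   EAEDISEK  target      14     7        -115.02694 2         3

# s2/psm_evaluations.tsv
bait      hit       hit_origin  score  delta_m    group  color  lipr
EAEDISEK  EAEISEK   target      14     115.02694  G2     Green  0.0
EAEISEK   EAEDISEK  target      14     -115.02694 G3     Green  0.0
```

Reading the first row: the two spectra share 7 masses as-is (`raw_spc`);
shifting the hit's masses by Δm at position 3 adds 8 matches and removes
1, lifting the score to a shift SPC of 14 (`score`), i.e. every fragment
of the hit is explained. The PSM falls in group G2 (Δm > 0), is
classified Green (the 115.02694 Da difference identifies exactly one
residue, D, at a known position) and has LIPR 0 (every shared mass is
backed by agreeing subsequences). The second row shows the symmetric
deletion-direction match.

The same library surface is available in Python:

```python
from omseval import generate_spectrum, count_spc, best_shift, classify_color

bait, hit = generate_spectrum("EAEDISEK"), generate_spectrum("EAEISEK")
delta = bait.peptide.mass - hit.peptide.mass
count_spc(bait, hit)                  # 7
a = best_shift(bait, hit, delta)      # position 3, shift SPC 14
classify_color("EAEDISEK", "EAEISEK", delta, a)  # 'Green'
```

Synthetic proteomes with planted, ground-truthed modifications come from
`omseval synth` (or `omseval.synthetic.generate_proteome` /
`plant_edits`), so the full pipeline is testable without any downloads.

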