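# Methods

## The modelling problem

MHC class I molecules present short peptides (7–15 residues) in a binding
groove formed by the G-ALPHA1/G-ALPHA2 domains (the "G-domain", residues
1–180 after renumbering). Peptides dock with *anchor* residues — canonically
P2 and PΩ (the last residue) — buried in conserved pockets, while the
central part of the peptide is comparatively free. Because the MHC fold is
highly conserved and the anchors fix the peptide's register, a pMHC-I
complex can be modelled accurately by (i) choosing a structurally solved
template complex, (ii) grafting the query sequences onto it, and (iii)
re-sampling only the non-anchor ("loop") part of the peptide under
restraints. This package implements that protocol end to end, together with
the database curation and evaluation machinery around it.

## Template database curation

Input structures (PDB format) are parsed strictly (malformed records are a
detectable, line-numbered failure), one MHC α chain and its bound peptide
are extracted, tolerated non-canonical residues are substituted by their
canonical parents (e.g. phosphoserine → serine by deleting the phosphate;
the table ships in `data/noncanonical.tsv` and is user-extensible), both
chains are renumbered from 1 and relabelled `M` (MHC) and `P` (peptide).
β2-microglobulin and all other chains are discarded. A candidate is
rejected — each input is counted exactly once — for one of five reasons:

| code | condition |
|---|---|
| `NONCANONICAL` | a non-canonical residue not in the tolerance table |
| `GROOVE_LIGAND` | a non-amino-acid group inside the binding groove |
| `UNPARSEABLE` | parse failure, or no receptor-length chain |
| `NO_ALLELE` | no allele annotation |
| `BAD_LENGTH` | no chain of peptide length (7–15, configurable) |

Choices the underlying protocol leaves open, decided here:

* **Groove-ligand geometry.** A ligand is "inside the groove" iff at least
  one of its atoms lies within 4.0 Å of atoms from ≥ 3 distinct peptide
  residues. This captures co-bound small molecules without rejecting surface
  crystallization additives. Both constants are `FilterSettings` fields.
* **α-chain recognition.** A protein chain with ≥ 150 resolved residues;
  with several copies in the asymmetric unit, the copy with the most
  resolved residues wins (tie → lowest chain id), and the peptide is the
  candidate chain with the smallest mean Cα distance to that copy's first
  180 residues.
* **Rejection precedence** when a structure has several defects:
  `NO_ALLELE` → `UNPARSEABLE` → `BAD_LENGTH` → `GROOVE_LIGAND` →
  `NONCANONICAL`.
* **Anchor annotation.** Template anchors default to the canonical {2, Ω}
  set and may be overridden per entry. `contact_anchors` additionally offers
  a **heuristic stand-in** for anchors derived from an experimental
  structure: the two peptide positions with the most side-chain heavy atoms
  within 4.5 Å of MHC atoms, searched among {1, 2, 3} and the last three
  positions respectively, with ties broken by the closest contact. It is a
  heuristic, not an established definition.
* **Persistence.** A single-file JSON archive with format/version header;
  loading a truncated or wrong-version file is an explicit error. Build
  metadata records the filter settings and the acceptance/rejection
  histogram but deliberately no wall-clock timestamp, so rebuilding or
  re-saving an identical database is byte-identical.

## Template selection

Candidates are gathered along the allele hierarchy of G-domain names
(`HLA-A*02:01` protein → `HLA-A*02` group → `HLA-A` gene); the first
non-empty tier is used. Within the tier, each template peptide is aligned to
the target with the *anchor-driven construction*: anchors are paired in
ascending order and forced into shared columns; a length mismatch within a
core segment (between consecutive anchors) is absorbed by a contiguous gap
block at the exact centre of the shorter segment (an odd surplus sits
immediately left of centre — after the first ⌊n/2⌋ characters); flank
mismatches become terminal gaps. This is prescriptive, not an optimal
alignment search, so anchors can never be gapped or shifted. Alignments are
scored with PAM30 (loaded from Biopython's NCBI matrix collection) plus
affine gap penalties (open −9, extend −1; unspecified upstream, standard
short-peptide values, configurable — the ranking is relative, so any
consistent penalty works). The best-scoring candidate wins; ties break by
better (lower) resolution, then lexicographically smallest source id.

## Model generation

1. **MHC alignment.** The target MHC sequence is resolved in priority
   order: user-provided sequence → reference table, exact allele →
   reference table, same allele group (warned) → the template's own M-chain
   sequence (warned). It is globally aligned to the template sequence
   (BLOSUM62, affine −11/−1) with `Bio.Align.PairwiseAligner`.
2. **Initial graft.** Per aligned column, the template residue's backbone
   (N, CA, C, O) is copied; identical residues keep all atoms, mismatches
   are truncated to Cβ at the template's (or ideal) position; glycine gets
   no Cβ. Target insertions are built by linear interpolation of the
   flanking Cα positions with approximate local geometry — they are loop
   residues, so the minimizer restores proper geometry.
3. **Ensemble.** Each of the `n_models` (default 20) models starts from the
   graft with every atom of every non-anchor peptide residue displaced by an
   independent uniform offset in ±5 Å per coordinate. Model *i* draws from
   seed `seed + i`, so enlarging the ensemble never reshuffles earlier
   models. Anchor residues and the whole M chain are never moved.
4. **Two-phase minimization.** The objective is a sum of harmonic distance
   terms (weights in Å² energy units, all configurable):

   * bonded, w=10: bond lengths (N–CA 1.46, CA–C 1.52, C–N 1.33, C=O 1.23,
     CA–Cβ) **and** the 1–3 distances implied by ideal bond angles — angle
     terms encoded as distances, with the Cβ reference distances derived
     from the same ideal-Cβ construction the graft uses, so an ideally
     built residue sits exactly at the bonded minimum;
   * clash, w=5: one-sided harmonic below d_min = 2.8 Å between non-bonded
     atom pairs (peptide–peptide beyond adjacent residues, and peptide–MHC);
   * anchor, w=100: harmonic tethers of anchor backbone atoms to their
     grafted positions (anchors are also hard-frozen, so this term guards
     non-default loop definitions);
   * secondary structure, w=10: helix requests expand to O(i)–N(i+4)
     targets of 3.0 Å over the span; strand-pair requests to hairpin
     Cα(start+k)–Cα(end−k) targets of 4.8 Å.

   Phase one minimizes bonded + anchor terms (default 200 iterations),
   phase two all terms (default 300); presets scale the budget (fast ×0.5,
   thorough ×4). The optimizer is steepest descent with a Barzilai–Borwein
   spectral step, safeguarded by step halving whenever a trial step would
   increase the objective — the accepted objective sequence is
   non-increasing by construction. Gradients are analytic and tested
   against central differences.
5. **Ranking.** The surrogate score of a model is its final minimization
   objective (lower is better); models are returned sorted ascending with
   ranks 1..n. This stands in for an engine-internal ranking score (such as
   MODELLER's molpdf) with the ranking semantics preserved exactly:
   ascending scores, and when the target peptide sequence **and** allele
   match the template, the unrandomized graft (the template conformation)
   is appended at rank 1 with a score one unit below the best generated
   model, with a log notice. The surrogate's absolute values are not
   comparable to any engine's score.

`emit_modeller_inputs` writes the alternative backend's files instead of
running the internal one: a PIR alignment (structureX entry for the
template, chains M/P joined by `/`, entries terminated by `*`), the
template PDB, and a plain-text restraint list; a PIR reader is provided for
round-trip checks.

## Evaluation

L-RMSD is computed the docking way: the model's G-domain (M-chain residues
1–180, backbone atoms, restricted to the subset resolved in both
structures) is superposed onto the reference by least squares (Kabsch, SVD,
proper rotation enforced) and the RMSD is then taken over corresponding
peptide atoms **without refitting**, in four dialects: backbone
{N, CA, C, O}, Cα-only, backbone+Cβ, full-atom. CAPRI-style classes bin the
backbone L-RMSD: High < 1 Å, Medium < 2 Å, Acceptable < 5 Å, else
Incorrect (the Incorrect class is open-ended; the bin edges are exposed in
`CAPRI_EDGES`). A *hit* is a model under the hit threshold (default 2 Å).
Per case, `hit_rate(K) = n_hits(K)/M` with M the case's total hit count —
a recall of achievable hits (the alternative reading normalizes by K; we
implement the recall form and say so). Cases with M = 0 are excluded from
cohort hit-rate averages. `success_rate(K)` is the fraction of cases with
at least one hit among their top K; it is non-decreasing in K.

## The synthetic fixture generator

`fixtures` builds everything the tests and the acceptance script consume.
The pseudo-MHC scaffold is **synthetic**: 180 residues of ideal-geometry
segments (two 60-residue wall helices flanking the peptide, a 50-residue
floor helix below, and one 5-residue pocket segment parked 3.2 Å beyond
each anchor's side chain along its Cβ direction) arranged so that chain
extraction, renumbering, G-domain superposition, the groove-ligand test and
the contact-anchor heuristic are all exercised with known ground truth. It
is *not* a real MHC fold: it has no native-like sequence, topology or
packing, so passing tests demonstrate the correctness of the pipeline's
mechanics and contracts, not predictive accuracy on experimental
structures.

Peptides are built by natural-extension (NeRF) placement from ideal bond
lengths/angles with canonical dihedrals — extended (φ, ψ) = (−139°, 135°),
helix (−57°, −47°) — giving extended Cα–Cα spacings of 3.80 Å and helical
O(i)–N(i+4) distances of ≈ 3.07 Å. Defect flags inject exactly one curation
failure each (unlisted residue code, groove ligand, corrupted coordinate
field, missing allele annotation, 6-mer peptide); contradictory recipes are
an error.

`make_benchmark_cohort` builds cross-docking-style cases: each reference
fixture is paired with a template derived from it by point-mutating
peptide positions outside the anchors (default 2 mutations) and jittering
every atom with Gaussian noise (default σ = 0.25 Å per coordinate,
"a similar but not identical crystal"). Because real templates keep
near-ideal covalent geometry regardless of conformational differences, the
jittered peptide is relaxed under the bonded objective (all residues free)
before becoming a template; the displacement stays at the noise scale but
bond lengths return to ideal. With zero mutations and zero noise the
template *is* the reference (self-docking), which is how the
identical-case shortcut is exercised.

Study conditions used by the tests and the acceptance script: 9-mer
peptides (12-mers with a helical 4–11 span for the secondary-structure
experiment), a 4-allele pool, 20-case cohorts. The modelling-contract
cohort uses 10 models per case and the sensitivity experiments 4 per case —
smaller than the default 20-model ensemble to keep the suites desk-scale;
the ensemble size only changes sampling depth, not any contract being
checked.

## Numerical choices and degenerate inputs

* Coordinates are carried at the 3-decimal precision of the PDB coordinate
  field; written structures re-parse exactly, and re-writing is
  byte-identical.
* Altloc handling keeps the highest-occupancy conformer (tie → 'A');
  insertion codes are flattened in author order before renumbering.
* Exact self-comparisons short-circuit the superposition to the identity
  transform, so a model evaluated against itself scores exactly 0 rather
  than machine epsilon.
* Randomization with amplitude 0 is the identity; negative amplitudes are
  an error. A non-finite objective aborts with diagnostics.
* Score ties in the ensemble are ordered by the per-model seed, so ranking
  is deterministic; the whole `model_case` output is bit-identical across
  reruns with the same seed.

## Known limitations

* Side chains beyond Cβ are neither copied for mismatches nor rebuilt; the
  evaluation is correspondingly backbone-centric (full-atom L-RMSD uses
  whatever atoms both structures share).
* The surrogate score ranks models within one run only; it is not an
  energy and not comparable across runs or to engine scores.
* The minimizer is a restrained geometry optimizer, not a force field: no
  electrostatics, torsional preferences or solvation.
* MHC-II is structurally supported by the generic anchor machinery
  (> 2 anchors align per-segment) but untested.
* The anchor "provider" hook (e.g. plugging in a binding-core predictor) is
  an interface only; no external predictor is bundled or invoked.
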