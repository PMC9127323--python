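# pmhcmodel

Anchor-restrained homology modelling of peptide:MHC class I (pMHC-I)
complexes, for structural immunologists and ML practitioners who need many
plausible 3D models of peptide–MHC binding rather than a handful of
hand-curated ones.

MHC-I molecules present short peptides (7–15 aa) in a groove formed by the
G-domain (residues 1–180); the peptide is fixed at *anchor* positions —
canonically P2 and PΩ — while its central part is flexible. The package
exploits the two structural facts that make pMHC modelling tractable: the
MHC fold is highly conserved, and the anchors pin the peptide's register.
Given a peptide sequence and an MHC allele name it:

1. **curates** a template database from PDB structures (chain extraction,
   renumbering to M/P chains starting at 1, tolerated non-canonical residue
   substitution, rejection of ligand-occupied grooves with per-reason
   accounting);
2. **selects** a template through the allele hierarchy (exact protein →
   allele group → gene) and an anchor-driven peptide alignment scored with
   PAM30, where length mismatches are absorbed by gaps at the exact centre
   of the binding core;
3. **models** a ranked ensemble: the target is grafted onto the template,
   each model's loop (all non-anchor peptide residues) is randomized by
   ±5 Å per coordinate and restored by a two-phase restrained minimization
   (bonded geometry first, then clash and optional helix/strand
   restraints), with anchors frozen throughout. Models are ranked by the
   final objective (lower = better); if the query is identical to the
   template, the template conformation itself is returned at rank 1 with a
   score one unit below the best generated model. Alternatively it emits
   MODELLER-ready inputs (PIR alignment, template PDB, restraint list);
4. **evaluates** models against references by L-RMSD — RMSD over peptide
   atoms after superposing only the G-domains, in four atom-set dialects —
   with CAPRI classes (High < 1 Å, Medium < 2 Å, Acceptable < 5 Å, else
   Incorrect) and cohort hit-rate / success-rate curves, where a hit is a
   model with L-RMSD < 2 Å.

A deterministic synthetic fixture generator (`pmhcmodel.fixtures`) makes
every stage testable offline — no downloads, no licensed modelling engine.
See `docs/methods.md` for the model, its parameters and its limitations.

## Worked example

```bash
# 1. generate the synthetic fixture set (12 structures, 4 with designed defects)
pmhcmodel make-fixtures --outdir fx --seed 0
cut -f1-4 fx/annotations.tsv > fx/ann.tsv

# 2. curate the template database
pmhcmodel build-db --structures fx/structures --annotations fx/ann.tsv \
                   --ref-fasta fx/ref.fasta --out db.json
# accepted 8/12 structures -> db.json
#   (log shows one rejection each for NONCANONICAL, GROOVE_LIGAND,
#    UNPARSEABLE and NO_ALLELE)

# 3. model an 8-mer with non-canonical anchors P1/P8
pmhcmodel model --db db.json --peptide LFGYPVYV --allele "HLA-A*02:01" \
                --anchors 1,8 --n-models 3 --seed 1 --outdir run1
cat run1/manifest.tsv
# rank  score     seed  anchor_max_disp  file
# 1     0.190106  2     0.0              model_1.pdb
# 2     0.190151  1     0.0              model_2.pdb
# 3     0.190606  3     0.0              model_3.pdb

# 4. score the models against a reference structure
pmhcmodel evaluate --model run1/model_1.pdb --reference fx/structures/FIX0001.pdb
# rank  model            backbone  c_alpha  backbone_cb  full_atom  capri       hit
# 1     run1/model_1.pdb 3.828     3.607    4.096        4.096      Acceptable  0
```

The manifest's `score` column is the final minimization objective (the
ranking surrogate; lower is better) and `anchor_max_disp` confirms the
anchor backbone never moved. The evaluation row reports the L-RMSD in each
atom-set dialect, the CAPRI class of the backbone value, and whether the
model is a hit at the default 2 Å threshold. Omitting `--anchors` logs and
uses the canonical {2, Ω} anchors. The same pipeline is available as a
library (`build_database`, `select_template`, `model_case`, `lrmsd`,
`success_rate`, ...).

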