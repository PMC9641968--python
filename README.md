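# ancsite

Ancestral site-state reconstruction and residue-combination analysis for
protein families, built around the question: *are the likely ancestral
states of a handful of functionally critical sites actually represented in
extant sequence diversity?* The packaged use case is the nitrogenase D
subunit, whose 24 substrate-channel residues control what the FeMoCo
active site can reach and reduce; the machinery is generic to any protein
with a curated site panel.

## What it computes

Given an alignment, a rooted (or outgroup-rootable) phylogeny with branch
lengths, and a reversible amino-acid substitution model with among-site
rate variation, `ancsite`:

1. **Reconstructs marginal ancestral states** at a target internal node
   (the MRCA of a chosen ingroup) by Felsenstein's pruning algorithm.
   For site *s* and state *x*, with rate categories (*w_k*, *r_k*),

       P(x | data) ∝ Σ_k w_k π_x L_k(x),

   where L_k(x) is the conditional likelihood of the whole tree re-rooted
   at the target node — valid because the models are time-reversible.
   Models: LG, WAG, BLOSUM62 (packaged PAML-style exchangeabilities S and
   frequencies π; Q_ij = S_ij π_j scaled to one expected substitution per
   site per unit branch length), with uniform, discrete-gamma, or
   FreeRate-style (w_k, r_k) mixtures.
2. **Detects variable sites** in a site panel: columns where ≥ 2 residues
   have posterior strictly above a threshold (default 0.10).
3. **Enumerates ancestral residue combinations** over the variable sites.
   Each combination's joint likelihood is the product of its per-site
   posteriors, L(combo) = Π_i p_i(a_i); combinations are ranked by this
   product (these are site-combination statistics, not full-sequence
   likelihoods).
4. **Recodes physicochemically** (Acidic E/D; Aliphatic I/L/M/V; Amine
   Q/N; Aromatic W/Y/F; Basic K/R; Small Hydroxyl S/T; Tiny A/G; C/H/P as
   singletons) to separate conservative from radical differences.
5. **Classifies each combination against extant diversity** as absent,
   rare (≤ 2 extant sequences by default) or common, at both the exact
   residue level and the recoded type level, with per-clade breakdowns
   and residue co-occurrence counts.

A simulator (`ancsite.synthetic_data`) evolves alignments down random or
given trees with full internal-node ground truth, so every stage is
testable without external data.

## Worked example

The packaged fixture encodes the reconstructed nitrogenase ancestor's
posteriors over the 24-site substrate-channel panel:

```python
import ancsite as ac

table, panel = ac.make_ancestor_fixture()
vs = ac.detect_variable_sites(table, panel, "AncNif", threshold=0.10)
print(vs.columns)                 # [348, 495, 496, 576, 603]
combos = ac.enumerate_combinations(vs)
print(len(combos))                # 64
print(combos[0].sequence, combos[1].sequence)   # AATGA AATGG
s = ac.combination_summary(combos)
print(round(s["max_joint"], 5))          # 0.07237
print(round(s["min_joint_percent"], 5))  # 0.025
print(ac.recode(tuple("AATGG")))
# ('tiny', 'tiny', 'small_hydroxyl', 'tiny', 'tiny')
```

Five of the 24 panel sites have more than one plausible ancestral state,
giving 4×2×2×2×2 = 64 candidate ancestral substrate-channel sequences.
The joint likelihoods span 0.072 down to 2.5e-4 (0.025%); the runner-up
combination AATGG is all tiny/small-hydroxyl residues. Classifying these
64 against an extant alignment (`ac.extract_profiles` + `ac.classify`)
reports how many are absent, rare or common at the residue and the
physicochemical-type level.

The same workflow runs from the shell:

```
ancsite asr --aln x.fasta --tree x.nwk --model LG --categories "gamma(1,4)" \
        --outgroup-file og.txt --ingroup-file ig.txt --out ancestor.state
ancsite panel --state ancestor.state --threshold 0.10 --out variable.tsv
ancsite combos --state ancestor.state --out combos.tsv
ancsite run --config config.yaml     # full pipeline + summary.json
```

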