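# Methods

## Model and likelihood

Sequences evolve under a reversible continuous-time Markov model on the 20
amino acids. A model is (S, π, {w_k, r_k}): a symmetric exchangeability
matrix with zero diagonal, a positive equilibrium frequency vector summing
to 1, and a discrete rate mixture with Σw_k = 1 and mean rate Σw_k r_k = 1.
The generator is Q_ij = S_ij π_j (i ≠ j), diagonal set so rows sum to zero,
globally rescaled so −Σ_i π_i Q_ii = 1; branch lengths are therefore
expected substitutions per site. Transition probabilities P(t, r) =
exp(Q r t) are computed from the eigendecomposition of the symmetrized
generator D Q D⁻¹ with D = diag(√π) (exact for reversible Q); entries are
clamped to [0, 1] and rows renormalized, absorbing round-off at the
~1e-15 level.

LG, WAG and BLOSUM62 ship as PAML-style lower-triangle text files with
their published frequency vectors; +F or ML-estimated frequencies are out
of scope. FreeRate mixtures (e.g. the R9/R10 fits used in large
nitrogenase analyses) are accepted as explicit (weight, rate) values and
never fitted here — fitting weights, rates, topology or branch lengths is
deliberately outside the package. Gamma rate heterogeneity is discretized
by category means over k equal-probability bins (the conditional mean of
each quantile bin via regularized incomplete gamma functions); the
median-based variant is not offered, to keep one canonical behavior.

## Pruning and marginal reconstruction

Per-site likelihoods use Felsenstein's pruning algorithm with partial
likelihood vectors per (node, rate category, site). Underflow is controlled
by per-(node, site) rescaling by the maximum entry across categories and
states, shared across categories so the mixture weights remain valid; the
log scaling factors accumulate and are added back to the site
log-likelihood. Leaf gaps ('-') and unknowns ('X') are missing data
(all-ones partial vectors), the conventional choice.

Marginal posteriors at an internal node are computed by re-rooting the tree
at that node and reading the root posterior
P(x | data) ∝ Σ_k w_k π_x L_k(x) — the standard marginal treatment in which
categories are mixed by their site-specific posterior weight, not the
single best category. Under reversibility the result is independent of the
original root placement; the test suite checks both this invariance and
exact agreement (within 1e-9) with explicit enumeration over all
internal-state assignments on trees of up to five leaves. Joint
(max-probability path) reconstruction and Bayesian sampling of ancestors
are non-goals: downstream combination analysis consumes per-site marginal
posteriors.

Outgroup rooting finds the bipartition whose one side equals the outgroup
and splits that branch's length equally between the two new root children.
The split is cosmetic under reversibility (total tree length is conserved
and the likelihood is invariant), which the tests verify directly.

## Site panel, variable sites, combinations

A site panel is a curated list of 1-based alignment columns with reference
labels (the packaged panel: 24 nitrogenase substrate-channel sites mapped
to *Azotobacter vinelandii* NifD numbering). A panel column is *variable*
when at least two residues have posterior strictly greater than the
threshold (default 0.10); the strict inequality means a clean 0.90/0.10
split is monomorphic. Sub-threshold states are retained in reports but
excluded from enumeration.

Combination joints are plain products of per-site marginal posteriors.
Because marginal posteriors are per-site independent quantities, the
product is a likelihood for the site combination only, not for a
full-length ancestral sequence, and the ranked list should be read as a
candidate library rather than a sequence-level posterior. The minimum
joint is reported both as a raw fraction and as a percentage
(`min_joint_percent = 100 × min_joint`) because published bounds on such
quantities are not always unit-consistent; the raw product is the primary
statistic. Ties in the ranking are broken lexicographically by residue
tuple (no ties arise in the packaged fixture).

## Physicochemical recoding and extant comparison

The recoding scheme is a total map from the 20 letters onto seven named
categories plus three singletons (C, H, P), which therefore partition the
alphabet; recoding a category tuple is a no-op. Singleton recodings are
logged whenever they fire, since they assert no similarity to anything.

"Extant" means the ingroup (the nitrogenase Nif/Vnf/Anf rows in the
packaged use case); outgroup rows are excluded by default but the ingroup
set is caller-controlled. Sequences with a gap or 'X' at any variable
column are excluded entirely (exact-tuple matching needs complete tuples)
and listed in an exclusion report. Classification thresholds: absent = 0
occurrences, rare = 1..rare_max (default 2), common = more. Summary
fractions use the combination-space size as denominator for residue-level
presence and type-level absence, and the type-present count as denominator
for the rare-among-present fraction. Clade tags are user-supplied
(id → clade TSV) because clade membership comes from curation of a tree
figure, not from a computable rule.

## Synthetic data

The simulator draws random topologies by successive random leaf attachment
(uniform edge choice, uniform split point, exponential new-leaf branch
lengths with configurable mean, default 0.3 expected substitutions/site —
a realistic within-family divergence), then evolves sites independently:
per-site rate category drawn from the mixture weights, root states from π
(or a fixed sequence), child states from the corresponding P(t·r) row.
Every internal node's true sequence is recorded. Alignments are generated
gap-free (indel simulation is a non-goal; gap handling is exercised by
hand-built cases), so simulator-based tests probe statistical recovery,
not alignment-error robustness — conclusions about real data with
alignment uncertainty require external validation.

The desk-scale ancestor fixture encodes, for one node over the packaged
24-site panel, the listed per-site posteriors (five sites with 2–4
states, nineteen near-invariant); each row's residual mass is assigned to
the lexicographically first residue with no listed probability, so rows
sum to 1 without perturbing the listed values. The extant fixture
(default 60 sequences: 25 + 25 + 10) gives the five variable columns
clade-structured profiles — one clade fixed at L/M/N/G/G, one at
A-dominant/I/N/G/G, and a small heterogeneous clade — qualitatively
mirroring the Group I / Group II / divergent-clade structure of extant
nitrogenase diversity, with generator-known expected counts for testing.

## Numerical and design choices

- Probability-vector validation at 1e-6; state-file rows deviating from
  sum 1 by ≤ 1e-4 are renormalized with a logged warning, larger
  deviations are errors.
- Provenance '#' headers are written on tabular outputs (state tables,
  TSV reports). FASTA and Newick writers emit clean standard format so
  round-trips are byte-identical and downstream tools are not confused by
  comment lines.
- Parameter-recovery checks run on a fixed 20-leaf, 500-site simulation
  with the matched LG + Γ(α=1, k=4) model across branch-length scales
  {0.01, 0.1, 1, 10}; root argmax accuracy is monotonically non-increasing
  in the scale. These sizes give stable accuracy estimates while keeping
  the whole suite fast.
- The pipeline accepts either alignment+tree (engine path) or a
  precomputed state file (re-analysis path); both produce identical
  downstream outputs given the same table, which is tested.

## Known limitations

- No tree search, branch-length optimization, model selection or
  frequency estimation: topology, lengths and model parameters are inputs.
- Marginal-only reconstruction; per-site independence is assumed by the
  joint-product statistic by construction.
- The extant classification is only as representative as the supplied
  ingroup alignment; unsampled diversity can turn "absent" into "rare".
- Indels are not simulated, and 'X'-heavy sequences reduce the scorable
  extant set.
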