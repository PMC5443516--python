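# Methods

## The statistical model

Contact inference assumes the aligned homolog family is (approximately) an
i.i.d. sample from a pairwise Markov random field over sequences: per-site
fields plus pairwise couplings on a fully connected graph. Under the naive
mean-field approximation the coupling blocks are the negative inverse of
the connected-correlation matrix of the (reweighted, pseudocounted) one-hot
column statistics. This inherits the usual assumptions — that pair
interactions suffice, that the MSA samples evolutionary history evenly, and
that couplings reflect structure — and the whole downstream pipeline
(topology filter, learned rescoring) exists precisely because the last
assumption fails for membrane proteins in predictable ways.

Two conventions deserve explicit statement:

* **Gauge.** The covariance matrix is built over q−1 = 20 states per
  column, dropping the gap state; couplings of the dropped state are fixed
  at 0 when the two-site model is assembled. This is the standard
  mean-field gauge and makes the matrix generically invertible once
  pseudocounts are applied.
* **Direct information.** The pair score is the mutual information of the
  pair's two-site model `P_ij(A,B) ∝ exp(e_ij(A,B)) h̃_i(A) h̃_j(B)`
  against the product of its site marginals, with the auxiliary fields
  `h̃` fitted so that `P_ij` reproduces the single-site frequencies. The
  fit is an alternating marginal-matching fixed point initialised at the
  uniform distribution, tolerance 1e-6 on the maximum marginal change,
  capped at 500 iterations; non-converged pairs are scored from the last
  iterate and counted in a single warning. DI is clipped at 0 against
  round-off and is symmetric by construction.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| sequence gap fraction | 0.30 (strict >) | prune rows before inference |
| column gap fraction | 0.30 (strict >) | prune columns; defines coverage Cov |
| identity threshold | 0.80 (strict >) | reweighting; identity = identical non-gap residues / width |
| pseudocount λ | 0.8 | uniform-background admixture before inversion |
| depth grading | k/(n+1) | n-residue TM span; 1/22…21/22 for n = 21 |
| vertical-separation threshold | 0.35 (strict >) | pairs above it are discarded |
| window | 9 (i ± 4 × j ± 4) | two helical turns around each site |
| min separation | 1 training / 12 evaluation | short-range pairs excluded from scoring |
| DT min node size | 20 | nodes below it are leaves |
| ANN η, α | 1.7e-5, 0 | gradient step on the summed squared error; momentum |
| L-fraction count | round-half-up(f·L), ≥ 1 | top-L selection |
| restraint | −1 ≤ 8 Å, 0 ≥ 20 Å | −sin((π/2)(20−d)/12) ramp between |
| FPP range | 0.0001–0.0055 | precision integral / enrichment objective |

Filtering order is sequences first, then columns (row gap fractions are
computed on the width that the sequence filter saw). Unknown residues
(X, B, Z, U, O) are treated as gaps everywhere. Coordinates are always
1-based positions of the original target sequence; filtered positions carry
a NaN sentinel and are excluded from ranking.

## Depth-orientation conventions

Within a transmembrane span the depth values `k/(n+1)` can be enumerated in
two ways, and the package ships both:

* `text` (default): depth measures the normalised distance from the outer
  membrane face — the outside-adjacent residue gets 1/(n+1) and the
  inside-adjacent one n/(n+1), identically for up- and down-going helices.
* `gradient`: the loop-continuous variant, rising smoothly from the inner
  side (≈0, adjoining inner loops) to the outer side (≈1).

Both orderings give identical vertical separations for pairs within the
same span; they differ for span-versus-loop pairs. The default follows the
worked-example enumeration; the alternative is one flag away
(`encode_membrane_depth(..., orientation="gradient")`). Re-entrant helix
symbols are folded into the flanking loop before encoding.

## Learning machinery

Cross-validation is at protein level: five equal blocks; fold k uses block
k as the independent set, block k+1 as the monitoring set, the rest for
training, so each protein is independent exactly once and linked
(sequence-similar) proteins are packed into one block. The ensemble
prediction is the arithmetic mean of the five members.

The decision-tree member is a standard CART classifier with splitting
forbidden below 20 node points. The network member is a single hidden
layer of 32 sigmoid units with a sigmoid output, trained by full-batch
gradient descent on the *summed* squared error — the η = 1.7e-5 step is
meaningful at that scaling because the gradient grows with the training-set
size — with momentum α, inputs standardised by training-fold statistics,
and the best-monitored weights kept (patience 100 evaluations, epoch budget
2000, which is where this scheme converges on the package's separability
check). The monitored quantity is RMSE for initial training and average
enrichment for a final training stage.

Descriptor selection: (i) single-feature ranking by the best
single-threshold F1 (both directions scanned over midpoints of observed
values) and the information gain of that split; (ii) iterative
input-sensitivity pruning, where sensitivity is the mean absolute change of
a member's output under a +1 SD perturbation of one feature over the
monitoring proteins, averaged over members — a perturbation stand-in for
the exact estimator of the original neural-network toolkit, so rankings,
not absolute values, are the contract. No stage may remove more than half
of the current descriptors; the default schedule scales the reference
210 → 160 → 130 → 70 progression. (iii) For network ensembles, a
weight-derived score: the output derivative w.r.t. each standardised input
evaluated at the centre of the training distribution; a feature is
*consistent* when that derivative keeps one sign across members, and the
magnitude score min-max rescales each member's |derivatives| into [0, 0.5],
sums per feature across members, and squares. Rescaling is per member
across features (rather than per feature across members) so that the score
remains comparable between features.

The enrichment objective evaluates precision at a uniform 100-point grid of
fraction-predicted-positive values over [0.0001, 0.0055] (top ⌈f·N⌉ pairs
predicted positive, ties broken by input order), reports the trapezoid
integral of precision and the mean of precision divided by the base rate.

## What the synthetic generator emulates — and what it does not

`synthetic.sample_coupled_msa` draws from a planted pairwise model:
independent per-site fields, plus `J(A,B) = s·δ(A,B)` on each planted pair
(s = 2.0 by default), one independent Gibbs chain per output sequence
(burn-in 1000 sweeps by default; only coupled sites need sweeping, and
uncoupled sites are drawn exactly). The gap state carries a −8 field bias
so synthetic alignments are effectively gap-free. Topology strings,
deterministic SSE/membrane probability tracks, and idealised helix bundles
(1.5 Å rise, 100°/residue, 2.3 Å radius, pseudo-Cβ 1.5 Å along the outward
radial, alternating up/down on a polygon) complete the fixture;
`make_end_to_end_fixture` plants true couplings on genuine bundle contacts
and false couplings across membrane faces.

This emulates exactly the statistical structure the method exploits —
direct couplings versus independent background, and topologically
implausible couplings. It does **not** emulate phylogenetic correlation,
gap structure, alignment error, transitive coupling chains, or realistic
amino-acid composition. Passing tests therefore demonstrate correctness of
the inference and filtering machinery, not benchmark-level accuracy on real
protein families, which depends on alignment depth and quality in ways the
generator deliberately sidesteps.

Problem sizes used by the test suite — planted model L = 30 / M = 2000,
independence check L = 30 / M = 2000, end-to-end bundle L = 79 / M = 1500
(burn-in 300), learning harness n = 5000 over 25 pseudo-proteins — are the
package's own choices: large enough that the planted signal dominates
sampling noise, small enough to iterate on.

## Numerical choices and degenerate inputs

* Dense symmetric inversion (LAPACK via scipy) for the covariance matrix;
  the matrix side is 20·C, i.e. ≈12,000 for a 600-residue target (~1.2 GB
  as float64) — the intended ceiling. DI is computed in a pair loop, so
  only the coupling blocks are held at once.
* A singular covariance raises an error naming the pseudocount remedy.
* Window aggregates use only in-range, scored entries; the raw window pads
  invalid slots with the protein-wide mean so edge windows stay unbiased.
  A zero protein-wide mean defines the normalised mean as 0 with a warning.
* Ranking ties break by larger sequence separation, then i, then j — the
  selection is byte-reproducible.
* The restraint ramp uses the verbatim −sin mapping, which has zero slope
  only at the 8 Å end; a cosine smoothstep flat at both ends is available
  via `RestraintPotential(form="cosine")`. Both agree on the plateau
  values.
* Evaluation labels use Cβ ≤ 8 Å (Cα for glycine) while restraint scoring
  uses Cα distances; the two conventions are deliberately not unified
  because folding engines restrain backbone atoms. Pairs in the 8–12 Å
  "near-contact" band count as non-contacts.
* All randomness flows through explicit integer seeds (generator models,
  CV planning, member initialisation); re-running the suite is
  deterministic.

## Known limitations

* Naive mean-field DCA only: no pseudo-likelihood/regularised Potts
  inference and no APC correction, by design.
* The exact membership of the full descriptor universe is configurable by
  category rather than enumerated; optional inputs (PSSM, SSE tracks)
  extend the schema when present.
* Homolog search, topology prediction and secondary-structure prediction
  are upstream tools whose outputs are inputs here.
* The monitoring-set early-stopping rule and the perturbation sensitivity
  estimator are reconstructions of an in-house toolkit's behaviour from its
  description; they preserve the selection semantics, not bit-level
  behaviour.
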