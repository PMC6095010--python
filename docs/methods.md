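# Methods

`doralisa` simulates how structured relational knowledge is learned from
unstructured perceptual input and then used for analogical reasoning, and how
a single maturational parameter — top-down lateral inhibition, the model's
proxy for inhibitory control — shapes both processes.  This note documents
the model, its parameters, the synthetic stimulus generator, the numerical
choices, and the limits of what the simulations show.

## Representational substrate

Knowledge is coded in a strictly layered symbolic-connectionist hierarchy
(the LISAese format of the DORA/LISA model family).  A shared pool of 1000
semantic units carries distributed features; above it sit three layers of
localist tokens:

* **PO units** code single predicates (relational roles) or objects, each
  connected downward to semantic units with weights in [0, 1] (stored
  sparsely; an absent connection is weight 0).
* **RB units** conjunctively bind exactly one predicate PO to one object PO
  (a role-filler pair).
* **P units** link RB units into multi-place propositions such as
  `contains(house, square)`.

Tokens are grouped into analogs, and analogs into three mutually exclusive
banks: the **driver** (current focus of attention), the **recipient**
(active memory that responds to the driver), and long-term memory.  Driver
and recipient communicate only through the shared semantic pool.

Role-filler binding is carried by *systematic asynchrony of firing*: when a
proposition enters working memory its role and filler POs fire in direct
sequence (role directly before filler, distinct pairs in disjoint time
slots).  We model firing as discrete slots with algebraic competition rather
than integrating oscillator differential equations; the slot-wise account is
faithful to the binding semantics, deterministic given its random draws, and
orders of magnitude faster.

## The inhibition parameter

Every competitive selection in the model is sharpened by one parameter,
lambda in (0, 1], fixed for an individual across learning and reasoning
(maturational assumption).  Selection temperature is

    tau(lambda) = (1 - lambda) + 0.01,

strictly decreasing in lambda (the 0.01 keeps it finite at lambda = 1).
Three processes use it:

1. **Working-memory entry.**  Driver propositions are selected by a softmax
   over support scores with temperature tau.  Support is uniform except for
   a recency penalty (the most recently fired proposition's support is
   halved); pragmatic centrality and inter-proposition support are named
   determinants of this competition but are not differentiated by our
   stimuli, so they are left as extension points.
2. **Recipient response.**  Units in the recipient compete divisively to
   respond to the semantic footprint of a firing driver unit:
   `a_i = in_i^(1/tau) / sum_j in_j^(1/tau)`.  At lambda near 1 this is
   winner-take-all; at low lambda activation spreads across every unit with
   nonzero input ("many units responding").
3. **Imperfect suppression (bleed).**  Weak inhibition fails to fully
   silence what is not currently selected.  During learning, the semantics
   of unselected working-memory items enter the Hebbian pass at activation
   `0.7 * (1 - lambda)`; during reasoning, every firing slot's footprint is
   smeared with the other driver POs' semantics at fraction
   `0.45 * (1 - lambda)` of their weight.  Both floors are the same
   mechanism applied to the two banks; their scales are calibrated constants
   (below).

## Relational learning

Learning is comparison-driven.  Each learning trial samples 2–6 items from
long-term memory and compares them pairwise under working-memory
competition: the focal item is selected by the softmax, and its comparison
partner is the sampled winner of the recipient competition over the other
items — with strong inhibition the most similar item, with weak inhibition a
near-random one.

When two items are compared, semantics shared by both receive twice the
input of unshared ones; after normalization shared features sit at
activation 1.0 and unshared at 0.5.  A newly recruited predicate PO learns
one Hebbian pass, `delta_w = gamma * activation` (clipped at 1), and an RB
is recruited binding it to each compared object.  The new predicate
therefore codes the featural overlap of the pair — e.g. the role *inside*
when two contained objects are compared.  Two context effects operate inside
the learning loop (the bare comparison operators are exposed unmodified):

* **Semantic-layer sharpening.**  The activation pattern is raised to the
  power `1 + lambda` before the Hebbian pass: strong inhibition suppresses
  weakly active (unshared, bled-in) semantics, weak inhibition lets them
  through.
* **Pruning.**  Connections below 0.3 of the predicate's strongest
  connection do not survive the pass (weak, unreinforced connections decay).

After an opening period of 100 purely object-driven trials, half of all
trials (probability 0.5) instead sample among *relevant* learned predicates
— those connected above 0.9 to every semantic defining some transformation
role — so learned representations feed later comparisons.  Comparing two
predicates of the same role reinforces the defining semantics and halves
accidental ones (refinement); with strong inhibition a few refinement
generations yield essentially pure role predicates, while with weak
inhibition the bleed floor re-contaminates every generation and quality
plateaus.  When one trial predicates both roles of the containment relation,
the two co-active role-filler pairs signal recruitment of a P unit over
them, forming the whole relation.

**Quality metric.**  A predicate's representation quality with respect to a
role is the mean connection weight to that role's defining semantics divided
by (mean of all other nonzero connection weights + 1); the +1 bounds the
metric in [0, 1].  A checkpoint's mean quality averages this over every
predicate learned so far, each scored against the role it codes most
strongly.

## Analogical mapping and inference

A test item places the A and B terms in the driver and the C term in the
recipient; the A–C correspondence is never given and must be discovered.
Mapping runs two full driver cycles.  Each fired slot computes recipient
responses from three input sources: semantic overlap with the (possibly
smeared) footprint; structural top-down support (after a role unit responds,
the objects bound to it in the recipient receive +1.3, and the remaining
role units of an engaged recipient proposition receive +1.3 — this keeps
role-filler pairs of one driver proposition aligned with one recipient
proposition and lets featurally disjoint fillers map through their roles);
and feedback from already-formed mapping connections (+1.0 per unit of
mapping weight), which breaks ties between indistinguishable candidates and
keeps the developing mapping coherent.  Every unit also receives a
spontaneous-activity floor of 0.1, negligible under strong competition but a
genuine error source when competition is weak.

The sampled responder counts as a clear winner when its activation reaches
0.3 of the strongest response; a clear winner is linked to the firing unit
by Hebbian learning with subtractive normalization,
`delta_m = eta * (a_d a_r - a_d * max_other_m)` with eta = 0.9, clipped to
[0, 1].  (An absolute winner criterion deadlocks when two recipient
candidates are exact duplicates — e.g. the two containment pairs of a
two-binary item — because both saturate just below any absolute cut; the
relative criterion plus mapping feedback resolves such ties the way LISA's
constraint satisfaction does.)  The final winner map takes pairs greedily by
descending weight under a one-to-one constraint per layer.

Inference is self-supervised: after mapping, a driver RB to which no
recipient role-filler pair ever clearly responded triggers recruitment in
the recipient — a predicate PO image Hebbian-copied from the firing driver
predicate, the mapped image of the driver object (or a blank object
inheriting its semantics at 0.5 when no image exists), and an RB binding
them; driver P units with two or more inferred RBs get a P image.  The
recruited structure is the model's generated D term.  With no mapping at
all, inference is refused and the empty answer scores as a failure.

**Retrieval.**  At encoding time each transformation in the item activates
its defining semantics, and the learned predicate retrieved for it is the
most *selective* responder: among predicates whose summed weight to those
semantics reaches 1.0, the one with the highest quality for that role.  A
role for which nothing reaches the threshold is left unencoded, so that
transformation can never be inferred.

## Stimulus generation

The generator defines the study conditions and is not tuned per experiment:

* **World:** 100 objects; each samples 2–4 of the five transformations
  (adding an element, changing size, halving, doubling, changing
  containment) without replacement, taking both defining semantics of each
  unary transformation and exactly one randomly chosen role (two semantics)
  of containment, plus 4 idiosyncratic features from the remaining pool.
* **Batteries:** 20 items per test phase at 30% hard (3 transformations),
  35% medium (2), 35% easy (1), with sub-mixes by largest-remainder
  rounding: at n = 20, 6 hard (2 each of 2-binary+1-unary, 1-binary+2-unary,
  3-unary), 7 medium (3 two-binary, 2 two-unary, 2 one-each), 7 easy
  (3 binary, 4 unary; odd remainder to unary).  Term objects carry 4 random
  features each; A and C objects are featurally disjoint (no featural
  lures), and the B term shows A's objects transformed, so driver encoding
  holds two parallel role structures over one object set.  Item difficulty
  is descriptively `0.5 x elements + 1 x transformations`.

## Longitudinal protocol

Four groups of 100 simulated individuals: lateral inhibition drawn once per
individual from N(0.4, 0.1), N(0.6, 0.1) or N(0.8, 0.1), clipped to
[0.05, 1.0].  Low-knowledge groups learn for 800 trials and use the
checkpoint at 100·t for test phase t = 1..8; the high-knowledge group
(inhibition mean 0.8) learns for 1000 trials and uses checkpoint 100·t+200,
modelling richer relational knowledge at study entry.  Each phase is a fresh
seeded 20-item battery (parallel forms); mapping connections never persist
across trials, and no learning occurs during testing.  Each generated D term
is scored per transformation instance — correct when an inferred role-filler
pair carries a predicate coding that role bound to the C object the correct
answer assigns — and the trial is classified analogical (all instances
correct), incomplete (some), or associative (none, including empty answers).

## Calibration and numerical choices

The published account of this simulation fixes the protocol, the stimulus
statistics, the inhibition distributions and the quality metric, but not the
learning rate, mapping-update rule, pass counts or noise scales.  Those free
constants were calibrated once against the pooled solution-type percentages
of the reference simulation and then frozen as the package defaults; all
tests and the acceptance script run this single configuration:

| constant | value | role |
|---|---|---|
| gamma | 1.0 | Hebbian rate for predicate recruitment (single-pass saturating) |
| learning bleed scale | 0.7 | working-memory bleed during learning |
| sharpening exponent | 1 + lambda | semantic-layer competition in the learning loop |
| prune fraction | 0.3 | relative weight-pruning cut |
| relevance threshold / mix | 0.9 / 0.5 | definition of relevant predicates; refinement rate |
| eta | 0.9 | mapping-connection learning rate |
| n_passes | 2 | full driver cycles before inference |
| clear-winner fraction | 0.3 | relative response criterion for a mapping update |
| structural support | 1.3 | top-down input to bound fillers / engaged propositions |
| mapping feedback | 1.0 | response input per unit of existing mapping weight |
| response noise | 0.1 | spontaneous recipient input floor |
| reasoning bleed scale | 0.45 | driver smear during mapping |
| retrieval threshold | 1.0 | minimum defining-semantics weight for retrieval |

Other numerical conventions: ties in winner assignment break by weight then
lowest token id; RB order within a P unit follows ascending token id; a
comparison of fully disjoint items yields a uniform activation pattern (no
shared structure) and its predicate is never relevant; inhibition draws
outside [0.05, 1.0] are clipped; all randomness flows through a single
`numpy` generator per simulated individual, spawned from a root seed, so
every run replays exactly.

## What the simulations show — and what they do not

The synthetic world reproduces the *statistics* of the study stimuli, not
their appearance: semantics are anonymous indices, not visual features, and
"drawing the D term" is modelled as recruiting relational structure, not
producing a picture.  Scoring is structural; a child's partially correct
drawing has no analog here beyond the per-transformation correctness count.
The generator also omits featural lures between A and C terms (a config
point left open), pedagogically structured curricula (training is entirely
unstructured by design), and feedback-driven learning during test sessions
(the protocol only swaps in later checkpoints).  Passing tests therefore
show that the inhibition mechanism produces the observed learning
trajectories and error profiles under these idealized conditions; they do
not show that the model captures children's item-level behaviour, reaction
times, or the perceptual front end.  The three-way tie between group
trajectory shapes and inhibition level is a consequence of one manipulated
parameter, which is the point of the exercise — but the absolute
percentages depend on the calibrated constants above and should be read
with that in mind.

Known limitations: predicates are never garbage-collected, so late
checkpoints retrieve from inventories containing many low-quality recruits
(retrieval by quality makes this benign but slows nothing down more than
linearly); hierarchical propositions (P units as role fillers) are not
supported; and the slot-wise dynamics cannot express graded reaction-time
predictions.
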