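# Methods and design notes

## Featurization

Structures are canonicalized with RDKit; two SMILES denoting the same
molecule map to identical canonical text, and the full chain from
SMILES to pair feature is deterministic (bit-identical across runs).
Fingerprints are hashed Morgan/circular fingerprints, radius 2 over
2048 bits — the community-standard width, configurable. Similarity is
the Dice coefficient on fingerprint bit sets.

The reference panel for similarity profiles is a configurable ordered
drug list; for synthetic studies it defaults to all drugs of the
generated registry in registry order, and the order is persisted with
the projection model. PCA (k = 50, no whitening) is fitted on the
profiles of all gold-standard drugs — features precede the
train/validation/test split in the workflow, so the fit uses the full
profile set. Component signs are fixed by making each component's
largest-magnitude loading positive, so refits are reproducible. The
projection model persists as a text file (JSON header + CSV matrix)
and round-trips bit-compatibly.

Degenerate SMILES policy: corpus loading retains records with a parse
error but flags them structure-less, excluding them from prediction
(mirroring the restriction of the gold standard to pairs where both
drugs have a usable structure); direct API calls raise instead.

## Classifier

Input 2k = 100, nine hidden layers of 2048 rectified-linear units,
86 sigmoid outputs; batch normalization after each hidden linear
transform and before the activation, with scale/shift counted as
trainable (framework convention). With batch-norm parameters the
default architecture has 33,990,742 trainable parameters, without them
33,953,878; both round to 34 million, and the parameter audit accepts
the rounded value so either counting convention passes.

The gold standard records exactly one type per pair, but the head is
sigmoid multi-label trained with per-output binary cross-entropy, so
several outputs can fire for one pair — the mechanism-inference
analysis depends on this. Categorical accuracy (argmax vs the recorded
type, ties to the lowest type id) is the only accuracy metric
reported. Training is Adam at learning rate 0.001, batch size 1024,
a fixed 20 epochs with no early stopping and no class reweighting.
One config seed controls initialization, shuffling and batching;
training is CPU-deterministic. Batches that would contain a single
sample are skipped because batch statistics are undefined for them.

The network is implemented directly in NumPy (explicit forward and
backward passes, Adam, batch-norm backprop with running statistics for
inference, momentum 0.9, epsilon 1e-5). Checkpoints are a `.npz` of
the arrays plus a JSON sidecar with the configuration.

Studies in this repository train the same nine-layer architecture at
reduced width (256 units, batch 256): at the shipped scenario size
(~6,000 records of 100 features) full width adds cost without
measurable benefit, and the reduced model trains in well under a
minute on one CPU.

## Prediction protocol

Both orderings of every unordered pair are evaluated, since sentences
are directional; a type is reported for the ordering in which it
fired, and when both orderings fire the same type only the
higher-scoring one is kept so each (pair, type) is tallied once. A
predicted record is *known* iff the gold standard holds the same
unordered pair with the same type. The screening threshold is 0.94,
read as exactly twice the default threshold 0.47.

Drug–food pairs reuse the same 86-type head. A predicted DFI survives
only if some approved drug has Dice ≥ 0.75 (inclusive) to the food
compound and itself appears in a same-type gold record, in either
role. Raising the Dice cut-off can only shrink the surviving set.

## Cohort screening

"Counting with repetitions" means: the same unordered pair occurring
in several patients' plans counts once per patient; within a plan each
pair counts once, so the cohort combination total is Σ C(m_i, 2) over
patients (m_i = predictable drugs in plan i). The switch analysis
removes *all* drugs of the registry's DMD category from a plan before
adding the candidate; adding a candidate the patient already takes is
idempotent. The interaction-count trend is fitted by least squares of
log(count + 1) on the medication count, with a patient-resampling
bootstrap band; the fit is skipped (with a warning path) below three
distinct medication counts.

## Substitution

"Same pharmacological action(s) with the same protein target(s)" is
read as exact set equality of (target, action) pairs — the strictest
reading; a superset-match relaxation exists behind a flag, default
off. A suggestion must keep every critical-type activation below 0.47
in *both* orderings of the candidate pair, since critical sentences
are directional. Gold-standard critical records for the candidate pair
additionally veto the suggestion — a conservative extension beyond the
activation check.

## Synthetic scenario

The generator emulates the licensed/private study inputs. Its defaults
are the shipped study conditions: 300 drugs (11 DMD, 5 BTKi — the
BTK-inhibitor class is investigational, so it is unapproved and has no
gold records), gold density 0.135 (~5,900 records), 627 patients,
150 food compounds, 80 food sources, seed 0.

*Drugs.* Each molecule is a carbon scaffold carrying one dominant
substructure motif (of eight: carboxylic acid, tertiary amine,
sulfonamide, trifluoromethyl, phenyl, pyridyl, nitrile, methyl ether)
and up to two secondary motifs. The dominant motif is attached three
times so that the label-determining substructure dominates the
fingerprint — a construction requirement: with single attachment the
dominant motif is not reliably recoverable from a similarity profile,
and the premise that the label function is visible in the features
would fail by construction rather than by any property of the method.
Target/action sets are shared across round-robin groups of drugs so
the substitution analysis always has candidates.

*Gold standard.* The label of an unordered pair is a fixed, seed-
independent rule-table entry for the ordered dominant motifs, with the
lexicographically lower drug id as subject — exactly one type per
pair. Pinned cells give the adverse-effect type 26 asymmetric
pharmacokinetic counterparts (so both orderings of such pairs fire 26
plus a mechanism type), critical cells feed the substitution analysis,
and concentration-altering cells populate the food network; remaining
cells cycle through a non-critical type pool.

*Cohort.* Per-patient medication counts follow a negative binomial
truncated to 0..19, with (r, p) solved numerically (Nelder–Mead on the
truncated moments) to match mean 5.3, SD 3.3 — an overdispersed count
family consistent with the printed mean/SD/range; 62% of patients
carry one DMD. At the default size and seed the sampled mean is
within 0.2 of target. The resulting gold-based and prediction-based
cohort prevalences (62% and 85% in the default run) bracket realistic
polypharmacy screening rates without claiming to reproduce any
specific cohort.

*Food.* 20% of compounds copy the structure of an approved drug (Dice
1.0), guaranteeing the validation path fires; one compound always has
twelve sources, exercising the top-10 truncation; amounts are
lognormal, strictly positive, in mg per 100 g. Source ranking uses the
per-source *maximum* reported amount after aggregation (robust to
duplicate content rows); a mean-based ranking is available behind a
flag.

What the generator does **not** emulate: real pharmacology (motifs are
structural, not mechanistic), the full catalogue of real interaction
sentence texts beyond the shipped template table, correlated comorbidity structure, dosing, or
the size and label noise of the real corpus. Passing the synthetic
end-to-end checks therefore demonstrates that the pipeline's machinery
is correct and that the classifier recovers a structure-determined
label function from similarity-profile features — not that any
particular real-data accuracy would be attained.

## Numerical choices and degenerate inputs

* Dice of two empty fingerprints is undefined; empty molecules are
  rejected upstream.
* Thresholds are inclusive (score ≥ threshold fires; Dice ≥ 0.75
  validates) and activation ties in ranked output break to the lowest
  type id.
* Dataset split: floor(N·f) per partition, remainder to training —
  deterministic and training-maximizing.
* Source ranking ties break lexicographically by source name.
* PCA requires k ≤ min(#profiles, panel size); violations raise.

## Template table

The packaged table pins the sentence texts of types 1–7, 9, 10, 15,
20, 26, 27, 29, 32, 52, 54 and 67 (the concentration, excretion,
critical and named pharmacodynamic types used throughout the
analyses); the remaining types carry distinct placeholder sentences.
The subject slot is the causal agent; affected-drug templates place
the affected compound in the object slot. Rendering is invertible
given the table. Type ids are meaningful only relative to the loaded
template file; the critical flag is validated against the 14-type set
at load time.

## Known limitations

* No severity grading, dosing, timing or route modelling — interaction
  flags are early warnings, not clinical judgments.
* Substitution uses only direct target/action annotations; potency,
  indication and route differences are ignored.
* The synthetic label function is noiseless; real interaction data are
  uncertain and imbalanced, which this artifact does not model.
* Biologic drugs without SMILES are out of scope end to end.
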