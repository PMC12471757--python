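# Methods

## Model

A metabolite's producing organism is classified as diazotrophic (FIX = 1) or
non-diazotrophic (FIX = 0) by one-nearest-neighbor similarity in fingerprint
space. For a query with Tanimoto similarity *s* to its most similar labeled
reference metabolite, whose class indicator is *I*<sub>NN</sub>,

    P(FIX = 1 | s) = 0.5 + 0.5 · s · (2·I_NN − 1)

This is a linear interpolation between ignorance (*s* = 0 → 0.5) and full
confidence in the neighbor's label (*s* = 1 → 0 or 1). It is deliberately
not a calibrated posterior: it is a monotone evidence score whose rank
ordering is what the ROC-AUC evaluation measures. The class decision uses a
strict threshold, predicted class 1 iff P > 0.5, so a completely
uninformative query defaults to the negative (non-diazotroph) call.

Assumptions the model leans on:

* metabolite structures are strongly lineage-private, so structural
  similarity is a proxy for shared biosynthetic origin and hence shared
  producer phenotype;
* one neighbor suffices — the evidence is local. No k > 1 voting or
  distance weighting is attempted;
* the labeled reference set spans the chemotypes of interest. Queries far
  from every reference fall back to 0.5 rather than extrapolating.

### Tie handling

If several references attain the maximal similarity, the tie count is
recorded and the lexicographically smallest reference id is reported, for
reproducible output. If the tied references span both classes the score
collapses to exactly 0.5 (maximal uncertainty), which the strict threshold
maps to class 0 — conservative toward positive diazotrophy calls. The
probability is never rounded internally; output files round to six decimals
at write time.

## Fingerprints

The default representation is a hashed path fingerprint, fully specified so
results are reproducible from this repository alone:

1. SMILES are parsed and sanitized with RDKit; aromaticity is normalized so
   kekulized and aromatic spellings of the same molecule coincide.
2. All simple paths (no repeated atom) of 0–`depth` bonds are enumerated;
   default depth 30, chosen so that paths can span the macrocycles of large
   cyclic peptides.
3. Each path is encoded as alternating atom tokens (element symbol,
   lowercase when aromatic) and bond tokens (`-`, `=`, `#`, `:`); an
   undirected path contributes the lexicographic minimum of its two
   directions. Multiplicity is discarded (set semantics), matching binary
   fingerprint conventions.
4. Each unique path string is hashed with 64-bit FNV-1a and folded modulo
   `n_bits` (default 262,144, a power of two).

Path enumeration is capped at `path_limit` (default 1,048,576) unique
strings per molecule because simple-path counts can explode in polycyclic
systems; enumeration order follows RDKit canonical atom ranks so truncation,
when it happens, is deterministic and independent of atom input order, and a
warning is raised.

Tanimoto similarity of two fingerprints with identical configurations is
|A∩B|/|A∪B| over set bits. Two empty fingerprints compare at 0, not 1, with
a warning: structureless parses should not be declared identical.

Alternate backends share the scorer: `extended` adds ring tokens (size and
aromaticity of each SSSR ring) to the path set; `graph` drops bond orders
and aromatic case; `maccs_like` uses the fixed 166-key MACCS substructure
set; `external` accepts any callable yielding bit indices, which is how
toolkit-native fingerprints can be benchmarked. Bit-level compatibility with
any other toolkit's path fingerprint is a non-goal — the method depends only
on the Tanimoto ordering, which is robust across fingerprint families.

## Labeling rules

Strain-level FIX labels derive from proteome annotations: presence of any of
the nitrogenase marker proteins NifH, NifD or NifK ⇒ 1; none of them and a
reported proteome of **more than** `min_proteome` = 100 proteins ⇒ 0; none
of them and a proteome of at most 100 ⇒ unlabeled, because absence of nif
markers in a shallow proteome is uninformative and risks false negatives.
The boundary value 100 itself is left unlabeled (strict inequality). Strain
identity is the (genus, species, strain) triple after whitespace trimming
and case folding. A metabolite reported from several organisms becomes one
record per organism; conflicting labels across those records are retained
with a warning rather than resolved silently.

## Evaluation

* **LOOCV**: each labeled record is scored against all the others (its own
  fingerprint is excluded — asserted in tests); the pooled holdout
  predictions give one confusion matrix and metric set.
* **Repeated stratified k-fold** (default 10×10): per repeat, a stratified
  partition (per-class fold counts differ by ≤ 1), each fold held out once,
  the k holdout folds pooled, one metric set computed. The repeat is the
  unit of observation: means, Student-t 95% confidence intervals with
  df = repeats − 1, and a one-sided one-sample t-test of per-repeat AUCs
  against 0.5. Zero variance across repeats degenerates to p = 0 (mean
  above 0.5) or p = 1. Whether a normal or t interval is intended by
  convention varies between fields; the t choice is recorded in the report
  metadata.
* **Metrics**: accuracy, precision, recall, F1 at the strict 0.5 threshold;
  ROC-AUC computed rank-based (Mann–Whitney, midranks for tied
  probabilities). Precision/recall with zero denominators report 0 and log.
* **Duplicates**: exact duplicate structures are kept by default, since real
  metabolite tables contain them; `--dedupe` collapses identical canonical
  SMILES and logs the leakage risk. With duplicates present, a holdout copy
  finds its twin at similarity 1, so CV scores should be read as optimistic.
* **Permutation null** (`permutation_null_cv`): each repeat independently
  shuffles the labels before its k-fold pass, so per-repeat AUCs are
  independent draws from the no-association null and their 95% CI should
  cover 0.5. A single fixed shuffle would not work here: nearest-neighbor
  predictions are dominated by a few structural hubs, so fold-to-fold
  variance is far smaller than shuffle-to-shuffle variance and the CI would
  be spuriously narrow around whatever AUC that one shuffle produced.

## Descriptors and chemical space

The nine descriptors are halogen count (F/Cl/Br/I), nitrogen count, oxygen
count, SSSR ring count, hetero-to-carbon ratio ((N+O+S+X)/C), N/C ratio,
amide count (SMARTS `[CX3](=[OX1])[#7]`), carboxyl count
(`[CX3](=[OX1])[OX2H1]`), and double-bond equivalents
(2C + 2 + N − H − X)/2. This concretization follows the descriptor families
that discriminate the two chemotypes (halogenation, heteroatom content, ring
architecture, amide/carboxyl functionality, unsaturation); it is an
interpretation, not a canonical list. Ratios are NaN for carbon-free
molecules and excluded from statistics.

Z-score summaries standardize each descriptor against the global mean and SD
over all molecules (population SD, ddof = 0 — exposed as a parameter), then
aggregate within groups by mean (class views) or median (cluster views).
Zero-variance descriptors report z = 0 with a warning.

Clustering is agglomerative on Tanimoto distances (d = 1 − s) cut at
`n_clusters` = 6; linkage defaults to average, which behaves robustly for
bounded chemical distances, with complete and single selectable. Cluster ids
are renumbered in order of first appearance along the sorted-id axis so the
partition is deterministic. Per-cluster enrichment is the percentage of
FIX = 1 members. Unknowns are assigned the cluster of their globally nearest
labeled metabolite (ties by smallest id), and the distribution of those
nearest distances per cluster measures how novel the unknowns are relative
to the labeled space.

The MDS embedding is classical Torgerson scaling: double-center the squared
distance matrix, take the top eigenpairs, scale eigenvectors by the square
roots of the eigenvalues; negative eigenvalues among the kept components are
truncated to zero with a warning. On exactly Euclidean-embeddable inputs the
pairwise embedded distances are reproduced to 1e-9 (tested).

## Synthetic data generator

The generator emulates the class contrast the method exploits, at the
chemistry level rather than the feature level, so parsing, fingerprinting
and scoring are exercised end-to-end:

* class 1: homodetic cyclic peptides — backbone N–Cα–C(=O) repeated and
  ring-closed — with side chains drawn from eight proteinogenic-like
  fragments, two of them nitrogen-rich (lysine- and arginine-like). Default
  3–8 residues, typical of cyanopeptide macrocycles.
* class 0: linear polyketide-like chains of 4–10 units (methylene, ketone,
  hydroxyl, alkene) halogenated with Cl/Br at rate 0.5 per unit; no
  nitrogen.

`separation` ∈ [0, 1] sets the probability (0.5 + separation/2) that a
record's chemotype matches its class, so separation = 1 gives structurally
disjoint classes and separation = 0 removes the signal entirely.
`label_noise` flips labels independently afterwards. All draws flow from one
seed; datasets are byte-identical across reruns.

What the generator does **not** emulate: real biosynthetic logic (NRPS/PKS
module grammar), stereochemistry, molecular-weight distributions, shared
scaffolds between classes, or database artifacts such as duplicated entries
and mixed naming. Passing tests on synthetic data therefore demonstrate that
the pipeline recovers a structural class signal when one exists and stays at
chance when it does not — not that any particular real-world accuracy will
be achieved, which depends on the reference database and its labels.

## Problem sizes and defaults

Tests and examples run the full default fingerprint (depth 30, 262,144 bits)
on datasets of 30+30 synthetic metabolites for LOOCV and 10×10 repeated CV —
sizes at which every result in the repository reproduces in seconds — and
smaller folded widths (4,096 bits) where only distance ordering matters.
Defaults elsewhere: decision threshold 0.5, k = 10 folds, 10 repeats,
6 clusters, average linkage, `min_proteome` = 100.

## Known limitations

* The probability is uncalibrated; 0.85 means "similarity 0.7 to a positive
  neighbor", not a frequency guarantee.
* Horizontal transfer of biosynthetic gene clusters and promiscuous
  tailoring enzymes can decouple a metabolite from its producer's genotype,
  producing structural false positives no chemistry-only model can remove.
* Fingerprint hashing collisions can inflate similarity between unrelated
  molecules at small `n_bits`; the 262,144-bit default makes this negligible
  but folded widths below ~4,096 bits should be used only for distances, not
  probabilities.
* Duplicate structures across records leak between CV folds unless
  `--dedupe` is used.
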