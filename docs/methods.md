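# Methods

`ipastrace` models the computational path from a genomic sequence to the
claim that a gene expresses a truncated, evolutionarily young protein
isoform driven by a repeat-borne intronic polyadenylation site (iPAS).
This note records the models, parameter choices, numerical details and
limitations behind each stage.

## PAS discovery and truncated-isoform prediction (`pas_scan`)

A polyadenylation signal is a hexamer, canonically AATAAA. The default
motif set is the canonical hexamer only; a flag enables the twelve common
variants (AATAAA, ATTAAA, TATAAA, AGTAAA, AAGAAA, AATATA, AATACA, CATAAA,
GATAAA, AATGAA, TTTAAA, ACTAAA). Scanning is case-insensitive because the
signals of interest sit inside soft-masked repeat sequence; N never
matches. Coordinates are 0-based half-open on the plus-strand genome axis
throughout; transcript orientation is derived from strand at operation
time. Minus-strand scans operate on the reverse complement and mirror
coordinates back, so strand symmetry is exact.

Hits are clustered by transitive closure under >=1 nt overlap — the
natural encoding of "partially overlapping" signals without a tunable
threshold. The cleavage site is predicted at a fixed offset (default
20 nt) downstream of the *end* of the 5'-most hexamer, encoding the
canonical PAS-to-cleavage spacing; no learned cleavage model is included.

ORF extension translates the CDS through the last shared exon, completes
any partial codon with intronic bases, and reads codons into the intron to
the first stop. The tail peptide comprises residues whose codons contain
at least one intronic base; the 3'UTR runs from the stop to the cleavage
site. Protein mass uses average isotopic residue masses (Biopython), with
the initiator Met retained and no post-translational modifications; a
single glycine reproduces free glycine's mass within 0.01 Da.

## Short-isoform fraction from junction counts (`junction_usage`)

Under a two-isoform mixture in which a fraction psi of transcripts
terminate at the iPAS, junctions upstream of the termination site receive
reads from all transcripts and downstream junctions from the read-through
fraction only, so E[mean(down)]/E[mean(up)] = 1 - psi. The estimator is

    psi_hat = clip(1 - mean(down) / mean(up), 0, 1),

using group means rather than sums so unequal group sizes (four upstream
vs five downstream junctions by default) do not bias the ratio. The raw,
possibly negative value is kept as a diagnostic. Confidence intervals are
percentile bootstrap (default 2,000 resamples) over a multinomial at the
observed total — resampling reads over junctions, seeded. The
no-truncation test is a chi-square goodness of fit against equal
expectations; for totals below 500 the p-value comes instead from a seeded
Monte-Carlo evaluation of the exact multinomial null (full enumeration
over count compositions is infeasible).

Only uniquely mapping junction reads (STAR `SJ.out.tab` column 7) count by
default; multi-mappers are parsed but ignored unless requested. The
pext-style exon inclusion is TPM-weighted transcript membership; tissues
with zero total expression are skipped with a warning.

Calibration, measured by the acceptance suite at the study depth of
10,000 junction reads: pooled over psi in {0.1, 0.3, 0.5, 0.7} (50 seeded
replicates each), |psi_hat - psi| < 0.03 in ~95-98% of replicates and the
95% bootstrap interval covers the truth in ~94-97%. A delta-method
calculation shows sd(psi_hat) ~ 0.018 at psi = 0.1 at this depth, so the
error band is intrinsically tighter at larger psi; per-psi guarantees at
psi = 0.1 would need more depth, not a different estimator.

## Long-read classification (`longread_classify`)

Reads are exon chains; isoforms are defined by their internal junction
chains. Collapse groups reads with identical junctions (splice junctions
are base-exact by default, junction tolerance 0 nt) and merges terminal
ends within 50 nt, taking the longest-span member as representative.
Classification requires a read's junctions to form an in-order subset of a
model's junctions, no read-through of a model intron, and a 3' terminus
within 50 nt of the model's. The 5' end is unconstrained because cDNA
long reads are frequently 5'-degraded. A read compatible with more than
one model — in particular a 3'-truncation artifact covering only shared
junctions — is "ambiguous", never evidence for the short isoform, because
the short isoform's only distinguishing feature is its terminus; a read
extending past a model terminus beyond tolerance matches nothing and is
"novel".

## PAS evolution on a species tree (`pas_evolution`)

Element presence follows Dollo parsimony: a retrotransposon insertion at
one orthologous position is a unique event, so a single gain is allowed
and all absence below it is explained by losses. Tips take one of three
states: `present`, `absent`, or `lost` — the last meaning absent *with
independent evidence of secondary deletion* (e.g. deletion breakpoints in
an alignment). The gain is placed on the branch above the MRCA of
present-or-lost tips; with plain `absent` the gain instead sits on the
smallest clade containing all present tips (the loss-minimizing placement).
The three-state design is needed because deletion evidence legitimately
forces a deeper gain than presence data alone would justify.

PAS count follows Sankoff parsimony with linear cost |i - j| (one
substitution creates or destroys one hexamer); unit cost is a flag. Tips
lacking the element are NA — not zero — because a deleted region has no
defined hexamer count; NA tips contribute zero cost in any state and never
increase the total. The DP computes bottom-up cost vectors and an outside
pass, yielding for every node the set of states attained in at least one
globally optimal assignment and for every branch the set of optimal
(parent, child) state pairs. A branch carries a *certain* event only when
no optimal pair leaves the state unchanged; changes present in some but
not all optima are listed separately as possible events. Ties in cost are
resolved by reporting sets, never by arbitrary choice (tolerance 1e-9 on
cost comparisons).

Node ages come from branch lengths when the tree is declared ultrametric
(age = tree height - root distance, in Mya); events are dated to the
[child age, parent age] interval of their branch. The bundled primate
fixture has 13 tips with standard divergence-time estimates (root 74 Mya;
Simiiformes 43; Catarrhini 29; human-chimp 6.5; human-Neanderthal 0.5,
with the Neanderthal tip at 0.05 Mya). On the bundled character matrix
the reconstruction yields a +2 count change on the Homo branch (interval
[0.5, 6.5] Mya), +1 on the gibbon stem, -1 on the Colobinae branch,
a single element insertion on the Simiiformes stem ([43, 69] Mya) and one
Platyrrhini loss — all certain (no ambiguous optima).

## IP-MS enrichment and NSAF stoichiometry (`ipms_nsaf`)

Enrichment follows the standard Perseus-style workflow: log2 transform,
per-run median centering, imputation of missing values from a down-shifted
Gaussian (per-run mean - 1.8 sd, width 0.3 sd — the Perseus convention,
configurable, seeded), Welch's t-test per protein (Student's by flag) and
Benjamini-Hochberg adjustment flagging q < FDR (default 0.01).
Permutation-based FDR with S0 is out of scope. With 3-vs-3 designs the
per-protein t-test has ~4 degrees of freedom; after BH correction the
power to flag even 8-fold enrichments is partial (~0.5 at the BH cutoff
for 5 true among 200 null proteins at sd 0.3), while false flags on null
data average well under 2% at FDR 0.01 — the workflow is conservative by
construction, which matches its screening role.

NSAF divides spectral counts by protein length (SAF) and normalizes each
run's SAF to sum to one over detected proteins; zero-count proteins have
NSAF 0 and are excluded from the denominator. Stoichiometry divides every
protein's NSAF by the bait's *per run*, then averages across replicate
runs (SEM = sd/sqrt(n)); normalizing per run before averaging is the
chosen order (the alternative — averaging NSAF first — differs only at
noticeable run-to-run depth imbalance). The bait is exactly 1 with SEM 0;
runs without the bait are excluded with a warning.

The recovery simulation plants a 2:1 partner:bait complex over a
background of nonspecific binders and checks the recovered mean ratio
against truth within 2 SEM. The simulated experiment uses 8 technical
replicates: the probability that a t-distributed mean lies within 2 SEM
of truth is the t(n-1) coverage of +/-2, which is ~82% at n = 3 and only
reaches ~90% at n >= 7, so a 90% recovery target is meaningful only at
that replication level. The generator's default remains n_runs = 3,
matching common IP-MS practice.

## SASA and interface mapping (`interface_map`)

Shrake-Rupley with a deterministic golden-spiral quadrature (default 960
points) on each atom's probe-inflated sphere (probe 1.4 A); neighbor
search by KD-tree. Identical inputs give bit-identical areas. Quadrature
error against the analytic isolated sphere is <0.5% and against the
two-sphere spherical-cap closed form <1% at defaults. Van der Waals radii
are a bundled Bondi-style element table (C 1.70, N 1.55, O 1.52, S 1.80
A, ...; default 1.70 A); heavy atoms only by default since cryo-EM models
typically lack hydrogens; alternate locations keep the highest-occupancy
conformer.

Buried fraction of a chain = (isolated SASA - in-complex SASA) / isolated
SASA. The per-residue interface map computes burial *pairwise* (target
plus one partner at a time) rather than leave-one-out: pairwise burial
attributes shared interfaces conservatively and matches the "main
interacting subunit" semantics (argmax of per-partner buried area; ties to
the earliest declared partner; fully exposed residues unassigned).
Residue numbers missing between a chain's first and last modelled residue
form the unresolved mask.

## Synthetic data (`synthetic_data`)

Every generator is a pure function of (seed, parameters); one global seed
fans out to per-stage child seeds through a fixed `SeedSequence`
derivation. Each dataset carries a ground-truth sidecar, and recovery
tests read truth only from sidecars.

What the generators emulate — and what they do not:

- **Locus**: a ten-exon gene whose fifth intron carries a FLAM-like
  monomeric element whose A-rich tail holds exactly k overlapping AATAAA
  hexamers (period-4 overlap), placed so the predicted cleavage site falls
  ~276 nt into the intron and the intron-derived 3'UTR is 240 nt; an
  11-codon in-frame tail precedes it. Chance AATAAA occurrences outside
  the planted run are destroyed so recovery is exact. Real introns have
  unmasked paralogous signals, GC heterogeneity and indels; passing tests
  therefore demonstrate coordinate and bookkeeping correctness, not motif
  discrimination in noisy sequence.
- **Junctions**: multinomial counts with upstream weight 1 and downstream
  weight 1 - psi (Dirichlet-multinomial under a dispersion parameter).
  Real libraries add mappability and length biases the estimator does not
  model.
- **Tree characters**: one insertion branch, per-branch loss probability,
  +/-1 count steps; truth records every event branch. Real evolution can
  hit one branch repeatedly, which parsimony cannot resolve.
- **Spectra**: per-run multinomials with sampling probability proportional
  to abundance x length over complex members plus low-abundance
  background — the exact generative assumption behind NSAF, so recovery
  tests validate the estimator under its own model, not detector
  saturation or peptide-level effects.
- **Long reads**: Gaussian terminal jitter (sd 10 nt) and optional
  junction corruption (10-30 nt shifts) that breaks exact matching by
  construction; no sequence-level error model.
- **Toy structures**: single spheres, sphere pairs and shell-enclosed
  atoms with closed-form accessible/buried areas.

## Problem sizes

The default verification run uses: 200 pooled psi replicates at depth
10,000 with 2,000 bootstrap resamples; 1,000 random sequences for the
scan oracle; 200 random trees (<= 8 tips, <= 4 states) against exhaustive
enumeration; 100 seeds x 200 proteins for the null-FDR simulation; 100
replicates for stoichiometry recovery; 960 quadrature points for SASA.
These sizes give stable pass/fail margins while keeping the whole suite
around a quarter of a minute of compute.

## Known limitations

- The cleavage-site heuristic is a fixed offset; it ignores sequence
  context downstream of the hexamer.
- Parsimony reports branch intervals, not point dates, and cannot split a
  +2 change into one or two mutational events.
- The enrichment test's BH-based FDR differs from permutation FDR with S0;
  q-values are comparable only qualitatively.
- Pairwise burial double-counts area buried against multiple partners
  simultaneously; chain-level buried fractions use the full complex and
  are unaffected.
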