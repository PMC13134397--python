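# Methods

This note documents the models, parameter choices and numerical
decisions behind `glycopop`, and what the synthetic-data tests do and
do not establish about real data.

## Composition algebra

Glycans are handled as *compositions* — multisets over
{Hex, HexNAc, Fuc, NeuAc, NeuGc} — the resolution of glycopeptide
database-search output. Residue monoisotopic masses are computed from
elemental residue formulas (Hex C6H10O5, HexNAc C8H13NO5, Fuc C6H10O4,
NeuAc C11H17NO8, NeuGc C11H17NO9) and validated to 1e-4 Da against any
user-supplied table. NeuGc is included by default because murine IgG
carries it. Constants: proton 1.00727646688 Da, water 18.0105646863 Da,
13C–12C spacing 1.00335483507 Da; fixed carbamidomethyl-Cys +57.02146,
optional Met oxidation +15.994915.

Linkage and topology are out of scope: Hex does not distinguish
mannose from galactose, and no isomer resolution is attempted
anywhere.

**Y-ion ladders** enumerate the full sub-composition lattice retaining
≥ 1 HexNAc (terminating at Y1 = peptide + HexNAc), because "sequential
monosaccharide losses" from a branched glycan do not follow a single
linear order; a linear-path mode exists for compact libraries.
**Oxonium ions** are protonated residue sums of glycan sub-units with
0–2 water losses (default {0, 1}), covering the 204.09/186.08,
163.06/145.05, 292.10/274.09 and 366.14 series; cross-ring fragments
are not modeled.

**Delta decomposition** enumerates every signed combination of at most
`max_changes` residues (default 2) whose net mass matches a precursor
difference within 0.1 Da, sorted by (number of changes, |error|).
Mixed signs are allowed: −Fuc+Hex explains +15.995 Da. With the
five-residue alphabet and two changes the search space is 61 signed
vectors, so exhaustive enumeration is exact and cheap.

## Spectral networking

Scans are retained when they contain a peak within 0.02 Da of
m/z 204.0867 (presence only by default; a relative-intensity floor is
configurable, and alternative target lists are supported). Before
clustering, peaks within ±17 Th of the precursor are removed and the
top 6 peaks per 50 Th window kept — standard molecular-networking
hygiene.

Cosine similarity uses square-root intensity weighting over an **exact
maximum-weight one-to-one peak matching** within the fragment
tolerance: candidate pairs form a bipartite graph whose connected
components are almost always single edges; ambiguous components are
solved by the Hungarian algorithm. This guarantees the score equals
exhaustive best matching (a greedy matcher can be suboptimal when one
peak has two partners in tolerance). Plain (non-shifted) cosine is the
default.

Clustering is greedy single linkage over scans sorted by
(precursor m/z, scan id) — deterministic and order-independent — with
0.02 Da precursor tolerance and the 0.7 cosine threshold also used for
edges (the consensus-building threshold is configurable separately).
Consensus peaks are intensity-weighted mean m/z of peak groups pooled
across members. Network edges require cosine ≥ 0.7 **and** ≥ 6 matched
ions; optional per-node top-k edge pruning (default off), as molecular
networking services commonly apply.

## Network walk

All mass comparisons are in neutral monoisotopic mass. When a node's
charge is unknown, charges 1–4 are tried and the best interpretation
kept. Seeding requires a member scan with a PSM whose glycopeptide
mass matches within 0.1 Da, allowing ±1 proton (ionization artifacts);
score > 100 (the conventional search-engine acceptance bar here);
conflicts resolve to the highest score. Each iteration applies the
exact one-proton transfer rule, then delta propagation; frontiers are
committed level by level, so results are independent of neighbor
visitation order. Conflict resolution: fewest hops, then smallest
cumulative |mass error|; competing distinct annotations set an
ambiguity flag with alternatives retained. Seeds are immutable, the
annotated set grows monotonically, and the walk terminates at a fixed
point. Propagated annotations never change the peptide backbone, and
no FDR is estimated for them — they are hypotheses, as in any
propagation scheme.

## Biosynthesis rules and substructure networks

Composition-level N-glycan validity (defaults): HexNAc ≥ 2, Hex ≥ 3
(Hex ≥ 2 with the paucimannose flag), NeuAc+NeuGc ≤ max(0, HexNAc−2),
sialic acid requires Hex > 3, Fuc ≤ 2, plus sanity caps per residue.
The endoglycosidase product class (HexNAc(1), Fuc ≤ 1, nothing else)
is valid only when the truncation flag is on. The rule set is a
configurable predicate table; published reaction-rule collections are
not reproduced verbatim, so theoretical-glycoform counts from these
defaults need not match any particular published tally.

The substructure network closes an observed composition set downward
to the trimannosyl core HexNAc(2)Hex(3) by single-residue removals,
keeping only rule-valid intermediates. It is a DAG by construction
(every edge strictly decreases residue count) and the closure is
idempotent. Observed compositions that cannot reach the root under the
rules are kept and flagged rather than dropped.

## Transition libraries and GlycoPOP-MS quantification

Precursors are the cross product of rule-valid compositions × peptides
× charges 1–4, filtered to the 100–1800 Th scan range. MS1 transitions
are 3 isotopes spaced 1.00336/z. Fragment transitions are the oxonium
series (sub-units up to 3 residues) plus the Y ladder.

Feature superclasses collapse fragment transitions across precursors.
Default criteria (documented proxies, configurable):

* fucosylation — fragments with Fuc ≥ 1 (mostly Y ions; core fucose
  rarely yields oxonium signal);
* galactosylation — oxonium fragments with Hex ≥ 1 and HexNAc ≥ 1 and
  **no sialic acid** (the 366.14 series). Sialylated antenna ions such
  as 657.24 contain galactose but track sialylation, and Y ions beyond
  Y1 always contain core Hex+HexNAc, so both are excluded;
* sialylation — fragments with NeuAc ≥ 1 or NeuGc ≥ 1 (292.10, 274.09,
  657.24, sialylated Y ions);
* high-mannose — Hex-only oxonium fragments (163.06/145.05 series).

A member transition is *specific* when no fragment anywhere in the
library that violates the criterion lies within the extraction
tolerance (10 ppm) of its m/z; only specific transitions are used for
feature quantification, which removes universally shared ions such as
204.09.

Extraction: 10 ppm, summed peak intensity per scan; MS2 XICs are taken
from every DIA window whose isolation range intersects the entry's
precursor range (feature entries draw on all windows), and areas from
multiple windows are summed. Integration is trapezoidal after
subtracting the in-window minimum (a simple, monotone baseline). For
DDA MS1 quantification a ±5 min gate around identification times is
supported. Missing values stay missing (default S/N floor 10,
configurable) and are excluded from percent-of-total denominators.
Feature areas are normalized to the sample's Y1 area; glycoform MS1
areas are expressed as percent of the per-site total. Group comparison
is a plumbing-level Welch test on log2 values with Benjamini–Hochberg
adjustment — not a full mixed-model analysis.

## Biodiversity statistics

Indices: richness, Shannon, inverse Simpson, Pielou J = H/ln S, Hill
evenness D₂/S, Fisher's α (bracketed Brent root of
S − α ln(1+N/α) = 0, tolerance 1e-8; +∞ when all species are
singletons), and Rényi profiles over
{0, 0.25, 0.5, 1, 2, 4, 8, 16, 32, 64, ∞} with analytic limits at
a = 0, 1, ∞. Rényi entropies factor out the dominant proportion before
exponentiation so large orders cannot underflow; exp(H₂) equals
inverse Simpson to 1e-10. Both Pielou and Hill evenness are reported
because published "evenness" values in this area sometimes exceed 1,
which no single standard definition produces. Percentages are
converted to pseudo-counts for Fisher fitting by scaling to 1000
individuals and rounding (keeping at least one count per present
glycoform). An exploratory AIC comparison against a discretized
lognormal and the broken-stick model is provided; it is heuristic, not
formal model selection. Rarefaction estimators are out of scope.

## Synthetic data generator

The generator emulates the study conditions end to end:

* **Populations**: log-series communities (default α = 5, N = 1000,
  matching the skew of quantified IgG glycoform tables) over a
  rule-valid IgG-like panel (high-mannose Man4–Man9 + bi/tri-antennary
  complex forms, 0–1 core fucose, 0–2 NeuAc). Condition presets
  (ivig, ava, fut-ko, gal-ko, st-ki, man-high, wt, uniform) assign the
  largest log-series counts to the compositions each condition
  favours, emulating expression systems and glycoengineering. The
  log-series sampler draws S = α ln(1+N/α) species with iid log-series
  abundances; a stopping-rule sampler would size-bias the last species
  and inflate re-fitted α.
* **Spectra**: oxonium + Y-ladder + 3 precursor isotopes. Oxonium
  weights are linear in residue counts with terminal-exposure factors:
  hexose oxonium signal comes predominantly from mannose-terminated
  structures, galactose in complex antennae appears mainly in the
  366.14 series (plus a small constant core term), sialic acid drives
  292.10/274.09/657.24. Y-ion intensity decays exponentially with
  residues lost; Y1 has its own weight. A two-parameter collision-
  energy mode (low/high/stepped) reproduces the qualitative contrast:
  low energy favours neutral-loss Y ions, high energy oxonium and Y1.
  Noise: Gaussian m/z jitter (sd 0.003 Da), lognormal intensity
  scatter (CV 0.15), Poisson noise peaks (mean 15 per MS/MS scan).
  Peptide b/y backbone ions are omitted by default (the pipeline never
  uses them).
* **Chromatography**: Gaussian peaks (σ 0.15 min); glycoforms of one
  backbone co-elute at 17 min with sialylated species +2 min, as seen
  for IgG glycopeptides on reversed phase.
* **Runs**: DDA emits 5 replicate MS/MS scans per glycoform around its
  apex (~3 Da isolation) plus MS1 surveys; DIA emits repeating cycles
  of MS1 + two 600 Da windows (600–1200, 1200–1800 Th) every 2 s over
  14–22 min. Wide-window MS2 scans contain the summed fragments of all
  co-isolated species — the GlycoPOP-MS geometry.
* **EndoS time course**: at each timepoint a non-decreasing fraction
  of every intact glycoform moves onto HexNAc(1) (or HexNAc(1)Fuc(1)
  when the parent was core-fucosylated); totals are conserved up to an
  optional hemoconcentration factor. The demonstration uses fractions
  (0, 0.75, 0.9, 0.98) over 0–36 h — rapid cleavage — because small
  truncated fractions transiently *raise* inverse Simpson (two new
  product species appear before dominance sets in); monotone decline
  from the baseline requires the dominance regime, which these
  fractions guarantee for any baseline with D₂ ≳ 2.3.

## Problem sizes and what the tests show

The end-to-end checks run at desk scale by design: ~30 glycoforms × 5
scans per DDA run, 8 DIA conditions, 4 time-course points. At this
scale: oxonium filtering is exact against ground truth; clustering
yields ≥ 95 % composition-pure nodes; the walk recovers ≥ 80 % of
unseeded compositions from 30 % seeding; Y1-normalized feature areas
for galactosylation, sialylation and high-mannose correlate with
planted residue content at r ≥ 0.95 across conditions; and the
truncation time course gives monotonically rising truncated areas and
falling inverse Simpson.

These results validate the *pipeline logic*, not instrument reality.
The generator omits: chimeric co-isolation in DDA, isotope-envelope
shapes beyond 3 peaks, charge-state mixtures per precursor (one charge
by default), retention-time drift between runs, interference from
non-glycopeptide ions beyond uniform noise, and detector saturation.
Passing tests therefore show the algorithms do what they claim on data
matching their assumptions; performance on real runs depends on how
far those assumptions hold.

## Numerical conventions

Ties in clustering and propagation are broken by sorted identifiers so
all stages are deterministic given a seed. Tolerances: 0.02 Da
(clustering/fragments), 0.1 Da (walk and seed matching), 10 ppm
(extraction and specificity). Degenerate inputs fail loudly (empty
spectra, all-zero abundance vectors, S > N count vectors) or are
flagged rather than silently coerced (zero Y1 areas, zero site totals,
unreachable observed compositions).
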