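# Methods

## Duplex anatomy

A candidate site is evaluated in two stages. The **seed match** is anchored
at the site's 3′ end: numbering target nucleotides t1, t2, … from the 3′ end
(t1 faces miRNA position 1), the classifier checks Watson–Crick pairing of
miRNA positions 2–8 against t2–t8 and the identity of t1. The hierarchy is
8mer (2–8 paired, t1 = A) > 7mer-m8 (2–8 paired) > 7mer-A1 (2–7 paired,
t1 = A) > 6mer (2–7 paired). The A1 rule is applied to the *target*
nucleotide regardless of the miRNA's position-1 identity, matching the
canonical definition of these classes.

The **3′ supplementary helix** is found by exhaustive enumeration of all
seed-anchored two-helix decompositions: a target-side loop of b unpaired
nucleotides, a miRNA-side loop of b′ unpaired nucleotides, then a contiguous
helix of L Watson–Crick pairs between the miRNA 3′ region (past the seed
helix) and the target 5′ segment. The decomposition maximising L is
reported; ties prefer the smaller target bulge, then the helix closest to
the seed on the miRNA strand. The site and miRNA lengths in play are ≤ 30
and ≤ 25 nt, so the enumeration is exact and fast; the unit tests check it
against an independently written brute-force oracle on 1,000 random pairs.

Pairing is strict Watson–Crick (A:U, G:C) by default. G:U wobble pairing is
available behind a flag and is reported as such. The strict default is the
auditable choice: on the published Serpine1 construct it yields 10
contiguous 3′ pairs for miR-30c-5p (where the published genomic alignment
counts 11) and 9 for miR-30b-5p; whether the extra base reflects a wobble
pair or a construct/genome sequence difference cannot be decided from the
printed sequence alone.

**Eligibility.** A duplex is TDMD-eligible when the seed class is 8mer or
7mer-m8, the supplementary helix spans ≥ 8 nt, and the target-side bulge is
1–7 nt. The 7-nt upper bound reflects the observation that the bulge can be
extended to seven nucleotides with only a modest loss of degradation; a
"strict" preset (bulge 3–4 nt) encodes the narrower >2 and <5 nt rule of
the ideal-candidate description. Bulge length is measured on the target
strand; the miRNA-side loop is kept as a diagnostic.

**UTR scanning** applies the classifier at every position; each reported
site window extends miRNA-length + 7 nt upstream of the seed to leave room
for the supplementary helix. Sites whose 8-nt seed regions overlap are
resolved by keeping the higher class. Overlap is judged on seed regions, not
whole windows, so tandem perfect sites (as in the four-repeat sensor) are
all reported.

## Candidate screen

The 3C-score (TargetScan's 3′ pairing contribution) is consumed from input
tables, never recomputed. Class boundaries: entry at −0.01, low/mid at
−0.03, mid/high at −0.05, with boundary values assigned to the more negative
class (the source legend does not state inclusivity; this choice is
documented and configurable). Expression filters: a gene counts as expressed
at ≥ 1 RPKM in at least one supplied condition; a miRNA at strictly > 10
CPM. Pool contribution of a target is its RPKM share of the summed RPKM of
all the miRNA's 3C-targets at or above a class floor, per condition.
Fold-changes use a 0.1-RPKM pseudocount so transcripts absent at the
reference time point (the first column, 0 h by convention) get bounded
values; pairs with several predicted sites are ranked by their best class.

## isomiR classification

Reads are assigned to a reference by exact prefix identity over the first
`len(canonical) − max_trim` nucleotides; reads matching two references'
anchors are ambiguous and excluded from profiles. A read equal to the
canonical sequence is CANONICAL; a canonical prefix shortened by ≤ 4 nt is
TRIM; an extension is first stripped of its longest prefix matching the
downstream genomic context (extensions fully explained this way are
TEMPLATED_3P and never counted as tailing), and the non-templated remainder
of ≤ 4 nt is typed NT_A (all A), NT_U (all U) or NT_MIXED. Anything else —
including 5′ variants — is OTHER. The 4-nt trim/tail windows are defaults in
the style of standard isomiR workflows and are configurable; the
longest-templated-prefix rule makes non-templated calls conservative.
Normalisation is reads-per-million with an optional per-condition division
by an externally supplied global-amplification factor.

## Stoichiometry

Standard curves are ordinary least squares of Cq on log₁₀(input copies)
(≥ 3 points; a warning is issued below a 2-decade span), with amplification
efficiency 10^(−1/slope) − 1. Copies per cell invert the curve and divide by
cells per reaction; conversions outside the calibrated range are flagged as
extrapolated. The target-per-miRNA ratio divides target cpc by miRNA cpc;
a pooled denominator (summed cpc over a family subset) is available because
the reported steady-state ratio of ~1 for Serpine1 is consistent only with a
pooled or higher-abundance-member denominator — which member the original
ratio used is not stated. Apparent half-life from an observed drop assumes
pure exponential loss with negligible synthesis: t½ = −Δt / log₂FC; the two
observed 4-h fold-changes (−0.88, −1.13) average to t½ ≈ 4.0 h.

## Activity statistics

Target-set shifts are differences of medians (set minus non-targets) with
two-sided Wilcoxon rank-sum p-values; raw p-values are reported by default
(Benjamini–Hochberg available behind a flag). Per-miRNA summaries require
≥ 50 targets present in the regulation table. Differential miRNA expression
uses two-sided Welch's t-tests on log₂(CPM + 1). The serum DEG filter keeps
genes with max RPKM > 1 and |log₂FC| > 1 versus wild type in *both* mutant
clones at one or more shared time points, additionally requiring sign
concordance between clones (the source is silent on discordant signs; they
are contradictory evidence and are excluded here). Cluster enrichment uses
uncorrected Pearson chi-square on the 2×2 in-cluster × in-set table.

The sensor estimator log-transforms both channels, sorts each population by
ΔNGFR, forms 100 equal-count bins of 1000 cells (bin size shrinks to
⌊n/100⌋ when events are scarce, with a log entry), and computes per-bin
repression as the ratio of geometric-mean dGFP, control over sensor, at
matched bin rank — so repression > 1, fixing the orientation the bracketed
published formula leaves ambiguous. The summary is the arithmetic mean over
bins (bin-mean rather than cell-pool averaging; the source does not state
which it used). The estimator is invariant to monotone rescaling of ΔNGFR
and multiplicative rescaling of dGFP.

## CRISPR arithmetic

Protospacers are exact 20-mer matches on either strand after automatic
stripping of the lowercase cloning overhangs of published oligos (the
leading g required by the U6 promoter is part of the overhang). PAMs are
NGG immediately 3′ of the protospacer on its strand; blunt cuts sit 3 bp 5′
of the PAM. Guides with multiple PAM-valid matches are a hard error (the
deletion design assumes unique sites). On the published construct the two
guides cut at positions 1260 and 1425, excising 165 nt — the "~160 nt"
reported — containing the miR-30 MRE.

## Synthetic data and the kinetics model

Generators are seeded through `numpy.random.default_rng` and are
reproducible bit-for-bit. The serum scenario plants one transcript induced
with log₂FC 6.92, peaking above 1000 RPKM at 2 h, over a flat log-normal
background; the planted miRNA's HIGH-class pool contains the planted target
plus five weak competitors (~8 RPKM each) so the planted pool share exceeds
90% at the peak, as observed for Serpine1. Multiplicative log-normal noise
(σ = 0.15) mimics biological/technical variability; it does not emulate
count noise, batch structure or correlated co-regulation, so passing the
screen here shows correct bookkeeping and ranking, not robustness to real
RNA-seq artefacts. Synthetic small-RNA references use downstream contexts
starting with G/C so planted tail classes cannot collide with templated
extensions — real loci do not offer that guarantee, which is exactly why
the classifier strips templated prefixes first. Flow events are bivariate
log-normal (ΔNGFR σ = 1.0 natural-log units, multiplicative dGFP noise
σ = 0.3) with the repression fold applied to the sensor population only.

TDMD kinetics are modelled as a saturable acceleration of miRNA decay,

  dM/dt = σ − [δ₀ + δ_T · T(t)/(T(t)+K)] · M,

integrated with explicit classical RK4 (dt ≤ 0.1 h; a negative state raises
an error). The saturable form captures both the steady-state effect at
TPM ≈ 1 (removing the TDMD term doubles the steady state when δ_T = δ₀) and
the acute effect at TPM > 10 with a single law; setting K ≫ T recovers
mass-action behaviour. The law itself is a modelling choice — no kinetic
mechanism is established for TDMD — and only its anchors are observational.
The "serum" preset uses basal half-life 14 h (δ₀ = ln2/14, σ = M₀δ₀ so the
pre-stimulus level is a steady state), K = 200 cpc, and a target pulse from
~90 to 4000 cpc peaking at 4 h. δ_T = 0.25 h⁻¹ is set so that the simulated
miRNA loses ~50% in the first 4 h (log₂FC ≈ −1.1, matching the observed
−0.88/−1.13), i.e. an *apparent* 4-h half-life over that window. Note the
distinction: because synthesis continues, matching the observed 4-h halving
requires an instantaneous half-life at peak target of ~2.4 h; an
instantaneous 4-h half-life would only produce log₂FC ≈ −0.6. The reported
"~4 h" is the apparent quantity (it is derived from the observed log₂FC by
the same arithmetic as `half_life_from_log2fc`), so the preset is anchored
to it.

## Numerical choices and limitations

- Boundary 3C-scores go to the more negative class; the CPM cutoff is
  strict (>), the RPKM cutoff inclusive (≥), following the wording of the
  respective filters.
- Supplementary-helix ties: longer helix, then smaller target bulge, then
  smaller miRNA bulge. Helices of length 0 report zero bulges.
- The exhaustive aligner maximises helix length only; it ignores pairing
  thermodynamics, so a long helix of weak A:U pairs outranks a shorter
  G:C-rich one. No folding energies or RISC structural constraints are
  modelled.
- Problem sizes in the test-suite simulations (10³–10⁵ reads, 2×10⁵ flow
  events, 10³ null replicates) were chosen as the smallest sizes at which
  the estimators' sampling error is well inside the asserted tolerances.
- Genome-scale results that depend on deposited sequencing data and
  TargetScan downloads (e.g. total eligible pair counts, transcriptome-wide
  median shifts) are out of scope; the statistics that produce them are
  implemented and validated on synthetic data with planted effects.
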