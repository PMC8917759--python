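# Methods

This note records the models, rules, numerical choices and known
limitations behind `oysteriap`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is quoted
from external runs.

## Scope and design

The package covers the desk-scale portion of an expanded-gene-family
characterization: it consumes the *outputs* of heavy external tools as
tables and files (HMM search hits, InterProScan-style domain scans,
RAxML-style trees with bootstrap labels, DESeq2-style DE tables, StringTie
count matrices) and implements everything downstream — curation logic, BIR
typing, architecture rules, expression classes and the co-expression
network — itself. Read mapping, tree inference, DE model fitting
(including shrinkage and variance-stabilizing transforms) and
secondary-structure prediction are deliberately out of scope; their
results enter as inputs.

All intervals are 0-based half-open internally; GFF3 and scan tables
(1-based inclusive) are converted only at the I/O boundary, and the
conversion is tested as an involution.

## Curation

* **Candidate filter.** A protein is retained iff its HMM E-value is
  strictly below 0.001 *and* the domain scan contains at least one
  BIR-accession hit from the CDD source. Candidates absent from the scan
  are treated as lacking CDD evidence, dropped and logged.
* **Identical collapse.** One representative per identical residue string;
  the representative is the lexicographically smallest id, which makes the
  collapse order-independent and deterministic.
* **Haplotig collapse.** Pairwise identity is global-alignment identity
  (matching columns over alignment length) under BLOSUM62 with affine gaps
  (open 10, extend 1); an edit-distance prescreen (edlib) skips pairs that
  cannot reach the identity bar, which keeps the stage O(n²) but cheap.
  Clusters are single-linkage components at identity > 0.95. Within a
  cluster, members with coverage strictly below 0.5× the cluster maximum
  are removed and mapped to the highest-coverage member; read counts of
  removed ids are added to the parent, so totals are conserved (tested).
  The identity metric and linkage rule are our quantification of a
  "similarity cluster"; both thresholds are configurable.
* **Intronless.** A gene is intronless iff *every* transcript has exactly
  one exon. The stricter all-transcript rule was chosen because a gene
  with any spliced isoform cannot be a clean retrocopy.
* **Tandem arrays.** Maximal runs of ≥ 2 IAP genes with ≤ 2 intervening
  non-IAP genes and ≤ 200 kb between consecutive members. The two
  constants quantify an otherwise informal notion of "tandem array" and
  are configurable; results at other settings are directly comparable
  because the detector is a pure function of gene order.
* **Retroposition flags.** Transposase Tc1-like accessions are fixed
  (IPR002492, IPR027805, IPR038717); the reverse-transcriptase accession
  list ships as configuration because the domain family has many
  accessions, and a description substring match ("reverse transcriptase")
  backs it up.
* **Annotation mining.** Apoptosis / regulated-cell-death gene discovery
  is case-insensitive whole-word alias matching against product names; the
  whole-word rule prevents aliases like "AIF" from firing inside unrelated
  tokens. The bundled catalog is a compact core; real studies should
  supply their full alias table.

## BIR typing

Typing is anchored: the query is globally aligned (BLOSUM62, gap open 10 /
extend 1, free end gaps) to a reference backbone whose ungapped positions
*are* the canonical numbering. Free end gaps make the anchoring invariant
to flanking sequence (tested up to 30 residues per side). Queries scoring
below 35% of the reference self-alignment score are rejected as
unanchorable rather than mistyped. The classifier itself is a pure total
function of the residues at positions 34, 57, 60, 76, 77, 80, 81, 82, 84
plus a deletion flag; precedence is NZBIR → Type Y → Type X → Type II →
Type I → Type II-like → Type I-like, i.e. single-position novel
diagnostics before broad conserved patterns, so that e.g. a sequence with
a full Type II pattern *and* T57 is called NZBIR. "Loss of three amino
acids including position 80" is implemented as ≥ 3 consecutive deleted
canonical positions whose span covers 80. Only E76 (not Q76) qualifies
for Type II-like, and only the two stated Type I-like diagnostics
(hydrophobic 80, S81) are implemented; both points are deliberate
narrow readings of rules whose broader variants are unstated.

The bundled reference alignment is a **synthetic stand-in**
(`data/bir_reference_synthetic.fasta`): it carries the canonical numbering,
the 15 conserved positions (G34, C57, C60, H77, C84 among them) and four
organism-style variant sequences, but is not derived from real
model-organism BIRs, which are not redistributable here. All typing logic
depends only on the numbering and key residues, so swapping in a real
alignment with the same position map is a drop-in replacement.

## Architectures

Scan hits become ordered tokens: BIR spans (merged across source
databases) are replaced by their typed token — or `BIR_STAR` when no CDD
source supports the span — and non-BIR accessions map through a
configurable accession→token table; unmapped accessions become
`OTHER(acc)` and are ignored during matching, because incidental domains
should not veto a named architecture. Overlapping same-token hits merge
into one token spanning their union. The rule table is ordered (most
specific patterns first) and matching is exact over the full token string,
so `BIRC5-like = [TII]` really means a single BIR and nothing else.
BIRC9, BIRC12, DIAP1-like and BIRC4-like patterns are provisional
placeholders (their compositions are only shown in figures in the source
material); they are marked as such in the config and the synthetic
generator treats them as first-class types so the matching machinery is
fully exercised regardless.

Cluster consensus: clades with bootstrap support strictly above 90
containing both oyster species, outermost qualifying clade wins (clusters
are disjoint, tested against an all-clades enumeration oracle). Consensus
is the unanimous type, else the majority type flagged non-conserved, with
ties reported as `mixed(...)`.

## Expression classes

The module operates strictly downstream of the DE model. Transcripts with
total counts < 10 are excluded entirely (the standard prefilter);
significance is padj ≤ 0.05 in ≥ 1 comparison of the experiment;
constitutive means never significant, past the prefilter, and ≥ 1 read in
every sample (the per-sample detection threshold is configurable; the
source statistic states none). Gene status: differential / constitutive /
mixed / not expressed, a partition (tested). The shared-DEG fraction is
|genes differential in ≥ 2 experiments| / |union of DEGs|; since the
denominator convention is ambiguous in the field, the stricter
all-experiments variant is always emitted alongside it.

## Co-expression network

* **bicor.** Median/MAD-based Tukey biweights, weighted cross-products
  normalized by weighted norms, clamped to [−1, 1]. Genes with zero MAD
  fall back to Pearson normalization for every pair they participate in;
  all-constant genes get correlation 0 with a warning. Equality with an
  independently coded direct formula is tested to 1e-10, and bicor tracks
  Pearson within 0.05 on clean Gaussian data.
* **Soft threshold.** For each candidate power 1..20: signed-hybrid
  adjacency, connectivity k, 10 equal-width bins of log10 k, regression of
  log10 p(k) on log10(mean k), signed R² = −sign(slope)·R². β is the
  smallest power with signed R² ≥ 0.8; if none passes and the design has
  < 30 samples, β = 9 (the small-sample signed-hybrid fallback). With
  ≥ 30 samples and no passing power the best-fitting power is returned and
  flagged — a case the fallback rule does not cover.
* **Modules.** Unsigned TOM; average-linkage clustering of 1 − TOM; a
  *static* cut at height 0.99 (configurable) with clusters below 30 genes
  unassigned (label 0). A static cut was chosen over dynamic tree cutting
  for reproducibility at desk scale: on this dissimilarity scale,
  unrelated genes merge at ≈ 0.999 and planted blocks at ≲ 0.96, so one
  fixed height separates both regimes; white noise yields all-unassigned
  (tested). Modules whose eigengenes correlate above 0.75
  (merge height 0.25) are merged iteratively.
* **Eigengenes and trait.** First right singular vector of the
  standardized module block, sign-aligned to mean expression. Trait
  association is a Pearson correlation with p from the exact t transform
  on n − 2 df (cross-checked against an independent implementation);
  significance additionally requires ≥ 1 IAP and > 1 apoptosis transcript
  in the module.
* **Direct edges.** IAP–apoptosis pairs sharing a significant module with
  adjacency ≥ 0.1. The 0.1 threshold quantifies the informal "shared
  edge" notion, ships in the config, and is stamped on every edge list;
  edge extraction is tested against a brute-force double loop and is
  invariant to gene ordering.

## Synthetic data

The generator is the package's study design, not a test hack; its defaults
define the conditions under which the acceptance checks run.

* **BIR/protein level.** Type templates are the reference backbone with
  the type's key residues installed (Type Y deletes canonical 79–81);
  mutations are placed only at non-key positions. Proteins concatenate
  domain templates with 8–15-residue random linkers; each BIR instance
  carries 6 non-key mutations and each non-BIR template instance 10%
  mutations, which keeps unrelated same-architecture proteins far below
  the 95% haplotig identity bar while leaving typing untouched.
  Haplotig copies are 3%-mutated duplicates of a parent at 0.3× its
  coverage. Decoy candidates fail either the E-value rule or the CDD
  rule. Only architecture variants containing ≥ 1 CDD-confirmed BIR are
  planted, so the curation funnel provably retains every planted IAP.
* **Genome level.** Tandem arrays are placed with ≤ 2 intervening filler
  genes and small gaps; everything else is separated by ≥ 3 fillers and
  large gaps, so the planted arrays are exactly the detectable ones.
  Intronless genes are single-exon; others have 2–4 exons.
* **Expression level.** Module genes load on a shared latent factor with
  pairwise correlation w (default 0.7); the factor correlates with a
  balanced binary challenge trait at a specified r. The module-recovery
  benchmark plants four 50-gene modules at w = 0.7 with *one*
  trait-associated module (r = 0.8): giving several modules the same
  strong trait effect correlates their latent factors (cor = r_i·r_j), at
  which point eigengene merging at 0.75 correctly fuses them — that is
  the merge rule operating as designed, not a recovery failure, so the
  benchmark plants modules that are actually distinct. Expression is
  generated directly on a transformed (log-like) scale; DE count matrices
  use overdispersed negative-binomial draws, since the DE model itself is
  out of scope.
* **Determinism.** All randomness flows through one integer-seeded
  generator; outputs are byte-identical across runs (tested), and the
  truth sidecar fully determines the expected output of every stage.

What passing on synthetic data does *not* show: robustness to real scan
noise (partial/fragmented domain hits, conflicting source databases),
non-Gaussian expression, unbalanced designs, or annotation errors. The
generator plants clean domain spans and well-separated modules; the
recovery rates are correctness checks of the implemented rules, not
field-performance estimates.

## Problem sizes

Acceptance-scale runs use 700 synthetic BIRs (100 per type), 200 proteins
across all architecture types, a 500-gene annotation with 50 haplotigs and
4 tandem arrays, and 10 replicate 240-gene × 20-sample expression
matrices; the complete suite plus acceptance script runs in well under a
minute on one CPU. These sizes were chosen to exercise every rule at
realistic family scale while keeping the analysis interactive.

## Known limitations

* The anchoring aligner reports one optimal alignment; for queries with
  repeats near a deletion the gap placement could be ambiguous, and key
  residues adjacent to such gaps should be read with care.
* Provisional architecture patterns (BIRC9, BIRC12, DIAP1-like,
  BIRC4-like) classify correctly against themselves but their
  compositions await confirmation against the figure-level definitions.
* Static-cut module detection trades the adaptivity of dynamic tree
  cutting for reproducibility; strongly nested module structure would
  need the cut height revisited.
* Reported intronless counts for the real genomes differ between sections
  of the source literature; this package reports its own counts on its own
  inputs and does not arbitrate.
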