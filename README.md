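# oysteriap

Characterization of the expanded Inhibitor-of-Apoptosis (IAP / BIRC) gene
family in oysters: curation of IAP gene sets from protein domain-scan
evidence, rule-based typing of BIR domains, domain-architecture
classification, expression-status categories across immune-challenge
experiments, and weighted co-expression analysis linking IAP transcripts to
apoptosis-related genes.

## The problem

Bivalve genomes carry dozens of IAP genes (69 in *Crassostrea virginica*,
40 in *C. gigas*) instead of the handful found in mammals or flies, produced
by tandem duplication and retroposition. Characterizing such a family
requires a chain of decisions that are individually simple but easy to get
subtly wrong: which HMM candidates count as IAPs, which near-identical
sequences are assembly artifacts (haplotigs) rather than genes, how a
~70-residue BIR (Baculovirus IAP Repeat) domain is typed from a handful of
diagnostic residues, how ordered domain content maps onto architecture
classes, and how co-expression with apoptosis genes is quantified on small
designs. This package implements that chain as tested, reusable code, with
a synthetic-data generator that emits every input format with known ground
truth, so the entire analysis runs end to end with no downloads and every
stage is checked against planted truth.

## The rules at the core

**Curation funnel** (in order): keep HMM candidates with E-value < 0.001
that carry a BIR hit from the Conserved Domain Database; collapse identical
protein sequences; inside single-linkage clusters at > 95% pairwise
identity, remove members with read coverage below half the cluster maximum
(suspected haplotigs) and fold their read counts into the retained parent.
Genes whose transcripts are all single-exon are flagged intronless
(retroposition candidates); runs of ≥ 2 IAP genes with ≤ 2 intervening
genes and ≤ 200 kb gaps are tandem arrays; Transposase Tc1-like
(IPR002492/IPR027805/IPR038717) or reverse-transcriptase domains in
translated ORFs flag transposition machinery.

**BIR typing.** Each BIR sequence is anchored to a canonical reference
backbone by global alignment (BLOSUM62, affine gaps open 10 / extend 1,
free end gaps) and typed from the residues at canonical positions
34, 57, 60, 76, 77, 80, 81, 82, 84, first match wins:

| precedence | type | rule |
|---|---|---|
| 1 | NZBIR | T at the first zinc-coordinating cysteine (57) |
| 2 | Type Y | 3-residue deletion spanning position 80 |
| 3 | Type X | G80 and R82 |
| 4 | Type II | E76 or Q76, H77, W80 or H80, C84 |
| 5 | Type I | H77, V80 or L80, C84 |
| 6 | Type II-like | E76 with H77 (short of full Type II) |
| 7 | Type I-like | hydrophobic I/V/L at 80 and/or S81 |

**Architectures.** Ordered N→C domain tokens (typed BIRs plus RING, DD,
UBA, UBC, BIRC6 domain, WD40) are matched against an ordered rule table of
14 types, e.g. BIRC2/3-like = TI-TII-DD-RING (± UBA, or NZBIR-TII-UBA-DD-RING),
BIRC10 = TII-DD, BIRC11 = TII-DD-RING or BIR\*-DD-RING, BIRC7-like =
TII-RING, BIRC5-like = a single BIR. Unmatched token strings are NOVEL.
Consensus architectures are assigned per phylogenetic cluster with > 90%
bootstrap support containing both oyster species.

**Expression classes.** Downstream of a differential-expression model:
transcripts with < 10 total reads are excluded; a transcript is significant
if BH-adjusted p ≤ 0.05 in any comparison, constitutive if never
significant but detected in every sample. Genes aggregate to differential /
constitutive / mixed / not expressed.

**Co-expression.** Biweight midcorrelation
(u = (x − med)/(9·MAD), w = (1 − u²)²·1[|u| < 1]), signed-hybrid adjacency
a = cor^β for cor > 0 else 0, soft power β chosen as the smallest candidate
with scale-free fit R² ≥ 0.8 and falling back to β = 9 for designs with
< 30 samples, topological overlap, average-linkage clustering with a static
cut, module eigengenes (first PC), eigengene–trait t-tests (significant at
p ≤ 0.05 with ≥ 1 IAP and > 1 apoptosis transcript in the module), and
direct IAP–apoptosis edges = gene pairs sharing a significant module with
adjacency ≥ 0.1.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (ground truth known by construction):

```bash
python analysis/01_simulate.py
python analysis/02_characterize_family.py
python analysis/03_bir_domain_census.py
python analysis/04_expression_status.py
python analysis/05_coexpression_network.py
```

`02_characterize_family.py` prints:

```
funnel: candidates=44 -> cdd_confirmed=40 -> after_identical_collapse=40 -> after_haplotig_collapse=36
haplotigs: 4 removed, exact match to truth: True
intronless: 4 flagged, exact: True
tandem arrays: 2 arrays of sizes [3, 4]
architectures: 36/36 match their planted type
BIR domains typed: 62 across 36 curated proteins
```

reading: 44 HMM candidates enter the funnel, 4 decoys fall to the E-value /
CDD rules, 4 planted haplotig copies are removed (their counts re-assigned
to parents), and every curated protein's architecture matches what the
generator planted. `05_coexpression_network.py` prints:

```
soft threshold beta = 9 (fallback rule: < 30 samples)
modules detected: 4; ARI vs planted labels: 0.971
direct IAP-apoptosis edges in significant modules: 150
```

i.e. with 20 samples the scale-free fit fails and the small-sample fallback
power is used; the four planted modules are recovered (adjusted Rand index
0.97 against the planted labels), one module is significantly associated
with the challenge trait (r = 0.88, p < 1e-6), and the IAP transcripts in
it are connected to their co-expressed apoptosis partners.

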