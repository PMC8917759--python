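"""Configuration dataclasses and accession maps shared across the pipeline.

Every numeric threshold used by a stage lives here with its default, so a run
manifest can serialize the complete decision surface.  Domain accessions follow
InterPro/CDD/Gene3D identifiers; the token map collapses them into the small
vocabulary used for architecture matching.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class CurationConfig:
    """Thresholds for the gene-family curation funnel.

    hmm_evalue_max: retain HMM candidates strictly below this E-value.
    haplotig_identity_min: single-linkage clustering joins pairs with global
        pairwise identity strictly above this fraction.
    haplotig_coverage_ratio: a clustered protein is a suspected haplotig iff
        its read coverage is strictly below this fraction of the cluster max.
    tandem_max_intervening: max non-IAP genes between consecutive array members.
    tandem_max_gap_bp: max genomic gap (bp) between consecutive array members.
    """

    hmm_evalue_max: float = 0.001
    haplotig_identity_min: float = 0.95
    haplotig_coverage_ratio: float = 0.5
    tandem_max_intervening: int = 2
    tandem_max_gap_bp: int = 200_000

    def __post_init__(self) -> None:
        if not 0 < self.hmm_evalue_max:
            raise ValueError("hmm_evalue_max must be positive")
        if not 0 < self.haplotig_identity_min < 1:
            raise ValueError("haplotig_identity_min must be in (0,1)")
        if not 0 < self.haplotig_coverage_ratio < 1:
            raise ValueError("haplotig_coverage_ratio must be in (0,1)")
        if self.tandem_max_intervening < 0 or self.tandem_max_gap_bp <= 0:
            raise ValueError("tandem thresholds out of range")


@dataclass
class ExpressionConfig:
    """Thresholds for expression-status classification."""

    padj_max: float = 0.05
    min_total_count: int = 10
    detection_min_count: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.padj_max <= 1):
            raise ValueError("padj_max must be in (0,1]")
        if self.min_total_count <= 0 or self.detection_min_count <= 0:
            raise ValueError("count thresholds must be positive")


@dataclass
class NetworkConfig:
    """Parameters of the signed-hybrid weighted co-expression network."""

    network_type: str = "signed_hybrid"
    candidate_powers: tuple[int, ...] = tuple(range(1, 21))
    scale_free_r2_min: float = 0.8
    fallback_power: int = 9
    min_module_size: int = 30
    cut_height: float = 0.99
    merge_height: float = 0.25
    module_trait_p_max: float = 0.05
    edge_adjacency_min: float = 0.1

    def __post_init__(self) -> None:
        if any(p < 1 for p in self.candidate_powers):
            raise ValueError("candidate powers must be >= 1")
        for name in ("scale_free_r2_min", "cut_height", "merge_height",
                     "module_trait_p_max"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0,1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")


# ---------------------------------------------------------------------------
# Domain accession vocabulary (InterPro / CDD / Pfam / Gene3D / SMART).

#: BIR-repeat accessions; spans with these accessions are typed by bir_typing.
BIR_ACCESSIONS = frozenset({"cd00022", "IPR001370", "PF00653", "SM00238"})

#: CDD source label used for the "BIR confirmed by CDD" curation rule.
CDD_SOURCE = "CDD"

#: Transposase Tc1-like accessions flagged as DNA-transposition machinery.
TC1_ACCESSIONS = frozenset({"IPR002492", "IPR027805", "IPR038717"})

#: Reverse-transcriptase accessions (config-supplied; LTR and non-LTR RT).
RT_ACCESSIONS = frozenset({"IPR000477", "IPR043502", "IPR013103"})

#: Map from non-BIR accession to architecture token.
TOKEN_MAP: dict[str, str] = {
    # RING finger
    "cd16713": "RING",
    "IPR013083": "RING",
    "IPR001841": "RING",
    # Death domain
    "G3DSA:1.10.533.10": "DD",
    # Ubiquitin-associated
    "IPR015940": "UBA",
    "cd14321": "UBA",
    # Ubiquitin-conjugating
    "IPR016135": "UBC",
    "IPR000608": "UBC",
    # BIRC6 characteristic domain
    "IPR022103": "BIRC6_DOMAIN",
    # WD40 repeats
    "IPR019775": "WD40",
    "IPR036322": "WD40",
}

#: Tokens that denote a BIR domain instance (typed or scan-only).
BIR_TOKEN_CLASS = frozenset(
    {"TI", "TII", "TI_like", "TII_like", "TX", "TY", "NZBIR", "BIR_STAR"}
)

#: Default apoptosis / regulated-cell-death target catalog (name -> aliases).
#: A compact core of the intrinsic/extrinsic pathway members the annotations
#: are mined for; extend via configuration for full-genome runs.
DEFAULT_RCD_CATALOG: dict[str, tuple[str, ...]] = {
    "caspase 2": ("caspase 2", "casp2"),
    "caspase 3": ("caspase 3", "casp3"),
    "caspase 7": ("caspase 7", "casp7"),
    "caspase 8": ("caspase 8", "casp8"),
    "caspase 9": ("caspase 9", "casp9"),
    "cytochrome c": ("cytochrome c", "cycs"),
    "apoptosis inducing factor": ("apoptosis inducing factor", "AIF", "AIFM1"),
    "TNF receptor-associated factor 2": ("TRAF2", "TNF receptor-associated factor 2"),
    "TNF receptor-associated factor 3": ("TRAF3", "TNF receptor-associated factor 3"),
    "TNF receptor-associated factor 6": ("TRAF6", "TNF receptor-associated factor 6"),
    "FAS-associated death domain protein": ("FADD",),
    "receptor-interacting protein kinase 1": ("RIPK1",),
    "poly [ADP-ribose] polymerase 1": ("PARP1", "poly [ADP-ribose] polymerase 1"),
    "macrophage migration inhibitory factor": ("MIF",),
    "bcl-2-like protein": ("bcl-2", "bcl2", "bcl-xl"),
    "p53": ("p53", "cellular tumor antigen p53"),
}


# ---------------------------------------------------------------------------
# Architecture rule table.  Pattern atoms:
#   TOKEN          exact token
#   A|B            one of the listed tokens
#   BIR_ANY        any BIR-class token
#   atom+          one or more repeats of the atom
#   atom?          optional atom
# Rules are matched in order; within a rule, any listed pattern may match.
# Patterns marked provisional are figure-derived placeholders (the source text
# does not spell out their token composition).

DEFAULT_ARCHITECTURE_RULES: tuple[tuple[str, tuple[tuple[str, ...], ...]], ...] = (
    ("BIRC6-like", (
        ("BIR_ANY+", "BIRC6_DOMAIN", "UBC"),
        ("BIR_ANY+", "BIRC6_DOMAIN", "WD40", "UBC"),
        ("BIR_ANY+", "BIRC6_DOMAIN", "UBC", "WD40"),
    )),
    ("BIRC2/3-like", (
        ("TI", "TII", "DD", "RING"),
        ("TI", "TII", "DD", "UBA", "RING"),
        ("NZBIR", "TII", "UBA", "DD", "RING"),
    )),
    ("BIRC4-like", (          # provisional (figure-derived placeholder)
        ("TI", "TI", "TII", "UBA", "RING"),
        ("TI", "TI", "TII", "RING"),
    )),
    ("BIRC9", (               # provisional (figure-derived placeholder)
        ("TX", "TII", "RING"),
    )),
    ("BIRC12", (              # provisional (figure-derived placeholder)
        ("TII", "BIR_STAR", "RING"),
    )),
    ("BIRC11", (
        ("TII", "DD", "RING"),
        ("BIR_STAR", "DD", "RING"),
    )),
    ("DIAP1-like", (          # provisional (figure-derived placeholder)
        ("TI|TII", "TII", "RING"),
    )),
    ("BIRC10", (
        ("TII", "DD"),
    )),
    ("BIRC7-like", (
        ("TII", "RING"),
    )),
    ("BIRC5-like", (
        ("TII",),
        ("TI",),
    )),
)


def config_as_dict(cfg) -> dict:
    """Serialize any of the config dataclasses for run manifests."""
    return dataclasses.asdict(cfg)


PACKAGE_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class RunConfig:
    """Paths and parameters for an end-to-end pipeline run."""

    input_dir: Path
    output_dir: Path
    seed: int = 0
    curation: CurationConfig = field(default_factory=CurationConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
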