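"""N-terminal feature classification of putative type III effectors.

Proteins secreted through the T3SS carry weak but characteristic signals in
their N-terminus: an abundance of serine and of polar residues, few acidic
residues among the first 12 positions, and an aliphatic residue at position
3 or 4 (the initiator Met is position 1).  Genes that carry an hrp box in
their promoter AND satisfy every enabled N-terminal criterion are called
putative effectors; this mirrors the two-step screen that shrinks the
box-positive gene list to a short effector candidate list.

Residue sets and thresholds are configurable because the literature never
pins them down; defaults are recorded in every output.  Two published
phrasings of the acidic rule contradict each other (a cap of one acidic
residue in the first 12 positions vs an "abundance" of them); the rule
direction is therefore an explicit config enum, defaulting to the cap, and
the choice in force is logged rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import pandas as pd

from .genome import AnnotatedGenome

__all__ = [
    "NTermFeatures",
    "EffectorThresholds",
    "EffectorCandidate",
    "FeatureError",
    "compute_features",
    "classify",
    "run_effector_screen",
    "candidates_to_frame",
    "DEFAULT_POLAR_SET",
    "DEFAULT_ALIPHATIC_SET",
]

logger = logging.getLogger(__name__)

DEFAULT_POLAR_SET = frozenset("STNQCYGH")
DEFAULT_ALIPHATIC_SET = frozenset("ILVAP")
ACIDIC = frozenset("DE")


class FeatureError(ValueError):
    """Protein too short (or otherwise unfit) for N-terminal feature analysis."""


@dataclass(frozen=True)
class NTermFeatures:
    gene_id: str
    window_len: int
    ser_frac: float
    polar_frac: float
    n_acidic_first12: int
    aliphatic_pos34: bool


@dataclass(frozen=True)
class EffectorThresholds:
    """Tunable criteria of the N-terminal screen (all surfaced in reports)."""

    window: int = 50
    min_ser_frac: float = 0.10
    min_polar_frac: float = 0.40
    acidic_rule: Literal["at_most_one", "none", "at_least_one"] = "at_most_one"
    polar_set: frozenset[str] = DEFAULT_POLAR_SET
    aliphatic_set: frozenset[str] = DEFAULT_ALIPHATIC_SET

    def __post_init__(self) -> None:
        if self.window < 12:
            raise ValueError("window must be >= 12")
        if not (0 <= self.min_ser_frac <= 1 and 0 <= self.min_polar_frac <= 1):
            raise ValueError("fraction thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class EffectorCandidate:
    gene_id: str
    features: NTermFeatures | None
    criterion_flags: dict[str, bool] = field(default_factory=dict)
    is_putative_effector: bool = False
    unevaluable_reason: str | None = None


def compute_features(
    protein: str,
    gene_id: str = "",
    window: int = 50,
    polar_set: frozenset[str] = DEFAULT_POLAR_SET,
    aliphatic_set: frozenset[str] = DEFAULT_ALIPHATIC_SET,
) -> NTermFeatures:
    """Feature vector over the first min(window, length) residues.

    The initiator Met counts as position 1.  Raises FeatureError for proteins
    shorter than 4 aa (position 3/4 undefined).
    """
    if window < 12:
        raise ValueError("window must be >= 12")
    protein = protein.upper().rstrip("*")
    if len(protein) < 4:
        raise FeatureError(
            f"protein {gene_id or '<anonymous>'!r} has {len(protein)} aa; "
            "need >= 4 for the position-3/4 criterion"
        )
    win = protein[: min(window, len(protein))]
    n = len(win)
    first12 = protein[:12]
    return NTermFeatures(
        gene_id=gene_id,
        window_len=n,
        ser_frac=win.count("S") / n,
        polar_frac=sum(aa in polar_set for aa in win) / n,
        n_acidic_first12=sum(aa in ACIDIC for aa in first12),
        aliphatic_pos34=protein[2] in aliphatic_set or protein[3] in aliphatic_set,
    )


def _acidic_ok(n: int, rule: str) -> bool:
    if rule == "at_most_one":
        return n <= 1
    if rule == "none":
        return n == 0
    if rule == "at_least_one":
        return n >= 1
    raise ValueError(f"unknown acidic rule {rule!r}")


def classify(
    features: NTermFeatures,
    thresholds: EffectorThresholds = EffectorThresholds(),
    hrp_box_positive: bool = True,
) -> EffectorCandidate:
    """Evaluate each criterion independently; the call is their conjunction."""
    flags = {
        "ser_abundance": features.ser_frac >= thresholds.min_ser_frac,
        "polar_abundance": features.polar_frac >= thresholds.min_polar_frac,
        "acidic_first12": _acidic_ok(features.n_acidic_first12, thresholds.acidic_rule),
        "aliphatic_pos34": features.aliphatic_pos34,
        "hrp_box": hrp_box_positive,
    }
    return EffectorCandidate(
        gene_id=features.gene_id,
        features=features,
        criterion_flags=flags,
        is_putative_effector=all(flags.values()),
    )


def run_effector_screen(
    genome: AnnotatedGenome,
    motif_table: pd.DataFrame,
    thresholds: EffectorThresholds = EffectorThresholds(),
) -> tuple[list[EffectorCandidate], pd.DataFrame]:
    """Classify hrp-box-positive genes; keep the feature table for all genes.

    Genes in the motif table whose protein is missing or shorter than 4 aa
    are recorded as unevaluable rather than dropped.  Returns (candidates
    for box-positive genes, feature table for every translatable gene).
    """
    logger.info(
        "effector screen: window=%d aa, ser>=%.2f, polar>=%.2f, acidic rule=%s "
        "(the published phrasings of the acidic rule disagree; using the configured one)",
        thresholds.window, thresholds.min_ser_frac, thresholds.min_polar_frac,
        thresholds.acidic_rule,
    )
    positive_ids = set(motif_table["gene_id"]) if len(motif_table) else set()

    all_features: list[NTermFeatures] = []
    by_gene: dict[str, NTermFeatures] = {}
    for f in genome.cds_features:
        protein = genome.protein_of(f.gene_id)
        if not protein or len(protein.rstrip("*")) < 4:
            continue
        feats = compute_features(
            protein, f.gene_id, thresholds.window,
            thresholds.polar_set, thresholds.aliphatic_set,
        )
        all_features.append(feats)
        by_gene[f.gene_id] = feats

    candidates: list[EffectorCandidate] = []
    for gene_id in motif_table["gene_id"] if len(motif_table) else []:
        if gene_id in by_gene:
            candidates.append(classify(by_gene[gene_id], thresholds, hrp_box_positive=True))
        else:
            try:
                protein = genome.protein_of(gene_id)
            except KeyError:
                protein = None
            reason = (
                "no translation available" if not protein
                else f"protein too short ({len(protein.rstrip('*'))} aa)"
            )
            candidates.append(
                EffectorCandidate(gene_id=gene_id, features=None, unevaluable_reason=reason)
            )

    feature_table = pd.DataFrame(
        [
            {
                "gene_id": x.gene_id,
                "window_len": x.window_len,
                "ser_frac": x.ser_frac,
                "polar_frac": x.polar_frac,
                "n_acidic_first12": x.n_acidic_first12,
                "aliphatic_pos34": x.aliphatic_pos34,
                "hrp_box_positive": x.gene_id in positive_ids,
            }
            for x in all_features
        ]
    )
    return candidates, feature_table


def candidates_to_frame(candidates: list[EffectorCandidate]) -> pd.DataFrame:
    rows = []
    for c in candidates:
        row = {
            "gene_id": c.gene_id,
            "is_putative_effector": c.is_putative_effector,
            "unevaluable_reason": c.unevaluable_reason or "",
        }
        if c.features is not None:
            row.update(
                ser_frac=c.features.ser_frac,
                polar_frac=c.features.polar_frac,
                n_acidic_first12=c.features.n_acidic_first12,
                aliphatic_pos34=c.features.aliphatic_pos34,
            )
        for name, ok in c.criterion_flags.items():
            row[f"pass_{name}"] = ok
        rows.append(row)
    return pd.DataFrame(rows)
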