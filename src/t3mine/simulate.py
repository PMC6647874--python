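"""Synthetic annotated genomes and alignments with planted ground truth.

Every screening stage of the pipeline is testable without downloads: the
generator emits a multi-kb genome with CDS on both strands, hrp boxes
planted at controlled spacer lengths and motif-gene distances, near-miss
decoy boxes (wrong spacer, wrong distance, mutated core), ORFs whose
N-termini satisfy the effector criteria with margin or violate exactly one
named criterion, and a contiguous cluster of diverged homologs of the
packaged T3SS component panel.  Everything planted is recorded in a
manifest, and the intergenic background is scrubbed of accidental motif
cores (both orientations), so the manifest is the complete truth: pipeline
positives can be scored for precision and recall exactly.

The background is i.i.d. nucleotides at a configurable GC content (no codon
model — adequate for scanner and filter testing, not for real-genome
mimicry); planted proteins are reverse-translated with uniformly chosen
synonymous codons (bacterial table).  All output is a deterministic
function of (config, seed).
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, dataclass, field
from io import StringIO
from pathlib import Path
from typing import Literal

import numpy as np
from Bio.Data import CodonTable
from skbio import TreeNode

from . import effectors as eff
from .clusters import ReferencePanel, default_panel
from .genome import (
    AnnotatedGenome,
    CDSFeature,
    reverse_complement,
    write_fasta,
    write_genbank,
    write_gff3,
)
from .motifs import DEFAULT_MAX_DIST, DEFAULT_MIN_DIST, HRP_BOX_SCREEN, screen_genome
from .phylo import MSA, DistanceMatrix, PhyloTree

__all__ = [
    "GenomeSimConfig",
    "PlantManifest",
    "PlantedBox",
    "PlantedEffector",
    "PlantedComponent",
    "ConfigError",
    "GeneratorError",
    "generate_genome",
    "save_genome",
    "generate_alignment",
    "random_additive_tree",
    "tree_distances",
]


class ConfigError(ValueError):
    """The generator configuration is infeasible or inconsistent."""


class GeneratorError(RuntimeError):
    """Planted truth failed post-generation verification."""


# ------------------------------------------------------------------ config

@dataclass(frozen=True)
class GenomeSimConfig:
    genome_length: int = 2_000_000
    gc_content: float = 0.60  # Pseudomonas-like
    n_conformant_boxes: int = 5
    n_decoy_wrong_spacer: int = 3
    n_decoy_wrong_distance: int = 4
    n_decoy_mutated_core: int = 3
    n_effectors: int = 10
    n_effector_decoys: int = 10
    n_background_genes: int = 20
    cluster_components: tuple[str, ...] | None = None  # None -> whole panel
    cluster_mutation_rate: float = 0.20
    genome_id: str = "synthetic_genome"
    contig_id: str = "syncontig_1"

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_content < 1.0):
            raise ConfigError("gc_content must be in (0, 1)")
        if not (0.0 <= self.cluster_mutation_rate < 1.0):
            raise ConfigError("cluster_mutation_rate must be in [0, 1)")
        for name in (
            "n_conformant_boxes", "n_decoy_wrong_spacer", "n_decoy_wrong_distance",
            "n_decoy_mutated_core", "n_effectors", "n_effector_decoys",
            "n_background_genes",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PlantedBox:
    gene_id: str
    motif: str
    spacer_len: int
    gene_distance: int
    conformant: bool
    kind: str  # conformant | wrong_spacer | wrong_distance | mutated_core


@dataclass(frozen=True)
class PlantedEffector:
    gene_id: str
    violated_criterion: str | None  # None = true effector


@dataclass(frozen=True)
class PlantedComponent:
    gene_id: str
    component_name: str
    mutation_rate: float


@dataclass
class PlantManifest:
    seed: int
    planted_hrp_boxes: list[PlantedBox] = field(default_factory=list)
    planted_effectors: list[PlantedEffector] = field(default_factory=list)
    planted_cluster: list[PlantedComponent] = field(default_factory=list)
    background: dict = field(default_factory=dict)

    @property
    def conformant_box_genes(self) -> set[str]:
        return {b.gene_id for b in self.planted_hrp_boxes if b.conformant}

    @property
    def true_effector_genes(self) -> set[str]:
        return {e.gene_id for e in self.planted_effectors if e.violated_criterion is None}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "planted_hrp_boxes": [asdict(b) for b in self.planted_hrp_boxes],
                    "planted_effectors": [asdict(e) for e in self.planted_effectors],
                    "planted_cluster": [asdict(c) for c in self.planted_cluster],
                    "background": self.background,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            seed=raw["seed"],
            planted_hrp_boxes=[PlantedBox(**b) for b in raw["planted_hrp_boxes"]],
            planted_effectors=[PlantedEffector(**e) for e in raw["planted_effectors"]],
            planted_cluster=[PlantedComponent(**c) for c in raw["planted_cluster"]],
            background=raw["background"],
        )


# ------------------------------------------------- sequence building blocks

_T11 = CodonTable.unambiguous_dna_by_id[11]
CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_T11.forward_table.items()):
    CODONS.setdefault(_aa, []).append(_codon)

_NT = "ACGT"
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# motif cores in both orientations; background is scrubbed of these so the
# manifest stays the complete truth
_FORWARD_CORE = re.compile(b"GGAAC[ACGT]{15,16}CCAC[ACGT]{2}AG")
_REVERSE_CORE = re.compile(b"CT[ACGT]{2}GTGG[ACGT]{15,16}GTTCC")

# geometry of the synthetic layout (bp)
_MAIN_MARGIN = 700       # intergenic room upstream of each main-block gene
_MIN_MAIN_PITCH = 2600
_CLUSTER_PITCH = 1250
_CLUSTER_CDS_OFFSET = 340  # leaves a full default scan window intergenic


def _rand_nt(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)
    return arr.tobytes().decode()


def _erase_motif_cores(buf: bytearray) -> int:
    """Destroy every accidental hrp-box core (both strands); returns #patches."""
    patched = 0
    changed = True
    while changed:
        changed = False
        for m in list(_FORWARD_CORE.finditer(bytes(buf))):
            buf[m.start() + 2] = ord("C")  # GGAAC -> GGCAC
            patched += 1
            changed = True
        for m in list(_REVERSE_CORE.finditer(bytes(buf))):
            buf[m.end() - 4] = ord("G")  # GTTCC -> GGTCC
            patched += 1
            changed = True
    return patched


def _motif_instance(rng: np.random.Generator, spacer_len: int, mutate_core: bool = False) -> str:
    def x() -> str:
        return _NT[rng.integers(4)]

    core = "GGTAC" if mutate_core else "GGAAC"
    spacer = "".join(_NT[rng.integers(4)] for _ in range(spacer_len))
    return x() + core + x() + spacer + "CCAC" + x() + x() + "AG"


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    codons = [CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein]
    return "".join(codons) + "TAA"


_TAIL_NONPOLAR = "KRMFWLIVA"  # non-acidic, non-polar-set filler


def _effector_nterm(rng: np.random.Generator, violate: str | None = None) -> str:
    """A 50-aa N-terminal window engineered around the effector criteria.

    violate=None passes every default criterion with >= 0.05 margin in each
    fraction; otherwise exactly the named criterion fails (with margin).
    """
    pos3, pos4 = ("K", "R") if violate == "aliphatic_pos34" else ("L", "T")
    if violate == "acidic_first12":
        first12 = ["M", "K", pos3, pos4, "D", "E", "D", "N", "Q", "T", "N", "Q"]
    else:
        first12 = ["M", "K", pos3, pos4, "D", "N", "Q", "T", "N", "Q", "T", "N"]
    polar12 = sum(aa in eff.DEFAULT_POLAR_SET for aa in first12)

    if violate == "ser_abundance":
        n_ser, polar_target = 2, 23
    elif violate == "polar_abundance":
        n_ser, polar_target = 6, 15
    else:
        n_ser, polar_target = 8, 23
    n_polar_other = polar_target - polar12 - n_ser
    if n_polar_other < 0:
        raise GeneratorError("infeasible N-terminal composition")
    tail = (
        ["S"] * n_ser
        + [("T", "N", "Q", "Y", "H", "G", "C")[i % 7] for i in range(n_polar_other)]
    )
    tail += [
        _TAIL_NONPOLAR[rng.integers(len(_TAIL_NONPOLAR))]
        for _ in range(38 - len(tail))
    ]
    tail = list(tail)
    rng.shuffle(tail)
    window = "".join(first12 + tail)

    feats = eff.compute_features(window, window=50)
    cand = eff.classify(feats, eff.EffectorThresholds(), hrp_box_positive=True)
    flags = {k: v for k, v in cand.criterion_flags.items() if k != "hrp_box"}
    expected_fail = {violate} if violate else set()
    actual_fail = {k for k, ok in flags.items() if not ok}
    if actual_fail != expected_fail:
        raise GeneratorError(
            f"engineered N-terminus failed {actual_fail}, expected {expected_fail}"
        )
    return window


def _background_protein(rng: np.random.Generator, length: int) -> str:
    body = "".join(_AA20[rng.integers(20)] for _ in range(length - 1))
    # non-effector genes must never satisfy the full criterion conjunction:
    # force positions 3 and 4 non-aliphatic
    p = list("M" + body)
    p[2], p[3] = "K", "R"
    return "".join(p)


# ----------------------------------------------------------- genome builder

def generate_genome(
    config: GenomeSimConfig = GenomeSimConfig(),
    seed: int = 0,
    panel: ReferencePanel | None = None,
) -> tuple[AnnotatedGenome, PlantManifest]:
    """Build a synthetic annotated genome plus its plant manifest.

    Reproducible bit-for-bit from (config, seed).  Raises ConfigError when
    the requested gene counts cannot fit the genome length and
    GeneratorError if post-generation verification ever disagrees with the
    manifest (which the background scrubbing is designed to preclude).
    """
    rng = np.random.default_rng(seed)
    if panel is None:
        panel = default_panel()
    comp_names = config.cluster_components or tuple(e.name for e in panel)
    for name in comp_names:
        panel.get(name)  # KeyError for unknown components

    # ---- layout feasibility
    plan: list[dict] = []
    for i in range(config.n_conformant_boxes):
        plan.append({"kind": "conformant", "gene_id": f"boxgene_{i + 1:03d}"})
    for i in range(config.n_decoy_wrong_spacer):
        plan.append({"kind": "wrong_spacer", "gene_id": f"decoy_spacer_{i + 1:03d}"})
    for i in range(config.n_decoy_wrong_distance):
        plan.append({"kind": "wrong_distance", "gene_id": f"decoy_dist_{i + 1:03d}"})
    for i in range(config.n_decoy_mutated_core):
        plan.append({"kind": "mutated_core", "gene_id": f"decoy_core_{i + 1:03d}"})
    for i in range(config.n_effectors):
        plan.append({"kind": "effector", "gene_id": f"effector_{i + 1:03d}"})
    violations = ("ser_abundance", "polar_abundance", "acidic_first12", "aliphatic_pos34")
    for i in range(config.n_effector_decoys):
        plan.append(
            {
                "kind": "effector_decoy",
                "gene_id": f"effdecoy_{i + 1:03d}",
                "violated": violations[i % len(violations)],
            }
        )
    for i in range(config.n_background_genes):
        plan.append({"kind": "background", "gene_id": f"bg_{i + 1:03d}"})

    n_main = len(plan)
    cluster_len = _CLUSTER_PITCH * len(comp_names)
    usable = config.genome_length - cluster_len - 2000
    if n_main:
        pitch = usable // n_main
        if pitch < _MIN_MAIN_PITCH:
            raise ConfigError(
                f"genome_length {config.genome_length} too small for {n_main} genes "
                f"plus a {cluster_len}-bp cluster (pitch {pitch} < {_MIN_MAIN_PITCH})"
            )
    else:
        pitch = 0
    cluster_start = 1000 + n_main * pitch
    if cluster_start + cluster_len + 500 > config.genome_length:
        raise ConfigError("cluster region does not fit the genome length")

    # ---- background, scrubbed of accidental motif cores
    buf = bytearray(_rand_nt(rng, config.genome_length, config.gc_content).encode())
    n_patched = _erase_motif_cores(buf)

    manifest = PlantManifest(seed=seed)
    features: list[CDSFeature] = []

    def write_at(start1: int, seq: str) -> None:
        buf[start1 - 1 : start1 - 1 + len(seq)] = seq.encode()

    def plant_box(cds: CDSFeature, motif: str, gene_distance: int) -> None:
        L = len(motif)
        if cds.strand == "+":
            write_at(cds.start - gene_distance - L, motif)
        else:
            write_at(cds.end + gene_distance + 1, reverse_complement(motif))

    # ---- main block
    for i, item in enumerate(plan):
        slot = 1000 + i * pitch
        strand = "+" if rng.integers(2) == 0 else "-"
        kind = item["kind"]
        if kind in ("effector", "effector_decoy"):
            violated = item.get("violated")
            window = _effector_nterm(rng, violated)
            tail_len = int(rng.integers(50, 200))
            protein = window + "".join(_AA20[rng.integers(20)] for _ in range(tail_len))
        else:
            protein = _background_protein(rng, int(rng.integers(100, 301)))
        cds_nt = _reverse_translate(rng, protein)

        if strand == "+":
            start = slot + _MAIN_MARGIN
            end = start + len(cds_nt) - 1
            write_at(start, cds_nt)
        else:
            start = slot + 100
            end = start + len(cds_nt) - 1
            write_at(start, reverse_complement(cds_nt))
        cds = CDSFeature(item["gene_id"], config.contig_id, start, end, strand, protein)
        features.append(cds)

        if kind == "background":
            continue
        # every non-background main gene carries a planted box of some kind
        if kind == "wrong_spacer":
            spacer = int(rng.choice([13, 14, 17, 18]))
            gd = int(rng.integers(DEFAULT_MIN_DIST, DEFAULT_MAX_DIST + 1))
            motif = _motif_instance(rng, spacer)
            conformant = False
        elif kind == "wrong_distance":
            spacer = int(rng.choice([15, 16]))
            gd = int(rng.integers(0, DEFAULT_MIN_DIST)) if rng.integers(2) == 0 \
                else int(rng.integers(DEFAULT_MAX_DIST + 1, DEFAULT_MAX_DIST + 70))
            motif = _motif_instance(rng, spacer)
            conformant = False
        elif kind == "mutated_core":
            spacer = int(rng.choice([15, 16]))
            gd = int(rng.integers(DEFAULT_MIN_DIST, DEFAULT_MAX_DIST + 1))
            motif = _motif_instance(rng, spacer, mutate_core=True)
            conformant = False
        else:  # conformant box, effector, effector_decoy
            spacer = int(rng.choice([15, 16]))
            gd = int(rng.integers(DEFAULT_MIN_DIST, DEFAULT_MAX_DIST + 1))
            motif = _motif_instance(rng, spacer)
            conformant = True
        plant_box(cds, motif, gd)
        manifest.planted_hrp_boxes.append(
            PlantedBox(item["gene_id"], motif, spacer, gd,
                       conformant, kind if kind in
                       ("wrong_spacer", "wrong_distance", "mutated_core") else "conformant")
        )
        if kind == "effector":
            manifest.planted_effectors.append(PlantedEffector(item["gene_id"], None))
        elif kind == "effector_decoy":
            manifest.planted_effectors.append(
                PlantedEffector(item["gene_id"], item["violated"])
            )

    # ---- cluster block: diverged homologs of the panel, shared orientation
    for i, comp in enumerate(comp_names):
        entry = panel.get(comp)
        mutated = _mutate_protein(rng, entry.sequence, config.cluster_mutation_rate)
        cds_nt = _reverse_translate(rng, mutated)
        start = cluster_start + i * _CLUSTER_PITCH + _CLUSTER_CDS_OFFSET
        end = start + len(cds_nt) - 1
        write_at(start, cds_nt)
        gene_id = f"cluster_{comp}"
        features.append(
            CDSFeature(gene_id, config.contig_id, start, end, "+", mutated)
        )
        manifest.planted_cluster.append(
            PlantedComponent(gene_id, comp, config.cluster_mutation_rate)
        )

    genome = AnnotatedGenome(
        config.genome_id, {config.contig_id: buf.decode()}, features
    )
    manifest.background = {
        "genome_length": config.genome_length,
        "gc_content": config.gc_content,
        "cds_count": len(features),
        "accidental_cores_patched": n_patched,
    }

    _verify_planted_truth(genome, manifest)
    return genome, manifest


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float) -> str:
    out = list(protein)
    for i in range(1, len(out)):  # keep the initiator Met
        if rng.random() < rate:
            choices = _AA20.replace(out[i], "")
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _verify_planted_truth(genome: AnnotatedGenome, manifest: PlantManifest) -> None:
    table = screen_genome(genome, HRP_BOX_SCREEN, DEFAULT_MIN_DIST, DEFAULT_MAX_DIST)
    found = set(table["gene_id"]) if len(table) else set()
    expected = manifest.conformant_box_genes
    if found != expected:
        raise GeneratorError(
            f"planted-truth verification failed: unexpected={sorted(found - expected)}, "
            f"missing={sorted(expected - found)}"
        )


def save_genome(
    genome: AnnotatedGenome, manifest: PlantManifest, outdir: str | Path
) -> dict[str, Path]:
    """Emit GenBank, FASTA + GFF3, and the JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genbank": outdir / f"{genome.genome_id}.gbk",
        "fasta": outdir / f"{genome.genome_id}.fasta",
        "gff3": outdir / f"{genome.genome_id}.gff3",
        "manifest": outdir / f"{genome.genome_id}.manifest.json",
    }
    write_genbank(genome, paths["genbank"])
    write_fasta(genome.contigs.items(), paths["fasta"])
    write_gff3(genome, paths["gff3"])
    manifest.to_json(paths["manifest"])
    return paths


# ------------------------------------------------------ alignment simulator

_TS_PARTNER = np.array([2, 3, 0, 1])       # A<->G, C<->T in ACGT order
_TV_PARTNER_1 = np.array([1, 0, 1, 0])
_TV_PARTNER_2 = np.array([3, 2, 3, 2])


def generate_alignment(
    tree: str | TreeNode | PhyloTree,
    model: Literal["k80", "jc_protein"] = "k80",
    length: int = 1000,
    seed: int = 0,
    kappa: float = 4.0,
) -> tuple[MSA, PhyloTree]:
    """Evolve sequences along a tree under K80 (with kappa) or 20-state JC.

    Branch lengths are in expected substitutions per site; the simulation
    uses the models' exact finite-time substitution probabilities per
    branch.  Returns the alignment and the true tree.
    """
    if length < 1:
        raise ConfigError("alignment length must be >= 1")
    if model == "k80" and kappa <= 0:
        raise ConfigError("kappa must be > 0")
    if isinstance(tree, PhyloTree):
        root = tree.tree
    elif isinstance(tree, TreeNode):
        root = tree
    else:
        root = TreeNode.read(StringIO(tree), format="newick")
    rng = np.random.default_rng(seed)
    n_states = 4 if model == "k80" else 20
    alphabet = _NT if model == "k80" else _AA20

    def evolve(seq: np.ndarray, bl: float) -> np.ndarray:
        if bl <= 0:
            return seq.copy()
        u = rng.random(seq.size)
        out = seq.copy()
        if model == "k80":
            beta = 1.0 / (kappa + 2.0)
            alpha = kappa * beta
            e1 = np.exp(-4.0 * beta * bl)
            e2 = np.exp(-2.0 * (alpha + beta) * bl)
            p_tv_each = 0.25 - 0.25 * e1
            p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
            p_same = 1.0 - p_ts - 2.0 * p_tv_each
            ts = (u >= p_same) & (u < p_same + p_ts)
            tv1 = (u >= p_same + p_ts) & (u < p_same + p_ts + p_tv_each)
            tv2 = u >= p_same + p_ts + p_tv_each
            out[ts] = _TS_PARTNER[seq[ts]]
            out[tv1] = _TV_PARTNER_1[seq[tv1]]
            out[tv2] = _TV_PARTNER_2[seq[tv2]]
        else:
            e = np.exp(-20.0 * bl / 19.0)
            p_same = 1.0 / 20.0 + (19.0 / 20.0) * e
            change = u >= p_same
            shift = rng.integers(1, n_states, size=int(change.sum()))
            out[change] = (seq[change] + shift) % n_states
        return out

    taxa: list[str] = []
    rows: list[str] = []

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            cseq = evolve(seq, child.length or 0.0)
            if child.is_tip():
                taxa.append(child.name)
                rows.append("".join(alphabet[i] for i in cseq))
            else:
                walk(child, cseq)

    root_seq = rng.integers(0, n_states, size=length)
    walk(root, root_seq)
    msa = MSA(tuple(taxa), tuple(rows))
    true_tree = PhyloTree(tree=root, taxa=tuple(sorted(taxa)))
    return msa, true_tree


def random_additive_tree(
    n_taxa: int,
    rng: np.random.Generator,
    min_bl: float = 0.05,
    max_bl: float = 1.0,
) -> PhyloTree:
    """Random unrooted binary tree with strictly positive branch lengths."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")
    nodes = [TreeNode(name=f"T{i + 1:02d}") for i in range(n_taxa)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(min_bl, max_bl))
        b.length = float(rng.uniform(min_bl, max_bl))
        new = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [new]
    for n in nodes:
        n.length = float(rng.uniform(min_bl, max_bl))
    root = TreeNode(children=nodes)
    taxa = tuple(sorted(t.name for t in root.tips()))
    return PhyloTree(tree=root, taxa=taxa)


def tree_distances(ptree: PhyloTree) -> DistanceMatrix:
    """Tip-to-tip path-sum distances of a tree (the additive matrix)."""
    dm = ptree.tree.tip_tip_distances()
    taxa = tuple(dm.ids)
    return DistanceMatrix(taxa, np.asarray(dm.data, dtype=float))
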