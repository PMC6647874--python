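"""Local alignment against the component panel and cluster chaining."""

import numpy as np
import pytest

from _oracles import sw_score
from t3mine.clusters import (
    AlignmentError,
    CORE_COMPONENTS,
    assemble_clusters,
    default_panel,
    find_components,
    local_align,
)
from t3mine.genome import AnnotatedGenome, CDSFeature
from t3mine.simulate import GenomeSimConfig, generate_genome

AA = "ACDEFGHIKLMNPQRSTVWY"


def test_identical_sequences_align_perfectly():
    seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIE"
    res = local_align(seq, seq)
    assert res.percent_identity == 100.0
    assert res.coverage == 1.0


def test_textbook_pair_blosum50():
    """The classic HEAGAWGHEE / PAWHEAE local alignment scores 28."""
    res = local_align("HEAGAWGHEE", "PAWHEAE", matrix="BLOSUM50", gap_open=8, gap_extend=8)
    assert res.score == 28.0
    assert sw_score("HEAGAWGHEE", "PAWHEAE", "BLOSUM50", 8, 8) == 28.0


def test_score_symmetry():
    a, b = "MKTAYIAKQR", "MKTWYIAKHR"
    assert local_align(a, b).score == local_align(b, a).score


def test_unknown_residue_is_named():
    with pytest.raises(AlignmentError, match="'1'"):
        local_align("MK1T", "MKAT")


def test_matches_exhaustive_dp_on_random_pairs():
    """local_align score equals the Gotoh DP oracle for short random pairs."""
    rng = np.random.default_rng(11)
    for _ in range(100):
        a = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(5, 31)))
        b = "".join(AA[i] for i in rng.integers(0, 20, rng.integers(5, 31)))
        assert local_align(a, b).score == pytest.approx(sw_score(a, b))


def test_panel_sequence_found_verbatim():
    panel = default_panel()
    entry = panel.get("rscC")
    nt_len = 3 * (len(entry.sequence) + 1)
    genome = AnnotatedGenome(
        "t",
        {"c": "A" * nt_len},
        [CDSFeature("g1", "c", 1, nt_len, "+", protein=entry.sequence)],
    )
    hits = find_components(genome, panel)
    assert len(hits) == 1
    assert hits[0].component_name == "rscC"
    assert hits[0].percent_identity == 100.0


def test_half_mutated_homolog_still_detected():
    """Mutate 50% of positions with a fixed seed; identity stays >= 30%."""
    panel = default_panel()
    entry = panel.get("rscN")
    rng = np.random.default_rng(5)
    seq = list(entry.sequence)
    n_mut = len(seq) // 2
    for i in rng.choice(len(seq), size=n_mut, replace=False):
        seq[i] = AA[(AA.index(seq[i]) + 1 + rng.integers(19)) % 20]
    mutated = "".join(seq)
    direct_identity = 100 * sum(x == y for x, y in zip(mutated, entry.sequence)) / len(seq)
    assert direct_identity >= 30.0
    genome = AnnotatedGenome(
        "t", {"c": "A" * (3 * len(seq) + 3)},
        [CDSFeature("g1", "c", 1, 3 * len(seq) + 3, "+", protein=mutated)],
    )
    hits = find_components(genome, panel)
    assert [h.component_name for h in hits] == ["rscN"]


def test_random_proteome_yields_no_hits():
    """Empirical null: unrelated random proteins fail default thresholds."""
    rng = np.random.default_rng(17)
    feats, contigs = [], {}
    for i in range(10):
        protein = "M" + "".join(AA[j] for j in rng.integers(0, 20, 249))
        cid = f"c{i}"
        contigs[cid] = "A" * 753
        feats.append(CDSFeature(f"g{i}", cid, 1, 753, "+", protein=protein))
    genome = AnnotatedGenome("t", contigs, feats)
    assert find_components(genome) == []


@pytest.fixture(scope="module")
def planted_cluster():
    genome, manifest = generate_genome(
        GenomeSimConfig(
            genome_length=120_000,
            n_conformant_boxes=0, n_decoy_wrong_spacer=0, n_decoy_wrong_distance=0,
            n_decoy_mutated_core=0, n_effectors=0, n_effector_decoys=0,
            n_background_genes=5,
        ),
        seed=13,
    )
    return genome, manifest


def test_planted_cluster_recovered_with_span(planted_cluster):
    genome, manifest = planted_cluster
    hits = find_components(genome)
    clusters = assemble_clusters(hits, genome)
    assert len(clusters) == 1
    c = clusters[0]
    assert len(c.member_hits) == len(manifest.planted_cluster)
    planted = [genome.get_cds(p.gene_id) for p in manifest.planted_cluster]
    assert c.start == min(f.start for f in planted)
    assert c.end == max(f.end for f in planted)
    assert c.missing_components == ()
    recovered = {h.gene_id: h.component_name for h in c.member_hits}
    assert recovered == {p.gene_id: p.component_name for p in manifest.planted_cluster}


def test_cluster_assembly_is_order_invariant(planted_cluster):
    genome, _ = planted_cluster
    hits = find_components(genome)
    fwd = assemble_clusters(hits, genome)
    rev = assemble_clusters(list(reversed(hits)), genome)
    assert fwd == rev


def test_large_gap_splits_and_max_gap_monotone(planted_cluster):
    genome, _ = planted_cluster
    hits = find_components(genome)
    joined = assemble_clusters(hits, genome, max_gap=50_000)
    tight = assemble_clusters(hits, genome, max_gap=100)
    assert len(joined) <= len(tight)
    assert len(joined) == 1
    # drop the middle member so a >max_gap hole splits the chain
    mid = len(hits) // 2
    split = assemble_clusters(hits[:mid] + hits[mid + 1:], genome, max_gap=1000)
    assert len(split) == 2


def test_missing_core_components_reported(planted_cluster):
    genome, _ = planted_cluster
    hits = [h for h in find_components(genome) if h.component_name != "rscV"]
    clusters = assemble_clusters(hits, genome, max_gap=10_000)
    assert all("rscV" in c.missing_components for c in clusters)
    assert "rscV" in CORE_COMPONENTS


def test_zero_hits_zero_clusters(planted_cluster):
    genome, _ = planted_cluster
    assert assemble_clusters([], genome) == []
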