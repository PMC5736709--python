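"""Proteome survey, identity clustering and taxon tabulation."""

import numpy as np
import pytest

from sbs.simulate import ProteomeConfig, gen_proteome
from sbs.survey import (
    cooccurrence_fraction,
    genus_counts,
    pairwise_identity,
    reduce_redundancy,
    survey_proteomes,
    tabulate_taxa,
)


@pytest.fixture(scope="module")
def planted_survey(models, seed_families):
    cfg = ProteomeConfig(n_proteins=50, cbm40_rate=0.6, cooccurrence_rate=0.7,
                         decoy_rate=0.5)
    sim = gen_proteome(seed_families, cfg, seed=42)
    records = survey_proteomes(
        sim.proteins, models["canonical"], models["vibrio"], models["gh33"],
        [models["decoy"]], combined_model=models["combined"],
        taxonomy=sim.taxonomy,
    )
    return sim, records


def test_survey_matches_planted_truth(planted_survey):
    sim, records = planted_survey
    planted_pos = {p for p, t in sim.truth.items()
                   if t["kind"] in ("canonical", "vibrio")}
    assert {r.sequence_id for r in records} == planted_pos
    for r in records:
        t = sim.truth[r.sequence_id]
        assert r.best_label == t["kind"]
        assert r.has_sialidase == t["has_gh33"]
        assert r.taxon == t["taxon"]
    # deterministic ordering
    assert [r.sequence_id for r in records] == sorted(r.sequence_id for r in records)


def test_empty_proteome_gives_empty_survey(models):
    assert survey_proteomes([], models["canonical"], models["vibrio"],
                            models["gh33"]) == []


def test_decoy_only_proteome_gives_empty_survey(models, seed_families):
    cfg = ProteomeConfig(n_proteins=10, cbm40_rate=0.0, decoy_rate=1.0)
    sim = gen_proteome(seed_families, cfg, seed=9)
    records = survey_proteomes(
        sim.proteins, models["canonical"], models["vibrio"], models["gh33"],
        [models["decoy"]],
    )
    assert records == []


def test_duplicate_ids_rejected(models):
    with pytest.raises(ValueError, match="duplicate"):
        survey_proteomes([("p1", "ACD"), ("p1", "ACD")],
                         models["canonical"], models["vibrio"], None)


def test_cooccurrence_fraction_recovers_planted_rate(planted_survey):
    sim, records = planted_survey
    frac_can = cooccurrence_fraction(records, "canonical")
    frac_vib = cooccurrence_fraction(records, "vibrio")
    planted = {
        lab: np.mean([t["has_gh33"] for t in sim.truth.values() if t["kind"] == lab])
        for lab in ("canonical", "vibrio")
    }
    assert frac_can == pytest.approx(planted["canonical"])
    assert frac_vib == pytest.approx(planted["vibrio"])


def test_cooccurrence_empty_class_errors(planted_survey):
    _, records = planted_survey
    with pytest.raises(ValueError, match="empty class"):
        cooccurrence_fraction(records, "no-such-label")


# ------------------------------------------------------------ identity
def test_identity_identical_sequences():
    assert pairwise_identity("ACDEF", "ACDEF", "aligned_columns") == 100.0
    assert pairwise_identity("ACDEF", "ACDEF", "global_align") == 100.0


def test_identity_gap_counts_as_mismatch():
    # 3 identities over 4 scored columns
    assert pairwise_identity("AC-D", "ACED", "aligned_columns") == 75.0


def test_identity_double_gap_columns_excluded():
    assert pairwise_identity("AC--D", "AC--D", "aligned_columns") == 100.0


def test_identity_disjoint_residues():
    assert pairwise_identity("AAAA", "WWWW", "aligned_columns") == 0.0


def test_identity_length_mismatch_errors():
    with pytest.raises(ValueError):
        pairwise_identity("ACD", "AC", "aligned_columns")


# ---------------------------------------------------------- clustering
def test_identical_sequences_cluster_together():
    cs = reduce_redundancy([("a", "ACDEFGHIKL"), ("b", "ACDEFGHIKL")])
    assert len(cs.clusters) == 1
    assert sorted(cs.clusters[0][1]) == ["a", "b"]


def test_mutually_similar_trio_forms_one_cluster():
    base = "ACDEFGHIKLMNPQRSTVWY" * 2
    variants = [base, base[:5] + "W" + base[6:], base[:11] + "C" + base[12:]]
    cs = reduce_redundancy(list(zip("abc", variants)), threshold=0.80)
    assert len(cs.clusters) == 1


def test_dissimilar_pair_stays_apart(rng):
    from sbs.alphabet import AA, BACKGROUND
    a = "".join(rng.choice(list(AA), size=60, p=BACKGROUND))
    b = "".join(rng.choice(list(AA), size=60, p=BACKGROUND))
    cs = reduce_redundancy([("a", a), ("b", b)], threshold=0.80)
    assert len(cs.clusters) == 2


def test_clustering_idempotent_and_threshold_monotone(seed_families, rng):
    # family members plus mild mutants: realistic redundancy structure
    from sbs.alphabet import AA
    seqs = []
    for i, (rid, row) in enumerate(seed_families["canonical"]):
        seq = row.replace("-", "")
        seqs.append((rid, seq))
        mutant = list(seq)
        for pos in rng.choice(len(mutant), size=max(len(mutant) // 20, 1),
                              replace=False):
            mutant[pos] = AA[rng.integers(20)]
        seqs.append((rid + "_mut", "".join(mutant)))
    prev_n = None
    for thr in (0.5, 0.8, 0.95):
        cs = reduce_redundancy(seqs, threshold=thr)
        # partition property
        members = sorted(m for _, ms in cs.clusters for m in ms)
        assert members == sorted(s for s, _ in seqs)
        # idempotence: clustering representatives again gives singletons
        reps = [(r, dict(seqs)[r]) for r in cs.representatives]
        cs2 = reduce_redundancy(reps, threshold=thr)
        assert all(len(ms) == 1 for _, ms in cs2.clusters)
        if prev_n is not None:
            assert len(cs.clusters) >= prev_n
        prev_n = len(cs.clusters)


def test_clustering_rejects_empty_input():
    with pytest.raises(ValueError):
        reduce_redundancy([])


# ----------------------------------------------------------- tabulation
def test_tabulate_planted_taxa(planted_survey):
    sim, records = planted_survey
    seqs = [(r.sequence_id, dict(sim.proteins)[r.sequence_id]) for r in records]
    clusters = reduce_redundancy(seqs, threshold=0.80)
    table = tabulate_taxa(records, clusters)
    assert table["count"].sum() == len(clusters.clusters)
    by_id = {r.sequence_id: r for r in records}
    expected_genera = {
        lab: len({by_id[rep].taxon[2] for rep in clusters.representatives
                  if by_id[rep].best_label == lab})
        for lab in {by_id[rep].best_label for rep in clusters.representatives}
    }
    assert genus_counts(table).to_dict() == expected_genera


def test_tabulate_unknown_taxon_binned_not_dropped(models, seed_families):
    cfg = ProteomeConfig(n_proteins=12, cbm40_rate=1.0)
    sim = gen_proteome(seed_families, cfg, seed=3)
    records = survey_proteomes(
        sim.proteins, models["canonical"], models["vibrio"], None,
        taxonomy=None,  # nobody has a taxon
    )
    assert records
    clusters = reduce_redundancy(
        [(r.sequence_id, dict(sim.proteins)[r.sequence_id]) for r in records]
    )
    table = tabulate_taxa(records, clusters)
    assert set(table["phylum"]) == {"unclassified"}
    assert table["count"].sum() == len(clusters.clusters)


def test_tabulate_missing_record_errors(planted_survey):
    from sbs.survey import ClusterSet
    _, records = planted_survey
    clusters = ClusterSet(clusters=[("ghost", ["ghost"])], identity_threshold=0.8)
    with pytest.raises(KeyError):
        tabulate_taxa(records, clusters)
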