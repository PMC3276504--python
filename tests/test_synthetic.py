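import numpy as np
import pytest
from scipy import stats

from reversig import overlap as ovl
from reversig import synthetic as syn
from reversig import window_opt as wop
from reversig.io_formats import annotation_index
from reversig.ranking import Window, rank_all_compounds, rank_disease


def test_config_validation():
    with pytest.raises(ValueError):
        syn.SimulationConfig(n_genes=0)
    with pytest.raises(ValueError):
        syn.SimulationConfig(reversal_noise=1.5)
    with pytest.raises(ValueError):
        syn.SimulationConfig(n_planted_reversers=5, n_compounds=4)


def test_same_seed_identical_outputs():
    a = syn.simulate_dataset(syn.SimulationConfig(seed=11))
    b = syn.simulate_dataset(syn.SimulationConfig(seed=11))
    np.testing.assert_array_equal(a.tissue.values, b.tissue.values)
    np.testing.assert_array_equal(a.bank.ranks, b.bank.ranks)
    assert a.truth.planted_compounds == b.truth.planted_compounds
    c = syn.simulate_dataset(syn.SimulationConfig(seed=12))
    assert not np.array_equal(a.tissue.values, c.tissue.values)


def test_zero_effect_tissue_has_no_de_signal():
    cfg = syn.SimulationConfig(seed=1, effect_size=0.0, filter_shift_fraction=0.0)
    tissue, de, targets = syn.simulate_tissue(cfg)
    assert targets == frozenset()
    normal = tissue.values[:, tissue.group_indices("normal")]
    disease = tissue.values[:, tissue.group_indices("disease")]
    _, p = stats.ttest_ind(normal, disease, axis=1, equal_var=False)
    q = ovl.bh_adjust(p)
    assert (q < 0.01).sum() == 0


def test_large_effect_de_genes_fill_extreme_windows():
    cfg = syn.SimulationConfig(
        seed=2, n_genes=500, de_fraction=0.1, effect_size=10.0,
        filter_shift_fraction=0.0, n_normal=5, n_disease=5,
    )
    tissue, de, _ = syn.simulate_tissue(cfg)
    rl = rank_disease(tissue, tissue.gene_ids)
    up = {g for g, s in de.items() if s > 0}
    down = {g for g, s in de.items() if s < 0}
    assert up <= rl.top(len(up))
    assert down <= rl.bottom(len(down))


def test_noiseless_reversal_full_overlap_every_k():
    cfg = syn.SimulationConfig(seed=3, n_genes=300, n_compounds=5, reversal_noise=0.0)
    tissue, _, _ = syn.simulate_tissue(cfg)
    disease = rank_disease(tissue, tissue.gene_ids)
    bank, planted = syn.simulate_compound_bank(cfg, disease)
    compounds = rank_all_compounds(
        bank, cfg.cell_line, tissue.gene_ids, {p: p for p in bank.probe_ids}
    )
    name = sorted(planted)[0]
    for k in (10, 50, 100):
        tests = ovl.test_all_compounds(disease, compounds, Window(k), Window(k))
        for t in tests:
            if t.compound == name:
                assert t.overlap == k


def test_full_noise_indistinguishable_from_random():
    cfg = syn.SimulationConfig(seed=4, n_genes=500, n_compounds=5, reversal_noise=1.0)
    tissue, _, _ = syn.simulate_tissue(cfg)
    disease = rank_disease(tissue, tissue.gene_ids)
    bank, planted = syn.simulate_compound_bank(cfg, disease)
    compounds = rank_all_compounds(
        bank, cfg.cell_line, tissue.gene_ids, {p: p for p in bank.probe_ids}
    )
    name = sorted(planted)[0]
    k = 50
    tests = ovl.test_all_compounds(disease, compounds, Window(k), Window(k))
    for t in tests:
        if t.compound == name:
            # expected null overlap k^2/N = 5; a fully shuffled planted list
            # should sit well inside the null bulk
            assert t.overlap < 15
            assert t.p_value > 1e-4


def test_noise_fraction_controls_overlap_concentration():
    # overlap of the planted compound at k concentrates near (1 - noise) * k
    k, n = 100, 2000
    overlaps = []
    for seed in range(10):
        cfg = syn.SimulationConfig(
            seed=seed, n_genes=n, n_compounds=2, reversal_noise=0.1,
            min_instances=1, max_instances=1,
        )
        tissue, _, _ = syn.simulate_tissue(cfg)
        disease = rank_disease(tissue, tissue.gene_ids)
        bank, planted = syn.simulate_compound_bank(cfg, disease)
        compounds = rank_all_compounds(
            bank, cfg.cell_line, tissue.gene_ids, {p: p for p in bank.probe_ids}
        )
        name = sorted(planted)[0]
        tests = ovl.test_all_compounds(disease, compounds, Window(k), Window(k))
        overlaps += [t.overlap for t in tests if t.compound == name]
    assert 80 <= np.mean(overlaps) <= 95


def test_annotations_enable_window_evaluation(default_dataset):
    ds = default_dataset
    anns = annotation_index(ds.annotations)
    tissue = ds.tissue
    disease = rank_disease(tissue, tissue.gene_ids)
    compounds = rank_all_compounds(
        ds.bank, ds.config.cell_line, tissue.gene_ids, ds.probe2gene
    )
    rec = wop.evaluate_k(disease, compounds, 100, anns, ds.config.target_disease)
    assert rec.sensitivity == 1.0
    assert rec.recovered_drugs == ds.truth.positives


def test_decoy_enrichment_p_uniformish(default_dataset):
    # decoy sets are uniform draws: their enrichment p-values against a random
    # query should not pile up near zero
    from reversig import enrichment as enr

    ds = default_dataset
    rng = np.random.default_rng(9)
    universe = list(ds.tissue.gene_ids)
    ps = []
    for _ in range(20):
        query = list(rng.choice(universe, size=50, replace=False))
        for r in enr.enrich(query, ds.gene_sets, universe, alpha=1.1):
            if r.set_id.startswith("path-decoy"):
                ps.append(r.p_value)
    assert np.mean(np.array(ps) < 0.05) < 0.15


def test_planted_pathway_detected(default_dataset):
    from reversig import enrichment as enr

    ds = default_dataset
    universe = list(ds.tissue.gene_ids)
    members = sorted(ds.gene_sets.sets[ds.truth.planted_set_id].members)
    results = enr.enrich(members, ds.gene_sets, universe, alpha=0.05)
    assert any(r.set_id == ds.truth.planted_set_id for r in results)


def test_no_planted_reversers_yields_no_discoveries():
    hits = 0
    for seed in range(3):
        cfg = syn.SimulationConfig(seed=seed, n_planted_reversers=0, n_compounds=30)
        tissue, _, _ = syn.simulate_tissue(cfg)
        disease = rank_disease(tissue, tissue.gene_ids)
        bank, _ = syn.simulate_compound_bank(cfg, disease)
        compounds = rank_all_compounds(
            bank, cfg.cell_line, tissue.gene_ids, {p: p for p in bank.probe_ids}
        )
        tests = ovl.test_all_compounds(disease, compounds, Window(100), Window(100))
        hits += sum(t.significant for t in tests)
    assert hits == 0


def test_truth_labels_match_annotations(default_dataset):
    ds = default_dataset
    anns = annotation_index(ds.annotations)
    for name in ds.truth.positives:
        assert anns[name].fda_approved
        assert ds.config.target_disease.lower() in anns[name].approved_indications
    for name in ds.truth.negatives:
        assert ds.config.target_disease.lower() in anns[name].failed_trial_indications
        assert name not in ds.truth.planted_compounds
    assert ds.truth.positives <= ds.truth.planted_compounds


def test_write_dataset_round_trip(tmp_path, default_dataset):
    from reversig import io_formats as iof

    paths = syn.write_dataset(default_dataset, tmp_path)
    tissue = iof.read_gds(paths["tissue"])
    np.testing.assert_array_equal(tissue.values, default_dataset.tissue.values)
    bank = iof.read_rank_matrix(paths["rank_matrix"], paths["rank_annotations"])
    np.testing.assert_array_equal(bank.ranks, default_dataset.bank.ranks)
    truth_text = paths["truth"].read_text()
    assert "planted_reverser" in truth_text
    assert f"# seed = {default_dataset.config.seed}" in truth_text
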