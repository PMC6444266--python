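"""The quartet generator: replayability, determinism, planted structure."""

import dataclasses

import pytest

from plastovar.io import find_quadripartite, gc_content, revcomp
from plastovar.simulate import (
    NRIndelPlan,
    SNPPlan,
    SSRPlan,
    SimulationConfig,
    default_config,
    generate_ancestor,
    replay_taxon,
    simulate_quartet,
)
from plastovar.variation import AlignmentSet, call_snps


def test_replay_reproduces_each_genome_bit_exactly(quartet):
    for taxon in quartet.config.taxa:
        assert replay_taxon(quartet.ledger, taxon) == quartet.genomes[taxon].sequence


def test_alignment_degaps_to_genomes(quartet):
    for taxon in quartet.config.taxa:
        assert quartet.alignment[taxon].replace("-", "") == quartet.genomes[taxon].sequence


def test_seed_determinism():
    a = simulate_quartet(default_config(seed=5))
    b = simulate_quartet(default_config(seed=5))
    assert a.alignment == b.alignment
    assert a.ledger.events == b.ledger.events
    c = simulate_quartet(default_config(seed=6))
    assert c.alignment != a.alignment


def test_ancestor_gc_near_target(quartet):
    gc = gc_content(quartet.ancestor.record)
    assert abs(gc - quartet.config.gc) < 0.005


def test_planted_structure_recovered_for_any_sufficient_min_ir(quartet):
    planted = quartet.ancestor.structure
    for min_ir in (500, 1500, planted.ir_length):
        st = find_quadripartite(quartet.ancestor.record, min_ir=min_ir)
        assert (st.irb.start, st.irb.length) == (planted.irb.start, planted.irb.length)
        assert (st.ssc.start, st.ssc.length) == (planted.ssc.start, planted.ssc.length)


def test_ledger_counts_match_plan(quartet):
    counts = quartet.ledger.counts()
    assert counts["snp_sites"] == 60
    assert counts["transitions"] == 40 and counts["transversions"] == 20
    assert counts["ssr_indels"] == 12 and counts["nr_indels"] == 15
    assert counts["inversions"] == 3


def test_zero_event_plan_gives_identical_genomes():
    config = SimulationConfig(
        seed=2,
        genome_length=8000,
        ssr_plan=[SSRPlan("A", 12, "LSC")],
        n_genes=6,
    )
    res = simulate_quartet(config)
    seqs = {r.sequence for r in res.genomes.values()}
    assert len(seqs) == 1
    assert res.ledger.counts()["snp_sites"] == 0


def test_ir_mirrored_snp_preserves_ir_identity_and_counts_two_columns():
    config = SimulationConfig(
        seed=3,
        genome_length=12000,
        n_genes=6,
        snp_plan=[SNPPlan("taxonB", "A→G/T→C", "IR")],
    )
    res = simulate_quartet(config)
    rec = res.genomes["taxonB"]
    st = find_quadripartite(rec, min_ir=500)
    assert st.irb.extract(rec.sequence) == revcomp(st.ira.extract(rec.sequence))
    aln = AlignmentSet(
        taxa=list(config.taxa),
        rows=[res.alignment[t] for t in config.taxa],
        reference_taxon=config.reference,
    )
    sites = call_snps(aln)
    assert len(sites) == 2  # one biological event, two alignment sites
    assert all(s.classes == ("A→G/T→C",) for s in sites)
    assert res.ledger.counts()["snp_sites"] == 2


def test_overflowing_plan_raises():
    config = SimulationConfig(
        seed=0,
        genome_length=3000,
        ssr_plan=[SSRPlan("A", 100, "SSC") for _ in range(20)],
    )
    with pytest.raises(ValueError, match="overflow|place"):
        generate_ancestor(config)


def test_inversion_in_ir_rejected():
    from plastovar.simulate import InversionPlan

    config = dataclasses.replace(
        default_config(0), inversion_plan=[InversionPlan("taxonB", 4, 8, "IR")]
    )
    with pytest.raises(ValueError, match="IR"):
        simulate_quartet(config)


def test_nr_indel_sequences_recorded_and_replayable():
    config = SimulationConfig(
        seed=4,
        genome_length=9000,
        n_genes=5,
        nr_indel_plan=[NRIndelPlan(("taxonC",), 7, "ins"), NRIndelPlan(("taxonD",), 9, "del")],
    )
    res = simulate_quartet(config)
    for taxon in config.taxa:
        assert replay_taxon(res.ledger, taxon) == res.genomes[taxon].sequence
    lengths = sorted(e["length"] for e in res.ledger.events)
    assert lengths == [7, 9]


def test_truth_ledger_json_round_trip(tmp_path, quartet):
    from plastovar.simulate import TruthLedger

    path = tmp_path / "ledger.json"
    quartet.ledger.to_json(path)
    back = TruthLedger.from_json(path)
    assert back.events == quartet.ledger.events
    assert back.alignment == quartet.ledger.alignment
    assert back.counts() == quartet.ledger.counts()
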